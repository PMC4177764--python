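"""ORF scanning under phage-annotation validity criteria, and genome
summary statistics.

An ORF candidate is valid when it encodes at least ``min_aa`` amino acids
(30 by default), starts with ATG, GTG or TTG, and — optionally — shows a
Shine–Dalgarno ribosome-binding site an appropriate distance upstream.
The scanner is deliberately criterion-driven and is not meant to
reproduce HMM-based gene callers; statistics for deposited genomes are
computed from their deposited features via :func:`genome_stats`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genome_io import (
    Feature,
    GenomeRecord,
    START_CODONS,
    STOP_CODONS,
    feature_sequence,
    reverse_complement,
    translate_cds,
)

SD_CONSENSUS = "AGGAGGT"


@dataclass
class OrfCandidate:
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int
    strand: str
    start_codon: str
    length_aa: int  # amino acids encoded, stop excluded
    rbs_score: int = 0
    rbs_spacer: int | None = None
    wraps: bool = False

    def as_feature(self, locus_tag: str) -> Feature:
        return Feature(locus_tag=locus_tag, kind="CDS", start=self.start,
                       end=self.end, strand=self.strand, wraps=self.wraps)


def score_rbs(
    upstream: str,
    spacer_window: tuple[int, int] = (4, 18),
    consensus: str = SD_CONSENSUS,
) -> tuple[int, int | None]:
    """Score a putative Shine–Dalgarno site in the region upstream of a start.

    ``upstream`` is the sequence immediately 5' of the start codon on the
    coding strand (conventionally 30 nt; shorter near the ends of linear
    genomes).  The score is the length of the longest contiguous match to
    the consensus whose 3' end lies within the spacer window — the
    distance in nt between the end of the match and the start codon.
    Matches shorter than 3 score 0.

    Returns ``(score, spacer)``; spacer is None when the score is 0.
    Among equal-length matches the smallest spacer (closest to the start
    codon) is reported.
    """
    lo, hi = spacer_window
    n = len(upstream)
    best_k, best_spacer = 0, None
    for k in range(len(consensus), 2, -1):
        if k <= best_k:
            break
        for off in range(len(consensus) - k + 1):
            sub = consensus[off : off + k]
            pos = upstream.find(sub)
            while pos != -1:
                spacer = n - (pos + k)
                if lo <= spacer <= hi and (
                    k > best_k or (k == best_k and spacer < best_spacer)
                ):
                    best_k, best_spacer = k, spacer
                pos = upstream.find(sub, pos + 1)
    return best_k, best_spacer


def _stop_bounded_orfs(frame_seq: str, frame_offset: int, min_aa: int,
                       starts: tuple[str, ...], longest_per_stop: bool):
    """Yield (start_nt_idx, stop_end_nt_idx) pairs in frame-local 0-based
    coordinates; start index points at the first base of the start codon,
    stop_end_nt_idx at the base after the stop codon."""
    codons = [frame_seq[i : i + 3] for i in range(0, len(frame_seq) - 2, 3)]
    region_starts: list[int] = []
    for ci, codon in enumerate(codons):
        if codon in STOP_CODONS:
            emitted = False
            for s_ci in region_starts:
                if ci - s_ci >= min_aa:
                    yield frame_offset + 3 * s_ci, frame_offset + 3 * (ci + 1)
                    emitted = True
                    if longest_per_stop and emitted:
                        break
            region_starts = []
        elif codon in starts:
            region_starts.append(ci)


def scan_orfs(
    record: GenomeRecord,
    min_aa: int = 30,
    starts: tuple[str, ...] = START_CODONS,
    longest_per_stop: bool = False,
    require_rbs: bool = False,
    min_rbs_score: int = 4,
    spacer_window: tuple[int, int] = (4, 18),
) -> list[OrfCandidate]:
    """Scan all six reading frames for stop-bounded ORFs meeting the
    validity criteria.

    On circular genomes frames wrap the junction.  ``scan_orfs`` itself
    never filters on the RBS unless ``require_rbs`` is set, so the length
    and RBS criteria can be studied independently.
    """
    L = len(record)
    results: dict[tuple[int, int, str], OrfCandidate] = {}
    for strand in "+-":
        base = record.sequence if strand == "+" else reverse_complement(record.sequence)
        # doubling lets ORFs cross the junction; any ORF shorter than the
        # genome appears intact in the doubled sequence
        scan_seq = base + base[:-1] if record.circular else base
        for frame in range(3):
            for s_idx, e_idx in _stop_bounded_orfs(
                scan_seq[frame:], frame, min_aa, starts, longest_per_stop
            ):
                if s_idx >= L:  # duplicate of an ORF already seen
                    continue
                if e_idx - s_idx > L:
                    continue  # would overlap itself on the circle
                cand = _make_candidate(record, base, strand, s_idx, e_idx, L,
                                       spacer_window)
                key = (cand.start, cand.end, cand.strand)
                results.setdefault(key, cand)
    out = sorted(results.values(), key=lambda c: (c.start, c.end, c.strand))
    if require_rbs:
        out = [c for c in out if c.rbs_score >= min_rbs_score]
    return out


def _make_candidate(record, oriented_seq, strand, s_idx, e_idx, L,
                    spacer_window) -> OrfCandidate:
    start_codon = oriented_seq[s_idx % L : s_idx % L + 3]
    if len(start_codon) < 3:  # wraps
        doubled = oriented_seq + oriented_seq
        start_codon = doubled[s_idx % L : s_idx % L + 3]
    # upstream 30 nt on the coding strand
    if record.circular:
        doubled = oriented_seq + oriented_seq
        up = doubled[s_idx % L + L - 30 : s_idx % L + L]
    else:
        up = oriented_seq[max(0, s_idx - 30) : s_idx]
    score, spacer = score_rbs(up, spacer_window)
    # map oriented-frame coordinates back to forward-strand 1-based coords
    if strand == "+":
        f_start = s_idx % L + 1
        f_end = (e_idx - 1) % L + 1
    else:
        f_start = L - ((e_idx - 1) % L)
        f_end = L - (s_idx % L)
    wraps = f_start > f_end
    return OrfCandidate(
        start=f_start, end=f_end, strand=strand, start_codon=start_codon,
        length_aa=(e_idx - s_idx) // 3 - 1, rbs_score=score, rbs_spacer=spacer,
        wraps=wraps,
    )


@dataclass
class GenomeStats:
    """Headline annotation statistics for one genome (a Table-1 analogue)."""

    genome_id: str
    length_bp: int
    gc_percent: float
    n_cds: int
    n_trna: int
    gene_density: float  # CDSs per kbp, 1 decimal
    coding_percent: float  # % of genome covered by >=1 CDS (span union)
    avg_product_aa: float
    min_product_aa: int
    max_product_aa: int
    start_codon_counts: Counter = field(default_factory=Counter)
    stop_codon_counts: Counter = field(default_factory=Counter)
    malformed: int = 0

    def to_dict(self) -> dict:
        d = {
            "genome_id": self.genome_id,
            "length_bp": self.length_bp,
            "gc_percent": round(self.gc_percent, 2),
            "n_cds": self.n_cds,
            "n_trna": self.n_trna,
            "gene_density": self.gene_density,
            "coding_percent": round(self.coding_percent, 1),
            "avg_product_aa": round(self.avg_product_aa, 1),
            "min_product_aa": self.min_product_aa,
            "max_product_aa": self.max_product_aa,
            "malformed": self.malformed,
        }
        for codon in START_CODONS:
            d[f"start_{codon}"] = self.start_codon_counts.get(codon, 0)
        for codon in STOP_CODONS:
            d[f"stop_{codon}"] = self.stop_codon_counts.get(codon, 0)
        return d


def _span_union(intervals: list[tuple[int, int]], L: int) -> int:
    """Total length covered by 1-based inclusive intervals on [1, L]."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    covered += cur_e - cur_s + 1
    return covered


def genome_stats(record: GenomeRecord) -> GenomeStats:
    """Compute annotation statistics from a record's deposited features.

    coding_percent counts each base once however many CDSs cover it
    (span-union semantics); start/stop tallies and product lengths come
    from the extracted feature sequences; CDSs whose length is not
    divisible by 3 are excluded from codon tallies and counted as
    ``malformed``.
    """
    cds = record.cds()
    if not cds:
        raise ValueError(f"record {record.id} has no CDS features")
    L = len(record)
    intervals: list[tuple[int, int]] = []
    for f in cds:
        if f.wraps:
            intervals.append((f.start, L))
            intervals.append((1, f.end))
        else:
            intervals.append((f.start, f.end))
    starts: Counter = Counter()
    stops: Counter = Counter()
    product_lengths: list[int] = []
    malformed = 0
    for f in cds:
        nt = feature_sequence(record, f)
        if len(nt) % 3 != 0 or len(nt) < 6:
            malformed += 1
            continue
        starts[nt[:3]] += 1
        stops[nt[-3:]] += 1
        product_lengths.append(len(nt) // 3 - 1)
    return GenomeStats(
        genome_id=record.id,
        length_bp=L,
        gc_percent=record.gc_percent(),
        n_cds=len(cds),
        n_trna=len(record.trnas()),
        gene_density=round(len(cds) / (L / 1000.0), 1),
        coding_percent=100.0 * _span_union(intervals, L) / L,
        avg_product_aa=sum(product_lengths) / len(product_lengths)
        if product_lengths else 0.0,
        min_product_aa=min(product_lengths) if product_lengths else 0,
        max_product_aa=max(product_lengths) if product_lengths else 0,
        start_codon_counts=starts,
        stop_codon_counts=stops,
        malformed=malformed,
    )
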