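"""Codon-usage tables, optimal codons, CAI, anticodon decoding and the
tRNA-optimality statistic.

Phage-encoded tRNAs are thought to compensate for codon-usage differences
between phage and host.  The headline statistic here asks, for each tRNA
a phage carries: does the codon that tRNA decodes (the reverse complement
of its anticodon, exact Watson-Crick pairing) coincide with the *optimal*
codon — the most frequently used synonymous codon — for that amino acid
across all of the phage's genes?  Suppressor/pyrrolysine tRNAs decode
stop codons and are never counted as optimality-related.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome_io import reverse_complement

_BASES = "TCAG"
ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def _codon_to_aa(table_id: int = 11) -> dict[str, str]:
    tab = unambiguous_dna_by_id[table_id]
    mapping = dict(tab.forward_table)
    for stop in tab.stop_codons:
        mapping[stop] = "*"
    return mapping


CODON_TO_AA = _codon_to_aa(11)
SYNONYMOUS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    SYNONYMOUS.setdefault(_aa, []).append(_codon)
for _aa in SYNONYMOUS:
    SYNONYMOUS[_aa].sort()


@dataclass
class CodonUsageTable:
    counts: Counter = field(default_factory=Counter)
    n_sequences: int = 0
    n_skipped_sequences: int = 0  # inputs whose length was not divisible by 3

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def per_thousand(self) -> dict[str, float]:
        t = self.total_codons
        return {c: 1000.0 * self.counts.get(c, 0) / t for c in ALL_CODONS} if t else {}

    def per_aa_fraction(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for aa, codons in SYNONYMOUS.items():
            tot = sum(self.counts.get(c, 0) for c in codons)
            if tot:
                out[aa] = {c: self.counts.get(c, 0) / tot for c in codons}
        return out

    def scaled(self, k: int) -> "CodonUsageTable":
        return CodonUsageTable(
            counts=Counter({c: n * k for c, n in self.counts.items()}),
            n_sequences=self.n_sequences,
        )


def codon_usage(cds_seqs) -> CodonUsageTable:
    """Count codons, in reading frame, across a collection of CDSs.

    Terminal stop codons are included in the counts; codons containing N
    are skipped; sequences whose length is not divisible by 3 are skipped
    entirely and tallied in ``n_skipped_sequences``.
    """
    table = CodonUsageTable()
    any_input = False
    for seq in cds_seqs:
        any_input = True
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            table.n_skipped_sequences += 1
            continue
        table.n_sequences += 1
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                continue
            table.counts[codon] += 1
    if not any_input:
        raise ValueError("codon_usage: empty input")
    return table


def optimal_codons(table: CodonUsageTable) -> dict[str, str]:
    """The most-frequent synonymous codon per amino acid.

    Stop codons are excluded; ties break lexicographically; amino acids
    absent from the table are omitted.
    """
    if table.total_codons == 0:
        raise ValueError("optimal_codons: empty table")
    out: dict[str, str] = {}
    for aa, codons in SYNONYMOUS.items():
        if aa == "*":
            continue
        present = [(c, table.counts.get(c, 0)) for c in codons]
        top = max(n for _, n in present)
        if top > 0:
            # codons are sorted, so the first argmax is the lexicographic tie-break
            out[aa] = next(c for c, n in present if n == top)
    return out


_WOBBLE_THIRD = {"G": ("C", "T"), "T": ("A", "G"), "A": ("T",), "C": ("G",)}


def decode_anticodon(anticodon: str, wobble: bool = False) -> set[str]:
    """Codons read by a tRNA with the given anticodon (written 5'->3').

    With ``wobble=False`` the single exact Watson-Crick codon (the reverse
    complement) is returned.  With ``wobble=True`` the 5' anticodon base
    pairs loosely with the codon third position: anticodon-5' G also reads
    codon-3' T, and anticodon-5' U(T) also reads codon-3' G.
    """
    anticodon = anticodon.upper().replace("U", "T")
    if len(anticodon) != 3 or any(c not in "ACGT" for c in anticodon):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    exact = reverse_complement(anticodon)
    if not wobble:
        return {exact}
    return {exact[:2] + third for third in _WOBBLE_THIRD[anticodon[0]]}


@dataclass
class TrnaGene:
    locus_tag: str
    amino_acid: str  # 3-letter code, or Sup/Pyl for stop-decoding tRNAs
    anticodon: str
    start: int = 0
    end: int = 0
    strand: str = "+"
    sequence: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1 if self.end else len(self.sequence)

    def gc_percent(self) -> float:
        s = self.sequence
        if not s:
            return float("nan")
        return 100.0 * (s.count("G") + s.count("C")) / len(s)


@dataclass
class OptimalityReport:
    rows: list[dict]  # per-tRNA: locus, aa, anticodon, codon, is_optimal, a_ending
    optimal: dict[str, str]
    n_trnas: int
    n_optimal_trnas: int
    n_a_ending: int


#: amino acids whose tRNAs decode stop codons
STOP_DECODERS = {"Sup", "Pyl", "Sec*", "Ter"}

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


def trna_optimality(trnas, optimal: dict[str, str]) -> OptimalityReport:
    """Relate a phage's tRNA set to its optimal codon usage.

    A tRNA is optimality-related iff its exact-pairing decoded codon
    equals the optimal codon of its amino acid.  Stop-decoding tRNAs
    (suppressor/Pyl) count in ``n_trnas`` but are never optimality-related.
    ``n_a_ending`` counts tRNAs whose decoded codon has A in the third
    position.
    """
    rows = []
    n_opt = 0
    n_a = 0
    for t in trnas:
        codon = next(iter(decode_anticodon(t.anticodon, wobble=False)))
        aa1 = _THREE_TO_ONE.get(t.amino_acid, None)
        decodes_stop = t.amino_acid in STOP_DECODERS or CODON_TO_AA.get(codon) == "*"
        is_opt = (not decodes_stop) and aa1 is not None and optimal.get(aa1) == codon
        a_ending = codon.endswith("A")
        rows.append({
            "locus_tag": t.locus_tag, "amino_acid": t.amino_acid,
            "anticodon": t.anticodon, "decoded_codon": codon,
            "decodes_stop": decodes_stop, "is_optimal": is_opt,
            "a_ending": a_ending,
        })
        n_opt += is_opt
        n_a += a_ending
    return OptimalityReport(rows=rows, optimal=optimal, n_trnas=len(rows),
                            n_optimal_trnas=n_opt, n_a_ending=n_a)


def cai(gene_cds: str, table: CodonUsageTable, w_floor: float = 0.01) -> float:
    """Codon adaptation index of one gene against a reference usage table.

    Geometric mean of per-codon relative adaptiveness
    ``w = count(codon) / count(best synonymous codon)``.  Stop codons,
    single-codon amino acids (Met, Trp) and codons containing N are
    excluded; ``w`` is floored for codons unobserved in the reference.
    """
    gene_cds = gene_cds.upper().replace("U", "T")
    if len(gene_cds) % 3 != 0:
        raise ValueError("CAI: CDS length not divisible by 3")
    log_sum = 0.0
    n = 0
    for i in range(0, len(gene_cds), 3):
        codon = gene_cds[i : i + 3]
        if "N" in codon:
            continue
        aa = CODON_TO_AA.get(codon)
        if aa is None or aa == "*" or len(SYNONYMOUS[aa]) == 1:
            continue
        best = max(table.counts.get(c, 0) for c in SYNONYMOUS[aa])
        if best == 0:
            continue
        w = max(table.counts.get(codon, 0) / best, w_floor)
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise ValueError("CAI: no scorable codons")
    return math.exp(log_sum / n)


def compare_trnas(
    set_a,
    set_b,
    min_coverage: float = 50.0,
    min_identity: float = 70.0,
) -> list[dict]:
    """Cross-genome tRNA homology by local nucleotide alignment.

    Mirrors a BLASTn-style comparison but reports deterministic
    coverage/identity pairs: match +2, mismatch -3, gap open 5, extend 2.
    Coverage is of the query (set_a) tRNA.  Pairs above both thresholds
    are reported.
    """
    from .proteome_compare import align

    out = []
    for ta in set_a:
        for tb in set_b:
            if not ta.sequence or not tb.sequence:
                continue
            res = align(ta.sequence, tb.sequence, mode="local", seq_type="nt")
            if res.identity_percent >= min_identity and res.coverage_query > min_coverage:
                out.append({
                    "query": ta.locus_tag, "subject": tb.locus_tag,
                    "query_aa": ta.amino_acid, "subject_aa": tb.amino_acid,
                    "coverage": res.coverage_query,
                    "identity": res.identity_percent,
                })
    return out
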