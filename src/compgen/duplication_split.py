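"""Lineage-specific duplications, duplication-vs-convergence
classification, and split-gene detection.

Two genes of one genome that align significantly at the protein level are
duplication *candidates*.  True duplications of an ancestral gene should
retain significant nucleotide identity as well, because protein
similarity then reflects accumulated point mutations on a shared DNA
template; candidates whose proteins align but whose DNA does not are
better explained by convergent evolution (similar proteins reached
through unrelated codon choices).  "Significant nucleotide identity" is
operationalised as >= ``nt_min_identity`` over >= ``nt_min_coverage`` of
the shorter CDS; both thresholds surface in every report.

A *split gene* is one gene of genome B represented by two or more genes
of genome A whose alignments tile (near-)disjoint segments of it — the
classic case being an ancestral ~680-aa ADP-ribosyltransferase gene
represented by fragments covering roughly its first and last thirds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GenomeRecord, feature_sequence
from .proteome_compare import AlignmentResult, Proteome, align, alignment_score, evalue, proteome_from_record


@dataclass
class DuplicationCall:
    gene_a: str
    gene_b: str
    aa_identity: float
    aa_evalue: float
    aa_coverage: float  # of the shorter protein
    nt_identity: float | None = None
    nt_coverage: float | None = None  # of the shorter CDS
    verdict: str = "candidate"  # duplication | convergent | ambiguous
    thresholds: dict = field(default_factory=dict)


def find_duplications(
    record: GenomeRecord,
    max_evalue: float = 1e-3,
    proteome: Proteome | None = None,
) -> list[DuplicationCall]:
    """Protein-level duplication candidates within one genome.

    All unordered CDS pairs are locally aligned at the amino-acid level;
    pairs reaching ``max_evalue`` are emitted once, without a verdict
    (see :func:`classify_duplication`).  The cut-off is looser than for
    cross-genome homologs because within-genome paralogs are typically
    anciently diverged (25-30% identity).
    """
    prot = proteome if proteome is not None else proteome_from_record(record)
    if len(prot.genes) < 2:
        raise ValueError("find_duplications needs >= 2 well-formed CDSs")
    calls = []
    genes = prot.genes
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            sc = alignment_score(a.sequence, b.sequence, seq_type="aa")
            e = evalue(sc, len(a.sequence), len(b.sequence))
            if e > max_evalue:
                continue
            res = align(a.sequence, b.sequence, seq_type="aa")
            short = min(len(a.sequence), len(b.sequence))
            cov = 100.0 * (res.q_end - res.q_start + 1) / short
            calls.append(DuplicationCall(
                gene_a=a.locus_tag, gene_b=b.locus_tag,
                aa_identity=res.identity_percent, aa_evalue=res.evalue,
                aa_coverage=min(cov, 100.0),
            ))
    return calls


def classify_duplication(
    call: DuplicationCall,
    record: GenomeRecord,
    nt_min_identity: float = 65.0,
    nt_min_coverage: float = 50.0,
    aa_max_evalue: float = 1e-3,
) -> DuplicationCall:
    """Assign duplication / convergent / ambiguous to a candidate pair.

    The pair's CDSs are locally aligned at the nucleotide level.
    ``duplication`` requires nt identity >= ``nt_min_identity`` over an
    aligned span >= ``nt_min_coverage`` % of the shorter CDS;
    ``convergent`` is a pair whose protein alignment is significant but
    whose DNA alignment fails that profile; anything else is
    ``ambiguous``.
    """
    feats = {f.locus_tag: f for f in record.cds()}
    fa, fb = feats[call.gene_a], feats[call.gene_b]
    nta = feature_sequence(record, fa)
    ntb = feature_sequence(record, fb)
    res = align(nta, ntb, mode="local", seq_type="nt")
    short = min(len(nta), len(ntb))
    nt_cov = 100.0 * (res.q_end - res.q_start + 1) / short if res.n_columns else 0.0
    nt_cov = min(nt_cov, 100.0)
    call.nt_identity = res.identity_percent
    call.nt_coverage = nt_cov
    call.thresholds = {
        "nt_min_identity": nt_min_identity,
        "nt_min_coverage": nt_min_coverage,
        "aa_max_evalue": aa_max_evalue,
    }
    nt_ok = res.identity_percent >= nt_min_identity and nt_cov >= nt_min_coverage
    if nt_ok:
        call.verdict = "duplication"
    elif call.aa_evalue <= aa_max_evalue:
        call.verdict = "convergent"
    else:
        call.verdict = "ambiguous"
    return call


def call_duplications(record: GenomeRecord, max_evalue: float = 1e-3,
                      nt_min_identity: float = 65.0,
                      nt_min_coverage: float = 50.0) -> list[DuplicationCall]:
    """find_duplications + classify_duplication in one pass."""
    return [
        classify_duplication(c, record, nt_min_identity=nt_min_identity,
                             nt_min_coverage=nt_min_coverage,
                             aa_max_evalue=max_evalue)
        for c in find_duplications(record, max_evalue=max_evalue)
    ]


@dataclass
class FragmentHit:
    fragment: str  # locus in the fragment proteome
    t_start: int  # aligned segment on the target protein, 1-based aa
    t_end: int
    identity: float
    evalue: float


@dataclass
class SplitCall:
    target: str
    fragments: list[FragmentHit]  # ordered by target-segment start
    combined_coverage: float  # % of target covered by the union of segments
    max_pairwise_overlap: float  # % of the shorter segment
    thresholds: dict = field(default_factory=dict)


def detect_splits(
    target_proteome: Proteome,
    fragment_proteome: Proteome,
    max_evalue: float = 1e-3,
    max_overlap: float = 20.0,
    min_combined_coverage: float = 50.0,
) -> list[SplitCall]:
    """Find target genes tiled by >= 2 near-disjoint fragment genes.

    For each target protein, every fragment protein reaching
    ``max_evalue`` contributes its aligned segment on the target.  A set
    of >= 2 segments qualifies when every pair overlaps by at most
    ``max_overlap`` % of the shorter segment and the union covers at
    least ``min_combined_coverage`` % of the target.  Fragments are
    assembled greedily in order of target-segment start, so the result is
    invariant to input order.
    """
    calls = []
    for t in target_proteome.genes:
        hits: list[FragmentHit] = []
        for f in fragment_proteome.genes:
            if t.locus_tag == f.locus_tag and target_proteome.genome_id == fragment_proteome.genome_id:
                continue
            sc = alignment_score(t.sequence, f.sequence, seq_type="aa")
            e = evalue(sc, len(t.sequence), len(f.sequence))
            if e > max_evalue:
                continue
            res = align(t.sequence, f.sequence, seq_type="aa")
            hits.append(FragmentHit(fragment=f.locus_tag, t_start=res.q_start,
                                    t_end=res.q_end,
                                    identity=res.identity_percent,
                                    evalue=res.evalue))
        if len(hits) < 2:
            continue
        # strongest evidence first, so spurious weak hits cannot displace
        # a true fragment sharing the same segment
        hits.sort(key=lambda h: (h.evalue, h.t_start, h.fragment))
        chosen: list[FragmentHit] = []
        max_ov = 0.0
        for h in hits:
            ok = all(_overlap_percent(c, h) <= max_overlap for c in chosen)
            if ok:
                for c in chosen:
                    max_ov = max(max_ov, _overlap_percent(c, h))
                chosen.append(h)
        if len(chosen) < 2:
            continue
        chosen.sort(key=lambda h: (h.t_start, h.t_end, h.fragment))
        cov = 100.0 * _union_length(chosen) / len(t.sequence)
        if cov < min_combined_coverage:
            continue
        calls.append(SplitCall(
            target=t.locus_tag, fragments=chosen,
            combined_coverage=cov, max_pairwise_overlap=max_ov,
            thresholds={"max_evalue": max_evalue, "max_overlap": max_overlap,
                        "min_combined_coverage": min_combined_coverage},
        ))
    return calls


def _overlap_percent(a: FragmentHit, b: FragmentHit) -> float:
    ov = min(a.t_end, b.t_end) - max(a.t_start, b.t_start) + 1
    if ov <= 0:
        return 0.0
    shorter = min(a.t_end - a.t_start + 1, b.t_end - b.t_start + 1)
    return 100.0 * ov / shorter


def _union_length(hits: list[FragmentHit]) -> int:
    ivs = sorted((h.t_start, h.t_end) for h in hits)
    total = 0
    cs, ce = ivs[0]
    for s, e in ivs[1:]:
        if s <= ce + 1:
            ce = max(ce, e)
        else:
            total += ce - cs + 1
            cs, ce = s, e
    total += ce - cs + 1
    return total
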