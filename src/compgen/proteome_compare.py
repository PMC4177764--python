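"""Pairwise alignment, E-values, homolog calling, core-genome matrices
and synteny blocks.

Alignment is affine-gap dynamic programming (Smith-Waterman / Needleman-
Wunsch via Bio.Align.PairwiseAligner): BLOSUM62 with gap open 11 / extend
1 for proteins, +2/-3 with gap open 5 / extend 2 for nucleotides (a gap
of length k costs open + k*extend).  Statistical significance uses the
Karlin-Altschul formula E = K*m*n*exp(-lambda*S) with gapped-BLOSUM62
defaults (lambda=0.267, K=0.041).

Homology is best-hit per query at an E-value cut-off (1e-6 by default,
the conventional threshold for phage proteome comparisons); a reference
gene is "core" when every other genome in the comparison has a qualifying
homolog.  Synteny blocks are maximal runs of homolog pairs monotone in
both genomes' gene orders, with a bounded number of skipped genes;
inverted blocks (descending in the second genome) are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GenomeRecord, cds_protein, feature_sequence

LAMBDA_DEFAULT = 0.267
K_DEFAULT = 0.041

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")
_NT_ALPHABET = set("ACGTN")


class AlignmentError(ValueError):
    pass


@dataclass
class AlignmentResult:
    score: float
    identity_percent: float
    coverage_query: float
    coverage_subject: float
    q_start: int  # 1-based bounds of the aligned segment
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    n_columns: int = 0  # aligned columns excluding gaps
    n_identical: int = 0


def evalue(score: float, m: int, n: int,
           lam: float = LAMBDA_DEFAULT, K: float = K_DEFAULT) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    return K * m * n * math.exp(-lam * score)


def _nt_matrix() -> substitution_matrices.Array:
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                mat[a, b] = 0
            else:
                mat[a, b] = 2 if a == b else -3
    return mat


_MATRICES: dict[str, substitution_matrices.Array] = {}


def _aligner(mode: str, seq_type: str, gap_open: float | None,
             gap_extend: float | None) -> Align.PairwiseAligner:
    if seq_type == "aa":
        if "aa" not in _MATRICES:
            _MATRICES["aa"] = substitution_matrices.load("BLOSUM62")
        matrix = _MATRICES["aa"]
        go = 11 if gap_open is None else gap_open
        ge = 1 if gap_extend is None else gap_extend
    else:
        if "nt" not in _MATRICES:
            _MATRICES["nt"] = _nt_matrix()
        matrix = _MATRICES["nt"]
        go = 5 if gap_open is None else gap_open
        ge = 2 if gap_extend is None else gap_extend
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    aligner.mode = mode
    aligner.open_gap_score = -(go + ge)  # first gap residue costs open+extend
    aligner.extend_gap_score = -ge
    return aligner


def _infer_type(seq: str) -> str:
    s = set(seq.upper())
    if s <= _NT_ALPHABET:
        return "nt"
    if s <= _AA_ALPHABET:
        return "aa"
    raise AlignmentError(f"unrecognised residues {sorted(s - _AA_ALPHABET)}")


def alignment_score(a: str, b: str, mode: str = "local",
                    seq_type: str = "auto",
                    gap_open: float | None = None,
                    gap_extend: float | None = None) -> float:
    """Alignment score only (no traceback) — cheap for all-vs-all scans."""
    if seq_type == "auto":
        seq_type = _resolve_types(a, b)
    return float(_aligner(mode, seq_type, gap_open, gap_extend).score(a, b))


def _resolve_types(a: str, b: str) -> str:
    ta, tb = _infer_type(a), _infer_type(b)
    if ta != tb:
        raise AlignmentError(f"mixed alphabets: {ta} vs {tb}")
    return ta


def align(a: str, b: str, mode: str = "local", seq_type: str = "auto",
          gap_open: float | None = None, gap_extend: float | None = None,
          lam: float = LAMBDA_DEFAULT, K: float = K_DEFAULT) -> AlignmentResult:
    """Align two sequences and report score, identity, coverage and E-value.

    Identity is computed over aligned columns excluding gaps; coverage is
    the aligned-segment span as a percentage of each sequence's length.
    """
    if not a or not b:
        raise AlignmentError("empty sequence")
    if seq_type == "auto":
        seq_type = _resolve_types(a, b)
    aligner = _aligner(mode, seq_type, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    score = float(aln.score)
    q_blocks, s_blocks = aln.aligned
    n_cols = 0
    n_id = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        n_cols += qe - qs
        n_id += sum(1 for x, y in zip(a[qs:qe], b[ss:se]) if x == y)
    if n_cols == 0:
        return AlignmentResult(score=score, identity_percent=0.0,
                               coverage_query=0.0, coverage_subject=0.0,
                               q_start=0, q_end=0, s_start=0, s_end=0,
                               evalue=evalue(max(score, 0.0), len(a), len(b), lam, K))
    q_start, q_end = int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])
    return AlignmentResult(
        score=score,
        identity_percent=100.0 * n_id / n_cols,
        coverage_query=100.0 * (q_end - q_start + 1) / len(a),
        coverage_subject=100.0 * (s_end - s_start + 1) / len(b),
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        evalue=evalue(max(score, 0.0), len(a), len(b), lam, K),
        n_columns=n_cols, n_identical=n_id,
    )


# ---------------------------------------------------------------------------
# Proteomes and homolog tables

@dataclass
class ProteinGene:
    locus_tag: str
    sequence: str  # amino acids
    index: int  # gene-order index in its genome
    strand: str = "+"
    start: int = 0  # genomic coordinate, for reports


@dataclass
class Proteome:
    genome_id: str
    genes: list[ProteinGene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def by_locus(self) -> dict[str, ProteinGene]:
        return {g.locus_tag: g for g in self.genes}


def proteome_from_record(record: GenomeRecord) -> Proteome:
    """Translate a record's CDS features into an ordered proteome.

    Malformed CDSs (length not divisible by 3) are skipped.
    """
    genes = []
    idx = 0
    for f in sorted(record.cds(), key=lambda f: f.start):
        nt = feature_sequence(record, f)
        if len(nt) % 3 != 0 or len(nt) < 6:
            continue
        tr = cds_protein(record, f)
        genes.append(ProteinGene(locus_tag=f.locus_tag, sequence=tr.protein,
                                 index=idx, strand=f.strand, start=f.start))
        idx += 1
    return Proteome(genome_id=record.id, genes=genes)


def find_homologs(
    proteome_a: Proteome,
    proteome_b: Proteome,
    max_evalue: float = 1e-6,
    min_identity: float | None = None,
    min_coverage: float | None = None,
    reciprocal: bool = False,
) -> pd.DataFrame:
    """Best-hit homologs from every gene of A into B.

    All-vs-all local protein alignment; for each query the subject with
    the smallest E-value is kept if it passes ``max_evalue`` (and the
    optional identity/query-coverage profile).  Self-pairs are excluded
    when A and B are the same proteome.  With ``reciprocal=True`` only
    reciprocal best hits are kept.

    Returns a DataFrame with one row per homolog pair.
    """
    if not proteome_a.genes or not proteome_b.genes:
        raise ValueError("find_homologs: empty proteome")
    same = proteome_a.genome_id == proteome_b.genome_id

    def best_hits(pa: Proteome, pb: Proteome) -> dict[str, tuple[ProteinGene, AlignmentResult]]:
        hits = {}
        for q in pa.genes:
            best: tuple[ProteinGene, float] | None = None
            for s in pb.genes:
                if same and q.locus_tag == s.locus_tag:
                    continue
                sc = alignment_score(q.sequence, s.sequence, seq_type="aa")
                e = evalue(sc, len(q.sequence), len(s.sequence))
                if best is None or e < best[1]:
                    best = (s, e)
            if best is None or best[1] > max_evalue:
                continue
            res = align(q.sequence, best[0].sequence, seq_type="aa")
            if min_identity is not None and res.identity_percent < min_identity:
                continue
            if min_coverage is not None and res.coverage_query < min_coverage:
                continue
            hits[q.locus_tag] = (best[0], res)
        return hits

    fwd = best_hits(proteome_a, proteome_b)
    if reciprocal:
        rev = best_hits(proteome_b, proteome_a)
        fwd = {
            q: (s, r) for q, (s, r) in fwd.items()
            if s.locus_tag in rev and rev[s.locus_tag][0].locus_tag == q
        }
    idx_a = {g.locus_tag: g for g in proteome_a.genes}
    rows = []
    for q_locus, (s_gene, res) in fwd.items():
        q_gene = idx_a[q_locus]
        rows.append({
            "query": q_locus, "subject": s_gene.locus_tag,
            "q_index": q_gene.index, "s_index": s_gene.index,
            "q_strand": q_gene.strand, "s_strand": s_gene.strand,
            "score": res.score, "evalue": res.evalue,
            "identity": res.identity_percent,
            "coverage_q": res.coverage_query, "coverage_s": res.coverage_subject,
            "q_start": res.q_start, "q_end": res.q_end,
            "s_start": res.s_start, "s_end": res.s_end,
        })
    df = pd.DataFrame(rows, columns=[
        "query", "subject", "q_index", "s_index", "q_strand", "s_strand",
        "score", "evalue", "identity", "coverage_q", "coverage_s",
        "q_start", "q_end", "s_start", "s_end",
    ])
    return df.sort_values("q_index").reset_index(drop=True)


@dataclass
class CoreGenomeResult:
    reference: str
    presence: pd.DataFrame  # bool, index = reference loci, columns = other genomes
    core: list[str]  # reference loci with a homolog in every other genome
    shared_counts: dict[str, int]  # reference genes with a homolog, per genome
    max_identity: dict[str, float]  # best pairwise identity, per genome
    homolog_tables: dict[str, pd.DataFrame]


def core_genome(
    proteomes: list[Proteome],
    reference: int = 0,
    max_evalue: float = 1e-6,
    min_identity: float | None = None,
    min_coverage: float | None = None,
) -> CoreGenomeResult:
    """Presence/absence of reference genes across genomes, and the core set.

    A reference gene is core iff it has a qualifying homolog in every
    other genome.  Per-genome shared counts and maximum identities mirror
    the headline cross-genome summaries of phage comparative papers.
    """
    if len(proteomes) < 2:
        raise ValueError("core_genome needs at least 2 proteomes")
    ref = proteomes[reference]
    others = [p for i, p in enumerate(proteomes) if i != reference]
    loci = [g.locus_tag for g in ref.genes]
    presence = pd.DataFrame(False, index=loci,
                            columns=[p.genome_id for p in others])
    tables = {}
    shared = {}
    max_ident = {}
    for p in others:
        df = find_homologs(ref, p, max_evalue=max_evalue,
                           min_identity=min_identity, min_coverage=min_coverage)
        tables[p.genome_id] = df
        presence.loc[df["query"].tolist(), p.genome_id] = True
        shared[p.genome_id] = int(len(df))
        max_ident[p.genome_id] = float(df["identity"].max()) if len(df) else 0.0
    core = presence.index[presence.all(axis=1)].tolist()
    return CoreGenomeResult(reference=ref.genome_id, presence=presence,
                            core=core, shared_counts=shared,
                            max_identity=max_ident, homolog_tables=tables)


# ---------------------------------------------------------------------------
# Synteny

@dataclass
class SyntenyBlock:
    pairs: list[tuple[str, str]]  # (query locus, subject locus) in block order
    q_indices: list[int]
    s_indices: list[int]
    orientation: str  # "colinear" | "inverted"

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SyntenyReport:
    blocks: list[SyntenyBlock]
    relocated: list[tuple[str, str]]  # homolog pairs in no block of length >= 2
    max_gap: int


def synteny_blocks(pairs: pd.DataFrame, max_gap: int = 3) -> SyntenyReport:
    """Chain homolog pairs into maximal gene-order-monotone blocks.

    ``pairs`` is a find_homologs table.  Within a block the subject
    indices are strictly increasing (colinear) or strictly decreasing
    (inverted), at most ``max_gap`` genes are skipped between consecutive
    pairs in either genome, and the strand relation is consistent
    (homologs of an inverted block sit on opposite strands).  Pairs in no
    block of length >= 2 are reported as relocated.
    """
    df = pairs.sort_values("q_index").reset_index(drop=True)
    blocks: list[SyntenyBlock] = []
    relocated: list[tuple[str, str]] = []
    cur: list[dict] = []
    cur_dir = 0  # +1 colinear, -1 inverted, 0 undetermined

    def flush():
        nonlocal cur, cur_dir
        if len(cur) >= 2:
            blocks.append(SyntenyBlock(
                pairs=[(r["query"], r["subject"]) for r in cur],
                q_indices=[int(r["q_index"]) for r in cur],
                s_indices=[int(r["s_index"]) for r in cur],
                orientation="inverted" if cur_dir == -1 else "colinear",
            ))
        elif cur:
            relocated.append((cur[0]["query"], cur[0]["subject"]))
        cur, cur_dir = [], 0

    for _, row in df.iterrows():
        r = row.to_dict()
        if not cur:
            cur = [r]
            continue
        prev = cur[-1]
        dq = r["q_index"] - prev["q_index"]
        ds = r["s_index"] - prev["s_index"]
        strand_rel = (r["q_strand"] == r["s_strand"])
        prev_rel = (prev["q_strand"] == prev["s_strand"])
        step_dir = 1 if ds > 0 else (-1 if ds < 0 else 0)
        ok = (
            0 < dq <= max_gap + 1
            and step_dir != 0
            and abs(ds) <= max_gap + 1
            and (cur_dir == 0 or step_dir == cur_dir)
            and strand_rel == prev_rel
        )
        if ok:
            cur.append(r)
            cur_dir = step_dir if cur_dir == 0 else cur_dir
        else:
            flush()
            cur = [r]
    flush()
    return SyntenyReport(blocks=blocks, relocated=relocated, max_gap=max_gap)


def shared_count_summary(result: CoreGenomeResult, n_ref_genes: int) -> pd.DataFrame:
    """Tabulate per-genome shared-homolog counts and percentages."""
    rows = []
    for gid, n in result.shared_counts.items():
        rows.append({
            "genome": gid, "shared_homologs": n,
            "shared_percent": round(100.0 * n / n_ref_genes, 1),
            "max_identity": round(result.max_identity[gid], 1),
        })
    return pd.DataFrame(rows)
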