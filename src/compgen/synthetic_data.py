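"""Synthetic phage-like genomes with known ground truth.

The generator emulates the salient features of T4-like phage genomes:
circular, AT-rich (~30-40% GC), densely packed with CDSs (~1.5 genes per
kbp, >90% coding), a Shine-Dalgarno motif a few nt upstream of every
start, a planted replication origin/terminus pair expressed as
two-replichore G/C strand asymmetry, and planted tRNA genes with chosen
anticodons.  :func:`evolve_genome` derives child genomes by point
mutation plus structural events (gene gain/loss, duplication, gene
splitting, block inversion), recording every event in a
:class:`SyntheticManifest` so that downstream detectors can be scored
against planted truth.

Genes are synthesised by sampling sense codons from a per-amino-acid
weight model; with no user weights the model is a single-parameter
GC-calibrated family ``q(codon) ~ theta^gc(codon)`` solved so realised
coding GC matches the target.  The replichore asymmetry is applied as a
multiplicative G-vs-C tilt on every freely chosen base (intergenic bases
and synonymous codon choice), with the tilt solved numerically so the
realised leading-strand skew matches ``skew_bias``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .codon_trna import CODON_TO_AA, SYNONYMOUS
from .genome_io import Feature, GenomeRecord, reverse_complement

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
STOP_WEIGHTS = {"TAA": 0.70, "TGA": 0.26, "TAG": 0.04}
RBS_MOTIF = "AGGAGG"

#: the tRNA complement of phage ZZ1 (amino acid, anticodon), used as the
#: default planted tRNA set; all on the minus strand as in the annotation
ZZ1_TRNAS: list[tuple[str, str]] = [
    ("Trp", "CCA"), ("Pro", "TGG"), ("Ser", "TGA"), ("Thr", "TGT"),
    ("Cys", "GCA"), ("Met", "CAT"), ("Arg", "TCT"), ("Sup", "CTA"),
]


@dataclass
class TrnaPlant:
    amino_acid: str
    anticodon: str
    strand: str = "-"
    length: int = 76


@dataclass
class GenomeSpec:
    """Study conditions for one synthetic genome.

    Defaults mirror a (scaled-down) T4-like Acinetobacter phage: 40 kbp
    circular genome at 35% GC, 1.5 genes/kbp with ~200-aa products,
    leading-strand GC skew 0.05, terminus at nt 1 and origin mid-genome,
    and the 8-tRNA ZZ1 complement.
    """

    length_bp: int = 40_000
    gc_percent: float = 35.0
    n_genes: int | None = None  # default: 1.5 genes per kbp
    gene_length_mean_aa: float = 200.0
    gene_length_sd_aa: float = 60.0
    gene_length_min_aa: int = 40
    min_intergenic: int = 30
    codon_weights: dict[str, dict[str, float]] | None = None  # per aa (1-letter)
    skew_bias: float = 0.05  # target leading-strand (G-C)/(G+C), in (0, 0.2)
    origin_pos: int | None = None  # default: length // 2
    terminus_pos: int = 1
    lead_strand_frac: float = 0.7  # genes co-oriented with the leading strand
    trnas: Sequence[TrnaPlant] | None = None  # None -> ZZ1 complement
    genome_id: str = "synth"

    def resolved_n_genes(self) -> int:
        return self.n_genes if self.n_genes is not None else round(self.length_bp * 0.0015)

    def resolved_origin(self) -> int:
        return self.origin_pos if self.origin_pos is not None else self.length_bp // 2

    def resolved_trnas(self) -> list[TrnaPlant]:
        if self.trnas is not None:
            return list(self.trnas)
        return [TrnaPlant(aa, ac) for aa, ac in ZZ1_TRNAS]


@dataclass
class GeneTruth:
    locus_tag: str
    family: str
    strand: str
    cds: str  # gene-strand sequence, start codon through stop codon
    protein: str  # translation, Met-initiated, stop stripped
    start: int = 0  # forward-strand 1-based coordinates, filled at assembly
    end: int = 0


@dataclass
class TrnaTruth:
    locus_tag: str
    amino_acid: str
    anticodon: str
    strand: str
    sequence: str  # gene-strand
    start: int = 0
    end: int = 0


@dataclass
class SyntheticManifest:
    genome_id: str
    origin_pos: int
    terminus_pos: int
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    trnas: dict[str, TrnaTruth] = field(default_factory=dict)
    element_order: list = field(default_factory=list)  # ("gene",locus)|("trna",locus)|("spacer",seq)
    events: list[dict] = field(default_factory=list)
    parent_id: str | None = None
    gc_percent: float = 35.0
    skew_bias: float = 0.05

    def families(self) -> dict[str, str]:
        return {locus: g.family for locus, g in self.genes.items()}

    def to_json(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "parent_id": self.parent_id,
            "origin_pos": self.origin_pos,
            "terminus_pos": self.terminus_pos,
            "genes": {k: asdict(v) for k, v in self.genes.items()},
            "trnas": {k: asdict(v) for k, v in self.trnas.items()},
            "events": self.events,
        }


# ---------------------------------------------------------------------------
# codon model calibration

def _gc_count(codon: str) -> int:
    return sum(1 for b in codon if b in "GC")


def _base_codon_probs(spec: GenomeSpec) -> np.ndarray:
    """Per-codon sampling probabilities before the skew tilt."""
    if spec.codon_weights is not None:
        probs = np.zeros(len(SENSE_CODONS))
        per_aa = {}
        for aa, wmap in spec.codon_weights.items():
            tot = sum(wmap.values())
            per_aa[aa] = {c: w / tot for c, w in wmap.items()}
        aas = sorted(per_aa)
        for i, codon in enumerate(SENSE_CODONS):
            aa = CODON_TO_AA[codon]
            if aa in per_aa:
                probs[i] = per_aa[aa].get(codon, 0.0) / len(aas)
        if probs.sum() == 0:
            raise ValueError("codon_weights cover no sense codons")
        return probs / probs.sum()
    # one-parameter GC family, calibrated so mean coding GC = target
    gc = np.array([_gc_count(c) for c in SENSE_CODONS], dtype=float)

    def mean_gc(log_theta: float) -> float:
        w = np.exp(log_theta * gc)
        w /= w.sum()
        return float((w * gc).sum() / 3.0)

    target = spec.gc_percent / 100.0
    lo, hi = -4.0, 4.0
    target = min(max(target, mean_gc(lo) + 1e-6), mean_gc(hi) - 1e-6)
    log_theta = brentq(lambda x: mean_gc(x) - target, lo, hi)
    w = np.exp(log_theta * gc)
    return w / w.sum()


_G_CNT = None
_C_CNT = None


def _gc_vectors() -> tuple[np.ndarray, np.ndarray]:
    global _G_CNT, _C_CNT
    if _G_CNT is None:
        _G_CNT = np.array([c.count("G") for c in SENSE_CODONS], dtype=float)
        _C_CNT = np.array([c.count("C") for c in SENSE_CODONS], dtype=float)
    return _G_CNT, _C_CNT


def _tilted_probs(base: np.ndarray, t: float, favour_g_forward: bool,
                  gene_strand: str) -> np.ndarray:
    """Codon distribution under a forward-strand G-vs-C tilt of strength t."""
    g, c = _gc_vectors()
    # bases of a '-' gene appear complemented on the forward strand
    g_fwd, c_fwd = (g, c) if gene_strand == "+" else (c, g)
    if not favour_g_forward:
        g_fwd, c_fwd = c_fwd, g_fwd
    w = base * (1.0 + t) ** g_fwd * (1.0 - t) ** c_fwd
    return w / w.sum()


def _expected_arc_skew(t: float, base: np.ndarray,
                       coding_plus: int, coding_minus: int,
                       intergenic: int, gc_frac: float) -> float:
    """Expected forward-strand (G-C)/(G+C) on the G-favoured arc."""
    g, c = _gc_vectors()
    num = 0.0
    den = 0.0
    for strand, n_codons in (("+", coding_plus // 3), ("-", coding_minus // 3)):
        if n_codons == 0:
            continue
        p = _tilted_probs(base, t, True, strand)
        g_fwd = g if strand == "+" else c
        c_fwd = c if strand == "+" else g
        num += n_codons * float((p * (g_fwd - c_fwd)).sum())
        den += n_codons * float((p * (g_fwd + c_fwd)).sum())
    num += intergenic * gc_frac * t
    den += intergenic * gc_frac
    return num / den if den else 0.0


def _calibrate_tilt(spec: GenomeSpec, base: np.ndarray,
                    coding_plus: int, coding_minus: int,
                    intergenic: int) -> float:
    s = spec.skew_bias
    if s <= 0:
        return 0.0
    gc_frac = spec.gc_percent / 100.0
    f = lambda t: _expected_arc_skew(t, base, coding_plus, coding_minus,
                                     intergenic, gc_frac) - s
    hi = 0.95
    if f(hi) < 0:
        return hi  # saturate: requested skew not reachable at this coding density
    return float(brentq(f, 0.0, hi, xtol=1e-4))


# ---------------------------------------------------------------------------
# generation

def _in_g_arc(pos: int, ori: int, ter: int, L: int) -> bool:
    """True on the arc [ori, ter) walking forward — the arc on which the
    forward strand is the leading (G-rich) strand."""
    if ori < ter:
        return ori <= pos < ter
    return pos >= ori or pos < ter


def _sample_lengths(spec: GenomeSpec, rng: np.random.Generator,
                    n_genes: int) -> list[int]:
    aa = rng.normal(spec.gene_length_mean_aa, spec.gene_length_sd_aa, n_genes)
    aa = np.maximum(np.round(aa).astype(int), spec.gene_length_min_aa)
    return aa.tolist()


def _distribute_intergenic(total: int, n_gaps: int, min_gap: int,
                           rng: np.random.Generator) -> list[int]:
    extra = total - n_gaps * min_gap
    if extra < 0:
        raise ValueError(
            f"infeasible packing: {total} intergenic nt cannot host "
            f"{n_gaps} gaps of >= {min_gap} nt"
        )
    parts = rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps))
    return [min_gap + int(x) for x in parts]


def _sample_spacer(n: int, gc_frac: float, t: float, favour_g: bool,
                   rng: np.random.Generator) -> str:
    tilt = t if favour_g else -t
    pg = gc_frac / 2 * (1 + tilt)
    pc = gc_frac / 2 * (1 - tilt)
    pa = pt = (1 - gc_frac) / 2
    idx = rng.choice(4, size=n, p=[pa, pc, pg, pt])
    return "".join("ACGT"[i] for i in idx)


def _embed_rbs(spacer: str, next_gene_strand: str | None,
               prev_gene_strand: str | None, rng: np.random.Generator) -> str:
    s = list(spacer)
    if next_gene_strand == "+" and len(s) >= len(RBS_MOTIF) + 12:
        d = int(rng.integers(5, 12))  # spacer between motif end and start codon
        pos = len(s) - d - len(RBS_MOTIF)
        s[pos : pos + len(RBS_MOTIF)] = RBS_MOTIF
    if prev_gene_strand == "-" and len(s) >= len(RBS_MOTIF) + 12:
        d = int(rng.integers(5, 12))
        motif = reverse_complement(RBS_MOTIF)
        s[d : d + len(motif)] = motif
    return "".join(s)


def _sample_gene(n_aa: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    """A CDS of n_aa amino acids: ATG + (n_aa-1) sampled codons + stop."""
    idx = rng.choice(len(SENSE_CODONS), size=n_aa - 1, p=probs)
    body = "".join(SENSE_CODONS[i] for i in idx)
    stops, sw = zip(*STOP_WEIGHTS.items())
    stop = stops[rng.choice(len(stops), p=np.array(sw) / sum(sw))]
    return "ATG" + body + stop


def _translate_cds_str(cds: str) -> str:
    aa = "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds) - 3, 3))
    return "M" + aa[1:]


def _sample_trna(plant: TrnaPlant, gc_frac: float,
                 rng: np.random.Generator) -> str:
    idx = rng.choice(4, size=plant.length,
                     p=[(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2])
    s = list("ACGT"[i] for i in idx)
    s[32:35] = plant.anticodon  # anticodon in the canonical loop position
    return "".join(s)


def generate_genome(spec: GenomeSpec, seed: int = 0) -> tuple[GenomeRecord, SyntheticManifest]:
    """Generate one phage-like genome plus its ground-truth manifest.

    Deterministic under (spec, seed).  Raises on infeasible packing
    before emitting anything.
    """
    rng = np.random.default_rng(seed)
    L = spec.length_bp
    ori = spec.resolved_origin()
    ter = spec.terminus_pos
    if ori == ter:
        raise ValueError("origin and terminus must differ")
    n_genes = spec.resolved_n_genes()
    lengths_aa = _sample_lengths(spec, rng, n_genes)
    trna_plants = spec.resolved_trnas()
    trna_nt = sum(p.length for p in trna_plants)
    n_elements = n_genes + len(trna_plants)
    budget = L - trna_nt - n_elements * spec.min_intergenic
    coding_nt = sum(3 * a + 3 for a in lengths_aa)
    if coding_nt > budget:
        # sampled lengths overshoot the genome: shrink proportionally
        f = (budget - 3 * n_genes) / (3 * sum(lengths_aa))
        lengths_aa = [max(spec.gene_length_min_aa, int(a * f)) for a in lengths_aa]
        coding_nt = sum(3 * a + 3 for a in lengths_aa)
    intergenic_total = L - coding_nt - trna_nt
    gaps = _distribute_intergenic(intergenic_total, n_elements, spec.min_intergenic, rng)

    strands = [
        "+" if rng.random() < spec.lead_strand_frac else "-" for _ in range(n_genes)
    ]
    base = _base_codon_probs(spec)
    # plan forward-strand coding totals per replichore arc for calibration
    plan_pos = 1
    coding_plus = coding_minus = 0
    order = list(range(n_genes))
    trna_insert_at = int(rng.integers(0, n_genes + 1))
    for k, gi in enumerate(order):
        plan_pos += gaps[k]
        glen = 3 * lengths_aa[gi] + 3
        # composition is mirror-symmetric between the arcs, so the tilt is
        # calibrated once against the genome-wide strand split
        if strands[gi] == "+":
            coding_plus += glen
        else:
            coding_minus += glen
        plan_pos += glen
    tilt = _calibrate_tilt(spec, base, coding_plus, coding_minus,
                           max(intergenic_total, 0))
    probs = {
        (s, arc): _tilted_probs(base, tilt, arc, s)
        for s in "+-" for arc in (True, False)
    }

    manifest = SyntheticManifest(
        genome_id=spec.genome_id, origin_pos=ori, terminus_pos=ter,
        gc_percent=spec.gc_percent, skew_bias=spec.skew_bias,
    )
    gc_frac = spec.gc_percent / 100.0
    parts: list[str] = []
    pos = 1
    gap_i = 0
    gene_no = 0
    trna_no = 0

    def g_arc(p: int) -> bool:
        return _in_g_arc(p, ori, ter, L)

    items: list[tuple[str, int]] = []  # ("gene", original index) / ("trna", idx)
    for k in range(n_genes + 1):
        if k == trna_insert_at:
            items.extend(("trna", i) for i in range(len(trna_plants)))
        if k < n_genes:
            items.append(("gene", k))

    prev_strand: str | None = None
    for kind, idx in items:
        gap = gaps[gap_i]
        gap_i += 1
        strand_next = strands[idx] if kind == "gene" else None
        spacer = _sample_spacer(gap, gc_frac, tilt, g_arc(pos + gap // 2), rng)
        spacer = _embed_rbs(spacer, strand_next, prev_strand, rng)
        manifest.element_order.append(("spacer", spacer))
        parts.append(spacer)
        pos += gap
        if kind == "gene":
            strand = strands[idx]
            glen = 3 * lengths_aa[idx] + 3
            arc = g_arc(pos + glen // 2)
            cds = _sample_gene(lengths_aa[idx], probs[(strand, arc)], rng)
            gene_no += 1
            locus = f"g{gene_no:03d}"
            truth = GeneTruth(locus_tag=locus, family=f"fam{gene_no:04d}",
                              strand=strand, cds=cds,
                              protein=_translate_cds_str(cds),
                              start=pos, end=pos + glen - 1)
            manifest.genes[locus] = truth
            manifest.element_order.append(("gene", locus))
            parts.append(cds if strand == "+" else reverse_complement(cds))
            pos += glen
            prev_strand = strand
        else:
            plant = trna_plants[idx]
            seq = _sample_trna(plant, gc_frac, rng)
            trna_no += 1
            locus = f"t{trna_no:03d}"
            manifest.trnas[locus] = TrnaTruth(
                locus_tag=locus, amino_acid=plant.amino_acid,
                anticodon=plant.anticodon, strand=plant.strand, sequence=seq,
                start=pos, end=pos + plant.length - 1)
            manifest.element_order.append(("trna", locus))
            parts.append(seq if plant.strand == "+" else reverse_complement(seq))
            pos += plant.length
            prev_strand = None

    record = _assemble(manifest, spec.genome_id)
    return record, manifest


def _assemble(manifest: SyntheticManifest, genome_id: str) -> GenomeRecord:
    """Rebuild sequence + features from the manifest's element order,
    refreshing all coordinates."""
    parts: list[str] = []
    pos = 1
    features: list[Feature] = []
    for kind, payload in manifest.element_order:
        if kind == "spacer":
            parts.append(payload)
            pos += len(payload)
        elif kind == "gene":
            g = manifest.genes[payload]
            g.start = pos
            g.end = pos + len(g.cds) - 1
            parts.append(g.cds if g.strand == "+" else reverse_complement(g.cds))
            features.append(Feature(locus_tag=g.locus_tag, kind="CDS",
                                    start=g.start, end=g.end, strand=g.strand))
            pos = g.end + 1
        else:
            t = manifest.trnas[payload]
            t.start = pos
            t.end = pos + len(t.sequence) - 1
            parts.append(t.sequence if t.strand == "+" else reverse_complement(t.sequence))
            features.append(Feature(locus_tag=t.locus_tag, kind="tRNA",
                                    start=t.start, end=t.end, strand=t.strand,
                                    anticodon=t.anticodon, amino_acid=t.amino_acid,
                                    product=f"tRNA-{t.amino_acid}"))
            pos = t.end + 1
    manifest.genome_id = genome_id
    return GenomeRecord(id=genome_id, sequence="".join(parts),
                        topology="circular", features=features)


# ---------------------------------------------------------------------------
# evolution

_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _site_kernel(kappa: float) -> dict[str, dict[str, float]]:
    """P(target | source) for one mutated site, transition:transversion kappa."""
    out = {}
    for b in "ACGT":
        others = [x for x in "ACGT" if x != b]
        w = {x: (kappa if x == _TS[b] else 1.0) for x in others}
        tot = sum(w.values())
        out[b] = {x: w[x] / tot for x in others}
    return out


def _codon_transition_matrix(p: float, kappa: float) -> np.ndarray:
    """64x64 row-stochastic codon mutation matrix under per-site prob p,
    with mutations into stop codons redirected (renormalised away)."""
    codons = SENSE_CODONS
    kern = _site_kernel(kappa)
    n = len(codons)
    cindex = {c: i for i, c in enumerate(codons)}
    M = np.zeros((n, n))
    all_codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    for i, src in enumerate(codons):
        for dst in all_codons:
            if CODON_TO_AA.get(dst) == "*":
                continue
            pr = 1.0
            for s_b, d_b in zip(src, dst):
                pr *= (1.0 - p) if s_b == d_b else p * kern[s_b][d_b]
            M[i, cindex[dst]] += pr
        M[i] /= M[i].sum()
    return M


def _expected_aa_divergence(codon_counts: np.ndarray, M: np.ndarray) -> float:
    aa = np.array([CODON_TO_AA[c] for c in SENSE_CODONS])
    diff = aa[:, None] != aa[None, :]
    per_codon = (M * diff).sum(axis=1)
    w = codon_counts / codon_counts.sum()
    return float((w * per_codon).sum())


def _calibrate_site_prob(codon_counts: np.ndarray, target_aa_div: float,
                         kappa: float) -> float:
    if target_aa_div <= 0:
        return 0.0
    f = lambda p: _expected_aa_divergence(codon_counts, _codon_transition_matrix(p, kappa)) - target_aa_div
    hi = 0.75
    if f(hi) < 0:
        return hi
    return float(brentq(f, 1e-6, hi, xtol=1e-5))


@dataclass
class EvolutionSpec:
    """Events and divergence applied when deriving a child genome.

    Substitutions are applied first (so divergence targets refer to
    pre-event orthologs), then structural events.  ``aa_divergence`` is
    the target fraction of amino-acid sites changed per gene;
    ``nt_site_prob`` overrides the solved per-site substitution
    probability directly when given.
    """

    aa_divergence: float = 0.0
    nt_site_prob: float | None = None
    ts_tv: float = 2.0
    gene_loss: int = 0
    gene_gain: int = 0
    n_duplications: int = 0
    duplication_nt_divergence: float = 0.10
    n_splits: int = 0
    split_deletion_aa: int = 0
    n_inversions: int = 0
    inversion_span_genes: int = 5
    child_id: str = "child"


def _mutate_gene(cds: str, M: np.ndarray, rng: np.random.Generator) -> str:
    """Mutate interior codons via the transition matrix; start and stop fixed."""
    cindex = {c: i for i, c in enumerate(SENSE_CODONS)}
    out = [cds[:3]]
    for i in range(3, len(cds) - 3, 3):
        src = cds[i : i + 3]
        row = M[cindex[src]]
        out.append(SENSE_CODONS[rng.choice(len(SENSE_CODONS), p=row)])
    out.append(cds[-3:])
    return "".join(out)


def _mutate_spacer(seq: str, p: float, kappa: float,
                   rng: np.random.Generator) -> str:
    if p <= 0 or not seq:
        return seq
    kern = _site_kernel(kappa)
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < p)[0]
    for i in hits:
        b = chars[i]
        if b not in "ACGT":
            continue
        targets, w = zip(*kern[b].items())
        chars[i] = targets[rng.choice(len(targets), p=np.array(w))]
    return "".join(chars)


def aa_identity(a: str, b: str) -> float:
    """Position-wise identity of two equal-length proteins, in percent."""
    if len(a) != len(b):
        raise ValueError("proteins differ in length")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def evolve_genome(
    parent: GenomeRecord,
    parent_manifest: SyntheticManifest,
    espec: EvolutionSpec,
    seed: int = 0,
) -> tuple[GenomeRecord, SyntheticManifest]:
    """Derive a child genome by substitutions followed by structural events.

    Gene family ids propagate from the parent; every event is recorded in
    the child manifest.  Deterministic under (inputs, seed).
    """
    rng = np.random.default_rng(seed)
    child = SyntheticManifest(
        genome_id=espec.child_id, parent_id=parent_manifest.genome_id,
        origin_pos=parent_manifest.origin_pos,
        terminus_pos=parent_manifest.terminus_pos,
        gc_percent=parent_manifest.gc_percent,
        skew_bias=parent_manifest.skew_bias,
    )

    # --- substitutions -----------------------------------------------------
    counts = np.zeros(len(SENSE_CODONS))
    cindex = {c: i for i, c in enumerate(SENSE_CODONS)}
    for g in parent_manifest.genes.values():
        for i in range(3, len(g.cds) - 3, 3):
            counts[cindex[g.cds[i : i + 3]]] += 1
    if espec.nt_site_prob is not None:
        p_site = espec.nt_site_prob
    else:
        p_site = _calibrate_site_prob(counts, espec.aa_divergence, espec.ts_tv)
    M = _codon_transition_matrix(p_site, espec.ts_tv) if p_site > 0 else None

    realized_div = {}
    for locus, g in parent_manifest.genes.items():
        cds = _mutate_gene(g.cds, M, rng) if M is not None else g.cds
        prot = _translate_cds_str(cds)
        child.genes[locus] = GeneTruth(locus_tag=locus, family=g.family,
                                       strand=g.strand, cds=cds, protein=prot)
        realized_div[locus] = round(100.0 - aa_identity(prot, g.protein), 2)
    for locus, t in parent_manifest.trnas.items():
        child.trnas[locus] = TrnaTruth(locus_tag=locus, amino_acid=t.amino_acid,
                                       anticodon=t.anticodon, strand=t.strand,
                                       sequence=t.sequence)
    child.element_order = [
        (k, _mutate_spacer(v, p_site, espec.ts_tv, rng)) if k == "spacer" else (k, v)
        for k, v in parent_manifest.element_order
    ]
    child.events.append({
        "event": "substitution", "site_prob": round(p_site, 5),
        "target_aa_divergence": espec.aa_divergence,
        "realized_aa_divergence_percent": realized_div,
    })

    gene_positions = [i for i, (k, _) in enumerate(child.element_order) if k == "gene"]

    # --- gene loss ---------------------------------------------------------
    if espec.gene_loss:
        lose = rng.choice(len(gene_positions), size=espec.gene_loss, replace=False)
        lost_loci = [child.element_order[gene_positions[i]][1] for i in lose]
        child.element_order = [
            (k, v) for k, v in child.element_order
            if not (k == "gene" and v in lost_loci)
        ]
        for locus in lost_loci:
            child.events.append({"event": "gene_loss", "locus": locus,
                                 "family": child.genes[locus].family})
            del child.genes[locus]

    # --- gene gain ---------------------------------------------------------
    next_no = len(parent_manifest.genes) + 1
    fam_no = max((int(g.family[3:]) for g in parent_manifest.genes.values()),
                 default=0) + 1
    probs_emp = counts / counts.sum()
    for _ in range(espec.gene_gain):
        n_aa = max(40, int(rng.normal(200, 60)))
        cds = _sample_gene(n_aa, probs_emp, rng)
        locus = f"g{next_no:03d}"
        next_no += 1
        strand = "+" if rng.random() < 0.5 else "-"
        child.genes[locus] = GeneTruth(locus_tag=locus, family=f"fam{fam_no:04d}",
                                       strand=strand, cds=cds,
                                       protein=_translate_cds_str(cds))
        fam_no += 1
        _insert_element(child, ("gene", locus), rng)
        child.events.append({"event": "gene_gain", "locus": locus,
                             "family": child.genes[locus].family})

    # --- duplications ------------------------------------------------------
    current = [v for k, v in child.element_order if k == "gene"]
    if espec.n_duplications:
        src_loci = rng.choice(current, size=espec.n_duplications, replace=False)
        Mdup = _codon_transition_matrix(
            _nt_to_site_prob(espec.duplication_nt_divergence), espec.ts_tv)
        for src in src_loci:
            g = child.genes[str(src)]
            cds = _mutate_gene(g.cds, Mdup, rng)
            locus = f"g{next_no:03d}"
            next_no += 1
            child.genes[locus] = GeneTruth(
                locus_tag=locus, family=g.family, strand=g.strand, cds=cds,
                protein=_translate_cds_str(cds))
            _insert_element(child, ("gene", locus), rng)
            nt_ident = 100.0 * sum(x == y for x, y in zip(cds, g.cds)) / len(g.cds)
            child.events.append({
                "event": "duplication", "source": str(src), "copy": locus,
                "family": g.family,
                "realized_nt_identity_percent": round(nt_ident, 2),
            })

    # --- splits ------------------------------------------------------------
    if espec.n_splits:
        eligible = [
            v for k, v in child.element_order
            if k == "gene" and len(child.genes[v].protein) >= 120
        ]
        targets = rng.choice(eligible, size=espec.n_splits, replace=False)
        for tgt in targets:
            _apply_split(child, str(tgt), espec.split_deletion_aa, rng)
            next_no += 2

    # --- inversions --------------------------------------------------------
    for _ in range(espec.n_inversions):
        _apply_inversion(child, espec.inversion_span_genes, rng)

    record = _assemble(child, espec.child_id)
    return record, child


def _nt_to_site_prob(nt_divergence: float) -> float:
    """Per-site mutation probability giving ~nt_divergence realised change.

    A mutated site always changes under the site kernel, so the realised
    divergence equals the site probability, minus a small deficit from
    mutations into stop codons being redirected.
    """
    return min(max(nt_divergence, 0.0), 0.75)


def _insert_element(manifest: SyntheticManifest, element, rng: np.random.Generator,
                    spacer_len: int = 40) -> None:
    """Insert an element (plus a fresh spacer) at a random gene boundary."""
    gc = manifest.gc_percent / 100.0
    spacer = _sample_spacer(spacer_len, gc, 0.0, True, rng)
    if element[0] == "gene" and manifest.genes[element[1]].strand == "+":
        spacer = _embed_rbs(spacer, "+", None, rng)
    boundaries = [i for i, (k, _) in enumerate(manifest.element_order) if k == "spacer"]
    at = int(rng.choice(boundaries))
    manifest.element_order[at + 1 : at + 1] = [("spacer", spacer), element]


def _apply_split(manifest: SyntheticManifest, locus: str, deletion_aa: int,
                 rng: np.random.Generator) -> None:
    g = manifest.genes[locus]
    n_aa = len(g.protein)
    b = n_aa // 2  # even split, as in the ancestral-gene case
    codons = [g.cds[i : i + 3] for i in range(0, len(g.cds), 3)]
    # codons[0] = start .. codons[n_aa-1] = last sense codon, codons[n_aa] = stop
    frag1 = "".join(codons[:b]) + "TAA"
    tail = codons[b + deletion_aa : n_aa]
    frag2 = "ATG" + "".join(tail) + "TAA"
    loc1, loc2 = f"{locus}a", f"{locus}b"
    manifest.genes[loc1] = GeneTruth(locus_tag=loc1, family=g.family,
                                     strand=g.strand, cds=frag1,
                                     protein=_translate_cds_str(frag1))
    manifest.genes[loc2] = GeneTruth(locus_tag=loc2, family=g.family,
                                     strand=g.strand, cds=frag2,
                                     protein=_translate_cds_str(frag2))
    gc = manifest.gc_percent / 100.0
    spacer = _embed_rbs(_sample_spacer(40, gc, 0.0, True, rng),
                        "+" if g.strand == "+" else None,
                        "-" if g.strand == "-" else None, rng)
    first, second = (loc1, loc2) if g.strand == "+" else (loc2, loc1)
    idx = manifest.element_order.index(("gene", locus))
    manifest.element_order[idx : idx + 1] = [
        ("gene", first), ("spacer", spacer), ("gene", second)
    ]
    del manifest.genes[locus]
    manifest.events.append({
        "event": "split", "source": locus, "family": g.family,
        "fragments": [loc1, loc2], "breakpoint_aa": b,
        "deletion_aa": deletion_aa,
        "fragment_segments": [[1, b], [b + deletion_aa + 1, n_aa]],
    })


def _apply_inversion(manifest: SyntheticManifest, span_genes: int,
                     rng: np.random.Generator) -> None:
    gene_idx = [i for i, (k, _) in enumerate(manifest.element_order) if k == "gene"]
    if len(gene_idx) < span_genes + 2:
        raise ValueError("not enough genes for the requested inversion span")
    start_gene = int(rng.integers(1, len(gene_idx) - span_genes))
    lo = gene_idx[start_gene]
    hi = gene_idx[start_gene + span_genes - 1]
    segment = manifest.element_order[lo : hi + 1]
    inverted = []
    for k, v in reversed(segment):
        if k == "gene":
            g = manifest.genes[v]
            g.strand = "+" if g.strand == "-" else "-"
            inverted.append((k, v))
        elif k == "trna":
            t = manifest.trnas[v]
            t.strand = "+" if t.strand == "-" else "-"
            inverted.append((k, v))
        else:
            inverted.append((k, reverse_complement(v)))
    manifest.element_order[lo : hi + 1] = inverted
    loci = [v for k, v in segment if k == "gene"]
    manifest.events.append({
        "event": "inversion", "loci": loci, "span_genes": span_genes,
        "families": [manifest.genes[l].family for l in loci],
    })


# ---------------------------------------------------------------------------
# fixture constructors

def back_translate(protein: str, codon_choice: dict[str, str]) -> str:
    """Deterministic back-translation under a per-amino-acid codon choice."""
    codons = [codon_choice[aa] for aa in protein]
    return "".join(codons) + "TAA"


def make_convergent_pair(
    n_aa: int = 150, aa_identity: float = 0.35, seed: int = 0,
) -> tuple[str, str, str, str]:
    """A convergent gene pair: related proteins, unrelated DNA.

    Returns ``(protein_a, protein_b, cds_a, cds_b)``.  The two proteins
    share ``aa_identity`` of their positions (the regime of anciently
    convergent paralogs); each is back-translated under a disjoint codon
    preference (lexicographically first vs most-dissimilar synonymous
    codon per amino acid), so even conserved residues rarely share
    codons and nucleotide identity stays near the random background.
    """
    rng = np.random.default_rng(seed)
    aas = sorted(set(CODON_TO_AA.values()) - {"*"})
    protein_a = "M" + "".join(rng.choice(aas) for _ in range(n_aa - 1))
    keep = set(rng.choice(np.arange(1, n_aa), size=round(aa_identity * n_aa) - 1,
                          replace=False))
    chars = ["M"]
    for i in range(1, n_aa):
        if i in keep:
            chars.append(protein_a[i])
        else:
            chars.append(str(rng.choice([a for a in aas if a != protein_a[i]])))
    protein_b = "".join(chars)
    first = {aa: sorted(SYNONYMOUS[aa])[0] for aa in aas}

    def hamming(x: str, y: str) -> int:
        return sum(a != b for a, b in zip(x, y))

    far = {
        aa: max(sorted(SYNONYMOUS[aa]), key=lambda c: (hamming(c, first[aa]), c))
        for aa in aas
    }
    return (protein_a, protein_b,
            back_translate(protein_a, first), back_translate(protein_b, far))


def make_classification_genome(
    n_duplications: int = 3,
    n_convergent: int = 3,
    n_background: int = 6,
    dup_nt_divergence: float = 0.10,
    gene_aa: int = 160,
    seed: int = 0,
) -> tuple[GenomeRecord, dict[frozenset, str]]:
    """A genome mixing planted duplication pairs and convergent pairs.

    Duplication pairs are a gene plus a point-mutated copy
    (``dup_nt_divergence`` per site); convergent pairs come from
    :func:`make_convergent_pair`.  Returns the assembled record and the
    truth map ``{frozenset({locus_a, locus_b}): "duplication"|"convergent"}``.
    """
    rng = np.random.default_rng(seed)
    uniform = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    Mdup = _codon_transition_matrix(_nt_to_site_prob(dup_nt_divergence), 2.0)
    genes: list[tuple[str, str]] = []  # (locus, cds)
    truth: dict[frozenset, str] = {}
    n = 0

    def add(cds: str) -> str:
        nonlocal n
        n += 1
        locus = f"g{n:03d}"
        genes.append((locus, cds))
        return locus

    for _ in range(n_duplications):
        cds = _sample_gene(gene_aa, uniform, rng)
        copy = _mutate_gene(cds, Mdup, rng)
        truth[frozenset({add(cds), add(copy)})] = "duplication"
    for k in range(n_convergent):
        _, _, cds_a, cds_b = make_convergent_pair(
            gene_aa, seed=int(rng.integers(0, 2**31)))
        truth[frozenset({add(cds_a), add(cds_b)})] = "convergent"
    for _ in range(n_background):
        add(_sample_gene(gene_aa, uniform, rng))

    order = rng.permutation(len(genes))
    parts = []
    features = []
    pos = 1
    for i in order:
        locus, cds = genes[i]
        spacer = _sample_spacer(40, 0.35, 0.0, True, rng)
        parts.append(spacer)
        pos += len(spacer)
        parts.append(cds)
        features.append(Feature(locus_tag=locus, kind="CDS", start=pos,
                                end=pos + len(cds) - 1, strand="+"))
        pos += len(cds)
    record = GenomeRecord(id=f"mix{seed}", sequence="".join(parts),
                          topology="circular", features=features)
    return record, truth
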