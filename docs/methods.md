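# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates, topology, translation

All coordinates in types and reports are 1-based inclusive, matching
GenBank; any half-open arithmetic is internal.  Genomes default to
circular topology (phage genomes are deposited as closed circles even
when virion DNA is linear and circularly permuted).  A feature may wrap
the circular junction (`start > end`, flagged); wrapping on a linear
genome is an error.  Translation uses the bacterial/plastid genetic code
(table 11) — hosts are bacteria — with GTG/TTG starts rendered as Met,
trailing stops stripped, internal stops flagged rather than dropped, and
N-containing codons translating to X and excluded from codon counts.

## ORF scanning and the RBS score

A candidate ORF is a stop-bounded, in-frame region with a start codon in
{ATG, GTG, TTG} and ≥ `min_aa` (default 30) encoded amino acids.  All
six frames are scanned; on circular genomes the sequence is logically
doubled so ORFs may cross the junction.  The scanner never filters on
the ribosome-binding site unless asked, so the length and RBS criteria
can be studied independently; `longest_per_stop` optionally keeps only
the most upstream valid start per stop.

The RBS score is the length of the longest contiguous match to the
Shine–Dalgarno consensus `AGGAGGT` whose 3′ end lies 4–18 nt upstream of
the start codon (standard prokaryotic SD spacing; the window is
configurable).  Matches under 3 nt score 0; among equal-length matches
the smallest spacer is reported.  The default validity threshold when
filtering is score ≥ 4.

De-novo scanning is *not* expected to reproduce curated annotations
produced by HMM-based gene callers plus manual inspection;
statistics for deposited genomes are always computed from the deposited
features.

## Genome statistics

Gene density is CDS count per kbp rounded to one decimal.  Coding
percentage uses the span-union convention (a base covered by several
CDSs counts once; wrapped spans are split at the junction).  Start/stop
tallies and product lengths come from extracted feature sequences; CDSs
whose length is not divisible by 3 are excluded from codon-derived
quantities and counted in a `malformed` field.  Union vs sum conventions
can differ by a few tenths of a percent on overlap-rich genomes, which
is why the convention is stated on the output.

## GC skew and origin calling

The cumulative skew is per-base (+1 for G, −1 for C, 0 otherwise) along
the forward strand, so extremum positions are resolution-independent;
the windowed skew (default window 1000, step 500, wrapping on circles)
exists for plotting.  The origin is called at the global cumulative
minimum and the terminus at the maximum, following the common
cumulative-skew convention; since only the *pair* of boundaries is
determined by the biology, the assignment is a switch
(`origin_at="min"|"max"`).  Ties break to the smallest position.  A flat
curve (no G/C) yields an explicit "no signal" status.  On AT-rich
genomes the curve has plateaus, so extremum positions are reproducible
only to the plateau scale (tens of nt).

## Codon usage, optimal codons, CAI, tRNA decoding

Codon counts are taken in reading frame over all well-formed CDSs,
*including* the terminal stop codon (so the total equals coding codons +
one stop per gene).  The optimal codon of an amino acid is its
most-frequent synonymous codon, ties broken lexicographically.  CAI is
the geometric mean of w = count(codon)/count(best synonym) over codons
of multi-codon amino acids, with w floored at 0.01 for unobserved
codons.  A tRNA decodes the reverse complement of its anticodon; wobble
expansion (anticodon-5′ G additionally reads codon-3′ T; 5′ U reads G)
is available but the headline optimality statistic uses exact
Watson–Crick decoding, which is the convention consistent with marking
single codons as tRNA-served.  Suppressor/Pyl tRNAs decode stop codons
and are counted in the tRNA total but can never be optimality-related.
Cross-genome tRNA comparison uses local nucleotide alignment (+2/−3,
gaps 5/2) and reports deterministic coverage/identity pairs with
defaults coverage > 50% and identity ≥ 70%, in place of a nucleotide
E-value model.

## Alignment and significance

Pairwise alignment is affine-gap dynamic programming via
Bio.Align.PairwiseAligner: BLOSUM62 with gap open 11 / extend 1 for
proteins, +2/−3 with gap open 5 / extend 2 for nucleotides; a gap of
length k costs open + k·extend.  Identity is computed over aligned
columns excluding gaps; coverage is the aligned-segment span over each
sequence's length.  Significance uses the Karlin–Altschul expectation
E = K·m·n·e^(−λS) with gapped-BLOSUM62 constants λ = 0.267, K = 0.041.
These constants are not re-estimated per matrix/gap combination, so
E-values are calibrated in the BLAST sense only approximately; they are
used as a ranking and thresholding device (homologs at E ≤ 10⁻⁶,
within-genome paralog candidates at E ≤ 10⁻³, the looser threshold
because anciently diverged paralogs sit at 25–30% identity).  The test
suite verifies the engine's scores against an independent brute-force
Gotoh implementation on random pairs.

Exact homolog *counts* from heuristic search tools are version- and
heuristic-dependent; this package's full dynamic programming with a
fixed E-model will not reproduce them number-for-number, and no attempt
is made to.  The contract is instead property-based: near-perfect
recall on families of known orthologs and near-zero hits between
unrelated proteomes.

## Homologs, core genome, synteny

Homology is best-hit per query (CoreGenes-style counting); a
reciprocal-best-hit switch exists.  "Coverage" in filtering profiles
means query coverage.  The core genome is reference-based: a reference
gene is core iff every other genome has a qualifying homolog, so
removing a genome can only grow the core.  Synteny operates on
gene-order indices, not nucleotide coordinates: blocks are maximal
chains of homolog pairs strictly monotone in both genomes with at most
`max_gap` (default 3) skipped genes on either side, consistent strand
relation, and descending partner order flagged as inverted.  Homolog
pairs in no block of length ≥ 2 are reported as relocated.

## Duplication vs convergence, split genes

"Significant nucleotide identity" — the discriminator between
duplication of an ancestral gene and convergent protein similarity — is
operationalised as ≥ 65% nt identity over ≥ 50% of the shorter CDS
(local alignment).  The thresholds are configuration values surfaced in
every report, since the underlying biology offers only
"significant"/"negligible".  Verdicts partition candidates:
`duplication` (DNA passes), `convergent` (protein passes, DNA fails),
`ambiguous` (otherwise).

Split detection collects, per target gene, all fragment-genome genes
aligning at E ≤ 10⁻³, selects a pairwise-compatible set greedily in
order of increasing E-value (strongest evidence first, so a weak
spurious hit cannot displace a true fragment), and accepts sets of ≥ 2
segments with pairwise overlap ≤ 20% of the shorter segment and union
coverage ≥ 50% of the target.  The 20% overlap allowance accommodates
alignment jitter around an exactly disjoint split.  Selection by
E-value also makes the result invariant to fragment input order.

## The synthetic-data generator

`generate_genome` emulates a T4-like phage genome: circular, default
40 kbp at 35% GC, 1.5 genes/kbp (~200 ± 60 aa products, minimum 40 aa),
≥ 30-nt intergenic gaps carrying an `AGGAGG` motif 5–11 nt upstream of
each planted start, eight planted tRNAs (the Trp/Pro/Ser/Thr/Cys/Met/
Arg/Sup complement typical of an *Acinetobacter* T4-like phage) on the
minus strand, terminus at nt 1 and origin at mid-genome.  The defaults
are a scaled-down version of the study conditions (a ~167-kbp genome
with 256 genes has the same density, GC and product-length profile);
tests and the acceptance script use 12–40 kbp genomes so the whole suite
runs in minutes on one CPU.

Genes are synthesised by sampling sense codons.  With no user weights
the codon model is the one-parameter family q(c) ∝ θ^gc(c) with θ solved
(Brent) so expected coding GC equals the target; intergenic bases are
sampled at the target GC directly.  Realised genome GC is within ±1
point of target for genomes ≥ 10 kbp under default weights; explicit
per-amino-acid codon weights (used to plant known optimal codons)
override the GC calibration for coding sequence.

The replichore structure interprets `skew_bias` as the target
leading-strand (G−C)/(G+C).  Every freely chosen base — intergenic
positions and the synonymous degrees of freedom of codon choice — is
tilted G-vs-C with a single strength parameter, with the sign set by the
element's replichore arc and strand; the strength is solved numerically
so the expected strand skew over the planned gene/intergenic composition
equals `skew_bias`.  Because most coding positions are constrained by
the protein, the free-site tilt needed for a genome-wide bias of 0.05 is
several-fold larger; it saturates at 0.95 if a requested bias is
unreachable at the given coding density.  Gene starts are fixed ATG and
stops are drawn TAA/TGA/TAG at 0.70/0.26/0.04, the tally profile typical
of AT-rich phage genomes.

`evolve_genome` applies substitutions first, then structural events, so
divergence targets refer to pre-event orthologs.  Substitution is
codon-wise under a site-independent two-parameter model (per-site
probability, transition:transversion ratio default 2) with mutations
into stop codons renormalised away; start and stop codons are kept.
When an amino-acid divergence target is given, the per-site probability
is solved from the exact expected amino-acid change rate under the
parent's codon composition, so realised divergence tracks the target
(median within ±5 points).  There is no indel model inside genes —
indels arise only through structural events — which keeps alignment
tests interpretable.  Structural events (loss, gain, duplication with
its own nt divergence, even in-frame splitting with optional deleted
linker, block inversion with strand flips) manipulate an element list
and are all recorded in the manifest, with family ids propagating so
recall can be scored exactly.

Planted convergent pairs are constructed at ~35% amino-acid identity
(the regime of anciently convergent paralogs), each back-translated
under a disjoint codon preference, rather than as 100%-identical
proteins: identical proteins force ≥ ~2/3 nucleotide identity at
synonymous-only freedom, which sits *on* the duplication decision
boundary and would make accuracy a coin flip about the threshold rather
than about the biology.

What the generator does not emulate: overlapping genes, operon
structure, promoters/terminators, rate heterogeneity and codon-model
selection, homing endonucleases/introns, terminal repeats, and real
intergenic composition.  Passing the recovery tests therefore shows the
detectors are correct under clean two-replichore, non-overlapping,
indel-free conditions — not that they are robust to every artefact of
real annotations.

## Problem sizes and determinism

The acceptance script (`scripts/acceptance.py`) uses: 100 random
residue pairs ≤ 30 aa for oracle agreement; 20 seeded 20-kbp families
at 20% amino-acid divergence for ortholog recall; 20 seeded 40-kbp
genomes at skew bias 0.05 (window 1000) for origin recovery; 20 planted
duplication/convergence mixtures; 20 planted split fixtures; and three
30-kbp genomes with planted codon weights.  All randomness derives from
`--seed`; rerunning with the same seed reproduces the JSON exactly.

## Limitations

- E-values use fixed gapped-BLOSUM62 constants; do not compare them
  numerically with BLAST output.
- Best-hit homology is not orthology; paralogs can absorb best hits in
  gene-family expansions (the RBH switch mitigates this).
- The origin call gives the cumulative extremum, which on weakly skewed
  or short genomes can sit hundreds of nt to a few kbp from the true
  boundary; windowed inspection of the curve is recommended.
- Full dynamic programming is quadratic per pair; all-vs-all comparison
  of many large proteomes is O(n²·L²) and is meant for phage-scale
  inputs (hundreds of genes), not bacterial pangenomes.
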