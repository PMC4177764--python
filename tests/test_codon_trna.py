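"""Codon usage, optimal codons, anticodon decoding, CAI and tRNA homology."""

import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compgen.codon_trna import (
    CODON_TO_AA,
    CodonUsageTable,
    SYNONYMOUS,
    TrnaGene,
    cai,
    codon_usage,
    compare_trnas,
    decode_anticodon,
    optimal_codons,
    trna_optimality,
)
from compgen.genome_io import reverse_complement
from compgen.synthetic_data import GenomeSpec, generate_genome


def test_codon_usage_trivial():
    t = codon_usage(["ATGAAATAA"])
    assert t.counts == Counter({"ATG": 1, "AAA": 1, "TAA": 1})
    assert t.total_codons == 3


def test_codon_usage_skips_bad_lengths_and_n_codons():
    t = codon_usage(["ATGAAATAA", "ATGAA", "ATGANATAA"])
    assert t.n_skipped_sequences == 1
    assert t.counts["ATG"] == 2 and "ANA" not in t.counts


def test_codon_usage_rejects_empty():
    with pytest.raises(ValueError):
        codon_usage([])


def test_codon_usage_matches_stepper_oracle():
    rng = random.Random(11)
    sense = sorted(CODON_TO_AA)
    seqs = ["".join(rng.choice(sense) for _ in range(rng.randint(10, 60)))
            for _ in range(100)]
    t = codon_usage(seqs)
    oracle = Counter()
    for s in seqs:
        i = 0
        while i + 3 <= len(s):
            oracle[s[i:i + 3]] += 1
            i += 3
    assert t.counts == oracle


def test_optimal_codons_argmax_and_tie():
    t = CodonUsageTable(counts=Counter({"AAA": 10, "AAG": 3, "GGA": 5, "GGC": 5}))
    opt = optimal_codons(t)
    assert opt["K"] == "AAA"
    assert opt["G"] == "GGA"  # tie broken lexicographically
    assert "L" not in opt  # absent amino acid omitted


def test_optimal_codons_matches_argmax_oracle():
    rng = random.Random(5)
    counts = Counter({c: rng.randint(0, 50) for c in CODON_TO_AA})
    opt = optimal_codons(CodonUsageTable(counts=counts))
    for aa, codons in SYNONYMOUS.items():
        if aa == "*" or all(counts[c] == 0 for c in codons):
            continue
        best = max(counts[c] for c in codons)
        assert counts[opt[aa]] == best


@pytest.mark.parametrize("anticodon,expected", [
    ("CCA", {"TGG"}),  # Trp
    ("CAT", {"ATG"}),  # Met
])
def test_decode_anticodon_exact(anticodon, expected):
    assert decode_anticodon(anticodon) == expected


def test_decode_anticodon_wobble():
    assert decode_anticodon("GCA", wobble=True) == {"TGC", "TGT"}
    assert decode_anticodon("TCT", wobble=True) == {"AGA", "AGG"}


def test_decode_anticodon_rejects_invalid():
    with pytest.raises(ValueError):
        decode_anticodon("CXA")


@settings(deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=3, max_size=3))
def test_decode_is_reverse_complement_involution(ac):
    codon = next(iter(decode_anticodon(ac)))
    assert reverse_complement(codon) == ac
    assert decode_anticodon(reverse_complement(codon)) == {codon}


def test_trna_optimality_met_and_suppressor():
    table = CodonUsageTable(counts=Counter({"ATG": 5, "AAA": 2}))
    opt = optimal_codons(table)
    trnas = [TrnaGene("t1", "Met", "CAT"), TrnaGene("t2", "Sup", "CTA")]
    rep = trna_optimality(trnas, opt)
    assert rep.n_trnas == 2 and rep.n_optimal_trnas == 1
    rows = {r["locus_tag"]: r for r in rep.rows}
    assert rows["t1"]["is_optimal"] is True
    assert rows["t2"]["decodes_stop"] is True and rows["t2"]["is_optimal"] is False
    assert rep.n_a_ending == 0  # ATG and TAG both end in G


def test_trna_a_ending_count():
    trnas = [TrnaGene("t1", "Lys", "TTT"),  # decodes AAA
             TrnaGene("t2", "Met", "CAT")]  # decodes ATG
    rep = trna_optimality(trnas, {"K": "AAA", "M": "ATG"})
    assert rep.n_a_ending == 1


def test_cai_all_optimal_is_one():
    table = CodonUsageTable(counts=Counter({"AAA": 10, "AAG": 2, "GAA": 8, "GAG": 1}))
    assert cai("AAAGAAAAA", table) == pytest.approx(1.0)


def test_cai_constant_w_half():
    table = CodonUsageTable(counts=Counter({"AAA": 10, "AAG": 5}))
    assert cai("AAGAAGAAG", table) == pytest.approx(0.5)


def test_cai_matches_product_formula_oracle():
    import math

    rng = random.Random(9)
    counts = Counter({c: rng.randint(1, 40) for c in CODON_TO_AA if CODON_TO_AA[c] != "*"})
    table = CodonUsageTable(counts=counts)
    sense = [c for c in counts if len(SYNONYMOUS[CODON_TO_AA[c]]) > 1]
    gene = "".join(rng.choice(sense) for _ in range(50))
    ws = []
    for i in range(0, len(gene), 3):
        codon = gene[i:i + 3]
        best = max(counts[c] for c in SYNONYMOUS[CODON_TO_AA[codon]])
        ws.append(max(counts[codon] / best, 0.01))
    expected = math.exp(sum(math.log(w) for w in ws) / len(ws))
    assert cai(gene, table) == pytest.approx(expected)


def test_cai_scale_invariance():
    rng = random.Random(13)
    counts = Counter({c: rng.randint(1, 40) for c in CODON_TO_AA if CODON_TO_AA[c] != "*"})
    table = CodonUsageTable(counts=counts)
    gene = "AAAGAACTGCTGTCT" * 4
    assert cai(gene, table) == pytest.approx(cai(gene, table.scaled(7)))


def test_planted_codon_preferences_recovered(small_genome):
    # strongly biased planted weights: the per-amino-acid mode must be
    # recovered exactly from the generated CDSs
    planted = {}
    weights = {}
    for aa, codons in SYNONYMOUS.items():
        if aa == "*" or len(codons) == 1:
            continue
        planted[aa] = codons[0]
        weights[aa] = {c: (0.7 if c == codons[0] else 0.3 / (len(codons) - 1))
                       for c in codons}
    rec, man = generate_genome(
        GenomeSpec(length_bp=30_000, codon_weights=weights, skew_bias=0.05),
        seed=21)
    from compgen.genome_io import feature_sequence

    table = codon_usage([feature_sequence(rec, f) for f in rec.cds()])
    opt = optimal_codons(table)
    for aa, codon in planted.items():
        assert opt[aa] == codon, aa


def test_compare_trnas_identical_and_mutated():
    rng = random.Random(3)
    seq = "".join(rng.choice("ACGT") for _ in range(76))
    a = TrnaGene("a", "Met", "CAT", sequence=seq)
    pairs = compare_trnas([a], [TrnaGene("b", "Met", "CAT", sequence=seq)])
    assert len(pairs) == 1
    assert pairs[0]["identity"] == pytest.approx(100.0)
    assert pairs[0]["coverage"] == pytest.approx(100.0)

    mutated = list(seq)
    for i in rng.sample(range(76), 15):  # ~20% of sites
        mutated[i] = rng.choice([b for b in "ACGT" if b != mutated[i]])
    b = TrnaGene("b", "Met", "CAT", sequence="".join(mutated))
    pairs = compare_trnas([a], [b])
    assert len(pairs) == 1
    assert 70 <= pairs[0]["identity"] <= 90


def test_compare_trnas_unrelated_rarely_match():
    rng = random.Random(17)
    hits = 0
    for _ in range(30):
        x = TrnaGene("x", "Met", "CAT",
                     sequence="".join(rng.choice("ACGT") for _ in range(76)))
        y = TrnaGene("y", "Met", "CAT",
                     sequence="".join(rng.choice("ACGT") for _ in range(76)))
        hits += len(compare_trnas([x], [y]))
    assert hits <= 1
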