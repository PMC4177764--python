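"""Alignment, E-values, homolog calling, core genome and synteny."""

import math
import random

import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from compgen.proteome_compare import (
    AlignmentError,
    Proteome,
    ProteinGene,
    align,
    alignment_score,
    core_genome,
    evalue,
    find_homologs,
    proteome_from_record,
    synteny_blocks,
)
from compgen.synthetic_data import EvolutionSpec, GenomeSpec, evolve_genome, generate_genome

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_oracle(a, b, mode, score_fn, open_cost, extend_cost):
    """Independent affine-gap DP (Gotoh), no vectorisation, no shortcuts.

    Opening a gap costs open_cost + extend_cost for its first residue.
    Local alignments may not end in a gap; empty local alignment scores 0.
    """
    NEG = -1e9
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    first = open_cost + extend_cost
    M[0][0] = 0
    if mode == "global":
        for i in range(1, n + 1):
            Ix[i][0] = -first - (i - 1) * extend_cost
        for j in range(1, m + 1):
            Iy[0][j] = -first - (j - 1) * extend_cost
    else:
        for i in range(n + 1):
            M[i][0] = 0
        for j in range(m + 1):
            M[0][j] = 0
    best_local = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_fn(a[i - 1], b[j - 1])
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            if mode == "local":
                diag = max(diag, s)
            M[i][j] = diag
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - extend_cost)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - extend_cost)
            if mode == "local" and M[i][j] > best_local:
                best_local = M[i][j]
    if mode == "local":
        return best_local
    return max(M[n][m], Ix[n][m], Iy[n][m])


def _random_protein(rng, n):
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))


def test_identical_proteins_full_identity():
    rng = random.Random(0)
    p = _random_protein(rng, 50)
    r = align(p, p, mode="local")
    assert r.identity_percent == pytest.approx(100.0)
    assert r.coverage_query == r.coverage_subject == pytest.approx(100.0)


def test_single_substitution_identity():
    a = "ACDEFG"
    b = "ACDKFG"
    r = align(a, b, mode="global")
    assert r.identity_percent == pytest.approx(100 * 5 / 6)


def test_score_symmetry():
    rng = random.Random(1)
    for _ in range(20):
        a = _random_protein(rng, rng.randint(5, 40))
        b = _random_protein(rng, rng.randint(5, 40))
        assert alignment_score(a, b) == alignment_score(b, a)


@pytest.mark.parametrize("mode", ["local", "global"])
def test_protein_scores_match_gotoh_oracle(mode):
    rng = random.Random(42)
    fn = lambda x, y: BLOSUM62[x, y]
    for _ in range(25):
        a = _random_protein(rng, rng.randint(3, 30))
        b = _random_protein(rng, rng.randint(3, 30))
        assert alignment_score(a, b, mode=mode, seq_type="aa") == pytest.approx(
            gotoh_oracle(a, b, mode, fn, 11, 1)), (a, b)


def test_nucleotide_scores_match_gotoh_oracle():
    rng = random.Random(43)
    fn = lambda x, y: 2 if x == y else -3
    for _ in range(25):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 30)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 30)))
        assert alignment_score(a, b, mode="local", seq_type="nt") == pytest.approx(
            gotoh_oracle(a, b, "local", fn, 5, 2)), (a, b)


def test_mixed_alphabet_rejected():
    with pytest.raises(AlignmentError):
        align("ACGT", "MKWQEH")


def test_evalue_closed_form_and_monotonicity():
    assert evalue(0, 100, 200) == pytest.approx(0.041 * 100 * 200)
    assert evalue(50, 200, 300) == pytest.approx(evalue(50, 100, 300) * 2)
    assert evalue(100, 200, 200) == pytest.approx(
        0.041 * 200 * 200 * math.exp(-0.267 * 100))
    assert evalue(60, 200, 200) < evalue(50, 200, 200)


def _toy_proteome(gid, seqs):
    return Proteome(genome_id=gid, genes=[
        ProteinGene(locus_tag=f"{gid}_{i}", sequence=s, index=i)
        for i, s in enumerate(seqs)])


def test_self_comparison_excludes_self_pairs():
    rng = random.Random(5)
    base = _random_protein(rng, 120)
    seqs = [base, base, _random_protein(rng, 120)]
    p = _toy_proteome("g", seqs)
    df = find_homologs(p, p, max_evalue=1e-6)
    assert all(df["query"] != df["subject"])
    pair = df[df["query"] == "g_0"].iloc[0]
    assert pair["subject"] == "g_1"


def test_unrelated_proteomes_give_no_hits():
    rng = random.Random(6)
    pa = _toy_proteome("a", [_random_protein(rng, 200) for _ in range(30)])
    pb = _toy_proteome("b", [_random_protein(rng, 200) for _ in range(30)])
    df = find_homologs(pa, pb, max_evalue=1e-6)
    assert len(df) <= 1  # expected ~0 under the E-value calibration


def test_ortholog_recall_on_diverged_family(diverged_pair):
    rec, man, child, cman = diverged_pair
    pa, pb = proteome_from_record(rec), proteome_from_record(child)
    df = find_homologs(pa, pb, max_evalue=1e-6)
    fam_a, fam_b = man.families(), cman.families()
    correct = sum(fam_a[q] == fam_b[s] for q, s in zip(df["query"], df["subject"]))
    assert correct / len(pa.genes) >= 0.95


def test_shared_count_near_symmetry(diverged_pair):
    rec, _, child, _ = diverged_pair
    pa, pb = proteome_from_record(rec), proteome_from_record(child)
    n_ab = len(find_homologs(pa, pb, max_evalue=1e-6))
    n_ba = len(find_homologs(pb, pa, max_evalue=1e-6))
    assert abs(n_ab - n_ba) <= 0.1 * min(len(pa.genes), len(pb.genes))


def test_core_genome_identical_triplet(small_genome):
    rec, _ = small_genome
    p = proteome_from_record(rec)
    ps = [Proteome(genome_id=f"g{i}", genes=p.genes) for i in range(3)]
    res = core_genome(ps)
    assert sorted(res.core) == sorted(g.locus_tag for g in p.genes)
    assert res.presence.all().all()


def test_core_monotone_under_genome_removal(small_genome):
    rec, man = small_genome
    child1, m1 = evolve_genome(rec, man, EvolutionSpec(aa_divergence=0.1,
                                                       gene_loss=3,
                                                       child_id="c1"), seed=1)
    child2, m2 = evolve_genome(rec, man, EvolutionSpec(aa_divergence=0.1,
                                                       gene_loss=3,
                                                       child_id="c2"), seed=2)
    ps = [proteome_from_record(r) for r in (rec, child1, child2)]
    full = core_genome(ps)
    reduced = core_genome(ps[:2])
    assert set(full.core) <= set(reduced.core)


def test_core_genome_recovers_planted_families(small_genome):
    rec, man = small_genome
    child1, m1 = evolve_genome(rec, man, EvolutionSpec(aa_divergence=0.15,
                                                       gene_loss=4,
                                                       child_id="c1"), seed=31)
    child2, m2 = evolve_genome(rec, man, EvolutionSpec(aa_divergence=0.15,
                                                       gene_loss=4,
                                                       child_id="c2"), seed=32)
    ps = [proteome_from_record(r) for r in (rec, child1, child2)]
    res = core_genome(ps)
    fams1 = set(m1.families().values())
    fams2 = set(m2.families().values())
    expected = {locus for locus, g in man.genes.items()
                if g.family in fams1 and g.family in fams2}
    assert set(res.core) == expected


def test_core_requires_two_genomes(small_genome):
    rec, _ = small_genome
    with pytest.raises(ValueError):
        core_genome([proteome_from_record(rec)])


def _pairs_df(rows):
    return pd.DataFrame(rows, columns=["query", "subject", "q_index", "s_index",
                                       "q_strand", "s_strand"])


def test_synteny_perfect_colinearity_single_block():
    rows = [(f"a{i}", f"b{i}", i, i, "+", "+") for i in range(20)]
    rep = synteny_blocks(_pairs_df(rows))
    assert len(rep.blocks) == 1
    assert len(rep.blocks[0]) == 20
    assert rep.blocks[0].orientation == "colinear"
    assert rep.relocated == []


def test_synteny_detects_planted_inversion():
    rows = []
    for i in range(20):
        if 8 <= i <= 12:  # 5-gene inversion: descending partner order
            rows.append((f"a{i}", f"b{i}", i, 20 - i, "+", "-"))
        else:
            rows.append((f"a{i}", f"b{i}", i, i, "+", "+"))
    rep = synteny_blocks(_pairs_df(rows), max_gap=3)
    orientations = [b.orientation for b in rep.blocks]
    assert "inverted" in orientations
    inv = next(b for b in rep.blocks if b.orientation == "inverted")
    assert [q for q, _ in inv.pairs] == [f"a{i}" for i in range(8, 13)]


def test_synteny_relocated_gene():
    rows = [(f"a{i}", f"b{i}", i, i, "+", "+") for i in range(10)]
    rows[5] = ("a5", "b5", 5, 55, "+", "+")  # moved across the genome
    rep = synteny_blocks(_pairs_df(rows), max_gap=3)
    assert ("a5", "b5") in rep.relocated
    assert len(rep.blocks) <= 2


def test_synteny_on_evolved_inversion(small_genome):
    rec, man = small_genome
    child, cman = evolve_genome(
        rec, man, EvolutionSpec(n_inversions=1, inversion_span_genes=5,
                                child_id="inv"), seed=9)
    planted = next(e for e in cman.events if e["event"] == "inversion")
    df = find_homologs(proteome_from_record(rec), proteome_from_record(child),
                       max_evalue=1e-6)
    rep = synteny_blocks(df, max_gap=3)
    inverted_loci = {q for b in rep.blocks if b.orientation == "inverted"
                     for q, _ in b.pairs}
    assert set(planted["loci"]) <= inverted_loci
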