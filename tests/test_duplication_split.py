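"""Duplication candidates, duplication-vs-convergence verdicts, split genes."""

import random

import numpy as np
import pytest

from compgen.duplication_split import call_duplications, detect_splits, find_duplications
from compgen.genome_io import Feature, GenomeRecord
from compgen.proteome_compare import Proteome, ProteinGene, proteome_from_record
from compgen.synthetic_data import (
    EvolutionSpec,
    GenomeSpec,
    evolve_genome,
    generate_genome,
    make_classification_genome,
    make_convergent_pair,
)


def _genome_of(cds_list):
    parts, features, pos = [], [], 1
    rng = random.Random(0)
    for i, cds in enumerate(cds_list):
        spacer = "".join(rng.choice("ACGT") for _ in range(40))
        parts.append(spacer)
        pos += 40
        parts.append(cds)
        features.append(Feature(f"g{i:03d}", "CDS", pos, pos + len(cds) - 1, "+"))
        pos += len(cds)
    return GenomeRecord(id="toy", sequence="".join(parts), features=features)


def test_exact_copy_is_called_duplication(small_genome):
    rec, man = small_genome
    locus, g = next(iter(man.genes.items()))
    toy = _genome_of([g.cds, g.cds])
    calls = call_duplications(toy)
    assert len(calls) == 1
    c = calls[0]
    assert c.verdict == "duplication"
    assert c.aa_identity == pytest.approx(100.0)
    assert c.nt_identity == pytest.approx(100.0)


def test_planted_paralog_pairs_all_recovered():
    # 14 pairs at ~30% amino-acid identity, the regime of ancient paralogs
    cds_list = []
    expected = set()
    for k in range(14):
        _, _, a, b = make_convergent_pair(160, aa_identity=0.30, seed=k)
        expected.add((f"g{2 * k:03d}", f"g{2 * k + 1:03d}"))
        cds_list += [a, b]
    calls = find_duplications(_genome_of(cds_list), max_evalue=1e-3)
    found = {(c.gene_a, c.gene_b) for c in calls} | {(c.gene_b, c.gene_a) for c in calls}
    assert expected <= found


def test_random_genes_give_no_candidates():
    rng = np.random.default_rng(1)
    from compgen.synthetic_data import SENSE_CODONS, _sample_gene

    uniform = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    genome = _genome_of([_sample_gene(150, uniform, rng) for _ in range(12)])
    calls = find_duplications(genome, max_evalue=1e-3)
    assert len(calls) <= 1  # expected ~0 by the E-value calibration


def test_recent_duplicate_classified_duplication(small_genome):
    rec, man = small_genome
    child, cman = evolve_genome(rec, man, EvolutionSpec(
        n_duplications=1, duplication_nt_divergence=0.05, child_id="d"), seed=3)
    ev = next(e for e in cman.events if e["event"] == "duplication")
    calls = call_duplications(child)
    pair = {ev["source"], ev["copy"]}
    match = [c for c in calls if {c.gene_a, c.gene_b} == pair]
    assert match and match[0].verdict == "duplication"
    assert match[0].nt_identity >= 90


def test_convergent_pair_classified_convergent():
    _, _, a, b = make_convergent_pair(160, seed=5)
    calls = call_duplications(_genome_of([a, b]))
    assert len(calls) == 1 and calls[0].verdict == "convergent"


def test_verdicts_partition_candidates():
    rec, truth = make_classification_genome(seed=3)
    for c in call_duplications(rec):
        assert c.verdict in ("duplication", "convergent", "ambiguous")


def test_classification_accuracy_on_planted_mixture():
    total = correct = 0
    for seed in range(5):
        rec, truth = make_classification_genome(seed=seed)
        verdicts = {frozenset({c.gene_a, c.gene_b}): c.verdict
                    for c in call_duplications(rec)}
        for pair, label in truth.items():
            total += 1
            correct += verdicts.get(pair) == label
    assert correct / total >= 0.9


def _protein_proteome(gid, seqs):
    return Proteome(genome_id=gid, genes=[
        ProteinGene(locus_tag=f"{gid}_{i}", sequence=s, index=i)
        for i, s in enumerate(seqs)])


def test_split_detection_on_disjoint_fragments():
    # the classic geometry: a 682-aa target with fragments matching
    # residues 1-217 and 409-643 (combined coverage ~66%, zero overlap)
    rng = random.Random(8)
    target = "M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(681))
    frag1 = target[0:217]
    frag2 = target[408:643]
    calls = detect_splits(_protein_proteome("t", [target]),
                          _protein_proteome("f", [frag1, frag2]))
    assert len(calls) == 1
    c = calls[0]
    assert [(f.t_start, f.t_end) for f in c.fragments] == [(1, 217), (409, 643)]
    assert c.combined_coverage == pytest.approx(100 * (217 + 235) / 682, abs=0.5)
    assert c.max_pairwise_overlap == 0.0


def test_fully_overlapping_fragments_are_not_a_split():
    rng = random.Random(9)
    target = "M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(400))
    frag = target[0:217]
    calls = detect_splits(_protein_proteome("t", [target]),
                          _protein_proteome("f", [frag, frag]))
    assert calls == []


def test_split_detection_invariant_to_fragment_order():
    rng = random.Random(10)
    target = "M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(500))
    f1, f2 = target[0:200], target[300:500]
    a = detect_splits(_protein_proteome("t", [target]),
                      _protein_proteome("f", [f1, f2]))
    b = detect_splits(_protein_proteome("t", [target]),
                      _protein_proteome("f", [f2, f1]))
    key = lambda calls: [(c.target, [(f.t_start, f.t_end) for f in c.fragments])
                         for c in calls]
    assert key(a) == key(b)


def test_planted_split_event_detected_exactly(medium_genome):
    rec, man = medium_genome
    child, cman = evolve_genome(rec, man, EvolutionSpec(
        n_splits=1, split_deletion_aa=40, child_id="sp"), seed=13)
    ev = next(e for e in cman.events if e["event"] == "split")
    calls = detect_splits(proteome_from_record(rec), proteome_from_record(child))
    by_target = {c.target: c for c in calls}
    assert ev["source"] in by_target
    got = {f.fragment for f in by_target[ev["source"]].fragments}
    assert got == set(ev["fragments"])
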