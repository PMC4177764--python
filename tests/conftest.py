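import pytest

from compgen.synthetic_data import EvolutionSpec, GenomeSpec, evolve_genome, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 12-kbp phage-like genome with 15 genes and the default tRNA set."""
    return generate_genome(GenomeSpec(length_bp=12_000, n_genes=15,
                                      genome_id="small"), seed=11)


@pytest.fixture(scope="session")
def medium_genome():
    """A 30-kbp genome at study-condition density (1.5 genes/kbp)."""
    return generate_genome(GenomeSpec(length_bp=30_000, genome_id="medium"), seed=5)


@pytest.fixture(scope="session")
def diverged_pair(medium_genome):
    """Parent plus a child at 20% target amino-acid divergence."""
    rec, man = medium_genome
    child, cman = evolve_genome(rec, man, EvolutionSpec(aa_divergence=0.20,
                                                        child_id="child20"),
                                seed=77)
    return rec, man, child, cman


@pytest.fixture(scope="session")
def genbank_file(small_genome, tmp_path_factory):
    from compgen.genome_io import write_genbank

    rec, _ = small_genome
    path = tmp_path_factory.mktemp("gb") / "small.gb"
    write_genbank(rec, path)
    return path
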