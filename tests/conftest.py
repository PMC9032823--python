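import pytest

from panbbh.genomes import Genome
from panbbh.simulate import SimConfig, simulate_genome_set

#: The nine published GC percentages used as the worked summary example.
TABLE1_GC = (65.2, 66.5, 66.2, 52.4, 63.9, 66.2, 66.2, 64.7, 66.5)


@pytest.fixture(scope="session")
def small_set():
    """4 genomes at low divergence: the standard ortholog-recovery fixture."""
    cfg = SimConfig(
        n_genomes=4,
        n_core=12,
        accessory_spectrum=((2, 4), (3, 3)),
        n_singletons_per_genome=2,
        protein_len=100,
        aa_divergence=0.02,
        nt_divergence=0.02,
        seed=5,
    )
    genomes, truth = simulate_genome_set(cfg)
    return cfg, genomes, truth


@pytest.fixture()
def toy_genome():
    return Genome(
        name="toy",
        contigs=[("c1", "ATGC" * 500), ("c2", "GGCC" * 400)],
        proteins=[("g1", "MKV"), ("g2", "HEAGAWGHEE")],
        gene_to_contig={"g1": "c1", "g2": "c2"},
    )
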