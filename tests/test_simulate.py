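"""Synthetic genome-set generator: determinism, counts, and divergence."""

import io

import numpy as np
import pytest

from panbbh.genomes import write_genome_fasta
from panbbh.simulate import (
    ConfigError,
    SimConfig,
    expected_counts,
    load_config,
    preset,
    read_truth,
    simulate_genome_set,
    write_truth,
)


def _fasta_bytes(genomes, tmp_path, tag):
    chunks = []
    for name, g in genomes.items():
        nt, aa = tmp_path / f"{tag}{name}.fna", tmp_path / f"{tag}{name}.faa"
        write_genome_fasta(g, nt, aa)
        chunks.append(nt.read_bytes() + aa.read_bytes())
    return b"".join(chunks)


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        cfg = SimConfig(n_genomes=3, n_core=5, n_singletons_per_genome=1,
                        protein_len=50, seed=11)
        a = _fasta_bytes(simulate_genome_set(cfg)[0], tmp_path, "a")
        b = _fasta_bytes(simulate_genome_set(cfg)[0], tmp_path, "b")
        assert a == b

    def test_different_seed_differs(self, tmp_path):
        cfg = SimConfig(n_genomes=3, n_core=5, protein_len=50, seed=11)
        import dataclasses

        cfg2 = dataclasses.replace(cfg, seed=12)
        a = _fasta_bytes(simulate_genome_set(cfg)[0], tmp_path, "a")
        b = _fasta_bytes(simulate_genome_set(cfg2)[0], tmp_path, "b")
        assert a != b


class TestStructure:
    def test_zero_divergence_core_identical(self):
        cfg = SimConfig(n_genomes=3, n_core=10, aa_divergence=0.0,
                        nt_divergence=0.0, protein_len=40, seed=1)
        genomes, truth = simulate_genome_set(cfg)
        assert truth.counts().core == 10
        seqs = [dict(g.proteins) for g in genomes.values()]
        for fam in truth.families:
            prots = {seqs[list(genomes).index(g)][gid] for g, gid in fam.members}
            assert len(prots) == 1  # all copies identical

    def test_family_arithmetic(self):
        cfg = SimConfig(n_genomes=4, n_core=10, accessory_spectrum=((2, 5),),
                        n_singletons_per_genome=2, protein_len=30, seed=2)
        genomes, truth = simulate_genome_set(cfg)
        counts = truth.counts()
        assert (counts.pan, counts.core, counts.accessory, counts.singleton) == (
            10 + 5 + 8, 10, 5, 8,
        )
        # partition property of the emitted genomes
        total_genes = sum(len(g.proteins) for g in genomes.values())
        assert total_genes == sum(len(f.members) for f in truth.families)

    def test_truth_classes_well_formed(self, small_set):
        cfg, genomes, truth = small_set
        for fam in truth.families:
            n = len(fam.members)
            if fam.category == "core":
                assert n == cfg.n_genomes
                assert {g for g, _ in fam.members} == set(genomes)
            elif fam.category == "singleton":
                assert n == 1
            else:
                assert 2 <= n <= cfg.n_genomes - 1

    def test_contig_structure_and_gene_map(self):
        cfg = SimConfig(n_genomes=2, n_core=6, protein_len=30, n_contigs=3, seed=4)
        genomes, _ = simulate_genome_set(cfg)
        for g in genomes.values():
            assert len(g.contigs) == 3
            assert set(g.gene_to_contig) == set(g.gene_ids)


class TestExpectedCounts:
    def test_paper_scale_preset(self):
        counts = expected_counts(preset("guyparkeria-like"))
        assert (counts.pan, counts.core, counts.accessory, counts.singleton) == (
            3204, 1458, 909, 837,
        )

    def test_all_zero(self):
        c = expected_counts(SimConfig(n_genomes=2, n_core=0))
        assert (c.pan, c.core, c.accessory, c.singleton) == (0, 0, 0, 0)

    def test_hand_count(self):
        c = expected_counts(
            SimConfig(n_genomes=2, n_core=1, n_singletons_per_genome=1)
        )
        assert (c.pan, c.core, c.accessory, c.singleton) == (3, 1, 0, 2)


class TestValidation:
    def test_impossible_spectrum(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genomes=3, n_core=1, accessory_spectrum=((4, 2),)).validate()

    def test_occupancy_equal_G_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genomes=3, n_core=1, accessory_spectrum=((3, 2),)).validate()

    def test_divergence_range(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genomes=2, n_core=1, aa_divergence=0.6).validate()


def test_realized_pairwise_divergence_converges():
    """At length 10,000 the realized pairwise substitution fraction is
    within 20% (relative) of the configured divergence."""
    for d in (0.05, 0.10):
        cfg = SimConfig(n_genomes=2, n_core=1, protein_len=10_000,
                        aa_divergence=d, nt_divergence=d, seed=17)
        genomes, _ = simulate_genome_set(cfg)
        a, b = (g.proteins[0][1] for g in genomes.values())
        frac = np.mean([x != y for x, y in zip(a, b)])
        assert abs(frac - d) / d < 0.20


def test_truth_round_trip(tmp_path, small_set):
    _, _, truth = small_set
    write_truth(truth, tmp_path / "truth.tsv")
    back = read_truth(tmp_path / "truth.tsv")
    orig = {f.family_id: (f.category, frozenset(f.members)) for f in truth.families}
    got = {f.family_id: (f.category, frozenset(f.members)) for f in back.families}
    assert orig == got


def test_config_from_yaml(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text(
        "n_genomes: 3\nn_core: 4\naccessory_spectrum: [[2, 2]]\n"
        "n_singletons_per_genome: [1, 0, 2]\nprotein_len: 25\nseed: 3\n"
    )
    cfg = load_config(p)
    assert cfg.n_genomes == 3 and cfg.singletons() == (1, 0, 2)
    assert expected_counts(cfg).pan == 4 + 2 + 3
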