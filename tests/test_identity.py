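"""AAI/ANI matrices, rank classification, and matrix ordering."""

import numpy as np
import pytest

from panbbh.identity import (
    ClassificationError,
    IdentityMatrix,
    RankThresholds,
    aai_matrix,
    ani_matrix,
    classify_pair,
    compute_aai,
    compute_ani,
    order_matrix,
)
from panbbh.simulate import SimConfig, simulate_genome_set


def _pair(aa_div, nt_div, seed, n_core=30, protein_len=300):
    cfg = SimConfig(n_genomes=2, n_core=n_core, protein_len=protein_len,
                    aa_divergence=aa_div, nt_divergence=nt_div, seed=seed)
    genomes, _ = simulate_genome_set(cfg)
    return tuple(genomes.values())


class TestComputeAAI:
    def test_identical_genomes(self):
        a, _ = _pair(0.0, 0.0, 1)
        aai, n = compute_aai(a, a)
        assert aai == 100.0 and n == 30

    def test_recovers_programmed_divergence(self):
        a, b = _pair(0.10, 0.02, 7)
        aai, n = compute_aai(a, b)
        assert 88.0 <= aai <= 92.0
        assert n == 30

    def test_disjoint_proteomes_na(self):
        cfg = SimConfig(n_genomes=2, n_core=0, n_singletons_per_genome=8,
                        protein_len=300, seed=13)
        genomes, _ = simulate_genome_set(cfg)
        a, b = genomes.values()
        assert compute_aai(a, b) == (None, 0)


class TestComputeANI:
    def test_identical_genomes(self):
        a, _ = _pair(0.0, 0.0, 2)
        ani, _ = compute_ani(a, a)
        assert ani == 100.0

    def test_recovers_programmed_divergence(self):
        a, b = _pair(0.02, 0.03, 9)
        ani, n = compute_ani(a, b)
        assert 96.0 <= ani <= 98.0
        assert n >= 20

    def test_unrelated_genomes_na(self):
        cfg = SimConfig(n_genomes=2, n_core=0, n_singletons_per_genome=15,
                        protein_len=300, seed=13)
        genomes, _ = simulate_genome_set(cfg)
        a, b = genomes.values()
        assert compute_ani(a, b) == (None, 0)


@pytest.fixture(scope="module")
def three_genomes():
    cfg = SimConfig(n_genomes=3, n_core=20, protein_len=300,
                    aa_divergence=0.05, nt_divergence=0.05, seed=21)
    genomes, _ = simulate_genome_set(cfg)
    return genomes


class TestMatrices:

    def test_aai_matrix_symmetric_diag_100(self, three_genomes):
        m = aai_matrix(three_genomes)
        assert np.allclose(m.values, m.values.T, atol=1e-9)
        assert np.all(np.diag(m.values) == 100.0)
        assert np.all((m.values >= 0) & (m.values <= 100))

    def test_ani_matrix_symmetric_diag_100(self, three_genomes):
        m = ani_matrix(three_genomes)
        assert np.allclose(m.values, m.values.T, atol=1e-9)
        assert np.all(np.diag(m.values) == 100.0)

    def test_matrix_tsv_round_shape(self, three_genomes, tmp_path):
        m = aai_matrix(three_genomes)
        m.write_tsv(tmp_path / "aai.tsv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "aai.tsv", sep="\t", index_col=0)
        assert list(df.columns) == m.genomes and df.shape == (3, 3)


def test_divergence_recovery_grid():
    """Mean absolute error between recovered identity and 100·(1−d) stays
    within 1 percentage point across the divergence grid."""
    errs_aai, errs_ani = [], []
    for i, d in enumerate((0.01, 0.05, 0.10)):
        a, b = _pair(d, d, 100 + i, n_core=25, protein_len=300)
        aai, _ = compute_aai(a, b)
        ani, _ = compute_ani(a, b)
        errs_aai.append(abs(aai - 100 * (1 - d)))
        errs_ani.append(abs(ani - 100 * (1 - d)))
    assert np.mean(errs_aai) <= 1.0
    assert np.mean(errs_ani) <= 1.0


class TestClassifyPair:
    @pytest.mark.parametrize(
        "aai,ani,s16,expected",
        [
            (None, 97.0, None, "same_species"),
            (82.36, 90.0, 96.46, "same_genus"),
            (50.0, 75.0, 90.0, "different_genus"),
            (80.0, None, None, "same_genus"),
            (96.0, 90.0, None, "different_genus"),  # AAI above genus window
        ],
    )
    def test_examples(self, aai, ani, s16, expected):
        assert classify_pair(aai, ani, s16) == expected

    def test_all_na_rejected(self):
        with pytest.raises(ClassificationError):
            classify_pair(None, None, None)

    def test_monotone_in_ani(self):
        rank = {"different_genus": 0, "same_genus": 1, "same_species": 2}
        for aai in (50.0, 80.0, 96.0):
            calls = [rank[classify_pair(aai, ani, None)]
                     for ani in np.linspace(60, 100, 41)]
            assert all(x <= y for x, y in zip(calls, calls[1:]))

    def test_threshold_override(self):
        t = RankThresholds(species_ani=98.0)
        assert classify_pair(None, 97.0, None, t) == "different_genus"


class TestOrderMatrix:
    def _matrix(self, names, values):
        v = np.array(values, dtype=float)
        return IdentityMatrix("AAI", list(names), v, np.zeros_like(v, dtype=int))

    def test_two_genomes_unchanged(self):
        m = self._matrix("ab", [[100, 80], [80, 100]])
        assert order_matrix(m).genomes == ["a", "b"]

    def test_close_pair_adjacent(self):
        m = self._matrix(
            "abc", [[100, 99, 70], [99, 100, 70], [70, 70, 100]]
        )
        ordered = order_matrix(m).genomes
        assert abs(ordered.index("a") - ordered.index("b")) == 1

    def test_all_equal_preserves_input_order(self):
        m = self._matrix(
            "abcd",
            100 * np.eye(4) + 85 * (1 - np.eye(4)),
        )
        assert order_matrix(m).genomes == ["a", "b", "c", "d"]

    def test_na_genomes_excluded(self):
        v = np.array([[100, 90, np.nan], [90, 100, np.nan], [np.nan, np.nan, 100]])
        m = self._matrix("abc", v)
        assert order_matrix(m).genomes == ["a", "b"]
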