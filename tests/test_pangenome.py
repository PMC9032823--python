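"""Partitioning, development curves, and growth-law fits."""

import numpy as np
import pytest

from panbbh.orthology import Family, OrthologTable
from panbbh.pangenome import (
    DevelopmentCurve,
    FitError,
    HeapsFit,
    classify_openness,
    development,
    fit_decay,
    fit_heaps,
    partition,
)
from oracles import exhaustive_medians, exhaustive_pan_core


def _table(occupancy_members, genomes):
    """Build a table from a list of member-genome sets."""
    fams = [
        Family(f"f{i}", {g: f"{g}_x{i}" for g in members})
        for i, members in enumerate(occupancy_members)
    ]
    return OrthologTable(genomes=list(genomes), families=fams)


TOY3 = _table(
    [{"a", "b", "c"}, {"a", "b", "c"}, {"a", "b"}, {"a"}, {"c"}], "abc"
)


class TestPartition:
    def test_hand_counted_toy(self):
        counts = partition(TOY3)
        assert (counts.pan, counts.core, counts.accessory, counts.singleton) == (
            5, 2, 1, 2,
        )

    def test_all_core(self):
        t = _table([{"a", "b"}] * 4, "ab")
        counts = partition(t)
        assert counts.core == counts.pan == 4
        assert counts.accessory == counts.singleton == 0

    def test_conservation_invariant(self, small_set):
        from panbbh.orthology import table_from_truth

        _, _, truth = small_set
        c = partition(table_from_truth(truth))
        assert c.pan == c.core + c.accessory + c.singleton


@pytest.fixture(scope="module")
def toy4(small_set):
    from panbbh.orthology import table_from_truth

    _, _, truth = small_set
    return table_from_truth(truth)


class TestDevelopment:

    def test_endpoint_N_equals_G(self, toy4):
        curve = development(toy4, seed=0)
        counts = partition(toy4)
        G = toy4.n_genomes
        assert curve.median_pan[G] == counts.pan
        assert curve.median_core[G] == counts.core

    def test_endpoint_N_1(self, toy4):
        curve = development(toy4, seed=0)
        sizes = sorted(len([f for f in toy4.families if g in f.members])
                       for g in toy4.genomes)
        med = (sizes[1] + sizes[2]) / 2
        assert curve.median_pan[1] == med
        assert curve.median_core[1] == med

    def test_medians_match_exhaustive_oracle(self, toy4):
        curve = development(toy4, seed=0)
        members = [set(f.members) for f in toy4.families]
        for n in curve.N:
            pan_med, core_med = exhaustive_medians(members, toy4.genomes, n)
            assert curve.median_pan[n] == pan_med
            assert curve.median_core[n] == core_med

    def test_monotone_medians(self, toy4):
        curve = development(toy4, seed=0)
        pans = [curve.median_pan[n] for n in curve.N]
        cores = [curve.median_core[n] for n in curve.N]
        assert all(x <= y for x, y in zip(pans, pans[1:]))
        assert all(x >= y for x, y in zip(cores, cores[1:]))

    def test_per_subset_invariants(self, toy4):
        curve = development(toy4, seed=0)
        sizes = {g: sum(1 for f in toy4.families if g in f.members)
                 for g in toy4.genomes}
        min_size, total = min(sizes.values()), sum(sizes.values())
        for n in curve.N:
            for pan, core in curve.samples_per_N[n]:
                assert core <= pan <= total
                assert core <= min_size or n == 1

    def test_sampled_agrees_with_exhaustive_medians(self, toy4):
        # tiny cap forces sampling; medians stay near exhaustive values
        full = development(toy4, max_samples_per_N=500, seed=0)
        sampled = development(toy4, max_samples_per_N=3, seed=1)
        members = [set(f.members) for f in toy4.families]
        for n in sampled.N:
            if sampled.exhaustive[n]:
                assert sampled.median_pan[n] == full.median_pan[n]
            # sampled subsets are genuine subsets: values within observed range
            pans = [p for p, _ in full.samples_per_N[n]]
            assert min(pans) <= sampled.median_pan[n] <= max(pans)

    def test_seed_reproducibility(self, toy4):
        a = development(toy4, max_samples_per_N=3, seed=9)
        b = development(toy4, max_samples_per_N=3, seed=9)
        assert a.samples_per_N == b.samples_per_N


class TestFits:
    def test_heaps_recovers_published_pan_function(self):
        N = np.arange(1, 9)
        curve = DevelopmentCurve.from_medians(N, 2092 * N**0.185, np.ones(8))
        fit = fit_heaps(curve)
        assert fit.gamma == pytest.approx(0.185, abs=1e-6)
        assert fit.alpha == pytest.approx(0.815, abs=1e-6)
        assert fit.k == pytest.approx(2092, rel=1e-6)

    def test_decay_recovers_published_core_function(self):
        N = np.arange(1, 9)
        core = 670.278 * np.exp(-N / 4.764) + 1384.351
        fit = fit_decay(DevelopmentCurve.from_medians(N, np.ones(8), core))
        assert fit.k == pytest.approx(670.278, rel=1e-3)
        assert fit.tau == pytest.approx(4.764, rel=1e-3)
        assert fit.tg_theta == pytest.approx(1384.351, rel=1e-3)

    def test_heaps_flat_curve(self):
        N = np.arange(1, 9)
        fit = fit_heaps(DevelopmentCurve.from_medians(N, np.full(8, 1234.0), N))
        assert fit.gamma == pytest.approx(0.0, abs=1e-9)
        assert fit.alpha == pytest.approx(1.0, abs=1e-9)

    def test_heaps_linear_growth(self):
        N = np.arange(1, 9)
        fit = fit_heaps(DevelopmentCurve.from_medians(N, N.astype(float), N))
        assert fit.k == pytest.approx(1.0, abs=1e-9)
        assert fit.gamma == pytest.approx(1.0, abs=1e-9)

    def test_decay_flat_curve_limit(self):
        N = np.arange(1, 9)
        fit = fit_decay(DevelopmentCurve.from_medians(N, N, np.full(8, 321.0)))
        assert np.max(np.abs(fit.predict(N) - 321.0)) < 1e-6

    def test_decay_self_consistency(self):
        N = np.arange(1, 9)
        core = 100.0 * np.exp(-N / 2.0) + 1000.0
        fit = fit_decay(DevelopmentCurve.from_medians(N, N, core))
        assert fit.k == pytest.approx(100.0, rel=1e-6)
        assert fit.tau == pytest.approx(2.0, rel=1e-6)
        assert fit.tg_theta == pytest.approx(1000.0, rel=1e-6)

    @pytest.mark.parametrize("gamma", [0.1, 0.5, 0.9])
    def test_heaps_parameter_recovery_grid(self, gamma):
        N = np.arange(1, 11)
        curve = DevelopmentCurve.from_medians(N, 1500 * N**gamma, N)
        fit = fit_heaps(curve)
        assert fit.gamma == pytest.approx(gamma, rel=1e-6)
        assert fit.k == pytest.approx(1500, rel=1e-6)

    def test_too_few_points_rejected(self):
        curve = DevelopmentCurve.from_medians([1, 2], [10.0, 12.0], [9.0, 8.0])
        with pytest.raises(FitError):
            fit_heaps(curve)
        with pytest.raises(FitError):
            fit_decay(curve)


class TestOpenness:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(0.815, "open"), (1.0, "closed"), (1.3, "closed")],
    )
    def test_boundary(self, alpha, expected):
        fit = HeapsFit(k=2000.0, gamma=1 - alpha, residual_ss=0.0)
        assert classify_openness(fit) == expected


def test_outlier_removal_narrows_core_spread():
    """Dropping a genome that misses many shared families tightens the
    inter-quartile range of core sizes at fixed N (the bipartite-pattern
    effect in core development plots)."""
    rng = np.random.default_rng(6)
    genomes = [f"g{i}" for i in range(5)]
    members = []
    # 60 families shared by all five; the outlier g4 misses 30 of them
    for i in range(60):
        full = set(genomes)
        if i < 30:
            full.discard("g4")
        members.append(full)
    members += [{g} for g in genomes for _ in range(3)]
    table = _table(members, genomes)
    with_outlier = development(table, seed=2)
    without = development(table.subset(genomes[:4]), seed=2)
    n = 3
    iqr_with = np.subtract(*reversed(with_outlier.quartiles_core[n]))
    iqr_without = np.subtract(*reversed(without.quartiles_core[n]))
    assert iqr_without < iqr_with
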