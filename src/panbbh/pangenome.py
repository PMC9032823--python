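"""Pan/core partitioning, development curves, and growth-law fits.

Given an ortholog table over G genomes, families are classed by occupancy:
core (all G genomes), accessory (2..G−1), singleton (exactly 1).  The
development curve tracks, for each subset size N, the distribution of pan
and core sizes over genome subsets — exhaustively when C(G, N) is small,
by uniform sampling of distinct subsets otherwise.

Two laws are fitted to the per-N medians by nonlinear least squares on the
original scale:

* Heaps' law for the pangenome, n = k·N^γ, with openness index α = 1 − γ;
  α < 1 indicates an open pangenome (new genomes keep contributing genes).
* Exponential decay for the core genome, n = k·e^(−N/τ) + tgθ, whose
  asymptote tgθ estimates the stable core size.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .orthology import OrthologTable

logger = logging.getLogger("panbbh")

DEFAULT_MAX_SAMPLES_PER_N = 500


class FitError(RuntimeError):
    """A nonlinear fit failed to converge."""


@dataclass(frozen=True)
class PartitionCounts:
    """Family counts by occupancy class; pan = core + accessory + singleton."""

    pan: int
    core: int
    accessory: int
    singleton: int

    def __post_init__(self):
        if self.pan != self.core + self.accessory + self.singleton:
            raise ValueError("partition counts do not sum to pan")

    def fractions(self) -> tuple[float, float, float]:
        """(core, accessory, singleton) as fractions of the pangenome."""
        if self.pan == 0:
            return (0.0, 0.0, 0.0)
        return (
            self.core / self.pan,
            self.accessory / self.pan,
            self.singleton / self.pan,
        )

    def percentages(self) -> tuple[int, int, int]:
        """Fractions as whole percentages (rounded half to even)."""
        return tuple(round(100 * f) for f in self.fractions())  # type: ignore


@dataclass
class DevelopmentCurve:
    """Pan/core size distributions over sampled genome subsets.

    ``samples_per_N[N]`` is a list of ``(pan, core)`` pairs, one per
    sampled subset; medians and quartiles are summarized per N.
    """

    N: list[int]
    samples_per_N: dict[int, list[tuple[int, int]]]
    median_pan: dict[int, float] = field(default_factory=dict)
    median_core: dict[int, float] = field(default_factory=dict)
    quartiles_pan: dict[int, tuple[float, float]] = field(default_factory=dict)
    quartiles_core: dict[int, tuple[float, float]] = field(default_factory=dict)
    exhaustive: dict[int, bool] = field(default_factory=dict)

    def summarize(self) -> None:
        for n in self.N:
            pans = np.array([p for p, _ in self.samples_per_N[n]], dtype=float)
            cores = np.array([c for _, c in self.samples_per_N[n]], dtype=float)
            self.median_pan[n] = float(np.median(pans))
            self.median_core[n] = float(np.median(cores))
            self.quartiles_pan[n] = tuple(np.percentile(pans, [25, 75]))
            self.quartiles_core[n] = tuple(np.percentile(cores, [25, 75]))

    @classmethod
    def from_medians(
        cls, N: Sequence[int], pan: Sequence[float], core: Sequence[float]
    ) -> "DevelopmentCurve":
        """Wrap precomputed per-N medians (one pseudo-sample per N)."""
        curve = cls(
            N=list(N),
            samples_per_N={
                int(n): [(float(p), float(c))] for n, p, c in zip(N, pan, core)
            },
        )
        curve.summarize()
        return curve

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.N:
            for k, (p, c) in enumerate(self.samples_per_N[n]):
                rows.append({"N": n, "sample_index": k, "pan": p, "core": c})
        return pd.DataFrame(rows)

    def medians_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": self.N,
                "median_pan": [self.median_pan[n] for n in self.N],
                "median_core": [self.median_core[n] for n in self.N],
                "q25_pan": [self.quartiles_pan[n][0] for n in self.N],
                "q75_pan": [self.quartiles_pan[n][1] for n in self.N],
                "q25_core": [self.quartiles_core[n][0] for n in self.N],
                "q75_core": [self.quartiles_core[n][1] for n in self.N],
            }
        )


@dataclass(frozen=True)
class HeapsFit:
    """Fitted Heaps'-law constants; alpha = 1 − gamma by definition."""

    k: float
    gamma: float
    residual_ss: float

    @property
    def alpha(self) -> float:
        return 1.0 - self.gamma

    def predict(self, N):
        return self.k * np.asarray(N, dtype=float) ** self.gamma


@dataclass(frozen=True)
class DecayFit:
    """Fitted exponential-decay constants for the core genome."""

    k: float
    tau: float
    tg_theta: float
    residual_ss: float

    def predict(self, N):
        return self.k * np.exp(-np.asarray(N, dtype=float) / self.tau) + self.tg_theta


# ---------------------------------------------------------------------------
# operations


def partition(table: OrthologTable) -> PartitionCounts:
    """Count families by occupancy class (G taken from the table)."""
    occ = table.occupancies()
    G = table.n_genomes
    core = int(np.sum(occ == G))
    singleton = int(np.sum(occ == 1)) if G > 1 else 0
    return PartitionCounts(
        pan=len(occ),
        core=core,
        accessory=len(occ) - core - singleton,
        singleton=singleton,
    )


def _subset_sizes(mat: np.ndarray, cols: Sequence[int]) -> tuple[int, int]:
    sub = mat[:, list(cols)]
    return int(sub.any(axis=1).sum()), int(sub.all(axis=1).sum())


def development(
    table: OrthologTable,
    max_samples_per_N: int = DEFAULT_MAX_SAMPLES_PER_N,
    seed: int | None = 0,
) -> DevelopmentCurve:
    """Pan/core development over genome subsets of every size 1..G.

    For each N, all C(G, N) subsets are enumerated when that count is at
    most ``max_samples_per_N``; otherwise ``max_samples_per_N`` distinct
    subsets are drawn uniformly at random (seeded, reproducible).
    """
    G = table.n_genomes
    if G < 2:
        raise ValueError("development needs at least two genomes")
    mat = table.presence_matrix()
    rng = np.random.default_rng(seed)
    curve = DevelopmentCurve(N=list(range(1, G + 1)), samples_per_N={})
    for n in curve.N:
        n_subsets = math.comb(G, n)
        if n_subsets <= max_samples_per_N:
            subsets = list(itertools.combinations(range(G), n))
            curve.exhaustive[n] = True
        else:
            chosen: set[tuple[int, ...]] = set()
            while len(chosen) < max_samples_per_N:
                chosen.add(tuple(sorted(rng.choice(G, size=n, replace=False).tolist())))
            subsets = sorted(chosen)
            curve.exhaustive[n] = False
        curve.samples_per_N[n] = [_subset_sizes(mat, s) for s in subsets]
    curve.summarize()
    return curve


def _medians(curve: DevelopmentCurve, which: str) -> tuple[np.ndarray, np.ndarray]:
    source = curve.median_pan if which == "pan" else curve.median_core
    N = np.array(sorted(source), dtype=float)
    y = np.array([source[int(n)] for n in N], dtype=float)
    return N, y


def fit_heaps(curve: DevelopmentCurve) -> HeapsFit:
    """Least-squares fit of n = k·N^γ to the median pan sizes.

    The fit is nonlinear on the original scale; log–log ordinary least
    squares only supplies the starting point.
    """
    N, y = _medians(curve, "pan")
    if len(N) < 3:
        raise FitError("fit_heaps needs medians at >= 3 distinct N")
    if np.any(y <= 0):
        raise FitError("fit_heaps needs positive pan sizes")
    slope, intercept = np.polyfit(np.log(N), np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        with warnings.catch_warnings():
            # covariance is unused and singular for degenerate inputs
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda n, k, g: k * n**g,
                N,
                y,
                p0=p0,
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
            )
    except RuntimeError as exc:
        raise FitError(f"Heaps fit did not converge (p0={p0}): {exc}") from exc
    k, gamma = float(popt[0]), float(popt[1])
    rss = float(np.sum((k * N**gamma - y) ** 2))
    return HeapsFit(k=k, gamma=gamma, residual_ss=rss)


def fit_decay(curve: DevelopmentCurve) -> DecayFit:
    """Least-squares fit of n = k·e^(−N/τ) + tgθ to the median core sizes.

    Initialization: tgθ₀ = min median, k₀ = max − min, τ₀ = G/3; bounds
    keep k ≥ 0, τ > 0, tgθ ≥ 0.
    """
    N, y = _medians(curve, "core")
    if len(N) < 4:
        raise FitError("fit_decay needs medians at >= 4 distinct N")
    tg0 = float(y.min())
    k0 = float(y.max() - y.min())
    tau0 = float(N.max() / 3.0)
    try:
        with warnings.catch_warnings():
            # the covariance estimate is unused; it is singular for
            # degenerate (e.g. flat) inputs
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda n, k, tau, tg: k * np.exp(-n / tau) + tg,
                N,
                y,
                p0=(k0, tau0, tg0),
                bounds=((0.0, 1e-9, 0.0), (np.inf, np.inf, np.inf)),
                maxfev=20000,
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
    except RuntimeError as exc:
        raise FitError(f"decay fit did not converge (p0={(k0, tau0, tg0)}): {exc}") from exc
    k, tau, tg = (float(v) for v in popt)
    rss = float(np.sum((k * np.exp(-N / tau) + tg - y) ** 2))
    return DecayFit(k=k, tau=tau, tg_theta=tg, residual_ss=rss)


def classify_openness(fit: HeapsFit) -> str:
    """'open' when α < 1 (growth never saturates), else 'closed'."""
    return "open" if fit.alpha < 1 else "closed"


# ---------------------------------------------------------------------------
# I/O


def write_curve(curve: DevelopmentCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)


def write_medians(curve: DevelopmentCurve, path: str | Path) -> None:
    curve.medians_frame().to_csv(path, sep="\t", index=False)


def fits_to_dict(heaps: HeapsFit | None, decay: DecayFit | None) -> dict:
    out: dict = {}
    if heaps is not None:
        out["heaps"] = {
            "k": heaps.k,
            "gamma": heaps.gamma,
            "alpha": heaps.alpha,
            "residual_ss": heaps.residual_ss,
            "openness": classify_openness(heaps),
        }
    if decay is not None:
        out["decay"] = {
            "k": decay.k,
            "tau": decay.tau,
            "tg_theta": decay.tg_theta,
            "residual_ss": decay.residual_ss,
        }
    return out


def write_fits(heaps: HeapsFit | None, decay: DecayFit | None, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fits_to_dict(heaps, decay), indent=2) + "\n")


def plot_development(curve: DevelopmentCurve, path: str | Path) -> None:
    """Two-panel pan/core development plot (medians with quartile bands)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    N = np.array(curve.N)
    for ax, which, color in ((ax1, "pan", "tab:blue"), (ax2, "core", "tab:orange")):
        med = curve.median_pan if which == "pan" else curve.median_core
        qs = curve.quartiles_pan if which == "pan" else curve.quartiles_core
        y = [med[n] for n in curve.N]
        lo = [qs[n][0] for n in curve.N]
        hi = [qs[n][1] for n in curve.N]
        ax.fill_between(N, lo, hi, alpha=0.3, color=color)
        ax.plot(N, y, "o-", color=color)
        ax.set_xlabel("genomes sampled (N)")
        ax.set_ylabel(f"{which} genome size (gene families)")
        ax.set_title(f"{which} development")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
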