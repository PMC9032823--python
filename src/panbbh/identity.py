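"""Pairwise AAI/ANI matrices and genus/species rank classification.

AAI is the mean protein percent identity over bidirectional-best-hit
ortholog pairs between two genomes; ANI is the mean identity of genomic
fragments placed in the partner genome, averaged over both directions.
Conventional rank windows: AAI 65–95% (together with 16S identity
95–98.6%, when available) delimits a genus; ANI above 95% delimits a
species, species taking precedence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from . import align
from .align import DEFAULT_MIN_BITSCORE, align_protein
from .genomes import Genome, GenomeSet
from .orthology import bbh_pairs

logger = logging.getLogger("panbbh")


class ClassificationError(ValueError):
    """No usable identity metric was supplied."""


@dataclass(frozen=True)
class RankThresholds:
    """Rank windows, in percent identity."""

    genus_aai: tuple[float, float] = (65.0, 95.0)
    genus_16s: tuple[float, float] = (95.0, 98.6)
    species_ani: float = 95.0


DEFAULT_THRESHOLDS = RankThresholds()


@dataclass
class IdentityMatrix:
    """Symmetric matrix of pairwise identity percentages over a genome set.

    ``values`` holds percentages with NaN for undefined (NA) cells; the
    diagonal is exactly 100.  ``n_pairs`` counts BBH pairs (AAI) or
    retained fragments (ANI) per cell.
    """

    kind: str  # "AAI" | "ANI"
    genomes: list[str]
    values: np.ndarray
    n_pairs: np.ndarray

    def value(self, a: str, b: str) -> float:
        i, j = self.genomes.index(a), self.genomes.index(b)
        return float(self.values[i, j])

    def validate(self) -> None:
        v = self.values
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError(f"{self.kind} matrix diagonal must be 100")
        mask = ~np.isnan(v)
        if not np.array_equal(mask, mask.T) or not np.allclose(
            v[mask & mask.T], v.T[mask & mask.T], atol=1e-9
        ):
            raise ValueError(f"{self.kind} matrix not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.round(self.values, 2), index=self.genomes, columns=self.genomes
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="", na_rep="")


# ---------------------------------------------------------------------------
# pairwise computations


def compute_aai(
    a: Genome,
    b: Genome,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    pairs: Iterable[tuple[str, str]] | None = None,
    length_weighted: bool = False,
) -> tuple[float | None, int]:
    """AAI between two genomes: mean identity over BBH ortholog pairs.

    ``pairs`` may supply precomputed ortholog gene-id pairs (e.g. from an
    ortholog table); otherwise BBH pairs are computed here.  Because exact
    Smith–Waterman scoring is symmetric, the a→b and b→a directions give
    the same pair set and identities, so no separate reverse pass is
    needed.  Returns ``(aai, n_pairs)``; ``(None, 0)`` without any pair.
    ``length_weighted=True`` weights each pair by its alignment length.
    """
    if pairs is None:
        pairs = bbh_pairs(a, b, min_bitscore)
    aseq = dict(a.proteins)
    bseq = dict(b.proteins)
    idents: list[float] = []
    lengths: list[int] = []
    for ga, gb in pairs:
        hit = align_protein(aseq[ga], bseq[gb], ga, gb)
        idents.append(hit.percent_identity)
        lengths.append(hit.aln_len)
    if not idents:
        return None, 0
    if length_weighted:
        return float(np.average(idents, weights=lengths)), len(idents)
    return float(np.mean(idents)), len(idents)


def compute_ani(
    a: Genome,
    b: Genome,
    frag_len: int = align.DEFAULT_FRAG_LEN,
    min_id: float = align.DEFAULT_MIN_ID,
    min_cov: float = align.DEFAULT_MIN_COV,
) -> tuple[float | None, int]:
    """ANI between two genomes: mean of the two one-way fragment ANIs.

    A one-way value that is NA is dropped; when both directions are NA the
    result is ``(None, 0)``.  Returns total retained fragments as n.
    """
    ab, n_ab = align.ani_fragments(a, b, frag_len, min_id, min_cov)
    ba, n_ba = align.ani_fragments(b, a, frag_len, min_id, min_cov)
    vals = [v for v in (ab, ba) if v is not None]
    if not vals:
        return None, 0
    return float(np.mean(vals)), n_ab + n_ba


def _matrix(
    kind: str,
    genomes: GenomeSet,
    pairwise,
) -> IdentityMatrix:
    names = list(genomes)
    n = len(names)
    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    np.fill_diagonal(values, 100.0)
    for i, j in itertools.combinations(range(n), 2):
        val, npairs = pairwise(genomes[names[i]], genomes[names[j]])
        if val is not None:
            values[i, j] = values[j, i] = val
        counts[i, j] = counts[j, i] = npairs
    mat = IdentityMatrix(kind=kind, genomes=names, values=values, n_pairs=counts)
    mat.validate()
    return mat


def aai_matrix(
    genomes: GenomeSet,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    pairs_by_pair: Mapping[tuple[str, str], Iterable[tuple[str, str]]] | None = None,
) -> IdentityMatrix:
    """Pairwise AAI over a genome set.

    ``pairs_by_pair`` optionally maps (genome_a, genome_b) → ortholog
    gene-id pairs, bypassing BBH recomputation.
    """

    def pairwise(a: Genome, b: Genome):
        pairs = None
        if pairs_by_pair is not None:
            pairs = pairs_by_pair.get((a.name, b.name))
            if pairs is None:
                rev = pairs_by_pair.get((b.name, a.name))
                pairs = [(y, x) for x, y in rev] if rev is not None else None
        return compute_aai(a, b, min_bitscore, pairs=pairs)

    return _matrix("AAI", genomes, pairwise)


def ani_matrix(
    genomes: GenomeSet,
    frag_len: int = align.DEFAULT_FRAG_LEN,
    min_id: float = align.DEFAULT_MIN_ID,
    min_cov: float = align.DEFAULT_MIN_COV,
) -> IdentityMatrix:
    """Pairwise ANI over a genome set (fragment method, both directions)."""
    return _matrix(
        "ANI", genomes, lambda a, b: compute_ani(a, b, frag_len, min_id, min_cov)
    )


# ---------------------------------------------------------------------------
# classification and ordering


def classify_pair(
    aai: float | None,
    ani: float | None,
    sixteen_s_id: float | None = None,
    thresholds: RankThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Rank call for one genome pair: same_species, same_genus, or
    different_genus.

    Species (ANI above the species bound) takes precedence over genus
    (AAI within the genus window, and 16S within its window when
    supplied).  Raising ANI can never demote a call.
    """
    if aai is None and ani is None and sixteen_s_id is None:
        raise ClassificationError("all identity metrics are NA")
    if ani is not None and ani > thresholds.species_ani:
        return "same_species"
    lo, hi = thresholds.genus_aai
    if aai is not None and lo <= aai <= hi:
        s_lo, s_hi = thresholds.genus_16s
        if sixteen_s_id is None or s_lo <= sixteen_s_id <= s_hi:
            return "same_genus"
    return "different_genus"


def classification_report(
    aai: IdentityMatrix,
    ani: IdentityMatrix,
    sixteen_s: Mapping[tuple[str, str], float] | None = None,
    thresholds: RankThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-pair TSV-ready table: genome_i, genome_j, aai, ani, call."""
    rows = []
    for i, j in itertools.combinations(range(len(aai.genomes)), 2):
        gi, gj = aai.genomes[i], aai.genomes[j]
        a = aai.values[i, j]
        n = ani.value(gi, gj) if gi in ani.genomes and gj in ani.genomes else np.nan
        s = None
        if sixteen_s is not None:
            s = sixteen_s.get((gi, gj), sixteen_s.get((gj, gi)))
        call = classify_pair(
            None if np.isnan(a) else float(a),
            None if np.isnan(n) else float(n),
            s,
            thresholds,
        )
        rows.append(
            {"genome_i": gi, "genome_j": gj, "aai": a, "ani": n, "call": call}
        )
    return pd.DataFrame(rows)


def order_matrix(matrix: IdentityMatrix) -> IdentityMatrix:
    """Reorder genomes by average-linkage clustering on 100 − identity.

    Genomes with any NA cell are excluded (logged) before clustering.
    With all pairwise distances tied, the input order is preserved.
    """
    # drop as few genomes as possible: repeatedly remove the genome with
    # the most NA cells (ties to the later name) until none remain
    keep = list(range(len(matrix.genomes)))
    while True:
        sub = matrix.values[np.ix_(keep, keep)]
        na_counts = np.isnan(sub).sum(axis=1)
        if na_counts.sum() == 0:
            break
        worst = max(range(len(keep)), key=lambda i: (na_counts[i], matrix.genomes[keep[i]]))
        keep.pop(worst)
    if len(keep) < len(matrix.genomes):
        dropped = [g for i, g in enumerate(matrix.genomes) if i not in keep]
        logger.warning("order_matrix: excluding genomes with NA cells: %s", dropped)
    names = [matrix.genomes[i] for i in keep]
    values = matrix.values[np.ix_(keep, keep)]
    counts = matrix.n_pairs[np.ix_(keep, keep)]
    dist = 100.0 - values
    np.fill_diagonal(dist, 0.0)
    offdiag = dist[~np.eye(len(names), dtype=bool)]
    if len(names) <= 2 or np.allclose(offdiag, offdiag.flat[0] if offdiag.size else 0):
        order = np.arange(len(names))  # nothing to separate: keep input order
    else:
        order = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    return IdentityMatrix(
        kind=matrix.kind,
        genomes=[names[i] for i in order],
        values=values[np.ix_(order, order)],
        n_pairs=counts[np.ix_(order, order)],
    )
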