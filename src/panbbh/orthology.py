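"""Gene-family construction across a genome set from bidirectional best hits.

The central artifact is the :class:`OrthologTable`: a partition of every
gene of every genome into families, with at most one gene per genome per
family (the matrix downstream pan/core counting needs is binary).

Construction is reference-anchored: families are seeded by the reference
genome's genes and each other genome contributes its BBH partner of the
reference gene.  Genes without a reference partner are then clustered
among themselves by single-linkage over the remaining pairwise BBH graph,
and anything still unmatched becomes a singleton family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .align import DEFAULT_MIN_BITSCORE, bit_score, protein_score_matrix
from .genomes import Genome, GenomeSet

logger = logging.getLogger("panbbh")


class TableError(ValueError):
    """An ortholog table violates its invariants or could not be parsed."""


@dataclass
class Family:
    family_id: str
    members: dict[str, str]  # genome name -> gene id

    @property
    def occupancy(self) -> int:
        return len(self.members)


@dataclass
class OrthologTable:
    """Gene-family × genome presence/absence structure."""

    genomes: list[str]
    families: list[Family] = field(default_factory=list)
    reference: str | None = None

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def occupancies(self) -> np.ndarray:
        return np.array([f.occupancy for f in self.families], dtype=int)

    def presence_matrix(self) -> np.ndarray:
        """Boolean families × genomes matrix."""
        idx = {g: j for j, g in enumerate(self.genomes)}
        mat = np.zeros((len(self.families), len(self.genomes)), dtype=bool)
        for i, fam in enumerate(self.families):
            for g in fam.members:
                mat[i, idx[g]] = True
        return mat

    def subset(self, genomes: list[str]) -> "OrthologTable":
        """Restrict to a genome subset; families emptied by the cut are dropped."""
        keep = set(genomes)
        fams = []
        for fam in self.families:
            members = {g: gid for g, gid in fam.members.items() if g in keep}
            if members:
                fams.append(Family(fam.family_id, members))
        ref = self.reference if self.reference in keep else None
        return OrthologTable(genomes=list(genomes), families=fams, reference=ref)

    def validate(self, genomes: GenomeSet | None = None) -> None:
        """Check the partition property (each gene in exactly one family)."""
        seen: set[tuple[str, str]] = set()
        for fam in self.families:
            if not fam.members:
                raise TableError(f"{fam.family_id}: empty family")
            for g, gid in fam.members.items():
                if g not in self.genomes:
                    raise TableError(f"{fam.family_id}: unknown genome {g!r}")
                key = (g, gid)
                if key in seen:
                    raise TableError(f"gene {gid!r} of {g!r} is in two families")
                seen.add(key)
        if genomes is not None:
            for name in self.genomes:
                expect = set(genomes[name].gene_ids)
                got = {gid for g, gid in seen if g == name}
                if expect != got:
                    missing = sorted(expect - got)[:5]
                    extra = sorted(got - expect)[:5]
                    raise TableError(
                        f"{name}: table does not partition the proteome "
                        f"(missing {missing}, extra {extra})"
                    )


# ---------------------------------------------------------------------------
# BBH


def bbh_pairs(
    a: Genome,
    b: Genome,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    score_matrix: np.ndarray | None = None,
    with_scores: bool = False,
):
    """Bidirectional best hits between two genomes.

    ``(x, y)`` is included iff y is x's best hit in b and x is y's best
    hit in a, both with bit score ≥ ``min_bitscore``.  Ties are broken
    toward the lexicographically smallest partner id, making the result a
    deterministic partial matching.  With ``with_scores=True`` a dict
    mapping pairs to bit scores is returned instead of a set.
    """
    if not a.proteins or not b.proteins:
        raise ValueError("both genomes must have at least one protein")
    if score_matrix is None:
        score_matrix = protein_score_matrix(a, b)
    aids, bids = a.gene_ids, b.gene_ids
    a_order = sorted(range(len(aids)), key=lambda i: aids[i])
    b_order = sorted(range(len(bids)), key=lambda j: bids[j])

    def _best(scores: np.ndarray, order) -> int | None:
        best = scores.max()
        if best <= 0:
            return None
        for k in order:
            if scores[k] == best:
                return k
        return None

    best_in_b = {i: _best(score_matrix[i, :], b_order) for i in range(len(aids))}
    best_in_a = {j: _best(score_matrix[:, j], a_order) for j in range(len(bids))}
    pairs: dict[tuple[str, str], float] = {}
    for i, j in best_in_b.items():
        if j is None or best_in_a[j] != i:
            continue
        bits = bit_score(float(score_matrix[i, j]))
        if bits >= min_bitscore:
            pairs[(aids[i], bids[j])] = bits
    return pairs if with_scores else set(pairs)


def build_table(
    genomes: GenomeSet,
    reference: str,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
) -> OrthologTable:
    """Build the ortholog table for a genome set, anchored on ``reference``.

    Requires ≥ 2 genomes.  After anchoring and single-linkage mop-up the
    partition property is verified.  When single linkage pulls two genes of
    one genome into a component, the gene with the higher summed bit score
    stays and the other is split off (logged), keeping families binary.
    """
    if reference not in genomes:
        raise KeyError(f"reference genome {reference!r} not in set")
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    names = list(genomes)
    # all pairwise BBH maps with bit scores, computed once per unordered pair
    pair_bbh: dict[tuple[str, str], dict[tuple[str, str], float]] = {}
    for ga, gb in itertools.combinations(names, 2):
        pair_bbh[(ga, gb)] = bbh_pairs(
            genomes[ga], genomes[gb], min_bitscore, with_scores=True
        )
        logger.debug("bbh %s~%s: %d pairs", ga, gb, len(pair_bbh[(ga, gb)]))

    def bbh_of(ga: str, gb: str) -> dict[tuple[str, str], float]:
        if (ga, gb) in pair_bbh:
            return pair_bbh[(ga, gb)]
        return {(y, x): s for (x, y), s in pair_bbh[(gb, ga)].items()}

    assigned: set[tuple[str, str]] = set()
    families: list[Family] = []

    # 1) anchor on the reference proteome
    anchor_map = {
        other: {x: y for (x, y) in bbh_of(reference, other)}
        for other in names
        if other != reference
    }
    for ref_gid in genomes[reference].gene_ids:
        members = {reference: ref_gid}
        for other, partner_of in anchor_map.items():
            if ref_gid in partner_of:
                members[other] = partner_of[ref_gid]
        families.append(Family(ref_gid, members))
        assigned.update((g, gid) for g, gid in members.items())

    # 2) single-linkage mop-up over BBH edges among leftover genes
    leftovers = [
        (g, gid)
        for g in names
        for gid in genomes[g].gene_ids
        if (g, gid) not in assigned
    ]
    index = {node: k for k, node in enumerate(leftovers)}
    parent = list(range(len(leftovers)))

    def find(k: int) -> int:
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    strength: dict[tuple[str, str], float] = {node: 0.0 for node in leftovers}
    for ga, gb in itertools.combinations(names, 2):
        for (x, y), s in pair_bbh[(ga, gb)].items():
            na, nb = (ga, x), (gb, y)
            if na in index and nb in index:
                ra, rb = find(index[na]), find(index[nb])
                if ra != rb:
                    parent[ra] = rb
                strength[na] += s
                strength[nb] += s

    components: dict[int, list[tuple[str, str]]] = {}
    for node, k in index.items():
        components.setdefault(find(k), []).append(node)

    mopped: list[list[tuple[str, str]]] = []
    n_split = 0
    for root in sorted(components, key=lambda r: sorted(components[r])[0]):
        comp = sorted(components[root], key=lambda n: (-strength[n], n))
        main: dict[str, tuple[str, str]] = {}
        extras: list[tuple[str, str]] = []
        for node in comp:
            if node[0] in main:
                extras.append(node)  # same-genome collision: weaker gene splits off
                n_split += 1
            else:
                main[node[0]] = node
        if len(main) > 0:
            mopped.append(sorted(main.values()))
        mopped.extend([e] for e in sorted(extras))
    if n_split:
        logger.info("build_table: %d gene(s) split off same-genome collisions", n_split)

    fam_idx = 0
    for comp in sorted(mopped, key=lambda c: c[0]):
        fam_idx += 1
        families.append(Family(f"FAM{fam_idx:05d}", dict(comp)))

    table = OrthologTable(genomes=names, families=families, reference=reference)
    table.validate(genomes)
    return table


def table_from_truth(truth) -> OrthologTable:
    """Build an OrthologTable directly from a simulator TruthTable.

    Bypasses alignment entirely; valid only for simulated input where the
    family design is known by construction.
    """
    families = [
        Family(fam.family_id, {g: gid for g, gid in fam.members})
        for fam in truth.families
    ]
    table = OrthologTable(genomes=list(truth.genomes), families=families)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# I/O


def write_table(table: OrthologTable, path: str | Path) -> None:
    """Lossless TSV: family_id, occupancy, then one gene-id column per genome."""
    rows = []
    for fam in table.families:
        row: dict[str, object] = {"family_id": fam.family_id, "occupancy": fam.occupancy}
        for g in table.genomes:
            row[g] = fam.members.get(g, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=["family_id", "occupancy", *table.genomes])
    with open(path, "w") as fh:
        if table.reference:
            fh.write(f"#reference\t{table.reference}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> OrthologTable:
    reference = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#reference\t"):
            reference = first.rstrip("\n").split("\t", 1)[1]
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["family_id", "occupancy"]:
        raise TableError(f"{path}: expected family_id/occupancy leading columns")
    genome_cols = list(df.columns[2:])
    if not genome_cols:
        raise TableError(f"{path}: no genome columns")
    families = []
    for _, row in df.iterrows():
        members = {g: row[g] for g in genome_cols if row[g] != ""}
        if not members:
            raise TableError(f"{path}: family {row['family_id']!r} has no members")
        if int(row["occupancy"]) != len(members):
            raise TableError(
                f"{path}: family {row['family_id']!r} occupancy column disagrees "
                "with member count"
            )
        families.append(Family(row["family_id"], members))
    table = OrthologTable(genomes=genome_cols, families=families, reference=reference)
    table.validate()
    return table


def write_presence_matrix(table: OrthologTable, path: str | Path) -> None:
    """Binary 0/1 families × genomes TSV for external tools."""
    mat = table.presence_matrix().astype(int)
    df = pd.DataFrame(
        mat, index=[f.family_id for f in table.families], columns=table.genomes
    )
    df.to_csv(path, sep="\t", index_label="family_id")
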