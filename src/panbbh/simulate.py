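"""Seeded synthetic genome sets with programmable pangenome structure.

The generator emulates a genus-level genome collection under a star
phylogeny: every gene family has a random root protein and a
back-translated root CDS; each genome carrying the family receives a copy
with i.i.d. substitutions at configurable amino-acid and nucleotide rates.
Families are drawn in three classes — core (present in every genome),
accessory (present in a configured number of genomes, chosen uniformly at
random), and per-genome singletons — and the design is recorded in a
:class:`TruthTable` so downstream ortholog recovery can be scored exactly.

Divergence parameters are calibrated pairwise: each copy substitutes
i.i.d. per site at rate 1 − sqrt(1 − d), never back to the original
symbol, so any two genomes' copies of a family differ at ≈ d of their
sites and realized pairwise identity is ≈ 100·(1 − d) — which makes
AAI/ANI recovery tests direct.  There are no indels, rearrangements,
length variation or phylogenetic correlation: the point is a controllable
truth, not realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genomes import Genome, GenomeSet, write_genome_fasta
from .pangenome import PartitionCounts

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# standard-table codons per residue (no stops), used for back-translation
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_NT = np.array(list("ACGT"))


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Design of a synthetic genome set.

    Parameters
    ----------
    n_genomes:
        Number of genomes G.
    n_core:
        Families present in every genome.
    accessory_spectrum:
        Tuple of ``(occupancy m, n_families)`` with 2 ≤ m ≤ G−1; each such
        family is placed in m genomes chosen uniformly without replacement.
    n_singletons_per_genome:
        Families unique to one genome; either a single count applied to
        every genome or one count per genome.
    protein_len:
        Protein length in residues (fixed; no length variation).
    aa_divergence, nt_divergence:
        Expected per-site substitution fraction between any two genomes'
        copies of a family (protein and CDS respectively); must lie in
        [0, 0.5).  Each copy is substituted relative to the family root
        at the compensating rate 1 − sqrt(1 − d).
    spacer_len:
        Length of the random intergenic spacer between consecutive CDS.
    n_contigs:
        Number of contigs each genome is split into (1 by default).
    seed:
        RNG seed; a fixed seed makes the emitted FASTA byte-identical.
    """

    n_genomes: int
    n_core: int
    accessory_spectrum: tuple[tuple[int, int], ...] = ()
    n_singletons_per_genome: int | tuple[int, ...] = 0
    protein_len: int = 300
    aa_divergence: float = 0.02
    nt_divergence: float = 0.02
    spacer_len: int = 120
    n_contigs: int = 1
    seed: int = 0
    genome_names: tuple[str, ...] | None = None

    def singletons(self) -> tuple[int, ...]:
        n = self.n_singletons_per_genome
        if isinstance(n, int):
            return (n,) * self.n_genomes
        return tuple(n)

    def names(self) -> tuple[str, ...]:
        if self.genome_names is not None:
            return self.genome_names
        return tuple(f"G{i + 1:02d}" for i in range(self.n_genomes))

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ConfigError("n_genomes must be >= 1")
        if self.n_core < 0 or self.protein_len < 1 or self.spacer_len < 0:
            raise ConfigError("counts must be non-negative and protein_len >= 1")
        for m, nfam in self.accessory_spectrum:
            if nfam < 0:
                raise ConfigError("family counts must be >= 0")
            if not (2 <= m <= self.n_genomes - 1):
                raise ConfigError(
                    f"accessory occupancy {m} outside [2, G-1] for G={self.n_genomes}"
                )
        sing = self.singletons()
        if len(sing) != self.n_genomes or any(s < 0 for s in sing):
            raise ConfigError("n_singletons_per_genome must give one count per genome")
        for d in (self.aa_divergence, self.nt_divergence):
            if not (0 <= d < 0.5):
                raise ConfigError("divergence must lie in [0, 0.5)")
        if self.n_contigs < 1:
            raise ConfigError("n_contigs must be >= 1")
        if len(self.names()) != self.n_genomes:
            raise ConfigError("genome_names length must equal n_genomes")


@dataclass(frozen=True)
class TruthFamily:
    family_id: str
    category: str  # "core" | "accessory" | "singleton"
    members: tuple[tuple[str, str], ...]  # (genome, gene_id)


@dataclass
class TruthTable:
    """Ground-truth family design of a simulated genome set."""

    genomes: list[str]
    families: list[TruthFamily] = field(default_factory=list)

    def counts(self) -> PartitionCounts:
        by = {"core": 0, "accessory": 0, "singleton": 0}
        for fam in self.families:
            by[fam.category] += 1
        return PartitionCounts(
            pan=len(self.families),
            core=by["core"],
            accessory=by["accessory"],
            singleton=by["singleton"],
        )


def expected_counts(config: SimConfig) -> PartitionCounts:
    """Pan/core/accessory/singleton family counts implied by a config.

    Pure arithmetic: pan = n_core + Σ accessory families + Σ singletons.
    """
    config.validate()
    accessory = sum(n for _, n in config.accessory_spectrum)
    singleton = sum(config.singletons())
    return PartitionCounts(
        pan=config.n_core + accessory + singleton,
        core=config.n_core,
        accessory=accessory,
        singleton=singleton,
    )


def _mutate(seq: np.ndarray, rate: float, alphabet: np.ndarray, rng) -> np.ndarray:
    """Substitute each site with probability ``rate``, never to itself."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hit) == 0:
        return out
    # pick among the (k-1) other symbols by offsetting the current index
    idx = np.searchsorted(alphabet, out[hit])
    offs = rng.integers(1, len(alphabet), size=len(hit))
    out[hit] = alphabet[(idx + offs) % len(alphabet)]
    return out


def simulate_genome_set(config: SimConfig) -> tuple[GenomeSet, TruthTable]:
    """Generate a genome set and its ground-truth family table.

    Deterministic for a fixed config (including seed): the same call twice
    yields byte-identical sequences.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.names()
    G = config.n_genomes

    # family roster: (category, member genome indices), in deterministic order
    roster: list[tuple[str, tuple[int, ...]]] = []
    roster += [("core", tuple(range(G)))] * config.n_core
    for m, nfam in config.accessory_spectrum:
        for _ in range(nfam):
            members = tuple(sorted(rng.choice(G, size=m, replace=False).tolist()))
            roster.append(("accessory", members))
    for gi, nsing in enumerate(config.singletons()):
        roster += [("singleton", (gi,))] * nsing

    per_genome: list[list[tuple[str, str, str]]] = [[] for _ in range(G)]  # (gid, aa, nt)
    truth = TruthTable(genomes=list(names))
    counters = {"core": 0, "accessory": 0, "singleton": 0}
    prefix = {"core": "C", "accessory": "A", "singleton": "S"}

    for category, members in roster:
        counters[category] += 1
        fam_id = f"{prefix[category]}{counters[category]:05d}"
        root_aa = rng.choice(_AA, size=config.protein_len)
        root_nt = np.array(
            [
                c
                for res in root_aa
                for c in _CODONS[res][rng.integers(len(_CODONS[res]))]
            ]
        )
        fam_members = []
        # per-copy root divergence that realizes the configured pairwise rate
        aa_rate = 1.0 - math.sqrt(1.0 - config.aa_divergence)
        nt_rate = 1.0 - math.sqrt(1.0 - config.nt_divergence)
        for gi in members:
            aa = _mutate(root_aa, aa_rate, _AA, rng)
            nt = _mutate(root_nt, nt_rate, _NT, rng)
            gid = f"{names[gi]}_g{len(per_genome[gi]) + 1:05d}"
            per_genome[gi].append((gid, "".join(aa), "".join(nt)))
            fam_members.append((names[gi], gid))
        truth.families.append(TruthFamily(fam_id, category, tuple(fam_members)))

    genomes: GenomeSet = {}
    for gi, name in enumerate(names):
        genes = per_genome[gi]
        chunks = np.array_split(np.arange(len(genes)), config.n_contigs)
        contigs: list[tuple[str, str]] = []
        gene_to_contig: dict[str, str] = {}
        for ci, chunk in enumerate(chunks):
            cid = f"{name}_c{ci + 1:02d}"
            parts: list[str] = []
            for k in chunk:
                gid, _, nt = genes[k]
                parts.append("".join(rng.choice(_NT, size=config.spacer_len)))
                parts.append(nt)
                gene_to_contig[gid] = cid
            parts.append("".join(rng.choice(_NT, size=config.spacer_len)))
            contigs.append((cid, "".join(parts)))
        genomes[name] = Genome(
            name=name,
            contigs=contigs,
            proteins=[(gid, aa) for gid, aa, _ in genes],
            gene_to_contig=gene_to_contig,
        )
    return genomes, truth


# ---------------------------------------------------------------------------
# presets

#: Eight genomes with the published genus-scale partition design
#: (1458 core, 909 accessory, 837 singleton families — pan 3204), at short
#: protein length so genus-scale matrices stay cheap to build.  909 accessory
#: families are spread over occupancies 2..7 and 837 singletons over the
#: eight genomes as evenly as integer counts allow.
_PRESETS: dict[str, SimConfig] = {
    "guyparkeria-like": SimConfig(
        n_genomes=8,
        n_core=1458,
        accessory_spectrum=((2, 152), (3, 152), (4, 152), (5, 151), (6, 151), (7, 151)),
        n_singletons_per_genome=(105, 105, 105, 105, 105, 104, 104, 104),
        protein_len=30,
        aa_divergence=0.02,
        nt_divergence=0.02,
        spacer_len=60,
        seed=0,
    ),
}


def preset(name: str, **overrides) -> SimConfig:
    """Return a named preset config, optionally with fields overridden."""
    if name not in _PRESETS:
        raise ConfigError(f"unknown preset {name!r}; have {sorted(_PRESETS)}")
    cfg = _PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg


def preset_names() -> list[str]:
    return sorted(_PRESETS)


# ---------------------------------------------------------------------------
# serialization

def write_genome_set(genomes: GenomeSet, outdir: str | Path) -> None:
    """Emit per-genome nucleotide and protein FASTA files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, genome in genomes.items():
        write_genome_fasta(genome, outdir / f"{name}.fna", outdir / f"{name}.faa")


def write_truth(truth: TruthTable, path: str | Path) -> None:
    """TSV with columns family_id, class, genome, gene_id (one row per member)."""
    with open(path, "w") as fh:
        fh.write("family_id\tclass\tgenome\tgene_id\n")
        for fam in truth.families:
            for genome, gid in fam.members:
                fh.write(f"{fam.family_id}\t{fam.category}\t{genome}\t{gid}\n")


def read_truth(path: str | Path) -> TruthTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    genomes = sorted(df["genome"].unique())
    families = []
    for fam_id, grp in df.groupby("family_id", sort=True):
        families.append(
            TruthFamily(
                family_id=str(fam_id),
                category=str(grp["class"].iloc[0]),
                members=tuple(zip(grp["genome"], grp["gene_id"])),
            )
        )
    return TruthTable(genomes=genomes, families=families)


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from YAML or JSON (keys = dataclass fields)."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if "accessory_spectrum" in data:
        data["accessory_spectrum"] = tuple(
            (int(m), int(n)) for m, n in data["accessory_spectrum"]
        )
    if isinstance(data.get("n_singletons_per_genome"), list):
        data["n_singletons_per_genome"] = tuple(data["n_singletons_per_genome"])
    if isinstance(data.get("genome_names"), list):
        data["genome_names"] = tuple(data["genome_names"])
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg
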