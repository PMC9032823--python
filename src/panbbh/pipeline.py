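"""End-to-end orchestration: filter → summaries → orthologs → partition →
development → fits → identity, with a JSON run manifest.

The manifest records the package version, the seed, a hash of the
configuration, and per-stage counts, so a rerun with the same config and
seed reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import (
    DEFAULT_FRAG_LEN,
    DEFAULT_MIN_BITSCORE,
    DEFAULT_MIN_COV,
    DEFAULT_MIN_ID,
)
from .genomes import (
    DEFAULT_MIN_SCAFFOLD_LEN,
    GenomeSet,
    filter_scaffolds,
    read_genome,
    summarize_genome,
    write_summary_table,
)
from .identity import aai_matrix, ani_matrix, classification_report
from .orthology import build_table, table_from_truth, write_table
from .pangenome import (
    DEFAULT_MAX_SAMPLES_PER_N,
    classify_openness,
    development,
    fit_decay,
    fit_heaps,
    fits_to_dict,
    partition,
    write_curve,
    write_fits,
    write_medians,
)
from .simulate import preset, simulate_genome_set, write_truth

logger = logging.getLogger("panbbh")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Input is either ``genome_files`` (name → (nt FASTA, aa FASTA)) or a
    simulator ``preset`` name.  ``ortholog_mode`` is "bbh" (bidirectional
    best hits; the default) or "truth" (take families from the simulator's
    design — only valid with simulated input, used to exercise genus-scale
    tables cheaply).
    """

    outdir: str
    reference: str | None = None
    genome_files: tuple[tuple[str, str, str], ...] | None = None  # (name, nt, aa)
    sim_preset: str | None = None
    min_scaffold_len: int = DEFAULT_MIN_SCAFFOLD_LEN
    min_bitscore: float = DEFAULT_MIN_BITSCORE
    frag_len: int = DEFAULT_FRAG_LEN
    ani_min_id: float = DEFAULT_MIN_ID
    ani_min_cov: float = DEFAULT_MIN_COV
    max_samples_per_N: int = DEFAULT_MAX_SAMPLES_PER_N
    seed: int = 0
    ortholog_mode: str = "bbh"
    run_identity: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from YAML/JSON.  Precedence: config file over explicit
        flags over defaults (file keys win over ``overrides``)."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "genome_files" in data and data["genome_files"] is not None:
            data["genome_files"] = tuple(tuple(x) for x in data["genome_files"])
        merged = {**overrides, **data}
        return cls(**merged)


def _load_genomes(config: RunConfig) -> tuple[GenomeSet, object | None]:
    if (config.genome_files is None) == (config.sim_preset is None):
        raise PipelineError("config: give exactly one of genome_files or sim_preset")
    if config.sim_preset is not None:
        cfg = preset(config.sim_preset, seed=config.seed)
        genomes, truth = simulate_genome_set(cfg)
        return genomes, truth
    genomes: GenomeSet = {}
    for name, nt, aa in config.genome_files:
        genomes[name] = read_genome(nt, aa, name=name)
    return genomes, None


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                counts = fn()
            except Exception as exc:
                _write_manifest(manifest, outdir)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = counts
            logger.info("stage %s: %s (%.2fs)", name, counts, time.time() - t0)

        return deco

    state: dict = {}

    @stage("load")
    def _load():
        genomes, truth = _load_genomes(config)
        state["genomes"], state["truth"] = genomes, truth
        return {"n_genomes": len(genomes)}

    @stage("filter")
    def _filter():
        genomes = {
            name: filter_scaffolds(g, config.min_scaffold_len)
            for name, g in state["genomes"].items()
        }
        state["genomes"] = genomes
        return {"n_contigs": sum(len(g.contigs) for g in genomes.values())}

    @stage("summaries")
    def _summaries():
        summaries = {n: summarize_genome(g) for n, g in state["genomes"].items()}
        write_summary_table(summaries, outdir / "summaries.tsv")
        return {"n_genomes": len(summaries)}

    @stage("orthologs")
    def _orthologs():
        if config.ortholog_mode == "truth":
            if state["truth"] is None:
                raise ValueError("ortholog_mode='truth' requires simulated input")
            table = table_from_truth(state["truth"])
            write_truth(state["truth"], outdir / "truth.tsv")
        elif config.ortholog_mode == "bbh":
            reference = config.reference
            if reference is None or reference not in state["genomes"]:
                raise KeyError(f"reference genome {reference!r} not in set")
            table = build_table(state["genomes"], reference, config.min_bitscore)
        else:
            raise ValueError(f"unknown ortholog_mode {config.ortholog_mode!r}")
        state["table"] = table
        write_table(table, outdir / "orthologs.tsv")
        return {"n_families": len(table.families)}

    @stage("partition")
    def _partition():
        counts = partition(state["table"])
        state["partition"] = counts
        (outdir / "partition.json").write_text(
            json.dumps(dataclasses.asdict(counts), indent=2) + "\n"
        )
        return dataclasses.asdict(counts)

    @stage("development")
    def _development():
        curve = development(state["table"], config.max_samples_per_N, config.seed)
        state["curve"] = curve
        write_curve(curve, outdir / "curve.tsv")
        write_medians(curve, outdir / "medians.tsv")
        return {"n_samples": sum(len(v) for v in curve.samples_per_N.values())}

    @stage("fits")
    def _fits():
        from .pangenome import FitError

        heaps = decay = None
        counts: dict = {}
        try:
            heaps = fit_heaps(state["curve"])
            counts.update(
                gamma=round(heaps.gamma, 6),
                alpha=round(heaps.alpha, 6),
                openness=classify_openness(heaps),
            )
        except FitError as exc:  # e.g. too few genomes for this law
            logger.warning("Heaps fit skipped: %s", exc)
            counts["heaps_skipped"] = str(exc)
        try:
            decay = fit_decay(state["curve"])
            counts.update(tau=round(decay.tau, 6), tg_theta=round(decay.tg_theta, 6))
        except FitError as exc:
            logger.warning("decay fit skipped: %s", exc)
            counts["decay_skipped"] = str(exc)
        write_fits(heaps, decay, outdir / "fits.json")
        return counts

    if config.run_identity:

        @stage("identity")
        def _identity():
            genomes = state["genomes"]
            pairs_by_pair = None
            if config.ortholog_mode == "truth":
                # reuse the table's family pairing instead of recomputing BBH
                pairs_by_pair = {}
                table = state["table"]
                for fam in table.families:
                    items = sorted(fam.members.items())
                    for (ga, xa), (gb, xb) in (
                        (p, q) for i, p in enumerate(items) for q in items[i + 1 :]
                    ):
                        pairs_by_pair.setdefault((ga, gb), []).append((xa, xb))
            aai = aai_matrix(genomes, config.min_bitscore, pairs_by_pair)
            ani = ani_matrix(
                genomes, config.frag_len, config.ani_min_id, config.ani_min_cov
            )
            aai.write_tsv(outdir / "aai.tsv")
            ani.write_tsv(outdir / "ani.tsv")
            classification_report(aai, ani).to_csv(
                outdir / "classification.tsv", sep="\t", index=False
            )
            return {"n_genomes": len(aai.genomes)}

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
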