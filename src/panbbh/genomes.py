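"""Genome containers, FASTA/GFF3 I/O, and assembly summary statistics.

A :class:`Genome` bundles the two views of a bacterial assembly the
pipeline needs: nucleotide contigs (for ANI and scaffold filtering) and
predicted protein sequences (for orthology and AAI).  An optional
gene→contig map, read from GFF3, lets the scaffold filter drop the
proteins encoded on discarded contigs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("panbbh")

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Minimum scaffold length retained by default, in nucleotides.  Scaffolds
#: strictly shorter than this are discarded; the bound is inclusive.
DEFAULT_MIN_SCAFFOLD_LEN = 1500


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a Genome invariant (e.g. duplicate ids)."""


class UndefinedGCError(ValueError):
    """GC content is undefined because no unambiguous bases are present."""


@dataclass
class Genome:
    """One assembly: named contigs plus predicted protein sequences.

    Contig and gene ids must each be unique within the genome.  Nucleotide
    sequences are over {A,C,G,T,N}; proteins over the 20 standard residues
    plus X.  Sequences are stored upper-case.
    """

    name: str
    contigs: list[tuple[str, str]] = field(default_factory=list)
    proteins: list[tuple[str, str]] = field(default_factory=list)
    gene_to_contig: dict[str, str] | None = None

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]

    @property
    def gene_ids(self) -> list[str]:
        return [gid for gid, _ in self.proteins]

    @property
    def n_bases(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def validate(self) -> None:
        for ids, what in ((self.contig_ids, "contig"), (self.gene_ids, "gene")):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            if dup:
                raise ValidationError(
                    f"{self.name}: duplicate {what} id(s): {', '.join(sorted(dup))}"
                )
        for cid, seq in self.contigs:
            bad = set(seq) - NT_ALPHABET
            if bad:
                raise ValidationError(
                    f"{self.name}/{cid}: illegal nucleotide(s) {sorted(bad)}"
                )
        for gid, seq in self.proteins:
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise ValidationError(
                    f"{self.name}/{gid}: illegal residue(s) {sorted(bad)}"
                )


#: A named collection of genomes, keyed (and ordered) by genome name.
GenomeSet = dict[str, Genome]


@dataclass(frozen=True)
class GenomeSummary:
    """Per-assembly summary: scaffold count, size, GC%, and CDS count."""

    n_scaffolds: int
    n_bases: int
    gc_percent: float
    n_cds: int


def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython is permissive
        raise FormatError(f"{path}: not parseable as FASTA ({exc})") from exc
    for rec in parsed:
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicated record id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return records


def _read_gff3_cds_map(path: str | Path) -> dict[str, str]:
    """Map CDS ``ID`` attributes to their seqid (contig) from a GFF3 file.

    Only the seqid, type and ID columns are consulted.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, *_rest, attrs = cols
            if ftype != "CDS":
                continue
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    mapping[item[3:].strip()] = seqid
                    break
    return mapping


def read_genome(
    fasta_nt_path: str | Path,
    fasta_aa_path: str | Path,
    gff3_path: str | Path | None = None,
    name: str | None = None,
) -> Genome:
    """Load a genome from a nucleotide FASTA and a protein FASTA.

    FASTA ids are the first whitespace-delimited token of the header.  An
    optional GFF3 file supplies the gene→contig map (CDS features, matching
    protein ids via the ``ID`` attribute); everything else in the GFF3 is
    ignored.  Duplicate ids raise :class:`ValidationError`.
    """
    if name is None:
        name = Path(fasta_nt_path).stem
    contigs = _read_fasta(fasta_nt_path)
    proteins = [(gid, seq.rstrip("*")) for gid, seq in _read_fasta(fasta_aa_path)]
    if not proteins:
        logger.warning("%s: protein FASTA %s holds no records", name, fasta_aa_path)
    gene_to_contig = None
    if gff3_path is not None:
        gene_to_contig = _read_gff3_cds_map(gff3_path)
    genome = Genome(name, contigs, proteins, gene_to_contig)
    genome.validate()
    return genome


def write_genome_fasta(
    genome: Genome, nt_path: str | Path, aa_path: str | Path
) -> None:
    """Write the genome back out as a nucleotide and a protein FASTA."""
    for path, records in ((nt_path, genome.contigs), (aa_path, genome.proteins)):
        SeqIO.write(
            (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
            str(path),
            "fasta",
        )


def filter_scaffolds(genome: Genome, min_len: int = DEFAULT_MIN_SCAFFOLD_LEN) -> Genome:
    """Discard scaffolds shorter than ``min_len`` nucleotides.

    The bound is inclusive: a scaffold of exactly ``min_len`` is kept.  When
    the genome carries a gene→contig map, proteins encoded on a discarded
    contig are removed too; without the map proteins are kept unchanged and
    a warning is logged.  Idempotent.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [(cid, seq) for cid, seq in genome.contigs if len(seq) >= min_len]
    n_dropped = len(genome.contigs) - len(kept)
    proteins = list(genome.proteins)
    gene_to_contig = genome.gene_to_contig
    if n_dropped:
        if gene_to_contig is not None:
            kept_ids = {cid for cid, _ in kept}
            proteins = [
                (gid, seq)
                for gid, seq in proteins
                if gene_to_contig.get(gid) in kept_ids
            ]
            gene_to_contig = {
                gid: cid for gid, cid in gene_to_contig.items() if cid in kept_ids
            }
        else:
            logger.warning(
                "%s: dropped %d scaffold(s) but no gene→contig map; proteins kept",
                genome.name,
                n_dropped,
            )
    if not kept:
        logger.warning("%s: no scaffolds of length >= %d remain", genome.name, min_len)
    return replace(genome, contigs=kept, proteins=proteins, gene_to_contig=gene_to_contig)


def summarize_genome(genome: Genome) -> GenomeSummary:
    """Compute scaffold count, total bases, GC%, and CDS count.

    GC% = 100·(G+C)/(A+C+G+T); N bases are excluded from both numerator and
    denominator but do count toward ``n_bases``.
    """
    counts: Counter[str] = Counter()
    for _, seq in genome.contigs:
        counts.update(seq)
    acgt = sum(counts[b] for b in "ACGT")
    if acgt == 0:
        raise UndefinedGCError(f"{genome.name}: no unambiguous bases; GC undefined")
    gc = 100.0 * (counts["G"] + counts["C"]) / acgt
    return GenomeSummary(
        n_scaffolds=len(genome.contigs),
        n_bases=genome.n_bases,
        gc_percent=gc,
        n_cds=len(genome.proteins),
    )


def summarize_set(
    summaries: Sequence[GenomeSummary] | Sequence[float],
) -> tuple[float, float | None]:
    """Mean and sample standard deviation (n−1) of GC% across genomes.

    Accepts either GenomeSummary objects or raw GC percentages.  With a
    single genome the SD is undefined and returned as ``None``.  Values are
    unrounded; round at reporting time (the field convention is 1 decimal).
    """
    if len(summaries) == 0:
        raise ValueError("summarize_set requires at least one summary")
    gc = np.array(
        [s.gc_percent if isinstance(s, GenomeSummary) else float(s) for s in summaries]
    )
    mean = float(np.mean(gc))
    sd = float(np.std(gc, ddof=1)) if len(gc) >= 2 else None
    return mean, sd


def write_summary_table(
    summaries: Mapping[str, GenomeSummary], path: str | Path
) -> None:
    """Write a TSV with columns genome, n_scaffolds, n_bases, gc_percent, n_cds."""
    df = pd.DataFrame(
        [
            {
                "genome": name,
                "n_scaffolds": s.n_scaffolds,
                "n_bases": s.n_bases,
                "gc_percent": round(s.gc_percent, 4),
                "n_cds": s.n_cds,
            }
            for name, s in summaries.items()
        ]
    )
    df.to_csv(path, sep="\t", index=False)
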