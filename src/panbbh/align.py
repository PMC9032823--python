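"""Pairwise comparison primitives: local protein alignment with bit
scores (for BBH orthology and AAI) and fragment-based nucleotide identity
(for ANI).

Protein alignment is exact Smith–Waterman under BLOSUM62 with affine gaps
(open 11, extend 1), the de facto defaults behind protein BLAST, executed
by Biopython's C aligner.  Raw scores are converted to bits with the
standard gapped Karlin–Altschul constants for that scoring system
(λ = 0.267, K = 0.041):  S' = (λ·S − ln K) / ln 2.  Exact alignment rather
than a seeded heuristic keeps best-hit results deterministic and testable
against a brute-force dynamic-programming oracle.

ANI follows the classic fragment recipe: query contigs are cut into
1020-nt windows, each window is placed at its best location in the subject
(edit-distance infix search), then re-aligned locally with match +1,
mismatch −1, gap open −5, extend −2; fragments with ≥30% identity over
≥70% of their length are retained and their mean identity is the one-way
ANI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .genomes import AA_ALPHABET, Genome

logger = logging.getLogger("panbbh")

# gapped Karlin–Altschul parameters for BLOSUM62 with (11, 1) affine gaps
KA_LAMBDA = 0.267
KA_K = 0.041

#: Default bit-score threshold for retaining a best hit (inclusive).
DEFAULT_MIN_BITSCORE = 60.0

# fragment-ANI defaults (classic recipe)
DEFAULT_FRAG_LEN = 1020
DEFAULT_MIN_ID = 30.0
DEFAULT_MIN_COV = 0.70
#: Trailing contig remainders at least this long are kept as short fragments.
MIN_TAIL_FRAGMENT = 200
# margin (nt) added around the edlib-located window before local re-alignment
_WINDOW_MARGIN = 75


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject sequence.

    ``percent_identity`` is computed over aligned columns (gap columns
    included, BLAST-style); ``query_cov`` is the aligned fraction of the
    query.  ``significant`` is False when no positive-scoring cell exists.
    """

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    percent_identity: float
    aln_len: int
    query_cov: float

    @property
    def significant(self) -> bool:
        return self.raw_score > 0


def bit_score(raw_score: float) -> float:
    """Convert a raw BLOSUM62(11,1) score to bits (Karlin–Altschul)."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2)


@lru_cache(maxsize=None)
def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST convention: a gap of length g costs 11 + g, i.e. first gap
    # position scores -12 and each extension -1
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


@lru_cache(maxsize=None)
def _fragment_aligner(
    match: int = 1, mismatch: int = -1, gap_open: int = -5, gap_extend: int = -2
) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _check_protein(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{label}: illegal residue(s) {sorted(bad)}")


def _hit_from_alignment(
    aligner: PairwiseAligner, query: str, subject: str, query_id: str, subject_id: str
) -> AlignmentHit:
    score = float(aligner.score(query, subject))
    if score <= 0:
        return AlignmentHit(query_id, subject_id, score, bit_score(score), 0.0, 0, 0.0)
    aln = aligner.align(query, subject)[0]
    counts = aln.counts()
    aln_len = int(aln.length)
    identity = 100.0 * counts.identities / aln_len if aln_len else 0.0
    blocks = aln.aligned[0]  # blocks on the first (query) sequence
    cov = (blocks[-1][1] - blocks[0][0]) / len(query)
    return AlignmentHit(
        query_id, subject_id, score, bit_score(score), identity, aln_len, float(cov)
    )


def align_protein(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Smith–Waterman local alignment of two protein sequences.

    BLOSUM62, affine gaps (open 11, extend 1); identity over aligned
    columns; bit score per the module constants.  Raises ``ValueError`` on
    empty sequences or residues outside the 20 standard amino acids + X.
    """
    _check_protein(query, query_id)
    _check_protein(subject, subject_id)
    return _hit_from_alignment(_protein_aligner(), query, subject, query_id, subject_id)


def protein_score_matrix(queries: Genome, subjects: Genome) -> np.ndarray:
    """Raw SW score of every query protein against every subject protein.

    Rows follow ``queries.proteins`` order, columns ``subjects.proteins``.
    Because SW with a symmetric matrix is symmetric, the transpose serves
    the reverse direction.
    """
    aligner = _protein_aligner()
    scores = np.zeros((len(queries.proteins), len(subjects.proteins)))
    for i, (_, qseq) in enumerate(queries.proteins):
        for j, (_, sseq) in enumerate(subjects.proteins):
            scores[i, j] = aligner.score(qseq, sseq)
    return scores


def best_hits(
    queries: Genome,
    subjects: Genome,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    score_matrix: np.ndarray | None = None,
) -> dict[str, AlignmentHit]:
    """Best subject hit per query, retained iff bit score ≥ ``min_bitscore``.

    Ties on bit score are broken toward the lexicographically smallest
    subject id (logged).  A precomputed ``score_matrix`` (rows = queries)
    avoids re-aligning when both directions are needed.
    """
    if not queries.proteins or not subjects.proteins:
        raise ValueError("both genomes must have at least one protein")
    if score_matrix is None:
        score_matrix = protein_score_matrix(queries, subjects)
    sids = subjects.gene_ids
    # resolve argmax ties toward the smallest subject id
    order = np.array(sorted(range(len(sids)), key=lambda j: sids[j]))
    hits: dict[str, AlignmentHit] = {}
    n_ties = 0
    for i, (qid, qseq) in enumerate(queries.proteins):
        row = score_matrix[i, order]
        best = row.max()
        if best <= 0:
            continue
        winners = np.flatnonzero(row == best)
        if len(winners) > 1:
            n_ties += 1
        j = int(order[winners[0]])
        if bit_score(float(best)) < min_bitscore:
            continue
        hits[qid] = _hit_from_alignment(
            _protein_aligner(), qseq, subjects.proteins[j][1], qid, sids[j]
        )
    if n_ties:
        logger.info(
            "best_hits(%s→%s): %d tie(s) broken toward smaller subject id",
            queries.name,
            subjects.name,
            n_ties,
        )
    return hits


# ---------------------------------------------------------------------------
# fragment-based nucleotide identity


def _fragments(genome: Genome, frag_len: int) -> list[str]:
    frags: list[str] = []
    for _, seq in genome.contigs:
        n_full, tail = divmod(len(seq), frag_len)
        for k in range(n_full):
            frags.append(seq[k * frag_len : (k + 1) * frag_len])
        if tail >= MIN_TAIL_FRAGMENT or (n_full == 0 and tail > 0):
            frags.append(seq[n_full * frag_len :])
    return frags


def _best_window(fragment: str, contigs: Sequence[tuple[str, str]]) -> str | None:
    """Locate the fragment's best placement across subject contigs (edlib
    infix search) and return the surrounding subject window."""
    best: tuple[int, str, tuple[int, int]] | None = None
    for _, seq in contigs:
        if not seq:
            continue
        res = edlib.align(fragment, seq, mode="HW", task="locations")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        loc = res["locations"][0]
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], seq, (loc[0] or 0, loc[1]))
    if best is None:
        return None
    _, seq, (start, end) = best
    return seq[max(0, start - _WINDOW_MARGIN) : end + 1 + _WINDOW_MARGIN]


def ani_fragments(
    query: Genome,
    subject: Genome,
    frag_len: int = DEFAULT_FRAG_LEN,
    min_id: float = DEFAULT_MIN_ID,
    min_cov: float = DEFAULT_MIN_COV,
) -> tuple[float | None, int]:
    """One-way ANI: mean identity of retained query fragments in subject.

    Returns ``(ani, n_retained)``; ani is ``None`` when no fragment passes
    the identity/coverage filters (e.g. unrelated genomes, where local
    alignments cover far less than ``min_cov`` of a fragment).
    """
    if not query.contigs or not subject.contigs:
        raise ValueError("both genomes need nucleotide contigs for ANI")
    aligner = _fragment_aligner()
    identities: list[float] = []
    for frag in _fragments(query, frag_len):
        window = _best_window(frag, subject.contigs)
        if window is None:
            continue
        score = float(aligner.score(frag, window))
        if score <= 0:
            continue
        aln = aligner.align(frag, window)[0]
        counts = aln.counts()
        aln_len = int(aln.length)
        if aln_len == 0:
            continue
        identity = 100.0 * counts.identities / aln_len
        blocks = aln.aligned[0]
        cov = (blocks[-1][1] - blocks[0][0]) / len(frag)
        if identity >= min_id and cov >= min_cov:
            identities.append(identity)
    if not identities:
        return None, 0
    return float(np.mean(identities)), len(identities)


# ---------------------------------------------------------------------------
# interoperability


def hits_to_frame(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    """Tabulate hits with BLAST outfmt-6-style column names."""
    return pd.DataFrame(
        [
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": round(h.percent_identity, 3),
                "length": h.aln_len,
                "bitscore": round(h.bit_score, 1),
                "raw_score": h.raw_score,
                "qcovs": round(h.query_cov, 3),
            }
            for h in hits
        ]
    )
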