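"""ORF-by-ORF cluster comparison: identity/similarity and synteny.

Homologous gene clusters are compared by all-vs-all global protein
alignment (Needleman-Wunsch, BLOSUM62, affine gaps 10/1, terminal gaps
free), reciprocal-best-hit ortholog pairing, and a synteny score from the
longest common subsequence of ortholog order.  Identity is reported over
aligned (non-terminal-gap) columns; similarity additionally counts
positive-scoring BLOSUM62 substitutions, the convention behind
"positives" percentages in homology tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SeqRecordLite

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aa_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


@dataclass(frozen=True)
class OrthologPair:
    query_orf: str
    subject_orf: str
    identity: float
    similarity: float
    reciprocal: bool
    tie: bool = False


@dataclass
class SyntenyReport:
    pairs: list[OrthologPair]
    order_conserved_fraction: float
    missing_in_subject: list[str] = field(default_factory=list)


def align_global(a: str, b: str) -> tuple[float, float]:
    """(identity %, similarity %) of a global alignment with free end gaps.

    Denominator: all alignment columns between the first and last aligned
    residue pair (internal gaps included, terminal overhangs excluded).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = next(iter(_aa_aligner().align(a, b)))
    blocks_a, blocks_b = aln.aligned
    matches = positives = aligned_cols = 0
    for (as_, ae), (bs, _be) in zip(blocks_a, blocks_b):
        for i in range(ae - as_):
            ra, rb = a[as_ + i], b[bs + i]
            aligned_cols += 1
            if ra == rb:
                matches += 1
                positives += 1
            elif _BLOSUM62[ra.upper(), rb.upper()] > 0:
                positives += 1
    # internal gap columns between consecutive blocks
    for k in range(1, len(blocks_a)):
        gap_a = blocks_a[k][0] - blocks_a[k - 1][1]
        gap_b = blocks_b[k][0] - blocks_b[k - 1][1]
        aligned_cols += gap_a + gap_b
    if aligned_cols == 0:
        return 0.0, 0.0
    return 100.0 * matches / aligned_cols, 100.0 * positives / aligned_cols


def reciprocal_best_hits(
    A: Sequence[SeqRecordLite], B: Sequence[SeqRecordLite]
) -> list[OrthologPair]:
    """Reciprocal best hits between two clusters by global alignment score.

    Score ties are broken toward the lower subject index and flagged on the
    pair.  Identity/similarity are computed for kept pairs only.
    """
    if not A or not B:
        raise ValueError("both clusters must be non-empty")
    aligner = _aa_aligner()
    scores = np.zeros((len(A), len(B)))
    for i, ra in enumerate(A):
        for j, rb in enumerate(B):
            scores[i, j] = aligner.score(ra.seq, rb.seq)
    best_b_for_a = scores.argmax(axis=1)  # argmax returns the lowest tied index
    best_a_for_b = scores.argmax(axis=0)
    pairs: list[OrthologPair] = []
    for i, j in enumerate(best_b_for_a):
        if best_a_for_b[j] != i:
            continue
        tie = bool((scores[i] == scores[i, j]).sum() > 1
                   or (scores[:, j] == scores[i, j]).sum() > 1)
        ident, sim = align_global(A[i].seq, B[j].seq)
        pairs.append(OrthologPair(
            query_orf=A[i].id, subject_orf=B[j].id,
            identity=ident, similarity=sim, reciprocal=True, tie=tie,
        ))
    return pairs


def _lcs_len(seq: Sequence[int]) -> int:
    """Length of the longest increasing subsequence (order conservation)."""
    tails: list[int] = []
    for x in seq:
        lo, hi = 0, len(tails)
        while lo < hi:
            mid = (lo + hi) // 2
            if tails[mid] < x:
                lo = mid + 1
            else:
                hi = mid
        if lo == len(tails):
            tails.append(x)
        else:
            tails[lo] = x
    return len(tails)


def synteny_report(
    pairs: Sequence[OrthologPair],
    orderA: Sequence[str],
    orderB: Sequence[str],
) -> SyntenyReport:
    """Order conservation between two clusters from their ortholog pairs.

    ``order_conserved_fraction`` is the longest common subsequence of
    subject positions taken in query order, divided by the smaller cluster
    size; ORFs of A without an ortholog are reported missing in B.
    """
    posB = {orf: k for k, orf in enumerate(orderB)}
    by_query = {p.query_orf: p for p in pairs}
    subject_positions = [
        posB[by_query[orf].subject_orf]
        for orf in orderA
        if orf in by_query and by_query[orf].subject_orf in posB
    ]
    denom = min(len(orderA), len(orderB))
    frac = _lcs_len(subject_positions) / denom if denom else 0.0
    missing = [orf for orf in orderA if orf not in by_query]
    return SyntenyReport(
        pairs=list(pairs), order_conserved_fraction=frac, missing_in_subject=missing
    )
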