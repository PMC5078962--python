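"""Fragment-based average nucleotide identity (ANIb) and species assignment.

The query genome is cut into consecutive 1,020 bp fragments (the
fragment-length convention of fragment-based ANI tools); each fragment is
placed on the subject by exact k-mer seeding and aligned as an infix of the
candidate subject window with edlib.  Hits are retained iff identity >= 30%
and alignable fragment coverage >= 70%, and ANIb is the unweighted mean
identity over retained fragments.  Both strands are searched and the best
kept per fragment.  ANIb is asymmetric in query and subject; both
directions are reported by the CLI.

Species assignment follows the genomic ANI criterion: two strains with
ANIb at or above the threshold (default 95%, the conventional 95-96% band
corresponding to 70% DNA-DNA relatedness) are called conspecific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .seqio import SeqRecordLite, SequenceError

DEFAULT_FRAG_LEN = 1020
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Fragment:
    id: str  # "<scaffold>:<offset>"
    seq: str


@dataclass
class AniResult:
    """One-directional ANIb between a query and a subject genome."""

    n_fragments: int
    n_retained: int
    mean_identity: float | None
    aligned_fraction: float
    same_species: bool
    threshold_used: float


def fragment_genome(
    records: Sequence[SeqRecordLite], frag_len: int = DEFAULT_FRAG_LEN
) -> list[Fragment]:
    """Cut scaffolds into consecutive non-overlapping windows.

    The terminal fragment of each scaffold is kept when it is at least half
    the window, dropped otherwise.
    """
    if not records:
        raise SequenceError("cannot fragment an empty genome")
    frags: list[Fragment] = []
    for rec in records:
        if rec.alphabet != "nt":
            raise SequenceError(f"record {rec.id!r} is not nucleotide")
        seq = rec.seq.upper()
        for off in range(0, len(seq), frag_len):
            piece = seq[off : off + frag_len]
            if len(piece) >= frag_len or len(piece) >= frag_len / 2:
                frags.append(Fragment(id=f"{rec.id}:{off}", seq=piece))
    if not frags:
        raise SequenceError("genome shorter than half a fragment; nothing to align")
    return frags


class _KmerIndex:
    """Exact k-mer positions of the subject, for seeding fragment placement."""

    def __init__(self, subject: str, k: int = 13):
        self.k = k
        self.subject = subject
        index: dict[str, list[int]] = {}
        for i in range(len(subject) - k + 1):
            index.setdefault(subject[i : i + k], []).append(i)
        self.index = index

    def best_window(self, frag: str, pad: int = 80, min_votes: int = 3) -> tuple[int, int] | None:
        """Top-voted diagonal among seed hits -> subject window, or None.

        Requiring several independent exact-seed votes on one diagonal
        keeps chance 13-mer matches between unrelated sequences from
        producing spurious placements.
        """
        k = self.k
        votes: dict[int, int] = {}
        for qpos in range(0, len(frag) - k + 1, 7):
            for spos in self.index.get(frag[qpos : qpos + k], ()):
                diag = spos - qpos
                votes[diag] = votes.get(diag, 0) + 1
        if not votes:
            return None
        # bin nearby diagonals so small indels do not split the vote
        binned: dict[int, int] = {}
        for diag, v in votes.items():
            binned[diag // 20] = binned.get(diag // 20, 0) + v
        best_bin = max(binned, key=lambda b: (binned[b], -b))
        if binned[best_bin] < min_votes:
            return None
        diag = best_bin * 20 + 10
        lo = max(0, diag - pad)
        hi = min(len(self.subject), diag + len(frag) + pad)
        return lo, hi


_CHUNK = 60  # columns per local-quality chunk
_CHUNK_MIN_MATCH = 0.70  # a chunk below this match fraction is unalignable


def _identity(frag: str, window: str) -> tuple[float, float] | None:
    """(percent identity, coverage) of the best infix alignment in window.

    The alignment is scanned in 60-column chunks; chunks whose match
    fraction falls below 70% (far outside the ANI regime, typical of a
    fragment overhanging a rearrangement breakpoint or an unrelated
    region) are treated as unalignable.  Identity is computed over the
    alignable chunks; coverage is their fraction of the alignment.
    """
    res = edlib.align(frag, window, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    nice = edlib.getNiceAlignment(res, frag, window)["matched_aligned"]
    if not nice:
        return None
    matches = aligned_cols = 0
    for i in range(0, len(nice), _CHUNK):
        chunk = nice[i : i + _CHUNK]
        m = chunk.count("|")
        if m / len(chunk) >= _CHUNK_MIN_MATCH:
            matches += m
            aligned_cols += len(chunk)
    if aligned_cols == 0:
        return None
    return 100.0 * matches / aligned_cols, aligned_cols / len(nice)


def anib(
    query: Sequence[SeqRecordLite],
    subject: Sequence[SeqRecordLite],
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
    frag_len: int = DEFAULT_FRAG_LEN,
    threshold: float = 95.0,
) -> AniResult:
    """One-directional fragment-based ANI of ``query`` against ``subject``.

    Each fragment is aligned on both strands and the better alignment kept;
    fragments with no seed match, identity below ``min_identity`` or
    aligned coverage below ``min_coverage`` are discarded.  With no
    retained fragment, ``mean_identity`` is None and the species call is
    False.
    """
    frags = fragment_genome(query, frag_len)
    subj_seq = "".join(r.seq.upper() for r in subject)
    if not subj_seq:
        raise SequenceError("empty subject genome")
    index = _KmerIndex(subj_seq)

    identities: list[float] = []
    for frag in frags:
        best: tuple[float, float] | None = None
        for oriented in (frag.seq, revcomp(frag.seq)):
            win = index.best_window(oriented)
            if win is None:
                continue
            got = _identity(oriented, subj_seq[win[0] : win[1]])
            if got is not None and (best is None or got[0] > best[0]):
                best = got
        if best is not None and best[0] >= min_identity and best[1] >= min_coverage:
            identities.append(best[0])

    n_ret = len(identities)
    mean = float(np.mean(identities)) if identities else None
    return AniResult(
        n_fragments=len(frags),
        n_retained=n_ret,
        mean_identity=mean,
        aligned_fraction=n_ret / len(frags),
        same_species=(mean is not None and mean >= threshold),
        threshold_used=threshold,
    )


def classify_species(result: AniResult, threshold: float = 95.0) -> bool:
    """Conspecificity call: mean identity at or above the ANI threshold."""
    if result.mean_identity is None:
        raise ValueError("mean identity undefined (no retained fragments)")
    return result.mean_identity >= threshold
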