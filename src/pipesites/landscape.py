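"""Window co-occurrence landscapes for a query protein pair.

For query proteins A and B, the landscape is an integer matrix H over
window-start index pairs: ``H[i, j]`` counts the oriented database pairs
(X, Y) in which window i of A re-occurs in X and window j of B re-occurs
in Y. Peaks in H mark candidate binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io_formats import InteractionDB, Protein


@dataclass(frozen=True)
class MatchParams:
    """Window-matching configuration.

    ``exact`` mode matches a window iff it occurs verbatim as a substring
    of the partner sequence. ``similarity`` mode matches iff some window of
    the partner scores at least ``score_threshold`` against it under the
    named substitution matrix (summed over the w aligned positions); 'X'
    never matches any position in this mode.
    """

    w: int = 20
    mode: str = "exact"
    substitution_matrix: str = "BLOSUM62"
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("window length must be >= 1")
        if self.mode not in ("exact", "similarity"):
            raise ValueError(f"unknown match mode {self.mode!r}")
        if self.mode == "similarity" and self.score_threshold is None:
            raise ValueError("similarity mode requires score_threshold")


@dataclass(frozen=True)
class Landscape:
    """Co-occurrence counts over window-start pairs of two query proteins.

    ``H`` has shape (lenA - w + 1, lenB - w + 1); row i-1 corresponds to the
    window starting at residue i of A (1-based), column j-1 likewise for B.
    """

    id_a: str
    id_b: str
    w: int
    H: np.ndarray

    @property
    def is_empty(self) -> bool:
        return self.H.size == 0


def windows(p: Protein, w: int) -> list[tuple[int, str]]:
    """All length-w windows of ``p`` as (1-based start, subsequence)."""
    return [(i + 1, p.sequence[i:i + w]) for i in range(p.length - w + 1)]


@lru_cache(maxsize=65536)
def _kmer_set(sequence: str, w: int) -> frozenset[str]:
    return frozenset(sequence[i:i + w] for i in range(len(sequence) - w + 1))


_X_PENALTY = -1.0e9  # 'X' can never contribute to reaching a threshold


@lru_cache(maxsize=8)
def _score_lut(matrix_name: str) -> tuple[str, np.ndarray]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(matrix_name)
    letters = "ACDEFGHIKLMNPQRSTVWYX"
    lut = np.full((len(letters), len(letters)), _X_PENALTY)
    for a_idx, a in enumerate(letters):
        for b_idx, b in enumerate(letters):
            if a == "X" or b == "X":
                continue
            lut[a_idx, b_idx] = float(mat[a, b])
    return letters, lut


def _encode(seq: str, letters: str) -> np.ndarray:
    codes = {c: i for i, c in enumerate(letters)}
    return np.fromiter((codes[c] for c in seq), dtype=np.int64, count=len(seq))


def window_match(win: str, target: Protein, params: MatchParams) -> bool:
    """Does ``win`` re-occur in ``target`` under the matching rule?"""
    if len(win) != params.w:
        raise ValueError(f"window length {len(win)} != w={params.w}")
    if params.mode == "exact":
        return win in _kmer_set(target.sequence, params.w)
    return bool(_similarity_hits(win, target.sequence, params))


def _similarity_hits(win: str, target: str, params: MatchParams) -> bool:
    w = params.w
    if len(target) < w:
        return False
    letters, lut = _score_lut(params.substitution_matrix)
    q = _encode(win, letters)
    t = _encode(target, letters)
    tw = np.lib.stride_tricks.sliding_window_view(t, w)
    scores = lut[q[np.newaxis, :], tw].sum(axis=1)
    return bool((scores >= params.score_threshold).any())


@lru_cache(maxsize=131072)
def _profile(query_seq: str, target_seq: str, params: MatchParams) -> frozenset[int]:
    w = params.w
    n = len(query_seq) - w + 1
    if n <= 0:
        return frozenset()
    if params.mode == "exact":
        kmers = _kmer_set(target_seq, w)
        return frozenset(
            i + 1 for i in range(n) if query_seq[i:i + w] in kmers
        )
    if len(target_seq) < w:
        return frozenset()
    letters, lut = _score_lut(params.substitution_matrix)
    q = _encode(query_seq, letters)
    t = _encode(target_seq, letters)
    qw = np.lib.stride_tricks.sliding_window_view(q, w)
    tw = np.lib.stride_tricks.sliding_window_view(t, w)
    # score[i, j] = sum over positions of lut[q_window_i, t_window_j]
    scores = lut[qw[:, np.newaxis, :], tw[np.newaxis, :, :]].sum(axis=2)
    hits = (scores >= params.score_threshold).any(axis=1)
    return frozenset(int(i) + 1 for i in np.nonzero(hits)[0])


def match_profile(query: Protein, db_protein: Protein, params: MatchParams) -> frozenset[int]:
    """Set of 1-based window starts of ``query`` that re-occur in ``db_protein``.

    Pure and cached per (query sequence, partner sequence, params); cached
    and uncached results are identical.
    """
    return _profile(query.sequence, db_protein.sequence, params)


def compute_landscape(
    a: Protein,
    b: Protein,
    db: InteractionDB,
    params: MatchParams,
    exclude_query_pair: bool = True,
) -> Landscape:
    """Co-occurrence landscape of query pair (a, b) against ``db``.

    Each unordered database pair contributes both orientations (X, Y) and
    (Y, X) — one for self-pairs — so the result does not depend on the
    arbitrary column order of the pair file. One count per oriented pair
    per cell, regardless of how many positions of X a window matches.

    When ``exclude_query_pair`` is true (the default for evaluation runs)
    the unordered pair {a.id, b.id} is removed from the database first,
    preventing a trivial self-hit when the query pair is also a training
    pair.

    Query sequences shorter than w yield a zero-dimension landscape.
    """
    w = params.w
    n_a = max(a.length - w + 1, 0)
    n_b = max(b.length - w + 1, 0)
    H = np.zeros((n_a, n_b), dtype=np.int64)
    if n_a == 0 or n_b == 0:
        return Landscape(a.id, b.id, w, H)
    if exclude_query_pair:
        db = db.without(a.id, b.id)
    for x, y in db.oriented_pairs():
        pa = match_profile(a, x, params)
        if not pa:
            continue
        pb = match_profile(b, y, params)
        if not pb:
            continue
        rows = np.fromiter((i - 1 for i in pa), dtype=np.int64, count=len(pa))
        cols = np.fromiter((j - 1 for j in pb), dtype=np.int64, count=len(pb))
        H[np.ix_(rows, cols)] += 1
    return Landscape(a.id, b.id, w, H)


def dump_landscape(ls: Landscape, path) -> None:
    """Write a landscape as TSV with window-start header row and column."""
    n_a, n_b = ls.H.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([""] + [str(j + 1) for j in range(n_b)]) + "\n")
        for i in range(n_a):
            fh.write("\t".join([str(i + 1)] + [str(v) for v in ls.H[i]]) + "\n")
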