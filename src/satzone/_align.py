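"""Vectorized Needleman-Wunsch machinery for monomer identity.

Scoring is fixed package-wide: match +1, mismatch -1, and -2 per gap
column (linear). Identity is reported as matches / alignment columns of
the optimal-score global alignment, with gap columns counted in the
denominator. Traceback ties are resolved deterministically
(diagonal > up > left) so that independent implementations of the same
convention agree exactly.
"""

from __future__ import annotations

import numpy as np

MATCH = 1
MISMATCH = -1
GAP = -2

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode_seq(seq: str) -> np.ndarray:
    return np.array([_ENCODE[c] for c in seq.upper()], dtype=np.int8)


def revcomp(enc: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[enc[::-1]]


def rotations_dimer(monomer: np.ndarray, repeats: int) -> np.ndarray:
    """All cyclic rotations of ``monomer``, each tiled into ``repeats`` copies.

    Returns an (L, L * repeats) matrix; row r is the dimerized rotation by r.
    """
    L = len(monomer)
    idx = (np.arange(L * repeats)[None, :] + np.arange(L)[:, None]) % L
    return monomer[idx]


def nw_scores_batch(query: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Optimal global-alignment scores of ``query`` against each row of ``targets``.

    Row-wise DP; the within-row horizontal-gap dependency is folded into a
    running maximum (H[i,j] = max(T[j], H[i,j-1] + GAP) equals
    max_{k<=j}(T[k] + GAP*(j-k)), computed with ``maximum.accumulate``).
    """
    n = len(query)
    R, m = targets.shape
    # substitution scores for every (query position, rotation, target position)
    subs = np.where(targets[None, :, :] == query[:, None, None], MATCH, MISMATCH).astype(
        np.int16
    )
    ramp = (-GAP * np.arange(m + 1)).astype(np.int16)  # GAP < 0; ramp ascends
    H = np.tile((GAP * np.arange(m + 1)).astype(np.int16), (R, 1))
    T = np.empty((R, m + 1), dtype=np.int16)
    for i in range(1, n + 1):
        T[:, 0] = GAP * i
        np.maximum(H[:, :-1] + subs[i - 1], H[:, 1:] + GAP, out=T[:, 1:])
        T += ramp
        np.maximum.accumulate(T, axis=1, out=H)
        H -= ramp
    return H[:, -1].astype(np.int64)


def nw_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full (n+1, m+1) global-alignment score matrix for one pair."""
    n, m = len(a), len(b)
    ramp = -GAP * np.arange(m + 1)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0] = GAP * np.arange(m + 1)
    T = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        s = np.where(b == a[i - 1], MATCH, MISMATCH)
        T[0] = GAP * i
        np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + GAP, out=T[1:])
        H[i] = np.maximum.accumulate(T + ramp) - ramp
    return H


def nw_identity(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(score, matches, columns) of the optimal global alignment of a vs b.

    Traceback prefers diagonal, then up (gap in b), then left (gap in a).
    """
    H = nw_matrix(a, b)
    i, j = len(a), len(b)
    matches = columns = 0
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0:
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if h == H[i - 1, j - 1] + s:
                matches += int(a[i - 1] == b[j - 1])
                i -= 1
                j -= 1
                columns += 1
                continue
        if i > 0 and h == H[i - 1, j] + GAP:
            i -= 1
            columns += 1
            continue
        j -= 1
        columns += 1
    return int(H[-1, -1]), matches, columns


def identity_upper_bound(score: float, n: int, m: int) -> float:
    """Upper bound (percent) on matches/columns given an alignment's score.

    With M matches, X mismatches and G gap columns: score = M - X + 2*GAP-ish
    algebra gives M <= (score + 2(n+m)) / 5 while columns >= max(n, m).
    Used to prune rotations that cannot beat the current best identity.
    """
    return 100.0 * (score + 2.0 * (n + m)) / (5.0 * max(n, m))
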