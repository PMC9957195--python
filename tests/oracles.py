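"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's alignment code: a plain-Python
Needleman-Wunsch over an exhaustive rotation x strand scan. Scoring and
tie-break conventions are restated literally (match +1, mismatch -1,
-2 per gap column; traceback prefers diagonal, then up, then left).
"""

from __future__ import annotations

O_MATCH = 1
O_MISMATCH = -1
O_GAP = -2

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def nw_identity_bruteforce(a: str, b: str) -> tuple[int, int, int]:
    """(score, matches, columns) of the optimal global alignment, plain Python."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = O_GAP * i
    for j in range(1, m + 1):
        H[0][j] = O_GAP * j
    for i in range(1, n + 1):
        row, prev = H[i], H[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = O_MATCH if ai == b[j - 1] else O_MISMATCH
            row[j] = max(prev[j - 1] + s, prev[j] + O_GAP, row[j - 1] + O_GAP)
    i, j = n, m
    matches = columns = 0
    while i > 0 or j > 0:
        h = H[i][j]
        if i > 0 and j > 0:
            s = O_MATCH if a[i - 1] == b[j - 1] else O_MISMATCH
            if h == H[i - 1][j - 1] + s:
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                columns += 1
                continue
        if i > 0 and h == H[i - 1][j] + O_GAP:
            i -= 1
            columns += 1
            continue
        j -= 1
        columns += 1
    return H[n][m], matches, columns


def _tile(seq: str, min_len: int) -> str:
    k = max(2, -(-min_len // len(seq)))
    return seq * k


def oracle_monomer_identity(a: str, b: str, min_len: int = 200) -> float:
    """Max identity over all rotations of the canonically-second monomer and
    both strands, identity taken from the optimal-score alignment."""
    if (len(a), a) > (len(b), b):
        a, b = b, a
    query = _tile(a, min_len)
    best = 0.0
    for strand in (b, revcomp(b)):
        for r in range(len(b)):
            rot = strand[r:] + strand[:r]
            _, matches, columns = nw_identity_bruteforce(query, _tile(rot, min_len))
            best = max(best, 100.0 * matches / columns)
    return best
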