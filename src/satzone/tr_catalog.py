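"""Grouping of TR consensus monomers into subfamilies, families and superfamilies.

Monomers are circular: identity between two consensuses is evaluated after
dimerizing both (tiling to >= 200 nt), over every cyclic rotation and both
strands. Clustering is single linkage on the pairwise identity graph:
edges at >= 95% identity define subfamilies, edges at >= 80% define
families, and pairs below 80% that still share detectable local homology
(a local alignment covering >= 50% of the shorter dimer at >= 70%
identity) join the same superfamily.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from . import _align
from .io_formats import TRConsensus

__all__ = [
    "IdentityResult",
    "TRCatalog",
    "dimerize",
    "monomer_identity",
    "has_local_homology",
    "build_catalog",
    "medoid",
    "write_catalog_tsv",
]

DEFAULT_THRESHOLDS: Mapping[str, float] = {"subfamily": 95.0, "family": 80.0}

#: Superfamily homology-detection rule (stand-in for masking-software defaults).
HOMOLOGY_MIN_COVERAGE = 0.5
HOMOLOGY_MIN_IDENTITY = 70.0


@dataclass(frozen=True)
class IdentityResult:
    """Best rotation/strand-aware identity between two monomers.

    ``rotation_offset`` is the cyclic shift (in [0, rul)) applied to the
    monomer named by ``rotated`` ("a" or "b"); identity is symmetric in the
    two arguments by construction.
    """

    identity_pct: float
    strand: str  # "forward" | "reverse"
    rotation_offset: int
    rotated: str = "b"
    matches: int = 0
    columns: int = 0


@dataclass
class TRCatalog:
    """Nested partition of consensus monomers (subfamily => family => superfamily)."""

    members: list[TRConsensus]
    subfamily_of: dict[str, int]
    family_of: dict[str, int]
    superfamily_of: dict[str, int]

    def __post_init__(self) -> None:
        for fine, coarse, what in (
            (self.subfamily_of, self.family_of, "subfamily/family"),
            (self.family_of, self.superfamily_of, "family/superfamily"),
        ):
            seen: dict[int, int] = {}
            for name, gid in fine.items():
                outer = coarse[name]
                if seen.setdefault(gid, outer) != outer:
                    raise ValueError(f"partition nesting violated at {what} for {name}")

    def n_groups(self, level: str) -> int:
        return len(set(getattr(self, f"{level}_of").values()))

    def group_members(self, level: str, gid: int) -> list[str]:
        mapping = getattr(self, f"{level}_of")
        return [m.name for m in self.members if mapping[m.name] == gid]


def dimerize(seq: TRConsensus, min_len: int = 200) -> str:
    """Tile a monomer head-to-tail until it spans ``min_len`` (at least a dimer).

    The repeat count is ``k = max(2, ceil(min_len / rul))``, so the result is
    always >= 2 monomers and >= ``min_len`` nt.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    k = max(2, math.ceil(min_len / seq.rul))
    return seq.sequence * k


def _dimer_repeats(rul: int, min_len: int) -> int:
    return max(2, math.ceil(min_len / rul))


def monomer_identity(
    a: TRConsensus,
    b: TRConsensus,
    min_len: int = 200,
    prune_below: float = 0.0,
) -> IdentityResult:
    """Rotation- and strand-aware global identity between two monomers.

    Both monomers are dimerized; every cyclic rotation of either partner and
    both strands of ``b`` are scored with Needleman-Wunsch, and the identity
    (matches / alignment columns, gaps in the denominator) of the
    best-scoring alignment per rotation is maximized. Rotations whose
    optimal score provably cannot beat the current best identity are pruned.

    ``prune_below`` trades exactness for speed: rotations that provably
    cannot reach that identity are not traced back, so the returned value is
    exact whenever it is >= ``prune_below`` and a lower bound otherwise
    (useful for threshold tests during clustering).
    """
    # canonical argument order makes the result symmetric: rotations are
    # always searched on the canonically-second monomer
    rotated = "b"
    if (a.rul, a.sequence) > (b.rul, b.sequence):
        a, b = b, a
        rotated = "a"
    enc_a = _align.encode_seq(a.sequence)
    enc_b = _align.encode_seq(b.sequence)
    ka = _dimer_repeats(a.rul, min_len)
    kb = _dimer_repeats(b.rul, min_len)
    dimer_a = np.tile(enc_a, ka)

    pools: list[tuple[np.ndarray, np.ndarray, int, str, str]] = [
        (dimer_a, enc_b, kb, "forward", rotated),
        (dimer_a, _align.revcomp(enc_b), kb, "reverse", rotated),
    ]

    scored: list[tuple[float, np.ndarray, np.ndarray, int, str, str]] = []
    for query, monomer, repeats, strand, rotated in pools:
        rots = _align.rotations_dimer(monomer, repeats)
        scores = _align.nw_scores_batch(query, rots)
        n, m = len(query), rots.shape[1]
        for offset in range(len(monomer)):
            bound = _align.identity_upper_bound(int(scores[offset]), n, m)
            scored.append((bound, query, rots[offset], offset, strand, rotated))

    # candidates sorted by their identity upper bound: once the bound drops
    # below the best identity found, no later candidate can win
    scored.sort(key=lambda t: -t[0])
    best: IdentityResult | None = None
    for bound, query, target, offset, strand, rotated in scored:
        if best is not None and (bound <= best.identity_pct or bound < prune_below):
            break
        _, matches, columns = _align.nw_identity(query, target)
        ident = 100.0 * matches / columns
        if best is None or ident > best.identity_pct:
            best = IdentityResult(ident, strand, offset, rotated, matches, columns)
    assert best is not None
    return best


_local_aligner: Align.PairwiseAligner | None = None


def _get_local_aligner() -> Align.PairwiseAligner:
    global _local_aligner
    if _local_aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = _align.MATCH
        aligner.mismatch_score = _align.MISMATCH
        aligner.open_gap_score = _align.GAP
        aligner.extend_gap_score = _align.GAP
        _local_aligner = aligner
    return _local_aligner


def has_local_homology(
    a: TRConsensus,
    b: TRConsensus,
    min_coverage: float = HOMOLOGY_MIN_COVERAGE,
    min_identity: float = HOMOLOGY_MIN_IDENTITY,
    min_len: int = 200,
) -> bool:
    """Detect residual sequence homology between diverged monomers.

    True when the best local alignment of the dimerized sequences (either
    strand) covers at least ``min_coverage`` of the shorter dimer with at
    least ``min_identity`` percent identity.
    """
    aligner = _get_local_aligner()
    da, db = dimerize(a, min_len), dimerize(b, min_len)
    for query in (db, _revcomp_str(db)):
        alignments = aligner.align(da, query)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        counts = aln.counts()
        columns = counts.gaps + counts.identities + counts.mismatches
        if columns == 0:
            continue
        identity = 100.0 * counts.identities / columns
        blocks_a, blocks_b = aln.aligned
        span_a = blocks_a[-1][1] - blocks_a[0][0]
        span_b = blocks_b[-1][1] - blocks_b[0][0]
        shorter = min(len(da), len(db))
        coverage = (span_a if len(da) <= len(db) else span_b) / shorter
        if coverage >= min_coverage and identity >= min_identity:
            return True
    return False


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp_str(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_catalog(
    members: Sequence[TRConsensus],
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    abundance: Mapping[str, float] | None = None,
    min_len: int = 200,
) -> TRCatalog:
    """Single-linkage clustering of monomers at the subfamily/family thresholds.

    Group ids are dense from 1, ordered by decreasing total abundance when
    ``abundance`` (per member name) is supplied, else by input order.
    """
    if not members:
        raise ValueError("need at least one member")
    sub_t, fam_t = thresholds["subfamily"], thresholds["family"]
    for t in (sub_t, fam_t):
        if not 0 < t <= 100:
            raise ValueError(f"threshold {t} not in (0, 100]")
    if sub_t < fam_t:
        raise ValueError("subfamily threshold must be >= family threshold")

    n = len(members)
    uf_sub, uf_fam, uf_super = _UnionFind(n), _UnionFind(n), _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            # exact identity only needed at/above the family threshold
            ident = monomer_identity(
                members[i], members[j], min_len=min_len, prune_below=fam_t
            ).identity_pct
            if ident >= sub_t:
                uf_sub.union(i, j)
            if ident >= fam_t:
                uf_fam.union(i, j)
                uf_super.union(i, j)
            elif has_local_homology(members[i], members[j], min_len=min_len):
                uf_super.union(i, j)

    def label(uf: _UnionFind) -> dict[str, int]:
        roots: dict[int, list[int]] = {}
        for idx in range(n):
            roots.setdefault(uf.find(idx), []).append(idx)

        def weight(indices: list[int]) -> float:
            if abundance is None:
                return 0.0
            return -sum(abundance.get(members[i].name, 0.0) for i in indices)

        ordered = sorted(roots.values(), key=lambda idxs: (weight(idxs), min(idxs)))
        out: dict[str, int] = {}
        for gid, idxs in enumerate(ordered, start=1):
            for i in idxs:
                out[members[i].name] = gid
        return out

    return TRCatalog(list(members), label(uf_sub), label(uf_fam), label(uf_super))


def medoid(members: Sequence[TRConsensus], min_len: int = 200) -> TRConsensus:
    """Representative consensus of a merged group: the member maximizing mean
    identity to the others (ties to input order)."""
    if len(members) == 1:
        return members[0]
    n = len(members)
    ident = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = monomer_identity(
                members[i], members[j], min_len=min_len
            ).identity_pct
    means = ident.sum(axis=1) / (n - 1)
    return members[int(np.argmax(means))]


def write_catalog_tsv(catalog: TRCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsubfamily\tfamily\tsuperfamily\n")
        for m in catalog.members:
            fh.write(
                f"{m.name}\t{catalog.subfamily_of[m.name]}\t"
                f"{catalog.family_of[m.name]}\t{catalog.superfamily_of[m.name]}\n"
            )
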