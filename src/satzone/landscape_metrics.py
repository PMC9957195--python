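"""Repeat landscapes in 0.5%-divergence bins and derived indices.

A landscape is a histogram of a family's genomic abundance (aligned bp)
over half-open divergence intervals [edge, edge + 0.5). From it come
DIVPEAK (divergence bin of maximum abundance, a degeneration index), RPS
(relative peak size, a homogenization index), and an amplification-time
estimate t = DIVPEAK / (2 * rate) in Mya. TSI (tandem structure index) is
computed separately from junction-annotated hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .io_formats import DivergenceHit

__all__ = [
    "RepeatLandscape",
    "LandscapeMetrics",
    "HitContext",
    "compute_landscape",
    "divpeak",
    "rps",
    "tsi",
    "amplification_time",
    "compute_metrics",
    "write_landscape_tsv",
    "read_landscape_tsv",
]

#: Library-wide satDNA turnover rate, percent divergence per lineage per Mya.
#: The dating formula's printed constant (1.11) is used, not the prose's 1.1.
DEFAULT_RATE = 1.11

DEFAULT_BIN_WIDTH = 0.5

_EPS = 1e-9


@dataclass
class RepeatLandscape:
    """Abundance of one family in one library, binned by divergence."""

    family: str
    library_id: str
    bins: dict[float, int]  # bin lower edge -> abundance (bp)
    bin_width: float = DEFAULT_BIN_WIDTH

    @property
    def total_bp(self) -> int:
        return sum(self.bins.values())

    @property
    def edges(self) -> list[float]:
        return sorted(self.bins)


@dataclass(frozen=True)
class LandscapeMetrics:
    divpeak_pct: float
    rps_pct: float
    time_mya: float
    tsi: Optional[float] = None


def compute_landscape(
    hits: Iterable[DivergenceHit],
    family: str,
    library_id: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> RepeatLandscape:
    """Bin hit lengths of one (family, library) into divergence intervals.

    Each hit contributes its aligned length to the half-open bin
    [edge, edge + width) containing its divergence; zero-abundance bins are
    retained up to the maximum observed divergence so the landscape's shape
    is explicit.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    selected = [
        h for h in hits if h.family == family and (not library_id or h.library_id == library_id)
    ]
    if not selected:
        raise ValueError(f"empty landscape for family={family!r} library={library_id!r}")
    counts: dict[int, int] = {}
    for h in selected:
        idx = int(math.floor(h.divergence_pct / bin_width + _EPS))
        counts[idx] = counts.get(idx, 0) + h.length_bp
    top = max(counts)
    bins = {round(i * bin_width, 10): counts.get(i, 0) for i in range(top + 1)}
    return RepeatLandscape(family, library_id, bins, bin_width)


def divpeak(landscape: RepeatLandscape) -> float:
    """Lower edge of the maximum-abundance bin; ties break toward lower divergence."""
    if not landscape.bins:
        raise ValueError("empty landscape")
    return min(landscape.edges, key=lambda e: (-landscape.bins[e], e))


def rps(landscape: RepeatLandscape, window_pct: float = 1.0) -> float:
    """Relative peak size: percent of total abundance within +-window of DIVPEAK.

    A bin counts when its lower edge lies within ``window_pct`` of the
    DIVPEAK edge.
    """
    if window_pct < landscape.bin_width:
        raise ValueError("window_pct must be >= bin width")
    peak = divpeak(landscape)
    in_window = sum(
        abundance
        for edge, abundance in landscape.bins.items()
        if abs(edge - peak) <= window_pct + _EPS
    )
    return 100.0 * in_window / landscape.total_bp


@dataclass(frozen=True)
class HitContext:
    """A hit annotated with whether its flanks are the same repeat (junction evidence)."""

    hit: DivergenceHit
    left_same: Optional[bool]
    right_same: Optional[bool]


def tsi(hit_contexts: Sequence[HitContext]) -> float:
    """Tandem structure index: abundance fraction of hits with >=1 same-repeat junction."""
    if not hit_contexts:
        raise ValueError("no hit contexts")
    total = tandem = 0
    for ctx in hit_contexts:
        if ctx.left_same is None or ctx.right_same is None:
            raise ValueError(f"hit of {ctx.hit.family!r} lacks junction annotation")
        total += ctx.hit.length_bp
        if ctx.left_same or ctx.right_same:
            tandem += ctx.hit.length_bp
    return tandem / total


def amplification_time(divpeak_pct: float, rate: float = DEFAULT_RATE) -> float:
    """Time (Mya) since the last amplification burst: DIVPEAK / (2 * rate).

    The factor 2 reflects divergence accruing on both descendant lineages of
    the amplified consensus. Reporting layers round to one decimal.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if divpeak_pct < 0:
        raise ValueError("divpeak_pct must be >= 0")
    return divpeak_pct / (2.0 * rate)


def compute_metrics(
    landscape: RepeatLandscape,
    rate: float = DEFAULT_RATE,
    window_pct: float = 1.0,
    hit_contexts: Sequence[HitContext] | None = None,
) -> LandscapeMetrics:
    peak = divpeak(landscape)
    return LandscapeMetrics(
        divpeak_pct=peak,
        rps_pct=rps(landscape, window_pct),
        time_mya=amplification_time(peak, rate),
        tsi=tsi(hit_contexts) if hit_contexts is not None else None,
    )


def write_landscape_tsv(landscape: RepeatLandscape, path: str | Path) -> None:
    total = landscape.total_bp
    with open(path, "w") as fh:
        fh.write("bin_lower\tabundance_bp\tfraction\n")
        for edge in landscape.edges:
            ab = landscape.bins[edge]
            fh.write(f"{edge:g}\t{ab}\t{ab / total:.6f}\n")


def read_landscape_tsv(path: str | Path, family: str = "", library_id: str = "") -> RepeatLandscape:
    bins: dict[float, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("bin_lower"):
            raise ValueError(f"{path}: not a landscape TSV")
        for line in fh:
            edge, ab, _ = line.split("\t")
            bins[float(edge)] = int(ab)
    edges = sorted(bins)
    width = min(b - a for a, b in zip(edges, edges[1:])) if len(edges) > 1 else DEFAULT_BIN_WIDTH
    return RepeatLandscape(family, library_id, bins, width)
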