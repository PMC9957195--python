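"""Allele-frequency clines along a transect and paired effect sizes.

Genotype counts become banded-allele frequencies (exact rational
arithmetic; rounding happens only at report time, half-up to two
decimals). The cline centre is the adjacent site pair whose segment
crosses q = 0.5 under linear interpolation on transect order, plus the
endpoint nearest 0.5. Paired marker comparisons use the mean paired
difference with a seeded BCa bootstrap confidence interval
(Gardner-Altman style estimation statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import GenotypeTable, TransectSite

__all__ = [
    "AlleleFrequencies",
    "ClineProfile",
    "ClineCenter",
    "PairedEffect",
    "allele_frequencies",
    "build_cline",
    "cline_center",
    "paired_mean_difference",
    "round_half_up",
]


def round_half_up(value, ndigits: int = 2) -> float:
    """Round half away from zero, as in the printed frequency tables."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AlleleFrequencies:
    """Exact banded/non-banded allele frequencies for one population-marker pair."""

    population: str
    marker: str
    n_chromosomes: int
    p_N: Fraction
    q_B: Fraction

    def __post_init__(self) -> None:
        if self.p_N + self.q_B != 1:
            raise ValueError("p_N + q_B must equal 1 exactly")

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        return round_half_up(self.p_N, ndigits), round_half_up(self.q_B, ndigits)


def allele_frequencies(gt: GenotypeTable) -> AlleleFrequencies:
    """Banded-allele frequency from genotype counts.

    Autosomal: q = (NB + 2*BB) / (2 * total males); X-linked (X0 males are
    hemizygous): q = B / (N + B). Arithmetic is exact.
    """
    if gt.total == 0:
        raise ValueError(f"{gt.population}/{gt.marker}: zero total count")
    if gt.linkage == "autosomal":
        nn, nb, bb = gt.counts
        n_chrom = 2 * (nn + nb + bb)
        q = Fraction(nb + 2 * bb, n_chrom)
    else:
        n, b = gt.counts
        n_chrom = n + b
        q = Fraction(b, n_chrom)
    return AlleleFrequencies(gt.population, gt.marker, n_chrom, 1 - q, q)


@dataclass
class ClineProfile:
    """Ordered allele frequencies along the transect for one marker."""

    marker: str
    entries: list[tuple[TransectSite, Optional[AlleleFrequencies]]]

    def frequencies(self) -> list[tuple[TransectSite, Fraction]]:
        return [(site, af.q_B) for site, af in self.entries if af is not None]


def build_cline(
    gts: Sequence[GenotypeTable],
    sites: Sequence[TransectSite],
    marker: str,
) -> ClineProfile:
    """Match genotype tables to transect sites and order them by transect position."""
    by_pop = {gt.population: gt for gt in gts if gt.marker == marker}
    site_pops = {s.population for s in sites}
    unmatched = set(by_pop) - site_pops
    if unmatched:
        raise ValueError(f"genotype populations without a transect site: {sorted(unmatched)}")
    entries: list[tuple[TransectSite, Optional[AlleleFrequencies]]] = []
    for site in sorted(sites, key=lambda s: s.order_index):
        gt = by_pop.get(site.population)
        entries.append((site, allele_frequencies(gt) if gt is not None else None))
    return ClineProfile(marker, entries)


@dataclass(frozen=True)
class ClineCenter:
    interval: tuple[TransectSite, TransectSite]
    nearest_site: TransectSite


def cline_center(profile: ClineProfile) -> Optional[ClineCenter]:
    """First adjacent site pair whose segment crosses q = 0.5, plus the
    endpoint whose frequency is nearer 0.5 (ties to the earlier site).

    Returns None when the profile never spans 0.5.
    """
    freqs = profile.frequencies()
    if len(freqs) < 2:
        raise ValueError("need at least two sites with frequencies")
    half = Fraction(1, 2)
    for (site_a, qa), (site_b, qb) in zip(freqs, freqs[1:]):
        lo, hi = min(qa, qb), max(qa, qb)
        if lo <= half <= hi:
            nearest = site_a if abs(qa - half) <= abs(qb - half) else site_b
            return ClineCenter((site_a, site_b), nearest)
    return None


@dataclass(frozen=True)
class PairedEffect:
    mean_difference: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean_difference <= self.ci_high:
            raise ValueError("CI must bracket the mean difference")


def paired_mean_difference(
    x: Sequence[float | Fraction],
    y: Sequence[float | Fraction],
    seed: int,
    n_boot: int = 5000,
    confidence_level: float = 0.95,
) -> PairedEffect:
    """Paired mean difference mean(y - x) with a seeded BCa bootstrap CI.

    Pairs are resampled with replacement; the interval is the
    bias-corrected-and-accelerated percentile interval of the bootstrap
    distribution. When every paired difference is identical the interval is
    degenerate at the point estimate.
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    diffs = np.asarray([float(b) - float(a) for a, b in zip(x, y)])
    mean = float(np.mean(diffs))
    if np.ptp(diffs) == 0:
        return PairedEffect(mean, mean, mean, len(x), n_boot, seed)
    res = stats.bootstrap(
        (diffs,),
        np.mean,
        n_resamples=n_boot,
        confidence_level=confidence_level,
        method="BCa",
        rng=np.random.default_rng(seed),
    )
    return PairedEffect(
        mean,
        float(res.confidence_interval.low),
        float(res.confidence_interval.high),
        len(x),
        n_boot,
        seed,
    )
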