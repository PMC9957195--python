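"""Comparison of FISH band tables between two taxa.

Families are classified by FISH pattern (B banded, DB dotted-banded,
D dotted, NS no signal); B and DB count as banded, D does not.
Heterozygous (asterisk) bands count toward presence. The karyotype is
fixed at eight autosomes plus the X.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import CHROMOSOMES, BandRecord

__all__ = [
    "PatternSummary",
    "DifferentialMarker",
    "BANDED_PATTERNS",
    "summarize_patterns",
    "spread_histogram",
    "differential_markers",
    "per_chromosome_counts",
    "families_on_chromosome",
]

BANDED_PATTERNS = frozenset({"B", "DB"})


@dataclass(frozen=True)
class PatternSummary:
    family: str
    taxon: str
    pattern: str
    chrom_count: int

    @property
    def banded(self) -> bool:
        return self.pattern in BANDED_PATTERNS


@dataclass(frozen=True)
class DifferentialMarker:
    """A family banded in exactly one of the two taxa (B/DB vs NS)."""

    family: str
    banded_in: str
    absent_in: str
    chromosomes: tuple[str, ...]


def summarize_patterns(
    bands: Iterable[BandRecord],
    patterns: Mapping[str, str],
    taxon: str,
) -> list[PatternSummary]:
    """Per-family summary for one taxon: pattern plus distinct-chromosome count.

    ``patterns`` must cover every family appearing in the band records; an
    NS family with band records is a validation error.
    """
    chroms: dict[str, set[str]] = {}
    for rec in bands:
        if rec.taxon != taxon:
            continue
        if rec.family not in patterns:
            raise ValueError(f"no pattern supplied for family {rec.family!r}")
        chroms.setdefault(rec.family, set()).add(rec.chromosome)
    out: list[PatternSummary] = []
    for family, pattern in patterns.items():
        count = len(chroms.get(family, ()))
        if pattern == "NS" and count:
            raise ValueError(f"family {family!r} is NS but has {count} band records")
        out.append(PatternSummary(family, taxon, pattern, count))
    return out


def spread_histogram(summaries: Iterable[PatternSummary], taxon: str) -> dict[int, int]:
    """Chromosome-spread histogram over banded families: chrom_count -> n families."""
    hist = {n: 0 for n in range(1, len(CHROMOSOMES) + 1)}
    for s in summaries:
        if s.taxon == taxon and s.banded:
            hist[s.chrom_count] += 1
    return hist


def differential_markers(
    summaries_a: Sequence[PatternSummary],
    summaries_b: Sequence[PatternSummary],
    bands_a: Iterable[BandRecord] = (),
    bands_b: Iterable[BandRecord] = (),
) -> list[DifferentialMarker]:
    """Families banded (B/DB) in exactly one taxon and NS in the other.

    Both summary sets must cover the same families. The affected chromosomes
    are taken from the banded taxon's records when supplied. Swapping the
    two taxa swaps ``banded_in``/``absent_in`` and nothing else.
    """
    a_by = {s.family: s for s in summaries_a}
    b_by = {s.family: s for s in summaries_b}
    if set(a_by) != set(b_by):
        missing = set(a_by) ^ set(b_by)
        raise ValueError(f"taxa cover different family sets: {sorted(missing)}")
    chrom_map: dict[tuple[str, str], set[str]] = {}
    for rec in list(bands_a) + list(bands_b):
        chrom_map.setdefault((rec.family, rec.taxon), set()).add(rec.chromosome)

    out: list[DifferentialMarker] = []
    for family in a_by:
        sa, sb = a_by[family], b_by[family]
        if sa.banded and sb.pattern == "NS":
            banded, absent = sa, sb
        elif sb.banded and sa.pattern == "NS":
            banded, absent = sb, sa
        else:
            continue
        chroms = sorted(
            chrom_map.get((family, banded.taxon), ()),
            key=CHROMOSOMES.index,
        )
        out.append(DifferentialMarker(family, banded.taxon, absent.taxon, tuple(chroms)))
    out.sort(key=lambda m: m.family)
    return out


def per_chromosome_counts(bands: Iterable[BandRecord], taxon: str) -> dict[str, int]:
    """Distinct families with at least one band on each chromosome."""
    fams: dict[str, set[str]] = {c: set() for c in CHROMOSOMES}
    for rec in bands:
        if rec.taxon == taxon:
            fams[rec.chromosome].add(rec.family)
    return {c: len(fams[c]) for c in CHROMOSOMES}


def families_on_chromosome(
    bands: Iterable[BandRecord],
    taxon: str,
    chromosome: str,
    location: str | None = None,
) -> set[str]:
    """Families with a band on one chromosome, optionally of one location class."""
    out: set[str] = set()
    for rec in bands:
        if rec.taxon != taxon or rec.chromosome != chromosome:
            continue
        if location is None or location in rec.locations:
            out.add(rec.family)
    return out
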