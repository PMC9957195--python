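"""Readers and writers for the external formats the pipeline touches.

All downstream modules consume the domain types defined here:
consensus sequences (FASTA), per-hit divergence/abundance records
(RepeatMasker ``.out``/``.align`` or the package's own TSV), cytogenetic
band tables, genotype-count tables and transect site tables (CSV).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "ParseError",
    "TRConsensus",
    "DivergenceHit",
    "BandRecord",
    "GenotypeTable",
    "TransectSite",
    "CHROMOSOMES",
    "read_fasta",
    "write_fasta",
    "read_repeatmasker_hits",
    "write_hits_tsv",
    "read_band_table",
    "write_band_table",
    "read_genotype_table",
    "write_genotype_table",
    "read_transect_sites",
    "write_transect_sites",
]

DNA_ALPHABET = frozenset("ACGTN")

#: Fixed karyotype: eight autosomes plus the X (X0 males / XX females).
CHROMOSOMES: tuple[str, ...] = ("1", "2", "3", "4", "5", "6", "7", "8", "X")

#: FISH signal classes: banded, dotted-banded, dotted, no signal.
PATTERNS: tuple[str, ...] = ("B", "DB", "D", "NS")

_LOCATIONS = frozenset("pid")

_NAME_RUL_RE = re.compile(r"-(\d+)$")


class ParseError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass(frozen=True)
class TRConsensus:
    """One tandem-repeat variant's consensus monomer.

    ``rul`` (repeat unit length) always equals ``len(sequence)``: exactly one
    monomer unit is stored; dimerization is an operation, never a storage
    convention.
    """

    name: str
    sequence: str
    rul: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.name!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence of {self.name!r} contains non-DNA characters: {sorted(bad)}"
            )
        if self.rul == 0:
            object.__setattr__(self, "rul", len(seq))
        if self.rul != len(seq):
            raise ValueError(
                f"{self.name!r}: rul={self.rul} does not match sequence length {len(seq)}"
            )


@dataclass(frozen=True)
class DivergenceHit:
    """One genomic hit of a repeat family, with its divergence from the consensus."""

    family: str
    divergence_pct: float
    length_bp: int
    library_id: str = ""
    divergence_source: str = "raw"  # "raw" or "kimura" (``.align`` dialect)

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence_pct <= 100.0:
            raise ValueError(f"divergence_pct out of [0, 100]: {self.divergence_pct}")
        if self.length_bp < 1:
            raise ValueError(f"length_bp must be >= 1, got {self.length_bp}")


@dataclass(frozen=True)
class BandRecord:
    """FISH bands of one family on one chromosome of one taxon.

    ``locations`` holds one entry per band over {p, i, d} (pericentromeric,
    interstitial, distal) with multiplicity; ``heterozygous`` flags bands
    observed on only one member of the chromosome pair (the asterisk
    convention of the printed tables).
    """

    family: str
    taxon: str
    chromosome: str
    locations: tuple[str, ...]
    heterozygous: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome {self.chromosome!r}")
        if not self.locations:
            raise ValueError(
                f"{self.family}/{self.chromosome}: a record must carry >=1 band"
            )
        if len(self.locations) != len(self.heterozygous):
            raise ValueError("locations and heterozygous flags differ in length")
        bad = set(self.locations) - _LOCATIONS
        if bad:
            raise ValueError(f"invalid band locations {sorted(bad)}")


@dataclass(frozen=True)
class GenotypeTable:
    """Genotype counts for one marker in one population.

    Autosomal tables carry a (NN, NB, BB) triple from male meiotic scoring;
    X-linked tables carry a hemizygous-male (N, B) pair — X0 males never
    contribute heterozygote counts.
    """

    population: str
    marker: str
    linkage: str  # "autosomal" | "x_linked"
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.linkage not in ("autosomal", "x_linked"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        want = 3 if self.linkage == "autosomal" else 2
        if len(self.counts) != want:
            raise ValueError(
                f"{self.population}/{self.marker}: {self.linkage} tables need "
                f"{want} counts, got {len(self.counts)}"
            )
        if any(c < 0 for c in self.counts):
            raise ValueError("negative genotype count")

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class TransectSite:
    population: str
    country: str
    latitude: float
    longitude: float
    altitude_m: float
    n_males: int
    order_index: int


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[TRConsensus]:
    """Read consensus monomers from FASTA.

    The repeat-unit length is parsed from a trailing ``-{int}`` name suffix
    when present (the ``CpaTR{NNN}-{RUL}`` convention) and must then match
    the sequence length; otherwise it defaults to the sequence length.
    An empty file yields an empty list.
    """
    out: list[TRConsensus] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            m = _NAME_RUL_RE.search(rec.id)
            rul = int(m.group(1)) if m else len(seq)
            out.append(TRConsensus(name=rec.id, sequence=seq, rul=rul))
        except ValueError as exc:
            raise ParseError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(consensuses: Iterable[TRConsensus], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for c in consensuses:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker hits

_ALIGN_HEADER_RE = re.compile(
    r"^\s*\d+\s+([\d.]+)\s+[\d.]+\s+[\d.]+\s+(\S+)\s+(\d+)\s+(\d+)\s+\(\d+\)\s+(C\s+)?(\S+)"
)
_KIMURA_RE = re.compile(r"^Kimura.*=\s*([\d.]+)")


def read_repeatmasker_hits(
    path: str | Path, dialect: str = "tsv", library_id: str = ""
) -> list[DivergenceHit]:
    """Read per-hit divergence records.

    ``dialect`` selects the format: RepeatMasker ``out`` (divergence is the
    ``perc div.`` column), RepeatMasker ``align`` (the Kimura-corrected value
    of the block is preferred when present, else the raw percent of its
    header line; which one was used is recorded in ``divergence_source``),
    or the package's own ``tsv`` (family, divergence_pct, length_bp,
    library_id). Hit lengths are 1-based inclusive: ``end - begin + 1``.
    """
    if dialect == "tsv":
        return _read_hits_tsv(path)
    if dialect == "out":
        return _read_hits_out(path, library_id)
    if dialect == "align":
        return _read_hits_align(path, library_id)
    raise ParseError(f"unknown dialect {dialect!r} (expected out, align or tsv)")


def _read_hits_tsv(path: str | Path) -> list[DivergenceHit]:
    hits: list[DivergenceHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected >=3 tab-separated fields")
            try:
                div = float(parts[1])
                length = int(parts[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            lib = parts[3] if len(parts) > 3 else ""
            hits.append(DivergenceHit(parts[0], div, length, lib))
    return hits


def _read_hits_out(path: str | Path, library_id: str) -> list[DivergenceHit]:
    hits: list[DivergenceHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            # skip the three-line header and blank lines
            if not parts or not parts[0].isdigit():
                continue
            try:
                div = float(parts[1])
                qbegin, qend = int(parts[5]), int(parts[6])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: malformed .out row: {exc}") from exc
            family = parts[9]
            hits.append(
                DivergenceHit(family, div, qend - qbegin + 1, library_id)
            )
    return hits


def _read_hits_align(path: str | Path, library_id: str) -> list[DivergenceHit]:
    hits: list[DivergenceHit] = []
    pending: dict | None = None

    def flush() -> None:
        nonlocal pending
        if pending is not None:
            hits.append(DivergenceHit(**pending))
            pending = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            m = _ALIGN_HEADER_RE.match(line)
            if m:
                flush()
                try:
                    div = float(m.group(1))
                except ValueError as exc:  # pragma: no cover - regex guards this
                    raise ParseError(f"line {lineno}: {exc}") from exc
                family = m.group(6).split("#")[0]
                qbegin, qend = int(m.group(3)), int(m.group(4))
                pending = dict(
                    family=family,
                    divergence_pct=div,
                    length_bp=qend - qbegin + 1,
                    library_id=library_id,
                    divergence_source="raw",
                )
                continue
            k = _KIMURA_RE.match(line)
            if k and pending is not None:
                pending["divergence_pct"] = float(k.group(1))
                pending["divergence_source"] = "kimura"
    flush()
    return hits


def write_hits_tsv(hits: Iterable[DivergenceHit], path: str | Path) -> None:
    """Write hits in the package TSV dialect (floats round-trip exactly)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.family}\t{h.divergence_pct!r}\t{h.length_bp}\t{h.library_id}\n")


# ---------------------------------------------------------------------------
# Band tables

_BAND_HEADER = ["family", "pattern", *[f"chr{c}" for c in CHROMOSOMES], "n_chrom"]


def parse_band_cell(cell: str, family: str = "?", chromosome: str = "?") -> tuple[tuple[str, ...], tuple[bool, ...]]:
    """Expand a compact band code like ``"p*i*d*"`` or ``"iii"``.

    Whitespace is ignored (the printed tables use ``"d *"``); each location
    character may be followed by ``*`` marking a heterozygous band.
    """
    compact = cell.replace(" ", "")
    locations: list[str] = []
    het: list[bool] = []
    i = 0
    while i < len(compact):
        ch = compact[i]
        if ch not in _LOCATIONS:
            raise ParseError(
                f"family {family}, chromosome {chromosome}: "
                f"invalid band character {ch!r} in cell {cell!r}"
            )
        i += 1
        flag = i < len(compact) and compact[i] == "*"
        if flag:
            i += 1
        locations.append(ch)
        het.append(flag)
    return tuple(locations), tuple(het)


def format_band_cell(record: BandRecord) -> str:
    return "".join(
        loc + ("*" if h else "") for loc, h in zip(record.locations, record.heterozygous)
    )


def read_band_table(path: str | Path, taxon: str) -> tuple[list[BandRecord], dict[str, str]]:
    """Read a band-table CSV (one row per family, one column per chromosome).

    Returns the expanded band records together with the per-family FISH
    pattern map (B/DB/D/NS). The redundant ``n_chrom`` column, when present,
    is validated against the recomputed distinct-chromosome count, and NS
    families must have no band cells.
    """
    records: list[BandRecord] = []
    patterns: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "family" not in reader.fieldnames:
            raise ParseError(f"{path}: missing band-table header")
        for row in reader:
            family = row["family"].strip()
            pattern = row["pattern"].strip()
            if pattern not in PATTERNS:
                raise ParseError(f"family {family}: unknown pattern {pattern!r}")
            patterns[family] = pattern
            n_chrom = 0
            for chrom in CHROMOSOMES:
                cell = (row.get(f"chr{chrom}") or "").strip()
                if not cell:
                    continue
                locs, het = parse_band_cell(cell, family, chrom)
                records.append(BandRecord(family, taxon, chrom, locs, het))
                n_chrom += 1
            claimed = (row.get("n_chrom") or "").strip()
            if claimed and int(claimed) != n_chrom:
                raise ParseError(
                    f"family {family}: n_chrom column says {claimed} but "
                    f"{n_chrom} chromosomes carry bands"
                )
            if pattern == "NS" and n_chrom:
                raise ParseError(f"family {family}: NS pattern but band cells present")
    return records, patterns


def write_band_table(
    records: Sequence[BandRecord],
    patterns: dict[str, str],
    path: str | Path,
) -> None:
    by_family: dict[str, dict[str, BandRecord]] = {}
    for rec in records:
        by_family.setdefault(rec.family, {})[rec.chromosome] = rec
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_BAND_HEADER)
        for family, pattern in patterns.items():
            cells = by_family.get(family, {})
            row = [family, pattern]
            row += [format_band_cell(cells[c]) if c in cells else "" for c in CHROMOSOMES]
            row.append(str(len(cells)))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Genotype tables

_GT_HEADER = ["population", "marker", "linkage", "NN", "NB", "BB", "N", "B"]


def read_genotype_table(path: str | Path) -> list[GenotypeTable]:
    tables: list[GenotypeTable] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            linkage = row["linkage"].strip()
            try:
                if linkage == "autosomal":
                    counts = tuple(int(row[k]) for k in ("NN", "NB", "BB"))
                elif linkage == "x_linked":
                    counts = tuple(int(row[k]) for k in ("N", "B"))
                else:
                    raise ParseError(
                        f"population {row.get('population')}: unknown linkage {linkage!r}"
                    )
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"population {row.get('population')}: bad counts ({exc})"
                ) from exc
            tables.append(
                GenotypeTable(row["population"].strip(), row["marker"].strip(), linkage, counts)
            )
    return tables


def write_genotype_table(tables: Sequence[GenotypeTable], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_GT_HEADER)
        for t in tables:
            if t.linkage == "autosomal":
                nn, nb, bb = t.counts
                writer.writerow([t.population, t.marker, t.linkage, nn, nb, bb, "", ""])
            else:
                n, b = t.counts
                writer.writerow([t.population, t.marker, t.linkage, "", "", "", n, b])


# ---------------------------------------------------------------------------
# Transect sites

_SITE_HEADER = [
    "population", "country", "latitude", "longitude", "altitude_m", "n_males", "order_index",
]


def read_transect_sites(path: str | Path) -> list[TransectSite]:
    sites: list[TransectSite] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            sites.append(
                TransectSite(
                    population=row["population"].strip(),
                    country=row["country"].strip(),
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                    altitude_m=float(row["altitude_m"]),
                    n_males=int(row["n_males"]),
                    order_index=int(row["order_index"]),
                )
            )
    sites.sort(key=lambda s: s.order_index)
    if any(a.order_index >= b.order_index for a, b in zip(sites, sites[1:])):
        raise ParseError("order_index must be strictly increasing along the transect")
    return sites


def write_transect_sites(sites: Sequence[TransectSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SITE_HEADER)
        for s in sorted(sites, key=lambda s: s.order_index):
            writer.writerow(
                [s.population, s.country, s.latitude, s.longitude, s.altitude_m, s.n_males, s.order_index]
            )
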