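"""Bundled data tables: band maps, hybrid-zone genotypes and transect sites.

The CSVs under ``satzone/data`` are transcriptions of the published
chromosome-band and genotype-frequency tables for the two subspecies
(CPP, CPE); loaders return fully parsed domain objects.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io_formats import (
    BandRecord,
    GenotypeTable,
    TransectSite,
    read_band_table,
    read_genotype_table,
    read_transect_sites,
)

__all__ = [
    "data_path",
    "load_band_table",
    "load_genotype_tables",
    "load_transect_sites",
    "AUTOSOMAL_MARKER",
    "X_LINKED_MARKER",
]

AUTOSOMAL_MARKER = "CpaTR100-295"
X_LINKED_MARKER = "CpaTR104-269"

_FILES = {
    "CPP": "cpp_bands.csv",
    "CPE": "cpe_bands.csv",
}


def data_path(name: str) -> Path:
    return Path(str(resources.files("satzone.data").joinpath(name)))


def load_band_table(taxon: str) -> tuple[list[BandRecord], dict[str, str]]:
    """Band records and FISH-pattern map for one taxon ("CPP" or "CPE")."""
    try:
        fname = _FILES[taxon.upper()]
    except KeyError:
        raise ValueError(f"unknown taxon {taxon!r}; expected CPP or CPE") from None
    return read_band_table(data_path(fname), taxon.upper())


def load_genotype_tables() -> list[GenotypeTable]:
    """Hybrid-zone genotype counts for both TR markers at the seven sites."""
    return read_genotype_table(data_path("hz_genotypes.csv"))


def load_transect_sites() -> list[TransectSite]:
    """The seven transect sites, ordered from the French to the Spanish end."""
    return read_transect_sites(data_path("transect_sites.csv"))
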