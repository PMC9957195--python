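"""Synthetic inputs with known ground truth.

Three generators cover the pipeline's inputs: monomer populations from
amplification bursts (for landscapes and dating), consensus libraries
with planted subfamily/family structure (for catalogue recovery), and
transect genotype samples under a sigmoid allele-frequency cline with
Hardy-Weinberg (autosomal) or hemizygous-male (X-linked) sampling.

The burst mutation model is parameterized so the dating estimator
t = DIVPEAK / (2 * rate) is unbiased: a copy's expected divergence from
the amplified consensus is 2 * rate * time percent. Substitutions are
uniform across sites and bases, no indels. All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import DivergenceHit, GenotypeTable, TransectSite

__all__ = [
    "BurstModel",
    "ClineModel",
    "random_monomer",
    "mutate_sequence",
    "simulate_burst_family",
    "simulate_library",
    "simulate_transect",
    "default_transect_sites",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _BASE_INDEX[_c] = _i


@dataclass(frozen=True)
class BurstModel:
    """One amplification burst: ``copies`` monomers drawn at ``burst_time_mya``
    accumulate substitutions at 2 * ``sub_rate_pct_per_mya`` percent per Mya."""

    burst_time_mya: float
    copies: int
    monomer_len: int
    seed: int
    sub_rate_pct_per_mya: float = 1.11
    family: str = "burstFam"
    library_id: str = "SIM"

    def __post_init__(self) -> None:
        if self.burst_time_mya < 0:
            raise ValueError("burst_time_mya must be >= 0")
        if self.copies < 1 or self.monomer_len < 1:
            raise ValueError("copies and monomer_len must be positive")
        if self.sub_rate_pct_per_mya <= 0:
            raise ValueError("sub_rate_pct_per_mya must be positive")

    @property
    def expected_divergence_pct(self) -> float:
        return 2.0 * self.sub_rate_pct_per_mya * self.burst_time_mya


def random_monomer(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_sequence(
    seq: str, divergence_pct: float, rng: np.random.Generator, exact: bool = False
) -> str:
    """Substitute sites of ``seq`` to a target divergence.

    By default each site is hit independently with probability
    ``divergence_pct``/100 (binomially distributed realized divergence);
    with ``exact`` a fixed ``round(p * len)`` count of distinct sites is
    substituted instead, for generators that must keep planted divergences
    tightly inside identity-threshold bands. Substituted sites always
    receive a different base (Jukes-Cantor-like), so the realized hamming
    divergence equals the number of hit sites.
    """
    p = divergence_pct / 100.0
    if not 0 <= p <= 1:
        raise ValueError("divergence_pct must be in [0, 100]")
    enc = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if np.any(enc > 3):
        raise ValueError("can only mutate A/C/G/T sequences")
    if exact:
        n_sites = round(p * len(enc))
        idx = rng.choice(len(enc), size=n_sites, replace=False)
    else:
        idx = np.flatnonzero(rng.random(len(enc)) < p)
    # shifting by 1-3 mod 4 always lands on a different base
    enc[idx] = (enc[idx] + rng.integers(1, 4, size=len(idx))) % 4
    return _BASES[enc].tobytes().decode()


def simulate_burst_family(model: BurstModel):
    """Draw burst copies from a random ancestral monomer.

    Returns (monomers, hits): the mutated copies as TRConsensus records
    (writable with ``write_fasta``) and one DivergenceHit per copy carrying
    its realized hamming divergence from the ancestor and the copy length.
    """
    from .io_formats import TRConsensus

    rng = np.random.default_rng(model.seed)
    ancestor = random_monomer(model.monomer_len, rng)
    anc = np.frombuffer(ancestor.encode(), dtype="S1")
    monomers: list[TRConsensus] = []
    hits: list[DivergenceHit] = []
    for i in range(model.copies):
        copy = mutate_sequence(ancestor, model.expected_divergence_pct, rng)
        arr = np.frombuffer(copy.encode(), dtype="S1")
        realized = 100.0 * float(np.count_nonzero(arr != anc)) / model.monomer_len
        monomers.append(TRConsensus(name=f"{model.family}_copy{i + 1}", sequence=copy))
        hits.append(
            DivergenceHit(model.family, realized, model.monomer_len, model.library_id)
        )
    return monomers, hits


def simulate_library(
    n_families: int,
    variants_per_family: int | Sequence[int],
    seed: int,
    family_divergence_pct: float = 10.0,
    variant_divergence_pct: float = 2.0,
    members_per_variant: int = 1,
    monomer_len: int = 150,
    scramble_phase: bool = True,
) -> tuple[list, dict[str, tuple[int, int]]]:
    """Consensus library with planted family/subfamily structure.

    Each family descends from an independent random ancestor; its variants
    (subfamilies) diverge pairwise by ~``family_divergence_pct`` and members
    within a variant by ~``variant_divergence_pct``. Emitted members are
    randomly rotated and strand-flipped when ``scramble_phase`` so catalogue
    building must solve the circular-phase problem. Returns TRConsensus
    members plus ground-truth (family, subfamily) labels per name.

    ``variants_per_family`` is an int (same count everywhere), a sequence of
    exactly ``n_families`` counts, or a (lo, hi) pair to draw counts
    uniformly per family.
    """
    from .io_formats import TRConsensus  # local import to avoid cycle at module load

    if not 0 <= variant_divergence_pct < family_divergence_pct:
        raise ValueError("need 0 <= variant divergence < family divergence")
    rng = np.random.default_rng(seed)
    if isinstance(variants_per_family, int):
        n_variants = [variants_per_family] * n_families
    elif len(variants_per_family) == n_families:
        n_variants = [int(v) for v in variants_per_family]
    elif len(variants_per_family) == 2:
        lo, hi = variants_per_family
        n_variants = [int(rng.integers(lo, hi + 1)) for _ in range(n_families)]
    else:
        raise ValueError("variants_per_family: int, per-family sequence, or (lo, hi)")

    members: list[TRConsensus] = []
    truth: dict[str, tuple[int, int]] = {}
    subfamily_id = 0
    for fam in range(1, n_families + 1):
        ancestor = random_monomer(monomer_len, rng)
        for var in range(n_variants[fam - 1]):
            subfamily_id += 1
            # half the pairwise target on each branch from the family ancestor
            variant_consensus = mutate_sequence(
                ancestor, family_divergence_pct / 2.0, rng, exact=True
            )
            for mem in range(members_per_variant):
                seq = mutate_sequence(
                    variant_consensus, variant_divergence_pct / 2.0, rng, exact=True
                )
                if scramble_phase:
                    shift = int(rng.integers(0, monomer_len))
                    seq = seq[shift:] + seq[:shift]
                    if rng.random() < 0.5:
                        seq = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
                name = f"fam{fam:02d}var{var + 1}m{mem + 1}"
                members.append(TRConsensus(name=name, sequence=seq))
                truth[name] = (fam, subfamily_id)
    return members, truth


@dataclass(frozen=True)
class ClineModel:
    """Sigmoid allele-frequency cline over ordered transect sites."""

    center: float
    width: float
    sites: tuple[TransectSite, ...]
    sample_sizes: tuple[int, ...]
    seed: int
    marker: str = "simMarker"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if len(self.sites) != len(self.sample_sizes):
            raise ValueError("one sample size per site required")

    def site_freq(self, order_index: float) -> float:
        from scipy.special import expit  # overflow-safe logistic

        return float(expit((order_index - self.center) / self.width))


def simulate_transect(
    model: ClineModel,
    linkage: str,
    site_freqs: Sequence[float] | None = None,
) -> list[GenotypeTable]:
    """Genotype samples along the transect under the planted cline.

    Autosomal sites draw n males from Hardy-Weinberg proportions at the
    site's banded-allele frequency; X-linked sites draw n hemizygous male
    X chromosomes Bernoulli(q). ``site_freqs`` overrides the model's
    sigmoid with explicit per-site frequencies (e.g. to emulate an
    empirical profile).
    """
    if linkage not in ("autosomal", "x_linked"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if site_freqs is not None and len(site_freqs) != len(model.sites):
        raise ValueError("need one frequency per site")
    rng = np.random.default_rng(model.seed)
    tables: list[GenotypeTable] = []
    for idx, (site, n) in enumerate(zip(model.sites, model.sample_sizes)):
        q = model.site_freq(site.order_index) if site_freqs is None else float(site_freqs[idx])
        p = 1.0 - q
        if linkage == "autosomal":
            nn, nb, bb = rng.multinomial(n, [p * p, 2 * p * q, q * q])
            counts: tuple[int, ...] = (int(nn), int(nb), int(bb))
        else:
            b = int(rng.binomial(n, q))
            counts = (n - b, b)
        tables.append(GenotypeTable(site.population, model.marker, linkage, counts))
    return tables


def default_transect_sites(n_sites: int = 7) -> tuple[TransectSite, ...]:
    """Abstract evenly-ordered sites (order_index 1..n) for simulations."""
    return tuple(
        TransectSite(
            population=f"S{i}",
            country="SIM",
            latitude=0.0,
            longitude=0.0,
            altitude_m=0.0,
            n_males=0,
            order_index=i,
        )
        for i in range(1, n_sites + 1)
    )
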