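"""Composition statistics: optical fat/lean fraction, DXA mass fractions,
and site-to-region aggregation.

The optical fat fraction (OFF) and optical lean fraction (OLF) combine the
three tissue constituents that track subcutaneous adiposity:

    OFF = fat / (THbMb + water + fat)
    OLF = (THbMb + water) / (THbMb + water + fat)

These are deliberately mixed-unit ratios — THbMb in uM (~0-200 in tissue),
water and fat in percent (0-100) — convenient precisely because the three
quantities share a numeric range.  A unit guard rejects inputs that are
clearly not on the (uM, %, %) scale.  OFF + OLF = 100% by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tissue_optics import ChromophoreSet, ScatterParams

__all__ = [
    "SITE_CODES",
    "REGIONS",
    "SITE_TO_REGION",
    "REGION_SITES",
    "SiteMeasurement",
    "RegionSummary",
    "DXARecord",
    "compute_off",
    "compute_olf",
    "dxa_fractions",
    "aggregate_region",
]

#: the 10 anatomical measurement sites
SITE_CODES = ("BS", "BL", "LL", "LR", "UL", "UR", "VL", "RF", "GM", "GL")

REGION_SITES = {
    "biceps": ("BS", "BL"),
    "abdomen": ("LL", "LR", "UL", "UR"),
    "quadriceps": ("VL", "RF"),
    "calf": ("GM", "GL"),
}
REGIONS = tuple(REGION_SITES)
SITE_TO_REGION = {s: r for r, sites in REGION_SITES.items() for s in sites}


class UndefinedMetricError(ValueError):
    """OFF/OLF denominator is zero."""


class UnitGuardError(ValueError):
    """Chromophore values are not on the expected (uM, %, %) scale."""


@dataclass(frozen=True)
class SiteMeasurement:
    """One replicate at one anatomical site."""

    participant_id: str
    site_code: str
    replicate_index: int
    chromophores: ChromophoreSet
    scatter: ScatterParams

    def __post_init__(self) -> None:
        if self.site_code not in SITE_CODES:
            raise ValueError(f"unknown site code: {self.site_code!r}")
        if not 1 <= self.replicate_index <= 3:
            raise ValueError("replicate_index must be 1-3")


@dataclass(frozen=True)
class RegionSummary:
    """Replicate- and site-averaged result for one anatomical region."""

    participant_id: str
    region: str
    chromophores: ChromophoreSet
    scatter: ScatterParams
    off: float
    olf: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region: {self.region!r}")


@dataclass(frozen=True)
class DXARecord:
    """Three-compartment DXA masses for one participant (kg)."""

    participant_id: str
    fat_mass: float
    lst_mass: float
    bone_mass: float

    def __post_init__(self) -> None:
        if min(self.fat_mass, self.lst_mass, self.bone_mass) < 0:
            raise ValueError("masses must be non-negative")
        if self.total_mass <= 0:
            raise ValueError("total mass must be positive")

    @property
    def total_mass(self) -> float:
        return self.fat_mass + self.lst_mass + self.bone_mass

    @property
    def fat_pct(self) -> float:
        return 100.0 * self.fat_mass / self.total_mass

    @property
    def lst_pct(self) -> float:
        return 100.0 * self.lst_mass / self.total_mass

    @property
    def bone_pct(self) -> float:
        return 100.0 * self.bone_mass / self.total_mass


def _unit_guard(c: ChromophoreSet) -> None:
    if not 0.0 <= c.water <= 100.0:
        raise UnitGuardError("water must be a percent volume fraction in [0, 100]")
    if not 0.0 <= c.fat <= 100.0:
        raise UnitGuardError("fat must be a percent volume fraction in [0, 100]")
    if c.thbmb > 1000.0:
        raise UnitGuardError(
            "thbmb looks out of uM scale (> 1000); OFF/OLF require uM inputs"
        )


def compute_off(chromophores: ChromophoreSet, as_fraction: bool = False) -> float:
    """Optical fat fraction: fat / (THbMb + water + fat).

    Returned in percent (0-100) by default; ``as_fraction=True`` yields the
    0-1 rendering.
    """
    _unit_guard(chromophores)
    denom = chromophores.thbmb + chromophores.water + chromophores.fat
    if denom <= 0:
        raise UndefinedMetricError("THbMb + water + fat is zero; OFF undefined")
    off = chromophores.fat / denom
    return off if as_fraction else 100.0 * off


def compute_olf(chromophores: ChromophoreSet, as_fraction: bool = False) -> float:
    """Optical lean fraction: (THbMb + water) / (THbMb + water + fat).

    Complement of OFF: OFF + OLF = 100% for any valid input.
    """
    _unit_guard(chromophores)
    denom = chromophores.thbmb + chromophores.water + chromophores.fat
    if denom <= 0:
        raise UndefinedMetricError("THbMb + water + fat is zero; OLF undefined")
    olf = (chromophores.thbmb + chromophores.water) / denom
    return olf if as_fraction else 100.0 * olf


def dxa_fractions(
    fat_mass: float, lst_mass: float, bone_mass: float
) -> tuple[float, float, float]:
    """(fat%, LST%, bone%) from the three-compartment masses; sums to 100."""
    rec = DXARecord("_", fat_mass, lst_mass, bone_mass)
    return rec.fat_pct, rec.lst_pct, rec.bone_pct


def _mean_chromophores(sets: Sequence[ChromophoreSet]) -> ChromophoreSet:
    v = np.mean([c.as_vector() for c in sets], axis=0)
    return ChromophoreSet(hbmbo2=v[0], hbmbr=v[1], water=v[2], fat=v[3])


def _mean_scatter(params: Sequence[ScatterParams]) -> ScatterParams:
    return ScatterParams(
        a500=float(np.mean([p.a500 for p in params])),
        b_power=float(np.mean([p.b_power for p in params])),
    )


def aggregate_region(
    sites: Iterable[SiteMeasurement],
    region: str,
    mean_of_metrics: bool = False,
) -> RegionSummary:
    """Average replicates per site, then sites across the region.

    OFF/OLF are computed from the region-averaged chromophores by default
    (matching how the cohort analysis averages before correlation); with
    ``mean_of_metrics=True`` the per-site metrics are averaged instead, as a
    sensitivity check.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region: {region!r}")
    sites = list(sites)
    if not sites:
        raise ValueError("need >= 1 site measurement")
    participant_ids = {s.participant_id for s in sites}
    if len(participant_ids) != 1:
        raise ValueError("sites span multiple participants")
    for s in sites:
        if SITE_TO_REGION[s.site_code] != region:
            raise ValueError(
                f"site {s.site_code} belongs to region "
                f"{SITE_TO_REGION[s.site_code]!r}, not {region!r}"
            )

    by_site: dict[str, list[SiteMeasurement]] = {}
    for s in sites:
        by_site.setdefault(s.site_code, []).append(s)

    site_chrom, site_scatter = [], []
    for code, reps in by_site.items():
        site_chrom.append(_mean_chromophores([r.chromophores for r in reps]))
        site_scatter.append(_mean_scatter([r.scatter for r in reps]))
    chrom = _mean_chromophores(site_chrom)
    scatter = _mean_scatter(site_scatter)

    if mean_of_metrics:
        off = float(np.mean([compute_off(c) for c in site_chrom]))
        olf = float(np.mean([compute_olf(c) for c in site_chrom]))
    else:
        off = compute_off(chrom)
        olf = compute_olf(chrom)

    return RegionSummary(
        participant_id=next(iter(participant_ids)),
        region=region,
        chromophores=chrom,
        scatter=scatter,
        off=off,
        olf=olf,
    )
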