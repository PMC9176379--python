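"""Synthetic cohort generator.

Emulates the statistical structure of a two-layer (adipose-over-muscle)
tissue study: each participant's measured optical signal at a site is a
depth-weighted mixture of a *lean* (muscle) and a *fat* (adipose) endmember
composition, with the mixing weight increasing with the skin+adipose tissue
thickness (SATT) as

    w(SATT) = 1 - exp(-SATT / z0),   z0 ~ 0.93 cm

(one third of the 28 mm source-detector separation, the rule-of-thumb optical
penetration depth).  On top of the mixture sit three multiplicative noise
tiers: participant-region "field" variability (biological heterogeneity,
shared by the sites of a region), a small per-site offset, and per-replicate
measurement noise.  Whole-body DXA fat% is planted as an affine function of
the four regional optical fat fractions plus Gaussian residual, so the
downstream regression model is recoverable by construction.

All draws come from a single seeded generator: the same seed reproduces the
cohort tables exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .composition_metrics import (
    REGION_SITES,
    REGIONS,
    SITE_TO_REGION,
    compute_off,
)
from .photon_diffusion import (
    CWSpectrum,
    DEFAULT_FREQUENCIES_MHZ,
    DEFAULT_SEPARATION_MM,
    FDMeasurement,
    cw_forward,
    fd_forward,
)
from .tissue_optics import (
    ChromophoreSet,
    ExtinctionLibrary,
    ScatterParams,
    compose_mua,
    default_extinction_library,
)

__all__ = [
    "LEAN_ENDMEMBER",
    "FAT_ENDMEMBER",
    "DEFAULT_PENETRATION_DEPTH_CM",
    "EndmemberPair",
    "NoiseConfig",
    "InstrumentConfig",
    "SyntheticCohort",
    "mixing_weight",
    "mix_endmembers",
    "generate_cohort",
    "generate_measurements",
    "quadriceps_screen_table",
]

#: in-vivo lean (muscle) endmember: thin-SATT reference composition
LEAN_ENDMEMBER = (
    ChromophoreSet.from_summary(thbmb=125.2, sto2=67.1, water=73.0, fat=1.1),
    ScatterParams.from_reported(a500=0.87, b=-1.28),
)

#: in-vivo fat (adipose) endmember: thick-SATT reference composition
FAT_ENDMEMBER = (
    ChromophoreSet.from_summary(thbmb=19.4, sto2=63.0, water=11.3, fat=67.3),
    ScatterParams.from_reported(a500=0.85, b=-0.42),
)

#: ~1/3 of the 28 mm source-detector separation, in cm
DEFAULT_PENETRATION_DEPTH_CM = 0.93

#: SATT distribution observed in the quadriceps (cm): log-normal spanning
#: roughly 0.2-1.6 cm
_SATT_LOG_MEAN = np.log(0.62)
_SATT_LOG_SD = 0.42
_SATT_RANGE_CM = (0.2, 1.6)

#: region thickness factors relative to the quadriceps
_REGION_SATT_FACTOR = {"biceps": 0.7, "abdomen": 1.5, "quadriceps": 1.0, "calf": 0.8}

#: planted whole-body model: fat% = intercept + sum coef[region] * OFF[region]
_DXA_INTERCEPT = 6.0
_DXA_COEFFS = {"biceps": 0.08, "abdomen": 0.16, "quadriceps": 0.10, "calf": 0.06}

_MIX_PARAMS = ("thbmb", "sto2", "water", "fat", "a500", "b_power")


@dataclass(frozen=True)
class EndmemberPair:
    """Lean (muscle) and fat (adipose) endmember compositions."""

    lean: tuple[ChromophoreSet, ScatterParams] = LEAN_ENDMEMBER
    fat: tuple[ChromophoreSet, ScatterParams] = FAT_ENDMEMBER

    def __post_init__(self) -> None:
        lean_c, fat_c = self.lean[0], self.fat[0]
        if not lean_c.fat < fat_c.fat:
            raise ValueError("lean endmember must have lower fat than the fat endmember")
        if not lean_c.thbmb > fat_c.thbmb:
            raise ValueError("lean endmember must have higher THbMb")


@dataclass(frozen=True)
class NoiseConfig:
    """Multiplicative (log-normal) noise magnitudes, as coefficients of variation.

    ``field_cv`` is per participant-region biological variability; defaults
    chosen so a cohort screen reproduces the qualitative correlation pattern
    of real quadriceps data (chromophores strongly SATT-coupled, scattering
    power weakly, amplitude not at all).  ``dxa_residual_sd`` is the Gaussian
    residual (percent fat) around the planted whole-body model.
    """

    field_cv: Mapping[str, float] = field(
        default_factory=lambda: {
            "thbmb": 0.10,
            "sto2": 0.05,
            "water": 0.10,
            "fat": 0.10,
            "a500": 0.10,
            "b_power": 0.30,
        }
    )
    site_cv: float = 0.03
    replicate_cv: float = 0.03
    satt_site_cv: float = 0.08
    dxa_residual_sd: float = 3.0

    def __post_init__(self) -> None:
        for k in _MIX_PARAMS:
            if k not in self.field_cv:
                raise ValueError(f"field_cv missing parameter {k!r}")
            if self.field_cv[k] < 0:
                raise ValueError(f"field_cv[{k!r}] must be >= 0")
        for name in ("site_cv", "replicate_cv", "satt_site_cv", "dxa_residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(
            field_cv={k: 0.0 for k in _MIX_PARAMS},
            site_cv=0.0, replicate_cv=0.0, satt_site_cv=0.0, dxa_residual_sd=0.0,
        )


@dataclass(frozen=True)
class InstrumentConfig:
    """Synthetic-instrument geometry and measurement noise."""

    separation_mm: float = DEFAULT_SEPARATION_MM
    frequencies_mhz: tuple = DEFAULT_FREQUENCIES_MHZ
    wavelengths_nm: tuple = (690.0, 785.0, 835.0)
    grid_step_nm: float = 1.0
    amplitude_noise_cv: float = 0.0
    phase_noise_deg: float = 0.0
    throughput: float = 1.0

    def __post_init__(self) -> None:
        if self.separation_mm <= 0 or self.grid_step_nm <= 0 or self.throughput <= 0:
            raise ValueError("separation, grid step and throughput must be positive")
        if self.amplitude_noise_cv < 0 or self.phase_noise_deg < 0:
            raise ValueError("noise magnitudes must be >= 0")

    @property
    def noiseless(self) -> bool:
        return self.amplitude_noise_cv == 0 and self.phase_noise_deg == 0


@dataclass
class SyntheticCohort:
    """Generated cohort tables.

    ``sites``: one row per (participant, site, replicate) with chromophore and
    scattering columns.  ``satt``: ultrasound-style SATT records at the two
    quadriceps sites.  ``dxa``: per-participant DXA masses and fractions.
    ``participants``: ground truth (per-region SATT, mixing weight, true OFF)
    plus demographic dressing.
    """

    sites: pd.DataFrame
    satt: pd.DataFrame
    dxa: pd.DataFrame
    participants: pd.DataFrame
    seed: int


def mixing_weight(satt_cm, z0: float = DEFAULT_PENETRATION_DEPTH_CM):
    """Adipose signal fraction w = 1 - exp(-SATT/z0), both in cm.

    0 at SATT = 0 (pure muscle signal), -> 1 for SATT far beyond the
    penetration depth ``z0``.
    """
    satt_cm = np.asarray(satt_cm, float)
    if np.any(satt_cm < 0):
        raise ValueError("satt must be >= 0")
    if z0 <= 0:
        raise ValueError("z0 must be positive")
    w = 1.0 - np.exp(-satt_cm / z0)
    return float(w) if w.ndim == 0 else w


def _mix(endmembers: EndmemberPair, w: float) -> dict[str, float]:
    """Linear mixture of endmember parameters at adipose weight ``w``.

    Heme is mixed at the (hbmbo2, hbmbr) level, which makes StO2 the
    THbMb-weighted average of the endmember saturations.
    """
    lean_c, lean_s = endmembers.lean
    fat_c, fat_s = endmembers.fat
    hbmbo2 = w * fat_c.hbmbo2 + (1 - w) * lean_c.hbmbo2
    hbmbr = w * fat_c.hbmbr + (1 - w) * lean_c.hbmbr
    thbmb = hbmbo2 + hbmbr
    return {
        "thbmb": thbmb,
        "sto2": 100.0 * hbmbo2 / thbmb,
        "water": w * fat_c.water + (1 - w) * lean_c.water,
        "fat": w * fat_c.fat + (1 - w) * lean_c.fat,
        "a500": w * fat_s.a500 + (1 - w) * lean_s.a500,
        "b_power": w * fat_s.b_power + (1 - w) * lean_s.b_power,
    }


def _chromophores_from_params(p: Mapping[str, float]) -> ChromophoreSet:
    sto2 = min(p["sto2"], 100.0)
    return ChromophoreSet.from_summary(
        thbmb=max(p["thbmb"], 0.0),
        sto2=max(sto2, 0.0),
        water=float(np.clip(p["water"], 0.0, 100.0)),
        fat=float(np.clip(p["fat"], 0.0, 100.0)),
    )


def mix_endmembers(
    endmembers: EndmemberPair, w: float
) -> tuple[ChromophoreSet, ScatterParams]:
    """Noiseless endmember mixture at adipose weight ``w`` in [0, 1]."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    p = _mix(endmembers, w)
    return _chromophores_from_params(p), ScatterParams(
        a500=p["a500"], b_power=p["b_power"]
    )


def _lognormal_factor(rng, cv: float, size=None):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(rng.normal(0.0, cv, size=size))


def generate_cohort(
    n: int,
    seed: int,
    endmembers: EndmemberPair | None = None,
    noise: NoiseConfig | None = None,
    satt_mode: str = "mixing",
    satt_coeffs: tuple[float, float] = (0.2856, 2.214),
) -> SyntheticCohort:
    """Generate a fully synthetic n-participant cohort.

    ``satt_mode="mixing"`` (default): quadriceps SATT is drawn log-normally
    over ~0.2-1.6 cm and drives the endmember mixing weight at every site.
    ``satt_mode="exponential"``: the recorded quadriceps SATT is instead
    computed from the participant's true regional OFF through
    ``satt = a * exp(b * OFF)`` with ``satt_coeffs``, planting the exponential
    OFF-SATT relationship exactly (useful for fit-recovery checks).
    """
    if n < 2:
        raise ValueError("need n >= 2 participants")
    if satt_mode not in ("mixing", "exponential"):
        raise ValueError("satt_mode must be 'mixing' or 'exponential'")
    endmembers = endmembers or EndmemberPair()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)

    site_rows, satt_rows, dxa_rows, part_rows = [], [], [], []
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        age = float(rng.uniform(7.0, 34.0))
        sex = "F" if rng.random() < 0.5 else "M"

        quad_satt = float(
            np.clip(
                np.exp(rng.normal(_SATT_LOG_MEAN, _SATT_LOG_SD)), *_SATT_RANGE_CM
            )
        )
        region_satt = {
            r: float(np.clip(quad_satt * f * _lognormal_factor(rng, 0.10), 0.05, 3.0))
            for r, f in _REGION_SATT_FACTOR.items()
        }
        region_satt["quadriceps"] = quad_satt

        # per-region biological field noise, shared by the region's sites
        field_factors = {
            r: {k: float(_lognormal_factor(rng, noise.field_cv[k])) for k in _MIX_PARAMS}
            for r in REGIONS
        }

        region_off_true: dict[str, float] = {}
        part_sites: dict[str, dict] = {}
        for region, codes in REGION_SITES.items():
            ff = field_factors[region]
            site_params_accum = []
            for code in codes:
                site_satt = float(
                    np.clip(
                        region_satt[region] * _lognormal_factor(rng, noise.satt_site_cv),
                        0.02, 4.0,
                    )
                )
                w = mixing_weight(site_satt)
                base = _mix(endmembers, w)
                site_f = {
                    k: float(_lognormal_factor(rng, noise.site_cv)) for k in _MIX_PARAMS
                }
                site_params = {k: base[k] * ff[k] * site_f[k] for k in _MIX_PARAMS}
                site_params_accum.append(site_params)
                part_sites[code] = {"satt": site_satt, "w": w}
                if code in ("VL", "RF"):
                    satt_rows.append(
                        {
                            "participant_id": pid, "site_code": code,
                            "region": region, "satt_cm": site_satt,
                        }
                    )
                for rep in (1, 2, 3):
                    rep_f = {
                        k: float(_lognormal_factor(rng, noise.replicate_cv))
                        for k in _MIX_PARAMS
                    }
                    p = {k: site_params[k] * rep_f[k] for k in _MIX_PARAMS}
                    chrom = _chromophores_from_params(p)
                    scat = ScatterParams(a500=p["a500"], b_power=p["b_power"])
                    site_rows.append(
                        {
                            "participant_id": pid, "site_code": code,
                            "region": region, "replicate_index": rep,
                            "hbmbo2": chrom.hbmbo2, "hbmbr": chrom.hbmbr,
                            "thbmb": chrom.thbmb, "sto2": chrom.sto2,
                            "water": chrom.water, "fat": chrom.fat,
                            "a500": scat.a500, "b_power": scat.b_power,
                            "mus800": scat.mus800,
                        }
                    )
            # regional ground truth: mean of the site-level (field-noised) params
            mean_params = {
                k: float(np.mean([sp[k] for sp in site_params_accum]))
                for k in _MIX_PARAMS
            }
            region_off_true[region] = compute_off(_chromophores_from_params(mean_params))

        if satt_mode == "exponential":
            a, b = satt_coeffs
            quad_satt = float(a * np.exp(b * region_off_true["quadriceps"] / 100.0))
            region_satt["quadriceps"] = quad_satt
            for row in satt_rows:
                if row["participant_id"] == pid:
                    row["satt_cm"] = quad_satt

        fat_pct = _DXA_INTERCEPT + sum(
            _DXA_COEFFS[r] * region_off_true[r] for r in REGIONS
        )
        fat_pct += float(rng.normal(0.0, noise.dxa_residual_sd))
        fat_pct = float(np.clip(fat_pct, 3.0, 60.0))
        bone_pct = float(np.clip(rng.normal(5.0, 0.4), 3.5, 6.5))
        lst_pct = 100.0 - fat_pct - bone_pct
        total_mass = float(np.exp(rng.normal(np.log(50.0), 0.25)))
        dxa_rows.append(
            {
                "participant_id": pid,
                "fat_mass": fat_pct / 100.0 * total_mass,
                "lst_mass": lst_pct / 100.0 * total_mass,
                "bone_mass": bone_pct / 100.0 * total_mass,
                "fat_pct": fat_pct, "lst_pct": lst_pct, "bone_pct": bone_pct,
                "total_mass": total_mass,
            }
        )
        part_rows.append(
            {
                "participant_id": pid, "age": age, "sex": sex,
                **{f"satt_{r}": region_satt[r] for r in REGIONS},
                **{f"off_true_{r}": region_off_true[r] for r in REGIONS},
                "w_quadriceps": mixing_weight(quad_satt),
            }
        )

    return SyntheticCohort(
        sites=pd.DataFrame(site_rows),
        satt=pd.DataFrame(satt_rows),
        dxa=pd.DataFrame(dxa_rows),
        participants=pd.DataFrame(part_rows),
        seed=seed,
    )


def quadriceps_screen_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-participant screening table: quadriceps-averaged optical parameters
    plus the (VL/RF mean) ultrasound SATT, one row per participant."""
    quad = cohort.sites[cohort.sites["region"] == "quadriceps"]
    params = quad.groupby("participant_id")[
        ["thbmb", "sto2", "water", "fat", "a500", "b_power", "mus800"]
    ].mean()
    satt = cohort.satt.groupby("participant_id")["satt_cm"].mean()
    return params.join(satt).reset_index()


def generate_measurements(
    chromophores: ChromophoreSet,
    scatter: ScatterParams,
    instrument: InstrumentConfig | None = None,
    lib: ExtinctionLibrary | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FDMeasurement, CWSpectrum]:
    """Forward-model one site's FD + broadband CW measurement.

    Absorption is composed from the chromophores, reduced scattering from the
    power law; the FD measurement is taken at the laser-diode wavelengths and
    the CW reflectance on the broadband grid, with optional multiplicative
    amplitude noise and additive phase noise.
    """
    instrument = instrument or InstrumentConfig()
    lib = lib or default_extinction_library()
    rng = rng or np.random.default_rng(0)

    lams = np.asarray(instrument.wavelengths_nm, float)
    mua_fd = compose_mua(chromophores, lib, lams)
    mus_fd = scatter.mus_prime(lams)
    amp = np.empty((lams.size, len(instrument.frequencies_mhz)))
    phase = np.empty_like(amp)
    for i in range(lams.size):
        a, p, _ = fd_forward(
            mua_fd[i], mus_fd[i], instrument.separation_mm, instrument.frequencies_mhz
        )
        amp[i], phase[i] = a, p
    amp = amp * instrument.throughput
    if instrument.amplitude_noise_cv > 0:
        amp = amp * np.exp(
            rng.normal(0.0, instrument.amplitude_noise_cv, size=amp.shape)
        )
    if instrument.phase_noise_deg > 0:
        phase = phase + rng.normal(
            0.0, np.deg2rad(instrument.phase_noise_deg), size=phase.shape
        )
    fd = FDMeasurement(
        wavelengths_nm=lams,
        frequencies_mhz=np.asarray(instrument.frequencies_mhz, float),
        amplitude=amp, phase=phase,
        separation_mm=instrument.separation_mm,
        noiseless=instrument.noiseless,
    )

    grid = np.arange(
        lib.wavelength_nm[0], lib.wavelength_nm[-1] + 1e-9, instrument.grid_step_nm
    )
    mua_grid = compose_mua(chromophores, lib, grid)
    mus_grid = scatter.mus_prime(grid)
    refl = cw_forward(mua_grid, mus_grid, instrument.separation_mm)
    refl = refl * instrument.throughput
    if instrument.amplitude_noise_cv > 0:
        refl = refl * np.exp(
            rng.normal(0.0, instrument.amplitude_noise_cv, size=refl.shape)
        )
    cw = CWSpectrum(
        wavelength_nm=grid, reflectance=refl,
        separation_mm=instrument.separation_mm,
        noiseless=instrument.noiseless,
    )
    return fd, cw
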