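"""Chromophore basis spectra, absorption composition/decomposition, and the
reduced-scattering power law.

Tissue near-infrared absorption is modelled as a linear mixture of four
chromophores: oxygenated hemo+myoglobin (HbMbO2), de-oxygenated hemo+myoglobin
(HbMbR), water, and fat (lipid).  Reduced scattering follows the Mie-slope
power law

    mus'(lambda) = A500 * (lambda / 500 nm)**(-b)

with amplitude ``A500`` (mm^-1, the value at 500 nm) and scattering power
``b`` (positive for normal tissue, i.e. scattering decreases with wavelength).

Units used throughout the package:

* wavelength: nm
* absorption and reduced scattering: mm^-1
* heme concentrations: uM; water and fat: percent volume fraction (0-100)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import nnls

__all__ = [
    "CHROMOPHORES",
    "WAVELENGTH_MIN_NM",
    "WAVELENGTH_MAX_NM",
    "ExtinctionLibrary",
    "ChromophoreSet",
    "ScatterParams",
    "OpticalProperties",
    "default_extinction_library",
    "compose_mua",
    "decompose_mua",
    "powerlaw_mus",
    "fit_powerlaw",
]

CHROMOPHORES = ("hbmbo2", "hbmbr", "water", "fat")

WAVELENGTH_MIN_NM = 650.0
WAVELENGTH_MAX_NM = 1000.0

#: molar extinction (cm^-1 / M, natural-log basis applied below) -> mm^-1 per uM
_MOLAR_TO_PER_UM_MM = 2.303e-7


class WavelengthRangeError(ValueError):
    """Requested wavelength outside the supported 650-1000 nm band."""


class UnderdeterminedError(ValueError):
    """Fewer wavelengths than chromophores in a spectral decomposition."""


# ---------------------------------------------------------------------------
# Extinction library
# ---------------------------------------------------------------------------

# Synthetic compilation of NIR chromophore spectra: smooth (PCHIP) curves
# through anchor points approximating the published shapes of oxy/deoxy
# hemoglobin molar extinction, pure-water and pure-lipid absorption.  Not a
# verbatim copy of any single literature table; it reproduces the qualitative
# features the analysis relies on (oxy/deoxy isosbestic crossing near 800 nm,
# lipid peak near 930 nm, water peak near 970 nm, non-negativity).

_HBO2_ANCHORS = (  # (nm, molar extinction cm^-1/M)
    (650, 368), (660, 320), (680, 290), (690, 276), (700, 290), (720, 350),
    (740, 446), (760, 586), (780, 710), (800, 816), (820, 916), (840, 1022),
    (860, 1092), (880, 1154), (900, 1198), (920, 1234), (940, 1214),
    (960, 1204), (980, 1184), (1000, 1190),
)

_HBR_ANCHORS = (
    (650, 3750), (660, 3227), (680, 2407), (690, 2052), (700, 1794),
    (720, 1464), (740, 1180), (750, 1405), (760, 1548), (770, 1311),
    (780, 1136), (800, 762), (820, 693), (840, 694), (860, 726), (880, 761),
    (900, 745), (920, 700), (940, 655), (960, 610), (980, 570), (1000, 534),
)

_WATER_ANCHORS = (  # (nm, pure-water mua in mm^-1)
    (650, 3.2e-4), (700, 6.0e-4), (730, 1.9e-3), (750, 2.6e-3),
    (760, 2.7e-3), (780, 2.3e-3), (800, 2.2e-3), (820, 2.8e-3),
    (840, 3.6e-3), (860, 4.7e-3), (880, 5.6e-3), (900, 6.8e-3),
    (920, 1.1e-2), (940, 2.7e-2), (960, 4.0e-2), (970, 4.5e-2),
    (980, 4.3e-2), (1000, 3.6e-2),
)

_FAT_ANCHORS = (  # (nm, pure-lipid mua in mm^-1)
    (650, 5.5e-4), (700, 6.5e-4), (750, 7.5e-4), (800, 9.0e-4),
    (850, 1.3e-3), (880, 2.2e-3), (900, 4.2e-3), (915, 7.3e-3),
    (925, 1.00e-2), (930, 1.07e-2), (940, 9.0e-3), (950, 5.4e-3),
    (960, 4.2e-3), (970, 3.9e-3), (980, 4.0e-3), (1000, 4.8e-3),
)


@dataclass(frozen=True)
class ExtinctionLibrary:
    """Specific absorption of the four NIR chromophores on a common grid.

    ``specific_absorption`` maps chromophore name to a spectrum in mm^-1 per
    unit concentration: per uM for the heme species, per 100% volume fraction
    (i.e. the pure-substance absorption coefficient) for water and fat.
    """

    wavelength_nm: np.ndarray
    specific_absorption: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        grid = np.asarray(self.wavelength_nm, dtype=float)
        object.__setattr__(self, "wavelength_nm", grid)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly ascending")
        spectra = {}
        for name in CHROMOPHORES:
            if name not in self.specific_absorption:
                raise ValueError(f"missing chromophore spectrum: {name}")
            spec = np.asarray(self.specific_absorption[name], dtype=float)
            if spec.shape != grid.shape:
                raise ValueError(f"{name} spectrum does not share the wavelength grid")
            if np.any(spec < 0):
                raise ValueError(f"{name} spectrum has negative values")
            spectra[name] = spec
        object.__setattr__(self, "specific_absorption", spectra)

    def interp(self, grid: Sequence[float]) -> "ExtinctionLibrary":
        """Resample onto ``grid`` (which must lie inside the library band)."""
        grid = _check_grid_in_band(grid, self.wavelength_nm)
        spectra = {
            name: np.interp(grid, self.wavelength_nm, spec)
            for name, spec in self.specific_absorption.items()
        }
        return ExtinctionLibrary(grid, spectra)

    def basis_matrix(self, grid: Sequence[float]) -> np.ndarray:
        """(n_wavelengths, 4) design matrix in package units.

        Columns follow :data:`CHROMOPHORES`; water/fat columns are divided by
        100 so concentrations multiply in percent.
        """
        lib = self.interp(grid)
        cols = []
        for name in CHROMOPHORES:
            col = lib.specific_absorption[name]
            if name in ("water", "fat"):
                col = col / 100.0
            cols.append(col)
        return np.column_stack(cols)

    # -- plain-text exchange format -------------------------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "wavelength_nm": self.wavelength_nm,
                "eps_hbmbo2": self.specific_absorption["hbmbo2"],
                "eps_hbmbr": self.specific_absorption["hbmbr"],
                "mua_water": self.specific_absorption["water"],
                "mua_fat": self.specific_absorption["fat"],
            }
        )
        with open(path, "w") as fh:
            fh.write(
                "# dosicomp extinction library; eps_* in mm^-1/uM, "
                "mua_* pure-substance mm^-1 (per 100%)\n"
            )
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExtinctionLibrary":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        return cls(
            df["wavelength_nm"].to_numpy(),
            {
                "hbmbo2": df["eps_hbmbo2"].to_numpy(),
                "hbmbr": df["eps_hbmbr"].to_numpy(),
                "water": df["mua_water"].to_numpy(),
                "fat": df["mua_fat"].to_numpy(),
            },
        )


@lru_cache(maxsize=1)
def default_extinction_library() -> ExtinctionLibrary:
    """Built-in synthetic chromophore library on a 650-1000 nm, 1 nm grid."""
    grid = np.arange(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM + 1.0, 1.0)

    def _curve(anchors, scale=1.0):
        lam, val = zip(*anchors)
        return np.clip(PchipInterpolator(lam, val)(grid) * scale, 0.0, None)

    return ExtinctionLibrary(
        grid,
        {
            "hbmbo2": _curve(_HBO2_ANCHORS, _MOLAR_TO_PER_UM_MM),
            "hbmbr": _curve(_HBR_ANCHORS, _MOLAR_TO_PER_UM_MM),
            "water": _curve(_WATER_ANCHORS),
            "fat": _curve(_FAT_ANCHORS),
        },
    )


def _check_grid_in_band(grid, band) -> np.ndarray:
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.any(grid < band[0]) or np.any(grid > band[-1]):
        raise WavelengthRangeError(
            f"wavelength(s) outside library band [{band[0]:g}, {band[-1]:g}] nm"
        )
    return grid


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromophoreSet:
    """Tissue chromophore concentrations.

    ``hbmbo2``/``hbmbr`` in uM; ``water``/``fat`` in percent volume fraction.
    ``thbmb`` and ``sto2`` are derived; ``sto2`` is None when THbMb is zero.
    """

    hbmbo2: float
    hbmbr: float
    water: float
    fat: float

    def __post_init__(self) -> None:
        for name in ("hbmbo2", "hbmbr", "water", "fat"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration: {name}")

    @property
    def thbmb(self) -> float:
        return self.hbmbo2 + self.hbmbr

    @property
    def sto2(self) -> float | None:
        t = self.thbmb
        return 100.0 * self.hbmbo2 / t if t > 0 else None

    @classmethod
    def from_summary(
        cls, thbmb: float, sto2: float, water: float, fat: float
    ) -> "ChromophoreSet":
        """Build from the reported (THbMb, StO2, water, fat) parameterisation."""
        if not 0.0 <= sto2 <= 100.0:
            raise ValueError("sto2 must be in [0, 100] percent")
        return cls(
            hbmbo2=thbmb * sto2 / 100.0,
            hbmbr=thbmb * (100.0 - sto2) / 100.0,
            water=water,
            fat=fat,
        )

    def as_vector(self) -> np.ndarray:
        return np.array([self.hbmbo2, self.hbmbr, self.water, self.fat])


@dataclass(frozen=True)
class ScatterParams:
    """Reduced-scattering power-law parameters.

    ``b_power`` is stored positive for normal tissue so that mus' decreases
    with wavelength.  Reported values using the opposite sign convention
    (negative scattering powers) are negated on ingest via
    :meth:`from_reported` with ``negative_convention=True``.
    """

    a500: float
    b_power: float

    def __post_init__(self) -> None:
        if self.a500 <= 0:
            raise ValueError("a500 must be positive")

    @property
    def mus800(self) -> float:
        return self.a500 * (800.0 / 500.0) ** (-self.b_power)

    @classmethod
    def from_reported(
        cls, a500: float, b: float, negative_convention: bool = True
    ) -> "ScatterParams":
        return cls(a500=a500, b_power=-b if negative_convention else b)

    def mus_prime(self, grid: Sequence[float]) -> np.ndarray:
        return powerlaw_mus(self, grid)


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering on a wavelength grid (mm^-1)."""

    wavelength_nm: np.ndarray
    mua: np.ndarray
    mus_prime: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.wavelength_nm, dtype=float)
        mua = np.asarray(self.mua, dtype=float)
        mus = np.asarray(self.mus_prime, dtype=float)
        if not (grid.shape == mua.shape == mus.shape):
            raise ValueError("grid, mua and mus_prime must share a shape")
        object.__setattr__(self, "wavelength_nm", grid)
        object.__setattr__(self, "mua", mua)
        object.__setattr__(self, "mus_prime", mus)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compose_mua(
    chromophores: ChromophoreSet,
    lib: ExtinctionLibrary | None = None,
    grid: Sequence[float] | None = None,
) -> np.ndarray:
    """Forward absorption model: mua(lambda) = sum_i eps_i(lambda) * c_i.

    Linear in every concentration.  Heme terms contribute eps [mm^-1/uM] * C
    [uM]; water and fat contribute their pure-substance absorption scaled by
    the percent volume fraction.
    """
    lib = lib or default_extinction_library()
    grid = lib.wavelength_nm if grid is None else grid
    basis = lib.basis_matrix(grid)
    return basis @ chromophores.as_vector()


def decompose_mua(
    mua: Sequence[float],
    lib: ExtinctionLibrary | None = None,
    grid: Sequence[float] | None = None,
) -> ChromophoreSet:
    """Spectral unmixing of an absorption spectrum into the four chromophores.

    Non-negative least squares over the basis spectra; round-trips
    :func:`compose_mua` to solver tolerance on noiseless input.  An all-zero
    spectrum yields an all-zero ChromophoreSet.
    """
    lib = lib or default_extinction_library()
    grid = lib.wavelength_nm if grid is None else np.asarray(grid, dtype=float)
    mua = np.asarray(mua, dtype=float)
    if mua.shape != np.shape(grid):
        raise ValueError("mua and grid must share a shape")
    if mua.size < len(CHROMOPHORES):
        raise UnderdeterminedError(
            f"need >= {len(CHROMOPHORES)} wavelengths, got {mua.size}"
        )
    basis = lib.basis_matrix(grid)
    # column scaling equilibrates the heme (1e-4) vs water/fat (1e-5..1e-3)
    # magnitudes for the active-set solver
    scale = np.linalg.norm(basis, axis=0)
    scale[scale == 0] = 1.0
    sol, _ = nnls(basis / scale, mua)
    c = sol / scale
    return ChromophoreSet(hbmbo2=c[0], hbmbr=c[1], water=c[2], fat=c[3])


def powerlaw_mus(params: ScatterParams, grid: Sequence[float]) -> np.ndarray:
    """Evaluate mus'(lambda) = A500 * (lambda/500)**(-b) on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("wavelengths must be positive")
    return params.a500 * (grid / 500.0) ** (-params.b_power)


def fit_powerlaw(
    wavelengths: Sequence[float], mus_prime: Sequence[float]
) -> ScatterParams:
    """Fit the scattering power law to mus' at >= 2 wavelengths.

    Linear least squares in log-log space; exact on noiseless power-law
    input, an interpolation with exactly two points.
    """
    lam = np.asarray(wavelengths, dtype=float)
    mus = np.asarray(mus_prime, dtype=float)
    if lam.size != mus.size:
        raise ValueError("wavelengths and mus_prime must have equal length")
    if lam.size < 2 or np.unique(lam).size < 2:
        raise ValueError("need >= 2 distinct wavelengths")
    if np.any(mus <= 0) or np.any(lam <= 0):
        raise ValueError("wavelengths and mus_prime must be positive")
    x = np.log(lam / 500.0)
    y = np.log(mus)
    slope, intercept = np.polyfit(x, y, 1)
    return ScatterParams(a500=float(np.exp(intercept)), b_power=float(-slope))
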