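"""Frequency-domain and CW diffuse reflectance for a semi-infinite medium.

The forward model is the standard diffusion-approximation Green's function
for a photon density wave launched at one reduced scattering mean free path
below the surface of a semi-infinite turbid medium, with the extrapolated
boundary condition (image source).  With

    D   = 1 / (3 (mua + mus'))            diffusion coefficient, mm
    k^2 = (mua + i w / c_n) / D           complex wavenumber, w = 2 pi f
    z0  = 1 / (mua + mus')                isotropic source depth
    zb  = 2 D (1 + R_eff) / (1 - R_eff)   extrapolated boundary distance

the fluence at source-detector separation rho is

    phi(rho) = [exp(-k r1)/r1 - exp(-k r2)/r2] / (4 pi D)
    r1 = sqrt(rho^2 + z0^2),  r2 = sqrt(rho^2 + (z0 + 2 zb)^2)

Amplitude is |phi|, phase the (positive) lag -arg(phi), which vanishes in the
DC limit.  The CW model is the same expression at zero modulation frequency.
The inverse problem fits (mua, mus') per wavelength to multi-frequency
amplitude and phase; amplitude is treated as relative (self-normalized) by
default since absolute instrument throughput is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .tissue_optics import (
    ChromophoreSet,
    ExtinctionLibrary,
    OpticalProperties,
    ScatterParams,
    decompose_mua,
    default_extinction_library,
    fit_powerlaw,
)

__all__ = [
    "SPEED_OF_LIGHT_MM_NS",
    "TISSUE_REFRACTIVE_INDEX",
    "DEFAULT_SEPARATION_MM",
    "DEFAULT_FREQUENCIES_MHZ",
    "FDMeasurement",
    "CWSpectrum",
    "fd_forward",
    "fd_invert",
    "cw_forward",
    "broadband_mua",
    "InversionResult",
    "recover_properties",
]

SPEED_OF_LIGHT_MM_NS = 299.792458  # vacuum, mm/ns
TISSUE_REFRACTIVE_INDEX = 1.4
DEFAULT_SEPARATION_MM = 28.0
#: synthetic-instrument modulation frequencies, MHz
DEFAULT_FREQUENCIES_MHZ = tuple(np.arange(50.0, 401.0, 50.0))


def _reff(n: float) -> float:
    # Groenhuis polynomial approximation to the effective internal reflection
    # coefficient for a tissue/air boundary
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


class InversionError(RuntimeError):
    """FD inversion failed to converge; carries the final residual norm."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class FDMeasurement:
    """Multi-frequency amplitude/phase at the laser-diode wavelengths.

    ``amplitude`` and ``phase`` are (n_wavelengths, n_frequencies) arrays;
    amplitude in arbitrary units, phase in radians (lag, positive).
    """

    wavelengths_nm: np.ndarray
    frequencies_mhz: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    separation_mm: float = DEFAULT_SEPARATION_MM
    noiseless: bool = False

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.atleast_1d(np.asarray(self.wavelengths_nm, float))
        self.frequencies_mhz = np.atleast_1d(np.asarray(self.frequencies_mhz, float))
        self.amplitude = np.atleast_2d(np.asarray(self.amplitude, float))
        self.phase = np.atleast_2d(np.asarray(self.phase, float))
        shape = (self.wavelengths_nm.size, self.frequencies_mhz.size)
        if self.amplitude.shape != shape or self.phase.shape != shape:
            raise ValueError("amplitude/phase must be (n_wavelengths, n_frequencies)")
        if np.any(self.amplitude <= 0):
            raise ValueError("amplitude must be positive")

    def at_wavelength(self, wavelength: float) -> tuple[np.ndarray, np.ndarray]:
        idx = np.flatnonzero(np.isclose(self.wavelengths_nm, wavelength))
        if idx.size == 0:
            raise ValueError(f"wavelength {wavelength} nm not in measurement")
        i = int(idx[0])
        return self.amplitude[i], self.phase[i]


@dataclass
class CWSpectrum:
    """Broadband calibrated CW diffuse reflectance (dimensionless)."""

    wavelength_nm: np.ndarray
    reflectance: np.ndarray
    separation_mm: float = DEFAULT_SEPARATION_MM
    noiseless: bool = False

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, float)
        self.reflectance = np.asarray(self.reflectance, float)
        if self.wavelength_nm.shape != self.reflectance.shape:
            raise ValueError("grid and reflectance must share a shape")
        if np.any(self.reflectance <= 0):
            raise ValueError("reflectance must be positive")


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------


def _fluence(mua, mus_prime, separation_mm, omega_rad_ns, n=TISSUE_REFRACTIVE_INDEX):
    """Complex photon-density-wave fluence, vectorised over omega."""
    mua = float(mua)
    mus_prime = float(mus_prime)
    mut = mua + mus_prime
    D = 1.0 / (3.0 * mut)
    c_n = SPEED_OF_LIGHT_MM_NS / n
    k = np.sqrt((mua + 1j * np.asarray(omega_rad_ns) / c_n) / D)
    z0 = 1.0 / mut
    reff = _reff(n)
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    r1 = np.hypot(separation_mm, z0)
    r2 = np.hypot(separation_mm, z0 + 2.0 * zb)
    return (np.exp(-k * r1) / r1 - np.exp(-k * r2) / r2) / (4.0 * np.pi * D)


def fd_forward(
    mua: float,
    mus_prime: float,
    separation_mm: float = DEFAULT_SEPARATION_MM,
    frequencies_mhz: Sequence[float] = DEFAULT_FREQUENCIES_MHZ,
    n: float = TISSUE_REFRACTIVE_INDEX,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Forward FD model; returns (amplitude, phase_rad, diffusion_valid).

    Phase is the positive lag, zero in the DC limit and increasing with
    modulation frequency.  ``diffusion_valid`` is False when mus' < 10 mua
    (diffusion approximation questionable) — a warning flag, not an error.
    """
    if mua <= 0 or mus_prime <= 0:
        raise ValueError("mua and mus_prime must be positive")
    freqs = np.asarray(frequencies_mhz, float)
    if np.any(freqs < 0):
        raise ValueError("frequencies must be non-negative")
    omega = 2.0 * np.pi * freqs * 1e-3  # MHz -> rad/ns
    phi = _fluence(mua, mus_prime, separation_mm, omega, n)
    amplitude = np.abs(phi)
    phase = -np.angle(phi)
    valid = bool(mus_prime >= 10.0 * mua)
    return amplitude, phase, valid


def cw_forward(
    mua,
    mus_prime,
    separation_mm: float = DEFAULT_SEPARATION_MM,
    n: float = TISSUE_REFRACTIVE_INDEX,
) -> np.ndarray:
    """CW reflectance: the FD Green's function at zero modulation frequency."""
    mua = np.atleast_1d(np.asarray(mua, float))
    mus = np.atleast_1d(np.asarray(mus_prime, float))
    if np.any(mua <= 0) or np.any(mus <= 0):
        raise ValueError("mua and mus_prime must be positive")
    out = np.empty(np.broadcast(mua, mus).shape)
    mua_b, mus_b = np.broadcast_arrays(mua, mus)
    for i in np.ndindex(out.shape):
        out[i] = _fluence(mua_b[i], mus_b[i], separation_mm, 0.0, n).real
    return out


# ---------------------------------------------------------------------------
# Inverse models
# ---------------------------------------------------------------------------


def fd_invert(
    meas: FDMeasurement,
    wavelength: float,
    amp_noise: float = 0.01,
    phase_noise_rad: float = np.deg2rad(0.1),
    relative_amplitude: bool = True,
    x0: tuple[float, float] = (0.01, 1.0),
) -> tuple[float, float]:
    """Recover (mua, mus') at one wavelength from multi-frequency data.

    Joint least squares on log-amplitude and phase residuals, each normalized
    by its noise scale.  In relative-amplitude mode (default) the log-amplitude
    residual is mean-centred, making the fit invariant to any constant
    amplitude scale.  Parameters are log-transformed so iterates stay positive.
    """
    amp, phase = meas.at_wavelength(wavelength)
    if meas.frequencies_mhz.size < 2:
        raise ValueError("need >= 2 modulation frequencies")
    log_amp = np.log(amp)

    def residuals(p):
        mua, mus = np.exp(p)
        a_mod, ph_mod, _ = fd_forward(
            mua, mus, meas.separation_mm, meas.frequencies_mhz
        )
        r_amp = np.log(a_mod) - log_amp
        if relative_amplitude:
            r_amp = r_amp - r_amp.mean()
        return np.concatenate([r_amp / amp_noise, (ph_mod - phase) / phase_noise_rad])

    sol = least_squares(
        residuals, np.log(x0), method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    resid = float(np.linalg.norm(sol.fun))
    if not sol.success:
        raise InversionError(f"FD inversion did not converge: {sol.message}", resid)
    mua, mus = np.exp(sol.x)
    return float(mua), float(mus)


def _invert_cw_point(r_target, mus_prime, separation_mm, lo=1e-7, hi=1.0):
    """Solve cw_forward(mua) = r_target for mua; None if unattainable."""

    def f(mua):
        return float(_fluence(mua, mus_prime, separation_mm, 0.0).real) - r_target

    # reflectance decreases monotonically with mua
    if f(lo) < 0 or f(hi) > 0:
        return None
    return brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)


def broadband_mua(
    cw: CWSpectrum,
    scatter: ScatterParams,
    anchors: Sequence[tuple[float, float]],
    smooth_window: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Broadband absorption from CW reflectance, anchored to FD absorption.

    The CW spectrum is known only up to an instrument throughput factor.  The
    scale is chosen so per-wavelength inversion (with mus'(lambda) from the
    scattering power law) reproduces the FD-derived (wavelength, mua) anchors
    in a least-squares sense; each anchor's exact-match scale is computed in
    closed form and combined by geometric mean.  The log-reflectance is first
    smoothed by a short moving average (``smooth_window`` points; the
    physical spectrum is smooth on the nm scale, so this suppresses
    uncorrelated per-point noise with negligible bias).  Returns
    (mua_grid, gap_flags) where flagged wavelengths were unattainable and
    filled by interpolation.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("need >= 1 anchor")
    grid = cw.wavelength_nm
    mus_grid = scatter.mus_prime(grid)
    sep = cw.separation_mm

    reflectance = cw.reflectance
    if smooth_window > 1 and grid.size >= smooth_window:
        from scipy.ndimage import uniform_filter1d

        reflectance = np.exp(
            uniform_filter1d(np.log(reflectance), smooth_window, mode="nearest")
        )

    scales = []
    spacing = float(np.max(np.diff(grid))) if grid.size > 1 else 0.0
    for lam, mua_anchor in anchors:
        idx = int(np.argmin(np.abs(grid - lam)))
        if abs(grid[idx] - lam) > max(spacing / 2.0, 1e-6):
            raise ValueError(f"anchor wavelength {lam} nm not on the CW grid")
        model = float(_fluence(mua_anchor, mus_grid[idx], sep, 0.0).real)
        scales.append(reflectance[idx] / model)
    scale = float(np.exp(np.mean(np.log(scales))))

    mua = np.full(grid.shape, np.nan)
    for i in range(grid.size):
        sol = _invert_cw_point(reflectance[i] / scale, mus_grid[i], sep)
        if sol is not None:
            mua[i] = sol
    gaps = np.isnan(mua)
    if gaps.all():
        raise InversionError("no CW wavelength was invertible", np.nan)
    if gaps.any():
        good = ~gaps
        mua[gaps] = np.interp(grid[gaps], grid[good], mua[good])
    return mua, gaps


# ---------------------------------------------------------------------------
# Full per-site inversion chain
# ---------------------------------------------------------------------------


@dataclass
class InversionResult:
    """Output of the complete per-site inversion."""

    properties: OpticalProperties
    chromophores: ChromophoreSet
    scatter: ScatterParams
    fd_mua: dict  # wavelength -> mua from the FD stage
    fd_mus: dict  # wavelength -> mus' from the FD stage
    gaps: np.ndarray


def recover_properties(
    fd: FDMeasurement,
    cw: CWSpectrum,
    lib: ExtinctionLibrary | None = None,
) -> InversionResult:
    """FD inversion -> scattering power law -> broadband absorption ->
    chromophore decomposition, the full measurement-analysis chain."""
    lib = lib or default_extinction_library()
    fd_mua, fd_mus = {}, {}
    for lam in fd.wavelengths_nm:
        mua, mus = fd_invert(fd, lam)
        fd_mua[float(lam)] = mua
        fd_mus[float(lam)] = mus
    scatter = fit_powerlaw(list(fd_mus), list(fd_mus.values()))
    anchors = [(lam, fd_mua[lam]) for lam in fd_mua]
    mua_grid, gaps = broadband_mua(cw, scatter, anchors)
    props = OpticalProperties(
        wavelength_nm=cw.wavelength_nm,
        mua=mua_grid,
        mus_prime=scatter.mus_prime(cw.wavelength_nm),
    )
    chrom = decompose_mua(mua_grid, lib, cw.wavelength_nm)
    return InversionResult(
        properties=props, chromophores=chrom, scatter=scatter,
        fd_mua=fd_mua, fd_mus=fd_mus, gaps=gaps,
    )
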