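"""Resonance physics of a periodic gold nanohole metasurface and its analyte response.

The chip supports two families of optical modes in the visible/NIR band:

* Surface plasmon polaritons (SPP) at a metal-dielectric interface, whose
  grating-coupled resonance wavelength is
  ``lambda_spp = P / sqrt(i^2 + j^2) * sqrt(eps_d * eps_m / (eps_d + eps_m))``
  for lattice period ``P``, diffraction order ``(i, j)``, dielectric
  permittivity ``eps_d`` and (negative) metal permittivity ``eps_m``.
* Wood-Rayleigh anomalies (WA), the grazing-diffraction condition
  ``lambda_wa = P / sqrt(i^2 + j^2) * sqrt(eps_d)``, which depends only on the
  period and the bulk index and is therefore insensitive to surface binding.

Analyte (small extracellular vesicle, sEV) capture perturbs the modes through
three coupled effects:

* a refractometric wavelength shift ``delta_lambda = S * delta_n`` driven by
  Langmuir monolayer coverage ``theta = K x / (1 + K x)`` mixed into an
  effective surface index ``n = theta * n_sEV + (1 - theta) * n_medium``;
* a Beer-Lambert intensity loss ``A = eps * c * l`` that multiplies the
  resonance dip contrast by ``10**-A``, driven by the cumulative particle load
  (a lower-affinity coverage channel that keeps growing after the monolayer
  saturates);
* resonance loading, modelled as linewidth broadening proportional to coverage.

Spectra are synthesized as inverted Lorentzian dips on a flat baseline; this is
a phenomenological stand-in for full-wave electromagnetic simulation, adequate
for studying readout and classification behaviour but not field distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

DEFAULT_BAND_NM = (500.0, 800.0)
DEFAULT_GRID_STEP_NM = 0.5


class ConvergenceError(RuntimeError):
    """Raised when the dispersive SPP fixed-point iteration fails; carries the last iterate."""

    def __init__(self, message: str, last_iterate: float):
        super().__init__(message)
        self.last_iterate = last_iterate


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChipGeometry:
    """Nanohole array geometry: 500 nm pitch, 200 nm holes, 200 nm depth by default."""

    period_nm: float = 500.0
    hole_diameter_nm: float = 200.0
    depth_nm: float = 200.0

    def __post_init__(self) -> None:
        if min(self.period_nm, self.hole_diameter_nm, self.depth_nm) <= 0:
            raise ValueError("all geometry dimensions must be strictly positive")
        if self.hole_diameter_nm >= self.period_nm:
            raise ValueError("hole diameter must be smaller than the period")


@dataclass(frozen=True)
class DiffractionOrder:
    i: int = 1
    j: int = 0

    def __post_init__(self) -> None:
        if self.i == 0 and self.j == 0:
            raise ValueError("diffraction order (0, 0) is not a propagating order")

    @property
    def magnitude(self) -> float:
        return math.hypot(self.i, self.j)


@dataclass(frozen=True)
class MaterialModel:
    """Optical constants of the sensing stack.

    ``eps_metal`` is either a constant (real part < 0 in the working band) or a
    callable ``wavelength_nm -> permittivity`` for dispersive gold.
    ``eps_dielectric`` defaults to ``n_medium**2``.
    """

    eps_metal: float | complex | Callable[[float], complex] = -16.0
    n_medium: float = 1.33
    n_analyte: float = 1.60
    eps_dielectric: float | None = None

    def __post_init__(self) -> None:
        if self.n_medium <= 0:
            raise ValueError("n_medium must be positive")
        if self.n_analyte < self.n_medium:
            raise ValueError("n_analyte must be >= n_medium")
        if self.eps_d <= 0:
            raise ValueError("eps_dielectric must be positive")
        if not callable(self.eps_metal) and np.real(self.eps_metal) >= 0:
            raise ValueError("metal permittivity must have negative real part")

    @property
    def eps_d(self) -> float:
        return self.eps_dielectric if self.eps_dielectric is not None else self.n_medium**2

    def eps_metal_at(self, wavelength_nm: float) -> complex:
        if callable(self.eps_metal):
            return complex(self.eps_metal(wavelength_nm))
        return complex(self.eps_metal)


@dataclass(frozen=True)
class OpticalMode:
    """One resonance of the chip; four (P1..P4) by default."""

    label: str
    kind: str  # "SPP" | "WA"
    center_wavelength_nm: float
    linewidth_nm: float  # FWHM
    depth: float  # dip amplitude in reflectance units
    bulk_sensitivity_nm_per_RIU: float
    interface: str = "medium"  # "medium" | "substrate"

    def __post_init__(self) -> None:
        if self.kind not in ("SPP", "WA"):
            raise ValueError(f"unknown mode kind {self.kind!r}")
        if self.interface not in ("medium", "substrate"):
            raise ValueError(f"unknown interface {self.interface!r}")
        if not 0 < self.depth <= 1:
            raise ValueError("depth must be in (0, 1]")
        if self.linewidth_nm <= 0:
            raise ValueError("linewidth must be positive")

    @property
    def responds_to_binding(self) -> bool:
        """Only medium-interface SPP modes feel a bound surface layer."""
        return self.kind == "SPP" and self.interface == "medium"


@dataclass(frozen=True)
class BindingState:
    """Langmuir binding of analyte at concentration ``x`` with affinity ``K``.

    Two coverage channels are derived:

    * ``theta`` — monolayer coverage ``Kx/(1+Kx)``; drives the refractometric
      wavelength shift.
    * ``theta_abs`` — cumulative-load coverage with the lower affinity
      ``K * absorbance_affinity_ratio``; drives the Beer-Lambert intensity
      loss, which therefore keeps growing after the monolayer saturates.
    """

    K: float
    x: float
    molar_absorptivity: float = 1.0
    path_length: float = 1.0
    concentration_scale: float = 2.5
    absorbance_affinity_ratio: float = 0.05

    def __post_init__(self) -> None:
        if self.K < 0 or self.x < 0:
            raise ValueError("K and x must be non-negative")
        if min(self.molar_absorptivity, self.path_length, self.concentration_scale) < 0:
            raise ValueError("absorbance factors must be non-negative")
        if self.absorbance_affinity_ratio < 0:
            raise ValueError("absorbance_affinity_ratio must be non-negative")

    @property
    def theta(self) -> float:
        return langmuir_coverage(self.K, self.x)

    @property
    def theta_abs(self) -> float:
        return langmuir_coverage(self.K * self.absorbance_affinity_ratio, self.x)


@dataclass(frozen=True)
class Spectrum:
    """A reflectance spectrum on a strictly ascending wavelength grid."""

    wavelength_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "reflectance", r)
        if wl.ndim != 1 or wl.shape != r.shape:
            raise ValueError("wavelength and reflectance must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(r))):
            raise ValueError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError("reflectance values must lie in [0, 1]")

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, Spectrum):
            return NotImplemented
        return np.array_equal(self.wavelength_nm, other.wavelength_nm) and np.array_equal(
            self.reflectance, other.reflectance
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise plus a random linear baseline tilt; fully seeded."""

    sigma_reflectance: float = 0.015
    baseline_tilt: float = 0.0375
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_reflectance < 0 or self.baseline_tilt < 0:
            raise ValueError("noise amplitudes must be non-negative")


# ---------------------------------------------------------------------------
# resonance conditions
# ---------------------------------------------------------------------------


def wood_anomaly_wavelength(
    geometry: ChipGeometry, order: DiffractionOrder, material: MaterialModel
) -> float:
    """Wood-Rayleigh anomaly wavelength ``P / sqrt(i^2+j^2) * sqrt(eps_d)``."""
    return geometry.period_nm * math.sqrt(material.eps_d) / order.magnitude


def _spp_closed_form(period_nm: float, order_mag: float, eps_d: float, eps_m: complex) -> float:
    ratio = eps_d * eps_m / (eps_d + eps_m)
    return period_nm / order_mag * math.sqrt(np.real(ratio))


def spp_wavelength(
    geometry: ChipGeometry,
    order: DiffractionOrder,
    material: MaterialModel,
    *,
    tol_nm: float = 1e-6,
    max_iter: int = 100,
    damping: float = 0.5,
) -> float:
    """Grating-coupled SPP resonance wavelength.

    With constant metal permittivity the closed form is exact.  With a
    dispersive (callable) permittivity the implicit condition
    ``lambda = f(eps_m(lambda))`` is solved by damped fixed-point iteration
    started from the Wood-anomaly wavelength of the same order.
    """
    eps_d = material.eps_d

    def check_bound(eps_m: complex) -> None:
        re = np.real(eps_m)
        if re >= 0 or abs(re) <= eps_d:
            raise ValueError(
                f"bound-mode condition violated: need Re(eps_metal) < -eps_d, got {re} vs eps_d={eps_d}"
            )

    if not callable(material.eps_metal):
        eps_m = material.eps_metal_at(0.0)
        check_bound(eps_m)
        return _spp_closed_form(geometry.period_nm, order.magnitude, eps_d, eps_m)

    lam = wood_anomaly_wavelength(geometry, order, material)
    for _ in range(max_iter):
        eps_m = material.eps_metal_at(lam)
        check_bound(eps_m)
        target = _spp_closed_form(geometry.period_nm, order.magnitude, eps_d, eps_m)
        new = (1.0 - damping) * lam + damping * target
        if abs(new - lam) < tol_nm:
            return new
        lam = new
    raise ConvergenceError(
        f"SPP fixed point did not converge within {max_iter} iterations (last {lam:.6f} nm)",
        last_iterate=lam,
    )


# ---------------------------------------------------------------------------
# binding response
# ---------------------------------------------------------------------------


def langmuir_coverage(K, x):
    """Langmuir isotherm ``theta = K x / (1 + K x)``; accepts scalars or arrays."""
    K = np.asarray(K, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(K < 0) or np.any(x < 0):
        raise ValueError("K and x must be non-negative")
    theta = K * x / (1.0 + K * x)
    return float(theta) if theta.ndim == 0 else theta


def effective_index(theta, material: MaterialModel):
    """Effective surface index: convex mix of analyte and medium indices."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta must lie in [0, 1]")
    n = theta * material.n_analyte + (1.0 - theta) * material.n_medium
    return float(n) if n.ndim == 0 else n


def refractometric_shift(mode: OpticalMode, delta_n: float) -> float:
    """Wavelength shift ``S * delta_n`` for a surface-binding index change.

    Wood anomalies and substrate-interface modes have no field overlap with the
    bound layer and return zero.
    """
    if not mode.responds_to_binding:
        return 0.0
    return mode.bulk_sensitivity_nm_per_RIU * delta_n


def beer_lambert_fraction(molar_absorptivity: float, concentration: float, path_length: float) -> float:
    """Transmitted fraction ``10**-(eps*c*l)`` of the Beer-Lambert law."""
    if min(molar_absorptivity, concentration, path_length) < 0:
        raise ValueError("Beer-Lambert factors must be non-negative")
    return 10.0 ** (-(molar_absorptivity * concentration * path_length))


def absorbance_attenuation(binding: BindingState) -> float:
    """Multiplicative dip-contrast factor from analyte absorbance in the near field."""
    c = binding.concentration_scale * binding.theta_abs
    return beer_lambert_fraction(binding.molar_absorptivity, c, binding.path_length)


def apply_binding(
    modes: Sequence[OpticalMode],
    binding: BindingState,
    material: MaterialModel,
    *,
    broadening_beta: float = 0.2,
) -> list[OpticalMode]:
    """Perturb the mode set by a binding event.

    Medium-interface SPP modes: center shifted by ``S * (n_eff(theta) -
    n_medium)``, dip depth multiplied by the Beer-Lambert factor, linewidth
    broadened by ``(1 + broadening_beta * theta)``.  Wood anomalies and
    substrate modes are returned unchanged.
    """
    theta = binding.theta
    delta_n = effective_index(theta, material) - material.n_medium
    attenuation = absorbance_attenuation(binding)
    out = []
    for mode in modes:
        if mode.responds_to_binding:
            out.append(
                replace(
                    mode,
                    center_wavelength_nm=mode.center_wavelength_nm
                    + refractometric_shift(mode, delta_n),
                    depth=mode.depth * attenuation,
                    linewidth_nm=mode.linewidth_nm * (1.0 + broadening_beta * theta),
                )
            )
        else:
            out.append(mode)
    return out


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------


def default_wavelength_grid(
    band_nm: tuple[float, float] = DEFAULT_BAND_NM, step_nm: float = DEFAULT_GRID_STEP_NM
) -> np.ndarray:
    lo, hi = band_nm
    n = int(round((hi - lo) / step_nm)) + 1
    return lo + step_nm * np.arange(n)


def default_modes() -> list[OpticalMode]:
    """The four configured modes of the 500 nm-pitch chip in water.

    P1/P4: medium-interface SPPs (P4 the most sensitive), P2: Wood anomaly,
    P3: substrate-interface SPP; P2 and P3 do not respond to surface binding.
    """
    return [
        OpticalMode("P1", "SPP", 580.0, 25.0, 0.30, 24.0, "medium"),
        OpticalMode("P2", "WA", 665.0, 12.0, 0.25, 500.0, "medium"),
        OpticalMode("P3", "SPP", 680.0, 15.0, 0.35, 0.0, "substrate"),
        OpticalMode("P4", "SPP", 728.0, 22.0, 0.40, 40.0, "medium"),
    ]


def synthesize_spectrum(
    modes: Sequence[OpticalMode],
    grid: np.ndarray | None = None,
    baseline_reflectance: float = 0.95,
) -> Spectrum:
    """Baseline minus a sum of Lorentzian dips, clipped to [0, 1]."""
    if grid is None:
        grid = default_wavelength_grid()
    grid = np.asarray(grid, dtype=float)
    if not 0 < baseline_reflectance <= 1:
        raise ValueError("baseline_reflectance must be in (0, 1]")
    labels = [m.label for m in modes]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate mode labels: {labels}")
    r = np.full_like(grid, baseline_reflectance)
    for mode in modes:
        hw = 0.5 * mode.linewidth_nm
        r -= mode.depth * hw**2 / ((grid - mode.center_wavelength_nm) ** 2 + hw**2)
    n_clip = int(np.sum((r < 0) | (r > 1)))
    if n_clip:
        logger.info("clipping %d reflectance samples to [0, 1]", n_clip)
        r = np.clip(r, 0.0, 1.0)
    return Spectrum(grid, r)


def add_noise(spectrum: Spectrum, noise: NoiseModel) -> Spectrum:
    """Seeded Gaussian noise plus a random linear baseline tilt, clipped to [0, 1]."""
    rng = np.random.default_rng(noise.seed)
    wl = spectrum.wavelength_nm
    r = spectrum.reflectance.copy()
    if noise.baseline_tilt > 0:
        drift = rng.uniform(-noise.baseline_tilt, noise.baseline_tilt)
        span = wl[-1] - wl[0]
        r = r + drift * (wl - 0.5 * (wl[0] + wl[-1])) / span
    if noise.sigma_reflectance > 0:
        r = r + rng.normal(0.0, noise.sigma_reflectance, size=r.shape)
    return Spectrum(wl, np.clip(r, 0.0, 1.0))


# ---------------------------------------------------------------------------
# response curves and binding-constant recovery
# ---------------------------------------------------------------------------


def binding_response_curves(
    mode: OpticalMode,
    material: MaterialModel,
    binding_template: BindingState,
    concentrations: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless wavelength-shift and dip-contrast-change curves vs concentration.

    Returns ``(delta_lambda_nm, delta_r_min)`` where the second channel is the
    rise of the minimum reflectance, ``depth * (1 - 10**-A)``.  The shift
    channel saturates with the monolayer while the intensity channel keeps
    growing with the cumulative load, so their normalized responses cross
    exactly once (shift dominant at low concentration, intensity at high).
    """
    concentrations = np.asarray(concentrations, dtype=float)
    shifts = np.empty_like(concentrations)
    drs = np.empty_like(concentrations)
    for idx, x in enumerate(concentrations):
        b = replace(binding_template, x=float(x))
        shifts[idx] = refractometric_shift(
            mode, effective_index(b.theta, material) - material.n_medium
        )
        drs[idx] = mode.depth * (1.0 - absorbance_attenuation(b))
    return shifts, drs


def fit_langmuir_constant(
    concentrations: np.ndarray, shifts_nm: np.ndarray
) -> tuple[float, float]:
    """Recover the Langmuir constant from a shift-vs-concentration curve.

    Fits ``delta_lambda = A_max * K x / (1 + K x)`` by nonlinear least squares;
    returns ``(K, A_max)``.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(shifts_nm, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need matching concentration/shift arrays with >= 3 points")

    def model(x, K, a_max):
        return a_max * K * x / (1.0 + K * x)

    a0 = max(float(np.max(y)), 1e-9)
    half = 0.5 * a0
    above = np.nonzero(y >= half)[0]
    x_half = x[above[0]] if above.size else float(np.median(x))
    k0 = 1.0 / max(x_half, 1e-12)
    popt, _ = curve_fit(model, x, y, p0=(k0, a0), maxfev=20000)
    k_fit, a_fit = float(popt[0]), float(popt[1])
    if k_fit <= 0:
        raise RuntimeError(f"Langmuir fit produced non-physical K={k_fit}")
    return k_fit, a_fit
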