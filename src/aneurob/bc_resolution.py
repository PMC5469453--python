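"""Boundary-condition generators and mesh/timestep sizing arithmetic.

Covers the quantities a solver setup needs around an aneurysm CFD run:

* a periodic internal-carotid flow waveform with adjustable pulsatility
  (the carotid siphon dampens the pulse by roughly 15% before the MCA);
* the pulsatile Womersley velocity profile for that waveform, scaled to a
  target cycle-mean inflow velocity (default 0.27 m/s, matching a mean ICA
  flow of 245 ml/min);
* resistance outlet pressures that distribute flow by Murray's law
  (flow ∝ radius³, p_i = K (Σ_j r_j³ / r_i³) Q_i with K = 10⁹ kg m⁻⁴ s⁻¹);
* boundary-layer sublayer schedules, Courant numbers and the effective
  resolution of higher-order elements.

Physical defaults: blood viscosity μ = 3.45 mPa·s, density ρ = 1056 kg/m³
(1.056 g/cm³), cardiac period T = 0.949 s (63 bpm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import jv

MU_BLOOD = 3.45e-3  # Pa s
RHO_BLOOD = 1056.0  # kg/m^3
CARDIAC_PERIOD = 0.949  # s
MURRAY_K = 1e9  # kg m^-4 s^-1

ML_PER_MIN_TO_M3_PER_S = 1e-6 / 60.0


@dataclass
class FlowWaveform:
    """Periodic flow-rate signal Q(t), ml/min, on a uniform grid over [0, T].

    ``samples`` includes both cycle endpoints (first == last within rounding).
    """

    period: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.samples.size < 3:
            raise ValueError("need at least 3 samples")
        if abs(self.samples[0] - self.samples[-1]) > 1e-9 * max(
                1.0, np.abs(self.samples).max()):
            raise ValueError("waveform must be periodic (first == last sample)")
        if self.mean <= 0:
            raise ValueError("mean flow must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.period, self.samples.size)

    @property
    def mean(self) -> float:
        """Cycle-mean flow rate (trapezoid; endpoint counted once)."""
        return float(np.trapezoid(self.samples, self.times) / self.period)

    @property
    def pulsatility(self) -> float:
        """Peak-to-peak amplitude over the mean (pulsatility index)."""
        return float((self.samples.max() - self.samples.min()) / self.mean)

    def fourier_coefficients(self, n_harmonics: int = 8) -> np.ndarray:
        """Complex coefficients c_k, k = 0..n: Q(t) ≈ c0 + 2ReΣ c_k e^{ikωt}."""
        q = self.samples[:-1]
        c = np.fft.rfft(q) / q.size
        n = min(n_harmonics, c.size - 1)
        return c[: n + 1]


def default_ica_waveform(n_samples: int = 200, mean: float = 245.0,
                         period: float = CARDIAC_PERIOD) -> FlowWaveform:
    """A smooth physiological ICA flow waveform, ml/min.

    Truncated-Fourier stand-in with a sharp systolic peak and diastolic
    decay; mean 245 ml/min and period 0.949 s by default.
    """
    t = np.linspace(0.0, period, n_samples)
    ph = 2 * np.pi * t / period
    shape = (1.0 + 0.45 * np.cos(ph - 0.8) + 0.20 * np.cos(2 * ph - 1.8)
             + 0.08 * np.cos(3 * ph - 2.9) + 0.03 * np.cos(4 * ph - 3.8))
    q = mean * shape / np.trapezoid(shape, t) * period
    q[-1] = q[0]
    return FlowWaveform(period, q)


def dampen_pulsatility(w: FlowWaveform, fraction: float = 0.15) -> FlowWaveform:
    """Shrink oscillation about the mean by ``fraction``; mean preserved.

    Q'(t) = mean + (1 − fraction)(Q(t) − mean).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    m = w.mean
    return replace(w, samples=m + (1.0 - fraction) * (w.samples - m))


@dataclass
class WomersleySpec:
    """Parameters of a pulsatile Womersley inflow profile.

    radius in mm; the profile is scaled so the cycle-mean cross-section
    average velocity equals ``target_mean_velocity`` (m/s).
    """

    radius: float
    waveform: FlowWaveform = field(default_factory=default_ica_waveform)
    mu: float = MU_BLOOD
    rho: float = RHO_BLOOD
    target_mean_velocity: float | None = 0.27
    n_harmonics: int = 8

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity, m²/s."""
        return self.mu / self.rho

    def alpha(self, harmonic: int = 1) -> float:
        """Womersley number R√(kω/ν) of the k-th harmonic."""
        omega = 2 * np.pi / self.waveform.period
        return (self.radius * 1e-3) * np.sqrt(harmonic * omega / self.nu)


def _womersley_shape(alpha: float, eta: np.ndarray) -> np.ndarray:
    """Normalized oscillatory profile φ(η): mean over the disc is 1.

    η = r/R; φ = (1 − J0(Λη)/J0(Λ)) / (1 − 2J1(Λ)/(ΛJ0(Λ))), Λ = i^{3/2} α.
    """
    lam = alpha * np.exp(1j * 3 * np.pi / 4)
    num = 1.0 - jv(0, lam * eta) / jv(0, lam)
    den = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
    return num / den


def womersley_velocity(spec: WomersleySpec, radial_position, t) -> np.ndarray:
    """Axial velocity u(r, t), m/s, of the Womersley solution.

    ``radial_position`` in mm (0 ≤ r ≤ R), ``t`` in s; both may be arrays
    (broadcast against each other). The zeroth harmonic is the Poiseuille
    parabola; each higher harmonic has the Bessel-function profile whose
    cross-section average reproduces that harmonic of the flow waveform, so
    the disc flux reproduces Q(t) up to Fourier truncation.
    """
    r = np.asarray(radial_position, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(r < 0) or np.any(r > spec.radius * (1 + 1e-12)):
        raise ValueError("radial position must lie in [0, R]")
    eta = np.clip(r / spec.radius, 0.0, 1.0)
    area = np.pi * (spec.radius * 1e-3) ** 2  # m^2
    coeffs = spec.waveform.fourier_coefficients(spec.n_harmonics)
    coeffs = coeffs * ML_PER_MIN_TO_M3_PER_S  # m^3/s
    u_mean0 = coeffs[0].real / area  # cycle-mean average velocity, m/s
    scale = 1.0 if spec.target_mean_velocity is None else \
        spec.target_mean_velocity / u_mean0
    omega = 2 * np.pi / spec.waveform.period
    u = 2.0 * u_mean0 * (1.0 - eta ** 2) * np.ones_like(t)
    for k in range(1, len(coeffs)):
        phi = _womersley_shape(spec.alpha(k), eta)
        u = u + 2.0 * np.real((coeffs[k] / area) * phi * np.exp(1j * k * omega * t))
    return scale * u


def womersley_flux(spec: WomersleySpec, t, n_quad: int = 64) -> np.ndarray:
    """Disc flux ∫ u dA, m³/s, by Gauss–Legendre quadrature in r."""
    t = np.asarray(t, dtype=float)
    x, w = np.polynomial.legendre.leggauss(n_quad)
    r = 0.5 * spec.radius * (x + 1.0)  # mm
    wr = 0.5 * spec.radius * w
    u = womersley_velocity(spec, r[:, None], t[None, :])
    r_m, wr_m = r * 1e-3, wr * 1e-3
    return np.sum(u * (2 * np.pi * r_m * wr_m)[:, None], axis=0)


@dataclass
class OutletSpec:
    """A resistance outlet: radius r_i (mm) among sibling outlet radii."""

    radius: float
    sibling_radii: tuple[float, ...]
    k: float = MURRAY_K

    def __post_init__(self) -> None:
        if self.radius <= 0 or any(r <= 0 for r in self.sibling_radii):
            raise ValueError("all radii must be positive")
        if self.k <= 0:
            raise ValueError("K must be positive")

    @property
    def resistance(self) -> float:
        """R_i = K Σ_j r_j³ / r_i³, kg m⁻⁴ s⁻¹ (radii in consistent units)."""
        return self.k * sum(r ** 3 for r in self.sibling_radii) / self.radius ** 3


def murray_outlet_pressure(spec: OutletSpec, flux: float) -> float:
    """Outlet pressure p_i = K (Σ_j r_j³ / r_i³) · flux, Pa (flux in m³/s)."""
    return spec.resistance * flux


def murray_split(outlets: list[OutletSpec], total_flow: float) -> np.ndarray:
    """Flow split of a common junction through resistance outlets.

    Solves the lumped linear system (one junction pressure P, outlet flows
    Q_i with R_i Q_i = P and Σ Q_i = total). With the Murray resistances and
    no branch resistance the solution is Q_i ∝ r_i³.
    """
    if len(outlets) < 2:
        raise ValueError("need at least 2 outlets")
    n = len(outlets)
    # unknowns: Q_1..Q_n, P
    a = np.zeros((n + 1, n + 1))
    b = np.zeros(n + 1)
    for i, o in enumerate(outlets):
        a[i, i] = o.resistance
        a[i, n] = -1.0
    a[n, :n] = 1.0
    b[n] = total_flow
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular outlet network: {exc}") from exc
    return sol[:n]


@dataclass
class MeshResolutionSpec:
    """Mesh sizing rules: target nodal distance h (mm) near the aneurysm,
    coarser parent/far-field factors, and the boundary-layer schedule."""

    h: float
    parent_factor: float = 1.25
    far_factor: float = 2.0
    boundary_layer_fraction: float = 0.3
    n_sublayers: int = 4
    sublayer_ratio: float = 0.6
    order: int = 2

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.parent_factor < 1 or self.far_factor < 1:
            raise ValueError("coarsening factors must be >= 1")
        if not 0 < self.sublayer_ratio < 1:
            raise ValueError("sublayer ratio must be in (0, 1)")


def boundary_layer_schedule(spec: MeshResolutionSpec) -> np.ndarray:
    """Sublayer thicknesses (fractions of h), thickest first.

    A geometric sequence with the given ratio whose n terms sum to the total
    boundary-layer fraction; with the defaults (0.3h total, 4 sublayers,
    ratio 0.6) the thinnest sublayer is ≈ 0.03h.
    """
    r, n = spec.sublayer_ratio, spec.n_sublayers
    first = spec.boundary_layer_fraction * (1 - r) / (1 - r ** n) if r != 1 \
        else spec.boundary_layer_fraction / n
    return first * r ** np.arange(n)


def courant_number(u: float, dt: float, h: float) -> float:
    """CFL number u·Δt/h for velocity u (m/s), step Δt (s), spacing h (mm)."""
    if u < 0 or dt <= 0 or h <= 0:
        raise ValueError("need u >= 0, dt > 0, h > 0")
    return (u * 1e3) * dt / h


def timestep_count(period: float, dt: float) -> int:
    """Number of time steps per cycle of length ``period``."""
    return int(round(period / dt))


def effective_resolution(h: float, order: int = 2) -> float:
    """Effective nodal spacing of order-p elements: h / p.

    Quadratic (P2) velocity elements on an h = 0.13 mm mesh resolve
    velocity at an effective 0.065 mm.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    return h / order


def linear_element_equivalent(n_cells: float, order: int = 2) -> float:
    """Number of linear elements with matching resolution: n · p³.

    Uniform refinement splits each tetrahedron into p³ subtetrahedra, so
    4.0 M quadratic cells correspond to 32 M linear elements.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    return n_cells * order ** 3


def beats_per_minute(period: float) -> float:
    """Heart rate for a cardiac period in seconds (0.949 s ↔ 63 bpm)."""
    if period <= 0:
        raise ValueError("period must be positive")
    return 60.0 / period
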