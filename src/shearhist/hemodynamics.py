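"""Pulsatile inflow and wall-shear boundary-condition computations.

Analytic Womersley velocity / wall-shear solution for a rigid straight tube,
Carreau-Yasuda shear-thinning viscosity, scaling of an inflow waveform to a
target cycle-averaged wall shear, and a stenosis-degree based outflow split.

Unit conventions at the API surface: radii in mm, flow rates in ml/s,
viscosities in Pa*s, density in kg/m^3, shear stress in Pa, time in s.
SI conversion happens internally.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import jv

_MM = 1e-3        # mm -> m
_ML_S = 1e-6      # ml/s -> m^3/s

#: Bessel arguments blow up roughly as exp(alpha/sqrt(2)); cap well below overflow.
MAX_WOMERSLEY_NUMBER = 50.0


@dataclass(frozen=True)
class FluidProperties:
    """Blood rheology parameters.

    ``mu_ref`` is the Newtonian reference viscosity used by the analytic
    formulas (the Womersley solution is only defined for Newtonian flow);
    the Carreau-Yasuda parameters describe the shear-thinning model used to
    document the full CFD setup and for viscosity queries.
    """

    density: float = 1060.0
    mu_ref: float = 0.0035
    cy_mu0: float = 0.022
    cy_muinf: float = 0.0022
    cy_lambda: float = 0.110
    cy_a: float = 0.644
    cy_n: float = 0.392

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.mu_ref <= 0:
            raise ValueError("mu_ref must be positive")
        if self.cy_muinf > self.cy_mu0:
            raise ValueError("cy_muinf must not exceed cy_mu0")
        if self.cy_lambda < 0:
            raise ValueError("cy_lambda must be non-negative")


DEFAULT_FLUID = FluidProperties()


def carreau_yasuda_viscosity(shear_rate, fluid: FluidProperties = DEFAULT_FLUID):
    """Apparent viscosity mu(gamma) in Pa*s for shear rate(s) in 1/s.

    mu = mu_inf + (mu_0 - mu_inf) * [1 + (lambda*gamma)^a]^((n-1)/a)
    """
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear_rate must be non-negative")
    mu = fluid.cy_muinf + (fluid.cy_mu0 - fluid.cy_muinf) * (
        1.0 + (fluid.cy_lambda * g) ** fluid.cy_a
    ) ** ((fluid.cy_n - 1.0) / fluid.cy_a)
    if np.ndim(shear_rate) == 0:
        return float(mu)
    return mu


@dataclass(frozen=True)
class FlowWaveform:
    """A periodic flow-rate waveform: uniform samples (ml/s) over one period.

    The samples are interpreted as values at t_k = k*T/n, k = 0..n-1, and are
    extended periodically.  ``harmonics`` returns the one-sided complex
    Fourier amplitudes; trigonometric interpolation (``evaluate``)
    reproduces the samples exactly at the sample times.
    """

    period: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.period) or self.period <= 0:
            raise ValueError("period must be positive and finite")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 4:
            raise ValueError("samples must be a 1D array with >= 4 entries")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def mean_flow(self) -> float:
        """Cycle-mean flow rate in ml/s."""
        return float(self.samples.mean())

    def harmonics(self) -> np.ndarray:
        """One-sided complex Fourier amplitudes c_k = rfft(samples)/n."""
        return np.fft.rfft(self.samples) / self.n

    def evaluate(self, t, n_harmonics: int | None = None) -> np.ndarray:
        """Band-limited (trigonometric) interpolation of the waveform at ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        c = self.harmonics()
        k_max = c.size - 1 if n_harmonics is None else min(n_harmonics, c.size - 1)
        omega = 2.0 * np.pi / self.period
        q = np.full(t.shape, c[0].real)
        for k in range(1, k_max + 1):
            # Nyquist term (even n) appears once in the one-sided spectrum.
            factor = 1.0 if (self.n % 2 == 0 and k == self.n // 2) else 2.0
            q = q + factor * np.real(c[k] * np.exp(1j * omega * k * t))
        return q

    def scaled(self, factor: float) -> "FlowWaveform":
        return replace(self, samples=self.samples * float(factor))

    def resampled(self, n: int) -> "FlowWaveform":
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return FlowWaveform(self.period, self.evaluate(t))


@dataclass(frozen=True)
class WomersleyResult:
    """Analytic pulsatile tube-flow solution sampled over one period.

    ``wall_shear_series`` is the signed axial wall shear (Pa), positive in
    the mean-flow direction.  ``velocity_profile`` has shape
    (n_radial, n_time) in m/s on the radial grid ``r_mm``.
    """

    times: np.ndarray
    period: float
    wall_shear_series: np.ndarray
    r_mm: np.ndarray
    velocity_profile: np.ndarray
    alpha: np.ndarray

    def tawss(self) -> float:
        """Cycle-averaged |wall shear| (Pa); exact periodic trapezoid on the
        uniform sample grid reduces to the plain mean."""
        return float(np.mean(np.abs(self.wall_shear_series)))

    def flow_rate(self) -> np.ndarray:
        """Cross-sectional flow integral of the velocity profile, per time
        sample, in ml/s (for checking flow conservation)."""
        from scipy.integrate import simpson

        r = self.r_mm * _MM
        q = simpson(self.velocity_profile * (2.0 * np.pi * r)[:, None], x=r, axis=0)
        return q / _ML_S


def womersley_wall_shear(
    waveform: FlowWaveform,
    radius: float,
    fluid: FluidProperties = DEFAULT_FLUID,
    n_time: int = 64,
    *,
    n_harmonics: int = 8,
    n_radial: int = 201,
) -> WomersleyResult:
    """Womersley solution for a rigid straight tube of the given radius (mm).

    The steady harmonic contributes the Poiseuille wall shear
    4*mu*Q0/(pi R^3); each oscillatory harmonic uses the complex
    Bessel-function solution of the oscillatory Stokes problem with
    Lambda_k = i^(3/2) * alpha_k, alpha_k = R sqrt(omega_k rho / mu).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_time < 4:
        raise ValueError("n_time must be >= 4")
    R = radius * _MM
    mu = fluid.mu_ref
    rho = fluid.density
    T = waveform.period
    t = np.linspace(0.0, T, n_time, endpoint=False)
    c = waveform.harmonics()
    k_max = min(n_harmonics, c.size - 1)

    q0 = c[0].real * _ML_S
    r = np.linspace(0.0, R, n_radial)
    tau = np.full(n_time, 4.0 * mu * q0 / (np.pi * R**3))
    u = np.repeat(
        (2.0 * q0 / (np.pi * R**2) * (1.0 - (r / R) ** 2))[:, None], n_time, axis=1
    )

    alphas = []
    for k in range(1, k_max + 1):
        omega = 2.0 * np.pi * k / T
        alpha = R * np.sqrt(omega * rho / mu)
        if alpha > MAX_WOMERSLEY_NUMBER:
            raise OverflowError(
                f"Womersley number {alpha:.1f} for harmonic {k} exceeds the "
                f"numerical range guard ({MAX_WOMERSLEY_NUMBER})"
            )
        alphas.append(alpha)
        factor = 1.0 if (waveform.n % 2 == 0 and k == waveform.n // 2) else 2.0
        qk = factor * c[k] * _ML_S
        lam = (1j**1.5) * alpha
        j0 = jv(0, lam)
        j1 = jv(1, lam)
        denom = 1.0 - 2.0 * j1 / (lam * j0)
        phase = np.exp(1j * omega * t)
        prof = (qk / (np.pi * R**2 * denom)) * (1.0 - jv(0, lam * r / R) / j0)
        u += np.real(prof[:, None] * phase[None, :])
        tau_c = -mu * qk / (np.pi * R**2 * denom) * (lam / R) * (j1 / j0)
        tau += np.real(tau_c * phase)

    return WomersleyResult(
        times=t,
        period=T,
        wall_shear_series=tau,
        r_mm=r / _MM,
        velocity_profile=u,
        alpha=np.asarray(alphas),
    )


def scale_waveform_to_target_wss(
    waveform: FlowWaveform,
    cca_radius: float,
    fluid: FluidProperties = DEFAULT_FLUID,
    target_tawss: float = 0.9,
    *,
    n_time: int = 128,
    n_harmonics: int = 8,
) -> tuple[FlowWaveform, float]:
    """Scale all waveform samples by one factor so that the analytic
    cycle-averaged |wall shear| in a straight tube of ``cca_radius`` mm
    equals ``target_tawss`` Pa.

    The wall shear is linear in the flow, so TAWSS is positively homogeneous
    in the scale factor and the 1D root is available in closed form as
    target/current; the result is verified by recomputation.
    """
    res = womersley_wall_shear(
        waveform, cca_radius, fluid, n_time, n_harmonics=n_harmonics
    )
    current = res.tawss()
    if current <= 1e-12:
        raise ValueError("waveform has (near-)zero cycle-averaged wall shear")
    factor = target_tawss / current
    scaled = waveform.scaled(factor)
    check = womersley_wall_shear(
        scaled, cca_radius, fluid, n_time, n_harmonics=n_harmonics
    ).tawss()
    if abs(check - target_tawss) > 1e-3:
        raise RuntimeError("waveform scaling failed to reach the target TAWSS")
    return scaled, factor


DEFAULT_OUTFLOW_TABLE = ((0.0, 0.64), (0.5, 0.64), (1.0, 0.0))


def split_outflow(
    stenosis_degree_ica: float,
    table: Sequence[tuple[float, float]] = DEFAULT_OUTFLOW_TABLE,
) -> tuple[float, float]:
    """(ICA fraction, ECA fraction) of the total outflow as a function of
    ICA stenosis degree; piecewise-linear in a configurable monotone table."""
    d = float(stenosis_degree_ica)
    if not 0.0 <= d <= 1.0:
        raise ValueError("stenosis degree must be in [0, 1]")
    xs = np.array([p[0] for p in table], dtype=float)
    ys = np.array([p[1] for p in table], dtype=float)
    if np.any(np.diff(xs) <= 0):
        raise ValueError("outflow table abscissae must be strictly increasing")
    if np.any(np.diff(ys) > 0):
        raise ValueError("outflow table must be non-increasing in stenosis degree")
    ica = float(np.interp(d, xs, ys))
    return ica, 1.0 - ica


def parametric_waveform(
    heart_rate_bpm: float = 68.0,
    mean_flow: float = 6.0,
    harmonics: Sequence[tuple[float, float]] = ((0.6, 0.0), (0.25, 1.2), (0.1, 2.4)),
    n_samples: int = 64,
) -> FlowWaveform:
    """Steady component plus a few harmonics; amplitudes are relative to the
    mean flow, phases in radians."""
    period = 60.0 / heart_rate_bpm
    t = np.linspace(0.0, period, n_samples, endpoint=False)
    q = np.full(n_samples, float(mean_flow))
    for k, (amp, phase) in enumerate(harmonics, start=1):
        q += mean_flow * amp * np.cos(2.0 * np.pi * k * t / period + phase)
    return FlowWaveform(period, q)


def random_waveform(
    rng: np.random.Generator,
    heart_rate_bpm: float = 68.0,
    mean_flow: float = 6.0,
    n_harmonics: int = 3,
    max_relative_amplitude: float = 0.5,
    n_samples: int = 64,
) -> FlowWaveform:
    """Random multi-harmonic waveform with a positive mean (for property tests)."""
    harmonics = [
        (rng.uniform(0.05, max_relative_amplitude) / (k + 1), rng.uniform(0, 2 * np.pi))
        for k in range(n_harmonics)
    ]
    return parametric_waveform(heart_rate_bpm, mean_flow, harmonics, n_samples)


def write_waveform_csv(waveform: FlowWaveform, path) -> None:
    path = Path(path)
    t = np.linspace(0.0, waveform.period, waveform.n, endpoint=False)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "Q_ml_s"])
        for ti, qi in zip(t, waveform.samples):
            writer.writerow([f"{ti:.9g}", f"{qi:.9g}"])


def read_waveform_csv(path) -> FlowWaveform:
    path = Path(path)
    t, q = [], []
    with path.open() as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            t.append(float(row["t_s"]))
            q.append(float(row["Q_ml_s"]))
    t = np.asarray(t)
    q = np.asarray(q)
    if t.size < 4:
        raise ValueError("waveform CSV needs >= 4 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("waveform CSV must be uniformly sampled")
    period = float(t[-1] - t[0] + dt[0])
    return FlowWaveform(period, q)
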