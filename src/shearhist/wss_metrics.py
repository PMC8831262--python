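"""Per-vertex time-averaged wall shear stress and oscillatory shear index.

Both metrics are computed from the WSS *vectors* (not magnitudes) over one
cardiac cycle with a periodic trapezoidal quadrature: the last interval
wraps around to the first sample.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: integrals with cycle-mean |wss| below this are treated as zero shear
ZERO_SHEAR_TOL = 1e-15


@dataclass(frozen=True)
class SurfaceWssSeries:
    """Time-resolved WSS vectors on a lumen surface.

    vertices : (n, 3) float, mm
    times    : (nt,) float, s, strictly increasing, spanning one cycle
    wss      : (n, nt, 3) float, Pa
    period   : cycle duration, s; defaults to times[-1] - times[0] + median dt
    """

    vertices: np.ndarray
    times: np.ndarray
    wss: np.ndarray
    period: float | None = None

    def __post_init__(self) -> None:
        vertices = np.asarray(self.vertices, dtype=float)
        times = np.asarray(self.times, dtype=float)
        wss = np.asarray(self.wss, dtype=float)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (n, 3)")
        if times.ndim != 1 or times.size < 4:
            raise ValueError("need at least 4 time samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if wss.shape != (vertices.shape[0], times.size, 3):
            raise ValueError("wss must have shape (n_vertices, n_times, 3)")
        if not np.all(np.isfinite(wss)):
            raise ValueError("wss vector components must be finite")
        period = self.period
        if period is None:
            period = float(times[-1] - times[0] + np.median(np.diff(times)))
        if period <= times[-1] - times[0]:
            raise ValueError("period must exceed the sampled time span")
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "wss", wss)
        object.__setattr__(self, "period", float(period))


def _cycle_weights(times: np.ndarray, period: float) -> np.ndarray:
    """Trapezoidal weights for a periodic integral over one cycle.

    Sample i receives (dt_{i-1} + dt_i)/2, where the interval after the last
    sample wraps to the first sample one period later.  The weights sum to
    the period.  For uniform sampling over [0, T) this reduces to dt per
    sample, i.e. the plain mean after division by T.
    """
    dt = np.diff(times)
    wrap = period - (times[-1] - times[0])
    left = np.concatenate(([wrap], dt))
    right = np.concatenate((dt, [wrap]))
    return 0.5 * (left + right)


@dataclass(frozen=True)
class MetricMap:
    """Per-vertex TAWSS (Pa) and OSI (dimensionless) with the mesh."""

    vertices: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray
    zero_shear: np.ndarray  # bool flag: cycle integral of |wss| vanished

    def __post_init__(self) -> None:
        if np.any(self.tawss < 0):
            raise ValueError("tawss must be non-negative")
        if np.any((self.osi < 0) | (self.osi > 0.5)):
            raise ValueError("osi must lie in [0, 0.5]")


def tawss(series: SurfaceWssSeries) -> np.ndarray:
    """(1/T) * cyclic integral of |tau_w(t)| per vertex, in Pa."""
    w = _cycle_weights(series.times, series.period)
    mag = np.linalg.norm(series.wss, axis=2)
    return mag @ w / series.period


def osi(series: SurfaceWssSeries) -> np.ndarray:
    """0.5 * (1 - |int tau dt| / int |tau| dt) per vertex, in [0, 0.5].

    Vertices whose cycle integral of |tau| vanishes are assigned OSI 0 (see
    :func:`metric_map` for the flag).
    """
    return _osi_with_flags(series)[0]


def _osi_with_flags(series: SurfaceWssSeries) -> tuple[np.ndarray, np.ndarray]:
    w = _cycle_weights(series.times, series.period)
    mean_vec = np.einsum("ntc,t->nc", series.wss, w)
    num = np.linalg.norm(mean_vec, axis=1)
    den = np.linalg.norm(series.wss, axis=2) @ w
    zero = den <= ZERO_SHEAR_TOL * series.period
    ratio = np.ones_like(den)
    np.divide(num, den, out=ratio, where=~zero)
    values = 0.5 * (1.0 - np.clip(ratio, 0.0, 1.0))
    values[zero] = 0.0
    return values, zero


def metric_map(series: SurfaceWssSeries) -> MetricMap:
    """Bundle TAWSS and OSI with the mesh vertices."""
    osi_values, zero = _osi_with_flags(series)
    return MetricMap(
        vertices=series.vertices,
        tawss=tawss(series),
        osi=osi_values,
        zero_shear=zero,
    )


def write_metric_map_csv(metric: MetricMap, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["vertex_id", "x", "y", "z", "tawss", "osi"])
        for i, (v, t, o) in enumerate(zip(metric.vertices, metric.tawss, metric.osi)):
            writer.writerow(
                [i, f"{v[0]:.9g}", f"{v[1]:.9g}", f"{v[2]:.9g}", f"{t:.9g}", f"{o:.9g}"]
            )


def read_metric_map_csv(path) -> MetricMap:
    path = Path(path)
    rows = []
    with path.open() as fh:
        for row in csv.DictReader(fh):
            rows.append(
                (float(row["x"]), float(row["y"]), float(row["z"]),
                 float(row["tawss"]), float(row["osi"]))
            )
    arr = np.asarray(rows, dtype=float)
    return MetricMap(
        vertices=arr[:, :3],
        tawss=arr[:, 3],
        osi=arr[:, 4],
        zero_shear=arr[:, 3] == 0.0,
    )
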