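"""Lumen-registration quality metrics and a simple rigid 2D contour alignment.

"Average Hausdorff distance" is implemented as the symmetric average surface
distance (mean point-to-contour distance in both directions, averaged); the
classical max-Hausdorff is reported alongside so either reading is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import LinearRing


@dataclass(frozen=True)
class LumenSegmentation:
    """Binary lumen mask with its boundary contour (mm)."""

    mask: np.ndarray
    pixel_size: float
    contour: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2D")
        contour = np.asarray(self.contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 3:
            raise ValueError("contour must be a closed (k, 2) polygon")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "contour", contour)


def dice_coefficient(a, b) -> float:
    """DSC = 2|A n B| / (|A| + |B|) for two same-grid binary masks."""
    ma = a.mask if isinstance(a, LumenSegmentation) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, LumenSegmentation) else np.asarray(b, dtype=bool)
    if isinstance(a, LumenSegmentation) and isinstance(b, LumenSegmentation):
        if a.pixel_size != b.pixel_size:
            raise ValueError("segmentations must share the pixel size")
    if ma.shape != mb.shape:
        raise ValueError("masks must share the grid shape")
    total = ma.sum() + mb.sum()
    if total == 0:
        raise ValueError("both masks are empty; DSC undefined")
    return float(2.0 * np.logical_and(ma, mb).sum() / total)


def resample_contour(contour: np.ndarray, step: float) -> np.ndarray:
    """Uniform arclength resampling of a closed contour."""
    contour = np.asarray(contour, dtype=float)
    try:
        ring = LinearRing(contour)
    except Exception as exc:
        raise ValueError(f"degenerate contour: {exc}") from exc
    if ring.length <= 0:
        raise ValueError("degenerate (zero-length) contour")
    n = max(8, int(np.ceil(ring.length / step)))
    s = np.linspace(0.0, ring.length, n, endpoint=False)
    return np.array([ring.interpolate(si).coords[0] for si in s])


@dataclass(frozen=True)
class HausdorffResult:
    average: float   # symmetric average surface distance, mm
    maximum: float   # classical (max) Hausdorff distance, mm


def average_hausdorff(
    a: np.ndarray, b: np.ndarray, resample_step: float = 0.05
) -> HausdorffResult:
    """Symmetric average surface distance between two closed contours (mm),
    with the classical max-Hausdorff as a secondary field."""
    if resample_step <= 0:
        raise ValueError("resample_step must be positive")
    pa = resample_contour(a, resample_step)
    pb = resample_contour(b, resample_step)
    d = cdist(pa, pb)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    return HausdorffResult(
        average=float(0.5 * (d_ab.mean() + d_ba.mean())),
        maximum=float(max(d_ab.max(), d_ba.max())),
    )


@dataclass(frozen=True)
class RigidTransform:
    """2D rotation (about the origin) followed by translation."""

    rotation: np.ndarray   # (2, 2) proper rotation matrix
    translation: np.ndarray  # (2,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    @property
    def angle(self) -> float:
        """Rotation angle in radians."""
        return float(np.arctan2(self.rotation[1, 0], self.rotation[0, 0]))


def _kabsch_2d(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    a = moving - mc
    b = fixed - fc
    # closed-form 2D rotation from the cross-covariance
    num = np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    den = np.sum(a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1])
    theta = np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    trans = fc - rot @ mc
    return RigidTransform(rotation=rot, translation=trans)


def rigid_align(
    moving: np.ndarray, fixed: np.ndarray, n_points: int = 180
) -> tuple[RigidTransform, np.ndarray]:
    """Least-squares rigid alignment of ``moving`` onto ``fixed``.

    Correspondences come from uniform arclength resampling with a cyclic
    search over the starting index (both traversal orientations are tried).
    The returned transform never yields a worse average distance than the
    identity; on failure to improve, the identity is returned.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(fixed))):
        raise ValueError("contour coordinates must be finite")
    if len(moving) < 3 or len(fixed) < 3:
        raise ValueError("contours need >= 3 points")
    step_m = LinearRing(moving).length / n_points
    pm = resample_contour(moving, step_m)[:n_points]
    step_f = LinearRing(fixed).length / n_points
    pf = resample_contour(fixed, step_f)[:n_points]
    n = min(len(pm), len(pf))
    pm, pf = pm[:n], pf[:n]

    def _evaluate(candidate, shifts):
        out = None
        for shift in shifts:
            rolled = np.roll(candidate, -int(shift), axis=0)
            tf = _kabsch_2d(rolled, pf)
            resid = float(np.mean(np.linalg.norm(tf.apply(rolled) - pf, axis=1)))
            if out is None or resid < out[0]:
                out = (resid, tf, int(shift))
        return out

    # coarse-to-fine cyclic-shift search over both traversal orientations
    stride = max(1, n // 45)
    best: tuple[float, RigidTransform] | None = None
    for candidate in (pm, pm[::-1]):
        coarse = _evaluate(candidate, range(0, n, stride))
        fine = _evaluate(
            candidate,
            [(coarse[2] + d) % n for d in range(-stride, stride + 1)],
        )
        if best is None or fine[0] < best[0]:
            best = (fine[0], fine[1])
    assert best is not None
    _, transform = best

    identity = RigidTransform(rotation=np.eye(2), translation=np.zeros(2))
    after = average_hausdorff(transform.apply(moving), fixed).average
    before = average_hausdorff(moving, fixed).average
    if after > before:
        transform = identity
    return transform, transform.apply(moving)
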