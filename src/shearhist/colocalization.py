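"""Map vertex-level WSS metrics onto histology cross-sections.

Vertices are projected to centerline arclength, averaged inside an axial
window of +/- 0.3 mm around each section, assigned to eight 45-degree
sectors measured counterclockwise (about the section normal) from an
explicit per-section angular reference, and pooled into one record per
(section, sector).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

if TYPE_CHECKING:  # pragma: no cover
    from .histology import PlaqueBinMeasures
    from .wss_metrics import MetricMap

#: fixed output schema of the bin table
BIN_TABLE_COLUMNS = [
    "patient_id",
    "section_id",
    "bin_index",
    "tawss_mean",
    "osi_mean",
    "nc_area_mm2",
    "fibrin_area_mm2",
    "macrophage_area_mm2",
    "cap_thickness_mm",
    "intima_area_mm2",
    "included",
    "exclusion_reason",
]

REASON_ARTIFACT = "histology-artifact"
REASON_MISMATCH = "registration-mismatch"
REASON_NO_COVERAGE = "no-coverage"


@dataclass(frozen=True)
class Centerline:
    """Ordered 3D polyline (mm) with cumulative arclength."""

    points: np.ndarray
    arclength: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
            raise ValueError("centerline needs >= 2 points of shape (m, 3)")
        arclength = self.arclength
        if arclength is None:
            seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
            arclength = np.concatenate(([0.0], np.cumsum(seg)))
        else:
            arclength = np.asarray(arclength, dtype=float)
        if np.any(np.diff(arclength) <= 0):
            raise ValueError("centerline arclength must be strictly increasing")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "arclength", arclength)

    def nearest_arclength(self, points: np.ndarray) -> np.ndarray:
        """Arclength of the nearest centerline point for each query point."""
        tree = cKDTree(self.points)
        _, idx = tree.query(np.asarray(points, dtype=float))
        return self.arclength[idx]


@dataclass(frozen=True)
class CrossSectionFrame:
    """Geometry of one histology section in the co-registered frame.

    ``angular_reference`` is a unit vector in the section plane that defines
    the zero angle of sector 0; angles increase counterclockwise about
    ``normal``.
    """

    section_id: str
    patient_id: str
    axial_position: float
    center: np.ndarray
    normal: np.ndarray
    angular_reference: np.ndarray

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        normal = np.asarray(self.normal, dtype=float)
        ref = np.asarray(self.angular_reference, dtype=float)
        for name, v in (("normal", normal), ("angular_reference", ref)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a unit vector")
        if abs(normal @ ref) > 1e-6:
            raise ValueError("normal and angular_reference must be orthogonal")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "normal", normal)
        object.__setattr__(self, "angular_reference", ref)


def axial_window_average(
    metric_map: "MetricMap",
    centerline: Centerline,
    section: CrossSectionFrame,
    half_window: float = 0.3,
) -> np.ndarray:
    """Indices of vertices whose projected arclength falls in
    [axial_position - half_window, axial_position + half_window]."""
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    s = centerline.nearest_arclength(metric_map.vertices)
    mask = np.abs(s - section.axial_position) <= half_window
    return np.flatnonzero(mask)


def assign_sectors(
    points: np.ndarray,
    section: CrossSectionFrame,
    n_bins: int = 8,
) -> np.ndarray:
    """Sector index in [0, n_bins) for each point.

    The angle is measured in the section plane, counterclockwise about the
    section normal, starting at the angular reference; sectors are the
    half-open intervals [k*360/n, (k+1)*360/n).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = points - section.center
    d_plane = d - np.outer(d @ section.normal, section.normal)
    if np.any(np.linalg.norm(d_plane, axis=1) < 1e-9):
        raise ValueError("point coincides with the section center")
    ref = section.angular_reference
    second_axis = np.cross(section.normal, ref)
    theta = np.arctan2(d_plane @ second_axis, d_plane @ ref) % (2.0 * np.pi)
    bins = np.floor(theta / (2.0 * np.pi / n_bins)).astype(int)
    return np.minimum(bins, n_bins - 1)  # guards theta == 2*pi round-off


def sector_means(
    metric_map: "MetricMap",
    centerline: Centerline,
    section: CrossSectionFrame,
    n_bins: int = 8,
    half_window: float = 0.3,
) -> pd.DataFrame:
    """Per-sector means of TAWSS and OSI over the axially windowed vertices.

    Sectors without any selected vertex carry NaN means and n_vertices 0.
    """
    idx = axial_window_average(metric_map, centerline, section, half_window)
    tawss_mean = np.full(n_bins, np.nan)
    osi_mean = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    if idx.size:
        sectors = assign_sectors(metric_map.vertices[idx], section, n_bins)
        for k in range(n_bins):
            sel = idx[sectors == k]
            counts[k] = sel.size
            if sel.size:
                tawss_mean[k] = metric_map.tawss[sel].mean()
                osi_mean[k] = metric_map.osi[sel].mean()
    return pd.DataFrame(
        {
            "section_id": section.section_id,
            "patient_id": section.patient_id,
            "bin_index": np.arange(n_bins),
            "tawss_mean": tawss_mean,
            "osi_mean": osi_mean,
            "n_vertices": counts,
        }
    )


def build_bin_table(
    metric_maps: Mapping[str, "MetricMap"],
    centerlines: Mapping[str, Centerline],
    sections: Sequence[CrossSectionFrame],
    measures: Mapping[str, Sequence["PlaqueBinMeasures"]],
    *,
    n_bins: int = 8,
    half_window: float = 0.3,
    mismatch_flags: Iterable[tuple[str, int]] = (),
) -> pd.DataFrame:
    """Join windowed sector WSS means with per-sector plaque measures.

    One row per (section, sector); exactly n_sections * n_bins rows.  A bin
    is excluded with a single primary reason, in precedence order:
    histology-artifact (from the measures' exclusion flags),
    registration-mismatch (caller-supplied flags), no-coverage (no vertex in
    the axial window / sector).
    """
    mismatch = set(mismatch_flags)
    rows = []
    for section in sections:
        if section.section_id not in measures:
            raise KeyError(
                f"no histology measures for section {section.section_id!r}"
            )
        if section.patient_id not in metric_maps:
            raise KeyError(f"no metric map for patient {section.patient_id!r}")
        wss = sector_means(
            metric_maps[section.patient_id],
            centerlines[section.patient_id],
            section,
            n_bins,
            half_window,
        )
        section_measures = {m.bin_index: m for m in measures[section.section_id]}
        for k in range(n_bins):
            m = section_measures.get(k)
            included = True
            reason = None
            if m is not None and not m.included:
                included, reason = False, m.exclusion_reason or REASON_ARTIFACT
            elif (section.section_id, k) in mismatch:
                included, reason = False, REASON_MISMATCH
            elif wss.loc[k, "n_vertices"] == 0:
                included, reason = False, REASON_NO_COVERAGE
            rows.append(
                {
                    "patient_id": section.patient_id,
                    "section_id": section.section_id,
                    "bin_index": k,
                    "tawss_mean": wss.loc[k, "tawss_mean"],
                    "osi_mean": wss.loc[k, "osi_mean"],
                    "nc_area_mm2": m.nc_area if m else np.nan,
                    "fibrin_area_mm2": m.fibrin_area if m else np.nan,
                    "macrophage_area_mm2": m.macrophage_area if m else np.nan,
                    "cap_thickness_mm": m.cap_thickness if m else np.nan,
                    "intima_area_mm2": m.intima_area if m else np.nan,
                    "included": included,
                    "exclusion_reason": reason,
                }
            )
    return pd.DataFrame(rows, columns=BIN_TABLE_COLUMNS)
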