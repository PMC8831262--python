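"""Quantify plaque components per 45-degree sector from class-coded masks.

Classes may nest: fibrin inside necrotic core counts toward both areas, so
nested combinations get their own codes.  Macrophage pixels that fall inside
necrotic core or artifact regions are excluded from the macrophage area (the
combination codes count toward NC / artifact only).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, Polygon

from .colocalization import REASON_ARTIFACT

CLASS_CODES = {
    "background": 0,
    "intima": 1,
    "nc": 2,
    "fibrin": 3,
    "macrophage": 4,
    "artifact": 5,
    "nc_fibrin": 6,          # fibrin nested inside NC: counts as NC and fibrin
    "nc_macrophage": 7,      # macrophage inside NC: counts as NC only
    "artifact_macrophage": 8,  # macrophage inside artifact: counts as artifact only
}

NC_CODES = frozenset({2, 6, 7})
FIBRIN_CODES = frozenset({3, 6})
MACROPHAGE_CODES = frozenset({4})
ARTIFACT_CODES = frozenset({5, 8})
#: codes contributing to the intima (total tissue) area
TISSUE_CODES = frozenset({1, 2, 3, 4, 6, 7})


@dataclass(frozen=True)
class SectionLabelMask:
    """Class-coded raster of one histology section.

    pixels        : (H, W) integer grid of CLASS_CODES values
    pixel_size    : mm per pixel edge
    origin        : (x, y) of the center of pixel [0, 0], section-plane mm
    center        : (x, y) sector-binning center (registered centerline point)
    angular_reference : 2D unit vector defining the zero angle of sector 0
    lumen_contour : (k, 2) closed simple polygon, mm
    """

    pixels: np.ndarray
    pixel_size: float
    origin: np.ndarray
    center: np.ndarray
    angular_reference: np.ndarray
    lumen_contour: np.ndarray
    section_id: str = ""
    patient_id: str = ""
    axial_position: float = float("nan")

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.isin(pixels, list(CLASS_CODES.values())).all():
            raise ValueError("pixels contain codes outside the class map")
        contour = np.asarray(self.lumen_contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 3:
            raise ValueError("lumen_contour must be a (k, 2) polygon, k >= 3")
        if not Polygon(contour).is_valid:
            raise ValueError("lumen_contour must be a simple (non-crossing) polygon")
        ref = np.asarray(self.angular_reference, dtype=float)
        if abs(np.linalg.norm(ref) - 1.0) > 1e-6:
            raise ValueError("angular_reference must be a unit vector")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "angular_reference", ref)
        object.__setattr__(self, "lumen_contour", contour)

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates (mm) of every pixel center, each of shape (H, W)."""
        h, w = self.pixels.shape
        x = self.origin[0] + np.arange(w) * self.pixel_size
        y = self.origin[1] + np.arange(h) * self.pixel_size
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class PlaqueBinMeasures:
    """Per-sector plaque quantification (areas mm^2, cap thickness mm)."""

    section_id: str
    bin_index: int
    nc_area: float
    fibrin_area: float
    macrophage_area: float
    intima_area: float
    cap_thickness: float  # NaN = missing (sector has no NC)
    artifact_fraction: float
    included: bool = True
    exclusion_reason: str | None = None


def _sector_indices(mask: SectionLabelMask, n_bins: int) -> np.ndarray:
    """Sector index per pixel (same angular convention as assign_sectors)."""
    x, y = mask.pixel_coords()
    dx = x - mask.center[0]
    dy = y - mask.center[1]
    rx, ry = mask.angular_reference
    theta = np.arctan2(rx * dy - ry * dx, rx * dx + ry * dy) % (2.0 * np.pi)
    bins = np.floor(theta / (2.0 * np.pi / n_bins)).astype(int)
    return np.minimum(bins, n_bins - 1)


def component_area_per_bin(
    mask: SectionLabelMask, n_bins: int = 8
) -> list[PlaqueBinMeasures]:
    """Pixel-count areas of NC / fibrin / macrophage / intima per sector.

    Cap thickness is left missing here; use :func:`measure_mask` for the
    combined quantification.
    """
    codes = mask.pixels
    if not np.isin(codes, list(TISSUE_CODES)).any():
        raise ValueError("mask contains no intima (tissue) pixels")
    sectors = _sector_indices(mask, n_bins)
    px_area = mask.pixel_size**2
    out = []
    for k in range(n_bins):
        sel = codes[sectors == k]
        nc = np.isin(sel, list(NC_CODES)).sum()
        fib = np.isin(sel, list(FIBRIN_CODES)).sum()
        mac = np.isin(sel, list(MACROPHAGE_CODES)).sum()
        art = np.isin(sel, list(ARTIFACT_CODES)).sum()
        tissue = np.isin(sel, list(TISSUE_CODES)).sum()
        denom = tissue + art
        out.append(
            PlaqueBinMeasures(
                section_id=mask.section_id,
                bin_index=k,
                nc_area=nc * px_area,
                fibrin_area=fib * px_area,
                macrophage_area=mac * px_area,
                intima_area=tissue * px_area,
                cap_thickness=float("nan"),
                artifact_fraction=art / denom if denom else 0.0,
            )
        )
    return out


def cap_thickness_per_bin(
    mask: SectionLabelMask, n_bins: int = 8, ray_step_deg: float = 1.0
) -> np.ndarray:
    """Minimum lumen-to-NC distance per sector, by ray casting from the center.

    For each ray (``ray_step_deg`` increments), the thickness is the radial
    distance from the lumen-contour crossing to the first NC-coded pixel.
    The per-sector value is the minimum over rays that hit NC; sectors whose
    rays never hit NC are NaN (missing).  Rays leaving the grid are skipped.
    """
    h, w = mask.pixels.shape
    poly = Polygon(mask.lumen_contour)
    boundary = poly.exterior
    cx, cy = mask.center
    rx, ry = mask.angular_reference
    extent = mask.pixel_size * (h + w)  # safely beyond the grid diagonal
    step = mask.pixel_size / 2.0
    result = np.full(n_bins, np.nan)
    nc_codes = np.array(list(NC_CODES))
    pixel_sector = _sector_indices(mask, n_bins)
    # rays offset half a step from sector boundaries; only NC pixels of the
    # ray's own sector count, so boundary rays cannot leak across sectors
    for deg in np.arange(ray_step_deg / 2.0, 360.0, ray_step_deg):
        theta = np.deg2rad(deg)
        # direction at angle theta ccw from the angular reference
        dx = rx * np.cos(theta) - ry * np.sin(theta)
        dy = rx * np.sin(theta) + ry * np.cos(theta)
        k = int(deg // (360.0 / n_bins)) % n_bins
        ray = LineString([(cx, cy), (cx + dx * extent, cy + dy * extent)])
        crossing = boundary.intersection(ray)
        if crossing.is_empty:
            continue
        pts = getattr(crossing, "geoms", [crossing])
        dists = []
        for g in pts:
            coords = np.asarray(g.coords)
            d = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
            dists.extend(d.tolist())
        r_lumen = min(dists)
        for r in np.arange(r_lumen + step / 2.0, extent, step):
            px = cx + dx * r
            py = cy + dy * r
            j = int(round((px - mask.origin[0]) / mask.pixel_size))
            i = int(round((py - mask.origin[1]) / mask.pixel_size))
            if not (0 <= i < h and 0 <= j < w):
                break
            if mask.pixels[i, j] in nc_codes and pixel_sector[i, j] == k:
                thickness = r - r_lumen
                if np.isnan(result[k]) or thickness < result[k]:
                    result[k] = thickness
                break
    return result


def measure_mask(
    mask: SectionLabelMask, n_bins: int = 8, ray_step_deg: float = 1.0
) -> list[PlaqueBinMeasures]:
    """Areas plus cap thickness per sector."""
    measures = component_area_per_bin(mask, n_bins)
    caps = cap_thickness_per_bin(mask, n_bins, ray_step_deg)
    return [
        dataclasses.replace(m, cap_thickness=float(caps[m.bin_index]))
        for m in measures
    ]


def exclude_bins(
    measures: list[PlaqueBinMeasures], artifact_threshold: float
) -> list[PlaqueBinMeasures]:
    """Flag bins whose artifact fraction exceeds the threshold."""
    if not 0.0 <= artifact_threshold <= 1.0:
        raise ValueError("artifact_threshold must be in [0, 1]")
    out = []
    for m in measures:
        if m.artifact_fraction > artifact_threshold:
            out.append(
                dataclasses.replace(
                    m, included=False, exclusion_reason=REASON_ARTIFACT
                )
            )
        else:
            out.append(m)
    return out


def write_mask(mask: SectionLabelMask, tiff_path) -> None:
    """Single-channel integer TIFF plus a JSON sidecar with the geometry."""
    import tifffile

    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, mask.pixels.astype(np.uint8))
    sidecar = {
        "pixel_size_mm": mask.pixel_size,
        "origin_mm": mask.origin.tolist(),
        "center_mm": mask.center.tolist(),
        "angular_reference": mask.angular_reference.tolist(),
        "lumen_contour_mm": mask.lumen_contour.tolist(),
        "section_id": mask.section_id,
        "patient_id": mask.patient_id,
        "axial_position_mm": None
        if np.isnan(mask.axial_position)
        else mask.axial_position,
        "class_codes": CLASS_CODES,
    }
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_mask(tiff_path) -> SectionLabelMask:
    import tifffile

    tiff_path = Path(tiff_path)
    pixels = tifffile.imread(tiff_path)
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    if meta.get("class_codes") != CLASS_CODES:
        raise ValueError("mask sidecar declares an unknown class-code map")
    axial = meta.get("axial_position_mm")
    return SectionLabelMask(
        pixels=pixels,
        pixel_size=meta["pixel_size_mm"],
        origin=np.asarray(meta["origin_mm"]),
        center=np.asarray(meta["center_mm"]),
        angular_reference=np.asarray(meta["angular_reference"]),
        lumen_contour=np.asarray(meta["lumen_contour_mm"]),
        section_id=meta.get("section_id", ""),
        patient_id=meta.get("patient_id", ""),
        axial_position=float("nan") if axial is None else float(axial),
    )
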