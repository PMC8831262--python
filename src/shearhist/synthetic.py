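"""Synthetic studies with known ground truth.

Generates vessel geometries (straight / stenotic / planar-Y bifurcation),
pulsatile WSS vector fields whose straight-tube values equal the analytic
Womersley solution exactly, and class-coded histology masks whose per-sector
component areas follow programmable tertile effects with per-patient random
intercepts.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import histology, stats, wss_metrics
from .colocalization import Centerline, CrossSectionFrame, sector_means
from .hemodynamics import (
    DEFAULT_FLUID,
    FlowWaveform,
    FluidProperties,
    parametric_waveform,
    womersley_wall_shear,
)
from .histology import CLASS_CODES, SectionLabelMask
from .wss_metrics import MetricMap, SurfaceWssSeries

_MM = 1e-3
_ML_S = 1e-6

COMPONENTS = ("nc", "fibrin", "macrophage", "cap")
DRIVERS = ("tawss", "osi")


@dataclass(frozen=True)
class EffectSpec:
    """Programmed WSS-tertile effect on one plaque component.

    ``group_means`` are the per-tertile outcome means (mm^2 for areas, mm for
    cap thickness) in (low, mid, high) order; ``patient_sd`` is the
    random-intercept standard deviation and ``residual_sd`` the
    within-patient noise.
    """

    component: str
    driver: str
    group_means: tuple[float, float, float]
    patient_sd: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"component must be one of {COMPONENTS}")
        if self.driver not in DRIVERS:
            raise ValueError(f"driver must be one of {DRIVERS}")
        if len(self.group_means) != 3 or not np.all(np.isfinite(self.group_means)):
            raise ValueError("group_means must be 3 finite values (low, mid, high)")
        if self.patient_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    def mean_for(self, label: str) -> float:
        return self.group_means[stats.TERTILE_LABELS.index(label)]


@dataclass(frozen=True)
class VesselGeometry:
    """Tubular lumen geometry along a centerline (all lengths in mm)."""

    centerline: np.ndarray        # (m, 3)
    radius_profile: np.ndarray    # (m,)
    arclength: np.ndarray         # (m,)
    segment_labels: np.ndarray    # (m,) str in {CCA, ICA, ECA, extension}
    vertices: np.ndarray          # (m * n_theta, 3), ring-major
    faces: np.ndarray             # (f, 3) int triangles
    n_theta: int
    section_arclengths: np.ndarray  # analysis-section positions

    def __post_init__(self) -> None:
        if np.any(self.radius_profile <= 0):
            raise ValueError("radii must be strictly positive")
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("centerline arclength must be strictly increasing")

    @property
    def n_rings(self) -> int:
        return len(self.centerline)

    def ring_index(self) -> np.ndarray:
        """Centerline-ring index of every surface vertex."""
        return np.repeat(np.arange(self.n_rings), self.n_theta)

    def vertex_radius(self) -> np.ndarray:
        return self.radius_profile[self.ring_index()]

    def vertex_angles(self) -> np.ndarray:
        """Ring-local angle of every vertex (offset half a step from 0)."""
        theta = (np.arange(self.n_theta) + 0.5) * 2.0 * np.pi / self.n_theta
        return np.tile(theta, self.n_rings)

    def radius_at(self, arclength) -> np.ndarray:
        return np.interp(arclength, self.arclength, self.radius_profile)

    def as_centerline(self) -> Centerline:
        return Centerline(points=self.centerline, arclength=self.arclength)


def _tube_mesh(
    centers: np.ndarray, radii: np.ndarray, n_theta: int
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated tube surface around a polyline with per-ring radii.

    Ring angles are offset by half a step so that no vertex sits exactly on a
    45-degree sector boundary.
    """
    m = len(centers)
    tangents = np.gradient(centers, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # parallel-transported frame to avoid twisting
    e1 = np.zeros_like(tangents)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ tangents[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - (ref @ tangents[0]) * tangents[0]
    e1[0] = v / np.linalg.norm(v)
    for i in range(1, m):
        v = e1[i - 1] - (e1[i - 1] @ tangents[i]) * tangents[i]
        e1[i] = v / np.linalg.norm(v)
    e2 = np.cross(tangents, e1)
    theta = (np.arange(n_theta) + 0.5) * 2.0 * np.pi / n_theta
    ct, st = np.cos(theta), np.sin(theta)
    vertices = (
        centers[:, None, :]
        + radii[:, None, None] * (ct[None, :, None] * e1[:, None, :]
                                  + st[None, :, None] * e2[:, None, :])
    ).reshape(m * n_theta, 3)
    faces = []
    for i in range(m - 1):
        base0 = i * n_theta
        base1 = (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([base0 + j, base1 + j, base1 + jn])
            faces.append([base0 + j, base1 + jn, base0 + jn])
    return vertices, np.asarray(faces, dtype=int)


def generate_vessel(
    kind: str = "straight",
    base_radius: float = 3.0,
    stenosis_degree: float = 0.0,
    n_sections: int = 8,
    seed: int = 0,
    *,
    section_spacing: float = 1.0,
    ring_spacing: float = 0.15,
    n_theta: int = 32,
    stenosis_span: float | None = None,
    bulb_dilation: float = 1.2,
) -> VesselGeometry:
    """Idealized lumen geometry with flow extensions.

    The stenotic kind applies a cosine-bump radius reduction reaching
    ``(1 - stenosis_degree) * base_radius`` at the throat.  Flow extensions
    of length five times the local radius are appended at the inlet and
    outlet(s).
    """
    if base_radius <= 0:
        raise ValueError("base_radius must be positive")
    if not 0.0 <= stenosis_degree < 1.0:
        raise ValueError("stenosis_degree must be in [0, 1)")
    if kind not in ("straight", "stenotic", "bifurcation"):
        raise ValueError(f"unknown vessel kind {kind!r}")
    if kind == "straight" and stenosis_degree != 0.0:
        raise ValueError("straight vessels cannot have a stenosis")

    main_length = n_sections * section_spacing
    ext = 5.0 * base_radius

    if kind in ("straight", "stenotic"):
        total = main_length + 2.0 * ext
        n_rings = max(int(np.ceil(total / ring_spacing)) + 1, 2)
        z = np.linspace(0.0, total, n_rings)
        radii = np.full(n_rings, float(base_radius))
        if kind == "stenotic" and stenosis_degree > 0:
            span = stenosis_span or min(10.0, 0.6 * main_length)
            z_throat = ext + main_length / 2.0
            in_bump = np.abs(z - z_throat) < span / 2.0
            radii[in_bump] -= (
                base_radius
                * (stenosis_degree / 2.0)
                * (1.0 + np.cos(2.0 * np.pi * (z[in_bump] - z_throat) / span))
            )
        labels = np.where(
            (z < ext) | (z > ext + main_length), "extension", "CCA"
        ).astype(object)
        if kind == "stenotic":
            labels[(z >= ext + main_length / 2.0) & (labels == "CCA")] = "ICA"
        centers = np.column_stack([np.zeros(n_rings), np.zeros(n_rings), z])
        section_s = ext + (np.arange(n_sections) + 0.5) * section_spacing
    else:
        # planar Y: CCA trunk along +z with a bulb, ICA branch continues
        # near-axially, ECA branches off in the x-z plane
        trunk_len = max(main_length * 0.6, 8.0)
        branch_len = max(main_length * 0.6, 8.0)
        r_ica = 0.8 * base_radius
        r_eca = 0.65 * base_radius
        dz = ring_spacing
        z_trunk = np.arange(0.0, ext + trunk_len + dz / 2, dz)
        r_trunk = np.full(z_trunk.shape, float(base_radius))
        bulb = z_trunk > (ext + trunk_len - 4.0 * base_radius)
        r_trunk[bulb] *= 1.0 + (bulb_dilation - 1.0) * np.sin(
            np.pi
            * (z_trunk[bulb] - (ext + trunk_len - 4.0 * base_radius))
            / (4.0 * base_radius)
        )
        trunk_pts = np.column_stack(
            [np.zeros_like(z_trunk), np.zeros_like(z_trunk), z_trunk]
        )
        trunk_lab = np.where(z_trunk < ext, "extension", "CCA").astype(object)

        def _branch(angle_deg, radius, label):
            direction = np.array(
                [np.sin(np.deg2rad(angle_deg)), 0.0, np.cos(np.deg2rad(angle_deg))]
            )
            s = np.arange(dz, branch_len + 5.0 * radius + dz / 2, dz)
            pts = trunk_pts[-1] + s[:, None] * direction
            lab = np.where(s > branch_len, "extension", label).astype(object)
            rr = np.full(s.shape, float(radius))
            return pts, rr, lab

        ica_pts, r_ica_arr, ica_lab = _branch(15.0, r_ica, "ICA")
        eca_pts, r_eca_arr, eca_lab = _branch(-35.0, r_eca, "ECA")
        centers = np.vstack([trunk_pts, ica_pts, eca_pts])
        radii = np.concatenate([r_trunk, r_ica_arr, r_eca_arr])
        labels = np.concatenate([trunk_lab, ica_lab, eca_lab])
        seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        arc = np.concatenate(([0.0], np.cumsum(seg)))
        section_s = ext + (np.arange(n_sections) + 0.5) * (
            (trunk_len + branch_len) / max(n_sections, 1)
        )
        vertices, faces = _tube_mesh(centers, radii, n_theta)
        return VesselGeometry(
            centerline=centers,
            radius_profile=radii,
            arclength=arc,
            segment_labels=labels,
            vertices=vertices,
            faces=faces,
            n_theta=n_theta,
            section_arclengths=section_s,
        )

    vertices, faces = _tube_mesh(centers, radii, n_theta)
    return VesselGeometry(
        centerline=centers,
        radius_profile=radii,
        arclength=z.copy(),
        segment_labels=labels,
        vertices=vertices,
        faces=faces,
        n_theta=n_theta,
        section_arclengths=section_s,
    )


def _check_mesh_quality(geometry: VesselGeometry) -> None:
    v = geometry.vertices
    f = geometry.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    if np.any(areas < 1e-12):
        raise ValueError("degenerate mesh: zero-area triangle present")


def generate_wss_field(
    geometry: VesselGeometry,
    waveform: FlowWaveform,
    fluid: FluidProperties = DEFAULT_FLUID,
    n_time: int = 32,
    *,
    n_harmonics: int = 8,
    azimuthal_amplitude: float = 0.0,
    azimuthal_phase: float = 0.0,
    osi_downstream: float = 0.0,
    osi_recovery_length: float = 10.0,
) -> SurfaceWssSeries:
    """Pulsatile WSS vectors on the lumen surface.

    Rings at the inlet radius carry the analytic Womersley wall-shear series
    exactly; narrowed rings use the quasi-steady Poiseuille scaling
    tau(t) = 4 mu Q(t) / (pi R(z)^3).  Downstream of a stenosis throat an
    oscillatory zero-mean component is blended in (weight ``osi_downstream``
    decaying over ``osi_recovery_length`` mm) to create high-OSI zones.
    ``azimuthal_amplitude`` adds a multiplicative cos(theta - phase)
    modulation of the magnitude (must be < 1).
    """
    if waveform.period <= 0:
        raise ValueError("waveform period must be positive")
    if n_time < 8:
        raise ValueError("n_time must be >= 8")
    if not 0.0 <= azimuthal_amplitude < 1.0:
        raise ValueError("azimuthal_amplitude must be in [0, 1)")
    _check_mesh_quality(geometry)

    mu = fluid.mu_ref
    r0 = float(geometry.radius_profile[0])
    wom = womersley_wall_shear(
        waveform, r0, fluid, n_time, n_harmonics=n_harmonics
    )
    times = wom.times
    tau0 = wom.wall_shear_series  # exact analytic series at the inlet radius

    q_si = waveform.evaluate(times, n_harmonics=n_harmonics) * _ML_S
    radii = geometry.radius_profile
    ring_tau = np.empty((geometry.n_rings, n_time))
    at_inlet_radius = np.abs(radii - r0) < 1e-12
    ring_tau[at_inlet_radius] = tau0
    narrow = ~at_inlet_radius
    if np.any(narrow):
        ring_tau[narrow] = (
            4.0 * mu * q_si[None, :] / (np.pi * (radii[narrow, None] * _MM) ** 3)
        )

    osc_weight = np.zeros(geometry.n_rings)
    if osi_downstream > 0 and np.any(narrow):
        throat = int(np.argmin(radii))
        s = geometry.arclength
        after = s > s[throat]
        osc_weight[after] = osi_downstream * np.clip(
            1.0 - (s[after] - s[throat]) / osi_recovery_length, 0.0, 1.0
        )
    if np.any(osc_weight > 0):
        amp = np.mean(np.abs(ring_tau), axis=1)
        osc = np.sin(2.0 * np.pi * times / waveform.period)
        ring_tau = (
            (1.0 - osc_weight[:, None]) * ring_tau
            + (osc_weight * amp)[:, None] * osc[None, :]
        )

    ring_idx = geometry.ring_index()
    tau_v = ring_tau[ring_idx]  # (n_vertices, n_time)
    if azimuthal_amplitude > 0:
        theta = geometry.vertex_angles()
        factor = 1.0 + azimuthal_amplitude * np.cos(theta - azimuthal_phase)
        tau_v = tau_v * factor[:, None]

    # meridian (axial) surface tangent per vertex via ring neighbours
    n_theta = geometry.n_theta
    v = geometry.vertices.reshape(geometry.n_rings, n_theta, 3)
    tang = np.empty_like(v)
    tang[1:-1] = v[2:] - v[:-2]
    tang[0] = v[1] - v[0]
    tang[-1] = v[-1] - v[-2]
    tang /= np.linalg.norm(tang, axis=2, keepdims=True)
    tang = tang.reshape(-1, 3)

    wss = tau_v[:, :, None] * tang[:, None, :]
    return SurfaceWssSeries(
        vertices=geometry.vertices,
        times=times,
        wss=wss,
        period=waveform.period,
    )


# --------------------------------------------------------------------------
# histology mask synthesis


@dataclass
class MaskGenWarning:
    section_id: str
    bin_index: int
    component: str
    message: str


def _circle(radius: float, n: int = 128) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t)])


def generate_histology_sections(
    geometry: VesselGeometry,
    sections: Sequence[CrossSectionFrame],
    bin_tertiles: pd.DataFrame,
    effects: Sequence[EffectSpec],
    pixel_size: float = 0.05,
    seed: int = 0,
    *,
    n_bins: int = 8,
    wall_thickness: float = 2.5,
    default_cap: float = 0.25,
    patient_intercepts: Mapping[str, float] | None = None,
    artifact_bins: Sequence[tuple[str, int]] = (),
    artifact_fill: float = 0.6,
) -> tuple[list[SectionLabelMask], pd.DataFrame, list[MaskGenWarning]]:
    """Raster label masks whose per-sector component areas realise the
    programmed tertile effects.

    ``bin_tertiles`` must carry columns section_id, bin_index,
    tawss_tertile, osi_tertile.  Component pixels are laid down in radial
    depth bands inside each sector: the cap (plain intima) from the lumen to
    the cap-thickness target, then the NC band sized to the NC area target
    (fibrin nests inside it), with macrophages filling non-NC pixels from
    the lumen outward.  Realized (pixel-quantized, post-artifact) values are
    recorded in the returned truth table.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rng = np.random.default_rng(seed)
    intercepts = dict(patient_intercepts or {})
    artifact_set = set(artifact_bins)
    px_area = pixel_size**2
    tert = bin_tertiles.set_index(["section_id", "bin_index"])
    bad = set(np.unique(bin_tertiles[["tawss_tertile", "osi_tertile"]].to_numpy())) - set(
        stats.TERTILE_LABELS
    )
    if bad:
        raise ValueError(f"tertile labels outside {stats.TERTILE_LABELS}: {bad}")

    masks: list[SectionLabelMask] = []
    truth_rows: list[dict] = []
    warnings_out: list[MaskGenWarning] = []

    for frame in sections:
        radius = float(geometry.radius_at(frame.axial_position))
        half_extent = radius + wall_thickness + 0.3
        n_px = int(np.ceil(2.0 * half_extent / pixel_size))
        origin = np.array([-(n_px - 1) / 2.0 * pixel_size] * 2)
        xs = origin[0] + np.arange(n_px) * pixel_size
        x, y = np.meshgrid(xs, xs)
        r = np.hypot(x, y)
        depth = r - radius
        pixels = np.zeros((n_px, n_px), dtype=np.uint8)
        tissue = (depth >= 0.0) & (depth < wall_thickness)
        pixels[tissue] = CLASS_CODES["intima"]

        theta = np.arctan2(y, x) % (2.0 * np.pi)
        sector = np.minimum(
            np.floor(theta / (2.0 * np.pi / n_bins)).astype(int), n_bins - 1
        )

        effect_by_comp = {e.component: e for e in effects}
        for k in range(n_bins):
            try:
                row = tert.loc[(frame.section_id, k)]
            except KeyError as exc:
                raise KeyError(
                    f"missing tertile labels for ({frame.section_id!r}, {k})"
                ) from exc
            labels = {"tawss": row["tawss_tertile"], "osi": row["osi_tertile"]}

            def target_for(comp: str) -> float | None:
                eff = effect_by_comp.get(comp)
                if eff is None:
                    return None
                value = (
                    eff.mean_for(labels[eff.driver])
                    + intercepts.get(comp, 0.0)
                    + (rng.normal(0.0, eff.residual_sd) if eff.residual_sd else 0.0)
                )
                return max(value, 0.0)

            in_sector = tissue & (sector == k)
            flat = np.flatnonzero(in_sector.ravel())
            order = np.argsort(depth.ravel()[flat], kind="stable")
            flat = flat[order]
            depths = depth.ravel()[flat]
            codes = pixels.ravel()

            cap_target = target_for("cap")
            cap_t = cap_target if cap_target is not None else default_cap

            nc_target = target_for("nc")
            nc_pix = np.array([], dtype=int)
            if nc_target is not None and nc_target > 0:
                eligible = flat[depths >= cap_t]
                n_nc = int(round(nc_target / px_area))
                if n_nc > eligible.size:
                    warnings_out.append(
                        MaskGenWarning(
                            frame.section_id, k, "nc",
                            "requested NC area exceeds sector capacity; capped",
                        )
                    )
                    n_nc = eligible.size
                nc_pix = eligible[:n_nc]
                codes[nc_pix] = CLASS_CODES["nc"]

            fib_target = target_for("fibrin")
            if fib_target is not None and fib_target > 0:
                n_fib = int(round(fib_target / px_area))
                nested = min(n_fib, nc_pix.size)
                codes[nc_pix[:nested]] = CLASS_CODES["nc_fibrin"]
                extra = n_fib - nested
                if extra > 0:
                    free = flat[(depths >= cap_t)]
                    free = free[codes[free] == CLASS_CODES["intima"]]
                    if extra > free.size:
                        warnings_out.append(
                            MaskGenWarning(
                                frame.section_id, k, "fibrin",
                                "requested fibrin area exceeds sector capacity; capped",
                            )
                        )
                        extra = free.size
                    codes[free[:extra]] = CLASS_CODES["fibrin"]

            mac_target = target_for("macrophage")
            if mac_target is not None and mac_target > 0:
                free = flat[codes[flat] == CLASS_CODES["intima"]]
                n_mac = int(round(mac_target / px_area))
                if n_mac > free.size:
                    warnings_out.append(
                        MaskGenWarning(
                            frame.section_id, k, "macrophage",
                            "requested macrophage area exceeds sector capacity; capped",
                        )
                    )
                    n_mac = free.size
                codes[free[:n_mac]] = CLASS_CODES["macrophage"]

            if (frame.section_id, k) in artifact_set:
                # overwrite an angular wedge of the sector with artifact
                sector_lo = k * 2.0 * np.pi / n_bins
                wedge = in_sector & (
                    theta < sector_lo + artifact_fill * 2.0 * np.pi / n_bins
                )
                wflat = np.flatnonzero(wedge.ravel())
                was_mac = codes[wflat] == CLASS_CODES["macrophage"]
                codes[wflat[was_mac]] = CLASS_CODES["artifact_macrophage"]
                codes[wflat[~was_mac]] = CLASS_CODES["artifact"]

            # realized, post-artifact values (pixel-quantized ground truth)
            sel = codes[flat]
            realized = {
                "nc": np.isin(sel, list(histology.NC_CODES)).sum() * px_area,
                "fibrin": np.isin(sel, list(histology.FIBRIN_CODES)).sum() * px_area,
                "macrophage": np.isin(sel, list(histology.MACROPHAGE_CODES)).sum()
                * px_area,
            }
            nc_mask_sel = np.isin(sel, list(histology.NC_CODES))
            realized["cap"] = (
                float(depths[nc_mask_sel].min()) if nc_mask_sel.any() else np.nan
            )
            for eff in effects:
                truth_rows.append(
                    {
                        "patient_id": frame.patient_id,
                        "section_id": frame.section_id,
                        "bin_index": k,
                        "component": eff.component,
                        "driver": eff.driver,
                        "tertile": labels[eff.driver],
                        "target": target_for(eff.component),
                        "realized": realized[eff.component],
                        "artifact": (frame.section_id, k) in artifact_set,
                    }
                )

        masks.append(
            SectionLabelMask(
                pixels=pixels,
                pixel_size=pixel_size,
                origin=origin,
                center=np.zeros(2),
                angular_reference=np.array([1.0, 0.0]),
                lumen_contour=_circle(radius),
                section_id=frame.section_id,
                patient_id=frame.patient_id,
                axial_position=frame.axial_position,
            )
        )

    truth = pd.DataFrame(truth_rows)
    return masks, truth, warnings_out


# --------------------------------------------------------------------------
# whole-study generation


@dataclass
class SyntheticStudy:
    """A complete synthetic study with recorded ground truth."""

    patients: list[str]
    geometries: dict[str, VesselGeometry]
    waveforms: dict[str, FlowWaveform]
    wss_series: dict[str, SurfaceWssSeries]
    metric_maps: dict[str, MetricMap]
    centerlines: dict[str, Centerline]
    sections: list[CrossSectionFrame]
    masks: dict[str, SectionLabelMask]      # by section_id
    truth: pd.DataFrame
    effects: tuple[EffectSpec, ...]
    intercepts: dict[str, dict[str, float]]  # patient -> component -> intercept
    artifact_bins: frozenset[tuple[str, int]]
    seed: int
    mask_warnings: list[MaskGenWarning] = field(default_factory=list)

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    def measures(
        self, artifact_threshold: float = 0.5, ray_step_deg: float = 1.0
    ) -> dict[str, list[histology.PlaqueBinMeasures]]:
        out = {}
        for frame in self.sections:
            mask = self.masks[frame.section_id]
            out[frame.section_id] = histology.exclude_bins(
                histology.measure_mask(mask, ray_step_deg=ray_step_deg),
                artifact_threshold,
            )
        return out

    def bin_table(
        self,
        artifact_threshold: float = 0.5,
        half_window: float = 0.3,
        n_bins: int = 8,
        mismatch_flags: Sequence[tuple[str, int]] = (),
        ray_step_deg: float = 1.0,
    ) -> pd.DataFrame:
        from .colocalization import build_bin_table

        return build_bin_table(
            self.metric_maps,
            self.centerlines,
            self.sections,
            self.measures(artifact_threshold, ray_step_deg),
            n_bins=n_bins,
            half_window=half_window,
            mismatch_flags=mismatch_flags,
        )


def _section_frames(
    geometry: VesselGeometry, patient_id: str
) -> list[CrossSectionFrame]:
    frames = []
    cl = geometry.centerline
    for k, s in enumerate(geometry.section_arclengths):
        idx = int(np.argmin(np.abs(geometry.arclength - s)))
        if idx == 0:
            tangent = cl[1] - cl[0]
        elif idx == len(cl) - 1:
            tangent = cl[-1] - cl[-2]
        else:
            tangent = cl[idx + 1] - cl[idx - 1]
        normal = tangent / np.linalg.norm(tangent)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(ref @ normal) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        ref = ref - (ref @ normal) * normal
        ref /= np.linalg.norm(ref)
        frames.append(
            CrossSectionFrame(
                section_id=f"{patient_id}-S{k:02d}",
                patient_id=patient_id,
                axial_position=float(geometry.arclength[idx]),
                center=cl[idx],
                normal=normal,
                angular_reference=ref,
            )
        )
    return frames


def generate_study(
    n_patients: int,
    sections_per_patient: int | Sequence[int],
    effects: Sequence[EffectSpec],
    seed: int = 0,
    *,
    pixel_size: float = 0.05,
    n_time: int = 32,
    fluid: FluidProperties = DEFAULT_FLUID,
    base_radius_range: tuple[float, float] = (2.6, 3.4),
    stenosis_range: tuple[float, float] = (0.35, 0.7),
    flow_scale_range: tuple[float, float] = (0.6, 1.8),
    azimuthal_amplitude: float = 0.35,
    osi_downstream: float = 0.8,
    wall_thickness: float = 2.5,
    n_artifact_bins: int = 0,
    n_bins: int = 8,
    half_window: float = 0.3,
    ring_spacing: float = 0.15,
    n_theta: int = 32,
) -> SyntheticStudy:
    """Generate a full multi-patient study.

    Per-patient geometry, stenosis severity, and flow scale are drawn from
    configurable ranges so that absolute WSS levels differ between patients
    and patient-specific tertiles are required.  The per-bin tertile labels
    that drive mask composition are computed from the generated WSS field
    itself, closing the loop for downstream parameter recovery.
    """
    if n_patients < 2:
        raise ValueError("need >= 2 patients for a random-intercept design")
    if isinstance(sections_per_patient, int):
        sections_counts = [sections_per_patient] * n_patients
    else:
        sections_counts = list(sections_per_patient)
        if len(sections_counts) != n_patients:
            raise ValueError("sections_per_patient list must match n_patients")

    effects = tuple(effects)
    seq = np.random.SeedSequence(seed)
    child_seeds = seq.spawn(n_patients + 1)
    study_rng = np.random.default_rng(child_seeds[-1])

    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    geometries: dict[str, VesselGeometry] = {}
    waveforms: dict[str, FlowWaveform] = {}
    series: dict[str, SurfaceWssSeries] = {}
    maps: dict[str, MetricMap] = {}
    centerlines: dict[str, Centerline] = {}
    all_sections: list[CrossSectionFrame] = []
    intercepts: dict[str, dict[str, float]] = {}
    per_patient_bins: dict[str, pd.DataFrame] = {}

    for pid, n_sec, child in zip(patients, sections_counts, child_seeds):
        rng = np.random.default_rng(child)
        base_radius = rng.uniform(*base_radius_range)
        degree = rng.uniform(*stenosis_range)
        geometry = generate_vessel(
            "stenotic",
            base_radius=base_radius,
            stenosis_degree=degree,
            n_sections=n_sec,
            ring_spacing=ring_spacing,
            n_theta=n_theta,
        )
        flow_scale = rng.uniform(*flow_scale_range)
        waveform = parametric_waveform(
            mean_flow=6.0 * flow_scale,
            harmonics=(
                (rng.uniform(0.3, 0.7), rng.uniform(0, 2 * np.pi)),
                (rng.uniform(0.1, 0.3), rng.uniform(0, 2 * np.pi)),
            ),
        )
        wss = generate_wss_field(
            geometry,
            waveform,
            fluid,
            n_time,
            azimuthal_amplitude=azimuthal_amplitude,
            azimuthal_phase=rng.uniform(0, 2 * np.pi),
            osi_downstream=osi_downstream,
        )
        mmap = wss_metrics.metric_map(wss)
        cl = geometry.as_centerline()
        frames = _section_frames(geometry, pid)

        rows = [
            sector_means(mmap, cl, f, n_bins=n_bins, half_window=half_window)
            for f in frames
        ]
        bins = pd.concat(rows, ignore_index=True)
        per_patient_bins[pid] = bins

        geometries[pid] = geometry
        waveforms[pid] = waveform
        series[pid] = wss
        maps[pid] = mmap
        centerlines[pid] = cl
        all_sections.extend(frames)
        intercepts[pid] = {
            e.component: (
                float(rng.normal(0.0, e.patient_sd)) if e.patient_sd > 0 else 0.0
            )
            for e in effects
        }

    # patient-specific tertiles of the generated per-bin WSS metrics
    masks: dict[str, SectionLabelMask] = {}
    truth_frames = []
    warnings_all: list[MaskGenWarning] = []

    # choose artifact bins study-wide
    all_bins = [(f.section_id, k) for f in all_sections for k in range(n_bins)]
    if n_artifact_bins > len(all_bins):
        raise ValueError("n_artifact_bins exceeds the number of bins")
    artifact_idx = study_rng.choice(
        len(all_bins), size=n_artifact_bins, replace=False
    )
    artifact_bins = frozenset(all_bins[i] for i in artifact_idx)

    for pid, child in zip(patients, child_seeds):
        bins = per_patient_bins[pid]
        labels = bins.copy()
        for metric, col in (("tawss", "tawss_mean"), ("osi", "osi_mean")):
            ta = stats.patient_tertiles(
                bins[col].to_numpy(dtype=float), pid, metric
            )
            labels[f"{metric}_tertile"] = ta.labels
        tert = labels[["section_id", "bin_index", "tawss_tertile", "osi_tertile"]]
        frames = [f for f in all_sections if f.patient_id == pid]
        mask_seed = int(np.random.default_rng(child).integers(0, 2**31 - 1))
        patient_masks, truth, warns = generate_histology_sections(
            geometries[pid],
            frames,
            tert,
            effects,
            pixel_size=pixel_size,
            seed=mask_seed,
            n_bins=n_bins,
            wall_thickness=wall_thickness,
            patient_intercepts=intercepts[pid],
            artifact_bins=[b for b in artifact_bins if b[0].startswith(pid + "-")],
        )
        for m in patient_masks:
            masks[m.section_id] = m
        truth_frames.append(truth)
        warnings_all.extend(warns)

    return SyntheticStudy(
        patients=patients,
        geometries=geometries,
        waveforms=waveforms,
        wss_series=series,
        metric_maps=maps,
        centerlines=centerlines,
        sections=all_sections,
        masks=masks,
        truth=pd.concat(truth_frames, ignore_index=True),
        effects=effects,
        intercepts=intercepts,
        artifact_bins=artifact_bins,
        seed=seed,
        mask_warnings=warnings_all,
    )


def simulate_bin_records(
    n_patients: int,
    bins_per_patient: int,
    effect: EffectSpec,
    seed: int = 0,
    outcome_col: str | None = None,
) -> pd.DataFrame:
    """Bin-level outcome simulation without rasterization.

    Tertile labels are balanced within each patient (shuffled), the outcome
    is group mean + patient intercept + residual noise.  Used for the
    statistical recovery and type-I-error simulation suites, where raster
    quantization is irrelevant.
    """
    rng = np.random.default_rng(seed)
    factor_col = f"{effect.driver}_tertile"
    outcome_col = outcome_col or (
        "cap_thickness_mm"
        if effect.component == "cap"
        else f"{effect.component}_area_mm2"
    )
    rows = []
    labels_cycle = np.array(
        (list(stats.TERTILE_LABELS) * (bins_per_patient // 3 + 1))[:bins_per_patient]
    )
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        b = rng.normal(0.0, effect.patient_sd) if effect.patient_sd > 0 else 0.0
        labels = labels_cycle.copy()
        rng.shuffle(labels)
        noise = (
            rng.normal(0.0, effect.residual_sd, bins_per_patient)
            if effect.residual_sd > 0
            else np.zeros(bins_per_patient)
        )
        for lab, eps in zip(labels, noise):
            rows.append(
                {
                    "patient_id": pid,
                    factor_col: lab,
                    outcome_col: effect.mean_for(lab) + b + eps,
                }
            )
    return pd.DataFrame(rows)
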