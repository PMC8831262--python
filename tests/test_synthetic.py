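import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from shearhist.hemodynamics import FlowWaveform, parametric_waveform, womersley_wall_shear
from shearhist.histology import component_area_per_bin
from shearhist.synthetic import (
    EffectSpec,
    generate_histology_sections,
    generate_study,
    generate_vessel,
    generate_wss_field,
    _section_frames,
)


class TestGenerateVessel:
    def test_straight_constant_radius(self):
        geom = generate_vessel("straight", base_radius=3.0, n_sections=5)
        assert np.allclose(geom.radius_profile, 3.0)

    def test_stenotic_throat_radius(self):
        geom = generate_vessel("stenotic", base_radius=3.0, stenosis_degree=0.5,
                               n_sections=12)
        assert geom.radius_profile.min() == pytest.approx(1.5, abs=1e-6)

    def test_area_ratio_closed_form(self):
        # throat/inlet cross-section area ratio = (1 - degree)^2
        degree = 0.7
        geom = generate_vessel("stenotic", base_radius=3.0, stenosis_degree=degree,
                               n_sections=12)
        ratio = (geom.radius_profile.min() / geom.radius_profile[0]) ** 2
        assert ratio == pytest.approx((1.0 - degree) ** 2, abs=1e-6)

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            generate_vessel("stenotic", stenosis_degree=1.0)
        with pytest.raises(ValueError):
            generate_vessel("stenotic", stenosis_degree=-0.1)
        with pytest.raises(ValueError):
            generate_vessel("straight", base_radius=-1.0)

    def test_flow_extensions_five_radii(self):
        geom = generate_vessel("straight", base_radius=3.0, n_sections=5)
        ext = geom.segment_labels == "extension"
        # inlet extension spans exactly 5 * radius of arclength
        first_main = np.flatnonzero(~ext)[0]
        assert geom.arclength[first_main] == pytest.approx(15.0, abs=0.2)

    def test_vertices_on_tube_surface(self):
        geom = generate_vessel("stenotic", base_radius=3.0, stenosis_degree=0.6,
                               n_sections=8)
        d, idx = cKDTree(geom.centerline).query(geom.vertices)
        # each vertex sits within a ring spacing of its ring radius
        assert np.all(np.abs(d - geom.radius_profile[idx]) < 0.2)

    def test_bifurcation_segments(self):
        geom = generate_vessel("bifurcation", base_radius=3.0, n_sections=8)
        labels = set(geom.segment_labels)
        assert {"CCA", "ICA", "ECA", "extension"} <= labels
        assert np.all(np.diff(geom.arclength) > 0)


class TestGenerateWssField:
    def test_steady_poiseuille_everywhere(self, fluid):
        geom = generate_vessel("straight", base_radius=3.0, n_sections=4)
        wf = FlowWaveform(1.0, np.full(16, 5.0))
        series = generate_wss_field(geom, wf, fluid, n_time=8)
        expected = 4.0 * fluid.mu_ref * 5e-6 / (np.pi * (3e-3) ** 3)
        mags = np.linalg.norm(series.wss, axis=2)
        assert np.allclose(mags, expected, rtol=1e-9)

    def test_pulsatile_matches_womersley_oracle(self, fluid):
        geom = generate_vessel("straight", base_radius=3.0, n_sections=4)
        wf = parametric_waveform()
        series = generate_wss_field(geom, wf, fluid, n_time=16)
        oracle = womersley_wall_shear(wf, 3.0, fluid, n_time=16).wall_shear_series
        signed = series.wss @ np.array([0.0, 0.0, 1.0])
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(signed - oracle[None, :])) / scale < 1e-6

    def test_stenotic_quasi_steady_scaling(self, fluid):
        geom = generate_vessel("stenotic", base_radius=3.0, stenosis_degree=0.5,
                               n_sections=12)
        wf = FlowWaveform(1.0, np.full(16, 5.0))
        series = generate_wss_field(geom, wf, fluid, n_time=8)
        mags = np.linalg.norm(series.wss, axis=2)
        ring = geom.ring_index()
        throat_ring = int(np.argmin(geom.radius_profile))
        inlet = mags[ring == 0].mean()
        throat = mags[ring == throat_ring].mean()
        expected = (geom.radius_profile[0] / geom.radius_profile.min()) ** 3
        assert throat / inlet == pytest.approx(expected, rel=1e-9)

    def test_vectors_tangent_to_straight_tube(self, fluid):
        geom = generate_vessel("straight", base_radius=3.0, n_sections=4)
        series = generate_wss_field(geom, parametric_waveform(), fluid, n_time=8)
        radial = geom.vertices.copy()
        radial[:, 2] = 0.0
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        dots = np.einsum("ntc,nc->nt", series.wss, radial)
        assert np.max(np.abs(dots)) < 1e-9

    def test_downstream_oscillation_raises_osi(self, fluid):
        from shearhist.wss_metrics import metric_map

        geom = generate_vessel("stenotic", base_radius=3.0, stenosis_degree=0.6,
                               n_sections=12)
        series = generate_wss_field(
            geom, parametric_waveform(), fluid, n_time=16, osi_downstream=0.9
        )
        mm = metric_map(series)
        s = geom.arclength[geom.ring_index()]
        throat_s = geom.arclength[int(np.argmin(geom.radius_profile))]
        downstream = (s > throat_s + 1.0) & (s < throat_s + 5.0)
        upstream = s < throat_s - 5.0
        assert mm.osi[downstream].mean() > mm.osi[upstream].mean() + 0.05

    def test_n_time_validation(self, fluid):
        geom = generate_vessel("straight", n_sections=3)
        with pytest.raises(ValueError):
            generate_wss_field(geom, parametric_waveform(), fluid, n_time=4)

    def test_degenerate_mesh_rejected(self, fluid):
        import dataclasses

        geom = generate_vessel("straight", n_sections=3)
        vertices = geom.vertices.copy()
        vertices[1] = vertices[0]  # collapse an edge -> zero-area triangles
        bad = dataclasses.replace(geom, vertices=vertices)
        with pytest.raises(ValueError):
            generate_wss_field(bad, parametric_waveform(), n_time=8)


class TestGenerateHistologySections:
    def make_inputs(self, group_means=(1.0, 1.0, 2.0), labels=("low", "mid", "high")):
        geom = generate_vessel("straight", base_radius=3.0, n_sections=2)
        frames = _section_frames(geom, "P01")
        rows = []
        for f in frames:
            for k in range(8):
                rows.append(
                    {
                        "section_id": f.section_id,
                        "bin_index": k,
                        "tawss_tertile": labels[k % 3],
                        "osi_tertile": labels[(k + 1) % 3],
                    }
                )
        return geom, frames, pd.DataFrame(rows)

    def test_noise_free_exact_areas(self):
        geom, frames, tert = self.make_inputs()
        effects = [EffectSpec("nc", "tawss", (1.0, 1.0, 2.0))]
        masks, truth, warns = generate_histology_sections(
            geom, frames, tert, effects, pixel_size=0.05, seed=0
        )
        assert not warns
        px = 0.05**2
        for mask in masks:
            measures = component_area_per_bin(mask)
            for m in measures:
                row = truth[
                    (truth.section_id == mask.section_id)
                    & (truth.bin_index == m.bin_index)
                    & (truth.component == "nc")
                ].iloc[0]
                # measured equals programmed group mean within one pixel
                assert m.nc_area == pytest.approx(row["target"], abs=px)
                # and equals recorded realized value exactly
                assert m.nc_area == pytest.approx(row["realized"], abs=1e-12)

    def test_determinism(self):
        geom, frames, tert = self.make_inputs()
        effects = [EffectSpec("nc", "tawss", (1.0, 1.5, 2.0), residual_sd=0.3)]
        m1, t1, _ = generate_histology_sections(
            geom, frames, tert, effects, seed=42
        )
        m2, t2, _ = generate_histology_sections(
            geom, frames, tert, effects, seed=42
        )
        for a, b in zip(m1, m2):
            assert np.array_equal(a.pixels, b.pixels)
        pd.testing.assert_frame_equal(t1, t2)

    def test_capacity_warning(self):
        geom, frames, tert = self.make_inputs()
        effects = [EffectSpec("nc", "tawss", (500.0, 500.0, 500.0))]
        _, _, warns = generate_histology_sections(
            geom, frames, tert, effects, pixel_size=0.1, seed=0
        )
        assert warns
        assert all(w.component == "nc" for w in warns)

    def test_artifact_injection(self):
        geom, frames, tert = self.make_inputs()
        sid = frames[0].section_id
        masks, _, _ = generate_histology_sections(
            geom, frames, tert,
            [EffectSpec("nc", "tawss", (1.0, 1.0, 1.0))],
            pixel_size=0.1, seed=0, artifact_bins=[(sid, 2)],
        )
        measures = component_area_per_bin(masks[0])
        assert measures[2].artifact_fraction > 0.5
        assert all(
            m.artifact_fraction == 0.0 for m in measures if m.bin_index != 2
        )

    def test_cap_effect_controls_cap_thickness(self):
        from shearhist.histology import cap_thickness_per_bin

        geom, frames, tert = self.make_inputs()
        effects = [
            EffectSpec("nc", "tawss", (1.5, 1.5, 1.5)),
            EffectSpec("cap", "osi", (0.8, 0.5, 0.3)),
        ]
        masks, truth, _ = generate_histology_sections(
            geom, frames, tert, effects, pixel_size=0.05, seed=0
        )
        caps = cap_thickness_per_bin(masks[0])
        cap_truth = truth[
            (truth.section_id == masks[0].section_id) & (truth.component == "cap")
        ].set_index("bin_index")
        for k in range(8):
            assert caps[k] == pytest.approx(cap_truth.loc[k, "target"], abs=0.08)


class TestGenerateStudy:
    def test_counting(self):
        effects = [EffectSpec("nc", "tawss", (1.0, 1.0, 2.0))]
        study = generate_study(3, 4, effects, seed=0, pixel_size=0.1)
        assert study.n_sections == 12
        table = study.bin_table()
        assert len(table) == 96

    def test_determinism_downstream(self):
        effects = [EffectSpec("nc", "tawss", (1.0, 1.3, 2.0), residual_sd=0.2)]
        t1 = generate_study(2, 3, effects, seed=5, pixel_size=0.1).bin_table()
        t2 = generate_study(2, 3, effects, seed=5, pixel_size=0.1).bin_table()
        pd.testing.assert_frame_equal(t1, t2)

    def test_min_patients(self):
        with pytest.raises(ValueError):
            generate_study(1, 3, [EffectSpec("nc", "tawss", (1, 1, 2))], seed=0)

    def test_patient_scales_differ(self, noise_free_study):
        study = noise_free_study
        means = [study.metric_maps[p].tawss.mean() for p in study.patients]
        assert not np.allclose(means[0], means[1], rtol=0.01)

    def test_truth_closure(self, noise_free_study):
        """Areas recomputed from masks equal the recorded realized truth."""
        study = noise_free_study
        attr = {"nc": "nc_area", "macrophage": "macrophage_area"}
        for frame in study.sections:
            measures = component_area_per_bin(study.masks[frame.section_id])
            t = study.truth[study.truth.section_id == frame.section_id]
            for m in measures:
                for comp, a in attr.items():
                    row = t[(t.bin_index == m.bin_index) & (t.component == comp)]
                    assert getattr(m, a) == pytest.approx(
                        row.iloc[0]["realized"], abs=1e-12
                    )

    def test_smoke_end_to_end(self, noise_free_study):
        table = noise_free_study.bin_table()
        included = table[table.included]
        assert len(included) > 0
        assert np.isfinite(included["tawss_mean"]).all()
        assert np.isfinite(included["nc_area_mm2"]).all()
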