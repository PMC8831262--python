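"""Text-based on-disk study format (write with ``simulate``, read in files mode).

Layout under the study directory:

    study.json                 seed, patients, effects, intercepts, periods
    truth.csv                  programmed per-bin ground truth
    <patient>/centerline.csv   x_mm, y_mm, z_mm, arclength_mm, radius_mm, segment
    <patient>/waveform.csv     t_s, Q_ml_s
    <patient>/surface.vtk      legacy-ASCII polydata, WSS_t<k> vectors, TAWSS/OSI
    <patient>/sections.json    cross-section frames
    <patient>/masks/<sid>.tif  class-coded mask (+ .json sidecar)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import histology, vtk_io, wss_metrics
from .colocalization import Centerline, CrossSectionFrame
from .hemodynamics import FlowWaveform, read_waveform_csv, write_waveform_csv
from .synthetic import EffectSpec, SyntheticStudy, VesselGeometry
from .wss_metrics import SurfaceWssSeries


def write_study(study: SyntheticStudy, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": study.seed,
        "patients": study.patients,
        "effects": [dataclasses.asdict(e) for e in study.effects],
        "intercepts": study.intercepts,
        "artifact_bins": sorted(list(b) for b in study.artifact_bins),
        "periods": {p: study.wss_series[p].period for p in study.patients},
        "times": {p: study.wss_series[p].times.tolist() for p in study.patients},
        "n_theta": {p: study.geometries[p].n_theta for p in study.patients},
        "section_arclengths": {
            p: study.geometries[p].section_arclengths.tolist()
            for p in study.patients
        },
    }
    (outdir / "study.json").write_text(json.dumps(meta, indent=1))
    study.truth.to_csv(outdir / "truth.csv", index=False)

    for pid in study.patients:
        pdir = outdir / pid
        (pdir / "masks").mkdir(parents=True, exist_ok=True)
        geom = study.geometries[pid]
        pd.DataFrame(
            {
                "x_mm": geom.centerline[:, 0],
                "y_mm": geom.centerline[:, 1],
                "z_mm": geom.centerline[:, 2],
                "arclength_mm": geom.arclength,
                "radius_mm": geom.radius_profile,
                "segment": geom.segment_labels,
            }
        ).to_csv(pdir / "centerline.csv", index=False)
        write_waveform_csv(study.waveforms[pid], pdir / "waveform.csv")

        wss = study.wss_series[pid]
        mmap = study.metric_maps[pid]
        vectors = {
            f"WSS_t{k}": wss.wss[:, k, :] for k in range(len(wss.times))
        }
        vtk_io.write_polydata(
            pdir / "surface.vtk",
            wss.vertices,
            geom.faces,
            point_scalars={"TAWSS": mmap.tawss, "OSI": mmap.osi},
            point_vectors=vectors,
        )
        frames = [f for f in study.sections if f.patient_id == pid]
        (pdir / "sections.json").write_text(
            json.dumps(
                [
                    {
                        "section_id": f.section_id,
                        "patient_id": f.patient_id,
                        "axial_position": f.axial_position,
                        "center": f.center.tolist(),
                        "normal": f.normal.tolist(),
                        "angular_reference": f.angular_reference.tolist(),
                    }
                    for f in frames
                ],
                indent=1,
            )
        )
        for f in frames:
            histology.write_mask(
                study.masks[f.section_id], pdir / "masks" / f"{f.section_id}.tif"
            )


def read_study(study_dir) -> SyntheticStudy:
    study_dir = Path(study_dir)
    meta = json.loads((study_dir / "study.json").read_text())
    patients = meta["patients"]
    effects = tuple(EffectSpec(**{**e, "group_means": tuple(e["group_means"])})
                    for e in meta["effects"])

    geometries = {}
    waveforms = {}
    series = {}
    maps = {}
    centerlines = {}
    sections = []
    masks = {}

    for pid in patients:
        pdir = study_dir / pid
        cl = pd.read_csv(pdir / "centerline.csv")
        points, faces, point_data = vtk_io.read_polydata(pdir / "surface.vtk")
        times = np.asarray(meta["times"][pid])
        wss = np.stack(
            [point_data[f"WSS_t{k}"] for k in range(len(times))], axis=1
        )
        geom = VesselGeometry(
            centerline=cl[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            radius_profile=cl["radius_mm"].to_numpy(),
            arclength=cl["arclength_mm"].to_numpy(),
            segment_labels=cl["segment"].to_numpy(dtype=object),
            vertices=points,
            faces=faces,
            n_theta=meta["n_theta"][pid],
            section_arclengths=np.asarray(meta["section_arclengths"][pid]),
        )
        geometries[pid] = geom
        waveforms[pid] = read_waveform_csv(pdir / "waveform.csv")
        s = SurfaceWssSeries(
            vertices=points, times=times, wss=wss, period=meta["periods"][pid]
        )
        series[pid] = s
        maps[pid] = wss_metrics.metric_map(s)
        centerlines[pid] = geom.as_centerline()
        for rec in json.loads((pdir / "sections.json").read_text()):
            frame = CrossSectionFrame(
                section_id=rec["section_id"],
                patient_id=rec["patient_id"],
                axial_position=rec["axial_position"],
                center=np.asarray(rec["center"]),
                normal=np.asarray(rec["normal"]),
                angular_reference=np.asarray(rec["angular_reference"]),
            )
            sections.append(frame)
            masks[frame.section_id] = histology.read_mask(
                pdir / "masks" / f"{frame.section_id}.tif"
            )

    truth_path = study_dir / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    return SyntheticStudy(
        patients=patients,
        geometries=geometries,
        waveforms=waveforms,
        wss_series=series,
        metric_maps=maps,
        centerlines=centerlines,
        sections=sections,
        masks=masks,
        truth=truth,
        effects=effects,
        intercepts=meta["intercepts"],
        artifact_bins=frozenset(tuple(b) for b in meta["artifact_bins"]),
        seed=meta["seed"],
    )
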