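"""End-to-end orchestration: generate/ingest -> metrics -> binning ->
histology quantification -> registration QC -> statistics -> report.

All stages are deterministic under a fixed seed, and the section/bin
bookkeeping identities (included + excluded = total, one primary exclusion
reason per excluded record) are enforced on every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from skimage.draw import polygon as draw_polygon

from . import registration_qc, stats
from .colocalization import REASON_MISMATCH
from .hemodynamics import FluidProperties
from .synthetic import EffectSpec, SyntheticStudy, generate_study

logger = logging.getLogger("shearhist")

SECTION_REASONS = ("deformation", "stenotic-gradient", "low-snr")

OUTCOME_COLUMNS = (
    "nc_area_mm2",
    "fibrin_area_mm2",
    "macrophage_area_mm2",
    "cap_thickness_mm",
)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class InflowConfig:
    target_tawss: float = 0.9       # Pa, cycle-averaged CCA wall shear
    heart_rate_bpm: float = 68.0
    mean_flow_ml_s: float = 6.0
    n_harmonics: int = 8


@dataclass(frozen=True)
class BinningConfig:
    n_bins: int = 8                 # 45-degree sectors
    half_window_mm: float = 0.3     # axial averaging window


DEFAULT_EFFECTS = (
    EffectSpec("nc", "tawss", (1.0, 1.2, 2.0), patient_sd=0.3, residual_sd=0.5),
    EffectSpec("macrophage", "osi", (0.8, 0.5, 0.3), patient_sd=0.1, residual_sd=0.2),
    EffectSpec("fibrin", "tawss", (0.4, 0.4, 0.4), patient_sd=0.1, residual_sd=0.2),
    EffectSpec("cap", "osi", (0.5, 0.35, 0.25), patient_sd=0.05, residual_sd=0.08),
)


@dataclass(frozen=True)
class RunConfig:
    mode: str = "synthetic"
    seed: int = 0
    outdir: str | None = None
    study_dir: str | None = None          # files mode input
    n_patients: int = 11
    sections_per_patient: int | tuple[int, ...] = 8
    fluid: FluidProperties = field(default_factory=FluidProperties)
    inflow: InflowConfig = field(default_factory=InflowConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    artifact_threshold: float = 0.5
    effects: tuple[EffectSpec, ...] = DEFAULT_EFFECTS
    section_exclusions: Mapping[str, int] = field(
        default_factory=lambda: {r: 0 for r in SECTION_REASONS}
    )
    bin_exclusions: Mapping[str, int] = field(
        default_factory=lambda: {"artifact": 0, "registration_mismatch": 0}
    )
    pixel_size: float = 0.05
    qc_jitter_mm: float = 0.15
    qc_noise_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        unknown = set(self.section_exclusions) - set(SECTION_REASONS)
        if unknown:
            raise ValueError(f"unknown section exclusion reasons: {sorted(unknown)}")
        unknown = set(self.bin_exclusions) - {"artifact", "registration_mismatch"}
        if unknown:
            raise ValueError(f"unknown bin exclusion reasons: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(key, klass):
            if key in data and isinstance(data[key], Mapping):
                sub = dict(data[key])
                sub_known = {f.name for f in dataclasses.fields(klass)}
                sub_unknown = set(sub) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown config keys under {key!r}: {sorted(sub_unknown)}"
                    )
                data[key] = klass(**sub)

        build("fluid", FluidProperties)
        build("inflow", InflowConfig)
        build("binning", BinningConfig)
        if "effects" in data:
            data["effects"] = tuple(
                e
                if isinstance(e, EffectSpec)
                else EffectSpec(**{**e, "group_means": tuple(e["group_means"])})
                for e in data["effects"]
            )
        if isinstance(data.get("sections_per_patient"), list):
            data["sections_per_patient"] = tuple(data["sections_per_patient"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunReport:
    sections_total: int
    sections_included: int
    section_exclusions: dict[str, int]
    bins_total: int
    bins_included: int
    bin_exclusions: dict[str, int]
    pct_sections_included: int
    pct_bins_included: int
    qc: dict[str, float]
    outputs: list[str]

    def __post_init__(self) -> None:
        if self.sections_included + sum(self.section_exclusions.values()) != (
            self.sections_total
        ):
            raise PipelineError("section bookkeeping identity violated")
        if self.bins_included + sum(self.bin_exclusions.values()) != self.bins_total:
            raise PipelineError("bin bookkeeping identity violated")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def summarize_exclusions(records) -> dict[str, int]:
    """Counts of excluded records by (single, mandatory) primary reason."""
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    counts: dict[str, int] = {}
    for rec in records:
        if rec.get("included", True):
            continue
        reasons = rec.get("reasons")
        if reasons is None:
            reason = rec.get("exclusion_reason")
            reasons = [reason] if reason not in (None, "") else []
        if len(reasons) != 1:
            raise PipelineError(
                f"excluded record must carry exactly one reason, got {reasons!r}"
            )
        counts[reasons[0]] = counts.get(reasons[0], 0) + 1
    return counts


def _allocate_section_exclusions(
    counts_per_patient: Sequence[int],
    exclusions: Mapping[str, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign section-level exclusion reasons to random section slots,
    keeping at least one included section per patient."""
    slots = [
        (p, s) for p, n in enumerate(counts_per_patient) for s in range(n)
    ]
    total_excl = sum(exclusions.values())
    if total_excl > len(slots) - len(counts_per_patient):
        raise PipelineError(
            "programmed section exclusions leave some patient without sections"
        )
    reasons = [r for r, n in exclusions.items() for _ in range(n)]
    order = rng.permutation(len(slots))
    remaining = {p: n for p, n in enumerate(counts_per_patient)}
    assigned: dict[tuple[int, int], str] = {}
    it = iter(order)
    for reason in reasons:
        while True:
            slot = slots[next(it)]
            if remaining[slot[0]] > 1 and slot not in assigned:
                assigned[slot] = reason
                remaining[slot[0]] -= 1
                break
    rows = []
    for p, s in slots:
        reason = assigned.get((p, s))
        rows.append(
            {
                "patient_index": p,
                "slot": s,
                "included": reason is None,
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def _qc_summary(
    study: SyntheticStudy,
    included_sections: Sequence[str],
    jitter_mm: float,
    noise_mm: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Emulated registration QC: perturb each included lumen contour with a
    small rigid offset plus radial noise, rigidly re-align, then score DSC
    and average Hausdorff distance against the original."""
    dscs = []
    hds = []
    for sid in included_sections:
        mask = study.masks[sid]
        contour = mask.lumen_contour
        angle = rng.uniform(-0.1, 0.1)
        shift = rng.uniform(-jitter_mm, jitter_mm, size=2)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        noise = rng.normal(0.0, noise_mm, size=contour.shape)
        moving = contour @ rot.T + shift + noise
        _, aligned = registration_qc.rigid_align(moving, contour, n_points=90)
        hds.append(registration_qc.average_hausdorff(aligned, contour).average)

        h, w = mask.pixels.shape

        def rasterize(poly):
            cols = (poly[:, 0] - mask.origin[0]) / mask.pixel_size
            rows_ = (poly[:, 1] - mask.origin[1]) / mask.pixel_size
            rr, cc = draw_polygon(rows_, cols, shape=(h, w))
            out = np.zeros((h, w), dtype=bool)
            out[rr, cc] = True
            return out

        dscs.append(
            registration_qc.dice_coefficient(rasterize(contour), rasterize(aligned))
        )
    dscs = np.asarray(dscs)
    hds = np.asarray(hds)

    def sem(a):
        return float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0

    return {
        "dsc_mean": float(dscs.mean()),
        "dsc_sem": sem(dscs),
        "avg_hd_mean_mm": float(hds.mean()),
        "avg_hd_sem_mm": sem(hds),
        "n_sections": len(dscs),
    }


def run_pipeline(config: RunConfig, outdir=None) -> RunReport:
    """Execute all stages and write result tables; returns the run report."""
    outdir = Path(outdir or config.outdir or "shearhist_out")
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # ---- stage: section bookkeeping + study generation / ingest
    if config.mode == "files":
        if not config.study_dir:
            raise PipelineError("files mode requires study_dir")
        from .study_io import read_study

        logger.info("stage=ingest dir=%s", config.study_dir)
        study = read_study(config.study_dir)
        section_book = pd.DataFrame(
            {
                "patient_index": 0,
                "slot": range(study.n_sections),
                "included": True,
                "exclusion_reason": None,
            }
        )
        n_mismatch = 0
    else:
        if isinstance(config.sections_per_patient, int):
            counts = [config.sections_per_patient] * config.n_patients
        else:
            counts = list(config.sections_per_patient)
        section_book = _allocate_section_exclusions(
            counts, config.section_exclusions, rng
        )
        included_counts = (
            section_book[section_book.included]
            .groupby("patient_index")
            .size()
            .reindex(range(config.n_patients), fill_value=0)
            .tolist()
        )
        logger.info(
            "stage=simulate sections_total=%d included=%d",
            len(section_book),
            sum(included_counts),
        )
        study = generate_study(
            config.n_patients,
            included_counts,
            config.effects,
            seed=config.seed,
            pixel_size=config.pixel_size,
            fluid=config.fluid,
            n_bins=config.binning.n_bins,
            half_window=config.binning.half_window_mm,
            n_artifact_bins=int(config.bin_exclusions.get("artifact", 0)),
        )
        n_mismatch = int(config.bin_exclusions.get("registration_mismatch", 0))

    sections_total = len(section_book)
    sections_included = int(section_book.included.sum())
    section_excl = summarize_exclusions(section_book)

    # ---- stage: binning + histology quantification
    all_bins = [
        (f.section_id, k)
        for f in study.sections
        for k in range(config.binning.n_bins)
    ]
    candidates = [b for b in all_bins if b not in study.artifact_bins]
    if n_mismatch > len(candidates):
        raise PipelineError("programmed mismatch exclusions exceed available bins")
    mismatch_idx = rng.choice(len(candidates), size=n_mismatch, replace=False)
    mismatch_flags = [candidates[i] for i in mismatch_idx]

    logger.info("stage=bin sections=%d", study.n_sections)
    bin_table = study.bin_table(
        artifact_threshold=config.artifact_threshold,
        half_window=config.binning.half_window_mm,
        n_bins=config.binning.n_bins,
        mismatch_flags=mismatch_flags,
    )
    bins_total = len(bin_table)
    included = bin_table[bin_table.included].copy()
    if included.empty:
        raise PipelineError("empty-analysis: no bins survive the exclusion filters")
    bin_excl = summarize_exclusions(bin_table)

    # ---- stage: statistics
    logger.info("stage=stats included_bins=%d", len(included))
    boundary_tables = []
    for metric, col in (("tawss", "tawss_mean"), ("osi", "osi_mean")):
        labels, boundaries = stats.assign_patient_tertiles(
            included, col, metric=metric
        )
        included[f"{metric}_tertile"] = labels
        boundary_tables.append(boundaries)
    boundaries = pd.concat(boundary_tables, ignore_index=True)

    labeled = included.dropna(subset=["tawss_tertile", "osi_tertile"])
    cooc = stats.cooccurrence_table(
        labeled["tawss_tertile"], labeled["osi_tertile"]
    )

    mean_rows = []
    contrast_rows = []
    for outcome in OUTCOME_COLUMNS:
        for factor in ("tawss_tertile", "osi_tertile"):
            try:
                res = stats.fit_tertile_lmm(labeled, outcome, factor)
            except (ValueError, RuntimeError) as exc:
                logger.warning("lmm skipped outcome=%s factor=%s: %s", outcome, factor, exc)
                continue
            frame = res.to_frame()
            frame.insert(0, "outcome", outcome)
            frame.insert(1, "model", factor)
            mean_rows.append(frame)
            cframe = res.contrasts_frame()
            cframe.insert(0, "outcome", outcome)
            cframe.insert(1, "model", factor)
            contrast_rows.append(cframe)
        try:
            res = stats.fit_combined_lmm(labeled, outcome)
        except (ValueError, RuntimeError) as exc:
            logger.warning("combined lmm skipped outcome=%s: %s", outcome, exc)
            continue
        frame = res.to_frame()
        frame.insert(0, "outcome", outcome)
        frame.insert(1, "model", "tawss_x_osi")
        mean_rows.append(frame)
        cframe = res.contrasts_frame()
        cframe.insert(0, "outcome", outcome)
        cframe.insert(1, "model", "tawss_x_osi")
        contrast_rows.append(cframe)

    # ---- stage: registration QC
    logger.info("stage=qc")
    qc = _qc_summary(
        study,
        [f.section_id for f in study.sections],
        config.qc_jitter_mm,
        config.qc_noise_mm,
        rng,
    )

    # ---- stage: report + outputs
    outputs = []

    def write_csv(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False)
        outputs.append(name)

    write_csv(bin_table, "bin_table.csv")
    write_csv(boundaries, "tertile_boundaries.csv")
    cooc_path = outdir / "cooccurrence.csv"
    cooc.counts.to_csv(cooc_path)
    outputs.append("cooccurrence.csv")
    if mean_rows:
        write_csv(pd.concat(mean_rows, ignore_index=True), "lmm_means.csv")
    if contrast_rows:
        write_csv(pd.concat(contrast_rows, ignore_index=True), "lmm_contrasts.csv")
    write_csv(section_book, "section_bookkeeping.csv")

    report = RunReport(
        sections_total=sections_total,
        sections_included=sections_included,
        section_exclusions=section_excl,
        bins_total=bins_total,
        bins_included=int(bin_table.included.sum()),
        bin_exclusions=bin_excl,
        pct_sections_included=int(round(100.0 * sections_included / sections_total)),
        pct_bins_included=int(
            round(100.0 * bin_table.included.sum() / bins_total)
        ),
        qc=qc,
        outputs=outputs,
    )
    (outdir / "report.json").write_text(report.to_json())
    return report
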