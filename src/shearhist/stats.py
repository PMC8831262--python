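"""Patient-specific tertiles, co-occurrence tables, and linear mixed models.

The mixed models use a per-patient random intercept fitted by REML
(statsmodels MixedLM) with cell-mean coding, so the fixed-effect
coefficients are directly the estimated group means.  Pairwise contrasts
are Wald z-tests, Bonferroni-adjusted over the emitted contrast family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
import statsmodels.api as sm

TERTILE_LABELS = ("low", "mid", "high")

#: residual scale below which the model is treated as deterministic
_ZERO_VARIANCE_TOL = 1e-10


@dataclass(frozen=True)
class TertileAssignment:
    """Per-patient tertile boundaries and per-bin labels for one metric."""

    patient_id: str
    metric: str
    boundary_low_mid: float
    boundary_mid_high: float
    labels: np.ndarray
    degenerate: bool = False  # tied boundaries (e.g. all values identical)


def patient_tertiles(
    bin_values: np.ndarray, patient_id: str = "", metric: str = "tawss"
) -> TertileAssignment:
    """Tertile boundaries at the 33.33/66.67 linear-interpolation percentiles.

    A value is 'low' if strictly below the low-mid boundary, 'high' if at or
    above the mid-high boundary, otherwise 'mid'.
    """
    values = np.asarray(bin_values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("need >= 3 bin values per patient for tertiles")
    if not np.all(np.isfinite(values)):
        raise ValueError("bin values must be finite")
    b1, b2 = np.percentile(values, [100.0 / 3.0, 200.0 / 3.0])
    labels = np.where(values < b1, "low", np.where(values >= b2, "high", "mid"))
    return TertileAssignment(
        patient_id=patient_id,
        metric=metric,
        boundary_low_mid=float(b1),
        boundary_mid_high=float(b2),
        labels=labels,
        degenerate=bool(b1 == b2),
    )


def assign_patient_tertiles(
    df: pd.DataFrame,
    value_col: str,
    patient_col: str = "patient_id",
    metric: str | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Apply :func:`patient_tertiles` per patient over a bin table.

    Returns the per-row labels (aligned with ``df``) and a boundary table
    with one row per patient (patients with < 3 bins are flagged and their
    rows labeled NA).
    """
    metric = metric or value_col
    labels = pd.Series(pd.NA, index=df.index, dtype="object")
    records = []
    for pid, grp in df.groupby(patient_col, sort=True):
        values = grp[value_col].to_numpy(dtype=float)
        if len(values) < 3 or not np.all(np.isfinite(values)):
            records.append(
                {
                    patient_col: pid,
                    "metric": metric,
                    "boundary_low_mid": np.nan,
                    "boundary_mid_high": np.nan,
                    "n_bins": len(values),
                    "flagged": True,
                }
            )
            continue
        ta = patient_tertiles(values, str(pid), metric)
        labels.loc[grp.index] = ta.labels
        records.append(
            {
                patient_col: pid,
                "metric": metric,
                "boundary_low_mid": ta.boundary_low_mid,
                "boundary_mid_high": ta.boundary_mid_high,
                "n_bins": len(values),
                "flagged": ta.degenerate,
            }
        )
    return labels, pd.DataFrame(records)


@dataclass(frozen=True)
class CooccurrenceTable:
    """3x3 counts indexed (TAWSS tertile, OSI tertile)."""

    counts: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def cooccurrence_table(tawss_labels, osi_labels) -> CooccurrenceTable:
    ta = np.asarray(tawss_labels, dtype=object)
    os_ = np.asarray(osi_labels, dtype=object)
    if ta.shape != os_.shape:
        raise ValueError("label arrays must have equal length")
    for arr in (ta, os_):
        bad = set(arr.tolist()) - set(TERTILE_LABELS)
        if bad:
            raise ValueError(f"labels outside {TERTILE_LABELS}: {sorted(map(str, bad))}")
    counts = pd.DataFrame(
        0, index=list(TERTILE_LABELS), columns=list(TERTILE_LABELS), dtype=int
    )
    for t, o in zip(ta, os_):
        counts.loc[t, o] += 1
    counts.index.name = "tawss_tertile"
    counts.columns.name = "osi_tertile"
    return CooccurrenceTable(counts)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """adjusted p = min(1, p * m); m defaults to the family size."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)


@dataclass(frozen=True)
class Contrast:
    name: str
    estimate: float
    se: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class LmmResult:
    outcome: str
    factor: str
    groups: tuple[str, ...]
    estimated_means: dict[str, float]
    standard_errors: dict[str, float]
    contrasts: tuple[Contrast, ...]
    model_converged: bool
    warnings: tuple[str, ...] = ()
    suppressed_contrasts: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "estimated_mean": self.estimated_means[g],
                "se": self.standard_errors[g],
            }
            for g in self.groups
        ]
        return pd.DataFrame(rows)

    def contrasts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contrast": c.name,
                    "estimate": c.estimate,
                    "se": c.se,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                }
                for c in self.contrasts
            ]
        )


def _wald_contrasts(
    pairs: Sequence[tuple[str, str]],
    coef: dict[str, float],
    cov: pd.DataFrame,
    m: int | None = None,
) -> list[Contrast]:
    raw = []
    for a, b in pairs:
        est = coef[a] - coef[b]
        var = cov.loc[a, a] + cov.loc[b, b] - 2.0 * cov.loc[a, b]
        se = float(np.sqrt(max(var, 0.0)))
        if se > 0:
            z = est / se
            p = float(2.0 * norm.sf(abs(z)))
        else:
            p = 1.0 if est == 0 else 0.0
        raw.append((f"{a} - {b}", est, se, p))
    m = m if m is not None else len(raw)
    adj = bonferroni_adjust([r[3] for r in raw], m)
    return [
        Contrast(name, est, se, p, float(pa))
        for (name, est, se, p), pa in zip(raw, adj)
    ]


def _deterministic_result(
    d: pd.DataFrame,
    outcome: str,
    factor: str,
    levels: list[str],
    label_col: str,
    note: str,
) -> LmmResult:
    means = {}
    ses = {}
    for lv in levels:
        y = d.loc[d[label_col] == lv, outcome].to_numpy(dtype=float)
        means[lv] = float(y.mean())
        ses[lv] = float(y.std(ddof=1) / np.sqrt(len(y))) if len(y) > 1 else 0.0
    cov = pd.DataFrame(
        np.diag([ses[lv] ** 2 for lv in levels]), index=levels, columns=levels
    )
    pairs = list(itertools.combinations(levels, 2))
    contrasts = _wald_contrasts(pairs, means, cov)
    return LmmResult(
        outcome=outcome,
        factor=factor,
        groups=tuple(levels),
        estimated_means=means,
        standard_errors=ses,
        contrasts=tuple(contrasts),
        model_converged=True,
        warnings=(note,),
    )


def _fit_mixedlm(endog, exog, groups, names):
    """REML fit returning (coef dict, cov DataFrame, converged, warnings)."""
    notes = []
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups)
        for method in ("lbfgs", "powell", "cg"):
            try:
                candidate = model.fit(reml=True, method=method)
            except Exception:  # singular fits raise LinAlgError and friends
                continue
            fit = candidate
            if bool(getattr(candidate, "converged", True)):
                break
    if fit is None:
        return None, None, False, ["mixed-model fit failed"]
    converged = bool(getattr(fit, "converged", True))
    if float(np.squeeze(fit.cov_re)) < _ZERO_VARIANCE_TOL:
        notes.append("random-intercept variance at boundary (near zero)")
    coef = dict(zip(names, np.asarray(fit.fe_params, dtype=float)))
    cov = pd.DataFrame(
        np.asarray(fit.cov_params())[: len(names), : len(names)],
        index=names,
        columns=names,
    )
    return coef, cov, converged, notes


def fit_tertile_lmm(
    records: pd.DataFrame,
    outcome: str,
    factor: str,
    patient_col: str = "patient_id",
) -> LmmResult:
    """Random-intercept model of ``outcome`` on the tertile ``factor`` column.

    Cell-mean coding: the coefficients are the estimated means per tertile.
    The three pairwise contrasts are Bonferroni-adjusted with m = 3.
    """
    d = records.dropna(subset=[outcome, factor]).copy()
    if d.empty:
        raise ValueError(f"no non-missing observations for outcome {outcome!r}")
    if d[patient_col].nunique() < 2:
        raise ValueError("random-intercept model needs >= 2 patients")
    levels = [lv for lv in TERTILE_LABELS if lv in set(d[factor])]
    if len(levels) < 2:
        raise ValueError("need >= 2 tertile levels with observations")

    exog = np.column_stack([(d[factor] == lv).to_numpy(float) for lv in levels])
    endog = d[outcome].to_numpy(dtype=float)

    # Zero-variance guard: if outcome is an exact function of factor + patient,
    # REML is degenerate; report plain per-group means instead.
    pats = pd.get_dummies(d[patient_col], drop_first=True).to_numpy(float)
    design = np.column_stack([exog, pats])
    resid = endog - design @ np.linalg.lstsq(design, endog, rcond=None)[0]
    scale = max(1.0, float(np.abs(endog).max()))
    if np.abs(resid).max() < _ZERO_VARIANCE_TOL * scale:
        return _deterministic_result(
            d, outcome, factor, levels, factor,
            "zero residual variance; per-group means reported",
        )

    coef, cov, converged, notes = _fit_mixedlm(
        endog, exog, d[patient_col].to_numpy(), levels
    )
    if coef is None:
        return _deterministic_result(
            d, outcome, factor, levels, factor,
            "mixed-model fit failed; per-group means reported",
        )
    pairs = list(itertools.combinations(levels, 2))
    contrasts = _wald_contrasts(pairs, coef, cov, m=3)
    return LmmResult(
        outcome=outcome,
        factor=factor,
        groups=tuple(levels),
        estimated_means={lv: float(coef[lv]) for lv in levels},
        standard_errors={
            lv: float(np.sqrt(max(cov.loc[lv, lv], 0.0))) for lv in levels
        },
        contrasts=tuple(contrasts) if converged else (),
        model_converged=converged,
        warnings=tuple(notes),
    )


def fit_combined_lmm(
    records: pd.DataFrame,
    outcome: str,
    tawss_col: str = "tawss_tertile",
    osi_col: str = "osi_tertile",
    patient_col: str = "patient_id",
) -> LmmResult:
    """Random-intercept model over the 9 TAWSS x OSI cells (cell means with
    interaction implied by the saturated cell coding).

    Contrasts: all within-row (same TAWSS tertile, differing OSI) and
    within-column pairs among occupied cells, Bonferroni-adjusted over the
    emitted set.  Contrasts touching an empty cell are suppressed with an
    explicit reason.
    """
    d = records.dropna(subset=[outcome, tawss_col, osi_col]).copy()
    if d.empty:
        raise ValueError(f"no non-missing observations for outcome {outcome!r}")
    if d[patient_col].nunique() < 2:
        raise ValueError("random-intercept model needs >= 2 patients")
    d["_cell"] = d[tawss_col].astype(str) + "/" + d[osi_col].astype(str)
    all_cells = [f"{t}/{o}" for t in TERTILE_LABELS for o in TERTILE_LABELS]
    occupied = [c for c in all_cells if c in set(d["_cell"])]
    if len(occupied) < 2:
        raise ValueError("need >= 2 occupied TAWSS x OSI cells")

    exog = np.column_stack([(d["_cell"] == c).to_numpy(float) for c in occupied])
    endog = d[outcome].to_numpy(dtype=float)

    pats = pd.get_dummies(d[patient_col], drop_first=True).to_numpy(float)
    design = np.column_stack([exog, pats])
    resid = endog - design @ np.linalg.lstsq(design, endog, rcond=None)[0]
    scale = max(1.0, float(np.abs(endog).max()))
    deterministic = np.abs(resid).max() < _ZERO_VARIANCE_TOL * scale

    if deterministic:
        result = _deterministic_result(
            d, outcome, f"{tawss_col}x{osi_col}", occupied, "_cell",
            "zero residual variance; per-cell means reported",
        )
        coef = dict(result.estimated_means)
        cov = pd.DataFrame(
            np.diag([result.standard_errors[c] ** 2 for c in occupied]),
            index=occupied,
            columns=occupied,
        )
        converged, notes = True, list(result.warnings)
    else:
        coef, cov, converged, notes = _fit_mixedlm(
            endog, exog, d[patient_col].to_numpy(), occupied
        )
        if coef is None:
            raise RuntimeError("combined mixed-model fit failed")

    pairs = []
    suppressed = []
    for t in TERTILE_LABELS:  # within-row: same TAWSS level
        for o1, o2 in itertools.combinations(TERTILE_LABELS, 2):
            a, b = f"{t}/{o1}", f"{t}/{o2}"
            if a in occupied and b in occupied:
                pairs.append((a, b))
            else:
                suppressed.append(f"{a} - {b}: empty cell")
    for o in TERTILE_LABELS:  # within-column: same OSI level
        for t1, t2 in itertools.combinations(TERTILE_LABELS, 2):
            a, b = f"{t1}/{o}", f"{t2}/{o}"
            if a in occupied and b in occupied:
                pairs.append((a, b))
            else:
                suppressed.append(f"{a} - {b}: empty cell")
    contrasts = _wald_contrasts(pairs, coef, cov) if converged else []
    return LmmResult(
        outcome=outcome,
        factor=f"{tawss_col}x{osi_col}",
        groups=tuple(occupied),
        estimated_means={c: float(coef[c]) for c in occupied},
        standard_errors={
            c: float(np.sqrt(max(cov.loc[c, c], 0.0))) for c in occupied
        },
        contrasts=tuple(contrasts),
        model_converged=converged,
        warnings=tuple(notes),
        suppressed_contrasts=tuple(suppressed),
    )
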