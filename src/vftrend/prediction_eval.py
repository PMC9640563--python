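"""Rolling-origin evaluation of visual-field prediction accuracy.

For each eye, a model is fitted point-wise to the first ``n_used``
examinations and used to predict the examination ``horizon`` steps ahead
(the first, second, or third future test).  The prediction error of one
(eye, model, horizon, window) cell is the mean absolute error (MAE) over the
68 locations; the mean-sensitivity (MS) path fits the same model to the
per-test MS series and reports the absolute error of the predicted MS.

Windows start at 5 tests and extend until the target is the thirteenth
examination, giving 8 / 7 / 6 windows for horizons 1 / 2 / 3.  Cross-eye
aggregation reports mean, SD and a 95 % normal confidence interval of the
per-eye MAE; the "number of VFs required" is the shortest window whose mean
MAE already lies within the 95 % CI of the best (longest-window) cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regression_models import (
    FITTERS,
    MIN_WINDOW,
    ModelKind,
    PointwiseFitError,
    fit_olslr,
    fit_pointwise,
    predict,
)
from .vf_core import SERIES_LENGTH, NormativeGrid, VFSeries, mean_deviation, mean_sensitivity

logger = logging.getLogger(__name__)

HORIZONS = (1, 2, 3)

#: z quantile for the 95 % normal confidence interval
Z_95 = 1.96

#: subgroup thresholds: severity split on initial MD, progression split on MD slope
SEVERITY_MD_THRESHOLD = -20.0
PROGRESSION_SLOPE_THRESHOLD = -0.25

ANALYSIS_PATHS = ("PW", "MS")
OVERALL = "overall"


def enumerate_windows(horizon: int) -> list[tuple[int, int]]:
    """(n_used, target_index) pairs for one horizon.

    The window grows from 5 tests until the target is the 13th examination:
    horizon 1 gives (5,6)...(12,13), horizon 2 (5,7)...(11,13), horizon 3
    (5,8)...(10,13).
    """
    if horizon not in HORIZONS:
        raise ValueError(f"horizon must be one of {HORIZONS}, got {horizon}")
    return [(n, n + horizon) for n in range(MIN_WINDOW, SERIES_LENGTH - horizon + 1)]


@dataclass
class PredictionOutcome:
    """Predicted vs. actual field for one (eye, model, horizon, window) cell."""

    eye_id: str
    model: ModelKind
    horizon: int
    n_used: int
    target_index: int
    predicted: np.ndarray
    actual: np.ndarray
    pw_abs_errors: np.ndarray
    mae: float
    ms_predicted: float
    ms_actual: float
    ms_ae: float


def evaluate_eye(series: VFSeries, model: ModelKind, horizon: int,
                 clamp: bool = False) -> list[PredictionOutcome]:
    """All rolling-window predictions of one eye for one model and horizon.

    A window is dropped for the eye (with a logged reason) if any location's
    fit fails there.
    """
    times = series.times()
    outcomes = []
    for n_used, target_index in enumerate_windows(horizon):
        target = series.tests[target_index - 1]
        t_new = times[target_index - 1]
        try:
            pw = fit_pointwise(series, n_used, model)
        except PointwiseFitError as exc:
            logger.warning("eye %s %s window %d dropped: %s",
                           series.eye_id, model.value, n_used, exc)
            continue
        predicted = pw.predict(t_new, clamp=clamp)
        actual = target.sensitivities
        abs_err = np.abs(predicted - actual)

        ms_series = np.array([mean_sensitivity(t) for t in series.tests[:n_used]])
        ms_fit = FITTERS[model](times[:n_used], ms_series)
        ms_pred = predict(ms_fit, t_new, clamp=clamp)
        ms_actual = mean_sensitivity(target)

        outcomes.append(PredictionOutcome(
            eye_id=series.eye_id, model=model, horizon=horizon, n_used=n_used,
            target_index=target_index, predicted=predicted, actual=actual,
            pw_abs_errors=abs_err, mae=float(np.mean(abs_err)),
            ms_predicted=float(ms_pred), ms_actual=float(ms_actual),
            ms_ae=float(abs(ms_pred - ms_actual)),
        ))
    return outcomes


def outcomes_to_frame(outcomes: Iterable[PredictionOutcome]) -> pd.DataFrame:
    """Flatten outcomes to one row per (eye, model, horizon, window)."""
    rows = [{
        "eye_id": o.eye_id, "model": o.model.value, "horizon": o.horizon,
        "n_used": o.n_used, "target_index": o.target_index,
        "mae": o.mae, "ms_ae": o.ms_ae,
    } for o in outcomes]
    return pd.DataFrame(rows)


@dataclass
class EvalCell:
    """Cross-eye summary of one (model, horizon, window) cell."""

    model: ModelKind
    horizon: int
    n_used: int
    n_eyes: int
    mean_mae: float
    sd_mae: float
    se_mae: float
    ci_low: float
    ci_high: float
    analysis_path: str = "PW"
    subgroup: str = OVERALL


def aggregate(outcomes: Iterable[PredictionOutcome], analysis_path: str = "PW",
              subgroup: str = OVERALL) -> list[EvalCell]:
    """Per-cell mean, SD (n-1 denominator), SE and 95 % CI of per-eye error.

    ``analysis_path`` selects the point-wise MAE ("PW") or the
    mean-sensitivity absolute error ("MS").  Single-eye cells carry NaN
    spread statistics (SD undefined; CI omitted).
    """
    if analysis_path not in ANALYSIS_PATHS:
        raise ValueError(f"analysis_path must be one of {ANALYSIS_PATHS}")
    value = "mae" if analysis_path == "PW" else "ms_ae"
    df = outcomes_to_frame(outcomes)
    cells = []
    if df.empty:
        return cells
    for (model, horizon, n_used), g in df.groupby(["model", "horizon", "n_used"]):
        vals = g[value].to_numpy()
        n = vals.size
        mean = float(np.mean(vals))
        if n >= 2:
            sd = float(np.std(vals, ddof=1))
            se = sd / np.sqrt(n)
            lo, hi = mean - Z_95 * se, mean + Z_95 * se
        else:
            logger.warning("cell %s h%d n_used=%d has a single eye; CI omitted",
                           model, horizon, n_used)
            sd = se = lo = hi = float("nan")
        cells.append(EvalCell(ModelKind(model), int(horizon), int(n_used), n,
                              mean, sd, se, lo, hi, analysis_path, subgroup))
    return cells


def cells_to_frame(cells: Iterable[EvalCell]) -> pd.DataFrame:
    return pd.DataFrame([{
        "analysis_path": c.analysis_path, "subgroup": c.subgroup,
        "model": c.model.value, "horizon": c.horizon, "n_used": c.n_used,
        "n_eyes": c.n_eyes, "mean_mae": c.mean_mae, "sd_mae": c.sd_mae,
        "se_mae": c.se_mae, "ci_low": c.ci_low, "ci_high": c.ci_high,
    } for c in cells])


@dataclass
class SaturationResult:
    """The "number of VFs required" for one horizon.

    ``best_n_used`` is the window with the smallest mean reference-model MAE
    (ties broken toward the longest window); ``n_required`` is the smallest
    window whose mean MAE already lies at or below the upper 95 % confidence
    bound of that best cell.
    """

    horizon: int
    best_n_used: int
    best_mae: float
    ci_upper: float
    n_required: int
    analysis_path: str = "PW"
    subgroup: str = OVERALL


def find_saturation(cells: Sequence[EvalCell], horizon: int,
                    model: ModelKind = ModelKind.OLSLR) -> SaturationResult:
    """Scan one horizon's reference-model cells for the saturation window."""
    sel = {c.n_used: c for c in cells
           if c.model is model and c.horizon == horizon}
    expected = [n for n, _ in enumerate_windows(horizon)]
    missing = [n for n in expected if n not in sel]
    if missing:
        raise ValueError(f"horizon {horizon}: missing windows {missing}")
    path = next(iter(sel.values())).analysis_path
    subgroup = next(iter(sel.values())).subgroup
    # longest window among ties for the minimum
    best = min(expected, key=lambda n: (sel[n].mean_mae, -n))
    ci_upper = sel[best].ci_high
    if not np.isfinite(ci_upper):
        raise ValueError(f"horizon {horizon}: best cell has no CI (single eye?)")
    # tiny epsilon so exactly-saturated (e.g. zero-error) tables scan cleanly
    n_required = next(n for n in expected if sel[n].mean_mae <= ci_upper + 1e-12)
    return SaturationResult(horizon=horizon, best_n_used=best,
                            best_mae=sel[best].mean_mae, ci_upper=ci_upper,
                            n_required=n_required, analysis_path=path,
                            subgroup=subgroup)


def saturation_to_frame(results: Iterable[SaturationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "analysis_path": r.analysis_path, "subgroup": r.subgroup,
        "horizon": r.horizon, "best_n_used": r.best_n_used,
        "best_mae": r.best_mae, "ci_upper": r.ci_upper,
        "n_required": r.n_required,
    } for r in results])


def md_series(series: VFSeries, norm: NormativeGrid) -> np.ndarray:
    return np.array([mean_deviation(t, norm) for t in series.tests])


def md_slope(series: VFSeries, norm: NormativeGrid) -> float:
    """OLS slope of the mean deviation over time, dB/year, over all tests."""
    fit = fit_olslr(series.times(), md_series(series, norm))
    return fit.params[0]


@dataclass(frozen=True)
class SubgroupLabel:
    """Severity (initial MD vs -20 dB) and progression (MD slope vs
    -0.25 dB/y) classification of one eye.  Boundary values fall in the
    less-severe group."""

    severity: str   # "early_moderate" | "advanced"
    progression: str  # "stable" | "progressive"


def classify_subgroups(series: VFSeries, norm: NormativeGrid) -> SubgroupLabel:
    # 1e-9 dB tolerance keeps the documented boundary rule stable against
    # floating-point noise in the OLS slope
    md0 = mean_deviation(series.tests[0], norm)
    slope = md_slope(series, norm)
    severity = ("early_moderate" if md0 >= SEVERITY_MD_THRESHOLD - 1e-9
                else "advanced")
    progression = ("stable" if slope >= PROGRESSION_SLOPE_THRESHOLD - 1e-9
                   else "progressive")
    return SubgroupLabel(severity=severity, progression=progression)


@dataclass
class ExperimentResult:
    """Full results bundle of one evaluation run."""

    outcomes: list[PredictionOutcome]
    outcomes_frame: pd.DataFrame
    cells: pd.DataFrame
    saturation: pd.DataFrame
    subgroup_labels: dict[str, SubgroupLabel]
    patient_map: dict[str, str]


def run_experiment(cohort: Sequence[VFSeries],
                   models: Sequence[ModelKind] = tuple(ModelKind),
                   horizons: Sequence[int] = HORIZONS,
                   norm: NormativeGrid | None = None,
                   clamp: bool = False,
                   analysis_paths: Sequence[str] = ANALYSIS_PATHS,
                   subgroups: bool = True) -> ExperimentResult:
    """Run the full rolling prediction experiment on a prepared cohort.

    Produces per-eye outcomes, cross-eye cells (overall and, optionally, per
    severity/progression subgroup), and saturation results per horizon for
    the reference model.  Deterministic given the cohort and settings.
    """
    norm = norm or NormativeGrid.constant()
    labels = {s.eye_id: classify_subgroups(s, norm) for s in cohort}
    patient_map = {s.eye_id: s.patient_id for s in cohort}

    outcomes: list[PredictionOutcome] = []
    for series in cohort:
        for model in models:
            for horizon in horizons:
                outcomes.extend(evaluate_eye(series, model, horizon, clamp=clamp))

    groupings: list[tuple[str, set[str]]] = [(OVERALL, set(labels))]
    if subgroups:
        for name in ("early_moderate", "advanced"):
            groupings.append((name, {e for e, l in labels.items() if l.severity == name}))
        for name in ("stable", "progressive"):
            groupings.append((name, {e for e, l in labels.items() if l.progression == name}))

    all_cells: list[EvalCell] = []
    saturations = []
    for path in analysis_paths:
        for name, eyes in groupings:
            if not eyes:
                logger.info("subgroup %s is empty; skipped", name)
                continue
            sub = [o for o in outcomes if o.eye_id in eyes]
            cells = aggregate(sub, analysis_path=path, subgroup=name)
            all_cells.extend(cells)
            if ModelKind.OLSLR in models:
                for horizon in horizons:
                    try:
                        saturations.append(find_saturation(cells, horizon))
                    except ValueError as exc:
                        logger.warning("saturation unavailable (%s, %s, h%d): %s",
                                       path, name, horizon, exc)

    return ExperimentResult(
        outcomes=outcomes,
        outcomes_frame=outcomes_to_frame(outcomes),
        cells=cells_to_frame(all_cells),
        saturation=saturation_to_frame(saturations),
        subgroup_labels=labels,
        patient_map=patient_map,
    )
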