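"""Formal comparison of prediction errors against the reference model.

Each candidate model's per-eye error in a (horizon, window) cell is compared
with the ordinary least-squares reference using a linear mixed model with a
random intercept per patient, which absorbs the pairing of the two errors
within an eye and the correlation between fellow eyes of one patient.  The
fixed effect of the model indicator is the estimated mean error difference;
its Wald test gives the raw p-value.  Within each family — one (horizon,
analysis path, subgroup) table across all candidate models and windows —
p-values are adjusted by the Benjamini–Hochberg step-up procedure and
significance is declared at adjusted p < 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .prediction_eval import ExperimentResult
from .regression_models import ModelKind

logger = logging.getLogger(__name__)

ALPHA = 0.05


class InsufficientDataError(ValueError):
    """Fewer than three patients in a comparison cell."""


@dataclass
class ComparisonResult:
    model: ModelKind
    horizon: int
    n_used: int
    estimate: float
    p_raw: float
    p_adjusted: float
    significant: bool
    analysis_path: str = "PW"
    subgroup: str = "overall"


def compare_cell(values_candidate: Mapping[str, float],
                 values_reference: Mapping[str, float],
                 patient_map: Mapping[str, str]) -> tuple[float, float]:
    """Mixed-model comparison of per-eye errors in one cell.

    Both mappings must cover the same eyes.  Returns (estimate, raw p):
    the fixed-effect coefficient of the candidate-model indicator in a
    random-intercept-per-patient mixed model on the stacked errors, and its
    Wald p-value.

    Degenerate cells are resolved without a model fit: identical errors give
    (0, 1); an exactly constant non-zero shift gives (shift, 0).
    """
    eyes = sorted(values_candidate)
    if sorted(values_reference) != eyes:
        raise ValueError("candidate and reference cells cover different eyes")
    patients = {patient_map[e] for e in eyes}
    if len(patients) < 3:
        raise InsufficientDataError(f"only {len(patients)} patients in cell")

    ref = np.array([values_reference[e] for e in eyes], dtype=float)
    cand = np.array([values_candidate[e] for e in eyes], dtype=float)
    diffs = cand - ref
    if np.ptp(diffs) < 1e-12:
        shift = float(np.mean(diffs))
        return (0.0, 1.0) if abs(shift) < 1e-12 else (shift, 0.0)

    endog = np.concatenate([ref, cand])
    indicator = np.concatenate([np.zeros(len(eyes)), np.ones(len(eyes))])
    exog = sm.add_constant(indicator)
    groups = np.array([patient_map[e] for e in eyes] * 2)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(endog, exog, groups=groups).fit(reml=True)
        estimate = float(res.params[1])
        p_raw = float(res.pvalues[1])
    except Exception as exc:
        logger.warning("mixed model failed (%s); cell reported without p", exc)
        return float(np.mean(diffs)), float("nan")
    if not np.isfinite(p_raw):
        logger.warning("mixed model p non-finite; cell reported without p")
        p_raw = float("nan")
    return estimate, p_raw


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    Sorted ascending, the adjusted value is min over j >= i of (m/j) p_(j),
    capped at 1, returned in the original order.  NaN entries (cells without
    a p-value) are passed through and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def compare_all(result: ExperimentResult,
                reference: ModelKind = ModelKind.OLSLR,
                alpha: float = ALPHA,
                subgroups: bool = True) -> pd.DataFrame:
    """Compare every candidate model against the reference in every cell.

    Families for the multiplicity adjustment are one (horizon, analysis
    path, subgroup) table across all candidate models and windows.
    """
    df = result.outcomes_frame
    labels = result.subgroup_labels
    groupings: list[tuple[str, set[str]]] = [("overall", set(labels))]
    if subgroups:
        for name in ("early_moderate", "advanced"):
            groupings.append((name, {e for e, l in labels.items() if l.severity == name}))
        for name in ("stable", "progressive"):
            groupings.append((name, {e for e, l in labels.items() if l.progression == name}))

    candidates = [ModelKind(m) for m in df["model"].unique()
                  if ModelKind(m) is not reference]
    rows = []
    for path, value in (("PW", "mae"), ("MS", "ms_ae")):
        for sub_name, eyes in groupings:
            sub = df[df["eye_id"].isin(eyes)]
            if sub.empty:
                continue
            family: list[dict] = []
            for horizon in sorted(sub["horizon"].unique()):
                hdf = sub[sub["horizon"] == horizon]
                for model in candidates:
                    for n_used in sorted(hdf["n_used"].unique()):
                        cell = hdf[hdf["n_used"] == n_used]
                        cand = cell[cell["model"] == model.value]
                        ref = cell[cell["model"] == reference.value]
                        common = sorted(set(cand["eye_id"]) & set(ref["eye_id"]))
                        if not common:
                            continue
                        vc = dict(zip(cand["eye_id"], cand[value]))
                        vr = dict(zip(ref["eye_id"], ref[value]))
                        vc = {e: vc[e] for e in common}
                        vr = {e: vr[e] for e in common}
                        try:
                            est, p = compare_cell(vc, vr, result.patient_map)
                        except InsufficientDataError as exc:
                            logger.warning("cell skipped (%s %s h%d n=%d): %s",
                                           path, sub_name, horizon, n_used, exc)
                            continue
                        family.append({
                            "analysis_path": path, "subgroup": sub_name,
                            "horizon": int(horizon), "n_used": int(n_used),
                            "model": model.value, "estimate": est, "p_raw": p,
                        })
            # BH within one (horizon, path, subgroup) family
            fam_df = pd.DataFrame(family)
            if fam_df.empty:
                continue
            for horizon, hfam in fam_df.groupby("horizon"):
                adj = bh_adjust(hfam["p_raw"].to_numpy())
                hfam = hfam.assign(p_adjusted=adj,
                                   significant=adj < alpha)
                rows.append(hfam)
    if not rows:
        return pd.DataFrame(columns=["analysis_path", "subgroup", "horizon",
                                     "n_used", "model", "estimate", "p_raw",
                                     "p_adjusted", "significant"])
    return pd.concat(rows, ignore_index=True)
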