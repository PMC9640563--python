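"""Synthetic longitudinal 10-2 visual-field cohorts.

The generator emulates the statistical structure of a glaucoma clinic
cohort followed with twice-yearly central 10-degree perimetry: 180 eyes of
133 patients, 13 reliable examinations per eye over about 7.5 years, severe
baseline damage (mean deviation about -19.8 +/- 8.1 dB) and slow point-wise
decay (MD slope about -0.33 +/- 0.40 dB/year), with sensitivity-dependent
test-retest noise, censoring to the 0-40 dB instrument range, integer
reporting, fellow-eye correlation within patients and occasional unreliable
tests.

Baseline damage per eye is a spatially correlated Gaussian defect field on
the grid (squared-exponential kernel) offset so the eye's true mean
deviation exactly equals its drawn value after clamping to [0, 35] dB.  The
drawn baseline MDs follow a truncated normal on [-33, 0] dB whose location
is recentred so the realised mean matches the configured mean.  Point-wise
slopes are the eye's MD slope plus a spatially correlated perturbation;
the true trajectory is floored at 0 dB (progression stops at the floor).

A :class:`TruthRecord` carries the generating baselines, slopes and
subgroup labels per eye for parameter-recovery tests, and
:func:`make_fixture` builds small deterministic series with known analytic
structure for unit tests.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import norm as _gaussian
from scipy.stats import truncnorm

from .vf_core import (
    N_POINTS,
    SERIES_LENGTH,
    NormativeGrid,
    VFSeries,
    VFTest,
    build_grid_10_2,
)

#: truncation bounds of the drawn baseline mean deviation, dB
MD_RANGE = (-33.0, 0.0)
#: baseline sensitivities are clamped below the normative ceiling
BASELINE_MAX_DB = 35.0


class ConfigError(ValueError):
    """The generator configuration is infeasible or inconsistent."""


@dataclass
class SynthConfig:
    """Cohort-generator configuration.

    Defaults reproduce the study conditions of a severe open-angle glaucoma
    clinic population followed with 10-2 perimetry roughly every six months
    (0.625-year mean interval, i.e. 7.5 years over 12 intervals).
    """

    n_patients: int = 133
    n_eyes: int = 180
    n_tests: int = 13
    interval_years_mean: float = 0.625
    interval_jitter_sd: float = 0.15
    baseline_md_mean: float = -19.8
    baseline_md_sd: float = 8.1
    md_slope_mean: float = -0.33
    md_slope_sd: float = 0.40
    within_patient_slope_correlation: float = 0.5
    pointwise_slope_sd: float = 0.2
    defect_correlation_length_deg: float = 4.0
    defect_field_sd: float = 5.0
    noise_sd_at_ceiling: float = 1.5
    noise_sd_at_floor: float = 4.0
    noise_reference_db: float = 35.0
    truth_shape: str = "linear"  # linear | exponential | logistic
    unreliable_test_rate: float = 0.05
    round_to_integer: bool = True
    normative_db: float = 33.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.n_patients <= self.n_eyes <= 2 * self.n_patients):
            raise ConfigError(
                f"cannot seat {self.n_eyes} eyes in {self.n_patients} patients"
            )
        if self.n_tests < SERIES_LENGTH:
            raise ConfigError(f"n_tests must be >= {SERIES_LENGTH}")
        for name in ("interval_jitter_sd", "baseline_md_sd", "md_slope_sd",
                     "pointwise_slope_sd", "defect_field_sd",
                     "noise_sd_at_ceiling", "noise_sd_at_floor"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.interval_years_mean <= 0:
            raise ConfigError("interval_years_mean must be > 0")
        if not 0 <= self.within_patient_slope_correlation <= 1:
            raise ConfigError("within_patient_slope_correlation must be in [0, 1]")
        if not 0 <= self.unreliable_test_rate < 1:
            raise ConfigError("unreliable_test_rate must be in [0, 1)")
        if self.truth_shape not in ("linear", "exponential", "logistic"):
            raise ConfigError(f"unknown truth_shape {self.truth_shape!r}")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SynthConfig":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and Path(source).exists()):
            data = yaml.safe_load(Path(source).read_text())
        else:
            data = yaml.safe_load(io.StringIO(str(source)))
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class TruthRecord:
    """Generating parameters per eye, aligned to the returned cohort."""

    eye_ids: list[str]
    patient_ids: list[str]
    baseline_db: np.ndarray        # (n_eyes, 68) true baseline sensitivities
    point_slopes: np.ndarray       # (n_eyes, 68) true slopes, dB/year
    md_baseline: np.ndarray        # (n_eyes,) true baseline MD, dB
    md_slope: np.ndarray           # (n_eyes,) drawn eye MD slope, dB/year
    severity: list[str]            # early_moderate | advanced (vs -20 dB)
    progression: list[str]         # stable | progressive (vs -0.25 dB/y)

    def point_frame(self) -> pd.DataFrame:
        rows = []
        for i, eye in enumerate(self.eye_ids):
            rows.append(pd.DataFrame({
                "eye_id": eye,
                "point_index": np.arange(N_POINTS),
                "true_baseline_db": self.baseline_db[i],
                "true_slope_db_per_year": self.point_slopes[i],
            }))
        return pd.concat(rows, ignore_index=True)

    def eye_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "eye_id": self.eye_ids,
            "patient_id": self.patient_ids,
            "true_md_baseline_db": self.md_baseline,
            "true_md_slope_db_per_year": self.md_slope,
            "severity": self.severity,
            "progression": self.progression,
        })


def _recentred_truncnorm(mean: float, sd: float,
                         lo: float, hi: float) -> tuple[float, float, float]:
    """Location of a truncated normal on [lo, hi] whose mean equals ``mean``.

    Truncating N(mean, sd) shifts its expectation away from ``mean``; the
    configured cohort moments are taken to describe the realised
    distribution, so the location parameter is solved for accordingly.
    Returns (loc, a, b) in scipy's standardised truncnorm parametrisation.
    """
    if sd == 0:
        return mean, -np.inf, np.inf

    def gap(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    loc = brentq(gap, lo - 5 * sd, hi + 5 * sd, xtol=1e-10)
    return loc, (lo - loc) / sd, (hi - loc) / sd


def _defect_kernel_chol(coords: np.ndarray, length: float) -> np.ndarray:
    """Cholesky factor of the squared-exponential spatial kernel."""
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    if length <= 0:
        K = np.eye(len(coords))
    else:
        K = np.exp(-d2 / (2.0 * length ** 2))
    return np.linalg.cholesky(K + 1e-9 * np.eye(len(coords)))


def _baseline_field(defect: np.ndarray, md_target: float,
                    normative: float) -> np.ndarray:
    """Offset the defect field so the clamped baseline hits the target MD."""

    def gap(c):
        return float(np.mean(np.clip(normative + defect + c, 0.0, BASELINE_MAX_DB))
                     - normative - md_target)

    lo, hi = -normative - float(np.max(defect)) - 1.0, BASELINE_MAX_DB + 50.0
    c = brentq(gap, lo, hi, xtol=1e-10)
    return np.clip(normative + defect + c, 0.0, BASELINE_MAX_DB)


def _truth_trajectory(baseline: np.ndarray, slopes: np.ndarray,
                      t: np.ndarray, shape: str) -> np.ndarray:
    """(n_times, 68) true sensitivities; floored at 0 dB."""
    b = baseline[None, :]
    s = slopes[None, :]
    tt = t[:, None]
    if shape == "linear":
        y = b + s * tt
    elif shape == "exponential":
        # rate chosen so the initial derivative matches the linear slope
        rate = s / np.maximum(b, 1.0)
        y = b * np.exp(rate * tt)
    elif shape == "logistic":
        p0 = np.clip(b / 40.0, 0.01, 0.99)
        k = s / (40.0 * p0 * (1.0 - p0))
        y = 40.0 / (1.0 + np.exp(-(np.log(p0 / (1 - p0)) + k * tt)))
    else:  # pragma: no cover
        raise ConfigError(f"unknown truth_shape {shape!r}")
    return np.maximum(y, 0.0)


#: search bounds for the per-eye slope calibration offset, dB/year
_SLOPE_CAL_BOUND = 3.0


def _expected_measured(truth: np.ndarray, cfg: "SynthConfig") -> np.ndarray:
    """Expectation of the censored measurement clip(truth + noise, 0, 40).

    Closed form for Gaussian noise; integer rounding is ignored (its bias is
    negligible).  Near the 0 dB floor the expectation exceeds the truth,
    which attenuates estimated trends — the slope calibration accounts for
    this.
    """
    sd = _noise_sd(truth, cfg)
    if np.all(sd == 0):
        return np.clip(truth, 0.0, 40.0)
    sd = np.maximum(sd, 1e-12)
    alpha = (0.0 - truth) / sd
    beta = (40.0 - truth) / sd
    pa, pb = ndtr(alpha), ndtr(beta)
    phi_a = np.exp(-0.5 * alpha ** 2) / np.sqrt(2 * np.pi)
    phi_b = np.exp(-0.5 * beta ** 2) / np.sqrt(2 * np.pi)
    return truth * (pb - pa) + sd * (phi_a - phi_b) + 40.0 * (1.0 - pb)


def _calibrate_slopes(baseline: np.ndarray, pslopes: np.ndarray,
                      t_sched: np.ndarray, target: float, shape: str,
                      cfg: "SynthConfig") -> np.ndarray:
    """Shift the point slopes so the eye's estimated MD slope realises the
    drawn value.

    Decay stops at the 0 dB floor and measurements near the floor are
    censored upward, so the OLS slope of the measured mean deviation is
    attenuated relative to the raw point slopes.  The configured MD slope
    describes the estimated trend of the realised cohort (that is what a
    clinical MD slope is), so a common offset is added to the point slopes
    such that the OLS slope of the expected measured MD over the scheduled
    visits equals the drawn value.  For eyes too close to the floor the
    target may be unreachable; the offset is then capped and the realised
    slope stays as close as the floor allows.
    """
    tc = t_sched - t_sched.mean()
    w = tc / np.sum(tc ** 2)

    def gap(delta: float) -> float:
        traj = _truth_trajectory(baseline, pslopes + delta, t_sched, shape)
        em = _expected_measured(traj, cfg)
        return float(w @ em.mean(axis=1)) - target

    lo, hi = -_SLOPE_CAL_BOUND, _SLOPE_CAL_BOUND
    glo, ghi = gap(lo), gap(hi)
    if glo == 0.0:
        return pslopes + lo
    if ghi == 0.0:
        return pslopes + hi
    if glo * ghi > 0:  # unreachable within bounds: take the closer boundary
        delta = lo if abs(glo) < abs(ghi) else hi
        return pslopes + delta
    delta = brentq(gap, lo, hi, xtol=1e-8)
    return pslopes + delta


def _noise_sd(truth: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Test-retest SD interpolating linearly from the floor to the reference
    sensitivity (smaller noise at higher, better-preserved sensitivities)."""
    frac = np.clip(truth, 0.0, cfg.noise_reference_db) / cfg.noise_reference_db
    return cfg.noise_sd_at_floor + (cfg.noise_sd_at_ceiling - cfg.noise_sd_at_floor) * frac


def generate_cohort(
    config: SynthConfig | None = None,
) -> tuple[list[VFSeries], TruthRecord, NormativeGrid]:
    """Generate a cohort, its truth record and the normative grid.

    Deterministic given ``config.seed``.  The returned series are raw (they
    include unreliable tests and must go through series preparation); the
    first test of every eye is reliable, and unreliable tests are extra
    examinations inserted between scheduled visits (a failed test is
    repeated at the next visit), so the retained 13-test follow-up keeps the
    configured visit schedule.
    """
    cfg = config or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    grid = build_grid_10_2()
    norm = NormativeGrid.constant(cfg.normative_db)
    L = _defect_kernel_chol(grid.coords(), cfg.defect_correlation_length_deg)
    loc, a, b = _recentred_truncnorm(cfg.baseline_md_mean, cfg.baseline_md_sd,
                                     *MD_RANGE)

    n_bilateral = cfg.n_eyes - cfg.n_patients
    rho = cfg.within_patient_slope_correlation
    sq, sr = np.sqrt(rho), np.sqrt(1.0 - rho)

    cohort: list[VFSeries] = []
    eye_ids, patient_ids = [], []
    baselines = np.empty((cfg.n_eyes, N_POINTS))
    slopes_all = np.empty((cfg.n_eyes, N_POINTS))
    md0_all = np.empty(cfg.n_eyes)
    mds_all = np.empty(cfg.n_eyes)
    severity, progression = [], []

    eye_counter = 0
    for p in range(cfg.n_patients):
        patient_id = f"P{p + 1:03d}"
        n_eyes_p = 2 if p < n_bilateral else 1
        sides = ["right", "left"][:n_eyes_p]
        # patient-level latent effects shared by fellow eyes
        u_sev = rng.standard_normal()
        u_slope = rng.standard_normal()
        for side in sides:
            eye_id = f"{patient_id}_{side[0].upper()}"
            # baseline MD: Gaussian copula over the recentred truncated normal,
            # sharing the patient severity latent between fellow eyes
            g = sq * u_sev + sr * rng.standard_normal()
            if cfg.baseline_md_sd == 0:
                md_target = float(np.clip(cfg.baseline_md_mean, *MD_RANGE))
            else:
                md_target = float(truncnorm.ppf(_gaussian.cdf(g), a, b, loc=loc,
                                                scale=cfg.baseline_md_sd))
            slope_eye = cfg.md_slope_mean + cfg.md_slope_sd * (
                sq * u_slope + sr * rng.standard_normal())

            defect = cfg.defect_field_sd * (L @ rng.standard_normal(N_POINTS))
            baseline = _baseline_field(defect, md_target, cfg.normative_db)
            pslopes = slope_eye + cfg.pointwise_slope_sd * (
                L @ rng.standard_normal(N_POINTS))

            # scheduled (reliable) visit times
            intervals = np.maximum(
                rng.normal(cfg.interval_years_mean, cfg.interval_jitter_sd,
                           cfg.n_tests - 1),
                0.05)
            t_sched = np.concatenate([[0.0], np.cumsum(intervals)])
            pslopes = _calibrate_slopes(baseline, pslopes,
                                        t_sched[:SERIES_LENGTH], slope_eye,
                                        cfg.truth_shape, cfg)

            # unreliable extra tests between visits (never before the first)
            times, reliable = [t_sched[0]], [True]
            for k in range(1, cfg.n_tests):
                if rng.random() < cfg.unreliable_test_rate:
                    frac = rng.uniform(0.3, 0.7)
                    times.append(t_sched[k - 1] + frac * intervals[k - 1])
                    reliable.append(False)
                times.append(t_sched[k])
                reliable.append(True)
            times = np.array(times)

            truth = _truth_trajectory(baseline, pslopes, times, cfg.truth_shape)
            noise = rng.standard_normal(truth.shape) * _noise_sd(truth, cfg)
            measured = np.clip(truth + noise, 0.0, 40.0)
            if cfg.round_to_integer:
                measured = np.round(measured)

            series = VFSeries(eye_id=eye_id, patient_id=patient_id,
                              laterality=side)
            for i, (t, ok) in enumerate(zip(times, reliable)):
                if ok:
                    fl = rng.uniform(0.0, 20.0)
                    fp = rng.uniform(0.0, 15.0)
                else:
                    if rng.random() < 0.5:
                        fl, fp = rng.uniform(20.5, 60.0), rng.uniform(0.0, 15.0)
                    else:
                        fl, fp = rng.uniform(0.0, 20.0), rng.uniform(15.5, 45.0)
                series.tests.append(VFTest(
                    eye_id=eye_id, test_index=i + 1, time_years=float(t),
                    sensitivities=measured[i], fixation_loss_pct=float(fl),
                    false_positive_pct=float(fp)))
            cohort.append(series)

            eye_ids.append(eye_id)
            patient_ids.append(patient_id)
            baselines[eye_counter] = baseline
            slopes_all[eye_counter] = pslopes
            md0_all[eye_counter] = float(np.mean(baseline)) - cfg.normative_db
            mds_all[eye_counter] = slope_eye
            severity.append("early_moderate" if md0_all[eye_counter] >= -20.0
                            else "advanced")
            progression.append("stable" if slope_eye >= -0.25 else "progressive")
            eye_counter += 1

    truth_rec = TruthRecord(eye_ids=eye_ids, patient_ids=patient_ids,
                            baseline_db=baselines, point_slopes=slopes_all,
                            md_baseline=md0_all, md_slope=mds_all,
                            severity=severity, progression=progression)
    return cohort, truth_rec, norm


# ---------------------------------------------------------------------------
# deterministic unit-test fixtures

FIXTURE_KINDS = ("noise_free_linear", "constant", "outlier_series",
                 "nonlinear_truth")


def make_fixture(kind: str, *, eye_id: str = "FIX_R", patient_id: str = "FIX",
                 laterality: str = "right", n_tests: int = SERIES_LENGTH,
                 interval: float = 0.625, baseline: float | np.ndarray = 30.0,
                 slope: float | np.ndarray = -1.0, level: float = 25.0,
                 offset: float = -15.0, at_test: int = 5,
                 shape: str = "exponential") -> VFSeries:
    """Small deterministic series with known analytic structure.

    * ``noise_free_linear`` — every location exactly ``baseline + slope*t``.
    * ``constant`` — all tests identical at ``level`` dB.
    * ``outlier_series`` — linear truth with one test shifted by ``offset``
      dB (exercises M-estimation).
    * ``nonlinear_truth`` — exponential or logistic trajectory with initial
      value ``baseline`` and initial derivative ``slope``.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    t = np.arange(n_tests) * interval
    b = np.broadcast_to(np.asarray(baseline, float), (N_POINTS,)).copy()
    s = np.broadcast_to(np.asarray(slope, float), (N_POINTS,)).copy()
    if kind == "constant":
        Y = np.full((n_tests, N_POINTS), float(level))
    elif kind == "noise_free_linear":
        Y = np.maximum(b[None, :] + s[None, :] * t[:, None], 0.0)
    elif kind == "outlier_series":
        Y = np.maximum(b[None, :] + s[None, :] * t[:, None], 0.0)
        Y[at_test - 1] = np.clip(Y[at_test - 1] + offset, 0.0, 40.0)
    else:
        Y = _truth_trajectory(b, s, t, shape)
    Y = np.clip(Y, 0.0, 40.0)
    series = VFSeries(eye_id=eye_id, patient_id=patient_id, laterality=laterality)
    for i in range(n_tests):
        series.tests.append(VFTest(eye_id=eye_id, test_index=i + 1,
                                   time_years=float(t[i]), sensitivities=Y[i]))
    return series


def write_truth(truth: TruthRecord, outdir: str | Path) -> None:
    """Write ``truth.csv`` (per point) and ``truth_eye.csv`` (per eye)."""
    outdir = Path(outdir)
    truth.point_frame().to_csv(outdir / "truth.csv", index=False)
    truth.eye_frame().to_csv(outdir / "truth_eye.csv", index=False)
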