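"""Domain model of the central 10-degree (10-2) visual field.

The 10-2 test pattern of the Humphrey Field Analyzer probes 68 locations
spaced 2 degrees apart within the central 10 degrees of vision.  Each
examination reports a light sensitivity in decibels (dB) per location,
censored to the instrument range [0, 40] dB, together with reliability
indices (fixation losses, false positives).  This module provides the grid
geometry, per-test summary indices (mean sensitivity, mean deviation),
reliability filtering, series preparation to a fixed 13-test follow-up, and
long-format CSV input/output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_POINTS = 68
SENS_MIN = 0.0
SENS_MAX = 40.0

#: reliability limits: a test with fixation losses strictly above 20 % or
#: false positives strictly above 15 % is discarded as unreliable
FIXATION_LOSS_LIMIT = 20.0
FALSE_POSITIVE_LIMIT = 15.0

#: number of examinations retained per eye for the longitudinal analysis
SERIES_LENGTH = 13

#: default age-expected sensitivity within the central 10 degrees
DEFAULT_NORMATIVE_DB = 33.0

CSV_COLUMNS = [
    "patient_id", "eye_id", "laterality", "test_index", "time_years",
    "fixation_loss_pct", "false_positive_pct", "point_index",
    "x_deg", "y_deg", "sensitivity_db",
]


class SchemaError(ValueError):
    """A CSV file does not conform to the long-format cohort schema."""


class IneligibleSeriesError(ValueError):
    """An eye does not have enough reliable tests for the analysis."""


@dataclass(frozen=True)
class GridPoint:
    """One 10-2 test location.

    ``x_deg``/``y_deg`` are eccentricities in degrees; on the 10-2 pattern
    both are odd integers with |x|, |y| <= 9 and x^2 + y^2 <= 82.
    """

    index: int
    x_deg: int
    y_deg: int


@dataclass(frozen=True)
class VFGrid:
    """The ordered 68-point 10-2 grid (row-major: y descending, x ascending)."""

    points: tuple[GridPoint, ...]

    def __len__(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        """(68, 2) array of (x_deg, y_deg)."""
        return np.array([(p.x_deg, p.y_deg) for p in self.points], dtype=float)


def build_grid_10_2() -> VFGrid:
    """Build the canonical 68-point 10-2 grid.

    Locations are all (x, y) with odd |x|, |y| <= 9 degrees subject to
    x^2 + y^2 <= 82 (the unique circular cutoff over the odd-offset lattice
    that yields exactly 68 points), ordered row-major with y descending and
    x ascending.
    """
    pts = []
    for y in range(9, -10, -2):
        for x in range(-9, 10, 2):
            if x * x + y * y <= 82:
                pts.append(GridPoint(index=len(pts), x_deg=x, y_deg=y))
    return VFGrid(points=tuple(pts))


@dataclass
class VFTest:
    """One visual-field examination of one eye."""

    eye_id: str
    test_index: int
    time_years: float
    sensitivities: np.ndarray
    fixation_loss_pct: float = 0.0
    false_positive_pct: float = 0.0

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        if self.sensitivities.shape != (N_POINTS,):
            raise ValueError(
                f"expected {N_POINTS} sensitivities, got {self.sensitivities.shape}"
            )
        if np.any(self.sensitivities < SENS_MIN) or np.any(self.sensitivities > SENS_MAX):
            raise ValueError("sensitivities outside the instrument range [0, 40] dB")


@dataclass
class NormativeGrid:
    """Age-expected sensitivity per location, used for the mean-deviation analogue."""

    normative_db: np.ndarray

    def __post_init__(self) -> None:
        self.normative_db = np.asarray(self.normative_db, dtype=float)
        if self.normative_db.shape != (N_POINTS,):
            raise ValueError(f"expected {N_POINTS} normative values")
        if np.any(self.normative_db <= 0) or np.any(self.normative_db > SENS_MAX):
            raise ValueError("normative values must lie in (0, 40] dB")

    @classmethod
    def constant(cls, level_db: float = DEFAULT_NORMATIVE_DB) -> "NormativeGrid":
        return cls(np.full(N_POINTS, float(level_db)))


@dataclass
class VFSeries:
    """Ordered examinations of one eye."""

    eye_id: str
    patient_id: str
    laterality: str
    tests: list[VFTest] = field(default_factory=list)

    def times(self) -> np.ndarray:
        return np.array([t.time_years for t in self.tests], dtype=float)

    def sensitivity_matrix(self) -> np.ndarray:
        """(n_tests, 68) matrix of sensitivities."""
        return np.array([t.sensitivities for t in self.tests], dtype=float)

    def __len__(self) -> int:
        return len(self.tests)


def mean_sensitivity(test: VFTest) -> float:
    """Unweighted mean of the 68 point-wise sensitivities (MS), dB."""
    return float(np.mean(test.sensitivities))


def mean_deviation(test: VFTest, norm: NormativeGrid) -> float:
    """Mean deviation analogue: unweighted mean of (sensitivity - normative), dB.

    Negative values indicate sensitivity loss.  Unlike the instrument's MD
    this is unweighted and uses a configurable normative grid.
    """
    return float(np.mean(test.sensitivities - norm.normative_db))


def is_reliable(test: VFTest) -> bool:
    """Reliability rule: discard tests with > 20 % fixation losses or > 15 %
    false positives (strict inequalities; boundary values are retained)."""
    return not (
        test.fixation_loss_pct > FIXATION_LOSS_LIMIT
        or test.false_positive_pct > FALSE_POSITIVE_LIMIT
    )


def prepare_series(raw: VFSeries, n_tests: int = SERIES_LENGTH) -> VFSeries:
    """Prepare a raw series for analysis.

    Drops unreliable tests, keeps the first ``n_tests`` reliable tests in
    chronological order, re-indexes them 1..n and rebases time so the first
    retained test is at 0 years.

    Raises
    ------
    IneligibleSeriesError
        If fewer than ``n_tests`` reliable tests remain.
    """
    reliable = [t for t in raw.tests if is_reliable(t)]
    if len(reliable) < n_tests:
        raise IneligibleSeriesError(
            f"eye {raw.eye_id}: {len(reliable)} reliable tests, {n_tests} required"
        )
    kept = reliable[:n_tests]
    t0 = kept[0].time_years
    tests = [
        replace(t, test_index=i + 1, time_years=t.time_years - t0,
                sensitivities=t.sensitivities.copy())
        for i, t in enumerate(kept)
    ]
    return VFSeries(eye_id=raw.eye_id, patient_id=raw.patient_id,
                    laterality=raw.laterality, tests=tests)


def prepare_cohort(
    cohort: Iterable[VFSeries], n_tests: int = SERIES_LENGTH
) -> tuple[list[VFSeries], list[str]]:
    """Prepare every eligible eye; return (prepared eyes, excluded eye ids)."""
    prepared, excluded = [], []
    for s in cohort:
        try:
            prepared.append(prepare_series(s, n_tests))
        except IneligibleSeriesError:
            excluded.append(s.eye_id)
    return prepared, excluded


# ---------------------------------------------------------------------------
# long-format CSV I/O

def series_to_frame(cohort: Sequence[VFSeries], grid: VFGrid | None = None) -> pd.DataFrame:
    grid = grid or build_grid_10_2()
    xs = np.array([p.x_deg for p in grid.points])
    ys = np.array([p.y_deg for p in grid.points])
    rows = []
    for s in cohort:
        for t in s.tests:
            rows.append(pd.DataFrame({
                "patient_id": s.patient_id,
                "eye_id": s.eye_id,
                "laterality": s.laterality,
                "test_index": t.test_index,
                "time_years": t.time_years,
                "fixation_loss_pct": t.fixation_loss_pct,
                "false_positive_pct": t.false_positive_pct,
                "point_index": np.arange(N_POINTS),
                "x_deg": xs,
                "y_deg": ys,
                "sensitivity_db": t.sensitivities,
            }))
    if not rows:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.concat(rows, ignore_index=True)[CSV_COLUMNS]


def write_series_csv(cohort: Sequence[VFSeries], path: str | Path) -> None:
    """Write a cohort as long-format CSV, one row per (eye, test, point)."""
    series_to_frame(cohort).to_csv(path, index=False)


def frame_to_series(df: pd.DataFrame) -> list[VFSeries]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if df.empty:
        return []
    dup = df.duplicated(subset=["eye_id", "test_index", "point_index"])
    if dup.any():
        row = df.index[dup][0]
        raise SchemaError(f"duplicate (eye, test, point) key at row {row}")
    cohort: list[VFSeries] = []
    for eye_id, eye_df in df.groupby("eye_id", sort=False):
        first = eye_df.iloc[0]
        series = VFSeries(eye_id=str(eye_id), patient_id=str(first["patient_id"]),
                          laterality=str(first["laterality"]))
        for test_index, test_df in eye_df.groupby("test_index", sort=True):
            if len(test_df) != N_POINTS:
                raise SchemaError(
                    f"eye {eye_id} test {test_index}: {len(test_df)} points, "
                    f"{N_POINTS} expected (first row {test_df.index[0]})"
                )
            test_df = test_df.sort_values("point_index")
            if not np.array_equal(test_df["point_index"].to_numpy(), np.arange(N_POINTS)):
                raise SchemaError(
                    f"eye {eye_id} test {test_index}: point_index not 0..{N_POINTS - 1}"
                )
            t = test_df.iloc[0]
            series.tests.append(VFTest(
                eye_id=str(eye_id),
                test_index=int(test_index),
                time_years=float(t["time_years"]),
                sensitivities=test_df["sensitivity_db"].to_numpy(dtype=float),
                fixation_loss_pct=float(t["fixation_loss_pct"]),
                false_positive_pct=float(t["false_positive_pct"]),
            ))
        series.tests.sort(key=lambda t: t.test_index)
        times = series.times()
        if np.any(np.diff(times) <= 0):
            raise SchemaError(f"eye {eye_id}: time_years not strictly increasing")
        cohort.append(series)
    return cohort


def read_series_csv(path: str | Path) -> list[VFSeries]:
    """Read a long-format cohort CSV (see ``write_series_csv``)."""
    df = pd.read_csv(path)
    return frame_to_series(df)


def write_normative_csv(norm: NormativeGrid, path: str | Path,
                        grid: VFGrid | None = None) -> None:
    grid = grid or build_grid_10_2()
    pd.DataFrame({
        "point_index": np.arange(N_POINTS),
        "x_deg": [p.x_deg for p in grid.points],
        "y_deg": [p.y_deg for p in grid.points],
        "normative_db": norm.normative_db,
    }).to_csv(path, index=False)


def read_normative_csv(path: str | Path) -> NormativeGrid:
    df = pd.read_csv(path)
    if "normative_db" not in df.columns or "point_index" not in df.columns:
        raise SchemaError("normative CSV needs point_index and normative_db columns")
    df = df.sort_values("point_index")
    return NormativeGrid(df["normative_db"].to_numpy(dtype=float))
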