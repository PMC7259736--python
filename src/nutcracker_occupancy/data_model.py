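"""Survey-data domain model: annual-cycle stages, detection histories, covariates.

The surveys this package analyses are repeated point counts for Clark's
nutcracker (*Nucifraga columbiana*): one survey is three sequential
ten-minute counts at a site, scored at two radii (within 100 m, and
unlimited distance).  Surveys are grouped into five stages of the
nutcracker annual cycle — breeding, early summer, late summer, fall seed
harvest and post-harvest — whose calendar boundaries are phenological and
therefore year-specific configuration.

This module provides the record types, CSV ingest with strict validation,
stage assignment, first-visit filtering (one detection history per
site-stage-year-radius), covariate standardization including the
binary + continuous decomposition used for zero-inflated habitat
variables, and naive (detection-uncorrected) occurrence metrics.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "StageWindows",
    "DEFAULT_STAGE_WINDOWS",
    "RadiusClass",
    "SurveyRecord",
    "DetectionHistory",
    "SiteCovariates",
    "DesignMatrix",
    "StageAssignmentError",
    "ValidationError",
    "assign_stage",
    "first_visit_filter",
    "zscore",
    "decompose_zero_inflated",
    "naive_metrics",
    "tally_surveys",
    "check_radius_consistency",
    "read_surveys",
    "read_covariates",
    "STUDY_SURVEY_SCHEDULE",
]


class Stage(str, Enum):
    """The five stages of the Clark's nutcracker annual cycle."""

    BREEDING = "breeding"
    EARLY_SUMMER = "early_summer"
    LATE_SUMMER = "late_summer"
    FALL_HARVEST = "fall_harvest"
    POST_HARVEST = "post_harvest"

    @property
    def order(self) -> int:
        return _STAGE_ORDER[self]


_STAGE_ORDER = {s: i for i, s in enumerate(Stage)}


class RadiusClass(str, Enum):
    """Survey radius at which detections were scored."""

    WITHIN_100M = "within_100m"
    INFINITE = "infinite"


class StageAssignmentError(ValueError):
    """A survey date that falls outside every configured stage window."""


class ValidationError(ValueError):
    """Malformed or internally inconsistent survey/covariate input."""


#: Default stage windows as (month, day) inclusive bounds.  The breeding
#: window opens on March 5 (earliest observed nest building) and closes
#: June 15 (last nestling observed); early summer starts June 16.  The
#: early/late-summer and harvest boundaries depend on whitebark pine cone
#: phenology, so per-year overrides are expected for real field data;
#: these defaults follow the typical survey calendar of the 2009-2013
#: Greater Yellowstone study.
DEFAULT_STAGE_WINDOWS: dict[Stage, tuple[tuple[int, int], tuple[int, int]]] = {
    Stage.BREEDING: ((3, 5), (6, 15)),
    Stage.EARLY_SUMMER: ((6, 16), (7, 6)),
    Stage.LATE_SUMMER: ((7, 7), (8, 11)),
    Stage.FALL_HARVEST: ((8, 12), (9, 28)),
    Stage.POST_HARVEST: ((9, 29), (10, 31)),
}


@dataclass(frozen=True)
class StageWindows:
    """Year-specific stage calendar.

    Parameters
    ----------
    windows
        Mapping from stage to an inclusive ``((start_month, start_day),
        (end_month, end_day))`` pair.  Windows must be ordered in the
        canonical stage order and non-overlapping.
    overrides
        Optional per-year replacement windows, keyed by calendar year.
    """

    windows: Mapping[Stage, tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_WINDOWS)
    )
    overrides: Mapping[int, Mapping[Stage, tuple[tuple[int, int], tuple[int, int]]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self._check(self.windows)
        for year_windows in self.overrides.values():
            self._check(year_windows)

    @staticmethod
    def _check(windows: Mapping[Stage, tuple[tuple[int, int], tuple[int, int]]]) -> None:
        prev_end = None
        for stage in Stage:
            if stage not in windows:
                raise ValidationError(f"missing window for stage {stage.value!r}")
            (sm, sd), (em, ed) = windows[stage]
            if (sm, sd) > (em, ed):
                raise ValidationError(f"window for {stage.value!r} ends before it starts")
            if prev_end is not None and (sm, sd) <= prev_end:
                raise ValidationError(
                    f"window for {stage.value!r} overlaps or precedes the previous stage"
                )
            prev_end = (em, ed)

    def for_year(self, year: int) -> Mapping[Stage, tuple[tuple[int, int], tuple[int, int]]]:
        return self.overrides.get(year, self.windows)


def assign_stage(date: _dt.date, windows: StageWindows | None = None) -> Stage:
    """Map a survey date to its annual-cycle stage.

    Raises
    ------
    StageAssignmentError
        If the date falls outside every configured window (e.g. mid-winter).
    """
    windows = windows or StageWindows()
    year_windows = windows.for_year(date.year)
    key = (date.month, date.day)
    for stage in Stage:
        start, end = year_windows[stage]
        if start <= key <= end:
            return stage
    raise StageAssignmentError(
        f"{date.isoformat()} falls outside all stage windows for {date.year}"
    )


@dataclass(frozen=True)
class SurveyRecord:
    """One survey visit: three sequential ten-minute counts at one radius."""

    site_id: str
    year: int
    date: _dt.date
    stage: Stage
    counts: tuple[int, int, int]
    radius_class: RadiusClass

    def __post_init__(self) -> None:
        if len(self.counts) != 3:
            raise ValidationError(f"counts must have exactly 3 entries, got {self.counts}")
        if any(c not in (0, 1) for c in self.counts):
            raise ValidationError(f"counts must be binary, got {self.counts}")
        if self.date.year != self.year:
            raise ValidationError(
                f"date {self.date.isoformat()} does not match year {self.year}"
            )


@dataclass(frozen=True)
class DetectionHistory:
    """Detection history for one (site, year, stage, radius) survey unit."""

    site_id: str
    year: int
    stage: Stage
    radius_class: RadiusClass
    h: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.h) != 3 or any(v not in (0, 1) for v in self.h):
            raise ValidationError(f"history must be a binary triple, got {self.h}")


@dataclass(frozen=True)
class SiteCovariates:
    """Per-site habitat measurements.

    Units: cone density in cones/ha; importance values on the 0-300
    point-quarter scale; landscape areas in hectares (whitebark pine
    within 32.6 km, Douglas-fir within 3.2 km); tree density in trees/ha.
    """

    site_id: str
    cone_density: float
    wbp_importance: float
    df_importance: float
    wbp_landscape_area: float
    df_landscape_area: float
    tree_density: float

    def __post_init__(self) -> None:
        for name in (
            "cone_density",
            "wbp_importance",
            "df_importance",
            "wbp_landscape_area",
            "df_landscape_area",
            "tree_density",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and non-negative, got {v}")
        for name in ("wbp_importance", "df_importance"):
            if getattr(self, name) > 300:
                raise ValidationError(f"{name} exceeds the 300-point maximum")


def first_visit_filter(records: Sequence[SurveyRecord]) -> list[SurveyRecord]:
    """Keep only the earliest visit per (site, year, stage, radius) unit.

    Repeat visits to a site within the same stage and year are dropped so
    that each survey unit contributes exactly one detection history; ties
    on date are broken by stable input order.  Idempotent.
    """
    best: dict[tuple[str, int, Stage, RadiusClass], SurveyRecord] = {}
    for rec in records:
        key = (rec.site_id, rec.year, rec.stage, rec.radius_class)
        if key not in best or rec.date < best[key].date:
            best[key] = rec
    kept = set(id(r) for r in best.values())
    return [r for r in records if id(r) in kept]


def zscore(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd, ``n-1`` denominator).

    Raises
    ------
    ValidationError
        For vectors shorter than 2 or with zero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("zscore requires a 1-d vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("zscore input must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def decompose_zero_inflated(
    values: Sequence[float] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a zero-inflated covariate into (absence indicator, magnitude).

    Zero-inflated habitat variables (cone density, importance values) enter
    occurrence models as a pair: a binary term coded 1 where the resource is
    *absent* (value 0) and 0 where present, plus a continuous term that is
    the z-score of the strictly positive values, set to 0 at absent sites so
    the magnitude effect vanishes exactly when the binary term signals
    absence.  This lets the model intercept shift with presence/absence
    while the magnitude slope acts only where the resource exists.

    Returns
    -------
    (absence, magnitude)
        ``absence`` is a 0/1 float vector; ``magnitude`` is the standardized
        positive part.  With fewer than two distinct positive values the
        magnitude column is returned as all-NaN (flagged undefined).
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValidationError("zero-inflated covariate must be finite and non-negative")
    absence = (x == 0).astype(float)
    positive = x[x > 0]
    magnitude = np.zeros_like(x)
    if positive.size < 2 or positive.std(ddof=1) == 0:
        magnitude[:] = np.nan
        magnitude[x == 0] = np.nan
        return absence, magnitude
    z = (x - positive.mean()) / positive.std(ddof=1)
    magnitude = np.where(x > 0, z, 0.0)
    return absence, magnitude


def naive_metrics(h: DetectionHistory | Sequence[int]) -> tuple[int, float]:
    """Naive occurrence and proportion of counts with a detection.

    ``naive_occurrence`` is 1 iff the species was detected on at least one
    of the three counts (no correction for imperfect detection);
    ``proportion_detected`` is the number of counts with a detection
    divided by 3 — the response variable used by earlier cone-crop
    occurrence models.
    """
    counts = h.h if isinstance(h, DetectionHistory) else tuple(h)
    if len(counts) != 3 or any(c not in (0, 1) for c in counts):
        raise ValidationError(f"history must be a binary triple, got {counts}")
    total = sum(counts)
    return (1 if total > 0 else 0, total / 3.0)


def tally_surveys(records: pd.DataFrame | Sequence[SurveyRecord]) -> pd.Series:
    """Count surveys per stage plus a grand total.

    Accepts either a list of :class:`SurveyRecord` or a table with a
    ``stage`` column and (optionally) an ``n_surveys`` column of
    pre-aggregated counts, as in a published survey-effort schedule.
    Returns a Series indexed by stage name with a final ``total`` entry.
    """
    if isinstance(records, pd.DataFrame):
        if "stage" not in records.columns:
            raise ValidationError("survey table must have a 'stage' column")
        stages = records["stage"].map(lambda s: Stage(s).value)
        if "n_surveys" in records.columns:
            counts = records.groupby(stages, sort=False)["n_surveys"].sum()
        else:
            counts = stages.value_counts(sort=False)
    else:
        stages = pd.Series([r.stage.value for r in records], dtype=object)
        counts = stages.value_counts(sort=False)
    out = pd.Series(
        [int(counts.get(s.value, 0)) for s in Stage],
        index=[s.value for s in Stage],
        dtype=int,
    )
    out["total"] = int(out.sum())
    return out


#: Survey effort of the 2009-2013 Greater Yellowstone nutcracker study:
#: number of surveys per annual-cycle stage and year.  Used as a reference
#: schedule for tallies and for sizing realistic simulations.
STUDY_SURVEY_SCHEDULE = pd.DataFrame(
    [
        ("breeding", 2009, 0),
        ("breeding", 2010, 0),
        ("breeding", 2011, 123),
        ("breeding", 2012, 0),
        ("breeding", 2013, 261),
        ("early_summer", 2009, 0),
        ("early_summer", 2010, 0),
        ("early_summer", 2011, 51),
        ("early_summer", 2012, 6),
        ("early_summer", 2013, 132),
        ("late_summer", 2009, 144),
        ("late_summer", 2010, 3),
        ("late_summer", 2011, 189),
        ("late_summer", 2012, 6),
        ("late_summer", 2013, 411),
        ("fall_harvest", 2009, 144),
        ("fall_harvest", 2010, 0),
        ("fall_harvest", 2011, 165),
        ("fall_harvest", 2012, 72),
        ("fall_harvest", 2013, 612),
        ("post_harvest", 2009, 144),
        ("post_harvest", 2010, 0),
        ("post_harvest", 2012, 45),
        ("post_harvest", 2013, 18),
    ],
    columns=["stage", "year", "n_surveys"],
)


def check_radius_consistency(records: Iterable[SurveyRecord]) -> list[str]:
    """Validate paired-radius records from the same physical visit.

    A detection within 100 m implies a detection at infinite radius for the
    same ten-minute count: the two radius classes are scored from one visit,
    with the 100 m class a strict subset.  Returns a list of human-readable
    violation messages (empty when consistent).
    """
    by_visit: dict[tuple[str, int, _dt.date], dict[RadiusClass, SurveyRecord]] = {}
    for rec in records:
        by_visit.setdefault((rec.site_id, rec.year, rec.date), {})[rec.radius_class] = rec
    problems = []
    for (site, year, date), pair in by_visit.items():
        if len(pair) < 2:
            continue
        near = pair[RadiusClass.WITHIN_100M].counts
        far = pair[RadiusClass.INFINITE].counts
        for t, (n, f) in enumerate(zip(near, far), start=1):
            if n == 1 and f == 0:
                problems.append(
                    f"site {site} {date.isoformat()}: count {t} detected within 100 m "
                    "but not at infinite radius"
                )
    return problems


_SURVEY_COLUMNS = {"site_id", "year", "date", "count1", "count2", "count3", "radius_class"}
_COVARIATE_COLUMNS = {
    "site_id",
    "cone_density",
    "wbp_importance",
    "df_importance",
    "wbp_landscape_area",
    "df_landscape_area",
    "tree_density",
}


def read_surveys(
    path,
    windows: StageWindows | None = None,
    check_radius: bool = True,
) -> list[SurveyRecord]:
    """Read and validate a survey CSV.

    Required columns: ``site_id, year, date, count1..count3, radius_class``;
    a ``stage`` column is optional and derived from the date when absent.
    Dates are ISO-8601.  Raises :class:`ValidationError` on header problems,
    non-binary counts, stage/date mismatches or radius inconsistencies.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = _SURVEY_COLUMNS - set(df.columns)
    if missing:
        raise ValidationError(f"survey CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        date = _dt.date.fromisoformat(str(row.date))
        if hasattr(row, "stage") and isinstance(row.stage, str) and row.stage:
            stage = Stage(row.stage)
        else:
            stage = assign_stage(date, windows)
        records.append(
            SurveyRecord(
                site_id=str(row.site_id),
                year=int(row.year),
                date=date,
                stage=stage,
                counts=(int(row.count1), int(row.count2), int(row.count3)),
                radius_class=RadiusClass(row.radius_class),
            )
        )
    if check_radius:
        problems = check_radius_consistency(records)
        if problems:
            raise ValidationError("radius inconsistencies:\n" + "\n".join(problems))
    return records


def read_covariates(path) -> pd.DataFrame:
    """Read a site-covariate CSV keyed by ``site_id`` (strict headers)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = _COVARIATE_COLUMNS - set(df.columns)
    if missing:
        raise ValidationError(f"covariate CSV missing columns: {sorted(missing)}")
    values = df[
        [c for c in df.columns if c != "site_id" and c in _COVARIATE_COLUMNS]
    ].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValidationError("covariates must be finite and non-negative")
    if df["site_id"].duplicated().any():
        raise ValidationError("duplicate site_id in covariate CSV")
    return df.set_index("site_id")


@dataclass
class DesignMatrix:
    """Standardized covariate design aligned to detection-history units.

    ``X`` holds one column per model term; ``terms`` groups columns into
    selectable blocks (a zero-inflated covariate contributes an
    ``(absence, magnitude)`` pair that is included or excluded together).
    ``column_stats`` records the mean/sd used for each standardized column
    (for zero-inflated pairs, over the strictly positive subset) so
    predictions can be made on the original covariate scale.
    """

    X: np.ndarray
    columns: list[str]
    terms: dict[str, list[str]]
    column_stats: dict[str, tuple[float, float]]
    column_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValidationError("X shape does not match column labels")

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def term_column_indices(self, term: str) -> list[int]:
        return [self.column_index(c) for c in self.terms[term]]


def build_design_matrix(
    units: pd.DataFrame,
    continuous: Sequence[str] = ("wbp_landscape_area", "df_landscape_area"),
    zero_inflated: Sequence[str] = ("cone_density",),
) -> DesignMatrix:
    """Assemble the occurrence design matrix from per-unit covariate columns.

    Plain continuous covariates are z-scored over all units; zero-inflated
    covariates are decomposed into an (absence, magnitude) column pair.
    Each covariate becomes one selectable term; the pair counts as one term.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    terms: dict[str, list[str]] = {}
    stats: dict[str, tuple[float, float]] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for name in continuous:
        x = units[name].to_numpy(dtype=float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        cols.append(zscore(x))
        names.append(name)
        terms[name] = [name]
        stats[name] = (mu, sd)
        ranges[name] = (float(x.min()), float(x.max()))
    for name in zero_inflated:
        x = units[name].to_numpy(dtype=float)
        absence, magnitude = decompose_zero_inflated(x)
        if np.isnan(magnitude).any():
            raise ValidationError(
                f"zero-inflated covariate {name!r} has no positive variation"
            )
        pos = x[x > 0]
        a_name, m_name = f"{name}_absent", f"{name}_magnitude"
        cols.extend([absence, magnitude])
        names.extend([a_name, m_name])
        terms[name] = [a_name, m_name]
        stats[a_name] = (0.0, 1.0)
        stats[m_name] = (float(pos.mean()), float(pos.std(ddof=1)))
        ranges[a_name] = (0.0, 1.0)
        ranges[m_name] = (float(pos.min()), float(pos.max()))
    X = np.column_stack(cols) if cols else np.empty((len(units), 0))
    return DesignMatrix(
        X=X, columns=names, terms=terms, column_stats=stats, column_ranges=ranges
    )
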