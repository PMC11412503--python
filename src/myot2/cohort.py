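"""Cohort-level statistics for the distribution biomarkers.

Covers the study-design questions the biomarkers exist for:

* test-retest repeatability via Bland-Altman analysis, with the minimum
  detectable change MDC = 1.96 * sd(differences) — the smallest change in
  a metric that exceeds measurement noise at ~95% confidence;
* simple linear regression of an external damage measure (Evans-blue dye
  uptake) on an image metric;
* ranking animals along a composite severity axis from the (IDR, skew)
  pair, and serpentine assignment of ranked animals into balanced
  treatment groups, optionally excluding the extremes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

from ._exceptions import InvalidParameterError, NumericalError

__all__ = [
    "CohortRecord",
    "RepeatabilityResult",
    "RegressionResult",
    "StratificationResult",
    "records_to_frame",
    "bland_altman",
    "regress_metric_vs_dye",
    "stratify",
    "balance_groups",
    "linearly_separable",
]

GENOTYPES = ("WT", "mdxB10", "mdxD2", "other")


@dataclass
class CohortRecord:
    """One animal/session row: genotype, metrics and optional ground truth.

    ``dye_uptake`` is in arbitrary optical-density units per mg of tissue;
    ``severity_true`` / ``lesion_burden`` are only set for synthetic data.
    """

    animal_id: str
    genotype: str = "other"
    session: int = 1
    idr_ms: float | None = None
    pearson_skew: float | None = None
    dye_uptake: float | None = None
    severity_true: float | None = None
    lesion_burden: float | None = None


def records_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    """Tabulate records; (animal_id, session) must be unique."""
    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        return df
    if df.duplicated(subset=["animal_id", "session"]).any():
        raise InvalidParameterError("duplicate (animal_id, session) pairs in cohort")
    return df


@dataclass(frozen=True)
class RepeatabilityResult:
    """Bland-Altman summary of paired test-retest measurements."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    mdc: float
    mdc_pct: float
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("bias", "loa_low", "loa_high", "sd_diff", "mdc", "mdc_pct", "n")}


def bland_altman(pairs: Sequence[tuple[float, float]]) -> RepeatabilityResult:
    """Bland-Altman agreement of session-1 vs session-2 measurements.

    Differences are session2 - session1.  Limits of agreement are
    bias +/- 1.96 sd; MDC = 1.96 sd (sd with n-1 denominator), reported
    also as a percentage of the grand mean of all 2n measurements.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InvalidParameterError("bland_altman needs at least 2 (s1, s2) pairs")
    diffs = arr[:, 1] - arr[:, 0]
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        warnings.warn("all paired differences identical: sd of differences is 0",
                      stacklevel=2)
    mdc = 1.96 * sd
    grand_mean = float(arr.mean())
    mdc_pct = 100.0 * mdc / grand_mean if grand_mean != 0 else float("nan")
    return RepeatabilityResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        sd_diff=sd, mdc=mdc, mdc_pct=mdc_pct, n=arr.shape[0],
    )


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression summary (dye regressed on an image metric)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("slope", "intercept", "r_squared", "p_value", "stderr", "n")}


_METRIC_COLUMNS = {"idr": "idr_ms", "skew": "pearson_skew", "burden": "lesion_burden"}


def regress_metric_vs_dye(records: pd.DataFrame | Iterable[CohortRecord],
                          metric: str = "idr") -> RegressionResult:
    """OLS of dye uptake on a metric across animals; two-sided slope p-value."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    col = _METRIC_COLUMNS.get(metric, metric)
    if col not in df.columns:
        raise InvalidParameterError(f"unknown metric column {metric!r}")
    sub = df[[col, "dye_uptake"]].dropna()
    if len(sub) < 3:
        raise InvalidParameterError("regression needs >= 3 records with metric and dye values")
    x = sub[col].to_numpy(dtype=np.float64)
    y = sub["dye_uptake"].to_numpy(dtype=np.float64)
    if np.ptp(x) == 0:
        raise NumericalError("metric has zero variance: regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), p_value=float(res.pvalue),
                            stderr=float(res.stderr), n=len(sub))


@dataclass(frozen=True)
class StratificationResult:
    """Cohort ordered along the composite severity axis."""

    table: pd.DataFrame  # per-animal rows with ranks, sorted mild -> severe
    group_summary: pd.DataFrame  # median / IQR of each metric per genotype
    scatter: pd.DataFrame = field(repr=False)  # (idr_ms, pearson_skew) for plotting


def stratify(records: pd.DataFrame | Iterable[CohortRecord]) -> StratificationResult:
    """Rank animals by disease severity from the (IDR, Pearson skew) pair.

    The composite is the sum of the two metrics' ranks (average ranks on
    ties), which is monotone in both metrics and invariant to any
    increasing rescaling of either one.  No training data or fitted
    discriminant is involved.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) < 2:
        raise InvalidParameterError("stratify needs >= 2 records")
    df = df.copy()
    for col in ("idr_ms", "pearson_skew"):
        if col not in df.columns or df[col].isna().any():
            raise InvalidParameterError(f"stratify requires complete column {col!r}")
    df["idr_rank"] = stats.rankdata(df["idr_ms"])
    df["skew_rank"] = stats.rankdata(df["pearson_skew"])
    df["severity_rank_score"] = df["idr_rank"] + df["skew_rank"]
    df = df.sort_values(
        ["severity_rank_score", "idr_ms", "animal_id"], kind="mergesort"
    ).reset_index(drop=True)
    df["severity_rank"] = np.arange(1, len(df) + 1)

    def _iqr(x: pd.Series) -> float:
        return float(np.percentile(x, 75) - np.percentile(x, 25))

    group_summary = (
        df.groupby("genotype")[["idr_ms", "pearson_skew"]]
        .agg(["median", _iqr, "count"])
        .rename(columns={"_iqr": "iqr"})
    )
    scatter = df[["animal_id", "genotype", "idr_ms", "pearson_skew"]].copy()
    return StratificationResult(table=df, group_summary=group_summary, scatter=scatter)


def balance_groups(records: pd.DataFrame | Iterable[CohortRecord], n_groups: int,
                   exclude_extremes: tuple[float, float] | None = None) -> pd.DataFrame:
    """Serpentine (snake) assignment of severity-ranked animals into groups.

    Animals are ranked by :func:`stratify` and dealt out in the order
    1..k, k..1, 1..k, ... so every group samples the whole severity
    spectrum.  ``exclude_extremes=(p_lo, p_hi)`` drops animals whose rank
    percentile (rank - 0.5)/n falls outside [p_lo, p_hi] (fractions in
    [0, 1]), the a-priori exclusion of unusually mild or severe animals.
    Returns the stratified table with a ``group`` column (NaN = excluded).
    """
    if n_groups < 1:
        raise InvalidParameterError("n_groups must be >= 1")
    table = stratify(records).table.copy()
    n = len(table)
    if n < n_groups:
        raise InvalidParameterError("need at least one animal per group")
    keep = np.ones(n, dtype=bool)
    if exclude_extremes is not None:
        p_lo, p_hi = exclude_extremes
        pos = (table["severity_rank"].to_numpy() - 0.5) / n
        keep = (pos >= p_lo) & (pos <= p_hi)
    cycle = list(range(n_groups)) + list(range(n_groups - 1, -1, -1))
    assignment = np.full(n, np.nan)
    for j, i in enumerate(np.nonzero(keep)[0]):
        assignment[i] = cycle[j % len(cycle)]
    table["group"] = assignment
    return table


def linearly_separable(points_a: np.ndarray, points_b: np.ndarray) -> bool:
    """True if two 2-D point clouds can be split by a straight line
    (equivalently, their convex hulls do not intersect).  Feasibility of
    ``w.x + b >= 1`` on A and ``<= -1`` on B, checked by linear programming."""
    a = np.atleast_2d(np.asarray(points_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(points_b, dtype=np.float64))
    d = a.shape[1]
    # variables: w (d), b; constraints as A_ub x <= b_ub
    a_ub = np.vstack([np.hstack([-a, -np.ones((len(a), 1))]),
                      np.hstack([b, np.ones((len(b), 1))])])
    b_ub = -np.ones(len(a) + len(b))
    res = linprog(c=np.zeros(d + 1), A_ub=a_ub, b_ub=b_ub,
                  bounds=[(None, None)] * (d + 1), method="highs")
    return bool(res.status == 0)
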