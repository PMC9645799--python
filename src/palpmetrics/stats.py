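"""Group comparisons and outcome models.

Three analyses relate palpation metrics to skill and to cannulation outcome:

* Pairwise Mann-Whitney U tests of each metric between the HP / MP / LP
  groups, starred at the 0.05 / 0.01 / 0.001 levels (raw p values, no
  multiple-testing correction).
* Per-group probability of successful cannulation (the stable-flashback
  flag ``stb``) with a 95% Wilson score interval.
* Stratified univariate logistic regressions of ``stb`` on each force
  metric within a skill group, with Wald p values and separation detection,
  summarized for significant metrics by a monotone Hill curve fitted to the
  decile-binned empirical success rates.

Comparisons are trial-level (within-subject clustering ignored); a
per-subject-median sensitivity mode is available in the report builders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import mannwhitneyu
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import EmptySample, FitFailure, SingleClass, ZeroTrials

__all__ = [
    "ComparisonResult",
    "SuccessEstimate",
    "LogisticFit",
    "HillCurve",
    "mann_whitney_u",
    "p_star",
    "success_probability_ci",
    "fit_univariate_logistic",
    "fit_hill_curve",
    "compare_groups",
    "success_table",
    "logistic_table",
    "hill_fits",
    "build_reports",
]

#: force-metric suite entering the stratified univariate outcome models
FORCE_MODEL_METRICS = (
    "idle_time",
    "dwell_time",
    "mean_tpt",
    "touchpoints",
    "total_force",
    "force_range",
    "frequency",
)

#: metrics requiring complete position data (compared on the location-valid subset)
LOCATION_METRICS = ("path_length", "rcm", "rntp", "mean_tpd")

GROUP_ORDER = ("LP", "MP", "HP")
PAIR_ORDER = (("LP", "HP"), ("LP", "MP"), ("MP", "HP"))


def p_star(p: float) -> str:
    """Significance stars at the conventional 0.05 / 0.01 / 0.001 thresholds."""
    if not np.isfinite(p):
        return "nc"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    U: float
    p: float
    star: str


@dataclass(frozen=True)
class SuccessEstimate:
    group: str
    n: int
    k: int
    p_hat: float
    ci_lo: float
    ci_hi: float


@dataclass(frozen=True)
class LogisticFit:
    metric: str
    stratum: str
    slope: float
    intercept: float
    p_wald: float
    converged: bool
    separation: bool


@dataclass(frozen=True)
class HillCurve:
    """Monotone sigmoid p(x) = p_min + (p_max - p_min) * x^h / (k^h + x^h).

    For ``direction == "decreasing"`` the mirrored form
    p(x) = p_min + (p_max - p_min) * k^h / (k^h + x^h) is used. ``k`` is the
    half-effect point in metric units and ``h > 0`` the Hill coefficient.
    """

    direction: str
    p_min: float
    p_max: float
    k: float
    h: float

    def __call__(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, float), 1e-12, None)
        frac = x**self.h / (self.k**self.h + x**self.h)
        if self.direction == "decreasing":
            frac = 1.0 - frac
        return self.p_min + (self.p_max - self.p_min) * frac


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for sample a, p).

    Uses the exact null distribution when both samples have at most 8
    observations and there are no ties (exhaustive over rank arrangements),
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise EmptySample("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def success_probability_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float, float]:
    """Binomial proportion with 95% Wilson score interval: (p_hat, lo, hi)."""
    if n < 1:
        raise ZeroTrials("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return k / n, float(lo), float(hi)


def fit_univariate_logistic(x, y, metric: str = "", stratum: str = "") -> LogisticFit:
    """Maximum-likelihood univariate logistic regression of y on x.

    Fits logit p = intercept + slope * x by Newton iteratively reweighted
    least squares and reports the Wald p value of the slope. Perfectly
    separated data (monotone likelihood) sets the ``separation`` flag and
    suppresses the coefficients.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise SingleClass("y must contain both classes")
    if len(x) != len(y) or len(x) < 10:
        raise ValueError("need len(x) == len(y) >= 10")

    # geometric separation check: a threshold on x splits the classes exactly
    if np.max(x[y == 0]) < np.min(x[y == 1]) or np.max(x[y == 1]) < np.min(x[y == 0]):
        return LogisticFit(metric, stratum, np.nan, np.nan, np.nan, False, True)

    X = sm.add_constant(x)
    try:
        fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticFit(metric, stratum, np.nan, np.nan, np.nan, False, True)
    converged = bool(fit.mle_retvals.get("converged", False))
    if not np.all(np.isfinite(fit.params)) or not np.all(np.isfinite(fit.bse)):
        return LogisticFit(metric, stratum, np.nan, np.nan, np.nan, False, True)
    return LogisticFit(
        metric=metric,
        stratum=stratum,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_wald=float(fit.pvalues[1]),
        converged=converged,
        separation=False,
    )


def fit_hill_curve(x, y, direction: str, n_bins: int = 10) -> HillCurve:
    """Fit a monotone Hill curve to decile-binned empirical success rates.

    ``x`` are metric values, ``y`` the 0/1 outcomes, ``direction`` the
    monotonicity hint ("increasing" or "decreasing") — normally the sign of
    the corresponding logistic slope. Parameters are box-constrained:
    0 <= p_min, p_max <= 1, k inside the data range, h in [0.1, 20].
    Raises :class:`FitFailure` for flat responses or non-convergence.
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be increasing|decreasing")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        raise FitFailure("metric values too discrete to bin")
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    centers, rates, weights = [], [], []
    for b in range(len(edges) - 1):
        m = which == b
        if m.sum() == 0:
            continue
        centers.append(x[m].mean())
        rates.append(y[m].mean())
        weights.append(m.sum())
    centers = np.asarray(centers)
    rates = np.asarray(rates)
    weights = np.asarray(weights, float)

    lo_x = max(np.min(centers), 1e-9)
    hi_x = max(np.max(centers), lo_x * (1 + 1e-6))

    def model(xx, p_min, p_max, k, h):
        return HillCurve(direction, p_min, p_max, k, h)(xx)

    p0 = [
        float(np.clip(np.min(rates), 0, 1)),
        float(np.clip(np.max(rates), 0, 1)),
        float(np.clip(np.median(x), lo_x, hi_x)),
        1.5,
    ]
    try:
        popt, _ = optimize.curve_fit(
            model,
            centers,
            rates,
            p0=p0,
            sigma=1.0 / np.sqrt(weights),
            bounds=([0.0, 0.0, lo_x, 0.1], [1.0, 1.0, hi_x, 20.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailure(f"Hill optimizer failed: {exc}") from exc
    p_min, p_max, k, h = popt
    if p_min > p_max:
        raise FitFailure("fitted range inverted; response not monotone as hinted")
    if p_max - p_min < 0.05:
        raise FitFailure(
            "flat response: fitted range < 0.05, Hill parameters unidentifiable"
        )
    if h >= 0.98 * 20.0 or h <= 1.02 * 0.1:
        raise FitFailure(
            "Hill coefficient pinned at its bound: response shape unidentifiable"
        )
    return HillCurve(direction, float(p_min), float(p_max), float(k), float(h))


# ---------------------------------------------------------------------------
# report builders (Table-1- and Table-2-style summaries)
# ---------------------------------------------------------------------------


def _metric_frame(df: pd.DataFrame, metric: str, per_subject: bool) -> pd.DataFrame:
    sub = df
    if metric in LOCATION_METRICS and "location_valid" in df.columns:
        sub = df[df["location_valid"].astype(bool)]
    sub = sub[np.isfinite(sub[metric].astype(float))]
    if per_subject:
        sub = (
            sub.groupby(["group", "subject_id"], as_index=False)[metric]
            .median()
        )
    return sub


def compare_groups(
    df: pd.DataFrame, metrics=None, per_subject: bool = False
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of each metric across skill groups.

    ``df`` needs columns ``group``, ``subject_id``, ``location_valid`` and
    the metric columns. Location metrics are restricted to location-valid
    trials. Emits both means and medians per group (their respective
    central-tendency conventions differ across reports). Pairs lacking data
    get star ``nc`` (not computable).
    """
    from .metrics import METRIC_NAMES

    metrics = list(metrics) if metrics is not None else list(METRIC_NAMES)
    rows = []
    for metric in metrics:
        sub = _metric_frame(df, metric, per_subject)
        for ga, gb in PAIR_ORDER:
            a = sub.loc[sub["group"] == ga, metric].to_numpy(float)
            b = sub.loc[sub["group"] == gb, metric].to_numpy(float)
            if a.size == 0 or b.size == 0:
                rows.append(
                    ComparisonResult(metric, ga, gb, a.size, b.size,
                                     np.nan, np.nan, np.nan, np.nan,
                                     np.nan, np.nan, "nc")
                )
                continue
            U, p = mann_whitney_u(a, b)
            rows.append(
                ComparisonResult(
                    metric, ga, gb, a.size, b.size,
                    float(a.mean()), float(b.mean()),
                    float(np.median(a)), float(np.median(b)),
                    U, p, p_star(p),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def success_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-group cannulation success probability with 95% Wilson CI."""
    rows = []
    for g in GROUP_ORDER:
        sub = df[df["group"] == g]
        n = len(sub)
        if n == 0:
            rows.append(SuccessEstimate(g, 0, 0, np.nan, np.nan, np.nan))
            continue
        k = int(sub["stb"].sum())
        p_hat, lo, hi = success_probability_ci(k, n)
        rows.append(SuccessEstimate(g, n, k, p_hat, lo, hi))
    return pd.DataFrame([r.__dict__ for r in rows])


def logistic_table(df: pd.DataFrame, metrics=FORCE_MODEL_METRICS) -> pd.DataFrame:
    """Stratified univariate logistic models of stb on each force metric."""
    rows = []
    for g in GROUP_ORDER:
        sub = df[df["group"] == g]
        for metric in metrics:
            x = sub[metric].to_numpy(float)
            y = sub["stb"].to_numpy(float)
            m = np.isfinite(x)
            x, y = x[m], y[m]
            if len(x) < 10 or len(np.unique(y)) < 2:
                rows.append(LogisticFit(metric, g, np.nan, np.nan, np.nan, False, False))
                continue
            rows.append(fit_univariate_logistic(x, y, metric=metric, stratum=g))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["star"] = out["p_wald"].map(p_star)
    return out


def hill_fits(
    df: pd.DataFrame, logit_df: pd.DataFrame, alpha: float = 0.05
) -> dict[str, dict]:
    """Hill-curve summaries for every significant stratified logistic model."""
    curves: dict[str, dict] = {}
    sig = logit_df[
        (~logit_df["separation"])
        & np.isfinite(logit_df["p_wald"])
        & (logit_df["p_wald"] < alpha)
    ]
    for _, row in sig.iterrows():
        g, metric = row["stratum"], row["metric"]
        sub = df[df["group"] == g]
        x = sub[metric].to_numpy(float)
        y = sub["stb"].to_numpy(float)
        m = np.isfinite(x)
        direction = "increasing" if row["slope"] > 0 else "decreasing"
        try:
            c = fit_hill_curve(x[m], y[m], direction)
        except FitFailure:
            continue
        curves[f"{g}:{metric}"] = {
            "stratum": g,
            "metric": metric,
            "direction": c.direction,
            "p_min": c.p_min,
            "p_max": c.p_max,
            "k": c.k,
            "h": c.h,
            "logistic_slope": float(row["slope"]),
            "logistic_p": float(row["p_wald"]),
        }
    return curves


def build_reports(df: pd.DataFrame, out_dir: str | Path, per_subject: bool = False) -> dict[str, Path]:
    """Write table1.csv, success.csv, table2.csv and hill_curves.json.

    Deterministic row order and float formatting: regenerating from the same
    inputs produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    t1 = compare_groups(df, per_subject=per_subject)
    paths["table1"] = out_dir / "table1.csv"
    t1.to_csv(paths["table1"], index=False, float_format="%.10g", lineterminator="\n")

    succ = success_table(df)
    paths["success"] = out_dir / "success.csv"
    succ.to_csv(paths["success"], index=False, float_format="%.10g", lineterminator="\n")

    t2 = logistic_table(df)
    paths["table2"] = out_dir / "table2.csv"
    t2.to_csv(paths["table2"], index=False, float_format="%.10g", lineterminator="\n")

    curves = hill_fits(df, t2)
    paths["hill_curves"] = out_dir / "hill_curves.json"
    with open(paths["hill_curves"], "w", encoding="utf-8") as fh:
        json.dump(curves, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
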