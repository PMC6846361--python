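"""Model-performance statistics with bootstrap uncertainty.

For each model the residual is measured GFR minus estimated GFR (absolute
mL/min).  Four summary metrics are reported:

``bias``
    median residual (mL/min); 0 is best.
``precision``
    interquartile range of the residuals (mL/min, type-7 quantiles).
``accuracy``
    root-mean-squared error of the residuals (mL/min).
``one_minus_p20``
    proportion of patients whose absolute percentage error
    |eGFR - mGFR| / mGFR strictly exceeds 20% — a clinical-robustness
    metric (smaller is better).

Confidence intervals use nonparametric bootstrap resampling of patients
(2000 repetitions by default) with a normal approximation:
estimate +/- z * SD(bootstrap statistics).  Model comparisons resample
patients jointly for both models (paired), and the two-sided p-value comes
from the normal approximation of the bootstrap distribution of the metric
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, EmptyCohortError
from .models import Sex, dubois_bsa, evaluate_frame

__all__ = [
    "ResidualSet",
    "MetricReport",
    "ComparisonResult",
    "GroupingSpec",
    "METRICS",
    "compute_residuals",
    "compute_metrics",
    "bootstrap_ci",
    "bootstrap_report",
    "compare_models",
    "subgroup_metrics",
    "matched_draw_comparison",
    "rank_models",
]

Z_975 = float(sps.norm.ppf(0.975))


@dataclass(frozen=True)
class ResidualSet:
    """Paired (mGFR, eGFR) values for one model on one cohort."""

    model_id: str
    mgfr: np.ndarray
    egfr: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mgfr", np.asarray(self.mgfr, float))
        object.__setattr__(self, "egfr", np.asarray(self.egfr, float))
        if self.mgfr.shape != self.egfr.shape:
            raise ValueError("mgfr and egfr must be the same length")

    @property
    def residuals(self) -> np.ndarray:
        return self.mgfr - self.egfr

    @property
    def ape(self) -> np.ndarray:
        return np.abs(self.egfr - self.mgfr) / self.mgfr

    def __len__(self) -> int:
        return self.mgfr.size


@dataclass(frozen=True)
class MetricReport:
    model_id: str
    bias: float
    precision: float
    accuracy: float
    one_minus_p20: float
    n: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    bootstrap_reps: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class ComparisonResult:
    model_a: str
    model_b: str
    metric: str
    delta: float  # metric(a) - metric(b)
    p_value: float
    ci: tuple[float, float]
    reps: int
    seed: int


# metric kernels operate on the last axis so that a (reps, n) resample
# matrix yields reps statistics in one vectorized call
def _bias(res, ape):
    return np.median(res, axis=-1)


def _precision(res, ape):
    q1, q3 = np.quantile(res, [0.25, 0.75], axis=-1)
    return q3 - q1


def _accuracy(res, ape):
    return np.sqrt(np.mean(res**2, axis=-1))


def _one_minus_p20(res, ape):
    return np.mean(ape > 0.20, axis=-1)


METRICS = {
    "bias": _bias,
    "precision": _precision,
    "accuracy": _accuracy,
    "one_minus_p20": _one_minus_p20,
}


def compute_residuals(cohort: Cohort, model_id: str) -> ResidualSet:
    """Residuals mGFR - eGFR (absolute mL/min) for one model on a cohort."""
    df = cohort.records
    if df.empty:
        raise EmptyCohortError("cannot compute residuals on an empty cohort")
    egfr = evaluate_frame(model_id, df)
    return ResidualSet(model_id=model_id, mgfr=df["mgfr_ml_min"].to_numpy(float), egfr=egfr)


def compute_metrics(rs: ResidualSet) -> MetricReport:
    """Point estimates of bias, precision, accuracy and 1-P20."""
    if len(rs) == 0:
        raise EmptyCohortError("cannot compute metrics on an empty residual set")
    res, ape = rs.residuals, rs.ape
    return MetricReport(
        model_id=rs.model_id,
        bias=float(_bias(res, ape)),
        precision=float(_precision(res, ape)),
        accuracy=float(_accuracy(res, ape)),
        one_minus_p20=float(_one_minus_p20(res, ape)),
        n=len(rs),
    )


def _resample_stats(rs: ResidualSet, metric: str, idx: np.ndarray) -> np.ndarray:
    res = rs.residuals[idx]
    ape = rs.ape[idx]
    return METRICS[metric](res, ape)


def bootstrap_ci(
    rs: ResidualSet,
    metric: str,
    reps: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Normal-approximation bootstrap CI for one metric.

    Patients are resampled with replacement ``reps`` times; the interval is
    the point estimate +/- z_{(1+level)/2} * SD of the bootstrap statistics.
    Deterministic given ``seed``.
    """
    n = len(rs)
    if n < 2:
        raise ValueError("bootstrap requires at least 2 observations")
    if reps < 2:
        raise ValueError("bootstrap requires at least 2 repetitions")
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    stats = _resample_stats(rs, metric, idx)
    est = float(METRICS[metric](rs.residuals, rs.ape))
    z = float(sps.norm.ppf(0.5 + level / 2))
    se = float(np.std(stats, ddof=1))
    return (est - z * se, est + z * se)


def bootstrap_report(
    rs: ResidualSet,
    reps: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> MetricReport:
    """All four metrics with bootstrap CIs from one shared resample matrix."""
    n = len(rs)
    if n < 2:
        raise ValueError("bootstrap requires at least 2 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    point = compute_metrics(rs)
    z = float(sps.norm.ppf(0.5 + level / 2))
    ci = {}
    for name in METRICS:
        stats = _resample_stats(rs, name, idx)
        se = float(np.std(stats, ddof=1))
        est = getattr(point, name)
        ci[name] = (est - z * se, est + z * se)
    return MetricReport(
        model_id=rs.model_id,
        bias=point.bias,
        precision=point.precision,
        accuracy=point.accuracy,
        one_minus_p20=point.one_minus_p20,
        n=n,
        ci=ci,
        bootstrap_reps=reps,
        seed=seed,
    )


def compare_models(
    cohort: Cohort,
    model_a: str,
    model_b: str,
    metric: str = "accuracy",
    reps: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Paired bootstrap comparison of two models on the same patients.

    Each bootstrap repetition resamples patients once and evaluates both
    models on the identical resample, so the difference distribution
    respects the pairing.  The p-value is computed from the normal
    approximation of the bootstrap difference distribution
    (two-sided by default; ``alternative`` in {"two-sided", "less",
    "greater"} refers to metric(a) - metric(b)).
    """
    rs_a = compute_residuals(cohort, model_a)
    rs_b = compute_residuals(cohort, model_b)
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    n = len(rs_a)
    if n < 2:
        raise ValueError("comparison requires at least 2 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    stats_a = _resample_stats(rs_a, metric, idx)
    stats_b = _resample_stats(rs_b, metric, idx)
    deltas = stats_a - stats_b
    point = float(
        METRICS[metric](rs_a.residuals, rs_a.ape)
        - METRICS[metric](rs_b.residuals, rs_b.ape)
    )
    se = float(np.std(deltas, ddof=1))
    z975 = float(sps.norm.ppf(0.5 + level / 2))
    ci = (point - z975 * se, point + z975 * se)
    if se == 0.0:
        p = 1.0 if point == 0.0 else 0.0
    else:
        z = point / se
        if alternative == "two-sided":
            p = float(2 * sps.norm.sf(abs(z)))
        elif alternative == "less":
            p = float(sps.norm.cdf(z))
        elif alternative == "greater":
            p = float(sps.norm.sf(z))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return ComparisonResult(
        model_a=model_a,
        model_b=model_b,
        metric=metric,
        delta=point,
        p_value=min(p, 1.0),
        ci=ci,
        reps=reps,
        seed=seed,
    )


@dataclass(frozen=True)
class GroupingSpec:
    """How to partition a cohort for subgroup metrics.

    ``variable`` names a record column or the derived ``bsa``.  For numeric
    variables ``bins`` gives explicit edges (right-closed); when None,
    cohort quartiles are used.  Categorical variables use their categories
    as-is.
    """

    variable: str
    bins: list[float] | None = None
    labels: list[str] | None = None


_CATEGORICAL = {"sex", "diagnosis_group", "center", "tracer", "race_black"}


def _group_column(cohort: Cohort, spec: GroupingSpec) -> pd.Series:
    df = cohort.records
    if spec.variable == "bsa":
        col = pd.Series(
            dubois_bsa(df["weight_kg"].to_numpy(float), df["height_cm"].to_numpy(float)),
            index=df.index,
            name="bsa",
        )
    elif spec.variable in df.columns:
        col = df[spec.variable]
    else:
        raise KeyError(f"unknown grouping variable {spec.variable!r}")
    if spec.variable in _CATEGORICAL:
        return col.astype(str)
    x = col.astype(float)
    if spec.bins is None:
        edges = np.unique(np.quantile(x, [0.0, 0.25, 0.5, 0.75, 1.0]))
    else:
        edges = np.asarray(spec.bins, float)
    return pd.cut(x, bins=edges, include_lowest=True, labels=spec.labels)


def subgroup_metrics(
    cohort: Cohort,
    model_ids: list[str],
    spec: GroupingSpec,
    reps: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """One row of metrics per model per subgroup.

    Subgroup n values partition the cohort n.  Empty subgroups are reported
    with n = 0 and missing metrics.  With ``reps`` > 0, bootstrap CIs are
    added per subgroup.
    """
    groups = _group_column(cohort, spec)
    if isinstance(groups.dtype, pd.CategoricalDtype):
        categories = list(groups.cat.categories)  # keeps empty bins visible
    else:
        categories = sorted(groups.unique())
    rows = []
    for gname in categories:
        gidx = groups.index[groups == gname]
        sub = cohort.with_records(cohort.records.loc[gidx])
        for model_id in model_ids:
            row = {"group": str(gname), "model": model_id, "n": len(sub)}
            if len(sub) == 0:
                row.update({m: np.nan for m in METRICS})
            else:
                rs = compute_residuals(sub, model_id)
                if reps > 0 and len(sub) >= 2:
                    rep = bootstrap_report(rs, reps=reps, seed=seed)
                    for m in METRICS:
                        row[f"{m}_lo"], row[f"{m}_hi"] = rep.ci[m]
                else:
                    rep = compute_metrics(rs)
                for m in METRICS:
                    row[m] = getattr(rep, m)
            rows.append(row)
    return pd.DataFrame(rows)


def matched_draw_comparison(
    cohort: Cohort,
    group_flag: str = "race_black",
    n_draws: int = 10,
    age_tolerance: float = 2.0,
    test: str = "ranksum",
    seed: int = 0,
    return_pairs: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated matched two-group comparison of BSA, mGFR and creatinine.

    For each of ``n_draws`` draws, every member of the flagged group (by
    default black patients) is matched 1:1 without replacement to an
    unflagged patient of the same sex whose age is nearest within
    ``age_tolerance`` years (ties broken at random).  BSA, measured GFR and
    creatinine are then compared between the matched groups with a
    two-sample test (``"ranksum"`` = Wilcoxon rank-sum / Mann-Whitney U,
    ``"ttest"`` = Welch t-test).

    Returns a tidy frame with one row per draw per variable carrying the
    test statistic, p-value, number of matched pairs, and the number of
    flagged patients for whom no candidate existed (the draw is flagged
    when any matching failed).  With ``return_pairs`` the per-pair matching
    table (draw, both ids, ages, sex) is returned alongside.
    """
    df = cohort.records.reset_index(drop=True)
    flagged = df[df[group_flag].astype(bool)]
    pool_all = df[~df[group_flag].astype(bool)]
    if flagged.empty or pool_all.empty:
        raise EmptyCohortError("both groups must be non-empty for matched draws")

    bsa = pd.Series(
        dubois_bsa(df["weight_kg"].to_numpy(float), df["height_cm"].to_numpy(float)),
        index=df.index,
    )
    variables = {
        "bsa_m2": bsa,
        "mgfr_ml_min": df["mgfr_ml_min"].astype(float),
        "creatinine_mgdl": df["creatinine_mgdl"].astype(float),
    }

    root = np.random.SeedSequence(seed)
    rows = []
    pair_rows = []
    for draw, ss in enumerate(root.spawn(n_draws)):
        rng = np.random.default_rng(ss)
        used: set[int] = set()
        matched_flagged: list[int] = []
        matched_control: list[int] = []
        n_failed = 0
        order = rng.permutation(flagged.index.to_numpy())
        for i in order:
            cand = pool_all[
                (pool_all["sex"] == df.at[i, "sex"])
                & ((pool_all["age"] - df.at[i, "age"]).abs() <= age_tolerance)
            ]
            cand = cand.index.difference(used)
            if len(cand) == 0:
                n_failed += 1
                continue
            gaps = (df.loc[cand, "age"] - df.at[i, "age"]).abs()
            nearest = gaps[gaps == gaps.min()].index.to_numpy()
            j = int(rng.choice(nearest))
            used.add(j)
            matched_flagged.append(i)
            matched_control.append(j)
            pair_rows.append(
                {
                    "draw": draw,
                    "flagged_id": df.at[i, "patient_id"],
                    "control_id": df.at[j, "patient_id"],
                    "flagged_age": float(df.at[i, "age"]),
                    "control_age": float(df.at[j, "age"]),
                    "flagged_sex": df.at[i, "sex"],
                    "control_sex": df.at[j, "sex"],
                }
            )
        for var, series in variables.items():
            a = series.loc[matched_flagged].to_numpy()
            b = series.loc[matched_control].to_numpy()
            if len(a) == 0:
                stat, p = np.nan, np.nan
            elif test == "ranksum":
                stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            elif test == "ttest":
                stat, p = sps.ttest_ind(a, b, equal_var=False)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append(
                {
                    "draw": draw,
                    "variable": var,
                    "n_pairs": len(a),
                    "n_failed": n_failed,
                    "flagged_incomplete": n_failed > 0,
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    summary = pd.DataFrame(rows)
    if return_pairs:
        return summary, pd.DataFrame(pair_rows)
    return summary


def rank_models(cohort: Cohort, model_ids: list[str], metric: str = "accuracy") -> pd.DataFrame:
    """Point-estimate league table of models, best (smallest) metric first."""
    rows = []
    for model_id in model_ids:
        rep = compute_metrics(compute_residuals(cohort, model_id))
        rows.append({"model": model_id, metric: getattr(rep, metric), "n": rep.n})
    out = pd.DataFrame(rows).sort_values(metric, key=np.abs if metric == "bias" else None)
    return out.reset_index(drop=True)
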