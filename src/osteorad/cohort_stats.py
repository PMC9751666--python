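"""Cohort statistics: normality-gated two-group tests, ANOVA + Tukey,
Kaplan–Meier survival with the Gehan–Breslow–Wilcoxon test, marker
fold-change summaries and biopsy-table percentages.

The decision rules mirror common practice in small-animal radiobiology
cohorts: every test is two-sided, p < 0.05 is significant and p < 0.075 is
reported as a trend.  Two-group comparisons are gated on normality — each
group is screened with a one-sample Kolmogorov–Smirnov test against a
normal with its own mean and SD; if either group looks non-normal the
comparison uses the Mann–Whitney U test, otherwise Welch's t test.

The Gehan–Breslow–Wilcoxon statistic is the weighted log-rank with the
number at risk as the weight at each event time, which up-weights early
deaths; because cohort sizes are small an exact-style label-permutation
p value is available alongside the chi-square approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "FoldChangeSummary",
    "CohortStatsError",
    "SIGNIFICANCE_P",
    "TREND_P",
    "stars",
    "normality_gate",
    "two_group_test",
    "mann_whitney_u",
    "welch_t",
    "anova_tukey",
    "km_estimator",
    "KMCurve",
    "gehan_breslow_wilcoxon",
    "fold_change_over_time",
    "biopsy_percentages",
    "survival_table",
    "COHORT_COLUMNS",
]

SIGNIFICANCE_P = 0.05
TREND_P = 0.075

#: Long-format cohort table schema: one row per (animal, measurement, time);
#: lifespan/event columns are repeated per animal.
COHORT_COLUMNS = [
    "animal_id",
    "group",
    "sex",
    "age_weeks",
    "event",
    "measurement",
    "time_weeks",
    "value",
]


class CohortStatsError(ValueError):
    pass


def stars(p: float) -> str:
    """Figure-legend star mapping."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise CohortStatsError("p value must be in [0, 1]")

    @property
    def decision(self) -> str:
        if self.p_value < SIGNIFICANCE_P:
            return "significant"
        if self.p_value < TREND_P:
            return "trend"
        return "not significant"

    @property
    def stars(self) -> str:
        return stars(self.p_value)


@dataclass(frozen=True)
class FoldChangeSummary:
    group: str
    marker: str
    early_mean: float
    late_mean: float
    ratio: float
    direction: str  # "up", "down" or "flat" (±5% dead band)
    p_value: float


def _as_array(sample) -> np.ndarray:
    a = np.asarray(sample, dtype=float).ravel()
    if a.size == 0:
        raise CohortStatsError("empty sample")
    return a


def normality_gate(sample_a, sample_b) -> str:
    """Choose the two-group test: 'welch_t' or 'mann_whitney_u'.

    One-sample KS against a fitted normal per group; either group with
    p < 0.05 (or degenerate SD, or n < 3) routes to Mann–Whitney.
    """
    a, b = _as_array(sample_a), _as_array(sample_b)
    if a.size < 3 or b.size < 3:
        warnings.warn(
            "normality gate needs n >= 3 per group; defaulting to Mann-Whitney",
            stacklevel=2,
        )
        return "mann_whitney_u"
    for sample in (a, b):
        sd = sample.std(ddof=1)
        if sd == 0:
            return "mann_whitney_u"
        p = stats.kstest(sample, "norm", args=(sample.mean(), sd)).pvalue
        if p < SIGNIFICANCE_P:
            return "mann_whitney_u"
    return "welch_t"


def mann_whitney_u(sample_a, sample_b) -> TestResult:
    """Two-sided Mann–Whitney U; exact enumeration for combined n <= 12
    without ties, normal approximation with tie correction otherwise."""
    a, b = _as_array(sample_a), _as_array(sample_b)
    combined = np.concatenate([a, b])
    exact = combined.size <= 12 and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult("mann_whitney_u", float(res.statistic), float(min(res.pvalue, 1.0)))


def welch_t(sample_a, sample_b) -> TestResult:
    """Welch's t test with Welch–Satterthwaite degrees of freedom."""
    a, b = _as_array(sample_a), _as_array(sample_b)
    if a.size < 2 or b.size < 2:
        raise CohortStatsError("welch_t requires n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise CohortStatsError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue))


def two_group_test(sample_a, sample_b) -> TestResult:
    """Normality-gated two-group comparison."""
    chosen = normality_gate(sample_a, sample_b)
    if chosen == "welch_t":
        return welch_t(sample_a, sample_b)
    return mann_whitney_u(sample_a, sample_b)


def anova_tukey(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> tuple[TestResult, dict[tuple[str, str], TestResult]]:
    """One-way ANOVA with Tukey's HSD post hoc pairwise comparisons."""
    arrays = [_as_array(g) for g in groups]
    if len(arrays) < 2:
        raise CohortStatsError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise CohortStatsError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    f_res = stats.f_oneway(*arrays)
    anova = TestResult("one_way_anova", float(f_res.statistic), float(f_res.pvalue))
    hsd = stats.tukey_hsd(*arrays)
    pairs: dict[tuple[str, str], TestResult] = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            pairs[(labels[i], labels[j])] = TestResult(
                "tukey_hsd",
                float(hsd.statistic[i, j]),
                float(hsd.pvalue[i, j]),
            )
    return anova, pairs


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous Kaplan–Meier step function with S(0) = 1."""

    event_times: np.ndarray
    survival: np.ndarray

    def survival_at(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t_arr, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def km_estimator(times, events) -> KMCurve:
    """Product-limit survival estimate (via lifelines)."""
    from lifelines import KaplanMeierFitter

    times = _as_array(times)
    events = np.asarray(events, dtype=bool).ravel()
    if np.any(times <= 0):
        raise CohortStatsError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KMCurve(
        event_times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


def _gbw_tables(times, events):
    times = _as_array(times)
    events = np.asarray(events, dtype=bool).ravel()
    tk = np.unique(times[events])
    if tk.size == 0:
        raise CohortStatsError("no events in either group")
    at_risk = times[:, None] >= tk[None, :]
    death = (times[:, None] == tk[None, :]) & events[:, None]
    return at_risk, death


def _gbw_statistic(z, at_risk, death):
    """Gehan–Breslow–Wilcoxon chi-square statistic for 0/1 group labels z.

    z may be a (B, n) stack for vectorized permutation evaluation.
    """
    N = at_risk.sum(axis=0).astype(float)
    d = death.sum(axis=0).astype(float)
    n1 = z @ at_risk
    d1 = z @ death
    w = N  # number at risk: the Gehan/Breslow generalization
    u = (w * (d1 - d * n1 / N)).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hyper = d * (n1 / N) * (1 - n1 / N) * np.where(N > 1, (N - d) / np.maximum(N - 1, 1), 0.0)
        var = (w**2 * hyper).sum(axis=-1)
    return np.where(var > 0, u * u / np.where(var > 0, var, 1.0), 0.0)


def gehan_breslow_wilcoxon(
    group1: tuple[Sequence[float], Sequence[bool]],
    group2: tuple[Sequence[float], Sequence[bool]],
    permutations: int | None = None,
    seed: int | None = None,
) -> TestResult:
    """Gehan–Breslow–Wilcoxon weighted log-rank test.

    The statistic is chi-square(1) under the null; when ``permutations`` is
    given the p value is instead the label-permutation tail probability
    (add-one estimator), which is preferable for small cohorts.
    """
    t1, e1 = _as_array(group1[0]), np.asarray(group1[1], dtype=bool).ravel()
    t2, e2 = _as_array(group2[0]), np.asarray(group2[1], dtype=bool).ravel()
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    at_risk, death = _gbw_tables(times, events)
    z = np.concatenate([np.ones(t1.size), np.zeros(t2.size)])
    observed = float(_gbw_statistic(z, at_risk, death))
    if permutations is None:
        p = float(stats.chi2.sf(observed, df=1))
        return TestResult("gehan_breslow_wilcoxon", observed, p)
    rng = np.random.default_rng(seed)
    n = times.size
    idx = rng.random((permutations, n)).argsort(axis=1)
    zperm = np.zeros((permutations, n))
    np.put_along_axis(zperm, idx[:, : t1.size], 1.0, axis=1)
    perm_stats = _gbw_statistic(zperm, at_risk, death)
    p = (1.0 + np.sum(perm_stats >= observed - 1e-12)) / (permutations + 1.0)
    return TestResult("gehan_breslow_wilcoxon_permutation", observed, float(p))


def survival_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-animal (group, sex, age_weeks, event) from a long cohort table."""
    per_animal = cohort.drop_duplicates("animal_id")[
        ["animal_id", "group", "sex", "age_weeks", "event"]
    ]
    return per_animal.reset_index(drop=True)


def fold_change_over_time(
    cohort: pd.DataFrame,
    marker: str,
    early_window: tuple[float, float],
    late_window: tuple[float, float],
    dead_band: float = 0.05,
) -> list[FoldChangeSummary]:
    """Late/early mean ratio per group for one marker.

    The direction arrow uses a ±``dead_band`` (default 5%) band around a
    ratio of 1; the within-group p value comes from the normality-gated
    two-group test of late vs early values.
    """
    rows = cohort[cohort["measurement"] == marker]
    if rows.empty:
        raise CohortStatsError(f"no measurements for marker {marker!r}")
    out = []
    for group, sub in rows.groupby("group", sort=False):
        early = sub[sub["time_weeks"].between(*early_window)]["value"].to_numpy()
        late = sub[sub["time_weeks"].between(*late_window)]["value"].to_numpy()
        if early.size == 0 or late.size == 0:
            which = "early" if early.size == 0 else "late"
            raise CohortStatsError(
                f"group {group!r}: empty {which} window for marker {marker!r}"
            )
        early_mean = float(early.mean())
        late_mean = float(late.mean())
        if early_mean <= 0:
            raise CohortStatsError(f"group {group!r}: nonpositive early mean")
        ratio = late_mean / early_mean
        if ratio > 1 + dead_band:
            direction = "up"
        elif ratio < 1 - dead_band:
            direction = "down"
        else:
            direction = "flat"
        p = two_group_test(early, late).p_value
        out.append(
            FoldChangeSummary(
                group=str(group),
                marker=marker,
                early_mean=early_mean,
                late_mean=late_mean,
                ratio=ratio,
                direction=direction,
                p_value=p,
            )
        )
    return out


def biopsy_percentages(
    counts: dict[str, dict[str, int]],
    denominators: dict[str, int],
    male_only_rows: Iterable[str] = (),
    male_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Necropsy finding percentages per group, rounded to one decimal.

    ``counts`` maps finding -> {group -> count}; rows listed in
    ``male_only_rows`` are divided by the per-group male counts instead of
    the full group sizes.
    """
    male_only = set(male_only_rows)
    if male_only and male_counts is None:
        raise CohortStatsError("male_only_rows given without male_counts")
    records = []
    for finding, per_group in counts.items():
        row: dict[str, float | str] = {"finding": finding}
        for group, count in per_group.items():
            denom = (
                male_counts[group] if finding in male_only else denominators[group]
            )
            if denom <= 0:
                raise CohortStatsError(f"nonpositive denominator for {group!r}")
            if count > denom:
                raise CohortStatsError(
                    f"{finding!r}/{group!r}: count {count} exceeds denominator {denom}"
                )
            row[group] = round(100.0 * count / denom, 1)
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("finding")
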