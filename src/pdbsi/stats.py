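"""Validation and group statistics: patch aggregation, OLS with confidence
bands, Wilcoxon rank-sum comparisons, and longitudinal summaries."""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
import scipy.stats

from .core_io import ConfigurationError, DataError

__all__ = [
    "RegressionResult",
    "patch_aggregate",
    "linear_regression",
    "ranksum_test",
    "validate_region_table",
    "validation_regression",
    "longitudinal_summary",
    "LongitudinalSummary",
    "ttest",
]

log = logging.getLogger(__name__)

#: combined sample size up to which the rank-sum test enumerates exactly
EXACT_RANKSUM_LIMIT = 12

REGION_TABLE_COLUMNS = ("region_id", "true_density", "estimated_cellularity", "snr")


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    """OLS fit of y on x with a pointwise 95% mean-response band."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    x: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    @property
    def slope_minus_one(self) -> float:
        """Distance of the slope from the identity line."""
        return abs(self.slope - 1.0)


def patch_aggregate(map2d: np.ndarray, patch: int = 5) -> np.ndarray:
    """Means of non-overlapping patch×patch blocks, row-major order.

    Trailing rows/columns that do not fill a whole patch are dropped.
    """
    if patch < 1:
        raise ConfigurationError("patch must be ≥ 1")
    m = np.asarray(map2d, dtype=float)
    if m.ndim != 2 or m.shape[0] < patch or m.shape[1] < patch:
        raise ConfigurationError("map must be 2D with dimensions ≥ patch")
    nr, nc = m.shape[0] // patch, m.shape[1] // patch
    trimmed = m[: nr * patch, : nc * patch]
    return trimmed.reshape(nr, patch, nc, patch).mean(axis=(1, 3)).ravel()


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares with two-sided slope p-value and 95% CI band."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("need n ≥ 3 matched observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise DataError("zero variance in x")
    fit = scipy.stats.linregress(x, y)
    n = x.size
    yhat = fit.intercept + fit.slope * x
    resid = y - yhat
    s2 = float(resid @ resid) / (n - 2) if n > 2 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_mean = np.sqrt(s2 * (1.0 / n + (x - x.mean()) ** 2 / sxx))
    tcrit = scipy.stats.t.ppf(0.975, n - 2)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        x=x,
        ci_lower=yhat - tcrit * se_mean,
        ci_upper=yhat + tcrit * se_mean,
        n=n,
    )


def _exact_ranksum_p(ranks_a_sum: float, ranks: np.ndarray, na: int) -> float:
    n = ranks.size
    mu = na * (n + 1) / 2.0
    obs = abs(ranks_a_sum - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), na):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= obs - 1e-9:
            count += 1
        total += 1
    return count / total


def ranksum_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns (rank sum of group_a, p).  Exact enumeration over all
    C(n, n_a) labellings when combined n ≤ 12 (tie-safe via midranks);
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 1 or b.size < 1:
        raise DataError("empty group")
    combined = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(combined)
    w = float(ranks[: a.size].sum())
    n = combined.size
    if n <= EXACT_RANKSUM_LIMIT:
        p = _exact_ranksum_p(w, ranks, a.size)
    else:
        p = float(
            scipy.stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    return w, min(p, 1.0)


def validate_region_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the region-density table contract and return it unchanged."""
    missing = [c for c in REGION_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"region table missing columns: {missing}")
    for col in ("true_density", "estimated_cellularity"):
        vals = table[col].to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise DataError(f"{col} outside [0, 1]")
    if table.duplicated(subset=["region_id", "snr"]).any():
        raise DataError("duplicate (region_id, snr) rows")
    return table


def validation_regression(table: pd.DataFrame, snr: float) -> RegressionResult:
    """Regress estimated cellularity on true density for one SNR stratum."""
    validate_region_table(table)
    stratum = table[np.isclose(table["snr"].to_numpy(dtype=float), snr)]
    if len(stratum) == 0:
        raise DataError(f"no rows at snr={snr}")
    if len(stratum) < 10:
        raise DataError(f"only {len(stratum)} regions at snr={snr}; need ≥ 10")
    return linear_regression(
        stratum["true_density"].to_numpy(), stratum["estimated_cellularity"].to_numpy()
    )


@dataclasses.dataclass
class LongitudinalSummary:
    """Per-group trend fits plus per-visit between-group comparisons."""

    group_regressions: dict[str, RegressionResult]
    visit_comparisons: pd.DataFrame

    def to_report(self) -> str:
        lines = ["# Longitudinal cellularity summary", ""]
        for group, reg in self.group_regressions.items():
            lines.append(
                f"group {group}: slope {reg.slope:.5g} per week, "
                f"r² {reg.r_squared:.4f}, p {reg.p_value:.3g} (n={reg.n})"
            )
        lines.append("")
        lines.append(self.visit_comparisons.to_string(index=False))
        return "\n".join(lines) + "\n"


def longitudinal_summary(cohort_table: pd.DataFrame) -> LongitudinalSummary:
    """Trend and group-difference statistics for a longitudinal cohort.

    Expects columns (patient_id, group, visit_week, mean_cellularity).
    Fits OLS of mean cellularity on gestational week within each group and
    compares groups at each visit by rank-sum; per-visit p-values are
    reported uncorrected, with a Bonferroni column alongside.
    """
    required = {"patient_id", "group", "visit_week", "mean_cellularity"}
    missing = required - set(cohort_table.columns)
    if missing:
        raise DataError(f"cohort table missing columns: {sorted(missing)}")
    groups = sorted(cohort_table["group"].unique())
    for g in groups:
        sub = cohort_table[cohort_table["group"] == g]
        if sub["patient_id"].nunique() < 2:
            raise DataError(f"group {g!r} has fewer than 2 patients")
    visits = sorted(cohort_table["visit_week"].unique())
    regressions: dict[str, RegressionResult] = {}
    for g in groups:
        sub = cohort_table[cohort_table["group"] == g]
        if sub["visit_week"].nunique() < 2:
            log.warning("group %r has a single visit; regression skipped", g)
            continue
        regressions[str(g)] = linear_regression(
            sub["visit_week"].to_numpy(), sub["mean_cellularity"].to_numpy()
        )
    rows = []
    if len(groups) == 2:
        ga, gb = groups
        n_tests = len(visits)
        for week in visits:
            at = cohort_table[cohort_table["visit_week"] == week]
            a = at.loc[at["group"] == ga, "mean_cellularity"].to_numpy()
            b = at.loc[at["group"] == gb, "mean_cellularity"].to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            stat, p = ranksum_test(a, b)
            rows.append(
                {
                    "visit_week": week,
                    "group_a": ga,
                    "group_b": gb,
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "statistic": stat,
                    "p_value": p,
                    "p_bonferroni": min(p * n_tests, 1.0),
                }
            )
    comparisons = pd.DataFrame(
        rows,
        columns=[
            "visit_week",
            "group_a",
            "group_b",
            "mean_a",
            "mean_b",
            "statistic",
            "p_value",
            "p_bonferroni",
        ],
    )
    return LongitudinalSummary(
        group_regressions=regressions, visit_comparisons=comparisons
    )


def ttest(group_a, group_b) -> tuple[float, float]:
    """Plain two-sample Welch t-test (demographic-table utility)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("need ≥ 2 per group")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
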