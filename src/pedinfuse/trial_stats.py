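"""Statistics for the two-period, two-arm crossover trial.

The trial compares a guided preparation app against the conventional
infusion-rate table.  Because the control-arm times shrink in the second
period (nurses who have just used the app prepare faster with the table —
a carryover effect), time outcomes are compared *between arms within each
period* with Welch's unequal-variance t test; no time data are paired.
Error proportions use exact Clopper–Pearson intervals, and the paired
app-vs-table error comparison uses the exact McNemar test on discordant
pairs.

All functions accept group *summaries* (n, mean, sd) as well as raw
records, so every interval and p-value in a published summary table can be
recomputed directly from the printed numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "CIResult",
    "TestResult",
    "one_sample_t_ci",
    "welch_t",
    "clopper_pearson",
    "mcnemar_exact",
    "paired_t",
    "TrialReport",
    "trial_report",
    "render_report",
    "format_p",
]


@dataclass(frozen=True)
class SummaryStats:
    """Group summary: size, mean, sample standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "SummaryStats":
        arr = np.asarray(x, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(n=int(arr.size), mean=float(arr.mean()), sd=sd)


@dataclass(frozen=True)
class CIResult:
    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    df: Optional[float] = None

    def __post_init__(self):
        if not self.lower <= self.estimate <= self.upper:
            raise ValueError("CI bounds must bracket the estimate")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: Optional[float]
    p: float
    method: str
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate and not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def one_sample_t_ci(s: SummaryStats, level: float = 0.95) -> CIResult:
    """t interval for a group mean: mean ± t_{1-a/2, n-1} · sd/√n."""
    if s.n < 2:
        raise ValueError("need n >= 2 for a t interval")
    half = stats.t.ppf(0.5 + level / 2, s.n - 1) * s.sd / math.sqrt(s.n)
    return CIResult(s.mean, s.mean - half, s.mean + half, level, df=s.n - 1)


def welch_t(
    s1: SummaryStats,
    s2: SummaryStats,
    level: float = 0.95,
    *,
    pooled: bool = False,
) -> tuple[CIResult, TestResult]:
    """Two-sample t comparison of mean1 − mean2 from group summaries.

    The default is Welch's unequal-variance form with Satterthwaite degrees
    of freedom

        df = SE⁴ / [ (s1²/n1)²/(n1−1) + (s2²/n2)²/(n2−1) ],  SE² = s1²/n1 + s2²/n2.

    ``pooled=True`` gives the classical equal-variance Student form instead.
    Degenerate inputs (both sds zero) return p = 1 when the means are equal.
    """
    if s1.n < 2 or s2.n < 2:
        raise ValueError("need n >= 2 in both groups")
    diff = s1.mean - s2.mean
    v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
    if pooled:
        df = s1.n + s2.n - 2
        sp2 = ((s1.n - 1) * s1.sd**2 + (s2.n - 1) * s2.sd**2) / df
        se = math.sqrt(sp2 * (1 / s1.n + 1 / s2.n))
        method = "pooled two-sample t"
    else:
        se = math.sqrt(v1 + v2)
        if se == 0:
            df = float(s1.n + s2.n - 2)
        else:
            df = (v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
        method = "Welch two-sample t"
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
        t_stat = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        return (
            CIResult(diff, diff, diff, level, df=df),
            TestResult(t_stat, df, p, method + " (degenerate)", degenerate=True),
        )
    t_stat = diff / se
    half = stats.t.ppf(0.5 + level / 2, df) * se
    p = 2 * stats.t.sf(abs(t_stat), df)
    return (
        CIResult(diff, diff - half, diff + half, level, df=df),
        TestResult(t_stat, df, p, method),
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> CIResult:
    """Exact binomial interval from beta quantiles; returned as fractions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    alpha = 1 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return CIResult(k / n, lower, upper, level, df=None)


def mcnemar_exact(b: int, c: int) -> TestResult:
    """Exact McNemar test on the discordant pair counts (b, c).

    Under the null the b discordant pairs of one kind among b + c total are
    Binomial(b + c, 1/2); the two-sided p is min(1, 2·P[X ≤ min(b, c)]).
    """
    if b < 0 or c < 0:
        raise ValueError("counts must be >= 0")
    if b + c == 0:
        raise ValueError("no discordant pairs")
    m = min(b, c)
    p = min(1.0, 2.0 * float(stats.binom.cdf(m, b + c, 0.5)))
    return TestResult(statistic=float(m), df=None, p=p, method="exact McNemar")


def paired_t(diffs: Sequence[float], level: float = 0.95) -> tuple[CIResult, TestResult]:
    """One-sample t on within-pair differences."""
    arr = np.asarray(diffs, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 differences")
    s = SummaryStats.from_sample(arr)
    if s.sd == 0:
        return (
            CIResult(s.mean, s.mean, s.mean, level, df=s.n - 1),
            TestResult(
                0.0 if s.mean == 0 else math.copysign(math.inf, s.mean),
                s.n - 1,
                float("nan"),
                "paired t (degenerate: zero variance)",
                degenerate=True,
            ),
        )
    ci = one_sample_t_ci(s, level)
    se = s.sd / math.sqrt(s.n)
    t_stat = s.mean / se
    p = 2 * stats.t.sf(abs(t_stat), s.n - 1)
    return ci, TestResult(t_stat, s.n - 1, p, "paired t")


# --------------------------------------------------------------------------
# full trial report

PERIODS = (1, 2)
METHODS = ("app", "conventional")
OUTCOMES = ("tdp_s", "tdd_s")

RECORD_COLUMNS = [
    "nurse_id",
    "arm",
    "period",
    "method",
    "drug",
    "tdp_s",
    "tdd_s",
    "prescribed_ug_kg_min",
    "delivered_ug_kg_min",
    "error_flag",
]


@dataclass(frozen=True)
class TimeCell:
    stats: SummaryStats
    ci: CIResult


@dataclass(frozen=True)
class TimeComparison:
    """Conventional − app difference within one period."""

    diff_ci: CIResult
    test: TestResult
    pct_reduction: int  # 100 x diff / conventional mean, nearest integer


@dataclass(frozen=True)
class ErrorCell:
    k: int
    n: int
    ci: CIResult  # proportion, as a fraction


@dataclass
class TrialReport:
    times: dict = field(default_factory=dict)  # (outcome, period, method) -> TimeCell
    comparisons: dict = field(default_factory=dict)  # (outcome, period) -> TimeComparison
    error_rates: dict = field(default_factory=dict)  # (method, period) -> ErrorCell
    pooled_error_rates: dict = field(default_factory=dict)  # method -> ErrorCell
    paired_errors: Optional[ErrorCell] = None  # discordant-pair rate over all pairs
    mcnemar: Optional[TestResult] = None
    missing: list = field(default_factory=list)  # absent (outcome/period/method) strata


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for r in records:
        if hasattr(r, "model_dump"):
            rows.append(r.model_dump())
        elif isinstance(r, dict):
            rows.append(r)
        else:
            rows.append(vars(r))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS if not rows else None)


def trial_report(records, level: float = 0.95) -> TrialReport:
    """Summarize per-nurse records into the full trial table set.

    Produces, per period and method, the time summaries with t intervals;
    per period, the Welch between-arm comparison and percent time reduction;
    per (method, period) and pooled, exact binomial error proportions; and
    the paired McNemar comparison of error rates across methods.
    """
    report = TrialReport()
    df = _as_frame(records)
    if df.empty:
        report.missing = [
            (o, p, m) for o in OUTCOMES for p in PERIODS for m in METHODS
        ]
        return report

    for outcome in OUTCOMES:
        for period in PERIODS:
            cells: dict[str, SummaryStats] = {}
            for method in METHODS:
                sub = df[(df["period"] == period) & (df["method"] == method)]
                if len(sub) < 2:
                    report.missing.append((outcome, period, method))
                    continue
                s = SummaryStats.from_sample(sub[outcome].to_numpy())
                cells[method] = s
                report.times[(outcome, period, method)] = TimeCell(
                    s, one_sample_t_ci(s, level)
                )
            if len(cells) == 2:
                ci, test = welch_t(cells["conventional"], cells["app"], level)
                pct = round(100.0 * ci.estimate / cells["conventional"].mean)
                report.comparisons[(outcome, period)] = TimeComparison(ci, test, pct)

    counts: dict[tuple[str, int], tuple[int, int]] = {}
    for method in METHODS:
        pooled_k = pooled_n = 0
        for period in PERIODS:
            sub = df[(df["period"] == period) & (df["method"] == method)]
            if sub.empty:
                continue
            k = int(sub["error_flag"].sum())
            n = len(sub)
            counts[(method, period)] = (k, n)
            report.error_rates[(method, period)] = ErrorCell(
                k, n, clopper_pearson(k, n, level)
            )
            pooled_k, pooled_n = pooled_k + k, pooled_n + n
        if pooled_n:
            report.pooled_error_rates[method] = ErrorCell(
                pooled_k, pooled_n, clopper_pearson(pooled_k, pooled_n, level)
            )

    # pair each nurse's observations across methods (every nurse uses both)
    b = c = concordant = 0
    for _, nurse_df in df.groupby("nurse_id"):
        by_method = {m: g for m, g in nurse_df.groupby("method")}
        if set(by_method) != set(METHODS):
            continue
        for _, conv_row in by_method["conventional"].iterrows():
            for _, app_row in by_method["app"].iterrows():
                conv_err = bool(conv_row["error_flag"])
                app_err = bool(app_row["error_flag"])
                if conv_err and not app_err:
                    b += 1
                elif app_err and not conv_err:
                    c += 1
                else:
                    concordant += 1
    n_pairs = b + c + concordant
    if n_pairs:
        discordant_net = b  # conventional-error / app-correct pairs
        report.paired_errors = ErrorCell(
            discordant_net, n_pairs, clopper_pearson(discordant_net, n_pairs, level)
        )
        if b + c > 0:
            report.mcnemar = mcnemar_exact(b, c)
    return report


def format_p(p: float) -> str:
    """Journal-style p-value: two decimals with a '<.001' floor."""
    if math.isnan(p):
        return "NA"
    if p < 0.001:
        return "<.001"
    digits = 3 if p < 0.01 else 2
    return f"={p:.{digits}f}".replace("=0.", "=.")


_OUTCOME_LABEL = {"tdp_s": "TDP", "tdd_s": "TDD"}


def render_report(report: TrialReport) -> str:
    """Human-readable report (times to 1 d.p., percents as integers)."""
    lines: list[str] = []
    for outcome in OUTCOMES:
        label = _OUTCOME_LABEL.get(outcome, outcome)
        for period in PERIODS:
            for method in METHODS:
                cell = report.times.get((outcome, period, method))
                if cell is None:
                    continue
                lines.append(
                    f"{label} period {period} {method:>12}: "
                    f"{cell.stats.mean:.1f} s "
                    f"(95% CI {cell.ci.lower:.1f}-{cell.ci.upper:.1f}), "
                    f"SD {cell.stats.sd:.1f}, n={cell.stats.n}"
                )
            comp = report.comparisons.get((outcome, period))
            if comp is not None:
                lines.append(
                    f"{label} period {period}   difference: "
                    f"{comp.diff_ci.estimate:.1f} s "
                    f"(95% CI {comp.diff_ci.lower:.1f}-{comp.diff_ci.upper:.1f}, "
                    f"P{format_p(comp.test.p)}; {comp.pct_reduction}% of conventional time)"
                )
    for (method, period), cell in sorted(report.error_rates.items()):
        lines.append(
            f"errors {method:>12} period {period}: {cell.k}/{cell.n} "
            f"({100 * cell.k / cell.n:.0f}%, 95% CI "
            f"{100 * cell.ci.lower:.0f}-{100 * cell.ci.upper:.0f})"
        )
    for method, cell in sorted(report.pooled_error_rates.items()):
        lines.append(
            f"errors {method:>12}   pooled: {cell.k}/{cell.n} "
            f"({100 * cell.k / cell.n:.0f}%, 95% CI "
            f"{100 * cell.ci.lower:.1f}-{100 * cell.ci.upper:.1f})"
        )
    if report.paired_errors is not None:
        pe = report.paired_errors
        lines.append(
            f"paired error difference: {pe.k}/{pe.n} "
            f"({100 * pe.k / pe.n:.0f}%, 95% CI "
            f"{100 * pe.ci.lower:.1f}-{100 * pe.ci.upper:.1f})"
        )
    if report.mcnemar is not None:
        lines.append(f"exact McNemar: P{format_p(report.mcnemar.p)}")
    if report.missing:
        lines.append(f"missing strata: {report.missing}")
    return "\n".join(lines)
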