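"""Paired pre/post cohort statistics and method-agreement analysis.

The workflow mirrors standard small-sample biomedical practice: effect
sizes are summarised as the percent change 100*(post - pre)/pre, paired
comparisons are gated on normality of the differences (Shapiro-Wilk at
alpha = 0.05) between a paired Student t-test and the Wilcoxon
signed-rank test, and bivariate association uses Pearson's r when both
marginals look normal, Spearman's rho otherwise. Raw per-variable
p-values are reported without multiple-testing correction by default; an
optional Benjamini-Hochberg adjustment can be switched on.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import DegenerateInputError, InsufficientDataError

#: significance level of the Shapiro-Wilk normality gate
NORMALITY_ALPHA = 0.05
#: largest sample size for which the Wilcoxon null is enumerated exactly
WILCOXON_EXACT_MAX_N = 25

TEST_PAIRED_T = "paired_t"
TEST_WILCOXON = "wilcoxon_signed_rank"

COHORT_COLUMNS = ("animal_id", "group", "variable", "pre", "post")


@dataclasses.dataclass
class ComparisonResult:
    """One paired pre/post comparison for a (group, variable) cell."""

    variable: str
    group: int | str | None
    n: int
    mean_pre: float
    mean_post: float
    sd_pre: float
    sd_post: float
    test_used: str
    statistic: float
    p_value: float
    mean_pct_change: float
    normality_p: float
    degenerate: bool = False
    exact: bool = False


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    method: str


@dataclasses.dataclass
class AgreementResult:
    """Pathologist-versus-program agreement summary.

    ``mean_difference`` is method A minus method B (positive = A scores
    higher); the correlation is computed on the two methods'
    percent-change vectors when pre/post pairs are supplied, on the raw
    vectors otherwise.
    """

    n: int
    mean_difference: float
    sd_difference: float
    correlation_of_pct_change: float
    correlation_method: str
    p_value: float


def percent_change(pre, post):
    """100 * (post - pre) / pre; positive means the value rose post.

    Accepts scalars or arrays; every ``pre`` must be non-zero.
    """
    pre_arr = np.asarray(pre, dtype=float)
    post_arr = np.asarray(post, dtype=float)
    if np.any(pre_arr == 0):
        raise DegenerateInputError("percent change is undefined for pre = 0")
    out = 100.0 * (post_arr - pre_arr) / pre_arr
    return float(out) if np.isscalar(pre) or out.ndim == 0 else out


def test_normality(values: Sequence[float]) -> tuple[bool, float]:
    """Shapiro-Wilk normality check; returns (is_normal, p_value).

    ``is_normal`` is ``p >= 0.05``. Needs n >= 3; a (near-)constant
    vector has no distribution to test and raises.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise InsufficientDataError(
            f"normality test needs n >= 3, got n = {vals.size}"
        )
    if np.ptp(vals) < 1e-12:
        raise DegenerateInputError(
            "constant vector: variance is zero, normality is undefined"
        )
    stat, p = sp_stats.shapiro(vals)
    return bool(p >= NORMALITY_ALPHA), float(p)


def _wilcoxon(d: np.ndarray) -> tuple[float, float, bool]:
    """Signed-rank test on nonzero differences.

    Zeros are dropped (Wilcoxon's treatment), ties get average ranks.
    The null distribution is exact for n <= 25 when the absolute
    differences are tie-free; otherwise a normal approximation with
    continuity correction is used. Returns (W, p, used_exact).
    """
    nz = d[d != 0]
    ties = np.unique(np.abs(nz)).size < nz.size
    exact = nz.size <= WILCOXON_EXACT_MAX_N and not ties
    res = sp_stats.wilcoxon(
        nz,
        zero_method="wilcox",
        correction=not exact,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return float(res.statistic), float(res.pvalue), exact


def compare_prepost(
    pre: Sequence[float],
    post: Sequence[float],
    variable: str = "",
    group: int | str | None = None,
    test: str = "auto",
) -> ComparisonResult:
    """Paired pre/post comparison with a normality-gated test choice.

    ``test`` may force ``"paired_t"`` or ``"wilcoxon"``; the default
    gates on Shapiro-Wilk of the paired differences. When every
    difference is zero the comparison is degenerate: p = 1 with the
    statistic at its null value, flagged rather than failed.
    """
    pre_arr = np.asarray(pre, dtype=float)
    post_arr = np.asarray(post, dtype=float)
    if pre_arr.shape != post_arr.shape:
        raise ValueError("pre and post must have equal length")
    n = pre_arr.size
    if n < 3:
        raise InsufficientDataError(f"paired comparison needs n >= 3, got {n}")
    d = post_arr - pre_arr

    nonzero_pre = pre_arr != 0
    pct = (
        float(np.mean(percent_change(pre_arr[nonzero_pre], post_arr[nonzero_pre])))
        if nonzero_pre.any()
        else float("nan")
    )
    common = dict(
        variable=variable,
        group=group,
        n=n,
        mean_pre=float(pre_arr.mean()),
        mean_post=float(post_arr.mean()),
        sd_pre=float(pre_arr.std(ddof=1)),
        sd_post=float(post_arr.std(ddof=1)),
        mean_pct_change=pct,
    )

    if np.all(d == 0):
        return ComparisonResult(
            **common,
            test_used=TEST_WILCOXON,
            statistic=0.0,
            p_value=1.0,
            normality_p=float("nan"),
            degenerate=True,
        )

    norm_p = float("nan")
    if test == "auto":
        try:
            is_normal, norm_p = test_normality(d)
        except DegenerateInputError:
            is_normal = False  # constant nonzero shift: no normality to speak of
        chosen = TEST_PAIRED_T if is_normal else TEST_WILCOXON
    elif test == "paired_t":
        chosen = TEST_PAIRED_T
    elif test == "wilcoxon":
        chosen = TEST_WILCOXON
    else:
        raise ValueError(f"unknown test {test!r}")

    if chosen == TEST_PAIRED_T:
        res = sp_stats.ttest_rel(post_arr, pre_arr)
        return ComparisonResult(
            **common,
            test_used=TEST_PAIRED_T,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            normality_p=norm_p,
        )
    stat, p, exact = _wilcoxon(d)
    return ComparisonResult(
        **common,
        test_used=TEST_WILCOXON,
        statistic=stat,
        p_value=p,
        normality_p=norm_p,
        exact=exact,
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> CorrelationResult:
    """Pearson or Spearman correlation with a normality-gated default.

    ``method="auto"`` uses Pearson when both marginals pass the
    Shapiro-Wilk gate, Spearman otherwise.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape:
        raise ValueError("x and y must have equal length")
    if x_arr.size < 3:
        raise InsufficientDataError(f"correlation needs n >= 3, got {x_arr.size}")
    if np.ptp(x_arr) < 1e-12 or np.ptp(y_arr) < 1e-12:
        raise DegenerateInputError("zero variance in x or y: correlation undefined")
    if method == "auto":
        x_normal, _ = test_normality(x_arr)
        y_normal, _ = test_normality(y_arr)
        method = "pearson" if (x_normal and y_normal) else "spearman"
    if method == "pearson":
        res = sp_stats.pearsonr(x_arr, y_arr)
    elif method == "spearman":
        res = sp_stats.spearmanr(x_arr, y_arr)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), method)


def method_agreement(pathologist, program, method: str = "auto") -> AgreementResult:
    """Agreement between the pathologist's and the program's steatosis scores.

    Each argument is either a vector of scores, or a ``(pre, post)`` pair
    of vectors. With pairs, the difference statistics are computed on the
    pre-moment scores and the correlation on the two methods'
    percent-change vectors; with plain vectors both use the raw values.
    """

    def unpack(arg):
        if isinstance(arg, tuple) and len(arg) == 2:
            return np.asarray(arg[0], float), np.asarray(arg[1], float)
        return np.asarray(arg, float), None

    pa, pa_post = unpack(pathologist)
    pr, pr_post = unpack(program)
    if pa.shape != pr.shape:
        raise ValueError("method vectors must have equal length")
    if pa.size < 3:
        raise InsufficientDataError(f"agreement needs n >= 3, got {pa.size}")
    diff = pa - pr
    if pa_post is not None and pr_post is not None:
        corr = correlate(
            percent_change(pa, pa_post), percent_change(pr, pr_post), method=method
        )
    else:
        corr = correlate(pa, pr, method=method)
    return AgreementResult(
        n=int(pa.size),
        mean_difference=float(diff.mean()),
        sd_difference=float(diff.std(ddof=1)),
        correlation_of_pct_change=corr.r,
        correlation_method=corr.method,
        p_value=corr.p_value,
    )


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy cohort-table contract; returns the table unchanged."""
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if table.duplicated(subset=["animal_id", "variable"]).any():
        raise ValueError("duplicate (animal_id, variable) pairs in cohort table")
    if not np.all(np.isfinite(table[["pre", "post"]].to_numpy(dtype=float))):
        raise ValueError("pre/post values must be finite")
    return table


def run_group_analysis(
    table: pd.DataFrame, bh_correction: bool = False
) -> tuple[list[ComparisonResult], list[dict]]:
    """One paired comparison per (group, variable) cell of a cohort table.

    Cells with fewer than 3 animals are reported in the skipped list, not
    failed. Results are ordered by group then variable. With
    ``bh_correction`` the p-values are Benjamini-Hochberg adjusted across
    all emitted comparisons (off by default: raw per-variable p-values).
    """
    validate_cohort(table)
    results: list[ComparisonResult] = []
    skipped: list[dict] = []
    for (group, variable), cell in table.groupby(["group", "variable"], sort=True):
        if len(cell) < 3:
            skipped.append({"group": group, "variable": variable, "n": len(cell)})
            continue
        results.append(
            compare_prepost(
                cell["pre"].to_numpy(),
                cell["post"].to_numpy(),
                variable=str(variable),
                group=group,
            )
        )
    if bh_correction and results:
        adjusted = sp_stats.false_discovery_control(
            [r.p_value for r in results], method="bh"
        )
        for r, p in zip(results, adjusted):
            r.p_value = float(p)
    return results, skipped


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results for CSV export."""
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
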