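"""Normality-gated univariate comparisons with false-discovery control.

Each variable (biomarker or metabolite) is compared between cases and
controls.  The Shapiro-Wilk test gates the choice of test: parametric when
normality is not rejected (paired t-test on within-pair differences, or
Welch's t-test for independent groups), otherwise the nonparametric
counterpart (Wilcoxon signed-rank, or Mann-Whitney).  Raw p-values from
one call form one adjustment family and receive Benjamini-Hochberg
step-up correction; adjusted p <= 0.05 is declared significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GROUP_CASE, GROUP_CONTROL, CohortError, PairedCohort

PAIRED_T = "paired t"
WILCOXON = "Wilcoxon signed-rank"
WELCH_T = "unpaired t (Welch)"
STUDENT_T = "unpaired t (pooled)"
MANN_WHITNEY = "Mann-Whitney"

ALPHA = 0.05
#: Exact signed-rank null up to this many non-zero differences; the normal
#: approximation with continuity and tie correction is used above.
_WILCOXON_EXACT_MAX_N = 25


@dataclass
class UnivariateResult:
    """Comparison of one variable between cases and controls."""

    variable: str
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    test: str
    p_raw: float
    p_adjusted: float = float("nan")

    @property
    def significant(self) -> bool:
        return bool(self.p_adjusted <= ALPHA)


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p-value; 0.0 for (near-)constant input with a warning."""
    x = np.asarray(x, float)
    if np.ptp(x) == 0.0:
        warnings.warn(
            "constant input: Shapiro-Wilk undefined, using nonparametric branch",
            stacklevel=3,
        )
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def choose_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    paired: bool,
    normality_alpha: float = ALPHA,
    pooled_variance: bool = False,
) -> str:
    """Select the comparison test via the Shapiro-Wilk normality gate.

    Paired mode tests normality of the within-pair differences ``a - b``;
    unpaired mode requires both groups to pass.  The parametric branch is
    chosen iff normality is not rejected (p > ``normality_alpha``).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if min(len(a), len(b)) < 3:
        raise CohortError("need at least 3 observations per group")
    if paired:
        if len(a) != len(b):
            raise CohortError("paired groups must have equal length")
        normal = _shapiro_p(a - b) > normality_alpha
        return PAIRED_T if normal else WILCOXON
    normal = (_shapiro_p(a) > normality_alpha) and (_shapiro_p(b) > normality_alpha)
    if normal:
        return STUDENT_T if pooled_variance else WELCH_T
    return MANN_WHITNEY


def _run_test(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == PAIRED_T:
        res = stats.ttest_rel(a, b)
    elif test == WILCOXON:
        d = a - b
        if np.all(d == 0):
            return 1.0  # identical members in every pair: no evidence
        nz = d[d != 0]
        exact_ok = (
            len(nz) <= _WILCOXON_EXACT_MAX_N
            and len(np.unique(np.abs(nz))) == len(nz)
            and len(nz) == len(d)
        )
        method = "exact" if exact_ok else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                                 method=method)
    elif test == WELCH_T:
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == STUDENT_T:
        res = stats.ttest_ind(a, b, equal_var=True)
    elif test == MANN_WHITNEY:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


def compare_groups(
    cohort: PairedCohort,
    table: pd.DataFrame,
    paired: bool = True,
    normality_alpha: float = ALPHA,
    pooled_variance: bool = False,
) -> pd.DataFrame:
    """Compare every column of ``table`` between cases and controls.

    ``table`` is indexed by subject id (concentration matrix values or the
    biomarker table).  All columns form one Benjamini-Hochberg family.
    Returns a result table with raw and adjusted p-values.
    """
    sub = cohort.subjects
    missing = set(sub.index) - set(table.index)
    if missing:
        raise CohortError(f"table lacks subjects: {sorted(missing)[:5]}")
    case_ids = sub.index[sub["group"] == GROUP_CASE]
    ctrl_ids = sub.index[sub["group"] == GROUP_CONTROL]
    if paired:
        # align both groups by pair id so differences are within-pair
        order = sub.loc[case_ids, "pair_id"].sort_values()
        case_ids = order.index
        pair_to_ctrl = {
            sub.at[i, "pair_id"]: i for i in ctrl_ids
        }
        try:
            ctrl_ids = pd.Index([pair_to_ctrl[p] for p in order.to_numpy()])
        except KeyError as e:  # pragma: no cover - guarded by PairedCohort
            raise CohortError(f"unmatched pair id {e.args[0]!r}") from e

    rows = []
    for col in table.columns:
        a = table.loc[case_ids, col].to_numpy(float)
        b = table.loc[ctrl_ids, col].to_numpy(float)
        test = choose_test(a, b, paired=paired, normality_alpha=normality_alpha,
                           pooled_variance=pooled_variance)
        rows.append(
            UnivariateResult(
                variable=col,
                mean_case=float(np.mean(a)), sd_case=float(np.std(a, ddof=1)),
                mean_control=float(np.mean(b)), sd_control=float(np.std(b, ddof=1)),
                test=test,
                p_raw=_run_test(a, b, test),
            )
        )
    p_adj = adjust_benjamini(np.array([r.p_raw for r in rows]))
    for r, p in zip(rows, p_adj):
        r.p_adjusted = float(p)
    out = pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "mean_lvr": [r.mean_case for r in rows],
            "sd_lvr": [r.sd_case for r in rows],
            "mean_ctrl": [r.mean_control for r in rows],
            "sd_ctrl": [r.sd_control for r in rows],
            "test": [r.test for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_adj": [r.p_adjusted for r in rows],
            "significant": [r.significant for r in rows],
        }
    ).set_index("variable")
    return out


def adjust_benjamini(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone in the ranks, capped at 1, order-preserving with respect to
    the input layout.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t")
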