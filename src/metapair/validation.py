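"""Exhaustive-partition validation of the paired PLS-DA classifier.

With matched pairs kept intact, allocating 22 of 32 pairs to training and
10 to testing admits C(32, 22) = 64,512,240 distinct partitions.  Rather
than materializing them, partitions are indexed by their lexicographic rank
and generated on demand by combinadic unranking; a systematic sample (every
310th rank by default, 208,104 models) makes the sweep tractable.  Each
sampled partition yields one PLS-DA model fit on the training pairs, scored
on the held-out pairs by AUROC, and assigned a p-value for the deviation of
that AUROC from 0.5 — the performance of the "mean model" that predicts
class membership at random.

The stream of per-model results is summarized by medians; the classifier is
accepted only when median AUROC >= 0.8 and median p <= 0.05, in which case
variables with median VIP > 1 across models are selected.  Both tails of
the significance fraction are reported separately: under a correct null
about 5% of models are significantly better and 5% significantly worse
than chance, about 10% combined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .latent import autoscale, plsda_fit, plsda_predict, within_pair_transform

DEFAULT_TRAIN_PAIRS = 22
DEFAULT_STEP = 310
AUROC_CUTOFF = 0.8
PVALUE_CUTOFF = 0.05
VIP_CUTOFF = 1.0
#: Exact Mann-Whitney null up to this product of group sizes.
_EXACT_U_MAX = 400


class ValidationError(ValueError):
    """Invalid partition plan or evaluation input."""


# ---------------------------------------------------------------------------
# combinatorics: counting, systematic thinning, combinadic unranking
# ---------------------------------------------------------------------------

def count_partitions(n: int, k: int) -> int:
    """Exact number of k-subsets of n items (arbitrary precision)."""
    if k < 0 or k > n or n < 0:
        raise ValidationError(f"invalid combination C({n}, {k})")
    return math.comb(n, k)


def systematic_sample(total: int, step: int, offset: int = 0) -> range:
    """Every ``step``-th rank starting at ``offset``: length ceil((total-offset)/step)."""
    if step < 1:
        raise ValidationError("step must be >= 1")
    if not (0 <= offset < step):
        raise ValidationError("offset must lie in [0, step)")
    return range(offset, total, step)


def unrank_combination(rank: int, n: int, k: int) -> tuple[int, ...]:
    """The ``rank``-th k-subset of {0..n-1} in lexicographic order.

    Combinadic unranking: walk the candidate elements in increasing order
    and subtract the block of combinations skipped by each choice.
    """
    total = count_partitions(n, k)
    if not (0 <= rank < total):
        raise ValidationError(f"rank {rank} out of range for C({n}, {k})")
    out = []
    x = 0
    r = rank
    for slot in range(k, 0, -1):
        while True:
            block = math.comb(n - x - 1, slot - 1)
            if r < block:
                break
            r -= block
            x += 1
        out.append(x)
        x += 1
    return tuple(out)


# ---------------------------------------------------------------------------
# AUROC and its mean-model significance
# ---------------------------------------------------------------------------

def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC with midrank tie handling.

    Equals the fraction of (positive, negative) score pairs ranked
    concordantly, ties counting one half.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes required to compute AUROC")
    ranks = stats.rankdata(scores)
    u = float(ranks[labels == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@lru_cache(maxsize=64)
def _exact_u_pmf(m: int, n: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic for group sizes (m, n).

    Counts f(i, j, u) of arrangements of i and j observations yielding
    U = u follow the classic recurrence
    f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u); normalizing by C(m+n, m)
    gives the null pmf (continuous data, no ties).
    """
    N = m * n
    # prev_i[j, u] = f(i-1, j, u); base f(0, j, u) = [u == 0]
    prev_i = np.zeros((n + 1, N + 1))
    prev_i[:, 0] = 1.0
    for _ in range(1, m + 1):
        cur = np.zeros_like(prev_i)
        cur[0, 0] = 1.0  # f(i, 0, u) = [u == 0]
        for j in range(1, n + 1):
            cur[j, j:] = prev_i[j, : N + 1 - j]
            cur[j] += cur[j - 1]
        prev_i = cur
    pmf = prev_i[n]
    return pmf / pmf.sum()


def auroc_pvalue(value: float, n_pos: int, n_neg: int,
                 directional: bool = False) -> float:
    """P-value for an AUROC's deviation from the chance value 0.5.

    Based on the null distribution of the Mann-Whitney U statistic (the
    "mean model" randomly ordering cases and controls): exact when
    ``n_pos * n_neg <= 400``, otherwise the normal approximation with
    continuity correction.  Symmetric: p(A) = p(1 - A).

    By default the smaller-tail probability is doubled (two-sided).  With
    ``directional=True`` the undoubled observed-direction tail is
    returned, so that p <= alpha captures an alpha-sized tail on each
    side of 0.5 separately — the convention under which roughly 5% of
    null models are significantly better and 5% significantly worse than
    chance, about 10% combined.
    """
    if not (0.0 <= value <= 1.0):
        raise ValidationError("AUROC must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("need at least one sample per class")
    mn = n_pos * n_neg
    u = value * mn
    u_low = min(u, mn - u)
    scale = 1.0 if directional else 2.0
    if mn <= _EXACT_U_MAX:
        pmf = _exact_u_pmf(min(n_pos, n_neg), max(n_pos, n_neg))
        cdf_low = float(pmf[: int(math.floor(u_low + 1e-9)) + 1].sum())
        return min(1.0, scale * cdf_low)
    sigma = math.sqrt(mn * (n_pos + n_neg + 1) / 12.0)
    z = (u_low - mn / 2.0 + 0.5) / sigma
    return min(1.0, scale * stats.norm.cdf(z))


@lru_cache(maxsize=64)
def _paired_u_pmf(n_pairs: int) -> np.ndarray:
    """Null pmf of the AUROC U statistic for mirrored paired test scores.

    After the within-pair transform the two members of a test pair carry
    exactly opposite deviations, so a linear classifier scores them as
    c + e_i (case) and c - e_i (control).  The concordance count is then
    U = #{(i, j): e_i + e_j > 0} (i = j included).  By the Walsh-average
    identity with the signed-rank statistic, U = sum over ranks i of
    (2i - 1) * [rank-i magnitude has positive sign]; under exchangeable
    labels the signs are iid fair coins, so U is a sum of independent
    weighted Bernoullis with weights 1, 3, ..., 2n-1 — distribution-free
    and exact.
    """
    N = n_pairs * n_pairs
    pmf = np.zeros(N + 1)
    pmf[0] = 1.0
    for i in range(1, n_pairs + 1):
        w = 2 * i - 1
        nxt = 0.5 * pmf
        nxt[w:] += 0.5 * pmf[: N + 1 - w]
        pmf = nxt
    return pmf


def paired_auroc_pvalue(value: float, n_pairs: int,
                        directional: bool = False) -> float:
    """AUROC p-value under the mirrored-pair (multilevel) null.

    Calibrated for test sets produced by the within-pair transform, where
    the Mann-Whitney null is anticonservative: the mirror symmetry couples
    every (case i, control i) comparison, roughly doubling the variance of
    U.  Exact and distribution-free given exchangeable labels within
    pairs.  ``directional`` selects the undoubled observed-direction tail
    as in :func:`auroc_pvalue`.
    """
    if not (0.0 <= value <= 1.0):
        raise ValidationError("AUROC must lie in [0, 1]")
    if n_pairs < 1:
        raise ValidationError("need at least one test pair")
    N = n_pairs * n_pairs
    u = value * N
    u_low = min(u, N - u)
    pmf = _paired_u_pmf(n_pairs)
    cdf_low = float(pmf[: int(math.floor(u_low + 1e-9)) + 1].sum())
    return min(1.0, (1.0 if directional else 2.0) * cdf_low)


# ---------------------------------------------------------------------------
# plan, per-partition evaluation, full run
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionPlan:
    """Systematically thinned enumeration of pair-level train/test splits."""

    n_pairs: int = 32
    n_train_pairs: int = DEFAULT_TRAIN_PAIRS
    step: int = DEFAULT_STEP
    offset: int = 0
    max_models: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.n_train_pairs < self.n_pairs):
            raise ValidationError("need 0 < n_train_pairs < n_pairs")
        systematic_sample(self.total_partitions, self.step, self.offset)

    @property
    def total_partitions(self) -> int:
        return count_partitions(self.n_pairs, self.n_train_pairs)

    @property
    def ranks(self) -> list[int]:
        r = systematic_sample(self.total_partitions, self.step, self.offset)
        ranks = list(r)
        if self.max_models is not None:
            ranks = ranks[: self.max_models]
        return ranks

    @property
    def n_models(self) -> int:
        return len(self.ranks)


@dataclass
class ModelResult:
    """One train/test partition: its AUROC, mean-model p-value and VIPs."""

    rank: int
    auroc: float
    p_value: float
    vip: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {"rank": self.rank, "auroc": self.auroc, "p_value": self.p_value,
             "vip": [round(v, 6) for v in self.vip.tolist()]})


@dataclass
class ValidationSummary:
    n_models: int
    mean_auroc: float
    median_auroc: float
    median_p: float
    fraction_significant: float
    fraction_significantly_better: float
    fraction_significantly_worse: float
    decision: bool
    selected_variables: list[str] = field(default_factory=list)
    auroc_cutoff: float = AUROC_CUTOFF
    p_cutoff: float = PVALUE_CUTOFF

    def to_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "mean_auroc": self.mean_auroc,
            "median_auroc": self.median_auroc,
            "median_p": self.median_p,
            "fraction_significant": self.fraction_significant,
            "fraction_significantly_better": self.fraction_significantly_better,
            "fraction_significantly_worse": self.fraction_significantly_worse,
            "decision": self.decision,
            "selected_variables": self.selected_variables,
            "auroc_cutoff": self.auroc_cutoff,
            "p_cutoff": self.p_cutoff,
        }


def _pair_blocks(pair_ids: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Unique pairs (first-appearance order) and row indices per pair."""
    pair_ids = np.asarray(pair_ids)
    uniq = pd.unique(pair_ids)
    rows = [np.flatnonzero(pair_ids == p) for p in uniq]
    return uniq, rows


def evaluate_partition(
    data: np.ndarray,
    pair_ids: np.ndarray,
    labels: np.ndarray,
    rank: int,
    n_components: int = 2,
    n_train_pairs: int = DEFAULT_TRAIN_PAIRS,
    null_model: str = "paired-exact",
    directional: bool = True,
) -> ModelResult:
    """Fit and score the PLS-DA model of one partition rank.

    ``data`` must already be quantitation-filtered and within-pair
    transformed.  The rank is unranked into training pairs; both members of
    a pair travel together.  Scaling statistics come from the training
    block only.

    ``null_model`` selects the AUROC reference distribution:
    ``"paired-exact"`` (default; calibrated for within-pair-transformed
    data, whose test pairs score as mirror images) or ``"mann-whitney"``
    (independent-sample U null, appropriate without the pair transform).
    """
    data = np.asarray(data, float)
    labels = np.asarray(labels).astype(int)
    pairs, rows = _pair_blocks(np.asarray(pair_ids))
    n_pairs = len(pairs)
    train_pair_idx = unrank_combination(rank, n_pairs, n_train_pairs)
    train_mask = np.zeros(n_pairs, bool)
    train_mask[list(train_pair_idx)] = True
    train_rows = np.concatenate([rows[i] for i in range(n_pairs) if train_mask[i]])
    test_rows = np.concatenate([rows[i] for i in range(n_pairs) if not train_mask[i]])

    scaler, X_test = autoscale(data[train_rows], data[test_rows])
    model = plsda_fit(scaler.values, labels[train_rows], n_components)
    scores = plsda_predict(model, X_test)
    test_labels = labels[test_rows]
    a = auroc(scores, test_labels)
    n_pos = int(test_labels.sum())
    n_neg = int(len(test_labels) - test_labels.sum())
    if null_model == "paired-exact":
        if n_pos != n_neg:
            raise ValidationError(
                "paired-exact null requires one case and one control per pair")
        p = paired_auroc_pvalue(a, n_pos, directional=directional)
    elif null_model == "mann-whitney":
        p = auroc_pvalue(a, n_pos, n_neg, directional=directional)
    else:
        raise ValidationError(f"unknown null_model {null_model!r}")
    return ModelResult(rank=rank, auroc=a, p_value=p, vip=model.vip)


def run_validation(
    data: np.ndarray,
    pair_ids: np.ndarray,
    labels: np.ndarray,
    plan: PartitionPlan,
    n_components: int = 2,
    variable_names: list[str] | None = None,
    stream_path: str | Path | None = None,
    auroc_cutoff: float = AUROC_CUTOFF,
    p_cutoff: float = PVALUE_CUTOFF,
    apply_pair_transform: bool = False,
    null_model: str = "paired-exact",
    directional: bool = True,
) -> tuple[ValidationSummary, pd.DataFrame]:
    """Evaluate every rank in ``plan`` and summarize the result stream.

    Returns the summary plus a per-model table (rank, AUROC, p).  When
    ``stream_path`` is given, every model is appended there as one JSON
    line including its VIP vector.  Variable selection (median VIP > 1)
    happens only when the decision rule median AUROC >= cutoff and
    median p <= cutoff is satisfied.
    """
    data = np.asarray(data, float)
    if apply_pair_transform:
        data = within_pair_transform(data, pair_ids)
    p_vars = data.shape[1]
    if variable_names is None:
        variable_names = [f"var{j}" for j in range(p_vars)]
    if len(variable_names) != p_vars:
        raise ValidationError("one variable name per column is required")

    ranks = plan.ranks
    aurocs = np.empty(len(ranks))
    pvals = np.empty(len(ranks))
    vips = np.empty((len(ranks), p_vars))
    handle = open(stream_path, "w") if stream_path is not None else None
    try:
        for i, rank in enumerate(ranks):
            try:
                res = evaluate_partition(
                    data, pair_ids, labels, rank, n_components,
                    plan.n_train_pairs, null_model, directional)
            except Exception as e:
                raise ValidationError(f"partition rank {rank} failed: {e}") from e
            aurocs[i], pvals[i], vips[i] = res.auroc, res.p_value, res.vip
            if handle is not None:
                handle.write(res.to_json() + "\n")
    finally:
        if handle is not None:
            handle.close()

    significant = pvals <= PVALUE_CUTOFF
    better = significant & (aurocs > 0.5)
    worse = significant & (aurocs < 0.5)
    median_auroc = float(np.median(aurocs))
    median_p = float(np.median(pvals))
    decision = bool(median_auroc >= auroc_cutoff and median_p <= p_cutoff)
    selected: list[str] = []
    if decision:
        median_vip = np.median(vips, axis=0)
        selected = [v for v, m in zip(variable_names, median_vip)
                    if m > VIP_CUTOFF]
    summary = ValidationSummary(
        n_models=len(ranks),
        mean_auroc=float(aurocs.mean()),
        median_auroc=median_auroc,
        median_p=median_p,
        fraction_significant=float(significant.mean()),
        fraction_significantly_better=float(better.mean()),
        fraction_significantly_worse=float(worse.mean()),
        decision=decision,
        selected_variables=selected,
        auroc_cutoff=auroc_cutoff,
        p_cutoff=p_cutoff,
    )
    results = pd.DataFrame({"rank": ranks, "auroc": aurocs, "p_value": pvals})
    return summary, results


def histogram_table(values: np.ndarray, bins: int = 50,
                    value_range: tuple[float, float] = (0.0, 1.0)) -> pd.DataFrame:
    """Histogram as a TSV-friendly table of bin edges and counts."""
    counts, edges = np.histogram(values, bins=bins, range=value_range)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
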