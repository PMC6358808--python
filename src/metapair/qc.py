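"""Quantitation-accuracy filtering of a targeted metabolite panel.

A measurement below the lower limit of quantitation (LLOQ) or above the
upper limit (ULOQ) is not quantified accurately.  A metabolite for which
more than 20% of measurements are out of range is excluded from statistical
analysis; the threshold is strict ("more than"), so an out-of-range
fraction of exactly 0.20 keeps the metabolite.  Missing (NaN) cells count
as not accurately measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CohortError, ConcentrationMatrix

DEFAULT_MAX_OUT_OF_RANGE = 0.20


class QCError(ValueError):
    """Quantitation filter cannot be applied."""


@dataclass
class RetentionReport:
    """Outcome of the quantitation filter.

    ``per_metabolite`` has one row per input metabolite: family, number of
    samples, out-of-range count and fraction, and the retention decision.
    """

    per_metabolite: pd.DataFrame
    n_input: int
    n_retained: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input

    @property
    def retained_names(self) -> list[str]:
        kept = self.per_metabolite["retained"]
        return list(self.per_metabolite.index[kept])

    def family_breakdown(self) -> pd.Series:
        """Retained metabolite count per biochemical family."""
        kept = self.per_metabolite[self.per_metabolite["retained"]]
        return kept.groupby("family").size()

    def write(self, path: str | Path) -> None:
        self.per_metabolite.to_csv(path, sep="\t", index_label="metabolite")


def flag_out_of_range(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Recompute censor flags from values and quantitation limits.

    A cell is flagged iff its value is strictly below LLOQ, strictly above
    ULOQ, or missing.  Values are left untouched.
    """
    limits = matrix.annotations[["lloq", "uloq"]]
    missing = limits.index[limits.isna().any(axis=1)]
    if len(missing):
        raise QCError(
            f"missing quantitation limits for metabolites: {list(missing[:5])}")
    values = matrix.values
    censor = (
        values.lt(limits["lloq"], axis=1)
        | values.gt(limits["uloq"], axis=1)
        | values.isna()
    )
    return ConcentrationMatrix(
        values=values.copy(), annotations=matrix.annotations.copy(), censor=censor)


def filter_metabolites(
    matrix: ConcentrationMatrix,
    max_fraction: float = DEFAULT_MAX_OUT_OF_RANGE,
) -> tuple[ConcentrationMatrix, RetentionReport]:
    """Drop metabolites whose out-of-range fraction exceeds ``max_fraction``.

    Retention is per metabolite: ``retained`` iff the fraction of censored
    cells is <= ``max_fraction``.  Column order is preserved.  Raises
    :class:`QCError` if nothing survives.
    """
    if not (0.0 <= max_fraction < 1.0):
        raise QCError("max_fraction must lie in [0, 1)")
    n_samples = matrix.n_samples
    n_flagged = matrix.censor.sum(axis=0)
    fraction = n_flagged / n_samples
    retained = fraction <= max_fraction
    report = RetentionReport(
        per_metabolite=pd.DataFrame(
            {
                "family": matrix.annotations["family"],
                "n_samples": n_samples,
                "n_out_of_range": n_flagged.astype(int),
                "out_of_range_fraction": fraction,
                "retained": retained,
            },
            index=matrix.values.columns,
        ),
        n_input=matrix.n_metabolites,
        n_retained=int(retained.sum()),
    )
    if report.n_retained == 0:
        raise QCError("no metabolite passes the quantitation filter")
    kept = list(matrix.values.columns[np.asarray(retained, bool)])
    return matrix.restrict(kept), report
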