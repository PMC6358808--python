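"""Core data containers for paired metabolomic cohorts.

A study consists of a :class:`PairedCohort` (matched case-control subjects
with clinical covariates and routine biomarkers) and a
:class:`ConcentrationMatrix` (samples x metabolites, micromol/L, with
per-metabolite family annotation and quantitation limits).  Both are thin
wrappers around :class:`pandas.DataFrame` with the invariants the analysis
relies on, plus CSV round-trip I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_CASE = "LVR"
GROUP_CONTROL = "noLVR"

METABOLITE_FAMILIES = (
    "acylcarnitines",
    "amino acids",
    "biogenic amines",
    "lysophosphatidylcholines",
    "phosphatidylcholines",
    "sphingomyelins",
    "hexoses",
)


class CohortError(ValueError):
    """Invalid cohort or matrix structure."""


@dataclass
class PairedCohort:
    """Matched case-control subjects.

    Attributes
    ----------
    subjects
        One row per subject, indexed by unique subject id, with columns
        ``pair_id`` and ``group`` (``"LVR"`` or ``"noLVR"``).  Every pair id
        appears exactly twice, once per group.
    covariates
        Clinical covariates (age in years, sex, hypertension flag, ...),
        same index as ``subjects``.
    biomarkers
        Routine biomarkers (CK peak UI/L, CRP mg/L, ...), same index.
    """

    subjects: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    biomarkers: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.subjects.index.is_unique:
            raise CohortError("subject ids must be unique")
        missing = {"pair_id", "group"} - set(self.subjects.columns)
        if missing:
            raise CohortError(f"subjects table lacks columns: {sorted(missing)}")
        bad = set(self.subjects["group"]) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise CohortError(f"unknown group labels: {sorted(bad)}")
        counts = self.subjects.groupby("pair_id")["group"].agg(
            lambda g: (len(g), len(set(g)))
        )
        for pair_id, (n, k) in counts.items():
            if n != 2 or k != 2:
                raise CohortError(
                    f"pair {pair_id!r} must have exactly one subject per group"
                )

    @property
    def n_pairs(self) -> int:
        return self.subjects["pair_id"].nunique()

    @property
    def labels(self) -> pd.Series:
        """Binary class label per subject (1 = case, 0 = control)."""
        return (self.subjects["group"] == GROUP_CASE).astype(int)

    @property
    def pair_ids(self) -> pd.Series:
        return self.subjects["pair_id"]

    def to_manifest(self) -> pd.DataFrame:
        """Single wide table: pair id, group, covariates, biomarkers."""
        return pd.concat([self.subjects, self.covariates, self.biomarkers], axis=1)

    def write_manifest(self, path: str | Path) -> None:
        self.to_manifest().to_csv(path, index_label="subject_id")

    @classmethod
    def read_manifest(
        cls,
        path: str | Path,
        covariate_columns: list[str] | None = None,
        biomarker_columns: list[str] | None = None,
    ) -> "PairedCohort":
        df = pd.read_csv(path, index_col=0)
        if covariate_columns is None and biomarker_columns is None:
            extra = [c for c in df.columns if c not in ("pair_id", "group")]
            covariate_columns, biomarker_columns = extra, []
        covariate_columns = covariate_columns or []
        biomarker_columns = biomarker_columns or []
        return cls(
            subjects=df[["pair_id", "group"]],
            covariates=df[covariate_columns],
            biomarkers=df[biomarker_columns],
        )


@dataclass
class ConcentrationMatrix:
    """Samples x metabolites concentration matrix with quantitation limits.

    Attributes
    ----------
    values
        Strictly positive concentrations (micromol/L); rows are samples in
        cohort subject order, columns are metabolites.
    annotations
        Per-metabolite table indexed by metabolite name with columns
        ``family``, ``lloq`` and ``uloq`` (micromol/L, ``lloq < uloq``).
    censor
        Boolean frame of the same shape as ``values``; True marks a cell
        whose value lies below LLOQ or above ULOQ (not quantified
        accurately).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    censor: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.values.columns) != list(self.annotations.index):
            raise CohortError("annotation index must match value columns in order")
        missing = {"family", "lloq", "uloq"} - set(self.annotations.columns)
        if missing:
            raise CohortError(f"annotations lack columns: {sorted(missing)}")
        if self.censor.shape != self.values.shape:
            raise CohortError("censor frame must have the shape of values")
        if not (
            list(self.censor.columns) == list(self.values.columns)
            and list(self.censor.index) == list(self.values.index)
        ):
            raise CohortError("censor frame must share the axes of values")
        # NaN limits are tolerated here; the QC stage rejects them by name
        limits = self.annotations[["lloq", "uloq"]].astype(float)
        complete = limits.notna().all(axis=1)
        bad = limits.index[complete & ~(limits["lloq"] < limits["uloq"])]
        if len(bad):
            raise CohortError(f"lloq >= uloq for metabolites: {list(bad[:5])}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def family_counts(self) -> pd.Series:
        return self.annotations["family"].value_counts()

    def restrict(self, metabolites: list[str]) -> "ConcentrationMatrix":
        """Column subset preserving order of ``self``."""
        keep = [m for m in self.values.columns if m in set(metabolites)]
        return ConcentrationMatrix(
            values=self.values[keep].copy(),
            annotations=self.annotations.loc[keep].copy(),
            censor=self.censor[keep].copy(),
        )

    # ---- CSV round trip (wide dialect: first column sample id) ----

    def write(self, prefix: str | Path) -> dict[str, Path]:
        """Write ``<prefix>_values.csv``, ``_annotations.csv``, ``_censor.csv``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "values": prefix.with_name(prefix.name + "_values.csv"),
            "annotations": prefix.with_name(prefix.name + "_annotations.csv"),
            "censor": prefix.with_name(prefix.name + "_censor.csv"),
        }
        self.values.to_csv(paths["values"], index_label="sample_id",
                           float_format="%.17g")
        self.annotations.to_csv(paths["annotations"], index_label="metabolite",
                                float_format="%.17g")
        self.censor.astype(int).to_csv(paths["censor"], index_label="sample_id")
        return paths

    @classmethod
    def read(cls, prefix: str | Path) -> "ConcentrationMatrix":
        prefix = Path(prefix)
        values = pd.read_csv(prefix.with_name(prefix.name + "_values.csv"),
                             index_col=0)
        annotations = pd.read_csv(
            prefix.with_name(prefix.name + "_annotations.csv"), index_col=0)
        censor_path = prefix.with_name(prefix.name + "_censor.csv")
        if censor_path.exists():
            censor = pd.read_csv(censor_path, index_col=0).astype(bool)
        else:
            censor = pd.DataFrame(
                np.zeros(values.shape, bool),
                index=values.index, columns=values.columns)
        return cls(values=values, annotations=annotations, censor=censor)
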