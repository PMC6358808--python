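"""End-to-end orchestration: simulate -> QC -> univariate -> PCA -> validation.

One :class:`RunConfig` (JSON or YAML) drives the whole analysis: generate
or load a matched cohort, apply the quantitation filter, run the paired
univariate screen on biomarkers and metabolites, screen for multivariate
outliers with paired PCA and Hotelling's T2, and sweep the partition
validation engine.  Every intermediate artifact is written to the output
directory and a machine-readable + human-readable run report records
retention counts, the univariate table, outliers, the validation summary
and the selection decision.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import latent, qc, univariate, validation
from .containers import ConcentrationMatrix, PairedCohort
from .synthetic import CohortConfig, generate_cohort, null_cohort

log = logging.getLogger("metapair")

MODES = ("synthetic-effect", "synthetic-null", "user-data")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    mode: str = "synthetic-effect"
    out_dir: str = "metapair_run"
    seed: int | None = 0
    n_pairs: int = 32
    # user-data inputs (ignored in synthetic modes)
    matrix_prefix: str | None = None
    manifest_path: str | None = None
    biomarker_columns: list[str] = field(default_factory=list)
    # stage parameters
    max_out_of_range: float = qc.DEFAULT_MAX_OUT_OF_RANGE
    paired: bool = True
    pair_transform: bool = True
    n_components: int = 2
    # None: allocate ~2/3 of pairs to training
    n_train_pairs: int | None = None
    step: int = validation.DEFAULT_STEP
    offset: int = 0
    max_models: int | None = 5000
    auroc_cutoff: float = validation.AUROC_CUTOFF
    p_cutoff: float = validation.PVALUE_CUTOFF
    t2_alpha: float = 0.95
    pca_components: int = 2

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise PipelineError(f"mode must be one of {MODES}")
        if self.mode.startswith("synthetic") and self.seed is None:
            raise PipelineError("seed is mandatory in synthetic modes")
        if not (0 <= self.max_out_of_range < 1):
            raise PipelineError("max_out_of_range must lie in [0, 1)")
        for name, v, lo, hi in (
            ("auroc_cutoff", self.auroc_cutoff, 0, 1),
            ("p_cutoff", self.p_cutoff, 0, 1),
            ("t2_alpha", self.t2_alpha, 0, 1),
        ):
            if not (lo < v <= hi):
                raise PipelineError(f"{name} out of range")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def setup_logging(out_dir: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "run.log"))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
        handlers=handlers,
        force=True,
    )


def _load_inputs(config: RunConfig) -> tuple[PairedCohort, ConcentrationMatrix]:
    if config.mode == "user-data":
        if not config.matrix_prefix or not config.manifest_path:
            raise PipelineError(
                "user-data mode requires matrix_prefix and manifest_path")
        try:
            cohort = PairedCohort.read_manifest(
                config.manifest_path,
                biomarker_columns=config.biomarker_columns or None)
            matrix = ConcentrationMatrix.read(config.matrix_prefix)
        except Exception as e:
            raise PipelineError(f"stage load: {e}") from e
        return cohort, matrix
    cfg = CohortConfig(n_pairs=config.n_pairs, seed=int(config.seed))
    gen = null_cohort if config.mode == "synthetic-null" else generate_cohort
    return gen(cfg)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    try:
        stage("load")
        cohort, matrix = _load_inputs(config)
        cohort.write_manifest(out / "cohort.csv")
        matrix.write(out / "raw")
        done("load")
        report["stages"]["load"] = {
            "n_pairs": cohort.n_pairs,
            "n_subjects": len(cohort.subjects),
            "n_metabolites": matrix.n_metabolites,
        }
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage load: {e}") from e

    try:
        stage("qc")
        matrix = qc.flag_out_of_range(matrix)
        filtered, retention = qc.filter_metabolites(matrix, config.max_out_of_range)
        retention.write(out / "retention.tsv")
        filtered.write(out / "filtered")
        done("qc")
        report["stages"]["qc"] = {
            "n_input": retention.n_input,
            "n_retained": retention.n_retained,
            "retained_fraction": retention.retained_fraction,
            "family_breakdown": retention.family_breakdown().to_dict(),
        }
    except Exception as e:
        raise PipelineError(f"stage qc: {e}") from e

    try:
        stage("univariate")
        uni_bio = univariate.compare_groups(
            cohort, cohort.biomarkers, paired=config.paired)
        uni_met = univariate.compare_groups(
            cohort, filtered.values, paired=config.paired)
        univariate.write_results(uni_bio, out / "univariate_biomarkers.tsv")
        univariate.write_results(uni_met, out / "univariate_metabolites.tsv")
        done("univariate")
        report["stages"]["univariate"] = {
            "significant_biomarkers":
                list(uni_bio.index[uni_bio["significant"]]),
            "significant_metabolites":
                list(uni_met.index[uni_met["significant"]]),
        }
    except Exception as e:
        raise PipelineError(f"stage univariate: {e}") from e

    try:
        stage("pca")
        X = filtered.values.to_numpy(float)
        pair_ids = cohort.pair_ids.to_numpy()
        if config.pair_transform:
            X = latent.within_pair_transform(X, pair_ids)
        scaler, _ = latent.autoscale(X)
        pca = latent.pca_nipals(scaler.values, config.pca_components)
        t2, outliers = latent.hotelling_t2(pca, config.t2_alpha)
        pd.DataFrame(
            {"t2": t2, "outlier": outliers}, index=filtered.values.index
        ).to_csv(out / "pca_t2.tsv", sep="\t")
        done("pca")
        report["stages"]["pca"] = {
            "explained": pca.explained.tolist(),
            "n_outliers": int(outliers.sum()),
            "outliers": list(filtered.values.index[outliers]),
        }
    except Exception as e:
        raise PipelineError(f"stage pca: {e}") from e

    try:
        stage("validation")
        labels = cohort.labels.to_numpy()
        n_train = (config.n_train_pairs
                   if config.n_train_pairs is not None
                   else max(1, round(2 * cohort.n_pairs / 3)))
        plan = validation.PartitionPlan(
            n_pairs=cohort.n_pairs,
            n_train_pairs=n_train,
            step=config.step,
            offset=config.offset,
            max_models=config.max_models,
        )
        summary, results = validation.run_validation(
            X, pair_ids, labels, plan,
            n_components=config.n_components,
            variable_names=list(filtered.values.columns),
            stream_path=out / "models.jsonl",
            auroc_cutoff=config.auroc_cutoff,
            p_cutoff=config.p_cutoff,
        )
        validation.histogram_table(results["auroc"].to_numpy()).to_csv(
            out / "auroc_histogram.tsv", sep="\t", index=False)
        validation.histogram_table(results["p_value"].to_numpy()).to_csv(
            out / "pvalue_histogram.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
        done("validation")
        report["stages"]["validation"] = summary.to_dict()
    except Exception as e:
        raise PipelineError(f"stage validation: {e}") from e

    report["timings_s"] = timings
    report["seed"] = config.seed
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "report.txt").write_text(render_report(report))
    log.info("run complete: %s", out / "report.json")
    return report


def render_report(report: dict) -> str:
    """Human-readable run summary."""
    s = report["stages"]
    v = s.get("validation", {})
    lines = [
        "metapair run report",
        "===================",
        f"mode: {report['config']['mode']}   seed: {report.get('seed')}",
        "",
        f"cohort: {s['load']['n_pairs']} pairs "
        f"({s['load']['n_subjects']} subjects), "
        f"{s['load']['n_metabolites']} metabolites on panel",
        f"quantitation filter: {s['qc']['n_retained']} / {s['qc']['n_input']} "
        f"retained ({100 * s['qc']['retained_fraction']:.1f}%)",
        f"significant biomarkers (BH <= 0.05): "
        f"{', '.join(s['univariate']['significant_biomarkers']) or 'none'}",
        f"significant metabolites (BH <= 0.05): "
        f"{', '.join(s['univariate']['significant_metabolites']) or 'none'}",
        f"PCA outliers (Hotelling T2): {s['pca']['n_outliers']}",
        "",
        f"partition validation: {v.get('n_models')} models",
        f"  median AUROC = {v.get('median_auroc'):.3f}   "
        f"median p = {v.get('median_p'):.3f}",
        f"  significant models: {100 * v.get('fraction_significant'):.1f}% "
        f"(better {100 * v.get('fraction_significantly_better'):.1f}%, "
        f"worse {100 * v.get('fraction_significantly_worse'):.1f}%)",
        f"  decision: {'variable selection performed' if v.get('decision') else 'no variable selection'}",
    ]
    if v.get("selected_variables"):
        lines.append(
            f"  selected (median VIP > 1): {', '.join(v['selected_variables'])}")
    return "\n".join(lines) + "\n"
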