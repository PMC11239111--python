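"""End-to-end pipeline: simulate/load -> filter -> popgen -> association ->
penalised model -> polygenic score, as one reproducible, seeded run.

A run is described by a :class:`RunConfig` (loadable from YAML; unknown keys
are rejected).  All randomness descends from the single ``seed``; per-stage
child seeds are derived deterministically, so two runs with the same config
produce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association, filters, io, lasso, popgen, prs, simulate

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "filter", "popgen", "assoc", "lasso", "prs")


@dataclass
class RunConfig:
    """Schema-validated pipeline configuration."""

    out_dir: str = "pgx_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulation (used when no VCF input is given)
    n_subjects: int = 69
    n_variants: int = 98
    # inputs (optional; override simulation)
    vcf: str | None = None
    pheno: str | None = None
    bed: str | None = None
    depth_tsv: str | None = None
    ref_af: str | None = None
    # model options
    cv_folds: int = 3
    cv_loss: str = "deviance"
    lambda_selection: str = "min"
    include_covariates_in_prs: bool = False
    ld_max_pairs: int = 5000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.cv_loss not in ("deviance", "mse"):
            raise ValueError("cv_loss must be 'deviance' or 'mse'")
        if self.lambda_selection not in ("min", "1se"):
            raise ValueError("lambda_selection must be 'min' or '1se'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Per-stage tables land as TSV, a machine summary as ``summary.json`` and
    a human log as ``run.log``.  A stage failure halts the run with a
    stage-tagged error; earlier outputs are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("pgxprs.pipeline")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("pgxprs %s; config: %s", __version__, dataclasses.asdict(config))

    summary: dict = {"version": __version__, "seed": config.seed,
                     "config": dataclasses.asdict(config)}
    tables: dict[str, pd.DataFrame] = {}
    stage = "init"
    try:
        # ---- cohort ------------------------------------------------------
        if config.vcf is not None:
            stage = "load"
            cohort = io.cohort_from_files(config.vcf, config.pheno)
        else:
            stage = "simulate"
            sim_cfg = simulate.default_config(
                seed=config.seed, n_subjects=config.n_subjects,
                n_variants=config.n_variants,
            )
            cohort = simulate.simulate_cohort(sim_cfg)
            if "simulate" in config.stages:
                simulate.write_cohort(
                    cohort, out / "cohort.vcf", out / "phenotypes.tsv",
                    out / "reference_af.tsv", seed=config.seed,
                )
        summary["n_subjects"] = cohort.n_subjects
        summary["n_variants_input"] = len(cohort.variant_ids)
        if cohort.htpr is not None:
            summary["htpr_fraction"] = float(cohort.htpr.mean())

        # ---- filter ------------------------------------------------------
        if "filter" in config.stages:
            stage = "filter"
            if config.vcf is not None:
                records, samples = io.read_vcf(config.vcf)
                kept, report = filters.apply_cascade(records)
                tables["filter_outcomes"] = report.outcomes.reset_index(names="variant_id")
                summary["filter_stage_counts"] = report.stage_counts
                keep_ids = [r.variant_id for r in kept]
                cohort.dosages = cohort.dosages[
                    [c for c in cohort.dosages.columns if c in keep_ids]
                ]
            cohort, dropped = filters.drop_monomorphic(cohort)
            summary["monomorphic_dropped"] = dropped
            if config.depth_tsv and config.bed:
                cov = filters.coverage_qc(
                    io.read_depth_tsv(config.depth_tsv), io.read_bed(config.bed)
                )
                tables["coverage_qc"] = cov
            summary["n_variants_analyzed"] = len(cohort.variant_ids)

        # ---- popgen ------------------------------------------------------
        if "popgen" in config.stages:
            stage = "popgen"
            hwe = popgen.hwe_scan(cohort)
            tables["hwe"] = hwe
            summary["hwe_equilibrium_fraction"] = float(hwe["in_equilibrium"].mean())
            if config.ref_af:
                tables["reference_af_comparison"] = popgen.compare_reference_af_scan(
                    cohort, io.read_reference_af(config.ref_af)
                )
            import itertools

            ids = cohort.variant_ids
            pairs = list(itertools.combinations(ids, 2))[: config.ld_max_pairs]
            ld = popgen.ld_pairwise(cohort, pairs)
            tables["ld"] = pd.DataFrame(
                [{"variant_a": r.variant_a, "variant_b": r.variant_b,
                  "D": r.d, "D_prime": r.d_prime, "r2": r.r2} for r in ld]
            )

        # ---- association -------------------------------------------------
        if "assoc" in config.stages and cohort.htpr is not None:
            stage = "assoc"
            assoc, ct_tab = association.association_scan(cohort)
            tables["association"] = assoc
            tables["ct_by_genotype"] = ct_tab
            summary["n_significant_assoc_p05"] = int(
                (assoc.loc[assoc["kind"] == "variant", "p"] < 0.05).sum()
            )

        # ---- lasso -------------------------------------------------------
        results = fm = None
        if "lasso" in config.stages and cohort.htpr is not None:
            stage = "lasso"
            fm = lasso.encode_features(cohort, impute_missing=True)
            model = lasso.PenalizedLogit(cohort.htpr.to_numpy(), fm.data)
            results = model.fit_cv(
                k=config.cv_folds, loss=config.cv_loss, seed=config.seed,
                selection=config.lambda_selection,
            )
            tables["lasso_coefficients"] = results.coef_table()
            tables["lasso_cv_curve"] = pd.DataFrame(
                {"lambda": results.lambda_path, "cv_mean": results.cv_mean,
                 "cv_se": results.cv_se, "n_nonzero": results.n_nonzero_path()}
            )
            roc = results.roc()
            tables["lasso_roc"] = pd.DataFrame(
                {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
            )
            oof = results.cv_roc()
            summary["lasso"] = {
                "lambda_min": results.lambda_min,
                "lambda_1se": results.lambda_1se,
                "selected_lambda": results.selected_lambda,
                "n_nonzero": len(results.nonzero_features()),
                "training_auc": roc.auc,
                "out_of_fold_auc": oof.auc,
            }
            log.info("lasso: %s", summary["lasso"])

        # ---- prs ---------------------------------------------------------
        if "prs" in config.stages and results is not None:
            stage = "prs"
            weights = prs.PRSWeights.from_results(
                results, fm, include_covariates=config.include_covariates_in_prs
            )
            weights.to_tsv(out / "prs_weights.tsv")
            pres = prs.score_and_validate(
                weights, fm,
                ct=cohort.ct.to_numpy() if cohort.ct is not None else None,
                htpr=cohort.htpr.to_numpy(),
            )
            tables["prs_scores"] = pres.scores.rename_axis("sample_id").reset_index()
            summary["prs"] = {
                "n_weights": len(weights.table),
                "mann_whitney_p": pres.mann_whitney_p,
                "spearman_rho": pres.spearman_rho,
                "spearman_p": pres.spearman_p,
                "ols_r2": pres.ols_r2,
            }
            log.info("prs: %s", summary["prs"])

    except Exception as exc:
        io.write_results(tables, out, summary)
        log.error("stage %s failed: %s", stage, exc)
        log.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    io.write_results(tables, out, summary)
    log.info("run complete: %s", out)
    log.removeHandler(handler)
    handler.close()
    return out
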