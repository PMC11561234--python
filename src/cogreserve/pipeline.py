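"""End-to-end orchestration: QC -> PL -> reserve model -> inference ->
validation, on a synthetic cohort bundle or user-supplied equivalents."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inference, pathload, qc, reserve, validation
from .datatypes import BootstrapResult, ContrastStack, CRPattern, PCABasis, ReserveFit, SubjectScores
from .synth import CohortBundle

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    kept_ids: list[str]
    exclusion: qc.ExclusionReport
    pl: pd.Series
    atrophy: pd.Series
    stack: ContrastStack
    basis: PCABasis
    n_components: int
    cv_table: pd.DataFrame
    fit: ReserveFit
    pattern: CRPattern
    scores: SubjectScores
    y: pd.Series
    covariates: pd.DataFrame
    bootstrap: BootstrapResult | None = None
    clusters: pd.DataFrame | None = None
    eq3_report: validation.ModerationFitReport | None = None
    edu_correlation: dict | None = None
    longitudinal: validation.LongitudinalFitReport | None = None


def run_pipeline(
    bundle: CohortBundle,
    pl_method: str = "pca",
    boxcox_lambda: float | None = None,
    candidates=None,
    n_folds: int = 10,
    n_boot: int = 0,
    level: float = 0.95,
    min_cluster_size: int = inference.MIN_CLUSTER_SIZE,
    connectivity: int = 26,
    run_validation: bool = True,
    seed: int = 0,
) -> PipelineResult:
    """Run the full reserve analysis on a cohort bundle.

    ``pl_method`` picks the 1-D pathology embedding ('pca' scores new data
    exactly and is the default for programmatic runs; 'tsne' mirrors the
    nonlinear reduction).  ``boxcox_lambda`` of None fits on the raw
    composite.  ``n_boot`` of 0 skips voxelwise inference.
    """
    report = qc.apply_exclusion_rules(bundle.behavior, bundle.contrasts)
    kept = report.kept_ids
    pheno = bundle.phenotypes.loc[kept]
    biomk = bundle.biomarkers.loc[kept]
    stack = bundle.contrasts.subset(kept)

    pl_result = pathload.pl_scores(biomk, method=pl_method, seed=seed)
    pl = pl_result.scores
    atrophy = pathload.atrophy_score(biomk)

    y_raw = pheno["pacc5"]
    shift = None
    if boxcox_lambda is not None:
        y_arr, shift = qc.boxcox_transform(y_raw.to_numpy(), lam=boxcox_lambda)
        y = pd.Series(y_arr, index=y_raw.index, name="y")
    else:
        y = y_raw.rename("y")

    covariates = reserve.build_covariates(pheno, n_sites=bundle.config.n_sites)
    pl_arr = pl.loc[stack.subjects].to_numpy()
    y_arr = y.loc[stack.subjects].to_numpy()
    cov_df = covariates.loc[stack.subjects]

    n_comp, cv_table = reserve.select_num_components(
        stack.data, pl_arr, y_arr, cov_df, candidates=candidates, n_folds=n_folds, seed=seed
    )
    basis = reserve.fit_pca(stack.data, n_comp)
    fit = reserve.fit_moderation(
        basis, pl_arr, y_arr, cov_df, n_components=n_comp,
        boxcox_lambda=boxcox_lambda, boxcox_shift=shift,
    )
    fit.cv_table = cv_table
    pattern = reserve.backproject(fit, basis)
    scores = reserve.subject_scores(pattern, stack)

    result = PipelineResult(
        kept_ids=kept,
        exclusion=report,
        pl=pl,
        atrophy=atrophy,
        stack=stack,
        basis=basis,
        n_components=n_comp,
        cv_table=cv_table,
        fit=fit,
        pattern=pattern,
        scores=scores,
        y=y,
        covariates=covariates,
    )

    if n_boot > 0:
        result.bootstrap = inference.bootstrap_pattern(
            basis, pl_arr, y_arr, cov_df, n_comp, n_boot, seed=seed, level=level
        )
        result.clusters = inference.cluster_table(
            result.bootstrap.significant,
            pattern.w,
            stack.data.mean(axis=0),
            stack.mask,
            affine=stack.affine,
            connectivity=connectivity,
            min_size=min_cluster_size,
        )

    if run_validation:
        sc = scores.to_frame().set_index("subject")
        keep = validation.cr_outlier_keep(sc["cr_score"])
        ids = sc.index[keep]
        result.eq3_report = validation.fit_proxy_moderation(
            y.loc[ids],
            (pl.loc[ids] ** 2).rename("pl2"),
            sc.loc[ids, "cr_score"],
            extra_main_terms=sc.loc[ids, ["bae"]],
            covariates=covariates.loc[ids],
            moderator_name="cr",
            tag="eq3",
        )
        result.edu_correlation = validation.correlate_cr_education(
            sc.loc[ids, "cr_score"].to_numpy(), pheno.loc[ids, "education"].to_numpy()
        )
        visits = bundle.visits[bundle.visits["subject"].isin(ids)]
        result.longitudinal = validation.fit_longitudinal(
            visits,
            cr=sc.loc[ids, "cr_score"],
            bae=sc.loc[ids, "bae"],
            atrophy=atrophy.loc[ids],
            covariates=covariates.loc[ids, [c for c in covariates.columns if c != "tiv_c"]],
        )
    return result
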