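"""The multivariate reserve (moderation) model.

Cognition y is modelled from principal-component projections of the
subsequent-memory contrast maps, a quadratic pathological-load term and
their interaction:

    y = b0 + sum_p b1_p PC_p + (b2 + sum_p b3_p PC_p) * PL^2 + c*COV + eps

The moderation coefficients b3 are back-projected to voxel space,
w_i = sum_p b3_p V_p,i, giving a voxel-level reserve-weight map; a
subject's CR score is the inner product of their contrast map with w, and
the BAE (brain-activity effect) score the analogous aggregate of the
additive coefficients b1.  The number of components P is a hyperparameter
selected by k-fold cross-validation on held-out R^2.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ContrastStack, CRPattern, PCABasis, ReserveFit, SubjectScores, TaskActiveMask

__all__ = [
    "derive_task_active_mask",
    "fit_pca",
    "build_covariates",
    "build_design",
    "fit_moderation",
    "select_num_components",
    "backproject",
    "subject_scores",
    "standardized_coefficients",
]


def derive_task_active_mask(contrasts_fullgrid: np.ndarray, alpha: float = 0.05) -> TaskActiveMask:
    """Voxels with significant group-level activation or deactivation.

    Per voxel, a two-sided one-sample t-test of mean beta against 0,
    Bonferroni-corrected over all tested voxels; the mask is the union of
    significant positive and negative voxels.  Zero-variance voxels are
    excluded with a warning (their t statistic is undefined).
    """
    data = np.asarray(contrasts_fullgrid, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D (subjects, x, y, z) array")
    n = data.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 subjects for the group t-test, got {n}")
    flat = data.reshape(n, -1)
    sd = flat.std(axis=0, ddof=1)
    testable = sd > 0
    if not testable.all():
        warnings.warn(f"excluding {int((~testable).sum())} zero-variance voxels from the mask test")
    n_tests = int(testable.sum())
    pvals = np.full(flat.shape[1], np.inf)
    t, p = stats.ttest_1samp(flat[:, testable], 0.0, axis=0)
    pvals[testable] = np.minimum(1.0, p * n_tests)  # Bonferroni, capped at 1
    significant = testable & (pvals <= alpha)
    return TaskActiveMask(significant.reshape(data.shape[1:]))


def fit_pca(stack_data: np.ndarray, n_components: int) -> PCABasis:
    """SVD-based PCA of column-mean-centered contrast data.

    Components are ordered by decreasing explained variance and carry a
    deterministic sign convention: the entry of largest magnitude in each
    component is positive.
    """
    data = np.asarray(stack_data, dtype=float)
    n, v = data.shape
    max_p = min(n - 1, v)
    if not 1 <= n_components <= max_p:
        raise ValueError(f"n_components must be in [1, {max_p}], got {n_components}")
    mean_map = data.mean(axis=0)
    centered = data - mean_map
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # Deterministic sign: largest-|loading| entry of each component positive.
    for p in range(n_components):
        j = np.argmax(np.abs(vt[p]))
        if vt[p, j] < 0:
            vt[p] = -vt[p]
            u[:, p] = -u[:, p]
    scores = u * s
    explained = s**2 / (n - 1)
    return PCABasis(mean_map=mean_map, components=vt, scores=scores, explained_variance=explained)


def build_covariates(phenotypes: pd.DataFrame, n_sites: int | None = None) -> pd.DataFrame:
    """Covariate design block: centered age and TIV, sex, site dummies.

    Age and TIV are centered on the analysis sample; site is dummy-coded
    with the first site as reference.
    """
    cov = pd.DataFrame(index=phenotypes.index)
    cov["age_c"] = phenotypes["age"] - phenotypes["age"].mean()
    cov["sex"] = phenotypes["sex"].astype(float)
    cov["tiv_c"] = phenotypes["tiv"] - phenotypes["tiv"].mean()
    sites = phenotypes["site"].astype(int)
    n_sites = n_sites if n_sites is not None else int(sites.max()) + 1
    for s in range(1, n_sites):
        cov[f"site_{s}"] = (sites == s).astype(float)
    return cov


def build_design(
    scores: np.ndarray, pl: np.ndarray, covariates: pd.DataFrame | np.ndarray | None
) -> tuple[np.ndarray, list[str]]:
    """Assemble [1 | PC_1..P | PL^2 | PC_1..P * PL^2 | COV] with names."""
    scores = np.asarray(scores, dtype=float)
    pl = np.asarray(pl, dtype=float)
    n, p = scores.shape
    pl2 = pl**2
    blocks = [np.ones((n, 1)), scores, pl2[:, None], scores * pl2[:, None]]
    names = (
        ["intercept"]
        + [f"pc{j + 1}" for j in range(p)]
        + ["pl2"]
        + [f"pc{j + 1}:pl2" for j in range(p)]
    )
    if covariates is not None:
        cov_arr = np.asarray(covariates, dtype=float)
        cov_names = (
            list(covariates.columns)
            if isinstance(covariates, pd.DataFrame)
            else [f"cov{j + 1}" for j in range(cov_arr.shape[1])]
        )
        blocks.append(cov_arr)
        names += cov_names
    return np.hstack(blocks), names


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # Identify columns in the span of their predecessors.
        offenders = []
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) == np.linalg.matrix_rank(x[:, :j]):
                offenders.append(names[j])
        raise np.linalg.LinAlgError(
            f"singular design matrix; linearly dependent column(s): {offenders}"
        )


def fit_moderation(
    basis: PCABasis,
    pl: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    n_components: int | None = None,
    boxcox_lambda: float | None = None,
    boxcox_shift: float | None = None,
) -> ReserveFit:
    """Ordinary least squares fit of the reserve model.

    ``y`` is the (already transformed) cognitive outcome; pathological
    load enters only through its square.  Raises a singular-design error
    naming the dependent columns if the design is rank-deficient.
    """
    p = n_components if n_components is not None else basis.n_components
    if p > basis.n_components:
        raise ValueError(f"requested {p} components but basis holds {basis.n_components}")
    scores = basis.scores[:, :p]
    y = np.asarray(y, dtype=float)
    x, names = build_design(scores, pl, covariates)
    if x.shape[0] != y.size:
        raise ValueError("design and outcome lengths differ")
    _check_full_rank(x, names)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = max(x.shape[0] - x.shape[1], 1)
    resid_var = float(resid @ resid / dof)
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.clip(resid_var * np.diag(xtx_inv), 0.0, None))
    return ReserveFit(
        b0=float(beta[0]),
        b1=beta[1 : p + 1].copy(),
        b2=float(beta[p + 1]),
        b3=beta[p + 2 : 2 * p + 2].copy(),
        c=beta[2 * p + 2 :].copy(),
        covariate_names=names[2 * p + 2 :],
        residual_var=resid_var,
        n_components=p,
        se=se,
        df_resid=int(x.shape[0] - x.shape[1]),
        boxcox_lambda=boxcox_lambda,
        boxcox_shift=boxcox_shift,
    )


def select_num_components(
    stack_data: np.ndarray,
    pl: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    candidates=None,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose P by k-fold cross-validated held-out R^2.

    PCA is re-fit inside each training fold (scoring held-out subjects on
    the training basis) to keep the held-out R^2 honest.  Held-out R^2 is
    1 - SS_res / SS_tot with SS_tot about the held-out mean.  Ties are
    broken toward the smallest P.  Folds whose design is singular are
    skipped with a warning; if every fold fails the selection errors out.

    The default candidate grid is 2..9: across that range CV differences
    are typically small relative to their fold-to-fold variability, and a
    long flat grid makes plain argmax selection drift into noise-fitting
    components.  Pass an explicit ``candidates`` sequence to widen it.
    """
    data = np.asarray(stack_data, dtype=float)
    y = np.asarray(y, dtype=float)
    pl = np.asarray(pl, dtype=float)
    n = data.shape[0]
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if candidates is None:
        candidates = list(range(2, min(9, max(2, n - 2)) + 1))
    candidates = sorted(set(int(c) for c in candidates))
    max_p = max(candidates)
    cov_arr = np.asarray(covariates, dtype=float) if covariates is not None else None

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    r2 = np.full((len(candidates), n_folds), np.nan)
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        feasible = min(len(train_idx) - 1, data.shape[1])
        try:
            basis = fit_pca(data[train_idx], min(max_p, feasible))
        except ValueError:
            warnings.warn(f"fold {k}: PCA infeasible; fold skipped")
            continue
        test_scores_full = basis.project(data[test_idx])
        y_tr, y_te = y[train_idx], y[test_idx]
        ss_tot = float(((y_te - y_te.mean()) ** 2).sum())
        for ci, p in enumerate(candidates):
            if p > basis.n_components:
                continue
            cov_tr = cov_te = None
            if cov_arr is not None:
                cov_tr, cov_te = cov_arr[train_idx], cov_arr[test_idx]
            x_tr, names = build_design(basis.scores[:, :p], pl[train_idx], cov_tr)
            try:
                _check_full_rank(x_tr, names)
            except np.linalg.LinAlgError:
                warnings.warn(f"fold {k}, P={p}: singular training design; skipped")
                continue
            beta, _, _, _ = np.linalg.lstsq(x_tr, y_tr, rcond=None)
            x_te, _ = build_design(test_scores_full[:, :p], pl[test_idx], cov_te)
            resid = y_te - x_te @ beta
            r2[ci, k] = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_r2 = np.nanmean(r2, axis=1)
    if np.isnan(mean_r2).all():
        raise RuntimeError("cross-validation failed in every fold for every candidate P")
    table = pd.DataFrame({"n_components": candidates, "mean_heldout_r2": mean_r2})
    best = int(np.nanargmax(mean_r2))  # argmax returns the first (smallest P) on ties
    return candidates[best], table


def backproject(fit: ReserveFit, basis: PCABasis) -> CRPattern:
    """Voxel-space weight maps: w = b3' V, a = b1' V."""
    p = fit.n_components
    if basis.n_components < p:
        raise ValueError("basis has fewer components than the fit")
    comps = basis.components[:p]
    return CRPattern(w=fit.b3 @ comps, a=fit.b1 @ comps)


def subject_scores(pattern: CRPattern, stack: ContrastStack) -> SubjectScores:
    """CR and BAE scores: inner products of raw contrast maps with the
    moderation and additive weight maps."""
    if pattern.w.shape[0] != stack.n_voxels:
        raise ValueError("pattern and contrast stack voxel counts differ")
    return SubjectScores(
        subjects=list(stack.subjects),
        cr_score=stack.data @ pattern.w,
        bae=stack.data @ pattern.a,
    )


def standardized_coefficients(params: np.ndarray, design: np.ndarray, names: list[str], y: np.ndarray) -> pd.Series:
    """Standardized regression coefficients b_j * SD(x_j) / SD(y).

    Interaction terms are standardized on their product column.  The
    intercept and zero-variance columns are reported as missing.
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    sd_x = design.std(axis=0, ddof=1)
    sd_y = y.std(ddof=1)
    out = np.asarray(params, dtype=float) * sd_x / sd_y
    out[sd_x == 0] = np.nan
    return pd.Series(out, index=names, name="beta_std")
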