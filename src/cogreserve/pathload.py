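"""One-dimensional pathological-load (PL) score from the A/T/N panel.

The three continuous markers — CSF A-beta 42:40 ratio (A), CSF p-tau (T)
and TIV-corrected hippocampal volume (N) — are z-scored and reduced to a
single coordinate per subject, by a 1-D t-SNE embedding (default) or the
first principal component.  Because a 1-D embedding's sign is arbitrary,
the coordinate is oriented so that it increases with the p-tau z-score
(p-tau rises with pathology), then min-max rescaled so the fitting
sample spans [0, 1]: 0 = minimal, 1 = maximal pathology in the sample.

The hippocampal-atrophy fallback score rescales -(hv/TIV) to [0, 1] the
same way, for subjects without CSF measures.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "standardize_panels",
    "embed_1d",
    "orient_and_rescale",
    "atrophy_score",
    "pl_scores",
    "PLResult",
]

PANEL_COLUMNS = ("abeta_ratio", "ptau", "hv_corrected")


@dataclass
class PLResult:
    """PL scores plus the metadata needed to reproduce them."""

    scores: pd.Series  # index subject, values in [0, 1]
    method: str
    seed: int
    hyperparams: dict
    raw_coords: np.ndarray
    flipped: bool


def standardize_panels(panels: pd.DataFrame) -> np.ndarray:
    """Column-wise z-scores of (abeta_ratio, ptau, hv_corrected)."""
    missing = [c for c in PANEL_COLUMNS if c not in panels.columns]
    if missing:
        raise ValueError(f"biomarker panel missing columns: {missing}")
    x = panels.loc[:, list(PANEL_COLUMNS)].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects to standardize")
    sd = x.std(axis=0, ddof=0)
    if (sd <= 0).any():
        bad = [PANEL_COLUMNS[i] for i in np.flatnonzero(sd <= 0)]
        raise ValueError(f"zero-variance biomarker column(s): {bad}")
    return (x - x.mean(axis=0)) / sd


def embed_1d(
    z_matrix: np.ndarray,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
    max_iter: int = 1000,
) -> np.ndarray:
    """Reduce the N x 3 z-scored panel to one coordinate per subject.

    ``tsne`` uses a 1-D t-SNE with PCA initialisation; ``pca`` uses the
    first principal-component score (the linear alternative, highly
    correlated with the nonlinear embedding on realistic panels).
    Deterministic given the seed.
    """
    z = np.asarray(z_matrix, dtype=float)
    n = z.shape[0]
    if method == "pca":
        if n < 2:
            raise ValueError("need at least 2 subjects for PCA")
        return PCA(n_components=1, random_state=seed).fit_transform(z).ravel()
    if method == "tsne":
        if n < max(4, int(3 * perplexity) + 1):
            raise ValueError(
                f"n={n} too small for t-SNE with perplexity {perplexity} "
                f"(need at least {max(4, int(3 * perplexity) + 1)})"
            )
        tsne = TSNE(
            n_components=1,
            perplexity=perplexity,
            init="pca",
            random_state=seed,
            max_iter=max_iter,
            method="barnes_hut",
        )
        return tsne.fit_transform(z).ravel()
    raise ValueError(f"unknown embedding method {method!r}; use 'tsne' or 'pca'")


def orient_and_rescale(coords: np.ndarray, ptau_z: np.ndarray, abeta_z: np.ndarray) -> tuple[np.ndarray, bool]:
    """Fix the embedding's sign and rescale to [0, 1].

    The sign is chosen so the coordinate correlates positively with p-tau
    (fallback: negatively with the A-beta ratio); the rescaled score is 0
    at the sample minimum and 1 at the sample maximum.  Returns (scores,
    flipped).
    """
    coords = np.asarray(coords, dtype=float)
    if np.ptp(coords) == 0:
        raise ValueError("embedding coordinates are constant; cannot rescale")
    rho_ptau = spearmanr(coords, ptau_z).statistic
    flipped = False
    if rho_ptau < 0:
        flipped = True
    elif rho_ptau == 0:
        rho_ab = spearmanr(coords, -np.asarray(abeta_z)).statistic
        if rho_ab == 0 or np.isnan(rho_ab):
            raise ValueError("cannot orient embedding: no correlation with p-tau or A-beta")
        flipped = rho_ab < 0
    oriented = -coords if flipped else coords
    scores = (oriented - oriented.min()) / np.ptp(oriented)
    return scores, flipped


def atrophy_score(panels: pd.DataFrame) -> pd.Series:
    """Hippocampal-atrophy score: -(hv/TIV) min-max rescaled to [0, 1].

    The subject with the smallest TIV-corrected hippocampal volume gets 1.
    Invariant to jointly rescaling hv and TIV.
    """
    hv_corr = (panels["hv"] / panels["tiv"]).to_numpy(dtype=float)
    if (panels["hv"] <= 0).any() or (panels["tiv"] <= 0).any():
        raise ValueError("hippocampal and intracranial volumes must be positive")
    neg = -hv_corr
    if np.ptp(neg) == 0:
        raise ValueError("hv/TIV is constant; atrophy score undefined")
    score = (neg - neg.min()) / np.ptp(neg)
    return pd.Series(score, index=panels.index, name="atrophy")


def pl_scores(
    panels: pd.DataFrame,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
    max_iter: int = 1000,
) -> PLResult:
    """Full PL pipeline: standardize, embed to 1-D, orient, rescale."""
    z = standardize_panels(panels)
    coords = embed_1d(z, method=method, seed=seed, perplexity=perplexity, max_iter=max_iter)
    scores, flipped = orient_and_rescale(coords, ptau_z=z[:, 1], abeta_z=z[:, 0])
    return PLResult(
        scores=pd.Series(scores, index=panels.index, name="pl"),
        method=method,
        seed=seed,
        hyperparams={"perplexity": perplexity, "max_iter": max_iter} if method == "tsne" else {},
        raw_coords=coords,
        flipped=flipped,
    )


def score_new_subjects(result: PLResult, fit_z: np.ndarray, new_z: np.ndarray, k: int = 3) -> np.ndarray:
    """Out-of-sample PL by k-nearest-neighbour interpolation in z-space.

    t-SNE has no parametric out-of-sample map; new subjects receive the
    inverse-distance-weighted mean PL of their ``k`` nearest fitting-sample
    neighbours (an exact match returns that subject's score).
    """
    fit_z = np.asarray(fit_z, dtype=float)
    new_z = np.atleast_2d(np.asarray(new_z, dtype=float))
    fit_scores = result.scores.to_numpy()
    out = np.empty(new_z.shape[0])
    for i, row in enumerate(new_z):
        d = np.linalg.norm(fit_z - row, axis=1)
        nearest = np.argsort(d)[:k]
        if d[nearest[0]] == 0:
            out[i] = fit_scores[nearest[0]]
        else:
            w = 1.0 / d[nearest]
            out[i] = float(np.average(fit_scores[nearest], weights=w))
    return out
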