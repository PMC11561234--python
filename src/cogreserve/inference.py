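"""Bootstrap voxelwise inference on the moderation weight map and cluster
descriptives.

Subjects are resampled with replacement; the reserve-model coefficients are
re-estimated on each resample against the *fixed* full-sample PCA basis
(re-fitting the basis would misalign component signs and order across
iterations), and the moderation coefficients are back-projected to voxel
space.  Per voxel, the B resampled weights are sorted ascending and the
confidence bounds read off at fixed order-statistic positions; a voxel is
significant when its interval excludes zero.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import BootstrapResult, PCABasis, TaskActiveMask
from .reserve import build_design, _check_full_rank

__all__ = [
    "ci_indices",
    "bootstrap_pattern",
    "voxel_ci_significance",
    "label_clusters",
    "cluster_stats",
    "cluster_table",
]

MIN_CLUSTER_SIZE = 50  # voxels; smaller clusters are omitted from reports


def ci_indices(n_boot: int, level: float = 0.95) -> tuple[int, int]:
    """1-based order-statistic positions of the bootstrap CI bounds.

    Lower bound: floor((1-level)/2 * B) + 1 (the value just above the lower
    tail); upper bound: ceil((1+level)/2 * B), which reduces to
    (1+level)/2 * B when that position is integral.  For B = 5000 at the
    95% level this gives (126, 4875).
    """
    alpha_half = (1.0 - level) / 2.0
    if n_boot * alpha_half < 1.0 - 1e-9:
        raise ValueError(f"B={n_boot} too small for a {level:.0%} interval")

    def _snap(x: float) -> float:
        # guard against float error at integral order-statistic positions
        return round(x) if abs(x - round(x)) < 1e-9 else x

    lo = int(np.floor(_snap(alpha_half * n_boot))) + 1
    hi = int(np.ceil(_snap((1.0 - alpha_half) * n_boot)))
    return lo, hi


def bootstrap_pattern(
    basis: PCABasis,
    pl: np.ndarray,
    y: np.ndarray,
    covariates,
    n_components: int,
    n_boot: int,
    seed: int,
    level: float = 0.95,
    max_redraw_fraction: float = 0.10,
) -> BootstrapResult:
    """Bootstrap the voxel moderation-weight map.

    Resamples with a singular design are redrawn (keeping B exact); more
    than ``max_redraw_fraction * B`` redraws aborts with an error.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    pl = np.asarray(pl, dtype=float)
    y = np.asarray(y, dtype=float)
    scores = basis.scores[:, :n_components]
    comps = basis.components[:n_components]
    cov_arr = np.asarray(covariates, dtype=float) if covariates is not None else None
    n = y.size
    rng = np.random.default_rng(seed)
    b3_hat = np.empty((n_boot, n_components))
    n_redrawn = 0
    max_redraws = int(np.ceil(max_redraw_fraction * n_boot))
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        cov_b = cov_arr[idx] if cov_arr is not None else None
        x, names = build_design(scores[idx], pl[idx], cov_b)
        try:
            _check_full_rank(x, names)
        except np.linalg.LinAlgError:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    f"more than {max_redraw_fraction:.0%} of bootstrap resamples "
                    "had singular designs"
                )
            continue
        beta, _, _, _ = np.linalg.lstsq(x, y[idx], rcond=None)
        b3_hat[b] = beta[n_components + 2 : 2 * n_components + 2]
        b += 1
    w_hat = b3_hat @ comps
    lower, upper, significant = voxel_ci_significance(w_hat, level)
    return BootstrapResult(
        w_hat=w_hat,
        n_boot=n_boot,
        seed=seed,
        level=level,
        ci_lower=lower,
        ci_upper=upper,
        significant=significant,
        n_redrawn=n_redrawn,
    )


def voxel_ci_significance(w_hat: np.ndarray, level: float = 0.95):
    """Per-voxel CI bounds and significance from the resampled weights.

    Each voxel's column is sorted ascending and the bounds taken at the
    ``ci_indices`` positions; a voxel is significant iff 0 lies outside
    [lower, upper].
    """
    w_hat = np.asarray(w_hat, dtype=float)
    if not np.isfinite(w_hat).all():
        raise ValueError("bootstrap weights contain non-finite values")
    lo_idx, hi_idx = ci_indices(w_hat.shape[0], level)
    w_sorted = np.sort(w_hat, axis=0)
    lower = w_sorted[lo_idx - 1]
    upper = w_sorted[hi_idx - 1]
    significant = (lower > 0) | (upper < 0)
    return lower, upper, significant


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_clusters(
    significant: np.ndarray,
    w: np.ndarray,
    mask: TaskActiveMask,
    connectivity: int = 26,
    min_size: int = MIN_CLUSTER_SIZE,
) -> list[np.ndarray]:
    """Connected components of significant voxels, sign-homogeneous.

    Positive-weight and negative-weight significant voxels are labeled
    separately (clusters are reported with a signed mean weight, so mixing
    signs inside one component would be meaningless).  Components smaller
    than ``min_size`` voxels are dropped.  Returns a list of linear-index
    arrays into the mask's voxel ordering.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    significant = np.asarray(significant, dtype=bool)
    w = np.asarray(w, dtype=float)
    structure = _STRUCTURES[connectivity]
    clusters: list[np.ndarray] = []
    lin_of_voxel = np.full(mask.grid.shape, -1, dtype=int)
    lin_of_voxel[mask.grid] = np.arange(mask.n_voxels)
    for sign in (1, -1):
        vol = mask.unmask(significant & (np.sign(w) == sign)).astype(bool)
        labels, n_found = ndimage.label(vol, structure=structure)
        for lab in range(1, n_found + 1):
            linear = lin_of_voxel[labels == lab]
            if linear.size >= min_size:
                clusters.append(np.sort(linear))
    # Largest first for stable reporting.
    clusters.sort(key=lambda c: -c.size)
    return clusters


def cluster_stats(
    cluster: np.ndarray,
    w: np.ndarray,
    group_sm_mean: np.ndarray,
    mask: TaskActiveMask,
    affine: np.ndarray | None = None,
) -> dict:
    """Descriptives for one cluster.

    ``percent_concordant`` is the share of cluster voxels whose moderation
    weight has the same sign as the group-mean subsequent-memory contrast
    there; voxels with a zero group mean count as discordant.  The peak is
    the voxel of maximal |w|, reported in grid and (if an affine is given)
    mm coordinates.
    """
    cluster = np.asarray(cluster, dtype=int)
    if cluster.size == 0:
        raise ValueError("empty cluster")
    w_c = np.asarray(w, dtype=float)[cluster]
    gm_c = np.asarray(group_sm_mean, dtype=float)[cluster]
    concordant = (np.sign(w_c) == np.sign(gm_c)) & (gm_c != 0)
    peak_local = int(np.argmax(np.abs(w_c)))
    peak_ijk = mask.ijk()[cluster[peak_local]]
    row = {
        "size": int(cluster.size),
        "mean_w": float(w_c.mean()),
        "peak_i": int(peak_ijk[0]),
        "peak_j": int(peak_ijk[1]),
        "peak_k": int(peak_ijk[2]),
        "percent_concordant": float(100.0 * concordant.mean()),
    }
    if affine is not None:
        mm = affine @ np.array([*peak_ijk, 1.0])
        row.update(peak_x_mm=float(mm[0]), peak_y_mm=float(mm[1]), peak_z_mm=float(mm[2]))
    return row


def cluster_table(
    significant: np.ndarray,
    w: np.ndarray,
    group_sm_mean: np.ndarray,
    mask: TaskActiveMask,
    affine: np.ndarray | None = None,
    connectivity: int = 26,
    min_size: int = MIN_CLUSTER_SIZE,
) -> pd.DataFrame:
    """Label clusters and compute one descriptive row per cluster."""
    clusters = label_clusters(significant, w, mask, connectivity, min_size)
    rows = []
    for cid, cluster in enumerate(clusters, start=1):
        row = {"cluster_id": cid}
        row.update(cluster_stats(cluster, w, group_sm_mean, mask, affine))
        rows.append(row)
    columns = ["cluster_id", "size", "mean_w", "peak_i", "peak_j", "peak_k", "percent_concordant"]
    if affine is not None:
        columns += ["peak_x_mm", "peak_y_mm", "peak_z_mm"]
    return pd.DataFrame(rows, columns=columns)
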