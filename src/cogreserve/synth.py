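"""Synthetic cohort generator with known ground truth.

Generates every data stream the reserve analysis consumes — phenotypes,
ATN biomarkers, behavioural/motion QC data, subsequent-memory contrast
maps and longitudinal cognition — from a latent per-subject disease
severity and a planted voxel-level reserve pattern, so that each pipeline
stage can be checked against the quantity it is supposed to recover.

Construction of the contrast maps: subject i's map is

    beta_i = mean_map + expression_i * w_star / ||w_star||^2
             + sum_k z_ik * nuisance_k + noise

with the nuisance components orthonormal to the reserve pattern and
``expression`` mean-centered, so that with zero map noise the inner product
of ``w_star`` with the subject's mean-centered map returns ``expression``
exactly.  Cognition follows the quadratic-pathology moderation model with
``severity`` standing in for the pathological-load score.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import GeneratorConfig, stage_seed
from .datatypes import ContrastStack, TaskActiveMask

__all__ = [
    "SyntheticTruth",
    "BehaviorMotionTable",
    "CohortBundle",
    "simulate_cohort",
    "simulate_biomarkers",
    "simulate_contrasts",
    "simulate_longitudinal",
    "simulate_behavior_motion",
    "make_task_mask",
]

# Far-offset added to planted voxel-outlier subjects; large enough to sit
# outside Q3 + 3*IQR of any realistically generated voxel distribution.
_R4_OFFSET = 50.0


@dataclass
class SyntheticTruth:
    """Ground truth planted into a synthetic cohort."""

    severity: np.ndarray  # (N,), in [0, 1]
    expression: np.ndarray  # (N,), mean-centered
    w_star: np.ndarray  # (V,), zero outside the mask by construction
    mask: TaskActiveMask
    mean_map: np.ndarray  # (V,)
    nuisance_components: np.ndarray  # (K-1, V), orthonormal, _|_ w_star
    nuisance_scores: np.ndarray  # (N, K-1), mean-centered
    atrophy: np.ndarray  # (N,), [0, 1], from the generated panels
    coef: "object"  # CoefTruth
    stage_seeds: dict[str, int]
    qc_fail_sets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def w_star_unit(self) -> np.ndarray:
        return self.w_star / np.linalg.norm(self.w_star)


@dataclass
class BehaviorMotionTable:
    """Behavioural and head-motion QC data for a cohort.

    ``scalars`` holds one row per subject (io_errors); ``ratings`` and
    ``motion`` map subject id to the per-item confidence ratings (ints 1..5)
    and the T x 6 motion-parameter series (3 translations in mm, 3
    rotations in radians).
    """

    scalars: pd.DataFrame
    ratings: dict[str, np.ndarray]
    motion: dict[str, np.ndarray]


@dataclass
class CohortBundle:
    """Everything the generator produces for one cohort."""

    config: GeneratorConfig
    phenotypes: pd.DataFrame
    biomarkers: pd.DataFrame
    behavior: BehaviorMotionTable
    contrasts: ContrastStack
    visits: pd.DataFrame
    truth: SyntheticTruth


def _subject_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"sub-{i:0{width}d}" for i in range(1, n + 1)]


def make_task_mask(grid_shape: tuple[int, int, int], mask_fraction: float) -> TaskActiveMask:
    """Central ellipsoidal task-active region covering exactly
    ``round(mask_fraction * n_voxels)`` voxels (ties broken by C-order)."""
    shape = tuple(int(s) for s in grid_shape)
    n_total = int(np.prod(shape))
    n_mask = int(round(mask_fraction * n_total))
    n_mask = max(1, min(n_mask, n_total))
    coords = np.indices(shape, dtype=float)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    r2 = np.zeros(shape)
    for ax in range(3):
        half = max(shape[ax] / 2.0, 1.0)
        r2 += ((coords[ax] - center[ax]) / half) ** 2
    order = np.argsort(r2.ravel(), kind="stable")
    grid = np.zeros(n_total, dtype=bool)
    grid[order[:n_mask]] = True
    return TaskActiveMask(grid.reshape(shape))


def _blob_map(config: GeneratorConfig, mask: TaskActiveMask) -> np.ndarray:
    """Signed Gaussian-blob pattern inside the mask, as a length-V vector."""
    shape = config.grid_shape
    full = np.zeros(shape)
    coords = np.indices(shape, dtype=float)
    for blob in config.w_star_blobs:
        c = [blob.center[ax] * (shape[ax] - 1) for ax in range(3)]
        d2 = sum((coords[ax] - c[ax]) ** 2 for ax in range(3))
        full += blob.amplitude * np.exp(-d2 / (2.0 * blob.sigma**2))
    return full[mask.grid]


def _smooth_random_map(rng: np.random.Generator, shape, mask: TaskActiveMask, fwhm_vox: float = 2.0) -> np.ndarray:
    raw = rng.standard_normal(shape)
    smooth = gaussian_filter(raw, sigma=fwhm_vox)
    vals = smooth[mask.grid]
    return vals / (vals.std() + 1e-12)


def simulate_biomarkers(severity: np.ndarray, noise_sd: float, seed: int) -> pd.DataFrame:
    """Generate the A/T/N biomarker panel from latent severity.

    Before noise, the CSF A-beta 42:40 ratio decreases strictly with
    severity, CSF p-tau increases, and the TIV-corrected hippocampal volume
    decreases.  ``noise_sd`` is a fraction of each marker's signal SD.
    """
    severity = np.asarray(severity, dtype=float)
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    if severity.min() < 0 or severity.max() > 1:
        raise ValueError("severity values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = severity.size

    def noisy(signal: np.ndarray) -> np.ndarray:
        scale = noise_sd * signal.std()
        return signal + rng.normal(0.0, scale, size=n) if scale > 0 else signal.copy()

    abeta = noisy(0.10 - 0.06 * severity)
    ptau = noisy(15.0 + 70.0 * severity)
    hv_corr = noisy(0.0062 - 0.0022 * severity)
    tiv = rng.normal(1.55e6, 1.4e5, size=n).clip(1.0e6, 2.2e6)
    return pd.DataFrame(
        {
            "abeta_ratio": abeta,
            "ptau": ptau,
            "hv": hv_corr * tiv,
            "tiv": tiv,
            "hv_corrected": hv_corr,
        }
    )


def _latent_structure(config: GeneratorConfig, mask: TaskActiveMask, seed: int):
    """Mean map, unit reserve pattern and orthonormal nuisance components."""
    rng = np.random.default_rng(seed)
    v = mask.n_voxels
    if config.n_latent > v:
        raise ValueError(f"n_latent={config.n_latent} exceeds mask voxel count {v}")
    mean_map = 0.6 * _smooth_random_map(rng, config.grid_shape, mask, fwhm_vox=3.0)
    blob = _blob_map(config, mask)
    u0 = blob / np.linalg.norm(blob)
    nuisance = []
    for _ in range(config.n_latent - 1):
        cand = _smooth_random_map(rng, config.grid_shape, mask, fwhm_vox=2.0)
        # Gram-Schmidt against the reserve pattern and earlier components.
        cand = cand - (cand @ u0) * u0
        for q in nuisance:
            cand = cand - (cand @ q) * q
        cand /= np.linalg.norm(cand)
        nuisance.append(cand)
    nuisance_arr = np.asarray(nuisance).reshape(config.n_latent - 1, v)
    return mean_map, u0, nuisance_arr


def simulate_contrasts(truth: SyntheticTruth, config: GeneratorConfig) -> ContrastStack:
    """Assemble subject contrast maps from the planted latent structure."""
    n = config.n_subjects
    rng = np.random.default_rng(truth.stage_seeds["contrast_noise"])
    s = config.pattern_strength
    data = np.tile(truth.mean_map, (n, 1))
    data += np.outer(truth.expression, s * truth.w_star_unit)
    if truth.nuisance_components.size:
        data += truth.nuisance_scores @ truth.nuisance_components
    if config.noise_sd.contrast > 0:
        data += rng.normal(0.0, config.noise_sd.contrast, size=data.shape)
    subjects = _subject_ids(n)
    # Planted voxel-outlier (rule 4) subjects: blow up 15% of mask voxels.
    for sid in truth.qc_fail_sets.get("r4_voxel_outliers", []):
        i = subjects.index(sid)
        n_bad = int(round(0.15 * truth.mask.n_voxels))
        bad = rng.choice(truth.mask.n_voxels, size=n_bad, replace=False)
        data[i, bad] += _R4_OFFSET
    affine = np.diag([3.5, 3.5, 3.5, 1.0])
    return ContrastStack(subjects=subjects, mask=truth.mask, data=data, affine=affine)


def simulate_behavior_motion(config: GeneratorConfig) -> BehaviorMotionTable:
    """Behavioural and motion QC data with planted exclusion-rule failures.

    Planted counts are exact: ``round(fraction * n_subjects)`` subjects per
    rule, drawn disjointly.  Rule-1 failures exceed 8 indoor/outdoor
    errors; rule-2 failures rate nearly everything 5 (response bias > 1.5);
    rule-3 failures carry a single 3.5 mm translation spike (framewise
    displacement > 0.5 mm).
    """
    truth_sets = _assign_qc_failures(config)
    return _behavior_motion_from_sets(config, truth_sets)


def _assign_qc_failures(config: GeneratorConfig) -> dict[str, list[str]]:
    rng = np.random.default_rng(stage_seed(config.seed, "qc_assignment"))
    subjects = _subject_ids(config.n_subjects)
    perm = rng.permutation(config.n_subjects)
    fracs = {
        "r1_errors": config.qc_fail_fractions.r1_errors,
        "r2_bias": config.qc_fail_fractions.r2_bias,
        "r3_motion": config.qc_fail_fractions.r3_motion,
        "r4_voxel_outliers": config.qc_fail_fractions.r4_voxel_outliers,
    }
    sets: dict[str, list[str]] = {}
    pos = 0
    for rule, frac in fracs.items():
        k = int(round(frac * config.n_subjects))
        sets[rule] = sorted(subjects[i] for i in perm[pos : pos + k])
        pos += k
    return sets


def _behavior_motion_from_sets(
    config: GeneratorConfig, fail_sets: dict[str, list[str]]
) -> BehaviorMotionTable:
    rng = np.random.default_rng(stage_seed(config.seed, "behavior"))
    subjects = _subject_ids(config.n_subjects)
    r1 = set(fail_sets.get("r1_errors", []))
    r2 = set(fail_sets.get("r2_bias", []))
    r3 = set(fail_sets.get("r3_motion", []))
    io_errors = []
    ratings: dict[str, np.ndarray] = {}
    motion: dict[str, np.ndarray] = {}
    t = config.n_volumes
    for sid in subjects:
        io_errors.append(9 + rng.poisson(2.0) if sid in r1 else int(rng.binomial(8, 0.25)))
        if sid in r2:
            r = np.where(rng.random(config.n_task_items) < 0.95, 5, 4)
        else:
            r = np.clip(np.rint(rng.normal(3.0, 1.2, size=config.n_task_items)), 1, 5)
        ratings[sid] = r.astype(int)
        steps = np.concatenate(
            [
                rng.normal(0.0, 0.02, size=(t - 1, 3)),  # translations, mm
                rng.normal(0.0, 4e-4, size=(t - 1, 3)),  # rotations, rad
            ],
            axis=1,
        )
        if sid in r3:
            spike_at = int(rng.integers(0, t - 1))
            steps[spike_at, 0] += 3.5
        motion[sid] = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    scalars = pd.DataFrame({"subject": subjects, "io_errors": io_errors}).set_index("subject")
    return BehaviorMotionTable(scalars=scalars, ratings=ratings, motion=motion)


def simulate_longitudinal(
    phenotypes: pd.DataFrame, truth: SyntheticTruth, config: GeneratorConfig
) -> pd.DataFrame:
    """Per-visit cognition table.

    PACC5 at time t is ``baseline + slope * t`` plus subject random
    intercept/slope and visit noise, where the yearly slope is
    ``g0 + g_atrophy * atrophy^2 + g_threeway * expression * atrophy^2``:
    positive ``g_threeway`` means pattern expression attenuates the
    atrophy-related decline.
    """
    if config.n_visits < 2:
        raise ValueError("n_visits must be at least 2 for slope identification")
    rng = np.random.default_rng(truth.stage_seeds["longitudinal"])
    n = config.n_subjects
    coef = truth.coef
    atr2 = truth.atrophy**2
    slope = coef.g0 + coef.g_atrophy * atr2 + coef.g_threeway * truth.expression * atr2
    u0 = rng.normal(0.0, config.noise_sd.rand_intercept, size=n)
    u1 = rng.normal(0.0, config.noise_sd.rand_slope, size=n)
    baseline = phenotypes["pacc5_latent"].to_numpy()
    rows = []
    subjects = phenotypes.index.to_numpy()
    for j in range(config.n_visits):
        t = j * config.visit_interval
        eps = rng.normal(0.0, config.noise_sd.visit, size=n) if config.noise_sd.visit > 0 else 0.0
        pacc5 = baseline + (slope + u1) * t + u0 + eps
        rows.append(
            pd.DataFrame(
                {"subject": subjects, "visit": j, "time_years": t, "pacc5": pacc5}
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Generate a complete synthetic cohort; deterministic given the seed."""
    seeds = {name: stage_seed(config.seed, name) for name in (
        "severity", "expression", "phenotypes", "biomarkers",
        "contrast_components", "contrast_noise", "cognition",
        "longitudinal", "behavior",
    )}
    n = config.n_subjects
    subjects = _subject_ids(n)
    coef = config.coef_truth

    severity = np.random.default_rng(seeds["severity"]).uniform(0.0, 1.0, size=n)

    rng_expr = np.random.default_rng(seeds["expression"])
    expression = rng_expr.normal(0.0, config.expression_sd, size=n)
    expression -= expression.mean()
    n_nuis = config.n_latent - 1
    nuisance_scores = rng_expr.normal(0.0, config.nuisance_score_sd, size=(n, n_nuis))
    if n_nuis:
        nuisance_scores -= nuisance_scores.mean(axis=0)

    biomarkers = simulate_biomarkers(severity, config.noise_sd.biomarker, seeds["biomarkers"])
    biomarkers.index = pd.Index(subjects, name="subject")
    hv_corr = biomarkers["hv_corrected"].to_numpy()
    rng_hv = -hv_corr
    atrophy = (rng_hv - rng_hv.min()) / (rng_hv.max() - rng_hv.min())

    rng_ph = np.random.default_rng(seeds["phenotypes"])
    age = rng_ph.normal(69.7, 5.6, size=n).clip(55.0, 92.0)
    sex = (rng_ph.random(n) < 0.53).astype(int)  # 1 = female
    site = rng_ph.integers(0, config.n_sites, size=n)
    # Education tracks pattern expression with the configured correlation.
    z_expr = (expression - expression.mean()) / (expression.std() + 1e-12)
    edu_noise = rng_ph.standard_normal(n)
    edu_noise = (edu_noise - edu_noise.mean()) / (edu_noise.std() + 1e-12)
    edu_z = config.edu_corr * z_expr + np.sqrt(1.0 - config.edu_corr**2) * edu_noise
    education = 14.6 + 2.9 * edu_z

    mask = make_task_mask(config.grid_shape, config.mask_fraction)
    mean_map, u0_map, nuisance = _latent_structure(config, mask, seeds["contrast_components"])
    w_star = u0_map / config.pattern_strength

    rng_y = np.random.default_rng(seeds["cognition"])
    tiv = biomarkers["tiv"].to_numpy()
    cov_effect = (
        coef.c_age * (age - age.mean())
        + coef.c_sex * sex
        + coef.c_tiv * (tiv - tiv.mean())
        + np.asarray(coef.site_offsets)[site]
    )
    add_effect = coef.b1 * nuisance_scores[:, 0] if n_nuis else 0.0
    latent = (
        coef.b0
        + add_effect
        + coef.b2 * severity**2
        + coef.moderation * expression * severity**2
        + cov_effect
    )
    y_noise = rng_y.normal(0.0, config.noise_sd.cognition, size=n) if config.noise_sd.cognition > 0 else 0.0
    pacc5 = latent + y_noise

    phenotypes = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "site": site,
            "education": education,
            "tiv": tiv,
            "pacc5": pacc5,
            "pacc5_latent": latent,
            "severity": severity,
        },
        index=pd.Index(subjects, name="subject"),
    )

    qc_fail_sets = _assign_qc_failures(config)
    truth = SyntheticTruth(
        severity=severity,
        expression=expression,
        w_star=w_star,
        mask=mask,
        mean_map=mean_map,
        nuisance_components=nuisance,
        nuisance_scores=nuisance_scores,
        atrophy=atrophy,
        coef=coef,
        stage_seeds=seeds,
        qc_fail_sets=qc_fail_sets,
    )
    contrasts = simulate_contrasts(truth, config)
    behavior = _behavior_motion_from_sets(config, qc_fail_sets)
    visits = simulate_longitudinal(phenotypes, truth, config)
    return CohortBundle(
        config=config,
        phenotypes=phenotypes,
        biomarkers=biomarkers,
        behavior=behavior,
        contrasts=contrasts,
        visits=visits,
        truth=truth,
    )
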