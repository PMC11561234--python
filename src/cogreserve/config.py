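"""Configuration objects for the synthetic-cohort generator and pipeline runs.

The generator emulates the statistical structure the reserve analysis
assumes: three ATN biomarkers monotone in a latent disease severity,
subsequent-memory contrast maps composed of a group-mean pattern plus latent
components (one of which is the planted reserve pattern), cognition following
the quadratic pathology model with an activity-pattern moderation term, and
longitudinal decline whose atrophy dependence is attenuated by pattern
expression.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass(frozen=True)
class Blob:
    """A Gaussian-profile signed blob of the planted reserve pattern.

    ``center`` is in fractional grid coordinates (0..1 per axis), ``sigma``
    in voxels, ``amplitude`` signed (positive = reserve-supporting
    activation, negative = reserve-supporting deactivation).
    """

    center: tuple[float, float, float]
    sigma: float
    amplitude: float


#: Default layout: two positive "inferior-temporal-like" blobs and one
#: negative "precuneus-like" blob inside the task-active region.
DEFAULT_BLOBS: tuple[Blob, ...] = (
    Blob((0.35, 0.30, 0.40), 2.0, 1.0),
    Blob((0.65, 0.30, 0.40), 2.0, 1.0),
    Blob((0.50, 0.68, 0.55), 2.5, -1.0),
)


@dataclass(frozen=True)
class CoefTruth:
    """Planted model coefficients.

    Cross-sectional cognition is generated as::

        y = b0 + b1 * nuisance_score_1 + b2 * severity**2
            + moderation * expression * severity**2
            + c_age*(age-mean) + c_sex*sex + c_tiv*(tiv-mean) + site offsets
            + noise

    ``b1`` acts on the score of the first nuisance latent component, so the
    additive brain-activity effect (BAE) has a spatial pattern distinct from
    the reserve pattern.  Longitudinal decline per year is
    ``g0 + g_atrophy*atrophy**2 + g_threeway*expression*atrophy**2``.
    """

    b0: float = 0.2
    b1: float = 0.03
    b2: float = -2.0
    moderation: float = 1.0
    c_age: float = -0.02
    c_sex: float = 0.1
    c_tiv: float = 2.0e-7
    site_offsets: tuple[float, ...] = (0.0, 0.15)
    g0: float = -0.05
    g_atrophy: float = -0.4
    g_threeway: float = 0.25


@dataclass(frozen=True)
class NoiseSD:
    """Per-channel noise scales.

    ``biomarker`` is a fraction of each marker's signal SD; ``contrast`` is
    the per-voxel SD of i.i.d. map noise; ``cognition`` and ``visit`` are on
    the PACC5 scale; ``rand_intercept``/``rand_slope`` are the SDs of the
    subject random effects in the longitudinal model.
    """

    biomarker: float = 0.2
    contrast: float = 1.0
    cognition: float = 0.3
    visit: float = 0.2
    rand_intercept: float = 0.3
    rand_slope: float = 0.03


@dataclass(frozen=True)
class QCFailFractions:
    """Planted fractions of subjects violating each exclusion rule."""

    r1_errors: float = 0.02
    r2_bias: float = 0.02
    r3_motion: float = 0.02
    r4_voxel_outliers: float = 0.02

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.r1_errors, self.r2_bias, self.r3_motion, self.r4_voxel_outliers)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Defaults describe the study conditions used throughout the test suite:
    300 subjects on a 20x20x20 grid (~3000 task-active voxels), four latent
    contrast components, moderate noise everywhere, education correlated 0.3
    with reserve-pattern expression, and four roughly annual visits.
    """

    n_subjects: int = 300
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    mask_fraction: float = 0.375
    n_latent: int = 4
    w_star_blobs: tuple[Blob, ...] = DEFAULT_BLOBS
    pattern_strength: float = 10.0
    nuisance_score_sd: float = 10.0
    expression_sd: float = 1.0
    coef_truth: CoefTruth = field(default_factory=CoefTruth)
    noise_sd: NoiseSD = field(default_factory=NoiseSD)
    edu_corr: float = 0.3
    n_visits: int = 4
    visit_interval: float = 1.1
    qc_fail_fractions: QCFailFractions = field(default_factory=QCFailFractions)
    n_sites: int = 2
    n_task_items: int = 88
    n_volumes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be a positive 3-tuple, got {self.grid_shape}")
        if not 0.0 < self.mask_fraction < 1.0:
            raise ValueError(f"mask_fraction must lie in (0, 1), got {self.mask_fraction}")
        if self.n_latent < 1:
            raise ValueError(f"n_latent must be positive, got {self.n_latent}")
        for name in ("biomarker", "contrast", "cognition", "visit", "rand_intercept", "rand_slope"):
            if getattr(self.noise_sd, name) < 0:
                raise ValueError(f"noise_sd.{name} must be non-negative")
        if not -1.0 < self.edu_corr < 1.0:
            raise ValueError(f"edu_corr must lie in (-1, 1), got {self.edu_corr}")
        if self.n_visits < 2:
            raise ValueError(f"n_visits must be at least 2 (no slope identifiable), got {self.n_visits}")
        fracs = self.qc_fail_fractions.as_tuple()
        if any(f < 0 for f in fracs) or sum(fracs) >= 1.0:
            raise ValueError("qc_fail_fractions must be non-negative and sum to < 1")
        if len(self.coef_truth.site_offsets) != self.n_sites:
            raise ValueError("coef_truth.site_offsets must have one entry per site")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "w_star_blobs" in d:
            d["w_star_blobs"] = tuple(
                b if isinstance(b, Blob) else Blob(tuple(b["center"]), b["sigma"], b["amplitude"])
                for b in d["w_star_blobs"]
            )
        for key, klass in (("coef_truth", CoefTruth), ("noise_sd", NoiseSD), ("qc_fail_fractions", QCFailFractions)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "coef_truth" and "site_offsets" in sub:
                    sub["site_offsets"] = tuple(sub["site_offsets"])
                d[key] = klass(**sub)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


# Fixed per-stage offsets added to the master seed, so any stage can be
# re-generated in isolation and stays reproducible when other stages change.
STAGE_SEED_OFFSETS: dict[str, int] = {
    "severity": 11,
    "expression": 23,
    "phenotypes": 37,
    "biomarkers": 51,
    "contrast_components": 67,
    "contrast_noise": 83,
    "cognition": 101,
    "longitudinal": 127,
    "behavior": 149,
    "qc_assignment": 173,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive the sub-stream seed for a named generation stage."""
    if stage not in STAGE_SEED_OFFSETS:
        raise KeyError(f"unknown generation stage: {stage!r}")
    return (int(master_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)
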