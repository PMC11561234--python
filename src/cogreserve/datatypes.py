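"""Shared in-memory containers for the reserve pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class TaskActiveMask:
    """Boolean 3-D grid of task-active voxels with its linear indexing.

    Linear voxel order is C-order over the grid restricted to True voxels,
    i.e. ``np.flatnonzero(grid.ravel())``.
    """

    grid: np.ndarray  # bool, 3-D

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if not self.grid.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def linear_indices(self) -> np.ndarray:
        return np.flatnonzero(self.grid.ravel())

    def ijk(self) -> np.ndarray:
        """(V, 3) integer grid coordinates of masked voxels, in linear order."""
        return np.argwhere(self.grid)

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a length-V vector back onto the full 3-D grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError("value length does not match mask voxel count")
        out = np.full(self.grid.shape, fill, dtype=float)
        out[self.grid] = values
        return out


@dataclass
class ContrastStack:
    """Subject x voxel matrix of subsequent-memory contrast values.

    ``data[i, j]`` is subject ``subjects[i]``'s beta at the mask's j-th
    voxel.  All subjects share one mask and one grid geometry.
    """

    subjects: list[str]
    mask: TaskActiveMask
    data: np.ndarray  # (N, V)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("contrast data must be 2-D (subjects x voxels)")
        if self.data.shape != (len(self.subjects), self.mask.n_voxels):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"({len(self.subjects)} subjects, {self.mask.n_voxels} mask voxels)"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("contrast data contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_voxels(self) -> int:
        return self.mask.n_voxels

    def subset(self, keep_ids: Sequence[str]) -> "ContrastStack":
        """Row-subset by subject id, preserving the stack's sorted order."""
        keep = set(keep_ids)
        rows = [i for i, s in enumerate(self.subjects) if s in keep]
        return ContrastStack(
            subjects=[self.subjects[i] for i in rows],
            mask=self.mask,
            data=self.data[rows],
            affine=self.affine,
        )


@dataclass
class PCABasis:
    """Principal-component basis of mean-centered contrast maps.

    ``components`` rows are orthonormal eigen-images; ``scores`` are the
    projections of centered subject maps onto them (mean-zero columns).
    """

    mean_map: np.ndarray  # (V,)
    components: np.ndarray  # (P, V)
    scores: np.ndarray  # (N, P)
    explained_variance: np.ndarray  # (P,)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, data: np.ndarray) -> np.ndarray:
        """Score new subject maps (rows) against this basis."""
        return (np.asarray(data, dtype=float) - self.mean_map) @ self.components.T


@dataclass
class ReserveFit:
    """Fitted multivariate reserve (moderation) model.

    Design column order: [intercept | PC_1..P | PL^2 | PC_1..P * PL^2 |
    covariates].  ``b1`` are the additive activity coefficients, ``b2`` the
    pathology main effect, ``b3`` the moderation coefficients.
    """

    b0: float
    b1: np.ndarray  # (P,)
    b2: float
    b3: np.ndarray  # (P,)
    c: np.ndarray  # covariate coefficients
    covariate_names: list[str]
    residual_var: float
    n_components: int
    se: np.ndarray | None = None  # standard errors, aligned with ``params``
    df_resid: int | None = None
    boxcox_lambda: float | None = None
    boxcox_shift: float | None = None
    cv_table: pd.DataFrame | None = None

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.b0], self.b1, [self.b2], self.b3, self.c])


@dataclass
class CRPattern:
    """Voxel-space weight maps back-projected from the component fit."""

    w: np.ndarray  # (V,) moderation weights
    a: np.ndarray  # (V,) additive-activity weights


@dataclass
class SubjectScores:
    """Per-subject pattern-expression scores.

    ``cr_score[i] = sum_j w[j] * beta[i, j]`` over mask voxels; ``bae``
    aggregates the additive map the same way.
    """

    subjects: list[str]
    cr_score: np.ndarray
    bae: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": self.subjects, "cr_score": self.cr_score, "bae": self.bae}
        )


@dataclass
class BootstrapResult:
    """Voxelwise bootstrap of the moderation weight map."""

    w_hat: np.ndarray  # (B, V)
    n_boot: int
    seed: int
    level: float
    ci_lower: np.ndarray  # (V,)
    ci_upper: np.ndarray  # (V,)
    significant: np.ndarray  # (V,) bool
    n_redrawn: int = 0
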