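"""Behavioural/motion quality control, the parametric modulator, the PACC5
composite and the outcome transformation.

Exclusion rules (a subject is excluded if any rule's statistic *strictly*
exceeds its threshold):

R1  more than 8 errors in the indoor/outdoor judgment;
R2  absolute response bias > 1.5 on the 5-point confidence scale
    (bias defined as mean rating minus the scale midpoint 3);
R3  framewise displacement > 0.5 mm in any single volume, or > 0.2 mm in
    more than 2% of volumes;
R4  extreme-outlier beta values (outside Q1 - 3*IQR or Q3 + 3*IQR computed
    across subjects per voxel) in more than 10% of masked voxels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ContrastStack
from .synth import BehaviorMotionTable

__all__ = [
    "arcsine_modulator",
    "framewise_displacement",
    "response_bias",
    "voxel_outlier_fraction",
    "apply_exclusion_rules",
    "compose_pacc5",
    "boxcox_transform",
    "iqr_bounds",
    "ExclusionReport",
]

R1_ERROR_THRESHOLD = 8
R2_BIAS_THRESHOLD = 1.5
R3_FD_SINGLE_MM = 0.5
R3_FD_SUSTAINED_MM = 0.2
R3_SUSTAINED_FRACTION = 0.02
R4_VOXEL_FRACTION = 0.10
R4_IQR_FACTOR = 3.0
DEFAULT_ROT_RADIUS_MM = 50.0


def arcsine_modulator(x) -> np.ndarray | float:
    """Parametric subsequent-memory modulator arcsin((x - 3) / 2) * 2 / pi.

    Maps a 5-point recognition-confidence rating to [-1, 1], odd-symmetric
    about the midpoint 3 and strictly increasing, giving extreme-confidence
    responses extra weight relative to a linear modulator.
    """
    arr = np.asarray(x)
    if not np.isin(arr, [1, 2, 3, 4, 5]).all():
        raise ValueError(f"confidence ratings must be integers 1..5, got {x!r}")
    out = np.arcsin((arr - 3.0) / 2.0) * 2.0 / np.pi
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def framewise_displacement(motion: np.ndarray, rot_radius_mm: float = DEFAULT_ROT_RADIUS_MM) -> np.ndarray:
    """Mean absolute between-volume difference of the six motion parameters.

    Rotations (columns 3..5, radians) are converted to arc length on a
    sphere of ``rot_radius_mm`` before differencing.  Returns a length
    T - 1 non-negative series in mm.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("motion series needs at least two volumes")
    if not np.isfinite(motion).all():
        raise ValueError("motion parameters contain non-finite values")
    scaled = motion.copy()
    scaled[:, 3:] *= rot_radius_mm
    return np.abs(np.diff(scaled, axis=0)).mean(axis=1)


def response_bias(ratings: np.ndarray) -> float:
    """Mean confidence rating minus the 5-point scale midpoint."""
    ratings = np.asarray(ratings, dtype=float)
    return float(ratings.mean() - 3.0)


def iqr_bounds(values: np.ndarray, k: float) -> tuple[float, float]:
    """(Q1 - k*IQR, Q3 + k*IQR) with linearly interpolated quartiles."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError(f"need at least 4 values for quartiles, got {values.size}")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def voxel_outlier_fraction(contrasts: ContrastStack, k: float = R4_IQR_FACTOR) -> pd.Series:
    """Per-subject fraction of masked voxels outside the across-subject
    extreme-outlier bounds Q1 - k*IQR .. Q3 + k*IQR.

    Voxels with zero IQR never flag (a degenerate spread carries no outlier
    information).
    """
    data = contrasts.data
    if data.shape[0] < 4:
        raise ValueError("need at least 4 subjects for voxel quartiles")
    q1, q3 = np.quantile(data, [0.25, 0.75], axis=0)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    outside = (data < lo) | (data > hi)
    outside[:, iqr <= 0] = False
    frac = outside.mean(axis=1)
    return pd.Series(frac, index=pd.Index(contrasts.subjects, name="subject"))


@dataclass
class ExclusionReport:
    """Per-subject QC outcome: kept flag, triggered rules, rule statistics."""

    table: pd.DataFrame  # index subject; columns kept, R1..R4 bools + statistics

    @property
    def kept_ids(self) -> list[str]:
        return sorted(self.table.index[self.table["kept"]])

    @property
    def excluded_ids(self) -> list[str]:
        return sorted(self.table.index[~self.table["kept"] & ~self.table["unevaluable"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def apply_exclusion_rules(
    behavior: BehaviorMotionTable,
    contrasts: ContrastStack | None = None,
    rot_radius_mm: float = DEFAULT_ROT_RADIUS_MM,
) -> ExclusionReport:
    """Evaluate the four exclusion rules; a subject is kept iff none fires.

    Subjects missing any rule input are flagged ``unevaluable`` and not
    kept (never silently retained).  ``contrasts`` may be omitted only when
    rule R4 should count as missing for everyone.
    """
    r4_frac = voxel_outlier_fraction(contrasts) if contrasts is not None else None
    rows = []
    for sid in behavior.scalars.index:
        io_err = behavior.scalars.loc[sid, "io_errors"]
        ratings = behavior.ratings.get(sid)
        motion = behavior.motion.get(sid)
        stats: dict[str, object] = {"subject": sid}
        missing = ratings is None or motion is None or pd.isna(io_err)
        if r4_frac is None or sid not in r4_frac.index:
            missing = True
            stats["voxel_outlier_fraction"] = np.nan
        else:
            stats["voxel_outlier_fraction"] = float(r4_frac.loc[sid])
        if ratings is not None and motion is not None and not pd.isna(io_err):
            fd = framewise_displacement(motion, rot_radius_mm)
            stats["io_errors"] = int(io_err)
            stats["response_bias"] = response_bias(ratings)
            stats["max_fd"] = float(fd.max())
            stats["high_fd_fraction"] = float((fd > R3_FD_SUSTAINED_MM).mean())
        else:
            stats.update(io_errors=np.nan, response_bias=np.nan, max_fd=np.nan, high_fd_fraction=np.nan)
        if missing:
            stats.update(R1_errors=False, R2_bias=False, R3_motion=False,
                         R4_voxel_outliers=False, unevaluable=True, kept=False)
        else:
            r1 = stats["io_errors"] > R1_ERROR_THRESHOLD
            r2 = abs(stats["response_bias"]) > R2_BIAS_THRESHOLD
            r3 = (stats["max_fd"] > R3_FD_SINGLE_MM) or (
                stats["high_fd_fraction"] > R3_SUSTAINED_FRACTION
            )
            r4 = stats["voxel_outlier_fraction"] > R4_VOXEL_FRACTION
            stats.update(R1_errors=bool(r1), R2_bias=bool(r2), R3_motion=bool(r3),
                         R4_voxel_outliers=bool(r4), unevaluable=False,
                         kept=not (r1 or r2 or r3 or r4))
        rows.append(stats)
    table = pd.DataFrame(rows).set_index("subject")
    return ExclusionReport(table=table)


def compose_pacc5(subitems: pd.DataFrame, unimpaired_ids) -> pd.Series:
    """PACC5 composite: mean of the five subitems, each z-scored to the
    cognitively unimpaired subsample.

    Subjects with any missing subitem get a missing composite.
    """
    if subitems.shape[1] != 5:
        raise ValueError(f"expected 5 subitem columns, got {subitems.shape[1]}")
    unimpaired = subitems.loc[list(unimpaired_ids)]
    if unimpaired.empty:
        raise ValueError("unimpaired reference sample is empty")
    mu = unimpaired.mean()
    sd = unimpaired.std(ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = list(sd.index[(sd <= 0) | sd.isna()])
        raise ValueError(f"zero-variance subitem(s) in the unimpaired sample: {bad}")
    z = (subitems - mu) / sd
    pacc5 = z.mean(axis=1, skipna=False)  # any missing subitem -> missing composite
    return pacc5.rename("pacc5")


def boxcox_transform(y, lam: float = 2.8, shift: float | None = None) -> tuple[np.ndarray, float]:
    """Box-Cox power transform ((y + shift)^lambda - 1) / lambda.

    If ``shift`` is None it is set to 1 - min(y) over the sample, making the
    smallest shifted value exactly 1 (transform value 0).  Returns the
    transformed vector and the shift used.  Strictly increasing in y for
    any lambda, so ranks are preserved.
    """
    y = np.asarray(y, dtype=float)
    if shift is None:
        shift = 1.0 - float(np.nanmin(y))
    shifted = y + shift
    if np.nanmin(shifted) <= 0:
        raise ValueError("y + shift must be strictly positive for Box-Cox")
    if lam == 0:
        out = np.log(shifted)
    else:
        out = (shifted**lam - 1.0) / lam
    return out, float(shift)
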