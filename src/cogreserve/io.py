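"""NIfTI and table I/O plus run provenance."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import BootstrapResult, ContrastStack, CRPattern, TaskActiveMask

__all__ = [
    "read_contrast_stack",
    "write_contrast_stack",
    "write_mask",
    "read_mask",
    "write_pattern_maps",
    "write_manifest",
    "save_cohort",
    "load_cohort",
]


def write_mask(mask: TaskActiveMask, path, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_mask(path) -> tuple[TaskActiveMask, np.ndarray]:
    img = nib.load(str(path))
    return TaskActiveMask(np.asanyarray(img.dataobj) > 0), img.affine


def write_contrast_stack(stack: ContrastStack, outdir, stem: str = "contrast") -> list[Path]:
    """One 3-D NIfTI per subject (values zero outside the mask), plus the
    mask itself.  Returns the written image paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mask(stack.mask, outdir / "mask.nii", stack.affine)
    paths = []
    for i, sid in enumerate(stack.subjects):
        vol = stack.mask.unmask(stack.data[i])
        p = outdir / f"{stem}_{sid}.nii"
        nib.save(nib.Nifti1Image(vol.astype(np.float64), stack.affine), str(p))
        paths.append(p)
    return paths


def read_contrast_stack(paths, mask_path) -> ContrastStack:
    """Load per-subject contrast images against a shared mask.

    Subject ids are taken from filenames (last '_'-separated stem token)
    and rows ordered by sorted id.  All images must share the mask's shape
    and affine; NaNs inside the mask are rejected naming the subject.
    """
    mask, affine = read_mask(mask_path)
    entries = []
    for p in paths:
        p = Path(p)
        sid = p.name.split(".")[0].split("_")[-1]
        entries.append((sid, p))
    entries.sort(key=lambda e: e[0])
    offenders = []
    rows = []
    for sid, p in entries:
        img = nib.load(str(p))
        if img.shape != mask.grid.shape or not np.allclose(img.affine, affine, atol=1e-4):
            offenders.append(sid)
            continue
        vol = np.asanyarray(img.dataobj, dtype=float)
        vals = vol[mask.grid]
        if np.isnan(vals).any():
            raise ValueError(f"subject {sid}: NaN values inside the mask")
        rows.append(vals)
    if offenders:
        raise ValueError(f"images with mismatched shape/affine: {offenders}")
    return ContrastStack(
        subjects=[sid for sid, _ in entries],
        mask=mask,
        data=np.asarray(rows),
        affine=affine,
    )


def write_pattern_maps(
    pattern: CRPattern,
    bootstrap: BootstrapResult | None,
    mask: TaskActiveMask,
    affine: np.ndarray,
    outdir,
) -> dict[str, Path]:
    """Write w/a maps and, if available, CI bounds and the significance
    mask as NIfTI volumes (zero outside the task-active mask)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    maps = {"w": pattern.w, "a": pattern.a}
    if bootstrap is not None:
        maps.update(
            ci_lower=bootstrap.ci_lower,
            ci_upper=bootstrap.ci_upper,
            significant=bootstrap.significant.astype(float),
        )
    for name, values in maps.items():
        vol = mask.unmask(values)
        p = outdir / f"{name}.nii"
        nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), str(p))
        out[name] = p
    return out


def save_cohort(bundle, outdir) -> None:
    """Serialize a synthetic cohort: CSV tables, NIfTI maps + mask, truth
    scalars as JSON and truth arrays alongside."""
    from .config import GeneratorConfig  # noqa: F401  (documented format owner)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.phenotypes.to_csv(outdir / "phenotypes.csv")
    bundle.biomarkers.to_csv(outdir / "biomarkers.csv")
    bundle.visits.to_csv(outdir / "visits.csv", index=False)
    bundle.behavior.scalars.to_csv(outdir / "behavior_scalars.csv")
    ratings = pd.DataFrame(bundle.behavior.ratings).T
    ratings.index.name = "subject"
    ratings.to_csv(outdir / "ratings.csv")
    np.savez_compressed(
        outdir / "motion.npz",
        **{sid: arr for sid, arr in bundle.behavior.motion.items()},
    )
    write_contrast_stack(bundle.contrasts, outdir / "contrasts")
    truth = bundle.truth
    np.savez_compressed(
        outdir / "truth_arrays.npz",
        severity=truth.severity,
        expression=truth.expression,
        w_star=truth.w_star,
        mean_map=truth.mean_map,
        nuisance_components=truth.nuisance_components,
        nuisance_scores=truth.nuisance_scores,
        atrophy=truth.atrophy,
    )
    meta = {
        "config": bundle.config.to_dict(),
        "stage_seeds": truth.stage_seeds,
        "qc_fail_sets": truth.qc_fail_sets,
        "coef": vars(truth.coef) if hasattr(truth.coef, "__dict__") else truth.coef.__dict__,
    }
    (outdir / "truth.json").write_text(json.dumps(meta, indent=2, default=str))


def load_cohort(indir):
    """Load a cohort previously written by :func:`save_cohort`."""
    from .config import GeneratorConfig
    from .synth import BehaviorMotionTable, CohortBundle, SyntheticTruth

    indir = Path(indir)
    meta = json.loads((indir / "truth.json").read_text())
    config = GeneratorConfig.from_dict(meta["config"])
    phenotypes = pd.read_csv(indir / "phenotypes.csv", index_col="subject")
    biomarkers = pd.read_csv(indir / "biomarkers.csv", index_col="subject")
    visits = pd.read_csv(indir / "visits.csv")
    scalars = pd.read_csv(indir / "behavior_scalars.csv", index_col="subject")
    ratings_df = pd.read_csv(indir / "ratings.csv", index_col="subject")
    ratings = {sid: row.to_numpy(dtype=int) for sid, row in ratings_df.iterrows()}
    with np.load(indir / "motion.npz") as z:
        motion = {sid: z[sid] for sid in z.files}
    behavior = BehaviorMotionTable(scalars=scalars, ratings=ratings, motion=motion)
    contrast_dir = indir / "contrasts"
    paths = sorted(p for p in contrast_dir.glob("contrast_*.nii"))
    stack = read_contrast_stack(paths, contrast_dir / "mask.nii")
    with np.load(indir / "truth_arrays.npz") as z:
        truth = SyntheticTruth(
            severity=z["severity"],
            expression=z["expression"],
            w_star=z["w_star"],
            mask=stack.mask,
            mean_map=z["mean_map"],
            nuisance_components=z["nuisance_components"],
            nuisance_scores=z["nuisance_scores"],
            atrophy=z["atrophy"],
            coef=config.coef_truth,
            stage_seeds=meta["stage_seeds"],
            qc_fail_sets=meta["qc_fail_sets"],
        )
    return CohortBundle(
        config=config,
        phenotypes=phenotypes,
        biomarkers=biomarkers,
        behavior=behavior,
        contrasts=stack,
        visits=visits,
        truth=truth,
    )


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir, config: dict, seeds: dict, inputs=(), extra: dict | None = None) -> Path:
    """Run manifest: config echo, effective seeds, software versions and
    input hashes — enough to reproduce every output."""
    import cogreserve

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "cogreserve",
        "version": cogreserve.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config,
        "seeds": seeds,
        "input_hashes": {str(p): _hash_file(Path(p)) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
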