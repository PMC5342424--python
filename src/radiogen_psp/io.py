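"""Readers and writers for the pipeline's on-disk formats.

All tabular data are plain text: imaging features as one TSV per time point
(samples x features, header row, sample-ID index column), expression as a
TSV (samples x genes), group labels as a two-column CSV
(``sample_id,group``), coefficients as per-time TSVs plus the unfolded
matrix. Masks are 8-bit label PNGs or NIfTI volumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .containers import CoefficientTensor, ExpressionMatrix, LongitudinalFeatureTensor
from .synthetic_data import MaskStack, SyntheticCohort

__all__ = [
    "write_feature_tensor",
    "read_feature_tensor",
    "write_expression",
    "read_expression",
    "write_labels",
    "read_labels",
    "write_coefficients",
    "write_cohort",
    "read_cohort",
    "write_mask_stack",
    "read_mask_stack",
    "write_manifest",
]


def write_feature_tensor(X: LongitudinalFeatureTensor, outdir: Path, stem: str = "X") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, label in enumerate(X.time_labels):
        frame = pd.DataFrame(
            X.timepoint(t), index=X.sample_ids, columns=X.feature_names
        )
        path = outdir / f"{stem}_{label}.tsv"
        frame.to_csv(path, sep="\t", index_label="sample_id")
        paths.append(path)
    return paths


def read_feature_tensor(paths) -> LongitudinalFeatureTensor:
    frames = [pd.read_csv(Path(p), sep="\t", index_col="sample_id") for p in paths]
    values = np.stack([f.values for f in frames], axis=2)
    return LongitudinalFeatureTensor(
        values=values,
        sample_ids=[str(s) for s in frames[0].index],
        feature_names=[str(c) for c in frames[0].columns],
        time_labels=[Path(p).stem.split("_")[-1] for p in paths],
    )


def write_expression(Y: ExpressionMatrix, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(Y.values, index=Y.sample_ids, columns=Y.gene_symbols)
    frame.to_csv(path, sep="\t", index_label="sample_id")
    return path


def read_expression(path: Path, labels_path: Path | None = None) -> ExpressionMatrix:
    frame = pd.read_csv(Path(path), sep="\t", index_col="sample_id")
    groups = None
    if labels_path is not None:
        labels = read_labels(labels_path)
        groups = labels.loc[frame.index, "group"].to_numpy(dtype=object)
    return ExpressionMatrix(
        values=frame.values,
        sample_ids=[str(s) for s in frame.index],
        gene_symbols=[str(c) for c in frame.columns],
        groups=groups,
    )


def write_labels(sample_ids, groups, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample_id": sample_ids, "group": groups}).to_csv(path, index=False)
    return path


def read_labels(path: Path) -> pd.DataFrame:
    return pd.read_csv(Path(path)).set_index("sample_id")


def write_coefficients(W: CoefficientTensor, outdir: Path, stem: str = "W") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, label in enumerate(W.time_labels):
        frame = pd.DataFrame(W.timepoint(t), index=W.feature_names, columns=W.gene_symbols)
        path = outdir / f"{stem}_{label}.tsv"
        frame.to_csv(path, sep="\t", index_label="feature")
        paths.append(path)
    unfolded = pd.DataFrame(W.unfold(), index=W.feature_names)
    path = outdir / f"{stem}_unfolded.tsv"
    unfolded.to_csv(path, sep="\t", index_label="feature")
    paths.append(path)
    return paths


def write_cohort(cohort: SyntheticCohort, outdir: Path) -> dict[str, object]:
    """Write a synthetic cohort (X TSVs, Y TSV, labels CSV, W_true TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {
        "X": [str(p) for p in write_feature_tensor(cohort.X, outdir)],
        "Y": str(write_expression(cohort.Y, outdir / "Y.tsv")),
        "labels": str(write_labels(cohort.Y.sample_ids, cohort.labels, outdir / "labels.csv")),
        "W_true": [str(p) for p in write_coefficients(cohort.W_true, outdir, stem="W_true")],
    }
    truth = {
        "active_genes": [int(j) for j in cohort.active_genes],
        "active_features": {str(j): [int(i) for i in idx] for j, idx in cohort.active_features.items()},
    }
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    written["ground_truth"] = str(truth_path)
    return written


def read_cohort(outdir: Path) -> tuple[LongitudinalFeatureTensor, ExpressionMatrix]:
    outdir = Path(outdir)
    x_paths = sorted(outdir.glob("X_*.tsv"))
    X = read_feature_tensor(x_paths)
    Y = read_expression(outdir / "Y.tsv", outdir / "labels.csv")
    return X, Y


def write_mask_stack(stack: MaskStack, outdir: Path, fmt: str = "png", stem: str = "slice") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    if fmt == "png":
        for i, s in enumerate(stack.slices):
            path = outdir / f"{stem}_{i:03d}.png"
            iio.imwrite(path, s.astype(np.uint8))
            paths.append(path)
    elif fmt == "nifti":
        import nibabel as nib

        volume = np.stack(stack.slices, axis=2).astype(np.uint8)
        affine = np.diag([stack.pixel_size, stack.pixel_size, 1.0, 1.0])
        path = outdir / f"{stem}.nii"
        nib.save(nib.Nifti1Image(volume, affine), path)
        paths.append(path)
    else:
        raise ValueError("fmt must be 'png' or 'nifti'")
    return paths


def read_mask_stack(source, pixel_size: float = 1.0) -> MaskStack:
    """Load a mask stack from a directory of PNGs, a list of paths, or a NIfTI file."""
    source = Path(source) if isinstance(source, (str, Path)) else source
    if isinstance(source, Path) and source.is_dir():
        paths = sorted(source.glob("*.png"))
    elif isinstance(source, Path):
        paths = [source]
    else:
        paths = [Path(p) for p in source]
    if len(paths) == 1 and paths[0].suffix in (".nii", ".gz"):
        import nibabel as nib

        volume = np.asarray(nib.load(paths[0]).dataobj)
        slices = [volume[:, :, k].astype(np.uint8) for k in range(volume.shape[2])]
    else:
        slices = [np.asarray(iio.imread(p)).astype(np.uint8) for p in paths]
    return MaskStack(slices=slices, pixel_size=pixel_size)


def write_manifest(manifest: dict[str, str], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=1))
    return path
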