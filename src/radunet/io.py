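"""Reading and writing images, masks, datasets and manifests.

Images are written as 16-bit PNG (intensities scaled from [0, 1]) and
masks as 8-bit PNG with values {0, 255}.  NIfTI export carries the pixel
spacing in the header.  DICOM input applies rescale slope/intercept to
recover Hounsfield units; PNG/TIFF inputs are treated as already
normalized to [0, 1].
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .phantom import PhantomSample, PhantomSpec, generate_dataset


def write_image_png(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 65535.0 + 0.5).astype(np.uint16))


def write_mask_png(path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG with foreground = 255."""
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_image(path) -> np.ndarray:
    """Read an image slice; returns float32.

    PNG/TIFF are rescaled by their dtype range to [0, 1].  DICOM files
    yield Hounsfield units (slope/intercept applied); NIfTI is returned
    as stored.
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".dcm", ".dicom")):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        return np.asarray(img.dataobj, dtype=np.float32).squeeze()
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) to grayscale
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        return (arr / np.iinfo(arr.dtype).max).astype(np.float32)
    return arr.astype(np.float32)


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def write_nifti(path, array: np.ndarray, pixel_spacing_mm: float = 1.0) -> None:
    import nibabel as nib

    affine = np.diag([pixel_spacing_mm, pixel_spacing_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def export_dataset(
    out_dir, spec: PhantomSpec, n: int, train_fraction: float = 0.8
) -> pd.DataFrame:
    """Generate a phantom dataset and write images, masks and a manifest CSV.

    The manifest has one row per sample: image/mask paths, split,
    n_nodules, per-nodule diameters (mm) and the dominant size class.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    train, test = generate_dataset(spec, n, train_fraction)
    rows = []
    for split, samples in (("train", train), ("test", test)):
        for i, s in enumerate(samples):
            stem = f"{split}_{i:04d}"
            img_path = out_dir / "images" / f"{stem}.png"
            msk_path = out_dir / "masks" / f"{stem}.png"
            write_image_png(img_path, s.image)
            write_mask_png(msk_path, s.mask)
            rows.append({
                "image": os.path.relpath(img_path, out_dir),
                "mask": os.path.relpath(msk_path, out_dir),
                "split": split,
                "n_nodules": s.n_nodules,
                "diameters_mm": ";".join(f"{d:.2f}" for d in s.diameters_mm),
                "category": s.dominant_category,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_dir) -> tuple[list[PhantomSample], list[PhantomSample]]:
    """Load an exported dataset back from its manifest."""
    manifest_dir = Path(manifest_dir)
    manifest = pd.read_csv(manifest_dir / "manifest.csv")
    train, test = [], []
    for _, row in manifest.iterrows():
        image = read_image(manifest_dir / row["image"])
        mask = read_mask(manifest_dir / row["mask"])
        diam = [float(d) for d in str(row["diameters_mm"]).split(";") if d]
        sample = PhantomSample(image, mask, diam)
        (train if row["split"] == "train" else test).append(sample)
    return train, test
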