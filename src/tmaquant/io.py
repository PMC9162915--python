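"""Disk formats of the pipeline: TIFF spot images, CSV tables, JSON
manifests and classifier artifacts.

Images are two-channel (nuclear, stain) float32 TIFFs; masks are 8-bit
PNGs; tables are UTF-8 comma-separated with a header row.  Every manifest
records the seed and the config hash so any output is regenerable
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .config import PipelineConfig, config_hash, save_config
from .segmentation import SpotImage
from .synthetic import iter_cohort, patient_truth_frame

__all__ = [
    "write_spot_image",
    "read_spot_image",
    "write_cohort",
    "read_manifest",
]


def write_spot_image(image: SpotImage, path) -> None:
    stack = np.stack([image.nuclear_channel, image.stain_channel]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        metadata={
            "axes": "CYX",
            "microns_per_pixel": image.microns_per_pixel,
            "spot_id": image.spot_id,
            "clone_name": image.clone_name,
        },
    )


def read_spot_image(path, spot_id: str = "", clone_name: str = "") -> SpotImage:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    mpp = float(meta.get("microns_per_pixel", 1.0))
    return SpotImage(
        nuclear_channel=stack[0],
        stain_channel=stack[1],
        microns_per_pixel=mpp,
        spot_id=spot_id or str(meta.get("spot_id", "")),
        clone_name=clone_name or str(meta.get("clone_name", "")),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(config: PipelineConfig, out_dir) -> dict:
    """Generate the configured cohort and write it to ``out_dir``.

    Layout: ``images/{patient}_{clone}.tif``, optional
    ``masks/{patient}_{clone}_nonspecific.png`` (only where a non-specific
    territory exists), ``truth_cells.csv`` (one row per cell),
    ``patients.csv`` (latent truth and covariates), ``config.yaml`` and
    ``manifest.json``.  The manifest records the seed, the config hash and
    a content hash per file, so identical seeds yield identical manifests.
    Returns the manifest dict.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    spots = []
    cell_rows = []
    truths = []
    for record in iter_cohort(config.cohort):
        truths.append(record.truth)
        for image, gt in zip(record.images, record.ground_truths):
            name = f"{image.spot_id}_{image.clone_name}"
            img_path = out / "images" / f"{name}.tif"
            write_spot_image(image, img_path)
            mask_path = None
            if gt.nonspecific_region_mask.any():
                mask_path = out / "masks" / f"{name}_nonspecific.png"
                iio.imwrite(
                    mask_path,
                    (gt.nonspecific_region_mask * np.uint8(255)),
                )
            for (row, col), cls in zip(gt.cell_centroids, gt.cell_class):
                cell_rows.append(
                    {
                        "spot_id": image.spot_id,
                        "clone": image.clone_name,
                        "x_px": float(col),
                        "y_px": float(row),
                        "class": cls,
                    }
                )
            spots.append(
                {
                    "spot_id": image.spot_id,
                    "clone": image.clone_name,
                    "patient_id": record.truth.patient_id,
                    "entity": record.truth.entity,
                    "image": str(img_path.relative_to(out)),
                    "nonspecific_mask": (
                        str(mask_path.relative_to(out)) if mask_path else None
                    ),
                    "true_density": gt.true_density,
                    "true_nonspecific_fraction": gt.true_nonspecific_fraction,
                }
            )

    pd.DataFrame(
        cell_rows, columns=["spot_id", "clone", "x_px", "y_px", "class"]
    ).to_csv(out / "truth_cells.csv", index=False)
    patient_truth_frame(truths, config.cohort.clone_names).to_csv(
        out / "patients.csv", index=False
    )
    save_config(config, out / "config.yaml")

    file_hashes = {
        s["image"]: _sha256(out / s["image"]) for s in spots
    }
    file_hashes.update(
        {
            s["nonspecific_mask"]: _sha256(out / s["nonspecific_mask"])
            for s in spots
            if s["nonspecific_mask"]
        }
    )
    for name in ("truth_cells.csv", "patients.csv"):
        file_hashes[name] = _sha256(out / name)
    manifest = {
        "seed": config.cohort.seed,
        "config_hash": config_hash(config),
        "n_patients": len(truths),
        "n_images": len(spots),
        "spots": spots,
        "file_sha256": file_hashes,
    }
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_manifest(in_dir) -> dict:
    path = Path(in_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest found at {path}")
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
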