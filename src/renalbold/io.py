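"""File I/O for the CLI pipeline: NIfTI, PNG, JSON sidecars, CSV.

All writers are atomic (write to a temporary sibling, then rename), so an
error never leaves a partial output file behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from PIL import Image as PILImage

from .clustering import IntensityImage, InvalidInputError
from .relaxometry import ROI, ROISet, EchoSeries


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path, mask_path=None) -> IntensityImage:
    """Read a grayscale image (NIfTI or PNG) as floating point."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        values = np.squeeze(np.asarray(img.dataobj, dtype=float))
    else:
        values = np.asarray(PILImage.open(path).convert("F"), dtype=float)
    mask = None
    if mask_path is not None:
        mask = read_image(mask_path).values > 0
    return IntensityImage(values=values, mask=mask)


def _atomic_bytes(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_nifti(path, array: np.ndarray, affine: Optional[np.ndarray] = None) -> None:
    """Write an array as NIfTI (affine passed through, identity default)."""
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(array), affine)
    # nibabel picks compression from the extension, so the temp file must
    # carry the same suffix as the target
    suffix = ".nii.gz" if path.name.lower().endswith(".nii.gz") else ".nii"
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix="tmp_", suffix=suffix)
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_labels(path, labels: np.ndarray, affine: Optional[np.ndarray] = None) -> None:
    write_nifti(path, np.asarray(labels, dtype=np.int16), affine)


def write_membership(path, membership: np.ndarray, grid_shape, mask, affine=None) -> None:
    """Write the n x c fuzzy partition as a multi-volume NIfTI stack
    (one volume per cluster, 0 outside the mask)."""
    u = np.asarray(membership, dtype=float)
    stack = np.zeros(tuple(grid_shape) + (u.shape[1],), dtype=np.float32)
    stack[np.asarray(mask, bool)] = u
    write_nifti(path, stack, affine)


def write_json(path, payload: dict) -> None:
    def _writer(tmp):
        with open(tmp, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    _atomic_bytes(Path(path), _writer)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_csv(path, frame) -> None:
    _atomic_bytes(Path(path), lambda tmp: frame.to_csv(tmp, index=False))


def read_echo_series(series_path, sidecar_path) -> EchoSeries:
    """Read a 4D NIfTI echo stack plus its JSON sidecar of echo times.

    The sidecar must contain ``echo_times_ms`` (list) and may carry
    ``tr_ms``.  The 4th NIfTI axis indexes echoes.
    """
    series_path, sidecar_path = Path(series_path), Path(sidecar_path)
    if not series_path.exists():
        raise FileNotFoundError(f"echo series not found: {series_path}")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"echo-time sidecar not found: {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    te = meta.get("echo_times_ms")
    if te is None:
        raise InvalidInputError(f"sidecar {sidecar_path} lacks 'echo_times_ms'")
    data = np.asarray(nib.load(str(series_path)).dataobj, dtype=float)
    if data.ndim != 4 and data.ndim != 3:
        raise InvalidInputError("echo series must be 3D (2D+echo) or 4D")
    vols = np.moveaxis(data, -1, 0)
    if vols.shape[0] != len(te):
        raise InvalidInputError(
            f"{vols.shape[0]} echo volumes but {len(te)} echo times in sidecar"
        )
    return EchoSeries(volumes=vols, echo_times=np.asarray(te, float),
                      tr=meta.get("tr_ms"))


def read_roi_set(labels_path, table_path) -> ROISet:
    """Read ROIs as an integer-labeled NIfTI plus a JSON table mapping
    label -> {compartment, side, pole}."""
    labels_path, table_path = Path(labels_path), Path(table_path)
    if not labels_path.exists():
        raise FileNotFoundError(f"ROI labels not found: {labels_path}")
    if not table_path.exists():
        raise FileNotFoundError(f"ROI table not found: {table_path}")
    labels = np.squeeze(np.asarray(nib.load(str(labels_path)).dataobj)).astype(int)
    with open(table_path) as fh:
        table = json.load(fh)
    regions = []
    for key, meta in table.items():
        lab = int(key)
        mask = labels == lab
        if not mask.any():
            continue
        regions.append(ROI(
            mask=mask,
            compartment=meta["compartment"],
            side=meta["side"],
            pole=meta.get("pole", "middle"),
            label=lab,
        ))
    return ROISet(regions=regions)
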