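"""Slice loading, resize / intensity preprocessing and the sixfold split.

Preprocessing mirrors common practice for screening-CT autoencoders: slices
are resized with bicubic interpolation (Keys a=-0.5 kernel, as implemented
by Pillow) and each case volume is min-max scaled to [0, 1] as a whole, so
one examinee's tissue maps to consistent gray levels across slices.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import ConfigurationError, FormatError
from .phantom import ExamVolume

__all__ = [
    "FoldAssignment", "load_volume", "resize_bicubic", "minmax_scale",
    "sixfold_split",
]

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class FoldAssignment:
    """One cross-validation fold over normal cases, abnormal cases test-only."""

    fold_id: int
    train_case_ids: tuple[str, ...]
    validation_case_ids: tuple[str, ...]
    test_case_ids: tuple[str, ...]
    abnormal_case_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "train_case_ids": list(self.train_case_ids),
            "validation_case_ids": list(self.validation_case_ids),
            "test_case_ids": list(self.test_case_ids),
            "abnormal_case_ids": list(self.abnormal_case_ids),
        }


def _read_slice(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im, dtype=np.float64)
    except OSError as exc:
        raise OSError(f"unreadable slice image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path} is not a single-channel image")
    return arr


def load_volume(path: str | Path) -> ExamVolume:
    """Load an examinee's slices from a DICOM series or a PNG/TIFF stack.

    DICOM slices are ordered by InstanceNumber, image files lexically by
    filename.  Raw intensities are preserved as floats (no rescaling); a
    ``volume.json`` sidecar, when present, supplies label and slice flags.
    """
    path = Path(path)
    if not path.is_dir():
        raise OSError(f"{path} is not a directory")
    dicoms = sorted(path.glob("*.dcm"))
    if dicoms:
        slices = _load_dicom_series(dicoms)
    else:
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES
                       and not p.name.startswith("mask_"))
        if not files:
            raise OSError(f"no slice images found in {path}")
        slices = [_read_slice(p) for p in files]
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise FormatError(f"mixed slice sizes in {path}: {sorted(shapes)}")
    stack = np.stack(slices)

    label = "normal"
    flags = np.zeros(len(slices), dtype=bool)
    sidecar = path / "volume.json"
    case_id = path.name
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("label", "normal")
        case_id = meta.get("case_id", case_id)
        if meta.get("anomaly_slice_flags") is not None:
            flags = np.asarray(meta["anomaly_slice_flags"], dtype=bool)
    masks = np.zeros_like(stack, dtype=bool)
    for s in range(len(slices)):
        mpath = path / f"mask_{s:03d}.png"
        if mpath.exists():
            masks[s] = _read_slice(mpath) > 0
    return ExamVolume(case_id=case_id, slices=stack, label=label,
                      anomaly_masks=masks, anomaly_slice_flags=flags,
                      meta={"source": str(path)})


def _load_dicom_series(files: Sequence[Path]) -> list[np.ndarray]:
    import pydicom

    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    out = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        out.append(arr * slope + intercept)
    return out


def resize_bicubic(image: np.ndarray, target_size: int) -> np.ndarray:
    """Resize a square image to target_size x target_size, bicubic kernel."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise FormatError(f"expected a square 2-D image, got {arr.shape}")
    if arr.shape[0] == target_size:
        return arr.copy()
    if target_size > arr.shape[0]:
        logger.info("bicubic upsampling %s -> %s", arr.shape[0], target_size)
    im = Image.fromarray(arr.astype(np.float32), mode="F")
    out = im.resize((target_size, target_size), resample=Image.BICUBIC)
    return np.asarray(out, dtype=np.float64)


def minmax_scale(volume: ExamVolume) -> ExamVolume:
    """Scale a whole case volume to [0, 1] by its global min and max."""
    s = volume.slices
    if s.size == 0:
        raise FormatError("empty volume")
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        warnings.warn("constant-intensity volume: min-max scaling maps all "
                      "pixels to 0", stacklevel=2)
        scaled = np.zeros_like(s)
    else:
        scaled = (s - lo) / (hi - lo)
    return ExamVolume(case_id=volume.case_id, slices=scaled,
                      label=volume.label, anomaly_masks=volume.anomaly_masks,
                      anomaly_slice_flags=volume.anomaly_slice_flags,
                      meta={**volume.meta, "minmax": (lo, hi)})


def sixfold_split(normal_case_ids: Sequence[str],
                  abnormal_case_ids: Sequence[str],
                  seed: int) -> list[FoldAssignment]:
    """Sixfold cross-validation over normal cases.

    Normal ids are shuffled and cut into six near-equal subsets (sizes
    differ by at most one).  Fold k uses subset k as the test set, subset
    (k+1) mod 6 for validation and the remaining four for training; every
    abnormal case is appended to every fold's test set and never trains.
    """
    normal = list(normal_case_ids)
    if len(normal) < 6:
        raise ConfigurationError("need at least 6 normal cases for six folds")
    if set(normal) & set(abnormal_case_ids):
        raise ConfigurationError("normal and abnormal id lists overlap")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(normal))
    shuffled = [normal[i] for i in order]
    subsets = [list(s) for s in np.array_split(np.array(shuffled, dtype=object), 6)]
    folds = []
    for k in range(6):
        val = (k + 1) % 6
        train = [cid for j in range(6) if j not in (k, val)
                 for cid in subsets[j]]
        folds.append(FoldAssignment(
            fold_id=k,
            train_case_ids=tuple(train),
            validation_case_ids=tuple(subsets[val]),
            test_case_ids=tuple(subsets[k]),
            abnormal_case_ids=tuple(abnormal_case_ids),
        ))
    return folds
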