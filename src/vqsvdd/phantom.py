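"""Synthetic chest-phantom volumes for slice-based anomaly detection.

Each examinee is a stack of 2-D grayscale slices that mimics the gross
statistics of an axial chest series: an elliptical body wall of soft-tissue
intensity, two darker lung fields whose cross-section waxes and wanes along
the stack, and bright curvilinear / punctate vessel-like structures that
vary slice to slice.  Abnormal volumes are normal volumes with a localized
deviation injected inside a lung field on a contiguous run of slices:

* ``nodule``       — a bright smooth focal blob (tumour-like),
* ``consolidation``— a diffuse textured intensity increase (pneumonia-like),
* ``void``         — a structure-free dark patch that also erases vessel
                     texture (emphysema/pneumothorax-like).

The generator is deterministic: every random draw derives from
(config.seed, case_index), so datasets are reproducible and independent of
generation order.  This module is the test bed for the detector; it does not
attempt anatomically calibrated CT simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, PlacementError

__all__ = [
    "PhantomConfig", "AnomalySpec", "ExamVolume",
    "generate_normal_volume", "inject_anomaly", "generate_dataset",
    "case_layout", "save_volume",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and noise settings of the phantom generator."""

    image_size: int = 64
    slices_per_case: tuple[int, int] = (8, 12)
    body_intensity: float = 0.6
    lung_intensity: float = 0.2
    vessel_intensity: float = 0.75
    vessel_count: int = 12
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        lo, hi = self.slices_per_case
        if lo < 1 or hi < lo:
            raise ConfigurationError("slices_per_case must be a range with min >= 1")
        for name in ("body_intensity", "lung_intensity", "vessel_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class AnomalySpec:
    """A localized synthetic lesion."""

    kind: Literal["nodule", "consolidation", "void"]
    radius_px: int = 6
    intensity_delta: float = 0.4
    n_slices_affected: int = 3
    # placement is always random-within-lung-field

    def __post_init__(self):
        if self.kind not in ("nodule", "consolidation", "void"):
            raise ConfigurationError(f"unknown anomaly kind {self.kind!r}")
        if self.radius_px < 1:
            raise ConfigurationError("radius_px must be >= 1")
        if self.n_slices_affected < 1:
            raise ConfigurationError("n_slices_affected must be >= 1")
        if self.kind == "void" and self.intensity_delta >= 0:
            raise ConfigurationError("void anomalies require a negative delta")


@dataclass
class ExamVolume:
    """An examinee's ordered slice stack with labels, flags and masks."""

    case_id: str
    slices: np.ndarray                     # (S, H, W) float64 in [0, 1]
    label: Literal["normal", "abnormal"]
    anomaly_masks: np.ndarray              # (S, H, W) bool
    anomaly_slice_flags: np.ndarray        # (S,) bool
    meta: dict = field(default_factory=dict)

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    def validate(self) -> None:
        s = self.slices
        if s.ndim != 3:
            raise ConfigurationError("slices must be a (S, H, W) stack")
        if s.min() < 0.0 or s.max() > 1.0:
            raise ConfigurationError("pixel values must lie in [0, 1]")
        flags = np.asarray(self.anomaly_slice_flags, bool)
        has_mask = self.anomaly_masks.reshape(self.n_slices, -1).any(axis=1)
        if not np.array_equal(flags, has_mask):
            raise ConfigurationError("flags inconsistent with masks")
        if (self.label == "abnormal") != bool(flags.any()):
            raise ConfigurationError("label inconsistent with slice flags")


def _case_rng(seed: int, case_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, case_index, stream])


def case_layout(config: PhantomConfig, case_index: int) -> dict:
    """Per-case anatomy parameters (body/lung ellipses), seeded by case."""
    rng = _case_rng(config.seed, case_index, stream=0)
    n = config.image_size
    cy = 0.5 + rng.uniform(-0.02, 0.02)
    cx = 0.5 + rng.uniform(-0.02, 0.02)
    return {
        "n_slices": int(rng.integers(config.slices_per_case[0],
                                     config.slices_per_case[1] + 1)),
        "center": (cy * n, cx * n),
        "body_axes": (rng.uniform(0.34, 0.38) * n, rng.uniform(0.42, 0.46) * n),
        "lung_dx": rng.uniform(0.18, 0.22) * n,
        "lung_axes": (rng.uniform(0.22, 0.26) * n, rng.uniform(0.13, 0.16) * n),
    }


def _ellipse_mask(n: int, center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    cy, cx = center
    ay, ax = axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _slice_masks(config: PhantomConfig, layout: dict,
                 slice_index: int) -> tuple[np.ndarray, np.ndarray]:
    """(body_mask, lung_mask) for one slice; lungs shrink toward the ends."""
    n = config.image_size
    t = slice_index / max(layout["n_slices"] - 1, 1)
    scale = 0.6 + 0.4 * np.sin(np.pi * np.clip(t, 0.02, 0.98))
    cy, cx = layout["center"]
    body = _ellipse_mask(n, (cy, cx), layout["body_axes"])
    lay, lax = layout["lung_axes"]
    left = _ellipse_mask(n, (cy, cx - layout["lung_dx"]),
                         (lay * scale, lax * scale))
    right = _ellipse_mask(n, (cy, cx + layout["lung_dx"]),
                          (lay * scale, lax * scale))
    lung = (left | right) & body
    return body, lung


def _draw_vessels(img: np.ndarray, lung: np.ndarray, rng: np.random.Generator,
                  config: PhantomConfig) -> None:
    """Bright random-walk curves and dots confined to the lung fields."""
    n = img.shape[0]
    coords = np.argwhere(lung)
    if coords.size == 0:
        return
    for _ in range(config.vessel_count):
        y, x = coords[rng.integers(len(coords))]
        ang = rng.uniform(0, 2 * np.pi)
        steps = int(rng.integers(n // 16, n // 6 + 1))
        for _ in range(steps):
            if 0 <= int(y) < n and 0 <= int(x) < n and lung[int(y), int(x)]:
                img[int(y), int(x)] = config.vessel_intensity
            ang += rng.normal(0, 0.35)
            y += np.sin(ang)
            x += np.cos(ang)
        # punctate cross-sections
        y, x = coords[rng.integers(len(coords))]
        img[y, x] = config.vessel_intensity


def generate_normal_volume(config: PhantomConfig, case_index: int) -> ExamVolume:
    """One normal examinee: shared per-case anatomy, per-slice vessel detail."""
    layout = case_layout(config, case_index)
    n = config.image_size
    rng = _case_rng(config.seed, case_index, stream=1)
    slices = np.empty((layout["n_slices"], n, n))
    lung_masks = np.empty((layout["n_slices"], n, n), dtype=bool)
    for s in range(layout["n_slices"]):
        body, lung = _slice_masks(config, layout, s)
        img = np.full((n, n), 0.03)
        img[body] = config.body_intensity
        img[lung] = config.lung_intensity
        _draw_vessels(img, lung, rng, config)
        img = ndimage.gaussian_filter(img, sigma=0.7)
        img = img + rng.normal(0.0, config.noise_sd, (n, n))
        slices[s] = np.clip(img, 0.0, 1.0)
        lung_masks[s] = lung
    return ExamVolume(
        case_id=f"case{case_index:04d}",
        slices=slices,
        label="normal",
        anomaly_masks=np.zeros_like(slices, dtype=bool),
        anomaly_slice_flags=np.zeros(layout["n_slices"], dtype=bool),
        meta={"case_index": case_index, "lung_masks": lung_masks,
              "config": dataclasses.asdict(config)},
    )


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return yy**2 + xx**2 <= radius**2


def inject_anomaly(volume: ExamVolume, spec: AnomalySpec,
                   seed: int) -> ExamVolume:
    """Return a new abnormal volume with a lesion on contiguous slices.

    The lesion center is drawn uniformly among lung-field pixels at which a
    disk of ``spec.radius_px`` fits inside the lung on every affected slice.
    """
    if volume.label != "normal":
        raise ConfigurationError("anomalies are injected into normal volumes")
    if "lung_masks" not in volume.meta:
        raise ConfigurationError("volume lacks lung-field masks "
                                 "(generate it with this module)")
    rng = np.random.default_rng([seed, volume.meta.get("case_index", 0), 2])
    ns = volume.n_slices
    k = min(spec.n_slices_affected, ns)
    if spec.n_slices_affected > ns:
        raise PlacementError(
            f"{spec.n_slices_affected} affected slices exceed the "
            f"{ns}-slice volume")
    # try slice windows in random order until the disk fits in the lung
    # on every affected slice (end slices have smaller lung sections)
    starts = rng.permutation(ns - k + 1)
    candidates = np.empty((0, 2), dtype=int)
    start = 0
    for cand_start in starts:
        lung = volume.meta["lung_masks"][cand_start:cand_start + k].all(axis=0)
        fit = ndimage.binary_erosion(lung, structure=_disk(spec.radius_px))
        candidates = np.argwhere(fit)
        if len(candidates):
            start = int(cand_start)
            break
    if len(candidates) == 0:
        raise PlacementError(
            f"no lung-field position fits radius {spec.radius_px}")
    cy, cx = candidates[rng.integers(len(candidates))]

    n = volume.slices.shape[1]
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    disk = r2 <= spec.radius_px**2
    profile = np.exp(-r2 / (2.0 * (0.6 * spec.radius_px) ** 2)) * disk

    slices = volume.slices.copy()
    masks = volume.anomaly_masks.copy()
    flags = volume.anomaly_slice_flags.copy()
    for s in range(start, start + k):
        img = slices[s]
        if spec.kind == "nodule":
            img = img + spec.intensity_delta * profile
        elif spec.kind == "consolidation":
            texture = 0.6 + 0.4 * rng.random((n, n))
            img = img + spec.intensity_delta * profile * texture
        else:  # void: blend toward a flat dark level, erasing structure
            target = volume.meta["config"]["lung_intensity"] + spec.intensity_delta
            img = img * (1.0 - profile) + profile * target
        slices[s] = np.clip(img, 0.0, 1.0)
        masks[s] = disk
        flags[s] = True

    out = ExamVolume(
        case_id=volume.case_id,
        slices=slices,
        label="abnormal",
        anomaly_masks=masks,
        anomaly_slice_flags=flags,
        meta={**volume.meta, "anomaly": dataclasses.asdict(spec),
              "anomaly_center": (int(cy), int(cx)),
              "anomaly_slices": (start, start + k)},
    )
    out.validate()
    return out


def generate_dataset(config: PhantomConfig, n_normal: int, n_abnormal: int,
                     anomaly_specs: Sequence[AnomalySpec] = ()) -> list[ExamVolume]:
    """n_normal normal plus n_abnormal abnormal volumes, specs cycled."""
    if n_normal < 0 or n_abnormal < 0:
        raise ConfigurationError("case counts must be >= 0")
    if n_abnormal > 0 and not anomaly_specs:
        raise ConfigurationError("abnormal cases requested without anomaly specs")
    volumes = [generate_normal_volume(config, i) for i in range(n_normal)]
    for j in range(n_abnormal):
        base = generate_normal_volume(config, n_normal + j)
        spec = anomaly_specs[j % len(anomaly_specs)]
        volumes.append(inject_anomaly(base, spec, seed=config.seed))
    return volumes


def save_volume(volume: ExamVolume, directory: str | Path) -> Path:
    """Write a volume as 16-bit PNG slices plus a JSON sidecar."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in range(volume.n_slices):
        arr = np.round(volume.slices[s] * 65535.0).astype(np.uint16)
        iio.imwrite(directory / f"slice_{s:03d}.png", arr)
        if volume.anomaly_slice_flags[s]:
            mask = (volume.anomaly_masks[s] * 255).astype(np.uint8)
            iio.imwrite(directory / f"mask_{s:03d}.png", mask)
    sidecar = {
        "case_id": volume.case_id,
        "label": volume.label,
        "anomaly_slice_flags": [bool(f) for f in volume.anomaly_slice_flags],
        "anomaly": volume.meta.get("anomaly"),
    }
    (directory / "volume.json").write_text(json.dumps(sidecar, indent=2))
    return directory
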