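"""Deterministic synthetic lesion-image generator.

Renders lesion-like test images so every stage of the pipeline — color
decomposition, descriptors, fusion, balancing, classification — can be
exercised end-to-end without downloading dermoscopy archives. Each image is
a skin-toned background with an elliptical "lesion" whose

* mean color,
* sinusoidal texture frequency and orientation, and
* border irregularity / eccentricity

depend on the class, plus additive Gaussian pixel noise. The class signal
is carried by both the color distribution and the texture frequency, so
per-channel color features genuinely carry more information than the
grayscale projection: the default two classes have nearly equal BT.601 luma
but chromatically distant lesion colors.

Every image is a pure function of ``(seed, class_id, index)``.

These fixtures emulate the *shape* of real dermoscopy data (image sizes
224×224 or 28×28, 2-class or 7-class label sets, imbalance on request) but
not its content: no hair, rulers, specular highlights or acquisition
variation. Results on fixtures demonstrate that the pipeline is correct and
that its feature representations can exploit color and texture, not that
any particular accuracy transfers to clinical images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InputError

__all__ = ["ClassParams", "FixtureSpec", "make_image", "make_dataset", "default_class_params"]


@dataclass(frozen=True)
class ClassParams:
    """Rendering parameters for one lesion class."""

    mean_rgb: tuple[float, float, float]
    texture_freq: float  # cycles per pixel of the sinusoidal texture
    texture_amp: float  # peak amplitude, gray levels
    texture_angle: float  # texture wave direction, degrees
    color_axis: tuple[float, float, float]  # RGB direction modulated by texture
    color_std: float  # per-image lesion color jitter (isotropic), gray levels
    ecc: float  # minor/major axis ratio of the ellipse
    irregularity: float  # relative amplitude of the border perturbation


def default_class_params(n_classes: int) -> tuple[ClassParams, ...]:
    """Built-in class parameter sets for 2- and 7-class fixture datasets.

    The two-class set keeps the lesion means nearly isoluminant (BT.601
    luma ≈ 105 for both) while ~82 gray levels apart in RGB, with distinct
    texture frequencies and orientations.
    """
    if n_classes == 2:
        return (
            ClassParams((140.0, 90.0, 90.0), 0.10, 18.0, 20.0, (0.20, -0.75, 0.63), 5.0, 0.85, 0.08),
            ClassParams((70.0, 122.0, 118.0), 0.22, 18.0, 70.0, (-0.62, 0.20, 0.76), 5.0, 0.60, 0.18),
        )
    if n_classes == 7:
        means = (
            (150.0, 100.0, 80.0),
            (95.0, 70.0, 60.0),
            (170.0, 130.0, 95.0),
            (120.0, 85.0, 110.0),
            (80.0, 110.0, 90.0),
            (60.0, 55.0, 75.0),
            (180.0, 90.0, 120.0),
        )
        axes = (
            (0.2, -0.7, 0.7),
            (-0.6, 0.2, 0.8),
            (0.7, 0.1, -0.7),
            (-0.3, 0.8, -0.5),
            (0.8, -0.5, -0.3),
            (0.0, 0.7, -0.7),
            (-0.7, 0.6, 0.3),
        )
        return tuple(
            ClassParams(
                means[i],
                0.06 + 0.035 * i,
                16.0,
                15.0 + 24.0 * i,
                axes[i],
                5.0,
                0.5 + 0.06 * i,
                0.05 + 0.02 * i,
            )
            for i in range(7)
        )
    raise InputError(f"no default class parameters for n_classes={n_classes}")


@dataclass(frozen=True)
class FixtureSpec:
    """Description of a synthetic dataset.

    ``per_class`` is either a single count applied to every class or a
    mapping class id → count (for deliberately imbalanced sets).
    """

    n_classes: int = 2
    per_class: int | dict = 100
    size: int = 224
    noise_sigma: float = 8.0
    seed: int = 0
    background_rgb: tuple[float, float, float] = (221.0, 178.0, 146.0)
    class_params: tuple[ClassParams, ...] | None = None

    def params(self) -> tuple[ClassParams, ...]:
        if self.class_params is not None:
            if len(self.class_params) != self.n_classes:
                raise InputError("class_params length must equal n_classes")
            return self.class_params
        return default_class_params(self.n_classes)

    def counts(self) -> dict[int, int]:
        if isinstance(self.per_class, dict):
            return {int(c): int(n) for c, n in sorted(self.per_class.items())}
        return {c: int(self.per_class) for c in range(self.n_classes)}


def make_image(spec: FixtureSpec, class_id: int, index: int) -> np.ndarray:
    """Render one image; bit-identical for identical (seed, class_id, index)."""
    if not 0 <= class_id < spec.n_classes:
        raise InputError(f"class_id {class_id} out of range [0, {spec.n_classes})")
    p = spec.params()[class_id]
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(class_id, index))
    )
    s = spec.size
    img = np.empty((s, s, 3), dtype=np.float64)
    img[:] = spec.background_rgb
    img += rng.normal(0.0, 3.0, size=3)  # per-image skin-tone shift

    # lesion geometry
    cy, cx = s / 2.0 + rng.uniform(-0.06, 0.06, size=2) * s
    major = 0.30 * s * (1.0 + rng.uniform(-0.10, 0.10))
    minor = major * p.ecc
    phi = rng.uniform(0.0, np.pi)
    psi1, psi2 = rng.uniform(0.0, 2 * np.pi, size=2)

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = -dx * np.sin(phi) + dy * np.cos(phi)
    rho = np.hypot(xr / major, yr / minor)
    ang = np.arctan2(yr, xr)
    border = 1.0 + p.irregularity * np.sin(3 * ang + psi1) + 0.5 * p.irregularity * np.sin(
        5 * ang + psi2
    )
    mask = rho <= border

    # lesion appearance: class mean + per-image color jitter + sinusoidal
    # texture modulating a (mostly chromatic) color direction
    color = np.asarray(p.mean_rgb) + rng.normal(0.0, p.color_std, size=3)
    alpha = np.radians(p.texture_angle)
    phase = rng.uniform(0.0, 2 * np.pi)
    wave = np.sin(2 * np.pi * p.texture_freq * (xx * np.cos(alpha) + yy * np.sin(alpha)) + phase)
    axis = np.asarray(p.color_axis)
    axis = axis / np.linalg.norm(axis)
    lesion = color[None, None, :] + p.texture_amp * wave[..., None] * axis[None, None, :]
    img[mask] = lesion[mask]

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def make_dataset(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[np.ndarray, np.ndarray, Path | None]:
    """Generate all images of a fixture set.

    Returns ``(images, labels, manifest_path)`` where images is an
    (N, size, size, 3) uint8 array. When ``out_dir`` is given, PNG files and
    a ``manifest.csv`` with header ``path,label`` are written there.
    """
    counts = spec.counts()
    if any(n < 1 for n in counts.values()):
        raise InputError("per-class count must be >= 1")
    images, labels, rows = [], [], []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for class_id, n in counts.items():
        for index in range(n):
            img = make_image(spec, class_id, index)
            images.append(img)
            labels.append(class_id)
            if out_path is not None:
                name = f"img_c{class_id}_{index:04d}.png"
                Image.fromarray(img).save(out_path / name)
                rows.append((name, class_id))
    manifest = None
    if out_path is not None:
        manifest = out_path / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label"])
            writer.writerows(rows)
    return np.stack(images), np.asarray(labels), manifest
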