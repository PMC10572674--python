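"""Feature fusion: colored features and hybrid features.

A *colored feature* computes one descriptor independently on each of the
three channels of a color space and concatenates the per-channel histograms
in the fixed channel order (e.g. colored LBP over YCbCr is the 768-long
concatenation ``[LBP(Y), LBP(Cb), LBP(Cr)]``).

A *hybrid feature* concatenates two or more different feature vectors
(e.g. LBP followed by MBC, 256 + 3072 = 3328 values).

Concatenation order is never changed silently: segment provenance records
each (channel, descriptor) slice so the original per-plane vectors can be
recovered exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .colorspace import ColorSpace, to_planes
from .descriptors import DEFAULT_CONFIG, Descriptor, DescriptorConfig, FeatureVector, extract
from .errors import ConfigError, UsageError

__all__ = ["colored_feature", "hybrid_feature", "save_features", "load_features"]


def colored_feature(
    img: np.ndarray,
    descriptor: Descriptor | str,
    space: ColorSpace | str,
    cfg: DescriptorConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """Extract one descriptor from each channel of a color space and
    concatenate, giving a vector 3× the per-channel length."""
    try:
        space = ColorSpace(space.upper() if isinstance(space, str) else space)
    except ValueError:
        raise ConfigError(f"unknown color space: {space!r}") from None
    if space is ColorSpace.GRAY:
        raise ConfigError("colored features require a 3-channel color space, not GRAY")
    parts = [extract(plane, descriptor, cfg) for plane in to_planes(img, space)]
    return hybrid_feature(parts)


def hybrid_feature(parts: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate feature vectors in the given order."""
    if len(parts) < 2:
        raise UsageError("hybrid fusion needs at least 2 feature vectors")
    values = np.concatenate([p.values for p in parts])
    segments = tuple(seg for p in parts for seg in p.segments)
    return FeatureVector(values, segments)


def save_features(X: np.ndarray, meta: dict, path: str | Path) -> None:
    """Persist a feature matrix with a JSON sidecar describing its layout."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), np.asarray(X, dtype=np.float64))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_features(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    X = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return X, meta
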