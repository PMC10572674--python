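"""Histogram-based local texture descriptors.

Each descriptor encodes every pixel of an intensity plane as a small integer
code derived from its 3×3 (or filtered) neighborhood, then summarizes the
plane as a histogram of those codes. Five descriptors are provided, with
fixed per-channel lengths:

========  ======  =========================================================
name      length  code
========  ======  =========================================================
LBP          256  8-bit neighbor-vs-center threshold pattern
LDN           56  (argmax, argmin) pair of the 8 Kirsch compass responses
LDiP          56  8-bit mask of the top-3 |Kirsch response| directions
PHOG         168  gradient-orientation histograms over a 3-level pyramid
MBC         3072  LBP-style codes of monogenic amplitude/phase/orientation
========  ======  =========================================================

Pixels without a full neighborhood are excluded (no padding), so an
unnormalized LBP/LDN/LDiP histogram sums exactly to the interior pixel
count ``(H-2)(W-2)``. With ``normalize=True`` (the default) each histogram
is L1-normalized, which the downstream margin classifiers require.

Neighbor convention: the 8 neighbors are visited clockwise starting at the
top-left corner, and bit ``i`` (weight ``2**i``) corresponds to the i-th
neighbor in that order. A neighbor contributes 1 iff its value is >= the
center value.

Kirsch convention: ``M0`` is the East mask ``[[-3,-3,5],[-3,0,5],[-3,-3,5]]``
and each subsequent mask rotates the ring of coefficients 45° counter-
clockwise (M1 = North-East, ..., M7 = South-East).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, SizeError

__all__ = [
    "Descriptor",
    "DescriptorConfig",
    "FeatureVector",
    "Segment",
    "DESCRIPTOR_LENGTHS",
    "kirsch_masks",
    "kirsch_responses",
    "lbp",
    "ldn",
    "ldip",
    "phog",
    "mbc",
    "extract",
]


class Descriptor(str, Enum):
    LBP = "LBP"
    LDN = "LDN"
    PHOG = "PHOG"
    LDIP = "LDIP"
    MBC = "MBC"


#: Per-channel histogram lengths; fixed by the descriptor definitions.
DESCRIPTOR_LENGTHS = {
    Descriptor.LBP: 256,
    Descriptor.LDN: 56,
    Descriptor.PHOG: 168,
    Descriptor.LDIP: 56,
    Descriptor.MBC: 3072,
}


@dataclass(frozen=True)
class Segment:
    """Provenance of one contiguous slice of a feature vector."""

    channel: str
    descriptor: str
    length: int


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length, non-negative descriptor vector with provenance."""

    values: np.ndarray
    segments: tuple[Segment, ...]

    def __len__(self) -> int:
        return self.values.shape[0]

    def segment_arrays(self) -> list[np.ndarray]:
        """Slice values back into per-segment arrays."""
        out, start = [], 0
        for seg in self.segments:
            out.append(self.values[start : start + seg.length])
            start += seg.length
        return out


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunable descriptor parameters.

    Defaults reproduce the fixed per-channel lengths; a configuration whose
    implied lengths differ is rejected.
    """

    lbp_radius: int = 1
    lbp_neighbors: int = 8
    phog_levels: int = 2  # pyramid levels 0..phog_levels, grid 2^l per side
    phog_bins: int = 8
    phog_signed: bool = True  # orientations span [0°, 360°)
    mbc_components: tuple[str, ...] = ("A", "P", "O")
    mbc_blocks: tuple[int, int] = (2, 2)
    mbc_bins: int = 256
    mbc_scales: int = 1
    mbc_wavelength: float = 4.0  # log-Gabor center wavelength, pixels
    mbc_sigma_on_f: float = 0.65
    mbc_scale_mult: float = 2.0  # wavelength multiplier between scales
    normalize: bool = True

    def validate(self) -> None:
        if self.lbp_radius != 1 or self.lbp_neighbors != 8:
            raise ConfigError("only the 3x3 8-neighbor LBP is supported")
        if self.phog_length != DESCRIPTOR_LENGTHS[Descriptor.PHOG]:
            raise ConfigError(
                f"PHOG config implies length {self.phog_length}, expected "
                f"{DESCRIPTOR_LENGTHS[Descriptor.PHOG]}"
            )
        if self.mbc_length != DESCRIPTOR_LENGTHS[Descriptor.MBC]:
            raise ConfigError(
                f"MBC config implies length {self.mbc_length}, expected "
                f"{DESCRIPTOR_LENGTHS[Descriptor.MBC]}"
            )
        if self.mbc_scales < 1:
            raise ConfigError("mbc_scales must be >= 1")

    @property
    def phog_length(self) -> int:
        return self.phog_bins * sum(4**l for l in range(self.phog_levels + 1))

    @property
    def mbc_length(self) -> int:
        return len(self.mbc_components) * self.mbc_blocks[0] * self.mbc_blocks[1] * self.mbc_bins


DEFAULT_CONFIG = DescriptorConfig()


# ---------------------------------------------------------------------------
# helpers


def _as_plane(plane, min_side: int = 3) -> np.ndarray:
    values = getattr(plane, "values", plane)
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise SizeError(f"expected a 2-D plane, got shape {arr.shape}")
    if arr.shape[0] < min_side or arr.shape[1] < min_side:
        raise SizeError(
            f"plane of shape {arr.shape} is smaller than {min_side}x{min_side}"
        )
    return arr


def _normalize(hist: np.ndarray) -> np.ndarray:
    total = hist.sum()
    return hist / total if total > 0 else hist


# 8 neighbor offsets, clockwise starting top-left; bit i has weight 2**i.
_NEIGHBOR_OFFSETS = (
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
)


def _neighbor_codes(arr: np.ndarray) -> np.ndarray:
    """8-bit threshold codes (neighbor >= center) for all interior pixels."""
    center = arr[1:-1, 1:-1]
    h, w = center.shape
    codes = np.zeros((h, w), dtype=np.int64)
    for bit, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        nb = arr[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        codes += (nb >= center).astype(np.int64) << bit
    return codes


# ---------------------------------------------------------------------------
# Kirsch compass masks


def kirsch_masks() -> np.ndarray:
    """The 8 Kirsch compass masks, shape (8, 3, 3).

    Mask 0 points East; mask k+1 rotates mask k's ring of coefficients 45°
    counterclockwise. Every mask's coefficients sum to zero.
    """
    # ring positions clockwise from the top-left corner
    ring_pos = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    ring0 = np.array([-3, -3, 5, 5, 5, -3, -3, -3])  # East: 5s in column 2
    masks = np.zeros((8, 3, 3), dtype=np.int64)
    for k in range(8):
        ring = np.roll(ring0, -k)
        for val, (r, c) in zip(ring, ring_pos):
            masks[k, r, c] = val
    return masks


_KIRSCH = kirsch_masks()


def kirsch_responses(plane) -> np.ndarray:
    """Correlate a plane with the 8 Kirsch masks.

    Returns an array of shape (8, H-2, W-2): responses at interior pixels
    only (border pixels lack a full 3×3 neighborhood).
    """
    arr = _as_plane(plane).astype(np.int64)
    windows = sliding_window_view(arr, (3, 3))  # (H-2, W-2, 3, 3)
    resp = np.tensordot(windows, _KIRSCH, axes=([2, 3], [1, 2]))  # (H-2, W-2, 8)
    return np.moveaxis(resp, -1, 0)


# ---------------------------------------------------------------------------
# descriptors


def lbp(plane, normalize: bool = True) -> np.ndarray:
    """Local Binary Pattern histogram, length 256."""
    arr = _as_plane(plane)
    codes = _neighbor_codes(arr)
    hist = np.bincount(codes.ravel(), minlength=256).astype(np.float64)
    return _normalize(hist) if normalize else hist


def ldn(plane, normalize: bool = True) -> np.ndarray:
    """Local Directional Number pattern histogram, length 56.

    Per pixel the code pairs the index of the strongest (argmax) and
    weakest (argmin) Kirsch response; ties go to the lowest index, and if
    argmin equals argmax (a flat neighborhood) the argmin is reassigned to
    the lowest index different from the argmax. The (i_max, i_min) pair is
    packed into 8*7 = 56 compact codes.
    """
    resp = kirsch_responses(plane)
    i_max = resp.argmax(axis=0)
    i_min = resp.argmin(axis=0)
    clash = i_min == i_max  # all 8 responses equal
    i_min = np.where(clash, np.where(i_max == 0, 1, 0), i_min)
    code = i_max * 7 + np.where(i_min < i_max, i_min, i_min - 1)
    hist = np.bincount(code.ravel(), minlength=56).astype(np.float64)
    return _normalize(hist) if normalize else hist


def _ldip_code_table() -> tuple[np.ndarray, np.ndarray]:
    valid = np.array([c for c in range(256) if bin(c).count("1") == 3])
    inv = np.full(256, -1, dtype=np.int64)
    inv[valid] = np.arange(valid.size)
    return valid, inv


_LDIP_CODES, _LDIP_INV = _ldip_code_table()


def ldip(plane, normalize: bool = True) -> np.ndarray:
    """Local Directional Pattern histogram, length 56.

    Sets bits at the 3 directions with the largest absolute Kirsch
    response (ties broken toward the lower index), giving an 8-bit code
    with popcount 3; the C(8,3) = 56 valid codes are binned in ascending
    code order.
    """
    resp = kirsch_responses(plane)
    mag = np.abs(resp)
    # stable sort on negated magnitude keeps the lower index first on ties
    order = np.argsort(-mag, axis=0, kind="stable")
    top3 = order[:3]  # (3, h, w)
    code = (1 << top3).sum(axis=0)
    hist = np.bincount(_LDIP_INV[code].ravel(), minlength=56).astype(np.float64)
    return _normalize(hist) if normalize else hist


def _cell_index(n_pix: int, n_cells: int) -> np.ndarray:
    return (np.arange(n_pix) * n_cells) // n_pix


def phog(plane, levels: int = 2, bins: int = 8, normalize: bool = True) -> np.ndarray:
    """Pyramid Histogram of Oriented Gradients, length 168.

    Centered-difference gradients (one-sided at the borders) give a
    magnitude and a signed orientation in [0°, 360°). For pyramid level
    ``l`` the plane is tiled into a ``2^l × 2^l`` grid and each cell
    accumulates a magnitude-weighted orientation histogram with 45° bins.
    Level histograms are concatenated (8·(1+4+16) = 168 values) and
    L1-normalized over the whole vector; a plane with zero total gradient
    yields the zero vector.
    """
    arr = _as_plane(plane, min_side=4).astype(np.float64)
    gy, gx = np.gradient(arr)
    mag = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 360.0
    ori = np.minimum((theta / (360.0 / bins)).astype(np.int64), bins - 1)

    h, w = arr.shape
    parts = []
    for level in range(levels + 1):
        n = 2**level
        cr = _cell_index(h, n)[:, None]
        cc = _cell_index(w, n)[None, :]
        flat = (cr * n + cc) * bins + ori
        hist = np.bincount(flat.ravel(), weights=mag.ravel(), minlength=n * n * bins)
        parts.append(hist)
    vec = np.concatenate(parts)
    return _normalize(vec) if normalize else vec


def _monogenic(arr: np.ndarray, wavelength: float, sigma_on_f: float):
    """Band-passed even part and the two Riesz (odd) parts of a plane."""
    h, w = arr.shape
    v = np.fft.fftfreq(h)[:, None]
    u = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(u, v)
    radius[0, 0] = 1.0  # avoid log(0); the DC gain is zeroed below
    f0 = 1.0 / wavelength
    log_gabor = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * np.log(sigma_on_f) ** 2))
    log_gabor[0, 0] = 0.0
    riesz1 = 1j * u / radius
    riesz2 = 1j * v / radius
    riesz1[0, 0] = 0.0
    riesz2[0, 0] = 0.0

    spectrum = np.fft.fft2(arr) * log_gabor
    even = np.fft.ifft2(spectrum).real
    odd1 = np.fft.ifft2(spectrum * riesz1).real
    odd2 = np.fft.ifft2(spectrum * riesz2).real
    return even, odd1, odd2


def mbc(plane, cfg: DescriptorConfig = DEFAULT_CONFIG, normalize: bool | None = None) -> np.ndarray:
    """Monogenic Binary Coding histogram, length 3072.

    The plane is band-passed with a log-Gabor filter and extended to the
    monogenic signal via the Riesz transform, giving local amplitude
    ``A = sqrt(e² + r1² + r2²)``, phase ``φ = atan2(sqrt(r1²+r2²), e)`` and
    orientation ``θ = atan2(r2, r1)``. Each component map is coded with the
    same 8-bit neighbor comparison as LBP and histogrammed over a 2×2 block
    grid (256 bins per block, each block L1-normalized), giving
    3 components × 4 blocks × 256 bins = 3072 values. With more than one
    scale, per-scale histograms are summed bin-wise before normalization,
    so the length does not depend on the scale count.
    """
    cfg.validate()
    if normalize is None:
        normalize = cfg.normalize
    arr = _as_plane(plane, min_side=8).astype(np.float64)

    br, bc = cfg.mbc_blocks
    n_blocks = br * bc
    acc = np.zeros((len(cfg.mbc_components), n_blocks, cfg.mbc_bins))
    for scale in range(cfg.mbc_scales):
        wavelength = cfg.mbc_wavelength * cfg.mbc_scale_mult**scale
        even, odd1, odd2 = _monogenic(arr, wavelength, cfg.mbc_sigma_on_f)
        odd_mag = np.hypot(odd1, odd2)
        comp_maps = {
            "A": np.sqrt(even**2 + odd1**2 + odd2**2),
            "P": np.arctan2(odd_mag, even),
            "O": np.arctan2(odd2, odd1),
        }
        for ci, comp in enumerate(cfg.mbc_components):
            codes = _neighbor_codes(comp_maps[comp])
            bi = 0
            for rows in np.array_split(codes, br, axis=0):
                for block in np.array_split(rows, bc, axis=1):
                    acc[ci, bi] += np.bincount(
                        block.ravel(), minlength=cfg.mbc_bins
                    )
                    bi += 1
    if normalize:
        for ci in range(acc.shape[0]):
            for bi in range(n_blocks):
                acc[ci, bi] = _normalize(acc[ci, bi])
    return acc.reshape(-1)


# ---------------------------------------------------------------------------
# dispatch


def extract(
    plane, descriptor: Descriptor | str, cfg: DescriptorConfig = DEFAULT_CONFIG
) -> FeatureVector:
    """Compute one descriptor on one plane, wrapped with provenance."""
    try:
        d = Descriptor(descriptor.upper() if isinstance(descriptor, str) else descriptor)
    except ValueError:
        raise ConfigError(f"unknown descriptor: {descriptor!r}") from None
    cfg.validate()
    if d is Descriptor.LBP:
        vec = lbp(plane, normalize=cfg.normalize)
    elif d is Descriptor.LDN:
        vec = ldn(plane, normalize=cfg.normalize)
    elif d is Descriptor.LDIP:
        vec = ldip(plane, normalize=cfg.normalize)
    elif d is Descriptor.PHOG:
        vec = phog(plane, levels=cfg.phog_levels, bins=cfg.phog_bins, normalize=cfg.normalize)
    else:
        vec = mbc(plane, cfg=cfg)
    channel = getattr(plane, "name", "PLANE")
    return FeatureVector(vec, (Segment(channel, d.value, vec.shape[0]),))
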