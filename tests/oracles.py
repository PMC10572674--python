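"""Independent brute-force oracles for the descriptor and statistics tests.

Everything here is written as plain per-pixel loops (and an O(N^2) direct
DFT for the monogenic signal) so it shares no code path with the package
implementation it is used to check.
"""

from __future__ import annotations

import math

import numpy as np

# The eight Kirsch compass masks, written out literally (E, NE, N, NW, W,
# SW, S, SE) rather than generated by rotation.
KIRSCH_MASKS = [
    np.array([[-3, -3, 5], [-3, 0, 5], [-3, -3, 5]]),  # E
    np.array([[-3, 5, 5], [-3, 0, 5], [-3, -3, -3]]),  # NE
    np.array([[5, 5, 5], [-3, 0, -3], [-3, -3, -3]]),  # N
    np.array([[5, 5, -3], [5, 0, -3], [-3, -3, -3]]),  # NW
    np.array([[5, -3, -3], [5, 0, -3], [5, -3, -3]]),  # W
    np.array([[-3, -3, -3], [5, 0, -3], [5, 5, -3]]),  # SW
    np.array([[-3, -3, -3], [-3, 0, -3], [5, 5, 5]]),  # S
    np.array([[-3, -3, -3], [-3, 0, 5], [-3, 5, 5]]),  # SE
]

# neighbor offsets clockwise from top-left; bit i weights 2**i
NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def kirsch_oracle(plane: np.ndarray) -> np.ndarray:
    """(8, H-2, W-2) responses by explicit 3x3 dot products."""
    arr = np.asarray(plane, dtype=np.int64)
    h, w = arr.shape
    out = np.zeros((8, h - 2, w - 2), dtype=np.int64)
    for k, mask in enumerate(KIRSCH_MASKS):
        for r in range(1, h - 1):
            for c in range(1, w - 1):
                out[k, r - 1, c - 1] = int((arr[r - 1 : r + 2, c - 1 : c + 2] * mask).sum())
    return out


def _code_at(arr: np.ndarray, r: int, c: int) -> int:
    code = 0
    for bit, (dr, dc) in enumerate(NEIGHBORS):
        if arr[r + dr, c + dc] >= arr[r, c]:
            code |= 1 << bit
    return code


def lbp_oracle(plane: np.ndarray, normalize: bool = True) -> np.ndarray:
    arr = np.asarray(plane)
    h, w = arr.shape
    hist = np.zeros(256)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            hist[_code_at(arr, r, c)] += 1
    return hist / hist.sum() if normalize and hist.sum() else hist


def ldn_oracle(plane: np.ndarray, normalize: bool = True) -> np.ndarray:
    resp = kirsch_oracle(plane)
    h, w = resp.shape[1:]
    hist = np.zeros(56)
    for r in range(h):
        for c in range(w):
            vals = resp[:, r, c]
            i_max = min(np.flatnonzero(vals == vals.max()))
            i_min = min(np.flatnonzero(vals == vals.min()))
            if i_min == i_max:
                i_min = 1 if i_max == 0 else 0
            hist[i_max * 7 + (i_min if i_min < i_max else i_min - 1)] += 1
    return hist / hist.sum() if normalize and hist.sum() else hist


def ldip_oracle(plane: np.ndarray, normalize: bool = True) -> np.ndarray:
    resp = kirsch_oracle(plane)
    valid = [c for c in range(256) if bin(c).count("1") == 3]
    h, w = resp.shape[1:]
    hist = np.zeros(56)
    for r in range(h):
        for c in range(w):
            mags = np.abs(resp[:, r, c])
            # top 3 by magnitude, ties to the lower direction index
            order = sorted(range(8), key=lambda i: (-mags[i], i))
            code = sum(1 << i for i in order[:3])
            hist[valid.index(code)] += 1
    return hist / hist.sum() if normalize and hist.sum() else hist


def phog_oracle(plane: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Pyramid orientation histograms via explicit per-pixel loops."""
    arr = np.asarray(plane, dtype=np.float64)
    h, w = arr.shape

    def diff(line, i, n):
        if i == 0:
            return line[1] - line[0]
        if i == n - 1:
            return line[n - 1] - line[n - 2]
        return (line[i + 1] - line[i - 1]) / 2.0

    parts = []
    for level in range(3):
        n = 2**level
        hist = np.zeros(n * n * 8)
        for r in range(h):
            for c in range(w):
                gy = diff(arr[:, c], r, h)
                gx = diff(arr[r, :], c, w)
                mag = math.hypot(gx, gy)
                theta = math.degrees(math.atan2(gy, gx)) % 360.0
                b = min(int(theta // 45.0), 7)
                cell = (r * n // h) * n + (c * n // w)
                hist[cell * 8 + b] += mag
        parts.append(hist)
    vec = np.concatenate(parts)
    return vec / vec.sum() if normalize and vec.sum() else vec


def _direct_dft2(arr: np.ndarray) -> np.ndarray:
    """O(N^2) two-dimensional DFT by direct summation (tiny planes only)."""
    h, w = arr.shape
    out = np.zeros((h, w), dtype=complex)
    for ku in range(h):
        for kv in range(w):
            s = 0.0j
            for r in range(h):
                for c in range(w):
                    s += arr[r, c] * np.exp(-2j * np.pi * (ku * r / h + kv * c / w))
            out[ku, kv] = s
    return out


def _direct_idft2(spec: np.ndarray) -> np.ndarray:
    h, w = spec.shape
    out = np.zeros((h, w), dtype=complex)
    for r in range(h):
        for c in range(w):
            s = 0.0j
            for ku in range(h):
                for kv in range(w):
                    s += spec[ku, kv] * np.exp(2j * np.pi * (ku * r / h + kv * c / w))
            out[r, c] = s / (h * w)
    return out


def mbc_oracle(
    plane: np.ndarray,
    wavelength: float = 4.0,
    sigma_on_f: float = 0.65,
    normalize: bool = True,
) -> np.ndarray:
    """MBC histogram via direct DFT monogenic maps + per-pixel coding."""
    arr = np.asarray(plane, dtype=np.float64)
    h, w = arr.shape
    v = np.fft.fftfreq(h)[:, None] * np.ones((1, w))
    u = np.fft.fftfreq(w)[None, :] * np.ones((h, 1))
    radius = np.sqrt(u**2 + v**2)
    radius[0, 0] = 1.0
    lg = np.exp(-(np.log(radius * wavelength) ** 2) / (2.0 * np.log(sigma_on_f) ** 2))
    lg[0, 0] = 0.0
    r1 = 1j * u / radius
    r2 = 1j * v / radius
    r1[0, 0] = 0.0
    r2[0, 0] = 0.0

    spec = _direct_dft2(arr) * lg
    even = _direct_idft2(spec).real
    odd1 = _direct_idft2(spec * r1).real
    odd2 = _direct_idft2(spec * r2).real
    amp = np.sqrt(even**2 + odd1**2 + odd2**2)
    phase = np.arctan2(np.sqrt(odd1**2 + odd2**2), even)
    orient = np.arctan2(odd2, odd1)

    out = []
    for comp in (amp, phase, orient):
        codes = np.zeros((h - 2, w - 2), dtype=int)
        for r in range(1, h - 1):
            for c in range(1, w - 1):
                codes[r - 1, c - 1] = _code_at(comp, r, c)
        ch, cw = codes.shape
        half_r = (ch + 1) // 2  # np.array_split puts the larger part first
        half_c = (cw + 1) // 2
        blocks = [
            codes[:half_r, :half_c],
            codes[:half_r, half_c:],
            codes[half_r:, :half_c],
            codes[half_r:, half_c:],
        ]
        for blk in blocks:
            hist = np.zeros(256)
            for code in blk.ravel():
                hist[code] += 1
            if normalize and hist.sum():
                hist = hist / hist.sum()
            out.append(hist)
    return np.concatenate(out)


def welch_p_oracle(t: float, df: float) -> float:
    """Two-tailed p by numerical quadrature of the t-density."""
    from scipy.integrate import quad

    def pdf(x):
        return (
            math.gamma((df + 1) / 2)
            / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            * (1 + x * x / df) ** (-(df + 1) / 2)
        )

    val, _ = quad(pdf, abs(t), np.inf)
    return 2.0 * val
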