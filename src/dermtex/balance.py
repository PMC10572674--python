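"""Class-imbalance correction with SMOTE.

Dermoscopy collections are heavily imbalanced (in HAM10000 the largest
class, melanocytic nevi, outnumbers the smallest, dermatofibroma, by ~58:1).
SMOTE (Synthetic Minority Oversampling Technique) counters this by
synthesizing minority-class samples on the segments between a real sample
and one of its k nearest same-class neighbors:

    x_new = x + u * (x_nn - x),   u ~ Uniform[0, 1]

Every class is oversampled up to the majority-class count. Original rows
are preserved verbatim (they form the prefix of the output), and the whole
procedure is a deterministic function of the seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import BalanceError, ConfigError

__all__ = ["smote"]


def smote(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every class to the majority-class count.

    Parameters
    ----------
    X, y
        N×D feature matrix and N integer labels in {0..C-1}.
    k
        Number of same-class nearest neighbors (Euclidean) to interpolate
        toward; effectively ``min(k, class size - 1)``.
    seed
        Seeds the single RNG that drives all sampling.

    Returns
    -------
    X_out, y_out with equal per-class counts; rows 0..N-1 are the input
    rows unchanged.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise BalanceError("X and y have different lengths")
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    rng = np.random.default_rng(seed)

    new_X, new_y = [X], [y]
    for c, n_c in zip(classes, counts):
        n_new = target - n_c
        if n_new == 0:
            continue
        if n_c < 2:
            raise BalanceError(
                f"class {c} has a single member; SMOTE needs at least 2"
            )
        Xc = X[y == c]
        k_eff = min(k, n_c - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        # drop the first column (each point is its own nearest neighbor)
        neighbors = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, n_c, size=n_new)
        pick = rng.integers(0, k_eff, size=n_new)
        u = rng.random(n_new)
        anchor = Xc[base]
        partner = Xc[neighbors[base, pick]]
        new_X.append(anchor + u[:, None] * (partner - anchor))
        new_y.append(np.full(n_new, c, dtype=y.dtype))

    return np.concatenate(new_X, axis=0), np.concatenate(new_y)
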