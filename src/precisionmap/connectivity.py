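"""Dense connectivity: correlation matrices, block z-scoring, seed maps,
distance exclusion and edge-density thresholding.

A participant's functional connectome is the Pearson correlation of every
grayordinate's time series with every other, computed over the retained
(censored/sampled) frames only.  Because subcortical BOLD has lower SNR than
cortex, correlations are z-scored separately within structural blocks
(within-hemisphere, inter-hemispheric, within-subcortex, cortex-subcortex)
before template matching.

Matrices are held single-precision with double-precision accumulation; at
full grayordinate resolution a dense double matrix would not be practical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gray_model import DenseTimeseries, GrayordinateSpace, ScalarMap
from .motion_prep import FrameMask

__all__ = [
    "ConnectivityMatrix",
    "block_ids",
    "BLOCK_NAMES",
    "dense_correlation",
    "blockwise_zscore",
    "seed_map",
    "distance_exclude",
    "density_threshold",
]

#: Block labels for the five-block z-scoring scheme.
BLOCK_NAMES = ("LL", "RR", "LR", "SS", "CS")


@dataclass
class ConnectivityMatrix:
    space: GrayordinateSpace
    values: np.ndarray
    normalized: str = "raw_r"  # or "block_z"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        n = self.space.n_gray
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be n_gray x n_gray")
        if not np.allclose(self.values, self.values.T, atol=1e-6):
            raise ValueError("connectivity matrix must be symmetric")


def _retained(ts: DenseTimeseries, mask: FrameMask | None) -> np.ndarray:
    if mask is None:
        return ts.values
    if len(mask.retained) != ts.n_frames:
        raise ValueError("mask length disagrees with time series")
    return ts.values[mask.retained]


def dense_correlation(ts: DenseTimeseries,
                      mask: FrameMask | None = None) -> ConnectivityMatrix:
    """Pearson correlation among all grayordinates over retained frames."""
    X = _retained(ts, mask)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 retained frames for correlation")
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance grayordinates among retained frames: "
            f"{zero[:20].tolist()}")
    Xc = (X - X.mean(axis=0)) / sd
    C = (Xc.T @ Xc) / X.shape[0]
    C = np.asarray((C + C.T) / 2.0)
    np.fill_diagonal(C, 1.0)
    return ConnectivityMatrix(space=ts.space, values=C.astype(np.float32),
                              normalized="raw_r")


def block_ids(space: GrayordinateSpace) -> np.ndarray:
    """Map every off-diagonal entry to one of the five structural blocks.

    Returns an n x n integer matrix indexing into :data:`BLOCK_NAMES`
    (diagonal entries get -1 and belong to no block).
    """
    tag = space.structure
    left = tag == "LEFT_CORTEX"
    right = tag == "RIGHT_CORTEX"
    sub = tag == "SUBCORTEX"
    cortex = left | right
    n = space.n_gray
    out = np.full((n, n), -1, dtype=np.int8)
    out[np.ix_(left, left)] = 0
    out[np.ix_(right, right)] = 1
    out[np.ix_(left, right)] = 2
    out[np.ix_(right, left)] = 2
    out[np.ix_(sub, sub)] = 3
    out[np.ix_(cortex, sub)] = 4
    out[np.ix_(sub, cortex)] = 4
    np.fill_diagonal(out, -1)
    return out


def blockwise_zscore(C: ConnectivityMatrix,
                     blocks: np.ndarray | None = None) -> ConnectivityMatrix:
    """Z-score each structural block with its own mean and s.d.

    Normalizes connectivity separately within each hemisphere, between
    hemispheres, within subcortex and cortex-to-subcortex, compensating for
    the lower subcortical SNR.
    """
    if C.normalized != "raw_r":
        raise ValueError("input must be a raw correlation matrix")
    if blocks is None:
        blocks = block_ids(C.space)
    V = C.values.astype(np.float64)
    out = np.zeros_like(V)
    for b in range(len(BLOCK_NAMES)):
        sel = blocks == b
        if not sel.any():
            continue
        x = V[sel]
        sd = x.std()
        if sd == 0:
            raise ValueError(f"constant block {BLOCK_NAMES[b]}; cannot z-score")
        out[sel] = (x - x.mean()) / sd
    out = (out + out.T) / 2.0  # blocks are symmetric, so this is exact
    return ConnectivityMatrix(space=C.space, values=out.astype(np.float32),
                              normalized="block_z")


def seed_map(ts: DenseTimeseries, seed: np.ndarray,
             mask: FrameMask | None = None,
             name: str = "seed") -> ScalarMap:
    """Correlate the mean series of a seed set with every grayordinate."""
    seed = np.asarray(seed, dtype=int).ravel()
    if seed.size == 0:
        raise ValueError("seed set is empty")
    X = _retained(ts, mask)
    s = X[:, seed].mean(axis=1)
    if s.std() == 0:
        raise ValueError("seed mean series has zero variance")
    sc = (s - s.mean()) / s.std()
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xc = (X - X.mean(axis=0)) / sd
    r = (sc @ Xc) / X.shape[0]
    r = np.where(sd == 0, 0.0, r)
    return ScalarMap(space=ts.space, name=name, values=np.clip(r, -1.0, 1.0))


def distance_exclude(C: ConnectivityMatrix, radius_mm: float = 30.0,
                     coords: np.ndarray | None = None) -> ConnectivityMatrix:
    """Zero out connections between grayordinates closer than ``radius_mm``.

    Short-range correlations are inflated by spatial smoothing; removing
    them avoids biasing graph community detection toward local cliques.
    The diagonal is always zeroed.
    """
    if coords is None:
        coords = C.space.coords
    from scipy.spatial.distance import squareform, pdist

    V = C.values.copy()
    close = squareform(pdist(coords)) < radius_mm
    V[close] = 0.0
    np.fill_diagonal(V, 0.0)
    return ConnectivityMatrix(space=C.space, values=V,
                              normalized=C.normalized)


def density_threshold(C: ConnectivityMatrix,
                      density_percent: float) -> np.ndarray:
    """Keep the top ``density_percent`` % of off-diagonal pairs by weight.

    Returns an undirected weighted edge list, an array of shape (m, 3) with
    columns (i, j, w), i < j.  Ranking is by signed weight, descending; ties
    are broken by (i, j) index order so the result is fully deterministic.
    """
    if not (0 < density_percent <= 100):
        raise ValueError("density must be in (0, 100]")
    n = C.space.n_gray
    iu, ju = np.triu_indices(n, k=1)
    w = C.values[iu, ju].astype(np.float64)
    n_pairs = len(w)
    m = int(np.floor(density_percent / 100.0 * n_pairs))
    if m < 1:
        raise ValueError(
            f"density {density_percent}% of {n_pairs} pairs keeps no edges")
    order = np.lexsort((ju, iu, -w))  # weight desc, then (i, j) asc
    top = order[:m]
    return np.column_stack([iu[top], ju[top], w[top]])
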