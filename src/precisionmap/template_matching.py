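"""Template matching: eta-squared similarity and winner-take-all assignment.

Each grayordinate's whole-brain connectivity row (block-z-scored, then
binarized at z >= 1) is compared to each network template's binarized
support with the eta-squared image-similarity coefficient.  With
m_i = (a_i + b_i) / 2 and Mbar = mean(m):

    eta2(a, b) = 1 - [sum (a_i - m_i)^2 + (b_i - m_i)^2]
                     / [sum (a_i - Mbar)^2 + (b_i - Mbar)^2]

eta2 is symmetric, equals 1 for identical patterns and 0 for maximally
dissimilar ones.  Winner-take-all assigns each grayordinate to the network
with the largest eta2; overlapping assignment (see :mod:`precisionmap.omni`)
instead thresholds each network's eta2 distribution separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gray_model import GrayordinateSpace, LabelMap
from .connectivity import ConnectivityMatrix
from .templates import TemplateSet

logger = logging.getLogger(__name__)

__all__ = ["EtaProfile", "eta_squared", "eta_profiles", "winner_take_all"]


@dataclass
class EtaProfile:
    """K networks x n_gray eta-squared similarities in [0, 1]."""

    space: GrayordinateSpace
    values: np.ndarray
    palette: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.palette = tuple(self.palette)
        if self.values.shape != (len(self.palette), self.space.n_gray):
            raise ValueError("profile shape must be (len(palette), n_gray)")
        if self.values.size and (self.values.min() < -1e-9
                                 or self.values.max() > 1 + 1e-9):
            raise ValueError("eta-squared values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)


def eta_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Eta-squared similarity between two equal-length patterns."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    m = (a + b) / 2.0
    mbar = m.mean()
    den = np.sum((a - mbar) ** 2 + (b - mbar) ** 2)
    if den == 0:
        raise ValueError("both patterns constant and equal: eta2 undefined")
    num = np.sum((a - m) ** 2 + (b - m) ** 2)
    return float(1.0 - num / den)


def _eta_squared_binary_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized eta2 between all rows of A (n x G) and rows of B (K x G).

    Uses the closed form that follows from m = (a+b)/2:
    numerator = ||a - b||^2 / 2, denominator = ||a||^2 + ||b||^2
    - (sum a + sum b)^2 / (2G).  Exact for any real inputs, applied here to
    binarized rows.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    G = A.shape[1]
    a2 = (A ** 2).sum(axis=1)                # (n,)
    b2 = (B ** 2).sum(axis=1)                # (K,)
    asum = A.sum(axis=1)
    bsum = B.sum(axis=1)
    cross = A @ B.T                          # (n, K)
    num = (a2[:, None] + b2[None, :] - 2.0 * cross) / 2.0
    den = (a2[:, None] + b2[None, :]
           - (asum[:, None] + bsum[None, :]) ** 2 / (2.0 * G))
    with np.errstate(invalid="ignore", divide="ignore"):
        eta = 1.0 - num / den
    eta[den <= 0] = 0.0
    return eta


def eta_profiles(C: ConnectivityMatrix, templates: TemplateSet,
                 z_cut: float = 1.0) -> EtaProfile:
    """Eta-squared of every grayordinate's thresholded row vs every template.

    Each row of the block-z-scored connectivity matrix is binarized at
    ``z >= z_cut`` and compared (over all grayordinates, zeros included) to
    each template's binary support.  Grayordinates whose binarized row is
    empty get a zero profile column; their count is logged.
    """
    if C.normalized != "block_z":
        raise ValueError("connectivity must be block-z-scored first")
    if templates.n_gray != C.space.n_gray:
        raise ValueError("templates and connectivity live in different spaces")
    rows = (C.values >= z_cut).astype(np.float64)
    empty = ~rows.any(axis=1)
    n_empty = int(empty.sum())
    if n_empty:
        logger.warning("%d grayordinates have empty thresholded rows", n_empty)
    supports = templates.support_matrix().astype(np.float64)
    eta = _eta_squared_binary_block(rows, supports).T  # (K, n_gray)
    eta[:, empty] = 0.0
    return EtaProfile(space=C.space, values=np.clip(eta, 0.0, 1.0),
                      palette=templates.palette,
                      provenance={"z_cut": z_cut, "n_empty_rows": n_empty})


def winner_take_all(profile: EtaProfile) -> LabelMap:
    """Assign each grayordinate to its maximum-eta2 network.

    All-zero profile columns stay unassigned (label 0).  Exact ties go to
    the lowest palette index; the tie count is logged.
    """
    V = profile.values
    labels = np.argmax(V, axis=0) + 1          # argmax takes lowest index on ties
    col_max = V.max(axis=0)
    labels[col_max <= 0.0] = 0
    n_ties = int(((V == col_max[None, :]).sum(axis=0) > 1)[col_max > 0].sum())
    if n_ties:
        logger.info("winner-take-all resolved %d exact ties to the lowest "
                    "palette index", n_ties)
    return LabelMap(space=profile.space, labels=labels,
                    palette=profile.palette)
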