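"""Overlapping MultiNetwork Imaging (OMNI).

Winner-take-all forces every grayordinate into exactly one network, but
association cortex plausibly participates in several.  OMNI instead derives
a separate, data-driven eta-squared threshold for each network from the
shape of that network's eta-squared distribution across grayordinates: the
distribution is characteristically bimodal (a low mode of non-members and a
high mode of members), and the valley between the modes is the natural
membership cut.  A grayordinate joins every network whose threshold its
eta-squared exceeds — possibly several, possibly none.

Procedure per network: histogram the eta-squared values into 10,000 bins on
[0, 1], interpolate the counts with a cubic spline, smooth with a 2,000-bin
Savitzky-Golay filter, and take the first local minimum (derivative sign
change - to +) of the smoothed curve between bins 4,000 and 7,000
(eta-squared 0.4-0.7).  If no interior minimum exists in the window (a
unimodal distribution), the argmin of the smoothed curve in the window is
used and flagged as a fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .gray_model import OverlapMap, ScalarMap
from .template_matching import EtaProfile

logger = logging.getLogger(__name__)

__all__ = [
    "EtaDistribution",
    "NetworkThreshold",
    "eta_histogram",
    "find_bimodal_threshold",
    "omni_thresholds",
    "omni_assign",
    "overlap_count",
]

N_BINS = 10_000


@dataclass
class EtaDistribution:
    """Fixed-support histogram of one network's eta-squared values."""

    network: str
    bin_edges: np.ndarray      # 10,001 edges over [0, 1]
    counts: np.ndarray         # 10,000 raw counts
    smoothed: np.ndarray       # cubic-spline interpolant at bin centers

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class NetworkThreshold:
    network: str
    eta_star: float
    bin_index: int
    fallback_used: bool = False


def eta_histogram(values: np.ndarray, network: str = "") -> EtaDistribution:
    """Histogram eta-squared values into 10,000 bins on [0, 1].

    Values outside [0, 1] are clamped with a warning.  The stored
    ``smoothed`` curve is the cubic-spline interpolant of the counts
    evaluated at bin centers (the pre-filter curve).
    """
    v = np.asarray(values, dtype=float).ravel()
    n_out = int(((v < 0) | (v > 1)).sum())
    if n_out:
        logger.warning("clamped %d eta-squared values outside [0, 1]", n_out)
        v = np.clip(v, 0.0, 1.0)
    edges = np.linspace(0.0, 1.0, N_BINS + 1)
    counts, _ = np.histogram(v, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    spline = CubicSpline(centers, counts.astype(float))
    return EtaDistribution(network=network, bin_edges=edges,
                           counts=counts.astype(float),
                           smoothed=spline(centers))


def find_bimodal_threshold(dist: EtaDistribution,
                           window: tuple[int, int] = (4000, 7000),
                           sg_window: int = 2000,
                           sg_order: int = 3) -> NetworkThreshold:
    """Locate the valley of a bimodal eta-squared distribution.

    The spline curve is smoothed with a Savitzky-Golay filter (window
    ``sg_window`` bins, polynomial order ``sg_order``); the threshold is the
    bin center at the first - to + sign change of the central-difference
    derivative inside ``window``.  Unimodal shapes fall back to the argmin
    of the smoothed curve in the window, with ``fallback_used=True``.
    """
    lo, hi = window
    if not (0 <= lo < hi <= N_BINS):
        raise ValueError("window must lie within the 10,000-bin support")
    win = min(sg_window, len(dist.smoothed))
    if win % 2 == 0:
        win -= 1  # savgol needs an odd window
    smooth = savgol_filter(dist.smoothed, window_length=win,
                           polyorder=min(sg_order, win - 1))
    # derivative of the smoothed curve, taken analytically from the same
    # local polynomial fit: central differences of `smooth` flicker sign at
    # single-bin scale on spiky 10,000-bin histograms and produce spurious
    # "valleys" at the window edge
    deriv = savgol_filter(dist.smoothed, window_length=win,
                          polyorder=min(sg_order, win - 1), deriv=1)
    centers = dist.bin_centers
    sign = np.sign(deriv[lo:hi])
    # interior minima: derivative sign changes - to + within the window.  A
    # crossing only counts as a between-peaks valley if the smoothed curve
    # carries real mass on both sides of it (filter wiggles in the empty
    # stretches of a unimodal histogram); among qualifying valleys, take the
    # deepest — a shoulder on the flank of the low mode can produce a
    # shallow local minimum well before the true inter-mode valley.
    cross = np.flatnonzero((sign[:-1] < 0) & (sign[1:] > 0))
    tol = 0.01 * smooth.max()
    valleys = []
    for c in cross:
        idx = lo + int(c) + 1
        if (smooth[:idx].max(initial=-np.inf) > smooth[idx] + tol
                and smooth[idx:].max(initial=-np.inf) > smooth[idx] + tol):
            valleys.append(idx)
    if valleys:
        idx = min(valleys, key=lambda i: (smooth[i], i))
        return NetworkThreshold(network=dist.network,
                                eta_star=float(centers[idx]),
                                bin_index=int(idx), fallback_used=False)
    idx = lo + int(np.argmin(smooth[lo:hi]))
    return NetworkThreshold(network=dist.network,
                            eta_star=float(centers[idx]),
                            bin_index=int(idx), fallback_used=True)


def omni_thresholds(profile: EtaProfile, **kwargs) -> list[NetworkThreshold]:
    """Per-network bimodal thresholds for one participant's eta profile."""
    out = []
    for k, name in enumerate(profile.palette):
        dist = eta_histogram(profile.values[k], network=name)
        out.append(find_bimodal_threshold(dist, **kwargs))
    return out


def omni_assign(profile: EtaProfile,
                thresholds: list[NetworkThreshold]) -> OverlapMap:
    """Assign each grayordinate to every network whose threshold it exceeds."""
    if len(thresholds) != len(profile.palette):
        raise ValueError("need one threshold per network")
    by_name = {t.network: t for t in thresholds}
    missing = [n for n in profile.palette if n not in by_name]
    if missing:
        raise ValueError(f"missing thresholds for networks: {missing}")
    member = np.zeros_like(profile.values, dtype=np.uint8)
    for k, name in enumerate(profile.palette):
        member[k] = profile.values[k] > by_name[name].eta_star
    return OverlapMap(space=profile.space, membership=member,
                      palette=profile.palette)


def overlap_count(om: OverlapMap, name: str = "overlap_count") -> ScalarMap:
    """Number of networks observed at each grayordinate."""
    return ScalarMap(space=om.space, name=name,
                     values=om.counts().astype(float))
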