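"""Population probabilistic atlases and their derivatives.

Across a cohort of individual network maps, the probability map of network k
is the fraction of participants assigning k at each grayordinate.  Regions
of high probability (>= 0.8 by default) form a probabilistic ROI set —
contiguous clusters of at least 30 grayordinates where network identity is
nearly invariant across people.  Averaging per-participant overlapping-
network counts instead yields the integration-zone map; thresholding the
mean count (default 2.2 networks) marks hub-like regions where several
networks converge across the population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from .gray_model import (DenseTimeseries, GrayordinateSpace, LabelMap,
                         OverlapMap, ScalarMap)
from .motion_prep import FrameMask

logger = logging.getLogger(__name__)

__all__ = [
    "ProbabilityAtlas",
    "Parcel",
    "Parcellation",
    "IntegrationZoneMap",
    "probability_maps",
    "derive_roiset",
    "integration_zones",
    "parcellate_timeseries",
    "parcel_connectivity",
    "network_block_stats",
]


@dataclass
class ProbabilityAtlas:
    """Per-network assignment frequency across a cohort."""

    space: GrayordinateSpace
    values: np.ndarray              # K x n_gray in [0, 1]
    palette: tuple[str, ...]
    n_participants: int
    source_mode: str = "single_assignment"   # or "omni"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.palette = tuple(self.palette)
        if self.values.shape != (len(self.palette), self.space.n_gray):
            raise ValueError("atlas shape must be (len(palette), n_gray)")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        colsum = self.values.sum(axis=0)
        if self.source_mode == "single_assignment" and colsum.max() > 1 + 1e-9:
            raise ValueError("single-assignment column sums must be <= 1")


@dataclass
class Parcel:
    parcel_id: int
    network: str
    members: np.ndarray

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=int).ravel()

    @property
    def size(self) -> int:
        return self.members.size


@dataclass
class Parcellation:
    space: GrayordinateSpace
    parcels: list[Parcel]
    palette: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        self.palette = tuple(self.palette)

    @property
    def n_parcels(self) -> int:
        return len(self.parcels)

    def to_labelmap(self) -> LabelMap:
        """Network labels of the parcellation (parcels collapse to networks)."""
        labels = np.zeros(self.space.n_gray, dtype=int)
        for p in self.parcels:
            labels[p.members] = self.palette.index(p.network) + 1
        return LabelMap(space=self.space, labels=labels, palette=self.palette)

    def parcel_networks(self) -> list[str]:
        return [p.network for p in self.parcels]


@dataclass
class IntegrationZoneMap:
    """Cohort-mean network counts and the thresholded hub-zone parcels."""

    mean_counts: ScalarMap
    threshold: float
    parcels: list[Parcel] = field(default_factory=list)

    def zone_mask(self) -> np.ndarray:
        mask = np.zeros(self.mean_counts.space.n_gray, dtype=bool)
        for p in self.parcels:
            mask[p.members] = True
        return mask


def probability_maps(cohort: Sequence[LabelMap | OverlapMap]) -> ProbabilityAtlas:
    """Assignment frequency per network across a cohort of maps.

    P[k, g] = (number of participants assigning network k at g) / N.  The
    cohort may hold winner-take-all ``LabelMap``s (single-assignment mode) or
    OMNI ``OverlapMap``s (omni mode, column sums may exceed 1).
    """
    if not cohort:
        raise ValueError("empty cohort")
    first = cohort[0]
    palette = first.palette
    space = first.space
    K = len(palette)
    acc = np.zeros((K, space.n_gray))
    mode = "omni" if isinstance(first, OverlapMap) else "single_assignment"
    for m in cohort:
        if m.palette != palette:
            raise ValueError("palette mismatch across cohort")
        if m.space.n_gray != space.n_gray:
            raise ValueError("space mismatch across cohort")
        if isinstance(m, OverlapMap):
            if mode != "omni":
                raise ValueError("cannot mix label and overlap maps")
            acc += m.membership
        else:
            if mode != "single_assignment":
                raise ValueError("cannot mix label and overlap maps")
            for k in range(K):
                acc[k] += m.labels == (k + 1)
    return ProbabilityAtlas(space=space, values=acc / len(cohort),
                            palette=palette, n_participants=len(cohort),
                            source_mode=mode)


def _structure_components(space: GrayordinateSpace, mask: np.ndarray,
                          adjacency: sparse.spmatrix | None = None
                          ) -> list[np.ndarray]:
    """Connected components of ``mask`` that never cross cortex/subcortex
    structure boundaries."""
    A = (adjacency if adjacency is not None else space.get_adjacency()).tocoo()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    pos = -np.ones(space.n_gray, dtype=int)
    pos[idx] = np.arange(idx.size)
    keep = (mask[A.row] & mask[A.col]
            & (space.structure[A.row] == space.structure[A.col]))
    sub = sparse.coo_matrix((np.ones(keep.sum()),
                             (pos[A.row[keep]], pos[A.col[keep]])),
                            shape=(idx.size, idx.size))
    n_comp, comp = sparse.csgraph.connected_components(sub, directed=False)
    return [idx[comp == c] for c in range(n_comp)]


def derive_roiset(atlas: ProbabilityAtlas, p_threshold: float = 0.8,
                  adjacency: sparse.spmatrix | None = None,
                  min_cluster: int = 30) -> Parcellation:
    """Probabilistic ROI set: high-probability clusters per network.

    For each network, take the connected components of
    {g : P[k, g] >= p_threshold} and keep those of at least ``min_cluster``
    grayordinates.  Parcel ids are assigned network-major, then by
    descending size, so output ordering is deterministic.  At thresholds
    above 0.5 on a single-assignment atlas, parcels of different networks
    are automatically disjoint.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    parcels: list[Parcel] = []
    pid = 1
    for k, name in enumerate(atlas.palette):
        mask = atlas.values[k] >= p_threshold
        comps = _structure_components(atlas.space, mask, adjacency)
        comps = [c for c in comps if c.size >= min_cluster]
        comps.sort(key=lambda c: (-c.size, c.min(initial=0)))
        for c in comps:
            parcels.append(Parcel(parcel_id=pid, network=name, members=c))
            pid += 1
    if not parcels:
        logger.warning("no cluster of >= %d grayordinates reaches P >= %g",
                       min_cluster, p_threshold)
    return Parcellation(space=atlas.space, parcels=parcels,
                        palette=atlas.palette, threshold=p_threshold)


def integration_zones(cohort_counts: Sequence[ScalarMap],
                      threshold: float = 2.2,
                      adjacency: sparse.spmatrix | None = None,
                      min_cluster: int = 30) -> IntegrationZoneMap:
    """Cohort-mean overlap counts thresholded into integration-zone parcels.

    ``cohort_counts`` are per-participant overlap-count maps (networks
    observed at each grayordinate).  The mean count is thresholded at
    ``threshold`` networks (default 2.2) and contiguous clusters of at least
    ``min_cluster`` grayordinates become the integration-zone region set.
    """
    if not cohort_counts:
        raise ValueError("empty cohort")
    space = cohort_counts[0].space
    M = np.stack([c.values for c in cohort_counts])
    mean = ScalarMap(space=space, name="mean_overlap_count",
                     values=M.mean(axis=0))
    mask = mean.values >= threshold
    comps = _structure_components(space, mask, adjacency)
    comps = [c for c in comps if c.size >= min_cluster]
    comps.sort(key=lambda c: (-c.size, c.min(initial=0)))
    parcels = [Parcel(parcel_id=i + 1, network="integration", members=c)
               for i, c in enumerate(comps)]
    return IntegrationZoneMap(mean_counts=mean, threshold=threshold,
                              parcels=parcels)


def parcellate_timeseries(ts: DenseTimeseries,
                          parcellation: Parcellation) -> np.ndarray:
    """Mean member time series per parcel: (n_parcels, T)."""
    if not parcellation.parcels:
        raise ValueError("parcellation has no parcels")
    return np.stack([ts.values[:, p.members].mean(axis=1)
                     for p in parcellation.parcels])


def parcel_connectivity(parcel_series: np.ndarray,
                        mask: FrameMask | None = None) -> np.ndarray:
    """Pearson correlation among parcel time series (parcels x parcels)."""
    X = np.asarray(parcel_series, dtype=float).T      # frames x parcels
    if mask is not None:
        X = X[mask.retained]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 frames for parcel connectivity")
    return np.corrcoef(X.T)


def network_block_stats(conn: np.ndarray,
                        parcel_networks: Sequence[str]) -> dict:
    """Within- and between-network mean connectivity.

    ``within[name]`` is the mean off-diagonal correlation among that
    network's parcels (None when the network has a single parcel);
    ``between`` is the mean over parcel pairs from different networks;
    ``within_mean`` averages within-network values over networks that have
    one.
    """
    conn = np.asarray(conn, dtype=float)
    nets = list(parcel_networks)
    if conn.shape != (len(nets), len(nets)):
        raise ValueError("connectivity shape disagrees with parcel networks")
    within: dict[str, float | None] = {}
    for name in dict.fromkeys(nets):
        idx = [i for i, n in enumerate(nets) if n == name]
        if len(idx) < 2:
            within[name] = None
            continue
        sub = conn[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        within[name] = float(sub[iu].mean())
    iu = np.triu_indices(len(nets), k=1)
    cross = [conn[i, j] for i, j in zip(*iu) if nets[i] != nets[j]]
    have = [v for v in within.values() if v is not None]
    return {
        "within": within,
        "within_mean": float(np.mean(have)) if have else None,
        "between": float(np.mean(cross)) if cross else None,
    }
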