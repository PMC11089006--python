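"""Multi-density community detection with consensus and Jaccard relabeling.

Graph community detection (e.g. the map-equation Infomap optimizer) run on a
density-thresholded connectivity graph yields anonymous communities at each
edge density.  The bespoke layer implemented here turns those solutions into
named network maps:

1. at each density, every community is matched to the reference group
   network with which it has the highest Jaccard index, iterating networks
   in a priority order (large, well-known networks first); matches below
   Jaccard 0.1 stay unassigned;
2. a consensus across densities gives each grayordinate the label it holds
   at the *sparsest* density where it was successfully assigned;
3. contiguous labeled clusters smaller than 30 grayordinates are merged into
   the neighboring network with the largest total size, iterating to a
   fixed point.

The optimizer itself is a pluggable backend (any callable mapping an edge
list to a partition).  The shipped reference backend — connected components
followed by a deterministic, seeded label-propagation refinement — makes the
layer fully testable without the map-equation package; an adapter for
python-igraph's Infomap is provided when that library is installed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse

from .gray_model import GrayordinateSpace, LabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "CommunitySolution",
    "ConsensusConfig",
    "detect_communities",
    "reference_backend",
    "igraph_infomap_backend",
    "jaccard_index",
    "match_communities",
    "consensus_across_densities",
    "clean_small_clusters",
    "drop_small_networks",
]

#: Paper-style priority tiers: large, well-known networks are claimed first.
DEFAULT_PRIORITY = ("DMN", "Vis", "SMd", "FPN", "CO", "DAN",
                    "VAN", "Sal", "PMN", "PON", "Tpole", "MTL",
                    "SMl", "Aud")


@dataclass
class CommunitySolution:
    """An anonymous partition at one edge density (0 = in no community)."""

    density_percent: float
    communities: np.ndarray

    def __post_init__(self) -> None:
        self.communities = np.asarray(self.communities, dtype=int).ravel()
        self.communities = _canonicalize(self.communities)

    def community_sets(self) -> dict[int, np.ndarray]:
        out = {}
        for cid in np.unique(self.communities):
            if cid != 0:
                out[int(cid)] = np.flatnonzero(self.communities == cid)
        return out


def _canonicalize(comms: np.ndarray) -> np.ndarray:
    """Relabel community ids to 1..m in order of first appearance."""
    out = np.zeros_like(comms)
    mapping: dict[int, int] = {}
    for i, c in enumerate(comms):
        if c == 0:
            continue
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out[i] = mapping[c]
    return out


@dataclass
class ConsensusConfig:
    densities: tuple[float, ...] = (0.3, 0.4, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    min_jaccard: float = 0.1
    network_priority: tuple[str, ...] = DEFAULT_PRIORITY
    min_cluster: int = 30
    min_network_group: int = 400
    extended_densities: tuple[float, ...] = (4.0, 5.0)

    def __post_init__(self) -> None:
        d = tuple(self.densities)
        if list(d) != sorted(d):
            raise ValueError("densities must be ascending")
        self.densities = d


# ---------------------------------------------------------------------------
# backends


def reference_backend(edges: np.ndarray, n_nodes: int,
                      seed: int = 0) -> np.ndarray:
    """Deterministic test backend: components + seeded label propagation.

    Nodes start in their connected component, then a weighted asynchronous
    label-propagation sweep (node order drawn once from ``seed``, ties to the
    smallest label) refines until stable.  Isolated nodes get community 0.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.size == 0:
        raise ValueError("empty edge list")
    i = edges[:, 0].astype(int)
    j = edges[:, 1].astype(int)
    w = np.abs(edges[:, 2])
    A = sparse.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])),
                          shape=(n_nodes, n_nodes)).tocsr()
    degree = np.asarray(A.sum(axis=1)).ravel()
    connected = degree > 0

    labels = np.arange(1, n_nodes + 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_nodes)
    indptr, indices, data = A.indptr, A.indices, A.data
    for _ in range(100):
        changed = 0
        for v in order:
            if not connected[v]:
                continue
            nbr = indices[indptr[v]:indptr[v + 1]]
            wts = data[indptr[v]:indptr[v + 1]]
            if nbr.size == 0:
                continue
            votes: dict[int, float] = {}
            for u, wt in zip(labels[nbr], wts):
                votes[u] = votes.get(u, 0.0) + wt
            best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            if best != labels[v]:
                labels[v] = best
                changed += 1
        if changed == 0:
            break
    out = labels.copy()
    out[~connected] = 0
    return _canonicalize(out)


def igraph_infomap_backend(edges: np.ndarray, n_nodes: int,
                           seed: int = 0) -> np.ndarray:
    """Map-equation optimizer via python-igraph (optional dependency)."""
    import igraph as ig

    edges = np.asarray(edges, dtype=float)
    g = ig.Graph(n=n_nodes,
                 edges=[(int(a), int(b)) for a, b in edges[:, :2]],
                 edge_attrs={"weight": np.abs(edges[:, 2]).tolist()})
    ig.set_random_number_generator(__import__("random").Random(seed))
    vc = g.community_infomap(edge_weights="weight")
    labels = np.asarray(vc.membership, dtype=int) + 1
    labels[np.asarray(g.degree()) == 0] = 0
    return _canonicalize(labels)


def detect_communities(edges: np.ndarray, n_nodes: int,
                       density_percent: float = 0.0,
                       backend: Callable[..., np.ndarray] | str = "reference",
                       seed: int = 0) -> CommunitySolution:
    """Run a community-detection backend on a weighted undirected edge list."""
    if isinstance(backend, str):
        if backend == "reference":
            fn = reference_backend
        elif backend == "infomap":
            fn = igraph_infomap_backend
        else:
            raise ValueError(f"unknown backend {backend!r}")
        name = backend
    else:
        fn, name = backend, getattr(backend, "__name__", "custom")
    try:
        comms = fn(edges, n_nodes, seed=seed)
    except Exception as exc:
        raise RuntimeError(f"community backend {name!r} failed: {exc}") from exc
    return CommunitySolution(density_percent=density_percent,
                             communities=comms)


# ---------------------------------------------------------------------------
# Jaccard relabeling


def jaccard_index(a: np.ndarray, b: np.ndarray) -> float:
    """|A intersect B| / |A union B|; 0 when both sets are empty."""
    sa, sb = set(np.asarray(a).ravel().tolist()), set(np.asarray(b).ravel().tolist())
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def match_communities(sol: CommunitySolution, reference: LabelMap,
                      cfg: ConsensusConfig | None = None) -> LabelMap:
    """Name each anonymous community after its best-Jaccard reference network.

    Networks are offered in priority order; within each network, candidate
    communities compete by Jaccard, the highest-Jaccard community claims the
    name first, and a name may be claimed by several communities (a network
    can appear as several communities at sparse densities).  A community
    whose best remaining Jaccard is below ``cfg.min_jaccard`` stays
    unassigned — it is a genuinely individual community with no group
    counterpart.
    """
    cfg = cfg or ConsensusConfig()
    priority = [n for n in cfg.network_priority if n in reference.palette]
    priority += [n for n in reference.palette if n not in priority]

    comm_sets = sol.community_sets()
    ref_sets = {name: np.flatnonzero(reference.labels ==
                                     (reference.palette.index(name) + 1))
                for name in priority}
    jac = {cid: {name: jaccard_index(members, ref_sets[name])
                 for name in priority}
           for cid, members in comm_sets.items()}

    assigned: dict[int, str] = {}
    # phase 1 — one claim per network, in priority order: the unassigned
    # community with the highest Jaccard (>= min_jaccard) wins the name;
    # competitors fall through to their next-best match
    for name in priority:
        pool = [cid for cid in comm_sets if cid not in assigned]
        if not pool:
            break
        best = max(pool, key=lambda cid: (jac[cid][name], -cid))
        if jac[best][name] >= cfg.min_jaccard:
            assigned[best] = name
    # phase 2 — leftover communities take their overall best-Jaccard network
    # (several communities may share a name: a network can split into
    # multiple communities at sparse densities)
    for cid in comm_sets:
        if cid in assigned:
            continue
        best_net = max(priority, key=lambda n: jac[cid][n])
        if jac[cid][best_net] >= cfg.min_jaccard:
            assigned[cid] = best_net

    labels = np.zeros(reference.space.n_gray, dtype=int)
    for cid, name in assigned.items():
        labels[comm_sets[cid]] = reference.palette.index(name) + 1
    return LabelMap(space=reference.space, labels=labels,
                    palette=reference.palette)


def consensus_across_densities(labelled: Sequence[tuple[float, LabelMap]]
                               ) -> LabelMap:
    """Sparsest-threshold consensus across density-tagged label maps.

    Each grayordinate receives the label it holds at the smallest density
    where its label is nonzero; grayordinates never assigned stay 0.
    """
    if not labelled:
        raise ValueError("need at least one labelled solution")
    items = sorted(labelled, key=lambda t: t[0])
    first = items[0][1]
    out = np.zeros(first.space.n_gray, dtype=int)
    for _, lm in items:
        if lm.space.n_gray != first.space.n_gray or lm.palette != first.palette:
            raise ValueError("inconsistent spaces or palettes across densities")
        fill = (out == 0) & (lm.labels != 0)
        out[fill] = lm.labels[fill]
    return LabelMap(space=first.space, labels=out, palette=first.palette)


def clean_small_clusters(lm: LabelMap,
                         adjacency: sparse.spmatrix | None = None,
                         min_cluster: int = 30) -> LabelMap:
    """Merge labeled contiguous clusters below ``min_cluster`` grayordinates.

    Each undersized connected component of equal-label grayordinates is
    reassigned wholesale to the adjacent network with the largest total
    (map-wide) size.  One component is merged per pass, smallest first;
    every merge unions the component with an adjacent same-label component,
    so the labeled-component count strictly decreases and the procedure
    terminates at a fixed point.  A small component with no differently
    labeled neighbor keeps its label (logged once).
    """
    A = adjacency if adjacency is not None else lm.space.get_adjacency()
    A = A.tocsr()
    labels = lm.labels.copy()
    n_unmergeable = 0
    while True:
        comp_id, comp_label, comp_size = _label_components(labels, A)
        net_size = np.bincount(labels, minlength=len(lm.palette) + 1)
        candidates = []
        for cid in range(len(comp_size)):
            if comp_label[cid] == 0 or comp_size[cid] >= min_cluster:
                continue
            members = np.flatnonzero(comp_id == cid)
            nbrs = np.unique(A[members].indices)
            nbr_labels = {int(l) for l in labels[nbrs]} \
                - {0, int(comp_label[cid])}
            if nbr_labels:
                candidates.append((comp_size[cid], members[0], members,
                                   nbr_labels))
        if not candidates:
            break
        _, _, members, nbr_labels = min(candidates,
                                        key=lambda c: (c[0], c[1]))
        target = max(nbr_labels, key=lambda l: (net_size[l], -l))
        labels[members] = target
    n_unmergeable = sum(
        1 for cid in range(len(comp_size))
        if comp_label[cid] != 0 and comp_size[cid] < min_cluster)
    if n_unmergeable:
        logger.info("%d small clusters have no labeled neighbor and were "
                    "left in place", n_unmergeable)
    return LabelMap(space=lm.space, labels=labels, palette=lm.palette)


def _label_components(labels: np.ndarray, A: sparse.csr_matrix):
    """Connected components of equal-label grayordinates."""
    same = sparse.coo_matrix(A)
    keep = labels[same.row] == labels[same.col]
    A_same = sparse.coo_matrix((same.data[keep],
                                (same.row[keep], same.col[keep])),
                               shape=A.shape).tocsr()
    n_comp, comp_id = sparse.csgraph.connected_components(A_same,
                                                          directed=False)
    comp_label = np.zeros(n_comp, dtype=int)
    comp_size = np.zeros(n_comp, dtype=int)
    for g in range(len(labels)):
        comp_label[comp_id[g]] = labels[g]
        comp_size[comp_id[g]] += 1
    return comp_id, comp_label, comp_size


def drop_small_networks(lm: LabelMap,
                        min_network_group: int = 400) -> LabelMap:
    """Group-level rule: networks with <= min_network_group members become
    unassigned (applied to group-average runs only)."""
    labels = lm.labels.copy()
    sizes = np.bincount(labels, minlength=len(lm.palette) + 1)
    for l in range(1, len(lm.palette) + 1):
        if 0 < sizes[l] <= min_network_group:
            labels[labels == l] = 0
    return LabelMap(space=lm.space, labels=labels, palette=lm.palette)
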