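"""Synthetic multi-participant grayordinate BOLD cohorts with known truth.

The generator emulates the structure of a developmental resting-state
cohort at desk scale: K networks planted on a two-hemisphere spherical-cap
cortex plus an interior subcortical ball; per-participant topographic jitter
of the network boundaries; designated hub zones where several networks
share a grayordinate; band-limited latent network signals mixed through the
membership weights plus white noise at a configurable SNR; motion traces
with censorable spikes; and behavioral scores generated from chosen
connectivity edges.  Every output is a deterministic function of the master
seed.

The planted memberships, hub masks and behavior-generating edges form the
ground truth against which network-recovery, overlap-recovery and
reliability operations are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gray_model import (CANONICAL_NETWORKS, DenseTimeseries,
                         GrayordinateSpace, LabelMap, OverlapMap)
from .motion_prep import MotionTrace, bandpass

__all__ = ["CohortSpec", "GroundTruth", "Participant", "Cohort",
           "make_space", "plant_networks", "simulate_bold",
           "simulate_motion", "simulate_behavior", "generate_cohort"]

CAP_RADIUS_MM = 70.0        # cortical grayordinates live on two mirrored caps
SUBCORTEX_RADIUS_MM = 25.0  # subcortical grayordinates fill an interior ball


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults are the desk-scale analogue of the source design: 20
    participants, 1,500 grayordinates, 8 networks, 3 mm topographic jitter,
    SNR 4, TR 0.8 s and 750 frames (10 minutes), three 12 mm hub zones of
    three networks each at partition boundaries.
    """

    n_participants: int = 20
    n_gray: int = 1500
    fractions: tuple[float, float, float] = (0.45, 0.45, 0.10)
    n_networks: int = 8
    jitter_sigma_mm: float = 3.0
    n_hubs: int = 3
    hub_radius_mm: float = 12.0
    hub_n_networks: int = 3
    snr: float = 4.0
    tr_seconds: float = 0.8
    n_frames: int = 750
    motion_baseline_sd: float = 0.02
    spike_prob: float = 0.05
    spike_amplitude_mm: float = 1.0
    behavior_effects: tuple[tuple[int, float], ...] = ((0, 0.8), (5, -0.5))
    behavior_noise_sd: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.fractions = tuple(self.fractions)
        self.behavior_effects = tuple(
            (int(e), float(b)) for e, b in self.behavior_effects)
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("structure fractions must sum to 1")
        if not (2 <= self.n_networks <= len(CANONICAL_NETWORKS)):
            raise ValueError("n_networks must be in 2..14")
        if not (2 <= self.hub_n_networks <= self.n_networks):
            raise ValueError("hub_n_networks must be in 2..n_networks")
        if min(self.n_participants, self.n_gray, self.snr, self.tr_seconds,
               self.n_frames) <= 0:
            raise ValueError("cohort parameters must be positive")

    @property
    def palette(self) -> tuple[str, ...]:
        return CANONICAL_NETWORKS[: self.n_networks]


@dataclass
class GroundTruth:
    group_labels: LabelMap
    participant_labels: list[LabelMap]
    participant_overlap: list[OverlapMap]
    hub_mask: np.ndarray
    weights: list[np.ndarray]          # per participant: n_gray x K
    behavior_edges: tuple[tuple[int, float], ...]


@dataclass
class Participant:
    index: int
    timeseries: DenseTimeseries
    motion: MotionTrace
    seed: int


@dataclass
class Cohort:
    spec: CohortSpec
    space: GrayordinateSpace
    participants: list[Participant]
    truth: GroundTruth
    behavior: np.ndarray = field(default=None)  # type: ignore[assignment]


def make_space(n_gray: int, fractions: Sequence[float] = (0.45, 0.45, 0.10),
               seed: int = 0, knn_k: int = 6) -> GrayordinateSpace:
    """Random grayordinate space: two mirrored cortical caps + interior ball.

    Left-hemisphere grayordinates sample the x < 0 half of a sphere of
    radius 70 mm, right-hemisphere ones are their mirrored counterparts'
    distribution (x > 0), and subcortical ones fill a central ball.  A
    symmetrized 6-nearest-neighbour graph supplies adjacency.
    """
    if n_gray < 100:
        raise ValueError("n_gray must be >= 100")
    if len(fractions) != 3 or abs(sum(fractions) - 1) > 1e-9 or min(fractions) <= 0:
        raise ValueError("fractions must be three positive numbers summing to 1")
    rng = np.random.default_rng(seed)
    n_left = int(round(n_gray * fractions[0]))
    n_right = int(round(n_gray * fractions[1]))
    n_sub = n_gray - n_left - n_right

    def cap(n: int, side: float) -> np.ndarray:
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v[:, 0] = side * np.abs(v[:, 0])
        return CAP_RADIUS_MM * v

    left = cap(n_left, -1.0)
    right = cap(n_right, +1.0)
    u = rng.normal(size=(n_sub, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = SUBCORTEX_RADIUS_MM * rng.uniform(0, 1, size=n_sub) ** (1 / 3)
    sub = u * r[:, None]

    coords = np.vstack([left, right, sub])
    structure = np.array(["LEFT_CORTEX"] * n_left + ["RIGHT_CORTEX"] * n_right
                         + ["SUBCORTEX"] * n_sub)
    return GrayordinateSpace(structure=structure, coords=coords, knn_k=knn_k)


def network_embedding(space: GrayordinateSpace) -> np.ndarray:
    """Mirror-symmetrized spherical embedding used to lay out networks.

    Hemispheres are folded onto each other (x -> |x|) so that planted
    networks come out bilaterally symmetric, as real large-scale networks
    roughly are; subcortical grayordinates are projected radially onto the
    same sphere so that the subcortex divides across networks instead of
    being swallowed whole by whichever network sits nearest the centre of
    the head.
    """
    m = space.coords.copy()
    m[:, 0] = np.abs(m[:, 0])
    norm = np.linalg.norm(m, axis=1, keepdims=True)
    norm[norm < 1e-6] = 1.0
    return CAP_RADIUS_MM * m / norm


def _group_seed_points(space: GrayordinateSpace, K: int,
                       rng: np.random.Generator,
                       lloyd_iters: int = 25) -> np.ndarray:
    """K network seed points in the embedding.

    Greedy farthest-point sampling spreads the initial seeds; Lloyd
    (k-means) iterations then relax them so network territories come out
    roughly equal-sized.  Without the relaxation, seeds drawn near the rim
    of the point cloud produce very small networks whose z >= 1 template
    supports badly overshoot their true membership, inflating spurious
    multi-network assignments.
    """
    pts = network_embedding(space)
    first = int(rng.integers(len(pts)))
    chosen = [first]
    d = np.linalg.norm(pts - pts[first], axis=1)
    for _ in range(K - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    seeds = pts[chosen].copy()
    for _ in range(lloyd_iters):
        part = _nearest_partition(pts, seeds)
        new = np.stack([
            pts[part == k].mean(axis=0) if (part == k).any() else seeds[k]
            for k in range(K)])
        if np.allclose(new, seeds, atol=1e-9):
            break
        seeds = new
    return seeds


def _nearest_partition(coords: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
    return np.argmin(d, axis=1)


def _hub_centers(space: GrayordinateSpace, seeds: np.ndarray, n_hubs: int,
                 m: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Hub centers at partition boundaries: embedding points whose distances
    to the m nearest network seeds are most nearly equal (m-way corners of
    the partition).  Returned centers live in embedding space, so each hub
    zone is bilateral."""
    emb = network_embedding(space)
    d = np.linalg.norm(emb[:, None, :] - seeds[None, :, :], axis=2)
    part = np.partition(d, m - 1, axis=1)
    spread = part[:, m - 1] - part[:, 0]      # small = near an m-way corner
    order = np.argsort(spread)
    centers = []
    taken: list[np.ndarray] = []
    for g in order:
        c = emb[g]
        if any(np.linalg.norm(c - t) < 3 * SUBCORTEX_RADIUS_MM for t in taken):
            continue
        nets = np.argsort(d[g])[:m]
        centers.append((c, nets))
        taken.append(c)
        if len(centers) == n_hubs:
            break
    return centers


def plant_networks(space: GrayordinateSpace, K: int,
                   jitter_sigma_mm: float,
                   hub_centers: list[tuple[np.ndarray, np.ndarray]],
                   hub_radius_mm: float,
                   group_seeds: np.ndarray,
                   participant_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant membership weights W (n_gray x K) and truth labels.

    The participant's partition is nearest-of-K on the group seed points
    jittered by an isotropic Gaussian of s.d. ``jitter_sigma_mm``; W is
    one-hot from that partition except inside hub zones, where the zone's
    m networks share weight 1/m.  Truth labels are argmax W (lowest index
    on hub ties); the overlap truth is the support of W.
    """
    rng = np.random.default_rng(participant_seed)
    emb = network_embedding(space)
    for _ in range(20):
        jitter = rng.normal(scale=jitter_sigma_mm, size=group_seeds.shape) \
            if jitter_sigma_mm > 0 else 0.0
        part = _nearest_partition(emb, group_seeds + jitter)
        if len(np.unique(part)) == K:
            break
    else:  # pragma: no cover - tiny-space safeguard
        import logging
        logging.getLogger(__name__).warning(
            "a network emptied under jitter; falling back to group partition")
        part = _nearest_partition(emb, group_seeds)

    W = np.zeros((space.n_gray, K))
    W[np.arange(space.n_gray), part] = 1.0
    for center, nets in hub_centers:
        zone = np.linalg.norm(emb - center, axis=1) <= hub_radius_mm
        W[zone] = 0.0
        W[np.ix_(zone, nets)] = 1.0 / len(nets)
    labels = np.argmax(W, axis=1) + 1
    return W, labels


def simulate_bold(W: np.ndarray, space: GrayordinateSpace, n_frames: int,
                  tr_seconds: float, snr: float,
                  seed: int) -> DenseTimeseries:
    """Mix band-limited latent network signals through W and add noise.

    x_g(t) = sum_k Wn[g, k] s_k(t) + e_g(t) / snr, with s_k independent
    unit-variance Gaussian series band-limited to the 9-80 mHz analysis band
    and e iid standard Gaussian.  Wn is W with each row scaled to unit L2
    norm, so the network-signal s.d. is 1 at every grayordinate — hub
    grayordinates mix several latents but are not penalized in signal power
    — and ``snr`` is uniformly the network-signal-to-noise s.d. ratio.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("every grayordinate needs at least one membership")
    W = W / norms
    K = W.shape[1]
    latents = rng.standard_normal((n_frames, K))
    carrier = DenseTimeseries(
        space=GrayordinateSpace(structure=np.array(["SUBCORTEX"] * K),
                                coords=np.zeros((K, 3))),
        tr_seconds=tr_seconds, values=latents)
    latents = bandpass(carrier).values
    # enforce exact in-sample independence: at a few hundred effective
    # degrees of freedom, raw band-limited draws carry sample correlations
    # of +-0.1-0.2 that leak systematic network-to-network coupling into
    # every participant; centered QR orthogonalization (columns stay in the
    # analysis band) removes it
    latents = latents - latents.mean(axis=0, keepdims=True)
    latents, _ = np.linalg.qr(latents)
    latents /= latents.std(axis=0, keepdims=True)
    noise = rng.standard_normal((n_frames, W.shape[0]))
    values = latents @ W.T + noise / snr
    return DenseTimeseries(space=space, tr_seconds=tr_seconds, values=values)


def simulate_motion(n_frames: int, spike_prob: float = 0.05,
                    amplitude_mm: float = 1.0, baseline_sd: float = 0.02,
                    seed: int = 0) -> MotionTrace:
    """Rigid-body trace: small Gaussian steps + Bernoulli displacement spikes.

    The baseline step s.d. (default 0.02 mm / frame, split over six
    parameters) keeps FD comfortably below the 0.2 mm censoring threshold;
    each spike adds ``amplitude_mm`` to one random translation for one
    frame, guaranteeing an FD violation.
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(scale=baseline_sd / 6.0, size=(n_frames, 6))
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    spikes = rng.random(n_frames) < spike_prob
    spikes[0] = False
    which = rng.integers(0, 3, size=n_frames)
    for t in np.flatnonzero(spikes):
        params[t, which[t]] += amplitude_mm
    return MotionTrace(params)


def simulate_behavior(conn_stack: np.ndarray,
                      effects: Sequence[tuple[int, float]],
                      noise_sd: float, seed: int = 0) -> np.ndarray:
    """Scores = sum_e beta_e * edge_e(participant) + Gaussian noise.

    Edge indices address ``np.triu_indices(p, k=1)`` order of the stacked
    connectivity matrices.
    """
    rng = np.random.default_rng(seed)
    conn_stack = np.asarray(conn_stack, dtype=float)
    iu = np.triu_indices(conn_stack.shape[1], k=1)
    E = conn_stack[:, iu[0], iu[1]]
    score = np.zeros(conn_stack.shape[0])
    for edge, beta in effects:
        score += beta * E[:, int(edge)]
    return score + rng.normal(scale=noise_sd, size=len(score))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Deterministically generate a full cohort bundle from the master seed.

    Per-participant seeds are drawn once from the master-seeded generator,
    so any single participant is reproducible given the spec.
    """
    root = np.random.default_rng(spec.master_seed)
    space_seed, seeds_seed, hub_seed = root.integers(2 ** 31, size=3)
    part_seeds = root.integers(2 ** 31, size=(spec.n_participants, 2))

    space = make_space(spec.n_gray, spec.fractions, seed=int(space_seed))
    K = spec.n_networks
    seed_rng = np.random.default_rng(int(seeds_seed))
    group_seeds = _group_seed_points(space, K, seed_rng)
    emb = network_embedding(space)
    group_part = _nearest_partition(emb, group_seeds)
    hubs = _hub_centers(space, group_seeds, spec.n_hubs, spec.hub_n_networks)

    hub_mask = np.zeros(space.n_gray, dtype=bool)
    for center, _ in hubs:
        hub_mask |= np.linalg.norm(emb - center, axis=1) <= spec.hub_radius_mm

    palette = spec.palette
    group_lm = LabelMap(space=space, labels=group_part + 1, palette=palette)

    participants, p_labels, p_overlap, weights = [], [], [], []
    for i in range(spec.n_participants):
        w_seed, b_seed = (int(part_seeds[i, 0]), int(part_seeds[i, 1]))
        W, labels = plant_networks(space, K, spec.jitter_sigma_mm, hubs,
                                   spec.hub_radius_mm, group_seeds,
                                   participant_seed=w_seed)
        ts = simulate_bold(W, space, spec.n_frames, spec.tr_seconds,
                           spec.snr, seed=b_seed)
        motion = simulate_motion(spec.n_frames, spec.spike_prob,
                                 spec.spike_amplitude_mm,
                                 spec.motion_baseline_sd, seed=b_seed + 1)
        participants.append(Participant(index=i, timeseries=ts,
                                        motion=motion, seed=b_seed))
        p_labels.append(LabelMap(space=space, labels=labels, palette=palette))
        p_overlap.append(OverlapMap(space=space,
                                    membership=(W.T > 0).astype(np.uint8),
                                    palette=palette))
        weights.append(W)

    truth = GroundTruth(group_labels=group_lm, participant_labels=p_labels,
                        participant_overlap=p_overlap, hub_mask=hub_mask,
                        weights=weights,
                        behavior_edges=tuple(spec.behavior_effects))
    return Cohort(spec=spec, space=space, participants=participants,
                  truth=truth)
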