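"""Reliability analyses: split-half NMI and subset brain-behavior curves.

Split-half reliability asks whether a participant's network map is a stable
individual trait: map each half of the data separately, score the agreement
of the two maps with normalized mutual information (NMI), and compare the
within-participant NMI distribution against the null of between-participant
half pairs with a one-tailed Welch t-test.

Subset reliability asks how many participants a brain-wide association
needs: for increasing subsample sizes, correlate edge-wise brain-behavior
r-vectors from group-1 subsamples against the full group-2 reference, and
summarize the curve with the exponential rise-to-maximum fit
y = y0 + a * (1 - exp(-b x)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .gray_model import DenseTimeseries, LabelMap

__all__ = [
    "SplitHalfResult",
    "RiseFitParams",
    "SubsetReliabilityCurve",
    "nmi",
    "split_timeseries",
    "split_half",
    "brain_behavior_vector",
    "subset_reliability",
    "fit_rise_to_max",
]


@dataclass
class SplitHalfResult:
    intra_nmi: np.ndarray          # per participant: own half-1 vs half-2
    inter_nmi: np.ndarray          # null: cross-participant half pairs
    t_statistic: float
    dof: float
    p_value: float
    tail: str = "one"
    variance_assumption: str = "unequal"

    def summary(self) -> str:
        return (
            f"split-half reliability: intra NMI {self.intra_nmi.mean():.3f} "
            f"(n={len(self.intra_nmi)}) vs null {self.inter_nmi.mean():.3f} "
            f"(n={len(self.inter_nmi)}); Welch t({self.dof:.2f}) = "
            f"{self.t_statistic:.3f}, {self.tail}-tailed p = {self.p_value:.3g}"
        )


@dataclass
class RiseFitParams:
    y0: float
    a: float
    b: float
    r_squared: float
    degenerate: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.y0 + self.a * (1.0 - np.exp(-self.b * np.asarray(x)))


@dataclass
class SubsetReliabilityCurve:
    sizes: np.ndarray
    correlations: np.ndarray       # sizes x replicates
    means: np.ndarray
    fit: RiseFitParams | None = None
    provenance: dict = field(default_factory=dict)


def nmi(A: LabelMap, B: LabelMap) -> float:
    """Normalized mutual information between two network maps.

    Normalization is by the arithmetic mean of the two entropies.
    Grayordinates unassigned (label 0) in either map are excluded pairwise —
    absence of an assignment is not a community.  Identical partitions score
    1 (up to relabeling); if either restricted partition has zero entropy
    while the maps differ, the score is 0 by contract.
    """
    from sklearn.metrics import normalized_mutual_info_score

    if A.space.n_gray != B.space.n_gray:
        raise ValueError("maps live in different spaces")
    both = (A.labels != 0) & (B.labels != 0)
    if not both.any():
        raise ValueError("no jointly assigned grayordinates")
    a, b = A.labels[both], B.labels[both]
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(normalized_mutual_info_score(a, b,
                                              average_method="arithmetic"))


def split_timeseries(ts: DenseTimeseries, mode: str = "interleaved"
                     ) -> tuple[DenseTimeseries, DenseTimeseries]:
    """Split a dense time series into two halves (interleaved or contiguous)."""
    T = ts.n_frames
    if mode == "interleaved":
        ia, ib = np.arange(0, T, 2), np.arange(1, T, 2)
    elif mode == "contiguous":
        ia, ib = np.arange(0, T // 2), np.arange(T // 2, T)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    make = lambda idx: DenseTimeseries(space=ts.space,
                                       tr_seconds=ts.tr_seconds,
                                       values=ts.values[idx])
    return make(ia), make(ib)


def split_half(cohort: Sequence[DenseTimeseries],
               mapper: Callable[[DenseTimeseries], LabelMap],
               mode: str = "interleaved",
               seed: int | None = None) -> SplitHalfResult:
    """Split-half reliability of a network-mapping function over a cohort.

    ``mapper`` takes a half time series to a LabelMap (e.g. template
    matching at a fixed template set).  Intra NMI compares each
    participant's two halves; the null compares every half of every
    participant with every half of every *other* participant.  The two
    distributions are compared with a one-tailed Welch (unequal-variance)
    t-test of intra > null.
    """
    if len(cohort) < 2:
        raise ValueError("need at least two participants")
    halves: list[tuple[LabelMap, LabelMap]] = []
    for ts in cohort:
        h1, h2 = split_timeseries(ts, mode=mode)
        halves.append((mapper(h1), mapper(h2)))

    intra = np.array([nmi(a, b) for a, b in halves])
    # null: every half of every participant vs every half of every other
    # participant, each unordered pair once
    inter = [nmi(ha, hb)
             for i in range(len(halves))
             for j in range(i + 1, len(halves))
             for ha in halves[i]
             for hb in halves[j]]
    inter = np.array(inter)
    t, p = stats.ttest_ind(intra, inter, equal_var=False,
                           alternative="greater")
    dof = _welch_dof(intra, inter)
    return SplitHalfResult(intra_nmi=intra, inter_nmi=inter,
                           t_statistic=float(t), dof=dof, p_value=float(p))


def _welch_dof(x: np.ndarray, y: np.ndarray) -> float:
    """Welch-Satterthwaite degrees of freedom."""
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    return float((vx + vy) ** 2 / (vx ** 2 / (len(x) - 1)
                                   + vy ** 2 / (len(y) - 1)))


def brain_behavior_vector(conn_stack: np.ndarray,
                          behavior: np.ndarray) -> np.ndarray:
    """Edge-wise across-participant correlation with a behavioral score.

    ``conn_stack`` is (n_participants, p, p); the return is the Pearson r of
    each upper-triangle edge's strengths with ``behavior``, in
    ``np.triu_indices(p, k=1)`` order.
    """
    conn_stack = np.asarray(conn_stack, dtype=float)
    behavior = np.asarray(behavior, dtype=float).ravel()
    if conn_stack.ndim != 3 or conn_stack.shape[1] != conn_stack.shape[2]:
        raise ValueError("conn_stack must be (n, p, p)")
    n = conn_stack.shape[0]
    if n < 4:
        raise ValueError("need at least 4 participants")
    if len(behavior) != n:
        raise ValueError("behavior length disagrees with participants")
    if behavior.std() == 0:
        raise ValueError("behavior has zero variance")
    iu = np.triu_indices(conn_stack.shape[1], k=1)
    E = conn_stack[:, iu[0], iu[1]]            # n x edges
    bz = (behavior - behavior.mean()) / behavior.std()
    sd = E.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Ez = (E - E.mean(axis=0)) / sd
    r = (bz @ Ez) / n
    return np.where(sd == 0, 0.0, np.clip(r, -1.0, 1.0))


def subset_reliability(conn_stack: np.ndarray, behavior: np.ndarray,
                       reference: np.ndarray,
                       sizes: Sequence[int], reps: int = 10,
                       seed: int | np.random.Generator = 0,
                       fit: bool = True) -> SubsetReliabilityCurve:
    """Intergroup reliability of brain-behavior maps vs subsample size.

    For each size and replicate, sample that many group-1 participants
    without replacement, compute the edge-wise brain-behavior vector, and
    correlate it with the group-2 ``reference`` vector.  The (size, r)
    points are then fitted with the rise-to-maximum curve.
    """
    rng = np.random.default_rng(seed)
    conn_stack = np.asarray(conn_stack, dtype=float)
    behavior = np.asarray(behavior, dtype=float).ravel()
    reference = np.asarray(reference, dtype=float).ravel()
    sizes = np.asarray(sorted(sizes), dtype=int)
    if sizes.min(initial=4) < 4:
        raise ValueError("minimum subsample size is 4")
    if sizes.max(initial=0) > conn_stack.shape[0]:
        raise ValueError("subsample size exceeds group size")
    n = conn_stack.shape[0]
    corrs = np.empty((len(sizes), reps))
    for si, size in enumerate(sizes):
        for rep in range(reps):
            pick = rng.choice(n, size=size, replace=False)
            vec = brain_behavior_vector(conn_stack[pick], behavior[pick])
            corrs[si, rep] = np.corrcoef(vec, reference)[0, 1]
    means = corrs.mean(axis=1)
    fitted = None
    if fit:
        x = np.repeat(sizes, reps).astype(float)
        y = corrs.ravel()
        fitted = fit_rise_to_max(x, y)
    return SubsetReliabilityCurve(sizes=sizes, correlations=corrs,
                                  means=means, fit=fitted,
                                  provenance={"reps": reps})


def fit_rise_to_max(x: np.ndarray, y: np.ndarray) -> RiseFitParams:
    """Nonlinear least squares for y = y0 + a * (1 - exp(-b x)).

    ``b`` (the rate of rise to the plateau y0 + a) is constrained
    non-negative.  A flat response is flagged degenerate (a ~ 0, b
    unidentified).  Non-convergence raises with the best iterate attached.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need >= 4 (x, y) points")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values")

    if y.std() == 0:
        return RiseFitParams(y0=float(y[0]), a=0.0, b=0.0, r_squared=1.0,
                             degenerate=True)

    span = y.max() - y.min()
    p0 = (float(y.min()), float(span if span > 0 else 1.0),
          1.0 / max(x.mean(), 1e-9))
    model = lambda xx, y0, a, b: y0 + a * (1.0 - np.exp(-b * xx))
    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=p0,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"rise-to-maximum fit did not converge "
                           f"(start {p0}): {exc}") from exc
    resid = y - model(x, *popt)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    degenerate = abs(popt[1]) < 1e-10
    return RiseFitParams(y0=float(popt[0]), a=float(popt[1]),
                         b=float(popt[2]), r_squared=r2,
                         degenerate=degenerate)
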