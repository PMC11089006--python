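"""Network template construction from a template cohort.

A template is a group-level picture of one network's whole-brain
connectivity: each template participant contributes a seed-based correlation
map for the network (the network's mean time series correlated against every
grayordinate), the maps are averaged across participants, the average map is
z-scored across grayordinates, and the template support is the set of
grayordinates with z >= 1 — for a Gaussian map, roughly the top 15.9% of
connections.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np

from .gray_model import DenseTimeseries, LabelMap
from .motion_prep import FrameMask
from .connectivity import seed_map

__all__ = [
    "NetworkTemplate",
    "TemplateSet",
    "network_mean_timeseries",
    "participant_seed_maps",
    "build_templates",
]


@dataclass
class NetworkTemplate:
    """One network's thresholded group connectivity pattern."""

    name: str
    support: np.ndarray          # binary, length n_gray
    zvalues: np.ndarray          # z-scores on the support, same length (0 off)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=bool).ravel()
        self.zvalues = np.asarray(self.zvalues, dtype=float).ravel()
        if self.support.shape != self.zvalues.shape:
            raise ValueError("support and zvalues length mismatch")
        if not self.support.any():
            raise ValueError(f"template {self.name!r} has empty support")


@dataclass
class TemplateSet:
    """Ordered templates matching a network palette."""

    templates: list[NetworkTemplate]
    palette: tuple[str, ...]
    n_template_participants: int = 0

    def __post_init__(self) -> None:
        self.palette = tuple(self.palette)
        names = [t.name for t in self.templates]
        if names != list(self.palette):
            raise ValueError("one template per palette entry, in order")

    @property
    def n_gray(self) -> int:
        return self.templates[0].support.shape[0]

    def support_matrix(self) -> np.ndarray:
        """K x n_gray binary matrix of template supports."""
        return np.stack([t.support for t in self.templates]).astype(np.uint8)

    def save(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        z = np.stack([t.zvalues for t in self.templates])
        np.savetxt(path, z, delimiter="\t", fmt="%.8g")
        meta = {"palette": list(self.palette),
                "n_template_participants": self.n_template_participants,
                "z_threshold": 1.0}
        path.with_suffix(".json").write_text(json.dumps(meta), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "TemplateSet":
        from pathlib import Path

        path = Path(path)
        z = np.loadtxt(path, delimiter="\t", ndmin=2)
        meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        templates = [
            NetworkTemplate(name=n, support=z[i] >= meta.get("z_threshold", 1.0),
                            zvalues=z[i])
            for i, n in enumerate(meta["palette"])
        ]
        return cls(templates=templates, palette=tuple(meta["palette"]),
                   n_template_participants=meta.get("n_template_participants", 0))


def network_mean_timeseries(ts: DenseTimeseries,
                            labels: LabelMap) -> np.ndarray:
    """Per-network mean time series, K x T, in palette order."""
    out = np.empty((len(labels.palette), ts.n_frames))
    for k, name in enumerate(labels.palette):
        members = labels.labels == (k + 1)
        if not members.any():
            raise ValueError(f"network {name!r} has no member grayordinates")
        out[k] = ts.values[:, members].mean(axis=1)
    return out


def participant_seed_maps(ts: DenseTimeseries, labels: LabelMap,
                          mask: FrameMask | None = None) -> np.ndarray:
    """K x n_gray seed-based correlation maps, one row per network.

    Row k is the correlation of network k's mean member series with every
    grayordinate, over retained frames.
    """
    out = np.empty((len(labels.palette), ts.space.n_gray))
    for k, name in enumerate(labels.palette):
        members = np.flatnonzero(labels.labels == (k + 1))
        if members.size == 0:
            raise ValueError(f"network {name!r} has no member grayordinates")
        out[k] = seed_map(ts, members, mask=mask, name=name).values
    return out


def build_templates(seed_map_stack: np.ndarray,
                    palette: tuple[str, ...],
                    z_threshold: float = 1.0) -> TemplateSet:
    """Average per-participant seed maps into thresholded network templates.

    Parameters
    ----------
    seed_map_stack : array, shape (n_participants, K, n_gray)
        Each participant's :func:`participant_seed_maps` output.
    palette : tuple of str
        Network names, one per row k.
    z_threshold : float
        Support cut on the per-network z-scored average map (default 1,
        i.e. ~top 15.9% of grayordinates for a Gaussian map).
    """
    stack = np.asarray(seed_map_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("seed_map_stack must be (participants, K, n_gray)")
    if stack.shape[0] < 1:
        raise ValueError("need at least one template participant")
    if stack.shape[1] != len(palette):
        raise ValueError("row count disagrees with palette")
    mean_maps = stack.mean(axis=0)
    templates = []
    for k, name in enumerate(palette):
        m = mean_maps[k]
        sd = m.std()
        if sd == 0:
            raise ValueError(
                f"average map for network {name!r} is constant; cannot z-score")
        z = (m - m.mean()) / sd
        support = z >= z_threshold
        if not support.any():
            raise ValueError(f"no grayordinate reaches z >= {z_threshold} "
                             f"for network {name!r}")
        templates.append(NetworkTemplate(name=name, support=support,
                                         zvalues=z))
    return TemplateSet(templates=templates, palette=tuple(palette),
                       n_template_participants=stack.shape[0])
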