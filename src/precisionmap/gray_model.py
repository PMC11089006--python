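"""Grayordinate data model and file I/O.

The grayordinate is the sampling unit of combined surface + volume brain
space: a cortical surface vertex (left or right hemisphere) or a subcortical
voxel.  Everything downstream — dense connectivity, network templates,
probabilistic atlases — is indexed by grayordinate, 0-based.

Two on-disk dialects are supported:

``cifti2``
    CIFTI-2 files via :mod:`nibabel` (``.dtseries.nii``, ``.dscalar.nii``,
    ``.dlabel.nii``).  Surface coordinates are not carried inside CIFTI
    matrices, so writers also emit the JSON space sidecar below; readers use
    it when present.

``plaintext``
    UTF-8 tab-delimited matrix, one frame (or map) per row, with a JSON
    sidecar ``<stem>.json`` carrying ``tr_seconds``, per-grayordinate
    structure tags and coordinates.  Designed for desk-scale inspection and
    fully self-contained round trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

__all__ = [
    "CANONICAL_NETWORKS",
    "STRUCTURES",
    "GrayordinateSpace",
    "DenseTimeseries",
    "ScalarMap",
    "LabelMap",
    "OverlapMap",
    "read_dense",
    "write_dense",
    "read_labels",
    "write_labels",
    "read_overlap",
    "write_overlap",
    "read_scalar",
    "write_scalar",
]

#: Canonical 14-network palette (large-scale functional networks).
CANONICAL_NETWORKS: tuple[str, ...] = (
    "DMN", "Vis", "FPN", "DAN", "VAN", "Sal", "CO",
    "SMd", "SMl", "Aud", "Tpole", "MTL", "PON", "PMN",
)

STRUCTURES = ("LEFT_CORTEX", "RIGHT_CORTEX", "SUBCORTEX")

_CIFTI_TO_TAG = {
    "CIFTI_STRUCTURE_CORTEX_LEFT": "LEFT_CORTEX",
    "CIFTI_STRUCTURE_CORTEX_RIGHT": "RIGHT_CORTEX",
}


@dataclass
class GrayordinateSpace:
    """Index space shared by every map and time series in an analysis.

    Parameters
    ----------
    structure : array of str, shape (n_gray,)
        Per-grayordinate tag, one of ``LEFT_CORTEX``, ``RIGHT_CORTEX``,
        ``SUBCORTEX``.
    coords : array, shape (n_gray, 3)
        Grayordinate positions in millimetres.
    adjacency : scipy.sparse matrix, optional
        Symmetric, irreflexive neighbour relation used by contiguity
        operations (cluster cleanup, ROI components).  Built lazily as a
        symmetrized k-nearest-neighbour graph on ``coords`` when absent.
    """

    structure: np.ndarray
    coords: np.ndarray
    adjacency: sparse.spmatrix | None = field(default=None, repr=False)
    knn_k: int = 6

    def __post_init__(self) -> None:
        self.structure = np.asarray(self.structure, dtype="U12")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_gray, 3)")
        if self.structure.shape[0] != self.coords.shape[0]:
            raise ValueError("structure and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        bad = set(np.unique(self.structure)) - set(STRUCTURES)
        if bad:
            raise ValueError(f"unknown structure tags: {sorted(bad)}")

    @property
    def n_gray(self) -> int:
        return self.coords.shape[0]

    def get_adjacency(self) -> sparse.csr_matrix:
        """Symmetric irreflexive neighbour graph (k-NN on coords by default)."""
        if self.adjacency is None:
            self.adjacency = _knn_adjacency(self.coords, self.knn_k)
        return self.adjacency

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, GrayordinateSpace):
            return NotImplemented
        return (
            self.n_gray == other.n_gray
            and np.array_equal(self.structure, other.structure)
            and np.allclose(self.coords, other.coords)
        )


def _knn_adjacency(coords: np.ndarray, k: int) -> sparse.csr_matrix:
    from sklearn.neighbors import kneighbors_graph

    n = coords.shape[0]
    k = min(k, n - 1)
    if k <= 0:
        return sparse.csr_matrix((n, n), dtype=bool)
    a = kneighbors_graph(coords, n_neighbors=k, mode="connectivity")
    a = ((a + a.T) > 0).tocsr()
    a.setdiag(False)
    a.eliminate_zeros()
    return a.astype(bool)


@dataclass
class DenseTimeseries:
    """Frames x grayordinates BOLD matrix with its repetition time."""

    space: GrayordinateSpace
    tr_seconds: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x grayordinates)")
        if self.values.shape[0] < 2:
            raise ValueError("a dense time series needs at least 2 frames")
        if self.values.shape[1] != self.space.n_gray:
            raise ValueError(
                f"column count {self.values.shape[1]} != space.n_gray "
                f"{self.space.n_gray}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series values must be finite")
        if not (self.tr_seconds > 0):
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_seconds


@dataclass
class ScalarMap:
    """A single real value per grayordinate (seed map, probability, count...)."""

    space: GrayordinateSpace
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape[0] != self.space.n_gray:
            raise ValueError("scalar map length must match space")


@dataclass
class LabelMap:
    """Single-network assignment per grayordinate; 0 means unassigned."""

    space: GrayordinateSpace
    labels: np.ndarray
    palette: tuple[str, ...] = CANONICAL_NETWORKS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        self.palette = tuple(self.palette)
        if len(set(self.palette)) != len(self.palette):
            raise ValueError("palette names must be unique")
        if self.labels.shape[0] != self.space.n_gray:
            raise ValueError("labels length must match space")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) > len(self.palette):
            raise ValueError(
                f"labels must lie in 0..{len(self.palette)} for this palette"
            )

    def network_mask(self, name: str) -> np.ndarray:
        return self.labels == (self.palette.index(name) + 1)


@dataclass
class OverlapMap:
    """Binary multi-network membership: K networks x n_gray grayordinates.

    A column may be all-zero — overlapping mapping does not force every
    grayordinate into a network.
    """

    space: GrayordinateSpace
    membership: np.ndarray
    palette: tuple[str, ...] = CANONICAL_NETWORKS

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership)
        self.palette = tuple(self.palette)
        if self.membership.ndim != 2:
            raise ValueError("membership must be K x n_gray")
        if self.membership.shape != (len(self.palette), self.space.n_gray):
            raise ValueError("membership shape must be (len(palette), n_gray)")
        if not np.isin(self.membership, (0, 1)).all():
            raise ValueError("membership entries must be 0 or 1")
        self.membership = self.membership.astype(np.uint8)

    def counts(self) -> np.ndarray:
        """Number of networks claiming each grayordinate."""
        return self.membership.sum(axis=0)


# ---------------------------------------------------------------------------
# sidecar helpers


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".dtseries.nii", ".dscalar.nii", ".dlabel.nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _write_sidecar(path: Path, space: GrayordinateSpace,
                   tr_seconds: float | None = None,
                   extra: dict | None = None) -> None:
    doc: dict = {
        "indexing": "0-based",
        "structure": space.structure.tolist(),
        "coords": np.round(space.coords, 6).tolist(),
    }
    if tr_seconds is not None:
        doc["tr_seconds"] = float(tr_seconds)
    if extra:
        doc.update(extra)
    _sidecar_path(path).write_text(json.dumps(doc), encoding="utf-8")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sc}")
    return json.loads(sc.read_text(encoding="utf-8"))


def _space_from_sidecar(doc: dict) -> GrayordinateSpace:
    return GrayordinateSpace(
        structure=np.array(doc["structure"]),
        coords=np.array(doc["coords"], dtype=float),
    )


def _read_matrix_plaintext(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    width = None
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(
                    f"row {i} of {path} has {len(cells)} cells, expected {width}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"non-numeric cell in row {i} of {path}: {exc}")
    if not rows:
        raise ValueError(f"{path} contains no data rows")
    return np.array(rows)


# ---------------------------------------------------------------------------
# dense time series I/O


def write_dense(ts: DenseTimeseries, path: str | Path,
                dialect: str = "plaintext") -> Path:
    """Write a dense time series under the named dialect.

    Both dialects also write the JSON space sidecar so that a file plus its
    sidecar fully reconstruct the ``DenseTimeseries``.
    """
    path = Path(path)
    if dialect == "plaintext":
        np.savetxt(path, ts.values, delimiter="\t", fmt="%.10g")
        _write_sidecar(path, ts.space, tr_seconds=ts.tr_seconds)
    elif dialect == "cifti2":
        img = _dense_to_cifti(ts)
        img.to_filename(str(path))
        _write_sidecar(path, ts.space, tr_seconds=ts.tr_seconds)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_dense(path: str | Path, dialect: str = "plaintext") -> DenseTimeseries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "plaintext":
        values = _read_matrix_plaintext(path)
        doc = _read_sidecar(path)
        if "tr_seconds" not in doc:
            raise ValueError(f"sidecar for {path} is missing field 'tr_seconds'")
        space = _space_from_sidecar(doc)
        return DenseTimeseries(space=space, tr_seconds=doc["tr_seconds"],
                               values=values)
    if dialect == "cifti2":
        return _dense_from_cifti(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _brain_model_axis(space: GrayordinateSpace):
    from nibabel.cifti2 import cifti2_axes as axes

    parts = []
    for tag, cname in (("LEFT_CORTEX", "CIFTI_STRUCTURE_CORTEX_LEFT"),
                       ("RIGHT_CORTEX", "CIFTI_STRUCTURE_CORTEX_RIGHT")):
        n = int((space.structure == tag).sum())
        if n:
            parts.append(axes.BrainModelAxis.from_surface(
                np.arange(n), n, name=cname))
    n_sub = int((space.structure == "SUBCORTEX").sum())
    if n_sub:
        voxels = np.column_stack([np.arange(n_sub),
                                  np.zeros(n_sub, int),
                                  np.zeros(n_sub, int)])
        parts.append(axes.BrainModelAxis(
            ["CIFTI_STRUCTURE_BRAIN_STEM"] * n_sub,
            voxel=voxels, affine=np.eye(4), volume_shape=(n_sub, 1, 1)))
    if not parts:
        raise ValueError("space has no structure tags; cannot build CIFTI axis")
    axis = parts[0]
    for p in parts[1:]:
        axis = axis + p
    return axis


def _dense_to_cifti(ts: DenseTimeseries):
    import nibabel as nib
    from nibabel.cifti2 import cifti2_axes as axes

    series = axes.SeriesAxis(start=0.0, step=ts.tr_seconds,
                             size=ts.n_frames, unit="SECOND")
    header = nib.cifti2.Cifti2Header.from_axes(
        (series, _brain_model_axis(ts.space)))
    return nib.cifti2.Cifti2Image(ts.values.astype(np.float32), header=header)


def _dense_from_cifti(path: Path) -> DenseTimeseries:
    import nibabel as nib

    img = nib.load(str(path))
    series = img.header.get_axis(0)
    bm = img.header.get_axis(1)
    tr = float(series.step)
    if series.unit == "SECOND":
        pass
    elif series.unit == "MILLISECOND":  # pragma: no cover - defensive
        tr /= 1000.0
    space = _space_from_cifti_axis(bm, path)
    return DenseTimeseries(space=space, tr_seconds=tr,
                           values=np.asarray(img.get_fdata(), dtype=float))


def _space_from_cifti_axis(bm, path: Path) -> GrayordinateSpace:
    sc = _sidecar_path(path)
    tags = np.array([_CIFTI_TO_TAG.get(name, "SUBCORTEX") for name in bm.name],
                    dtype="U12")
    if sc.exists():
        doc = json.loads(sc.read_text(encoding="utf-8"))
        space = _space_from_sidecar(doc)
        if space.n_gray == len(tags):
            return space
    # no sidecar: synthesize placeholder coordinates from the grayordinate
    # index (contiguity operations then need an explicit adjacency)
    coords = np.column_stack([np.arange(len(tags), dtype=float),
                              np.zeros(len(tags)), np.zeros(len(tags))])
    return GrayordinateSpace(structure=tags, coords=coords)


# ---------------------------------------------------------------------------
# label / overlap / scalar I/O


def write_labels(lm: LabelMap, path: str | Path,
                 dialect: str = "plaintext") -> Path:
    path = Path(path)
    if dialect == "plaintext":
        np.savetxt(path, lm.labels[None, :], delimiter="\t", fmt="%d")
        _write_sidecar(path, lm.space, extra={"palette": list(lm.palette)})
    elif dialect == "cifti2":
        img = _labels_to_cifti(lm.labels[None, :], lm.palette, lm.space,
                               map_names=["labels"])
        img.to_filename(str(path))
        _write_sidecar(path, lm.space, extra={"palette": list(lm.palette)})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_labels(path: str | Path, dialect: str = "plaintext") -> LabelMap:
    path = Path(path)
    if dialect == "plaintext":
        values = _read_matrix_plaintext(path)
        doc = _read_sidecar(path)
        space = _space_from_sidecar(doc)
        palette = tuple(doc["palette"])
        labels = values[0].astype(int)
        _check_label_range(labels, palette, path)
        return LabelMap(space=space, labels=labels, palette=palette)
    if dialect == "cifti2":
        import nibabel as nib

        img = nib.load(str(path))
        lab_axis = img.header.get_axis(0)
        bm = img.header.get_axis(1)
        doc = _read_sidecar(path)
        palette = tuple(doc["palette"])
        space = _space_from_cifti_axis(bm, path)
        labels = np.asarray(img.get_fdata())[0].astype(int)
        _check_label_range(labels, palette, path)
        return LabelMap(space=space, labels=labels, palette=palette)
    raise ValueError(f"unknown dialect {dialect!r}")


def _check_label_range(labels: np.ndarray, palette: tuple[str, ...],
                       path: Path) -> None:
    if labels.size and (labels.min() < 0 or labels.max() > len(palette)):
        bad = int(labels.max() if labels.max() > len(palette) else labels.min())
        raise ValueError(
            f"{path}: label {bad} outside palette range 0..{len(palette)}")


def write_overlap(om: OverlapMap, path: str | Path,
                  dialect: str = "plaintext") -> Path:
    """Overlap maps use the multi-row label dialect: K rows of 0/1."""
    path = Path(path)
    if dialect == "plaintext":
        np.savetxt(path, om.membership, delimiter="\t", fmt="%d")
        _write_sidecar(path, om.space,
                       extra={"palette": list(om.palette), "kind": "overlap"})
    elif dialect == "cifti2":
        img = _labels_to_cifti(om.membership, ("member",), om.space,
                               map_names=list(om.palette))
        img.to_filename(str(path))
        _write_sidecar(path, om.space,
                       extra={"palette": list(om.palette), "kind": "overlap"})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_overlap(path: str | Path, dialect: str = "plaintext") -> OverlapMap:
    path = Path(path)
    if dialect == "plaintext":
        values = _read_matrix_plaintext(path)
        doc = _read_sidecar(path)
        return OverlapMap(space=_space_from_sidecar(doc),
                          membership=values.astype(int),
                          palette=tuple(doc["palette"]))
    if dialect == "cifti2":
        import nibabel as nib

        img = nib.load(str(path))
        doc = _read_sidecar(path)
        space = _space_from_cifti_axis(img.header.get_axis(1), path)
        return OverlapMap(space=space,
                          membership=np.asarray(img.get_fdata()).astype(int),
                          palette=tuple(doc["palette"]))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_scalar(sm: ScalarMap, path: str | Path,
                 dialect: str = "plaintext") -> Path:
    path = Path(path)
    if dialect == "plaintext":
        np.savetxt(path, sm.values[None, :], delimiter="\t", fmt="%.10g")
        _write_sidecar(path, sm.space, extra={"name": sm.name})
    elif dialect == "cifti2":
        import nibabel as nib
        from nibabel.cifti2 import cifti2_axes as axes

        scalar = axes.ScalarAxis([sm.name])
        header = nib.cifti2.Cifti2Header.from_axes(
            (scalar, _brain_model_axis(sm.space)))
        nib.cifti2.Cifti2Image(sm.values[None, :].astype(np.float32),
                               header=header).to_filename(str(path))
        _write_sidecar(path, sm.space, extra={"name": sm.name})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_scalar(path: str | Path, dialect: str = "plaintext") -> ScalarMap:
    path = Path(path)
    if dialect == "plaintext":
        values = _read_matrix_plaintext(path)
        doc = _read_sidecar(path)
        return ScalarMap(space=_space_from_sidecar(doc),
                         name=doc.get("name", path.stem), values=values[0])
    if dialect == "cifti2":
        import nibabel as nib

        img = nib.load(str(path))
        doc = _read_sidecar(path)
        space = _space_from_cifti_axis(img.header.get_axis(1), path)
        return ScalarMap(space=space, name=doc.get("name", path.stem),
                         values=np.asarray(img.get_fdata())[0])
    raise ValueError(f"unknown dialect {dialect!r}")


def _labels_to_cifti(rows: np.ndarray, palette: tuple[str, ...],
                     space: GrayordinateSpace, map_names: list[str]):
    import nibabel as nib
    from nibabel.cifti2 import cifti2_axes as axes

    rng = np.random.default_rng(0)  # reproducible label colours
    table = {0: ("unassigned", (0.0, 0.0, 0.0, 0.0))}
    for i, name in enumerate(palette, start=1):
        r, g, b = rng.uniform(0.2, 1.0, size=3)
        table[i] = (name, (float(r), float(g), float(b), 1.0))
    lab = axes.LabelAxis(map_names, [dict(table)] * len(map_names))
    header = nib.cifti2.Cifti2Header.from_axes(
        (lab, _brain_model_axis(space)))
    return nib.cifti2.Cifti2Image(np.asarray(rows, dtype=np.float32),
                                  header=header)
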