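"""Shared in-memory containers for hippocampal parcellation and surface FC mapping.

The pipeline moves three kinds of data around:

* voxel- or vertex-wise BOLD time series (:class:`BoldSeries`),
* integer label volumes over a hippocampal voxel grid
  (:class:`ParcellationVolume`),
* scalar fields on a triangulated cortical surface (:class:`VertexMap`,
  carried on a :class:`SurfaceMesh`).

Voxel coordinates are 0-based integer indices into the label volume; a
"location id" in a :class:`BoldSeries` is the flat (C-order) index of a voxel
in that volume, or a vertex index when the series lives on a surface.  The
longitudinal (anterior -> posterior) axis of the hippocampus is axis 0 of
every label volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class BoldSeries:
    """One subject's masked voxel-by-time (or vertex-by-time) signal matrix.

    Parameters
    ----------
    values : (n_locations, n_timepoints) float array
    location_ids : (n_locations,) int array
        Flat voxel indices into the parent volume, or vertex indices.
    tr_seconds : float
        Sampling interval (repetition time).
    """

    values: np.ndarray
    location_ids: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.location_ids = np.asarray(self.location_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (locations x time) matrix")
        if self.values.shape[1] < 2:
            raise ValueError("a BOLD series needs at least 2 timepoints")
        if self.values.shape[0] != self.location_ids.shape[0]:
            raise ValueError("location_ids length must match number of rows")
        if len(np.unique(self.location_ids)) != len(self.location_ids):
            raise ValueError("location_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD series contains non-finite values")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_locations(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass
class ParcellationVolume:
    """Integer label per hippocampal voxel; 0 is background.

    Nonzero labels are expected to partition the hippocampal mask.  Parcel
    index ordering follows the anterior -> posterior rule: the centroid
    coordinate along axis 0 is non-decreasing in the parcel label (see
    :func:`hippofc.parcellation.order_parcels_anterior_posterior`).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D integer volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must have an integer dtype")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative (0 = background)")

    @property
    def mask(self) -> np.ndarray:
        """Boolean volume, True where a voxel carries a nonzero label."""
        return self.labels > 0

    @property
    def parcel_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def voxel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def flat_labels(self, location_ids: np.ndarray) -> np.ndarray:
        """Labels of the voxels addressed by flat indices ``location_ids``."""
        return self.labels.ravel()[np.asarray(location_ids)]

    def same_mask(self, other: "ParcellationVolume") -> bool:
        return self.labels.shape == other.labels.shape and bool(
            np.array_equal(self.mask, other.mask)
        )


@dataclass
class SurfaceMesh:
    """Triangulated cortical surface: vertex positions and triangle indices."""

    vertex_positions: np.ndarray
    triangles: np.ndarray
    _adjacency: csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertex_positions = np.asarray(self.vertex_positions, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertex_positions.ndim != 2 or self.vertex_positions.shape[1] != 3:
            raise ValueError("vertex_positions must be V x 3")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be T x 3")
        v = self.n_vertices
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= v:
            raise ValueError("triangle indices out of range")
        # degenerate triangles: repeated vertex or zero area
        t = self.triangles
        if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
            raise ValueError("mesh contains degenerate (repeated-vertex) triangles")
        p = self.vertex_positions
        cross = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
        if np.any(np.linalg.norm(cross, axis=1) < 1e-12):
            raise ValueError("mesh contains zero-area triangles")
        n_comp, _ = connected_components(self.adjacency, directed=False)
        if n_comp != 1:
            raise ValueError("mesh must be edge-connected")

    @property
    def n_vertices(self) -> int:
        return self.vertex_positions.shape[0]

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with e[:,0] < e[:,1]."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @property
    def adjacency(self) -> csr_matrix:
        """Symmetric boolean vertex adjacency (cached)."""
        if self._adjacency is None:
            e = self.edges
            v = self.n_vertices
            data = np.ones(len(e), dtype=np.int8)
            a = coo_matrix((data, (e[:, 0], e[:, 1])), shape=(v, v))
            self._adjacency = (a + a.T).tocsr()
        return self._adjacency

    @property
    def mean_edge_length_mm(self) -> float:
        e = self.edges
        d = self.vertex_positions[e[:, 0]] - self.vertex_positions[e[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())


VERTEX_MAP_KINDS = ("r", "z", "t", "p_corrected", "significance", "coverage")


@dataclass
class VertexMap:
    """Per-vertex scalar field on a cortical mesh.

    ``kind`` states the interpretation and is validated against the value
    range it implies (correlations in [-1, 1], p-values in [0, 1],
    significance binary, coverage in [0, 1]).
    """

    values: np.ndarray
    kind: str
    flags: np.ndarray | None = None  # per-vertex bookkeeping (e.g. missing)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("a VertexMap holds one scalar per vertex")
        if self.kind not in VERTEX_MAP_KINDS:
            raise ValueError(f"kind must be one of {VERTEX_MAP_KINDS}")
        v = self.values
        if self.kind == "r" and (v.min(initial=0) < -1 or v.max(initial=0) > 1):
            raise ValueError("r-kind values must lie in [-1, 1]")
        if self.kind in ("p_corrected", "coverage") and (
            v.min(initial=0) < 0 or v.max(initial=0) > 1
        ):
            raise ValueError(f"{self.kind}-kind values must lie in [0, 1]")
        if self.kind == "significance" and not np.all(np.isin(v, (0.0, 1.0))):
            raise ValueError("significance values must be binary")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.values.shape:
                raise ValueError("flags must align with values")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    def binary(self) -> np.ndarray:
        """Boolean view of a significance map."""
        if self.kind != "significance":
            raise ValueError("binary() is defined for significance maps only")
        return self.values.astype(bool)


@dataclass
class NetworkAtlas:
    """Per-vertex resting-state network labels (1..n) with network names."""

    labels: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("atlas labels are one integer per vertex")
        self.names = list(self.names)
        n = len(self.names)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, n + 1)):
            raise ValueError(
                "atlas labels must cover exactly 1..n with every network non-empty"
            )

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def n_vertices(self) -> int:
        return self.labels.shape[0]

    def network_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n + 1)[1:]
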