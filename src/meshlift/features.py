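"""Nearest-neighbour feature construction for the mesh-fidelity surrogate.

For every mesh node, the surrogate's input vector concatenates the distances
to its J nearest neighbours, the coarse-level solution at those neighbours,
and the coarse-level solution at the node itself — q = 2J + 1 features per
node, ordered ``[d_1..d_J, y(nb_1)..y(nb_J), y(self)]`` with neighbours
sorted by ascending distance (ties broken by node index).  The training
target is the solution at the same node on the next refinement level, paired
exactly through node nesting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .mesh import TriMesh
from .transport import ConcentrationField

__all__ = [
    "SUPPORTED_METRICS",
    "NeighborSet",
    "NeighborhoodFeatureTable",
    "TrainingSet",
    "nearest_neighbors",
    "build_feature_table",
    "build_training_set",
]

SUPPORTED_METRICS = ("cityblock", "euclidean", "mahalanobis")


@dataclass
class NeighborSet:
    """J nearest neighbours per node (self excluded), ascending distance."""

    mesh: TriMesh
    J: int
    metric: str
    indices: np.ndarray   # (n, J) neighbour node indices
    distances: np.ndarray  # (n, J) metric distances, sorted ascending


@dataclass
class NeighborhoodFeatureTable:
    """Per-node surrogate input vectors of length q = 2J + 1."""

    X: np.ndarray          # (n, 2J+1)
    J: int
    metric: str
    node_ids: np.ndarray   # source node indices (row alignment)
    source_level: int
    output_kind: str

    @property
    def q(self) -> int:
        return 2 * self.J + 1


@dataclass
class TrainingSet:
    """Aligned (features, refined-level target) pairs for one output kind."""

    X: np.ndarray
    y: np.ndarray
    J: int
    metric: str
    output_kind: str

    @property
    def l(self) -> int:  # noqa: E743 - the field's customary symbol
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    def feature_groups(self) -> np.ndarray:
        """Group label per feature column: 0 = neighbour distances,
        1 = neighbour solutions, 2 = own solution."""
        return np.concatenate(
            [np.zeros(self.J, int), np.ones(self.J, int), np.full(1, 2, int)]
        )


def nearest_neighbors(mesh: TriMesh, J: int, metric: str = "cityblock") -> NeighborSet:
    """Find each node's J nearest distinct neighbours under the given metric.

    Distances are computed on raw node coordinates (metres).  The
    mahalanobis metric uses the sample covariance of this mesh's node
    coordinates.  Ordering is ascending distance with ties broken by node
    index (stable), so results are independent of storage order up to exact
    ties.
    """
    if metric not in SUPPORTED_METRICS:
        raise ValueError(f"unsupported metric {metric!r}; choose from {SUPPORTED_METRICS}")
    n = mesh.n_nodes
    if not (0 < J < n):
        raise ValueError(f"J must satisfy 0 < J < n_nodes={n}, got {J}")
    coords = mesh.node_coords
    if metric == "mahalanobis":
        cov = np.cov(coords, rowvar=False)
        if np.linalg.matrix_rank(cov) < coords.shape[1]:
            raise ValueError("singular coordinate covariance; mesh is degenerate")
        D = cdist(coords, coords, metric="mahalanobis", VI=np.linalg.inv(cov))
    else:
        D = cdist(coords, coords, metric=metric)
    np.fill_diagonal(D, np.inf)  # a node is never its own neighbour
    order = np.argsort(D, axis=1, kind="stable")[:, :J]
    dists = np.take_along_axis(D, order, axis=1)
    return NeighborSet(mesh=mesh, J=J, metric=metric, indices=order, distances=dists)


def build_feature_table(
    field: ConcentrationField, neighbors: NeighborSet, output_kind: str
) -> NeighborhoodFeatureTable:
    """Assemble rows ``[d_1..d_J, y(nb_1)..y(nb_J), y(self)]`` from a solved
    field and a neighbour set on the same mesh."""
    if field.mesh is not neighbors.mesh:
        if (
            field.mesh.n_nodes != neighbors.mesh.n_nodes
            or not np.array_equal(field.mesh.node_coords, neighbors.mesh.node_coords)
        ):
            raise ValueError("field and neighbour set are defined on different meshes")
    y0 = field.values(output_kind)
    X = np.hstack(
        [neighbors.distances, y0[neighbors.indices], y0[:, None]]
    )
    return NeighborhoodFeatureTable(
        X=X,
        J=neighbors.J,
        metric=neighbors.metric,
        node_ids=np.arange(field.mesh.n_nodes),
        source_level=field.mesh.level,
        output_kind=output_kind,
    )


def build_training_set(
    coarse_features: NeighborhoodFeatureTable,
    fine_field: ConcentrationField,
    correspondence: np.ndarray,
) -> TrainingSet:
    """Pair coarse-level feature rows with refined-level targets.

    ``correspondence`` is the (n_coarse, 2) array of (coarse, fine) node
    index pairs from :func:`meshlift.mesh.common_nodes`.
    """
    corr = dict(zip(correspondence[:, 0].tolist(), correspondence[:, 1].tolist()))
    try:
        fine_idx = np.array([corr[int(i)] for i in coarse_features.node_ids])
    except KeyError as exc:
        raise ValueError(f"node {exc} has no image in the fine mesh") from exc
    y_fine = fine_field.values(coarse_features.output_kind)
    return TrainingSet(
        X=coarse_features.X,
        y=y_fine[fine_idx],
        J=coarse_features.J,
        metric=coarse_features.metric,
        output_kind=coarse_features.output_kind,
    )
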