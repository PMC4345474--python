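"""Annular triangular meshes and nested longest-edge refinement.

The computational domain is an arterial cross-section: an annulus with lumen
radius ``R`` and wall thickness ``W``.  A hierarchy of meshes is produced by
bisecting the longest edge of every element (with recursive Rivara-style
closure bisections so no hanging node survives).  Because bisection only adds
midpoints, the node set of every level is a superset of its parent's node
set — the property the multi-fidelity learning pipeline relies on to pair
coarse-mesh nodes with their refined-mesh solutions exactly, without any
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "DomainGeometry",
    "TriMesh",
    "InvalidGeometryError",
    "RefinementError",
    "LineageError",
    "build_annulus_mesh",
    "refine_longest_edge",
    "common_nodes",
]

# boundary tag codes
INTERIOR = 0
MURAL = 1          # lumen-facing (inner) surface: drug flux enters here
PERIVASCULAR = 2   # adventitial (outer) surface: perfect sink

TAG_NAMES = {INTERIOR: "interior", MURAL: "mural", PERIVASCULAR: "perivascular"}


class InvalidGeometryError(ValueError):
    """Raised for non-positive lumen radius or wall thickness."""


class RefinementError(RuntimeError):
    """Raised when refinement encounters a degenerate element."""


class LineageError(ValueError):
    """Raised when two meshes are not in an ancestry relation."""


@dataclass(frozen=True)
class DomainGeometry:
    """Annulus geometry: lumen radius ``R`` and wall thickness ``W`` (metres)."""

    R: float = 3.0e-3
    W: float = 0.5e-3

    def __post_init__(self) -> None:
        if not (self.R > 0.0 and self.W > 0.0):
            raise InvalidGeometryError(
                f"R and W must be strictly positive, got R={self.R}, W={self.W}"
            )

    @property
    def outer_radius(self) -> float:
        return self.R + self.W

    @property
    def area(self) -> float:
        """Exact annulus area pi*((R+W)^2 - R^2)."""
        return np.pi * (self.outer_radius**2 - self.R**2)


@dataclass
class TriMesh:
    """Conforming triangular mesh with refinement lineage.

    Attributes
    ----------
    node_coords : (n, 2) float array, metres.
    elements : (m, 3) int array of node indices, counter-clockwise.
    boundary_tag : (n,) int array with codes interior/mural/perivascular.
    level : refinement level (0 = coarsest).
    parent : the mesh this one was refined from, or None.
    parent_node_map : (n_parent,) int array; injection of parent node indices
        into this mesh's node indices (coordinate-preserving).
    geometry : the annulus geometry, if known (used to project boundary
        midpoints onto the exact circles during refinement).
    """

    node_coords: np.ndarray
    elements: np.ndarray
    boundary_tag: np.ndarray
    level: int = 0
    parent: "TriMesh | None" = field(default=None, repr=False)
    parent_node_map: np.ndarray | None = None
    geometry: DomainGeometry | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_areas(self) -> np.ndarray:
        """Signed areas (positive for counter-clockwise elements)."""
        p = self.node_coords[self.elements]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def total_area(self) -> float:
        return float(np.sum(self.element_areas()))

    def min_angle(self) -> float:
        """Smallest interior angle over all elements, in radians."""
        p = self.node_coords[self.elements]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return float(np.min(angles))

    def boundary_nodes(self, tag: int) -> np.ndarray:
        return np.flatnonzero(self.boundary_tag == tag)

    def edges(self) -> np.ndarray:
        """All unique undirected element edges as (n_edges, 2) sorted pairs."""
        e = self.elements
        pairs = np.vstack([e[:, [0, 1]], e[:, [1, 2]], e[:, [2, 0]]])
        pairs.sort(axis=1)
        return np.unique(pairs, axis=0)

    def permute_nodes(self, perm: np.ndarray) -> "TriMesh":
        """Relabel nodes by permutation ``perm`` (new index of old node i is
        perm[i]).  Used to verify that downstream results are invariant to
        storage order.  Lineage links are dropped."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        coords = np.empty_like(self.node_coords)
        coords[perm] = self.node_coords
        tags = np.empty_like(self.boundary_tag)
        tags[perm] = self.boundary_tag
        return TriMesh(
            node_coords=coords,
            elements=perm[self.elements],
            boundary_tag=tags,
            level=self.level,
            geometry=self.geometry,
        )


def _ensure_ccw(coords: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p = coords[elements]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    area2 = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    flip = area2 < 0
    elements = elements.copy()
    elements[flip] = elements[flip][:, [0, 2, 1]]
    return elements


def build_annulus_mesh(
    geometry: DomainGeometry, target_element_count: int, seed: int = 0
) -> TriMesh:
    """Delaunay-triangulate the annular cross-section.

    Points are placed on concentric rings between the two circles with a
    seeded angular jitter (and a mild radial jitter for interior rings) so
    elements are variably sized, then triangulated with scipy's Delaunay and
    the triangles falling inside the lumen discarded by centroid radius.
    Inner-circle nodes are tagged mural, outer-circle nodes perivascular.

    The element count lands within roughly +/-20% of ``target_element_count``.
    Deterministic for a fixed seed.
    """
    if target_element_count < 16:
        raise ValueError("target_element_count must be >= 16")
    R, W = geometry.R, geometry.W
    area = geometry.area
    # structured estimate: elements ~= 2 * n_radial * n_angular
    h = np.sqrt(2.0 * area / target_element_count)
    n_r = max(1, round(W / h))
    n_t = max(8, round(target_element_count / (2.0 * n_r)))

    rng = np.random.default_rng(seed)
    pts = []
    tags = []
    dr = W / n_r
    for i in range(n_r + 1):
        r = R + i * dr
        # stagger alternate rings by half a cell; jitter breaks symmetry
        offs = (0.5 * (i % 2) + rng.uniform(-0.22, 0.22, size=n_t)) * (2 * np.pi / n_t)
        ang = 2.0 * np.pi * np.arange(n_t) / n_t + offs + rng.uniform(0, 2 * np.pi)
        if i == 0:
            tag = MURAL
            rr = np.full(n_t, r)
        elif i == n_r:
            tag = PERIVASCULAR
            rr = np.full(n_t, r)
        else:
            tag = INTERIOR
            rr = r + rng.uniform(-0.2, 0.2, size=n_t) * dr
        pts.append(np.column_stack([rr * np.cos(ang), rr * np.sin(ang)]))
        tags.append(np.full(n_t, tag, dtype=np.int8))
    coords = np.vstack(pts)
    tag_arr = np.concatenate(tags)

    tri = Delaunay(coords)
    # triangles spanning the lumen hole have all three vertices on the inner
    # circle (only mural nodes bound the hole); everything else is annulus
    simp = tri.simplices
    lumen = np.all(tag_arr[simp] == MURAL, axis=1)
    elements = _ensure_ccw(coords, simp[~lumen].astype(np.int64))

    mesh = TriMesh(
        node_coords=coords,
        elements=elements,
        boundary_tag=tag_arr,
        level=0,
        geometry=geometry,
    )
    if np.any(mesh.element_areas() <= 0):
        raise RefinementError("degenerate element produced by triangulation")
    return mesh


def _longest_edge(coords: list, tri: tuple[int, int, int]) -> tuple[int, int]:
    """Longest edge of a triangle; ties broken by lexicographically smallest
    (min-index, max-index) pair so refinement is deterministic."""
    best = None
    best_len = -1.0
    for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
        key = (min(a, b), max(a, b))
        pa, pb = coords[a], coords[b]
        d = (pa[0] - pb[0]) ** 2 + (pa[1] - pb[1]) ** 2
        if d > best_len or (d == best_len and key < best):
            best_len = d
            best = key
    return best


def refine_longest_edge(mesh: TriMesh) -> TriMesh:
    """Bisect the longest edge of every element, with recursive closure.

    Splitting the longest edge of a triangle leaves a hanging node on the
    neighbouring triangle; that neighbour is then bisected at *its* longest
    edge, recursively (Rivara), until the mesh is conforming again.  Existing
    nodes never move, so node sets nest across levels.  A midpoint created on
    a boundary edge (both endpoints mural, or both perivascular) is projected
    onto the exact circle when the mesh knows its geometry, keeping the
    discrete boundary converging to the true circles without disturbing
    interior nesting.
    """
    areas = mesh.element_areas()
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        raise RefinementError(f"degenerate input element(s): {bad.tolist()}")

    coords = [tuple(p) for p in mesh.node_coords]
    tags = list(mesh.boundary_tag)
    geometry = mesh.geometry
    midpoint: dict[tuple[int, int], int] = {}

    def coords_arr(idx: int) -> np.ndarray:
        return np.asarray(coords[idx])

    def get_midpoint(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        m = midpoint.get(key)
        if m is not None:
            return m
        p = 0.5 * (coords_arr(a) + coords_arr(b))
        ta, tb = tags[a], tags[b]
        if ta == tb and ta in (MURAL, PERIVASCULAR):
            tag = ta
            if geometry is not None:
                r = geometry.R if ta == MURAL else geometry.outer_radius
                nrm = np.hypot(p[0], p[1])
                if nrm > 0:
                    p = p * (r / nrm)
        else:
            tag = INTERIOR
        coords.append((float(p[0]), float(p[1])))
        tags.append(tag)
        m = len(coords) - 1
        midpoint[key] = m
        return m

    def has_hanging(tri: tuple[int, int, int]) -> tuple[int, int] | None:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if (min(a, b), max(a, b)) in midpoint:
                return (a, b)
        return None

    def bisect(tri: tuple[int, int, int]) -> tuple[tuple, tuple]:
        a, b = _longest_edge(coords, tri)
        c = next(v for v in tri if v not in (a, b))
        m = get_midpoint(a, b)
        return (a, m, c), (m, b, c)

    # Phase 1: every original element gets its longest edge bisected.
    # Phase 2 (closure): keep bisecting any triangle with a hanging node.
    work = [tuple(int(v) for v in e) for e in mesh.elements]
    done: list[tuple[int, int, int]] = []
    stack = [(t, True) for t in work]  # (triangle, must_split)
    guard = 0
    max_ops = 200 * len(work) + 10000
    while stack:
        guard += 1
        if guard > max_ops:  # longest-edge bisection terminates; this is a safety net
            raise RefinementError("closure bisection did not terminate")
        tri, must = stack.pop()
        if must or has_hanging(tri) is not None:
            t1, t2 = bisect(tri)
            stack.append((t1, False))
            stack.append((t2, False))
        else:
            done.append(tri)

    # closure may have put midpoints on edges of triangles finalized earlier
    changed = True
    while changed:
        changed = False
        nxt = []
        for tri in done:
            if has_hanging(tri) is not None:
                t1, t2 = bisect(tri)
                nxt.extend([t1, t2])
                changed = True
            else:
                nxt.append(tri)
        done = nxt

    new_coords = np.asarray(coords, dtype=float)
    elements = _ensure_ccw(new_coords, np.asarray(done, dtype=np.int64))
    refined = TriMesh(
        node_coords=new_coords,
        elements=elements,
        boundary_tag=np.asarray(tags, dtype=np.int8),
        level=mesh.level + 1,
        parent=mesh,
        parent_node_map=np.arange(mesh.n_nodes, dtype=np.int64),
        geometry=geometry,
    )
    if np.any(refined.element_areas() <= 0):
        raise RefinementError("refinement produced a degenerate element")
    return refined


def build_hierarchy(
    geometry: DomainGeometry, target_element_count: int, n_refinements: int, seed: int = 0
) -> list[TriMesh]:
    """Level-0 mesh plus ``n_refinements`` nested longest-edge refinements."""
    meshes = [build_annulus_mesh(geometry, target_element_count, seed=seed)]
    for _ in range(n_refinements):
        meshes.append(refine_longest_edge(meshes[-1]))
    return meshes


def common_nodes(coarse: TriMesh, fine: TriMesh) -> np.ndarray:
    """Pair every coarse node with its image in a refinement descendant.

    Returns an (n_coarse, 2) array of (coarse_index, fine_index) pairs; the
    paired nodes have identical coordinates because refinement never moves a
    parent node.  Raises :class:`LineageError` if ``fine`` is not ``coarse``
    or one of its refinement descendants.
    """
    if fine is coarse:
        idx = np.arange(coarse.n_nodes, dtype=np.int64)
        return np.column_stack([idx, idx])
    chain = []
    m = fine
    while m is not None and m is not coarse:
        chain.append(m)
        m = m.parent
    if m is None:
        raise LineageError("meshes are not in an ancestry relation")
    # compose parent_node_maps from coarse up to fine
    mapping = np.arange(coarse.n_nodes, dtype=np.int64)
    for child in reversed(chain):
        mapping = child.parent_node_map[mapping]
    return np.column_stack([np.arange(coarse.n_nodes, dtype=np.int64), mapping])
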