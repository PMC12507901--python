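"""Tetrahedral meshes from label masks.

Each labelled voxel is split into a fixed five-tet (or six-tet Kuhn)
decomposition on the shared corner-node grid. For the five-tet split the
mirror variant alternates with voxel parity so that triangular faces on
shared cube faces coincide and the mesh is watertight; the Kuhn split uses
one consistent main diagonal and matches by translation. Element region
labels are inherited from the voxel labels. Node sets at the distal (low z)
and proximal (high z) ends are defined by a configurable fraction of the
labelled z-extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import BACKGROUND, BONE, GAP, IMPLANT

__all__ = ["TetMesh", "MeshConfig", "build_mesh", "promote_to_quadratic"]

# Cube corner local indices: bit 0 -> x, bit 1 -> y, bit 2 -> z, i.e.
# v0=(0,0,0) v1=(1,0,0) v2=(0,1,0) v3=(1,1,0) v4=(0,0,1) v5=(1,0,1) v6=(0,1,1) v7=(1,1,1)
_CORNER_OFFSETS = np.array(
    [[(c >> 0) & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)], dtype=np.int64
)

# Five-tet decomposition; the central tet spans the odd (even) parity corners
# and the variant alternates with (i+j+k) parity so shared-face diagonals match.
_FIVE_TET_EVEN = np.array(
    [[0, 1, 2, 4], [3, 1, 2, 7], [5, 1, 4, 7], [6, 2, 4, 7], [1, 2, 4, 7]], dtype=np.int64
)
_FIVE_TET_ODD = np.array(
    [[1, 0, 3, 5], [2, 0, 3, 6], [4, 0, 5, 6], [7, 3, 5, 6], [0, 3, 5, 6]], dtype=np.int64
)

# Six-tet Kuhn decomposition along the 0-7 diagonal (parity independent).
_SIX_TET = np.array(
    [[0, 1, 3, 7], [0, 1, 5, 7], [0, 2, 3, 7], [0, 2, 6, 7], [0, 4, 5, 7], [0, 4, 6, 7]],
    dtype=np.int64,
)


@dataclass
class MeshConfig:
    """Knobs for the voxel-to-tet conversion."""

    decomposition: str = "5tet"  # '5tet' | '6tet'
    include_labels: tuple[int, ...] = (BONE, 2, GAP, IMPLANT)  # bone(1)/trabecular(2)/gap/implant
    end_set_fraction: float = 0.02  # z-extent fraction defining distal/proximal node sets

    def __post_init__(self) -> None:
        if self.decomposition not in ("5tet", "6tet"):
            raise ValueError("decomposition must be '5tet' or '6tet'")
        if not 0 < self.end_set_fraction < 0.5:
            raise ValueError("end-set fraction must lie in (0, 0.5)")


@dataclass
class TetMesh:
    """Tetrahedral mesh with per-element region labels and end node sets.

    ``nodes`` are mm coordinates (n, 3); ``elements`` is (m, 4) for linear
    tets or (m, 10) for quadratic tets (corner nodes first, then midside
    nodes in the conventional edge order 01,12,20,03,13,23). ``region`` holds
    one label per element using the volume label constants (bone voxels keep
    their cortical/trabecular code but both count as bone). ``node_sets``
    maps set names ('distal', 'proximal') to node index arrays.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_voxel: np.ndarray | None = None  # flat index of each element's source voxel

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.region = np.asarray(self.region, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] not in (4, 10):
            raise ValueError("elements must be (m, 4) or (m, 10)")
        if self.region.shape != (self.n_elements,):
            raise ValueError("one region label per element required")
        if self.elements.size and (self.elements.min() < 0 or self.elements.max() >= self.n_nodes):
            raise ValueError("element connectivity references nodes out of range")
        for name, idx in self.node_sets.items():
            idx = np.asarray(idx, dtype=np.int64)
            self.node_sets[name] = idx
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise ValueError(f"node set {name!r} references nodes out of range")
        d = self.node_sets.get("distal")
        p = self.node_sets.get("proximal")
        if d is not None and p is not None and np.intersect1d(d, p).size:
            raise ValueError("distal and proximal node sets must be disjoint")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def order(self) -> int:
        return 1 if self.elements.shape[1] == 4 else 2

    def corner_elements(self) -> np.ndarray:
        """(m, 4) corner connectivity regardless of element order."""
        return self.elements[:, :4]

    def volumes(self) -> np.ndarray:
        """Signed tet volumes from the corner nodes (positive for valid meshes)."""
        x = self.nodes[self.corner_elements()]
        a = x[:, 1] - x[:, 0]
        b = x[:, 2] - x[:, 0]
        c = x[:, 3] - x[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def elements_in(self, *labels: int) -> np.ndarray:
        return np.flatnonzero(np.isin(self.region, labels))

    def gap_elements(self) -> np.ndarray:
        return self.elements_in(GAP)

    def implant_elements(self) -> np.ndarray:
        return self.elements_in(IMPLANT)

    def bone_elements(self) -> np.ndarray:
        return self.elements_in(1, 2)


def build_mesh(labels: np.ndarray, spacing, config: MeshConfig | None = None) -> TetMesh:
    """Convert a label map into a watertight tet mesh.

    Parameters
    ----------
    labels:
        Integer label map, shape (nx, ny, nz); voxels whose label is in
        ``config.include_labels`` are meshed.
    spacing:
        Voxel edge length(s) in mm (scalar or per-axis triple).
    """
    config = config or MeshConfig()
    labels = np.asarray(labels)
    spacing = np.broadcast_to(np.atleast_1d(np.asarray(spacing, dtype=float)), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    sel = np.isin(labels, config.include_labels) & (labels != BACKGROUND)
    vox = np.argwhere(sel)
    if vox.size == 0:
        raise ValueError("no labelled voxels to mesh")

    # Corner node ids on the (nx+1, ny+1, nz+1) grid, allocated lazily.
    grid_shape = tuple(np.asarray(labels.shape) + 1)
    corner_idx = vox[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (v, 8, 3)
    flat = np.ravel_multi_index(corner_idx.reshape(-1, 3).T, grid_shape)
    unique_flat, inverse = np.unique(flat, return_inverse=True)
    corner_ids = inverse.reshape(-1, 8)  # (v, 8) global node ids
    nodes = np.column_stack(np.unravel_index(unique_flat, grid_shape)).astype(float) * spacing

    if config.decomposition == "6tet":
        tets = corner_ids[:, _SIX_TET].reshape(-1, 4)
        tets_per_vox = 6
    else:
        parity = vox.sum(axis=1) % 2
        local = np.where(parity[:, None, None] == 0, _FIVE_TET_EVEN[None], _FIVE_TET_ODD[None])
        tets = np.take_along_axis(
            corner_ids[:, None, :].repeat(5, axis=1), local, axis=2
        ).reshape(-1, 4)
        tets_per_vox = 5

    region = np.repeat(labels[sel.nonzero()], tets_per_vox)
    element_voxel = np.repeat(np.ravel_multi_index(vox.T, labels.shape), tets_per_vox)

    mesh = TetMesh(nodes, tets, region, element_voxel=element_voxel)
    _orient_positive(mesh)
    mesh.node_sets = _end_node_sets(mesh, config.end_set_fraction)
    return TetMesh(mesh.nodes, mesh.elements, mesh.region, mesh.node_sets, mesh.element_voxel)


def _orient_positive(mesh: TetMesh) -> None:
    """Swap two nodes of any negatively oriented tet so all volumes are > 0."""
    vol = mesh.volumes()
    flip = vol < 0
    if np.any(flip):
        e = mesh.elements
        e[flip, 2], e[flip, 3] = e[flip, 3].copy(), e[flip, 2].copy()
    if np.any(np.isclose(mesh.volumes(), 0)):
        bad = int(np.flatnonzero(np.isclose(mesh.volumes(), 0))[0])
        raise ValueError(f"degenerate (zero-volume) element {bad}")


def _end_node_sets(mesh: TetMesh, fraction: float) -> dict[str, np.ndarray]:
    z = mesh.nodes[:, 2]
    z_lo, z_hi = z.min(), z.max()
    band = fraction * (z_hi - z_lo)
    distal = np.flatnonzero(z <= z_lo + band)
    proximal = np.flatnonzero(z >= z_hi - band)
    return {"distal": distal, "proximal": proximal}


# Edge order for the 10-node tet: midside nodes on edges 01, 12, 20, 03, 13, 23.
_TET10_EDGES = np.array([[0, 1], [1, 2], [2, 0], [0, 3], [1, 3], [2, 3]], dtype=np.int64)


def promote_to_quadratic(mesh: TetMesh) -> TetMesh:
    """Insert shared midside nodes, turning linear tets into 10-node tets."""
    if mesh.order != 1:
        raise ValueError("mesh is already quadratic")
    e = mesh.elements
    edges = e[:, _TET10_EDGES]  # (m, 6, 2)
    edges_sorted = np.sort(edges.reshape(-1, 2), axis=1)
    unique_edges, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.nodes[unique_edges[:, 0]] + mesh.nodes[unique_edges[:, 1]])
    mid_ids = mesh.n_nodes + inverse.reshape(mesh.n_elements, 6)
    nodes = np.vstack([mesh.nodes, mid])
    elements = np.hstack([e, mid_ids])
    node_sets = {}
    for name, idx in mesh.node_sets.items():
        members = np.zeros(mesh.n_nodes, dtype=bool)
        members[idx] = True
        on_set = members[unique_edges].all(axis=1)
        node_sets[name] = np.concatenate([idx, mesh.n_nodes + np.flatnonzero(on_set)])
    return TetMesh(nodes, elements, mesh.region.copy(), node_sets, mesh.element_voxel)
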