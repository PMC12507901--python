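"""Linear-elastic static finite elements on tetrahedral meshes.

Small-strain isotropic elasticity, mm-N-MPa units (1 N/mm² = 1 MPa).
Constant-strain 4-node tets are the baseline; 10-node quadratic tets use
4-point Gauss quadrature with the per-element strain reported as the
volume average over integration points, so downstream consumers always see
one strain tensor per element.

The distal node set is fully constrained in the three translations; the
gait-cycle amplitude table applies a total (Fx, Fy, Fz) at each sample time,
split equally over the proximal nodes as concentrated loads. Because the
problem is linear, the default solution path factorizes the constrained
stiffness once, solves three unit-load systems (1 N total along each axis)
and superposes them with the amplitude table; a per-sample re-solve mode
exists as an independent cross-check.

Voigt order is (xx, yy, zz, xy, yz, xz) with engineering shear strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "LoadCase",
    "BoundaryCondition",
    "FEResult",
    "LinearGaitSolver",
    "assemble",
    "solve_static",
    "von_mises",
]

_GAUSS_A = 0.5854101966249685  # 4-point tet rule barycentric coordinates
_GAUSS_B = 0.1381966011250105


@dataclass
class LoadCase:
    """Amplitude table of total knee-force components over the gait cycle.

    ``times`` are cycle fractions (strictly increasing, within [0, 1]);
    ``forces`` holds the total (Fx, Fy, Fz) in Newtons applied to the target
    node set at each sample.
    """

    times: np.ndarray
    forces: np.ndarray
    node_set: str = "proximal"
    level: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("amplitude table must be non-empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("amplitude times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] > 1:
            raise ValueError("amplitude times must lie in [0, 1]")
        if self.forces.shape != (self.times.size, 3):
            raise ValueError(f"forces must be ({self.times.size}, 3)")

    def scaled(self, alpha: float) -> "LoadCase":
        return LoadCase(self.times.copy(), alpha * self.forces, self.node_set, self.level)

    def peak_force_magnitude(self) -> float:
        return float(np.linalg.norm(self.forces, axis=1).max())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "t_frac": self.times,
                "Fx_N": self.forces[:, 0],
                "Fy_N": self.forces[:, 1],
                "Fz_N": self.forces[:, 2],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "LoadCase":
        df = pd.read_csv(path)
        return cls(df["t_frac"].to_numpy(), df[["Fx_N", "Fy_N", "Fz_N"]].to_numpy(), **kw)


@dataclass
class BoundaryCondition:
    """Fixed translational DOFs (U1, U2, U3) on a node set, default distal."""

    node_set: str = "distal"
    dofs: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if not self.dofs or any(d not in (0, 1, 2) for d in self.dofs):
            raise ValueError("only translational DOFs 0..2 exist for solid tets")


def _isotropic_D(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Batched 6x6 isotropic elasticity matrices (engineering shear)."""
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(E <= 0):
        raise ValueError("Young's modulus must be positive")
    if np.any(nu < 0) or np.any(nu >= 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros(E.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            D[..., i, j] = lam
        D[..., i, i] = lam + 2 * mu
        D[..., 3 + i, 3 + i] = mu
    return D


def _tet_geometry(nodes: np.ndarray, corners: np.ndarray):
    """Volumes and constant shape-function gradients for each tet."""
    x = nodes[corners]  # (m, 4, 3)
    M = np.concatenate([np.ones_like(x[..., :1]), x], axis=2)  # (m, 4, 4)
    vol = np.linalg.det(M) / 6.0
    if np.any(vol <= 0):
        bad = int(np.flatnonzero(vol <= 0)[0])
        raise ValueError(f"degenerate or inverted element {bad} (volume {vol[bad]:g})")
    C = np.linalg.inv(M)  # rows: 1, x, y, z; columns: shape functions
    grads = C[:, 1:4, :].transpose(0, 2, 1)  # (m, 4, 3): dN_i/d(x,y,z)
    return vol, grads


def _strain_B_linear(grads: np.ndarray) -> np.ndarray:
    """(m, 6, 12) strain-displacement matrices for constant-strain tets."""
    m = grads.shape[0]
    B = np.zeros((m, 6, 12))
    for i in range(4):
        gx, gy, gz = grads[:, i, 0], grads[:, i, 1], grads[:, i, 2]
        c = 3 * i
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


_TET10_EDGES = np.array([[0, 1], [1, 2], [2, 0], [0, 3], [1, 3], [2, 3]])


def _tet10_shape_gradients(grad_L: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Gradients of the 10 quadratic shape functions at barycentric point L.

    ``grad_L`` is (m, 4, 3) with the (constant) gradients of the barycentric
    coordinates; returns (m, 10, 3).
    """
    m = grad_L.shape[0]
    g = np.zeros((m, 10, 3))
    for i in range(4):
        g[:, i] = (4 * L[i] - 1) * grad_L[:, i]
    for e, (a, b) in enumerate(_TET10_EDGES):
        g[:, 4 + e] = 4 * (L[a] * grad_L[:, b] + L[b] * grad_L[:, a])
    return g


def _strain_B_from_gradients(g: np.ndarray) -> np.ndarray:
    """(m, 6, 3*nn) B matrix from per-node shape gradients (m, nn, 3)."""
    m, nn, _ = g.shape
    B = np.zeros((m, 6, 3 * nn))
    for i in range(nn):
        gx, gy, gz = g[:, i, 0], g[:, i, 1], g[:, i, 2]
        c = 3 * i
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


@dataclass
class _ElementCache:
    volumes: np.ndarray  # (m,)
    B_mean: np.ndarray  # (m, 6, 3*nn) element-average strain-displacement matrix
    D: np.ndarray  # (m, 6, 6)
    dof_map: np.ndarray  # (m, 3*nn) global dof per local dof


def assemble(mesh, materials, _chunk: int = 50_000):
    """Assemble the global stiffness matrix.

    Returns ``(K, cache)`` where ``K`` is CSR of shape (3n, 3n), symmetric and
    positive semi-definite before constraints (rigid-body modes in its null
    space), and ``cache`` carries per-element data for strain/stress recovery.
    """
    E = np.asarray(materials.E, dtype=float)
    nu = np.asarray(materials.nu, dtype=float)
    m = mesh.n_elements
    if E.shape != (m,) or nu.shape != (m,):
        raise ValueError("materials must provide one (E, nu) pair per element")
    D = _isotropic_D(E, nu)

    corners = mesh.corner_elements()
    vol, grads = _tet_geometry(mesh.nodes, corners)

    if mesh.order == 1:
        conn = corners
        nn = 4
        B_gauss = [_strain_B_linear(grads)]
        w_gauss = [vol]
    else:
        conn = mesh.elements
        nn = 10
        B_gauss, w_gauss = [], []
        for gp in range(4):
            L = np.full(4, _GAUSS_B)
            L[gp] = _GAUSS_A
            g = _tet10_shape_gradients(grads, L)
            B_gauss.append(_strain_B_from_gradients(g))
            w_gauss.append(vol / 4.0)
    B_mean = sum(w[:, None, None] * B for w, B in zip(w_gauss, B_gauss)) / vol[:, None, None]

    dof_map = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(m, 3 * nn)
    ndof = 3 * mesh.n_nodes

    rows_all, cols_all, vals_all = [], [], []
    for start in range(0, m, _chunk):
        sl = slice(start, start + _chunk)
        Ke = np.zeros((dof_map[sl].shape[0], 3 * nn, 3 * nn))
        for w, B in zip(w_gauss, B_gauss):
            Ke += np.einsum("eji,ejk,ekl,e->eil", B[sl], D[sl], B[sl], w[sl], optimize=True)
        dm = dof_map[sl]
        rows_all.append(np.repeat(dm, 3 * nn, axis=1).ravel())
        cols_all.append(np.tile(dm, (1, 3 * nn)).ravel())
        vals_all.append(Ke.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(ndof, ndof),
    ).tocsr()
    return K, _ElementCache(volumes=vol, B_mean=B_mean, D=D, dof_map=dof_map)


class FEResult:
    """Field outputs of a static gait-cycle solve.

    Per sample time the result exposes nodal displacements U (mm), one
    symmetric strain tensor E per element, the stress tensor S and von Mises
    stress (MPa), time-invariant element volumes IVOL (mm³) and the total
    reaction force RF (N) at the fixed nodes. Internally the fields are
    linear combinations of a small solution basis (three unit-load solutions
    in superposition mode; one solution per sample in re-solve mode).
    """

    def __init__(self, times, coeffs, basis_U, basis_strain, cache: _ElementCache,
                 rf_basis, applied):
        self.times = np.asarray(times, dtype=float)
        self._coeffs = np.asarray(coeffs, dtype=float)  # (k, p)
        self._basis_U = basis_U  # (p, n, 3)
        self._basis_strain = basis_strain  # (p, m, 6)
        self._cache = cache
        self._rf_basis = np.asarray(rf_basis, dtype=float)  # (p, 3)
        self.applied = np.asarray(applied, dtype=float)  # (k, 3)

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def element_volumes(self) -> np.ndarray:
        """IVOL: element volumes in mm³ (time-invariant)."""
        return self._cache.volumes

    def displacement(self, i: int) -> np.ndarray:
        """(n, 3) nodal displacement at sample i, mm."""
        return np.einsum("p,pnc->nc", self._coeffs[i], self._basis_U)

    def strain_voigt(self, i: int, elements=None) -> np.ndarray:
        basis = self._basis_strain if elements is None else self._basis_strain[:, elements]
        return np.einsum("p,pmv->mv", self._coeffs[i], basis)

    def strain_history(self, elements=None) -> np.ndarray:
        """(k, m_sel, 6) engineering-Voigt strain for the selected elements."""
        basis = self._basis_strain if elements is None else self._basis_strain[:, elements]
        return np.einsum("kp,pmv->kmv", self._coeffs, basis)

    def strain_tensors(self, i: int, elements=None) -> np.ndarray:
        """(m_sel, 3, 3) symmetric strain tensors (tensorial shear) at sample i."""
        return voigt_to_tensor(self.strain_voigt(i, elements))

    def stress_voigt(self, i: int, elements=None) -> np.ndarray:
        D = self._cache.D if elements is None else self._cache.D[elements]
        return np.einsum("mvw,mw->mv", D, self.strain_voigt(i, elements))

    def von_mises_field(self, i: int, elements=None) -> np.ndarray:
        return von_mises(self.stress_voigt(i, elements))

    def von_mises_history(self, elements=None) -> np.ndarray:
        """(k, m_sel) von Mises stress over the cycle."""
        D = self._cache.D if elements is None else self._cache.D[elements]
        basis_stress = np.einsum("mvw,pmw->pmv", D,
                                 self._basis_strain if elements is None
                                 else self._basis_strain[:, elements])
        stress = np.einsum("kp,pmv->kmv", self._coeffs, basis_stress)
        return von_mises(stress)

    def reaction_force(self, i: int) -> np.ndarray:
        """Total (Rx, Ry, Rz) at the fixed nodes at sample i, N."""
        return self._coeffs[i] @ self._rf_basis

    def reaction_trace(self) -> np.ndarray:
        """(k, 3) reaction-force totals over the cycle."""
        return self._coeffs @ self._rf_basis


def _nodal_force_vector(mesh, node_set: str, total: np.ndarray,
                        distribution: str = "equal") -> np.ndarray:
    """Concentrated loads on a node set summing to ``total``.

    ``distribution='equal'`` splits the total equally across the set (the
    default for the gait pipeline). ``'area'`` weights nodes by the
    consistent (tributary-area) load of a constant traction on the boundary
    faces spanned by the set — the distribution that reproduces a uniform
    stress state exactly on a coarse mesh, used for analytic verification.
    """
    nodes = mesh.node_sets.get(node_set)
    if nodes is None or nodes.size == 0:
        raise ValueError(f"load target node set {node_set!r} is empty or missing")
    if distribution == "equal":
        w = np.full(nodes.size, 1.0 / nodes.size)
    elif distribution == "area":
        w_full = _tributary_weights(mesh, nodes)
        w = w_full[nodes]
        if w.sum() <= 0:
            raise ValueError(f"node set {node_set!r} spans no boundary faces")
        w = w / w.sum()
    else:
        raise ValueError("distribution must be 'equal' or 'area'")
    f = np.zeros(3 * mesh.n_nodes)
    for c in range(3):
        f[3 * nodes + c] = total[c] * w
    return f


_FACE_CORNERS = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
# Midside nodes of each corner face in the 10-node ordering (edges 01,12,20,03,13,23)
_FACE_MIDSIDES = np.array([[4, 5, 6], [4, 8, 7], [6, 7, 9], [5, 9, 8]])


def _tributary_weights(mesh, nodes: np.ndarray) -> np.ndarray:
    """Consistent-load weights per node for constant traction on the boundary
    faces whose nodes all belong to ``nodes``."""
    corners = mesh.corner_elements()
    faces = corners[:, _FACE_CORNERS].reshape(-1, 3)  # (4m, 3)
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inverse] == 1
    member = np.zeros(mesh.n_nodes, dtype=bool)
    member[nodes] = True
    on_set = member[faces].all(axis=1) & boundary
    idx = np.flatnonzero(on_set)
    w = np.zeros(mesh.n_nodes)
    tri = faces[idx]
    a = mesh.nodes[tri[:, 1]] - mesh.nodes[tri[:, 0]]
    b = mesh.nodes[tri[:, 2]] - mesh.nodes[tri[:, 0]]
    area = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
    if mesh.order == 1:
        for c in range(3):
            np.add.at(w, tri[:, c], area / 3.0)
    else:
        # Quadratic face under constant traction: corners get zero, the three
        # midside nodes A/3 each.
        elem_idx = idx // 4
        face_idx = idx % 4
        mids = mesh.elements[elem_idx[:, None], _FACE_MIDSIDES[face_idx]]
        for c in range(3):
            np.add.at(w, mids[:, c], area / 3.0)
    return w


class LinearGaitSolver:
    """Assemble and factorize once; solve many amplitude tables.

    Because the model is linear, three unit-load solutions (1 N total along
    each axis over the target node set) span every gait-cycle state; a
    :class:`LoadCase` then only selects coefficients. Comparing different
    weight-bearing levels on the same construct therefore costs one
    factorization total.
    """

    def __init__(self, mesh, materials, bc: BoundaryCondition | None = None,
                 node_set: str = "proximal", distribution: str = "equal"):
        bc = bc or BoundaryCondition()
        self.mesh = mesh
        self.bc = bc
        self.node_set = node_set
        self.distribution = distribution
        self.K, self.cache = assemble(mesh, materials)
        fixed_nodes = mesh.node_sets.get(bc.node_set)
        if fixed_nodes is None or fixed_nodes.size == 0:
            raise ValueError(f"fixed node set {bc.node_set!r} is empty: system would be singular")
        self._fixed_nodes = fixed_nodes
        ndof = 3 * mesh.n_nodes
        self._fixed = np.concatenate([3 * fixed_nodes + d for d in bc.dofs])
        self._free = np.setdiff1d(np.arange(ndof), self._fixed)
        self._K_ff = self.K[self._free][:, self._free].tocsc()
        self._lu = splu(self._K_ff)
        self._unit = None  # lazily computed unit-load basis

    def _solve_one(self, f: np.ndarray):
        """Solve for one full-length force vector; returns (U, strain, rf_total)."""
        mesh, cache = self.mesh, self.cache
        u = np.zeros(3 * mesh.n_nodes)
        u[self._free] = self._lu.solve(f[self._free])
        if not np.all(np.isfinite(u)):
            raise RuntimeError("solver produced non-finite displacements")
        residual = self._K_ff @ u[self._free] - f[self._free]
        nf = np.linalg.norm(f[self._free])
        if nf > 0 and np.linalg.norm(residual) > 1e-8 * nf:
            raise RuntimeError(
                f"solver did not converge: relative residual {np.linalg.norm(residual) / nf:.3e}"
            )
        strain = np.einsum("mvd,md->mv", cache.B_mean, u[cache.dof_map])
        r_full = self.K @ u - f
        r_fixed = np.zeros((mesh.n_nodes, 3))
        for d in self.bc.dofs:
            r_fixed[self._fixed_nodes, d] = r_full[3 * self._fixed_nodes + d]
        return u.reshape(-1, 3), strain, r_fixed.sum(axis=0)

    def _unit_basis(self):
        if self._unit is None:
            m = self.mesh.n_elements
            basis_U = np.zeros((3, self.mesh.n_nodes, 3))
            basis_strain = np.zeros((3, m, 6))
            rf_basis = np.zeros((3, 3))
            for c in range(3):
                f = _nodal_force_vector(self.mesh, self.node_set, np.eye(3)[c],
                                        self.distribution)
                basis_U[c], basis_strain[c], rf_basis[c] = self._solve_one(f)
            self._unit = (basis_U, basis_strain, rf_basis)
        return self._unit

    def result(self, load: LoadCase, mode: str = "superpose") -> FEResult:
        if mode not in ("superpose", "per_sample"):
            raise ValueError("mode must be 'superpose' or 'per_sample'")
        if load.node_set != self.node_set:
            raise ValueError("load targets a different node set than the solver")
        if mode == "superpose":
            basis_U, basis_strain, rf_basis = self._unit_basis()
            coeffs = load.forces
        else:
            k = load.times.size
            basis_U = np.zeros((k, self.mesh.n_nodes, 3))
            basis_strain = np.zeros((k, self.mesh.n_elements, 6))
            rf_basis = np.zeros((k, 3))
            for i in range(k):
                f = _nodal_force_vector(self.mesh, load.node_set, load.forces[i],
                                        self.distribution)
                basis_U[i], basis_strain[i], rf_basis[i] = self._solve_one(f)
            coeffs = np.eye(k)
        return FEResult(load.times, coeffs, basis_U, basis_strain, self.cache,
                        rf_basis, load.forces.copy())


def solve_static(mesh, materials, bc: BoundaryCondition, load: LoadCase,
                 mode: str = "superpose", distribution: str = "equal") -> FEResult:
    """Solve the constrained linear system for every amplitude sample.

    ``mode='superpose'`` (default) solves three unit-load systems and combines
    them with the amplitude table; ``mode='per_sample'`` re-solves each sample
    independently (used as a cross-check — the two agree to solver precision
    by linearity). ``distribution`` selects how the total load is spread over
    the target node set ('equal' per-node splitting, or consistent 'area'
    weighting for analytic verification).
    """
    return LinearGaitSolver(mesh, materials, bc, node_set=load.node_set,
                            distribution=distribution).result(load, mode=mode)


# ---------------------------------------------------------------------------
# Invariants


def voigt_to_tensor(v: np.ndarray) -> np.ndarray:
    """(..., 6) engineering Voigt -> (..., 3, 3) symmetric tensor (shear halved)."""
    v = np.asarray(v, dtype=float)
    T = np.zeros(v.shape[:-1] + (3, 3))
    T[..., 0, 0] = v[..., 0]
    T[..., 1, 1] = v[..., 1]
    T[..., 2, 2] = v[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = v[..., 3] / 2
    T[..., 1, 2] = T[..., 2, 1] = v[..., 4] / 2
    T[..., 0, 2] = T[..., 2, 0] = v[..., 5] / 2
    return T


def tensor_to_voigt(T: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric tensor -> (..., 6) engineering Voigt."""
    T = _check_symmetric(T)
    return np.stack(
        [T[..., 0, 0], T[..., 1, 1], T[..., 2, 2],
         2 * T[..., 0, 1], 2 * T[..., 1, 2], 2 * T[..., 0, 2]], axis=-1
    )


def _check_symmetric(T: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) tensors")
    scale = np.maximum(np.abs(T).max(axis=(-2, -1)), 1e-300)
    if np.any(np.abs(T - np.swapaxes(T, -1, -2)).max(axis=(-2, -1)) > tol * scale):
        raise ValueError("tensor is not symmetric")
    return T


def von_mises(S: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress sqrt(3/2 s:s) of (..., 3, 3) or Voigt (..., 6) stress.

    Note stress Voigt components carry the plain shear stresses (no factor 2).
    """
    S = np.asarray(S, dtype=float)
    if S.shape[-2:] == (3, 3):
        S = _check_symmetric(S)
        sx, sy, sz = S[..., 0, 0], S[..., 1, 1], S[..., 2, 2]
        txy, tyz, txz = S[..., 0, 1], S[..., 1, 2], S[..., 0, 2]
    elif S.shape[-1] == 6:
        sx, sy, sz, txy, tyz, txz = (S[..., i] for i in range(6))
    else:
        raise ValueError("stress must be (..., 3, 3) or Voigt (..., 6)")
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + txz**2)
    )
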