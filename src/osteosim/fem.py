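"""Small-strain linear elasticity on the structured voxel model.

Every non-void voxel is an 8-node trilinear hexahedron with 2x2x2 Gauss
quadrature. The isotropic constitutive tensor is split into its Lame parts,
``C = lambda * C_lam + mu * C_mu``, so the element stiffness of any material
is a linear combination of two precomputed 24x24 matrices and reassembly
under evolving tissue properties is a vectorized array operation.

Boundary conditions follow the compression set-up of the scaffold model:
uniform traction p on the top face of the top endplate, bottom endplate
fully fixed (or a frictionless roller for analytic fixtures), and zero
normal displacement on the two quarter-symmetry planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import sparse
from scipy.sparse import linalg as sla

from .geometry import RegionLabel, VoxelModel

# local node order: VTK hexahedron (x fastest, counter-clockwise bottom then top)
_NODE_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)
_XI = 2.0 * _NODE_OFFSETS - 1.0  # corner signs in the reference cube [-1,1]^3

_C_LAM = np.zeros((6, 6))
_C_LAM[:3, :3] = 1.0
_C_MU = np.diag([2.0, 2.0, 2.0, 1.0, 1.0, 1.0])


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_i/dxi at a reference point, shape (3, 8)."""
    g = np.empty((3, 8))
    for i in range(8):
        a, b, c = _XI[i]
        g[0, i] = a * (1 + b * xi[1]) * (1 + c * xi[2]) / 8.0
        g[1, i] = (1 + a * xi[0]) * b * (1 + c * xi[2]) / 8.0
        g[2, i] = (1 + a * xi[0]) * (1 + b * xi[1]) * c / 8.0
    return g


def _b_matrix(grad_x: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (engineering shear), shape (6, 24)."""
    B = np.zeros((6, 24))
    for i in range(8):
        gx, gy, gz = grad_x[:, i]
        c = 3 * i
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def _reference_matrices() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K_lam, K_mu for a unit voxel (edge 1) and the centroid B matrix."""
    g = 1.0 / np.sqrt(3.0)
    K_lam = np.zeros((24, 24))
    K_mu = np.zeros((24, 24))
    for p in _XI * g:  # 8 Gauss points at corner signs scaled by 1/sqrt(3)
        grad = _shape_gradients(p) * 2.0  # dxi/dx = 2/edge, edge = 1
        B = _b_matrix(grad)
        detJ = 0.125  # (edge/2)^3
        K_lam += B.T @ _C_LAM @ B * detJ
        K_mu += B.T @ _C_MU @ B * detJ
    B0 = _b_matrix(_shape_gradients(np.zeros(3)) * 2.0)
    return K_lam, K_mu, B0


_K_LAM1, _K_MU1, _B0_UNIT = _reference_matrices()


def lame_parameters(E, nu):
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


def build_element_stiffness(E: float, nu: float, voxel_edge: float = 1.0) -> np.ndarray:
    """24x24 hex-8 stiffness matrix for an isotropic material.

    Scales linearly with ``voxel_edge`` for the cube element. Symmetric
    positive-semidefinite with the six rigid-body zero-energy modes.
    """
    if not E > 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not 0.0 <= nu < 0.5:
        raise ValueError(f"Poisson's ratio must lie in [0, 0.5), got {nu}")
    lam, mu = lame_parameters(E, nu)
    return voxel_edge * (lam * _K_LAM1 + mu * _K_MU1)


@dataclass
class MaterialField:
    """Per-element isotropic material (E in MPa, Poisson's ratio)."""

    E: np.ndarray
    nu: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if np.any(self.E <= 0):
            raise ValueError("all element moduli must be positive")
        if np.any((self.nu < 0) | (self.nu >= 0.5)):
            raise ValueError("Poisson's ratios must lie in [0, 0.5)")


@dataclass
class LoadCase:
    """Compression load case of the scaffold model.

    ``pressure_mpa`` acts downward (-z) on the top face of the model;
    ``bottom`` is ``"fixed"`` (all DOFs of the bottom endplate) or
    ``"roller"`` (u_z = 0 on the bottom face only, for analytic fixtures).
    """

    pressure_mpa: float = 0.5
    bottom: str = "fixed"

    def __post_init__(self) -> None:
        if self.bottom not in ("fixed", "roller"):
            raise ValueError("bottom must be 'fixed' or 'roller'")


@dataclass
class ElementStrainState:
    """Per-element centroid strain state of the active elements."""

    tensor: np.ndarray  # (nelem, 6) [exx, eyy, ezz, gxy, gyz, gxz]
    principal: np.ndarray  # (nelem, 3) sorted descending: e1 >= e2 >= e3


class SingularModelError(RuntimeError):
    """The FE domain is disconnected and the system is singular."""


class VoxelFEModel:
    """Assembled finite-element view of a :class:`VoxelModel`.

    Precomputes element connectivity and the sparse-matrix pattern once;
    per-iteration reassembly with new materials is then a weighted bincount.
    """

    def __init__(self, model: VoxelModel):
        self.model = model
        self.edge = model.spacing_um
        labels = model.labels
        nx, ny, nz = labels.shape
        self.grid_shape = (nx, ny, nz)
        active = model.active_mask
        self._check_connected(active)
        self.active_index = np.flatnonzero(active.ravel())
        self.element_ijk = np.stack(np.nonzero(active), axis=1)  # (nelem, 3)
        self.n_elements = self.element_ijk.shape[0]

        node_shape = (nx + 1, ny + 1, nz + 1)
        self.node_shape = node_shape
        corner = self.element_ijk[:, None, :] + _NODE_OFFSETS[None, :, :]
        self.element_nodes = np.ravel_multi_index(
            (corner[..., 0], corner[..., 1], corner[..., 2]), node_shape
        )  # (nelem, 8)
        self.n_nodes = int(np.prod(node_shape))
        self.n_dofs = 3 * self.n_nodes
        dofs = (3 * self.element_nodes[:, :, None] + np.arange(3)[None, None, :])
        self.element_dofs = dofs.reshape(self.n_elements, 24)

        self._pattern = None  # built lazily on first assembly
        self._static = None  # optional cached contribution of fixed-material elements

    # -- connectivity ------------------------------------------------------

    @staticmethod
    def _check_connected(active: np.ndarray) -> None:
        lab, ncomp = ndimage.label(active)
        if ncomp > 1:
            sizes = np.bincount(lab.ravel())[1:]
            small = int(np.argmin(sizes)) + 1
            where = np.argwhere(lab == small)[0]
            raise SingularModelError(
                f"FE domain has {ncomp} disconnected components; e.g. a "
                f"floating region of {sizes.min()} voxels near index "
                f"{tuple(int(v) for v in where)}"
            )

    # -- assembly ----------------------------------------------------------

    def _build_pattern(self) -> None:
        d = self.element_dofs
        rows = np.broadcast_to(d[:, :, None], (self.n_elements, 24, 24)).ravel()
        cols = np.broadcast_to(d[:, None, :], (self.n_elements, 24, 24)).ravel()
        order = np.lexsort((cols, rows))
        rs, cs = rows[order], cols[order]
        new = np.empty(rs.size, dtype=bool)
        new[0] = True
        new[1:] = (rs[1:] != rs[:-1]) | (cs[1:] != cs[:-1])
        slot = np.cumsum(new) - 1  # sorted entry -> nnz slot
        nnz = int(slot[-1]) + 1
        indices = cs[new]
        counts = np.bincount(rs[new], minlength=self.n_dofs)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        # map each raw (unsorted) contribution to its nnz slot
        entry_slot = np.empty(rs.size, dtype=np.int64)
        entry_slot[order] = slot
        self._pattern = (entry_slot, indices.astype(np.int32), indptr.astype(np.int64), nnz)

    def _element_data(self, lam, mu):
        return (
            lam[:, None, None] * _K_LAM1[None] + mu[:, None, None] * _K_MU1[None]
        ) * self.edge

    def cache_static_elements(self, static_sel: np.ndarray, materials: MaterialField) -> None:
        """Precompute the stiffness contribution of elements whose material
        never changes; subsequent :meth:`assemble` calls only re-integrate
        the remaining (regulated) elements."""
        if self._pattern is None:
            self._build_pattern()
        entry_slot, _, _, nnz = self._pattern
        slots = entry_slot.reshape(self.n_elements, 576)
        lam, mu = lame_parameters(materials.E, materials.nu)
        ke = self._element_data(lam[static_sel], mu[static_sel])
        static_data = np.bincount(
            slots[static_sel].ravel(), weights=ke.ravel(), minlength=nnz
        )
        self._static = (np.asarray(static_sel, bool), static_data)

    def assemble(self, materials: MaterialField) -> sparse.csr_array:
        """Global stiffness for per-active-element materials."""
        if materials.E.shape != (self.n_elements,):
            raise ValueError(
                f"materials must provide one (E, nu) pair per active element "
                f"({self.n_elements}), got {materials.E.shape}"
            )
        if self._pattern is None:
            self._build_pattern()
        entry_slot, indices, indptr, nnz = self._pattern
        lam, mu = lame_parameters(materials.E, materials.nu)
        if self._static is not None:
            static_sel, static_data = self._static
            dyn = ~static_sel
            slots = entry_slot.reshape(self.n_elements, 576)
            ke = self._element_data(lam[dyn], mu[dyn])
            data = static_data + np.bincount(
                slots[dyn].ravel(), weights=ke.ravel(), minlength=nnz
            )
        else:
            ke = self._element_data(lam, mu)
            data = np.bincount(entry_slot, weights=ke.ravel(), minlength=nnz)
        return sparse.csr_array((data, indices, indptr), shape=(self.n_dofs, self.n_dofs))

    def element_internal_forces(self, u: np.ndarray, materials: MaterialField) -> np.ndarray:
        """Nodal force vector K@u accumulated element-wise (for reactions)."""
        lam, mu = lame_parameters(materials.E, materials.nu)
        ue = u[self.element_dofs]  # (nelem, 24)
        fe = self.edge * (
            lam[:, None] * (ue @ _K_LAM1.T) + mu[:, None] * (ue @ _K_MU1.T)
        )
        f = np.zeros(self.n_dofs)
        np.add.at(f, self.element_dofs.ravel(), fe.ravel())
        return f

    # -- boundary conditions ----------------------------------------------

    def _node_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nxn, nyn, nzn = self.node_shape
        return np.meshgrid(
            np.arange(nxn), np.arange(nyn), np.arange(nzn), indexing="ij"
        )

    def boundary_conditions(self, load: LoadCase) -> tuple[np.ndarray, np.ndarray]:
        """Fixed-DOF mask and nodal force vector for the load case."""
        nxn, nyn, nzn = self.node_shape
        fixed = np.zeros((self.n_nodes, 3), dtype=bool)
        node_ids = np.arange(self.n_nodes).reshape(self.node_shape)

        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.element_nodes.ravel()] = True
        used3 = used.reshape(self.node_shape)

        if load.bottom == "fixed":
            bottom_elems = self.model.labels == RegionLabel.ENDPLATE_BOTTOM
            if not bottom_elems.any():
                raise ValueError("model has no bottom endplate to fix")
            bot_nodes = np.zeros(self.node_shape, dtype=bool)
            idx = np.argwhere(bottom_elems)
            for off in _NODE_OFFSETS:
                bot_nodes[idx[:, 0] + off[0], idx[:, 1] + off[1], idx[:, 2] + off[2]] = True
            fixed[node_ids[bot_nodes]] = True
        else:  # roller on the z=0 face
            fixed[node_ids[:, :, 0], 2] = True

        if self.model.quarter_symmetry:
            for axis, plane in self.model.symmetry_planes:
                sel = [slice(None)] * 3
                sel[axis] = plane
                fixed[node_ids[tuple(sel)].ravel(), axis] = True

        fixed &= used3.reshape(-1, 1) | False
        fixed[~used] = True  # pin unused grid nodes (no element support)

        # consistent nodal load: uniform traction on top-face element faces
        f = np.zeros((self.n_nodes, 3))
        top_k = self.grid_shape[2] - 1
        top_elems = self.element_ijk[self.element_ijk[:, 2] == top_k]
        if top_elems.size == 0:
            raise ValueError("no elements on the top face to load")
        face_force = load.pressure_mpa * self.edge**2 / 4.0
        for di, dj in ((0, 0), (1, 0), (1, 1), (0, 1)):
            nid = node_ids[top_elems[:, 0] + di, top_elems[:, 1] + dj, top_k + 1]
            np.add.at(f[:, 2], nid, -face_force)
        return fixed.ravel(), f.ravel()


class RecycledCholeskySolver:
    """Iterative solver for a sequence of slowly drifting stiffness systems.

    The free DOFs are renumbered so the two short grid axes vary fastest,
    giving the stiffness matrix a modest bandwidth; a banded Cholesky
    factorization (single precision, LAPACK pbtrf) is computed occasionally
    and recycled as the preconditioner of a warm-started conjugate-gradient
    iteration while the materials evolve. The factorization is refreshed
    whenever CG stops converging quickly.
    """

    def __init__(self, fe: "VoxelFEModel", fixed: np.ndarray, rtol: float = 1e-8,
                 cg_maxiter: int = 60, refactor_threshold: int = 14):
        self.fe = fe
        self.fixed = fixed
        self.rtol = rtol
        self.cg_maxiter = cg_maxiter
        self.refactor_threshold = refactor_threshold
        self.free = np.flatnonzero(~fixed)
        nxn, nyn, nzn = fe.node_shape
        # renumber nodes so the z (longest) axis is slowest -> small bandwidth
        ix, iy, iz = np.meshgrid(
            np.arange(nxn), np.arange(nyn), np.arange(nzn), indexing="ij"
        )
        newpos = (iz * (nxn * nyn) + iy * nxn + ix).ravel()
        order_nodes = np.argsort(newpos, kind="stable")
        dof_order = (3 * order_nodes[:, None] + np.arange(3)).ravel()
        free_mask = ~fixed
        self.fp = dof_order[free_mask[dof_order]]  # new position -> full dof id
        self._factor = None
        self._x_prev = None
        self._datamap = None
        self.n_factorizations = 0
        self.last_cg_iters = 0

    def _permuted(self, K: sparse.csr_array) -> sparse.csr_array:
        """Reduced, renumbered stiffness; the sparsity pattern is cached so
        repeat calls only gather the data vector."""
        if self._datamap is None:
            tracer = sparse.csr_array(
                (np.arange(K.nnz, dtype=np.int64), K.indices, K.indptr), shape=K.shape
            )
            Kp = tracer[self.fp][:, self.fp].tocsr()
            self._datamap = (Kp.data.copy(), Kp.indices.copy(), Kp.indptr.copy())
        dmap, indices, indptr = self._datamap
        n = self.fp.size
        return sparse.csr_array((K.data[dmap], indices, indptr), shape=(n, n))

    def _refactor(self, Kp: sparse.csr_array) -> None:
        from scipy.linalg import cholesky_banded

        co = Kp.tocoo()
        upper = co.row <= co.col
        r, c, v = co.row[upper], co.col[upper], co.data[upper]
        bw = int((c - r).max())
        ab = np.zeros((bw + 1, Kp.shape[0]), dtype=np.float32)
        ab[bw + r - c, c] = v
        self._factor = cholesky_banded(ab, lower=False, check_finite=False)
        self.n_factorizations += 1

    def _precondition(self, r: np.ndarray) -> np.ndarray:
        from scipy.linalg import cho_solve_banded

        return cho_solve_banded(
            (self._factor, False), r.astype(np.float32), check_finite=False
        ).astype(np.float64)

    def _pcg(self, A, b, x0):
        x = x0.copy()
        r = b - A @ x
        nb = np.linalg.norm(b)
        if nb == 0.0:
            return np.zeros_like(b), 0, True
        z = self._precondition(r)
        p = z.copy()
        rz = r @ z
        for it in range(1, self.cg_maxiter + 1):
            if np.linalg.norm(r) <= self.rtol * nb:
                return x, it - 1, True
            Ap = A @ p
            pAp = p @ Ap
            if not np.isfinite(pAp) or pAp <= 0:
                return x, it, False
            alpha = rz / pAp
            x += alpha * p
            r -= alpha * Ap
            z = self._precondition(r)
            rz_new = r @ z
            p = z + (rz_new / rz) * p
            rz = rz_new
        return x, self.cg_maxiter, np.linalg.norm(r) <= self.rtol * nb

    def solve(self, K: sparse.csr_array, f: np.ndarray) -> np.ndarray:
        """Solve K u = f on the free DOFs; returns the full displacement vector."""
        Kp = self._permuted(K)
        b = f[self.fp]
        # refactor proactively once drift makes solves expensive: a fresh
        # factorization costs about as much as ~50 preconditioned iterations
        # but then amortizes over many near-instant solves
        if self._factor is None or self.last_cg_iters >= self.refactor_threshold:
            self._refactor(Kp)
            self.last_cg_iters = 0
        x0 = self._x_prev if self._x_prev is not None else np.zeros_like(b)
        x, iters, ok = self._pcg(Kp, b, x0)
        if not ok:
            self._refactor(Kp)
            x, iters, ok = self._pcg(Kp, b, x)
            if not ok:  # fall back to a fresh double-precision direct solve
                x = sla.splu(Kp.tocsc()).solve(b)
        self.last_cg_iters = iters
        self._x_prev = x.copy()
        u = np.zeros(self.fe.n_dofs)
        u[self.fp] = x
        return u


def solve_displacements(
    model_or_fe: VoxelModel | VoxelFEModel,
    materials: MaterialField,
    load: LoadCase,
    solver: str = "direct",
    rtol: float = 1e-8,
) -> np.ndarray:
    """Solve the compression problem; returns the full nodal displacement vector."""
    fe = model_or_fe if isinstance(model_or_fe, VoxelFEModel) else VoxelFEModel(model_or_fe)
    fixed, f = fe.boundary_conditions(load)
    K = fe.assemble(materials)
    return solve_system(K, f, fixed, solver=solver, rtol=rtol)


def solve_system(
    K: sparse.csr_array,
    f: np.ndarray,
    fixed: np.ndarray,
    u_fixed: np.ndarray | None = None,
    solver: str = "direct",
    rtol: float = 1e-8,
    lu=None,
) -> np.ndarray:
    """Reduce a global system by (possibly inhomogeneous) Dirichlet DOFs and solve.

    ``solver`` is ``"direct"`` (sparse LU) or ``"cg"`` (Jacobi-preconditioned
    conjugate gradients, optionally preconditioned by a previous LU object).
    """
    n = f.size
    free = ~fixed
    u = np.zeros(n)
    if u_fixed is not None:
        u[fixed] = u_fixed[fixed]
    free_idx = np.flatnonzero(free)
    Kff = K[free_idx][:, free_idx].tocsc()
    rhs = f[free]
    if u_fixed is not None and np.any(u[fixed]):
        rhs = rhs - K[free_idx][:, np.flatnonzero(fixed)] @ u[fixed]
    if solver == "direct":
        u[free] = sla.splu(Kff).solve(rhs)
    elif solver == "cg":
        if lu is not None:
            M = sla.LinearOperator(Kff.shape, matvec=lu.solve)
        else:
            d = Kff.diagonal()
            M = sla.LinearOperator(Kff.shape, matvec=lambda x: x / d)
        sol, info = sla.cg(Kff, rhs, rtol=rtol, maxiter=2000, M=M)
        if info != 0:
            sol = sla.splu(Kff).solve(rhs)
        u[free] = sol
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return u


def compute_element_strains(
    fe: VoxelFEModel, displacements: np.ndarray, subset: np.ndarray | None = None
) -> ElementStrainState:
    """Centroid strain tensor and sorted principal strains per active element.

    ``subset`` (boolean over active elements) restricts the computation.
    """
    B0 = _B0_UNIT / fe.edge  # gradients scale with 1/edge
    dofs = fe.element_dofs if subset is None else fe.element_dofs[subset]
    ue = displacements[dofs]
    eps = ue @ B0.T  # (nelem, 6) engineering shear
    n = eps.shape[0]
    T = np.empty((n, 3, 3))
    T[:, 0, 0] = eps[:, 0]
    T[:, 1, 1] = eps[:, 1]
    T[:, 2, 2] = eps[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = 0.5 * eps[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = 0.5 * eps[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = 0.5 * eps[:, 5]
    principal = np.linalg.eigvalsh(T)[:, ::-1]  # descending
    return ElementStrainState(tensor=eps, principal=principal)
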