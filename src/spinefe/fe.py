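"""Linear-tetrahedron finite-element core.

Assembles and solves the static elasticity problem for a heterogeneous
C3D4 mesh with:

* per-element anisotropic elasticity matrices (from the material card),
* tension-only 2-node ligament cables resolved by fixed-point iteration,
* a virtual master point rigidly coupled to the superior surface through
  linear multipoint constraints (small-rotation kinematics), on which both
  displacement ramps and pure moments are imposed,
* the inferior surface fixed in all translations,
* element stress recovery and closed-form principal stresses.

Units: mm, N, MPa; moments in N*mm; rotations in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import FENonConvergenceError, FESingularError
from .materials import MaterialCard
from .meshing import CableElement, TetMesh

#: Voigt order used throughout: xx, yy, zz, yz, xz, xy (engineering shears).
VOIGT_ORDER = ("xx", "yy", "zz", "yz", "xz", "xy")


@dataclass
class FEModel:
    """Mesh + materials + cables + boundary conditions, ready to assemble."""

    mesh: TetMesh
    card: MaterialCard
    cables: list[CableElement] = field(default_factory=list)
    tension_only: bool = True
    couple_superior: bool = True
    master_point: np.ndarray | None = None

    def __post_init__(self):
        if self.master_point is None and self.couple_superior:
            self.master_point = self.mesh.nodes[self.mesh.superior_nodes].mean(axis=0)

    @property
    def fixed_nodes(self) -> np.ndarray:
        return self.mesh.inferior_nodes


@dataclass
class Solution:
    """Static equilibrium solution."""

    u: np.ndarray  # (N, 3) nodal displacements, mm
    master_u: np.ndarray | None  # (6,) master translations + rotations
    master_reaction: np.ndarray | None  # (6,) force (N) + moment (N*mm)
    inferior_reaction: np.ndarray  # (3,) total force at the fixed surface
    strain: np.ndarray  # (M, 6)
    stress: np.ndarray  # (M, 6), damage-scaled
    cable_forces: np.ndarray  # (n_cables,) axial force, >= 0 when tension-only
    active_cables: np.ndarray  # (n_cables,) bool
    damage: np.ndarray | None = None

    @property
    def principal(self) -> np.ndarray:
        return principal_stresses(self.stress)


def principal_stresses(stress_voigt: np.ndarray) -> np.ndarray:
    """Principal stresses (s_I >= s_II >= s_III) of Voigt tensors, (M, 3).

    Closed-form eigenvalues of the symmetric 3x3 tensor via the invariant /
    Lode-angle representation; exact for hydrostatic states.
    """
    s = np.atleast_2d(stress_voigt)
    sxx, syy, szz, syz, sxz, sxy = (s[:, i] for i in range(6))
    m = (sxx + syy + szz) / 3.0
    dxx, dyy, dzz = sxx - m, syy - m, szz - m
    j2 = 0.5 * (dxx**2 + dyy**2 + dzz**2) + sxy**2 + syz**2 + sxz**2
    j3 = (
        dxx * dyy * dzz
        + 2.0 * sxy * syz * sxz
        - dxx * syz**2
        - dyy * sxz**2
        - dzz * sxy**2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(np.maximum(j2 / 3.0, 0.0))
        arg = np.where(j2 > 0, j3 / np.maximum(2.0 * r**3, 1e-300), 0.0)
    theta = np.arccos(np.clip(arg, -1.0, 1.0)) / 3.0
    two_r = 2.0 * r
    out = np.empty((len(s), 3))
    out[:, 0] = m + two_r * np.cos(theta)
    out[:, 2] = m + two_r * np.cos(theta + 2.0 * np.pi / 3.0)
    out[:, 1] = 3.0 * m - out[:, 0] - out[:, 2]
    return out


def _element_b_matrices(nodes: np.ndarray, elems: np.ndarray):
    """Constant-strain B operators (M, 6, 12) and signed volumes (M,)."""
    c = nodes[elems]  # (M, 4, 3)
    d = np.transpose(c[:, 1:] - c[:, :1], (0, 2, 1))  # columns p_i - p_0
    vols = np.linalg.det(d) / 6.0
    dinv = np.linalg.inv(d)  # rows = grad xi_i
    grads = np.empty((len(elems), 4, 3))
    grads[:, 1:] = dinv
    grads[:, 0] = -dinv.sum(axis=1)
    B = np.zeros((len(elems), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        col = 3 * a
        B[:, 0, col] = gx
        B[:, 1, col + 1] = gy
        B[:, 2, col + 2] = gz
        B[:, 3, col + 1] = gz
        B[:, 3, col + 2] = gy
        B[:, 4, col] = gz
        B[:, 4, col + 2] = gx
        B[:, 5, col] = gy
        B[:, 5, col + 1] = gx
    return B, vols


class FEOperator:
    """Precomputed element operators + constraint reduction for one model.

    Separates the expensive, state-independent work (B matrices, undamaged
    element stiffnesses, the multipoint-constraint transformation) from the
    per-state assembly (damage scales, active cable set), so damage stepping
    only pays for sparse assembly and refactorization.
    """

    def __init__(self, model: FEModel):
        self.model = model
        mesh = model.mesh
        self.n_nodes = mesh.n_nodes
        self.B, self.vols = _element_b_matrices(mesh.nodes, mesh.elems)
        if self.vols.min() <= 0:
            raise FESingularError("mesh contains non-positive element volumes")
        self.C = model.card.elasticity()  # (M, 6, 6)
        # undamaged element stiffness: V * B^T C B
        CB = np.einsum("eij,ejk->eik", self.C, self.B)
        self.Ke0 = np.einsum("eji,ejk->eik", self.B, CB) * self.vols[:, None, None]
        self.CB = CB  # for stress recovery: sigma = C B u_e

        edofs = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(-1, 12)
        self.rows = np.repeat(edofs, 12, axis=1).ravel()
        self.cols = np.tile(edofs, (1, 12)).ravel()
        self.edofs = edofs
        # precompute the COO -> CSR scatter once so that re-assembly under a
        # new damage state costs one fancy-indexed reduction, not a sort
        ndof = 3 * self.n_nodes
        key = self.rows.astype(np.int64) * ndof + self.cols
        self._order = np.argsort(key, kind="stable")
        skey = key[self._order]
        starts = np.flatnonzero(np.r_[True, skey[1:] != skey[:-1]])
        self._starts = starts
        ukey = skey[starts]
        self._csr_indices = (ukey % ndof).astype(np.int32)
        csr_rows = (ukey // ndof).astype(np.int64)
        self._csr_indptr = np.searchsorted(csr_rows, np.arange(ndof + 1))

        # cables
        self.cables = model.cables
        nc = len(self.cables)
        self.cable_dirs = np.zeros((nc, 3))
        self.cable_len = np.ones(nc)
        self.cable_ea = np.zeros(nc)
        cable_ke = np.zeros((nc, 6, 6))
        crows, ccols = [], []
        for i, c in enumerate(self.cables):
            pu, pl = mesh.nodes[c.node_upper], mesh.nodes[c.node_lower]
            vec = pu - pl
            L = np.linalg.norm(vec)
            n = vec / L
            self.cable_dirs[i] = n
            self.cable_len[i] = L
            self.cable_ea[i] = c.E * c.area
            k = c.E * c.area / L
            nn = k * np.outer(n, n)
            cable_ke[i, :3, :3] = nn
            cable_ke[i, 3:, 3:] = nn
            cable_ke[i, :3, 3:] = -nn
            cable_ke[i, 3:, :3] = -nn
            dofs = np.concatenate([
                3 * c.node_upper + np.arange(3), 3 * c.node_lower + np.arange(3)
            ])
            crows.append(np.repeat(dofs, 6))
            ccols.append(np.tile(dofs, 6))
        self.cable_ke = cable_ke
        self.cable_rows = np.concatenate(crows) if nc else np.empty(0, int)
        self.cable_cols = np.concatenate(ccols) if nc else np.empty(0, int)

        self._build_transformation()

    # -- constraint reduction ------------------------------------------------

    def _build_transformation(self):
        """T maps reduced dofs [retained node dofs..., master 6] -> full dofs.

        Superior-surface nodes are slaves of the master point:
        u_s = u_m + theta x r_s  (small rotations), i.e. the slave block is
        [I3 | -[r_s]_x].
        """
        mesh = self.model.mesh
        N = self.n_nodes
        if self.model.couple_superior:
            slaves = np.asarray(mesh.superior_nodes)
        else:
            slaves = np.empty(0, dtype=int)
        is_slave = np.zeros(N, dtype=bool)
        is_slave[slaves] = True
        retained = np.flatnonzero(~is_slave)
        self.q_of_node = np.full(N, -1, dtype=int)
        self.q_of_node[retained] = np.arange(len(retained))
        nq = 3 * len(retained) + (6 if self.model.couple_superior else 0)
        self.nq = nq
        self.master_q0 = 3 * len(retained) if self.model.couple_superior else None

        rows, cols, vals = [], [], []
        r_idx = 3 * retained[:, None] + np.arange(3)
        q_idx = 3 * self.q_of_node[retained][:, None] + np.arange(3)
        rows.append(r_idx.ravel())
        cols.append(q_idx.ravel())
        vals.append(np.ones(r_idx.size))
        if self.model.couple_superior:
            xm = self.model.master_point
            m0 = self.master_q0
            for s in slaves:
                r = mesh.nodes[s] - xm
                A = np.array([
                    [0.0, r[2], -r[1]],
                    [-r[2], 0.0, r[0]],
                    [r[1], -r[0], 0.0],
                ])  # d(theta x r)/d(theta)
                block = np.hstack([np.eye(3), A])
                rr, cc = np.meshgrid(3 * s + np.arange(3), m0 + np.arange(6),
                                     indexing="ij")
                rows.append(rr.ravel())
                cols.append(cc.ravel())
                vals.append(block.ravel())
        self.T = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(3 * N, nq),
        )
        fq = 3 * self.q_of_node[self.model.fixed_nodes]
        self.fixed_q = np.concatenate([fq + i for i in range(3)])
        if np.any(self.q_of_node[self.model.fixed_nodes] < 0):
            raise FESingularError("a fixed node is also a coupled slave node")

    # -- assembly ------------------------------------------------------------

    def assemble(
        self,
        damage: np.ndarray | None = None,
        active_cables: np.ndarray | None = None,
    ) -> sp.csr_matrix:
        """Reduced stiffness T^T K T for a damage state and active-cable set.

        ``damage`` is a per-element stiffness scale in (0, 1]; absent damage
        is identical to all-ones.
        """
        if damage is None:
            data = self.Ke0
        else:
            damage = np.asarray(damage, dtype=float)
            if np.any(damage <= 0) or np.any(damage > 1):
                raise FESingularError("damage scales must lie in (0, 1]")
            data = self.Ke0 * damage[:, None, None]
        csr_data = np.add.reduceat(data.ravel()[self._order], self._starts)
        K = sp.csr_matrix(
            (csr_data, self._csr_indices, self._csr_indptr),
            shape=(3 * self.n_nodes, 3 * self.n_nodes),
        )
        if len(self.cables):
            act = (
                np.ones(len(self.cables), dtype=bool)
                if active_cables is None
                else np.asarray(active_cables, dtype=bool)
            )
            cdata = self.cable_ke * act[:, None, None]
            K = K + sp.coo_matrix(
                (cdata.ravel(), (self.cable_rows, self.cable_cols)),
                shape=K.shape,
            ).tocsr()
        return (self.T.T @ K @ self.T).tocsr()

    def factorize(self, K_red: sp.csr_matrix, prescribed_q: np.ndarray):
        """LU factorization of the free-free block after constraints."""
        nq = self.nq
        pres = np.unique(np.concatenate([self.fixed_q, prescribed_q])) \
            if len(prescribed_q) else np.unique(self.fixed_q)
        if pres.size == 0:
            raise FESingularError(
                "no constrained degrees of freedom: free rigid-body modes "
                "(translations and rotations) make the system singular"
            )
        free = np.setdiff1d(np.arange(nq), pres)
        Kuu = K_red[np.ix_(free, free)].tocsc()
        Kup = K_red[np.ix_(free, pres)].tocsc()
        Kpu = K_red[np.ix_(pres, free)].tocsc()
        Kpp = K_red[np.ix_(pres, pres)].tocsc()
        try:
            # symmetric-mode minimum-degree ordering: ~2x less fill than
            # COLAMD on these SPD elasticity matrices
            lu = splu(Kuu, permc_spec="MMD_AT_PLUS_A",
                      options={"SymmetricMode": True, "DiagPivotThresh": 0.001})
        except RuntimeError as err:  # exactly singular
            raise FESingularError(
                f"constrained stiffness is singular ({err}); check for "
                "unconstrained rigid-body modes"
            ) from err
        return _Factor(self, lu, free, pres, Kup, Kpu, Kpp)

    # -- recovery ------------------------------------------------------------

    def expand(self, q: np.ndarray) -> np.ndarray:
        """Full nodal displacement vector (3N,) from reduced dofs."""
        return self.T @ q

    def element_stress_strain(self, u_full: np.ndarray,
                              damage: np.ndarray | None = None):
        ue = u_full[self.edofs]  # (M, 12)
        strain = np.einsum("eij,ej->ei", self.B, ue)
        stress = np.einsum("eij,ej->ei", self.CB, ue)
        if damage is not None:
            stress = stress * np.asarray(damage)[:, None]
        return strain, stress

    def cable_elongations(self, u_full: np.ndarray) -> np.ndarray:
        if not len(self.cables):
            return np.empty(0)
        iu = np.array([c.node_upper for c in self.cables])
        il = np.array([c.node_lower for c in self.cables])
        du = u_full.reshape(-1, 3)[iu] - u_full.reshape(-1, 3)[il]
        return np.einsum("ij,ij->i", du, self.cable_dirs)


class _Factor:
    """Factorized constrained system; solves for arbitrary RHS/prescribed."""

    def __init__(self, op, lu, free, pres, Kup, Kpu, Kpp):
        self.op = op
        self.lu = lu
        self.free = free
        self.pres = pres
        self.Kup, self.Kpu, self.Kpp = Kup, Kpu, Kpp

    def solve(self, prescribed_values: np.ndarray | None = None,
              f: np.ndarray | None = None):
        """Returns (q, reactions-at-prescribed)."""
        nq = self.op.nq
        qp = np.zeros(len(self.pres))
        if prescribed_values is not None:
            qp[:] = prescribed_values
        rhs = np.zeros(len(self.free))
        if f is not None:
            rhs += f[self.free]
        rhs -= self.Kup @ qp
        qu = self.lu.solve(rhs)
        q = np.zeros(nq)
        q[self.free] = qu
        q[self.pres] = qp
        reactions = self.Kpu @ qu + self.Kpp @ qp
        if f is not None:
            reactions = reactions - f[self.pres]
        return q, reactions


def assemble(model: FEModel, damage: np.ndarray | None = None):
    """Reduced stiffness matrix for a model (spec-level convenience)."""
    op = FEOperator(model)
    return op.assemble(damage=damage), op


def solve_static(
    model: FEModel,
    master_force: np.ndarray | None = None,
    master_prescribed: dict[int, float] | None = None,
    damage: np.ndarray | None = None,
    max_tension_iters: int = 20,
    operator: FEOperator | None = None,
) -> Solution:
    """Static solve with tension-only ligament resolution.

    ``master_force`` is a generalized (Fx, Fy, Fz, Mx, My, Mz) load on the
    virtual master point (N and N*mm); ``master_prescribed`` maps master dof
    indices (0-5) to imposed values (mm / rad).  The inferior surface is
    always fixed.  Compressed cables are deactivated and the system re-solved
    until the active set is stable; an oscillating set raises.
    """
    op = operator or FEOperator(model)
    if model.couple_superior:
        m0 = op.master_q0
        pres_idx = np.array(sorted(master_prescribed)) + m0 \
            if master_prescribed else np.empty(0, dtype=int)
        pres_val = np.array([master_prescribed[i] for i in sorted(master_prescribed)]) \
            if master_prescribed else None
    else:
        pres_idx, pres_val = np.empty(0, dtype=int), None

    f = None
    if master_force is not None:
        if not model.couple_superior:
            raise FESingularError("master force requires a coupled superior surface")
        f = np.zeros(op.nq)
        f[op.master_q0: op.master_q0 + 6] = master_force

    nc = len(op.cables)
    active = np.ones(nc, dtype=bool)
    n_iter = max_tension_iters if (model.tension_only and nc) else 1

    q = None
    seen: list[bytes] = []
    for it in range(max(1, n_iter)):
        K = op.assemble(damage=damage, active_cables=active if nc else None)
        fac = op.factorize(K, pres_idx)
        full_pres = np.zeros(len(fac.pres))
        if pres_val is not None:
            # fixed dofs come first in fac.pres ordering; map master values
            for j, idx in enumerate(fac.pres):
                if idx in pres_idx:
                    full_pres[j] = pres_val[list(pres_idx).index(idx)]
        q, reactions = fac.solve(full_pres, f)
        if not (model.tension_only and nc):
            break
        u_full = op.expand(q)
        elong = op.cable_elongations(u_full)
        new_active = elong > 1e-12
        if np.array_equal(new_active, active):
            break
        key = new_active.tobytes()
        if key in seen:
            raise FENonConvergenceError(
                "tension-only iteration oscillates between active sets "
                f"(sizes {int(active.sum())} <-> {int(new_active.sum())})"
            )
        seen.append(key)
        active = new_active
    else:
        if model.tension_only and nc:
            raise FENonConvergenceError(
                f"tension-only iteration did not settle in {max_tension_iters} "
                "iterations"
            )

    return build_solution(op, q, fac, reactions, damage=damage, active=active)


def build_solution(op: FEOperator, q: np.ndarray, fac, reactions,
                   damage: np.ndarray | None, active: np.ndarray) -> Solution:
    model = op.model
    u_full = op.expand(q)
    strain, stress = op.element_stress_strain(u_full, damage)
    elong = op.cable_elongations(u_full)
    if len(op.cables):
        forces = np.where(active, op.cable_ea / op.cable_len * elong, 0.0)
    else:
        forces = np.empty(0)

    # reactions at fixed inferior nodes (sum of the three translations)
    react_map = dict(zip(fac.pres.tolist(), reactions.tolist()))
    inferior = np.zeros(3)
    for n in model.fixed_nodes:
        base = 3 * op.q_of_node[n]
        for i in range(3):
            inferior[i] += react_map.get(base + i, 0.0)

    master_u = master_reaction = None
    if model.couple_superior:
        m0 = op.master_q0
        master_u = q[m0: m0 + 6].copy()
        mr = np.zeros(6)
        for i in range(6):
            mr[i] = react_map.get(m0 + i, np.nan)
        master_reaction = mr
    return Solution(
        u=u_full.reshape(-1, 3),
        master_u=master_u,
        master_reaction=master_reaction,
        inferior_reaction=inferior,
        strain=strain,
        stress=stress,
        cable_forces=forces,
        active_cables=active,
        damage=None if damage is None else np.asarray(damage).copy(),
    )
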