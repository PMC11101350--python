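"""Network mechanics: bilinear activated bond law and equilibrium solution.

Each bond carries the force law

    F(r) = K_t <(r - r_a)/r_a>  -  K_c <(r_a - r)/r_a>,      r_a = a r0,

with Macaulay brackets ``<x> = max(x, 0)``: linear in the elastic strain
with different tensile and compressive moduli, zero at the activated
rest length ``r_a``.  The bond energy is defined so that ``dE/dr = F``:

    E(r) = 1/2 r_a [ K_t <(r-r_a)/r_a>^2 + K_c <(r_a-r)/r_a>^2 ].

Equilibria of a network under displacement boundary conditions are
found by minimising the total energy over the free node positions.
Random fibre networks of this kind are sub-isostatic (floppy modes),
so the solver is gradient-based: limited-memory BFGS drives the energy
down, and a regularised Newton polish on the sparse tangent stiffness
pushes the residual force norm below the convergence threshold of
1e-3 nN (1 pN).  Activation is applied along a ramp (a: 1 -> target in
a few equal steps, re-minimising at each) to stabilise the descent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import fmin_l_bfgs_b
from scipy.sparse import coo_matrix, csc_matrix, identity
from scipy.sparse.linalg import splu

from .materials import BondMaterial
from .netgen import CellNetwork

#: Default convergence threshold on the 2-norm of the residual force
#: vector over all free nodes: 1 pN.
DEFAULT_FTOL = 1e-3


@dataclass(frozen=True)
class BondState:
    """Kinematic state of a single bond."""

    r: float
    r0: float
    a: float = 1.0

    @property
    def ra(self) -> float:
        return self.a * self.r0

    @property
    def elastic_stretch(self) -> float:
        return self.r / self.ra


def bond_force(material: BondMaterial, state: BondState) -> float:
    """Signed axial bond force in nN (tension positive)."""
    if state.r <= 0:
        raise ValueError("degenerate bond: r <= 0")
    ra = state.ra
    strain = (state.r - ra) / ra
    return (material.K_t if strain > 0 else material.K_c) * strain


def bond_energy(material: BondMaterial, state: BondState) -> float:
    """Bond strain energy in nN·μm, with ``dE/dr = bond_force``."""
    if state.r <= 0:
        raise ValueError("degenerate bond: r <= 0")
    ra = state.ra
    strain = (state.r - ra) / ra
    K = material.K_t if strain > 0 else material.K_c
    return 0.5 * ra * K * strain * strain


# ---------------------------------------------------------------------------
# Vectorised network assembly
# ---------------------------------------------------------------------------


def _bond_kinematics(net: CellNetwork, positions: np.ndarray):
    i, j = net.bonds[:, 0], net.bonds[:, 1]
    d = positions[j] - positions[i]
    r = np.hypot(d[:, 0], d[:, 1])
    if (r <= 0).any():
        raise ValueError("coincident bond endpoints (r = 0)")
    return i, j, d, r


def _forces_energy(
    net: CellNetwork, positions: np.ndarray, activation: np.ndarray
):
    i, j, d, r = _bond_kinematics(net, positions)
    ra = activation * net.r0
    strain = (r - ra) / ra
    K = np.where(strain > 0.0, net.K_t, net.K_c)
    F = K * strain
    energy = float(np.sum(0.5 * ra * K * strain * strain))
    scale = F / r
    fbx = scale * d[:, 0]
    fby = scale * d[:, 1]
    N = len(positions)
    forces = np.empty_like(positions)
    forces[:, 0] = np.bincount(i, fbx, N) - np.bincount(j, fbx, N)
    forces[:, 1] = np.bincount(i, fby, N) - np.bincount(j, fby, N)
    return forces, energy, (i, j, d, r, ra, strain, K, F)


def assemble_forces(
    net: CellNetwork,
    displacements: np.ndarray,
    activation: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-node internal force vectors (nN) and total energy (nN·μm).

    ``displacements`` is (N, 2) relative to the generated positions.
    The force on a node is the pull of its incident bonds; a bond in
    tension contributes equal and opposite forces to its endpoints.
    """
    act = net.a if activation is None else activation
    positions = net.positions + displacements
    forces, energy, _ = _forces_energy(net, positions, act)
    return forces, energy


def tangent_stiffness(
    net: CellNetwork,
    positions: np.ndarray,
    activation: np.ndarray | None = None,
) -> csc_matrix:
    """Sparse tangent stiffness ``d(-force)/d(position)`` (2N x 2N).

    Per bond: material term ``(K/ra) n n^T`` plus geometric term
    ``(F/r)(I - n n^T)`` along/transverse to the bond direction.
    """
    act = net.a if activation is None else activation
    i, j, d, r = _bond_kinematics(net, positions)
    ra = act * net.r0
    strain = (r - ra) / ra
    K = np.where(strain > 0.0, net.K_t, net.K_c)
    F = K * strain
    n = d / r[:, None]
    k_ax = K / ra
    k_tr = F / r
    # 2x2 block per bond: k_ax n n^T + k_tr (I - n n^T)
    blocks = (
        (k_ax - k_tr)[:, None, None] * n[:, :, None] * n[:, None, :]
        + k_tr[:, None, None] * np.eye(2)[None, :, :]
    )
    rows, cols, vals = [], [], []
    for (bi, bj, sign) in ((i, i, 1.0), (j, j, 1.0), (i, j, -1.0), (j, i, -1.0)):
        for p in range(2):
            for q in range(2):
                rows.append(2 * bi + p)
                cols.append(2 * bj + q)
                vals.append(sign * blocks[:, p, q])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    nn = 2 * len(positions)
    return coo_matrix((vals, (rows, cols)), shape=(nn, nn)).tocsc()


# ---------------------------------------------------------------------------
# Energy minimisation
# ---------------------------------------------------------------------------


@dataclass
class EquilibriumState:
    """Result of an energy minimisation under displacement BCs."""

    u: np.ndarray  # (N, 2) node displacements, μm
    forces: np.ndarray  # (N, 2) internal nodal forces at equilibrium, nN
    bc_ids: np.ndarray  # constrained node ids
    f_C: np.ndarray  # (n_bc, 2) force required to hold each constrained node
    energy: float  # nN·μm
    converged: bool
    n_iter: int
    force_norm: float  # 2-norm of residual forces on free nodes, nN

    def reactions(self) -> dict[int, np.ndarray]:
        return {int(k): self.f_C[idx] for idx, k in enumerate(self.bc_ids)}


def _normalise_bc(bc) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(bc, dict):
        ids = np.array(sorted(bc), dtype=int)
        U = np.array([bc[k] for k in ids], dtype=float)
    else:
        ids, U = bc
        ids = np.asarray(ids, dtype=int)
        U = np.asarray(U, dtype=float)
    return ids, U


def minimize_energy(
    net: CellNetwork,
    bc,
    *,
    ftol: float = DEFAULT_FTOL,
    ramp_steps: int = 5,
    max_rounds: int = 30,
    lbfgs_maxiter: int = 4000,
    x0: np.ndarray | None = None,
    newton_polish: bool = True,
) -> EquilibriumState:
    """Minimise the network energy over free nodes under displacement BCs.

    Parameters
    ----------
    bc : dict[int, array] or (ids, U)
        Imposed displacements of the constrained (FA) nodes.
    ftol : float
        Convergence threshold on the 2-norm of the free-node force
        vector, nN.  Default 1e-3 nN (1 pN).
    ramp_steps : int
        Activation is ramped ``a: 1 -> target`` in this many equal
        steps, re-minimising at each.  Ignored on warm starts (``x0``),
        which are assumed already activated.
    x0 : (N, 2) array, optional
        Warm-start displacement field.

    Returns an :class:`EquilibriumState`; ``f_C`` holds, per constrained
    node, the external force that must be applied to keep it at its
    imposed displacement (equal to minus the internal nodal force).
    """
    ids, U = _normalise_bc(bc)
    if len(ids) == 0:
        raise ValueError("at least one constrained node is required")
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate node ids in boundary conditions")
    N = net.n_nodes
    if ids.max() >= N:
        raise ValueError("boundary condition on nonexistent node")
    free = np.ones(N, dtype=bool)
    free[ids] = False

    # the constrained set should pin rigid-body modes; a gradient descent
    # still converges to *a* minimum otherwise (e.g. the single-bond case),
    # so flag rather than refuse
    if len(ids) == 1 or (len(ids) >= 2 and _collinear(net.positions[ids])):
        import warnings

        warnings.warn(
            "constrained nodes are collinear: rigid-body modes remain and "
            "the equilibrium position is non-unique",
            stacklevel=2,
        )

    pos = net.positions.copy()
    if x0 is not None:
        pos = net.positions + x0
    pos[ids] = net.positions[ids] + U

    schedules = (
        [net.a]
        if x0 is not None or ramp_steps <= 1
        else [1.0 + t * (net.a - 1.0) for t in np.linspace(1 / ramp_steps, 1.0, ramp_steps)]
    )

    n_iter = 0
    converged = False
    fnorm = np.inf
    for step, act in enumerate(schedules):
        # intermediate ramp states only need a rough equilibrium
        step_ftol = ftol if step == len(schedules) - 1 else 100.0 * ftol
        pos, n_it, fnorm, converged = _solve_at_activation(
            net, pos, act, free, step_ftol, max_rounds, lbfgs_maxiter, newton_polish
        )
        n_iter += n_it

    forces, energy, _ = _forces_energy(net, pos, net.a)
    u = pos - net.positions
    f_C = -forces[ids]
    return EquilibriumState(
        u=u,
        forces=forces,
        bc_ids=ids,
        f_C=f_C,
        energy=energy,
        converged=converged,
        n_iter=n_iter,
        force_norm=fnorm,
    )


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    if len(pts) < 3:
        return True
    d = pts - pts.mean(axis=0)
    s = np.linalg.svd(d, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def _solve_at_activation(
    net, pos, act, free, ftol, max_rounds, lbfgs_maxiter, newton_polish
):
    act = np.broadcast_to(np.asarray(act, dtype=float), net.K_t.shape)
    free_idx = np.flatnonzero(free)
    nf = len(free_idx)
    if nf == 0:  # fully constrained network: nothing to relax
        return pos, 0, 0.0, True
    n_iter = 0

    def fun(x):
        p = pos.copy()
        p[free_idx] = x.reshape(nf, 2)
        forces, energy, _ = _forces_energy(net, p, act)
        return energy, -forces[free_idx].ravel()

    def fnorm_at(p):
        forces, _, _ = _forces_energy(net, p, act)
        return float(np.linalg.norm(forces[free_idx].ravel()))

    x = pos[free_idx].ravel().copy()
    pgtol = max(ftol / max(np.sqrt(2.0 * nf), 1.0) * 0.3, 1e-14)
    fnorm = fnorm_at(pos)
    if fnorm <= ftol:
        return pos, 0, fnorm, True
    if newton_polish:
        # Newton on the residual forces is the cheapest route whenever the
        # line search accepts; fall back to L-BFGS descent otherwise
        pos, fnorm, _ = _newton_polish(net, pos, act, free_idx, ftol, fnorm)
        n_iter += 1
        x = pos[free_idx].ravel()
        if fnorm <= ftol:
            return pos, n_iter, fnorm, True
    for round_ in range(max_rounds):
        # short L-BFGS bursts; the Newton polish handles the endgame
        x, _, info = fmin_l_bfgs_b(
            fun, x, m=20, pgtol=pgtol, factr=10.0,
            maxiter=min(lbfgs_maxiter, 400 * (round_ + 1)),
        )
        n_iter += info["nit"]
        pos[free_idx] = x.reshape(nf, 2)
        fnorm = fnorm_at(pos)
        if fnorm <= ftol:
            return pos, n_iter, fnorm, True
        if newton_polish:
            pos, fnorm, moved = _newton_polish(
                net, pos, act, free_idx, ftol, fnorm
            )
            n_iter += 1
            x = pos[free_idx].ravel()
            if fnorm <= ftol:
                return pos, n_iter, fnorm, True
            if not moved and info["warnflag"] == 0:
                # L-BFGS converged to its own tolerance and Newton cannot
                # improve: accept as stagnated
                break
        elif info["warnflag"] == 0:
            break
    return pos, n_iter, fnorm, fnorm <= ftol


def _newton_polish(net, pos, act, free_idx, ftol, fnorm0, max_steps: int = 30):
    """Regularised Newton iteration on the residual force vector.

    Solves ``(K_ff + mu I) dx = f_free`` with the sparse tangent
    stiffness; steps are accepted only if the free-force norm drops.
    """
    nf = len(free_idx)
    dof = np.concatenate([2 * free_idx, 2 * free_idx + 1])
    dof.sort()
    fnorm = fnorm0
    moved = False
    lu = None
    for _ in range(max_steps):
        forces, _, _ = _forces_energy(net, pos, act)
        f_free = forces[free_idx].ravel()
        fnorm = float(np.linalg.norm(f_free))
        if fnorm <= ftol:
            return pos, fnorm, True
        K = tangent_stiffness(net, pos, act)
        K_ff = K[dof][:, dof]
        mu = 1e-8 * max(K_ff.diagonal().mean(), 1.0)
        try:
            lu = splu((K_ff + mu * identity(2 * nf, format="csc")).tocsc())
            dx = lu.solve(f_free)
        except RuntimeError:
            return pos, fnorm, moved
        step = 1.0
        accepted = False
        for _ls in range(8):
            trial = pos.copy()
            trial[free_idx] += step * dx.reshape(nf, 2)
            try:
                tnorm = _free_force_norm(net, trial, act, free_idx)
            except ValueError:
                tnorm = np.inf
            if tnorm < fnorm:
                pos, fnorm = trial, tnorm
                accepted = moved = True
                break
            step *= 0.5
        if not accepted:
            return pos, fnorm, moved
    return pos, fnorm, moved


def _free_force_norm(net, pos, act, free_idx) -> float:
    forces, _, _ = _forces_energy(net, pos, act)
    return float(np.linalg.norm(forces[free_idx].ravel()))
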