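"""Weak cell–substrate coupling by per-FA force-residual minimisation.

The cell network and the substrate operator are solved separately and
coupled by enforcing equal displacements ``u^(k)`` at every FA site k.
With ``f_C^(k)`` the force required to hold FA k of the cell at its
displacement and ``f_S^(k)`` the force required to impose the same
displacement on the substrate patch, force balance at the FA reads

    R^(k) = f_S^(k) + f_C^(k) = 0 ,

and the cell-scale residual is the 2-norm over FAs,
``Rbar_cell = sqrt(sum_k |R^(k)|^2)``.

The residual is driven down by a damped (Levenberg–Marquardt type)
Gauss–Newton scheme on the partitioned problem.  Per coupling
iteration the FA set is swept in a few fixed groups: each group takes
a damped step computed from the analytic Jacobian of its own residuals
(substrate patch stiffness plus the cell tangent condensed onto the FA
degrees of freedom), both sub-models are re-solved at the trial
displacements, and the step is kept only where the residual dropped
(classic LM damping updates ``mu_k`` per FA).  Because the partitioned
sweep converges geometrically, an Anderson-type mixing of the recent
iterates (the standard accelerator for partitioned multiphysics
coupling) is attempted at the end of each iteration and kept only when
it lowers the residual further.  Accepted iterations never increase
the cell-scale residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve
from scipy.sparse import identity
from scipy.sparse.linalg import splu

from .mechanics import (
    DEFAULT_FTOL,
    EquilibriumState,
    minimize_energy,
    tangent_stiffness,
)
from .netgen import CellNetwork
from .substrate import (
    LoadCase,
    SubstrateOperator,
    SubstrateSpec,
    build_substrate_operator,
)


@dataclass
class FAState:
    """Per-FA coupling state."""

    X: np.ndarray  # reference position, μm
    u: np.ndarray  # current displacement, μm
    f_C: np.ndarray  # cell-side holding force, nN
    f_S: np.ndarray  # substrate-side holding force, nN
    R: np.ndarray  # residual f_S + f_C, nN
    J: np.ndarray | None = None  # 2x2 dR/du, nN/μm
    mu: float = 0.0  # LM damping


@dataclass
class CoupledResult:
    """Outcome of a coupled cell–substrate equilibrium run."""

    network: CellNetwork
    operator: SubstrateOperator
    load_case: LoadCase
    u_fa: np.ndarray  # (n_fa, 2) final FA displacements
    f_C: np.ndarray
    f_S: np.ndarray
    R: np.ndarray
    rbar_history: list[float]  # cell-scale residual per accepted iteration
    cell_state: EquilibriumState
    n_iterations: int
    accepted_log: list[int] = field(default_factory=list)  # accepted FAs/iter

    @property
    def rbar(self) -> float:
        return self.rbar_history[-1]

    @property
    def reduction(self) -> float:
        """Final over initial cell-scale residual."""
        return self.rbar_history[-1] / self.rbar_history[0]

    def fa_states(self) -> list[FAState]:
        X = self.network.positions[self.network.fa_ids]
        return [
            FAState(X=X[k], u=self.u_fa[k], f_C=self.f_C[k],
                    f_S=self.f_S[k], R=self.R[k])
            for k in range(len(X))
        ]

    def surface_closure(self):
        """Surface displacement field of the final substrate state."""
        return self.operator.displacement_closure(self.f_S, self.load_case)


def rbar_cell(R: np.ndarray) -> float:
    """Cell-scale residual: 2-norm over the per-FA residual vectors."""
    return float(np.sqrt(np.sum(np.asarray(R) ** 2)))


def evaluate_residuals(
    net: CellNetwork,
    operator: SubstrateOperator,
    fa_displacements: np.ndarray,
    load_case: LoadCase,
    *,
    warm: EquilibriumState | None = None,
    ftol: float = DEFAULT_FTOL,
) -> tuple[EquilibriumState, np.ndarray, np.ndarray, float]:
    """Solve both sub-models at the given FA displacements.

    Returns ``(cell_state, f_S, R, rbar)``; ``cell_state.f_C`` holds the
    cell-side forces.
    """
    u = np.asarray(fa_displacements, dtype=float)
    cell_state = minimize_energy(
        net,
        (net.fa_ids, u),
        ftol=ftol,
        x0=None if warm is None else warm.u,
    )
    f_S = operator.reactions(u, load_case)
    R = f_S + cell_state.f_C
    return cell_state, f_S, R, rbar_cell(R)


# ---------------------------------------------------------------------------
# Jacobians
# ---------------------------------------------------------------------------


def cell_schur_matrix(net: CellNetwork, cell_state: EquilibriumState) -> np.ndarray:
    """Cell tangent stiffness condensed onto the FA degrees of freedom.

    Static condensation (Schur complement) of the analytic tangent at
    the given equilibrium: the interior relaxes, the FA set carries the
    condensed 2n_FA x 2n_FA stiffness.  A small regularisation handles
    the floppy (sub-isostatic) interior modes.
    """
    pos = net.positions + cell_state.u
    K = tangent_stiffness(net, pos)
    fa = net.fa_ids
    fa_dof = np.sort(np.concatenate([2 * fa, 2 * fa + 1]))
    free = np.ones(net.n_nodes, dtype=bool)
    free[fa] = False
    free_idx = np.flatnonzero(free)
    fdof = np.sort(np.concatenate([2 * free_idx, 2 * free_idx + 1]))
    K_cc = K[fa_dof][:, fa_dof]
    if len(fdof) == 0:  # no interior: the FA block is the whole tangent
        return K_cc.toarray()
    K_cf = K[fa_dof][:, fdof]
    K_ff = K[fdof][:, fdof].tocsc()
    mu = 1e-6 * max(K_ff.diagonal().mean(), 1.0)
    lu = splu((K_ff + mu * identity(K_ff.shape[0], format="csc")).tocsc())
    Y = lu.solve(K_cf.T.toarray())
    return K_cc.toarray() - K_cf @ Y


def cell_jacobian_blocks(
    net: CellNetwork,
    cell_state: EquilibriumState,
    method: str = "schur",
    fd_step: float = 0.05,
) -> np.ndarray:
    """Per-FA 2x2 blocks of ``d f_C / d u^(k)`` (other FAs held fixed).

    Methods
    -------
    ``"schur"``
        Diagonal blocks of the condensed analytic tangent
        (:func:`cell_schur_matrix`); exact linearisation, cheap.
    ``"local"``
        Incident-bond stiffness only (interior frozen); a stiff upper
        bound used as a fast approximation.
    ``"fd"``
        Forward finite differences with step ``fd_step`` (μm),
        re-minimising the network per perturbation.  Matches the schur
        blocks in the small-step limit; expensive, intended for small
        fixtures and verification.
    """
    fa = net.fa_ids
    n_fa = len(fa)
    if method == "schur":
        S = cell_schur_matrix(net, cell_state)
        return _diag_blocks(S, n_fa)
    if method == "local":
        pos = net.positions + cell_state.u
        K = tangent_stiffness(net, pos)
        fa_dof = np.sort(np.concatenate([2 * fa, 2 * fa + 1]))
        Kd = K[fa_dof][:, fa_dof].toarray()
        return _diag_blocks(Kd, n_fa)
    if method == "fd":
        blocks = np.empty((n_fa, 2, 2))
        u0 = cell_state.u[fa]
        for k in range(n_fa):
            for comp in range(2):
                u_pert = u0.copy()
                u_pert[k, comp] += fd_step
                st = minimize_energy(
                    net, (fa, u_pert), x0=cell_state.u, ftol=DEFAULT_FTOL
                )
                blocks[k][:, comp] = (st.f_C[k] - cell_state.f_C[k]) / fd_step
        return blocks
    raise ValueError(f"unknown Jacobian method {method!r}")


def _diag_blocks(M: np.ndarray, n: int) -> np.ndarray:
    blocks = np.empty((n, 2, 2))
    for k in range(n):
        blocks[k] = M[2 * k : 2 * k + 2, 2 * k : 2 * k + 2]
    return blocks


def estimate_fa_jacobian(
    k: int,
    net: CellNetwork,
    cell_state: EquilibriumState,
    operator: SubstrateOperator,
    *,
    method: str = "schur",
    fd_step: float = 0.05,
) -> np.ndarray:
    """Simplified 2x2 coupling Jacobian ``dR^(k)/du^(k)`` of a single FA:
    cell-side block plus the analytic substrate patch stiffness."""
    cell_blocks = cell_jacobian_blocks(net, cell_state, method=method, fd_step=fd_step)
    sub_blocks = operator.stiffness_blocks()
    return cell_blocks[k] + sub_blocks[k]


# ---------------------------------------------------------------------------
# Coupled equilibrium driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CouplingOptions:
    max_iter: int = 10
    rbar_tol: float = 0.0  # absolute stop threshold on Rbar_cell, nN
    n_groups: int = 3  # FA groups swept per iteration
    cluster_cutoff: float = 4.0  # μm; closer FAs always share a group
    jacobian_method: str = "schur"  # cell-side linearisation for the sweep
    in_group_coupling: bool = True  # use full in-group Jacobian blocks
    mu_init_scale: float = 0.02
    mu_up: float = 4.0
    mu_down: float = 0.5
    max_step: float = 2.0  # μm, per-FA trial step cap
    group_retries: int = 2  # re-damped retries of a rejected group step
    accel_from: int = 2  # first iteration eligible for residual acceleration
    accel_window: int = 4  # iterates mixed by the Anderson step
    accel_coef_cap: float = 30.0  # reject wild extrapolation coefficients
    cell_ftol: float = DEFAULT_FTOL
    divergence_patience: int = 3
    reorient_patches: bool = False
    verbose: bool = False


def run_coupled_equilibrium(
    net: CellNetwork,
    substrate_spec: SubstrateSpec,
    load_case: LoadCase,
    options: CouplingOptions = CouplingOptions(),
    rng: np.random.Generator | None = None,
) -> CoupledResult:
    """Iterate the damped partitioned coupling for ``max_iter`` iterations.

    Initial FA displacements follow the load case: zero for the
    unstretched substrate, the far-field affine motion
    ``(sqrt(1.1)-1) X`` for 10% substrate area strain.  Patch major
    axes are oriented along the initial displacement (10% case) or
    randomly (0% case), then re-oriented once along the first
    substrate force estimate.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    X = net.positions[net.fa_ids]
    n = len(X)
    u = load_case.affine_displacement(X)

    if load_case.area_strain != 0.0:
        theta = np.arctan2(u[:, 1], u[:, 0])
    else:
        theta = rng.uniform(0.0, np.pi, size=n)
    operator = build_substrate_operator(substrate_spec, X, theta)

    cell_state, f_S, R, rbar = evaluate_residuals(
        net, operator, u, load_case, ftol=options.cell_ftol
    )
    if options.reorient_patches:
        # one-off patch re-orientation along the initial force estimate;
        # afterwards the operator stays fixed so accepted iterations compare
        # residuals of one and the same system
        fmag = np.linalg.norm(R, axis=1)
        theta = np.where(fmag > 1e-9, np.arctan2(R[:, 1], R[:, 0]), theta)
        operator = build_substrate_operator(substrate_spec, X, theta)
        f_S = operator.reactions(u, load_case)
        R = f_S + cell_state.f_C
        rbar = rbar_cell(R)

    Ks = cho_solve(operator._cho, np.eye(2 * n))
    groups = _proximity_groups(X, options.n_groups, options.cluster_cutoff, rng)
    mu = None
    history = [rbar]
    accepted_log: list[int] = []
    hist_u: list[np.ndarray] = []
    hist_R: list[np.ndarray] = []
    grow_streak = 0

    for it in range(1, options.max_iter + 1):
        if options.in_group_coupling and options.jacobian_method == "schur":
            S = cell_schur_matrix(net, cell_state)
        else:
            blocks = cell_jacobian_blocks(
                net, cell_state, method=options.jacobian_method
            )
            S = np.zeros((2 * n, 2 * n))
            for k in range(n):
                S[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] = blocks[k]
        K_full = Ks + S
        if mu is None:
            diag = _diag_blocks(K_full, n)
            JtJ = np.einsum("kji,kjl->kil", diag, diag)
            mu = options.mu_init_scale * 0.5 * np.einsum("kii->k", JtJ)

        rbar_before = rbar
        u_start = u.copy()
        n_accepted = 0
        for g in groups:
            m = len(g)
            gd = np.ravel(np.column_stack([2 * g, 2 * g + 1]))
            Kgg = (
                K_full[np.ix_(gd, gd)]
                if options.in_group_coupling
                else _block_diag_of(K_full, g)
            )
            for attempt in range(options.group_retries + 1):
                if attempt < options.group_retries:
                    # bold Gauss-Seidel step: in-group Jacobian only, other
                    # groups assumed to adapt in their own sweeps
                    KtK = Kgg.T @ Kgg
                    KtR = Kgg.T @ R[g].ravel()
                else:
                    # fallback: block-coordinate Gauss-Newton with the full
                    # column block, whose damped steps always descend
                    Kcols = K_full[:, gd]
                    KtK = Kcols.T @ Kcols
                    KtR = Kcols.T @ R.ravel()
                A = KtK.copy()
                for a_ in range(m):
                    A[2 * a_ : 2 * a_ + 2, 2 * a_ : 2 * a_ + 2] += mu[g[a_]] * np.eye(2)
                du = -np.linalg.solve(A, KtR).reshape(m, 2)
                sn = np.linalg.norm(du, axis=1)
                over = sn > options.max_step
                du[over] *= (options.max_step / sn[over])[:, None]
                trial_u = u.copy()
                trial_u[g] += du
                t_state, t_fS, t_R, t_rbar = evaluate_residuals(
                    net, operator, trial_u, load_case,
                    warm=cell_state, ftol=options.cell_ftol,
                )
                improved = np.linalg.norm(t_R[g], axis=1) <= np.linalg.norm(R[g], axis=1)
                if t_rbar <= rbar:
                    u, cell_state, f_S, R, rbar = trial_u, t_state, t_fS, t_R, t_rbar
                    mu[g] = np.where(
                        improved, mu[g] * options.mu_down, mu[g] * options.mu_up
                    )
                    n_accepted += int(improved.sum())
                    break
                # rejected: raise damping on the FAs that did not improve
                # and retry the group with more conservative steps
                mu[g] = np.where(improved, mu[g], mu[g] * options.mu_up)

        # Anderson acceleration on the force residual: combine the recent
        # post-sweep iterates so the linearised residual of the mixture is
        # minimal, and keep the mixed point only if it actually improves
        hist_u.append(u.copy())
        hist_R.append(R.copy())
        if len(hist_u) > options.accel_window:
            hist_u.pop(0)
            hist_R.pop(0)
        if len(hist_u) >= 2 and it >= options.accel_from:
            base_R = hist_R[-1].ravel()
            D = np.stack([(r_.ravel() - base_R) for r_ in hist_R[:-1]], axis=1)
            DtD = D.T @ D
            ridge = 1e-12 * max(np.trace(DtD), 1e-30)
            try:
                gamma = np.linalg.solve(
                    DtD + ridge * np.eye(len(hist_u) - 1), -D.T @ base_R
                )
            except np.linalg.LinAlgError:
                gamma = None
            if gamma is not None and np.abs(gamma).sum() <= options.accel_coef_cap:
                xu = (1.0 - gamma.sum()) * hist_u[-1]
                for gi, ui in zip(gamma, hist_u[:-1]):
                    xu = xu + gi * ui
                x_state, x_fS, x_R, x_rbar = evaluate_residuals(
                    net, operator, xu, load_case,
                    warm=cell_state, ftol=options.cell_ftol,
                )
                if options.verbose:
                    print(
                        f"  it {it}: anderson m={len(hist_u)} "
                        f"rbar {rbar:.3f} -> {x_rbar:.3f} "
                        f"{'accepted' if x_rbar < rbar else 'rejected'}"
                    )
                if x_rbar < rbar:
                    u, cell_state, f_S, R, rbar = xu, x_state, x_fS, x_R, x_rbar
                    hist_u.append(u.copy())
                    hist_R.append(R.copy())
                    if len(hist_u) > options.accel_window:
                        hist_u.pop(0)
                        hist_R.pop(0)

        accepted_log.append(n_accepted)
        history.append(rbar)
        grow_streak = grow_streak + 1 if rbar > rbar_before else 0
        if grow_streak >= options.divergence_patience:
            raise RuntimeError(
                f"coupling diverging: Rbar_cell grew {grow_streak} consecutive "
                f"iterations (history {history})"
            )
        if rbar <= options.rbar_tol:
            break

    return CoupledResult(
        network=net,
        operator=operator,
        load_case=load_case,
        u_fa=u,
        f_C=cell_state.f_C,
        f_S=f_S,
        R=R,
        rbar_history=history,
        cell_state=cell_state,
        n_iterations=len(history) - 1,
        accepted_log=accepted_log,
    )


def _proximity_groups(
    X: np.ndarray, n_groups: int, cutoff: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Split the FA set into sweep groups, keeping FAs closer than
    ``cutoff`` in the same group.

    Nearly coincident adhesions couple almost singularly through the
    substrate; splitting such a pair across groups makes the sweep
    contraction arbitrarily slow, whereas the exact in-group Jacobian
    handles the pair in one step.
    """
    from scipy.spatial import cKDTree

    n = len(X)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in cKDTree(X).query_pairs(r=cutoff):
        parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    order = rng.permutation(list(clusters))
    groups: list[list[int]] = [[] for _ in range(n_groups)]
    sizes = np.zeros(n_groups, dtype=int)
    for root in order:
        g = int(np.argmin(sizes))  # balance group sizes
        groups[g].extend(clusters[root])
        sizes[g] += len(clusters[root])
    return [np.asarray(sorted(g), dtype=int) for g in groups if g]


def _block_diag_of(M: np.ndarray, g: np.ndarray) -> np.ndarray:
    m = len(g)
    out = np.zeros((2 * m, 2 * m))
    for a_, k in enumerate(g):
        out[2 * a_ : 2 * a_ + 2, 2 * a_ : 2 * a_ + 2] = M[
            2 * k : 2 * k + 2, 2 * k : 2 * k + 2
        ]
    return out
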