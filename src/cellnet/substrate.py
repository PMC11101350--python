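"""Elastic substrate operator: FA patch reactions and surface displacements.

The substrate (a soft silicone block, 1000x1000x100 μm, small-strain
Young's modulus E ~ 7 kPa derived from its neo-Hookean C10 in the
incompressible limit, E = 6 C10) is represented by the tangential
surface Green's function of a linear-elastic half space (Cerruti-type
kernel).  Each focal adhesion acts on the surface through a rigid
elliptical patch (default 2 x 1 μm, ~30 in-plane sample points); the
patch-level compliance matrix couples all FAs, and its inverse maps
imposed rigid-patch displacements (relative to an optional far-field
equibiaxial stretch) to patch reaction forces.

The half-space kernel replaces a finite-thickness finite-element block:
at the strains considered (<= ~10%) and with the layer thick relative
to the FA spacing, the linearised half-space response is an accurate
and very fast stand-in, and keeps the operator purely algebraic.

Sign convention: ``substrate_reactions`` returns, per FA, the force
that must be applied *to the substrate patch* to hold it at the imposed
displacement.  The derivative of this force w.r.t. the displacement is
positive definite (it is the patch stiffness).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

#: Average-displacement correction of a uniformly loaded disc relative
#: to the rigid flat punch (32 / (3 pi^2)); used for self-compliance
#: regularisation of the discretised kernel.
_UNIFORM_OVER_PUNCH = 32.0 / (3.0 * math.pi**2)

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class LoadCase:
    """Far-field equibiaxial loading of the substrate surface."""

    area_strain: float = 0.0  # ε_A applied: 0.0 or 0.10

    def __post_init__(self) -> None:
        if self.area_strain < -1.0:
            raise ValueError("area strain below -100% is unphysical")

    @property
    def stretch(self) -> float:
        return math.sqrt(1.0 + self.area_strain)

    def affine_displacement(self, X: np.ndarray) -> np.ndarray:
        """u_aff(X) = (sqrt(1+ε_A) - 1) X, with X measured from the
        substrate-domain centre."""
        return (self.stretch - 1.0) * np.asarray(X, dtype=float)


@dataclass(frozen=True)
class SubstrateSpec:
    """Substrate geometry, material, and FA patch discretisation."""

    dimensions: tuple[float, float, float] = (1000.0, 1000.0, 100.0)
    C10: float = 1.166  # kPa
    D1: float = 1.2008  # MPa^-1 (recorded; the operator is incompressible)
    E: float | None = None  # kPa; derived from C10 if None
    nu: float = 0.5
    patch_semi_axes: tuple[float, float] = (1.0, 0.5)  # μm
    patch_samples: int = 30
    inner_region: float = 200.0  # μm, refined central square about the origin
    backend: str = "greens_halfspace"

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("E must be positive")
        if not (0.0 < self.nu <= 0.5):
            raise ValueError("nu must be in (0, 0.5]")
        if min(self.patch_semi_axes) <= 0:
            raise ValueError("patch semi-axes must be positive")
        if self.backend != "greens_halfspace":
            raise NotImplementedError(f"unknown backend {self.backend!r}")

    @property
    def young_modulus(self) -> float:
        """Small-strain Young's modulus in kPa (= nN/μm²)."""
        return 6.0 * self.C10 if self.E is None else self.E

    @property
    def shear_modulus(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.nu))


def tangential_greens_tensor(
    dx: np.ndarray, E: float, nu: float, r_min: float = 0.0
) -> np.ndarray:
    """Cerruti surface Green's tensor for tangential point loads.

    ``G_ij(x) = (1+nu)/(pi E) [ (1-nu) δ_ij / r + nu x_i x_j / r^3 ]``
    mapping a tangential point force (nN) at the origin to the in-plane
    surface displacement (μm) at offset ``dx``.  ``r_min`` smoothly
    regularises the singularity (``r -> sqrt(r^2 + r_min^2)``).

    Returns an array of shape ``dx.shape[:-1] + (2, 2)``.
    """
    dx = np.asarray(dx, dtype=float)
    r2 = np.sum(dx * dx, axis=-1) + r_min * r_min
    r = np.sqrt(r2)
    pref = (1.0 + nu) / (math.pi * E)
    out = np.empty(dx.shape[:-1] + (2, 2))
    iso = pref * (1.0 - nu) / r
    aniso = pref * nu / (r * r2)
    out[..., 0, 0] = iso + aniso * dx[..., 0] * dx[..., 0]
    out[..., 1, 1] = iso + aniso * dx[..., 1] * dx[..., 1]
    out[..., 0, 1] = out[..., 1, 0] = aniso * dx[..., 0] * dx[..., 1]
    return out


def flat_punch_stiffness(radius: float, E: float, nu: float) -> float:
    """Closed-form tangential stiffness (nN/μm) of a rigid circular
    patch of given radius on a half space: ``8 G a / (2 - nu)``."""
    G = E / (2.0 * (1.0 + nu))
    return 8.0 * G * radius / (2.0 - nu)


def ellipse_sample_points(
    centre: np.ndarray, semi_axes: tuple[float, float], angle: float, n: int
) -> np.ndarray:
    """Deterministic sunflower (golden-angle) layout of ``n`` points
    filling an oriented ellipse."""
    k = np.arange(n)
    rad = np.sqrt((k + 0.5) / n)
    th = k * GOLDEN_ANGLE
    a, b = semi_axes
    x = a * rad * np.cos(th)
    y = b * rad * np.sin(th)
    c, s = math.cos(angle), math.sin(angle)
    pts = np.column_stack([c * x - s * y, s * x + c * y])
    return pts + np.asarray(centre)


class SubstrateOperator:
    """Assembled patch-level substrate compliance/stiffness operator.

    Exposes one 2D displacement/force pair per FA patch.  Attributes of
    interest: ``compliance`` (2n x 2n, μm/nN, symmetric positive
    definite), ``fa_positions``, ``orientations``.
    """

    def __init__(
        self,
        spec: SubstrateSpec,
        fa_positions: np.ndarray,
        orientations: np.ndarray,
        compliance: np.ndarray,
        sample_points: np.ndarray,
        r_min: float,
    ) -> None:
        self.spec = spec
        self.fa_positions = fa_positions
        self.orientations = orientations
        self.compliance = compliance
        self.sample_points = sample_points  # (n_fa, n_samples, 2)
        self.r_min = r_min
        self._cho = cho_factor(compliance)

    @property
    def n_fa(self) -> int:
        return len(self.fa_positions)

    def reactions(self, fa_displacements: np.ndarray, load_case: LoadCase) -> np.ndarray:
        """Patch forces (nN) required to impose the given rigid-patch
        displacements on top of the far-field affine field."""
        u = np.asarray(fa_displacements, dtype=float)
        if u.shape != (self.n_fa, 2):
            raise ValueError("one 2D displacement per FA required")
        du = u - load_case.affine_displacement(self.fa_positions)
        return cho_solve(self._cho, du.ravel()).reshape(self.n_fa, 2)

    def stiffness_blocks(self) -> np.ndarray:
        """Per-FA diagonal 2x2 blocks of the patch stiffness matrix
        (inverse compliance); analytic substrate part of the coupling
        Jacobians."""
        K = cho_solve(self._cho, np.eye(2 * self.n_fa))
        blocks = np.empty((self.n_fa, 2, 2))
        for k in range(self.n_fa):
            blocks[k] = K[2 * k : 2 * k + 2, 2 * k : 2 * k + 2]
        return blocks

    def surface_displacements(
        self,
        query_points: np.ndarray,
        fa_forces: np.ndarray,
        load_case: LoadCase,
        chunk: int = 2048,
    ) -> np.ndarray:
        """In-plane surface displacement (μm) at the query points:
        far-field affine motion plus Green's superposition of the patch
        forces (distributed uniformly over each patch's samples)."""
        q = np.atleast_2d(np.asarray(query_points, dtype=float))
        f = np.asarray(fa_forces, dtype=float)
        src = self.sample_points.reshape(-1, 2)
        n_s = self.sample_points.shape[1]
        fsrc = np.repeat(f, n_s, axis=0) / n_s  # (n_fa*n_s, 2)
        E, nu = self.spec.young_modulus, self.spec.nu
        out = load_case.affine_displacement(q)
        for start in range(0, len(q), chunk):
            block = q[start : start + chunk]
            dx = block[:, None, :] - src[None, :, :]
            G = tangential_greens_tensor(dx, E, nu, r_min=self.r_min)
            out[start : start + chunk] += np.einsum("qsij,sj->qi", G, fsrc)
        return out

    def displacement_closure(self, fa_forces: np.ndarray, load_case: LoadCase):
        """Callable ``points -> displacements`` capturing the final
        substrate state; consumed by the virtual TFM pipeline."""

        def closure(points: np.ndarray) -> np.ndarray:
            return self.surface_displacements(points, fa_forces, load_case)

        return closure


def _patch_self_compliance(
    pts: np.ndarray, E: float, nu: float, r_min: float, self_c: float
) -> np.ndarray:
    """Rigid condensation of one patch: 2x2 compliance of the rigidly
    coupled sample points."""
    n = len(pts)
    dx = pts[:, None, :] - pts[None, :, :]
    G = tangential_greens_tensor(dx, E, nu, r_min=r_min)
    G[np.arange(n), np.arange(n)] = self_c * np.eye(2)
    Gm = G.transpose(0, 2, 1, 3).reshape(2 * n, 2 * n)
    Km = np.linalg.inv(Gm)
    K = Km.reshape(n, 2, n, 2).sum(axis=(0, 2))
    return np.linalg.inv(K)


def build_substrate_operator(
    spec: SubstrateSpec,
    fa_positions: np.ndarray,
    fa_orientations: np.ndarray | None = None,
    near_factor: float = 4.0,
) -> SubstrateOperator:
    """Assemble the patch-level substrate operator.

    Each FA is an oriented rigid elliptical patch discretised by
    ``spec.patch_samples`` points.  Diagonal compliance blocks come from
    rigid condensation of the within-patch kernel; off-diagonal blocks
    use sample-averaged kernels for nearby patches and the
    centre-to-centre kernel for well separated ones (separation beyond
    ``near_factor`` major axes).
    """
    X = np.atleast_2d(np.asarray(fa_positions, dtype=float))
    n = len(X)
    half = spec.inner_region / 2.0
    if (np.abs(X) > half + 1e-9).any():
        raise ValueError(
            "FA positions must lie within the inner refined region "
            f"(|x|,|y| <= {half} μm about the substrate centre); "
            "re-centre the cell on the substrate"
        )
    theta = (
        np.zeros(n) if fa_orientations is None else np.asarray(fa_orientations)
    )
    a, b = spec.patch_semi_axes
    E, nu = spec.young_modulus, spec.nu

    # per-sample equivalent disc radius for self-term regularisation
    patch_area = math.pi * a * b
    a_eq = math.sqrt(patch_area / spec.patch_samples / math.pi)
    r_min = a_eq
    self_c = _UNIFORM_OVER_PUNCH / flat_punch_stiffness(a_eq, E, nu)

    samples = np.stack(
        [ellipse_sample_points(X[k], (a, b), theta[k], spec.patch_samples) for k in range(n)]
    )

    d_centres = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    if n > 1:
        off = d_centres[~np.eye(n, dtype=bool)]
        if (off < 2.0 * b).any():
            warnings.warn(
                "overlapping FA patches detected; compliance blocks of the "
                "involved patches share surface area",
                stacklevel=2,
            )

    C = np.zeros((n, 2, n, 2))
    near_cut = near_factor * 2.0 * a
    for k in range(n):
        C[k, :, k, :] = _patch_self_compliance(samples[k], E, nu, r_min, self_c)
    # far pairs in one vectorised sweep
    far = (d_centres > near_cut) & ~np.eye(n, dtype=bool)
    if far.any():
        ki, kj = np.nonzero(far)
        G = tangential_greens_tensor(X[ki] - X[kj], E, nu)
        C[ki, :, kj, :] = G
    near = (d_centres <= near_cut) & ~np.eye(n, dtype=bool)
    for k, l in zip(*np.nonzero(near)):
        if k > l:
            continue
        dx = samples[k][:, None, :] - samples[l][None, :, :]
        G = tangential_greens_tensor(dx, E, nu, r_min=r_min).mean(axis=(0, 1))
        C[k, :, l, :] = G
        C[l, :, k, :] = G.T
    C = C.reshape(2 * n, 2 * n)
    C = 0.5 * (C + C.T)
    return SubstrateOperator(spec, X, theta, C, samples, r_min)


def export_surface_grid(
    operator: SubstrateOperator,
    fa_forces: np.ndarray,
    load_case: LoadCase,
    path,
    extent: float = 200.0,
    spacing: float = 2.0,
):
    """Write the surface displacement field on a regular grid as CSV
    (columns x, y, ux, uy; μm)."""
    import pandas as pd

    half = extent / 2.0
    ax = np.arange(-half, half + spacing / 2, spacing)
    XX, YY = np.meshgrid(ax, ax)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    u = operator.surface_displacements(pts, fa_forces, load_case)
    pd.DataFrame(
        {"x": pts[:, 0], "y": pts[:, 1], "ux": u[:, 0], "uy": u[:, 1]}
    ).to_csv(path, index=False)
    return path


def substrate_reactions(
    operator: SubstrateOperator,
    fa_displacements: np.ndarray,
    load_case: LoadCase,
) -> np.ndarray:
    """Functional wrapper around :meth:`SubstrateOperator.reactions`."""
    return operator.reactions(fa_displacements, load_case)


def surface_displacements(
    operator: SubstrateOperator,
    query_points: np.ndarray,
    fa_forces: np.ndarray,
    load_case: LoadCase,
) -> np.ndarray:
    """Functional wrapper around
    :meth:`SubstrateOperator.surface_displacements`."""
    return operator.surface_displacements(query_points, fa_forces, load_case)
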