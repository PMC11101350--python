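"""Shared fixtures: toy networks and the session-wide HUVEC cohort.

The cohort study (5 cells x 2 load cases x 10 coupling iterations) is
the expensive part of the suite; it is computed once per session and
shared by the acceptance-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellnet.materials import BondMaterial
from cellnet.netgen import (
    CellGenParams,
    CellGeometry,
    CellNetwork,
    Ellipse,
    generate_cell,
)
from cellnet.study import StudyConfig, centre_network, generate_cohort, replicate_tfm_study

#: Seed of the deterministic test cohort.
COHORT_SEED = 0


def toy_geometry(positions: np.ndarray) -> CellGeometry:
    """Minimal valid geometry enclosing the given node positions."""
    from shapely.geometry import MultiPoint

    hull = MultiPoint([tuple(p) for p in positions]).convex_hull.buffer(1.0, quad_segs=2)
    poly = np.asarray(hull.exterior.coords)[:-1]
    centre = positions.mean(axis=0)
    nucleus = Ellipse((float(centre[0]), float(centre[1])), (0.2, 0.1), 0.0)
    return CellGeometry(
        polygon=poly,
        membrane_points=poly,
        nucleus=nucleus,
        nuclear_membrane_points=nucleus.boundary_points(8),
    )


def make_toy_network(
    positions,
    bonds,
    material: BondMaterial | None = None,
    fa_ids=(),
    K_t=None,
    K_c=None,
    a=None,
    r0=None,
    bond_class="cortex",
) -> CellNetwork:
    """Hand-built network for small mechanics/coupling fixtures."""
    positions = np.asarray(positions, dtype=float)
    bonds = np.asarray(bonds, dtype=int)
    m = len(bonds)
    if material is not None:
        K_t = np.full(m, material.K_t)
        K_c = np.full(m, material.K_c)
        a = np.full(m, material.a)
    K_t = np.asarray(K_t, dtype=float)
    K_c = np.asarray(K_c, dtype=float)
    a = np.asarray(a, dtype=float)
    if r0 is None:
        d = positions[bonds[:, 1]] - positions[bonds[:, 0]]
        r0 = np.hypot(d[:, 0], d[:, 1])
    return CellNetwork(
        positions=positions,
        kinds=np.full(len(positions), "cortex", dtype="<U16"),
        bonds=bonds,
        bond_class=np.full(m, bond_class, dtype="<U16"),
        K_t=K_t,
        K_c=K_c,
        a=a,
        r0=np.asarray(r0, dtype=float),
        fa_ids=np.asarray(fa_ids, dtype=int),
        geometry=toy_geometry(positions),
    )


def random_toy_network(
    n_nodes: int,
    seed: int,
    *,
    activation: float = 1.0,
    span: float = 10.0,
    stiffness: float = 5.0,
) -> CellNetwork:
    """Random Delaunay-triangulated spring network on ``n_nodes`` nodes."""
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, span, size=(n_nodes, 2))
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            e = (simplex[i], simplex[(i + 1) % 3])
            edges.add((min(e), max(e)))
    bonds = np.asarray(sorted(edges), dtype=int)
    K_t = stiffness * rng.uniform(0.5, 1.5, size=len(bonds))
    hull = np.unique(tri.convex_hull.ravel())
    return make_toy_network(
        pts,
        bonds,
        fa_ids=hull,
        K_t=K_t,
        K_c=0.1 * K_t,
        a=np.full(len(bonds), activation),
    )


@pytest.fixture(scope="session")
def cell1() -> CellNetwork:
    """One full-size HUVEC network, centred on the substrate origin."""
    return centre_network(generate_cell(CellGenParams(seed=1)))


@pytest.fixture(scope="session")
def cell1_eq(cell1):
    """Equilibrium of cell1 with every FA pinned at zero displacement."""
    from cellnet.mechanics import minimize_energy

    bc = (cell1.fa_ids, np.zeros((len(cell1.fa_ids), 2)))
    return minimize_energy(cell1, bc)


@pytest.fixture(scope="session")
def study_config() -> StudyConfig:
    return StudyConfig(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort(study_config):
    """The 5-cell HUVEC cohort of the replication study."""
    return generate_cohort(study_config)


@pytest.fixture(scope="session")
def cohort_study(study_config, cohort):
    """Full replication study: 5 cells x {0%, 10%} x 10 coupling
    iterations, with coupled states retained for downstream analyses."""
    return replicate_tfm_study(
        study_config, cells=cohort, keep_coupled=True, verbose=True
    )
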