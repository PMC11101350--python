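"""Stochastic generation of discrete cytoskeletal network models (DNMs).

A single endothelial cell is represented in 2D by

* a convex polygon (the cell membrane outline), its boundary subdivided
  into membrane segments,
* a nucleus ellipse inside the polygon, its boundary subdivided into
  nuclear-membrane segments,
* a cortical actin mesh: Voronoi tessellation of Poisson-disc samples,
  clipped to the polygon and tied to the membrane points,
* focal adhesions (FAs): a random subset of cortex nodes, at a surface
  density of ~0.04 FAs/μm²,
* ventral stress fibres: single bonds between distant FA pairs,
* perinuclear stress fibres: two-segment paths relayed over the nearest
  nuclear-membrane point of a chord passing the nucleus,
* nuclear actin: random chords between nuclear-membrane points.

Monolayers are built by Voronoi-partitioning a domain into cell
polygons, shrinking each towards its centroid by ``delta`` and running
the single-cell pipeline per polygon; adjacent cells are connected by
junction bonds between nearby membrane points.

All randomness flows through one ``numpy.random.Generator`` seeded from
the parameter set, so identical parameters yield identical networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.spatial import Voronoi, cKDTree
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import LineString, Point, Polygon

from .materials import DEFAULT_MATERIALS, BondMaterial, FibreClass


class GenerationError(RuntimeError):
    """Raised when a network cannot be generated under the given parameters."""


# ---------------------------------------------------------------------------
# Parameters and geometric containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGenParams:
    """Generation parameters of a single-cell DNM.

    Lengths in μm.  ``n_FA="auto"`` selects ``round(0.04 * polygon
    area)`` clipped to [200, 300], reproducing the reported FA surface
    density of 0.04 FAs/μm².  The polygon acceptance window keeps the
    auto FA count inside its admissible range.
    """

    box_size: float = 100.0
    n_polygon_points: int = 6
    n_FA: int | str = "auto"
    n_ventral_SF: tuple[int, int] = (35, 40)
    n_perinuclear_SF: tuple[int, int] = (10, 20)
    n_nuclear_actin: int = 50
    # calibrated so the mean cortex bond (Voronoi edge) length comes out
    # at ~1.5 μm, the filament length behind the cortex stiffness value
    poisson_radius: float = 1.8
    min_SF_span: float = 30.0
    membrane_segment_length: float = 2.0
    n_nuclear_membrane_segments: int = 40
    polygon_area_window: tuple[float, float] = (5000.0, 7500.0)
    nucleus_semi_major: tuple[float, float] = (8.0, 15.0)
    nucleus_semi_minor: tuple[float, float] = (5.0, 10.0)
    nucleus_vicinity: float = 5.0
    fa_under_nucleus_weight: float = 0.5
    fa_density: float = 0.04
    fa_count_range: tuple[int, int] = (200, 300)
    # adhesions are finite objects (elliptical patches of ~2 μm on the
    # substrate); two FAs closer than one patch length would overlap
    min_FA_separation: float = 2.0
    seed: int = 0
    max_attempts: int = 2000

    def __post_init__(self) -> None:
        if self.n_polygon_points < 3:
            raise ValueError("need at least 3 polygon points")
        if self.poisson_radius <= 0:
            raise ValueError("poisson_radius must be positive")
        if not (0 < self.min_SF_span < self.box_size * math.sqrt(2)):
            raise ValueError("min_SF_span must be positive and fit the box")
        for name in ("n_nuclear_actin", "n_nuclear_membrane_segments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.n_FA, int) and self.n_FA <= 0:
            raise ValueError("n_FA must be positive")


@dataclass(frozen=True)
class Ellipse:
    """Axis-angle parameterisation of the nucleus outline."""

    centre: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float  # radians, orientation of the major axis

    def boundary_points(self, n: int) -> np.ndarray:
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        a, b = self.semi_axes
        x = a * np.cos(t)
        y = b * np.sin(t)
        c, s = math.cos(self.angle), math.sin(self.angle)
        pts = np.column_stack([c * x - s * y, s * x + c * y])
        return pts + np.asarray(self.centre)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorised strict-interior test."""
        p = np.atleast_2d(points) - np.asarray(self.centre)
        c, s = math.cos(self.angle), math.sin(self.angle)
        u = c * p[:, 0] + s * p[:, 1]
        v = -s * p[:, 0] + c * p[:, 1]
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 < 1.0

    def as_polygon(self, n: int = 96) -> Polygon:
        return Polygon(self.boundary_points(n))


@dataclass(frozen=True)
class CellGeometry:
    """Membrane and nucleus geometry of one cell."""

    polygon: np.ndarray  # (k, 2) ordered convex polygon vertices
    membrane_points: np.ndarray  # (m, 2) ordered points on the boundary
    nucleus: Ellipse
    nuclear_membrane_points: np.ndarray  # (q, 2) ordered points on the ellipse

    @property
    def area(self) -> float:
        return Polygon(self.polygon).area

    def shapely_polygon(self) -> Polygon:
        return Polygon(self.polygon)


#: Node kinds used in a cell network.
NODE_KINDS = ("membrane", "cortex", "nuclear_membrane")


@dataclass
class CellNetwork:
    """Assembled cell DNM: nodes, bonds with materials, FA node ids."""

    positions: np.ndarray  # (N, 2) float, μm
    kinds: np.ndarray  # (N,) '<U16'
    bonds: np.ndarray  # (M, 2) int node indices
    bond_class: np.ndarray  # (M,) '<U16' FibreClass values
    K_t: np.ndarray  # (M,) nN
    K_c: np.ndarray  # (M,) nN
    a: np.ndarray  # (M,) activation
    r0: np.ndarray  # (M,) generated length, μm
    fa_ids: np.ndarray  # (n_FA,) int
    geometry: CellGeometry
    params: CellGenParams | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def ra(self) -> np.ndarray:
        """Activated rest lengths ``a * r0``."""
        return self.a * self.r0

    def bond_lengths(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions if positions is None else positions
        d = pos[self.bonds[:, 1]] - pos[self.bonds[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def with_materials(
        self, overrides: dict[FibreClass, BondMaterial]
    ) -> "CellNetwork":
        """Return a copy with the materials of some fibre classes replaced."""
        K_t, K_c, a = self.K_t.copy(), self.K_c.copy(), self.a.copy()
        for cls, mat in overrides.items():
            mask = self.bond_class == cls.value
            K_t[mask], K_c[mask], a[mask] = mat.K_t, mat.K_c, mat.a
        return replace_fields(self, K_t=K_t, K_c=K_c, a=a)


def replace_fields(net: CellNetwork, **kw) -> CellNetwork:
    d = {
        "positions": net.positions,
        "kinds": net.kinds,
        "bonds": net.bonds,
        "bond_class": net.bond_class,
        "K_t": net.K_t,
        "K_c": net.K_c,
        "a": net.a,
        "r0": net.r0,
        "fa_ids": net.fa_ids,
        "geometry": net.geometry,
        "params": net.params,
    }
    d.update(kw)
    return CellNetwork(**d)


# ---------------------------------------------------------------------------
# Geometry generation
# ---------------------------------------------------------------------------


def _subdivide_ring(vertices: np.ndarray, segment_length: float) -> np.ndarray:
    """Subdivide a closed polygon boundary into ~equal segments per edge,
    keeping the original vertices."""
    points = []
    k = len(vertices)
    for i in range(k):
        p, q = vertices[i], vertices[(i + 1) % k]
        n_seg = max(1, int(round(np.linalg.norm(q - p) / segment_length)))
        for j in range(n_seg):
            points.append(p + (q - p) * (j / n_seg))
    return np.asarray(points)


def _convex_hull(points: np.ndarray) -> np.ndarray:
    hull = shapely.convex_hull(shapely.MultiPoint(points))
    if not isinstance(hull, Polygon):
        raise GenerationError("degenerate (collinear) polygon sample")
    xy = np.asarray(hull.exterior.coords)[:-1]
    return xy


def generate_cell_geometry(
    params: CellGenParams, rng: np.random.Generator | None = None
) -> CellGeometry:
    """Sample the cell polygon, membrane points, nucleus and its outline.

    The polygon is the convex hull of ``n_polygon_points`` uniform points
    in the generation box, resampled until its area falls inside the
    acceptance window; the nucleus ellipse is resampled until it lies
    fully inside the polygon.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    lo, hi = params.polygon_area_window
    for _ in range(params.max_attempts):
        pts = rng.uniform(0.0, params.box_size, size=(params.n_polygon_points, 2))
        try:
            poly = _convex_hull(pts)
        except GenerationError:
            continue
        area = Polygon(poly).area
        if params.n_polygon_points <= 3 or lo <= area <= hi:
            break
    else:
        raise GenerationError(
            f"no admissible polygon with area in [{lo}, {hi}] after "
            f"{params.max_attempts} attempts"
        )
    return _finish_geometry(poly, params, rng)


def _finish_geometry(
    poly: np.ndarray, params: CellGenParams, rng: np.random.Generator
) -> CellGeometry:
    shp = Polygon(poly)
    membrane_points = _subdivide_ring(poly, params.membrane_segment_length)
    nucleus = _sample_nucleus(shp, params, rng)
    nm_points = nucleus.boundary_points(params.n_nuclear_membrane_segments)
    return CellGeometry(
        polygon=poly,
        membrane_points=membrane_points,
        nucleus=nucleus,
        nuclear_membrane_points=nm_points,
    )


def _sample_nucleus(
    shp: Polygon, params: CellGenParams, rng: np.random.Generator
) -> Ellipse:
    minx, miny, maxx, maxy = shp.bounds
    shrink = 1.0
    for attempt in range(params.max_attempts):
        # progressively shrink the axis ranges so small (monolayer) cells
        # still receive an admissible nucleus
        if attempt and attempt % 200 == 0:
            shrink *= 0.8
        centre = rng.uniform((minx, miny), (maxx, maxy))
        if not shp.contains(Point(centre)):
            continue
        a = rng.uniform(*params.nucleus_semi_major) * shrink
        b = rng.uniform(*params.nucleus_semi_minor) * shrink
        angle = rng.uniform(0.0, math.pi)
        ell = Ellipse(tuple(centre), (a, b), angle)
        if shp.contains(ell.as_polygon(64)):
            return ell
    raise GenerationError("could not place nucleus ellipse inside the polygon")


# ---------------------------------------------------------------------------
# Cortex: Poisson-disc sampling + Voronoi tessellation
# ---------------------------------------------------------------------------


def poisson_disc_samples(
    shp: Polygon, radius: float, rng: np.random.Generator, k: int = 30
) -> np.ndarray:
    """Bridson dart-throwing: points inside ``shp`` with pairwise distance
    >= ``radius``."""
    minx, miny, maxx, maxy = shp.bounds
    cell = radius / math.sqrt(2.0)
    nx = int((maxx - minx) / cell) + 1
    ny = int((maxy - miny) / cell) + 1
    grid = -np.ones((nx, ny), dtype=int)
    samples: list[np.ndarray] = []
    active: list[int] = []

    def grid_idx(p):
        return int((p[0] - minx) / cell), int((p[1] - miny) / cell)

    def fits(p):
        gx, gy = grid_idx(p)
        x0, x1 = max(gx - 2, 0), min(gx + 3, nx)
        y0, y1 = max(gy - 2, 0), min(gy + 3, ny)
        for i in range(x0, x1):
            for j in range(y0, y1):
                s = grid[i, j]
                if s >= 0 and np.hypot(*(samples[s] - p)) < radius:
                    return False
        return True

    # initial point
    for _ in range(1000):
        p = rng.uniform((minx, miny), (maxx, maxy))
        if shp.contains(Point(p)):
            break
    else:
        raise GenerationError("empty polygon for Poisson-disc sampling")
    samples.append(p)
    gx, gy = grid_idx(p)
    grid[gx, gy] = 0
    active.append(0)

    while active:
        idx = rng.integers(len(active))
        base = samples[active[idx]]
        for _ in range(k):
            rad = rng.uniform(radius, 2.0 * radius)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            p = base + rad * np.array([math.cos(ang), math.sin(ang)])
            if not (minx <= p[0] < maxx and miny <= p[1] < maxy):
                continue
            if not shp.contains(Point(p)):
                continue
            if fits(p):
                samples.append(p)
                gx, gy = grid_idx(p)
                grid[gx, gy] = len(samples) - 1
                active.append(len(samples) - 1)
                break
        else:
            active.pop(idx)
    return np.asarray(samples)


def _voronoi_segments(vor: Voronoi, span: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Finite segments for all Voronoi ridges; infinite ridges are extended
    far beyond the domain so clipping handles them uniformly."""
    centre = vor.points.mean(axis=0)
    segments = []
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 >= 0 and v2 >= 0:
            segments.append((vor.vertices[v1], vor.vertices[v2]))
            continue
        finite = v2 if v1 < 0 else v1
        t = vor.points[p2] - vor.points[p1]
        t = t / np.linalg.norm(t)
        n = np.array([-t[1], t[0]])
        midpoint = 0.5 * (vor.points[p1] + vor.points[p2])
        direction = n if np.dot(midpoint - centre, n) > 0 else -n
        far = vor.vertices[finite] + direction * span
        segments.append((vor.vertices[finite], far))
    return segments


def generate_cortex(
    geometry: CellGeometry,
    params: CellGenParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the cortical actin mesh.

    Returns ``(cortex_nodes, cortex_bonds, membrane_bond_targets)``:
    positions of interior cortex nodes, bond index pairs into the
    concatenated ``[membrane_points, cortex_nodes]`` array, where
    boundary-crossing Voronoi edges have been re-terminated at the
    nearest membrane point.
    """
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    shp = geometry.shapely_polygon()
    seeds = poisson_disc_samples(shp, params.poisson_radius, rng)
    if len(seeds) < 4:
        raise GenerationError(
            "poisson_radius too large: cortex seeding produced "
            f"{len(seeds)} points"
        )
    vor = Voronoi(seeds)
    span = 4.0 * params.box_size
    membrane = geometry.membrane_points
    mem_tree = cKDTree(membrane)

    node_pos: list[np.ndarray] = []
    vert_id: dict[int, int] = {}  # voronoi vertex index -> cortex node id
    n_mem = len(membrane)

    inside = np.array([shp.contains(Point(v)) for v in vor.vertices])

    def cortex_id(vidx: int) -> int:
        if vidx not in vert_id:
            vert_id[vidx] = n_mem + len(node_pos)
            node_pos.append(vor.vertices[vidx])
        return vert_id[vidx]

    boundary = shp.exterior
    bonds: set[tuple[int, int]] = set()
    for (a_pt, b_pt), (v1, v2) in zip(
        _voronoi_segments(vor, span),
        (rv for rv in vor.ridge_vertices),
    ):
        in1 = v1 >= 0 and inside[v1]
        in2 = v2 >= 0 and inside[v2]
        if in1 and in2:
            i, j = cortex_id(v1), cortex_id(v2)
        elif in1 or in2:
            seg = LineString([a_pt, b_pt])
            cut = seg.intersection(shp)
            if cut.is_empty or cut.geom_type != "LineString":
                continue
            # endpoint on the boundary -> snap to nearest membrane point
            ends = np.asarray(cut.coords)
            interior_first = in1
            hit = ends[-1] if interior_first else ends[0]
            if boundary.distance(Point(hit)) > 1e-6:
                hit = ends[0] if interior_first else ends[-1]
            _, mem_idx = mem_tree.query(hit)
            i = cortex_id(v1 if in1 else v2)
            j = int(mem_idx)
        else:
            continue
        if i != j:
            bonds.add((min(i, j), max(i, j)))

    cortex_nodes = (
        np.asarray(node_pos) if node_pos else np.empty((0, 2), dtype=float)
    )
    if len(cortex_nodes) == 0:
        raise GenerationError("no cortex nodes inside the polygon")
    bond_arr = np.asarray(sorted(bonds), dtype=int)

    # keep only the component connected to the membrane
    n_total = n_mem + len(cortex_nodes)
    ring = np.column_stack(
        [np.arange(n_mem), (np.arange(n_mem) + 1) % n_mem]
    )
    all_edges = np.vstack([bond_arr, ring])
    adj = coo_matrix(
        (np.ones(len(all_edges)), (all_edges[:, 0], all_edges[:, 1])),
        shape=(n_total, n_total),
    )
    _, labels = connected_components(adj, directed=False)
    keep = labels == labels[0]
    if not keep.all():
        old_to_new = -np.ones(n_total, dtype=int)
        old_to_new[keep] = np.arange(keep.sum())
        bond_arr = bond_arr[keep[bond_arr].all(axis=1)]
        bond_arr = old_to_new[bond_arr]
        cortex_nodes = cortex_nodes[keep[n_mem:]]
    return cortex_nodes, bond_arr, ring


# ---------------------------------------------------------------------------
# Focal adhesions and stress fibres
# ---------------------------------------------------------------------------


def auto_fa_count(area: float, params: CellGenParams) -> int:
    lo, hi = params.fa_count_range
    return int(np.clip(round(params.fa_density * area), lo, hi))


def select_focal_adhesions(
    cortex_nodes: np.ndarray,
    cortex_offset: int,
    geometry: CellGeometry,
    params: CellGenParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pick FA node ids among the interior cortex nodes.

    Nodes underneath the nucleus are down-weighted, reflecting the lower
    observed FA density under the nucleus.
    """
    rng = np.random.default_rng(params.seed + 2) if rng is None else rng
    n = (
        auto_fa_count(geometry.area, params)
        if params.n_FA == "auto"
        else int(params.n_FA)
    )
    if n > len(cortex_nodes):
        raise GenerationError(
            f"requested {n} FAs but only {len(cortex_nodes)} cortex nodes exist"
        )
    weights = np.ones(len(cortex_nodes))
    weights[geometry.nucleus.contains(cortex_nodes)] = params.fa_under_nucleus_weight
    # weighted sequential sampling with a minimum mutual separation so
    # the finite adhesion patches cannot overlap on the substrate
    tree = cKDTree(cortex_nodes)
    available = np.ones(len(cortex_nodes), dtype=bool)
    chosen: list[int] = []
    while len(chosen) < n:
        idx = np.flatnonzero(available)
        if len(idx) == 0:
            raise GenerationError(
                f"only {len(chosen)} FAs placeable with separation >= "
                f"{params.min_FA_separation} μm (requested {n})"
            )
        w = weights[idx] / weights[idx].sum()
        pick = int(rng.choice(idx, p=w))
        chosen.append(pick)
        for nb in tree.query_ball_point(
            cortex_nodes[pick], params.min_FA_separation
        ):
            available[nb] = False
    return np.sort(np.asarray(chosen, dtype=int)) + cortex_offset


@dataclass
class StressFibres:
    """Ventral SF bonds and perinuclear SF paths (as FA–relay–FA triples)."""

    ventral: np.ndarray  # (n_v, 2) FA node ids
    perinuclear: np.ndarray  # (n_p, 3) [fa_i, nuclear_membrane_point_index, fa_j]


def generate_stress_fibres(
    fa_ids: np.ndarray,
    positions: np.ndarray,
    geometry: CellGeometry,
    params: CellGenParams,
    rng: np.random.Generator | None = None,
) -> StressFibres:
    """Sample ventral and perinuclear stress fibres between FAs."""
    rng = np.random.default_rng(params.seed + 3) if rng is None else rng
    fa_pos = positions[fa_ids]
    n_fa = len(fa_ids)
    d = np.linalg.norm(fa_pos[:, None, :] - fa_pos[None, :, :], axis=-1)
    iu, ju = np.triu_indices(n_fa, k=1)

    # --- ventral: distant FA pairs
    admissible = d[iu, ju] >= params.min_SF_span
    pairs = np.column_stack([iu[admissible], ju[admissible]])
    n_v = int(rng.integers(params.n_ventral_SF[0], params.n_ventral_SF[1] + 1))
    if len(pairs) < n_v:
        raise GenerationError(
            f"only {len(pairs)} FA pairs with span >= {params.min_SF_span} μm; "
            f"need {n_v} ventral SFs"
        )
    pick = rng.choice(len(pairs), size=n_v, replace=False)
    ventral = fa_ids[pairs[pick]]

    # --- perinuclear: chords passing the nucleus vicinity but not the nucleus
    ell_poly = geometry.nucleus.as_polygon(96)
    nm_pts = geometry.nuclear_membrane_points
    centre = np.asarray(geometry.nucleus.centre)

    cand = []
    for i, j in zip(iu, ju):
        p, q = fa_pos[i], fa_pos[j]
        # chord must pass beside the nucleus, not merely end near it
        t = np.dot(centre - p, q - p) / max(np.dot(q - p, q - p), 1e-12)
        if not (0.05 < t < 0.95):
            continue
        chord = LineString([p, q])
        if chord.intersects(ell_poly):
            continue
        if chord.distance(ell_poly) > params.nucleus_vicinity:
            continue
        relay = _admissible_relay(p, q, chord, nm_pts, ell_poly)
        if relay is not None:
            cand.append((i, j, relay))
    n_p = int(
        rng.integers(params.n_perinuclear_SF[0], params.n_perinuclear_SF[1] + 1)
    )
    if len(cand) < n_p:
        raise GenerationError(
            f"only {len(cand)} admissible perinuclear chords (vicinity "
            f"{params.nucleus_vicinity} μm); need {n_p}"
        )
    pick = rng.choice(len(cand), size=n_p, replace=False)
    peri = [
        (fa_ids[cand[ci][0]], cand[ci][2], fa_ids[cand[ci][1]]) for ci in pick
    ]
    return StressFibres(
        ventral=np.asarray(ventral, dtype=int),
        perinuclear=np.asarray(peri, dtype=int),
    )


def _admissible_relay(p, q, chord, nm_pts, ell_poly) -> int | None:
    """Nuclear-membrane point closest to the FA-FA chord such that neither
    relayed leg cuts through the nucleus interior; None if no point
    qualifies."""
    order = np.argsort([chord.distance(Point(pt)) for pt in nm_pts])
    for nm_idx in order:
        leg1 = LineString([p, nm_pts[nm_idx]])
        leg2 = LineString([nm_pts[nm_idx], q])
        if (
            leg1.intersection(ell_poly).length < 1e-6
            and leg2.intersection(ell_poly).length < 1e-6
        ):
            return int(nm_idx)
    return None


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


def assemble_cell_network(
    geometry: CellGeometry,
    cortex_nodes: np.ndarray,
    cortex_bonds: np.ndarray,
    fa_ids: np.ndarray,
    fibres: StressFibres,
    params: CellGenParams,
    rng: np.random.Generator | None = None,
    materials: dict[FibreClass, BondMaterial] | None = None,
) -> CellNetwork:
    """Assemble all node and bond sets into one :class:`CellNetwork`.

    Node ordering: membrane points, interior cortex nodes, nuclear
    membrane points.  Nuclear actin chords are sampled here (random
    distinct pairs of nuclear-membrane points).  Bond materials come
    from the material table; ``r0`` is the as-generated bond length and
    ``ra = a * r0``.
    """
    rng = np.random.default_rng(params.seed + 4) if rng is None else rng
    materials = DEFAULT_MATERIALS if materials is None else materials

    membrane = geometry.membrane_points
    nm_pts = geometry.nuclear_membrane_points
    n_mem, n_cor, n_nm = len(membrane), len(cortex_nodes), len(nm_pts)
    nm_offset = n_mem + n_cor
    positions = np.vstack([membrane, cortex_nodes, nm_pts])
    kinds = np.array(
        ["membrane"] * n_mem + ["cortex"] * n_cor + ["nuclear_membrane"] * n_nm,
        dtype="<U16",
    )

    bond_list: list[tuple[int, int, FibreClass]] = []
    ring = [(i, (i + 1) % n_mem, FibreClass.MEMBRANE) for i in range(n_mem)]
    bond_list += ring
    bond_list += [
        (nm_offset + i, nm_offset + (i + 1) % n_nm, FibreClass.NUCLEAR_MEMBRANE)
        for i in range(n_nm)
    ]
    bond_list += [(int(i), int(j), FibreClass.CORTEX) for i, j in cortex_bonds]

    # nuclear actin: random distinct chords between nuclear-membrane points
    seen: set[tuple[int, int]] = set()
    guard = 0
    while len(seen) < params.n_nuclear_actin:
        i, j = rng.integers(0, n_nm, size=2)
        guard += 1
        if guard > 100 * params.n_nuclear_actin:
            raise GenerationError("cannot sample enough nuclear actin chords")
        if i == j or abs(i - j) in (1, n_nm - 1):  # skip loop-adjacent pairs
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        bond_list.append((nm_offset + key[0], nm_offset + key[1], FibreClass.NUCLEAR_ACTIN))

    bond_list += [
        (int(i), int(j), FibreClass.VENTRAL_SF) for i, j in fibres.ventral
    ]
    for fa_i, nm_idx, fa_j in fibres.perinuclear:
        relay = nm_offset + int(nm_idx)
        bond_list.append((int(fa_i), relay, FibreClass.PERINUCLEAR_SF))
        bond_list.append((relay, int(fa_j), FibreClass.PERINUCLEAR_SF))

    bonds = np.array([(i, j) for i, j, _ in bond_list], dtype=int)
    classes = np.array([c.value for _, _, c in bond_list], dtype="<U16")
    K_t = np.empty(len(bonds))
    K_c = np.empty(len(bonds))
    act = np.empty(len(bonds))
    for cls in FibreClass:
        mask = classes == cls.value
        if not mask.any():
            continue
        if cls not in materials:
            raise GenerationError(f"no material defined for fibre class {cls.value}")
        mat = materials[cls]
        K_t[mask], K_c[mask], act[mask] = mat.K_t, mat.K_c, mat.a
    d = positions[bonds[:, 1]] - positions[bonds[:, 0]]
    r0 = np.hypot(d[:, 0], d[:, 1])

    return CellNetwork(
        positions=positions,
        kinds=kinds,
        bonds=bonds,
        bond_class=classes,
        K_t=K_t,
        K_c=K_c,
        a=act,
        r0=r0,
        fa_ids=np.asarray(fa_ids, dtype=int),
        geometry=geometry,
        params=params,
    )


def generate_cell(
    params: CellGenParams,
    materials: dict[FibreClass, BondMaterial] | None = None,
) -> CellNetwork:
    """Run the full single-cell pipeline under one seeded RNG."""
    rng = np.random.default_rng(params.seed)
    geometry = generate_cell_geometry(params, rng)
    return _cell_from_geometry(geometry, params, rng, materials)


def generate_cell_from_polygon(
    polygon: np.ndarray,
    params: CellGenParams,
    rng: np.random.Generator,
    materials: dict[FibreClass, BondMaterial] | None = None,
) -> CellNetwork:
    """Single-cell pipeline on a prescribed polygon (monolayer path)."""
    geometry = _finish_geometry(np.asarray(polygon, dtype=float), params, rng)
    return _cell_from_geometry(geometry, params, rng, materials)


def _cell_from_geometry(
    geometry: CellGeometry,
    params: CellGenParams,
    rng: np.random.Generator,
    materials: dict[FibreClass, BondMaterial] | None,
) -> CellNetwork:
    cortex_nodes, cortex_bonds, _ = generate_cortex(geometry, params, rng)
    n_mem = len(geometry.membrane_points)
    fa_ids = select_focal_adhesions(cortex_nodes, n_mem, geometry, params, rng)
    positions = np.vstack([geometry.membrane_points, cortex_nodes])
    fibres = generate_stress_fibres(fa_ids, positions, geometry, params, rng)
    return assemble_cell_network(
        geometry, cortex_nodes, cortex_bonds, fa_ids, fibres, params, rng, materials
    )


# ---------------------------------------------------------------------------
# Monolayers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonolayerParams:
    """Parameters of an endothelial-monolayer DNM."""

    n_cells: int = 9
    domain_size: float = 300.0
    shrink_delta: float = 1.0
    cell_params: CellGenParams = field(default_factory=CellGenParams)
    junction_material: BondMaterial = field(
        default_factory=lambda: DEFAULT_MATERIALS[FibreClass.JUNCTION]
    )
    junction_cutoff_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("a monolayer needs at least 2 cells")
        if self.shrink_delta <= 0:
            raise ValueError("shrink_delta must be positive")


@dataclass
class JunctionBond:
    """Bond connecting membrane nodes of two adjacent cells."""

    cell_i: int
    node_i: int
    cell_j: int
    node_j: int
    r0: float
    material: BondMaterial


@dataclass
class MonolayerNetwork:
    cells: list[CellNetwork]
    junction_bonds: list[JunctionBond]
    polygons: list[np.ndarray]  # shrunk cell polygons
    params: MonolayerParams


def _clipped_voronoi_polygons(
    seeds: np.ndarray, domain: Polygon
) -> list[np.ndarray]:
    """Voronoi polygons of ``seeds`` clipped to ``domain``; seeds are
    mirrored across the domain edges so every region is finite."""
    minx, miny, maxx, maxy = domain.bounds
    mirrored = [seeds]
    for axis, lo, hi in ((0, minx, maxx), (1, miny, maxy)):
        for bound in (lo, hi):
            m = seeds.copy()
            m[:, axis] = 2 * bound - m[:, axis]
            mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    polys = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise GenerationError("unbounded Voronoi region despite mirroring")
        poly = Polygon(vor.vertices[region]).intersection(domain)
        polys.append(np.asarray(poly.exterior.coords)[:-1])
    return polys


def generate_monolayer(params: MonolayerParams) -> MonolayerNetwork:
    """Voronoi-partition the domain, shrink each cell polygon by ``delta``,
    generate one DNM per polygon, and connect adjacent cells by junction
    bonds between nearest membrane-point pairs."""
    rng = np.random.default_rng(params.seed)
    L = params.domain_size
    domain = Polygon([(0, 0), (L, 0), (L, L), (0, L)])
    seeds = rng.uniform(0.0, L, size=(params.n_cells, 2))
    polys = _clipped_voronoi_polygons(seeds, domain)

    shrunk = []
    for poly in polys:
        centroid = np.asarray(Polygon(poly).centroid.coords[0])
        v = centroid - poly
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        if (norms <= params.shrink_delta).any():
            raise GenerationError(
                "shrink_delta too large: degenerate shrunk polygon"
            )
        shrunk.append(poly + params.shrink_delta * v / norms)

    cp = params.cell_params
    cells = []
    for poly in shrunk:
        # per-cell RNG substream; geometry is prescribed, so no polygon window
        cell_rng = np.random.default_rng(rng.integers(2**31))
        cells.append(generate_cell_from_polygon(poly, cp, cell_rng))

    # junction bonds: nearest membrane-point pairs across shared edges
    cutoff = params.junction_cutoff_factor * params.shrink_delta
    junctions: list[JunctionBond] = []
    trees = [cKDTree(c.positions[c.kinds == "membrane"]) for c in cells]
    mem_idx = [np.flatnonzero(c.kinds == "membrane") for c in cells]
    for i in range(len(cells)):
        pts_i = cells[i].positions[mem_idx[i]]
        for j in range(i + 1, len(cells)):
            dists, nearest = trees[j].query(pts_i, distance_upper_bound=cutoff)
            hit = np.isfinite(dists)
            if not hit.any():
                continue
            used_j: set[int] = set()
            for local_i in np.flatnonzero(hit):
                nj = int(nearest[local_i])
                if nj in used_j:
                    continue
                used_j.add(nj)
                junctions.append(
                    JunctionBond(
                        cell_i=i,
                        node_i=int(mem_idx[i][local_i]),
                        cell_j=j,
                        node_j=int(mem_idx[j][nj]),
                        r0=float(dists[local_i]),
                        material=params.junction_material,
                    )
                )
    return MonolayerNetwork(
        cells=cells, junction_bonds=junctions, polygons=shrunk, params=params
    )
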