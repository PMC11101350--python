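"""Virtual multistep traction-force-microscopy (TFM) analysis.

The coupled cell–substrate solution provides an exact surface
displacement field.  The virtual experiment mimics the laboratory
pipeline step by step:

1. fluorescent strain markers are emulated by random points on the
   substrate surface, displaced by the surface field;
2. marker images can be rendered at the experimental resolution
   (0.229 μm/px, Gaussian dots of ~9 px width);
3. the displacement field is re-estimated from the markers alone by a
   least-squares fit of a coarse tensor-product cubic B-spline field on
   an 8x8 control grid — the same expressive power (and the same
   smoothing bias) as the elastic image registration used on real
   images;
4. the local area strain eps_A = lambda_1 lambda_2 - 1 = det(F) - 1 is
   evaluated per pixel from the analytic spline gradient;
5. area strains underneath the cell and in its vicinity (a region of
   ~4x the cell area around it) are each collapsed into four-bin
   histograms; the under-cell aggregate is the occurrence-weighted mean
   of the two lowest bins, the surrounding aggregate is the modal bin
   value, and their difference Delta eps_A measures cellular
   contraction on the substrate.

Because marker correspondences are known exactly in silico, the image
registration itself is bypassed: the spline field is fit directly to
the marker displacements.  The scientifically relevant distortion —
the coarse 8x8 spline smoothing — is retained, and rendered images
remain available for external cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import BSpline
from shapely.geometry import Polygon

#: Experimental image resolution, μm per pixel.
PIXEL_SIZE = 0.229
#: Marker dot diameter in pixels (full width of the Gaussian profile).
MARKER_DIAMETER_PX = 9
#: B-spline control grid used by the registration emulation.
SPLINE_GRID = 8
SPLINE_DEGREE = 3


@dataclass(frozen=True)
class Region:
    """Axis-aligned imaged window on the substrate surface (μm)."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    @property
    def extent(self) -> tuple[float, float]:
        return (self.xmax - self.xmin, self.ymax - self.ymin)

    @classmethod
    def centred(cls, size: float, centre=(0.0, 0.0)) -> "Region":
        cx, cy = centre
        h = size / 2.0
        return cls(cx - h, cy - h, cx + h, cy + h)


@dataclass
class MarkerSet:
    """Reference and displaced marker positions inside the imaged region."""

    reference: np.ndarray  # (n, 2) μm
    displaced: np.ndarray  # (n, 2) μm
    region: Region

    def __post_init__(self) -> None:
        if self.reference.shape != self.displaced.shape:
            raise ValueError("marker sets must correspond one-to-one")

    @property
    def displacements(self) -> np.ndarray:
        return self.displaced - self.reference


def seed_and_displace_markers(
    surface_closure,
    region: Region,
    n_markers: int = 1500,
    seed: int | np.random.Generator = 0,
) -> MarkerSet:
    """Seed uniform random markers in the region and displace them with
    the substrate surface field."""
    import warnings

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if n_markers < 100:
        warnings.warn(
            "fewer than 100 markers: the spline field fit will be "
            "under-determined",
            stacklevel=2,
        )
    ref = rng.uniform(
        (region.xmin, region.ymin), (region.xmax, region.ymax), size=(n_markers, 2)
    )
    disp = ref + surface_closure(ref)
    return MarkerSet(reference=ref, displaced=disp, region=region)


def render_marker_image(
    positions: np.ndarray,
    region: Region,
    pixel_size: float = PIXEL_SIZE,
    diameter_px: int = MARKER_DIAMETER_PX,
) -> np.ndarray:
    """8-bit grayscale marker image (row 0 at ymin; x along columns).

    Each marker adds a Gaussian dot whose full width spans
    ``diameter_px`` pixels; intensities are clipped at 255.
    """
    w, h = region.extent
    if w < pixel_size or h < pixel_size:
        raise ValueError("region smaller than one pixel")
    nx = math.ceil(w / pixel_size)
    ny = math.ceil(h / pixel_size)
    img = np.zeros((ny, nx), dtype=float)
    sigma = diameter_px / 4.0  # dot edge at ~2 sigma
    half = diameter_px // 2 + 2
    peak = 200.0
    for x, y in np.atleast_2d(positions):
        cx = (x - region.xmin) / pixel_size
        cy = (y - region.ymin) / pixel_size
        ix, iy = int(round(cx)), int(round(cy))
        x0, x1 = max(ix - half, 0), min(ix + half + 1, nx)
        y0, y1 = max(iy - half, 0), min(iy + half + 1, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.arange(x0, x1) - cx
        gy = np.arange(y0, y1) - cy
        img[y0:y1, x0:x1] += peak * np.exp(
            -(gx[None, :] ** 2 + gy[:, None] ** 2) / (2.0 * sigma**2)
        )
    return np.clip(img, 0.0, 255.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# B-spline displacement field
# ---------------------------------------------------------------------------


def _clamped_knots(lo: float, hi: float, n_coef: int, degree: int) -> np.ndarray:
    n_interior = n_coef - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )


@dataclass
class BSplineField:
    """Tensor-product cubic B-spline displacement field u(x, y)."""

    knots_x: np.ndarray
    knots_y: np.ndarray
    coef: np.ndarray  # (2, n_coef_x, n_coef_y): ux and uy coefficient grids
    region: Region
    degree: int = SPLINE_DEGREE
    fit_residual: float = 0.0  # RMS misfit at the markers, μm

    def _basis(self, t: np.ndarray, knots: np.ndarray, deriv: int) -> np.ndarray:
        n_coef = len(knots) - self.degree - 1
        t = np.clip(t, knots[0], knots[-1] - 1e-12 * (knots[-1] - knots[0]))
        cols = []
        for k in range(n_coef):
            c = np.zeros(n_coef)
            c[k] = 1.0
            b = BSpline(knots, c, self.degree)
            if deriv:
                b = b.derivative(deriv)
            cols.append(b(t))
        return np.column_stack(cols)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Displacements (n, 2) at arbitrary points."""
        p = np.atleast_2d(points)
        Bx = self._basis(p[:, 0], self.knots_x, 0)
        By = self._basis(p[:, 1], self.knots_y, 0)
        ux = np.einsum("ni,ij,nj->n", Bx, self.coef[0], By)
        uy = np.einsum("ni,ij,nj->n", Bx, self.coef[1], By)
        return np.column_stack([ux, uy])

    def gradient_on_grid(
        self, x: np.ndarray, y: np.ndarray
    ) -> np.ndarray:
        """Displacement gradient du_i/dx_j on the tensor grid x × y;
        returns (len(y), len(x), 2, 2) with row index = y."""
        Bx = self._basis(x, self.knots_x, 0)
        By = self._basis(y, self.knots_y, 0)
        dBx = self._basis(x, self.knots_x, 1)
        dBy = self._basis(y, self.knots_y, 1)
        out = np.empty((len(y), len(x), 2, 2))
        for comp in (0, 1):
            C = self.coef[comp]
            out[:, :, comp, 0] = (dBx @ C @ By.T).T
            out[:, :, comp, 1] = (Bx @ C @ dBy.T).T
        return out

    def evaluate_on_grid(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        Bx = self._basis(x, self.knots_x, 0)
        By = self._basis(y, self.knots_y, 0)
        out = np.empty((len(y), len(x), 2))
        for comp in (0, 1):
            out[:, :, comp] = (Bx @ self.coef[comp] @ By.T).T
        return out


def fit_displacement_field(
    markers: MarkerSet,
    n_coef: int = SPLINE_GRID,
    regularisation: float = 1e-10,
) -> BSplineField:
    """Least-squares fit of the coarse spline field to the marker
    displacements (the in-silico stand-in for elastic image
    registration).

    A tiny ridge penalty keeps the normal equations well posed when
    markers leave spline cells empty; the regularisation is raised
    automatically (with a warning) on rank deficiency.
    """
    import warnings

    n = len(markers.reference)
    if n < n_coef * n_coef:
        raise ValueError(
            f"{n} markers cannot determine {n_coef}x{n_coef} spline "
            "coefficients"
        )
    r = markers.region
    kx = _clamped_knots(r.xmin, r.xmax, n_coef, SPLINE_DEGREE)
    ky = _clamped_knots(r.ymin, r.ymax, n_coef, SPLINE_DEGREE)
    field = BSplineField(kx, ky, np.zeros((2, n_coef, n_coef)), r)
    Bx = field._basis(markers.reference[:, 0], kx, 0)
    By = field._basis(markers.reference[:, 1], ky, 0)
    A = np.einsum("ni,nj->nij", Bx, By).reshape(n, n_coef * n_coef)
    AtA = A.T @ A
    scale = np.trace(AtA) / len(AtA)
    U = markers.displacements
    lam = regularisation
    for _ in range(12):
        M = AtA + lam * scale * np.eye(len(AtA))
        try:
            sol = np.linalg.solve(M, A.T @ U)
            break
        except np.linalg.LinAlgError:
            lam *= 100.0
            warnings.warn(
                f"rank-deficient spline fit; regularisation raised to {lam}",
                stacklevel=2,
            )
    coef = sol.T.reshape(2, n_coef, n_coef)
    resid = A @ sol - U
    field.coef = coef
    field.fit_residual = float(np.sqrt(np.mean(resid**2)))
    return field


# ---------------------------------------------------------------------------
# Area strain and the Delta eps_A statistic
# ---------------------------------------------------------------------------


@dataclass
class AreaStrainMap:
    """Pixel grid of the local area strain eps_A = det(F) - 1."""

    eps_A: np.ndarray  # (ny, nx)
    valid: np.ndarray  # (ny, nx) bool; det F > 0
    x: np.ndarray  # pixel-centre coordinates, μm
    y: np.ndarray
    pixel_size: float
    cell_mask: np.ndarray | None = None
    vicinity_mask: np.ndarray | None = None


def compute_area_strain(
    field: BSplineField,
    pixel_size: float = PIXEL_SIZE,
) -> AreaStrainMap:
    """Evaluate eps_A per pixel from the analytic spline gradient.

    ``F = I + grad(u)``; ``eps_A = det F - 1``.  Pixels with
    non-positive ``det F`` (folding; cannot occur for physical fields)
    are flagged invalid and excluded from binning.
    """
    r = field.region
    w, h = r.extent
    nx = math.ceil(w / pixel_size)
    ny = math.ceil(h / pixel_size)
    x = r.xmin + (np.arange(nx) + 0.5) * pixel_size
    y = r.ymin + (np.arange(ny) + 0.5) * pixel_size
    grad = field.gradient_on_grid(x, y)
    F = grad + np.eye(2)[None, None]
    det = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    return AreaStrainMap(
        eps_A=det - 1.0,
        valid=det > 0.0,
        x=x,
        y=y,
        pixel_size=pixel_size,
    )


def attach_region_masks(
    smap: AreaStrainMap,
    cell_polygon: np.ndarray,
    vicinity_area_factor: float = 4.0,
) -> AreaStrainMap:
    """Set the under-cell and vicinity masks of an area-strain map.

    The under-cell region is the (deformed) membrane polygon; the
    vicinity is the polygon scaled about its centroid to
    ``vicinity_area_factor`` times the cell area, minus the cell
    region.
    """
    poly = Polygon(cell_polygon)
    if not poly.is_valid:
        poly = poly.buffer(0.0)
    scale = math.sqrt(vicinity_area_factor)
    cx, cy = poly.centroid.coords[0]
    outer = shapely.affinity.scale(poly, xfact=scale, yfact=scale, origin=(cx, cy))
    XX, YY = np.meshgrid(smap.x, smap.y)
    inside_cell = shapely.contains_xy(poly, XX.ravel(), YY.ravel()).reshape(XX.shape)
    inside_outer = shapely.contains_xy(outer, XX.ravel(), YY.ravel()).reshape(XX.shape)
    smap.cell_mask = inside_cell
    smap.vicinity_mask = inside_outer & ~inside_cell
    return smap


@dataclass
class TFMResult:
    """Aggregated area strains and the Delta eps_A statistic."""

    under_cell: float  # aggregated eps_A underneath the cell
    surrounding: float  # aggregated eps_A in the vicinity
    delta: float  # surrounding - under_cell (dimensionless)
    under_hist: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)
    vicinity_hist: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)

    @property
    def delta_percent(self) -> float:
        return 100.0 * self.delta


def _aggregate_bins(values: np.ndarray, bins) -> tuple[np.ndarray, np.ndarray]:
    counts, edges = np.histogram(values, bins=bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return counts, centres


def aggregate_delta_area_strain(
    smap: AreaStrainMap, n_bins: int = 4, shared_edges: bool = True
) -> TFMResult:
    """Bin the two regions' pixel strains and form Delta eps_A.

    Each region's strains are collapsed into ``n_bins`` equal-width
    bins.  The under-cell aggregate is the occurrence-weighted mean of
    the two lowest-value bin centres; the surrounding aggregate is the
    centre of the most occupied bin.  ``delta = surrounding -
    under_cell`` is positive for a cell that contracts its substrate.

    With ``shared_edges`` (default) the bins of both regions span the
    combined value range, as when both histograms are drawn on one
    axis; this makes the modal-bin read-out robust against the random
    marker choice (with per-region ranges, near-ties between adjacent
    modal bins flip with the marker set).  ``shared_edges=False``
    bins each region over its own range instead.
    """
    if smap.cell_mask is None or smap.vicinity_mask is None:
        raise ValueError("region masks not set; call attach_region_masks first")
    under_vals = smap.eps_A[smap.cell_mask & smap.valid]
    around_vals = smap.eps_A[smap.vicinity_mask & smap.valid]
    if under_vals.size == 0 or around_vals.size == 0:
        raise ValueError("empty region mask")

    if shared_edges:
        lo = min(under_vals.min(), around_vals.min())
        hi = max(under_vals.max(), around_vals.max())
        if hi - lo < 1e-12:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, n_bins + 1)
        u_counts, u_centres = _aggregate_bins(under_vals, edges)
        a_counts, a_centres = _aggregate_bins(around_vals, edges)
    else:
        u_counts, u_centres = _aggregate_bins(under_vals, n_bins)
        a_counts, a_centres = _aggregate_bins(around_vals, n_bins)

    if np.ptp(under_vals) < 1e-12:
        under = float(under_vals.mean())  # degenerate region: single value
    else:
        w = u_counts[:2]
        under = (
            float(np.average(u_centres[:2], weights=w))
            if w.sum() > 0
            else float(u_centres[0])
        )
    around = (
        float(around_vals.mean())
        if np.ptp(around_vals) < 1e-12
        else float(a_centres[np.argmax(a_counts)])
    )
    return TFMResult(
        under_cell=under,
        surrounding=around,
        delta=around - under,
        under_hist=(u_counts, u_centres),
        vicinity_hist=(a_counts, a_centres),
    )


def analyse_coupled_result(
    coupled,
    region: Region | None = None,
    n_markers: int = 1500,
    seed: int | np.random.Generator = 0,
    pixel_size: float = PIXEL_SIZE,
) -> tuple[TFMResult, AreaStrainMap, MarkerSet, BSplineField]:
    """Full virtual-TFM pipeline on a coupled equilibrium result.

    Seeds markers, fits the coarse spline field, computes the area
    strain map, masks the deformed cell outline and its vicinity, and
    aggregates Delta eps_A.
    """
    net = coupled.network
    if region is None:
        region = Region.centred(200.0)
    closure = coupled.surface_closure()
    markers = seed_and_displace_markers(closure, region, n_markers, seed)
    fld = fit_displacement_field(markers)
    smap = compute_area_strain(fld, pixel_size=pixel_size)
    mem = net.kinds == "membrane"
    deformed_outline = (net.positions + coupled.cell_state.u)[mem]
    attach_region_masks(smap, deformed_outline)
    return aggregate_delta_area_strain(smap), smap, markers, fld
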