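"""Breast-organ segmentation: air-breast boundary and chest-wall line.

The stage separates the breast from the dark air background and from
the pectoral/chest region.  The air-breast interface comes from a
classical preprocessing chain (thresholding, morphological opening and
closing, hole filling, largest connected component, boundary contour
extraction).  The chest-wall line (CWL) starts as the straight segment
between the two vertices where the tissue contour meets the chest-side
image edge and is then refined by alternating gradient-vector-flow
(GVF) snake evolution with least-squares polynomial fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, transform

from breastcad.contour import Contour, trace_boundary

__all__ = [
    "ChestWallCurve",
    "SnakeParams",
    "BreastSegConfig",
    "binarize",
    "morphological_clean",
    "extract_boundary_contour",
    "initial_chest_wall_line",
    "gvf_field",
    "refine_chest_wall",
    "segment_breast",
]


@dataclass
class SnakeParams:
    """Active-contour parameters (Xu-Prince GVF snake)."""

    alpha: float = 0.1  # tension
    beta: float = 0.05  # rigidity
    step: float = 1.0  # time step (gamma)
    kappa: float = 2.0  # external (GVF) force weight
    iterations: int = 30  # snake steps per outer iteration
    gvf_mu: float = 0.2  # GVF diffusion regularisation
    gvf_iterations: int = 80


@dataclass
class ChestWallCurve:
    """Polynomial chest-wall line: column as a function of row.

    ``poly_coeffs`` are in increasing-degree order over the raw row
    coordinate.  ``endpoints`` are the two anchor vertices (row, col)
    on the outer tissue contour; ``rows`` span the fitted range.
    """

    poly_coeffs: np.ndarray
    endpoints: tuple[tuple[float, float], tuple[float, float]]
    rows: np.ndarray
    side: str = "left"

    def columns(self, rows: np.ndarray | None = None) -> np.ndarray:
        rows = self.rows if rows is None else np.asarray(rows, dtype=float)
        return np.polynomial.polynomial.polyval(rows, self.poly_coeffs)


@dataclass
class BreastSegConfig:
    threshold: float | None = None  # None -> Otsu
    open_radius: int = 3
    close_radius: int = 5
    poly_degree: int = 3
    outer_iterations: int = 5
    snake: SnakeParams = field(default_factory=SnakeParams)


def binarize(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Foreground mask of pixels above ``threshold`` (Otsu if omitted)."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        if image.min() == image.max():
            raise ValueError("degenerate histogram: constant image")
        threshold = filters.threshold_otsu(image)
        return image > threshold
    return image >= threshold if threshold == 0 else image > threshold


def morphological_clean(
    mask: np.ndarray, open_radius: int = 3, close_radius: int = 5
) -> np.ndarray:
    """Opening, closing, hole filling, then largest connected component."""
    if open_radius < 0 or close_radius < 0:
        raise ValueError("radii must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if open_radius > 0:
        mask = morphology.opening(mask, morphology.disk(open_radius))
    if not mask.any():
        raise ValueError("no foreground component after opening")
    if close_radius > 0:
        mask = morphology.closing(mask, morphology.disk(close_radius))
    mask = ndi.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def extract_boundary_contour(mask: np.ndarray) -> Contour:
    """Closed outer boundary of a single-component mask, in order."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    n_comp = measure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"expected exactly one component, found {n_comp}")
    return trace_boundary(mask)


def _edge_contacts(contour: Contour, shape: tuple[int, int]) -> dict[str, np.ndarray]:
    pts = contour.points
    h, w = shape
    return {
        "left": pts[pts[:, 1] == 0],
        "right": pts[pts[:, 1] == w - 1],
        "top": pts[pts[:, 0] == 0],
        "bottom": pts[pts[:, 0] == h - 1],
    }


def detect_chest_side(contour: Contour, shape: tuple[int, int]) -> str:
    """Image edge with the largest tissue contact length."""
    contacts = _edge_contacts(contour, shape)
    side = max(contacts, key=lambda s: len(contacts[s]))
    if len(contacts[side]) == 0:
        raise ValueError("no chest anchors: contour never touches an image edge")
    return side


def initial_chest_wall_line(
    contour: Contour, shape: tuple[int, int], side: str | None = None
) -> Contour:
    """Straight initial CWL between the two chest-edge anchor vertices.

    The anchors are the extremal contour points lying on the chest-side
    image edge; the returned open contour is sampled at one point per
    row (or per column for top/bottom chest sides).
    """
    if not contour.closed:
        raise ValueError("expected a closed outer contour")
    side = side or detect_chest_side(contour, shape)
    contacts = _edge_contacts(contour, shape)[side]
    if len(contacts) == 0:
        raise ValueError(
            f"no chest anchors: contour never touches the {side} edge"
        )
    axis = 0 if side in ("left", "right") else 1
    lo = contacts[contacts[:, axis].argmin()]
    hi = contacts[contacts[:, axis].argmax()]
    n = int(hi[axis] - lo[axis]) + 1
    if n < 2:
        raise ValueError("chest-edge contact is degenerate (single point)")
    along = np.arange(lo[axis], hi[axis] + 1, dtype=float)
    across = np.linspace(lo[1 - axis], hi[1 - axis], n)
    pts = np.stack([along, across] if axis == 0 else [across, along], axis=1)
    return Contour(points=pts, closed=False)


def _laplacian(u: np.ndarray) -> np.ndarray:
    return (
        np.roll(u, 1, 0) + np.roll(u, -1, 0) + np.roll(u, 1, 1) + np.roll(u, -1, 1)
        - 4.0 * u
    )


def _gvf_iterate(fr, fc, u, v, mu_gvf: float, iterations: int):
    b = fr**2 + fc**2
    # Explicit diffusion, dt = 1: stable for mu_gvf <= 0.25 on the unit grid.
    for _ in range(int(iterations)):
        u = u + mu_gvf * _laplacian(u) - (u - fr) * b
        v = v + mu_gvf * _laplacian(v) - (v - fc) * b
    return u, v


def gvf_field(
    image: np.ndarray,
    mu_gvf: float = 0.2,
    iterations: int = 80,
    smooth_sigma: float = 2.0,
    levels: int | str = "auto",
) -> np.ndarray:
    """Gradient-vector-flow field of the image edge map.

    The edge map is the squared gradient magnitude of the Gaussian-
    smoothed image, normalised to [0, 1]; its gradient is diffused by
    the Xu-Prince iteration ``u_t = mu * lap(u) - (u - f_x) |grad f|^2``.

    The diffusion runs coarse-to-fine over a ``levels``-deep 2x image
    pyramid (``"auto"`` picks a depth that brings the coarsest grid to
    roughly 64 pixels): the explicit iteration's capture range grows
    only like sqrt(iterations), so plain single-grid diffusion cannot
    propagate edge information across a 512-pixel image in a sensible
    iteration budget, while each coarse level doubles the effective
    range at negligible cost.  Returns an array of shape ``(2, H, W)``:
    (row-component, col-component).
    """
    img = np.asarray(image, dtype=np.float32)
    smoothed = ndi.gaussian_filter(img, smooth_sigma)
    gr, gc = np.gradient(smoothed)
    f = gr**2 + gc**2
    fmax = f.max()
    if fmax > 0:
        # Robust normalisation: scale by a high percentile and saturate,
        # so every genuine anatomical edge carries full data weight in
        # the diffusion instead of being dwarfed by the single strongest
        # boundary (the air-skin interface on these images).
        scale = np.quantile(f, 0.99)
        if scale <= 0:
            scale = fmax
        f = np.minimum(f / scale, 1.0)

    if levels == "auto":
        levels = max(0, int(np.log2(max(min(f.shape) / 64.0, 1.0))))
    levels = int(levels)

    # Edge-map pyramid by block averaging.
    pyramid = [f]
    for _ in range(levels):
        prev = pyramid[-1]
        h, w = (prev.shape[0] // 2) * 2, (prev.shape[1] // 2) * 2
        if min(h, w) < 8:
            break
        coarse = prev[:h, :w].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
        pyramid.append(coarse)

    u = v = None
    for level in reversed(pyramid):
        fr, fc = np.gradient(level)
        if u is None:
            u, v = fr.copy(), fc.copy()
        else:
            u = transform.resize(u, level.shape, order=1, mode="edge").astype(
                np.float32
            )
            v = transform.resize(v, level.shape, order=1, mode="edge").astype(
                np.float32
            )
        u, v = _gvf_iterate(fr, fc, u, v, mu_gvf, iterations)
    return np.stack([u, v]).astype(np.float64)


def _sample_field(
    field_: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    normalize: str = "unit",
) -> np.ndarray:
    """Bilinear sample of a (2, H, W) field at float coordinates.

    ``normalize`` rescales the sampled vectors:

    - ``"unit"``: unit length (zero vectors stay zero) — the snake
      advances at a uniform rate however far the diffused field has
      decayed; right for long-range searches across flat regions.
    - ``"soft"``: saturating length ``|f| / (|f| + 0.05 max|f|)`` —
      strong edges pull with near-unit force while weak texture
      gradients stay weak; right for local refinement near a boundary.
    - ``"none"``: raw field values.
    """
    coords = np.vstack([rows, cols])
    fr = ndi.map_coordinates(field_[0], coords, order=1, mode="nearest")
    fc = ndi.map_coordinates(field_[1], coords, order=1, mode="nearest")
    out = np.stack([fr, fc], axis=1)
    if normalize == "none":
        return out
    mag = np.hypot(fr, fc)
    unit = np.where(mag > 1e-12, 1.0 / np.maximum(mag, 1e-12), 0.0)
    if normalize == "soft":
        fmax = float(np.hypot(field_[0], field_[1]).max())
        unit = unit * mag / (mag + 0.05 * fmax + 1e-30)
    return out * unit[:, None]


def _internal_matrix(n: int, alpha: float, beta: float, step: float, closed: bool) -> np.ndarray:
    """Semi-implicit snake system matrix ``I + step * (alpha D2' + beta D4')``."""
    a, b = alpha, beta
    row = np.zeros(n)
    row[0] = 2 * a + 6 * b
    row[1] = -a - 4 * b
    row[2] = b
    if closed:
        A = np.empty((n, n))
        base = np.zeros(n)
        base[:3] = row[:3]
        base[-2:] = [b, -a - 4 * b]
        for i in range(n):
            A[i] = np.roll(base, i)
    else:
        A = (
            np.diag(np.full(n, 2 * a + 6 * b))
            + np.diag(np.full(n - 1, -a - 4 * b), 1)
            + np.diag(np.full(n - 1, -a - 4 * b), -1)
            + np.diag(np.full(n - 2, b), 2)
            + np.diag(np.full(n - 2, b), -2)
        )
        # Natural boundary: reduce stiffness at the free ends.
        A[0, 0] = a + b
        A[-1, -1] = a + b
        A[1, 1] = 2 * a + 5 * b
        A[-2, -2] = 2 * a + 5 * b
    return np.eye(n) + step * A


def _robust_polyfit(
    x: np.ndarray, y: np.ndarray, degree: int, delta: float = 3.0, iters: int = 5
) -> np.ndarray:
    """Huber-weighted IRLS polynomial fit (delta in pixels)."""
    w = np.ones_like(y)
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    for _ in range(iters):
        coeffs = np.polynomial.polynomial.polyfit(x, y, degree, w=np.sqrt(w))
        resid = np.abs(y - np.polynomial.polynomial.polyval(x, coeffs))
        w = np.minimum(1.0, delta / np.maximum(resid, 1e-12))
    return coeffs


def refine_chest_wall(
    image: np.ndarray,
    init: Contour,
    snake_params: SnakeParams | None = None,
    poly_degree: int = 3,
    outer_iterations: int = 5,
    gvf: np.ndarray | None = None,
    max_col: np.ndarray | None = None,
) -> ChestWallCurve:
    """Refine an initial CWL by GVF-snake and polynomial-fit iterations.

    The snake is a column graph (one point per row): each outer
    iteration evolves the columns under internal tension/rigidity and
    the column component of the GVF force, then replaces them with a
    degree-``poly_degree`` least-squares polynomial fit, which is also
    the returned curve.

    ``max_col`` optionally bounds each snake point's column (one value
    per snake row).  The chest-wall line only exists inside tissue, so
    callers that know the foreground extent should pass its rightmost
    column per row; otherwise points at rows with little tissue can
    drift into the background, where the GVF force carries no chest-
    wall information, and drag the polynomial fit with them.
    """
    params = snake_params or SnakeParams()
    pts = np.asarray(init.points, dtype=float)
    rows = pts[:, 0]
    cols = pts[:, 1].copy()
    n = len(rows)
    if n < poly_degree + 1:
        raise ValueError("underdetermined fit: fewer snake points than degree+1")

    if gvf is None:
        gvf = gvf_field(image, params.gvf_mu, params.gvf_iterations)

    h, w = np.asarray(image).shape
    upper = np.full(n, w - 1, dtype=float) if max_col is None else np.asarray(
        max_col, dtype=float
    )

    endpoints = (tuple(pts[0]), tuple(pts[-1]))
    if outer_iterations <= 0:
        coeffs = np.polynomial.polynomial.polyfit(rows, cols, poly_degree)
        return ChestWallCurve(np.atleast_1d(coeffs), endpoints, rows)

    A = _internal_matrix(n, params.alpha, params.beta, params.step, closed=False)
    solve = np.linalg.inv(A)

    prev_fit = None
    trust = 5.0  # px: first refinement cycle's search band around the fit
    for outer in range(int(outer_iterations)):
        band = trust / max(outer, 1)  # annealed: later cycles refine locally
        for _ in range(int(params.iterations)):
            force = _sample_field(gvf, rows, cols)[:, 1]
            cols = solve @ (cols + params.step * params.kappa * force)
            np.clip(cols, 0, upper, out=cols)
            if prev_fit is not None:
                # Trust region: once a fit exists, each cycle only refines
                # locally; rows attracted by a competing edge (skin arc,
                # image border) cannot run away between fits, and the
                # shrinking band freezes the curve as iterations proceed.
                np.clip(cols, prev_fit - band, prev_fit + band, out=cols)
        if len(np.unique(rows)) < poly_degree + 1:
            raise ValueError("underdetermined fit: snake collapsed")
        # Huber-robust fit: stray rows (points caught by a competing
        # edge) are downweighted instead of bending the polynomial.
        coeffs = _robust_polyfit(rows, cols, poly_degree)
        new_fit = np.polynomial.polynomial.polyval(rows, coeffs)
        np.clip(new_fit, 0, upper, out=new_fit)
        delta = np.abs(new_fit - prev_fit) if prev_fit is not None else None
        converged = delta is not None and (
            delta.max() < 0.5 or delta.mean() < 0.3
        )
        cols = new_fit.copy()
        prev_fit = new_fit
        if converged:
            break

    return ChestWallCurve(np.atleast_1d(coeffs), endpoints, rows)


def _canonical_orientation(side: str):
    """(forward, inverse) transforms putting the chest side at the left edge."""
    if side == "left":
        fwd = inv = lambda a: a
    elif side == "right":
        fwd = inv = lambda a: a[:, ::-1]
    elif side == "top":
        fwd = inv = lambda a: a.T
    else:  # bottom: (r, c) -> (c, H-1-r)
        fwd = lambda a: a[::-1, :].T
        inv = lambda a: a.T[::-1, :]
    return fwd, inv


def segment_breast(
    image: np.ndarray, config: BreastSegConfig | None = None
) -> tuple[np.ndarray, ChestWallCurve]:
    """Full breast segmentation: preprocessing chain plus CWL refinement.

    Returns the breast mask (tissue on the breast side of the fitted
    chest-wall line, largest component, holes filled) and the fitted
    :class:`ChestWallCurve` in canonical (chest-at-left) coordinates.
    """
    cfg = config or BreastSegConfig()
    image = np.asarray(image)

    fg = binarize(image, cfg.threshold)
    fg = morphological_clean(fg, cfg.open_radius, cfg.close_radius)
    contour = extract_boundary_contour(fg)
    side = detect_chest_side(contour, fg.shape)

    fwd, inv = _canonical_orientation(side)
    img_c = np.ascontiguousarray(fwd(image))
    fg_c = np.ascontiguousarray(fwd(fg))
    contour_c = extract_boundary_contour(fg_c)

    init = initial_chest_wall_line(contour_c, fg_c.shape, side="left")
    # Rightmost tissue column per snake row bounds the chest-wall search.
    snake_rows = init.points[:, 0].astype(int)
    w_c = fg_c.shape[1]
    reach = np.where(
        fg_c[snake_rows].any(axis=1),
        w_c - 1 - np.argmax(fg_c[snake_rows, ::-1], axis=1),
        0,
    ).astype(float)
    cwl = refine_chest_wall(
        img_c,
        init,
        cfg.snake,
        poly_degree=cfg.poly_degree,
        outer_iterations=cfg.outer_iterations,
        max_col=reach,
    )
    cwl.side = side

    h, w = fg_c.shape
    rr, cc = np.mgrid[0:h, 0:w]
    fitted = cwl.columns(np.arange(h, dtype=float))
    breast_c = fg_c & (cc >= fitted[:, None])
    labels = measure.label(breast_c, connectivity=2)
    if labels.max() == 0:
        raise ValueError("chest-wall clipping removed all tissue")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    breast_c = ndi.binary_fill_holes(labels == counts.argmax())

    breast = np.ascontiguousarray(inv(breast_c))
    return breast, cwl
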