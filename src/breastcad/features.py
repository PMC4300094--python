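"""GLCM texture and morphological shape descriptors of a segmented mass.

Texture: 13 Haralick statistics of the gray-level co-occurrence matrix
(GLCM) at pixel distance 1, computed for the four directions 0, 45, 90
and 135 degrees and averaged.  Pairs are counted only when both pixels
lie inside the mask; intensities are quantised to ``levels`` bins over
the mask's own intensity range.  Logarithms are base 2 with the
``0 * log 0 = 0`` convention.

Morphology: ten descriptors of the mask alone — area, perimeter-based
compactness and circularity, extent, solidity, eccentricity and
elongation from second central moments, entropy of the normalised
radial-length distribution, spiculation (cyclic total variation of the
radial profile), and the box-counting fractal dimension of the
boundary pixel set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from breastcad.contour import contour_length, trace_boundary

__all__ = [
    "TEXTURE_NAMES",
    "MORPHOLOGY_NAMES",
    "FEATURE_NAMES",
    "GLCM_ANGLES",
    "Glcm",
    "compute_glcm",
    "haralick_features",
    "texture_features",
    "radial_length_profile",
    "morphological_features",
    "extract_features",
]

TEXTURE_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "info_measure_correlation_1",
    "info_measure_correlation_2",
)

MORPHOLOGY_NAMES = (
    "compactness",
    "spiculation",
    "extent",
    "elongation",
    "solidity",
    "circularity",
    "radial_length_entropy",
    "eccentricity",
    "area",
    "boundary_fractal_dimension",
)

FEATURE_NAMES = TEXTURE_NAMES + MORPHOLOGY_NAMES

GLCM_ANGLES = (0, 45, 90, 135)

# (row, col) displacement per direction; angles measured in the usual
# image convention (0 deg = east, positive angles counter-clockwise).
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class Glcm:
    matrix: np.ndarray  # (levels, levels) normalised, symmetric
    distance: int
    angle: int
    levels: int


def _quantize(image: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    vals = image[mask].astype(float)
    lo, hi = vals.min(), vals.max()
    q = np.zeros(image.shape, dtype=int)
    if hi > lo:
        scaled = (image.astype(float) - lo) / (hi - lo) * levels
        q = np.clip(scaled.astype(int), 0, levels - 1)
    return q


def compute_glcm(
    image: np.ndarray,
    mask: np.ndarray,
    distance: int = 1,
    angle: int = 0,
    levels: int = 32,
    region: str = "mask",
) -> Glcm:
    """Symmetric, normalised co-occurrence matrix over in-mask pairs.

    ``region="bbox"`` counts pairs over the mask's axis-aligned bounding
    box instead, including the margin tissue around the mass.
    """
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {GLCM_ANGLES}")
    if levels < 2:
        raise ValueError("levels must be at least 2")
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if region == "bbox":
        rows, cols = np.nonzero(mask)
        mask = np.zeros_like(mask)
        mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1] = True
    elif region != "mask":
        raise ValueError(f"unknown region mode {region!r}")

    q = _quantize(image, mask, levels)
    dr, dc = (d * distance for d in _OFFSETS[angle])
    h, w = mask.shape

    r0, c0 = max(0, -dr), max(0, -dc)
    r1, c1 = h - max(0, dr), w - max(0, dc)
    src = (slice(r0, r1), slice(c0, c1))
    dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))

    valid = mask[src] & mask[dst]
    if not valid.any():
        raise ValueError("empty GLCM: no valid in-mask pixel pairs")
    i = q[src][valid]
    j = q[dst][valid]

    mat = np.zeros((levels, levels), dtype=float)
    np.add.at(mat, (i, j), 1.0)
    np.add.at(mat, (j, i), 1.0)  # symmetric accumulation
    mat /= mat.sum()
    return Glcm(matrix=mat, distance=distance, angle=angle, levels=levels)


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 log 0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_features(glcm: Glcm) -> dict[str, float]:
    """The 13 Haralick statistics of a normalised GLCM.

    Indices are the 0-based quantisation bins.  ``difference_variance``
    is the variance of the difference distribution p_{|i-j|};
    ``sum_variance`` is the variance of p_{i+j} about the sum average.
    """
    p = np.asarray(glcm.matrix, dtype=float)
    L = glcm.levels
    i = np.arange(L, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    # Sum and difference distributions.
    ksum = np.arange(2 * L - 1, dtype=float)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    kdiff = np.arange(L, dtype=float)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((ksum * p_sum).sum())
    sum_var = float(((ksum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = float(-_xlog2(p_sum).sum())
    entropy = float(-_xlog2(p).sum())
    diff_avg = float((kdiff * p_diff).sum())
    diff_var = float(((kdiff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = float(-_xlog2(p_diff).sum())

    hxy = entropy
    pxy = px[:, None] * py[None, :]
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    hxy2 = float(-_xlog2(pxy).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    values = (
        asm, contrast, correlation, idm, sum_avg, sum_var, sum_ent,
        entropy, diff_avg, diff_var, diff_ent, imc1, imc2,
    )
    return dict(zip(TEXTURE_NAMES, values))


def texture_features(
    image: np.ndarray,
    mask: np.ndarray,
    distance: int = 1,
    levels: int = 32,
) -> dict[str, float]:
    """Haralick features averaged over the four standard directions."""
    per_angle = [
        haralick_features(compute_glcm(image, mask, distance, a, levels))
        for a in GLCM_ANGLES
    ]
    return {
        name: float(np.mean([f[name] for f in per_angle]))
        for name in TEXTURE_NAMES
    }


def radial_length_profile(mask: np.ndarray) -> np.ndarray:
    """Normalised centroid-to-boundary distances ordered by polar angle."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    contour = trace_boundary(mask)
    rows, cols = np.nonzero(mask)
    centroid = (rows.mean(), cols.mean())
    dr = contour.rows - centroid[0]
    dc = contour.cols - centroid[1]
    dist = np.hypot(dr, dc)
    angle = np.arctan2(dr, dc)
    order = np.argsort(angle)
    profile = dist[order]
    mx = profile.max()
    if mx <= 0:
        raise ValueError("degenerate boundary: zero radial extent")
    return profile / mx


def _box_counting_dimension(
    boundary_rows: np.ndarray, boundary_cols: np.ndarray,
    sizes: tuple[int, ...] = (2, 4, 8, 16, 32),
) -> float:
    """Box-counting slope of log N(s) against log(1/s)."""
    r = boundary_rows - boundary_rows.min()
    c = boundary_cols - boundary_cols.min()
    counts = []
    for s in sizes:
        boxes = {(int(rr // s), int(cc // s)) for rr, cc in zip(r, c)}
        counts.append(len(boxes))
    logs = np.log(1.0 / np.asarray(sizes, dtype=float))
    logn = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(logs, logn, 1)[0]
    return float(slope)


def morphological_features(mask: np.ndarray) -> dict[str, float]:
    """Ten shape descriptors of a single-component mask (area >= 30 px)."""
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area < 30:
        raise ValueError("mask too small: need at least 30 pixels")
    labels = measure.label(mask, connectivity=2)
    if labels.max() != 1:
        raise ValueError("mask must be a single connected component")

    contour = trace_boundary(mask)
    perimeter = contour_length(contour)
    compactness = perimeter**2 / (4.0 * np.pi * area)
    circularity = min(1.0, 4.0 * np.pi * area / perimeter**2)

    props = measure.regionprops(labels.astype(int))[0]
    extent = float(props.extent)
    solidity = float(props.solidity)
    major = props.axis_major_length
    minor = props.axis_minor_length
    if major <= 0:
        raise ValueError("degenerate moments: zero major axis")
    eccentricity = float(props.eccentricity)
    elongation = float(1.0 - minor / major)

    profile = radial_length_profile(mask)
    hist, _ = np.histogram(profile, bins=10, range=(0.0, 1.0))
    pk = hist / hist.sum()
    radial_entropy = float(-_xlog2(pk).sum() / np.log2(10))

    d = profile
    spiculation = float(np.abs(np.diff(np.concatenate([d, d[:1]]))).sum() / d.sum())

    fractal = _box_counting_dimension(
        contour.rows.astype(int), contour.cols.astype(int)
    )

    values = (
        compactness, spiculation, extent, elongation, solidity,
        circularity, radial_entropy, eccentricity, float(area), fractal,
    )
    return dict(zip(MORPHOLOGY_NAMES, values))


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    distance: int = 1,
    levels: int = 32,
) -> dict[str, float]:
    """Full 23-value feature vector (13 texture + 10 morphology)."""
    out = texture_features(image, mask, distance, levels)
    out.update(morphological_features(mask))
    return {name: out[name] for name in FEATURE_NAMES}
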