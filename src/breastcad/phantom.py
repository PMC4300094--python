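"""Seeded synthetic sagittal-breast MR phantoms with exact ground truth.

Each phantom emulates a single postcontrast sagittal slice: dark air,
a pectoral/chest band along one image edge, a bright breast bulge
bounded by a cubic chest-wall curve, and one contrast-enhanced mass.
Benign masses have near-elliptical boundaries and mild internal
heterogeneity; malignant masses are spiculated (high-order, high-
amplitude radial harmonics) with stronger heterogeneity.  Ground-truth
masks are the exact pre-noise geometry, so they are independent of the
noise level.

Cohorts are reproducible from ``(n_benign, n_malignant, seed)`` alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "CaseRecord",
    "benign_spec",
    "malignant_spec",
    "generate_case",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic case.

    Intensities are 8-bit gray levels and must satisfy
    ``air < chest < breast < mass`` so that thresholding separates air
    from tissue and the enhancing mass is the brightest structure, as in
    a postcontrast acquisition.

    The mass boundary is ``r(theta) = r0 * (1 + sum a_k cos(k theta + phi_k))``
    with one ``(order, amplitude, phase)`` triple per harmonic.  The
    chest-wall curve is a polynomial ``col(t)`` in the normalised row
    coordinate ``t in [-1, 1]`` spanning the breast rows.
    """

    image_size: int = 512
    air_intensity: float = 10.0
    chest_intensity: float = 90.0
    breast_intensity: float = 140.0
    mass_intensity: float = 220.0
    noise_sigma: float = 5.0
    psf_sigma: float = 1.2  # acquisition point-spread blur (pixels)
    mass_radius: float = 22.0
    mass_center: tuple[float, float] | None = None  # (row, col); auto if None
    boundary_harmonics: tuple[tuple[int, float, float], ...] = ()
    core_dip: float = 0.0  # rim enhancement: gray-level dip at the centre
    heterogeneity_sigma: float = 8.0
    heterogeneity_scale: float = 3.0
    parenchyma_sigma: float = 18.0  # fibroglandular texture amplitude
    parenchyma_scale: float = 6.0  # its correlation length (pixels)
    retromammary_gap: float = 25.0  # smooth (fat) band anterior to the wall
    chest_wall_coeffs: tuple[float, ...] = (60.0, 8.0, -7.0, 3.0)
    breast_row_span: tuple[float, float] = (0.14, 0.86)  # fractions of height
    breast_depth: float = 0.58  # outer-bulge depth, fraction of width
    label: str = "benign"
    seed: int = 0

    def validate(self) -> None:
        levels = (
            self.air_intensity,
            self.chest_intensity,
            self.breast_intensity,
            self.mass_intensity,
        )
        if not all(0 <= v <= 255 for v in levels):
            raise ValueError("intensities must lie in [0, 255]")
        if not (
            self.air_intensity
            < self.chest_intensity
            < self.breast_intensity
            < self.mass_intensity
        ):
            raise ValueError(
                "intensity ordering air < chest < breast < mass violated"
            )
        if self.label not in ("benign", "malignant"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.mass_radius <= 0:
            raise ValueError("mass_radius must be positive")
        if self.noise_sigma < 0 or self.heterogeneity_sigma < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class CaseRecord:
    """One phantom case: image, exact masks, class label, provenance."""

    case_id: str
    image: np.ndarray  # uint8 (H, W)
    breast_mask: np.ndarray  # bool (H, W)
    mass_mask: np.ndarray  # bool (H, W)
    label: str
    seed: int
    spec: PhantomSpec | None = None


def benign_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Preset: near-elliptical, mildly heterogeneous mass."""
    spec = PhantomSpec(
        boundary_harmonics=((2, 0.05, 0.4), (3, 0.03, 1.1)),
        heterogeneity_sigma=8.0,
        core_dip=10.0,
        label="benign",
        seed=seed,
    )
    return replace(spec, **overrides)


def malignant_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Preset: spiculated boundary, strong internal heterogeneity."""
    spec = PhantomSpec(
        boundary_harmonics=(
            (5, 0.14, 0.0),
            (7, 0.12, 1.9),
            (9, 0.09, 0.7),
        ),
        heterogeneity_sigma=16.0,
        core_dip=40.0,
        label="malignant",
        seed=seed,
    )
    return replace(spec, **overrides)


def _breast_geometry(spec: PhantomSpec):
    """Foreground (tissue), chest and breast masks from the spec geometry.

    The pectoral/chest band spans the full image height along the
    chest-side (left) edge, bounded by the chest-wall polynomial; the
    breast is the part of an elliptical anterior bulge on the breast
    side of that curve, as in a sagittal view with the breast hanging
    into the coil.
    """
    n = spec.image_size
    rr, cc = np.mgrid[0:n, 0:n].astype(float)

    r_top = spec.breast_row_span[0] * n
    r_bot = spec.breast_row_span[1] * n
    rc = 0.5 * (r_top + r_bot)
    a_r = 0.5 * (r_bot - r_top)  # vertical semi-axis of the bulge
    a_c = spec.breast_depth * n  # bulge depth (cols)

    t = (rr[:, 0] - rc) / a_r  # normalised row coordinate per row
    cw_cols = np.polynomial.polynomial.polyval(t, spec.chest_wall_coeffs)
    if cw_cols.min() < 2 or cw_cols.max() > 0.9 * n:
        raise ValueError("chest_wall_coeffs leave the image over the row span")

    bulge = ((rr - rc) / a_r) ** 2 + (cc / a_c) ** 2 <= 1.0
    chest = cc < cw_cols[:, None]
    breast = bulge & ~chest
    tissue = chest | breast
    return tissue, chest, breast, cw_cols


def chest_wall_columns(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth chest-wall column per image row (NaN outside tissue)."""
    n = spec.image_size
    tissue, _, breast, cw_cols = _breast_geometry(spec)
    out = np.full(n, np.nan)
    has_breast = breast.any(axis=1)
    out[has_breast] = cw_cols[has_breast]
    return out


def _mass_mask(spec: PhantomSpec, center: tuple[float, float]):
    """Mass mask and relative radial coordinate rho / r(theta) in [0, 1]."""
    n = spec.image_size
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    radius = np.full_like(theta, spec.mass_radius)
    for order, amp, phase in spec.boundary_harmonics:
        radius += spec.mass_radius * amp * np.cos(order * theta + phase)
    radius = np.maximum(radius, 1e-6)
    return rho <= radius, np.minimum(rho / radius, 1.0)


def _default_mass_center(spec: PhantomSpec) -> tuple[float, float]:
    n = spec.image_size
    r_top, r_bot = (f * n for f in spec.breast_row_span)
    rc = 0.5 * (r_top + r_bot)
    t0 = 0.0
    cw0 = float(np.polynomial.polynomial.polyval(t0, spec.chest_wall_coeffs))
    depth = spec.breast_depth * n
    return (rc, cw0 + 0.45 * (depth - cw0))


def generate_case(spec: PhantomSpec, case_id: str = "case0000") -> CaseRecord:
    """Render one phantom case with exact ground-truth masks.

    The image is the noise-free geometry plus a spatially correlated
    heterogeneity field inside the mass and additive Gaussian noise
    everywhere, clipped to [0, 255] and quantised to 8 bits.  Masks are
    the exact pre-noise geometry.

    Raises
    ------
    ValueError
        If the spec violates its invariants or the mass does not fit
        entirely inside the breast region.
    """
    spec.validate()
    tissue, chest, breast, _ = _breast_geometry(spec)

    center = spec.mass_center or _default_mass_center(spec)
    mass, rel_radius = _mass_mask(spec, center)
    if not mass.any():
        raise ValueError("mass specification produced an empty mask")
    if (mass & ~breast).any():
        raise ValueError(
            "mass does not fit inside the breast region; shrink mass_radius "
            "or move mass_center"
        )

    img = np.full(tissue.shape, spec.air_intensity, dtype=float)
    img[chest] = spec.chest_intensity
    img[breast] = spec.breast_intensity
    img[mass] = spec.mass_intensity
    if spec.core_dip > 0:
        # Rim enhancement: contrast uptake is strongest at the mass
        # periphery; the interior dips smoothly toward the centre.
        img[mass] -= spec.core_dip * (1.0 - rel_radius[mass] ** 2)

    rng = np.random.default_rng(spec.seed)
    het_rng, tex_rng, noise_rng = rng.spawn(3)

    if spec.parenchyma_sigma > 0:
        # Fibroglandular texture: correlated field over the breast tissue,
        # tapered to zero across the retromammary (fat) gap so the
        # pectoral boundary stays the dominant edge, as in real anatomy.
        tex = gaussian_filter(
            tex_rng.standard_normal(tissue.shape), spec.parenchyma_scale
        )
        _, _, _, cw_cols = _breast_geometry(spec)
        cc = np.arange(spec.image_size, dtype=float)[None, :]
        dist_to_wall = cc - cw_cols[:, None]
        taper = np.clip(dist_to_wall / max(spec.retromammary_gap, 1e-9), 0.0, 1.0)
        breast_only = breast & ~mass
        vals = tex[breast_only]
        sd = vals.std()
        if sd > 0:
            img[breast_only] += (
                (vals - vals.mean()) / sd
                * spec.parenchyma_sigma
                * taper[breast_only]
            )
    else:
        tex_rng.standard_normal(tissue.shape)

    if spec.heterogeneity_sigma > 0:
        field_ = het_rng.standard_normal(tissue.shape)
        field_ = gaussian_filter(field_, spec.heterogeneity_scale)
        inside = field_[mass]
        sd = inside.std()
        if sd > 0:
            img[mass] += (inside - inside.mean()) / sd * spec.heterogeneity_sigma
    else:
        # Keep the random stream layout identical across specs.
        het_rng.standard_normal(tissue.shape)

    if spec.psf_sigma > 0:
        # Acquisition point-spread function: partial-volume mixing at
        # every tissue interface, applied before the (post-detection)
        # noise.
        img = gaussian_filter(img, spec.psf_sigma)

    if spec.noise_sigma > 0:
        img += noise_rng.normal(0.0, spec.noise_sigma, size=tissue.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return CaseRecord(
        case_id=case_id,
        image=img,
        breast_mask=breast,
        mass_mask=mass,
        label=spec.label,
        seed=spec.seed,
        spec=spec,
    )


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    seed: int,
    preset_overrides: dict | None = None,
) -> list[CaseRecord]:
    """Generate a reproducible cohort with within-class variation.

    Per-case seeds and geometry jitter (mass radius, centre, harmonic
    amplitudes/phases, chest-wall shape) derive deterministically from
    the cohort seed, so identical arguments give bit-identical cohorts.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("case counts must be non-negative")
    preset_overrides = preset_overrides or {}

    rng = np.random.default_rng(seed)
    cases: list[CaseRecord] = []
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    for i, label in enumerate(labels):
        case_seed = int(rng.integers(0, 2**31 - 1))
        jitter = np.random.default_rng(case_seed)
        base = benign_spec(case_seed) if label == "benign" else malignant_spec(case_seed)

        radius = float(jitter.uniform(14.0, 30.0))
        harmonics = tuple(
            (order, amp * float(jitter.uniform(0.7, 1.3)), float(jitter.uniform(0, 2 * np.pi)))
            for order, amp, _ in base.boundary_harmonics
        )
        cw = tuple(
            c * float(jitter.uniform(0.85, 1.15)) for c in base.chest_wall_coeffs
        )
        n = base.image_size
        row0, col0 = _default_mass_center(replace(base, chest_wall_coeffs=cw))
        center = (
            row0 + float(jitter.uniform(-0.08, 0.08)) * n,
            col0 + float(jitter.uniform(-0.05, 0.05)) * n,
        )
        spec = replace(
            base,
            mass_radius=radius,
            boundary_harmonics=harmonics,
            chest_wall_coeffs=cw,
            mass_center=center,
            **preset_overrides,
        )
        cases.append(generate_case(spec, case_id=f"case{i:04d}"))
    return cases


def _write_png(path: Path, array: np.ndarray) -> None:
    Image.fromarray(array).save(path)


def save_cohort(cases: Iterable[CaseRecord], out_dir: str | Path) -> Path:
    """Write images, masks (0/255 PNG) and a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    spec_cols = (
        "image_size", "mass_radius", "noise_sigma", "psf_sigma",
        "heterogeneity_sigma", "parenchyma_sigma", "core_dip",
        "mass_intensity", "breast_intensity", "chest_intensity",
        "air_intensity",
    )
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "label", "seed", *spec_cols])
        for case in cases:
            _write_png(out / f"{case.case_id}.png", case.image)
            _write_png(
                out / f"{case.case_id}.mass.png",
                (case.mass_mask.astype(np.uint8) * 255),
            )
            _write_png(
                out / f"{case.case_id}.breast.png",
                (case.breast_mask.astype(np.uint8) * 255),
            )
            extra = [
                getattr(case.spec, c) if case.spec is not None else ""
                for c in spec_cols
            ]
            writer.writerow([case.case_id, case.label, case.seed, *extra])
    return manifest


def load_cohort(manifest: str | Path) -> list[CaseRecord]:
    """Read a cohort previously written by :func:`save_cohort`."""
    manifest = Path(manifest)
    root = manifest.parent
    cases = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            cid = row["case_id"]
            image = np.asarray(Image.open(root / f"{cid}.png"))
            mass = np.asarray(Image.open(root / f"{cid}.mass.png")) > 127
            breast = np.asarray(Image.open(root / f"{cid}.breast.png")) > 127
            cases.append(
                CaseRecord(
                    case_id=cid,
                    image=image,
                    breast_mask=breast,
                    mass_mask=mass,
                    label=row["label"],
                    seed=int(row["seed"]),
                )
            )
    return cases
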