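"""Synthetic axial-slice phantoms with exact fat-content ground truth.

A phantom emulates the quantity the measurement pipeline estimates on a real
axial T2-weighted slice: each muscle region is a set of pixels, a known
fraction of which carry the (bright) fat intensity and the rest the (darker)
lean-muscle intensity. The clean two-class image is then degraded the way MRI
degrades it — multiplied by a smooth quadratic bias surface (coil shading)
and perturbed with additive Gaussian noise — while the pre-degradation truth
(which pixels are fat) is recorded. That makes recovery of the true fat
fraction by the composition module exactly checkable.

The default layout mimics an L4-level slice: an elliptical posterior
paraspinal (PPM) region and an elliptical psoas region on each side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .composition import (
    RoiMask,
    SliceImage,
    evaluate_quadratic_surface,
    normalized_coordinates,
)

__all__ = [
    "EllipseRegion",
    "PhantomSpec",
    "PhantomSlice",
    "default_spec",
    "generate_phantom",
    "evaluate_bias_surface",
    "write_phantom",
    "read_truth",
]

IDENTITY_BIAS = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def evaluate_bias_surface(coefficients, x, y):
    """Quadratic surface c00 + c10 x + c01 y + c20 x^2 + c11 xy + c02 y^2.

    Coordinates follow the normalized [-1, 1]^2 convention over the image.
    """
    return evaluate_quadratic_surface(coefficients, x, y)


@dataclass(frozen=True)
class EllipseRegion:
    """Elliptical muscle footprint in pixel coordinates (row/col center, semi-axes)."""

    muscle: str
    side: str
    center_rc: tuple[float, float]
    semi_axes_rc: tuple[float, float]

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        cr, ccn = self.center_rc
        ar, ac = self.semi_axes_rc
        return ((rr - cr) / ar) ** 2 + ((cc - ccn) / ac) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one phantom slice deterministically.

    true_fat_fraction maps each (muscle, side) region to its ground-truth
    fat fraction in [0, 1]. ``deterministic_counts=True`` (default) places
    exactly round(f * N) fat pixels at seeded positions so the truth
    fraction is exact; False draws each pixel Bernoulli(f).
    """

    image_height_px: int = 128
    image_width_px: int = 128
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    regions: tuple[EllipseRegion, ...] = ()
    true_fat_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    mu_muscle: float = 100.0
    mu_fat: float = 140.0
    noise_sd: float = 0.0
    bias_coefficients: tuple[float, float, float, float, float, float] = IDENTITY_BIAS
    deterministic_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")
        if self.mu_fat <= self.mu_muscle:
            raise ValueError("mu_fat must exceed mu_muscle")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        bad = {k: v for k, v in self.true_fat_fraction.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"fat fractions outside [0, 1]: {bad}")


@dataclass(frozen=True)
class PhantomSlice:
    """A generated phantom: degraded image, masks, and pre-degradation truth."""

    image: SliceImage
    masks: RoiMask
    truth_fat_mask: np.ndarray
    truth_fat_fraction: dict[tuple[str, str], float]
    applied_bias: tuple[float, float, float, float, float, float]
    seed: int


def default_spec(**overrides) -> PhantomSpec:
    """An L4-like layout: bilateral elliptical PPM and psoas regions.

    PPM ellipses sit posteriorly (lower half of the grid), psoas ellipses
    anteriorly near the midline; a fixture convention, not anatomy.
    """
    h = overrides.get("image_height_px", 128)
    w = overrides.get("image_width_px", 128)
    regions = (
        EllipseRegion("PPM", "left", (0.72 * h, 0.32 * w), (0.14 * h, 0.13 * w)),
        EllipseRegion("PPM", "right", (0.72 * h, 0.68 * w), (0.14 * h, 0.13 * w)),
        EllipseRegion("psoas", "left", (0.42 * h, 0.38 * w), (0.10 * h, 0.07 * w)),
        EllipseRegion("psoas", "right", (0.42 * h, 0.62 * w), (0.10 * h, 0.07 * w)),
    )
    fractions = {
        ("PPM", "left"): 0.40,
        ("PPM", "right"): 0.40,
        ("psoas", "left"): 0.05,
        ("psoas", "right"): 0.05,
    }
    spec = PhantomSpec(regions=regions, true_fat_fraction=fractions)
    return replace(spec, **overrides)


def _region_masks(spec: PhantomSpec) -> dict[tuple[str, str], np.ndarray]:
    shape = (spec.image_height_px, spec.image_width_px)
    masks: dict[tuple[str, str], np.ndarray] = {}
    occupied = np.zeros(shape, dtype=bool)
    for region in spec.regions:
        m = region.rasterize(shape)
        overlap = occupied & m
        if overlap.any():
            raise ValueError(
                f"region ({region.muscle}, {region.side}) overlaps a previous region"
            )
        occupied |= m
        masks[(region.muscle, region.side)] = m
    return masks


def generate_phantom(spec: PhantomSpec) -> PhantomSlice:
    """Generate a phantom slice from a spec; identical spec+seed is bit-identical.

    Per region: assign fat pixels (deterministic count round(f*N) at seeded
    positions, or Bernoulli(f) per pixel), set clean intensities to the class
    means, multiply the whole image by the quadratic bias surface, then add
    Gaussian noise. The truth mask is recorded before bias and noise.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_height_px, spec.image_width_px)
    region_masks = _region_masks(spec)

    missing = set(region_masks) - set(spec.true_fat_fraction)
    if missing:
        raise ValueError(f"regions without a true_fat_fraction: {sorted(missing)}")

    clean = np.zeros(shape, dtype=float)
    truth_fat = np.zeros(shape, dtype=bool)
    truth_fraction: dict[tuple[str, str], float] = {}
    labels = np.zeros(shape, dtype=np.int32)
    label_table: dict[int, tuple[str, str]] = {}

    for i, (key, mask) in enumerate(region_masks.items(), start=1):
        labels[mask] = i
        label_table[i] = key
        f = spec.true_fat_fraction[key]
        idx = np.flatnonzero(mask.ravel())
        n = idx.size
        if spec.deterministic_counts:
            n_fat = int(round(f * n))
            fat_idx = rng.choice(idx, size=n_fat, replace=False)
        else:
            fat_idx = idx[rng.random(n) < f]
        flat_fat = np.zeros(clean.size, dtype=bool)
        flat_fat[fat_idx] = True
        region_fat = flat_fat.reshape(shape)
        truth_fat |= region_fat
        truth_fraction[key] = float(region_fat.sum() / n)
        clean[mask] = spec.mu_muscle
        clean[region_fat] = spec.mu_fat

    xg, yg = normalized_coordinates(shape)
    surface = evaluate_bias_surface(spec.bias_coefficients, xg, yg)
    if np.any(surface <= 0):
        raise ValueError("bias surface must be positive over the image")
    image = clean * surface
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)

    return PhantomSlice(
        image=SliceImage(image, spec.pixel_spacing_mm),
        masks=RoiMask(labels, label_table),
        truth_fat_mask=truth_fat,
        truth_fat_fraction=truth_fraction,
        applied_bias=spec.bias_coefficients,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_phantom(phantom: PhantomSlice, out_dir: str | Path, fmt: str = "nifti") -> dict:
    """Write image + mask (NIfTI or CSV), label table and a JSON truth sidecar.

    Returns the paths written, keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        import nibabel as nib

        sr, sc = phantom.image.pixel_spacing_mm
        affine = np.diag([sr, sc, 1.0, 1.0])
        img_path = out / "image.nii"
        mask_path = out / "mask.nii"
        nib.save(nib.Nifti1Image(phantom.image.intensities, affine), str(img_path))
        nib.save(
            nib.Nifti1Image(phantom.masks.labels.astype(np.int16), affine),
            str(mask_path),
        )
    elif fmt == "csv":
        img_path = out / "image.csv"
        mask_path = out / "mask.csv"
        np.savetxt(img_path, phantom.image.intensities, delimiter=",")
        np.savetxt(mask_path, phantom.masks.labels, fmt="%d", delimiter=",")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'nifti' or 'csv'")

    labels_path = out / "labels.json"
    with open(labels_path, "w") as fh:
        json.dump(
            {
                str(lbl): {"muscle": m, "side": s}
                for lbl, (m, s) in phantom.masks.label_table.items()
            },
            fh,
            indent=2,
        )
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "seed": phantom.seed,
                "applied_bias": list(phantom.applied_bias),
                "pixel_spacing_mm": list(phantom.image.pixel_spacing_mm),
                "truth_fat_fraction": {
                    f"{m}/{s}": v for (m, s), v in phantom.truth_fat_fraction.items()
                },
            },
            fh,
            indent=2,
        )
    return {
        "image": img_path,
        "mask": mask_path,
        "labels": labels_path,
        "truth": truth_path,
    }


def read_truth(path: str | Path) -> dict[tuple[str, str], float]:
    """Read the truth sidecar back as a {(muscle, side): fraction} dict."""
    with open(path) as fh:
        data = json.load(fh)
    out = {}
    for key, v in data["truth_fat_fraction"].items():
        muscle, side = key.split("/")
        out[(muscle, side)] = float(v)
    return out
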