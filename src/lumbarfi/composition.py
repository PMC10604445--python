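"""Muscle composition from a single axial MRI slice.

The quantification core: given a T2-weighted-like axial slice and a labeled
region-of-interest mask for each muscle (psoas and the posterior paraspinal
muscles, per side), classify every in-region pixel as fat or lean muscle with
an automatically selected intensity threshold, after correcting the smooth
multiplicative intensity inhomogeneity (coil shading) with an iteratively
fitted 2-D quadratic surface. From the classified pixels:

    CSA  = total region area          (cm^2)
    FAT  = fat-classified area        (cm^2)
    fCSA = CSA - FAT                  (cm^2, lean "functional" area)
    FI   = 100 * FAT / CSA            (%, fat infiltration)

Left and right sides are summed per muscle and areas are normalized by the
patient's height squared (cm^2/m^2). Lumbar lordosis enters as the Cobb angle
between the superior endplates of L1 and S1, computed from landmark
coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SliceImage",
    "RoiMask",
    "BiasModel",
    "MuscleComposition",
    "NormalizedComposition",
    "EndplateLandmarks",
    "MeasureConfig",
    "evaluate_quadratic_surface",
    "normalized_coordinates",
    "select_threshold",
    "classify_pixels",
    "fit_bias_field",
    "measure_muscle",
    "measure_all",
    "combine_sides",
    "normalize_by_height",
    "cobb_angle",
    "DegenerateHistogramError",
    "read_slice",
    "read_mask",
    "write_composition_rows",
]

MUSCLES = ("psoas", "PPM")
SIDES = ("left", "right")


class DegenerateHistogramError(ValueError):
    """Raised when a threshold is requested for a single-valued sample."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SliceImage:
    """A 2-D intensity grid with physical pixel spacing in millimetres."""

    intensities: np.ndarray
    pixel_spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 2-D grid")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(
            self, "pixel_spacing_mm", tuple(float(s) for s in self.pixel_spacing_mm)
        )

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1]


@dataclass(frozen=True)
class RoiMask:
    """Integer label grid aligned to a slice plus the label semantics.

    ``label_table`` maps each nonzero label to ``(muscle, side)`` with muscle
    in {"psoas", "PPM"} and side in {"left", "right"}.
    """

    labels: np.ndarray
    label_table: Mapping[int, tuple[str, str]]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(int)
        object.__setattr__(self, "labels", lab)
        present = set(np.unique(lab)) - {0}
        missing = present - set(int(k) for k in self.label_table)
        if missing:
            raise ValueError(f"labels missing from label_table: {sorted(missing)}")
        for lbl, (muscle, side) in self.label_table.items():
            if muscle not in MUSCLES or side not in SIDES:
                raise ValueError(f"bad label table entry {lbl}: ({muscle}, {side})")

    def pixels(self, label: int) -> np.ndarray:
        return np.argwhere(self.labels == label)

    def find(self, muscle: str, side: str) -> int:
        for lbl, (m, s) in self.label_table.items():
            if m == muscle and s == side:
                return int(lbl)
        raise KeyError(f"no label for ({muscle}, {side})")


@dataclass(frozen=True)
class BiasModel:
    """A fitted 2-D quadratic intensity surface.

    coefficients order: (c00, c10, c01, c20, c11, c02) for
    ``c00 + c10*x + c01*y + c20*x^2 + c11*x*y + c02*y^2`` with x, y the
    column/row coordinates normalized to [-1, 1] over the image extent.
    """

    coefficients: tuple[float, float, float, float, float, float]
    coordinate_convention: str = "normalized_unit_square"
    fit_iterations: int = 0
    converged: bool = True

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return evaluate_quadratic_surface(self.coefficients, x, y)


@dataclass(frozen=True)
class MuscleComposition:
    """CSA/fCSA/FAT areas (cm^2) and fat infiltration FI (%) of one region."""

    muscle: str
    side: str
    CSA: float
    fCSA: float
    FAT: float
    FI: float
    threshold_used: float
    n_pixels: int
    single_tissue: bool = False

    def __post_init__(self) -> None:
        if not np.isclose(self.CSA, self.fCSA + self.FAT, rtol=0, atol=1e-9):
            raise ValueError("CSA must equal fCSA + FAT")
        if not (0.0 <= self.FI <= 100.0):
            raise ValueError("FI must lie in [0, 100]")


@dataclass(frozen=True)
class NormalizedComposition:
    """Bilateral areas divided by height^2 (cm^2/m^2); FI is unchanged."""

    muscle: str
    CSA: float
    fCSA: float
    FAT: float
    FI: float
    height_m: float


@dataclass(frozen=True)
class EndplateLandmarks:
    """Two points on the superior endplate of L1 and two on that of S1."""

    L1_superior: tuple[tuple[float, float], tuple[float, float]]
    S1_superior: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (p, q) in (("L1", self.L1_superior), ("S1", self.S1_superior)):
            if np.allclose(p, q):
                raise ValueError(f"{name} endplate landmarks coincide")


@dataclass(frozen=True)
class MeasureConfig:
    """Knobs of the per-region measurement pipeline.

    bias_correction
        Apply the iterative quadratic bias-field correction before
        thresholding. Off, the threshold is taken on raw intensities.
    max_iterations / threshold_tolerance
        Stopping rule of the coupled correct-and-threshold loop: stop when
        the automatic threshold moves by less than ``threshold_tolerance``
        times the corrected intensity range, or after ``max_iterations``.
    """

    bias_correction: bool = True
    max_iterations: int = 25
    threshold_tolerance: float = 1e-6


# ---------------------------------------------------------------------------
# Quadratic surface
# ---------------------------------------------------------------------------


def evaluate_quadratic_surface(
    coefficients: Iterable[float], x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Evaluate c00 + c10 x + c01 y + c20 x^2 + c11 xy + c02 y^2."""
    c00, c10, c01, c20, c11, c02 = (float(c) for c in coefficients)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return c00 + c10 * x + c01 * y + c20 * x * x + c11 * x * y + c02 * y * y


def normalized_coordinates(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (x, y) grids mapped to [-1, 1] over the image extent.

    x runs along columns, y along rows. A single-row or single-column image
    maps to coordinate 0 on the degenerate axis.
    """
    nrow, ncol = shape
    y = np.linspace(-1.0, 1.0, nrow) if nrow > 1 else np.zeros(1)
    x = np.linspace(-1.0, 1.0, ncol) if ncol > 1 else np.zeros(1)
    xg, yg = np.meshgrid(x, y)
    return xg, yg


def _design_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(x), x, y, x * x, x * y, y * y]
    )


# ---------------------------------------------------------------------------
# Thresholding and classification
# ---------------------------------------------------------------------------


def select_threshold(intensities: np.ndarray) -> float:
    """Automatic fat/muscle threshold by Otsu's criterion on the raw values.

    Maximizes the between-class variance over every cut between consecutive
    distinct values of the sample (no histogram binning), and returns the
    midpoint of the optimal cut — strictly between the sample min and max.

    Raises
    ------
    DegenerateHistogramError
        If all values are identical (no two-class structure).
    """
    v = np.sort(np.asarray(intensities, dtype=float).ravel())
    if v.size < 2 or v[0] == v[-1]:
        raise DegenerateHistogramError(
            "threshold selection needs at least two distinct intensity values"
        )
    n = v.size
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)  # lower class sizes for cuts between v[k-1] and v[k]
    mu_lo = csum[:-1] / k
    mu_hi = (total - csum[:-1]) / (n - k)
    between = k * (n - k) * (mu_lo - mu_hi) ** 2  # / n^2 omitted (monotone)
    # only cuts between distinct values are valid thresholds
    valid = v[1:] > v[:-1]
    between = np.where(valid, between, -np.inf)
    i = int(np.argmax(between))
    return float(0.5 * (v[i] + v[i + 1]))


def classify_pixels(corrected_intensities: np.ndarray, threshold: float) -> np.ndarray:
    """Fat mask: intensity strictly above the threshold is fat.

    A pixel exactly at the threshold counts as muscle — the conservative
    tie-break for a fat-infiltration measure.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(corrected_intensities, dtype=float) > threshold


# ---------------------------------------------------------------------------
# Bias-field fitting
# ---------------------------------------------------------------------------

MIN_ROI_FOR_FIT = 12  # 2x the 6 surface coefficients


def fit_bias_field(
    image: SliceImage,
    roi: np.ndarray,
    *,
    max_iterations: int = 25,
    threshold_tolerance: float = 1e-6,
) -> BiasModel:
    """Fit a multiplicative quadratic bias surface over one muscle region.

    The correction and the automatic threshold are coupled, so both are
    solved by fixed-point iteration: split the (current) corrected
    intensities into provisional muscle/fat classes with Otsu's threshold,
    least-squares fit the quadratic surface to the *raw* intensities of the
    muscle-class pixels (lean muscle is assumed homogeneous, so its raw
    signal traces the shading surface), divide by the refit surface and
    repeat until the threshold is stable to ``threshold_tolerance`` of the
    corrected intensity range.

    The returned surface absorbs the mean muscle intensity (a global scale),
    which cancels when the image is divided by it.

    Parameters
    ----------
    roi
        (n, 2) array of (row, col) pixel indices of the region.
    """
    roi = np.asarray(roi)
    if roi.ndim != 2 or roi.shape[1] != 2:
        raise ValueError("roi must be an (n, 2) array of (row, col) indices")
    if roi.shape[0] < MIN_ROI_FOR_FIT:
        raise ValueError(
            f"bias fit needs at least {MIN_ROI_FOR_FIT} roi pixels, "
            f"got {roi.shape[0]}"
        )
    xg, yg = normalized_coordinates(image.intensities.shape)
    rows, cols = roi[:, 0], roi[:, 1]
    x = xg[rows, cols]
    y = yg[rows, cols]
    raw = image.intensities[rows, cols]
    design = _design_matrix(x, y)

    def fit_surface(muscle: np.ndarray) -> np.ndarray:
        new_coeffs, *_ = np.linalg.lstsq(design[muscle], raw[muscle], rcond=None)
        surface = design @ new_coeffs
        if np.any(surface <= 0):
            raise ValueError(
                "degenerate bias fit: fitted surface is not positive over the roi"
            )
        return new_coeffs, surface

    if np.ptp(raw) == 0:
        # single-valued region: the whole roi is "muscle", one flat fit
        coeffs, _ = fit_surface(np.ones(raw.shape, dtype=bool))
        return BiasModel(
            coefficients=tuple(float(c) for c in coeffs),
            fit_iterations=1,
            converged=True,
        )

    coeffs = np.array([raw.mean(), 0, 0, 0, 0, 0])
    corrected = raw.copy()
    prev_threshold = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        threshold = select_threshold(corrected)
        muscle = corrected <= threshold
        if muscle.sum() < 6:  # not enough points to pin 6 coefficients
            break
        coeffs, surface = fit_surface(muscle)
        corrected = raw / surface
        if np.ptp(corrected) == 0:  # surface absorbed everything
            converged = True
            break
        new_threshold = select_threshold(corrected)
        if np.array_equal(corrected <= new_threshold, muscle):
            converged = True  # classification is a fixed point
            break
        if prev_threshold is not None and abs(new_threshold - prev_threshold) <= (
            threshold_tolerance * float(np.ptp(corrected))
        ):
            converged = True
            break
        prev_threshold = new_threshold

    return BiasModel(
        coefficients=tuple(float(c) for c in coeffs),
        fit_iterations=iterations,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Per-region measurement
# ---------------------------------------------------------------------------


def measure_muscle(
    image: SliceImage,
    mask: RoiMask,
    label: int,
    config: MeasureConfig = MeasureConfig(),
) -> MuscleComposition:
    """Measure CSA/fCSA/FAT/FI of one labeled muscle region.

    Pipeline: fit the quadratic bias surface (coupled with Otsu
    thresholding), divide the region intensities by it, select the final
    threshold on the corrected values, classify pixels (above = fat), and
    convert pixel counts to areas with the slice's pixel spacing
    (mm^2 -> cm^2).

    A single-tissue region (all intensities equal after correction) cannot
    support a two-class threshold; it is returned with FAT = 0, FI = 0 and
    ``single_tissue=True``, with a warning.
    """
    if image.intensities.shape != mask.labels.shape:
        raise ValueError("image and mask grids differ in shape")
    muscle, side = mask.label_table[label]
    roi = mask.pixels(label)
    if roi.shape[0] == 0:
        raise ValueError(f"region for label {label} ({muscle} {side}) is empty")
    raw = image.intensities[roi[:, 0], roi[:, 1]]

    single_tissue = False
    try:
        if config.bias_correction:
            bias = fit_bias_field(
                image,
                roi,
                max_iterations=config.max_iterations,
                threshold_tolerance=config.threshold_tolerance,
            )
            xg, yg = normalized_coordinates(image.intensities.shape)
            surface = bias.evaluate(xg[roi[:, 0], roi[:, 1]], yg[roi[:, 0], roi[:, 1]])
            values = raw / surface
        else:
            values = raw
        # numerical jitter from the surface division must not fake two classes
        if np.ptp(values) <= 1e-9 * max(1.0, float(np.max(np.abs(values)))):
            raise DegenerateHistogramError("single-valued region")
        threshold = select_threshold(values)
        fat = classify_pixels(values, threshold)
    except DegenerateHistogramError:
        single_tissue = True
        threshold = float(raw[0])
        fat = np.zeros(raw.shape, dtype=bool)
        warnings.warn(
            f"single-tissue region for label {label} ({muscle} {side}): "
            "degenerate intensity histogram, FI set to 0",
            stacklevel=2,
        )

    px_cm2 = image.pixel_area_mm2 / 100.0
    n = int(roi.shape[0])
    n_fat = int(fat.sum())
    csa = n * px_cm2
    fat_area = n_fat * px_cm2
    return MuscleComposition(
        muscle=muscle,
        side=side,
        CSA=csa,
        fCSA=csa - fat_area,
        FAT=fat_area,
        FI=100.0 * n_fat / n,
        threshold_used=float(threshold),
        n_pixels=n,
        single_tissue=single_tissue,
    )


def combine_sides(left: MuscleComposition, right: MuscleComposition) -> MuscleComposition:
    """Sum the left and right sides of one muscle.

    Areas add; FI is recomputed area-weighted as 100*(FAT_L+FAT_R)/(CSA_L+CSA_R),
    not the mean of the per-side FIs.
    """
    if left.muscle != right.muscle:
        raise ValueError(
            f"cannot combine different muscles: {left.muscle} vs {right.muscle}"
        )
    csa = left.CSA + right.CSA
    fat = left.FAT + right.FAT
    return MuscleComposition(
        muscle=left.muscle,
        side="both",
        CSA=csa,
        fCSA=csa - fat,
        FAT=fat,
        FI=100.0 * fat / csa if csa > 0 else 0.0,
        threshold_used=float("nan"),
        n_pixels=left.n_pixels + right.n_pixels,
        single_tissue=left.single_tissue and right.single_tissue,
    )


def normalize_by_height(c: MuscleComposition, height_m: float) -> NormalizedComposition:
    """Divide each area by height^2 (m^2), giving cm^2/m^2; FI is unchanged."""
    if not (1.0 < height_m < 2.5):
        raise ValueError(f"implausible patient height {height_m} m (expect 1.0-2.5)")
    h2 = height_m * height_m
    return NormalizedComposition(
        muscle=c.muscle,
        CSA=c.CSA / h2,
        fCSA=c.fCSA / h2,
        FAT=c.FAT / h2,
        FI=c.FI,
        height_m=float(height_m),
    )


def measure_all(
    image: SliceImage,
    mask: RoiMask,
    height_m: float | None = None,
    config: MeasureConfig = MeasureConfig(),
) -> dict[str, MuscleComposition | NormalizedComposition]:
    """Measure every muscle present, combine sides and optionally normalize.

    Returns a dict keyed by muscle name; values are bilateral
    ``MuscleComposition`` (or ``NormalizedComposition`` if height given).
    """
    by_muscle: dict[str, dict[str, MuscleComposition]] = {}
    for label, (muscle, side) in mask.label_table.items():
        if np.any(mask.labels == label):
            by_muscle.setdefault(muscle, {})[side] = measure_muscle(
                image, mask, int(label), config
            )
    out: dict[str, MuscleComposition | NormalizedComposition] = {}
    for muscle, sides in by_muscle.items():
        if set(sides) == {"left", "right"}:
            combined = combine_sides(sides["left"], sides["right"])
        else:
            (combined,) = sides.values()
        if height_m is not None:
            out[muscle] = normalize_by_height(combined, height_m)
        else:
            out[muscle] = combined
    return out


# ---------------------------------------------------------------------------
# Lordosis
# ---------------------------------------------------------------------------


def cobb_angle(landmarks: EndplateLandmarks) -> float:
    """Unsigned Cobb angle (degrees, in [0, 90]) between two endplate lines."""
    angles = []
    for p, q in (landmarks.L1_superior, landmarks.S1_superior):
        d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
        angles.append(np.arctan2(d[1], d[0]))
    diff = np.degrees(abs(angles[0] - angles[1])) % 180.0
    return float(min(diff, 180.0 - diff))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_slice(path: str | Path) -> SliceImage:
    """Read a 2-D slice from NIfTI (.nii/.nii.gz, spacing from header) or CSV."""
    path = Path(path)
    if path.suffix == ".csv":
        return SliceImage(np.loadtxt(path, delimiter=","), (1.0, 1.0))
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"{path} is not a single 2-D slice")
    zooms = img.header.get_zooms()[:2]
    return SliceImage(data, (float(zooms[0]), float(zooms[1])))


def read_mask(path: str | Path, label_table_path: str | Path) -> RoiMask:
    """Read an integer label mask (NIfTI or CSV) plus its JSON label table.

    The JSON maps label -> {"muscle": ..., "side": ...}.
    """
    path = Path(path)
    if path.suffix == ".csv":
        labels = np.loadtxt(path, delimiter=",").astype(int)
    else:
        import nibabel as nib

        labels = np.squeeze(np.asarray(nib.load(str(path)).dataobj)).astype(int)
    with open(label_table_path) as fh:
        raw = json.load(fh)
    table = {int(k): (v["muscle"], v["side"]) for k, v in raw.items()}
    return RoiMask(labels, table)


def write_composition_rows(
    path: str | Path,
    patient_id: str,
    measured: Mapping[str, MuscleComposition],
    normalized: Mapping[str, NormalizedComposition] | None = None,
) -> None:
    """Write per-muscle composition rows as CSV.

    Columns: patient_id, muscle, CSA, fCSA, FAT, FI, CSA_norm, fCSA_norm,
    FAT_norm, threshold_used (norm columns empty when no height was given).
    """
    import pandas as pd

    rows = []
    for muscle, comp in measured.items():
        norm = normalized.get(muscle) if normalized else None
        rows.append(
            {
                "patient_id": patient_id,
                "muscle": muscle,
                "CSA": comp.CSA,
                "fCSA": comp.fCSA,
                "FAT": comp.FAT,
                "FI": comp.FI,
                "CSA_norm": norm.CSA if norm else np.nan,
                "fCSA_norm": norm.fCSA if norm else np.nan,
                "FAT_norm": norm.FAT if norm else np.nan,
                "threshold_used": comp.threshold_used,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
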