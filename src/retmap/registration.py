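"""Eccentricity bookkeeping, anatomically restricted window extraction and
patient-level cohort splitting.

Coordinate convention: rows are axial depth (row 0 = vitreous), columns are
lateral position.  Eccentricity is signed lateral distance from the foveal
center in millimetres, nasal positive, temporal negative.  mm -> px rounding
uses round-half-away-from-zero for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

RIT_NORMALIZATION_MINUTES = 40.0
PIXEL_NORMALIZATION = 255.0

SPLIT_NAMES = ("train", "val", "test")


class EccentricityRangeError(ValueError):
    """Requested eccentricity falls outside the imaged field."""


class WindowExtractionError(ValueError):
    """A window cannot be placed fully inside the image laterally."""


class SplitConfigError(ValueError):
    """Invalid split fractions or cohort too small."""


@dataclass
class BScanImage:
    """One registered grayscale foveal B-scan with physical scales.

    ``pixels`` is a (height, width) uint8 array; ``fovea_col`` is the
    0-based column of the foveal center.
    """

    pixels: np.ndarray
    fovea_col: int
    lateral_scale_mm_per_px: float
    axial_scale_mm_per_px: float
    patient_id: str
    eye_id: str
    volume_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D (height, width) array")
        if not 0 <= self.fovea_col < self.pixels.shape[1]:
            raise ValueError("fovea_col outside image width")
        if self.lateral_scale_mm_per_px <= 0 or self.axial_scale_mm_per_px <= 0:
            raise ValueError("physical scales must be positive")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class WindowSpec:
    """Placement rule for one anatomic-location training window."""

    center_eccentricity_mm: float
    width_px: int = 64
    height_px: int = 256
    placement: str = "mip_argmax"

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("window dimensions must be positive")
        if self.width_px % 2 or self.height_px % 2:
            raise ValueError("window dimensions must be even")
        if self.placement != "mip_argmax":
            raise ValueError(f"unknown placement rule {self.placement!r}")


@dataclass
class TrainingWindow:
    """A normalized (height, width) patch with its normalized RIT label."""

    patch: np.ndarray
    label: float | None
    patient_id: str
    eye_id: str
    volume_id: str
    center_eccentricity_mm: float
    origin: tuple[int, int]  # (top row, left col) in the source image

    def __post_init__(self) -> None:
        if self.patch.min() < 0.0 or self.patch.max() > 1.0:
            raise ValueError("patch values must lie in [0, 1]")
        if self.label is not None and self.label <= 0:
            raise ValueError("label must be positive")


def round_half_away(x: float) -> int:
    """Round-half-away-from-zero (symmetric about 0)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def eccentricity_to_col(ecc_mm: float, image: BScanImage) -> int:
    """Signed eccentricity (mm, nasal positive) -> 0-based column index."""
    col = image.fovea_col + round_half_away(ecc_mm / image.lateral_scale_mm_per_px)
    if not 0 <= col < image.width:
        lo = -image.fovea_col * image.lateral_scale_mm_per_px
        hi = (image.width - 1 - image.fovea_col) * image.lateral_scale_mm_per_px
        raise EccentricityRangeError(
            f"eccentricity {ecc_mm:+.3f} mm outside the imaged field "
            f"[{lo:+.3f}, {hi:+.3f}] mm")
    return col


def col_to_eccentricity(col: int, image: BScanImage) -> float:
    """Pseudo-inverse of :func:`eccentricity_to_col`."""
    return (col - image.fovea_col) * image.lateral_scale_mm_per_px


def compute_vertical_center(image: BScanImage, col_range: tuple[int, int]) -> int:
    """Row of the horizontal maximum intensity projection over ``col_range``.

    The columns of the range are pooled into one axial mean-intensity
    profile; returns its argmax, ties broken to the smallest row index.
    """
    c0, c1 = col_range
    if not (0 <= c0 < c1 <= image.width):
        raise ValueError(f"empty or out-of-bounds column range [{c0}, {c1})")
    profile = image.pixels[:, c0:c1].mean(axis=1)
    return int(np.argmax(profile))


def window_placement(image: BScanImage, spec: WindowSpec) -> tuple[int, int]:
    """(top row, left col) of the window; lateral overhang is an error,
    axial overhang is resolved by the minimal vertical shift that fits."""
    center_col = eccentricity_to_col(spec.center_eccentricity_mm, image)
    c0 = center_col - spec.width_px // 2
    c1 = c0 + spec.width_px
    if c0 < 0 or c1 > image.width:
        half_mm = (spec.width_px // 2) * image.lateral_scale_mm_per_px
        lo = -(image.fovea_col - spec.width_px // 2) * image.lateral_scale_mm_per_px
        hi = (image.width - image.fovea_col - (spec.width_px - spec.width_px // 2)) \
            * image.lateral_scale_mm_per_px
        raise WindowExtractionError(
            f"window of half-width {half_mm:.3f} mm at eccentricity "
            f"{spec.center_eccentricity_mm:+.3f} mm overhangs the field; "
            f"allowed centers span [{lo:+.3f}, {hi:+.3f}] mm")
    if image.height < spec.height_px:
        raise WindowExtractionError(
            f"image height {image.height} px smaller than window "
            f"height {spec.height_px} px")
    vcenter = compute_vertical_center(image, (c0, c1))
    r0 = vcenter - spec.height_px // 2
    r0 = min(max(r0, 0), image.height - spec.height_px)
    return r0, c0


def extract_window(image: BScanImage, spec: WindowSpec,
                   rit_minutes: float | None = None) -> TrainingWindow:
    """Extract the normalized training window for one anatomic location.

    Pixel intensities are divided by 255; the label, when a RIT is given,
    is the RIT divided by 40 minutes.
    """
    r0, c0 = window_placement(image, spec)
    patch = image.pixels[r0:r0 + spec.height_px,
                         c0:c0 + spec.width_px].astype(np.float64)
    patch /= PIXEL_NORMALIZATION
    label = None
    if rit_minutes is not None:
        if not np.isfinite(rit_minutes) or rit_minutes <= 0:
            raise ValueError("rit_minutes must be finite and positive")
        label = float(rit_minutes) / RIT_NORMALIZATION_MINUTES
    return TrainingWindow(patch=patch, label=label,
                          patient_id=image.patient_id, eye_id=image.eye_id,
                          volume_id=image.volume_id,
                          center_eccentricity_mm=spec.center_eccentricity_mm,
                          origin=(r0, c0))


@dataclass
class SplitAssignment:
    """patient_id -> split in {train, val, test}; patient-level exclusive."""

    assignment: dict[str, str] = field(default_factory=dict)

    def of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def patients(self, split: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == split)

    def counts(self) -> dict[str, int]:
        return {s: len(self.patients(s)) for s in SPLIT_NAMES}


def split_cohort(records, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                 seed: int = 0) -> SplitAssignment:
    """Random patient-level train/val/test assignment.

    Counts are (round(f_train * n), round(f_val * n), remainder) with
    round-half-away-from-zero; every volume of a patient inherits the
    patient's split.
    """
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise SplitConfigError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitConfigError(f"fractions must sum to 1, got {sum(fractions)}")
    patients = sorted({r.patient_id for r in records})
    n = len(patients)
    if n < 3:
        raise SplitConfigError(f"need at least 3 patients, got {n}")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(n)]
    n_train = round_half_away(fractions[0] * n)
    n_val = round_half_away(fractions[1] * n)
    assignment = {}
    for i, patient in enumerate(order):
        if i < n_train:
            assignment[patient] = "train"
        elif i < n_train + n_val:
            assignment[patient] = "val"
        else:
            assignment[patient] = "test"
    return SplitAssignment(assignment)


def build_training_windows(images, records, spec: WindowSpec,
                           split: SplitAssignment | None = None,
                           subset: str | None = None) -> list[TrainingWindow]:
    """Extract one labelled window per B-scan, optionally restricted to one
    split subset.  Raises WindowExtractionError if any image fails."""
    rit_by_volume = {r.volume_id: r.rit_minutes for r in records}
    windows = []
    for image in images:
        if subset is not None:
            if split is None:
                raise ValueError("subset filtering requires a SplitAssignment")
            if split.of(image.patient_id) != subset:
                continue
        windows.append(extract_window(image, spec, rit_by_volume[image.volume_id]))
    return windows
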