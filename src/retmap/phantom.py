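"""Synthetic layered-retina B-scan phantoms with a known injected biomarker.

The phantom renders horizontally continuous outer-retinal reflectivity bands
(inner retina, ONL, ELM, myoid zone, EZ, sub-EZ hyporeflective gap, IZ,
RPE-BrM) over a vitreous/choroid background, with a Gaussian foveal pit cut
into the inner retinal surface.  The "biomarker" raises the intensity of the
two hyporeflective bands flanking the EZ (myoid zone and sub-EZ gap) inside a
configurable lateral footprint, proportionally to a latent per-patient
severity b in [0, 1].  A continuous rod-intercept-time label is linked
affinely to b with additive Gaussian noise.  Multiplicative gamma speckle
emulates coherent-imaging noise.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml
from PIL import Image

from .registration import BScanImage

# band order from vitreous toward choroid
BAND_ORDER = ("inner_retina", "onl", "elm", "myoid", "ez", "subez_gap",
              "iz", "rpe_brm")
# the two hyporeflective bands flanking the EZ that carry the biomarker
BIOMARKER_BANDS = ("myoid", "subez_gap")


class PhantomConfigError(ValueError):
    """Invalid phantom configuration."""


def _default_thickness() -> dict[str, int]:
    return {"inner_retina": 64, "onl": 46, "elm": 4, "myoid": 16,
            "ez": 8, "subez_gap": 14, "iz": 6, "rpe_brm": 12}


def _default_intensities() -> dict[str, float]:
    return {"inner_retina": 120, "onl": 30, "elm": 140, "myoid": 40,
            "ez": 235, "subez_gap": 40, "iz": 140, "rpe_brm": 195,
            "vitreous": 8, "choroid": 56}


@dataclass
class PhantomConfig:
    """Geometry, reflectivity, biomarker and label-link parameters."""

    image_width_px: int = 384
    image_height_px: int = 496
    lateral_scale_mm_per_px: float = 0.015
    axial_scale_mm_per_px: float = 0.0039
    surface_row_px: int = 96
    band_thickness_px: dict[str, int] = field(default_factory=_default_thickness)
    band_intensities: dict[str, float] = field(default_factory=_default_intensities)
    pit_depth_px: int = 40
    pit_sigma_mm: float = 0.30
    biomarker_center_mm: float = 0.3
    biomarker_width_mm: float = 0.5
    biomarker_contrast: float = 60.0
    biomarker_profile: str = "boxcar"  # or "cosine" (tapered to 0 at edges)
    speckle_shape: float = 8.0  # gamma shape; 0 disables speckle
    rit_min_minutes: float = 5.0
    rit_max_minutes: float = 40.0
    rit_noise_sd_minutes: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise PhantomConfigError("image dimensions must be positive")
        if self.lateral_scale_mm_per_px <= 0 or self.axial_scale_mm_per_px <= 0:
            raise PhantomConfigError("physical scales must be positive")
        missing = set(BAND_ORDER) - set(self.band_thickness_px)
        if missing:
            raise PhantomConfigError(f"missing band thicknesses: {sorted(missing)}")
        for name, value in self.band_intensities.items():
            if not 0 <= value <= 255:
                raise PhantomConfigError(
                    f"band intensity {name}={value} outside [0, 255]")
        if not 0 < self.rit_min_minutes < self.rit_max_minutes <= 40.0:
            raise PhantomConfigError(
                "require 0 < rit_min < rit_max <= 40 minutes")
        if self.rit_noise_sd_minutes < 0:
            raise PhantomConfigError("rit_noise_sd_minutes must be >= 0")
        if self.speckle_shape < 0:
            raise PhantomConfigError("speckle_shape must be >= 0")
        if self.biomarker_width_mm < 0:
            raise PhantomConfigError("biomarker_width_mm must be >= 0")
        if self.biomarker_profile not in ("boxcar", "cosine"):
            raise PhantomConfigError("biomarker_profile must be boxcar or cosine")
        fovea_col = self.image_width_px // 2
        half_field_lo = fovea_col * self.lateral_scale_mm_per_px
        half_field_hi = (self.image_width_px - 1 - fovea_col) \
            * self.lateral_scale_mm_per_px
        lo = self.biomarker_center_mm - self.biomarker_width_mm / 2
        hi = self.biomarker_center_mm + self.biomarker_width_mm / 2
        if lo < -half_field_lo or hi > half_field_hi:
            raise PhantomConfigError(
                f"biomarker footprint [{lo:+.3f}, {hi:+.3f}] mm outside the "
                f"lateral field [{-half_field_lo:+.3f}, {half_field_hi:+.3f}] mm")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PhantomConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = cls().to_dict()
        merged.update(data)
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class EyePhantomParams:
    """Per-eye latent severity and geometry jitter."""

    patient_id: str
    eye_id: str
    biomarker_strength: float = 0.0
    jitter_px: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.biomarker_strength <= 1.0:
            raise ValueError("biomarker_strength must lie in [0, 1]")


@dataclass(frozen=True)
class RITRecord:
    """One eye-visit rod-intercept-time label in minutes."""

    patient_id: str
    eye_id: str
    volume_id: str
    rit_minutes: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.rit_minutes) or self.rit_minutes <= 0:
            raise ValueError("rit_minutes must be finite and positive")


class Cohort(NamedTuple):
    """Rendered cohort plus the latent per-patient severities.

    ``severities`` maps patient_id -> b; it is the ground truth that the
    pipeline is supposed to rediscover, exposed for testing only.
    """

    images: list[BScanImage]
    records: list[RITRecord]
    severities: dict[str, float]


def rit_link(b: float, cfg: PhantomConfig, rng: np.random.Generator) -> float:
    """Affine severity->RIT link with additive Gaussian noise.

    rit = rit_min + b * (rit_max - rit_min) + N(0, sd), truncated below
    at 0.1 minutes.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"biomarker strength b={b} outside [0, 1]")
    rit = cfg.rit_min_minutes + b * (cfg.rit_max_minutes - cfg.rit_min_minutes)
    if cfg.rit_noise_sd_minutes > 0:
        rit += rng.normal(0.0, cfg.rit_noise_sd_minutes)
    return max(float(rit), 0.1)


def band_rows(cfg: PhantomConfig, jitter_px: int = 0) -> dict[str, tuple[int, int]]:
    """Flat [top, bottom) row span of every band, before the pit is cut."""
    spans = {}
    top = cfg.surface_row_px + jitter_px
    for name in BAND_ORDER:
        thickness = cfg.band_thickness_px[name]
        spans[name] = (top, top + thickness)
        top += thickness
    return spans


def biomarker_columns(cfg: PhantomConfig, fovea_col: int) -> np.ndarray:
    """Boolean lateral mask of the biomarker footprint."""
    cols = np.arange(cfg.image_width_px)
    x_mm = (cols - fovea_col) * cfg.lateral_scale_mm_per_px
    return np.abs(x_mm - cfg.biomarker_center_mm) <= cfg.biomarker_width_mm / 2


def biomarker_weights(cfg: PhantomConfig, fovea_col: int) -> np.ndarray:
    """Per-column intensity-shift weight in [0, 1].

    ``boxcar``: 1 everywhere inside the footprint (hard edges).
    ``cosine``: raised-cosine taper, 1 at the center falling to 0 at the
    footprint edges, which makes the injected location identifiable by
    windows with partial overlap.
    """
    mask = biomarker_columns(cfg, fovea_col)
    if cfg.biomarker_profile == "boxcar":
        return mask.astype(float)
    cols = np.arange(cfg.image_width_px)
    x_mm = (cols - fovea_col) * cfg.lateral_scale_mm_per_px
    half = cfg.biomarker_width_mm / 2
    with np.errstate(invalid="ignore"):
        taper = 0.5 * (1 + np.cos(np.pi * (x_mm - cfg.biomarker_center_mm)
                                  / half))
    return np.where(mask, taper, 0.0)


def generate_bscan(cfg: PhantomConfig, eye: EyePhantomParams,
                   rng: np.random.Generator,
                   volume_id: str = "V000") -> BScanImage:
    """Render one 8-bit phantom B-scan.

    Bands are painted as flat strata; the Gaussian foveal pit is cut into
    the inner surface by painting vitreous above the pit profile.  Within
    the biomarker lateral footprint the two hyporeflective bands flanking
    the EZ are raised by b * biomarker_contrast before speckle.  Gamma
    speckle (mean 1) is multiplicative; output is clipped to [0, 255].
    """
    cfg.validate()
    h, w = cfg.image_height_px, cfg.image_width_px
    fovea_col = w // 2
    img = np.full((h, w), float(cfg.band_intensities["vitreous"]))
    spans = band_rows(cfg, eye.jitter_px)
    bottom = spans[BAND_ORDER[-1]][1]
    if bottom > h:
        raise PhantomConfigError("band stack extends below the image")
    for name in BAND_ORDER:
        r0, r1 = spans[name]
        img[r0:r1, :] = cfg.band_intensities[name]
    img[bottom:, :] = cfg.band_intensities["choroid"]

    # biomarker: raise the hyporeflective bands flanking the EZ in-footprint
    weights = biomarker_weights(cfg, fovea_col)
    for name in BIOMARKER_BANDS:
        r0, r1 = spans[name]
        img[r0:r1, :] += eye.biomarker_strength * cfg.biomarker_contrast \
            * weights[None, :]

    # Gaussian foveal pit cut into the inner surface
    cols = np.arange(w)
    x_mm = (cols - fovea_col) * cfg.lateral_scale_mm_per_px
    pit = cfg.pit_depth_px * np.exp(-0.5 * (x_mm / cfg.pit_sigma_mm) ** 2)
    surface = cfg.surface_row_px + eye.jitter_px + np.rint(pit).astype(int)
    row_idx = np.arange(h)[:, None]
    img[row_idx < surface[None, :]] = cfg.band_intensities["vitreous"]

    if cfg.speckle_shape > 0:
        img *= rng.gamma(cfg.speckle_shape, 1.0 / cfg.speckle_shape, size=(h, w))

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return BScanImage(pixels=pixels, fovea_col=fovea_col,
                      lateral_scale_mm_per_px=cfg.lateral_scale_mm_per_px,
                      axial_scale_mm_per_px=cfg.axial_scale_mm_per_px,
                      patient_id=eye.patient_id, eye_id=eye.eye_id,
                      volume_id=volume_id)


def sample_cohort(cfg: PhantomConfig, n_patients: int,
                  volumes_per_eye: int = 1,
                  rng: np.random.Generator | None = None,
                  eyes_per_patient: int = 1) -> Cohort:
    """Draw a reproducible phantom cohort.

    Per patient one severity b ~ U(0, 1) is drawn and shared by both eyes;
    each eye gets an independent small geometry jitter and
    ``volumes_per_eye`` rendered scans, each with its own RIT label drawn
    through :func:`rit_link`.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if volumes_per_eye < 1 or not 1 <= eyes_per_patient <= 2:
        raise ValueError("volumes_per_eye >= 1 and eyes_per_patient in {1, 2}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    images: list[BScanImage] = []
    records: list[RITRecord] = []
    severities: dict[str, float] = {}
    eye_names = ("OD", "OS")[:eyes_per_patient]
    for p in range(n_patients):
        patient_id = f"P{p:04d}"
        b = float(rng.uniform(0.0, 1.0))
        severities[patient_id] = b
        for eye_name in eye_names:
            jitter = int(rng.integers(-2, 3))
            eye = EyePhantomParams(patient_id=patient_id, eye_id=eye_name,
                                   biomarker_strength=b, jitter_px=jitter)
            for v in range(volumes_per_eye):
                volume_id = f"{patient_id}_{eye_name}_V{v:02d}"
                images.append(generate_bscan(cfg, eye, rng, volume_id))
                rit = rit_link(b, cfg, rng)
                records.append(RITRecord(patient_id, eye_name, volume_id, rit))
    return Cohort(images, records, severities)


# ---------------------------------------------------------------------------
# cohort I/O: 8-bit grayscale PNGs + CSV sidecar

CSV_COLUMNS = ("patient_id", "eye_id", "volume_id", "path", "fovea_col",
               "lateral_scale_mm_per_px", "axial_scale_mm_per_px",
               "rit_minutes", "split")


def save_cohort(outdir: str | Path, cohort: Cohort,
                split: "dict[str, str] | None" = None) -> Path:
    """Write images as PNGs under ``outdir/images`` and a metadata/label CSV.

    Returns the CSV path.  ``split`` optionally maps patient_id -> split
    name; the column is left empty otherwise.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rit_by_volume = {r.volume_id: r.rit_minutes for r in cohort.records}
    rows = []
    for image in cohort.images:
        rel = Path("images") / f"{image.volume_id}.png"
        Image.fromarray(image.pixels, mode="L").save(outdir / rel)
        rows.append({
            "patient_id": image.patient_id,
            "eye_id": image.eye_id,
            "volume_id": image.volume_id,
            "path": str(rel),
            "fovea_col": image.fovea_col,
            "lateral_scale_mm_per_px": image.lateral_scale_mm_per_px,
            "axial_scale_mm_per_px": image.axial_scale_mm_per_px,
            "rit_minutes": rit_by_volume[image.volume_id],
            "split": (split or {}).get(image.patient_id, ""),
        })
    csv_path = outdir / "cohort.csv"
    tmp_path = csv_path.with_suffix(".csv.tmp")
    with open(tmp_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    tmp_path.rename(csv_path)
    return csv_path


def load_cohort(csv_path: str | Path) -> tuple[list[BScanImage], list[RITRecord],
                                               dict[str, str]]:
    """Read a cohort CSV + PNG layout back into memory.

    Returns (images, records, split) where split maps patient_id to its
    split name for rows that have one.
    """
    csv_path = Path(csv_path)
    base = csv_path.parent
    images, records, split = [], [], {}
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            pixels = np.asarray(Image.open(base / row["path"]).convert("L"))
            images.append(BScanImage(
                pixels=pixels, fovea_col=int(row["fovea_col"]),
                lateral_scale_mm_per_px=float(row["lateral_scale_mm_per_px"]),
                axial_scale_mm_per_px=float(row["axial_scale_mm_per_px"]),
                patient_id=row["patient_id"], eye_id=row["eye_id"],
                volume_id=row["volume_id"]))
            records.append(RITRecord(row["patient_id"], row["eye_id"],
                                     row["volume_id"], float(row["rit_minutes"])))
            if row.get("split"):
                split[row["patient_id"]] = row["split"]
    return images, records, split
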