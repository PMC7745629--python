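"""Run configuration, stage manifests and the Markdown report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .phantom import PhantomConfig
from .regressor import Architecture, TrainConfig

PROFILES = ("paper_faithful", "desk")


class RunConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Parsed pipeline configuration (one YAML file drives every stage)."""

    output_dir: Path
    seed: int
    phantom: PhantomConfig
    n_patients: int
    volumes_per_eye: int
    eyes_per_patient: int
    split_fractions: tuple[float, float, float]
    split_seed: int
    train: TrainConfig
    grid: list[float]
    window_width_px: int
    window_height_px: int
    occlusion: dict
    n_occlusion_images: int
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            return cls._parse(raw)
        except (ValueError, TypeError, KeyError) as exc:
            raise RunConfigError(str(exc)) from exc

    @classmethod
    def _parse(cls, raw: dict) -> "RunConfig":
        seed = int(raw.get("seed", 0))
        phantom_section = dict(raw.get("phantom", {}))
        n_patients = int(phantom_section.pop("n_patients", 40))
        volumes_per_eye = int(phantom_section.pop("volumes_per_eye", 1))
        eyes_per_patient = int(phantom_section.pop("eyes_per_patient", 1))
        phantom_section.setdefault("seed", seed)
        phantom = PhantomConfig.from_dict(phantom_section)

        split_section = raw.get("split", {})
        fractions = tuple(split_section.get("fractions", (0.6, 0.2, 0.2)))
        if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
            raise RunConfigError(
                f"split fractions must be 3 numbers summing to 1, "
                f"got {fractions}")
        split_seed = int(split_section.get("seed", seed))

        train_section = dict(raw.get("train", {}))
        profile = train_section.pop("profile", "desk")
        if profile not in PROFILES:
            raise RunConfigError(f"profile must be one of {PROFILES}")
        arch_section = train_section.pop("architecture", None)
        arch = None
        if arch_section is not None:
            arch_section = dict(arch_section)
            for key in ("conv_channels", "input_shape"):
                if key in arch_section:
                    arch_section[key] = tuple(arch_section[key])
            arch = Architecture(**arch_section)
        base = TrainConfig.paper_faithful if profile == "paper_faithful" \
            else TrainConfig.desk
        train = base(base_seed=int(train_section.pop("base_seed", seed)),
                     architecture=arch)
        for key, value in train_section.items():  # explicit overrides
            if not hasattr(train, key):
                raise RunConfigError(f"unknown train key {key!r}")
            setattr(train, key, type(getattr(train, key))(value))
        train.__post_init__()

        sweep_section = raw.get("sweep", {})
        if "grid" in sweep_section:
            grid = [float(g) for g in sweep_section["grid"]]
        else:
            lo = float(sweep_section.get("grid_min_mm", -1.5))
            hi = float(sweep_section.get("grid_max_mm", 1.5))
            step = float(sweep_section.get("grid_step_mm", 0.25))
            grid = [round(g, 6) for g in np.arange(lo, hi + step / 2, step)]
        width_px = int(sweep_section.get("width_px", 64))
        height_px = int(sweep_section.get("height_px", 256))
        if (height_px, width_px) != train.architecture.input_shape:
            train.architecture = dataclasses.replace(
                train.architecture, input_shape=(height_px, width_px))

        occlusion_section = dict(raw.get("occlusion", {}))
        n_occ = int(occlusion_section.pop("n_images", 4))

        return cls(output_dir=Path(raw.get("output_dir", "runs/run")),
                   seed=seed, phantom=phantom, n_patients=n_patients,
                   volumes_per_eye=volumes_per_eye,
                   eyes_per_patient=eyes_per_patient,
                   split_fractions=fractions, split_seed=split_seed,
                   train=train, grid=grid, window_width_px=width_px,
                   window_height_px=height_px, occlusion=occlusion_section,
                   n_occlusion_images=n_occ, raw=raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


class ManifestWriter:
    """Records per-stage inputs/outputs, seeds and wall time."""

    def __init__(self, cfg: RunConfig, stage: str) -> None:
        self.cfg = cfg
        self.stage = stage
        self.inputs: list[str] = []
        self.outputs: list[str] = []
        self._t0 = time.monotonic()
        self.complete = True

    def add_input(self, path: str | Path) -> None:
        self.inputs.append(str(path))

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self) -> Path:
        for out in self.outputs:
            if not Path(out).exists():
                raise FileNotFoundError(f"manifest output missing: {out}")
        manifest = {
            "stage": self.stage,
            "config_hash": self.cfg.config_hash(),
            "software_version": __version__,
            "seed": self.cfg.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "wall_time_s": round(time.monotonic() - self._t0, 3),
            "complete": self.complete,
        }
        path = Path(self.cfg.output_dir) / f"manifest_{self.stage}.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        return path


def _df_to_markdown(df) -> str:
    cols = list(df.columns)
    rows = ["| " + " | ".join(cols) + " |",
            "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        cells = [f"{v:.3f}" if isinstance(v, float) else str(v) for v in row]
        rows.append("| " + " | ".join(cells) + " |")
    return "\n".join(rows)


def write_report(outdir: Path, best_ecc: float, curve_df, metrics: dict,
                 overlay_paths: list[Path], config_hash: str) -> Path:
    """Assemble the Markdown run report from stage outputs."""
    lines = [
        "# Localization run report",
        "",
        f"- config hash: `{config_hash}`",
        f"- software version: {__version__}",
        f"- best location (argmin mean validation RMSE): "
        f"**{best_ecc:+.2f} mm**",
        "",
        "## Test-split metrics at the best location",
        "",
        f"| RMSE (min) | MAE (min) | Pearson r |",
        f"|---|---|---|",
        f"| {metrics['rmse']:.3f} | {metrics['mae']:.3f} "
        f"| {metrics['pearson']:.3f} |",
        "",
        "## Eccentricity curve (validation RMSE, minutes)",
        "",
        _df_to_markdown(curve_df),
        "",
        "![eccentricity curve](curve.png)",
        "",
        "## Occlusion overlays (red = RIT lengthening, blue = shortening)",
        "",
    ]
    for path in overlay_paths:
        rel = path.relative_to(outdir)
        lines.append(f"![{rel}]({rel})")
    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path
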