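"""Signed occlusion perturbation mapping with a frozen per-location ensemble.

For each occlusion center on a stride grid, a small patch of the B-scan is
replaced (by its own mean, zeros, or a permutation of its own pixels), the
model window — whose placement is frozen from the unperturbed image — is
re-extracted, and the change in predicted RIT (minutes, perturbed minus
baseline) is recorded.  ``fixed_window`` mode evaluates only centers whose
patch intersects the window footprint (elsewhere the delta is exactly 0 by
construction); ``sliding_window`` mode re-centers the window laterally at
each occlusion column for a full-width map.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .registration import BScanImage, WindowSpec, window_placement
from .regressor import ModelEnsemble, predict_rit_batch

FILLS = ("mean", "zero", "permute")


class OcclusionRangeError(ValueError):
    """Occlusion center outside the image."""


@dataclass(frozen=True)
class OcclusionConfig:
    patch_w_px: int = 16  # lateral
    patch_h_px: int = 6   # axial
    fill: str = "mean"
    stride_px: int = 1
    inference_mode: str = "fixed_window"
    permute_seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_w_px < 1 or self.patch_h_px < 1:
            raise ValueError("patch dimensions must be >= 1")
        if self.stride_px < 1:
            raise ValueError("stride must be >= 1")
        if self.fill not in FILLS:
            raise ValueError(f"fill must be one of {FILLS}")
        if self.inference_mode not in ("fixed_window", "sliding_window"):
            raise ValueError("inference_mode must be fixed_window or "
                             "sliding_window")


@dataclass
class OcclusionMap:
    """Signed per-center ΔRIT grid (minutes) plus provenance."""

    delta_rit_minutes: np.ndarray          # (n_rows, n_cols) grid
    rows: np.ndarray                       # image row of each grid row
    cols: np.ndarray                       # image col of each grid col
    evaluated: np.ndarray                  # bool grid: prediction actually run
    baseline_rit_minutes: float
    config: OcclusionConfig
    window_origin: tuple[int, int]
    image_shape: tuple[int, int]

    def to_dataframe(self) -> pd.DataFrame:
        rr, cc = np.meshgrid(self.rows, self.cols, indexing="ij")
        return pd.DataFrame({"row": rr.ravel(), "col": cc.ravel(),
                             "delta_rit_minutes": self.delta_rit_minutes.ravel()})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_tiff(self, path) -> None:
        from PIL import Image
        Image.fromarray(self.delta_rit_minutes.astype(np.float32)).save(path)

    def full_resolution(self) -> np.ndarray:
        """Upsample the stride grid back to image resolution (nearest)."""
        s = self.config.stride_px
        full = np.repeat(np.repeat(self.delta_rit_minutes, s, axis=0), s, axis=1)
        h, w = self.image_shape
        return full[:h, :w]


def _patch_bounds(center: tuple[int, int], cfg: OcclusionConfig,
                  shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """Cropped [r0, r1) x [c0, c1) patch bounds around ``center``."""
    r, c = center
    h, w = shape
    r0 = max(r - cfg.patch_h_px // 2, 0)
    r1 = min(r - cfg.patch_h_px // 2 + cfg.patch_h_px, h)
    c0 = max(c - cfg.patch_w_px // 2, 0)
    c1 = min(c - cfg.patch_w_px // 2 + cfg.patch_w_px, w)
    return r0, r1, c0, c1


def _fill_block(patch: np.ndarray, cfg: OcclusionConfig,
                center: tuple[int, int]) -> np.ndarray:
    """Replacement values for one (cropped) patch; float, not re-quantized."""
    if cfg.fill == "mean":
        return np.full(patch.shape, patch.mean())
    if cfg.fill == "zero":
        return np.zeros(patch.shape)
    rng = np.random.default_rng((cfg.permute_seed, center[0], center[1]))
    return rng.permutation(patch.ravel()).reshape(patch.shape)


def occlude_patch(image: np.ndarray, center: tuple[int, int],
                  cfg: OcclusionConfig) -> np.ndarray:
    """Return a float copy of ``image`` with the patch at ``center`` filled.

    Patches overhanging the borders are cropped; mean/permute statistics
    are computed on the cropped support.
    """
    arr = np.asarray(image, dtype=np.float64)
    r, c = center
    h, w = arr.shape
    if not (0 <= r < h and 0 <= c < w):
        raise OcclusionRangeError(f"center {center} outside image {arr.shape}")
    out = arr.copy()
    r0, r1, c0, c1 = _patch_bounds(center, cfg, arr.shape)
    out[r0:r1, c0:c1] = _fill_block(arr[r0:r1, c0:c1], cfg, center)
    return out


def occlusion_map(ensemble: ModelEnsemble, image: BScanImage,
                  window_spec: WindowSpec, cfg: OcclusionConfig,
                  chunk: int = 256) -> OcclusionMap:
    """Signed mean-occlusion (or variant) map over the whole B-scan.

    Window placement is computed once from the unperturbed image and held
    fixed for all perturbations.
    """
    wh, ww = window_spec.height_px, window_spec.width_px
    ah, aw = ensemble.architecture.input_shape
    if (wh, ww) != (ah, aw):
        raise ValueError(f"window {wh}x{ww} does not match ensemble input "
                         f"{ah}x{aw}")
    if cfg.inference_mode == "sliding_window":
        return _sliding_window_map(ensemble, image, window_spec, cfg, chunk)

    img = image.pixels.astype(np.float64)
    h, w = img.shape
    r0, c0 = window_placement(image, window_spec)
    r1, c1 = r0 + wh, c0 + ww
    base_window = img[r0:r1, c0:c1]
    baseline = float(predict_rit_batch(ensemble, base_window[None] / 255.0)[0])

    rows = np.arange(0, h, cfg.stride_px)
    cols = np.arange(0, w, cfg.stride_px)
    delta = np.zeros((len(rows), len(cols)))
    evaluated = np.zeros((len(rows), len(cols)), dtype=bool)

    pending: list[tuple[int, int]] = []       # (grid_i, grid_j)
    batch: list[np.ndarray] = []

    def flush() -> None:
        if not batch:
            return
        preds = predict_rit_batch(ensemble, np.stack(batch) / 255.0, chunk)
        for (gi, gj), pred in zip(pending, preds):
            delta[gi, gj] = pred - baseline
            evaluated[gi, gj] = True
        pending.clear()
        batch.clear()

    for gi, r in enumerate(rows):
        for gj, c in enumerate(cols):
            pr0, pr1, pc0, pc1 = _patch_bounds((r, c), cfg, img.shape)
            ir0, ir1 = max(pr0, r0), min(pr1, r1)
            ic0, ic1 = max(pc0, c0), min(pc1, c1)
            if ir0 >= ir1 or ic0 >= ic1:
                continue  # patch disjoint from window footprint: delta = 0
            block = _fill_block(img[pr0:pr1, pc0:pc1], cfg, (r, c))
            sub = block[ir0 - pr0:ir1 - pr0, ic0 - pc0:ic1 - pc0]
            if np.array_equal(sub, base_window[ir0 - r0:ir1 - r0,
                                               ic0 - c0:ic1 - c0]):
                evaluated[gi, gj] = True  # identity perturbation: exact 0
                continue
            modified = base_window.copy()
            modified[ir0 - r0:ir1 - r0, ic0 - c0:ic1 - c0] = sub
            pending.append((gi, gj))
            batch.append(modified)
            if len(batch) >= chunk:
                flush()
    flush()
    return OcclusionMap(delta_rit_minutes=delta, rows=rows, cols=cols,
                        evaluated=evaluated, baseline_rit_minutes=baseline,
                        config=cfg, window_origin=(r0, c0),
                        image_shape=(h, w))


def _sliding_window_map(ensemble: ModelEnsemble, image: BScanImage,
                        window_spec: WindowSpec, cfg: OcclusionConfig,
                        chunk: int) -> OcclusionMap:
    """Full-width map: the window is re-centered laterally at each occlusion
    column (clamped at the borders); vertical placement and per-placement
    baselines come from the unperturbed image."""
    from .registration import compute_vertical_center

    img = image.pixels.astype(np.float64)
    h, w = img.shape
    wh, ww = window_spec.height_px, window_spec.width_px
    rows = np.arange(0, h, cfg.stride_px)
    cols = np.arange(0, w, cfg.stride_px)
    delta = np.zeros((len(rows), len(cols)))
    evaluated = np.zeros((len(rows), len(cols)), dtype=bool)

    placements: dict[int, tuple[int, float]] = {}  # c0 -> (r0, baseline)

    def placement_for(col: int) -> tuple[int, int, float]:
        c0 = int(np.clip(col - ww // 2, 0, w - ww))
        if c0 not in placements:
            v = compute_vertical_center(image, (c0, c0 + ww))
            r0 = int(np.clip(v - wh // 2, 0, h - wh))
            base = float(predict_rit_batch(
                ensemble, img[r0:r0 + wh, c0:c0 + ww][None] / 255.0)[0])
            placements[c0] = (r0, base)
        r0, base = placements[c0]
        return c0, r0, base

    for gj, c in enumerate(cols):
        c0, r0, base = placement_for(int(c))
        r1, c1 = r0 + wh, c0 + ww
        batch, pending = [], []
        for gi, r in enumerate(rows):
            pr0, pr1, pc0, pc1 = _patch_bounds((int(r), int(c)), cfg, img.shape)
            ir0, ir1 = max(pr0, r0), min(pr1, r1)
            ic0, ic1 = max(pc0, c0), min(pc1, c1)
            if ir0 >= ir1 or ic0 >= ic1:
                evaluated[gi, gj] = True  # evaluated trivially: delta 0
                continue
            block = _fill_block(img[pr0:pr1, pc0:pc1], cfg, (int(r), int(c)))
            sub = block[ir0 - pr0:ir1 - pr0, ic0 - pc0:ic1 - pc0]
            if np.array_equal(sub, img[ir0:ir1, ic0:ic1]):
                evaluated[gi, gj] = True  # identity perturbation: exact 0
                continue
            modified = img[r0:r1, c0:c1].copy()
            modified[ir0 - r0:ir1 - r0, ic0 - c0:ic1 - c0] = sub
            batch.append(modified)
            pending.append(gi)
        if batch:
            preds = predict_rit_batch(ensemble, np.stack(batch) / 255.0, chunk)
            for gi, pred in zip(pending, preds):
                delta[gi, gj] = pred - base
                evaluated[gi, gj] = True
    r0_center, c0_center = window_placement(image, window_spec)
    return OcclusionMap(delta_rit_minutes=delta, rows=rows, cols=cols,
                        evaluated=evaluated,
                        baseline_rit_minutes=placements[min(
                            placements, key=lambda k: abs(k - c0_center))][1],
                        config=cfg, window_origin=(r0_center, c0_center),
                        image_shape=(h, w))


def sensitivity_suite(ensemble: ModelEnsemble, images: list[BScanImage],
                      window_spec: WindowSpec,
                      base_cfg: OcclusionConfig) -> pd.DataFrame:
    """Robustness of the map to fill rule and patch size.

    Recomputes maps under fill in {mean, zero, permute} at the base patch
    size and under mean fill at half/double patch sizes, then reports the
    pairwise Spearman correlation of |delta| over jointly evaluated
    positions, averaged across images.  Zero-variance (degenerate) pairs
    yield NaN and are flagged.
    """
    if not images:
        raise ValueError("need at least one image")
    variants: dict[str, OcclusionConfig] = {}
    for fill in FILLS:
        name = f"{fill}_{base_cfg.patch_w_px}x{base_cfg.patch_h_px}"
        variants[name] = OcclusionConfig(
            patch_w_px=base_cfg.patch_w_px, patch_h_px=base_cfg.patch_h_px,
            fill=fill, stride_px=base_cfg.stride_px,
            inference_mode=base_cfg.inference_mode,
            permute_seed=base_cfg.permute_seed)
    for scale in (0.5, 2.0):
        pw = max(int(round(base_cfg.patch_w_px * scale)), 1)
        ph = max(int(round(base_cfg.patch_h_px * scale)), 1)
        variants[f"mean_{pw}x{ph}"] = OcclusionConfig(
            patch_w_px=pw, patch_h_px=ph, fill="mean",
            stride_px=base_cfg.stride_px,
            inference_mode=base_cfg.inference_mode)

    maps = {name: [occlusion_map(ensemble, img, window_spec, cfg)
                   for img in images]
            for name, cfg in variants.items()}
    records = []
    for name_a, name_b in combinations(variants, 2):
        rhos = []
        degenerate = False
        for map_a, map_b in zip(maps[name_a], maps[name_b]):
            joint = map_a.evaluated & map_b.evaluated
            va = np.abs(map_a.delta_rit_minutes[joint])
            vb = np.abs(map_b.delta_rit_minutes[joint])
            if va.size < 2 or np.ptp(va) == 0 or np.ptp(vb) == 0:
                degenerate = True
                continue
            rhos.append(float(stats.spearmanr(va, vb).statistic))
        records.append({"variant_a": name_a, "variant_b": name_b,
                        "spearman_abs_delta": float(np.mean(rhos)) if rhos
                        else float("nan"),
                        "degenerate": degenerate and not rhos})
    return pd.DataFrame.from_records(records)


def render_overlay(omap: OcclusionMap, image: BScanImage) -> np.ndarray:
    """Diverging overlay on the grayscale B-scan: red where occlusion
    lengthens the predicted RIT, blue where it shortens it; opacity scales
    with |delta| relative to the map's 99th-percentile magnitude."""
    if omap.image_shape != image.pixels.shape:
        raise ValueError(f"map built for image shape {omap.image_shape}, "
                         f"got {image.pixels.shape}")
    gray = image.pixels.astype(np.float64)
    rgb = np.stack([gray, gray, gray], axis=-1)
    delta = omap.full_resolution()
    magnitudes = np.abs(omap.delta_rit_minutes[omap.evaluated])
    scale = float(np.percentile(magnitudes, 99)) if magnitudes.size else 0.0
    if scale == 0.0 and magnitudes.size:  # nearly-sparse map: use the max
        scale = float(magnitudes.max())
    if scale > 0:
        alpha = np.clip(np.abs(delta) / scale, 0.0, 1.0)
        red = np.array([255.0, 0.0, 0.0])
        blue = np.array([0.0, 0.0, 255.0])
        color = np.where((delta > 0)[..., None], red, blue)
        mask = (delta != 0)[..., None]
        blended = (1 - alpha[..., None]) * rgb + alpha[..., None] * color
        rgb = np.where(mask, blended, rgb)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
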