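"""Whole-image inference: tiling, stitching, softmax ensembling, decoding.

A large image is sliced into fixed-size tiles, each tile is pushed
through a network, and the per-pixel probability outputs are stitched
back together.  Stitching is interior-crop: tiles overlap by a margin,
but every pixel's probability vector is taken from the single tile
whose interior contains it, so the stitched map is independent of tile
traversal order and of the overlap (away from the image border).
Overlap-averaging is available behind a flag.

The two network families are combined by taking the arithmetic mean of
their per-pixel softmax outputs; the class with the highest ensemble
probability wins, ties broken toward the lowest class id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .taxonomy import ClassTaxonomy

__all__ = [
    "ProbabilityMap",
    "TilingPlan",
    "plan_tiles",
    "predict_map",
    "ensemble_average",
    "decode",
]

_SIMPLEX_ATOL = 1e-5


@dataclass
class ProbabilityMap:
    values: np.ndarray  # (H, W, K) float64 on the simplex
    spacing: float
    case_id: str
    source: str  # "u-net" | "dense-net" | "ensemble" | stub tag

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError("probability map must be (H, W, K)")
        if (v < -_SIMPLEX_ATOL).any() or (v > 1 + _SIMPLEX_ATOL).any():
            raise ValueError("probabilities must lie in [0, 1]")
        sums = v.sum(axis=-1)
        if np.abs(sums - 1.0).max() > _SIMPLEX_ATOL:
            raise ValueError("per-pixel probabilities must sum to 1")
        self.values = v


@dataclass
class TilingPlan:
    tile_size: int
    overlap: int
    origins: list[tuple[int, int]]  # interior origins (row, col)
    interior_shape: list[tuple[int, int]]  # interior extent per tile
    image_shape: tuple[int, int]


def plan_tiles(
    image_shape: tuple[int, int], tile_size: int, overlap: int = 0
) -> TilingPlan:
    """Plan a tiling whose interiors exactly partition the image.

    Each tile spans ``tile_size`` pixels; its interior is the tile minus
    an ``overlap`` margin on every side.  Interiors are laid out on a
    grid of stride ``tile_size − 2·overlap``; tiles extending past the
    image are mirror-padded at prediction time.  An image smaller than
    one interior yields a single padded tile.
    """
    if overlap < 0 or tile_size < 2 * overlap + 1:
        raise ValueError("tile size must be at least 2*overlap + 1")
    h, w = image_shape
    step = tile_size - 2 * overlap
    origins, interiors = [], []
    for r in range(0, h, step):
        for c in range(0, w, step):
            origins.append((r, c))
            interiors.append((min(step, h - r), min(step, w - c)))
    return TilingPlan(tile_size, overlap, origins, interiors, (h, w))


def predict_map(
    model,
    image_pixels: np.ndarray,
    plan: TilingPlan,
    spacing: float = 0.5,
    case_id: str = "",
    average_overlap: bool = False,
) -> ProbabilityMap:
    """Stitch per-tile model outputs into a whole-image probability map.

    ``model`` must expose ``predict_proba((1,H,W,3)) -> (1,H,W,K)`` on
    the simplex; a violation of that contract is an error.  ``image_pixels``
    is (H, W, 3) in [0, 1] float (uint8 accepted and scaled).
    """
    px = np.asarray(image_pixels)
    if px.dtype == np.uint8:
        px = px.astype(np.float32) / 255.0
    h, w = plan.image_shape
    if px.shape[:2] != (h, w):
        raise ValueError("image does not match tiling plan")
    t, ov = plan.tile_size, plan.overlap
    pad = ov + t  # generous mirror pad so any tile window is in range
    padded = np.pad(px, ((pad, pad), (pad, pad), (0, 0)), mode="symmetric")
    k = None
    out = None
    weight = None
    for (r, c), (ih, iw) in zip(plan.origins, plan.interior_shape):
        r0, c0 = r - ov + pad, c - ov + pad
        tile = padded[r0: r0 + t, c0: c0 + t]
        probs = np.asarray(model.predict_proba(tile[None]))[0].astype(np.float64)
        if probs.shape[:2] != (t, t):
            raise ValueError("model output does not preserve tile shape")
        if np.abs(probs.sum(axis=-1) - 1.0).max() > _SIMPLEX_ATOL:
            raise ValueError("model violated the softmax output contract")
        if out is None:
            k = probs.shape[-1]
            out = np.zeros((h, w, k))
            weight = np.zeros((h, w, 1))
        if average_overlap:
            rr0, cc0 = max(r - ov, 0), max(c - ov, 0)
            rr1, cc1 = min(r + ih + ov, h), min(c + iw + ov, w)
            out[rr0:rr1, cc0:cc1] += probs[
                ov + (rr0 - r): ov + (rr1 - r), ov + (cc0 - c): ov + (cc1 - c)
            ]
            weight[rr0:rr1, cc0:cc1] += 1.0
        else:
            out[r: r + ih, c: c + iw] = probs[ov: ov + ih, ov: ov + iw]
    if average_overlap:
        out = out / weight
    return ProbabilityMap(out, spacing, case_id, getattr(model, "source", "model"))


def ensemble_average(maps: list[ProbabilityMap]) -> ProbabilityMap:
    """Per-pixel arithmetic mean of probability maps (softmax ensembling)."""
    if not maps:
        raise ValueError("need at least one probability map")
    shape = maps[0].values.shape
    spacing = maps[0].spacing
    for m in maps[1:]:
        if m.values.shape != shape:
            raise ValueError(f"shape mismatch: {m.values.shape} vs {shape}")
        if m.spacing != spacing:
            raise ValueError("probability maps must share pixel spacing")
    mean = np.mean([m.values for m in maps], axis=0)
    return ProbabilityMap(mean, spacing, maps[0].case_id, "ensemble")


def decode(prob_map: ProbabilityMap) -> np.ndarray:
    """Arg-max label map; exact ties go to the lowest class id."""
    return np.argmax(prob_map.values, axis=-1).astype(np.uint8)


def save_probability_map(prob_map: ProbabilityMap, path) -> None:
    """Write a probability map as multi-channel TIFF."""
    import tifffile

    tifffile.imwrite(path, prob_map.values.astype(np.float32))


def save_label_map(labels: np.ndarray, taxonomy: ClassTaxonomy, path) -> None:
    """Write a label map as single-channel PNG plus an id-mapping sidecar."""
    import json
    from pathlib import Path

    from PIL import Image

    Image.fromarray(labels.astype(np.uint8)).save(path)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps({c.name: c.id for c in taxonomy.classes}))
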