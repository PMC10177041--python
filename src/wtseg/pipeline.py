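"""End-to-end experiment orchestration on synthetic cohorts.

Generates a cohort, performs the case-exclusive 70/15/15 split, trains
the U-Net and the DenseNet on training-partition annotations, produces
tiled whole-image probability maps for the held-out test cases,
ensembles the two networks by per-pixel softmax averaging, and scores
everything against the rasterized test annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet, LabeledImage, split_by_case
from .evaluation import ConfusionMatrix, confusion, macro_dice, pooled_metrics
from .inference import ProbabilityMap, decode, ensemble_average, plan_tiles, predict_map
from .networks import DEFAULT_PATCH_SHAPES, NetworkSpec, build_network
from .patches import AugmentationConfig, PatchSpec, resample_image
from .synthetic import CohortConfig, generate_cases
from .taxonomy import ClassTaxonomy, build_default_taxonomy
from .training import PatchSampler, TrainingConfig, TrainingHistory, train

__all__ = ["RecoveryResult", "run_recovery_experiment", "evaluate_cases"]

logger = logging.getLogger(__name__)

#: batch size per family, following the published recipe
BATCH_SIZES = {"u-net": 4, "dense-net": 16}


@dataclass
class RecoveryResult:
    overall_dice: dict[str, float]  # source -> micro Dice (= accuracy)
    macro_dice: dict[str, float]  # source -> mean per-class Dice
    confusions: dict[str, ConfusionMatrix]
    histories: dict[str, TrainingHistory]
    split_fractions: tuple[float, float, float]


def _partition_images(
    images: list[LabeledImage], annset: AnnotationSet, seed: int
) -> tuple[dict[str, list[LabeledImage]], tuple[float, float, float]]:
    split = split_by_case(annset, (0.70, 0.15, 0.15), seed)
    by_case = {im.case_id: im for im in images}
    parts = {
        p: [by_case[c] for c in sorted(split.cases_in(p))]
        for p in ("train", "validation", "test")
    }
    counts = {p: sum(len(annset.for_case(im.case_id)) for im in ims)
              for p, ims in parts.items()}
    total = max(sum(counts.values()), 1)
    fracs = tuple(counts[p] / total for p in ("train", "validation", "test"))
    return parts, fracs


def evaluate_cases(
    maps: dict[str, list[ProbabilityMap]],
    truths: list[np.ndarray],
    taxonomy: ClassTaxonomy,
) -> tuple[dict[str, float], dict[str, float], dict[str, ConfusionMatrix]]:
    """Pool confusion over cases and score each prediction source."""
    overall, macro, cms = {}, {}, {}
    for source, mlist in maps.items():
        cm = None
        for m, truth in zip(mlist, truths):
            c = confusion(truth, decode(m), taxonomy)
            cm = c if cm is None else cm + c
        cms[source] = cm
        overall[source] = pooled_metrics(cm, list(range(taxonomy.n_classes)))[2]
        macro[source] = macro_dice(cm)
    return overall, macro, cms


def run_recovery_experiment(
    seed: int,
    n_cases: int = 20,
    image_size: int = 256,
    difficulty: float = 0.0,
    epochs: int = 10,
    iterations: int = 50,
    preset: str = "tiny",
    base_spacing: float = 0.5,
    coverage: float = 0.7,
    tile_overlap: int | None = None,
) -> RecoveryResult:
    """Full two-network recovery run on a synthetic cohort.

    Every random stream (cohort, split, both trainings, validation)
    derives from ``seed``.  Returns pooled test-set metrics for each
    network and the softmax-average ensemble.
    """
    taxonomy = build_default_taxonomy()
    cfg = CohortConfig(
        n_cases=n_cases,
        image_size=image_size,
        base_spacing=base_spacing,
        difficulty=difficulty,
        coverage=coverage,
        seed=seed,
    )
    images, annset = generate_cases(cfg, taxonomy=taxonomy)
    parts, fracs = _partition_images(images, annset, seed)
    logger.info("split fractions (annotations): %s", fracs)

    aug = AugmentationConfig()
    histories: dict[str, TrainingHistory] = {}
    models = {}
    for family in ("u-net", "dense-net"):
        shape = DEFAULT_PATCH_SHAPES[(family, preset)]
        spec = PatchSpec(shape=shape, spacing=0.5, class_balanced=True)
        sampler = PatchSampler(parts["train"], spec, aug)
        val_sampler = PatchSampler(parts["validation"], spec, None)
        net = build_network(
            NetworkSpec(family, shape, taxonomy.n_classes, preset, seed=seed)
        )
        tcfg = TrainingConfig(
            epochs=epochs,
            iterations_per_epoch=iterations,
            batch_size=BATCH_SIZES[family],
            seed=seed,
        )
        net, hist = train(net, sampler, val_sampler, tcfg)
        models[family] = net
        histories[family] = hist

    # held-out prediction at the shared working resolution
    test_images = [resample_image(im, 0.5) for im in parts["test"]]
    truths = [im.labels for im in test_images]
    maps: dict[str, list[ProbabilityMap]] = {f: [] for f in models}
    for family, net in models.items():
        tile = DEFAULT_PATCH_SHAPES[(family, preset)][0]
        overlap = tile // 4 if tile_overlap is None else tile_overlap
        for im in test_images:
            plan = plan_tiles(im.labels.shape, tile, overlap)
            maps[family].append(
                predict_map(net, im.pixels, plan, 0.5, im.case_id)
            )
    maps["ensemble"] = [
        ensemble_average([maps["u-net"][i], maps["dense-net"][i]])
        for i in range(len(test_images))
    ]
    overall, macro, cms = evaluate_cases(maps, truths, taxonomy)
    logger.info("overall Dice: %s | macro Dice: %s", overall, macro)
    return RecoveryResult(overall, macro, cms, histories, fracs)
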