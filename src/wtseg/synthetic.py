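"""Synthetic H&E-like cohort generator.

Real post-chemotherapy nephroblastoma slides are not publicly
distributable, so the pipeline is exercised on generated images that
reproduce the *statistical* structure the analysis assumes: each case is
an RGB image partitioned into polygonal regions drawn from the 15
tissue classes, every class has a distinctive color/texture signature
(base stain color, nuclear density/size/elongation, noise), and only a
random subset of regions is exported as polygon annotations — the
annotation sparsity of real cohorts.  The full dense mask is kept as
evaluation ground truth.

Region layout is a seeded Voronoi tessellation of uniform random sites,
clipped to the image, which yields simple polygons directly exportable
to the annotation XML dialect.  A ``difficulty`` dial in [0, 1] shrinks
the color separation of class pairs that are genuinely confusable in
real tissue (epithelium vs. blastema, mesenchyme vs. stroma, regression
vs. stroma) and raises pixel noise, so recovery experiments can probe
easy and hard regimes.  A per-case quota forces every class to appear,
keeping per-class metrics defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram
from skimage.draw import ellipse as draw_ellipse

from .annotations import (
    AnnotationSet,
    CaseRecord,
    LabeledImage,
    PolygonAnnotation,
    rasterize,
    write_annotations,
)
from .taxonomy import UNANNOTATED, ClassTaxonomy, build_default_taxonomy

__all__ = [
    "TextureModel",
    "CohortConfig",
    "default_texture_models",
    "generate_case",
    "generate_cases",
    "generate_cohort",
    "MIN_COLOR_SEPARATION",
]

#: Minimum pairwise distance between class color means at difficulty 0.
MIN_COLOR_SEPARATION = 30.0


@dataclass
class TextureModel:
    """Visual signature of one tissue class."""

    class_id: int
    base_color: np.ndarray  # mean RGB, float (3,)
    color_cov: np.ndarray  # 3x3 covariance of per-region color jitter
    nuclear_density: float  # expected nuclei per pixel of region area
    nucleus_size: tuple[float, float]  # mean, sd of semi-minor axis (px)
    nucleus_color: np.ndarray  # mean RGB
    anisotropy: float  # semi-major / semi-minor elongation
    noise_sd: float  # per-pixel gaussian noise

    def __post_init__(self) -> None:
        self.base_color = np.clip(np.asarray(self.base_color, float), 0, 255)
        self.nucleus_color = np.clip(np.asarray(self.nucleus_color, float), 0, 255)
        self.color_cov = np.asarray(self.color_cov, float)
        if self.nuclear_density < 0 or self.noise_sd < 0:
            raise ValueError("densities and noise must be non-negative")
        if min(self.nucleus_size) < 0:
            raise ValueError("nucleus size must be non-negative")


@dataclass
class CohortConfig:
    n_cases: int = 20
    image_size: int = 256
    base_spacing: float = 0.24  # μm/pixel
    regions_per_case: int = 30
    class_weights: np.ndarray | None = None  # None = uniform over 15
    difficulty: float = 0.0
    coverage: float = 0.7  # fraction of regions exported as annotations
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, float)
            if w.min() < 0 or w.sum() <= 0:
                raise ValueError("class weights must be non-negative, not all 0")
            self.class_weights = w / w.sum()


# Base stain colors at difficulty 0, one per class in taxonomy order.
# Chosen H&E-like: basophilic (purple) cellular components, eosinophilic
# (pink) stroma/necrosis, erythrocyte red for bleeding, pale fat.
_BASE_COLORS = np.array(
    [
        (95, 60, 150),  # Blastema: dense basophilic
        (235, 170, 195),  # Stroma: eosinophilic pink
        (165, 105, 175),  # Epithelium: violet
        (235, 205, 155),  # Necrosis: amorphous eosinophilic
        (195, 55, 55),  # Bleeding: erythrocyte red
        (245, 215, 225),  # Regression: pale paucicellular pink
        (150, 150, 200),  # Glomeruli
        (205, 125, 135),  # Tubules
        (250, 245, 250),  # Fat: near-white
        (200, 200, 160),  # Mesenchyme / connective tissue
        (150, 40, 90),  # Vessels
        (230, 190, 120),  # Nerves
        (110, 110, 190),  # Lymph nodes
        (170, 200, 230),  # Urothelium
        (60, 120, 110),  # Nephrogenic rest
    ],
    dtype=float,
)

# (mover, target): at difficulty 1 the mover's color mean reaches the
# target's, emulating the pairs that are confusable in real tissue.
_CONFUSABLE = {"Epithelium": "Blastema", "Mesenchyme": "Stroma",
               "Regression": "Stroma"}

# nuclear density (per px), size mean/sd, anisotropy per class
_NUCLEI = {
    "Blastema": (0.060, 1.6, 0.3, 1.2),
    "Stroma": (0.008, 2.0, 0.4, 3.0),
    "Epithelium": (0.030, 2.2, 0.4, 1.3),
    "Necrosis": (0.0, 2.0, 0.3, 1.0),
    "Bleeding": (0.0, 2.0, 0.3, 1.0),
    "Regression": (0.003, 2.0, 0.4, 2.0),
    "Glomeruli": (0.040, 1.8, 0.3, 1.2),
    "Tubules": (0.020, 2.0, 0.3, 1.4),
    "Fat": (0.002, 1.8, 0.3, 1.5),
    "Mesenchyme": (0.010, 1.9, 0.4, 2.5),
    "Vessels": (0.012, 1.9, 0.3, 2.0),
    "Nerves": (0.010, 1.8, 0.3, 2.5),
    "Lymph nodes": (0.070, 1.5, 0.3, 1.1),
    "Urothelium": (0.030, 2.0, 0.4, 1.5),
    "Nephrogenic rest": (0.050, 1.7, 0.3, 1.2),
}


def default_texture_models(
    taxonomy: ClassTaxonomy | None = None, difficulty: float = 0.0
) -> list[TextureModel]:
    """One texture model per evaluated class.

    At difficulty 0 all color means are separated by at least
    :data:`MIN_COLOR_SEPARATION`; at difficulty 1 the confusable pairs
    share a color mean and noise is doubled.
    """
    taxonomy = taxonomy or build_default_taxonomy()
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError("difficulty must lie in [0, 1]")
    colors = _BASE_COLORS.copy()
    for mover, target in _CONFUSABLE.items():
        i, j = taxonomy.class_of(mover), taxonomy.class_of(target)
        colors[i] = (1 - difficulty) * colors[i] + difficulty * colors[j]
    noise = 6.0 * (1.0 + difficulty)
    models = []
    for c in taxonomy.classes:
        dens, sz, sz_sd, aniso = _NUCLEI[c.name]
        dark = np.array([60, 40, 110], float)  # hematoxylin-dark nuclei
        models.append(
            TextureModel(
                class_id=c.id,
                base_color=colors[c.id],
                color_cov=np.eye(3) * 16.0,
                nuclear_density=dens,
                nucleus_size=(sz, sz_sd),
                nucleus_color=dark,
                anisotropy=aniso,
                noise_sd=noise,
            )
        )
    return models


def _voronoi_regions(sites: np.ndarray, size: int) -> list[np.ndarray]:
    """Clipped Voronoi cell polygons, ordered like ``sites``."""
    env = box(0.0, 0.0, float(size), float(size))
    cells = voronoi_diagram(MultiPoint(sites.tolist()), envelope=env)
    polys: list[np.ndarray | None] = [None] * len(sites)
    for geom in cells.geoms:
        clipped = geom.intersection(env)
        if clipped.is_empty:
            continue
        for i, s in enumerate(sites):
            if polys[i] is None and geom.contains(Point(s)):
                polys[i] = np.asarray(clipped.exterior.coords[:-1], float)
                break
    if any(p is None for p in polys):  # degenerate tessellation
        raise RuntimeError("voronoi tessellation failed to cover all sites")
    return polys  # type: ignore[return-value]


def _region_classes(
    config: CohortConfig, n_classes: int, rng: np.random.Generator
) -> np.ndarray:
    w = (
        config.class_weights
        if config.class_weights is not None
        else np.full(n_classes, 1.0 / n_classes)
    )
    n = config.regions_per_case
    labels = rng.choice(n_classes, size=n, p=w)
    # per-case quota: every class appears at least once (when room allows)
    quota = rng.permutation(n_classes)[: min(n, n_classes)]
    slots = rng.permutation(n)[: len(quota)]
    labels[slots] = quota
    return labels


def generate_case(
    config: CohortConfig,
    texture_models: list[TextureModel],
    case_index: int,
) -> tuple[LabeledImage, list[PolygonAnnotation]]:
    """Generate one case: rendered image, dense mask and sparse polygons.

    Deterministic given (config.seed, case_index).  The returned
    :class:`LabeledImage` carries the sparse annotation rasterization in
    ``labels`` and the full dense ground truth in ``dense_labels``.
    """
    rng = np.random.default_rng([config.seed, case_index])
    size = config.image_size
    case_id = f"case_{case_index:03d}"
    n = config.regions_per_case

    sites = rng.uniform(1.0, size - 1.0, size=(n, 2))
    polys = _voronoi_regions(sites, size)
    classes = _region_classes(config, len(texture_models), rng)

    all_annotations = [
        PolygonAnnotation(case_id, int(classes[i]), [tuple(v) for v in polys[i]], i)
        for i in range(n)
    ]
    record = CaseRecord(case_id, spacing=config.base_spacing)
    full_set = AnnotationSet(all_annotations, [record])
    dense = rasterize(full_set, case_id, (size, size))
    # pixel centers exactly on shared cell edges stay unlabeled; assign
    # them to the nearest labeled pixel so the ground truth is dense
    if (dense == UNANNOTATED).any():
        _, (ir, ic) = ndimage.distance_transform_edt(
            dense == UNANNOTATED, return_indices=True
        )
        dense = dense[ir, ic]

    region_ids = _region_id_map(full_set, case_id, size)
    pixels = _render(dense, region_ids, classes, texture_models, rng)

    n_annotated = max(1, int(np.ceil(config.coverage * n)))
    keep = np.sort(rng.permutation(n)[:n_annotated])
    annotations = [all_annotations[i] for i in keep]
    sparse = rasterize(AnnotationSet(annotations, [record]), case_id, (size, size))

    image = LabeledImage(
        pixels=pixels,
        labels=sparse,
        spacing=config.base_spacing,
        case_id=case_id,
        dense_labels=dense,
    )
    return image, annotations


def _region_id_map(
    annset: AnnotationSet, case_id: str, size: int
) -> np.ndarray:
    """Rasterize annotation ids (not classes) for per-region rendering."""
    remap = AnnotationSet(
        [
            PolygonAnnotation(a.case_id, 0, a.vertices, a.annotation_id)
            for a in annset.annotations
        ],
        annset.cases,
    )
    ids = np.full((size, size), -1, dtype=np.int32)
    for a in sorted(annset.annotations, key=lambda a: a.annotation_id):
        one = AnnotationSet(
            [PolygonAnnotation(a.case_id, 0, a.vertices, a.annotation_id)],
            annset.cases,
        )
        m = rasterize(one, case_id, (size, size))
        ids[m != UNANNOTATED] = a.annotation_id
    if (ids < 0).any():
        _, (ir, ic) = ndimage.distance_transform_edt(ids < 0, return_indices=True)
        ids = ids[ir, ic]
    return ids


def _render(
    dense: np.ndarray,
    region_ids: np.ndarray,
    classes: np.ndarray,
    models: list[TextureModel],
    rng: np.random.Generator,
) -> np.ndarray:
    size = dense.shape[0]
    img = np.zeros((size, size, 3), dtype=float)
    by_id = {m.class_id: m for m in models}
    for rid in range(len(classes)):
        mask = region_ids == rid
        area = int(mask.sum())
        if area == 0:
            continue
        tm = by_id[int(classes[rid])]
        col = rng.multivariate_normal(tm.base_color, tm.color_cov)
        img[mask] = np.clip(col, 0, 255)
        # nuclei as filled ellipses with Poisson counts
        count = rng.poisson(tm.nuclear_density * area)
        if count:
            rows, cols_ = np.nonzero(mask)
            pick = rng.integers(0, area, size=count)
            sizes = np.maximum(
                rng.normal(tm.nucleus_size[0], tm.nucleus_size[1], count), 0.6
            )
            angles = rng.uniform(0, np.pi, count)
            jitter = rng.normal(0, 10, size=(count, 3))
            for j in range(count):
                rr, cc = draw_ellipse(
                    rows[pick[j]],
                    cols_[pick[j]],
                    sizes[j] * tm.anisotropy,
                    sizes[j],
                    shape=(size, size),
                    rotation=angles[j],
                )
                img[rr, cc] = np.clip(tm.nucleus_color + jitter[j], 0, 255)
    noise_sd = np.array([by_id[int(c)].noise_sd for c in dense.ravel()])
    img += rng.standard_normal(img.shape) * noise_sd.reshape(size, size, 1)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_cases(
    config: CohortConfig,
    texture_models: list[TextureModel] | None = None,
    taxonomy: ClassTaxonomy | None = None,
) -> tuple[list[LabeledImage], AnnotationSet]:
    """Generate the whole cohort in memory."""
    taxonomy = taxonomy or build_default_taxonomy()
    models = texture_models or default_texture_models(taxonomy, config.difficulty)
    images, annotations, cases = [], [], []
    offset = 0
    for i in range(config.n_cases):
        img, anns = generate_case(config, models, i)
        # cohort-unique annotation ids, preserving per-case order
        anns = [
            PolygonAnnotation(a.case_id, a.class_id, a.vertices,
                              a.annotation_id + offset)
            for a in anns
        ]
        offset += config.regions_per_case
        images.append(img)
        annotations.extend(anns)
        cases.append(CaseRecord(img.case_id, spacing=config.base_spacing))
    return images, AnnotationSet(annotations, cases)


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path,
    taxonomy: ClassTaxonomy | None = None,
) -> AnnotationSet:
    """Generate and write a cohort: images, annotation XML, dense masks
    and a manifest.  Returns the in-memory annotation set, which equals
    the set re-read from disk."""
    taxonomy = taxonomy or build_default_taxonomy()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, annset = generate_cases(config, taxonomy=taxonomy)
    entries = []
    for img in images:
        img_name = f"{img.case_id}.png"
        xml_name = f"{img.case_id}.xml"
        mask_name = f"{img.case_id}_mask.png"
        Image.fromarray(img.pixels).save(out / img_name)
        Image.fromarray(img.dense_labels).save(out / mask_name)
        write_annotations(out / xml_name, annset.for_case(img.case_id), taxonomy)
        entries.append(
            {
                "case_id": img.case_id,
                "image": img_name,
                "annotations": xml_name,
                "mask": mask_name,
                "spacing": config.base_spacing,
            }
        )
    manifest = {"spacing": config.base_spacing, "cases": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    taxonomy.save(out / "taxonomy.yaml")
    return annset
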