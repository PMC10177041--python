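"""Tissue-class taxonomy for Wilms-tumor (nephroblastoma) segmentation.

Post-chemotherapy Wilms tumor specimens are annotated with a fixed
vocabulary of tissue components.  Fifteen classes are modeled; four
further annotation classes (background, anaplasia and the two adrenal
components) are recognized but excluded from modeling.  Two clinically
meaningful groups — the vital tumor components and the
chemotherapy-induced changes — and a coarser tumor / non-tumor partition
are carried alongside the class list so that every pipeline stage shares
one label vocabulary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "TissueClass",
    "ClassTaxonomy",
    "build_default_taxonomy",
    "UnknownClassError",
]

#: Reserved label value for pixels carrying no annotation.
UNANNOTATED = 255

# Evaluated classes in canonical report order.  The id is the position.
_CLASS_NAMES = (
    "Blastema",
    "Stroma",
    "Epithelium",
    "Necrosis",
    "Bleeding",
    "Regression",
    "Glomeruli",
    "Tubules",
    "Fat",
    "Mesenchyme",
    "Vessels",
    "Nerves",
    "Lymph nodes",
    "Urothelium",
    "Nephrogenic rest",
)

_EXCLUDED = ("Background", "Anaplasia", "Adrenal medulla", "Adrenal cortex")

_GROUPS = {
    "vital tumor components": ("Blastema", "Stroma", "Epithelium"),
    "chemotherapy-induced changes": ("Necrosis", "Bleeding", "Regression"),
}

# Coarse partition used for optional auxiliary supervision.  Membership of
# the chemotherapy-induced classes and nephrogenic rest on the tumor side
# is a configuration choice and can be overridden via the serialized form.
_OVERARCHING = {
    "tumor": (
        "Blastema",
        "Stroma",
        "Epithelium",
        "Necrosis",
        "Bleeding",
        "Regression",
        "Nephrogenic rest",
    ),
    "non-tumor": (
        "Glomeruli",
        "Tubules",
        "Fat",
        "Mesenchyme",
        "Vessels",
        "Nerves",
        "Lymph nodes",
        "Urothelium",
    ),
}

# Alternative spellings accepted by :meth:`ClassTaxonomy.class_of`.
_ALIASES = {
    "wt-blastema": "Blastema",
    "wt-stroma": "Stroma",
    "wt-epithelium": "Epithelium",
    "nephrogenic rests": "Nephrogenic rest",
    "lymph node": "Lymph nodes",
    "connective tissue": "Mesenchyme",
    "glomerulus": "Glomeruli",
    "tubule": "Tubules",
}


class UnknownClassError(KeyError):
    """Raised when a name matches no evaluated class or alias."""


@dataclass(frozen=True)
class TissueClass:
    name: str
    id: int
    group: str | None  # fine group tag, None if ungrouped


@dataclass
class ClassTaxonomy:
    """The evaluated class system shared by all pipeline stages.

    ``classes`` is ordered; a class's id equals its position.  ``groups``
    and ``overarching`` map group names to member class ids; ``excluded``
    lists annotation class names that are recognized but never modeled.
    """

    classes: list[TissueClass]
    groups: dict[str, list[int]]
    excluded: list[str]
    overarching: dict[str, list[int]]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.classes]
        if ids != list(range(len(self.classes))):
            raise ValueError("class ids must be contiguous from 0 in order")
        cover = sorted(i for ids_ in self.overarching.values() for i in ids_)
        if cover != list(range(len(self.classes))):
            raise ValueError("overarching labels must partition the classes")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]

    def class_of(self, name_or_alias: str) -> int:
        """Resolve a class name or registered alias to its canonical id.

        Lookup is case-insensitive.  Excluded or unknown names raise
        :class:`UnknownClassError` naming the offender.
        """
        key = name_or_alias.strip().lower()
        canonical = self.aliases.get(key, key).lower()
        for c in self.classes:
            if c.name.lower() == canonical:
                return c.id
        raise UnknownClassError(
            f"unknown or excluded tissue class: {name_or_alias!r}"
        )

    def is_known_excluded(self, name: str) -> bool:
        return name.strip().lower() in (e.lower() for e in self.excluded)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": [
                {"name": c.name, "id": c.id, "group": c.group}
                for c in self.classes
            ],
            "groups": {k: list(v) for k, v in self.groups.items()},
            "excluded": list(self.excluded),
            "overarching": {k: list(v) for k, v in self.overarching.items()},
            "aliases": dict(self.aliases),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassTaxonomy":
        return cls(
            classes=[
                TissueClass(c["name"], c["id"], c.get("group"))
                for c in d["classes"]
            ],
            groups={k: list(v) for k, v in d["groups"].items()},
            excluded=list(d["excluded"]),
            overarching={k: list(v) for k, v in d["overarching"].items()},
            aliases=dict(d.get("aliases", {})),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ClassTaxonomy":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def build_default_taxonomy() -> ClassTaxonomy:
    """Build the default 15-class taxonomy with groups and the coarse
    tumor / non-tumor partition.  Deterministic."""
    group_of = {
        name: gname for gname, members in _GROUPS.items() for name in members
    }
    classes = [
        TissueClass(name, i, group_of.get(name))
        for i, name in enumerate(_CLASS_NAMES)
    ]
    name_to_id = {name: i for i, name in enumerate(_CLASS_NAMES)}
    return ClassTaxonomy(
        classes=classes,
        groups={
            g: [name_to_id[n] for n in members] for g, members in _GROUPS.items()
        },
        excluded=list(_EXCLUDED),
        overarching={
            g: [name_to_id[n] for n in members]
            for g, members in _OVERARCHING.items()
        },
        aliases=dict(_ALIASES),
    )
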