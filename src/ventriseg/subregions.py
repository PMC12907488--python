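"""The twelve ventricular subregion classes and their fixed integer coding.

Class ids 0..11 follow the canonical reporting order (bodies of the lateral
ventricles, midline ventricles, then right- and left-sided horns/atria).
Label volumes store ``id + 1`` per voxel with 0 reserved for background.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SubregionClass:
    """One ventricular subregion: id, canonical name and laterality."""

    id: int
    name: str
    laterality: str  # "left" | "right" | "midline"

    @property
    def label_value(self) -> int:
        """Integer code used in label volumes (background is 0)."""
        return self.id + 1


SUBREGIONS: tuple[SubregionClass, ...] = (
    SubregionClass(0, "body_right_lateral", "right"),
    SubregionClass(1, "body_left_lateral", "left"),
    SubregionClass(2, "third_ventricle", "midline"),
    SubregionClass(3, "fourth_ventricle", "midline"),
    SubregionClass(4, "right_anterior_horn", "right"),
    SubregionClass(5, "right_atrium", "right"),
    SubregionClass(6, "right_posterior_horn", "right"),
    SubregionClass(7, "right_temporal_horn", "right"),
    SubregionClass(8, "left_anterior_horn", "left"),
    SubregionClass(9, "left_atrium", "left"),
    SubregionClass(10, "left_posterior_horn", "left"),
    SubregionClass(11, "left_temporal_horn", "left"),
)

N_CLASSES = len(SUBREGIONS)

NAME_TO_CLASS = {c.name: c for c in SUBREGIONS}

#: id of the mirror-image class under a left/right flip (midline maps to itself)
MIRROR_CLASS = {0: 1, 1: 0, 2: 2, 3: 3, 4: 8, 5: 9, 6: 10, 7: 11,
                8: 4, 9: 5, 10: 6, 11: 7}

#: anatomical structure of each class, used for fusion priority and the
#: posterior-horn model pooling
STRUCTURE = {0: "body", 1: "body", 2: "third", 3: "fourth",
             4: "anterior_horn", 5: "atrium", 6: "posterior_horn",
             7: "temporal_horn", 8: "anterior_horn", 9: "atrium",
             10: "posterior_horn", 11: "temporal_horn"}

#: when several per-subregion models claim the same voxel the rarest/smallest
#: structure wins; lower rank = higher priority
FUSION_PRIORITY = ("posterior_horn", "temporal_horn", "atrium",
                   "anterior_horn", "third", "fourth", "body")

#: volume-report groupings: the sides pool anterior horn, body, atrium and
#: temporal horn; the midline pools third and fourth ventricle
GROUPS = {
    "whole_system": tuple(c.id for c in SUBREGIONS),
    "right_side": (4, 0, 5, 7),
    "left_side": (8, 1, 9, 11),
    "midline": (2, 3),
}


def class_by_name(name: str) -> SubregionClass:
    try:
        return NAME_TO_CLASS[name]
    except KeyError:
        raise KeyError(f"unknown subregion class {name!r}") from None


def fusion_rank(class_id: int) -> int:
    return FUSION_PRIORITY.index(STRUCTURE[class_id])
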