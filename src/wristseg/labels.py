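"""Canonical 15-bone label table for the wrist.

Label ids are small positive integers used in every LabelMap produced by the
pipeline; 0 is always background.  Short names follow the usual radiological
lettering: R radius, U ulna, M1-M5 metacarpals, and A-H for the eight carpals
(scaphoid, lunate, triquetrum, pisiform, trapezium, trapezoid, capitate,
hamate).
"""

from __future__ import annotations

BONE_NAMES: dict[int, str] = {
    1: "R",
    2: "U",
    3: "M1",
    4: "M2",
    5: "M3",
    6: "M4",
    7: "M5",
    8: "A",
    9: "B",
    10: "C",
    11: "D",
    12: "E",
    13: "F",
    14: "G",
    15: "H",
}

BONE_IDS: dict[str, int] = {v: k for k, v in BONE_NAMES.items()}

LONG_NAMES: dict[str, str] = {
    "R": "radius",
    "U": "ulna",
    "M1": "first metacarpal",
    "M2": "second metacarpal",
    "M3": "third metacarpal",
    "M4": "fourth metacarpal",
    "M5": "fifth metacarpal",
    "A": "scaphoid",
    "B": "lunate",
    "C": "triquetrum",
    "D": "pisiform",
    "E": "trapezium",
    "F": "trapezoid",
    "G": "capitate",
    "H": "hamate",
}

#: Reporting groups used when aggregating segmentation-quality metrics.
GROUPS: dict[str, tuple[str, ...]] = {
    "radius_ulna": ("R", "U"),
    "metacarpals": ("M1", "M2", "M3", "M4", "M5"),
    "carpals": ("A", "B", "C", "D", "E", "F", "G", "H"),
}

RADIOULNAR = GROUPS["radius_ulna"]
METACARPALS = GROUPS["metacarpals"]
CARPALS = GROUPS["carpals"]


def group_of(name: str) -> str:
    for group, members in GROUPS.items():
        if name in members:
            return group
    raise KeyError(f"unknown bone name: {name!r}")
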