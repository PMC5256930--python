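"""Diplotype coding for the congenic region.

Individuals carry one of three diplotypes at the introgressed segment:
``B/B`` (homozygous for the C57BL/6J-derived haplotype), ``B/C``
(heterozygous) or ``C/C`` (homozygous for the wild *M. m. castaneus*-derived
haplotype). The additive coding counts C-haplotype dosage 0/1/2.
"""

from __future__ import annotations

import numpy as np

#: Canonical diplotype order used in all reports (as printed column order).
DIPLOTYPES: tuple[str, ...] = ("B/B", "B/C", "C/C")

#: C-haplotype dosage under additive coding.
DOSAGE: dict[str, int] = {"B/B": 0, "B/C": 1, "C/C": 2}

#: Priority used to break ties when sorting groups by mean (highest first).
TIE_ORDER: tuple[str, ...] = ("C/C", "B/C", "B/B")


class DiplotypeError(ValueError):
    """Raised for malformed or incomplete diplotype labels."""


def validate(labels) -> np.ndarray:
    """Return labels as an object array, rejecting anything not in B/B, B/C, C/C."""
    arr = np.asarray(labels, dtype=object)
    for i, lab in enumerate(arr.ravel()):
        if lab not in DOSAGE:
            raise DiplotypeError(
                f"invalid diplotype {lab!r} at position {i}; expected one of {DIPLOTYPES}"
            )
    return arr


def dosage(labels) -> np.ndarray:
    """C-haplotype dosage (0/1/2) for a sequence of diplotype labels."""
    arr = validate(labels)
    return np.array([DOSAGE[lab] for lab in arr], dtype=float)


def require_all_classes(labels, min_per_class: int = 1) -> None:
    """Raise :class:`DiplotypeError` unless all three diplotypes are present."""
    arr = validate(labels)
    for dip in DIPLOTYPES:
        n = int(np.sum(arr == dip))
        if n < min_per_class:
            raise DiplotypeError(
                f"diplotype class {dip} has {n} individuals; need >= {min_per_class}"
            )
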