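"""Per-nucleus classification of red/green FISH spot counts.

A nucleus with R target spots and G control spots is binned by its R/G
ratio into one of four interpretable bands (G = 0 is uninterpretable):

* ``deletion``                      — R/G < 0.75
* ``instability``                   — 0.75 <= R/G < 1
* ``normal``                        — R/G = 1
* ``polysomy_without_deletion``     — R/G > 1

A cell carries the control-polysomy flag whenever G >= 3 — three or
more copies of the retained control arm — irrespective of its band.
Deleted cells that are also control-polysomic fall into one of four
signal categories by ratio:

* category 1 (homozygous pattern)   — R = 0
* category 2 (hemizygous pattern)   — 0 < R/G < 0.5
* category 3 (polyploid pattern)    — R/G = 0.5
* category 4 (instability pattern)  — 0.5 < R/G < 0.75

The 1/2 signature — the plain codeleted pattern — never carries a
category.  All band and category boundaries are decided by integer
cross-multiplication (e.g. R/G < 3/4 iff 4R < 3G), so ties such as 3/4
or 2/4 are exact, never subject to floating-point rounding.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .io_formats import CellSignal

__all__ = ["Band", "Category", "CellCall", "classify_cell", "classify_counts", "signature_label"]


class Band(enum.Enum):
    DELETION = "deletion"
    INSTABILITY = "instability"
    NORMAL = "normal"
    POLYSOMY_WITHOUT_DELETION = "polysomy_without_deletion"
    UNINTERPRETABLE = "uninterpretable"


class Category(enum.Enum):
    CAT1_HOMOZYGOUS = "cat1_homozygous"
    CAT2_HEMIZYGOUS = "cat2_hemizygous"
    CAT3_POLYPLOID_PATTERN = "cat3_polyploid_pattern"
    CAT4_INSTABILITY_PATTERN = "cat4_instability_pattern"
    NONE = "none"


@dataclass(frozen=True)
class CellCall:
    """Classification of one nucleus."""

    signature: str
    ratio: float | None
    band: Band
    control_polysomy: bool
    category: Category


def signature_label(cell: CellSignal) -> str:
    """Return the literal "R/G" signature string, e.g. ``"2/4"``."""
    return f"{cell.red_count}/{cell.green_count}"


def classify_cell(cell: CellSignal, *, strict_deletion_boundary: bool = True) -> CellCall:
    """Classify a single nucleus into band, polysomy flag and category.

    ``strict_deletion_boundary`` controls whether a ratio of exactly 0.75
    counts as deletion (``False``) or instability (``True``, the
    default): the assay cut-off is defined by a strict R/G < 0.75.
    """
    r, g = cell.red_count, cell.green_count
    if r < 0 or g < 0:
        raise ValueError("spot counts must be non-negative")

    sig = f"{r}/{g}"
    if g == 0:
        return CellCall(sig, None, Band.UNINTERPRETABLE, False, Category.NONE)

    ratio = r / g
    control_polysomy = g >= 3

    # band by exact integer comparison: R/G vs 3/4 <=> 4R vs 3G
    if 4 * r < 3 * g or (not strict_deletion_boundary and 4 * r == 3 * g):
        band = Band.DELETION
    elif r < g:
        band = Band.INSTABILITY
    elif r == g:
        band = Band.NORMAL
    else:
        band = Band.POLYSOMY_WITHOUT_DELETION

    category = Category.NONE
    if band is Band.DELETION and control_polysomy:
        if r == 0:
            category = Category.CAT1_HOMOZYGOUS
        elif 2 * r < g:
            category = Category.CAT2_HEMIZYGOUS
        elif 2 * r == g:
            category = Category.CAT3_POLYPLOID_PATTERN
        else:  # 0.5 < ratio < 0.75
            category = Category.CAT4_INSTABILITY_PATTERN

    return CellCall(sig, ratio, band, control_polysomy, category)


_BAND_CODES = {b: i for i, b in enumerate(Band)}


def classify_counts(
    red: np.ndarray, green: np.ndarray, *, strict_deletion_boundary: bool = True
) -> dict[str, np.ndarray]:
    """Vectorised classification of count arrays.

    Returns arrays ``band`` (values from :class:`Band`), ``control_polysomy``
    (bool) and ``category`` (values from :class:`Category`), aligned with the
    inputs.  Semantically identical to mapping :func:`classify_cell`.
    """
    r = np.asarray(red, dtype=np.int64)
    g = np.asarray(green, dtype=np.int64)
    if (r < 0).any() or (g < 0).any():
        raise ValueError("spot counts must be non-negative")

    deletion = 4 * r < 3 * g
    if not strict_deletion_boundary:
        deletion |= 4 * r == 3 * g
    band = np.where(
        g == 0,
        _BAND_CODES[Band.UNINTERPRETABLE],
        np.where(
            deletion,
            _BAND_CODES[Band.DELETION],
            np.where(
                r < g,
                _BAND_CODES[Band.INSTABILITY],
                np.where(r == g, _BAND_CODES[Band.NORMAL], _BAND_CODES[Band.POLYSOMY_WITHOUT_DELETION]),
            ),
        ),
    )
    control_polysomy = (g >= 3) & (g > 0)

    cats = np.full(r.shape, 4, dtype=np.int64)  # Category.NONE
    eligible = (band == _BAND_CODES[Band.DELETION]) & control_polysomy
    cats[eligible & (r == 0)] = 0
    cats[eligible & (r > 0) & (2 * r < g)] = 1
    cats[eligible & (2 * r == g) & (r > 0)] = 2
    cats[eligible & (2 * r > g)] = 3

    band_members = list(Band)
    cat_members = list(Category)
    return {
        "band": np.array([band_members[i] for i in band.ravel()], dtype=object).reshape(band.shape),
        "control_polysomy": control_polysomy,
        "category": np.array([cat_members[i] for i in cats.ravel()], dtype=object).reshape(cats.shape),
    }
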