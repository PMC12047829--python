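"""Per-sample and per-cohort distributions of R/G signatures.

A signature profile records, over the interpretable nuclei of one
sample+assay, the empirical frequency of every literal R/G signature,
of the four ratio bands, and of the four deletion+polysomy categories.
The seven predominant polysomy signatures (0/3, 0/4, 1/3, 1/4, 2/5,
2/4, 2/3) are reported as a dedicated sub-mapping because they carry
almost all the polysomy signal seen in codeleted oligodendrogliomas.

Cohort summaries average per-sample fractions (each tumour weighted
equally) rather than pooling cells; pooling is available behind a flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .cell_classifier import Band, Category, classify_counts
from .io_formats import CellSignal, ProbeAssay
from .sample_caller import NoCallError

__all__ = ["PREDOMINANT_SEVEN", "SignatureProfile", "profile_sample", "cohort_band_summary"]

#: The seven signatures that dominate the polysomic signal, with their category.
PREDOMINANT_SEVEN: dict[str, Category] = {
    "0/3": Category.CAT1_HOMOZYGOUS,
    "0/4": Category.CAT1_HOMOZYGOUS,
    "1/3": Category.CAT2_HEMIZYGOUS,
    "1/4": Category.CAT2_HEMIZYGOUS,
    "2/5": Category.CAT2_HEMIZYGOUS,
    "2/4": Category.CAT3_POLYPLOID_PATTERN,
    "2/3": Category.CAT4_INSTABILITY_PATTERN,
}

#: Signatures with both counts above this are binned as "other" in reports.
_BIN_LIMIT = 12


@dataclass(frozen=True)
class SignatureProfile:
    sample_id: str
    assay: ProbeAssay
    n_cells_interpretable: int
    signature_fractions: Mapping[str, float]
    band_fractions: Mapping[Band, float]
    category_fractions: Mapping[Category, float]
    predominant_seven: Mapping[str, float]
    #: fraction of interpretable cells that are both deleted and G >= 3
    fraction_deletion_polysomy: float

    def binned_signature_fractions(self) -> dict[str, float]:
        """Signature fractions with rare high-count signatures pooled as "other"."""
        out: dict[str, float] = {}
        for sig, frac in self.signature_fractions.items():
            r, g = (int(x) for x in sig.split("/"))
            key = "other" if r > _BIN_LIMIT and g > _BIN_LIMIT else sig
            out[key] = out.get(key, 0.0) + frac
        return out


def profile_sample(cells: Sequence[CellSignal]) -> SignatureProfile:
    """Compute the exact empirical signature/band/category frequencies."""
    cells = [c for c in cells if c.green_count >= 1]
    if not cells:
        raise NoCallError("no interpretable cells to profile")
    sample_ids = {c.sample_id for c in cells}
    assays = {c.assay for c in cells}
    if len(sample_ids) != 1 or len(assays) != 1:
        raise ValueError("profile_sample expects cells from one sample+assay")

    r = np.array([c.red_count for c in cells], dtype=np.int64)
    g = np.array([c.green_count for c in cells], dtype=np.int64)
    res = classify_counts(r, g)
    n = len(cells)

    sig_counts = Counter(f"{ri}/{gi}" for ri, gi in zip(r, g))
    band_counts = Counter(res["band"])
    cat_counts = Counter(c for c in res["category"] if c is not Category.NONE)
    n_del_poly = int(sum(
        1 for b, p in zip(res["band"], res["control_polysomy"]) if b is Band.DELETION and p
    ))

    sig_fracs = {s: c / n for s, c in sorted(sig_counts.items())}
    return SignatureProfile(
        sample_id=cells[0].sample_id,
        assay=cells[0].assay,
        n_cells_interpretable=n,
        signature_fractions=sig_fracs,
        band_fractions={b: c / n for b, c in band_counts.items()},
        category_fractions={c: k / n for c, k in cat_counts.items()},
        predominant_seven={s: sig_fracs.get(s, 0.0) for s in PREDOMINANT_SEVEN},
        fraction_deletion_polysomy=n_del_poly / n,
    )


def cohort_band_summary(
    groups: Mapping[str, Sequence[SignatureProfile]],
    *,
    pooled: bool = False,
) -> dict:
    """Summarise band/category fractions per group of profiles.

    Returns per-group mean fractions for every band, category and the
    deletion+polysomy compound, plus (when there are exactly two groups)
    a Mann-Whitney rank-sum p-value per band comparing the per-sample
    fractions between groups.  With ``pooled=True`` the summary weights
    every cell equally instead of every sample.
    """
    if not groups:
        raise ValueError("no groups supplied")
    for name, profiles in groups.items():
        if not profiles:
            raise ValueError(f"group {name!r} is empty")

    def band_value(p: SignatureProfile, band: Band) -> float:
        return p.band_fractions.get(band, 0.0)

    summary: dict = {"groups": {}, "p_values": {}}
    per_group_vectors: dict[str, dict[Band, np.ndarray]] = {}
    for name, profiles in groups.items():
        weights = np.array([p.n_cells_interpretable for p in profiles], dtype=float)
        weights = weights / weights.sum() if pooled else np.full(len(profiles), 1 / len(profiles))
        bands = {}
        vectors = {}
        for band in Band:
            if band is Band.UNINTERPRETABLE:
                continue
            v = np.array([band_value(p, band) for p in profiles])
            vectors[band] = v
            bands[band.value] = float(v @ weights)
        cats = {}
        for cat in Category:
            if cat is Category.NONE:
                continue
            v = np.array([p.category_fractions.get(cat, 0.0) for p in profiles])
            cats[cat.value] = float(v @ weights)
        dp = np.array([p.fraction_deletion_polysomy for p in profiles])
        summary["groups"][name] = {
            "n_samples": len(profiles),
            "band_fractions": bands,
            "category_fractions": cats,
            "deletion_polysomy_fraction": float(dp @ weights),
        }
        per_group_vectors[name] = vectors

    if len(groups) == 2:
        (na, va), (nb, vb) = per_group_vectors.items()
        for band in va:
            a, b = va[band], vb[band]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                p = 1.0  # identical constant samples: no evidence of difference
            else:
                p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
            summary["p_values"][band.value] = p
    return summary
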