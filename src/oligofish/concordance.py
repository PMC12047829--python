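"""Manual-vs-automated agreement on the sample-level polysomy call.

In routine FISH practice the manual rater scores 100 non-overlapping
nuclei, whereas the automated platform scores every detected nucleus
(typically around a thousand).  Both apply the same cut-offs, so any
disagreement between the resulting binary polysomy calls stems mostly
from sampling depth.  This module emulates the manual rater by
subsampling nuclei, cross-tabulates the two boolean call vectors, and
quantifies agreement with Cohen's kappa and raw percent agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import CellSignal

__all__ = [
    "AgreementTable",
    "manual_subsample",
    "agreement_table",
    "cohen_kappa",
    "percent_agreement",
]


@dataclass(frozen=True)
class AgreementTable:
    """2x2 cross-tabulation of manual (rows) vs automated (columns) calls."""

    n_both_negative: int
    n_manual_neg_auto_pos: int
    n_manual_pos_auto_neg: int
    n_both_positive: int

    def __post_init__(self) -> None:
        for f in (
            self.n_both_negative,
            self.n_manual_neg_auto_pos,
            self.n_manual_pos_auto_neg,
            self.n_both_positive,
        ):
            if f < 0:
                raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return (
            self.n_both_negative
            + self.n_manual_neg_auto_pos
            + self.n_manual_pos_auto_neg
            + self.n_both_positive
        )

    @property
    def manual_negative(self) -> int:
        return self.n_both_negative + self.n_manual_neg_auto_pos

    @property
    def manual_positive(self) -> int:
        return self.n_manual_pos_auto_neg + self.n_both_positive

    @property
    def auto_negative(self) -> int:
        return self.n_both_negative + self.n_manual_pos_auto_neg

    @property
    def auto_positive(self) -> int:
        return self.n_manual_neg_auto_pos + self.n_both_positive


def manual_subsample(
    cells: Sequence[CellSignal], n: int = 100, seed: int | np.random.Generator = 0
) -> list[CellSignal]:
    """Draw the manual rater's nuclei: uniform without replacement.

    Only interpretable nuclei (G >= 1) are eligible — the rater skips
    nuclei without control signal.  Reproducible given the seed.
    """
    eligible = [c for c in cells if c.green_count >= 1]
    if n > len(eligible):
        raise ValueError(f"requested {n} cells but only {len(eligible)} interpretable available")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


def agreement_table(
    manual_calls: Mapping[str, bool], auto_calls: Mapping[str, bool]
) -> AgreementTable:
    """Cross-tabulate per-sample boolean calls from the two raters."""
    if set(manual_calls) != set(auto_calls):
        missing = set(manual_calls) ^ set(auto_calls)
        raise ValueError(f"sample id mismatch between raters: {sorted(missing)}")
    n_nn = n_np = n_pn = n_pp = 0
    for sid, m in manual_calls.items():
        a = auto_calls[sid]
        if m and a:
            n_pp += 1
        elif m:
            n_pn += 1
        elif a:
            n_np += 1
        else:
            n_nn += 1
    return AgreementTable(n_nn, n_np, n_pn, n_pp)


def cohen_kappa(table: AgreementTable) -> float:
    """Chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (diagonal fraction) and p_e the
    agreement expected from the marginal call rates alone.  Returns 1.0
    in the degenerate case p_e = 1 with perfect observed agreement.
    """
    n = table.total
    if n == 0:
        raise ValueError("empty agreement table")
    p_o = (table.n_both_negative + table.n_both_positive) / n
    p_e = (
        table.manual_negative * table.auto_negative
        + table.manual_positive * table.auto_positive
    ) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def percent_agreement(table: AgreementTable) -> float:
    """Raw agreement as a percentage, 100 * diagonal / total."""
    if table.total == 0:
        raise ValueError("empty agreement table")
    return 100.0 * (table.n_both_negative + table.n_both_positive) / table.total
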