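"""Sample-level deletion / polysomy / CDKN2A calling.

Per-cell classifications are aggregated over the interpretable nuclei
of one sample+assay (a nucleus is interpretable when it shows at least
one control signal, G >= 1).  A sample is:

* *deleted* when >= 55% of interpretable nuclei have R/G < 0.75;
* *polysomic* when >= 30% of interpretable nuclei show three or more
  control-arm signals (G >= 3), concurrent with the deletion cut-off
  being evaluated independently;
* CDKN2A *homozygously deleted* when >= 30% of nuclei show the
  homozygous pattern (R = 0, G >= 1), else *hemizygously deleted* when
  >= 40% show the hemizygous pattern (R >= 1, G >= 2, R < G).

All cut-off comparisons are inclusive (>=) and evaluated as exact
rational comparisons so a fraction of exactly 55% or 30% flips the call.
The two chromosome assays combine into a codeletion status and a
polysomy subgroup (1p and 19q / 1p alone / 19q alone), and the joint
signal patterns support an extrapolation between whole-genome ploidy
change and chromosome-specific polysomy: identical dominant >2n
patterns on both chromosomes (2R4G -> tetraploid, 3R6G -> hexaploid)
indicate a ploidy shift, whereas a plain 1R2G pattern on one chromosome
with a >2n pattern on the other indicates true polysomy.
"""

from __future__ import annotations

import enum
import statistics
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .cell_classifier import Band, classify_counts
from .io_formats import CellSignal, ProbeAssay

__all__ = [
    "SampleCall",
    "CDKN2ACall",
    "CDKN2AStatus",
    "CombinedStatus",
    "PolysomySubgroup",
    "Ploidy",
    "CutoffCalibration",
    "NoCallError",
    "call_assay",
    "call_cdkn2a",
    "calibrate_cutoff",
    "combine_assays",
    "infer_ploidy",
]

DELETION_CUTOFF = 0.55
POLYSOMY_CUTOFF = 0.30
CDKN2A_HEMI_CUTOFF = 0.40
CDKN2A_HOMO_CUTOFF = 0.30


class NoCallError(ValueError):
    """Raised when a sample has no interpretable cells for an assay."""


class PolysomySubgroup(enum.Enum):
    NONE = "none"
    BOTH_1P_19Q = "both_1p_19q"
    ONLY_1P = "only_1p"
    ONLY_19Q = "only_19q"


class Ploidy(enum.Enum):
    NOT_APPLICABLE = "not_applicable"
    TETRAPLOID = "tetraploid"
    HEXAPLOID = "hexaploid"
    POLYPLOID_MIXED = "polyploid_mixed"
    POLYSOMIC = "polysomic"


class CDKN2AStatus(enum.Enum):
    NORMAL = "normal"
    HEMIZYGOUS = "hemizygous"
    HOMOZYGOUS = "homozygous"


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    assay: ProbeAssay
    n_cells_total: int
    n_cells_interpretable: int
    fraction_deleted: float
    fraction_control_polysomy: float
    deletion_called: bool
    polysomy_called: bool


@dataclass(frozen=True)
class CDKN2ACall:
    sample_id: str
    n_cells_interpretable: int
    fraction_homozygous_pattern: float
    fraction_hemizygous_pattern: float
    call: CDKN2AStatus


@dataclass(frozen=True)
class CombinedStatus:
    sample_id: str
    codeleted: bool
    polysomy_subgroup: PolysomySubgroup
    ploidy: Ploidy = Ploidy.NOT_APPLICABLE


@dataclass(frozen=True)
class CutoffCalibration:
    """Mean + 3 SD cut-off calibrated on non-neoplastic control samples."""

    control_fractions: tuple[float, ...]
    mean: float
    sd: float
    cutoff: float


def _frac_ge(numerator: int, denominator: int, cutoff: float) -> bool:
    """Exact inclusive comparison numerator/denominator >= cutoff.

    The cutoff is interpreted through its decimal representation so that
    e.g. 55/100 >= 0.55 holds exactly.
    """
    return Fraction(numerator, denominator) >= Fraction(str(cutoff))


def _counts(cells: Sequence[CellSignal]) -> tuple[np.ndarray, np.ndarray]:
    r = np.array([c.red_count for c in cells], dtype=np.int64)
    g = np.array([c.green_count for c in cells], dtype=np.int64)
    return r, g


def call_assay(
    cells: Sequence[CellSignal],
    deletion_cutoff: float = DELETION_CUTOFF,
    polysomy_cutoff: float = POLYSOMY_CUTOFF,
    *,
    strict_deletion_boundary: bool = True,
) -> SampleCall:
    """Aggregate one sample+assay's cells into a deletion/polysomy call."""
    cells = list(cells)
    if not cells:
        raise NoCallError("no cells supplied")
    sample_ids = {c.sample_id for c in cells}
    assays = {c.assay for c in cells}
    if len(sample_ids) != 1 or len(assays) != 1:
        raise ValueError(f"cells span multiple samples/assays: {sample_ids}, {assays}")

    r, g = _counts(cells)
    interpretable = g >= 1
    n_interp = int(interpretable.sum())
    if n_interp == 0:
        raise NoCallError(f"sample {cells[0].sample_id}: zero interpretable cells")

    res = classify_counts(r[interpretable], g[interpretable],
                          strict_deletion_boundary=strict_deletion_boundary)
    n_del = int(sum(1 for b in res["band"] if b is Band.DELETION))
    n_poly = int(res["control_polysomy"].sum())

    return SampleCall(
        sample_id=cells[0].sample_id,
        assay=cells[0].assay,
        n_cells_total=len(cells),
        n_cells_interpretable=n_interp,
        fraction_deleted=n_del / n_interp,
        fraction_control_polysomy=n_poly / n_interp,
        deletion_called=_frac_ge(n_del, n_interp, deletion_cutoff),
        polysomy_called=_frac_ge(n_poly, n_interp, polysomy_cutoff),
    )


def call_cdkn2a(
    cells: Sequence[CellSignal],
    hemi_cutoff: float = CDKN2A_HEMI_CUTOFF,
    homo_cutoff: float = CDKN2A_HOMO_CUTOFF,
) -> CDKN2ACall:
    """Call CDKN2A (9p21) deletion status against the CEP9 control.

    The homozygous pattern (no 9p signal with at least one centromere)
    takes precedence over the hemizygous one (reduced but present 9p
    signal with >= 2 centromeres).
    """
    cells = list(cells)
    if not cells:
        raise NoCallError("no cells supplied")
    r, g = _counts(cells)
    interpretable = g >= 1
    n_interp = int(interpretable.sum())
    if n_interp == 0:
        raise NoCallError(f"sample {cells[0].sample_id}: zero interpretable cells")
    r, g = r[interpretable], g[interpretable]

    n_homo = int(((r == 0) & (g >= 1)).sum())
    n_hemi = int(((r >= 1) & (g >= 2) & (r < g)).sum())

    if _frac_ge(n_homo, n_interp, homo_cutoff):
        status = CDKN2AStatus.HOMOZYGOUS
    elif _frac_ge(n_hemi, n_interp, hemi_cutoff):
        status = CDKN2AStatus.HEMIZYGOUS
    else:
        status = CDKN2AStatus.NORMAL

    return CDKN2ACall(
        sample_id=cells[0].sample_id,
        n_cells_interpretable=n_interp,
        fraction_homozygous_pattern=n_homo / n_interp,
        fraction_hemizygous_pattern=n_hemi / n_interp,
        call=status,
    )


def calibrate_cutoff(control_fractions: Iterable[float]) -> CutoffCalibration:
    """Calibrate a positivity cut-off as mean + 3 SD over control samples.

    The SD is the sample standard deviation (n - 1 denominator); at
    least two control samples are required for it to be defined.
    """
    fractions = tuple(float(f) for f in control_fractions)
    if len(fractions) < 2:
        raise ValueError("at least 2 control samples required (sd undefined)")
    if any(not 0 <= f <= 1 for f in fractions):
        raise ValueError("control fractions must lie in [0, 1]")
    mean = statistics.fmean(fractions)
    sd = statistics.stdev(fractions)
    return CutoffCalibration(fractions, mean, sd, mean + 3 * sd)


def combine_assays(chr1: SampleCall, chr19: SampleCall) -> CombinedStatus:
    """Combine the two chromosome assays into codeletion + polysomy subgroup."""
    if chr1.sample_id != chr19.sample_id:
        raise ValueError(f"sample id mismatch: {chr1.sample_id!r} vs {chr19.sample_id!r}")
    if chr1.assay is not ProbeAssay.CHR1 or chr19.assay is not ProbeAssay.CHR19:
        raise ValueError("combine_assays expects a CHR1 call and a CHR19 call")

    if chr1.polysomy_called and chr19.polysomy_called:
        subgroup = PolysomySubgroup.BOTH_1P_19Q
    elif chr1.polysomy_called:
        subgroup = PolysomySubgroup.ONLY_1P
    elif chr19.polysomy_called:
        subgroup = PolysomySubgroup.ONLY_19Q
    else:
        subgroup = PolysomySubgroup.NONE

    return CombinedStatus(
        sample_id=chr1.sample_id,
        codeleted=chr1.deletion_called and chr19.deletion_called,
        polysomy_subgroup=subgroup,
    )


# >2n signatures considered compatible with a (possibly mixed) ploidy shift
_POLYPLOID_SIGNATURES = {"2/4", "3/6", "2/5", "2/6", "3/4", "3/5", "4/4", "4/5", "4/6"}


def _dominant_signature(cells: Sequence[CellSignal]) -> tuple[str | None, bool]:
    """Return (dominant >2n signature or None/"mixed", has_polysomy_cells).

    The dominant signature is the modal R/G pattern among G >= 3 cells,
    required to cover more than half of them; otherwise "mixed".
    """
    sigs = [f"{c.red_count}/{c.green_count}" for c in cells if c.green_count >= 3]
    if not sigs:
        return None, False
    counts = Counter(sigs)
    sig, n = counts.most_common(1)[0]
    if 2 * n > len(sigs):
        return sig, True
    return "mixed", True


def infer_ploidy(
    chr1_cells: Sequence[CellSignal],
    chr19_cells: Sequence[CellSignal],
    polysomy_cutoff: float = POLYSOMY_CUTOFF,
) -> Ploidy:
    """Extrapolate ploidy vs polysomy from the joint two-assay patterns.

    An assay counts as ">2n" when its control-polysomy fraction reaches
    the polysomy cut-off.  Identical dominant patterns on both
    chromosomes indicate a genome-wide ploidy change (2/4 tetraploid,
    3/6 hexaploid); unequal or heterogeneous >2n patterns a mixed
    polyploid profile; a >2n pattern on one chromosome with a plain 2n
    profile on the other, chromosome-specific polysomy.
    """
    calls = []
    doms = []
    for cells in (chr1_cells, chr19_cells):
        cells = list(cells)
        if not cells:
            raise NoCallError("both assays need interpretable cells")
        sc = call_assay(cells, polysomy_cutoff=polysomy_cutoff)
        calls.append(sc)
        doms.append(_dominant_signature(cells))

    over_2n = [sc.polysomy_called for sc in calls]
    if not any(over_2n):
        return Ploidy.NOT_APPLICABLE
    if not all(over_2n):
        return Ploidy.POLYSOMIC

    d1, d19 = doms[0][0], doms[1][0]
    if d1 == d19 == "2/4":
        return Ploidy.TETRAPLOID
    if d1 == d19 == "3/6":
        return Ploidy.HEXAPLOID
    return Ploidy.POLYPLOID_MIXED
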