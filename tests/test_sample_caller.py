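"""Sample-level calling: cut-off exactness, CDKN2A precedence, ploidy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligofish.io_formats import CellSignal, ProbeAssay
from oligofish.sample_caller import (
    CDKN2AStatus,
    NoCallError,
    Ploidy,
    PolysomySubgroup,
    calibrate_cutoff,
    call_assay,
    call_cdkn2a,
    combine_assays,
    infer_ploidy,
)
from tests.conftest import make_cells


class TestDeletionCutoff:
    def test_flips_at_exactly_55_percent(self):
        deleted, normal = "1/2", "2/2"
        at = call_assay(make_cells([deleted] * 55 + [normal] * 45))
        below = call_assay(make_cells([deleted] * 54 + [normal] * 46))
        assert at.deletion_called and not below.deletion_called
        assert at.fraction_deleted == 0.55

    def test_56_of_100_deleted_is_called(self):
        sc = call_assay(make_cells(["1/3"] * 56 + ["2/2"] * 44))
        assert sc.deletion_called

    def test_all_one_two_cells(self):
        sc = call_assay(make_cells(["1/2"] * 50))
        assert sc.fraction_deleted == 1.0
        assert sc.deletion_called
        assert not sc.polysomy_called


class TestPolysomyCutoff:
    def test_flips_at_exactly_30_percent(self):
        at = call_assay(make_cells(["1/3"] * 30 + ["1/2"] * 70))
        below = call_assay(make_cells(["1/3"] * 29 + ["1/2"] * 71))
        assert at.polysomy_called and not below.polysomy_called

    def test_ratio_one_cells_with_three_controls_count(self):
        # the polysomy definition depends only on control-arm signals
        sc = call_assay(make_cells(["3/3"] * 30 + ["2/2"] * 70))
        assert sc.polysomy_called
        assert sc.fraction_control_polysomy == 0.30

    def test_uninterpretable_cells_excluded_from_denominator(self):
        sc = call_assay(make_cells(["1/3"] * 3 + ["1/0"] * 5 + ["1/2"] * 7))
        assert sc.n_cells_total == 15
        assert sc.n_cells_interpretable == 10
        assert sc.fraction_control_polysomy == 0.3
        assert sc.polysomy_called

    def test_no_interpretable_cells_is_a_no_call(self):
        with pytest.raises(NoCallError):
            call_assay(make_cells(["2/0"] * 10))
        with pytest.raises(NoCallError):
            call_assay([])

    def test_mixed_samples_rejected(self):
        cells = make_cells(["1/2"], sample_id="A") + make_cells(["1/2"], sample_id="B")
        with pytest.raises(ValueError):
            call_assay(cells)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.tuples(st.integers(0, 8), st.integers(0, 8)), min_size=1, max_size=60))
    def test_brute_force_recount_agrees(self, sigs):
        """Fractions and booleans match an independent loop-and-count."""
        if not any(g >= 1 for _, g in sigs):
            return
        sc = call_assay(make_cells(sigs))
        interp = [(r, g) for r, g in sigs if g >= 1]
        n_del = sum(1 for r, g in interp if r / g < 0.75)
        n_poly = sum(1 for r, g in interp if g >= 3)
        assert sc.fraction_deleted == pytest.approx(n_del / len(interp))
        assert sc.fraction_control_polysomy == pytest.approx(n_poly / len(interp))
        assert sc.deletion_called == (n_del / len(interp) >= 0.55 - 1e-12)
        assert sc.polysomy_called == (n_poly / len(interp) >= 0.30 - 1e-12)

    def test_adding_high_control_cell_never_decreases_polysomy_fraction(self):
        base = ["1/3"] * 3 + ["1/2"] * 7
        sc0 = call_assay(make_cells(base))
        sc1 = call_assay(make_cells(base + ["2/4"]))
        assert sc1.fraction_control_polysomy >= sc0.fraction_control_polysomy


class TestCDKN2A:
    def test_homozygous_at_35_percent(self):
        cells = make_cells(["0/2"] * 35 + ["2/2"] * 65, assay=ProbeAssay.CDKN2A)
        assert call_cdkn2a(cells).call is CDKN2AStatus.HOMOZYGOUS

    def test_hemizygous_when_homozygous_fraction_low(self):
        cells = make_cells(
            ["1/2"] * 45 + ["0/2"] * 10 + ["2/2"] * 45, assay=ProbeAssay.CDKN2A
        )
        call = call_cdkn2a(cells)
        assert call.call is CDKN2AStatus.HEMIZYGOUS
        assert call.fraction_homozygous_pattern == 0.10

    def test_normal_below_both_cutoffs(self):
        cells = make_cells(
            ["1/2"] * 20 + ["0/2"] * 5 + ["2/2"] * 75, assay=ProbeAssay.CDKN2A
        )
        assert call_cdkn2a(cells).call is CDKN2AStatus.NORMAL

    def test_cutoffs_are_inclusive(self):
        homo = make_cells(["0/1"] * 30 + ["2/2"] * 70, assay=ProbeAssay.CDKN2A)
        assert call_cdkn2a(homo).call is CDKN2AStatus.HOMOZYGOUS
        hemi = make_cells(["1/3"] * 40 + ["2/2"] * 60, assay=ProbeAssay.CDKN2A)
        assert call_cdkn2a(hemi).call is CDKN2AStatus.HEMIZYGOUS

    def test_homozygous_precedence_over_hemizygous(self):
        cells = make_cells(
            ["0/2"] * 30 + ["1/2"] * 45 + ["2/2"] * 25, assay=ProbeAssay.CDKN2A
        )
        assert call_cdkn2a(cells).call is CDKN2AStatus.HOMOZYGOUS


class TestCutoffCalibration:
    def test_zero_spread_gives_the_mean(self):
        cal = calibrate_cutoff([0.10] * 10)
        assert cal.sd == 0
        assert cal.cutoff == pytest.approx(0.10)

    def test_mean_point_one_sd_point_one_gives_forty_percent(self):
        # two-point list with mean 0.10 and sample sd 0.10
        fractions = [0.1 - 0.1 / np.sqrt(2), 0.1 + 0.1 / np.sqrt(2)]
        cal = calibrate_cutoff(fractions)
        assert cal.mean == pytest.approx(0.10)
        assert cal.sd == pytest.approx(0.10)
        assert cal.cutoff == pytest.approx(0.40)

    def test_single_control_is_an_error(self):
        with pytest.raises(ValueError):
            calibrate_cutoff([0.1])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=20))
    def test_equals_closed_form(self, fractions):
        cal = calibrate_cutoff(fractions)
        assert cal.cutoff == pytest.approx(
            np.mean(fractions) + 3 * np.std(fractions, ddof=1), abs=1e-12
        )
        assert cal.cutoff >= cal.mean - 1e-12
        assert cal.sd >= 0


def _sample_call(polysomy, deletion=True, sample_id="S1", assay=ProbeAssay.CHR1):
    from oligofish.sample_caller import SampleCall

    return SampleCall(sample_id, assay, 100, 100, 0.8 if deletion else 0.1,
                      0.4 if polysomy else 0.1, deletion, polysomy)


class TestCombineAssays:
    @pytest.mark.parametrize(
        "p1, p19, subgroup",
        [
            (True, True, PolysomySubgroup.BOTH_1P_19Q),
            (True, False, PolysomySubgroup.ONLY_1P),
            (False, True, PolysomySubgroup.ONLY_19Q),
            (False, False, PolysomySubgroup.NONE),
        ],
    )
    def test_subgroups(self, p1, p19, subgroup):
        combined = combine_assays(
            _sample_call(p1), _sample_call(p19, assay=ProbeAssay.CHR19)
        )
        assert combined.polysomy_subgroup is subgroup
        assert combined.codeleted

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_assays(
                _sample_call(True, sample_id="A"),
                _sample_call(True, sample_id="B", assay=ProbeAssay.CHR19),
            )


class TestInferPloidy:
    def test_dominant_2_4_on_both_is_tetraploid(self):
        sigs = ["2/4"] * 40 + ["1/2"] * 60
        assert infer_ploidy(
            make_cells(sigs), make_cells(sigs, assay=ProbeAssay.CHR19)
        ) is Ploidy.TETRAPLOID

    def test_dominant_3_6_on_both_is_hexaploid(self):
        sigs = ["3/6"] * 40 + ["1/2"] * 60
        assert infer_ploidy(
            make_cells(sigs), make_cells(sigs, assay=ProbeAssay.CHR19)
        ) is Ploidy.HEXAPLOID

    def test_plain_codeletion_plus_gain_is_polysomic(self):
        chr1 = make_cells(["1/2"] * 100)
        chr19 = make_cells(["2/4"] * 40 + ["1/2"] * 60, assay=ProbeAssay.CHR19)
        assert infer_ploidy(chr1, chr19) is Ploidy.POLYSOMIC

    def test_heterogeneous_gains_are_polyploid_mixed(self):
        sigs = ["2/4"] * 15 + ["2/3"] * 15 + ["1/3"] * 15 + ["1/2"] * 55
        assert infer_ploidy(
            make_cells(sigs), make_cells(sigs, assay=ProbeAssay.CHR19)
        ) is Ploidy.POLYPLOID_MIXED

    def test_no_gains_anywhere_not_applicable(self):
        chr1 = make_cells(["1/2"] * 100)
        chr19 = make_cells(["1/2"] * 100, assay=ProbeAssay.CHR19)
        assert infer_ploidy(chr1, chr19) is Ploidy.NOT_APPLICABLE
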