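"""CVF1/2/3 detection, interval arithmetic, rCVF scores, velocity labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvflow.tac import AcquisitionGrid, Tac
from cvflow.timing import (
    CensoredClearanceError,
    CensoredOnsetError,
    HemisphereCvfTimes,
    VeinEnhancement,
    classify_velocity,
    derive_intervals,
    detect_cvf1,
    detect_cvf2,
    detect_cvf3,
    relative_cvf,
)

GRID = AcquisitionGrid(tuple(8.0 + 2.0 * i for i in range(19)))


def vein(enh, name="SMCV", present=True, grid=GRID):
    tac = Tac(grid, tuple(40.0 + np.asarray(enh, dtype=float)), baseline=40.0)
    return VeinEnhancement(name, "affected", tac, present=present)


def bump(onset_idx, peak_idx, clear_idx, peak=300.0, plateau=120.0, n=19):
    """Enhancement >= plateau on [onset_idx, clear_idx), unique max at peak_idx."""
    e = np.zeros(n)
    e[onset_idx:clear_idx] = plateau
    e[peak_idx] = peak
    return e


class TestDetectCvf1:
    def test_single_crossing_at_index_5(self):
        v = vein(bump(5, 8, 15))
        # linear-scan oracle over the grid
        oracle = next(t for t, e in zip(GRID.times, bump(5, 8, 15)) if e >= 50)
        assert detect_cvf1([v]) == oracle == GRID.times[5]

    def test_any_vein_minimum_of_onsets(self):
        early = vein(bump(4, 8, 15), "SMCV")
        late = vein(bump(6, 8, 15), "VOT")
        assert detect_cvf1([early, late]) == GRID.times[4]

    def test_all_below_threshold_is_censored(self):
        with pytest.raises(CensoredOnsetError):
            detect_cvf1([vein(np.full(19, 30.0))])

    def test_absent_veins_excluded(self):
        absent = vein(bump(2, 3, 10), "SMCV", present=False)
        present = vein(bump(6, 8, 15), "VOT")
        assert detect_cvf1([absent, present]) == GRID.times[6]
        with pytest.raises(ValueError):
            detect_cvf1([absent])


class TestDetectCvf2:
    def test_single_vein_argmax_with_zero_tolerance(self):
        v = vein(bump(4, 9, 15))
        assert detect_cvf2([v], peak_tolerance=0.0) == GRID.times[9]

    def test_three_identical_curves(self):
        veins = [vein(bump(4, 9, 15), n) for n in ("SMCV", "VOT", "VOL")]
        assert detect_cvf2(veins) == GRID.times[9]

    def test_majority_half_of_two_veins(self):
        # peaks at indices 6 and 8; ceil(0.5*2)=1 vein suffices -> earlier peak
        a = vein(bump(4, 6, 15), "SMCV")
        b = vein(bump(4, 8, 15), "VOT")
        t = detect_cvf2([a, b], peak_tolerance=0.0, majority_fraction=0.5)
        # exhaustive scan oracle
        oracle = min(GRID.times[6], GRID.times[8])
        assert t == oracle

    def test_unattainable_majority_falls_back_to_best_count(self):
        # distinct peaks, tol 0: no time has both veins at their maxima, so
        # the earliest time with the best attainable count is returned
        a = vein(bump(4, 6, 15), "SMCV")
        b = vein(bump(4, 8, 15), "VOT")
        t = detect_cvf2([a, b], peak_tolerance=0.0, majority_fraction=0.75)
        assert t == GRID.times[6]


class TestDetectCvf3:
    def test_clearance_scan(self):
        veins = [vein(bump(4, 8, 12), n) for n in ("SMCV", "VOT")]
        cvf2 = detect_cvf2(veins)
        # linear-scan oracle: first time > cvf2 with every enhancement < 50
        oracle = next(
            t for t, i in zip(GRID.times, range(19)) if t > cvf2 and all(bump(4, 8, 12)[i] < 50 for _ in veins)
        )
        assert detect_cvf3(veins, after=cvf2) == oracle == GRID.times[12]

    def test_still_opacified_at_last_volume_censored(self):
        v = vein(bump(4, 8, 19))  # never clears
        with pytest.raises(CensoredClearanceError):
            detect_cvf3([v], after=GRID.times[8])

    def test_single_vein_first_post_peak_time(self):
        e = np.zeros(19)
        e[5] = 300.0  # single-volume blip
        v = vein(e)
        assert detect_cvf3([v], after=GRID.times[5]) == GRID.times[6]


class TestIntervals:
    @pytest.mark.parametrize(
        "times, expected",
        [
            ((20.9, 24.8, 37.7), (3.9, 16.8)),  # first worked case, affected side
            ((19.0, 24.8, 32.7), (5.8, 13.7)),  # first worked case, contralateral
            ((12.6, 19.2, 25.2), (6.6, 12.6)),  # second worked case, contralateral
            ((16.4, 25.0, 32.9), (8.6, 16.5)),  # third worked case, affected
            ((15.0, 15.0, 15.0), (0.0, 0.0)),
        ],
    )
    def test_printed_derived_values(self, times, expected):
        assert derive_intervals(*times) == pytest.approx(expected)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            derive_intervals(10.0, 9.0, 12.0)
        with pytest.raises(ValueError):
            HemisphereCvfTimes(10.0, 12.0, 11.0)


class TestRelativeCvf:
    def test_first_case_rcvfs(self):
        aff = HemisphereCvfTimes(20.9, 24.8, 37.7)
        con = HemisphereCvfTimes(19.0, 24.8, 32.7)
        r = relative_cvf(aff, con)
        assert (r.rcvf1, r.rcvf2, r.rcvf3) == pytest.approx((1.9, 0.0, 5.0))
        assert (r.rcvf21, r.rcvf31) == pytest.approx((-1.9, 3.1))

    def test_third_case_rcvf21(self):
        aff = HemisphereCvfTimes(16.4, 25.0, 32.9)
        con = HemisphereCvfTimes(14.5, 23.0, 28.9)
        assert relative_cvf(aff, con).rcvf21 == pytest.approx(0.1)

    @given(
        st.lists(st.floats(min_value=5, max_value=40), min_size=6, max_size=6)
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, raw):
        a = HemisphereCvfTimes(*sorted(raw[:3]))
        b = HemisphereCvfTimes(*sorted(raw[3:]))
        fwd, rev = relative_cvf(a, b), relative_cvf(b, a)
        for k, v in fwd.as_dict().items():
            assert rev.as_dict()[k] == pytest.approx(-v, abs=1e-9)

    def test_identical_hemispheres_all_zero(self):
        h = HemisphereCvfTimes(14.0, 20.0, 28.0)
        assert all(v == 0 for v in relative_cvf(h, h).as_dict().values())


class TestClassifyVelocity:
    def test_median_threshold_is_inclusive(self):
        labels = classify_velocity([1.9, 0.4, 4.5], index="rcvf21")
        by_val = {l.value: l.label for l in labels}
        assert by_val[1.9] == "fast"  # at the median -> fast

    def test_sorting_oracle(self):
        labels = classify_velocity([1.0, 2.0, 3.0])
        assert [l.label for l in labels] == ["fast", "fast", "slow"]
        assert labels[0].threshold == pytest.approx(np.median([1, 2, 3]))

    def test_all_equal_all_fast(self):
        assert all(l.fast for l in classify_velocity([2.0] * 5))

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_at_least_half_fast(self, vals):
        labels = classify_velocity(vals)
        n = len(vals)
        assert sum(l.fast for l in labels) >= -(-n // 2)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            classify_velocity([])


class TestShiftEquivariance:
    def test_grid_shift_moves_cvf_times_not_intervals(self):
        veins = [vein(bump(4, 8, 13), n) for n in ("SMCV", "VOT", "VOL")]
        c1, c2 = detect_cvf1(veins), detect_cvf2(veins)
        c3 = detect_cvf3(veins, after=c2)
        k = 2  # shift two grid intervals later
        shifted = [
            VeinEnhancement(v.vein, v.hemisphere, v.tac.shifted(k), present=True) for v in veins
        ]
        s1, s2 = detect_cvf1(shifted), detect_cvf2(shifted)
        s3 = detect_cvf3(shifted, after=s2)
        dt = k * GRID.spacing
        assert (s1, s2, s3) == pytest.approx((c1 + dt, c2 + dt, c3 + dt))
        assert derive_intervals(s1, s2, s3) == pytest.approx(derive_intervals(c1, c2, c3))

    def test_order_invariant_on_noiseless_hemisphere(self):
        veins = [vein(bump(3, 7, 14), n) for n in ("SMCV", "VOT", "VOL")]
        c1, c2 = detect_cvf1(veins), detect_cvf2(veins)
        c3 = detect_cvf3(veins, after=c2)
        assert c1 <= c2 <= c3
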