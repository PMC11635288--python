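"""Connectivity classes, the CI chain, QC flags, and cut-off calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frapconn.connectivity import (
    CiInputs,
    ConnectivityClass,
    calibrate_cutoff,
    ci_from_series,
    classify_recovery,
    compute_ci,
    delta_intensity,
)
from frapconn.recovery import FitResult

from conftest import simulate_experiment


def _fit(t_half, mobile, converged=True):
    k = np.log(2) / t_half if t_half else None
    return FitResult(
        rate_k=k, t_half_s=t_half, plateau=None, floor=None,
        mobile_fraction=mobile, r_squared=0.99, converged=converged,
    )


class TestClassifyRecovery:
    @pytest.mark.parametrize(
        "t_half,mobile,expected",
        [
            (1.0, 0.8, ConnectivityClass.FAST),
            (3.0, 0.8, ConnectivityClass.MEDIUM),
            (7.0, 0.8, ConnectivityClass.SLOW),
            (1.0, 0.25, ConnectivityClass.NO_RECOVERY),
            # boundary semantics: >= at 2 and 5, strict < at 30%
            (2.0, 0.8, ConnectivityClass.MEDIUM),
            (5.0, 0.8, ConnectivityClass.SLOW),
            (1.0, 0.30, ConnectivityClass.FAST),
            (1.999999, 0.8, ConnectivityClass.FAST),
        ],
    )
    def test_threshold_table(self, t_half, mobile, expected):
        assert classify_recovery(_fit(t_half, mobile)) is expected

    def test_failed_fit_is_no_recovery(self):
        fit = FitResult(None, None, None, None, None, None, converged=False)
        assert classify_recovery(fit) is ConnectivityClass.NO_RECOVERY

    def test_matches_brute_force_threshold_table_on_grid(self):
        """Independent re-evaluation of the class table on a 10^4-point grid."""
        t_halves = np.linspace(0.05, 10.0, 100)
        mobiles = np.linspace(0.0, 1.0, 100)
        for t in t_halves:
            for m in mobiles:
                got = classify_recovery(_fit(t, m)).value
                if m < 0.30:
                    want = "no_recovery"
                elif t < 2.0:
                    want = "fast"
                elif t < 5.0:
                    want = "medium"
                else:
                    want = "slow"
                assert got == want, (t, m)


class TestDeltaIntensity:
    def test_pre_frame_denominator(self):
        assert delta_intensity(100, 60, "pre_frame") == pytest.approx(-40.0)

    def test_no_change_is_zero_under_both_conventions(self):
        assert delta_intensity(100, 100, "pre_frame") == 0.0
        assert delta_intensity(100, 100, "post_frame") == 0.0

    def test_post_frame_denominator(self):
        assert delta_intensity(100, 60, "post_frame") == pytest.approx(-200 / 3)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            delta_intensity(100, 0, "post_frame")

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            delta_intensity(100, 60, "geometric_mean")


class TestComputeCi:
    @pytest.mark.parametrize("denominator", ["pre_frame", "post_frame"])
    def test_perfect_mixing_gives_ci_one(self, denominator):
        inputs = CiInputs(100, 60, 100, 60, 100, 100)
        res = compute_ci(inputs, denominator)
        assert res.ci == 1.0
        assert res.qc_flag == "ok"

    @pytest.mark.parametrize("denominator", ["pre_frame", "post_frame"])
    def test_neighbor_identical_gives_ci_zero(self, denominator):
        inputs = CiInputs(100, 60, 100, 100, 100, 100)
        res = compute_ci(inputs, denominator)
        assert res.ci == 0.0
        assert res.qc_flag == "ok"

    def test_half_recovery_chain(self):
        res = compute_ci(CiInputs(100, 60, 100, 80, 100, 100), "pre_frame")
        assert res.dI_a == pytest.approx(-40.0)
        assert res.dI_b == pytest.approx(-20.0)
        assert res.dI_c == pytest.approx(0.0)
        assert res.rel == pytest.approx(-20.0)
        assert res.ref == pytest.approx(-40.0)
        assert res.ci == pytest.approx(0.5)

    def test_ref_zero_raises(self):
        with pytest.raises(ValueError, match="Ref"):
            compute_ci(CiInputs(100, 80, 100, 90, 100, 80))

    def test_qc_drift_negative(self):
        # the distant same-vacuole area gained intensity (drift artifact)
        res = compute_ci(CiInputs(100, 60, 100, 115, 100, 100))
        assert res.ci < 0
        assert res.qc_flag == "drift_negative"

    def test_qc_drift_above_one(self):
        # the distant area lost even more than the bleached area
        res = compute_ci(CiInputs(100, 60, 100, 50, 100, 100))
        assert res.ci > 1
        assert res.qc_flag == "drift_above_one"

    def test_qc_weak_bleach(self):
        res = compute_ci(CiInputs(100, 95, 100, 100, 100, 100))
        assert res.qc_flag == "weak_bleach"

    def test_frame_swap_never_silent(self):
        # pre/post exchanged: the "bleached" area gains signal
        res = compute_ci(CiInputs(60, 100, 60, 60, 100, 100))
        assert res.qc_flag != "ok"

    @given(scale=st.floats(0.01, 1000.0))
    @settings(max_examples=30, deadline=None)
    def test_ci_invariant_to_uniform_rescaling(self, scale):
        base = (100.0, 60.0, 100.0, 80.0, 100.0, 99.0)
        r1 = compute_ci(CiInputs(*base))
        r2 = compute_ci(CiInputs(*(v * scale for v in base)))
        assert r2.ci == pytest.approx(r1.ci, rel=1e-9)


class TestCiFromSeries:
    def test_fragmented_network_scores_below_cutoff(self, fragmented_experiment):
        exp = fragmented_experiment
        res = ci_from_series(exp.series, exp.rois)
        assert res.ci < 0.1

    def test_tubular_network_scores_above_cutoff(self, tubular_experiment):
        exp = tubular_experiment
        res = ci_from_series(exp.series, exp.rois)
        assert res.ci >= 0.1

    def test_missing_roi_raises(self, tubular_experiment):
        from frapconn.series_io import RoiSet

        exp = tubular_experiment
        partial = RoiSet({"a": exp.rois["a"], "b": exp.rois["b"]})
        with pytest.raises(KeyError, match="'c'"):
            ci_from_series(exp.series, partial)

    def test_prebleach_mean_mode_close_to_single_frame(self, tubular_experiment):
        exp = tubular_experiment
        single = ci_from_series(exp.series, exp.rois, pre_frame_mode="single")
        mean = ci_from_series(exp.series, exp.rois, pre_frame_mode="mean")
        assert mean.ci == pytest.approx(single.ci, abs=0.2)


class TestCalibrateCutoff:
    def test_cutoff_bounded_by_negative_controls(self):
        res = calibrate_cutoff([0.8, 0.9, 0.95], [0.0, 0.01, 0.02], alpha=0.05)
        assert res.cutoff <= 0.02
        assert res.separable

    def test_identical_distributions_warn(self):
        with pytest.warns(UserWarning, match="not separable"):
            res = calibrate_cutoff([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert not res.separable

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            calibrate_cutoff([], [0.1])

    def test_simulated_controls_give_cutoff_below_default(self):
        """Fragmented (negative) vs tubular (positive) simulations separate
        with an empirical cut-off below the 0.1 pipeline default."""
        negatives, positives = [], []
        for seed in range(1, 7):
            frag = simulate_experiment(
                "fragmented", 3, seed=seed, noise_model="poisson", n_postbleach=10
            )
            negatives.append(ci_from_series(frag.series, frag.rois).ci)
            tub = simulate_experiment(
                "tubular", 4, seed=seed, noise_model="poisson", n_postbleach=10
            )
            positives.append(ci_from_series(tub.series, tub.rois).ci)
        res = calibrate_cutoff(positives, negatives, alpha=0.05)
        assert res.separable
        assert res.cutoff < 0.1
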