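import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gebvrel import (
    FULL_GENETIC,
    MARKER_CAPTURED,
    InfoSource,
    PopulationParams,
    merge_pedigree_genomic_sit,
    merge_subpops_fi,
    merge_subpops_sit,
    r2_from_theta,
    r2_from_theta_selfconsistent,
    reliability_joint_fit,
    sum_information,
    theta_from_r2_full,
    theta_from_r2_marker,
    theta_from_r2_marker_selfconsistent,
)


class TestInfoSource:
    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            InfoSource(-0.1, MARKER_CAPTURED)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            InfoSource(1.0, "polygenic")


class TestR2FromTheta:
    def test_second_example_frozen(self):
        # frozen residual at the per-source reliability reproduces the
        # combined pedigree+genomic value
        assert r2_from_theta(2.7590, 0.3, 0.6297) == pytest.approx(0.7728, abs=5e-5)

    def test_zero_theta(self):
        assert r2_from_theta(0.0, 0.5, 0.4) == 0.0

    def test_h2_zero_oracle(self):
        # theta/(theta+1) regardless of the residual reference
        assert r2_from_theta(1.0, 0.0, 0.99) == pytest.approx(0.5, abs=1e-14)

    def test_bad_residual_ref(self):
        with pytest.raises(ValueError):
            r2_from_theta(1.0, 0.3, 1.2)


class TestSelfConsistent:
    def test_second_example_value(self):
        assert r2_from_theta_selfconsistent(2.7590, 0.3) == pytest.approx(0.7829, abs=5e-5)

    def test_zero_theta(self):
        assert r2_from_theta_selfconsistent(0.0, 0.3) == 0.0

    def test_equals_joint_fit_q2_one(self):
        for theta in (0.2, 1.0, 4.0):
            assert r2_from_theta_selfconsistent(theta, 0.45) == pytest.approx(
                reliability_joint_fit(theta, 0.45, 1.0).r2, abs=1e-14
            )

    def test_marker_route_gives_deviation_reliability(self):
        # theta=3.0 through the marker route with q2=0.8 pre-scaling
        r2 = reliability_joint_fit(3.0, 0.3, 0.8).r2
        assert r2 == pytest.approx(0.6297, abs=5e-5)


class TestMarkerInversion:
    def test_zero(self, example1_params):
        assert theta_from_r2_marker(0.0, example1_params).theta == 0.0
        assert theta_from_r2_marker(0.0, example1_params).target == MARKER_CAPTURED

    def test_round_trip_oracle(self, example1_params):
        # forward-evaluate the frozen-residual form at theta=0.75, then invert
        p = example1_params
        s = p.segment_variance
        r2 = p.q2 * 0.75 / (0.75 + 1 - s)
        assert r2 == pytest.approx(0.342975, abs=5e-6)
        assert theta_from_r2_marker(r2, p).theta == pytest.approx(0.75, abs=1e-12)

    def test_pole_approach_monotone(self, example1_params):
        p = example1_params
        rs = np.linspace(0.70, 0.7999, 50)
        thetas = [theta_from_r2_marker(r, p).theta for r in rs]
        assert all(b > a for a, b in zip(thetas, thetas[1:]))
        assert thetas[-1] > 1e3

    def test_r2_at_or_above_q2_rejected(self, example1_params):
        with pytest.raises(ValueError):
            theta_from_r2_marker(0.8, example1_params)

    def test_selfconsistent_inversion_recovers_design_theta(self, example1_params):
        # first worked example: the joint-fit reliability at theta=0.75 maps
        # back to 0.75 through the self-consistent inversion
        r2 = reliability_joint_fit(0.75, 0.3, 0.8).r2
        got = theta_from_r2_marker_selfconsistent(r2, example1_params).theta
        assert got == pytest.approx(0.75, abs=1e-10)


class TestFullInversion:
    def test_second_example_value(self):
        r_d = reliability_joint_fit(3.0, 0.3, 0.8).r2  # unrounded 0.6297...
        assert theta_from_r2_full(r_d, 0.3).theta == pytest.approx(1.3795, abs=5e-5)

    def test_zero(self):
        src = theta_from_r2_full(0.0, 0.3)
        assert src.theta == 0.0
        assert src.target == FULL_GENETIC

    def test_r2_one_rejected(self):
        with pytest.raises(ValueError):
            theta_from_r2_full(1.0, 0.3)

    @given(
        r2=st.floats(0.01, 0.99),
        h2=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_inverse_pair(self, r2, h2):
        theta = theta_from_r2_full(r2, h2).theta
        assert r2_from_theta_selfconsistent(theta, h2) == pytest.approx(r2, abs=1e-9)


class TestSumInformation:
    def test_marker_sum(self):
        total = sum_information(
            [InfoSource(0.75, MARKER_CAPTURED), InfoSource(0.75, MARKER_CAPTURED)]
        )
        assert total.theta == pytest.approx(1.5)
        assert total.target == MARKER_CAPTURED

    def test_full_sum(self):
        total = sum_information(
            [InfoSource(1.3795, FULL_GENETIC), InfoSource(1.3795, FULL_GENETIC)]
        )
        assert total.theta == pytest.approx(2.7590)

    def test_mixed_targets_refused(self):
        with pytest.raises(ValueError, match="different genetic components"):
            sum_information(
                [InfoSource(1.0, MARKER_CAPTURED, "genomic"),
                 InfoSource(1.0, FULL_GENETIC, "pedigree")]
            )

    def test_empty_refused(self):
        with pytest.raises(ValueError):
            sum_information([])


class TestMergeSubpopsSit:
    def test_first_example(self):
        r = reliability_joint_fit(0.75, 0.3, 0.8).r2
        assert merge_subpops_sit(r, r, 0.8) == pytest.approx(0.5020, abs=5e-5)

    def test_empty_second_subpop(self):
        assert merge_subpops_sit(0.3, 0.0, 0.8) == pytest.approx(0.3, abs=1e-14)

    def test_q2_one_reduces_to_pedigree_form(self):
        assert merge_subpops_sit(0.3, 0.2, 1.0) == pytest.approx(
            merge_pedigree_genomic_sit(0.3, 0.2), abs=1e-14
        )

    def test_symmetric(self):
        assert merge_subpops_sit(0.25, 0.4, 0.9) == pytest.approx(
            merge_subpops_sit(0.4, 0.25, 0.9), abs=1e-14
        )

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError):
            merge_subpops_sit(0.8, 0.8, 0.8)


class TestMergePedigreeGenomicSit:
    def test_second_example(self):
        r = reliability_joint_fit(3.0, 0.3, 0.8).r2
        assert merge_pedigree_genomic_sit(r, r) == pytest.approx(0.7728, abs=5e-5)

    def test_half_half_oracle(self):
        # (0.5 + 0.5 - 2*0.25)/(1 - 0.25) = 0.5/0.75
        assert merge_pedigree_genomic_sit(0.5, 0.5) == pytest.approx(2 / 3, abs=1e-12)

    def test_zero_source(self):
        assert merge_pedigree_genomic_sit(0.42, 0.0) == pytest.approx(0.42, abs=1e-14)

    @given(a=st.floats(0.0, 0.98), b=st.floats(0.0, 0.98))
    @settings(max_examples=200, deadline=None)
    def test_dominates_inputs_below_one(self, a, b):
        merged = merge_pedigree_genomic_sit(a, b)
        assert merged >= max(a, b) - 1e-12
        assert merged < 1.0


class TestMergeSubpopsFi:
    def test_frozen_first_example(self, example1_params):
        r = reliability_joint_fit(0.75, 0.3, 0.8).r2
        res = merge_subpops_fi([r, r], example1_params, account_residual_reduction=False)
        assert res.r2 == pytest.approx(0.5020, abs=5e-5)
        assert res.residual_assumption == "fixed_reference_r2"

    def test_reduced_first_example(self, example1_params):
        r = reliability_joint_fit(0.75, 0.3, 0.8).r2
        res = merge_subpops_fi([r, r], example1_params, account_residual_reduction=True)
        assert res.r2 == pytest.approx(0.5114, abs=5e-5)
        assert res.residual_assumption == "joint_fit"

    @pytest.mark.parametrize("flag", [False, True])
    def test_single_source_unchanged(self, flag, example1_params):
        res = merge_subpops_fi([0.31], example1_params, account_residual_reduction=flag)
        assert res.r2 == pytest.approx(0.31, abs=1e-10)

    def test_empty_rejected(self, example1_params):
        with pytest.raises(ValueError):
            merge_subpops_fi([], example1_params)

    def test_reduced_never_below_frozen(self, example1_params):
        rs = np.linspace(0.02, 0.75, 15)
        for r1 in rs:
            for r2 in rs:
                off = merge_subpops_fi([r1, r2], example1_params, False).r2
                on = merge_subpops_fi([r1, r2], example1_params, True).r2
                assert on >= off - 1e-12

    def test_zero_source_is_neutral(self, example1_params):
        base = merge_subpops_fi([0.3, 0.25], example1_params, False).r2
        with_zero = merge_subpops_fi([0.3, 0.25, 0.0], example1_params, False).r2
        assert with_zero == pytest.approx(base, abs=1e-12)


class TestEquivalenceTheorem:
    """The central claim: SIT and frozen-residual FI agree exactly."""

    @pytest.mark.parametrize("q2", [0.5, 0.65, 0.8, 0.9, 1.0])
    @pytest.mark.parametrize("h2", [0.1, 0.4, 0.9])
    def test_grid(self, q2, h2):
        params = PopulationParams(0, h2, q2, 400)
        rs = np.arange(0.05, q2 - 0.049, 0.1)
        for r1 in rs:
            for r2 in rs:
                sit = merge_subpops_sit(r1, r2, q2)
                fi = merge_subpops_fi([r1, r2], params, False).r2
                assert fi == pytest.approx(sit, abs=1e-9)

    def test_merged_dominates_and_capped_by_q2(self):
        params = PopulationParams(0, 0.3, 0.8, 400)
        for r1 in (0.1, 0.4, 0.7):
            for r2 in (0.05, 0.3, 0.6):
                merged = merge_subpops_fi([r1, r2], params, False).r2
                assert merged >= max(r1, r2) - 1e-12
                assert merged <= params.q2 + 1e-12
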