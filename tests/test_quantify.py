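import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from otolithist import (
    InstrumentConfig,
    StandardBracket,
    blank_correct,
    block_average,
    bracket_from_runs,
    compute_blank_stats,
    lod_filter,
    measure_standard,
    quantify_block,
    to_molar_ratio,
)
from otolithist.errors import (
    CalibrationError,
    CoverageError,
    EmptyInputError,
    ParameterError,
    RoleError,
)


class TestBlockAverage:
    def test_mean_of_constants_is_exact(self, make_run):
        run = make_run(Sr87=np.full(20, 7.0), Ca43=np.full(20, 3.0))
        out = block_average(run, 10)
        assert len(out) == 2
        np.testing.assert_array_equal(out.intensities["Sr87"], [7.0, 7.0])

    def test_arithmetic_means_per_block(self, make_run):
        run = make_run(Sr87=np.arange(1.0, 21.0), Ca43=np.ones(20))
        out = block_average(run, 10)
        np.testing.assert_allclose(out.intensities["Sr87"], [5.5, 15.5])
        np.testing.assert_allclose(out.times, [4.5, 14.5])  # mean of block times

    def test_trailing_partial_block_dropped(self, make_run):
        run = make_run(Sr87=np.arange(25.0), Ca43=np.ones(25))
        assert len(block_average(run, 10)) == 2

    def test_block_size_one_is_identity(self, make_run):
        run = make_run(Sr87=np.arange(5.0), Ca43=np.arange(5.0) + 1)
        out = block_average(run, 1)
        np.testing.assert_array_equal(out.intensities["Sr87"], run.intensities["Sr87"])

    def test_missing_reads_excluded_from_block_mean(self, make_run):
        sr = np.array([1.0, np.nan, 3.0, 5.0])
        run = make_run(Sr87=sr, Ca43=np.ones(4))
        out = block_average(run, 2)
        np.testing.assert_allclose(out.intensities["Sr87"], [1.0, 4.0])

    def test_default_reads_per_point_is_ten(self, config):
        assert config.block_size == 10

    def test_run_shorter_than_one_block_errors(self, make_run):
        run = make_run(Sr87=np.ones(5), Ca43=np.ones(5))
        with pytest.raises(EmptyInputError):
            block_average(run, 10)


class TestBlankStats:
    def test_pooled_mean_and_sample_sd(self, make_run):
        blank = make_run(role="blank", Sr87=[90.0, 100.0, 110.0], Ca43=[1.0, 1.0, 1.0])
        stats = compute_blank_stats([blank])
        assert stats.mean["Sr87"] == pytest.approx(100.0)
        assert stats.sd["Sr87"] == pytest.approx(10.0)  # sample SD, ddof=1
        assert stats.sd["Ca43"] == 0.0

    def test_two_identical_blanks_pool_to_same_stats(self, make_run):
        blank = make_run(role="blank", Sr87=[90.0, 100.0, 110.0], Ca43=[1.0, 2.0, 3.0])
        one = compute_blank_stats([blank])
        two = compute_blank_stats([blank, blank])
        assert two.mean == one.mean
        assert two.sd["Sr87"] == pytest.approx(np.std([90, 100, 110] * 2, ddof=1))
        assert two.n_blanks == 2

    def test_missing_read_excluded(self, make_run):
        blank = make_run(role="blank", Sr87=[90.0, np.nan, 110.0], Ca43=[1.0, 1.0, 1.0])
        stats = compute_blank_stats([blank])
        assert stats.mean["Sr87"] == pytest.approx(100.0)

    def test_mixed_roles_rejected(self, make_run):
        sample = make_run(role="sample", Sr87=[1.0], Ca43=[1.0])
        with pytest.raises(RoleError):
            compute_blank_stats([sample])

    def test_no_blanks_rejected(self):
        with pytest.raises(EmptyInputError):
            compute_blank_stats([])


class TestBlankCorrect:
    def test_subtracts_blank_mean(self, make_run):
        run = make_run(Sr87=[500.0], Ca43=[1000.0])
        blank = make_run(role="blank", Sr87=[100.0, 100.0], Ca43=[50.0, 50.0])
        out = blank_correct(run, compute_blank_stats([blank]))
        assert out.intensities["Sr87"][0] == pytest.approx(400.0)
        assert out.intensities["Ca43"][0] == pytest.approx(950.0)

    def test_zero_blank_is_identity(self, make_run):
        run = make_run(Sr87=[500.0], Ca43=[1000.0])
        blank = make_run(role="blank", Sr87=[0.0, 0.0], Ca43=[0.0, 0.0])
        out = blank_correct(run, compute_blank_stats([blank]))
        np.testing.assert_array_equal(out.intensities["Sr87"], run.intensities["Sr87"])

    def test_blank_level_signal_may_go_negative(self, make_run):
        run = make_run(Sr87=[95.0, 105.0], Ca43=[100.0, 100.0])
        blank = make_run(role="blank", Sr87=[100.0, 100.0], Ca43=[100.0, 100.0])
        out = blank_correct(run, compute_blank_stats([blank]))
        assert out.intensities["Sr87"][0] < 0 < out.intensities["Sr87"][1]

    def test_uncovered_isotope_rejected(self, make_run):
        run = make_run(Sr87=[1.0], Ca43=[1.0])
        blank = make_run(role="blank", Sr87=[0.0, 0.0], Ca43=[0.0, 0.0])
        stats = compute_blank_stats([blank])
        del stats.mean["Ca43"]
        with pytest.raises(CoverageError):
            blank_correct(run, stats)


class TestLodFilter:
    @pytest.fixture
    def stats(self, make_run):
        rng = np.random.default_rng(0)
        # mean 100, sd 10 by construction
        reads = np.array([90.0, 100.0, 110.0])
        blank = make_run(role="blank", Sr87=reads, Ca43=reads)
        return compute_blank_stats([blank])

    def test_threshold_is_mean_minus_k_sd(self, make_run, stats):
        # threshold 100 - 3*10 = 70: 65 flagged, 75 kept
        run = make_run(Sr87=[65.0, 75.0], Ca43=[500.0, 500.0])
        out = lod_filter(run, stats, multiplier=3.0, sign=-1)
        assert list(out.flags) == ["below_lod", "ok"]

    def test_point_removed_whole_on_either_isotope(self, make_run, stats):
        run = make_run(Sr87=[500.0], Ca43=[65.0])
        out = lod_filter(run, stats, 3.0, -1)
        assert out.flags[0] == "below_lod"

    def test_zero_sd_threshold_equals_blank_mean(self, make_run):
        blank = make_run(role="blank", Sr87=[100.0, 100.0], Ca43=[100.0, 100.0])
        stats = compute_blank_stats([blank])
        run = make_run(Sr87=[99.0, 100.0, 101.0], Ca43=[500.0] * 3)
        out = lod_filter(run, stats, 3.0, -1)
        assert list(out.flags) == ["below_lod", "ok", "ok"]

    def test_conventional_plus_sign_switch(self, make_run, stats):
        run = make_run(Sr87=[125.0, 135.0], Ca43=[500.0, 500.0])
        out = lod_filter(run, stats, 3.0, sign=+1)  # threshold 130
        assert list(out.flags) == ["below_lod", "ok"]

    def test_flag_count_non_increasing_in_multiplier(self, make_run, stats):
        rng = np.random.default_rng(1)
        run = make_run(Sr87=rng.uniform(0, 200, 100), Ca43=np.full(100, 500.0))
        counts = [
            (lod_filter(run, stats, m, -1).flags == "below_lod").sum()
            for m in [0.0, 1.0, 2.0, 3.0, 5.0]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_negative_multiplier_is_a_parameter_error(self, make_run, stats):
        run = make_run(Sr87=[100.0], Ca43=[100.0])
        with pytest.raises(ParameterError):
            lod_filter(run, stats, -3.0)


class TestToMolarRatio:
    def _run_with_ratio(self, make_run, config, raw_ratio, n=4):
        ab = config.isotope_abundance
        ca_el = 1000.0
        return make_run(
            Sr87=np.full(n, ca_el * raw_ratio * ab["Sr87"]),
            Ca43=np.full(n, ca_el * ab["Ca43"]),
        )

    def test_standard_self_calibration_returns_certified_value(self, make_run, config):
        std = self._run_with_ratio(make_run, config, raw_ratio=0.004)
        measured = measure_standard(std.replace(role="standard", fish_id=None), config)
        bracket = StandardBracket(certified_mmol_mol=config.certified_mmol_mol, pre=measured)
        profile = to_molar_ratio(std, bracket, config)
        np.testing.assert_allclose(profile.ratios, config.certified_mmol_mol, rtol=1e-12)

    @settings(
        max_examples=25, deadline=None, derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_ratio_invariance_under_intensity_scaling(self, make_run, config, k):
        run = self._run_with_ratio(make_run, config, raw_ratio=0.002)
        scaled = run.replace(intensities={i: a * k for i, a in run.intensities.items()})
        bracket = StandardBracket(certified_mmol_mol=2.0, pre=0.004)
        base = to_molar_ratio(run, bracket, config).ratios
        np.testing.assert_allclose(to_molar_ratio(scaled, bracket, config).ratios, base, rtol=1e-9)

    def test_single_standard_gives_constant_factor(self, config):
        b = StandardBracket(certified_mmol_mol=2.0, pre=0.004)
        assert b.factor_at(0.0) == b.factor_at(1.0) == 500.0

    def test_factor_interpolates_between_standards(self, config):
        b = StandardBracket(certified_mmol_mol=2.0, pre=0.004, post=0.005)
        assert b.factor_at(0.0) == pytest.approx(500.0)
        assert b.factor_at(1.0) == pytest.approx(400.0)
        assert b.factor_at(0.5) == pytest.approx(450.0)

    def test_positions_are_times_by_scan_speed(self, make_run, config):
        run = self._run_with_ratio(make_run, config, 0.002)
        bracket = StandardBracket(certified_mmol_mol=2.0, pre=0.004)
        profile = to_molar_ratio(run, bracket, config)
        np.testing.assert_allclose(profile.positions, run.times * 5.0)

    def test_nonpositive_standard_ratio_is_a_calibration_error(self):
        with pytest.raises(CalibrationError):
            StandardBracket(certified_mmol_mol=2.0, pre=-0.004)

    def test_missing_bracket_is_a_calibration_error(self):
        with pytest.raises(CalibrationError):
            StandardBracket(certified_mmol_mol=2.0)

    def test_flagged_points_carry_nan_and_keep_flags(self, make_run, config):
        run = self._run_with_ratio(make_run, config, 0.002)
        flags = np.array(["ok", "below_lod", "ok", "missing"], dtype=object)
        run = run.replace(flags=flags)
        bracket = StandardBracket(certified_mmol_mol=2.0, pre=0.004)
        profile = to_molar_ratio(run, bracket, config)
        assert list(profile.flags) == ["ok", "below_lod", "ok", "missing"]
        assert np.isnan(profile.ratios[[1, 3]]).all()
        assert np.isfinite(profile.ratios[[0, 2]]).all()


class TestQuantifyBlock:
    def test_full_block_reduction_recovers_known_ratio(self, make_run, config):
        """A sample whose raw ratio equals the standard's must calibrate to the certificate."""
        ab = config.isotope_abundance
        n = 40
        blank_level = 50.0
        raw_ratio = 0.004

        def runs(role, rid):
            return make_run(
                role=role,
                Sr87=np.full(n, 1000.0 * raw_ratio * ab["Sr87"] + blank_level),
                Ca43=np.full(n, 1000.0 * ab["Ca43"] + blank_level),
            ).replace(run_id=rid, fish_id="f1" if role == "sample" else None)

        blank = make_run(role="blank", Sr87=np.full(n, blank_level), Ca43=np.full(n, blank_level))
        profiles = quantify_block(
            [runs("sample", "s")], [blank], config,
            pre_standard=runs("standard", "pre"), post_standard=runs("standard", "post"),
        )
        assert len(profiles) == 1
        ok = profiles[0].ok_ratios
        assert len(ok) == n // config.block_size
        np.testing.assert_allclose(ok, config.certified_mmol_mol, rtol=1e-9)
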