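import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoichlab import (
    ArgumentError,
    BandType,
    Construct,
    DataError,
    FitError,
    GelBand,
    GelLane,
    GelTable,
    anova_units,
    assay1_stoichiometry,
    assay2_stoichiometry,
    default_assay1_config,
    default_assay2_config,
    estimate_mw,
    fit_standard_curve,
    normalize_migration,
    simulate_gel,
    stoichiometry_hypothesis_fit,
    summarize_units,
)
from stoichlab.gel import StoichiometryResult


def make_lane(lane_id="L1", d_us1=12.0, d_us2=160.0, d_shift=60.0):
    return GelLane(
        lane_id=lane_id,
        bands=[
            GelBand(BandType.REF_UPPER, d_us1),
            GelBand(BandType.REF_LOWER, d_us2),
            GelBand(BandType.LOWER_SHIFT, d_shift),
        ],
    )


class TestNormalizeMigration:
    def test_reference_difference(self):
        assert normalize_migration(make_lane(), BandType.LOWER_SHIFT) == 100.0

    def test_band_comigrating_with_fast_reference(self):
        lane = make_lane(d_shift=160.0)
        assert normalize_migration(lane, BandType.LOWER_SHIFT) == 0.0

    def test_missing_reference_names_lane(self):
        lane = GelLane(
            lane_id="L7",
            bands=[
                GelBand(BandType.REF_LOWER, 160.0),
                GelBand(BandType.LOWER_SHIFT, 60.0),
            ],
        )
        with pytest.raises(DataError, match="L7"):
            normalize_migration(lane, BandType.LOWER_SHIFT)

    def test_missing_band_is_error(self):
        with pytest.raises(DataError, match="supershift"):
            normalize_migration(make_lane(), BandType.SUPERSHIFT)

    @settings(max_examples=50, derandomize=True)
    @given(
        d_us1=st.floats(0, 50),
        gap=st.floats(0.1, 200),
        d_shift=st.floats(0, 300),
    )
    def test_algebraic_identity(self, d_us1, gap, d_shift):
        """The ref_upper term cancels: result equals d_ref_lower - d_band."""
        lane = make_lane(d_us1=d_us1, d_us2=d_us1 + gap, d_shift=d_shift)
        norm = normalize_migration(lane, BandType.LOWER_SHIFT)
        assert norm == pytest.approx((d_us1 + gap) - d_shift, abs=1e-9)


class TestStandardCurve:
    def test_two_point_fit_is_exact(self):
        curve = fit_standard_curve([(50.0, 100.0), (150.0, 1000.0)], anchor_index=0)
        assert curve.slope == pytest.approx(0.01)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_recovers_generating_law_without_noise(self):
        # forward model d = c1 + c2*log10(MW) inverts to slope 1/c2
        c1, c2 = 20.0, 80.0
        mws = np.geomspace(50, 2000, 9)
        standards = [(c1 + c2 * np.log10(m), m) for m in mws]
        curve = fit_standard_curve(standards, anchor_index=0)
        assert curve.slope == pytest.approx(1.0 / c2, rel=1e-10)
        assert curve.r_squared == pytest.approx(1.0)

    def test_high_correlation_at_low_noise(self):
        rng = np.random.default_rng(7)
        c1, c2 = 20.0, 80.0
        mws = np.geomspace(50, 2000, 9)
        d = np.array([c1 + c2 * np.log10(m) for m in mws])
        d = d + rng.normal(0, 0.01 * np.ptp(d), size=d.size)
        curve = fit_standard_curve(list(zip(d, mws)), anchor_index=0)
        assert curve.r_squared > 0.97

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_standard_curve([(50.0, 100.0)])

    def test_duplicate_distances(self):
        with pytest.raises(FitError):
            fit_standard_curve([(50.0, 100.0), (50.0, 1000.0)])

    def test_estimate_mw_example(self):
        curve = fit_standard_curve([(50.0, 100.0), (150.0, 1000.0)], anchor_index=0)
        assert estimate_mw(curve, 100.0) == pytest.approx(316.2, abs=0.1)

    def test_estimate_mw_identity_at_anchor(self):
        curve = fit_standard_curve([(50.0, 100.0), (150.0, 1000.0)], anchor_index=0)
        assert estimate_mw(curve, curve.anchor_distance) == pytest.approx(
            curve.anchor_mw
        )

    def test_estimate_mw_strictly_increasing(self):
        curve = fit_standard_curve([(50.0, 100.0), (150.0, 1000.0)], anchor_index=0)
        grid = np.linspace(0, 250, 40)
        est = [estimate_mw(curve, d) for d in grid]
        assert np.all(np.diff(est) > 0)

    def test_forward_inverse_round_trip(self):
        c1, c2 = 20.0, 80.0
        mws = np.geomspace(50, 2000, 9)
        standards = [(c1 + c2 * np.log10(m), m) for m in mws]
        curve = fit_standard_curve(standards, anchor_index=0)
        for m in (75.0, 333.0, 1500.0):
            assert estimate_mw(curve, c1 + c2 * np.log10(m)) == pytest.approx(m)


class TestSummarizeUnits:
    def test_fcs_ratio_group(self):
        mean, half, n = summarize_units([3.84, 3.43, 3.35, 2.95, 3.15])
        assert round(mean, 2) == 3.34
        assert round(half, 2) == 0.41
        assert n == 5

    def test_monomer_control_group(self):
        mean, half, n = summarize_units([1.47, 1.23, 1.76])
        assert round(mean, 2) == 1.49
        assert round(half, 2) == 0.66

    def test_zero_variance(self):
        mean, half, n = summarize_units([2.0, 2.0, 2.0])
        assert (mean, half, n) == (2.0, 0.0, 3)

    def test_single_value_has_undefined_ci(self):
        mean, half, n = summarize_units([3.1])
        assert mean == 3.1 and n == 1 and np.isnan(half)

    def test_empty_is_error(self):
        with pytest.raises(ArgumentError):
            summarize_units([])


class TestAssayRoundTrips:
    @pytest.mark.parametrize("true_units", [1, 2, 3, 4, 5, 6])
    def test_assay1_exact_at_zero_noise(self, znf, true_units):
        cfg = default_assay1_config(
            znf, true_units=true_units, seed=3, band_noise_sd=0.0, lane_offset_sd=4.0
        )
        result = assay1_stoichiometry(simulate_gel(cfg), znf)
        assert result.mean_units == pytest.approx(true_units, abs=1e-6)
        for u in result.per_measurement_units:
            assert u == pytest.approx(true_units, abs=1e-6)

    @pytest.mark.parametrize("true_units", [1, 2, 3, 4, 5, 6])
    def test_assay2_exact_at_zero_noise(self, znf, true_units):
        cfg = default_assay2_config(
            znf, true_units=true_units, seed=3, band_noise_sd=0.0, lane_offset_sd=4.0
        )
        result = assay2_stoichiometry(simulate_gel(cfg), znf, cfg.probe_fragment)
        assert result.mean_units == pytest.approx(true_units, abs=1e-6)

    def test_assays_agree_for_other_monomer_sizes(self, eyfp_znf):
        """Both estimators recover the same truth for a different construct."""
        cfg1 = default_assay1_config(
            eyfp_znf, true_units=3, seed=5, band_noise_sd=0.0, lane_offset_sd=2.0
        )
        cfg2 = default_assay2_config(
            eyfp_znf, true_units=3, seed=5, band_noise_sd=0.0, lane_offset_sd=2.0
        )
        r1 = assay1_stoichiometry(simulate_gel(cfg1), eyfp_znf)
        r2 = assay2_stoichiometry(simulate_gel(cfg2), eyfp_znf, cfg2.probe_fragment)
        assert abs(r1.mean_units - r2.mean_units) < 1e-6

    def test_assay2_free_dna_lane_reads_as_zero_units(self, znf):
        """A 'complex' migrating exactly as free probe DNA implies 0 units."""
        cfg = default_assay2_config(
            znf, true_units=0, seed=0, band_noise_sd=0.0, lane_offset_sd=0.0
        )
        result = assay2_stoichiometry(simulate_gel(cfg), znf, cfg.probe_fragment)
        assert result.mean_units == pytest.approx(0.0, abs=1e-6)

    def test_assay1_requires_enough_standards(self, znf):
        cfg = default_assay1_config(znf, seed=0, band_noise_sd=0.0)
        gel = simulate_gel(cfg)
        truncated = GelTable(lanes=gel.lanes[:2], assay_mode="assay1")
        with pytest.raises(DataError):
            assay1_stoichiometry(truncated, znf)

    def test_assay1_requires_a_supershift(self, znf):
        cfg = default_assay1_config(znf, seed=0, band_noise_sd=0.0)
        gel = simulate_gel(cfg)
        standards_only = GelTable(
            lanes=[l for l in gel.lanes if not l.has_band(BandType.SUPERSHIFT)],
            assay_mode="assay1",
        )
        with pytest.raises(DataError):
            assay1_stoichiometry(standards_only, znf)

    def test_assay2_requires_ladder(self, znf):
        cfg = default_assay2_config(znf, seed=0, band_noise_sd=0.0)
        gel = simulate_gel(cfg)
        no_ladder = GelTable(
            lanes=[l for l in gel.lanes if l.construct is not None],
            assay_mode="assay2",
        )
        with pytest.raises(DataError):
            assay2_stoichiometry(no_ladder, znf, cfg.probe_fragment)

    def test_noisy_round_trip_recovers_trimer(self, znf):
        """Mean over 20 seeds at default (1%-of-span) noise stays near 3."""
        means = []
        for seed in range(20):
            cfg = default_assay2_config(znf, true_units=3, seed=seed)
            means.append(
                assay2_stoichiometry(
                    simulate_gel(cfg), znf, cfg.probe_fragment
                ).mean_units
            )
        assert abs(np.mean(means) - 3.0) < 0.3


class TestHypothesisFit:
    @pytest.mark.parametrize("truth", [2, 3])
    def test_generating_truth_wins(self, znf, truth):
        cfg = default_assay1_config(
            znf, true_units=truth, seed=2, band_noise_sd=0.0, lane_offset_sd=2.0
        )
        fit = stoichiometry_hypothesis_fit(simulate_gel(cfg), znf, {2, 3, 4})
        assert fit.best == truth
        assert fit[truth]["score"] == pytest.approx(0.0, abs=1e-12)
        assert fit[truth]["slope"] == pytest.approx(1.0)

    def test_single_hypothesis_returned_with_stats(self, znf):
        cfg = default_assay1_config(znf, true_units=3, seed=2, band_noise_sd=0.0)
        fit = stoichiometry_hypothesis_fit(simulate_gel(cfg), znf, {3})
        assert fit.best == 3
        assert set(fit[3]) == {"slope", "intercept", "r_squared", "score"}

    def test_empty_hypotheses_rejected(self, znf):
        cfg = default_assay1_config(znf, seed=0)
        with pytest.raises(ArgumentError):
            stoichiometry_hypothesis_fit(simulate_gel(cfg), znf, set())


class TestAnova:
    def _result(self, construct, values):
        mean, half, n = summarize_units(values)
        return StoichiometryResult(construct, list(values), mean, half, n)

    def test_identical_groups_give_zero_f(self, znf, eyfp_znf):
        r1 = self._result(znf, [3.0, 3.0, 3.0])
        r2 = self._result(eyfp_znf, [3.0, 3.0, 3.0])
        f, p = anova_units([r1, r2])
        assert f == 0.0 and p == 1.0

    def test_separated_groups_are_significant(self, znf, eyfp_znf):
        rng = np.random.default_rng(11)
        a = rng.normal(3.0, 0.1, size=10)
        b = rng.normal(5.0, 0.1, size=10)
        f, p = anova_units([self._result(znf, a), self._result(eyfp_znf, b)])
        assert p < 1e-3

    def test_single_group_rejected(self, znf):
        with pytest.raises(ArgumentError):
            anova_units([self._result(znf, [3.0, 3.1])])

    def test_undersized_group_rejected(self, znf, eyfp_znf):
        with pytest.raises(ArgumentError):
            anova_units(
                [self._result(znf, [3.0, 3.1]), self._result(eyfp_znf, [3.0])]
            )
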