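import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoichlab import (
    ArgumentError,
    DataError,
    DnaFragment,
    FitError,
    TitrationPoint,
    TitrationSimConfig,
    digest_rearrangement,
    dna_mw,
    fit_kd,
    fraction_bound,
    predict_band_pattern,
    simulate_titration,
    tandem_fractions,
)


class TestFractionBound:
    def test_closed_form_at_kd(self):
        # (101 - sqrt(9241)) / 10
        expected = (101 - math.sqrt(9241)) / 10
        assert fraction_bound(48.0, 5.0, 48.0) == pytest.approx(expected)
        assert fraction_bound(48.0, 5.0, 48.0) == pytest.approx(0.487, abs=5e-4)

    def test_no_protein_no_binding(self):
        assert fraction_bound(0.0, 5.0, 48.0) == 0.0

    def test_saturation_limit(self):
        assert fraction_bound(1e12, 5.0, 48.0) == pytest.approx(1.0, abs=1e-6)

    def test_dilute_dna_limit_is_hyperbola(self):
        p0, kd = 30.0, 48.0
        assert fraction_bound(p0, 1e-9, kd) == pytest.approx(p0 / (p0 + kd), rel=1e-6)
        assert fraction_bound(p0, 0.0, kd) == p0 / (p0 + kd)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ArgumentError):
            fraction_bound(-1.0, 5.0, 48.0)
        with pytest.raises(ArgumentError):
            fraction_bound(1.0, 5.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        p0=st.floats(1e-3, 1e5),
        d0=st.floats(1e-3, 1e5),
        kd=st.floats(1e-3, 1e5),
    )
    def test_bounds_and_mass_conservation(self, p0, d0, kd):
        """FB in [0,1]; bound DNA can never exceed total protein."""
        fb = fraction_bound(p0, d0, kd)
        assert 0.0 <= fb <= 1.0
        assert fb * d0 <= p0 * (1 + 1e-9)

    def test_monotone_in_protein(self):
        p = np.geomspace(1e-3, 1e5, 200)
        fb = fraction_bound(p, 5.0, 48.0)
        assert np.all(np.diff(fb) >= 0)


class TestTandemFractions:
    @pytest.mark.parametrize(
        "theta, expected",
        [(0.5, (0.25, 0.5, 0.25)), (0.0, (1, 0, 0)), (1.0, (0, 0, 1))],
    )
    def test_known_points(self, theta, expected):
        assert tandem_fractions(theta) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(theta=st.floats(0, 1))
    def test_sums_to_one(self, theta):
        assert sum(tandem_fractions(theta)) == pytest.approx(1.0, abs=1e-12)

    def test_lower_shift_maximized_at_half_occupancy(self):
        """Grid-search oracle: the single-complex fraction peaks at theta=0.5."""
        grid = np.linspace(0, 1, 1001)
        lower = np.array([tandem_fractions(t)[1] for t in grid])
        assert grid[np.argmax(lower)] == pytest.approx(0.5, abs=1e-3)
        assert lower.max() == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ArgumentError):
            tandem_fractions(1.2)


class TestFitKd:
    def test_exact_recovery_without_noise(self):
        pts = simulate_titration(TitrationSimConfig(kd=48.0, noise_cv=0.0))
        assert fit_kd(pts).kd == pytest.approx(48.0, rel=1e-6)

    def test_median_error_under_noise(self):
        errs = []
        for seed in range(100):
            pts = simulate_titration(
                TitrationSimConfig(kd=48.0, noise_cv=0.05, seed=seed)
            )
            errs.append(abs(fit_kd(pts).kd - 48.0) / 48.0)
        assert float(np.median(errs)) < 0.10

    def test_tandem_sum_mode(self):
        pts = simulate_titration(
            TitrationSimConfig(kd=35.0, mode="tandem", noise_cv=0.0)
        )
        fit = fit_kd(pts, mode="tandem_sum")
        # effective single-species K_D of summed shifts, same order of magnitude
        assert 5.0 < fit.kd < 100.0

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            fit_kd([])

    def test_flat_response_rejected(self):
        pts = [
            TitrationPoint(protein_conc=p, dna_conc=5.0, fraction_unbound=1.0)
            for p in (1.0, 2.0, 4.0)
        ]
        with pytest.raises(FitError):
            fit_kd(pts)


class TestBandPattern:
    def test_one_dna_per_complex_two_fragments(self, znf, single_75, single_273):
        pattern = predict_band_pattern(
            "one_dna_per_complex", [single_75, single_273], znf, 3
        )
        assert pattern.n_bands == 4

    def test_multi_dna_per_complex_two_fragments(self, znf, single_75, single_273):
        pattern = predict_band_pattern(
            "multi_dna_per_complex", [single_75, single_273], znf, 3
        )
        assert pattern.n_bands == 5

    def test_single_fragment_gives_two_bands(self, znf, single_75):
        pattern = predict_band_pattern("one_dna_per_complex", [single_75], znf, 3)
        assert pattern.n_bands == 2

    @settings(max_examples=30, derandomize=True)
    @given(bp1=st.integers(50, 400), bp2=st.integers(401, 900))
    def test_band_count_laws(self, bp1, bp2):
        from stoichlab import Construct

        c = Construct(name="c", monomer_mw=55.0)
        frags = [
            DnaFragment(name="a", length=bp1, n_sites=1),
            DnaFragment(name="b", length=bp2, n_sites=1),
        ]
        assert predict_band_pattern("one_dna_per_complex", frags, c, 3).n_bands == 4
        assert predict_band_pattern("multi_dna_per_complex", frags, c, 3).n_bands == 5

    def test_siteless_fragment_excluded_with_warning(self, znf, single_75):
        bare = DnaFragment(name="bare", length=200, n_sites=0)
        with pytest.warns(UserWarning, match="bare"):
            pattern = predict_band_pattern(
                "one_dna_per_complex", [single_75, bare], znf, 3
            )
        assert pattern.n_bands == 2

    def test_all_siteless_rejected(self, znf):
        bare = DnaFragment(name="bare", length=200, n_sites=0)
        with pytest.warns(UserWarning):
            with pytest.raises(ArgumentError):
                predict_band_pattern("one_dna_per_complex", [bare], znf, 3)


class TestDigestRearrangement:
    def test_free_tandem_becomes_two_free_products(self, znf, tandem_bamhi):
        pattern = digest_rearrangement(tandem_bamhi, "free", construct=znf, n_units=3)
        mws = sorted(mw for _, mw in pattern.species)
        assert mws == pytest.approx([dna_mw(75), dna_mw(157)])

    def test_supershift_becomes_two_single_complexes(self, znf, tandem_bamhi):
        """Each product carries one oligomer, migrating as a one-site shift."""
        pattern = digest_rearrangement(tandem_bamhi, "super", construct=znf, n_units=3)
        mws = sorted(mw for _, mw in pattern.species)
        assert mws == pytest.approx(
            [dna_mw(75) + 3 * 55.0, dna_mw(157) + 3 * 55.0]
        )
        assert pattern.n_bands == 2

    def test_lower_shift_gives_free_and_bound_products(self, znf, tandem_bamhi):
        pattern = digest_rearrangement(tandem_bamhi, "lower", construct=znf, n_units=3)
        assert pattern.n_bands == 4

    def test_fragment_without_cut_site_rejected(self, znf, single_75):
        with pytest.raises(ArgumentError):
            digest_rearrangement(single_75, "free", construct=znf, n_units=3)
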