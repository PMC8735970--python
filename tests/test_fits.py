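"""Quantification fits: decay normalization and fitting, FRAP recovery,
bath-calibrated protein counting, 3-D spot detection, chemotaxis index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selectorswitch import fits, synth

LN2 = math.log(2.0)


class TestNormalization:
    def test_endpoints(self):
        assert fits.normalize_induction_counts(np.array([5.0]), 5, 25)[0] == 0.0
        assert fits.normalize_induction_counts(np.array([25.0]), 5, 25)[0] == 1.0

    def test_midpoint(self):
        assert fits.normalize_induction_counts(np.array([15.0]), 5, 25)[0] \
            == pytest.approx(0.5)

    def test_rejects_degenerate_references(self):
        with pytest.raises(ValueError):
            fits.normalize_induction_counts(np.array([1.0]), 5, 5)

    @given(st.floats(-10, 10), st.floats(0, 30))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_inverts_affinely(self, n, spread):
        ctrl, hs = 5.0, 5.0 + spread + 0.1
        x = ctrl + n * (hs - ctrl)
        out = fits.normalize_induction_counts(np.array([x]), ctrl, hs)[0]
        assert out == pytest.approx(n, abs=1e-9)


class TestExponentialDecayFit:
    def test_noiseless_recovery_is_exact(self):
        t = np.array([0.0, 600, 1200, 1800, 2400])
        a_true = LN2 / 1020.0
        fit = fits.fit_exponential_decay(t, np.exp(-a_true * t), n_boot=0)
        assert fit.rate == pytest.approx(a_true, rel=1e-6)
        assert fit.half_life == pytest.approx(1020.0, rel=1e-6)

    def test_constant_series_rate_zero(self):
        t = np.array([0.0, 600, 1200, 1800])
        with pytest.warns(UserWarning):
            fit = fits.fit_exponential_decay(t, np.ones(4), n_boot=0)
        assert fit.rate == 0.0

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            fits.fit_exponential_decay([0, 1], [1.0, 0.5])

    def test_scale_invariance_of_rate(self):
        """The decay rate does not depend on intensity units (the series is
        normalized before fitting)."""
        ds = synth.gen_decay_chase(seed=5)
        df = ds.payload
        chase = df[df.group == "chase"]
        ctrl = df[df.group == "control"]["count"].mean()
        t0 = chase.t_seconds.min()
        hs = chase.loc[chase.t_seconds == t0, "count"].mean()
        for scale in (1.0, 7.3):
            norm = fits.normalize_induction_counts(
                chase["count"].to_numpy() * scale, ctrl * scale, hs * scale)
            fit = fits.fit_exponential_decay(chase.t_seconds.to_numpy(), norm,
                                             n_boot=0)
            if scale == 1.0:
                base = fit.rate
        assert fit.rate == pytest.approx(base, rel=1e-9)

    def test_synthetic_chase_round_trip(self):
        """The generator's true 17-min half-life is recovered within the CI
        of the full normalize-and-fit pipeline."""
        ds = synth.gen_decay_chase(true_half_life=17 * 60.0, seed=12)
        fit = fits.fit_decay_chase(ds.payload, n_boot=200, seed=1)
        lo, hi = fit.ci_half_life
        assert lo <= 17 * 60.0 <= hi
        assert fit.half_life == pytest.approx(17 * 60.0, rel=0.35)


class TestFrapFit:
    def test_noiseless_recovery_is_exact(self):
        t = np.arange(0.0, 4 * 3600, 600.0)
        b, f, x0 = LN2 / (83 * 60.0), LN2 / (83 * 60.0) * 1.0, 0.2
        y = f / b + (x0 - f / b) * np.exp(-b * t)
        fit = fits.fit_frap_recovery(t, y)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.x0 == pytest.approx(x0, rel=1e-6)
        assert fit.half_life == pytest.approx(83 * 60.0, rel=1e-6)

    def test_model_value_at_zero_is_x0(self):
        assert fits._frap_model(0.0, 0.3, 1e-4, 1e-3) == pytest.approx(0.3)

    def test_scale_invariance_of_rate(self):
        t = np.arange(0.0, 4 * 3600, 600.0)
        rng = np.random.default_rng(0)
        y = 1.0 - 0.8 * np.exp(-t / 4000.0) + rng.normal(0, 0.01, len(t))
        b1 = fits.fit_frap_recovery(t, y).b
        b2 = fits.fit_frap_recovery(t, 100.0 * y).b
        assert b1 == pytest.approx(b2, rel=1e-6)

    def test_synthetic_traces_round_trip(self):
        """Mean fitted half-life of six noisy traces is within 2 SD of 83 min."""
        ds = synth.gen_frap_trace(seed=3)
        times, traces = ds.payload
        fit = fits.fit_frap_recovery(times, traces)
        assert abs(fit.half_life - 83 * 60.0) < 2 * fit.half_life_sd


class TestProteinCounting:
    def test_zero_intensity_zero_count(self):
        assert fits.protein_count_from_bath_calibration(
            0.0, 100.0, 72.0, (1, 1, 1)) == 0.0

    def test_unit_conversion_at_bath_intensity(self):
        """Matching the 72 nM bath in a 4 um^3 nucleus gives ~173 molecules."""
        r = (4.0 * 3 / (4 * math.pi)) ** (1 / 3)   # radii for V = 4 um^3
        n = fits.protein_count_from_bath_calibration(50.0, 50.0, 72.0,
                                                     (r, r, r))
        assert n == pytest.approx(72.0 * 4.0 * 0.6022, rel=1e-6)
        assert n == pytest.approx(173.0, abs=1.0)

    def test_ellipsoid_volume_from_unit_radii(self):
        n = fits.protein_count_from_bath_calibration(1.0, 1.0, 1.0, (1, 1, 1))
        assert n == pytest.approx(4 * math.pi / 3 * 0.6022, rel=1e-9)

    def test_diameter_flag_halves(self):
        a = fits.protein_count_from_bath_calibration(1.0, 1.0, 1.0, (2, 2, 2),
                                                     diameters=True)
        b = fits.protein_count_from_bath_calibration(1.0, 1.0, 1.0, (1, 1, 1))
        assert a == pytest.approx(b)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            fits.protein_count_from_bath_calibration(1.0, 0.0, 72.0, (1, 1, 1))
        with pytest.raises(ValueError):
            fits.protein_count_from_bath_calibration(1.0, 1.0, 72.0, (0, 1, 1))


class TestSpotCounting:
    def test_noise_only_stack_counts_zero(self):
        ds = synth.gen_smfish_stack(n_spots=0, seed=1)
        n, coords, _ = fits.count_spots_3d(ds.payload, kernel_sigma=1.0)
        assert n == 0 and len(coords) == 0

    def test_threshold_above_maximum_counts_zero(self):
        ds = synth.gen_smfish_stack(n_spots=5, seed=2)
        n, _, _ = fits.count_spots_3d(ds.payload, threshold=1e9)
        assert n == 0

    def test_well_separated_spots_counted_exactly(self):
        ds = synth.gen_smfish_stack(n_spots=7, min_separation=8.0, seed=3)
        n, coords, _ = fits.count_spots_3d(ds.payload, kernel_sigma=1.0,
                                           min_separation=3)
        assert n == 7
        # every detected spot sits near a true one
        true = np.array(ds.ground_truth["positions"])
        for c in coords:
            assert np.min(np.linalg.norm(true - c, axis=1)) < 3.0

    def test_overlapping_pair_split_by_regional_maxima(self):
        """Two spots merged into one thresholded blob are still resolved."""
        pos = np.array([[8.0, 30.0, 28.0], [8.0, 30.0, 34.0]])
        ds = synth.gen_smfish_stack(positions=pos, noise_sd=2.0, seed=4)
        n, _, _ = fits.count_spots_3d(ds.payload, kernel_sigma=1.0,
                                      min_separation=3)
        assert n == 2

    def test_count_monotone_in_threshold(self):
        ds = synth.gen_smfish_stack(n_spots=6, seed=5)
        thresholds = [110.0, 130.0, 150.0, 200.0]
        counts = [fits.count_spots_3d(ds.payload, threshold=th)[0]
                  for th in thresholds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_deterministic_given_parameters(self):
        ds = synth.gen_smfish_stack(n_spots=4, seed=6)
        r1 = fits.count_spots_3d(ds.payload, kernel_sigma=1.0)
        r2 = fits.count_spots_3d(ds.payload, kernel_sigma=1.0)
        assert r1[0] == r2[0] and np.array_equal(r1[1], r2[1])


class TestChemotaxisIndex:
    @pytest.mark.parametrize("on,off,ci", [(100, 0, 1.0), (50, 50, 0.0),
                                           (75, 25, 0.5), (0, 80, -1.0)])
    def test_formula(self, on, off, ci):
        assert fits.chemotaxis_index(on, off) == pytest.approx(ci)

    def test_rejects_empty_assay(self):
        with pytest.raises(ValueError):
            fits.chemotaxis_index(0, 0)
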