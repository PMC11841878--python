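import numpy as np
import pytest

from canopyhsm.pe_classification import (DEFAULT_LABELS, BreakpointFit,
                                         HabitatClasses, build_classes,
                                         classify_grid, fit_breakpoints,
                                         fit_breakpoints_bruteforce,
                                         forced_unsuitable_break, pe_curve,
                                         smooth_pe)
from canopyhsm.raster import Raster


def curve_from_values(centers, values):
    """Hand-built PECurve with every bin defined."""
    from canopyhsm.pe_classification import PECurve

    centers = np.asarray(centers, dtype=float)
    vals = np.asarray(values, dtype=float)
    n = np.full(centers.size, 10)
    return PECurve(centers, 0.01, vals, n, n)


class TestPeCurve:
    def test_identical_samples_give_unit_ratio(self, rng):
        x = rng.uniform(0.05, 0.9, 5000)
        c = pe_curve(x, x)
        np.testing.assert_allclose(c.raw[c.defined], 1.0)

    def test_uniform_shift_analytic_ratio(self, rng):
        # used ~ U(0.5, 1), available ~ U(0, 1): density ratio is 0 below
        # 0.5 and 2 above, up to bin-width blur
        used = rng.uniform(0.5, 1.0, 100_000)
        avail = rng.uniform(0.0, 1.0, 100_000)
        c = pe_curve(used, avail)
        low = c.centers < 0.49
        high = (c.centers > 0.51) & (c.centers < 0.95)
        assert np.nanmax(c.raw[low & c.defined]) < 0.1
        ratios = c.raw[high & c.defined]
        assert ratios.mean() == pytest.approx(2.0, abs=0.05)
        np.testing.assert_allclose(ratios, 2.0, atol=0.25)  # per-bin noise

    def test_empty_available_bin_flagged_undefined(self):
        used = np.array([0.1, 0.5])
        avail = np.array([0.1, 0.1, 0.12])
        c = pe_curve(used, avail)
        assert np.isnan(c.raw[~c.defined]).all()
        assert (~c.defined).any()

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pe_curve(np.full(10, 0.5), np.full(10, 0.5))

    def test_mass_weighted_mean_near_one(self, rng):
        # with used drawn from the available pool, the available-mass
        # weighted mean of defined P/E ratios is ~1
        avail = rng.beta(2, 5, 50_000)
        used = rng.choice(avail, 5000)
        c = pe_curve(used, avail)
        d = c.defined
        weighted = np.average(c.raw[d], weights=c.n_available[d])
        assert weighted == pytest.approx(1.0, rel=0.05)


class TestSmoothing:
    def test_constant_curve_unchanged(self):
        c = curve_from_values(np.linspace(0.02, 0.3, 30), np.full(30, 1.7))
        s = smooth_pe(c)
        np.testing.assert_allclose(s.smoothed, 1.7)

    def test_line_reproduced_exactly(self):
        x = np.linspace(0.02, 0.3, 40)
        c = curve_from_values(x, 2.0 + 3.0 * x)
        s = smooth_pe(c)
        np.testing.assert_allclose(s.smoothed, 2.0 + 3.0 * x, atol=1e-12)

    def test_bin_count_preserved_and_noise_reduced(self, rng):
        x = np.linspace(0.02, 0.5, 100)
        y = 1 + 2 * x + rng.normal(0, 0.3, 100)
        s = smooth_pe(curve_from_values(x, y))
        assert s.smoothed.size == 100
        resid_raw = y - (1 + 2 * x)
        resid_sm = s.smoothed - (1 + 2 * x)
        assert np.std(resid_sm) < np.std(resid_raw)

    def test_too_few_bins_rejected(self):
        c = curve_from_values(np.linspace(0.02, 0.04, 5), np.ones(5))
        with pytest.raises(ValueError):
            smooth_pe(c)


class TestForcedBreak:
    def test_crossing_at_0p03(self):
        x = np.round(np.arange(0.02, 0.1, 0.002), 3)
        y = np.where(x <= 0.03, 0.5, 1.5)
        assert forced_unsuitable_break(curve_from_values(x, y)) == pytest.approx(0.03)

    def test_always_above_one_warns(self):
        c = curve_from_values([0.02, 0.04, 0.06], [1.5, 2.0, 2.5])
        with pytest.warns(UserWarning, match="never drops below"):
            assert forced_unsuitable_break(c) == pytest.approx(0.02)

    def test_always_below_one_warns_returns_max(self):
        c = curve_from_values([0.02, 0.04, 0.06], [0.2, 0.4, 0.6])
        with pytest.warns(UserWarning, match="never reaches"):
            assert forced_unsuitable_break(c) == pytest.approx(0.06)


def piecewise(x, kinks, slopes, intercept=0.0):
    y = intercept + slopes[0] * x
    for kink, extra in zip(kinks, slopes[1:]):
        y = y + extra * np.clip(x - kink, 0, None)
    return y


class TestBreakpoints:
    def test_noiseless_kinks_recovered_exactly(self):
        x = np.round(np.arange(0.05, 0.8, 0.025), 4)
        y = piecewise(x, [0.2, 0.5], [1.0, 3.0, -2.0], intercept=1.0)
        c = curve_from_values(x, y)
        fit = fit_breakpoints(c, k=2, forced_break=0.04)
        assert fit.breakpoints == pytest.approx((0.2, 0.5))
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_k_zero_reduces_to_ols(self, rng):
        x = np.linspace(0.1, 0.6, 25)
        y = 1 + 2 * x + rng.normal(0, 0.1, 25)
        fit = fit_breakpoints(curve_from_values(x, y), k=0, forced_break=0.05)
        design = np.column_stack([np.ones_like(x), x])
        coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert fit.sse == pytest.approx(float(res[0]))

    def test_matches_bruteforce_oracle_on_30_bins(self, rng):
        x = np.linspace(0.05, 0.65, 30)
        y = piecewise(x, [0.3], [2.0, -3.0], 0.5) + rng.normal(0, 0.05, 30)
        c = curve_from_values(x, y)
        fit = fit_breakpoints(c, k=2, forced_break=0.04)
        combo, sse = fit_breakpoints_bruteforce(x, y, 2, x[1:-1])
        assert fit.breakpoints == pytest.approx(combo)
        assert fit.sse == pytest.approx(sse, abs=1e-9)

    def test_noisy_kink_recovery_within_one_step(self):
        hits = 0
        x = np.round(np.arange(0.05, 0.75, 0.01), 4)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = piecewise(x, [0.3], [1.0, 8.0], 1.0) + rng.normal(0, 0.1, x.size)
            fit = fit_breakpoints(curve_from_values(x, y), k=1,
                                  forced_break=0.04, max_candidates=1000)
            hits += abs(fit.breakpoints[0] - 0.3) <= 0.0101
        assert hits >= 9

    def test_k_too_large_rejected(self):
        c = curve_from_values(np.linspace(0.1, 0.2, 6), np.ones(6))
        with pytest.raises(ValueError):
            fit_breakpoints(c, k=10, forced_break=0.05)


class TestClasses:
    def test_published_breakpoints_make_five_classes(self):
        fit = (0.19, 0.34, 0.57)
        classes = build_classes(0.03, fit, max_hsi=0.78)
        assert classes.labels == DEFAULT_LABELS
        assert classes.boundaries == (0.03, 0.19, 0.34, 0.57, 0.78)

    def test_merges_drop_breakpoints(self):
        # five fitted breaks; the 0.27 and 0.69 breaks merged away
        classes = build_classes(0.03, (0.19, 0.27, 0.34, 0.57, 0.69),
                                max_hsi=0.78, merges=(0.27, 0.69))
        assert classes.boundaries == (0.03, 0.19, 0.34, 0.57, 0.78)
        assert classes.labels == DEFAULT_LABELS

    def test_merge_everything_leaves_two_classes(self):
        classes = build_classes(0.03, (0.2, 0.4), max_hsi=0.8, merges=(0.2, 0.4))
        assert classes.n_classes == 2

    def test_unknown_merge_rejected(self):
        with pytest.raises(ValueError, match="merge"):
            build_classes(0.03, (0.2,), max_hsi=0.8, merges=(0.5,))

    def test_label_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            HabitatClasses((0.1, 0.5), ("a", "b", "c"))

    @pytest.mark.parametrize("hsi, expected", [
        (0.10, 1),   # marginal
        (0.19, 2),   # boundary belongs to the upper (low) class
        (0.40, 3),   # medium
        (0.78, 4),   # top closed
        (0.001, 0),  # unsuitable
    ])
    def test_classification_conventions(self, hsi, expected):
        classes = build_classes(0.03, (0.19, 0.34, 0.57), max_hsi=0.78)
        assert classes.classify(np.array([hsi]))[0] == expected

    def test_monotone_in_hsi(self, rng):
        classes = build_classes(0.03, (0.19, 0.34, 0.57), max_hsi=0.78)
        x = np.sort(rng.uniform(0, 0.78, 500))
        codes = classes.classify(x)
        assert (np.diff(codes) >= 0).all()

    def test_negative_hsi_rejected(self):
        classes = build_classes(0.03, (0.19,), max_hsi=0.78,
                                labels=("a", "b", "c"))
        with pytest.raises(ValueError):
            classes.classify(np.array([-0.1]))

    def test_above_top_clamps_with_warning(self):
        classes = build_classes(0.03, (0.19, 0.34, 0.57), max_hsi=0.78)
        with pytest.warns(UserWarning, match="clamped"):
            assert classes.classify(np.array([0.95]))[0] == 4

    def test_classify_grid_and_json_roundtrip(self, tmp_path):
        classes = build_classes(0.03, (0.19, 0.34, 0.57), max_hsi=0.78)
        hsi = Raster(np.array([[0.01, 0.2], [0.5, 0.7]]), 0, 0, 5.0)
        out = classify_grid(hsi, classes)
        np.testing.assert_array_equal(out.values, [[0, 2], [3, 4]])
        classes.to_json(tmp_path / "c.json")
        back = HabitatClasses.from_json(tmp_path / "c.json")
        assert back.boundaries == classes.boundaries
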