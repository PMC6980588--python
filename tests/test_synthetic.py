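"""Synthetic-data generators: closed-form means, determinism, calibration."""

import numpy as np
import pytest
from scipy import stats

from otolife import (
    BombCurveConfig,
    DicProfileConfig,
    ReaderErrorModel,
    average_percent_error,
    bomb_curve_mean,
    catch_composition,
    dic_profile_mean,
    generate_dic_profile,
    generate_double_reads,
    generate_population_sample,
    generate_reference_series,
)
from otolife.growth import GridSpec, observed_cell_counts


class TestBombCurve:
    def test_prebomb_plateau_and_anchors_exact(self):
        cfg = BombCurveConfig(noise_sd=0.0)
        assert bomb_curve_mean(1950.0, cfg) == pytest.approx(cfg.prebomb_level, abs=1e-9)
        assert bomb_curve_mean(cfg.peak_year, cfg) == pytest.approx(cfg.peak_level, abs=1e-9)
        assert bomb_curve_mean(cfg.end_year, cfg) == pytest.approx(cfg.end_level, abs=1e-9)

    def test_monotone_rise_and_decline(self):
        cfg = BombCurveConfig(noise_sd=0.0)
        rise = bomb_curve_mean(np.linspace(cfg.rise_start_year, cfg.peak_year, 200), cfg)
        decline = bomb_curve_mean(np.linspace(cfg.peak_year, cfg.end_year, 200), cfg)
        assert np.all(np.diff(rise) >= -1e-9)
        assert np.all(np.diff(decline) <= 1e-9)

    def test_prebomb_value_consistent_with_measured_core(self):
        # a 1958 birth year sits on the pre-rise plateau near -55 permil,
        # consistent with the -60.72 +- 2.1 measured for that cohort
        cfg = BombCurveConfig(seed=3)
        series = generate_reference_series(cfg)
        idx = np.argmin(np.abs(series.year - 1958.0))
        mean_1958 = bomb_curve_mean(series.year[idx], cfg)
        assert mean_1958 == pytest.approx(-55.0, abs=1.0)
        assert abs(series.d14c[idx] - mean_1958) <= 3 * cfg.noise_sd

    def test_seed_determinism_and_validation(self):
        a = generate_reference_series(BombCurveConfig(seed=7))
        b = generate_reference_series(BombCurveConfig(seed=7))
        assert np.array_equal(a.d14c, b.d14c) and np.array_equal(a.year, b.year)
        c = generate_reference_series(BombCurveConfig(seed=8))
        assert not np.array_equal(a.d14c, c.d14c)
        with pytest.raises(ValueError):
            BombCurveConfig(rise_start_year=1980, peak_year=1974)
        with pytest.raises(ValueError):
            BombCurveConfig(noise_sd=-1)
        with pytest.raises(ValueError):
            BombCurveConfig(n_points=3)


class TestDicProfile:
    def test_mixed_layer_plateau_and_linear_decline(self):
        cfg = DicProfileConfig(noise_sd=0.0)
        assert dic_profile_mean(100.0, cfg) == pytest.approx(60.0)
        d200, d600 = dic_profile_mean(np.array([200.0, 600.0]), cfg)
        assert d600 - d200 == pytest.approx(cfg.slope * 400.0)  # -115.6
        assert d600 - d200 == pytest.approx(-115.6)

    def test_default_profile_recovers_slope_within_2se(self):
        from otolife import fit_depth_regression

        rep = fit_depth_regression(generate_dic_profile(DicProfileConfig(seed=4)))
        assert abs(rep.slope - (-0.289)) < 2 * rep.slope_se

    def test_determinism_and_validation(self):
        a = generate_dic_profile(DicProfileConfig(seed=1))
        b = generate_dic_profile(DicProfileConfig(seed=1))
        assert np.array_equal(a.d14c, b.d14c)
        with pytest.raises(ValueError):
            DicProfileConfig(mixed_layer_depth=1300.0)
        with pytest.raises(ValueError):
            DicProfileConfig(slope=np.inf)


class TestDoubleReads:
    def test_zero_error_reads_equal_truth(self):
        ages = np.array([3, 10, 41])
        reads = generate_double_reads(ages, ReaderErrorModel(sd_per_year=0.0, seed=0))
        assert np.array_equal(reads, np.column_stack([ages, ages]))
        assert average_percent_error(reads) == 0.0

    def test_pure_bias_shifts_second_reader_by_one(self):
        ages = np.arange(2, 30)
        reads = generate_double_reads(ages, ReaderErrorModel(sd_per_year=0.0, bias=1.0, seed=0))
        assert np.all(reads[:, 1] - reads[:, 0] == 1)

    def test_empty_input_and_floor(self):
        assert generate_double_reads([], ReaderErrorModel()).shape == (0, 2)
        reads = generate_double_reads(np.ones(200), ReaderErrorModel(sd_per_year=0.9, seed=1))
        assert reads.min() >= 1
        with pytest.raises(ValueError):
            generate_double_reads([0], ReaderErrorModel())

    def test_default_error_yields_ape_of_order_ten_percent(self, table1_params):
        fish = generate_population_sample(table1_params, 485, seed=5)
        reads = generate_double_reads(fish["age_years"].to_numpy(), ReaderErrorModel(seed=2))
        ape = average_percent_error(reads)
        assert 1.0 < ape < 30.0


class TestPopulationSample:
    def test_rejects_empty_and_is_deterministic(self, table1_params):
        with pytest.raises(ValueError):
            generate_population_sample(table1_params, 0, seed=1)
        a = generate_population_sample(table1_params, 200, seed=9)
        b = generate_population_sample(table1_params, 200, seed=9)
        assert a.equals(b)

    def test_age_distribution_right_skewed(self, table1_params):
        fish = generate_population_sample(table1_params, 5000, seed=2)
        ages = fish["age_years"].to_numpy()
        assert np.median(ages) < 15
        assert np.mean(ages < 10) > 0.4
        assert stats.skew(ages) > 0.5
        assert (fish["tl_mm"] > 0).all()

    def test_cell_frequencies_match_composition(self, table1_params):
        """Chi-square goodness of fit of sampled cells at n = 100,000."""
        n = 100_000
        spec = GridSpec()
        grid = catch_composition(table1_params, spec)
        fish = generate_population_sample(table1_params, n, seed=9, spec=spec)
        obs = fish[["age_years", "tl_mm"]].to_numpy(float)
        cells, counts = observed_cell_counts(obs, spec)
        full = np.zeros(spec.max_age * spec.n_bins)
        full[cells] = counts
        expected = grid.probs.ravel() * n
        big = expected >= 5
        o = np.concatenate([full[big], [full[~big].sum()]])
        e = np.concatenate([expected[big], [expected[~big].sum()]])
        chi2 = float(((o - e) ** 2 / e).sum())
        p = stats.chi2.sf(chi2, o.size - 1)
        assert p > 0.01

    def test_mean_length_at_age_matches_vbgf_without_fishing(self, table1_params):
        """With F ~ 0 and selectivity ~ 1, sampled mean length at age tracks
        the VBGF mean within 1% wherever counts are large."""
        from otolife import vbgf_mean_length

        p0 = table1_params.with_(f_mort=1e-12, l50=1e-9, sel_steepness=1e-3)
        fish = generate_population_sample(p0, 200_000, seed=3)
        obs = fish[["age_years", "tl_mm"]].to_numpy(float)
        mu = vbgf_mean_length(table1_params, np.arange(1, 66))
        for a in range(5, 21):
            sel = obs[obs[:, 0] == a, 1]
            assert sel.size > 1000
            assert abs(sel.mean() / mu[a - 1] - 1) < 0.01
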