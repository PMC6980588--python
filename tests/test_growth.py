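"""Growth model primitives: VBGF, selectivity, composition, mortality."""

import numpy as np
import pytest
from scipy import stats

from otolife import (
    GrowthParams,
    catch_composition,
    fit_vbgf_least_squares,
    hewitt_hoenig_m,
    log_likelihood,
    logistic_selectivity,
    mortality_summary,
    simulate_catch,
    vbgf_mean_length,
)
from otolife.growth import GridSpec, observed_cell_counts


class TestVbgf:
    def test_floor_at_root_and_asymptote(self, table1_params):
        assert vbgf_mean_length(table1_params, table1_params.t0) == 1.0
        assert vbgf_mean_length(table1_params, 500.0) == pytest.approx(
            table1_params.linf, rel=1e-12
        )

    def test_published_point_value(self, table1_params):
        # 1533 * (1 - e^(-0.14 * 8.18))
        assert vbgf_mean_length(table1_params, 10.0) == pytest.approx(1045.26, abs=0.01)

    def test_rejects_nonpositive_age(self, table1_params):
        with pytest.raises(ValueError):
            vbgf_mean_length(table1_params, 0.0)


class TestSelectivity:
    def test_half_selection_and_limits(self, table1_params):
        assert logistic_selectivity(table1_params, table1_params.l50) == 0.5
        assert logistic_selectivity(table1_params, 1e7) == pytest.approx(1.0)
        lengths = np.linspace(0, 2500, 400)
        v = logistic_selectivity(table1_params, lengths)
        assert np.all(np.diff(v) > 0)

    def test_published_point_value(self, table1_params):
        # one steepness unit above l50: 1/(1 + e^-1)
        assert logistic_selectivity(table1_params, 812 + 78.8) == pytest.approx(
            0.7311, abs=1e-4
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(1533, 0.14, 1.82, 0.17, 812, -1.0, 0.066, 0.34)
        with pytest.raises(ValueError):
            GrowthParams(1533, 0.14, 1.82, 1.5, 812, 78.8, 0.066, 0.34)  # cv >= 1


class TestCatchComposition:
    def test_normalisation_and_smoothing_floor(self, table1_params):
        grid = catch_composition(table1_params)
        assert grid.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert grid.probs.min() > 0

    def test_age_marginal_geometric_when_fully_selected(self, table1_params):
        """V = 1 collapses the model to exponential total-mortality decay."""
        z = 0.25
        p = table1_params.with_(m_nat=z / 2, f_mort=z / 2, l50=1e-9, sel_steepness=1e-3)
        grid = catch_composition(p)
        spec = grid.spec
        raw = np.exp(-z * np.arange(spec.max_age))  # geometric survivorship
        expected = (raw + spec.eps * spec.n_bins) / (raw.sum() + spec.eps * spec.max_age * spec.n_bins)
        np.testing.assert_allclose(grid.age_marginal, expected, rtol=1e-9)

    def test_mean_length_matches_vbgf_without_size_selection(self, table1_params):
        p = table1_params.with_(f_mort=1e-12, l50=1e-9, sel_steepness=1e-3)
        grid = catch_composition(p)
        mu = vbgf_mean_length(table1_params, grid.spec.ages)
        rel = grid.mean_length_at_age() / mu - 1
        assert np.max(np.abs(rel[4:])) < 0.005

    def test_size_selective_thinning_lowers_mean_length_at_old_ages(self, table1_params):
        fished = catch_composition(table1_params).mean_length_at_age()
        unfished = catch_composition(table1_params.with_(f_mort=1e-12)).mean_length_at_age()
        old = slice(20, 60)
        assert np.all(fished[old] <= unfished[old] + 1e-9)
        assert fished[40] < unfished[40] - 10  # materially lower, not just ties


class TestLogLikelihood:
    def test_single_observation_is_log_cell_probability(self, table1_params):
        grid = catch_composition(table1_params)
        obs = np.array([[10.0, 1025.0]])
        cell = grid.spec.bin_of(1025.0)
        expected = np.log(grid.probs[9, int(cell)])
        assert log_likelihood(table1_params, obs) == pytest.approx(float(expected))

    def test_permutation_invariance_and_count_oracle(self, table1_params):
        rng = np.random.default_rng(0)
        obs = simulate_catch(table1_params, 100, seed=3)
        ll = log_likelihood(table1_params, obs)
        ll_perm = log_likelihood(table1_params, obs[rng.permutation(100)])
        assert ll == pytest.approx(ll_perm, abs=1e-9)
        # brute-force per-observation sum
        grid = catch_composition(table1_params)
        brute = sum(
            np.log(grid.probs[int(a) - 1, int(grid.spec.bin_of(l))]) for a, l in obs
        )
        assert ll == pytest.approx(float(brute), abs=1e-8)

    def test_out_of_grid_observation_rejected(self, table1_params):
        with pytest.raises(ValueError):
            log_likelihood(table1_params, [[70.0, 500.0]])
        with pytest.raises(ValueError):
            log_likelihood(table1_params, [[5.0, 2600.0]])


class TestSimulateCatch:
    def test_seed_determinism(self, table1_params):
        a = simulate_catch(table1_params, 500, seed=5)
        b = simulate_catch(table1_params, 500, seed=5)
        assert np.array_equal(a, b)

    def test_old_age_spread_spans_hundreds_of_mm(self, table1_params):
        """Size-at-age for ages > 20 spans an envelope of roughly
        Linf +- a third, reflecting persistent growth variation."""
        obs = simulate_catch(table1_params, 200_000, seed=4)
        old = obs[obs[:, 0] > 20, 1]
        assert old.size > 500
        assert old.max() - old.min() > 800
        assert old.min() < table1_params.linf - 400
        assert old.max() > table1_params.linf + 250
        # size-selective thinning keeps the fished mean below Linf
        assert old.mean() < table1_params.linf


class TestMortality:
    @pytest.mark.parametrize(
        "t_max, expected", [(61, 0.069), (4.22, 1.0), (42.2, 0.1)]
    )
    def test_hewitt_hoenig_values(self, t_max, expected):
        assert hewitt_hoenig_m(t_max) == expected

    def test_hewitt_hoenig_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hewitt_hoenig_m(0)

    def test_summary_published_values(self):
        ms = mortality_summary(0.34, 0.066)
        assert ms.z == pytest.approx(0.406)
        assert ms.f_over_m_reported == 5.1

    def test_summary_edge_cases(self):
        assert mortality_summary(0.0, 0.1).f_over_m == 0.0
        assert mortality_summary(0.1, 0.1).f_over_m_reported == 1.0
        with pytest.raises(ZeroDivisionError):
            mortality_summary(0.1, 0.0)


class TestVbgfLeastSquares:
    def test_noiseless_recovery(self):
        ages = np.arange(1, 30, dtype=float)
        lengths = 1500 * (1 - np.exp(-0.12 * (ages + 0.5)))
        fit = fit_vbgf_least_squares(np.column_stack([ages, lengths]))
        assert fit.converged
        assert fit.linf == pytest.approx(1500, abs=1e-4)
        assert fit.k == pytest.approx(0.12, abs=1e-7)
        assert fit.t0 == pytest.approx(-0.5, abs=1e-5)

    def test_too_few_distinct_ages(self):
        with pytest.raises(ValueError):
            fit_vbgf_least_squares([[5.0, 800.0], [5.0, 850.0], [5.0, 900.0]])

    def test_gear_selected_catch_biases_t0_downward(self, table1_params):
        """Naive least squares on gear-selected catch data is biologically
        misleading: t0 is pulled well below truth and Linf/k are displaced."""
        obs = simulate_catch(table1_params, 1338, seed=11)
        fit = fit_vbgf_least_squares(obs)
        assert fit.converged
        assert fit.t0 < table1_params.t0 - 0.3
        displaced = (
            abs(fit.linf / table1_params.linf - 1) > 0.10
            or abs(fit.k / table1_params.k - 1) > 0.25
        )
        assert displaced


def test_grid_spec_validation():
    with pytest.raises(ValueError):
        GridSpec(max_age=0)
    with pytest.raises(ValueError):
        GridSpec(bin_width=-5)
    spec = GridSpec()
    assert spec.n_bins == 50
    cells, counts = observed_cell_counts([[1.0, 25.0], [1.0, 25.0]], spec)
    assert cells.tolist() == [0] and counts.tolist() == [2.0]
    with pytest.raises(ValueError):
        observed_cell_counts([[1.5, 25.0]], spec)  # non-integer age
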