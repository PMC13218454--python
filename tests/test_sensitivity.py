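"""DSA tornado, PSA distributions and reproducibility, CEAC, threshold grid."""

import numpy as np
import pytest
from scipy import stats

from acescreen import sensitivity as sn
from acescreen.parameters import load_default_parameters


class TestDistributionParameterization:
    @pytest.mark.parametrize(
        "p, n, alpha, beta",
        [(0.75, 100, 75, 25), (0.5, 2, 1, 1), (0.9, 100, 90, 10)],
    )
    def test_beta_from_pn(self, p, n, alpha, beta):
        spec = sn.beta_from_pn(p, n)
        assert (spec.alpha, spec.beta) == pytest.approx((alpha, beta))
        assert spec.mean == pytest.approx(p)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_p_rejected(self, p):
        with pytest.raises(ValueError, match="point mass"):
            sn.beta_from_pn(p, 100)

    @pytest.mark.parametrize(
        "mu, sigma, shape, scale",
        [(1900, 380, 25, 76), (100, 10, 100, 1)],
    )
    def test_gamma_from_mu_sigma(self, mu, sigma, shape, scale):
        spec = sn.gamma_from_mu_sigma(mu, sigma)
        assert (spec.shape, spec.scale) == pytest.approx((shape, scale))
        assert spec.mean == pytest.approx(mu)
        assert spec.variance == pytest.approx(sigma**2)

    @pytest.mark.parametrize(
        "spec, dist",
        [
            (sn.beta_from_pn(0.75, 100), stats.beta(75, 25)),
            (sn.gamma_from_mu_sigma(1900, 380), stats.gamma(25, scale=76)),
        ],
    )
    def test_moment_recovery_at_10k_draws(self, spec, dist):
        """Empirical mean and variance match analytic moments within
        three standard errors of the respective estimator."""
        n = 10_000
        x = spec.sample(np.random.default_rng(12345), n)
        mean, var, _, kurt = dist.stats(moments="mvsk")
        se_mean = np.sqrt(var / n)
        assert abs(x.mean() - mean) < 3 * se_mean
        se_var = np.sqrt((kurt + 2.0) * var**2 / n)
        assert abs(x.var(ddof=1) - var) < 3 * se_var


@pytest.fixture(scope="module")
def dsa():
    return sn.one_way_dsa(load_default_parameters())


class TestOneWayDsa:
    def test_entries_sorted_by_descending_swing(self, dsa):
        _, entries = dsa
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)

    def test_unread_parameter_has_zero_swing(self, dsa):
        _, entries = dsa
        by_name = {e.parameter: e for e in entries}
        # the MRI is charged identically in both arms, so its price cannot
        # move the incremental result
        assert by_name["mri_cost"].swing == pytest.approx(0.0, abs=1e-6)
        # full-health idiopathic utility has zero disutility to vary
        assert by_name["utility_idiopathic"].swing == pytest.approx(0.0, abs=1e-6)

    def test_cost_parameters_are_linear_and_symmetric(self, dsa):
        base_nmb, entries = dsa
        e = {x.parameter: x for x in entries}["achr_test_cost"]
        # cost enters the NMB linearly: symmetric bars around the base case
        assert e.nmb_high - base_nmb == pytest.approx(-(e.nmb_low - base_nmb), rel=1e-9)
        # and the swing doubles when the variation doubles
        params = load_default_parameters()
        import dataclasses

        wide = params.replace(
            settings=dataclasses.replace(params.settings, dsa_variation=0.4)
        )
        _, entries_wide = sn.one_way_dsa(wide, vary=["achr_test_cost"])
        assert entries_wide[0].swing == pytest.approx(2 * e.swing, rel=1e-9)

    def test_swing_matches_direct_reevaluation(self):
        from acescreen import economics as ec

        params = load_default_parameters()
        _, entries = sn.one_way_dsa(params, vary=["mg_prevalence"])
        e = entries[0]

        def nmb_at(prev):
            p = sn._set_prev(params, "mg", prev)
            non = ec.evaluate_strategy(p, "none")
            uni = ec.evaluate_strategy(p, "universal")
            return ec.net_monetary_benefit(
                uni.cost - non.cost, uni.qalys - non.qalys, params.settings.wtp_lower
            )

        assert e.nmb_low == pytest.approx(nmb_at(e.low_value))
        assert e.nmb_high == pytest.approx(nmb_at(e.high_value))

    def test_accuracy_ranges_stay_inside_unit_interval(self, dsa):
        _, entries = dsa
        for e in entries:
            if e.parameter.startswith(("achr_", "tft_")) and "cost" not in e.parameter:
                assert 0.0 <= e.low_value <= e.high_value <= 1.0

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            sn.one_way_dsa(load_default_parameters(), vary=["warp_drive_cost"])


def synthetic_psa(delta_cost, delta_qaly):
    delta_cost = np.asarray(delta_cost, dtype=float)
    return sn.PSAResult(
        delta_cost=delta_cost,
        delta_qaly=np.asarray(delta_qaly, dtype=float),
        draws=len(delta_cost),
        seed=0,
        accounting_mode="accumulated",
        parameter_names=(),
        samples={},
    )


class TestCeac:
    def test_at_zero_wtp_counts_cost_saving_draws(self):
        psa = synthetic_psa([-1, 1, 2, -3], [1, 1, 1, 1])
        assert sn.ceac(psa, [0.0])[0] == 0.5

    def test_limit_counts_qaly_gaining_draws(self):
        psa = synthetic_psa([5, 5, 5, 5], [1, 1, -1, 1])
        assert sn.ceac(psa, [1e12])[0] == 0.75

    def test_monotone_in_wtp_when_all_gains_positive(self):
        rng = np.random.default_rng(7)
        psa = synthetic_psa(rng.normal(3e5, 1e5, 500), rng.uniform(0.1, 2.0, 500))
        curve = sn.ceac(psa, np.linspace(0, 5e5, 51))
        assert (np.diff(curve) >= 0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sn.ceac(synthetic_psa([1.0], [1.0]), [])


class TestPsa:
    def test_reproducible_for_identical_seed(self):
        params = load_default_parameters()
        a = sn.run_psa(params, draws=40, seed=11)
        b = sn.run_psa(params, draws=40, seed=11)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)
        c = sn.run_psa(params, draws=40, seed=12)
        assert not np.array_equal(a.delta_cost, c.delta_cost)

    def test_degenerate_psa_reproduces_base_case(self):
        from acescreen import economics as ec

        params = load_default_parameters()
        psa = sn.run_psa(params, draws=5, seed=0, registry=[])
        non = ec.evaluate_strategy(params, "none")
        uni = ec.evaluate_strategy(params, "universal")
        assert np.allclose(psa.delta_cost, uni.cost - non.cost)
        assert np.allclose(psa.delta_qaly, uni.qalys - non.qalys)

    def test_sampled_parameter_means_recover_base_values(self):
        params = load_default_parameters()
        psa = sn.run_psa(params, draws=10_000, seed=3)
        registry = {p.name: p for p in sn.default_registry()}
        for name in ("achr_sensitivity", "mg_prevalence", "utility_delayed_omg"):
            dist = registry[name].psa_dist(params)
            se = np.sqrt(dist.variance / psa.draws)
            assert abs(psa.samples[name].mean() - dist.mean) < 3 * se

    def test_draw_count_validation(self):
        with pytest.raises(ValueError):
            sn.run_psa(load_default_parameters(), draws=0)


@pytest.fixture(scope="module")
def coarse_grid():
    return sn.two_way_threshold(
        load_default_parameters(),
        price_grid=np.arange(0, 3001, 500),
        prevalence_grid=np.arange(0.005, 0.101, 0.01),
    )


class TestTwoWayThreshold:
    def test_icer_nonincreasing_in_prevalence_at_fixed_price(self, coarse_grid):
        icer = coarse_grid.icer
        finite = np.isfinite(icer)
        for c in range(icer.shape[1]):
            col = icer[finite[:, c], c]
            assert (np.diff(col) <= 1e-6).all()

    def test_icer_nondecreasing_in_price_at_fixed_prevalence(self, coarse_grid):
        icer = coarse_grid.icer
        for r in range(icer.shape[0]):
            row = icer[r, np.isfinite(icer[r])]
            assert (np.diff(row) >= -1e-6).all()

    def test_base_case_cell_is_not_cost_effective(self, coarse_grid):
        r = int(np.argmin(np.abs(coarse_grid.prevalence_grid - 0.027)))
        c = int(np.argmin(np.abs(coarse_grid.price_grid - 1900)))
        assert not coarse_grid.cost_effective[r, c]

    def test_threshold_lookups_are_consistent(self, coarse_grid):
        thr = coarse_grid.prevalence_threshold(1900)
        if thr is not None:
            assert thr > 0.027  # base prevalence must sit below the boundary

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            sn.two_way_threshold(
                load_default_parameters(), price_grid=[100, 50], prevalence_grid=[0.01, 0.02]
            )
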