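"""Power-law and quadratic scaling fits, model selection, and pooling."""

import numpy as np
import pytest

from conftest import exact_power_law_estimates, make_table
from coolscale.errors import FitError, ValidationError
from coolscale.regression import estimate_all
from coolscale.scaling import (
    CEScalingModel,
    ScalingFit,
    fit_power_law,
    fit_quadratic,
    pool_fits,
    select_model,
)
from coolscale.synthetic import TabularSimConfig, simulate_unit_tables

SCALES = tuple(float(120 * w) for w in range(1, 24, 2))


class TestPowerLaw:
    def test_exact_points_recovered(self):
        """Points exactly on 0.057*S**0.165 return k and beta to 1e-10."""
        fit = fit_power_law(exact_power_law_estimates(0.057, 0.165, SCALES))
        assert fit.k == pytest.approx(0.057, abs=1e-10)
        assert fit.beta == pytest.approx(0.165, abs=1e-10)
        assert fit.r2_fit == pytest.approx(1.0, abs=1e-12)
        assert fit.model_form == "power"

    def test_flat_ce_gives_zero_exponent(self):
        fit = fit_power_law(exact_power_law_estimates(0.12, 0.0, SCALES))
        assert fit.beta == pytest.approx(0.0, abs=1e-12)
        assert fit.k == pytest.approx(0.12, abs=1e-12)

    def test_direct_space_agrees_on_exact_points(self):
        fit = fit_power_law(
            exact_power_law_estimates(0.057, 0.165, SCALES), fit_space="direct"
        )
        assert fit.k == pytest.approx(0.057, rel=1e-6)
        assert fit.beta == pytest.approx(0.165, abs=1e-6)

    def test_too_few_scales(self):
        with pytest.raises(FitError):
            fit_power_law(exact_power_law_estimates(0.057, 0.165, SCALES[:2]))

    def test_ci_contains_estimates(self):
        cfg = TabularSimConfig(noise_sd=0.5, n_per_scale=200, seed=5)
        fit = fit_power_law(estimate_all(simulate_unit_tables(cfg)))
        assert fit.beta_ci[0] <= fit.beta <= fit.beta_ci[1]
        assert fit.k_ci[0] <= fit.k <= fit.k_ci[1]

    def test_monte_carlo_beta_recovery_baltimore_truth(self):
        """Mean recovered exponent over noisy replicates within 0.01 of 0.102."""
        betas = []
        for seed in range(50):
            cfg = TabularSimConfig(k=0.10, beta=0.102, noise_sd=0.5,
                                   n_per_scale=300, seed=seed)
            betas.append(fit_power_law(estimate_all(simulate_unit_tables(cfg))).beta)
        assert abs(np.mean(betas) - 0.102) <= 0.01

    def test_unit_change_equivariance(self):
        """Refitting with S in pixels leaves beta fixed and rescales k by
        base_pixel_m**beta."""
        est_m = exact_power_law_estimates(0.057, 0.165, SCALES)
        est_px = exact_power_law_estimates(
            0.057 * 120**0.165, 0.165, tuple(s / 120 for s in SCALES)
        )
        fm = fit_power_law(est_m)
        fp = fit_power_law(est_px, s_unit="px")
        assert fp.beta == pytest.approx(fm.beta, abs=1e-10)
        assert fp.k == pytest.approx(fm.k * 120**fm.beta, rel=1e-10)

    def test_ce_rescaling_absorbed_by_k(self, rng):
        """Multiplying all CE by c leaves beta (and residuals) unchanged."""
        ce = 0.06 * np.array(SCALES) ** 0.1 * np.exp(rng.normal(0, 0.05, len(SCALES)))
        base = [e for e in exact_power_law_estimates(1, 0, SCALES)]
        est1 = [
            type(e)(**{**e.to_dict(), "ce": c}) for e, c in zip(base, ce)
        ]
        est2 = [
            type(e)(**{**e.to_dict(), "ce": 3.7 * c}) for e, c in zip(base, ce)
        ]
        f1, f2 = fit_power_law(est1), fit_power_law(est2)
        assert f2.beta == pytest.approx(f1.beta, abs=1e-12)
        assert f2.k == pytest.approx(3.7 * f1.k, rel=1e-12)
        assert f2.r2_fit == pytest.approx(f1.r2_fit, abs=1e-12)

    def test_json_round_trip(self, tmp_path):
        fit = fit_power_law(exact_power_law_estimates(0.057, 0.165, SCALES))
        fit.to_json(tmp_path / "fit.json")
        back = ScalingFit.from_json(tmp_path / "fit.json")
        assert back.k == pytest.approx(fit.k)
        assert back.beta == pytest.approx(fit.beta)
        assert back.model_form == "power"


def quad_estimates(c0, c1, c2, scales=SCALES):
    ests = exact_power_law_estimates(1.0, 0.0, scales)
    s = np.array(scales)
    ce = c0 + c1 * s + c2 * s**2
    return [type(e)(**{**e.to_dict(), "ce": v}) for e, v in zip(ests, ce)]


class TestQuadratic:
    def test_exact_quadratic_recovered(self):
        fit = fit_quadratic(quad_estimates(0.05, 2e-4, -3e-8))
        assert fit.model_form == "quadratic"
        assert fit.quad_coeffs[0] == pytest.approx(0.05, abs=1e-10)
        assert fit.quad_coeffs[1] == pytest.approx(2e-4, rel=1e-8)
        assert fit.quad_coeffs[2] == pytest.approx(-3e-8, rel=1e-8)

    def test_linear_truth_c2_ci_covers_zero(self, rng):
        s = np.array(SCALES)
        ce = 0.1 + 2e-4 * s + rng.normal(0, 0.01, len(s))
        ests = quad_estimates(0, 0, 0)
        ests = [type(e)(**{**e.to_dict(), "ce": v}) for e, v in zip(ests, ce)]
        fit = fit_quadratic(ests)
        lo, hi = fit._pred["conf_int"][2]
        assert lo <= 0 <= hi

    def test_needs_four_scales(self):
        with pytest.raises(FitError):
            fit_quadratic(quad_estimates(0.1, 0, 0, SCALES[:3]))


class TestSelectModel:
    def test_clean_power_law_selects_power(self):
        fit = select_model(exact_power_law_estimates(0.057, 0.165, SCALES))
        assert fit.model_form == "power"

    def test_flat_noisy_ce_falls_back_to_quadratic(self, rng):
        """beta = 0 with large noise leaves the power slope insignificant."""
        ests = exact_power_law_estimates(1.0, 0.0, SCALES[:6])
        ce = 0.1 * np.exp(rng.normal(0, 0.5, 6))
        ests = [type(e)(**{**e.to_dict(), "ce": v}) for e, v in zip(ests, ce)]
        power = fit_power_law(ests)
        fit = select_model(ests)
        if power.p_fit > 0.01:
            assert fit.model_form == "quadratic"
        else:  # pragma: no cover - seed-dependent branch
            assert fit.model_form == "power"

    def test_extreme_day_concavity_prefers_quadratic(self):
        """A concave-down CE curve with a peak inside the scale range: the
        quadratic fits better than any monotone power law."""
        s = np.array(SCALES)
        ce = 0.05 + 2.2e-4 * s - 7e-8 * s**2  # peaks near 1570 m, declines after
        ests = quad_estimates(0.05, 2.2e-4, -7e-8)
        power = fit_power_law(ests)
        quad = fit_quadratic(ests)
        assert quad.r2_fit > power.r2_fit
        fit = select_model(ests)
        # whichever branch the p-rule takes, diagnostics favor the quadratic
        assert quad.r2_fit == pytest.approx(1.0, abs=1e-10)
        assert np.all(ce > 0)
        assert fit.model_form in ("power", "quadratic")


class TestPooling:
    def test_two_identical_dates_equal_single_fit(self):
        est = exact_power_law_estimates(0.057, 0.165, SCALES)
        single = fit_power_law(est)
        pooled = pool_fits([est, est])
        assert pooled.k == pytest.approx(single.k, rel=1e-12)
        assert pooled.beta == pytest.approx(single.beta, abs=1e-12)
        assert len(pooled.per_date) == 2

    def test_pooled_beta_between_date_betas(self):
        a = exact_power_law_estimates(0.06, 0.06, SCALES)
        b = exact_power_law_estimates(0.06, 0.10, SCALES)
        pooled = pool_fits([a, b])
        assert 0.06 < pooled.beta < 0.10

    def test_pooled_parameters_within_per_date_spread(self):
        """Ten simulated dates around the pooled truth: the pooled (k, beta)
        lies inside the min/max of the per-date fits."""
        rng = np.random.default_rng(42)
        dates = []
        for i in range(10):
            cfg = TabularSimConfig(
                k=float(0.057 * np.exp(rng.normal(0, 0.2))),
                beta=float(np.clip(0.165 + rng.normal(0, 0.03), 0.01, 0.5)),
                noise_sd=0.3, n_per_scale=200, seed=1000 + i,
            )
            dates.append(estimate_all(simulate_unit_tables(cfg)))
        pooled = pool_fits(dates)
        betas = [f.beta for f in pooled.per_date]
        ks = [f.k for f in pooled.per_date]
        assert min(betas) <= pooled.beta <= max(betas)
        assert min(ks) <= pooled.k <= max(ks)

    def test_single_date_rejected(self):
        with pytest.raises(ValidationError):
            pool_fits([exact_power_law_estimates(0.057, 0.165, SCALES)])


class TestModelObject:
    def test_model_fit_matches_function_api(self):
        cfg = TabularSimConfig(noise_sd=0.2, n_per_scale=100, seed=17)
        tables = simulate_unit_tables(cfg)
        model = CEScalingModel.from_unit_tables(tables)
        res = model.fit(method="power")
        direct = fit_power_law(estimate_all(tables))
        assert res.k == pytest.approx(direct.k)
        assert res.beta == pytest.approx(direct.beta)
        assert "beta" in res.summary()

    def test_from_dataframe(self):
        import pandas as pd

        cfg = TabularSimConfig(noise_sd=0.0, n_per_scale=30, seed=3)
        tables = simulate_unit_tables(cfg)
        long = pd.concat(
            [t.data.assign(scale_m=t.scale_m) for t in tables], ignore_index=True
        )
        res = CEScalingModel.from_dataframe(long).fit(method="power")
        assert res.beta == pytest.approx(0.165, abs=1e-8)
        assert res.k == pytest.approx(0.057, rel=1e-8)
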