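"""Densities, growth rates, realized surfaces, regional/local trends."""

import numpy as np
import pandas as pd
import pytest

import scrtrend as st
from scrtrend.derived import (DensitySurface, TrendEstimate, growth_rate,
                              local_growth, pooled_growth, regional_growth,
                              trend_with_se)
from scrtrend.likelihood import FitResult, ModelSpec, build_designs
from conftest import make_detectors, make_encounters


# ---------------------------------------------------------------------------
# Densities and growth rates (closed-form cases)
# ---------------------------------------------------------------------------

class TestGrowthRate:
    def test_eight_interval_examples(self):
        assert growth_rate(7.77, 11.45, 8) == pytest.approx(1.050, abs=5e-4)
        assert growth_rate(5.78, 7.51, 8) == pytest.approx(1.033, abs=5e-4)

    def test_identity_when_density_constant(self):
        for x, k in [(3.0, 1), (11.0, 8), (0.4, 3)]:
            assert growth_rate(x, x, k) == pytest.approx(1.0)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            growth_rate(0.0, 5.0, 8)

    def test_pooled_sums_sexes_before_ratio(self):
        lam = pooled_growth({2004: 7.77, 2012: 11.45},
                            {2004: 5.78, 2012: 7.51}, 2004, 2012, 8)
        assert lam == pytest.approx(1.043, abs=5e-4)

    def test_pooled_lies_between_sex_specific_rates(self):
        f = {2004: 7.77, 2012: 11.45}
        m = {2004: 5.78, 2012: 7.51}
        lam_f = growth_rate(f[2004], f[2012], 8)
        lam_m = growth_rate(m[2004], m[2012], 8)
        lam = pooled_growth(f, m, 2004, 2012, 8)
        assert min(lam_f, lam_m) < lam < max(lam_f, lam_m)

    def test_missing_sex_rejected(self):
        with pytest.raises(ValueError, match="male"):
            pooled_growth({2004: 1, 2012: 2}, {2004: 1}, 2004, 2012, 8)


class TestWaldIntervals:
    def test_upper_bound_worked_example(self):
        est = TrendEstimate.from_lambda_se(1.050, 0.020, 8)
        assert est.ucl == pytest.approx(1.089, abs=5e-4)
        assert est.lcl == pytest.approx(1.011, abs=5e-4)

    def test_zero_se_collapses_to_point(self):
        est = TrendEstimate.from_lambda_se(1.05, 0.0, 8)
        assert est.lcl == est.ucl == est.lam

    def test_lognormal_density_interval(self):
        """log D = 2.05, SE 0.10 -> D 7.77 with CI [6.39, 9.45]."""
        fit = _manual_linear_fit(b0=2.05, se_b0=0.10)
        row = st.density_estimates(fit).iloc[0]
        assert row["D"] == pytest.approx(7.77, abs=0.01)
        assert row["lcl"] == pytest.approx(6.39, abs=0.01)
        assert row["ucl"] == pytest.approx(9.45, abs=0.01)

    def test_zero_se_density_interval_degenerates(self):
        fit = _manual_linear_fit(b0=0.0, se_b0=0.0)
        row = st.density_estimates(fit).iloc[0]
        assert row["D"] == row["lcl"] == row["ucl"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Manual fits over a tiny dataset (no optimization)
# ---------------------------------------------------------------------------

def _tiny_prepared(spec=None, years=(2020,)):
    det = make_detectors([("A", t, 0.0, 0.0, [100, 130]) for t in years]
                         + [("B", t, 4.0, 0.0, [100, 130]) for t in years])
    enc = make_encounters([("f1", "F", years[0], "A", 1)])
    ss = st.build_state_space(det, 6, 4)
    return det, enc, ss, build_designs(enc, det, ss, spec or ModelSpec())


def _manual_linear_fit(b0, se_b0, b1=0.0, se_b1=0.0, years=(2020,)):
    _, _, _, prep = _tiny_prepared(years=years)
    theta = np.array([b0, b1, -2.0, 1.0])
    cov = np.diag([se_b0 ** 2, se_b1 ** 2, 0.1 ** 2, 0.1 ** 2])
    return FitResult(spec=prep.spec, theta=theta,
                     param_names=prep.param_names(), cov=cov, loglik=0.0,
                     K=4, n_individuals=1, aicc=0.0, converged=True,
                     grad_norm=0.0, message="manual", prepared=prep)


class TestTrendWithSE:
    def test_linear_model_closed_form(self):
        fit = _manual_linear_fit(b0=2.0, se_b0=0.1, b1=np.log(1.05),
                                 se_b1=0.02, years=(2004, 2012))
        est = trend_with_se(fit, 2004, 2012, 8)
        assert est.lam == pytest.approx(1.05, rel=1e-12)
        assert est.se == pytest.approx(1.05 * 0.02, rel=1e-12)
        assert est.n_intervals == 8

    def test_year_specific_uses_covariance(self):
        det = make_detectors([("A", t, 0.0, 0.0, [100, 130])
                              for t in (2004, 2012)])
        enc = make_encounters([("f1", "F", 2004, "A", 1)])
        ss = st.build_state_space(det, 6, 4)
        prep = build_designs(enc, det, ss, ModelSpec(density="year"))
        v04, v12, c = 0.04, 0.09, 0.01
        cov = np.zeros((4, 4))
        cov[0, 0], cov[1, 1], cov[0, 1], cov[1, 0] = v04, v12, c, c
        fit = FitResult(spec=prep.spec, theta=np.array([2.0, 2.4, -2.0, 1.0]),
                        param_names=prep.param_names(), cov=cov, loglik=0.0,
                        K=4, n_individuals=1, aicc=0.0, converged=True,
                        grad_norm=0.0, message="manual", prepared=prep)
        est = trend_with_se(fit, 2004, 2012, 8)
        lam = np.exp((2.4 - 2.0) / 8)
        var_loglam = (v04 + v12 - 2 * c) / 64
        assert est.lam == pytest.approx(lam)
        assert est.se == pytest.approx(lam * np.sqrt(var_loglam))

    def test_delta_se_matches_parametric_bootstrap(self, desk_fit):
        """SD of lambda over draws from the fitted covariance ~ delta SE."""
        est = trend_with_se(desk_fit, 2004, 2012, 8)
        rng = np.random.default_rng(31)
        draws = rng.multivariate_normal(desk_fit.theta, desk_fit.cov, size=500)
        i = desk_fit.param_names.index("D.b1")
        lams = np.exp(draws[:, i])
        assert np.std(lams) == pytest.approx(est.se, rel=0.02)

    def test_session_outside_fit_rejected(self, desk_fit):
        with pytest.raises(ValueError, match="session"):
            trend_with_se(desk_fit, 1999, 2012, 8)


# ---------------------------------------------------------------------------
# Realized surfaces
# ---------------------------------------------------------------------------

class TestRealizedSurface:
    def test_two_pixel_hand_enumeration(self):
        """Posterior and surface match direct arithmetic to 1e-12."""
        det = make_detectors([("A", 2020, 0.0, 0.0, [100, 130])])
        enc = make_encounters([("f1", "F", 2020, "A", 1)])
        ss = st.StateSpace(points=np.array([[0.0, 0.0], [4.0, 0.0]]),
                           spacing=4.0)
        prep = build_designs(enc, det, ss, ModelSpec())
        b0, p0l, lsig = 2.0, -1.2, np.log(3.0)
        theta = np.array([b0, 0.0, p0l, lsig])
        fit = FitResult(spec=prep.spec, theta=theta,
                        param_names=prep.param_names(), cov=np.eye(4),
                        loglik=0.0, K=4, n_individuals=1, aicc=0.0,
                        converged=True, grad_norm=0.0, message="manual",
                        prepared=prep)
        surf = st.realized_surface(fit, 2020)

        p0 = 1 / (1 + np.exp(-p0l))
        p_u = np.array([p0, p0 * np.exp(-16 / (2 * 9.0))])  # per pixel
        mu = np.exp(b0) * 16.0 / 1000.0
        lik = p_u                       # one detection, one occasion
        post = lik / lik.sum()
        undet = mu * (1 - p_u)
        np.testing.assert_allclose(surf.detected, post, atol=1e-12)
        np.testing.assert_allclose(surf.undetected, undet, atol=1e-12)
        assert surf.total() == pytest.approx(1 + undet.sum(), abs=1e-12)

    def test_no_detections_gives_pure_intensity(self):
        det = make_detectors([("A", 2020, 0.0, 0.0, [100, 130]),
                              ("A", 2021, 0.0, 0.0, [100, 130])])
        enc = make_encounters([("f1", "F", 2021, "A", 1)])
        ss = st.build_state_space(det, 6, 4)
        prep = build_designs(enc, det, ss, ModelSpec(density="year"))
        theta = np.array([1.0, 1.5, -40.0, 1.0])   # p0 ~ 0
        fit = FitResult(spec=prep.spec, theta=theta,
                        param_names=prep.param_names(), cov=np.eye(4),
                        loglik=0.0, K=4, n_individuals=1, aicc=0.0,
                        converged=True, grad_norm=0.0, message="manual",
                        prepared=prep)
        surf = fit and st.realized_surface(fit, 2020)
        mu = np.exp(1.0) * 16.0 / 1000.0
        np.testing.assert_allclose(surf.dhat, mu, rtol=1e-10)

    def test_symmetric_posterior_around_single_detector(self, desk_fit):
        surf = st.realized_surface(desk_fit, 2004)
        assert (surf.dhat >= 0).all()
        # mode of the detected mass sits where animals were caught
        assert surf.detected.max() > surf.detected.mean()

    def test_mass_conservation(self, desk_fit):
        for t in desk_fit.prepared.sessions:
            surf = st.realized_surface(desk_fit, t)
            ids, post = st.activity_center_posterior(desk_fit, t)
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
            assert surf.total() == pytest.approx(
                surf.n_detected + surf.undetected.sum(), abs=1e-8)


# ---------------------------------------------------------------------------
# Local and regional growth
# ---------------------------------------------------------------------------

def _flat_surface(session, values, pts=None):
    pts = pts if pts is not None else np.array([[0.0, 0.0], [0.0, 4.0],
                                                [0.0, 8.0], [0.0, -4.0]])
    vals = np.full(len(pts), float(values)) if np.isscalar(values) else values
    return DensitySurface(session=session, points=pts, detected=vals * 0,
                          undetected=np.asarray(vals, float), pixel_area=16.0,
                          n_detected=0)


class TestLocalGrowth:
    def test_identical_surfaces_give_unity(self):
        out = local_growth(_flat_surface(2004, 0.5), _flat_surface(2012, 0.5), 8)
        assert np.allclose(out["lam"], 1.0)
        assert out["valid"].all()

    def test_doubling_gives_eighth_root_of_two(self):
        out = local_growth(_flat_surface(2004, 0.5), _flat_surface(2012, 1.0), 8)
        assert np.allclose(out["lam"], 2 ** 0.125)

    def test_pixels_missing_in_either_year_are_flagged_not_zero(self):
        s04 = _flat_surface(2004, 0.5)
        s12 = _flat_surface(2012, 1.0, pts=s04.points[:2])
        out = local_growth(s04, s12, 8)
        assert out["valid"].sum() == 2
        assert out.loc[~out["valid"], "lam"].isna().all()

    def test_weighted_mean_of_local_rates_matches_whole_area_rate(self):
        rng = np.random.default_rng(5)
        start = _flat_surface(2004, rng.uniform(0.2, 1.0, size=4))
        end = _flat_surface(2012, rng.uniform(0.2, 1.0, size=4))
        out = local_growth(start, end, 8)
        whole = growth_rate(start.dhat.sum(), end.dhat.sum(), 8)
        # start-density-weighted mean of lam(u)^8 recovers the total ratio
        ratio = (start.dhat * out["lam"] ** 8).sum() / start.dhat.sum()
        assert ratio ** (1 / 8) == pytest.approx(whole, rel=1e-12)


class TestRegionalGrowth:
    def _regioned_space(self):
        pts = np.array([[0.0, 4.0], [0.0, 8.0], [0.0, -4.0], [0.0, -8.0]])
        ss = st.StateSpace(points=pts, spacing=4.0)
        return st.assign_regions(ss, 0.0), pts

    def test_single_region_matches_whole_space_rate(self):
        pts = np.array([[0.0, 4.0], [0.0, 8.0]])
        ss = st.assign_regions(st.StateSpace(points=pts, spacing=4.0), -100.0)
        surfaces = {2004: _flat_surface(2004, 0.5, pts),
                    2012: _flat_surface(2012, 0.8, pts)}
        out = regional_growth(surfaces, ss, 2004, 2012, 8)
        assert len(out) == 1
        assert out["lam"].iloc[0] == pytest.approx(growth_rate(1.0, 1.6, 8))

    def test_two_equal_halves_of_uniform_surface_agree(self):
        ss, pts = self._regioned_space()
        surfaces = {2004: _flat_surface(2004, 0.5, pts),
                    2012: _flat_surface(2012, 0.7, pts)}
        out = regional_growth(surfaces, ss, 2004, 2012, 8)
        assert out["lam"].nunique() == 1

    def test_south_weighted_growth_detected(self):
        ss, pts = self._regioned_space()
        start = _flat_surface(2004, np.array([1.0, 1.0, 1.0, 1.0]), pts)
        end = _flat_surface(2012, np.array([1.1, 1.1, 1.8, 1.8]), pts)
        out = regional_growth({2004: start, 2012: end}, ss, 2004, 2012, 8
                              ).set_index("region")
        assert out.loc["south", "lam"] > out.loc["north", "lam"]

    def test_empty_region_rejected(self):
        pts = np.array([[0.0, 4.0], [0.0, 8.0]])
        ss = st.assign_regions(st.StateSpace(points=pts, spacing=4.0), 0.0)
        # both pixels are north; make a surface lacking southern pixels
        surfaces = {2004: _flat_surface(2004, 0.5, pts),
                    2012: _flat_surface(2012, 0.8, pts)}
        ss.region[0] = "south"
        ss2 = st.StateSpace(points=pts, spacing=4.0,
                            region=np.array(["north", "south"], dtype=object))
        surfaces_missing = {2004: _flat_surface(2004, 0.5, pts[:1]),
                            2012: _flat_surface(2012, 0.8, pts[:1])}
        with pytest.raises(ValueError, match="empty"):
            regional_growth(surfaces_missing, ss2, 2004, 2012, 8)
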