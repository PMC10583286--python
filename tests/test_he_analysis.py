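"""Decay fitting, field regression, CSA subtraction and ξ-space geometry."""

import itertools
import math

import numpy as np
import pytest

from methylmq.constants import Coherence, FieldSpec, MQ_COHERENCES
from methylmq.he_analysis import (DecayCurve, RateMeasurement, chi2_surface,
                                  fit_decay, regress_field, subtract_csa)
from methylmq.rates import (MethylSystem, XiPair, csa_contribution,
                            exchange_contribution_fast)
from methylmq.synth import HE_DELAYS_MS

from conftest import forward_rates

T950 = np.asarray(HE_DELAYS_MS[950.0]) * 1e-3


def make_curve(rate, amp=100.0, sigma=0.5, times=T950, rng=None):
    a = amp * np.exp(-rate * times)
    if rng is not None:
        a = a + rng.normal(0.0, sigma, size=times.size)
    return DecayCurve(times=times, amplitudes=a, sigma=sigma,
                      coherence=Coherence.QQ, fieldspec=FieldSpec(950.0),
                      methyl_id="m")


class TestFitDecay:
    def test_noiseless_exact_recovery(self):
        res = fit_decay(make_curve(50.0))
        assert res.rate == pytest.approx(50.0, abs=1e-8)
        assert res.converged

    def test_flat_curve_zero_rate(self):
        res = fit_decay(make_curve(0.0))
        assert abs(res.rate) <= 3 * res.err
        assert res.rate == pytest.approx(0.0, abs=1e-8)

    def test_monte_carlo_three_sigma_coverage(self):
        # 1 % amplitude noise, R = 150 s⁻¹: truth within 3 SE nearly always
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            res = fit_decay(make_curve(150.0, sigma=1.0, rng=rng))
            if abs(res.rate - 150.0) <= 3 * res.err:
                hits += 1
        assert hits / n_rep >= 0.99

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            DecayCurve(times=np.array([0.0, 0.01, 0.02]),
                       amplitudes=np.array([1.0, 0.9, 0.8]), sigma=0.1,
                       coherence=Coherence.ZQ, fieldspec=FieldSpec(600.0))


class TestRegressField:
    def test_noiseless_linear_model_exact(self, fields):
        r20, beta = 20.0, 0.05
        ms = [RateMeasurement("m", Coherence.ZQ, fs,
                              r20 + beta * fs.b0 ** 2, 0.1)
              for fs in fields]
        reg = regress_field(ms)
        assert reg.intercept == pytest.approx(r20, rel=1e-10)
        assert reg.slope == pytest.approx(beta, rel=1e-10)

    def test_equal_rates_zero_slope(self, fields):
        ms = [RateMeasurement("m", Coherence.DQ, fs, 31.0, 0.2)
              for fs in fields]
        assert regress_field(ms).slope == pytest.approx(0.0, abs=1e-12)

    def test_weighted_solution_matches_normal_equations(self, fields):
        # heteroscedastic data against a closed-form weighted-LS oracle
        rng = np.random.default_rng(5)
        x = np.array([fs.b0 ** 2 for fs in fields])
        y = 15.0 + 0.04 * x + rng.normal(0, 0.3, x.size)
        err = np.array([0.1, 0.5, 0.2, 0.8])
        ms = [RateMeasurement("m", Coherence.QQ, fs, float(yy), float(ee))
              for fs, yy, ee in zip(fields, y, err)]
        reg = regress_field(ms)
        w = 1.0 / err ** 2
        A = np.vstack([np.ones_like(x), x]).T
        ata = A.T @ (w[:, None] * A)
        sol = np.linalg.solve(ata, A.T @ (w * y))
        assert reg.intercept == pytest.approx(sol[0], rel=1e-10)
        assert reg.slope == pytest.approx(sol[1], rel=1e-10)
        assert np.allclose(reg.cov, np.linalg.inv(ata), rtol=1e-8)

    def test_insufficient_fields_rejected(self, fields):
        ms = [RateMeasurement("m", Coherence.ZQ, fs, 20.0, 0.1)
              for fs in fields[:2]]
        with pytest.raises(ValueError, match="3 distinct fields"):
            regress_field(ms)


class TestSubtractCsa:
    def test_zero_csa_passes_slope_through(self, fields):
        ms = [RateMeasurement("m", Coherence.DQ, fs,
                              10.0 + 0.03 * fs.b0 ** 2, 0.1)
              for fs in fields]
        con = subtract_csa(regress_field(ms), MethylSystem(s2tau=0.0),
                           Coherence.DQ)
        assert con.beta_ex == pytest.approx(0.03, rel=1e-9)
        assert con.exchange_flag == "ok"

    def test_pure_csa_slope_gives_zero_exchange(self, fields):
        sys_ = MethylSystem(s2tau=50e-9, dsigma_c=25.0, dsigma_h=0.4)
        for coh in MQ_COHERENCES:
            ms = [RateMeasurement("m", coh, fs,
                                  12.0 + csa_contribution(coh, sys_, fs),
                                  0.1) for fs in fields]
            con = subtract_csa(regress_field(ms), sys_, coh)
            assert con.beta_ex == pytest.approx(0.0, abs=1e-10)

    def test_forward_inverse_recovers_xi_combination(self, fields):
        sys_ = MethylSystem(s2tau=40e-9, dsigma_c=30.0, dsigma_h=0.5)
        xi = XiPair(xi_h=0.1, xi_c=0.25)
        r20 = {c.name: 15.0 for c in MQ_COHERENCES}
        per = forward_rates(sys_, xi, r20, fields)
        for coh in MQ_COHERENCES:
            con = subtract_csa(regress_field(per[coh]), sys_, coh)
            assert con.beta_ex == pytest.approx(
                (xi.xi_c + coh.n_h * xi.xi_h) ** 2, rel=1e-8)

    def test_overestimated_csa_flagged(self, fields):
        sys_ = MethylSystem(s2tau=80e-9, dsigma_c=50.0)
        ms = [RateMeasurement("m", Coherence.QQ, fs, 10.0 + 1e-4 * fs.b0 ** 2,
                              0.01) for fs in fields]
        con = subtract_csa(regress_field(ms), sys_, Coherence.QQ)
        assert con.exchange_flag == "no_exchange_or_csa_overestimate"
        assert con.lines() is None


def _intersections(constraints, truth_signs):
    """Pairwise line intersections for a given root-sign assignment."""
    pts = []
    for (n1, r1), (n2, r2) in itertools.combinations(
            [(c.n_h, s * math.sqrt(c.beta_ex))
             for c, s in zip(constraints, truth_signs)], 2):
        if n1 == n2:
            continue
        xh = (r1 - r2) / (n1 - n2)
        xc = r1 - n1 * xh
        pts.append((xh, xc))
    return pts


class TestXiGeometry:
    def setup_method(self):
        self.fields = [FieldSpec(f) for f in (600.0, 700.0, 800.0, 950.0)]
        self.sys = MethylSystem(s2tau=45e-9, dsigma_c=32.0, dsigma_h=0.3)
        self.xi = XiPair(xi_h=0.12, xi_c=0.28)
        self.r20 = {c.name: 18.0 for c in MQ_COHERENCES}
        self.per = forward_rates(self.sys, self.xi, self.r20, self.fields)

    def test_four_lines_concurrent_at_truth(self):
        cons = [subtract_csa(regress_field(self.per[c]), self.sys, c)
                for c in MQ_COHERENCES]
        best = math.inf
        for signs in itertools.product((1, -1), repeat=4):
            pts = _intersections(cons, signs)
            spread = max(math.dist(a, b)
                         for a, b in itertools.combinations(pts, 2))
            best = min(best, spread)
        assert best < 1e-9

    def test_inconsistent_input_has_no_common_intersection(self):
        # three-state-like data: high-order coherences follow a different
        # ξ pair, so the lines cannot all meet and min χ² stays positive
        other = XiPair(xi_h=0.2, xi_c=0.15)
        per = dict(self.per)
        per[Coherence.DQprime] = forward_rates(
            self.sys, other, self.r20, self.fields)[Coherence.DQprime]
        per[Coherence.QQ] = forward_rates(
            self.sys, other, self.r20, self.fields)[Coherence.QQ]
        cons = [subtract_csa(regress_field(per[c]), self.sys, c)
                for c in MQ_COHERENCES]
        best = math.inf
        for signs in itertools.product((1, -1), repeat=4):
            pts = _intersections(cons, signs)
            spread = max(math.dist(a, b)
                         for a, b in itertools.combinations(pts, 2))
            best = min(best, spread)
        assert best > 1e-3
        surf = chi2_surface(per, self.sys, n_grid=121)
        assert surf.min_chi2 > 10.0

    def _grid_with_truth(self, span=0.6, n=121):
        # symmetric grid containing the exact ± truth nodes
        g = np.linspace(-span, span, n)
        gh = np.sort(np.unique(np.concatenate(
            [g, [self.xi.xi_h, -self.xi.xi_h]])))
        gc = np.sort(np.unique(np.concatenate(
            [g, [self.xi.xi_c, -self.xi.xi_c]])))
        return gh, gc

    def test_noiseless_surface_minimum_zero_at_truth(self):
        gh, gc = self._grid_with_truth()
        surf = chi2_surface(self.per, self.sys, xi_h=gh, xi_c=gc)
        assert surf.min_chi2 == pytest.approx(0.0, abs=1e-6)
        found = {tuple(np.round(m, 10)) for m in surf.minima}
        assert (round(self.xi.xi_h, 10), round(self.xi.xi_c, 10)) in found \
            or (round(-self.xi.xi_h, 10), round(-self.xi.xi_c, 10)) in found

    def test_surface_symmetric_under_global_sign_flip(self):
        surf = chi2_surface(self.per, self.sys, n_grid=61)
        assert np.allclose(surf.chi2, surf.chi2[::-1, ::-1], rtol=1e-9,
                           atol=1e-9)

    def test_low_order_surface_swap_symmetric_full_surface_not(self):
        g = np.linspace(-0.5, 0.5, 81)
        lo = chi2_surface(self.per, self.sys, xi_h=g, xi_c=g,
                          coherences=(Coherence.ZQ, Coherence.DQ))
        assert np.allclose(lo.chi2, lo.chi2.T, rtol=1e-8, atol=1e-8)
        full = chi2_surface(self.per, self.sys, xi_h=g, xi_c=g)
        assert not np.allclose(full.chi2, full.chi2.T, rtol=1e-3)

    def test_confidence_contour_coverage_calibration(self):
        # 2 % rate noise at 4 fields: the 95 % region contains the truth
        # in at least 90 % of seeded replicates
        rng = np.random.default_rng(7)
        n_rep, hits = 200, 0
        gh, gc = self._grid_with_truth(span=0.6, n=161)
        for _ in range(n_rep):
            per = forward_rates(self.sys, self.xi, self.r20, self.fields,
                                rng=rng, noise=0.02)
            surf = chi2_surface(per, self.sys, xi_h=gh, xi_c=gc)
            if surf.contains(self.xi, level=0.95):
                hits += 1
        assert hits / n_rep >= 0.90
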