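"""Quartet lineshape algebra, cluster fitting and IPAP ¹H CSA recovery."""

import math

import numpy as np
import pytest

from methylmq.constants import CONSTANTS, Coherence, FieldSpec
from methylmq.csa_fit import (IPAPDataset, QuartetModel, cluster_peaks,
                              eta_rates, fit_quartet_cluster, ipap_h_csa,
                              quartet_lineshape)
from methylmq.he_analysis import DecayCurve
from methylmq.synth import gen_pseudo3d

FS800 = FieldSpec(800.0)
DELAYS = (0.0011, 0.05, 0.1, 0.15)


def make_model(**kw):
    # r2_c exceeds 3(η_CHCH + η_CHC) so every multiplet line decays
    base = dict(amp=1.0, omega0_h=0.7, omega0_c=22.0, r2_h=30.0, r2_c=160.0,
                j_ch=125.0, s2tau=50e-9, dsigma_c=30.0, fieldspec=FS800)
    base.update(kw)
    return QuartetModel(**base)


class TestEtaRates:
    def test_zero_order_parameter_gives_zero_rates(self):
        e = eta_rates(0.0, 30.0, 0.5, FS800)
        assert all(getattr(e, f) == 0.0 for f in
                   ("eta_hhhh", "eta_hhhc", "eta_chch", "eta_chc", "eta_h"))

    def test_field_scaling_only_for_csa_dipole_terms(self):
        e1 = eta_rates(50e-9, 30.0, 0.5, FieldSpec(600.0))
        e2 = eta_rates(50e-9, 30.0, 0.5, FieldSpec(1200.0))
        for f in ("eta_hhhh", "eta_hhhc", "eta_chch"):
            assert getattr(e2, f) == pytest.approx(getattr(e1, f), rel=1e-12)
        for f in ("eta_chc", "eta_c", "eta_h"):
            assert getattr(e2, f) == pytest.approx(2 * getattr(e1, f),
                                                   rel=1e-12)

    def test_csa_rate_ratio_is_gyromagnetic_ratio(self):
        e = eta_rates(40e-9, 25.0, 0.4, FS800)
        assert e.eta_c / e.eta_h == pytest.approx(
            (CONSTANTS.gamma_c * 25.0) / (CONSTANTS.gamma_h * 0.4),
            rel=1e-12)


class TestQuartetLineshape:
    def test_rigid_limit_pattern_3113(self):
        # Δ → 1 at S²τc = 0: outer/inner intensity ratio 6:2 = 3:1 at T=0
        m = make_model(s2tau=0.0, dsigma_c=0.0, r2_c=30.0)
        # evaluate at the line centres: angular offsets ±3πJ, ±πJ
        radps_per_ppm = CONSTANTS.gamma_c * FS800.b0 * 1e-6
        wc = 22.0 + np.array([3, 1, -1, -3]) * math.pi * m.j_ch / \
            radps_per_ppm
        wh = np.array([0.7])
        spec = quartet_lineshape(m, 0.0, wh, wc)[:, 0]
        # equal linewidths at Δσ=0, S²τc=0: peak heights ∝ intensities,
        # up to sub-percent Lorentzian tail overlap between lines
        assert spec[0] / spec[1] == pytest.approx(3.0, rel=1e-2)
        assert spec[3] / spec[2] == pytest.approx(3.0, rel=1e-2)

    def test_reflection_symmetric_without_carbon_csa(self):
        m = make_model(dsigma_c=0.0)
        wh = np.linspace(0.55, 0.85, 21)
        wc = 22.0 + np.linspace(-3.0, 3.0, 201)
        spec = quartet_lineshape(m, 0.08, wh, wc)
        assert np.allclose(spec, spec[::-1, :], rtol=1e-9, atol=1e-12)

    def test_outer_line_decay_asymmetry(self):
        # amplitude ratio of downfield/upfield outer lines after T equals
        # exp(−(R_ααα − R_βββ)·T) = exp(−6·η_CHC·T)
        m = make_model(s2tau=5e-9, r2_c=30.0)   # η_CHC ≈ 2.4 s⁻¹
        etas = eta_rates(m.s2tau, m.dsigma_c, 0.0, FS800)
        radps_per_ppm = CONSTANTS.gamma_c * FS800.b0 * 1e-6
        wc = 22.0 + np.array([3, -3]) * math.pi * m.j_ch / radps_per_ppm
        wh = np.array([0.7])
        t = 0.1
        s0 = quartet_lineshape(m, 0.0, wh, wc)[:, 0]
        st = quartet_lineshape(m, t, wh, wc)[:, 0]
        # peak heights include the 1/R linewidth factor; normalise at T=0
        ratio = (st[0] / s0[0]) / (st[1] / s0[1])
        assert ratio == pytest.approx(math.exp(-6 * etas.eta_chc * t),
                                      rel=2e-2)

    def test_numeric_asymmetry_example(self):
        # η_CHC = 2 s⁻¹, T = 0.1 s → ratio e^−1.2 ≈ 0.301
        assert math.exp(-6 * 2.0 * 0.1) == pytest.approx(0.301, abs=0.001)

    def test_degenerate_cross_correlations_single_decay(self):
        m = make_model(s2tau=0.0, dsigma_c=0.0)
        wh = np.linspace(0.6, 0.8, 11)
        wc = 22.0 + np.linspace(-3.0, 3.0, 101)
        t = 0.12
        s0 = quartet_lineshape(m, 0.0, wh, wc)
        st = quartet_lineshape(m, t, wh, wc)
        assert np.allclose(st, s0 * math.exp(-m.r2_c * t), rtol=1e-9)

    def test_integrated_intensity_conservation(self):
        # multiplet intensity at T=0 sums to 2·I_outer + 2·I_inner = 12+4Δ
        m = make_model(dsigma_c=0.0, r2_c=60.0)
        etas = eta_rates(m.s2tau, 0.0, 0.0, FS800)
        tau = 1.0 / (2 * m.j_ch)
        delta = math.exp(-4 * etas.eta_hhhh * tau) * math.cosh(
            2 * etas.eta_hhhc * tau)
        wh = np.array([0.7])
        wc = 22.0 + np.linspace(-120.0, 120.0, 240001)
        spec = quartet_lineshape(m, 0.0, wh, wc)[:, 0]
        radps_per_ppm = CONSTANTS.gamma_c * FS800.b0 * 1e-6
        area = np.trapezoid(spec, wc * radps_per_ppm)
        # each Lorentzian integrates to π; the ¹H factor is L_H(0) = 1/R_H
        expected = (12 + 4 * delta) * math.pi * m.amp / m.r2_h
        assert area == pytest.approx(expected, rel=2e-3)


class TestClusterPeaks:
    def test_strip_threshold_behaviour(self):
        close = [("a", 0.70, 22.0), ("b", 0.74, 22.5)]   # within 0.05/2.4
        assert len(cluster_peaks(close)) == 1
        far_h = [("a", 0.70, 22.0), ("b", 0.76, 22.5)]   # 0.06 ppm in 1H
        assert len(cluster_peaks(far_h)) == 2
        far_c = [("a", 0.70, 22.0), ("b", 0.74, 25.0)]   # 3 ppm in 13C
        assert len(cluster_peaks(far_c)) == 2

    def test_single_linkage_chains(self):
        chain = [("a", 0.70, 22.0), ("b", 0.74, 22.0), ("c", 0.78, 22.0)]
        assert len(cluster_peaks(chain)) == 1


class TestFitQuartetCluster:
    def test_noiseless_single_peak_recovery(self):
        m = make_model()
        spectra, wh, wc = gen_pseudo3d([m], delays_s=DELAYS)
        res = fit_quartet_cluster(spectra, list(DELAYS), wh, wc,
                                  [("pk", 0.7, 22.0)], FS800,
                                  sigma=1e-6 * float(np.max(spectra[0])))
        assert res.flags["pk"] == "ok"
        assert res.s2tau["pk"] == pytest.approx(50e-9, rel=1e-3)
        assert res.dsigma_c["pk"] == pytest.approx(30.0, rel=1e-3)

    def test_overlapping_pair_recovery_with_noise(self):
        m1 = make_model()
        m2 = make_model(amp=0.8, omega0_h=0.73, omega0_c=22.3, s2tau=35e-9,
                        dsigma_c=20.0)
        spectra, wh, wc = gen_pseudo3d([m1, m2], delays_s=DELAYS,
                                       noise=0.01 * 0.9, seed=4)
        sigma = 0.01 * float(np.max(
            gen_pseudo3d([m1, m2], delays_s=DELAYS)[0][0]))
        res = fit_quartet_cluster(spectra, list(DELAYS), wh, wc,
                                  [("p1", 0.7, 22.0), ("p2", 0.73, 22.3)],
                                  FS800, sigma=sigma)
        for pid, s2_true, dsc_true in (("p1", 50e-9, 30.0),
                                       ("p2", 35e-9, 20.0)):
            assert abs(res.s2tau[pid] - s2_true) <= \
                3 * res.s2tau_err[pid] + 1e-12
            assert abs(res.dsigma_c[pid] - dsc_true) <= \
                3 * res.dsigma_c_err[pid] + 1e-6

    def test_csa_sign_recovered(self):
        m = make_model(dsigma_c=-30.0)
        spectra, wh, wc = gen_pseudo3d([m], delays_s=DELAYS)
        res = fit_quartet_cluster(spectra, list(DELAYS), wh, wc,
                                  [("pk", 0.7, 22.0)], FS800,
                                  sigma=1e-6 * float(np.max(spectra[0])))
        assert res.dsigma_c["pk"] == pytest.approx(-30.0, rel=1e-3)


class TestIpapHCsa:
    def _dataset(self, dsigma_h, s2tau=50e-9, fs=FieldSpec(950.0),
                 rng=None, sigma=0.05, swap=False):
        e = eta_rates(s2tau, 0.0, dsigma_h, fs)
        ra, rb = 25.0 + e.eta_h, 25.0 - e.eta_h
        if swap:
            ra, rb = rb, ra
        t = np.array([2, 5, 10, 15, 20, 30, 50, 75, 100, 150]) * 1e-3

        def mk(rate):
            a = 100 * np.exp(-rate * t)
            if rng is not None:
                a = a + rng.normal(0, sigma, t.size)
            return DecayCurve(times=t, amplitudes=a, sigma=sigma,
                              coherence=Coherence.SQ_H, fieldspec=fs)
        return IPAPDataset(alpha=mk(ra), beta=mk(rb))

    def test_equal_rates_zero_csa(self):
        ds, _ = ipap_h_csa(self._dataset(0.0), 50e-9, FieldSpec(950.0))
        assert ds == pytest.approx(0.0, abs=1e-9)

    def test_roundtrip_with_noise(self):
        rng = np.random.default_rng(3)
        ds, err = ipap_h_csa(self._dataset(0.8, rng=rng), 50e-9,
                             FieldSpec(950.0))
        assert abs(ds - 0.8) <= 3 * err
        assert ds == pytest.approx(0.8, abs=0.1)

    def test_state_swap_flips_sign(self):
        d1, _ = ipap_h_csa(self._dataset(0.8), 50e-9, FieldSpec(950.0))
        d2, _ = ipap_h_csa(self._dataset(0.8, swap=True), 50e-9,
                           FieldSpec(950.0))
        assert d2 == pytest.approx(-d1, rel=1e-9)

    def test_zero_s2tau_is_indeterminate(self):
        with pytest.raises(ValueError, match="indeterminate"):
            ipap_h_csa(self._dataset(0.5), 0.0, FieldSpec(950.0))
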