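"""Order-parameter and CSA determination from quartet lineshapes and IPAP.

S²axis·τc and the ¹³C CSA are estimated jointly from relaxation-weighted
¹H-coupled HSQC spectra: the ¹³C quartet's inner/outer intensity ratio
encodes S²axis·τc through the dipole–dipole cross-correlated rates, while
the up-/down-field decay asymmetry encodes ΔσC through the CSA–dipole
rate. The ¹H CSA follows from spin-state-selective relaxation rates
(IPAP sub-spectra): ηH = (Rα − Rβ)/2 ∝ γH·B0·ΔσH·S²axis·τc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
import lmfit

from .constants import CONSTANTS, Constants, FieldSpec
from .he_analysis import DecayCurve, fit_decay

__all__ = [
    "EtaRates", "QuartetModel", "IPAPDataset", "eta_rates",
    "quartet_lineshape", "cluster_peaks", "fit_quartet_cluster",
    "QuartetFitResult", "ipap_h_csa",
]


@dataclass(frozen=True)
class EtaRates:
    """Cross-correlated relaxation rates of the methyl spin system (s⁻¹).

    The dipole–dipole rates (``eta_hhhh``, ``eta_hhhc``, ``eta_chch``) are
    field-independent and linear in S²axis·τc; the CSA–dipole rates
    (``eta_chc``, ``eta_c``, ``eta_h``) are additionally linear in B0.
    ``eta_c`` and ``eta_chc`` are the same physical quantity (¹³C
    CSA / C–H dipole cross-correlation), kept as separate fields to mirror
    their two roles (multiplet decay asymmetry vs CSA inversion).
    """

    eta_hhhh: float
    eta_hhhc: float
    eta_chch: float
    eta_chc: float
    eta_c: float
    eta_h: float


def eta_rates(s2tau: float, dsigma_c: float, dsigma_h: float,
              fieldspec: FieldSpec,
              constants: Constants = CONSTANTS) -> EtaRates:
    """Evaluate all cross-correlated rates for one methyl group.

    ``dsigma_c``/``dsigma_h`` in ppm; ``s2tau`` in seconds. Prefactors:
    9/40 (H–H auto), 1/5 (H–H/C–H cross), 2/45 (C–H auto),
    4/45 (CSA–dipole).
    """
    if s2tau < 0:
        raise ValueError("s2tau must be >= 0")
    c = constants
    dd = (c.mu0 / (4.0 * math.pi)) ** 2 * c.hbar ** 2
    b0 = fieldspec.b0
    eta_hhhh = (9.0 / 40.0) * dd * c.gamma_h ** 4 / c.r_hh ** 6 * s2tau
    eta_hhhc = (1.0 / 5.0) * dd * c.gamma_c * c.gamma_h ** 3 / (
        c.r_ch ** 3 * c.r_hh ** 3) * s2tau
    eta_chch = (2.0 / 45.0) * dd * c.gamma_c ** 2 * c.gamma_h ** 2 / (
        c.r_ch ** 6) * s2tau
    csa_pref = (4.0 / 45.0) * (c.mu0 / (4.0 * math.pi)) * c.hbar * \
        c.gamma_c * c.gamma_h / c.r_ch ** 3 * b0 * s2tau
    eta_chc = csa_pref * c.gamma_c * dsigma_c * 1e-6
    eta_h = csa_pref * c.gamma_h * dsigma_h * 1e-6
    return EtaRates(eta_hhhh=eta_hhhh, eta_hhhc=eta_hhhc, eta_chch=eta_chch,
                    eta_chc=eta_chc, eta_c=eta_chc, eta_h=eta_h)


@dataclass(frozen=True)
class QuartetModel:
    """Parameters of one ¹³C quartet multiplet in the coupled HSQC."""

    amp: float
    omega0_h: float      # ppm
    omega0_c: float      # ppm
    r2_h: float          # s-1
    r2_c: float          # s-1
    j_ch: float          # Hz, near 125
    s2tau: float         # s
    dsigma_c: float      # ppm
    fieldspec: FieldSpec = dfield(default_factory=lambda: FieldSpec(800.0))

    def __post_init__(self) -> None:
        if not 100.0 <= self.j_ch <= 150.0:
            raise ValueError("j_ch expected within 125 Hz +/- 20 %")
        if self.r2_h <= 0 or self.r2_c <= 0:
            raise ValueError("line relaxation rates must be positive")


def _lorentz(omega: np.ndarray, omega0: float, rate: float) -> np.ndarray:
    """L(ω; ω0, R) = R / (R² + (ω − ω0)²)."""
    d = omega - omega0
    return rate / (rate * rate + d * d)


def quartet_lineshape(model: QuartetModel, t_relax: float,
                      wh_ppm: np.ndarray, wc_ppm: np.ndarray,
                      constants: Constants = CONSTANTS) -> np.ndarray:
    """2D intensity of one quartet at relaxation delay T (shape C × H).

    Four Lorentzian lines at ω0,C ± πJ, ± 3πJ (angular units) with
    intensities I_outer = 3 + 3Δ, I_inner = 3 − Δ where
    Δ = exp(−4η_HHHH·τ)·cosh(2η_HHHC·τ), τ = 1/(2J); each line decays
    during T at its spin-state-specific rate
    R_ααα = R2,C + 3η_CHCH + 3η_CHC (and cyclic variants). The ¹H
    dimension is a single Lorentzian at ω0,H.
    """
    if t_relax < 0:
        raise ValueError("t_relax must be >= 0")
    fs = model.fieldspec
    c = constants
    etas = eta_rates(model.s2tau, model.dsigma_c, 0.0, fs, c)
    tau = 1.0 / (2.0 * model.j_ch)
    delta = math.exp(-4.0 * etas.eta_hhhh * tau) * math.cosh(
        2.0 * etas.eta_hhhc * tau)
    i_outer = 3.0 + 3.0 * delta
    i_inner = 3.0 - delta

    r_aaa = model.r2_c + 3.0 * etas.eta_chch + 3.0 * etas.eta_chc
    r_aab = model.r2_c - etas.eta_chch + etas.eta_chc
    r_abb = model.r2_c - etas.eta_chch - etas.eta_chc
    r_bbb = model.r2_c + 3.0 * etas.eta_chch - 3.0 * etas.eta_chc

    # ppm -> angular offsets from the multiplet centre
    wh = (np.asarray(wh_ppm, dtype=float) - model.omega0_h) * 1e-6 * \
        c.gamma_h * fs.b0
    wc = (np.asarray(wc_ppm, dtype=float) - model.omega0_c) * 1e-6 * \
        c.gamma_c * fs.b0
    pij = math.pi * model.j_ch
    lines = (
        (i_outer, r_aaa, +3.0 * pij),
        (i_inner, r_aab, +1.0 * pij),
        (i_inner, r_abb, -1.0 * pij),
        (i_outer, r_bbb, -3.0 * pij),
    )
    c_profile = np.zeros_like(wc)
    for inten, rate, offset in lines:
        c_profile += inten * math.exp(-rate * t_relax) * _lorentz(
            wc, offset, rate)
    h_profile = _lorentz(wh, 0.0, model.r2_h)
    return model.amp * np.outer(c_profile, h_profile)


def cluster_peaks(peaks: list[tuple[str, float, float]],
                  strip_h: float = 0.05,
                  strip_c: float = 2.4) -> list[list[int]]:
    """Single-linkage clustering of (id, ωH ppm, ωC ppm) peak entries.

    Two peaks join a cluster when they fall within the ¹H × ¹³C strip
    windows (defaults 0.05 ppm × 2.4 ppm). Returns index groups.
    """
    n = len(peaks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (abs(peaks[i][1] - peaks[j][1]) <= strip_h
                    and abs(peaks[i][2] - peaks[j][2]) <= strip_c):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


@dataclass
class QuartetFitResult:
    """Per-peak estimates from a cluster fit of pseudo-3D quartet data."""

    peak_ids: list[str]
    s2tau: dict[str, float]
    s2tau_err: dict[str, float]
    dsigma_c: dict[str, float]
    dsigma_c_err: dict[str, float]
    chi2: float
    flags: dict[str, str]      # "ok" | "non_converged" | "at_bound"
    params: "lmfit.Parameters"


def fit_quartet_cluster(spectra: list[np.ndarray], delays: list[float],
                        wh_ppm: np.ndarray, wc_ppm: np.ndarray,
                        peaks: list[tuple[str, float, float]],
                        fieldspec: FieldSpec, sigma: float = 1.0,
                        constants: Constants = CONSTANTS) -> QuartetFitResult:
    """Joint nonlinear fit of all quartets in one cluster.

    ``spectra`` is a pseudo-3D stack (one 2D grid per relaxation delay,
    shape C × H, shared ppm axes). Peak positions come from a decoupled
    reference spectrum and are refined within narrow windows; J_CH is
    fitted per peak within [100, 150] Hz from a 125 Hz start.
    """
    if len(spectra) != len(delays) or len(spectra) < 3:
        raise ValueError("need >= 3 delays with matching spectra")
    for _, _, wc0 in peaks:
        if wc0 - wc_span_ppm(fieldspec, constants) < wc_ppm.min() or \
           wc0 + wc_span_ppm(fieldspec, constants) > wc_ppm.max():
            import warnings
            warnings.warn("grid may not cover the outer quartet lines "
                          f"(+/-3πJ) around {wc0} ppm", stacklevel=2)
    params = lmfit.Parameters()
    keys = []
    for k, (pid, wh0, wc0) in enumerate(peaks):
        key = f"p{k}"
        keys.append(key)
        # peak height ≈ amp·6/(R2C·R2H); invert for the amplitude start
        amp0 = float(np.max(spectra[0])) * 100.0 * 30.0 / 6.0
        params.add(f"{key}_amp", value=amp0, min=0.0)
        params.add(f"{key}_w0h", value=wh0, min=wh0 - 0.05, max=wh0 + 0.05)
        params.add(f"{key}_w0c", value=wc0, min=wc0 - 0.3, max=wc0 + 0.3)
        params.add(f"{key}_r2h", value=30.0, min=0.1, max=500.0)
        params.add(f"{key}_r2c", value=100.0, min=0.1, max=500.0)
        params.add(f"{key}_j", value=125.0, min=100.0, max=150.0)
        params.add(f"{key}_s2tau", value=30e-9, min=0.0, max=500e-9)
        params.add(f"{key}_dsc", value=10.0, min=-100.0, max=100.0)

    def models_from(p: lmfit.Parameters) -> list[QuartetModel]:
        return [QuartetModel(
            amp=p[f"{k}_amp"].value, omega0_h=p[f"{k}_w0h"].value,
            omega0_c=p[f"{k}_w0c"].value, r2_h=p[f"{k}_r2h"].value,
            r2_c=p[f"{k}_r2c"].value, j_ch=p[f"{k}_j"].value,
            s2tau=p[f"{k}_s2tau"].value, dsigma_c=p[f"{k}_dsc"].value,
            fieldspec=fieldspec) for k in keys]

    def residual(p: lmfit.Parameters) -> np.ndarray:
        res = []
        ms = models_from(p)
        for spec, t in zip(spectra, delays):
            calc = sum(quartet_lineshape(m, t, wh_ppm, wc_ppm, constants)
                       for m in ms)
            res.append(((spec - calc) / sigma).ravel())
        return np.concatenate(res)

    out = lmfit.minimize(residual, params, method="leastsq")
    flags, s2, s2e, dsc, dsce = {}, {}, {}, {}, {}
    for k, (pid, _, _) in zip(keys, peaks):
        flag = "ok" if out.success else "non_converged"
        for pname in (f"{k}_s2tau", f"{k}_dsc", f"{k}_j"):
            par = out.params[pname]
            if par.value in (par.min, par.max):
                flag = "at_bound"
        flags[pid] = flag
        s2[pid] = out.params[f"{k}_s2tau"].value
        s2e[pid] = out.params[f"{k}_s2tau"].stderr or float("nan")
        dsc[pid] = out.params[f"{k}_dsc"].value
        dsce[pid] = out.params[f"{k}_dsc"].stderr or float("nan")
    return QuartetFitResult(
        peak_ids=[p[0] for p in peaks], s2tau=s2, s2tau_err=s2e,
        dsigma_c=dsc, dsigma_c_err=dsce, chi2=float(out.chisqr),
        flags=flags, params=out.params)


def wc_span_ppm(fieldspec: FieldSpec,
                constants: Constants = CONSTANTS) -> float:
    """Half-width in ppm of the quartet (±3πJ at J = 150 Hz)."""
    return 3.0 * math.pi * 150.0 / (constants.gamma_c * fieldspec.b0 * 1e-6)


@dataclass(frozen=True)
class IPAPDataset:
    """¹³C spin-state-selective ¹H decay curves (shared delay list)."""

    alpha: DecayCurve
    beta: DecayCurve

    def __post_init__(self) -> None:
        if not np.array_equal(self.alpha.times, self.beta.times):
            raise ValueError("alpha/beta sub-spectra must share delays")


def ipap_h_csa(data: IPAPDataset, s2tau: float, fieldspec: FieldSpec,
               s2tau_err: float = 0.0,
               constants: Constants = CONSTANTS) -> tuple[float, float]:
    """¹H CSA (ppm) and its standard error from IPAP relaxation rates.

    Fits Rα and Rβ by exponential decay, forms ηH = (Rα − Rβ)/2 and
    inverts ηH = (4/45)(μ0ħγCγH/4πr_CH³)·γH·B0·ΔσH·S²τc. Swapping the
    α/β assignment flips the sign of the result.
    """
    if s2tau <= 0:
        raise ValueError("CSA indeterminate: s2tau must be positive")
    ra = fit_decay(data.alpha)
    rb = fit_decay(data.beta)
    if not (ra.converged and rb.converged):
        raise RuntimeError("spin-state decay fit did not converge")
    eta_h = 0.5 * (ra.rate - rb.rate)
    eta_h_err = 0.5 * math.hypot(ra.err, rb.err)
    c = constants
    pref = (4.0 / 45.0) * (c.mu0 / (4.0 * math.pi)) * c.hbar * \
        c.gamma_c * c.gamma_h / c.r_ch ** 3 * c.gamma_h * fieldspec.b0 * s2tau
    dsigma_h = eta_h / pref * 1e6
    rel = (eta_h_err / eta_h) ** 2 if eta_h != 0 else 0.0
    rel += (s2tau_err / s2tau) ** 2
    err = abs(dsigma_h) * math.sqrt(rel) if eta_h != 0 else \
        eta_h_err / pref * 1e6
    return dsigma_h, err
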