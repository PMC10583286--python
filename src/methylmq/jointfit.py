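"""Global fit of field-dependent Hahn-echo rates and CPMG dispersions.

Residues assigned to one cluster share the exchange parameters (p_B,
k_ex); each methyl carries its own chemical shift differences (ΔδC, ΔδH)
and baseline rates. Hahn-echo rates are modelled as

    R_2,obs = R_2,0 + R_CSA(B0) + Rex(B0),

with Rex from the dominant Liouvillian eigenvalue (valid in all exchange
regimes, so the fast-exchange assumption of the ξ-space analysis is
relaxed), and CPMG data are modelled by numerical propagation through
ideal echo trains. All residuals are weighted by their standard errors
and minimised jointly with Levenberg–Marquardt; parameter uncertainties
come from the curvature of the χ² surface at the optimum.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field as dfield

import numpy as np
import lmfit

from .constants import Coherence, FieldSpec, MQ_COHERENCES
from .exchange import (CPMGDataset, TwoStateExchange, cpmg_profile,
                       rex_closed_form)
from .he_analysis import RateMeasurement
from .rates import MethylSystem, XiPair, csa_contribution, xi_from_exchange

__all__ = ["ClusterSpec", "FitResult", "he_model", "global_fit",
           "back_calculate_xi", "combined_shift"]


@dataclass(frozen=True)
class ClusterSpec:
    """Assignment of methyl groups to shared exchange processes."""

    clusters: dict[str, tuple[str, ...]]   # cluster_id -> methyl ids

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        norm = {}
        for cid, methyls in self.clusters.items():
            methyls = tuple(methyls)
            norm[cid] = methyls
            for m in methyls:
                if m in seen:
                    raise ValueError(
                        f"methyl {m!r} assigned to both {seen[m]!r} and "
                        f"{cid!r}")
                seen[m] = cid
        object.__setattr__(self, "clusters", norm)

    def cluster_of(self, methyl_id: str) -> str:
        for cid, methyls in self.clusters.items():
            if methyl_id in methyls:
                return cid
        raise KeyError(methyl_id)


@dataclass
class FitResult:
    """Outcome of the joint HE + CPMG fit."""

    params: "lmfit.Parameters"
    chi2: float
    ndata: int
    nvarys: int
    success: bool
    clusters: ClusterSpec
    residuals: np.ndarray
    correlation_flags: list[str]
    all_starts: list[tuple[float, float, float]]  # (kex0, pB0, chi2)

    @property
    def redchi(self) -> float:
        return self.chi2 / max(self.ndata - self.nvarys, 1)

    def exchange_model(self, methyl_id: str) -> TwoStateExchange:
        cid = _key(self.clusters.cluster_of(methyl_id))
        m = _key(methyl_id)
        return TwoStateExchange(
            p_b=self.params[f"pB_{cid}"].value,
            k_ex=self.params[f"kex_{cid}"].value,
            ddelta_c=self.params[f"ddC_{m}"].value,
            ddelta_h=self.params[f"ddH_{m}"].value)

    def value(self, name: str) -> float:
        return self.params[name].value

    def stderr(self, name: str) -> float:
        e = self.params[name].stderr
        return float(e) if e else float("nan")


def _key(s: str) -> str:
    return re.sub(r"\W", "_", s)


def he_model(r20: float, model: TwoStateExchange, system: MethylSystem,
             coherence: Coherence, fieldspec: FieldSpec) -> float:
    """Predicted Hahn-echo rate R_2,0 + CSA + Rex (s⁻¹).

    The CSA parameters are fixed external inputs; the exchange term uses
    the closed-form dominant eigenvalue at the coherence's Δω.
    """
    dw = model.delta_omega(coherence, fieldspec)
    return (r20 + csa_contribution(coherence, system, fieldspec)
            + rex_closed_form(dw, model))


def _default_starts(n_starts: int) -> list[tuple[float, float]]:
    """Log-spaced kex × pB launch grid for the multi-start search."""
    if n_starts <= 1:
        return [(1000.0, 0.05)]
    n_k = max(2, round(math.sqrt(n_starts * 2)))
    n_p = max(2, n_starts // n_k + 1)
    kexs = np.geomspace(1e2, 1e5, n_k)
    pbs = np.geomspace(0.005, 0.2, n_p)
    grid = [(float(k), float(p)) for k in kexs for p in pbs]
    return grid[:n_starts]


def global_fit(he_data: list[RateMeasurement],
               cpmg_data: list[CPMGDataset],
               clusters: ClusterSpec,
               systems: dict[str, MethylSystem],
               start: dict[str, float] | None = None,
               n_starts: int = 8,
               cpmg_start_coherence: str = "DQ") -> FitResult:
    """Joint Levenberg–Marquardt fit of all HE and CPMG datasets.

    Free parameters: per cluster (p_B, k_ex); per methyl (ΔδC ≥ 0 by sign
    convention, ΔδH of free sign); one exchange-free R_2,0 per
    (methyl, HE coherence); one baseline per (methyl, experiment kind,
    field) for CPMG. ``start`` may pin explicit starting values by
    parameter name; otherwise ``n_starts`` launches over a log-spaced
    (k_ex, p_B) grid are tried and the best-χ² solution is kept (all
    starts are logged on the result).
    """
    methyls = sorted({m for ms in clusters.clusters.values() for m in ms})
    he_by_methyl: dict[str, list[RateMeasurement]] = {m: [] for m in methyls}
    for meas in he_data:
        if meas.methyl_id not in he_by_methyl:
            raise ValueError(f"HE methyl {meas.methyl_id!r} not in clusters")
        he_by_methyl[meas.methyl_id].append(meas)
    for ds in cpmg_data:
        if ds.methyl_id not in he_by_methyl:
            raise ValueError(f"CPMG methyl {ds.methyl_id!r} not in clusters")

    def build_params(kex0: float, pb0: float) -> lmfit.Parameters:
        p = lmfit.Parameters()
        for cid in clusters.clusters:
            p.add(f"pB_{_key(cid)}", value=pb0, min=1e-4, max=0.499)
            p.add(f"kex_{_key(cid)}", value=kex0, min=1.0, max=1e6)
        for m in methyls:
            p.add(f"ddC_{_key(m)}", value=0.5, min=0.0, max=10.0)
            p.add(f"ddH_{_key(m)}", value=0.05, min=-3.0, max=3.0)
        for m, ms in he_by_methyl.items():
            for coh in {x.coherence for x in ms}:
                rates = [x.rate for x in ms if x.coherence is coh]
                p.add(f"r20_{_key(m)}_{coh.name}",
                      value=max(min(rates) * 0.8, 0.1), min=0.0, max=2e3)
        for ds in cpmg_data:
            exp = ds.experiment
            p.add(f"base_{_key(ds.methyl_id)}_{exp.kind}_"
                  f"{int(exp.fieldspec.larmor_h)}",
                  value=min(ds.reff) * 0.9, min=0.0, max=2e3)
        if start:
            for name, val in start.items():
                p[name].set(value=val)
        return p

    def residual(p: lmfit.Parameters) -> np.ndarray:
        res = []
        for m in methyls:
            cid = _key(clusters.cluster_of(m))
            model = TwoStateExchange(
                p_b=p[f"pB_{cid}"].value, k_ex=p[f"kex_{cid}"].value,
                ddelta_c=p[f"ddC_{_key(m)}"].value,
                ddelta_h=p[f"ddH_{_key(m)}"].value)
            for meas in he_by_methyl[m]:
                pred = he_model(
                    p[f"r20_{_key(m)}_{meas.coherence.name}"].value,
                    model, systems[m], meas.coherence, meas.fieldspec)
                res.append((meas.rate - pred) / meas.err)
        for ds in cpmg_data:
            m = ds.methyl_id
            cid = _key(clusters.cluster_of(m))
            model = TwoStateExchange(
                p_b=p[f"pB_{cid}"].value, k_ex=p[f"kex_{cid}"].value,
                ddelta_c=p[f"ddC_{_key(m)}"].value,
                ddelta_h=p[f"ddH_{_key(m)}"].value)
            exp = ds.experiment
            base = p[f"base_{_key(m)}_{exp.kind}_"
                     f"{int(exp.fieldspec.larmor_h)}"].value
            pred = cpmg_profile(model, exp, base,
                                start=cpmg_start_coherence)
            res.extend((np.asarray(ds.reff) - pred)
                       / np.asarray(ds.err))
        return np.asarray(res, dtype=float)

    launches = ([(start.get("kex", 1000.0), start.get("pB", 0.05))]
                if start and ("kex" in start or "pB" in start)
                else _default_starts(n_starts))
    best = None
    log: list[tuple[float, float, float]] = []
    for kex0, pb0 in launches:
        params = build_params(kex0, pb0)
        if start:
            for name, val in start.items():
                if name in params:
                    params[name].set(value=val)
        try:
            out = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        log.append((kex0, pb0, float(out.chisqr)))
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError("all optimisation starts failed")

    flags = []
    if best.params and getattr(best, "covar", None) is not None:
        var_names = best.var_names
        corr = _correlation(best.covar)
        for i in range(len(var_names)):
            for j in range(i + 1, len(var_names)):
                if abs(corr[i, j]) > 0.95:
                    flags.append(
                        f"strong correlation {var_names[i]}~{var_names[j]}"
                        f" ({corr[i, j]:+.3f})")
    else:
        flags.append("covariance unavailable (rank-deficient Jacobian); "
                     "parameter combinations may be non-identifiable")
    return FitResult(params=best.params, chi2=float(best.chisqr),
                     ndata=int(best.ndata), nvarys=int(best.nvarys),
                     success=bool(best.success), clusters=clusters,
                     residuals=np.asarray(best.residual),
                     correlation_flags=flags, all_starts=log)


def _correlation(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    return cov / np.outer(d, d)


def back_calculate_xi(result: FitResult, methyl_id: str) -> XiPair:
    """(ξH, ξC) implied by the fitted exchange parameters of one methyl."""
    model = result.exchange_model(methyl_id)
    return xi_from_exchange(model.p_b, model.k_ex,
                            model.ddelta_c, model.ddelta_h)


def combined_shift(ddelta_c: float, ddelta_h: float) -> float:
    """Combined methyl shift magnitude Δδ_CH = sqrt((ΔδC/4)² + ΔδH²)."""
    return math.hypot(ddelta_c / 4.0, ddelta_h)
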