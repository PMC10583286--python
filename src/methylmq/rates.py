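"""Forward calculators for methyl multiple-quantum transverse relaxation.

The observed Hahn-echo rate of each coherence decomposes into three
additive contributions:

* dipolar relaxation from *external* protons/deuterons (intra-methyl
  dipolar relaxation of the ZQ/DQ/DQ′/QQ coherences is identically zero),
* CSA relaxation, (4/45)·(γC·ΔσC + n_H·γH·ΔσH)²·B0²·S²axis·τc,
* chemical exchange, in the fast limit (ξC + n_H·ξH)²·B0².

ξX = sqrt(pA·pB/kex)·γX·ΔδX·1e-6 is the chemical shift difference
normalised by the exchange parameters, in units such that ξ²·B0² is s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield
from typing import Sequence

from .constants import (CONSTANTS, Constants, Coherence, ExternalSpin,
                        FieldSpec, MQ_COHERENCES)

__all__ = [
    "MethylSystem", "XiPair", "csa_contribution", "exchange_contribution_fast",
    "dipolar_contribution", "mq_combine", "total_rate", "csa_impact",
]


@dataclass(frozen=True)
class MethylSystem:
    """Physical parameters of one methyl group.

    s2tau
        S²axis·τc in seconds (order parameter squared times rotational
        correlation time); scales all CSA terms.
    tau_c
        τc in seconds, required only for external-spin dipolar sums.
    dsigma_c, dsigma_h
        ¹³C and ¹H chemical shift anisotropies in ppm.
    externals
        external protons/deuterons contributing dipolar relaxation.
    """

    s2tau: float = 0.0
    tau_c: float | None = None
    dsigma_c: float = 0.0
    dsigma_h: float = 0.0
    externals: tuple[ExternalSpin, ...] = ()

    def __post_init__(self) -> None:
        if self.s2tau < 0:
            raise ValueError("s2tau must be >= 0")
        if not (math.isfinite(self.dsigma_c) and math.isfinite(self.dsigma_h)):
            raise ValueError("CSA values must be finite")
        object.__setattr__(self, "externals", tuple(self.externals))


@dataclass(frozen=True)
class XiPair:
    """Normalised chemical shift differences (ξH, ξC).

    Units are per tesla, such that the exchange contribution
    (ξC + n_H·ξH)²·B0² is in s⁻¹.
    """

    xi_h: float
    xi_c: float


# Table-1 dipolar coefficients: (c_bC², c_bH², c_cross) per coherence,
# for external protons and deuterons respectively.
_DIP_PROTON = {
    Coherence.ZQ:      (1 / 5, 11 / 20, -2 / 5),
    Coherence.DQ:      (1 / 5, 11 / 20, +2 / 5),
    Coherence.DQprime: (1 / 5, 39 / 20, -6 / 5),
    Coherence.QQ:      (1 / 5, 39 / 20, +6 / 5),
}
_DIP_DEUTERON = {
    Coherence.ZQ:      (8 / 15, 8 / 15, -16 / 15),
    Coherence.DQ:      (8 / 15, 8 / 15, +16 / 15),
    Coherence.DQprime: (8 / 15, 24 / 5, -16 / 5),
    Coherence.QQ:      (8 / 15, 24 / 5, +16 / 5),
}


def _require_mq(coherence: Coherence) -> None:
    if coherence not in MQ_COHERENCES:
        raise ValueError(
            f"{coherence.name} unsupported; expected one of "
            + ", ".join(c.name for c in MQ_COHERENCES))


def csa_contribution(coherence: Coherence, system: MethylSystem,
                     fieldspec: FieldSpec) -> float:
    """CSA contribution (4/45)(γCΔσC + n_H·γHΔσH)²·B0²·S²τc in s⁻¹."""
    _require_mq(coherence)
    c = fieldspec.constants
    term = (c.gamma_c * system.dsigma_c
            + coherence.n_h * c.gamma_h * system.dsigma_h) * 1e-6
    return (4.0 / 45.0) * term * term * fieldspec.b0 ** 2 * system.s2tau


def exchange_contribution_fast(coherence: Coherence, xi: XiPair,
                               fieldspec: FieldSpec) -> float:
    """Fast-exchange contribution (ξC + n_H·ξH)²·B0² in s⁻¹."""
    _require_mq(coherence)
    comb = xi.xi_c + coherence.n_h * xi.xi_h
    return comb * comb * fieldspec.b0 ** 2


def dipolar_contribution(coherence: Coherence, system: MethylSystem) -> float:
    """External-spin dipolar contribution in s⁻¹ (0 if no external spins).

    Intra-methyl dipolar relaxation of these coherences is zero; only
    interactions with external protons and deuterons contribute, each as
    (c1·b_C² + c2·b_H² + c3·b_C·b_H)·τc with the printed coefficients.
    """
    _require_mq(coherence)
    if not system.externals:
        return 0.0
    if system.tau_c is None:
        raise ValueError("tau_c is required when external spins are present")
    total = 0.0
    for spin in system.externals:
        coefs = (_DIP_PROTON if spin.kind == "proton" else _DIP_DEUTERON)[coherence]
        c1, c2, c3 = coefs
        total += (c1 * spin.b_c ** 2 + c2 * spin.b_h ** 2
                  + c3 * spin.b_c * spin.b_h) * system.tau_c
    return total


def total_rate(coherence: Coherence, system: MethylSystem, xi: XiPair,
               fieldspec: FieldSpec) -> float:
    """R₂ = dipolar + CSA + fast-exchange contributions (s⁻¹)."""
    return (dipolar_contribution(coherence, system)
            + csa_contribution(coherence, system, fieldspec)
            + exchange_contribution_fast(coherence, xi, fieldspec))


def mq_combine(r_zq: float, r_dq: float) -> tuple[float, float]:
    """Sum/difference combinations of ZQ and DQ rates.

    Returns (R_MQ, ΔR_MQ) = ((R_ZQ + R_DQ)/2, (R_ZQ − R_DQ)/2), so that
    R_ZQ = R_MQ + ΔR_MQ and R_DQ = R_MQ − ΔR_MQ.
    """
    if not (math.isfinite(r_zq) and math.isfinite(r_dq)):
        raise ValueError("rates must be finite")
    return 0.5 * (r_zq + r_dq), 0.5 * (r_zq - r_dq)


def xi_from_exchange(p_b: float, k_ex: float, ddelta_c: float,
                     ddelta_h: float,
                     constants: Constants = CONSTANTS) -> XiPair:
    """ξX = sqrt(pA·pB/kex)·γX·ΔδX·1e-6 for both nuclei (per tesla)."""
    norm = math.sqrt((1.0 - p_b) * p_b / k_ex)
    return XiPair(xi_h=norm * constants.gamma_h * ddelta_h * 1e-6,
                  xi_c=norm * constants.gamma_c * ddelta_c * 1e-6)


def csa_impact(system: MethylSystem, xi: XiPair) -> dict[str, float]:
    """Relative impact of each CSA on relaxation, versus the exchange terms.

    For nucleus X the impact is defined as the summed absolute change of
    the per-coherence CSA coefficients when Δσ_X is zeroed, relative to the
    summed fast-exchange coefficients (B0² cancels):

        impact_X = Σ_coh |β_CSA(ΔσC, ΔσH) − β_CSA(Δσ_X → 0)| / Σ_coh β_ex

    Returned as percentages under keys ``"C"`` and ``"H"``. This is an
    order-of-magnitude diagnostic of whether per-methyl CSA measurement is
    needed or residue-type averages suffice.
    """
    unit = FieldSpec(600.0, constants=CONSTANTS)  # any field: ratio is B0-free
    b0sq = unit.b0 ** 2

    def beta_csa(sys_: MethylSystem) -> dict[Coherence, float]:
        return {c: csa_contribution(c, sys_, unit) / b0sq
                for c in MQ_COHERENCES}

    full = beta_csa(system)
    no_c = beta_csa(MethylSystem(s2tau=system.s2tau, dsigma_c=0.0,
                                 dsigma_h=system.dsigma_h))
    no_h = beta_csa(MethylSystem(s2tau=system.s2tau, dsigma_c=system.dsigma_c,
                                 dsigma_h=0.0))
    beta_ex = sum(exchange_contribution_fast(c, xi, unit) / b0sq
                  for c in MQ_COHERENCES)
    if beta_ex <= 0:
        raise ValueError("exchange terms are zero; impact undefined")
    impact_c = sum(abs(full[c] - no_c[c]) for c in MQ_COHERENCES) / beta_ex
    impact_h = sum(abs(full[c] - no_h[c]) for c in MQ_COHERENCES) / beta_ex
    return {"C": 100.0 * impact_c, "H": 100.0 * impact_h}
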