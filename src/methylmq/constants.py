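"""Physical constants, coherence algebra and dipolar couplings.

All internal frequencies are angular (rad s⁻¹); user-facing chemical
shifts are in ppm and magnetic fields are specified by the ¹H Larmor
frequency in MHz. The ppm → rad s⁻¹ conversion happens only inside the
operations defined here and in :mod:`methylmq.rates`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum


@dataclass(frozen=True)
class Constants:
    """Fundamental constants and effective methyl geometry (SI units).

    ``r_ch`` and ``r_hh`` are *effective* methyl C–H and H–H distances,
    vibrationally averaged values commonly used for ¹³CH₃ relaxation
    analysis. Both may be overridden via configuration.
    """

    gamma_h: float = 2.6752218744e8   # rad s-1 T-1
    gamma_c: float = 6.728284e7       # rad s-1 T-1
    gamma_d: float = 4.10629791e7     # rad s-1 T-1
    mu0: float = 1.25663706212e-6     # N A-2
    hbar: float = 1.054571817e-34     # J s
    r_ch: float = 1.106e-10           # m
    r_hh: float = 1.813e-10           # m

    def with_overrides(self, **kwargs: float) -> "Constants":
        return replace(self, **kwargs)


#: default constants instance shared across modules
CONSTANTS = Constants()


class Coherence(Enum):
    """Methyl coherences analysed in the Hahn-echo experiments.

    The value is the signed ¹H frequency coefficient ``n_H``: the
    coherence evolves at ``ωC + n_H·ωH`` (``SQ_H`` carries no ¹³C term).
    """

    ZQ = -1
    DQ = 1
    DQprime = -3
    QQ = 3
    SQ_H = 1  # distinct member despite sharing n_H with DQ

    def __new__(cls, n_h: int):
        obj = object.__new__(cls)
        # Enum disallows duplicate values; store n_H separately
        obj._value_ = len(cls.__members__)
        obj.n_h = n_h
        return obj

    @property
    def has_carbon(self) -> bool:
        return self is not Coherence.SQ_H


#: the four multiple-quantum coherences of the Hahn-echo analysis
MQ_COHERENCES = (Coherence.ZQ, Coherence.DQ, Coherence.DQprime, Coherence.QQ)


def parse_coherence(name: str) -> Coherence:
    key = name.strip().replace("'", "prime").replace("′", "prime")
    aliases = {"ZQ": "ZQ", "DQ": "DQ", "DQPRIME": "DQprime", "DQP": "DQprime",
               "QQ": "QQ", "SQ_H": "SQ_H", "SQH": "SQ_H", "HSQ": "SQ_H"}
    try:
        return Coherence[aliases[key.upper()]]
    except KeyError:
        valid = ", ".join(m.name for m in Coherence)
        raise ValueError(f"unknown coherence {name!r}; valid: {valid}") from None


@dataclass(frozen=True)
class FieldSpec:
    """Static magnetic field, specified by the ¹H Larmor frequency in MHz."""

    larmor_h: float  # MHz
    constants: Constants = field(default=CONSTANTS, compare=False)

    def __post_init__(self) -> None:
        if self.larmor_h <= 0:
            raise ValueError("larmor_h must be positive (MHz)")

    @property
    def b0(self) -> float:
        """Static field strength in tesla."""
        return 2.0 * math.pi * self.larmor_h * 1e6 / self.constants.gamma_h


@dataclass(frozen=True)
class ExternalSpin:
    """An external proton or deuteron dipolar-coupled to the methyl group.

    ``b_c``/``b_h`` are the dipolar couplings (rad s⁻¹) to the methyl ¹³C
    and ¹H spins; signs carry the P₂ geometry factor.
    """

    kind: str           # "proton" | "deuteron"
    b_c: float
    b_h: float

    def __post_init__(self) -> None:
        if self.kind not in ("proton", "deuteron"):
            raise ValueError("kind must be 'proton' or 'deuteron'")
        if not (math.isfinite(self.b_c) and math.isfinite(self.b_h)):
            raise ValueError("dipolar couplings must be finite")


def p2(x: float) -> float:
    """Second Legendre polynomial P₂(x) = (3x² − 1)/2."""
    return 0.5 * (3.0 * x * x - 1.0)


def dipolar_coupling(gamma_a: float, gamma_b: float, r_ab: float,
                     theta_b: float = 0.0,
                     constants: Constants = CONSTANTS) -> float:
    """Dipolar coupling b_AB = (μ0 ħ γA γB / 4π r³)·P₂(cos θ_B) in rad s⁻¹."""
    if r_ab <= 0:
        raise ValueError("r_ab must be positive")
    pref = constants.mu0 * constants.hbar * gamma_a * gamma_b / (
        4.0 * math.pi * r_ab ** 3)
    return pref * p2(math.cos(theta_b))


def coherence_delta_omega(coherence: Coherence, ddelta_c: float,
                          ddelta_h: float, fieldspec: FieldSpec) -> float:
    """Angular frequency difference of a coherence between exchange states.

    Parameters are the per-nucleus chemical shift differences ΔδC, ΔδH in
    ppm. Returns γC·B0·ΔδC·1e-6 + n_H·γH·B0·ΔδH·1e-6 (the ¹³C term is
    absent for ``SQ_H``).
    """
    if not isinstance(coherence, Coherence):
        raise TypeError(f"expected Coherence, got {coherence!r}")
    c = fieldspec.constants
    b0 = fieldspec.b0
    dw = coherence.n_h * c.gamma_h * b0 * ddelta_h * 1e-6
    if coherence.has_carbon:
        dw += c.gamma_c * b0 * ddelta_c * 1e-6
    return dw
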