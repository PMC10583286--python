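import numpy as np
import pytest

from methylmq.constants import CONSTANTS, Coherence, FieldSpec, MQ_COHERENCES
from methylmq.he_analysis import RateMeasurement
from methylmq.rates import MethylSystem, XiPair, csa_contribution, \
    exchange_contribution_fast


@pytest.fixture
def fields():
    """The four-spectrometer study design (¹H Larmor frequencies, MHz)."""
    return [FieldSpec(f) for f in (600.0, 700.0, 800.0, 950.0)]


@pytest.fixture
def field_800():
    return FieldSpec(800.0)


def forward_rates(system: MethylSystem, xi: XiPair, r20: dict,
                  fields, err: float = 0.1, rng=None, noise: float = 0.0):
    """Noiseless (or rate-noised) fast-limit HE rates for all coherences."""
    out = {}
    for coh in MQ_COHERENCES:
        ms = []
        for fs in fields:
            rate = (r20[coh.name] + csa_contribution(coh, system, fs)
                    + exchange_contribution_fast(coh, xi, fs))
            if noise and rng is not None:
                rate += rng.normal(0.0, noise * rate)
            ms.append(RateMeasurement("m", coh, fs, rate,
                                      max(err, noise * rate) if noise
                                      else err))
        out[coh] = ms
    return out
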