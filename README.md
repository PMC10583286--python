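# methylmq

Analysis of chemical exchange in ¹³CH₃-labelled methyl groups from
**multiple-quantum Hahn-echo relaxation** and **CPMG relaxation
dispersion** measurements.

Transverse relaxation of methyl zero-quantum (ZQ), double-quantum (DQ),
four-spin double-quantum (DQ′) and quadruple-quantum (QQ) coherences is
exquisitely sensitive to microsecond–millisecond conformational exchange.
These coherences are protected against intra-methyl dipolar relaxation in
perdeuterated proteins, yet their exchange broadening scales with the
square of an effective frequency difference ΔωC + n·ΔωH (n = −1, +1, −3,
+3), making the four-spin transitions up to nine-fold more sensitive to
¹H chemical shift differences than conventional methyl-TROSY coherences.
`methylmq` implements the relaxation theory and the complete data-analysis
pipeline for such experiments, for NMR spectroscopists studying sparsely
populated protein states.

## The model

For a two-site exchange process A ⇌ B (minor population p_B, exchange
rate k_ex, shift differences ΔδC, ΔδH), the observed Hahn-echo rate of
coherence n at static field B0 decomposes as

    R2,obs = R2,0 (dipolar, field-independent)
           + (4/45)(γC·ΔσC + n·γH·ΔσH)²·B0²·S²axis·τc   (CSA)
           + Rex(B0)                                     (exchange)

with the exchange term given in general by the dominant eigenvalue of the
two-site Bloch–McConnell evolution matrix,

    Rex = Re{ ½[k_ex + iΔω − √((k_ex + iΔω)² − 4i·k_ex·p_B·Δω)] },

which reduces to (ξC + n·ξH)²·B0² in fast exchange, where
ξX = √(pA·pB/k_ex)·γX·ΔδX are shift differences normalised by the
exchange parameters. The pipeline:

1. **Decay fitting** — exponential fits of peak amplitudes per coherence
   and field (`he_analysis.fit_decay`).
2. **Field regression** — weighted straight-line fits of R2,obs vs B0²
   (`regress_field`), CSA subtraction (`subtract_csa`), and the
   (ξH, ξC)-space constraint analysis: each coherence restrains the pair
   to the line pair ξC + n·ξH = ±√β_ex, and the four-line intersection
   plus χ² surface (`chi2_surface`) determines (ξH, ξC) up to a global
   sign — and diagnoses non-two-state behaviour when the lines fail to
   meet.
3. **CSA control measurements** — S²axis·τc and ΔσC from quartet
   lineshape fitting of relaxation-weighted ¹H-coupled HSQC pseudo-3D
   data (`csa_fit.fit_quartet_cluster`), ΔσH from IPAP spin-state-
   selective relaxation (`csa_fit.ipap_h_csa`).
4. **Joint fitting** — a global Levenberg–Marquardt fit of Hahn-echo
   rates (all four coherences, all fields) together with MQ and ¹H SQ
   CPMG dispersions, sharing (p_B, k_ex) across a residue cluster
   (`jointfit.global_fit`). CPMG profiles are computed by numerical
   propagation through ideal [τ−π−τ] echo trains; an exact analytical
   two-state dispersion is included as an independent cross-check.

A synthetic-data generator (`methylmq.synth`) produces every input the
pipeline consumes with known ground truth and seeded noise.

## Worked example

Exchange broadening of the four coherences for a slow-ish process
(p_B = 0.029, k_ex = 872 s⁻¹, ΔδC = 1.0 ppm, ΔδH = 0.12 ppm):

```python
from methylmq import TwoStateExchange, FieldSpec, Coherence, rex_closed_form

model = TwoStateExchange(p_b=0.029, k_ex=872.0, ddelta_c=1.0, ddelta_h=0.12)
for f in (600.0, 950.0):
    fs = FieldSpec(f)
    for coh in (Coherence.ZQ, Coherence.DQ, Coherence.DQprime, Coherence.QQ):
        dw = model.delta_omega(coh, fs)
        print(f"{f:5.0f} MHz  {coh.name:8s} dw = {dw:8.1f} rad/s"
              f"   Rex = {rex_closed_form(dw, model):6.2f} 1/s")
```

```
  600 MHz  ZQ       dw =    495.8 rad/s   Rex =   6.17 1/s
  600 MHz  DQ       dw =   1400.5 rad/s   Rex =  18.51 1/s
  600 MHz  DQprime  dw =   -409.0 rad/s   Rex =   4.53 1/s
  600 MHz  QQ       dw =   2305.3 rad/s   Rex =  22.32 1/s
  950 MHz  ZQ       dw =    784.9 rad/s   Rex =  11.47 1/s
  950 MHz  DQ       dw =   2217.5 rad/s   Rex =  22.11 1/s
  950 MHz  DQprime  dw =   -647.6 rad/s   Rex =   9.06 1/s
  950 MHz  QQ       dw =   3650.1 rad/s   Rex =  24.03 1/s
```

The four coherences respond very differently to the same process — the
information the field-dependence analysis exploits.

A full synthetic round trip from the shell (2 % amplitude noise):

```bash
methylmq simulate  --preset slow-cluster --seed 1 --out demo/sim
methylmq fit-decay --decays demo/sim/he_decays.csv --out demo/rates
methylmq fit-he    --rates demo/rates/rates.csv --csa demo/sim/csa.csv --out demo/he
methylmq jointfit  --rates demo/rates/rates.csv --cpmg demo/sim/cpmg.csv \
                   --clusters demo/sim/clusters.csv --csa demo/sim/csa.csv \
                   --out demo/jf --n-starts 4
```

The joint fit prints `joint fit chi2=188.298 (reduced 1.046)` and
recovers the generating parameters within error:

```
pB_slow        0.0296 +/- 0.0014      (truth 0.029)
kex_slow     907.0572 +/- 39.4454     (truth 872)
ddC_I1         0.9485 +/- 0.0549      (truth 1.0)
ddH_I1         0.1182 +/- 0.0035      (truth 0.12)
```

The back-calculated normalised shifts (ξH ≈ 0.178, ξC ≈ 0.359 per tesla,
`demo/jf/jointfit_xi.csv`) agree with the manifest truth (0.182, 0.382)
— whereas the fast-exchange-only `fit-he` stage underestimates them for
this k_ex, which is precisely why Hahn-echo and CPMG data are fitted
jointly.

## Layout

| module | contents |
| --- | --- |
| `methylmq.constants` | constants, coherence algebra, dipolar couplings |
| `methylmq.rates` | dipolar / CSA / exchange rate calculators, ξ algebra |
| `methylmq.exchange` | two-state engine: closed form, eigenvalue, CPMG trains |
| `methylmq.he_analysis` | decay fits, field regression, ξ constraints, χ² maps |
| `methylmq.csa_fit` | η rates, quartet lineshapes, cluster fits, IPAP |
| `methylmq.jointfit` | global HE + CPMG fitting and ξ back-calculation |
| `methylmq.synth` | synthetic-data generator with ground-truth manifests |
| `methylmq.io`, `methylmq.cli` | file formats, config, `methylmq` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
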