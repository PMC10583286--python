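# Methods

This note records the models implemented in `methylmq`, their
assumptions, the defaults that matter, and the numerical choices made
where the design was genuinely open.

## Spin system and rate expressions

A ¹³CH₃ methyl group is treated in the macromolecular limit with rapid
rotation about its three-fold symmetry axis. The package works with the
four slowly relaxing multiple-quantum coherences — ZQ, DQ, DQ′ and QQ —
labelled by their signed ¹H frequency coefficient n ∈ {−1, +1, −3, +3}
(the ¹³C coefficient is 1), plus the ¹H single-quantum coherence used in
SQ CPMG experiments.

Each observed transverse rate is the sum of three contributions:

* **Dipolar.** Intra-methyl dipolar relaxation of these four coherences
  vanishes; what remains are interactions with external protons and
  deuterons, entered as per-spin couplings b_C, b_H (rad s⁻¹, carrying
  the P₂(cos θ) geometry factor) with fixed per-coherence coefficient
  triples for (b_C², b_H², b_C·b_H), multiplied by τc. The proton
  coefficients are {1/5, 11/20, ±2/5} for ZQ/DQ and {1/5, 39/20, ±6/5}
  for DQ′/QQ; deuteron coefficients {8/15, 8/15, ±16/15} and
  {8/15, 24/5, ±16/5}. These coefficients are adopted as printed in the
  source theory; no independent re-derivation of the spin-1 factors is
  attempted here.
* **CSA.** (4/45)(γC·ΔσC + n·γH·ΔσH)²·B0²·S²axis·τc, with both CSAs in
  ppm. Scales exactly as B0².
* **Exchange.** In fast exchange, (ξC + n·ξH)²·B0² with
  ξX = √(pA·pB/k_ex)·γX·ΔδX·10⁻⁶ per tesla. This unit convention is
  fixed so that ξ²·B0² is in s⁻¹ directly. In general, the exchange
  broadening is the real part of the slow eigenvalue of the two-site
  evolution matrix (below).

MQ sum/difference combinations follow R_MQ = (R_ZQ + R_DQ)/2 and
ΔR_MQ = (R_ZQ − R_DQ)/2. With exchange-only inputs this yields
ΔR_MQ,ex = −2ξCξH·B0² under this sign convention; the sign of ΔR_MQ,ex
is convention-dependent in the literature and only the ZQ/DQ rates
themselves are treated as primary.

## Two-state exchange engine

The closed-form Hahn-echo broadening,
Rex = Re{½[k_ex + iΔω − √((k_ex + iΔω)² − 4i·k_ex·p_B·Δω)]} (principal
branch), is checked at run time against a direct numerical
eigendecomposition of the 2×2 evolution matrix
[[−k_AB, k_BA], [k_AB, −k_BA + iΔω]]; the two routes agree to better
than 10⁻⁸ relative over wide parameter ranges. Limits: Δω → 0 gives 0;
k_ex ≫ Δω gives pA·pB·Δω²/k_ex; Δω ≫ k_ex gives lifetime broadening
k_AB = p_B·k_ex.

**CPMG timing convention.** ν_CPMG = 1/(4τ): a constant-time period T
holds N = 2·ν·T ideal π pulses at spacing 2τ = 1/(2ν), i.e. the element
[τ−π−τ] repeated N times. ν values must make N an integer (and even for
MQ experiments, so the detected pathway returns to its starting
coherence). Propagation is piecewise: free-evolution propagators are 2×2
matrix exponentials per exchange-site block (closed-form
eigendecomposition), π pulses are exact permutations — ¹³C π exchanges
ZQ± ↔ DQ∓, ¹H π conjugates the SQ coherence. The initial state carries
populations (pA, pB) on the starting coherence (DQ by default; a config
flag selects ZQ or the average — the choice differs only through
finite-train ordering effects that vanish by ~1 kHz), and
R_eff = −ln(|S(T)|/|S(0)|)/T plus the baseline rate. Off-resonance
effects and pulse imperfections are deliberately not modelled.

For ¹H SQ experiments an **exact analytical dispersion** is also
implemented: scalar hyperbolic expressions for the free-evolution
propagator combined with the analytic eigen-projection of one two-echo
cycle, valid for any even pulse count. It reduces to the classic
many-pulse (Carver–Richards-type) expression asymptotically and differs
from it by up to ~0.1 s⁻¹ at the lowest pulse rates, where finite-train
endpoint terms matter. The numerical propagation agrees with it to
~10⁻¹² s⁻¹; the two routes share only the timing convention.

## Hahn-echo field-dependence analysis

Decay curves are fitted as A·exp(−R·T) by weighted least squares with
the supplied amplitude noise (absolute-σ covariance). Rates at ≥3 fields
(the study design uses 600/700/800/950 MHz) are fitted by
inverse-variance-weighted linear regression against B0²; the CSA slope
computed from (S²axis·τc, ΔσC, ΔσH) is subtracted to leave the exchange
slope β_ex, with first-order error propagation from the regression and
the CSA inputs. A β_ex more than 2σ below zero is flagged as "no
detectable exchange / CSA overestimate" rather than clipped.

Each coherence then restrains (ξH, ξC) to the line pair
ξC + n·ξH = ±√β_ex. The χ²(ξH, ξC) surface is evaluated on a grid, with
the per-coherence intercepts R2,0 profiled out in closed form (weighted
mean of rate − slope·B0²); this is exact, so the surface at each node is
a quadratic form in the model slope. Negative measured slopes need no
special handling — the model slope is bounded below by the CSA term, so
they simply raise the χ² floor. The default grid is symmetric, spanning
±1.5× the largest |√β_ex| with 301 points per axis (configurable).
Confidence contours use two-parameter Δχ² thresholds 2.30 (68 %) and
6.18 (95 %); the threshold convention is a documented choice. The
surface is exactly symmetric under (ξH, ξC) → (−ξH, −ξC) — the global
sign is not determined by these data — and with only ZQ and DQ it is
also symmetric under ξH ↔ ξC, a degeneracy the four-spin coherences
break. For data inconsistent with a single two-state process the four
lines fail to meet and the χ² minimum rises above zero, which is the
intended diagnostic.

## CSA and order-parameter measurements

Cross-correlated rates are evaluated from their standard expressions
with prefactors 9/40 (H–H auto), 1/5 (H–H/C–H cross), 2/45 (C–H auto)
and 4/45 (CSA–dipole); the CSA–dipole rates scale linearly with B0,
the dipole–dipole rates do not. The ¹³C quartet of a
relaxation-weighted ¹H-coupled HSQC is modelled as four Lorentzian
lines at ω0,C ± πJ, ±3πJ with intensities I_outer = 3 + 3Δ,
I_inner = 3 − Δ, Δ = exp(−4η_HHHH·τ)·cosh(2η_HHHC·τ), τ = 1/(2J), and
spin-state-specific decays R = R2,C ± {1,3}·η_CHCH ± {1,3}·η_CHC during
the relaxation period. The Lorentzian convention is
L(ω; ω0, R) = R/(R² + (ω−ω0)²) (normalisation absorbed into the
amplitude). S²axis·τc is encoded in the inner/outer intensity pattern
and ΔσC in the up-/down-field decay asymmetry
(ratio exp(−6·η_CHC·T) for the outer lines).

Peaks are grouped into clusters by single-linkage within
0.05 ppm (¹H) × 2.4 ppm (¹³C) strips and each cluster is fitted jointly
over all delays (Levenberg–Marquardt) for per-peak amplitude, positions
(narrow windows around reference-spectrum values), line rates,
J ∈ [100, 150] Hz initialised at 125 Hz, S²axis·τc and ΔσC. Amplitude
starts are inverted from the tallest grid point via the peak-height
relation amp·6/(R2C·R2H). Fits that stop on a bound or fail to converge
are flagged per peak. ¹H-dimension processing effects are not modelled;
synthetic spectra come from the same forward model, so lineshape tests
probe self-consistency of the analysis, not robustness to processing
artefacts.

The ¹H CSA follows from IPAP spin-state-selective rates:
ηH = (Rα − Rβ)/2 inverted through the CSA–dipole expression with a known
S²axis·τc; errors propagate from both rate fits and the S²axis·τc
uncertainty. Swapping the α/β assignment flips the sign.

**CSA impact diagnostic.** To judge whether residue-type average CSAs
suffice, the package defines impact_X = Σ_coh |β_CSA − β_CSA(Δσ_X→0)| /
Σ_coh β_ex over the four coherences in the fast limit (B0-independent).
For a representative case (ΔδC = 1.5 ppm, ΔδH = 0.2 ppm, p_B = 0.1,
k_ex = 5000 s⁻¹, S²τc = 50 ns, valine-average CSAs 34.2/0.29 ppm) this
gives ≈5 % for ¹³C and ≈0.7 % for ¹H: the ¹³C CSA must not be neglected,
but using average values contributes only of order one percent
uncertainty.

## Joint Hahn-echo + CPMG fitting

Residues assigned to one cluster share (p_B, k_ex); each methyl carries
(ΔδC ≥ 0 by sign convention, ΔδH free sign). Baselines: one
field-independent R2,0 per (methyl, HE coherence) — dipolar relaxation
does not depend on B0 — and one baseline per (methyl, experiment kind,
field) for CPMG, since constant-time baselines are not comparable across
experiment types; sharing choices are configurable. CSA parameters are
fixed inputs (measured or residue means), never co-fitted, since
separate experiments determine them. HE predictions use the
eigenvalue-exact exchange broadening, so the fast-exchange assumption of
the ξ analysis is dropped at this stage; CPMG predictions use the
numerical echo-train propagation.

All residuals are weighted by their standard errors and minimised with
Levenberg–Marquardt from multiple starts (default 8, log-spaced over
k_ex ∈ [10², 10⁵] s⁻¹ and p_B ∈ [0.005, 0.2]); the best-χ² solution is
kept and all starts are logged. Uncertainties come from the χ² curvature
(inverse-Hessian covariance); parameter pairs with |correlation| > 0.95
are flagged — in fast exchange p_B and Δδ² are intrinsically correlated
and HE-only fits are ridge-degenerate, which the CPMG data resolve.
ξ values back-calculated from the fit land inside the HE-only
confidence region on synthetic data, closing the loop between the two
analyses. Combined shift magnitudes are reported as
Δδ_CH = √((ΔδC/4)² + ΔδH²).

## Synthetic data

The generator emulates the study design: HE decays at 600/700/800/950
MHz with the per-field delay lists of the real experiments
(0.1–60 ms), CPMG with a 40 ms constant-time period and 28 frequencies
from 25 Hz to 2 kHz (all multiples of 25 Hz, keeping pulse counts even),
MQ CPMG at 800/950 MHz and ¹H SQ at 800 MHz. Noise is additive Gaussian
on amplitudes/intensities — never on rates — so rate errors emerge from
fitting exactly as in the real measurement chain; CPMG rate errors are
propagated from the intensity noise through the −ln(I/I0)/T conversion.
Defaults: 2 % amplitude noise on HE decays, 0.005 absolute on
unit-normalised CPMG intensities. Two presets mirror the studied
regimes: a "slow-cluster" (p_B = 0.029, k_ex = 872 s⁻¹, ΔδC = 1.0 ppm,
ΔδH = 0.12 ppm) and a "fast-cluster" (k_ex = 6900 s⁻¹, p_B = 0.05,
ΔδC = 1.5 ppm, ΔδH = 0.2 ppm); the fast-cluster minor population is a
package choice of a realistic fast-exchange value, and shift differences
are chosen at magnitudes typical of methyl probes of partial unfolding.
Generation is bit-reproducible for a given seed, and every dataset ships
with a JSON manifest of the ground truth.

What the generator does **not** emulate: FID-level processing (window
functions, linear prediction), pulse imperfections and off-resonance
effects, spectrometer artefacts, three-state exchange (except as
deliberately inconsistent test inputs). Passing tests therefore
demonstrate correctness of the theory and estimators under the stated
noise model, not robustness to raw-data pathologies.

## Problem sizes and numerical choices

Calibration tests use Monte-Carlo sizes chosen for tight yet fast
checks: 1000 replicates for decay-fit coverage, 200 for χ²-contour
coverage, 100 single-methyl replicates (9-point CPMG grids, single
optimiser start) for joint-fit interval coverage; the acceptance script
uses 60. Joint-fit tests use 12-point CPMG grids; user-facing defaults
remain the full 28-point design. Eigen-degenerate matrix exponentials
fall back to a first-order expansion; CPMG signals are floored at
10⁻³⁰⁰ before taking logarithms; χ² surfaces may dip a few parts in
10¹⁰ below zero through floating-point cancellation and are reported
as computed.

## Known limitations

* Absolute signs of (ΔδC, ΔδH) are undetermined by these data; results
  are reported with ΔδC ≥ 0 by convention.
* The intercepts of the field regression (zero-field rates) are not yet
  used as exchange-free restraints.
* Only two-state exchange is fitted; multi-state behaviour is detected
  (non-intersecting constraint lines) but not modelled.
* The quartet model assumes uniform ¹J_CH within [100, 150] Hz and a
  single ¹H Lorentzian per methyl.
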