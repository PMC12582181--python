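# Methods

This note records the scientific conventions, default parameters and design
choices behind `pritdose`, and what the synthetic-data generator does and
does not emulate.

## Decay chain and energy per decay

The ²²⁵Ac series is modelled as an ordered chain with one branch point:
Ac-225 → Fr-221 → At-217 → Bi-213, which decays 97.8% by β to the α emitter
Po-213 and 2.2% by α to Tl-209, both converging on Pb-209 → Bi-209
(effectively stable). Intensity-weighted mean α energies (MeV) compiled
from the NNDC/ENSDF decay data sheets are stored in
`src/pritdose/data/ac225_chain.json`: 5.79 (Ac-225), 6.31 (Fr-221), 7.07
(At-217), 5.86 (Bi-213 α branch), 8.376 (Po-213). The branching-weighted
total is **27.49 MeV per parent decay**; published compilations vary by a
few tenths of an MeV depending on which minor lines are included, so the
shipped constant is documented to ±1%.

Two assumptions make chain dosimetry tractable:

1. **Local absorption.** All progeny decay where the parent decayed, so
   chain α energy is credited to the parent's location. The longest-lived
   α-relevant daughter (Bi-213, 45.6 min) is short against the multi-day
   biodistribution timescale. No daughter-migration model is included; in
   reality some Fr-221/Bi-213 can redistribute (notably to kidney), which
   this package deliberately does not model.
2. **α-only dose.** β and γ emissions are excluded; for ²²⁵Ac chains the α
   component dominates the absorbed dose at the source site and the
   high-LET component is what the RBE weighting addresses.

## Decay-correction convention

Whether %IA/g values are decay-corrected to injection time is an
acquisition convention that the data themselves cannot reveal, so every
sample carries a mandatory `decay_corrected` flag. Integration always runs
on the *physical* (decay-inclusive) curve; decay-corrected input must pass
through `undecay_correct`, which multiplies by `exp(-λt)` and re-flags the
curve. This makes the convention explicit and testable instead of silent.

## Time-integrated activity

The TIA integral has three pieces, each a deliberate convention:

- **Lead-in** (0 → first sample): the first observed value held constant.
  Blood activity is maximal immediately post-injection, so assuming zero
  at t=0 would underestimate dose; for a 2-h first sample the bias either
  way is small and the constant hold is the conservative choice.
- **Observed span**: trapezoid over the samples (`numpy.trapezoid`).
- **Tail** (beyond the last sample): default `physical-decay` contributes
  `A_last/λ`, i.e. no biological clearance after the last sample —
  conservative for dose. `fitted-monoexponential` fits the last ≥2 points
  log-linearly for an effective rate `λ_eff ≥ λ` and contributes
  `A_last/λ_eff`; a fitted rate slower than physical decay is unphysical
  (it implies a rising decay-corrected tail) and falls back to
  physical-decay with a warning. `none` contributes 0 and necessarily
  undershoots whenever sampling does not span many half-lives.

The tail conventions are this package's own; they are reported alongside
every result (`tail_model`, `tail_fraction`).

## Dose coefficients

Because uptake is per gram of tissue, organ masses cancel and dose follows
directly from concentration:

```
Gy/kBq = TIA [%IA·h/g] × 10 [Bq·h/g per %IA·h/g of 1 kBq] × 3600 [s/h]
         × E_α [MeV] × 1.602176634e-13 [J/MeV] × 1000 [g/kg] × RBE
```

Each coefficient carries this unit chain as an `audit` tuple. RBE defaults
to 5 for α radiation. Cycle doses add with no repair or fractionation
correction. Therapeutic indices are reported at full precision — quotients
of independently rounded tabulated coefficients can differ from a source
table's TI in the second digit, and the package does not force such
rounding. Extrapolation between administered-mass regimens scales a
reference coefficient by the ratio of 24-h uptakes, which assumes the
time–activity curve *shape* is unchanged (clearance kinetics unaffected by
receptor saturation); it is exact only to the extent that assumption holds
and is flagged `derivation="extrapolated"`.

## Saturation and internalization

Tumor capture is modelled as single-site Langmuir binding with the
administered hapten amount as the free-ligand proxy:
`u(m) = 100·B_max/(K_m + m)` %IA/g. Two observations admit an exact
algebraic solution; more are fitted by least squares in log-uptake
(multiplicative errors). The two default anchors (0.60 nmol → 10.48 %IA/g;
26.9 nmol → 0.38 %IA/g) give `B_max ≈ 0.1037 nmol/g`, `K_m ≈ 0.389 nmol`.
Single-site binding is the minimal model reproducing both regimens; it
ignores BsAb cross-linking and in-vivo hapten clearance competing with
capture.

Internalized fraction uses total = membrane + internalized (the assay's
"of total cell-bound" convention); points with zero total are flagged NaN,
not zero. The AUC-weighted overall percentage is a trapezoid ratio over the
observed span only, with no extrapolation beyond 24 h.

## Therapy endpoints and survival statistics

- **Complete response**: final recorded volume ≤ 4.2 mm³ (inclusive).
  Judging the final measurement rather than the any-time minimum prevents
  a dip-and-regrow trajectory from counting as a response.
- **Endpoint time**: first day the volume doubles baseline (or the
  diameter reaches 10 mm), linearly interpolated between the bracketing
  twice-weekly measurements (interpolation is the default; the
  first-day-past-threshold rule is available). Animals that die of other
  causes are events at the death day; animals never reaching the endpoint
  are censored at last observation.
- **Kaplan–Meier / log-rank**: implemented natively (product-limit
  estimator; Mantel–Cox statistic from per-event-time 2×2 tables with
  hypergeometric variance, referred to χ² with 1 df) and cross-checked
  against `lifelines` in the test suite. Censoring tied with an event time
  is at risk for that event. Median survival is the smallest time with
  S(t) ≤ 0.5, reported as ">last follow-up" when never reached. p-values
  display to 4 decimals; no multiple-testing correction is applied.

## Synthetic-data generator

The generator's defaults define the emulated study conditions; they are
calibrated once, as follows, and are not per-test knobs.

**Time–activity curves.** `A(t) = S·(e^(−k_c t) − e^(−k_u t))·e^(−λt)`,
sampled at {2, 24, 72, 192, 240} h, scaled so the 24-h physical value
matches the arm's anchor (the saturation model for tumor; fixed anchors
for blood 0.68/0.03 and kidney 0.63/0.47 %IA/g). Default rates (per hour):

| tissue | k_u   | k_c     | rationale |
|--------|-------|---------|-----------|
| tumor  | 0.025 | 0.00036 | slow continued accretion, near-irreversible capture; with the 24-h anchor this reproduces a 5.670 Gy/kBq pipeline coefficient |
| kidney | 0.5   | 0.005   | fast renal uptake, ~6-d biological clearance; reproduces ~0.095 Gy/kBq |
| blood  | 2.0   | 0.06    | rapid clearing-agent-sharpened blood clearance |

Tumor and kidney rates were solved against two printed anchors each (the
24-h uptake and the regimen's dose coefficient), so the generator's curves
carry the study's dosimetric content, not just its 24-h snapshot. The true
curve shapes of the underlying study are not public; this anchoring is
approximate by construction. Blood clears too fast for the 5-point
schedule to integrate accurately (trapezoid over a steep exponential
overestimates by ~30%); recovering the blood coefficient requires a denser
early grid, which the tests demonstrate. The 2% parameter-recovery claim
therefore applies to tumor and kidney, whose kinetics the default schedule
resolves.

**Noise.** Multiplicative lognormal, mean-preserving
(`σ² = ln(1+CV²)`, `μ = −σ²/2`), CV 0.30 and n = 5 per time point by
default — matching the observed scatter (SD/mean ≈ 3.66/10.48). Lognormal
rather than Gaussian keeps %IA/g positive at ~50% CVs.

**Internalization.** Total bound
`T(t) = A(1−e^(−k_b t))e^(−k_off t)` with k_b = 4/h (binding complete
within the first hour) and A, k_off solved from the bound anchors (19.02%
at 1 h, 16.41% at 24 h per 10⁶ cells). The internalized share
`f(t) = a(1−e^(−k_i t))` has a and k_i solved exactly from the 9% (1 h)
and 28% (24 h) anchors, giving k_i ≈ 0.388/h. With the default sampling
times (0–24 h) the AUC-weighted overall internalized percentage is ~24.7%;
an assay with denser early sampling or a more gradual fraction rise would
give lower values, so this figure characterizes the two-pool emulation,
not the original assay.

**Therapy cohorts.** Per animal: baseline volume lognormal around 100 mm³
(CV 0.20), growth rate lognormal around ln2/25 d⁻¹ (CV 0.15) so the median
control time-to-doubling is ≈25 d; treatment multiplies the growing clone
by the single-hit survival fraction `e^(−dose/D0)` with D0 = 20 Gy
(RBE-weighted) while the sterilized bulk resorbs with a 7-d half-time;
caliper noise is lognormal at CV 0.05 — kept small because upward noise
spikes trigger threshold crossings early and would bias the observed
median doubling time downward. The single-hit form (no linear-quadratic
term) is the classical α-kill model; D0 here is a tissue-level shape
parameter chosen so a ~210-Gy arm is curative, not a cell-survival
constant. The generator does not emulate immune-mediated growth delay,
histopathology, hematology, or inter-model radiosensitivity differences —
so passing tests demonstrate internal consistency of the pipeline under
the stated model, not fidelity to any particular animal study beyond the
anchors listed above.

## Numerical choices and degenerate inputs

- Internal time unit is hours; half-lives accept d/h/min/s with explicit
  tags and convert exactly (round-trip to 1e-12).
- Two-point saturation calibration refuses non-positive algebraic
  solutions (rising uptake with mass) rather than returning an invalid
  model; >2-point fits start from the widest-separated pair.
- CSV round-trips are bit-exact (`repr` on write,
  `float_precision="round_trip"` on read).
- Log-rank with no events in either group returns NaN (flagged undefined)
  rather than raising.
- Display rounding (2–3 significant figures for doses, 3 decimals for
  coefficients, 1 decimal for ratios) is presentation-layer only; all
  arithmetic is double precision.

## Problem sizes

Default analyses integrate 5-point curves for 3 tissues, simulate 10
animals per therapy group over 140 d at twice-weekly measurements, and the
noisy parameter-recovery check uses 200 replicate studies at n = 5 — sizes
chosen to mirror the emulated study design while keeping the full suite
fast on a laptop.

## Known limitations

- No organ-mass dosimetry, S values, microdosimetry or photon cross-dose;
  concentration-based murine dosimetry only.
- No daughter redistribution; kidney dose from released Bi-213 is ignored.
- The 24-h extrapolation between regimens cannot capture saturation-driven
  changes in curve shape; for tumor (where saturation is strong) scaling
  the 24-h %IA/g and scaling absolute uptake give different answers, and
  both are exposed rather than adjudicated.
- Native survival statistics cover two-group comparison only; no Cox
  regression or competing risks.
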