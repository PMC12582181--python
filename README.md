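# pritdose

Biodistribution-driven α-particle dosimetry and survival analysis for
preclinical **pretargeted radioimmunotherapy (PRIT)** with actinium-225.

In 3-step PRIT, a bispecific antibody (anti-tumor × anti-DOTA-hapten) is
given first, a clearing agent removes the circulating antibody, and a small
radiolabelled DOTA-hapten is given last and captured at the tumor. With
²²⁵Ac — a 9.92-day α emitter whose chain releases ~27.5 MeV of α energy per
parent decay — this produces very high tumor-to-normal-tissue dose ratios.
`pritdose` implements the complete analysis such a study needs:

- **`nuclides`** — decay arithmetic and the ²²⁵Ac chain (Fr-221, At-217,
  the Bi-213/Po-213 branch) under the local-absorption assumption, with the
  nuclear constants in a versioned JSON data file.
- **`biodist`** — %IA/g biodistribution data model, CSV I/O, %IA/g → pmol/g
  conversion, tumor-to-normal uptake ratios.
- **`tia`** — time-integrated activity (TIA): trapezoidal integration of
  serial time–activity curves with explicit decay-correction handling,
  a conservative constant lead-in and a physical-decay (or fitted) tail.
- **`dosimetry`** — RBE-weighted dose coefficients (Gy/kBq), absorbed and
  cumulative doses, therapeutic indices, and 24-h-uptake extrapolation
  between administered-mass regimens.
- **`binding`** — Langmuir saturation of tumor capture vs administered
  hapten mass (B_max, K_m), and internalization-assay kinetics (per-time
  internalized fractions and AUC-weighted overall percentage).
- **`therapy`** — complete-response classification (volume ≤ 4.2 mm³),
  time-to-doubling / time-to-10-mm endpoints, and native Kaplan–Meier,
  median-survival and Mantel–Cox log-rank statistics.
- **`synthetic_data`** — a deterministic generator for every input the
  pipeline consumes (serial biodistribution, internalization series,
  therapy cohorts), calibrated to the study conditions.
- **`cli`** — a `pritdose` command with `simulate`, `biodist`, `dose`,
  `therapy` and `run` subcommands.

## The model

For a tissue with activity concentration $A(t)$ in %IA/g (physical,
decay-inclusive), the time-integrated activity per administered kBq is

$$\tilde A = \int_0^\infty A(t)\,dt \;\; [\%\mathrm{IA{\cdot}h/g}],$$

integrated by trapezoid over the samples with a physical-decay tail
$A_\mathrm{last}/\lambda$. The RBE-weighted dose coefficient is

$$D = \tilde A \times 10 \times 3600 \times E_\alpha \times 1.602\times10^{-13} \times 1000 \times \mathrm{RBE} \;\;[\mathrm{Gy/kBq}],$$

with $E_\alpha \approx 27.49$ MeV per ²²⁵Ac decay (all chain α energy
deposited locally) and RBE = 5. Tumor capture saturates with administered
hapten mass $m$ as $u(m) = 100\,B_\mathrm{max}/(K_m + m)$ %IA/g.

## Worked example

```bash
pritdose run --out demo --seed 1
cat demo/report.txt
```

```
pritdose pipeline report
package version: 0.1.0
config hash:     cb8b3c307f07deff   seed: 1
RBE: 5.0   alpha energy/decay: 27.49 MeV

24-h tumor_to_blood ratio (high_mass): 14.2
24-h tumor_to_kidney ratio (high_mass): 0.9
24-h tumor_to_blood ratio (low_mass): 12.8
24-h tumor_to_kidney ratio (low_mass): 14.8
dose coefficient blood: 0.051 Gy/kBq
dose coefficient kidney: 0.092 Gy/kBq
dose coefficient tumor: 6.023 Gy/kBq
kidney therapeutic index: 65.5
group control: n=10, median survival 25.9984 d, CR rate 0%
group prit_37kbq: n=10, median survival >140 d, CR rate 100%
log-rank control vs prit_37kbq: chi2=21.84, p=0.0000
```

The run simulates a two-arm biodistribution study (37 kBq/0.60 nmol vs
296 kBq/26.9 nmol) with lognormal measurement noise (CV 0.30, n = 5),
integrates the serial low-mass-arm curves to TIA, converts them to
RBE-weighted dose coefficients — the tumor coefficient of ~6 Gy/kBq means a
single 37-kBq cycle delivers ~210 Gy to tumor while the kidney receives
~3.5 Gy — and analyzes a simulated therapy study: untreated tumors double
in ~25 days, while the 210-Gy arm ends with every animal at or below the
4.2-mm³ complete-response threshold (log-rank p < 0.0001). The machine-
readable version of everything above is written to `demo/results.json`.

Noise-free values (`gen_biodist_study(..., noise_cv=0)`) reproduce the
calibration anchors exactly: tumor 5.672 and kidney 0.095 Gy/kBq.

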