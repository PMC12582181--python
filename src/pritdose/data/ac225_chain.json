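{
  "comment": [
    "Actinium-225 decay series under the local-absorption assumption:",
    "every daughter decays where the parent decayed, instantaneously on the",
    "dosimetric timescale, so branching-weighted mean alpha energies sum to",
    "the alpha energy released per parent decay (~27.5 MeV).",
    "Mean alpha energies are intensity-weighted means of the principal alpha",
    "lines compiled from the NNDC/ENSDF decay data sheets for the Ac-225",
    "series (A=225,221,217,213,209 chains); branching fractions likewise.",
    "Steps sharing a 'position' are alternative branches and their",
    "branching fractions sum to 1. Beta/gamma emissions carry no entry here:",
    "only alpha energy is counted for dose."
  ],
  "parent": {"name": "Ac-225", "half_life": 9.92, "half_life_unit": "d"},
  "steps": [
    {"position": 0, "nuclide": {"name": "Ac-225", "half_life": 9.92, "half_life_unit": "d"},
     "branching_fraction": 1.0, "mean_alpha_energy_mev": 5.79, "stable": false},
    {"position": 1, "nuclide": {"name": "Fr-221", "half_life": 4.9, "half_life_unit": "min"},
     "branching_fraction": 1.0, "mean_alpha_energy_mev": 6.31, "stable": false},
    {"position": 2, "nuclide": {"name": "At-217", "half_life": 0.0323, "half_life_unit": "s"},
     "branching_fraction": 1.0, "mean_alpha_energy_mev": 7.07, "stable": false},
    {"position": 3, "nuclide": {"name": "Bi-213", "half_life": 45.6, "half_life_unit": "min"},
     "branching_fraction": 0.022, "mean_alpha_energy_mev": 5.86, "stable": false,
     "note": "alpha branch to Tl-209"},
    {"position": 3, "nuclide": {"name": "Bi-213", "half_life": 45.6, "half_life_unit": "min"},
     "branching_fraction": 0.978, "mean_alpha_energy_mev": 0.0, "stable": false,
     "note": "beta branch to Po-213"},
    {"position": 4, "nuclide": {"name": "Tl-209", "half_life": 2.16, "half_life_unit": "min"},
     "branching_fraction": 0.022, "mean_alpha_energy_mev": 0.0, "stable": false},
    {"position": 4, "nuclide": {"name": "Po-213", "half_life": 4.2e-6, "half_life_unit": "s"},
     "branching_fraction": 0.978, "mean_alpha_energy_mev": 8.376, "stable": false},
    {"position": 5, "nuclide": {"name": "Pb-209", "half_life": 3.23, "half_life_unit": "h"},
     "branching_fraction": 1.0, "mean_alpha_energy_mev": 0.0, "stable": false},
    {"position": 6, "nuclide": {"name": "Bi-209", "half_life": 1.6e23, "half_life_unit": "d"},
     "branching_fraction": 1.0, "mean_alpha_energy_mev": 0.0, "stable": true,
     "note": "effectively stable terminator (half-life ~1.9e19 y)"}
  ]
}
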