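"""Synthetic-data generator for the whole PRIT analysis pipeline.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes, so all stages are testable without animal
data.  The generator emulates a 3-step pretargeting study in a
HER2-positive xenograft model:

* **Tissue time–activity curves** follow an uptake-and-clearance shape
  ``A(t) = S (exp(-k_c t) - exp(-k_u t)) exp(-lambda t)`` (physical decay
  included), scaled so the 24-h value matches the regimen's anchor: the
  calibrated saturation model for tumor, fixed per-arm anchors for blood and
  kidney.  Default kinetic rates are calibrated so the low-mass-arm tumor
  and kidney dose coefficients computed by the pipeline from the default
  sampling schedule reproduce the study-condition coefficients
  (5.670 and ~0.095 Gy/kBq).

* **Group biodistribution samples** carry multiplicative lognormal noise
  (mean-preserving) with CV matching the observed scatter (~0.30).

* **Internalization** uses a two-pool model: total bound rises quickly and
  is near-constant after 1 h; the internalized share follows
  ``f(t) = a (1 - exp(-k_i t))`` with ``a`` and ``k_i`` solved exactly from
  the two fraction anchors (9% at 1 h, 28% at 24 h).

* **Therapy cohorts** grow exponentially (control median time-to-doubling
  25 d); treatment multiplies the growing clone by a single-hit survival
  factor ``exp(-dose/D0)`` while the sterilized bulk resorbs exponentially.

All generators are pure functions of (config, seed): same seed, identical
output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

from .biodist import Administration, BiodistSample, write_biodist
from .binding import InternalizationSeries, SaturationModel, calibrate_saturation, predicted_uptake
from .nuclides import AC225, Nuclide, decay_factor
from .therapy import TumorSeries
from .tia import TimeActivityCurve

__all__ = [
    "ArmConfig",
    "TissueKinetics",
    "InternalizationConfig",
    "CohortConfig",
    "GeneratorConfig",
    "saturation_model",
    "anchor_24h",
    "tac_value",
    "gen_time_activity",
    "config_implied_tia",
    "gen_biodist_study",
    "gen_internalization",
    "gen_therapy_cohort",
    "write_fixture_dir",
]


@dataclass(frozen=True)
class ArmConfig:
    """One administration arm: activity and molar amount of the hapten injection."""

    activity_kbq: float
    amount_nmol: float

    def administration(self, label: str = "") -> Administration:
        return Administration(
            activity_kbq=self.activity_kbq, amount_nmol=self.amount_nmol, label=label
        )


@dataclass(frozen=True)
class TissueKinetics:
    """Uptake/clearance rates (per hour) of the biological curve component."""

    uptake_rate: float  # k_u, per h
    clearance_rate: float  # k_c, per h

    def __post_init__(self) -> None:
        if not (self.uptake_rate > self.clearance_rate > 0):
            raise ValueError("need uptake_rate > clearance_rate > 0")


@dataclass(frozen=True)
class InternalizationConfig:
    """Two-pool internalization parameters anchored on two observed fractions."""

    frac_t1: float = 0.09  # internalized share at t1
    t1_h: float = 1.0
    frac_t2: float = 0.28  # internalized share at t2
    t2_h: float = 24.0
    bound_t1: float = 19.02  # % added activity per 1e6 cells at t1
    bound_t2: float = 16.41  # at t2
    bind_rate: float = 4.0  # cell-binding on-rate, per h
    times_h: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0)


@dataclass(frozen=True)
class CohortConfig:
    """Tumor-growth and kill parameters for therapy cohorts."""

    n_per_group: int = 10
    doubling_time_d: float = 25.0  # median control time-to-doubling
    growth_cv: float = 0.15  # animal-to-animal spread of growth rate
    baseline_volume_mm3: float = 100.0
    baseline_cv: float = 0.20
    measurement_cv: float = 0.05  # caliper noise; kept small so noise-driven
    # early threshold crossings do not bias the observed median doubling time
    d0_gy: float = 20.0  # single-hit kill sensitivity (RBE-weighted Gy)
    resorption_halftime_d: float = 7.0
    measurement_interval_d: float = 3.5
    horizon_d: float = 140.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Full study configuration; defaults are the emulated study conditions."""

    seed: int = 1234
    arms: dict[str, ArmConfig] = field(
        default_factory=lambda: {
            "low_mass": ArmConfig(37.0, 0.60),
            "high_mass": ArmConfig(296.0, 26.9),
        }
    )
    # two-point calibration anchors: (administered nmol, 24-h tumor %IA/g)
    saturation_anchors: tuple[tuple[float, float], ...] = (
        (0.60, 10.48),
        (26.9, 0.38),
    )
    # fixed 24-h anchors for non-saturable tissues, per arm (%IA/g, physical)
    anchors_24h: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "blood": {"low_mass": 0.68, "high_mass": 0.03},
            "kidney": {"low_mass": 0.63, "high_mass": 0.47},
        }
    )
    kinetics: dict[str, TissueKinetics] = field(
        default_factory=lambda: {
            "tumor": TissueKinetics(0.025, 0.00036),
            "blood": TissueKinetics(2.0, 0.06),
            "kidney": TissueKinetics(0.5, 0.005),
        }
    )
    sample_times_h: tuple[float, ...] = (2.0, 24.0, 72.0, 192.0, 240.0)
    noise_cv: float = 0.30
    n_per_group: int = 5
    decay_corrected_output: bool = False
    internalization: InternalizationConfig = field(default_factory=InternalizationConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n per group must be >= 1")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["arms"] = {k: ArmConfig(**v) for k, v in raw.get("arms", {}).items()}
        raw["kinetics"] = {
            k: TissueKinetics(**v) for k, v in raw.get("kinetics", {}).items()
        }
        if "internalization" in raw:
            ic = raw["internalization"]
            ic["times_h"] = tuple(ic["times_h"])
            raw["internalization"] = InternalizationConfig(**ic)
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        raw["saturation_anchors"] = tuple(
            tuple(p) for p in raw.get("saturation_anchors", ())
        )
        raw["sample_times_h"] = tuple(raw.get("sample_times_h", ()))
        return cls(**raw)


def _rng(config: GeneratorConfig, *streams: str | int | float) -> np.random.Generator:
    """Deterministic per-stream generator derived from the config seed."""
    key = [config.seed & 0x7FFFFFFF]
    for s in streams:
        if isinstance(s, str):
            key.append(zlib.crc32(s.encode()))
        else:
            key.append(zlib.crc32(repr(float(s)).encode()))
    return np.random.default_rng(key)


def saturation_model(config: GeneratorConfig) -> SaturationModel:
    """Saturation model calibrated on the configured anchor pairs."""
    return calibrate_saturation(list(config.saturation_anchors))


def anchor_24h(config: GeneratorConfig, tissue: str, arm: str) -> float:
    """The 24-h physical %IA/g anchor for a tissue/arm combination."""
    if arm not in config.arms:
        raise KeyError(f"unknown arm {arm!r}")
    if tissue == "tumor":
        return predicted_uptake(saturation_model(config), config.arms[arm].amount_nmol)
    try:
        return config.anchors_24h[tissue][arm]
    except KeyError:
        raise KeyError(f"no 24-h anchor for tissue {tissue!r} in arm {arm!r}") from None


def tac_value(
    config: GeneratorConfig,
    tissue: str,
    arm: str,
    t_h: np.ndarray | float,
    nuclide: Nuclide = AC225,
) -> np.ndarray:
    """Analytic physical activity A(t) (%IA/g) of the generating curve."""
    kin = config.kinetics[tissue]
    ku, kc = kin.uptake_rate, kin.clearance_rate
    lam = nuclide.decay_constant
    t = np.asarray(t_h, dtype=float)
    shape = (np.exp(-kc * t) - np.exp(-ku * t)) * np.exp(-lam * t)
    at24 = (np.exp(-kc * 24.0) - np.exp(-ku * 24.0)) * np.exp(-lam * 24.0)
    scale = anchor_24h(config, tissue, arm) / at24
    return scale * shape


def gen_time_activity(
    config: GeneratorConfig,
    tissue: str,
    arm: str = "low_mass",
    nuclide: Nuclide = AC225,
) -> TimeActivityCurve:
    """Noise-free physical time–activity curve at the configured sample times."""
    acts = tac_value(config, tissue, arm, np.asarray(config.sample_times_h), nuclide)
    return TimeActivityCurve(
        tissue=tissue,
        times_h=tuple(config.sample_times_h),
        activities=tuple(float(a) for a in acts),
        decay_corrected=False,
        provenance=f"synthetic arm={arm} seed={config.seed}",
    )


def config_implied_tia(
    config: GeneratorConfig,
    tissue: str,
    arm: str = "low_mass",
    nuclide: Nuclide = AC225,
    dt_h: float = 0.01,
) -> float:
    """Fine-grid reference TIA (%IA·h/g) of the generating curve.

    Trapezoid at ``dt_h`` resolution over [0, last sample time] plus the
    physical-decay tail — the same convention as the pipeline, with the
    sampling-grid discretization removed.  This is the independent truth
    used by parameter-recovery checks.
    """
    t_end = config.sample_times_h[-1]
    grid = np.arange(0.0, t_end + dt_h / 2, dt_h)
    a = tac_value(config, tissue, arm, grid, nuclide)
    tail = float(tac_value(config, tissue, arm, t_end, nuclide)) / nuclide.decay_constant
    return float(np.trapezoid(a, grid)) + tail


def gen_biodist_study(
    config: GeneratorConfig,
    arm: str = "low_mass",
    tissues: tuple[str, ...] = ("tumor", "blood", "kidney"),
    noise_cv: float | None = None,
    n: int | None = None,
    nuclide: Nuclide = AC225,
    replicate: int = 0,
) -> list[BiodistSample]:
    """Group-level biodistribution samples for one arm.

    With ``noise_cv=0`` the sample means equal the generating curve exactly
    and SDs are 0.  Otherwise each of ``n`` animals per tissue/time gets an
    independent mean-preserving lognormal factor with the given CV, and the
    group mean/SD are reported.  ``decay_corrected_output=True`` converts the
    reported values to the decay-corrected convention (flagged as such).
    """
    cv = config.noise_cv if noise_cv is None else noise_cv
    n_animals = config.n_per_group if n is None else n
    rng = _rng(config, "biodist", arm, replicate)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    samples: list[BiodistSample] = []
    for tissue in tissues:
        truth = tac_value(config, tissue, arm, np.asarray(config.sample_times_h), nuclide)
        for t, mu in zip(config.sample_times_h, truth):
            if cv == 0:
                mean, sd = float(mu), 0.0
            else:
                draws = mu * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n_animals)
                mean, sd = float(np.mean(draws)), float(np.std(draws, ddof=1))
            if config.decay_corrected_output:
                f = decay_factor(nuclide, t)
                mean, sd = mean / f, sd / f
            samples.append(
                BiodistSample(
                    tissue=tissue,
                    time_h=t,
                    uptake_mean=mean,
                    uptake_sd=sd,
                    n=n_animals,
                    decay_corrected=config.decay_corrected_output,
                )
            )
    return samples


def _bound_params(ic: InternalizationConfig) -> tuple[float, float]:
    """Solve (A_bind, k_off) of the total-bound curve from its two anchors."""
    kb = ic.bind_rate
    k_off = (
        np.log(
            (ic.bound_t1 * (1 - np.exp(-kb * ic.t2_h)))
            / (ic.bound_t2 * (1 - np.exp(-kb * ic.t1_h)))
        )
        / (ic.t2_h - ic.t1_h)
    )
    a_bind = ic.bound_t2 / ((1 - np.exp(-kb * ic.t2_h)) * np.exp(-k_off * ic.t2_h))
    return float(a_bind), float(k_off)


def _fraction_params(ic: InternalizationConfig) -> tuple[float, float]:
    """Solve (a, k_i) of ``f(t) = a (1 - exp(-k_i t))`` from the two fraction anchors."""
    ratio = ic.frac_t2 / ic.frac_t1
    if ratio <= 1:
        raise ValueError("internalized fraction must increase between anchors")

    def g(k: float) -> float:
        return (1 - np.exp(-ic.t2_h * k)) / (1 - np.exp(-ic.t1_h * k)) - ratio

    k_i = brentq(g, 1e-9, 50.0)
    return float(ic.frac_t1 / (1 - np.exp(-ic.t1_h * k_i))), float(k_i)


def gen_internalization(config: GeneratorConfig) -> InternalizationSeries:
    """Two-pool internalization time course hitting the configured anchors.

    Total bound ``T(t) = A (1 - exp(-k_b t)) exp(-k_off t)`` (near-constant
    after 1 h); internalized pool ``I(t) = T(t) a (1 - exp(-k_i t))``; the
    membrane channel is the remainder.  Zero fraction anchors give a pure
    membrane-bound series (no internalization).
    """
    ic = config.internalization
    t = np.asarray(ic.times_h, dtype=float)
    a_bind, k_off = _bound_params(ic)
    total = a_bind * (1 - np.exp(-ic.bind_rate * t)) * np.exp(-k_off * t)
    if ic.frac_t1 == 0 and ic.frac_t2 == 0:
        internal = np.zeros_like(total)
    else:
        a, k_i = _fraction_params(ic)
        internal = a * (1 - np.exp(-k_i * t)) * total
    return InternalizationSeries(
        times_h=tuple(ic.times_h),
        membrane=tuple(float(x) for x in total - internal),
        internalized=tuple(float(x) for x in internal),
    )


def gen_therapy_cohort(
    config: GeneratorConfig,
    tumor_dose_gy: float,
    group: str = "cohort",
    n: int | None = None,
) -> list[TumorSeries]:
    """Simulated tumor-volume series for one treatment group.

    Control animals (dose 0) grow exponentially with median time-to-doubling
    ``doubling_time_d``.  Treatment splits the tumor into a surviving clone
    (fraction ``exp(-dose/D0)``) that keeps growing and a sterilized bulk
    that resorbs with the configured half-time.  Measurements carry
    mean-preserving lognormal caliper noise on a twice-weekly schedule.
    """
    if tumor_dose_gy < 0:
        raise ValueError("dose must be >= 0")
    cc = config.cohort
    n_animals = cc.n_per_group if n is None else n
    rng = _rng(config, "therapy", group, tumor_dose_gy)
    days = np.arange(0.0, cc.horizon_d + 1e-9, cc.measurement_interval_d)
    g_median = np.log(2.0) / cc.doubling_time_d
    sf = float(np.exp(-tumor_dose_gy / cc.d0_gy)) if tumor_dose_gy > 0 else 1.0
    k_res = np.log(2.0) / cc.resorption_halftime_d
    sig_m = float(np.sqrt(np.log1p(cc.measurement_cv**2)))

    cohort: list[TumorSeries] = []
    for i in range(n_animals):
        v0 = cc.baseline_volume_mm3 * float(
            rng.lognormal(mean=0.0, sigma=np.sqrt(np.log1p(cc.baseline_cv**2)))
        )
        g = g_median * float(rng.lognormal(mean=0.0, sigma=np.sqrt(np.log1p(cc.growth_cv**2))))
        true_v = v0 * (sf * np.exp(g * days) + (1.0 - sf) * np.exp(-k_res * days))
        if cc.measurement_cv > 0:
            noise = rng.lognormal(mean=-sig_m**2 / 2, sigma=sig_m, size=days.size)
        else:
            noise = np.ones_like(days)
        measured = true_v * noise
        cohort.append(
            TumorSeries(
                animal_id=f"{group}-{i + 1:02d}",
                group=group,
                days=tuple(float(d) for d in days),
                values=tuple(float(v) for v in measured),
                kind="volume",
            )
        )
    return cohort


def write_fixture_dir(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete fixture directory in the pipeline's CSV/JSON schemas."""
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    config.to_yaml(out / "config.yaml")
    written["config"] = out / "config.yaml"

    for arm, arm_cfg in config.arms.items():
        p = out / f"biodist_{arm}.csv"
        write_biodist(gen_biodist_study(config, arm=arm), p)
        written[f"biodist_{arm}"] = p
        pj = out / f"administration_{arm}.json"
        arm_cfg.administration(label=arm).to_json(pj)
        written[f"administration_{arm}"] = pj

    series = gen_internalization(config)
    p = out / "internalization.csv"
    pd.DataFrame(
        {
            "time_h": series.times_h,
            "membrane": series.membrane,
            "internalized": series.internalized,
        }
    ).to_csv(p, index=False)
    written["internalization"] = p

    rows = []
    for group, dose in (("control", 0.0), ("prit_37kbq", 209.79)):
        for s in gen_therapy_cohort(config, dose, group=group):
            for d, v in zip(s.days, s.values):
                rows.append(
                    {"animal_id": s.animal_id, "group": s.group, "day": d, "volume_mm3": v}
                )
    p = out / "tumors.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written["tumors"] = p
    return written
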