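"""Ex vivo biodistribution data model: %IA/g samples, unit conversion, ratios.

Biodistribution studies sacrifice groups of animals at serial time points and
report, per tissue, the percentage of the injected (administered) activity
found per gram of tissue (%IA/g).  Whether the counts were decay-corrected to
injection time is an acquisition convention, so every sample carries an
explicit ``decay_corrected`` flag; downstream integration requires physical
(decay-inclusive) curves and un-corrects explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

__all__ = [
    "Administration",
    "BiodistSample",
    "CORE_TISSUES",
    "BIODIST_COLUMNS",
    "read_biodist",
    "write_biodist",
    "pia_to_pmol",
    "uptake_ratio",
]

#: controlled core tissue vocabulary; unknown labels are kept with a warning
CORE_TISSUES = frozenset(
    {
        "tumor",
        "blood",
        "kidney",
        "liver",
        "spleen",
        "heart",
        "lung",
        "stomach",
        "small intestine",
        "large intestine",
        "muscle",
        "bone",
        "skin",
        "tail",
    }
)

#: required CSV column schema for biodistribution files
BIODIST_COLUMNS = ("tissue", "time_h", "pia_g_mean", "pia_g_sd", "n", "decay_corrected")


@dataclass(frozen=True)
class Administration:
    """One 3-step PRIT administration record.

    The regimen is: bispecific antibody (BsAb) at -28 h, clearing agent at
    -4 h, radiolabelled hapten at 0 h.  ``activity_kbq`` and ``amount_nmol``
    describe the hapten injection; their quotient is the specific activity
    (kBq/nmol), the lever that controls how much cold mass competes for the
    tumor's saturable capture sites.
    """

    activity_kbq: float
    amount_nmol: float
    bsab_amount_nmol: float = 1.19
    bsab_time_h: float = -28.0
    clearing_agent_amount_nmol: float = 2.76
    clearing_agent_time_h: float = -4.0
    hapten_time_h: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.activity_kbq < 0:
            raise ValueError("administered activity must be >= 0")
        if not (self.amount_nmol > 0):
            raise ValueError("administered molar amount must be positive")
        if not (self.bsab_time_h < self.clearing_agent_time_h < self.hapten_time_h):
            raise ValueError(
                "administration order must be BsAb < clearing agent < hapten"
            )

    @property
    def specific_activity_kbq_per_nmol(self) -> float:
        return self.activity_kbq / self.amount_nmol

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path: str | Path) -> "Administration":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class BiodistSample:
    """Group-level uptake of one tissue at one time point (mean ± SD, n animals)."""

    tissue: str
    time_h: float
    uptake_mean: float  # %IA/g
    uptake_sd: float  # %IA/g
    n: int
    decay_corrected: bool

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("sample time must be >= 0 h")
        if self.uptake_mean < 0:
            raise ValueError("uptake mean must be >= 0 %IA/g")
        if self.uptake_sd < 0:
            raise ValueError("uptake SD must be >= 0")
        if self.n < 1:
            raise ValueError("animal count must be >= 1")


def read_biodist(path: str | Path) -> list[BiodistSample]:
    """Read a biodistribution CSV with the declared schema.

    Required columns: ``tissue, time_h, pia_g_mean, pia_g_sd, n,
    decay_corrected``.  Unknown tissue labels are preserved verbatim with a
    warning; a negative uptake raises naming the offending row.
    """
    # round_trip parsing keeps floats bit-exact through a write/read cycle
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in BIODIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"biodistribution file {path} missing columns: {missing}")
    samples: list[BiodistSample] = []
    for idx, row in df.iterrows():
        tissue = str(row["tissue"]).strip()
        if tissue.lower() not in CORE_TISSUES:
            warnings.warn(
                f"unknown tissue label {tissue!r} (row {idx}); kept verbatim",
                stacklevel=2,
            )
        if row["pia_g_mean"] < 0:
            raise ValueError(
                f"negative uptake {row['pia_g_mean']} in row {idx} "
                f"(tissue {tissue!r}, t={row['time_h']} h)"
            )
        samples.append(
            BiodistSample(
                tissue=tissue,
                time_h=float(row["time_h"]),
                uptake_mean=float(row["pia_g_mean"]),
                uptake_sd=float(row["pia_g_sd"]),
                n=int(row["n"]),
                decay_corrected=bool(row["decay_corrected"]),
            )
        )
    return samples


def write_biodist(samples: list[BiodistSample], path: str | Path) -> None:
    """Write samples back to the declared CSV schema (round-trip safe)."""
    df = pd.DataFrame(
        {
            "tissue": [s.tissue for s in samples],
            "time_h": [s.time_h for s in samples],
            "pia_g_mean": [s.uptake_mean for s in samples],
            "pia_g_sd": [s.uptake_sd for s in samples],
            "n": [s.n for s in samples],
            "decay_corrected": [s.decay_corrected for s in samples],
        }
    )
    # repr keeps the round-trip bit-exact (pandas' default float formatting
    # can drop the last ulp)
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def pia_to_pmol(uptake_pia_g: float, administered_amount_nmol: float) -> float:
    """Convert %IA/g to pmol of compound per gram of tissue.

    ``uptake/100`` is the fraction of the injected amount per gram;
    multiplying by the administered nmol and by 1000 pmol/nmol gives pmol/g.
    Linear in both arguments.
    """
    if uptake_pia_g < 0:
        raise ValueError("uptake must be >= 0")
    if not (administered_amount_nmol > 0):
        raise ValueError("administered amount must be positive")
    return uptake_pia_g / 100.0 * administered_amount_nmol * 1000.0


def uptake_ratio(a: BiodistSample, b: BiodistSample, ndigits: int | None = 1) -> float:
    """Tissue-to-tissue uptake ratio from group means at a shared time point.

    Reported to 1 decimal by default (pass ``ndigits=None`` for full
    precision), matching how tumor-to-normal ratios are conventionally
    tabulated.
    """
    if a.time_h != b.time_h:
        raise ValueError(
            f"mismatched time points: {a.time_h} h vs {b.time_h} h"
        )
    if b.uptake_mean <= 0:
        raise ValueError("denominator tissue has non-positive uptake")
    ratio = a.uptake_mean / b.uptake_mean
    return ratio if ndigits is None else round(ratio, ndigits)
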