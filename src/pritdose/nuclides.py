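"""Nuclear-data constants and decay arithmetic for alpha-emitting chains.

The dosimetry downstream assumes *local absorption*: every daughter in the
chain decays at the site where the parent decayed, instantaneously on the
timescale of the biodistribution (the longest-lived daughter of ^225Ac that
matters for alpha energy, Bi-213, has a 46-min half-life against serial
sampling over days).  Under that assumption the alpha energy released per
parent decay is simply the branching-weighted sum of the chain's mean alpha
energies, and the parent's exponential decay governs the whole chain.

Chain constants live in a JSON data file (``data/ac225_chain.json``) with the
source recorded alongside the numbers, not in code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "Nuclide",
    "DecayStep",
    "DecayChain",
    "decay_factor",
    "alpha_energy_per_decay",
    "load_chain",
    "ac225_chain",
    "AC225",
]

#: hours per supported half-life unit
_UNIT_TO_HOURS = {"d": 24.0, "h": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0}


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide identified by name and half-life.

    Parameters
    ----------
    name : str
        Label, e.g. ``"Ac-225"``.
    half_life : float
        Half-life in ``half_life_unit`` units; must be positive.
    half_life_unit : str
        One of ``d``, ``h``, ``min``, ``s``.
    """

    name: str
    half_life: float
    half_life_unit: str = "h"

    def __post_init__(self) -> None:
        if self.half_life_unit not in _UNIT_TO_HOURS:
            raise ValueError(
                f"unknown half-life unit {self.half_life_unit!r}; "
                f"expected one of {sorted(_UNIT_TO_HOURS)}"
            )
        if not (self.half_life > 0):
            raise ValueError(f"half-life must be positive, got {self.half_life}")

    @property
    def half_life_h(self) -> float:
        """Half-life in hours."""
        return self.half_life * _UNIT_TO_HOURS[self.half_life_unit]

    @property
    def decay_constant(self) -> float:
        """Decay constant lambda = ln(2)/T1/2, per hour."""
        return math.log(2.0) / self.half_life_h


@dataclass(frozen=True)
class DecayStep:
    """One decay in a chain.

    ``branching_fraction`` is the probability that a single parent decay
    passes through this step; steps sharing a ``position`` are alternative
    branches whose fractions sum to 1.  ``mean_alpha_energy_mev`` is the
    intensity-weighted mean alpha energy emitted by this step (0 for pure
    beta/gamma steps).
    """

    nuclide: Nuclide
    branching_fraction: float
    mean_alpha_energy_mev: float
    position: int = 0
    stable: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.branching_fraction <= 1.0):
            raise ValueError(
                f"branching fraction must be in (0, 1], got {self.branching_fraction}"
            )
        if self.mean_alpha_energy_mev < 0:
            raise ValueError("mean alpha energy must be >= 0")


@dataclass(frozen=True)
class DecayChain:
    """Ordered decay chain with branch points, terminating in a stable step."""

    parent: Nuclide
    steps: tuple[DecayStep, ...] = field(default_factory=tuple)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("decay chain must contain at least one step")
        if not any(s.stable for s in self.steps):
            raise ValueError("decay chain must terminate in a stable step")
        # alternative branches at one chain position must exhaust probability
        by_pos: dict[int, float] = {}
        for s in self.steps:
            by_pos[s.position] = by_pos.get(s.position, 0.0) + s.branching_fraction
        for pos, total in by_pos.items():
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"branching fractions at chain position {pos} sum to "
                    f"{total!r}, expected 1"
                )


def decay_factor(nuclide: Nuclide, t_hours: float) -> float:
    """Fraction of activity remaining after ``t_hours`` of physical decay.

    Returns ``exp(-lambda * t)``; strictly decreasing in ``t`` and in (0, 1].

    Raises
    ------
    ValueError
        If ``t_hours`` is negative.
    """
    if t_hours < 0:
        raise ValueError(f"time must be non-negative, got {t_hours}")
    return math.exp(-nuclide.decay_constant * t_hours)


def alpha_energy_per_decay(chain: DecayChain) -> float:
    """Total alpha energy (MeV) released per parent decay.

    Branching-weighted sum over the chain's steps; valid under the
    local-absorption / secular-equilibrium assumption documented in the
    module docstring.  Independent of step order.
    """
    return sum(s.branching_fraction * s.mean_alpha_energy_mev for s in chain.steps)


def _nuclide_from_dict(d: dict) -> Nuclide:
    return Nuclide(
        name=d["name"],
        half_life=float(d["half_life"]),
        half_life_unit=d["half_life_unit"],
    )


def load_chain(path: str | Path | None = None) -> DecayChain:
    """Load a decay chain from a JSON file; default is the shipped ^225Ac chain."""
    if path is None:
        text = (
            resources.files("pritdose.data").joinpath("ac225_chain.json").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    steps = tuple(
        DecayStep(
            nuclide=_nuclide_from_dict(s["nuclide"]),
            branching_fraction=float(s["branching_fraction"]),
            mean_alpha_energy_mev=float(s["mean_alpha_energy_mev"]),
            position=int(s.get("position", i)),
            stable=bool(s.get("stable", False)),
        )
        for i, s in enumerate(raw["steps"])
    )
    source = raw.get("comment", "")
    if isinstance(source, list):
        source = " ".join(source)
    return DecayChain(parent=_nuclide_from_dict(raw["parent"]), steps=steps, source=source)


def ac225_chain() -> DecayChain:
    """The shipped ^225Ac decay chain (cached)."""
    global _AC225_CHAIN
    if _AC225_CHAIN is None:
        _AC225_CHAIN = load_chain()
    return _AC225_CHAIN


_AC225_CHAIN: DecayChain | None = None

#: ^225Ac parent nuclide (half-life 9.92 d)
AC225 = Nuclide(name="Ac-225", half_life=9.92, half_life_unit="d")
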