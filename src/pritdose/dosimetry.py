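"""RBE-weighted absorbed-dose coefficients, dose ledgers, and therapeutic indices.

Dose here is concentration-based murine dosimetry: because uptake is
expressed per gram of tissue, organ masses cancel and the absorbed dose per
administered kBq follows from the time-integrated activity directly.  All
alpha energy of the decay chain is deposited locally, weighted by a relative
biological effectiveness (RBE, default 5) to express the high-LET alpha dose
on a biologically comparable scale.

Unit chain for the coefficient (the ``audit`` trail on each result spells
this out numerically)::

    TIA [%IA·h/g per kBq administered]
      x 10      -> Bq·h per g per kBq    (1 %IA of 1 kBq = 10 Bq)
      x 3600    -> decays per g per kBq
      x E [MeV] x 1.602176634e-13 [J/MeV]  -> J per g per kBq
      x 1000    -> J per kg = Gy per kBq
      x RBE     -> RBE-weighted Gy per kBq
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .nuclides import DecayChain, alpha_energy_per_decay
from .tia import TIAResult

__all__ = [
    "MEV_TO_JOULE",
    "DoseModel",
    "DoseCoefficient",
    "dose_coefficient",
    "absorbed_dose",
    "cumulative_dose",
    "therapeutic_index",
    "extrapolate_coefficient",
    "round_sig",
]

#: CODATA exact conversion, J per MeV
MEV_TO_JOULE = 1.602176634e-13


@dataclass(frozen=True)
class DoseModel:
    """Energy-per-decay and RBE weighting used to turn TIA into dose."""

    rbe: float = 5.0
    energy_per_decay_mev: float = 27.49  # shipped ^225Ac chain total

    def __post_init__(self) -> None:
        if not (self.rbe > 0):
            raise ValueError("RBE must be positive")
        if not (self.energy_per_decay_mev > 0):
            raise ValueError("energy per decay must be positive")

    @classmethod
    def from_chain(cls, chain: DecayChain, rbe: float = 5.0) -> "DoseModel":
        return cls(rbe=rbe, energy_per_decay_mev=alpha_energy_per_decay(chain))


@dataclass(frozen=True)
class DoseCoefficient:
    """Absorbed dose per administered activity for one tissue (Gy/kBq)."""

    tissue: str
    value: float  # Gy/kBq administered
    rbe_weighted: bool = True
    derivation: str = "integrated"  # or "extrapolated"
    audit: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("dose coefficient must be >= 0")
        if self.derivation not in ("integrated", "extrapolated"):
            raise ValueError(f"unknown derivation {self.derivation!r}")


def dose_coefficient(tia: TIAResult, model: DoseModel) -> DoseCoefficient:
    """RBE-weighted dose coefficient (Gy/kBq) from a TIA result.

    The TIA must come from a physical curve normalized per administered kBq
    (which %IA/g is by construction).
    """
    value = (
        tia.tia
        * 10.0  # %IA/g per kBq -> Bq·h/g per kBq
        * 3600.0  # h -> s: decays per g per kBq
        * model.energy_per_decay_mev
        * MEV_TO_JOULE  # -> J/g per kBq
        * 1000.0  # -> J/kg = Gy per kBq
        * model.rbe
    )
    audit = (
        f"TIA = {tia.tia:.6g} %IA·h/g per kBq (tail: {tia.tail_model})",
        "x 10 Bq per %IA-of-1-kBq -> Bq·h/g",
        "x 3600 s/h -> decays/g",
        f"x {model.energy_per_decay_mev:.4g} MeV/decay x {MEV_TO_JOULE:.10g} J/MeV -> J/g",
        "x 1000 g/kg -> Gy/kBq",
        f"x RBE {model.rbe:.3g} -> RBE-weighted Gy/kBq",
        f"= {value:.6g} Gy/kBq",
    )
    return DoseCoefficient(
        tissue=tia.tissue, value=value, rbe_weighted=True, derivation="integrated", audit=audit
    )


def absorbed_dose(coeff: DoseCoefficient, administered_kbq: float) -> float:
    """Absorbed dose (Gy) for one administration: coefficient x activity."""
    if administered_kbq < 0:
        raise ValueError("administered activity must be >= 0")
    return coeff.value * administered_kbq


def cumulative_dose(cycles: list[tuple[DoseCoefficient, float]]) -> float:
    """Total dose (Gy) over treatment cycles; per-cycle doses simply add.

    No repair or fractionation correction is applied: a 2-cycle regimen at
    the same coefficient and activity delivers exactly twice the single-cycle
    dose.
    """
    if not cycles:
        raise ValueError("cumulative dose needs at least one cycle")
    return sum(absorbed_dose(c, kbq) for c, kbq in cycles)


def therapeutic_index(tumor: DoseCoefficient, organ: DoseCoefficient) -> float:
    """Tumor-to-organ dose-coefficient ratio (dimensionless, full precision).

    Both coefficients must share the RBE-weighting status; the RBE itself
    cancels in the quotient.
    """
    if tumor.rbe_weighted != organ.rbe_weighted:
        raise ValueError("cannot mix RBE-weighted and unweighted coefficients")
    if organ.value <= 0:
        raise ValueError("organ coefficient must be positive")
    return tumor.value / organ.value


def extrapolate_coefficient(
    ref: DoseCoefficient, ref_uptake_24h: float, new_uptake_24h: float
) -> DoseCoefficient:
    """Scale a reference coefficient to another regimen by its 24-h uptake.

    Assumes the time–activity curve *shape* is unchanged between regimens
    (clearance kinetics unaffected by receptor saturation), so the
    coefficient scales with the single 24-h uptake anchor.  Homogeneous:
    scaling both uptakes by a common factor leaves the result unchanged.
    """
    if not (ref_uptake_24h > 0):
        raise ValueError("reference 24-h uptake must be positive")
    if new_uptake_24h < 0:
        raise ValueError("new 24-h uptake must be >= 0")
    scale = new_uptake_24h / ref_uptake_24h
    return replace(
        ref,
        value=ref.value * scale,
        derivation="extrapolated",
        audit=ref.audit + (f"x uptake scale {new_uptake_24h}/{ref_uptake_24h} = {scale:.6g}",),
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display helper; math stays full precision)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
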