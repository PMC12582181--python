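"""Saturable tumor capture and radioligand internalization kinetics.

Two in-vitro/in-vivo phenomena shape PRIT performance:

* **Mass-dose saturation.**  The pre-localized bispecific antibody presents a
  finite density of hapten-capture sites, so fractional tumor uptake (%IA/g)
  falls as the administered hapten mass rises.  A single-site Langmuir form
  with the administered amount as the free-ligand proxy,
  ``uptake = 100 * bmax / (km + administered)``, is the minimal model that
  reproduces both observed regimens.

* **Internalization.**  Membrane-bound radioligand is internalized over
  hours; the internalized share of total cell-bound activity and its
  AUC-weighted overall percentage quantify how much decay energy is
  retained intracellularly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SaturationModel",
    "InternalizationSeries",
    "predicted_uptake",
    "calibrate_saturation",
    "internalized_fraction",
    "auc_internalized_percent",
]


@dataclass(frozen=True)
class SaturationModel:
    """Langmuir-type capture model.

    ``bmax`` is the bindable amount per gram of tumor (nmol/g); ``km`` the
    administered amount (nmol) at which fractional uptake halves relative to
    the tracer limit ``100*bmax/km`` %IA/g.
    """

    bmax: float  # nmol bindable per g tissue
    km: float  # nmol administered at half-saturation

    def __post_init__(self) -> None:
        if not (self.bmax > 0):
            raise ValueError("bmax must be positive")
        if not (self.km > 0):
            raise ValueError("km must be positive")


@dataclass(frozen=True)
class InternalizationSeries:
    """Paired membrane-bound / internalized activity time course.

    Units: % of added activity per 10^6 cells, both channels.
    """

    times_h: tuple[float, ...]
    membrane: tuple[float, ...]
    internalized: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        m = np.asarray(self.membrane, dtype=float)
        i = np.asarray(self.internalized, dtype=float)
        if not (t.size == m.size == i.size):
            raise ValueError("all three channels must have equal length")
        if t.size == 0:
            raise ValueError("series needs at least one point")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(m < 0) or np.any(i < 0):
            raise ValueError("activities must be >= 0")


def predicted_uptake(model: SaturationModel, administered_nmol: float) -> float:
    """Fractional tumor uptake (%IA/g) at a given administered hapten mass.

    ``100 * bmax / (km + administered)``: strictly decreasing in the
    administered amount; the *absolute* bound amount per gram,
    ``predicted_uptake/100 * administered`` nmol/g, rises toward ``bmax``.
    """
    if not (administered_nmol > 0):
        raise ValueError("administered amount must be positive")
    return 100.0 * model.bmax / (model.km + administered_nmol)


def calibrate_saturation(
    observations: list[tuple[float, float]],
) -> SaturationModel:
    """Fit the saturation model to (administered nmol, uptake %IA/g) pairs.

    Two points admit an exact algebraic solution of::

        u1 (km + a1) = u2 (km + a2) = 100 bmax

    More than two points are fitted by least squares in log-uptake (errors in
    %IA/g are multiplicative).  Uptake that *increases* with administered
    mass contradicts saturable capture and triggers a misfit warning.
    """
    obs = [(float(a), float(u)) for a, u in observations]
    if len(obs) < 2:
        raise ValueError("calibration needs >= 2 observations")
    amounts = [a for a, _ in obs]
    if len(set(amounts)) < len(amounts):
        raise ValueError("administered amounts must be distinct")
    if any(u <= 0 for _, u in obs):
        raise ValueError("uptakes must be positive")
    ordered = sorted(obs)
    if any(u2 > u1 for (_, u1), (_, u2) in zip(ordered, ordered[1:])):
        warnings.warn(
            "uptake increases with administered mass; saturation model misfit",
            stacklevel=2,
        )

    if len(obs) == 2:
        (a1, u1), (a2, u2) = obs
        if u1 == u2:
            raise ValueError("equal uptakes at distinct amounts: km is unidentifiable")
        km = (u2 * a2 - u1 * a1) / (u1 - u2)
        bmax = u1 * (km + a1) / 100.0
        if km <= 0 or bmax <= 0:
            raise ValueError(
                "two-point calibration gives non-positive parameters; "
                "data inconsistent with Langmuir capture"
            )
        return SaturationModel(bmax=bmax, km=km)

    a = np.array([x for x, _ in obs])
    u = np.array([y for _, y in obs])
    # start from the two most widely separated amounts
    i_lo, i_hi = int(np.argmin(a)), int(np.argmax(a))
    start = calibrate_saturation([obs[i_lo], obs[i_hi]])

    def resid(p: np.ndarray) -> np.ndarray:
        bmax, km = np.exp(p)
        return np.log(100.0 * bmax / (km + a)) - np.log(u)

    sol = least_squares(resid, x0=np.log([start.bmax, start.km]))
    bmax, km = np.exp(sol.x)
    return SaturationModel(bmax=float(bmax), km=float(km))


def internalized_fraction(series: InternalizationSeries) -> np.ndarray:
    """Internalized share of total cell-bound activity at each time point.

    ``internalized / (membrane + internalized)`` in [0, 1]; points with zero
    total bound activity are undefined and returned as NaN (flagged, not 0).
    """
    m = np.asarray(series.membrane, dtype=float)
    i = np.asarray(series.internalized, dtype=float)
    total = m + i
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, i / np.where(total > 0, total, 1.0), np.nan)
    return frac


def auc_internalized_percent(series: InternalizationSeries) -> float:
    """Overall internalized percentage by area-under-the-curve analysis.

    ``100 x AUC(internalized) / AUC(membrane + internalized)`` by trapezoid
    over the observed span only (no extrapolation).  Invariant to uniform
    rescaling of both channels.
    """
    if len(series.times_h) < 2:
        raise ValueError("AUC needs >= 2 time points")
    t = np.asarray(series.times_h, dtype=float)
    m = np.asarray(series.membrane, dtype=float)
    i = np.asarray(series.internalized, dtype=float)
    auc_total = float(np.trapezoid(m + i, t))
    if auc_total <= 0:
        raise ValueError("total-bound AUC is zero; percentage undefined")
    return 100.0 * float(np.trapezoid(i, t)) / auc_total
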