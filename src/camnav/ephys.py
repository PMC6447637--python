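"""Electrophysiology-derived scalar metrics.

Two measurement-side computations accompany the equilibrium model:

* the Ca2+-dependent inactivation (CDI) statistic, computed from a series of
  peak Na+ current magnitudes recorded around a Ca2+ uncaging event:
  CDI = 1 - (average of the last few post-uncaging peaks) / (pre-uncaging peak);
* ratiometric Ca2+ indicator calibration, converting a two-colour
  fluorescence ratio R into free [Ca2+] via
  [Ca2+] = Kd (R - Rmin) / (Rmax - R), and back-solving the indicator Kd from
  a single reference measurement at known [Ca2+].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "UncagingRecord",
    "RatiometricCalibration",
    "compute_cdi",
    "ratio_to_ca",
    "ca_to_ratio",
    "calibrate_kd",
]


@dataclass(frozen=True)
class UncagingRecord:
    """Ordered peak Na+ current magnitudes around a Ca2+ uncaging event.

    ``peak_currents`` are positive magnitudes in pA (inward currents are
    sign-flipped at ingest).  ``uncage_index`` is the position of the first
    post-uncaging response; ``n_tail`` is how many terminal responses enter
    the post-uncaging average (3 or 4 in practice).
    """

    peak_currents: tuple[float, ...]
    uncage_index: int
    n_tail: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peak_currents", tuple(float(p) for p in self.peak_currents)
        )
        n = len(self.peak_currents)
        if not 1 <= self.uncage_index < n:
            raise ValueError("uncage_index must leave >=1 sweep on each side")
        n_post = n - self.uncage_index
        if not 1 <= self.n_tail <= n_post:
            raise ValueError(f"n_tail must be in [1, {n_post}]")

    @property
    def pre(self) -> tuple[float, ...]:
        return self.peak_currents[: self.uncage_index]

    @property
    def post(self) -> tuple[float, ...]:
        return self.peak_currents[self.uncage_index :]


@dataclass(frozen=True)
class RatiometricCalibration:
    """Indicator Kd (molar) and the ratio extremes Rmin (zero Ca2+) / Rmax (saturating)."""

    kd: float
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if not self.r_max > self.r_min:
            raise ValueError("r_max must exceed r_min")


def compute_cdi(
    record: UncagingRecord,
    reference: Literal["last_pre", "mean_pre"] = "last_pre",
) -> float:
    """CDI = 1 - mean(last ``n_tail`` post-uncaging peaks) / pre-uncaging peak.

    The reference peak is the last pre-uncaging response by default
    (``mean_pre`` averages all pre-uncaging sweeps instead).  Returns 0 for
    unattenuated currents, 1 for complete inactivation; negative values mean
    facilitation.
    """
    if reference == "last_pre":
        ref = record.pre[-1]
    elif reference == "mean_pre":
        ref = float(np.mean(record.pre))
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    if ref <= 0:
        raise ValueError("pre-uncaging reference peak must be positive")
    tail = record.post[-record.n_tail :]
    return 1.0 - float(np.mean(tail)) / ref


def ratio_to_ca(r: float, calib: RatiometricCalibration) -> float:
    """Free [Ca2+] (molar) from a fluorescence ratio: Kd (R - Rmin)/(Rmax - R).

    Monotone increasing in R on [Rmin, Rmax).  A ratio at or above Rmax means
    the indicator is saturated and the concentration is undefined (raises);
    a ratio below Rmin is measurement noise around zero Ca2+ and is clamped
    to 0 with a warning.
    """
    if r >= calib.r_max:
        raise ValueError(
            f"ratio {r:g} at or above r_max={calib.r_max:g}: indicator saturated"
        )
    if r < calib.r_min:
        warnings.warn(
            f"ratio {r:g} below r_min={calib.r_min:g}; clamping [Ca2+] to 0",
            stacklevel=2,
        )
        return 0.0
    return calib.kd * (r - calib.r_min) / (calib.r_max - r)


def ca_to_ratio(ca: float, calib: RatiometricCalibration) -> float:
    """Algebraic inverse of :func:`ratio_to_ca`: R = (Rmin Kd + Rmax Ca)/(Kd + Ca)."""
    if ca < 0:
        raise ValueError("ca must be non-negative")
    return (calib.r_min * calib.kd + calib.r_max * ca) / (calib.kd + ca)


def calibrate_kd(r_min: float, r_max: float, r_ref: float, ca_ref: float) -> float:
    """Indicator Kd from a single reference ratio at known free [Ca2+].

    Solves the calibration equation for Kd:
    Kd = Ca_ref (Rmax - R_ref)/(R_ref - Rmin).  The reference ratio must lie
    strictly between Rmin and Rmax.
    """
    if not r_min < r_ref < r_max:
        raise ValueError("r_ref must lie strictly between r_min and r_max")
    if ca_ref <= 0:
        raise ValueError("ca_ref must be positive")
    return ca_ref * (r_max - r_ref) / (r_ref - r_min)
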