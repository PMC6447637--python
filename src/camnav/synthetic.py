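"""Seeded generators emulating the statistical structure of the raw inputs.

Each generator is a pure function of its arguments and an explicit seed
(one ``numpy.random.default_rng`` stream per call, no global state), and
returns the generating truth alongside the artifact so recovery tests are
self-describing.

What is emulated, per consumer:

* :func:`make_uncaging_record` -- peak Na+ current envelopes around a Ca2+
  uncaging step: a flat pre-uncaging level, then a step down to
  ``pre_peak * (1 - attenuation)``, with Gaussian sweep-to-sweep noise.
  The step is instantaneous; real CDI develops over a few sweeps, which is
  irrelevant to the tail-average statistic.
* :func:`make_ratio_trace` -- two-colour indicator ratios for a list of
  known free [Ca2+] values, with Gaussian ratio noise, clipped below Rmax so
  every sample remains invertible.
* :func:`perturb_affinity_table` -- multiplicative log-normal jitter on the
  four Kd's of an affinity table, for robustness scans of the dominance
  claims.

ITC thermograms are generated by :func:`camnav.itc.simulate_thermogram`,
which already carries its own seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .ephys import RatiometricCalibration, UncagingRecord, ca_to_ratio
from .equilibria import CTermAffinityTable

__all__ = [
    "GeneratorSpec",
    "make_uncaging_record",
    "make_ratio_trace",
    "perturb_affinity_table",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Provenance of one generated artifact: seed, noise model and truth."""

    seed: int
    noise_model: str
    noise_sd: float
    truth: dict[str, Any] = field(default_factory=dict)


def make_uncaging_record(
    pre_peak: float = 1000.0,
    attenuation: float = 0.3,
    n_pre: int = 10,
    n_post: int = 15,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_tail: int = 3,
) -> tuple[UncagingRecord, GeneratorSpec]:
    """Synthetic peak-current series around an uncaging event.

    ``attenuation`` is the fractional drop of the post-uncaging steady state,
    so on noiseless output ``compute_cdi`` returns exactly ``attenuation``.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_pre < 1 or n_post < 1:
        raise ValueError("need at least one sweep on each side of the event")
    rng = np.random.default_rng(seed)
    peaks = np.concatenate(
        [
            np.full(n_pre, pre_peak),
            np.full(n_post, pre_peak * (1.0 - attenuation)),
        ]
    )
    if noise_sd > 0:
        peaks = peaks + rng.normal(0.0, noise_sd, size=peaks.size)
    record = UncagingRecord(tuple(peaks), uncage_index=n_pre, n_tail=n_tail)
    spec = GeneratorSpec(
        seed=seed,
        noise_model="gaussian_additive_pA",
        noise_sd=noise_sd,
        truth={"pre_peak": pre_peak, "attenuation": attenuation},
    )
    return record, spec


def make_ratio_trace(
    ca_values: Sequence[float],
    calib: RatiometricCalibration,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GeneratorSpec]:
    """Fluorescence ratios for known free [Ca2+] values, with Gaussian noise.

    Noisy ratios are clipped to stay strictly below Rmax (a saturated ratio
    carries no concentration information) and at or above Rmin.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    ratios = np.array([ca_to_ratio(ca, calib) for ca in ca_values])
    if noise_sd > 0:
        ratios = ratios + rng.normal(0.0, noise_sd, size=ratios.size)
        ceiling = calib.r_max - 1e-9 * (calib.r_max - calib.r_min)
        ratios = np.clip(ratios, calib.r_min, ceiling)
    spec = GeneratorSpec(
        seed=seed,
        noise_model="gaussian_additive_ratio",
        noise_sd=noise_sd,
        truth={"kd": calib.kd, "r_min": calib.r_min, "r_max": calib.r_max},
    )
    return ratios, spec


def perturb_affinity_table(
    table: CTermAffinityTable,
    log10_sd: float,
    seed: int = 0,
) -> tuple[CTermAffinityTable, GeneratorSpec]:
    """Multiplicative log-normal jitter on all four Kd's (positivity preserved).

    Each Kd is multiplied by 10**N(0, log10_sd); used to test whether the
    dominance claims survive realistic affinity uncertainty.
    """
    if log10_sd < 0:
        raise ValueError("log10_sd must be non-negative")
    rng = np.random.default_rng(seed)
    factors = 10.0 ** rng.normal(0.0, log10_sd, size=4) if log10_sd > 0 else np.ones(4)
    kds = table.kds() * factors
    perturbed = CTermAffinityTable(
        isoform=table.isoform,
        construct=table.construct,
        kd_apo=float(kds[0]),
        kd_2n=float(kds[1]),
        kd_2c=float(kds[2]),
        kd_4=float(kds[3]),
    )
    spec = GeneratorSpec(
        seed=seed,
        noise_model="lognormal_multiplicative_kd",
        noise_sd=log10_sd,
        truth={"kd_M": dict(zip(("apo", "2N", "2C", "4"), map(float, table.kds())))},
    )
    return perturbed, spec
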