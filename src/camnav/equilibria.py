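"""Coupled-equilibrium model of calmodulin Ca2+ saturation and NaV CTerm binding.

Calmodulin (CaM) is treated as a two-lobe receptor in which each lobe (the
N-terminal and C-terminal EF-hand pairs) binds two Ca2+ ions as a single
cooperative event.  This collapses the 16 microscopic Ca2+-occupancy states
onto four macro-species -- apo, (Ca2+)2-N, (Ca2+)2-C and (Ca2+)4 -- whose
relative populations follow from a four-state partition function built from
the two lobe macro free energies.  Each of the four species then competes for
a single site on the structured C-terminal domain (CTerm) of a voltage-gated
Na+ channel, with species-specific dissociation constants.

Two occupancy paths are provided:

* :func:`cterm_occupancy` -- the free-ligand approximation, valid when the
  channel concentration is negligible relative to CaM (the physiological
  regime: CaM is present at micromolar levels, channels far below that).
* :func:`exact_occupancy` -- the full per-species mass balance in which CTerm
  binding depletes each CaM species, solved self-consistently.  It serves as
  the numerical oracle validating the approximation.

Free Ca2+ is always a clamped independent variable: the bath sets it, CaM
does not deplete it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ThermoConstants",
    "LobeBindingEnergies",
    "CaMSpeciesFractions",
    "CTermAffinityTable",
    "CTermOccupancy",
    "PopulationSurface",
    "EVANS_SHEA",
    "LINSE",
    "LOBE_ENERGY_SETS",
    "SPECIES",
    "SPECIES_WITH_FREE",
    "kd_to_dg",
    "dg_to_kd",
    "half_saturation",
    "cam_fractions",
    "cterm_occupancy",
    "exact_occupancy",
    "population_surface",
    "dominant_species",
    "default_ca_grid",
    "default_cam_grid",
]

#: Fixed ordering of the four CaM Ca2+-saturation species.  Used for vector
#: layouts and as the tie-break order in :func:`dominant_species`.
SPECIES: tuple[str, ...] = ("apo", "2N", "2C", "4")
SPECIES_WITH_FREE: tuple[str, ...] = SPECIES + ("free",)


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant and temperature used in every Kd <-> free-energy conversion.

    Defaults are R = 1.9872e-3 kcal mol-1 K-1 and T = 298.15 K (room
    temperature, matching the calorimetry conditions).
    """

    gas_constant: float = 1.9872e-3  # kcal mol-1 K-1
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.gas_constant <= 0:
            raise ValueError("gas_constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def rt(self) -> float:
        """RT in kcal mol-1."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class LobeBindingEnergies:
    """Macro free energies of cooperative two-ion Ca2+ binding to each CaM lobe.

    ``dg_n`` and ``dg_c`` are standard free energies (kcal mol-1, negative for
    favourable binding) for the single collapsed event in which a lobe takes
    up both of its Ca2+ ions; single-ion intermediates are not modelled.
    """

    dg_n: float
    dg_c: float
    source_label: str = "custom"

    def __post_init__(self) -> None:
        if not (self.dg_n < 0 and self.dg_c < 0):
            raise ValueError("lobe free energies must be negative (favourable)")

    def macro_constant(self, lobe: str, constants: ThermoConstants) -> float:
        """Two-ion association macro-constant K_L = exp(-dG_L/RT), units M-2."""
        dg = {"N": self.dg_n, "C": self.dg_c}[lobe]
        return math.exp(-dg / constants.rt)


#: Lobe energies measured by Evans & Shea (default input set).
EVANS_SHEA = LobeBindingEnergies(dg_n=-12.82, dg_c=-15.06, source_label="evans_shea")
#: Alternate lobe energies measured by Linse and co-workers.
LINSE = LobeBindingEnergies(dg_n=-12.7, dg_c=-14.9, source_label="linse")

LOBE_ENERGY_SETS: Mapping[str, LobeBindingEnergies] = {
    "evans_shea": EVANS_SHEA,
    "linse": LINSE,
}


@dataclass(frozen=True)
class CaMSpeciesFractions:
    """Normalized populations of the four CaM Ca2+-saturation species."""

    ca_free: float
    f_apo: float
    f_2n: float
    f_2c: float
    f_4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_apo, self.f_2n, self.f_2c, self.f_4])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SPECIES, self.as_array()))


@dataclass(frozen=True)
class CTermAffinityTable:
    """Dissociation constants (molar) of one CTerm construct for the four CaM species."""

    isoform: str
    construct: str
    kd_apo: float
    kd_2n: float
    kd_2c: float
    kd_4: float

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.kds()):
            raise ValueError("all dissociation constants must be positive")

    def kds(self) -> np.ndarray:
        """Kd vector in species order (apo, 2N, 2C, 4), molar."""
        return np.array([self.kd_apo, self.kd_2n, self.kd_2c, self.kd_4])

    def kd(self, species: str) -> float:
        return float(self.kds()[SPECIES.index(species)])


@dataclass(frozen=True)
class CTermOccupancy:
    """Fractional occupancy of CTerm by each CaM species, plus the free fraction."""

    ca_free: float
    cam_total: float
    b_apo: float
    b_2n: float
    b_2c: float
    b_4: float
    b_free: float

    def bound_array(self) -> np.ndarray:
        return np.array([self.b_apo, self.b_2n, self.b_2c, self.b_4])

    def as_array(self) -> np.ndarray:
        """All five components in order (apo, 2N, 2C, 4, free)."""
        return np.array([self.b_apo, self.b_2n, self.b_2c, self.b_4, self.b_free])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SPECIES_WITH_FREE, self.as_array()))


@dataclass
class PopulationSurface:
    """CTerm occupancy evaluated on a (Ca2+, CaM) concentration grid.

    ``fractions`` maps each species label (including ``"free"``) to a 2-D array
    of shape ``(len(ca_grid), len(cam_grid))``.
    """

    ca_grid: np.ndarray
    cam_grid: np.ndarray
    fractions: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def occupancy_at(self, i: int, j: int) -> CTermOccupancy:
        return CTermOccupancy(
            ca_free=float(self.ca_grid[i]),
            cam_total=float(self.cam_grid[j]),
            b_apo=float(self.fractions["apo"][i, j]),
            b_2n=float(self.fractions["2N"][i, j]),
            b_2c=float(self.fractions["2C"][i, j]),
            b_4=float(self.fractions["4"][i, j]),
            b_free=float(self.fractions["free"][i, j]),
        )


def kd_to_dg(kd: float, constants: ThermoConstants = ThermoConstants()) -> float:
    """Convert a dissociation constant to a binding free energy.

    dG = RT ln(Kd / 1 M), kcal mol-1; negative for sub-molar Kd.  The 1 M
    standard state makes the conversion dimensionless inside the log.
    """
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd!r}")
    return constants.rt * math.log(kd)


def dg_to_kd(dg: float, constants: ThermoConstants = ThermoConstants()) -> float:
    """Inverse of :func:`kd_to_dg`: Kd = exp(dG/RT) in molar."""
    if not math.isfinite(dg):
        raise ValueError("dg must be finite")
    return math.exp(dg / constants.rt)


def half_saturation(
    dg_lobe: float, constants: ThermoConstants = ThermoConstants()
) -> float:
    """Free [Ca2+] (molar) at which a lobe with two-ion macro energy ``dg_lobe`` is half occupied.

    With the lobe filling as a single two-ion event, occupancy is
    K_L [Ca]^2 / (1 + K_L [Ca]^2), so half saturation occurs where
    K_L [Ca]^2 = 1, i.e. [Ca] = exp(dG_L / (2 RT)).  For the N-lobe
    (-12.82 kcal mol-1) this is ~20 uM -- the intrinsically low N-lobe
    affinity that keeps it unloaded at resting Ca2+.
    """
    if dg_lobe >= 0:
        raise ValueError("dg_lobe must be negative (favourable binding)")
    return math.exp(dg_lobe / (2.0 * constants.rt))


def cam_fractions(
    ca_free: float,
    energies: LobeBindingEnergies = EVANS_SHEA,
    constants: ThermoConstants = ThermoConstants(),
) -> CaMSpeciesFractions:
    """Fractions of the four CaM Ca2+-saturation species at clamped free [Ca2+].

    The lobes load independently, so the four Boltzmann weights are
    1, K_N ca^2, K_C ca^2 and K_N K_C ca^4 with Z their sum (the
    thermodynamic square closes with path-independent free energies).
    """
    if ca_free < 0:
        raise ValueError("ca_free must be non-negative")
    rt = constants.rt
    # Work with log-weights to stay finite at very high [Ca2+].
    if ca_free == 0.0:
        return CaMSpeciesFractions(ca_free, 1.0, 0.0, 0.0, 0.0)
    ln_ca = math.log(ca_free)
    log_w = np.array(
        [
            0.0,
            -energies.dg_n / rt + 2.0 * ln_ca,
            -energies.dg_c / rt + 2.0 * ln_ca,
            -(energies.dg_n + energies.dg_c) / rt + 4.0 * ln_ca,
        ]
    )
    w = np.exp(log_w - log_w.max())
    f = w / w.sum()
    return CaMSpeciesFractions(ca_free, *map(float, f))


def cterm_occupancy(
    ca_free: float,
    cam_total: float,
    table: CTermAffinityTable,
    energies: LobeBindingEnergies = EVANS_SHEA,
    constants: ThermoConstants = ThermoConstants(),
) -> CTermOccupancy:
    """CTerm occupancy under the free-ligand approximation.

    Each CaM species is present at [X] = f_X * cam_total (the receptor is too
    dilute to deplete it); the CTerm site then partitions as

        b_X = ([X]/Kd_X) / (1 + sum_Y [Y]/Kd_Y),   b_free = 1 / (1 + sum_Y [Y]/Kd_Y).
    """
    if ca_free < 0 or cam_total < 0:
        raise ValueError("concentrations must be non-negative")
    fractions = cam_fractions(ca_free, energies, constants)
    ratios = fractions.as_array() * cam_total / table.kds()
    denom = 1.0 + ratios.sum()
    b = ratios / denom
    return CTermOccupancy(
        ca_free, cam_total, *map(float, b), b_free=float(1.0 / denom)
    )


def exact_occupancy(
    ca_free: float,
    cam_total: float,
    cterm_total: float,
    table: CTermAffinityTable,
    energies: LobeBindingEnergies = EVANS_SHEA,
    constants: ThermoConstants = ThermoConstants(),
    rtol: float = 1e-12,
) -> CTermOccupancy:
    """CTerm occupancy from the full mass balance with CaM depletion.

    Free Ca2+ is clamped by the bath, so free CaM remains speciated at the
    partition-function fractions f_X while CTerm binding depletes the shared
    CaM pool: with C the free-CaM total and P the total CTerm,

        C + P * S(C) / (1 + S(C)) = cam_total,   S(C) = sum_X f_X C / Kd_X.

    The single unknown C is bracketed on [max(0, cam_total - P), cam_total]
    and solved with Brent's method; occupancy then follows the same
    competitive partition as :func:`cterm_occupancy` evaluated at the free
    (rather than total) CaM concentration.  Converges to
    :func:`cterm_occupancy` as cterm_total/cam_total -> 0.

    Raises
    ------
    RuntimeError
        If the scalar solve fails to converge; the message reports the
        residual at the last iterate.
    """
    if min(ca_free, cam_total, cterm_total) < 0:
        raise ValueError("concentrations must be non-negative")
    if cterm_total == 0.0 or cam_total == 0.0:
        return cterm_occupancy(ca_free, cam_total, table, energies, constants)

    fractions = cam_fractions(ca_free, energies, constants).as_array()
    inv_kd_eff = float((fractions / table.kds()).sum())  # 1/M, lumped affinity
    p = cterm_total

    def residual(c: float) -> float:
        s = inv_kd_eff * c
        return c + p * s / (1.0 + s) - cam_total

    lo = max(0.0, cam_total - p)
    try:
        c_free = brentq(residual, lo, cam_total, xtol=1e-300, rtol=max(rtol, 4e-16))
    except ValueError as exc:  # pragma: no cover - bracket is analytic
        raise RuntimeError(
            f"mass-balance solve failed: residual({lo:.3e})={residual(lo):.3e}, "
            f"residual({cam_total:.3e})={residual(cam_total):.3e}"
        ) from exc
    res = residual(c_free)
    if abs(res) > 1e-6 * cam_total:
        raise RuntimeError(f"mass-balance solve did not converge: residual={res:.3e}")

    ratios = fractions * c_free / table.kds()
    denom = 1.0 + float(ratios.sum())
    b = ratios / denom
    return CTermOccupancy(
        ca_free, cam_total, *map(float, b), b_free=float(1.0 / denom)
    )


def _validate_grid(grid: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(grid), dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} grid must be non-empty")
    if np.any(arr <= 0):
        raise ValueError(f"{name} grid must be strictly positive")
    if arr.size > 1 and np.any(np.diff(arr) <= 0):
        raise ValueError(f"{name} grid must be strictly increasing")
    return arr


def population_surface(
    ca_grid: Sequence[float],
    cam_grid: Sequence[float],
    table: CTermAffinityTable,
    energies: LobeBindingEnergies = EVANS_SHEA,
    constants: ThermoConstants = ThermoConstants(),
) -> PopulationSurface:
    """Evaluate :func:`cterm_occupancy` on every (Ca2+, CaM) grid cell."""
    ca = _validate_grid(ca_grid, "ca")
    cam = _validate_grid(cam_grid, "cam")
    fractions = {s: np.empty((ca.size, cam.size)) for s in SPECIES_WITH_FREE}
    for i, ca_i in enumerate(ca):
        for j, cam_j in enumerate(cam):
            occ = cterm_occupancy(ca_i, cam_j, table, energies, constants)
            for s, v in occ.as_dict().items():
                fractions[s][i, j] = v
    metadata = {
        "isoform": table.isoform,
        "construct": table.construct,
        "kd_M": dict(zip(SPECIES, map(float, table.kds()))),
        "lobe_energies": {
            "dg_n": energies.dg_n,
            "dg_c": energies.dg_c,
            "source": energies.source_label,
        },
        "temperature_K": constants.temperature,
        "gas_constant_kcal_per_mol_K": constants.gas_constant,
    }
    return PopulationSurface(ca, cam, fractions, metadata)


def dominant_species(occupancy: CTermOccupancy, include_free: bool = False) -> str:
    """Label of the most populated CTerm state.

    Considers the four bound species, plus free CTerm when ``include_free``.
    Exact ties resolve to the earliest label in the fixed order
    apo < 2N < 2C < 4 < free (np.argmax keeps the first maximum).
    """
    if include_free:
        values, labels = occupancy.as_array(), SPECIES_WITH_FREE
    else:
        values, labels = occupancy.bound_array(), SPECIES
    return labels[int(np.argmax(values))]


def default_ca_grid(n: int = 50) -> np.ndarray:
    """Log-spaced free Ca2+ grid, 10 nM to 1 mM (resting to uncaging-peak range)."""
    return np.logspace(-8, -3, n)


def default_cam_grid(n: int = 50) -> np.ndarray:
    """Log-spaced total CaM grid, 0.1 uM to 100 uM."""
    return np.logspace(-7, -4, n)
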