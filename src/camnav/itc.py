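"""One-site ITC binding isotherm: forward model, simulator and fitter.

The forward model is the standard single-site isotherm for a titration in
which ligand (CaM) is injected into a cell containing the macromolecule
(CTerm).  Each injection displaces an equal volume of cell contents (the
overflow convention of perfusion-type calorimeters): after injecting dV into
a cell of volume V0, every cell concentration is scaled by (1 - dV/V0) and
the titrant gains syringe_conc * dV/V0.  The heat of injection i is the
enthalpy of the *newly formed* complex,

    q_i = dH * V0 * ( [MX]_i - [MX]_{i-1} * (1 - dV_i/V0) ),

in which the second term is the pre-existing complex surviving in the cell.
Heats of dilution are taken as zero.

The bound-complex concentration at each step is the closed-form root of the
one-site mass balance: with n binding sites per monomer, total sites
S = n * M_t and total ligand X_t,

    [MX] = ( (S + X_t + Kd) - sqrt( (S + X_t + Kd)^2 - 4 S X_t ) ) / 2.

Fitting is weighted nonlinear least squares (lmfit / Levenberg-Marquardt)
against the same forward model, with Kd handled on a log scale and a coarse
log-grid pre-scan to make the default initialisation robust across c-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np

__all__ = [
    "TitrationProtocol",
    "OneSiteParams",
    "Thermogram",
    "FitResult",
    "predict_heats",
    "simulate_thermogram",
    "fit_one_site",
    "default_protocol",
]

KCAL_TO_UCAL = 1e9  # 1 kcal = 1e9 ucal


@dataclass(frozen=True)
class TitrationProtocol:
    """Cell and syringe setup of one titration.

    All volumes in litres, concentrations in molar.  ``injection_volumes`` is
    the ordered list of injection volumes.
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injection_volumes", tuple(float(v) for v in self.injection_volumes)
        )
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if len(self.injection_volumes) < 2:
            raise ValueError("at least 2 injections are required")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def molar_ratios(self) -> np.ndarray:
        """Cumulative titrant/macromolecule molar ratio after each injection."""
        m, x = _concentration_ladder(self)
        return x / m


@dataclass(frozen=True)
class OneSiteParams:
    """Stoichiometry, dissociation constant (molar) and enthalpy (kcal mol-1)."""

    n: float
    kd: float
    dh: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("stoichiometry n must be positive")
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if not math.isfinite(self.dh):
            raise ValueError("dh must be finite")


@dataclass(frozen=True)
class Thermogram:
    """Per-injection heats (ucal) together with the protocol that produced them."""

    protocol: TitrationProtocol
    heats: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "heats", tuple(float(q) for q in self.heats))
        if len(self.heats) != self.protocol.n_injections:
            raise ValueError("heats and injection_volumes must have equal length")


@dataclass
class FitResult:
    params: Optional[OneSiteParams]
    param_errors: dict[str, float] = field(default_factory=dict)
    residuals: Optional[np.ndarray] = None
    converged: bool = False
    message: str = ""


def _bound_complex(m_tot: float, x_tot: float, n: float, kd: float) -> float:
    """Closed-form [MX] of the one-site mass balance (stable quadratic root)."""
    sites = n * m_tot
    b = sites + x_tot + kd
    disc = b * b - 4.0 * sites * x_tot
    disc = max(disc, 0.0)
    # Citardauq form avoids cancellation when kd << sites + x_tot.
    return 2.0 * sites * x_tot / (b + math.sqrt(disc))


def _concentration_ladder(protocol: TitrationProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Cell macromolecule and titrant concentrations after each injection."""
    m = np.empty(protocol.n_injections)
    x = np.empty(protocol.n_injections)
    m_cur, x_cur = protocol.cell_conc, 0.0
    for i, dv in enumerate(protocol.injection_volumes):
        frac = dv / protocol.cell_volume
        m_cur *= 1.0 - frac
        x_cur = x_cur * (1.0 - frac) + protocol.syringe_conc * frac
        m[i], x[i] = m_cur, x_cur
    return m, x


def predict_heats(protocol: TitrationProtocol, params: OneSiteParams) -> np.ndarray:
    """Per-injection heats (ucal) of the one-site model."""
    m, x = _concentration_ladder(protocol)
    v0 = protocol.cell_volume
    heats = np.empty(protocol.n_injections)
    mx_prev = 0.0
    for i, dv in enumerate(protocol.injection_volumes):
        mx = _bound_complex(m[i], x[i], params.n, params.kd)
        surviving = mx_prev * (1.0 - dv / v0)
        heats[i] = params.dh * v0 * (mx - surviving) * KCAL_TO_UCAL
        mx_prev = mx
    return heats


def simulate_thermogram(
    protocol: TitrationProtocol,
    params: OneSiteParams,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Thermogram:
    """Forward model plus i.i.d. Gaussian heat noise; identical seed, identical output."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    heats = predict_heats(protocol, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.size)
    return Thermogram(protocol, tuple(heats))


def _heuristic_init(thermogram: Thermogram) -> OneSiteParams:
    """Starting values: dH from early injections, n from the half-heat molar
    ratio, Kd refined by a coarse log-grid scan."""
    protocol = thermogram.protocol
    heats = np.asarray(thermogram.heats)
    ratios = protocol.molar_ratios()
    v0 = protocol.cell_volume

    # Early injections in a tight titration bind everything injected.
    injected = protocol.syringe_conc * np.asarray(protocol.injection_volumes)
    dh0 = float(np.mean(heats[:2] / (injected[:2] * KCAL_TO_UCAL)))
    if dh0 == 0.0:
        dh0 = -1.0

    cum = np.cumsum(heats)
    half = 0.5 * cum[-1]
    idx = int(np.argmin(np.abs(cum - half)))
    n0 = float(np.clip(ratios[idx], 0.1, 10.0))

    best_kd, best_sse = None, np.inf
    for kd in np.logspace(-11, -3, 33):
        try:
            pred = predict_heats(protocol, OneSiteParams(n0, kd, dh0))
        except ValueError:
            continue
        sse = float(np.sum((pred - heats) ** 2))
        if sse < best_sse:
            best_kd, best_sse = kd, sse
    return OneSiteParams(n0, best_kd if best_kd is not None else 1e-7, dh0)


def fit_one_site(
    thermogram: Thermogram,
    init: Optional[OneSiteParams] = None,
    weights: Optional[Sequence[float]] = None,
) -> FitResult:
    """Weighted nonlinear least-squares fit of the one-site model.

    Weights default to uniform.  Non-convergence (including degenerate
    all-zero thermograms) is reported with ``converged=False`` and a
    diagnostic message; parameter standard errors are reported only when the
    covariance estimate is available.
    """
    protocol = thermogram.protocol
    heats = np.asarray(thermogram.heats)
    w = np.ones_like(heats) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != heats.shape:
        raise ValueError("weights must match the number of injections")

    scale = float(np.max(np.abs(heats)))
    if scale == 0.0 or not np.isfinite(scale):
        return FitResult(
            params=None,
            residuals=np.zeros_like(heats),
            converged=False,
            message="degenerate thermogram: no measurable heats",
        )

    start = init if init is not None else _heuristic_init(thermogram)

    pars = lmfit.Parameters()
    pars.add("n", value=start.n, min=1e-3, max=100.0)
    pars.add("log10_kd", value=math.log10(start.kd), min=-13.0, max=0.0)
    pars.add("dh", value=start.dh if start.dh != 0 else -1.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        trial = OneSiteParams(p["n"].value, 10.0 ** p["log10_kd"].value, p["dh"].value)
        return (predict_heats(protocol, trial) - heats) * w

    out = lmfit.minimize(residual, pars, method="leastsq")

    fitted = OneSiteParams(
        n=float(out.params["n"].value),
        kd=float(10.0 ** out.params["log10_kd"].value),
        dh=float(out.params["dh"].value),
    )
    res = residual(out.params)
    converged = bool(out.success) and out.errorbars
    errors: dict[str, float] = {}
    if converged:
        errors["n"] = float(out.params["n"].stderr)
        errors["dh"] = float(out.params["dh"].stderr)
        # delta method: sd(Kd) = Kd * ln(10) * sd(log10 Kd)
        errors["kd"] = float(fitted.kd * math.log(10.0) * out.params["log10_kd"].stderr)
    return FitResult(
        params=fitted,
        param_errors=errors,
        residuals=res,
        converged=converged,
        message=str(out.message),
    )


def default_protocol(
    cell_conc: float = 10e-6,
    syringe_conc: float = 150e-6,
    cell_volume: float = 1.4e-3,
    n_injections: int = 25,
    injection_volume: float = 10e-6,
) -> TitrationProtocol:
    """A representative VP-ITC-style protocol: 10 uM macromolecule in a 1.4 mL
    cell titrated with 25 x 10 uL injections of 150 uM ligand."""
    return TitrationProtocol(
        cell_volume=cell_volume,
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        injection_volumes=(injection_volume,) * n_injections,
    )
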