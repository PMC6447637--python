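# Methods

## The coupled-equilibrium model

### CaM speciation (stage 1)

Calmodulin's two lobes each bind a pair of Ca²⁺ ions with strong intra-lobe
cooperativity, so the model collapses each lobe's loading into a single
two-ion event and ignores single-ion intermediates. The species space is
therefore {apo, (Ca²⁺)₂-N, (Ca²⁺)₂-C, (Ca²⁺)₄}. The two-ion association
macro-constant of lobe L is K_L = exp(−ΔG_L/RT) with units M⁻², and with the
lobes loading independently (the four-state thermodynamic square closes with
path-independent free energies — the two printed lobe energies leave no
degrees of freedom for inter-lobe coupling) the populations at clamped free
Ca²⁺ are Boltzmann weights 1, K_N·ca², K_C·ca², K_N·K_C·ca⁴ over their sum.
Weights are evaluated in log space so the partition function stays finite at
arbitrarily high Ca²⁺.

A lobe half-saturates where K_L·ca² = 1, i.e. ca½ = exp(ΔG_L/(2RT)): 20.0 µM
for the N-lobe (−12.82 kcal mol⁻¹) and 3.02 µM for the C-lobe
(−15.06 kcal mol⁻¹). This order-of-magnitude split is what makes the C-lobe
load first as Ca²⁺ rises.

Free Ca²⁺ is an independent, clamped variable throughout: the bath (or the
uncaging step) sets it, and CaM binding does not deplete it. This matches how
the populations are normally plotted — against [Ca²⁺] as an axis.

### Competitive CTerm occupancy (stage 2)

The four CaM species compete for a single site on the channel C-terminal
domain. Under the free-ligand approximation each species is present at
[X] = f_X·[CaM]_total, and the site partitions among the five states
(four bound + free) by the ratios [X]/Kd_X. This approximation rests on
channels being far scarcer than CaM, which holds in cells and in the
modelled concentration regime.

`exact_occupancy` is the validating oracle: it solves the full mass balance
in which CTerm binding depletes CaM. Because free Ca²⁺ is clamped, CaM
molecules interconvert between saturation states through the bath, so the
conserved quantity is **total** CaM, and the free pool remains speciated at
the partition-function fractions. That reduces the balance to one scalar
equation in the free-CaM total, C + P·S/(1+S) = CaM_total with
S = C·Σ f_X/Kd_X, solved by Brent's method on the analytic bracket
[max(0, CaM_total − P), CaM_total]; non-convergence raises with the residual
rather than returning silent garbage. An alternative formulation that
conserves each species separately (appropriate for a pre-mixed cocktail of
non-interconverting mutants rather than wild-type CaM in a Ca²⁺ bath) was
deliberately not used: it is thermodynamically inconsistent with a clamped
Ca²⁺ bath, and it makes the free-ligand approximation fail for minor species
even at receptor/CaM ratios of 10⁻³. With the linkage formulation the
approximation agrees with the oracle to < 1% absolute whenever
CTerm ≤ 10⁻³·CaM (property-tested over 1000 random parameter draws).

### Parameters and defaults

| parameter | default | units | notes |
|---|---|---|---|
| R | 1.9872×10⁻³ | kcal mol⁻¹ K⁻¹ | overridable via `ThermoConstants` |
| T | 298.15 | K | room-temperature calorimetry |
| ΔG_N, ΔG_C | −12.82, −15.06 | kcal mol⁻¹ | `evans_shea` set (default) |
| ΔG_N, ΔG_C (alternate) | −12.7, −14.9 | kcal mol⁻¹ | `linse` set |
| Ca²⁺ grid | 10 nM – 1 mM, 50 pts, log | M | resting to uncaging-peak range |
| CaM grid | 0.1 – 100 µM, 50 pts, log | M | physiological CaM abundance |

The bundled affinity table (`camnav/data/cterm_affinities.csv`) carries the
measured Kd of each CaM species for the NaV1.4 and NaV1.5 CTerm, Long and
Short constructs, together with the fit errors and the published binding
free energies. One published source quotes the NaV1.5/(Ca²⁺)₄ affinity as
70 nM in prose; the tabulated 89 ± 7 nM is used. All concentrations are
molar internally; file and CLI boundaries carry explicit units (nM, µM).

### Sensitivity to the lobe-energy input set

The two published lobe-energy sets differ by 0.12 (N) and 0.16 (C)
kcal mol⁻¹. The C-lobe difference is a 1.3× factor on K_C, i.e. a ~14% shift
of the C-lobe loading transition along the Ca²⁺ axis. Away from that
transition the occupancy curves from the two sets agree to < 0.05 absolute;
at the transition midpoint (free Ca²⁺ ≈ 3–10 µM) pointwise differences reach
~0.07 in the bare species fractions and ~0.10 in the occupancy of the
apo-bound state at 10 µM CaM (the competitive denominator amplifies the
speciation shift). The dominant-species assignments and every qualitative
crossover are unchanged between the sets; the robustness test asserts the
measured bound (< 0.15 everywhere, < 0.05 outside the 0.5–50 µM window).

### Tie-breaking and degenerate inputs

`dominant_species` resolves exact ties by the fixed order
apo < 2N < 2C < 4 < free. Zero Ca²⁺ yields pure apo-CaM; zero CaM yields
fully free CTerm; negative concentrations raise domain errors. Grids must be
non-empty, positive and strictly increasing.

## One-site ITC model

Per-injection heats follow the standard single-site isotherm. The cell is
treated with the overflow (perfusion) convention: injecting dV into volume
V₀ scales every cell concentration by (1 − dV/V₀) and adds titrant at
syringe_conc·dV/V₀. The bound-complex concentration after each injection is
the closed-form quadratic root of the mass balance (evaluated in the
cancellation-safe citardauq form), and the heat of injection i is
ΔH·V₀·([MX]_i − [MX]_{i−1}·(1−dV_i/V₀)) — only newly formed complex
generates heat. Heats of dilution are assumed zero (no blank-subtraction
step is modelled). Heats are reported in µcal, enthalpies in kcal mol⁻¹.

The simulator adds i.i.d. Gaussian noise on per-injection heats — the
simplest defensible instrument model; real thermograms also carry baseline
drift and first-injection artifacts that this generator does not emulate, so
recovery tests bound estimator behaviour under clean noise only.

The fitter runs Levenberg–Marquardt (lmfit) on (n, log₁₀Kd, ΔH) with
positivity enforced by bounds, uniform weights by default (configurable),
and a default initialisation that needs no user input: ΔH from the first two
injection heats, n from the molar ratio at which cumulative heat crosses
half its total, and Kd from a 33-point log-grid pre-scan. Convergence is
reported honestly: an all-zero thermogram or a failed covariance estimate
returns `converged=False` with diagnostics instead of numbers. The reported
Kd standard error is delta-method-propagated from the log-scale fit; across
noisy replicates it tracks the empirical spread within a few percent
(tested at a factor-2 sanity band). First-injection exclusion is not applied
by default (single-replicate convention); callers can pass weights to
downweight or exclude injections.

## Electrophysiology metrics

CDI = 1 − mean(last n_tail post-uncaging peaks)/reference. n_tail defaults
to 3 (the convention is "last three to four"; it is a field, not a rule).
The reference is the last pre-uncaging sweep by default, with mean-of-pre
selectable, since the definition does not specify averaging. Currents are
handled as magnitudes — inward peaks are sign-flipped at ingest — keeping
CDI in [0, 1] for attenuating responses; the statistic is invariant to
uniform scaling of all peaks.

Ratiometric calibration applies [Ca²⁺] = Kd·(R−Rmin)/(Rmax−R) exactly, with
its algebraic inverse and the single-reference Kd back-solve
Kd = Ca_ref·(Rmax−R_ref)/(R_ref−Rmin). Ratios at or above Rmax are a
saturation error; ratios below Rmin are clamped to zero with a warning
(noise around the zero-Ca²⁺ floor).

## Synthetic data

Every generator is a pure function of its arguments and an explicit integer
seed (one `numpy.random.default_rng` stream per call) and returns a
`GeneratorSpec` recording seed, noise model and generating truth alongside
the artifact. The uncaging generator produces an instantaneous step from the
pre-uncaging level to (1−attenuation)·pre — real CDI develops over several
sweeps, which the tail-average statistic is insensitive to. The ratio-trace
generator clips noisy ratios into [Rmin, Rmax) so every sample stays
invertible. The affinity perturber applies independent 10^N(0, σ) factors to
the four Kd's; at σ = 0.1 the NaV1.4 2C-dominance at 10 µM Ca²⁺/CaM is
retained in ~70% of draws — the margin over apo-bound CaM is only 0.084
log₁₀ units, so this claim is genuinely jitter-sensitive, and the test
asserts the analytically expected band rather than near-certain retention.

## Problem sizes

Default analyses use 50×50 log grids (surface), 100–120-point Ca²⁺ scans,
1000 random draws for the oracle-agreement property, and 100 seeds per
condition for the ITC recovery study — sizes at which every result in the
test suite is stable to seed choice while the whole suite runs in seconds.

## Known limitations

- Equilibrium only: no kinetics of CDI onset, no time-dependent occupancy.
- No single-ion CaM microstates and no inter-lobe coupling terms.
- No Mg²⁺ competition; the lobe energies are taken as given inputs.
- One CaM-binding site per CTerm; the post-IQ N-lobe site of NaV1.5 enters
  only through its effect on the measured species Kd's.
- ITC: no multi-site/sequential/competitive models, no raw-power-trace
  baseline handling.
- The free-ligand approximation is validated, not replaced: at comparable
  CTerm and CaM concentrations use `exact_occupancy`.
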