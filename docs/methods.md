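# Methods

## The equilibrium model

### Single-species isodesmic aggregation

A self-oligomer is modelled as a one-dimensional chain of monomers held by
nearest-neighbour contacts. Every monomer addition releases the same Gibbs
free energy ΔG° (kJ/mol, negative = favourable), independent of chain
length — the isodesmic assumption, appropriate for filamentous growth but
not for assemblies whose geometry changes with size. With association
constant K = exp(−ΔG°/RT)/c₀ (standard concentration c₀ = 1 M) the species
concentrations at free monomer m follow the geometric law

    [Aₙ] = Kⁿ⁻¹ mⁿ ,  n = 1, 2, …  (convergent for K·m < 1)

and the closed forms used throughout are

    total mass        m/(1−Km)²
    oligomer particles (n ≥ 2)   K m²/(1−Km)
    oligomer mass     m/(1−Km)² − m .

The mass balance m/(1−Km)² = c_total is a quadratic in x = Km; the package
solves it with the cancellation-free root x = 2τ/(2τ+1+√(4τ+1)), τ = K·c_total,
which is exact to machine precision at any concentration (the test suite
additionally checks it against a pure-bisection oracle at 10⁻¹⁰ relative).

Oligomers and fibrils are structurally distinct states and carry separate
free energies, ΔG°(oligo) and ΔG°(fib). The fibrillar state enters only
through its critical aggregation concentration CAC = c₀·exp(ΔG°(fib)/RT):
once the total peptide concentration exceeds the fibril CAC, the solution
phase (free monomer plus oligomers) is frozen at its state at the CAC and
all excess mass is fibrillar. This "total-concentration cap" makes the
oligomer concentration plateau exactly at the CAC, continuous at the
crossover, and conserves mass identically. With ΔG°(oligo) = −36.3 kJ/mol
and CAC = 222 nM the two-colour-observable oligomer plateau is 18.8 nM;
with CAC = 86 nM it is 3.8 nM — matching the observed ranges (0–20 nM for
Aβ40, 0–4 nM for Aβ42) of the steady-state experiments. An alternative
reading — capping the free monomer itself at the fibril CAC — was
considered and rejected: it moves the plateau onset to ~438 nM total and a
~53 nM observable plateau, inconsistent with both the data range and the
description of the plateau beginning when the *total* concentration
reaches the CAC. No fibril length distribution is modelled; fibril length
never enters any reported quantity.

### Two-species co-oligomer (dimer) model

At nanomolar concentrations the single-species model predicts oligomer
populations utterly dominated by dimers (the size ratio [Aₙ₊₁]/[Aₙ] = K·m
is ~1.3×10⁻³ at 1 nM), so the Aβ40/Aβ42 mixture is truncated at dimers:

    [AA] = K_AA a² ,  [BB] = K_BB b² ,  [AB] = g·K_AB a b

with free monomers a, b and the heterodimer degeneracy factor g. An AB
pair has two distinguishable arrangements where AA and BB have one, so
g = 2 is the default; g = 1 (degeneracy absorbed into K_AB) is supported
because published heterodimer free energies do not always state the
convention, and scenario reports print both. The coupled mass balances

    a + 2K_AA a² + gK_AB a b = c_A ,  b + 2K_BB b² + gK_AB a b = c_B

are solved by damped alternating substitution: holding b, the balance for
a is a quadratic with a unique positive root (solved in rationalised
form), and vice versa; each sweep relaxes halfway toward the new root
(relaxation 0.5) and iteration stops when both relative residuals fall
below 10⁻¹². The substitution map is monotone, so the positive fixed point
is unique; non-convergence within 500 sweeps raises an error with
diagnostics (never observed over the tested parameter ranges). The test
suite verifies the solution against two independent routes: nested Brent
root-finding, and direct minimisation of the ideal-solution Gibbs free
energy over the three dimer concentrations (whose stationarity conditions
are exactly the mass-action laws, including the g inside the mixing-entropy
term). Per-isoform fibril caps are off by default for the mixed system —
the 1:1 mixed measurements show no plateau, consistent with both isoforms
remaining below their CACs — but can be enabled for extrapolation.

### Observation model

TCCD counts assemblies carrying at least one blue- and one red-labelled
monomer. With independent random labelling at blue fraction p (0.5 for 1:1
mixing of identically behaving labelled stocks) the coincident fraction of
n-mers is 1 − pⁿ − (1−p)ⁿ: 0 for monomers, 0.5 for dimers at p = 0.5,
approaching 1 for large n. For a self system the coincidence-filtered
concentration has the closed form

    [x²/(1−x) − (px)²/(1−px) − (qx)²/(1−qx)]/K ,  x = Km, q = 1−p.

In the cross-colour mixed experiment (Aβ40 blue, Aβ42 red) only the AB
heterodimer is two-coloured, so the observable is [AB] alone. Model curves
are fitted in the coincidence-filtered ("coincident") space by default —
the assumption-free choice, since whether published curves were corrected
for single-colour oligomers is not stated — with a `"true"`-space option.
The burst-level instrument physics (thresholds, chance coincidence,
calibration against a DNA standard) is upstream of this package: inputs
are already concentrations.

## Fitting

Estimators follow the scikit-learn contract so they compose with
`sklearn` model selection and pipelines. The objective is unweighted least
squares on nanomolar concentrations (an inverse-variance weighting over
replicate SDs is available). `SelfOligomerFit` optimises (ΔG°(oligo),
log₁₀ CAC_fib) by bounded Powell search from a 5×5 start grid over
ΔG° ∈ [−45, −25] kJ/mol, CAC ∈ [10, 1000] nM, plus a data-driven start at
the estimated plateau onset; the best converged optimum is kept, ties
broken toward lower ΔG°, and boundary-pinned optima are flagged rather
than hidden. `MixedDimerFit` is a 1-D bounded scalar minimisation over
ΔG°(AB) with the self parameters held fixed (matching the one-parameter
design of the mixed experiment). Everything is deterministic given the
data.

The plateau-onset initialiser is a model-free changepoint: the observed
curve rises with local log–log slope ≈ 2 in the dilute regime, so a
trailing run of inter-point slopes below half the maximum rising slope
marks the cap; the onset is the crossing of the fitted rising power law
with the plateau level. Flat data yield the first grid point; data that
keep rising yield a not-in-range sentinel (∞), which the fit records as a
`no_plateau_in_range` flag (the CAC is then unidentifiable from above).

Uncertainties are percentile intervals from a case-resampling bootstrap:
within each total concentration the replicate measurements are resampled
with replacement and the fit repeated (default 1000 draws; every draw uses
the recorded seed, so reports are byte-reproducible). The experiments have
three replicates per concentration; at least two are required to resample.

## Synthetic data

The generator evaluates the model curve on the experimental grid —
1–250 nM, nine roughly log-spaced points (1, 5, 10, 25, 50, 100, 150, 200,
250 nM), three replicates per point — and applies unit-mean multiplicative
lognormal noise with CV 0.35, clipped below at a detection floor (default
0). Lognormal noise was chosen over additive Gaussian because
concentrations are positive and relative error dominates at these scales;
the CV reflects the large sample-to-sample variation of the single-molecule
measurements. What the generator emulates: replicate scatter, the
grow-then-plateau shape, the coincidence-filtered observable, and the
per-system magnitudes (~0–20 nM Aβ40, ~0–4 nM Aβ42, and 0–3 nM for the
mixed series under the g = 1 convention). What it does not emulate:
incubation-time kinetics (steady state is assumed attained), detection-
floor censoring structure, inter-day calibration drift, or any correlation
between replicates — so parameter-recovery results certify the inference
machinery under idealised noise, not the field performance of the assay.

## Predictions and scenarios

Membrane-bound oligomers are counted as dimer particles weighted by
relative membrane affinities w_AA : w_AB : w_BB = 1 : 2 : 4 (Aβ42 dimers
bind neuronal membranes ~4× as strongly as Aβ40 dimers; co-dimers are
assigned the intermediate value), normalised to pure Aβ40 at the baseline
concentration — only relative bound numbers are meaningful, and the result
is invariant under common rescaling of the weights. No surface-site
saturation or monomer binding is modelled. In the dilute regime every
dimer concentration is quadratic in total peptide, so a fold change f
multiplies oligomer numbers by ≈ f²; the 1.5× scenario gives +124.5%
exactly at 1 nM (125% in the dilute limit). The bound-oligomer curve over
the Aβ42 fraction has a single interior minimum, analytically at
x* = (2w_AA K_AA − w_AB g K_AB)/(2w_AA K_AA + 2w_BB K_BB − 2w_AB g K_AB)
in the dilute limit (≈ 0.129 at the default parameters, near the
physiological 9:1 ratio). The 22:1 Aβ42:Aβ40 scenario is evaluated at
unchanged 1 nM total concentration. Fraction sweeps default to 101
inclusive grid points.

## Parameters and defaults

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| temperature | 310.15 | K | incubation temperature (37 °C); uniquely consistent with both printed CAC↔ΔG° conversions (298.15 K is not) |
| standard_concentration | 1.0 | M | reference state c₀ in ΔG° = RT ln(CAC/c₀) |
| dG_oligo (A, B) | −36.3 | kJ/mol | fitted oligomer monomer-addition free energies |
| dG_AB | −32.6 | kJ/mol | fitted heterodimer bond free energy |
| cac_fib (A, B) | 222, 86 | nM | fitted fibril critical aggregation concentrations |
| hetero_degeneracy | 2 | — | statistical factor g in [AB] = g·K_AB·a·b |
| affinity weights | 1, 2, 4 | — | relative membrane affinities of AA, AB, BB dimers |
| noise CV | 0.35 | — | replicate coefficient of variation of the generator |
| n_max | 1000 | — | explicit size-distribution cutoff (fibrils live beyond ~10³ monomers; closed forms used wherever possible) |

## Numerical choices and degenerate inputs

- All concentrations are molar internally; the CSV/CLI boundary is
  nanomolar and free energies are kJ/mol everywhere.
- Zero total concentration returns an all-zero state; zero observed
  vectors raise a fit error for self systems and pin ΔG°(AB) at its upper
  bound (flagged) for the mixed fit, where "no heterodimers seen" is a
  one-sided statement.
- Supersaturated inputs (K·m ≥ 1) raise a dedicated error rather than
  returning divergent sums.
- Composition fractions are undefined (error) when no dimers are present.
- ΔG° ↔ CAC conversions round-trip to 10⁻¹² relative; a CAC at or above
  c₀ warns (non-negative implied free energy) instead of failing.

## Problem sizes

The test suite works at the scale of the original experiments: 9
concentrations × 3 replicates per dataset; 100 simulated datasets for the
parameter-recovery check; 200 random parameter draws for mass-conservation
properties; 20 instances per solver-oracle comparison; bootstrap examples
use 20–30 draws (the package default is 1000).

## Known limitations

- The model is strictly thermodynamic: no nucleation kinetics, no rates,
  no pathway information; steady state is assumed attained.
- The dimer truncation of the mixed model is justified only at dilute
  (sub-CAC) concentrations; it is not a general co-polymerisation model.
- The oligomer/fibril split is a hard cap at the fibril CAC; no mixed
  fibrils and no fibril length distribution.
- Absolute membrane-bound concentrations are out of reach by design; only
  ratios under the stated affinity assumptions are reported.
- The in-vivo situation involves clearance, surfaces and crowding; the
  package predicts equilibrium populations, which exceed in-vivo oligomer
  observations above fibril-containing compartments by design of the model.
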