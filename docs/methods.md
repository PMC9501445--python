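# Methods

Units throughout: energies kcal/mol, heat capacities kcal/mol/K,
temperatures K internally (°C in files and user interfaces), concentrations
mol/L internally (mM / µM in files as labelled). Gas constant
R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹. Reference state: T₀ = 298.15 K,
cref = 0.1 M K⁺.

## Linked-equilibrium model (`core_model`)

Species: U, I, Q, QL, IL, LI, LIL. Elementary steps: the folding steps
U→I and I→Q, binding site 1 (only on the intermediate: I + L → LI,
LI + L → LIL) and binding site 2 (Q + L → QL, I + L → IL, LI + L → LIL).
There is no ligand complex of Q at site 1, and no LQ species.

Temperature propagation of each step:

```
ΔG(T)  = ΔH₀ − T·(ΔH₀ − ΔG₀)/T₀ + ΔCp·[(T − T₀) − T·ln(T/T₀)]
ΔH(T)  = ΔH₀ + ΔCp·(T − T₀)
```

Potassium linkage applies to the folding steps only:
`ΔG(T, cK) = ΔG(T, cref) + n·R·T·ln(cK/cref)`. Entropy is never an
independent parameter; `TΔS₀ = ΔH₀ − ΔG₀` everywhere.

Speciation uses Boltzmann-type weights built from the step constants
(1, K_UI, K_UI·K_IQ, K_UI·K_IQ·K₂·L, K_UI·K₂·L, K_UI·K₁·L, K_UI·K₁·K₂·L²).
The free-ligand level is the root of the ligand-conservation equation,
solved with `scipy.optimize.brentq` on the scaled variable x = L/cL ∈ [0, 1]
at machine-precision tolerances; the equilibrium constants are computed once
per solve. The ligand-free three-state case has a closed form evaluated in
log space.

## Forward models (`observables`)

- **DSC.** Excess heat capacity is d⟨ΔH⟩/dT of the population-weighted
  enthalpy relative to U, evaluated by `np.gradient` on an internal 0.1 K
  grid and interpolated to the data grid. The instrument baseline is a
  quadratic fitted to user-specified low/high temperature windows.
- **CD melting.** Normalised signal f = α_I·f_I + α_U interpolates between
  folded (f = 0) and unfolded (f = 1) linear baselines; f_I is the fraction
  of the unfolded-minus-folded signal change shown by the intermediate at
  the monitoring wavelength.
- **ITC (reverse titration).** DNA (syringe, 70 µM) is titrated into ligand
  (cell, 10 µM; 25 × 10 µL into 1.4 mL by default). Injections use the
  instantaneous-displacement convention
  `c_new = c_old·(1 − dV/V₀) + c_syringe·dV/V₀`. The per-injection heat per
  mole of injected DNA is the change in cell enthalpy content corrected for
  displaced volume and for the enthalpy the DNA carries in from the syringe
  (its ligand-free equilibrium mixture), plus a constant dilution offset.
- **Extinction.** Nearest-neighbour ε₂₆₀ for single strands:
  sum of dinucleotide values minus internal mononucleotides
  (Cantor–Warshaw–Shapiro tables).

## SVD rank analysis (`svd_spectra`)

Plain `numpy.linalg.svd` of the wavelength × temperature matrix. Rank
criteria: singular-value threshold (components above 5% of the largest) and
first-lag autocorrelation of the singular vectors (> 0.8). Synthetic
three-species spectra at 2% noise give rank 3 under both.

## Global fitting (`global_fit`)

`scipy.optimize.least_squares` (trust-region reflective) from
Latin-hypercube multi-starts (`scipy.stats.qmc`). Linear nuisance
parameters are profiled out exactly at each residual evaluation (variable
projection): the quadratic DSC baseline (3 coefficients), the four CD
baseline coefficients via the design [1, t, f, f·t], and the ITC offset.
Only shared thermodynamic parameters and one f_I per CD melting curve are
nonlinear. Weights default to 1/(n·σ²) with σ² estimated from first
differences of each trace. Uncertainties come from the Jacobian
(s²·pinv(JᵀJ)) with a residual-bootstrap alternative. Mechanism comparison
(full scheme, two independent sites, sequential two-site, one-site) ranks
models by AICc, counting profiled offsets in k.

## Phase space (`phase_space`)

Binding decomposition at 25 °C: ΔG_hyd = 80 K × ΔCp, ΔG_int = ΔH,
ΔG_other closes the balance exactly. Pseudophase diagrams label each cell
of a (T, log₁₀ cK) or (T, r = cL/cDNA) grid (minimum 50 × 50, default
200 × 200) with the most populated species; boundaries are refined by
bisection to |f₁ − f₂| < 10⁻⁶ and triple points by a 2-D root solve on the
pairwise fraction gaps, accepted when the three fractions tie within 10⁻⁵.
Failed cells are labelled −1, never silently filled.

## Synthetic data (`synthetic_data`)

No raw thermograms, melting curves or isotherms are deposited for this
system, so fitting and recovery tests run on seeded synthetic data from the
package's own forward models: forward signal at the default (published)
parameter set, smooth instrument baselines, white Gaussian noise (DSC
0.05 kcal mol⁻¹ K⁻¹; CD 2% of signal range; ITC 0.2 kcal/mol of injectant),
the reverse-titration protocol above, and Gaussian-band basis spectra whose
extrema mimic an antiparallel quadruplex. All randomness flows through the
scenario seed; identical seeds give bit-identical datasets. Every dataset
carries its noiseless truth for recovery tests.

The basis-spectrum shapes, noise magnitudes and default problem sizes
(three salt levels, three ITC temperatures, grid steps) are this package's
own choices, selected so the full test suite runs in minutes on one CPU.

## Limitations

- Parameter values are a fixed published set; the package recovers them
  from synthetic data but cannot re-derive them from raw experiments.
- The hydration decomposition uses a literature scaling factor (80 K) with
  ±10 K spread that is not propagated.
- Two-state instrument-level effects (scan-rate kinetics, injection mixing
  time) are not modelled; titration heats assume instantaneous equilibrium.
- Activity coefficients are ignored; the ion linkage is the standard
  log-linear approximation.
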