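# Methods

`ocpkin` implements the computational analyses used to characterize
photoactivation of the Orange Carotenoid Protein (OCP): global and target
analysis of femtosecond transient-absorption (TA) surfaces, slow
photocycle kinetics with Arrhenius analysis, steady-state orange/red
spectral decomposition, and geometry reports from deposited coordinate
files.  This note records the models, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Excited-state kinetic model

The core model is a five-compartment branched scheme for the
keto-carotenoid excited states in OCP.  Photoexcitation at 520 nm populates
S2, which decays with rate constant `k2` into a hot intermediate ("mixed
state") S_H.  S_H branches into S1, an intramolecular charge-transfer state
(ICT) and the long-lived S* state with rate constants `k1`, `k_ICT` and
`k_S*`; those three states decay to the ground state S0 with `m1`, `m_ICT`
and `m_S*`.  In matrix form `dX/dt = K X` with columns as source
compartments, so each column of K sums to minus that compartment's
ground-loss rate; the ground state is implicit and recovered as
`X_S0 = 1 − Σ X_i`, which makes probability conservation an exact
invariant of the solver (checked to 1e−10 in the tests).

Populations are computed analytically through the eigendecomposition
`K = V Λ V⁻¹`.  Under a delta-function excitation the response of each
eigenmode is the causal exponential `exp(λ t)·θ(t)`; under a Gaussian
instrument response function (IRF) of width σ centred at t0 it is the
closed form

    g(t) = ½ · exp(λ(t−t0) + λ²σ²/2) · erfc( (−(t−t0) − λσ²) / (σ√2) ),

evaluated via the scaled complementary error function `erfcx` on the branch
where the naive expression overflows.  The default IRF FWHM is 0.026 ps,
the pump-pulse duration of the emulated experiment.  Eigenvalue
degeneracies (which the physical scheme does not generically produce) are
resolved by a relative 1e−9 multiplicative jitter of the rate matrix with a
logged notice, never silently.

Branch yields are `Φ_c = k_c / (k1 + k_ICT + k_S*)`; they sum to 1 exactly
by construction.

### Default rates

The default `ocp_five_state_scheme()` uses lifetimes 0.07 ps (S2), 0.15 ps
(S_H total depletion), 3.0 ps (S1), 0.34 ps (ICT) and 9.3 ps (S*), with
branch fractions 0.50/0.25/0.25 so the S* yield is 25% — the regime
reported for the OCP^WW variant.  The S_H lifetime is the least constrained
of these values (the experimental signature is an ESA accumulation over
300–400 fs) and 0.15 ps should be read as a stand-in of the right order,
not a measured constant.

## Global (DADS) analysis

`GlobalKineticModel` fits all wavelengths simultaneously with a shared set
of exponential lifetimes convolved with the IRF.  The nonlinear parameters
are the log-lifetimes (positivity without constraints) and, by default, the
IRF centre and log-FWHM; at every iterate the wavelength-dependent
amplitudes — the decay-associated difference spectra (DADS) — are solved by
ordinary linear least squares (variable projection), which removes
`n_components × n_wavelengths` linear parameters from the nonlinear
problem.  Optimization uses trust-region least squares (`scipy`'s `trf`)
with function tolerance 1e−10 and an iteration cap of 500; desk-scale
surfaces converge in well under 50 evaluations.  Components are returned in
ascending lifetime order with DADS rows permuted accordingly; DADS signs
are meaningful (negative lobes are rises) and are left free.  Lifetime
pairs closer than a ratio of 1.05 are nearly collinear in the basis and are
flagged with a warning rather than rejected.

When no starting lifetimes are given, log-spaced guesses spanning the
positive delay range are used.

## Target (SAS) analysis and identifiability

`TargetKineticModel` fits the kinetic scheme itself: free rate constants
are optimized in the log domain, populations come from the analytic solver
with the initial condition X_S2(0) = 1, and the species-associated spectra
(SAS) are eliminated by per-wavelength linear least squares exactly as in
the global fit.  The hot intermediate S_H carries its own SAS.  SAS are
signed (ground-state bleach makes true SAS negative in the bleach region),
so no non-negativity is imposed.

**Branch-split identifiability.**  With fully free SAS the individual
branch rates are *structurally unidentifiable*: the population of a branch
target is exactly linear in its feeding rate (`X1 = k1 · (X_H ⊛ e^{−m1 t})`),
so scaling `k1 → βk1` while rescaling `SAS_1 → SAS_1/β` (and adjusting
another branch to keep the total `k1+k_ICT+k_S*` fixed, with its own SAS
compensation) reproduces the data surface exactly.  The test suite
demonstrates this invariance to 1e−10.  The data therefore constrain the
total depopulation rate of S_H and all decay rates, but not the split.
Two policies are offered:

* `branch_policy="tied"` (default): the optimizer varies the identifiable
  total while the branch *fractions* are held at the template's split.
  Reported branch rates are `Φ_template · k_total_fit`.
* `branch_policy="free"`: all rates float; the optimizer then wanders along
  the exactly flat directions driven only by finite-difference noise, and
  the affected confidence intervals (computed from the SVD of the Jacobian)
  come out orders of magnitude wider than the estimates, which is noted on
  the result.

This means a reported 25% S* yield is conditional on the assumed branch
split or, equivalently, on the SAS amplitude scale — a caveat that applies
to any target analysis with free species spectra, not only to this
implementation.

Confidence intervals for all rates come from the linearized covariance at
the optimum (delta method through the log parametrization).  Residual
diagnostics include the RMS and, in the tests, the lag-1 autocorrelation of
the residuals (< 0.1 on correctly specified fits).

`transform_sas_to_dads` bridges the two representations: with
`X(t) = V diag(e^{λt}) V⁻¹ x0`, the compartment surface regroups into modes
with `DADS = (V diag(V⁻¹x0))ᵀ · SAS`, and the two reconstructions agree
pointwise (1e−10, tested on random acyclic schemes).

## Chirp (group-delay) correction

The supercontinuum probe is dispersed, so time zero varies with wavelength.
The model is a polynomial `t0(λ) = Σ a_j ((λ−λc)/100 nm)^j` of order ≤ 4.
Estimation uses a parameter-free onset proxy per wavelength: the delay at
which |ΔA|, lightly smoothed with a 5-sample moving average, first reaches
50% of its extremum, with the crossing located by linear interpolation.
The smoothing matters: without it the *first* noisy sample above threshold
triggers the crossing, an extreme-value bias that grows with grid density.
Columns with peak signal below 5% of the surface maximum are excluded.

Correction re-interpolates each wavelength column onto the common delay
axis shifted by −t0(λ) using piecewise-linear interpolation (splines ring
on sparse delay grids); samples shifted outside the measured range are
zero-filled and counted in the dataset's warning list, and a shift
exceeding half the delay span triggers a warning rather than silence.  The
zero model returns the input unchanged, bitwise.

Onset-based estimation presumes a prompt signal at each wavelength.  For
surfaces whose red/ESA bands rise only with a delayed population (tens of
femtoseconds later), the onset lags by a kinetics-dependent amount and the
estimate inherits a bias of that order; dispersion should then be
calibrated on a prompt-response measurement, which is what the
parallel-scheme synthetic preset emulates (all compartments populated at
t = 0).

## Photocycle kinetics and Arrhenius analysis

The slow orange ↔ red photocycle is modelled as the minimal two-state
scheme consistent with a monoexponential red-state decay: under actinic
light `dR/dt = k_OR(1−R) − k_RO·R`, in the dark `dR/dt = −k_RO·R`, solved
piecewise in closed form (verified against an adaptive ODE integrator to
1e−9).  The observable is `OD550 = baseline + ΔOD_max · R(t)`.  Richer
photocycles with resolved red intermediates are out of scope and the
two-state form is an acknowledged approximation.

`fit_relaxation` fits a single exponential plus offset to the dark segment
(invariant to baseline and amplitude scaling); `fit_conversion` fits the
light-on rise with `k_RO` fixed from the relaxation fit.  A rise whose
fitted amplitude is indistinguishable from the noise floor yields an
infinite standard error rather than an exception.  `arrhenius_fit` is
ordinary least squares of ln k on 1/T; `E_A = −slope·R` with
R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹, reported in kcal/mol.  Temperatures
are taken in °C at the CLI and converted to kelvin internally.  Duplicate
temperatures are collapsed to their mean ln k with a notice.

With four temperatures spanning 15 K and a 1% scatter on the rates
themselves, the OLS slope has a sampling deviation near 2% — recovery
claims tighter than that are not meaningful at that design.  Fitting the
rates from full traces (hundreds of samples at 1% amplitude noise) reduces
the per-rate error to a few tenths of a percent, and the activation
energies 7.5 and 31.8 kcal/mol used as study conditions are then recovered
within 3%.

## Steady-state decomposition

A dark-adapted spectrum is decomposed as orange + s·red by finding the
largest scale `s ≥ 0` such that `dark − s·red_ref ≥ −ε` everywhere in the
analysis window (default 400–600 nm, the carotenoid S0→S2 band), by
bisection to 1e−6.  ε defaults to 0.5% of the dark-spectrum maximum; it
exists to tolerate noise and baseline imperfections, and for noiseless data
a smaller ε tightens the recovery proportionally.  Fractions are defined on
integrated band area (trapezoidal) rather than peak height; differences in
extinction coefficient between the two forms are not modelled, which is a
stated limitation of area-based fractions.  The scale is monotone in the
true red fraction (property-tested).

The vibronic-structure metric returns `(A_peak − A_trough)/A_peak` for the
two highest adjacent local maxima of the band, 0 for structureless spectra.

## Structure geometry

Coordinate files are parsed with gemmi; atoms are re-exposed as a flat,
altLoc-aware record list.  A distance query must resolve to exactly one
atom: where alternate conformers exist (the 'IN'/'OUT' rotamers of the
engineered tryptophan at position 201) an explicit altLoc is required and
the error lists the candidates; elsewhere the highest-occupancy conformer
is the default.  Hydrogen bonds are reported heavy-atom to heavy-atom
(O···N, O···O).  The carotenoid keto oxygen is identified as the ligand's
sole carbonyl oxygen, robust to nomenclature differences between
depositions.  Cα RMSD uses Kabsch superposition (SVD with the reflection
branch disallowed) after matching residues by author numbering within the
chain pair; unmatched residues are dropped.

The checks against the deposited OCP entries (6T6K/6T6M/6T6O and the WT
reference 4XB5) need the coordinate files locally:
`python scripts/fetch_pdb.py` downloads them once into `data/pdb/`.  All
geometry algorithms are additionally tested on synthetic miniature
structures built in PDB format at test time, including alternate-conformer
handling and rigid-motion invariance.

## Synthetic data

`simulate_ta` builds `ΔA(t,λ) = Σ_i SAS_i(λ)·X_i(t)` from the analytic
populations and Gaussian band shapes (optionally with vibronic
progressions at fixed energy spacing, converted via 10⁷/λ cm⁻¹).  Chirp is
applied *exactly* by shifting the IRF centre per wavelength rather than by
resampling, so the distortion carries no interpolation error.  Noise is
homoscedastic i.i.d. Gaussian from a seeded generator; a seed is a required
field and identical configurations reproduce bitwise.  "SNR 100" in the
presets means σ = max|signal|/100.

The default delay grid samples −1 to 1 ps in 10 fs steps (resolving the
26 fs IRF and the chirp sweep) and continues with 80 log-spaced points to
200 ps; the wavelength grid is 400–910 nm in 5 nm steps.  Band placements
follow the assigned signatures: ground-state bleach as a negative vibronic
progression near 497 nm, S1–SN ESA near 650 nm, ICT ESA above 700 nm, the
S* signature near 555 nm, and the S2–SM ESA at the red edge.

What the generators do **not** emulate: wavelength-dependent (shot/detector)
noise, coherent-artifact spikes around time zero, pump scatter,
anisotropy, spectro-temporal band narrowing, and Franck–Condon band shapes.
Passing closed-loop tests therefore demonstrates correctness of the
estimators under the stated noise model, not robustness to every artifact
of real measurements.

Problem sizes used in the tests and the acceptance script — 103
wavelengths × 281 delays per surface, 10 seeds for recovery statistics,
four temperatures for Arrhenius loops — were chosen as the smallest designs
at which the recovery statistics stabilize.

## Interfaces

Everything is accessible as a library (model/results objects mirroring the
statsmodels idiom, with `summary()` methods) and as the `ocpkin` command
line with subcommands `simulate`, `preprocess`, `fit-global`, `fit-target`,
`arrhenius`, `decompose`, `geometry`.  TA surfaces use a fixed matrix-CSV
dialect (corner cell `nm\ps`, first row delays in ps, first column
wavelengths in nm, body in mOD); kinetic schemes serialize to JSON; numeric
outputs are emitted as schema-tagged JSON for scripting.
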