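# Methods

## Blood–brain-barrier transport model

The tissue unit is a chain of three symmetric four-state glucose
carriers (blood:endothelium, endothelium:interstice,
interstice:intracellular) feeding one Michaelis–Menten hexokinase sink.
Eliminating the four carrier states from the linear balance equations
gives the net flux through one carrier in closed form,

    J = Ct·d·f1·f2·(a − b) / (P·a + Q),   a = kon·G_cis, b = kon·G_trans,
    P = 2·b·f2 + d·(f1+f2) + 2·f1·f2,
    Q = b·d·(f1+f2) + 2·b·f1·f2 + 2·d²·f1 + 4·d·f1·f2,  d = koff,

which is antisymmetric in (a, b), linear in the carrier amount Ct, and
saturates at Ct·d·f1·f2/P. Because J is a Möbius function of `a`, the
inverse problem (the cis concentration sustaining a required flux) is
also closed-form; the steady state of the whole chain therefore reduces
to one bracketed Brent root find on intracellular glucose, with the
blood-glucose mismatch as the (monotone) objective. The flux-balance
residual at the returned solution is below 10⁻⁹ μM/s; the solver is
deterministic. A demand beyond any carrier's saturating flux is
reported as a flagged non-convergence.

An independent transient integrator (`simulate_transient`) evolves all
twelve carrier states plus the three glucose pools (LSODA); its
long-time limit is the cross-check for the algebraic solve. Compartment
volume fractions (defaults 0.04 / 0.001 / 0.20 / 0.76) affect only the
dynamics, never the steady state — equilibration of the intracellular
pool takes ~1 h of model time, which is why the transient path is an
oracle rather than the production solver.

### Parameters and calibration

Carrier rates f1 = 200 s⁻¹, f2 = 3000 s⁻¹, kon = 10⁸ M⁻¹s⁻¹,
koff = 4×10⁶ s⁻¹ on every membrane; amounts 0.2/0.2/2.0 μM (1:1:10).
Gray matter uses HK1 with Vmax = 6.8 μM/s and Km = 0.05 mM. The Km is
carried in millimolar as 0.05 (i.e. 50 μM): the documented gray-matter
operating point (G_in = 1.2 mM with F_hex = 6.5 μM/s under
Vmax = 6.8 μM/s) is only consistent with a Km far below G_in, and a
50 mM Km would also invert the direction of the basal-glucose
sensitivity. HK2's Km is 5.6× the HK1 value (0.28 mM), inside the
3–10× range reported for the isoforms.

Simulation clamp levels default to 100 mg/dL (5.55 mM) and 300 mg/dL
(16.65 mM) — the upper ends of the protocol target ranges, matching the
achieved plasma plateaus (104.3 and 301.5 mg/dL). The euglycemic
choice is pinned by the model itself: at 5.55 mM blood glucose the
gray-matter tissue sits at G_in = 1.23 mM and F_hex = 6.54 μM/s, i.e.
the documented operating point at the printed precision.

White matter is calibrated by (i) setting
Vmax = F_target·(Km+G_target)/G_target and (ii) uniformly scaling all
three carrier amounts (preserving 1:1:10) until the euglycemic solve
lands on G_target; scaling a single membrane instead is available and
changes the clamp-contrast percent flux change by <0.1 percentage
points. Defaults: G_target one-third of the gray steady state, F_target
the gray flux divided by 1.7 (the study's gray/white CMRglc contrast).
Under these conditions the white-matter flux rises by 41% between the
clamp levels (16% when G_target equals the gray value), versus a ~3%
gray-matter response. The 41% sits below the ~50% the source study
quotes for this configuration; we find no parameterisation consistent
with the printed rate constants, the G_in = 1.2 mM anchor and the
stated clamp targets that yields 50% — reaching it requires a
hyperglycemic level near 450 mg/dL, or abandoning the euglycemic anchor
(90→300 mg/dL gives 50.5% but pushes the equal-basal case to 19.8%).
The sensitivity directions (flux change increasing in Km, decreasing in
basal glucose) and the equal-basal 16% figure reproduce exactly.

## FDG kinetics

The reversible two-tissue model is solved analytically: the impulse
response of C₁+C₂ is a biexponential with exponents
a₁,₂ = ((k₂+k₃+k₄) ∓ √((k₂+k₃+k₄)² − 4k₂k₄))/2. The arterial input is
interpolated piecewise-linearly on a 1-s grid and convolved with each
exponential by the exact per-interval recursion (a first-order IIR
filter), so the forward model carries no quadrature error beyond the
input interpolation — it matches a stiff ODE integration to ~10⁻¹⁰.
The measured signal is (1−V_b)(C₁+C₂) + V_b·C_wb, averaged within
frames (trapezoidal). K₁ is carried in mL/hg/min with 1 hg ≡ 100 mL of
tissue; activities are assumed decay-corrected.

Fitting is bounded trust-region least squares (K₁∈[0,60], k₂,k₃∈[0,2],
k₄∈[0,0.2], V_b∈[0,0.2]; start (6, 0.3, 0.1, 0.01, 0.05); three seeded
random restarts on non-convergence). Two weighting modes: the default
duration/activity variance proxy, and a "proportional" mode for
signal-proportional noise that refits once with weights from the
inverse squared *model-predicted* activity (predicted rather than
observed, to avoid weight–residual correlation bias). Under 5%
proportional noise on the 25-frame hour-long scheme the proportional
mode keeps the median |K₁| error at 3–5%; k₄ is the least identifiable
parameter and its spread exceeds K₁'s several-fold at high noise.

The basis-function parametric fitter precomputes Cp⊗e^(−θt) on a θ
grid, solves every ordered exponent pair plus the whole-blood term per
voxel by linear least squares (non-negative amplitudes, V_b ≤ 0.2
required), and keeps the grid minimum. The spatial constraint — one
pass shrinking each voxel's exponent pair toward its 3×3×3
neighbourhood median (weight 0.5), snapping back to the grid, and
re-solving the linear step — is this package's own formulation of a
smoothness prior for hierarchical basis schemes; it is exactly neutral
on spatially constant volumes and can be disabled.

CMRglc = G_p·K₁·k₃/(k₂+k₃)/LC with LC = 0.81 by default. The
glucose-adjusted table interpolates LC piecewise-linearly between
(5 mM, 0.81) and (15 mM, 0.7614), embodying the ~6% hyperglycemic
decrease extrapolated from rat data; queries outside the table clamp to
the boundary with a warning.

## Regional pipeline

SUVR divides an uptake image by the mean over a reference mask; rOGI is
the voxelwise O₂-SUVR/FDG-SUVR ratio renormalised to a unit
reference-region mean (zero denominators are masked and counted). The
reference region is chosen empirically: the n (default 3) parcellation
regions with the smallest absolute condition change in the regional
table, computed from subject-level means using all available subjects
per condition (unpaired subjects contribute where they have data), with
deterministic label-order tie-breaks.

The condition contrast at each voxel is `value ~ condition` with a
subject random intercept. Estimation is an own vectorised REML: for the
random-intercept structure, V = I + λZZᵀ gives closed-form GLS,
log-determinants and the REML criterion for any λ, so the variance
ratio is profiled on a dense log grid (601 points, 10⁻⁶–10⁶)
simultaneously for all voxels. Agreement with statsmodels MixedLM is at
machine precision for the effect and <0.5% for its standard error. The
Wald statistic is referred to a t distribution with containment degrees
of freedom n_obs − n_subjects − (p−1) — the exact paired-t df in the
balanced case; measured null tail probabilities match the nominal ones
at 0.05 through 0.001, where the large-sample normal reference (kept as
an option) is anticonservative by a factor ~2 at n = 8 subjects.
Multiple testing uses Benjamini–Hochberg step-up (Benjamini–Yekutieli
by flag).

Images are Gaussian-smoothed (5 mm FWHM) before statistics by default,
mirroring the imaging pipeline. On the tiny synthetic phantom the
localisation checks run unsmoothed: smoothing deliberately trades
localisation for SNR, and on a phantom whose effect region is a few
voxels across it converts a ring of truly-null neighbours into genuine
post-smoothing effects, making a sharp-truth false-discovery proportion
ill-defined; the phantom's piecewise-constant regions need no SNR help.

## Clamp timecourse model

Per analyte, the population curve is a hinge regression: intercept,
condition indicator, time, time×condition, and one
max(0, t−55 min) hinge per condition — continuous at the breakpoint by
construction (the breakpoint is fixed, not estimated). Random
intercepts for subject and for visit nested within subject; REML via
statsmodels MixedLM; asymptotic-normal 95% CIs; slopes tested at
p < 0.05 uncorrected. With exactly zero residual variance (noiseless
synthetic data) the mixed model is degenerate and the same design is
solved by OLS, reported as such. Generator defaults encode the study's
series: baseline 83.6 mg/dL in both conditions, plateaus 104.3 and
301.5 mg/dL reached at 55 min, slight negative post-breakpoint drift,
residual SD 4 mg/dL, subject/visit intercept SDs 3 and 2 mg/dL.

## Expression analysis

Single-cell matrices are binarized at count > 0 (the isoform panel
defaults to HK1, HK2, HK3, GCK and is configuration, not code);
fractions are tabulated per cell type or per class, and the
non-neuronal share of expressing cells is reported per gene. Regional
statistics correlate the per-region expression ratio of two genes
against a metabolic change table over shared regions (Pearson).
External atlas data enter only through generic MTX/CSV adapters; no
downloaders are shipped.

## Synthetic data

Every generator is a pure function of (config, seed) and emits its
latent truth. The arterial input is a Feng-style gamma-variate bolus
with triexponential clearance, sampled densely over the bolus and
sparsely late, with whole blood at 0.85× plasma. TAC replicates apply
proportional Gaussian noise to the analytic forward model at the
study's condition kinetics (K₁ 12.67 eu / 6.61 hyper mL/hg/min). The
image phantom is a 16×16×10 labelled box — white core, eight gray
octants, three designated reference regions — with gray/white baselines
32/19 μMol/hg/min (whole-brain ≈ 30.7, contrast ≈ 1.7), a ×1.62
hyperglycemic white-matter scaling, subject random intercepts and
voxel noise; the reference regions reuse the euglycemic noise
realisation so their observed change is exactly zero (the
"metabolically stable" anchor the selection step is meant to find),
and every other non-white voxel is an exact null. The construction
concentrates the increase where baseline is lowest, giving the strong
inverse baseline-change coupling (|r| ≈ 0.92–0.99 across seeds).
Expression counts are Bernoulli-thinned with per-type probabilities
that make HK2 nearly absent from neurons and majority-isoform only in
microglia; regional expression ratios are coupled to a metabolic map
through a seeded Gaussian copula at a target correlation.

What the generators do **not** emulate: scanner physics (point-spread,
partial volume, attenuation, motion), anatomy, metabolite correction,
insulin dynamics, or realistic single-cell library-size variation.
Passing tests therefore demonstrate the correctness and calibration of
the estimators under the stated statistical structure, not robustness
to real-data artefacts.

## Problem sizes

Defaults are chosen for desk-scale runs: 16×16×10 phantom (2 560
voxels, <1 s per voxelwise analysis), 25-frame TACs on a 1-s
convolution grid (~50 ms per kinetic fit), 10-subject clamp series
(~0.3 s per mixed-model fit), 5 000-cell expression matrices. All are
configuration fields.

## Known limitations

- The transport model inherits its rate constants from the literature;
  no fitting to measured data is provided, and the white-matter percent
  flux change depends on the assumed clamp levels (documented above).
- The basis-function spatial constraint is a stated reimplementation
  choice, not a published algorithm's exact form.
- Containment df are exact only for the balanced paired design; heavily
  unbalanced designs would warrant Satterthwaite-type corrections.
- rOGI is computed per subject and then modelled; computing it from
  group means instead would change small-sample behaviour.
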