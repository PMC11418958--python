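# neuroglyc

Analysis toolkit for PET glucose-clamp studies of human brain energy
metabolism: why does acute hyperglycemia raise glucose consumption in
white matter but not cortex, without any change in oxygen use?

The package is written for imaging neuroscientists and modellers who
want to reproduce or extend that analysis chain: a mechanistic
blood-brain-barrier transport simulator, [¹⁸F]FDG kinetic modelling,
SUVR/rOGI regional statistics, clamp-timecourse regression, and
hexokinase-isoform expression summaries — with seeded synthetic-data
generators standing in for raw imaging data, so everything runs on a
desk machine with no downloads.

## The models

**Transport.** Glucose crosses three serial membranes (blood →
endothelium → interstice → cell) by facilitated diffusion. Each carrier
is the symmetric four-state alternating transporter (translocation rates
f₁ = 200 s⁻¹ unbound, f₂ = 3000 s⁻¹ bound; K_on = 10⁸ M⁻¹s⁻¹,
K_off = 4×10⁶ s⁻¹; carrier amounts 1:1:10 with 2 μM on the third
membrane). Intracellular glucose is consumed by hexokinase,

    F_hex = Vmax · G_in / (Km + G_in),

with HK1 (gray matter, Km = 0.05 mM — saturated at euglycemia) or HK2
(white matter, Km = 5.6× higher). The steady state equalises the flux
through all three carriers with F_hex; the carrier flux law is solved in
closed form, so a full tissue solve takes ~1 ms.

**FDG kinetics.** The reversible two-tissue compartment model
(K₁, k₂, k₃, k₄, V_b) with analytic biexponential convolution of the
arterial input, nonlinear least-squares and basis-function parametric
fitting, and CMRglc = G_p·K₁·k₃/(k₂+k₃)/LC with a lumped constant
LC = 0.81, optionally glucose-adjusted.

**Statistics.** Voxelwise linear mixed models (condition fixed effect,
subject random intercept; vectorised REML) with Benjamini–Hochberg FDR;
SUVR/rOGI normalisation against an empirically selected stable reference
region; piecewise-linear mixed regression of clamp timecourses with a
55-min breakpoint and visit-within-subject random intercepts; binarized
single-cell hexokinase isoform fractions.

## Worked example

```bash
python examples/transport_steady_state.py
```

prints

```
tissue   clamp         blood mM  G_in mM  F_hex uM/s
gray     euglycemia        5.55    1.233       6.535
gray     hyperglycemia     16.65    5.267       6.736
white    euglycemia        5.55    0.411       3.844
white    hyperglycemia     16.65    1.457       5.420
gray: flux change eu -> hyper = +3.1 %
white: flux change eu -> hyper = +41.0 %
```

At euglycemia the gray-matter tissue sits at G_in ≈ 1.2 mM and
F_hex ≈ 6.5 μM/s; tripling blood glucose moves its flux by only ~3%
because HK1 is saturated. The white-matter HK2 tissue, calibrated to a
third of the gray intracellular glucose and 1.7-fold lower flux, is far
from saturation and increases its flux by ~41% — the mechanistic account
of the selectively raised white-matter glucose consumption during
hyperglycemia.

The other scripts in `examples/` walk through FDG fitting
(`fdg_kinetic_fit.py`), the SUVR/mixed-model pipeline
(`regional_pipeline.py`), clamp regression (`clamp_fit.py`) and
expression fractions (`expression_fractions.py`).

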