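# Methods

## Model structure and assumptions

The pipeline chains three stages, each expressed relative to its dark
stationary level so that every species starts at 1 (except Pfr, which
jumps to R_Pfr at the light switch) and darkness is an exact fixed point
of the whole cascade.

**PhyB (two-state photoreceptor).** Pr and Pfr interconvert fast compared
with their turnover, so the pair collapses to one linear ODE for total
PhyB with composite decay factor Q_Pfr and Pfr fraction R_Pfr. The exact
two-variable system is retained (`integrate_two_state_ode(form="two_state")`)
purely as a numerical oracle for the reduction; its validity requires the
photoconversion rates to exceed the decay rates by orders of magnitude,
which holds for physiological light fluxes. A single dark→light switch at
t = 0 is assumed throughout; light–dark cycling is out of scope, and
additional PhyB states (nuclear bodies, heterodimers) are absorbed into
the effective constants.

**PIF3.** The mechanistic three-variable system (monomer, dimer,
phosphorylated dimer) reduces to one ODE when (i) dimerization
equilibrates fast, (ii) de-phosphorylation is slow compared with both
phosphorylation and proteasomal removal, and (iii) unphosphorylated
dimers are long-lived. `PIFFullParams.regime_flags` evaluates these
conditions; `REGIME_FIXTURE` is a synthetic parameter set satisfying them
that collapses exactly onto the default reduced model (the mechanistic
rate constants are not individually measured, so this fixture is an
internal-consistency device, not a calibration). Two caveats found while
implementing the full system: the dimer pool buffers the fast monomer
decay, so the reduction is only accurate when the dimerized fraction is
small (the fixture uses K_dim^PIF·[PIF]_D = 0.02, giving ≤ 2% tracking
error after the first ~1 h); and mass consistency requires the
phosphorylation flux leaving the dimer pool to equal the flux entering
the phosphorylated pool, which fixes the form of the third equation.

**Interaction strength and light quality.** R_PP lumps the
phosphorylation rate, both dimer equilibria, the dark PIF3 level and the
*squared red-light Pfr fraction* (0.875²). The reduced equation is
therefore written in terms of [PhyB], valid at the red-light
photoequilibrium where it was calibrated. The solvers rescale R_PP by
(R_Pfr/0.875)² so that other photoequilibria — darkness in particular,
where the drive must vanish even though scaled [PhyB] ≡ 1 — behave
physically. At the default photoequilibrium this is the identity.

**Gene expression.** PIF3 binds target promoters as a dimer; the
occupancy-based synthesis rate gives the relative drive
φ = (K_PIF+1)/(K_PIF+[PIF]²), and transcript level follows a linear
relaxation toward φ. The convolution-integral solution (adaptive
quadrature over an interpolant of φ) serves as an independent oracle for
the ODE route; the two agree to ≤ 1e-4 relative on all six default genes.

## Parameters

| parameter | default | unit | origin |
|---|---|---|---|
| K_Pfr | 7 | – | 13% residual Pr in red light |
| Q_Pfr | 8.75 | – | PhyB decay calibration (fixes Γ_Pfr = 69/7) |
| Q_Pfr·γ_Pr | 3 ln 2 | /day | 8-h PhyB half-life in red light |
| R_PP | 350 | – | PhyB/PIF3 decay-curve calibration |
| γ_PIF·R_PP | 96 | /day | 15-min PIF3 half-life in red light |
| γ (all transcripts) | 4 ln 2 | /day | mean mRNA half-life ~6 h |
| K_PIF | 0.32/0.22/0.35/0.12/0.48/0.09 | – | per-gene fits (SIG2/SIG6/PAP1/PAP2/PAP5/PRIN2) |
| q (phyB mutant) | 0.25 | – | mutant expression-profile match |

Only the products Q_Pfr·γ_Pr and γ_PIF·R_PP are empirically constrained;
the individual rates are defined by dividing through the composite
(γ_Pr = 3 ln 2/8.75, γ_PIF = 96/350 per day). This is one consistent
split, not a claim about the separate rates. Canonical time unit is days;
`to_days` converts tagged hour/minute inputs on load.

**Stationary expression has two conventions.** The long-time limit of the
explicit PIF3 approximation is PIF_∞ = Q(√R_PP − Q/2)/R_PP ≈ 0.35833,
whereas the exact slow manifold at the PhyB plateau gives ≈ 0.37090
(a 3.4% gap that measures the approximation error). `expression_stationary`
defaults to the explicit-solution limit (mode `"limit"`), offers the
slow-manifold value (mode `"slow_manifold"`, consistent with the numeric
engine's long-time state), and keeps the typeset stationary formula with
inner term (Q/√R_PP + Q²/2)² verbatim behind mode `"as_printed"`; that
form evaluates to ~1e-3-scale values inconsistent with the others and is
retained for comparison only, with no intent guessed.

## Fitting

One free parameter per problem: K_PIF per gene (bounds 1e-4…10) or the
mutant scaling q (bounds 0…1), minimising Σ wᵢ(meanᵢ − modelᵢ)² with
wᵢ = 1/SEᵢ² when standard errors are available, else uniform. The loss is
quasi-convex in 1-D; a 50-point log-spaced pre-scan brackets the minimum
before bounded Brent refinement (parameter tolerance 1e-6), and the fitted
loss is verified in tests to beat a 50-point log-grid everywhere. Nearly
constant series are flagged as unidentifiable (the model degenerates to
φ → 1 as K_PIF → ∞, pushing the estimate to the upper bound). Exponential
decay rates (half-life calibrations) are least-squares fits with the floor
either fixed or co-fitted; a two-point input uses the closed form.

## Synthetic data

The generator emulates the study conditions the analysis assumes: nine
sampling times over 0–7 days (0, 0.125, 0.25, 0.5, 1, 2, 3, 5, 7), nine
replicates per point with multiplicative lognormal noise of CV 0.15
(mean-1 parameterisation, so replicate means are unbiased around the
model), summarised as mean ± SE. Fold-changes are positive and qPCR
errors roughly multiplicative, hence the lognormal family; the true
replicate noise magnitude of the original experiments is unknown, so the
CV is a configurable emulation choice, not a claim. Promoter fixtures are
i.i.d. backgrounds at Arabidopsis-like GC 0.36 with every spontaneous
target-motif occurrence (either strand) rewritten before planting, so a
scan recovers exactly the planted set; the default 13-gene fixture plants
a PBE-box in every promoter and a G-box in a subset, clustered in three
upstream regions, mirroring the qualitative published pattern. What
passing tests show is therefore internal consistency — the pipeline
recovers parameters from data generated under its own assumptions — not
robustness to real-data features such as non-lognormal error, replicate
correlation, transcript-specific decay rates, or degenerate promoters.

## Numerical choices

- ODEs: `scipy.integrate.solve_ivp`, LSODA at rtol 1e-8 / atol 1e-10 with
  dense output sampled onto the user grid (the cascade mixes ~15-minute
  and ~3-day timescales, a ~300-fold separation); the stiff full PIF3
  system uses Radau at atol 1e-12.
- Quadrature: adaptive `scipy.integrate.quad` at epsrel 1e-9 over a
  monotone (PCHIP) interpolant of the PIF3 trajectory.
- Tiny negative solver round-off (< 1e-9) is clipped to zero; genuine
  negativity is rejected.
- `pif_slow` switches to its series expansion 1 − a + 2a² when
  a = R_PP·[PhyB]² < 1e-8 to avoid 0/0.
- Motif scanning is exact fixed-string matching (the motifs are fixed
  6-mers, so no position-weight scoring is needed); overlapping matches
  count, windows containing N never match, minus-strand hits are placed
  at forward-strand coordinates so palindrome hits coincide; ties in
  `peak_metrics` resolve to the earliest time; histogram "clusters" are
  local maxima separated by at least two lower-or-empty bins — a
  reporting convention, not a statistical test.
- Seeding: `numpy.random.SeedSequence(seed, spawn_key=...)` gives each
  generator purpose (expression noise, decay noise, each promoter) an
  independent, reproducible stream; identical seed and configuration give
  bit-identical outputs.

## Problem sizes

Simulations use 701-point grids over 0–7 days (800 log-spaced points when
following trajectories to day 30); recovery experiments use 50 seeded
replicate fits at CV 0.10 with 9 replicates; scanner cross-checks run 100
seeded random sequences. These sizes make every acceptance property
measurable with comfortable margin while keeping the full suite fast.

## Known limitations

- The explicit PIF3 approximation undershoots the numeric solution by up
  to ~52% around t ≈ 0.5 day (frozen as a regression value); downstream
  consumers therefore default to the numeric engine, with the explicit
  one behind `engine="closed_form"`.
- The short-time expression expansion deviates from the exact convolution
  by up to ~12% within its nominal validity window (largest near t ≈ 1 h);
  it is a readability aid, not a compute path.
- All transcripts share one decay rate; differences between genes are
  attributed entirely to K_PIF by construction.
- The model describes population-average kinetics; no stochastic
  single-cell behaviour, no transcriptional regulation of PIF3 itself,
  and no absolute transcript counts (inputs and outputs are fold-changes
  relative to dark).
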