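# Methods

## Generative model

One flanker trial is modeled as a single evidence accumulator driven by a
shrinking attentional spotlight. The spotlight is a zero-mean Gaussian over
the five-item array (items of unit width, target centered at 0); its SD
follows the discrete recursion sd_a(t) = sd_a(t−1) − r_d, i.e.
sd_a(t) = max(sd_a(0) − r_d·t, 0.001) with a hard floor of 0.001 width
units. Item activations are the Gaussian masses over
(−∞,−1.5], (−1.5,−0.5], (−0.5,0.5], (0.5,1.5], (1.5,∞); they sum to one by
construction. Drift is v(t) = P·Σᵢ sᵢ·aᵢ(t) with sᵢ = +1 for every item on
congruent trials and −1 for the four flankers on incongruent trials, so
v = P on congruent trials (an exact identity used as a test oracle) and
v = P·(2·a_target − 1) on incongruent trials.

Evidence follows X_t = X_{t−1} + v(t)·dt + σ·√dt·ε with X_0 = 0 and
symmetric absorbing boundaries at ±b; the upper boundary is "correct"
(the model is left/right symmetric, so target direction is not modeled).
σ is fixed at 7.0 — drift, boundary and diffusion scale are not jointly
identifiable, so σ is a unit convention tied to millisecond time steps. The
drift increment for the step ending at time (k+1)·dt uses the spotlight
width at (k+1)·dt, matching the recursion above. Observed RT adds a
nondecision time drawn from a normal(Ndt, Ndtσ) truncated at zero; the
distributional family sits behind one function (`draw_nondecision`) so a
uniform alternative is a one-line swap. Accumulation is censored at the
task's 950 ms response window; censored trials are flagged and excluded
from summaries.

The simulator integrates at dt = 1 ms by default (σ interpreted per-step at
that dt). dt is exposed because the discrete walk overshoots the boundary:
at dt = 1, σ = 7 the overshoot inflates congruent accuracy by roughly 0.017
over the continuous-limit absorption probability 1/(1 + exp(−2vb/σ²));
by dt = 0.02 the measured bias is below 10⁻³, which is where the simulator
is checked against that closed form. The inner loop is a numba kernel that
consumes a NumPy `Generator`, so results are bit-reproducible for a given
seed and all stochastic entry points take an explicit generator.

## Fitting targets and objective

Per congruency, the observed data are reduced to ten cells: six CDF cells —
correct-response RTs partitioned at the (0.1, 0.3, 0.5, 0.7, 0.9, 1)
quantiles (the mass above the 0.9 quantile closes the last cell) — and four
CAF cells holding the error counts within all-trial RT quartiles
(0.25, 0.5, 0.75, 1.0). Observed counts use rank partitions (exact cell
sizes); simulated trials are classified by the observed quantile edges.
The objective is Σ_cells −2·log Binomial(k_ij | N_i, π_ij), where π_ij are
simulated cell proportions floored at 1/(10·n_sim) — so an empty simulated
cell yields a large finite penalty rather than an infinite one — and
renormalized. Goodness of fit uses Pearson's χ² = Σᵢ Nᵢ Σⱼ (pᵢⱼ−πᵢⱼ)²/πᵢⱼ
with df = (cells − 1 per congruency) − 6 free parameters by default (the df
convention is configurable; "acceptable" means non-significant at α = 0.05),
and RMSEA = √(max(χ²−df, 0)/(df·(N−1))), aggregated across observations by
pooling χ² and df before the formula.

## Optimization

Candidates are scored by simulating n_sim trials per congruency with a
simulation seed fixed for the whole phase (common random numbers), so
Nelder–Mead sees a deterministic surface. Two properties of that surface
shaped the optimizer:

* it is piecewise constant (counts change only when a simulated trial
  crosses a bin edge), so a single simplex run stalls; every start is
  optimized by a chain of Nelder–Mead runs, each re-seeded with a fresh
  simplex of decreasing edge length, keeping the best point;
* sd_a(0) and r_d trade off along a narrow valley of nearly constant
  sd_a(0)/r_d (the spotlight convergence time). The optimizer therefore
  works in internal coordinates u₀ = log sd_a(0), u₁ = log(sd_a(0)/r_d),
  with the remaining four parameters scaled by the start-distribution SDs,
  which straightens the valley so the simplex can track its floor.

A fit runs in phases: (1) explore — every start from the truncated-normal
start distribution is chain-optimized against a cheap objective (smaller
n_sim); (2) the explore optima are re-ranked under a high-precision
objective (4 × n_sim by default) because the cheap surface's noise is
larger than the depth differences between candidate regions; (3) the best
candidates are polish-chained at full n_sim; (4) a width scan — the
narrow-spotlight and wide-spotlight regimes can nearly mimic one another,
so spotlight width is scanned on the high-precision surface (holding the
best candidate's ratio and nuisance parameters) and the best scan point is
polished as an extra candidate; (5) the winner under the high-precision
objective takes a short final descent on that low-noise surface.
Out-of-bound candidates are simulated at the clipped point plus a quadratic
penalty. Stopping uses xatol = 10⁻³ (scaled units) and fatol = 1 deviance
unit per run, with per-phase iteration caps.

Two profiles package these choices. "paper" keeps the original scale
(100 starts, 12,500 simulated trials per congruency, long chains);
"desk" is the single-CPU profile used throughout the tests: 10 starts,
exploration at 5,000 simulated trials per congruency, polish at 12,500,
selection and final descent at 50,000. With desk settings, refitting
25,000-trial datasets generated at the start-distribution means recovers
sd_a(0), r_d and Ndt with median relative errors of roughly 10%, 16% and
<1% over 20 replicates.

## Hierarchical estimation

Stage 1 fits one population vector against every participant-by-condition
observation's cells at once, summing per-observation deviances (shared
simulation per candidate, per-observation classification via binary search
on the sorted simulated sample). Stages 2 and 3 fit zero-centered deviation
vectors per condition (that condition's observations, all participants) and
per participant (that participant's observations, all conditions),
independently around the population vector, drawing starts from zero-mean
truncated normals with the published SDs and bounds that keep
population + Δ inside [0, (6.0, 0.2, 5.0, 200, 450, 90)]. Stage 4 fits a
noise deviation per observation around population + Δcondition +
Δparticipant; because that base is already close, the noise stage runs with
at most 4 starts and one polish candidate by default. Observation-level
sums are clipped to the stage bounds; within-transformed sums
(population + Δcondition + Δparticipant) are deliberately left unclipped,
as they feed linear models that assume unbounded normal variation.

Delta stages score candidates against per-observation cells rather than a
pooled summary: pooling mixes participants' RT distributions and inflates
the apparent nondecision variability, which in turn blurs the
spotlight-width information. A milder form of that inflation is inherent to
any common-vector stage — a single vector explaining observations whose
nondecision means differ by ±30 ms can only do so with a wider Ndtσ — and
is visible in population-stage estimates on heterogeneous synthetic data.

## Condition analysis

Within-transformed values are analyzed with a condition-only fixed-effect
GLM (residual = participant variation), matching the denoised-sum logic:
the condition deltas are common to all participants, so participant
variation is pure noise for the condition contrast. Observation-level
values are analyzed with a one-way repeated-measures ANOVA (pingouin) on
complete cases. Effect sizes: partial η² for the omnibus; for pairwise
contrasts, Cohen's d is the marginal-mean difference over √MSE at the GLM
level and the standardized mean paired difference (d_z) at the
repeated-measures level. No sphericity correction is applied by default
with three levels. The convergence ratio sd_a(0)/r_d (ms to reach the
minimal window) is computed per observation and then averaged — never as a
ratio of averages — and its ANOVA is skipped when any observation has
non-positive r_d (possible for unclipped within-transformed sums).

## Synthetic study generator

The generator emulates the within-subject crossover design: 29 participants
× 3 induction conditions (FA, OM, C) × 512 trials, half congruent, RTs
bounded by the 950 ms response window. Condition profiles default to the
study's estimated condition means — sd_a(0) = (0.42, 4.63, 4.43),
r_d = (0.001, 0.105, 0.081), Ndt = (271.2, 285.0, 273.0),
Ndtσ = (17.65, 31.42, 18.64) for (FA, OM, C) — with perceptual input 0.6
and boundary 60 common to all conditions (no condition differences were
reported there). Each participant draws one zero-mean truncated-normal
baseline deviation, shared across their three sessions, with per-parameter
SDs defaulting to half the start-distribution SDs
(0.6, 0.025, 0.15, 15, 30, 10); composed parameters are clipped into
[simulation floor, stage upper bounds] and clipping is recorded in the
ground-truth table. Parameters are drawn independently across participants;
the strong empirical correlation between sd_a(0) and r_d is not imposed
(a correlated mode would be a straightforward extension).

What the generator does not emulate: session-order effects, within-session
fatigue or learning, contaminant/anticipatory responses, and any departure
of real nondecision distributions from the truncated normal. Passing
recovery tests on this generator therefore demonstrates that the pipeline
recovers the model's own structure at study-like sizes, not that the model
is correct for real data.

## Scaled-down checks and their limits

The test suite exercises the pipeline at deliberately reduced sizes chosen
to keep a full run on one CPU within minutes: recovery uses 25,000-trial
datasets with the 10-start desk profile; the end-to-end sign-recovery check
uses 8 participants × 128 trials per condition without the noise stage; the
acceptance script runs the same pipeline with the noise stage plus a
6-replicate recovery study. At the 8 × 128 scale the focused-attention
spotlight width is only weakly identified by the condition stage: with
participant baselines dispersed as above, the common-vector likelihood for
the FA condition is nearly flat in width between ≈2 and ≈5 width units
(the narrow-regime signature — no fast errors — is largely erased once the
stage's inflated Ndtσ smears the conditional accuracy profile), while at
the full 29 × 512 scale the same stage recovers FA ≈ 0.5–1.4 against
OM ≈ 3–5.5 cleanly. The scaled-down sign check therefore carries a residual
failure probability driven by the data size, not by the estimator; the
width-scan phase exists precisely to keep that probability small.

## Numerical details and edge cases

* Truncated-normal draws use rejection sampling (bounds sit within a few
  SD, acceptance is high) with an inverse-CDF fallback for extreme
  intervals; collapsed bounds return the point mass.
* Simulation floors: candidate vectors are clipped to
  (0.001, 0, 10⁻⁶, 10⁻³, 0, 0) before simulation so the generative process
  stays defined; r_d = 0 (spotlight never shrinks) and Ndtσ = 0 (degenerate
  nondecision) are valid.
* Internal log coordinates floor sd_a(0) at 10⁻⁴ and r_d at 10⁻⁶; r_d = 0
  is representable in results (deltas are stored in raw space) but the
  optimizer approaches it asymptotically.
* An observed cell with no responded or no correct trials raises an error
  naming the cell; an empty simulated sample inside the objective returns a
  large finite penalty.
* A summary's observed counts come from rank partitions while simulated
  classification uses quantile edges; with heavily tied RTs the two can
  differ by a trial per cell, which is below the objective's resolution.
* Zero-variance inputs to the ANOVAs (identical values everywhere) return
  F = 0, p = 1 rather than NaN.
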