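# Methods

This note records the scientific and numerical choices behind `hpakit`: what
is modelled, how the numerics are configured, what the synthetic data
emulate, and where the design was genuinely open.

## The system being modelled

The hypothalamic-pituitary-adrenal (HPA) axis is the CRH → ACTH → cortisol
cascade that drives the endocrine stress response. Cortisol, acting through
glucocorticoid receptors (GR), represses CRH and ACTH synthesis, closing a
negative-feedback loop; a circadian drive from the suprachiasmatic nucleus
imposes a ~24-h rhythm peaking around 8 AM, and secretion is pulsatile
(ultradian episodes of 60–90 min period, 12–18 per day). In laboratory
protocols a standardized 20-min psychosocial stressor (a Trier Social Stress
Test, TSST) transiently elevates both hormones, with blood sampled on an
11-point grid from 30 min before the test to 90 min after it ends.

`hpakit` is a verification-and-validation harness for differential-equation
models of this axis: it integrates a model, scores it against hormone
time-series with a scale-free cost, calibrates free parameters by
differential evolution, and aggregates repeated calibrations across subjects
into a comparable model ranking. Any model enters through the `ModelSpec`
plugin contract (states, parameter table with bounds, delays, drivers,
output map); three built-in demonstration models exercise the structural
motifs of the published model family.

## Demonstration models

* **minimal** — three states (CRH `C`, ACTH `A`, cortisol `F`) with
  Hill-type repression of CRH and ACTH production by cortisol:

      dC/dt = k_c·circ(t)·stress(t)/(1 + (F/K_i)^n) − w_c·C
      dA/dt = k_a·C/(1 + (F/K_i2)^m) − w_a·A
      dF/dt = k_f·A − w_f·F

* **receptor** — adds a GR state `R`; feedback acts through the bound
  complex `F·R` and receptor production carries a positive-feedback Hill
  term in `(F·R)²`, the motif that gives receptor models intrinsic ultradian
  capability.
* **delayed** — the minimal cascade with action delays (CRH→pituitary 5 min,
  ACTH→adrenal 10 min, cortisol feedback 15 min by default), a genuine DDE.

Default rate constants are implementation constants, not literature values.
They were chosen so that (i) the flat-driver steady state is strictly
positive (`C*=1`, `A*=30`, `F*=10` in the minimal model, with half-maximal
feedback at rest), (ii) decay rates respect the physiological ordering (CRH
clears fastest, τ≈8 min; cortisol slowest, τ≈40 min), and (iii) the
canonical 20-min stress episode produces a peak-and-return cortisol response
that is back within 5% of baseline four hours later. Every test in the suite
depends on such qualitative properties, never on the specific constants.

Units: time is minutes everywhere internally; a model declaring hours is
converted at registration (derivatives ÷60, lags ×60). Concentration scales
are arbitrary because the cost normalises them away; units recorded on data
(pg/mL for ACTH, µg/dL for cortisol) are metadata only.

## Integration

A single hand-written Dormand–Prince 5(4) embedded pair with the standard
quartic dense-output interpolant serves both ODEs and DDEs. Choices:

* Mixed error control `atol + rtol·max(|y₀|,|y₁|)` with RMS norm; step
  factors 0.9·err^(−1/5) clipped to [0.2, 10]. Defaults `rtol = 1e−6`,
  `atol = 1e−9` — well below assay noise, well above float granularity.
* **Delays (method of steps):** lagged states are read from the history
  function for times at or before the start, and from the accumulated dense
  segments afterwards. The step is capped at the smallest positive lag, so a
  lookup during a trial stage (`t + c·h − τ`, `τ ≥ h`) always lands in
  accepted history; zero lags return the current stage state, making the
  zero-lag DDE bitwise-consistent with the ODE right-hand side. Propagated
  derivative discontinuities at `t₀ + k·τ` are handled by error control plus
  the lag cap, not explicit discontinuity tracking — adequate at these
  tolerances, and a documented limitation.
* **Forced points:** stress-episode on/off times become exact mesh points;
  the right-hand side is re-evaluated at each breakpoint (no FSAL reuse
  across it), so the piecewise-constant driver never straddles a step.
* Stiff problems are out of scope: step-size underflow raises an error
  naming the time reached, which the calibration layer converts to an
  infinite cost.

Dense evaluation snaps exact mesh (and the cost spline snaps exact knot)
queries to stored values, so "exact at nodes" holds bitwise, not merely to
round-off.

## Cost function

Simulated outputs are splined (cubic, not-a-knot — reproduces cubics
exactly; end conditions were unspecified in the protocol this mirrors, and
not-a-knot is the standard default) over the solver mesh and evaluated at
the data times, because an adaptive mesh never lands exactly on the sampling
grid. Residuals are formed after normalisation and reduced as

    total = (1/(N·H)) · Σ_i Σ_h r_{h,i}²,   r = d/μ_d − s/μ

Two recorded conventions:

* `normalize`: `"data"` (default) sets `μ = μ_d`, the data mean — the
  literal mean-normalisation reading; `"shape"` sets `μ` to the simulation's
  own sampled mean, comparing pure shapes across models with incompatible
  concentration scales. Both are provided because the two readings are
  genuinely defensible; neither is asserted as canonical, and every saved
  result carries its convention label.
* `average`: `"mean"` (default) divides by points × hormones for
  comparability across grids of different lengths; `"sum_half"` keeps the
  sum over points divided only by the hormone count (the printed-equation
  form).

Single-hormone (cortisol-only basal) data use the same formula with H = 1.
The full 11-point grid enters the sum, including pre-test baselines.
Alternative costs (`max_max`, `mean_max` of absolute normalised residuals)
are provided behind the same interface. The data mean must be positive;
non-positive simulated means under the shape convention are treated as
failed evaluations (infinite cost) rather than errors during optimisation.

## Calibration protocol

`evaluate_params` turns a parameter vector into a cost: initialise at the
flat-driver steady state (Powell-hybrid root of the algebraic system,
residual < 1e−10, nonnegative), pre-roll `burn_in` minutes before the first
sample so the trajectory settles onto the driven attractor (default one full
day; studies that use flat circadian drivers need far less and say so),
simulate through the canonical stress episode aligned at t = 0, sample on
the subject grid, score. Any integration or steady-state failure becomes an
infinite cost with a logged reason.

The optimiser is a self-contained rand/1/bin differential evolution:
uniform initialisation within bounds, dithered mutation factor
F ~ U[0.5, 1), binomial crossover CR = 0.7, greedy selection, candidates
clipped to bounds. The model's default parameter vector is injected as one
initial population member, which guarantees the optimised cost never
exceeds the default-parameter cost and costs nothing in exploration. The
repeated-run protocol performs five independent DE repeats per dataset with
distinct seeds; a dataset's summary is mean ± sample SD and best single
cost; a model's overall score is the mean of its per-dataset means; models
rank by ascending overall score with name ties. "Iterations" of the
optimisation algorithm are read as independent repeats of the whole run,
and reported statistics are computed over repeats.

Which parameters are free is controlled per-run: the parameter table's
`optimize` flags define the default free set, and an explicit free-list
overrides it (supporting both "only population-varying parameters" and
"everything" modes). Alternative global optimisers can be plugged behind
the same objective contract; none are re-implemented here.

## Parameter-recovery study design

`hpakit.studies.parameter_recovery_study` refits `(k_c, K_i, w_f)` of the
minimal model from synthetic 11-point TSST data generated at a known truth.
The study runs in a deliberately chosen **steep-feedback threshold regime**:
Hill exponents n = m = 8, feedback thresholds K_i = K_i2 = 16 with resting
cortisol ≈ 10 (feedback nearly off at baseline), a strong stress drive
(amplitude 8, i.e. a 9× hypothalamic drive during the 20-min test, giving a
~1.8× cortisol excursion), truth k_c = 0.1, w_f = 0.03, and a 240-min
pre-roll with flat circadian drive (the steady state is then exact, so a
longer burn-in would only cost time).

The regime matters: when feedback is half-engaged at rest (shallow Hill,
threshold at the resting level), the gain `k_c` and threshold `K_i`
compensate along a likelihood ridge — homeostasis hides gain changes from
the observed ACTH/cortisol — and under 10% observation noise the
maximum-likelihood estimate genuinely wanders tens of percent from the
truth; no optimiser can fix that. With the threshold just above baseline
and a steep Hill, the resting levels pin `k_c` (the whole curve scales with
it) while peak clipping pins `K_i`, and a Fisher-information check plus a
20-realisation Monte-Carlo of local maximum-likelihood fits confirmed the
estimate concentrates well inside ±25% for all three parameters at 10%
multiplicative log-normal noise. This is a practical-identifiability design
choice, documented here precisely because it is one.

## Synthetic data

The TSST cohort generator is phenomenological (it does not integrate a
model): per subject, log-normal baselines (medians 20 pg/mL ACTH, 10 µg/dL
cortisol, 25% inter-subject CV), a half-sine rise from test start to a peak
drawn in [10, 35] min with ACTH peaking 5–10 min before cortisol, and an
exponential return whose rate is drawn so the 110-min sample lies within
5–15% of baseline; multiplicative log-normal assay noise (CV 15%) keeps
values positive. A configurable fraction of subjects are anomalous
responders emulating the documented outlier phenotype: monotonically
decreasing ACTH across the whole grid (noise applied, then sorted) with the
cortisol peak forced to the +50 min grid point — 30 min after the test ends.
The default group mix mirrors the documented cohort composition (15/58
controls, 43/58 MDD across three subtypes).

The basal generator lays ultradian pulse times at intervals drawn from
U(60, 90) min; when more candidates fit the day than the requested pulse
count (12–18 by default), the surplus pulses with the lowest circadian
envelope value are dropped, emulating the overnight quiescent period.
Gaussian secretory pulses (σ ≈ 8–10 min, ACTH leading cortisol by ~8 min)
are modulated by a cosinor envelope peaking at clock minute 480 (8 AM) and
sampled at 10-min intervals.

What passing tests on these data do and do not show: the generators
reproduce the *shape statistics* the pipeline consumes (baseline–rise–return
geometry, peak ordering and timing, pulse counts, group labels), so they
exercise every code path a clinical table would. They do not reproduce
assay-specific error structure, within-subject circadian baseline drift
across the TSST window, missing-data patterns (exclusion handling is tested
with explicitly constructed incomplete files), or any genuine
MDD-versus-control physiological contrast — group labels carry no effect by
default. Passing therefore validates the machinery, not any clinical claim.

## Problem sizes used in the shipped studies

The seven-dataset optimised-versus-default study runs the documented
protocol shape — six individual subjects plus the cohort mean, five DE
repeats each (35 runs) — with population size 10 and a 15-generation budget
on a 58-subject synthetic cohort, and a 120-min pre-roll. These sizes are
the package's own defaults for the canned study; the full protocol scales
linearly in generations and repeats. The recovery study uses population 15
and 200 generations. Numerical tolerances in the test suite mirror the
guarantees stated above (integrator oracles to 1e−6/1e−7, spline fidelity
to 1e−9, exact cost identities to machine precision, report arithmetic to
1e−12).

## Known limitations

* Explicit RK only: stiff models will fail fast rather than integrate
  slowly; an implicit backend would be a separate contribution.
* No state-dependent or distributed delays; no event detection beyond
  forced mesh points.
* DDE discontinuity propagation is handled by error control, not tracking;
  very tight tolerances on long delayed runs will over-resolve the early
  intervals.
* The demonstration models are structural stand-ins, not reproductions of
  any published model's equations; real models enter through `ModelSpec`.
* Basal (24-h) data currently share the cohort CSV schema with clock-minute
  times; a richer basal schema (evening/morning windows) was left open
  deliberately.
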