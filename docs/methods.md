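# Methods

This note documents the models, estimators, defaults and design choices
behind `inducekit`, and what the synthetic benchmarks do and do not show.

## Synthetic data generator

**Networks.** `generate_network(n_genes, n_regulators, sparsity, ...)`
places `round(sparsity · n_genes²)` edges uniformly in the columns of the
designated regulators (no self-edges). Edge magnitudes are
`Uniform(0.5, 1.5) × effect_scale` with random sign; `effect_scale`
defaults to 10⁻³ min⁻¹ per unit ratio-deviation, which against a ~50-fold
induced regulator produces direct-target responses of a few log₂ units
over 90 min — the magnitude range of strong responses in induction
atlases. A `beta_fraction` of edges additionally receives a
target-proportional (β) coefficient.

**Dynamics.** The induced gene is exogenous: it follows a forced logistic
profile re-anchored so y(0) = 1 exactly and y(∞) = `induction_fold`
(default 50, half-time 5 min, slope 1 min⁻¹ — saturation within ~10 min).
All other genes evolve by

  d ln y_i/dt = Σ_k α_ik (y_k − 1) + β_ik (y_i y_k − 1)/y_i,

integrated with a fixed-step classical Runge–Kutta scheme in ln-space
(positivity is automatic; default step 0.1 min; halving the step changes
sampled values by ≪ 0.1%). Integration aborts with the offending gene
named if |ln y| exceeds 12. The default sampling grid is 0, 5, 10, 15,
20, 30, 45, 90 min. Because the generator reuses the same functional form
the regression later fits, coefficient recovery is a well-posed question;
an unobserved-regulator mode (`hide_genes`) introduces deliberate model
mismatch for robustness studies.

**Measurement corruption.** Observed values are
`true × stress(t) × exp(ε)` with ε ~ N(0, σ²_gene + σ²_array) in natural
log (log-normal noise varying over both genes and arrays; defaults 0.1
and 0.05). The stress signature is a per-class (GEV/ZEV) ratio-scale
multiplier shared by all genes, emulating the induction systems' common
background response. Each timecourse is finally re-divided by its own
t = 0 value, mirroring the ratio-to-time-zero normalization of the assay.

**Spot rendering and artifact ledger.** Expression ratios are expanded to
red/green intensities (green ≈ 1000 a.u., red = green × ratio × spot
noise, default 2 spots). Three artifact types are planted at configured
rates on *distinct* timecourses and recorded exactly: one spot's ratio
multiplied by 5 (duplicate-spot disagreement, > 4× rule), one interior
observation multiplied by 6 (spike, ≥ 4× move and reversal), and a whole
timecourse's green channel inflated 10× for t > 0 (crosstalk, > 8× rule).
Each planting is verified against its detection rule on the corrupted
table (with redraws where underlying dynamics would mask it), so the
ledger is an exact answer key and cleaning tests are bit-exact rather
than statistical.

## Cleaning chain

Ratios use the intensity floor C = 2 a.u. in both channels:
`max(red, C)/max(green, C)`. Aggregation over spots records
min/max/median/sd (for two spots the sd equals (max−min)/√2).

Repairs, in order, all replacing a value by the geometric mean of the
nearest non-flagged bracketing time points (single neighbor at the ends):

1. **Spot disagreement** — max/min of per-spot ratios > 4 (symmetric in
   spot order).
2. **Spikes** — the median ratio moves ≥ 4× between consecutive times and
   then ≥ 4× in the opposite direction (both up-then-down and
   down-then-up).
3. **Crosstalk** — per timecourse, the 30% quantile over t > 0 of
   green(t)/green(0) exceeds 8 *and* the 30% quantile of
   |log₂(ratio(t)/ratio(0))| exceeds a twofold change (a conjunction);
   repaired by recomputing every spot's ratio against that spot's t = 0
   green channel (same floor). Quantiles use t > 0 only, since the t = 0
   ratio is 1 by construction.

Using nearest *non-flagged* bracket values makes both geometric-mean
repairs idempotent even for adjacent flags. All untouched values are
bit-identical to input.

**Class-median subtraction.** Per gene and induction-system class, the
median ln-timecourse across the class's experiments is subtracted from
every experiment of the class. Since most genes do not respond to most
induced TFs, this median reflects only shared background (the stress
signature) and cancels it exactly when all experiments share it;
single-experiment classes are skipped with a warning (subtraction would
zero them).

**Hard thresholding.** The log value of an invariant gene is modeled as
N(0, σ²_gene,i + σ²_array,a), one array per (experiment, time). The
components are estimated robustly from the invariant majority by MAD:
with per-gene scale s_i (over arrays), per-array scale s_a (over genes),
and overall scale s, the moment-matched per-observation variance is
max(s_i² + s_a² − s², floor²) (floor 10⁻³). Each timecourse is scored by
T = Σ_{t>0}(l_t/σ)², referred to χ² with one df per post-zero time, and
selected by Benjamini–Hochberg at q = 0.05. Non-selected timecourses are
set to *exactly* zero log fold change (hard, not soft). The per-gene
scale needs multiple experiments to be robust to a gene's own signal; on
a 2 000-gene, 10-experiment simulation with 5% responders at 8σ the rule
reaches 100% sensitivity at < 1% false selection. With a single
experiment the gene component is confounded with signal and sensitivity
collapses — the regime the method is built for is multi-experiment.

## Kinetic models

Signal timecourses (log₂ fold change, 0 at t = 0) are fit with
σ(x) = 1/(1+e⁻ˣ):

- **sigmoid** (3 parameters): f(t) = v_inter · σ(slope·(t − t_rise));
- **impulse** (5 parameters): f(t) = σ(slope·(t − t_rise)) ·
  [v_final + (v_inter − v_final) · σ(−slope·(t − t_fall))].

The impulse is the product-form double sigmoid with zero initial
amplitude and one slope shared by both transitions — the only way to
reach five parameters given {t_rise, t_fall, v_inter, v_final} — and
reduces exactly to the sigmoid at v_final = v_inter.

**Fitting** is MAP under Gaussian noise with the ML (profiled) σ, by
multi-start L-BFGS-B (default 8 seeded starts spanning early/late
half-max times; per-timecourse seeds derive deterministically from the
gene/experiment identifiers). Priors, all configurable in
`KineticPriors`:

- half-normal on slope, scale 1 min⁻¹ (penalizes step-like fits);
- quadratic penalty 4·f(0)² (nothing changes before the inducer is
  added; together with the bound t_rise ≥ 0 this rules out pre-induction
  transitions);
- weak normal priors on v_inter/v_final, sd 4 log₂ units;
- box constraints: slope ∈ [10⁻³, 10] min⁻¹, |v| ≤ 12, t_fall > t_rise.

**Model selection.** The likelihood-ratio statistic
2(ℓ_impulse − ℓ_sigmoid) (unpenalized log-likelihoods at the MAP points;
the impulse is refit once from the sigmoid solution if it scored lower,
and a residual negative statistic is reported as 0) is converted to a
p-value using the small-sample nested-least-squares reference
F = ((RSS_sig − RSS_imp)/2)/(RSS_imp/(n−5)) ~ F(2, n−5) by default. On
the standard 8-point grid the asymptotic χ²₂ reference is far too liberal
— five parameters recover most of the residual of eight points, and
sigmoid-truth simulations at sd 0.1 would select the impulse ~30% of the
time at α = 0.05 versus ~3% under the F reference (with ~100% power on
strong impulses). χ²₂ remains available via `reference="chisq"`. The
impulse is chosen iff p < α (default 0.05).

**Summaries.** A transition is x-saturated at
t{sat=x} = t_coef + ln(x/(1−x))/slope with t_coef = t_rise (rises) or
t_fall (falls); response intervals are the 5–95% saturation windows
clipped to the observed range, with events below 0.1 log₂ units of
amplitude dropped.

## Dynamical regression

For each target i, rows are consecutive-interval finite differences:
dependent (ln y(t₊) − ln y(t))/Δt; predictors (y_k − 1) and
(y_i y_k − 1)/y_i evaluated at the interval start (an interval-midpoint
option exists). Because y = 1 at t = 0 for every gene, all first-interval
predictors are exactly zero and no intercept is fit, so the predicted
rate at induction time is machine-zero — the pre-induction steady-state
constraint is structural, not numeric. Self-edges are excluded by
default. Each induced gene's rows from its *own* experiments are excluded
from its own regression when an experiment→induced-gene map is supplied:
there its dynamics are forced by the inducer, and the unexplainable
variance otherwise drives the penalty selection to zero out true incoming
edges.

Coefficients minimize ‖y − Xw‖² + λ‖w‖₁ (coordinate descent via
scikit-learn, duality-gap tolerance 10⁻⁸; λ = 0 falls back to least
squares). The per-target λ comes from BIC = n ln(RSS/n) + df ln n
(df = nonzero coefficients; ties resolve to the sparsest model) over a
30-point grid, geometric from 10⁻⁶ to 30 — the ceiling is set so full
shrinkage is reachable against ~50-fold induced predictors.
Leave-one-experiment-out cross-validation is available instead, with the
one-SE rule as an option; for pure-noise targets the CV curve is nearly
flat and the one-SE rule is the selector that reliably returns the empty
model. Per-target failures are isolated and logged, never fatal.

Predicted rates integrate teacher-forced (cumulative sum of rate × Δt
from 0, predictors observed), giving log₂ trajectories for the
attribution step. Point-wise regression on a coarse grid carries
discretization bias for fast dynamics (the 0–5 min interval's rate is
structurally 0 while the observed change is not), so exact-recovery
checks (R² ≥ 0.99, integrated predictions within 2% RMS at zero noise)
are run on data generated by the model's own discrete forward recursion
(`benchmark.simulate_discrete`); continuous-ODE data are used for all
noisy recovery benchmarks, where the bias is far below the noise.

**Edge scoring and controls.** Candidate edges are ranked by |α| + |β|.
The benchmark universe is (target × designated regulator) pairs:
non-regulator columns never vary in these designs, so their scores are
structurally zero, and including them would inflate the permutation null
(≈ 0.8 instead of 0.5) purely because all positives live in
high-variance columns — a hub artifact, not recovery. The negative
control remaps each row's dependent variable to a different experiment
(never one inducing the same gene, which would re-align signal when
regulators are induced repeatedly); the benchmark reports the mean AUROC
over several such permutations. A plain expression-on-expression LASSO
with one global λ serves as the baseline comparator.

## Marginal attribution

For a response interval [t_start, t_end] (ends pro-rated linearly, which
matches linear interpolation of the piecewise-linear predicted ln
trajectory exactly), regulator j's marginal log₂ change is the integral
of its rate terms, and Σ_j f_j = f_model to machine precision by
linearity. Attribution is gated by the predictive-value filter
min(f_model, f_observed)/max(f_model, f_observed) > 0.2 (opposite signs
fail; 0/0 fails). Shares ψ_j = f_j/Σf_j may be negative (a regulator
opposing the net change); the ψ > 0.2 driver cutoff applies to signed ψ,
with an absolute-value option. Near-cancellation
(|Σf_j| < 0.1·Σ|f_j|) is flagged unstable rather than silently divided
through; intervals narrower than one grid spacing are flagged
low-confidence.

## Graphs and evaluation

Direct edges require a passing attribution (ψ > 0.2 on a filtered
response), weighted by ψ, one edge per (source, target, experiment)
keeping the stronger of a rise/fall pair. Indirect edges run from the
induced gene to every gene surviving hard thresholding in that
experiment. The meta-graph unions experiment graphs with per-edge support
counts and per-node hub scores (distinct direct targets). Reference
networks are treated as undirected (either orientation matches). ROC uses
mid-rank tie handling; the null permutes the target column of the scored
edge list (preserving each source's out-count and each target's
in-count) 25 times by default. Rise-time rankings score induced→responder
edges by −t_rise with ties broken by gene identifier. Gene-set linkage is
upper-tail hypergeometric overlap with Benjamini–Hochberg control.

## What the synthetic benchmarks show — and what they do not

The generator reproduces the *structure* of induction experiments
(steady-state start, forced ~50-fold induction, sparse propagation,
class-shared background, log-normal gene/array noise, duplicate spots,
the three artifact classes) but not everything in real data: no
post-transcriptional or combinatorial regulation, no mRNA-stability
differences, no growth dilution as a separate process (all kinetics are
absorbed into the coefficients), no scanner-level dye bias (removed
upstream by vendor software in real pipelines), and — unless the
unobserved-regulator mode is enabled — no model mismatch. Passing
benchmarks therefore demonstrate correctness and calibration of the
estimators under the stated model, not performance on a real atlas, whose
headline quantities depend on the full deposited dataset and external
reference networks.

Problem sizes used by the test-suite and acceptance benchmarks — a
50-gene/10-regulator/20-experiment network recovery, 200 kinetic
recoveries, 300–600 model-selection simulations, a 2 000 × 10 threshold
calibration, 30 planted artifacts — were chosen so the whole suite runs
in a few minutes on one CPU while keeping every Monte-Carlo margin wide.
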