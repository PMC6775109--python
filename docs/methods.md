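# Methods

## The model

For every ordered pair of simultaneously recorded neurons, the package
pools the spike times of a *target* neuron measured relative to every
spike of a *reference* neuron within a window of ±W (default W = 50 ms).
The pooled lags form a realization of an inhomogeneous Poisson process
on [−W, +W] whose intensity (the expected lag density, in lags per
second) is modelled as

    c(t) = exp( a(t) + J12 f(t) + J21 f(−t) ),
    f(t) = exp(−(t − d)/τ)   for t > d,   0 otherwise.

`J12` and `J21` are the dimensionless coupling weights of the two
directions (reference→target on positive lags and the reverse), `f` is
a delayed exponential synaptic filter with impact time scale τ and
transmission delay d, and `a(t)` is a slowly varying log-baseline that
absorbs correlogram structure not attributable to the direct
connection — shared input, co-modulated rates, slow "wavy" fluctuations
common in vivo.  The baseline is discretized as piecewise constant on
1-ms bins and regularized by a smoothness prior

    log p(a) = −(1/γ) Σ_m (a_{m+1} − a_m)² / Δ,

with Δ in milliseconds and γ in 1/ms, so small γ forces a nearly flat
baseline.  Couplings carry flat priors.

### Estimation

The posterior is maximized over (a, J12, J21) by a damped-Newton
(Levenberg–Marquardt) ascent.  Because the intensity is piecewise
log-linear-in-parameters, the Poisson integral over each bin — and its
first two derivatives — has a closed form in the exponential integral
Ei, so objective, gradient and Hessian are exact (verified against
central finite differences to <1e−5 relative error).  The data enter
only through per-bin lag counts and the summed filter values, so the
cost per iteration is independent of the number of lags.  Damping is
multiplied by 10 on a rejected step and divided by 10 on an accepted
one; convergence is declared when the largest parameter change falls
below 1e−4 (default cap 1000 iterations).  An empty lag set returns the
no-coupling fit with the baseline at a floor intensity.

### Significance test

Under the null hypothesis of independent stationary firing, counting
statistics give the bound

    |Ĵ| > 1.57 · z_α · (τ c(0))^(−1/2)

for declaring a connection, where z_α is the two-sided normal critical
value and the prefactor 1.57 is the minimum over the counting-window
width D of √D/(τ(1 − e^{−D/τ})), attained at D = 1.26 τ (both constants
are recomputed numerically by `detectability_prefactor`).  The baseline
intensity c(0) is taken from the fitted baseline exp(a) averaged over
the central ±5 ms (coupling excluded), falling back to T·λ_pre·λ_post
for degenerate fits; both estimators agree on null data.  Significant
couplings are translated into postsynaptic potentials via the
calibrated proportionality J = a·w with a = 0.39 /mV (excitatory) and
a = 1.57 /mV (inhibitory); undetermined pairs are encoded as w = 0.

### Parameter defaults and why

- **τ = 1 ms** package-wide.  τ should be selected per dataset by
  maximized likelihood (`select_tau`); 1 ms is the selection for
  recorded cortical/hippocampal data and the value the
  recording-duration table uses.  Analyses of the package's own
  synthetic pairs pass τ = 4 ms, matching the generator kinetics.
- **γ = 5e−4 /ms.**  The flatness hyperparameter of the baseline.
  Note a consequence quantified during development: with the baseline
  free to bend on a ~2.4 ms scale, the null fluctuations of Ĵ exceed
  the analytic 1.57-rule scale by ~30% at τ = 4 ms (the filter is wide
  enough for the baseline to absorb part of it), while at τ = 1 ms the
  test is near-calibrated and slightly conservative.  The significance
  machinery is therefore exact at the recorded-data τ and approximate
  at larger τ.
- **d fixed at 1 ms** by default.  Searching a per-pair delay grid and
  keeping the best posterior is supported (`delay_grid`), but the
  analytic threshold does not account for that selection and the null
  test becomes anticonservative (measured ~2–10× the nominal α); the
  default therefore fixes the delay at the smallest physiological
  value.  Grid search remains appropriate for exploratory fitting where
  calibrated error rates are not required.
- **Shadow interval.** For extracellularly sorted data, near-synchronous
  spikes are lost to waveform overlap; a ±1 ms exclusion (`shadow`)
  removes those lags from both the likelihood sum and the integral, so
  the structural zeros are not mistaken for inhibition.  Default 0 for
  synthetic data.

### Recording-duration calculator

Approximating c(0) ≈ T λ_pre λ_post turns the bound into the
confidence interval J± = ±c/√(T τ λ_pre λ_post) with c = 1.57 z_α, and
with J = a·w into the required duration

    T > c² / (τ λ_pre λ_post a² w²),

supplemented by the coincidence-count floor T λ_pre λ_post > 10/τ.
Printed cells convert the binding constraint to minutes (below an hour)
or hours and round to one significant figure; a value that rounds to
≥60 min is promoted to hours (58.4 min → "1 h").  This rounding rule
reproduces all 30 cells of the reference table at τ = 1 ms, α = 0.001.
T_required is by construction the *even-odds* detectability boundary:
measured detection power at exactly T_required is 49–50%, rising to
>90% at 2·T_required and falling to a few percent at T_required/4.

## Comparison detectors

The conventional correlogram test assumes two independent stationary
Poisson trains: with Δ = 1 ms bins over ±50 ms, the expected count is
n̄ = λ_pre λ_post T Δ, and any bin outside n̄ ± z_α √n̄ in the causal
short-lag region ([1, 4] ms; full-window scan optional) flags a
connection (α = 0.01 by default).

The jitter test perturbs every target spike independently by
Uniform(±5 ms), which destroys millisecond timing but preserves slow
co-modulation.  A simultaneous 99% band over the region bins is built
by the max-statistic method — the upper bound is the 99.5th percentile
of the per-surrogate *maximum* bin count, the lower bound the 0.5th
percentile of the minimum — so a null correlogram exits the band
anywhere with ~1% probability.  1000 surrogates by default; bands are
bit-reproducible given a seed.

## Scoring against ground truth

Directed pairs are scored one-vs-rest in two categories (excitatory,
inhibitory) with the Matthews correlation coefficient; the macro
average of the two summarizes a reconstruction.  True excitatory
connections at or below 1 mV are excluded from the excitatory category
entirely (they are undetectable within realistic recording times and
would swamp the false-negative count); they still count as
non-inhibitory in the inhibitory category.  A connection detected with
the wrong sign is a false negative in its true category and a false
positive in the predicted one.  Zero-denominator MCC is defined as 0.
`select_alpha` sweeps the significance level and returns the macro-MCC
maximizer; on mixed populations with marginal-strength couplings the
optimum is interior — lax levels admit false positives, stringent ones
lose true weak connections.

## Synthetic data

### Coupled point-process pairs

`generate_glm_pair` samples the model's own generative form: neuron 1
is Poisson (optionally log-sinusoidally modulated), neuron 2 is
conditionally Poisson with intensity λ2·exp(J12 Σ_k f(t − t_k)), and
mutual coupling is supported (both J12 and J21 may be nonzero; the
delayed filter keeps the joint process causal).  Sampling is exact
Ogata thinning with a certified piecewise envelope, so the pooled lag
histogram converges to the model intensity exactly; the correlogram of
a generated pair is base·exp(J f(t)) up to Poisson noise (checked at
T = 1e4 s).  Defaults are 10 Hz baselines, τ = 4 ms, d = 1 ms.  On this
fixture the fitted coupling is unbiased to within ~1% at T = 5400 s
(mean over 100 seeds within one standard error of truth) and sign
accuracy at |J| = 1 is 100%.

### Independent Poisson nulls

`generate_independent_poisson` provides the calibration fixture: on 200
seeded 10-Hz hour-long pairs, the GLMCC verdict rate at α = 0.001, the
conventional band's per-bin exceedance at α = 0.01, and the jitter
band's exit rate at the 99% level all fall inside the exact binomial
95% intervals around their nominal rates.

### Conductance-based network with known ground truth

The simulator couples Hodgkin–Huxley-type neurons: regular-spiking
pyramidal cells (Na⁺, delayed-rectifier K⁺, muscarinic M current;
Traub–Miles-style kinetics with V_T = −55 mV and an M time constant
scale of 1 s) and Erisir-type fast-spiking interneurons (Na⁺, Kv1.3,
Kv3.1–3.2).  Excitatory synapses combine a Tsodyks–Markram depressing
AMPA conductance with first-order NMDA kinetics under the standard
Mg²⁺ block f(V) = 1/(1 + 0.28 e^{−0.062V}); inhibitory synapses are
depressing GABA-A conductances.  AMPA peak conductances are log-normal
(ln-mean −3.37, ln-SD 1.3, mS/cm²); NMDA and GABA conductances are
normal with negatives resampled; excitatory cells innervate 12.5% of
the others, inhibitory cells 25%; conduction delays are uniform 0–2 ms
(excitatory) and 1–3 ms (inhibitory).  Every neuron receives an
independent Ornstein–Uhlenbeck conductance pair (exact AR(1)
discretization; stationary mean/SD reproduce the table values to <5%
on a 100-s path).

Implementation notes, in decreasing order of consequence:

- **Spike-triggered resource depletion.**  The two-state reduction of
  the depressing synapse transfers U·r of the recovered resource into
  the effective state at each release (r jumps down by U·r; between
  spikes r relaxes toward 1 − w with τ_rec = 500 ms).  Without the
  jump, depletion acts only through the 2.7-ms effective state and
  depression is negligible at realistic rates.
- **Desk-scale background compensation.**  The default network (24
  excitatory, 6 inhibitory neurons, 30 s) carries ~2% of the recurrent
  input of a full-size cortical sheet, so — following the same logic
  that motivates the background current in the first place — the
  excitatory background onto pyramidal cells is raised (mean ×5.4,
  SD ×7.5) together with their inhibitory background (mean ×5.0),
  placing them in a high-conductance fluctuation-driven regime, and
  the excitatory background onto interneurons is raised (mean ×3.0),
  making them mean-driven.  This reproduces the full-scale structure:
  interneurons fire faster and more regularly (population mean ~10–30
  Hz, median Lv ≲ 0.2) than pyramids (~0–7 Hz, skewed across cells,
  median Lv ≳ 0.5), robustly across seeds.  Larger desk-scale networks
  with these synaptic statistics slowly ratchet into a tonically firing
  subnetwork wired by the strong lognormal-tail EPSPs — containing that
  tail requires the O(100) convergent inhibition of the full network —
  which is why the default stays at 30 neurons.
- **Integration.**  Exponential-Euler updates for both gating variables
  and membrane potential (all currents are conductance-based, hence
  linear in V at fixed gating), 0.01 ms steps for pyramidal cells and
  0.001 ms substeps for interneurons; synaptic and background
  conductances are piecewise constant over the outer step.  Spikes are
  upward crossings of 0 mV with a 2-ms hold, and the detector re-arms
  only after V falls below −30 mV so that depolarization-block plateaus
  are not counted as spike trains.
- **Ground-truth PSPs.**  Each connection is probed deterministically:
  the postsynaptic cell is settled at its nominal operating point (mean
  background conductances, noise off — about −66 mV for both classes),
  one presynaptic spike is delivered (AMPA+NMDA jointly for excitatory
  connections), and the PSP is the peak signed deviation from an
  input-free control trajectory.  At this operating point GABA-A is
  hyperpolarizing (E_GABA = −75 mV), so the truth matrix is
  sign-consistent by construction; probing from the background-free
  rest (−80 mV for pyramids) would make GABA depolarizing, which is why
  the probe is defined at the operating point.  A zero conductance
  returns exactly 0 mV; negative conductances are rejected.

## What the synthetic fixtures do and do not show

The coupled-pair generator *is* the fitted model, so recovery tests on
it validate the estimator and the significance machinery, not the
model's adequacy for biological spike trains.  The network simulator
breaks that circularity — its spikes come from membrane dynamics, not
from the fitted intensity — but at desk scale its activity regime is
held in place by the compensated background rather than emerging from
recurrence, and recording durations (tens of seconds) are far below the
table's requirements for the weak majority of synapses, so it is used
for structural checks (rate and irregularity orderings, ground-truth
sign structure, skewed EPSP distribution), not for end-to-end detection
benchmarks.  Real recordings additionally contain sorting errors,
nonstationarity beyond slow rate waves, and electrode drift, none of
which the generators emulate.

## Problem sizes used by the test suite

The shipped acceptance tests use: 200 hour-long null pairs for
calibration; 100 seeds × three coupling values (90-min pairs) for
recovery; 80–200 seeds per duration for the power curve; a 12-neuron
mixed population (15 min) for the significance-level sweep; and one
30-neuron, 30-s network run for the structural checks.  These sizes
were chosen so the full suite completes in well under half an hour on
one core while keeping every binomial comparison inside its stated
confidence interval.
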