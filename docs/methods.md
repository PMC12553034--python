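# Methods

This note documents the models, algorithms, default parameters and design
choices behind `mmn_dcm`, and what the synthetic-data experiments do and do
not establish.

## The scientific setting

In the auditory roving oddball paradigm, a tone is repeated 3–11 times
before its frequency changes (400–800 Hz in 50 Hz steps); the first tone of
each block is a deviant that becomes the new standard upon repetition.  The
mismatch negativity (MMN) is the difference between the evoked response to
the deviant and to a repeated standard, here quantified from planar
gradiometers 140–160 ms post-stimulus.  Dynamic causal modeling (DCM)
explains these evoked responses with a biophysical cortical-column model
whose parameters — laminar-specific gains and inter-regional connection
strengths — are estimated from the data.  The package implements the full
chain: synthetic multi-subject data generation, first-level model
inversion, Bayesian model comparison over a space of network architectures,
and second-level (group/longitudinal) analysis.

## Canonical microcircuit model

Each cortical source is a four-population column: spiny stellate (granular
input) cells, superficial pyramidal cells, inhibitory interneurons and deep
pyramidal cells.  Each population `p` obeys second-order synaptic kinetics

    v̇ = i,   i̇ = κ_p u − 2 κ_p i − κ_p² v,

with rate constants `κ_p = 1000 / T_p`, default time constants
`T = (2, 2, 16, 28) ms` for (ss, sp, ii, dp).  The presynaptic drive `u`
sums signed intrinsic gains applied to the firing rates of the column's
populations, delayed extrinsic inputs, and exogenous input.  Firing rates
follow a centered logistic `S(v) = 1/(1+e^{−rv}) − ½` with baseline slope
`r = 2/3 mV⁻¹`.  The ten intrinsic connections and default magnitudes
(in s⁻¹, negative = inhibitory) are

    ss←ss −800, ss←ii −1600, ss←sp −800, sp←ss +800, sp←sp −800,
    ii←ss +800, ii←dp +400, ii←ii −800, dp←ii −400, dp←dp −200.

`sp←sp` is the superficial-pyramidal self-inhibition.  Its reciprocal is
the *gain* of that population — the quantity interpreted as encoding the
precision of prediction errors — so "increased gain" means *reduced*
self-inhibition.  The topology is the published canonical-microcircuit
form; the magnitudes are a conventional default set chosen for a stable
resting point (all Jacobian eigenvalues at rest have negative real parts; a
test asserts this) and realistic evoked-response shapes.  They are config
values (`DynamicsConfig`), not estimated.

Extrinsic connections follow the laminar asymmetry of the microcircuit:
forward connections originate in superficial pyramidal cells and target
spiny stellate (+800) and deep pyramidal (+400) populations; backward
connections originate in deep pyramidal cells and target superficial
pyramidal (−800) and inhibitory (+400) populations.  Conduction delay is
16 ms, globally scaled by a free log-parameter.  Auditory input — a
Gaussian bump peaking 64 ms after stimulus onset with 16 ms width — drives
the spiny stellate cells of bilateral primary auditory cortex; expectancy
input drives the superficial pyramidal cells of the highest regions of a
model (laminar target configurable; where the hippocampal origin of such
input would project is not known at laminar resolution).  The measured
source signal is a fixed pyramidal-dominated voltage mixture
(0.9·sp + 0.1·dp), scaled per region by a free log-gain.

All estimated quantities are log-scale factors on these defaults with
Gaussian priors (below), so `θ = 0` is the default model and effects
compose multiplicatively.

## Repetition (condition) model

Six conditions are modeled: the deviant and repetitions 1–5 (later
repetitions occur in the raw trial sequence but are excluded from the
evoked set).  Two repetition bases over condition index `k = 0…5`:

* exponential: `b_exp(k) = e^{−k/τ_e}`, default `τ_e = 4` conditions;
* phasic: `b_ph(0) = 0`, `b_ph(k) = −e^{−(k−1)/τ_p}` for `k ≥ 1`, unit
  maximum magnitude, default `τ_p = 2`.

Extrinsic connections are scaled through the exponential column,
`log A → log A + B_ext · b_exp(k)`: positive coefficients give
stimulus-specific adaptation (strongest coupling for the deviant, decaying
with repetition).  The superficial-pyramidal gain is modulated through the
phasic column in the combined ("EG") models.  Because the underlying
circuit parameter is the self-inhibition (reciprocal gain), the coefficient
enters with a minus sign, `log G_sp → log G_sp − B_sp · b_ph(k)`; a
positive `B_sp` therefore makes the gain (and the response) dip sharply at
the first repetition and recover over subsequent tones.  The exact
functional form of the phasic basis is a design choice of this package (the
shape is qualitative in the literature): a decaying exponential re-based to
zero at the deviant.

## Network model space

Eight sources: bilateral A1 (MNI −42 −22 7 / 46 −14 8), STG (−61 −32 8 /
59 −25 8), IFG (−46 20 8 / 46 20 8) and IPC (−58 −27 30 / 59 −41 30);
coordinates are reporting metadata only — geometry never enters the
dynamics (lead fields are synthetic).  The within-hemisphere hierarchy
IFG > STG > A1 is fixed; STG additionally sends forward connections to IPC
in every architecture (the parietal node is always attached to the temporal
hierarchy).  The six architectures differ in the IFG–IPC relation (none /
IPC above IFG / IFG above IPC) and in whether IPC receives expectancy input
(architectures 4–6) in addition to IFG.  Crossed with the two bases this
gives 12 models with a stable ordering 1E…6E, 1EG…6EG.  Homologous lateral
A1–A1 and STG–STG connections are included symmetrically (configurable);
whether the hemispheres were coupled this way in comparable studies is not
always reported, so the flag exists.

A union ("superset") model containing both IFG–IPC orderings, both
expectancy inputs and the EG basis nests every candidate; each subject is
inverted once under it, and the 12 candidates are scored analytically by
Bayesian model reduction.

A reduced **demo network** (bilateral A1+STG, hierarchy STG > A1, lateral
connections, auditory input only) exercises the full pipeline quickly.  It
deliberately has no expectancy input: in a two-level network that input
would drive the same superficial-pyramidal populations whose gain is the
quantity of interest and render it unidentifiable.

## Priors

Zero-mean diagonal Gaussians on the log-scale parameters ("default-v1"
profile): variance 1/8 on the superficial-pyramidal gain, 1/16 on extrinsic
weights and repetition coefficients, 1/128 on rate constants, 1/64 on
input gains, output gains, delay and sigmoid slope.  Parameters a model
forbids (masked connections, absent inputs, phasic coefficients in E
models, the nine conventional intrinsic gains other than sp←sp) have
exactly zero variance and are fixed constants of the inversion.  The
asymmetry is deliberate: the scientific parameters (gain, connectivity,
repetition effects) are loosely constrained while conventional biophysical
nuisance quantities are pinned tightly, because the latter can otherwise
absorb condition- and group-related variance and destroy the
identifiability of the former (their sensitivity directions are nearly
collinear in so smooth a signal).

## Numerical integration

Fixed-step classical Runge–Kutta (RK4) at 1 ms over 0–300 ms (0–500 ms when
generating epochs), from rest.  The conduction delay is a real number of
steps (≥ 3); delayed firing rates at stage times are read from the stored
rate history by quadratic interpolation at the exact delayed time, so the
discretized delay is independent of the step size.  Halving the step
changes the output by ~2·10⁻⁵ relative L2 at default parameters and stays
below 10⁻³ across prior-scale random draws (tested).  A trajectory whose
state exceeds 10⁶ is declared divergent: generation raises an error;
inside an inversion the draw is flagged and handled by step rejection, and
divergence at the prior mean is an inversion failure.  All integration is
batched over (parameter draw, condition) pairs, so the ~120 finite
-difference perturbations of a Jacobian cost one vectorized run.

An earlier implementation used the matrix-exponential local-linearization
update conventional for neural-mass ERP models; it proved only first-order
accurate for the delayed and nonlinear terms at usable step sizes and was
replaced by the RK4 scheme, which meets the 10⁻³ accuracy target at the
same cost.

## Forward model and data features

Sensor predictions are `G · diag(e^{log L}) · s(t)` with `G` the lead
field.  Model and data are compared on the 0–300 ms window at 500 Hz (151
samples, endpoints inclusive), multiplied sample-wise by a Hanning taper —
the taper weights the residuals; it does not truncate the dynamics.  Both
are reduced to principal spatial modes of the data's condition means
(default 8; deterministic sign convention), computed by SVD.  At inversion
setup the lead field is rescaled once so the prior-mean prediction matches
the data rms, and data/predictions are normalized to unit data rms, making
the noise hyperpriors scale-free.  Synthetic lead fields are smooth random
ring topographies with unit-norm columns and planar-pair structure; they
stand in for subject-specific anatomical forward models and carry no
geometry.

## Variational Laplace

Gaussian fixed-form variational inference maximizing the free energy
`F = accuracy − complexity`, exact for linear-Gaussian models (verified to
10⁻⁴ nats against closed-form evidence on random conjugate problems).
Parameter updates are Gauss–Newton with Levenberg–Marquardt damping; steps
that do not increase `F` are rejected and the damping increased
(multiplier 8, up to 6 retries), giving a monotone accepted-step trace.
Sensitivities are central finite differences with step `10⁻³(1+|θ|)`.
Noise precision is diagonal, `π_j = exp(λ_g + λ_m)` with one global and one
per-mode log-precision, Gaussian hyperpriors (global mean `log(16/var y)`,
per-mode mean 0, variance 1 — the variance is looser than a strict
fraction-style hyperprior so the estimated noise can track the actual
simulation noise across the SNR range used here), updated by Newton steps
on the exact concave conditional objective.  Convergence: ΔF < 10⁻² nats on
three successive iterations, cap 32 iterations (16 in the pipeline's demo
profile; typical runs converge in 10–14).  Inversions start at the prior
mean; there is no random initialization and no per-subject prior tweaking —
a subject that fails to integrate is excluded downstream, mirroring the
conservative convention of clinical DCM pipelines.

## Bayesian model reduction and PEB

BMR scores any model whose prior differs from the fitted model's in means
or variances analytically from the full posterior; switched-off parameters
get prior variance 10⁻⁸ rather than exactly zero to keep precisions finite
(the refit-oracle tests use the same convention).  Model comparison pools
ΔF over subjects (fixed effects, as when free energies are averaged over
participants) and reports softmax posterior model probabilities.

PEB places the second-level prior `N(X_i β, Σ_β)` on each subject's
selected parameters.  The per-subject evidence adjustment is an exact
quadratic in `β`, so the posterior over group effects and the second-level
free energy are closed-form given the between-subject variance; this
linear-Gaussian structure is the same variational objective solved exactly
rather than iteratively.  Defaults: effect prior variance 1/16;
between-subject variance = first-level prior variance/16 scaled by
`e^{−γ}` with `γ` optimized by bounded scalar search on `F` in [−4, 8].
The study designs are provided: unitary + group (patients coded 1), the
age-covariate variant, and the longitudinal design with a session indicator
(follow-up = 1) and a standardized follow-up interval regressor (zero for
baseline rows; mean 0, sd 1 over follow-up rows).  Longitudinal PEB treats
each scan as a row; the within-subject correlation is absorbed by the mean
regressor — an approximation, noted.  In the pipeline's progression stage
the BMA over the session/interval effects runs on the reduced space of
parameter pairs that differentiated the groups at baseline (inclusion
probability above 0.95); if none did, the full symmetric space is used so
the stage still reports calibrated null effects.

BMA enumerates on/off combinations of hemispherically symmetric parameter
pairs on the effect regressors (2^pairs reduced models, exhaustive up to
16 pairs, greedy pruning beyond), scores them by BMR on the `β` posterior,
and reports the probability-weighted moment-matched average plus each
parameter's inclusion probability `Pp` (left/right homologues share `Pp`
by construction).

## Sensor statistics

* Robust averaging: per condition independently, iteratively reweighted
  means with bisquare weights on MAD-standardized residuals per
  (sensor, sample), tuning constant 4.685, ≤ 8 iterations, tolerance 10⁻⁶;
  degenerate zero-scale cells keep unit weights.  A zero-phase 4th-order
  Butterworth low-pass at 40 Hz follows, correcting high frequencies the
  reweighting can introduce.
* Gradiometer RMS / "global field power": per planar pair
  `sqrt((a²+b²)/2)` per sample, then the mean over pairs.
* Mismatch amplitude: mean over 140–160 ms (both endpoints included — the
  window convention is fixed here as inclusive) of GFP(rep1) −
  GFP(deviant); negative = attenuated repetition response.
* Welch t from summary statistics with Welch–Satterthwaite df and CI;
  paired/one-sample t; one-tailed directions follow the stated predictions
  (patients < controls, follow-up < baseline).
* Repeated-measures ANOVA with Greenhouse–Geisser correction (the default;
  epsilon from the double-centered condition covariance).  A
  between-subject factor adds the group and interaction strata (verified
  against `pingouin.mixed_anova`); a between-subject covariate is handled
  by residualizing the centered covariate from each condition column — a
  documented approximation to full repeated-measures ANCOVA.
* ICC(A,1): two-way absolute-agreement single-measure intraclass
  correlation from mean squares (equal to ICC(2,1); verified against
  `pingouin`); the `form="average"` flag gives ICC(A,k).
* Minimum detectable effect: smallest Cohen's d reaching target power
  under the noncentral t (bisection to 10⁻⁶), two-sample or paired.

## Synthetic cohorts — what they emulate and what they do not

A cohort has controls (baseline session only) and patients (baseline; a
2-week retest for 14/45 of them; an annual follow-up for 32/45, with
intervals uniform on 0.8–2.2 years, standardized in the longitudinal
design), matching the study structure; the default analyzed sizes 14 and
45 are available but the shipped experiments run at demonstration scale
(below).  Subject parameters are the cohort baseline profile plus Gaussian
jitter (sd 0.1, log scale) on the free parameters plus any injected
effects, with per-subject streams derived from the master seed via
`SeedSequence(master, spawn_key)` (documented counter-based splitting, so
any subject regenerates in isolation).  The baseline profile sets
`B_ext = +0.5` on the within-hemisphere forward connections and
`B_sp = +0.5` everywhere, producing the canonical repetition pattern — a
large deviant response, a sharp drop at the first repetition, gradual
partial recovery — without which the paradigm would carry no mismatch
signal.  The default injected patient effects are −0.3 log-units on the
gain-modulation coefficients of auditory (and, in the 8-region network,
inferior frontal) regions and on the forward-connection adaptation of the
hierarchy edges — the regions and connection types the disease hypothesis
implicates.

Sensor noise is white Gaussian, identical physical level for every subject
(calibrated once at the prior-mean response so that the *averaged* evoked
response has the target amplitude SNR, default 5, at the default 60 trials
per condition — a plausible post-rejection trial count; the true value is
not knowable from summary reports).  Tone frequency affects only labels,
not responses (the analyses collapse over frequency).  Not emulated: head
movement, sensor artifacts, correlated (AR) noise — a hook exists but the
default is white — frequency-specific adaptation, inter-subject anatomical
variability beyond the per-region gains, and any relation between clinical
covariates and parameters.  Passing tests therefore demonstrate the
*internal* consistency and statistical calibration of the chain (effects
in → effects out; null in → null out), not performance on real MEG data.

## Problem sizes of the shipped experiments

The acceptance experiments run at a demonstration scale chosen to exercise
every stage: group-effect recovery uses the demo network with 8 controls +
8 patients per cohort (one effect cohort, one matched null), SNR 5, 60
trials/condition, 8 spatial modes, inversion cap 16 iterations;
model-comparison recovery simulates 3 subjects from architecture 6-EG at
the full 8 regions and inverts the superset model (cap 12 iterations);
the ANOVA calibration uses 1000 null replicates; conjugate oracles use 20
random problems.  At these sizes the whole acceptance script completes in
roughly a quarter hour on one core.  Larger cohorts sharpen the same
conclusions (the experiments at 8+8 already give inclusion probabilities
near 1 for targeted and < 0.6 for untargeted parameters).

## Known limitations

* Absolute (condition-invariant) gain and connectivity levels are only
  weakly identifiable from a single evoked dataset — their sensitivity
  directions are nearly collinear with output/input gains.  The analyses
  therefore target the repetition-modulation coefficients, which are
  identified by between-condition differences; this matches the scientific
  question (how the network's response to repetitions changes) but means
  per-subject absolute parameter estimates should not be over-interpreted.
* Fixed-effects model comparison assumes the same architecture across
  subjects; a random-effects alternative is not implemented.
* The longitudinal design's two-rows-per-subject approximation ignores
  residual within-subject correlation beyond the mean regressor.
* The greedy BMA search above 16 symmetric pairs explores a chain of
  single-pair exclusions, not the full lattice.
* Inversion failures are excluded, not diagnosed; at default scales and
  priors they essentially never occur, so the exclusion path is exercised
  only by constructed divergent priors in the tests.
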