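# mmn-dcm

Dynamic causal modeling of the auditory roving mismatch negativity, as a
self-contained, testable pipeline: a canonical-microcircuit (CMC)
neural-mass model of an eight-region parieto-frontal network, variational
Laplace inversion of evoked MEG responses, Bayesian model reduction (BMR)
over a 12-model architecture space, parametric empirical Bayes (PEB) group
and longitudinal analyses with Bayesian model averaging (BMA), and the
accompanying sensor-level statistics — driven by a synthetic multi-subject
data generator that emulates the paradigm's trial structure and a
patient/control cohort design, so the entire chain runs with no external
data.

**Who it is for.** Researchers who analyze evoked-response DCMs of
mismatch/oddball paradigms and want an inspectable, scriptable Python
implementation of the full first-level + second-level chain; and anyone who
needs calibrated synthetic benchmarks for gain/connectivity recovery
through that chain.

## The model in brief

Each cortical source is a four-population column (spiny stellate `ss`,
superficial pyramidal `sp`, inhibitory interneurons `ii`, deep pyramidal
`dp`) with second-order synaptic kinetics

    v̇ = i,   i̇ = κ u − 2κ i − κ² v,

sigmoidal voltage-to-rate coupling, laminar-specific extrinsic connections
(forward: `sp → ss, dp`; backward: `dp → sp, ii`) and conduction delays.
All estimated quantities are log-scale factors θ with Gaussian priors, so
`θ = 0` is the default microcircuit.  Responses to the deviant and first
five repetitions are tied together by repetition bases: exponential decay
`e^{−k/τ}` on the extrinsic connections (stimulus-specific adaptation) and
a phasic basis on the superficial-pyramidal *gain* — the precision
parameter of predictive-coding accounts — which dips after the deviant and
recovers.  Inversion maximizes the variational free energy
`F = accuracy − complexity` (a lower bound on log evidence, exact for
linear-Gaussian models); candidate architectures are scored from one
superset fit by BMR; group effects are estimated by PEB
(`θ_i ~ N(X_i β, Σ)`) and averaged over all hemispherically symmetric
parameter combinations, yielding per-parameter effect sizes and inclusion
probabilities `Pp`.  See `docs/methods.md` for the complete specification.

## A worked example

`examples/02_simulate_evoked.py` simulates one subject of the demo network
(bilateral A1+STG) at evoked SNR 5 and prints the sensor-level repetition
profile:

```
mean GFP in the 140-160 ms window per condition:
  deviant  0.0196
  rep1     0.0161
  rep2     0.0173
  rep3     0.0171
  rep4     0.0173
  rep5     0.0172
mismatch amplitude (rep1 - deviant): -0.0035
```

The deviant evokes the largest response; the first repetition the
smallest; later repetitions partially recover — the classic mismatch
pattern, produced here by the generative model's adaptation and phasic
gain modulation.  The negative mismatch amplitude (gradiometer-RMS units)
is the quantity compared between groups and sessions.

`examples/06_peb_group_effects.py` runs the full group chain on a small
cohort whose patients carry −0.3 log-unit reductions in auditory
gain modulation and forward-connection adaptation; it prints per-parameter
group effects with their `Pp`, recovering negative effects on the targeted
parameters and near-zero effects elsewhere.  The other examples cover the
trial-sequence generator, single-subject inversion, the 12-model space and
the sensor statistics.

A thin CLI wraps the same pipeline:

```bash
mmn-dcm all --seed 1 --out runs/demo --demo
```

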