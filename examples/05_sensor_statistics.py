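"""Sensor-level statistics: group comparison, power, reliability.

Reproduces the style of the cohort-level sensor analyses from printed
summary statistics and from synthetic data: a Welch t test on age-like
summary data, minimum detectable effect sizes for the study's sample sizes,
and a test-retest intraclass correlation on synthetic mismatch amplitudes.
"""
import numpy as np
from mmn_dcm import welch_t, min_detectable_effect, icc_absolute, \
    build_demo_network, make_cohort, make_leadfield, simulate_cohort_epochs, \
    robust_average, mmn_amplitude

# Welch t from summary statistics (two groups of 14 and 45)
r = welch_t(65.3, 7.29, 14, 73.8, 7.32, 45, tail="two")
print(f"Welch t({r.df:.1f}) = {r.statistic:.2f}, "
      f"95% CI [{r.ci[0]:.1f}, {r.ci[1]:.2f}], p = {r.p:.4f}")

# minimum detectable effects at 80% power, one-tailed alpha = 0.05
d_between = min_detectable_effect(14, 45, tails=1)
d_paired = min_detectable_effect(32, tails=1)
print(f"minimum detectable d: between-group (14 vs 45) = {d_between:.2f}, "
      f"paired (n=32) = {d_paired:.2f}")

# test-retest ICC(A,1) on synthetic mismatch amplitudes
net = build_demo_network()
cohort = make_cohort(0, 8, {}, seed=11, network=net, n_retest=8, n_followup=0)
lf = make_leadfield(32, net, seed=12)
epochs = simulate_cohort_epochs(cohort, lf, snr=5.0, n_trials_per_condition=60)
amps = {ses: [] for ses in ("baseline", "retest")}
for sub in cohort.subjects:
    for ses in ("baseline", "retest"):
        ev = robust_average(epochs[(sub.subject_id, ses)])
        amps[ses].append(mmn_amplitude(ev, lf.sensor_pairs))
icc = icc_absolute(amps["baseline"], amps["retest"])
print(f"test-retest ICC(A,1) of the mismatch amplitude: {icc:.2f} "
      f"(same true parameters, independent noise)")
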