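"""Synthetic roving cohorts: sequences, lead fields, epochs, containers."""

import numpy as np
import pytest

from mmn_dcm.synthetic import (generate_roving_sequence, make_leadfield,
                               make_cohort, simulate_subject_evoked,
                               simulate_cohort_epochs, noise_sd_for_snr,
                               n_epoch_samples, TONE_FREQUENCIES_HZ,
                               default_baseline_profile, CONDITION_LABELS)
from mmn_dcm.model_space import build_demo_network, default_priors
from mmn_dcm import io as mio


class TestRovingSequence:
    def test_single_block_has_one_deviant(self):
        seq = generate_roving_sequence(1, seed=0)
        assert (seq.repetition_index == 0).sum() == 1
        assert seq.condition_label[0] == "deviant"

    def test_block_structure_invariants(self):
        seq = generate_roving_sequence(50, seed=1)
        for b in np.unique(seq.block_index):
            m = seq.block_index == b
            freqs = seq.tone_frequency_hz[m]
            assert len(set(freqs)) == 1          # constant within block
            assert 3 <= m.sum() <= 11
            assert seq.repetition_index[m][0] == 0
            labs = np.array(seq.condition_label)[m]
            assert labs[0] == "deviant"
        # frequency changes across consecutive blocks, grid respected
        starts = [seq.tone_frequency_hz[seq.block_index == b][0]
                  for b in range(50)]
        assert all(a != b for a, b in zip(starts, starts[1:]))
        assert set(starts) <= set(map(float, TONE_FREQUENCIES_HZ))

    def test_mean_block_length_matches_uniform_3_11(self):
        seq = generate_roving_sequence(1000, seed=2)
        lengths = np.bincount(seq.block_index)
        se = np.sqrt(np.var(np.arange(3, 12)) / 1000)
        assert abs(lengths.mean() - 7.0) < 3 * se

    def test_surplus_labels_beyond_rep5(self):
        seq = generate_roving_sequence(200, seed=3)
        reps = seq.repetition_index
        labs = np.array(seq.condition_label)
        assert np.all(labs[reps > 5] == "surplus")

    def test_invalid_block_count(self):
        with pytest.raises(ValueError):
            generate_roving_sequence(0, seed=0)


class TestLeadField:
    def test_deterministic_under_seed(self, demo_net):
        a = make_leadfield(32, demo_net, seed=5)
        b = make_leadfield(32, demo_net, seed=5)
        assert np.array_equal(a.gain_matrix, b.gain_matrix)

    def test_unit_norm_columns_and_full_rank(self, demo_net):
        lf = make_leadfield(64, demo_net, seed=6)
        norms = np.linalg.norm(lf.gain_matrix, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-12)
        assert np.linalg.matrix_rank(lf.gain_matrix) == 4
        assert not np.any(np.all(lf.gain_matrix == 0, axis=1))

    def test_pairs_partition_sensors(self, demo_net):
        lf = make_leadfield(32, demo_net, seed=6)
        flat = sorted(s for p in lf.sensor_pairs for s in p)
        assert flat == list(range(32))

    def test_too_few_or_odd_sensors_rejected(self, demo_net):
        with pytest.raises(ValueError):
            make_leadfield(6, demo_net, seed=0)
        with pytest.raises(ValueError):
            make_leadfield(33, demo_net, seed=0)


class TestCohort:
    def test_null_effect_groups_identical_in_expectation(self, demo_net):
        coh = make_cohort(40, 40, {}, seed=9, network=demo_net,
                          baseline_profile={})
        lay = demo_net.layout
        j = lay.index["B_sp[A1l]"]
        ctrl = [lay.to_vector(s.true_params["baseline"])[j]
                for s in coh.by_group("control")]
        pat = [lay.to_vector(s.true_params["baseline"])[j]
               for s in coh.by_group("patient")]
        se = 0.1 * np.sqrt(1 / 40 + 1 / 40)
        assert abs(np.mean(ctrl) - np.mean(pat)) < 4 * se

    def test_null_cohorts_reject_at_nominal_rate(self, demo_net):
        # with no injected effect, a two-sample t test on a true parameter
        # across groups rejects at the nominal 5% rate over replicate
        # cohorts (within 2 Monte-Carlo standard errors)
        from scipy import stats as sps
        lay = demo_net.layout
        j = lay.index["B_sp[A1l]"]
        reps = 500
        rej = 0
        for r in range(reps):
            coh = make_cohort(4, 4, {}, seed=20000 + r, network=demo_net)
            ctrl = [lay.to_vector(s.true_params["baseline"])[j]
                    for s in coh.by_group("control")]
            pat = [lay.to_vector(s.true_params["baseline"])[j]
                   for s in coh.by_group("patient")]
            if sps.ttest_ind(ctrl, pat).pvalue < 0.05:
                rej += 1
        rate = rej / reps
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 2 * mc_se

    def test_injected_group_effect_recovered_at_large_n(self, demo_net):
        coh = make_cohort(150, 150, {"B_sp[A1l]": -0.3}, seed=10,
                          network=demo_net)
        lay = demo_net.layout
        j = lay.index["B_sp[A1l]"]
        diff = np.mean([lay.to_vector(s.true_params["baseline"])[j]
                        for s in coh.by_group("patient")]) \
            - np.mean([lay.to_vector(s.true_params["baseline"])[j]
                       for s in coh.by_group("control")])
        se = 0.1 * np.sqrt(2 / 150)
        assert abs(diff - (-0.3)) < 3 * se

    def test_study_sized_cohort_and_session_structure(self, demo_net):
        coh = make_cohort(14, 45, {}, seed=11, network=demo_net)
        assert len(coh.by_group("control")) == 14
        assert len(coh.by_group("patient")) == 45
        assert all(s.sessions == ("baseline",)
                   for s in coh.by_group("control"))
        n_re = sum("retest" in s.sessions for s in coh.by_group("patient"))
        n_fu = sum("followup" in s.sessions for s in coh.by_group("patient"))
        assert (n_re, n_fu) == (14, 32)
        for s in coh.by_group("patient"):
            if "followup" in s.sessions:
                assert 0.8 <= s.interval_years <= 2.2

    def test_unknown_effect_name_rejected(self, demo_net):
        with pytest.raises(KeyError):
            make_cohort(1, 1, {"nonsense": 1.0}, seed=0, network=demo_net)

    def test_session_effect_applies_at_followup_only(self, demo_net):
        coh = make_cohort(0, 10, {"B_sp[A1l]": {"session": -0.5}}, seed=12,
                          network=demo_net, n_followup=10)
        lay = demo_net.layout
        j = lay.index["B_sp[A1l]"]
        for s in coh.subjects:
            base = lay.to_vector(s.true_params["baseline"])[j]
            fu = lay.to_vector(s.true_params["followup"])[j]
            assert fu - base == pytest.approx(-0.5)


class TestEpochSimulation:
    def test_epoch_grid_has_301_samples(self):
        assert n_epoch_samples() == 301

    def test_zero_noise_single_trial_reproduces_prediction(self, demo_net,
                                                           demo_leadfield):
        p = demo_net.layout.zeros()
        ep = simulate_subject_evoked(p, demo_net, demo_leadfield, 0.0, 1,
                                     seed=1)
        assert ep.data.shape == (6, 32, 301)
        ep2 = simulate_subject_evoked(p, demo_net, demo_leadfield, 0.0, 3,
                                      seed=2)
        for k in range(6):
            lab = CONDITION_LABELS[k]
            assert np.allclose(ep2.condition_mean(lab), ep.data[k])

    def test_no_modulation_makes_conditions_identical(self, demo_net,
                                                      demo_leadfield):
        p = demo_net.layout.zeros()      # all B coefficients zero
        ep = simulate_subject_evoked(p, demo_net, demo_leadfield, 0.0, 1,
                                     seed=1)
        for k in range(1, 6):
            assert np.allclose(ep.data[k], ep.data[0], atol=1e-12)

    def test_sem_scaling_with_trial_count(self, demo_net, demo_leadfield):
        p = demo_net.layout.zeros()
        ep = simulate_subject_evoked(p, demo_net, demo_leadfield,
                                     noise_sd=1.0,
                                     n_trials_per_condition=100, seed=3)
        # with unit-sd trial noise, the SEM of a 100-trial condition mean
        # is 0.1 per sample
        per_sample_sem = np.std(ep.data[:100], axis=0).mean() / 10.0
        assert per_sample_sem == pytest.approx(0.1, rel=0.05)

    def test_snr_calibration(self, demo_net, demo_leadfield):
        p = demo_net.layout.zeros()
        sd = noise_sd_for_snr(p, demo_net, demo_leadfield, snr=5.0,
                              n_trials_per_condition=60)
        clean = simulate_subject_evoked(p, demo_net, demo_leadfield, 0.0, 1,
                                        seed=0).data
        assert sd == pytest.approx(
            np.sqrt(np.mean(clean**2)) * np.sqrt(60) / 5.0, rel=1e-9)

    def test_negative_noise_rejected(self, demo_net, demo_leadfield):
        with pytest.raises(ValueError):
            simulate_subject_evoked(demo_net.layout.zeros(), demo_net,
                                    demo_leadfield, -1.0, 1, seed=0)


class TestDeterminismAndContainers:
    def test_dataset_bytes_reproducible(self, demo_net, tmp_path):
        import hashlib

        def build(path):
            coh = make_cohort(1, 1, {}, seed=33, network=demo_net)
            lf = make_leadfield(16, demo_net, seed=34)
            eps = simulate_cohort_epochs(coh, lf, snr=5.0,
                                         n_trials_per_condition=4)
            mio.write_dataset(path, eps, lf, coh)
            return mio.file_sha256(path)

        h1 = build(tmp_path / "a.h5")
        h2 = build(tmp_path / "b.h5")
        assert h1 == h2

    def test_hdf5_roundtrip(self, demo_net, tmp_path):
        coh = make_cohort(1, 1, {}, seed=35, network=demo_net)
        lf = make_leadfield(16, demo_net, seed=36)
        eps = simulate_cohort_epochs(coh, lf, snr=5.0,
                                     n_trials_per_condition=3)
        path = tmp_path / "d.h5"
        mio.write_dataset(path, eps, lf, coh)
        eps2, lf2 = mio.read_dataset(path)
        assert np.array_equal(lf2.gain_matrix, lf.gain_matrix)
        key = next(iter(eps))
        assert np.array_equal(eps2[key].data, eps[key].data)
        assert eps2[key].condition_label == eps[key].condition_label

    def test_subject_table_and_ground_truth(self, demo_net):
        coh = make_cohort(2, 3, {}, seed=37, network=demo_net)
        t = mio.subject_table(coh)
        assert set(t.columns) >= {"subject_id", "group", "session",
                                  "interval_years"}
        assert (t.session == "baseline").sum() == 5
        import json
        gt = json.loads(mio.ground_truth_to_json(coh))
        assert len(gt["subjects"]) == 5
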