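"""Bayesian model reduction, PEB hierarchies, and model averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal as mvn

from mmn_dcm.parameters import GaussianDensity, PriorDensity
from mmn_dcm.bmr_peb import (bayesian_model_reduction, fit_peb,
                             bma_over_parameter_sets, build_designs,
                             compare_model_space, hemispheric_pairs,
                             PEBDesign)


def _conjugate(rng, N=25, p=5):
    X = rng.normal(size=(N, p))
    pi = rng.uniform(0.5, 3.0, N)
    m0 = rng.normal(scale=0.3, size=p)
    v0 = rng.uniform(0.3, 2.0, p)
    y = X @ (m0 + rng.normal(size=p) * np.sqrt(v0)) \
        + rng.normal(size=N) / np.sqrt(pi)

    def fit(m, V):
        S = np.diag(1 / pi) + X @ V @ X.T
        lev = mvn.logpdf(y, X @ m, S)
        P = (X.T * pi) @ X + np.linalg.inv(V)
        C = np.linalg.inv(P)
        return lev, C @ ((X.T * pi) @ y + np.linalg.inv(V) @ m), C

    return X, pi, m0, v0, y, fit


class TestBMR:
    def test_identity_reduction_is_neutral(self, rng):
        X, pi, m0, v0, y, fit = _conjugate(rng)
        _, mq, Sq = fit(m0, np.diag(v0))
        labels = tuple(f"p{i}" for i in range(len(m0)))
        post = GaussianDensity(mq, Sq, labels)
        prior = GaussianDensity(m0, np.diag(v0), labels)
        dF, rq = bayesian_model_reduction(post, prior, prior)
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rq.mean, mq)

    def test_matches_explicit_refits(self, rng):
        for _ in range(20):
            X, pi, m0, v0, y, fit = _conjugate(rng)
            lev_full, mq, Sq = fit(m0, np.diag(v0))
            v0r = v0.copy()
            v0r[:2] = 1e-8
            m0r = m0.copy()
            m0r[3] += 0.4
            lev_red, m_ref, _ = fit(m0r, np.diag(v0r))
            labels = tuple(f"p{i}" for i in range(len(m0)))
            dF, rq = bayesian_model_reduction(
                GaussianDensity(mq, Sq, labels),
                GaussianDensity(m0, np.diag(v0), labels),
                GaussianDensity(m0r, np.diag(v0r), labels))
            assert dF == pytest.approx(lev_red - lev_full, abs=1e-4)
            assert np.max(np.abs(rq.mean - m_ref)) < 1e-6

    def test_pruning_spurious_parameter_saves_complexity(self, rng):
        # a weakly-informed regressor with no true effect: shrinking its
        # prior to (near) zero removes its complexity cost and increases
        # the evidence; checked against the explicit refit oracle
        rng = np.random.default_rng(4)
        N, p = 30, 3
        X = rng.normal(size=(N, p))
        pi = np.ones(N)
        m0, v0 = np.zeros(p), np.ones(p)
        y = X[:, :2] @ rng.normal(size=2) + rng.normal(size=N)
        P = (X.T * pi) @ X + np.eye(p)
        Sq = np.linalg.inv(P)
        mq = Sq @ (X.T @ y)
        labels = ("a", "b", "c")
        v0r = v0.copy()
        v0r[2] = 1e-8
        dF, _ = bayesian_model_reduction(
            GaussianDensity(mq, Sq, labels),
            GaussianDensity(m0, np.diag(v0), labels),
            GaussianDensity(m0, np.diag(v0r), labels))
        from scipy.stats import multivariate_normal as mvn
        lev_full = mvn.logpdf(y, np.zeros(N),
                              np.eye(N) + X @ np.diag(v0) @ X.T)
        lev_red = mvn.logpdf(y, np.zeros(N),
                             np.eye(N) + X @ np.diag(v0r) @ X.T)
        assert dF == pytest.approx(lev_red - lev_full, abs=1e-4)
        assert dF > 0

    def test_label_mismatch_rejected(self, rng):
        g1 = GaussianDensity(np.zeros(2), np.eye(2), ("a", "b"))
        g2 = GaussianDensity(np.zeros(2), np.eye(2), ("a", "c"))
        with pytest.raises(ValueError):
            bayesian_model_reduction(g1, g1, g2)


class TestModelSpaceComparison:
    def test_identical_models_split_probability(self, demo_net, demo_priors):
        from mmn_dcm.model_space import build_demo_network
        post = demo_priors.free_density()
        df = compare_model_space([post], demo_net,
                                 [build_demo_network(), build_demo_network()],
                                 demo_priors)
        assert np.allclose(df.posterior_prob, 0.5)
        assert df.posterior_prob.sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_subject_skipped_with_warning(self, demo_net,
                                                  demo_priors):
        from mmn_dcm.model_space import build_demo_network
        post = demo_priors.free_density()
        with pytest.warns(UserWarning):
            df = compare_model_space([post, None], demo_net,
                                     [build_demo_network()], demo_priors)
        assert len(df) == 1


class TestPEB:
    def _make_posts(self, rng, n, k_extra=2, effect=0.0, obs_sd=0.15):
        # first level: direct noisy observation of parameters
        pfull = 4 + k_extra
        labels = tuple([f"f{i}" for i in range(4)]
                       + [f"n{i}" for i in range(k_extra)])
        v0 = np.array([0.25] * 4 + [0.1] * k_extra)
        X = np.column_stack([np.ones(n),
                             np.r_[np.zeros(n // 2), np.ones(n - n // 2)]])
        posts = []
        for i in range(n):
            th = np.zeros(pfull)
            th[:2] += X[i, 1] * effect      # group effect on f0, f1
            th += rng.normal(0, 0.1, pfull)
            obs = th + rng.normal(0, obs_sd, pfull)
            P = np.diag(1 / v0) + np.eye(pfull) / obs_sd**2
            C = np.linalg.inv(P)
            posts.append(GaussianDensity(C @ (obs / obs_sd**2), C, labels))
        pri = PriorDensity(np.zeros(pfull), v0, labels)
        des = PEBDesign(X, ("mean", "group"),
                        tuple(str(i) for i in range(n)),
                        tuple(f"f{i}" for i in range(4)))
        return posts, pri, des

    def test_single_subject_unitary_design_returns_first_level(self, rng):
        posts, pri, _ = self._make_posts(rng, 2)
        des = PEBDesign(np.ones((1, 1)), ("mean",), ("0",),
                        ("f0", "f1", "f2", "f3"))
        peb = fit_peb(posts[:1], des, pri)
        first = posts[0].marginal(("f0", "f1", "f2", "f3"))
        est = np.array([peb.effects("mean")[f] for f in
                        ("f0", "f1", "f2", "f3")])
        # with a broad between-subject variance the second level tracks the
        # single subject's posterior for the selected fields
        assert np.allclose(est, first.mean, atol=0.08)

    def test_group_effect_recovered(self, rng):
        posts, pri, des = self._make_posts(rng, 20, effect=-0.4)
        peb = fit_peb(posts, des, pri)
        eff = peb.effects("group")
        assert eff["f0"] < -0.2 and eff["f1"] < -0.2
        assert abs(eff["f2"]) < 0.15 and abs(eff["f3"]) < 0.15

    def test_permuted_labels_shrink_effects(self, rng):
        shrunk = 0
        for rep in range(10):
            r2 = np.random.default_rng(100 + rep)
            posts, pri, des = self._make_posts(r2, 16, effect=-0.4)
            peb = fit_peb(posts, des, pri)
            true_mag = abs(peb.effects("group")["f0"])
            perm = r2.permutation(16)
            Xp = des.X.copy()
            Xp[:, 1] = Xp[perm, 1]
            des_p = PEBDesign(Xp, des.regressor_names, des.row_ids,
                              des.field_selection)
            peb_p = fit_peb(posts, des_p, pri)
            if abs(peb_p.effects("group")["f0"]) < true_mag:
                shrunk += 1
        assert shrunk >= 8

    def test_rank_deficient_design_rejected(self, rng):
        posts, pri, des = self._make_posts(rng, 4)
        X = np.ones((4, 2))
        with pytest.raises(ValueError):
            PEBDesign(X, ("mean", "dup"), tuple("abcd"))

    def test_empty_field_selection_rejected(self, rng):
        posts, pri, des = self._make_posts(rng, 4)
        des2 = PEBDesign(des.X[:4], ("mean", "group"), tuple("abcd"))
        with pytest.raises(ValueError):
            fit_peb(posts[:4], des2, pri)


class TestBMA:
    def test_single_model_average_equals_that_model(self, rng):
        posts = [GaussianDensity(np.array([0.5, 0.5]),
                                 0.01 * np.eye(2), ("fl", "fr"))
                 for _ in range(4)]
        pri = PriorDensity(np.zeros(2), np.array([0.25, 0.25]), ("fl", "fr"))
        des = PEBDesign(np.column_stack([np.ones(4), [0, 0, 1, 1]]),
                        ("mean", "group"), tuple("abcd"), ("fl", "fr"))
        peb = fit_peb(posts, des, pri)
        bma = bma_over_parameter_sets(peb, symmetry_pairs=[("fl", "fr")])
        # strong-evidence case: the all-on model dominates, BMA ~ its posterior
        assert set(bma.pp) == {"group:fl", "group:fr"}

    def test_left_right_homologues_share_pp(self, rng):
        posts, pri, des = TestPEB()._make_posts(rng, 16, effect=-0.5)
        # rename fields to hemisphere-style labels
        peb = fit_peb(posts, des, pri)
        bma = bma_over_parameter_sets(
            peb, symmetry_pairs=[("f0", "f1"), ("f2", "f3")])
        assert bma.pp["group:f0"] == bma.pp["group:f1"]
        assert bma.pp["group:f2"] == bma.pp["group:f3"]
        assert bma.pp["group:f0"] > 0.95          # injected strong effect
        assert bma.pp["group:f2"] < 0.5

    def test_unpaired_parameter_rejected(self, rng):
        posts, pri, des = TestPEB()._make_posts(rng, 8)
        peb = fit_peb(posts, des, pri)
        with pytest.raises(ValueError):
            bma_over_parameter_sets(peb, symmetry_pairs=[("f0", "nope")])

    def test_hemispheric_pairing_of_layout_labels(self):
        pairs = hemispheric_pairs(["B_sp[A1l]", "B_sp[A1r]",
                                   "B_fwd[A1l->STGl]", "B_fwd[A1r->STGr]"])
        assert ("B_sp[A1l]", "B_sp[A1r]") in pairs
        assert ("B_fwd[A1l->STGl]", "B_fwd[A1r->STGr]") in pairs
        with pytest.raises(ValueError):
            hemispheric_pairs(["B_sp[A1l]"])


class TestLongitudinalPEB:
    def test_session_effect_recovered_on_reduced_space(self, rng):
        # patients scanned at baseline and follow-up; a -0.4 session effect
        # on f0/f1; the BMA runs over the reduced space of pairs flagged at
        # baseline, exercising the longitudinal design end to end on a
        # linear first level
        n_pat, k_sel = 10, 4
        labels = tuple(f"f{i}" for i in range(k_sel))
        v0 = np.full(k_sel, 0.25)
        rows = []
        posts = []
        for i in range(n_pat):
            base = rng.normal(0, 0.1, k_sel)
            for ses, shift in (("baseline", 0.0), ("followup", -0.4)):
                th = base.copy()
                th[:2] += shift
                obs = th + rng.normal(0, 0.1, k_sel)
                P = np.diag(1 / v0) + np.eye(k_sel) / 0.1**2
                C = np.linalg.inv(P)
                posts.append(GaussianDensity(C @ (obs / 0.1**2), C, labels))
                rows.append(dict(subject_id=f"P{i}", group="patient",
                                 session=ses,
                                 interval_years=1.0 + 0.1 * i))
        table = pd.DataFrame(rows)
        design = build_designs(table)["longitudinal"]
        pri = PriorDensity(np.zeros(k_sel), v0, labels)
        peb = fit_peb(posts, PEBDesign(design.X, design.regressor_names,
                                       design.row_ids, labels), pri)
        eff = peb.effects("session")
        assert eff["f0"] < -0.2 and eff["f1"] < -0.2
        assert abs(eff["f2"]) < 0.15
        # reduced model space: only the pair flagged at "baseline"
        bma = bma_over_parameter_sets(
            peb, symmetry_pairs=[("f0", "f1")],
            regressors=("session", "interval"))
        assert bma.pp["session:f0"] > 0.95
        assert bma.pp["session:f0"] == bma.pp["session:f1"]


class TestDesigns:
    def _table(self):
        return pd.DataFrame([
            dict(subject_id="C0", group="control", session="baseline",
                 interval_years=0.0, age=66.0),
            dict(subject_id="C1", group="control", session="baseline",
                 interval_years=0.0, age=64.0),
            dict(subject_id="P0", group="patient", session="baseline",
                 interval_years=0.0, age=72.0),
            dict(subject_id="P0", group="patient", session="followup",
                 interval_years=1.0, age=72.0),
            dict(subject_id="P1", group="patient", session="baseline",
                 interval_years=0.0, age=75.0),
            dict(subject_id="P1", group="patient", session="followup",
                 interval_years=2.0, age=75.0),
            dict(subject_id="P2", group="patient", session="baseline",
                 interval_years=0.0, age=70.0),
        ])

    def test_baseline_group_coding(self):
        d = build_designs(self._table())["baseline_group"]
        assert d.X.shape == (5, 2)
        assert np.array_equal(d.X[:, 1], [0, 0, 1, 1, 1])

    def test_age_covariate_adds_one_column(self):
        designs = build_designs(self._table())
        assert designs["baseline_group_age"].X.shape[1] == \
            designs["baseline_group"].X.shape[1] + 1

    def test_longitudinal_interval_standardized_over_followups(self):
        d = build_designs(self._table())["longitudinal"]
        fu = d.X[:, 1] == 1
        iv = d.X[fu, 2]
        assert iv.mean() == pytest.approx(0.0, abs=1e-12)
        assert iv.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert np.all(d.X[~fu, 2] == 0)
        # only subjects with a follow-up contribute rows
        assert len(d.X) == 4

    def test_missing_interval_rejected(self):
        t = self._table()
        t.loc[3, "interval_years"] = np.nan
        with pytest.raises(ValueError):
            build_designs(t)
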