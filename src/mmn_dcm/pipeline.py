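"""Orchestration: simulate -> sensor stats -> invert -> compare -> PEB.

A :class:`RunConfig` fully determines a run; every stage persists its
outputs under the run directory and the manifest records configuration,
derived seeds and content hashes, so identical configurations give
hash-identical artifacts.  Subjects whose inversion fails are recorded in
the manifest and excluded from the group stages rather than refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import logging
from pathlib import Path
import numpy as np
import pandas as pd

from .model_space import (build_demo_network, build_full_network,
                          enumerate_model_space, default_priors)
from .synthetic import (make_cohort, make_leadfield, simulate_cohort_epochs,
                        CONDITION_LABELS)
from .inversion import fit_vl, VLOptions, InversionFailure
from .bmr_peb import (fit_peb, bma_over_parameter_sets, build_designs,
                      compare_model_space, PEBDesign)
from .sensor_stats import (robust_average, mmn_amplitude, welch_t, paired_t,
                           icc_absolute, rm_anova_gg, min_detectable_effect)
from . import io as mio

__all__ = ["RunConfig", "run_pipeline", "invert_cohort", "sensor_report",
           "default_group_effects"]

log = logging.getLogger("mmn_dcm")


def default_group_effects(network, amount: float = -0.3) -> dict:
    """Study-hypothesis group effects: reduced superficial-pyramidal gain
    modulation in auditory and inferior frontal cortices and reduced forward
    pyramidal connectivity along the within-hemisphere hierarchy."""
    lay = network.layout
    rn = lay.region_names
    eff = {f"B_sp[{r}]": amount for r in rn
           if r.startswith(("A1", "IFG"))}
    for (s, d) in lay.fwd_edges:
        if rn[s][:-1] != rn[d][:-1]:    # hierarchy edges, not laterals
            eff[f"B_fwd[{rn[s]}->{rn[d]}]"] = amount
    return eff


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "runs/demo"
    demo: bool = True                  # bilateral A1+STG network
    n_controls: int = 8
    n_patients: int = 8
    effects: dict | None = None        # None -> study-hypothesis defaults
    null_effects: bool = False         # override: no injected effects
    snr: float = 5.0
    n_trials: int = 60
    n_sensors: int = 32
    n_modes: int = 8
    max_iter: int = 16
    run_model_comparison: bool = False
    run_peb: bool = True
    run_longitudinal: bool = False     # session/interval PEB on patients
    jobs: int = 1
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as f:
            payload = yaml.safe_load(f) or {}
        return cls(**payload)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _network(cfg: RunConfig):
    return build_demo_network() if cfg.demo else build_full_network()


def simulate_stage(cfg: RunConfig, out: Path):
    net = _network(cfg)
    if cfg.null_effects:
        effects = {}
    elif cfg.effects is None:
        effects = default_group_effects(net)
    else:
        effects = cfg.effects
    cohort = make_cohort(cfg.n_controls, cfg.n_patients, effects,
                         seed=cfg.seed, network=net)
    lf_seed = int(np.random.SeedSequence(cfg.seed, spawn_key=(9,))
                  .generate_state(1)[0] % (2**31))
    lf = make_leadfield(cfg.n_sensors, net, seed=lf_seed)
    epochs = simulate_cohort_epochs(cohort, lf, snr=cfg.snr,
                                    n_trials_per_condition=cfg.n_trials)
    mio.write_dataset(out / "dataset.h5", epochs, lf, cohort)
    mio.subject_table(cohort).to_csv(out / "subjects.csv", index=False)
    (out / "ground_truth.json").write_text(mio.ground_truth_to_json(cohort))
    return net, cohort, lf, epochs


def _condition_means(ep):
    ev = robust_average(ep)
    return ev


def sensor_report(cohort, epochs, leadfield, out: Path | None = None) -> dict:
    """Sensor-space analysis: MMN amplitudes, group/session tests, ICC."""
    pairs = leadfield.sensor_pairs
    table = []
    gfps = {}
    for (sid, ses), ep in epochs.items():
        ev = robust_average(ep)
        amp = mmn_amplitude(ev, pairs)
        grp = next(s.group for s in cohort.subjects if s.subject_id == sid)
        table.append(dict(subject_id=sid, session=ses, group=grp, mmn=amp))
        from .sensor_stats import gradiometer_rms_gfp, MMN_WINDOW_MS
        gfp = gradiometer_rms_gfp(ev, pairs)
        m = (ev.times_ms >= MMN_WINDOW_MS[0] - 1e-9) \
            & (ev.times_ms <= MMN_WINDOW_MS[1] + 1e-9)
        gfps[(sid, ses)] = gfp[:, m].mean(axis=1)  # per-condition amplitude
    df = pd.DataFrame(table)

    report = {}
    base = df[df.session == "baseline"]
    ctrl = base[base.group == "control"]["mmn"]
    pat = base[base.group == "patient"]["mmn"]
    if len(ctrl) >= 2 and len(pat) >= 2:
        # prediction: response magnitude smaller (less negative MMN
        # difference in magnitude) in patients; tested one-tailed
        r = welch_t(pat.mean(), pat.std(ddof=1), len(pat),
                    ctrl.mean(), ctrl.std(ddof=1), len(ctrl), tail="greater")
        report["baseline_group_t"] = dict(t=r.statistic, df=r.df, p=r.p)
        # repetition-number ANOVA with group factor
        rows = [gfps[(s, "baseline")] for s in base["subject_id"]]
        res = rm_anova_gg(np.stack(rows), group=base["group"].to_numpy())
        report["rm_anova"] = {k: dict(F=v.statistic, df=list(np.atleast_1d(v.df)),
                                      p=v.p) for k, v in res.items()}
    fu = df[df.session == "followup"].set_index("subject_id")["mmn"]
    b2 = df[df.session == "baseline"].set_index("subject_id")["mmn"]
    common = [s for s in fu.index if s in b2.index]
    if len(common) >= 2:
        r = paired_t((fu[common] - b2[common]).to_numpy(), tail="greater")
        report["longitudinal_t"] = dict(t=r.statistic, df=r.df, p=r.p)
    rt = df[df.session == "retest"].set_index("subject_id")["mmn"]
    common = [s for s in rt.index if s in b2.index]
    if len(common) >= 3:
        report["icc_test_retest"] = icc_absolute(b2[common], rt[common])
    report["mde_between_d"] = min_detectable_effect(
        max(len(ctrl), 2), max(len(pat), 2), tails=1)
    if out is not None:
        df.to_csv(out / "mmn_amplitudes.csv", index=False)
        (out / "sensor_stats.json").write_text(json.dumps(report, indent=1))
    return report


def invert_cohort(cohort, epochs, leadfield, priors=None, session="baseline",
                  options: VLOptions | None = None, jobs: int = 1,
                  network=None):
    """Invert every subject with data in ``session``; None for failures."""
    net = network or cohort.network
    priors = priors or default_priors(net)
    options = options or VLOptions()
    keys = [s.subject_id for s in cohort.subjects if session in s.sessions]

    def one(sid):
        ep = epochs[(sid, session)]
        means = np.stack([ep.condition_mean(l) for l in CONDITION_LABELS])
        try:
            return fit_vl(means, ep.times_ms, net, leadfield.gain_matrix,
                          priors, options)
        except InversionFailure as err:
            log.warning("inversion failed for %s: %s", sid, err)
            return None

    if jobs > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=jobs)(delayed(one)(s) for s in keys)
    else:
        results = [one(s) for s in keys]
    return dict(zip(keys, results))


def _longitudinal_stage(cfg, cohort, epochs, lf, priors, baseline_inv,
                        analyses, baseline_bmas, out):
    """Disease-progression PEB: patients' baseline + follow-up scans.

    Rows carry a subject-mean regressor, a session indicator (follow-up =
    1) and the standardized follow-up interval; BMA runs over the reduced
    space of the parameter pairs that differentiated the groups at
    baseline (all pairs when none did).
    """
    from .bmr_peb import hemispheric_pairs

    opts = VLOptions(max_iter=cfg.max_iter, n_modes=cfg.n_modes)
    fu_inv = invert_cohort(cohort, epochs, lf, priors, "followup", opts,
                           jobs=cfg.jobs)
    ok_fu = [s for s in fu_inv
             if fu_inv[s] is not None and baseline_inv.get(s) is not None]
    if len(ok_fu) < 2:
        log.warning("longitudinal PEB skipped: <2 usable follow-ups")
        return {"skipped": "fewer than 2 usable follow-up inversions"}

    posts, rows = [], []
    intervals = {s.subject_id: s.interval_years for s in cohort.subjects}
    for ses, results in (("baseline", baseline_inv), ("followup", fu_inv)):
        for sid in ok_fu:
            posts.append(results[sid].posterior)
            rows.append(dict(subject_id=sid, group="patient", session=ses,
                             interval_years=intervals[sid]))
    table = pd.DataFrame(rows)
    design = build_designs(table)["longitudinal"]

    summary = {}
    for name, fields in analyses.items():
        peb = fit_peb(posts, PEBDesign(design.X, design.regressor_names,
                                       design.row_ids, fields), priors)
        pairs = hemispheric_pairs(fields)
        flagged = [pr for pr in pairs
                   if baseline_bmas[name].pp.get(f"group:{pr[0]}", 0.0)
                   > 0.95]
        bma = bma_over_parameter_sets(
            peb, symmetry_pairs=flagged or pairs,
            regressors=("session", "interval"))
        t = bma.table()
        t.to_csv(out / f"peb_longitudinal_{name}.csv", index=False)
        summary[name] = {
            "n_followups": len(ok_fu),
            "reduced_space_pairs": [list(p) for p in (flagged or pairs)],
            "session_effects": {p: dict(effect=float(e), pp=float(pp))
                                for p, e, pp in zip(
                                    t[t.regressor == "session"].parameter,
                                    t[t.regressor == "session"].effect,
                                    t[t.regressor == "session"].pp)},
        }
    return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain and return the manifest (also written)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity, logging.INFO))
    manifest = {"config": json.loads(cfg.to_json()), "stages": {},
                "failures": []}

    log.info("simulate: %d controls, %d patients (seed %d)",
             cfg.n_controls, cfg.n_patients, cfg.seed)
    net, cohort, lf, epochs = simulate_stage(cfg, out)
    manifest["stages"]["simulate"] = {
        "dataset": mio.file_sha256(out / "dataset.h5"),
        "subjects": mio.file_sha256(out / "subjects.csv"),
    }

    log.info("sensor statistics")
    stats = sensor_report(cohort, epochs, lf, out)
    manifest["stages"]["sensor"] = {
        "report": mio.file_sha256(out / "sensor_stats.json")}

    priors = default_priors(net)
    opts = VLOptions(max_iter=cfg.max_iter, n_modes=cfg.n_modes)
    log.info("inverting %d subjects", len(cohort.subjects))
    inv = invert_cohort(cohort, epochs, lf, priors, "baseline", opts,
                        jobs=cfg.jobs)
    manifest["failures"] = [k for k, v in inv.items() if v is None]
    mio.write_inversions(out / "inversions.h5", inv)
    manifest["stages"]["invert"] = {
        "inversions": mio.file_sha256(out / "inversions.h5"),
        "mean_fit_correlation": float(np.mean(
            [v.fit_correlation for v in inv.values() if v is not None])),
    }

    if cfg.run_model_comparison and not cfg.demo:
        log.info("model comparison over the 12-model space")
        cmp_df = compare_model_space(
            [inv[k] for k in inv if inv[k] is not None], net,
            enumerate_model_space(), priors)
        cmp_df.to_csv(out / "model_comparison.csv", index=False)
        manifest["stages"]["compare"] = {
            "winner": cmp_df.loc[cmp_df.delta_F.idxmax(), "model_id"]}

    if cfg.run_peb:
        if not any(s.group == "patient" for s in cohort.subjects) or \
                not any(s.group == "control" for s in cohort.subjects):
            raise ValueError("PEB group design needs both groups")
        table = mio.subject_table(cohort)
        ok = [k for k, v in inv.items() if v is not None]
        base = table[(table.session == "baseline")
                     & table.subject_id.isin(ok)]
        X = np.column_stack([np.ones(len(base)),
                             (base.group == "patient").astype(float)])
        design = PEBDesign(X, ("mean", "group"), tuple(base.subject_id))
        posts = [inv[s].posterior for s in base.subject_id]
        lay = net.layout
        analyses = {
            "sp_gain_modulation": tuple(f"B_sp[{r}]"
                                        for r in lay.region_names),
            "extrinsic_connectivity": tuple(
                l for l in priors.free_labels
                if l.startswith(("B_fwd", "B_bwd"))),
        }
        peb_out = {}
        baseline_bmas = {}
        for name, fields in analyses.items():
            peb = fit_peb(posts, design, priors, fields)
            bma = bma_over_parameter_sets(peb)
            baseline_bmas[name] = bma
            t = bma.table()
            t.to_csv(out / f"peb_{name}.csv", index=False)
            from .plotting import plot_bma_effects
            plot_bma_effects(bma, "group", out / f"peb_{name}.svg")
            peb_out[name] = {
                "free_energy": peb.free_energy,
                "group_effects": {p: dict(effect=float(e), pp=float(pp))
                                  for p, e, pp in zip(
                                      t[t.regressor == "group"].parameter,
                                      t[t.regressor == "group"].effect,
                                      t[t.regressor == "group"].pp)},
            }

        if cfg.run_longitudinal:
            peb_out["longitudinal"] = _longitudinal_stage(
                cfg, cohort, epochs, lf, priors, inv, analyses,
                baseline_bmas, out)

        (out / "peb_summary.json").write_text(json.dumps(peb_out, indent=1))
        manifest["stages"]["peb"] = {
            "summary": mio.file_sha256(out / "peb_summary.json")}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
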