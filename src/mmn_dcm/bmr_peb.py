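"""Bayesian model reduction, parametric empirical Bayes, and model averaging.

Bayesian model reduction (BMR) scores a model whose prior differs from the
fitted ("full") model's analytically, from the full posterior alone — no
refitting.  With Gaussian prior/posterior pairs (m0, S0) -> (mq, Sq) and a
reduced prior (m0r, S0r), the reduced posterior precision is

    Pqr = Pq + P0r - P0,
    mqr = Pqr^{-1} (Pq mq - P0 m0 + P0r m0r),

and the log-evidence change is a ratio of Gaussian normalizers.  Parameters
are "switched off" by shrinking their prior variance to (numerically) zero.

Parametric empirical Bayes (PEB) places a second-level linear model over
subjects' first-level posteriors: the selected parameters of subject ``i``
receive the prior ``N(X[i] @ beta, Sigma_between)``, and because the
per-subject evidence adjustment is an analytic quadratic in the prior mean,
the posterior over the group effects ``beta`` and the second-level free
energy are closed-form for a given between-subject variance; the
between-subject log-precision is optimized by scalar search.  Model
comparison over group effects (e.g. all hemispherically symmetric on/off
combinations) then reuses BMR on the Gaussian ``beta`` posterior, and
Bayesian model averaging (BMA) mixes the reduced posteriors by their
posterior model probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .parameters import GaussianDensity, PriorDensity
from .model_space import NetworkModel, default_priors

__all__ = [
    "PEBDesign",
    "PEBResult",
    "BMAResult",
    "bayesian_model_reduction",
    "reduced_prior_for_model",
    "compare_model_space",
    "build_designs",
    "fit_peb",
    "bma_over_parameter_sets",
    "hemispheric_pairs",
]

#: Prior variance used to switch a parameter "off" in a reduced model.
OFF_VARIANCE = 1e-8
#: Default prior variance of second-level effects.
PEB_EFFECT_VARIANCE = 1.0 / 16


def _logdet(M):
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-positive-definite matrix in BMR")
    return ld


def bayesian_model_reduction(full_posterior: GaussianDensity,
                             full_prior: GaussianDensity,
                             reduced_prior: GaussianDensity):
    """Evidence change and posterior under a reduced prior (no refit).

    All three densities must share the same labels.  Returns
    ``(delta_F, reduced_posterior)`` where ``delta_F`` is the log-evidence
    of the reduced model minus that of the full model.
    """
    if full_posterior.labels != full_prior.labels or \
            full_posterior.labels != reduced_prior.labels:
        raise ValueError("densities must share labels")
    mq, Sq = full_posterior.mean, full_posterior.cov
    m0, S0 = full_prior.mean, full_prior.cov
    mr, Sr = reduced_prior.mean, reduced_prior.cov

    Pq = np.linalg.inv(Sq)
    P0 = np.linalg.inv(S0)
    P0r = np.linalg.inv(Sr)
    Pqr = Pq + P0r - P0
    try:
        Sqr = np.linalg.inv(Pqr)
        ld_qr = -_logdet(Sqr)
    except np.linalg.LinAlgError as err:
        bad = [l for l, d in zip(full_posterior.labels, np.diag(Pqr)) if d <= 0]
        raise np.linalg.LinAlgError(
            f"reduced posterior precision not PSD (parameters: {bad[:5]})"
        ) from err
    mqr = Sqr @ (Pq @ mq - P0 @ m0 + P0r @ mr)

    dF = 0.5 * (_logdet(P0r) - _logdet(P0) + _logdet(Pq) - ld_qr) \
        - 0.5 * (mr @ P0r @ mr - m0 @ P0 @ m0 + mq @ Pq @ mq
                 - mqr @ Pqr @ mqr)
    return float(dF), GaussianDensity(mqr, 0.5 * (Sqr + Sqr.T),
                                      full_posterior.labels)


def reduced_prior_for_model(superset_prior: PriorDensity,
                            model_prior: PriorDensity) -> PriorDensity:
    """Superset prior with parameters absent from ``model_prior`` switched off."""
    if superset_prior.labels != model_prior.labels:
        raise ValueError("priors must share the full layout")
    out = superset_prior.copy()
    off = superset_prior.free_mask & ~model_prior.free_mask
    out.variance[off] = OFF_VARIANCE
    return out


def compare_model_space(subject_results, full_network: NetworkModel,
                        model_space, superset_prior: PriorDensity | None = None):
    """Fixed-effects comparison of candidate models via per-subject BMR.

    Parameters
    ----------
    subject_results : list of VLResult (or GaussianDensity posteriors), all
        inverted under the full (superset) model; entries that are None are
        skipped with a warning (e.g. inversion failures).
    model_space : list of NetworkModel candidates.

    Returns a DataFrame with per-model summed delta-F and posterior model
    probabilities (softmax over the summed free energies).
    """
    import warnings
    superset_prior = superset_prior or default_priors(full_network)
    prior_free = superset_prior.free_density()

    posteriors = []
    for i, r in enumerate(subject_results):
        if r is None:
            warnings.warn(f"subject {i} missing (inversion failure); skipped")
            continue
        posteriors.append(r if isinstance(r, GaussianDensity) else r.posterior)

    rows = []
    for model in model_space:
        mp = default_priors(model)
        rp_full = reduced_prior_for_model(superset_prior, mp)
        rp = GaussianDensity(rp_full.mean[superset_prior.free_mask],
                             np.diag(rp_full.variance[superset_prior.free_mask]),
                             prior_free.labels)
        dF = sum(bayesian_model_reduction(post, prior_free, rp)[0]
                 for post in posteriors)
        rows.append((model.model_id, dF))
    df = pd.DataFrame(rows, columns=["model_id", "delta_F"])
    z = df["delta_F"] - df["delta_F"].max()
    w = np.exp(z)
    df["posterior_prob"] = w / w.sum()
    return df


# ----------------------------------------------------------------------
# PEB


@dataclass
class PEBDesign:
    """Second-level design: subjects/scans x regressors."""

    X: np.ndarray
    regressor_names: tuple[str, ...]
    row_ids: tuple[str, ...]
    field_selection: tuple[str, ...] = ()

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, float))
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first regressor must be the unitary column")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")


@dataclass
class PEBResult:
    design: PEBDesign
    beta_posterior: GaussianDensity     # labels "<regressor>:<param>"
    free_energy: float
    between_log_precision: float
    field_labels: tuple[str, ...]
    beta_prior: GaussianDensity = None

    def effects(self, regressor: str) -> dict:
        """Posterior mean effect per parameter for one regressor."""
        out = {}
        for i, l in enumerate(self.beta_posterior.labels):
            r, p = l.split(":", 1)
            if r == regressor:
                out[p] = self.beta_posterior.mean[i]
        return out


def build_designs(subject_table: pd.DataFrame) -> dict:
    """The study's second-level designs from a cohort table.

    ``subject_table`` needs columns ``subject_id``, ``group``, ``session``
    (one row per scan) and, for longitudinal designs, ``interval_years``;
    an optional ``age`` column enables the age-covariate variant.

    Returns designs keyed ``baseline_group``, ``baseline_group_age`` (when
    age is available) and ``longitudinal`` (patients' baseline + follow-up
    scans with a session indicator and a standardized-interval regressor).
    """
    t = subject_table
    designs = {}

    base = t[t["session"] == "baseline"]
    has_both_groups = (base["group"] == "patient").any() \
        and (base["group"] == "control").any()
    if len(base) and has_both_groups:
        X = np.column_stack([np.ones(len(base)),
                             (base["group"] == "patient").astype(float)])
        designs["baseline_group"] = PEBDesign(
            X, ("mean", "group"), tuple(base["subject_id"]))
        if "age" in t.columns and base["age"].notna().all():
            Xa = np.column_stack([X, base["age"].to_numpy(float)])
            designs["baseline_group_age"] = PEBDesign(
                Xa, ("mean", "group", "age"), tuple(base["subject_id"]))

    pat = t[(t["group"] == "patient")
            & t["session"].isin(["baseline", "followup"])]
    fu_subjects = set(pat[pat["session"] == "followup"]["subject_id"])
    pat = pat[pat["subject_id"].isin(fu_subjects)]
    if len(pat):
        if pat[pat["session"] == "followup"]["interval_years"].isna().any():
            raise ValueError("missing follow-up interval for a scan row")
        session = (pat["session"] == "followup").astype(float).to_numpy()
        interval = np.zeros(len(pat))
        fu = session == 1
        iv = pat[pat["session"] == "followup"]["interval_years"].to_numpy(float)
        if len(iv) > 1 and np.std(iv, ddof=1) > 0:
            iv_std = (iv - iv.mean()) / iv.std(ddof=1)
        else:
            iv_std = np.zeros(len(iv))
        interval[fu] = iv_std
        X = np.column_stack([np.ones(len(pat)), session, interval])
        rows = tuple(f"{s}:{ses}" for s, ses in
                     zip(pat["subject_id"], pat["session"]))
        designs["longitudinal"] = PEBDesign(
            X, ("mean", "session", "interval"), rows)
    return designs


def _subject_quadratic(post: GaussianDensity, prior_mean, prior_var,
                       sel_idx, Bsel, sigma2_sel):
    """Per-subject BMR evidence as an exact quadratic in beta.

    The reduced prior replaces the selected parameters' prior with mean
    ``Bsel @ beta`` and variance ``sigma2_sel``.  Returns (const, g, H) with
    dF_i(beta) = const + g @ beta - 0.5 * beta @ H @ beta.
    """
    p = len(prior_mean)
    P0d = 1.0 / prior_var
    P0rd = P0d.copy()
    P0rd[sel_idx] = 1.0 / sigma2_sel
    Pq = np.linalg.inv(post.cov)
    Pqr = Pq + np.diag(P0rd - P0d)
    Sqr = np.linalg.inv(Pqr)

    mq = post.mean
    a = prior_mean.copy()
    a[sel_idx] = 0.0                      # prior mean of selected fields = X beta
    Bfull = np.zeros((p, Bsel.shape[1]))
    Bfull[sel_idx] = Bsel

    c0 = Pq @ mq - P0d * prior_mean + P0rd * a
    PB = P0rd[:, None] * Bfull

    ld_P0r = np.sum(np.log(P0rd))
    ld_P0 = np.sum(np.log(P0d))
    ld_Pq = -_logdet(post.cov)
    ld_Pqr = _logdet(Pqr)
    const = 0.5 * (ld_P0r - ld_P0 + ld_Pq - ld_Pqr) \
        - 0.5 * (a @ (P0rd * a) - prior_mean @ (P0d * prior_mean)
                 + mq @ Pq @ mq - c0 @ Sqr @ c0)
    # dF_i(beta): -(1/2)(a + B b)' P0r (a + B b) + (1/2) c(b)' Sqr c(b)
    # with c(b) = c0 + P0r B b, collected into linear and quadratic terms
    g = -PB.T @ a + PB.T @ (Sqr @ c0)
    H = Bfull.T @ PB - PB.T @ Sqr @ PB
    H = 0.5 * (H + H.T)
    return const, g, H


def fit_peb(first_level: list, design: PEBDesign, priors: PriorDensity,
            field_selection=None,
            effect_variance: float = PEB_EFFECT_VARIANCE,
            gamma_bounds: tuple = (-4.0, 8.0)) -> PEBResult:
    """Hierarchical (parametric empirical Bayes) model over subjects.

    Parameters
    ----------
    first_level : list of GaussianDensity (or VLResult), one per design row,
        posteriors over the free parameters of the shared first-level model.
    design : PEBDesign
    priors : the first-level PriorDensity (full layout).
    field_selection : parameter labels entering the second level (default:
        the design's ``field_selection``).

    The between-subject variance of the selected parameters is
    ``prior_variance / 16 * exp(-gamma)`` with ``gamma`` optimized by scalar
    search on the second-level free energy.
    """
    posts = [r if isinstance(r, GaussianDensity) else r.posterior
             for r in first_level]
    n = len(posts)
    if n < 1:
        raise ValueError("need at least one first-level posterior")
    if design.X.shape[0] != n:
        raise ValueError(f"design has {design.X.shape[0]} rows for {n} subjects")
    fields = tuple(field_selection or design.field_selection)
    if not fields:
        raise ValueError("empty field selection")

    free_labels = posts[0].labels
    for q in posts[1:]:
        if q.labels != free_labels:
            raise ValueError("first-level posteriors must share labels")
    sel_idx = np.array([free_labels.index(f) for f in fields])
    k = len(sel_idx)
    nreg = design.X.shape[1]

    m0 = priors.mean[priors.free_mask]
    v0 = priors.variance[priors.free_mask]
    base_var = v0[sel_idx]

    beta_labels = tuple(f"{r}:{f}" for r in design.regressor_names
                        for f in fields)
    prior_beta_var = np.full(nreg * k, effect_variance)
    Pb0 = 1.0 / prior_beta_var

    def assemble(gamma):
        # raises LinAlgError when this gamma makes a reduced precision
        # indefinite; the scalar search treats that as F = -inf
        sigma2 = base_var / 16.0 * np.exp(-gamma)
        const = 0.0
        g = np.zeros(nreg * k)
        H = np.zeros((nreg * k, nreg * k))
        for i, post in enumerate(posts):
            # prior mean of the selected block is sum_r X[i, r] * beta_r
            Bsel = np.kron(design.X[i][None, :], np.eye(k)).reshape(k, nreg * k)
            c, gi, Hi = _subject_quadratic(post, m0, v0, sel_idx, Bsel,
                                           sigma2)
            const += c
            g += gi
            H += Hi
        Pb = H + np.diag(Pb0)
        Sb = np.linalg.inv(Pb)
        mb = Sb @ g
        # F(gamma) = sum_i const_i + (1/2) g' Sb g + (1/2) ln|Sb| + (1/2) ln|Pb0|
        F = const + 0.5 * g @ mb + 0.5 * _logdet(Sb) \
            + 0.5 * np.sum(np.log(Pb0))
        return F, mb, Sb

    def neg_F(gmm):
        try:
            return -assemble(gmm)[0]
        except np.linalg.LinAlgError:
            return np.inf

    res = minimize_scalar(neg_F, bounds=gamma_bounds, method="bounded",
                          options={"xatol": 1e-2})
    gamma = float(res.x)
    if not np.isfinite(neg_F(gamma)):
        raise np.linalg.LinAlgError(
            "PEB between-subject precision search found no valid gamma")
    F, mb, Sb = assemble(gamma)

    post_beta = GaussianDensity(mb, 0.5 * (Sb + Sb.T), beta_labels)
    prior_beta = GaussianDensity(np.zeros(nreg * k), np.diag(prior_beta_var),
                                 beta_labels)
    return PEBResult(design, post_beta, float(F), gamma, fields,
                     beta_prior=prior_beta)


# ----------------------------------------------------------------------
# BMA over parameter combinations


@dataclass
class BMAResult:
    posterior: GaussianDensity          # moment-matched BMA over beta
    pp: dict                            # parameter label -> posterior prob of inclusion
    model_free_energies: np.ndarray
    model_masks: list
    regressors: tuple[str, ...]

    def table(self) -> pd.DataFrame:
        rows = []
        for i, l in enumerate(self.posterior.labels):
            reg, par = l.split(":", 1)
            rows.append((reg, par, self.posterior.mean[i],
                         np.sqrt(self.posterior.cov[i, i]),
                         self.pp.get(l, 1.0)))
        return pd.DataFrame(rows, columns=["regressor", "parameter",
                                           "effect", "sd", "pp"])


def hemispheric_pairs(labels) -> list[tuple[str, str]]:
    """Pair parameter labels with their other-hemisphere homologues.

    Homologues are found by swapping the 'l'/'r' suffix of every region
    token inside the label.  Raises if any label has no partner.
    """
    def mirror(label):
        out = label
        for pre in ("A1", "STG", "IFG", "IPC"):
            out = out.replace(f"{pre}l", f"\x00{pre}\x00") \
                     .replace(f"{pre}r", f"{pre}l") \
                     .replace(f"\x00{pre}\x00", f"{pre}r")
        return out

    labels = list(labels)
    seen, pairs = set(), []
    for l in labels:
        if l in seen:
            continue
        m = mirror(l)
        if m == l:
            pairs.append((l, l))
            seen.add(l)
            continue
        if m not in labels:
            raise ValueError(f"no hemispheric homologue for {l!r}")
        pairs.append((l, m))
        seen.update((l, m))
    return pairs


def bma_over_parameter_sets(peb: PEBResult,
                            symmetry_pairs=None,
                            regressors=None,
                            max_exhaustive: int = 16) -> BMAResult:
    """Bayesian model averaging over symmetric on/off parameter combinations.

    Every left/right pair of selected parameters is switched on or off
    jointly on the chosen regressors (default: all but the unitary mean
    regressor), giving ``2^n_pairs`` reduced second-level models scored by
    BMR on the ``beta`` posterior.  Posteriors are averaged with their model
    probabilities; a parameter's ``Pp`` is the summed probability of the
    models that include it.  Above ``max_exhaustive`` pairs a greedy pruning
    discards the least probable single-pair exclusions first.
    """
    labels = list(peb.beta_posterior.labels)
    regs = tuple(regressors if regressors is not None
                 else peb.design.regressor_names[1:])
    if not regs:
        raise ValueError("no regressors to average over")
    pairs = symmetry_pairs or hemispheric_pairs(peb.field_labels)
    for l, r in pairs:
        for f in (l, r):
            if f not in peb.field_labels:
                raise ValueError(f"unpaired/unknown parameter {f!r}")

    prior = peb.beta_prior
    post = peb.beta_posterior

    def model_prior(mask):
        var = np.diag(prior.cov).copy()
        for onoff, (l, r) in zip(mask, pairs):
            if onoff:
                continue
            for reg in regs:
                for f in {l, r}:
                    var[labels.index(f"{reg}:{f}")] = OFF_VARIANCE
        return GaussianDensity(prior.mean, np.diag(var), prior.labels)

    n = len(pairs)
    if n <= max_exhaustive:
        masks = list(product([1, 0], repeat=n))
    else:
        # greedy: start from all-on, repeatedly toggle the pair whose
        # exclusion costs least evidence, keeping the visited set
        masks = [tuple([1] * n)]
        cur = np.ones(n, int)
        for _ in range(n):
            cand = []
            for j in range(n):
                if cur[j]:
                    m = cur.copy(); m[j] = 0
                    dF, _ = bayesian_model_reduction(post, prior,
                                                     model_prior(m))
                    cand.append((dF, j, tuple(m)))
            if not cand:
                break
            dF, j, m = max(cand)
            masks.append(m)
            cur[j] = 0

    dFs, reduced = [], []
    for m in masks:
        dF, rq = bayesian_model_reduction(post, prior, model_prior(m))
        dFs.append(dF)
        reduced.append(rq)
    dFs = np.asarray(dFs)
    w = np.exp(dFs - dFs.max())
    w /= w.sum()

    mean = sum(wi * r.mean for wi, r in zip(w, reduced))
    second = sum(wi * (r.cov + np.outer(r.mean, r.mean))
                 for wi, r in zip(w, reduced))
    cov = second - np.outer(mean, mean)
    bma_post = GaussianDensity(mean, 0.5 * (cov + cov.T), post.labels)

    pp = {}
    for j, (l, r) in enumerate(pairs):
        pj = float(sum(wi for wi, m in zip(w, masks) if m[j]))
        for reg in regs:
            for f in {l, r}:
                pp[f"{reg}:{f}"] = pj
    return BMAResult(bma_post, pp, dFs, masks, regs)
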