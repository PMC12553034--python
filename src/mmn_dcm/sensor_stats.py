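"""Sensor-space statistics for the roving mismatch-negativity paradigm.

Implements the sensor-level analysis arm: robust (bisquare-weighted)
averaging of epochs per condition, combination of planar gradiometers by
root-mean-square and their mean across pairs ("global field power"), the
mismatch-negativity amplitude as the 140-160 ms mean of the
repetition-1-minus-deviant difference, the group/session t tests,
repeated-measures ANOVA with Greenhouse-Geisser correction, test-retest
intraclass correlation (absolute agreement, single measure, ICC(A,1)) and
minimum-detectable-effect power computations under the noncentral t.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import signal, stats

from .synthetic import SensorEpochs, CONDITION_LABELS

__all__ = [
    "MMN_WINDOW_MS",
    "EvokedSet",
    "StatResult",
    "robust_average",
    "gradiometer_rms_gfp",
    "mmn_amplitude",
    "welch_t",
    "paired_t",
    "rm_anova_gg",
    "icc_absolute",
    "min_detectable_effect",
]

#: A priori mismatch window (ms), endpoints inclusive.
MMN_WINDOW_MS = (140.0, 160.0)
#: Bisquare tuning constant (95% Gaussian efficiency).
BISQUARE_C = 4.685
#: Low-pass corner applied after robust averaging (Hz).
POST_AVERAGE_LOWPASS_HZ = 40.0


@dataclass
class EvokedSet:
    """Per-condition means with the robust weights that produced them."""

    means: np.ndarray          # (conditions, sensors, samples)
    weights: dict              # label -> (epochs, sensors, samples) weights
    condition_labels: tuple
    sfreq_hz: float
    window_ms: tuple

    @property
    def times_ms(self) -> np.ndarray:
        return self.window_ms[0] + np.arange(self.means.shape[2]) \
            * 1000.0 / self.sfreq_hz

    def mean(self, label: str) -> np.ndarray:
        return self.means[self.condition_labels.index(label)]


@dataclass
class StatResult:
    statistic: float
    df: float | tuple
    p: float
    ci: tuple
    tail: str
    name: str = ""
    extra: dict | None = None


def _bisquare_mean(x: np.ndarray, max_iter: int = 8, tol: float = 1e-6):
    """Iteratively reweighted mean over axis 0 with bisquare weights.

    Residuals are standardized per (sensor, sample) by the
    median-absolute-deviation scale; observations beyond the tuning constant
    get zero weight.  Degenerate (zero-scale) cells keep unit weights.
    """
    x = np.asarray(x, float)
    w = np.ones_like(x)
    mu = x.mean(axis=0)
    for _ in range(max_iter):
        r = x - mu
        scale = np.median(np.abs(r - np.median(r, axis=0)), axis=0) * 1.4826
        scale = np.where(scale <= 0, np.inf, scale)
        u = r / (BISQUARE_C * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        w = np.where(np.isinf(scale) & np.isnan(w), 1.0, w)
        wsum = w.sum(axis=0)
        wsum = np.where(wsum <= 0, 1.0, wsum)
        mu_new = (w * x).sum(axis=0) / wsum
        if np.max(np.abs(mu_new - mu)) < tol * max(1.0, np.max(np.abs(mu))):
            mu = mu_new
            break
        mu = mu_new
    return mu, w


def robust_average(epochs: SensorEpochs, conditions=None,
                   lowpass_hz: float | None = POST_AVERAGE_LOWPASS_HZ,
                   max_iter: int = 8) -> EvokedSet:
    """Robust per-condition averaging with a final zero-phase low-pass.

    Conditions are weighted separately and independently.  The concluding
    low-pass (4th-order Butterworth, ``filtfilt``) removes high frequencies
    that sample-wise reweighting can introduce.
    """
    labels = tuple(conditions or CONDITION_LABELS)
    means, weights = [], {}
    for lab in labels:
        mask = np.array([l == lab for l in epochs.condition_label])
        if mask.sum() < 2:
            raise ValueError(f"condition {lab!r} has fewer than 2 epochs")
        mu, w = _bisquare_mean(epochs.data[mask], max_iter=max_iter)
        if lowpass_hz:
            b, a = signal.butter(4, lowpass_hz / (epochs.sfreq_hz / 2.0))
            mu = signal.filtfilt(b, a, mu, axis=-1)
        means.append(mu)
        weights[lab] = w
    return EvokedSet(np.stack(means), weights, labels,
                     epochs.sfreq_hz, epochs.window_ms)


def gradiometer_rms_gfp(evoked, pairs) -> np.ndarray:
    """Mean across planar pairs of the pairwise RMS signal.

    For each pair (a, b): ``sqrt((a^2 + b^2)/2)`` per sample, then the mean
    over pairs — the "global field power" style summary.  Accepts an
    :class:`EvokedSet` (returns conditions x samples) or a plain
    (sensors x samples) array (returns samples).
    """
    x = evoked.means if isinstance(evoked, EvokedSet) else np.asarray(evoked, float)
    single = x.ndim == 2
    if single:
        x = x[None]
    S = x.shape[1]
    flat = [s for p in pairs for s in p]
    if sorted(flat) != list(range(S)):
        raise ValueError("pairs must partition the sensor set")
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    rms = np.sqrt((x[:, a, :] ** 2 + x[:, b, :] ** 2) / 2.0)
    out = rms.mean(axis=1)
    return out[0] if single else out


def _window_mask(times_ms, window=MMN_WINDOW_MS):
    t = np.asarray(times_ms, float)
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError("analysis window lies outside the epoch")
    return (t >= lo - 1e-9) & (t <= hi + 1e-9)


def mmn_amplitude(evoked: EvokedSet, pairs, window=MMN_WINDOW_MS) -> float:
    """Mismatch amplitude: mean over the window of GFP(rep1) - GFP(deviant).

    Negative values indicate an attenuated repetition response relative to
    the deviant.
    """
    gfp = gradiometer_rms_gfp(evoked, pairs)
    i_dev = evoked.condition_labels.index("deviant")
    i_rep = evoked.condition_labels.index("rep1")
    m = _window_mask(evoked.times_ms, window)
    return float(np.mean(gfp[i_rep, m] - gfp[i_dev, m]))


def _t_ci(est, se, df, alpha, tail):
    if tail == "two":
        q = stats.t.ppf(1 - alpha / 2, df)
        return est - q * se, est + q * se
    q = stats.t.ppf(1 - alpha, df)
    if tail == "less":
        return -np.inf, est + q * se
    return est - q * se, np.inf


def welch_t(mean1, sd1, n1, mean2, sd2, n2, tail="two",
            alpha=0.05) -> StatResult:
    """Welch's unequal-variance t test from summary statistics.

    ``tail``: "two", "less" (group 1 < group 2) or "greater".  The CI is for
    ``mean1 - mean2`` at level ``1 - alpha`` (one-sided bounds for one-sided
    tests).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative sd")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    diff = mean1 - mean2
    if se == 0:
        t_stat, df = 0.0, n1 + n2 - 2.0
    else:
        t_stat = diff / se
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if tail == "two":
        p = 2 * stats.t.sf(abs(t_stat), df)
    elif tail == "less":
        p = stats.t.cdf(t_stat, df)
    else:
        p = stats.t.sf(t_stat, df)
    ci = _t_ci(diff, se, df, alpha, tail)
    return StatResult(float(t_stat), float(df), float(p), ci, tail, "welch_t")


def paired_t(differences, tail="two", alpha=0.05) -> StatResult:
    """One-sample / paired t test on a vector of differences."""
    d = np.asarray(differences, float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 differences")
    m = d.mean()
    sd = d.std(ddof=1)
    se = sd / np.sqrt(n)
    flagged = sd == 0 and m != 0
    if sd == 0:
        t_stat = 0.0 if m == 0 else np.inf * np.sign(m)
    else:
        t_stat = m / se
    df = n - 1.0
    if tail == "two":
        p = 2 * stats.t.sf(abs(t_stat), df) if np.isfinite(t_stat) else 0.0
    elif tail == "less":
        p = stats.t.cdf(t_stat, df) if np.isfinite(t_stat) else float(t_stat > 0)
    else:
        p = stats.t.sf(t_stat, df) if np.isfinite(t_stat) else float(t_stat < 0)
    ci = _t_ci(m, se, df, alpha, tail) if sd > 0 else (m, m)
    return StatResult(float(t_stat), df, float(p), ci, tail, "paired_t",
                      extra={"zero_variance": flagged} if flagged else None)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of conditions."""
    k = data.shape[1]
    S = np.cov(data.T, ddof=1)
    C = np.eye(k) - np.ones((k, k)) / k     # double-centering
    V = C @ S @ C
    num = np.trace(V) ** 2
    den = (k - 1) * np.sum(V * V)
    return float(np.clip(num / den if den > 0 else 1.0, 1.0 / (k - 1), 1.0))


def rm_anova_gg(data: np.ndarray, group=None, covariate=None) -> dict:
    """Repeated-measures ANOVA with Greenhouse-Geisser correction.

    Parameters
    ----------
    data : (subjects, conditions) array of the repeated measure.
    group : optional (subjects,) labels for a between-subject factor; adds
        the group main effect and group x condition interaction (mixed
        design).
    covariate : optional (subjects,) values regressed out of every condition
        column (centered) before the ANOVA — the repeated-measures ANCOVA
        approximation for a between-subject covariate.

    Returns a dict of :class:`StatResult` keyed "condition" and, with a
    group factor, "group" and "interaction".  Within-subject effects carry
    GG-corrected p values; ``extra`` holds epsilon and uncorrected dfs.
    """
    y = np.asarray(data, float)
    if y.ndim != 2:
        raise ValueError("data must be subjects x conditions")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")
    n, k = y.shape
    if covariate is not None:
        c = np.asarray(covariate, float)
        c = c - c.mean()
        beta = (c @ y) / (c @ c)
        y = y - np.outer(c, beta)

    eps = _gg_epsilon(y)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    out = {}

    if group is None:
        ss_cond = n * np.sum((cond_means - grand) ** 2)
        resid = y - subj_means[:, None] - cond_means[None, :] + grand
        ss_err = np.sum(resid**2)
        df1, df2 = k - 1.0, (k - 1.0) * (n - 1.0)
        F = (ss_cond / df1) / (ss_err / df2)
        p = stats.f.sf(F, df1 * eps, df2 * eps)
        out["condition"] = StatResult(float(F), (df1 * eps, df2 * eps),
                                      float(p), (np.nan, np.nan), "two",
                                      "rm_anova",
                                      extra={"epsilon": eps,
                                             "df_uncorrected": (df1, df2)})
        return out

    g = np.asarray(group)
    levels = np.unique(g)
    ns = np.array([(g == l).sum() for l in levels])
    if np.any(ns < 2):
        raise ValueError("each group needs at least 2 subjects")
    # between-subject stratum
    gm = np.array([subj_means[g == l].mean() for l in levels])
    ss_group = k * np.sum(ns * (gm - grand) ** 2)
    ss_subj = k * np.sum((subj_means - np.array(
        [gm[list(levels).index(x)] for x in g])) ** 2)
    dfg, dfs = len(levels) - 1.0, float(n - len(levels))
    Fg = (ss_group / dfg) / (ss_subj / dfs)
    out["group"] = StatResult(float(Fg), (dfg, dfs),
                              float(stats.f.sf(Fg, dfg, dfs)),
                              (np.nan, np.nan), "two", "group")
    # within stratum
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    cell = np.stack([y[g == l].mean(axis=0) for l in levels])  # (G, k)
    ss_inter = np.sum(ns[:, None] * (cell - gm[:, None] - cond_means[None, :]
                                     + grand) ** 2)
    resid = y.copy()
    for i, l in enumerate(levels):
        resid[g == l] -= cell[i][None, :]
    resid -= (subj_means - np.array(
        [gm[list(levels).index(x)] for x in g]))[:, None]
    ss_err = np.sum(resid**2)
    df1 = k - 1.0
    df2 = (k - 1.0) * (n - len(levels))
    Fc = (ss_cond / df1) / (ss_err / df2)
    Fi = (ss_inter / (df1 * dfg)) / (ss_err / df2)
    out["condition"] = StatResult(
        float(Fc), (df1 * eps, df2 * eps),
        float(stats.f.sf(Fc, df1 * eps, df2 * eps)), (np.nan, np.nan),
        "two", "rm_anova", extra={"epsilon": eps,
                                  "df_uncorrected": (df1, df2)})
    out["interaction"] = StatResult(
        float(Fi), (df1 * dfg * eps, df2 * eps),
        float(stats.f.sf(Fi, df1 * dfg * eps, df2 * eps)), (np.nan, np.nan),
        "two", "group_x_condition", extra={"epsilon": eps})
    return out


def icc_absolute(test, retest, form: str = "single") -> float:
    """Two-way absolute-agreement intraclass correlation, ICC(A,1).

    From the two-way mean squares with subjects as rows and the two sessions
    as columns:

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).

    ``form="average"`` returns the k-measurement variant ICC(A,k).
    """
    x = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    mse = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2) \
        / ((n - 1) * (k - 1))
    if form == "single":
        return float((msr - mse) / (msr + (k - 1) * mse
                                    + k * (msc - mse) / n))
    return float((msr - mse) / (msr + (msc - mse) / n))


def _power_two_sample(d, n1, n2, alpha, tails):
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if tails == 1:
        crit = stats.t.ppf(1 - alpha, df)
        return stats.nct.sf(crit, df, ncp)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)


def _power_paired(d, n, alpha, tails):
    df = n - 1
    ncp = d * np.sqrt(n)
    if tails == 1:
        crit = stats.t.ppf(1 - alpha, df)
        return stats.nct.sf(crit, df, ncp)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)


def min_detectable_effect(n1, n2=None, alpha=0.05, power=0.8,
                          tails=1, tol=1e-6) -> float:
    """Smallest Cohen's d reaching the target power (noncentral t).

    Two-sample when ``n2`` is given, else paired/one-sample with ``n1``
    pairs.  Solved by bisection to ``tol``.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    f = (lambda d: _power_two_sample(d, n1, n2, alpha, tails)) if n2 \
        else (lambda d: _power_paired(d, n1, alpha, tails))
    lo, hi = 0.0, 0.1
    while f(hi) < power:
        hi *= 2
        if hi > 100:
            raise ValueError("requested power unattainable")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
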