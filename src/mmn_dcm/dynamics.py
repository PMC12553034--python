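"""Canonical-microcircuit neural-mass dynamics and ERP integration.

Each cortical region holds four populations — spiny stellate (granular),
superficial pyramidal, inhibitory interneuron and deep pyramidal — with
second-order synaptic kinetics per population,

    v' = i
    i' = kappa * u - 2 kappa * i - kappa^2 * v,

where ``u`` is the presynaptic drive: signed intrinsic gains applied to the
firing rates of the within-region populations, extrinsic (between-region)
terms with a conduction delay, and exogenous input.  Firing rates follow a
centered logistic of the membrane potential.  The laminar rules are those of
the canonical microcircuit: forward connections originate in superficial
pyramidal cells and target spiny stellate and deep pyramidal populations;
backward connections originate in deep pyramidal cells and target
superficial pyramidal and inhibitory populations.  Auditory input drives the
spiny stellate cells of primary auditory cortex; expectancy input drives the
superficial pyramidal cells of the highest regions (configurable laminar
target).

Integration uses fixed-step classical Runge-Kutta (RK4) at 1 ms with the
conduction delay rounded to the integration grid; delayed firing rates at
the half-step stage are obtained by quadratic interpolation of the stored
rate history, preserving high-order accuracy for the delay terms.  All
heavy paths are batched over (parameter draw, condition) pairs so that
finite-difference sensitivities cost a single vectorized integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .parameters import (CMCParameters, ParameterLayout, POPULATIONS,
                         INTRINSIC_GAIN_LABELS, SP_GAIN_INDEX)
from .model_space import NetworkModel

__all__ = [
    "DynamicsConfig",
    "BasisSet",
    "IntegrationError",
    "sigmoid_rate",
    "repetition_basis",
    "apply_condition_modulation",
    "cmc_flow",
    "integrate_erp",
    "predict_sources",
    "N_CONDITIONS",
]

#: Conditions modeled: deviant plus the first five repetitions.
N_CONDITIONS = 6

_SS, _SP, _II, _DP = 0, 1, 2, 3


class IntegrationError(RuntimeError):
    """Raised when the neural-mass integration diverges."""


@dataclass
class DynamicsConfig:
    """Fixed biophysical constants and numerical settings of the CMC model.

    The intrinsic topology is fixed; the magnitudes below are a documented
    conventional default set.  All quantities that the inversion estimates
    enter multiplicatively on top of these defaults via the log-scale
    parameters.
    """

    #: population time constants in ms (ss, sp, ii, dp)
    T_ms: tuple = (2.0, 2.0, 16.0, 28.0)
    #: signed intrinsic gain magnitudes (s^-1), order INTRINSIC_GAIN_LABELS
    intrinsic_gains: tuple = (-800.0, -1600.0, -800.0, 800.0, -800.0,
                              800.0, 400.0, -800.0, -400.0, -200.0)
    #: extrinsic forward weights (to ss, to dp), s^-1
    fwd_weights: tuple = (800.0, 400.0)
    #: extrinsic backward weights (to sp, to ii); sp target is inhibitory
    bwd_weights: tuple = (-800.0, 400.0)
    #: exogenous input gain (s^-1) for unit bump amplitude
    input_gain: float = 2000.0
    #: Gaussian input bump: peak latency and width, ms
    input_peak_ms: float = 64.0
    input_sd_ms: float = 16.0
    #: extrinsic conduction delay, ms
    delay_ms: float = 16.0
    #: baseline sigmoid slope (mV^-1)
    sigmoid_slope: float = 2.0 / 3.0
    #: source output mixture over population voltages (ss, sp, ii, dp)
    source_mixture: tuple = (0.0, 0.9, 0.0, 0.1)
    #: integration step, ms
    dt_ms: float = 1.0
    #: state magnitude treated as divergence
    state_bound: float = 1e6
    #: repetition-basis time constants, in units of condition index
    tau_exp: float = 4.0
    tau_phasic: float = 2.0
    #: laminar target of expectancy input ("sp" per default, or "ss")
    expectancy_target: str = "sp"


@dataclass
class BasisSet:
    """Repetition basis over the six conditions (deviant, rep1..rep5)."""

    kind: str
    matrix: np.ndarray  # (n_conditions, n_basis)

    @property
    def exponential(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def phasic(self) -> np.ndarray:
        if self.matrix.shape[1] < 2:
            raise ValueError("exponential-only basis has no phasic column")
        return self.matrix[:, 1]


def sigmoid_rate(v, slope_scale=0.0, r0=2.0 / 3.0):
    """Centered logistic voltage-to-rate transform.

    ``S(v) = 1/(1 + exp(-r v)) - 1/2`` with ``r = r0 * exp(slope_scale)``;
    bounded in (-1/2, 1/2) with ``S(0) = 0`` and slope ``r/4`` at rest.
    """
    r = r0 * np.exp(slope_scale)
    return 1.0 / (1.0 + np.exp(-r * np.asarray(v, float))) - 0.5


def repetition_basis(kind: str, tau_exp: float = 4.0,
                     tau_phasic: float = 2.0) -> BasisSet:
    """Exponential-decay (and optionally phasic) repetition basis.

    Column 1 decays exponentially with repetition, ``exp(-k / tau_exp)`` for
    condition index ``k = 0..5`` (0 = deviant).  For the combined kind a
    second, phasic column is zero at the deviant, maximal (negative) at the
    first repetition and recovers thereafter:
    ``b_ph(k) = -exp(-(k - 1)/tau_phasic)`` for ``k >= 1``, normalized to
    unit maximum magnitude.
    """
    if tau_exp <= 0 or tau_phasic <= 0:
        raise ValueError("basis time constants must be positive")
    if kind not in ("E", "EG", "exponential", "exponential_plus_phasic"):
        raise ValueError(f"unknown basis kind {kind!r}")
    k = np.arange(N_CONDITIONS, dtype=float)
    b_exp = np.exp(-k / tau_exp)
    if kind in ("E", "exponential"):
        return BasisSet("exponential", b_exp[:, None])
    b_ph = np.where(k >= 1, -np.exp(-(k - 1) / tau_phasic), 0.0)
    b_ph = b_ph / np.max(np.abs(b_ph))
    return BasisSet("exponential_plus_phasic", np.column_stack([b_exp, b_ph]))


def apply_condition_modulation(params: CMCParameters, basis: BasisSet,
                               condition: int) -> CMCParameters:
    """Condition-specific parameters under the repetition basis.

    Extrinsic connections are scaled through the exponential column
    (``log A -> log A + B * b_exp(k)``).  The superficial-pyramidal *gain*
    (excitability) is modulated through the phasic column; since the
    corresponding microcircuit parameter is the self-inhibition (the
    reciprocal of the gain), its log-scale receives ``- B_sp * b_ph(k)``:
    a positive gain-modulation coefficient makes the gain dip after the
    deviant (phasic column is -1 at the first repetition) and recover over
    subsequent tones.
    """
    if not 0 <= condition < N_CONDITIONS:
        raise ValueError(f"condition must be in 0..{N_CONDITIONS - 1}")
    out = params.copy()
    be = basis.exponential[condition]
    out.log_A_fwd = params.log_A_fwd + params.B_fwd * be
    out.log_A_bwd = params.log_A_bwd + params.B_bwd * be
    if basis.matrix.shape[1] > 1:
        bp = basis.phasic[condition]
        out.log_G = params.log_G.copy()
        out.log_G[:, SP_GAIN_INDEX] = (params.log_G[:, SP_GAIN_INDEX]
                                       - params.B_sp * bp)
    return out


# ----------------------------------------------------------------------
# batched system assembly


def _assemble(theta: np.ndarray, conditions: np.ndarray,
              network: NetworkModel, config: DynamicsConfig,
              basis: BasisSet):
    """Build batched system matrices for (parameter draw, condition) pairs.

    Parameters are given as layout vectors ``theta`` (B, L) with matching
    ``conditions`` (B,).  Returns kappa (B, n), intrinsic matrix (B, n, n),
    delayed extrinsic matrix (B, n, n), input vector (B, n), per-system delay
    in integration steps (B,), sigmoid slopes (B,), and source gains (B, R).
    """
    lay = network.layout
    B = theta.shape[0]
    R = lay.n_regions
    n = 4 * R

    o = 0
    log_T = theta[:, o:o + 4 * R].reshape(B, R, 4); o += 4 * R
    log_G = theta[:, o:o + 10 * R].reshape(B, R, 10); o += 10 * R
    Ef, Eb = len(lay.fwd_edges), len(lay.bwd_edges)
    log_Af = theta[:, o:o + Ef]; o += Ef
    log_Ab = theta[:, o:o + Eb]; o += Eb
    B_f = theta[:, o:o + Ef]; o += Ef
    B_b = theta[:, o:o + Eb]; o += Eb
    B_sp = theta[:, o:o + R]; o += R
    C_aud = theta[:, o:o + len(lay.aud_regions)]; o += len(lay.aud_regions)
    C_exp = theta[:, o:o + len(lay.exp_regions)]; o += len(lay.exp_regions)
    log_D = theta[:, o]; o += 1
    log_S = theta[:, o]; o += 1
    log_L = theta[:, o:o + R]; o += R

    # condition modulation
    be = basis.exponential[conditions][:, None]             # (B, 1)
    log_Af = log_Af + B_f * be
    log_Ab = log_Ab + B_b * be
    log_G = log_G.copy()
    if basis.matrix.shape[1] > 1:
        # B_sp modulates the gain; the self-inhibition is its reciprocal
        bp = basis.phasic[conditions][:, None]
        log_G[:, :, SP_GAIN_INDEX] = log_G[:, :, SP_GAIN_INDEX] - B_sp * bp

    kappa0 = 1000.0 / np.asarray(config.T_ms)               # s^-1
    kappa = kappa0[None, None, :] * np.exp(log_T)           # (B, R, 4)
    kappa = kappa.reshape(B, n)

    # intrinsic coupling (block diagonal over regions)
    M_in = np.zeros((B, n, n))
    g0 = np.asarray(config.intrinsic_gains)
    for c, lab in enumerate(INTRINSIC_GAIN_LABELS):
        tgt, src = lab.split("<-")
        ti, si = POPULATIONS.index(tgt), POPULATIONS.index(src)
        w = g0[c] * np.exp(log_G[:, :, c])                  # (B, R)
        idx = np.arange(R)
        M_in[:, 4 * idx + ti, 4 * idx + si] += w

    # extrinsic (delayed) coupling
    M_ex = np.zeros((B, n, n))
    wf_ss, wf_dp = config.fwd_weights
    wb_sp, wb_ii = config.bwd_weights
    rnmask_f = np.array([network.fwd_mask[d, s] for (s, d) in lay.fwd_edges])
    rnmask_b = np.array([network.bwd_mask[d, s] for (s, d) in lay.bwd_edges])
    for e, (s, d) in enumerate(lay.fwd_edges):
        if not rnmask_f[e]:
            continue
        w = np.exp(log_Af[:, e])
        M_ex[:, 4 * d + _SS, 4 * s + _SP] += wf_ss * w
        M_ex[:, 4 * d + _DP, 4 * s + _SP] += wf_dp * w
    for e, (s, d) in enumerate(lay.bwd_edges):
        if not rnmask_b[e]:
            continue
        w = np.exp(log_Ab[:, e])
        M_ex[:, 4 * d + _SP, 4 * s + _DP] += wb_sp * w
        M_ex[:, 4 * d + _II, 4 * s + _DP] += wb_ii * w

    # exogenous input vector (shared Gaussian bump waveform)
    c_vec = np.zeros((B, n))
    for k, r in enumerate(lay.aud_regions):
        if r in network.auditory_input:
            c_vec[:, 4 * r + _SS] += config.input_gain * np.exp(C_aud[:, k])
    ptgt = POPULATIONS.index(config.expectancy_target)
    for k, r in enumerate(lay.exp_regions):
        if r in network.expectancy_input:
            c_vec[:, 4 * r + ptgt] += config.input_gain * np.exp(C_exp[:, k])

    # real-valued delay in integration steps (interpolated on the grid)
    delay_steps = config.delay_ms * np.exp(log_D) / config.dt_ms
    slopes = config.sigmoid_slope * np.exp(log_S)           # (B,)
    src_gain = np.exp(log_L)                                # (B, R)
    return kappa, M_in, M_ex, c_vec, delay_steps, slopes, src_gain


def cmc_flow(state: np.ndarray, params: CMCParameters, network: NetworkModel,
             exogenous_input: np.ndarray | float = 0.0,
             delayed_rates: np.ndarray | None = None,
             config: DynamicsConfig | None = None) -> np.ndarray:
    """State derivative of the CMC network at one instant.

    ``state`` is ``[v (4R), i (4R)]``; ``exogenous_input`` is the scalar
    input-waveform amplitude at this instant (applied through the network's
    input vectors); ``delayed_rates`` are the presynaptic firing rates seen
    by extrinsic connections (defaults to the instantaneous rates, i.e. zero
    delay).
    """
    config = config or DynamicsConfig()
    state = np.asarray(state, float)
    if not np.all(np.isfinite(state)):
        raise IntegrationError("non-finite state passed to cmc_flow")
    lay = network.layout
    n = 4 * lay.n_regions
    if state.shape != (2 * n,):
        raise ValueError(f"state must have shape ({2 * n},)")
    basis = repetition_basis("E", config.tau_exp, config.tau_phasic)
    # evaluate at the parameters as given: zero the modulation coefficients so
    # the basis does not rescale the extrinsic weights (b_exp(0) = 1)
    p0 = params.copy()
    p0.B_fwd = np.zeros_like(p0.B_fwd)
    p0.B_bwd = np.zeros_like(p0.B_bwd)
    p0.B_sp = np.zeros_like(p0.B_sp)
    kappa, M_in, M_ex, c_vec, _, slopes, _ = _assemble(
        lay.to_vector(p0)[None, :], np.zeros(1, int), network, config, basis)

    v, cur = state[:n], state[n:]
    s = sigmoid_rate(v, 0.0, slopes[0])
    s_del = s if delayed_rates is None else np.asarray(delayed_rates, float)
    u = M_in[0] @ s + M_ex[0] @ s_del + c_vec[0] * float(np.asarray(exogenous_input))
    k = kappa[0]
    return np.concatenate([cur, k * u - 2.0 * k * cur - k**2 * v])


def rest_jacobian(kappa, M_in, M_ex, slopes):
    """Analytic flow Jacobian at the resting point (delay folded to lag 0).

    The sigmoid slope at rest is ``r/4``.  Returns (B, 2n, 2n).
    """
    B, n, _ = M_in.shape
    m = 2 * n
    J = np.zeros((B, m, m))
    J[:, :n, n:] = np.eye(n)
    dSdv = (slopes / 4.0)[:, None, None]
    K = kappa[:, :, None] * ((M_in + M_ex) * dSdv)
    J[:, n:, :n] = K - kappa[:, :, None]**2 * np.eye(n)
    J[:, n:, n:] = -2.0 * kappa[:, :, None] * np.eye(n)
    return J


def _integrate_batch(kappa, M_in, M_ex, c_vec, delay_steps, slopes,
                     n_steps, dt_s, bump_fn, state_bound=1e6):
    """Integrate a batch of systems from rest with classical RK4.

    The conduction delay is a real number of steps (at least three); the
    delayed firing rates needed at each Runge-Kutta stage are obtained by
    quadratic interpolation of the stored rate history at the exact delayed
    time, so the discretized delay does not depend on the step size and the
    scheme retains third-order accuracy for the delayed terms.  ``bump_fn``
    evaluates the input waveform at an arbitrary time in seconds.  Systems
    whose state diverges are frozen at zero and flagged in the returned
    validity mask.
    """
    B, n, _ = M_in.shape
    v = np.zeros((B, n))
    cur = np.zeros((B, n))
    ok = np.ones(B, bool)
    delta = np.maximum(np.asarray(delay_steps, float), 3.0)
    s_hist = np.zeros((n_steps + 1, B, n))
    v_hist = np.zeros((n_steps, B, n))
    r = slopes[:, None]
    bidx = np.arange(B)

    # per-system interpolation stencils for stage offsets c in {0, 1/2, 1}:
    # delayed time t + c - delta = (t + base) + frac with frac in [0, 1)
    stencils = []
    for c in (0.0, 0.5, 1.0):
        tau = c - delta
        base = np.floor(tau).astype(int)
        a = tau - base
        w = np.stack([0.5 * a * (a - 1.0), 1.0 - a * a,
                      0.5 * a * (a + 1.0)], axis=1)  # nodes base-1, base, base+1
        stencils.append((base, w))

    def gather(idx):
        # history at integer step indices, zero (rest) before t = 0
        return np.where((idx >= 0)[:, None],
                        s_hist[np.clip(idx, 0, None), bidx, :], 0.0)

    def s_delayed(t, stage):
        base, w = stencils[stage]
        k = t + base
        return (w[:, 0:1] * gather(k - 1) + w[:, 1:2] * gather(k)
                + w[:, 2:3] * gather(k + 1))

    def fl(x, s_del, g):
        vv, ii = x[:, :n], x[:, n:]
        with np.errstate(over="ignore"):   # saturates harmlessly pre-guard
            ss = 1.0 / (1.0 + np.exp(-r * vv)) - 0.5
        uu = (np.einsum("bij,bj->bi", M_in, ss)
              + np.einsum("bij,bj->bi", M_ex, s_del) + c_vec * g)
        return np.concatenate(
            [ii, kappa * uu - 2.0 * kappa * ii - kappa**2 * vv], axis=1)

    for t in range(n_steps - 1):
        s0 = s_delayed(t, 0)
        smid = s_delayed(t, 1)
        s1 = s_delayed(t, 2)
        g0 = bump_fn(t * dt_s)
        gm = bump_fn((t + 0.5) * dt_s)
        g1 = bump_fn((t + 1) * dt_s)

        x = np.concatenate([v, cur], axis=1)
        k1 = fl(x, s0, g0)
        k2 = fl(x + 0.5 * dt_s * k1, smid, gm)
        k3 = fl(x + 0.5 * dt_s * k2, smid, gm)
        k4 = fl(x + dt_s * k3, s1, g1)
        x = x + dt_s / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

        bad = ~np.all(np.isfinite(x), axis=1) | (
            np.max(np.abs(x), axis=1) > state_bound)
        if np.any(bad & ok):
            ok &= ~bad
        x[~ok] = 0.0
        v, cur = x[:, :n], x[:, n:]
        with np.errstate(over="ignore"):
            s_hist[t + 1] = 1.0 / (1.0 + np.exp(-r * v)) - 0.5
        v_hist[t + 1] = v
    return v_hist, ok


def _source_from_v(v_hist, src_gain, config):
    """Mix population voltages into per-region source output (B, R, T)."""
    T, B, n = v_hist.shape
    R = n // 4
    w = np.asarray(config.source_mixture)
    vr = v_hist.reshape(T, B, R, 4)
    src = np.einsum("tbrp,p->brt", vr, w)
    return src * src_gain[:, :, None]


def predict_sources(theta_batch: np.ndarray, network: NetworkModel,
                    config: DynamicsConfig | None = None,
                    t_end_ms: float = 300.0,
                    conditions=None):
    """Source responses for a batch of parameter vectors.

    Parameters
    ----------
    theta_batch : (B, L) array
        Layout vectors.
    conditions : sequence of int, optional
        Conditions to simulate (default all six).

    Returns
    -------
    src : (B, n_cond, R, T) array
        Per-region source output on the integration grid (0..t_end, dt).
    ok : (B,) bool array
        False where the integration diverged (output zeroed).
    times_ms : (T,) array
    """
    config = config or DynamicsConfig()
    theta_batch = np.atleast_2d(np.asarray(theta_batch, float))
    B, L = theta_batch.shape
    conditions = np.arange(N_CONDITIONS) if conditions is None \
        else np.asarray(conditions, int)
    K = len(conditions)
    basis = repetition_basis(network.basis_kind, config.tau_exp,
                             config.tau_phasic)

    theta_full = np.repeat(theta_batch, K, axis=0)
    cond_full = np.tile(conditions, B)
    kappa, M_in, M_ex, c_vec, dsteps, slopes, src_gain = _assemble(
        theta_full, cond_full, network, config, basis)

    dt_s = config.dt_ms / 1000.0
    n_steps = int(round(t_end_ms / config.dt_ms)) + 1
    tgrid = np.arange(n_steps) * config.dt_ms
    mu_s, sd_s = config.input_peak_ms / 1000.0, config.input_sd_ms / 1000.0

    def bump_fn(t_s):
        return np.exp(-0.5 * ((t_s - mu_s) / sd_s) ** 2)

    v_hist, ok = _integrate_batch(kappa, M_in, M_ex, c_vec, dsteps, slopes,
                                  n_steps, dt_s, bump_fn,
                                  state_bound=config.state_bound)
    src = _source_from_v(v_hist, src_gain, config)
    R = network.layout.n_regions
    src = src.reshape(B, K, R, n_steps)
    ok = ok.reshape(B, K).all(axis=1)
    return src, ok, tgrid


def integrate_erp(params: CMCParameters, network: NetworkModel,
                  config: DynamicsConfig | None = None,
                  t_end_ms: float = 300.0,
                  dt_ms: float | None = None):
    """Per-condition source time series for one parameter set.

    Returns ``(src, times_ms)`` with ``src`` of shape
    (n_conditions, regions, samples).  Raises :class:`IntegrationError` if
    the state diverges.
    """
    config = config or DynamicsConfig()
    if dt_ms is not None:
        from dataclasses import replace
        config = replace(config, dt_ms=dt_ms)
    if config.dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    theta = network.layout.to_vector(params)
    src, ok, tgrid = predict_sources(theta[None, :], network, config,
                                     t_end_ms)
    if not ok[0]:
        raise IntegrationError(
            "neural-mass integration diverged; largest |log-scale| parameter "
            f"= {np.max(np.abs(theta)):.3f}")
    return src[0], tgrid
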