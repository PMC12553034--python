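"""Synthetic roving-paradigm cohorts: trial sequences, lead fields, epochs.

Emulates the study structure end to end so the whole modeling chain can be
exercised without any external recording: a roving oddball tone sequence
(blocks of 3-11 repeated tones, frequencies 400-800 Hz in 50 Hz steps, the
first tone of each block a deviant), a patient/control cohort whose
ground-truth microcircuit parameters carry configurable group and session
log-effects, smooth synthetic planar-gradiometer lead fields, and noisy
sensor epochs (-100..500 ms at 500 Hz) generated from the canonical
microcircuit forward model.

Randomness is reproducible: a single master seed is split into per-subject
and per-purpose streams with ``numpy.random.SeedSequence(master, spawn_key)``
counter-based derivation, so any subject can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .parameters import CMCParameters
from .model_space import NetworkModel, build_demo_network, default_priors
from .dynamics import DynamicsConfig, predict_sources, N_CONDITIONS

__all__ = [
    "TONE_FREQUENCIES_HZ",
    "BLOCK_LENGTH_RANGE",
    "EPOCH_WINDOW_MS",
    "EPOCH_SFREQ_HZ",
    "CONDITION_LABELS",
    "TrialSequence",
    "LeadField",
    "SensorEpochs",
    "SubjectRecord",
    "CohortSpec",
    "generate_roving_sequence",
    "make_leadfield",
    "make_cohort",
    "simulate_subject_evoked",
    "noise_sd_for_snr",
    "simulate_cohort_epochs",
]

#: Tone frequency grid of the roving paradigm (Hz).
TONE_FREQUENCIES_HZ = tuple(range(400, 801, 50))
#: Tones per block (inclusive bounds).
BLOCK_LENGTH_RANGE = (3, 11)
#: Epoch window (ms) and sampling rate (Hz).
EPOCH_WINDOW_MS = (-100.0, 500.0)
EPOCH_SFREQ_HZ = 500.0
#: Modeled condition labels (deviant = first tone of a block).
CONDITION_LABELS = ("deviant", "rep1", "rep2", "rep3", "rep4", "rep5")

#: Study-emulating cohort defaults: fractions of patients with a 2-week
#: retest and an annual follow-up session (14/45 and 32/45 in the study).
RETEST_FRACTION = 14.0 / 45.0
FOLLOWUP_FRACTION = 32.0 / 45.0
#: Follow-up interval range in years.
INTERVAL_RANGE_YEARS = (0.8, 2.2)
#: Default between-subject jitter (sd, log scale) and trials per condition.
DEFAULT_JITTER_SD = 0.1
DEFAULT_TRIALS_PER_CONDITION = 60


def n_epoch_samples() -> int:
    w0, w1 = EPOCH_WINDOW_MS
    return int(round((w1 - w0) / 1000.0 * EPOCH_SFREQ_HZ)) + 1


@dataclass
class TrialSequence:
    """Roving-paradigm trial structure."""

    block_index: np.ndarray      # (n_trials,) int
    tone_frequency_hz: np.ndarray
    repetition_index: np.ndarray  # 0 = deviant
    condition_label: list[str]   # deviant, rep1..rep5, surplus

    @property
    def n_trials(self) -> int:
        return len(self.block_index)


@dataclass
class LeadField:
    """Synthetic sensors x regions gain matrix with planar-gradiometer pairs.

    Columns are smooth random topographies with unit norm; ``sensor_pairs``
    partition the sensors into planar pairs.  This stands in for a
    subject-specific anatomical forward model; its geometry never enters the
    dynamics.
    """

    gain_matrix: np.ndarray
    sensor_pairs: list[tuple[int, int]]
    region_order: tuple[str, ...]

    @property
    def n_sensors(self) -> int:
        return self.gain_matrix.shape[0]


@dataclass
class SensorEpochs:
    """Single-trial sensor data: epochs x sensors x samples."""

    data: np.ndarray
    condition_label: list[str]
    sfreq_hz: float = EPOCH_SFREQ_HZ
    window_ms: tuple = EPOCH_WINDOW_MS

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.shape[0] != len(self.condition_label):
            raise ValueError("one condition label per epoch required")

    @property
    def times_ms(self) -> np.ndarray:
        return self.window_ms[0] + np.arange(self.data.shape[2]) \
            * 1000.0 / self.sfreq_hz

    def condition_mean(self, label: str) -> np.ndarray:
        mask = np.array([l == label for l in self.condition_label])
        if not mask.any():
            raise ValueError(f"no epochs with label {label!r}")
        return self.data[mask].mean(axis=0)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                      # "control" | "patient"
    sessions: tuple[str, ...]       # subset of (baseline, retest, followup)
    interval_years: float           # follow-up interval (0 if none)
    true_params: dict               # session -> CMCParameters
    seed: int                       # per-subject derived seed


@dataclass
class CohortSpec:
    subjects: list[SubjectRecord]
    network: NetworkModel
    master_seed: int

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]


def generate_roving_sequence(n_blocks: int, seed: int) -> TrialSequence:
    """Sample a roving tone sequence.

    Block lengths are uniform on 3..11; each block's frequency is drawn
    uniformly from the 9-step 400-800 Hz grid, excluding the previous
    block's frequency so every block change is audible.  The first tone of
    each block is the deviant (repetition index 0).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    freqs = np.asarray(TONE_FREQUENCIES_HZ, float)
    lo, hi = BLOCK_LENGTH_RANGE
    blocks, tones, reps, labels = [], [], [], []
    prev = None
    for b in range(n_blocks):
        length = int(rng.integers(lo, hi + 1))
        choices = freqs if prev is None else freqs[freqs != prev]
        f = float(rng.choice(choices))
        prev = f
        for k in range(length):
            blocks.append(b)
            tones.append(f)
            reps.append(k)
            if k == 0:
                labels.append("deviant")
            elif k <= 5:
                labels.append(f"rep{k}")
            else:
                labels.append("surplus")
    return TrialSequence(np.array(blocks), np.array(tones),
                         np.array(reps), labels)


def make_leadfield(n_sensors: int, network: NetworkModel,
                   seed: int) -> LeadField:
    """Smooth random sensor topographies, one unit-norm column per region.

    Sensors are laid out on a ring; each region's topography is a mixture of
    a few random Gaussian blobs over that layout, giving spatially smooth,
    generically independent columns.  Consecutive sensors (2i, 2i+1) form
    the planar-gradiometer pairs.
    """
    R = network.layout.n_regions
    if n_sensors < 2 * R:
        raise ValueError(f"need at least {2 * R} sensors for {R} regions")
    if n_sensors % 2:
        raise ValueError("n_sensors must be even (planar pairs)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pos = np.arange(n_sensors) / n_sensors  # ring coordinate in [0, 1)
    cols = np.zeros((n_sensors, R))
    for r in range(R):
        for _ in range(3):
            c = rng.uniform()
            w = rng.uniform(0.05, 0.2)
            a = rng.normal()
            d = np.minimum(np.abs(pos - c), 1.0 - np.abs(pos - c))
            cols[:, r] += a * np.exp(-0.5 * (d / w) ** 2)
    cols /= np.linalg.norm(cols, axis=0, keepdims=True)
    pairs = [(2 * i, 2 * i + 1) for i in range(n_sensors // 2)]
    return LeadField(cols, pairs, network.region_names)


def default_baseline_profile(network: NetworkModel) -> dict:
    """Cohort-mean parameters that generate a realistic mismatch response.

    Responses attenuate sharply at the first repetition and partially
    recover over subsequent tones.  This arises from (a) stimulus-specific
    adaptation of extrinsic forward connections — strongest for the deviant,
    decaying exponentially with repetition (positive coefficient on the
    exponential basis) — and (b) a phasic dip in superficial-pyramidal gain
    after the deviant (positive coefficient on the phasic basis).  Without
    such a profile every condition would evoke the same response and the
    paradigm would carry no mismatch signal.
    """
    lay = network.layout
    rn = lay.region_names
    prof = {f"B_sp[{r}]": 0.5 for r in rn}
    for (s, d) in lay.fwd_edges:
        if rn[s][:-1] != rn[d][:-1]:      # within-hemisphere hierarchy edges
            prof[f"B_fwd[{rn[s]}->{rn[d]}]"] = 0.5
    return prof


def _split_effect(value):
    if isinstance(value, dict):
        unknown = set(value) - {"group", "session", "interval"}
        if unknown:
            raise KeyError(f"unknown effect keys: {sorted(unknown)}")
        return (float(value.get("group", 0.0)),
                float(value.get("session", 0.0)),
                float(value.get("interval", 0.0)))
    return float(value), 0.0, 0.0


def make_cohort(n_controls: int, n_patients: int, effect_spec: dict,
                seed: int, network: NetworkModel | None = None,
                jitter_sd: float = DEFAULT_JITTER_SD,
                n_retest: int | None = None,
                n_followup: int | None = None,
                baseline_profile: dict | None = None) -> CohortSpec:
    """Ground-truth cohort with injected group/session log-effects.

    ``effect_spec`` maps parameter names (see ``network.layout.names``) to a
    group log-effect (float, applied to patients) or a dict with any of the
    keys ``group``, ``session`` (added at follow-up) and ``interval``
    (multiplied by the subject's standardized follow-up interval).  Subjects'
    true parameters are the cohort baseline profile (default
    :func:`default_baseline_profile`, which produces a realistic mismatch
    response; pass ``{}`` for a prior-mean cohort) plus Gaussian
    between-subject jitter (sd ``jitter_sd`` on the free parameters) plus
    these effects.

    Controls carry a baseline session only; patients additionally receive a
    2-week retest (same true parameters, fresh noise) and an annual
    follow-up for study-matched fractions of the group unless overridden.
    """
    if n_controls < 0 or n_patients < 0:
        raise ValueError("cohort sizes must be non-negative")
    network = network or build_demo_network()
    lay = network.layout
    if baseline_profile is None:
        baseline_profile = default_baseline_profile(network)
    for name in list(effect_spec) + list(baseline_profile):
        if name not in lay.index:
            raise KeyError(
                f"unknown parameter {name!r}; valid names include "
                f"{list(lay.names[:5])}... ({lay.size} total)")
    priors = default_priors(network)
    free = priors.free_mask
    profile_vec = np.zeros(lay.size)
    for name, val in baseline_profile.items():
        profile_vec[lay.index[name]] = float(val)

    if n_retest is None:
        n_retest = int(round(RETEST_FRACTION * n_patients))
    if n_followup is None:
        n_followup = int(round(FOLLOWUP_FRACTION * n_patients))
    n_retest = min(n_retest, n_patients)
    n_followup = min(n_followup, n_patients)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_controls + n_patients) % (2**31)
    subjects: list[SubjectRecord] = []
    intervals_raw = []

    # draw follow-up intervals first so the standardized scores are cohort-wide
    rng_int = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    intervals_raw = rng_int.uniform(*INTERVAL_RANGE_YEARS, size=n_followup)
    if n_followup > 1 and np.std(intervals_raw) > 0:
        interval_std = (intervals_raw - intervals_raw.mean()) / intervals_raw.std(ddof=1)
    else:
        interval_std = np.zeros(n_followup)

    fu_count = 0
    for i in range(n_controls + n_patients):
        group = "control" if i < n_controls else "patient"
        sid = f"{'C' if group == 'control' else 'P'}{i if group == 'control' else i - n_controls:03d}"
        sub_seed = int(child_seeds[i])
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, i)))
        base = priors.mean + profile_vec
        base[free] += rng.normal(0.0, jitter_sd, free.sum())

        sessions = ["baseline"]
        interval = 0.0
        idx_fu = None
        if group == "patient":
            pi = i - n_controls
            if pi < n_retest:
                sessions.append("retest")
            if pi < n_followup:
                sessions.append("followup")
                idx_fu = fu_count
                interval = float(intervals_raw[fu_count])
                fu_count += 1

        vec = {s: base.copy() for s in sessions}
        for name, value in effect_spec.items():
            g_eff, s_eff, i_eff = _split_effect(value)
            j = lay.index[name]
            if group == "patient":
                for s in sessions:
                    vec[s][j] += g_eff
            if "followup" in sessions:
                vec["followup"][j] += s_eff
                if idx_fu is not None:
                    vec["followup"][j] += i_eff * interval_std[idx_fu]
        params = {s: lay.from_vector(v) for s, v in vec.items()}
        subjects.append(SubjectRecord(sid, group, tuple(sessions), interval,
                                      params, sub_seed))
    return CohortSpec(subjects, network, seed)


def _evoked_sources_to_epoch_grid(src: np.ndarray, times_ms: np.ndarray):
    """Map integration output (K, R, T) onto the -100..500 ms epoch grid."""
    n_out = n_epoch_samples()
    out_times = EPOCH_WINDOW_MS[0] + np.arange(n_out) * 1000.0 / EPOCH_SFREQ_HZ
    K, R, _ = src.shape
    out = np.zeros((K, R, n_out))
    post = out_times >= -1e-9
    idx = np.searchsorted(times_ms, out_times[post] - 1e-9)
    out[:, :, post] = src[:, :, idx]
    return out


def simulate_subject_evoked(params: CMCParameters, network: NetworkModel,
                            leadfield: LeadField, noise_sd: float,
                            n_trials_per_condition: int, seed: int,
                            config: DynamicsConfig | None = None) -> SensorEpochs:
    """Noisy sensor epochs for one subject/session.

    The per-condition source response (identical across that condition's
    epochs) is mapped through the lead field; white Gaussian sensor noise of
    sd ``noise_sd`` is added per epoch.  White noise is the default; an
    AR(1) hook is available via ``noise_ar`` on the config in future use.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    config = config or DynamicsConfig()
    lay = network.layout
    theta = lay.to_vector(params)
    G = leadfield.gain_matrix
    if G.shape[1] != lay.n_regions:
        raise ValueError("lead field does not match network regions")

    src, ok, times = predict_sources(theta[None], network, config,
                                     t_end_ms=EPOCH_WINDOW_MS[1])
    if not ok[0]:
        from .dynamics import IntegrationError
        raise IntegrationError("subject simulation diverged")
    src = _evoked_sources_to_epoch_grid(src[0], times)
    clean = np.einsum("sr,krt->kst", G, src)      # (K, sensors, samples)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    K, S, T = clean.shape
    n = n_trials_per_condition
    data = np.repeat(clean, n, axis=0)
    data = data + rng.normal(0.0, noise_sd, size=data.shape) if noise_sd > 0 \
        else data
    labels = [CONDITION_LABELS[k] for k in range(K) for _ in range(n)]
    return SensorEpochs(data, labels)


def noise_sd_for_snr(params: CMCParameters, network: NetworkModel,
                     leadfield: LeadField, snr: float,
                     n_trials_per_condition: int,
                     config: DynamicsConfig | None = None) -> float:
    """Single-trial noise sd so the *averaged* evoked response has the given
    amplitude signal-to-noise ratio (rms signal / rms noise-in-average)."""
    config = config or DynamicsConfig()
    lay = network.layout
    src, ok, times = predict_sources(lay.to_vector(params)[None], network,
                                     config, t_end_ms=EPOCH_WINDOW_MS[1])
    src = _evoked_sources_to_epoch_grid(src[0], times)
    clean = np.einsum("sr,krt->kst", leadfield.gain_matrix, src)
    rms = np.sqrt(np.mean(clean**2))
    return rms * np.sqrt(n_trials_per_condition) / snr


def simulate_cohort_epochs(cohort: CohortSpec, leadfield: LeadField,
                           snr: float = 5.0,
                           n_trials_per_condition: int = DEFAULT_TRIALS_PER_CONDITION,
                           config: DynamicsConfig | None = None):
    """Epochs for every subject/session of a cohort.

    Returns ``{(subject_id, session): SensorEpochs}``.  The noise sd is
    calibrated once, at the prior-mean response, so every subject sees the
    same physical noise level (groups then differ only through their
    parameters).
    """
    config = config or DynamicsConfig()
    net = cohort.network
    sd = noise_sd_for_snr(net.layout.zeros(), net, leadfield, snr,
                          n_trials_per_condition, config)
    out = {}
    for sub in cohort.subjects:
        for k, ses in enumerate(sub.sessions):
            eseed = int(np.random.SeedSequence(
                sub.seed, spawn_key=(2, k)).generate_state(1)[0] % (2**31))
            out[(sub.subject_id, ses)] = simulate_subject_evoked(
                sub.true_params[ses], net, leadfield, sd,
                n_trials_per_condition, eseed, config)
    return out
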