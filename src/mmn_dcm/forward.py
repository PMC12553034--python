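"""Source-to-sensor forward model: lead field, Hanning taper, spatial modes.

The sensor prediction is linear in the source output,

    y_k(t) = G diag(exp(log_L)) s_k(t),

with ``G`` the (synthetic or supplied) lead field and ``log_L`` the free
per-region source gains.  Model and data are compared over 0-300 ms after
stimulus onset at 500 Hz, sample-wise weighted by a Hanning taper spanning
that window (the taper multiplies both data and prediction rather than
truncating the dynamics).  Optionally both are reduced to a small number of
principal spatial modes.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .model_space import NetworkModel
from .dynamics import DynamicsConfig, predict_sources

__all__ = [
    "FIT_SFREQ_HZ",
    "FIT_WINDOW_MS",
    "fit_window_samples",
    "hanning_taper",
    "SpatialProjector",
    "fit_projector",
    "predict_sensors",
    "sensor_prediction_batch",
]

#: Sampling rate of the fitted evoked data (Hz).
FIT_SFREQ_HZ = 500.0
#: Modeled peristimulus window (ms).
FIT_WINDOW_MS = (0.0, 300.0)


def fit_window_samples(sfreq_hz: float = FIT_SFREQ_HZ,
                       window_ms: tuple = FIT_WINDOW_MS) -> int:
    """Number of retained samples over the fit window, endpoints inclusive."""
    return int(round((window_ms[1] - window_ms[0]) / 1000.0 * sfreq_hz)) + 1


def hanning_taper(n_samples: int | None = None) -> np.ndarray:
    """Hanning taper over the fit window (zero at both endpoints)."""
    n = n_samples or fit_window_samples()
    return np.hanning(n)


@dataclass
class SpatialProjector:
    """Orthonormal spatial modes (sensors x modes) with explained variance."""

    basis: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self):
        self.basis = np.asarray(self.basis, float)
        g = self.basis.T @ self.basis
        if np.max(np.abs(g - np.eye(self.basis.shape[1]))) > 1e-10:
            raise ValueError("projector basis is not orthonormal")

    @property
    def n_modes(self) -> int:
        return self.basis.shape[1]

    def project(self, data: np.ndarray) -> np.ndarray:
        """Apply along the sensor axis (axis -2 of ... x sensors x samples)."""
        return np.einsum("sm,...st->...mt", self.basis, data)

    def back_project(self, modes: np.ndarray) -> np.ndarray:
        return np.einsum("sm,...mt->...st", self.basis, modes)


def fit_projector(condition_means: np.ndarray, n_modes: int) -> SpatialProjector:
    """Principal spatial modes of concatenated condition means.

    Parameters
    ----------
    condition_means : (conditions, sensors, samples) array
    n_modes : int
        1 <= n_modes <= sensors.

    Deterministic up to the sign convention that the largest-magnitude
    element of each mode is positive.
    """
    x = np.asarray(condition_means, float)
    if x.ndim != 3:
        raise ValueError("expected conditions x sensors x samples")
    K, S, T = x.shape
    if not 1 <= n_modes <= S:
        raise ValueError(f"n_modes must be in 1..{S}")
    flat = np.transpose(x, (1, 0, 2)).reshape(S, K * T)
    U, sv, _ = np.linalg.svd(flat, full_matrices=False)
    basis = U[:, :n_modes]
    for m in range(n_modes):
        j = np.argmax(np.abs(basis[:, m]))
        if basis[j, m] < 0:
            basis[:, m] = -basis[:, m]
    var = sv**2
    ev = var[:n_modes] / var.sum() if var.sum() > 0 else np.zeros(n_modes)
    return SpatialProjector(basis, ev)


def _window_indices(times_ms: np.ndarray,
                    sfreq_hz: float = FIT_SFREQ_HZ,
                    window_ms: tuple = FIT_WINDOW_MS) -> np.ndarray:
    """Indices of the integration grid that land on the 500 Hz fit grid."""
    t0, t1 = window_ms
    targets = t0 + np.arange(fit_window_samples(sfreq_hz, window_ms)) \
        * 1000.0 / sfreq_hz
    idx = np.searchsorted(times_ms, targets - 1e-9)
    if np.max(np.abs(times_ms[idx] - targets)) > 1e-6:
        raise ValueError("integration grid does not contain the fit grid")
    return idx


def sensor_prediction_batch(theta_batch: np.ndarray, network: NetworkModel,
                            leadfield_gain: np.ndarray,
                            config: DynamicsConfig | None = None,
                            projector: SpatialProjector | None = None,
                            taper: bool = True):
    """Windowed sensor (or mode) predictions for a batch of parameter draws.

    Returns ``(pred, ok)`` where ``pred`` has shape
    (B, conditions, channels, samples) on the 0-300 ms / 500 Hz grid and
    ``ok`` flags draws whose integration diverged.  ``leadfield_gain`` is the
    sensors x regions matrix (per-region log-gains are part of the
    parameters and applied inside the source model).
    """
    config = config or DynamicsConfig()
    G = np.asarray(leadfield_gain, float)
    src, ok, times = predict_sources(theta_batch, network, config,
                                     t_end_ms=FIT_WINDOW_MS[1])
    if G.shape[1] != src.shape[2]:
        raise ValueError(
            f"lead field has {G.shape[1]} regions, model has {src.shape[2]}")
    idx = _window_indices(times)
    src = src[:, :, :, idx]
    pred = np.einsum("sr,bkrt->bkst", G, src)
    if projector is not None:
        pred = projector.project(pred)
    if taper:
        pred = pred * hanning_taper(len(idx))
    return pred, ok


def predict_sensors(params, network: NetworkModel, leadfield_gain: np.ndarray,
                    config: DynamicsConfig | None = None,
                    projector: SpatialProjector | None = None,
                    taper: bool = True) -> np.ndarray:
    """Predicted evoked responses for one parameter set.

    Returns (conditions, channels, samples) over 0-300 ms at 500 Hz, Hanning
    tapered.  Raises if the integration diverges.
    """
    from .dynamics import IntegrationError
    lay = network.layout
    theta = lay.to_vector(params) if not isinstance(params, np.ndarray) \
        else np.asarray(params, float)
    pred, ok = sensor_prediction_batch(theta[None, :], network,
                                       leadfield_gain, config, projector,
                                       taper)
    if not ok[0]:
        raise IntegrationError("sensor prediction diverged")
    return pred[0]
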