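"""Optional adapters for real MEG evoked data (requires ``mne``).

The pipeline consumes plain arrays (conditions x sensors x samples with a
time axis); these helpers build them from `mne.Evoked` objects or FIF
files so a real roving-paradigm dataset can be fed to :func:`fit_vl` and
the sensor statistics without touching the core modules.
"""

from __future__ import annotations

import numpy as np

from .synthetic import CONDITION_LABELS

__all__ = ["condition_means_from_evokeds", "read_evoked_fif"]


def _require_mne():
    try:
        import mne
    except ImportError as err:                      # pragma: no cover
        raise ImportError(
            "the MEG adapters need the optional dependency 'mne' "
            "(pip install mmn-dcm[meg])") from err
    return mne


def condition_means_from_evokeds(evokeds: dict, picks: str = "grad"):
    """Stack per-condition `mne.Evoked` objects into pipeline arrays.

    Parameters
    ----------
    evokeds : mapping condition label -> mne.Evoked
        Must cover the six modeled conditions (deviant, rep1..rep5), all
        with identical channel sets and sampling.
    picks : channel type passed to ``Evoked.pick`` (planar gradiometers by
        default, matching the sensor-level analyses).

    Returns
    -------
    (data, times_ms, ch_names) : ((6, sensors, samples) array, (samples,)
        array in milliseconds, list of channel names)
    """
    _require_mne()
    missing = [l for l in CONDITION_LABELS if l not in evokeds]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    out, times, names = [], None, None
    for lab in CONDITION_LABELS:
        ev = evokeds[lab].copy().pick(picks)
        if times is None:
            times = ev.times * 1000.0
            names = list(ev.ch_names)
        elif ev.ch_names != names or len(ev.times) != len(times):
            raise ValueError("evokeds differ in channels or sampling")
        out.append(ev.data)
    return np.stack(out), times, names


def read_evoked_fif(path, picks: str = "grad"):
    """Read a FIF evoked file whose comments name the six conditions."""
    mne = _require_mne()
    evs = mne.read_evokeds(path, verbose="error")
    by_label = {ev.comment: ev for ev in evs}
    return condition_means_from_evokeds(by_label, picks)
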