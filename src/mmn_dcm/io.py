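"""HDF5/CSV/JSON containers for datasets, inversions and group results.

Layout of the evoked container::

    /leadfield/gain_matrix          sensors x regions
    /leadfield/sensor_pairs         pairs x 2
    /subjects/<id>/<session>/epochs epochs x sensors x samples
        attrs: sfreq_hz, window_ms, labels, group

Ground-truth parameters (synthetic cohorts) go to JSON, the subject table to
CSV, so every artifact stays plain and diffable.
"""

from __future__ import annotations

import json
import hashlib
import numpy as np
import pandas as pd
import h5py

from .parameters import GaussianDensity
from .synthetic import (CohortSpec, SubjectRecord, SensorEpochs, LeadField,
                        CONDITION_LABELS)

__all__ = [
    "write_dataset",
    "read_dataset",
    "subject_table",
    "ground_truth_to_json",
    "write_inversions",
    "read_inversions",
    "file_sha256",
]


def _as_str(x):
    return x.decode() if isinstance(x, bytes) else str(x)


def subject_table(cohort: CohortSpec) -> pd.DataFrame:
    """One row per scan: subject, group, session, interval."""
    rows = []
    for s in cohort.subjects:
        for ses in s.sessions:
            rows.append(dict(subject_id=s.subject_id, group=s.group,
                             session=ses,
                             interval_years=(s.interval_years
                                             if ses == "followup" else 0.0),
                             seed=s.seed))
    return pd.DataFrame(rows)


def ground_truth_to_json(cohort: CohortSpec) -> str:
    lay = cohort.network.layout
    payload = {
        "master_seed": cohort.master_seed,
        "network": cohort.network.model_id,
        "parameter_names": list(lay.names),
        "subjects": {
            s.subject_id: {
                "group": s.group,
                "interval_years": s.interval_years,
                "true_params": {ses: lay.to_vector(p).tolist()
                                for ses, p in s.true_params.items()},
            } for s in cohort.subjects
        },
    }
    return json.dumps(payload, indent=1)


def write_dataset(path, epochs: dict, leadfield: LeadField,
                  cohort: CohortSpec | None = None) -> None:
    """Write ``{(subject_id, session): SensorEpochs}`` plus the lead field."""
    with h5py.File(path, "w") as f:
        lf = f.create_group("leadfield")
        lf.create_dataset("gain_matrix", data=leadfield.gain_matrix)
        lf.create_dataset("sensor_pairs", data=np.asarray(leadfield.sensor_pairs))
        lf.attrs["region_order"] = np.array(
            [str(r) for r in leadfield.region_order], dtype="S")
        groups = {}
        if cohort is not None:
            groups = {s.subject_id: s.group for s in cohort.subjects}
        for (sid, ses), ep in epochs.items():
            g = f.require_group(f"subjects/{sid}/{ses}")
            d = g.create_dataset("epochs", data=ep.data)
            d.attrs["sfreq_hz"] = ep.sfreq_hz
            d.attrs["window_ms"] = list(ep.window_ms)
            d.attrs["labels"] = np.array(
                [str(l) for l in ep.condition_label], dtype="S")
            d.attrs["group"] = groups.get(sid, "")


def read_dataset(path):
    """Inverse of :func:`write_dataset`."""
    epochs = {}
    with h5py.File(path, "r") as f:
        lf = LeadField(
            f["leadfield/gain_matrix"][()],
            [tuple(p) for p in f["leadfield/sensor_pairs"][()]],
            tuple(_as_str(x) for x in f["leadfield"].attrs["region_order"]),
        )
        for sid in f["subjects"]:
            for ses in f[f"subjects/{sid}"]:
                d = f[f"subjects/{sid}/{ses}/epochs"]
                epochs[(sid, ses)] = SensorEpochs(
                    d[()], [_as_str(l) for l in d.attrs["labels"]],
                    float(d.attrs["sfreq_hz"]),
                    tuple(d.attrs["window_ms"]),
                )
    return epochs, lf


def write_inversions(path, results: dict) -> None:
    """Persist VL results keyed ``(subject_id, session)`` (or any str key).

    Failed inversions may be passed as None; they are recorded as flagged
    empty groups so downstream stages can report exclusions.
    """
    with h5py.File(path, "w") as f:
        for key, res in results.items():
            name = "/".join(key) if isinstance(key, tuple) else str(key)
            g = f.create_group(name)
            if res is None:
                g.attrs["failed"] = True
                continue
            g.attrs["failed"] = False
            g.create_dataset("posterior_mean", data=res.posterior.mean)
            g.create_dataset("posterior_cov", data=res.posterior.cov)
            g.attrs["labels"] = np.array(list(res.posterior.labels),
                                          dtype="S")
            g.attrs["free_energy"] = res.free_energy
            g.attrs["fit_correlation"] = res.fit_correlation
            g.create_dataset("trace", data=res.trace)
            g.create_dataset("theta_full", data=res.theta_full)


def read_inversions(path) -> dict:
    """Read posteriors back as ``{key: GaussianDensity | None}`` plus meta."""
    out = {}
    with h5py.File(path, "r") as f:
        def visit(name, obj):
            if isinstance(obj, h5py.Group) and "failed" in obj.attrs:
                key = tuple(name.split("/")) if "/" in name else name
                if obj.attrs["failed"]:
                    out[key] = None
                else:
                    out[key] = dict(
                        posterior=GaussianDensity(
                            obj["posterior_mean"][()],
                            obj["posterior_cov"][()],
                            tuple(_as_str(l) for l in obj.attrs["labels"])),
                        free_energy=float(obj.attrs["free_energy"]),
                        fit_correlation=float(obj.attrs["fit_correlation"]),
                        trace=obj["trace"][()],
                        theta_full=obj["theta_full"][()],
                    )
        f.visititems(visit)
    return out


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
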