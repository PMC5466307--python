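"""Persistent formats: per-subject HDF5 containers, CSV tables, JSON manifests.

One HDF5 file holds a complete synthetic acquisition: the complex echo
stream under ``/kspace``, the ECG under ``/ecg``, and the ground truth under
``/truth``; the subject and acquisition configs travel as JSON-encoded root
attributes.
"""

from __future__ import annotations

import json
from typing import List

import h5py
import numpy as np

from .config import AcquisitionConfig, SubjectConfig
from .simulate import ECGTrace, EchoStream, GroundTruth, Subject


def save_subject(path: str, subject: Subject) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["subject_config"] = subject.config.to_json()
        f.attrs["acquisition_config"] = json.dumps(subject.acq.to_dict(), sort_keys=True)
        g = f.create_group("kspace")
        g.create_dataset("samples", data=subject.echoes.samples, compression="gzip")
        g.create_dataset("echo_times", data=subject.echoes.echo_times)
        g.create_dataset("venc_toggle", data=subject.echoes.venc_toggle)
        g = f.create_group("ecg")
        g.create_dataset("samples", data=subject.ecg.samples, compression="gzip")
        g.attrs["fs"] = subject.ecg.fs
        g.create_dataset("online_detections", data=subject.ecg.online_detections)
        g = f.create_group("truth")
        g.create_dataset("r_times", data=subject.truth.r_times)
        g.create_dataset("rr_durations", data=subject.truth.rr_durations)
        g.create_dataset("end_systole_s", data=subject.truth.end_systole_s)
        g.create_dataset("aorta_pixels", data=subject.truth.aorta_pixels)
        g.create_dataset("is_ectopic", data=subject.truth.is_ectopic)
        for i, pix in enumerate(subject.truth.confounder_pixels):
            g.create_dataset(f"confounder_{i}", data=pix)


def load_subject(path: str) -> Subject:
    with h5py.File(path, "r") as f:
        config = SubjectConfig.from_json(f.attrs["subject_config"])
        acq = AcquisitionConfig.from_dict(json.loads(f.attrs["acquisition_config"]))
        echoes = EchoStream(
            samples=f["kspace/samples"][...],
            echo_times=f["kspace/echo_times"][...],
            venc_toggle=f["kspace/venc_toggle"][...],
            config=acq,
        )
        ecg = ECGTrace(
            samples=f["ecg/samples"][...],
            fs=float(f["ecg"].attrs["fs"]),
            online_detections=f["ecg/online_detections"][...],
        )
        confounders: List[np.ndarray] = []
        i = 0
        while f"truth/confounder_{i}" in f:
            confounders.append(f[f"truth/confounder_{i}"][...])
            i += 1
        truth = GroundTruth(
            r_times=f["truth/r_times"][...],
            rr_durations=f["truth/rr_durations"][...],
            end_systole_s=f["truth/end_systole_s"][...],
            aorta_pixels=f["truth/aorta_pixels"][...],
            confounder_pixels=confounders,
            is_ectopic=f["truth/is_ectopic"][...].astype(bool),
        )
    return Subject(echoes=echoes, ecg=ecg, truth=truth, config=config, acq=acq)


def write_table(df, path: str) -> None:
    """Deterministic CSV output (fixed float format, no index)."""
    df.to_csv(path, index=False, float_format="%.10g")


def write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
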