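"""Reading and writing cohort files.

On-disk cohort layout written by :func:`write_cohort`::

    <dir>/manifest.json            ids, groups, per-subject seeds, EEG geometry
    <dir>/fixations.csv            subject_id,test,aoi,onset_ms,duration_ms
    <dir>/eeg/<subject_id>.txt     plain channels x samples numeric matrix

Real EDF/EDF+ recordings can be read through mne when it is installed
(``pip install gazegraph[edf]``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .eeg import EEGRecording
from .eye import FixationRecord
from .synthetic import SyntheticSubject, subject_seeds

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_fixation_log",
    "read_fixation_log",
    "read_eeg_matrix",
    "read_edf",
    "write_feature_table",
]

FIXATION_COLUMNS = ["subject_id", "test", "aoi", "onset_ms", "duration_ms"]


def write_fixation_log(
    subjects: Sequence[SyntheticSubject], path: str | Path
) -> pd.DataFrame:
    """One CSV of all subjects' fixation events."""
    rows = [
        {
            "subject_id": s.subject_id,
            "test": r.test,
            "aoi": r.aoi,
            "onset_ms": r.onset_ms,
            "duration_ms": r.duration_ms,
        }
        for s in subjects
        for r in s.fixations
    ]
    df = pd.DataFrame(rows, columns=FIXATION_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")  # exact float round trip
    return df


def read_fixation_log(path: str | Path) -> dict[str, list[FixationRecord]]:
    """Fixation CSV -> per-subject record lists."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(FIXATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation log missing column(s) {sorted(missing)}")
    out: dict[str, list[FixationRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            FixationRecord(
                test=row.test,
                aoi=row.aoi,
                onset_ms=float(row.onset_ms),
                duration_ms=float(row.duration_ms),
            )
        )
    return out


def read_eeg_matrix(
    path: str | Path,
    rate_hz: float,
    channel_names: Sequence[str] | None = None,
) -> EEGRecording:
    """Plain whitespace-delimited channels x samples matrix file."""
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    names = (
        tuple(channel_names)
        if channel_names is not None
        else tuple(f"CH{i + 1}" for i in range(data.shape[0]))
    )
    return EEGRecording(data=data, rate_hz=rate_hz, channel_names=names)


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/EDF+ recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input needs mne: pip install gazegraph[edf]") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        rate_hz=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
    )


def write_cohort(
    subjects: Sequence[SyntheticSubject],
    directory: str | Path,
    master_seed: int | None = None,
    fmt: str = "%.6e",
) -> Path:
    """Serialize a cohort: manifest JSON, fixation CSV, per-subject matrices."""
    out = Path(directory)
    (out / "eeg").mkdir(parents=True, exist_ok=True)
    manifest = {
        "subjects": [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "n_channels": s.eeg.n_channels,
                "rate_hz": s.eeg.rate_hz,
                "channel_names": list(s.eeg.channel_names),
                "seeds": list(subject_seeds(master_seed, i)) if master_seed is not None else None,
            }
            for i, s in enumerate(subjects)
        ],
        "master_seed": master_seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    write_fixation_log(subjects, out / "fixations.csv")
    for s in subjects:
        np.savetxt(out / "eeg" / f"{s.subject_id}.txt", s.eeg.data, fmt=fmt)
    return out


def read_cohort(directory: str | Path) -> list[SyntheticSubject]:
    """Load a cohort written by :func:`write_cohort`."""
    src = Path(directory)
    manifest = json.loads((src / "manifest.json").read_text())
    fixations = read_fixation_log(src / "fixations.csv")
    subjects = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                group=entry["group"],
                eeg=read_eeg_matrix(
                    src / "eeg" / f"{sid}.txt",
                    rate_hz=entry["rate_hz"],
                    channel_names=entry["channel_names"],
                ),
                fixations=fixations.get(sid, []),
            )
        )
    return subjects


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)
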