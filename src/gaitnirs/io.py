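"""Reading and writing cohorts, feature tables and reports.

A cohort directory contains one CSV per (subject, state, signal kind)
trial — header ``time,ch1,...,ch22``, one row per sample — plus a
``manifest.json`` sidecar with the onset index, sampling period and
labels of every file.  Python's shortest round-trip float repr is used
when writing, so a write/read cycle is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import N_CHANNELS, Recording, ValidationError
from .states import GaitState

MANIFEST_NAME = "manifest.json"


def _filename(recording: Recording) -> str:
    return f"{recording.subject_id}_{recording.state.label}_{recording.signal_kind}.csv"


def write_cohort(recordings: Sequence[Recording], directory: str | Path) -> list[Path]:
    """Write a cohort to ``directory``; returns the data file paths.

    An empty recording list still produces a (empty) manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format_version": 1, "recordings": {}}
    paths = []
    for rec in recordings:
        name = _filename(rec)
        frame = pd.DataFrame(
            rec.samples.T,
            columns=[f"ch{c + 1}" for c in range(rec.n_channels)],
        )
        frame.insert(0, "time", np.arange(rec.n_time) * rec.sampling_period)
        path = directory / name
        # %.17g is lossless for IEEE doubles
        frame.to_csv(path, index=False, float_format="%.17g")
        manifest["recordings"][name] = {
            "subject_id": rec.subject_id,
            "state": rec.state.label,
            "signal_kind": rec.signal_kind,
            "onset_index": rec.onset_index,
            "sampling_period": rec.sampling_period,
            "n_channels": rec.n_channels,
        }
        paths.append(path)
    with open(directory / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths


def _load_manifest(directory: Path) -> dict:
    path = directory / MANIFEST_NAME
    if not path.exists():
        raise ValidationError(f"no {MANIFEST_NAME} in {directory}")
    with open(path) as fh:
        return json.load(fh)


def read_recording(path: str | Path, min_onset: int = 180) -> Recording:
    """Parse one trial CSV plus its manifest entry into a Recording.

    Validates the header, channel count, absence of NaN cells and that
    the onset leaves at least ``min_onset`` pre-movement samples.
    """
    path = Path(path)
    manifest = _load_manifest(path.parent)
    entry = manifest["recordings"].get(path.name)
    if entry is None:
        raise ValidationError(f"{path}: no manifest entry")
    frame = pd.read_csv(path, float_precision="round_trip")
    expected = ["time"] + [f"ch{c + 1}" for c in range(entry["n_channels"])]
    if list(frame.columns) != expected:
        raise ValidationError(
            f"{path}: malformed header {list(frame.columns)[:4]}..., expected "
            f"time,ch1..ch{entry['n_channels']}"
        )
    if entry["n_channels"] != N_CHANNELS:
        raise ValidationError(
            f"{path}: {entry['n_channels']} channels, expected {N_CHANNELS}"
        )
    values = frame[expected[1:]].to_numpy(dtype=float).T
    if np.isnan(values).any():
        raise ValidationError(f"{path}: NaN cells in data")
    if entry["onset_index"] < min_onset:
        raise ValidationError(
            f"{path}: onset index {entry['onset_index']} leaves fewer than "
            f"{min_onset} pre-movement samples"
        )
    return Recording(
        subject_id=entry["subject_id"],
        state=GaitState.from_label(entry["state"]),
        signal_kind=entry["signal_kind"],
        samples=values,
        sampling_period=float(entry["sampling_period"]),
        onset_index=int(entry["onset_index"]),
    )


def read_cohort(directory: str | Path) -> list[Recording]:
    """Read every trial listed in a cohort directory's manifest."""
    directory = Path(directory)
    manifest = _load_manifest(directory)
    return [read_recording(directory / name) for name in sorted(manifest["recordings"])]


# ---------------------------------------------------------------------------
# long-format feature tables (one row per matrix cell)


def write_feature_table(
    featmats: Mapping[tuple[str, str, str], np.ndarray], path: str | Path
) -> None:
    """Write slope matrices as a long CSV: subject,state,signal_kind,band,channel,value."""
    rows = []
    for (subject, state, kind), mat in sorted(featmats.items()):
        mat = np.asarray(mat)
        for band in range(mat.shape[0]):
            for ch in range(mat.shape[1]):
                rows.append((subject, state, kind, band + 1, ch + 1, mat[band, ch]))
    pd.DataFrame(
        rows, columns=["subject", "state", "signal_kind", "band", "channel", "value"]
    ).to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> dict[tuple[str, str, str], np.ndarray]:
    """Inverse of :func:`write_feature_table`."""
    frame = pd.read_csv(path)
    featmats: dict[tuple[str, str, str], np.ndarray] = {}
    for (subject, state, kind), grp in frame.groupby(
        ["subject", "state", "signal_kind"], sort=True
    ):
        mat = np.zeros((int(grp["band"].max()), int(grp["channel"].max())))
        mat[grp["band"] - 1, grp["channel"] - 1] = grp["value"]
        featmats[(str(subject), str(state), str(kind))] = mat
    return featmats
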