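"""Reading and writing epoched recordings, cohorts and configuration.

Two on-disk formats are supported for EEG input:

* European Data Format (``.edf``), read through :mod:`mne`;
* a dependency-free delimited matrix (channels x samples CSV) with a JSON
  sidecar ``{"fs": Hz, "channels": [...], "epoch_length_s": s}``.

Continuous input is segmented into non-overlapping epochs of
``epoch_length_s`` seconds, truncating any trailing partial epoch.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .datatypes import CohortDataset, EpochedRecording, PipelineConfig, Subject

__all__ = [
    "read_epochs",
    "write_epochs",
    "select_channels",
    "save_cohort",
    "load_cohort",
    "load_config",
    "save_config",
]


class FormatError(ValueError):
    """Missing or contradictory file metadata."""


def _epoch_continuous(data: np.ndarray, fs: float, epoch_length_s: float) -> np.ndarray:
    """(channels, samples) -> (channels, epochs, samples_per_epoch), truncating."""
    spe = int(round(epoch_length_s * fs))
    if spe <= 0:
        raise FormatError(f"epoch_length_s={epoch_length_s} at fs={fs} gives no samples")
    n_epochs = data.shape[1] // spe
    if n_epochs == 0:
        raise FormatError(
            f"recording shorter ({data.shape[1]} samples) than one epoch ({spe})"
        )
    return data[:, : n_epochs * spe].reshape(data.shape[0], n_epochs, spe)


def read_epochs(path: str | Path, metadata: str | Path | None = None) -> EpochedRecording:
    """Read an EDF file or a delimited matrix (+ JSON sidecar) as epochs.

    Parameters
    ----------
    path
        ``.edf`` file, or a delimited numeric matrix with one row per channel.
    metadata
        JSON sidecar for the delimited format. Defaults to ``<path>.json``.
        For EDF input a sidecar may still supply ``epoch_length_s``
        (default 4 s).
    """
    path = Path(path)
    side: dict = {}
    meta_path = Path(metadata) if metadata is not None else path.with_suffix(path.suffix + ".json")
    if meta_path.exists():
        side = json.loads(meta_path.read_text())

    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne uses volts internally
        fs = float(raw.info["sfreq"])
        labels = tuple(raw.ch_names)
        epoch_length_s = float(side.get("epoch_length_s", 4.0))
    else:
        if not side:
            raise FormatError(f"no JSON sidecar found for delimited input {path}")
        try:
            fs = float(side["fs"])
            labels = tuple(side["channels"])
            epoch_length_s = float(side["epoch_length_s"])
        except KeyError as err:
            raise FormatError(f"sidecar {meta_path} missing key {err}") from err
        data = np.loadtxt(path, delimiter=",", ndmin=2)

    if data.shape[0] != len(labels):
        raise FormatError(
            f"{len(labels)} channel labels but {data.shape[0]} data rows in {path}"
        )
    if np.isnan(data).any():
        raise ValueError(f"NaN samples in {path}")
    epochs = _epoch_continuous(data, fs, epoch_length_s)
    return EpochedRecording(epochs, fs, labels, epoch_length_s)


def write_epochs(rec: EpochedRecording, path: str | Path, metadata: str | Path | None = None) -> None:
    """Write a recording in the delimited format (full float precision)."""
    path = Path(path)
    meta_path = Path(metadata) if metadata is not None else path.with_suffix(path.suffix + ".json")
    flat = rec.data.reshape(rec.n_channels, rec.n_epochs * rec.n_samples)
    np.savetxt(path, flat, delimiter=",", fmt="%.17g")
    meta_path.write_text(
        json.dumps(
            {
                "fs": rec.fs,
                "channels": list(rec.channel_labels),
                "epoch_length_s": rec.epoch_length_s,
            }
        )
    )


def select_channels(rec: EpochedRecording, keep: Sequence[str]) -> EpochedRecording:
    """Restrict and reorder a recording's channels (default use: 64 -> 60 scalp)."""
    return rec.select_channels(keep)


# --------------------------------------------------------------------------
# cohorts on disk: one delimited recording per subject x condition, plus a
# manifest CSV (subject, group, mmse, conditions)
# --------------------------------------------------------------------------

def save_cohort(cohort: CohortDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id,group,mmse,conditions"]
    for s in cohort:
        conds = ";".join(s.recordings)
        rows.append(f"{s.subject_id},{s.group},{s.mmse:g},{conds}")
        for cond, rec in s.recordings.items():
            write_epochs(rec, directory / f"{s.subject_id}_{cond}.csv")
    (directory / "manifest.csv").write_text("\n".join(rows) + "\n")


def load_cohort(directory: str | Path) -> CohortDataset:
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FormatError(f"no manifest.csv in {directory}")
    subjects = []
    lines = manifest.read_text().strip().splitlines()
    for line in lines[1:]:
        sid, group, mmse, conds = line.split(",")
        recordings = {
            cond: read_epochs(directory / f"{sid}_{cond}.csv")
            for cond in conds.split(";")
            if cond
        }
        subjects.append(Subject(sid, group, float(mmse), recordings))
    return CohortDataset(subjects)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
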