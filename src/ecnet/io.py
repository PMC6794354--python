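"""Core domain types and file I/O.

Recordings travel either as EDF (read via mne) or as a self-describing
tab-delimited matrix: one comment header line holding the sampling rate and
condition tag, then one row per channel (label followed by samples, in
microvolts).  Adjacency matrices and result tables are plain TSV.  Adjacency
orientation is always row-sends-to-column and every adjacency file says so in
its header line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, channel_hemisphere, REGIONS

_KNOWN_REGIONS = set(REGIONS)
_CONDITIONS = ("EO", "L", "other")


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples, in microvolts."""

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    condition: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"label count ({len(self.labels)}) does not match channel "
                f"row count ({self.data.shape[0]})"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite sample at channel {self.labels[bad[0]]!r}, "
                f"index {bad[1]}"
            )
        if self.condition not in _CONDITIONS:
            raise ValueError(f"condition must be one of {_CONDITIONS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return replace(self, data=np.asarray(data, dtype=float))


def write_eeg(rec: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# eeg fs={rec.fs:.17g} condition={rec.condition}\n")
        for label, row in zip(rec.labels, rec.data):
            fh.write(label + "\t" + "\t".join(format(v, ".17g") for v in row)
                     + "\n")


def _read_eeg_delimited(path: Path) -> EEGRecording:
    fs = None
    condition = "other"
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if tok.startswith("fs="):
                        fs = float(tok[3:])
                    elif tok.startswith("condition="):
                        condition = tok[len("condition="):]
                continue
            parts = line.split("\t")
            label = parts[0]
            try:
                rows.append(np.array([float(v) for v in parts[1:]]))
            except ValueError as err:
                raise ValueError(
                    f"{path}: non-numeric payload in row {lineno} "
                    f"(channel {label!r}): {err}"
                ) from None
            labels.append(label)
    if fs is None:
        raise ValueError(f"{path}: missing '# eeg fs=...' header line")
    if not rows:
        raise ValueError(f"{path}: no channel rows")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: channel rows have unequal lengths {sorted(lengths)}")
    return EEGRecording(np.vstack(rows), fs=fs, labels=tuple(labels), condition=condition)


def _read_eeg_edf(path: Path) -> EEGRecording:
    import mne  # heavy import, only needed for EDF

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data, fs=float(raw.info["sfreq"]),
                        labels=tuple(raw.ch_names))


def read_eeg(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read a recording from EDF or the delimited-matrix format.

    Format is inferred from the extension (.edf) unless given explicitly as
    ``"edf"`` or ``"delimited"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_eeg_edf(path)
    if format == "delimited":
        return _read_eeg_delimited(path)
    raise ValueError(f"unknown format {format!r}")


def write_montage(montage: Montage, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tx\ty\tz\tregion\themisphere\n")
        for ch in montage.channels:
            x, y, z = montage.positions[ch]
            fh.write(f"{ch}\t{x:.17g}\t{y:.17g}\t{z:.17g}\t{montage.region[ch]}"
                     f"\t{montage.hemisphere[ch]}\n")


def read_montage(path: str | Path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    names = [str(n) for n in df["name"]]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate channel name(s) in montage file: {dupes}")
    positions, region, hemisphere = {}, {}, {}
    for _, row in df.iterrows():
        name = str(row["name"])
        reg = str(row["region"])
        if reg not in _KNOWN_REGIONS:
            raise ValueError(f"unknown region label {reg!r} for channel {name!r}")
        positions[name] = np.array([row["x"], row["y"], row["z"]], dtype=float)
        region[name] = reg
        hemisphere[name] = (str(row["hemisphere"]) if "hemisphere" in df.columns
                            else channel_hemisphere(name))
    return Montage(tuple(names), positions, region, hemisphere)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_adjacency(matrix: np.ndarray, labels: list[str] | tuple[str, ...],
                    path: str | Path, comment: str = "") -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match label count")
    with open(path, "w") as fh:
        header = "# adjacency: row sends to column"
        if comment:
            header += f"; {comment}"
        fh.write(header + "\n")
        fh.write("\t" + "\t".join(labels) + "\n")
        for label, row in zip(labels, matrix):
            fh.write(label + "\t" + "\t".join(format(v, ".17g") for v in row)
                     + "\n")


def read_adjacency(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    labels: list[str] | None = None
    rows = []
    row_labels = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if labels is None:
                labels = [p for p in parts if p]
                continue
            row_labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if labels is None or not rows:
        raise ValueError(f"{path}: empty adjacency file")
    if row_labels != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    return np.array(rows), tuple(labels)


def write_manifest(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
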