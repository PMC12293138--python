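"""Core data types and I/O for source-space motor-imagery analysis.

Defines the trial/epoch containers used throughout the pipeline, the scalp
montage with its nested 19/30/61/118-channel caps, a reader for the
competition-format matrix files (continuous signal + cue markers + channel
info), and serialization of per-subject results tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RIGHT_HAND = "right_hand"
RIGHT_FOOT = "right_foot"
UNKNOWN = "unknown"
CLASSES = (RIGHT_HAND, RIGHT_FOOT)

#: raw integer units of the competition recordings, in µV
RAW_UNIT_UV = 0.1

METRIC_COLUMNS = ("Acc", "Sen", "Spec", "Pre", "F1")


class FormatError(ValueError):
    """A data file does not follow the expected layout."""


class ConfigurationError(ValueError):
    """A name or parameter does not resolve to anything defined."""


class ChannelMismatchError(ValueError):
    """Requested channels are absent from the data at hand."""


def round2(x: float) -> float:
    """Round half-up to 2 decimals (reporting convention for percentages)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _canon(name: str) -> str:
    """Canonical channel name: case-insensitive, whitespace-trimmed."""
    return name.strip().lower()


# ---------------------------------------------------------------------------
# trial containers


@dataclass
class Trial:
    """One epoch: a channels x samples matrix in µV with its class label."""

    data: np.ndarray
    label: str
    fs: float
    channel_names: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"row count {self.data.shape[0]} != number of channel names "
                f"{len(self.channel_names)}"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in CLASSES + (UNKNOWN,):
            raise ValueError(f"unknown class label {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """An ordered collection of trials for one subject with a train/test split.

    ``split`` holds one boolean per trial, True for training trials; train and
    test subsets are disjoint and together exhaust the collection.
    """

    trials: list[Trial]
    split: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.split = np.asarray(self.split, dtype=bool)
        if self.split.shape != (len(self.trials),):
            raise ValueError("split must hold exactly one flag per trial")
        if self.trials:
            first = self.trials[0]
            for t in self.trials:
                if t.fs != first.fs:
                    raise ValueError("all trials must share the sampling rate")
                if list(t.channel_names) != list(first.channel_names):
                    raise ValueError("all trials must share the channel order")
                if t.n_samples != first.n_samples:
                    raise ValueError("all trials must share the sample count")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    @property
    def channel_names(self) -> Sequence[str]:
        return self.trials[0].channel_names

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.trials]

    def data_array(self) -> np.ndarray:
        """Stack trials into an (n_trials, channels, samples) array."""
        return np.stack([t.data for t in self.trials])

    def train(self) -> "EpochSet":
        keep = [t for t, s in zip(self.trials, self.split) if s]
        return EpochSet(keep, np.ones(len(keep), bool), self.subject_id)

    def test(self) -> "EpochSet":
        keep = [t for t, s in zip(self.trials, self.split) if not s]
        return EpochSet(keep, np.zeros(len(keep), bool), self.subject_id)


# ---------------------------------------------------------------------------
# montage

SUBSET_NAMES = ("19", "30", "61", "118")


@dataclass
class Montage:
    """A named electrode set with unit-sphere positions and nested sub-caps."""

    electrode_names: list[str]
    positions: np.ndarray
    subset_defs: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.electrode_names), 3):
            raise ValueError("positions must be an n_electrodes x 3 array")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode positions must lie on the unit sphere")
        canon = {_canon(n) for n in self.electrode_names}
        if len(canon) != len(self.electrode_names):
            raise ValueError("duplicate electrode names")
        for sub, names in self.subset_defs.items():
            missing = [n for n in names if _canon(n) not in canon]
            if missing:
                raise ValueError(f"subset {sub!r} references unknown electrodes: {missing}")

    def __len__(self) -> int:
        return len(self.electrode_names)

    def index_of(self, names: Iterable[str]) -> np.ndarray:
        """Row indices of the given electrode names (case-insensitive)."""
        lookup = {_canon(n): i for i, n in enumerate(self.electrode_names)}
        idx, missing = [], []
        for n in names:
            key = _canon(n)
            if key in lookup:
                idx.append(lookup[key])
            else:
                missing.append(n)
        if missing:
            raise ChannelMismatchError(f"electrodes not in montage: {missing}")
        return np.asarray(idx, dtype=int)

    def subset_names_for(self, subset_name: str) -> list[str]:
        if subset_name not in self.subset_defs:
            raise ConfigurationError(
                f"unknown channel subset {subset_name!r}; "
                f"defined: {sorted(self.subset_defs)}"
            )
        return list(self.subset_defs[subset_name])

    def subset(self, subset_name: str) -> "Montage":
        """Montage restricted to one named cap, in the cap's order."""
        names = self.subset_names_for(subset_name)
        idx = self.index_of(names)
        return Montage([self.electrode_names[i] for i in idx], self.positions[idx])

    @classmethod
    def from_file(cls, path: str | Path, subset_defs: Mapping[str, Sequence[str]] | None = None) -> "Montage":
        """Read a plain-text montage: one electrode per line, ``name x y z``."""
        names, pos = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"montage line must be 'name x y z': {line!r}")
            names.append(parts[0])
            pos.append([float(v) for v in parts[1:]])
        return cls(names, np.asarray(pos), dict(subset_defs or {}))


def _read_name_list(path) -> list[str]:
    return [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]


def default_montage() -> Montage:
    """The shipped 118-electrode 10-05 montage with nested 19/30/61 caps.

    Positions are idealized spherical coordinates; all four caps are nested
    subsets of the 118-channel cap. The files are plain text and editable.
    """
    data = resources.files("mi_esi.data")
    subset_defs: dict[str, list[str]] = {}
    with resources.as_file(data / "montage_118.txt") as p:
        m = Montage.from_file(p)
    for sub in ("19", "30", "61"):
        with resources.as_file(data / f"subset_{sub}.txt") as p:
            subset_defs[sub] = _read_name_list(p)
    subset_defs["118"] = list(m.electrode_names)
    for sub, expected in zip(SUBSET_NAMES, (19, 30, 61, 118)):
        assert len(subset_defs[sub]) == expected
    return Montage(m.electrode_names, m.positions, subset_defs)


def subset_channels(epochs: EpochSet, montage: Montage, subset_name: str) -> EpochSet:
    """Restrict every trial to a named channel subset, in subset order."""
    names = montage.subset_names_for(subset_name)
    lookup = {_canon(n): i for i, n in enumerate(epochs.channel_names)}
    idx, missing = [], []
    for n in names:
        key = _canon(n)
        if key in lookup:
            idx.append(lookup[key])
        else:
            missing.append(n)
    if missing:
        raise ChannelMismatchError(
            f"subset {subset_name!r} channels missing from epochs: {missing}"
        )
    idx = np.asarray(idx, dtype=int)
    kept = [names[i] for i in range(len(names))]
    trials = [Trial(t.data[idx], t.label, t.fs, kept) for t in epochs.trials]
    return EpochSet(trials, epochs.split.copy(), epochs.subject_id)


# ---------------------------------------------------------------------------
# competition matrix-file reader


@dataclass
class Recording:
    """A continuous multichannel recording with cue markers."""

    data: np.ndarray  # channels x samples, µV
    fs: float
    channel_names: list[str]
    cue_samples: np.ndarray  # sample index of each cue
    labels: list[str]  # per-cue class label, "unknown" where absent
    positions: np.ndarray | None = None  # 2-D layout coordinates if present


def _mat_variables(path: Path) -> dict:
    """Load a matrix file (v5/v6/v7 via scipy, v7.3 via h5py)."""
    from scipy.io import loadmat

    try:
        return loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except NotImplementedError:
        import h5py

        out: dict = {}
        with h5py.File(path, "r") as f:

            def visit(name, obj):
                if isinstance(obj, h5py.Dataset):
                    out[name] = np.asarray(obj)

            f.visititems(visit)
        return out


def _struct_get(struct, name: str, flat: dict, prefix: str):
    if struct is not None and hasattr(struct, name):
        return getattr(struct, name)
    key = f"{prefix}/{name}"
    if key in flat:
        return flat[key]
    return None


def read_competition_recording(path: str | Path) -> Recording:
    """Read a competition-format matrix file.

    The layout is a continuous time x channels integer array (``cnt``, raw
    units of 0.1 µV), a marker structure (``mrk``: cue positions, class
    labels, class names) and an info structure (``nfo``: sampling rate and
    channel labels). Raw values are converted to µV. Cues whose label entry
    is missing or NaN (unlabeled competition test trials) are retained with
    the label "unknown".
    """
    path = Path(path)
    raw = _mat_variables(path)

    if "cnt" not in raw:
        raise FormatError("missing variable 'cnt' (continuous signal)")
    cnt = np.asarray(raw["cnt"], dtype=float)
    mrk = raw.get("mrk")
    nfo = raw.get("nfo")

    fs = _struct_get(nfo, "fs", raw, "nfo")
    if fs is None:
        raise FormatError("missing field 'nfo.fs' (sampling rate)")
    fs = float(np.ravel(np.asarray(fs))[0])

    clab = _struct_get(nfo, "clab", raw, "nfo")
    if clab is None:
        raise FormatError("missing field 'nfo.clab' (channel names)")
    channel_names = [str(c).strip() for c in np.ravel(np.asarray(clab, dtype=object))]

    pos_ = _struct_get(mrk, "pos", raw, "mrk")
    if pos_ is None:
        raise FormatError("missing field 'mrk.pos' (cue positions)")
    cue_samples = np.atleast_1d(np.asarray(pos_, dtype=float)).ravel().astype(int)

    y = _struct_get(mrk, "y", raw, "mrk")
    class_names = _struct_get(mrk, "className", raw, "mrk")
    if class_names is None:
        class_names = [RIGHT_HAND, RIGHT_FOOT]
    else:
        mapping = {"right": RIGHT_HAND, "hand": RIGHT_HAND, "foot": RIGHT_FOOT}
        class_names = [
            mapping.get(str(c).strip().lower(), str(c).strip().lower())
            for c in np.ravel(np.asarray(class_names, dtype=object))
        ]

    labels: list[str] = []
    if y is None:
        labels = [UNKNOWN] * len(cue_samples)
    else:
        y = np.atleast_1d(np.asarray(y, dtype=float)).ravel()
        if y.shape[0] != cue_samples.shape[0]:
            raise FormatError("'mrk.y' length does not match 'mrk.pos'")
        for v in y:
            if np.isnan(v):
                labels.append(UNKNOWN)
            else:
                k = int(v) - 1
                if not 0 <= k < len(class_names):
                    raise FormatError(f"class index {v} out of range")
                labels.append(class_names[k])

    # continuous array is stored time x channels; transpose and scale to µV
    if cnt.ndim != 2:
        raise FormatError("'cnt' must be a 2-D array")
    if cnt.shape[1] != len(channel_names) and cnt.shape[0] == len(channel_names):
        cnt = cnt.T
    if cnt.shape[1] != len(channel_names):
        raise FormatError(
            f"'cnt' channel dimension {cnt.shape} does not match "
            f"{len(channel_names)} channel names"
        )
    data = cnt.T * RAW_UNIT_UV

    positions = None
    xpos = _struct_get(nfo, "xpos", raw, "nfo")
    ypos = _struct_get(nfo, "ypos", raw, "nfo")
    if xpos is not None and ypos is not None:
        positions = np.column_stack([np.ravel(xpos), np.ravel(ypos)]).astype(float)

    return Recording(data, fs, channel_names, cue_samples, labels, positions)


# ---------------------------------------------------------------------------
# results tables


class ResultsTable:
    """Metric rows keyed by (subject, n_channels, kernel), plus mean rows.

    Metric values are percentages; the mean row per (n_channels, kernel) is
    the arithmetic mean of the subject rows, reported half-up to 2 decimals.
    """

    def __init__(self) -> None:
        self._rows: list[dict] = []

    def add(self, subject: str, n_channels: int, kernel: str, metrics: Mapping[str, float], **extra) -> None:
        row = {"subject": subject, "n_channels": int(n_channels), "kernel": kernel}
        for m in METRIC_COLUMNS:
            row[m] = float(metrics[m])
        row.update(extra)
        self._rows.append(row)

    def __len__(self) -> int:
        return len(self._rows)

    def to_frame(self, with_means: bool = True) -> pd.DataFrame:
        """The table as a DataFrame, mean rows (subject='mean') appended."""
        if not self._rows:
            raise ValueError("results table is empty")
        df = pd.DataFrame(self._rows)
        if with_means:
            means = (
                df.groupby(["n_channels", "kernel"], sort=True)[list(METRIC_COLUMNS)]
                .mean()
                .reset_index()
            )
            means.insert(0, "subject", "mean")
            df = pd.concat([df, means], ignore_index=True)
        for m in METRIC_COLUMNS:
            df[m] = df[m].map(round2)
        return df

    def write(self, path: str | Path) -> None:
        """Write CSV and JSON renderings (2-decimal percentages)."""
        path = Path(path)
        df = self.to_frame()
        path.parent.mkdir(parents=True, exist_ok=True)
        csv_path = path.with_suffix(".csv")
        df.to_csv(csv_path, index=False, float_format="%.2f")
        records = df.to_dict(orient="records")
        path.with_suffix(".json").write_text(json.dumps(records, indent=1) + "\n")

    @staticmethod
    def read_json(path: str | Path) -> pd.DataFrame:
        return pd.DataFrame(json.loads(Path(path).read_text()))


def write_results(table: ResultsTable, path: str | Path) -> None:
    """Write a results table to ``path`` as both ``.csv`` and ``.json``."""
    table.write(path)


def reference_results() -> pd.DataFrame:
    """The shipped published benchmark: per-subject metrics for each
    (channel count, kernel) cell of the four-configuration ablation."""
    data = resources.files("mi_esi.data")
    with resources.as_file(data / "reference_results.csv") as p:
        return pd.read_csv(p)
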