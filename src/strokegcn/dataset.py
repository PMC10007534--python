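"""Labelled trial containers and motion-capture ingestion.

A :class:`Trial` is one stroke: a ``frames x markers x 3`` coordinate array
in millimetres at 100 Hz plus a class label.  A :class:`TrialSet` is a
marker-order-consistent collection from which the padded network input is
built.  Classes are fixed as::

    0 forehand, 1 backhand, 2 volley_forehand, 3 volley_backhand

Ingestion reads standard C3D files, reorders markers to the canonical
order, converts metres to millimetres where needed, and linearly
interpolates invalid samples across gaps of at most 10 frames (longer gaps
reject the trial; full capture-pipeline gap filling is out of scope here).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .c3d import read_c3d_file, write_c3d_file
from .markers import MarkerSet

__all__ = [
    "CLASS_NAMES",
    "Trial",
    "TrialSet",
    "read_c3d",
    "write_c3d",
    "assemble_dataset",
    "pad_to_max",
    "unpad",
    "strip_racket",
    "save_npz",
    "load_npz",
]

log = logging.getLogger(__name__)

CLASS_NAMES = ("forehand", "backhand", "volley_forehand", "volley_backhand")
_MAX_GAP = 10


@dataclass
class Trial:
    """One recorded (or synthesized) stroke."""

    coords: np.ndarray                 # T x M x 3, millimetres
    label: int                         # class id 0..3
    marker_names: tuple[str, ...]
    subject_id: str = "S00"
    handedness: str = "right"
    rate: float = 100.0
    source: str = "synthetic"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be T x M x 3, got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("trial must have at least one frame")
        if self.coords.shape[1] != len(self.marker_names):
            raise ValueError("marker_names length does not match coords")
        if not (0 <= self.label < len(CLASS_NAMES)):
            raise ValueError(f"label must be 0..3, got {self.label}")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_markers(self) -> int:
        return self.coords.shape[1]


@dataclass
class TrialSet:
    """A marker-consistent collection of labelled trials."""

    trials: list[Trial]
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        if self.trials:
            ref = self.trials[0].marker_names
            for t in self.trials:
                if t.marker_names != ref:
                    raise ValueError("all trials must share marker order")

    def __len__(self):
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        if isinstance(i, (list, np.ndarray)):
            return TrialSet([self.trials[j] for j in i], self.class_names)
        return self.trials[i]

    @property
    def nf(self) -> int:
        """Maximum frame count over all trials."""
        return max(t.n_frames for t in self.trials)

    @property
    def n_markers(self) -> int:
        return self.trials[0].n_markers

    @property
    def marker_names(self) -> tuple[str, ...]:
        return self.trials[0].marker_names

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=np.int64)

    def class_counts(self) -> dict[str, int]:
        labels = self.labels
        return {name: int((labels == i).sum())
                for i, name in enumerate(self.class_names)}


# ---------------------------------------------------------------------------
# C3D ingestion


def _fill_gaps(coords: np.ndarray, invalid: np.ndarray, path) -> np.ndarray:
    """Linearly interpolate invalid samples; reject long gaps."""
    T = coords.shape[0]
    t = np.arange(T)
    out = coords.copy()
    for m in range(coords.shape[1]):
        bad = invalid[:, m]
        if not bad.any():
            continue
        if bad.all():
            raise ValueError(f"{path}: marker {m} has no valid samples")
        # longest run of consecutive invalid frames
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))[::2]
        if runs.size and runs.max() > _MAX_GAP:
            raise ValueError(
                f"{path}: gap of {int(runs.max())} frames exceeds the "
                f"{_MAX_GAP}-frame interpolation limit")
        good = ~bad
        for ax in range(3):
            out[bad, m, ax] = np.interp(t[bad], t[good], coords[good, m, ax])
    return out


def read_c3d(path, expected_markers: MarkerSet) -> Trial | None:
    """Read one C3D trial, reordered to ``expected_markers`` order, in mm.

    The class label is not stored in C3D; the returned Trial carries label 0
    and callers (``assemble_dataset``) overwrite it from the label map.
    """
    content = read_c3d_file(path)
    label_to_idx = {l: i for i, l in enumerate(content.labels)}
    missing = [l for l in expected_markers.names if l not in label_to_idx]
    if missing:
        raise ValueError(f"{path}: missing marker label(s) {missing}")
    order = [label_to_idx[l] for l in expected_markers.names]
    coords = content.points[:, order, :]
    residuals = content.residuals[:, order]
    if content.units.lower().startswith("m") and content.units.lower() != "mm":
        coords = coords * 1000.0
    invalid = (residuals < 0) | ~np.isfinite(coords).all(axis=2)
    if invalid.any():
        coords = _fill_gaps(np.nan_to_num(coords), invalid, path)
        log.info("%s: interpolated %d invalid samples", path, int(invalid.sum()))
    return Trial(coords=coords, label=0, marker_names=expected_markers.names,
                 rate=content.rate, source=str(path))


def write_c3d(trial: Trial, path) -> None:
    """Write a trial as a standard little-endian float C3D file in mm."""
    write_c3d_file(path, list(trial.marker_names), trial.coords,
                   rate=trial.rate, units="mm")


def assemble_dataset(root, label_map, expected_markers: MarkerSet) -> TrialSet:
    """Build a TrialSet from a directory of C3D files and a label-map CSV.

    The CSV columns are ``filename,label,subject,handedness`` where label is
    a class name or id.  Per-class counts are logged.
    """
    root = Path(root)
    rows = []
    with open(label_map, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(row)
    if not rows:
        raise ValueError(f"label map {label_map} is empty")
    name_to_id = {n: i for i, n in enumerate(CLASS_NAMES)}
    trials = []
    for row in rows:
        raw = row["label"].strip()
        if raw in name_to_id:
            label = name_to_id[raw]
        elif raw.isdigit() and int(raw) < len(CLASS_NAMES):
            label = int(raw)
        else:
            raise ValueError(f"unknown stroke label {raw!r}; expected one of "
                             f"{CLASS_NAMES} or an id 0..3")
        path = root / row["filename"]
        if not path.is_file():
            raise FileNotFoundError(path)
        trial = read_c3d(path, expected_markers)
        trial.label = label
        trial.subject_id = row.get("subject", "S00") or "S00"
        trial.handedness = row.get("handedness", "right") or "right"
        trials.append(trial)
    ts = TrialSet(trials)
    log.info("assembled %d trials: %s", len(ts), ts.class_counts())
    return ts


# ---------------------------------------------------------------------------
# padding and racket stripping


def pad_to_max(ts: TrialSet) -> tuple[np.ndarray, np.ndarray]:
    """Stack trials into an ``N x nf x M x 3`` tensor with trailing zeros.

    Trials shorter than the corpus maximum ``nf`` keep frames ``0..T_i``
    unchanged; the missing values are set to 0.  Returns the tensor and the
    true lengths.
    """
    if len(ts) == 0:
        raise ValueError("cannot pad an empty trial set")
    nf, M = ts.nf, ts.n_markers
    out = np.zeros((len(ts), nf, M, 3))
    lengths = np.zeros(len(ts), dtype=np.int64)
    for i, t in enumerate(ts):
        out[i, :t.n_frames] = t.coords
        lengths[i] = t.n_frames
    return out, lengths


def unpad(tensor: np.ndarray, lengths: np.ndarray) -> list[np.ndarray]:
    """Inverse of :func:`pad_to_max`: recover the per-trial arrays."""
    return [tensor[i, :int(n)].copy() for i, n in enumerate(lengths)]


def save_npz(ts: TrialSet, path) -> None:
    """Store a TrialSet as a compressed npz (padded tensor + lengths)."""
    X, lengths = pad_to_max(ts)
    np.savez_compressed(
        path, coords=X, lengths=lengths, labels=ts.labels,
        marker_names=np.array(ts.marker_names),
        class_names=np.array(ts.class_names),
        subjects=np.array([t.subject_id for t in ts]),
        handedness=np.array([t.handedness for t in ts]),
        rates=np.array([t.rate for t in ts]))


def load_npz(path) -> TrialSet:
    """Inverse of :func:`save_npz`."""
    with np.load(path, allow_pickle=False) as z:
        names = tuple(str(n) for n in z["marker_names"])
        class_names = tuple(str(n) for n in z["class_names"])
        subjects = z["subjects"] if "subjects" in z else None
        handed = z["handedness"] if "handedness" in z else None
        rates = z["rates"] if "rates" in z else None
        trials = []
        for i, T in enumerate(z["lengths"]):
            trials.append(Trial(
                coords=z["coords"][i, :int(T)].copy(),
                label=int(z["labels"][i]), marker_names=names,
                subject_id=str(subjects[i]) if subjects is not None else "S00",
                handedness=str(handed[i]) if handed is not None else "right",
                rate=float(rates[i]) if rates is not None else 100.0,
                source=str(path)))
    return TrialSet(trials, class_names)


def strip_racket(ts: TrialSet, n_body: int = 39) -> TrialSet:
    """Drop the racket channels, keeping the player's silhouette only.

    The body markers come first in the canonical 46-marker order, so the
    first ``n_body`` channels are kept bit-identically.
    """
    if ts.n_markers <= n_body:
        raise ValueError(
            f"trial set has {ts.n_markers} markers; nothing to strip "
            f"(expected more than {n_body})")
    body_names = ts.marker_names[:n_body]
    trials = [replace(t, coords=t.coords[:, :n_body, :].copy(),
                      marker_names=body_names) for t in ts]
    return TrialSet(trials, ts.class_names)
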