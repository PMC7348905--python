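"""Epoched-EEG data model, on-disk bundle format, and selection utilities.

The central container is :class:`EpochSet`, a labeled ``trials x channels x
samples`` tensor in microvolts with sampling metadata.  Time is expressed in
milliseconds relative to the first-flash onset (t = 0); sample ``i`` lies at
``t0_ms + 1000 * i / srate``.  Analysis windows are half-open ``[start, end)``
so that adjacent windows tile without duplication — e.g. 500–850 ms at 200 Hz
contains exactly 70 samples.

Class labels follow the sign convention of the fused decision rule:
``+1`` for the 400 ms prediction condition (T400), ``-1`` for 600 ms (T600);
``0`` is reserved for no-timing (NT) trials, which are used by descriptive
metrics only, never by the two-class classifiers.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LABEL_T400",
    "LABEL_T600",
    "LABEL_NT",
    "CENTRAL_18",
    "EpochSet",
    "BandSpec",
    "WindowSpec",
    "EpochFormatError",
    "load_epochs",
    "save_epochs",
    "select",
]

LABEL_T400 = 1
LABEL_T600 = -1
LABEL_NT = 0

#: The 18 centro-parietal electrodes used for classification.
CENTRAL_18 = (
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
)


class EpochFormatError(ValueError):
    """Raised when an epoch bundle on disk is malformed or inconsistent."""


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band; ``lo_hz == 0`` denotes a pure low-pass band."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 <= lo_hz < hi_hz, "
                f"got ({self.lo_hz}, {self.hi_hz})"
            )


#: Frequency bands of the analysis, plus the fused high band used by CSP
#: and the 0–90 Hz broadband.
BANDS = {
    "delta": BandSpec("delta", 0.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 15.0, 30.0),
    "mgamma": BandSpec("mgamma", 45.0, 65.0),
    "high": BandSpec("high", 20.0, 60.0),
    "broad": BandSpec("broad", 0.0, 90.0),
}


@dataclass(frozen=True)
class WindowSpec:
    """Half-open time window ``[start_ms, end_ms)`` relative to flash onset."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError(
                f"window start must precede end, got [{self.start_ms}, {self.end_ms})"
            )

    @property
    def length_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class EpochSet:
    """Labeled epoched EEG: ``data[trial, channel, sample]`` in microvolts."""

    data: np.ndarray
    labels: np.ndarray
    srate: float
    t0_ms: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, samples), got {self.data.ndim}-D")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match n_trials {self.data.shape[0]}"
            )
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )
        if not self.srate > 0:
            raise ValueError(f"srate must be positive, got {self.srate}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time of every sample in ms relative to first-flash onset."""
        return self.t0_ms + 1000.0 * np.arange(self.n_samples) / self.srate

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.labels.copy(), self.srate, self.t0_ms, self.channel_names
        )

    def take(self, indices: np.ndarray) -> "EpochSet":
        """Subset of trials by positional index (order preserved)."""
        idx = np.asarray(indices)
        return EpochSet(
            self.data[idx].copy(), self.labels[idx].copy(),
            self.srate, self.t0_ms, self.channel_names,
        )

    def with_data(self, data: np.ndarray, t0_ms: float | None = None,
                  srate: float | None = None) -> "EpochSet":
        """New EpochSet sharing labels/channels with replaced payload."""
        return EpochSet(
            data,
            self.labels.copy(),
            self.srate if srate is None else srate,
            self.t0_ms if t0_ms is None else t0_ms,
            self.channel_names,
        )

    def sample_slice(self, window: WindowSpec) -> slice:
        """Index slice of samples whose time lies in ``[start, end)``."""
        t = self.times_ms
        # half-open on a uniform grid; tolerance guards float rounding of t
        tol = 1e-9 * max(1.0, abs(self.t0_ms) + 1000.0 * self.n_samples / self.srate)
        step = 1000.0 / self.srate
        if window.start_ms < self.t0_ms - tol or window.end_ms > t[-1] + step + tol:
            raise ValueError(
                f"window [{window.start_ms}, {window.end_ms}) ms exceeds epoch span "
                f"[{self.t0_ms}, {t[-1] + step}) ms"
            )
        inside = (t >= window.start_ms - tol) & (t < window.end_ms - tol)
        idx = np.nonzero(inside)[0]
        if idx.size == 0:
            raise ValueError(
                f"window [{window.start_ms}, {window.end_ms}) ms contains no samples "
                f"(epoch spans {t[0]:.1f}..{t[-1]:.1f} ms)"
            )
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):  # pragma: no cover
            raise AssertionError("window selection must be contiguous")
        return slice(int(idx[0]), int(idx[-1]) + 1)


def _match_channels(available: Sequence[str], requested: Sequence[str]) -> list[int]:
    lut = {name.upper(): i for i, name in enumerate(available)}
    out = []
    for name in requested:
        key = str(name).upper()
        if key not in lut:
            raise KeyError(
                f"unknown channel {name!r}; available: {', '.join(available)}"
            )
        out.append(lut[key])
    return out


def select(
    epochs: EpochSet,
    channels: Sequence[str] | None = None,
    window: WindowSpec | None = None,
    labels: Sequence[int] | None = None,
) -> EpochSet:
    """Restrict an EpochSet to given channels, time window and/or labels.

    Channel matching is case-insensitive on 10–20 names and the output
    channel order follows the request.  ``t0_ms`` of the result is the
    window start.  Raises on unknown channels and on empty selections.
    """
    data = epochs.data
    trial_labels = epochs.labels
    names = epochs.channel_names
    t0 = epochs.t0_ms

    if labels is not None:
        keep = np.isin(trial_labels, np.asarray(list(labels)))
        if not keep.any():
            raise ValueError(f"no trials with labels {list(labels)}")
        data = data[keep]
        trial_labels = trial_labels[keep]

    if channels is not None:
        idx = _match_channels(names, channels)
        if not idx:
            raise ValueError("empty channel selection")
        data = data[:, idx, :]
        names = tuple(names[i] for i in idx)

    if window is not None:
        sl = epochs.sample_slice(window)
        data = data[:, :, sl]
        t0 = float(window.start_ms)

    return EpochSet(data.copy(), trial_labels.copy(), epochs.srate, t0, names)


# ---------------------------------------------------------------------------
# On-disk epoch bundle: directory with metadata.json + data.bin (float32 LE,
# trial-major, then channel, then sample).  data.csv (one row per
# trial-channel pair, samples as columns) is accepted on read.
# ---------------------------------------------------------------------------

_META_KEYS = ("n_trials", "n_channels", "n_samples", "srate_hz", "t0_ms",
              "channel_names", "labels")


def save_epochs(epochs: EpochSet, path: str | os.PathLike) -> None:
    """Write an epoch bundle directory; overwrites files atomically."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_samples,
        "srate_hz": float(epochs.srate),
        "t0_ms": float(epochs.t0_ms),
        "channel_names": list(epochs.channel_names),
        "labels": [int(v) for v in epochs.labels],
    }
    payload = np.ascontiguousarray(epochs.data, dtype="<f4").tobytes()
    for fname, blob in (("metadata.json", json.dumps(meta, indent=1).encode()),
                        ("data.bin", payload)):
        fd, tmp = tempfile.mkstemp(dir=path, prefix=f".{fname}.")
        try:
            with os.fdopen(fd, "wb") as fh:
                fh.write(blob)
            os.replace(tmp, path / fname)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


def load_epochs(path: str | os.PathLike) -> EpochSet:
    """Read an epoch bundle written by :func:`save_epochs` (or the CSV form)."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.is_file():
        raise EpochFormatError(f"no metadata.json in {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise EpochFormatError(f"metadata.json is not valid JSON: {exc}") from exc
    for key in _META_KEYS:
        if key not in meta:
            raise EpochFormatError(f"metadata.json missing required field {key!r}")

    n_trials, n_channels, n_samples = (int(meta[k]) for k in
                                       ("n_trials", "n_channels", "n_samples"))
    if len(meta["channel_names"]) != n_channels:
        raise EpochFormatError(
            f"field 'channel_names' has {len(meta['channel_names'])} entries "
            f"but 'n_channels' is {n_channels}"
        )
    if len(meta["labels"]) != n_trials:
        raise EpochFormatError(
            f"field 'labels' has {len(meta['labels'])} entries but 'n_trials' is {n_trials}"
        )

    bin_path = path / "data.bin"
    csv_path = path / "data.csv"
    if bin_path.is_file():
        raw = np.fromfile(bin_path, dtype="<f4")
        expect = n_trials * n_channels * n_samples
        if raw.size != expect:
            raise EpochFormatError(
                f"data.bin holds {raw.size} float32 values; metadata implies {expect}"
            )
        data = raw.reshape(n_trials, n_channels, n_samples)
    elif csv_path.is_file():
        flat = np.loadtxt(csv_path, delimiter=",", ndmin=2, dtype=np.float64)
        if flat.shape != (n_trials * n_channels, n_samples):
            raise EpochFormatError(
                f"data.csv shape {flat.shape} does not match metadata "
                f"({n_trials * n_channels} rows x {n_samples} columns expected)"
            )
        data = flat.reshape(n_trials, n_channels, n_samples)
    else:
        raise EpochFormatError(f"no data.bin or data.csv in {path}")

    return EpochSet(
        data=data,
        labels=np.asarray(meta["labels"], dtype=np.int64),
        srate=float(meta["srate_hz"]),
        t0_ms=float(meta["t0_ms"]),
        channel_names=tuple(meta["channel_names"]),
    )
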