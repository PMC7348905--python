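"""Signal conditioning: downsampling, zero-phase filtering, band
decomposition and baseline correction.

Filters are 4th-order Butterworth applied forward-backward (zero net phase,
effective order 8).  Epochs are short relative to delta-band impulse
responses, so every filter call pads by signal reflection (at least 0.5 s)
before filtering and trims afterwards.  A band whose lower edge is 0 Hz is a
pure low-pass; DC is removed later by baseline correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import BandSpec, EpochSet, WindowSpec

__all__ = [
    "FilterSpec",
    "design_filter",
    "zero_phase_filter",
    "downsample",
    "baseline_correct",
    "band_decompose",
]

#: Minimum reflection padding, seconds.
MIN_PAD_S = 0.5


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth filter: ``lowpass`` (one edge) or ``bandpass``."""

    kind: str
    edges_hz: tuple[float, ...]
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise ValueError(f"kind must be 'lowpass' or 'bandpass', got {self.kind!r}")
        n_expected = 1 if self.kind == "lowpass" else 2
        if len(self.edges_hz) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} edge(s), got {self.edges_hz}")
        if self.order < 2:
            raise ValueError(f"order must be >= 2, got {self.order}")
        if not self.zero_phase:
            raise ValueError("only zero-phase filtering is supported")

    @classmethod
    def from_band(cls, band: BandSpec, order: int = 4) -> "FilterSpec":
        if band.lo_hz == 0:
            return cls("lowpass", (band.hi_hz,), order)
        return cls("bandpass", (band.lo_hz, band.hi_hz), order)


def design_filter(spec: FilterSpec, srate: float) -> np.ndarray:
    """Second-order sections for a FilterSpec at a given sampling rate."""
    nyq = srate / 2.0
    for e in spec.edges_hz:
        if not 0 < e < nyq:
            raise ValueError(
                f"filter edge {e} Hz outside (0, {nyq}) Hz for srate {srate} Hz"
            )
    wn = spec.edges_hz[0] if spec.kind == "lowpass" else list(spec.edges_hz)
    sos = signal.butter(spec.order, wn, btype=spec.kind, fs=srate, output="sos")
    if not np.all(np.isfinite(sos)):
        raise ValueError(
            f"unstable filter design at order {spec.order}; try a lower order"
        )
    return sos


def _filtfilt_padded(sos: np.ndarray, data: np.ndarray, srate: float) -> np.ndarray:
    padlen = max(int(MIN_PAD_S * srate), 3 * (sos.shape[0] * 2 + 1))
    padlen = min(padlen, data.shape[-1] - 1)
    return signal.sosfiltfilt(sos, data, axis=-1, padtype="even", padlen=padlen)


def zero_phase_filter(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    """Forward-backward filter every trial and channel; shape is preserved."""
    sos = design_filter(spec, epochs.srate)
    return epochs.with_data(_filtfilt_padded(sos, epochs.data, epochs.srate))


def downsample(epochs: EpochSet, target_hz: float, *,
               allow_rational: bool = False) -> EpochSet:
    """Anti-aliased decimation to ``target_hz``.

    Integer decimation uses a zero-phase FIR anti-alias filter.  Non-integer
    ratios require ``allow_rational=True`` (polyphase resampling).
    ``t0_ms`` is preserved: the first output sample is the first input sample.
    """
    if target_hz > epochs.srate:
        raise ValueError(f"cannot downsample {epochs.srate} Hz to {target_hz} Hz")
    if target_hz == epochs.srate:
        return epochs.copy()
    ratio = epochs.srate / target_hz
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        data = signal.decimate(epochs.data, q, ftype="fir", axis=-1, zero_phase=True)
    elif allow_rational:
        from fractions import Fraction

        frac = Fraction(target_hz / epochs.srate).limit_denominator(1000)
        data = signal.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    else:
        raise ValueError(
            f"{epochs.srate} -> {target_hz} Hz is not integer decimation; "
            "pass allow_rational=True for polyphase resampling"
        )
    return epochs.with_data(np.ascontiguousarray(data), srate=float(target_hz))


def baseline_correct(epochs: EpochSet, window: WindowSpec) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    sl = epochs.sample_slice(window)
    baseline = epochs.data[:, :, sl].mean(axis=-1, keepdims=True)
    return epochs.with_data(epochs.data - baseline)


def band_decompose(epochs: EpochSet, bands: list[BandSpec]) -> dict[str, EpochSet]:
    """One zero-phase band-filtered copy per band, keyed by band name."""
    out: dict[str, EpochSet] = {}
    for band in bands:
        try:
            out[band.name] = zero_phase_filter(epochs, FilterSpec.from_band(band))
        except ValueError as exc:
            raise ValueError(f"band {band.name!r}: {exc}") from exc
    return out
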