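"""Descriptive feature metrics: grand averages, window amplitude,
fractional-area latency, trial-wise SNR, Fisher discriminative ratio, and
event-related spectral perturbation (ERSP).

SNR follows the energy-ratio definition

    SNR = 10 log10( mean(AMP)^2 / (mean(AMP^2) - mean(AMP)^2) )   [dB]

with population (1/N) moments over per-trial window amplitudes, and the
Fisher discriminative ratio (FDR — discriminability, not false discovery)

    FDR = (m1 - m2)^2 / (S1^2 + S2^2)

over two groups of samples.  ERSP is Morlet-wavelet power, trial-averaged,
divisively baseline-normalized per frequency and expressed in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochSet, WindowSpec

__all__ = [
    "ErspGrid",
    "grand_average",
    "window_amplitude",
    "fractional_area_latency",
    "snr_db",
    "fdr_score",
    "ersp",
]


def grand_average(epochs: EpochSet, label: int) -> np.ndarray:
    """Mean waveform over all trials of one class: ``[n_channels, n_samples]``."""
    mask = epochs.labels == label
    if not mask.any():
        raise ValueError(f"no trials with label {label}")
    return epochs.data[mask].mean(axis=0)


def window_amplitude(waveform: np.ndarray, window: WindowSpec, *,
                     t0_ms: float, srate: float) -> np.ndarray:
    """Mean amplitude within a half-open window; per channel if 2-D input."""
    w = np.atleast_2d(np.asarray(waveform, dtype=np.float64))
    dummy = EpochSet(w[None], np.zeros(1, dtype=int), srate, t0_ms,
                     tuple(f"ch{i}" for i in range(w.shape[0])))
    sl = dummy.sample_slice(window)
    out = w[:, sl].mean(axis=-1)
    return out[0] if np.ndim(waveform) == 1 else out


def fractional_area_latency(waveform: np.ndarray, window: WindowSpec,
                            fraction: float = 0.5, *, t0_ms: float,
                            srate: float, rectify: bool = True) -> float:
    """Time before which ``fraction`` of the component area lies.

    The area is the rectified (absolute) waveform integrated over the
    window by default, which handles biphasic components; set
    ``rectify=False`` for signed-positive area.  The crossing time is
    linearly interpolated between samples.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    w = np.asarray(waveform, dtype=np.float64)
    if w.ndim != 1:
        raise ValueError("fractional_area_latency expects a single-channel waveform")
    dummy = EpochSet(w[None, None], np.zeros(1, dtype=int), srate, t0_ms, ("ch0",))
    sl = dummy.sample_slice(window)
    seg = np.abs(w[sl]) if rectify else np.clip(w[sl], 0.0, None)
    times = t0_ms + 1000.0 * np.arange(len(w))[sl] / srate
    # trapezoidal cumulative area on the sample grid, extended to window edges
    dt = 1000.0 / srate
    edges = np.concatenate(([window.start_ms], times + dt / 2.0))
    edges[-1] = min(edges[-1], window.end_ms)
    cum = np.concatenate(([0.0], np.cumsum(seg * np.diff(edges))))
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero total area in window; latency undefined")
    target = fraction * total
    i = int(np.searchsorted(cum, target))
    i = min(max(i, 1), len(cum) - 1)
    # interpolate inside the i-th strip [edges[i-1], edges[i])
    frac_in = (target - cum[i - 1]) / max(cum[i] - cum[i - 1], 1e-300)
    return float(edges[i - 1] + frac_in * (edges[i] - edges[i - 1]))


def snr_db(amplitudes: np.ndarray) -> float:
    """Energy SNR in dB of per-trial amplitudes, population moments."""
    a = np.asarray(amplitudes, dtype=np.float64)
    if a.size < 2:
        raise ValueError("need at least 2 trials for SNR")
    mean = a.mean()
    var = np.mean(a**2) - mean**2
    if var <= 0:
        raise ValueError("degenerate: identical trials (zero variance)")
    if mean == 0:
        raise ValueError("degenerate: zero signal (zero mean amplitude)")
    return float(10.0 * np.log10(mean**2 / var))


def fdr_score(samples1: np.ndarray, samples2: np.ndarray, *,
              ddof: int = 0) -> float:
    """Fisher discriminative ratio between two groups of values.

    ``ddof=0`` (population standard deviations) matches the SNR
    convention; pass ``ddof=1`` for the sample convention.
    """
    a = np.asarray(samples1, dtype=np.float64)
    b = np.asarray(samples2, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    denom = a.var(ddof=ddof) + b.var(ddof=ddof)
    if denom == 0:
        raise ValueError("both groups have zero variance; FDR undefined")
    return float((a.mean() - b.mean()) ** 2 / denom)


@dataclass
class ErspGrid:
    """Baseline-normalized time-frequency power, in dB."""

    power_db: np.ndarray          # [n_freqs, n_samples] (or [n_ch, n_f, n_s])
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    baseline: WindowSpec

    def band_mean(self, lo_hz: float, hi_hz: float,
                  window: WindowSpec) -> float:
        """Mean dB over a frequency band and time window (last two axes)."""
        fmask = (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)
        tmask = (self.times_ms >= window.start_ms) & (self.times_ms < window.end_ms)
        if not fmask.any() or not tmask.any():
            raise ValueError("empty band/window for ERSP summary")
        return float(self.power_db[..., fmask, :][..., tmask].mean())


def ersp(epochs: EpochSet, freqs: np.ndarray, baseline: WindowSpec, *,
         n_cycles: float = 7.0, average_channels: bool = True,
         labels: list[int] | None = None) -> ErspGrid:
    """Morlet-wavelet ERSP relative to a pre-stimulus baseline.

    Power is averaged over trials (optionally restricted to ``labels``),
    divided by the mean baseline power per frequency, and expressed as
    ``10 log10`` dB, so baseline columns average ~0 dB by construction.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any(freqs >= epochs.srate / 2):
        raise ValueError("requested frequencies must lie below Nyquist")
    span_s = epochs.n_samples / epochs.srate
    support_s = n_cycles / freqs.min()
    if support_s > span_s:
        raise ValueError(
            f"lowest frequency {freqs.min()} Hz needs {support_s:.2f} s of data "
            f"({n_cycles} cycles) but the epoch has only {span_s:.2f} s"
        )
    data = epochs.data
    if labels is not None:
        mask = np.isin(epochs.labels, labels)
        if not mask.any():
            raise ValueError(f"no trials with labels {labels}")
        data = data[mask]

    power = tfr_array_morlet(data, sfreq=epochs.srate, freqs=freqs,
                             n_cycles=n_cycles, output="power", zero_mean=True)
    mean_power = power.mean(axis=0)  # [n_ch, n_freqs, n_samples]
    if average_channels:
        mean_power = mean_power.mean(axis=0)

    sl = epochs.sample_slice(baseline)
    base = mean_power[..., sl].mean(axis=-1, keepdims=True)
    power_db = 10.0 * np.log10(mean_power / base)
    return ErspGrid(power_db=power_db, freqs_hz=freqs,
                    times_ms=epochs.times_ms.copy(), baseline=baseline)
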