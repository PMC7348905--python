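"""Synthetic two-class (plus optional no-timing) epoched EEG.

The generator emulates the signal structure that timing prediction induces
in centro-parietal EEG, so that every downstream stage — filtering, ERP
metrics, DCPM, CSP, and decision fusion — is testable without a real
recording:

* a stimulus-locked N1 after each flash (first flash at 0 ms, second at
  900 ms), identical across conditions;
* a contingent negative variation (CNV): a slow negative drift starting
  ~200 ms after the first flash;
* a class-dependent, smooth positive-going deflection beginning ~200 ms
  after the predicted moment (600 ms into the epoch for T400, 800 ms for
  T600; absent for NT), which terminates the drift;
* class-dependent 20-60 Hz power suppression: it starts earlier (about
  100 ms for T400, 220 ms for T600, 300 ms for NT) and is deeper when the
  predicted moment is earlier, implemented as a multiplicative amplitude
  envelope ramping from 1 to (1 - depth) on band-limited noise, so a depth
  d reads as 20*log10(1-d) dB in the ERSP;
* pink (1/f^a) plus white background noise, independent across channels.

Evoked components and the suppression depth are concentrated on central
channels through a per-channel gain map.  Single-trial variability —
multiplicative amplitude jitter, deflection-latency jitter, and
suppression-onset jitter — keeps single-trial decodability in the realistic
mid-range rather than at ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal

from .core import CENTRAL_18, LABEL_NT, LABEL_T400, LABEL_T600, BandSpec, EpochSet

__all__ = ["SimConfig", "make_erp_kernel", "simulate_subject", "simulate_cohort",
           "LABEL_OF_CLASS"]

LABEL_OF_CLASS = {"T400": LABEL_T400, "T600": LABEL_T600, "NT": LABEL_NT}

DEFAULT_CHANNELS = CENTRAL_18 + ("FP1", "FP2", "OZ")


def _default_profile() -> dict[str, float]:
    """Per-channel effect gain, strongest at the centro-parietal midline.

    The gradient across the central strip matters: a spatially uniform
    power change is invisible to CSP after trace normalization, whereas
    real timing-prediction effects peak near the midline and fall off
    laterally.
    """
    prof = {}
    prof.update({name: 1.0 for name in ("CZ", "CPZ", "C1", "C2", "CP1", "CP2")})
    prof.update({name: 0.7 for name in ("C3", "C4", "CP3", "CP4",
                                        "C5", "C6", "CP5", "CP6")})
    prof.update({name: 0.4 for name in ("T7", "T8", "TP7", "TP8")})
    prof.update({"FP1": 0.25, "FP2": 0.25, "OZ": 0.25})
    return prof


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic subject; defaults mirror the study design.

    Amplitudes are in microvolts, times in milliseconds.  ``noise_scale``
    multiplies every noise component jointly.
    """

    n_trials_per_class: int = 40
    srate: float = 200.0
    epoch_span_ms: tuple[float, float] = (-500.0, 2500.0)
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    classes: tuple[str, ...] = ("T400", "T600")
    predicted_moment_ms: Mapping[str, float] = field(
        default_factory=lambda: {"T400": 400.0, "T600": 600.0})
    # slow-wave / ERP morphology
    erp_amp_uv: float = 4.5            # positive-going deflection amplitude
    erp_offset_ms: float = 200.0       # deflection onset after predicted moment
    erp_rise_ms: float = 150.0
    erp_hold_ms: float = 200.0
    erp_decay_ms: float = 600.0
    cnv_onset_ms: float = 200.0
    cnv_slope_uv_s: float = -6.0
    cnv_plateau_ms: float = 1000.0     # drift stops deepening here
    n1_amp_uv: float = -4.0
    n1_latency_ms: float = 160.0
    n1_width_ms: float = 25.0
    second_flash_ms: float = 900.0
    # high-frequency suppression
    supp_band: BandSpec = BandSpec("high", 20.0, 60.0)
    supp_depth: float = 0.5
    supp_onset_ms: Mapping[str, float] = field(
        default_factory=lambda: {"T400": 100.0, "T600": 220.0, "NT": 300.0})
    #: per-class multiplier on supp_depth: besides starting earlier, the
    #: suppression is deeper when the predicted moment is earlier
    supp_depth_scale: Mapping[str, float] = field(
        default_factory=lambda: {"T400": 1.0, "T600": 0.7, "NT": 0.5})
    supp_ramp_ms: float = 100.0
    # noise model
    noise_scale: float = 1.0
    pink_rms_uv: float = 4.0
    pink_exponent: float = 1.7         # PSD slope of the 1/f^a background
    white_rms_uv: float = 1.0
    band_rms_uv: float = 5.0
    # single-trial variability
    erp_gain_jitter: float = 0.4       # sigma of lognormal amplitude factor
    erp_latency_jitter_ms: float = 60.0
    supp_onset_jitter_ms: float = 40.0
    # cohort-level variability (used by simulate_cohort)
    subject_jitter: float = 0.25
    spatial_profile: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be positive")
        if not 0 <= self.supp_depth < 1:
            raise ValueError(f"supp_depth must be in [0, 1), got {self.supp_depth}")
        if not self.noise_scale > 0:
            raise ValueError("noise_scale must be positive")
        for cls in self.classes:
            if cls not in LABEL_OF_CLASS:
                raise ValueError(f"unknown class {cls!r}; expected T400/T600/NT")

    @property
    def n_samples(self) -> int:
        lo, hi = self.epoch_span_ms
        return int(round((hi - lo) * self.srate / 1000.0))

    @property
    def times_ms(self) -> np.ndarray:
        return self.epoch_span_ms[0] + 1000.0 * np.arange(self.n_samples) / self.srate

    def profile_vector(self) -> np.ndarray:
        prof = dict(_default_profile())
        if self.spatial_profile is not None:
            prof.update({k.upper(): float(v) for k, v in self.spatial_profile.items()})
        return np.array([prof.get(name.upper(), 0.3) for name in self.channels])


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def _deflection(t: np.ndarray, onset: float, cfg: SimConfig) -> np.ndarray:
    """Smooth positive wave: half-cosine rise, plateau, exponential decay."""
    u = (t - onset) / cfg.erp_rise_ms
    rise = np.where(u <= 0, 0.0, np.where(u >= 1, 1.0, 0.5 * (1 - np.cos(np.pi * np.clip(u, 0, 1)))))
    t_dec = t - (onset + cfg.erp_rise_ms + cfg.erp_hold_ms)
    decay = np.exp(-np.maximum(t_dec, 0.0) / cfg.erp_decay_ms)
    return rise * decay


def make_erp_kernel(label: str, cfg: SimConfig, *,
                    amp_factor: float = 1.0,
                    latency_shift_ms: float = 0.0) -> np.ndarray:
    """Deterministic evoked waveform for one condition, in microvolts.

    The CNV drift and the flash-locked N1s are common to all conditions;
    only the positive-going deflection (onset = predicted moment +
    ``erp_offset_ms``) is condition-specific, so a zero deflection
    amplitude makes all kernels identical.
    """
    if label not in LABEL_OF_CLASS:
        raise ValueError(f"unknown label {label!r}; expected T400/T600/NT")
    t = cfg.times_ms
    k = cfg.n1_amp_uv * _gauss(t, cfg.n1_latency_ms, cfg.n1_width_ms)
    k = k + cfg.n1_amp_uv * _gauss(t, cfg.second_flash_ms + cfg.n1_latency_ms,
                                   cfg.n1_width_ms)
    drift_ms = np.clip(t - cfg.cnv_onset_ms, 0.0, cfg.cnv_plateau_ms - cfg.cnv_onset_ms)
    k = k + cfg.cnv_slope_uv_s * drift_ms / 1000.0
    if label != "NT":
        onset = cfg.predicted_moment_ms[label] + cfg.erp_offset_ms + latency_shift_ms
        k = k + cfg.erp_amp_uv * amp_factor * _deflection(t, onset, cfg)
    return k


def _band_filter_sos(cfg: SimConfig) -> tuple[np.ndarray, float]:
    """SOS for the suppression band plus the filter's white-noise power gain."""
    sos = signal.butter(4, (cfg.supp_band.lo_hz, cfg.supp_band.hi_hz),
                        btype="bandpass", fs=cfg.srate, output="sos")
    w, h = signal.sosfreqz(sos, worN=2048)
    gain2 = float(np.mean(np.abs(h) ** 2))  # E[var] of filtered unit white noise
    return sos, gain2


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                srate: float, exponent: float = 1.7) -> np.ndarray:
    """Unit-variance 1/f^a noise along the last axis (FFT spectral shaping).

    ``exponent`` is the power-spectral-density slope; EEG background falls
    roughly as 1/f^1.5..2 over 1-100 Hz.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    scale = np.empty_like(freqs)
    scale[0] = 0.0  # no DC
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[-1] = 0.0  # drop the Nyquist bin (cannot carry a random phase)
    spec = (rng.standard_normal(shape[:-1] + (freqs.size,))
            + 1j * rng.standard_normal(shape[:-1] + (freqs.size,))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    # E[x^2] = (4 / n^2) * sum_k scale_k^2 for the interior rfft bins
    x /= 2.0 * np.sqrt(np.sum(scale**2)) / n
    return x


def _supp_envelope(t: np.ndarray, onset: float, depth: float,
                   ramp_ms: float) -> np.ndarray:
    """Amplitude gain 1 -> (1 - depth) over ``ramp_ms``.

    Band power is therefore reduced by (1 - depth)^2, i.e. a depth of 0.5
    reads as 20*log10(0.5) = -6.02 dB in the ERSP.
    """
    frac = np.clip((t - onset) / ramp_ms, 0.0, 1.0)
    return 1.0 - depth * frac


def simulate_subject(cfg: SimConfig) -> EpochSet:
    """Generate one subject's epoched EEG; identical config => identical data."""
    rng = np.random.default_rng(cfg.seed)
    t = cfg.times_ms
    n_ch = len(cfg.channels)
    n_s = cfg.n_samples
    profile = cfg.profile_vector()
    sos, band_gain2 = _band_filter_sos(cfg)
    band_scale = cfg.band_rms_uv / np.sqrt(band_gain2)

    trials, labels = [], []
    for cls in cfg.classes:
        depth_ch = np.clip(
            cfg.supp_depth * cfg.supp_depth_scale.get(cls, 1.0)
            * np.clip(profile, 0.0, 1.0), 0.0, 0.99)
        for _ in range(cfg.n_trials_per_class):
            amp_factor = float(np.exp(rng.normal(0.0, cfg.erp_gain_jitter))) \
                if cfg.erp_gain_jitter > 0 else 1.0
            lat_shift = float(rng.normal(0.0, cfg.erp_latency_jitter_ms)) \
                if cfg.erp_latency_jitter_ms > 0 else 0.0
            kernel = make_erp_kernel(cls, cfg, amp_factor=amp_factor,
                                     latency_shift_ms=lat_shift)

            pink = _pink_noise(rng, (n_ch, n_s), cfg.srate,
                               cfg.pink_exponent) * cfg.pink_rms_uv
            white = rng.standard_normal((n_ch, n_s)) * cfg.white_rms_uv
            # lead-in lets the causal band filter reach steady state
            pad = int(cfg.srate)
            band = signal.sosfilt(sos, rng.standard_normal((n_ch, n_s + pad)),
                                  axis=-1)[:, pad:] * band_scale
            onset = cfg.supp_onset_ms[cls] + (
                float(rng.normal(0.0, cfg.supp_onset_jitter_ms))
                if cfg.supp_onset_jitter_ms > 0 else 0.0)
            env = np.stack([_supp_envelope(t, onset, d, cfg.supp_ramp_ms)
                            for d in depth_ch])
            trial = (profile[:, None] * kernel[None, :]
                     + cfg.noise_scale * (pink + white + band * env))
            trials.append(trial)
            labels.append(LABEL_OF_CLASS[cls])

    return EpochSet(
        data=np.stack(trials),
        labels=np.asarray(labels, dtype=np.int64),
        srate=cfg.srate,
        t0_ms=cfg.epoch_span_ms[0],
        channel_names=cfg.channels,
    )


def simulate_cohort(cfg: SimConfig, n_subjects: int, base_seed: int) -> list[EpochSet]:
    """Deterministic cohort: per-subject seeds spawned from ``base_seed``.

    With ``cfg.subject_jitter > 0`` subjects additionally differ in effect
    size (lognormal factor on the deflection amplitude and suppression
    depth, the latter clipped below 0.95).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * n_subjects)
    out = []
    for i in range(n_subjects):
        sub_cfg = replace(cfg, seed=int(seeds[2 * i] % (2**31)))
        if cfg.subject_jitter > 0:
            jrng = np.random.default_rng(int(seeds[2 * i + 1] % (2**31)))
            f_amp = float(np.exp(jrng.normal(0.0, cfg.subject_jitter)))
            f_dep = float(np.exp(jrng.normal(0.0, cfg.subject_jitter)))
            sub_cfg = replace(
                sub_cfg,
                erp_amp_uv=cfg.erp_amp_uv * f_amp,
                supp_depth=min(cfg.supp_depth * f_dep, 0.95),
            )
        out.append(simulate_subject(sub_cfg))
    return out
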