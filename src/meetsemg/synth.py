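"""Synthetic sEMG acquisition emulating a blocked gesture protocol.

Each subject performs ``n_classes`` gestures in sequence; every gesture is
held for ``gesture_duration_s`` seconds of repeated effort bursts spaced
1-2 s apart.  A burst is class-signature band-limited Gaussian noise under a
raised-cosine on/off envelope; baseline wander, 50 Hz powerline pickup and
wideband sensor noise are added on top.  The generator is fully seeded:
identical configuration and seed give byte-identical signals.

This is a statistical surrogate of surface EMG, not a motor-unit
simulation: class separability is controlled through per-class amplitude
and spectral signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .recording import RawRecording

__all__ = ["ClassSignature", "SynthConfig", "generate_recording", "generate_dataset"]


@dataclass(frozen=True)
class ClassSignature:
    """Spectral/amplitude fingerprint of one gesture class.

    amplitude    RMS of the active burst, in mV.
    center_hz    spectral center of the burst energy (must lie in the
                 10-500 Hz EMG band and below Nyquist).
    bandwidth_hz width of the burst band around the center.
    """

    amplitude: float
    center_hz: float
    bandwidth_hz: float


def default_signatures(n_classes: int) -> tuple[ClassSignature, ...]:
    """Evenly spread spectral centers over 80-400 Hz with graded amplitudes."""
    if n_classes < 1:
        raise ConfigurationError("n_classes must be >= 1")
    centers = np.linspace(80.0, 400.0, n_classes) if n_classes > 1 else np.array([200.0])
    amps = np.linspace(0.8, 1.3, n_classes) if n_classes > 1 else np.array([1.0])
    return tuple(
        ClassSignature(amplitude=float(a), center_hz=float(c), bandwidth_hz=60.0)
        for a, c in zip(amps, centers)
    )


@dataclass
class SynthConfig:
    """Parameters of the emulated acquisition protocol.

    Defaults mirror a two-channel, 2000 Hz, six-gesture protocol with 40 s
    per gesture and effort repetitions every 1-2 s, giving 480,000 samples
    per subject.
    """

    n_subjects: int = 4
    n_classes: int = 6
    n_channels: int = 2
    sample_rate: int = 2000
    gesture_duration_s: float = 40.0
    #: uniform range (s) of the repetition cycle length between burst onsets
    burst_period_s: tuple[float, float] = (1.0, 2.0)
    #: fraction of each repetition cycle during which the muscle is active
    burst_duty: float = 0.7
    #: residual activation between repetitions, as a fraction of the burst
    #: amplitude — the task is held continuously, so the muscle relaxes only
    #: partially between efforts
    rest_floor: float = 0.15
    #: raised-cosine ramp length (s) at each burst edge
    ramp_s: float = 0.05
    class_signatures: tuple[ClassSignature, ...] | None = None
    powerline_amplitude: float = 0.10
    powerline_hz: float = 50.0
    drift_amplitude: float = 0.05
    drift_hz: float = 0.5
    noise_sd: float = 0.02
    #: if True, inter-burst rest inside a gesture block keeps the block's
    #: class label (the whole block is windowed); if False rest is labelled 0
    label_rest_as_block: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ConfigurationError("n_subjects and n_channels must be >= 1")
        if self.gesture_duration_s <= 0 or self.sample_rate <= 0:
            raise ConfigurationError("durations and sample_rate must be positive")
        lo, hi = self.burst_period_s
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid burst_period_s range {self.burst_period_s}")
        if not 0 < self.burst_duty <= 1:
            raise ConfigurationError("burst_duty must be in (0, 1]")
        if not 0 <= self.rest_floor < 1:
            raise ConfigurationError("rest_floor must be in [0, 1)")
        if self.class_signatures is None:
            self.class_signatures = default_signatures(self.n_classes)
        if len(self.class_signatures) != self.n_classes:
            raise ConfigurationError(
                f"{len(self.class_signatures)} signatures for {self.n_classes} classes"
            )
        nyq = self.sample_rate / 2
        for i, sig in enumerate(self.class_signatures):
            if not (0 < sig.center_hz + sig.bandwidth_hz / 2 < nyq):
                raise ConfigurationError(
                    f"class {i + 1} spectral band exceeds Nyquist ({nyq} Hz)"
                )
        if self.drift_hz >= 5.0:
            raise ConfigurationError("drift_hz must stay below 5 Hz")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_signatures"] = [asdict(s) for s in self.class_signatures]
        return d

    @property
    def samples_per_block(self) -> int:
        return int(round(self.gesture_duration_s * self.sample_rate))

    @property
    def samples_per_subject(self) -> int:
        return self.n_classes * self.samples_per_block


def _signature_filter(sig: ClassSignature, fs: int) -> tuple[np.ndarray, np.ndarray]:
    # A single-peaked resonator (peak exactly at center_hz, -3 dB width
    # bandwidth_hz) rather than a flat-top bandpass: real sEMG spectra are
    # unimodal, and a unique spectral maximum keeps class signatures
    # identifiable from an averaged periodogram.
    q = sig.center_hz / sig.bandwidth_hz
    return sps.iirpeak(sig.center_hz, q, fs=fs)


def _burst_envelope(n: int, fs: int, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit on/off envelope of repeated bursts with raised-cosine edges."""
    env = np.zeros(n)
    ramp_n = max(int(round(cfg.ramp_s * fs)), 1)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    pos = 0
    while pos < n:
        cycle = int(round(rng.uniform(*cfg.burst_period_s) * fs))
        burst = int(round(cfg.burst_duty * cycle))
        end = min(pos + burst, n)
        env[pos:end] = 1.0
        m = min(ramp_n, end - pos)
        env[pos : pos + m] = np.minimum(env[pos : pos + m], ramp[:m])
        env[end - m : end] = np.minimum(env[end - m : end], ramp[:m][::-1])
        pos += cycle
    return env


def generate_recording(config: SynthConfig, subject_index: int) -> RawRecording:
    """Generate one subject's contiguous recording.

    The recording has ``n_classes`` consecutive gesture blocks of
    ``gesture_duration_s`` each; class codes 1..N label block membership.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigurationError(
            f"subject_index {subject_index} outside 0..{config.n_subjects - 1}"
        )
    fs = config.sample_rate
    block_n = config.samples_per_block
    total_n = config.samples_per_subject
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))

    signal = np.zeros((config.n_channels, total_n))
    labels = np.zeros(total_n, dtype=np.int64)
    t_block = np.arange(block_n) / fs

    for c, sig in enumerate(config.class_signatures):
        sl = slice(c * block_n, (c + 1) * block_n)
        env = _burst_envelope(block_n, fs, config, rng)
        # continuous task: partial relaxation between repetitions
        amp_env = config.rest_floor + (1.0 - config.rest_floor) * env
        if sig.amplitude > 0:
            b, a = _signature_filter(sig, fs)
        for ch in range(config.n_channels):
            burst = np.zeros(block_n)
            if sig.amplitude > 0:
                white = rng.standard_normal(block_n)
                burst = sps.lfilter(b, a, white)
                rms = np.sqrt(np.mean(burst**2))
                if rms > 0:
                    burst *= sig.amplitude / rms
            drift = config.drift_amplitude * np.sin(
                2 * np.pi * config.drift_hz * t_block + rng.uniform(0, 2 * np.pi)
            )
            powerline = config.powerline_amplitude * np.sin(
                2 * np.pi * config.powerline_hz * t_block + rng.uniform(0, 2 * np.pi)
            )
            white_noise = (
                config.noise_sd * rng.standard_normal(block_n) if config.noise_sd > 0 else 0.0
            )
            signal[ch, sl] = amp_env * burst + drift + powerline + white_noise
        if config.label_rest_as_block:
            labels[sl] = c + 1
        else:
            blab = np.where(env > 0, c + 1, 0)
            labels[sl] = blab
    return RawRecording(
        subject_id=f"S{subject_index + 1:02d}", sample_rate=fs, signal=signal, labels=labels
    )


def generate_dataset(config: SynthConfig) -> list[RawRecording]:
    """Generate all subjects of the configured cohort."""
    return [generate_recording(config, i) for i in range(config.n_subjects)]
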