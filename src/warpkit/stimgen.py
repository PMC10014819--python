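"""Vowel-continuum synthesis, speech-shaped noise, and SNR mixing.

The stimulus set is a 7-step /u/-/a/ vowel continuum in which only the first
formant (F1) varies, in equal steps between 430 and 730 Hz; fundamental (F0),
second and third formants are shared by all tokens (100, 1090, 2350 Hz).
Tokens are synthesized with a cascade (Klatt-style) source-filter model:
an impulse-train glottal source at F0 passed through second-order resonators
in series, one per formant.  A speech-shaped masker is generated by filtering
white noise to the long-term power spectrum (LTPS) of the vowel set, and
speech and masker are combined at an exact target signal-to-noise ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "ContinuumSpec",
    "Waveform",
    "MixResult",
    "token_f1",
    "synthesize_vowel",
    "synthesize_continuum",
    "rms_normalize",
    "build_ltps_noise",
    "vowel_set_psd",
    "mix_at_snr",
    "measure_snr",
    "write_continuum",
    "read_wav",
]

# Klatt-style default formant bandwidths (Hz) for B1..B3; not part of the
# continuum parameterization — they shape timbre, not the F1 gradient.
DEFAULT_BANDWIDTHS = (60.0, 90.0, 150.0)


@dataclass(frozen=True)
class ContinuumSpec:
    """Acoustic parameterization of the /u/-/a/ F1 continuum.

    F1 of token ``k`` (1-based) is ``f1_start + (k-1)*(f1_end-f1_start)/(n_steps-1)``;
    all other parameters are shared across tokens.
    """

    n_steps: int = 7
    f1_start: float = 430.0
    f1_end: float = 730.0
    f0: float = 100.0
    f2: float = 1090.0
    f3: float = 2350.0
    duration_ms: float = 100.0
    ramp_ms: float = 10.0
    sample_rate: int = 48828
    rms_target: float = 0.1

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not self.f1_start < self.f1_end:
            raise ValueError("f1_start must be below f1_end")
        if 2 * self.ramp_ms > self.duration_ms:
            raise ValueError("onset+offset ramps exceed token duration")
        if not 0 < self.rms_target <= 1:
            raise ValueError("rms_target must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sample_rate / 1000.0))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ContinuumSpec":
        return cls(**json.loads(text))


@dataclass
class Waveform:
    """A mono audio buffer with its sample rate; amplitudes nominally in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform is mono: samples must be 1-D")

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def token_f1(spec: ContinuumSpec, token_index: int) -> float:
    """F1 target (Hz) of a 1-based continuum token: linear interpolation
    over exactly equidistant steps."""
    if not 1 <= token_index <= spec.n_steps:
        raise IndexError(
            f"token_index {token_index} outside 1..{spec.n_steps}"
        )
    step = (spec.f1_end - spec.f1_start) / (spec.n_steps - 1)
    return spec.f1_start + (token_index - 1) * step


def rms_normalize(w: Waveform, target: float) -> Waveform:
    """Scale a waveform to an exact target RMS. Idempotent."""
    r = w.rms
    if r == 0:
        raise ValueError("cannot RMS-normalize a silent waveform")
    return Waveform(w.samples * (target / r), w.sample_rate)


def _resonator_coeffs(f: float, bw: float, fs: float):
    # Klatt second-order resonator: y[n] = A x[n] + B y[n-1] + C y[n-2]
    T = 1.0 / fs
    C = -np.exp(-2.0 * np.pi * bw * T)
    B = 2.0 * np.exp(-np.pi * bw * T) * np.cos(2.0 * np.pi * f * T)
    A = 1.0 - B - C
    return A, B, C


def _impulse_train(f0: float, n: int, fs: float) -> np.ndarray:
    src = np.zeros(n)
    period = fs / f0
    k = 0
    while True:
        i = int(round(k * period))
        if i >= n:
            break
        src[i] = 1.0
        k += 1
    return src


def synthesize_vowel(spec: ContinuumSpec, token_index: int) -> Waveform:
    """Synthesize one continuum token with the cascade formant model.

    The glottal source is an impulse train at F0; three second-order
    resonators in series impose F1 (token-specific), F2 and F3.  Raised-cosine
    on/off ramps of ``ramp_ms`` suppress spectral splatter, and the result is
    RMS-normalized to ``spec.rms_target``.
    """
    f1 = token_f1(spec, token_index)  # validates the index
    fs = float(spec.sample_rate)
    n = spec.n_samples

    x = _impulse_train(spec.f0, n, fs)
    for f, bw in zip((f1, spec.f2, spec.f3), DEFAULT_BANDWIDTHS):
        A, B, C = _resonator_coeffs(f, bw, fs)
        x = signal.lfilter([A], [1.0, -B, -C], x)

    n_ramp = int(round(spec.ramp_ms * fs / 1000.0))
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]

    return rms_normalize(Waveform(x, spec.sample_rate), spec.rms_target)


def synthesize_continuum(spec: ContinuumSpec) -> list[Waveform]:
    """All ``n_steps`` tokens, in order (token 1 = /u/ endpoint, lowest F1)."""
    return [synthesize_vowel(spec, k) for k in range(1, spec.n_steps + 1)]


def vowel_set_psd(vowels: list[Waveform], nperseg: int = 4096):
    """Welch PSD (one-sided) of the concatenated vowel set."""
    if not vowels:
        raise ValueError("vowel list is empty")
    rates = {w.sample_rate for w in vowels}
    if len(rates) > 1:
        raise ValueError(f"mixed sample rates in vowel set: {sorted(rates)}")
    fs = vowels[0].sample_rate
    concat = np.concatenate([w.samples for w in vowels])
    nperseg = min(nperseg, len(concat))
    freqs, psd = signal.welch(concat, fs=fs, nperseg=nperseg,
                              noverlap=nperseg // 2)
    return freqs, psd


def smooth_fractional_octave(freqs: np.ndarray, psd: np.ndarray,
                             fraction: float = 3.0) -> np.ndarray:
    """Smooth a PSD over 1/``fraction``-octave bands centered on each bin.

    A periodic vowel set has a harmonic-comb raw PSD; its long-term power
    spectrum in the speech-shaped-noise sense is this smoothed envelope.
    """
    half = 2.0 ** (1.0 / (2.0 * fraction))
    lo = np.searchsorted(freqs, freqs / half)
    hi = np.searchsorted(freqs, freqs * half, side="right")
    hi = np.maximum(hi, lo + 1)
    csum = np.concatenate([[0.0], np.cumsum(psd)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def third_octave_levels(freqs: np.ndarray, psd: np.ndarray,
                        lo: float = 100.0, hi: float = 8000.0):
    """Mean PSD level (dB) in standard 1/3-octave bands between lo and hi Hz."""
    centers = 1000.0 * 2.0 ** (np.arange(-12, 12) / 3.0)
    centers = centers[(centers >= lo) & (centers <= hi)]
    half = 2.0 ** (1.0 / 6.0)
    levels = []
    for c in centers:
        m = (freqs >= c / half) & (freqs < c * half)
        levels.append(10.0 * np.log10(np.mean(psd[m])))
    return centers, np.array(levels)


def build_ltps_noise(
    vowels: list[Waveform],
    duration_ms: float,
    seed: int,
    rms: float | None = None,
    nperseg: int = 4096,
) -> Waveform:
    """Speech-shaped (LTPS) noise matching the vowel set's long-term spectrum.

    Seeded white Gaussian noise is shaped in the frequency domain (zero-phase
    filtering) to the 1/3-octave-smoothed envelope of the vowels' Welch PSD,
    so the masker's long-term spectrum matches the vowel set's by
    construction.  Deterministic given ``seed``; RMS defaults to the vowel
    set's RMS.
    """
    freqs, psd = vowel_set_psd(vowels, nperseg=nperseg)
    envelope = smooth_fractional_octave(freqs, psd)
    fs = vowels[0].sample_rate

    n = int(round(duration_ms * fs / 1000.0))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    fgrid = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.interp(fgrid, freqs, np.sqrt(envelope))
    shaped = np.fft.irfft(spectrum * amp, n)

    if rms is None:
        rms = float(np.sqrt(np.mean(np.concatenate(
            [w.samples for w in vowels]) ** 2)))
    return rms_normalize(Waveform(shaped, fs), rms)


@dataclass
class MixResult:
    """Speech+noise mixture with its components kept for exact SNR audit.

    ``clip_rescale`` is the global gain (<= 1) applied to protect against
    |sample| > 1; a global rescale preserves the speech/noise RMS ratio.
    """

    waveform: Waveform
    speech_component: Waveform
    noise_component: Waveform
    snr_db: float
    clip_rescale: float = 1.0


def mix_at_snr(
    speech: Waveform,
    noise: Waveform,
    snr_db: float,
    offset: int = 0,
) -> MixResult:
    """Mix speech into a masker segment at an exact SNR (dB).

    The masker is conceptually continuous: ``offset`` selects which segment
    of the (longer) noise buffer underlies the token.  Speech RMS is left
    unchanged and the noise segment rescaled so that
    ``20*log10(rms_speech / rms_noise) == snr_db``.  If the sum clips, the
    mixture is rescaled globally (ratio-preserving) and the factor recorded.
    """
    if speech.sample_rate != noise.sample_rate:
        raise ValueError("speech and noise sample rates differ")
    if len(noise) < len(speech) + offset:
        raise ValueError("noise shorter than speech at requested offset")
    seg = noise.samples[offset:offset + len(speech)]
    rms_s = speech.rms
    rms_n = float(np.sqrt(np.mean(seg**2)))
    if rms_s == 0 or rms_n == 0:
        raise ValueError("zero-energy speech or noise segment")

    scale = rms_s / (rms_n * 10.0 ** (snr_db / 20.0))
    s = speech.samples.copy()
    m = scale * seg
    mix = s + m
    clip_rescale = 1.0
    peak = np.max(np.abs(mix))
    if peak > 1.0:
        clip_rescale = 1.0 / peak
        mix, s, m = mix * clip_rescale, s * clip_rescale, m * clip_rescale
    fs = speech.sample_rate
    return MixResult(Waveform(mix, fs), Waveform(s, fs), Waveform(m, fs),
                     snr_db, clip_rescale)


def measure_snr(mix: MixResult) -> float:
    """SNR (dB) recomputed from the mixture's stored components."""
    return 20.0 * np.log10(mix.speech_component.rms / mix.noise_component.rms)


def write_wav(path: Path | str, w: Waveform) -> None:
    wavfile.write(str(path), w.sample_rate, w.samples.astype(np.float32))


def read_wav(path: Path | str) -> Waveform:
    fs, data = wavfile.read(str(path))
    return Waveform(np.asarray(data, dtype=np.float64), int(fs))


def write_continuum(
    spec: ContinuumSpec,
    outdir: Path | str,
    noise_duration_ms: float = 5000.0,
    noise_seed: int = 0,
) -> dict:
    """Write ``tok01.wav .. tokNN.wav`` plus the LTPS masker and a JSON sidecar.

    Returns the sidecar dict (spec parameters, per-token F1 targets, file names).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vowels = synthesize_continuum(spec)
    files = []
    for k, w in enumerate(vowels, start=1):
        name = f"tok{k:02d}.wav"
        write_wav(outdir / name, w)
        files.append(name)
    noise = build_ltps_noise(vowels, noise_duration_ms, seed=noise_seed)
    write_wav(outdir / "ltps_noise.wav", noise)
    sidecar = {
        "spec": asdict(spec),
        "token_f1_hz": [token_f1(spec, k) for k in range(1, spec.n_steps + 1)],
        "tokens": files,
        "noise_file": "ltps_noise.wav",
        "noise_seed": noise_seed,
        "noise_duration_ms": noise_duration_ms,
    }
    (outdir / "continuum.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
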