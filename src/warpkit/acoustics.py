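"""Acoustic measurement: LPC formant estimation and autocorrelation pitch.

Used to verify that synthesized tokens hit their formant/F0 targets. Both
estimators are standard: linear-prediction formant tracking (Burg method,
which is less biased than the autocorrelation method on short harmonic
segments) and F0 by autocorrelation peak picking with parabolic refinement.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, signal

from .stimgen import Waveform

__all__ = ["lpc_burg", "lpc_autocorrelation", "estimate_formants", "estimate_f0"]


def lpc_burg(x: np.ndarray, order: int) -> np.ndarray:
    """Burg-method LPC: returns the prediction polynomial [1, a1, ..., a_order].

    Minimizes forward+backward prediction error with a lattice recursion;
    guaranteed-stable all-pole model.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) <= order + 1:
        raise ValueError("signal shorter than LPC order")
    f = x[1:].copy()
    b = x[:-1].copy()
    a = np.array([1.0])
    for _ in range(order):
        denom = np.dot(f, f) + np.dot(b, b)
        k = 0.0 if denom == 0 else -2.0 * np.dot(f, b) / denom
        a_ext = np.concatenate([a, [0.0]])
        a = a_ext + k * a_ext[::-1]
        f_new = f + k * b
        b_new = b + k * f
        f = f_new[1:]
        b = b_new[:-1]
    return a


def lpc_autocorrelation(x: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method LPC (Levinson-Durbin via Toeplitz solve)."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) <= order:
        raise ValueError("signal shorter than LPC order")
    r = np.correlate(x, x, mode="full")[len(x) - 1:len(x) + order]
    a = linalg.solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    return np.concatenate([[1.0], a])


def _steady_state(w: Waveform, trim_ms: float = 15.0) -> np.ndarray:
    """Central portion of a token, excluding the on/off ramps."""
    k = int(round(trim_ms * w.sample_rate / 1000.0))
    if len(w) <= 2 * k:
        return w.samples
    return w.samples[k:len(w) - k]


def estimate_formants(
    w: Waveform,
    n_formants: int = 3,
    analysis_rate: int = 10000,
    order: int = 10,
    fmin: float = 90.0,
    fmax: float = 4500.0,
    max_bandwidth: float = 700.0,
) -> np.ndarray:
    """Formant frequencies (Hz, ascending) of a vowel's steady state.

    The token is decimated to roughly ``analysis_rate`` (LPC on a band just
    covering the formants, standard practice) and the complex Burg-LPC roots
    with plausible bandwidth inside (fmin, fmax) are reported as formants.
    """
    x = _steady_state(w)
    if w.sample_rate > analysis_rate:
        down = int(round(w.sample_rate / analysis_rate))
        x = signal.resample_poly(x, 1, down)
        fs = w.sample_rate / down
    else:
        fs = float(w.sample_rate)

    a = lpc_burg(x, order)
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * fs / (2.0 * np.pi)
    bws = -np.log(np.abs(roots)) * fs / np.pi
    keep = (freqs > fmin) & (freqs < fmax) & (bws < max_bandwidth)
    formants = np.sort(freqs[keep])
    return formants[:n_formants]


def estimate_f0(
    w: Waveform,
    fmin: float = 60.0,
    fmax: float = 400.0,
    center_ms: float | None = 80.0,
) -> float:
    """Fundamental frequency (Hz) by autocorrelation peak picking.

    Analyzes the central ``center_ms`` of the token; the lag of the largest
    autocorrelation peak in the [fmin, fmax] band is refined by parabolic
    interpolation.
    """
    fs = w.sample_rate
    x = w.samples
    if center_ms is not None:
        n = int(round(center_ms * fs / 1000.0))
        if n < len(x):
            start = (len(x) - n) // 2
            x = x[start:start + n]
    x = x - np.mean(x)
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    lag_lo = int(np.floor(fs / fmax))
    lag_hi = min(int(np.ceil(fs / fmin)), len(ac) - 2)
    if lag_hi <= lag_lo:
        raise ValueError("analysis window too short for the F0 search band")
    k = int(np.argmax(ac[lag_lo:lag_hi + 1])) + lag_lo
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return fs / (k + delta)
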