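"""Mouse-trajectory geometry: normalization, mirroring, curvature, proximity.

Raw 100 Hz cursor traces are mapped to the unit square, resampled onto a
common normalized-time grid (T = 101 points, the mouse-tracking convention),
and reduced to the two geometry measures used to quantify response
competition:

* area under the curve (a.u.c.): the area enclosed between a trajectory and
  the straight chord from its start to its end point, positive when the
  path bows away from the chosen target (toward the competing response);
* proportional Euclidean proximity: 1 - d/max(d), the cursor's normalized
  closeness to the chosen target over normalized time.

Left-target trials are mirrored (x -> 1-x) so all trials reference a common
right-side target before averaging; condition curves are compared with a
running (sample-by-sample) paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .experiment import TARGET_CENTERS

__all__ = [
    "NormalizedTrack",
    "CurvatureStat",
    "ProximityCurve",
    "normalize_coordinates",
    "time_normalize",
    "TrajectoryTimeNormalizer",
    "mirror_track",
    "mirror_pool",
    "compute_auc",
    "proximity_curve",
    "running_ttest",
    "SignificantRun",
    "trial_geometry",
    "condition_proximity",
    "T_DEFAULT",
]

T_DEFAULT = 101  # normalized-time grid points


@dataclass
class NormalizedTrack:
    """A trajectory resampled to T equally spaced normalized-time points."""

    x: np.ndarray
    y: np.ndarray
    target_side: str
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")

    @property
    def T(self) -> int:
        return len(self.x)


@dataclass
class CurvatureStat:
    """Signed and absolute area (unit-square units^2) between path and chord."""

    auc_signed: float
    auc_absolute: float
    degenerate: bool = False


@dataclass
class ProximityCurve:
    """1 - d/max(d) toward the response target at each normalized time point."""

    proximity: np.ndarray
    target: tuple[float, float]
    degenerate: bool = False


def normalize_coordinates(xy_px, resolution) -> np.ndarray:
    """Pixel coordinates -> unit square: x/(width-1), y/(height-1).

    Convention: pixel origin bottom-left, y increasing upward toward the
    response boxes.  Positions outside the screen are clamped with a warning.
    """
    w, h = resolution
    if w <= 1 or h <= 1:
        raise ValueError("resolution must exceed 1 pixel per axis")
    xy = np.asarray(xy_px, dtype=float)
    out = xy / np.array([w - 1.0, h - 1.0])
    if np.any((out < 0) | (out > 1)):
        warnings.warn("positions outside the screen were clamped to [0, 1]")
        out = np.clip(out, 0.0, 1.0)
    return out


def time_normalize(x, y, T: int = T_DEFAULT,
                   target_side: str = "right") -> NormalizedTrack:
    """Resample a trajectory onto T points of normalized time.

    Linear interpolation of x(t), y(t) between threshold crossing (first
    sample) and response termination (last sample); endpoints are preserved
    exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    src = np.linspace(0.0, 1.0, len(x))
    dst = np.linspace(0.0, 1.0, T)
    xi = np.interp(dst, src, x)
    yi = np.interp(dst, src, y)
    xi[0], yi[0], xi[-1], yi[-1] = x[0], y[0], x[-1], y[-1]
    return NormalizedTrack(xi, yi, target_side)


class TrajectoryTimeNormalizer:
    """Transformer-style wrapper: list of (x, y, side) -> stacked (n, T, 2).

    Stateless; exposes get_params/set_params for pipeline composition.
    """

    def __init__(self, T: int = T_DEFAULT):
        self.T = T

    def get_params(self, deep: bool = True) -> dict:
        return {"T": self.T}

    def set_params(self, **params) -> "TrajectoryTimeNormalizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "TrajectoryTimeNormalizer":
        return self

    def transform(self, X) -> list[NormalizedTrack]:
        return [time_normalize(x, y, T=self.T, target_side=side)
                for x, y, side in X]


def mirror_track(track: NormalizedTrack) -> NormalizedTrack:
    """Reflect across the vertical midline: x -> 1-x, target side flipped."""
    side = "right" if track.target_side == "left" else "left"
    return NormalizedTrack(1.0 - track.x, track.y.copy(), side,
                           mirrored=not track.mirrored)


def mirror_pool(tracks: list[NormalizedTrack]) -> list[NormalizedTrack]:
    """Reflect all left-target tracks so every track references the right
    target; right-target tracks pass through unchanged."""
    return [mirror_track(t) if t.target_side == "left" else t for t in tracks]


def pooled_mean(tracks: list[NormalizedTrack]) -> NormalizedTrack:
    """Pointwise mean of mirror-pooled tracks (all toward the right target)."""
    pooled = mirror_pool(tracks)
    xs = np.mean([t.x for t in pooled], axis=0)
    ys = np.mean([t.y for t in pooled], axis=0)
    return NormalizedTrack(xs, ys, "right")


def compute_auc(track: NormalizedTrack) -> CurvatureStat:
    """Area between the trajectory and its start-to-end chord.

    The closed polygon (path vertices, implicitly closed by the chord) is
    integrated with the shoelace formula; the sign is oriented so that
    bowing away from the target side — toward the competing response — is
    positive.  The absolute variant integrates |lateral deviation| along the
    chord, so S-shaped paths do not cancel.
    """
    x, y = track.x, track.y
    if len(x) < 3:
        raise ValueError("need at least 3 samples for an area")
    # shoelace over the path vertices with implicit closure: the closing
    # edge is exactly the reversed chord, so this is the signed area of the
    # (path + chord) polygon.  CCW positive.
    shoelace = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

    start = np.array([x[0], y[0]])
    end = np.array([x[-1], y[-1]])
    chord = end - start
    clen = np.hypot(*chord)
    if clen < 1e-12:
        return CurvatureStat(float(shoelace), float(abs(shoelace)), True)

    # rotate into chord coordinates: "along" on the chord, "lateral" > 0 to
    # the left of it.  In these coordinates the closing edge lies on the
    # axis, so the shoelace area equals -∫ lateral d(along); the lateral
    # form also gives the cancellation-free absolute variant.
    u = chord / clen
    rel = np.stack([x - start[0], y - start[1]], axis=1)
    along = rel @ u
    lateral = rel[:, 0] * (-u[1]) + rel[:, 1] * u[0]
    auc_abs = float(np.trapezoid(np.abs(lateral), along))

    # sign convention: positive when the path bows away from the target
    # side, i.e. toward the competing response.  For a right-side target the
    # competitor lies to the left of the chord (positive lateral); mirrored
    # for left-side targets.
    signed_lateral = float(-shoelace)  # == trapezoid(lateral, along) exactly
    auc_signed = signed_lateral if track.target_side == "right" else -signed_lateral
    return CurvatureStat(float(auc_signed), auc_abs, False)


def proximity_curve(track: NormalizedTrack,
                    target: tuple[float, float] | None = None,
                    max_distance: float | None = None) -> ProximityCurve:
    """Proportional Euclidean proximity 1 - d/max(d) over normalized time.

    ``max(d)`` defaults to the within-trial maximum (the start point is
    typically the farthest sample); pass ``max_distance`` to normalize by a
    shared (e.g. per-condition) maximum instead.
    """
    if target is None:
        target = TARGET_CENTERS[track.target_side]
    d = np.hypot(track.x - target[0], track.y - target[1])
    dmax = float(np.max(d)) if max_distance is None else float(max_distance)
    if dmax <= 0:
        return ProximityCurve(np.ones_like(d), tuple(target), True)
    return ProximityCurve(1.0 - d / dmax, tuple(target), False)


@dataclass
class SignificantRun:
    """A maximal contiguous run of below-alpha samples on the t* grid."""

    start: int
    end: int          # inclusive index
    t_start: float    # normalized time of the first sample
    t_end: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def running_ttest(curves_a: np.ndarray, curves_b: np.ndarray,
                  alpha: float = 0.01, min_run: int = 1):
    """Paired t-test at every normalized-time sample.

    ``curves_a``/``curves_b``: (n_subjects, T) paired subject-level mean
    curves.  Returns (t, p, runs): per-sample statistics plus the maximal
    contiguous runs with p < alpha of at least ``min_run`` samples.  A
    zero-variance sample yields p = 1 when the differences are all zero and
    p = 0 when they are a nonzero constant (logged).
    """
    a = np.asarray(curves_a, dtype=float)
    b = np.asarray(curves_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("curve matrices must be equal-shape (n_subjects, T)")
    n, T = a.shape
    if n < 3:
        raise ValueError("need >= 3 subject pairs")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    if zero_var.any():
        exact_zero = zero_var & (mean == 0)
        const_nonzero = zero_var & (mean != 0)
        p[exact_zero] = 1.0
        t[exact_zero] = 0.0
        if const_nonzero.any():
            warnings.warn(f"{const_nonzero.sum()} samples with constant "
                          "nonzero differences: p set to 0")
            p[const_nonzero] = 0.0
            t[const_nonzero] = np.inf * np.sign(mean[const_nonzero])

    sig = p < alpha
    runs: list[SignificantRun] = []
    tgrid = np.linspace(0.0, 1.0, T)
    i = 0
    while i < T:
        if sig[i]:
            j = i
            while j + 1 < T and sig[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                runs.append(SignificantRun(i, j, float(tgrid[i]),
                                           float(tgrid[j])))
            i = j + 1
        else:
            i += 1
    return t, p, runs


# ---------------------------------------------------------------------------
# Trial-log level drivers

def _iter_trials(trial_log: pd.DataFrame):
    keys = ["subject_id", "block_id", "trial_index"]
    for key, g in trial_log.groupby(keys, sort=True, observed=True):
        g = g.sort_values("sample_t_ms")
        yield key, g


def trial_geometry(trial_log: pd.DataFrame, T: int = T_DEFAULT) -> pd.DataFrame:
    """Per-trial geometry table from a long-format log.

    Each trial is time-normalized, mirrored onto the right target when the
    response was "u", and summarized as signed/absolute a.u.c.  Returns one
    row per trial with condition labels preserved.
    """
    rows = []
    for (sid, bid, idx), g in _iter_trials(trial_log):
        side = "left" if g["response"].iloc[0] == "u" else "right"
        track = time_normalize(g["sample_x"].to_numpy(),
                               g["sample_y"].to_numpy(), T=T,
                               target_side=side)
        track = mirror_track(track) if side == "left" else track
        stat = compute_auc(track)
        rows.append({
            "subject_id": sid, "block_id": bid, "trial_index": idx,
            "token": int(g["token"].iloc[0]),
            "order": g["order"].iloc[0], "snr": g["snr"].iloc[0],
            "response": g["response"].iloc[0],
            "rt_ms": float(g["rt_ms"].iloc[0]),
            "auc_signed": stat.auc_signed, "auc_absolute": stat.auc_absolute,
            "degenerate": stat.degenerate,
        })
    return pd.DataFrame(rows)


def condition_proximity(trial_log: pd.DataFrame, T: int = T_DEFAULT,
                        tokens: tuple[int, ...] = (1, 7),
                        pool_serial: bool = True) -> pd.DataFrame:
    """Subject-level mean proximity curves per condition.

    Uses the endpoint tokens (Tk1 mirrored + Tk7 by default), mirror-pools
    trials onto the right target, computes each trial's proximity curve, and
    averages within subject x SNR x order.  With ``pool_serial`` the forward
    and reverse blocks form a single "serial" level.  Returns a long frame:
    subject_id, snr, order, t_index, t_star, proximity.
    """
    sel = trial_log[trial_log["token"].isin(tokens)]
    rows = []
    for (sid, bid, idx), g in _iter_trials(sel):
        side = "left" if g["response"].iloc[0] == "u" else "right"
        track = time_normalize(g["sample_x"].to_numpy(),
                               g["sample_y"].to_numpy(), T=T,
                               target_side=side)
        track = mirror_track(track) if side == "left" else track
        prox = proximity_curve(track)
        order = g["order"].iloc[0]
        if pool_serial and order in ("forward", "reverse"):
            order = "serial"
        rows.append({"subject_id": sid, "snr": g["snr"].iloc[0],
                     "order": order, "curve": prox.proximity})
    if not rows:
        return pd.DataFrame(
            columns=["subject_id", "snr", "order", "t_index", "t_star",
                     "proximity"])
    df = pd.DataFrame(rows)
    out = []
    tgrid = np.linspace(0.0, 1.0, T)
    for (sid, snr, order), g in df.groupby(["subject_id", "snr", "order"],
                                           sort=True, observed=True):
        mean_curve = np.mean(np.stack(g["curve"].to_list()), axis=0)
        out.append(pd.DataFrame({
            "subject_id": sid, "snr": snr, "order": order,
            "t_index": np.arange(T), "t_star": tgrid,
            "proximity": mean_curve}))
    return pd.concat(out, ignore_index=True)
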