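"""Psychometric identification analysis: sigmoid fits, RTs, reliability.

Each subject x condition identification curve is fit with the two-parameter
logistic

    P(x) = 1 / (1 + exp(-beta1 * (x - beta0)))

where ``x`` is the token index, ``beta0`` the category boundary (the token
at which P = 0.5) and ``beta1`` the slope (steepness of categorization).
Perceptual warping is the displacement of beta0 between serial and random
presentation.  Reaction times are medianized per token after excluding
trials outside the 250-2500 ms window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator

__all__ = [
    "PsychometricRegression",
    "PsychometricFit",
    "RTProfile",
    "fit_sigmoid",
    "boundary_shift",
    "filter_rts",
    "median_rt_per_token",
    "proportions_from_trials",
    "fit_conditions",
    "split_half_reliability",
    "RT_WINDOW_MS",
]

#: Closed RT inclusion window (ms): values outside are outliers.
RT_WINDOW_MS = (250.0, 2500.0)

# Optimizer box: boundary within (extended) continuum, slope positive-bounded.
BETA0_BOUNDS = (0.0, 8.0)
BETA1_BOUNDS = (1e-6, 20.0)
BETA_INIT = (4.0, 1.0)


@dataclass
class PsychometricFit:
    """Fitted boundary/slope with least-squares diagnostics."""

    beta0: float
    beta1: float
    sse: float
    converged: bool
    n_trials_used: int
    flags: tuple[str, ...] = ()

    def predict(self, x) -> np.ndarray:
        """Identification probability of the fitted logistic at token x."""
        return expit(self.beta1 * (np.asarray(x, dtype=float) - self.beta0))


class PsychometricRegression(BaseEstimator):
    """Two-parameter logistic psychometric curve, scikit-learn style.

    Fit on per-token proportions (weighted least squares) or, equivalently,
    on raw binary trials.  Deterministic: bounded trust-region least squares
    from a fixed initial point (boundary mid-continuum, unit slope).

    Parameters
    ----------
    beta0_bounds, beta1_bounds : (low, high)
        Optimizer box constraints; the boundary box spans the (extended)
        token axis and the slope box keeps beta1 positive and finite.

    Attributes
    ----------
    beta0_ : float
        Category boundary: token where identification probability is 0.5.
    beta1_ : float
        Sigmoid slope per token step.
    sse_ : float
        Weighted sum of squared residuals.
    converged_ : bool
    n_trials_used_ : int
    flags_ : tuple of str
        Diagnostics: "non_identifiable" (constant proportions; beta1 at the
        lower box edge), "non_monotone" (proportions decrease with token).
    """

    def __init__(self, beta0_bounds=BETA0_BOUNDS, beta1_bounds=BETA1_BOUNDS):
        self.beta0_bounds = beta0_bounds
        self.beta1_bounds = beta1_bounds

    def fit(self, X, y, sample_weight=None):
        """Fit to per-token proportions.

        X: token indices (n,) or (n,1); y: fraction of /a/ responses per
        token in [0,1]; sample_weight: trials behind each proportion.
        """
        x = np.asarray(X, dtype=float).reshape(-1)
        p = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != p.shape:
            raise ValueError("X and y lengths differ")
        ok = ~np.isnan(p)
        x, p = x[ok], p[ok]
        if sample_weight is None:
            w = np.ones_like(p)
        else:
            w = np.asarray(sample_weight, dtype=float).reshape(-1)[ok]
        if len(x) < 2:
            raise ValueError("need proportions for at least 2 tokens")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("proportions must lie in [0, 1]")

        flags = []
        if np.ptp(p) == 0:
            flags.append("non_identifiable")
        elif len(x) > 2 and pearsonr(x, p)[0] < 0:
            flags.append("non_monotone")
            warnings.warn("proportions decrease with token index; "
                          "fitting as-is")

        sw = np.sqrt(w)

        def resid(theta):
            b0, b1 = theta
            return sw * (p - expit(b1 * (x - b0)))

        lo = (self.beta0_bounds[0], self.beta1_bounds[0])
        hi = (self.beta0_bounds[1], self.beta1_bounds[1])
        sol = least_squares(resid, x0=BETA_INIT, bounds=(lo, hi),
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        self.beta0_ = float(sol.x[0])
        self.beta1_ = float(sol.x[1])
        self.sse_ = float(np.sum(sol.fun**2))
        self.converged_ = bool(sol.success) and "non_identifiable" not in flags
        self.n_trials_used_ = int(np.sum(w))
        self.flags_ = tuple(flags)
        return self

    def fit_trials(self, tokens, responses_a):
        """Fit from raw binary trials (1 = /a/), aggregating per token."""
        tokens = np.asarray(tokens)
        resp = np.asarray(responses_a, dtype=float)
        levels = np.unique(tokens)
        props = np.array([resp[tokens == t].mean() for t in levels])
        weights = np.array([(tokens == t).sum() for t in levels])
        return self.fit(levels.astype(float), props, sample_weight=weights)

    def predict_proba(self, X) -> np.ndarray:
        """P(/a/ label) at token X under the fitted curve."""
        x = np.asarray(X, dtype=float).reshape(-1)
        return expit(self.beta1_ * (x - self.beta0_))

    def result_(self) -> PsychometricFit:
        return PsychometricFit(self.beta0_, self.beta1_, self.sse_,
                               self.converged_, self.n_trials_used_,
                               self.flags_)


def fit_sigmoid(proportions, weights=None, tokens=None) -> PsychometricFit:
    """Least-squares logistic fit to per-token /a/ proportions.

    ``tokens`` defaults to 1..n.  Thin wrapper over PsychometricRegression.
    """
    p = np.asarray(proportions, dtype=float)
    x = np.arange(1, len(p) + 1, dtype=float) if tokens is None else tokens
    est = PsychometricRegression().fit(x, p, sample_weight=weights)
    return est.result_()


def boundary_shift(fit_serial: PsychometricFit,
                   fit_random: PsychometricFit) -> tuple[float, float]:
    """Signed and absolute boundary displacement (serial minus random).

    Propagates non-convergence as NaN rather than raising.
    """
    if not (fit_serial.converged and fit_random.converged):
        return float("nan"), float("nan")
    d = fit_serial.beta0 - fit_random.beta0
    return d, abs(d)


def filter_rts(rts, window=RT_WINDOW_MS) -> tuple[np.ndarray, int]:
    """Keep RTs inside the closed outlier window; returns (kept, n_excluded)."""
    rts = np.asarray(rts, dtype=float)
    keep = (rts >= window[0]) & (rts <= window[1])
    return rts[keep], int(len(rts) - keep.sum())


@dataclass
class RTProfile:
    """Per-token median RT (ms) after outlier exclusion."""

    tokens: np.ndarray
    median_rt_ms: np.ndarray     # NaN where no retained trials
    n_excluded: int
    exclusion_window: tuple[float, float] = RT_WINDOW_MS


def median_rt_per_token(tokens, rts, n_tokens: int | None = None,
                        window=RT_WINDOW_MS) -> RTProfile:
    """Median retained RT per token; tokens without retained trials are NaN."""
    tokens = np.asarray(tokens)
    rts = np.asarray(rts, dtype=float)
    if n_tokens is None:
        n_tokens = int(tokens.max()) if len(tokens) else 0
    keep = (rts >= window[0]) & (rts <= window[1])
    levels = np.arange(1, n_tokens + 1)
    med = np.full(len(levels), np.nan)
    for i, t in enumerate(levels):
        sel = keep & (tokens == t)
        if sel.any():
            med[i] = np.median(rts[sel])
    return RTProfile(levels, med, int(len(rts) - keep.sum()), window)


def _per_trial(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per trial from a long-format (per-sample) log."""
    keys = ["subject_id", "block_id", "trial_index"]
    return (trials.groupby(keys, sort=True, observed=True)
            .agg(token=("token", "first"), order=("order", "first"),
                 snr=("snr", "first"), response=("response", "first"),
                 rt_ms=("rt_ms", "first"))
            .reset_index())


def proportions_from_trials(trials: pd.DataFrame,
                            n_tokens: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Per-token /a/ proportion and trial counts from per-trial rows."""
    props = np.full(n_tokens, np.nan)
    counts = np.zeros(n_tokens)
    for t in range(1, n_tokens + 1):
        sel = trials["token"] == t
        counts[t - 1] = sel.sum()
        if counts[t - 1]:
            props[t - 1] = (trials.loc[sel, "response"] == "a").mean()
    return props, counts


def fit_conditions(trial_log: pd.DataFrame, pool_serial: bool = True,
                   n_tokens: int = 7) -> pd.DataFrame:
    """Fit the sigmoid per subject x SNR x order and summarize RTs.

    With ``pool_serial`` the forward and reverse blocks are additionally
    pooled into a "serial" pseudo-order (the per-direction fits remain in
    the table for signed-shift analyses).  Returns one row per fit with
    beta0, beta1, sse, convergence, per-token median RTs and the exclusion
    count.
    """
    per_trial = _per_trial(trial_log)
    rows = []
    orders = list(per_trial["order"].unique())
    groups: list[tuple[str, pd.Series]] = [
        (o, per_trial["order"] == o) for o in orders]
    if pool_serial and {"forward", "reverse"} <= set(orders):
        groups.append(("serial", per_trial["order"].isin(["forward", "reverse"])))
    for sid, sub in per_trial.groupby("subject_id", sort=True, observed=True):
        for snr in sub["snr"].unique():
            for label, mask in groups:
                cell = sub[(sub["snr"] == snr) & mask.loc[sub.index]]
                if cell.empty:
                    continue
                props, counts = proportions_from_trials(cell, n_tokens)
                fit = fit_sigmoid(props, weights=counts)
                prof = median_rt_per_token(
                    cell["token"].to_numpy(), cell["rt_ms"].to_numpy(),
                    n_tokens=n_tokens)
                row = {"subject_id": sid, "snr": snr, "order": label,
                       "beta0": fit.beta0, "beta1": fit.beta1,
                       "sse": fit.sse, "converged": fit.converged,
                       "n_trials_used": fit.n_trials_used,
                       "n_rt_excluded": prof.n_excluded}
                for t, m in zip(prof.tokens, prof.median_rt_ms):
                    row[f"median_rt_tk{t}"] = m
                rows.append(row)
    return pd.DataFrame(rows)


def split_half_reliability(trial_log: pd.DataFrame,
                           n_tokens: int = 7) -> tuple[float, float, int]:
    """Within-subject stability of the boundary across task halves.

    Splits every block at its temporal midpoint, fits beta0 per subject on
    first-half vs last-half trials (pooled across orders and SNRs), and
    returns the Pearson (r, p, n_subjects) across subjects.  Subjects with
    an unfittable half are dropped (logged via warning).
    """
    per_trial = _per_trial(trial_log)
    half_idx = per_trial.groupby("block_id", observed=True)["trial_index"].transform("median")
    per_trial = per_trial.assign(half=np.where(
        per_trial["trial_index"] < half_idx, "first", "last"))
    b0 = {"first": [], "last": []}
    kept = []
    for sid, sub in per_trial.groupby("subject_id", sort=True, observed=True):
        fits = {}
        for half in ("first", "last"):
            cell = sub[sub["half"] == half]
            props, counts = proportions_from_trials(cell, n_tokens)
            fits[half] = fit_sigmoid(props, weights=counts)
        if all(f.converged for f in fits.values()):
            b0["first"].append(fits["first"].beta0)
            b0["last"].append(fits["last"].beta0)
            kept.append(sid)
        else:
            warnings.warn(f"subject {sid} dropped from split-half "
                          "reliability (unfittable half)")
    if len(kept) < 3:
        raise ValueError("need >= 3 subjects with both halves fittable")
    r, p = pearsonr(b0["first"], b0["last"])
    return float(r), float(p), len(kept)
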