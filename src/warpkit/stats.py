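"""Condition-level inference on subject x condition cell means.

Classical repeated-measures ANOVA (subject as the random blocking factor)
with partial eta-squared effect sizes, Holm-corrected pairwise contrasts,
and the Pearson correlations linking psychometric warping (|delta beta0|)
to trajectory change.  The design is balanced by construction, where the
cell-mean decomposition is exact; subjects with missing cells are removed
listwise (with a warning).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "rm_anova",
    "holm_contrasts",
    "pearson",
    "warping_correlation",
]


@dataclass
class CorrelationResult:
    """Pearson correlation with two-tailed p and pair count."""

    r: float
    p: float
    n: int
    flags: tuple[str, ...] = ()


def _cell_means(df: pd.DataFrame, dv: str, within: list[str],
                subject: str) -> pd.DataFrame:
    """Average to one value per subject x cell; drop incomplete subjects."""
    cells = df.groupby([subject, *within], observed=True)[dv].mean().reset_index()
    n_cells = int(np.prod([cells[f].nunique() for f in within]))
    counts = cells.groupby(subject, observed=True).size()
    complete = counts[counts == n_cells].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        warnings.warn(f"subjects dropped listwise (incomplete cells): {dropped}")
    return cells[cells[subject].isin(complete)]


def rm_anova(df: pd.DataFrame, dv: str, within: list[str],
             subject: str = "subject_id") -> pd.DataFrame:
    """Repeated-measures ANOVA on a balanced within-subject design.

    Decomposes the subject x cell means into main effects and interactions
    of the ``within`` factors; each effect is tested against its own
    effect-by-subject interaction (the classical univariate error term).
    Returns a table with one row per effect: df1, df2, SS_effect, SS_error,
    F, p, partial eta^2 (= SS_effect / (SS_effect + SS_error)).
    """
    if not within:
        raise ValueError("need at least one within factor")
    cells = _cell_means(df, dv, within, subject)
    subjects = sorted(cells[subject].unique())
    if len(subjects) < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 subjects")

    factors = [subject, *within]
    levels = {f: sorted(cells[f].unique()) for f in factors}
    shape = tuple(len(levels[f]) for f in factors)
    index = {f: {lv: i for i, lv in enumerate(levels[f])} for f in factors}
    data = np.full(shape, np.nan)
    for _, row in cells.iterrows():
        pos = tuple(index[f][row[f]] for f in factors)
        data[pos] = row[dv]
    if np.isnan(data).any():
        raise ValueError("design not balanced after listwise deletion")

    axes = {f: i for i, f in enumerate(factors)}

    def effect_array(subset: tuple[str, ...]) -> np.ndarray:
        """Inclusion-exclusion effect estimate, broadcast to the full grid."""
        total = np.zeros(shape)
        for r in range(len(subset) + 1):
            for b in itertools.combinations(subset, r):
                drop = tuple(axes[f] for f in factors if f not in b)
                marg = data.mean(axis=drop, keepdims=True)
                total = total + (-1.0) ** (len(subset) - len(b)) * marg
        return total

    def ss_df(subset: tuple[str, ...]) -> tuple[float, int]:
        eff = effect_array(subset)
        ss = float(np.sum(eff**2))
        dfree = int(np.prod([len(levels[f]) - 1 for f in subset]))
        return ss, dfree

    rows = []
    for k in range(1, len(within) + 1):
        for combo in itertools.combinations(within, k):
            ss_e, df_e = ss_df(combo)
            ss_err, df_err = ss_df((subject, *combo))
            ms_e = ss_e / df_e
            ms_err = ss_err / df_err
            F = ms_e / ms_err if ms_err > 0 else (0.0 if ss_e == 0 else np.inf)
            p = float(sps.f.sf(F, df_e, df_err)) if np.isfinite(F) else 0.0
            if F == 0.0:
                p = 1.0
            rows.append({
                "effect": ":".join(combo), "df1": df_e, "df2": df_err,
                "SS_effect": ss_e, "SS_error": ss_err, "F": float(F),
                "p": p,
                "partial_eta2": ss_e / (ss_e + ss_err) if ss_e + ss_err > 0
                else 0.0,
            })
    return pd.DataFrame(rows)


def holm_contrasts(df: pd.DataFrame, dv: str, factor: str,
                   subject: str = "subject_id") -> pd.DataFrame:
    """All pairwise paired-t contrasts between levels of ``factor``,
    Holm step-down adjusted; raw p reported alongside.

    Other within factors are averaged out per subject x level first.
    """
    cells = (df.groupby([subject, factor], observed=True)[dv].mean()
             .unstack(factor))
    cells = cells.dropna(axis=0)
    lev = list(cells.columns)
    rows = []
    for a, b in itertools.combinations(lev, 2):
        diff = cells[a] - cells[b]
        if np.allclose(diff.std(ddof=1), 0) and np.allclose(diff.mean(), 0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(cells[a], cells[b])
        rows.append({"level_a": a, "level_b": b,
                     "mean_diff": float(diff.mean()),
                     "t": float(t), "df": len(cells) - 1, "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def pearson(x, y) -> CorrelationResult:
    """Pearson r with two-tailed p; constant input is flagged (r = NaN)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return CorrelationResult(np.nan, np.nan, len(x), ("too_few_pairs",))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, len(x), ("constant_input",))
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))


def warping_correlation(fits: pd.DataFrame, geometry: pd.DataFrame,
                        snr: str, rt_token: int = 4) -> dict:
    """Correlate per-subject psychometric warping with trajectory change
    within one SNR stratum.

    ``fits``: output of psychometrics.fit_conditions (needs the pooled
    "serial" rows).  ``geometry``: per-trial a.u.c. table
    (mousetrack.trial_geometry).  Computes, per subject within ``snr``:

    * |delta beta0| = |beta0(serial) - beta0(random)|;
    * delta a.u.c. = mean a.u.c.(serial) - mean a.u.c.(random) on endpoint
      tokens (1 and 7);
    * median RT at the maximally ambiguous token (``rt_token``).

    Returns {"warp_vs_auc": CorrelationResult, "rt_vs_auc": ...,
    "table": per-subject DataFrame}.
    """
    f = fits[fits["snr"] == snr].set_index(["subject_id", "order"])["beta0"]
    g = geometry[(geometry["snr"] == snr)
                 & geometry["token"].isin((1, 7))].copy()
    g["order_pooled"] = np.where(g["order"].isin(("forward", "reverse")),
                                 "serial", g["order"])
    auc = (g.groupby(["subject_id", "order_pooled"], observed=True)
           ["auc_absolute"].mean().unstack("order_pooled"))

    rt_g = geometry[(geometry["snr"] == snr)
                    & (geometry["token"] == rt_token)]
    rt4 = rt_g.groupby("subject_id", observed=True)["rt_ms"].median()

    rows = []
    for sid in auc.index:
        try:
            db0 = abs(f.loc[(sid, "serial")] - f.loc[(sid, "random")])
        except KeyError:
            continue
        if not {"serial", "random"} <= set(auc.columns):
            continue
        rows.append({"subject_id": sid, "abs_delta_beta0": db0,
                     "delta_auc": auc.loc[sid, "serial"]
                     - auc.loc[sid, "random"],
                     "rt_tk_ms": rt4.get(sid, np.nan)})
    table = pd.DataFrame(rows)
    if len(table) < 4:
        raise ValueError("need >= 4 complete subject pairs per stratum")
    return {
        "warp_vs_auc": pearson(table["abs_delta_beta0"],
                               np.abs(table["delta_auc"])),
        "rt_vs_auc": pearson(table["rt_tk_ms"], table["delta_auc"]),
        "table": table,
    }
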