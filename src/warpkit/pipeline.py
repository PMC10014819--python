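"""End-to-end orchestration: synth -> simulate -> fit -> geometry -> stats.

A run is fully described by a :class:`RunConfig`; identical configs
regenerate byte-identical CSV/JSON outputs (and identical WAVs given the
same seed).  Each stage writes its declared files into the run directory
and never mutates upstream outputs; a JSON-lines log records filter counts,
dropped subjects and convergence flags.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stimgen import ContinuumSpec, write_continuum
from .experiment import DesignSpec, write_trial_log, read_trial_log
from .observer import ObserverParams, PopulationParams, simulate_experiment
from . import psychometrics as psy
from . import mousetrack as mt
from . import stats as st

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    n_subjects: int = 29
    seed: int = 7
    design: DesignSpec = field(default_factory=DesignSpec)
    continuum: ContinuumSpec = field(default_factory=ContinuumSpec)
    population: PopulationParams = field(default_factory=PopulationParams)
    timepoints: int = mt.T_DEFAULT
    alpha: float = 0.01
    synth_audio: bool = True
    noise_duration_ms: float = 5000.0
    make_figures: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "design" in d:
            d["design"] = DesignSpec.from_json(json.dumps(d["design"]))
        if "continuum" in d:
            d["continuum"] = ContinuumSpec(**d["continuum"])
        if "population" in d:
            pop = d["population"]
            if "template" in pop:
                pop["template"] = ObserverParams(**pop["template"])
            d["population"] = PopulationParams(**pop)
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def emit(self, stage: str, **fields) -> None:
        with self.path.open("a") as fh:
            fh.write(json.dumps({"stage": stage, **fields}, sort_keys=True,
                                default=str) + "\n")


def _stage_synth(cfg: RunConfig, out: Path, log: _RunLog) -> None:
    sidecar = write_continuum(cfg.continuum, out / "stimuli",
                              noise_duration_ms=cfg.noise_duration_ms,
                              noise_seed=cfg.seed)
    log.emit("synth", tokens=len(sidecar["tokens"]),
             noise_file=sidecar["noise_file"])


def _stage_simulate(cfg: RunConfig, out: Path, log: _RunLog) -> pd.DataFrame:
    trials, params = simulate_experiment(
        cfg.design, cfg.population, cfg.n_subjects, seed=cfg.seed,
        return_params=True)
    write_trial_log(trials, out / "trials.csv")
    params.to_csv(out / "observer_params.csv", index=False,
                  float_format="%.10g")
    log.emit("simulate", n_subjects=cfg.n_subjects,
             n_rows=len(trials),
             n_trials=int(trials.groupby(
                 ["subject_id", "block_id", "trial_index"], observed=True).ngroups))
    return trials


def _stage_psychometrics(cfg: RunConfig, out: Path, trials: pd.DataFrame,
                         log: _RunLog) -> pd.DataFrame:
    fits = psy.fit_conditions(trials, pool_serial=True,
                              n_tokens=cfg.design.n_tokens)
    fits.to_csv(out / "fits.csv", index=False, float_format="%.10g")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            r, p, n = psy.split_half_reliability(
                trials, n_tokens=cfg.design.n_tokens)
        except ValueError as exc:  # too few fittable subjects
            r, p, n = float("nan"), float("nan"), 0
            log.emit("psychometrics", split_half_skipped=str(exc))
    for w in caught:
        log.emit("psychometrics", warning=str(w.message))
    (out / "reliability.json").write_text(json.dumps(
        {"split_half_r": r, "p": p, "n_subjects": n,
         "config_hash": cfg.config_hash}, indent=2, sort_keys=True))
    log.emit("psychometrics", n_fits=len(fits),
             n_unconverged=int((~fits["converged"]).sum()),
             rt_excluded_total=int(fits["n_rt_excluded"].sum()),
             split_half_r=r)
    return fits


def _stage_mousetrack(cfg: RunConfig, out: Path, trials: pd.DataFrame,
                      log: _RunLog):
    geom = mt.trial_geometry(trials, T=cfg.timepoints)
    geom.to_csv(out / "geometry.csv", index=False, float_format="%.10g")
    prox = mt.condition_proximity(trials, T=cfg.timepoints)
    prox.to_csv(out / "proximity.csv", index=False, float_format="%.10g")

    runs_report = {"alpha": cfg.alpha, "config_hash": cfg.config_hash,
                   "comparisons": {}}
    for snr in trials["snr"].unique():
        sub = prox[prox["snr"] == snr]
        piv = {o: sub[sub["order"] == o].pivot(index="subject_id",
                                               columns="t_index",
                                               values="proximity")
               for o in ("serial", "random")}
        common = piv["serial"].index.intersection(piv["random"].index)
        entry: dict = {"n_subjects": len(common)}
        try:
            tstat, pval, runs = mt.running_ttest(
                piv["serial"].loc[common].to_numpy(),
                piv["random"].loc[common].to_numpy(), alpha=cfg.alpha)
            entry["n_significant_samples"] = int((pval < cfg.alpha).sum())
            entry["runs"] = [{"start": r.start, "end": r.end,
                              "t_start": r.t_start, "t_end": r.t_end}
                             for r in runs]
        except ValueError as exc:  # too few paired subjects to test
            entry["skipped"] = str(exc)
            log.emit("mousetrack", running_ttest_skipped=str(exc), snr=snr)
        runs_report["comparisons"][f"serial_vs_random_{snr}"] = entry
    (out / "significant_runs.json").write_text(
        json.dumps(runs_report, indent=2, sort_keys=True))
    log.emit("mousetrack", n_trials=len(geom),
             n_degenerate=int(geom["degenerate"].sum()))
    return geom, prox, runs_report


def _stage_stats(cfg: RunConfig, out: Path, fits: pd.DataFrame,
                 geom: pd.DataFrame, log: _RunLog) -> dict:
    results = {}
    # beta0 / beta1: snr x order (random vs pooled serial)
    f2 = fits[fits["order"].isin(["random", "serial"])]
    for dv in ("beta0", "beta1"):
        table = st.rm_anova(f2, dv, within=["snr", "order"])
        table.to_csv(out / f"anova_{dv}.csv", index=False,
                     float_format="%.10g")
        results[f"anova_{dv}"] = table

    # RT: token x snr x order on per-subject medians of retained trials
    per_trial = geom.copy()
    per_trial["order"] = np.where(
        per_trial["order"].isin(("forward", "reverse")), "serial",
        per_trial["order"])
    kept = per_trial[(per_trial["rt_ms"] >= psy.RT_WINDOW_MS[0])
                     & (per_trial["rt_ms"] <= psy.RT_WINDOW_MS[1])]
    rt_cells = (kept.groupby(["subject_id", "token", "snr", "order"],
                             observed=True)["rt_ms"].median().reset_index())
    table = st.rm_anova(rt_cells, "rt_ms", within=["token", "snr", "order"])
    table.to_csv(out / "anova_rt.csv", index=False, float_format="%.10g")
    results["anova_rt"] = table
    results["rt_contrasts"] = st.holm_contrasts(rt_cells, "rt_ms", "order")
    results["rt_contrasts"].to_csv(out / "contrasts_rt_order.csv",
                                   index=False, float_format="%.10g")

    # a.u.c.: snr x order on endpoint tokens
    auc_cells = (per_trial[per_trial["token"].isin((1, 7))]
                 .groupby(["subject_id", "snr", "order"], observed=True)
                 ["auc_absolute"].mean().reset_index())
    table = st.rm_anova(auc_cells, "auc_absolute", within=["snr", "order"])
    table.to_csv(out / "anova_auc.csv", index=False, float_format="%.10g")
    results["anova_auc"] = table

    # warping correlations per SNR stratum
    corr_rows = []
    for snr in fits["snr"].unique():
        try:
            res = st.warping_correlation(fits, geom, snr)
        except ValueError as exc:  # too few complete subject pairs
            log.emit("stats", warping_correlation_skipped=str(exc), snr=snr)
            corr_rows.append({"snr": snr, "comparison": "warp_vs_auc",
                              "r": np.nan, "p": np.nan, "n": 0,
                              "flags": "skipped"})
            continue
        for name in ("warp_vs_auc", "rt_vs_auc"):
            c = res[name]
            corr_rows.append({"snr": snr, "comparison": name, "r": c.r,
                              "p": c.p, "n": c.n,
                              "flags": ";".join(c.flags)})
        res["table"].to_csv(out / f"warping_subjects_{snr}.csv", index=False,
                            float_format="%.10g")
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(out / "correlations.csv", index=False, float_format="%.10g")
    results["correlations"] = corr
    log.emit("stats", tables=sorted(results.keys()))
    return results


def _figures(cfg: RunConfig, out: Path, trials: pd.DataFrame,
             fits: pd.DataFrame, geom: pd.DataFrame, prox: pd.DataFrame):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    per_trial = geom
    # identification curves
    fig, ax = plt.subplots(figsize=(5, 4))
    for snr, style in zip(("clean", "0dB"), ("-o", "--s")):
        sub = per_trial[per_trial["snr"] == snr]
        props = [(sub[sub["token"] == t]["response"] == "a").mean()
                 for t in range(1, cfg.design.n_tokens + 1)]
        ax.plot(range(1, cfg.design.n_tokens + 1), props, style, label=snr)
    ax.set_xlabel("token")
    ax.set_ylabel("proportion /a/")
    ax.legend()
    fig.savefig(figdir / "identification.png", dpi=110)
    plt.close(fig)

    # RT profile
    fig, ax = plt.subplots(figsize=(5, 4))
    for order in ("random", "serial"):
        sub = per_trial[per_trial["order"].isin(
            ("forward", "reverse") if order == "serial" else (order,))]
        med = [sub[sub["token"] == t]["rt_ms"].median()
               for t in range(1, cfg.design.n_tokens + 1)]
        ax.plot(range(1, cfg.design.n_tokens + 1), med, "-o", label=order)
    ax.set_xlabel("token")
    ax.set_ylabel("median RT (ms)")
    ax.legend()
    fig.savefig(figdir / "rt_profile.png", dpi=110)
    plt.close(fig)

    # mean endpoint tracks
    fig, ax = plt.subplots(figsize=(5, 4))
    end = trials[trials["token"].isin((1, 7))]
    for (snr, order_group), color in zip(
            [("clean", ("random",)), ("clean", ("forward", "reverse")),
             ("0dB", ("random",)), ("0dB", ("forward", "reverse"))],
            ("C0", "C1", "C2", "C3")):
        sub = end[(end["snr"] == snr) & end["order"].isin(order_group)]
        tracks = []
        for _, g in sub.groupby(["subject_id", "block_id", "trial_index"], observed=True):
            g = g.sort_values("sample_t_ms")
            side = "left" if g["response"].iloc[0] == "u" else "right"
            tr = mt.time_normalize(g["sample_x"].to_numpy(),
                                   g["sample_y"].to_numpy(),
                                   T=cfg.timepoints, target_side=side)
            tracks.append(mt.mirror_track(tr) if side == "left" else tr)
        if tracks:
            mean = mt.pooled_mean(tracks)
            label = f"{snr} {'serial' if len(order_group) == 2 else 'random'}"
            ax.plot(mean.x, mean.y, color=color, label=label)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.savefig(figdir / "mean_tracks.png", dpi=110)
    plt.close(fig)

    # proximity curves
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax2, snr in zip(axes, ("clean", "0dB")):
        sub = prox[prox["snr"] == snr]
        for order in ("random", "serial"):
            g = sub[sub["order"] == order]
            m = g.groupby("t_star", observed=True)["proximity"].mean()
            ax2.plot(m.index, m.values, label=order)
        ax2.set_title(snr)
        ax2.set_xlabel("normalized time")
        ax2.legend()
    axes[0].set_ylabel("proximity to target")
    fig.savefig(figdir / "proximity.png", dpi=110)
    plt.close(fig)

    # warping correlation scatter
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax2, snr in zip(axes, ("clean", "0dB")):
        path = out / f"warping_subjects_{snr}.csv"
        if path.exists():
            tab = pd.read_csv(path)
            ax2.scatter(tab["abs_delta_beta0"], np.abs(tab["delta_auc"]))
            ax2.set_title(snr)
            ax2.set_xlabel("|delta beta0| (tokens)")
    axes[0].set_ylabel("|delta a.u.c.|")
    fig.savefig(figdir / "warping_correlation.png", dpi=110)
    plt.close(fig)


def _report(cfg: RunConfig, out: Path, fits: pd.DataFrame,
            runs_report: dict, results: dict) -> None:
    lines = [
        "# warpkit run report",
        "",
        f"config hash: `{cfg.config_hash}`; seed {cfg.seed}; "
        f"{cfg.n_subjects} subjects; "
        f"{cfg.design.trials_per_block} trials/block.",
        "",
        "## 1. Behavioral identification",
        "",
        "```",
        fits[fits["order"].isin(["random", "serial"])]
        .groupby(["snr", "order"], observed=True)[["beta0", "beta1"]]
        .mean().round(3).to_string(),
        "```",
        "",
        "## 2. Reaction times",
        "",
        "```",
        results["anova_rt"].round(4).to_string(index=False),
        "```",
        "",
        "## 3. Trajectory curvature (a.u.c.)",
        "",
        "```",
        results["anova_auc"].round(4).to_string(index=False),
        "```",
        "",
        "## 4. Proximity over normalized time",
        "",
        "```json",
        json.dumps(runs_report["comparisons"], indent=2, sort_keys=True),
        "```",
        "",
        "## 5. Warping correlations",
        "",
        "```",
        results["correlations"].round(4).to_string(index=False),
        "```",
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))


def run_all(cfg: RunConfig, outdir: Path | str, resume: bool = False) -> Path:
    """Execute every stage into ``outdir``; returns the run directory.

    With ``resume``, stages whose trial log already exists reuse it instead
    of resimulating (downstream stages always recompute from the stored
    upstream files, so re-running a stage never mutates its inputs).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl")
    (out / "config.json").write_text(cfg.to_json())
    (out / "manifest.json").write_text(json.dumps(
        {"config_hash": cfg.config_hash, "seed": cfg.seed}, indent=2,
        sort_keys=True))

    if cfg.synth_audio:
        _stage_synth(cfg, out, log)
    if resume and (out / "trials.csv").exists():
        trials = read_trial_log(out / "trials.csv")
        log.emit("simulate", resumed=True)
    else:
        trials = _stage_simulate(cfg, out, log)
    fits = _stage_psychometrics(cfg, out, trials, log)
    geom, prox, runs_report = _stage_mousetrack(cfg, out, trials, log)
    results = _stage_stats(cfg, out, fits, geom, log)
    if cfg.make_figures:
        _figures(cfg, out, trials, fits, geom, prox)
    _report(cfg, out, fits, runs_report, results)
    log.emit("done", config_hash=cfg.config_hash)
    return out
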