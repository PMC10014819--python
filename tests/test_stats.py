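"""Repeated-measures ANOVA, Holm contrasts, warping correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from warpkit.stats import rm_anova, holm_contrasts, pearson, warping_correlation


def _long_frame(data, factors):
    """data: array (n_subjects, l1, l2, ...) -> long frame."""
    n = data.shape[0]
    rows = []
    levels = [range(k) for k in data.shape[1:]]
    for s in range(n):
        for combo in itertools.product(*levels):
            rows.append({"subject_id": f"S{s}", "y": data[(s, *combo)],
                         **{f: f"{f}{c}" for f, c in zip(factors, combo)}})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_constant_cells_give_zero_f(self):
        data = np.full((6, 2, 3), 5.0)
        out = rm_anova(_long_frame(data, ["a", "b"]), "y", ["a", "b"])
        assert (out["F"] == 0).all()
        assert (out["p"] == 1).all()

    def test_two_level_f_equals_paired_t_squared(self, rng):
        data = rng.standard_normal((12, 2))
        df = _long_frame(data, ["cond"])
        out = rm_anova(df, "y", ["cond"])
        t, p = sps.ttest_rel(data[:, 0], data[:, 1])
        assert out["F"].iloc[0] == pytest.approx(t**2, rel=1e-9)
        assert out["p"].iloc[0] == pytest.approx(p, rel=1e-9)
        assert out["df1"].iloc[0] == 1 and out["df2"].iloc[0] == 11

    def test_sums_of_squares_decompose_total(self, rng):
        data = rng.standard_normal((8, 2, 4, 3))
        df = _long_frame(data, ["a", "b", "c"])
        out = rm_anova(df, "y", ["a", "b", "c"])
        grand = data.mean()
        ss_total = np.sum((data - grand) ** 2)
        ss_subject = np.sum(
            (data.mean(axis=(1, 2, 3)) - grand) ** 2) * np.prod(data.shape[1:])
        ss_model = out["SS_effect"].sum() + out["SS_error"].sum()
        assert ss_model + ss_subject == pytest.approx(ss_total, rel=1e-9)

    def test_matches_pingouin_two_way(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.standard_normal((10, 2, 3)) + \
            np.arange(3) * 0.5  # a main effect on the second factor
        df = _long_frame(data, ["a", "b"])
        ours = rm_anova(df, "y", ["a", "b"]).set_index("effect")
        theirs = pg.rm_anova(data=df, dv="y", within=["a", "b"],
                             subject="subject_id", detailed=True)
        p_col = "p_unc" if "p_unc" in theirs.columns else "p-unc"
        for eff_ours, eff_pg in [("a", "a"), ("b", "b"), ("a:b", "a * b")]:
            row = theirs[theirs["Source"] == eff_pg].iloc[0]
            assert ours.loc[eff_ours, "F"] == pytest.approx(row["F"],
                                                            rel=1e-6)
            assert ours.loc[eff_ours, "p"] == pytest.approx(row[p_col],
                                                            rel=1e-6)

    def test_incomplete_subject_dropped_with_warning(self, rng):
        data = rng.standard_normal((5, 2, 2))
        df = _long_frame(data, ["a", "b"])
        df = df[~((df["subject_id"] == "S0") & (df["a"] == "a0")
                  & (df["b"] == "b0"))]
        with pytest.warns(UserWarning, match="S0"):
            out = rm_anova(df, "y", ["a", "b"])
        assert out["df2"].iloc[0] == 3  # 4 remaining subjects

    def test_single_subject_rejected(self):
        df = _long_frame(np.zeros((1, 2)), ["a"])
        with pytest.raises(ValueError):
            rm_anova(df, "y", ["a"])

    def test_p_values_uniform_under_null(self):
        """KS check: two-level within-subject F test has uniform p under
        the null."""
        r = np.random.default_rng(7)
        pvals = []
        for _ in range(2000):
            d = r.standard_normal(10)  # paired differences
            t = d.mean() / (d.std(ddof=1) / np.sqrt(10))
            pvals.append(2 * sps.t.sf(abs(t), 9))
        stat, p = sps.kstest(pvals, "uniform")
        assert p > 0.01

    def test_interaction_power_on_simulated_curvature(self):
        """The snr x order interaction the observer generates is detected
        in at least 80% of simulated experiments."""
        from warpkit.observer import ObserverParams, PopulationParams, \
            simulate_trajectory
        from warpkit.mousetrack import time_normalize, compute_auc
        root = np.random.SeedSequence(99)
        detected = 0
        n_sims = 25
        for sim_seq in root.spawn(n_sims):
            rng = np.random.default_rng(sim_seq)
            pop = PopulationParams()
            rows = []
            for s in range(29):
                params = pop.sample(rng)
                p_end = 1.0 / (1.0 + np.exp(-params.beta1 * 3.0))
                for snr in ("clean", "0dB"):
                    for order in ("random", "serial"):
                        sin = order == "serial" and snr == "0dB"
                        aucs = []
                        for _ in range(15):  # endpoint trials per cell
                            traj = simulate_trajectory(
                                params, p_end, "a", 700.0, rng,
                                serial_in_noise=sin)
                            tr = time_normalize(traj.x, traj.y)
                            aucs.append(compute_auc(tr).auc_absolute)
                        rows.append({"subject_id": f"S{s}", "snr": snr,
                                     "order": order,
                                     "auc": float(np.mean(aucs))})
            out = rm_anova(pd.DataFrame(rows), "auc", ["snr", "order"])
            p_int = out.set_index("effect").loc["snr:order", "p"]
            detected += int(p_int < 0.05)
        assert detected >= 0.8 * n_sims


class TestHolmContrasts:
    def test_single_pair_adjusted_equals_raw(self, rng):
        data = rng.standard_normal((9, 2))
        out = holm_contrasts(_long_frame(data, ["a"]), "y", "a")
        assert len(out) == 1
        assert out["p_holm"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_identical_levels_all_p_one(self):
        data = np.tile(np.arange(6.0)[:, None], (1, 3))
        out = holm_contrasts(_long_frame(data, ["a"]), "y", "a")
        assert (out["p_holm"] == 1.0).all()

    def test_step_down_rule_reproduced_by_enumeration(self, rng):
        """Holm on k=3 contrasts equals the hand-applied step-down rule."""
        data = rng.standard_normal((12, 3))
        data[:, 1] += 1.0
        data[:, 2] += 0.4
        out = holm_contrasts(_long_frame(data, ["a"]), "y", "a")
        raw = out["p_raw"].to_numpy()
        order = np.argsort(raw)
        adj = np.empty(3)
        running_max = 0.0
        for rank, idx in enumerate(order):
            val = min(1.0, (3 - rank) * raw[idx])
            running_max = max(running_max, val)
            adj[idx] = running_max
        np.testing.assert_allclose(out["p_holm"].to_numpy(), adj, rtol=1e-12)


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-9

    def test_constant_input_flagged(self):
        res = pearson(np.ones(8), np.arange(8.0))
        assert np.isnan(res.r)
        assert "constant_input" in res.flags

    def test_null_rejection_rate_calibrated(self):
        r = np.random.default_rng(31)
        hits = 0
        n_sims = 2000
        for _ in range(n_sims):
            res = pearson(r.standard_normal(29), r.standard_normal(29))
            hits += int(res.p < 0.05)
        assert hits / n_sims == pytest.approx(0.05, abs=0.015)

    def test_warping_correlation_pipeline_shapes(self):
        fits = pd.DataFrame([
            {"subject_id": f"S{i}", "snr": "0dB", "order": o,
             "beta0": 4 + (0.1 * i if o == "serial" else 0.0), "beta1": 1.5}
            for i in range(6) for o in ("random", "serial")])
        geom = pd.DataFrame([
            {"subject_id": f"S{i}", "snr": "0dB", "order": o, "token": t,
             "auc_absolute": 0.1 - (0.01 * i if o != "random" else 0.0),
             "rt_ms": 800.0}
            for i in range(6) for o in ("random", "forward")
            for t in (1, 4, 7)])
        res = warping_correlation(fits, geom, "0dB")
        # |delta beta0| grows with i and so does |delta auc|: r == 1
        assert res["warp_vs_auc"].r == pytest.approx(1.0)
        assert len(res["table"]) == 6

    def test_warping_correlation_needs_four_subjects(self):
        fits = pd.DataFrame([{"subject_id": "S0", "snr": "0dB",
                              "order": o, "beta0": 4.0} for o in
                             ("random", "serial")])
        geom = pd.DataFrame([{"subject_id": "S0", "snr": "0dB",
                              "order": "random", "token": 1,
                              "auc_absolute": 0.1, "rt_ms": 500.0}])
        with pytest.raises(ValueError):
            warping_correlation(fits, geom, "0dB")
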