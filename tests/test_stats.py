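import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from actisym.stats import (
    cycle_associations,
    fit_symptom_lmm,
    intra_person_corr,
    partial_corr,
    rmcorr,
    surgical_change,
)


def brute_force_rmcorr(x, y, subject):
    """ANCOVA by explicit design-matrix least squares (test oracle)."""
    df = pd.DataFrame({"x": x, "y": y, "s": subject}).dropna()
    df = df[df.groupby("s")["x"].transform("size") >= 2]
    subs = sorted(df["s"].unique())
    D = np.column_stack([(df["s"] == s).to_numpy(float) for s in subs])
    Xf = np.column_stack([D, df["x"].to_numpy()])
    yv = df["y"].to_numpy()
    bf, *_ = np.linalg.lstsq(Xf, yv, rcond=None)
    rss_full = float(np.sum((yv - Xf @ bf) ** 2))
    br, *_ = np.linalg.lstsq(D, yv, rcond=None)
    rss_red = float(np.sum((yv - D @ br) ** 2))
    ss_measure = rss_red - rss_full
    slope = bf[-1]
    r = np.sign(slope) * np.sqrt(ss_measure / (ss_measure + rss_full))
    dof = len(df) - len(subs) - 1
    from scipy import stats as sps
    f = ss_measure / (rss_full / dof)
    return float(r), dof, float(sps.f.sf(f, 1, dof))


def simulate_pairs(rng, n_subj=5, n_obs=20, r=0.5):
    xs, ys, ss = [], [], []
    for j in range(n_subj):
        x = rng.normal(0, 1, n_obs)
        y = r * x + np.sqrt(1 - r**2) * rng.normal(0, 1, n_obs) + rng.normal(0, 3)
        xs.append(x)
        ys.append(y)
        ss.extend([f"S{j}"] * n_obs)
    return np.concatenate(xs), np.concatenate(ys), np.array(ss)


class TestRmcorr:
    def test_perfect_within_subject(self):
        x = np.tile(np.arange(10.0), 3)
        sub = np.repeat(["a", "b", "c"], 10)
        offs = np.repeat([0.0, 5.0, -2.0], 10)
        res = rmcorr(x, x + offs, sub)
        assert res.r == pytest.approx(1.0)
        res_neg = rmcorr(x, -x + offs, sub)
        assert res_neg.r == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_ancova(self, seed):
        rng = np.random.default_rng(seed)
        x, y, s = simulate_pairs(rng)
        res = rmcorr(x, y, s)
        r_bf, df_bf, p_bf = brute_force_rmcorr(x, y, s)
        assert res.r == pytest.approx(r_bf, abs=1e-10)
        assert res.df == df_bf
        assert res.p == pytest.approx(p_bf, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        x, y, s = simulate_pairs(rng)
        res = rmcorr(x, y, s)
        ref = pingouin.rm_corr(
            data=pd.DataFrame({"x": x, "y": y, "s": s}), x="x", y="y", subject="s"
        )
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert res.df == int(ref["dof"].iloc[0])

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            rmcorr(np.ones(20), np.arange(20.0), np.repeat(["a", "b"], 10))


class TestIntraPersonCorr:
    def test_min_pairs_rule(self):
        x = np.arange(19.0)
        out = intra_person_corr(x, 2 * x, np.repeat("a", 19))
        assert not out.loc[0, "included"]
        assert out.loc[0, "reason"] == "too few pairs"

    def test_exact_linear(self):
        x = np.arange(20.0)
        out = intra_person_corr(x, 2 * x, np.repeat("a", 20))
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_constant_subject_excluded(self):
        out = intra_person_corr(np.ones(25), np.arange(25.0), np.repeat("a", 25))
        assert out.loc[0, "reason"] == "constant input"

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        out = intra_person_corr(x, y, np.repeat("a", 30))
        sx, sy = x - x.mean(), y - y.mean()
        expected = np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2))
        assert out.loc[0, "r"] == pytest.approx(expected, abs=1e-12)


class TestPartialCorr:
    def test_two_variables_equal_pairwise(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (50, 2)), columns=["a", "b"])
        pc = partial_corr(df)
        assert pc.loc["a", "b"] == pytest.approx(np.corrcoef(df["a"], df["b"])[0, 1], abs=1e-12)

    def test_three_variable_recursion(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (100, 3)), columns=["x", "y", "z"])
        pc = partial_corr(df)
        r = df.corr().to_numpy()
        rxy, rxz, rzy = r[0, 1], r[0, 2], r[2, 1]
        expected = (rxy - rxz * rzy) / np.sqrt((1 - rxz**2) * (1 - rzy**2))
        assert pc.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_confounder_removed(self, rng):
        n = 10_000
        z = rng.normal(0, 1, n)
        df = pd.DataFrame({
            "x": z + rng.normal(0, 1, n),
            "y": z + rng.normal(0, 1, n),
            "z": z,
        })
        pc = partial_corr(df)
        assert abs(pc.loc["x", "y"]) < 0.05

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.normal(0, 1, (80, 3)), columns=["x", "y", "z"])
        pc = partial_corr(df)
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z"])
        assert pc.loc["x", "y"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_singular_matrix_reported(self, rng):
        a = rng.normal(0, 1, 50)
        df = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(0, 1, 50)})
        with pytest.raises(ValueError, match="collinear"):
            partial_corr(df)


def simulate_lmm_data(rng, n_subj=40, n_days=28, beta=None, phi=0.5, su=0.5,
                      standardized_scale=True):
    """Simulate daily data from the random-intercept AR(1) model.

    With standardized_scale=True the variance components are chosen so the
    response has unit marginal variance, making the standardized
    coefficients equal to the simulation coefficients.
    """
    covs = ["global_pain", "m10", "m10_lag1", "sleep_min", "sleep_min_lag1",
            "waso_min", "waso_min_lag1", "sri"]
    b = np.zeros(8) if beta is None else np.asarray(beta, float)
    se2 = max(1.0 - su**2 - float(np.sum(b**2)), 0.1) if standardized_scale else 1.0
    se = np.sqrt(se2)
    rows = []
    for j in range(n_subj):
        X = rng.normal(0, 1, (n_days, 8))
        u = rng.normal(0, su)
        e = np.zeros(n_days)
        e[0] = rng.normal(0, se)
        for i in range(1, n_days):
            e[i] = phi * e[i - 1] + rng.normal(0, se * np.sqrt(1 - phi**2))
        y = X @ b + u + e
        for i in range(n_days):
            row = {"participant": f"S{j:02d}", "study_day": i, "global_bfi": y[i]}
            row.update(dict(zip(covs, X[i])))
            rows.append(row)
    return pd.DataFrame(rows)


class TestSymptomLmm:
    def test_recovers_coefficient_and_phi(self):
        rng = np.random.default_rng(5)
        est, phis = [], []
        for _ in range(5):
            df = simulate_lmm_data(rng, beta=[0, -0.30, 0, 0, 0, 0, 0, 0])
            fit = fit_symptom_lmm(df, "fatigue")
            est.append(fit.params["m10"])
            phis.append(fit.phi)
        assert abs(np.mean(est) - (-0.30)) < 0.05
        assert abs(np.mean(phis) - 0.5) < 0.1

    def test_null_coefficients_within_3se(self):
        rng = np.random.default_rng(6)
        df = simulate_lmm_data(rng, beta=np.zeros(8))
        fit = fit_symptom_lmm(df, "fatigue")
        assert fit.converged
        inside = (fit.params.drop("intercept").abs() < 3 * fit.bse.drop("intercept")).mean()
        assert inside >= 7 / 8

    def test_lag_construction_drops_first_day(self):
        rng = np.random.default_rng(7)
        df = simulate_lmm_data(rng, n_subj=4, n_days=10)
        df = df.drop(columns=["m10_lag1", "sleep_min_lag1", "waso_min_lag1"])
        fit = fit_symptom_lmm(df, "fatigue")
        # first day of each participant has no lag and is dropped
        assert fit.n_obs == 4 * 9

    def test_matches_r_nlme(self, tmp_path):
        rng = np.random.default_rng(8)
        df = simulate_lmm_data(rng, n_subj=10, n_days=15,
                               beta=[0, -0.3, 0, 0.2, 0, 0, 0, 0])
        covs = ["global_pain", "m10", "sleep_min"]
        fit = fit_symptom_lmm(df, "fatigue", covariates=covs)
        z = df.copy()
        for c in ["global_bfi"] + covs:
            z[c] = (z[c] - z[c].mean()) / z[c].std(ddof=1)
        csv = tmp_path / "d.csv"
        z.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(nlme))
        d <- read.csv("{csv}")
        m <- lme(global_bfi ~ global_pain + m10 + sleep_min, random = ~1 | participant,
                 correlation = corCAR1(form = ~study_day | participant),
                 data = d, method = "REML")
        cat(fixef(m), coef(m$modelStruct$corStruct, unconstrained = FALSE), sep = ",")
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().split(",")]
        r_beta, r_phi = vals[:4], vals[4]
        for ours, theirs in zip(fit.params.to_numpy(), r_beta):
            assert ours == pytest.approx(theirs, abs=2e-3)
        assert fit.phi == pytest.approx(r_phi, abs=0.02)


class TestCycleAssociations:
    def test_self_and_monotone(self, rng):
        x = rng.normal(0, 1, 30)
        df = pd.DataFrame({"a": x, "b": np.exp(x), "c": rng.normal(0, 1, 30)})
        out = cycle_associations(df, pairs=[("a", "b")])
        assert out.loc[0, "estimate"] == pytest.approx(1.0)
        assert out.loc[0, "strong"]

    def test_too_few_cycles_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 1, 3]})
        out = cycle_associations(df, pairs=[("a", "b")])
        assert np.isnan(out.loc[0, "estimate"])

    def test_no_adjustment_metadata(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (20, 2)), columns=["a", "b"])
        out = cycle_associations(df)
        assert out.attrs["multiple_comparison_adjustment"] == "none"


class TestSurgicalChange:
    def make_daily(self, n_pre=14, n_post=10, post_vals=0.2, pre_vals=1.0, pid="P1"):
        pre_dates = pd.date_range("2024-03-04", periods=n_pre, freq="D")
        post_dates = pd.date_range("2024-04-02", periods=n_post, freq="D")
        df = pd.DataFrame({
            "participant": pid,
            "cycle": [1] * n_pre + [2] * n_post,
            "date": list(pre_dates) + list(post_dates),
            "m10": [pre_vals] * n_pre + [post_vals] * n_post,
        })
        return df

    def surgery(self, pid="P1"):
        return pd.DataFrame([{"participant": pid, "surgery_date": pd.Timestamp("2024-04-01")}])

    def test_negative_delta_detected(self):
        res = surgical_change(self.make_daily(), self.surgery(), ["m10"])
        assert res.deltas.loc[0, "m10"] < 0

    def test_min_points_rule(self):
        daily = self.make_daily(n_post=2)
        res = surgical_change(daily, self.surgery(), ["m10"])
        assert np.isnan(res.deltas.loc[0, "m10"])
        assert res.excluded.loc[0, "reason"].startswith("only 2")

    def test_trajectory_coverage_rule(self):
        # 5 participants; post-op day 3 covered by only 2 of 5 (40%)
        frames, sdates = [], []
        for k in range(5):
            d = self.make_daily(pid=f"P{k}")
            if k >= 2:
                d = d[d["date"] != pd.Timestamp("2024-04-04")]  # drop post-op day 3
            frames.append(d)
            sdates.append({"participant": f"P{k}", "surgery_date": pd.Timestamp("2024-04-01")})
        res = surgical_change(pd.concat(frames), pd.DataFrame(sdates), ["m10"])
        days = set(res.trajectory["post_day"])
        assert 3 not in days
        assert 2 in days

    def test_scaled_range_and_affine_invariance(self):
        daily = self.make_daily()
        res1 = surgical_change(daily, self.surgery(), ["m10"])
        daily2 = daily.assign(m10=daily["m10"] * 50 + 7)
        res2 = surgical_change(daily2, self.surgery(), ["m10"])
        assert res1.deltas.loc[0, "m10"] == pytest.approx(res2.deltas.loc[0, "m10"], abs=1e-12)
        assert res1.trajectory["mean"].between(0, 1).all()
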