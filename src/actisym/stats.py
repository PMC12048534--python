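"""Within-person association statistics for daily symptom/actigraphy data.

* ``rmcorr`` — repeated-measures correlation via the ANCOVA formulation
  (subject as a factor, common slope): the common within-subject
  association pooled across participants, with df = n_obs - n_subjects - 1
  and a p-value from the F-ratio.
* ``intra_person_corr`` — per-participant Pearson correlations, reported
  only for participants with at least ``min_pairs`` complete pairs.
* ``partial_corr`` — partial correlations from the inverse correlation
  (precision) matrix; Spearman variant ranks first.
* ``fit_symptom_lmm`` — a random-intercept linear mixed model for daily
  fatigue (or pain) with same-day and previous-day activity/sleep
  covariates and a continuous-time AR(1) residual correlation indexed by
  study day (corr = phi^|Δdays|), fitted by restricted maximum
  likelihood.  All variables are z-standardized over included rows.
* ``cycle_associations`` — Spearman (partial) correlations between
  cycle-level summaries, flagged as "strong" at |R| > 0.3; no multiple-
  comparison adjustment is applied (exploratory convention).
* ``surgical_change`` — pre/post-surgery deltas of min-max-scaled daily
  measures (baseline cycle vs the 10 days after surgery) and the cohort
  mean post-operative trajectory restricted to days covered by at least
  half the participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "RmcorrResult",
    "LmmFit",
    "rmcorr",
    "intra_person_corr",
    "partial_corr",
    "fit_symptom_lmm",
    "cycle_associations",
    "surgical_change",
]

STRONG_R = 0.3


@dataclass
class RmcorrResult:
    r: float
    df: int
    p: float
    n_subjects: int
    n_obs: int


def rmcorr(x, y, subject) -> RmcorrResult:
    """Repeated-measures correlation (ANCOVA with subject factor).

    Rows with a missing x or y are excluded; subjects retaining fewer
    than two complete pairs are dropped.  The coefficient is the
    correlation of the within-subject-centered x and y, its sign that of
    the common slope; df = n_obs - n_subjects - 1.
    """
    df_in = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float), "s": subject})
    df_in = df_in.dropna()
    counts = df_in.groupby("s")["x"].transform("size")
    df_in = df_in[counts >= 2]
    k = df_in["s"].nunique()
    n = len(df_in)
    if k < 2:
        raise ValueError("rmcorr requires at least 2 subjects with >= 2 complete pairs")
    xc = df_in["x"] - df_in.groupby("s")["x"].transform("mean")
    yc = df_in["y"] - df_in.groupby("s")["y"].transform("mean")
    sxx = float((xc**2).sum())
    syy = float((yc**2).sum())
    sxy = float((xc * yc).sum())
    if sxx == 0 or syy == 0:
        raise ValueError("no within-subject variation in x or y")
    r = sxy / np.sqrt(sxx * syy)
    dof = n - k - 1
    with np.errstate(divide="ignore"):
        f = r**2 * dof / (1 - r**2) if abs(r) < 1 else np.inf
    p = float(sps.f.sf(f, 1, dof))
    return RmcorrResult(r=float(r), df=dof, p=p, n_subjects=k, n_obs=n)


def intra_person_corr(x, y, subject, min_pairs: int = 20) -> pd.DataFrame:
    """Per-subject Pearson correlations with the >= min_pairs inclusion rule.

    Returns a table (subject, r, n, included, reason); excluded subjects
    carry the exclusion reason ('too few pairs' or 'constant input').
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float), "s": subject}).dropna()
    rows = []
    for s, grp in df.groupby("s"):
        n = len(grp)
        if n < min_pairs:
            rows.append({"subject": s, "r": np.nan, "n": n, "included": False, "reason": "too few pairs"})
            continue
        if grp["x"].nunique() == 1 or grp["y"].nunique() == 1:
            rows.append({"subject": s, "r": np.nan, "n": n, "included": False, "reason": "constant input"})
            continue
        r = float(np.corrcoef(grp["x"], grp["y"])[0, 1])
        rows.append({"subject": s, "r": r, "n": n, "included": True, "reason": ""})
    return pd.DataFrame(rows)


def partial_corr(data: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Partial correlation matrix, each pair controlling for all others.

    Complete-case rows only; from the correlation matrix R the precision
    P = R^-1 gives partial r_ij = -P_ij / sqrt(P_ii P_jj).  The Spearman
    variant ranks columns first.
    """
    df = data.dropna()
    k = df.shape[1]
    if len(df) < k + 2:
        raise ValueError("need at least k+2 complete rows for k variables")
    vals = df.rank().to_numpy(float) if method == "spearman" else df.to_numpy(float)
    corr = np.corrcoef(vals, rowvar=False)
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0 or logdet < -30:
        sds = df.std()
        bad = list(df.columns[sds == 0]) or list(df.columns)
        raise ValueError(f"singular correlation matrix; collinear variables: {bad}")
    prec = np.linalg.inv(corr)
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    return pd.DataFrame(pcorr, index=df.columns, columns=df.columns)


@dataclass
class LmmFit:
    params: pd.Series  # fixed effects
    bse: pd.Series
    pvalues: pd.Series
    phi: float  # AR(1) parameter per day
    var_intercept: float
    var_resid: float
    converged: bool
    n_obs: int
    n_subjects: int
    loglik: float = float("nan")


def _reml_neg_loglik(theta, groups, X_all, y_all):
    """Negative REML log-likelihood; theta = (log su2, log se2, atanh-ish phi)."""
    su2 = np.exp(theta[0])
    se2 = np.exp(theta[1])
    phi = np.tanh(theta[2])
    p = X_all.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    solves = []
    for idx, tdays in groups:
        Xj = X_all[idx]
        yj = y_all[idx]
        dist = np.abs(tdays[:, None] - tdays[None, :])
        # continuous-time AR(1): corr = phi^|Δt| (sign handled for integer lags)
        V = su2 * np.ones_like(dist) + se2 * (np.sign(phi) ** dist) * (np.abs(phi) ** dist)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e10
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        Zx = np.linalg.solve(L, Xj)
        Zy = np.linalg.solve(L, yj)
        XtVX += Zx.T @ Zx
        XtVy += Zx.T @ Zy
        solves.append((Zy, Zx))
    sign, ld_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return 1e10
    beta = np.linalg.solve(XtVX, XtVy)
    quad = 0.0
    for Zy, Zx in solves:
        resid = Zy - Zx @ beta
        quad += float(resid @ resid)
    return 0.5 * (logdet + ld_xvx + quad)


def _fit_reml(X, y, subject_idx, days, start=None):
    groups = []
    for s in np.unique(subject_idx):
        idx = np.nonzero(subject_idx == s)[0]
        groups.append((idx, days[idx]))
    x0 = start if start is not None else np.array([np.log(0.25), np.log(0.75), np.arctanh(0.3)])
    res = optimize.minimize(
        _reml_neg_loglik, x0, args=(groups, X, y), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    su2, se2, phi = np.exp(res.x[0]), np.exp(res.x[1]), float(np.tanh(res.x[2]))
    # recompute beta and covariance at the optimum
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    for idx, tdays in groups:
        dist = np.abs(tdays[:, None] - tdays[None, :])
        V = su2 * np.ones_like(dist) + se2 * (np.sign(phi) ** dist) * (np.abs(phi) ** dist)
        L = np.linalg.cholesky(V)
        Zx = np.linalg.solve(L, X[idx])
        Zy = np.linalg.solve(L, y[idx])
        XtVX += Zx.T @ Zx
        XtVy += Zx.T @ Zy
    cov = np.linalg.inv(XtVX)
    beta = cov @ XtVy
    return beta, cov, phi, su2, se2, res.success, -res.fun


LMM_COVARIATES = {
    "fatigue": ["global_pain", "m10", "m10_lag1", "sleep_min", "sleep_min_lag1",
                "waso_min", "waso_min_lag1", "sri"],
    "pain": ["global_bfi", "m10", "m10_lag1", "sleep_min", "sleep_min_lag1",
             "waso_min", "waso_min_lag1", "sri"],
}


def fit_symptom_lmm(
    daily: pd.DataFrame,
    response: str = "fatigue",
    covariates: list[str] | None = None,
    day_col: str = "study_day",
) -> LmmFit:
    """Random-intercept mixed model with continuous-time AR(1) residuals.

    ``daily`` carries one row per participant-day with the response
    (global_bfi for fatigue, global_pain for pain), the covariates
    including lagged columns (suffix ``_lag1``; the caller builds lags,
    or they are derived here by shifting within participant when absent),
    and ``study_day`` (days since enrollment) for the AR(1) distance.
    All variables are z-standardized over the included (complete-case)
    rows before fitting; estimation is by REML.
    """
    y_col = {"fatigue": "global_bfi", "pain": "global_pain"}.get(response, response)
    covs = covariates if covariates is not None else LMM_COVARIATES.get(response)
    if covs is None:
        raise ValueError(f"unknown response {response!r} and no covariates supplied")
    df = daily.copy().sort_values(["participant", day_col])
    for c in covs:
        if c.endswith("_lag1") and c not in df.columns:
            base = c[:-5]
            lag = df.groupby("participant")[base].shift(1)
            gap = df.groupby("participant")[day_col].diff()
            df[c] = lag.where(gap == 1)  # lag must be the actual previous day
    cols = [y_col] + covs
    df = df.dropna(subset=cols + [day_col])
    if df["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    z = (df[cols] - df[cols].mean()) / df[cols].std(ddof=1)
    X = np.column_stack([np.ones(len(df)), z[covs].to_numpy()])
    y = z[y_col].to_numpy()
    subj, _ = pd.factorize(df["participant"])
    days = df[day_col].to_numpy(float)
    beta, cov, phi, su2, se2, ok, ll = _fit_reml(X, y, subj, days)
    names = ["intercept"] + covs
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2 * sps.norm.sf(np.abs(zstat))
    return LmmFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        phi=phi,
        var_intercept=float(su2),
        var_resid=float(se2),
        converged=bool(ok),
        n_obs=len(df),
        n_subjects=int(df["participant"].nunique()),
        loglik=float(ll),
    )


def cycle_associations(
    summaries: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    control: list[str] | None = None,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman (optionally partial) associations between cycle summaries.

    ``summaries`` is wide: one row per cycle (or participant), columns are
    variables.  With ``control`` given, each pair is a partial Spearman
    correlation controlling for those covariates.  Results carry a
    ``strong`` flag at |R| > 0.3 and metadata noting that no multiple-
    comparison adjustment was applied.
    """
    cols = list(summaries.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]
                 if a not in (control or []) and b not in (control or [])]
    rows = []
    for a, b in pairs:
        use = [a, b] + (control or [])
        sub = summaries[use].dropna()
        n = len(sub)
        if n < max(min_n, len(use) + 2):
            rows.append({"variable_x": a, "variable_y": b, "estimate": np.nan, "p": np.nan,
                         "n": n, "strong": False})
            continue
        if control:
            pc = partial_corr(sub, method="spearman")
            est = float(pc.loc[a, b])
            # t-test on the partial coefficient with n - k - 2 df
            dof = n - len(control) - 2
            t = est * np.sqrt(dof / max(1e-12, 1 - est**2))
            p = float(2 * sps.t.sf(abs(t), dof))
        else:
            est, p = sps.spearmanr(sub[a], sub[b])
            est, p = float(est), float(p)
        rows.append({"variable_x": a, "variable_y": b, "estimate": est, "p": p,
                     "n": n, "strong": abs(est) > STRONG_R})
    out = pd.DataFrame(rows)
    out.attrs["multiple_comparison_adjustment"] = "none"
    return out


@dataclass
class SurgicalChange:
    deltas: pd.DataFrame  # participant x measure deltas on the min-max scale
    excluded: pd.DataFrame  # participant, measure, reason
    trajectory: pd.DataFrame  # post-op day, measure, cohort mean, coverage


def surgical_change(
    daily: pd.DataFrame,
    surgery_dates: pd.DataFrame,
    measures: list[str],
    post_days: int = 10,
    min_points: int = 3,
    min_coverage: float = 0.5,
    baseline_cycle: int = 1,
) -> SurgicalChange:
    """Pre/post-surgery change analysis on min-max-scaled daily measures.

    Each measure is min-max scaled over all daily data from all
    participants.  Per participant the delta is the mean over post-op
    days 1..10 minus the mean over the baseline cycle; participants with
    fewer than 3 post-op points for a measure are excluded.  The cohort
    trajectory keeps only post-op days with data from at least 50% of the
    included participants.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    scaled = {}
    for m in measures:
        lo, hi = df[m].min(), df[m].max()
        scaled[m] = (df[m] - lo) / (hi - lo) if hi > lo else df[m] * np.nan
    sc = df[["participant", "cycle", "date"]].assign(**scaled)
    sdates = {r.participant: pd.Timestamp(r.surgery_date).normalize()
              for r in surgery_dates.itertuples() if pd.notna(r.surgery_date)}
    delta_rows, excl_rows, traj_frames = [], [], []
    for pid, sday in sdates.items():
        sub = sc[sc["participant"] == pid]
        post = sub[(sub["date"] > sday) & (sub["date"] <= sday + pd.Timedelta(days=post_days))]
        base = sub[sub["cycle"] == baseline_cycle]
        base = base[base["date"] <= sday]
        row = {"participant": pid}
        for m in measures:
            npost = post[m].notna().sum()
            if npost < min_points:
                excl_rows.append({"participant": pid, "measure": m,
                                  "reason": f"only {npost} post-op points"})
                row[m] = np.nan
                continue
            if base[m].notna().sum() == 0:
                excl_rows.append({"participant": pid, "measure": m, "reason": "no baseline data"})
                row[m] = np.nan
                continue
            row[m] = float(post[m].mean() - base[m].mean())
        delta_rows.append(row)
        t = post.assign(post_day=(post["date"] - sday).dt.days)[["post_day"] + measures]
        t["participant"] = pid
        traj_frames.append(t)
    deltas = pd.DataFrame(delta_rows)
    n_participants = len(sdates)
    traj_rows = []
    if traj_frames:
        allt = pd.concat(traj_frames)
        for m in measures:
            g = allt.groupby("post_day")[m]
            cover = g.apply(lambda s: s.notna().sum()) / max(n_participants, 1)
            means = g.mean()
            for day in means.index:
                if cover[day] >= min_coverage:
                    traj_rows.append({"post_day": int(day), "measure": m,
                                      "mean": float(means[day]), "coverage": float(cover[day])})
    return SurgicalChange(
        deltas=deltas,
        excluded=pd.DataFrame(excl_rows, columns=["participant", "measure", "reason"]),
        trajectory=pd.DataFrame(traj_rows, columns=["post_day", "measure", "mean", "coverage"]),
    )
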