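"""Repeated-measures statistical battery for masticatory-performance cohorts.

Implements the analysis chain applied to a 3-session cohort table:
systematic-error paired t-test, normality screening (Lilliefors KS +
Shapiro-Wilk), the age/consumption eta-squared association, Mauchly's
sphericity test with Greenhouse-Geisser / Huynh-Feldt epsilons, the 3x3
split-plot ("mixed") ANOVA with sphericity-corrected degrees of freedom and
Type III sums of squares, Bonferroni pairwise session contrasts on estimated
marginal means, Levene's homogeneity test, the heteroscedastic Welch F
one-way ANOVA with Games-Howell pairwise comparisons, and a normal/identity
GEE with robust sandwich covariance.

Conventions follow the mainstream commercial implementation of these
procedures (pooled within-group covariance for sphericity and EMM standard
errors, Type III sums of squares, unweighted marginal means), so results are
comparable with published tables produced that way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

__all__ = [
    "descriptives", "paired_t", "eta_squared", "normality_battery",
    "mauchly", "mixed_anova", "bonferroni_pairwise", "levene",
    "welch_anova", "games_howell", "fit_gee",
    "SphericityResult", "MixedAnovaResult", "GEEResult",
]

_K_SESSIONS = 3


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _wide(cohort: pd.DataFrame):
    """(subjects x 3 sessions) outcome matrix plus per-subject group labels."""
    wide = cohort.pivot(index="subject_id", columns="session", values="vhh")
    if wide.isna().any().any() or set(wide.columns) != {1, 2, 3}:
        raise ValueError("cohort must have exactly one vhh per subject per session 1..3")
    wide = wide[[1, 2, 3]]
    groups = (cohort.drop_duplicates("subject_id").set_index("subject_id")
              .loc[wide.index, "cgc"].to_numpy())
    return wide.to_numpy(dtype=float), groups, wide.index.to_numpy()


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) matrix with orthonormal columns orthogonal to the unit vector."""
    helmert = np.zeros((k, k - 1))
    for j in range(1, k):
        helmert[:j, j - 1] = 1.0
        helmert[j, j - 1] = -j
        helmert[:, j - 1] /= np.linalg.norm(helmert[:, j - 1])
    return helmert


def _pooled_within_cov(y: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, int]:
    """Pooled within-group covariance of the session vectors, df = N - g."""
    levels = np.unique(groups)
    n, k = y.shape
    s = np.zeros((k, k))
    for lv in levels:
        sub = y[groups == lv]
        if len(sub) < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 subjects")
        s += (len(sub) - 1) * np.cov(sub, rowvar=False)
    return s / (n - len(levels)), n - len(levels)


def _sum_coded(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-zero coded group dummies (g-1 columns) and the level array."""
    levels = np.unique(groups)
    g = len(levels)
    x = np.zeros((len(groups), g - 1))
    for j, lv in enumerate(levels[:-1]):
        x[groups == lv, j] = 1.0
    x[groups == levels[-1], :] = -1.0
    return x, levels


def _ss_res(x: np.ndarray, y: np.ndarray) -> float:
    if x.shape[1] == 0:
        return float((y ** 2).sum())
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return float(((y - x @ beta) ** 2).sum())


# --------------------------------------------------------------------------
# descriptives / simple tests
# --------------------------------------------------------------------------

def descriptives(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per (CGC, SESSION) cell: n, min, max, mean, sd of vhh plus the cell's
    subject age distribution (ages repeat across sessions within a CGC)."""
    rows = []
    for (cgc, session), cell in cohort.groupby(["cgc", "session"]):
        v, a = cell["vhh"], cell["age"]
        if len(cell) == 0:
            continue
        rows.append({
            "cgc": cgc, "session": session, "n": len(cell),
            "vhh_min": v.min(), "vhh_max": v.max(),
            "vhh_mean": v.mean(), "vhh_sd": v.std(ddof=1) if len(v) > 1 else 0.0,
            "age_min": a.min(), "age_max": a.max(),
            "age_mean": a.mean(), "age_sd": a.std(ddof=1) if len(a) > 1 else 0.0,
        })
    full = [{"cgc": c, "session": s} for c in sorted(cohort["cgc"].unique())
            for s in (1, 2, 3)]
    out = pd.DataFrame(full).merge(pd.DataFrame(rows), how="left",
                                   on=["cgc", "session"])
    out["n"] = out["n"].fillna(0).astype(int)
    return out


def paired_t(x, y) -> tuple[float, float]:
    """Paired t-test; identical vectors give (0, 1), zero-variance nonzero
    differences are reported as the degenerate (inf, 0) limit."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired t-test needs equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def eta_squared(values, groups) -> float:
    """eta^2 = SS_between / SS_total of ``values`` across group levels."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("eta_squared needs at least 2 groups")
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    ss_between = sum(((values[groups == lv].mean() - grand) ** 2) *
                     (groups == lv).sum() for lv in levels)
    return float(ss_between / ss_total) if ss_total > 0 else 0.0


def normality_battery(cohort: pd.DataFrame, grouping: list[str] | None = None
                      ) -> pd.DataFrame:
    """Lilliefors-corrected KS and Shapiro-Wilk per group of vhh values.

    ``grouping=None`` tests the pooled measurements.  Groups with n < 3 are
    skipped with a warning row; constant groups are flagged degenerate.
    """
    from statsmodels.stats.diagnostic import lilliefors

    if grouping:
        iterator = cohort.groupby(grouping)["vhh"]
    else:
        iterator = [(("all",), cohort["vhh"])]
    rows = []
    for key, v in iterator:
        key = key if isinstance(key, tuple) else (key,)
        row = {"group": "/".join(map(str, key)), "n": len(v)}
        v = np.asarray(v, float)
        if len(v) < 3:
            row["note"] = "skipped: n < 3"
        elif np.ptp(v) == 0:
            row["note"] = "degenerate: constant values"
        else:
            sw_stat, sw_p = sps.shapiro(v)
            row.update(sw_stat=float(sw_stat), sw_p=float(sw_p))
            if len(v) >= 4:  # estimated-parameter KS needs n >= 4
                ks_stat, ks_p = lilliefors(v, dist="norm")
                row.update(ks_stat=float(ks_stat), ks_p=float(ks_p))
            else:
                row["note"] = "KS skipped: n < 4"
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# sphericity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SphericityResult:
    W: float
    chi2: float
    df: int
    p: float
    eps_gg: float
    eps_hf: float
    eps_lower: float


def mauchly(cohort: pd.DataFrame) -> SphericityResult:
    """Mauchly's sphericity test plus the epsilon correction factors.

    W is computed from the covariance of orthonormal session contrasts of
    the pooled within-group covariance matrix; the chi-square approximation
    uses df = k(k-1)/2 - 1.  Greenhouse-Geisser epsilon comes from the same
    contrast covariance; Huynh-Feldt applies the between-group design
    correction (N total subjects, g groups) and is capped at 1.
    """
    y, groups, _ = _wide(cohort)
    n, k = y.shape
    g = len(np.unique(groups))
    if n <= k:
        raise ValueError("need more subjects than sessions")
    s_pool, df_err = _pooled_within_cov(y, groups)
    m = _orthonormal_contrasts(k)
    t = m.T @ s_pool @ m

    w = float(np.linalg.det(t) / (np.trace(t) / (k - 1)) ** (k - 1))
    d = 1.0 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6.0 * (k - 1) * df_err)
    chi2 = float(-df_err * d * np.log(max(w, np.finfo(float).tiny)))
    df = k * (k - 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))

    eps_gg = float(np.trace(t) ** 2 / ((k - 1) * np.trace(t @ t)))
    eps_hf = float((n * (k - 1) * eps_gg - 2)
                   / ((k - 1) * (n - g - (k - 1) * eps_gg)))
    return SphericityResult(W=w, chi2=chi2, df=df, p=p, eps_gg=eps_gg,
                            eps_hf=min(1.0, eps_hf),
                            eps_lower=1.0 / (k - 1))


# --------------------------------------------------------------------------
# mixed (split-plot) ANOVA
# --------------------------------------------------------------------------

@dataclass
class MixedAnovaResult:
    within: pd.DataFrame        # SESSION, SESSION*CGC, Error(SESSION) rows
    between: pd.DataFrame       # CGC, Error rows
    sphericity: SphericityResult
    correction: str             # "none" | "greenhouse-geisser" | "huynh-feldt"

    @property
    def table(self) -> pd.DataFrame:
        return pd.concat([self.within, self.between], ignore_index=True)


def _choose_correction(sph: SphericityResult, alpha: float = 0.05) -> str:
    if sph.p >= alpha:
        return "none"
    return "huynh-feldt" if sph.eps_gg > 0.75 else "greenhouse-geisser"


def mixed_anova(cohort: pd.DataFrame, correction: str = "auto") -> MixedAnovaResult:
    """3 (SESSION, within) x g (CGC, between) split-plot ANOVA.

    Type III sums of squares are obtained on orthonormal session-contrast
    scores with sum-coded group effects, which matches the unweighted-means
    (cell-means) decomposition for unbalanced group sizes.  The within-subject
    F statistics are unaffected by the sphericity correction; only their
    degrees of freedom (and hence p-values) are rescaled by epsilon.  The
    correction is chosen by the usual decision rule: none if Mauchly's test
    is not significant, Huynh-Feldt if eps_GG > 0.75, otherwise
    Greenhouse-Geisser.  Pass ``correction`` explicitly to override.
    """
    y, groups, _ = _wide(cohort)
    n, k = y.shape
    levels = np.unique(groups)
    g = len(levels)
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"CGC group {lv!r} has fewer than 2 subjects")

    sph = mauchly(cohort)
    if correction == "auto":
        correction = _choose_correction(sph)
    eps = {"none": 1.0, "greenhouse-geisser": sph.eps_gg,
           "huynh-feldt": sph.eps_hf, "lower-bound": sph.eps_lower}[correction]

    m = _orthonormal_contrasts(k)
    z = y @ m                                  # (n, k-1) within-contrast scores
    gsum, _ = _sum_coded(groups)
    ones = np.ones((n, 1))
    x_full = np.hstack([ones, gsum])

    ss_session = ss_inter = ss_err_w = 0.0
    for j in range(k - 1):
        zj = z[:, j]
        full = _ss_res(x_full, zj)
        ss_session += _ss_res(gsum, zj) - full
        ss_inter += _ss_res(ones, zj) - full
        ss_err_w += full

    df_s, df_i, df_e = (k - 1) * eps, (k - 1) * (g - 1) * eps, (k - 1) * (n - g) * eps
    ms_err = ss_err_w / df_e
    f_s = (ss_session / df_s) / ms_err
    f_i = (ss_inter / df_i) / ms_err
    within = pd.DataFrame([
        {"source": "SESSION", "SS": ss_session, "df": df_s, "MS": ss_session / df_s,
         "F": f_s, "p": float(sps.f.sf(f_s, df_s, df_e)),
         "partial_eta_sq": ss_session / (ss_session + ss_err_w)},
        {"source": "SESSION*CGC", "SS": ss_inter, "df": df_i, "MS": ss_inter / df_i,
         "F": f_i, "p": float(sps.f.sf(f_i, df_i, df_e)),
         "partial_eta_sq": ss_inter / (ss_inter + ss_err_w)},
        {"source": "Error(SESSION)", "SS": ss_err_w, "df": df_e, "MS": ms_err,
         "F": np.nan, "p": np.nan, "partial_eta_sq": np.nan},
    ])

    p_scores = y @ (np.ones(k) / np.sqrt(k))   # between-subject component
    full_b = _ss_res(x_full, p_scores)
    ss_cgc = _ss_res(ones, p_scores) - full_b
    f_b = (ss_cgc / (g - 1)) / (full_b / (n - g))
    between = pd.DataFrame([
        {"source": "CGC", "SS": ss_cgc, "df": float(g - 1), "MS": ss_cgc / (g - 1),
         "F": f_b, "p": float(sps.f.sf(f_b, g - 1, n - g)),
         "partial_eta_sq": ss_cgc / (ss_cgc + full_b)},
        {"source": "Error(between)", "SS": full_b, "df": float(n - g),
         "MS": full_b / (n - g), "F": np.nan, "p": np.nan,
         "partial_eta_sq": np.nan},
    ])
    return MixedAnovaResult(within=within, between=between, sphericity=sph,
                            correction=correction)


def bonferroni_pairwise(cohort: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise session contrasts on estimated marginal
    means (unweighted across CGC groups), with the pooled within-group
    session covariance supplying the standard errors (df = N - g)."""
    y, groups, _ = _wide(cohort)
    n, k = y.shape
    levels = np.unique(groups)
    g = len(levels)
    s_pool, df_err = _pooled_within_cov(y, groups)
    cell_means = np.stack([y[groups == lv].mean(axis=0) for lv in levels])
    emm = cell_means.mean(axis=0)              # unweighted across groups
    inv_n = sum(1.0 / (groups == lv).sum() for lv in levels)
    n_pairs = k * (k - 1) // 2

    rows = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            c = np.zeros(k)
            c[i], c[j] = 1.0, -1.0
            se = float(np.sqrt(max(c @ s_pool @ c, 0.0) * inv_n / g ** 2))
            diff = float(emm[i] - emm[j])
            if se == 0.0:  # noise-free degenerate limit
                t = np.inf if diff else 0.0
                p_adj = 0.0 if diff else 1.0
            else:
                t = diff / se
                p_adj = min(1.0, n_pairs * 2.0 * float(sps.t.sf(abs(t), df_err)))
            crit = float(sps.t.ppf(1.0 - alpha / (2.0 * n_pairs), df_err))
            rows.append({"level_i": i + 1, "level_j": j + 1, "mean_diff": diff,
                         "se": se, "p_adjusted": p_adj,
                         "ci_low": diff - crit * se, "ci_high": diff + crit * se})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# heteroscedastic one-way battery
# --------------------------------------------------------------------------

def levene(values, groups) -> tuple[float, float]:
    """Classic (mean-centred) Levene test of variance homogeneity."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("levene needs at least 2 groups")
    samples = [values[groups == lv] for lv in levels]
    f, p = sps.levene(*samples, center="mean")
    return float(f), float(p)


def _group_stats(values, groups):
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    ns, means, variances = [], [], []
    for lv in levels:
        v = values[groups == lv]
        if len(v) < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 observations")
        var = v.var(ddof=1)
        if var == 0:
            raise ValueError(f"group {lv!r} has zero variance")
        ns.append(len(v)); means.append(v.mean()); variances.append(var)
    return levels, np.array(ns), np.array(means), np.array(variances)


def welch_anova(values, groups) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way F test; returns (F, df1, df2, p)."""
    _, n, mean, var = _group_stats(values, groups)
    g = len(n)
    w = n / var
    mw = (w * mean).sum() / w.sum()
    a = (w * (mean - mw) ** 2).sum() / (g - 1)
    lam = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    b = 1.0 + 2.0 * (g - 2) / (g ** 2 - 1) * lam
    f = a / b
    df1 = g - 1.0
    df2 = (g ** 2 - 1.0) / (3.0 * lam)
    return float(f), df1, float(df2), float(sps.f.sf(f, df1, df2))


def games_howell(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (unequal variances and sizes).

    Each pair uses the Welch standard error and Welch-Satterthwaite df; the
    p-value and confidence interval come from the studentized range
    distribution with the full number of groups.
    """
    levels, n, mean, var = _group_stats(values, groups)
    g = len(levels)
    rows = []
    for i in range(g):
        for j in range(g):
            if i == j:
                continue
            vi, vj = var[i] / n[i], var[j] / n[j]
            se = np.sqrt(vi + vj)
            df = (vi + vj) ** 2 / (vi ** 2 / (n[i] - 1) + vj ** 2 / (n[j] - 1))
            diff = mean[i] - mean[j]
            q = abs(diff) / se * np.sqrt(2.0)
            p = float(np.clip(studentized_range.sf(q, g, df), 0.0, 1.0))
            q_crit = float(studentized_range.ppf(1.0 - alpha, g, df))
            half = q_crit / np.sqrt(2.0) * se
            rows.append({"level_i": levels[i], "level_j": levels[j],
                         "mean_diff": float(diff), "se": float(se),
                         "df": float(df), "p_adjusted": p,
                         "ci_low": float(diff - half),
                         "ci_high": float(diff + half)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# GEE
# --------------------------------------------------------------------------

@dataclass
class GEEResult:
    table: pd.DataFrame         # term, B, se, wald_ci_low/high, wald_chi2, df, p
    scale: float
    working_correlation: str
    dropped_terms: list[str] = field(default_factory=list)


def _gee_design(cohort: pd.DataFrame) -> pd.DataFrame:
    d = pd.DataFrame(index=cohort.index)
    d["Intercept"] = 1.0
    d["Sex"] = (cohort["sex"] == "male").astype(float)
    d["CGC=2"] = (cohort["cgc"] == 2).astype(float)
    d["CGC=1"] = (cohort["cgc"] == 1).astype(float)
    d["Dental Status"] = (cohort["dental_status"] == "artificial").astype(float)
    d["Session=3"] = (cohort["session"] == 3).astype(float)
    d["Session=2"] = (cohort["session"] == 2).astype(float)
    d["Age"] = cohort["age"].astype(float)
    for c in ("CGC=2", "CGC=1"):
        d[f"Sex*[{c}]"] = d["Sex"] * d[c]
    d["Sex*Dental Status"] = d["Sex"] * d["Dental Status"]
    d["Sex*Age"] = d["Sex"] * d["Age"]
    for c in ("CGC=1", "CGC=2"):
        d[f"[{c}]*Dental Status"] = d[c] * d["Dental Status"]
    for c in ("CGC=2", "CGC=1"):
        for s in ("Session=3", "Session=2"):
            d[f"[{c}]*[{s}]"] = d[c] * d[s]
    for c in ("CGC=2", "CGC=1"):
        d[f"[{c}]*Age"] = d[c] * d["Age"]
    for s in ("Session=3", "Session=2"):
        d[f"Dental Status*[{s}]"] = d["Dental Status"] * d[s]
    d["Dental Status*Age"] = d["Dental Status"] * d["Age"]
    for s in ("Session=3", "Session=2"):
        d[f"[{s}]*Age"] = d[s] * d["Age"]
    return d


def fit_gee(cohort: pd.DataFrame, working_correlation: str = "independent"
            ) -> GEEResult:
    """Marginal normal/identity-link GEE of vhh on the full covariate set.

    Subjects are the clusters (3 sessions each); standard errors are robust
    (sandwich).  Terms: main effects of sex, CGC (reference 0), dental
    status, session (reference 1) and age, plus all two-way interactions of
    the published model.  An interaction whose supporting cell is empty
    (e.g. no artificial-denture high consumers) is dropped and reported in
    ``dropped_terms``.  Wald chi-square = (B/se)^2 with df 1; 95% CIs are
    Wald intervals.
    """
    import statsmodels.api as sm

    x = _gee_design(cohort)
    dropped = [c for c in x.columns if c != "Intercept" and x[c].abs().sum() == 0]
    x = x.drop(columns=dropped)

    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # identify aliased columns by greedy rank growth
        aliased, cols = [], []
        for c in x.columns:
            trial = x[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols) + 1:
                cols.append(c)
            else:
                aliased.append(c)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    cov_struct = {
        "independent": sm.cov_struct.Independence,
        "exchangeable": sm.cov_struct.Exchangeable,
        "ar1": sm.cov_struct.Autoregressive,
    }[working_correlation]()
    y = cohort["vhh"].to_numpy(dtype=float)
    model = sm.GEE(y, x, groups=cohort["subject_id"].to_numpy(),
                   family=sm.families.Gaussian(), cov_struct=cov_struct)
    # parameter-change tolerance scaled to the outcome magnitude (vhh is at
    # the 1e7 scale, so an absolute 1e-6 criterion would never trigger)
    res = model.fit(ctol=1e-10 * (1.0 + float(np.std(y))))

    b, se = res.params, res.bse
    wald = (b / se) ** 2
    table = pd.DataFrame({
        "term": x.columns, "B": b.to_numpy(), "se": se.to_numpy(),
        "wald_ci_low": (b - 1.96 * se).to_numpy(),
        "wald_ci_high": (b + 1.96 * se).to_numpy(),
        "wald_chi2": wald.to_numpy(), "df": 1,
        "p": sps.chi2.sf(wald.to_numpy(), 1),
    })
    return GEEResult(table=table, scale=float(res.scale),
                     working_correlation=working_correlation,
                     dropped_terms=dropped)


def format_p(p: float, floor: float = 0.001) -> str:
    """Human-readable p-value: '<0.001' below the floor, 3 decimals above."""
    if np.isnan(p):
        return ""
    return f"<{floor}" if p < floor else f"{p:.3f}"
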