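"""Statistics on cognitive loads and behavior.

Two-way repeated-measures ANOVA (condition x linguistic component, both
within subject) with Bonferroni post hoc tests, the adjusted reaction
time (observed RT minus the estimated per-subject offset), and partial
Pearson correlations between loads and adjusted RT with Bonferroni
correction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    table: pd.DataFrame          # effect -> SS, df, MS, F, p
    cell_means: pd.DataFrame     # condition x component means and SEs
    posthoc: pd.DataFrame        # pairwise component contrasts within condition
    sphericity_correction: str   # "none" or "greenhouse-geisser"


@dataclass
class AssociationResult:
    table: pd.DataFrame          # per (condition, component) partial r and p
    family_size: int
    covariates: str


def _cell_pivot(loads: pd.DataFrame, value: str = "load") -> np.ndarray:
    """subjects x conditions x components array; errors on missing cells."""
    piv = loads.pivot_table(index="subject", columns=["condition", "component"],
                            values=value, aggfunc="mean")
    conds = sorted(loads["condition"].unique())
    comps = sorted(loads["component"].unique())
    full = pd.MultiIndex.from_product([conds, comps])
    piv = piv.reindex(columns=full)
    bad = piv.index[piv.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"incomplete condition x component cells for subjects {bad}")
    return piv.to_numpy().reshape(len(piv), len(conds), len(comps)), conds, comps, piv.index.tolist()


def rm_anova_two_way(
    loads: pd.DataFrame,
    value: str = "load",
    greenhouse_geisser: bool = False,
    posthoc_family: int | None = None,
) -> AnovaResult:
    """Classical two-way within-subject ANOVA on the load table.

    Strata: subject, condition (error: subject x condition), component
    (error: subject x component), interaction (error: residual).  Post hoc
    contrasts are paired t tests between components within each condition,
    Bonferroni-corrected over the pairwise family (family size recorded;
    default = the number of contrasts).  A Greenhouse-Geisser epsilon
    correction of the effect p values is available behind a flag.
    """
    Y, conds, comps, subjects = _cell_pivot(loads, value)
    s, a, b = Y.shape
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_total = ((Y - grand) ** 2).sum()
    ss_subj = a * b * ((m_s - grand) ** 2).sum()
    ss_a = s * b * ((m_a - grand) ** 2).sum()
    ss_b = s * a * ((m_b - grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_ab = s * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_res = ss_total - ss_subj - ss_a - ss_b - ss_sa - ss_sb - ss_ab

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err, eps_data in [
        ("condition", ss_a, a - 1, ss_sa, (s - 1) * (a - 1), Y.mean(axis=2)),
        ("component", ss_b, b - 1, ss_sb, (s - 1) * (b - 1), Y.mean(axis=1)),
        ("condition:component", ss_ab, (a - 1) * (b - 1), ss_res,
         (s - 1) * (a - 1) * (b - 1), None),
    ]:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        if ms_err == 0 or not np.isfinite(ms_err):
            f = 0.0 if ss_eff <= 1e-12 else np.inf
        else:
            f = ms_eff / ms_err
        d1, d2 = df_eff, df_err
        if greenhouse_geisser and eps_data is not None:
            eps = _gg_epsilon(eps_data)
            d1, d2 = df_eff * eps, df_err * eps
        p = 1.0 if f == 0.0 else float(sps.f.sf(f, d1, d2))
        rows.append({"effect": name, "ss": ss_eff, "df": df_eff, "ms": ms_eff,
                     "ss_error": ss_err, "df_error": df_err, "F": f, "p": p})
    table = pd.DataFrame(rows)

    cell_rows = []
    for i, cond in enumerate(conds):
        for j, comp in enumerate(comps):
            vals = Y[:, i, j]
            cell_rows.append({"condition": cond, "component": comp,
                              "mean": vals.mean(),
                              "se": vals.std(ddof=1) / np.sqrt(s) if s > 1 else np.nan})
    cell_means = pd.DataFrame(cell_rows)

    ph_rows = []
    for i, cond in enumerate(conds):
        for (j1, c1), (j2, c2) in itertools.combinations(enumerate(comps), 2):
            diff = Y[:, i, j1] - Y[:, i, j2]
            if diff.std(ddof=1) == 0:
                t, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
            else:
                res = sps.ttest_rel(Y[:, i, j1], Y[:, i, j2])
                t, p = float(res.statistic), float(res.pvalue)
            ph_rows.append({"condition": cond, "component_a": c1, "component_b": c2,
                            "mean_diff": float(diff.mean()), "t": t, "p_raw": p})
    posthoc = pd.DataFrame(ph_rows)
    m = posthoc_family if posthoc_family is not None else len(posthoc)
    posthoc["family_size"] = m
    posthoc["p_bonferroni"] = np.minimum(1.0, posthoc["p_raw"] * m)

    return AnovaResult(table=table, cell_means=cell_means, posthoc=posthoc,
                       sphericity_correction="greenhouse-geisser" if greenhouse_geisser else "none")


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the subjects x levels matrix."""
    k = data.shape[1]
    S = np.cov(data.T)
    J = np.eye(k) - 1.0 / k
    Sc = J @ S @ J  # double-centered covariance
    den = (k - 1) * np.sum(Sc**2)
    if den <= 0:
        return 1.0
    return float(np.clip(np.trace(Sc) ** 2 / den, 1.0 / (k - 1), 1.0))


def adjusted_rt(behavior: pd.DataFrame, rt_col: str = "rt_ms") -> pd.DataFrame:
    """Reaction time with the per-subject additive offset removed.

    The model has a fixed condition effect and a per-subject offset; the
    adjusted RT is the observation minus the estimated offset.  In the
    balanced complete case this equals subject-mean centering plus the
    grand mean.  Subjects observed in fewer than two conditions are
    dropped with a warning.
    """
    df = behavior.copy()
    counts = df.groupby("subject")["condition"].nunique()
    thin = counts[counts < 2].index.tolist()
    if thin:
        warnings.warn(f"adjusted_rt: dropping subjects with <2 conditions: {thin}")
        df = df[~df["subject"].isin(thin)]
    subjects = sorted(df["subject"].unique())
    conds = sorted(df["condition"].unique())
    s_idx = df["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    c_idx = df["condition"].map({c: i for i, c in enumerate(conds)}).to_numpy()
    n = len(df)
    # design: intercept + condition dummies (ref first) + sum-zero subject effects
    X = np.zeros((n, 1 + len(conds) - 1 + len(subjects) - 1))
    X[:, 0] = 1.0
    for j in range(1, len(conds)):
        X[c_idx == j, j] = 1.0
    for i in range(len(subjects) - 1):
        X[s_idx == i, len(conds) + i] = 1.0
    X[s_idx == len(subjects) - 1, len(conds):] = -1.0
    y = df[rt_col].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    subj_eff = np.append(coef[len(conds):], -coef[len(conds):].sum())
    out = df[["subject", "condition"]].copy()
    out["adjusted_rt"] = y - subj_eff[s_idx]
    return out.reset_index(drop=True)


def partial_pearson(
    y: np.ndarray, x: np.ndarray, controls: np.ndarray | None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given controls (residual
    regression); two-tailed p from t with df = n - 2 - k."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    k = 0 if controls is None or controls.size == 0 else np.atleast_2d(controls.T).shape[0]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} observations for {k} controls")
    design = np.ones((n, 1))
    if k:
        design = np.column_stack([design, controls])
    Q, _ = np.linalg.qr(design)
    yr = y - Q @ (Q.T @ y)
    xr = x - Q @ (Q.T @ x)
    ny, nx = np.linalg.norm(yr), np.linalg.norm(xr)
    # a residual at numerical-noise level means the variable is fully
    # explained by the controls: the partial correlation is zero
    tol = 1e-8
    if (ny <= tol * max(np.linalg.norm(y - y.mean()), 1.0)
            or nx <= tol * max(np.linalg.norm(x - x.mean()), 1.0)):
        return 0.0, 1.0
    r = float(np.clip((yr @ xr) / (ny * nx), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    return r, float(2 * sps.t.sf(abs(t), df))


def load_rt_partial_correlation(
    loads: pd.DataFrame,
    adj_rt: pd.DataFrame,
    family: int = 3,
) -> AssociationResult:
    """Partial correlation between loads and adjusted RT per cell.

    For each (condition, component), the across-subject correlation of
    that cell's load with the condition's adjusted RT is computed
    controlling the other two components' loads in the same condition
    (the control set is an assumption, recorded in the output).  Raw and
    Bonferroni-adjusted p values over the stated family are reported.
    """
    if family < 1:
        raise ValueError("family must be >= 1")
    piv = loads.pivot_table(index="subject", columns=["condition", "component"],
                            values="load")
    rt = adj_rt.groupby(["subject", "condition"])["adjusted_rt"].mean().unstack()
    subjects = sorted(set(piv.index) & set(rt.index))
    piv, rt = piv.loc[subjects], rt.loc[subjects]
    conds = sorted(loads["condition"].unique())
    comps = sorted(loads["component"].unique())
    rows = []
    for cond in conds:
        for comp in comps:
            x = piv[(cond, comp)].to_numpy()
            y = rt[cond].to_numpy()
            controls = np.column_stack([piv[(cond, c)].to_numpy()
                                        for c in comps if c != comp])
            r, p = partial_pearson(y, x, controls)
            rows.append({"condition": cond, "component": comp,
                         "partial_r": r, "p_raw": p,
                         "p_bonferroni": min(1.0, p * family),
                         "n": len(subjects)})
    table = pd.DataFrame(rows)
    return AssociationResult(table=table, family_size=family,
                             covariates="other two components' loads within the same condition (assumed)")
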