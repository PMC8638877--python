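"""Internal consistency, agreement, stability and validation statistics.

Conventions throughout (chosen to match standard statistics-package output):
sample (n-1) variances, two-tailed p-values, pooled-SD Cohen's d for
independent groups, d = t/sqrt(n) for paired comparisons, and seeded
percentile-bootstrap confidence intervals resampling participants (pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .scoring import Session, clean_trials
from .task import INHIBITORY, Variant

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "AgeTrendResult",
    "cronbach_alpha",
    "inhibitory_item_matrix",
    "cohens_kappa",
    "welch_t",
    "welch_t_from_stats",
    "paired_t",
    "paired_d_from_t",
    "mixed_anova",
    "rm_anova",
    "correlate",
    "partial_correlate",
    "age_trend",
]


# --- internal consistency & agreement --------------------------------------


def cronbach_alpha(items) -> float:
    """Cronbach's alpha over an items matrix (rows = participants).

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance(total score))``
    with sample (n-1) variances.  Requires >= 2 participants, >= 2 items and
    non-zero total-score variance (raises ``ValueError`` otherwise — never NaN).
    """
    m = np.asarray(items, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("items must be a 2-D matrix with >= 2 rows and >= 2 columns")
    if np.isnan(m).any():
        raise ValueError("items matrix must be complete (no missing entries)")
    k = m.shape[1]
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha is undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def inhibitory_item_matrix(
    sessions: list[Session], variant: Variant | None = None, k: int = 8
) -> np.ndarray:
    """Binary accuracy matrix over the first ``k`` valid inhibitory trials.

    Only participants with at least ``k`` valid inhibitory trials are
    retained (complete-case rule; ``k=8`` keeps only sessions with all
    inhibitory trials valid, ``k=6`` is the fallback that retains nearly all
    toddlers at the cost of fewer items).
    """
    rows = []
    for s in sessions:
        acc, _ = clean_trials(s, variant)
        inhib = [t for t in acc if t.spec.condition == INHIBITORY]
        if len(inhib) >= k:
            rows.append([int(t.correct) for t in inhib[:k]])
    return np.asarray(rows, dtype=int).reshape(-1, k)


def cohens_kappa(r1, r2) -> float:
    """Chance-corrected agreement between two label sequences.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with marginal chance agreement
    ``p_e``; undefined (raises) when ``p_e = 1``.
    """
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("empty label sequences")
    labels = np.union1d(a, b)
    if labels.size < 2:
        raise ValueError("need >= 2 observed categories")
    p_o = float(np.mean(a == b))
    p_e = float(sum(np.mean(a == c) * np.mean(b == c) for c in labels))
    if p_e >= 1.0:
        raise ValueError("chance agreement is 1; kappa is undefined")
    return (p_o - p_e) / (1.0 - p_e)


# --- t tests ----------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d: float
    mean_diff: float
    ci: tuple[float, float]


def _pooled_d(m1, s1, n1, m2, s2, n2) -> float:
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return float((m1 - m2) / sp)


def welch_t(x, y) -> TTestResult:
    """Welch's unequal-variance t test on two raw samples.

    Effect size is pooled-SD Cohen's d; the CI is the analytic Welch interval
    for the mean difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    return welch_t_from_stats(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def welch_t_from_stats(m1, sd1, n1, m2, sd2, n2) -> TTestResult:
    """Welch's t from summary statistics (M, SD, n per group)."""
    se2 = sd1**2 / n1 + sd2**2 / n2
    if se2 == 0:
        if m1 == m2:
            return TTestResult(0.0, float(n1 + n2 - 2), 1.0, 0.0, 0.0, (0.0, 0.0))
        raise ValueError("zero variance in both groups with unequal means")
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (
        (sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    d = _pooled_d(m1, sd1, n1, m2, sd2, n2)
    crit = sps.t.ppf(0.975, df)
    diff = m1 - m2
    half = crit * np.sqrt(se2)
    return TTestResult(float(t), float(df), float(p), d, float(diff),
                       (float(diff - half), float(diff + half)))


def paired_t(x, y) -> TTestResult:
    """Paired-samples t test; pairs with a missing value are dropped.

    Effect size convention: ``d = t / sqrt(n)`` (mean difference divided by
    the SD of the differences).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 complete pairs")
    diffs = x - y
    sd = diffs.std(ddof=1)
    if sd == 0:
        t = 0.0 if diffs.mean() == 0 else np.inf * np.sign(diffs.mean())
        p = 1.0 if t == 0 else 0.0
        return TTestResult(float(t), float(n - 1), p, float(t) / np.sqrt(n) if np.isfinite(t) else np.inf,
                           float(diffs.mean()), (float(diffs.mean()), float(diffs.mean())))
    res = sps.ttest_rel(x, y)
    t = float(res.statistic)
    df = float(n - 1)
    se = sd / np.sqrt(n)
    crit = sps.t.ppf(0.975, df)
    md = float(diffs.mean())
    return TTestResult(t, df, float(res.pvalue), paired_d_from_t(t, n), md,
                       (md - crit * se, md + crit * se))


def paired_d_from_t(t: float, n: int) -> float:
    """Paired-comparison effect size under the ``d = t/sqrt(n)`` convention."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(t) / float(np.sqrt(n))


# --- ANOVA ------------------------------------------------------------------


def _f_row(effect, ss_eff, df_eff, ss_err, df_err):
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
    p = float(sps.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
    np2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return {"effect": effect, "F": float(F), "df1": float(df_eff),
            "df2": float(df_err), "p": p, "np2": float(np2)}


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: str,
    between: str | None = None,
) -> pd.DataFrame:
    """Mixed (between x within) or one-way repeated-measures ANOVA.

    Balanced designs, one observation per subject x within-cell (cells are
    averaged first); subjects with any missing cell are dropped (listwise
    deletion).  Returns a table of F, dfs, two-tailed p and partial eta
    squared (``SS_effect / (SS_effect + SS_error)``) per effect.
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="mean").dropna()
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValueError("need >= 2 subjects with complete data and >= 2 within levels")
    Y = wide.to_numpy(dtype=float)
    n_s, b = Y.shape
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_within_cond = n_s * ((col_means - grand) ** 2).sum()

    if between is None:
        ss_err = ss_total - ss_between_subj - ss_within_cond
        rows = [_f_row(within, ss_within_cond, b - 1, ss_err, (n_s - 1) * (b - 1))]
        return pd.DataFrame(rows).set_index("effect")

    group_map = data[[subject, between]].drop_duplicates().set_index(subject)[between]
    if group_map.index.duplicated().any():
        raise ValueError(f"subject maps to multiple {between!r} levels")
    groups = group_map.loc[wide.index].to_numpy()
    levels = pd.unique(groups)
    a = len(levels)
    if a < 2:
        raise ValueError("between factor needs >= 2 levels after listwise deletion")

    ss_A = 0.0
    ss_AB = 0.0
    for g in levels:
        mask = groups == g
        n_g = int(mask.sum())
        g_mean = Y[mask].mean()
        ss_A += n_g * b * (g_mean - grand) ** 2
        cell_means = Y[mask].mean(axis=0)
        ss_AB += n_g * ((cell_means - g_mean - col_means + grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_A
    ss_err_within = ss_total - ss_A - ss_subj_within - ss_within_cond - ss_AB

    rows = [
        _f_row(between, ss_A, a - 1, ss_subj_within, n_s - a),
        _f_row(within, ss_within_cond, b - 1, ss_err_within, (n_s - a) * (b - 1)),
        _f_row(f"{between} * {within}", ss_AB, (a - 1) * (b - 1),
               ss_err_within, (n_s - a) * (b - 1)),
    ]
    return pd.DataFrame(rows).set_index("effect")


def rm_anova(
    data: pd.DataFrame, dv: str, subject: str, within: list[str]
) -> pd.DataFrame:
    """Fully within-subjects two-factor repeated-measures ANOVA.

    Each effect is tested against its own effect-by-subject interaction (no
    sphericity correction; two-level contrasts are unaffected).  Subjects
    with any missing cell are dropped.
    """
    if len(within) == 1:
        return mixed_anova(data, dv=dv, subject=subject, within=within[0])
    if len(within) != 2:
        raise ValueError("within must name one or two factors")
    wa, wb = within
    wide = data.pivot_table(index=subject, columns=[wa, wb], values=dv,
                            aggfunc="mean").dropna()
    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    a, b = len(a_levels), len(b_levels)
    n_s = wide.shape[0]
    if n_s < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 complete subjects and >= 2 levels per factor")
    Y = np.empty((n_s, a, b))
    for i, la in enumerate(a_levels):
        for j, lb in enumerate(b_levels):
            Y[:, i, j] = wide[(la, lb)].to_numpy(dtype=float)

    grand = Y.mean()
    P = Y.mean(axis=(1, 2))          # subject means
    A = Y.mean(axis=(0, 2))          # factor-A means
    B = Y.mean(axis=(0, 1))          # factor-B means
    SA = Y.mean(axis=2)              # subject x A
    SB = Y.mean(axis=1)              # subject x B
    AB = Y.mean(axis=0)              # A x B

    ss_A = n_s * b * ((A - grand) ** 2).sum()
    ss_B = n_s * a * ((B - grand) ** 2).sum()
    ss_AB = n_s * ((AB - A[:, None] - B[None, :] + grand) ** 2).sum()
    ss_AS = b * ((SA - A[None, :] - P[:, None] + grand) ** 2).sum()
    ss_BS = a * ((SB - B[None, :] - P[:, None] + grand) ** 2).sum()
    resid = (
        Y
        - SA[:, :, None]
        - SB[:, None, :]
        - AB[None, :, :]
        + A[None, :, None]
        + B[None, None, :]
        + P[:, None, None]
        - grand
    )
    ss_ABS = (resid**2).sum()

    rows = [
        _f_row(wa, ss_A, a - 1, ss_AS, (a - 1) * (n_s - 1)),
        _f_row(wb, ss_B, b - 1, ss_BS, (b - 1) * (n_s - 1)),
        _f_row(f"{wa} * {wb}", ss_AB, (a - 1) * (b - 1),
               ss_ABS, (a - 1) * (b - 1) * (n_s - 1)),
    ]
    return pd.DataFrame(rows).set_index("effect")


# --- correlation ------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    ci_low: float
    ci_high: float


def _bootstrap_r(x: np.ndarray, y: np.ndarray, b: int, seed: int) -> np.ndarray:
    """Vectorised percentile-bootstrap replicates of Pearson r (resampling pairs)."""
    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(b, n))
    xs = x[idx]
    ys = y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r[np.isfinite(r)]


def correlate(x, y, b_resamples: int = 1000, seed: int = 0) -> CorrelationResult:
    """Pearson correlation with a seeded percentile-bootstrap 95% CI.

    Pairwise-complete observations; degenerate bootstrap replicates (zero
    variance in a resample) are dropped from the percentile computation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    boots = _bootstrap_r(x, y, b_resamples, seed)
    if boots.size == 0:
        lo = hi = float(r)
    else:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(float(r), n, float(p), float(lo), float(hi))


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlate(
    x, y, controls, b_resamples: int = 1000, seed: int = 0
) -> CorrelationResult:
    """Partial Pearson correlation of x and y given control variables.

    Computed as the correlation of least-squares residuals after projecting
    on the controls (plus intercept); p from t with ``df = n - 2 - k``.  The
    bootstrap resamples whole rows (participant-wise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(controls, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, y, C = x[keep], y[keep], C[keep]
    n, k = x.size, C.shape[1]
    if n < 3 + k:
        raise ValueError("need n >= 3 + number of controls")
    Z = np.column_stack([np.ones(n), C])

    def _pr(xv, yv, Zv) -> float:
        rx = _residualize(xv, Zv)
        ry = _residualize(yv, Zv)
        if rx.std() == 0 or ry.std() == 0:
            raise ValueError("zero residual variance; partial correlation undefined")
        return float(np.corrcoef(rx, ry)[0, 1])

    r = _pr(x, y, Z)
    df = n - 2 - k
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2)) if abs(r) < 1 else np.inf * np.sign(r)
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(b_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            boots.append(_pr(x[idx], y[idx], Z[idx]))
        except ValueError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = r
    return CorrelationResult(r, n, p, float(lo), float(hi))


# --- age trends -------------------------------------------------------------


@dataclass(frozen=True)
class AgeTrendResult:
    """Hierarchical linear-then-quadratic age regression.

    Coefficients are on centred age (months); ``f_increment`` tests the gain
    from adding the quadratic term.
    """

    linear_coefs: tuple[float, float]
    linear_r2: float
    linear_p: float
    quadratic_coefs: tuple[float, float, float]
    quadratic_r2: float
    delta_r2: float
    f_increment: float
    p_increment: float


def age_trend(age, score) -> AgeTrendResult:
    """Compare linear and quadratic age trends by hierarchical least squares."""
    age = np.asarray(age, dtype=float)
    score = np.asarray(score, dtype=float)
    keep = np.isfinite(age) & np.isfinite(score)
    age, score = age[keep], score[keep]
    n = age.size
    if n <= 3:
        raise ValueError("need n > 3")
    if np.unique(age).size < 3:
        raise ValueError("age values are degenerate (need >= 3 distinct ages)")
    a_c = age - age.mean()
    X1 = sm.add_constant(a_c)
    X2 = sm.add_constant(np.column_stack([a_c, a_c**2]))
    fit1 = sm.OLS(score, X1).fit()
    fit2 = sm.OLS(score, X2).fit()
    delta_r2 = fit2.rsquared - fit1.rsquared
    df_resid = n - 3
    if fit2.rsquared >= 1.0:
        f_inc, p_inc = np.inf, 0.0
    else:
        f_inc = delta_r2 / ((1.0 - fit2.rsquared) / df_resid)
        p_inc = float(sps.f.sf(f_inc, 1, df_resid))
    return AgeTrendResult(
        linear_coefs=tuple(float(c) for c in fit1.params),
        linear_r2=float(fit1.rsquared),
        linear_p=float(fit1.pvalues[1]),
        quadratic_coefs=tuple(float(c) for c in fit2.params),
        quadratic_r2=float(fit2.rsquared),
        delta_r2=float(delta_r2),
        f_increment=float(f_inc),
        p_increment=float(p_inc),
    )
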