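"""Behavioral statistics: 2 x 2 mixed ANOVA, JZS Bayes factors, and the
a-priori power computation for the within-between interaction.

The ANOVA is a split-plot design with one between-subjects factor (group:
high-ALT vs low-ALT) and one within-subjects factor (emotion: positive vs
negative), both two-level.  The implementation is an explicit
sums-of-squares decomposition on subject means and difference scores
(unweighted/Type-III cell means, so it agrees with common software on
unbalanced groups), which makes two classical identities structural: the
interaction F equals the squared pooled t on the within-subject
difference scores, and SS_total splits exactly into between- and
within-subject parts.  Effect size is partial eta squared,
SS_effect / (SS_effect + SS_error).

The Bayes factor is the Jeffreys-Zellner-Siow default for an
independent-samples t-test: a Cauchy prior (scale 0.707) on the
standardized effect size, marginal likelihood by numeric integration of
the noncentral-t density; BF01 > 1 favors the null.

The power routine reproduces the G*Power "within-between interaction"
convention: noncentrality lambda = f^2 * N * m / (1 - rho) (times the
nonsphericity epsilon, trivially 1 for two levels), F with
df = ((g-1)(m-1), (N-g)(m-1)), returning the smallest total N that is a
multiple of the group count and reaches the target power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "AnovaResult",
    "BayesResult",
    "mixed_anova",
    "bayes_ttest_indep",
    "power_mixed_anova_interaction",
    "achieved_power",
    "bonferroni",
    "simple_effects",
]


@dataclass
class AnovaResult:
    """F, degrees of freedom, p and partial eta squared per effect
    (``group``, ``emotion``, ``interaction``), plus the SS bookkeeping
    needed to verify the decomposition."""

    effects: dict[str, dict]
    ss_total: float
    ss_between_subjects: float
    ss_within_subjects: float
    dv: str


@dataclass
class BayesResult:
    bf01: float
    r_scale: float = 0.707

    @property
    def bf10(self) -> float:
        return 1.0 / self.bf01


def _dv_column(dv: str) -> str:
    if dv not in ("rt", "acc", "rating"):
        raise ValueError("dv must be one of 'rt', 'acc', 'rating'")
    return f"mean_{dv}"


def mixed_anova(behavior: pd.DataFrame, dv: str, task: str | None = None) -> AnovaResult:
    """2 (emotion, within) x 2 (group, between) mixed ANOVA on one
    dependent variable."""
    col = _dv_column(dv)
    df = behavior
    if task is not None:
        df = df[df["task"] == task]
    wide = df.pivot_table(index=["subject_id", "group"], columns="emotion", values=col)
    if wide.isna().any().any() or wide.shape[1] != 2:
        raise ValueError("every subject needs both emotion-level values")
    wide = wide.reset_index()
    groups = np.sort(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    y_pos = wide["positive"].to_numpy(dtype=float)
    y_neg = wide["negative"].to_numpy(dtype=float)
    g = wide["group"].to_numpy()
    n_g = np.array([(g == lab).sum() for lab in groups])
    if n_g.min() < 2:
        raise ValueError("each group needs at least 2 subjects")
    N = len(g)
    m = 2

    u = (y_pos + y_neg) / 2.0  # subject means
    d = y_pos - y_neg  # within-subject difference scores
    u_bar = np.array([u[g == lab].mean() for lab in groups])
    d_bar = np.array([d[g == lab].mean() for lab in groups])
    inv_n = (1.0 / n_g).sum()

    ss_err_between = m * sum(((u[g == lab] - u_bar[i]) ** 2).sum() for i, lab in enumerate(groups))
    ss_err_within = 0.5 * sum(((d[g == lab] - d_bar[i]) ** 2).sum() for i, lab in enumerate(groups))
    if ss_err_between <= 0 or ss_err_within <= 0:
        raise ValueError("zero error variance; ANOVA ill-defined")
    df_err = N - 2

    # Type-III (unweighted cell means) effect sums of squares
    ss_group = m * (u_bar[0] - u_bar[1]) ** 2 / inv_n
    u_d = d_bar.mean()
    ss_emotion = 2.0 * u_d**2 / inv_n
    ss_inter = (d_bar[0] - d_bar[1]) ** 2 / (2.0 * inv_n)

    grand = u.mean()
    ss_total = ((y_pos - grand) ** 2).sum() + ((y_neg - grand) ** 2).sum()
    ss_between_subjects = m * ((u - grand) ** 2).sum()

    def effect(ss: float, ss_err: float) -> dict:
        F = (ss / 1.0) / (ss_err / df_err)
        p = float(stats.f.sf(F, 1, df_err))
        return {
            "F": float(F),
            "df": (1, df_err),
            "p": p,
            "eta_p_sq": float(ss / (ss + ss_err)),
            "SS": float(ss),
            "SS_error": float(ss_err),
        }

    return AnovaResult(
        effects={
            "group": effect(ss_group, ss_err_between),
            "emotion": effect(ss_emotion, ss_err_within),
            "interaction": effect(ss_inter, ss_err_within),
        },
        ss_total=float(ss_total),
        ss_between_subjects=float(ss_between_subjects),
        ss_within_subjects=float(ss_total - ss_between_subjects),
        dv=dv,
    )


def bayes_ttest_indep(x, y, r_scale: float = 0.707) -> BayesResult:
    """JZS Bayes factor for an independent-samples t-test.

    BF10 is the ratio of the Cauchy-prior marginal likelihood of the t
    statistic (noncentral-t density integrated over the prior on the
    standardized effect) to its point-null density; BF01 = 1/BF10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    nu = n1 + n2 - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / nu
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    n_eff = n1 * n2 / (n1 + n2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, nu, delta * np.sqrt(n_eff)) * stats.cauchy.pdf(
            delta, 0.0, r_scale
        )

    marginal, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    null_density = stats.t.pdf(t, nu)
    bf10 = marginal / null_density
    return BayesResult(bf01=float(1.0 / bf10), r_scale=r_scale)


def achieved_power(
    n_total: int,
    f: float = 0.25,
    alpha: float = 0.05,
    n_groups: int = 2,
    n_measures: int = 2,
    rho: float = 0.5,
    epsilon: float = 1.0,
) -> float:
    """Noncentral-F power of the within-between interaction at total N."""
    g, m = n_groups, n_measures
    lam = f**2 * n_total * m * epsilon / (1.0 - rho)
    df1 = (g - 1) * (m - 1) * epsilon
    df2 = (n_total - g) * (m - 1) * epsilon
    if df2 <= 0:
        return 0.0
    crit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def power_mixed_anova_interaction(
    f: float = 0.25,
    alpha: float = 0.05,
    power: float = 0.80,
    n_groups: int = 2,
    n_measures: int = 2,
    rho: float = 0.5,
    epsilon: float = 1.0,
    n_max: int = 10**6,
) -> int:
    """Smallest total N (multiple of ``n_groups``) whose interaction power
    reaches the target."""
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if f <= 0:
        raise ValueError("effect size f must be > 0")
    n = n_groups * 2
    while n <= n_max:
        if achieved_power(n, f, alpha, n_groups, n_measures, rho, epsilon) >= power:
            return n
        n += n_groups
    raise ValueError("target power unreachable below n_max")


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Plain alpha/m adjustment: p_adj = min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


def simple_effects(behavior: pd.DataFrame, dv: str, task: str | None = None) -> pd.DataFrame:
    """Follow-up simple-effects t-tests with Bonferroni-adjusted p-values:
    emotion within each group (paired) and group within each emotion
    (independent, pooled variance)."""
    col = _dv_column(dv)
    df = behavior if task is None else behavior[behavior["task"] == task]
    wide = df.pivot_table(index=["subject_id", "group"], columns="emotion", values=col).reset_index()
    rows = []
    for lab in np.sort(df["group"].unique()):
        sub = wide[wide["group"] == lab]
        t, p = stats.ttest_rel(sub["positive"], sub["negative"])
        rows.append({"contrast": f"emotion within {lab}", "t": float(t), "p": float(p)})
    groups = np.sort(df["group"].unique())
    for emo in ("positive", "negative"):
        a = wide.loc[wide["group"] == groups[0], emo]
        b = wide.loc[wide["group"] == groups[1], emo]
        t, p = stats.ttest_ind(a, b)
        rows.append({"contrast": f"group within {emo}", "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p"].to_numpy())
    return out
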