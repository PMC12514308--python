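"""Group inference on features and connectivity, plus ADE drinking
measures.

Feature tables are tidy (subject, group, treatment, channel, measure,
value); the omnibus test per measure is a mixed-design ANOVA with the
between factor group and within factors treatment and channel.  Non-normal
connectivity values are compared with Mann-Whitney U and a rank-biserial
effect size; multiplicity is handled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "mann_whitney_effect",
    "fdr_adjust",
    "rm_anova",
    "paired_t_by_channel",
    "partial_spearman",
    "drinking_measures",
    "DrinkingResult",
]


def mann_whitney_effect(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with the rank-biserial effect size
    r = 1 - 2U / (n_a n_b), where U counts (a > b) pair wins for group a.

    Exact null distribution for small tie-free samples, otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 10 and not ties) else "asymptotic"
    res = sst.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    r_rb = 1.0 - 2.0 * u / (a.size * b.size)
    return u, float(res.pvalue), r_rb


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Mixed-design ANOVA: between = group, within = treatment x channel
# ---------------------------------------------------------------------------

def _gg_epsilon(mat: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x levels score matrix."""
    k = mat.shape[1]
    if k < 2:
        return 1.0
    S = np.cov(mat, rowvar=False)
    d = S.mean(axis=0)
    gm = S.mean()
    num = (k * (np.trace(S) / k - gm)) ** 2
    den = (k - 1) * (
        (S**2).sum() - 2 * k * (d**2).sum() + k**2 * gm**2
    )
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def rm_anova(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Mixed-design ANOVA for one measure.

    Expects a balanced complete tidy frame with columns subject, group,
    treatment, channel and the value column.  Subjects are the repeated
    unit, nested in group.  Returns one row per effect with F, dfs and p;
    the channel effects additionally carry a Greenhouse-Geisser-corrected p.
    """
    needed = {"subject", "group", "treatment", "channel", value}
    if not needed <= set(table.columns):
        raise ValueError(f"table must contain columns {sorted(needed)}")
    counts = table.groupby(["subject", "treatment", "channel"])[value].count()
    n_cells = (
        table["subject"].nunique()
        * table["treatment"].nunique()
        * table["channel"].nunique()
    )
    if (
        len(counts) != n_cells
        or counts.nunique() != 1
        or counts.iloc[0] != 1
        or table[value].isna().any()
    ):
        raise ValueError(
            "unbalanced or incomplete design; impute the feature table first"
        )
    groups = sorted(table["group"].unique())
    subj_group = table.groupby("subject")["group"].first()
    n_per = subj_group.value_counts()
    if n_per.nunique() != 1:
        raise ValueError("groups must have equal numbers of subjects")

    subjects = sorted(table["subject"].unique())
    treats = sorted(table["treatment"].unique())
    chans = sorted(table["channel"].unique())
    a, b, c = len(groups), len(treats), len(chans)
    n = int(n_per.iloc[0])

    # Y[subject, treatment, channel]
    pivot = table.pivot_table(
        index="subject", columns=["treatment", "channel"], values=value
    )
    cols = pd.MultiIndex.from_product([treats, chans])
    Y = pivot.reindex(index=subjects, columns=cols).to_numpy()
    Y = Y.reshape(len(subjects), b, c)
    g_of = np.array([groups.index(subj_group[s]) for s in subjects])

    gm = Y.mean()
    m_subj = Y.mean(axis=(1, 2))
    m_A = np.array([Y[g_of == gi].mean() for gi in range(a)])
    m_B = Y.mean(axis=(0, 2))
    m_C = Y.mean(axis=(0, 1))
    m_AB = np.array([Y[g_of == gi].mean(axis=(0, 2)) for gi in range(a)])
    m_AC = np.array([Y[g_of == gi].mean(axis=(0, 1)) for gi in range(a)])
    m_BC = Y.mean(axis=0)
    m_ABC = np.array([Y[g_of == gi].mean(axis=0) for gi in range(a)])
    m_sB = Y.mean(axis=2)  # subject x treatment
    m_sC = Y.mean(axis=1)  # subject x channel

    ss_A = b * c * n * ((m_A - gm) ** 2).sum()
    ss_subj = b * c * ((m_subj - m_A[g_of]) ** 2).sum()
    ss_B = a * c * n * ((m_B - gm) ** 2).sum()
    ss_AB = c * n * ((m_AB - m_A[:, None] - m_B[None, :] + gm) ** 2).sum()
    ss_Bsubj = c * (
        (m_sB - m_subj[:, None] - m_AB[g_of] + m_A[g_of][:, None]) ** 2
    ).sum()
    ss_C = a * b * n * ((m_C - gm) ** 2).sum()
    ss_AC = b * n * ((m_AC - m_A[:, None] - m_C[None, :] + gm) ** 2).sum()
    ss_Csubj = b * (
        (m_sC - m_subj[:, None] - m_AC[g_of] + m_A[g_of][:, None]) ** 2
    ).sum()
    ss_BC = a * n * (
        (m_BC - m_B[:, None] - m_C[None, :] + gm) ** 2
    ).sum()
    ss_ABC = n * (
        (
            m_ABC
            - m_AB[:, :, None]
            - m_AC[:, None, :]
            - m_BC[None, :, :]
            + m_A[:, None, None]
            + m_B[None, :, None]
            + m_C[None, None, :]
            - gm
        )
        ** 2
    ).sum()
    ss_total = ((Y - gm) ** 2).sum()
    ss_BCsubj = ss_total - (
        ss_A + ss_subj + ss_B + ss_AB + ss_Bsubj
        + ss_C + ss_AC + ss_Csubj + ss_BC + ss_ABC
    )

    df = {
        "group": (a - 1, a * (n - 1), ss_A, ss_subj),
        "treatment": ((b - 1), a * (n - 1) * (b - 1), ss_B, ss_Bsubj),
        "group:treatment": ((a - 1) * (b - 1), a * (n - 1) * (b - 1), ss_AB, ss_Bsubj),
        "channel": ((c - 1), a * (n - 1) * (c - 1), ss_C, ss_Csubj),
        "group:channel": ((a - 1) * (c - 1), a * (n - 1) * (c - 1), ss_AC, ss_Csubj),
        "treatment:channel": (
            (b - 1) * (c - 1), a * (n - 1) * (b - 1) * (c - 1), ss_BC, ss_BCsubj,
        ),
        "group:treatment:channel": (
            (a - 1) * (b - 1) * (c - 1),
            a * (n - 1) * (b - 1) * (c - 1),
            ss_ABC, ss_BCsubj,
        ),
    }
    eps_c = _gg_epsilon(m_sC) if c > 1 else 1.0
    rows = []
    for effect, (df1, df2, ss, ss_err) in df.items():
        if df1 == 0 or df2 == 0:
            continue
        ms = ss / df1
        ms_err = ss_err / df2
        F = ms / ms_err if ms_err > 0 else 0.0
        p = float(sst.f.sf(F, df1, df2)) if ms_err > 0 else 1.0
        p_gg = np.nan
        if effect in ("channel", "group:channel") and eps_c < 1.0:
            p_gg = float(sst.f.sf(F, df1 * eps_c, df2 * eps_c))
        rows.append((effect, ss, df1, df2, F, p, p_gg))
    out = pd.DataFrame(
        rows, columns=["effect", "ss", "df1", "df2", "F", "p", "p_gg"]
    )
    out.attrs["gg_epsilon_channel"] = eps_c
    return out


def paired_t_by_channel(pre: np.ndarray, post: np.ndarray) -> pd.DataFrame:
    """Channelwise paired t-tests between treatments.

    ``pre`` and ``post`` are (subjects, channels).  A zero-variance
    difference is flagged: t = 0, p = 1 when the constant shift is zero,
    otherwise t = +/-inf with p = 0.
    """
    pre = np.atleast_2d(np.asarray(pre, float))
    post = np.atleast_2d(np.asarray(post, float))
    if pre.shape != post.shape:
        raise ValueError("pre and post must have the same shape")
    if pre.shape[0] < 3:
        raise ValueError("need at least 3 paired subjects")
    rows = []
    for ch in range(pre.shape[1]):
        d = post[:, ch] - pre[:, ch]
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                t, p, flag = 0.0, 1.0, True
            else:
                t, p, flag = float(np.sign(d.mean()) * np.inf), 0.0, True
        else:
            res = sst.ttest_rel(post[:, ch], pre[:, ch])
            t, p, flag = float(res.statistic), float(res.pvalue), False
        rows.append((ch, t, p, flag))
    out = pd.DataFrame(rows, columns=["channel", "t", "p", "zero_variance"])
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    return out


def partial_spearman(x, y, covariate) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given one covariate.

    All three series are rank-transformed; rho is the Pearson correlation
    of the residuals after regressing the ranked x and y on the ranked
    covariate, with a t approximation on n - 3 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(covariate, float)
    n = x.size
    if not (y.size == n == z.size) or n < 5:
        raise ValueError("need three equal-length series with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.ptp(z) == 0:
        raise ValueError("constant input series")
    rx, ry, rz = (sst.rankdata(v) for v in (x, y, z))

    def _resid(v, c):
        c1 = np.column_stack([np.ones(n), c])
        beta, *_ = np.linalg.lstsq(c1, v, rcond=None)
        return v - c1 @ beta

    ex, ey = _resid(rx, rz), _resid(ry, rz)
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom == 0:
        raise ValueError("degenerate residuals")
    rho = float((ex * ey).sum() / denom)
    dfree = n - 3
    rho_c = min(max(rho, -0.999999), 0.999999)
    t = rho_c * np.sqrt(dfree / (1.0 - rho_c**2))
    p = float(2.0 * sst.t.sf(abs(t), dfree))
    return rho, p


# ---------------------------------------------------------------------------
# Drinking behaviour
# ---------------------------------------------------------------------------

@dataclass
class DrinkingResult:
    per_rat: pd.DataFrame  # rat x concentration (incl. total) x measure
    anova: pd.DataFrame  # drinking phase x concentration rmANOVA
    relapse_tests: pd.DataFrame  # one-sample t of relapse vs 0


def drinking_measures(table: pd.DataFrame, bl_days: int = 7) -> DrinkingResult:
    """BL / ADE / relapse summaries and their tests.

    Per rat and concentration: BL is the mean intake over the last
    ``bl_days`` days of each drinking phase (averaged across phases), ADE
    the intake on the first day after each deprivation (averaged across
    cycles), relapse the per-cycle ADE minus the immediately preceding
    phase's BL (averaged).  Totals sum the three concentrations.  The
    phase x concentration comparison is a repeated-measures ANOVA; relapse
    is tested against zero per concentration and for the total.
    """
    from statsmodels.stats.anova import AnovaRM

    phases = table[["phase"]].drop_duplicates()["phase"].tolist()
    kinds = [p.rsplit("_", 1)[0] for p in phases]
    if "deprivation" not in kinds:
        raise ValueError("table contains no deprivation phase")

    drinking_phases = [p for p, k in zip(phases, kinds) if k == "drinking"]
    rows = []
    for rat, df_r in table.groupby("rat"):
        for conc, df_c in df_r.groupby("concentration"):
            df_c = df_c.sort_values("day")
            bl_by_phase = {}
            for ph in drinking_phases:
                days = df_c[df_c["phase"] == ph]
                if len(days) == 0:
                    continue
                bl_by_phase[ph] = days.tail(bl_days)["intake"].mean()
            ades, relapses = [], []
            for i, ph in enumerate(phases):
                if kinds[i] != "deprivation" or i + 1 >= len(phases):
                    continue
                nxt = df_c[df_c["phase"] == phases[i + 1]].sort_values("day")
                if len(nxt) == 0:
                    continue
                ade = float(nxt["intake"].iloc[0])
                ades.append(ade)
                prev = phases[i - 1]
                if prev in bl_by_phase:
                    relapses.append(ade - bl_by_phase[prev])
            rows.append(
                (
                    rat, conc,
                    float(np.mean(list(bl_by_phase.values()))),
                    float(np.mean(ades)) if ades else np.nan,
                    float(np.mean(relapses)) if relapses else np.nan,
                )
            )
    per = pd.DataFrame(rows, columns=["rat", "concentration", "BL", "ADE", "relapse"])
    totals = (
        per.groupby("rat")[["BL", "ADE", "relapse"]].sum().reset_index()
    )
    totals["concentration"] = "total"
    per["concentration"] = per["concentration"].astype(str)
    per_rat = pd.concat([per, totals], ignore_index=True)

    long = per[per["concentration"] != "total"].melt(
        id_vars=["rat", "concentration"],
        value_vars=["BL", "ADE"],
        var_name="drinking_phase",
        value_name="intake",
    )
    anova = AnovaRM(
        long, depvar="intake", subject="rat",
        within=["drinking_phase", "concentration"],
    ).fit().anova_table.reset_index(names="effect")

    t_rows = []
    for conc, df_c in per_rat.groupby("concentration"):
        vals = df_c["relapse"].dropna().to_numpy()
        res = sst.ttest_1samp(vals, 0.0)
        t_rows.append(
            (conc, vals.mean(), vals.std(ddof=1), float(res.statistic), float(res.pvalue))
        )
    relapse_tests = pd.DataFrame(
        t_rows, columns=["concentration", "mean", "sd", "t", "p"]
    )
    return DrinkingResult(per_rat=per_rat, anova=anova, relapse_tests=relapse_tests)
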