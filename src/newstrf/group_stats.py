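"""Inferential statistics for the group x news factorial design.

A two-way mixed ANOVA (between factor: depressed / non-depressed; within
factor: negative / neutral / positive news) with unweighted-cell-means sums
of squares (harmonic-mean group size), Greenhouse-Geisser sphericity
correction gated on Mauchly's test, partial eta squared, and
Bonferroni-corrected post-hoc t-tests.  Subjective ratings are aligned-
rank-transformed before the ANOVA (one aligned/ranked response per effect);
EEG measures enter untransformed.  Participant-table checks: chi-square
test of independence with Cramer's V and the pooled-variance independent
t-test with Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_core import CONDITIONS, GROUPS

EFFECTS = ("Group", "News", "Group x News")


@dataclass
class ANOVAResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    epsilon: float = 1.0
    p_gg: float | None = None        # GG-adjusted p (reported when Mauchly fails)
    sphericity_violated: bool = False


@dataclass
class PosthocResult:
    contrast: str
    kind: str                        # "paired" or "unpaired"
    t: float
    df: float
    p_raw: float
    p_bonferroni: float


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "group", "news", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"factorial table needs columns {sorted(required)}")
    counts = table.groupby(["subject", "news"]).size()
    if (counts != 1).any():
        raise ValueError("each subject must appear exactly once per news level")
    per_subj = table.groupby("subject")["news"].nunique()
    incomplete = per_subj[per_subj < len(CONDITIONS)]
    if not incomplete.empty:
        warnings.warn(f"excluding subjects with missing levels: {list(incomplete.index)}",
                      stacklevel=3)
        table = table[~table["subject"].isin(incomplete.index)]
    ngroups = table.groupby("subject")["group"].nunique()
    if (ngroups != 1).any():
        raise ValueError("each subject must belong to exactly one group")
    return table


def _wide(table: pd.DataFrame):
    """(wide value matrix subjects x news, group label per subject)."""
    wide = table.pivot(index="subject", columns="news", values="value")[list(CONDITIONS)]
    groups = table.groupby("subject")["group"].first().loc[wide.index]
    return wide, groups


def aligned_rank_transform(table: pd.DataFrame) -> dict:
    """Aligned rank transform: one ranked response per factorial effect.

    For each effect, every observation is stripped of all estimated effects
    except the target (cell-mean decomposition with unweighted means), and
    the aligned values are midranked.  Returns ``{effect: table with the
    'value' column replaced by ranks}``.
    """
    table = _check_table(table.copy())
    cell = table.groupby(["group", "news"])["value"].mean().unstack()  # 2 x 3 cell means
    mu = cell.to_numpy().mean()
    a = cell.mean(axis=1) - mu                      # group effect
    b = cell.mean(axis=0) - mu                      # news effect
    ab = cell.sub(a, axis=0).sub(b, axis=1) - mu    # interaction cell effects
    g = table["group"].to_numpy()
    n = table["news"].to_numpy()
    resid = table["value"].to_numpy() - cell.to_numpy()[
        [list(cell.index).index(x) for x in g],
        [list(cell.columns).index(x) for x in n]]
    estimates = {
        "Group": a.loc[g].to_numpy(),
        "News": b.loc[n].to_numpy(),
        "Group x News": np.array([ab.loc[gi, ni] for gi, ni in zip(g, n)]),
    }
    out = {}
    for effect, est in estimates.items():
        t = table.copy()
        t["value"] = sstats.rankdata(resid + est, method="average")
        out[effect] = t
    return out


def mixed_anova(table: pd.DataFrame) -> list:
    """Two-way mixed ANOVA with unweighted-cell-means sums of squares.

    Between effect tested against subjects-within-groups; within effect and
    interaction against news x subjects-within-groups.  Unequal group sizes
    use the harmonic mean cell size.  Greenhouse-Geisser epsilon is always
    reported with the original degrees of freedom; the adjusted p replaces
    the unadjusted one only when Mauchly's test rejects sphericity at 0.05.
    """
    table = _check_table(table.copy())
    wide, groups = _wide(table)
    Y = wide.to_numpy(dtype=float)
    k = Y.shape[1]
    glabels = [g for g in GROUPS if g in set(groups)]
    n_g = np.array([int((groups == g).sum()) for g in glabels], dtype=float)
    if (n_g < 2).any():
        raise ValueError("each group needs at least 2 subjects")
    N, G = int(n_g.sum()), len(glabels)
    n_h = G / np.sum(1.0 / n_g)                       # harmonic mean group size

    cell = np.stack([Y[(groups == g).to_numpy()].mean(axis=0) for g in glabels])
    gm = cell.mean()
    a_eff = cell.mean(axis=1) - gm
    b_eff = cell.mean(axis=0) - gm
    ab_eff = cell - cell.mean(axis=1, keepdims=True) - cell.mean(axis=0) + gm

    ss_a = n_h * k * np.sum(a_eff ** 2)
    ss_b = n_h * G * np.sum(b_eff ** 2)
    ss_ab = n_h * np.sum(ab_eff ** 2)

    subj_means = Y.mean(axis=1)
    ss_subj = 0.0
    resid_within = np.empty_like(Y)
    for gi, g in enumerate(glabels):
        m = (groups == g).to_numpy()
        ss_subj += k * np.sum((subj_means[m] - subj_means[m].mean()) ** 2)
        # per-subject residual after removing subject mean and cell profile
        profile = cell[gi] - cell[gi].mean()
        resid_within[m] = Y[m] - subj_means[m][:, None] - profile[None, :]
    ss_err_within = np.sum(resid_within ** 2)

    df_a, df_b, df_ab = G - 1.0, k - 1.0, (G - 1.0) * (k - 1.0)
    df_subj = N - G
    df_err_within = (N - G) * (k - 1.0)

    degenerate_between = ss_subj <= 1e-12
    degenerate_within = ss_err_within <= 1e-12
    if degenerate_between or degenerate_within:
        warnings.warn("zero error variance; degenerate F reported as 0", stacklevel=2)

    eps = gg_epsilon(table)
    _, mauchly_p = mauchly_test(table)
    violated = mauchly_p < 0.05

    def _f(ss_eff, df_eff, ss_err, df_err, degenerate, use_eps):
        if degenerate:
            return ANOVAResult("", 0.0, df_eff, df_err, 1.0, 0.0)
        F = (ss_eff / df_eff) / (ss_err / df_err)
        p = float(sstats.f.sf(F, df_eff, df_err))
        res = ANOVAResult("", float(F), df_eff, df_err, p,
                          float(ss_eff / (ss_eff + ss_err)))
        if use_eps:
            res.epsilon = eps
            res.sphericity_violated = violated
            res.p_gg = float(sstats.f.sf(F, df_eff * eps, df_err * eps))
            if violated:
                res.p = res.p_gg
        return res

    out = []
    for effect, (ss_e, df_e, ss_err, df_err, degen, within) in {
        "Group": (ss_a, df_a, ss_subj, df_subj, degenerate_between, False),
        "News": (ss_b, df_b, ss_err_within, df_err_within, degenerate_within, True),
        "Group x News": (ss_ab, df_ab, ss_err_within, df_err_within, degenerate_within, True),
    }.items():
        res = _f(ss_e, df_e, ss_err, df_err, degen, within)
        res.effect = effect
        out.append(res)
    return out


def _pooled_within_cov(table: pd.DataFrame) -> tuple:
    """Covariance of the within-subject measures pooled over groups."""
    wide, groups = _wide(table)
    Y = wide.to_numpy(dtype=float)
    k = Y.shape[1]
    S = np.zeros((k, k))
    dof = 0
    for g in set(groups):
        Yg = Y[(groups == g).to_numpy()]
        if Yg.shape[0] > 1:
            S += np.cov(Yg, rowvar=False) * (Yg.shape[0] - 1)
            dof += Yg.shape[0] - 1
    return S / dof, dof


def gg_epsilon(table: pd.DataFrame) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-measure covariance."""
    S, _ = _pooled_within_cov(table)
    k = S.shape[0]
    if k < 3:
        return 1.0
    C = np.eye(k) - np.ones((k, k)) / k
    Sc = C @ S @ C
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc ** 2)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def mauchly_test(table: pd.DataFrame) -> tuple:
    """Mauchly's sphericity test (W statistic, asymptotic chi-square p)."""
    S, dof = _pooled_within_cov(table)
    k = S.shape[0]
    if k < 3:
        return 1.0, 1.0
    # orthonormal contrasts of the k within levels
    M = np.linalg.qr(np.eye(k) - np.ones((k, k)) / k)[0][:, : k - 1].T
    T = M @ S @ M.T
    d = k - 1
    eig = np.linalg.eigvalsh(T)
    if np.any(eig <= 0):
        return 0.0, 0.0
    W = float(np.prod(eig) / (np.mean(eig) ** d))
    f_corr = 1.0 - (2.0 * d ** 2 + d + 2.0) / (6.0 * d * dof)
    chi2 = -f_corr * dof * np.log(W)
    df = d * (d + 1) // 2 - 1
    p = float(sstats.chi2.sf(chi2, df))
    return W, p


def posthoc_contrasts(table: pd.DataFrame, anova: list, alpha: float = 0.05) -> list:
    """Bonferroni-corrected post-hoc t-tests gated on the ANOVA.

    Significant News main effect -> paired t over condition pairs (pooled
    groups); significant interaction -> paired t over condition pairs per
    group; significant Group or interaction -> unpaired t between groups
    per condition.  The Bonferroni factor is the number of tests in each
    family, and corrected p clamps at 1.
    """
    table = _check_table(table.copy())
    wide, groups = _wide(table)
    by_effect = {r.effect: r for r in anova}
    results = []
    pairs = [(a, b) for i, a in enumerate(CONDITIONS) for b in CONDITIONS[i + 1:]]

    def _paired(sub: pd.DataFrame, label: str):
        fam = []
        for a, b in pairs:
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            t, p = sstats.ttest_rel(x, y)
            if np.isnan(t):  # identical samples -> zero variance
                t, p = 0.0, 1.0
            fam.append(PosthocResult(f"{label}{a} vs {b}", "paired", float(t),
                                     len(x) - 1.0, float(p), 0.0))
        for r in fam:
            r.p_bonferroni = min(1.0, r.p_raw * len(fam))
        return fam

    if by_effect["News"].p < alpha:
        results += _paired(wide, "")
    if by_effect["Group x News"].p < alpha:
        for g in GROUPS:
            m = (groups == g).to_numpy()
            if m.any():
                results += _paired(wide[m], f"{g}: ")
    if by_effect["Group"].p < alpha or by_effect["Group x News"].p < alpha:
        fam = []
        for cond in CONDITIONS:
            x = wide[cond][(groups == GROUPS[0]).to_numpy()].to_numpy()
            y = wide[cond][(groups == GROUPS[1]).to_numpy()].to_numpy()
            t, df, p, _ = independent_t(x, y)
            fam.append(PosthocResult(f"{cond}: {GROUPS[0]} vs {GROUPS[1]}",
                                     "unpaired", t, df, p, 0.0))
        for r in fam:
            r.p_bonferroni = min(1.0, r.p_raw * len(fam))
        results += fam
    return results


def chi2_independence(counts) -> tuple:
    """Chi-square test of independence with Cramer's V.

    Asymptotic chi-square p, no continuity correction.  Returns
    (chi2, df, p, V).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("need a 2-D table of non-negative counts")
    chi2, p, df, _ = sstats.chi2_contingency(obs, correction=False)
    n = obs.sum()
    v = float(np.sqrt(chi2 / (n * (min(obs.shape) - 1))))
    return float(chi2), int(df), float(p), v


def independent_t(x, y) -> tuple:
    """Pooled-variance independent t-test with Cohen's d.

    Returns (t, df, p, d); d uses the pooled SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = sstats.ttest_ind(x, y, equal_var=True)
    df = x.size + y.size - 2.0
    sp = np.sqrt(((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df)
    d = float((x.mean() - y.mean()) / sp) if sp > 0 else 0.0
    if np.isnan(t):
        t, p = 0.0, 1.0
    return float(t), df, float(p), d


def anova_to_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "effect": r.effect, "F": r.F, "df1": r.df1, "df2": r.df2,
        "epsilon": r.epsilon, "p": r.p, "partial_eta_sq": r.partial_eta_sq,
        "sphericity_violated": r.sphericity_violated,
    } for r in results])


def posthoc_to_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "contrast": r.contrast, "kind": r.kind, "t": r.t, "df": r.df,
        "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni,
    } for r in results])


def measure_tables(measures: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Factorial tables for every EEG measure (channel x component x kind)."""
    merged = measures.merge(labels[["subject_id", "group"]], on="subject_id")
    tables = {}
    for (ch, comp), sub in merged.groupby(["channel", "component"]):
        for kind, col in (("amplitude", "mean_amplitude"), ("latency", "peak_latency_ms")):
            tables[f"{comp}_{kind}_{ch}"] = pd.DataFrame({
                "subject": sub["subject_id"], "group": sub["group"],
                "news": sub["condition"], "value": sub[col]})
    return tables


def rating_tables(ratings: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Factorial tables of per-subject condition means for each rating scale."""
    merged = ratings.merge(labels[["subject_id", "group"]], on="subject_id")
    means = merged.groupby(["subject_id", "group", "condition"])[
        ["valence", "arousal", "interest", "comprehensibility"]].mean().reset_index()
    return {scale: pd.DataFrame({
        "subject": means["subject_id"], "group": means["group"],
        "news": means["condition"], "value": means[scale]})
        for scale in ("valence", "arousal", "interest", "comprehensibility")}


def run_stats_stage(measures: pd.DataFrame, ratings: pd.DataFrame,
                    labels: pd.DataFrame):
    """ANOVA + post-hocs for every EEG measure and (ART) rating scale."""
    anova_rows, posthoc_rows = [], []

    def _run(name: str, table: pd.DataFrame, use_art: bool):
        if use_art:
            per_effect = aligned_rank_transform(table)
            results = []
            for effect in EFFECTS:
                res = [r for r in mixed_anova(per_effect[effect]) if r.effect == effect][0]
                results.append(res)
        else:
            results = mixed_anova(table)
        af = anova_to_frame(results)
        af.insert(0, "measure", name)
        anova_rows.append(af)
        ph = posthoc_contrasts(table, results)
        if ph:
            pf = posthoc_to_frame(ph)
            pf.insert(0, "measure", name)
            posthoc_rows.append(pf)

    for name, table in measure_tables(measures, labels).items():
        _run(name, table, use_art=False)
    for name, table in rating_tables(ratings, labels).items():
        _run(name, table, use_art=True)
    anova_df = pd.concat(anova_rows, ignore_index=True)
    posthoc_df = (pd.concat(posthoc_rows, ignore_index=True)
                  if posthoc_rows else pd.DataFrame())
    return anova_df, posthoc_df
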