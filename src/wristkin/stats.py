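"""Group comparison workflow for motion cohorts.

Per pose and motion channel the cohort is gated through Shapiro–Wilk
normality: if every (bone × condition) group looks normal the parametric
branch runs (two-way ANOVA, Tukey's HSD for bone-wise pairs, t contrasts),
otherwise the rank branch runs (Kruskal–Wallis, Dunn's z pairs with
Bonferroni adjustment, Mann–Whitney contrasts).  Per-bone condition
contrasts always report the mean difference transected − intact, the raw
p-value and a family-adjusted p-value across bones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ROTATION_CHANNELS = ["rot_x_deg", "rot_z_deg", "rot_y_deg"]
TRANSLATION_CHANNELS = ["trans_x_mm", "trans_y_mm", "trans_z_mm"]
CHANNELS = ROTATION_CHANNELS + TRANSLATION_CHANNELS

#: default bone families entering the bone-vs-bone omnibus tests
DEFAULT_ROW_GROUPS = {
    "proximal_row": ["scaphoid", "lunate", "triquetrum", "pisiform"],
    "distal_row": ["trapezium", "trapezoid", "capitate", "hamate"],
    "metacarpal": ["mc1", "mc2", "mc3", "mc4", "mc5"],
}


class StatsError(ValueError):
    pass


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p for one sample (3 ≤ n ≤ 5000)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise StatsError(f"Shapiro–Wilk needs 3..5000 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise StatsError("sample has zero variance")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-squared p (k−1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups) \
            or sum(len(g) for g in groups) < 3:
        raise StatsError("need >= 2 non-empty groups, total n >= 3")
    if np.ptp(np.concatenate(groups)) == 0:
        raise StatsError("all observations identical")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        stepped = np.minimum((m - np.arange(m)) * p[order], 1.0)
        out = np.empty(m)
        out[order] = np.maximum.accumulate(stepped)
        return out
    raise ValueError(f"unknown adjustment {method!r}")


def tukey_hsd(groups: dict) -> list[dict]:
    """Studentized-range adjusted pairwise comparisons."""
    names = list(groups)
    if len(names) < 2:
        raise StatsError("Tukey HSD needs at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    res = sps.tukey_hsd(*arrays)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out.append({"a": names[i], "b": names[j],
                        "estimate": float(arrays[i].mean() - arrays[j].mean()),
                        "adjusted_p": float(min(res.pvalue[i, j], 1.0)),
                        "test": "tukey_hsd"})
    return out


def dunn(groups: dict, adjust: str = "bonferroni") -> list[dict]:
    """Dunn's rank-based pairwise z tests after Kruskal–Wallis.

    Mean ranks over the pooled sample, z = ΔR̄ / sqrt((N(N+1)/12 − T) (1/nᵢ +
    1/nⱼ)) with tie correction T = Σ(t³−t)/(12(N−1)); two-sided normal p,
    Bonferroni-adjusted by default (the convention of common commercial
    statistics packages), Holm optionally.
    """
    names = list(groups)
    if len(names) < 2:
        raise StatsError("Dunn's test needs at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + len(a)].mean())
        start += len(a)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs, raw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_base * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            pairs.append((i, j, z))
            raw.append(2.0 * sps.norm.sf(abs(z)))
    adj = _adjust(np.array(raw), adjust)
    return [{"a": names[i], "b": names[j], "z": float(z),
             "estimate": float(arrays[i].mean() - arrays[j].mean()),
             "p": float(raw[k]), "adjusted_p": float(adj[k]), "test": "dunn"}
            for k, (i, j, z) in enumerate(pairs)]


def two_way_anova(table: pd.DataFrame, response: str,
                  factors: tuple[str, str] = ("condition", "bone")) -> dict:
    """Type-II two-way ANOVA with interaction (statsmodels OLS backend)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    fa, fb = factors
    counts = table.groupby([fa, fb], observed=True)[response].count()
    full = (table[fa].nunique() * table[fb].nunique())
    if len(counts) < full or (counts < 2).any():
        bad = counts[counts < 2].index.tolist() if len(counts) == full else \
            "missing cells"
        raise StatsError(f"two-way ANOVA needs >= 2 observations per cell: {bad}")
    if np.ptp(table[response].to_numpy(dtype=float)) == 0:
        raise StatsError("response is constant everywhere")
    model = ols(f"{response} ~ C({fa}) * C({fb})", data=table).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    def row(key):
        return {"F": float(tab.loc[key, "F"]), "p": float(tab.loc[key, "PR(>F)"])}
    return {fa: row(f"C({fa})"), fb: row(f"C({fb})"),
            "interaction": row(f"C({fa}):C({fb})"),
            "residual_df": float(tab.loc["Residual", "df"])}


@dataclass
class StatResult:
    """All tests for one pose × motion channel."""

    pose: str
    channel: str
    normal: bool                      # did every group pass the normality gate
    test_name: str                    # omnibus branch that ran
    statistic: float                  # omnibus condition-effect statistic
    p_value: float                    # omnibus condition-effect p
    omnibus: dict = field(default_factory=dict)
    condition_contrasts: list = field(default_factory=list)
    bone_contrasts: list = field(default_factory=list)


def _normality_gate(values_by_group: dict, alpha: float) -> bool:
    for vals in values_by_group.values():
        if len(vals) < 3:
            return False
        if np.ptp(vals) == 0:
            return False
        if shapiro_wilk(vals)[1] <= alpha:
            return False
    return True


def _condition_contrast(intact: np.ndarray, transected: np.ndarray,
                        parametric: bool, paired: bool) -> tuple[float, float, str]:
    estimate = float(transected.mean() - intact.mean())
    if paired:
        if len(intact) != len(transected):
            raise StatsError("paired contrast needs matched samples")
        diff = transected - intact
        if parametric:
            p = float(sps.ttest_rel(transected, intact).pvalue)
            return estimate, p, "paired_t"
        if np.allclose(diff, 0):
            return estimate, 1.0, "wilcoxon"
        return estimate, float(sps.wilcoxon(diff).pvalue), "wilcoxon"
    if parametric:
        return estimate, float(sps.ttest_ind(transected, intact).pvalue), "t"
    p = float(sps.mannwhitneyu(transected, intact,
                               alternative="two-sided").pvalue)
    return estimate, p, "mann_whitney"


def compare_conditions(cohort: pd.DataFrame, alpha: float = 0.05,
                       paired: bool = False,
                       poses: list[str] | None = None,
                       channels: list[str] | None = None,
                       row_groups: dict | None = None,
                       adjust: str = "holm") -> list[StatResult]:
    """Full statistical workflow over a motion cohort table.

    For each pose × channel: Shapiro–Wilk gate per (bone × condition) group,
    then either two-way ANOVA (+ Tukey bone pairs, t condition contrasts) or
    Kruskal–Wallis per factor (+ Dunn bone pairs, Mann–Whitney condition
    contrasts).  Bone-vs-bone pairs are compared within each condition and
    carpal-row family, on the referential-frame channel values, and only
    when that family's omnibus test is significant at ``alpha``.
    """
    required = {"specimen", "bone", "pose", "condition"}
    if not required <= set(cohort.columns):
        raise StatsError(f"cohort table must contain columns {sorted(required)}")
    conditions = sorted(cohort["condition"].unique())
    if set(conditions) != {"intact", "transected"}:
        raise StatsError("cohort must contain both intact and transected conditions")
    cohort = cohort.sort_values(["specimen", "bone", "pose", "condition"],
                                kind="stable")
    poses = poses or [p for p in cohort["pose"].unique() if p != "neutral"]
    channels = channels or [c for c in CHANNELS if c in cohort.columns]
    row_groups = row_groups if row_groups is not None else DEFAULT_ROW_GROUPS
    results = []
    for pose in poses:
        sub = cohort[cohort["pose"] == pose]
        bones = sorted(sub["bone"].unique())
        for channel in channels:
            groups = {
                (bone, cond): g[channel].to_numpy(dtype=float)
                for (bone, cond), g in sub.groupby(["bone", "condition"],
                                                   observed=True)}
            normal = _normality_gate(groups, alpha)
            omnibus: dict = {}
            if normal:
                anova = two_way_anova(sub, channel)
                omnibus["two_way_anova"] = anova
                stat, p = anova["condition"]["F"], anova["condition"]["p"]
                test_name = "two_way_anova"
            else:
                kw_cond = kruskal_wallis(
                    [sub[sub["condition"] == c][channel].to_numpy(dtype=float)
                     for c in conditions])
                kw_bone = kruskal_wallis(
                    [sub[sub["bone"] == b][channel].to_numpy(dtype=float)
                     for b in bones])
                omnibus["kruskal_condition"] = {"H": kw_cond[0], "p": kw_cond[1]}
                omnibus["kruskal_bone"] = {"H": kw_bone[0], "p": kw_bone[1]}
                stat, p = kw_cond
                test_name = "kruskal_wallis"
            # per-bone condition contrasts (transected − intact)
            contrasts = []
            raw_ps = []
            for bone in bones:
                est, praw, test = _condition_contrast(
                    groups[(bone, "intact")], groups[(bone, "transected")],
                    parametric=normal, paired=paired)
                contrasts.append({"bone": bone, "estimate": est, "p": praw,
                                  "test": test})
                raw_ps.append(praw)
            adj = _adjust(np.array(raw_ps),
                          adjust if normal else "bonferroni")
            for c, pa in zip(contrasts, adj):
                c["adjusted_p"] = float(pa)
            # bone-vs-bone contrasts within condition and row family
            bone_pairs = []
            for cond in conditions:
                for row_name, row_bones in row_groups.items():
                    present = [b for b in row_bones if (b, cond) in groups]
                    if len(present) < 2:
                        continue
                    fam = {b: groups[(b, cond)] for b in present}
                    if normal:
                        fam_h, fam_p = _anova_oneway(fam)
                        pairs = tukey_hsd(fam) if fam_p <= alpha else []
                    else:
                        try:
                            fam_h, fam_p = kruskal_wallis(list(fam.values()))
                        except StatsError:
                            continue
                        pairs = dunn(fam) if fam_p <= alpha else []
                    for pr in pairs:
                        pr.update({"condition": cond, "row": row_name})
                        bone_pairs.append(pr)
            results.append(StatResult(pose=pose, channel=channel, normal=normal,
                                      test_name=test_name, statistic=float(stat),
                                      p_value=float(p), omnibus=omnibus,
                                      condition_contrasts=contrasts,
                                      bone_contrasts=bone_pairs))
    return results


def _anova_oneway(groups: dict) -> tuple[float, float]:
    res = sps.f_oneway(*[np.asarray(v, dtype=float) for v in groups.values()])
    return float(res.statistic), float(res.pvalue)


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    """Flat summary table (one row per pose × channel)."""
    rows = []
    for r in results:
        for c in r.condition_contrasts:
            rows.append({"pose": r.pose, "channel": r.channel,
                         "normal": r.normal, "omnibus_test": r.test_name,
                         "omnibus_p": r.p_value, "bone": c["bone"],
                         "estimate": c["estimate"], "p": c["p"],
                         "adjusted_p": c["adjusted_p"], "test": c["test"]})
    return pd.DataFrame(rows)
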