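"""2AFC behavioral analysis: logit transform, chance-level tests, mixed ANOVA.

Correct-response proportions from a two-alternative forced-choice test are
binomial, so they are logit-transformed before parametric testing; at the
chance level p = 0.5 the logit is exactly 0, which makes the chance-level
comparison a one-sample t-test against zero.  Group differences in overall
accuracy use an independent-samples pooled-variance t with Hedges'
small-sample-corrected standardized mean difference
g = d * (1 - 3 / (4 df - 1)).  The Group x Modality design is analysed
with a classical split-plot (mixed-design) ANOVA: group between subjects,
modality within, with subjects-within-group and modality x
subjects-within-group error strata and partial eta squared effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "logit_proportion",
    "one_sample_t",
    "independent_t_hedges",
    "mixed_anova_2x3",
    "BehavioralStudy",
    "BehavioralResults",
]

MODALITIES = ("audiovisual", "auditory", "visual")


def logit_proportion(n_correct: int, n_trials: int, correction: bool = True) -> float:
    """Logit of a correct-response proportion.

    With ``correction`` (default) the proportion is shrunk as
    p' = (k + 0.5) / (n + 1) so that 0 and n stay finite; without it the
    raw proportion is used and k in {0, n} raises.  Chance (k = n/2) maps
    to 0 in both modes.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 <= n_correct <= n_trials):
        raise ValueError("n_correct must lie in [0, n_trials]")
    if correction:
        p = (n_correct + 0.5) / (n_trials + 1.0)
    else:
        p = n_correct / n_trials
        if p in (0.0, 1.0):
            raise ValueError("raw proportion of 0 or 1 has an infinite logit; enable the correction")
    return math.log(p / (1.0 - p))


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, int, float, float]:
    """One-sample t-test with Cohen's d; returns (t, df, d, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    n = x.size
    d = (x.mean() - mu0) / sd
    t = d * math.sqrt(n)
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), n - 1, float(d), float(p)


def independent_t_hedges(
    group_a=None,
    group_b=None,
    *,
    summary: tuple[float, float, int, float, float, int] | None = None,
) -> tuple[float, int, float, float]:
    """Pooled-variance two-sample t-test with Hedges' g; returns (t, df, g, p).

    Either pass the two samples, or ``summary = (mean_a, sd_a, n_a,
    mean_b, sd_b, n_b)`` to recompute from reported statistics.
    """
    if summary is not None:
        ma, sa, na, mb, sb, nb = summary
    else:
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least 2 observations per group")
        ma, sa, na = a.mean(), a.std(ddof=1), a.size
        mb, sb, nb = b.mean(), b.std(ddof=1), b.size
    df = na + nb - 2
    pooled_var = ((na - 1) * sa**2 + (nb - 1) * sb**2) / df
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    pooled_sd = math.sqrt(pooled_var)
    d = (ma - mb) / pooled_sd
    t = d / math.sqrt(1.0 / na + 1.0 / nb)
    g = d * (1.0 - 3.0 / (4.0 * df - 1.0))
    p = 2.0 * sps.t.sf(abs(t), df=df)
    return float(t), int(df), float(g), float(p)


def mixed_anova_2x3(table: pd.DataFrame, value_col: str = "logit_value") -> pd.DataFrame:
    """Classical split-plot ANOVA: Group (between) x Modality (within).

    ``table`` needs columns subject, group, modality and the value column,
    with every subject measured in every modality (complete data).
    Returns a table with sums of squares, F, df and partial eta squared
    for the group main effect, the modality main effect and the
    interaction.
    """
    req = {"subject", "group", "modality", value_col}
    if not req <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    wide = table.pivot_table(index=["group", "subject"], columns="modality", values=value_col)
    if wide.isna().any().any():
        raise ValueError("incomplete data: every subject needs a value for every modality")
    groups = wide.index.get_level_values("group")
    y = wide.to_numpy()
    n_total, b = y.shape
    levels = pd.unique(groups)
    a = len(levels)
    if a < 2 or b < 2:
        raise ValueError("need at least 2 groups and 2 within-subject levels")
    gm = y.mean()
    subj_means = y.mean(axis=1)
    ss_total = ((y - gm) ** 2).sum()
    ss_subjects = b * ((subj_means - gm) ** 2).sum()
    ss_group = 0.0
    ss_cells = 0.0
    for g in levels:
        sel = groups == g
        ss_group += b * sel.sum() * (y[sel].mean() - gm) ** 2
        ss_cells += sel.sum() * ((y[sel].mean(axis=0) - y[sel].mean() - y.mean(axis=0) + gm) ** 2).sum()
    ss_subj_within = ss_subjects - ss_group
    ss_modality = n_total * ((y.mean(axis=0) - gm) ** 2).sum()
    ss_interaction = ss_cells
    ss_resid = ss_total - ss_subjects - ss_modality - ss_interaction
    df_group, df_subj = a - 1, n_total - a
    df_mod, df_int = b - 1, (a - 1) * (b - 1)
    df_resid = (b - 1) * (n_total - a)
    rows = []
    for name, ss, df1, ss_err, df2 in (
        ("group", ss_group, df_group, ss_subj_within, df_subj),
        ("modality", ss_modality, df_mod, ss_resid, df_resid),
        ("group_x_modality", ss_interaction, df_int, ss_resid, df_resid),
    ):
        ms, ms_err = ss / df1, ss_err / df2
        f = ms / ms_err if ms_err > 0 else 0.0
        rows.append(
            {
                "effect": name,
                "ss": ss,
                "df1": df1,
                "df2": df2,
                "F": f,
                "p": float(sps.f.sf(f, df1, df2)) if ms_err > 0 else 1.0,
                "partial_eta_sq": ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BehavioralResults:
    """Fitted behavioral analysis: chance tests, ANOVA, group comparison."""

    table: pd.DataFrame
    chance_tests: pd.DataFrame
    anova: pd.DataFrame
    group_comparison: dict

    def summary(self) -> str:
        lines = ["2AFC behavioral analysis", "========================", "", "Chance-level tests (logit units, mu0 = 0):"]
        for _, r in self.chance_tests.iterrows():
            lines.append(
                f"  {r['group']:<14} {r['modality']:<12} mean={r['mean']: .3f}  "
                f"t({int(r['df'])})={r['t']:.3f} (d={r['cohen_d']:.3f})  p={r['p']:.3g}"
            )
        lines.append("")
        lines.append("Mixed ANOVA (Group between, Modality within):")
        for _, r in self.anova.iterrows():
            lines.append(
                f"  {r['effect']:<18} F({int(r['df1'])}, {int(r['df2'])}) = {r['F']:.3f}  "
                f"p={r['p']:.3g}  partial eta^2={r['partial_eta_sq']:.3f}"
            )
        gc = self.group_comparison
        lines.append("")
        lines.append(
            f"Group comparison ({gc['group_a']} - {gc['group_b']}): "
            f"t({gc['df']}) = {gc['t']:.3f}, p = {gc['p']:.3g}, Hedges' g = {gc['hedges_g']:.4f}"
        )
        return "\n".join(lines)


class BehavioralStudy:
    """Model object for the 2AFC study; ``fit()`` runs the full analysis.

    The input table has one row per subject x modality with counts
    ``n_correct`` / ``n_trials`` (or a precomputed ``logit_value``).
    """

    def __init__(self, table: pd.DataFrame, correction: bool = True):
        t = table.copy()
        req = {"subject", "group", "modality"}
        if not req <= set(t.columns):
            raise ValueError(f"table must have columns {sorted(req)}")
        bad = set(t["modality"]) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities {sorted(bad)}; expected {MODALITIES}")
        if "logit_value" not in t.columns:
            if not {"n_correct", "n_trials"} <= set(t.columns):
                raise ValueError("need either logit_value or n_correct/n_trials columns")
            if ((t["n_correct"] < 0) | (t["n_correct"] > t["n_trials"])).any():
                raise ValueError("n_correct must lie in [0, n_trials]")
            t["logit_value"] = [
                logit_proportion(k, n, correction) for k, n in zip(t["n_correct"], t["n_trials"])
            ]
        self.table = t
        self.correction = correction

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, correction: bool = True) -> "BehavioralStudy":
        return cls(table, correction=correction)

    @classmethod
    def from_tsv(cls, path, correction: bool = True) -> "BehavioralStudy":
        return cls(pd.read_csv(path, sep="\t"), correction=correction)

    def fit(self) -> BehavioralResults:
        t = self.table
        rows = []
        for (group, modality), sub in t.groupby(["group", "modality"], sort=True):
            tt, df, d, p = one_sample_t(sub["logit_value"], mu0=0.0)
            rows.append(
                {"group": group, "modality": modality, "mean": sub["logit_value"].mean(),
                 "t": tt, "df": df, "cohen_d": d, "p": p}
            )
        chance = pd.DataFrame(rows)
        anova = mixed_anova_2x3(t)
        # overall accuracy per subject: logit of the pooled counts when counts
        # are available, otherwise the mean logit across modalities
        if {"n_correct", "n_trials"} <= set(t.columns):
            pooled = t.groupby(["group", "subject"], sort=True)[["n_correct", "n_trials"]].sum().reset_index()
            pooled["overall"] = [
                logit_proportion(k, n, self.correction) for k, n in zip(pooled["n_correct"], pooled["n_trials"])
            ]
        else:
            pooled = t.groupby(["group", "subject"], sort=True)["logit_value"].mean().rename("overall").reset_index()
        groups = list(pd.unique(pooled["group"]))
        if len(groups) != 2:
            raise ValueError("group comparison needs exactly 2 groups")
        ga = pooled.loc[pooled["group"] == groups[0], "overall"]
        gb = pooled.loc[pooled["group"] == groups[1], "overall"]
        tt, df, g, p = independent_t_hedges(ga, gb)
        comparison = {"group_a": groups[0], "group_b": groups[1], "t": tt, "df": df, "hedges_g": g, "p": p,
                      "mean_a": float(ga.mean()), "mean_b": float(gb.mean())}
        return BehavioralResults(table=t, chance_tests=chance, anova=anova, group_comparison=comparison)
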