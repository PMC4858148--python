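"""RT-qPCR relative quantification and the temporal biomarker-panel rule.

Cq values are normalized to the U6 small-RNA reference
(dCq = Cq_miRNA - mean Cq_U6 of the stage), expressed relative to a
baseline stage with the 2^-ddCq method, and tested across weekly
stages with one-way fixed-effects ANOVA. A miRNA joins the
puberty-onset biomarker panel when its profile is (i) stable over the
early weeks, (ii) rises significantly (P < 0.01) across the onset
pair of weeks (12 -> 13 by default), and (iii) stays at or above the
onset level through the last sampled week.

Significance calls that would demote a miRNA (early instability, a
post-onset drop) additionally require a minimum effect size
(``min_effect_cq``, default 1 Cq = 2-fold): with truly flat profiles
the ANOVA p-value is uniform, so a pure p >= alpha stability rule
would spuriously reject 5% of genuinely stable miRNAs. Setting
``min_effect_cq=0`` restores the pure significance rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_ID = "U6"
CQ_COLUMNS = ("mirna", "stage_week", "replicate", "cq")


def load_cq_table(path_or_df) -> pd.DataFrame:
    """Load and validate a Cq table (TSV or DataFrame with columns
    mirna, stage_week, replicate, cq)."""
    df = (path_or_df if isinstance(path_or_df, pd.DataFrame)
          else pd.read_csv(path_or_df, sep="\t"))
    missing = set(CQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    sizes = df.groupby(["mirna", "stage_week"]).size()
    thin = sizes[sizes < 2]
    if len(thin):
        raise ValueError(
            f"need >= 2 replicates per (miRNA, stage); offending groups: "
            f"{list(thin.index[:5])}")
    return df


def validate_reference(cq: pd.DataFrame, reference: str = REFERENCE_ID,
                       max_diff: float = 0.6) -> tuple[bool, pd.DataFrame]:
    """Reference-gene stability check: stable iff every pairwise absolute
    difference of stage-mean reference Cq is < max_diff. Returns the flag
    and the per-stage-pair difference table; errors if the reference is
    absent from any stage sampled for the other miRNAs."""
    stages = sorted(cq["stage_week"].unique())
    ref = cq[cq["mirna"] == reference]
    ref_stages = set(ref["stage_week"])
    if missing := [s for s in stages if s not in ref_stages]:
        raise ValueError(f"reference {reference!r} missing at stages {missing}")
    means = ref.groupby("stage_week")["cq"].mean()
    rows = [
        {"stage_a": a, "stage_b": b, "abs_diff": abs(means[a] - means[b])}
        for i, a in enumerate(stages) for b in stages[i + 1:]
    ]
    diffs = pd.DataFrame(rows)
    return bool(diffs["abs_diff"].max() < max_diff), diffs


def delta_cq(cq: pd.DataFrame, reference: str = REFERENCE_ID,
             per_replicate: bool = False) -> pd.DataFrame:
    """Per-replicate dCq = Cq_miRNA - reference Cq of the same stage.

    The reference value is the stage mean by default (replicate pairing
    across plates is usually unknown); ``per_replicate=True`` pairs
    replicate indices instead.
    """
    ref = cq[cq["mirna"] == reference]
    if ref.empty:
        raise ValueError(f"reference {reference!r} absent from Cq table")
    out = cq[cq["mirna"] != reference].copy()
    if per_replicate:
        key = ref.set_index(["stage_week", "replicate"])["cq"]
        out["dcq"] = out["cq"].to_numpy() - key.loc[
            list(zip(out["stage_week"], out["replicate"]))].to_numpy()
    else:
        ref_mean = ref.groupby("stage_week")["cq"].mean()
        out["dcq"] = out["cq"].to_numpy() - ref_mean.loc[
            out["stage_week"]].to_numpy()
    return out


def rel_expression(dcq_means: pd.Series, baseline_stage: int = 10) -> pd.Series:
    """2^-ddCq relative level per stage, with ddCq = dCq(stage) -
    dCq(baseline); the baseline level is exactly 1."""
    if baseline_stage not in dcq_means.index:
        raise ValueError(f"baseline stage {baseline_stage} absent")
    return 2.0 ** -(dcq_means - dcq_means[baseline_stage])


def stage_anova(groups: list[np.ndarray]) -> float:
    """One-way fixed-effects ANOVA p across stage replicate groups; all
    values identical (zero between- and within-group variance) gives
    p = 1 by convention. Requires >= 2 groups of >= 2 values."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 stages with >= 2 replicates each")
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return 1.0
    res = stats.f_oneway(*groups)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


@dataclass
class ExpressionProfile:
    mirna: str
    stages: list[int]
    dcq_mean: pd.Series            # per stage
    levels: pd.Series              # 2^-ddCq vs baseline
    level_sd: pd.Series            # sd of per-replicate 2^-ddCq
    replicates: dict[int, np.ndarray]  # stage -> replicate dCq values
    anova_p: float
    adjacent_p: dict[tuple[int, int], float]


def expression_profile(dcq: pd.DataFrame, mirna: str,
                       baseline_stage: int = 10) -> ExpressionProfile:
    """Summarize one miRNA: stage-mean dCq, relative levels vs baseline,
    per-replicate level spread, overall ANOVA and adjacent-week tests."""
    sub = dcq[dcq["mirna"] == mirna]
    if sub.empty:
        raise ValueError(f"no dCq rows for {mirna!r}")
    stages = sorted(sub["stage_week"].unique())
    groups = {s: sub.loc[sub["stage_week"] == s, "dcq"].to_numpy()
              for s in stages}
    dcq_mean = pd.Series({s: g.mean() for s, g in groups.items()})
    levels = rel_expression(dcq_mean, baseline_stage)
    base = dcq_mean[baseline_stage]
    level_sd = pd.Series({s: (2.0 ** -(g - base)).std(ddof=1)
                          for s, g in groups.items()})
    anova_p = stage_anova(list(groups.values()))
    adjacent = {(a, b): stage_anova([groups[a], groups[b]])
                for a, b in zip(stages, stages[1:])}
    return ExpressionProfile(mirna, stages, dcq_mean, levels, level_sd,
                             groups, anova_p, adjacent)


@dataclass
class PanelDecision:
    mirna: str
    early_stable: bool
    onset_jump: bool
    sustained: bool

    @property
    def verdict(self) -> bool:
        return self.early_stable and self.onset_jump and self.sustained


def panel_classify(profiles: list[ExpressionProfile],
                   alpha_stable: float = 0.05,
                   alpha_jump: float = 0.01,
                   alpha_drop: float = 0.05,
                   onset_pair: tuple[int, int] = (12, 13),
                   min_effect_cq: float = 1.0,
                   stability_mode: str = "change") -> list[PanelDecision]:
    """Apply the temporal biomarker rule to expression profiles.

    early_stable: no significant early-week (up to the first onset week)
    expression change — ANOVA p >= alpha_stable, or the largest early
    stage-mean dCq difference below min_effect_cq (``stability_mode=
    "low_level"`` instead requires early expression significantly lower
    than post-onset). onset_jump: the onset-pair test significant at
    alpha_jump with rising expression (dCq decreasing). sustained: no
    post-onset week drops below the onset level by min_effect_cq or more
    with significance at alpha_drop.
    """
    w_pre, w_on = onset_pair
    decisions = []
    for pr in profiles:
        if w_pre not in pr.replicates or w_on not in pr.replicates:
            raise ValueError(
                f"{pr.mirna}: onset stages {onset_pair} not both sampled")
        early = [s for s in pr.stages if s <= w_pre]
        early_groups = [pr.replicates[s] for s in early]
        if len(early_groups) >= 2:
            p_early = stage_anova(early_groups)
            spread = max(pr.dcq_mean[s] for s in early) - \
                min(pr.dcq_mean[s] for s in early)
            if stability_mode == "change":
                early_stable = (p_early >= alpha_stable
                                or spread < min_effect_cq)
            elif stability_mode == "low_level":
                late = [s for s in pr.stages if s >= w_on]
                p_low = stage_anova([
                    np.concatenate(early_groups),
                    np.concatenate([pr.replicates[s] for s in late])])
                mean_early = np.concatenate(early_groups).mean()
                mean_late = np.concatenate(
                    [pr.replicates[s] for s in late]).mean()
                early_stable = p_low < alpha_stable and mean_early > mean_late
            else:
                raise ValueError(f"unknown stability_mode {stability_mode!r}")
        else:
            early_stable = True
        p_jump = stage_anova([pr.replicates[w_pre], pr.replicates[w_on]])
        onset_jump = (p_jump < alpha_jump
                      and pr.dcq_mean[w_on] < pr.dcq_mean[w_pre])
        sustained = True
        for w in (s for s in pr.stages if s > w_on):
            drop = pr.dcq_mean[w] - pr.dcq_mean[w_on]  # +ve = expression fell
            if drop < min_effect_cq or drop <= 0:
                continue
            p_drop = stage_anova([pr.replicates[w_on], pr.replicates[w]])
            if p_drop < alpha_drop:
                sustained = False
                break
        decisions.append(PanelDecision(pr.mirna, early_stable, onset_jump,
                                       sustained))
    return decisions


def profiles_frame(profiles: list[ExpressionProfile]) -> pd.DataFrame:
    rows = []
    for pr in profiles:
        for s in pr.stages:
            rows.append({"mirna": pr.mirna, "stage_week": s,
                         "mean_dcq": pr.dcq_mean[s], "level": pr.levels[s],
                         "level_sd": pr.level_sd[s]})
    return pd.DataFrame(rows)


def decisions_frame(decisions: list[PanelDecision]) -> pd.DataFrame:
    return pd.DataFrame([
        {"mirna": d.mirna, "early_stable": d.early_stable,
         "onset_jump": d.onset_jump, "sustained": d.sustained,
         "verdict": "biomarker" if d.verdict else "rejected"}
        for d in decisions
    ])
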