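"""Calibrated relative expression from qRT-PCR Ct tables.

Each well measures a target gene in duplex with a reference gene (an 18S
rRNA partner), giving per-replicate ΔCt = Ct_target − Ct_reference.  Per
condition the mean ΔCt is converted to a fold change relative to a
calibrator condition (the monokaryon, assigned a value of 1):

    fold(condition) = efficiency ** (mean ΔCt_calibrator − mean ΔCt_condition)

With the default amplification efficiency of 2.0 per cycle this is the
classic ΔΔCt method; a per-call efficiency override covers assays whose
standard-curve efficiency differs.  Group separation uses one-way ANOVA
followed by Tukey's HSD at α = 0.05, with a compact letter display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DEFAULT_EFFICIENCY = 2.0
DEFAULT_CALIBRATOR = "monokaryon"


@dataclass(frozen=True)
class CtRecord:
    gene: str
    condition: str
    replicate: int
    ct_target: float
    ct_reference: float


@dataclass(frozen=True)
class RelExpression:
    gene: str
    condition: str
    fold: float
    sd: float  # NaN when < 2 replicates
    n_replicates: int
    group_label: str = ""


def read_ct_csv(path: str | Path) -> list[CtRecord]:
    """Read a Ct table CSV: gene,condition,replicate,ct_target,ct_reference.

    Accepts both per-replicate raw tables and pre-averaged tables (the
    latter simply have one row per gene × condition).
    """
    df = pd.read_csv(path, comment="#")
    required = {"gene", "condition", "replicate", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return [
        CtRecord(str(r.gene), str(r.condition), int(r.replicate),
                 float(r.ct_target), float(r.ct_reference))
        for r in df.itertuples(index=False)
    ]


def relative_expression(
    records: Sequence[CtRecord],
    calibrator: str = DEFAULT_CALIBRATOR,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """Per-gene, per-condition calibrated fold changes.

    The calibrator condition is 1 by construction for every gene.  The
    per-condition sd is the spread of per-replicate folds (each replicate
    ΔCt converted against the calibrator mean); it is NaN with fewer than
    2 replicates.  Records with a missing reference Ct are dropped with a
    warning.  Returns a DataFrame with columns gene, condition, fold, sd,
    n_replicates.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"amplification efficiency must be in (1, 2], got {efficiency}")
    kept = []
    for r in records:
        if not (math.isfinite(r.ct_target) and math.isfinite(r.ct_reference)):
            warnings.warn(f"dropping {r.gene}/{r.condition} rep {r.replicate}: missing Ct")
            continue
        if r.ct_target <= 0 or r.ct_reference <= 0:
            raise ValueError(f"non-positive Ct in {r.gene}/{r.condition} rep {r.replicate}")
        kept.append(r)
    df = pd.DataFrame(
        [(r.gene, r.condition, r.ct_target - r.ct_reference) for r in kept],
        columns=["gene", "condition", "dct"],
    )
    rows = []
    for gene, sub in df.groupby("gene", sort=False):
        cal = sub.loc[sub.condition == calibrator, "dct"]
        if cal.empty:
            raise ValueError(f"calibrator condition {calibrator!r} missing for gene {gene}")
        cal_mean = cal.mean()
        for condition, grp in sub.groupby("condition", sort=False):
            rep_folds = efficiency ** (cal_mean - grp.dct.to_numpy())
            fold = 1.0 if condition == calibrator else float(
                efficiency ** (cal_mean - grp.dct.mean())
            )
            sd = float(np.std(rep_folds, ddof=1)) if len(rep_folds) >= 2 else float("nan")
            rows.append((gene, condition, fold, sd, len(rep_folds)))
    return pd.DataFrame(rows, columns=["gene", "condition", "fold", "sd", "n_replicates"])


def fold_ratio(
    records: Sequence[CtRecord],
    numerator: str = "monokaryon",
    denominator: str = "dikaryon",
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.Series:
    """Per-gene expression ratio numerator/denominator (e.g. mono over di).

    This is the "F-fold higher in the monokaryon" number: with the
    numerator as calibrator it equals 1 / fold(denominator).
    """
    rel = relative_expression(records, calibrator=numerator, efficiency=efficiency)
    den = rel[rel.condition == denominator].set_index("gene").fold
    return (1.0 / den).rename("ratio")


@dataclass(frozen=True)
class GroupTestResult:
    f_stat: float
    p_value: float
    tukey: pd.DataFrame          # pairwise table (group1, group2, meandiff, reject, ...)
    letters: dict[str, str]      # compact letter display per group
    degenerate: bool             # all groups had zero within-group variance


def group_test(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupTestResult:
    """One-way ANOVA plus Tukey HSD over named replicate groups.

    Groups sharing a letter in the compact letter display are not
    significantly different at ``alpha``.  With zero within-group
    variance in every group the ANOVA is degenerate and is flagged
    (pairs with any mean difference are then marked separated).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need at least 2 replicates per group")
    degenerate = all(np.ptp(a) == 0 for a in arrays)
    if degenerate:
        means = {g: float(a.mean()) for g, a in zip(names, arrays)}
        pairs = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = means[names[j]] - means[names[i]]
                pairs.append((names[i], names[j], diff, diff != 0))
        tukey_df = pd.DataFrame(pairs, columns=["group1", "group2", "meandiff", "reject"])
        return GroupTestResult(
            float("inf") if any(p[3] for p in pairs) else 0.0,
            float("nan"), tukey_df, _letters(names, tukey_df), True,
        )
    f_stat, p_value = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey_df = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    return GroupTestResult(
        float(f_stat), float(p_value), tukey_df, _letters(names, tukey_df), False
    )


def _letters(names: Sequence[str], tukey_df: pd.DataFrame) -> dict[str, str]:
    """Greedy compact letter display from the pairwise reject table."""
    separated = {
        frozenset((str(r.group1), str(r.group2)))
        for r in tukey_df.itertuples(index=False)
        if bool(r.reject)
    }
    letters: dict[str, str] = {}
    clusters: list[set[str]] = []  # groups sharing a letter
    for g in names:
        placed = False
        for cluster in clusters:
            if all(frozenset((g, other)) not in separated for other in cluster):
                cluster.add(g)
                placed = True
                break
        if not placed:
            clusters.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for g in names:
        letters[g] = "".join(
            alphabet[i] for i, cluster in enumerate(clusters) if g in cluster
        )
    return letters


def expression_report(
    records: Sequence[CtRecord],
    calibrator: str = DEFAULT_CALIBRATOR,
    efficiency: float = DEFAULT_EFFICIENCY,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fold table with per-gene Tukey group letters attached.

    Replicate folds (against the calibrator mean ΔCt) are the units the
    per-gene ANOVA compares across conditions.
    """
    rel = relative_expression(records, calibrator, efficiency)
    df = pd.DataFrame(
        [(r.gene, r.condition, r.ct_target - r.ct_reference) for r in records
         if math.isfinite(r.ct_target) and math.isfinite(r.ct_reference)],
        columns=["gene", "condition", "dct"],
    )
    group_col = []
    for row in rel.itertuples(index=False):
        sub = df[df.gene == row.gene]
        cal_mean = sub.loc[sub.condition == calibrator, "dct"].mean()
        groups = {
            cond: list(efficiency ** (cal_mean - grp.dct.to_numpy()))
            for cond, grp in sub.groupby("condition", sort=False)
        }
        try:
            letters = group_test(groups, alpha=alpha).letters
            group_col.append(letters.get(row.condition, ""))
        except ValueError:
            group_col.append("")
    out = rel.copy()
    out["group"] = group_col
    return out


def plot_expression(rel: pd.DataFrame, path: str | Path) -> None:
    """Bar plot of calibrated folds with sd error bars, one bar group per gene."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = list(dict.fromkeys(rel.gene))
    conditions = list(dict.fromkeys(rel.condition))
    x = np.arange(len(genes))
    width = 0.8 / max(len(conditions), 1)
    fig, ax = plt.subplots(figsize=(1.5 * len(genes) + 2, 4))
    for k, cond in enumerate(conditions):
        sub = rel[rel.condition == cond].set_index("gene").reindex(genes)
        ax.bar(x + k * width, sub.fold, width, yerr=sub.sd.fillna(0),
               capsize=3, label=cond)
    ax.set_xticks(x + width * (len(conditions) - 1) / 2)
    ax.set_xticklabels(genes, rotation=45, ha="right")
    ax.set_ylabel("relative expression (calibrator = 1)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
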