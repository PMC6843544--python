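"""Relative qPCR expression by the 2^-ΔΔCt (Pfaffl) method.

Workflow: technical replicates of each (sample, gene) are averaged first;
ΔCt = Ct(target) − Ct(reference gene, e.g. EF-α) per biological replicate;
ΔΔCt = ΔCt(sample) − mean ΔCt(control group); the expression ratio is
2^−ΔΔCt (or the efficiency-corrected generalisation
E_target^−ΔCt_target / E_ref^−ΔCt_ref when amplification efficiencies
differ from the ideal doubling).  Group comparisons use one-way ANOVA
followed by Tukey's HSD, with significance stars at p < 0.05 (*) and
p < 0.01 (**).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CtTable",
    "FoldChangeResult",
    "read_ct_table",
    "delta_ct",
    "delta_delta_ct_table",
    "fold_change",
    "pfaffl_ratio",
    "anova_tukey",
    "stars",
]

CT_COLUMNS = ["sample_id", "genotype", "tissue", "condition", "gene", "bio_rep", "tech_rep", "ct"]


@dataclass(frozen=True)
class FoldChangeResult:
    """Relative expression of one group versus its control."""

    group: str
    delta_ct: float
    delta_delta_ct: float
    ratio: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("expression ratio must be positive")


class CtTable:
    """Long-format qPCR Ct measurements.

    One row per well: sample_id, genotype, tissue, condition, gene
    ('target' or 'reference'), bio_rep, tech_rep, ct.
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(CT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if (df["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        self.df = df.copy()

    def tech_averaged(self) -> pd.DataFrame:
        """Average technical replicates within each (sample, gene)."""
        keys = ["sample_id", "genotype", "tissue", "condition", "gene", "bio_rep"]
        return self.df.groupby(keys, as_index=False)["ct"].mean()


def read_ct_table(path: str | Path) -> CtTable:
    return CtTable(pd.read_csv(path))


def delta_ct(target_ct: float | Sequence[float], reference_ct: float | Sequence[float]) -> float:
    """ΔCt = mean(target Ct) − mean(reference Ct), technical reps averaged."""
    t = np.atleast_1d(np.asarray(target_ct, dtype=float))
    r = np.atleast_1d(np.asarray(reference_ct, dtype=float))
    if t.size == 0 or r.size == 0:
        raise ValueError("both target and reference Ct values are required")
    return float(t.mean() - r.mean())


def pfaffl_ratio(
    delta_ct_target: float,
    delta_ct_reference: float = 0.0,
    efficiency_target: float = 2.0,
    efficiency_reference: float = 2.0,
) -> float:
    """Efficiency-corrected expression ratio.

    ``delta_ct_*`` here are Ct(control) − Ct(sample) exponents per gene.
    With both efficiencies at the ideal 2.0 this reduces to 2^-ΔΔCt.
    """
    if efficiency_target <= 1 or efficiency_reference <= 1:
        raise ValueError("amplification efficiencies must exceed 1")
    return (efficiency_target**delta_ct_target) / (efficiency_reference**delta_ct_reference)


def fold_change(sample_delta_cts: Sequence[float], control_delta_cts: Sequence[float], group: str = "sample") -> FoldChangeResult:
    """Pfaffl 2^-ΔΔCt fold change of a sample group against its control.

    ΔΔCt uses the mean control ΔCt; the dispersion reported is the SEM of
    the per-biological-replicate ratios.
    """
    s = np.asarray(sample_delta_cts, dtype=float)
    c = np.asarray(control_delta_cts, dtype=float)
    if c.size == 0:
        raise ValueError("control group is empty")
    if s.size == 0:
        raise ValueError("sample group is empty")
    ddct = s - c.mean()
    ratios = 2.0 ** (-ddct)
    sem = float(ratios.std(ddof=1) / math.sqrt(ratios.size)) if ratios.size > 1 else 0.0
    return FoldChangeResult(
        group=group,
        delta_ct=float(s.mean()),
        delta_delta_ct=float(ddct.mean()),
        ratio=float(ratios.mean()),
        sem=sem,
        n=int(s.size),
    )


def delta_delta_ct_table(
    table: CtTable,
    control_condition: object,
    by: Sequence[str] = ("genotype", "tissue"),
) -> pd.DataFrame:
    """Per-group Pfaffl results across conditions.

    Within each ``by`` stratum (default: genotype × tissue) every condition
    is compared against that stratum's own ``control_condition``.  Returns
    one row per (stratum, condition) with ΔCt, ΔΔCt, ratio, SEM, n, and the
    per-replicate ratios needed for downstream ANOVA/Tukey.
    """
    avg = table.tech_averaged()
    piv = avg.pivot_table(
        index=[*by, "condition", "bio_rep"], columns="gene", values="ct"
    ).reset_index()
    for gene in ("target", "reference"):
        if gene not in piv.columns:
            raise ValueError(f"Ct table has no {gene!r} gene rows")
    if piv[["target", "reference"]].isna().any().any():
        raise ValueError("each biological replicate needs both target and reference Ct")
    piv["delta_ct"] = piv["target"] - piv["reference"]

    rows = []
    for stratum, sub in piv.groupby(list(by)):
        controls = sub.loc[sub["condition"] == control_condition, "delta_ct"].to_numpy()
        if controls.size == 0:
            raise ValueError(f"no control condition {control_condition!r} in stratum {stratum}")
        for cond, grp in sub.groupby("condition"):
            ddct = grp["delta_ct"].to_numpy() - controls.mean()
            ratios = 2.0 ** (-ddct)
            rows.append(
                {
                    **dict(zip(by, stratum if isinstance(stratum, tuple) else (stratum,))),
                    "condition": cond,
                    "n": len(ratios),
                    "delta_ct": grp["delta_ct"].mean(),
                    "delta_delta_ct": float(np.mean(ddct)),
                    "ratio": float(np.mean(ratios)),
                    "sem": float(np.std(ratios, ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else 0.0,
                    "replicate_ratios": tuple(float(r) for r in ratios),
                }
            )
    return pd.DataFrame(rows)


def stars(p: float) -> str:
    """Significance annotation: ** for p<0.01, * for p<0.05, else ns."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    control: str | None = None,
    include_pairwise: bool = True,
) -> dict[str, object]:
    """One-way ANOVA followed by Tukey HSD pairwise comparisons.

    Returns the omnibus p-value, a DataFrame of Tukey-adjusted pairwise
    p-values with significance stars, and (when ``control`` is given) the
    stars of each group against the control.  A fully degenerate input —
    zero variance everywhere and equal group means — yields omnibus p = 1.
    ``include_pairwise=False`` skips the Tukey table (omnibus only), useful
    in calibration loops.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 replicates")

    pooled = np.concatenate(arrays)
    if np.allclose(pooled.var(), 0.0):
        p_omnibus = 1.0
        pairs = pd.DataFrame(
            [
                {"group_a": a, "group_b": b, "meandiff": 0.0, "p_adj": 1.0, "stars": "ns"}
                for i, a in enumerate(labels)
                for b in labels[i + 1 :]
            ]
        )
    else:
        p_omnibus = float(stats.f_oneway(*arrays).pvalue)
        if not include_pairwise:
            return {"p_omnibus": p_omnibus, "pairwise": None, "stars_omnibus": stars(p_omnibus)}
        values = np.concatenate(arrays)
        codes = np.concatenate([[g] * len(a) for g, a in zip(labels, arrays)])
        tk = pairwise_tukeyhsd(values, codes, alpha=0.05)
        from itertools import combinations

        pair_labels = list(combinations([str(g) for g in tk.groupsunique], 2))
        pairs = pd.DataFrame(
            [
                {
                    "group_a": a,
                    "group_b": b,
                    "meandiff": float(md),
                    "p_adj": float(p),
                }
                for (a, b), md, p in zip(pair_labels, tk.meandiffs, tk.pvalues)
            ]
        )
        pairs["stars"] = pairs["p_adj"].map(stars)

    out: dict[str, object] = {"p_omnibus": p_omnibus, "pairwise": pairs, "stars_omnibus": stars(p_omnibus)}
    if control is not None:
        if control not in labels:
            raise KeyError(f"control group {control!r} not among groups")
        vs = {}
        for _, row in pairs.iterrows():
            if control in (row["group_a"], row["group_b"]):
                other = row["group_b"] if row["group_a"] == control else row["group_a"]
                vs[other] = row["stars"]
        out["stars_vs_control"] = vs
    return out
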