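"""Per-cell lipid peroxidation ratio quantification and group comparison.

The assay images cells loaded with a ratiometric lipid peroxidation
sensor; per cell, the ratio of the oxidized (510 nm emission) to the
non-oxidized (590 nm emission) channel quantifies peroxidized membrane
lipid. Conditions are compared by one-way ANOVA with Tukey HSD all-pairs
or Dunnett many-to-one post-hoc tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def per_cell_ratio(i510: float, i590: float) -> float:
    """Oxidized / non-oxidized channel ratio for one cell."""
    if i590 <= 0:
        raise ValueError("non-oxidized channel intensity must be positive")
    if i510 < 0:
        raise ValueError("oxidized channel intensity must be non-negative")
    return i510 / i590


def ratio_table(records: pd.DataFrame) -> pd.DataFrame:
    """Attach per-cell ratios; cells with zero 590 nm signal are excluded."""
    bad = records["i590"] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} cells with zero 590 nm signal")
    out = records.loc[~bad].copy()
    out["ratio"] = out["i510"] / out["i590"]
    return out


def condition_summary(records: pd.DataFrame, expected_n: int = 50) -> pd.DataFrame:
    """Mean, SD and n of the per-cell ratio for each condition.

    Warns when a condition deviates from the expected number of analyzed
    cells (50 per condition by assay convention).
    """
    if len(records) == 0:
        raise ValueError("no cells provided")
    if "ratio" not in records.columns:
        records = ratio_table(records)
    rows = []
    for cond, sub in records.groupby("condition"):
        n = len(sub)
        if n == 0:
            raise ValueError(f"empty condition {cond!r}")
        if n != expected_n:
            warnings.warn(f"condition {cond!r} has {n} cells, expected {expected_n}")
        rows.append((cond, sub["ratio"].mean(), sub["ratio"].std(ddof=1), n))
    return pd.DataFrame(rows, columns=["condition", "mean", "sd", "n"]).set_index("condition")


@dataclass
class ConditionComparison:
    f_statistic: float
    p_anova: float
    posthoc: pd.DataFrame
    method: str


def compare_conditions(
    records: pd.DataFrame,
    posthoc: str = "tukey",
    control: str | None = None,
) -> ConditionComparison:
    """One-way ANOVA across conditions with familywise post-hoc tests.

    ``posthoc="tukey"`` runs all-pairs Tukey HSD; ``posthoc="dunnett"``
    compares every condition against ``control`` with the exact Dunnett
    many-to-one procedure.
    """
    if "ratio" not in records.columns:
        records = ratio_table(records)
    by_cond = {c: s["ratio"].to_numpy() for c, s in records.groupby("condition")}
    if len(by_cond) < 2:
        raise ValueError("need >= 2 conditions")
    if any(len(v) < 2 for v in by_cond.values()):
        raise ValueError("need >= 2 cells per condition")
    if all(np.var(v) == 0 for v in by_cond.values()):
        raise ValueError("zero within-group variance in every condition")

    names = sorted(by_cond)
    arrays = [by_cond[n] for n in names]
    f, p = sps.f_oneway(*arrays)

    if posthoc == "tukey":
        res = sps.tukey_hsd(*arrays)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    (names[i], names[j], float(res.statistic[i, j]), float(res.pvalue[i, j]))
                )
        table = pd.DataFrame(rows, columns=["condition_a", "condition_b", "mean_diff", "p_adj"])
    elif posthoc == "dunnett":
        if control is None or control not in by_cond:
            raise ValueError("dunnett post-hoc requires a valid control condition")
        others = [n for n in names if n != control]
        res = sps.dunnett(*[by_cond[n] for n in others], control=by_cond[control])
        table = pd.DataFrame(
            {
                "condition_a": others,
                "condition_b": control,
                "mean_diff": [by_cond[n].mean() - by_cond[control].mean() for n in others],
                "p_adj": res.pvalue,
            }
        )
    else:
        raise ValueError("posthoc must be 'tukey' or 'dunnett'")
    return ConditionComparison(float(f), float(p), table, posthoc)
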