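"""RNAi screen scoring: condition scores, summary scores, top-k overlaps.

Each knockdown x treatment-arm x endpoint condition is summarized as a
magnitude (SER for viability, knockdown/control fold change otherwise)
and a p-value (Welch t vs. the non-targeting control within the arm; the
one-way ANOVA omnibus p across genes is reported alongside). The
condition score -log10(p) * magnitude rewards strong, reproducible
sensitization, and the per-gene summary score sums conditions over
endpoints, arms and cell models.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import radiobiology

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
BASAL_ARM = "basal"
VIABILITY = "viability"


def endpoint_statistics(
    measurements: pd.DataFrame,
    control_gene: str = "siC",
    basal_arm: str = BASAL_ARM,
) -> pd.DataFrame:
    """Magnitude and p-value per (cell model, gene, arm, endpoint).

    Viability magnitude in a treated arm is the SER against the basal
    arm; in the basal arm it is control/knockdown (so that killing scores
    above 1). Other endpoints use knockdown/control within the arm. p is
    the two-sided Welch t of knockdown vs control replicates in the arm;
    the ANOVA omnibus p over all genes in the arm x endpoint cell is
    attached as ``p_anova``. Conditions with < 2 replicates are dropped.
    """
    required = {"cell_model", "gene", "arm", "endpoint", "replicate", "value"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    basal_lookup = {
        key: sub["value"].to_numpy()
        for key, sub in measurements[measurements["arm"] == basal_arm].groupby(
            ["cell_model", "endpoint", "gene"]
        )
    }
    rows = []
    for (model, arm, ep), cell in measurements.groupby(["cell_model", "arm", "endpoint"]):
        byg = {g: v["value"].to_numpy() for g, v in cell.groupby("gene")}
        if control_gene not in byg:
            raise ValueError(f"control {control_gene!r} absent in {(model, arm, ep)}")
        ctrl = byg[control_gene]
        groups = [v for v in byg.values() if len(v) >= 2]
        p_anova = (
            float(sps.f_oneway(*groups).pvalue) if len(groups) >= 2 else float("nan")
        )
        for gene, vals in byg.items():
            if gene == control_gene:
                continue
            if len(vals) < 2 or len(ctrl) < 2:
                logger.warning("dropping %s: <2 replicates", (model, gene, arm, ep))
                continue
            if ep == VIABILITY:
                if arm == basal_arm:
                    magnitude = float(ctrl.mean() / vals.mean())
                else:
                    c0 = basal_lookup[(model, ep, control_gene)]
                    g0 = basal_lookup[(model, ep, gene)]
                    magnitude = radiobiology.ser(ctrl, c0, vals, g0).ser
            else:
                magnitude = float(vals.mean() / ctrl.mean())
            p = float(sps.ttest_ind(vals, ctrl, equal_var=False).pvalue)
            rows.append((model, gene, arm, ep, magnitude, p, p_anova))
    return pd.DataFrame(
        rows,
        columns=["cell_model", "gene", "arm", "endpoint", "magnitude", "p", "p_anova"],
    )


def condition_score(magnitude: float, p: float) -> float:
    """Score = -log10(p) * magnitude, with p floored at 1e-300."""
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    return float(-np.log10(max(p, P_FLOOR)) * magnitude)


def score_conditions(stats: pd.DataFrame) -> pd.DataFrame:
    """Attach the condition score to an endpoint-statistics table."""
    out = stats.copy()
    out["score"] = [
        condition_score(m, p) for m, p in zip(out["magnitude"], out["p"])
    ]
    return out


def summary_score(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary score: sum of condition scores over everything.

    Returns genes ranked by descending total with per-model subtotals.
    """
    if "score" not in scores.columns:
        scores = score_conditions(scores)
    total = scores.groupby("gene")["score"].sum()
    n_cond = scores.groupby("gene")["score"].size()
    per_model = scores.pivot_table(
        index="gene", columns="cell_model", values="score", aggfunc="sum", fill_value=0.0
    )
    out = pd.DataFrame({"total": total, "n_conditions": n_cond}).join(
        per_model.add_prefix("total_")
    )
    out = out.sort_values(["total", "gene"], ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def endpoint_rankings(scores: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Gene ranking per (cell model, endpoint), by score summed over arms."""
    if "score" not in scores.columns:
        scores = score_conditions(scores)
    rankings: dict[tuple[str, str], list[str]] = {}
    for (model, ep), sub in scores.groupby(["cell_model", "endpoint"]):
        totals = sub.groupby("gene")["score"].sum().sort_values(ascending=False, kind="stable")
        rankings[(model, ep)] = totals.index.tolist()
    return rankings


def top_k_overlap(
    rankings: Mapping[tuple[str, str], Sequence[str]],
    k: int = 3,
) -> dict[str, list[str]]:
    """Per endpoint, the intersection of top-k genes across cell models.

    Output lists are lexicographically sorted.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    endpoints = sorted({ep for _, ep in rankings})
    out = {}
    for ep in endpoints:
        tops = [
            set(list(genes)[:k]) for (model, e), genes in rankings.items() if e == ep
        ]
        out[ep] = sorted(set.intersection(*tops)) if tops else []
    return out


def plot_score_matrix(scores: pd.DataFrame, ax=None):
    """Plain gene x condition matrix plot of the screen scores."""
    import matplotlib.pyplot as plt

    if "score" not in scores.columns:
        scores = score_conditions(scores)
    mat = scores.pivot_table(
        index="gene",
        columns=["cell_model", "arm", "endpoint"],
        values="score",
        aggfunc="first",
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, mat.shape[1] * 0.35), max(4, mat.shape[0] * 0.3)))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(mat.index)), mat.index)
    ax.set_xticks(range(len(mat.columns)), ["|".join(map(str, c)) for c in mat.columns], rotation=90, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="score")
    return ax
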