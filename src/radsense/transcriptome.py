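"""Candidate prioritization from bulk expression and survival data.

Implements the tumor-target nomination chain: low-expression filtering,
log2-CPM with cyclic loess normalization, tumor-vs-normal differential
expression, a one-sample high-expression test across a cell-line panel,
top-N ranking, a median-split log-rank survival screen, hypergeometric
overrepresentation against GMT gene sets, and ward.D2 sample clustering.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import ExpressionMatrix, COUNTS, LOG2CPM
from .stats import (
    bh_adjust,
    hypergeom_upper_tail,
    logrank_two_group,
    pearson_distance,
    ward_d2_cluster,
)

logger = logging.getLogger(__name__)

PRIOR_COUNT = 0.5  # added to CPM before log2 to avoid -inf


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def cpm(counts: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million; each sample column sums to 1e6."""
    if counts.units != COUNTS:
        raise ValueError("cpm expects raw counts")
    lib = counts.values.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    return counts.values.div(lib, axis=1) * 1e6


def filter_low_expression(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Drop unexpressed genes, then genes below 1 CPM in >50% of samples.

    Gene order is preserved. Genes at exactly 50% low samples are kept
    (the cut is strictly "more than half").
    """
    if counts.units != COUNTS:
        raise ValueError("filter expects raw counts")
    nonzero = counts.values.sum(axis=1) > 0
    kept = counts.values.loc[nonzero]
    c = cpm(ExpressionMatrix(kept, counts.sample_groups, units=COUNTS))
    n = c.shape[1]
    low_frac = (c < 1.0).sum(axis=1) / n
    keep = low_frac <= 0.5
    if not keep.any():
        logger.warning("all genes removed by the low-expression filter")
    return ExpressionMatrix(kept.loc[keep].copy(), dict(counts.sample_groups), units=COUNTS)


def _pair_trend(a: np.ndarray, m: np.ndarray, span: float, max_exact: int = 500) -> np.ndarray:
    """Loess fit of M on A, evaluated at every gene.

    Above ``max_exact`` genes the trend is fitted on ~200 quantile-bin
    means and linearly interpolated; the MA trend is smooth at that scale
    so the approximation error is negligible next to count noise.
    """
    if a.size <= max_exact:
        return lowess(m, a, frac=span, it=1, delta=0.0, return_sorted=False)
    n_bins = 200
    order = np.argsort(a, kind="stable")
    a_s, m_s = a[order], m[order]
    edges = np.linspace(0, a.size, n_bins + 1).astype(int)
    widths = np.diff(edges)
    a_b = np.add.reduceat(a_s, edges[:-1]) / widths
    m_b = np.add.reduceat(m_s, edges[:-1]) / widths
    fit_sorted = lowess(
        m_b, a_b, frac=span, it=0, delta=0.01 * np.ptp(a_b), return_sorted=True
    )
    return np.interp(a, fit_sorted[:, 0], fit_sorted[:, 1])


def normalize_log2cpm_cyclicloess(
    counts: ExpressionMatrix,
    span: float = 0.7,
    iterations: int = 3,
) -> ExpressionMatrix:
    """log2-CPM with pairwise cyclic loess normalization.

    For every sample pair the loess trend of M = x_i - x_j against
    A = (x_i + x_j)/2 is removed symmetrically (half from each sample),
    cycling over all pairs ``iterations`` times. Removes intensity-
    dependent between-sample trends that scaling alone cannot.
    """
    if counts.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    x = np.log2(cpm(counts).to_numpy() + PRIOR_COUNT)
    n = x.shape[1]
    for _ in range(iterations):
        for i in range(n - 1):
            for j in range(i + 1, n):
                a = 0.5 * (x[:, i] + x[:, j])
                m = x[:, i] - x[:, j]
                fit = _pair_trend(a, m, span)
                x[:, i] -= fit / 2.0
                x[:, j] += fit / 2.0
    values = pd.DataFrame(x, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(values, dict(counts.sample_groups), units=LOG2CPM)


# ---------------------------------------------------------------------------
# differential expression (tumor vs normal)
# ---------------------------------------------------------------------------

def differential_expression(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    lfc_cut: float = 0.3,
    alpha: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group one-way ANOVA on log-scale expression.

    The two-group ANOVA F equals the square of the pooled-variance t, so
    the reported p is the two-sided t probability. Retains genes with
    |log2FC| > ``lfc_cut`` and p < ``alpha`` unless ``return_all``.
    """
    if tumor.units != LOG2CPM or normal.units != LOG2CPM:
        raise ValueError("differential expression expects log2-CPM input")
    if not tumor.values.index.equals(normal.values.index):
        raise ValueError("gene sets differ between groups")
    if tumor.values.shape[1] < 2 or normal.values.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")

    xt = tumor.values.to_numpy()
    xn = normal.values.to_numpy()
    t_stat, p = sps.ttest_ind(xt, xn, axis=1, equal_var=True)
    log2fc = xt.mean(axis=1) - xn.mean(axis=1)
    out = pd.DataFrame(
        {
            "gene": tumor.values.index,
            "log2fc": log2fc,
            "t": t_stat,
            "F": t_stat**2,
            "p": p,
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    ).set_index("gene")
    out["significant"] = (out["p"] < alpha) & (out["log2fc"].abs() > lfc_cut)
    if return_all:
        return out
    return out[out["significant"]].drop(columns="significant")


# ---------------------------------------------------------------------------
# high expression across the cell-line panel
# ---------------------------------------------------------------------------

def high_expression_test(cellline_log2cpm: ExpressionMatrix, per_model_mean: bool = True) -> pd.DataFrame:
    """One-sample one-sided test that mean log-expression exceeds zero.

    With ``per_model_mean`` the replicates of each cell model are averaged
    first so the test units are independent models. Zero-variance genes
    get p forced to 0 (mean > 0) or 1, flagged ``degenerate``. Output is
    sorted by BH q ascending, ties by mean descending then gene id.
    """
    if cellline_log2cpm.units != LOG2CPM:
        raise ValueError("high_expression_test expects log2-CPM input")
    df = cellline_log2cpm.values
    if per_model_mean:
        groups = cellline_log2cpm.groups()
        df = df.T.groupby(groups).mean().T
    x = df.to_numpy()
    n = x.shape[1]
    if n < 2:
        raise ValueError("need >= 2 cell models")
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = sps.t.sf(t, df=n - 1)
    p = np.where(degenerate, np.where(mean > 0, 0.0, 1.0), p)
    t = np.where(degenerate, np.where(mean > 0, np.inf, -np.inf), t)
    out = pd.DataFrame(
        {
            "gene": df.index,
            "mean_log2cpm": mean,
            "t_stat": t,
            "p_one_sided": p,
            "q_fdr": bh_adjust(p),
            "degenerate": degenerate,
        }
    ).set_index("gene")
    out = out.sort_values(
        ["q_fdr", "mean_log2cpm", "gene"], ascending=[True, False, True]
    )
    return out


def rank_candidates(
    deg: pd.DataFrame,
    heg: pd.DataFrame,
    top_n: int = 200,
    by: str = "p",
) -> list[str]:
    """Intersect up-regulated DEGs with the high-expression table and rank.

    ``by="p"`` orders by -log10 of the high-expression p descending
    (default); ``by="expression"`` orders by mean log2-CPM. Ties break by
    descending mean then gene id. Returns at most ``top_n`` genes.
    """
    if by not in ("p", "expression"):
        raise ValueError("by must be 'p' or 'expression'")
    up = deg.index[deg["direction"] == "up"]
    eligible = heg.loc[heg.index.intersection(up)].sort_index(kind="stable")
    keys, asc = (
        (["p_one_sided", "mean_log2cpm"], [True, False])
        if by == "p"
        else (["mean_log2cpm", "p_one_sided"], [False, True])
    )
    eligible = eligible.sort_values(keys, ascending=asc, kind="stable")
    if len(eligible) < top_n:
        logger.info("only %d eligible genes for top-%d ranking", len(eligible), top_n)
    return eligible.index[:top_n].tolist()


# ---------------------------------------------------------------------------
# survival screen
# ---------------------------------------------------------------------------

def logrank_median_split(expression_row: pd.Series, survival: pd.DataFrame):
    """Median-split log-rank test for one gene.

    Patients at or below the median expression form the low arm; the
    Mantel-Cox statistic is chi-square with 1 df, and ``high_is_worse``
    reports whether the high arm saw more events than expected.
    """
    surv = survival.set_index("patient") if "patient" in survival.columns else survival
    common = expression_row.index.intersection(surv.index)
    if len(common) < 4:
        raise ValueError("need >= 2 patients per arm after the split")
    expr = expression_row.loc[common]
    surv = surv.loc[common]
    is_high = (expr > expr.median()).to_numpy()
    return logrank_two_group(
        surv["time_months"].to_numpy(), surv["event"].to_numpy(), is_high
    )


def select_prognostic(
    top_genes: Sequence[str],
    expression: ExpressionMatrix,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Retain candidates whose high expression associates with worse survival.

    Per-gene median-split log-rank at unadjusted ``alpha``, gated on the
    direction flag (high expression must carry the excess events).
    """
    rows = []
    for g in top_genes:
        if g not in expression.values.index:
            continue
        res = logrank_median_split(expression.values.loc[g], survival)
        rows.append((g, res.statistic, res.p, res.high_is_worse))
    out = pd.DataFrame(rows, columns=["gene", "statistic", "p", "high_is_worse"]).set_index("gene")
    out["selected"] = (out["p"] < alpha) & out["high_is_worse"]
    return out


# ---------------------------------------------------------------------------
# overrepresentation and clustering
# ---------------------------------------------------------------------------

def ora_gene_sets(
    candidates: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of candidates in each gene set.

    Gene sets are restricted to the universe; sets with no member in the
    universe are skipped. BH adjustment across the tested sets.
    """
    uni = set(universe)
    cand = set(candidates)
    if not cand <= uni:
        raise ValueError("candidates must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & uni
        if not members:
            logger.info("gene set %s has no overlap with the universe; skipped", name)
            continue
        overlap = len(members & cand)
        p = hypergeom_upper_tail(overlap, len(uni), len(members), len(cand))
        rows.append((name, overlap, len(members), len(cand), len(uni), p))
    out = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "candidates", "universe", "p_hyper"],
    ).set_index("set_name")
    out["q_fdr"] = bh_adjust(out["p_hyper"].to_numpy()) if len(out) else []
    return out


def cluster_samples(log2cpm: ExpressionMatrix):
    """Ward.D2 clustering of samples on 1 - Pearson correlation.

    Returns (linkage matrix, leaf order as sample labels, merge heights).
    """
    if log2cpm.values.shape[1] < 3:
        raise ValueError("need >= 3 samples to cluster")
    dist = pearson_distance(log2cpm.values)
    z, leaves = ward_d2_cluster(dist)
    return z, leaves, z[:, 2].copy()


# ---------------------------------------------------------------------------
# end-to-end prioritization
# ---------------------------------------------------------------------------

def prioritize(
    counts: ExpressionMatrix,
    celllines: ExpressionMatrix,
    patient_expression: ExpressionMatrix,
    survival: pd.DataFrame,
    lfc_cut: float = 0.3,
    alpha: float = 0.05,
    top_n: int = 200,
    survival_alpha: float = 0.05,
    loess_span: float = 0.7,
    loess_iterations: int = 3,
) -> dict:
    """Full candidate-prioritization chain on raw inputs.

    filter -> normalize -> tumor/normal DE -> cell-line high-expression
    test -> top-N ranking -> median-split survival screen. Returns the
    intermediate tables and the selected candidate genes.
    """
    filtered = filter_low_expression(counts)
    norm = normalize_log2cpm_cyclicloess(filtered, span=loess_span, iterations=loess_iterations)
    tumor = norm.subset_group("tumor")
    normal = norm.subset_group("normal")
    deg = differential_expression(tumor, normal, lfc_cut=lfc_cut, alpha=alpha)

    cl_filtered = filter_low_expression(celllines)
    cl_norm = normalize_log2cpm_cyclicloess(
        cl_filtered, span=loess_span, iterations=loess_iterations
    )
    heg = high_expression_test(cl_norm)

    top = rank_candidates(deg, heg, top_n=top_n)
    prog = select_prognostic(top, patient_expression, survival, alpha=survival_alpha)
    selected = prog.index[prog["selected"]].tolist()
    return {
        "deg": deg,
        "heg": heg,
        "top_genes": top,
        "prognostic": prog,
        "selected": selected,
    }
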