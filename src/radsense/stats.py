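"""Shared statistical kernels.

Standard procedures (t-tests, BH-FDR, hierarchical agglomeration) delegate
to scipy/statsmodels; the Mantel-Cox log-rank statistic is computed here
explicitly because the screen needs the signed observed-minus-expected
direction of the high-expression arm, which canned implementations do not
expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LogRankResult:
    statistic: float
    p: float
    high_is_worse: bool
    o_high: float
    e_high: float
    n_low: int
    n_high: int
    degenerate: bool = False


def logrank_two_group(time, event, is_high) -> LogRankResult:
    """Mantel-Cox two-group log-rank test.

    At each distinct event time the observed number of events in the
    high group is compared with its hypergeometric expectation given the
    risk sets; the summed (O-E)^2/V is chi-square with 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    is_high = np.asarray(is_high, dtype=bool)
    if time.shape != event.shape or time.shape != is_high.shape:
        raise ValueError("time, event and group arrays must align")
    if is_high.sum() < 2 or (~is_high).sum() < 2:
        raise ValueError("need at least 2 subjects per arm")

    n_low = int((~is_high).sum())
    n_high = int(is_high.sum())
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return LogRankResult(0.0, 1.0, False, 0.0, 0.0, n_low, n_high, degenerate=True)

    o = e = v = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n_h = (at_risk & is_high).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d_h = (dying & is_high).sum()
        o += d_h
        e += d * n_h / n
        if n > 1:
            v += d * (n_h / n) * (1 - n_h / n) * (n - d) / (n - 1)
    if v <= 0:
        return LogRankResult(0.0, 1.0, o > e, float(o), float(e), n_low, n_high, degenerate=True)
    stat = (o - e) ** 2 / v
    p = float(sps.chi2.sf(stat, df=1))
    return LogRankResult(float(stat), p, bool(o > e), float(o), float(e), n_low, n_high)


def pearson_distance(data: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between the columns of ``data``."""
    if (data.std(axis=0, ddof=0) == 0).any():
        bad = data.columns[data.std(axis=0, ddof=0) == 0].tolist()
        raise ValueError(f"zero-variance columns, correlation undefined: {bad}")
    corr = data.corr(method="pearson")
    return 1.0 - corr


def ward_d2_cluster(distance: pd.DataFrame):
    """Ward.D2 agglomeration on a precomputed symmetric distance matrix.

    Returns (linkage matrix, leaf labels in dendrogram order). Labels are
    sorted before clustering so that exact ties merge deterministically.
    """
    order = np.argsort(distance.index.to_numpy())
    d = distance.iloc[order, order]
    labels = d.index.to_list()
    condensed = squareform(np.clip(d.to_numpy(), 0, None), checks=False)
    z = linkage(condensed, method="ward")
    leaf_labels = [labels[i] for i in leaves_list(z)]
    return z, leaf_labels


def welch_t_test(a, b) -> tuple[float, float]:
    """Two-sided Welch t-test; returns (t, p)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pooled_t_test(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance t-test (equivalent to one-way ANOVA F=t^2)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=True)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups) -> tuple[float, float]:
    res = sps.f_oneway(*[np.asarray(g, float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def hypergeom_upper_tail(overlap: int, universe: int, set_size: int, draws: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, draws)."""
    return float(sps.hypergeom.sf(overlap - 1, universe, set_size, draws))
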