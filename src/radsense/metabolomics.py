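"""Untargeted/targeted metabolomics differential-abundance analytics.

From LC-MS feature tables: tolerance-based library annotation (ppm mass
error, retention time, collision cross section), control-relative
differential abundance on log-transformed intensities, class counts,
pathway impact percentages, cross-model overlaps of significant
metabolites, change-correlation clustering, and a NIPALS PLS-DA for
group separation. Targeted peak-area tables run through the same
differential operations; only the input provenance differs.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import PLSDAResult
from .stats import bh_adjust, ward_d2_cluster

logger = logging.getLogger(__name__)

FEATURE_META = ["feature_id", "mz", "rt_min", "ccs", "polarity"]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def match_features(
    features: pd.DataFrame,
    library: pd.DataFrame,
    ppm_tol: float = 10.0,
    rt_tol_min: float = 0.3,
    ccs_tol_frac: float = 0.03,
) -> pd.DataFrame:
    """Annotate features against a reference metabolite library.

    A feature matches an entry iff the ppm mass error is <= ``ppm_tol``
    AND (no reference RT, or |dRT| <= ``rt_tol_min``) AND (no reference
    CCS, or the relative CCS deviation is <= ``ccs_tol_frac``); the best
    match minimizes (ppm, dRT, dCCS) lexicographically, then library
    name, making the result independent of library row order. Unmatched
    features are excluded.
    """
    if len(library) == 0:
        raise ValueError("empty reference library")
    lib = library.reset_index(drop=True)
    ref_mz = lib["ref_mz"].to_numpy(float)
    ref_rt = lib["ref_rt"].to_numpy(float) if "ref_rt" in lib else np.full(len(lib), np.nan)
    ref_ccs = lib["ref_ccs"].to_numpy(float) if "ref_ccs" in lib else np.full(len(lib), np.nan)

    # relative guard so that deviations computed to sit exactly on the
    # tolerance are accepted despite float round-off
    eps = 1 + 1e-9
    out_rows = []
    for _, feat in features.iterrows():
        ppm = np.abs(feat["mz"] - ref_mz) / ref_mz * 1e6
        ok = ppm <= ppm_tol * eps
        drt = np.abs(feat.get("rt_min", np.nan) - ref_rt)
        with np.errstate(invalid="ignore"):
            ok &= np.isnan(ref_rt) | np.isnan(feat.get("rt_min", np.nan)) | (drt <= rt_tol_min * eps)
            dccs = np.abs(feat.get("ccs", np.nan) - ref_ccs) / ref_ccs
            ok &= np.isnan(ref_ccs) | np.isnan(feat.get("ccs", np.nan)) | (dccs <= ccs_tol_frac * eps)
        if not ok.any():
            continue
        cand = pd.DataFrame(
            {
                "ppm_dev": ppm[ok],
                "rt_dev": np.nan_to_num(drt[ok], nan=0.0),
                "ccs_dev": np.nan_to_num(dccs[ok], nan=0.0),
                "name": lib.loc[ok, "name"].to_numpy(),
            }
        ).sort_values(["ppm_dev", "rt_dev", "ccs_dev", "name"], kind="stable")
        best_name = cand.iloc[0]["name"]
        best = lib[lib["name"] == best_name].iloc[0]
        row = feat.to_dict()
        row.update(
            name=best["name"],
            **{"class": best.get("class", "")},
            pathways=best.get("pathways", ""),
            ppm_dev=float(cand.iloc[0]["ppm_dev"]),
            rt_dev=float(cand.iloc[0]["rt_dev"]),
            ccs_dev=float(cand.iloc[0]["ccs_dev"]),
        )
        out_rows.append(row)
    if not out_rows:
        return pd.DataFrame(columns=list(features.columns) + ["name", "class", "pathways", "ppm_dev", "rt_dev", "ccs_dev"])
    return pd.DataFrame(out_rows).reset_index(drop=True)


def annotated_intensity_table(annotated: pd.DataFrame) -> pd.DataFrame:
    """Metabolite x sample intensity matrix from an annotated feature table.

    Features mapping to the same metabolite are summed.
    """
    meta = [c for c in FEATURE_META + ["name", "class", "pathways", "ppm_dev", "rt_dev", "ccs_dev"] if c in annotated.columns]
    sample_cols = [c for c in annotated.columns if c not in meta]
    return annotated.groupby("name")[sample_cols].sum()


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def differential_abundance(
    intensities: pd.DataFrame,
    groups: Mapping[str, str],
    test_group: str,
    control_group: str,
    alpha: float = 0.05,
    transform: str = "log10",
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-metabolite fold change and t-test against the control group.

    ``intensities`` is metabolite x sample; the contrast (test and
    control group) is always explicit. Fold change is the ratio of raw
    group means; the two-sided t-test runs on transformed intensities
    (log10 by default, glog available) to meet the normality assumption.
    Metabolites with a non-positive control mean are flagged and excluded.
    """
    g = pd.Series({s: groups[s] for s in intensities.columns})
    test_cols = g.index[g == test_group]
    ctrl_cols = g.index[g == control_group]
    if len(test_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 replicates in test and control groups")

    def _tf(x):
        if transform == "log10":
            return np.log10(x)
        if transform == "glog":
            return np.log10((x + np.sqrt(x**2 + 1)) / 2)
        if transform is None or transform == "none":
            return x
        raise ValueError(f"unknown transform {transform!r}")

    rows = []
    for name, row in intensities.iterrows():
        tv = row[test_cols].to_numpy(float)
        cv = row[ctrl_cols].to_numpy(float)
        if cv.mean() <= 0:
            logger.warning("metabolite %s has non-positive control mean; excluded", name)
            continue
        fc = tv.mean() / cv.mean()
        if transform in ("log10",) and ((tv <= 0).any() or (cv <= 0).any()):
            logger.warning("metabolite %s has non-positive intensities; excluded", name)
            continue
        t, p = sps.ttest_ind(_tf(tv), _tf(cv), equal_var=True)
        rows.append((name, fc, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["name", "fold_change", "t", "p"]).set_index("name")
    pcol = "p"
    if adjust:
        out["q_fdr"] = bh_adjust(out["p"].to_numpy())
        pcol = "q_fdr"
    sig = out[pcol] < alpha
    out["direction"] = np.where(
        sig & (out["fold_change"] > 1), "up",
        np.where(sig & (out["fold_change"] < 1), "down", "unchanged"),
    )
    return out


def class_counts(diff: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Counts of significant up/down metabolites per chemical class."""
    ann = annotations.drop_duplicates("name").set_index("name")
    sig = diff[diff["direction"] != "unchanged"]
    if len(sig) == 0:
        return pd.DataFrame(columns=["up", "down"]).rename_axis("class")
    cls = ann.loc[sig.index.intersection(ann.index), "class"]
    tab = (
        pd.crosstab(cls, sig.loc[cls.index, "direction"])
        .reindex(columns=["up", "down"], fill_value=0)
        .rename_axis("class")
    )
    return tab


def _pathway_sets(annotations: pd.DataFrame) -> pd.Series:
    ann = annotations.drop_duplicates("name").set_index("name")
    return ann["pathways"].fillna("").map(
        lambda s: frozenset(p for p in str(s).split(";") if p)
    )


def pathway_impact(diff: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Percentage of measured pathway members significantly up / down.

    n_measured counts annotated metabolites in the differential table
    that belong to the pathway; pathways with no measured member are
    omitted.
    """
    sets = _pathway_sets(annotations)
    sets = sets.loc[sets.index.intersection(diff.index)]
    all_paths = sorted(set().union(*sets) if len(sets) else set())
    rows = []
    for pw in all_paths:
        members = sets.index[sets.map(lambda s: pw in s)]
        n = len(members)
        if n == 0:
            continue
        d = diff.loc[members, "direction"]
        up = int((d == "up").sum())
        down = int((d == "down").sum())
        rows.append((pw, n, 100.0 * up / n, 100.0 * down / n))
    return pd.DataFrame(
        rows, columns=["pathway", "n_measured", "pct_up", "pct_down"]
    ).set_index("pathway")


def overlap_significant(tables: Mapping[str, pd.DataFrame]) -> dict:
    """Shared / unique significant metabolites across >= 2 contrasts.

    Shared metabolites carry a concordance flag (same direction in every
    table).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 differential tables")
    sig = {
        k: t[t["direction"] != "unchanged"]["direction"] for k, t in tables.items()
    }
    keys = sorted(sig)
    shared = set.intersection(*(set(s.index) for s in sig.values()))
    concordant = {
        m: len({sig[k][m] for k in keys}) == 1 for m in shared
    }
    unique = {
        k: sorted(set(sig[k].index) - set().union(*(set(sig[j].index) for j in keys if j != k)))
        for k in keys
    }
    return {
        "shared": sorted(shared),
        "concordant": concordant,
        "unique": unique,
    }


# ---------------------------------------------------------------------------
# change correlation and clustering
# ---------------------------------------------------------------------------

def change_correlation(change_matrix: pd.DataFrame):
    """Pearson correlation between metabolite change vectors + clustering.

    ``change_matrix`` is metabolites x conditions of log2 fold changes.
    Zero-variance metabolites are excluded with a notice. Returns the
    correlation matrix (symmetric, unit diagonal) and the ward.D2
    dendrogram leaf order on 1 - r.
    """
    if change_matrix.shape[1] < 2:
        raise ValueError("need >= 2 conditions")
    sd = change_matrix.std(axis=1, ddof=0)
    if (sd == 0).any():
        dropped = change_matrix.index[sd == 0].tolist()
        logger.warning("excluding zero-variance change vectors: %s", dropped)
        change_matrix = change_matrix.loc[sd > 0]
    corr = change_matrix.T.corr(method="pearson")
    if len(corr) < 2:
        return corr, corr.index.tolist()
    dist = 1.0 - corr
    _, leaves = ward_d2_cluster(dist)
    return corr, leaves


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def plsda(
    intensities: pd.DataFrame,
    groups: Mapping[str, str],
    n_components: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSDAResult:
    """NIPALS PLS-DA on autoscaled log intensities.

    ``intensities`` is samples x variables. The response is the centered
    one-hot group matrix; each component's score vector is iterated from
    the first response column to convergence (deterministic). Returns
    scores, loadings, weights and the fraction of autoscaled X variance
    captured per component. Constant columns are dropped with a notice.
    """
    y_labels = pd.Series({s: groups[s] for s in intensities.index})
    if y_labels.nunique() < 2:
        raise ValueError("need >= 2 groups")
    if len(intensities) < n_components + 1:
        raise ValueError("need more samples than components")

    x = intensities.copy().astype(float)
    sd = x.std(axis=0, ddof=1)
    dropped = x.columns[sd == 0].tolist()
    if dropped:
        logger.warning("dropping %d constant columns", len(dropped))
        x = x.drop(columns=dropped)
        sd = sd.drop(dropped)
    xs = (x - x.mean(axis=0)) / sd
    xmat = xs.to_numpy()
    total_var = float((xmat**2).sum())

    dummies = pd.get_dummies(y_labels).astype(float)
    ymat = (dummies - dummies.mean(axis=0)).to_numpy()

    n, p = xmat.shape
    scores = np.empty((n, n_components))
    loadings = np.empty((p, n_components))
    weights = np.empty((p, n_components))
    explained = np.empty(n_components)

    xk, yk = xmat.copy(), ymat.copy()
    for k in range(n_components):
        u = yk[:, 0].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = xk.T @ u / (u @ u)
            w /= np.linalg.norm(w)
            t = xk @ w
            q = yk.T @ t / (t @ t)
            u = yk @ q / (q @ q)
            if np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
        pload = xk.T @ t / (t @ t)
        xk = xk - np.outer(t, pload)
        b = (t @ u) / (t @ t)
        yk = yk - b * np.outer(t, q)
        scores[:, k] = t
        loadings[:, k] = pload
        weights[:, k] = w
        explained[k] = float((np.outer(t, pload) ** 2).sum()) / total_var

    comp = [f"PC{i + 1}" for i in range(n_components)]
    return PLSDAResult(
        scores=pd.DataFrame(scores, index=intensities.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=xs.columns, columns=comp),
        weights=pd.DataFrame(weights, index=xs.columns, columns=comp),
        explained_x_variance=explained,
        group_labels=y_labels,
        dropped_columns=dropped,
    )
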