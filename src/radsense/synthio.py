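"""Synthetic dataset generators with planted ground truth.

Every pipeline input (count matrices, survival tables, screen endpoint
tables, clonogenic counts, LC-MS feature tables, per-cell lipid
peroxidation intensities) can be generated here with known planted
structure, emitted together with a :class:`~radsense.datatypes.TruthSheet`
recording exactly which entities carry effects. All generators are pure
functions of their arguments and a single integer seed: the same call
yields byte-identical tables.

Model choices (documented in docs/methods.md):

* counts: negative binomial with dispersion 0.1 around lognormal gene
  baselines, per-sample library sizes uniform in a stated range;
* survival: exponential event times; a latent binary risk factor drives
  both the elevated expression of planted prognostic genes and the hazard
  multiplier, so that per-gene median splits concord with the risk group;
* screen / metabolome / lipid ratios: lognormal replicate noise with a
  stated coefficient of variation around control-relative means.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, LQModel, TruthSheet, LOG2CPM

CONTROL_GENE = "siC"
ARMS = ("basal", "TMZ", "IR", "TMZ+IR")
ENDPOINTS = ("viability", "residual_DSB", "autophagy", "apoptosis")

# control-arm response of each endpoint relative to basal conditions
# (viability drops under treatment; damage/stress endpoints rise)
DEFAULT_ARM_RESPONSE: dict[tuple[str, str], float] = {}
for _arm, _mult in (("basal", 1.0), ("TMZ", 0.75), ("IR", 0.6), ("TMZ+IR", 0.45)):
    DEFAULT_ARM_RESPONSE[(_arm, "viability")] = _mult
for _arm, _mult in (("basal", 1.0), ("TMZ", 1.6), ("IR", 2.2), ("TMZ+IR", 2.8)):
    DEFAULT_ARM_RESPONSE[(_arm, "residual_DSB")] = _mult
for _arm, _mult in (("basal", 1.0), ("TMZ", 1.3), ("IR", 1.5), ("TMZ+IR", 1.8)):
    DEFAULT_ARM_RESPONSE[(_arm, "autophagy")] = _mult
for _arm, _mult in (("basal", 1.0), ("TMZ", 1.4), ("IR", 1.6), ("TMZ+IR", 2.0)):
    DEFAULT_ARM_RESPONSE[(_arm, "apoptosis")] = _mult

METABOLITE_CLASSES = (
    "Lipids and lipid-like molecules",
    "Carboxylic acids and derivatives",
    "Nucleosides and analogues",
    "Organooxygen compounds",
    "Organonitrogen compounds",
)
METABOLIC_PATHWAYS = (
    "Carnitine synthesis",
    "Cysteine and methionine metabolism",
    "Arginine and proline metabolism",
    "Spermidine and spermine biosynthesis",
    "Glutathione metabolism",
    "Glycolysis",
    "Purine metabolism",
)
NAMED_METABOLITES = (
    "S-Adenosylmethionine",
    "S-Adenosylhomocysteine",
    "L-Carnitine",
    "L-Acetylcarnitine",
    "5'-Methylthioadenosine",
    "gamma-Glutamylcysteine",
    "L-Cystathionine",
    "L-Cysteine",
    "L-Methionine",
    "Serine",
    "Spermidine",
    "Putrescine",
)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream: one shared seed, spawn keys per table."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _lognormal_around_mean(rng, mean, cv, size):
    """Lognormal draws whose arithmetic mean equals ``mean``."""
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.asarray(mean) * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def _nb_counts(rng, mean, dispersion):
    mean = np.clip(mean, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


# ---------------------------------------------------------------------------
# bulk counts, tumor vs normal
# ---------------------------------------------------------------------------

def gen_counts(
    n_genes: int,
    n_tumor: int,
    n_normal: int,
    deg_fraction: float = 0.05,
    lfc_sd: float = 1.0,
    libsize_range: tuple[int, int] = (800_000, 1_200_000),
    seed: int = 0,
    dispersion: float = 0.1,
    planted_lfc: Mapping[str, float] | None = None,
) -> tuple[ExpressionMatrix, TruthSheet]:
    """Tumor/normal count matrix with a planted fraction of DE genes.

    ``deg_fraction`` of genes receive a log2 fold change drawn from
    N(0, lfc_sd) applied to the tumor group; ``planted_lfc`` overrides the
    random planting with explicit gene -> log2FC assignments.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_tumor <= 0 or n_normal <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= deg_fraction <= 1):
        raise ValueError("deg_fraction must lie in [0, 1]")

    genes = [f"G{i:05d}" for i in range(n_genes)]
    rng = _rng(seed, 1)
    base_log2 = rng.normal(3.0, 1.5, n_genes)        # relative abundance scale
    rel = np.power(2.0, base_log2)
    rel /= rel.sum()

    if planted_lfc is not None:
        unknown = set(planted_lfc) - set(genes)
        if unknown:
            raise ValueError(f"planted genes not in matrix: {sorted(unknown)[:5]}")
        lfc = pd.Series(0.0, index=genes)
        for g, v in planted_lfc.items():
            lfc[g] = v
        planted = [(g, float(v)) for g, v in planted_lfc.items()]
    else:
        n_deg = round(deg_fraction * n_genes)
        idx = rng.choice(n_genes, size=n_deg, replace=False)
        lfc = pd.Series(0.0, index=genes)
        effects = rng.normal(0.0, lfc_sd, n_deg)
        lfc.iloc[idx] = effects
        planted = [(genes[i], float(e)) for i, e in zip(idx, effects)]

    tumor_rel = rel * np.power(2.0, lfc.to_numpy())
    samples = [f"tumor_{i + 1:02d}" for i in range(n_tumor)] + [
        f"normal_{i + 1:02d}" for i in range(n_normal)
    ]
    libsizes = rng.integers(libsize_range[0], libsize_range[1] + 1, size=len(samples))
    cols = {}
    for j, s in enumerate(samples):
        group_rel = tumor_rel if s.startswith("tumor") else rel
        mu = libsizes[j] * group_rel / group_rel.sum()
        cols[s] = _nb_counts(rng, mu, dispersion)
    values = pd.DataFrame(cols, index=genes)
    groups = {s: ("tumor" if s.startswith("tumor") else "normal") for s in samples}
    truth = TruthSheet(seed=seed, planted_deg_genes=sorted(planted))
    return ExpressionMatrix(values, groups, units="counts"), truth


def gen_cellline_counts(
    gene_ids: Sequence[str],
    n_models: int = 8,
    n_reps: int = 3,
    heg_genes: Sequence[str] = (),
    heg_boost_log2: float = 3.0,
    libsize_range: tuple[int, int] = (800_000, 1_200_000),
    seed: int = 0,
    dispersion: float = 0.1,
    model_sd_log2: float = 0.3,
) -> tuple[ExpressionMatrix, TruthSheet]:
    """Cell-line panel counts with planted highly expressed genes.

    ``heg_genes`` receive a ``heg_boost_log2`` baseline elevation in every
    model, placing them at the top of the one-sample high-expression test.
    """
    genes = list(gene_ids)
    unknown = set(heg_genes) - set(genes)
    if unknown:
        raise ValueError(f"heg genes not in gene_ids: {sorted(unknown)[:5]}")
    rng = _rng(seed, 2)
    base_log2 = rng.normal(3.0, 1.5, len(genes))
    boost = pd.Series(0.0, index=genes)
    boost[list(heg_genes)] = heg_boost_log2
    base_log2 = base_log2 + boost.to_numpy()

    cols = {}
    groups = {}
    for m in range(n_models):
        model = f"GBM{m + 1:02d}"
        model_shift = rng.normal(0.0, model_sd_log2, len(genes))
        rel = np.power(2.0, base_log2 + model_shift)
        rel /= rel.sum()
        for r in range(n_reps):
            s = f"{model}_r{r + 1}"
            lib = rng.integers(libsize_range[0], libsize_range[1] + 1)
            cols[s] = _nb_counts(rng, lib * rel, dispersion)
            groups[s] = model
    values = pd.DataFrame(cols, index=genes)
    truth = TruthSheet(seed=seed, planted_heg_genes=sorted(heg_genes))
    return ExpressionMatrix(values, groups, units="counts"), truth


# ---------------------------------------------------------------------------
# patient expression + survival
# ---------------------------------------------------------------------------

def gen_patient_expression(
    n_patients: int,
    gene_ids: Sequence[str],
    prognostic_genes: Sequence[str] = (),
    effect_log2: float = 1.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Patient-level log2 expression with a latent binary risk factor.

    Planted prognostic genes are elevated by ``effect_log2`` in risk-group
    patients; their per-gene median splits therefore concord with the
    latent group that drives survival in :func:`gen_survival`.
    """
    genes = list(gene_ids)
    unknown = set(prognostic_genes) - set(genes)
    if unknown:
        raise ValueError(f"prognostic genes not in gene_ids: {sorted(unknown)[:5]}")
    rng = _rng(seed, 3)
    patients = [f"P{i + 1:04d}" for i in range(n_patients)]
    risk = np.zeros(n_patients, dtype=int)
    risk[rng.permutation(n_patients)[: n_patients // 2]] = 1
    base = rng.normal(5.0, 2.0, len(genes))
    values = base[:, None] + rng.normal(0.0, noise_sd, (len(genes), n_patients))
    mask = pd.Index(genes).isin(prognostic_genes)
    values[np.ix_(mask, risk == 1)] += effect_log2
    df = pd.DataFrame(values, index=genes, columns=patients)
    em = ExpressionMatrix(df, {p: "patient" for p in patients}, units=LOG2CPM)
    return em, risk


def gen_survival(
    n_patients: int | None = None,
    expression: ExpressionMatrix | None = None,
    prognostic_genes: Sequence[str] = (),
    hazard_ratio: float = 2.0,
    censor_rate: float = 0.3,
    seed: int = 0,
    base_median_months: float = 14.0,
    risk: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TruthSheet]:
    """Overall-survival table with exponential event times.

    Patients in the high-risk group carry ``hazard_ratio`` times the
    baseline hazard. The risk indicator is either supplied directly, or
    derived from ``expression`` as an above-median mean z-score over the
    planted prognostic genes; with no prognostic genes all patients share
    the baseline hazard.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")
    if expression is not None:
        patients = list(expression.sample_ids)
    else:
        if n_patients is None:
            raise ValueError("need n_patients or an expression matrix")
        patients = [f"P{i + 1:04d}" for i in range(n_patients)]
    n = len(patients)

    if risk is None:
        if expression is not None and len(prognostic_genes) > 0:
            sub = expression.values.loc[list(prognostic_genes)]
            z = (sub.sub(sub.mean(axis=1), axis=0)).div(sub.std(axis=1).replace(0, 1), axis=0)
            score = z.mean(axis=0).to_numpy()
            risk = (score > np.median(score)).astype(int)
        else:
            risk = np.zeros(n, dtype=int)

    rng = _rng(seed, 4)
    lam0 = math.log(2.0) / base_median_months
    lam = lam0 * np.power(hazard_ratio, risk)
    times = rng.exponential(1.0 / lam)
    censored = rng.random(n) < censor_rate
    times = np.where(censored, times * rng.random(n), times)
    times = np.maximum(times, 1e-6)
    table = pd.DataFrame(
        {
            "patient": patients,
            "time_months": times,
            "event": (~censored).astype(int),
        }
    )
    truth = TruthSheet(
        seed=seed,
        planted_prognostic_genes=sorted((g, float(hazard_ratio)) for g in prognostic_genes),
        extras={"risk_group": [int(r) for r in risk]},
    )
    return table, truth


# ---------------------------------------------------------------------------
# RNAi screen
# ---------------------------------------------------------------------------

def gen_screen(
    genes: Sequence[str],
    arms: Sequence[str] = ARMS,
    endpoints: Sequence[str] = ENDPOINTS,
    sensitizer_effects: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
    cv: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    cell_models: Sequence[str] = ("DD-T4",),
    arm_response: Mapping[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, TruthSheet]:
    """Long-format replicate endpoint table for an RNAi screen.

    ``sensitizer_effects`` maps gene -> {(arm, endpoint): multiplier}
    applied on top of the control-arm response; the non-targeting control
    ``siC`` is present in every arm x endpoint x model.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (variance needed downstream)")
    unknown_arms = set(arms) - set(ARMS)
    if unknown_arms:
        raise ValueError(f"unknown arms: {sorted(unknown_arms)}")
    unknown_eps = set(endpoints) - set(ENDPOINTS)
    if unknown_eps:
        raise ValueError(f"unknown endpoints: {sorted(unknown_eps)}")
    effects = {g: dict(m) for g, m in (sensitizer_effects or {}).items()}
    response = dict(DEFAULT_ARM_RESPONSE)
    if arm_response:
        response.update(arm_response)

    rng = _rng(seed, 5)
    all_genes = [CONTROL_GENE] + [g for g in genes if g != CONTROL_GENE]
    rows = []
    for model in cell_models:
        for gene in all_genes:
            for arm in arms:
                for ep in endpoints:
                    mean = response[(arm, ep)]
                    mean *= effects.get(gene, {}).get((arm, ep), 1.0)
                    vals = _lognormal_around_mean(rng, mean, cv, n_reps)
                    for r, v in enumerate(vals, start=1):
                        rows.append((model, gene, arm, ep, r, float(v)))
    table = pd.DataFrame(
        rows, columns=["cell_model", "gene", "arm", "endpoint", "replicate", "value"]
    )
    truth = TruthSheet(
        seed=seed,
        planted_sensitizers=sorted(
            (g, {f"{a}|{e}": float(v) for (a, e), v in m.items()})
            for g, m in effects.items()
        ),
    )
    return table, truth


# ---------------------------------------------------------------------------
# clonogenic assay
# ---------------------------------------------------------------------------

def gen_clonogenic(
    model: LQModel,
    doses: Sequence[float],
    cells_seeded: Sequence[int],
    n_reps: int = 3,
    seed: int = 0,
    condition: str = "control",
) -> pd.DataFrame:
    """Poisson colony counts under linear-quadratic survival.

    Expected colonies at dose d are ``seeded * pe0 * exp(-alpha*d - beta*d^2)``.
    """
    doses = list(doses)
    cells_seeded = list(cells_seeded)
    if len(cells_seeded) == 1:
        cells_seeded = cells_seeded * len(doses)
    if len(cells_seeded) != len(doses):
        raise ValueError("cells_seeded must match doses (or be a single value)")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be non-negative")
    rng = _rng(seed, 6)
    rows = []
    for d, seeded in zip(doses, cells_seeded):
        sf = model.surviving_fraction(float(d))
        mu = seeded * model.pe0 * sf
        for r in range(1, n_reps + 1):
            colonies = int(min(rng.poisson(mu), seeded))
            rows.append((condition, float(d), int(seeded), colonies, r))
    return pd.DataFrame(
        rows, columns=["condition", "dose_gy", "cells_seeded", "colonies", "replicate"]
    )


# ---------------------------------------------------------------------------
# untargeted metabolome
# ---------------------------------------------------------------------------

def gen_metabolome(
    n_features: int = 120,
    groups: Sequence[str] = ("siC_0Gy", "siC_IR", "siEXT2_0Gy", "siEXT2_IR"),
    library_size: int = 150,
    planted: Mapping[str, float | Mapping[str, float]] | None = None,
    match_noise: Mapping[str, float] | None = None,
    seed: int = 0,
    n_reps: int = 4,
    cv: float = 0.2,
    match_fraction: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSheet]:
    """LC-MS feature table + reference library with planted group effects.

    A ``match_fraction`` subset of features are true library matches whose
    m/z, RT and CCS are perturbed *within* the matcher tolerances; the rest
    are decoys perturbed well beyond them. ``planted`` maps metabolite name
    -> fold change (float: applied to every non-control group; dict: per
    group); the first entry of ``groups`` is the control.
    """
    planted = dict(planted or {})
    tol = {"ppm": 10.0, "rt_min": 0.3, "ccs_frac": 0.03}
    tol.update(match_noise or {})
    n_true = round(match_fraction * n_features)
    if library_size < max(n_true, len(planted)):
        raise ValueError("library_size smaller than the number of planted matches")

    rng = _rng(seed, 7)
    names = list(NAMED_METABOLITES[: min(len(NAMED_METABOLITES), library_size)])
    names += [f"MET_{i:04d}" for i in range(len(names), library_size)]
    library = pd.DataFrame(
        {
            "name": names,
            "class": [METABOLITE_CLASSES[i % len(METABOLITE_CLASSES)] for i in range(library_size)],
            "pathways": [
                ";".join(
                    sorted(
                        rng.choice(
                            METABOLIC_PATHWAYS, size=rng.integers(1, 3), replace=False
                        )
                    )
                )
                for _ in range(library_size)
            ],
            "ref_mz": rng.uniform(80.0, 900.0, library_size),
            "ref_rt": rng.uniform(0.5, 8.0, library_size),
            "ref_ccs": rng.uniform(110.0, 310.0, library_size),
        }
    )

    # planted metabolites must be among the truly matched features
    planted_names = list(planted)
    unknown = set(planted_names) - set(names)
    if unknown:
        raise ValueError(f"planted metabolites absent from library: {sorted(unknown)}")
    other = [n for n in names if n not in planted]
    matched_names = planted_names + list(
        rng.choice(other, size=n_true - len(planted_names), replace=False)
    )

    lib_by_name = library.set_index("name")
    sample_cols = [f"{g}_r{r + 1}" for g in groups for r in range(n_reps)]
    control = groups[0]

    rows = []
    truth_matches = {}
    for i in range(n_features):
        fid = f"F{i + 1:05d}"
        is_true = i < n_true
        if is_true:
            name = matched_names[i]
            ref = lib_by_name.loc[name]
            mz = ref.ref_mz * (1 + rng.uniform(-0.6, 0.6) * tol["ppm"] * 1e-6)
            rt = ref.ref_rt + rng.uniform(-0.6, 0.6) * tol["rt_min"]
            ccs = ref.ref_ccs * (1 + rng.uniform(-0.6, 0.6) * tol["ccs_frac"])
            truth_matches[fid] = name
        else:
            ref = lib_by_name.iloc[int(rng.integers(0, library_size))]
            # push each identifier dimension far outside its tolerance
            mz = ref.ref_mz * (1 + rng.choice([-1, 1]) * rng.uniform(2.5, 5.0) * tol["ppm"] * 1e-6)
            rt = ref.ref_rt + rng.choice([-1, 1]) * rng.uniform(2.0, 4.0) * tol["rt_min"]
            ccs = ref.ref_ccs * (1 + rng.choice([-1, 1]) * rng.uniform(2.0, 4.0) * tol["ccs_frac"])
        base = 1e5 * 2 ** rng.normal(0.0, 1.5)
        row = {
            "feature_id": fid,
            "mz": float(mz),
            "rt_min": float(rt),
            "ccs": float(ccs),
            "polarity": "pos" if rng.random() < 0.5 else "neg",
        }
        fc_map = {}
        if is_true and name in planted:
            eff = planted[name]
            if isinstance(eff, Mapping):
                fc_map = dict(eff)
            else:
                fc_map = {g: float(eff) for g in groups if g != control}
        for g in groups:
            mean = base * fc_map.get(g, 1.0)
            vals = _lognormal_around_mean(rng, mean, cv, n_reps)
            for r in range(n_reps):
                row[f"{g}_r{r + 1}"] = float(vals[r])
        rows.append(row)

    features = pd.DataFrame(rows, columns=["feature_id", "mz", "rt_min", "ccs", "polarity"] + sample_cols)
    truth = TruthSheet(
        seed=seed,
        planted_metabolites=sorted(
            (n, float(v) if not isinstance(v, Mapping) else float(np.mean(list(v.values()))))
            for n, v in planted.items()
        ),
        extras={
            "true_matches": truth_matches,
            "decoys": [f"F{i + 1:05d}" for i in range(n_true, n_features)],
            "groups": {c: c.rsplit("_r", 1)[0] for c in sample_cols},
            "control_group": control,
        },
    )
    return features, library, truth


# ---------------------------------------------------------------------------
# lipid peroxidation
# ---------------------------------------------------------------------------

def gen_lipid_ratios(
    n_cells: int = 50,
    mean_ratio: float = 1.0,
    cv: float = 0.2,
    seed: int = 0,
    condition: str = "control",
) -> pd.DataFrame:
    """Per-cell oxidized (510 nm) / non-oxidized (590 nm) channel pairs.

    The per-cell ratio is lognormal with geometric mean ``mean_ratio``;
    channel intensities are strictly positive.
    """
    if mean_ratio <= 0:
        raise ValueError("mean_ratio must be positive")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = _rng(seed, 8)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    ratios = mean_ratio * np.exp(rng.normal(0.0, sigma, n_cells))
    i590 = 1000.0 * np.exp(rng.normal(0.0, 0.3, n_cells))
    return pd.DataFrame(
        {
            "condition": condition,
            "cell_index": np.arange(1, n_cells + 1),
            "i510": ratios * i590,
            "i590": i590,
        }
    )


# ---------------------------------------------------------------------------
# composite study for end-to-end candidate recovery
# ---------------------------------------------------------------------------

def gen_triple_positive_study(
    n_genes: int = 2000,
    n_planted: int = 100,
    n_tumor: int = 12,
    n_normal: int = 12,
    n_models: int = 8,
    n_reps_cellline: int = 3,
    n_patients: int = 150,
    lfc: float = 1.0,
    hazard_ratio: float = 2.5,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> dict:
    """Full candidate-prioritization study with triple-positive planted genes.

    The same ``n_planted`` genes are (i) tumor-overexpressed by ``lfc``
    log2 units, (ii) highly expressed across the cell-line panel, and
    (iii) prognostic with the stated hazard ratio; everything else is null.
    """
    rng = _rng(seed, 9)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    planted = sorted(rng.choice(genes, size=n_planted, replace=False))

    counts, _ = gen_counts(
        n_genes,
        n_tumor,
        n_normal,
        planted_lfc={g: lfc for g in planted},
        seed=seed,
    )
    celllines, _ = gen_cellline_counts(
        genes, n_models=n_models, n_reps=n_reps_cellline, heg_genes=planted, seed=seed
    )
    patient_expr, risk = gen_patient_expression(
        n_patients, genes, prognostic_genes=planted, seed=seed
    )
    survival, _ = gen_survival(
        expression=patient_expr,
        prognostic_genes=planted,
        hazard_ratio=hazard_ratio,
        censor_rate=censor_rate,
        seed=seed,
        risk=risk,
    )
    truth = TruthSheet(
        seed=seed,
        planted_deg_genes=[(g, float(lfc)) for g in planted],
        planted_heg_genes=list(planted),
        planted_prognostic_genes=[(g, float(hazard_ratio)) for g in planted],
        extras={"risk_group": [int(r) for r in risk]},
    )
    return {
        "counts": counts,
        "celllines": celllines,
        "patient_expression": patient_expr,
        "survival": survival,
        "truth": truth,
    }
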