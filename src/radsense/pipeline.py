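"""End-to-end orchestration of the target-nomination workflow.

A single YAML-configurable run chains the stages: simulate inputs ->
transcriptome candidate prioritization -> RNAi screen scoring ->
radiobiology statistics (SER, Bliss, clonogenic SF) -> metabolomics ->
lipid peroxidation -> machine-readable JSON report. All randomness flows
from one top-level seed; identical config + seed gives byte-identical
numeric outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io, lipidperox, metabolomics, radiobiology, screen, synthio, transcriptome
from .datatypes import LQModel

logger = logging.getLogger(__name__)


class PrioritizeParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = Field(600, ge=10)
    n_planted: int = Field(30, ge=0)
    n_tumor: int = Field(8, ge=2)
    n_normal: int = Field(8, ge=2)
    n_models: int = Field(5, ge=2)
    n_patients: int = Field(100, ge=8)
    lfc: float = 1.0
    hazard_ratio: float = Field(2.5, gt=0)
    censor_rate: float = Field(0.3, ge=0, lt=1)
    lfc_cut: float = Field(0.3, ge=0)
    alpha: float = Field(0.05, gt=0, le=1)
    top_n: int = Field(200, ge=1)


class ScreenParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = Field(12, ge=1)
    cv: float = Field(0.1, gt=0)
    n_reps: int = Field(3, ge=2)
    top_k: int = Field(3, ge=1)
    top_effect: float = Field(2.0, gt=0)


class RadiobiologyParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pe0: float = Field(0.1, gt=0, le=1)
    alpha_gy: float = Field(0.3, ge=0)
    beta_gy2: float = Field(0.03, ge=0)
    dose: float = Field(4.0, ge=0)
    cells_seeded: int = Field(1000, ge=1)
    n_boot: int = Field(2000, ge=100)


class MetabolomeParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_features: int = Field(120, ge=10)
    library_size: int = Field(150, ge=10)
    planted_fc: float = Field(2.0, gt=0)
    alpha: float = Field(0.05, gt=0, le=1)


class LipidParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cells: int = Field(50, ge=2)
    cv: float = Field(0.2, gt=0)
    effect_ratio: float = Field(1.6, gt=0)


class RunConfig(BaseModel):
    """Strictly validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "radsense_run"
    log_level: str = "INFO"
    prioritize: PrioritizeParams = PrioritizeParams()
    screen: ScreenParams = ScreenParams()
    radiobiology: RadiobiologyParams = RadiobiologyParams()
    metabolome: MetabolomeParams = MetabolomeParams()
    lipid: LipidParams = LipidParams()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on synthetic inputs and write tables + report.

    Returns the report dict (also written to ``out_dir/report.json``).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    report: dict = {"config": config.model_dump(), "tables": {}}

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        io.write_table(df, path, index=index)
        report["tables"][name.rsplit(".", 1)[0]] = str(path)

    # --- stage 1: prioritization on a planted triple-positive study -------
    pp = config.prioritize
    study = synthio.gen_triple_positive_study(
        n_genes=pp.n_genes,
        n_planted=pp.n_planted,
        n_tumor=pp.n_tumor,
        n_normal=pp.n_normal,
        n_models=pp.n_models,
        n_patients=pp.n_patients,
        lfc=pp.lfc,
        hazard_ratio=pp.hazard_ratio,
        censor_rate=pp.censor_rate,
        seed=seed,
    )
    res = transcriptome.prioritize(
        study["counts"],
        study["celllines"],
        study["patient_expression"],
        study["survival"],
        lfc_cut=pp.lfc_cut,
        alpha=pp.alpha,
        top_n=pp.top_n,
    )
    planted = {g for g, _ in study["truth"].planted_deg_genes}
    selected = set(res["selected"])
    recovery = len(selected & planted) / len(planted) if planted else float("nan")
    fdr = len(selected - planted) / max(len(selected), 1)
    save(res["deg"].reset_index(), "deg.csv")
    save(res["prognostic"].reset_index(), "prognostic.csv")
    study["truth"].to_json(out / "truth_prioritize.json")
    report["prioritize"] = {
        "n_selected": len(selected),
        "recovery": recovery,
        "false_discovery_rate": fdr,
        "selected": sorted(selected),
    }

    # --- stage 2: RNAi screen ---------------------------------------------
    sp = config.screen
    genes = [f"GENE{i + 1:02d}" for i in range(sp.n_genes)]
    top_gene = genes[0]
    effects = {
        top_gene: {
            ("IR", "viability"): 1.0 / sp.top_effect,
            ("TMZ+IR", "viability"): 1.0 / sp.top_effect,
            ("IR", "apoptosis"): sp.top_effect,
            ("TMZ+IR", "apoptosis"): sp.top_effect,
            ("IR", "residual_DSB"): sp.top_effect,
            ("TMZ+IR", "residual_DSB"): sp.top_effect,
        }
    }
    screen_table, screen_truth = synthio.gen_screen(
        genes,
        sensitizer_effects=effects,
        cv=sp.cv,
        n_reps=sp.n_reps,
        seed=seed,
        cell_models=("DD-T4", "U-251MG"),
    )
    stats = screen.score_conditions(screen.endpoint_statistics(screen_table))
    summary = screen.summary_score(stats)
    overlap = screen.top_k_overlap(screen.endpoint_rankings(stats), k=sp.top_k)
    save(screen_table, "screen_measurements.csv")
    save(stats, "screen_scores.csv")
    save(summary.reset_index(), "screen_summary.csv")
    report["screen"] = {
        "top_gene": summary.index[0],
        "top_summary_score": float(summary["total"].iloc[0]),
        "planted_top_gene": top_gene,
        "top3_overlap": overlap,
    }

    # --- stage 3: radiobiology --------------------------------------------
    rp = config.radiobiology
    lq = LQModel(pe0=rp.pe0, alpha=rp.alpha_gy, beta=rp.beta_gy2)
    clono = synthio.gen_clonogenic(
        lq, doses=[0.0, rp.dose], cells_seeded=[rp.cells_seeded], n_reps=3, seed=seed
    )
    sf = radiobiology.sf_from_records(clono, rp.dose)
    save(clono, "clonogenic.csv")

    via = screen_table[
        (screen_table["endpoint"] == "viability")
        & (screen_table["cell_model"] == "U-251MG")
    ]

    def arm_vals(gene, arm):
        m = via[(via["gene"] == gene) & (via["arm"] == arm)]
        return m["value"].to_numpy()

    control0 = arm_vals("siC", "basal").mean()
    f_a = radiobiology.fractional_effect(arm_vals(top_gene, "basal"), control0)
    f_b = radiobiology.fractional_effect(arm_vals("siC", "IR"), control0)
    f_ab = radiobiology.fractional_effect(arm_vals(top_gene, "IR"), control0)
    bliss = radiobiology.bliss_independence(f_a, f_b, f_ab, n_boot=rp.n_boot, seed=seed)
    ser_res = radiobiology.ser(
        arm_vals("siC", "IR"),
        arm_vals("siC", "basal"),
        arm_vals(top_gene, "IR"),
        arm_vals(top_gene, "basal"),
    )
    report["radiobiology"] = {
        "sf_estimated": sf,
        "sf_true": lq.surviving_fraction(rp.dose),
        "ser_top_gene": ser_res.ser,
        "bliss_excess": bliss.excess,
        "bliss_call": bliss.synergy_call,
    }

    # --- stage 4: metabolomics --------------------------------------------
    mp = config.metabolome
    kd_groups = ("siEXT2_0Gy", "siEXT2_IR")
    planted_mets = {
        "S-Adenosylmethionine": {g: mp.planted_fc for g in kd_groups},
        "L-Carnitine": {g: mp.planted_fc for g in kd_groups},
        "gamma-Glutamylcysteine": {g: 1.0 / mp.planted_fc for g in kd_groups},
    }
    features, library, met_truth = synthio.gen_metabolome(
        n_features=mp.n_features,
        library_size=mp.library_size,
        planted=planted_mets,
        seed=seed,
    )
    annotated = metabolomics.match_features(features, library)
    intens = metabolomics.annotated_intensity_table(annotated)
    groups = {c: c.rsplit("_r", 1)[0] for c in intens.columns}
    diff = metabolomics.differential_abundance(
        intens, groups, test_group="siEXT2_IR", control_group="siC_IR", alpha=mp.alpha
    )
    classes = metabolomics.class_counts(diff, annotated)
    impact = metabolomics.pathway_impact(diff, annotated)
    pls = metabolomics.plsda(np.log10(intens.T), groups)
    save(features, "metabolome_features.csv")
    save(library, "metabolome_library.csv")
    save(diff.reset_index(), "metabolome_differential.csv")
    save(impact.reset_index(), "metabolome_pathway_impact.csv")
    sig = diff[diff["direction"] != "unchanged"]
    recovered = set(sig.index) & set(planted_mets)
    report["metabolome"] = {
        "n_features": int(len(features)),
        "n_annotated": int(len(annotated)),
        "n_significant": int(len(sig)),
        "planted_recovered": sorted(recovered),
        "plsda_explained_x": [float(v) for v in pls.explained_x_variance],
        "class_counts": {str(k): [int(v["up"]), int(v["down"])] for k, v in classes.iterrows()},
    }

    # --- stage 5: lipid peroxidation --------------------------------------
    lp = config.lipid
    conds = {
        "siC_0Gy": 1.0,
        "siC_4Gy": lp.effect_ratio,
        "siEXT2_0Gy": lp.effect_ratio,
        "siEXT2_4Gy": lp.effect_ratio**2,
    }
    lipid = pd.concat(
        [
            synthio.gen_lipid_ratios(lp.n_cells, ratio, lp.cv, seed=seed + i, condition=c)
            for i, (c, ratio) in enumerate(conds.items())
        ],
        ignore_index=True,
    )
    lipid = lipidperox.ratio_table(lipid)
    lsummary = lipidperox.condition_summary(lipid, expected_n=lp.n_cells)
    comp = lipidperox.compare_conditions(lipid, posthoc="tukey")
    save(lipid, "lipid_ratios.csv")
    save(lsummary.reset_index(), "lipid_summary.csv")
    report["lipid"] = {
        "anova_p": comp.p_anova,
        "condition_means": {c: float(m) for c, m in lsummary["mean"].items()},
    }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    report["report_path"] = str(report_path)
    return report
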