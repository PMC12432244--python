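"""Clonogenic and viability endpoint statistics.

Plating efficiency, surviving fraction, basal-condition normalization,
the single-dose sensitizer enhancement ratio (SER) and Bliss-independence
synergy with a bootstrap confidence interval on the excess effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BlissResult, SERResult


@dataclass
class PlatingEfficiency:
    per_replicate: pd.Series
    mean: float
    sd: float
    not_countable: bool


def plating_efficiency(records: pd.DataFrame) -> PlatingEfficiency:
    """PE = colonies / cells seeded, per replicate plus mean +/- SD.

    If no replicate produced a single colony the result is PE = 0 flagged
    "not countable" (the assay convention for plates without colonies).
    """
    if (records["cells_seeded"] <= 0).any():
        raise ValueError("cells_seeded must be positive")
    if (records["colonies"] < 0).any():
        raise ValueError("colonies must be non-negative")
    pe = records["colonies"] / records["cells_seeded"]
    pe.index = records["replicate"] if "replicate" in records.columns else pe.index
    nc = bool((records["colonies"] == 0).all())
    sd = float(pe.std(ddof=1)) if len(pe) > 1 else float("nan")
    return PlatingEfficiency(pe, float(pe.mean()), sd, nc)


def surviving_fraction(pe_dose: float, pe_zero: float) -> float:
    """SF = PE(dose) / PE(0 Gy)."""
    if pe_zero <= 0:
        raise ValueError("plating efficiency at 0 Gy not countable (zero)")
    return pe_dose / pe_zero


def sf_from_records(records: pd.DataFrame, dose: float) -> float:
    """Surviving fraction at ``dose`` from a clonogenic record table."""
    pe0 = plating_efficiency(records[records["dose_gy"] == 0])
    ped = plating_efficiency(records[records["dose_gy"] == dose])
    if pe0.not_countable:
        raise ValueError("plating efficiency at 0 Gy not countable")
    return surviving_fraction(ped.mean, pe0.mean)


def normalize_to_basal(
    values: pd.DataFrame,
    reference_condition: str,
    condition_col: str = "condition",
    value_col: str = "value",
) -> pd.DataFrame:
    """Divide every value by the mean of the reference condition."""
    ref = values.loc[values[condition_col] == reference_condition, value_col]
    if len(ref) == 0:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ref_mean = ref.mean()
    if ref_mean == 0:
        raise ValueError("reference condition has zero mean")
    out = values.copy()
    out[value_col] = out[value_col] / ref_mean
    return out


def ser(
    control_treated,
    control_untreated,
    test_treated,
    test_untreated,
) -> SERResult:
    """Sensitizer enhancement ratio at a single dose.

    SER = [mean(control treated)/mean(control untreated)] /
          [mean(test treated)/mean(test untreated)]; values above 1 mean
    the test perturbation amplifies the treatment effect.
    """
    arms = {
        "control_treated": np.mean(control_treated),
        "control_untreated": np.mean(control_untreated),
        "test_treated": np.mean(test_treated),
        "test_untreated": np.mean(test_untreated),
    }
    for name, m in arms.items():
        if m <= 0:
            raise ValueError(f"arm {name!r} has non-positive mean {m}")
    reference_ratio = arms["control_treated"] / arms["control_untreated"]
    test_ratio = arms["test_treated"] / arms["test_untreated"]
    return SERResult(reference_ratio, test_ratio, reference_ratio / test_ratio)


def fractional_effect(treated, control_mean: float) -> np.ndarray:
    """Fractional inhibition f = 1 - treated/control, clamped to [0, 1].

    Negative effects (stimulation) clamp to 0 with a warning.
    """
    f = 1.0 - np.asarray(treated, float) / control_mean
    if (f < 0).any():
        warnings.warn("negative fractional effect clamped to 0 (stimulation)")
    return np.clip(f, 0.0, 1.0)


def bliss_independence(
    effect_a,
    effect_b,
    effect_ab,
    n_boot: int = 2000,
    seed: int = 0,
) -> BlissResult:
    """Bliss-independence synergy of two treatments.

    Under independence the expected combined fractional effect is
    f_A + f_B - f_A*f_B; the observed-minus-expected excess gets a seeded
    bootstrap percentile CI over replicates, and the call is synergistic
    if the CI lies above 0, antagonistic if below.
    """
    arms = []
    for name, e in (("effect_a", effect_a), ("effect_b", effect_b), ("effect_ab", effect_ab)):
        e = np.asarray(e, dtype=float)
        if e.size == 0:
            raise ValueError(f"missing arm {name!r}")
        if (e < 0).any():
            warnings.warn(f"negative fractional effects in {name} clamped to 0")
        arms.append(np.clip(e, 0.0, 1.0))
    fa, fb, fab = arms

    f_a, f_b, f_ab = fa.mean(), fb.mean(), fab.mean()
    f_expected = f_a + f_b - f_a * f_b
    obs_excess = f_ab - f_expected

    rng = np.random.default_rng(seed)
    ma = fa[rng.integers(0, fa.size, (n_boot, fa.size))].mean(axis=1)
    mb = fb[rng.integers(0, fb.size, (n_boot, fb.size))].mean(axis=1)
    mab = fab[rng.integers(0, fab.size, (n_boot, fab.size))].mean(axis=1)
    boots = mab - (ma + mb - ma * mb)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    eps = 1e-9  # guard against float round-off when the CI touches zero
    if ci_low > eps:
        call = "synergistic"
    elif ci_high < -eps:
        call = "antagonistic"
    else:
        call = "independent"
    return BlissResult(
        float(f_a), float(f_b), float(f_ab), float(f_expected),
        float(obs_excess), call, float(ci_low), float(ci_high),
    )
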