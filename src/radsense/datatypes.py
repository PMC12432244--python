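"""Core in-memory containers shared across the pipeline stages.

The containers are deliberately thin wrappers around pandas objects: every
analysis operation consumes and returns DataFrames so that intermediate
results stay inspectable, while the wrappers carry the metadata (units,
group labels, planted truth) that the bare tables cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

COUNTS = "counts"
LOG2CPM = "log2cpm"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample. Raw counts
        (non-negative integers) or normalized log2 counts-per-million,
        flagged by ``units``.
    sample_groups
        Mapping sample id -> group label (e.g. ``tumor`` / ``normal`` or a
        cell-model name).
    units
        ``"counts"`` or ``"log2cpm"``.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    units: str = COUNTS

    def __post_init__(self) -> None:
        if self.units not in (COUNTS, LOG2CPM):
            raise ValueError(f"unknown units {self.units!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.sample_groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite expression values")
        if self.units == COUNTS and (arr < 0).any():
            raise ValueError("negative counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def groups(self) -> pd.Series:
        """Group label per sample, aligned to the column order."""
        return pd.Series({s: self.sample_groups[s] for s in self.values.columns})

    def subset_group(self, group: str) -> "ExpressionMatrix":
        cols = [s for s in self.values.columns if self.sample_groups[s] == group]
        return ExpressionMatrix(
            self.values[cols].copy(),
            {s: group for s in cols},
            units=self.units,
        )


@dataclass
class TruthSheet:
    """Planted ground truth emitted alongside every synthetic dataset.

    All downstream recovery tests compare pipeline output against these
    fields; the seed fully determines the generated tables.
    """

    seed: int
    planted_deg_genes: list[tuple[str, float]] = field(default_factory=list)
    planted_heg_genes: list[str] = field(default_factory=list)
    planted_prognostic_genes: list[tuple[str, float]] = field(default_factory=list)
    planted_sensitizers: list[tuple[str, dict]] = field(default_factory=list)
    planted_metabolites: list[tuple[str, float]] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSheet":
        d = json.loads(Path(path).read_text())
        d["planted_deg_genes"] = [tuple(x) for x in d["planted_deg_genes"]]
        d["planted_prognostic_genes"] = [tuple(x) for x in d["planted_prognostic_genes"]]
        d["planted_sensitizers"] = [tuple(x) for x in d["planted_sensitizers"]]
        d["planted_metabolites"] = [tuple(x) for x in d["planted_metabolites"]]
        return cls(**d)


@dataclass(frozen=True)
class LQModel:
    """Linear-quadratic clonogenic survival model.

    SF(d) = exp(-alpha*d - beta*d^2); ``pe0`` is the plating efficiency of
    unirradiated cells (colonies per cell seeded at 0 Gy).
    """

    pe0: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0 < self.pe0 <= 1):
            raise ValueError("pe0 must lie in (0, 1]")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")

    def surviving_fraction(self, dose: float | np.ndarray) -> float | np.ndarray:
        d = np.asarray(dose, dtype=float)
        if (d < 0).any():
            raise ValueError("dose must be non-negative")
        sf = np.exp(-self.alpha * d - self.beta * d**2)
        return float(sf) if np.isscalar(dose) else sf


@dataclass
class SERResult:
    """Sensitizer enhancement ratio for a single-dose contrast.

    ``reference_ratio`` is treated/untreated survival in the control arm,
    ``test_ratio`` the same in the perturbed arm; SER > 1 means the
    perturbation amplifies the treatment effect.
    """

    reference_ratio: float
    test_ratio: float
    ser: float


@dataclass
class BlissResult:
    """Bliss-independence assessment of a two-treatment combination."""

    f_a: float
    f_b: float
    f_ab_observed: float
    f_expected: float
    excess: float
    synergy_call: str
    ci_low: float
    ci_high: float


@dataclass
class PLSDAResult:
    """Scores/loadings of a NIPALS partial least-squares discriminant fit."""

    scores: pd.DataFrame               # samples x components
    loadings: pd.DataFrame             # variables x components
    weights: pd.DataFrame              # variables x components
    explained_x_variance: np.ndarray   # fraction of autoscaled X variance
    group_labels: pd.Series
    dropped_columns: list[str]


def check_groups(groups: Mapping[str, str], samples) -> pd.Series:
    """Validate that every sample has a group label and return the mapping."""
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    return pd.Series({s: groups[s] for s in samples})
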