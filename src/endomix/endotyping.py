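"""Sputum inflammatory endotype classification.

COPD sputum samples are partitioned into four inflammatory subgroups from
differential cell counts using the established two-threshold rule:

* neutrophilic:       eosinophils < 3 %  and neutrophils >= 61 %
* eosinophilic:       eosinophils >= 3 % and neutrophils < 61 %
* mixed-granulocytic: eosinophils >= 3 % and neutrophils >= 61 %
* paucigranulocytic:  eosinophils < 3 %  and neutrophils < 61 %

A sample with a missing percentage is labelled ``unassigned`` — no
imputation is attempted. Percentages are compared as decimals without
rounding, with the boundary inclusive on the >= side exactly as printed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core_io import CohortDataset

__all__ = [
    "ENDOTYPE_LABELS",
    "EndotypeThresholds",
    "EndotypeClassifier",
    "classify_endotype",
    "classify_dataset",
]

ENDOTYPE_LABELS = (
    "neutrophilic",
    "eosinophilic",
    "mixed",
    "paucigranulocytic",
    "unassigned",
)


@dataclass(frozen=True)
class EndotypeThresholds:
    """Cell-percentage cutoffs; defaults are the established clinical rule."""

    eosinophil_cutoff: float = 3.0
    neutrophil_cutoff: float = 61.0

    def __post_init__(self) -> None:
        if self.eosinophil_cutoff <= 0 or self.neutrophil_cutoff <= 0:
            raise ValueError("endotype thresholds must be positive")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or pd.isna(x)


def classify_endotype(
    eosinophil_pct: float | None,
    neutrophil_pct: float | None,
    thresholds: EndotypeThresholds = EndotypeThresholds(),
) -> str:
    """Deterministic endotype label from the two-threshold rule."""
    if _is_missing(eosinophil_pct) or _is_missing(neutrophil_pct):
        return "unassigned"
    for name, val in (("eosinophil_pct", eosinophil_pct), ("neutrophil_pct", neutrophil_pct)):
        if not 0 <= val <= 100:
            raise ValueError(f"{name}={val} outside [0, 100]")
    eos_high = eosinophil_pct >= thresholds.eosinophil_cutoff
    neu_high = neutrophil_pct >= thresholds.neutrophil_cutoff
    if eos_high and neu_high:
        return "mixed"
    if eos_high:
        return "eosinophilic"
    if neu_high:
        return "neutrophilic"
    return "paucigranulocytic"


class EndotypeClassifier(BaseEstimator):
    """Threshold-rule endotype classifier with an sklearn predict surface.

    The rule has no free parameters to estimate, so ``fit`` only validates
    and records the thresholds; ``predict`` maps an (n, 2) array of
    [eosinophil %, neutrophil %] to labels, treating NaN as missing.
    """

    def __init__(self, eosinophil_cutoff: float = 3.0, neutrophil_cutoff: float = 61.0):
        self.eosinophil_cutoff = eosinophil_cutoff
        self.neutrophil_cutoff = neutrophil_cutoff

    def fit(self, X=None, y=None) -> "EndotypeClassifier":
        self.thresholds_ = EndotypeThresholds(self.eosinophil_cutoff, self.neutrophil_cutoff)
        self.classes_ = np.asarray(ENDOTYPE_LABELS)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): [eosinophil %, neutrophil %]")
        out = [
            classify_endotype(None if np.isnan(e) else e, None if np.isnan(n) else n, self.thresholds_)
            for e, n in X
        ]
        return np.asarray(out, dtype=object)


def classify_dataset(
    dataset: CohortDataset, thresholds: EndotypeThresholds = EndotypeThresholds()
) -> pd.Series:
    """Endotype label per sample of a cohort, aligned to the abundance table."""
    meta = dataset.aligned_metadata()
    eos = meta.get("eosinophil_pct", pd.Series(np.nan, index=meta.index))
    neu = meta.get("neutrophil_pct", pd.Series(np.nan, index=meta.index))
    clf = EndotypeClassifier(thresholds.eosinophil_cutoff, thresholds.neutrophil_cutoff).fit()
    labels = clf.predict(np.column_stack([eos.to_numpy(float), neu.to_numpy(float)]))
    return pd.Series(labels, index=meta.index, name="endotype")
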