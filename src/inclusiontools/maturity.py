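"""Ratiometric inclusion-maturity classification.

Inclusions of the TC9-Httex1 biosensor bind the biarsenical FlAsH dye only
while the aggregated protein is in a disordered conformation; amyloid
conversion abolishes binding. The FlAsH:Cerulean intensity ratio inside an
inclusion therefore reports its age: Highly Biarsenical-Reactive (HBR,
recently formed) inclusions have high ratios, Poorly Biarsenical-Reactive
(PBR, mature) inclusions low ratios.

Ratios are calibrated per experiment: an inclusion is HBR if its ratio lies
more than one standard error of the mean (SEM) above the population mean of
that experiment, PBR if more than one SEM below, and INTERMEDIATE inside the
±SEM band. Inequalities are strict, so a ratio exactly on a threshold (or a
population with SEM 0) is INTERMEDIATE. INTERMEDIATE inclusions are labelled
explicitly rather than silently dropped, so downstream summaries can report
all three counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class MaturityLabel(str, Enum):
    HBR = "HBR"
    PBR = "PBR"
    INTERMEDIATE = "INTERMEDIATE"


@dataclass(frozen=True)
class MaturityThresholds:
    """Population mean and SEM of FlAsH:Cerulean ratios for one experiment."""

    population_mean: float
    population_sem: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.population_sem < 0:
            raise ValueError("SEM must be >= 0")
        if self.n is not None and self.n < 2:
            raise ValueError("thresholds estimated from a sample need n >= 2")

    @property
    def lower(self) -> float:
        return self.population_mean - self.population_sem

    @property
    def upper(self) -> float:
        return self.population_mean + self.population_sem


def flash_cerulean_ratio(flash_mean: float, cerulean_mean: float) -> float:
    """FlAsH:Cerulean intensity ratio of one inclusion."""
    if cerulean_mean <= 0:
        raise ValueError("cerulean mean must be > 0 (unexpressed cell)")
    if flash_mean < 0:
        raise ValueError("flash mean must be >= 0")
    return flash_mean / cerulean_mean


def population_thresholds(ratios) -> MaturityThresholds:
    """Mean ± SEM thresholds from a sample of per-inclusion ratios.

    SEM is the sample standard deviation (n-1 denominator) over sqrt(n).
    """
    arr = np.asarray(list(ratios), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 ratios to estimate thresholds")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(n))
    return MaturityThresholds(mean, sem, n)


def classify(ratio: float, thresholds: MaturityThresholds) -> MaturityLabel:
    """HBR above mean+SEM, PBR below mean-SEM, INTERMEDIATE in the band."""
    if ratio > thresholds.upper:
        return MaturityLabel.HBR
    if ratio < thresholds.lower:
        return MaturityLabel.PBR
    return MaturityLabel.INTERMEDIATE


def classify_population(table: pd.DataFrame) -> pd.DataFrame:
    """Per-inclusion classification table.

    Input needs columns ``inclusion_id``, ``flash_mean``, ``cerulean_mean``.
    Returns those plus ``ratio``, ``population_mean``, ``population_sem`` and
    ``label`` — the per-inclusion CSV layout this stage exports.
    """
    required = {"inclusion_id", "flash_mean", "cerulean_mean"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = table.copy()
    out["ratio"] = [
        flash_cerulean_ratio(f, c)
        for f, c in zip(out["flash_mean"], out["cerulean_mean"])
    ]
    thr = population_thresholds(out["ratio"])
    out["population_mean"] = thr.population_mean
    out["population_sem"] = thr.population_sem
    out["label"] = [classify(r, thr).value for r in out["ratio"]]
    return out
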