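"""Pulse-shape gating, log-binned inclusion-fraction surfaces, stall ratios.

Flow cytometry of Httex1-transfected cells yields pulse area, height and
width per channel. Cells whose fluorescence is concentrated into an inclusion
produce narrower, taller pulses at a given pulse area than cells with diffuse
protein — the basis of Pulse Shape Analysis (PulSA) gating. The gate here is
a supervised linear discriminant on area-normalised log pulse-shape features
(log width - log area, log height - log area), calibrated on explicit
negative (inclusion-free) and positive (inclusion-bearing) control event
sets; the original gate geometry is not restated in this reconstruction's
source data, so the calibrated discriminant is the auditable stand-in.

Dose-response surfaces assign each gated event to one of 20 logarithmic
cerulean (Httex1 expression) bins spanning the recorded range and one of four
modifier (HaloTag/TMR) categories — none (below a detection floor), then
low/medium/high log-spaced from the floor to that construct's maximum — and
report the fraction of inclusion-bearing cells per (expression, modifier)
bin.

Stall-reporter populations (GFP-test-mCherry cassettes) are summarised by
per-event mCherry:GFP ratios; ribosome stalling within the test sequence
lowers the ratio below one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import CalibrationError, SeparabilityWarning

TMR_CATEGORIES = ["none", "low", "medium", "high"]


# ---------------------------------------------------------------------------
# PulSA gate
# ---------------------------------------------------------------------------


def _pulse_features(events: pd.DataFrame) -> np.ndarray:
    """Area-normalised log pulse-shape features (log w - log a, log h - log a)."""
    for col in ("cerulean_area", "cerulean_height", "cerulean_width"):
        if col not in events.columns:
            raise ValueError(f"missing pulse column {col!r}")
        if (events[col] <= 0).any():
            raise ValueError(f"non-positive values in {col!r}")
    la = np.log(events["cerulean_area"].to_numpy(float))
    return np.column_stack([
        np.log(events["cerulean_width"].to_numpy(float)) - la,
        np.log(events["cerulean_height"].to_numpy(float)) - la,
    ])


@dataclass
class PulsaGate:
    """A fitted pulse-shape discriminant. Application is deterministic."""

    model: LinearDiscriminantAnalysis
    training_accuracy: float
    separable: bool

    def apply(self, events: pd.DataFrame) -> np.ndarray:
        return self.model.predict(_pulse_features(events)).astype(bool)


def fit_pulsa_gate(
    negative: pd.DataFrame,
    positive: pd.DataFrame,
    min_events: int = 100,
    accuracy_floor: float = 0.75,
) -> PulsaGate:
    """Fit the linear discriminant on calibration control populations."""
    if len(negative) < min_events or len(positive) < min_events:
        raise CalibrationError(
            f"calibration sets need >= {min_events} events each "
            f"(got {len(negative)}, {len(positive)})"
        )
    xn, xp = _pulse_features(negative), _pulse_features(positive)
    if xn.shape == xp.shape and np.allclose(np.sort(xn, axis=0),
                                            np.sort(xp, axis=0), atol=1e-12):
        raise CalibrationError("degenerate calibration: identical populations")
    x = np.vstack([xn, xp])
    y = np.concatenate([np.zeros(len(xn)), np.ones(len(xp))])
    model = LinearDiscriminantAnalysis()
    model.fit(x, y)
    acc = float((model.predict(x) == y).mean())
    separable = acc >= accuracy_floor
    if not separable:
        warnings.warn(
            f"pulse-shape populations barely separable "
            f"(calibration accuracy {acc:.2f})",
            SeparabilityWarning,
        )
    return PulsaGate(model=model, training_accuracy=acc, separable=separable)


def pulsa_gate(events: pd.DataFrame, calibration: dict) -> np.ndarray:
    """Gate inclusion-bearing events.

    ``calibration`` maps ``negative``/``positive`` to control event tables.
    Returns a boolean has_inclusion flag per event.
    """
    gate = fit_pulsa_gate(calibration["negative"], calibration["positive"])
    return gate.apply(events)


# ---------------------------------------------------------------------------
# log binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinEdges:
    """Log-spaced bin edges: global cerulean edges, per-construct TMR edges."""

    cerulean_edges: np.ndarray  # 21 edges -> 20 bins
    tmr_edges: dict  # construct -> 4 edges (floor..max) -> 3 bins above floor
    tmr_floor: float
    qc: dict = field(default_factory=dict)


def make_bins(
    events: pd.DataFrame,
    n_cerulean_bins: int = 20,
    tmr_floor: float | None = None,
    floor_calibration: pd.DataFrame | None = None,
) -> BinEdges:
    """Log-uniform bin edges spanning the recorded intensity ranges.

    Cerulean: ``n_cerulean_bins`` log-uniform bins from the minimum to the
    maximum positive recorded value. TMR: per construct, categories none
    (below the detection floor) then low/medium/high log-uniform from the
    floor to that construct's maximum. The default floor is the 1st
    percentile of ``floor_calibration`` (a modifier-free control population)
    when given, else of the events themselves. Zero or negative intensities
    are excluded from binning and counted in the QC sidecar.
    """
    cer = events["cerulean_area"].to_numpy(float)
    pos = cer[cer > 0]
    qc = {"n_nonpositive_cerulean": int((cer <= 0).sum())}
    if np.unique(pos).size < 2:
        raise ValueError("need >= 2 distinct positive cerulean values")
    cer_edges = np.geomspace(pos.min(), pos.max(), n_cerulean_bins + 1)

    if tmr_floor is None:
        src = floor_calibration if floor_calibration is not None else events
        tmr_all = src["tmr_area"].to_numpy(float)
        tmr_all = tmr_all[tmr_all > 0]
        if tmr_all.size == 0:
            raise ValueError("no positive TMR values to set a detection floor")
        tmr_floor = float(np.percentile(tmr_all, 1.0))

    tmr_edges = {}
    for construct, grp in events.groupby("construct"):
        tmr = grp["tmr_area"].to_numpy(float)
        qc[f"n_nonpositive_tmr_{construct}"] = int((tmr <= 0).sum())
        tmr_max = tmr[tmr > 0].max(initial=tmr_floor)
        hi = max(tmr_max, tmr_floor * (1 + 1e-9))
        tmr_edges[construct] = np.geomspace(tmr_floor, hi, 4)
    return BinEdges(cer_edges, tmr_edges, float(tmr_floor), qc)


def _assign(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [lo, hi) bins, last bin closed; exact interior-edge values go
    to the higher bin. Returns -1 for values outside [edges[0], edges[-1]]."""
    idx = np.digitize(values, edges, right=False) - 1
    idx[values == edges[-1]] = len(edges) - 2
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


@dataclass
class BinGrid:
    """Counts and inclusion fractions on the 20x4 expression-by-modifier grid."""

    construct: str
    cerulean_edges: np.ndarray
    tmr_edges: np.ndarray
    tmr_floor: float
    counts: np.ndarray  # (n_cerulean_bins, 4) ints
    inclusion_counts: np.ndarray

    @property
    def fraction(self) -> np.ndarray:
        """Inclusion fraction per bin; NaN where the bin is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts > 0,
                            self.inclusion_counts / np.maximum(self.counts, 1),
                            np.nan)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        nbins = self.counts.shape[0]
        frac = self.fraction
        for i in range(nbins):
            for j, cat in enumerate(TMR_CATEGORIES):
                rows.append({
                    "construct": self.construct,
                    "cerulean_bin_lo": self.cerulean_edges[i],
                    "cerulean_bin_hi": self.cerulean_edges[i + 1],
                    "tmr_category": cat,
                    "n": int(self.counts[i, j]),
                    "n_inclusion": int(self.inclusion_counts[i, j]),
                    "fraction": frac[i, j],
                })
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "construct": self.construct,
            "cerulean_edges": self.cerulean_edges.tolist(),
            "tmr_edges": self.tmr_edges.tolist(),
            "tmr_floor": self.tmr_floor,
            "tmr_categories": TMR_CATEGORIES,
            "counts": self.counts.tolist(),
            "inclusion_counts": self.inclusion_counts.tolist(),
            "fraction": [[None if np.isnan(v) else v for v in row]
                         for row in self.fraction],
        }))


def inclusion_fraction(
    events: pd.DataFrame,
    flags: np.ndarray,
    edges: BinEdges,
) -> dict:
    """Per-construct 20x4 grids of event counts and inclusion fractions.

    Every event with positive intensities lands in exactly one grid cell, so
    grid counts sum to the number of binned events (conservation).
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(events):
        raise ValueError("flags not aligned with events")
    grids = {}
    n_bins = len(edges.cerulean_edges) - 1
    for construct, grp in events.groupby("construct"):
        gflags = flags[grp.index.to_numpy()]
        cer = grp["cerulean_area"].to_numpy(float)
        tmr = grp["tmr_area"].to_numpy(float)
        ci = _assign(cer, edges.cerulean_edges)
        t_edges = edges.tmr_edges[construct]
        tj = np.where(tmr < edges.tmr_floor, 0, _assign(tmr, t_edges) + 1)
        tj = np.clip(tj, 0, 3)
        counts = np.zeros((n_bins, 4), dtype=int)
        incl = np.zeros((n_bins, 4), dtype=int)
        ok = ci >= 0
        np.add.at(counts, (ci[ok], tj[ok]), 1)
        np.add.at(incl, (ci[ok], tj[ok]), gflags[ok].astype(int))
        grids[construct] = BinGrid(construct, edges.cerulean_edges, t_edges,
                                   edges.tmr_floor, counts, incl)
    return grids


# ---------------------------------------------------------------------------
# stall ratios
# ---------------------------------------------------------------------------


@dataclass
class StallSummary:
    """Per-construct mCherry:GFP ratio summaries and per-event ratios."""

    table: pd.DataFrame  # construct, n, n_excluded, median, q25, q75
    ratios: dict  # construct -> per-event ratio array

    def median(self, construct: str) -> float:
        row = self.table.set_index("construct").loc[construct]
        return float(row["median"])


def stall_ratios(events: pd.DataFrame, gfp_floor: float = 0.0) -> StallSummary:
    """Per-event mCherry:GFP ratios, summarised per construct.

    Events at or below ``gfp_floor`` in GFP are excluded and counted; an
    empty result (no events above the floor) raises.
    """
    rows, ratios = [], {}
    for construct, grp in events.groupby("construct"):
        gfp = grp["gfp_area"].to_numpy(float)
        mch = grp["mcherry_area"].to_numpy(float)
        keep = gfp > gfp_floor
        if not keep.any():
            raise ValueError(f"no events above GFP floor for construct {construct!r}")
        ratio = mch[keep] / gfp[keep]
        if (ratio < 0).any():
            raise ValueError("negative mCherry:GFP ratio")
        ratios[construct] = ratio
        q25, med, q75 = np.percentile(ratio, [25, 50, 75])
        rows.append({"construct": construct, "n": int(keep.sum()),
                     "n_excluded": int((~keep).sum()),
                     "median": float(med), "q25": float(q25), "q75": float(q75)})
    return StallSummary(pd.DataFrame(rows), ratios)
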