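"""Replicate synchrony and variability statistics.

Given technical replicates of one sample (spectra on an identical
nucleotide grid plus their peak tables), computes the average pairwise
Pearson correlation (raw and max-height-normalized intensities), the
median lag of maximum cross-correlation between replicate pairs, and the
median coefficient of variation of normalized peak quantities across
replicate-matched peak groups.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import correlate

from .errors import GlycotraceError
from .peaks import PeakTable
from .types import Spectrum

REPORT_COLUMNS = ["sample", "pearson_raw", "pearson_mh", "median_lag",
                  "cv_area_ta", "cv_height_mh"]


@dataclass
class ReplicateSet:
    """Technical replicates of one sample on identical nt grids."""

    sample_id: str
    spectra: list[Spectrum]
    peak_tables: list[PeakTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.spectra) < 2:
            raise GlycotraceError("a replicate set needs at least 2 spectra")
        grid = self.spectra[0].positions
        for s in self.spectra[1:]:
            if len(s) != len(grid) or not np.allclose(s.positions, grid):
                raise GlycotraceError("replicate spectra must share one nt grid")
        if self.peak_tables and len(self.peak_tables) != len(self.spectra):
            raise GlycotraceError("one peak table per spectrum required")


@dataclass
class ReproReport:
    sample_id: str
    pearson_raw: float
    pearson_mh: float
    median_lag: float
    cv_area_ta: float
    cv_height_mh: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sample": self.sample_id, "pearson_raw": self.pearson_raw,
            "pearson_mh": self.pearson_mh, "median_lag": self.median_lag,
            "cv_area_ta": self.cv_area_ta, "cv_height_mh": self.cv_height_mh,
        }], columns=REPORT_COLUMNS)


def _pearson(a: np.ndarray, b: np.ndarray, label_a: str, label_b: str) -> float:
    if a.std() == 0 or b.std() == 0:
        zero = label_a if a.std() == 0 else label_b
        raise GlycotraceError(
            f"replicate {zero}: zero-variance spectrum, Pearson undefined")
    return float(np.corrcoef(a, b)[0, 1])


def pairwise_pearson(repl: ReplicateSet, normalized: bool = False) -> float:
    """Mean Pearson correlation over all unordered replicate pairs.

    With ``normalized`` each spectrum is divided by its maximum first
    (max-height normalization).
    """
    vecs = []
    for k, s in enumerate(repl.spectra):
        v = s.intensities.astype(float)
        if normalized:
            top = v.max()
            if top == 0:
                raise GlycotraceError(f"replicate {k}: zero maximum, cannot normalize")
            v = v / top
        vecs.append(v)
    rhos = [_pearson(vecs[i], vecs[j], f"#{i}", f"#{j}")
            for i, j in combinations(range(len(vecs)), 2)]
    return float(np.mean(rhos))


def xcorr_lag(a: np.ndarray, b: np.ndarray) -> int:
    """Integer lag maximizing the cross-correlation of mean-centered,
    max-normalized signals.  Positive lag = ``b`` is delayed relative to
    ``a``."""
    def prep(v):
        v = v - v.mean()
        top = np.abs(v).max()
        return v / top if top > 0 else v
    a, b = prep(a), prep(b)
    cc = correlate(b, a, mode="full")
    if not np.any(cc):
        return 0  # featureless signals: no defined lag
    return int(np.argmax(cc) - (a.size - 1))


def median_xcorr_lag(repl: ReplicateSet) -> float:
    """Median over replicate pairs of the absolute argmax cross-correlation
    lag, in measurement points."""
    lags = [abs(xcorr_lag(repl.spectra[i].intensities, repl.spectra[j].intensities))
            for i, j in combinations(range(len(repl.spectra)), 2)]
    return float(np.median(lags))


def _group_peaks(repl: ReplicateSet, tol_nt: float = 1.0
                 ) -> tuple[list[dict[int, int]], list[dict[int, int]]]:
    """Group peaks across replicates by apex proximity after lag correction.

    Returns (complete_groups, partial_groups); each group maps replicate
    index -> peak index within that replicate's table.  Lags are measured
    against replicate 0 and converted to nt via the grid step.
    """
    if not repl.peak_tables:
        raise GlycotraceError("replicate set has no peak tables")
    step = repl.spectra[0].step
    ref = repl.spectra[0].intensities
    shifts = [0.0]
    for s in repl.spectra[1:]:
        shifts.append(xcorr_lag(ref, s.intensities) * step)

    entries = []  # (corrected apex, replicate, peak index)
    for r, table in enumerate(repl.peak_tables):
        for k, p in enumerate(table.peaks):
            entries.append((p.apex_nt - shifts[r], r, k))
    entries.sort()

    groups: list[dict[int, int]] = []
    centers: list[float] = []
    for apex, r, k in entries:
        placed = False
        if groups and abs(apex - centers[-1]) <= tol_nt and r not in groups[-1]:
            g = groups[-1]
            g[r] = k
            centers[-1] = (centers[-1] * (len(g) - 1) + apex) / len(g)
            placed = True
        if not placed:
            groups.append({r: k})
            centers.append(apex)
    n = len(repl.spectra)
    complete = [g for g in groups if len(g) == n]
    partial = [g for g in groups if len(g) < n]
    return complete, partial


def peak_cv(repl: ReplicateSet, quantity: str = "area_ta",
            tol_nt: float = 1.0) -> tuple[float, list[float], int]:
    """Median CV of a normalized peak quantity over replicate-matched groups.

    ``quantity`` is ``area_ta`` or ``height_mh``.  Groups missing from some
    replicate are excluded from the median but counted in the returned
    partial-group tally: (median CV, per-group CVs, n_partial).
    """
    if quantity not in ("area_ta", "height_mh"):
        raise GlycotraceError(f"unknown quantity {quantity!r}")
    complete, partial = _group_peaks(repl, tol_nt)
    if not complete:
        raise GlycotraceError("no peak groups matched across all replicates")
    cvs = []
    for g in complete:
        vals = np.array([getattr(repl.peak_tables[r].peaks[k], quantity)
                         for r, k in sorted(g.items())])
        mean = vals.mean()
        cvs.append(float(vals.std(ddof=1) / mean) if mean != 0 else 0.0)
    return float(np.median(cvs)), cvs, len(partial)


def build_report(repl: ReplicateSet, tol_nt: float = 1.0) -> ReproReport:
    """All synchrony/variability statistics for one replicate set."""
    return ReproReport(
        sample_id=repl.sample_id,
        pearson_raw=pairwise_pearson(repl, normalized=False),
        pearson_mh=pairwise_pearson(repl, normalized=True),
        median_lag=median_xcorr_lag(repl),
        cv_area_ta=peak_cv(repl, "area_ta", tol_nt)[0],
        cv_height_mh=peak_cv(repl, "height_mh", tol_nt)[0])


def reports_to_tsv(reports: Sequence[ReproReport], path) -> None:
    pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g")
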