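"""Migration-scale normalization against a co-injected size standard.

The ladder channel carries labeled oligonucleotide fragments of known
length.  Their apexes calibrate a monotone scan-index -> nucleotide mapping
that puts the glycan channel onto the nucleotide axis, from which the
glycomic region (150-350 nt by default) is excised on a uniform grid.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator, interp1d
from scipy.signal import find_peaks

from .errors import CalibrationError, ExtrapolationError, GlycotraceError
from .types import DEFAULT_REGION, DEFAULT_STEP, LadderDefinition, RawTrace, Spectrum


@dataclass
class MigrationMap:
    """Monotone mapping from scan index to nucleotide coordinate.

    ``knots`` are (scan index, nucleotide size) pairs, one per calibrated
    ladder fragment; ``residuals`` are the per-knot fit residuals in nt
    (zero for interpolating maps).
    """

    knots: list[tuple[float, float]]
    kind: str = "pchip"
    residuals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        scans = np.array([k[0] for k in self.knots], dtype=float)
        sizes = np.array([k[1] for k in self.knots], dtype=float)
        if scans.size < 3:
            raise CalibrationError(f"need at least 3 knots, got {scans.size}")
        if not np.all(np.diff(scans) > 0):
            raise CalibrationError("knot scan indices must be strictly increasing")
        if not np.all(np.diff(sizes) > 0):
            raise CalibrationError("knot sizes must be strictly increasing")
        if self.kind == "pchip":
            self._fn = PchipInterpolator(scans, sizes, extrapolate=False)
        elif self.kind == "linear":
            self._fn = interp1d(scans, sizes, kind="linear", bounds_error=True)
        else:
            raise GlycotraceError(f"unknown interpolant kind {self.kind!r}")
        self._scans = scans
        self._sizes = sizes
        fitted = self(scans)
        if not self.residuals:
            self.residuals = tuple(float(r) for r in (fitted - sizes))

    @property
    def span(self) -> tuple[float, float]:
        """Calibrated nucleotide span (first to last fragment size)."""
        return float(self._sizes[0]), float(self._sizes[-1])

    @property
    def max_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)))

    def __call__(self, scan: np.ndarray | float) -> np.ndarray | float:
        return self._fn(scan)

    def check_monotone(self, grid: np.ndarray) -> None:
        vals = np.asarray(self(grid), dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size >= 2 and not np.all(np.diff(vals) > 0):
            raise CalibrationError(
                "fitted migration map is not strictly increasing on the "
                "evaluation grid (mis-called ladder?)")

    def scan_at(self, size: float | np.ndarray) -> np.ndarray | float:
        """Inverse mapping nucleotide -> scan index (monotone, numeric)."""
        lo, hi = self._scans[0], self._scans[-1]
        grid = np.linspace(lo, hi, 20001)
        vals = np.asarray(self(grid), dtype=float)
        return np.interp(size, vals, grid)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind,
                       "knots": [[float(s), float(z)] for s, z in self.knots],
                       "residuals": list(self.residuals)}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MigrationMap":
        with open(path) as fh:
            d = json.load(fh)
        return cls(knots=[tuple(k) for k in d["knots"]], kind=d["kind"],
                   residuals=tuple(d.get("residuals", ())))


def call_ladder_peaks(ladder: RawTrace, expected: LadderDefinition,
                      rel_threshold: float = 0.10) -> list[int]:
    """Locate one apex per expected ladder fragment, in ascending scan order.

    Candidates are local maxima with height and prominence of at least
    ``rel_threshold`` of the ladder maximum; the fragment count must be
    matched exactly by the top-prominence candidates, otherwise calibration
    fails rather than guessing.
    """
    n_frag = len(expected)
    y = ladder.values
    if y.size <= 10 * n_frag:
        raise CalibrationError(
            f"ladder trace too short ({y.size} scans) for {n_frag} fragments")
    span = float(y.max() - y.min())
    if span <= 0:
        raise CalibrationError("flat ladder trace: no fragments detectable")
    thr = y.min() + rel_threshold * span
    idx, props = find_peaks(y, height=thr, prominence=rel_threshold * span)
    if idx.size < n_frag:
        raise CalibrationError(
            f"found {idx.size} candidate ladder apexes for {n_frag} expected "
            f"fragments")
    if idx.size > n_frag:
        # keep the n_frag most prominent candidates, restore scan order
        order = np.argsort(props["prominences"])[::-1][:n_frag]
        idx = np.sort(idx[order])
    return [int(i) for i in idx]


def fit_migration_map(apexes: Sequence[int], expected: LadderDefinition,
                      kind: str = "pchip") -> MigrationMap:
    """Fit a monotone interpolant through (apex scan, fragment size) knots."""
    apexes = list(apexes)
    if len(apexes) != len(expected):
        raise CalibrationError(
            f"{len(apexes)} apexes for {len(expected)} ladder fragments")
    if any(b <= a for a, b in zip(apexes, apexes[1:])):
        raise CalibrationError("ladder apexes are not strictly ascending")
    knots = [(float(s), float(z)) for s, z in zip(apexes, expected.fragment_sizes)]
    mm = MigrationMap(knots=knots, kind=kind)
    mm.check_monotone(np.linspace(apexes[0], apexes[-1], 4096))
    return mm


def to_nucleotide_axis(glycan: RawTrace, mm: MigrationMap,
                       region: tuple[float, float] = DEFAULT_REGION,
                       step: float = DEFAULT_STEP) -> Spectrum:
    """Resample a glycan trace onto a uniform nucleotide grid over ``region``.

    Intensities are linearly interpolated from the scan axis; the result has
    stage ``normalized``.  Requesting a region outside the calibrated ladder
    span raises :class:`ExtrapolationError`.
    """
    lo, hi = float(region[0]), float(region[1])
    if hi <= lo:
        raise GlycotraceError(f"empty region {region}")
    span = mm.span
    if lo < span[0] or hi > span[1]:
        raise ExtrapolationError(
            f"region [{lo}, {hi}] nt outside calibrated ladder span "
            f"[{span[0]}, {span[1]}] nt")
    scans = np.arange(len(glycan), dtype=float)
    nt_of_scan = np.asarray(mm(scans), dtype=float)
    ok = np.isfinite(nt_of_scan)
    nt_of_scan, vals = nt_of_scan[ok], glycan.values[ok]
    # closed interval [lo, hi]
    n_pts = int(round((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n_pts)
    y = np.interp(grid, nt_of_scan, vals)
    return Spectrum(grid, y, stage="normalized", sample_id=glycan.sample_id)
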