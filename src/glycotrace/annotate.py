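"""Peak annotation by dynamic-time-warping alignment to a reference.

A sample spectrum is elastically aligned to a reference spectrum (both
max-height normalized, absolute-difference pointwise cost, Sakoe-Chiba
band).  Sample peaks are matched to reference peaks when the optimal
warping path connects their apexes; matched peaks inherit the reference's
structural annotations (Oxford notation).  Manual overrides from visual
inspection are applied last and recorded with ``match_mode = "manual"``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .errors import GlycotraceError
from .peaks import Peak, PeakTable
from .types import Spectrum

try:  # optional JIT; the pure-python fallback is exact but slower
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass(frozen=True)
class ReferencePeak:
    """One peak of the reference spectrum with its structural annotation."""

    ref_id: int
    apex_nt: float | None
    structures: tuple[str, ...]


@dataclass
class MatchTable:
    """DTW-derived correspondence between sample peaks and reference peaks."""

    pairs: list[tuple[int, int, str]]  # (sample peak index, ref_id, match_mode)
    unmatched_sample: list[int]
    unmatched_ref: list[int]
    dtw_distance: float
    secondary: list[tuple[int, int]] = field(default_factory=list)
    rule: str = "apex-window"


@_njit(cache=True)
def _dtw_fill(a, b, w):  # pragma: no cover - exercised via dtw_align
    n, m = a.size, b.size
    D = np.full((n, m), np.inf)
    ratio = (m - 1) / (n - 1) if n > 1 else 1.0
    D[0, 0] = abs(a[0] - b[0])
    for i in range(n):
        jc = i * ratio
        j0 = int(jc - w)
        j1 = int(jc + w) + 1
        if j0 < 0:
            j0 = 0
        if j1 > m - 1:
            j1 = m - 1
        for j in range(j0, j1 + 1):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and D[i - 1, j] < best:
                best = D[i - 1, j]
            if j > 0 and D[i, j - 1] < best:
                best = D[i, j - 1]
            if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                best = D[i - 1, j - 1]
            if best < np.inf:
                D[i, j] = abs(a[i] - b[j]) + best
    return D


def dtw_align(sample: Spectrum, reference: Spectrum, band_nt: float = 10.0,
              normalize: bool = True) -> tuple[list[tuple[int, int]], float]:
    """Optimal monotone warping path between two spectra.

    Both spectra are max-height normalized before alignment (disable with
    ``normalize=False`` for pre-normalized inputs); the pointwise
    cost is the absolute intensity difference and the returned distance is
    the accumulated cost along the optimal path.  ``band_nt`` bounds the
    warp (Sakoe-Chiba band) in nucleotides.

    Returns (path, distance); the path starts at (0, 0), ends at
    (n-1, m-1), and is non-decreasing in both indices.
    """
    a, b = sample.intensities, reference.intensities
    if a.size < 2 or b.size < 2:
        raise GlycotraceError("DTW needs at least 2 samples per spectrum")

    def norm(v):
        top = np.abs(v).max()
        return v / top if top > 0 else v.copy()

    an, bn = (norm(a), norm(b)) if normalize else (a.astype(float), b.astype(float))
    w = max(int(round(band_nt / sample.step)), 1)
    D = _dtw_fill(an, bn, w)
    n, m = a.size, b.size
    dist = float(D[n - 1, m - 1])
    if not np.isfinite(dist):
        raise GlycotraceError("DTW band too narrow: no feasible path")

    # backtrack, diagonal-preferring on ties for determinism
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while i > 0 or j > 0:
        cands = []
        if i > 0 and j > 0:
            cands.append((D[i - 1, j - 1], i - 1, j - 1))
        if i > 0:
            cands.append((D[i - 1, j], i - 1, j))
        if j > 0:
            cands.append((D[i, j - 1], i, j - 1))
        _, i, j = min(cands, key=lambda t: t[0])
        path.append((i, j))
    path.reverse()
    return path, dist


def _ref_apex_index(ref_peak: ReferencePeak, ref_spectrum: Spectrum) -> int:
    if ref_peak.apex_nt is None:
        raise GlycotraceError(
            f"reference peak {ref_peak.ref_id} has no apex position; it can "
            "annotate but not be DTW-matched")
    start = float(ref_spectrum.positions[0])
    return int(round((ref_peak.apex_nt - start) / ref_spectrum.step))


def match_peaks(path: Sequence[tuple[int, int]], sample_peaks: PeakTable,
                ref_peaks: Sequence[ReferencePeak], ref_spectrum: Spectrum,
                dtw_distance: float = float("nan"),
                rule: str = "apex-window", window: int = 1) -> MatchTable:
    """Establish sample->reference peak correspondences from a warping path.

    Under the default ``apex-window`` rule, sample peak *s* matches
    reference peak *r* iff some path pair (i, j) lies within ``window``
    samples of both apexes.  The alternative ``span`` rule accepts path
    pairs anywhere inside the sample peak's [left, right] index span
    (against the ref apex window).  One-to-many matches collapse to the
    pair whose apexes are closest along the path; the rest are reported as
    secondary.  Crossing matches are pruned to preserve monotone order.
    """
    if rule not in ("apex-window", "span"):
        raise GlycotraceError(f"unknown match rule {rule!r}")
    path = np.asarray(path, dtype=int)
    step = ref_spectrum.step
    start = float(sample_peaks.region[0])

    ref_idx = {r.ref_id: _ref_apex_index(r, ref_spectrum) for r in ref_peaks}
    candidates: dict[int, list[tuple[float, int]]] = {}
    for s_pos, speak in enumerate(sample_peaks.peaks):
        si = speak.apex_index
        if rule == "apex-window":
            on_s = np.abs(path[:, 0] - si) <= window
        else:
            li = int(round((speak.left_nt - start) / step))
            ri = int(round((speak.right_nt - start) / step))
            on_s = (path[:, 0] >= li) & (path[:, 0] <= ri)
        if not on_s.any():
            continue
        js = path[on_s]
        for r in ref_peaks:
            rj = ref_idx[r.ref_id]
            hit = np.abs(js[:, 1] - rj) <= window
            if hit.any():
                # closeness of the apex-to-apex connection along the path
                score = float(np.min(np.abs(js[hit][:, 0] - si)
                                     + np.abs(js[hit][:, 1] - rj)))
                candidates.setdefault(s_pos, []).append((score, r.ref_id))

    pairs: list[tuple[int, int, str]] = []
    secondary: list[tuple[int, int]] = []
    for s_pos in sorted(candidates):
        ranked = sorted(candidates[s_pos])
        pairs.append((s_pos, ranked[0][1], "dtw"))
        secondary.extend((s_pos, rid) for _, rid in ranked[1:])

    # prune crossings: keep a monotone subsequence in ref apex order
    kept: list[tuple[int, int, str]] = []
    last_rj = -1
    for s_pos, rid, mode in pairs:
        rj = ref_idx[rid]
        if rj >= last_rj:
            kept.append((s_pos, rid, mode))
            last_rj = rj
        else:
            secondary.append((s_pos, rid))
    matched_s = {p[0] for p in kept}
    matched_r = {p[1] for p in kept}
    return MatchTable(
        pairs=kept,
        unmatched_sample=[i for i in range(len(sample_peaks)) if i not in matched_s],
        unmatched_ref=[r.ref_id for r in ref_peaks if r.ref_id not in matched_r],
        dtw_distance=float(dtw_distance),
        secondary=secondary,
        rule=rule)


def transfer_annotations(match: MatchTable, sample_peaks: PeakTable,
                         ref_table: Sequence[ReferencePeak],
                         overrides: Sequence[dict] | None = None) -> PeakTable:
    """Copy reference structures onto matched sample peaks.

    ``overrides`` is a list of ``{"sample_peak": i, "ref_ids": [...]}``
    records from visual inspection, applied last (``match_mode="manual"``);
    an empty ``ref_ids`` list removes any annotation.  Unknown ref ids in an
    override raise.
    """
    by_id = {r.ref_id: r for r in ref_table}
    for p in sample_peaks.peaks:
        p.ref_ids, p.structures, p.match_mode = (), (), ""
    for s_pos, rid, mode in match.pairs:
        if rid not in by_id:
            raise GlycotraceError(f"matched ref_id {rid} absent from reference table")
        ref = by_id[rid]
        peak = sample_peaks.peaks[s_pos]
        peak.ref_ids = (rid,)
        peak.structures = tuple(ref.structures)
        peak.match_mode = mode
    for ov in overrides or ():
        s_pos = int(ov["sample_peak"])
        rids = [int(r) for r in ov.get("ref_ids", [])]
        unknown = [r for r in rids if r not in by_id]
        if unknown:
            raise GlycotraceError(f"override names unknown ref_id(s) {unknown}")
        if s_pos < 0 or s_pos >= len(sample_peaks):
            raise GlycotraceError(f"override sample_peak {s_pos} out of range")
        peak = sample_peaks.peaks[s_pos]
        peak.ref_ids = tuple(rids)
        structures: list[str] = []
        for rid in rids:
            structures.extend(by_id[rid].structures)
        peak.structures = tuple(structures)
        peak.match_mode = "manual" if rids else ""
    return sample_peaks


def load_reference(path) -> list[ReferencePeak]:
    """Load a reference peak list from JSON: [{ref_id, apex_nt, structures}]."""
    with open(path) as fh:
        raw = json.load(fh)
    out = []
    for rec in raw:
        apex = rec.get("apex_nt")
        out.append(ReferencePeak(
            ref_id=int(rec["ref_id"]),
            apex_nt=float(apex) if apex is not None else None,
            structures=tuple(rec.get("structures", []))))
    if len({r.ref_id for r in out}) != len(out):
        raise GlycotraceError("reference peak ids must be unique")
    return out


def packaged_reference() -> list[ReferencePeak]:
    """Built-in plasma N-glycome reference annotation table."""
    with resources.files("glycotrace.data").joinpath(
            "reference_plasma.json").open() as fh:
        raw = json.load(fh)
    return [ReferencePeak(int(r["ref_id"]),
                          r.get("apex_nt"),
                          tuple(r["structures"])) for r in raw]


def packaged_overrides() -> list[dict]:
    """Built-in visual-inspection override list for the packaged reference."""
    with resources.files("glycotrace.data").joinpath(
            "manual_overrides.json").open() as fh:
        return json.load(fh)
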