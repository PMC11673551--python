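"""Peak detection and quantification on baseline-corrected spectra.

Apexes are local maxima whose height and topological prominence both reach
at least 1% (configurable) of the highest point in the region.  Each peak
gets a local Gaussian fit; boundaries are placed at +/-3 fitted SDs from
the center, clipped to the region; areas come from composite Simpson
integration on the sampled grid.  Heights are additionally reported
normalized to the region maximum (``height_mh``) and areas normalized to
the summed area (``area_ta``).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import GlycotraceError, ParameterError
from .types import Spectrum

TSV_COLUMNS = ["apex_nt", "height", "prominence", "sigma_nt", "left_nt",
               "right_nt", "area", "height_mh", "area_ta", "overlap_flag"]


@dataclass
class Peak:
    apex_nt: float
    height: float
    prominence: float
    sigma_nt: float
    left_nt: float
    right_nt: float
    area: float
    height_mh: float = 0.0
    area_ta: float = 0.0
    overlap_flag: bool = False
    apex_index: int = 0
    flags: tuple[str, ...] = ()
    # annotation slots, filled by the annotate module
    ref_ids: tuple[int, ...] = ()
    structures: tuple[str, ...] = ()
    match_mode: str = ""


@dataclass
class PeakTable:
    sample_id: str
    peaks: list[Peak]
    region: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        apexes = [p.apex_nt for p in self.peaks]
        if any(b <= a for a, b in zip(apexes, apexes[1:])):
            raise GlycotraceError("peak apexes must be strictly ascending and unique")

    def __len__(self) -> int:
        return len(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.peaks:
            row = {c: getattr(p, c) for c in TSV_COLUMNS}
            row["ref_id"] = ";".join(str(r) for r in p.ref_ids) or "NA"
            row["structures"] = ";".join(p.structures) or "NA"
            row["match_mode"] = p.match_mode or "NA"
            row["flags"] = ";".join(p.flags)
            rows.append(row)
        return pd.DataFrame(rows, columns=TSV_COLUMNS + ["ref_id", "structures",
                                                         "match_mode", "flags"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self, path) -> None:
        payload = {"sample_id": self.sample_id, "region": list(self.region),
                   "provenance": self.provenance,
                   "peaks": [asdict(p) for p in self.peaks]}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "PeakTable":
        with open(path) as fh:
            d = json.load(fh)
        peaks = []
        for rec in d["peaks"]:
            rec = dict(rec)
            for key in ("flags", "ref_ids", "structures"):
                rec[key] = tuple(rec.get(key, ()))
            peaks.append(Peak(**rec))
        return cls(sample_id=d["sample_id"], peaks=peaks,
                   region=tuple(d["region"]), provenance=d.get("provenance", {}))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def detect_apexes(spec: Spectrum, rel_threshold: float = 0.01) -> list[int]:
    """Indices of local maxima passing the relative height+prominence gate.

    The threshold is ``rel_threshold`` times the maximum of the processed
    spectrum in the region.  Plateau ties resolve to the leftmost plateau
    sample.  A flat or empty spectrum yields an empty list.
    """
    if spec.stage != "baseline-corrected":
        raise GlycotraceError(
            f"peak detection expects a baseline-corrected spectrum, got stage "
            f"{spec.stage!r}")
    if not (0 < rel_threshold < 1):
        raise ParameterError("rel_threshold must be in (0, 1)")
    y = spec.intensities
    top = float(y.max(initial=0.0))
    if top <= 0 or np.allclose(y, y[0]):
        return []
    thr = rel_threshold * top
    idx, props = find_peaks(y, height=thr, prominence=thr, plateau_size=(1, None))
    return [int(i) for i in props["left_edges"]]


def _gauss(x, a, c, s):
    return a * np.exp(-0.5 * ((x - c) / s) ** 2)


def _moment_sigma(x: np.ndarray, y: np.ndarray, apex: int) -> float:
    """Half-height width estimate of the peak SD around a local apex."""
    h = y[apex]
    half = h / 2.0
    li = apex
    while li > 0 and y[li] > half:
        li -= 1
    ri = apex
    while ri < y.size - 1 and y[ri] > half:
        ri += 1
    # linear interpolation of the half-height crossings
    if y[li] <= half < y[li + 1]:
        xl = np.interp(half, [y[li], y[li + 1]], [x[li], x[li + 1]])
    else:
        xl = x[li]
    if y[ri] <= half < y[ri - 1]:
        xr = np.interp(half, [y[ri], y[ri - 1]], [x[ri], x[ri - 1]])
    else:
        xr = x[ri]
    fwhm = max(xr - xl, x[1] - x[0])
    return float(fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))))


def _fit_window(spec: Spectrum, apex: int, apexes: Sequence[int],
                sigma0: float) -> tuple[int, int]:
    """Fit window: up to the minima toward adjacent apexes, capped at
    +/-5 initial sigmas around the apex."""
    x, y = spec.positions, spec.intensities
    pos = list(apexes)
    k = pos.index(apex)
    left_lim = pos[k - 1] if k > 0 else 0
    right_lim = pos[k + 1] if k < len(pos) - 1 else y.size - 1
    li = left_lim + int(np.argmin(y[left_lim: apex + 1])) if apex > left_lim else apex
    ri = apex + int(np.argmin(y[apex: right_lim + 1])) if right_lim > apex else apex
    step = spec.step
    cap = max(int(round(5.0 * sigma0 / step)), 3)
    li = max(li, apex - cap)
    ri = min(ri, apex + cap)
    return li, ri


def fit_peak_shape(spec: Spectrum, apex: int,
                   apexes: Sequence[int] | None = None
                   ) -> tuple[float, float, float, bool]:
    """Local Gaussian fit at an apex -> (center_nt, sigma_nt, amplitude, fallback).

    ``fallback`` is True when the nonlinear fit did not converge (or the apex
    sits on a saturated plateau) and a moment-based sigma estimate was used
    instead.
    """
    x, y = spec.positions, spec.intensities
    if apexes is None:
        apexes = [apex]
    sigma0 = _moment_sigma(x, y, apex)
    h0 = float(y[apex])

    # saturated flat-top: a run of >=3 equal samples at the apex
    plateau = 1
    j = apex
    while j + 1 < y.size and y[j + 1] == y[apex]:
        plateau += 1
        j += 1
    if plateau >= 3:
        return float(x[apex]), sigma0, h0, True

    li, ri = _fit_window(spec, apex, apexes, sigma0)
    if ri - li + 1 < 4:
        return float(x[apex]), sigma0, h0, True
    xw, yw = x[li: ri + 1], y[li: ri + 1]
    try:
        popt, _ = curve_fit(
            _gauss, xw, yw, p0=(h0, x[apex], sigma0),
            bounds=([0.0, xw[0], spec.step / 10.0],
                    [np.inf, xw[-1], 100.0 * (xw[-1] - xw[0] + spec.step)]),
            maxfev=2000)
    except (RuntimeError, ValueError):
        return float(x[apex]), sigma0, h0, True
    a, c, s = (float(v) for v in popt)
    if not np.isfinite(s) or s <= 0:
        return float(x[apex]), sigma0, h0, True
    return c, s, a, False


def integrate_peak(spec: Spectrum, left_nt: float, right_nt: float
                   ) -> tuple[float, str]:
    """Composite Simpson integral of the signal over [left_nt, right_nt].

    Returns (area, method).  With an odd number of intervals the last one is
    patched with the trapezoid rule; fewer than 3 samples in range falls
    back to the trapezoid rule entirely (method ``"trapezoid"``).
    """
    if right_nt <= left_nt:
        raise GlycotraceError(f"invalid integration bounds [{left_nt}, {right_nt}]")
    x, y = spec.positions, spec.intensities
    sel = (x >= left_nt - 1e-12) & (x <= right_nt + 1e-12)
    xs, ys = x[sel], y[sel]
    n = xs.size
    if n < 2:
        return 0.0, "trapezoid"
    if n < 3:
        return float(np.trapezoid(ys, xs)), "trapezoid"
    h = spec.step
    n_int = n - 1
    if n_int % 2 == 0:
        area = _simpson_even(ys, h)
        return float(area), "simpson"
    area = _simpson_even(ys[:-1], h) + 0.5 * h * (ys[-2] + ys[-1])
    return float(area), "simpson+trapezoid"


def _simpson_even(y: np.ndarray, h: float) -> float:
    """Composite Simpson for an even interval count (odd sample count)."""
    return (h / 3.0) * (y[0] + y[-1] + 4.0 * y[1:-1:2].sum() + 2.0 * y[2:-2:2].sum())


def build_peak_table(spec: Spectrum, rel_threshold: float = 0.01,
                     boundary_sigmas: float = 3.0,
                     provenance: dict | None = None) -> PeakTable:
    """Detect, fit, bound, integrate and normalize all peaks of a spectrum."""
    region = (float(spec.positions[0]), float(spec.positions[-1]))
    apexes = detect_apexes(spec, rel_threshold)
    y = spec.intensities
    top = float(y.max(initial=0.0))
    peaks: list[Peak] = []
    if apexes:
        from scipy.signal import peak_prominences
        proms = peak_prominences(y, apexes)[0]
        for apex, prom in zip(apexes, proms):
            center, sigma, amp, fallback = fit_peak_shape(spec, apex, apexes)
            flags = ["fit_fallback"] if fallback else []
            left = center - boundary_sigmas * sigma
            right = center + boundary_sigmas * sigma
            if left < region[0]:
                left = region[0]
                flags.append("clipped_left")
            if right > region[1]:
                right = region[1]
                flags.append("clipped_right")
            area, method = integrate_peak(spec, left, right)
            if method != "simpson":
                flags.append(f"integration_{method}")
            peaks.append(Peak(apex_nt=float(spec.positions[apex]),
                              height=float(y[apex]), prominence=float(prom),
                              sigma_nt=sigma, left_nt=left, right_nt=right,
                              area=area, apex_index=int(apex),
                              flags=tuple(flags)))
    total_area = sum(p.area for p in peaks)
    for p in peaks:
        p.height_mh = p.height / top if top > 0 else 0.0
        p.area_ta = p.area / total_area if total_area > 0 else 0.0
    for a, b in zip(peaks, peaks[1:]):
        if b.left_nt < a.right_nt:
            a.overlap_flag = True
            b.overlap_flag = True
    prov = dict(provenance or {})
    prov.update({"rel_threshold": rel_threshold,
                 "boundary_sigmas": boundary_sigmas})
    return PeakTable(sample_id=spec.sample_id, peaks=peaks, region=region,
                     provenance=prov)
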