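"""Ground-truthed synthetic CGE-LIF runs.

Generates a glycan channel (Gaussian peaks placed on the nucleotide axis
and rendered through a monotone quadratic migration law), a ladder channel
(narrow peaks at the law's images of the size-standard fragments), baseline
drift, additive white noise, replicate-level jitter, and warped
reference/sample pairs.  Every generated artifact ships with a manifest
holding the planted truth, so the simulator doubles as the oracle for the
rest of the package.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import GlycotraceError
from .types import LIZ500, LadderDefinition, RawTrace, Spectrum


@dataclass
class SceneSpec:
    """Full description of one simulated run.

    The migration law ``scan(size) = a + b*size + c*size**2`` must be
    strictly increasing over the ladder span; ``noise_sd`` is a fraction of
    the tallest planted peak; all randomness flows from ``seed``.
    """

    peaks: list[tuple[float, float, float]] = field(default_factory=list)  # (center_nt, height, sigma_nt)
    law: tuple[float, float, float] = (150.0, 12.0, 0.002)  # a, b, c
    baseline: tuple[str, float] = ("constant", 0.0)  # kind in {constant, linear, exponential-decay}
    noise_sd: float = 0.0
    ladder: LadderDefinition = field(default_factory=lambda: LIZ500)
    ladder_height: float = 2000.0
    ladder_sigma_scans: float = 4.0
    crosstalk: float = 0.0  # fraction of the ladder bleeding into the glycan channel
    n_scans: int = 7000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ladder.fragment_sizes[0], self.ladder.fragment_sizes[-1]
        a, b, c = self.law
        grid = np.linspace(lo, hi, 2048)
        if np.any(np.diff(a + b * grid + c * grid ** 2) <= 0):
            raise GlycotraceError("migration law must be strictly increasing "
                                  "over the ladder span")

    def scan_of_nt(self, size):
        a, b, c = self.law
        size = np.asarray(size, dtype=float)
        return a + b * size + c * size ** 2

    def nt_of_scan(self, scan):
        """Analytic inverse of the quadratic law."""
        a, b, c = self.law
        scan = np.asarray(scan, dtype=float)
        if c == 0:
            return (scan - a) / b
        disc = np.maximum(b * b - 4.0 * c * (a - scan), 0.0)
        return (-b + np.sqrt(disc)) / (2.0 * c)


@dataclass
class Manifest:
    """Planted truth for a simulated artifact; the oracle for every test."""

    peaks: list[dict] = field(default_factory=list)
    ladder_scans: list[float] = field(default_factory=list)
    baseline: tuple[str, float] = ("constant", 0.0)
    noise_sd: float = 0.0
    seed: int = 0
    replicates: list[dict] = field(default_factory=list)
    correspondence: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Manifest":
        with open(path) as fh:
            d = json.load(fh)
        d["baseline"] = tuple(d["baseline"])
        return cls(**d)


def _baseline_values(kind: str, amplitude: float, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    if kind == "constant":
        return np.full(n, amplitude)
    if kind == "linear":
        return amplitude * t
    if kind == "exponential-decay":
        return amplitude * np.exp(-3.0 * t)
    raise GlycotraceError(f"unknown baseline kind {kind!r}")


def _glycan_signal(spec: SceneSpec) -> np.ndarray:
    """Noise- and baseline-free glycan channel: Gaussians in nt coordinates
    evaluated at the law's inverse image of each scan."""
    nt = spec.nt_of_scan(np.arange(spec.n_scans))
    y = np.zeros(spec.n_scans)
    for center, height, sigma in spec.peaks:
        y += height * np.exp(-0.5 * ((nt - center) / sigma) ** 2)
    return y


def _ladder_signal(spec: SceneSpec) -> tuple[np.ndarray, list[float]]:
    scans = np.arange(spec.n_scans, dtype=float)
    y = np.zeros(spec.n_scans)
    centers = []
    for size in spec.ladder.fragment_sizes:
        c = float(spec.scan_of_nt(size))
        centers.append(c)
        y += spec.ladder_height * np.exp(-0.5 * ((scans - c) / spec.ladder_sigma_scans) ** 2)
    return y, centers


def simulate_run(spec: SceneSpec) -> tuple[RawTrace, RawTrace, Manifest]:
    """One simulated run -> (glycan trace, ladder trace, manifest)."""
    rng = np.random.default_rng(spec.seed)
    clean = _glycan_signal(spec)
    kind, amp = spec.baseline
    y = clean + _baseline_values(kind, amp, spec.n_scans)
    ladder, centers = _ladder_signal(spec)
    if spec.crosstalk:
        y = y + spec.crosstalk * ladder
    top = max((h for _, h, _ in spec.peaks), default=1.0)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd * top, spec.n_scans)
    manifest = Manifest(
        peaks=[{"center_nt": c, "height": h, "sigma_nt": s,
                "area": h * s * np.sqrt(2.0 * np.pi)}
               for c, h, s in spec.peaks],
        ladder_scans=centers, baseline=spec.baseline,
        noise_sd=spec.noise_sd, seed=spec.seed)
    sid = f"sim-{spec.seed}"
    return (RawTrace(y, channel_tag="DATA,1", sample_id=sid),
            RawTrace(ladder, channel_tag="DATA,105", sample_id=sid),
            manifest)


def simulate_replicates(spec: SceneSpec, n: int,
                        jitter: tuple[float, float] = (3.0, 0.05)
                        ) -> tuple[list[tuple[RawTrace, RawTrace]], Manifest]:
    """n replicate runs of one scene with per-replicate jitter.

    ``jitter`` = (shift SD in scan points, amplitude-scale SD as a
    fraction).  Each replicate redraws its noise; the manifest records the
    drawn shift and amplitude factor per replicate.
    """
    if n < 2:
        raise GlycotraceError("need at least 2 replicates")
    shift_sd, amp_sd = jitter
    rng = np.random.default_rng(spec.seed)
    clean = _glycan_signal(spec)
    ladder, centers = _ladder_signal(spec)
    kind, amp = spec.baseline
    base = _baseline_values(kind, amp, spec.n_scans)
    top = max((h for _, h, _ in spec.peaks), default=1.0)

    runs = []
    rep_records = []
    scans = np.arange(spec.n_scans, dtype=float)
    for k in range(n):
        shift = float(np.round(rng.normal(0.0, shift_sd))) if shift_sd > 0 else 0.0
        factor = float(max(1.0 + rng.normal(0.0, amp_sd), 0.05)) if amp_sd > 0 else 1.0
        y = np.interp(scans - shift, scans, clean) * factor + base
        lad = np.interp(scans - shift, scans, ladder)
        if spec.crosstalk:
            y = y + spec.crosstalk * lad
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd * top, spec.n_scans)
        sid = f"sim-{spec.seed}-rep{k}"
        runs.append((RawTrace(y, channel_tag="DATA,1", sample_id=sid),
                     RawTrace(lad, channel_tag="DATA,105", sample_id=sid)))
        rep_records.append({"replicate": k, "shift_points": shift,
                            "amplitude_factor": factor})
    manifest = Manifest(
        peaks=[{"center_nt": c, "height": h, "sigma_nt": s,
                "area": h * s * np.sqrt(2.0 * np.pi)}
               for c, h, s in spec.peaks],
        ladder_scans=centers, baseline=spec.baseline,
        noise_sd=spec.noise_sd, seed=spec.seed, replicates=rep_records)
    return runs, manifest


def sinusoidal_warp(amplitude_nt: float, period_nt: float = 80.0,
                    origin_nt: float = 150.0):
    """Smooth monotone nt-axis distortion; monotone iff
    ``|amplitude| * 2*pi / period < 1``."""
    if abs(amplitude_nt) * 2.0 * np.pi / period_nt >= 1.0:
        raise GlycotraceError("warp is not strictly monotone")

    def warp(x):
        x = np.asarray(x, dtype=float)
        return x + amplitude_nt * np.sin(2.0 * np.pi * (x - origin_nt) / period_nt)

    return warp


def simulate_reference_pair(spec: SceneSpec, warp
                            ) -> tuple[tuple[RawTrace, RawTrace],
                                       tuple[RawTrace, RawTrace], Manifest]:
    """A reference run and a warped sample run with exact correspondences.

    Sample peak centers are ``warp(reference centers)``; the manifest's
    ``correspondence`` lists (reference index, ref center, sample center).
    The warp must be strictly monotone over the planted centers.
    """
    centers = np.array([c for c, _, _ in spec.peaks])
    warped = np.asarray(warp(centers), dtype=float)
    if centers.size >= 2 and np.any(np.diff(warped[np.argsort(centers)]) <= 0):
        raise GlycotraceError("warp is not strictly monotone over peak centers")
    ref_g, ref_l, ref_man = simulate_run(spec)
    sample_spec = SceneSpec(
        peaks=[(float(w), h, s) for w, (_, h, s) in zip(warped, spec.peaks)],
        law=spec.law, baseline=spec.baseline, noise_sd=spec.noise_sd,
        ladder=spec.ladder, ladder_height=spec.ladder_height,
        ladder_sigma_scans=spec.ladder_sigma_scans, n_scans=spec.n_scans,
        seed=spec.seed + 1)
    smp_g, smp_l, _ = simulate_run(sample_spec)
    ref_man.correspondence = [
        {"index": i, "ref_center_nt": float(c), "sample_center_nt": float(w)}
        for i, (c, w) in enumerate(zip(centers, warped))]
    return (ref_g, ref_l), (smp_g, smp_l), ref_man


def default_scene(seed: int = 0, n_peaks: int = 30,
                  noise_sd: float = 0.002,
                  baseline: tuple[str, float] = ("exponential-decay", 50.0)
                  ) -> SceneSpec:
    """A plasma-like scene: ``n_peaks`` well-spread Gaussians in the
    glycomic region with a 100:1 dynamic range floor at 2% of max."""
    rng = np.random.default_rng(seed)
    # random gaps of at least 5 nt keep every planted peak resolvable
    gap_hi = min(6.3, 5.0 + (188.0 / max(n_peaks - 1, 1) - 5.0) * 2)
    gap_hi = max(gap_hi, 5.01)
    gaps = rng.uniform(5.0, gap_hi, max(n_peaks - 1, 0))
    centers = 156.0 + np.concatenate([[0.0], np.cumsum(gaps)])
    if centers[-1] > 345.0:
        centers = 156.0 + (centers - 156.0) * (189.0 / (centers[-1] - 156.0))
    heights = rng.uniform(0.03, 1.0, n_peaks) * 1000.0
    sigmas = rng.uniform(0.4, 0.8, n_peaks)
    return SceneSpec(
        peaks=[(float(c), float(h), float(s))
               for c, h, s in zip(centers, heights, sigmas)],
        baseline=baseline, noise_sd=noise_sd, seed=seed)
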