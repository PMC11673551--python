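"""Core value types shared across the pipeline.

All downstream modules consume :class:`RawTrace` (scan axis, instrument
units) and :class:`Spectrum` (nucleotide axis after migration
normalization).  Both are thin, validated wrappers around numpy arrays.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GlycotraceError

#: Processing stages a Spectrum moves through, in pipeline order.
STAGES = ("normalized", "smoothed", "baseline-corrected")


@dataclass(frozen=True)
class RawTrace:
    """One fluorescence channel sampled uniformly in scan points.

    Parameters
    ----------
    values
        Fluorescence intensities in instrument units, one per scan.
    channel_tag
        Tag name and number of origin, e.g. ``"DATA,1"``, or
        ``"synthetic"`` for simulated traces.
    sample_id
        Free-text identifier of the run.
    """

    values: np.ndarray
    channel_tag: str = "synthetic"
    sample_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise GlycotraceError("trace must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise GlycotraceError("trace contains non-finite values")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class Spectrum:
    """Signal on the nucleotide axis, uniformly sampled.

    ``stage`` records where in the pipeline the intensities stand:
    ``normalized`` (resampled onto nt axis), ``smoothed`` or
    ``baseline-corrected``.
    """

    positions: np.ndarray
    intensities: np.ndarray
    stage: str = "normalized"
    sample_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if pos.shape != y.shape or pos.ndim != 1:
            raise GlycotraceError("positions and intensities must be 1-D of equal length")
        if pos.size >= 2 and not np.all(np.diff(pos) > 0):
            raise GlycotraceError("positions must be strictly ascending")
        if self.stage not in STAGES:
            raise GlycotraceError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def step(self) -> float:
        """Sampling step in nt (assumes uniform grid)."""
        return float(self.positions[1] - self.positions[0])

    def with_intensities(self, intensities: Sequence[float], stage: str) -> "Spectrum":
        return Spectrum(self.positions.copy(), np.asarray(intensities, dtype=float),
                        stage=stage, sample_id=self.sample_id)

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.positions, self.intensities]),
                   fmt="%.6f\t%.8g", header="position\tintensity", comments="")

    @classmethod
    def from_tsv(cls, path, stage: str = "baseline-corrected", sample_id: str = "") -> "Spectrum":
        arr = np.loadtxt(path, skiprows=1)
        return cls(arr[:, 0], arr[:, 1], stage=stage, sample_id=sample_id)


@dataclass
class LadderDefinition:
    """Known fragment sizes of a co-injected oligonucleotide size standard."""

    fragment_sizes: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.fragment_sizes)
        if len(sizes) < 4:
            raise GlycotraceError("ladder needs at least 4 fragments")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise GlycotraceError("fragment sizes must be strictly ascending")
        self.fragment_sizes = sizes

    def __len__(self) -> int:
        return len(self.fragment_sizes)


#: GeneScan-500 LIZ fragment sizes (nt).  The instrument standard named by
#: the protocol; overridable wherever a LadderDefinition is accepted.
LIZ500 = LadderDefinition(
    (35, 50, 75, 100, 139, 150, 160, 200, 250, 300, 340, 350, 400, 450, 490, 500),
    name="LIZ500",
)

#: Default glycomic region on the nucleotide axis, closed interval.
DEFAULT_REGION = (150.0, 350.0)

#: Default resampling step on the nucleotide axis (nt).
DEFAULT_STEP = 0.05
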