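"""End-to-end processing of one run: trace container to peak table."""
from __future__ import annotations

from pathlib import Path

from . import abif, migration, peaks, preprocess
from .config import RunConfig
from .types import RawTrace, Spectrum


def process_traces(glycan: RawTrace, ladder: RawTrace,
                   cfg: RunConfig) -> tuple[Spectrum, peaks.PeakTable]:
    """Ladder calibration, resampling, preprocessing and peak quantification.

    Returns the baseline-corrected spectrum and its peak table.
    """
    apexes = migration.call_ladder_peaks(ladder, cfg.ladder(),
                                         rel_threshold=cfg.ladder_rel_threshold)
    mm = migration.fit_migration_map(apexes, cfg.ladder(), kind=cfg.map_kind)
    spectrum = migration.to_nucleotide_axis(glycan, mm, region=cfg.region,
                                            step=cfg.step)
    corrected = preprocess.preprocess(
        spectrum,
        preprocess.SmoothingParams(cfg.smooth_sigma_points, cfg.smooth_truncation),
        preprocess.ArplsParams(cfg.arpls_lam, cfg.arpls_ratio, cfg.arpls_max_iter))
    table = peaks.build_peak_table(corrected, rel_threshold=cfg.rel_threshold,
                                   boundary_sigmas=cfg.boundary_sigmas,
                                   provenance={"config": cfg.to_dict()})
    return corrected, table


def process_file(path, cfg: RunConfig) -> tuple[Spectrum, peaks.PeakTable]:
    """Process one ABIF file (or a two-column TSV pair ``stem.glycan.tsv`` /
    ``stem.ladder.tsv`` when given the glycan TSV)."""
    path = Path(path)
    sample_id = path.stem
    if path.suffix.lower() in (".fsa", ".ab1", ".abif"):
        record = abif.read_abif(path)
        glycan, ladder = abif.extract_channels(record, cfg.glycan_tag,
                                               cfg.ladder_tag, sample_id=sample_id)
    else:
        ladder_path = path.with_name(path.name.replace(".glycan", ".ladder"))
        glycan = abif.read_trace_tsv(path, sample_id=sample_id)
        ladder = abif.read_trace_tsv(ladder_path, sample_id=sample_id)
    return process_traces(glycan, ladder, cfg)
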