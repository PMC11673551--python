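# glycotrace

Processing pipeline for CGE-LIF N-glycome electropherograms: from raw
capillary-analyzer trace files (ABIF `.fsa`/`.ab1` or plain-text) to a
quantified, structurally annotated N-glycan peak table, plus cross-replicate
reproducibility statistics and a ground-truthed synthetic run simulator.

## Pipeline

1. **abif** — parse ABIF containers, extract the APTS-labeled glycan channel
   (default tag `DATA,1`) and the LIZ-labeled oligonucleotide size-standard
   channel (default `DATA,105`); minimal writer for fixtures.
2. **migration** — call one apex per ladder fragment (default GeneScan-500
   LIZ sizes), fit a monotone scan→nucleotide map (PCHIP, linear optional),
   resample the glycan trace onto a uniform nt grid, and excise the glycomic
   region (default 150–350 nt, 0.05 nt step).
3. **preprocess** — 1-D Gaussian denoising (SD = 5 measurement points),
   then ARPLS baseline correction (λ = 1e5, ratio = 1e-6 defaults).
4. **peaks** — local maxima gated at ≥1% of the region maximum in both
   height and topological prominence; per-peak Gaussian fit; boundaries at
   ±3 fitted SDs; composite Simpson areas; max-height-normalized heights
   and total-area-normalized areas; automatic overlap flags.
5. **annotate** — banded DTW alignment to a reference spectrum; peaks
   matched where the optimal warping path connects their apexes; structure
   strings (Oxford notation) transferred from the packaged or a
   user-supplied reference table; manual overrides applied last.
6. **repro** — pairwise Pearson correlation (raw and max-height
   normalized), median lag of maximum cross-correlation, and median CV of
   normalized peak quantities across technical replicates.
7. **synthetic** — seeded scene simulator (Gaussian peaks, quadratic
   migration law, baseline drift, noise, replicate jitter, monotone warps)
   whose manifests serve as ground truth throughout the test suite.

## CLI

```sh
# generate a seeded synthetic fixture (ABIF + manifest)
glycotrace simulate --seed 7 --n-peaks 30 --out-dir fixtures/

# full pipeline: trace file -> corrected spectrum + peak table
glycotrace process fixtures/scene-7.fsa --out-dir out/

# DTW annotation against a reference spectrum + peak list
glycotrace annotate --spectrum out/scene-7.corrected.tsv \
    --peaks out/scene-7.peaks.json \
    --ref-spectrum ref.corrected.tsv --ref-peaks ref_peaks.json \
    --out out/scene-7.annotated.tsv

# replicate reproducibility report
glycotrace repro --spectra r1.corrected.tsv --spectra r2.corrected.tsv \
    --peaks r1.peaks.json --peaks r2.peaks.json --out report.tsv
```

Defaults that mirror the published protocol are marked "paper default" in
`--help`; everything is overridable per flag or via `--config` (JSON/TOML,
unknown keys rejected). Every output directory gets a `provenance.json`
sufficient to regenerate its contents bit-identically.

## Layout

```
src/glycotrace/
  abif.py        ABIF container I/O + plain-text fallback
  migration.py   ladder calling, scan->nt mapping, region excision
  preprocess.py  Gaussian smoothing, ARPLS baseline
  peaks.py       detection, Gaussian fits, Simpson areas, normalization
  annotate.py    DTW alignment, peak matching, annotation transfer
  repro.py       replicate synchrony & variability statistics
  synthetic.py   ground-truthed run simulator
  pipeline.py    end-to-end composition
  cli.py         process / annotate / repro / simulate
  config.py      validated run configuration
  data/          packaged reference annotations + manual overrides
```
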