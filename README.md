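# linkmap

Genetic linkage maps of meiotic recombination built from SGA (synthetic
genetic array) colony-size screens, with recombination hotspot calling,
pericentric-linkage analysis and chromatin-track summaries — plus a synthetic
data generator with known ground truth so the whole pipeline is testable
offline.

## What it does

- **Distance estimation** (`linkmap.distances`): the recombinant fraction of a
  double mutant is estimated from normalized colony sizes,
  `R = 0.5 · f_ij / (f_i · f_j)`, converted to a genetic distance under a
  Poisson (Haldane) crossover model `m = −ln(1 − 2R)`, `M = m/2` Morgans, and
  reported in SGA-GD units capped at 50 (50 SGA-GD = independent segregation).
  A linear mode (`100·R`) is available for sensitivity analysis. Screens are
  re-anchored so the query-self residual colony maps to distance 0; replicate
  screens are averaged on the R scale.
- **Linkage maps** (`linkmap.linkage`): per-chromosome bin × bin (default
  5 kb) matrices of mean distances, query/array direction consolidation
  `G' = (G + Gᵀ)/2` (with per-chromosome exclusions), marker-region masks, and
  the per-chromosome total-genetic-length linear fit `aL + b`.
- **Hotspots** (`linkmap.hotspots`): per-position recombination rate
  (SGA-GD/kb, 25-kb window), moving-average smoothing, local-maximum hotspot
  calls above the genome average, and precision/sensitivity comparison against
  reference hotspot sets at a bp tolerance.
- **Pericentric analysis** (`linkmap.pericentric`): cis/trans classification
  of same-chromosome gene pairs against the centromere, linkage extents from
  distance-binned pair averages, hotspot- and genetic-map-based centromere
  gaps, and Pearson correlations of extents with chromosome size (with
  chromosome exclusion sets).
- **Chromatin profiles** (`linkmap.chromatin`): DSB-repressed region widths
  from cumulative Spo11-oligo walks (threshold 3000), asymmetry scores, and
  cohesin (Rec8/Mcd1) centromere-peak widths above the global genomic average
  after 25-position smoothing.
- **Synthetic data** (`linkmap.simulate`): crossover-rate maps with hotspots
  and (optionally size-coupled) pericentric suppression, colony-size screens
  generated through the same Poisson model the estimator inverts, plus Spo11
  count tracks, cohesin binding tracks, hotspot lists and a classical-style
  genetic map, all deterministic in the seed with a `truth.json` sidecar.
- **I/O** (`linkmap.io_formats`): tab-delimited screen matrices (header row of
  array IDs, first column query IDs, duplicate rows = replicates, empty cell =
  missing), annotation tables (6-column tab dialect or a GFF3 subset),
  bedGraph / two-column tracks, BED-like site lists and locus/cM tables.
  Coordinates are 1-based inclusive internally; bedGraph is converted at the
  reader boundary.

## CLI

```sh
# generate a synthetic dataset with ground truth
linkmap simulate --seed 1 --out data/ --chromosomes 16 --genes 40 \
    --hotspots 3 --pericentric-radius-kb 10 --size-coupling 15

# build linkage maps, call hotspots, run the pericentric/chromatin summaries
linkmap build      --annotation data/annotation.tsv --screens data/screens --out out/
linkmap hotspots   --annotation data/annotation.tsv --screens data/screens \
                   --reference data/hotspots.bed --out out/
linkmap pericentric --annotation data/annotation.tsv --screens data/screens --out out/
linkmap chromatin  --annotation data/annotation.tsv --tracks data/tracks --out out/

# or everything from a YAML config (keys = PipelineConfig fields)
linkmap all --config pipeline.yaml --set bin_size=5000
```

Outputs land under `--out`: consolidated matrices (`maps/*.gprime.tsv`),
`hotspots.bed`, `pericentric.tsv`, `size_correlations.tsv`,
`dsb_regions.tsv`, `rec8_peaks.tsv` / `mcd1_peaks.tsv`, a `config_echo.yaml`
recording every default, and `run.log`. Exit codes: 0 success, 2 config
error, 3 data error.

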