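# atcq — automated temporal tracking of cellular quiescence

`atcq` analyses (and simulates) two-channel time-lapse movies of cells
carrying a dual cell-cycle reporter: the G0 sensor **mVenus-p27K⁻** (a
fluorescent fusion to a CDK-binding-defective p27 mutant, accumulating in
quiescence) and the G1 sensor **mCherry-hCdt1(30/120)** from the FUCCI
system. It is aimed at quantitative cell biologists studying the
proliferation–quiescence decision — in particular *spontaneous* quiescence
(G0 entry under full-serum, pro-proliferative conditions) and *asynchronous*
decisions in daughter-cell pairs, where one daughter of a mitosis enters G1
while its sibling remains in G0. Both phenomena matter for tumour-dormancy
biology, e.g. in PC3 prostate cancer cells.

The core operational definitions:

* after mitosis a cell turns Venus on, then Cherry (~2–6 h later),
  becoming **double positive (DP)** — the G0 decision window;
* a DP phase **prolonged beyond 14 h** is scored as spontaneous G0;
* a DP phase of **more than 4 h** that ends in G1 entry (Venus
  degradation) is transient G0;
* a daughter pair is **synchronous G0** (both remain DP), **synchronous
  G1** (both enter G1 within 1 h of each other) or **asynchronous**
  otherwise; the G1-entry difference Δ quantifies the asynchrony.

The package provides, as composable library modules and a CLI:

* `atcq.simulate` / `atcq.render` — a generative model of per-cell reporter
  kinetics, lineages and motility under named condition profiles
  (PC3 cell-hotel / plate, NIH/3T3 full/low serum, serum-free cohorts,
  dormancy-signal treatment presets), rendered into noisy 16-bit TIFF
  movies with exportable ground truth;
* `atcq.segmentation` — per-frame spot detection and intensity measurement;
* `atcq.tracking` — Hungarian linking, gap closing, division detection and
  lineage trees;
* `atcq.classification` — trace binarization, reporter-state segmentation
  (DN / V_ONLY / DP / C_ONLY) and quiescence calls;
* `atcq.lineage` — daughter-pair scoring, population summaries,
  Mann-Whitney dwell-time comparisons.

See `docs/methods.md` for the model, parameter meanings and defaults.

## Worked example

Simulate a small PC3 "cell hotel" field (10 founder cells, 72 h at 0.5 h
per frame) and analyse the rendered movie blind:

```sh
$ atcq simulate --profile pc3_hotel --n 10 --seed 7 --out sim
wrote sim/movie.tif (144 frames)
  DIRECT_G1: 15
  SPONT_G0: 17
  TRANSIENT_G0_TO_G1: 16

$ atcq run --movie sim/movie.tif --out analysis
2721 detections | 48 tracks | 47 calls | 19 pairs (1 tracks below min length dropped)
spontaneous G0: 11/28 (39.3%), async pairs: 38.5%
```

The simulation printed the ground-truth fate counts (48 cells arise from
the 10 founders; 17 are spontaneously quiescent). The analysis — which sees
only the pixels — detected, tracked and classified the cells:
`analysis/summary.yaml` reports 28 classifiable post-mitotic cells with at
least 24 h of follow-up, of which 11 (39.3 %) exceeded the 14 h
double-positive threshold, and 19 detected divisions of which 13 daughter
pairs were scorable (5 synchronous G0, 3 synchronous G1, 5 asynchronous).
At this field size the percentages carry sampling error of ±10 points or
so; the recovery experiments below pool many fields. Every intermediate
table (detections, tracks, lineage, per-cell calls, pairs) is written
alongside, and each stage can be rerun independently
(`atcq segment|track|classify|pairs|summarize`); `atcq show-config` prints
every tunable default.

The same analysis is available as a library:

```python
import atcq
profile = atcq.get_profile("pc3_hotel")
spec = atcq.MovieSpec()
lineage = atcq.simulate_population(profile, 10, spec, seed=7)
stack, truth = atcq.render_movie(lineage, spec, seed=8, profile=profile)
result = atcq.analyze_stack(stack, spec.frame_interval_h)
print(result.summary.percent_spontaneous_g0)
```

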