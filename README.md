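# divtrap

Automated division tracking and replicative-lifespan analysis for
trap-based time-lapse microscopy of budding yeast — from raw fields of
view to per-frame cell-state classification, division counting,
lifespan reconstruction, senescence-entry-point (SEP) detection,
semantic segmentation with fluorescence quantification, and population
survival statistics. A synthetic trap-movie generator with complete
groundtruth makes the whole pipeline trainable and testable on a single
CPU in minutes.

## Pipeline

1. **`divtrap.trapsynth`** — synthetic cell histories (lognormal cycle
   durations, per-generation death hazard, post-SEP slowdown), rendered
   60×60-px trap movies with brightfield + fluorescence channels,
   per-pixel masks, field-of-view grids, and controlled label noise.
2. **`divtrap.roi`** — trap detection in fields of view by normalized
   cross-correlation with non-maximum suppression; fixed-box extraction
   of per-trap movies; z-stack → RGB composition.
3. **`divtrap.classify`** — six-state per-frame classification
   (`unbud, small, large, dead, clog, empty`) with a small conv net,
   feature extraction, and a bidirectional LSTM sequence classifier;
   plus the post-processing variant that ignores isolated `dead` frames.
   The neural nets are a compact numpy implementation (manual backprop,
   Adam) sized for desk-scale training — no GPU or deep-learning
   framework required.
4. **`divtrap.lifespan`** — budding-event detection from label
   oscillations, the four stop rules (death, >10 h division arrest,
   clog, empty), censoring, trajectory alignment, death-fraction traces.
5. **`divtrap.sep`** — pre/post-SEP sequence classification from class
   probabilities, reduced to a single changepoint; rule-based oracle.
6. **`divtrap.segment`** — tiny encoder/decoder semantic segmentation
   (background/mother/other and background/nucleus), F1-maximizing
   threshold selection, central-component mother selection, area and
   background-subtracted fluorescence quantification, cross-validation.
7. **`divtrap.survival`** — Kaplan–Meier with Greenwood 95% bands,
   discrete hazard with bootstrap SD, log-rank and rank-sum tests.
8. **`divtrap.benchmarks`** — confusion matrices, per-class
   precision/recall/F1, tolerance-based optimal event pairing,
   correlation metrics, whole-pipeline reports.
9. **`divtrap.deskbench`** — the reproducible desk-scale end-to-end
   benchmark protocols used by the test suite.

## CLI

All stages are exposed as subcommands that read/write plain files
(multi-page TIFF movies, PNG masks, CSV tables, JSON-lines records) and
drop a run manifest beside their outputs:

```bash
divtrap simulate    --set simulate.n_cells=50 --out runs/sim
divtrap train-frame --data runs/sim --out runs/models
divtrap train-seq   --data runs/sim --cnn runs/models --out runs/models
divtrap classify    --data runs/sim --cnn runs/models --lstm runs/models --out runs/pred
divtrap lifespan    --labels runs/pred/labels_pred.csv --out runs/lifespan
divtrap survival    --records runs/lifespan/records.jsonl --out runs/surv
divtrap benchmark   --truth runs/truth.jsonl --pred runs/lifespan/records.jsonl --out runs/bench
```

Configuration is a YAML tree (see `divtrap/config.py` for the schema
and defaults) overridable per key with `--set a.b.c=value`. Every
stochastic step takes an explicit integer seed; identical seeds give
byte-identical outputs.

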