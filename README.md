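# pcbc

Hierarchical predictive-coding networks with divisive input modulation
(DIM) for visual recognition. Two explaining-away stages are stacked:
a matching stage whose prediction neurons infer which dictionary
elements (mean training patches) are present in an image, and a voting
stage that pools those responses into class decisions or — run
convolutionally with one unit per pixel — into Hough-style object
location hypotheses.

## What is inside

| Module | Purpose |
| --- | --- |
| `pcbc.core` | Matrix-form DIM dynamics: `r = Vy`, `e = x ⊘ max(ε₂, r)`, `y ← max(ε₁, y) ⊙ We`; steady-state solving and generalized-KL diagnostics |
| `pcbc.conv` | Convolutional DIM with spatially replicated prediction neurons (zero-padded cross-correlation, interchangeable with the matrix form) |
| `pcbc.preprocess` | ON/OFF local-contrast channels (Gaussian local mean, mirror padding, joint [0,1] rescale) and ZMNCC patch similarity |
| `pcbc.dictionary` | Whole-image / Harris-keypoint patch extraction, complete-linkage agglomerative clustering (κ threshold, λ minimum cluster size), stage-1 weight assembly |
| `pcbc.hierarchy` | Stage-2 learning: per-class summed-response weights, or per-pixel voting kernels smoothed across space (and scale) |
| `pcbc.recognize` | Classification (argmax), per-element non-maximum suppression, supra-floor region finding, population-vector decoding, detection |
| `pcbc.metrics` | Greedy detection/ground-truth matching, precision–recall curves, f score, equal error rate, classification error |
| `pcbc.synthetic` | Deterministic procedural glyph datasets and cluttered annotated scenes (no downloads needed anywhere) |
| `pcbc.cli` / `pcbc.config` / `pcbc.io` | `pcbc` command-line pipeline, YAML config with task presets, PNG/IDX/annotation/model-archive I/O |

## CLI

```bash
# synthetic 10-class glyph classification, end to end
pcbc make-data --config cfg.yaml --out data/
pcbc train     --config cfg.yaml --data data/ --out model.npz
pcbc classify  --config cfg.yaml --model model.npz --data data/ --out out/
pcbc evaluate  --predictions out/predictions.tsv \
               --truth data/test/labels.tsv --out out/eval

# detection on synthetic scenes (task: detect in the config)
pcbc make-data --config det.yaml --out det_data/
pcbc train     --config det.yaml --data det_data/ --out det_model.npz
pcbc detect    --config det.yaml --model det_model.npz --data det_data/ --out det_out/
pcbc evaluate  --detections det_out/detections.csv \
               --truth det_data/annotations.txt --out det_out/eval
```

Configs are flat YAML mappings of `pcbc.config.PipelineConfig` fields;
`PipelineConfig.digits() / .faces(delta) / .cars()` carry the published
per-task defaults (κ ∈ {0.85, 0.9, 0.4}, λ ∈ {0, 12}, σ ∈ {4, 2.5√δ,
3.5}, 50 iterations, 0.001 response floor, 2-px stage-2 smoothing).
Every command appends its full parameter set and seed to
`run_log.jsonl` next to its outputs; identical config + seed reproduce
outputs bit for bit.

An IDX reader (`pcbc.io.read_idx_dataset`) is included for standard
digit archives; nothing in the test suite downloads anything.

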