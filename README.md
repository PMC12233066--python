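# morphoscreen

Label-free, morphology-based phenotypic analysis of confluent cell
cultures from phase-contrast micrographs, with a synthetic image generator
standing in for the microscope.

The pipeline mirrors an image-based drug-screening workflow for muscle-cell
disease models:

1. **synth** — renders phase-contrast-like fields of elongated capsule
   cells (dark bodies, bright halo rims, illumination gradient, sensor
   noise) with pixel-aligned ground-truth instance masks and true shape
   parameters, so every downstream stage is testable without any data
   download.
2. **segment** — a seven-stage label-free segmentation: background
   adjustment, texture enhancement (local SD), binarization (Otsu),
   small-object removal, closing, hole filling, and frame-touching object
   removal, followed by connected-component labeling. Touching cells are
   deliberately not split; population statistics absorb the merges.
3. **morphometry** — six descriptors per cell: area, perimeter, length,
   width, length-to-width ratio, compactness (4πA/P², ≤ 1). Length/width
   are the sides of the minimum-area oriented bounding rectangle; the
   perimeter estimate is the larger of Crofton-4 and the convex-hull
   polygon perimeter (orientation-robust).
4. **profiling** — replicate wells are pooled (wells with < 200 cells
   rejected, > 5000 subsampled), then 10 bootstrap samples of 200 cells
   are drawn per condition; each sample becomes a 12-feature
   **morphological profile** (mean and SD of each descriptor).
5. **analyze** — feature z-scoring, PCA (deterministic signs),
   hierarchical clustering with correlation distance and average (UPGMA)
   linkage, optional seeded UMAP, plus a feature-correlation report.
6. **classify** — a drug-effect-category random forest: 50 bootstrap
   training datasets of 1000 cells per category (six categories by
   default), grouped cross-validation that holds out whole
   bootstrap-source groups, per-category confusion matrix and normalized
   feature importances.

Everything is deterministic for a fixed seed: one global seed derives
per-stage streams, and rerunning a pipeline reproduces all CSV outputs
bit-identically.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (structural
fidelity, analytic morphometry oracles, segmentation ground-truth
benchmarks, profiling statistics, a brute-force UPGMA oracle, classifier
recovery, and end-to-end determinism).

## CLI

```bash
# full pipeline on the bundled two-condition demo (≈15 s)
morphoscreen run --out out/demo --seed 42

# or stage by stage
morphoscreen simulate --config spec.yaml --out imgs --seed 1 --replicates 3
morphoscreen segment  --config seg.yaml --in imgs --out masks
morphoscreen measure  --masks masks --calibration 2.0 --condition a --out cells.csv
morphoscreen profile  --cells cells.csv --config prof.yaml --out profiles.csv
morphoscreen analyze  --profiles profiles.csv --out analysis [--umap]
morphoscreen train    --profiles profiles.csv --out model.pkl
morphoscreen cv       --profiles profiles.csv --out cvdir
morphoscreen predict  --model model.pkl --profiles profiles.csv --out pred.csv
```

Exit codes: 0 ok, 1 user error, 2 internal error. `run` writes a
`manifest.json` tying every output to config hashes, seeds and stage
timings. Configuration is strict YAML (unknown keys are rejected); see
`src/morphoscreen/data/demo.yaml` for a complete example.

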