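# glossprobe

A toolkit for modeling how specular highlights are identified in images of
glossy, textured surfaces. It covers the full pipeline:

- **stimuli** — a procedural renderer for undulating glossy surfaces lit by
  a square area source, producing exact per-pixel intrinsic components
  (diffuse shading, ground-truth specular map, texture) plus geometry
  buffers. 15 conditions per scene: plain, 12 procedural textures (Voronoi,
  marble, checker at four spatial scales), and two "false highlight"
  conditions that reuse another scene's specular map as texture. Roughly 3%
  of pixels carry specular reflection under the default calibration.
- **threshold** — the baseline predictor: a single learned global intensity
  threshold with a monotone squashing above it, fitted by per-pixel binary
  cross-entropy.
- **probes** — pixel categorization by agreement between binarized ground
  truth and the threshold model (categories a–d), and argmax probe-pixel
  selection: the default design yields 720 probes on 240 images
  (120 four-category images + 120 two-category images).
- **observers** — a reader for real response CSVs plus a simulator of
  idiosyncratic binary observers (logistic evidence mixture with lapse,
  per-observer bias, and weight jitter), and the split-half / intra- vs
  inter-rater consistency statistics.
- **network** — a 7-scale, 4-tier convolutional architecture (177 filters,
  61,233 trainable parameters) implemented in pure NumPy with hand-written
  backprop and an Adam trainer; predictions can be masked by a 98-bit
  inter-tier connection on/off vector without touching weights.
- **pruning** — a genetic algorithm over the 98-bit masks maximizing the
  Pearson correlation between masked-network probe predictions and mean
  observer responses (10 elites + 10 mutated elites + 80 fitness-weighted
  crossover children per generation), plus rank-sum candidate selection.
- **evaluation** — probe correlations, pixel-group prediction means,
  decision-rate curves, the rotated-highlight RMSE test, and the
  uniform-noise RMSE baseline (analytic value sqrt(1/6) ≈ 0.408).
- **rsa** — a 34-predictor bank in 7 categories, first/second-order RDMs,
  metric MDS embedding of units, and single-filter lesion analysis.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the acceptance criteria, including a
reduced-scale end-to-end run (64×64 stimuli, a 60-scene catalog, a short
training schedule, one small GA run) shared by its sub-tests through a
session fixture. The full suite takes roughly 10–20 minutes on one CPU.

## CLI

```sh
glossprobe render --scenes 40 --size 128 --seed 1 --out catalog/
glossprobe fit-threshold --scenes 40 --size 128 --seed 1 --out model.json
glossprobe select-probes --scenes 60 --size 128 --seed 1 \
    --threshold-json model.json --n-four 120 --n-two 120 --out probes.csv
glossprobe simulate-observers --scenes 60 --size 128 --seed 1 \
    --threshold-json model.json --probes-csv probes.csv --out responses.csv
glossprobe train --scenes 40 --size 64 --preset desk --seed 1 --out net.npz
glossprobe prune --ckpt net.npz --threshold-json model.json \
    --probes-csv probes.csv --responses-csv responses.csv \
    --runs 1 --generations 10 --out ga.jsonl
glossprobe analyze --what noise-baseline --seed 1 --out noise.json
```

A real response CSV with columns
`observer_id,image_id,row,col,category,response` can be supplied anywhere
the simulated one is used.

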