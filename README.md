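# swpnet

Frequency-specific weighted brain-network analysis, from region-of-interest
(ROI) time series to small-world propensity (SWP) curves:

1. **synth** — seeded multi-subject ROI time-series generator with a planted,
   band-specific envelope-coupling backbone on a known graph (plus toy graph
   and multi-subject adjacency fixtures).
2. **spectral** — analytic time-frequency decomposition with Generalized
   Morse Wavelets on a 23-carrier quarter-octave grid (2^0.5 … 2^6 Hz).
3. **connectivity** — pairwise power-envelope orthogonalization, log-power
   Pearson correlation, Fisher-z adjacency matrices, and cross-subject
   consistency thresholding (coefficient-of-variation edge ranking) over a
   1–100 % density sweep.
4. **metrics** — node strength, Onnela weighted clustering, weighted shortest
   paths, lattice/random equivalent null models, SWP and the classic σ
   small-worldness index, swept across density levels.
5. **stats** — repeated-measures ANOVA with Mauchly / Greenhouse–Geisser
   handling, within-subject Tukey HSD, Bonferroni thresholds, functional
   (curve-level) permutation testing, and per-density paired PRE/POST
   contrasts.
6. **pipeline / CLI** — a YAML-configured, seeded, manifest-writing
   orchestration of all stages.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed-form
anchors, oracle equivalences on small graphs, Watts–Strogatz vs Erdős–Rényi
recovery, planted frequency-specific SWP recovery with FDA permutation
testing, and type-I-error calibration of the permutation tests).

## CLI

```sh
swpnet synth   --config synth.yaml --out ts.h5
swpnet connect --in ts.h5 --out fc.h5
swpnet metrics --fc fc.h5 --out curves.csv --seed 1 --nreps 10
swpnet stats   --curves curves.csv --carrier-a 8 --carrier-b 64 --out fda.json
swpnet run     --config run.yaml          # full pipeline + manifest.json
```

A run config looks like:

```yaml
out_dir: runs/demo
seed: 5
synth:
  n_subjects: 12
  n_nodes: 20
  fs: 256.0
  duration: 60.0
  coupling_band_hz: 8.0
  backbone: {n: 20, k: 4, p_rewire: 0.1}
grid: {min_exp: 0.5, max_exp: 6.0, step: 0.25}
density: {min: 1, max: 100, step: 1}
metrics: {n_reps: 10}
stats: {contrasts: [[10, 22]], n_perm: 1000}
```

Omit the `synth` block and set `input_h5` to analyse recorded data instead
(HDF5 layout `/subjects/<id>/data` with `fs` and `node_labels` attributes,
or per-subject CSVs via the Python API).

## Notes on conventions

- Negative Fisher-z edge weights are rectified to 0 before graph analysis.
- The path-length deviation in SWP uses `(L_obs − L_rand)` in the numerator;
  a warning documents this choice on first use.
- SWP values on thresholded graphs with > 5 % unreachable node pairs are
  flagged unreliable in the curve output rather than dropped.
- Morse defaults: gamma 3, beta 25/3 (time-bandwidth product 5); both are
  exposed in config and the CLI.
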