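# corticomm

Analysis toolkit for trial-structured, multi-region cortical population
recordings from a delayed-response task with mid-delay distractors. The
package bundles, as tested reusable components:

- **`corticomm.synthio`** — session data model (activity matrix, region
  labels, trial table), HDF5/CSV session I/O, task-epoch frame windows, and a
  synthetic cohort generator emulating two cohorts: a `control` preset and a
  `reduced_connectivity` preset with weaker inter-regional transmission,
  lower cross-target channel overlap, within-trial channel drift, and higher
  distractor susceptibility.
- **`corticomm.behavior`** — task performance per distractor condition and
  logistic learning-curve fitting.
- **`corticomm.resampling`** — one-tailed bootstrap group comparison
  (difference of means, plus-one correction, half-tie counting) and
  Benjamini-Hochberg FDR.
- **`corticomm.selectivity`** — per-neuron epoch selectivity (two-tailed
  rank-sum, P < 0.01, regions with < 10 neurons excluded), trial-type
  selectivity profiles, and distractor-mediated modulation.
- **`corticomm.connectivity`** — ITI and trial-window pairwise correlation
  matrices, activity-matched cross-cohort subsampling, and cross-validated
  ridge population prediction (10-neuron samples, 20 repeats).
- **`corticomm.subspace`** — ridge regression with 10-fold CV, reduced-rank
  regression (predictive dimensions `B_bar = B_ridge V`), performance-by-rank
  curves with the one-SEM rank rule, principal-angle subspace similarity
  (cosine of the largest angle), spatial/temporal degeneracy, and ablation of
  predictive dimensions (`M = B_bar' Sigma`, projection onto its null space).
- **`corticomm.rnn`** — FORCE-trained recurrent network simulator (Euler
  integration, sigmoid units, recursive-least-squares training), target
  construction via the inverse sigmoid, choice-axis projection, decision
  switch detection, synaptic-strength summaries, and distractor /
  weight-ablation experiments.
- **`corticomm.decoding`** — pseudo-mouse construction (fixed per-region cell
  counts stacked across sessions on canonical trial slots), pluggable 3-d
  embedding backends (deterministic supervised linear projection by default;
  optional contrastive backend if the `cebra` package is installed),
  cosine-kNN decoding, relative accuracy around distractors, and per-region
  contribution via mean-substitution ablation.
- **`corticomm.pipeline` / CLI** — configuration-driven orchestration with
  per-stage CSV outputs, a JSON contrast summary (direction + one-tailed
  bootstrap p per metric), and per-stage timing logs.

## CLI

```bash
corticomm generate --seed 1 --out results/        # write synthetic cohorts
corticomm analyze --seed 1 --out results/         # run all analysis stages
corticomm analyze --stages behavior,connectivity  # subset of stages
corticomm rnn-train --units 64 --epochs 300 --out results/
corticomm rnn-perturb --model-path results/rnn_model.h5 --levels 0,0.1,0.2
corticomm report --out results/                   # print contrast summary
```

`analyze` accepts a YAML config (`--config run.yaml`) mirroring
`corticomm.pipeline.RunConfig` (cohort sizes, stage toggles, seeds,
bootstrap settings).

## Data

Real sessions are expected as HDF5 containers (datasets `/activity`
(neurons x frames, z-scored), `/region_of`, `/frame_rate`, trial table under
`/trials` mirrored as CSV) with eight region labels
(ALM, M1a, M1p, M2, S1fl, vS1, RSC, PPC) at ~9.35 Hz. `synthio.read_session`
documents the expected layout; the synthetic generator produces sessions in
exactly this form.
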