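# dyadsync

Dual-EEG ("hyperscanning") inter-brain synchrony analysis: from
two-person multichannel recordings to theta-band weighted-phase-lag-index
(wPLI) connectivity matrices, mass-univariate max-F permutation inference,
surrogate-pair nulls, and behavior/connectivity change-score coupling — plus
a synthetic dyad generator with known ground truth so the whole pipeline is
testable without any recordings.

## What's inside

| module                 | role |
|------------------------|------|
| `dyadsync.synth`       | synthetic two-person EEG (coupled phase oscillators over 1/f noise), jump/ocular artifact injection with ground-truth metadata, behavioral event-log simulation |
| `dyadsync.preprocess`  | zero-phase FIR band-pass, 1-s/500-ms overlapping epochs, subject-wise peak-to-peak rejection with automatic threshold search, template-correlation ICA cleanup, dyad duration/epoch matching |
| `dyadsync.interbrain`  | Hann-taper epoch cross-spectra at integer-Hz band bins, wPLI and PLV over a configurable adult × infant pair grid (default 6 × 6 = 36 pairs) |
| `dyadsync.permstats`   | mass-univariate repeated-measures ANOVA, max-F permutation with FWER control (exhaustive sign-flip enumeration for small n), pseudo-dyad surrogate nulls, change scores, 3-SD exclusion, paired t / Pearson |
| `dyadsync.behavior`    | gaze/affect microcoding proportions (visual attention, positive arousal) and the 7-item CIB safety composite |
| `dyadsync.pipeline` / `dyadsync.cli` | config-driven end-to-end runs with provenance logging |
| `dyadsync.io`          | columnar TSV + JSON sidecar, 16-bit EDF (self-contained codec), event-log CSV, connectivity TSV, stats JSON |

## CLI

```sh
# write synthetic recordings + behavior logs (TSV or EDF)
dyadsync simulate --scenario c4p8-contrast --n-dyads 10 --duration 180 --out simulated/

# full contrast: preprocess -> connectivity -> permutation stats
dyadsync stats --config run.yaml

# change-score correlation between connectivity and visual attention
dyadsync brain-behavior --config run.yaml

# everything
dyadsync run-all --config run.yaml
```

A minimal `run.yaml`:

```yaml
scenario: c4p8-contrast      # or `manifest: [...]` listing recording files
n_dyads: 10
conditions: [blank, BO]
band: {name: theta, fmin: 4, fmax: 7}
n_perm: 1000
alpha: 0.05
seed: 1
out_dir: results/run1
```

Outputs: `connectivity.tsv` (long format), `stats.json` (+ a
`.null_max_F.tsv` sidecar with the permutation null), `run_log.json`
(config hash, seeds, per-dyad epoch counts), `brain_behavior.json`.
Exit codes distinguish configuration (2), data (3) and stage (4) errors.

## Notes on method choices

- wPLI per pair and bin is `|Σ_e Im S_e| / Σ_e |Im S_e|` (0/0 := 0), band
  value is the unweighted mean across integer-Hz bins; the standard, not
  the debiased-square, estimator.
- Permutation p-values use the add-one convention `(1 + count)/(1 + n_perm)`
  for sampled permutations and exact proportions under exhaustive
  enumeration (`2^n` sign assignments when `2^n <= exhaustive_limit`).
- Epoch rejection replaces an opaque optimizer with a transparent
  subject-wise grid search over log-spaced peak-to-peak thresholds
  (reject-only, no channel repair); the chosen threshold and rejection
  fraction are reported.
- Ocular cleanup is template-correlation over a seeded FastICA
  decomposition; components with |r| ≥ 0.8 against the template are zeroed.
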