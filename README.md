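# popcode

Analysis pipeline for motor-cortical population activity recorded during
unimanual (ipsilateral / contralateral) and bimanual food handling, plus a
synthetic data generator that produces kinematics, ethogram ground truth and
Poisson spike trains with controllable laterality/manuality dependence, so
every stage has a known-answer test.

## What it does

- **Behavior**: hand–nose / hand–hand distance variables; three-state-per-hand
  segmentation combined into the seven-state ethogram; sigmoid (transport-to-
  mouth) and exponential (lowering-from-mouth) transition fits; condition-
  labeled transport events with exclusion rules (uni-to-bimanual, hand swaps,
  armbar starts).
- **Event-aligned activity**: 20 ms PETHs over ±1 s with cross-cycle
  oromanual masking, sham-event bootstrap significance (1000 draws,
  p < 0.001), per-trial baseline subtraction, z-scoring, 8-way responsiveness
  categories.
- **Preferences**: response areas in the 100 ms peak window, preference
  indices (A−B)/(A+B), Mann-Whitney strong-preference 3×3 grid, KS and
  earth-mover's-distance permutation tests with hierarchical
  (trials → units → probes → days → mice) averaging.
- **Population geometry**: soft-normalized PCA, participation ratio, first
  principal angles, top-10 alignment index, and finite-data bootstrap
  predictions under invariant and orthogonal encoding.
- **Correlation structure**: 5 ms pairwise correlation matrices per condition
  and between-condition similarity.
- **Decoding**: ridge lagged-window decoders (200 ms before to 50 ms after,
  5 ms bins), contiguous tuning/training/testing thirds, cross-body and
  uni-to-bimanual generalization (ΔR²/R²₀), and perfect/no-generalization
  bootstrap nulls.

## CLI

All stages share `--config` (YAML overriding the defaults in
`popcode/config.py`), `--seed`, `--out-dir`, `--log-level`, and operate on a
single bundle directory:

```sh
popcode simulate --scenario flM1_like --seed 7 --out-dir run/
popcode ethogram --out-dir run/
popcode peth     --out-dir run/ --seed 7
popcode prefs    --out-dir run/
popcode geometry --out-dir run/ --seed 7
popcode corr     --out-dir run/
popcode decode   --out-dir run/ --seed 7
popcode report   --out-dir run/
```

Scenarios: `flM1_like` (transient, laterality-dependent), `LOM_like`
(sustained, invariant), `null` (no event-locked modulation), `linear_decode`
(linear lagged kinematic encoding with stored true filter taps).

File formats are plain CSV/JSON (`spikes.csv` + `spikes.json` sidecar,
`kinematics.csv`, `events.csv`); stage outputs are CSV/JSON plus HDF5 for
array-heavy intermediates (`peth.h5`, `correlations.h5`).

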