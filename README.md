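# oculofatigue

A toolkit for oculometrics-based fatigue monitoring during computer
work: from raw gaze/pupil sample streams (nominal 360 Hz) to ocular
events, segment-level oculometric features, a label-noise-robust
decision-tree-ensemble fatigue classifier evaluated person-wise, and a
micro-break trigger state machine.  A synthetic gaze generator with
full ground truth makes the entire chain testable offline.

## Components

| module | role |
| --- | --- |
| `oculofatigue.io_gaze` | CSV formats for gaze streams, annotations and segment feature tables; `GazeRecording`, `SessionMeta`, `LabeledDataset` |
| `oculofatigue.event_detection` | visual-angle conversion, Savitzky–Golay kinematics, blink detection from zero-pupil runs, adaptive-threshold saccade detection, fixation segmentation, pupil preprocessing |
| `oculofatigue.oculometrics` | the 32 segment-level features (blink, pupil, fixation, saccade families) with explicit missing-value semantics |
| `oculofatigue.fatigue_model` | KSS dichotomization (fatigued iff KSS ≥ 5), leave-one-person-out evaluation, Youden's J, SFFS feature selection, permutation test |
| `oculofatigue.boosting` | native noise-robust boosting of depth-limited trees (error-goal / max-margin weight schedule) |
| `oculofatigue.biofeedback` | session state machine: 180 cycles, 20-cycle segments, 5-s KSS pauses, 25-s micro-breaks, manual and automatic trigger paths |
| `oculofatigue.synthgen` | synthetic participants, rendered gaze segments and fast-path feature datasets with ground truth |
| `oculofatigue.cli` | `oculofatigue` command with `extract`, `train`, `evaluate`, `permtest`, `simulate`, `synth` subcommands |

## CLI quick start

```sh
# generate a synthetic 38x12 feature dataset with ground truth
oculofatigue --seed 1 synth dataset --participants 38 --segments 12 \
    --out oldset_synth.csv --truth truth.json

# train the deployed-configuration ensemble on the selected features
oculofatigue --seed 1 train --features oldset_synth.csv --out model.bin

# person-wise cross-validated evaluation (report + ROC table)
oculofatigue --seed 1 evaluate --features oldset_synth.csv --out report

# chance-level permutation test
oculofatigue --seed 1 permtest --features oldset_synth.csv --out perm.json

# simulate a full automatic biofeedback session
oculofatigue --seed 1 simulate --mode automatic --model model.bin --out session.json
```

Configuration (detector constants, feature thresholds, model
hyperparameters) lives in one YAML file passed via `--config`; every
output embeds the SHA-256 hash of the effective configuration.

## File formats

* gaze samples — CSV `time_s, gaze_x_cm, gaze_y_cm, pupil_mm`
  (coordinates in cm relative to screen center; pupil 0 = closed eye);
* annotations — CSV `label, start_s, end_s`, half-open intervals with
  labels `cycle:<k>`, `kss_pause`, `micro_break`;
* feature tables — CSV with one row per segment: `participant_id,
  segment_index`, the 32 feature mnemonics, `age, sex, kss, label`.
  The label column is always recomputed from `kss` on load.
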