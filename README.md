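# mmrlink

Linking source-level MEG mismatch responses (MMR) to behavioral phonetic
discrimination (d′), as a tested, reusable pipeline:

- **synthetic** — cohort generator: oddball trial sequences, SDT-driven AX
  behavior, and label-level free-orientation evoked responses with a planted
  group MMR difference and a one-group-only log-MMR → d′ coupling.
- **behavior** — AX table scoring into hit/false-alarm rates and d′
  (1/(2N) or log-linear edge correction).
- **mmr** — vector difference-wave magnitudes per label/time, vertex-to-label
  averaging, ROI/time-window means, log transform.
- **group_inference** — two-sample t tests (pooled/Welch), Cohen's d, and a
  spatiotemporal TFCE permutation test with max-statistic FWER control.
- **neurolink** — ROI OLS of d′ on log MMR × group with simple slopes, and
  time-resolved leave-one-out linear-SVR decoding against a pooled
  permutation null (99th-percentile criterion), final model and per-label
  contribution map.
- **cli/io** — TSV + HDF5 containers, config parsing, and the end-to-end
  `run-all` pipeline with a deterministic run manifest.

## CLI

All stages hang off one umbrella command:

```sh
mmrlink simulate       --config run.ini --out cohort/ --seed 1
mmrlink score-behavior --in cohort/behavior.tsv --out cohort/scores.tsv
mmrlink compute-mmr    --in cohort/ --out cohort/mmr.h5
mmrlink cluster-test   --mmr cohort/mmr.h5 --groups cohort/groups.tsv \
                       --adjacency cohort/adjacency.tsv --n-perm 1024 \
                       --seed 2 --out cohort/maps.tsv
mmrlink roi-regress    --mmr cohort/mmr.h5 --scores cohort/scores.tsv \
                       --groups cohort/groups.tsv --rois cohort/rois.tsv \
                       --window 0.2:0.5 --out cohort/roi.tsv
mmrlink svr-decode     --mmr cohort/mmr.h5 --scores cohort/scores.tsv \
                       --groups cohort/groups.tsv --group native \
                       --n-perm 100 --seed 3 --out cohort/decode/
mmrlink run-all        --config run.ini --out run/ --seed 1
```

`run-all` chains every stage on a synthetic cohort and writes
`manifest.json` (tool version, config snapshot, master seed, per-stage child
seeds, SHA-256 of every output). Re-running with the same seed and config
reproduces every output byte-for-byte.

Config files are flat `key = value` INI sections (`[simulation]`,
`[cluster]`, `[roi]`, `[decode]`); see the docstring of `mmrlink/cli.py`
for the full key list. Unknown keys are rejected by name.

## Data formats

- `behavior.tsv` — subject_id, group, pair_type (AA/AB/BB/BA), trial_index,
  response (same/different/none).
- `cohort.h5` — evoked container: `/evoked/<subject>/<condition>` arrays of
  shape (labels × times × 3), plus time metadata and label names; a lossless
  long-format TSV export exists for every array container.
- `mmr.h5` — subjects × labels × times nonnegative MMR magnitudes.
- `adjacency.tsv` — undirected label adjacency (label_a, label_b).
- `truth.tsv` — planted per-subject sensitivity/criterion and per-label
  deviant amplitudes, recorded exactly as drawn.
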