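# stressrep

Metrics of discrete-individual repeatability for replicated stress-response
curves — e.g. corticosterone time courses measured repeatedly on the same
animals — together with tie-aware ranking, rank-correlation comparison, and
a replicate-subsampling ("combination") analysis against the consensus
score.

Three metrics are implemented, each scoring one individual from its own
replicate curves:

| metric  | what it measures | direction |
|---------|------------------|-----------|
| `PR`    | profile repeatability: per-timepoint variances, max variance, curve crossings, and an interpolation penalty, combined into a bounded score | 1 = perfectly repeatable |
| `KL`    | generalized (unnormalized) Kullback–Leibler divergence averaged over successive replicate pairs | 0 = perfectly repeatable, unbounded above |
| `RMSSD` | root mean square of successive differences of per-replicate mean levels ("HPA flexibility") | 0 = perfectly repeatable, unbounded above |

Only `PR` tolerates missing cells (they are interpolated in replicate-index
space and penalized); `KL` and `RMSSD` refuse incomplete data.

## Package layout

- `stressrep.data_model` — `CurveMatrix` / `StressCurveDataset` types,
  validation, long-format (`individual,replicate,time,value`) CSV/TSV I/O.
- `stressrep.metrics` — the three metrics plus shared sub-computations
  (missing-cell interpolation, crossing counter).
- `stressrep.ranking_stats` — competition ("min") ranking with ties,
  external visual-rank columns, Pearson correlations on rank vectors with
  significance codes (`***` p<0.001, `**` p<0.01, `*` p<0.05, `.` p<0.10).
- `stressrep.combination` — scores every replicate subset per size (capped
  at 100 uniformly sampled distinct subsets) against the consensus score.
- `stressrep.synthgen` — seeded generator of curve panels spanning a
  repeatability gradient (presets: `synthetic` 11×4×4, `two_point` 5×28×2,
  `three_point` 10×10×3).
- `stressrep.datasets` — bundled reference table of scores, competition
  ranks, and human visual rankings for the three example panels.
- `stressrep.cli` — command-line front end.

## CLI

```sh
stressrep simulate --preset three_point --seed 1 --output curves.csv
stressrep score     --input curves.csv --metrics pr,kl,rmssd --output scores.csv
stressrep rank      --input scores.csv --output ranks.csv
stressrep correlate --input ranks.csv --ranks majority.csv --output corr.csv
stressrep combos    --input curves.csv --seed 1 --cap 100 \
                    --output combos.csv --summary-output summary.csv
```

Seeds are mandatory for every stochastic subcommand; identical command
lines produce byte-identical outputs. External rank files (e.g. a human
"majority" ranking) are two-column `individual,rank` tables merged by id.

## Python API sketch

```python
import stressrep as sr

ds = sr.generate(sr.preset("three_point", seed=1))
scores = sr.score_dataset(ds)                 # individual × metric scores
ranks = sr.rank_scores(scores)                # competition ranks, 1 = best
corr = sr.correlate_ranks(ranks)              # pairwise Pearson r, p, stars
combos = sr.combination_analysis(ds, seed=1)  # subset scores vs consensus
summary = sr.summarize_combinations(combos)
```
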