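# windfa

Sliding-window detrended fluctuation analysis (DFA) for event-locked
multichannel biosignals, with a ground-truthed synthetic cohort
generator.

The package implements a complete analysis chain for experiments in
which short motor tasks transiently change the long-range correlation
structure of a recorded signal:

1. **`windfa.dfa`** — classical DFA: profile construction, segmentwise
   polynomial detrending, fluctuation function `F(n)`, and the log-log
   scaling exponent `alpha` (0.5 = uncorrelated, 0.5–1 = persistent
   power-law correlations, >1 = integrated behaviour).
2. **`windfa.sliding`** — a floating window (default 500 samples = 2 s at
   250 Hz) slides over the signal; DFA on each excerpt yields a
   time-resolved trajectory `alpha(t)`.  Vectorised across windows and
   numerically identical to per-excerpt DFA.
3. **`windfa.preprocess`** — zero-phase Butterworth bandpass (1–100 Hz)
   and 50 Hz notch filtering, plus event-aligned epoch extraction.
4. **`windfa.response`** — per-trial `alpha(t)` segments are normalised
   to start at 1.0; the per-second OLS growth rate `r` of the normalised
   response is the discriminating statistic.  Averaging is two-stage:
   over trials within a subject, then over subjects within a group.
5. **`windfa.stats`** — Mann-Whitney U comparison of per-subject slopes
   between groups (exact enumerated null for small samples without ties,
   tie-corrected normal approximation otherwise) and a per-channel group
   difference map normalised by its maximum.
6. **`windfa.synth`** — exact circulant-embedding fractional Gaussian
   noise, piecewise-Hurst modulated signals (raised-cosine crossfades),
   and a full two-group cohort generator with per-subject variability,
   per-hand/segment slope targets, a sensorimotor channel-gain
   topography, and a JSON ground-truth manifest for recovery tests.
7. **`windfa.pipeline` / `windfa.cli`** — configuration, orchestration
   and the `windfa` command-line tool.

## Test

```sh
python -m pytest tests/            # full suite incl. acceptance tests
python -m pytest tests/ --ignore=tests/test_acceptance.py   # fast subset
```

## CLI quick tour

```sh
# generate a small synthetic cohort
windfa simulate --seed 42 --subjects 3 --out-dir scratch/sim

# whole-signal DFA per channel
windfa dfa --input scratch/sim/elderly00.csv --order 1 --fit-range 1.2:3.0

# alpha trajectory
windfa sliding --input scratch/sim/elderly00.csv --window 500 --step 25

# full pipeline: filter, epoch, sliding DFA, slopes, statistics
windfa analyze --data-dir scratch/sim --out-dir scratch/out --channels C3,C4,Cz

# group comparison from a slope table
windfa stats --slopes scratch/out/subject_slopes.tsv --alpha 0.05
```

`windfa analyze` writes TSV tables (`subject_slopes`, `group_slopes`,
`group_curves`, `stats_report`, `hand_contrast`, `channel_map`), each
stamped with the hash of the producing configuration, plus a
`run_log.json` with every parameter.  Analysis defaults live in
`windfa.config.PipelineConfig` (YAML-overridable, unknown keys
rejected).

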