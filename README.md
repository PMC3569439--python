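# mrnadecay

Tools for analysing non-exponential mRNA decay. A transcript's degradation
is modelled as a linear absorbing Markov chain (maturation rate ω between
biochemical states, degradation rate δᵢ out of each state); the molecule
lifetime is then phase-type distributed, and the measured decay curve after
a transcription stop is the normalised tail integral of its survival
function. The package provides:

- **`lifetime_models`** — chain construction/validation, the generic
  matrix-exponential lifetime, and numerically hardened closed forms for
  the exponential, first-step-distinct (fast→slow) and terminal-step
  (slow→fast) variants.
- **`decay_patterns`** — the lifetime → decay-pattern transform for
  transcription-stop and pulse protocols, half-life solving, and the
  *bona-fide* screen (steady-state curves must be monotone decreasing and
  convex).
- **`aging`** — age-dependent degradation rate (hazard) from the model or
  directly from measured patterns, residual-lifetime densities and means,
  residual protein synthesis capacity, stationary age law.
- **`copy_number`** — Poisson copy-number laws at steady state and after
  the stop, plus the finite-transcription-window construction.
- **`fitting`** — bounded multi-start nonlinear least squares of the three
  variants against measured decay tables, the 10% RSS nested-model
  selection rule, and the 3-way classification
  (0 = exponential, 1 = slow→fast, 2 = fast→slow).
- **`simulate`** — exact competing-clock single-molecule simulator
  (Monte-Carlo oracle for every analytic law) and the synthetic
  decay-table generator with truth manifests.
- **`cli_io`** — CSV readers/writers and the `mrnadecay` CLI.

## CLI

```bash
# synthetic decay tables (9-point 0–60 min grid) with a truth manifest
mrnadecay simulate -o tables.csv --genes 30 --seed 7 --noise 0.02

# fit + classify each gene; writes gene_id, category, rates, RSS,
# mean lifetime, half-life and the input levels
mrnadecay fit tables.csv -o results.csv

# convexity/monotonicity screen and per-category counts
mrnadecay check tables.csv
mrnadecay classify-summary results.csv

# evaluate N_rel, hazard, mean residual lifetime and capacity on a grid
mrnadecay curves --variant first_step --omega 0.1 --delta1 0.2 \
    --delta2 0.02 --grid 0:60:1 -o curves.csv
```

Decay tables are CSV with a `gene_id` column followed by one column per
time point named by its time in minutes (`0,5,10,...`); the level at t=0
must be 1 (renormalised with a warning if within 2%).

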