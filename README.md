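# fakesim

Simulation and probabilistic reconstruction of **fake-good distortion** in
ordinal (Likert-type) questionnaire data.

Self-report responses are sometimes deliberately inflated ("faking good").
Given a suspected-fake `n × m` response matrix on a `1..q` scale, this
package reconstructs hypothetical honest data by applying, entrywise, a
*reversing* replacement distribution: with probability `π` an observed value
`k` is replaced by a lower value `h < k`, where `h` is drawn from a
two-shape-parameter discrete generalized beta family on `{1, ..., k−1}`.
Three canonical scenarios fix the shape pair:

| scenario      | γ   | δ   | behaviour of replaced values        |
|---------------|-----|-----|-------------------------------------|
| uninformative | 1   | 1   | uniform over admissible values      |
| slight        | 4   | 1.5 | concentrate adjacent to `k`         |
| extreme       | 1.5 | 4   | concentrate far from `k`            |

Repeating the perturbation `B` times per (scenario, π) cell yields a
Monte-Carlo collection of reconstructed matrices; per-replicate marginal
means, one-factor CFA loadings, and fit indices (NFI/CFI/NNFI/RMSEA) are
compared with control statistics through the **average relative bias**
(ARB, %). The (scenario, π) cell with |ARB| closest to zero identifies the
most plausible faking configuration. A *forward* mirror of the replacement
model corrupts honest data for recovery experiments, and a calibrated
latent one-factor ordinal generator (binomial-shaped marginals, uniform
inter-item correlation) supplies synthetic honest data.

## Library overview

- `fakesim.replacement` — `dg_pmf`, `replacement_pmf`, `perturb_matrix`,
  `scenario_params`; reverse (reconstruction) and forward (corruption)
  directions.
- `fakesim.generator` — `generate_true_data` with
  `binomial_thresholds` / `calibrate_latent_correlation` (latent
  equicorrelation calibrated so the *observed*-scale Pearson correlation
  hits the target).
- `fakesim.cfa` — `fit_one_factor` (ML, unconstrained uniquenesses so
  Heywood cases surface), `baseline_chi_square`, `compute_fit_indices`,
  `flag_improper` (negative variance or |loading| > 10).
- `fakesim.experiment` — `ScenarioGrid`, `run_grid`, `compute_arb`,
  `summarize_grid` (excludes non-converged/improper replicates and reports
  the bookkeeping).
- `fakesim.io` — CSV matrix reader/writer (strict validation, no
  imputation), `make_fixture` for honest/fake pairs, `RunConfig`.

## CLI

```sh
# synthetic honest data: 126 respondents, 12 five-point items
fakesim generate --n 126 --m 12 --q 5 --p-binom 0.5 --rho 0.25 --seed 1 --out honest.csv

# corrupt it with a slight forward fake-good process (25% of entries)
fakesim perturb --input honest.csv --scenario slight --pi 0.25 \
    --direction forward --seed 2 --out fake.csv

# single reconstruction pass (reverse direction)
fakesim reconstruct --input fake.csv --scenario slight --pi 0.25 --seed 3 --out recon.csv

# one-factor CFA report (JSON)
fakesim fit --input fake.csv

# full Monte-Carlo grid: 3 scenarios x {0.25, 0.5, 0.75, 1} x B replicates
fakesim experiment --input fake.csv --control honest.csv --b 2000 --seed 4 \
    --outdir results/run1
```

The `experiment` command writes `replicates.csv` (one row per replicate),
`arb_summary.csv` (one row per family × scenario × π), `config.yaml`
(echoed configuration, sufficient to reproduce the run), and `run.log`.
Control statistics may come from a control-group CSV, the input itself
(`--control self`), or a generative model
(`--control generate:n=126,m=12,p_binom=0.5,rho=0.25,seed=9`).

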