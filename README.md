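# mird

Multiple imputation of missing time-to-event data from **retrieved dropouts**
(MI-RD) for outcome trials, plus the simulation machinery to study its
operating characteristics.

In long outcome trials (e.g. CVOTs), subjects who leave the study with no
prior endpoint event are *missing data*; subjects who stop randomized
treatment but stay in the study to the end ("retrieved dropouts", RDs) are
the closest observable analogue. `mird` imputes each missing subject's
outcome by inverting a conditional survival function fitted to the RD
subset — under the MNAR assumption that missing subjects behave like RDs of
the same arm — then analyzes each completed dataset with a Cox
proportional-hazards model and pools the B estimates with Rubin's rules.

Three imputation flavors are provided:

| method      | survival model on the RD subset | inversion |
|-------------|--------------------------------|-----------|
| `bootstrap` | Cox PH refit on B bootstrap resamples | linear interpolation on a survival grid (default width 60 days) |
| `pwe`       | piecewise-exponential PH (default cuts: quartiles of RD observed times) | closed form |
| `weibull`   | Weibull AFT (`log T = γ0 + Zγ + σε`) | closed form |
| `j2r`       | Weibull AFT, jump-to-reference (active dropouts follow the placebo distribution post-dropout) | closed form |

Parametric imputations are "proper": each imputation uses a fresh parameter
vector drawn from the multivariate-normal large-sample distribution of the
MLE (hazards and scale sampled on the log scale). `--partial-cov` restricts
piecewise-exponential sampling to the regression coefficients with hazards
pinned at the MLE (the behavior of R's `eha`-based implementation, and the
default for simulation grids, where quartile cuts routinely produce
event-free intervals).

## CLI

```bash
# full pipeline on a subject-level CSV (one row per subject)
mird analyze --input trial.csv --method weibull -B 100 --seed 17 -o out/

# write the B completed datasets only
mird impute --input trial.csv --method pwe --cuts quartiles -B 50 -o imputed/

# operating-characteristics grid (resumable; see example below)
mird simulate --grid grid.yaml --methods pwe,bootstrap,weibull -o sim_out/
```

Input columns (rename via `--dialect map.yaml`): `id`, `trt` (0/1), `R`
(randomization day), `T_obs` (days from randomization to event/censoring),
`E` (1 = event), optional `trt_disc_day`, `study_disc_day`, `death_day`, and
either a `D` column or `--dcut` for the common data-cut day. Subject horizons
use `C = D - R + 1`.

`grid.yaml` is a list of scenario mappings, e.g.:

```yaml
- {N_total: 5000, rd_frac: 0.20, disc_frac: 0.15, reps: 1000, B: 10, seed: 1}
- {N_total: 5000, rd_frac: 0.20, disc_frac: 0.15, hr: 0.8, hr_star: 0.9,
   disc_offset_active: -0.02, reps: 250, B: 10, seed: 2}
```

## Python API

```python
import mird

data = mird.read_trial_table("trial.csv")
result = mird.run_mird(data, "weibull", B=100, seed=17)
print(result.hr, result.ci95, result.p_value)

spec = mird.ScenarioSpec(N_total=5000, rd_frac=0.2, disc_frac=0.15,
                         reps=500, B=10, seed=1)
summary = mird.run_scenario_grid([spec], methods=["pwe", "bootstrap", "weibull"])
print(mird.summarize_table2(summary))
```

## Layout

- `src/mird/trial_data.py` — subject-level data model, disposition
  classification (completer / RD / missing), delimited I/O
- `src/mird/imputation_models.py` — RD-subset model fits (bootstrap Cox,
  piecewise exponential, Weibull AFT) and proper parameter draws
- `src/mird/imputers.py` — conditional-survival inversion and outcome
  finalization against the horizon / death date
- `src/mird/analysis.py` — per-imputation Cox analysis, Rubin's rules,
  end-to-end pipeline
- `src/mird/simulator.py` — synthetic trial generator, scenario grids,
  log-rank reference power
- `src/mird/cli.py` — `mird analyze | impute | simulate`
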