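# ising-ews

Early-warning signals of criticality in the two-dimensional Ising model.

Many complex systems — ecosystems, physiological networks, climate
subsystems — sit near critical thresholds, and generic statistical
*early-warning signals* (rising variance, changing skewness and kurtosis,
rising lag-1 autocorrelation, spectral reddening) have been proposed to
detect an approaching transition from time series alone. This package
studies those indicators in a system whose critical point is exactly known:
the ferromagnetic Ising model on an `L x L` periodic square lattice,

    H(sigma) = -J sum_<ij> sigma_i sigma_j ,   sigma_i = +/-1 ,   J = k = 1 ,

with critical temperature `T_c = 2/ln(1 + sqrt 2) ~= 2.27`. Metropolis
single-spin-flip dynamics generates a per-sweep magnetization trace
`M_t = (1/N) sum_i sigma_i`, and critical slowing down near `T_c` imprints
itself on that series. For ensembles of runs across a temperature grid the
package computes:

* the first four temporal moments (population conventions; kurtosis
  non-excess, normal reference 3) with ensemble standard errors;
* the lag-1 autocorrelation `C(1)` (biased estimator);
* the ensemble-averaged periodogram, and a dual flat/power-law fit to its
  log-log form whose breakpoint — the **crossover frequency** `C_f` — acts
  as an early-warning statistic: a pure power law (temporal scale
  invariance) at `T_c`, with a widening white low-frequency plateau as the
  temperature moves away;
* a mean-field companion (pitchfork normal form and Landau free energy) and
  an exact-enumeration oracle on tiny lattices that validates the sampler.

It is intended for researchers studying critical-transition indicators who
want a fully controlled, exactly reproducible testbed; the indicator suite
also accepts any univariate CSV.

## Worked example

Simulate one run at the critical temperature and one in the disordered
phase, then compute its indicators:

```sh
ising-ews simulate --T 2.27 --L 50 --sweeps 2000 --burn-in 500 --seed 7 --out m227.csv
ising-ews indicators m227.csv
```

prints (abridged)

```json
{"variance": 0.0069, "abs_skewness": 0.6786, "kurtosis": 3.389,
 "autocorr_lag1": 0.9574,
 "crossover": {"crossover_frequency": 0.0033, "slope": -1.5224}}
```

while the same command with `--T 2.9` gives

```json
{"variance": 0.0053, "abs_skewness": 0.0593, "kurtosis": 2.7406,
 "autocorr_lag1": 0.8688,
 "crossover": {"crossover_frequency": 0.034, "slope": -1.6804}}
```

Read: near `T_c` the trace is strongly autocorrelated (`C(1) = 0.96`),
leptokurtic and skewed, and its PSD is a power law essentially all the way
down (`C_f = 0.0033` cycles/sweep — the flat segment holds 4 of 750
frequencies). At `T = 2.9` the memory is weaker, the distribution
platykurtic and symmetric, and the white plateau has grown tenfold
(`C_f = 0.034`): the crossover frequency tracks distance from criticality.

The full experiment — ensembles over a temperature grid, with summary
tables, per-temperature PSDs, crossover fits and a reproducibility
manifest — runs via

```sh
ising-ews sweep --out-dir results/sweep --scale 0.05 --seed 1   # reduced scale
ising-ews gridsize --sizes 30,50 --out-dir results/gridsize --scale 0.05
ising-ews meanfield --beta-min 0.5 --beta-max 2 --out branches.csv
ising-ews validate --L 2 --T 2.27                                # sampler check
```

Reference scale (the defaults: `L=100`, T = 1.42..3.12 step 0.05, 1000 runs
x 5000 sweeps, burn-in 1000) is an hours-scale batch job; `--scale` shrinks
the ensemble proportionally. The same machinery is available as a library:

```python
from ising_ews import SweepConfig, run_sweep
summary = run_sweep(SweepConfig.desk_scale(base_seed=1))
print(summary.table[["T", "variance", "ac1", "crossover_freq"]])
```

Details of the estimator conventions, the desk-scale study conditions, and
the numerical choices behind the crossover fit are in
[docs/methods.md](docs/methods.md).

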