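# aseforecast

Forecasting unprecedented ("Black Swan") fluctuations in ecological time
series by exploiting avalanche scaling laws.

Many ecosystems — plankton communities, intertidal assemblages, forest
carbon fluxes — display aperiodic bursts spanning orders of magnitude in
size and duration.  Empirical forecasting methods built on attractor
reconstruction (delay embedding plus locally weighted regression, the
"S-map" family) fail exactly when it matters: during events larger than
anything in the historical record, where no nearby neighbors exist in
the reconstructed state space.

This package implements a remedy built on three conserved statistics of
near-neutral ("marginally stable") dynamics.  Excursions of a series
above its mean — *avalanches*, each with duration T and area S — obey

    p(T) ~ T^(-alpha),   p(S) ~ S^(-tau),   <S_T> = b T^gamma,

with universal exponents alpha ≈ 3/2, tau ≈ 4/3, gamma = 3/2 linked by
gamma = (alpha−1)/(tau−1), and a universal average event shape Y_n(t′)
(unit duration, unit area).  Because only the prefactor b is
system-specific, large events can be synthesized from small ones:

    Y_T(t) = Y_n(t/T) · b · T^(gamma−1)        (ASE)

Avalanche Scaling Extrapolation (ASE) fits b from a short history,
stretches the universal shape to a ladder of durations, and appends the
synthetic events to the training data.  A k-nearest-neighbor S-map (or a
hybrid that draws neighbors from raw and synthetic embeddings, weighted
(1−μ) and μ) can then extrapolate into amplitude regimes the history
never visited.

The package provides:

* `aseforecast.series` — uniformly sampled series I/O (CSV), linear
  detrending, mean normalization;
* `aseforecast.avalanche` — segmentation, log-binned densities,
  truncated power-law/exponential MLE with AIC model comparison,
  size-duration regression, average-shape collapse;
* `aseforecast.models` — the linear response model at marginal
  stability, the converged reference shape, and a chaotic surrogate;
* `aseforecast.ase` — unit-size fitting and augmented-dataset assembly;
* `aseforecast.forecast` — delay embedding, kNN S-map, hybrid, AR1;
* `aseforecast.evaluate` — error metrics, training-set protocols, and
  benchmark runners;
* a thin `aseforecast` CLI (`simulate`, `segment`, `fit`, `ase`,
  `forecast`, `benchmark`) over the same functions.

## Worked example

```python
from aseforecast import (MarginalParams, simulate_linear_response,
                         segment_avalanches, compute_baseline,
                         fit_truncated_power_law, bin_average_size_duration,
                         fit_size_duration)

series = simulate_linear_response(
    MarginalParams(lam=1e-3, eps=0.01, n_steps=10**6, seed=42))
series = series.slice(1000, len(series))           # drop burn-in
catalog = segment_avalanches(series, compute_baseline(series))
alpha = fit_truncated_power_law(catalog.durations, lo=0.95, hi=100)
gamma = fit_size_duration(bin_average_size_duration(catalog, 5))
print(len(catalog), round(alpha.exponent, 3), round(gamma.gamma, 3))
```

prints

```
7134 1.583 1.566
```

— about 7000 events whose duration distribution has MLE exponent 1.58
and whose mean size grows as T^1.57, close to the theoretical 3/2 for
marginally stable dynamics (the duration estimate carries a small upward
bias from duration quantization; see `docs/methods.md`).

The `examples/` directory contains one short narrative script per
capability; `python examples/05_black_swan_benchmark.py` runs a reduced
train-low/predict-high benchmark and prints, per method, the median
relative error on the top-5% amplitude targets:

```
method     median RE               IQR       n
smap          0.3165 [0.1489, 0.5390]   10000
smap_ase      0.2270 [0.0912, 0.3553]    9000
hybrid        0.2395 [0.1078, 0.4140]    9000
ar1           3.9436 [2.5484, 5.4236]   10000
hybrid vs raw paired t-test: p = 5.1e-09
```

Lower is better: predictors using synthetic scale-extrapolated events
(`smap_ase`, `hybrid`) beat the raw-data S-map on events beyond the
training range, while the AR1 baseline fitted to low-amplitude history
collapses.

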