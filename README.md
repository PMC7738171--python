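# lagkit

Single-cell and population growth-lag analysis for diauxic shifts.

When *Escherichia coli* is switched from glucose to lactose, every cell
transiently arrests growth. The arrest durations are bimodal: cells holding
even a single pre-existing *lac* operon protein sense the new sugar and
resume within tens of minutes, while "sensorless" cells with exactly zero
copies must wait for a stochastic expression burst and lag for one to three
hours. The fraction of sensorless cells therefore controls the lag of the
whole population — a fitness trait in fluctuating environments. `lagkit`
implements the computational chain needed to study this at every scale:

- **Single-cell lags** (`lagkit.single_cell`) — from time-lapse traces of
  cell length and LacZ-GFP reporter level: the *induction lag* (delay until
  the reporter rises 200 molecules above its post-switch baseline) and the
  *growth lag* (a Bayesian changepoint fit to log-length). The growth-lag
  model is log-linear growth resuming at time τ,
  `L(t) = λ·Λτ(t) + Λ0 + ε`, with `Λτ(t) = (t−τ)Θ(t−τ)` and Gaussian noise
  `ε ~ N(0, σ²)`. Marginalising Λ0 (uniform prior) and σ (Jeffreys prior)
  and handling λ by the Laplace method gives the one-dimensional profile

  `log p(D|τ) = ((2−T)/2)·log Var[L − λτ·Λτ] − ½·log Var[Λτ] + const`,

  with `λτ = Cov[L, Λτ]/Var[Λτ]`, maximised over a 1-min τ grid.
- **Transcriptional memory** (`lagkit.memory`) — inherited-molecule
  estimates by pure dilution (`Lm/2^nd`), lag fractions stratified by
  inherited molecules, per-experiment fluorescence centring with a
  one-sided Welch test, and the three-criteria FLCS GFP-positive call.
- **Population lags** (`lagkit.popsim`) — a discrete-time simulator that
  converts any single-cell lag distribution into a population growth curve
  (100 equally weighted subpopulations, arrest then exponential regrowth)
  and reports the lag in minutes and in "doublings lost", with an exact
  closed form `Δ/T_d = −log2(Σᵢ wᵢ·2^(−τᵢ/T_d))` as oracle.
- **Diauxie curves** (`lagkit.diauxie`) — plate-reader analysis: sliding
  window background estimation, OD = 0.01 alignment, first-passage maps
  t = f(OD), replicate-averaged delay-vs-OD curves against IPTG-induced
  controls, and plateau-based population-lag extraction.
- **Sensorless survey** (`lagkit.survey`) — expected zero-copy fractions
  under Poisson expression noise (`P(N=0) = e^−λ`; ≥5% of cells are
  sensorless whenever the mean is ≤3 copies/cell) across sensory systems
  and growth conditions.
- **Synthetic data** (`lagkit.synthetic`) — generators for mother-machine
  traces, dilution lineages, diauxie plate curves and abundance tables,
  always paired with ground-truth tables so every estimator can be scored.

## Worked example

```python
import numpy as np
from lagkit import SimScenario, generate_cell_traces, analyze_traces
from lagkit.popsim import SimConfig, population_lag_from_lags

sc = SimScenario(seed=42)                      # glucose -> lactose switch
traces, truth = generate_cell_traces(sc, 300)  # 300 mother-machine lineages
table = analyze_traces(traces, sc.switch_time,
                       focal_ids=truth["focal_cell_id"].tolist())
meas = table[table["induction_status"] == "measured"]
print("fraction short (<50 min):", (meas["induction_lag"] < 50).mean())
both = table.dropna(subset=["induction_lag", "growth_lag"])
r2 = np.corrcoef(both["induction_lag"], both["growth_lag"])[0, 1] ** 2
print("induction-growth r^2:", round(r2, 3))
res = population_lag_from_lags(meas["induction_lag"].to_numpy(), SimConfig())
print(f"population lag: {res.lag_minutes:.1f} min "
      f"= {res.lag_divisions:.2f} doublings lost")
```

prints

```
fraction short (<50 min): 0.29
induction-growth r^2: 0.999
population lag: 84.1 min = 1.45 doublings lost
```

29% of the simulated cells carried at least one reporter molecule at the
switch and induced in under 50 minutes; induction and growth lags agree
cell by cell (the arrest ends when the operon induces); and feeding the
measured lag distribution to the population simulator shows the mixed
population reaching any given size 84 minutes (≈1.4 lactose doublings)
later than a population that never arrests.

The same steps are available from a shell:

```sh
lagkit simulate --n-cells 300 --seed 42 --traces-out traces.csv
lagkit lags --traces traces.csv --switch-time 60 --out lags.csv
lagkit popsim --lags lags.csv --doubling-pre 49 --doubling-post 58
```

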