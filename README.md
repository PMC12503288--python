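# migsim

A stochastic evolution model for international migration: bilateral
migration flows are sampled from probability distributions calibrated on
partitioned flow data, and native populations and migrant stocks are
advanced through demographic accounting equations under Monte-Carlo
sampling, yielding median trajectories with 50% and 95% prediction
intervals. A deterministic variant substitutes every draw by its
distribution's median. The package is aimed at quantitative migration
researchers and demographic modellers who want hindcasts or projections of
bilateral migrant stocks with honest uncertainty bands, without committing
to an explicit behavioural migration mechanism.

## Model

Each country `i` carries a native population `P_i` and migrant stocks
`D_ik` (people born in `k` living in `i`, country-of-birth definition).
One yearly step applies emigration `M`, return migration `R` and migrant
births `B` simultaneously:

```
P_i(t+1) = (P_i(t) − Σ_l M_il(t)) · (1 + c_i(t)) + Σ_l R_li(t) + Σ_l B_il(t)
D_ik(t+1) = D_ik(t) · (1 − c†_k(t)) − R_ik(t) + M_ki(t)
```

with natural change rate `c`, death rate `c†`, and

```
M_ij = P_i · M̃(P_i) · s(g_ij, d_ij)      emigration: rate × destination share
R_ik = D_ik · R                           return migration
B_il = D_il · c*_l                        births from migrant stocks
```

`M̃(P)` is a Jones–Faddy skew-t random variable whose parameters depend on
the origin's population-size bin (P1–P4, order-of-magnitude bins);
`s(g, d)` is a Weibull-maximum random variable per (GDPc-ratio bin g1–g4,
relative-diaspora bin d1–d5), renormalized so shares sum to one; `R` is
Student-t distributed. All draws are truncated to [0, 1]. Calibration
converts 5-year flow data to yearly rates via `m1 = 1 − (1 − m5)^(1/5)`,
discards return rates above 100%, fits by maximum likelihood, and ranks
candidate families by histogram SSE. See `docs/methods.md` for the full
account.

## Worked example

The synthetic-world module generates a complete study offline: a country
panel, an initial stock matrix, and a 5-year flow history produced by the
model itself from a known ground truth — so calibration can be checked
against the distributions that generated the data.

```python
import migsim as m

cfg = m.SyntheticConfig(seed=11)          # 40 countries, 1990-2020
panel, initial = m.generate_world(cfg)
truth = m.default_truth()
res = m.generate_flow_history(panel, initial, truth, seed=7)
dists = m.calibrate_model(res.history, res.stocks, res.panel)

for label in ("P1", "P2", "P3", "P4"):
    d = dists.emigration[label]
    print(f"{label}: median {d.truncated_median():.5f} (n={d.n_fit})")

summary = m.run_ensemble(initial, panel, dists, horizon=30,
                         n_samples=200, seed=42)
band = summary.band("total_migrant_stock")
print(f"2020 total migrant stock: median {band['median'][-1]/1e6:.1f}M, "
      f"95% PI [{band['q2.5'][-1]/1e6:.1f}M, {band['q97.5'][-1]/1e6:.1f}M]")
det = m.deterministic_run(initial, panel, dists, 30)
print(f"deterministic 2020 stock: {det.states[-1].total_migrant_stock/1e6:.1f}M")
```

prints

```
P1: median 0.00647 (n=60)
P2: median 0.00413 (n=60)
P3: median 0.00210 (n=60)
P4: median 0.00104 (n=60)
2020 total migrant stock: median 246.0M, 95% PI [242.1M, 249.8M]
deterministic 2020 stock: 245.9M
```

The recalibrated emigration-rate medians fall with origin population size
and recover the generating values (0.006, 0.004, 0.002, 0.001) within a
few percent from 60 origin-period observations per bin; the ensemble then
turns the calibrated distributions into a median stock trajectory with
prediction intervals. Under the default mildly-skewed truth the
deterministic run sits close to the ensemble median; under strongly
right-skewed rate distributions (`m.right_skewed_truth()`) it falls
systematically below it, because median substitution discards the heavy
upper tail.

## Command line

The same pipeline is exposed as a CLI over tidy CSV files:

```bash
migsim synth     --config cfg.yaml --out world/
migsim calibrate --flows world/flows.csv --return-flows world/return_flows.csv \
                 --stocks world/stocks.csv --panel world/panel.csv \
                 --out world/dists.json
migsim simulate  --dists world/dists.json --panel world/panel.csv \
                 --init world/stocks.csv --config cfg.yaml \
                 --mapping world/mapping.csv --out world/summary.csv
migsim evaluate  --summary world/summary.csv --reference ref.csv \
                 --out world/report.csv
```

`simulate` writes tidy `series,year,stat,value` summaries (with optional
region/income-group aggregates, computed per ensemble sample); `evaluate`
reports absolute and relative errors and 50%/95%-band coverage against
reference stocks. Real datasets in the same dialects — bilateral flow
estimates, population prospects, stock matrices, GDP panels — can be
substituted for the synthetic files; the panel reader implements linear
population interpolation and the PPP → MER → USD → closest-year GDP
fallback chain.

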