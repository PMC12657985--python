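# airedna

A joint Bayesian state-space model linking three ways of observing fish in
a river — visual counts at a hatchery fish ladder, eDNA concentrations in
river water, and eDNA deposited on passive air samplers hung above the
water — to a single latent daily fish-accumulation rate.  It is aimed at
molecular ecologists quantifying cross-medium (water-to-air) eDNA transfer
and at anyone who needs a calibrated qPCR observation model rather than
fixed LOD/LOQ cutoffs.

## The model

At each of six weekly sampling events *t*:

```
counts   N_t  ~ NegBin(X_t · E_t, φ)                    φ = 20 fixed
water    W_t  = X_t · e^ω                               [copies/L]
air      ln A_tj = η_j + ln W_t + ε_tj,  ε_tj ~ N(0, τ_j)
         ln A_tjb = ln A_tj + δ_tjb,     δ_tjb ~ N(0, ρ_j),  Σ_b δ_tjb = 0
qPCR     Z ~ Bernoulli(1 − e^(−K·θ))
         Y | Z=1 ~ N(β₀ + β₁ₚ ln K,  e^(γ₀ + γ₁ ln K))
units    U_t = W_t·F/V          (water: F = 1 L, V = 10 µL)
         Q_tjb = A_tjb·S·P/V    (air: S = 16 or 750 cm², P = 1 day)
```

`X_t` is the latent fish rate (fish/day), `E_t` the days since the last
gate opening, `ω` the integrated eDNA factor converting fish/day into
copies/L, `η_j` the water-to-air transfer (dilution) intercept per sampler
type *j* (gelatin, PTFE, air-suspended MCE, open DI-water tray), `τ_j` the
sampler's residual tracking error and `ρ_j` its replicate repeatability.
One shared qPCR calibration (θ, β₀, β₁ₚ, γ₀, γ₁) ties standards, water
wells and air wells together, so observation-level uncertainty propagates
into every estimate.  Derived quantities: capture efficiency
`e^(η_j − η̄)` and dilution magnitude `e^(−η_j)`.

A synthetic-data generator reproduces all three input tables with this
exact generative structure, so the full pipeline is testable without any
field download.  Inference is blocked-Gibbs MCMC — every model
coordinate has an exact conjugate or fine-grid full conditional — over one
canonical NumPy log-density; diagnostics (split-R̂, bulk ESS, posterior
predictive checks, prior-sensitivity overlap) follow the standard
protocol.  See `docs/methods.md` for the full account.

## Worked example

```bash
python analysis/01_simulate.py --seed 1     # writes results/data/
python analysis/02_fit.py      --seed 1     # writes results/fit/
python analysis/03_diagnose.py --seed 1     # writes results/diagnostics/
python analysis/04_summarize.py             # writes results/summary/
```

`01` simulates the study: counts `[0, 1306, 2262, 1073, 797, 664]` over
efforts `[0, 7, 7, 7, 7, 7]` days and 164 qPCR wells (158 amplified).
`02` fits the joint model (4 chains × 500+500 iterations, ~30 s) and
prints, among others:

```
                mean     sd    q2.5  q97.5   rhat     ess
omega_log      9.562  0.110   9.344  9.770  1.000  1320.2
eta[gelatin] -10.173  0.351 -10.840 -9.464  1.003  1545.0
eta[ptfe]     -9.428  0.276  -9.932 -8.856  1.002  1628.3
eta[mce_air] -10.941  0.536 -11.846 -9.866  1.002  1603.8
eta[mce_di]  -10.130  0.714 -11.399 -8.460  1.000  1742.3
max R-hat 1.013; divergences 0
```

— the generating values (ω = 9.578, η = −10.45/−9.53/−10.91/−9.95) sit
inside every interval.  `04` turns the fit into the headline quantities:

```
            eta    tau    rho  capture_efficiency
gelatin -10.173  0.767  0.536               1.062
ptfe     -9.428  0.600  0.071               2.200
mce_air -10.941  1.151    NaN               0.569
mce_di  -10.130  1.605    NaN               1.246

1 fish/day -> 14295 copies/L [11428, 17506] (95% CI)
overall water-to-air dilution ~ 26,896 x  [15,220, 41,371]
season-average fish rate 161.5 fish/day [132.5, 196.4]
```

Reading: one fish per day passing the ladder corresponds to roughly
14,000 eDNA copies per litre of river water; airborne deposition is four
to five orders of magnitude more dilute than the water signal; PTFE
filters capture about twice the across-sampler average while the
air-suspended MCE filter captures about half.

Longer studies: `analysis/06_recovery_study.py` repeats simulate+fit over
20 seeds and tabulates credible-interval coverage of every transfer
parameter; `analysis/05_paper_scale_diagnostics.py` runs the full
4 × (5000 + 5000) sampler configuration and checks the complete
convergence protocol (tens of minutes).

The same pipeline is scriptable via the `airedna` CLI
(`simulate`, `fit`, `diagnose`, `summarize`, `run`) with `--seed`,
`--config`, `--out` flags, and accepts external data as three CSV tables
(`counts.csv`, `metadata.csv`, `plate_table.csv`; see
`airedna.io.read_inputs` for the schemas).

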