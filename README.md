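# yeastcolony

Multiscale modelling of *Saccharomyces cerevisiae* colony growth, from
single-microenvironment metabolism to three-dimensional colony structure.

Budding yeast switches metabolic state as it exhausts its carbon sources:
cells first ferment glucose, then — after the diauxic shift — respire the
ethanol they produced, and finally enter a non-growing quiescent state.
This package implements, calibrates, and simulates a model of that process
at two scales:

1. **Microenvironment model.** A five-variable ODE system for the cell mass
   in the glucose (`m_g`), ethanol (`m_e`) and quiescent (`m_q`) states plus
   the glucose (`g`) and ethanol (`e`) pools:

   ```
   dm_g/dt = mu1 m_g g − beta1 m_g/(g+K) − beta2 m_g
   dg/dt   = −(mu1/gamma1) m_g g
   dm_e/dt = mu2 m_e e + beta1 m_g/(g+K) − beta3 m_e
   de/dt   = (mu1/gamma2) m_g g − (mu2/gamma3) m_e e
   dm_q/dt = beta2 m_g + beta3 m_e
   ```

   The observable is the total mass `m = m_g + m_e + m_q` (OD units).
   Three nested switching topologies are compared: H1 (quiescence reachable
   from both growing states), H2 (`beta2 = 0`, quiescence only via the
   ethanol state) and H3 (`beta3 = 0`).  A respiratory-deficient *petite*
   strain corresponds to `mu2 = 0`.

2. **Bayesian calibration and model selection.**  The likelihood combines
   replicate-averaged growth curves (per-timepoint sample variances) with
   steady-state composition observations at 80 h; priors are standard
   normal in log-parameter space.  Marginal likelihoods are estimated by
   population MCMC over a temperature ladder `beta_i = ((i−1)/(N−1))^5`
   with adaptive random-walk moves and adjacent-temperature swaps, and
   thermodynamic integration of the mean log-likelihood over the ladder.
   Convergence is monitored with the Gelman–Rubin PSRF.

3. **Colony simulator.**  Space is discretized into 0.1 mm cubes, each a
   homogeneous microenvironment.  Cell mass moves between neighbouring
   cubes only when it exceeds a fill threshold (`th = 1`), carrying the
   donor cube's state fractions; nutrients move by linear fluxes at rate
   `lambda_agar` (agar side) or `lambda_col` (colony side).  Transport is
   exactly mass-conserving; time stepping is explicit Euler at
   `dt = 0.0025 h`.  The two transfer rates are calibrated against colony
   footprint-area curves by Gaussian-process Bayesian optimization
   (squared-exponential kernel, expected-improvement proposals, Latin
   hypercube initialization) of the cost
   `xi = log Σ_i (A_sim(t_i) − A_meas(t_i))²`.

No experimental inputs are bundled; the `synthdata` module generates
growth-curve, composition, and footprint datasets with the statistical
structure the inference assumes, so the full pipeline is testable
end-to-end.

## Worked example

```python
from yeastcolony import GrowthModel, generate_growth_curves

data = generate_growth_curves(seed=1)     # 6 replicates, 15-min grid, 88 h
model = GrowthModel(data, hypothesis="H2")
result = model.fit(seed=0)                # multistart MAP
print(result.summary())
```

```
Growth model fit  [H2]
  log posterior : 1028.661
  curve RMSE    : 0.00798
  fractions at t_N=80 h : ethanol 0.275, quiescent 0.633
  parameter      log-space      natural
  m_g0              -2.2824      0.10204
  mu1               -0.0016      0.99841
  beta1             -2.0615      0.12726
  K                  1.6443      5.17739
  mu2               -1.8662      0.15471
  gamma1             0.4008      1.49308
  gamma2             1.1897      3.28595
  gamma3             0.7939      2.21201
  beta3             -3.6730      0.02540
```

The fitted curve tracks the replicate mean to below the replicate-mean
noise floor (RMSE 0.0080 OD against noise sd 0.02/√6 ≈ 0.0082), recovers
the generating glucose growth rate `mu1 = 1.0/h` to 0.2%, and places
27.5% of the 80-h biomass in the ethanol state and 63.3% in the quiescent
state, close to the 29%/62% steady-state composition the observations
encode.  Hypothesis comparison
(`yeastcolony.select_hypothesis`) returns log marginal likelihoods and
posterior probabilities over H1/H2/H3, and `ColonyCalibrator` fits the two
spatial transfer rates to a footprint series.

A command-line interface covers the same stages:

```sh
yeastcolony gen-synth --kind growth --seed 1 --out growth.csv
yeastcolony fit-micro --data growth.csv --hypothesis H2 --seed 0 --out fit.json
yeastcolony select-hypothesis --data growth.csv --seed 0 --out evidence.json
yeastcolony simulate-colony --horizon 48 --sample-dt 1 --out footprint.csv
yeastcolony calibrate-spatial --data footprint.csv --seed 0 --out rates.json
```

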