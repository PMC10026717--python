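# troutstock

Size–age stock assessment for river salmonid populations from
cross-sectional capture records (one row per fish: total length, wet mass,
fractional age, gear, river tract, transect). It was built around the
assessment of the marble trout (*Salmo marmoratus*) population of the Toce
River (Lake Maggiore basin), a critically endangered salmonid exploited by
a recreational fishery, but every stage is generic.

The pipeline chains five classical estimators:

1. **Length–weight allometry** — OLS of `log10(W) = b·log10(TL) + log10(a)`;
   the inverse imputes missing masses for biomass-density estimates.
2. **Growth trajectories** — von Bertalanffy
   `TL(t) = TL∞(1 − e^(−K(t−t0)))`, Gompertz
   `TL(t) = TL∞·e^(−e^(−G(t−t0)))`, and logistic
   `TL(t) = TL∞/(1 + e^(−G′(t−t0)))` fitted by nonlinear least squares to
   length-at-age and ranked by AICc (k = 4, Gaussian likelihood). For the
   Gompertz fit the absolute maximum growth rate is `AMGR = G·TL∞/e`.
3. **Catch-curve mortality** — on the descending limb of catch-at-age
   (classes above the first fully-recruited age, recoded from zero) the
   Chapman–Robson estimator gives annual survival `S = T/(n+T−1)` and the
   Hoenig-corrected instantaneous total mortality
   `Z = −ln S − (n−1)(n−2)/(n(T+1)(n+T−1))`. Natural mortality comes from
   the longevity estimator `M = 5.109/t_max`, fishing mortality from
   `F = Z − M`, annual rates from `A = 1 − e^(−rate)`, and the exploitation
   ratio from `E = F/Z` (E ≈ 0.5, i.e. F = M, is the classical
   optimal-yield heuristic).
4. **Length-based reference points** — published cross-species empirical
   relations predict the mean length at first maturity
   (`log10 TLm = 0.8979·log10 TL∞ − 0.0782`) and the optimum length
   (`log10 TLopt = 1.0421·log10 TL∞ − 0.2742`) with 95% prediction
   intervals from their residual standard errors; the optimum harvest slot
   is `TLopt ± 10%` and fish above it are megaspawners.
5. **Harvest-policy evaluation** — minimum-length limits (MLL) and harvest
   slots applied to a length-frequency catch sample, cross-classified
   against the reference points (immature / within optimum slot / mature
   outside slot / megaspawner) to expose recruitment- and
   growth-overfishing risk.

A synthetic-population generator (`troutstock.simulate`) produces datasets
with exactly the structure these estimators assume — truncated-geometric
age structure with reduced catchability before full recruitment, Gompertz
lengths with Gaussian noise, lognormal allometric masses, missing-mass
records — so the whole chain is testable end to end without any field data.

## Worked example

```sh
troutstock assess --simulate --seed 1 --n 2000 --policy mll:40 --policy slot:60,70
```

simulates 2000 captures under the default study conditions (Z = 0.924 yr⁻¹,
Gompertz TL∞ = 105 cm, G = 0.216 yr⁻¹, t0 = 3.99 yr) and runs the full
assessment. Abridged output:

```
AICc model comparison
                    AICc  delta_AICc  weight
gompertz        6455.058       0.000   0.994
logistic        6465.191      10.133   0.006
von_bertalanffy 6483.084      28.026   0.000

Growth fit (gompertz), n = 2000
  TL_inf     98.864  (s.e. 5.334, 95% CI 88.402, 109.325)
  G           0.228  (s.e. 0.011, 95% CI 0.207, 0.249)
  t0          3.711  (s.e. 0.245, 95% CI 3.230, 4.192)

Mortality partition (instantaneous yr^-1 / annual proportion)
  Z  0.921   A_Z  0.602
  M  0.464   A_M  0.372
  F  0.457   A_F  0.367
  E  0.496  (F/Z; 0.5 = F = M optimal-yield heuristic)

Length-based reference points (TL_inf = 98.9 cm)
  TL_m    51.659 cm  (95% PI 29.1, 91.6)
  TL_opt  63.801 cm  (95% PI 45.9, 88.7)
  optimum slot  57.4-70.2 cm  (megaspawners > 70.2 cm)
```

The Gompertz family wins the AICc comparison (weight 0.994) and recovers
the generating parameters within their confidence intervals; the
von Bertalanffy asymptote diverges on sigmoid data and is flagged as
biologically unrealistic rather than suppressed. The mortality chain
splits total mortality roughly evenly between natural and fishing
components (E ≈ 0.5), and the policy table shows why a minimum-length
limit is risky here: of the 132 retainable fish under a 40-cm MLL, 73%
are immature, while a 60–70 cm harvest slot contracts the harvestable
catch to 9 fish, all inside the optimum-yield window.

The same assessment runs on a real dataset with
`troutstock assess --input records.csv [--transects transects.csv]`, and
every stage is available as a library call (`LengthWeightModel`,
`GrowthModel`, `chapman_robson`, `compute_reference_points`,
`compare_policies`, ...).

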