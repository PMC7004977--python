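# wildens

Cost-aware comparison of three wildlife density-estimation methods —
non-invasive genetic mark-recapture, camera-trap spatially explicit
capture-recapture (SECR), and removal trapping — built around the
monitoring problem for invasive wild pigs (*Sus scrofa*), where a
manager must pick the cheapest sampling design that still yields a
reliable density.

The package provides, as a tested library plus CLI:

- **Estimators.** A joint multi-habitat Huggins-type closed
  mark-recapture model with behavioral response (`p` vs `c`,
  `N = n/(1-(1-p)^K)`); maximum-likelihood SECR for binary proximity
  detectors with half-normal detection `p(d) = g0·e^{-d²/2σ²}`
  integrated over a habitat mask (Poisson-n form, density `D` a direct
  parameter); and an exact grid-posterior Bayesian removal model
  `r_t ~ Bin(N_t, 1-(1-θ)^{E_t})` that adjusts for nightly trap effort.
- **Density conversion.** Exact buffered-area geometry
  (`A + Pb + πb²`) using the mean-maximum-distance-moved buffer
  (1.123 km).
- **Cost model.** Itemized equipment/consumables/labor ledgers and
  per-method calibrated cost functions anchored to the study's printed
  totals.
- **Effort surfaces.** Bootstrap subsampling (fewer
  transects/occasions; all 47 rectangular camera subgrids × day
  windows) and a clustered-landscape removal simulation, producing
  scaled-bias / variance / cost surfaces per design.
- **Decision tree.** Filters designs to <1% absolute scaled bias and
  full convergence, then recommends by cost or variance under
  decision-maker attributes (removal goal, non-invasive requirement,
  risk aversion, equipment on hand, labor limits).
- **Synthetic data.** Generators with known truth for all three data
  streams: multilocus scat genotypes with qPCR quality, allelic dropout
  and false alleles; camera detection histories; clustered-population
  removal series.

## Worked example

Simulate one study with known truth and run all three estimators:

```python
from wildens import synth, genotypes, closed_cr, secr, removal, costs

scn = synth.SyntheticScenario(seed=1, true_density=2.5,
                              mean_cluster_size=1.0, extent_km=(9.0, 8.0),
                              deposition_rate=0.8, genotyping_success=0.5)
rng = scn.rng()
truth = synth.gen_population(scn, rng)
print(round(truth.true_density, 3))          # 2.5   (realized pigs/km^2)

# fecal DNA -> matching -> closed CR -> density over the buffered transects
samples, _ = synth.gen_fecal(scn, truth, rng=rng)
passing = genotypes.screen_qpcr(samples)                 # C_t <= 36 twice
report = genotypes.match_individuals(
    [genotypes.consensus_genotype(s) for s in passing])
hists = genotypes.build_capture_history(report, passing, n_occasions=6)
_, ests = closed_cr.fit_closed_cr(list(hists.values()))
area = costs.buffered_area(costs.transect_footprint())   # 27.00 km^2
est = next(iter(ests.values()))
print(round(est.N_hat / area, 3))            # 2.638 (fecal CR density)

# camera grid -> SECR (density is estimated directly)
cam, _ = synth.gen_camera(scn, truth, rng=rng)
model, _ = secr.fit_secr(cam, spec=secr.SECRModelSpec(behavior=False, time="none"))
print(round(model.D, 3))                     # 2.506 (SECR density)

# corral-trap removal -> posterior density over the buffered trap grid
_, series = synth.gen_removal(scn, truth, rng=rng)
post = removal.fit_removal(series)
trap_area = costs.buffered_area(costs.grid_footprint(2, 5, 1.0))
print(round(post.N0_median / trap_area, 3))  # 2.084 (removal density)
```

All three estimates bracket the true 2.5 pigs/km², with the removal
estimate lowest — the same ordering the field comparison found.  Cost
of the full designs:

```python
>>> costs.calibrated_cost("fecal", 4, 6)
11355.0
>>> costs.calibrated_cost("camera", 20, 12)
9525.0
>>> costs.calibrated_cost("removal", 10, 14)
11593.0
```

The CLI ties the stages together:

```sh
wildens run-all --seed 1 --n-boot 20 --outdir out/
```

writes the simulated data (CSV), the three fits (JSON), a removal
bias/variance/cost surface (CSV), a decision-tree recommendation
(JSON), and a manifest with the seed and config hash.

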