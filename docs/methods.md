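# Methods

`wildens` implements a cost-aware comparison of three field methods for
estimating the density of a clustered, mobile mammal population —
motivated by invasive wild pigs (*Sus scrofa*) sampled across three
forest habitats over a ~1-month closed period: non-invasive fecal-DNA
mark-recapture along transects, a camera-trap grid analysed with
spatially explicit capture-recapture (SECR), and corral-trap removal
analysed with an effort-adjusted catch-effort model.  This note
documents the models, their assumptions, the numerical choices, and
what the synthetic-data experiments do and do not demonstrate.

## Closed-population mark-recapture (fecal DNA)

Genotyped scats yield per-habitat detection histories over K = 6
occasions.  We maximize a Huggins-type conditional likelihood: each
individual contributes Bernoulli terms with first-detection probability
`p` (by habitat in the default `Mb_habitat` structure) and redetection
probability `c` (shared), conditioned on being detected at least once.
Abundance follows as `N = n / (1 - (1-p)^K)`; its variance combines the
binomial component `n(1-π)/π²` with a delta-method parameter term using
an exact central-difference Hessian.  The 95% interval is lognormal on
`N - n`, the closed-CR convention, because the sampling distribution of
`N` is right-skewed.  Structures `M0`, `Mt`, `Mb`, and per-habitat `c`
are available; the two-occasion `Mt` fit coincides with the
Lincoln–Petersen closed form, which the tests use as an oracle.

Assumptions: demographic and geographic closure over the study window,
correct individual identification, independent habitats.  The
behavioral-response MLE can diverge (`p → 0`) in a small percentage of
weak datasets; such fits are visible as absurd `N` with huge SE and are
the known boundary pathology of `Mb`-type models, not a numerical bug.

Genotype pipeline: samples pass a qPCR quality screen when both
extractions amplify at C_t ≤ 36; consensus genotypes require each
allele in ≥ 2 of 3 replicate PCRs; samples typed at fewer than 8 of 9
loci are excluded (operationalizing "more than 7 loci").  Samples
differing at one allele merge only when the mismatched locus was
heterozygous in at least one replicate of either sample — the allelic
dropout signature; merges close transitively, and flagged pairs are
reported (the wet-lab verification re-run is modelled as this flag,
with merging as the default resolution).  Panel power is summarized by
the sibling identity probability per locus,
`P = 1/4 + S2/2 + S2²/2 - S4/4` with `S2 = Σp²`, `S4 = Σp⁴`, multiplied
over loci; the default synthetic panel (9 loci × 6 even alleles) gives
≈ 7×10⁻⁵, comfortably below the 7×10⁻⁴ working threshold.

## Spatially explicit capture-recapture (cameras)

Binary proximity detectors: a camera can record each individual at most
once per 24-h occasion.  Detection is half-normal,
`p(d) = g0 exp(-d²/2σ²)`, with σ per habitat and optional effects on
logit(g0): a learned behavioral response (animal-level, applying to all
occasions after first detection anywhere — the plain reading of
"behavior"), and a linear time trend (a full 11-level occasion factor is
available by configuration but is fragile at this sample size, so the
trend is the default).  Activity centres are integrated over a regular
habitat mask (endpoint-inclusive lattice; default buffer 4×(initial σ),
spacing buffer/10, initial σ from MMDM/2); the number detected uses the
Poisson form, so density D enters the likelihood directly and sessions
(habitats) share D by default.  Variance comes from the numeric Hessian
on log D with a lognormal CI.

Fits are refused below the sufficiency rule — fewer than 40 total
detections or no individual at two distinct detectors — which is the
empirical threshold below which such models stop converging.  Mask
convergence (D stable to <1% under refinement and buffer growth) is
verified in tests.  With a single mask point and no effects the
likelihood reduces exactly to the non-spatial Poisson-N closed-CR
likelihood, which provides a degenerate-geometry oracle.

## Effort-adjusted removal model (trapping)

Removals `r_t` deplete the population:
`r_t ~ Binomial(N_t, 1-(1-θ)^{E_t})`, `N_t = N0 - Σ_{s<t} r_s`, with θ a
per-trap-night capture rate and `E_t` the active traps that night.  The
posterior is computed exactly on a grid — N0 discrete-uniform on
`[Σr, 10·Σr]`, θ on a 400-point midpoint quadrature with a Beta(1,1)
prior — giving reproducible medians, equal-tailed 95% intervals, and
the joint mode.  Fits are flagged (not silently reported) when total
catch is below 10 (hard) or 20 (soft), and when the upper posterior
tail presses against the N_max bound, the signature of a flat,
non-declining catch.

A note on the classical two-pass closed form `N = c1²/(c1-c2)`: it
solves the Stirling-approximated score equation, not the exact one.
For catches 50/25 the exact binomial posterior mode is N = 96; the
closed form re-emerges exactly as the conditional mode over N at the
two-pass capture rate (the likelihood ratio `L(N)/L(N-1)` crosses 1 at
`T/(1-q^K)`).  Both facts are asserted in the test suite; the package
reports the exact joint mode.

## Density conversion and geometry

Abundance-based methods divide by a buffered effective area: the convex
envelope of the sampling footprint buffered by the mean maximum
distance moved (MMDM = 1.123 km).  For a convex region of area A and
perimeter P the buffered area is exactly `A + Pb + πb²` (segment:
`2Lb + πb²`; point: `πb²`), computed from the shapely convex hull rather
than a discretized polygon buffer.  The four-transect footprint
(4 km × 2.25 km) gives 27.00 km².

## Cost model

Costs are itemized (equipment / consumables / labor, field / lab) with
quantities driven by a small rule grammar (constant, per unit, per day,
per unit-day, per sample).  Calibrated per-method totals anchor to the
printed study figures: fecal `4255 + 710·(T+D)` USD (the $710 saving
per transect or occasion; the low-effort corner evaluates $1 above the
printed total — a rounding artifact in the source, reported as such);
camera `2024 + 184·K + 15.92·K·D` with the per-camera kit price fixed
($159 camera + $25 card/mount) and the remaining two coefficients
solved from the printed endpoints; removal `2023.7 + 909.8·R + 3.37·R·D`
solved exactly from three printed anchors.  The default ledgers
reproduce these totals item-by-item; category shares are structural
defaults (fecal labor-dominated, camera equipment-led with photo-review
labor on camera-days, removal led by trap hardware), not published
percentages.  Monetary values are rounded to whole dollars only at
presentation.

## Effort-reduction surfaces

For fecal CR and SECR, reduced designs are evaluated by bootstrap
subsampling of the data (uniform transect/occasion subsets; rectangular
camera subgrids — all 47 reduced configurations of the 4×5 grid with ≥6
cameras — crossed with uniformly placed contiguous day windows),
refitting from scratch, and recording the scaled bias
`(D_reduced - D_full)/D_full`, the variance of the replicate estimates,
the calibrated cost, and the fraction of replicates that converged.
Day windows are contiguous to preserve the behavioral/time structure.
Full-effort cells are deterministic with scaled bias exactly zero.
Default 100 replicates per cell with a fixed seed.

Removal designs cannot be subsampled without breaking closure (removed
animals stay removed), so they are evaluated by forward simulation: a
Poisson cluster process of activity centres (cluster intensity
density/mean-size, zero-truncated Poisson sizes with mean 6 — a typical
sounder — members scattered with SD 0.3 km) mimics gregarious social
structure; traps are placed one per 1-km² cell of a centred block;
nightly encounters follow a truncated Gaussian in distance (σ from the
SECR movement scale, truncated at 3σ — the source gives no radius),
with capture-given-encounter θ_enc = 0.025, calibrated once so that the
field design (10 traps × 14 nights at 2.5 pigs/km²) removes ≈ 20
animals per site, matching the observed catch.  The effective area a
design samples is estimated by OLS of implied area (N̂ / true density)
on trap count and nights; because that surface is convex, the fitted
plane can dip below zero at the smallest designs, so predictions are
floored at the smallest implied area observed during calibration — a
transparent clamp that keeps the density conversion defined everywhere.

## Decision tree

Candidate designs must have |scaled bias| < 1% (strict) and all
replicates converged.  Branches then apply in order: population
reduction as a goal restricts to removal trapping; a non-invasive
requirement excludes it; equipment on hand zeroes the matching purchase
items before costing (lab access changes nothing by default because lab
work is assumed sent out with no equipment purchase); risk-averse
decision makers minimize variance, others minimize cost with the labor
share breaking ties when labor is the binding constraint; remaining
ties resolve deterministically to fewer units, then fewer days.  The
recommendation carries the ordered list of branch decisions applied.

## Synthetic data: what it does and does not show

The generators draw one clustered population with known truth that can
feed all three samplers (the field study ran them sequentially on a
changing population; an independent-truth mode is available by drawing
separate populations).  Defaults encode the study conditions: density
2.5 /km² (within the 1.07–2.74 regional range), σ = 0.7 km, a qPCR
quality model calibrated so ~20% of scats pass the screen (the observed
genotyping rate), allelic dropout 5% and false alleles 0.5% per
replicate, g0 = 0.15, and the removal calibration above.  Scat
deposition is a thinned process that decays half-normally with distance
from the nearest transect — a modelling convenience, not a measured
deposition model.

Passing recovery tests therefore show that each estimator is correctly
implemented and approximately calibrated *under its own assumptions*
(plus controlled violations such as clustered centres for the removal
simulation).  They do not validate field performance: real scat decay,
bait attraction, camera misidentification, trap shyness, and closure
violations are all outside the generators.  Recovery experiments use
CSR populations (cluster size 1) where the fitted model assumes a
homogeneous Poisson process; clustered populations inflate the variance
of realized density and are used where group structure is the point.

## Problem sizes and reproducibility

Simulation-based tests use 100 replicates per claim (bootstrap cells
default to 100, reduced to 5–50 in some tests) with fixed seeds; every
generator takes an explicit seed or `numpy` Generator and is
reproducible bit-for-bit.  `scripts/acceptance.py` recomputes the
fixture totals, geometry, cost anchors, closed-form oracles, one full
synthetic study through all three estimators (≈ 180 animals), the
removal calibration (100 landscapes), and credible-interval coverage
(100 series) in well under a minute of compute.

## Known limitations

- The behavioral-response CR likelihood can hit the `p → 0` boundary on
  weak data; divergent fits are identifiable but not automatically
  censored.
- SECR assumes an unbounded homogeneous landscape; simulated
  populations are confined to a finite extent, so masks larger than the
  populated region mildly bias D downward (test extents are chosen to
  contain the default mask).
- The camera cost function is underdetermined by the two printed
  endpoints; the per-camera kit price is fixed by assumption.
- The effective-area plane is a first-order summary of a convex
  surface; its floor at small designs is a pragmatic clamp.
- Per-habitat `σ` and shared `D` follow the study's model; habitat-level
  density differences are only recoverable via the abundance-based
  methods.
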