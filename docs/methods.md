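# Methods

## The assessment model

`streamvuln` treats climate-change vulnerability as three separately
falsifiable claims about a species, each evaluated on habitat-suitability
surfaces defined over stream subcatchments:

1. **Exposure.** The environment of the species' *current* habitat moves
   away from what the species experiences today.  For each exposure factor
   the departure is `mean |future − current| / SD` over the subcatchments of
   the current (dispersal-weighted, thresholded) habitat.  The working
   assumption is that a species copes with variation comparable to what its
   range already spans, so the default SD is the spatial SD of current
   values across that same habitat; callers with inter-annual series can
   supply external SDs instead (`sd_mode="external"`).  Departures are
   absolute — a shift is a shift in either direction.  Flags: any factor
   > 2 SD, or ≥ 2 factors > 1 SD ("multiple" read minimally as two), or a
   sea-level rule: ≥ 10% of suitable subcatchments with mean elevation
   ≤ 1 m.  The seven modelling factors map onto five exposure factors
   (temperature mean/seasonality, precipitation mean/seasonality, flow);
   the precipitation mean is the row-mean of the wettest- and
   driest-quarter values, and the mapping is configurable.

2. **Sensitivity.**  `S = (ΣHS_cur − ΣHS_fut) / ΣHS_fut` after zeroing
   suitability below the species' TSS threshold τ.  S is scale-free,
   negative for expanding species, 1 exactly when future totals halve, and
   flagged (strictly) above 1.  A species with no thresholded future
   suitability at all is reported `degenerate` with S = NaN and
   sensitive = True rather than an infinity: reports stay finite and
   sortable.  Negative S is kept raw in records; clamping to zero happens
   only in priority maps, where an expanding species should add nothing
   rather than subtract.

3. **Dispersal pressure.**  Reachability is a four-parameter logistic
   kernel of least-cost distance.  Costs: land 1, open water 2 (barrier
   scenario: 100).  Distances are 8-connected shortest paths with step
   weight `cell_size × mean(end-point costs) × √2 (diagonals)`, computed
   with Dijkstra on the sparse grid graph; a subcatchment reads its
   distance at the member cell nearest its centroid, from the species'
   occupied cells (minimum over records).  Kernel: a = 1, c = 0,
   d₀ = 300/630/1080 km (current/2055/2085; the two future horizons encode
   15 km yr⁻¹), steepness b = 4 by default so k ≈ 0.99 at 0.3 d₀ and
   k ≈ 0.06 at 2 d₀ — a sharp but not cliff-edged cut around the threshold.
   The pressure score combines (i) a one-sided rank-sum comparison of
   record-to-habitat distances, current vs future habitat (z ≥ 1.96 → 1
   point, z ≥ 3 → 2; an empty future habitat scores 2 with a sentinel
   infinite z), and (ii) a 30-level sweep of d₀ from the future threshold
   down to 300 km: within each tercile of levels, OLS of S on ln d₀; the
   first tercile (high, then medium, then low) with slope ≤ −1 scores
   3/2/1.  Since S(d₀) is non-increasing in d₀, meaningful slopes are
   negative and the cut is applied as ≤ −1.  Total ≥ 3 of 5 flags pressure.

Flags combine into categories 1 (all three), 2 (exposed + sensitive),
3 (exposed + pressured), 4 (sensitive + pressured); the remaining four
combinations are reported LC with their component flags preserved so users
can re-bin.  Priority maps score subcatchments by Σ max(S,0) × HS over
Category-1/2 species, suitability again thresholded at τ.

## Suitability modelling around the assessment

The assessment is agnostic to the SDM algorithm; the package fits any
scorer exposing `fit(X, y)` / `predict(X)` behind `register_scorer`.  The
built-in scorer is a product-Gaussian niche
`P(presence|v) = peak · Π_f exp(−((v_f−opt_f)/tol_f)²/2)` fitted by
maximum likelihood (L-BFGS-B on standardized factors, three starts to guard
against local minima, zero-variance factors dropped with a warning).  The
default build fits 5 seeded replicates on 70/30 presence/absence splits
(configurable to 10); each replicate's held-out TSS, floored at zero,
becomes its ensemble weight, and the projection is the weight-normalised
mean.  τ maximises TSS of the *ensemble* scores over all localities (the
per-replicate alternative is a config flag away in spirit: thresholds are
recorded per replicate in the evaluation report).  Pseudo-absences are
taken from background localities of other species within a 300 km
Euclidean radius of any presence (excluding presence subcatchments), topped
up by random subcatchment centroids to a standard total.  Projections into
novel environments are clamped: a subcatchment with more than one factor
outside the fit's training limits has suitability multiplied by 0 (the
penalty is configurable); one exceedance is tolerated as reasonable
gap-filling extrapolation.  Binarisation is inclusive: suitable iff
HS ≥ τ, so τ itself remains a suitable score.

## The synthetic study system

The generator emulates the statistical structure the assessment consumes,
not any real geography:

- **Landscape.**  Elevation is a Gaussian-smoothed random field rescaled to
  [0, 1200 m]; the lowest `sea_fraction` of cells become sea, and whenever
  there is any sea a full-width strait is carved near the southern edge,
  separating an island landmass from the mainland — the geography the
  barrier scenario probes.  Land cells adjacent to water are forced below
  1 m so the sea-level rule is exercisable.  Subcatchments grow by seeded
  region-growing from random land cells: contiguous, irregular units
  without hydrological modelling.  Demo grid: 50×50 cells of 40 km, i.e. a
  2000 km domain on which the 300–1080 km kernel thresholds actually bite.
- **Factors.**  Seven factors with continental flavour: temperature falls
  poleward and with elevation, precipitation and flow swing coast-to-
  interior, and each factor carries independent local noise.  Future
  stacks add per-subcatchment Normal(shift, SD) anomalies; the default
  tables follow a high-emissions trajectory (≈ +1.8 °C by 2055, roughly
  doubled by 2085, with drying).  Null anomalies reproduce the current
  stack exactly.
- **Species.**  Ground-truth niches are product-Gaussians anchored at the
  realized factor vector of a random subcatchment (jittered, clipped to the
  realized range), tolerances 0.5–1.5 × the factor's spatial SD, peak
  0.6–0.95.  Each species' home region is its anchor's landmass: records
  are confined there even where other landmasses are climatically suitable,
  emulating dispersal-limited ranges (island endemics and mainland species
  that have never crossed the strait).
- **Sampling.**  Records are drawn with probability ∝ occupancy × bias,
  bias = exp(−bias_strength · d / L) with d the distance to the nearest
  designated bias centre ("towns") and L the landscape diagonal — so
  bias_strength 0 is exactly unbiased and larger values concentrate
  records, one knob.  Years, life stages and sexes are uniform window
  draws; they exist so readers and filters can be tested.

What the generator does *not* emulate — flow accumulation and hydrological
routing, spatially correlated anomaly fields, niche interactions between
factors, imperfect detection, taxonomic error — bounds what green tests
mean: they certify the scoring machinery against a known truth, not the
realism of any particular continental projection.

## Numerical choices and edge cases

- Exposure with zero SD raises, naming the factor (a uniform current field
  cannot scale departures).
- Rank-sum z uses midranks and tie-corrected variance; the one-sided p
  applies the usual 0.5 continuity correction (the exact-enumeration mode
  does not need it).  Score thresholds act on the plain z.
- Sweep levels are equally spaced on the linear distance scale (log
  spacing is a flag); regressions use the 10 points of each tercile.
  A level where thresholded future suitability is zero has undefined S and
  is dropped from its tercile's regression; a tercile left with fewer than
  two finite points counts as qualifying (habitat vanished there, the
  strongest possible dependence), and a species degenerate at *every* level
  scores 3 with a flag.
- Distance fields can carry +inf (unreachable); the kernel maps +inf to
  suitability 0 regardless of its lower asymptote.
- AUC uses the midrank convention; the TSS threshold search scans every
  distinct predicted score and returns the smallest maximiser.
- The pipeline skips (and logs) individual species whose fit or assessment
  degenerates — e.g. a species never modelled as present — rather than
  aborting the stage; genuine stage failures abort with the stage name.
- All randomness descends from one master seed through named
  `SeedSequence` spawns; reports are byte-identical across reruns and every
  output file carries the config hash and seed.

## Problem sizes

The default demo assessment uses a 50×50 grid (2000×2000 km), 400
subcatchments, 30 species × 150 records, 300 pseudo-absences, 5 ensemble
replicates and two future horizons, and completes in well under a minute on
one CPU; scorer-recovery checks use a 30×30 grid with 250 subcatchments and
20 replicates of 300 records.  These sizes were chosen as the smallest at
which every mechanism (strait crossing, threshold sweep, roster cutoffs)
operates with headroom.

## Known limitations

- The built-in scorer assumes independent Gaussian responses per factor;
  with strongly collinear factors (e.g. mean and coldest-month temperature
  sharing a latitudinal gradient) individual optima are weakly identified
  even when predictions are accurate — an intrinsic property of the
  estimation problem, visible in the recovery diagnostics.
- Sensitivity compares totals only; there is no per-subcatchment
  decomposition of where value is lost.
- The sea-level rule acts through subcatchment mean elevation only; there
  is no inundation or salt-intrusion modelling.
- Priority maps are weighted sums, not complementarity-based reserve
  selection.
- The narrative link between an SD of exposure and the share of habitat
  outside the current environmental extent depends on a distributional
  convention the method does not fix; it is documentation, not a computed
  quantity.
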