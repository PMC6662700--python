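# Methods

`eetolab` studies the explore–exploit trade-off (EETO) in commercial
fishing fleets: how the breadth of a vessel's fishing-ground portfolio
relates to its revenue, and whether a history of exploration buffers
revenue when a spatial closure abruptly removes part of the grounds.
Because real vessel-monitoring (VMS) and logbook data are confidential,
the package pairs the analysis pipeline with a synthetic fleet generator
that emulates the structure of such data; every stage is exercised end to
end on generated data.

## The analysis pipeline

### Track processing

Hourly position reports (pings) are cleaned by (i) an extent filter, (ii)
duplicate/ordering repair, and (iii) an iterative speed filter: per-ping
arrival speed is derived from the rhumb-line (loxodromic) distance between
successive pings on a sphere of radius 6,371,000 m divided by the elapsed
time, and pings arriving faster than 20 m/s (a physically implausible speed
for a fishing vessel) are deleted. Deletion is iterative: after removing an
outlier, the successor's speed is recomputed against the new predecessor,
and only the first ping of a consecutive fast run is removed per round, so
a single bad fix never drags its neighbours out with it. Cleaning is
idempotent and no retained ping exceeds the threshold.

Each interior ping (one with both a predecessor and a successor) yields six
movement features: speed (m/s), turning angle (degrees in [0, 180], from
successive local-planar courses), depth at the ping position (m), hour of
day (UTC), displacement from port (km, rhumb), and a centred 3-ping moving
average of speed. This closed feature list is the smallest set that
separates the three behavioural regimes the generator produces (fishing
< 2 m/s, transit ≈ 5 m/s, port ≈ 0 m/s at the harbour).

Activity is classified by a 500-tree random forest. The observer-labeled
subset is split into equal training and testing halves (stratified); the
forest is fitted on the training half and its fishing/non-fishing
**balanced accuracy** — the mean of the true-positive and true-negative
rates after collapsing activities to fishing vs non-fishing — is computed
on the reserved half and stored before any deployment use. Pings within a
configurable 2 km port radius are labeled `port` by rule at prediction
time.

### Fishing grounds and visitation series

Fishing pings are rasterized onto a 30 × 30 grid fitted to the bounding box
of the whole fleet's fishing activity. Cells are half-open `[low, high)`
with the maximal row/column closed above so every point is assignable.
Consecutive fishing pings in one cell collapse into a visit bout; a new
visitation element is appended when the fished cell changes or after any
port call (a revisit after a port call repeats the element — the entropy
below depends only on frequencies, so adjacency is immaterial). Bout
duration is `(last − first ping time) + one ping interval`, giving
single-ping bouts one interval of residence. The chronological bout-cell
sequence `L_i` is vessel *i*'s visitation series. A per-ping mode (one
element per fishing ping) is available for sensitivity checks.

### Strategy metrics

**Choice entropy.** For each prefix of length *m* of `L_i`, with `f_i(j)`
the empirical frequency of location *j* among the first *m* choices and
`N_im` the number of distinct locations so far,

```
S_im = − Σ_{j=1..N_im} f_i(j) · log2 f_i(j)        (bits)
```

computed incrementally and verified against a brute-force per-prefix
recount. The trajectory satisfies `0 ≤ S_im ≤ log2(N_im)`, `S_i1 = 0`, and
its endpoint is permutation-invariant. The strategy score `S` is the mean
of the trajectory after a burn-in of `floor(|L_i| / 2)` elements (the floor
convention is a deliberate tie-break; the score is insensitive to it for
trajectories long enough to pass the sparse-vessel filter). Vessels with
fewer than 20 visitation elements are excluded as sparse.

**Patch residence time (PRT)** is the arithmetic mean bout duration in
hours. Grid-level PRT is attenuated relative to the generative bout scale
because long bouts occasionally straddle cell boundaries; rank order is
preserved, which is what the downstream standardized regressions use.

**Displacement** is the fraction of a vessel's pre-closure fished cells
whose centers fall inside the closure polygon (0.8 = 80% of grounds lost).
Cell centers keep the unit consistent with the gridded portfolio.

**Activity** is the sum of trip durations (days) landing in a lagged
window that precedes the modeled period, keeping the covariate exogenous.

Diagnostics: entropy scores are recomputed on grids from 20 × 20 to
95 × 95 and Spearman-correlated against the 30 × 30 scores; `S` is
regressed on mean fishing depth (reported, not asserted) to check the
metric is not an inshore/offshore gradient in disguise; and `S` is
regressed on revenue per kilometre traveled (per-vessel total revenue over
summed inter-ping rhumb distances) to quantify the travel cost of
exploration.

### Business-as-usual model and deviance

Undisturbed trip revenue is modeled by OLS with vessel fixed effects:

```
Ru_it = P_i + β1·D_it + β2·F_−it + ε_it
```

where `D_it` is trip duration (days) and `F_−it` the leave-one-out fleet
index: the mean revenue of *other* vessels' trips landing in the half-open
two-week window after trip *t*. The trailing window avoids mixing
post-closure revenues into pre-closure indices; trips landing in the two
weeks before the closure are pruned for the same reason, and a comparison
against a symmetric ±7-day window is reported as a bias check. Absolute
per-vessel performance is the reference-coded estimate plus the intercept.
An automatic outlier rule removes any revenue exceeding 5× the next
largest, iteratively, replacing a manual screen so unattended synthetic
runs behave.

For each disturbed trip, measured performance strips the trip-level terms
from observed revenue, and deviance standardizes it against the vessel's
business-as-usual performance:

```
Md_it = Rd_it − β̂1·D_it − β̂2·F_−it
ΔP_it = Md_it / Ed_it − 1,     Ed_it = P̂_i
```

`Ed_it = P̂_i` is the expected value of `Md_it` absent disturbance, so
`ΔP` is centred on zero under business as usual — the property the null
calibration tests assert. (Defining `Ed` as the full revenue prediction
`P̂_i + β̂1·D + β̂2·F` would compare a duration/fleet-stripped numerator
with an unstripped denominator and is offered only as a diagnostic via
`include_trip_terms=True`.) A log-revenue mode applies the whole chain on
the log scale; the identity link is the default because the deviance
arithmetic is linear.

### Inference

Covariates are standardized to zero mean, unit sample SD; quadratic terms
are squares of the standardized linear terms, so the "humped strategy"
test is centred on the fleet mean. Pre-closure performance is regressed on
S, S², prt, prt², activity and length by OLS. Disturbed-period deviance is
fitted by a linear mixed model with a per-vessel random intercept
(restricted maximum likelihood; Wald-normal p values and CIs; a singular
random-intercept variance triggers an OLS fallback with the variance
pinned at zero and a `singular_` flag — which also covers the degenerate
one-trip-per-vessel case exactly). Backward stepwise selection drops a
term only if neither AIC nor BIC increases, never removes a linear term
while its quadratic partner remains, and stops at the first fixed point.
Fleet-level strategy shifts (before vs during the closure) are tested by
one-way ANOVA. The growing-window analysis refits the full deviance model
on nested subsets `[0, 10], …, [0, 50]` days since closure, tracing each
coefficient's trajectory; windows too sparse to fit are flagged, and the
final window reproduces a direct fit on all ≤50-day data by construction.

## The synthetic fleet generator

The generator emulates the *structure* of VMS/logbook data, not the Gulf
of Mexico itself. The default world is a shelf with a single port on the
northern coast, a deterministic depth surface (linear offshore gradient
plus two smooth ridges), a 24 × 24 lattice of candidate fishing sites, and
a rectangular core of preferentially used sites that is closed at the
disturbance.

Per vessel: portfolio size ~ uniform{2..20}; choice weights ~ symmetric
Dirichlet with log-uniform concentration in [0.3, 6] (low concentration =
skewed, low-entropy chooser); sites drawn without replacement around a
random home center with spatial spread growing with portfolio size, so
broad explorers also travel farther — producing the negative
revenue-per-km relationship; mean bout duration ~ uniform[6, 48] h
(bouts lognormal, shape 0.5); skill `P_i` ~ Normal(10 000, 1 500) revenue
units; length ~ uniform[15, 30] m. Vessels alternate exponential port
stays (mean 3 d) with trips of planned length uniform[2, 15] d; trips are
transit legs (~5 m/s, hourly pings along the leg) alternating with fishing
bouts (positional jitter SD 0.004°, implying speeds well under 2 m/s),
sampled from the choice weights with replacement. Trip revenue is

```
Ru_it = P_i + β1·D_it + β2·F_t + ε,   β1 = 800/day, β2 = 1, σ_ε = 500
```

with `F_t` a fleet-wide daily factor: a seasonal sinusoid (amplitude
1 000) plus AR(1) shocks (SD 300, lag-1 correlation 0.8). A fraction
(default 20%) of trips carries per-ping observer activity labels.

At the closure, each vessel exits with probability
`logistic(exit_baseline − exit_entropy_coef · z(S_true))`
(defaults 0 and 1.5: broad explorers tend to stay). Survivors fish only
outside the polygon (weights renormalized; a fully displaced vessel
relocates to fresh outside sites). Disturbed revenue perturbs the
performance component,

```
Rd_it = (1 + δ_it)·P_i + β1·D + β2·F + ε
δ_it = (a·z(S) − b·z(displacement)) · 2^(−days/halflife) + η
```

so a generated δ is recoverable on the ΔP scale (fleet-mean ΔP ≈ δ). The
effect sizes `a = b = 0.2` (per SD), `σ_η = 0.05` and half-life 20 d are
free parameters of the design, sized once by a pilot power analysis so the
decay is resolvable across 10-day windows (≈2 SE per step) at the default
scale of 100 vessels; they were not revisited afterwards.

All randomness descends from a single root seed with independent
per-vessel sub-streams, so fleets are bit-for-bit reproducible and stable
under fleet-size changes.

**Default scale.** 100 vessels, one undisturbed year and a 50-day closure
at hourly pings (~0.9 M pings). Multi-seed recovery, calibration and
dissipation studies use the generator's trip-level fast path
(`simulate_trip_table`) — the same cadence and revenue model without
hourly track synthesis — and supply the latent fleet factor as the fleet
index, isolating the estimator's properties from the sampling noise of the
empirical leave-one-out proxy. The pipeline itself always uses the
empirical index. Unit and property tests run reduced fleets (8–40 vessels,
60–250 days), chosen as the smallest sizes at which each property is
comfortably resolved.

**What the generator does not emulate.** Real bathymetry and coastline
geometry; gear mechanics and catch composition; market-price
microstructure; multi-gear fleets; spatial autocorrelation of revenue
beyond the shared fleet factor; information sharing between vessels.
Passing tests therefore demonstrate the pipeline's correctness and
statistical calibration under a controlled data-generating process, not
ecological conclusions about any real fishery.

## Numerical choices and edge cases

- Rhumb distances use the standard Mercator-stretch formula with the
  east–west limit `q = cos φ` when Δψ < 1e−12; longitudes wrap across the
  antimeridian; pole latitudes are rejected.
- The entropy recursion tracks `Σ c·log2 c` and clips the −0.0 that
  floating subtraction produces on single-location prefixes.
- The fleet-index window is half-open `(t, t + 14 d]` on landing dates.
- Stepwise ties (equal AIC/BIC) favour the simpler model; among qualifying
  drops the lowest AIC wins.
- Zero-variance covariates, empty portfolios, empty visitation series,
  single-class label sets, and sub-3-ping vessels all raise or warn
  explicitly rather than propagating NaNs.
- Mixed-model AIC/BIC comparisons across different fixed-effect sets
  should use maximum likelihood (`reml=False`); reported fits use REML.

## Known limitations

- Grid-level PRT is attenuated by bout splitting at cell boundaries
  (rank-preserving, level-biased).
- The empirical leave-one-out fleet index absorbs part of the revenue
  level into the fleet coefficient, shrinking absolute `P̂_i`; deviances
  remain centred but are scaled relative to a latent-factor fit. This
  mirrors what any real-data application of the same index does.
- Mixed-model p values rely on the Wald normal approximation; no
  small-sample degrees-of-freedom correction is applied.
- The activity classifier is validated on observer trips drawn from the
  same generative process as deployment data; transfer error on real
  observer programs is out of scope.
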