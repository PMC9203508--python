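# Methods

`nichecast` implements an ensemble species-distribution-modelling (SDM)
pipeline for presence-only marine occurrence data: occurrence quality
control and gridding, environmental-space preparation with convex-hull
pseudo-absences, calibration and selection of eight niche-modelling
algorithms by cross-validated Continuous Boyce Index (CBI), delta bias
correction of general-circulation-model (GCM) fields, and projection of
an Environmental Suitability Index (ESI) under Representative
Concentration Pathway (RCP) scenarios, summarised as range-change
percentages and Exclusive Economic Zone (EEZ) means.  Because the
pipeline's contracts are what matters, every stage is exercised against
a synthetic world whose niche truth is known analytically.

## The model

The quantity modelled is the per-cell ESI ∈ [0, 1]: how suitable the
local environment is for the species.  The ensemble assumptions are the
standard SDM ones — niche conservatism (the realized niche is stable in
time) and the equilibrium hypothesis (the species occupies the suitable
space) — plus the usual presence-only caveat that sampling effort is
spatially heterogeneous, which the environmental filter and the
convex-hull pseudo-absence design mitigate.

### Occurrence preparation

Records are dropped when flagged unreliable, when exact duplicates
(after rounding coordinates to 4 decimals — database re-submissions),
when on land or outside the domain, or when geographic outliers.
Records dated ≥ 1990 are kept unconditionally; older or undated records
survive only within `edge_distance` (default 100 km) of a recent record
— the "distribution edge confirmed by recent records" rule
operationalised with an explicit radius, since only the intent is
standard.  Outliers are records farther than `outlier_distance`
(default 1000 km) beyond the 99% spatial-density envelope (radius from
the median centre); a deliberately simple, testable stand-in for a rule
that has no canonical definition.  Cleaned records are aggregated to
one presence per occupied 0.1° cell (half-open cell intervals).

Candidate habitat is screened hierarchically: a marine cell passes if
its depth lies in the species' observed depth range (default
150–1000 m), or else if it lies within 50 km of the coast — so narrow
shelves do not exclude near-coastal habitat.

### Environmental space

Among the ten candidate layers, variables are retained greedily in a
priority order, keeping a variable only if |Pearson r| ≤ 0.7 against
every already-kept variable at presence cells.  In the synthetic world
this reproduces the classic outcome: the bottom-temperature seasonal
range and monthly variance are collinear (r ≈ 0.8+) and only the
higher-priority range survives, leaving SBT, SBTr and Log_PP as the
informative set.

Presences are thinned to one per occupied bin of a 0.5-unit grid in
environmental space (0.5 °C for temperature variables, 0.5 psu for
salinity, 0.5 log-units for primary production; the log-scale width is
the only scale-free reading for PP).  The retained observation per bin
is the most recent record, ties broken by lowest cell id — a
deterministic rule that makes thinning idempotent and order-invariant.

Pseudo-absences equal the filtered presences in number and are drawn
uniformly without replacement from the realized environments of
habitat-screened marine cells lying strictly outside the trimmed convex
hull of presence environments.  Trimming removes points outside any
per-variable [2.5, 97.5] percentile interval before the hull is built
(per-variable trimming matches the hull's definition as "occurrences
within the percentiles for each parameter").  Hull membership uses facet
half-space tests with tolerance 1e−9; boundary points count as inside,
so pseudo-absences are strictly exterior.  Sampling from realized cell
environments (rather than abstract space) means every pseudo-absence
maps to a geographic cell.

### Algorithms

Eight candidates: NPPEN, GLM, GAM, GBM, ANN, FDA, MARS, RF.  All share
one contract — fit on the presence/pseudo-absence table, predict
ESI ∈ [0, 1] at any finite environmental point, bit-identical refits
given identical data and seed.

NPPEN is presence-only and non-parametric: with reference matrix Y
(thinned presence environments), centroid μ and covariance Σ, a
candidate x is scored by the rank of its squared Mahalanobis distance
D²(x) = (x − μ)ᵀΣ⁻¹(x − μ) within the reference distances — ESI is the
fraction of reference points at least as far from the centroid,
a permutation-style p-value of niche membership (the ≥ convention means
a reference point itself never scores zero).  A singular Σ falls back
to a ridge-regularized inverse (ε = 1e−8) with a warning.  The
implementation is pinned by a brute-force Monte-Carlo oracle in the
test suite and is affine-invariant by construction.

The other algorithms use explicit frozen defaults rather than some
external package's unstated ones: GLM is a binomial/logit fit with
linear + quadratic terms; GAM a binomial GLM on per-variable cubic
B-spline bases (df = 4, constant extrapolation beyond the training
range); GBM gradient boosting with 2500 trees, depth 3, shrinkage
1e−3; ANN a single hidden layer of 5 units, best of 3 restarts; RF 500
trees; MARS a forward-stepwise hinge-basis expansion (≤ 13 terms,
second-order interactions, 12 candidate knots per variable) refitted
with a logistic link so scores live on [0, 1]; FDA its classical
formulation — linear discriminant analysis on the adaptively selected
hinge basis — with a logistic squash.  MARS and FDA are implemented
in-package in their textbook forms.

### Evaluation and selection

Each algorithm is evaluated on ten independent random 70/30 splits.
CBI slides 101 windows of width 0.1 across [0, 1]; per window the
predicted-to-expected ratio P/E compares the share of hold-out presence
predictions to the share of all hold-out predictions, windows with zero
expected share are dropped (not imputed), and CBI is the Spearman
correlation of window midpoints against P/E.  An algorithm is retained
iff its mean CBI over the ten runs exceeds 0.5 *and* all its response
curves (covariates swept with the others at training medians) are
plausible — at most one interior local maximum with prominence above
0.02 ESI after light smoothing; the named spurious case is a bimodal
thermal response.  Only unimodality is screened; no further "a priori
expectations" are encoded.  An empty retained set is a hard error.

A calibration caveat established by the null simulations: with 1000
presence and 1000 background predictions, single-run null CBI scatters
far beyond ±0.3 (values up to ≈ 0.7 occur) because the 101 overlapping
windows correlate the P/E noise, leaving the Spearman statistic few
effective degrees of freedom.  "CBI ≈ 0 for a random model" holds in
expectation, and the calibration tests therefore bound the mean over 20
replicate seeds rather than each seed.

### Climate pre-treatment and projection

Coarse future fields are regridded bilinearly to the 0.1° grid (edge
cells take the nearest coarse value; no extrapolation), decade-averaged
over 2030–2039, 2050–2059 and 2090–2099, and delta-corrected per cell:
`corrected = gcm_future + (obs_common − gcm_common)`.  On the common
period this reproduces the observations exactly — r = 1, zero centred
RMSD, equal SD (Taylor convention: centred RMSD with the mean bias
reported separately, under which the identity holds either way) — while
leaving the simulated change signal untouched.  Temperature-derived
variables are corrected additively; primary production multiplicatively
(an additive shift in log space with the implied ratio clamped to
[0.1, 10] to preserve positivity); salinity is held constant in time.
Because the correction is linear, averaging then correcting equals
correcting then averaging; the pipeline averages first.

Ensemble maps are unweighted member means with the per-cell member
standard deviation: members are (algorithm × CV run) for the
contemporary map and (algorithm × CV run × GCM) for future maps — 50
members per retained algorithm with 10 runs and 5 GCMs.  "Suitable
habitat" for area bookkeeping is ESI ≥ 0.5 by default, with a 0.3/0.5/
0.7 sensitivity sweep always reported, since no canonical threshold
exists; areas use latitude-corrected cell sizes,
(111.195·Δ)·(111.195·Δ·cos φ) km².  Range change is the signed
percentage versus the contemporary area.  EEZ summaries are unweighted
means over valid cells whose centres fall inside each polygon ("mean by
pixel"); catch is display metadata only, attached as log₁₀ tonnes with
entries under 1000 t/yr flagged below the display threshold but kept.

## The synthetic world

The generator emulates the statistical structure the analysis assumes,
not ocean physics.  On a default 10° × 12° domain at 0.1° (lon −2…8,
lat 36…48): land along a wiggly eastern coast; a shelf deepening into a
basin (−60 m to −5500 m); SBT decreasing poleward (≈ 25 °C at the warm
edge, gradient 1.1 °C/°lat, slightly colder over deep water); SBTr
largest over the shallow shelf with a mild mid-latitude maximum, and
SBTvar ≈ 0.8·SBTr + noise so the r > 0.7 pruning is exercised; surface
analogues tied to the bottom fields; an eastward salinity gradient; and
log primary production enriched within ~300 km of the coast.  All
fields are deterministic functions of the seed.

The species truth is a product of independent Gaussians over
(SBT, SBTr, Log_PP) — matching the three predictors the selection should
recover and making recovery checks analytic — with optima
(17.5 °C, 5 °C, −6.7) and tolerances (2.0, 2.5, 0.8).  The SBT optimum
is placed so both flanks of the thermal response are observable inside
the domain; a species whose cold flank is truncated by the domain edge
biases any ESI-weighted optimum estimate warm.  Sampling weights are
suitability × effort, with effort = coastal survey bias
(1 + 2·e^(−d/150 km)) × a demersal depth affinity (weight 1 inside the
150–1000 m range or the 50 km coastal band, 0.02 outside).
Contamination rates: 5% exact duplicates, 2% on-land points, 5%
unreliable flags, and a year mix of ≈ 73% ≥ 1990, ≈ 11% pre-1990,
≈ 16% undated — the mix occurrence databases report.

GCM emulation: each of the 5 GCMs gets one discrepancy field per
variable (smooth bias, sd 0.5 °C, plus i.i.d. cell noise, sd 0.2 °C)
drawn once and shared between its common-period and future fields, so
the per-cell delta correction is *exactly* sufficient — the point is to
isolate the correction's contract, not to emulate non-stationary model
error.  Warming deltas rise across RCPs and decades, reaching +3.2 °C
under RCP8.5 by 2090–2099 (the headline end-of-century warming level);
the full delta applies to mean temperatures, a 0.3-scaled delta to
seasonal-range/variance layers (seasonal amplitude responds far less
than the mean — adding +3.2 °C to a *range* would not be physical), and
log-PP declines mildly with warming.  EEZs are longitude-band polygons
tiling the domain, with lognormal catches including sub-1000 t entries.

What the synthetic world does **not** emulate — and hence what passing
tests do not show about real data: spatially autocorrelated presence
noise, taxonomic misidentification structure, niche non-stationarity,
biotic interactions, brackish-basin dynamics, GCM errors that change
between the common period and the future (against which a delta
correction is *not* sufficient), and dispersal limits on range shifts.

## Numerical choices and problem sizes

Deterministic seeds everywhere: stage seeds are derived from the master
seed plus the stage name, kept below 2³¹; refits are bit-identical.
Degenerate inputs: constant variables are excluded from correlation
pruning with a warning; coplanar point sets fall back to a bounding-box
hull with a warning; all-identical background predictions make CBI
undefined (missing, with a warning) rather than raising.

Default test/check problem sizes — chosen as the smallest sizes at
which the statistical behaviour is stable: the full-scale world is
120 × 100 cells with n = 1000 presences (≈ 200 filtered presences, so
≈ 400 model-ready rows per fit), the plumbing tests use a 50 × 50-cell
world with three fast algorithms, and the NPPEN oracle uses a 50-point
reference with 10⁴ Monte-Carlo draws.

## Known limitations

The GAM has fixed smoothness (no penalty selection); the MARS forward
pass has no backward pruning (the logistic refit shrinks useless
terms); FDA's basis is selected by least squares before the
discriminant step; response-curve screening encodes only unimodality;
the per-cell delta correction assumes stationary model bias; and the
suitable-area threshold, while swept, remains a reporting convention
rather than an ecological quantity.
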