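# Methods

This note documents the models, defaults and numerical choices behind
`basinbio`, and what the synthetic-data generator does and does not
emulate.

## Spatial model

Space is a three-level nesting: level-5 drainage basins inside level-4
catchments inside bioregions (six by default). "Adjacency" between
level-5 basins means sharing a level-4 parent; this is the donor pool for
gap-filling, chosen because resampling within the catchment conservatively
assumes low dispersal capacity and cannot enlarge the species pool beyond
the catchment's observed fauna. Basin footprints in synthetic data are
abstract axis-aligned lon/lat boxes: they exist only so that
coordinate-based cleaning and point-in-basin assignment have something to
chew on. Real data should arrive with a pre-assigned basin id (the GIS
join is out of scope).

## Sample coverage and the gap-fill loop

Coverage of a basin is estimated from its unique records (unique
combination of species, coordinates rounded to 4 decimals ≈ 11 m, and
sampling date, with missing dates kept as one distinct value):

Ĉ = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁ + 2f₂)], with the (f₁ − 1) substitution
when f₂ = 0 and Ĉ = 0 when n = 1 (the closed-form limit; a lone record
carries no information about the fauna). The lower 95% bound comes from a
nonparametric bootstrap over records (B = 200, percentile method,
clipped to the point estimate); the bootstrap was chosen because no
distributional form is defensible for record counts, and it is cheap.

A basin is *acceptable* when lower bound ≥ 0.75 AND n > 50. The same
joint rule is used to enter and to exit the augmentation loop; using the
point estimate instead is available via `GapfillConfig.criterion` because
the unstable-small-sample argument only motivates the entry test. Each
loop iteration draws one record uniformly with replacement from the
pooled sibling-basin records (record-wise, not basin-wise, weighting).
`max_insertions` (default 10,000) guarantees termination; hitting the cap
flags the basin as non-converged rather than silently accepting it.
Unacceptable basins with no sibling are excluded and listed. The default
of 100 replicate matrices matches the number used for uncertainty
propagation in continental analyses of this design.

## Diversity metrics

- SAR: OLS of log10 S on log10 area over basins with S ≥ 1. Dropping
  S = 0 basins loses nothing at these scales and keeps the log defined.
- Density: S / area^b with the fitted b.
- PE: branch length divided by the *count* of level-5 basins holding any
  descendant tip (count-based weighted endemism, the construction that
  maps PE per basin); summed per basin. Σ over basins of PE equals the
  PD of the tree restricted to placed tips — enforced to 1e-9 relative
  in tests.
- ED: fair proportion. Σ ED = total tree length.
- DR: inverse equal splits; pendant edge weight 1, halving at each split
  toward the root. Unifurcations (e.g. a zero-length root edge) add no
  split and so do not change DR; polytomies are rejected rather than
  silently resolved because resolution changes the equal-splits sums.
- Metric uncertainty: mean and SD across the replicate presence matrices;
  basins never touched by the fill have SD exactly 0.

## Range-evolution model

States are the 2^A − 1 non-empty subsets of A bioregions. Anagenetic
dispersal: rate(R → R∪{k}) = d · Σ_{j∈R} m[j,k]; anagenetic extirpation:
rate(R → R\{k}) = e for |R| > 1. The empty range is excluded and loss
from singletons forbidden — an extant lineage always occupies at least
one bioregion. Cladogenesis copies the range to both daughters; no
founder-event (jump) parameter, because basin-bound fishes need river
connections to disperse. Multipliers do not scale e: they encode
connectivity for dispersal, while loss is a local process.

Time strata: contiguous [start, end] Ma intervals, each with its own
A × A multiplier matrix. The default configuration uses the five
boundaries 255–33–23–10–5–0 Ma with all-ones matrices as an illustrative
stand-in; real analyses must supply their own connectivity values.
Branches older than the oldest boundary use the oldest stratum's matrix.

Likelihood: Felsenstein pruning; branch transition matrices are ordered
(old → young) products of exp(Q_s Δt) over the strata the branch
crosses. The root prior is uniform over the non-empty states (neutral
default; configurable). Propagators use the spectral decomposition of
each stratum generator, validated once against scipy's expm at a
reference time and falling back to expm wholesale if the generator is
too ill-conditioned (accuracy thresholds 1e-10; row-stochasticity checked
to 1e-9). The pruning pass itself uses spectral mat-vec products and
per-node rescaling, so a 63-state, 200-tip likelihood costs ~10 ms.

ML fit: L-BFGS-B on (log d, log e) with bounds [1e-8, 10] events/My and
multi-start (defaults 0.001/0.001, 0.01/0.01, 0.1/0.05). AIC = −2lnL + 2k
with k = 2; AICc uses n = number of tips as the sample size (the tips
are the observations entering the likelihood). Marginal ancestral states
come from the standard inside/outside message pass and are checked
against brute-force enumeration on small instances.

## Stochastic mapping and dispersal accounting

Histories are sampled by backward filtering / forward sampling: the root
state from prior × partial likelihood, each child conditionally on its
parent, then each branch path conditional on its endpoints. Interior
stratum-boundary states are sampled with suffix products of the segment
matrices; within a segment the endpoint-conditioned path is drawn by
uniformization (jump count from the Poisson-weighted power series of
R = I + Q/μ, then a conditioned discrete chain). Uniformization was
preferred over rejection sampling because it cannot stall on stiff
generators or improbable endpoint pairs. Default 20 maps.

A gain event is a dispersal event. Its source within a multi-area range
is sampled proportionally to m[j, k] — the single biggest interpretive
choice in the accounting, since directional flows require an attribution
rule; a uniform-over-range mode is provided for sensitivity checks.

Binning: half-open [t, t−1) Ma bins, oldest edge at ceil(root age); an
event at 12.3 Ma falls in [13, 12). Lineages per bin are counted at the
bin midpoint (unambiguous, cheap). The relative series divides mean
counts by max(ln(lineages), 1): the log damps the mechanical rise of
absolute counts toward the present, and the clamp avoids dividing by
ln(1) = 0 near the root; log10 is available by configuration, and the
raw (unlogged) series can be recovered by binning alone.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes:
six bioregions; nested basins with lognormal areas (median ≈ 10⁴ km²);
a birth–death tree (defaults b = 0.1/My, d = 0.05/My) conditioned on its
tip count by the simple-sampling scheme — grow from a crown pair, retry
on extinction, stop at the first passage to n tips, and place the
present uniformly inside the waiting time to the next event so pendant
edges stay positive; ranges evolved forward under the same stratified
gain/loss process that the inference assumes (defaults d = 0.02,
e = 0.01 events/My, the order of magnitude recovered from continental
fish data); per-basin occupancy scaled by (area/median)^0.15 so the
fauna shows a mild, realistic species–area slope; and occurrence records
whose per-basin counts follow a deterministic log-spaced effort gradient
spanning a ten-fold difference — the level of heterogeneity documented
for South American fish sampling — with species drawn from lognormal
abundances (σ = 1), which produces the heavy singleton/doubleton tails
coverage estimation feeds on. Optional injections (synonym variants,
exotic species, out-of-range coordinates, duplicate rows) corrupt the
table at configured rates and are indexed in a manifest so cleaning can
be verified row by row.

What it does not emulate: real geography or hydrography (footprints are
boxes), spatially autocorrelated sampling, detection differences among
species, taxonomic churn beyond simple synonym pairs, or
cladogenetic range change. Passing tests therefore demonstrate the
internal correctness and calibration of the chain — estimators match
their closed forms and brute-force oracles, the fill reduces richness
error under effort bias, parameters are recoverable at realistic scales —
not robustness to every pathology of real museum data.

## Problem sizes

The bundled scenario used by tests and by `scripts/acceptance.py` runs
60 level-5 basins (6 bioregions × 2 catchments × 5 basins), 300 species,
~29,000 records, 100 gap-fill matrices, a 63-state range model and 20
stochastic maps — small enough to run on a laptop core in tens of
seconds while exercising every code path at realistic parameter values.
Parameter-recovery checks use a 200-tip tree with 50 independent range
simulations.

## Known limitations

- The gap-fill loop re-estimates the bootstrap bound after every
  insertion; its decision sequence is therefore a random function of the
  replicate stream (by design — the 100 matrices carry that uncertainty).
- Areas beyond ~10 bioregions are impractical (state space 2^A − 1).
- AICc model comparison covers parameterizations of this gain/loss model
  only; alternative cladogenetic models are out of scope.
- The source-attribution rule for multi-area ranges is an interpretive
  convention, not an estimate; flows should be read accordingly.
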