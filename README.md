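# basinbio

Tools for studying how river-basin history structures freshwater fish
diversity. The package implements, as one reusable and fully tested
pipeline, the analytical chain used in continental-scale studies of
basin-bound faunas: occurrence-record cleaning, completeness-based
gap-filling of unevenly sampled drainage basins, per-basin diversity
metrics, and time-stratified ancestral-range inference with stochastic
mapping of dispersal events. A synthetic-data module generates basin
hierarchies, dated phylogenies, species ranges and effort-biased
occurrence records, so the whole pipeline runs and is testable with no
external downloads.

It is aimed at biogeographers and macroecologists working with
basin-structured occurrence data (e.g. HydroBASINS-style nested drainage
units) and a time-calibrated phylogeny.

## What it computes

**Sample coverage and gap-filling.** For each level-5 basin, the
completeness of sampling is the estimated probability that the next
record belongs to an already-recorded species, computed from singleton
and doubleton counts (Chao-style estimator):

    Ĉ = 1 − (f₁/n) · [(n−1) f₁ / ((n−1) f₁ + 2 f₂)]

A basin is acceptably sampled when the lower 95% bootstrap bound of Ĉ is
≥ 0.75 and it holds more than 50 unique records (unique combination of
species, coordinates and sampling date). An under-sampled basin is
augmented by drawing records, uniformly with replacement, from its
level-4 sibling basins until the criterion is met; repeating the pass
(default 100×) yields replicate presence/absence matrices whose spread
carries the uncertainty of the fill. Basins failing the criterion with no
level-4 sibling are excluded.

**Diversity metrics.** Species density S/Area^b with the exponent b fit
from the species–area relationship (OLS on log10–log10 axes);
phylogenetic endemism PE(basin) = Σ_branches L_β / R_β where R_β counts
the basins holding any descendant of branch β; fair-proportion
evolutionary distinctiveness; and the DR (inverse equal splits)
diversification statistic, DR_i = 1 / Σ_k l_k 2^−(k−1).

**Range evolution.** An anagenetic-only CTMC over the 2^A − 1 non-empty
subsets of A bioregions: single-area gains at rate d weighted by
time-stratified dispersal-multiplier matrices, single-area losses at rate
e, both daughters inheriting the parental range at speciation (no
founder-event jumps). Likelihoods by Felsenstein pruning with piecewise
matrix exponentials across strata; (d, e) fit by multi-start ML;
AIC/AICc reported; marginal ancestral ranges per node.

**Dispersal accounting.** Biogeographical stochastic mapping (backward
filtering, forward sampling; endpoint-conditioned paths by
uniformization) yields full event histories. Gains are dispersal events;
each is attributed a source area within the pre-event range,
proportional to the dispersal multipliers. Events are binned in 1-My
slices and normalized by the log-number of lineages alive in each bin.

## Worked example

```python
import numpy as np
from basinbio import (SyntheticConfig, GapfillConfig, coverage, gapfill_all,
                      fit_sar, fit_ml, stochastic_map, summarize_flows)
from basinbio.synth import (simulate_basins, simulate_tree, simulate_ranges,
                            presence_from_ranges, simulate_occurrences)
from basinbio.ranges import RangeModel, BayAreaParams
from basinbio.occurrences import unique_records
from basinbio.trees import IndexedTree

# sample coverage of a basin with 10 records: two singletons, one doubleton
est = coverage(np.array([1, 1, 2, 6]), bootstrap_B=500, rng=np.random.default_rng(0))
print(f"coverage: point={est.point:.3f} lower95={est.lower_ci:.3f} n={est.n}")

# a synthetic continent: 6 bioregions, 60 basins, 300 species, 10x effort bias
cfg = SyntheticConfig(seed=1, n_tips=300)
basins = simulate_basins(cfg)
tree = IndexedTree.from_dendropy(simulate_tree(cfg))
model = RangeModel(basins.bioregion_ids, cfg.strata, BayAreaParams(cfg.true_d, cfg.true_e))
history = simulate_ranges(tree, model, cfg.rng("ranges"))
presence = presence_from_ranges(history.tip_ranges, basins, cfg.rng("presence"))
occ, _, _ = simulate_occurrences(basins, presence, cfg)
occ, _ = unique_records(occ)

pm = gapfill_all(occ, basins, GapfillConfig(n_matrices=25, seed=1))
sar = fit_sar(pm.mean_richness(), basins.areas())
print(f"SAR: b={sar.b:.3f} (r^2={sar.r_squared:.2f}, {sar.n_basins} basins)")

fit = fit_ml(tree, history.tip_ranges, cfg.strata, 6)
print(f"range model: d={fit.params.d:.4f}/My e={fit.params.e:.4f}/My AICc={fit.aicc:.1f}")

maps = stochastic_map(tree, history.tip_ranges, fit.params, cfg.strata, 6, n_maps=20, seed=1)
flows = summarize_flows(maps, 6, basins.bioregion_ids)
print(f"dispersal: {flows.total_events_mean:.1f} events/map; "
      f"top source {flows.source_share.idxmax()} ({flows.source_share.max():.1f}%)")
```

Output:

```
coverage: point=0.820 lower95=0.730 n=10
SAR: b=0.154 (r^2=0.16, 60 basins)
range model: d=0.0182/My e=0.0087/My AICc=864.0
dispersal: 200.1 events/map; top source R1 (17.3%)
```

Reading the numbers: the 10-record basin has point coverage 0.82 but its
lower bound (0.73) fails the 0.75 rule, so it would be gap-filled. The
fitted species–area exponent (0.154) recovers the mild area scaling the
generator builds in, and the ML rates bracket the true simulation values
d = 0.02, e = 0.01. With flat dispersal multipliers no bioregion
dominates as a source (1/6 ≈ 16.7%).

The same chain is available as a CLI:

```sh
basinbio generate demo --seed 1       # write synthetic inputs + run config
basinbio run-all demo/run_config.yml  # clean → gapfill → metrics → fit → map
```

## Layout

- `basinbio.synth` — synthetic basin hierarchies, birth–death trees, forward range simulation, effort-biased occurrence records
- `basinbio.occurrences` — cleaning, deduplication, basin assignment, tree intersection
- `basinbio.gapfill` — coverage estimation and the resampling gap-fill
- `basinbio.metrics` — SAR/density, phylogenetic endemism, ED, DR
- `basinbio.ranges` — stratified range-evolution CTMC, ML fit, ancestral marginals
- `basinbio.bsm` — stochastic mapping, source attribution, event binning
- `basinbio.pipeline` / `basinbio.cli` — orchestration and the command line

See `docs/methods.md` for model assumptions, parameter defaults, and
numerical choices.
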