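import numpy as np
import pytest

from basinbio.ranges import BayAreaParams, RangeModel, Stratum
from basinbio.synth import (
    SyntheticConfig,
    default_strata,
    effort_multipliers,
    presence_from_ranges,
    simulate_basins,
    simulate_occurrences,
    simulate_ranges,
    simulate_tree,
)
from basinbio.trees import IndexedTree, to_newick

from oracle_utils import conditioned_bd_mean_span


class TestSimulateBasins:
    def test_single_parent_complete_adjacency(self):
        cfg = SyntheticConfig(n_bioregions=1, n_level4_per_bioregion=1, n_level5_per_level4=3)
        h = simulate_basins(cfg)
        assert len(h.basin_ids) == 3
        for b in h.basin_ids:
            assert sorted(h.neighbors(b)) == sorted(x for x in h.basin_ids if x != b)

    def test_counts_multiply(self):
        cfg = SyntheticConfig(n_bioregions=6, n_level4_per_bioregion=4, n_level5_per_level4=5)
        h = simulate_basins(cfg)
        assert len(h.basin_ids) == 120
        assert h.table["level4_id"].nunique() == 24
        assert len(h.bioregion_ids) == 6

    def test_every_basin_has_one_parent_chain(self):
        h = simulate_basins(SyntheticConfig())
        for b in h.basin_ids:
            assert h.bioregion_of(b).startswith("R")
            assert h.level4_of(b).startswith(h.bioregion_of(b))

    def test_deterministic_under_seed(self):
        a = simulate_basins(SyntheticConfig(seed=7))
        b = simulate_basins(SyntheticConfig(seed=7))
        assert a.table.equals(b.table)
        assert a.footprints == b.footprints

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_bioregions=0)


class TestSimulateTree:
    def test_two_tip_pure_birth_is_cherry(self):
        cfg = SyntheticConfig(birth_rate=1.0, death_rate=0.0, n_tips=2, seed=5)
        t = IndexedTree.from_dendropy(simulate_tree(cfg))
        assert t.n_tips == 2
        assert t.is_binary()
        assert t.root_age > 0

    def test_deterministic_newick(self):
        cfg = SyntheticConfig(seed=9, n_tips=30)
        assert to_newick(simulate_tree(cfg)) == to_newick(simulate_tree(cfg))

    def test_tips_extant_and_ultrametric(self):
        cfg = SyntheticConfig(seed=3, n_tips=50)
        t = IndexedTree.from_dendropy(simulate_tree(cfg))
        assert t.n_tips == 50
        assert t.is_ultrametric(tol=1e-8)

    def test_mean_span_matches_birth_death_expectation(self):
        # conditioned first-passage oracle computed by independent linear algebra
        b, d, n, reps = 0.1, 0.05, 30, 200
        expected = conditioned_bd_mean_span(b, d, n)
        spans = []
        for i in range(reps):
            cfg = SyntheticConfig(birth_rate=b, death_rate=d, n_tips=n, seed=1000 + i)
            t = IndexedTree.from_dendropy(simulate_tree(cfg))
            # the oldest sampled point of the full simulation is the crown age
            # only when both initial lineages survive; use root age as a lower
            # bound and compare the mean against the oracle loosely via spans
            spans.append(t.root_age)
        spans = np.asarray(spans)
        se = spans.std(ddof=1) / np.sqrt(reps)
        # the reconstructed root age is at most the simulated span; with both
        # crown lineages surviving they coincide, so the mean sits slightly
        # below the oracle but within a few SE for these rates
        assert spans.mean() < expected + 4 * se
        assert spans.mean() > 0.5 * expected

    def test_pure_birth_root_age_matches_closed_form(self):
        # E[span] = (1/b) sum_{k=2}^{n-1} 1/k + 0.5/(b n); no pruning when d=0
        b, n, reps = 0.5, 20, 300
        expected = (1.0 / b) * sum(1.0 / k for k in range(2, n)) + 0.5 / (b * n)
        ages = []
        for i in range(reps):
            cfg = SyntheticConfig(birth_rate=b, death_rate=0.0, n_tips=n, seed=5000 + i)
            ages.append(IndexedTree.from_dendropy(simulate_tree(cfg)).root_age)
        ages = np.asarray(ages)
        se = ages.std(ddof=1) / np.sqrt(reps)
        assert abs(ages.mean() - expected) < 4 * se


class TestSimulateRanges:
    def _model(self, d, e, n_areas=2, start=300.0):
        return RangeModel(
            [f"A{i}" for i in range(n_areas)],
            [Stratum(start, 0.0, np.ones((n_areas, n_areas)))],
            BayAreaParams(d, e),
        )

    def test_zero_rates_inherit_root_range(self, five_tip_tree):
        hist = simulate_ranges(five_tip_tree, self._model(0.0, 0.0), 1)
        assert all(v == hist.root_state for v in hist.tip_ranges.values())
        assert len(hist.events) == 0

    def test_large_d_absorbs_full_range(self, five_tip_tree):
        model = self._model(50.0, 0.0)
        hist = simulate_ranges(five_tip_tree, model, 2)
        assert all(v == frozenset({0, 1}) for v in hist.tip_ranges.values())

    def test_tips_never_empty(self, five_tip_tree):
        for seed in range(20):
            hist = simulate_ranges(five_tip_tree, self._model(0.05, 0.5), seed)
            assert all(len(v) >= 1 for v in hist.tip_ranges.values())

    def test_events_obey_stratified_rates(self):
        # second stratum forbids all gains: no gain events younger than 5 Ma
        tree = IndexedTree.from_newick("((a:6.0,b:6.0):4.0,(c:8.0,d:8.0):2.0);")
        strata = [
            Stratum(300.0, 5.0, np.ones((2, 2))),
            Stratum(5.0, 0.0, np.zeros((2, 2))),
        ]
        model = RangeModel(["A0", "A1"], strata, BayAreaParams(5.0, 0.0))
        for seed in range(10):
            hist = simulate_ranges(tree, model, seed)
            gains = hist.events[hist.events["kind"] == "gain"]
            if len(gains):
                assert gains["time_ma"].min() >= 5.0 - 1e-9

    def test_gain_counts_match_integrated_intensity(self):
        # martingale check: total observed gains vs total integrated gain rate
        cfg = SyntheticConfig(seed=21, n_tips=200)
        tree = IndexedTree.from_dendropy(simulate_tree(cfg))
        model = RangeModel(
            [f"A{i}" for i in range(6)],
            [Stratum(max(300.0, tree.root_age + 1), 0.0, np.ones((6, 6)))],
            BayAreaParams(0.02, 0.01),
        )
        observed, integral = 0.0, 0.0
        reps = 200
        d = 0.02
        for rep in range(reps):
            hist = simulate_ranges(tree, model, 300 + rep)
            ev = hist.events
            observed += float((ev["kind"] == "gain").sum())
            # integrate the gain intensity along each simulated trajectory:
            # rate while in range of size r is d * r * (6 - r) under flat m
            node_range = dict(hist.node_states)
            node_range.update(hist.tip_ranges)
            by_branch = {k: g for k, g in ev.groupby("branch")}
            for v in range(1, tree.n_nodes):
                parent_lab = tree.labels[tree.parent[v]]
                start_set = set(node_range.get(parent_lab, hist.root_state))
                t_hi = float(tree.age[tree.parent[v]])
                t_lo = float(tree.age[v])
                branch_ev = by_branch.get(tree.labels[v])
                branch_ev = (
                    branch_ev.sort_values("time_ma", ascending=False)
                    if branch_ev is not None
                    else ev.iloc[0:0]
                )
                cur, t_cur = set(start_set), t_hi
                for _, r in branch_ev.iterrows():
                    rr = len(cur)
                    integral += d * rr * (6 - rr) * (t_cur - float(r["time_ma"]))
                    if r["kind"] == "gain":
                        cur.add(int(r["area"]))
                    else:
                        cur.discard(int(r["area"]))
                    t_cur = float(r["time_ma"])
                rr = len(cur)
                integral += d * rr * (6 - rr) * (t_cur - t_lo)
        # Poisson-style MC error on the total count
        se = np.sqrt(observed)
        assert abs(observed - integral) < 4 * se

    def test_deterministic_under_seed(self, five_tip_tree):
        h1 = simulate_ranges(five_tip_tree, self._model(0.1, 0.05), 7)
        h2 = simulate_ranges(five_tip_tree, self._model(0.1, 0.05), 7)
        assert h1.tip_ranges == h2.tip_ranges
        assert h1.events.equals(h2.events)


class TestSimulateOccurrences:
    def test_flat_effort_gives_similar_counts(self, tiny_hierarchy):
        cfg = SyntheticConfig(
            effort_heterogeneity=1.0, abundance_sigma=0.0,
            mean_records_per_basin=500.0, seed=3,
        )
        import pandas as pd

        presence = pd.DataFrame(
            1, index=[f"sp{i}" for i in range(20)], columns=tiny_hierarchy.basin_ids
        )
        occ, _, _ = simulate_occurrences(tiny_hierarchy, presence, cfg)
        counts = occ.groupby("basin_id").size()
        assert counts.max() / counts.min() < 1.5  # Poisson noise only

    def test_tenfold_gradient_reproduced(self, tiny_hierarchy):
        import pandas as pd

        cfg = SyntheticConfig(effort_heterogeneity=10.0, mean_records_per_basin=400.0, seed=4)
        presence = pd.DataFrame(
            1, index=[f"sp{i}" for i in range(30)], columns=tiny_hierarchy.basin_ids
        )
        ratios = []
        rng = cfg.rng("ratio-test")
        for _ in range(100):
            occ, _, _ = simulate_occurrences(tiny_hierarchy, presence, cfg, rng)
            counts = occ.groupby("basin_id").size()
            ratios.append(counts.max() / counts.min())
        mean_ratio = float(np.mean(ratios))
        assert 8.0 < mean_ratio < 13.0

    def test_effort_multipliers_span(self, tiny_hierarchy):
        eff = effort_multipliers(tiny_hierarchy, 10.0)
        assert eff.min() == pytest.approx(1.0)
        assert eff.max() == pytest.approx(10.0)

    def test_no_records_for_absent_species(self, gapfill_scenario):
        occ = gapfill_scenario["occurrences"]
        truth = gapfill_scenario["true_presence"]
        clean = occ[~occ["species"].str.endswith("_syn")]
        clean = clean[~clean["species"].str.startswith("Exoticus")]
        for basin, grp in clean.groupby("basin_id"):
            present = set(truth.index[truth[basin] == 1])
            assert set(grp["species"]) <= present

    def test_zero_injection_rates_leave_table_clean(self, tiny_hierarchy):
        import pandas as pd

        cfg = SyntheticConfig(seed=5)
        presence = pd.DataFrame(
            1, index=[f"sp{i}" for i in range(5)], columns=tiny_hierarchy.basin_ids
        )
        occ, manifest, _ = simulate_occurrences(tiny_hierarchy, presence, cfg)
        assert len(manifest) == 0
        assert (occ["lat"].abs() <= 90).all()
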