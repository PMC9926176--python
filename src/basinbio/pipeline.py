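"""End-to-end orchestration: clean -> dedupe -> assign -> intersect ->
gap-fill -> diversity metrics -> range-model fit -> stochastic mapping ->
dispersal summaries, with every intermediate artifact written to disk and a
machine-readable manifest of counts and seeds.

One master seed fans out into named sub-streams (synthetic, gapfill,
mapping) so stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import seed_stream
from .basins import BasinHierarchy
from .bsm import bin_events, events_to_frame, stochastic_map, summarize_flows
from .gapfill import GapfillConfig, gapfill_all
from .metrics import (
    dr_statistic,
    evolutionary_distinctiveness,
    fit_sar,
    phylogenetic_endemism,
    replicate_summary,
    species_density,
)
from .occurrences import (
    CleaningTables,
    assign_to_basins,
    clean_occurrences,
    intersect_with_tree,
    read_occurrences,
    unique_records,
    write_occurrences,
)
from .ranges import (
    fit_ml,
    read_strata_yaml,
    tip_ranges_from_frame,
    tip_ranges_from_presence_set,
    write_strata_yaml,
)
from .synth import (
    SyntheticConfig,
    presence_from_ranges,
    simulate_basins,
    simulate_occurrences,
    simulate_ranges,
    simulate_tree,
)
from .trees import IndexedTree, read_newick, to_newick

__all__ = ["RunConfig", "generate_demo", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Paths and sub-configurations of one pipeline run."""

    occurrences: str
    basins: str
    tree: str
    strata: str
    outdir: str
    synonyms: str | None = None
    exotics: str | None = None
    master_seed: int = 0
    gapfill: dict = field(default_factory=dict)
    n_maps: int = 20
    tip_range_rule: str = "majority"
    fit_starts: list | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _read_cleaning_tables(config: RunConfig) -> CleaningTables:
    synonym_map: dict[str, str] = {}
    exotic: set[str] = set()
    if config.synonyms:
        df = pd.read_csv(config.synonyms, dtype=str)
        synonym_map = dict(zip(df["name"], df["accepted"]))
    if config.exotics:
        exotic = set(pd.read_csv(config.exotics, dtype=str)["species"])
    return CleaningTables(synonym_map, exotic)


def generate_demo(
    outdir, config: SyntheticConfig | None = None
) -> tuple[Path, RunConfig]:
    """Write a complete synthetic input set and a matching run config.

    Produces the basin table, dated tree, true presence matrix,
    effort-biased occurrence records (with mild injected errors so the
    cleaning stage has work to do), cleaning tables, and the stratified
    dispersal-multiplier config.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or SyntheticConfig(
        synonym_rate=0.02, exotic_rate=0.01, coord_error_rate=0.01, duplicate_rate=0.02
    )
    hierarchy = simulate_basins(cfg)
    tree = simulate_tree(cfg)
    from .ranges import BayAreaParams, RangeModel

    model = RangeModel(
        areas=hierarchy.bioregion_ids,
        strata=cfg.strata,
        params=BayAreaParams(cfg.true_d, cfg.true_e),
    )
    history = simulate_ranges(tree, model, cfg.rng("ranges"))
    presence = presence_from_ranges(
        history.tip_ranges, hierarchy, cfg.rng("presence"),
        cfg.basin_occupancy, cfg.area_occupancy_exponent,
    )
    occurrences, manifest, tables = simulate_occurrences(hierarchy, presence, cfg)

    hierarchy.write_csv(out / "basins.csv")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(to_newick(tree) + "\n")
    presence.to_csv(out / "true_presence.csv")
    write_occurrences(occurrences, out / "occurrences.csv")
    manifest.to_csv(out / "injection_manifest.csv", index=False)
    history.events.to_csv(out / "true_range_events.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [(k, v) for k, v in sorted(tables.synonym_map.items())], columns=["name", "accepted"]
    ).to_csv(out / "synonyms.csv", index=False)
    pd.DataFrame({"species": sorted(tables.exotic_list)}).to_csv(
        out / "exotics.csv", index=False
    )
    write_strata_yaml(out / "strata.yml", hierarchy.bioregion_ids, cfg.strata)

    run_cfg = RunConfig(
        occurrences=str(out / "occurrences.csv"),
        basins=str(out / "basins.csv"),
        tree=str(out / "tree.nwk"),
        strata=str(out / "strata.yml"),
        outdir=str(out / "results"),
        synonyms=str(out / "synonyms.csv"),
        exotics=str(out / "exotics.csv"),
        master_seed=cfg.seed,
        gapfill={"n_matrices": 25},
    )
    run_cfg.to_yaml(out / "run_config.yml")
    return out, run_cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_echo.yml")
    manifest: dict = {"version": __version__, "master_seed": config.master_seed, "stages": {}}

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts

    try:
        hierarchy = BasinHierarchy.read_csv(config.basins)
        tree = read_newick(config.tree)
        raw = read_occurrences(config.occurrences)
        tables = _read_cleaning_tables(config)
        area_names, strata = read_strata_yaml(config.strata)
        stage("inputs", records=len(raw), basins=len(hierarchy.basin_ids),
              tips=len(tree.taxon_namespace))

        clean, rejects = clean_occurrences(raw, tables)
        rejects.to_csv(out / "rejected_records.csv", index=False, float_format=_FLOAT_FMT)
        stage("clean", records_in=len(raw), records_out=len(clean), rejected=len(rejects))

        deduped, n_dup = unique_records(clean)
        stage("dedupe", records_in=len(clean), records_out=len(deduped), duplicates=n_dup)

        assigned, no_basin = assign_to_basins(deduped, hierarchy)
        stage("assign", records_in=len(deduped), records_out=len(assigned),
              rejected=len(no_basin))

        pruned_tree, table, counts = intersect_with_tree(assigned, tree)
        with open(out / "pruned_tree.nwk", "w") as fh:
            fh.write(to_newick(pruned_tree) + "\n")
        write_occurrences(table, out / "analysis_records.csv")
        stage("intersect", **counts)

        gf_cfg = GapfillConfig(seed=config.master_seed, **config.gapfill)
        pm = gapfill_all(table, hierarchy, gf_cfg)
        pm.write(out / "presence_matrices")
        stage("gapfill", n_matrices=pm.n_matrices, excluded_basins=len(pm.excluded_basins),
              converged=int(pm.convergence.to_numpy().sum()))

        itree = IndexedTree.from_dendropy(pruned_tree)
        areas = hierarchy.areas()
        rich = replicate_summary(pm.matrices, lambda m: m.sum(axis=0))
        sar = fit_sar(rich["mean"], areas)
        dens = species_density(rich["mean"], areas.loc[rich.index], sar.b)
        pe = replicate_summary(pm.matrices, lambda m: phylogenetic_endemism(itree, m))
        ed = evolutionary_distinctiveness(itree)
        dr = dr_statistic(itree)
        basin_metrics = pd.DataFrame(
            {
                "richness_mean": rich["mean"], "richness_sd": rich["sd"],
                "density_mean": dens,
                "pe_mean": pe["mean"], "pe_sd": pe["sd"],
            }
        )
        basin_metrics.to_csv(out / "basin_metrics.csv", float_format=_FLOAT_FMT)
        pd.DataFrame({"ED": ed, "DR": dr}).to_csv(
            out / "species_metrics.csv", float_format=_FLOAT_FMT
        )
        stage("metrics", sar_b=sar.b, sar_r2=sar.r_squared, n_basins=sar.n_basins)

        b2r = {b: hierarchy.bioregion_of(b) for b in hierarchy.basin_ids}
        bioregions = [a for a in area_names]
        tip_frame = tip_ranges_from_presence_set(
            pm.matrices, b2r, bioregions, rule=config.tip_range_rule
        )
        tip_frame = tip_frame.loc[[t.label for t in pruned_tree.taxon_namespace]]
        tip_frame.to_csv(out / "tip_ranges.csv")
        tip_ranges = tip_ranges_from_frame(tip_frame)
        fit = fit_ml(
            itree, tip_ranges, strata, len(bioregions),
            starts=[tuple(s) for s in config.fit_starts] if config.fit_starts else None,
        )
        with open(out / "range_fit.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2, sort_keys=True)
        from .ranges import ancestral_marginals

        marg = ancestral_marginals(itree, tip_ranges, fit.params, strata, len(bioregions))
        marg.to_csv(out / "ancestral_marginals.csv", float_format=_FLOAT_FMT)
        with open(out / "labeled_tree.nwk", "w") as fh:
            fh.write(itree.to_newick(label_internal=True) + "\n")
        stage("fit", **{k: v for k, v in fit.to_dict().items() if k != "message"})

        map_seed = seed_stream(config.master_seed, "mapping")
        histories = stochastic_map(
            itree, tip_ranges, fit.params, strata, len(bioregions),
            n_maps=config.n_maps, seed=map_seed,
        )
        events_to_frame(histories).to_csv(
            out / "dispersal_events.csv", index=False, float_format=_FLOAT_FMT
        )
        flows = summarize_flows(histories, len(bioregions), bioregions)
        flows.counts_mean.to_csv(out / "flow_counts_mean.csv", float_format=_FLOAT_FMT)
        flows.source_percent.to_csv(out / "flow_source_percent.csv", float_format=_FLOAT_FMT)
        binned = bin_events(histories, itree)
        binned.to_csv(out / "dispersal_through_time.csv", index=False, float_format=_FLOAT_FMT)
        stage("mapping", n_maps=len(histories),
              total_events_mean=flows.total_events_mean)
    except Exception as exc:
        manifest["error"] = {"stage": _last_stage(manifest), "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        raise

    manifest["outputs"] = sorted(
        {str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()}
        | {"manifest.json"}
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    return manifest


def _last_stage(manifest: dict) -> str:
    stages = list(manifest["stages"])
    return stages[-1] if stages else "inputs"


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
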