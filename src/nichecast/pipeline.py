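"""End-to-end pipeline orchestration.

Stages (``synth → prep → envspace → fit → evaluate → climate → project
→ eez``) run from a single validated :class:`~nichecast.config.RunConfig`.
Each stage writes versioned outputs plus a manifest (parameter/input
hash and the seed it used) into its own subdirectory of the run
directory; a stage whose manifest matches the current configuration is
loaded from cache instead of recomputed, so downstream stages can be
re-run without refitting.  Every stochastic stage derives its seed from
the master seed and the stage name, which makes whole runs bit-for-bit
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from pathlib import Path

import pandas as pd

from . import climate as clim
from . import envspace as es
from . import eez as eezmod
from . import occurrences as occ
from . import projection as proj
from . import synth
from .config import RunConfig
from .ensemble import EnsembleSDM
from .grids import EnvGrid, write_ascii_grid

log = logging.getLogger("nichecast")

STAGES = ("synth", "prep", "envspace", "fit", "evaluate", "climate", "project", "eez")


class MissingUpstreamError(RuntimeError):
    pass


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _Stage:
    """Manifest bookkeeping for one stage directory."""

    def __init__(self, outdir: Path, name: str, key: str, seed: int):
        self.dir = outdir / name
        self.name = name
        self.key = key
        self.seed = seed
        self.manifest_path = self.dir / "manifest.json"

    def cached(self) -> bool:
        if not self.manifest_path.exists():
            return False
        m = json.loads(self.manifest_path.read_text())
        return m.get("key") == self.key

    def write_manifest(self, outputs: list[str]) -> None:
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path.write_text(
            json.dumps(
                {"stage": self.name, "key": self.key, "seed": self.seed, "outputs": sorted(outputs)},
                indent=2,
                sort_keys=True,
            )
        )


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    stages: list[str] | None = None,
) -> dict:
    """Execute the pipeline; returns the in-memory stage products.

    ``stages`` restricts which stages may be (re)computed; stages not in
    the list must be loadable from cache or a
    :class:`MissingUpstreamError` names the stage to rerun.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(stages) if stages else list(STAGES)
    for s in requested:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    config.to_yaml(outdir / "config.yaml")
    state: dict = {"config": config}
    last = max(STAGES.index(s) for s in requested)

    def done(name: str) -> bool:
        """True when every requested stage has now run."""
        return STAGES.index(name) >= last

    def gate(stage: _Stage) -> str:
        """'cached' | 'run' | raises if neither possible."""
        if stage.cached():
            return "cached"
        if stage.name in requested:
            return "run"
        raise MissingUpstreamError(
            f"stage {stage.name!r} has no cached artifact matching the config; rerun it first"
        )

    # ------------------------------------------------------------- synth
    cfg = config
    st = _Stage(outdir, "synth", _hash(["synth", cfg.domain.model_dump(), cfg.synth.model_dump(), cfg.seed]), cfg.stage_seed("synth"))
    if gate(st) == "cached":
        log.info("synth: cached")
        grid = EnvGrid.from_netcdf(st.dir / "grid.nc")
        raw = pd.read_csv(st.dir / "occurrences_raw.csv")
        polygons = synth.polygons_from_geojson(st.dir / "eez.geojson")
        catch = pd.read_csv(st.dir / "catch.csv")
    else:
        log.info("synth: generating world")
        st.dir.mkdir(parents=True, exist_ok=True)
        grid = synth.make_env_grid(cfg.domain.bounds, cfg.domain.cell_size, seed=st.seed)
        truth = synth.NicheTruth(cfg.synth.niche_optima, cfg.synth.niche_tolerances)
        effort = synth.coastal_effort(
            grid, cfg.synth.effort_strength, cfg.synth.effort_scale_km
        ) * synth.depth_affinity(
            grid, cfg.prep.min_depth_m, cfg.prep.max_depth_m, cfg.prep.coastal_buffer_km
        )
        noise = synth.NoiseSpec(
            duplicate_fraction=cfg.synth.duplicate_fraction,
            onland_fraction=cfg.synth.onland_fraction,
            unreliable_fraction=cfg.synth.unreliable_fraction,
            pre1990_fraction=cfg.synth.pre1990_fraction,
            undated_fraction=cfg.synth.undated_fraction,
        )
        raw = synth.sample_occurrences(
            grid, truth, cfg.synth.n_occurrences, effort, noise,
            seed=cfg.stage_seed("synth-occurrences"), species=cfg.species,
        )
        polygons, catch = synth.make_eez_and_catch(
            cfg.domain.bounds, cfg.synth.n_eez, seed=cfg.stage_seed("synth-eez"), species=[cfg.species]
        )
        grid.to_netcdf(st.dir / "grid.nc")
        raw.to_csv(st.dir / "occurrences_raw.csv", index=False)
        synth.polygons_to_geojson(polygons, st.dir / "eez.geojson")
        catch.to_csv(st.dir / "catch.csv", index=False)
        st.write_manifest(["grid.nc", "occurrences_raw.csv", "eez.geojson", "catch.csv"])
    state.update(grid=grid, raw=raw, polygons=polygons, catch=catch)
    if done("synth"):
        return state

    # -------------------------------------------------------------- prep
    st_prev = st
    st = _Stage(outdir, "prep", _hash(["prep", st_prev.key, cfg.prep.model_dump()]), cfg.stage_seed("prep"))
    depth = occ.DepthRange(cfg.prep.min_depth_m, cfg.prep.max_depth_m, cfg.prep.coastal_buffer_km)
    if gate(st) == "cached":
        log.info("prep: cached")
        presences_tab = pd.read_csv(st.dir / "presences.csv")
        occset = occ.OccurrenceSet(
            cfg.species, presences_tab["cell_id"].values,
            presences_tab.rename(columns={})[["cell_id", "n_records", "last_year"]],
        )
    else:
        log.info("prep: cleaning %d raw records", len(raw))
        rules = occ.CleaningRules(
            recent_year=cfg.prep.recent_year,
            edge_distance_km=cfg.prep.edge_distance_km,
            outlier_distance_km=cfg.prep.outlier_distance_km,
            round_decimals=cfg.prep.round_decimals,
        )
        clean = occ.clean_occurrences(raw, grid, rules)
        occset = occ.grid_occurrences(clean, grid, species=cfg.species)
        keep = occ.apply_depth_coast_filter(occset, depth, grid)
        occset = occ.OccurrenceSet(
            cfg.species, occset.cells[keep], occset.provenance[occset.provenance["cell_id"].isin(occset.cells[keep])],
        )
        st.dir.mkdir(parents=True, exist_ok=True)
        clean.to_csv(st.dir / "occurrences_clean.csv", index=False)
        occset.provenance.to_csv(st.dir / "presences.csv", index=False)
        mask_grid = grid.with_layers({"habitat_mask": occ.depth_coast_mask(grid, depth).astype(float)})
        write_ascii_grid(st.dir / "habitat_mask.asc", mask_grid, "habitat_mask")
        st.write_manifest(["occurrences_clean.csv", "presences.csv", "habitat_mask.asc"])
    habitat_mask = occ.depth_coast_mask(grid, depth)
    state.update(occset=occset, habitat_mask=habitat_mask, depth=depth)
    if done("prep"):
        return state

    # ---------------------------------------------------------- envspace
    st_prev = st
    st = _Stage(outdir, "envspace", _hash(["envspace", st_prev.key, cfg.envspace.model_dump()]), cfg.stage_seed("envspace"))
    if gate(st) == "cached":
        log.info("envspace: cached")
        pa_table = pd.read_csv(st.dir / "pa_table.csv")
        variables = json.loads((st.dir / "variables.json").read_text())
    else:
        log.info("envspace: %d presence cells", len(occset))
        iy, ix = grid.unravel(occset.cells)
        env_at_pres = pd.DataFrame({v: grid.layer(v)[iy, ix] for v in cfg.envspace.priority})
        variables = es.select_uncorrelated_variables(
            env_at_pres, cfg.envspace.priority, cfg.envspace.correlation_threshold
        )
        resolutions = {v: cfg.envspace.bin_width for v in variables}
        filtered = es.environmental_filter(occset, grid, variables, resolutions)
        hull = es.TrimmedHull(filtered, variables, *cfg.envspace.hull_percentiles)
        domain_tab = grid.table(variables, mask=habitat_mask)
        pa = es.sample_pseudo_absences(hull, len(filtered), domain_tab, seed=st.seed)
        pa_table = es.build_pa_table(filtered, pa, variables)
        st.dir.mkdir(parents=True, exist_ok=True)
        pa_table.to_csv(st.dir / "pa_table.csv", index=False)
        (st.dir / "variables.json").write_text(json.dumps(variables))
        st.write_manifest(["pa_table.csv", "variables.json"])
    state.update(pa_table=pa_table, variables=variables)
    if done("envspace"):
        return state

    # --------------------------------------------------------------- fit
    st_prev = st
    st = _Stage(outdir, "fit", _hash(["fit", st_prev.key, cfg.models.model_dump()]), cfg.stage_seed("fit"))
    if gate(st) == "cached":
        log.info("fit: cached models")
        with open(st.dir / "models.pkl", "rb") as fh:
            results = pickle.load(fh)
    else:
        log.info("fit: %d algorithms x %d CV runs", len(cfg.models.algorithms), cfg.models.cv_runs)
        model = EnsembleSDM(
            pa_table,
            variables,
            algorithms=tuple(cfg.models.algorithms),
            cv_runs=cfg.models.cv_runs,
            cbi_threshold=cfg.models.cbi_threshold,
            curve_tolerance=cfg.models.curve_tolerance,
            seed=st.seed,
        )
        results = model.fit()
        st.dir.mkdir(parents=True, exist_ok=True)
        with open(st.dir / "models.pkl", "wb") as fh:
            pickle.dump(results, fh)
        (st.dir / "models.json").write_text(
            json.dumps(
                {
                    "format_version": 1,
                    "algorithms": list(cfg.models.algorithms),
                    "variables": variables,
                    "seed": st.seed,
                    "training_hash": _hash(pa_table.values.tolist()),
                },
                indent=2,
            )
        )
        results.cbi.to_csv(st.dir / "cbi_runs.csv", index=False)
        st.write_manifest(["models.pkl", "models.json", "cbi_runs.csv"])
    state["results"] = results
    if done("fit"):
        return state

    # ---------------------------------------------------------- evaluate
    st_prev = st
    st = _Stage(outdir, "evaluate", _hash(["evaluate", st_prev.key]), cfg.stage_seed("evaluate"))
    if gate(st) == "run":
        st.dir.mkdir(parents=True, exist_ok=True)
        results.save_report(st.dir / "selection.json")
        (st.dir / "summary.txt").write_text(results.summary() + "\n")
        st.write_manifest(["selection.json", "summary.txt"])
    log.info("retained: %s", ", ".join(results.retained))
    if done("evaluate"):
        return state

    # ----------------------------------------------------------- climate
    scen = synth.make_scenarios(
        grid, cfg.synth.gcm_bias_sd, cfg.synth.gcm_noise_sd,
        n_gcms=cfg.synth.n_gcms, seed=cfg.stage_seed("synth-scenarios"),
    )
    corrected = clim.correct_scenarios(scen, grid)
    st_prev = st
    st = _Stage(outdir, "climate", _hash(["climate", st_prev.key, cfg.synth.model_dump()]), cfg.stage_seed("climate"))
    if gate(st) == "run":
        rows = []
        for g in scen.gcms:
            for v in ("SBT", "SST"):
                for label, fld in (("raw", scen.common[g][v]), ("corrected", corrected.common[g][v])):
                    ts = clim.taylor_stats(fld, grid.layer(v), grid.marine_mask)
                    rows.append(
                        {"gcm": g, "variable": v, "fields": label, "r": ts.r,
                         "crmsd": ts.crmsd, "sd_diff": ts.sd_diff, "bias": ts.bias}
                    )
        st.dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(st.dir / "taylor_stats.csv", index=False)
        st.write_manifest(["taylor_stats.csv"])
    state.update(scenarios=scen, corrected=corrected)
    if done("climate"):
        return state

    # ----------------------------------------------------------- project
    st_prev = st
    st = _Stage(outdir, "project", _hash(["project", st_prev.key, cfg.projection.model_dump()]), cfg.stage_seed("project"))
    gate(st)  # always recompute cheaply from cached models if requested
    contemporary = results.project(grid, habitat_mask, provenance={"scenario": "contemporary"})
    future_maps: dict[tuple[float, str], proj.SuitabilityMap] = {}
    for rcp in cfg.projection.rcps:
        for decade in cfg.projection.decades:
            envs = [corrected.fields[(g, rcp, decade)] for g in scen.gcms]
            future_maps[(rcp, decade)] = results.project(
                grid, habitat_mask, env=envs,
                provenance={"scenario": f"RCP{rcp}", "decade": decade, "retained": results.retained},
            )
    change = proj.range_change_table(
        contemporary, future_maps, grid, cfg.projection.threshold_sweep, species=cfg.species
    )
    if st.name in requested or not st.cached():
        st.dir.mkdir(parents=True, exist_ok=True)
        esi_grid = grid.with_layers({"ESI": contemporary.esi, "SD": contemporary.sd})
        write_ascii_grid(st.dir / "esi_contemporary.asc", esi_grid, "ESI")
        write_ascii_grid(st.dir / "esi_sd_contemporary.asc", esi_grid, "SD")
        for (rcp, decade), m in future_maps.items():
            g2 = grid.with_layers({"ESI": m.esi, "SD": m.sd, "dESI": proj.diff_map(m, contemporary)})
            tag = f"rcp{rcp}_{decade}"
            write_ascii_grid(st.dir / f"esi_{tag}.asc", g2, "ESI")
            write_ascii_grid(st.dir / f"desi_{tag}.asc", g2, "dESI")
        change.to_csv(st.dir / "range_change.csv", index=False)
        st.write_manifest(sorted(p.name for p in st.dir.glob("*.asc")) + ["range_change.csv"])
    state.update(contemporary=contemporary, future_maps=future_maps, range_change=change)
    if done("project"):
        return state

    # --------------------------------------------------------------- eez
    st_prev = st
    st = _Stage(outdir, "eez", _hash(["eez", st_prev.key, cfg.eez.model_dump()]), cfg.stage_seed("eez"))
    gate(st)
    summary = eezmod.esi_by_eez(contemporary, grid, polygons).rename(columns={"mean_esi": "esi_contemporary"})
    for (rcp, decade), m in future_maps.items():
        col = f"esi_rcp{rcp}_{decade}"
        fut = eezmod.esi_by_eez(m, grid, polygons)[["eez", "mean_esi"]].rename(columns={"mean_esi": col})
        summary = summary.merge(fut, on="eez")
        summary[f"desi_rcp{rcp}_{decade}"] = summary[col] - summary["esi_contemporary"]
    summary = eezmod.attach_catch(summary, catch, cfg.species, cfg.eez.min_catch_t)
    if st.name in requested or not st.cached():
        st.dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(st.dir / "eez_summary.csv", index=False)
        st.write_manifest(["eez_summary.csv"])
    state["eez_summary"] = summary
    return state
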