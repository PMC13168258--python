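"""End-to-end orchestration: simulate -> baseline -> scenarios -> profiles
-> overlaps -> sensitivity -> report, with per-stage caching and a run
manifest.

The run is configured by a single YAML file with ``world``, ``scenario``,
``profile`` and ``output`` sections.  Each stage writes its outputs into the
output directory and records a cache key (a hash of the relevant config plus
the upstream stages' keys); re-running an unchanged configuration skips
every stage whose outputs are present and whose content hashes still match,
so outputs are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as t30io
from .baseline import build_baseline
from .grid import RasterLayer
from .scenarios import (
    ScenarioConfig,
    build_biodiversity_scenario,
    build_itt_scenario,
    build_ncp_scenario,
    coarsen_frequency,
)
from .social import overlap_analysis, profile, profile_by_continent, sensitivity_sweep
from .synthetic import WorldConfig, generate, plant_contrast

logger = logging.getLogger(__name__)

STAGES = ("simulate", "baseline", "scenario_biodiversity", "scenario_ncp",
          "scenario_itt", "profile", "overlap", "sensitivity", "report")


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _key(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path: str | Path | dict) -> dict:
    if isinstance(path, dict):
        cfg = dict(path)
    else:
        cfg = yaml.safe_load(Path(path).read_text()) or {}
    cfg.setdefault("world", {})
    cfg.setdefault("scenario", {})
    cfg.setdefault("profile", {})
    cfg.setdefault("contrast", {})
    # validate against the dataclass schemas early, with a clear stage name
    try:
        WorldConfig(**cfg["world"])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section 'world' invalid: {exc}") from exc
    try:
        ScenarioConfig(**cfg["scenario"])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section 'scenario' invalid: {exc}") from exc
    return cfg


class _StageRunner:
    """Runs one stage unless its cache key and output hashes are intact."""

    def __init__(self, out_dir: Path, manifest: RunManifest):
        self.out_dir = out_dir
        self.manifest = manifest
        self.keys: dict[str, str] = {}
        self.dirty: set[str] = set()

    def run(self, name: str, key_obj, outputs: list[str], fn,
            deps: tuple[str, ...] = ()) -> dict:
        key = _key(key_obj)
        self.keys[name] = key
        keyfile = self.out_dir / f"{name}.stagekey.json"
        paths = [self.out_dir / o for o in outputs]
        fresh_upstream = not any(d in self.dirty for d in deps)
        if keyfile.exists() and fresh_upstream:
            try:
                rec = json.loads(keyfile.read_text())
            except json.JSONDecodeError:
                rec = {}
            if (
                rec.get("key") == key
                and all(p.exists() for p in paths)
                and all(rec.get("outputs", {}).get(o) == _sha256(self.out_dir / o)
                        for o in outputs)
            ):
                logger.info("stage %s: cache hit", name)
                self.manifest.stages[name] = {**rec, "cached": True}
                return rec
        self.dirty.add(name)
        t0 = time.perf_counter()
        fn()
        missing = [o for o in outputs if not (self.out_dir / o).exists()]
        if missing:
            raise RuntimeError(f"stage {name} did not produce {missing}")
        rec = {
            "key": key,
            "outputs": {o: _sha256(self.out_dir / o) for o in outputs},
            "seconds": round(time.perf_counter() - t0, 4),
            "cached": False,
        }
        keyfile.write_text(json.dumps(rec, indent=2, sort_keys=True))
        self.manifest.stages[name] = rec
        return rec


def run(config: str | Path | dict, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline; returns the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    wcfg = WorldConfig(**cfg["world"])
    scfg = ScenarioConfig(**cfg["scenario"])
    buffer_km = float(cfg["profile"].get("buffer_km", 10.0))
    buffers = [float(b) for b in cfg["profile"].get("sensitivity_buffers_km", [5.0, 10.0, 15.0])]
    coarsen = int(cfg["profile"].get("itt_display_coarsen_factor", 4))

    manifest = RunManifest(
        config=cfg,
        seeds={"world": wcfg.seed, "scenario": scfg.seed},
        version=__version__,
    )
    runner = _StageRunner(out, manifest)

    # stage outputs are also this process's working objects; stages always
    # recompute in memory (cheap) but skip re-writing cached files.
    world = generate(wcfg)
    contrast = cfg.get("contrast") or {}
    if contrast:
        world = plant_contrast(
            world,
            iplc_hdi_offset=float(contrast.get("iplc_hdi_offset", 0.0)),
            iplc_wildharvest_multiplier=float(
                contrast.get("iplc_wildharvest_multiplier", 1.0)),
        )

    sim_outputs = [
        "world/land.asc", "world/population_t0.asc", "world/population_t1.asc",
        "world/hdi.asc", "world/wildharvest_pop.asc", "world/farm_nonfarmed.asc",
        "world/farm_small.asc", "world/farm_large.asc", "world/livestock_system.asc",
        "world/hmi.asc", "world/ncp_rank.asc", "world/continents.asc",
        "world/tropics.asc", "world/kbas.asc", "world/pa_records.geojson",
        "world/iplc_lands.geojson", "world/icca_records.geojson", "world/truth.json",
    ]

    def _simulate():
        d = out / "world"
        d.mkdir(exist_ok=True)
        ly = world.layers
        t30io.write_mask(world.land, d / "land.asc")
        t30io.write_ascii_grid(ly.population_t0, d / "population_t0.asc")
        t30io.write_ascii_grid(ly.population_t1, d / "population_t1.asc")
        t30io.write_ascii_grid(ly.hdi, d / "hdi.asc")
        t30io.write_ascii_grid(ly.wildharvest_pop, d / "wildharvest_pop.asc")
        t30io.write_ascii_grid(ly.farm_nonfarmed, d / "farm_nonfarmed.asc")
        t30io.write_ascii_grid(ly.farm_small, d / "farm_small.asc")
        t30io.write_ascii_grid(ly.farm_large, d / "farm_large.asc")
        t30io.write_ascii_grid(ly.livestock_system, d / "livestock_system.asc")
        t30io.write_ascii_grid(world.hmi, d / "hmi.asc")
        t30io.write_ascii_grid(world.ncp_rank, d / "ncp_rank.asc")
        t30io.write_ascii_grid(ly.continents, d / "continents.asc")
        t30io.write_mask(ly.tropics, d / "tropics.asc")
        t30io.write_mask(world.kbas, d / "kbas.asc")
        t30io.write_pa_records(world.pa_records, d / "pa_records.geojson")
        t30io.write_iplc_lands(world.iplc_lands, d / "iplc_lands.geojson")
        t30io.write_pa_records(world.icca_records, d / "icca_records.geojson")
        (d / "truth.json").write_text(json.dumps(world.truth, indent=2, sort_keys=True))

    runner.run("simulate", {"world": dataclasses.asdict(wcfg), "contrast": contrast},
               sim_outputs, _simulate)

    baseline_net = build_baseline(world.pa_records, world.grid, world.land)

    def _baseline():
        t30io.write_mask(baseline_net.mask, out / "baseline_mask.asc")
        t30io.write_audit(baseline_net.audit, out / "baseline_audit.csv")
        (out / "baseline.json").write_text(json.dumps(
            {"coverage_fraction": baseline_net.coverage_fraction,
             "n_cells": baseline_net.mask.n_cells}, indent=2))

    runner.run("baseline", {"up": runner.keys["simulate"]},
               ["baseline_mask.asc", "baseline_audit.csv", "baseline.json"], _baseline,
               deps=("simulate",))

    scen_cfg_echo = dataclasses.asdict(scfg)
    results = {}

    bio = build_biodiversity_scenario(
        world.features, baseline_net.mask, world.kbas, scfg, world.grid, world.land)
    results["biodiversity"] = bio

    def _bio():
        t30io.write_mask(bio.mask, out / "scenario_biodiversity_mask.asc")
        bio.objective_report.to_csv(out / "scenario_biodiversity_objective.csv", index=False)
        (out / "scenario_biodiversity.json").write_text(json.dumps(
            {"achieved_fraction": bio.achieved_fraction,
             "objective": bio.provenance.get("objective")}, indent=2))

    runner.run("scenario_biodiversity",
               {"up": runner.keys["baseline"], "scenario": scen_cfg_echo},
               ["scenario_biodiversity_mask.asc", "scenario_biodiversity_objective.csv",
                "scenario_biodiversity.json"], _bio, deps=("baseline",))

    ncp = build_ncp_scenario(world.ncp_rank, baseline_net.mask, scfg, world.grid, world.land)
    results["ncp"] = ncp

    def _ncp():
        t30io.write_mask(ncp.mask, out / "scenario_ncp_mask.asc")
        (out / "scenario_ncp.json").write_text(json.dumps(
            {"achieved_fraction": ncp.achieved_fraction,
             "captured_value_share": ncp.provenance["captured_value_share"]}, indent=2))

    runner.run("scenario_ncp", {"up": runner.keys["baseline"], "scenario": scen_cfg_echo},
               ["scenario_ncp_mask.asc", "scenario_ncp.json"], _ncp, deps=("baseline",))

    itt = build_itt_scenario(world.iplc_lands, world.icca_records, baseline_net.mask,
                             world.hmi, scfg, world.grid, world.land)
    results["itt"] = itt

    def _itt():
        t30io.write_mask(itt.mask, out / "scenario_itt_mask.asc")
        t30io.write_ascii_grid(itt.inclusion_frequency, out / "scenario_itt_frequency.asc")
        try:
            disp = coarsen_frequency(itt.inclusion_frequency, coarsen)
            t30io.write_ascii_grid(disp, out / "scenario_itt_presence_coarse.asc")
        except ValueError:
            # grid not divisible by the display factor: write at native scale
            t30io.write_ascii_grid(itt.inclusion_frequency,
                                   out / "scenario_itt_presence_coarse.asc")
        (out / "scenario_itt.json").write_text(json.dumps(
            {"achieved_fraction": itt.achieved_fraction,
             "pre_thinning_fraction": itt.provenance["pre_thinning_fraction"],
             "replicates": scfg.replicates}, indent=2))

    runner.run("scenario_itt", {"up": runner.keys["baseline"], "scenario": scen_cfg_echo},
               ["scenario_itt_mask.asc", "scenario_itt_frequency.asc",
                "scenario_itt_presence_coarse.asc", "scenario_itt.json"], _itt,
               deps=("baseline",))

    # scenario statistics are reported for *expansion* areas (new cells
    # beyond the baseline); the current network is profiled as its own row
    masks = {"current": baseline_net.mask,
             "biodiversity": bio.mask - baseline_net.mask,
             "ncp": ncp.mask - baseline_net.mask,
             "itt": itt.mask - baseline_net.mask}
    itt_new_freq = RasterLayer(
        world.grid,
        itt.inclusion_frequency.values * ~baseline_net.mask.included,
        kind="continuous",
    )
    profiles = {}
    for name, mask in masks.items():
        weights = itt_new_freq if name == "itt" else None
        profiles[name] = profile(mask, world.layers, buffer_km=buffer_km,
                                 inclusion_weights=weights, name=name)
    prof_df = pd.DataFrame([p.to_dict() for p in profiles.values()])
    cont_df = pd.concat(
        [profile_by_continent(m, world.layers).assign(scenario=n)
         for n, m in masks.items()],
        ignore_index=True,
    )

    def _profile():
        prof_df.to_csv(out / "profiles.csv", index=False)
        cont_df.to_csv(out / "profiles_by_continent.csv", index=False)

    runner.run("profile",
               {"ups": [runner.keys[s] for s in
                        ("scenario_biodiversity", "scenario_ncp", "scenario_itt")],
                "buffer_km": buffer_km},
               ["profiles.csv", "profiles_by_continent.csv"], _profile,
               deps=("scenario_biodiversity", "scenario_ncp", "scenario_itt"))

    new_masks = {n: results[n].mask - baseline_net.mask
                 for n in ("biodiversity", "ncp", "itt")}
    report_ov = overlap_analysis(new_masks, world.land, baseline_net.mask)

    def _overlap():
        report_ov.to_frame().to_csv(out / "overlap.csv", index=False)

    runner.run("overlap", {"up": runner.keys["profile"]}, ["overlap.csv"], _overlap, deps=("profile",))

    sens_df = sensitivity_sweep(
        {n: m for n, m in masks.items()}, world.layers, buffer_list=buffers)

    def _sensitivity():
        sens_df.to_csv(out / "sensitivity.csv", index=False)

    runner.run("sensitivity", {"up": runner.keys["profile"], "buffers": buffers},
               ["sensitivity.csv"], _sensitivity, deps=("profile",))

    def _report():
        (out / "report.md").write_text(render_report(profiles, report_ov, baseline_net))

    runner.run("report", {"ups": [runner.keys["overlap"], runner.keys["sensitivity"]]},
               ["report.md"], _report, deps=("overlap", "sensitivity"))

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def render_report(profiles: dict, overlap, baseline_net) -> str:
    """Markdown summary mirroring the population / HDI / livelihoods panels."""
    lines = ["# Target 3 scenario social profile", ""]
    lines.append(f"Current protected/conserved coverage: "
                 f"{100 * baseline_net.coverage_fraction:.1f}% of land\n")
    lines.append("## a. Resident and neighbouring population")
    lines.append("| scenario | resident | within buffer |")
    lines.append("|---|---|---|")
    for n, p in profiles.items():
        lines.append(f"| {n} | {p.resident_pop:,.0f} | {p.buffer_pop:,.0f} |")
    lines.append("")
    lines.append("## b. HDI structure of the resident population (%)")
    lines.append("| scenario | low | medium | high | very high | mean HDI |")
    lines.append("|---|---|---|---|---|---|")
    for n, p in profiles.items():
        c = p.hdi_category_pcts
        mh = f"{p.mean_hdi:.3f}" if p.mean_hdi is not None else "n/a"
        lines.append(f"| {n} | {c['low']:.1f} | {c['medium']:.1f} | {c['high']:.1f} "
                     f"| {c['very_high']:.1f} | {mh} |")
    lines.append("")
    lines.append("## c. Livelihoods")
    lines.append("| scenario | wild-harvest share (% tropical pop) | small farms (% area) "
                 "| large farms (% area) | non-farmed (% area) | rangeland (% area) |")
    lines.append("|---|---|---|---|---|---|")
    for n, p in profiles.items():
        wh = f"{p.wildharvest_share_pct:.1f}" if p.wildharvest_share_pct is not None else "n/a"
        f = p.farm_shares_pct
        lines.append(f"| {n} | {wh} | {f['small_farms']:.1f} | {f['large_farms']:.1f} "
                     f"| {f['nonfarmed']:.1f} | {p.rangeland_share_pct:.1f} |")
    lines.append("")
    lines.append("## Scenario overlap (new areas only)")
    for name, v in overlap.unique_fraction.items():
        lines.append(f"- {name}: {100 * v:.1f}% of its new area unique to it")
    lines.append(f"- shared among all three: {100 * overlap.triple_shared_fraction:.1f}% "
                 f"of new areas ({100 * overlap.triple_shared_land_fraction:.1f}% of land)")
    lines.append(f"- {100 * overlap.none_fraction:.1f}% of land in no scenario")
    lines.append("")
    return "\n".join(lines)
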