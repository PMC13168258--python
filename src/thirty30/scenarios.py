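"""Builders for the three 30% (Target 3) expansion scenarios.

All three scenarios start from the current protected-and-conserved baseline
and add cells until total coverage reaches the target fraction (default
30% of land):

* *Biodiversity*: minimum-shortfall selection over conservation features
  (species areas of habitat, ecoregions) with baseline and Key Biodiversity
  Areas locked in.
* *NCP* (nature's contributions to people): a per-cell priority rank is
  consumed greedily from the top, with baseline cells treated as
  highest-priority.
* *ITT* (Indigenous and traditional territories): union of ICCA records,
  IPLC lands and the baseline, restricted to low-human-modification cells,
  then randomly thinned down to the target with ICCA and baseline cells
  never removed; repeated over replicates to average out the thinning.

The minimum-shortfall solver is a deterministic greedy heuristic with an
exhaustive-enumeration exact counterpart for small instances.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import shapely

from .baseline import PARecord, area_circle
from .grid import (
    CellMask,
    Grid,
    RasterLayer,
    rasterize_coverage,
    regrid,
    threshold_mask,
)

logger = logging.getLogger(__name__)

#: range-size knees of the species representation-target rule (km^2)
SPECIES_TARGET_LOWER_KM2 = 1_000.0
SPECIES_TARGET_UPPER_KM2 = 250_000.0
SPECIES_TARGET_FLOOR = 0.10


@dataclass
class ConservationFeature:
    """A species / ecoregion / KBA with its spatial amount and target.

    ``amount`` holds the feature's area per cell in km^2 (area of habitat
    for species, ecoregion area for ecoregions); ``target_amount`` is the
    representation target in km^2 (may be filled in later by a scenario
    builder); ``weight`` scales the feature's term in the shortfall
    objective.
    """

    id: str
    kind: str  # species | ecoregion | kba
    amount: RasterLayer
    target_amount: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("species", "ecoregion", "kba"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("feature weight must be positive")

    @property
    def total_amount(self) -> float:
        return float(np.nansum(self.amount.values))


@dataclass
class ScenarioConfig:
    total_target_fraction: float = 0.30
    ecoregion_target_fraction: float = 0.15
    hmi_threshold: float = 0.1
    replicates: int = 100
    seed: int = 0
    tie_break: str = "row_major"

    def __post_init__(self) -> None:
        if not (0 < self.total_target_fraction <= 1):
            raise ValueError("total_target_fraction must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.tie_break != "row_major":
            raise ValueError("only row_major tie-breaking is supported")


@dataclass
class ScenarioResult:
    name: str
    mask: CellMask
    achieved_fraction: float
    inclusion_frequency: RasterLayer
    objective_report: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)
    replicate_masks: list[np.ndarray] | None = field(default=None, repr=False)


def species_target(aoh_total_km2: float) -> float:
    """Representation-target fraction for a species from its AOH extent.

    Piecewise log-linear: full protection (1.0) below 1,000 km^2, a 10%
    floor above 250,000 km^2 and log-linear interpolation in between.
    """
    if aoh_total_km2 <= 0:
        raise ValueError("AOH extent must be positive")
    lo, hi = SPECIES_TARGET_LOWER_KM2, SPECIES_TARGET_UPPER_KM2
    if aoh_total_km2 < lo:
        return 1.0
    if aoh_total_km2 > hi:
        return SPECIES_TARGET_FLOOR
    frac = (math.log(aoh_total_km2) - math.log(lo)) / (math.log(hi) - math.log(lo))
    return 1.0 - (1.0 - SPECIES_TARGET_FLOOR) * frac


def shortfall_objective(
    held: np.ndarray, targets: np.ndarray, weights: np.ndarray
) -> float:
    """Sum_f w_f * max(0, t_f - h_f) / t_f."""
    return float(np.sum(weights * np.maximum(0.0, targets - held) / targets))


def _feature_matrix(
    features: list[ConservationFeature], grid: Grid
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[ConservationFeature]]:
    """(F, n_cells) amount matrix plus targets and weights; features with a
    zero target are excluded from the objective with a warning."""
    usable = []
    for f in features:
        if f.target_amount is None:
            raise ValueError(f"feature {f.id}: target_amount not set")
        if f.target_amount == 0:
            warnings.warn(
                f"feature {f.id} has a zero target; excluded from the objective"
            )
            continue
        if f.amount.grid != grid:
            raise ValueError(f"feature {f.id}: amount layer not on the given grid")
        usable.append(f)
    if not usable:
        return (
            np.zeros((0, grid.n_cells)),
            np.zeros(0),
            np.zeros(0),
            [],
        )
    A = np.stack([np.nan_to_num(f.amount.values.ravel()) for f in usable])
    t = np.array([f.target_amount for f in usable], dtype=float)
    w = np.array([f.weight for f in usable], dtype=float)
    return A, t, w, usable


def _objective_report(
    usable: list[ConservationFeature], held: np.ndarray
) -> pd.DataFrame:
    rows = [
        {
            "feature_id": f.id,
            "kind": f.kind,
            "target_km2": f.target_amount,
            "held_km2": float(h),
            "shortfall": float(max(0.0, f.target_amount - h) / f.target_amount),
        }
        for f, h in zip(usable, held)
    ]
    return pd.DataFrame(rows, columns=["feature_id", "kind", "target_km2", "held_km2", "shortfall"])


def min_shortfall_select(
    features: list[ConservationFeature],
    locked_in: CellMask,
    budget_cells: int,
    grid: Grid,
    candidates: CellMask | None = None,
    beam_width: int = 10,
    refine_swaps: bool = True,
    max_swaps: int | None = None,
) -> ScenarioResult:
    """Minimum-shortfall selection of up to ``budget_cells`` cells beyond
    the locked-in set.

    The solver is a deterministic beam search over greedy additions: at
    each step every beam state is expanded by its ``beam_width`` candidate
    cells with the largest marginal decrease of
    ``sum_f w_f max(0, t_f - h_f)/t_f`` (ties to the lowest row-major
    index) and the best ``beam_width`` partial selections are kept;
    ``beam_width=1`` reduces to plain greedy.  The search stops early once
    no cell improves the objective.  A final iterative-improvement phase
    (the exchange step familiar from reserve-selection software) applies
    the best strictly-improving one-out/one-in swap until none exists,
    removing residual saturation artefacts of myopic ordering.
    """
    if budget_cells < 0:
        raise ValueError("budget_cells must be >= 0")
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    A, t, w, usable = _feature_matrix(features, grid)
    locked_flat = locked_in.included.ravel()
    if candidates is None:
        cand_flat = ~locked_flat
    else:
        cand_flat = candidates.included.ravel() & ~locked_flat

    held0 = A[:, locked_flat].sum(axis=1) if len(usable) else np.zeros(0)
    obj0 = shortfall_objective(held0, t, w) if len(usable) else 0.0
    scale = w / t if len(usable) else None

    # beam over partial selections: each state is (objective, added-cells
    # tuple, held vector); expanded by the beam_width best additions
    best_state = (obj0, (), held0)
    if len(usable) and budget_cells > 0:
        beam = [best_state]
        for _ in range(budget_cells):
            pool: dict[tuple, tuple] = {}
            for obj, added, held in beam:
                r = np.maximum(t - held, 0.0)
                if not r.any():
                    continue
                idx = np.flatnonzero(cand_flat)
                if added:
                    idx = idx[~np.isin(idx, added)]
                if idx.size == 0:
                    continue
                dec = scale @ np.minimum(A[:, idx], r[:, None])
                k = min(beam_width, idx.size)
                top = np.argpartition(-dec, k - 1)[:k]
                # deterministic order: largest decrease, then lowest index
                top = top[np.lexsort((idx[top], -dec[top]))]
                for j in top:
                    if dec[j] <= 0:
                        continue
                    cell = int(idx[j])
                    new_added = tuple(sorted(added + (cell,)))
                    if new_added in pool:
                        continue
                    pool[new_added] = (obj - float(dec[j]), new_added,
                                       held + A[:, cell])
            if not pool:
                break
            beam = sorted(pool.values(), key=lambda s: (s[0], s[1]))[:beam_width]
            if beam[0][0] < best_state[0] - 1e-15 or len(beam[0][1]) > len(
                    best_state[1]):
                best_state = beam[0]

    obj_final, added, held = best_state
    selected = locked_flat.copy()
    selected[list(added)] = True
    n_added = len(added)
    trace = [obj0, obj_final] if added else [obj0]

    n_swaps = 0
    if refine_swaps and len(usable) and n_added > 0:
        if max_swaps is None:
            max_swaps = 4 * n_added
        while n_swaps < max_swaps:
            swap = _best_swap(A, t, w, selected, locked_flat, cand_flat, held)
            if swap is None:
                break
            c_out, c_in, new_held = swap
            selected[c_out] = False
            selected[c_in] = True
            held = new_held
            trace.append(shortfall_objective(held, t, w))
            n_swaps += 1

    mask = CellMask(grid, selected.reshape(grid.shape))
    freq = RasterLayer(grid, mask.included.astype(float), kind="continuous")
    return ScenarioResult(
        name="min_shortfall",
        mask=mask,
        achieved_fraction=mask.n_cells / grid.n_cells,
        inclusion_frequency=freq,
        objective_report=_objective_report(usable, held),
        provenance={
            "budget_cells": budget_cells,
            "cells_added": n_added,
            "swaps_applied": n_swaps,
            "objective": trace[-1],
            "objective_trace": trace,
        },
    )


def _best_swap(A, t, w, selected, locked_flat, cand_flat, held):
    """Best strictly-improving (remove one selected, add one candidate)
    exchange, or None.  Ties break to the lowest (out, in) row-major pair."""
    scale = w / t
    removable = np.flatnonzero(selected & ~locked_flat)
    addable = np.flatnonzero(cand_flat & ~selected)
    if removable.size == 0 or addable.size == 0:
        return None
    cur_obj = shortfall_objective(held, t, w)
    best = None
    best_obj = cur_obj - 1e-12
    for c_out in removable:
        h_minus = held - A[:, c_out]
        r = np.maximum(t - h_minus, 0.0)
        # objective after removal, minus the best achievable decrease
        obj_minus = shortfall_objective(h_minus, t, w)
        dec = scale @ np.minimum(A[:, addable], r[:, None])
        j = int(np.argmax(dec))
        obj_swap = obj_minus - dec[j]
        if obj_swap < best_obj - 1e-12:
            best_obj = obj_swap
            best = (int(c_out), int(addable[j]), h_minus + A[:, addable[j]])
    return best


def min_shortfall_exact(
    features: list[ConservationFeature],
    locked_in: CellMask,
    budget_cells: int,
    grid: Grid,
    candidates: CellMask | None = None,
) -> tuple[CellMask, float]:
    """Exhaustive-enumeration optimum of the minimum-shortfall problem.

    Only feasible for small instances (<= 20 candidate cells); intended as
    the exact counterpart of the greedy solver on desk-scale problems.
    Ties resolve to the lexicographically smallest (row-major) cell set.
    """
    A, t, w, usable = _feature_matrix(features, grid)
    locked_flat = locked_in.included.ravel()
    if candidates is None:
        cand_flat = ~locked_flat
    else:
        cand_flat = candidates.included.ravel() & ~locked_flat
    cand_idx = np.flatnonzero(cand_flat)
    if cand_idx.size > 20:
        raise ValueError(
            f"{cand_idx.size} candidate cells; exact enumeration is capped at 20"
        )
    base_held = A[:, locked_flat].sum(axis=1) if len(usable) else np.zeros(0)
    k = min(budget_cells, cand_idx.size)
    best_obj = np.inf
    best_set: tuple[int, ...] = ()
    for combo in combinations(range(cand_idx.size), k):
        held = base_held + (A[:, cand_idx[list(combo)]].sum(axis=1) if combo else 0.0)
        obj = shortfall_objective(held, t, w) if len(usable) else 0.0
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_set = combo
    sel = locked_flat.copy()
    sel[cand_idx[list(best_set)]] = True
    return CellMask(grid, sel.reshape(grid.shape)), float(best_obj)


def assign_feature_targets(
    features: list[ConservationFeature], config: ScenarioConfig
) -> None:
    """Fill in default representation targets in place.

    Ecoregions get ``ecoregion_target_fraction`` (default 15%) of their
    area; species get the AOH-dependent fraction from
    :func:`species_target`; KBA features get a 100% target (though KBAs are
    normally locked in rather than optimised for).
    """
    for f in features:
        if f.target_amount is not None:
            continue
        total = f.total_amount
        if f.kind == "ecoregion":
            f.target_amount = config.ecoregion_target_fraction * total
        elif f.kind == "species":
            f.target_amount = species_target(total) * total if total > 0 else 0.0
        else:
            f.target_amount = total


def _target_cells(land: CellMask, config: ScenarioConfig) -> int:
    return int(round(config.total_target_fraction * land.n_cells))


def build_biodiversity_scenario(
    features: list[ConservationFeature],
    baseline: CellMask,
    kbas: CellMask,
    config: ScenarioConfig,
    grid: Grid,
    land: CellMask,
) -> ScenarioResult:
    """Minimum-shortfall expansion with baseline and KBAs locked in."""
    assign_feature_targets(features, config)
    locked = (baseline | kbas) & land
    n_target = _target_cells(land, config)
    if locked.n_cells > n_target:
        raise ValueError(
            f"locked-in cells ({locked.n_cells}) already exceed the "
            f"{config.total_target_fraction:.0%} target ({n_target} cells) "
            f"by {locked.n_cells - n_target}"
        )
    budget = n_target - locked.n_cells
    result = min_shortfall_select(features, locked, budget, grid, candidates=land)
    # If the greedy pass stalls (every remaining cell leaves the objective
    # unchanged), pad with the first candidate cells in row-major order so
    # the scenario still reaches the coverage target.
    short = n_target - result.mask.n_cells
    if short > 0:
        sel = result.mask.included.ravel().copy()
        free = np.flatnonzero(land.included.ravel() & ~sel)
        sel[free[:short]] = True
        result.mask = CellMask(grid, sel.reshape(grid.shape))
        result.inclusion_frequency = RasterLayer(
            grid, result.mask.included.astype(float), kind="continuous"
        )
    result.name = "biodiversity"
    result.achieved_fraction = result.mask.coverage_fraction(land)
    result.provenance.update(
        {"config": vars(config).copy(), "locked_cells": locked.n_cells}
    )
    return result


def build_ncp_scenario(
    rank: RasterLayer,
    baseline: CellMask,
    config: ScenarioConfig,
    grid: Grid,
    land: CellMask,
) -> ScenarioResult:
    """Top-rank selection of the NCP priority layer.

    Baseline cells are overridden to the highest priority, then cells are
    taken in descending rank (row-major tie-break) until the coverage target
    is reached.  Also reports the captured share of total NCP value,
    computed on the original (pre-override) rank layer.
    """
    vals = rank.values.ravel().astype(float)
    land_flat = land.included.ravel()
    vals = np.where(land_flat, vals, np.nan)
    if not land_flat.any() or np.all(np.isnan(vals[land_flat])):
        raise ValueError("NCP rank layer is all-nodata on land")
    n_target = _target_cells(land, config)
    base_flat = baseline.included.ravel() & land_flat

    override = vals.copy()
    override[base_flat] = np.inf
    # stable sort on (-rank, row-major index); NaN cells sort last
    keys = np.where(np.isnan(override), -np.inf, override)
    order = np.argsort(-keys, kind="stable")
    order = order[land_flat[order] & ~np.isnan(vals[order]) | base_flat[order]]
    take = order[: max(n_target, int(base_flat.sum()))]
    sel = np.zeros(grid.n_cells, dtype=bool)
    sel[take] = True
    sel |= base_flat  # baseline always in, even if rank was nodata there
    mask = CellMask(grid, sel.reshape(grid.shape))

    with np.errstate(invalid="ignore"):
        total_value = float(np.nansum(vals[land_flat]))
    captured = float(np.nansum(vals[sel & land_flat]))
    share = captured / total_value if total_value > 0 else float("nan")
    freq = RasterLayer(grid, mask.included.astype(float), kind="continuous")
    return ScenarioResult(
        name="ncp",
        mask=mask,
        achieved_fraction=mask.coverage_fraction(land),
        inclusion_frequency=freq,
        provenance={
            "config": vars(config).copy(),
            "captured_value_share": share,
        },
    )


def build_itt_scenario(
    iplc_lands: list[tuple[shapely.Geometry, str]],
    icca_records: list[PARecord],
    baseline: CellMask,
    hmi: RasterLayer,
    config: ScenarioConfig,
    grid: Grid,
    land: CellMask,
) -> ScenarioResult:
    """Indigenous-and-traditional-territories scenario.

    Steps: buffer point ICCAs to their reported area; drop IPLC geometries
    flagged as subject to other special rights; union ICCA + IPLC +
    baseline on the grid; drop candidate cells (not ICCA, not baseline)
    whose human-modification index exceeds the threshold; then, if coverage
    exceeds the target, remove uniformly-random eligible cells until the
    target is met.  The removal is replicated (seeds ``seed+1 .. seed+R``);
    the reported mask is replicate 1 and ``inclusion_frequency`` is the
    per-cell mean over replicates.
    """
    icca_geoms = []
    for rec in icca_records:
        if rec.geometry_kind == "point":
            if rec.reported_area_km2 is None or rec.reported_area_km2 <= 0:
                logger.info("ICCA %s: point without reported area, dropped", rec.id)
                continue
            icca_geoms.append((rec.id, area_circle(rec.geometry, rec.reported_area_km2)))
        elif rec.geometry is not None and rec.geometry.is_valid:
            icca_geoms.append((rec.id, rec.geometry))
    iplc_geoms = [
        (f"iplc_{i}", geom)
        for i, (geom, flag) in enumerate(iplc_lands)
        if flag != "other_special_rights"
    ]

    icca_cells = threshold_mask(rasterize_coverage(icca_geoms, grid), 0.5) & land
    union_cells = (
        threshold_mask(rasterize_coverage(icca_geoms + iplc_geoms, grid), 0.5) & land
    ) | baseline | icca_cells

    protected = (icca_cells | baseline).included
    high_mod = np.zeros(grid.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        high_mod = hmi.values > config.hmi_threshold
    keepable = union_cells.included & (protected | ~high_mod)

    n_target = _target_cells(land, config)
    fixed = keepable & protected
    removable_idx = np.flatnonzero((keepable & ~protected).ravel())
    n_fixed = int(fixed.sum())
    if n_fixed > n_target:
        raise ValueError(
            f"non-removable ICCA/baseline cells ({n_fixed}) alone exceed the "
            f"coverage target ({n_target} cells)"
        )
    n_keep = min(n_target - n_fixed, removable_idx.size)

    R = config.replicates
    freq_acc = np.zeros(grid.n_cells, dtype=float)
    replicate_masks: list[np.ndarray] = []
    fixed_flat = fixed.ravel()
    for rep in range(1, R + 1):
        rng = np.random.default_rng(config.seed + rep)
        keep = rng.choice(removable_idx, size=n_keep, replace=False)
        sel = fixed_flat.copy()
        sel[keep] = True
        replicate_masks.append(sel.reshape(grid.shape))
        freq_acc += sel

    freq = RasterLayer(grid, (freq_acc / R).reshape(grid.shape), kind="continuous")
    mask = CellMask(grid, replicate_masks[0])
    return ScenarioResult(
        name="itt",
        mask=mask,
        achieved_fraction=mask.coverage_fraction(land),
        inclusion_frequency=freq,
        provenance={
            "config": vars(config).copy(),
            "replicate_seeds": [config.seed + r for r in range(1, R + 1)],
            "n_fixed_cells": n_fixed,
            "n_removable_cells": int(removable_idx.size),
            "n_kept_removable": int(n_keep),
            "pre_thinning_fraction": union_cells.coverage_fraction(land),
        },
        replicate_masks=replicate_masks,
    )


def coarsen_frequency(freq: RasterLayer, factor: int) -> RasterLayer:
    """Privacy-preserving coarse presence layer: mean-regrid then binarize.

    A coarse block is marked present (1.0) if the scenario touches any of
    its fine cells; used only for display/reporting of sensitive layers.
    """
    coarse = regrid(freq, factor, "mean")
    with np.errstate(invalid="ignore"):
        present = np.where(
            np.isnan(coarse.values), np.nan, (coarse.values > 0).astype(float)
        )
    return RasterLayer(coarse.grid, present, kind="continuous")
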