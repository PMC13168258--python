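"""Social statistics for a scenario mask: population, HDI, livelihoods.

Given a cell mask (the baseline network or a 30% expansion scenario) and a
stack of social layers on the same grid, this module computes the resident
and 10 km-buffer populations, the Human Development Index (HDI) structure of
the resident population, livelihood shares (tropical wild harvesting, farm
area by size class, livestock rangeland area), population growth between two
epochs, continental disaggregation and cross-scenario overlap statistics.

HDI categories follow the UNDP thresholds, made half-open so every value
falls in exactly one class: Low [0, 0.55), Medium [0.55, 0.70),
High [0.70, 0.80), Very High [0.80, 1].  The mean HDI is population-weighted
("the average HDI of the population"), not area-weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .grid import (
    CellMask,
    RasterLayer,
    ZeroWeightError,
    buffer_mask,
)

logger = logging.getLogger(__name__)

HDI_CATEGORIES = ("low", "medium", "high", "very_high")
HDI_EDGES = (0.55, 0.70, 0.80)


def hdi_category_codes(hdi_values: np.ndarray) -> np.ndarray:
    """0=Low, 1=Medium, 2=High, 3=Very High; -1 where HDI is nodata."""
    codes = np.full(hdi_values.shape, -1, dtype=np.int64)
    ok = ~np.isnan(hdi_values)
    v = hdi_values[ok]
    c = np.zeros(v.shape, dtype=np.int64)
    for edge in HDI_EDGES:
        c += v >= edge
    codes[ok] = c
    return codes


@dataclass
class SocialLayers:
    """All gridded social inputs on the common grid."""

    population_t0: RasterLayer
    population_t1: RasterLayer
    hdi: RasterLayer
    wildharvest_pop: RasterLayer
    farm_nonfarmed: RasterLayer
    farm_small: RasterLayer
    farm_large: RasterLayer
    livestock_system: RasterLayer
    tropics: CellMask
    continents: RasterLayer
    land: CellMask
    livestock_only_code: int = 2
    continent_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = self.population_t0.grid
        for name in (
            "population_t1",
            "hdi",
            "wildharvest_pop",
            "farm_nonfarmed",
            "farm_small",
            "farm_large",
            "livestock_system",
            "continents",
        ):
            if getattr(self, name).grid != grid:
                raise ValueError(f"layer {name} is not on the common grid")
        for name in ("tropics", "land"):
            if getattr(self, name).grid != grid:
                raise ValueError(f"mask {name} is not on the common grid")


@dataclass
class SocialProfile:
    """All per-mask social statistics; ``None`` marks not-applicable."""

    name: str
    n_cells: int
    area_km2: float
    resident_pop: float
    buffer_pop: float
    buffer_km: float
    hdi_category_pops: dict[str, float]
    hdi_category_pcts: dict[str, float]
    mean_hdi: float | None
    wildharvest_share_pct: float | None
    tropical_resident_pop: float
    farm_shares_pct: dict[str, float]
    rangeland_share_pct: float
    growth_pct: float | None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "n_cells": self.n_cells,
            "area_km2": self.area_km2,
            "resident_pop": self.resident_pop,
            "buffer_pop": self.buffer_pop,
            "buffer_km": self.buffer_km,
            "mean_hdi": self.mean_hdi,
            "wildharvest_share_pct": self.wildharvest_share_pct,
            "tropical_resident_pop": self.tropical_resident_pop,
            "rangeland_share_pct": self.rangeland_share_pct,
            "growth_pct": self.growth_pct,
        }
        for k, v in self.hdi_category_pops.items():
            d[f"pop_hdi_{k}"] = v
        for k, v in self.hdi_category_pcts.items():
            d[f"pct_hdi_{k}"] = v
        for k, v in self.farm_shares_pct.items():
            d[f"pct_area_{k}"] = v
        return d


@dataclass
class OverlapReport:
    """Set statistics over the scenarios' *new* cells (baseline excluded)."""

    unique_fraction: dict[str, float]
    pairwise_directional: dict[tuple[str, str], float]  # |A&B| / |A|
    pairwise_jaccard: dict[tuple[str, str], float]  # |A&B| / |A|B union|
    triple_shared_fraction: float  # of the union of all new cells
    triple_shared_land_fraction: float
    none_fraction: float  # of land outside baseline and every scenario

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in self.unique_fraction.items():
            rows.append({"statistic": f"unique[{k}]", "value": v})
        for (a, b), v in self.pairwise_directional.items():
            rows.append({"statistic": f"shared[{a}&{b}]/|{a}|", "value": v})
        for (a, b), v in self.pairwise_jaccard.items():
            rows.append({"statistic": f"jaccard[{a},{b}]", "value": v})
        rows.append({"statistic": "triple_shared_of_union", "value": self.triple_shared_fraction})
        rows.append({"statistic": "triple_shared_of_land", "value": self.triple_shared_land_fraction})
        rows.append({"statistic": "none_of_land", "value": self.none_fraction})
        return pd.DataFrame(rows)


def _weighted_sum(values: np.ndarray, w: np.ndarray) -> float:
    return float(np.nansum(values * w))


def profile(
    mask: CellMask,
    layers: SocialLayers,
    buffer_km: float = 10.0,
    inclusion_weights: RasterLayer | None = None,
    name: str = "scenario",
) -> SocialProfile:
    """Full social profile of a mask.

    ``inclusion_weights`` (a per-cell inclusion-frequency layer in [0, 1],
    as produced by the ITT scenario replicates) turns every zonal sum into a
    frequency-weighted sum, which equals the replicate mean exactly for
    population counts and areas and is the corresponding ratio-of-means for
    shares.  The buffer ring is always computed from the reference mask.
    """
    grid = mask.grid
    if layers.population_t0.grid != grid:
        raise ValueError("layers are not on the mask's grid")
    if inclusion_weights is not None:
        w = np.nan_to_num(inclusion_weights.values).astype(float)
        if w.min() < 0 or w.max() > 1 + 1e-9:
            raise ValueError("inclusion weights must lie in [0, 1]")
    else:
        w = mask.included.astype(float)

    pop0 = layers.population_t0.values
    pop1 = layers.population_t1.values
    resident = _weighted_sum(pop0, w)

    ring = buffer_mask(mask, buffer_km)
    buffer_pop = _weighted_sum(pop0, ring.included.astype(float))

    codes = hdi_category_codes(layers.hdi.values)
    cat_pops: dict[str, float] = {}
    for i, cname in enumerate(HDI_CATEGORIES):
        cat_pops[cname] = _weighted_sum(np.where(codes == i, pop0, 0.0), w)
    cat_total = sum(cat_pops.values())
    if cat_total > 0:
        cat_pcts = {k: 100.0 * v / cat_total for k, v in cat_pops.items()}
    else:
        cat_pcts = {k: float("nan") for k in cat_pops}

    pw = np.where(codes >= 0, pop0, 0.0) * w
    pw_tot = float(np.nansum(pw))
    mean_hdi = (
        float(np.nansum(np.nan_to_num(layers.hdi.values) * pw) / pw_tot)
        if pw_tot > 0
        else None
    )

    trop_w = w * layers.tropics.included
    trop_pop = _weighted_sum(pop0, trop_w)
    if trop_pop > 0:
        wildharvest_share = 100.0 * _weighted_sum(
            layers.wildharvest_pop.values, trop_w
        ) / trop_pop
    else:
        wildharvest_share = None
        logger.info("%s: no tropical resident population; wild-harvest share n/a", name)

    area = float(w.sum()) * grid.cell_area_km2
    if area > 0:
        farm_shares = {
            "nonfarmed": 100.0 * _weighted_sum(layers.farm_nonfarmed.values, w) / area,
            "small_farms": 100.0 * _weighted_sum(layers.farm_small.values, w) / area,
            "large_farms": 100.0 * _weighted_sum(layers.farm_large.values, w) / area,
        }
        livestock_only = (
            layers.livestock_system.values == layers.livestock_only_code
        ).astype(float)
        rangeland_share = (
            100.0 * float((livestock_only * w).sum()) * grid.cell_area_km2 / area
        )
    else:
        farm_shares = {k: float("nan") for k in ("nonfarmed", "small_farms", "large_farms")}
        rangeland_share = float("nan")

    if resident > 0:
        growth = 100.0 * (_weighted_sum(pop1, w) - resident) / resident
    else:
        growth = None
        logger.info("%s: zero resident population; growth n/a", name)

    return SocialProfile(
        name=name,
        n_cells=mask.n_cells,
        area_km2=mask.area_km2,
        resident_pop=resident,
        buffer_pop=buffer_pop,
        buffer_km=buffer_km,
        hdi_category_pops=cat_pops,
        hdi_category_pcts=cat_pcts,
        mean_hdi=mean_hdi,
        wildharvest_share_pct=wildharvest_share,
        tropical_resident_pop=trop_pop,
        farm_shares_pct=farm_shares,
        rangeland_share_pct=rangeland_share,
        growth_pct=growth,
    )


def profile_by_continent(
    mask: CellMask, layers: SocialLayers, buffer_km: float = 10.0
) -> pd.DataFrame:
    """Per-continent resident population and population-weighted mean HDI.

    ``continental_mean_hdi`` is the population-weighted mean over the whole
    continent (the dashed reference line of a per-continent comparison
    figure); cells whose continent code is nodata land in an ``unassigned``
    row.  Per-continent resident populations sum to the global figure.
    """
    grid = mask.grid
    cont = layers.continents.values
    nod = layers.continents.nodata
    pop0 = np.nan_to_num(layers.population_t0.values)
    hdi = layers.hdi.values
    codes_present = sorted(
        int(c) for c in np.unique(cont[layers.land.included]) if c != nod
    )
    rows = []
    for code in codes_present + [None]:
        if code is None:
            in_cont = (cont == nod) & layers.land.included
            cname = "unassigned"
            if not (in_cont & mask.included).any() and not in_cont.any():
                continue
        else:
            in_cont = cont == code
            cname = layers.continent_names.get(code, f"continent_{code}")
        sel = in_cont & mask.included
        pop = float(pop0[sel].sum())
        hdi_ok = ~np.isnan(hdi)
        pw = float(pop0[sel & hdi_ok].sum())
        mh = float((pop0 * np.nan_to_num(hdi))[sel & hdi_ok].sum() / pw) if pw > 0 else None
        cw = float(pop0[in_cont & hdi_ok].sum())
        cmh = (
            float((pop0 * np.nan_to_num(hdi))[in_cont & hdi_ok].sum() / cw)
            if cw > 0
            else None
        )
        rows.append(
            {
                "continent": cname,
                "continent_code": -1 if code is None else code,
                "n_cells": int(sel.sum()),
                "resident_pop": pop,
                "mean_hdi": mh,
                "continental_mean_hdi": cmh,
            }
        )
    return pd.DataFrame(rows)


def overlap_analysis(
    new_masks: dict[str, CellMask],
    land: CellMask,
    baseline: CellMask,
) -> OverlapReport:
    """Overlap statistics among the scenarios' new (beyond-baseline) cells.

    ``new_masks`` must already exclude baseline cells; passing a mask that
    intersects the baseline is an error so the caller cannot silently mix
    existing and new areas.  Because the printed denominator of a pairwise
    "X% overlap" figure is ambiguous, both directional (|A&B|/|A|, both
    orders) and symmetric (Jaccard) versions are reported.
    """
    names = list(new_masks)
    for n, m in new_masks.items():
        if (m.included & baseline.included).any():
            raise ValueError(f"mask {n!r} intersects the baseline; subtract it first")
    arr = {n: m.included for n, m in new_masks.items()}
    union_new = np.zeros(land.grid.shape, dtype=bool)
    for a in arr.values():
        union_new |= a

    unique = {}
    for n in names:
        others = np.zeros_like(union_new)
        for m in names:
            if m != n:
                others |= arr[m]
        denom = arr[n].sum()
        unique[n] = float((arr[n] & ~others).sum() / denom) if denom else float("nan")

    directional = {}
    jaccard = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = int((arr[a] & arr[b]).sum())
            uni = int((arr[a] | arr[b]).sum())
            directional[(a, b)] = float(inter / arr[a].sum()) if arr[a].sum() else float("nan")
            directional[(b, a)] = float(inter / arr[b].sum()) if arr[b].sum() else float("nan")
            jaccard[(a, b)] = float(inter / uni) if uni else float("nan")

    triple = np.ones_like(union_new)
    for a in arr.values():
        triple &= a
    n_union = int(union_new.sum())
    triple_of_union = float(triple.sum() / n_union) if n_union else float("nan")
    n_land = land.n_cells
    triple_of_land = float(triple.sum() / n_land)
    covered = union_new | baseline.included
    none_frac = float((land.included & ~covered).sum() / n_land)
    return OverlapReport(
        unique_fraction=unique,
        pairwise_directional=directional,
        pairwise_jaccard=jaccard,
        triple_shared_fraction=triple_of_union,
        triple_shared_land_fraction=triple_of_land,
        none_fraction=none_frac,
    )


def sensitivity_sweep(
    masks: dict[str, CellMask] | CellMask,
    layers: SocialLayers,
    alternates: dict[str, dict[str, RasterLayer]] | None = None,
    buffer_list: list[float] = (10.0,),
) -> pd.DataFrame:
    """Re-run the profiler over layer substitutions and buffer distances.

    ``alternates`` maps a dataset label to a dict of ``SocialLayers`` field
    substitutions (e.g. ``{"altpop": {"population_t0": other_layer}}``); the
    unmodified layer stack is always included under the label ``primary``.
    Combinations whose substitute layers are on a different grid are skipped
    with a logged reason.  Returns a long-form table keyed by scenario x
    dataset x buffer.
    """
    if isinstance(masks, CellMask):
        masks = {"scenario": masks}
    alternates = alternates or {}
    layer_sets: dict[str, SocialLayers | None] = {"primary": layers}
    for label, subs in alternates.items():
        try:
            layer_sets[label] = dc_replace(layers, **subs)
        except ValueError as exc:
            logger.warning("sensitivity set %r skipped: %s", label, exc)
            layer_sets[label] = None
    rows = []
    for sname, mask in masks.items():
        for label, ls in layer_sets.items():
            if ls is None:
                continue
            for bk in buffer_list:
                try:
                    p = profile(mask, ls, buffer_km=bk, name=sname)
                except (ValueError, ZeroWeightError) as exc:
                    logger.warning(
                        "sensitivity combination (%s, %s, %s km) skipped: %s",
                        sname, label, bk, exc,
                    )
                    continue
                row = {"scenario": sname, "dataset": label, "buffer_km": bk}
                row.update(p.to_dict())
                rows.append(row)
    return pd.DataFrame(rows)
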