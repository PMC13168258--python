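"""Seeded generator of a fictitious world for end-to-end testing.

The generator emulates the *statistical structure* of the global layers the
analysis consumes — clustered population, HDI spatially correlated with
density, wild harvesting concentrated in the low-HDI tropics, a
human-modification index that decays away from population clusters, IPLC
lands preferentially placed on remote low-modification cells — without any
resemblance to real geography.  Everything flows from a single seed through
named substreams, so adding draws to one component never perturbs another.

Latitude is synthesized as a linear north-south coordinate so the +-24
degree tropics band is exercised without spherical geometry.  The default
world is a 60x60 grid of 5 km cells (~3,600 cells) and generates in well
under a second; population is generated on a 5x finer grid and aggregated
by summation, so the sum-conservation path of the regridder is exercised on
every world.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .baseline import PARecord
from .grid import CATEGORICAL_NODATA, CellMask, Grid, RasterLayer, regrid
from .scenarios import ConservationFeature
from .social import SocialLayers

_SUBSTREAMS = (
    "land",
    "population",
    "hdi",
    "hmi",
    "vegetation",
    "wildharvest",
    "farms",
    "livestock",
    "ncp",
    "species",
    "ecoregions",
    "kbas",
    "pa",
    "iplc",
    "icca",
    "continents",
    "growth",
)


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults give a ~3,600-cell world."""

    n_rows: int = 60
    n_cols: int = 60
    cell_size_km: float = 5.0
    fine_factor: int = 5
    land_fraction: float = 0.70
    lat_max_deg: float = 57.5

    n_population_clusters: int = 12
    cluster_mass_log_mu: float = 12.0   # log persons; median e^12 ~ 160k
    cluster_mass_log_sigma: float = 1.0
    cluster_sigma_km_range: tuple[float, float] = (10.0, 40.0)
    rural_background_density_per_km2: float = 2.0

    hdi_density_rho: float = 0.8

    wildharvest_base_rate: float = 0.55
    wildharvest_hdi_slope: float = 8.0  # logistic slope on (hdi_mid - hdi)
    wildharvest_hdi_mid: float = 0.62
    # participation ceiling outside custodian territories; leaves headroom
    # for the planted within-IPLC contrast
    wildharvest_max_rate: float = 0.75

    n_species: int = 40
    aoh_km2_range: tuple[float, float] = (200.0, 400_000.0)
    n_ecoregions: int = 8
    n_kbas: int = 6

    pa_count: int = 26
    pa_radius_km_range: tuple[float, float] = (6.0, 18.0)
    n_proposed: int = 2
    n_mab: int = 2
    n_marine: int = 2
    n_point_with_area: int = 3
    n_point_no_area: int = 2

    iplc_count: int = 14
    iplc_radius_km_range: tuple[float, float] = (12.0, 32.0)
    iplc_low_hmi_threshold: float = 0.1
    iplc_tropics_weight: float = 4.0
    iplc_special_rights_fraction: float = 0.15
    icca_count: int = 6
    icca_point_fraction: float = 0.5

    hmi_decay_km: float = 25.0
    hmi_low_fraction: float = 0.40  # share of land kept minimally modified
    n_continents: int = 3

    growth_base: float = 0.09
    growth_low_hdi_boost: float = 0.9  # extra growth per unit HDI below the mid

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.land_fraction <= 1):
            raise ValueError("land_fraction must lie in (0, 1]")
        if self.land_fraction == 0 and self.n_population_clusters > 0:
            raise ValueError("cannot place population clusters with no land")
        for name in ("n_population_clusters", "n_species", "n_ecoregions",
                     "n_kbas", "pa_count", "iplc_count", "icca_count",
                     "n_continents"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticWorld:
    grid: Grid
    land: CellMask
    layers: SocialLayers
    hmi: RasterLayer
    ncp_rank: RasterLayer
    latitude: RasterLayer
    features: list[ConservationFeature]
    pa_records: list[PARecord]
    iplc_lands: list[tuple[shapely.Geometry, str]]
    icca_records: list[PARecord]
    kbas: CellMask
    population_fine: RasterLayer
    truth: dict = field(default_factory=dict)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {n: np.random.default_rng(c) for n, c in zip(_SUBSTREAMS, children)}


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / (f.std() + 1e-12)


def _sample_land_cells(
    rng: np.random.Generator, land: np.ndarray, n: int, weights: np.ndarray | None = None
) -> np.ndarray:
    idx = np.flatnonzero(land.ravel())
    if weights is not None:
        p = weights.ravel()[idx].astype(float)
        p = np.clip(p, 0, None)
        p = p / p.sum() if p.sum() > 0 else None
    else:
        p = None
    return rng.choice(idx, size=min(n, idx.size), replace=False, p=p)


def generate(config: WorldConfig | None = None) -> SyntheticWorld:
    """Generate a complete world; deterministic given ``config.seed``."""
    cfg = config or WorldConfig()
    rngs = _rngs(cfg.seed)
    grid = Grid(cfg.n_rows, cfg.n_cols, cfg.cell_size_km)
    R, C = grid.shape

    # --- land: smoothed noise, thresholded at the exact cell count --------
    fld = _smooth_field(rngs["land"], (R, C), sigma=6.0)
    n_land = max(1, int(round(cfg.land_fraction * grid.n_cells)))
    order = np.argsort(-fld.ravel(), kind="stable")
    land_arr = np.zeros(grid.n_cells, dtype=bool)
    land_arr[order[:n_land]] = True
    land = CellMask(grid, land_arr.reshape(R, C))

    # --- latitude (linear north-south) and tropics band -------------------
    lat_rows = np.linspace(cfg.lat_max_deg, -cfg.lat_max_deg, R)
    lat = np.tile(lat_rows[:, None], (1, C))
    latitude = RasterLayer(grid, lat, kind="continuous")
    tropics = CellMask(grid, (np.abs(lat) <= 24.0) & land.included)

    # --- population: Gaussian clusters on a 5x finer grid ------------------
    f = cfg.fine_factor
    fine_grid = Grid(R * f, C * f, cfg.cell_size_km / f)
    rng = rngs["population"]
    centers = _sample_land_cells(rng, land.included, cfg.n_population_clusters)
    cx = grid.cell_centers()[centers]
    masses = np.exp(
        rng.normal(cfg.cluster_mass_log_mu, cfg.cluster_mass_log_sigma,
                   size=len(centers))
    )
    sig = rng.uniform(*cfg.cluster_sigma_km_range, size=len(centers))
    fx = fine_grid.x_centers()
    fy = fine_grid.y_centers()
    fxx, fyy = np.meshgrid(fx, fy)
    dens_fine = np.zeros((R * f, C * f))
    for (px, py), m, s in zip(cx, masses, sig):
        d2 = (fxx - px) ** 2 + (fyy - py) ** 2
        kern = np.exp(-d2 / (2 * s * s))
        dens_fine += m * kern / kern.sum()
    land_fine = np.kron(land.included, np.ones((f, f), dtype=bool))
    # diffuse rural background so remote cells are inhabited, as in real
    # census-disaggregated population surfaces
    dens_fine += cfg.rural_background_density_per_km2 * fine_grid.cell_area_km2
    dens_fine *= land_fine
    pop_fine = RasterLayer(fine_grid, dens_fine, kind="count")
    pop0 = regrid(pop_fine, f, "sum")
    pop0 = RasterLayer(grid, np.nan_to_num(pop0.values), kind="count")

    # --- HDI: latent = rho * z(log density) + sqrt(1-rho^2) * noise --------
    rng = rngs["hdi"]
    logd = np.log1p(pop0.values)
    zl = np.zeros((R, C))
    li = land.included
    zl[li] = (logd[li] - logd[li].mean()) / (logd[li].std() + 1e-12)
    noise = _smooth_field(rng, (R, C), sigma=3.0)
    noise[li] = (noise[li] - noise[li].mean()) / (noise[li].std() + 1e-12)
    rho = cfg.hdi_density_rho
    latent = rho * zl + np.sqrt(max(0.0, 1 - rho * rho)) * noise
    hdi_arr = expit(0.5 * latent + 0.45)
    hdi_arr = np.where(li, hdi_arr, np.nan)
    hdi = RasterLayer(grid, hdi_arr, kind="continuous")

    # --- HMI: saturating in smoothed population density + light noise -----
    # The decay scale is calibrated per world so that minimally modified
    # cells (HMI <= low_hmi quantile threshold 0.1) cover a realistic share
    # of land, mirroring the global prevalence of low-modification lands.
    rng = rngs["hmi"]
    sigma_cells = cfg.hmi_decay_km / cfg.cell_size_km
    d_per_km2 = pop0.values / grid.cell_area_km2
    spread = gaussian_filter(d_per_km2, sigma_cells, mode="constant")
    q = np.quantile(spread[li], cfg.hmi_low_fraction)
    tau = max(q, 1e-9) / -np.log(1.0 - cfg.iplc_low_hmi_threshold)
    hmi_arr = 1.0 - np.exp(-spread / tau)
    hmi_arr += 0.02 * _smooth_field(rng, (R, C), sigma=2.0)
    hmi_arr = np.clip(hmi_arr, 0.0, 1.0)
    hmi_arr = np.where(li, hmi_arr, np.nan)
    hmi = RasterLayer(grid, hmi_arr, kind="continuous")

    # --- vegetation intactness and NCP priority rank -----------------------
    veg = 0.75 + 0.25 * _smooth_field(rngs["vegetation"], (R, C), sigma=4.0)
    veg = np.clip(veg, 0.05, None)
    rank_arr = gaussian_filter(np.nan_to_num(1.0 - hmi_arr) * veg, 1.5)
    rank_arr += 0.05 * np.abs(_smooth_field(rngs["ncp"], (R, C), sigma=1.0))
    rank_arr = np.where(li, np.clip(rank_arr, 1e-6, None), np.nan)
    ncp_rank = RasterLayer(grid, rank_arr, kind="continuous")

    # --- wild harvesting: logistic decline in HDI, tropics only ------------
    rate = np.minimum(
        cfg.wildharvest_max_rate,
        2.0 * cfg.wildharvest_base_rate
        * expit(cfg.wildharvest_hdi_slope * (cfg.wildharvest_hdi_mid - np.nan_to_num(hdi_arr))),
    )
    wh_arr = np.where(tropics.included, pop0.values * rate, 0.0)
    wildharvest = RasterLayer(grid, wh_arr, kind="count")

    # --- farm-area partition of each land cell ------------------------------
    rng = rngs["farms"]
    farmed_frac = np.clip(0.85 * (1.0 - np.exp(-d_per_km2 / 10.0)), 0.0, 0.85)
    farmed_frac += 0.03 * np.abs(_smooth_field(rng, (R, C), sigma=2.0))
    farmed_frac = np.clip(farmed_frac, 0.0, 0.9) * li
    small_share = expit(6.0 * (0.65 - np.nan_to_num(hdi_arr, nan=0.65)))
    ca = grid.cell_area_km2
    farm_small = RasterLayer(grid, ca * farmed_frac * small_share, kind="count")
    farm_large = RasterLayer(grid, ca * farmed_frac * (1 - small_share), kind="count")
    farm_nonfarmed = RasterLayer(grid, ca * (1.0 - farmed_frac) * li, kind="count")

    # --- livestock production systems --------------------------------------
    rng = rngs["livestock"]
    score = _smooth_field(rng, (R, C), sigma=3.0) - 0.5 * np.minimum(d_per_km2 / 50.0, 1.0)
    ls = np.full((R, C), CATEGORICAL_NODATA, dtype=np.int64)
    sc = score[li]
    q70, q40 = np.quantile(sc, [0.70, 0.40])
    codes = np.where(sc >= q70, 2, np.where(sc >= q40, 1, 0))
    ls[li] = codes
    livestock = RasterLayer(grid, ls, kind="categorical", nodata=CATEGORICAL_NODATA)

    # --- continents: nearest of k random centers ----------------------------
    rng = rngs["continents"]
    ccenters = grid.cell_centers()[_sample_land_cells(rng, np.ones((R, C), bool), cfg.n_continents)]
    allc = grid.cell_centers()
    d2 = ((allc[:, None, :] - ccenters[None, :, :]) ** 2).sum(axis=2)
    cont = np.argmin(d2, axis=1).reshape(R, C).astype(np.int64)
    cont = np.where(li, cont, CATEGORICAL_NODATA)
    continents = RasterLayer(grid, cont, kind="categorical", nodata=CATEGORICAL_NODATA)

    # --- population growth to the second epoch ------------------------------
    rng = rngs["growth"]
    g = cfg.growth_base + cfg.growth_low_hdi_boost * np.maximum(
        0.0, cfg.wildharvest_hdi_mid - np.nan_to_num(hdi_arr, nan=cfg.wildharvest_hdi_mid)
    )
    g += 0.01 * _smooth_field(rng, (R, C), sigma=2.0)
    pop1 = RasterLayer(grid, pop0.values * np.clip(1.0 + g, 0.0, None) * li, kind="count")

    # --- ecoregion features --------------------------------------------------
    rng = rngs["ecoregions"]
    features: list[ConservationFeature] = []
    if cfg.n_ecoregions > 0:
        ec_centers = grid.cell_centers()[_sample_land_cells(rng, land.included, cfg.n_ecoregions)]
        d2e = ((allc[:, None, :] - ec_centers[None, :, :]) ** 2).sum(axis=2)
        eco = np.argmin(d2e, axis=1).reshape(R, C)
        for i in range(cfg.n_ecoregions):
            amt = np.where((eco == i) & li, ca, 0.0)
            if amt.sum() == 0:
                continue
            features.append(
                ConservationFeature(
                    id=f"eco_{i:03d}", kind="ecoregion",
                    amount=RasterLayer(grid, amt, kind="count"),
                )
            )

    # --- species areas of habitat -------------------------------------------
    rng = rngs["species"]
    lo, hi = cfg.aoh_km2_range
    centers_xy = grid.cell_centers()
    for s in range(cfg.n_species):
        a_target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        radius = np.sqrt(a_target / np.pi)
        ci = _sample_land_cells(rng, land.included, 1)[0]
        d = np.sqrt(((centers_xy - centers_xy[ci]) ** 2).sum(axis=1)).reshape(R, C)
        inside = (d <= radius) & li
        inside.flat[ci] = True
        amt = np.where(inside, ca, 0.0)
        features.append(
            ConservationFeature(
                id=f"sp_{s:04d}", kind="species",
                amount=RasterLayer(grid, amt, kind="count"),
            )
        )

    # --- KBAs ----------------------------------------------------------------
    rng = rngs["kbas"]
    kba_arr = np.zeros((R, C), dtype=bool)
    for ci in _sample_land_cells(rng, land.included, cfg.n_kbas):
        rad = rng.uniform(5.0, 14.0)
        d = np.sqrt(((centers_xy - centers_xy[ci]) ** 2).sum(axis=1)).reshape(R, C)
        kba_arr |= (d <= rad) & li
    kbas = CellMask(grid, kba_arr)

    # --- protected-area records (with tricky fixtures) -----------------------
    rng = rngs["pa"]
    pa_records: list[PARecord] = []
    rid = 0

    def _circle_at(ci: int, radius: float) -> shapely.Geometry:
        x, y = centers_xy[ci]
        return shapely.Point(x, y).buffer(radius, quad_segs=16)

    for _ in range(cfg.pa_count):
        ci = _sample_land_cells(rng, land.included, 1)[0]
        rad = rng.uniform(*cfg.pa_radius_km_range)
        cat = "OECM" if rng.random() < 0.2 else "PA"
        pa_records.append(
            PARecord(id=f"pa_{rid:04d}", status="designated", category=cat,
                     geometry=_circle_at(ci, rad))
        )
        rid += 1
    for _ in range(cfg.n_proposed):
        ci = _sample_land_cells(rng, land.included, 1)[0]
        pa_records.append(
            PARecord(id=f"pa_{rid:04d}", status="proposed",
                     geometry=_circle_at(ci, rng.uniform(*cfg.pa_radius_km_range)))
        )
        rid += 1
    for _ in range(cfg.n_mab):
        ci = _sample_land_cells(rng, land.included, 1)[0]
        pa_records.append(
            PARecord(id=f"pa_{rid:04d}", designation_flag="MAB_biosphere",
                     geometry=_circle_at(ci, rng.uniform(*cfg.pa_radius_km_range)))
        )
        rid += 1
    ocean = ~land.included
    for _ in range(cfg.n_marine):
        pool = ocean if ocean.any() else land.included
        ci = _sample_land_cells(rng, pool, 1)[0]
        pa_records.append(
            PARecord(id=f"pa_{rid:04d}", realm="marine",
                     geometry=_circle_at(ci, rng.uniform(*cfg.pa_radius_km_range)))
        )
        rid += 1
    for _ in range(cfg.n_point_with_area):
        ci = _sample_land_cells(rng, land.included, 1)[0]
        pa_records.append(
            PARecord(id=f"pa_{rid:04d}", geometry_kind="point",
                     geometry=shapely.Point(*centers_xy[ci]),
                     reported_area_km2=float(rng.uniform(60, 400)))
        )
        rid += 1
    for _ in range(cfg.n_point_no_area):
        ci = _sample_land_cells(rng, land.included, 1)[0]
        pa_records.append(
            PARecord(id=f"pa_{rid:04d}", geometry_kind="point",
                     geometry=shapely.Point(*centers_xy[ci]))
        )
        rid += 1

    # --- IPLC lands: blobs biased toward low-HMI cells ------------------------
    rng = rngs["iplc"]
    low_hmi = np.nan_to_num(hmi_arr, nan=1.0) <= cfg.iplc_low_hmi_threshold
    pool = land.included & low_hmi
    if pool.sum() < cfg.iplc_count:
        # fall back to the lowest-modification land cells
        hv = np.where(li, np.nan_to_num(hmi_arr, nan=1.0), np.inf).ravel()
        pool = np.zeros(grid.n_cells, dtype=bool)
        pool[np.argsort(hv, kind="stable")[: max(cfg.iplc_count * 4, 40)]] = True
        pool = pool.reshape(R, C) & li
    iplc_lands: list[tuple[shapely.Geometry, str]] = []
    # IPLC lands concentrate in the tropics (as the mapped territories do):
    # tropical low-modification cells get a higher sampling weight.
    iplc_w = np.where(tropics.included, cfg.iplc_tropics_weight, 1.0)
    for ci in _sample_land_cells(rng, pool, cfg.iplc_count, weights=iplc_w):
        rad = rng.uniform(*cfg.iplc_radius_km_range)
        flag = (
            "other_special_rights"
            if rng.random() < cfg.iplc_special_rights_fraction
            else "none"
        )
        iplc_lands.append((_circle_at(ci, rad), flag))

    # --- ICCA records ----------------------------------------------------------
    rng = rngs["icca"]
    icca_records: list[PARecord] = []
    for k in range(cfg.icca_count):
        ci = _sample_land_cells(rng, pool, 1)[0]
        if rng.random() < cfg.icca_point_fraction:
            icca_records.append(
                PARecord(id=f"icca_{k:03d}", geometry_kind="point",
                         geometry=shapely.Point(*centers_xy[ci]),
                         reported_area_km2=float(rng.uniform(100, 900)))
            )
        else:
            icca_records.append(
                PARecord(id=f"icca_{k:03d}",
                         geometry=_circle_at(ci, rng.uniform(6.0, 16.0)))
            )

    layers = SocialLayers(
        population_t0=pop0,
        population_t1=pop1,
        hdi=hdi,
        wildharvest_pop=wildharvest,
        farm_nonfarmed=farm_nonfarmed,
        farm_small=farm_small,
        farm_large=farm_large,
        livestock_system=livestock,
        tropics=tropics,
        continents=continents,
        land=land,
        livestock_only_code=2,
    )
    realized_rho = float(np.corrcoef(hdi_arr[li], logd[li])[0, 1]) if li.sum() > 2 else float("nan")
    truth = {
        "config": dataclasses.asdict(cfg),
        "cluster_centers": cx.tolist(),
        "cluster_masses": masses.tolist(),
        "realized_hdi_logdensity_corr": realized_rho,
        "total_population_t0": float(pop0.values.sum()),
        "clip_warnings": [],
    }
    return SyntheticWorld(
        grid=grid, land=land, layers=layers, hmi=hmi, ncp_rank=ncp_rank,
        latitude=latitude, features=features, pa_records=pa_records,
        iplc_lands=iplc_lands, icca_records=icca_records, kbas=kbas,
        population_fine=pop_fine, truth=truth,
    )


def random_prioritization_instance(
    seed: int,
    max_rows: int = 4,
    max_cols: int = 5,
    max_features: int = 4,
    max_budget: int = 3,
) -> tuple[Grid, list[ConservationFeature], int]:
    """Small random minimum-shortfall instance with planning-unit structure.

    Features have presence/absence amounts (one full cell area per occupied
    cell, as an area-of-habitat or ecoregion raster does) and a fractional
    representation target of their total extent.  Suitable for exhaustive
    enumeration (grid capped at 20 cells).
    """
    rng = np.random.default_rng(seed)
    grid = Grid(int(rng.integers(3, max_rows + 1)),
                int(rng.integers(3, max_cols + 1)), 5.0)
    ca = grid.cell_area_km2
    feats = []
    for i in range(int(rng.integers(2, max_features + 1))):
        pres = rng.random(grid.shape) < rng.uniform(0.2, 0.7)
        if not pres.any():
            pres.flat[int(rng.integers(grid.n_cells))] = True
        target = rng.uniform(0.2, 0.9) * pres.sum() * ca
        feats.append(ConservationFeature(
            id=f"f{i}", kind="species",
            amount=RasterLayer(grid, pres * ca, kind="count"),
            target_amount=float(target)))
    budget = int(rng.integers(1, max_budget + 1))
    return grid, feats, budget


def plant_contrast(
    world: SyntheticWorld,
    iplc_hdi_offset: float = 0.0,
    iplc_wildharvest_multiplier: float = 1.0,
) -> SyntheticWorld:
    """Return a copy of the world with a known contrast planted inside the
    IPLC footprint: HDI shifted by ``iplc_hdi_offset`` and wild-harvest
    population scaled by ``iplc_wildharvest_multiplier`` (capped at the
    resident population).  Values clipped to stay in range are recorded in
    ``truth['clip_warnings']``.
    """
    from .grid import rasterize_coverage, threshold_mask  # local to avoid cycle

    if iplc_hdi_offset == 0.0 and iplc_wildharvest_multiplier == 1.0:
        return world

    geoms = [(f"iplc_{i}", g) for i, (g, flag) in enumerate(world.iplc_lands)
             if flag != "other_special_rights"]
    fp = threshold_mask(rasterize_coverage(geoms, world.grid), 0.5) & world.land
    inside = fp.included

    hdi_new = world.layers.hdi.values.copy()
    shifted = hdi_new[inside] + iplc_hdi_offset
    clip_warnings = list(world.truth.get("clip_warnings", []))
    if np.any(shifted < 0) or np.any(shifted > 1):
        clip_warnings.append(
            f"hdi offset {iplc_hdi_offset} clipped on "
            f"{int(np.sum((shifted < 0) | (shifted > 1)))} cells"
        )
    hdi_new[inside] = np.clip(shifted, 0.0, 1.0)

    pop = world.layers.population_t0.values
    wh_new = world.layers.wildharvest_pop.values.copy()
    wh_new[inside] = np.minimum(
        pop[inside], wh_new[inside] * iplc_wildharvest_multiplier
    )

    layers = dataclasses.replace(
        world.layers,
        hdi=RasterLayer(world.grid, hdi_new, kind="continuous"),
        wildharvest_pop=RasterLayer(world.grid, wh_new, kind="count"),
    )
    truth = dict(world.truth)
    truth["planted_contrast"] = {
        "iplc_hdi_offset": iplc_hdi_offset,
        "iplc_wildharvest_multiplier": iplc_wildharvest_multiplier,
        "n_footprint_cells": int(inside.sum()),
    }
    truth["clip_warnings"] = clip_warnings
    return dataclasses.replace(world, layers=layers, truth=truth)
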