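"""Synthetic landscapes, species pools, captures and chronosequences.

This module generates data with the statistical structure the analysis
assumes, so every downstream stage — effort standardization,
forest-dependency classification, ordination, multimodel inference and
landscape projection — can be exercised end to end without field data.

It emulates the design of the original survey: 19 forest patches
spanning four orders of magnitude of area (1.4-14,480.5 ha) plus three
continuous-forest reference sites, each patch paired with a matrix
stratum; a pool of ~20 species split into three habitat-preference
archetypes (forest-dependent, matrix-tolerant, open-habitat); Poisson
capture counts proportional to trapping effort; and a monotone
deforestation chronosequence of binary grids.

Capture rates are multiplicative in the site covariates:

    rate_forest = base_rate_forest
                  * exp(area_slope * (log10 A - log10 A_ref))
                  * exp(prox_slope * (log10 P - log10 P_ref))
                  * exp(mc_slope * (MC - MC_ref))

with the continuous-forest surrogates as the reference point, so a
forest-dependent archetype (positive area slope) thins out toward small
patches while an open-habitat archetype (negative slope) thrives there.
Forest-dependent species have a structurally zero matrix rate.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import study
from .effort import FOREST, LIVE, MATRIX, PITFALL, TrapDesign
from .forest_dependency import FOREST_DEPENDENT, MATRIX_TOLERANT, OPEN_HABITAT
from .landscape_projection import ForestGrid

__all__ = [
    "ArchetypeSpec",
    "SimulationConfig",
    "DEFAULT_ARCHETYPES",
    "generate_landscape",
    "generate_species_pool",
    "simulate_captures",
    "generate_chronosequence",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Rate parameters of one habitat-preference archetype.

    Rates are expected live-trap captures per 1000 trap-nights at the
    continuous-forest reference covariates; slopes act multiplicatively
    (see module docstring).
    """

    archetype: str
    base_rate_forest: float
    base_rate_matrix: float
    area_slope: float = 0.0
    prox_slope: float = 0.0
    matrix_complexity_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.base_rate_forest < 0 or self.base_rate_matrix < 0:
            raise ValueError("rates must be non-negative")
        if self.archetype == FOREST_DEPENDENT and self.base_rate_matrix != 0:
            raise ValueError("forest_dependent archetype must have zero matrix rate")
        if self.archetype == OPEN_HABITAT and not (
            self.base_rate_matrix > self.base_rate_forest
        ):
            raise ValueError("open_habitat archetype must be commoner in the matrix")
        if self.archetype not in (FOREST_DEPENDENT, MATRIX_TOLERANT, OPEN_HABITAT):
            raise ValueError(f"unknown archetype {self.archetype!r}")


#: Default archetypes. Base rates put matrix-tolerant species at roughly a
#: dozen expected matrix captures under the default design (so the
#: threshold-defining matrix records are reliably observed), and keep the
#: open-habitat matrix rate well above its forest rate.
DEFAULT_ARCHETYPES = (
    ArchetypeSpec(FOREST_DEPENDENT, base_rate_forest=20.0, base_rate_matrix=0.0,
                  area_slope=0.15, prox_slope=0.05),
    ArchetypeSpec(MATRIX_TOLERANT, base_rate_forest=15.0, base_rate_matrix=6.0,
                  area_slope=0.0, prox_slope=0.0, matrix_complexity_slope=-0.03),
    ArchetypeSpec(OPEN_HABITAT, base_rate_forest=4.0, base_rate_matrix=20.0,
                  area_slope=-0.15, prox_slope=0.0, matrix_complexity_slope=-0.05),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a simulated survey."""

    n_patches: int = study.N_PATCHES
    n_continuous: int = study.N_CONTINUOUS
    area_range_ha: tuple = study.AREA_RANGE_HA
    n_species_per_archetype: tuple = study.ARCHETYPE_COUNTS
    area_prox_correlation: float = 0.8
    overdispersion: Optional[float] = None
    design: TrapDesign = field(default_factory=TrapDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.area_range_ha
        if not (0 < lo < hi):
            raise ValueError("area range must be positive with span > 0")
        if self.n_patches < 2:
            raise ValueError("need at least 2 patches")
        if not (0 <= self.area_prox_correlation <= 1):
            raise ValueError("correlation must be in [0, 1]")


# covariate reference values (continuous-forest surrogates, Table-style)
_LOG10_AREA_REF = np.log10(study.CF_AREA_HA)
_LOG10_PROX_REF = np.log10(study.CF_PROX)
_MC_REF = float(study.CF_MATRIX_COMPLEXITY)


def generate_landscape(config: SimulationConfig) -> pd.DataFrame:
    """Site table: patches with covariates, plus continuous-forest sites.

    Patch areas are log-uniform over the configured range. The
    proximity index shares a latent factor with log-area (target
    correlation ``area_prox_correlation``, mirroring the strong observed
    area-isolation collinearity). Remaining covariates are drawn within
    the observed field ranges. Continuous-forest sites carry the
    surrogate metrics (full cover, saturated proximity, circular shape).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.area_range_ha
    n = config.n_patches
    log_area = rng.uniform(np.log10(lo), np.log10(hi), size=n)
    z = (log_area - log_area.mean()) / (log_area.std() or 1.0)
    rho = config.area_prox_correlation
    latent = rho * z + np.sqrt(max(1.0 - rho ** 2, 0.0)) * rng.standard_normal(n)
    log_prox = np.clip(3.3 + 1.6 * latent, np.log10(0.8), np.log10(5.1e6))
    cover = np.clip(41.0 + 25.0 * (0.5 * z + 0.87 * rng.standard_normal(n)),
                    5.8, 99.9)
    mc_probs = 0.55 ** np.arange(1, 11)
    mc = rng.choice(np.arange(1, 11), size=n, p=mc_probs / mc_probs.sum())
    shape = np.clip(rng.lognormal(1.5, 0.6, size=n), 1.69, 18.88)
    veg = rng.choice([1, 2, 3], size=n, p=[0.40, 0.35, 0.25])
    burn = rng.choice([0, 1, 2, 3, 4], size=n, p=[0.10, 0.20, 0.30, 0.25, 0.15])
    cattle = rng.binomial(1, 0.42, size=n)
    age = rng.integers(1, 26, size=n)
    logging = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.20, 0.30, 0.25, 0.15, 0.10])

    patches = pd.DataFrame({
        "site_id": [f"P{i + 1:02d}" for i in range(n)],
        "site_type": "patch",
        "area_ha": 10.0 ** log_area,
        "cover": cover,
        "prox": 10.0 ** log_prox,
        "matrix_complexity": mc,
        "shape": shape,
        "veg": veg,
        "burn": burn,
        "cattle": cattle,
        "age": age,
        "logging": logging,
    })
    cf_age = [1] + [0] * max(config.n_continuous - 1, 0)
    cf = pd.DataFrame({
        "site_id": [f"CF{i + 1}" for i in range(config.n_continuous)],
        "site_type": "continuous",
        "area_ha": study.CF_AREA_HA,
        "cover": study.CF_COVER,
        "prox": study.CF_PROX,
        "matrix_complexity": study.CF_MATRIX_COMPLEXITY,
        "shape": study.CF_SHAPE,
        "veg": 3,
        "burn": 0,
        "cattle": 0,
        "age": cf_age[: config.n_continuous],
        "logging": 1,
    })
    return pd.concat([patches, cf], ignore_index=True)


_PREFIX = {FOREST_DEPENDENT: "FD", MATRIX_TOLERANT: "MT", OPEN_HABITAT: "OH"}
_DIETS = ("insectivore", "frugivore", "granivore", "omnivore")
_LOCOMOTION = ("terrestrial", "scansorial", "arboreal")
_RANGES = ("amazonia", "amazonia_cerrado", "widespread")


def generate_species_pool(
    config: SimulationConfig,
    archetypes: Sequence[ArchetypeSpec] = DEFAULT_ARCHETYPES,
) -> pd.DataFrame:
    """Species pool with traits and per-species rate parameters.

    One row per species; archetype base rates are jittered by a modest
    multiplicative factor (clipped lognormal) so species within an
    archetype differ, without crossing archetype invariants. Species
    ids are stable under the seed.
    """
    if len(archetypes) == 0:
        raise ValueError("need at least one archetype")
    counts = config.n_species_per_archetype
    if len(counts) != len(archetypes):
        raise ValueError("n_species_per_archetype must match the archetype list")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for spec, k in zip(archetypes, counts):
        for i in range(k):
            jitter_f = float(np.clip(rng.lognormal(0.0, 0.2), 0.7, 1.4))
            jitter_m = float(np.clip(rng.lognormal(0.0, 0.2), 0.7, 1.4))
            taxon = rng.choice(["rodent", "marsupial"])
            rows.append({
                "species_id": f"{_PREFIX[spec.archetype]}{i + 1:02d}",
                "archetype": spec.archetype,
                "taxon": taxon,
                "body_mass_g": float(np.round(rng.lognormal(4.0, 0.8), 1)),
                "diet": rng.choice(_DIETS),
                "locomotion": rng.choice(_LOCOMOTION),
                "geo_range": rng.choice(_RANGES),
                "base_rate_forest": spec.base_rate_forest * jitter_f,
                "base_rate_matrix": spec.base_rate_matrix * jitter_m,
                "area_slope": spec.area_slope,
                "prox_slope": spec.prox_slope,
                "matrix_complexity_slope": spec.matrix_complexity_slope,
                "live_affinity": 1.0,
                "pitfall_affinity": 0.6,
            })
    return pd.DataFrame(rows)


def _expected_rates(sites: pd.DataFrame, pool: pd.DataFrame) -> pd.DataFrame:
    """Expected captures per 1000 TN for every (site, stratum, species)."""
    grid = sites.merge(pool, how="cross")
    mult = np.exp(
        grid["area_slope"] * (np.log10(grid["area_ha"]) - _LOG10_AREA_REF)
        + grid["prox_slope"] * (np.log10(grid["prox"]) - _LOG10_PROX_REF)
        + grid["matrix_complexity_slope"] * (grid["matrix_complexity"] - _MC_REF)
    )
    forest = grid[["site_id", "species_id", "live_affinity", "pitfall_affinity"]].copy()
    forest["stratum"] = FOREST
    forest["rate"] = grid["base_rate_forest"] * mult
    mat = grid.loc[grid["site_type"] == "patch",
                   ["site_id", "species_id", "live_affinity", "pitfall_affinity"]].copy()
    mat["stratum"] = MATRIX
    mc_mult = np.exp(grid["matrix_complexity_slope"]
                     * (grid["matrix_complexity"] - _MC_REF))
    mat["rate"] = (grid["base_rate_matrix"] * mc_mult)[grid["site_type"] == "patch"]
    return pd.concat([forest, mat], ignore_index=True)


def simulate_captures(
    sites: pd.DataFrame,
    pool: pd.DataFrame,
    effort: pd.DataFrame,
    seed: int,
    overdispersion: Optional[float] = None,
) -> pd.DataFrame:
    """Draw capture counts for every (site, stratum, species, trap class).

    count ~ Poisson(rate * trap_nights / 1000 * class affinity); with
    ``overdispersion`` phi > 0, a gamma-Poisson mixture (negative
    binomial with variance mean + phi * mean^2) replaces the Poisson.
    Raises when a site lacks effort records for a stratum it possesses.
    """
    required = []
    for _, s in sites.iterrows():
        required.append((s["site_id"], FOREST))
        if s["site_type"] == "patch":
            required.append((s["site_id"], MATRIX))
    have = set(zip(effort["site_id"], effort["stratum"]))
    missing = [r for r in required if r not in have]
    if missing:
        raise ValueError(f"missing effort records for {missing}")

    rates = _expected_rates(sites, pool)
    if (rates["rate"] < 0).any():
        raise ValueError("negative expected rates")
    merged = effort.merge(rates, on=["site_id", "stratum"], how="inner")
    affinity = np.where(merged["trap_class"] == LIVE,
                        merged["live_affinity"], merged["pitfall_affinity"])
    mean = merged["rate"].to_numpy() * merged["trap_nights"].to_numpy() / 1000.0 * affinity
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    if overdispersion:
        shape = 1.0 / overdispersion
        lam = np.where(mean > 0,
                       rng.gamma(shape, np.maximum(mean, 1e-300) * overdispersion),
                       0.0)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mean)
    out = merged[["site_id", "stratum", "species_id", "trap_class"]].copy()
    out["count"] = counts
    return out.sort_values(["site_id", "stratum", "trap_class", "species_id"],
                           ignore_index=True)


def _clearing_order(shape: tuple, rng: np.random.Generator,
                    n_seeds: int = 25, mode: str = "region_growing") -> np.ndarray:
    """Permutation of flat pixel indices in the order they get cleared."""
    nrow, ncol = shape
    npix = nrow * ncol
    if mode == "random":
        return rng.permutation(npix)
    if mode != "region_growing":
        raise ValueError(f"unknown clearing mode {mode!r}")
    # randomized multi-source growth (Eden-like): contiguous clearings that
    # fragment the remaining forest into many small patches
    order = np.empty(npix, dtype=np.int64)
    visited = np.zeros(npix, dtype=bool)
    heap = [(rng.random(), int(s)) for s in
            rng.choice(npix, size=min(n_seeds, npix), replace=False)]
    heapq.heapify(heap)
    pos = 0
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
    while heap:
        _, idx = heapq.heappop(heap)
        if visited[idx]:
            continue
        visited[idx] = True
        order[pos] = idx
        pos += 1
        r, c = divmod(idx, ncol)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol:
                nb = rr * ncol + cc
                if not visited[nb]:
                    heapq.heappush(heap, (rng.random(), nb))
    return order[:pos]


def generate_chronosequence(
    grid_shape: tuple,
    pixel_area_ha: float,
    clearing_fractions: Sequence[float],
    seed: int,
    years: Optional[Sequence] = None,
    n_seeds: int = 25,
    mode: str = "region_growing",
) -> list[ForestGrid]:
    """Monotone deforestation series of binary forest grids.

    A single seeded clearing order (spatially autocorrelated
    region-growing by default) is shared across years, so each year's
    cleared pixels are a superset of the previous year's; the fraction
    cleared per year follows ``clearing_fractions`` (non-decreasing,
    each in [0, 1]).
    """
    fracs = list(clearing_fractions)
    if any(not (0 <= f <= 1) for f in fracs):
        raise ValueError("clearing fractions must lie in [0, 1]")
    if any(b < a for a, b in zip(fracs, fracs[1:])):
        raise ValueError("clearing fractions must be non-decreasing (monotone loss)")
    if years is None:
        years = list(range(len(fracs)))
    if len(years) != len(fracs):
        raise ValueError("years and clearing_fractions must align")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    order = _clearing_order(tuple(grid_shape), rng, n_seeds=n_seeds, mode=mode)
    npix = grid_shape[0] * grid_shape[1]
    grids = []
    for year, f in zip(years, fracs):
        n_clear = int(round(f * npix))
        data = np.ones(npix, dtype=np.int8)
        data[order[:n_clear]] = 0
        grids.append(ForestGrid(data=data.reshape(grid_shape),
                                pixel_area_ha=pixel_area_ha, year=year))
    return grids
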