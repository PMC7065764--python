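"""Species forest-dependency index and community-weighted average.

The forest-dependency index (FD) of a species is the log10 ratio of its
effort-standardized capture rate inside forest to its rate in the
adjacent open-habitat matrix, with a small pseudo-count so species never
captured in the matrix still receive a finite value:

    FD = log10((r_forest + c) / (r_matrix + c)),   c = 0.01 by default.

FD < 0 marks open-habitat species (commoner in the matrix); species
with 0 <= FD <= tau are matrix-tolerant, where tau is the largest FD
among species recorded at least once in the matrix; FD > tau marks
strictly forest-dependent species. The community-averaged FD of a site
is the abundance-weighted mean of species FD values — a
community-weighted mean trait.

FD is computed from live-trap data only (the matrix carries no pitfall
arrays, so only live-trap rates are comparable across strata); the
community average weights by all standardized abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .effort import FOREST, LIVE, MATRIX, CommunityMatrix, standardize_abundance

__all__ = [
    "FDConfig",
    "SpeciesProfile",
    "species_fd",
    "species_fd_se",
    "fd_threshold",
    "classify_species",
    "impute_fd",
    "community_fd",
    "build_species_profiles",
]

OPEN_HABITAT = "open_habitat"
MATRIX_TOLERANT = "matrix_tolerant"
FOREST_DEPENDENT = "forest_dependent"
CLASSES = (FOREST_DEPENDENT, MATRIX_TOLERANT, OPEN_HABITAT)


@dataclass(frozen=True)
class FDConfig:
    """Knobs of the FD computation.

    pseudo_count
        Rate offset ``c`` guarding against zero rates; 0.01 by
        convention.
    rate_unit
        Trap-night denominator of the standardized rates. The FD ratio
        itself is unit-free only in the limit c -> 0; the unit used is
        recorded so results are comparable.
    formula_variant
        ``ratio_offset_both`` (default): c added to both rates inside
        the ratio. ``ratio_then_offset``: log10(r_F / r_M + c), a
        literal alternative reading; undefined when r_M = 0.
    threshold_override
        Fixed classification threshold to use instead of the
        data-derived maximum over matrix-recorded species.
    """

    pseudo_count: float = 0.01
    rate_unit: float = 1000.0
    formula_variant: str = "ratio_offset_both"
    threshold_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be > 0")
        if self.formula_variant not in ("ratio_offset_both", "ratio_then_offset"):
            raise ValueError(f"unknown formula_variant {self.formula_variant!r}")


@dataclass
class SpeciesProfile:
    """Per-species forest-dependency value, uncertainty and class."""

    species_id: str
    fd_value: float = math.nan
    fd_se: float = math.nan
    fd_class: Optional[str] = None
    imputed: bool = False
    donor_species: Optional[str] = None
    taxon: Optional[str] = None
    body_mass_g: Optional[float] = None
    diet: Optional[str] = None
    locomotion: Optional[str] = None
    geo_range: Optional[str] = None

    def __post_init__(self) -> None:
        if self.imputed and not self.donor_species:
            raise ValueError("imputed profile requires donor_species")


def species_fd(rate_forest: float, rate_matrix: float, config: FDConfig = FDConfig()) -> float:
    """Forest-dependency index from pooled live-trap capture rates."""
    if rate_forest < 0 or rate_matrix < 0:
        raise ValueError("capture rates must be non-negative")
    c = config.pseudo_count
    if config.formula_variant == "ratio_offset_both":
        return math.log10((rate_forest + c) / (rate_matrix + c))
    if rate_matrix == 0:
        raise ValueError("ratio_then_offset variant undefined for zero matrix rate")
    return math.log10(rate_forest / rate_matrix + c)


def species_fd_se(
    rates_forest_by_site: Sequence[float],
    rates_matrix_by_site: Sequence[float],
    config: FDConfig = FDConfig(),
    method: str = "delta",
) -> float:
    """Uncertainty of FD from the across-site spread of capture rates.

    ``delta`` (default) propagates the per-stratum standard deviations
    through the log-ratio:

        se = (1/ln 10) * sqrt(sd_F^2/(rbar_F+c)^2 + sd_M^2/(rbar_M+c)^2)

    ``plugin`` evaluates FD at mean +/- SD in each stratum and returns
    half the widest spread.
    """
    rf = np.asarray(rates_forest_by_site, dtype=float)
    rm = np.asarray(rates_matrix_by_site, dtype=float)
    if rf.size == 0 or rm.size == 0:
        raise ValueError("need at least one site per stratum")
    c = config.pseudo_count
    mf, mm = rf.mean(), rm.mean()
    sf = rf.std(ddof=1) if rf.size > 1 else 0.0
    sm = rm.std(ddof=1) if rm.size > 1 else 0.0
    if method == "delta":
        return math.sqrt((sf / (mf + c)) ** 2 + (sm / (mm + c)) ** 2) / math.log(10)
    if method == "plugin":
        corners = [
            species_fd(max(mf + df, 0.0), max(mm + dm, 0.0), config)
            for df in (-sf, sf) for dm in (-sm, sm)
        ]
        return (max(corners) - min(corners)) / 2.0
    raise ValueError(f"unknown method {method!r}")


def fd_threshold(
    fd_values: Mapping[str, float],
    matrix_recorded: Iterable[str],
    config: FDConfig = FDConfig(),
) -> float:
    """Classification threshold tau: max FD over matrix-recorded species."""
    recorded = [s for s in matrix_recorded if s in fd_values]
    if not recorded:
        if config.threshold_override is not None:
            return config.threshold_override
        raise ValueError("no matrix-recorded species and no threshold_override")
    return max(fd_values[s] for s in recorded)


def classify_species(fd_value: float, tau: float) -> str:
    """Partition the FD axis: (<0) open, [0, tau] matrix-tolerant, (>tau) forest-dependent.

    The boundary FD = tau falls to matrix-tolerant because the threshold
    species is by construction itself matrix-recorded.
    """
    if not math.isfinite(fd_value):
        raise ValueError("FD value must be finite")
    if not math.isfinite(tau):
        raise ValueError("threshold must be finite")
    if fd_value < 0:
        return OPEN_HABITAT
    if fd_value <= tau:
        return MATRIX_TOLERANT
    return FOREST_DEPENDENT


def impute_fd(
    species_id: str,
    donor_map: Mapping[str, str],
    profiles: Mapping[str, SpeciesProfile],
    tau: float,
) -> SpeciesProfile:
    """Borrow the FD of an ecologically similar donor species.

    Used for species detected only by pitfall traps, which have no
    live-trap rates to form the ratio. Chained imputation (a donor that
    is itself imputed) is refused.
    """
    if species_id not in donor_map:
        raise KeyError(f"no donor declared for species {species_id!r}")
    donor = donor_map[species_id]
    if donor not in profiles:
        raise KeyError(f"donor species {donor!r} not found")
    donor_profile = profiles[donor]
    if donor_profile.imputed:
        raise ValueError(f"donor {donor!r} is itself imputed; chained imputation refused")
    if not math.isfinite(donor_profile.fd_value):
        raise ValueError(f"donor {donor!r} has no FD value")
    base = profiles.get(species_id, SpeciesProfile(species_id=species_id))
    return replace(
        base,
        fd_value=donor_profile.fd_value,
        fd_se=donor_profile.fd_se,
        fd_class=classify_species(donor_profile.fd_value, tau),
        imputed=True,
        donor_species=donor,
    )


def community_fd(
    matrix: CommunityMatrix,
    profiles: Mapping[str, SpeciesProfile],
) -> pd.DataFrame:
    """Abundance-weighted mean FD per site (community-weighted trait mean).

    ``matrix`` holds forest-stratum standardized abundances. Every
    species present (abundance > 0) at any site must carry a measured or
    imputed FD. Sites with zero total abundance are returned with
    ``cfd`` NaN and ``defined`` False.
    """
    data = matrix.data
    present = data.columns[(data > 0).any(axis=0)]
    missing = [s for s in present
               if s not in profiles or not math.isfinite(profiles[s].fd_value)]
    if missing:
        raise ValueError(f"species without FD value: {missing}")
    fd = np.array([profiles[s].fd_value if s in profiles else np.nan
                   for s in data.columns])
    weights = data.to_numpy(dtype=float)
    totals = np.nansum(weights, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cfd = np.where(totals > 0,
                       (weights * np.nan_to_num(fd)).sum(axis=1) / np.where(totals > 0, totals, 1),
                       np.nan)
    return pd.DataFrame({
        "site_id": data.index,
        "cfd": cfd,
        "n_individuals_weighted": totals,
        "defined": totals > 0,
    }).set_index("site_id")


def build_species_profiles(
    captures: pd.DataFrame,
    effort: pd.DataFrame,
    config: FDConfig = FDConfig(),
    donor_map: Optional[Mapping[str, str]] = None,
    traits: Optional[pd.DataFrame] = None,
) -> tuple[dict[str, SpeciesProfile], float]:
    """Full FD pipeline from raw captures: rates -> FD -> tau -> classes.

    Live-trap data only. Species with zero live-trap records in both
    strata get FD from ``donor_map`` when declared, else are left
    without an FD value. Returns (profiles by species, tau).
    """
    forest = standardize_abundance(captures, effort, per=config.rate_unit,
                                   stratum=FOREST, trap_classes=[LIVE])
    matrix = standardize_abundance(captures, effort, per=config.rate_unit,
                                   stratum=MATRIX, trap_classes=[LIVE])
    all_species = sorted(
        set(captures.loc[captures["count"] > 0, "species_id"])
        | set(forest.species_ids) | set(matrix.species_ids)
    )
    f_rates = forest.data.reindex(columns=all_species, fill_value=0.0)
    m_rates = matrix.data.reindex(columns=all_species, fill_value=0.0)

    live = captures[(captures["trap_class"] == LIVE) & (captures["count"] > 0)]
    live_recorded = set(live["species_id"])
    matrix_recorded = set(live.loc[live["stratum"] == MATRIX, "species_id"])

    fd_values: dict[str, float] = {}
    fd_ses: dict[str, float] = {}
    for s in all_species:
        if s not in live_recorded:
            continue  # pitfall-only: needs imputation
        fd_values[s] = species_fd(f_rates[s].mean(), m_rates[s].mean(), config)
        fd_ses[s] = species_fd_se(f_rates[s].to_numpy(), m_rates[s].to_numpy(), config)

    if config.threshold_override is not None:
        tau = config.threshold_override
    else:
        tau = fd_threshold(fd_values, matrix_recorded, config)

    profiles: dict[str, SpeciesProfile] = {}
    for s in all_species:
        prof = SpeciesProfile(species_id=s)
        if traits is not None and s in traits.index:
            row = traits.loc[s]
            for f in ("taxon", "body_mass_g", "diet", "locomotion", "geo_range"):
                if f in row:
                    setattr(prof, f, row[f])
        if s in fd_values:
            prof.fd_value = fd_values[s]
            prof.fd_se = fd_ses[s]
            prof.fd_class = classify_species(fd_values[s], tau)
        profiles[s] = prof
    if donor_map:
        for s in donor_map:
            if s in profiles and not math.isfinite(profiles[s].fd_value):
                profiles[s] = impute_fd(s, donor_map, profiles, tau)
    return profiles, tau
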