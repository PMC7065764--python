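"""Trapping effort and effort standardization.

Sampling effort in live-trapping studies is measured in trap-nights (one
trap open for one night). Because survey designs allocate more traps to
larger sites, raw capture counts are not comparable across sites; this
module derives per-site effort from the survey design, converts counts
to capture rates per fixed effort unit, and checks sampling adequacy
with the abundance-based sample-coverage estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrapDesign",
    "CommunityMatrix",
    "design_effort",
    "design_effort_table",
    "standardize_abundance",
    "sample_coverage",
]

FOREST = "forest"
MATRIX = "matrix"
LIVE = "live"
PITFALL = "pitfall"


@dataclass(frozen=True)
class TrapDesign:
    """Trap allocation rules of the survey design.

    Small patches (area below ``small_patch_threshold_ha``) receive a
    reduced design; larger patches and continuous forest receive the
    full design. Each live-trap transect holds ``stations_per_transect``
    stations with ``live_traps_per_station`` traps (one Sherman and one
    wire-mesh per station in the original design). The matrix stratum
    receives live-trap transects only — no pitfall arrays.
    """

    live_transects_small: int = 1
    live_transects_large: int = 3
    stations_per_transect: int = 5
    live_traps_per_station: int = 2
    pitfall_arrays_small: int = 2
    pitfall_arrays_large: int = 4
    pitfalls_per_array: int = 4
    matrix_transects: int = 1
    nights: int = 10
    small_patch_threshold_ha: float = 2.0

    def __post_init__(self) -> None:
        counts = (
            self.live_transects_small, self.live_transects_large,
            self.stations_per_transect, self.live_traps_per_station,
            self.pitfall_arrays_small, self.pitfall_arrays_large,
            self.pitfalls_per_array, self.matrix_transects,
        )
        if any(c < 0 for c in counts):
            raise ValueError("trap counts must be non-negative")
        if self.nights < 1:
            raise ValueError("nights must be >= 1")


@dataclass
class CommunityMatrix:
    """Sites x species effort-standardized abundances.

    ``data`` holds capture rates (captures per ``per`` trap-nights,
    conventionally 1000) with site ids as the index and species ids as
    columns. ``stratum`` records which stratum the rates describe.
    """

    data: pd.DataFrame
    stratum: str = FOREST
    per: float = 1000.0

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("community matrix contains non-finite values")
        if (vals < 0).any():
            raise ValueError("community matrix contains negative values")

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)


def design_effort(site, design: TrapDesign = TrapDesign()) -> pd.DataFrame:
    """Effort records implied by the survey design for one site.

    ``site`` is a mapping (or Series) with ``site_id``, ``site_type``
    ('patch' or 'continuous') and, for patches, ``area_ha``. Returns a
    table with columns (site_id, stratum, trap_class, trap_nights).
    Patches get a forest stratum plus an adjacent matrix stratum (live
    traps only); continuous-forest sites get a forest stratum only.
    """
    site_id = site["site_id"]
    site_type = site.get("site_type", "patch")
    rows = []
    if site_type == "continuous":
        small = False
    else:
        area = site.get("area_ha")
        if area is None or (isinstance(area, float) and np.isnan(area)):
            raise ValueError(f"patch site {site_id!r} has no area")
        small = float(area) < design.small_patch_threshold_ha

    live_transects = design.live_transects_small if small else design.live_transects_large
    arrays = design.pitfall_arrays_small if small else design.pitfall_arrays_large
    live_traps = live_transects * design.stations_per_transect * design.live_traps_per_station
    pitfalls = arrays * design.pitfalls_per_array
    rows.append((site_id, FOREST, LIVE, live_traps * design.nights))
    rows.append((site_id, FOREST, PITFALL, pitfalls * design.nights))
    if site_type != "continuous":
        m_live = design.matrix_transects * design.stations_per_transect * design.live_traps_per_station
        rows.append((site_id, MATRIX, LIVE, m_live * design.nights))
        rows.append((site_id, MATRIX, PITFALL, 0))
    return pd.DataFrame(rows, columns=["site_id", "stratum", "trap_class", "trap_nights"])


def design_effort_table(sites: pd.DataFrame, design: TrapDesign = TrapDesign()) -> pd.DataFrame:
    """Concatenate :func:`design_effort` over every row of a site table."""
    parts = [design_effort(row, design) for _, row in sites.iterrows()]
    return pd.concat(parts, ignore_index=True)


def standardize_abundance(
    captures: pd.DataFrame,
    effort: pd.DataFrame,
    per: float = 1000.0,
    stratum: str = FOREST,
    trap_classes=None,
) -> CommunityMatrix:
    """Convert counts to capture rates per ``per`` trap-nights.

    Counts are pooled over the requested trap classes and divided by the
    pooled effort, which is equivalent to the effort-weighted mean of
    per-class rates. Sites present in the effort table for the requested
    stratum appear in the output even with zero captures.

    Raises ``ValueError`` naming the offending site/class when captures
    exist for a (site, trap class) with zero or missing recorded effort.
    """
    eff = effort[effort["stratum"] == stratum]
    cap = captures[captures["stratum"] == stratum]
    if trap_classes is not None:
        eff = eff[eff["trap_class"].isin(trap_classes)]
        cap = cap[cap["trap_class"].isin(trap_classes)]
    if (cap["count"] < 0).any():
        raise ValueError("negative capture counts")

    eff_by_class = eff.groupby(["site_id", "trap_class"])["trap_nights"].sum()
    for (site, cls), n in cap.groupby(["site_id", "trap_class"])["count"].sum().items():
        if n > 0 and eff_by_class.get((site, cls), 0) <= 0:
            raise ValueError(
                f"captures recorded for site {site!r} trap class {cls!r} "
                f"in stratum {stratum!r} with zero recorded effort"
            )

    total_eff = eff.groupby("site_id")["trap_nights"].sum()
    sites = total_eff.index
    counts = (
        cap.groupby(["site_id", "species_id"])["count"].sum().unstack(fill_value=0)
        .reindex(sites, fill_value=0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = counts.div(total_eff, axis=0).mul(per)
    rates = rates.fillna(0.0)
    return CommunityMatrix(data=rates, stratum=stratum, per=per)


def sample_coverage(counts) -> float:
    """Abundance-based sample-coverage estimate for one site.

    With ``n`` individuals, ``f1`` singleton species and ``f2``
    doubletons::

        C = 1 - (f1/n) * ((n-1) f1) / ((n-1) f1 + 2 f2)

    Returns 1 when there are no singletons. Raises on an empty sample.
    """
    c = np.asarray(counts)
    if c.size == 0 or np.any(c < 0) or np.any(c != np.floor(c)):
        raise ValueError("counts must be non-negative integers")
    n = int(c.sum())
    if n < 1:
        raise ValueError("sample coverage undefined for an empty sample (n = 0)")
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:  # n == 1, single individual
        return 0.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / denom)
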