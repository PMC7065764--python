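"""Patch delineation and multi-year community-FD projection.

Given binary forest grids, forest patches are delineated as connected
components (8-neighbourhood by default), each patch receives a projected
community-average forest-dependency from the fitted quadratic
area-response

    cfd = b0 + b1 * log10(area_ha) + b2 * log10(area_ha)^2,

and a deforestation chronosequence is summarized per year (patch
counts, forest area, area fraction with negative projected cfd) plus
transition fractions between chosen years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import study

__all__ = [
    "ForestGrid",
    "PatchMap",
    "ProjectionCoefficients",
    "label_patches",
    "proximity_index",
    "project_cfd",
    "chronosequence_summary",
    "transition_metric",
    "CONTINUOUS_FOREST_PROX",
]

#: Surrogate proximity value assigned to continuous-forest reference sites.
CONTINUOUS_FOREST_PROX = study.CF_PROX


@dataclass
class ForestGrid:
    """Binary forest raster: 1 = forest, 0 = cleared."""

    data: np.ndarray
    pixel_area_ha: float
    year: object = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("forest grid must be binary (0/1)")
        if self.pixel_area_ha <= 0:
            raise ValueError("pixel_area_ha must be > 0")
        self.data = arr.astype(np.int8)

    @property
    def forest_area_ha(self) -> float:
        return float(self.data.sum()) * self.pixel_area_ha


@dataclass
class PatchMap:
    """Delineated patches: per-patch table plus the labelled raster."""

    table: pd.DataFrame
    labels: np.ndarray
    pixel_area_ha: float
    year: object = None


@dataclass(frozen=True)
class ProjectionCoefficients:
    """Quadratic community-FD response to log10 patch area."""

    b0: float = 0.0
    b1: float = study.PROJECTION_B1
    b2: float = study.PROJECTION_B2

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.b0, self.b1, self.b2)):
            raise ValueError("coefficients must be finite")

    def __call__(self, area_ha):
        x = np.log10(area_ha)
        return self.b0 + self.b1 * x + self.b2 * x ** 2

    @property
    def vertex_log10_area(self) -> float:
        """log10 area where the quadratic response peaks."""
        return -self.b1 / (2.0 * self.b2)


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def label_patches(grid: ForestGrid, connectivity: int = 8) -> PatchMap:
    """Delineate forest patches as connected components.

    Patch ids are assigned in raster-scan order of each patch's first
    pixel, which makes the labelling deterministic. The per-patch table
    holds pixel counts, areas (pixel count x pixel area, exact) and
    centroids in (row, col) pixel coordinates.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(grid.data, structure=_STRUCTURES[connectivity])
    # scipy assigns ids in raster-scan order of first pixels already, but we
    # relabel explicitly so the documented invariant never depends on it.
    if n > 0:
        first = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
        flat = labels.ravel()
        nz = np.flatnonzero(flat)
        np.minimum.at(first, flat[nz], nz)
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        labels = remap[labels]
    ids = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    if n > 0:
        centroids = ndimage.center_of_mass(grid.data, labels, ids)
    else:
        centroids = []
    table = pd.DataFrame({
        "patch_id": ids,
        "year": grid.year,
        "pixel_count": counts,
        "area_ha": counts * grid.pixel_area_ha,
        "centroid_row": [c[0] for c in centroids],
        "centroid_col": [c[1] for c in centroids],
    })
    return PatchMap(table=table, labels=labels,
                    pixel_area_ha=grid.pixel_area_ha, year=grid.year)


def _boundary_pixels(labels: np.ndarray, patch_id: int) -> np.ndarray:
    mask = labels == patch_id
    interior = ndimage.binary_erosion(mask, structure=_STRUCTURES[4])
    return np.argwhere(mask & ~interior)


def _edge_distance_m(px_a: np.ndarray, px_b: np.ndarray, pixel_side_m: float) -> float:
    """Nearest distance between pixel boundaries of two patches.

    For axis-aligned square pixels the boundary gap between pixels at
    integer offsets (dr, dc) is sqrt(max(|dr|-1,0)^2 + max(|dc|-1,0)^2)
    pixel sides; touching pixels have distance 0.
    """
    dr = np.abs(px_a[:, None, 0] - px_b[None, :, 0]) - 1
    dc = np.abs(px_a[:, None, 1] - px_b[None, :, 1]) - 1
    gap = np.hypot(np.maximum(dr, 0), np.maximum(dc, 0))
    return float(gap.min()) * pixel_side_m


def proximity_index(patch_map: PatchMap, focal_id: int, radius_m: float,
                    form: str = "standard") -> float:
    """Proximity (PROX) of a focal patch to its neighbours within a radius.

    ``standard``: sum over non-touching neighbour patches with
    edge-to-edge distance d <= radius of area_ha / d^2 (the FRAGSTATS
    form; larger = less isolated). ``literal`` uses the alternative
    written form (sum of areas) / (sum of distances)^2. Edge-to-edge
    distances are between nearest pixel boundaries, not centroids.
    Returns 0 when no neighbour lies within the radius.
    """
    table = patch_map.table
    if focal_id not in set(table["patch_id"]):
        raise KeyError(f"unknown focal patch id {focal_id!r}")
    pixel_side_m = math.sqrt(patch_map.pixel_area_ha * 10_000.0)
    focal_px = _boundary_pixels(patch_map.labels, focal_id)
    areas, dists = [], []
    for pid, area in zip(table["patch_id"], table["area_ha"]):
        if pid == focal_id:
            continue
        d = _edge_distance_m(focal_px, _boundary_pixels(patch_map.labels, pid),
                             pixel_side_m)
        if d <= 0 or d > radius_m:
            continue  # touching patches and out-of-radius patches excluded
        areas.append(float(area))
        dists.append(d)
    if not areas:
        return 0.0
    if form == "standard":
        return float(sum(a / d ** 2 for a, d in zip(areas, dists)))
    if form == "literal":
        return float(sum(areas) / sum(dists) ** 2)
    raise ValueError(f"unknown form {form!r}")


def project_cfd(patches: pd.DataFrame,
                coeffs: ProjectionCoefficients = ProjectionCoefficients()) -> pd.DataFrame:
    """Attach the projected community-average FD to every patch."""
    if (patches["area_ha"] <= 0).any():
        raise ValueError("patch areas must be positive")
    out = patches.copy()
    cfd = coeffs(out["area_ha"].to_numpy(dtype=float))
    out["cfd"] = cfd
    out["cfd_sign"] = np.sign(cfd).astype(int)
    return out


def chronosequence_summary(patch_tables: Sequence[pd.DataFrame],
                           pixel_area_ha: Optional[float] = None) -> pd.DataFrame:
    """Per-year landscape aggregates over projected patch tables.

    Requires the ``cfd`` column from :func:`project_cfd`. Forest areas
    are exact integer pixel arithmetic times the pixel area.
    """
    if len(patch_tables) == 0:
        raise ValueError("need at least one year")
    rows = []
    for t in patch_tables:
        area = float(t["area_ha"].sum())
        neg = t["cfd"] < 0 if "cfd" in t else pd.Series(False, index=t.index)
        neg_area = float(t.loc[neg, "area_ha"].sum())
        rows.append({
            "year": t["year"].iloc[0] if len(t) else None,
            "n_patches": int(len(t)),
            "n_negative_cfd": int(neg.sum()),
            "forest_area_ha": area,
            "area_fraction_negative": neg_area / area if area > 0 else 0.0,
        })
    return pd.DataFrame(rows)


def _cfd_raster(patch_map: PatchMap, table: pd.DataFrame) -> np.ndarray:
    n = int(patch_map.labels.max())
    cfd = np.full(n + 1, np.nan)
    cfd[table["patch_id"].to_numpy()] = table["cfd"].to_numpy(dtype=float)
    return cfd[patch_map.labels]


def transition_metric(map_a: PatchMap, table_a: pd.DataFrame,
                      map_b: PatchMap, table_b: pd.DataFrame,
                      denominator: str = "forest_a",
                      threshold: float = 0.0) -> float:
    """Fraction of high-FD forest in year A no longer high-FD in year B.

    A pixel qualifies in a year when it is forest and belongs to a patch
    with projected cfd above ``threshold``. The numerator is the area of
    pixels qualifying in A but not in B (cleared, or in a patch at or
    below the threshold); the denominator is the forest area of year A
    (``forest_a``) or year B (``forest_b``).
    """
    if map_a.labels.shape != map_b.labels.shape:
        raise ValueError("grids must share the same shape")
    if denominator not in ("forest_a", "forest_b"):
        raise ValueError("denominator must be 'forest_a' or 'forest_b'")
    cfd_a = _cfd_raster(map_a, table_a)
    cfd_b = _cfd_raster(map_b, table_b)
    qual_a = (map_a.labels > 0) & (cfd_a > threshold)
    qual_b = (map_b.labels > 0) & (cfd_b > threshold)
    lost = qual_a & ~qual_b
    denom_pixels = (map_a.labels > 0).sum() if denominator == "forest_a" \
        else (map_b.labels > 0).sum()
    if denom_pixels == 0:
        raise ValueError("zero denominator: no forest in the reference year")
    return float(lost.sum()) / float(denom_pixels)
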