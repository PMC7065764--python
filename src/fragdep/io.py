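"""Reading and writing the package's delimited-text formats.

All tables are UTF-8 comma-separated files with a header row; binary
forest grids are plain-text 0/1 matrices (whitespace separated), one
row per raster row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .effort import CommunityMatrix
from .landscape_projection import ForestGrid

__all__ = [
    "read_table", "write_table",
    "read_community_matrix", "write_community_matrix",
    "read_grid", "write_grid",
]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)


def write_community_matrix(cm: CommunityMatrix, path) -> None:
    out = cm.data.copy()
    out.index.name = "site_id"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path)


def read_community_matrix(path, stratum: str = "forest",
                          per: float = 1000.0) -> CommunityMatrix:
    data = pd.read_csv(path, index_col="site_id")
    return CommunityMatrix(data=data, stratum=stratum, per=per)


def read_grid(path, pixel_area_ha: float, year=None) -> ForestGrid:
    data = np.loadtxt(path, dtype=np.int8)
    return ForestGrid(data=np.atleast_2d(data), pixel_area_ha=pixel_area_ha,
                      year=year)


def write_grid(grid: ForestGrid, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, grid.data, fmt="%d")
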