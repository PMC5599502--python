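"""STDEV*COEFF contour extraction: from PLS coefficients back to 3D regions.

The display convention of field-based QSAR: at every kept lattice point the
product coefficient * column standard deviation measures how much observed
activity variation that point explains, with sign.  Contouring the extreme
percentiles of this scalar field yields the familiar favored (e.g. "bulky
groups increase activity here") and disfavored regions.

Percentile thresholds are taken over the NONZERO values only (filtered-out
columns hold exact zeros) and membership is strict — a constant field yields
empty contour sets.  Defaults: favored above the 80th, disfavored below the
20th percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .field_engine import GridRegion
from .pls_engine import DescriptorMatrix, PLSModel

__all__ = ["ContourSet", "stdev_coeff_field", "extract_contours", "write_dx"]


@dataclass
class ContourSet:
    field_label: str
    favored_points: np.ndarray      # (k, 4): x, y, z, value
    disfavored_points: np.ndarray   # (m, 4)
    thresholds: tuple[float, float]  # (upper percentile value, lower)

    @property
    def n_favored(self) -> int:
        return int(self.favored_points.shape[0])

    @property
    def n_disfavored(self) -> int:
        return int(self.disfavored_points.shape[0])


def stdev_coeff_field(
    model: PLSModel, X: DescriptorMatrix, field_label: str, grid: GridRegion
) -> np.ndarray:
    """Per-lattice-point STDEV*COEFF values for one field (zeros at columns
    dropped by the filter).  Invariant under per-column rescaling of X."""
    if model.block_index is None:
        raise ValueError("model carries no block index; fit on a DescriptorMatrix")
    labels = {lab for lab, _ in X.block_index}
    if field_label not in labels:
        raise KeyError(f"unknown field label {field_label!r}; have {sorted(labels)}")
    sds = X.X.std(axis=0, ddof=1)
    out = np.zeros(grid.n_points)
    for j, (lab, p) in enumerate(X.block_index):
        if lab == field_label:
            out[p] = model.coefficients[j] * sds[j]
    return out


def extract_contours(
    field: np.ndarray,
    grid: GridRegion,
    fav_pct: float = 80.0,
    disfav_pct: float = 20.0,
    field_label: str = "",
) -> ContourSet:
    """Contour a scalar lattice field at percentile thresholds.

    Favored = points strictly above the ``fav_pct`` percentile of the
    nonzero values; disfavored = strictly below the ``disfav_pct``
    percentile.  Invariant under positive rescaling of the field.
    """
    if not 0 < disfav_pct < fav_pct < 100:
        raise ValueError("need 0 < disfav_pct < fav_pct < 100")
    field = np.asarray(field, dtype=float)
    if field.size != grid.n_points:
        raise ValueError("field length must match grid points")
    nz = field[field != 0]
    points = grid.points()
    if nz.size == 0:
        warnings.warn("all-zero scalar field; contour sets are empty")
        empty = np.empty((0, 4))
        return ContourSet(field_label, empty, empty, (np.nan, np.nan))
    hi = float(np.percentile(nz, fav_pct))
    lo = float(np.percentile(nz, disfav_pct))
    fav_mask = field > hi
    dis_mask = (field < lo) & (field != 0)
    fav = np.column_stack([points[fav_mask], field[fav_mask]])
    dis = np.column_stack([points[dis_mask], field[dis_mask]])
    return ContourSet(field_label, fav, dis, (hi, lo))


def write_dx(field: np.ndarray, grid: GridRegion, path) -> None:
    """Write a scalar lattice field as an OpenDX regular grid (text), the
    format molecular viewers read for isosurface display."""
    field = np.asarray(field, dtype=float)
    nx, ny, nz = grid.dims
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
        f"delta {grid.spacing:.6f} 0.0 0.0",
        f"delta 0.0 {grid.spacing:.6f} 0.0",
        f"delta 0.0 0.0 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {field.size} data follows",
    ]
    vals = field.reshape(-1)
    for i in range(0, vals.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in vals[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    Path(path).write_text("\n".join(lines) + "\n")
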