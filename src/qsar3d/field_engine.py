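"""CoMFA and CoMSIA molecular interaction fields on a common lattice.

CoMFA samples probe-interaction energies: a 6-12 Lennard-Jones steric term
and a Coulomb electrostatic term (distance-dependent dielectric eps(r) = r,
Coulomb constant 332.06 kcal*A/(mol*e^2)), both truncated to +/- cutoff
(default 30 kcal/mol).  At lattice points buried inside an atom the steric
energy plateaus at +cutoff and the electrostatic value carries no signal;
following the classic convention such entries are replaced by the column
mean over the non-buried molecules.

CoMSIA replaces hard potentials with Gaussian similarity indices

    A_Fk(q) = sum_i  W_probe,k * W_ik * exp(-alpha * r_iq^2)

evaluated for five atomic properties (steric, electrostatic, hydrophobic,
H-bond donor, H-bond acceptor) with attenuation factor alpha = 0.3 A^-2 and
no distance cutoff, so every lattice point sees every atom.

Low-information lattice columns (value range across molecules below a
threshold, default 2.0 kcal/mol) are removed by :func:`column_filter` before
regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .molecules import Molecule, load_parameter_table

__all__ = [
    "GridRegion",
    "Probe",
    "FieldBlock",
    "COULOMB_KCAL",
    "COMFA_FIELDS",
    "COMSIA_FIELDS",
    "default_comfa_probe",
    "default_comsia_probe",
    "build_grid",
    "comfa_fields",
    "comsia_fields",
    "comfa_blocks",
    "comsia_blocks",
    "column_filter",
    "save_blocks",
    "load_blocks",
]

#: Coulomb constant in kcal*Angstrom/(mol*e^2).
COULOMB_KCAL = 332.06

COMFA_FIELDS = ("comfa_steric", "comfa_electrostatic")
COMSIA_FIELDS = (
    "comsia_steric",
    "comsia_electrostatic",
    "comsia_hydrophobic",
    "comsia_donor",
    "comsia_acceptor",
)


# ---------------------------------------------------------------------------
# Grid and probe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridRegion:
    """Axis-aligned lattice: origin, uniform spacing and point counts."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be positive")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3), C-order over (ix, iy, iz)."""
        axes = [
            self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def point_index(self) -> np.ndarray:
        """(n_points, 3) integer lattice coordinates matching :meth:`points`."""
        ii = np.indices(self.dims).reshape(3, -1).T
        return ii


@dataclass(frozen=True)
class Probe:
    """Probe atom parameters: CoMFA uses a charged sp3 carbon; CoMSIA a unit
    probe with W_probe,k = 1 for every property."""

    vdw_radius: float = 1.7
    well_depth: float = 0.1094
    charge: float = 1.0
    comsia_props: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError("probe vdw_radius must be positive")
        if self.well_depth < 0:
            raise ValueError("probe well_depth must be non-negative")


def default_comfa_probe(scheme: str = "default") -> Probe:
    p = load_parameter_table(scheme)["probes"]["comfa_sp3_carbon"]
    return Probe(p["vdw_radius"], p["well_depth"], p["charge"])


def default_comsia_probe() -> Probe:
    return Probe(vdw_radius=1.0, well_depth=0.0, charge=1.0)


@dataclass
class FieldBlock:
    """One descriptor field for a molecule set: rows = molecules, columns =
    lattice points.  CoMFA values are kcal/mol; CoMSIA values are
    dimensionless similarity indices.

    ``point_ids`` maps each column to its flat lattice index (all points for
    a freshly computed block; a subset after column filtering)."""

    field_label: str
    values: np.ndarray
    grid: GridRegion
    molecule_ids: tuple[str, ...]
    point_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("field values must be a 2-D matrix")
        if self.point_ids is None:
            if self.values.shape[1] != self.grid.n_points:
                raise ValueError("field columns must match grid points")
            self.point_ids = np.arange(self.grid.n_points)
        else:
            self.point_ids = np.asarray(self.point_ids, dtype=int)
            if self.values.shape[1] != self.point_ids.size:
                raise ValueError("field columns must match point_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in field {self.field_label}")

    def point_coords(self) -> np.ndarray:
        """Lattice coordinates (A) of this block's columns, shape (ncol, 3)."""
        return self.grid.points()[self.point_ids]


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

def build_grid(mols: Sequence[Molecule], spacing: float = 1.0, margin: float = 4.0) -> GridRegion:
    """Minimal lattice covering every atom of every molecule plus ``margin``
    on each face, at uniform ``spacing`` (defaults: 1 A spacing, 4 A margin).
    """
    if len(mols) == 0:
        raise ValueError("cannot build a grid from an empty molecule list")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    coords = np.vstack([m.coords for m in mols])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    span = hi - lo
    # guard float fuzz so an exact multiple of spacing is not rounded up
    dims = tuple(int(np.ceil(round(s / spacing, 9))) + 1 for s in span)
    return GridRegion(origin=tuple(float(x) for x in lo), spacing=float(spacing), dims=dims)


# ---------------------------------------------------------------------------
# CoMFA
# ---------------------------------------------------------------------------

def comfa_fields(
    mol: Molecule,
    grid: GridRegion | np.ndarray,
    probe: Probe | None = None,
    cutoff: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steric and electrostatic probe energies for one molecule.

    Returns ``(steric, electrostatic, excluded)``: two value vectors over the
    lattice points (truncated to +/- cutoff) and a boolean mask marking
    sterically excluded points (steric at the +cutoff plateau), where the
    electrostatic value is physically meaningless and later replaced by the
    column mean over non-excluded molecules (see :func:`comfa_blocks`).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    probe = probe or default_comfa_probe()
    points = grid.points() if isinstance(grid, GridRegion) else np.asarray(grid, float)
    r = cdist(points, mol.coords)
    r = np.maximum(r, 1e-12)  # atom exactly on a lattice point

    # 6-12 LJ with R_min = r_i + r_probe, eps = sqrt(eps_i * eps_probe)
    rmin = mol.vdw_radii + probe.vdw_radius
    eps = np.sqrt(mol.well_depths * probe.well_depth)
    s6 = (rmin / r) ** 6
    with np.errstate(over="ignore"):
        steric_raw = (eps * (s6 * s6 - 2.0 * s6)).sum(axis=1)
    excluded = steric_raw >= cutoff
    steric = np.clip(steric_raw, -cutoff, cutoff)

    # Coulomb with distance-dependent dielectric eps(r) = r -> q q' K / r^2
    elec_raw = (COULOMB_KCAL * probe.charge * mol.charges / r**2).sum(axis=1)
    elec = np.clip(elec_raw, -cutoff, cutoff)
    return steric, elec, excluded


def comfa_blocks(
    mols: Sequence[Molecule],
    grid: GridRegion,
    probe: Probe | None = None,
    cutoff: float = 30.0,
) -> dict[str, FieldBlock]:
    """CoMFA steric + electrostatic FieldBlocks for a molecule set, applying
    the column-mean substitution of electrostatic values at sterically
    excluded entries."""
    probe = probe or default_comfa_probe()
    points = grid.points()
    n = len(mols)
    steric = np.empty((n, grid.n_points))
    elec = np.empty((n, grid.n_points))
    excl = np.empty((n, grid.n_points), dtype=bool)
    ids = tuple(m.id for m in mols)
    for i, mol in enumerate(mols):
        steric[i], elec[i], excl[i] = comfa_fields(mol, points, probe, cutoff)

    # replace electrostatics inside the steric exclusion zone by the column
    # mean over non-excluded molecules (0 when every molecule is buried)
    ok = ~excl
    n_ok = ok.sum(axis=0)
    col_mean = np.where(n_ok > 0, (elec * ok).sum(axis=0) / np.maximum(n_ok, 1), 0.0)
    elec = np.where(excl, col_mean[None, :], elec)

    return {
        "comfa_steric": FieldBlock("comfa_steric", steric, grid, ids),
        "comfa_electrostatic": FieldBlock("comfa_electrostatic", elec, grid, ids),
    }


# ---------------------------------------------------------------------------
# CoMSIA
# ---------------------------------------------------------------------------

def comsia_fields(
    mol: Molecule,
    grid: GridRegion | np.ndarray,
    probe: Probe | None = None,
    alpha: float = 0.3,
) -> np.ndarray:
    """Gaussian similarity indices for one molecule.

    Returns a (5, n_points) array ordered (steric, electrostatic,
    hydrophobic, donor, acceptor):

        A_k(q) = sum_i W_probe,k * W_ik * exp(-alpha * r_iq^2)

    summed over all atoms with no distance cutoff.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    probe = probe or default_comsia_probe()
    points = grid.points() if isinstance(grid, GridRegion) else np.asarray(grid, float)
    r2 = cdist(points, mol.coords, metric="sqeuclidean")
    g = np.exp(-alpha * r2)  # (n_points, n_atoms)
    vals = g @ mol.comsia_props  # (n_points, 5)
    vals = vals * np.asarray(probe.comsia_props, dtype=float)[None, :]
    return vals.T


def comsia_blocks(
    mols: Sequence[Molecule],
    grid: GridRegion,
    probe: Probe | None = None,
    alpha: float = 0.3,
    fields: Sequence[str] = COMSIA_FIELDS,
) -> dict[str, FieldBlock]:
    """CoMSIA FieldBlocks (five properties by default) for a molecule set."""
    probe = probe or default_comsia_probe()
    ids = tuple(m.id for m in mols)
    points = grid.points()
    all_vals = np.empty((len(mols), 5, grid.n_points))
    for i, mol in enumerate(mols):
        all_vals[i] = comsia_fields(mol, points, probe, alpha)
    out = {}
    for k, label in enumerate(COMSIA_FIELDS):
        if label in fields:
            out[label] = FieldBlock(label, all_vals[:, k, :], grid, ids)
    return out


# ---------------------------------------------------------------------------
# Column filtering
# ---------------------------------------------------------------------------

def column_filter(
    blocks: Mapping[str, FieldBlock] | Sequence[FieldBlock],
    threshold: float = 2.0,
) -> tuple[dict[str, FieldBlock], dict[str, np.ndarray]]:
    """Drop lattice columns whose value range (max - min across molecules)
    falls below ``threshold``; ties (range == threshold) are kept.

    Returns the filtered blocks and, per field label, the boolean kept-column
    mask needed to map model coefficients back onto the lattice.
    """
    if not isinstance(blocks, Mapping):
        blocks = {b.field_label: b for b in blocks}
    ids = {b.molecule_ids for b in blocks.values()}
    if len(ids) > 1:
        raise ValueError("field blocks do not share a molecule ordering")
    filtered: dict[str, FieldBlock] = {}
    masks: dict[str, np.ndarray] = {}
    total_kept = 0
    for label, block in blocks.items():
        rng = block.values.max(axis=0) - block.values.min(axis=0)
        mask = rng >= threshold if threshold > 0 else np.ones(rng.shape, dtype=bool)
        masks[label] = mask
        total_kept += int(mask.sum())
        filtered[label] = FieldBlock(
            label,
            block.values[:, mask],
            block.grid,
            block.molecule_ids,
            point_ids=block.point_ids[mask],
        )
    if total_kept == 0:
        raise ValueError(
            "column filter dropped every column; lower the threshold "
            f"(currently {threshold})"
        )
    return filtered, masks


# ---------------------------------------------------------------------------
# Serialization: one matrix file per field + a JSON sidecar
# ---------------------------------------------------------------------------

def save_blocks(
    blocks: Mapping[str, FieldBlock],
    directory,
    masks: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write each FieldBlock as a whitespace-delimited matrix plus a JSON
    sidecar holding grid metadata, molecule ids and kept-column masks."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta: dict = {"fields": {}}
    for label, block in blocks.items():
        np.savetxt(directory / f"{label}.mat", block.values, fmt="%.10g")
        meta["fields"][label] = {
            "grid": {
                "origin": list(block.grid.origin),
                "spacing": block.grid.spacing,
                "dims": list(block.grid.dims),
            },
            "molecule_ids": list(block.molecule_ids),
            "point_ids": np.asarray(block.point_ids).tolist(),
            "kept_mask": (
                np.asarray(masks[label], dtype=int).tolist()
                if masks is not None and label in masks
                else None
            ),
        }
    (directory / "fields.json").write_text(json.dumps(meta, indent=1))


def load_blocks(directory) -> tuple[dict[str, FieldBlock], dict[str, np.ndarray]]:
    directory = Path(directory)
    meta = json.loads((directory / "fields.json").read_text())
    blocks: dict[str, FieldBlock] = {}
    masks: dict[str, np.ndarray] = {}
    for label, info in meta["fields"].items():
        g = info["grid"]
        grid = GridRegion(tuple(g["origin"]), g["spacing"], tuple(g["dims"]))
        values = np.loadtxt(directory / f"{label}.mat", ndmin=2)
        blocks[label] = FieldBlock(
            label,
            values,
            grid,
            tuple(info["molecule_ids"]),
            point_ids=np.asarray(info["point_ids"], dtype=int),
        )
        if info.get("kept_mask") is not None:
            masks[label] = np.asarray(info["kept_mask"], dtype=bool)
    return blocks, masks
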