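"""Molecule containers, atomic parameterization and rigid scaffold superposition.

A congeneric-series 3D-QSAR study starts from a set of small molecules with
measured activities (pIC50 = -log10 IC50 [mol/L]).  Before any field can be
sampled, every molecule must carry per-atom parameters (partial charge,
van der Waals radius and well depth, and the five CoMSIA property weights:
steric, electrostatic, hydrophobic, H-bond donor, H-bond acceptor) and every
molecule must be rigidly superposed onto a template via a shared scaffold —
here classically the furanone ring common to the series.

Charges are Gasteiger PEOE (iterative partial equalization of orbital
electronegativity) as implemented in RDKit; vdW parameters come from a small
versioned element table shipped with the package (see ``data/vdw_params.json``).
Superposition is the Kabsch least-squares rigid fit (rotation + translation,
proper rotation only — no scaling or reflection).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "Atom",
    "Molecule",
    "ScaffoldMap",
    "load_parameter_table",
    "read_structures",
    "read_activities",
    "assign_parameters",
    "align_to_template",
    "kabsch",
    "write_sdf",
    "COMSIA_PROPERTY_NAMES",
]

#: Order of the five CoMSIA per-atom property weights W_ik.
COMSIA_PROPERTY_NAMES = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """A parameterized atom.

    ``comsia_props`` holds the five property weights W_ik used by the CoMSIA
    similarity-index field (steric, electrostatic, hydrophobic, donor,
    acceptor).  Units: coords in Angstrom, partial_charge in elementary
    charges, well_depth in kcal/mol, steric weight in Angstrom^3.
    """

    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    vdw_radius: float = 1.7
    well_depth: float = 0.1
    comsia_props: np.ndarray = field(default_factory=lambda: np.zeros(5))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.comsia_props = np.asarray(self.comsia_props, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if self.comsia_props.shape != (5,):
            raise ValueError("comsia_props must be a 5-vector")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if self.well_depth < 0:
            raise ValueError("well_depth must be non-negative")
        if not np.all(np.isfinite(self.comsia_props)):
            raise ValueError("comsia_props must be finite")


@dataclass
class Molecule:
    """An ordered collection of atoms with an optional activity (pIC50)."""

    id: str
    atoms: list[Atom]
    activity: float | None = None
    #: underlying RDKit mol when the molecule was read from a structure file;
    #: needed for connectivity-aware steps (charge assignment, donor flags).
    rdmol: Chem.Mol | None = None

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError(f"molecule {self.id!r} has no atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate matrix in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def well_depths(self) -> np.ndarray:
        return np.array([a.well_depth for a in self.atoms], dtype=float)

    @property
    def comsia_props(self) -> np.ndarray:
        """(n_atoms, 5) CoMSIA property weight matrix W_ik."""
        return np.array([a.comsia_props for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate matrix shape mismatch")
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Molecule(self.id, atoms, self.activity, self.rdmol)


@dataclass(frozen=True)
class ScaffoldMap:
    """Atom correspondence (molecule index, template index) used for the fit.

    Rigid superposition needs at least three non-collinear anchor points;
    for the furanone series the natural choice is the five ring atoms.
    """

    pairs: tuple[tuple[int, int], ...]

    def __init__(self, pairs: Iterable[Sequence[int]]):
        object.__setattr__(self, "pairs", tuple((int(a), int(b)) for a, b in pairs))
        if len(self.pairs) < 3:
            raise ValueError("scaffold map needs at least 3 atom pairs")
        mol_idx = [p[0] for p in self.pairs]
        tpl_idx = [p[1] for p in self.pairs]
        if len(set(mol_idx)) != len(mol_idx) or len(set(tpl_idx)) != len(tpl_idx):
            raise ValueError("scaffold map indices must be unique on each side")
        if min(mol_idx) < 0 or min(tpl_idx) < 0:
            raise ValueError("scaffold map indices must be non-negative")

    @classmethod
    def identity(cls, n: int) -> "ScaffoldMap":
        return cls([(i, i) for i in range(n)])


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

def load_parameter_table(scheme: str = "default") -> dict:
    """Load the shipped element parameter table (vdW radii, well depths,
    hydrophobic increments) plus probe definitions.

    Only one scheme ships for now; the argument exists so alternative tables
    can be dropped in without touching call sites.
    """
    if scheme not in ("default", "bondi-amber-v1"):
        raise ValueError(f"unknown parameter scheme {scheme!r}")
    text = resources.files("qsar3d.data").joinpath("vdw_params.json").read_text()
    return json.loads(text)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_activities(path) -> pd.Series:
    """Read an activity table: CSV with columns ``id,pIC50`` or ``id,IC50_M``.

    IC50 values given in mol/L are converted as pIC50 = -log10(IC50).
    """
    df = pd.read_csv(path, dtype={"id": str})
    if "pIC50" in df.columns:
        vals = df["pIC50"].astype(float)
    elif "IC50_M" in df.columns:
        vals = -np.log10(df["IC50_M"].astype(float))
    else:
        raise ValueError("activity table needs a 'pIC50' or 'IC50_M' column")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in activity table: {dupes}")
    return pd.Series(vals.values, index=df["id"].values, name="pIC50")


def _mol_id(rdmol: Chem.Mol, index: int) -> str:
    if rdmol.HasProp("_Name") and rdmol.GetProp("_Name").strip():
        return rdmol.GetProp("_Name").strip()
    return f"mol_{index}"


def _from_rdkit(rdmol: Chem.Mol, mol_id: str, activity: float | None) -> Molecule:
    conf = rdmol.GetConformer()
    atoms = []
    for i, a in enumerate(rdmol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        atoms.append(Atom(element=a.GetSymbol(), coords=np.array([p.x, p.y, p.z])))
    return Molecule(id=mol_id, atoms=atoms, activity=activity, rdmol=rdmol)


def read_structures(path, activities: pd.Series | None = None) -> list[Molecule]:
    """Read an SDF (V2000) or MOL2 file into a list of :class:`Molecule`.

    Record names become molecule ids; when an activity table is supplied the
    matching pIC50 is attached (molecules absent from the table keep
    ``activity=None``).  Raises on unparseable records (naming the record
    index) and on duplicate ids.
    """
    path = str(path)
    mols: list[Molecule] = []
    if path.lower().endswith((".sdf", ".sd", ".mol")):
        supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=True)
        raw = list(supplier)
    elif path.lower().endswith(".mol2"):
        raw = [Chem.MolFromMol2File(path, removeHs=False)]
    else:
        raise ValueError(f"unsupported structure format: {path}")

    seen: set[str] = set()
    for idx, rdmol in enumerate(raw):
        if rdmol is None:
            raise ValueError(f"unparseable structure record at index {idx} in {path}")
        mid = _mol_id(rdmol, idx)
        if mid in seen:
            raise ValueError(f"duplicate molecule id {mid!r}")
        seen.add(mid)
        act = None
        if activities is not None and mid in activities.index:
            act = float(activities.loc[mid])
        mols.append(_from_rdkit(rdmol, mid, act))
    return mols


def write_sdf(mols: Sequence[Molecule], path) -> None:
    """Write molecules (current coordinates) to an SDF file, preserving ids."""
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            rdmol = mol.rdmol
            if rdmol is None:
                rdmol = _pseudo_rdmol(mol)
            else:
                rdmol = Chem.Mol(rdmol)
            conf = rdmol.GetConformer()
            for i, atom in enumerate(mol.atoms):
                conf.SetAtomPosition(i, atom.coords.tolist())
            rdmol.SetProp("_Name", mol.id)
            if mol.activity is not None:
                rdmol.SetProp("pIC50", f"{mol.activity:.4f}")
            writer.write(rdmol)
    finally:
        writer.close()


def _pseudo_rdmol(mol: Molecule) -> Chem.Mol:
    """Build a bond-less RDKit mol for atoms-only (synthetic) molecules."""
    rw = Chem.RWMol()
    for atom in mol.atoms:
        rw.AddAtom(Chem.Atom(atom.element))
    conf = Chem.Conformer(mol.n_atoms)
    for i, atom in enumerate(mol.atoms):
        conf.SetAtomPosition(i, atom.coords.tolist())
    m = rw.GetMol()
    m.AddConformer(conf)
    return m


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

def _donor_acceptor_flags(rdatom: Chem.Atom) -> tuple[float, float]:
    # Rule-based: O/N bearing hydrogens donate; O always accepts, N accepts
    # unless positively charged / quaternary.
    sym = rdatom.GetSymbol()
    donor = 0.0
    acceptor = 0.0
    if sym in ("N", "O"):
        if rdatom.GetTotalNumHs(includeNeighbors=True) > 0:
            donor = 1.0
        if sym == "O":
            acceptor = 1.0
        elif rdatom.GetFormalCharge() <= 0 and rdatom.GetTotalDegree() <= 3:
            acceptor = 1.0
    return donor, acceptor


def assign_parameters(mol: Molecule, scheme: str = "default") -> Molecule:
    """Populate partial charges, vdW parameters and CoMSIA property weights.

    Charges are Gasteiger PEOE (graph-based, hence pose-independent); vdW
    radius/well depth and the hydrophobic increment come from the element
    table; steric weight is r_vdw^3, electrostatic weight is the partial
    charge, and donor/acceptor are rule-based flags.
    """
    if mol.rdmol is None:
        raise ValueError(
            f"molecule {mol.id!r} has no structure graph; parameters must be "
            "set directly for synthetic molecules"
        )
    table = load_parameter_table(scheme)["elements"]
    rdmol = Chem.Mol(mol.rdmol)
    unknown = sorted({a.GetSymbol() for a in rdmol.GetAtoms()} - set(table))
    if unknown:
        raise ValueError(f"elements missing from parameter table: {unknown}")
    AllChem.ComputeGasteigerCharges(rdmol)

    atoms = []
    for i, (atom, rdatom) in enumerate(zip(mol.atoms, rdmol.GetAtoms())):
        q = float(rdatom.GetDoubleProp("_GasteigerCharge"))
        if not math.isfinite(q):  # isolated/odd atoms can yield nan
            q = 0.0
        params = table[rdatom.GetSymbol()]
        donor, acceptor = _donor_acceptor_flags(rdatom)
        props = np.array(
            [params["vdw_radius"] ** 3, q, params["hydrophobic"], donor, acceptor]
        )
        atoms.append(
            Atom(
                element=atom.element,
                coords=atom.coords.copy(),
                partial_charge=q,
                vdw_radius=params["vdw_radius"],
                well_depth=params["well_depth"],
                comsia_props=props,
            )
        )
    return Molecule(mol.id, atoms, mol.activity, rdmol)


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit mapping points ``P`` onto ``Q``.

    Returns ``(R, t)`` with ``R`` a proper rotation (det = +1, reflections
    rejected) and ``t`` a translation so that ``P @ R.T + t ~= Q``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _scaffold_rank(points: np.ndarray) -> int:
    centered = points - points.mean(axis=0)
    return int(np.linalg.matrix_rank(centered, tol=1e-8))


def align_to_template(
    mol: Molecule, template: Molecule, scaffold_map: ScaffoldMap
) -> tuple[Molecule, float]:
    """Rigidly superpose ``mol`` onto ``template`` over the mapped scaffold atoms.

    Returns the transformed molecule and the achieved scaffold RMSD (Angstrom).
    The transform minimizes RMSD over the mapped pairs only, but is applied to
    every atom.  Degenerate (collinear) scaffolds are rejected.
    """
    mol_idx = [p[0] for p in scaffold_map.pairs]
    tpl_idx = [p[1] for p in scaffold_map.pairs]
    if max(mol_idx) >= mol.n_atoms or max(tpl_idx) >= template.n_atoms:
        raise IndexError("scaffold map index out of range")
    P = mol.coords[mol_idx]
    Q = template.coords[tpl_idx]
    if _scaffold_rank(Q) < 2 or _scaffold_rank(P) < 2:
        raise ValueError("scaffold atoms are collinear; rigid fit is degenerate")
    R, t = kabsch(P, Q)
    new_coords = mol.coords @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((new_coords[mol_idx] - Q) ** 2, axis=1))))
    return mol.with_coords(new_coords), rmsd


def scaffold_rmsd(mol: Molecule, template: Molecule, scaffold_map: ScaffoldMap) -> float:
    """RMSD over mapped scaffold pairs in the current (untransformed) pose."""
    P = mol.coords[[p[0] for p in scaffold_map.pairs]]
    Q = template.coords[[p[1] for p in scaffold_map.pairs]]
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
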