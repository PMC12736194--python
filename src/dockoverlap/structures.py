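"""Geometric data model and file I/O for docked ligand poses.

A docking run leaves behind multi-record SDF files (one record per ligand
pose) and occasionally single-molecule PDB files.  All poses are assumed to
share one receptor-fixed Cartesian frame in angstroms, so that spatial
overlap between two poses means co-location in the binding site.  Volumes
are computed from atom-centered van der Waals spheres, which requires
attaching an element-specific radius to every atom; files do not carry
radii, so assignment is an explicit, logged step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Bondi (1964) van der Waals radii for the main-group elements that occur
#: in the study compounds, extended with Batsanov's value for iron.  All in
#: angstroms.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Fe": 2.05,
}

FORMS = ("monomer", "dimer", "reference")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element symbol, position (Å, receptor frame), vdW radius.

    ``radius`` is ``None`` until explicitly assigned from a
    :class:`RadiusTable`; a silent default would hide which table produced
    downstream volumes.
    """

    element: str
    position: np.ndarray
    radius: float | None = None
    formal_charge: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.radius is not None and not self.radius > 0:
            raise ValueError(f"assigned radius must be positive, got {self.radius}")


@dataclass
class MoleculePose:
    """A rigid molecule in the shared receptor frame.

    Parameters
    ----------
    id:
        Unique pose label, e.g. ``"7b"``, ``"7b.2"``, ``"don"``.
    form:
        ``"monomer"``, ``"dimer"`` or ``"reference"``.
    atoms:
        Ordered atom list (file order preserved; 0-based indexing).
    binding_energy:
        Eb = -ΔG in kcal/mol from docking; larger = stronger predicted
        binding.  Optional.
    bonds:
        0-based index pairs from the SDF bond block.  Bonds never enter
        volume computations (everything is atom-sphere based); they are kept
        only so pharmacophore typing can detect rings.
    """

    id: str
    form: str = "monomer"
    atoms: list[AtomRecord] = field(default_factory=list)
    binding_energy: float | None = None
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("pose id must be non-empty")
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {self.form!r}")
        if not self.atoms:
            raise ValueError(f"pose {self.id!r} has no atoms")
        if self.binding_energy is not None and not np.isfinite(self.binding_energy):
            raise ValueError(f"binding_energy of {self.id!r} is not finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array, Å."""
        return np.array([a.position for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        """(n,) radius array; raises if any radius is unassigned."""
        vals = [a.radius for a in self.atoms]
        if any(r is None for r in vals):
            raise ValueError(
                f"pose {self.id!r} has unassigned radii; call assign_radii first"
            )
        return np.array(vals, dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "MoleculePose":
        """Copy of this pose with replaced coordinates (same atoms/order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return MoleculePose(
            id=id or self.id,
            form=self.form,
            atoms=atoms,
            binding_energy=self.binding_energy,
            bonds=list(self.bonds),
        )

    def translated(self, shift: Sequence[float]) -> "MoleculePose":
        return self.with_coords(self.coords + np.asarray(shift, dtype=float))

    def bounding_sphere(self) -> tuple[np.ndarray, float]:
        """(center, radius) of a sphere enclosing all atom spheres.

        Centered on the axis-aligned bounding-box midpoint; not minimal but
        cheap and sufficient for disjointness short-circuits.
        """
        xyz = self.coords
        rad = self.radii
        lo = (xyz - rad[:, None]).min(axis=0)
        hi = (xyz + rad[:, None]).max(axis=0)
        center = (lo + hi) / 2
        radius = float(np.max(np.linalg.norm(xyz - center, axis=1) + rad))
        return center, radius


class RadiusTable:
    """Case-insensitive element → vdW radius lookup with an explicit fallback.

    All radii must lie in (0.5, 3.5) Å — outside that window a value is
    almost certainly a typo, not a van der Waals radius.
    """

    def __init__(
        self,
        radii: Mapping[str, float] | None = None,
        default_radius: float = 2.0,
        name: str = "bondi",
    ) -> None:
        radii = dict(BONDI_RADII) if radii is None else dict(radii)
        for el, r in radii.items():
            if not (0.5 < r < 3.5):
                raise ValueError(f"radius for {el!r} out of the physical window (0.5, 3.5): {r}")
        if not (0.5 < default_radius < 3.5):
            raise ValueError(f"default_radius out of (0.5, 3.5): {default_radius}")
        self._radii = {el.capitalize(): float(r) for el, r in radii.items()}
        self.default_radius = float(default_radius)
        self.name = name

    def __contains__(self, element: str) -> bool:
        return element.capitalize() in self._radii

    def __getitem__(self, element: str) -> float:
        return self._radii[element.capitalize()]

    def lookup(self, element: str) -> tuple[float, bool]:
        """(radius, was_fallback) for an element symbol."""
        key = element.capitalize()
        if key in self._radii:
            return self._radii[key], False
        return self.default_radius, True


def assign_radii(pose: MoleculePose, table: RadiusTable | None = None) -> MoleculePose:
    """Return a copy of ``pose`` with every atom's vdW radius set from ``table``.

    Unknown elements fall back to ``table.default_radius``; each fallback is
    logged so a surprising element never silently shapes a volume.  The input
    pose is not modified.  Idempotent.
    """
    table = table or RadiusTable()
    atoms = []
    for atom in pose.atoms:
        radius, fallback = table.lookup(atom.element)
        if fallback:
            logger.warning(
                "element %r of pose %r not in radius table %r; using default %.2f Å",
                atom.element, pose.id, table.name, radius,
            )
        atoms.append(replace(atom, radius=radius))
    return MoleculePose(
        id=pose.id,
        form=pose.form,
        atoms=atoms,
        binding_energy=pose.binding_energy,
        bonds=list(pose.bonds),
    )


def strip_hydrogens(pose: MoleculePose) -> MoleculePose:
    """Copy of ``pose`` without hydrogen atoms (bond list dropped).

    Hydrogens are kept by default everywhere; this switch exists because it
    is not universal whether vendor volume tools count them.
    """
    atoms = [a for a in pose.atoms if a.element.capitalize() != "H"]
    if not atoms:
        raise ValueError(f"pose {pose.id!r} contains only hydrogens")
    return MoleculePose(id=pose.id, form=pose.form, atoms=atoms,
                        binding_energy=pose.binding_energy, bonds=[])


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path, form: str = "monomer") -> list[MoleculePose]:
    """Read a (possibly multi-record) V2000/V3000 SDF into poses.

    Ids come from each record's title line; blank titles become
    ``record_<k>`` (k 1-based in file order) and duplicate ids are
    deduplicated by suffixing.  Coordinates are copied verbatim (Å); radii
    are left unassigned.  Bond blocks are parsed into index pairs but play
    no role in volumes.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    poses: list[MoleculePose] = []
    seen: dict[str, int] = {}
    for k, mol in enumerate(supplier, start=1):
        if mol is None:
            raise ValueError(f"{path}: record {k} could not be parsed (malformed counts/atom block?)")
        if mol.GetNumConformers() == 0 or mol.GetNumAtoms() == 0:
            raise ValueError(f"{path}: record {k} has no atoms/coordinates")
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not name:
            name = f"record_{k}"
        if name in seen:
            seen[name] += 1
            name = f"{name}_{seen[name]}"
        else:
            seen[name] = 1
        conf = mol.GetConformer()
        atoms = [
            AtomRecord(
                element=a.GetSymbol(),
                position=np.array(conf.GetAtomPosition(a.GetIdx())),
                formal_charge=a.GetFormalCharge(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
        poses.append(MoleculePose(id=name, form=form, atoms=atoms, bonds=bonds))
    if not poses:
        raise ValueError(f"{path} contains no SDF records")
    return poses


def write_sdf(poses: Iterable[MoleculePose], path: str | Path) -> None:
    """Write poses as a concatenated multi-record V2000 SDF.

    Coordinates are written at the SDF fixed-point precision (1e-4 Å), the
    round-trip tolerance for everything downstream.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for pose in poses:
            rw = Chem.RWMol()
            for atom in pose.atoms:
                a = Chem.Atom(atom.element)
                a.SetFormalCharge(atom.formal_charge)
                a.SetNoImplicit(True)
                rw.AddAtom(a)
            for i, j in pose.bonds:
                rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
            conf = Chem.Conformer(pose.n_atoms)
            for i, atom in enumerate(pose.atoms):
                conf.SetAtomPosition(i, Point3D(*map(float, atom.position)))
            mol = rw.GetMol()
            mol.AddConformer(conf)
            mol.SetProp("_Name", pose.id)
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> MoleculePose:
    """Read all ATOM/HETATM records of a PDB file as one pose.

    The element comes from columns 77-78 when present, otherwise it is
    inferred from the atom-name field (the standard PDB fallback).  The pose
    id is the filename stem.
    """
    import warnings

    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    atoms = []
    for atom in structure.get_atoms():
        element = (atom.element or "").strip().capitalize()
        if not element:
            raise ValueError(f"{path}: atom {atom.get_name()!r} has no inferable element")
        atoms.append(AtomRecord(element=element, position=np.array(atom.coord, dtype=float)))
    if not atoms:
        raise ValueError(f"{path} contains no ATOM/HETATM coordinate records")
    return MoleculePose(id=path.stem, atoms=atoms)


# ---------------------------------------------------------------------------
# Endpoint tables
# ---------------------------------------------------------------------------

ENDPOINT_COLUMNS = ["id", "form", "binding_energy", "displacement_raw_pct", "inhibition_pct"]


def read_endpoints(path: str | Path):
    """Read a per-compound endpoint table (CSV).

    Columns: ``id, form, binding_energy, displacement_raw_pct,
    inhibition_pct``; blank cells are missing values.
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    missing = [c for c in ENDPOINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"endpoint table {path} lacks columns {missing}")
    return df[ENDPOINT_COLUMNS]


def write_endpoints(df, path: str | Path) -> None:
    import pandas as pd  # noqa: F401

    df = df[ENDPOINT_COLUMNS]
    df.to_csv(path, index=False, lineterminator="\n")
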