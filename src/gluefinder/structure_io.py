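"""Macromolecular structure input/output and partitioning.

Reads PDB/mmCIF entries into a light in-memory model that partitions every
atom into exactly one of {polymer residue, ligand instance, water}, which is
the granularity all downstream interface/pocket rules operate on.  Hydrogens
are dropped on input and alternate locations are reduced to the
highest-occupancy conformer, so every geometric quantity in the package is a
heavy-atom, single-conformer quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueKey",
    "Chain",
    "LigandInstance",
    "StructureModel",
    "StructureFormatError",
    "EmptyStructureError",
    "NotADimerError",
    "read_structure",
    "select_dimer",
    "write_pose",
    "read_pose",
    "write_model_pdb",
]


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed in the named dialect."""


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no atoms at all."""


class NotADimerError(ValueError):
    """Raised when a model does not contain exactly two polymer chains."""

    def __init__(self, n_chains: int):
        self.n_chains = n_chains
        super().__init__(f"expected exactly 2 polymer chains, found {n_chains}")


class ResidueKey(NamedTuple):
    """Hashable identity of a residue: chain id, author number, insertion code."""

    chain_id: str
    number: int
    icode: str


@dataclass
class Atom:
    element: str
    name: str
    coords: np.ndarray  # (3,) in Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str  # chemical component code
    atoms: list[Atom]
    polymer: bool

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.number, self.icode)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


# one-letter codes resolved through gemmi's component table at import cost;
# unknown components map to 'X'
def _one_letter(comp: str) -> str:
    info = gemmi.find_tabulated_residue(comp)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(_one_letter(r.name) for r in self.residues)

    def heavy_coords(self) -> np.ndarray:
        if not self.residues:
            return np.zeros((0, 3))
        return np.concatenate([r.heavy_coords() for r in self.residues])

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LigandInstance:
    code: str
    residue: Residue
    is_metal: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        if not self.residue.atoms:
            raise ValueError("ligand instance must have at least one atom")
        if self.is_metal and self.is_water:
            raise ValueError("ligand cannot be both metal and water")

    @property
    def atoms(self) -> list[Atom]:
        return self.residue.atoms

    def coords(self) -> np.ndarray:
        return self.residue.heavy_coords()

    def center_of_mass(self) -> np.ndarray:
        """Unweighted heavy-atom centroid."""
        return self.coords().mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandInstance":
        res = Residue(
            chain_id=self.residue.chain_id,
            number=self.residue.number,
            icode=self.residue.icode,
            name=self.residue.name,
            atoms=[
                Atom(a.element, a.name, rotation @ a.coords + translation,
                     a.occupancy, a.altloc, a.hetero)
                for a in self.residue.atoms
            ],
            polymer=False,
        )
        return LigandInstance(self.code, res, self.is_metal, self.is_water)


@dataclass
class StructureModel:
    entry_id: str
    chains: list[Chain]
    ligands: list[LigandInstance]
    waters: list[LigandInstance] = field(default_factory=list)
    assembly_id: str | None = None
    provenance: Literal["experimental", "predicted"] = "experimental"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in model {self.entry_id}: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def polymer_coords(self) -> np.ndarray:
        arrays = [c.heavy_coords() for c in self.chains if len(c)]
        if not arrays:
            return np.zeros((0, 3))
        return np.concatenate(arrays)

    def all_heavy_coords(self) -> np.ndarray:
        parts = [self.polymer_coords()]
        parts += [l.coords() for l in self.ligands]
        parts += [w.coords() for w in self.waters]
        parts = [p for p in parts if len(p)]
        return np.concatenate(parts) if parts else np.zeros((0, 3))


_METAL_CACHE: dict[str, bool] = {}


def _is_metal_element(symbol: str) -> bool:
    sym = symbol.capitalize()
    if sym not in _METAL_CACHE:
        _METAL_CACHE[sym] = gemmi.Element(sym).is_metal
    return _METAL_CACHE[sym]


def _dedupe_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for at in res:
        prev = by_name.get(at.name)
        if prev is None:
            by_name[at.name] = at
        elif (at.occ, -ord(at.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
            # higher occupancy wins; on a tie the lexicographically earlier
            # altloc id wins (negated ordinal)
            by_name[at.name] = at
    return list(by_name.values())


def _convert_residue(chain_id: str, res: gemmi.Residue, polymer: bool) -> Residue | None:
    atoms = []
    for at in _dedupe_altlocs(res):
        if at.element.is_hydrogen:
            continue
        atoms.append(
            Atom(
                element=at.element.name,
                name=at.name,
                coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                occupancy=min(max(at.occ, 0.0), 1.0),
                altloc=at.altloc or "",
                hetero=at.element.name != "" and res.het_flag == "H",
            )
        )
    if not atoms:
        return None
    return Residue(
        chain_id=chain_id,
        number=res.seqid.num,
        icode=res.seqid.icode.strip() if res.seqid.icode else "",
        name=res.name.strip(),
        atoms=atoms,
        polymer=polymer,
    )


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    assembly_policy: Literal["asymmetric_unit", "assembly_1", "auto"] = "auto",
    provenance: Literal["experimental", "predicted"] = "experimental",
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``assembly_policy`` selects the coordinate frame: ``assembly_1`` expands
    the first depositor-defined biological assembly, ``asymmetric_unit`` keeps
    the deposited coordinates, and ``auto`` (default) uses assembly 1 when the
    file defines one and the asymmetric unit otherwise.

    Hydrogens are discarded; only the highest-occupancy alternate conformer is
    kept; selenomethionine (and other polymer-linked modified residues) stay
    in the polymer, never in the ligand list; waters are flagged separately.
    """
    path = Path(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    st.setup_entities()

    model0 = st[0] if len(st) else None
    if model0 is None or model0.count_atom_sites() == 0:
        raise EmptyStructureError(f"{path} contains no atoms")

    use_assembly = (
        assembly_policy == "assembly_1"
        or (assembly_policy == "auto" and len(st.assemblies) > 0)
    )
    assembly_id = None
    if use_assembly and len(st.assemblies) > 0:
        model0 = gemmi.make_assembly(
            st.assemblies[0], model0, gemmi.HowToNameCopiedChain.AddNumber
        )
        assembly_id = st.assemblies[0].name
    elif assembly_policy == "assembly_1":
        # requested explicitly but the file defines none: fall back to the AU
        assembly_id = None

    chains: list[Chain] = []
    ligands: list[LigandInstance] = []
    waters: list[LigandInstance] = []
    for ch in model0:
        poly_residues: list[Residue] = []
        for res in ch:
            is_water = res.is_water()
            info = gemmi.find_tabulated_residue(res.name)
            # polymer membership from gemmi entity typing, with a chemical
            # fallback for files lacking entity records
            in_polymer = res.entity_type == gemmi.EntityType.Polymer or (
                res.entity_type == gemmi.EntityType.Unknown
                and info is not None
                and (info.is_amino_acid() or info.is_nucleic_acid())
            )
            converted = _convert_residue(ch.name, res, in_polymer)
            if converted is None:
                continue
            if in_polymer:
                poly_residues.append(converted)
            elif is_water:
                waters.append(LigandInstance(res.name, converted, is_water=True))
            else:
                metal = len(converted.atoms) == 1 and _is_metal_element(
                    converted.atoms[0].element
                )
                ligands.append(LigandInstance(res.name, converted, is_metal=metal))
        if poly_residues:
            chains.append(Chain(ch.name, poly_residues))

    return StructureModel(
        entry_id=st.name or path.stem,
        chains=chains,
        ligands=ligands,
        waters=waters,
        assembly_id=assembly_id,
        provenance=provenance,
    )


def select_dimer(model: StructureModel) -> tuple[Chain, Chain]:
    """Return the two polymer chains of a dimer, in input order."""
    if len(model.chains) != 2:
        raise NotADimerError(len(model.chains))
    return model.chains[0], model.chains[1]


def write_pose(
    pose: LigandInstance, path: str | Path, format: Literal["pdb", "sdf"] = "pdb"
) -> Path:
    """Write a ligand pose to PDB (HETATM records) or SDF (V2000, no bonds)."""
    path = Path(path)
    if not pose.atoms:
        raise ValueError("empty pose")
    if format == "pdb":
        st = gemmi.Structure()
        st.name = pose.code
        model = gemmi.Model("1")
        ch = gemmi.Chain(pose.residue.chain_id or "X")
        res = gemmi.Residue()
        res.name = pose.code
        res.seqid = gemmi.SeqId(pose.residue.number or 1, " ")
        res.het_flag = "H"
        for a in pose.atoms:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coords)
            at.occ = a.occupancy
            res.add_atom(at)
        ch.add_residue(res)
        model.add_chain(ch)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))
    elif format == "sdf":
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        mol = Chem.RWMol()
        conf = Chem.Conformer(len(pose.atoms))
        for i, a in enumerate(pose.atoms):
            mol.AddAtom(Chem.Atom(a.element.capitalize()))
            conf.SetAtomPosition(i, Point3D(*map(float, a.coords)))
        mol.AddConformer(conf)
        out = mol.GetMol()
        out.SetProp("_Name", pose.code)
        with Chem.SDWriter(str(path)) as writer:
            writer.write(out)
    else:
        raise ValueError(f"unsupported pose format: {format}")
    return path


def read_pose(path: str | Path, format: Literal["pdb", "sdf"] = "pdb") -> LigandInstance:
    """Read back a ligand pose written by :func:`write_pose`."""
    path = Path(path)
    if format == "pdb":
        model = read_structure(path, format="pdb", assembly_policy="asymmetric_unit")
        pool = model.ligands + model.waters
        if not pool:
            # single amino-acid-like components parse as polymer
            for ch in model.chains:
                for res in ch.residues:
                    return LigandInstance(res.name, res)
            raise EmptyStructureError(f"no ligand found in {path}")
        return pool[0]
    if format == "sdf":
        from rdkit import Chem

        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mol = next(iter(supplier), None)
        if mol is None:
            raise StructureFormatError(f"cannot parse SDF {path}")
        conf = mol.GetConformer()
        atoms = [
            Atom(
                element=mol.GetAtomWithIdx(i).GetSymbol(),
                name=f"{mol.GetAtomWithIdx(i).GetSymbol()}{i + 1}",
                coords=np.array(list(conf.GetAtomPosition(i))),
                hetero=True,
            )
            for i in range(mol.GetNumAtoms())
        ]
        code = mol.GetProp("_Name") if mol.HasProp("_Name") else "LIG"
        res = Residue("X", 1, "", code, atoms, polymer=False)
        return LigandInstance(code, res)
    raise ValueError(f"unsupported pose format: {format}")


def write_model_pdb(model: StructureModel, path: str | Path) -> Path:
    """Serialize a :class:`StructureModel` (polymer + ligands + waters) to PDB."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = model.entry_id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gc.add_residue(_to_gemmi_residue(res, het=False))
        gm.add_chain(gc)
    het_by_chain: dict[str, list[Residue]] = {}
    for lig in list(model.ligands) + list(model.waters):
        het_by_chain.setdefault(lig.residue.chain_id or "L", []).append(lig.residue)
    for cid, residues in het_by_chain.items():
        existing = None
        for gch in gm:
            if gch.name == cid:
                existing = gch
                break
        gc = existing if existing is not None else gemmi.Chain(cid)
        for res in residues:
            gc.add_residue(_to_gemmi_residue(res, het=True))
        if existing is None:
            gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
    return path


def _to_gemmi_residue(res: Residue, het: bool) -> gemmi.Residue:
    gr = gemmi.Residue()
    gr.name = res.name
    gr.seqid = gemmi.SeqId(res.number, res.icode or " ")
    gr.het_flag = "H" if het else "A"
    for a in res.atoms:
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        at.occ = a.occupancy
        gr.add_atom(at)
    return gr
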