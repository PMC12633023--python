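"""Deterministic synthetic structures and chemistry with planted ground truth.

Every generator here is a pure function of its arguments and a mandatory
seed.  The geometry is idealized -- Calpha-only traces with 3.8 A spacing
for open dimers, and dense atom shells for enclosed cavities -- because all
the rules under test (interface contacts, ligand contacts, cavity volumes,
pocket alignment) are residue-level distance rules that do not require
full-atom realism.

Planted quantities (contact counts, ligand per-chain contacts, cavity
volumes, homolog residue mappings, rigid transforms) are returned as
:class:`FixtureTruth` so tests can verify the production code against
construction-time ground truth and independent brute-force oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .chem_cluster import Fingerprint
from .pocket_align import PocketStructure, RigidTransform
from .structure_io import (
    Atom,
    Chain,
    LigandInstance,
    Residue,
    ResidueKey,
    StructureModel,
)

__all__ = [
    "FixtureError",
    "FixtureTruth",
    "PlantedLigand",
    "DimerSpec",
    "make_dimer_fixture",
    "make_cavity_fixture",
    "make_glue_complex",
    "make_homolog",
    "make_random_pocket",
    "perturb_pocket",
    "make_fingerprint_blobs",
    "random_transform",
    "AMINO_ACIDS",
]

AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

CA_SPACING = 3.8  # idealized Calpha-Calpha distance, A
CONTACT_Y = 4.0  # planted inter-chain contact distance, A
FAR_Y = 20.0  # separation of non-interface residues, A
LIGAND_Z = 3.5  # height of planted ligand atoms above their residue, A
WALL_OFFSET = 1.7  # carbon vdW radius: wall planes sit exactly one radius
#                    outside the nominal void, so the sphere-free region is
#                    the requested box


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


@dataclass
class PlantedLigand:
    code: str = "LIG"
    contacts_a: int = 5
    contacts_b: int = 5
    element: str = "C"


@dataclass
class DimerSpec:
    residues_per_chain: int = 30
    contacts: int = 6  # planted inter-chain contacting residue pairs
    ligands: list[PlantedLigand] = field(default_factory=list)
    n_waters: int = 0
    seed: int = 42


@dataclass
class FixtureTruth:
    """Construction-time ground truth accompanying a fixture."""

    interface_a: frozenset[ResidueKey] = frozenset()
    interface_b: frozenset[ResidueKey] = frozenset()
    ligand_contacts: dict[str, tuple[int, int]] = field(default_factory=dict)
    volume: float | None = None
    box_dims: tuple[float, float, float] | None = None
    center: np.ndarray | None = None
    native_ligand: LigandInstance | None = None
    residue_mapping: dict[ResidueKey, ResidueKey] = field(default_factory=dict)
    index_mapping: list[tuple[int, int]] = field(default_factory=list)
    transform: RigidTransform | None = None
    mutation_rate: float | None = None
    labels: list[int] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, n: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=n)]


def _ca_residue(chain_id: str, number: int, name: str, xyz) -> Residue:
    return Residue(
        chain_id=chain_id,
        number=number,
        icode="",
        name=name,
        atoms=[Atom("C", "CA", np.asarray(xyz, dtype=float))],
        polymer=True,
    )


def random_transform(rng: np.random.Generator, max_translation: float = 20.0) -> RigidTransform:
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(rot, trans)


# ---------------------------------------------------------------------------
# open dimer with controllable contacts


def make_dimer_fixture(spec: DimerSpec) -> tuple[StructureModel, FixtureTruth]:
    """Two Calpha traces with exactly ``spec.contacts`` inter-chain residue
    contacts at 4.0 A and ligands with exact per-chain contact counts.

    Chain A runs along x at y=0.  The first ``contacts`` residues of chain B
    sit at y=4.0 (in contact with their A counterparts); the rest sit at
    y=20.  A planted ligand atom hovers 3.5 A above exactly one residue, so
    per-chain contacted-residue counts equal the number of planted atoms.
    """
    n = spec.residues_per_chain
    k = spec.contacts
    rng = np.random.default_rng(spec.seed)
    if k > n:
        raise FixtureError(f"cannot plant {k} contacts with {n} residues per chain")
    need_a = sum(l.contacts_a for l in spec.ligands)
    need_b = sum(l.contacts_b for l in spec.ligands)
    if need_a > n or need_b > n:
        raise FixtureError("ligand contact demands exceed residues per chain")

    names_a = _random_sequence(rng, n)
    names_b = _random_sequence(rng, n)
    chain_a = Chain(
        "A",
        [_ca_residue("A", i + 1, names_a[i], (CA_SPACING * i, 0.0, 0.0)) for i in range(n)],
    )
    res_b = []
    for j in range(n):
        y = CONTACT_Y if j < k else FAR_Y
        res_b.append(_ca_residue("B", j + 1, names_b[j], (CA_SPACING * j, y, 0.0)))
    chain_b = Chain("B", res_b)

    ligands = []
    truth_contacts: dict[str, tuple[int, int]] = {}
    next_a = 0
    next_b = 0
    for li, lspec in enumerate(spec.ligands):
        atoms = []
        for i in range(next_a, next_a + lspec.contacts_a):
            atoms.append(
                Atom(lspec.element, f"C{len(atoms) + 1}",
                     (CA_SPACING * i, 0.0, LIGAND_Z), hetero=True)
            )
        for j in range(next_b, next_b + lspec.contacts_b):
            y = CONTACT_Y if j < k else FAR_Y
            atoms.append(
                Atom(lspec.element, f"C{len(atoms) + 1}",
                     (CA_SPACING * j, y, LIGAND_Z), hetero=True)
            )
        next_a += lspec.contacts_a
        next_b += lspec.contacts_b
        if not atoms:  # non-binder: single far-away atom
            atoms = [Atom(lspec.element, "C1", (0.0, 60.0, 0.0), hetero=True)]
        res = Residue("L", 100 + li, "", lspec.code, atoms, polymer=False)
        ligands.append(LigandInstance(lspec.code, res))
        truth_contacts[lspec.code] = (lspec.contacts_a, lspec.contacts_b)

    waters = []
    for w in range(spec.n_waters):
        res = Residue(
            "W", 200 + w, "", "HOH",
            [Atom("O", "O", (-15.0 - 5.0 * w, -15.0, 0.0), hetero=True)],
            polymer=False,
        )
        waters.append(LigandInstance("HOH", res, is_water=True))

    model = StructureModel(
        entry_id=f"DIMER{spec.seed}",
        chains=[chain_a, chain_b],
        ligands=ligands,
        waters=waters,
    )
    truth = FixtureTruth(
        interface_a=frozenset(ResidueKey("A", i + 1, "") for i in range(k)),
        interface_b=frozenset(ResidueKey("B", j + 1, "") for j in range(k)),
        ligand_contacts=truth_contacts,
    )
    return model, truth


# ---------------------------------------------------------------------------
# enclosed cavities


def _box_shell_atoms(
    dims: tuple[float, float, float],
    thickness: int,
    lattice: float = 1.0,
) -> np.ndarray:
    """Atom positions of a closed shell around the void [0,Lx]x[0,Ly]x[0,Lz].

    Wall planes sit one carbon vdW radius outside each face, so the
    sphere-free interior equals the requested box exactly.
    """
    lx, ly, lz = dims
    points: list[tuple[float, float, float]] = []
    for layer in range(thickness):
        off = WALL_OFFSET + layer * lattice
        xs = np.arange(-lattice, lx + lattice + 1e-9, lattice)
        ys = np.arange(-lattice, ly + lattice + 1e-9, lattice)
        zs = np.arange(-lattice, lz + lattice + 1e-9, lattice)
        for y in ys:
            for z in zs:
                points.append((-off, y, z))
                points.append((lx + off, y, z))
        for x in xs:
            for z in zs:
                points.append((x, -off, z))
                points.append((x, ly + off, z))
        for x in xs:
            for y in ys:
                points.append((x, y, -off))
                points.append((x, y, lz + off))
    return np.unique(np.round(np.asarray(points, dtype=float), 6), axis=0)


def make_cavity_fixture(
    box_dims: tuple[float, float, float] = (5.0, 5.0, 5.0),
    shell_thickness: int = 1,
    seed: int = 42,
    jitter: float = 0.0,
) -> tuple[StructureModel, FixtureTruth]:
    """A single-chain atom shell enclosing an empty box of known volume."""
    if min(box_dims) < 1.0:
        raise FixtureError("box dimensions must be at least the grid spacing")
    rng = np.random.default_rng(seed)
    pts = _box_shell_atoms(box_dims, shell_thickness)
    if jitter > 0:
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    names = _random_sequence(rng, len(pts))
    residues = [
        _ca_residue("A", i + 1, names[i], p) for i, p in enumerate(pts)
    ]
    model = StructureModel(
        entry_id=f"CAV{seed}", chains=[Chain("A", residues)], ligands=[]
    )
    truth = FixtureTruth(
        volume=float(np.prod(box_dims)),
        box_dims=tuple(float(d) for d in box_dims),
        center=np.asarray(box_dims, dtype=float) / 2.0,
    )
    return model, truth


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistant unit vectors (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def make_glue_complex(
    mean_radius: float = 4.5,
    ligand_code: str = "LIG",
    seed: int = 42,
    jitter: float = 0.2,
    lumpiness: float = 0.8,
    lining_spacing: float = 2.6,
    tail_residues: int = 80,
    metal: bool = False,
    entry_id: str | None = None,
) -> tuple[StructureModel, FixtureTruth]:
    """A two-chain cage dimer with a ligand planted in the interface cavity.

    The cavity is an irregular ellipsoid (seeded axes and a low-order lumpy
    radial profile) lined by sparse Calpha pseudo-residues at roughly
    protein-like spacing, enclosed by a dense outer blocker shell that is
    collapsed into one many-atom residue per chain.  The sparse lining
    gives each fixture an individual, alignable residue arrangement (dense
    regular walls would make every fixture pocket near-identical at the
    alignment score's distance scale, and indistinguishable from a planted
    homolog), while the blockers guarantee grid enclosure without flooding
    the pocket lining.  The cage is split along z into chains A (lower) and
    B (upper), so the seam provides inter-chain contacts and the cavity is
    interface-adjacent by construction.  Each chain also carries a compact
    lattice of ``tail_residues`` sequence-padding residues far from the
    cavity -- real chains are much longer than their pocket lining, and
    template sequence-identity filters behave very differently on 25-mers
    than on realistic chain lengths.  The metal variant plants a single Zn
    at the seam with a 10-residue coordination ring (5 per chain).
    """
    rng = np.random.default_rng(seed)
    center = np.zeros(3)
    # seeded ellipsoidal axes: unrelated fixtures differ in gross cavity shape
    axes = mean_radius * rng.uniform(0.85, 1.5, size=3)
    waves = []
    for _ in range(4):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        waves.append((axis, rng.uniform(-1.0, 1.0)))

    def lumpy_surface(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        radial = np.zeros(len(dirs))
        for axis, coef in waves:
            radial += coef * (dirs @ axis)
        peak = max(np.abs(radial).max(), 1e-9)
        radial = radial * (lumpiness / peak)
        surface = dirs * axes
        normals = surface / np.linalg.norm(surface, axis=1, keepdims=True)
        return surface + normals * radial[:, None], normals

    orient = Rotation.random(random_state=rng)
    mean_extent = float(np.mean(axes))
    # sparse lining residues at protein-like spacing
    n_lining = max(24, int(4.0 * np.pi * mean_extent**2 / lining_spacing**2))
    dirs_l = orient.apply(_fibonacci_sphere(n_lining))
    base_l, normals_l = lumpy_surface(dirs_l)
    lining_pts = base_l + normals_l * WALL_OFFSET
    if jitter > 0:
        lining_pts = lining_pts + rng.normal(0.0, jitter, size=lining_pts.shape)
    # dense blocker shell, outside lining reach of the cavity cells
    n_block = max(200, int(4.0 * np.pi * (mean_extent + 3.9) ** 2 / 1.2**2))
    dirs_b = orient.apply(_fibonacci_sphere(n_block))
    base_b, normals_b = lumpy_surface(dirs_b)
    blockers = np.concatenate(
        [base_b + normals_b * (WALL_OFFSET + 2.2), base_b + normals_b * (WALL_OFFSET + 3.2)]
    )

    zc = 0.0
    order = np.lexsort((lining_pts[:, 0], lining_pts[:, 1], lining_pts[:, 2]))
    lining_pts = lining_pts[order]
    lining_normals = normals_l[order]

    metal_ring: list[np.ndarray] = []
    metal_pos = None
    if metal:
        # a single atom only reaches >= 5 residues of both chains with an
        # explicit coordination ring straddling the seam
        metal_pos = np.array([float(min(axes)) - lumpiness - 1.5, 0.0, 0.0])
        for k in range(10):
            ang = 2.0 * np.pi * (k + 0.5) / 10.0  # 5 ring members per chain
            metal_ring.append(
                metal_pos + 2.5 * np.array([0.0, np.cos(ang), np.sin(ang)])
            )

    extent = float(np.max(np.abs(blockers))) + 20.0

    def _tail_points(sign: float) -> np.ndarray:
        """Compact 3.8 A lattice blob far from the cage along +-x."""
        side = int(np.ceil(tail_residues ** (1.0 / 3.0)))
        axis = np.arange(side) * 3.8
        grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
        pts = grid.reshape(-1, 3)[:tail_residues]
        return pts + np.array([sign * extent, 0.0, sign * 5.0])

    def chain_residues(chain_id: str, lower: bool) -> list[Residue]:
        sel = lining_pts[:, 2] < zc if lower else lining_pts[:, 2] >= zc
        pts = list(lining_pts[sel])
        pts += [p for p in metal_ring if (p[2] < zc) == lower]
        pts += list(_tail_points(-1.0 if lower else 1.0))
        names = _random_sequence(rng, len(pts))
        residues = [
            _ca_residue(chain_id, i + 1, names[i], p) for i, p in enumerate(pts)
        ]
        bsel = blockers[:, 2] < zc if lower else blockers[:, 2] >= zc
        blocker_atoms = [
            Atom("C", f"X{i + 1}", p) for i, p in enumerate(blockers[bsel])
        ]
        residues.append(
            Residue(chain_id, 900, "", "UNK", blocker_atoms, polymer=True)
        )
        return residues

    res_a = chain_residues("A", lower=True)
    res_b = chain_residues("B", lower=False)

    if metal:
        atoms = [Atom("Zn", "ZN", metal_pos, hetero=True)]
        code = ligand_code if ligand_code != "LIG" else "ZN"
        res = Residue("L", 500, "", code, atoms, polymer=False)
        ligand = LigandInstance(code, res, is_metal=True)
    else:
        # anchor 6 ligand atoms 3.0 A inside cavity-surface residues of each
        # chain, so the ligand contacts >= 6 distinct residues per chain and
        # is interface-adjacent by construction
        atoms = []
        for lower in (True, False):
            idx = np.nonzero(lining_pts[:, 2] < zc if lower else lining_pts[:, 2] >= zc)[0]
            stride = max(1, len(idx) // 6)
            for i in idx[::stride][:6]:
                atoms.append(
                    Atom(
                        "C",
                        f"C{len(atoms) + 1}",
                        lining_pts[i] - 3.0 * lining_normals[i],
                        hetero=True,
                    )
                )
        res = Residue("L", 500, "", ligand_code, atoms, polymer=False)
        ligand = LigandInstance(ligand_code, res)

    model = StructureModel(
        entry_id=entry_id or f"GLUE{seed}",
        chains=[Chain("A", res_a), Chain("B", res_b)],
        ligands=[ligand],
    )
    truth = FixtureTruth(
        volume=float(4.0 / 3.0 * np.pi * np.prod(axes)),  # nominal, pre-erosion
        center=center,
        native_ligand=ligand,
    )
    return model, truth


@dataclass
class BenchmarkFixture:
    """Targets with planted native ligands plus a template model stream."""

    targets: list[tuple[StructureModel, FixtureTruth]]
    template_models: list[StructureModel]  # remote homologs, one per target
    decoy_models: list[StructureModel]


def make_benchmark_set(
    n_targets: int = 10,
    seed: int = 42,
    mutation_rate: float = 0.8,
    noise_sigma: float = 0.5,
    n_decoys: int = 5,
) -> BenchmarkFixture:
    """Targets (cage dimers with native interface ligands) and a template
    stream holding one remote homolog per target plus unrelated decoys.

    The default mutation rate leaves 20% of positions untouched; the
    *aligned* homolog-target sequence identity measures ~0.25 (global
    alignment with gaps recovers slightly more matches than the gapless
    planted fraction), emulating remote-homology template transfer.
    """
    rng = np.random.default_rng(seed)
    targets = []
    template_models = []
    for i in range(n_targets):
        tgt, truth = make_glue_complex(
            seed=int(rng.integers(2**31)),
            ligand_code=f"L{i:02d}",
            entry_id=f"TGT{i:02d}",
        )
        hom, _ = make_homolog(
            tgt,
            mutation_rate=mutation_rate,
            noise_sigma=noise_sigma,
            transform=random_transform(rng),
            seed=int(rng.integers(2**31)),
            entry_id=f"TPL{i:02d}",
        )
        targets.append((tgt, truth))
        template_models.append(hom)
    decoys = []
    for j in range(n_decoys):
        dec, _ = make_glue_complex(
            seed=int(rng.integers(2**31)),
            ligand_code=f"D{j:02d}",
            entry_id=f"DEC{j:02d}",
        )
        decoys.append(dec)
    return BenchmarkFixture(targets, template_models, decoys)


# ---------------------------------------------------------------------------
# homologs


def make_homolog(
    model: StructureModel,
    mutation_rate: float = 0.0,
    noise_sigma: float = 0.0,
    deletion_rate: float = 0.0,
    transform: RigidTransform | None = None,
    seed: int = 42,
    entry_id: str | None = None,
) -> tuple[StructureModel, FixtureTruth]:
    """Mutate, delete, perturb and rigidly move a model; return the mapping.

    Mutation and deletion counts are deterministic (``round(rate * n)`` per
    chain, positions seeded), so the planted sequence identity is exact up
    to rounding.  Gaussian noise applies to polymer atoms only; the rigid
    transform applies to polymer and ligands alike.
    """
    for rate in (mutation_rate, deletion_rate):
        if not (0.0 <= rate <= 1.0):
            raise FixtureError(f"rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    transform = transform if transform is not None else RigidTransform.identity()
    mapping: dict[ResidueKey, ResidueKey] = {}
    new_chains = []
    for chain in model.chains:
        n = len(chain.residues)
        n_del = round(deletion_rate * n)
        n_mut = round(mutation_rate * (n - n_del))
        deleted = set(rng.choice(n, size=n_del, replace=False)) if n_del else set()
        kept = [i for i in range(n) if i not in deleted]
        mutated = (
            set(np.asarray(kept)[rng.choice(len(kept), size=n_mut, replace=False)])
            if n_mut
            else set()
        )
        new_residues = []
        for new_idx, old_idx in enumerate(kept):
            old = chain.residues[old_idx]
            name = old.name
            if old_idx in mutated:
                choices = [a for a in AMINO_ACIDS if a != name]
                name = choices[int(rng.integers(len(choices)))]
            atoms = []
            for a in old.atoms:
                xyz = a.coords + (
                    rng.normal(0.0, noise_sigma, size=3) if noise_sigma > 0 else 0.0
                )
                atoms.append(Atom(a.element, a.name, transform.apply(xyz),
                                  a.occupancy, a.altloc, a.hetero))
            new_res = Residue(chain.chain_id, new_idx + 1, "", name, atoms, True)
            new_residues.append(new_res)
            mapping[old.key] = new_res.key
        new_chains.append(Chain(chain.chain_id, new_residues))

    new_ligands = [
        lig.transformed(transform.rotation, transform.translation)
        for lig in model.ligands
    ]
    out = StructureModel(
        entry_id=entry_id or f"{model.entry_id}-H{seed}",
        chains=new_chains,
        ligands=new_ligands,
        waters=list(model.waters),
        provenance=model.provenance,
    )
    truth = FixtureTruth(
        residue_mapping=mapping,
        transform=transform,
        mutation_rate=mutation_rate,
    )
    return out, truth


# ---------------------------------------------------------------------------
# pocket-level generators (fast paths for alignment statistics)


_ONE = "ACDEFGHIKLMNPQRSTVWY"


def make_random_pocket(
    n_residues: int = 25, seed: int = 42, min_separation: float = 3.2
) -> PocketStructure:
    """A compact random Calpha cloud posing as a pocket lining."""
    rng = np.random.default_rng(seed)
    radius = 2.2 * n_residues ** (1.0 / 3.0)
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n_residues:
        attempts += 1
        if attempts > 200 * n_residues:
            raise FixtureError("cannot pack the requested pocket; lower min_separation")
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) > radius:
            continue
        if points and np.min(np.linalg.norm(np.asarray(points) - p, axis=1)) < min_separation:
            continue
        points.append(p)
    seq = "".join(_ONE[i] for i in rng.integers(0, len(_ONE), size=n_residues))
    keys = [ResidueKey("P", i + 1, "") for i in range(n_residues)]
    return PocketStructure(keys, np.asarray(points), seq)


def perturb_pocket(
    pocket: PocketStructure,
    mutation_rate: float = 0.0,
    noise_sigma: float = 0.0,
    deletion_rate: float = 0.0,
    transform: RigidTransform | None = None,
    seed: int = 42,
) -> tuple[PocketStructure, FixtureTruth]:
    """Homolog of a pocket structure with a known index mapping."""
    rng = np.random.default_rng(seed)
    transform = transform if transform is not None else random_transform(rng)
    n = len(pocket)
    n_del = round(deletion_rate * n)
    deleted = set(rng.choice(n, size=n_del, replace=False)) if n_del else set()
    kept = [i for i in range(n) if i not in deleted]
    n_mut = round(mutation_rate * len(kept))
    mutated = (
        set(np.asarray(kept)[rng.choice(len(kept), size=n_mut, replace=False)])
        if n_mut
        else set()
    )
    coords = []
    seq = []
    mapping = []
    for new_idx, old_idx in enumerate(kept):
        xyz = pocket.coords[old_idx] + (
            rng.normal(0.0, noise_sigma, size=3) if noise_sigma > 0 else 0.0
        )
        coords.append(transform.apply(xyz))
        letter = pocket.sequence[old_idx]
        if old_idx in mutated:
            options = [c for c in _ONE if c != letter]
            letter = options[int(rng.integers(len(options)))]
        seq.append(letter)
        mapping.append((old_idx, new_idx))
    keys = [ResidueKey("P", i + 1, "") for i in range(len(kept))]
    out = PocketStructure(keys, np.asarray(coords), "".join(seq))
    truth = FixtureTruth(
        index_mapping=mapping, transform=transform, mutation_rate=mutation_rate
    )
    return out, truth


# ---------------------------------------------------------------------------
# labeled calibration set


def make_calibration_set(
    n_positive: int = 400,
    n_negative: int = 400,
    seed: int = 42,
    n_pockets: int = 80,
    null_pairs: int = 800,
):
    """Labeled (score, p-value) features for precision calibration.

    Candidate matches are alignments of a pocket against a perturbed
    homolog of itself (coordinate noise 0.3-0.9 A scaled with the pocket's
    d0, mutations 10-80%, deletions up to 15% -- the remote-homology regime
    the screen operates in) and alignments of unrelated random pockets.  The label is
    outcome-based, mirroring what binding precision estimates: a match is
    positive when transferring a pose through the alignment lands within
    2 A of the planted ground truth (unrelated pairs have no correct pose
    and are always negative).  Returns ``(scores, p_values, labels,
    null_model)`` with the null model fitted on the same pocket population.
    """
    from .pocket_align import _d0, align_pockets, fit_null_model

    rng = np.random.default_rng(seed)
    pockets = [
        make_random_pocket(int(n), seed=int(rng.integers(2**31)))
        for n in rng.integers(15, 45, size=n_pockets)
    ]
    null = fit_null_model(pockets, n_pairs=null_pairs, seed=int(rng.integers(2**31)))
    scores: list[float] = []
    ps: list[float] = []
    labels: list[int] = []
    for _ in range(n_positive):
        q = pockets[int(rng.integers(len(pockets)))]
        planted = random_transform(rng)
        size_scale = _d0(len(q)) / _d0(30)
        t, _ = perturb_pocket(
            q,
            mutation_rate=float(rng.uniform(0.1, 0.8)),
            noise_sigma=float(rng.uniform(0.3, 0.9)) * size_scale,
            deletion_rate=float(rng.uniform(0.0, 0.15)),
            transform=planted,
            seed=int(rng.integers(2**31)),
        )
        aln = align_pockets(q, t)
        # outcome label: does pose transfer through the alignment land on
        # the planted location (a pseudo-ligand at the pocket centroid)?
        probe = q.coords.mean(axis=0)
        transferred = aln.transform.apply(planted.apply(probe))
        err = float(np.linalg.norm(transferred - probe))
        scores.append(aln.score)
        ps.append(null.p_value(aln.score, aln.aligned_length))
        labels.append(int(err <= 2.0))
    for _ in range(n_negative):
        i = int(rng.integers(len(pockets)))
        j = int(rng.integers(len(pockets) - 1))
        if j >= i:
            j += 1
        aln = align_pockets(pockets[i], pockets[j])
        scores.append(aln.score)
        ps.append(null.p_value(aln.score, aln.aligned_length))
        labels.append(0)
    return np.asarray(scores), np.asarray(ps), np.asarray(labels), null


# ---------------------------------------------------------------------------
# fingerprint blobs


def make_fingerprint_blobs(
    n_blobs: int = 3,
    members_per_blob: int = 5,
    within_similarity: float = 0.9,
    between_similarity: float = 0.3,
    seed: int = 42,
    n_bits: int = 2048,
    core_bits: int = 120,
) -> tuple[list[Fingerprint], FixtureTruth]:
    """Bit vectors with pairwise Tanimoto >= within inside blobs and
    <= between across blobs (cross-blob bit sets are disjoint, T = 0).

    Each member carries a shared blob core of ``core_bits`` bits plus
    ``u = floor(core*(1-w)/(2w))`` private bits, giving within-blob
    similarity core/(core+2u) >= w exactly.
    """
    if not (0.0 < within_similarity <= 1.0) or not (0.0 <= between_similarity < 1.0):
        raise FixtureError("similarity targets must lie in (0,1]/[0,1)")
    if within_similarity <= between_similarity:
        raise FixtureError("within-similarity must exceed between-similarity")
    u = math.floor(core_bits * (1.0 - within_similarity) / (2.0 * within_similarity))
    per_blob = core_bits + members_per_blob * u
    if n_blobs * per_blob > n_bits:
        raise FixtureError(
            f"need {n_blobs * per_blob} bits for disjoint blobs, have {n_bits}"
        )
    rng = np.random.default_rng(seed)
    all_bits = rng.permutation(n_bits)
    fps: list[Fingerprint] = []
    labels: list[int] = []
    cursor = 0
    for b in range(n_blobs):
        core = all_bits[cursor:cursor + core_bits]
        cursor += core_bits
        for m in range(members_per_blob):
            private = all_bits[cursor:cursor + u]
            cursor += u
            bits = np.zeros(n_bits, dtype=bool)
            bits[core] = True
            bits[private] = True
            fps.append(
                Fingerprint(bits, n_bits, "synthetic-blob", f"B{b}M{m:02d}")
            )
            labels.append(b)
    return fps, FixtureTruth(labels=labels)
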