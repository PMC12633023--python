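"""Grid-based cavity detection and pocket filtering.

Pockets are found with a LIGSITE-style protein-solvent-protein scan: the
structure is rasterized onto a cubic grid using per-element van der Waals
radii, and an empty cell is a cavity cell when protein occurs on *both*
sides along at least ``enclosure_min`` of seven scan directions (the three
axes plus the four body diagonals).  Maximal 6-connected sets of cavity
cells form pockets.  The screening library keeps pockets with at least 10
lining residues and 100 A^3 of volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .interface_miner import InterfaceSummary
from .structure_io import ResidueKey, StructureModel

__all__ = [
    "Grid",
    "Pocket",
    "VDW_RADII",
    "DEFAULT_SPACING",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_ENCLOSURE_MIN",
    "DEFAULT_MIN_LINING_RESIDUES",
    "DEFAULT_MIN_VOLUME",
    "detect_pockets",
    "passes_library_filter",
    "is_interface_adjacent",
]

# Bondi-style van der Waals radii (Angstrom); fallback 1.7 for unlisted elements
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "FE": 1.60, "ZN": 1.39, "MG": 1.73, "CA": 1.70, "NA": 2.27, "K": 2.75,
    "MN": 1.60, "CU": 1.40, "NI": 1.63, "CO": 1.60, "CD": 1.58,
}
_DEFAULT_RADIUS = 1.70

DEFAULT_SPACING = 1.0  # Angstrom
DEFAULT_PROBE_RADIUS = 1.4  # Angstrom, water probe
DEFAULT_ENCLOSURE_MIN = 5  # of 7 scan direction pairs
DEFAULT_MIN_LINING_RESIDUES = 10
DEFAULT_MIN_VOLUME = 100.0  # Angstrom^3

# labels
SOLVENT, PROTEIN, CAVITY = 0, 1, 2

_SCAN_DIRECTIONS = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass
class Grid:
    origin: np.ndarray  # (3,) corner of cell (0,0,0)
    spacing: float
    labels: np.ndarray  # (nx, ny, nz) uint8 in {SOLVENT, PROTEIN, CAVITY}

    def cell_centers(self, cells: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(cells, dtype=float) + 0.5) * self.spacing


@dataclass
class Pocket:
    pocket_id: int
    cells: np.ndarray  # (n, 3) integer grid indices
    volume: float  # cell count x spacing^3
    lining_residues: frozenset[ResidueKey]
    centroid: np.ndarray  # (3,) Angstrom
    spacing: float
    grid: Grid | None = None
    interface_adjacent: bool | None = None

    @property
    def n_lining(self) -> int:
        return len(self.lining_residues)

    def cell_coords(self) -> np.ndarray:
        assert self.grid is not None
        return self.grid.cell_centers(self.cells)


def _shift(mask: np.ndarray, d: tuple[int, int, int], steps: int) -> np.ndarray:
    """mask shifted so out[c] = mask[c + steps*d], zero-filled at borders."""
    out = np.zeros_like(mask)
    src = []
    dst = []
    for axis in range(3):
        offset = d[axis] * steps
        n = mask.shape[axis]
        if offset >= n or offset <= -n:
            return out
        if offset >= 0:
            src.append(slice(offset, n))
            dst.append(slice(0, n - offset))
        else:
            src.append(slice(0, n + offset))
            dst.append(slice(-offset, n))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _blocked_along(protein: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Boolean grid: protein occurs somewhere strictly along +d from each cell.

    Log-doubling OR-scan: after k rounds the reach covers 2^k - 1 steps.
    """
    reach = _shift(protein, d, 1)
    steps = 1
    limit = max(protein.shape)
    while steps < limit:
        reach = reach | _shift(reach, d, steps)
        steps *= 2
    return reach


def rasterize(
    model: StructureModel, spacing: float, margin: float = 3.0
) -> Grid | None:
    """Mark grid cells whose center lies inside any heavy atom's vdW sphere.

    The origin is snapped to a multiple of ``spacing`` so that grids for
    translated copies of the same rigid structure are compatible.
    """
    coords = model.polymer_coords()
    if len(coords) <= 3:
        return None
    elements = [
        a.element.upper()
        for c in model.chains
        for r in c.residues
        for a in r.atoms
    ]
    radii = np.array([VDW_RADII.get(e, _DEFAULT_RADIUS) for e in elements])
    lo = np.floor((coords.min(axis=0) - margin) / spacing) * spacing
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    labels = np.zeros(tuple(shape), dtype=np.uint8)
    # per-atom local sphere stamping
    for xyz, r in zip(coords, radii):
        c0 = np.floor((xyz - r - lo) / spacing).astype(int)
        c1 = np.ceil((xyz + r - lo) / spacing).astype(int)
        c0 = np.maximum(c0, 0)
        c1 = np.minimum(c1, shape - 1)
        if np.any(c0 > c1):
            continue
        ix, iy, iz = [np.arange(c0[k], c1[k] + 1) for k in range(3)]
        centers = lo + (np.stack(np.meshgrid(ix, iy, iz, indexing="ij"), axis=-1) + 0.5) * spacing
        inside = np.sum((centers - xyz) ** 2, axis=-1) <= r * r
        sub = labels[c0[0]:c1[0] + 1, c0[1]:c1[1] + 1, c0[2]:c1[2] + 1]
        sub[inside] = PROTEIN
    return Grid(origin=lo, spacing=spacing, labels=labels)


def detect_pockets(
    model: StructureModel,
    spacing: float = DEFAULT_SPACING,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    enclosure_min: int = DEFAULT_ENCLOSURE_MIN,
    margin: float = 3.0,
) -> list[Pocket]:
    """Detect cavities as maximal 6-connected sets of enclosed empty cells.

    Degenerate models (<= 3 heavy atoms) yield an empty list, not an error.
    Pockets are returned sorted by volume (descending), ties by centroid.
    """
    if not model.chains:
        raise ValueError("model has no polymer chains")
    if not (0.5 <= spacing <= 2.0):
        raise ValueError(f"spacing {spacing} outside [0.5, 2.0] A")
    grid = rasterize(model, spacing, margin)
    if grid is None:
        return []
    protein = grid.labels == PROTEIN
    empty = ~protein

    enclosed_pairs = np.zeros(protein.shape, dtype=np.int8)
    for d in _SCAN_DIRECTIONS:
        plus = _blocked_along(protein, d)
        minus = _blocked_along(protein, tuple(-x for x in d))
        enclosed_pairs += (plus & minus).astype(np.int8)
    cavity = empty & (enclosed_pairs >= enclosure_min)
    grid.labels[cavity] = CAVITY

    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labeled, n_components = ndimage.label(cavity, structure=structure)
    if n_components == 0:
        return []

    # atom table for lining residue assignment
    atom_coords = []
    atom_keys = []
    for chain in model.chains:
        for res in chain.residues:
            for a in res.atoms:
                atom_coords.append(a.coords)
                atom_keys.append(res.key)
    tree = cKDTree(np.asarray(atom_coords))
    lining_cutoff = probe_radius + spacing

    pockets: list[Pocket] = []
    for comp in range(1, n_components + 1):
        cells = np.argwhere(labeled == comp)
        centers = grid.cell_centers(cells)
        lining: set[ResidueKey] = set()
        for idx_list in tree.query_ball_point(centers, r=lining_cutoff):
            lining.update(atom_keys[i] for i in idx_list)
        pockets.append(
            Pocket(
                pocket_id=comp,
                cells=cells,
                volume=len(cells) * spacing**3,
                lining_residues=frozenset(lining),
                centroid=centers.mean(axis=0),
                spacing=spacing,
                grid=grid,
            )
        )
    pockets.sort(key=lambda p: (-p.volume, tuple(np.round(p.centroid, 3))))
    for i, p in enumerate(pockets, start=1):
        p.pocket_id = i
    return pockets


def passes_library_filter(
    pocket: Pocket,
    min_residues: int = DEFAULT_MIN_LINING_RESIDUES,
    min_volume: float = DEFAULT_MIN_VOLUME,
) -> bool:
    """Screening-library rule: >= 10 lining residues and >= 100 A^3 volume."""
    return pocket.n_lining >= min_residues and pocket.volume >= min_volume


def is_interface_adjacent(pocket: Pocket, summary: InterfaceSummary) -> bool:
    """True iff the lining includes interface residues from *both* chains."""
    lining = pocket.lining_residues
    return bool(lining & summary.residues_a) and bool(lining & summary.residues_b)
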