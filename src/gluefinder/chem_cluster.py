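"""Path-based fingerprints, Tanimoto similarity, and leader clustering.

Fingerprints hash every linear heavy-atom path of 0..max_path bonds (atom
element sequence plus bond orders, canonicalized over the two traversal
directions) into a fixed-length bit vector -- the Daylight-style scheme.
Single atoms count as zero-bond paths, so any non-empty molecule sets at
least one bit.  Clustering is Butina leader clustering at a Tanimoto
threshold, with the cluster centroid being the member with the highest mean
within-cluster similarity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Fingerprint",
    "ClusterResult",
    "SCHEME_ID",
    "path_fingerprint",
    "fingerprint_from_smiles",
    "tanimoto",
    "threshold_cluster",
    "read_component_dictionary",
]

SCHEME_ID = "linear-path-sha1-v1"


@dataclass
class Fingerprint:
    bits: np.ndarray  # boolean vector
    n_bits: int
    scheme: str
    ligand_code: str

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (self.n_bits,):
            raise ValueError("bit vector length disagrees with n_bits")

    @property
    def on_bits(self) -> np.ndarray:
        return np.nonzero(self.bits)[0]


@dataclass
class ClusterResult:
    clusters: list[list[str]]  # member ligand codes per cluster
    centroids: list[str]  # one centroid code per cluster
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _bit_index(token: str, n_bits: int) -> int:
    digest = hashlib.sha1(token.encode("ascii")).digest()
    return int.from_bytes(digest[:8], "big") % n_bits


def _enumerate_paths(mol, max_path: int) -> set[str]:
    """Canonical tokens of all simple linear paths up to max_path bonds."""
    n = mol.GetNumAtoms()
    adjacency: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = str(bond.GetBondType())
        adjacency[i].append((j, order))
        adjacency[j].append((i, order))
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    tokens: set[str] = set()

    def walk(path: list[int], bonds: list[str]) -> None:
        forward = "|".join(
            s for pair in zip(map(symbols.__getitem__, path), bonds + [""]) for s in pair if s
        )
        backward = "|".join(
            s
            for pair in zip(map(symbols.__getitem__, path[::-1]), bonds[::-1] + [""])
            for s in pair
            if s
        )
        tokens.add(min(forward, backward))
        if len(bonds) >= max_path:
            return
        for nxt, order in adjacency[path[-1]]:
            if nxt not in path:
                walk(path + [nxt], bonds + [order])

    for start in range(n):
        walk([start], [])
    return tokens


def path_fingerprint(
    mol, max_path: int = 7, n_bits: int = 2048, ligand_code: str = ""
) -> Fingerprint:
    """Hash all linear paths of a molecular graph into a bit vector.

    ``mol`` is an rdkit molecule (hydrogens ignored if absent from the
    graph).  Deterministic: the same molecule always yields the same bits.
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    bits = np.zeros(n_bits, dtype=bool)
    for token in _enumerate_paths(mol, max_path):
        bits[_bit_index(token, n_bits)] = True
    return Fingerprint(bits, n_bits, f"{SCHEME_ID}/max_path={max_path}", ligand_code)


def fingerprint_from_smiles(
    smiles: str, ligand_code: str = "", max_path: int = 7, n_bits: int = 2048
) -> Fingerprint:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES: {smiles!r}")
    return path_fingerprint(mol, max_path, n_bits, ligand_code or smiles)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A & B| / |A | B|; 0.0 when both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"bit length mismatch: {a.n_bits} vs {b.n_bits}")
    union = np.count_nonzero(a.bits | b.bits)
    if union == 0:
        return 0.0
    return np.count_nonzero(a.bits & b.bits) / union


def threshold_cluster(
    fingerprints: Sequence[Fingerprint], threshold: float = 0.8
) -> ClusterResult:
    """Butina leader clustering at a Tanimoto threshold.

    Molecules are sorted by neighbour count (pairs with similarity >=
    threshold), ties broken by ligand code; the leader absorbs all its
    unassigned neighbours.  The centroid of each cluster is the member with
    the highest mean similarity to its cluster, ties by code order.
    """
    if not fingerprints:
        raise ValueError("need at least one fingerprint")
    n = len(fingerprints)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(fingerprints[i], fingerprints[j])
    neighbors = [set(np.nonzero(sim[i] >= threshold)[0]) - {i} for i in range(n)]
    order = sorted(
        range(n), key=lambda i: (-len(neighbors[i]), fingerprints[i].ligand_code, i)
    )
    assigned = np.zeros(n, dtype=bool)
    clusters_idx: list[list[int]] = []
    for leader in order:
        if assigned[leader]:
            continue
        members = [leader] + sorted(
            m for m in neighbors[leader] if not assigned[m]
        )
        for m in members:
            assigned[m] = True
        clusters_idx.append(members)

    clusters: list[list[str]] = []
    centroids: list[str] = []
    for members in clusters_idx:
        codes = [fingerprints[m].ligand_code for m in members]
        mean_sim = [float(np.mean([sim[m, o] for o in members])) for m in members]
        best = max(
            range(len(members)), key=lambda k: (mean_sim[k], codes[k]), default=0
        )
        # ties by code order: among equal mean similarity prefer the earliest code
        best_val = max(mean_sim)
        tied = [k for k in range(len(members)) if np.isclose(mean_sim[k], best_val)]
        best = min(tied, key=lambda k: codes[k])
        clusters.append(sorted(codes))
        centroids.append(codes[best])
    return ClusterResult(clusters=clusters, centroids=centroids, threshold=threshold)


def read_component_dictionary(path: str | Path) -> dict[str, "object"]:
    """Read a ligand-code -> molecule mapping from a SMILES file or SDF.

    SMILES files are whitespace-delimited ``SMILES CODE`` lines; SDF entries
    use the molecule title as the code.
    """
    from rdkit import Chem

    path = Path(path)
    out = {}
    if path.suffix.lower() in {".smi", ".smiles", ".txt"}:
        for line in path.read_text().splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            smiles = parts[0]
            code = parts[1] if len(parts) > 1 else smiles
            mol = Chem.MolFromSmiles(smiles)
            if mol is not None:
                out[code] = mol
    else:
        for mol in Chem.SDMolSupplier(str(path), removeHs=True):
            if mol is None:
                continue
            code = mol.GetProp("_Name") if mol.HasProp("_Name") else f"LIG{len(out)}"
            out[code] = mol
    return out
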