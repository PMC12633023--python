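"""Protein-protein interface detection and interface-adjacent ligand rules.

A dimer interface is defined at residue level: two residues from opposite
chains are "interacting" when their minimum heavy-atom distance is at or
below a cutoff (default 4.5 A, the standard heavy-atom contact criterion).
A dimer is genuine when each chain contributes at least five interacting
residues, and a bound ligand is interface-adjacent (an IAP ligand) when it
contacts at least five distinct residues on each chain.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    Chain,
    LigandInstance,
    NotADimerError,
    ResidueKey,
    StructureModel,
    select_dimer,
)

__all__ = [
    "ContactPair",
    "InterfaceSummary",
    "IAPRecord",
    "IAPCatalog",
    "LigandRejectedError",
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_MIN_RESIDUES_PER_CHAIN",
    "residue_contact_map",
    "interface_residue_sets",
    "qualifies_as_dimer",
    "ligand_chain_contacts",
    "classify_ligand",
    "build_catalog",
]

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 4.5  # Angstrom, heavy-atom minimum distance
DEFAULT_MIN_RESIDUES_PER_CHAIN = 5


class LigandRejectedError(ValueError):
    """Raised when a water is passed where a classifiable ligand is required."""


@dataclass(frozen=True)
class ContactPair:
    residue_a: ResidueKey
    residue_b: ResidueKey
    distance: float  # minimum heavy-atom distance, Angstrom


@dataclass
class InterfaceSummary:
    residues_a: frozenset[ResidueKey]
    residues_b: frozenset[ResidueKey]
    contacts: list[ContactPair]
    cutoff: float

    @property
    def counts(self) -> tuple[int, int]:
        return len(self.residues_a), len(self.residues_b)


@dataclass(frozen=True)
class IAPRecord:
    ligand_code: str
    entry_id: str
    contacts_a: int
    contacts_b: int
    classification: Literal["iap", "single_chain", "non_binder"]
    is_metal: bool = False


@dataclass
class IAPCatalog:
    """Aggregate of per-ligand interface classifications over many entries."""

    records: list[IAPRecord] = field(default_factory=list)

    @property
    def code_histogram(self) -> Counter:
        return Counter(r.ligand_code for r in self.records)

    @property
    def iap_histogram(self) -> Counter:
        return Counter(r.ligand_code for r in self.records if r.classification == "iap")

    @property
    def metal_histogram(self) -> Counter:
        return Counter(
            r.ligand_code
            for r in self.records
            if r.classification == "iap" and r.is_metal
        )

    @property
    def iap_fraction(self) -> float | None:
        """Fraction of all classified ligands that are interface-adjacent.

        ``None`` when the catalog is empty (the fraction is undefined).
        """
        if not self.records:
            return None
        n_iap = sum(1 for r in self.records if r.classification == "iap")
        return n_iap / len(self.records)

    def iap_codes(self) -> frozenset[str]:
        return frozenset(self.iap_histogram)


def _chain_atom_table(chain: Chain) -> tuple[np.ndarray, np.ndarray, list[ResidueKey]]:
    """Flatten a chain to (coords, residue-index-per-atom, residue keys)."""
    coords = []
    res_idx = []
    keys = []
    for i, res in enumerate(chain.residues):
        keys.append(res.key)
        for atom in res.atoms:
            coords.append(atom.coords)
            res_idx.append(i)
    return np.asarray(coords, dtype=float), np.asarray(res_idx, dtype=int), keys


def residue_contact_map(
    chain_a: Chain, chain_b: Chain, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> list[ContactPair]:
    """All residue pairs across two chains with min heavy-atom distance <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not chain_a.residues or not chain_b.residues:
        raise ValueError("chains must be non-empty")
    xa, ia, keys_a = _chain_atom_table(chain_a)
    xb, ib, keys_b = _chain_atom_table(chain_b)
    pairs = cKDTree(xa).sparse_distance_matrix(
        cKDTree(xb), max_distance=cutoff, output_type="coo_matrix"
    )
    best: dict[tuple[int, int], float] = {}
    for ai, bi, d in zip(pairs.row, pairs.col, pairs.data):
        key = (ia[ai], ib[bi])
        if d < best.get(key, np.inf):
            best[key] = d
    return [
        ContactPair(keys_a[ra], keys_b[rb], float(d))
        for (ra, rb), d in sorted(best.items())
    ]


def interface_residue_sets(
    dimer: tuple[Chain, Chain], cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> InterfaceSummary:
    """Project the contact map onto per-chain interface residue sets."""
    chain_a, chain_b = dimer
    contacts = residue_contact_map(chain_a, chain_b, cutoff)
    return InterfaceSummary(
        residues_a=frozenset(c.residue_a for c in contacts),
        residues_b=frozenset(c.residue_b for c in contacts),
        contacts=contacts,
        cutoff=cutoff,
    )


def qualifies_as_dimer(
    summary: InterfaceSummary, min_per_chain: int = DEFAULT_MIN_RESIDUES_PER_CHAIN
) -> bool:
    """True iff each chain contributes at least ``min_per_chain`` interface residues."""
    na, nb = summary.counts
    return na >= min_per_chain and nb >= min_per_chain


def ligand_chain_contacts(
    ligand: LigandInstance, chain: Chain, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> int:
    """Number of distinct chain residues within ``cutoff`` of any ligand heavy atom."""
    if not ligand.atoms:
        raise ValueError("ligand has no atoms")
    xc, ic, _ = _chain_atom_table(chain)
    if len(xc) == 0:
        return 0
    tree = cKDTree(xc)
    hit = set()
    for idx_list in tree.query_ball_point(ligand.coords(), r=cutoff):
        hit.update(ic[i] for i in idx_list)
    return len(hit)


def classify_ligand(
    ligand: LigandInstance,
    dimer: tuple[Chain, Chain],
    entry_id: str = "",
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_per_chain: int = DEFAULT_MIN_RESIDUES_PER_CHAIN,
) -> IAPRecord:
    """Classify a ligand as iap / single_chain / non_binder against a dimer.

    ``iap`` requires at least ``min_per_chain`` contacted residues on *each*
    chain; ``single_chain`` means exactly one chain meets the threshold.
    Waters are never classified.
    """
    if ligand.is_water:
        raise LigandRejectedError("waters are not classified as interface ligands")
    ca = ligand_chain_contacts(ligand, dimer[0], cutoff)
    cb = ligand_chain_contacts(ligand, dimer[1], cutoff)
    if ca >= min_per_chain and cb >= min_per_chain:
        cls = "iap"
    elif ca >= min_per_chain or cb >= min_per_chain:
        cls = "single_chain"
    else:
        cls = "non_binder"
    return IAPRecord(ligand.code, entry_id, ca, cb, cls, is_metal=ligand.is_metal)


def build_catalog(
    models: Iterable[StructureModel],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_per_chain: int = DEFAULT_MIN_RESIDUES_PER_CHAIN,
) -> IAPCatalog:
    """Scan dimer models and classify every non-water ligand.

    Models failing the dimer selection or the five-residues-per-chain
    interface rule are logged and skipped, never fatal.
    """
    catalog = IAPCatalog()
    for model in models:
        try:
            dimer = select_dimer(model)
            summary = interface_residue_sets(dimer, cutoff)
            if not qualifies_as_dimer(summary, min_per_chain):
                logger.info(
                    "skipping %s: interface counts %s below %d per chain",
                    model.entry_id, summary.counts, min_per_chain,
                )
                continue
            for ligand in model.ligands:
                catalog.records.append(
                    classify_ligand(
                        ligand, dimer, model.entry_id, cutoff, min_per_chain
                    )
                )
        except (NotADimerError, ValueError) as exc:
            logger.warning("skipping %s: %s", model.entry_id, exc)
    return catalog
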