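"""Template library, ligand pose transfer, precision estimation, screening.

The screening loop: for every interface-adjacent pocket of a target dimer,
align all library template pockets onto it, keep matches that are
statistically significant (pocket p-value <= cutoff) and whose template is
sequence-distant from *both* target chains, transfer the template-bound
ligand through the alignment transform, sanity-check the transferred pose
sterically, and estimate a binding precision from a calibration table.
Predictions are grouped per chemical component code into pose ensembles and
ranked deterministically.

Binding precision here is a transparent calibration-table estimate: a
piecewise-constant, monotone map from (similarity score, p-value) bins to
the empirical fraction of true binders observed in a labeled set, with hard
steric disqualification above a clash limit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .interface_miner import (
    DEFAULT_CONTACT_CUTOFF,
    IAPCatalog,
    interface_residue_sets,
)
from .pocket_align import (
    AlignmentInfeasibleError,
    AlignParams,
    NullModel,
    PocketAlignment,
    PocketStructure,
    align_pockets,
    global_sequence_identity,
    pocket_structure,
)
from .pocket_finder import (
    DEFAULT_MIN_LINING_RESIDUES,
    DEFAULT_MIN_VOLUME,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SPACING,
    Pocket,
    detect_pockets,
    is_interface_adjacent,
    passes_library_filter,
)
from .structure_io import LigandInstance, StructureModel, select_dimer

__all__ = [
    "TemplateRecord",
    "GluePrediction",
    "BenchmarkReport",
    "BenchmarkTarget",
    "ScreenSummary",
    "ScreenConfig",
    "CalibrationTable",
    "build_template_library",
    "ligand_exposure_fraction",
    "transfer_pose",
    "steric_clash_count",
    "com_deviation",
    "estimate_precision",
    "screen_target",
    "run_benchmark",
    "summarize_screen",
    "default_calibration_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    p_cutoff: float = 0.05
    identity_cutoff: float | None = None  # None = no template identity filter
    precision_threshold: float = 0.15
    require_adjacent: bool = True
    clash_overlap: float = 1.5  # Angstrom
    clash_limit: int = 5  # more clashes than this zeroes the precision
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    spacing: float = DEFAULT_SPACING
    probe_radius: float = DEFAULT_PROBE_RADIUS
    min_lining_residues: int = DEFAULT_MIN_LINING_RESIDUES
    min_volume: float = DEFAULT_MIN_VOLUME
    align_params: AlignParams = field(default_factory=AlignParams)


@dataclass
class TemplateRecord:
    entry_id: str
    pocket: PocketStructure
    ligand_code: str
    ligand_pose: LigandInstance
    sequences: list[str]  # source chain sequence(s)
    exposure: float | None = None  # solvent-exposure fraction of the ligand


@dataclass
class GluePrediction:
    ligand_code: str
    poses: list[LigandInstance]  # ensemble of transferred poses
    best_score: float
    best_p_value: float
    max_identity: float
    precision: float
    clash_count: int
    template_entries: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("prediction must carry at least one pose")
        if not (0.0 <= self.precision <= 1.0):
            raise ValueError("precision must be in [0, 1]")


@dataclass
class BenchmarkConditionResult:
    p_cutoff: float
    identity_cutoff: float | None
    recall: float
    n_recovered: int
    n_targets: int
    mean_precision: float | None  # over recovered native ligands
    mean_com_deviation: float | None  # Angstrom, over recovered native ligands


@dataclass
class BenchmarkReport:
    conditions: list[BenchmarkConditionResult]

    def by_condition(
        self, p_cutoff: float, identity_cutoff: float | None
    ) -> BenchmarkConditionResult:
        for c in self.conditions:
            if c.p_cutoff == p_cutoff and c.identity_cutoff == identity_cutoff:
                return c
        raise KeyError((p_cutoff, identity_cutoff))


@dataclass
class BenchmarkTarget:
    model: StructureModel
    native_code: str
    native_pose: LigandInstance


@dataclass
class ScreenSummary:
    fraction_with_predictions: float
    mean_precision: float | None
    known_iap_fraction: float | None
    mean_best_precision: float | None
    max_best_precision: float | None


# ---------------------------------------------------------------------------
# template library


def _assign_ligand_pocket(
    ligand: LigandInstance, pockets: Sequence[Pocket], reach: float
) -> Pocket | None:
    """Pocket whose cavity cells lie closest to the ligand, within ``reach``."""
    best = None
    best_hits = 0
    for pocket in pockets:
        cells = pocket.cell_coords()
        tree = cKDTree(cells)
        d, _ = tree.query(ligand.coords())
        hits = int(np.sum(d <= reach))
        if hits > best_hits:
            best_hits = hits
            best = pocket
    return best


def build_template_library(
    models: Iterable[StructureModel], config: ScreenConfig | None = None
) -> list[TemplateRecord]:
    """One record per (qualifying pocket, bound ligand) pair.

    Pockets must pass the library filter (>= 10 lining residues, >= 100 A^3).
    Ligands from single-chain (monomeric) models are annotated with their
    solvent-exposure fraction.  Deterministic in stream order.
    """
    config = config or ScreenConfig()
    records: list[TemplateRecord] = []
    for model in models:
        try:
            pockets = [
                p
                for p in detect_pockets(model, config.spacing, config.probe_radius)
                if passes_library_filter(
                    p, config.min_lining_residues, config.min_volume
                )
            ]
        except ValueError as exc:
            logger.warning("skipping %s: %s", model.entry_id, exc)
            continue
        if not pockets:
            continue
        sequences = [c.sequence for c in model.chains]
        monomer = len(model.chains) == 1
        reach = config.probe_radius + 2.0 * config.spacing
        for ligand in model.ligands:
            pocket = _assign_ligand_pocket(ligand, pockets, reach)
            if pocket is None:
                continue
            exposure = ligand_exposure_fraction(ligand, model) if monomer else None
            records.append(
                TemplateRecord(
                    entry_id=model.entry_id,
                    pocket=pocket_structure(model, pocket),
                    ligand_code=ligand.code,
                    ligand_pose=ligand,
                    sequences=sequences,
                    exposure=exposure,
                )
            )
    return records


def ligand_exposure_fraction(ligand: LigandInstance, model: StructureModel) -> float:
    """Solvent-accessible surface area of the ligand in context over isolated.

    Shrake-Rupley with a 1.4 A probe (element-based radii).  1.0 means the
    ligand is fully exposed, ~0 means it is buried in the protein.
    """
    import biotite.structure as struc

    lig_coords = ligand.coords()
    lig_elements = [a.element.capitalize() for a in ligand.atoms]
    prot_coords = model.polymer_coords()
    prot_elements = [
        a.element.capitalize()
        for c in model.chains
        for r in c.residues
        for a in r.atoms
    ]

    def _sasa(coords: np.ndarray, elements: list[str], mask: np.ndarray) -> float:
        arr = struc.AtomArray(len(coords))
        arr.coord = np.asarray(coords, dtype=np.float32)
        arr.element = np.array([e.upper() for e in elements])
        arr.res_id = np.arange(len(coords)) + 1
        arr.atom_name = np.array([f"X{i}" for i in range(len(coords))])
        arr.res_name = np.array(["LIG"] * len(coords))
        values = struc.sasa(
            arr,
            probe_radius=1.4,
            atom_filter=mask,
            ignore_ions=False,
            point_number=240,
            vdw_radii="Single",
        )
        return float(np.nansum(values[mask]))

    isolated = _sasa(lig_coords, lig_elements, np.ones(len(lig_coords), dtype=bool))
    if isolated <= 0:
        return 0.0
    if len(prot_coords) == 0:
        return 1.0
    coords = np.concatenate([prot_coords, lig_coords])
    elements = prot_elements + lig_elements
    mask = np.zeros(len(coords), dtype=bool)
    mask[len(prot_coords):] = True
    in_context = _sasa(coords, elements, mask)
    return float(min(max(in_context / isolated, 0.0), 1.0))


# ---------------------------------------------------------------------------
# pose transfer and geometry checks


def transfer_pose(template: TemplateRecord, alignment: PocketAlignment) -> LigandInstance:
    """Carry the template-bound ligand into the query frame."""
    if alignment.transform is None:
        raise ValueError("alignment carries no transform")
    t = alignment.transform
    return template.ligand_pose.transformed(t.rotation, t.translation)


def steric_clash_count(
    pose: LigandInstance, model: StructureModel, overlap: float = 1.5
) -> int:
    """(ligand atom, protein heavy atom) pairs closer than ``overlap`` A."""
    prot = model.polymer_coords()
    if len(prot) == 0:
        return 0
    tree = cKDTree(prot)
    return int(sum(len(hits) for hits in tree.query_ball_point(pose.coords(), r=overlap)))


def com_deviation(pose_a: LigandInstance, pose_b: LigandInstance) -> float:
    """Euclidean distance between unweighted heavy-atom centers of mass (A)."""
    return float(np.linalg.norm(pose_a.center_of_mass() - pose_b.center_of_mass()))


# ---------------------------------------------------------------------------
# precision calibration


class CalibrationTable:
    """Monotone piecewise-constant map (score, p-value) -> binding precision.

    ``values[i, j]`` is the precision for score bin i and p-value bin j; it
    is non-decreasing in i (better score) and non-increasing in j (worse
    p-value).  Features outside the fitted range clamp to the edge bins.
    """

    def __init__(
        self,
        score_edges: Sequence[float],
        p_edges: Sequence[float],
        values: np.ndarray,
    ):
        self.score_edges = np.asarray(score_edges, dtype=float)
        self.p_edges = np.asarray(p_edges, dtype=float)
        self.values = np.asarray(values, dtype=float)
        expected = (len(self.score_edges) + 1, len(self.p_edges) + 1)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("precision values must lie in [0, 1]")

    def lookup(self, score: float, p_value: float) -> float:
        i = int(np.searchsorted(self.score_edges, score, side="right"))
        j = int(np.searchsorted(self.p_edges, p_value, side="right"))
        return float(self.values[i, j])

    @classmethod
    def from_labeled(
        cls,
        scores: Sequence[float],
        p_values: Sequence[float],
        labels: Sequence[int],
        n_bins: int = 10,
    ) -> "CalibrationTable":
        """Fit from a labeled set (1 = true binder).

        Bin edges are feature deciles.  The two features are pooled into a
        combined rank (score decile up, p-value decile down) and the label
        fraction is fitted with 1D isotonic regression over that rank; the
        cell value is the fitted fraction at the cell's combined rank.
        This makes the table monotone non-decreasing in score and
        non-increasing in p-value by construction while remaining a
        calibrated (empirical-fraction) estimate.
        """
        from sklearn.isotonic import IsotonicRegression

        scores = np.asarray(scores, dtype=float)
        p_values = np.asarray(p_values, dtype=float)
        labels = np.asarray(labels, dtype=float)
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        score_edges = np.unique(np.quantile(scores, qs))
        p_edges = np.unique(np.quantile(p_values, qs))
        ns, npb = len(score_edges) + 1, len(p_edges) + 1
        si = np.searchsorted(score_edges, scores, side="right")
        pj = np.searchsorted(p_edges, p_values, side="right")
        combined = si + (npb - 1 - pj)
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(combined, labels)
        ranks = np.arange(ns + npb - 1, dtype=float)
        g = iso.predict(ranks)
        ii, jj = np.meshgrid(np.arange(ns), np.arange(npb), indexing="ij")
        values = g[ii + (npb - 1 - jj)]
        return cls(score_edges, p_edges, values)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "score_edges": self.score_edges.tolist(),
                    "p_edges": self.p_edges.tolist(),
                    "values": self.values.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationTable":
        d = json.loads(Path(path).read_text())
        return cls(d["score_edges"], d["p_edges"], np.asarray(d["values"]))


_DEFAULT_TABLE: CalibrationTable | None = None


def default_calibration_table() -> CalibrationTable:
    """The calibration table shipped with the package (synthetic labeled set)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        from importlib import resources

        with resources.as_file(
            resources.files("gluefinder").joinpath("data/calibration.json")
        ) as p:
            _DEFAULT_TABLE = CalibrationTable.from_json(p)
    return _DEFAULT_TABLE


def estimate_precision(
    score: float,
    p_value: float,
    identity: float,
    clash_count: int,
    calibration: CalibrationTable | None = None,
    clash_limit: int = 5,
) -> float:
    """Binding-precision estimate for one match.

    Piecewise-constant lookup in the calibration table; a clash count above
    the hard limit disqualifies the pose (precision 0).
    """
    if clash_count > clash_limit:
        return 0.0
    table = calibration or default_calibration_table()
    return table.lookup(score, p_value)


# ---------------------------------------------------------------------------
# screening


def _max_identity(template: TemplateRecord, target_sequences: Sequence[str]) -> float:
    return max(
        global_sequence_identity(ts, qs)
        for ts in template.sequences
        for qs in target_sequences
        if ts and qs
    )


def screen_target(
    model: StructureModel,
    library: Sequence[TemplateRecord],
    config: ScreenConfig | None = None,
    null_model: NullModel | None = None,
    calibration: CalibrationTable | None = None,
) -> list[GluePrediction]:
    """Screen a target dimer against a template pocket/ligand library.

    Returns predictions grouped per ligand code and ranked by precision
    (desc), p-value (asc), identity (desc), then code.  An empty list is
    returned when the target has no interface-adjacent pocket.
    """
    config = config or ScreenConfig()
    if not library:
        raise ValueError("template library is empty")
    dimer = select_dimer(model)
    summary = interface_residue_sets(dimer, config.contact_cutoff)
    pockets = detect_pockets(model, config.spacing, config.probe_radius)
    if config.require_adjacent:
        pockets = [p for p in pockets if is_interface_adjacent(p, summary)]
    if not pockets:
        logger.info("%s: no interface-adjacent pocket", model.entry_id)
        return []
    target_sequences = [c.sequence for c in model.chains]

    matches: dict[str, list[dict]] = {}
    identity_cache: dict[str, float] = {}
    for pocket in pockets:
        query = pocket_structure(model, pocket)
        if len(query) < config.align_params.min_residues:
            continue
        for template in library:
            try:
                aln = align_pockets(query, template.pocket, config.align_params)
            except AlignmentInfeasibleError:
                continue
            if aln.aligned_length < 3:
                continue
            p = (
                null_model.p_value(aln.score, aln.aligned_length)
                if null_model is not None
                else 1.0 - min(aln.score, 1.0 - 1e-9)
            )
            if p > config.p_cutoff:
                continue
            if template.entry_id not in identity_cache:
                identity_cache[template.entry_id] = _max_identity(
                    template, target_sequences
                )
            identity = identity_cache[template.entry_id]
            if config.identity_cutoff is not None and identity > config.identity_cutoff:
                continue
            pose = transfer_pose(template, aln)
            clashes = steric_clash_count(pose, model, config.clash_overlap)
            precision = estimate_precision(
                aln.score, p, identity, clashes, calibration, config.clash_limit
            )
            matches.setdefault(template.ligand_code, []).append(
                {
                    "pose": pose,
                    "score": aln.score,
                    "p": p,
                    "identity": identity,
                    "precision": precision,
                    "clashes": clashes,
                    "entry": template.entry_id,
                }
            )

    predictions = []
    for code, hits in matches.items():
        predictions.append(
            GluePrediction(
                ligand_code=code,
                poses=[h["pose"] for h in hits],
                best_score=max(h["score"] for h in hits),
                best_p_value=min(h["p"] for h in hits),
                max_identity=max(h["identity"] for h in hits),
                precision=max(h["precision"] for h in hits),
                clash_count=min(h["clashes"] for h in hits),
                template_entries=sorted({h["entry"] for h in hits}),
            )
        )
    predictions.sort(
        key=lambda g: (-g.precision, g.best_p_value, -g.max_identity, g.ligand_code)
    )
    return predictions


def run_benchmark(
    targets: Sequence[BenchmarkTarget],
    library: Sequence[TemplateRecord],
    conditions: Sequence[tuple[float, float | None]],
    config: ScreenConfig | None = None,
    null_model: NullModel | None = None,
    calibration: CalibrationTable | None = None,
) -> BenchmarkReport:
    """Native-ligand recovery benchmark over a condition grid.

    For each target the library entries from the target's own entry id are
    excluded.  Recall is the fraction of targets whose native ligand code is
    among the predictions of a condition; for recovered ligands the
    center-of-mass deviation of the best pose vs the native pose and the
    predicted precision are averaged.  Alignments are computed once per
    (target, template) pair; the (p_cutoff, identity_cutoff) grid only
    filters post-alignment quantities, so the per-condition results are
    identical to independent runs.
    """
    base = config or ScreenConfig()
    loosest_p = max(p for p, _ in conditions)
    per_condition: dict[tuple[float, float | None], dict] = {
        c: {"recovered": 0, "precisions": [], "deviations": []} for c in conditions
    }
    for target in targets:
        lib = [t for t in library if t.entry_id != target.model.entry_id]
        permissive = replace(base, p_cutoff=loosest_p, identity_cutoff=None)
        predictions = screen_target(
            target.model, lib, permissive, null_model, calibration
        )
        for (p_cut, id_cut), acc in per_condition.items():
            surviving = [
                g
                for g in predictions
                if g.best_p_value <= p_cut
                and (id_cut is None or g.max_identity <= id_cut)
            ]
            native = next(
                (g for g in surviving if g.ligand_code == target.native_code), None
            )
            if native is None:
                continue
            acc["recovered"] += 1
            acc["precisions"].append(native.precision)
            acc["deviations"].append(
                min(com_deviation(pose, target.native_pose) for pose in native.poses)
            )
    results = []
    for (p_cut, id_cut), acc in per_condition.items():
        n_rec = acc["recovered"]
        results.append(
            BenchmarkConditionResult(
                p_cutoff=p_cut,
                identity_cutoff=id_cut,
                recall=n_rec / len(targets) if targets else 0.0,
                n_recovered=n_rec,
                n_targets=len(targets),
                mean_precision=float(np.mean(acc["precisions"])) if n_rec else None,
                mean_com_deviation=float(np.mean(acc["deviations"])) if n_rec else None,
            )
        )
    return BenchmarkReport(conditions=results)


def summarize_screen(
    per_target_predictions: dict[str, list[GluePrediction]],
    precision_threshold: float = 0.15,
    native_catalog: IAPCatalog | None = None,
) -> ScreenSummary:
    """Aggregate a screen: per-target hit fractions and precision statistics."""
    n_targets = len(per_target_predictions)
    if n_targets == 0:
        return ScreenSummary(0.0, None, None, None, None)
    passing_per_target = {
        t: [g for g in preds if g.precision >= precision_threshold]
        for t, preds in per_target_predictions.items()
    }
    with_hit = sum(1 for v in passing_per_target.values() if v)
    all_passing = [g for v in passing_per_target.values() for g in v]
    mean_precision = (
        float(np.mean([g.precision for g in all_passing])) if all_passing else None
    )
    known_fraction = None
    if native_catalog is not None and all_passing:
        known_codes = native_catalog.iap_codes()
        codes = {g.ligand_code for g in all_passing}
        known_fraction = sum(1 for c in codes if c in known_codes) / len(codes)
    best = [
        max((g.precision for g in preds), default=None)
        for preds in per_target_predictions.values()
    ]
    best = [b for b in best if b is not None]
    return ScreenSummary(
        fraction_with_predictions=with_hit / n_targets,
        mean_precision=mean_precision,
        known_iap_fraction=known_fraction,
        mean_best_precision=float(np.mean(best)) if best else None,
        max_best_precision=float(np.max(best)) if best else None,
    )
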