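"""Rigid superposition, pocket structural alignment, and alignment statistics.

The pocket aligner is an iterative seed-superpose-extend procedure over the
Calpha atoms of pocket lining residues.  Candidate seeds are pairs of
consecutive residue triples whose internal distance patterns agree; each
seed is refined by alternating mutual-nearest-neighbour correspondence
(under a distance gate of 2*d0) with Kabsch re-superposition until the
correspondence reaches a fixed point.  The best result is kept under a
(score, aligned length, -RMSD) ordering.

The similarity score is TM-score-like: s = (1/L_min) * sum 1/(1+(d_i/d0)^2)
with d0 = 0.55 * L_min^(1/3) + 1.0 A, so it is bounded by 1, equals 1 for a
pocket aligned to a rigid copy of itself, and is length-normalized.

Statistical significance is an empirical null: scores of randomly paired,
unrelated pockets are fitted per aligned-length bin and the p-value of an
observed score is the fitted upper tail probability.  The score is a
bounded average of per-residue similarity terms, so its null distribution
is close to Gaussian with a mild left skew (the score cannot exceed 1); a
per-bin normal location/scale fit reproduces the observed null closely,
which an extreme-value (Gumbel) shape does not -- the best alignment is a
maximum over strongly correlated seeds, not independent trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm

from .pocket_finder import Pocket
from .structure_io import ResidueKey, StructureModel

__all__ = [
    "RigidTransform",
    "PocketStructure",
    "PocketAlignment",
    "AlignParams",
    "NullModel",
    "DegenerateInputError",
    "AlignmentInfeasibleError",
    "CalibrationError",
    "superpose",
    "align_pockets",
    "fit_null_model",
    "global_sequence_identity",
    "pocket_structure",
]


class DegenerateInputError(ValueError):
    """Fewer than 3 point pairs, or collinear points."""


class AlignmentInfeasibleError(ValueError):
    """A pocket is too small to align (fewer than 5 lining residues)."""


class CalibrationError(ValueError):
    """Not enough unrelated pocket pairs to fit the null model."""


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Unchecked Kabsch: (rotation, translation, rmsd) mapping mobile onto reference."""
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    xm = mobile - mu_m
    xr = reference - mu_r
    h = xm.T @ xr
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_r - rot @ mu_m
    rmsd = float(np.sqrt(np.mean(np.sum((mobile @ rot.T + trans - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-RMSD rigid transform mapping ``mobile`` onto ``reference`` (Kabsch).

    Both arrays are (n, 3) with paired rows, n >= 3 and non-collinear.
    Returns the transform and the residual RMSD in Angstrom.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("expected two equal-shape (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 point pairs, got {n}")
    # collinearity check on both point sets
    for x in (mobile - mobile.mean(axis=0), reference - reference.mean(axis=0)):
        sv = np.linalg.svd(x, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise DegenerateInputError("points are collinear")
    rot, trans, rmsd = _kabsch(mobile, reference)
    return RigidTransform(rot, trans), rmsd


@dataclass
class PocketStructure:
    """Alignable view of a pocket: ordered lining residues with one
    representative (Calpha) coordinate and a one-letter code each."""

    residue_keys: list[ResidueKey]
    coords: np.ndarray  # (n, 3) representative atoms
    sequence: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.residue_keys) != len(self.coords) or len(self.sequence) != len(self.coords):
            raise ValueError("keys, coords and sequence must have equal length")

    def __len__(self) -> int:
        return len(self.coords)


def pocket_structure(model: StructureModel, pocket: Pocket) -> PocketStructure:
    """Extract the representative-atom view of a pocket's lining residues.

    Residues are ordered by (chain id, residue number, insertion code); the
    representative atom is the Calpha when present, else the first heavy atom.
    """
    residues = {
        res.key: res for chain in model.chains for res in chain.residues
    }
    keys = sorted(pocket.lining_residues)
    coords = []
    seq = []
    from .structure_io import _one_letter  # local import to avoid cycle at module load

    for key in keys:
        res = residues[key]
        ca = res.atom("CA")
        coords.append(ca.coords if ca is not None else res.atoms[0].coords)
        seq.append(_one_letter(res.name))
    return PocketStructure(keys, np.asarray(coords), "".join(seq))


@dataclass
class AlignParams:
    seed_triple_tolerance: float = 1.0  # A, per internal distance of a 3-mer pair
    max_seeds: int = 24
    max_iterations: int = 50
    early_exit_score: float = 0.9
    min_residues: int = 5


@dataclass
class PocketAlignment:
    correspondence: list[tuple[int, int]]  # (query index, template index)
    transform: RigidTransform  # maps template coords into the query frame
    aligned_length: int
    rmsd: float
    score: float
    p_value: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must be in (0, 1]")


def _d0(l_min: int) -> float:
    return 0.55 * l_min ** (1.0 / 3.0) + 1.0


def _score(distances: np.ndarray, d0: float, l_min: int) -> float:
    return float(np.sum(1.0 / (1.0 + (distances / d0) ** 2)) / l_min)


def _mutual_nearest(q_moved: np.ndarray, t: np.ndarray, gate2: float) -> tuple[np.ndarray, np.ndarray]:
    """Mutual nearest neighbours within a squared distance gate.

    Returns sorted index arrays (qi, ti).
    """
    dm = cdist(q_moved, t, "sqeuclidean")
    nn_q = dm.argmin(axis=1)
    nn_t = dm.argmin(axis=0)
    qi = np.arange(len(q_moved))
    mutual = (nn_t[nn_q] == qi) & (dm[qi, nn_q] <= gate2)
    return qi[mutual], nn_q[mutual]


def _triples(coords: np.ndarray) -> np.ndarray:
    """Internal distance signatures (d01, d12, d02) of consecutive triples."""
    n = len(coords)
    if n < 3:
        return np.zeros((0, 3))
    a, b, c = coords[:-2], coords[1:-1], coords[2:]
    return np.stack(
        [
            np.linalg.norm(a - b, axis=1),
            np.linalg.norm(b - c, axis=1),
            np.linalg.norm(a - c, axis=1),
        ],
        axis=1,
    )


def align_pockets(
    query: PocketStructure,
    template: PocketStructure,
    params: AlignParams | None = None,
) -> PocketAlignment:
    """Structurally align a template pocket onto a query pocket.

    Deterministic for fixed inputs and parameters, and exactly symmetric
    under role swap (the computation runs in a canonical orientation and is
    inverted if needed).  The returned transform maps *template*
    coordinates into the query frame (the direction needed to carry a
    template-bound ligand over to the query).
    """
    params = params or AlignParams()

    def canon_key(p: PocketStructure) -> tuple:
        return (len(p), p.sequence, np.round(p.coords, 6).tobytes())

    if canon_key(template) < canon_key(query):
        inner = _align_impl(template, query, params)
        return PocketAlignment(
            correspondence=sorted((b, a) for a, b in inner.correspondence),
            transform=inner.transform.inverse(),
            aligned_length=inner.aligned_length,
            rmsd=inner.rmsd,
            score=inner.score,
            p_value=inner.p_value,
        )
    return _align_impl(query, template, params)


def _align_impl(
    query: PocketStructure,
    template: PocketStructure,
    params: AlignParams,
) -> PocketAlignment:
    nq, nt = len(query), len(template)
    if nq < params.min_residues or nt < params.min_residues:
        raise AlignmentInfeasibleError(
            f"pockets must have >= {params.min_residues} lining residues (got {nq}, {nt})"
        )
    l_min = min(nq, nt)
    d0 = _d0(l_min)
    gate = 2.0 * d0

    # candidate seeds: consecutive-triple pairs with matching internal distances
    sig_q = _triples(query.coords)
    sig_t = _triples(template.coords)
    seeds: list[tuple[float, int, int]] = []
    if len(sig_q) and len(sig_t):
        diff = np.abs(sig_q[:, None, :] - sig_t[None, :, :])
        ok = np.all(diff < params.seed_triple_tolerance, axis=2)
        qs, ts = np.nonzero(ok)
        mism = diff[qs, ts].sum(axis=1)
        order = np.lexsort((ts, qs, np.round(mism, 6)))
        seeds = [(float(mism[i]), int(qs[i]), int(ts[i])) for i in order]
    if len(seeds) > params.max_seeds:
        # deterministic thinning: best-matching seeds first, then an even
        # stride through the remainder for coverage
        keep = seeds[: params.max_seeds // 2]
        rest = seeds[params.max_seeds // 2:]
        stride = max(1, len(rest) // (params.max_seeds - len(keep)))
        keep += rest[::stride][: params.max_seeds - len(keep)]
        seeds = keep

    # always include the index-aligned seed so that self-alignment is exact
    identity_seed = (np.arange(l_min), np.arange(l_min))
    gate2 = gate * gate
    tq = query.coords
    tt = template.coords

    best: tuple[float, int, float] | None = None  # (score, length, -rmsd)
    best_state: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None

    def refine(qi: np.ndarray, ti: np.ndarray) -> None:
        nonlocal best, best_state
        rot = trans = None
        seen_score = -1.0
        stale = 0
        for _ in range(params.max_iterations):
            if len(qi) < 3:
                return
            centered = tt[ti] - tt[ti].mean(axis=0)
            if np.linalg.svd(centered, compute_uv=False)[1] <= 1e-10:
                return
            rot, trans, _ = _kabsch(tt[ti], tq[qi])
            moved_t = tt @ rot.T + trans
            new_qi, new_ti = _mutual_nearest(tq, moved_t, gate2)
            if len(new_qi) >= 3:
                d2 = np.sum((moved_t[new_ti] - tq[new_qi]) ** 2, axis=1)
                s = _score(np.sqrt(d2), d0, l_min)
                if s <= seen_score + 1e-12:
                    stale += 1
                else:
                    seen_score = s
                    stale = 0
            if (
                len(new_qi) == len(qi)
                and np.array_equal(new_qi, qi)
                and np.array_equal(new_ti, ti)
            ) or stale >= 3:
                qi, ti = new_qi, new_ti
                break
            qi, ti = new_qi, new_ti
        if rot is None or len(qi) < 3:
            return
        rot, trans, rmsd = _kabsch(tt[ti], tq[qi])
        dists = np.linalg.norm(tt[ti] @ rot.T + trans - tq[qi], axis=1)
        s = _score(dists, d0, l_min)
        key = (s, len(qi), -rmsd)
        if best is None or key > best:
            best = key
            best_state = (qi, ti, rot, trans)

    refine(*identity_seed)
    if best is None or best[0] < params.early_exit_score:
        for _, sq, st in seeds:
            refine(np.arange(sq, sq + 3), np.arange(st, st + 3))
            if best is not None and best[0] >= params.early_exit_score:
                break

    if best_state is None:
        # no seed produced >= 3 gated pairs: report a minimal, worthless match
        return PocketAlignment([], RigidTransform.identity(), 0, 0.0, 0.0)
    qi, ti, rot, trans = best_state
    rmsd = float(np.sqrt(np.mean(np.sum((tt[ti] @ rot.T + trans - tq[qi]) ** 2, axis=1))))
    return PocketAlignment(
        correspondence=[(int(a), int(b)) for a, b in zip(qi, ti)],
        transform=RigidTransform(rot, trans),
        aligned_length=int(len(qi)),
        rmsd=rmsd,
        score=float(best[0]),
    )


# aligned-length bins of the empirical null
NULL_BINS = ((5, 15), (16, 30), (31, 10**9))


@dataclass
class NullModel:
    """Empirical normal null of pocket-pair similarity scores, per aligned-length bin."""

    loc: dict[int, float]  # bin index -> location
    scale: dict[int, float]  # bin index -> scale (> 0)
    counts: dict[int, int]
    seed: int
    n_pairs: int

    @staticmethod
    def bin_index(aligned_length: int) -> int:
        for i, (lo, hi) in enumerate(NULL_BINS):
            if lo <= aligned_length <= hi:
                return i
        return 0

    def p_value(self, score: float, aligned_length: int) -> float:
        b = self.bin_index(aligned_length)
        if b not in self.loc:
            b = max(self.loc)  # fall back to the largest fitted bin
        p = float(norm.sf(score, loc=self.loc[b], scale=self.scale[b]))
        return min(max(p, 1e-16), 1.0)

    def to_dict(self) -> dict:
        return {
            "loc": {str(k): v for k, v in self.loc.items()},
            "scale": {str(k): v for k, v in self.scale.items()},
            "counts": {str(k): v for k, v in self.counts.items()},
            "seed": self.seed,
            "n_pairs": self.n_pairs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NullModel":
        return cls(
            loc={int(k): float(v) for k, v in d["loc"].items()},
            scale={int(k): float(v) for k, v in d["scale"].items()},
            counts={int(k): int(v) for k, v in d["counts"].items()},
            seed=int(d["seed"]),
            n_pairs=int(d["n_pairs"]),
        )


def fit_null_model(
    pocket_library: list[PocketStructure],
    n_pairs: int = 10_000,
    seed: int = 17,
    min_samples_per_bin: int = 30,
    params: AlignParams | None = None,
) -> NullModel:
    """Fit the empirical score null from randomly drawn unrelated pocket pairs.

    Pairs (i != j) are drawn with replacement from the library; the normal
    location/scale are maximum-likelihood fits per aligned-length bin.  Bins
    with fewer than ``min_samples_per_bin`` alignments inherit the pooled fit.
    Reproducible for a fixed ``seed``.
    """
    if len(pocket_library) < 2:
        raise CalibrationError("need at least two pockets to draw unrelated pairs")
    rng = np.random.default_rng(seed)
    scores_by_bin: dict[int, list[float]] = {i: [] for i in range(len(NULL_BINS))}
    all_scores: list[float] = []
    for _ in range(n_pairs):
        i = int(rng.integers(len(pocket_library)))
        j = int(rng.integers(len(pocket_library) - 1))
        if j >= i:
            j += 1
        try:
            aln = align_pockets(pocket_library[i], pocket_library[j], params)
        except AlignmentInfeasibleError:
            continue
        scores_by_bin[NullModel.bin_index(aln.aligned_length)].append(aln.score)
        all_scores.append(aln.score)
    if len(all_scores) < min_samples_per_bin:
        raise CalibrationError(
            f"only {len(all_scores)} alignable pairs; need >= {min_samples_per_bin}"
        )
    pooled_loc, pooled_scale = norm.fit(all_scores)
    loc, scale, counts = {}, {}, {}
    for b, scores in scores_by_bin.items():
        if len(scores) >= min_samples_per_bin:
            l, s = norm.fit(scores)
        else:
            l, s = pooled_loc, pooled_scale
        loc[b] = float(l)
        scale[b] = float(max(s, 1e-9))
        counts[b] = len(scores)
    return NullModel(loc=loc, scale=scale, counts=counts, seed=seed, n_pairs=n_pairs)


_ALIGNER = None


def _get_aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _ALIGNER = aligner
    return _ALIGNER


def global_sequence_identity(seq_a: str, seq_b: str) -> float:
    """Fraction identical positions over global alignment length (incl. gaps).

    Needleman-Wunsch with BLOSUM62, gap open 11 / extend 1.  Symmetric;
    identical sequences give exactly 1.0.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    valid = set("ACDEFGHIKLMNPQRSTVWYBZX*")
    sa = "".join(c if c in valid else "X" for c in seq_a.upper())
    sb = "".join(c if c in valid else "X" for c in seq_b.upper())
    if sa == sb:
        return 1.0
    aln = _get_aligner().align(sa, sb)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def chain_superposition_rmsd(chain_a, chain_b) -> float:
    """Sequence-alignment-guided Calpha superposition RMSD of two chains (A).

    Residues are paired through a global sequence alignment of the two
    chains, Calpha atoms of the aligned (non-gap) columns are superposed
    with Kabsch, and the residual RMSD is returned.  This is the standard
    way to compare the conformation of one protein solved in different
    crystallographic contexts (e.g. a monomer versus its copy in a dimer).
    """
    valid = set("ACDEFGHIKLMNPQRSTVWYBZX*")
    sa = "".join(c if c in valid else "X" for c in chain_a.sequence.upper())
    sb = "".join(c if c in valid else "X" for c in chain_b.sequence.upper())
    aln = _get_aligner().align(sa, sb)[0]
    coords_a = []
    coords_b = []
    for block_a, block_b in zip(aln.aligned[0], aln.aligned[1]):
        for ia, ib in zip(range(*block_a), range(*block_b)):
            ca_a = chain_a.residues[ia].atom("CA")
            ca_b = chain_b.residues[ib].atom("CA")
            if ca_a is not None and ca_b is not None:
                coords_a.append(ca_a.coords)
                coords_b.append(ca_b.coords)
    if len(coords_a) < 3:
        raise DegenerateInputError("fewer than 3 aligned Calpha pairs")
    _, rmsd = superpose(np.asarray(coords_a), np.asarray(coords_b))
    return rmsd
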