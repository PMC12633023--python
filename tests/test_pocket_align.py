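"""Superposition, pocket alignment, null model, sequence identity."""

import numpy as np
import pytest
from scipy.stats import kstest

from gluefinder import (
    AlignmentInfeasibleError,
    DegenerateInputError,
    align_pockets,
    fit_null_model,
    global_sequence_identity,
    superpose,
)
from gluefinder import fixtures as fx
from gluefinder.pocket_align import RigidTransform


def quaternion_superpose_rmsd(mobile, reference):
    """Independent oracle: Horn's closed-form quaternion superposition."""
    xm = mobile - mobile.mean(axis=0)
    xr = reference - reference.mean(axis=0)
    m = xm.T @ xr
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = float((xm**2).sum() + (xr**2).sum())
    msd = max((e0 - 2.0 * lam) / len(mobile), 0.0)
    return float(np.sqrt(msd))


class TestSuperpose:
    def test_identical_lists_give_identity(self):
        pts = np.random.default_rng(0).normal(size=(20, 3))
        transform, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0.0, atol=1e-9)

    def test_exact_rigid_motion_is_recovered(self):
        pts = np.random.default_rng(1).normal(size=(30, 3)) * 5
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        shift = np.array([3.0, -2.0, 7.0])
        moved = pts @ rot.T + shift
        transform, rmsd = superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.rotation, rot.T, atol=1e-9)
        back = transform.apply(moved)
        assert np.allclose(back, pts, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_quaternion_oracle_on_noisy_points(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(50, 3)) * 4
        moved = fx.random_transform(rng).apply(pts) + rng.normal(0, 0.5, size=pts.shape)
        _, rmsd = superpose(moved, pts)
        oracle = quaternion_superpose_rmsd(moved, pts)
        assert rmsd == pytest.approx(oracle, rel=0.20)

    def test_rigid_premotion_leaves_rmsd_invariant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(25, 3)) * 3
        b = a + rng.normal(0, 0.8, size=a.shape)
        _, base = superpose(a, b)
        for seed in (4, 5):
            pre = fx.random_transform(np.random.default_rng(seed))
            _, moved = superpose(pre.apply(a), b)
            assert moved == pytest.approx(base, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(DegenerateInputError):
            superpose(line, line)


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_and_inverse(self):
        rng = np.random.default_rng(8)
        t1 = fx.random_transform(rng)
        t2 = fx.random_transform(rng)
        pts = rng.normal(size=(10, 3))
        assert np.allclose(t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)))
        assert np.allclose(t1.inverse().apply(t1.apply(pts)), pts, atol=1e-9)


class TestAlignPockets:
    def test_self_alignment_is_perfect(self):
        pocket = fx.make_random_pocket(25, seed=3)
        aln = align_pockets(pocket, pocket)
        assert aln.score == pytest.approx(1.0, abs=1e-9)
        assert aln.rmsd == pytest.approx(0.0, abs=1e-9)
        assert aln.aligned_length == 25

    def test_rigid_copy_scores_one(self):
        pocket = fx.make_random_pocket(30, seed=6)
        moved, _ = fx.perturb_pocket(
            pocket, transform=fx.random_transform(np.random.default_rng(7)), seed=8
        )
        aln = align_pockets(pocket, moved)
        assert aln.score == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_homolog_mapping_recovery(self, seed):
        """Known mapping, 0.5 A noise, 20% deletions: >= 80% recovered."""
        pocket = fx.make_random_pocket(30, seed=40 + seed)
        homolog, truth = fx.perturb_pocket(
            pocket,
            mutation_rate=0.2,
            noise_sigma=0.5,
            deletion_rate=0.2,
            transform=fx.random_transform(np.random.default_rng(50 + seed)),
            seed=60 + seed,
        )
        aln = align_pockets(pocket, homolog)
        planted = set(truth.index_mapping)
        recovered = planted & set(aln.correspondence)
        assert len(recovered) / len(planted) >= 0.8

    def test_score_is_symmetric_under_role_swap(self):
        q = fx.make_random_pocket(28, seed=70)
        t, _ = fx.perturb_pocket(q, noise_sigma=0.7, mutation_rate=0.3, seed=71)
        a1 = align_pockets(q, t)
        a2 = align_pockets(t, q)
        assert a1.score == pytest.approx(a2.score, abs=1e-6)
        assert a1.aligned_length == a2.aligned_length
        assert sorted((b, a) for a, b in a1.correspondence) == sorted(a2.correspondence)

    def test_too_small_pockets_rejected(self):
        small = fx.make_random_pocket(4, seed=9)
        big = fx.make_random_pocket(20, seed=10)
        with pytest.raises(AlignmentInfeasibleError):
            align_pockets(small, big)

    def test_deterministic(self):
        q = fx.make_random_pocket(22, seed=80)
        t = fx.make_random_pocket(25, seed=81)
        a1 = align_pockets(q, t)
        a2 = align_pockets(q, t)
        assert a1.score == a2.score
        assert a1.correspondence == a2.correspondence
        assert np.array_equal(a1.transform.rotation, a2.transform.rotation)


@pytest.fixture(scope="module")
def pocket_library():
    rng = np.random.default_rng(90)
    return [
        fx.make_random_pocket(int(n), seed=int(rng.integers(2**31)))
        for n in rng.integers(15, 45, size=50)
    ]


class TestNullModel:
    def test_same_seed_reproduces_fit(self, pocket_library):
        n1 = fit_null_model(pocket_library, n_pairs=120, seed=17)
        n2 = fit_null_model(pocket_library, n_pairs=120, seed=17)
        assert n1.loc == n2.loc and n1.scale == n2.scale

    def test_p_monotone_decreasing_in_score(self, pocket_library):
        null = fit_null_model(pocket_library, n_pairs=150, seed=17)
        for length in (10, 20, 40):
            ps = [null.p_value(s, length) for s in np.linspace(0.3, 1.0, 15)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))
            assert all(0 < p <= 1 for p in ps)

    def test_planted_homologs_significant_random_pairs_not(self, pocket_library):
        null = fit_null_model(pocket_library, n_pairs=250, seed=17)
        rng = np.random.default_rng(91)
        random_ps = []
        for _ in range(120):
            i = int(rng.integers(len(pocket_library)))
            j = int(rng.integers(len(pocket_library) - 1))
            j += j >= i
            aln = align_pockets(pocket_library[i], pocket_library[j])
            random_ps.append(null.p_value(aln.score, aln.aligned_length))
        homolog_ps = []
        for i in range(15):
            q = pocket_library[i]
            t, _ = fx.perturb_pocket(
                q, mutation_rate=0.2, noise_sigma=0.5, deletion_rate=0.1,
                transform=fx.random_transform(rng), seed=int(rng.integers(2**31)),
            )
            aln = align_pockets(q, t)
            homolog_ps.append(null.p_value(aln.score, aln.aligned_length))
        assert max(homolog_ps) < 0.05
        assert np.mean(np.asarray(random_ps) >= 0.05) >= 0.9


class TestSequenceIdentity:
    def test_identical_sequences(self):
        assert global_sequence_identity("ACDEFGHIK", "ACDEFGHIK") == 1.0

    def test_unrelated_sequences_near_zero(self):
        assert global_sequence_identity("AAAAAAAA", "WWWWWWWW") < 0.05

    def test_thirty_gapless_substitutions_give_070(self):
        rng = np.random.default_rng(13)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        seq = "".join(rng.choice(list(letters), size=100))
        positions = rng.choice(100, size=30, replace=False)
        mutated = list(seq)
        for pos in positions:
            mutated[pos] = next(c for c in letters if c != seq[pos])
        assert global_sequence_identity(seq, "".join(mutated)) == pytest.approx(0.70)

    def test_symmetry_and_single_mutation_step(self):
        rng = np.random.default_rng(14)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        other = "M" + seq[1:]
        assert global_sequence_identity(seq, other) == pytest.approx(
            global_sequence_identity(other, seq)
        )
        assert global_sequence_identity(seq, other) == pytest.approx(1.0 - 1.0 / 60.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_sequence_identity("", "ACD")

    def test_homolog_fixture_hits_planted_identity(self):
        model, _ = fx.make_dimer_fixture(fx.DimerSpec(residues_per_chain=200, contacts=0, seed=15))
        homolog, _ = fx.make_homolog(model, mutation_rate=0.75, seed=16)
        ident = global_sequence_identity(model.chains[0].sequence, homolog.chains[0].sequence)
        assert ident == pytest.approx(0.25, abs=0.05)
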