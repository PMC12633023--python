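"""Template library, pose transfer, precision estimation, screening."""

import numpy as np
import pytest

from gluefinder import (
    BenchmarkTarget,
    CalibrationTable,
    GluePrediction,
    ScreenConfig,
    build_catalog,
    build_template_library,
    com_deviation,
    default_calibration_table,
    estimate_precision,
    fit_null_model,
    ligand_exposure_fraction,
    run_benchmark,
    screen_target,
    steric_clash_count,
    summarize_screen,
    transfer_pose,
)
from gluefinder import fixtures as fx
from gluefinder.glue_screen import TemplateRecord
from gluefinder.pocket_align import align_pockets
from gluefinder.structure_io import Atom, Chain, LigandInstance, Residue, StructureModel


@pytest.fixture(scope="module")
def small_bench():
    """6 cage targets with remote-homolog templates and 3 decoys."""
    bench = fx.make_benchmark_set(n_targets=6, seed=21, n_decoys=3)
    library = build_template_library(bench.template_models + bench.decoy_models)
    null = fit_null_model([r.pocket for r in library], n_pairs=200, seed=17)
    return bench, library, null


class TestTemplateLibrary:
    def test_glue_fixture_yields_one_record(self, glue_case):
        _, _, homolog, _ = glue_case
        library = build_template_library([homolog])
        assert len(library) == 1
        record = library[0]
        assert record.ligand_code == "LG0"
        assert len(record.sequences) == 2
        assert len(record.pocket) >= 10

    def test_library_build_is_deterministic(self, glue_case):
        _, _, homolog, _ = glue_case
        lib1 = build_template_library([homolog])
        lib2 = build_template_library([homolog])
        assert [(r.entry_id, r.ligand_code) for r in lib1] == [
            (r.entry_id, r.ligand_code) for r in lib2
        ]
        assert np.array_equal(lib1[0].pocket.coords, lib2[0].pocket.coords)

    def test_monomer_ligand_gets_exposure_annotation(self):
        model, _ = fx.make_cavity_fixture((5.0, 6.0, 6.0))
        buried = LigandInstance(
            "BUR",
            Residue("L", 1, "", "BUR",
                    [Atom("C", f"C{i+1}", np.array([2.5, 3.0, 3.0]) + off)
                     for i, off in enumerate([np.zeros(3), np.array([1.0, 0, 0])])],
                    False),
        )
        model.ligands.append(buried)
        library = build_template_library([model])
        assert len(library) == 1
        assert library[0].exposure is not None
        assert library[0].exposure < 0.05


class TestExposure:
    def test_isolated_ligand_fully_exposed(self):
        lig = LigandInstance(
            "ISO", Residue("L", 1, "", "ISO", [Atom("C", "C1", np.zeros(3))], False)
        )
        empty = StructureModel("EMPTY", [], [lig])
        assert ligand_exposure_fraction(lig, empty) == pytest.approx(1.0)

    def test_enclosed_ligand_is_buried(self):
        model, _ = fx.make_cavity_fixture((5.0, 5.0, 5.0))
        lig = LigandInstance(
            "BUR",
            Residue("L", 1, "", "BUR",
                    [Atom("C", "C1", np.array([2.5, 2.5, 2.5]))], False),
        )
        assert ligand_exposure_fraction(lig, model) < 0.05

    def test_fraction_bounded(self, glue_case):
        target, truth, _, _ = glue_case
        frac = ligand_exposure_fraction(truth.native_ligand, target)
        assert 0.0 <= frac <= 1.0


class TestPoseTransfer:
    def test_self_template_transfers_identically(self, glue_case):
        target, truth, _, _ = glue_case
        library = build_template_library([target])
        aln = align_pockets(library[0].pocket, library[0].pocket)
        pose = transfer_pose(library[0], aln)
        assert com_deviation(pose, truth.native_ligand) == pytest.approx(0.0, abs=1e-9)

    def test_pre_rotated_template_gives_same_pose(self, glue_case):
        target, truth, homolog, _ = glue_case
        library = build_template_library([target])
        record = library[0]
        pre = fx.random_transform(np.random.default_rng(99))
        rotated = TemplateRecord(
            entry_id="ROT",
            pocket=type(record.pocket)(
                record.pocket.residue_keys,
                pre.apply(record.pocket.coords),
                record.pocket.sequence,
            ),
            ligand_code=record.ligand_code,
            ligand_pose=record.ligand_pose.transformed(pre.rotation, pre.translation),
            sequences=record.sequences,
        )
        query = record.pocket
        pose_a = transfer_pose(record, align_pockets(query, record.pocket))
        pose_b = transfer_pose(rotated, align_pockets(query, rotated.pocket))
        assert np.allclose(pose_a.coords(), pose_b.coords(), atol=1e-6)

    def test_homolog_transfer_lands_near_truth(self, glue_case):
        target, truth, homolog, _ = glue_case
        library = build_template_library([homolog])
        query = build_template_library([target])[0].pocket
        aln = align_pockets(query, library[0].pocket)
        pose = transfer_pose(library[0], aln)
        assert com_deviation(pose, truth.native_ligand) < 2.0


class TestGeometryChecks:
    def test_clash_counts(self, glue_case):
        target, truth, _, _ = glue_case
        native = truth.native_ligand
        far = native.transformed(np.eye(3), np.array([100.0, 0, 0]))
        assert steric_clash_count(far, target) == 0
        onto_atom = native.transformed(
            np.eye(3),
            target.chains[0].residues[0].atoms[0].coords - native.coords()[0],
        )
        assert steric_clash_count(onto_atom, target) >= 1

    def test_clash_matches_brute_force(self, glue_case):
        target, truth, _, _ = glue_case
        pose = truth.native_ligand.transformed(np.eye(3), np.array([2.0, 1.0, 0.0]))
        prot = target.polymer_coords()
        brute = int(
            (np.linalg.norm(pose.coords()[:, None, :] - prot[None, :, :], axis=2) < 1.5).sum()
        )
        assert steric_clash_count(pose, target, overlap=1.5) == brute

    def test_com_deviation_analytic(self, glue_case):
        _, truth, _, _ = glue_case
        native = truth.native_ligand
        assert com_deviation(native, native) == 0.0
        shifted = native.transformed(np.eye(3), np.array([3.0, 0.0, 0.0]))
        assert com_deviation(native, shifted) == pytest.approx(3.0)
        rng = np.random.default_rng(4)
        other = native.transformed(np.eye(3), rng.normal(size=3))
        brute = float(np.linalg.norm(native.coords().mean(0) - other.coords().mean(0)))
        assert com_deviation(native, other) == pytest.approx(brute)


class TestPrecision:
    def test_clash_limit_disqualifies(self):
        assert estimate_precision(0.99, 1e-12, 0.2, clash_count=6) == 0.0
        assert estimate_precision(0.99, 1e-12, 0.2, clash_count=5) > 0.0

    def test_perfect_match_hits_table_maximum(self):
        table = default_calibration_table()
        assert estimate_precision(1.0, 1e-16, 0.0, 0) == table.values.max()

    def test_monotone_in_score_and_p(self):
        table = default_calibration_table()
        for p in (1e-10, 0.01, 0.5):
            vals = [table.lookup(s, p) for s in np.linspace(0.3, 1.0, 20)]
            assert all(a <= b for a, b in zip(vals, vals[1:]))
        for s in (0.6, 0.8, 0.95):
            vals = [table.lookup(s, p) for p in np.logspace(-12, 0, 20)]
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_calibration_by_construction(self):
        """Fitted bin estimates track empirical positive fractions."""
        scores, ps, labels, _ = fx.make_calibration_set(
            n_positive=250, n_negative=250, seed=11, n_pockets=60, null_pairs=400
        )
        table = CalibrationTable.from_labeled(scores, ps, labels)
        si = np.searchsorted(table.score_edges, scores, side="right")
        pj = np.searchsorted(table.p_edges, ps, side="right")
        combined = si + (len(table.p_edges) - pj)
        for c in np.unique(combined):
            mask = combined == c
            if mask.sum() >= 30:
                estimate = np.mean(
                    [table.lookup(s, p) for s, p in zip(scores[mask], ps[mask])]
                )
                assert abs(estimate - labels[mask].mean()) <= 0.05


class TestScreenTarget:
    def test_remote_template_ranks_its_ligand_first(self, small_bench):
        bench, library, null = small_bench
        target, truth = bench.targets[0]
        config = ScreenConfig(p_cutoff=0.05, identity_cutoff=0.30)
        predictions = screen_target(target, library, config, null)
        assert predictions
        assert predictions[0].ligand_code == truth.native_ligand.code
        assert predictions[0].best_p_value <= 0.05
        assert predictions[0].max_identity <= 0.30

    def test_high_identity_template_excluded(self, glue_case):
        target, truth, _, _ = glue_case
        near, _ = fx.make_homolog(
            target, mutation_rate=0.02, noise_sigma=0.3,
            transform=fx.random_transform(np.random.default_rng(3)),
            seed=4, entry_id="NEAR",
        )
        library = build_template_library([near])
        null = fit_null_model(
            [library[0].pocket, fx.make_random_pocket(30, seed=5),
             fx.make_random_pocket(35, seed=6), fx.make_random_pocket(25, seed=7)],
            n_pairs=100, seed=17,
        )
        open_cfg = ScreenConfig(p_cutoff=0.05, identity_cutoff=None)
        hits = screen_target(target, library, open_cfg, null)
        assert any(g.ligand_code == truth.native_ligand.code for g in hits)
        strict = ScreenConfig(p_cutoff=0.05, identity_cutoff=0.30)
        assert screen_target(target, library, strict, null) == []

    def test_empty_library_is_a_configuration_error(self, glue_case):
        target, _, _, _ = glue_case
        with pytest.raises(ValueError):
            screen_target(target, [], ScreenConfig())

    def test_self_recovery_with_own_template(self, small_bench):
        """Own pocket+ligand in the library, no identity cutoff: the native
        ligand comes back with zero CoM deviation and the best p-value."""
        bench, library, null = small_bench
        target, truth = bench.targets[1]
        self_lib = build_template_library([target]) + list(library)
        config = ScreenConfig(p_cutoff=0.05, identity_cutoff=None)
        predictions = screen_target(target, self_lib, config, null)
        native = next(g for g in predictions if g.ligand_code == truth.native_ligand.code)
        best_dev = min(com_deviation(p, truth.native_ligand) for p in native.poses)
        assert best_dev == pytest.approx(0.0, abs=1e-6)
        assert native.best_p_value <= min(g.best_p_value for g in predictions)

    def test_filter_nesting(self, small_bench):
        bench, library, null = small_bench
        target, _ = bench.targets[2]
        tight = screen_target(
            target, library, ScreenConfig(p_cutoff=0.01, identity_cutoff=0.30), null
        )
        loose = screen_target(
            target, library, ScreenConfig(p_cutoff=0.05, identity_cutoff=0.40), null
        )
        assert {g.ligand_code for g in tight} <= {g.ligand_code for g in loose}


class TestBenchmark:
    def test_synthetic_benchmark_full_recall(self, small_bench):
        bench, library, null = small_bench
        targets = [
            BenchmarkTarget(m, t.native_ligand.code, t.native_ligand)
            for m, t in bench.targets
        ]
        conditions = [(0.05, 0.3), (0.05, 0.7), (0.01, 0.3)]
        report = run_benchmark(targets, library, conditions, null_model=null)
        loose = report.by_condition(0.05, 0.7)
        assert loose.recall == 1.0
        assert loose.mean_com_deviation < 2.0
        # nested filters: p<=0.01 recall cannot exceed p<=0.05 recall
        assert report.by_condition(0.01, 0.3).recall <= report.by_condition(0.05, 0.3).recall
        # looser identity cutoff cannot lower recall
        assert report.by_condition(0.05, 0.3).recall <= report.by_condition(0.05, 0.7).recall

    def test_benchmark_deterministic(self, small_bench):
        bench, library, null = small_bench
        targets = [
            BenchmarkTarget(m, t.native_ligand.code, t.native_ligand)
            for m, t in bench.targets[:3]
        ]
        r1 = run_benchmark(targets, library, [(0.05, 0.5)], null_model=null)
        r2 = run_benchmark(targets, library, [(0.05, 0.5)], null_model=null)
        assert r1 == r2


class TestScreenSummary:
    def _prediction(self, code, precision):
        pose = LigandInstance(
            code, Residue("L", 1, "", code, [Atom("C", "C1", np.zeros(3))], False)
        )
        return GluePrediction(
            ligand_code=code, poses=[pose], best_score=0.9, best_p_value=1e-6,
            max_identity=0.2, precision=precision, clash_count=0,
        )

    def test_no_prediction_meets_threshold(self):
        preds = {"T1": [self._prediction("AAA", 0.05)], "T2": []}
        summary = summarize_screen(preds, precision_threshold=0.15)
        assert summary.fraction_with_predictions == 0.0
        assert summary.mean_precision is None

    def test_known_catalog_fraction(self):
        model, _ = fx.make_dimer_fixture(
            fx.DimerSpec(residues_per_chain=30, contacts=6,
                         ligands=[fx.PlantedLigand("AAA", 6, 5)], seed=30)
        )
        catalog = build_catalog([model])
        preds = {"T1": [self._prediction("AAA", 0.5)]}
        summary = summarize_screen(preds, 0.15, catalog)
        assert summary.known_iap_fraction == 1.0

    def test_four_of_five_targets_pass(self):
        preds = {
            f"T{i}": [self._prediction("AAA", 0.3 + 0.1 * i)] for i in range(4)
        }
        preds["T4"] = [self._prediction("BBB", 0.01)]
        summary = summarize_screen(preds, precision_threshold=0.15)
        assert summary.fraction_with_predictions == pytest.approx(0.8)
        assert summary.max_best_precision == pytest.approx(0.6)
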