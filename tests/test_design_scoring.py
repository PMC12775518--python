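import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import brute_force_rmsd
from solenoidforge import (
    RedesignResult,
    RepeatSpec,
    SolenoidClass,
    evaluate_cap_filter,
    is_designable_backbone,
    kabsch_rmsd,
    passes_design_threshold,
    rank_redesigns,
    solenoid_score,
)
from solenoidforge.design_scoring import FitnessReport
from solenoidforge.errors import (
    IncompleteReportError,
    InvalidInputError,
    InvalidStateError,
)
from solenoidforge.oracle_interfaces import SolenoidProfile, ScriptedCapPredictor


def _profile(rows):
    return SolenoidProfile(probabilities=np.asarray(rows, dtype=float))


def _report(per_model, solenoid):
    return FitnessReport(
        plddt_mean=float(np.mean(per_model)),
        solenoid_score=solenoid,
        per_model_plddt=tuple(per_model),
        passes=False,
    )


class TestSolenoidScore:
    def test_all_residues_target(self):
        p = _profile([[0.0, 1.0, 0.0, 0.0]] * 5)
        assert solenoid_score([p], SolenoidClass.BETA) == 1.0

    def test_counting_fraction(self):
        rows = [[0.0, 1.0, 0.0, 0.0]] * 6 + [[1.0, 0.0, 0.0, 0.0]] * 4
        assert solenoid_score([_profile(rows)], SolenoidClass.BETA) == pytest.approx(0.6)

    def test_mean_over_models(self):
        a = _profile([[0.0, 1.0, 0.0, 0.0]] * 4 + [[1.0, 0.0, 0.0, 0.0]] * 6)  # 0.4
        b = _profile([[0.0, 1.0, 0.0, 0.0]] * 8 + [[1.0, 0.0, 0.0, 0.0]] * 2)  # 0.8
        assert solenoid_score([a, b], SolenoidClass.BETA) == pytest.approx(0.6)

    def test_permutation_invariant_over_residues(self, rng):
        probs = rng.dirichlet(np.ones(4), size=20)
        p = _profile(probs)
        shuffled = _profile(probs[rng.permutation(20)])
        for cls in SolenoidClass:
            assert solenoid_score([p], cls) == solenoid_score([shuffled], cls)

    def test_argmax_tie_breaks_to_lowest_class_index(self):
        p = _profile([[0.25, 0.25, 0.25, 0.25]])
        assert solenoid_score([p], SolenoidClass.ALPHA) == 1.0
        assert solenoid_score([p], SolenoidClass.BETA) == 0.0

    def test_empty_profile_list_raises(self):
        with pytest.raises(InvalidInputError):
            solenoid_score([], SolenoidClass.ALPHA)


class TestDesignThreshold:
    SPEC_BETA = RepeatSpec(25, 6, SolenoidClass.BETA)
    SPEC_AB = RepeatSpec(25, 6, SolenoidClass.ALPHABETA)

    @pytest.mark.parametrize(
        "per_model,solenoid,spec,expected",
        [
            ((0.71, 0.72, 0.73, 0.74, 0.75), 0.65, SPEC_BETA, True),
            ((0.69, 0.9, 0.9, 0.9, 0.9), 0.9, SPEC_BETA, False),  # one model below
            ((0.9,) * 5, 0.65, SPEC_AB, False),  # alphabeta needs >= 0.7
            ((0.9,) * 5, 0.70, SPEC_AB, True),
            ((0.70,) * 5, 0.9, SPEC_BETA, False),  # strictly above 0.70
            ((0.9,) * 5, 0.60, SPEC_BETA, True),  # score gate inclusive
        ],
    )
    def test_truth_table(self, per_model, solenoid, spec, expected):
        assert passes_design_threshold(_report(per_model, solenoid), spec) is expected

    def test_missing_models_raise(self):
        with pytest.raises(InvalidStateError):
            passes_design_threshold(_report((0.9, 0.9), 0.9), self.SPEC_BETA)


class TestKabschRmsd:
    def test_identical_sets_zero(self, rng):
        a = rng.normal(size=(8, 3))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_transform_invariance(self, rng):
        a = rng.normal(size=(10, 3))
        r = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        b = a @ r.T + np.array([5.0, -3.0, 2.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-8)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-12)

    def test_invariant_under_joint_rigid_motion(self, rng):
        a, b = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        r = Rotation.random(random_state=3).as_matrix()
        t = np.array([1.0, 2.0, -4.0])
        assert kabsch_rmsd(a @ r.T + t, b @ r.T + t) == pytest.approx(
            kabsch_rmsd(a, b), abs=1e-9
        )

    def test_mirror_image_not_zero(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mirrored = a * np.array([1.0, 1.0, -1.0])
        assert kabsch_rmsd(a, mirrored) > 0.1

    def test_single_moved_point_matches_brute_force(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        b = a.copy()
        b[3] = [0, 0, 1.5]
        assert kabsch_rmsd(a, b) == pytest.approx(brute_force_rmsd(a, b), abs=1e-6)

    def test_matches_brute_force_oracle(self, rng):
        for i in range(25):
            n = int(rng.integers(4, 11))
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            assert kabsch_rmsd(a, b) == pytest.approx(
                brute_force_rmsd(a, b, seed=i), abs=1e-4
            )

    def test_shape_errors(self):
        with pytest.raises(InvalidInputError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(InvalidInputError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDesignability:
    @pytest.mark.parametrize(
        "rmsd,plddt,expected",
        [
            (4.9, 0.81, True),
            (5.1, 0.95, False),  # RMSD gate strict
            (5.0, 0.95, False),
            (4.0, 0.80, False),  # pLDDT gate strict
        ],
    )
    def test_designable_boundaries(self, rmsd, plddt, expected):
        result = RedesignResult(sequence="A" * 10, mean_plddt=plddt, rmsd_to_parent=rmsd)
        assert result.designable is expected

    def test_any_designable_suffices(self):
        bad = RedesignResult("A", 0.5, 9.0)
        good = RedesignResult("D", 0.9, 1.0)
        assert is_designable_backbone([bad] * 19 + [good]) is True
        assert is_designable_backbone([bad] * 20) is False
        assert is_designable_backbone([good] * 3) is True

    def test_empty_results_raise(self):
        with pytest.raises(InvalidInputError):
            is_designable_backbone([])

    def test_rank_redesigns_orders_designable_first(self):
        from solenoidforge.fixtures import canonical_coords
        from solenoidforge.oracle_interfaces import OracleEnsemble, StructurePrediction

        backbone = canonical_coords(30)

        class StubPredictor:
            """Prescribed (pLDDT, axial shift) per sequence index."""

            script = {"A": (0.9, 0.0), "D": (0.9, 1.0), "E": (0.5, 0.5), "F": (0.95, 9.0)}

            def predict(self, sequence, mode="repredict"):
                plddt, shift = self.script[sequence[0]]
                coords = backbone + np.array([shift, 0.0, 0.0])
                n = len(sequence)
                preds = tuple(
                    StructurePrediction(
                        model_id=m + 1,
                        ca_coords=coords,
                        plddt=np.full(n, plddt),
                        pae=np.zeros((n, n)),
                        ptm=plddt,
                    )
                    for m in range(5)
                )
                return OracleEnsemble(predictions=preds)

        seqs = [aa * 30 for aa in "ADEF"]
        ranked = rank_redesigns(backbone, seqs, StubPredictor())
        # A and D are designable (rigid shifts superpose to RMSD 0);
        # E fails pLDDT, F fails nothing? F has a 9 Å rigid shift that
        # superposition removes, so only E is non-designable.
        flags = [r.designable for r in ranked]
        assert flags == sorted(flags, reverse=True)
        assert ranked[-1].sequence.startswith("E")
        # descending pLDDT within the designable block
        designable_plddts = [r.mean_plddt for r in ranked if r.designable]
        assert designable_plddts == sorted(designable_plddts, reverse=True)


class TestCapFilter:
    def test_all_gates_pass(self):
        report = evaluate_cap_filter(1.9, 4.9, 4.9, 0.81, 0.81, succ50=0.72)
        assert report.passes_structural is True
        assert report.passes_final is True

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rmsd_to_backbone=2.0),  # exact boundary fails
            dict(mean_pae_full=5.0),
            dict(mean_pae_terminal=5.0),
            dict(plddt_predictor_a=0.80),
            dict(plddt_predictor_b=0.80),
        ],
    )
    def test_structural_boundaries_fail(self, kwargs):
        base = dict(
            rmsd_to_backbone=1.0,
            mean_pae_full=3.0,
            mean_pae_terminal=3.0,
            plddt_predictor_a=0.9,
            plddt_predictor_b=0.9,
        )
        base.update(kwargs)
        assert evaluate_cap_filter(**base).passes_structural is False

    def test_succ50_boundary_strict(self):
        assert evaluate_cap_filter(1.0, 3.0, 3.0, 0.9, 0.9, succ50=0.71).passes_final is False
        assert evaluate_cap_filter(1.0, 3.0, 3.0, 0.9, 0.9, succ50=0.711).passes_final is True

    def test_missing_succ50_raises_when_final_requested(self):
        with pytest.raises(IncompleteReportError):
            evaluate_cap_filter(1.0, 3.0, 3.0, 0.9, 0.9, require_final=True)

    def test_gates_are_pure(self):
        a = evaluate_cap_filter(1.5, 4.0, 4.5, 0.85, 0.83, succ50=0.75)
        b = evaluate_cap_filter(1.5, 4.0, 4.5, 0.85, 0.83, succ50=0.75)
        assert (a.passes_structural, a.passes_final) == (b.passes_structural, b.passes_final)
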