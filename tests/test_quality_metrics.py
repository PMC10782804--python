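"""Structural quality labels (fnat, DockQ, Kabsch) and ranking metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import roc_auc_score

from dockgraph.errors import (
    DegenerateLabelsError,
    InsufficientPointsError,
    NoNativeContactsError,
)
from dockgraph.quality_metrics import (
    QualityRecord,
    classification_metrics,
    dockq,
    fnat,
    kabsch_superpose,
    native_contacts,
    rank_records,
    roc_curve_interpolated,
    success_rate,
)
from dockgraph.structure_io import min_heavy_atom_distance
from dockgraph.synthetic_data import DecoyLadderSpec, generate_complex, generate_decoys

from conftest import two_residue_complex


class TestNativeContacts:
    def test_separated_chains_have_none(self):
        assert native_contacts(two_residue_complex(20.0)) == set()

    def test_single_pair_at_three_angstroms(self):
        contacts = native_contacts(two_residue_complex(3.0))
        assert contacts == {(("A", 1, ""), ("B", 1, ""))}

    def test_matches_bruteforce_enumeration(self):
        _, cplx, _ = generate_complex(12, seed=8)
        a, b = (cplx.chains[c] for c in cplx.chain_ids)
        brute = {(ra.key, rb.key) for ra in a for rb in b
                 if min_heavy_atom_distance(ra, rb) <= 5.0}
        assert native_contacts(cplx) == brute


class TestFnat:
    def test_reference_against_itself_is_one(self):
        _, cplx, _ = generate_complex(10, seed=9)
        assert fnat(cplx, cplx) == 1.0

    def test_separated_model_is_zero(self):
        _, cplx, _ = generate_complex(10, seed=9)
        far = cplx.transformed(np.eye(3), np.array([50.0, 0, 0]), chains={"B"})
        assert fnat(far, cplx) == 0.0

    def test_no_native_contacts_raises(self):
        with pytest.raises(NoNativeContactsError, match="no native contacts"):
            fnat(two_residue_complex(20.0), two_residue_complex(20.0))

    def test_ladder_values_equal_contact_set_arithmetic(self):
        _, ref, _ = generate_complex(12, seed=10)
        decoys, table = generate_decoys(ref, DecoyLadderSpec(n_decoys=6, seed=1))
        ref_contacts = native_contacts(ref)
        for (did, decoy), row in zip(decoys, table.itertuples()):
            expected = len(native_contacts(decoy) & ref_contacts) / len(ref_contacts)
            assert row.fnat == pytest.approx(expected)

    def test_invariant_under_joint_rigid_motion(self):
        _, ref, _ = generate_complex(10, seed=12)
        decoys, _ = generate_decoys(ref, DecoyLadderSpec(n_decoys=3, seed=2))
        model = decoys[1][1]
        rot = Rotation.from_rotvec([0.4, 0.1, -0.9]).as_matrix()
        moved = model.transformed(rot, np.array([7.0, -1.0, 4.0]))  # both chains
        assert fnat(moved, ref) == pytest.approx(fnat(model, ref))


class TestKabsch:
    def test_identical_point_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_a_known_rotation(self, rng):
        pts = rng.normal(size=(12, 3))
        true_rot = Rotation.from_rotvec([0.7, -0.3, 1.2]).as_matrix()
        moved = pts @ true_rot.T + np.array([3.0, 4.0, -1.0])
        rot, trans, rmsd = kabsch_superpose(pts, moved)
        np.testing.assert_allclose(rot @ true_rot, np.eye(3), atol=1e-6)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        # transform really maps b onto a
        np.testing.assert_allclose(moved @ rot.T + trans, pts, atol=1e-9)

    def test_rmsd_equals_direct_recomputation(self, rng):
        a = rng.normal(size=(8, 3))
        b = a + 0.3 * rng.normal(size=(8, 3))
        rot, trans, rmsd = kabsch_superpose(a, b)
        direct = np.sqrt((((b @ rot.T + trans) - a) ** 2).sum(axis=1).mean())
        assert rmsd == pytest.approx(direct, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDockq:
    def test_reference_scores_one(self):
        _, cplx, _ = generate_complex(10, seed=13)
        q = dockq(cplx, cplx)
        assert q["dockq"] == pytest.approx(1.0)
        assert q["fnat"] == 1.0
        assert q["irmsd"] == pytest.approx(0.0, abs=1e-6)
        assert q["lrmsd"] == pytest.approx(0.0, abs=1e-6)

    def test_formula_from_components(self):
        _, ref, _ = generate_complex(12, seed=14)
        decoys, _ = generate_decoys(ref, DecoyLadderSpec(n_decoys=8, seed=3))
        for _, decoy in decoys[1:4]:
            q = dockq(decoy, ref)
            expected = (q["fnat"] + 1 / (1 + (q["irmsd"] / 1.5) ** 2)
                        + 1 / (1 + (q["lrmsd"] / 8.5) ** 2)) / 3
            assert q["dockq"] == pytest.approx(expected)

    def test_limit_of_far_separated_model(self):
        _, ref, _ = generate_complex(10, seed=15)
        far = ref.transformed(np.eye(3), np.array([500.0, 0, 0]), chains={"B"})
        q = dockq(far, ref)
        assert q["fnat"] == 0.0
        assert q["dockq"] < 0.02


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        _, auc = roc_curve_interpolated(scores, labels)
        assert auc == pytest.approx(1.0, abs=1e-9)  # vertex-refined grid is exact

    def test_equals_rank_sum_auc_on_random_inputs(self, rng):
        for n in (20, 100, 500):
            scores = rng.normal(size=n)
            labels = (rng.random(n) < 0.4).astype(int)
            labels[0], labels[1] = 0, 1  # both classes present
            _, auc = roc_curve_interpolated(scores, labels)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-3)

    def test_handles_tied_scores_atomically(self, rng):
        scores = np.repeat([0.9, 0.5, 0.1], 10)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        _, auc = roc_curve_interpolated(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-3)

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(size=400)
        labels = np.array([0, 1] * 200)
        _, auc = roc_curve_interpolated(scores, labels)
        assert abs(auc - 0.5) < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc_curve_interpolated(np.array([0.1, 0.2]), np.array([1, 1]))


class TestClassificationMetrics:
    def test_all_correct(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        m = classification_metrics(scores, labels)
        assert m["precision"] == m["recall"] == m["f1"] == m["mcc"] == 1.0

    def test_perfect_continuous_agreement(self):
        y = np.array([0.1, 0.4, 0.9])
        m = classification_metrics(y, (y > 0.5).astype(int), targets=y)
        assert m["r2"] == pytest.approx(1.0)
        assert m["pearson"] == pytest.approx(1.0)

    def test_hand_computed_confusion_table(self):
        # TP=3, FP=1, FN=2, TN=4
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        scores = np.array([.9, .9, .9, .1, .1, .9, .1, .1, .1, .1])
        m = classification_metrics(scores, labels)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.6)
        assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        mcc = (3 * 4 - 1 * 2) / np.sqrt((3 + 1) * (3 + 2) * (4 + 1) * (4 + 2))
        assert m["mcc"] == pytest.approx(mcc)
        assert m["accuracy"] == pytest.approx(0.7)


class TestSuccessRate:
    def _records(self, hits_top1, n_complexes=13, per_complex=4):
        records = []
        for c in range(n_complexes):
            for d in range(per_complex):
                near = (d == 0 and c < hits_top1) or d == per_complex - 1
                records.append(QualityRecord(
                    graph_id=f"c{c}_d{d}", complex_id=f"c{c}",
                    fnat=0.0, dockq=0.5 if near else 0.0,
                    predicted_score=1.0 - 0.1 * d))
        return rank_records(records)

    def test_every_top1_near_native(self):
        records = self._records(hits_top1=13)
        assert success_rate(records, 1) == 100.0

    def test_no_near_native_anywhere(self):
        records = [QualityRecord(f"g{i}", f"c{i % 3}", 0.0, 0.0, float(i))
                   for i in range(9)]
        for k in (1, 5, 20):
            assert success_rate(rank_records(records), k) == 0.0

    def test_two_of_thirteen_top1(self):
        records = self._records(hits_top1=2)
        assert success_rate(records, 1) == pytest.approx(100 * 2 / 13)

    def test_non_decreasing_in_k(self):
        records = self._records(hits_top1=5)
        rates = [success_rate(records, k) for k in (1, 5, 20, 50)]
        assert rates == sorted(rates)

    def test_ranks_form_permutation_with_lexicographic_ties(self):
        records = rank_records([
            QualityRecord("b", "c", 0, 0, 0.5), QualityRecord("a", "c", 0, 0, 0.5),
            QualityRecord("z", "c", 0, 0, 0.9)])
        by_id = {r.graph_id: r.rank for r in records}
        assert by_id == {"z": 1, "a": 2, "b": 3}
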