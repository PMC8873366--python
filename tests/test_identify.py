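import numpy as np
import pandas as pd
import pytest

import nirsprint as nz
from nirsprint.identify import (
    ModeSpec,
    cross_task_matrix,
    cross_view_matrix,
    predict_identity,
    run_mode,
    similarity,
    summarize,
)

from conftest import make_bfn


def brute_force_predict(target, source_set):
    """Exhaustive similarity scan, independent of the argmax implementation."""
    iu = np.triu_indices(target.n_channels, 1)
    best, best_sim = None, -2.0
    for s in source_set:
        r = float(np.corrcoef(target.weights[iu], s.weights[iu])[0, 1])
        if r > best_sim:
            best, best_sim = s.subject_id, r
    return best


class TestSimilarity:
    def test_self_similarity_is_one(self):
        b = make_bfn([0.1, -0.4, 0.7])
        assert similarity(b, b) == pytest.approx(1.0)

    def test_affine_transform_of_edges_gives_one(self):
        a = make_bfn([0.1, 0.2, 0.3])
        b = make_bfn([0.25, 0.45, 0.65])  # 2x + 0.05
        assert similarity(a, b) == pytest.approx(1.0)

    def test_reversed_edges_give_minus_one(self):
        a = make_bfn([0.1, 0.2, 0.3])
        b = make_bfn([0.3, 0.2, 0.1])
        assert similarity(a, b) == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a = make_bfn(rng.uniform(-0.5, 0.5, 10))
        b = make_bfn(rng.uniform(-0.5, 0.5, 10))
        assert similarity(a, b) == pytest.approx(similarity(b, a))

    def test_constant_edges_rejected(self):
        a = make_bfn([0.2, 0.2, 0.2])
        b = make_bfn([0.1, 0.3, 0.5])
        with pytest.raises(ValueError, match="zero variance"):
            similarity(a, b)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            similarity(make_bfn([0.1]), make_bfn([0.1, 0.2, 0.3]))

    def test_full_vectorization_differs_from_upper(self):
        rng = np.random.default_rng(1)
        a = make_bfn(rng.uniform(-0.5, 0.5, 10))
        b = make_bfn(rng.uniform(-0.5, 0.5, 10))
        assert similarity(a, b, "full") != pytest.approx(similarity(a, b, "upper"))


class TestPredictIdentity:
    def test_exact_match_wins(self):
        rng = np.random.default_rng(2)
        sources = [
            make_bfn(rng.uniform(-0.5, 0.5, 6), subject=f"S{i}") for i in range(5)
        ]
        target = make_bfn(sources[3].weights[np.triu_indices(4, 1)], subject="S3")
        assert predict_identity(target, sources) == "S3"

    def test_single_source_always_predicted(self):
        target = make_bfn([0.5, -0.5, 0.1], subject="T")
        source = make_bfn([-0.1, 0.2, 0.4], subject="ONLY")
        assert predict_identity(target, [source]) == "ONLY"

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            sources = [
                make_bfn(rng.uniform(-0.9, 0.9, 15), subject=f"S{i}")
                for i in range(8)
            ]
            target = make_bfn(rng.uniform(-0.9, 0.9, 15))
            assert predict_identity(target, sources) == brute_force_predict(
                target, sources
            )

    def test_duplicate_subject_ids_rejected(self):
        b = make_bfn([0.1, 0.2, 0.3], subject="S1")
        with pytest.raises(ValueError, match="duplicate"):
            predict_identity(b, [b, b])

    def test_tie_warns_and_picks_earliest(self):
        pattern = [0.1, 0.2, 0.3]
        s1 = make_bfn(pattern, subject="S1")
        s2 = make_bfn(pattern, subject="S2")
        target = make_bfn(pattern, subject="T")
        with pytest.warns(UserWarning, match="tie"):
            assert predict_identity(target, [s1, s2]) == "S1"


def toy_cohort(n=3, seed=0, classes=("RHT", "LHT", "FT", "REST")):
    """FingerprintSets with independent random fingerprints per class/view."""
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n):
        for view in (nz.OXY, nz.DEOXY):
            fps = {
                c: make_bfn(
                    rng.uniform(-0.8, 0.8, 45), subject=f"S{i}", view=view, label=c
                )
                for c in classes
            }
            sets.append(
                nz.FingerprintSet(subject_id=f"S{i}", view=view, fingerprints=fps)
            )
    return sets


class TestRunMode:
    def test_self_match_accuracy_is_exactly_one(self):
        sets = toy_cohort()
        res = run_mode(ModeSpec("RHT", "RHT"), sets)
        assert res.accuracy == 1.0
        assert res.n_correct == 3

    def test_zero_accuracy_when_targets_swap(self):
        a = [0.1, 0.2, 0.3, -0.5, 0.4, 0.0]
        b = [0.3, -0.2, 0.1, 0.5, -0.4, 0.2]
        sets = []
        for sid, src, tgt in (("S0", a, b), ("S1", b, a)):
            sets.append(
                nz.FingerprintSet(
                    subject_id=sid,
                    view=nz.OXY,
                    fingerprints={
                        "RHT": make_bfn(src, subject=sid, label="RHT"),
                        "LHT": make_bfn(tgt, subject=sid, label="LHT"),
                    },
                )
            )
        res = run_mode(ModeSpec("RHT", "LHT"), sets)
        assert res.accuracy == 0.0
        assert res.predictions == {"S0": "S1", "S1": "S0"}

    def test_similarity_table_shape_and_labels(self):
        sets = toy_cohort(n=4)
        res = run_mode(ModeSpec("FT", "REST"), sets)
        assert res.similarity_table.shape == (4, 4)
        assert list(res.similarity_table.index) == [f"S{i}" for i in range(4)]

    def test_missing_fingerprint_names_subject_and_class(self):
        sets = toy_cohort()
        del sets[0].fingerprints["FT"]
        with pytest.raises(ValueError, match="'FT'"):
            run_mode(ModeSpec("FT", "REST"), sets)

    def test_missing_view_named(self):
        sets = [s for s in toy_cohort() if s.view == nz.OXY]
        with pytest.raises(ValueError, match="DEOXY"):
            run_mode(ModeSpec("RHT", "LHT", target_view=nz.DEOXY), sets)


class TestAccuracyMatrices:
    def test_sixteen_cells_with_unit_diagonal(self):
        sets = toy_cohort(n=5, seed=4)
        m = cross_task_matrix(sets, nz.OXY)
        assert m.shape == (4, 4)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)
        assert m.index.name == "target"
        assert m.columns.name == "source"

    def test_cross_view_with_same_view_reduces_to_cross_task(self, small_cohort_sets):
        ct = cross_task_matrix(small_cohort_sets, nz.OXY)
        cv = cross_view_matrix(small_cohort_sets, nz.OXY, nz.OXY)
        pd.testing.assert_frame_equal(ct, cv)

    def test_subject_order_permutation_leaves_accuracies_unchanged(
        self, small_cohort_sets
    ):
        m1 = cross_task_matrix(small_cohort_sets, nz.OXY)
        rng = np.random.default_rng(5)
        shuffled = [small_cohort_sets[i] for i in rng.permutation(len(small_cohort_sets))]
        m2 = cross_task_matrix(shuffled, nz.OXY)
        assert np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_simulated_cohort_identifies_across_tasks(self, small_cohort_sets):
        m = cross_task_matrix(small_cohort_sets, nz.OXY)
        off = m.to_numpy()[~np.eye(4, dtype=bool)]
        assert off.min() >= 0.5  # well-separated small cohort

    def test_accuracy_nondecreasing_in_subject_effect(self):
        """Mean off-diagonal accuracy rises with the subject-effect dial
        (Spearman trend over 4 effect sizes x 5 seeds)."""
        from scipy.stats import spearmanr

        p = nz.ParadigmConfig(n_subjects=6, n_sessions=1, trials_per_session=12)
        effects = [0.0, 0.5, 1.5, 4.0]
        means = []
        for effect in effects:
            accs = []
            for seed in range(5):
                sets = nz.cohort_fingerprints(
                    p, subject_effect=effect, master_seed=200 + seed, views=(nz.OXY,)
                )
                m = cross_task_matrix(sets, nz.OXY).to_numpy()
                accs.append(m[~np.eye(4, dtype=bool)].mean())
            means.append(np.mean(accs))
        rho, _ = spearmanr(effects, means)
        assert rho > 0


class TestSummarize:
    def test_all_ones(self):
        m = pd.DataFrame(np.ones((4, 4)))
        assert summarize(m, include_diagonal=True) == (1.0, 0.0)

    def test_mean_of_two_values(self):
        m = pd.DataFrame([[1.0, 0.5], [1.0, 0.5]])
        mean, _ = summarize(m, include_diagonal=True)
        assert mean == pytest.approx(0.75)

    def test_diagonal_exclusion_changes_summary(self):
        m = pd.DataFrame(np.full((4, 4), 0.5) + 0.5 * np.eye(4))
        assert summarize(m, include_diagonal=False)[0] == pytest.approx(0.5)
        assert summarize(m, include_diagonal=True)[0] > 0.5

    def test_sample_sd(self):
        m = pd.DataFrame([[1.0, 0.0], [1.0, 0.0]])
        _, sd = summarize(m, include_diagonal=True)
        assert sd == pytest.approx(np.std([1, 0, 1, 0], ddof=1))
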