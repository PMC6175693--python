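"""kNN classification, fusion, pooling, performance tests, searchlight."""

import numpy as np
import pandas as pd
import pytest

from oscnet.classify import (
    ClassWeights,
    KnnModel,
    cross_session_subject_id,
    fuse,
    identify_subjects,
    knn_class_weights,
    knn_predict,
    label_shuffle_null,
    loso_state_classification,
    merge_rest_task,
    performance_tests,
    pool_segments,
    searchlight_recognition,
    subsample_curve,
)
from oscnet.montage import Montage, neighbor_pairs
from oscnet.networks import ElementIndex, NetworkVector
from oscnet.synthgen import VectorModelParams, generate_vectors


def vectors_at_correlations(x, corrs, rng):
    """Training vectors with prescribed Pearson correlation to x."""
    d = len(x)
    xc = (x - x.mean())
    xc /= np.linalg.norm(xc)
    out = []
    for c in corrs:
        z = rng.standard_normal(d)
        z -= z.mean()
        z -= (z @ xc) * xc
        z /= np.linalg.norm(z)
        out.append(c * xc + np.sqrt(1 - c * c) * z)
    return np.array(out)


class TestKnnPredict:
    def test_hand_computed_inverse_distance_weights(self, rng):
        # distances (0.1, 0.1, 0.2, 0.4, 0.4), labels (A, A, B, B, B):
        # weight A = 1/.1 + 1/.1 = 20, weight B = 1/.2 + 2/.4 = 10 -> A wins
        x = rng.standard_normal(100)
        X = vectors_at_correlations(x, [0.9, 0.9, 0.8, 0.6, 0.6], rng)
        model = KnnModel(X, np.array(["A", "A", "B", "B", "B"]), k=5)
        posterior, label = knn_predict(model, x)
        assert label == "A"
        assert posterior["A"] == pytest.approx(20 / 30, abs=1e-9)
        assert posterior["B"] == pytest.approx(10 / 30, abs=1e-9)

    def test_zero_distance_neighbor_wins_outright(self, rng):
        X = rng.standard_normal((6, 40))
        labels = np.array(["A", "B", "B", "B", "B", "B"])
        model = KnnModel(X, labels, k=5)
        posterior, label = knn_predict(model, X[0])
        assert label == "A"
        assert posterior["A"] == pytest.approx(1.0)

    def test_affine_rescaled_duplicate_still_zero_distance(self, rng):
        X = rng.standard_normal((6, 40))
        model = KnnModel(X, np.array(["A", "B", "B", "B", "B", "B"]), k=5)
        _, label = knn_predict(model, 5.0 * X[0] - 2.0)
        assert label == "A"

    def test_uniform_labels_give_unit_posterior(self, rng):
        X = rng.standard_normal((5, 30))
        model = KnnModel(X, np.array(["rest"] * 5), k=5)
        posterior, label = knn_predict(model, rng.standard_normal(30))
        assert label == "rest"
        assert posterior["rest"] == pytest.approx(1.0)

    def test_k1_self_retrieval_is_perfect(self, rng):
        X = rng.standard_normal((8, 50))
        labels = np.array([f"s{i}" for i in range(8)])
        model = KnnModel(X, labels, k=1)
        for i in range(8):
            _, lab = knn_predict(model, X[i])
            assert lab == labels[i]

    def test_k_larger_than_training_rejected(self, rng):
        with pytest.raises(ValueError):
            KnnModel(rng.standard_normal((3, 10)), np.array(["a", "b", "c"]), k=5)


class TestFusionOps:
    def cw(self, rows, index=None, classes=("A", "B")):
        idx = index or [f"x{i}" for i in range(len(rows))]
        return ClassWeights(pd.DataFrame(rows, index=idx, columns=list(classes)))

    def test_fusing_identical_posteriors_is_identity(self):
        a = self.cw([[0.8, 0.2], [0.3, 0.7]])
        out = fuse([a, self.cw([[0.8, 0.2], [0.3, 0.7]])])
        assert np.allclose(out.weights.to_numpy(), a.weights.to_numpy())

    def test_opposed_posteriors_tie_break_to_first_class(self):
        out = fuse([self.cw([[1.0, 0.0]]), self.cw([[0.0, 1.0]])])
        assert np.allclose(out.weights.to_numpy(), 0.5)
        assert out.assign().iloc[0] == "A"  # deterministic tie-break

    def test_pool_segments_averages_within_subject(self):
        cw = self.cw([[0.8, 0.2], [0.4, 0.6]], index=["s1|b1", "s1|b2"])
        pooled = pool_segments(cw, pd.Series(["s1", "s1"], index=["s1|b1", "s1|b2"]))
        assert np.allclose(pooled.weights.loc["s1"].to_numpy(), [0.6, 0.4])

    def test_single_segment_pooling_is_identity(self):
        cw = self.cw([[0.9, 0.1]], index=["s1|b1"])
        pooled = pool_segments(cw, pd.Series(["s1"], index=["s1|b1"]))
        assert np.allclose(pooled.weights.to_numpy(), [[0.9, 0.1]])

    def test_merge_rest_task_takes_per_class_maximum(self):
        rest = self.cw([[0.9, 0.1]], index=["s1"])
        task = self.cw([[0.2, 0.6]], index=["s1"])
        merged = merge_rest_task(rest, task)
        assert np.allclose(merged.weights.to_numpy(), [[0.9, 0.6]])
        assert merged.assign().iloc[0] == "A"

    def test_merge_with_all_zero_input_keeps_other(self):
        rest = self.cw([[0.0, 0.0]], index=["s1"])
        task = self.cw([[0.2, 0.6]], index=["s1"])
        assert merge_rest_task(rest, task).assign().iloc[0] == "B"


class TestStateClassification:
    def test_strong_state_templates_classified_above_90(self):
        p = VectorModelParams(
            length=300, v_group=0.3, v_subject=0.3, v_state=4.0, v_noise=1.0,
            n_subjects=6, bands=("alpha",), metrics=("plv",), seed=31,
        )
        vecs = [v for v in generate_vectors(p) if v.session == "A"]
        df = loso_state_classification(vecs, include_fused=False)
        assert (df["accuracy"] > 0.9).all()

    def test_absent_state_structure_stays_at_chance(self):
        # balanced rest/task blocks so chance is exactly 50%: the default
        # 7:2 protocol imbalance would let majority voting sit near 78%
        from oscnet.synthgen import Block, ProtocolSpec

        prot = ProtocolSpec(
            tuple(Block("A", st_, f"{st_}_A{i}") for st_ in ("rest", "task") for i in range(1, 5))
        )
        p = VectorModelParams(
            length=120, v_group=1.0, v_subject=1.0, v_state=0.0, v_noise=1.0,
            n_subjects=10, bands=("alpha",), metrics=("plv",), seed=32,
        )
        vecs = generate_vectors(p, prot)
        df = loso_state_classification(vecs, include_fused=False)
        acc, n = df.loc[0, "accuracy"], df.loc[0, "n_test"]
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(acc - 0.5) <= 3 * se

    def test_duplicate_state_prototypes_classified_perfectly(self, rng):
        protos = {"rest": rng.standard_normal(60), "task": rng.standard_normal(60)}
        vecs = []
        for s in range(4):
            for b, st_ in [("b1", "rest"), ("b2", "rest"), ("b3", "task"), ("b4", "task")]:
                vecs.append(
                    NetworkVector(
                        values=protos[st_].copy(),
                        element_index=ElementIndex("synthetic", tuple(range(60))),
                        subject=f"s{s}", session="A", state=st_, block_id=b,
                        band="alpha", metric="plv",
                    )
                )
        df = loso_state_classification(vecs, include_fused=False)
        assert df["accuracy"].iloc[0] == 1.0


class TestSubjectIdentification:
    def test_chance_rate_with_21_training_identities(self):
        p = VectorModelParams(
            length=60, v_subject=1.0, n_subjects=21, bands=("alpha",), metrics=("plv",), seed=5,
        )
        vecs = generate_vectors(p)
        train = [v for v in vecs if v.session in ("A", "B")]
        test = [v for v in vecs if v.session == "C"]
        df = cross_session_subject_id(train, test)
        assert df["chance"].iloc[0] == pytest.approx(1 / 21, abs=1e-12)
        assert df["chance"].iloc[0] == pytest.approx(0.048, abs=0.001)

    def test_strong_fingerprints_identified_near_perfectly(self):
        p = VectorModelParams(
            length=300, v_group=1.0, v_subject=4.0, v_state=0.25, v_noise=1.0,
            n_subjects=8, bands=("alpha",), metrics=("plv",), seed=6,
        )
        vecs = generate_vectors(p)
        train = [v for v in vecs if v.session in ("A", "B")]
        test = [v for v in vecs if v.session == "C"]
        rep = identify_subjects(train, test)
        assert rep["fused_segment_accuracy"] >= 0.95
        assert rep["merged_identity_accuracy"] == 1.0

    def test_no_fingerprint_stays_at_chance(self):
        p = VectorModelParams(
            length=100, v_group=1.0, v_subject=0.0, v_state=0.25, v_noise=1.0,
            n_subjects=12, bands=("alpha",), metrics=("plv",), seed=7,
        )
        vecs = generate_vectors(p)
        train = [v for v in vecs if v.session in ("A", "B")]
        test = [v for v in vecs if v.session == "C"]
        df = cross_session_subject_id(train, test)
        chance = df["chance"].iloc[0]
        n = df["n_test"].iloc[0]
        se = np.sqrt(chance * (1 - chance) / n)
        assert abs(df["accuracy"].iloc[0] - chance) <= 3 * se

    def test_fusion_beats_or_matches_best_single_type(self):
        p = VectorModelParams(
            length=150, v_group=1.0, v_subject=1.5, v_state=0.25, v_noise=1.0,
            n_subjects=8, bands=("theta", "alpha", "beta", "gamma"),
            metrics=("power", "plv", "aec"), seed=8,
        )
        vecs = generate_vectors(p)
        train = [v for v in vecs if v.session in ("A", "B")]
        test = [v for v in vecs if v.session == "C"]
        rep = identify_subjects(train, test)
        best = rep["per_type"]["accuracy"].max()
        n = rep["per_type"]["n_test"].iloc[0]
        se = np.sqrt(best * (1 - best) / n)
        assert rep["fused_segment_accuracy"] >= best - 2 * se

    def test_fusing_noise_classifier_causes_bounded_harm(self):
        # informative + pure-noise classifier: fused accuracy must not drop
        # by as much as the noise classifier's own deficit
        p_info = VectorModelParams(
            length=150, v_group=0.5, v_subject=2.0, v_state=0.0, v_noise=1.0,
            n_subjects=8, bands=("alpha",), metrics=("plv",), seed=9,
        )
        p_noise = VectorModelParams(
            length=150, v_group=0.5, v_subject=0.0, v_state=0.0, v_noise=1.0,
            n_subjects=8, bands=("alpha",), metrics=("aec",), seed=10,
        )
        vecs = generate_vectors(p_info) + generate_vectors(p_noise)
        train = [v for v in vecs if v.session in ("A", "B")]
        test = [v for v in vecs if v.session == "C"]
        rep = identify_subjects(train, test)
        per = rep["per_type"].set_index("metric")["accuracy"]
        solo_deficit = per["plv"] - per["aec"]
        assert per["plv"] - rep["fused_segment_accuracy"] < solo_deficit


class TestPerformanceTests:
    def test_57_of_70_at_one_in_21_is_astronomical(self):
        binom_p, _ = performance_tests(57, 70, 1 / 21)
        assert binom_p < 1e-16

    def test_observed_exactly_at_chance_not_significant(self):
        binom_p, _ = performance_tests(10, 20, 0.5)
        assert binom_p >= 0.5

    def test_permutation_p_from_shuffled_labels(self, rng):
        # no class structure: observed accuracy should not be extreme
        X = rng.standard_normal((40, 30))
        y = np.array(["a", "b"] * 20)
        Xt = rng.standard_normal((20, 30))
        yt = np.array(["a", "b"] * 10)
        null = label_shuffle_null(X, y, Xt, yt, reps=39, seed=0)
        model = KnnModel(X, y, k=5)
        pred = ClassWeights(knn_class_weights(model, Xt)).assign()
        correct = int((pred.to_numpy() == yt).sum())
        _, perm_p = performance_tests(correct, 20, 0.5, null_accuracies=null)
        assert perm_p > 0.05

    def test_invalid_chance_rejected(self):
        with pytest.raises(ValueError):
            performance_tests(5, 10, 1.5)


class TestSubsampleCurve:
    def make_id_problem(self, seed=11):
        p = VectorModelParams(
            length=120, v_group=0.5, v_subject=2.0, v_state=0.0, v_noise=1.0,
            n_subjects=6, bands=("alpha",), metrics=("plv",), seed=seed,
        )
        vecs = generate_vectors(p)
        train = [v for v in vecs if v.session in ("A", "B")]
        test = [v for v in vecs if v.session == "C"]
        Xtr = np.vstack([v.values for v in train])
        ytr = np.array([v.subject for v in train])
        Xte = np.vstack([v.values for v in test])
        yte = np.array([v.subject for v in test])
        return Xtr, ytr, Xte, yte

    def test_full_size_equals_full_network_accuracy(self):
        Xtr, ytr, Xte, yte = self.make_id_problem()
        df = subsample_curve(Xtr, ytr, Xte, yte, sizes=[120], reps=3, seed=0)
        model = KnnModel(Xtr, ytr, k=5)
        pred = ClassWeights(knn_class_weights(model, Xte)).assign()
        full = float((pred.to_numpy() == yte).mean())
        assert df["mean"].iloc[0] == pytest.approx(full)
        assert df["sd"].iloc[0] == 0.0

    def test_exactly_reps_accuracy_values_per_size(self):
        Xtr, ytr, Xte, yte = self.make_id_problem()
        df = subsample_curve(Xtr, ytr, Xte, yte, sizes=[5, 20], reps=10, seed=0, chance=1 / 6)
        assert (df["reps"] == 10).all()
        assert {"mean", "sd", "min", "max", "t", "p"} <= set(df.columns)

    def test_accuracy_grows_with_network_size(self):
        Xtr, ytr, Xte, yte = self.make_id_problem()
        df = subsample_curve(Xtr, ytr, Xte, yte, sizes=[2, 10, 40, 120], reps=8, seed=1)
        means = df["mean"].to_numpy()
        # expected nondecreasing trend: strongly positive rank correlation
        from scipy.stats import spearmanr

        assert means[-1] > means[0]
        assert spearmanr(df["size"], means).statistic > 0.7

    def test_oversized_request_rejected(self):
        Xtr, ytr, Xte, yte = self.make_id_problem()
        with pytest.raises(ValueError):
            subsample_curve(Xtr, ytr, Xte, yte, sizes=[121], reps=2)


class TestSearchlight:
    def ring_montage(self, n=12):
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pos = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
        return Montage(tuple(f"ch{i}" for i in range(n)), pos)

    def make_power_vectors(self, values_by_subject_block, names):
        vecs = []
        for (subj, block, session, state), vals in values_by_subject_block.items():
            vecs.append(
                NetworkVector(
                    values=vals,
                    element_index=ElementIndex("channels", names),
                    subject=subj, session=session, state=state, block_id=block,
                    band="alpha", metric="power",
                )
            )
        return vecs

    def test_planted_fingerprint_peaks_inside_informative_channels(self, rng):
        n_ch, informative = 12, {0, 1, 2, 3, 4}
        montage = self.ring_montage(n_ch)
        idx = neighbor_pairs(montage, dist=1e-6)  # no exclusions
        data = {}
        for s in range(5):
            fp = np.zeros(n_ch)
            fp[list(informative)] = 3.0 * rng.standard_normal(len(informative))
            for session, blocks in (("A", 4), ("C", 3)):
                for b in range(blocks):
                    vals = fp + 0.5 * rng.standard_normal(n_ch)
                    data[(f"s{s}", f"r{session}{b}", session, "rest")] = vals
        vecs = self.make_power_vectors(data, montage.names)
        train = [v for v in vecs if v.session == "A"]
        test = [v for v in vecs if v.session == "C"]
        df = searchlight_recognition(train, test, montage, idx, dist=1.2, k=3)
        peak_channel = int(df.loc[df["accuracy"].idxmax(), "channel"].removeprefix("ch"))
        assert peak_channel in informative

    def test_singleton_sets_reduce_to_per_electrode_classification(self, rng):
        n_ch = 6
        montage = self.ring_montage(n_ch)
        idx = neighbor_pairs(montage, dist=1e-6)
        data = {}
        for s in range(4):
            fp = rng.standard_normal(n_ch)
            for session, blocks in (("A", 3), ("C", 2)):
                for b in range(blocks):
                    data[(f"s{s}", f"r{session}{b}", session, "rest")] = fp + 0.3 * rng.standard_normal(n_ch)
        vecs = self.make_power_vectors(data, montage.names)
        train = [v for v in vecs if v.session == "A"]
        test = [v for v in vecs if v.session == "C"]
        df = searchlight_recognition(train, test, montage, idx, dist=1e-6, k=3)
        # oracle: direct kNN on each electrode's scalar value
        Xtr = np.vstack([v.values for v in train])
        ytr = np.array([v.subject for v in train])
        Xte = np.vstack([v.values for v in test])
        yte = np.array([v.subject for v in test])
        for c in range(n_ch):
            model = KnnModel(Xtr[:, [c]], ytr, k=3)
            pred = ClassWeights(knn_class_weights(model, Xte[:, [c]])).assign()
            direct = float((pred.to_numpy() == yte).mean())
            assert df.loc[c, "accuracy"] == pytest.approx(direct)
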