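"""kNN state classification and long-term subject identification.

Classifiers are k-nearest-neighbor (k = 5) on the correlation distance
(1 - Pearson R) between network vectors, with inverse-distance weighted
voting, so that training networks more similar to a test network
contribute more to its label. One classifier is trained per network type
(band x metric); evidence is combined by averaging per-class posterior
probabilities across classifiers ("class weights" — the averages need
not sum to 1), across a subject's data segments, and finally across the
composite rest and task classifiers by taking the per-class maximum.

Behavioral state (rest vs task) is classified with leave-one-subject-out
cross-validation; subject identity is classified across sessions by
training on the first visit (sessions A and B) and testing on the
follow-up (session C), where chance is 1 / n_training_subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .montage import Montage, PairIndex, searchlight_sets
from .networks import NetworkVector

__all__ = [
    "KnnModel",
    "ClassWeights",
    "knn_predict",
    "knn_class_weights",
    "loso_state_classification",
    "cross_session_subject_id",
    "identify_subjects",
    "fuse",
    "pool_segments",
    "merge_rest_task",
    "performance_tests",
    "label_shuffle_null",
    "subsample_curve",
    "searchlight_recognition",
]

_ZERO_DIST = 1e-12


@dataclass
class KnnModel:
    """Training set for correlation-distance kNN with inverse-distance votes."""

    X: np.ndarray
    labels: np.ndarray
    k: int = 5

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("one label per training vector required")
        if self.k > self.X.shape[0]:
            raise ValueError(f"k={self.k} exceeds {self.X.shape[0]} training networks")
        self.classes_ = np.array(sorted(set(self.labels.tolist())))


def _correlation_distances(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson R between rows of T (tests) and rows of X (train).

    Falls back to scaled Euclidean distance when vectors are too short for
    a correlation (fewer than 2 elements); constant rows get maximal
    correlation distance to everything.
    """
    if X.shape[1] < 2:
        d = np.abs(T[:, None, 0] - X[None, :, 0])
        scale = max(d.max(), 1.0)
        return d / scale
    Xs = X - X.mean(axis=1, keepdims=True)
    Ts = T - T.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xs, axis=1)
    tn = np.linalg.norm(Ts, axis=1)
    bad_x, bad_t = xn == 0, tn == 0
    xn[bad_x] = 1.0
    tn[bad_t] = 1.0
    corr = (Ts / tn[:, None]) @ (Xs / xn[:, None]).T
    d = 1.0 - corr
    if bad_x.any() or bad_t.any():
        warnings.warn("constant network vector(s): correlation distance undefined, set to 2", stacklevel=3)
        d[:, bad_x] = 2.0
        d[bad_t, :] = 2.0
    return np.clip(d, 0.0, None)


def knn_class_weights(model: KnnModel, T: np.ndarray) -> pd.DataFrame:
    """Posterior class probabilities for each row of T.

    For each test network the k nearest training networks vote with
    weight 1/distance, normalized over the k neighbors. A zero-distance
    neighbor (an exact duplicate up to affine scaling) wins outright:
    posterior mass is split over the zero-distance neighbors' classes.
    """
    T = np.atleast_2d(np.asarray(T, float))
    D = _correlation_distances(model.X, T)
    k = model.k
    classes = model.classes_
    cls_pos = {c: i for i, c in enumerate(classes)}
    out = np.zeros((T.shape[0], len(classes)))
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    for i in range(T.shape[0]):
        nbrs = order[i]
        d = D[i, nbrs]
        zero = d <= _ZERO_DIST
        if zero.any():
            for nb in nbrs[zero]:
                out[i, cls_pos[model.labels[nb]]] += 1.0 / zero.sum()
        else:
            w = 1.0 / d
            w /= w.sum()
            for nb, wi in zip(nbrs, w):
                out[i, cls_pos[model.labels[nb]]] += wi
    return pd.DataFrame(out, columns=classes)


def knn_predict(model: KnnModel, x: np.ndarray) -> tuple[dict, object]:
    """Posterior per class and the assigned label for one test vector.

    Ties in the argmax break deterministically toward the lowest class in
    sort order.
    """
    w = knn_class_weights(model, np.atleast_2d(x)).iloc[0]
    return w.to_dict(), w.idxmax()


@dataclass
class ClassWeights:
    """Per-test-network fused class evidence (rows: test ids, cols: classes).

    Values are averages of posteriors and need not sum to 1. The assigned
    label is the argmax, with ties broken toward the first class in
    column (sorted) order.
    """

    weights: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.weights.to_numpy() < -1e-12).any():
            raise ValueError("class weights must be nonnegative")
        self.weights = self.weights[sorted(self.weights.columns)]

    def assign(self) -> pd.Series:
        return self.weights.idxmax(axis=1)

    def accuracy(self, truth: pd.Series) -> float:
        pred = self.assign()
        return float((pred.to_numpy() == truth.loc[pred.index].to_numpy()).mean())


def fuse(weight_sets: list[ClassWeights]) -> ClassWeights:
    """Average posteriors elementwise across classifiers of interest."""
    if not weight_sets:
        raise ValueError("nothing to fuse")
    first = weight_sets[0].weights
    for w in weight_sets[1:]:
        if not w.weights.index.equals(first.index) or list(w.weights.columns) != list(first.columns):
            raise ValueError("class-weight tables must share test networks and classes")
    stacked = np.mean([w.weights.to_numpy() for w in weight_sets], axis=0)
    return ClassWeights(pd.DataFrame(stacked, index=first.index, columns=first.columns))


def pool_segments(cw: ClassWeights, groups: pd.Series) -> ClassWeights:
    """Average class weights across each subject's data segments.

    ``groups`` maps test-network ids to a pooling key (typically the
    subject, with rest and task pooled separately).
    """
    if not groups.index.equals(cw.weights.index):
        missing = cw.weights.index.difference(groups.index)
        if len(missing):
            raise ValueError("grouping must cover every test network")
        groups = groups.loc[cw.weights.index]
    pooled = cw.weights.groupby(groups).mean()
    return ClassWeights(pooled)


def merge_rest_task(w_rest: ClassWeights, w_task: ClassWeights) -> ClassWeights:
    """Combine composite rest and task classifiers by per-class maximum."""
    if list(w_rest.weights.columns) != list(w_task.weights.columns):
        raise ValueError("rest and task classifiers must share the class set")
    idx = w_rest.weights.index.union(w_task.weights.index)
    a = w_rest.weights.reindex(idx, fill_value=0.0)
    b = w_task.weights.reindex(idx, fill_value=0.0)
    return ClassWeights(pd.DataFrame(np.maximum(a.to_numpy(), b.to_numpy()), index=idx, columns=a.columns))


# --- network-vector plumbing ----------------------------------------------


def _stack_by_type(nets: list[NetworkVector]) -> dict[tuple[str, str], tuple[np.ndarray, pd.DataFrame]]:
    groups: dict[tuple[str, str], list[NetworkVector]] = {}
    for v in nets:
        groups.setdefault(v.network_type, []).append(v)
    out = {}
    for t, vs in sorted(groups.items()):
        X = np.vstack([v.values for v in vs])
        meta = pd.DataFrame([v.labels for v in vs])
        out[t] = (X, meta)
    return out


def loso_state_classification(nets: list[NetworkVector], k: int = 5, include_fused: bool = True) -> pd.DataFrame:
    """Leave-one-subject-out rest/task classification accuracy per network type.

    Each classifier is trained on all other subjects' networks and tested
    on the held-out subject's; accuracy is the proportion of held-out
    networks labeled correctly (chance 50%). When ``include_fused`` is
    set, a final row reports accuracy after averaging posteriors across
    all network types.
    """
    by_type = _stack_by_type(nets)
    types = list(by_type)
    meta0 = by_type[types[0]][1]
    subjects = sorted(meta0["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")

    correct = {t: 0 for t in types}
    total = {t: 0 for t in types}
    fused_correct = 0
    fused_total = 0
    for subj in subjects:
        if meta0.loc[meta0["subject"] == subj, "state"].nunique() < 2:
            warnings.warn(f"subject {subj} has a single behavioral state; skipped as test fold", stacklevel=2)
            continue
        per_type_weights = []
        truth = None
        for t in types:
            X, meta = by_type[t]
            te = meta["subject"] == subj
            model = KnnModel(X[~te.to_numpy()], meta.loc[~te, "state"].to_numpy(), k=k)
            w = knn_class_weights(model, X[te.to_numpy()])
            w.index = meta.loc[te, "block_id"].to_numpy()
            truth_t = meta.loc[te, "state"]
            truth_t.index = w.index
            pred = ClassWeights(w).assign()
            correct[t] += int((pred.to_numpy() == truth_t.to_numpy()).sum())
            total[t] += int(te.sum())
            per_type_weights.append(ClassWeights(w))
            truth = truth_t
        if include_fused and per_type_weights:
            pred = fuse(per_type_weights).assign()
            fused_correct += int((pred.to_numpy() == truth.to_numpy()).sum())
            fused_total += len(pred)

    rows = [
        {"band": t[0], "metric": t[1], "accuracy": correct[t] / total[t], "n_test": total[t]}
        for t in types
    ]
    if include_fused:
        rows.append({"band": "all", "metric": "fused", "accuracy": fused_correct / fused_total, "n_test": fused_total})
    return pd.DataFrame(rows)


def cross_session_subject_id(
    train: list[NetworkVector], test: list[NetworkVector], k: int = 5
) -> pd.DataFrame:
    """Per-segment subject identification accuracy per network type.

    Classifiers are trained on the training-session networks (subject
    identity as the class) and tested per segment; chance is
    1/n_training_subjects. Test subjects absent from training count as
    forced errors (logged).
    """
    tr = _stack_by_type(train)
    te = _stack_by_type(test)
    rows = []
    for t in tr:
        if t not in te:
            continue
        Xtr, mtr = tr[t]
        Xte, mte = te[t]
        train_subjects = set(mtr["subject"])
        missing = sorted(set(mte["subject"]) - train_subjects)
        if missing:
            warnings.warn(f"test subject(s) {missing} absent from training: forced errors", stacklevel=2)
        model = KnnModel(Xtr, mtr["subject"].to_numpy(), k=k)
        w = knn_class_weights(model, Xte)
        pred = ClassWeights(w).assign()
        acc = float((pred.to_numpy() == mte["subject"].to_numpy()).mean())
        rows.append(
            {
                "band": t[0],
                "metric": t[1],
                "accuracy": acc,
                "n_test": len(mte),
                "chance": 1.0 / len(train_subjects),
            }
        )
    return pd.DataFrame(rows)


def identify_subjects(train: list[NetworkVector], test: list[NetworkVector], k: int = 5) -> dict:
    """Full identification pipeline: per-type kNN -> fusion -> segment
    pooling -> rest/task merge -> one identity call per subject.

    Returns a dict with the per-type table, fused per-segment accuracy,
    pooled composite accuracies for rest and task, and the final merged
    per-subject identification accuracy.
    """
    tr = _stack_by_type(train)
    te = _stack_by_type(test)
    types = [t for t in tr if t in te]
    if not types:
        raise ValueError("no shared network types between train and test")
    mte0 = te[types[0]][1]
    seg_ids = mte0["subject"] + "|" + mte0["block_id"]
    truth_seg = pd.Series(mte0["subject"].to_numpy(), index=seg_ids.to_numpy())
    train_subjects = sorted(set(te[types[0]][1]["subject"]) | set(tr[types[0]][1]["subject"]))

    per_type = []
    weights = []
    for t in types:
        Xtr, mtr = tr[t]
        Xte, mte = te[t]
        model = KnnModel(Xtr, mtr["subject"].to_numpy(), k=k)
        w = knn_class_weights(model, Xte)
        w.index = (mte["subject"] + "|" + mte["block_id"]).to_numpy()
        w = w.reindex(columns=sorted(set(mtr["subject"])), fill_value=0.0)
        cw = ClassWeights(w)
        weights.append(cw)
        per_type.append(
            {"band": t[0], "metric": t[1], "accuracy": cw.accuracy(truth_seg), "n_test": len(w)}
        )
    fused = fuse(weights)
    fused_acc = fused.accuracy(truth_seg)

    state_of = pd.Series(mte0["state"].to_numpy(), index=seg_ids.to_numpy())
    subject_of = pd.Series(mte0["subject"].to_numpy(), index=seg_ids.to_numpy())
    out = {"per_type": pd.DataFrame(per_type), "fused_segment_accuracy": fused_acc}

    composites = {}
    for st in ("rest", "task"):
        ids = state_of.index[state_of == st]
        if len(ids) == 0:
            continue
        sub = ClassWeights(fused.weights.loc[ids])
        pooled = pool_segments(sub, subject_of.loc[ids])
        composites[st] = pooled
        truth_subj = pd.Series(pooled.weights.index, index=pooled.weights.index)
        out[f"pooled_{st}_accuracy"] = pooled.accuracy(truth_subj)
    if len(composites) == 2:
        merged = merge_rest_task(composites["rest"], composites["task"])
    elif composites:
        merged = next(iter(composites.values()))
    else:
        raise ValueError("no test segments")
    truth_subj = pd.Series(merged.weights.index, index=merged.weights.index)
    out["merged_identity_accuracy"] = merged.accuracy(truth_subj)
    out["chance"] = 1.0 / max(len(set(tr[types[0]][1]["subject"])), 1)
    return out


# --- performance testing ----------------------------------------------------


def performance_tests(
    correct: int,
    total: int,
    chance: float,
    null_accuracies: np.ndarray | None = None,
) -> tuple[float, float | None]:
    """Binomial and (optional) label-shuffle permutation p-values.

    The binomial p is the exact upper tail P(X >= correct) at the chance
    rate; the permutation p compares the observed accuracy against
    accuracies of classifiers re-trained on shuffled labels, with the
    (b+1)/(m+1) convention.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 < chance < 1:
        raise ValueError("chance must lie in (0, 1)")
    binom_p = float(_st.binomtest(correct, total, chance, alternative="greater").pvalue)
    if null_accuracies is None:
        return binom_p, None
    null_accuracies = np.asarray(null_accuracies, float)
    obs = correct / total
    perm_p = (int((null_accuracies >= obs).sum()) + 1) / (len(null_accuracies) + 1)
    return binom_p, float(perm_p)


def label_shuffle_null(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    reps: int = 100,
    seed: int = 0,
    k: int = 5,
) -> np.ndarray:
    """Accuracies of classifiers re-trained on shuffled training labels."""
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    y = np.asarray(train_y)
    for r in range(reps):
        perm = rng.permutation(len(y))
        model = KnnModel(train_X, y[perm], k=k)
        pred = ClassWeights(knn_class_weights(model, test_X)).assign()
        out[r] = float((pred.to_numpy() == np.asarray(test_y)).mean())
    return out


def subsample_curve(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    sizes: list[int],
    reps: int = 10,
    seed: int = 0,
    k: int = 5,
    chance: float | None = None,
) -> pd.DataFrame:
    """Classification accuracy as a function of network size.

    At each size, that many elements (connections or electrodes —
    columns of the vectors) are selected at random; the classifier is
    retrained and retested, and the whole process is repeated ``reps``
    times. Returns per-size mean/SD/min/max accuracy and, when a chance
    rate is given, a one-sample t test of the rep accuracies against
    chance.
    """
    n_el = train_X.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > n_el:
            raise ValueError(f"size {size} exceeds {n_el} available elements")
        accs = np.empty(reps)
        for r in range(reps):
            cols = np.sort(rng.choice(n_el, size=size, replace=False)) if size < n_el else np.arange(n_el)
            model = KnnModel(train_X[:, cols], train_y, k=k)
            pred = ClassWeights(knn_class_weights(model, test_X[:, cols])).assign()
            accs[r] = float((pred.to_numpy() == np.asarray(test_y)).mean())
        row = {
            "size": size,
            "mean": accs.mean(),
            "sd": accs.std(ddof=1) if reps > 1 else 0.0,
            "min": accs.min(),
            "max": accs.max(),
            "reps": reps,
        }
        if chance is not None:
            if np.ptp(accs) == 0:
                row["t"], row["p"] = np.nan, (0.0 if accs[0] > chance else 1.0)
            else:
                t, p = _st.ttest_1samp(accs, chance)
                row["t"], row["p"] = float(t), float(p / 2 if t > 0 else 1 - p / 2)  # one-tailed above chance
        rows.append(row)
    return pd.DataFrame(rows)


def searchlight_recognition(
    train: list[NetworkVector],
    test: list[NetworkVector],
    montage: Montage,
    pair_index: PairIndex,
    dist: float = 0.65,
    k: int = 5,
) -> pd.DataFrame:
    """Per-electrode subject recognition map.

    For each electrode, classifiers are trained and tested on the local
    subnetwork only — the electrode, its neighbors at ``dist``, the power
    values of those members, and the non-neighboring connections among
    them — and their posteriors fused. Returns a table (channel,
    accuracy) of fused per-segment identification accuracy suitable for
    topographic plotting.
    """
    sets = searchlight_sets(montage, dist, pair_index)
    tr = _stack_by_type(train)
    te = _stack_by_type(test)
    types = [t for t in tr if t in te]
    kind_of = {v.network_type: v.element_index.kind for v in train}
    # map full-pair-list indices -> column position within kept-pair vectors
    kept = pair_index.kept
    col_of = {int(p): i for i, p in enumerate(kept)}

    mte0 = te[types[0]][1]
    truth = mte0["subject"].to_numpy()
    rows = []
    for s in sets:
        members = np.array(s.members)
        conn_cols = np.array([col_of[p] for p in s.pair_indices if p in col_of], dtype=int)
        weights = []
        for t in types:
            Xtr, mtr = tr[t]
            Xte, _ = te[t]
            # power vectors live on channels, connectivity vectors on kept pairs
            cols = members if kind_of[t] == "channels" else conn_cols
            if len(cols) == 0:
                continue
            model = KnnModel(Xtr[:, cols], mtr["subject"].to_numpy(), k=k)
            w = knn_class_weights(model, Xte[:, cols])
            w = w.reindex(columns=sorted(set(mtr["subject"])), fill_value=0.0)
            weights.append(ClassWeights(w))
        if not weights:
            rows.append({"channel": montage.names[s.center], "accuracy": np.nan})
            continue
        pred = fuse(weights).assign()
        rows.append(
            {
                "channel": montage.names[s.center],
                "accuracy": float((pred.to_numpy() == truth).mean()),
                "n_members": len(members),
                "n_connections": len(conn_cols),
            }
        )
    return pd.DataFrame(rows)
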