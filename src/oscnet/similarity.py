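"""Network similarity: pairwise Pearson R, all-pairs similarity matrices,
aggregation over labeled comparison categories, and MDS embedding.

Network similarity is the Pearson correlation between two network
vectors — invariant to overall scale and offset of activity, so it
captures the *pattern* of power or coupling rather than absolute levels.
Aggregation over labeled pair categories (within-subject rest pairs,
rest-task pairs, ...) follows the representational-similarity-analysis
convention: average the similarity values over the relevant matrix
entries, each unique pair counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .networks import NetworkVector

__all__ = [
    "SimilarityMatrix",
    "ComparisonSelector",
    "network_similarity",
    "similarity_matrix",
    "aggregate",
    "mds_embed",
]


def network_similarity(u: NetworkVector, v: NetworkVector) -> float:
    """Pearson correlation between two network vectors.

    The vectors must be defined over the identical element index. Raises
    on zero variance (a constant network has no pattern to compare).
    """
    if u.element_index != v.element_index:
        raise ValueError("network vectors are defined over different element indexes")
    if np.ptp(u.values) == 0 or np.ptp(v.values) == 0:
        raise ValueError("zero-variance network vector; similarity undefined")
    return float(np.corrcoef(u.values, v.values)[0, 1])


@dataclass
class SimilarityMatrix:
    """All-pairs Pearson similarity across a set of networks.

    values is symmetric with unit diagonal (self-similarity); row_meta
    carries the full label set per network, row-aligned with values.
    """

    values: np.ndarray
    row_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if len(self.row_meta) != v.shape[0]:
            raise ValueError("row_meta must align with matrix rows")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def display_values(self) -> np.ndarray:
        """Copy with the diagonal zeroed, for plotting only."""
        out = self.values.copy()
        np.fill_diagonal(out, 0.0)
        return out

    def to_csv(self, path) -> None:
        labels = [
            f"{r.subject}|{r.block_id}|{r.band}|{r.metric}" for r in self.row_meta.itertuples()
        ]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)


def similarity_matrix(nets: list[NetworkVector]) -> SimilarityMatrix:
    """Pearson similarity between every unique pair of networks.

    All networks must share an element index; each unique pair is
    computed once and mirrored.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    idx0 = nets[0].element_index
    for n in nets[1:]:
        if n.element_index != idx0:
            raise ValueError("mixed element indexes; all networks must share one")
    X = np.vstack([n.values for n in nets])
    if (X.std(axis=1) == 0).any():
        raise ValueError("zero-variance network vector in set")
    vals = np.corrcoef(X)
    np.fill_diagonal(vals, 1.0)
    meta = pd.DataFrame([n.labels for n in nets])
    return SimilarityMatrix(values=vals, row_meta=meta)


@dataclass(frozen=True)
class ComparisonSelector:
    """A named symmetric predicate over pairs of network label sets."""

    name: str
    predicate: Callable[[pd.Series, pd.Series], bool]

    def mask(self, meta: pd.DataFrame) -> np.ndarray:
        """Boolean upper-triangle mask (i < j) of selected pairs."""
        n = len(meta)
        rows = [meta.iloc[i] for i in range(n)]
        m = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = bool(self.predicate(rows[i], rows[j]))
        return m


def selector(name: str, **conditions) -> ComparisonSelector:
    """Build common selectors declaratively.

    Supported keyword conditions: same=(fields...) requiring equality
    across the pair; states=(a, b) requiring the unordered state pair;
    each=dict(field=value) applying to both members.
    """
    same = tuple(conditions.pop("same", ()))
    states = conditions.pop("states", None)
    each = conditions.pop("each", {})
    if conditions:
        raise TypeError(f"unknown selector conditions: {sorted(conditions)}")

    def pred(a: pd.Series, b: pd.Series) -> bool:
        for f in same:
            if a[f] != b[f]:
                return False
        if states is not None and {a["state"], b["state"]} != set(states):
            return False
        for f, v in each.items():
            if a[f] != v or b[f] != v:
                return False
        return True

    return ComparisonSelector(name, pred)


def aggregate(sm: SimilarityMatrix, sel: ComparisonSelector) -> tuple[float, int]:
    """Mean similarity over the pairs a selector picks out.

    Returns (mean R, number of unique pairs). Raises if the selector
    matches nothing.
    """
    mask = sel.mask(sm.row_meta)
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        raise ValueError(f"selector {sel.name!r} matched no pairs")
    return float(sm.values[mask].mean()), n_pairs


def mds_embed(
    sm: SimilarityMatrix,
    dims: int = 2,
    seed: int = 0,
    metric: bool = True,
) -> np.ndarray:
    """Embed networks in ``dims`` dimensions from correlation distances.

    Distance is 1 - R. Metric (SMACOF) stress minimization with a fixed
    seed is the default for determinism; nonmetric scaling is available
    via ``metric=False``. The embedding is for visualization only — all
    statistics operate on the full-dimensional vectors.
    """
    from sklearn.manifold import MDS

    if dims >= sm.n:
        raise ValueError("embedding dimension must be below the number of networks")
    d = 1.0 - sm.values
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    d = (d + d.T) / 2.0
    kwargs = dict(
        n_components=dims,
        dissimilarity="precomputed",
        random_state=seed,
        n_init=4,
        normalized_stress=False if metric else "auto",
    )
    try:
        mds = MDS(metric_mds=metric, **kwargs)
    except TypeError:  # older scikit-learn spelling
        mds = MDS(metric=metric, **kwargs)
    return mds.fit_transform(d)
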