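"""Resampling statistics for network similarity.

For every comparison of interest a null distribution is built by
repeatedly selecting as many random networks as entered the observed
comparison (the observed networks remain eligible for selection) and
averaging the pairwise similarities of each selection. When the number
of unique selections is at most 1,000 every combination is enumerated
exactly once (exhaustive mode); otherwise 1,000 Monte-Carlo draws are
taken. Baseline similarity is the mean of the null distribution.

Observations are z-scored against their null and converted to one-tailed
normal p-values (all hypotheses are directional: observed similarity
greater than baseline). Raw permutation p-values use the (b+1)/(m+1)
convention and are floored at 1/(n_iter+1), so with 1,000 iterations the
smallest obtainable value is just under 0.001 — the z-based p-values are
preferred precisely because they resolve effects beyond that floor.
Multiple comparisons are corrected with the Benjamini-Hochberg false
discovery procedure, applied within nested analysis families (e.g.
across subjects within one network type) rather than across every
comparison performed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .networks import NetworkVector
from .similarity import similarity_matrix

__all__ = [
    "NullDistribution",
    "StatResult",
    "build_null",
    "z_test",
    "fdr",
    "group_t_vs_baseline",
    "run_comparison_suite",
    "SCHEMES",
    "MAX_EXHAUSTIVE",
]

#: Above this many unique combinations, Monte-Carlo sampling (this many
#: iterations) replaces exhaustive enumeration.
MAX_EXHAUSTIVE = 1000

SCHEMES = (
    "within_subject_rest",
    "within_subject_task",
    "rest_task",
    "frequency_clustering",
    "metric_clustering",
    "metric_clustering_no_power",
    "group_state_clustering",
)


@dataclass
class NullDistribution:
    """Surrogate distribution of mean-similarity values."""

    samples: np.ndarray
    mode: str  # "monte_carlo" | "exhaustive"
    n_iter: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.mode not in ("monte_carlo", "exhaustive"):
            raise ValueError("mode must be 'monte_carlo' or 'exhaustive'")
        if self.mode == "monte_carlo" and len(self.samples) != MAX_EXHAUSTIVE:
            raise ValueError(f"monte_carlo nulls use exactly {MAX_EXHAUSTIVE} samples")

    @property
    def baseline(self) -> float:
        """Center of the null distribution: the no-effect reference."""
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=0))


@dataclass
class StatResult:
    observed: float
    z: float
    p_z: float
    p_perm: float
    baseline: float
    significant_fdr: bool | None = None
    q: float | None = None
    extra: dict = field(default_factory=dict)


def _mean_pairwise(sim: np.ndarray, idx: np.ndarray) -> float:
    sub = sim[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def _mean_cross(sim: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    return float(sim[np.ix_(idx_a, idx_b)].mean())


def null_from_matrix(
    sim: np.ndarray,
    pool: np.ndarray,
    n_select: int,
    seed: int,
    fixed: np.ndarray | None = None,
) -> NullDistribution:
    """Null distribution of mean similarity over random selections.

    Each iteration selects ``n_select`` networks from ``pool`` (indices
    into ``sim``) and computes the mean pairwise similarity among them —
    or, when ``fixed`` is given, the mean similarity between the
    selection and the fixed set (used for rest-task style comparisons).
    Exhaustive when the number of combinations is at most 1,000.
    """
    pool = np.asarray(pool)
    if n_select < (1 if fixed is not None else 2):
        raise ValueError("n_select too small")
    if len(pool) < n_select:
        raise ValueError(f"pool of {len(pool)} networks cannot supply {n_select}")
    n_comb = math.comb(len(pool), n_select)
    stat = (
        (lambda idx: _mean_cross(sim, idx, fixed))
        if fixed is not None
        else (lambda idx: _mean_pairwise(sim, idx))
    )
    if n_comb <= MAX_EXHAUSTIVE:
        samples = np.array([stat(np.array(c)) for c in itertools.combinations(pool, n_select)])
        return NullDistribution(samples=samples, mode="exhaustive", n_iter=n_comb, seed=seed)
    rng = np.random.default_rng(seed)
    samples = np.empty(MAX_EXHAUSTIVE)
    for i in range(MAX_EXHAUSTIVE):
        samples[i] = stat(rng.choice(pool, size=n_select, replace=False))
    return NullDistribution(samples=samples, mode="monte_carlo", n_iter=MAX_EXHAUSTIVE, seed=seed)


def build_null(pool: list[NetworkVector], n_select: int, seed: int = 0) -> NullDistribution:
    """Null distribution from a pool of network vectors (mean pairwise similarity)."""
    if n_select < 2:
        raise ValueError("n_select must be >= 2")
    sm = similarity_matrix(pool)
    return null_from_matrix(sm.values, np.arange(len(pool)), n_select, seed)


def z_test(observed: float, null: NullDistribution, two_tailed: bool = False) -> StatResult:
    """z-score an observation against its null distribution.

    p_z is the upper normal tail (one-tailed by default: the hypothesis
    is always that observed similarity exceeds baseline); p_perm counts
    null samples at or above the observation with the (b+1)/(m+1)
    convention.
    """
    sd = null.sd
    if sd == 0:
        raise ValueError("null distribution has zero spread; z undefined")
    z = (observed - null.baseline) / sd
    p_z = float(2 * _st.norm.sf(abs(z))) if two_tailed else float(_st.norm.sf(z))
    p_z = max(p_z, np.finfo(float).tiny)
    m = len(null.samples)
    p_perm = (int((null.samples >= observed).sum()) + 1) / (m + 1)
    return StatResult(observed=float(observed), z=float(z), p_z=p_z, p_perm=float(p_perm), baseline=null.baseline)


def fdr(pvals: list[float] | np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level q."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    if (pvals <= 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def group_t_vs_baseline(observed: np.ndarray, baseline: float) -> tuple[float, int, float]:
    """One-sample t test of per-subject similarity scores against baseline.

    Returns (t, df, two-sided p).
    """
    observed = np.asarray(observed, float)
    if observed.size < 2:
        raise ValueError("need at least 2 subjects")
    d = observed - baseline
    if d.std(ddof=1) == 0:
        # degenerate spread: all scores equal; t is 0 at the baseline,
        # otherwise infinitely far from it
        if d[0] == 0:
            return 0.0, int(observed.size - 1), 1.0
        return float(np.sign(d[0]) * np.inf), int(observed.size - 1), 0.0
    res = _st.ttest_1samp(observed, popmean=baseline)
    return float(res.statistic), int(observed.size - 1), float(res.pvalue)


# --- comparison suite ------------------------------------------------------


def _by_type(vectors: list[NetworkVector]) -> dict[tuple[str, str], list[int]]:
    groups: dict[tuple[str, str], list[int]] = {}
    for i, v in enumerate(vectors):
        groups.setdefault(v.network_type, []).append(i)
    return groups


def run_comparison_suite(
    vectors: list[NetworkVector],
    scheme: str,
    q: float = 0.05,
    seed: int = 0,
    session: str | None = "A",
    null_scope: str = "shared",
) -> pd.DataFrame:
    """Run one of the canonical similarity comparisons over a vector set.

    Within-subject schemes ("within_subject_rest", "within_subject_task",
    "rest_task") test, per subject and network type, whether that
    subject's networks are more alike than random selections from the
    population; clustering schemes ("frequency_clustering",
    "metric_clustering", "metric_clustering_no_power",
    "group_state_clustering") test at the group level whether networks
    sharing a band / metric / behavioral state are more alike than
    selections from the pooled set. ``session`` restricts within-subject
    schemes to one session (the reference analyses use session A); pass
    None to use all sessions.

    ``null_scope`` controls whether the within-state schemes evaluate
    every subject against one Monte-Carlo draw of the common null
    ("shared", the default) or against independent draws per subject
    ("per_subject"); the null *construction* is identical either way, and
    exhaustive enumerations are unaffected. The rest-task scheme always
    builds a separate null per individual, since it resamples against
    each subject's own task networks.

    Returns a tidy table with one row per (unit, network type):
    observed, baseline, z, one-tailed z-based p, permutation p, and a BH
    false-discovery flag applied within the scheme's family (across
    subjects within a network type, or across groups within an analysis).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if null_scope not in ("shared", "per_subject"):
        raise ValueError("null_scope must be 'shared' or 'per_subject'")
    if not vectors:
        raise ValueError("no vectors supplied")
    rows: list[dict] = []
    if scheme in ("within_subject_rest", "within_subject_task", "rest_task"):
        rows = _within_subject_scheme(vectors, scheme, seed, session, null_scope)
        family_keys = ("band", "metric")  # FDR across subjects within network type
    else:
        rows = _clustering_scheme(vectors, scheme, seed)
        family_keys = ("scheme",)  # FDR across groups within the analysis

    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError(f"scheme {scheme!r} found no applicable comparisons in the supplied labels")
    df["fdr_flag"] = False
    for _, idx in df.groupby(list(family_keys)).groups.items():
        df.loc[idx, "fdr_flag"] = fdr(df.loc[idx, "p_z"].to_numpy(), q=q)
    df["q"] = q
    return df


def _within_subject_scheme(vectors, scheme, seed, session, null_scope="shared"):
    rows = []
    for (band, metric), idxs in sorted(_by_type(vectors).items()):
        nets = [vectors[i] for i in idxs]
        if session is not None:
            keep = [i for i, v in enumerate(nets) if v.session == session]
            nets = [nets[i] for i in keep]
        if len(nets) < 3:
            continue
        sm = similarity_matrix(nets)
        meta = sm.row_meta
        subjects = sorted(meta["subject"].unique())
        rest_pool = meta.index[meta["state"] == "rest"].to_numpy()
        task_pool = meta.index[meta["state"] == "task"].to_numpy()

        shared_null = None
        for s_i, subj in enumerate(subjects):
            own = meta["subject"] == subj
            if scheme in ("within_subject_rest", "within_subject_task"):
                state = "rest" if scheme == "within_subject_rest" else "task"
                pool = rest_pool if state == "rest" else task_pool
                sel = meta.index[own & (meta["state"] == state)].to_numpy()
                if len(sel) < 2:
                    continue
                observed = _mean_pairwise(sm.values, sel)
                if null_scope == "per_subject":
                    null = null_from_matrix(sm.values, pool, len(sel), seed + 7919 * s_i)
                else:  # one Monte-Carlo draw of the common null for everyone
                    if shared_null is None:
                        shared_null = null_from_matrix(sm.values, pool, len(sel), seed)
                    null = shared_null
                n_pairs = len(sel) * (len(sel) - 1) // 2
            else:  # rest_task: per-individual null (own task vs random rest)
                own_rest = meta.index[own & (meta["state"] == "rest")].to_numpy()
                own_task = meta.index[own & (meta["state"] == "task")].to_numpy()
                if len(own_rest) < 1 or len(own_task) < 1:
                    continue
                observed = _mean_cross(sm.values, own_rest, own_task)
                null = null_from_matrix(
                    sm.values, rest_pool, len(own_rest), seed + s_i, fixed=own_task
                )
                n_pairs = len(own_rest) * len(own_task)
            res = z_test(observed, null)
            rows.append(
                {
                    "scheme": scheme,
                    "unit": subj,
                    "band": band,
                    "metric": metric,
                    "observed": res.observed,
                    "baseline": res.baseline,
                    "z": res.z,
                    "p_z": res.p_z,
                    "p_perm": res.p_perm,
                    "n_pairs": n_pairs,
                    "null_mode": null.mode,
                    "null_n": len(null.samples),
                }
            )
    return rows


_CLUSTER_FIELD = {
    "frequency_clustering": "band",
    "metric_clustering": "metric",
    "metric_clustering_no_power": "metric",
    "group_state_clustering": "state",
}


def _clustering_scheme(vectors, scheme, seed):
    field_name = _CLUSTER_FIELD[scheme]
    nets = list(vectors)
    if scheme == "metric_clustering_no_power":
        nets = [v for v in nets if v.metric != "power"]
    # pool dimension: all levels of the clustered field, holding the others fixed
    if field_name == "band":
        fixed_of = lambda v: (v.metric, v.state)
    elif field_name == "metric":
        fixed_of = lambda v: (v.band, v.state)
    else:
        fixed_of = lambda v: (v.band, v.metric)

    rows = []
    pools: dict[tuple, list[int]] = {}
    for i, v in enumerate(nets):
        pools.setdefault(fixed_of(v), []).append(i)
    for p_i, (fixed, idxs) in enumerate(sorted(pools.items())):
        sub = [nets[i] for i in idxs]
        sm = similarity_matrix(sub)
        meta = sm.row_meta
        levels = sorted(meta[field_name].unique())
        if len(levels) < 2:
            continue
        pool_all = np.arange(len(sub))
        for l_i, level in enumerate(levels):
            sel = meta.index[meta[field_name] == level].to_numpy()
            if len(sel) < 2:
                continue
            observed = _mean_pairwise(sm.values, sel)
            null = null_from_matrix(sm.values, pool_all, len(sel), seed + 97 * p_i + l_i)
            res = z_test(observed, null)
            if field_name == "band":
                band, metric = level, fixed[0]
            elif field_name == "metric":
                band, metric = fixed[0], level
            else:
                band, metric = fixed
            rows.append(
                {
                    "scheme": scheme,
                    "unit": level,
                    "band": band,
                    "metric": metric,
                    "fixed": "|".join(map(str, fixed)),
                    "observed": res.observed,
                    "baseline": res.baseline,
                    "z": res.z,
                    "p_z": res.p_z,
                    "p_perm": res.p_perm,
                    "n_pairs": len(sel) * (len(sel) - 1) // 2,
                    "null_mode": null.mode,
                    "null_n": len(null.samples),
                }
            )
    return rows
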