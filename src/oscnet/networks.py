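"""Network vectors: assembly from connectivity matrices, Box-Cox
standardization, power-to-connection expansion, and global summaries.

A "network" is the brain-wide pattern of one oscillatory measure for one
data segment and frequency band: a power vector V with one dB value per
electrode (length 60 on the reference cap), or a connectivity vector U
with one value per non-neighboring electrode pair (length 1,578 on the
reference cap after excluding the 192 neighbor pairs).

Connectivity values are skewed, so before Pearson-based similarity each
connectivity vector is shifted by +1 (ensuring positivity), Box-Cox power
transformed with a per-vector exponent, and z-scored. Power vectors are
already approximately normal in dB and are never Box-Cox transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import ConnectivityMatrix
from .montage import PairIndex

__all__ = [
    "ElementIndex",
    "NetworkVector",
    "assemble_connectivity_vector",
    "power_vector",
    "boxcox_standardize",
    "expand_power_vector",
    "global_stat",
]

_POSITIVITY_EPS = 1e-12


@dataclass(frozen=True)
class ElementIndex:
    """Identifies what each vector element refers to.

    kind is "channels" (power: element = electrode) or "pairs"
    (connectivity: element = non-neighboring channel pair); ids is the
    ordered tuple of element identifiers. Vectors are only comparable when
    their element indexes match.
    """

    kind: str
    ids: tuple

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class NetworkVector:
    """One network: values plus the element index and full metadata."""

    values: np.ndarray
    element_index: ElementIndex
    subject: str
    session: str
    state: str
    block_id: str
    band: str
    metric: str
    transformed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("network vector values must be 1-D")
        if len(v) != len(self.element_index):
            raise ValueError("values length must match element_index")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)

    @property
    def labels(self) -> dict:
        return {
            "subject": self.subject,
            "session": self.session,
            "state": self.state,
            "block_id": self.block_id,
            "band": self.band,
            "metric": self.metric,
        }

    @property
    def network_type(self) -> tuple[str, str]:
        """(band, metric) combination, e.g. ('alpha', 'plv')."""
        return (self.band, self.metric)


def pair_element_index(idx: PairIndex, channel_names: tuple[str, ...] | None = None) -> ElementIndex:
    """Element index over the non-neighboring pairs of ``idx`` (pair order preserved)."""
    kept = idx.kept_pairs
    if channel_names:
        ids = tuple((channel_names[j], channel_names[k]) for j, k in kept)
    else:
        ids = tuple((int(j), int(k)) for j, k in kept)
    return ElementIndex("pairs", ids)


def assemble_connectivity_vector(m: ConnectivityMatrix, idx: PairIndex) -> NetworkVector:
    """Extract the connectivity vector U from a symmetric matrix.

    Upper-triangle entries are taken in the deterministic row-major pair
    order, with neighbor-masked pairs dropped (on the reference cap:
    1,770 pairs minus 192 neighbors = 1,578 elements). Missing (NaN)
    entries are an error — they indicate a degenerate metric value that
    must be resolved upstream.
    """
    if m.n_channels != idx.n_channels:
        raise ValueError("matrix and pair index disagree on channel count")
    if not np.allclose(m.values, m.values.T, equal_nan=True):
        raise ValueError("connectivity matrix must be symmetric")
    kept = idx.kept_pairs
    vals = m.values[kept[:, 0], kept[:, 1]]
    if np.isnan(vals).any():
        raise ValueError(f"{int(np.isnan(vals).sum())} missing connectivity entries; cannot assemble vector")
    return NetworkVector(
        values=vals,
        element_index=pair_element_index(idx, m.channel_names or None),
        subject=m.labels.get("subject", "?"),
        session=m.labels.get("session", "?"),
        state=m.labels.get("state", "?"),
        block_id=m.labels.get("block_id", "?"),
        band=m.band,
        metric=m.metric,
    )


def power_vector(values: np.ndarray, channel_names: tuple[str, ...], labels: dict, band: str) -> NetworkVector:
    """Wrap per-channel dB band power values as a power network vector V."""
    return NetworkVector(
        values=np.asarray(values, float),
        element_index=ElementIndex("channels", tuple(channel_names)),
        subject=labels["subject"],
        session=labels["session"],
        state=labels["state"],
        block_id=labels["block_id"],
        band=band,
        metric="power",
    )


def _boxcox_transform(x: np.ndarray, lam: float, gm: float) -> np.ndarray:
    """Geometric-mean-normalized Box-Cox transform (scale-comparable across lambda)."""
    if lam == 0.0:
        return gm * np.log(x)
    return (np.power(x, lam) - 1.0) / (lam * gm ** (lam - 1.0))


def select_boxcox_lambda(
    x: np.ndarray,
    grid: np.ndarray | None = None,
    mode: str = "normalized",
) -> float:
    """Per-vector Box-Cox exponent minimizing the transformed SD.

    The default "normalized" mode minimizes the SD of the geometric-mean-
    normalized transform (x^lam - 1) / (lam * GM^(lam-1)) over a grid of
    lambda in [-5, 5] with step 0.01; this is equivalent to maximizing the
    Box-Cox profile log-likelihood and is well-posed. The literal "raw"
    mode (SD of (x^lam - 1)/lam without normalization) is exposed for
    comparison but degenerates toward the grid edge for most data.
    """
    if grid is None:
        grid = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.01), 10)
    logs = np.log(x)
    if np.ptp(logs) == 0:
        return 1.0  # constant vector: any lambda; identity by convention
    gm = np.exp(logs.mean())
    lam = grid[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        t = np.where(
            lam == 0.0,
            gm * logs[None, :],
            (np.exp(lam * logs[None, :]) - 1.0) / np.where(lam == 0.0, 1.0, lam * gm ** (lam - 1.0)),
        )
        sds = t.std(axis=1)
    if mode == "raw":
        with np.errstate(over="ignore", invalid="ignore"):
            t_raw = np.where(
                lam == 0.0,
                logs[None, :],
                (np.exp(lam * logs[None, :]) - 1.0) / np.where(lam == 0.0, 1.0, lam),
            )
            sds = t_raw.std(axis=1)
    elif mode != "normalized":
        raise ValueError("mode must be 'normalized' or 'raw'")
    sds = np.where(np.isfinite(sds), sds, np.inf)
    return float(grid[int(np.argmin(sds))])


def boxcox_standardize(u: NetworkVector, mode: str = "normalized") -> NetworkVector:
    """Shift (+1), Box-Cox transform, and z-score a connectivity vector.

    Applies only to connectivity vectors: power vectors are approximately
    normal after the dB transform and are left untouched. After the +1
    shift all entries must be positive (PLV maps to [1, 2], AEC to
    [0, 2]); exact zeros (the theoretical AEC = -1 edge) are nudged to a
    strict-positivity guard of 1e-12. The selected exponent is recorded in
    ``meta['boxcox_lambda']``. z-scoring gives the transformed vector mean
    0 and SD 1 but does not affect subsequent Pearson correlations.
    """
    if u.metric == "power":
        raise ValueError("power vectors are never Box-Cox transformed")
    if u.transformed:
        raise ValueError("vector already transformed")
    x = u.values + 1.0
    if (x < 0).any():
        raise ValueError("nonpositive entries after +1 shift; connectivity values below -1 are invalid")
    x = np.maximum(x, _POSITIVITY_EPS)
    lam = select_boxcox_lambda(x, mode=mode)
    gm = float(np.exp(np.log(x).mean()))
    t = _boxcox_transform(x, lam, gm)
    sd = t.std()
    if sd == 0:
        z = np.zeros_like(t)
    else:
        z = (t - t.mean()) / sd
    out = replace(u, values=z, transformed=True, meta={**u.meta, "boxcox_lambda": lam})
    return out


def expand_power_vector(v: NetworkVector, idx: PairIndex) -> NetworkVector:
    """Expand a power vector to "power connectivity" format.

    Each pair (j, k) receives the average power of the two electrodes,
    (V_j + V_k) / 2, with neighbor pairs dropped — yielding a vector of
    the same length and element order as the connectivity vectors so that
    power and connectivity networks can be compared directly. The
    expansion adds no information (every entry is a linear combination of
    the original powers) and with all pairs retained leaves Pearson
    network similarity exactly unchanged.
    """
    if v.element_index.kind != "channels":
        raise ValueError("expand_power_vector expects a per-channel power vector")
    if len(v) != idx.n_channels:
        raise ValueError("power vector length must equal pair-index channel count")
    kept = idx.kept_pairs
    vals = (v.values[kept[:, 0]] + v.values[kept[:, 1]]) / 2.0
    names = v.element_index.ids
    return replace(
        v,
        values=vals,
        element_index=pair_element_index(idx, tuple(names)),
        meta={**v.meta, "expanded_from": "power"},
    )


def global_stat(x: NetworkVector) -> float:
    """Global power / global connectivity: the mean over vector elements.

    Defined on untransformed vectors only (after z-scoring the mean is 0
    by construction and carries no information).
    """
    if x.transformed:
        raise ValueError("global statistic is defined on untransformed vectors")
    return float(np.mean(x.values))
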