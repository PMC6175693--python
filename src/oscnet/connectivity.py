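"""Pairwise functional connectivity metrics and fragment-averaged matrices.

Primary metrics: the phase locking value (PLV) — the length of the
time-averaged unit phasor of the phase difference between two channels —
and amplitude envelope correlation (AEC) — the Spearman rank correlation
between Hilbert amplitude envelopes (rank-based because envelopes are
generally not normally distributed).

Control metrics robust to zero-lag (volume-conducted) coupling: the
weighted phase lag index (wPLI), based on the imaginary part of the
cross-spectrum, and orthogonalized envelope correlation (oAEC), which
removes at each sample the component of one analytic signal parallel to
the other before correlating envelopes.

Connectivity for a segment is estimated per fragment (default 10 equal
fragments) and averaged, limiting the influence of outliers and
nonstationary phase relations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectral import AnalyticBand, fragment

__all__ = ["ConnectivityMatrix", "plv", "aec", "wpli", "oaec", "connectivity_matrix", "METRICS"]

METRICS = ("plv", "aec", "wpli", "oaec")
#: Metrics implemented as volume-conduction controls rather than primary measures.
CONTROL_METRICS = ("wpli", "oaec")


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels connectivity values for one segment/band."""

    values: np.ndarray
    metric: str
    band: str
    labels: dict = field(default_factory=dict)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be square")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def plv(phase_j: np.ndarray, phase_k: np.ndarray) -> float:
    """Phase locking value: ``|mean(exp(i (phi_j - phi_k)))|`` in [0, 1].

    1 indicates a perfectly consistent phase relation (including any fixed
    lag); 0 indicates random phase relations.
    """
    phase_j = np.asarray(phase_j, float)
    phase_k = np.asarray(phase_k, float)
    if phase_j.shape != phase_k.shape:
        raise ValueError("phase series must have equal length")
    if phase_j.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_j - phase_k)))))


def aec(amp_j: np.ndarray, amp_k: np.ndarray) -> float:
    """Amplitude envelope correlation: Spearman rho of the two envelopes.

    Returns NaN (error flag) when either envelope has zero variance.
    """
    amp_j = np.asarray(amp_j, float)
    amp_k = np.asarray(amp_k, float)
    if amp_j.shape != amp_k.shape:
        raise ValueError("amplitude series must have equal length")
    if amp_j.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(amp_j) == 0 or np.ptp(amp_k) == 0:
        return float("nan")
    rho = stats.spearmanr(amp_j, amp_k).statistic
    return float(rho)


def wpli(x_j: np.ndarray, x_k: np.ndarray) -> float:
    """Weighted phase lag index from two complex analytic series.

    wPLI = |mean(Im S)| / mean(|Im S|) with S the sample cross-spectrum
    ``x_j * conj(x_k)``; defined as 0 when the imaginary cross-spectrum
    vanishes (e.g., pure zero-lag coupling).
    """
    x_j = np.asarray(x_j, complex)
    x_k = np.asarray(x_k, complex)
    if x_j.shape != x_k.shape:
        raise ValueError("analytic series must have equal length")
    s = x_j * np.conj(x_k)
    im = np.imag(s)
    denom = np.mean(np.abs(im))
    # guard against pure float noise from an exactly-real cross-spectrum
    if denom <= 1e-12 * np.mean(np.abs(s)):
        warnings.warn("wPLI: imaginary cross-spectrum vanishes; returning 0", stacklevel=2)
        return 0.0
    return float(np.abs(np.mean(im)) / denom)


def oaec(x_j: np.ndarray, x_k: np.ndarray, _tol: float = 1e-12) -> float:
    """Orthogonalized envelope correlation (symmetrized).

    At each sample the component of one analytic signal parallel to the
    other is removed (the residual envelope is |Im(x_k conj(x_j))| / |x_j|),
    the residual envelope is Spearman-correlated with the other signal's
    envelope, and the two directions are averaged. Shared (zero-lag)
    signal is thereby suppressed; a degenerate residual (identical signals
    up to real scale) is defined as 0.
    """
    x_j = np.asarray(x_j, complex)
    x_k = np.asarray(x_k, complex)
    if x_j.shape != x_k.shape:
        raise ValueError("analytic series must have equal length")
    if x_j.size < 3:
        raise ValueError("need at least 3 samples")
    aj, ak = np.abs(x_j), np.abs(x_k)
    if not (aj > 0).all() or not (ak > 0).all():
        return float("nan")

    def one_way(a_ref: np.ndarray, x_ref: np.ndarray, x_other: np.ndarray) -> float:
        resid = np.abs(np.imag(x_other * np.conj(x_ref))) / np.abs(x_ref)
        if np.ptp(resid) <= _tol * max(np.max(resid), 1.0) or np.ptp(a_ref) == 0:
            return 0.0
        return float(stats.spearmanr(a_ref, resid).statistic)

    return 0.5 * (one_way(aj, x_j, x_k) + one_way(ak, x_k, x_j))


# --- vectorized per-fragment matrix computations --------------------------


def _plv_matrix(phase: np.ndarray) -> np.ndarray:
    e = np.exp(1j * phase)
    n = phase.shape[1]
    return np.abs(e @ e.conj().T) / n


def _aec_matrix(amp: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(amp, axis=1)
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(ranks)
    m[sd == 0, :] = np.nan
    m[:, sd == 0] = np.nan
    return m


def _wpli_matrix(z: np.ndarray) -> np.ndarray:
    # pairwise Im cross-spectra; chunk rows to bound memory on large caps
    n = z.shape[0]
    out = np.zeros((n, n))
    chunk = max(1, int(2e7 // max(z.shape[1], 1) // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        s = z[start:stop, None, :] * np.conj(z)[None, :, :]
        im = np.imag(s)
        num = np.abs(im.mean(axis=2))
        den = np.abs(im).mean(axis=2)
        floor = 1e-12 * np.abs(s).mean(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            block = np.where(den > floor, num / den, 0.0)
        out[start:stop] = block
    np.fill_diagonal(out, 0.0)
    return out


def _oaec_matrix(z: np.ndarray, _tol: float = 1e-12) -> np.ndarray:
    n = z.shape[0]
    amp = np.abs(z)
    if not (amp > 0).all():
        bad = np.flatnonzero(~(amp > 0).all(axis=1))
        out = np.full((n, n), np.nan)
        good = np.setdiff1d(np.arange(n), bad)
        zg = z[good]
        sub = _oaec_matrix_dense(zg, _tol)
        out[np.ix_(good, good)] = sub
        return out
    return _oaec_matrix_dense(z, _tol)


def _oaec_matrix_dense(z: np.ndarray, _tol: float) -> np.ndarray:
    n, L = z.shape
    amp = np.abs(z)
    amp_ranks = stats.rankdata(amp, axis=1)
    out = np.eye(n)
    for j in range(n):
        # residual envelope of every channel orthogonalized w.r.t. channel j
        resid = np.abs(np.imag(z * np.conj(z[j])[None, :])) / amp[j][None, :]
        r_ranks = stats.rankdata(resid, axis=1)
        rj = amp_ranks[j]
        sd_r = r_ranks.std(axis=1)
        sd_j = rj.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = ((r_ranks - r_ranks.mean(axis=1, keepdims=True)) @ (rj - rj.mean())) / L
            rho = cov / (sd_r * sd_j)
        degenerate = np.ptp(resid, axis=1) <= _tol * np.maximum(resid.max(axis=1), 1.0)
        rho[degenerate] = 0.0
        out[j, :] += 0.0  # keep diagonal 1 from eye
        for k in range(n):
            if k == j:
                continue
            out[k, j] += 0.5 * rho[k]
            out[j, k] += 0.5 * rho[k]
    return out


_MATRIX_FNS = {
    "plv": lambda ab: _plv_matrix(ab.phase),
    "aec": lambda ab: _aec_matrix(ab.amplitude),
    "wpli": lambda ab: _wpli_matrix(ab.amplitude * np.exp(1j * ab.phase)),
    "oaec": lambda ab: _oaec_matrix(ab.amplitude * np.exp(1j * ab.phase)),
}


def connectivity_matrix(ab: AnalyticBand, metric: str, n_frag: int = 10) -> ConnectivityMatrix:
    """Fragment-averaged connectivity matrix for one band-limited segment.

    The metric is computed separately within each of ``n_frag`` equal
    fragments and the estimates are arithmetically averaged. Per-pair
    error flags (NaN, e.g. a flat envelope) propagate as missing entries.
    """
    if metric not in _MATRIX_FNS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    frags = fragment(ab, n_frag)
    if any(f.n_samples < 3 for f in frags):
        raise ValueError("fragments shorter than 3 samples; reduce n_frag or provide longer data")
    acc = np.zeros((ab.n_channels, ab.n_channels))
    for f in frags:
        acc += _MATRIX_FNS[metric](f)
    vals = acc / n_frag
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry against float noise
    np.fill_diagonal(vals, 1.0 if metric in ("aec", "oaec", "plv") else 0.0)
    return ConnectivityMatrix(
        values=vals,
        metric=metric,
        band=ab.band.name,
        labels=dict(ab.labels),
        channel_names=ab.channel_names,
    )
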