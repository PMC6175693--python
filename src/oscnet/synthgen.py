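"""Synthetic data with the statistical structure the analysis assumes.

Two generators are provided so that every downstream stage is testable
without access to raw recordings:

* :func:`generate_segments` emulates multichannel recordings at the
  spatially-filtered level: per frequency band, latent band-limited
  sources are projected to the sensors through a mixing matrix composed
  of a group template plus subject-, state-, and session-specific
  perturbations, on top of 1/f background noise. Subject-specific mixing
  that is stable across states and sessions is what gives rise to
  individual network "fingerprints" downstream.

* :func:`generate_vectors` skips signal processing and draws network
  vectors directly from an additive variance-components model
  x = G(band,metric) + T(band,metric,state) + S(subject,band,metric) + e,
  for which :func:`expected_similarity` gives the exact expected Pearson
  similarity of any pair relation — the oracle for recovery tests.

All randomness derives deterministically from the integer seed; the same
seed reproduces outputs bit for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .montage import Montage
from .networks import ElementIndex, NetworkVector
from .spectral import DEFAULT_BANDS, BandDefinition, Segment, design_bandpass

__all__ = [
    "Block",
    "ProtocolSpec",
    "default_protocol",
    "SignalModelParams",
    "VectorModelParams",
    "generate_segments",
    "generate_vectors",
    "expected_similarity",
    "RELATIONS",
]

RELATIONS = ("same-subject-same-state", "same-subject-cross-state", "cross-subject")


@dataclass(frozen=True)
class Block:
    """One behavioral block: a session, a state (rest/task), and a unique id."""

    session: str
    state: str
    block_id: str


@dataclass(frozen=True)
class ProtocolSpec:
    """The sequence of labeled blocks making up a study protocol."""

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        ids = [b.block_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ValueError("block ids must be unique")
        for b in self.blocks:
            if b.state not in ("rest", "task"):
                raise ValueError(f"unknown state {b.state!r}")

    @property
    def sessions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in self.blocks:
            if b.session not in seen:
                seen.append(b.session)
        return tuple(seen)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def default_protocol() -> ProtocolSpec:
    """The reference three-session protocol: 20 blocks in total.

    Session A: 7 rest + 2 task; session B (same day, hours later): 4 rest;
    session C (months later): 5 rest + 2 task.
    """
    blocks = []
    blocks += [Block("A", "rest", f"rest_A{i}") for i in range(1, 8)]
    blocks += [Block("A", "task", f"task_A{i}") for i in range(1, 3)]
    blocks += [Block("B", "rest", f"rest_B{i}") for i in range(1, 5)]
    blocks += [Block("C", "rest", f"rest_C{i}") for i in range(1, 6)]
    blocks += [Block("C", "task", f"task_C{i}") for i in range(1, 3)]
    return ProtocolSpec(tuple(blocks))


def _rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic child generator keyed by (seed, tags) via hashing."""
    digest = hashlib.blake2b(repr(tags).encode(), digest_size=16).digest()
    words = np.frombuffer(digest, dtype=np.uint32).tolist()
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *words]))


# --- signal-level generator ----------------------------------------------


@dataclass(frozen=True)
class SignalModelParams:
    """Parameters of the multichannel signal generator.

    Effects are dimensionless multipliers on the corresponding mixing
    perturbations relative to the group template; noise_level scales the
    1/f background relative to unit-variance oscillatory channel signal.
    Defaults (fs=200 Hz, 60 s) favor test speed; recording-scale values
    (400 Hz, ~290 s) are available through configuration.
    """

    n_subjects: int = 6
    fs: float = 200.0
    duration: float = 60.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    n_sources_per_band: int = 8
    subject_effect: float = 1.0
    state_effect: float = 0.5
    session_drift: float = 0.2
    noise_level: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_effect", "state_effect", "session_drift", "noise_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        bands = sorted(self.bands, key=lambda b: b.lo)
        for a, b in zip(bands, bands[1:]):
            if b.lo < a.hi:
                raise ValueError(f"bands {a.name} and {b.name} overlap")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with ~1/f power, unit variance."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # flat below 1 Hz
    spec *= scale[None, :]
    out = np.fft.irfft(spec, n=n, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _band_sources(params: SignalModelParams, block: Block, band: BandDefinition) -> np.ndarray:
    """Latent unit-variance band-limited sources, keyed by (session, block, band).

    Sources are deliberately keyed independently of subject identity: two
    subjects differ only through their mixing matrices, so setting all
    subject/state/session effects to zero makes their recordings identical.
    """
    n = int(round(params.fs * params.duration))
    rng = _rng(params.seed, "sources", block.session, block.block_id, band.name)
    raw = rng.standard_normal((params.n_sources_per_band, n))
    taps = design_bandpass(band, params.fs)
    src = _signal.filtfilt(taps, [1.0], raw, axis=1)
    sd = src.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return src / sd


def _mixing(params: SignalModelParams, n_ch: int, subject: str, block: Block, band: BandDefinition) -> np.ndarray:
    shape = (n_ch, params.n_sources_per_band)
    norm = np.sqrt(params.n_sources_per_band)

    def tpl(*tags) -> np.ndarray:
        return _rng(params.seed, *tags).standard_normal(shape) / norm

    mix = tpl("group", band.name)
    if params.subject_effect:
        mix = mix + params.subject_effect * tpl("subject", subject, band.name)
    if params.state_effect:
        mix = mix + params.state_effect * tpl("state", block.state, band.name)
    if params.session_drift:
        mix = mix + params.session_drift * tpl("drift", block.session, band.name)
    return mix


def generate_segments(
    params: SignalModelParams,
    protocol: ProtocolSpec | None = None,
    montage: Montage | None = None,
    n_channels: int | None = None,
) -> list[Segment]:
    """Simulate labeled multichannel segments for every subject and block.

    Channel count comes from ``montage`` when given, else ``n_channels``
    (default 60). Per band, channel signals are mixing @ sources with the
    mixing matrix composed as group template + subject_effect * subject
    template + state_effect * state template + session_drift * session
    perturbation; 1/f background noise is added on top. Fully reproducible
    from the seed.
    """
    if protocol is None:
        protocol = default_protocol()
    nyq = params.fs / 2
    for band in params.bands:
        if band.hi >= nyq:
            raise ValueError(f"band {band.name} extends to {band.hi} Hz, at or above Nyquist {nyq} Hz")
    if params.duration < 10:
        raise ValueError("duration must be at least 10 s")
    if montage is not None:
        n_ch = montage.n_channels
        names = montage.names
    else:
        n_ch = n_channels or 60
        names = tuple(f"ch{i}" for i in range(n_ch))

    segments: list[Segment] = []
    subjects = [f"sub{i + 1:02d}" for i in range(params.n_subjects)]
    # sources are shared across subjects within a block: compute once per block/band
    for block in protocol.blocks:
        sources = {band.name: _band_sources(params, block, band) for band in params.bands}
        for subject in subjects:
            n = int(round(params.fs * params.duration))
            data = np.zeros((n_ch, n))
            for band in params.bands:
                data += _mixing(params, n_ch, subject, block, band) @ sources[band.name]
            if params.noise_level:
                rng = _rng(params.seed, "background", subject, block.session, block.block_id)
                data += params.noise_level * _pink_noise(rng, (n_ch, n), params.fs)
            segments.append(
                Segment(
                    data=data,
                    fs=params.fs,
                    subject=subject,
                    session=block.session,
                    state=block.state,
                    block_id=block.block_id,
                    channel_names=names,
                )
            )
    return segments


# --- direct vector-level generator ----------------------------------------


@dataclass(frozen=True)
class VectorModelParams:
    """Variance components of the direct network-vector generator.

    Every vector of a given (band, metric) is the sum of a shared group
    pattern (variance v_group), a state pattern shared across subjects
    (v_state), a subject fingerprint stable across states and sessions
    (v_subject), and i.i.d. element noise (v_noise).
    """

    length: int = 200
    v_group: float = 1.0
    v_subject: float = 1.0
    v_state: float = 0.25
    v_noise: float = 1.0
    n_subjects: int = 6
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")
    metrics: tuple[str, ...] = ("power", "plv", "aec")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("vector length must be >= 2")
        for name in ("v_group", "v_subject", "v_state", "v_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total_variance(self) -> float:
        return self.v_group + self.v_subject + self.v_state + self.v_noise


def generate_vectors(params: VectorModelParams, protocol: ProtocolSpec | None = None) -> list[NetworkVector]:
    """Draw labeled network-vector populations from the variance model.

    Returns one vector per (subject, block, band, metric), with all
    components i.i.d. normal at the stated variances and labels attached
    per the protocol.
    """
    if protocol is None:
        protocol = default_protocol()
    L = params.length
    element_index = ElementIndex("synthetic", tuple(range(L)))
    subjects = [f"sub{i + 1:02d}" for i in range(params.n_subjects)]

    def draw(v: float, *tags) -> np.ndarray:
        if v == 0:
            return np.zeros(L)
        return np.sqrt(v) * _rng(params.seed, *tags).standard_normal(L)

    out: list[NetworkVector] = []
    for band in params.bands:
        for metric in params.metrics:
            g = draw(params.v_group, "vg", band, metric)
            t_state = {
                st: draw(params.v_state, "vt", band, metric, st) for st in ("rest", "task")
            }
            s_subj = {
                s: draw(params.v_subject, "vs", band, metric, s) for s in subjects
            }
            for subject in subjects:
                for block in protocol.blocks:
                    e = draw(params.v_noise, "ve", band, metric, subject, block.block_id)
                    out.append(
                        NetworkVector(
                            values=g + t_state[block.state] + s_subj[subject] + e,
                            element_index=element_index,
                            subject=subject,
                            session=block.session,
                            state=block.state,
                            block_id=block.block_id,
                            band=band,
                            metric=metric,
                        )
                    )
    return out


def expected_similarity(params: VectorModelParams, relation: str) -> float:
    """Exact expected Pearson similarity between two vectors of one relation.

    Under the additive model the expected correlation is the shared
    variance divided by the total variance:

    * same-subject-same-state: (v_group + v_state + v_subject) / total
    * same-subject-cross-state: (v_group + v_subject) / total
    * cross-subject (same state): (v_group + v_state) / total
    """
    total = params.total_variance
    if total <= 0:
        raise ValueError("total variance must be positive")
    shared = {
        "same-subject-same-state": params.v_group + params.v_state + params.v_subject,
        "same-subject-cross-state": params.v_group + params.v_subject,
        "cross-subject": params.v_group + params.v_state,
    }
    if relation not in shared:
        raise ValueError(f"unknown relation {relation!r}; choose from {RELATIONS}")
    return shared[relation] / total
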