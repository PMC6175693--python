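"""Band definitions, zero-phase band-pass filtering, analytic signal, Welch
band power (dB), and fragmenting of phase/amplitude time series.

The canonical band set is theta (3-7 Hz), alpha (8-12 Hz), beta (13-30 Hz),
gamma (32-60 Hz). Band power is computed per channel with Welch's method
(5-s Hamming windows, 50% overlap), each PSD bin dB-transformed as
10*log10(power), then averaged across the bins whose center frequency falls
inside the band (edges inclusive) — the dB-then-average order matters for
skewed spectra and is fixed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "Segment",
    "AnalyticBand",
    "bandpass",
    "analytic",
    "welch_band_power_db",
    "fragment",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"require 0 < lo < hi, got [{self.lo}, {self.hi}]")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 3.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 32.0, 60.0),
)


@dataclass
class Segment:
    """One labeled multichannel time-series block (the unit of analysis).

    data is channels x samples in arbitrary amplitude units; labels identify
    the subject, session, behavioral state (rest/task) and block id. ``edge``
    counts samples at each end contaminated by filtering, to be excluded
    from phase/amplitude analyses.
    """

    data: np.ndarray
    fs: float
    subject: str
    session: str
    state: str
    block_id: str
    channel_names: tuple[str, ...] = ()
    edge: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains missing/non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for lbl in (self.subject, self.session, self.state, self.block_id):
            if lbl == "":
                raise ValueError("segment labels (subject/session/state/block_id) must be complete")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def labels(self) -> dict:
        return {
            "subject": self.subject,
            "session": self.session,
            "state": self.state,
            "block_id": self.block_id,
        }


@dataclass
class AnalyticBand:
    """Instantaneous phase (radians, (-pi, pi]) and nonnegative amplitude of a
    band-limited segment, with edge samples already trimmed."""

    phase: np.ndarray
    amplitude: np.ndarray
    band: BandDefinition
    fs: float
    labels: dict = field(default_factory=dict)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude must share shape")

    @property
    def n_channels(self) -> int:
        return self.phase.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phase.shape[1]


def design_bandpass(band: BandDefinition, fs: float) -> np.ndarray:
    """Windowed-sinc (Hamming) FIR band-pass taps for ``band``.

    Transition width is min(2 Hz, 25% of the band width), which keeps
    adjacent default bands' pass-bands essentially non-overlapping
    (Hamming stop-band attenuation ~53 dB).
    """
    if band.hi >= fs / 2:
        raise ValueError(f"band {band.name} upper edge {band.hi} Hz at or above Nyquist ({fs / 2} Hz)")
    width = min(2.0, 0.25 * (band.hi - band.lo))
    # Hamming window design rule: transition width ~ 3.3 / numtaps (normalized)
    numtaps = int(np.ceil(3.3 * fs / width))
    numtaps |= 1  # odd length -> type-I linear phase
    return signal.firwin(numtaps, [band.lo, band.hi], window="hamming", pass_zero=False, fs=fs)


def bandpass(seg: Segment, band: BandDefinition) -> Segment:
    """Zero-phase FIR band-pass filter a segment.

    Filtering is forward-backward (filtfilt), so the effective impulse
    response is the squared-magnitude FIR and the phase response is zero.
    The returned segment's ``edge`` marks one filter length at each end as
    contaminated.
    """
    taps = design_bandpass(band, seg.fs)
    if seg.n_samples < 3 * len(taps):
        raise ValueError(
            f"segment too short for band {band.name}: {seg.n_samples} samples "
            f"< 3 x filter length {len(taps)}"
        )
    logger.debug("bandpass %s: %d taps at fs=%g", band.name, len(taps), seg.fs)
    out = signal.filtfilt(taps, [1.0], seg.data, axis=1)
    return replace(seg, data=out, edge=len(taps))


def analytic(seg: Segment, band: BandDefinition | None = None) -> AnalyticBand:
    """Instantaneous phase and amplitude via the Hilbert analytic signal.

    The input must already be band-limited (see :func:`bandpass`); the
    segment's ``edge`` samples are trimmed from both ends of the output.
    """
    z = signal.hilbert(seg.data, axis=1)
    e = seg.edge
    if e > 0:
        if seg.n_samples <= 2 * e:
            raise ValueError("segment shorter than twice the filter edge; nothing left after trim")
        z = z[:, e:-e]
    if band is None:
        band = BandDefinition("unspecified", 1e-9, seg.fs / 2 - 1e-9)
    return AnalyticBand(
        phase=np.angle(z),
        amplitude=np.abs(z),
        band=band,
        fs=seg.fs,
        labels=seg.labels,
        channel_names=seg.channel_names,
    )


def analytic_complex(seg: Segment) -> np.ndarray:
    """Raw complex analytic signal (edge-trimmed), for cross-spectral metrics."""
    z = signal.hilbert(seg.data, axis=1)
    e = seg.edge
    return z[:, e:-e] if e > 0 else z


def welch_band_power_db(
    seg: Segment,
    band: BandDefinition,
    win: float = 5.0,
    overlap: float = 0.5,
) -> np.ndarray:
    """Per-channel band power in dB (Welch PSD, Hamming windows).

    Each PSD bin is transformed as 10*log10(power) and the dB values are
    averaged over the bins whose center frequency lies in [lo, hi]
    inclusive. Returns one value per channel (the power network vector V
    for a 60-channel segment).
    """
    nperseg = int(round(win * seg.fs))
    if seg.n_samples < 2 * nperseg * (1 - overlap) + nperseg * overlap:
        raise ValueError(f"segment length {seg.n_samples} supports fewer than 2 Welch windows of {win}s")
    noverlap = int(round(nperseg * overlap))
    freqs, psd = signal.welch(
        seg.data, fs=seg.fs, window="hamming", nperseg=nperseg, noverlap=noverlap, axis=1
    )
    in_band = (freqs >= band.lo) & (freqs <= band.hi)
    if not in_band.any():
        raise ValueError(f"no PSD bins fall inside band {band.name} [{band.lo}, {band.hi}] Hz")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(psd[:, in_band])
    return db.mean(axis=1)


def fragment(x: AnalyticBand, n: int = 10) -> list[AnalyticBand]:
    """Split phase/amplitude series into ``n`` equal contiguous fragments.

    Fragment length is ``floor(samples / n)``; trailing remainder samples
    are dropped (and logged). Fragmenting reduces the influence of
    outliers and, for phase coupling, accommodates nonstationary phase
    relations within a segment.
    """
    if n < 1:
        raise ValueError("fragment count must be >= 1")
    if x.n_samples < n:
        raise ValueError(f"cannot split {x.n_samples} samples into {n} fragments")
    flen = x.n_samples // n
    dropped = x.n_samples - flen * n
    if dropped:
        logger.debug("fragment: dropping %d trailing samples", dropped)
    return [
        AnalyticBand(
            phase=x.phase[:, i * flen:(i + 1) * flen],
            amplitude=x.amplitude[:, i * flen:(i + 1) * flen],
            band=x.band,
            fs=x.fs,
            labels=x.labels,
            channel_names=x.channel_names,
        )
        for i in range(n)
    ]
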