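"""Reading and writing segments and derived tables.

Segments travel either as EDF (read through mne) or as the package's
plain array container: a text file whose first line is a ``#``-prefixed
JSON header (sampling rate, labels, channel names) followed by a
whitespace-delimited channels x samples matrix. The container is
human-inspectable and needs nothing beyond numpy to parse.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .spectral import Segment

__all__ = ["write_segment", "read_segment", "read_edf_segment", "write_connectivity_csv", "read_connectivity_csv"]


def write_segment(seg: Segment, path: str | Path) -> Path:
    """Write a segment to the plain array container (text)."""
    path = Path(path)
    header = {
        "fs": seg.fs,
        "subject": seg.subject,
        "session": seg.session,
        "state": seg.state,
        "block_id": seg.block_id,
        "channel_names": list(seg.channel_names),
        "edge": seg.edge,
    }
    with path.open("w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        np.savetxt(fh, seg.data, fmt="%.9g")
    return path


def read_segment(path: str | Path) -> Segment:
    """Read a segment from the plain array container."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[1:])
        data = np.loadtxt(fh, ndmin=2)
    return Segment(
        data=data,
        fs=header["fs"],
        subject=header["subject"],
        session=header["session"],
        state=header["state"],
        block_id=header["block_id"],
        channel_names=tuple(header["channel_names"]),
        edge=int(header.get("edge", 0)),
    )


def read_edf_segment(path: str | Path, subject: str, session: str, state: str, block_id: str) -> Segment:
    """Read a multichannel EDF recording as one labeled segment (via mne)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Segment(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        subject=subject,
        session=session,
        state=state,
        block_id=block_id,
        channel_names=tuple(raw.ch_names),
    )


def write_connectivity_csv(m: ConnectivityMatrix, path: str | Path) -> Path:
    """Square CSV with channel-name headers plus a JSON metadata sidecar."""
    path = Path(path)
    names = list(m.channel_names) or [f"ch{i}" for i in range(m.n_channels)]
    pd.DataFrame(m.values, index=names, columns=names).to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"metric": m.metric, "band": m.band, "labels": m.labels}))
    return path


def read_connectivity_csv(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ConnectivityMatrix(
        values=df.to_numpy(),
        metric=meta.get("metric", "unknown"),
        band=meta.get("band", "unknown"),
        labels=meta.get("labels", {}),
        channel_names=tuple(df.columns),
    )
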