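"""Sensor geometry: montages, neighbor structure, pair indexing, searchlights.

All connectivity vectors downstream inherit the deterministic pair ordering
defined here (row-major over the strict upper triangle of the channel ×
channel matrix). Neighbor relations are computed from 3D Euclidean distance
after normalizing sensor positions to unit mean head radius, so that the
customary dimensionless neighbor thresholds (0.55 for connection exclusion,
0.65 for searchlight neighborhoods) apply to any cap geometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Montage",
    "PairIndex",
    "SearchlightSet",
    "load_montage",
    "neighbor_pairs",
    "threshold_for_neighbor_count",
    "searchlight_sets",
    "fixture_montage_60",
    "fixture_neighbor_threshold",
    "FIXTURE_NEIGHBOR_COUNT",
]

#: Number of neighboring electrode pairs excluded from connectivity vectors
#: on the packaged 60-channel fixture cap.
FIXTURE_NEIGHBOR_COUNT = 192


@dataclass(frozen=True)
class Montage:
    """An ordered set of named sensors with 3D positions.

    Positions are stored as given; all distance computations normalize to
    unit mean radius about the sensor centroid, making neighbor thresholds
    dimensionless and cap-size independent.
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.names) != pos.shape[0]:
            raise ValueError("one position required per channel name")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate channel names in montage")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def normalized_positions(self) -> np.ndarray:
        """Positions centered on the sensor centroid, scaled to unit mean radius."""
        pos = self.positions - self.positions.mean(axis=0)
        radius = np.linalg.norm(pos, axis=1).mean()
        if radius <= 0:
            raise ValueError("degenerate montage: all sensors coincide")
        return pos / radius

    def distances(self) -> np.ndarray:
        """Condensed inter-sensor distance vector in upper-triangle pair order."""
        return pdist(self.normalized_positions())


@dataclass(frozen=True)
class PairIndex:
    """Deterministic enumeration of unordered channel pairs with a neighbor mask.

    Pairs traverse the strict upper triangle row-major: (0,1), (0,2), ...,
    (0,n-1), (1,2), ... For n channels there are n(n-1)/2 pairs; the
    neighbor mask marks pairs closer than the exclusion threshold.
    """

    n_channels: int
    pairs: np.ndarray  # (m, 2) int
    neighbor_mask: np.ndarray  # (m,) bool
    threshold: float = field(default=np.nan)

    def __post_init__(self) -> None:
        expect = self.n_channels * (self.n_channels - 1) // 2
        if len(self.pairs) != expect:
            raise ValueError("pairs must enumerate the strict upper triangle exactly once")
        if len(self.neighbor_mask) != len(self.pairs):
            raise ValueError("neighbor_mask length must match pairs")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_neighbors(self) -> int:
        return int(self.neighbor_mask.sum())

    @property
    def kept(self) -> np.ndarray:
        """Indices (into the pair list) of non-neighbor pairs, in order."""
        return np.flatnonzero(~self.neighbor_mask)

    @property
    def kept_pairs(self) -> np.ndarray:
        return self.pairs[~self.neighbor_mask]


def upper_triangle_pairs(n: int) -> np.ndarray:
    """Row-major strict upper-triangle pair enumeration for n channels."""
    j, k = np.triu_indices(n, k=1)
    return np.column_stack([j, k])


def load_montage(path: str | Path) -> Montage:
    """Read a montage from an SFP (``name x y z``) or TSV file.

    TSV files must carry a header with columns ``name``, ``x``, ``y``, ``z``
    (order free); SFP files are whitespace-delimited with no header. Unknown
    channel names are accepted; duplicate names or missing coordinates are
    rejected.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty montage file: {path}")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]

    first = lines[0].split("\t") if "\t" in lines[0] else lines[0].split()
    lowered = [c.strip().lower() for c in first]
    names: list[str] = []
    coords: list[list[float]] = []
    if {"name", "x", "y", "z"}.issubset(lowered):
        idx = {c: lowered.index(c) for c in ("name", "x", "y", "z")}
        for ln in lines[1:]:
            parts = ln.split("\t") if "\t" in ln else ln.split()
            if len(parts) <= max(idx.values()):
                raise ValueError(f"montage row has missing columns: {ln!r}")
            names.append(parts[idx["name"]].strip())
            coords.append(_parse_xyz(parts, (idx["x"], idx["y"], idx["z"]), ln))
    else:
        for ln in lines:
            parts = ln.split()
            if len(parts) != 4:
                raise ValueError(f"SFP row must be 'name x y z': {ln!r}")
            names.append(parts[0])
            coords.append(_parse_xyz(parts, (1, 2, 3), ln))

    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate channel name(s) in montage: {dupes}")
    return Montage(tuple(names), np.asarray(coords, dtype=float))


def _parse_xyz(parts: list[str], cols: tuple[int, int, int], line: str) -> list[float]:
    try:
        return [float(parts[c]) for c in cols]
    except (ValueError, IndexError) as exc:
        raise ValueError(f"missing or invalid coordinate in montage row {line!r}") from exc


def neighbor_pairs(montage: Montage, dist: float) -> PairIndex:
    """Enumerate all channel pairs and mark those closer than ``dist``.

    ``dist`` is dimensionless (positions normalized to unit mean head
    radius). The neighbor count is monotonically nondecreasing in ``dist``.
    """
    if montage.n_channels < 2:
        raise ValueError("need at least 2 channels to form pairs")
    if dist <= 0:
        raise ValueError("neighbor distance must be positive")
    d = montage.distances()
    return PairIndex(
        n_channels=montage.n_channels,
        pairs=upper_triangle_pairs(montage.n_channels),
        neighbor_mask=d < dist,
        threshold=float(dist),
    )


def threshold_for_neighbor_count(montage: Montage, count: int) -> float:
    """Distance threshold at which exactly ``count`` pairs are neighbors.

    Returns the midpoint between the ``count``-th and ``count+1``-th smallest
    inter-sensor distances; raises if tied distances make the count
    unattainable.
    """
    d = np.sort(montage.distances())
    if not 0 < count < len(d):
        raise ValueError(f"count must lie in (0, {len(d)})")
    lo, hi = d[count - 1], d[count]
    if hi <= lo:
        raise ValueError(f"tied inter-sensor distances: no threshold yields exactly {count} neighbors")
    return float((lo + hi) / 2.0)


@dataclass(frozen=True)
class SearchlightSet:
    """One electrode's local subnetwork: the seed, its neighbors, and the
    non-neighboring connections among them (indices into the full PairIndex)."""

    center: int
    members: tuple[int, ...]
    pair_indices: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "center": self.center,
            "members": list(self.members),
            "pair_indices": list(self.pair_indices),
        }


def searchlight_sets(
    montage: Montage,
    dist: float = 0.65,
    pair_index: PairIndex | None = None,
) -> list[SearchlightSet]:
    """Per-channel searchlight neighborhoods.

    For each channel the member set is the channel plus its neighbors at
    ``dist``; the connection set contains every pair of members that is NOT
    a neighbor pair at the analysis exclusion threshold carried by
    ``pair_index`` (so searchlight classification sees exactly the
    connections that survive into the full network vectors). When
    ``pair_index`` is None, no pairs are excluded.
    """
    if dist <= 0:
        raise ValueError("searchlight distance must be positive")
    n = montage.n_channels
    D = squareform(montage.distances())
    if pair_index is None:
        pair_index = PairIndex(
            n_channels=n,
            pairs=upper_triangle_pairs(n),
            neighbor_mask=np.zeros(n * (n - 1) // 2, dtype=bool),
        )
    if pair_index.n_channels != n:
        raise ValueError("pair_index does not match montage")

    # map (j, k) -> position in the row-major pair list
    pair_pos = {(int(j), int(k)): i for i, (j, k) in enumerate(pair_index.pairs)}
    out = []
    for c in range(n):
        members = tuple(np.flatnonzero(D[c] < dist).tolist())  # includes c (D[c,c]=0)
        conn = tuple(
            pair_pos[(a, b)]
            for ai, a in enumerate(members)
            for b in members[ai + 1:]
            if not pair_index.neighbor_mask[pair_pos[(a, b)]]
        )
        out.append(SearchlightSet(center=c, members=members, pair_indices=conn))
    return out


def searchlight_to_json(sets: list[SearchlightSet], path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in sets], indent=1))


# --- packaged 60-channel fixture -----------------------------------------

# 60-channel subset of the extended 10-20 layout, typical of a 62-channel
# cap with the ground (AFz) and non-scalp electrodes removed.
_FIXTURE_EXCLUDE = {
    "T3", "T4", "T5", "T6",  # legacy aliases of T7/T8/P7/P8
    "M1", "M2", "A1", "A2",  # mastoids / earlobes
    "Iz", "AFz",
    "AF1", "AF2", "AF5", "AF6", "PO1", "PO2", "PO5", "PO6",
    "AF9", "AF10", "F9", "F10", "FT9", "FT10", "T9", "T10",
    "TP9", "TP10", "P9", "P10", "PO9", "PO10", "O9", "O10",
}


def fixture_montage_60() -> Montage:
    """The packaged 60-channel reference cap (extended 10-20 positions)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1020")
    ch_pos = std.get_positions()["ch_pos"]
    names = [n for n in ch_pos if n not in _FIXTURE_EXCLUDE]
    if len(names) != 60:  # pragma: no cover - template drift guard
        raise RuntimeError(f"fixture montage resolved to {len(names)} channels, expected 60")
    return Montage(tuple(names), np.array([ch_pos[n] for n in names]))


def fixture_neighbor_threshold(montage: Montage | None = None) -> float:
    """Exclusion threshold calibrated so the fixture cap has exactly 192
    neighboring pairs (11% of 1,770), reproducing the canonical vector
    length of 1,578 non-neighboring connections."""
    if montage is None:
        montage = fixture_montage_60()
    return threshold_for_neighbor_count(montage, FIXTURE_NEIGHBOR_COUNT)
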