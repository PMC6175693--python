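"""End-to-end orchestration: simulate -> features -> networks -> similarity
-> stats -> classify -> searchlight -> report.

Each stage reads the previous stage's artifacts from the run directory,
writes tidy CSV/JSON outputs, and records a manifest (config hash, seed,
stage, package version) so every number is traceable to the
configuration that produced it. Stages are idempotent under unchanged
inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import identify_subjects, loso_state_classification, searchlight_recognition
from .connectivity import connectivity_matrix
from .io import read_segment, write_segment
from .montage import (
    Montage,
    fixture_montage_60,
    fixture_neighbor_threshold,
    load_montage,
    neighbor_pairs,
)
from .networks import (
    NetworkVector,
    assemble_connectivity_vector,
    boxcox_standardize,
    expand_power_vector,
    power_vector,
)
from .resampling import run_comparison_suite
from .similarity import aggregate, selector, similarity_matrix
from .spectral import BandDefinition, Segment, analytic, bandpass, welch_band_power_db
from .synthgen import ProtocolSpec, SignalModelParams, default_protocol, generate_segments

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "networks", "similarity", "stats", "classify", "searchlight", "report")

__all__ = ["RunConfig", "run", "STAGES"]


@dataclass
class RunConfig:
    """Declarative configuration for a pipeline run (YAML-serializable)."""

    out_dir: str = "oscnet_run"
    seed: int = 0
    montage: str = "fixture"  # "fixture" or a path to an SFP/TSV file
    n_channels: int = 60
    bands: list = field(default_factory=lambda: [["theta", 3.0, 7.0], ["alpha", 8.0, 12.0], ["beta", 13.0, 30.0], ["gamma", 32.0, 60.0]])
    metrics: list = field(default_factory=lambda: ["power", "plv", "aec"])
    n_frag: int = 10
    neighbor_dist: str | float = "calibrated"
    searchlight_dist: float = 0.65
    boxcox_mode: str = "normalized"
    fdr_q: float = 0.05
    knn_k: int = 5
    schemes: list = field(default_factory=lambda: ["within_subject_rest", "rest_task"])
    # synthetic-data settings
    n_subjects: int = 6
    fs: float = 200.0
    duration: float = 60.0
    subject_effect: float = 1.0
    state_effect: float = 0.5
    session_drift: float = 0.2
    noise_level: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(BandDefinition(str(n), float(lo), float(hi)) for n, lo, hi in self.bands)

    def resolve_montage(self) -> Montage:
        if self.montage == "fixture":
            return fixture_montage_60()
        return load_montage(self.montage)

    def resolve_neighbor_dist(self, montage: Montage) -> float:
        if self.neighbor_dist == "calibrated":
            return fixture_neighbor_threshold(montage)
        return float(self.neighbor_dist)


def _write_manifest(cfg: RunConfig, stage: str, outputs: list[str]) -> None:
    path = Path(cfg.out_dir) / f"manifest_{stage}.json"
    path.write_text(
        json.dumps(
            {
                "stage": stage,
                "config_hash": cfg.config_hash,
                "seed": cfg.seed,
                "version": __version__,
                "outputs": sorted(outputs),
            },
            indent=1,
        )
    )


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact {path}; run the '{producer}' stage first")
    return path


def run(stage: str, config: RunConfig) -> None:
    """Execute one pipeline stage (or 'all') under the given configuration."""
    if stage == "all":
        for s in STAGES:
            run(s, config)
        return
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES} or 'all'")
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    config.to_yaml(Path(config.out_dir) / "config.yaml")
    logger.info("stage %s (config %s)", stage, config.config_hash)
    _STAGE_FNS[stage](config)


# --- stages ----------------------------------------------------------------


def _stage_simulate(cfg: RunConfig) -> None:
    montage = cfg.resolve_montage() if cfg.montage == "fixture" and cfg.n_channels == 60 else None
    params = SignalModelParams(
        n_subjects=cfg.n_subjects,
        fs=cfg.fs,
        duration=cfg.duration,
        bands=cfg.band_definitions(),
        subject_effect=cfg.subject_effect,
        state_effect=cfg.state_effect,
        session_drift=cfg.session_drift,
        noise_level=cfg.noise_level,
        seed=cfg.seed,
    )
    segs = generate_segments(params, default_protocol(), montage=montage, n_channels=cfg.n_channels)
    seg_dir = Path(cfg.out_dir) / "segments"
    seg_dir.mkdir(exist_ok=True)
    outputs = []
    for seg in segs:
        p = write_segment(seg, seg_dir / f"{seg.subject}_{seg.block_id}.seg")
        outputs.append(str(p))
    _write_manifest(cfg, "simulate", outputs)


def _load_segments(cfg: RunConfig) -> list[Segment]:
    seg_dir = _require(Path(cfg.out_dir) / "segments", "simulate")
    files = sorted(seg_dir.glob("*.seg"))
    if not files:
        raise FileNotFoundError(f"no segment files in {seg_dir}; run the 'simulate' stage first")
    return [read_segment(p) for p in files]


def _stage_features(cfg: RunConfig) -> None:
    segs = _load_segments(cfg)
    bands = cfg.band_definitions()
    conn_metrics = [m for m in cfg.metrics if m != "power"]
    power_rows = []
    feat_dir = Path(cfg.out_dir) / "features"
    feat_dir.mkdir(exist_ok=True)
    outputs = []
    for seg in segs:
        for band in bands:
            if "power" in cfg.metrics:
                v = welch_band_power_db(seg, band)
                for ch, val in zip(seg.channel_names, v):
                    power_rows.append({**seg.labels, "band": band.name, "channel": ch, "power_db": val})
            if conn_metrics:
                ab = analytic(bandpass(seg, band), band)
                for metric in conn_metrics:
                    m = connectivity_matrix(ab, metric, n_frag=cfg.n_frag)
                    p = feat_dir / f"conn__{seg.subject}__{seg.block_id}__{band.name}__{metric}.csv"
                    names = list(seg.channel_names)
                    pd.DataFrame(m.values, index=names, columns=names).to_csv(p)
                    outputs.append(str(p))
    if power_rows:
        p = feat_dir / "power.csv"
        pd.DataFrame(power_rows).to_csv(p, index=False)
        outputs.append(str(p))
    _write_manifest(cfg, "features", outputs)


def _vectors_path(cfg: RunConfig) -> Path:
    return Path(cfg.out_dir) / "networks" / "vectors.csv"


def _stage_networks(cfg: RunConfig) -> None:
    from .connectivity import ConnectivityMatrix

    feat_dir = _require(Path(cfg.out_dir) / "features", "features")
    montage = cfg.resolve_montage()
    segs = _load_segments(cfg)
    names = segs[0].channel_names
    if cfg.montage == "fixture" and len(names) != montage.n_channels:
        # simulated caps smaller than the fixture use their own geometry-free index
        montage = Montage(tuple(names), _synthetic_positions(len(names)))
    dist = cfg.resolve_neighbor_dist(montage)
    idx = neighbor_pairs(montage, dist)

    rows = []
    power_csv = feat_dir / "power.csv"
    label_cols = ["subject", "session", "state", "block_id"]
    power_vecs: list[NetworkVector] = []
    if power_csv.exists():
        df = pd.read_csv(power_csv)
        for (subject, session, state, block_id, band), g in df.groupby(label_cols + ["band"]):
            g = g.set_index("channel").loc[list(names)]
            pv = power_vector(
                g["power_db"].to_numpy(),
                tuple(names),
                {"subject": subject, "session": str(session), "state": state, "block_id": block_id},
                str(band),
            )
            power_vecs.append(pv)
            power_vecs.append(expand_power_vector(pv, idx))
    conn_vecs: list[NetworkVector] = []
    for p in sorted(feat_dir.glob("conn__*.csv")):
        _, subject, block_id, band, metric = p.stem.split("__")
        seg = next(s for s in segs if s.subject == subject and s.block_id == block_id)
        df = pd.read_csv(p, index_col=0)
        m = ConnectivityMatrix(df.to_numpy(), metric=metric, band=band, labels=seg.labels, channel_names=names)
        u = assemble_connectivity_vector(m, idx)
        conn_vecs.append(boxcox_standardize(u, mode=cfg.boxcox_mode))

    for v in power_vecs + conn_vecs:
        kind = v.element_index.kind
        for el, val in zip(v.element_index.ids, v.values):
            el_str = el if isinstance(el, str) else "-".join(map(str, el))
            rows.append({**v.labels, "kind": kind, "transformed": v.transformed, "element": el_str, "value": val})
    out = _vectors_path(cfg)
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)
    _write_manifest(cfg, "networks", [str(out)])


def _synthetic_positions(n: int) -> np.ndarray:
    """Evenly spread points on the upper unit hemisphere (deterministic)."""
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = i / max(n - 1, 1) * 0.95
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(i * golden), r * np.sin(i * golden), z])


def load_network_vectors(cfg: RunConfig, transformed_only: bool = True) -> list[NetworkVector]:
    """Reload network vectors written by the 'networks' stage."""
    from .networks import ElementIndex

    path = _require(_vectors_path(cfg), "networks")
    df = pd.read_csv(path)
    vecs = []
    keys = ["subject", "session", "state", "block_id", "band", "metric", "kind", "transformed"]
    for vals, g in df.groupby(keys, sort=True):
        rec = dict(zip(keys, vals))
        idx = ElementIndex(rec["kind"], tuple(g["element"].tolist()))
        vecs.append(
            NetworkVector(
                values=g["value"].to_numpy(),
                element_index=idx,
                subject=str(rec["subject"]),
                session=str(rec["session"]),
                state=str(rec["state"]),
                block_id=str(rec["block_id"]),
                band=str(rec["band"]),
                metric=str(rec["metric"]),
                transformed=bool(rec["transformed"]),
            )
        )
    if transformed_only:
        vecs = [v for v in vecs if v.transformed or v.metric == "power"]
    return vecs


def _stage_similarity(cfg: RunConfig) -> None:
    vecs = load_network_vectors(cfg)
    sim_dir = Path(cfg.out_dir) / "similarity"
    sim_dir.mkdir(exist_ok=True)
    outputs = []
    agg_rows = []
    by_type: dict[tuple[str, str, str], list[NetworkVector]] = {}
    for v in vecs:
        by_type.setdefault((v.band, v.metric, v.element_index.kind), []).append(v)
    for (band, metric, kind), nets in sorted(by_type.items()):
        if len(nets) < 2:
            continue
        sm = similarity_matrix(nets)
        p = sim_dir / f"sim_{band}_{metric}_{kind}.csv"
        sm.to_csv(p)
        outputs.append(str(p))
        for name, sel in (
            ("within_subject_rest", selector("within_subject_rest", same=("subject",), each={"state": "rest"})),
            ("within_subject_rest_task", selector("rest_task", same=("subject",), states=("rest", "task"))),
            ("between_subject_rest", None),
        ):
            try:
                if sel is None:
                    sel2 = selector("between_subject_rest", each={"state": "rest"})
                    mean_r, n_pairs = aggregate(sm, sel2)
                    # subtract the within-subject pairs to leave between-subject only
                    w_mean, w_n = aggregate(sm, selector("w", same=("subject",), each={"state": "rest"}))
                    n_between = n_pairs - w_n
                    mean_r = (mean_r * n_pairs - w_mean * w_n) / n_between if n_between > 0 else np.nan
                    agg_rows.append({"band": band, "metric": metric, "kind": kind, "selector": name, "mean_r": mean_r, "n_pairs": n_between})
                else:
                    mean_r, n_pairs = aggregate(sm, sel)
                    agg_rows.append({"band": band, "metric": metric, "kind": kind, "selector": name, "mean_r": mean_r, "n_pairs": n_pairs})
            except ValueError:
                continue
    p = sim_dir / "aggregates.csv"
    pd.DataFrame(agg_rows).to_csv(p, index=False)
    outputs.append(str(p))
    _write_manifest(cfg, "similarity", outputs)


def _stage_stats(cfg: RunConfig) -> None:
    vecs = load_network_vectors(cfg)
    stats_dir = Path(cfg.out_dir) / "stats"
    stats_dir.mkdir(exist_ok=True)
    outputs = []
    # clustering schemes compare across metrics/bands and need a shared element
    # index: pair-based vectors incl. the expanded power networks. Within-subject
    # schemes use electrode-level power instead, so each (band, metric) group is
    # homogeneous in element index.
    pair_vecs = [v for v in vecs if v.element_index.kind == "pairs"]
    within_vecs = [v for v in vecs if not (v.metric == "power" and v.element_index.kind == "pairs")]
    for scheme in cfg.schemes:
        pool = pair_vecs if scheme.startswith(("frequency", "metric", "group")) else within_vecs
        try:
            df = run_comparison_suite(pool, scheme, q=cfg.fdr_q, seed=cfg.seed)
        except ValueError as exc:
            logger.warning("scheme %s skipped: %s", scheme, exc)
            continue
        p = stats_dir / f"{scheme}.csv"
        df.to_csv(p, index=False)
        outputs.append(str(p))
    _write_manifest(cfg, "stats", outputs)


def _stage_classify(cfg: RunConfig) -> None:
    vecs = load_network_vectors(cfg)
    cls_dir = Path(cfg.out_dir) / "classify"
    cls_dir.mkdir(exist_ok=True)
    outputs = []
    # expanded power duplicates electrode-level power; classifiers use the latter
    vecs = [v for v in vecs if not (v.metric == "power" and v.element_index.kind == "pairs")]
    # behavioral state: session-A networks, leave one subject out
    sa = [v for v in vecs if v.session == "A"]
    if sa:
        state_df = loso_state_classification(sa, k=cfg.knn_k)
        p = cls_dir / "state_classification.csv"
        state_df.to_csv(p, index=False)
        outputs.append(str(p))
    # subject identity: train on A+B, test on C
    train = [v for v in vecs if v.session in ("A", "B")]
    test = [v for v in vecs if v.session == "C"]
    if train and test:
        report = identify_subjects(train, test, k=cfg.knn_k)
        per_type = report.pop("per_type")
        p = cls_dir / "subject_id_per_type.csv"
        per_type.to_csv(p, index=False)
        outputs.append(str(p))
        p = cls_dir / "subject_id.json"
        p.write_text(json.dumps({k: v for k, v in report.items()}, indent=1))
        outputs.append(str(p))
    _write_manifest(cfg, "classify", outputs)


def _stage_searchlight(cfg: RunConfig) -> None:
    vecs = load_network_vectors(cfg)
    segs = _load_segments(cfg)
    names = segs[0].channel_names
    montage = cfg.resolve_montage()
    if len(names) != montage.n_channels:
        montage = Montage(tuple(names), _synthetic_positions(len(names)))
    idx = neighbor_pairs(montage, cfg.resolve_neighbor_dist(montage))
    def usable(v):  # exclude expanded power: searchlight uses electrode-level power
        return not (v.metric == "power" and v.element_index.kind == "pairs")

    train = [v for v in vecs if v.session in ("A", "B") and usable(v)]
    test = [v for v in vecs if v.session == "C" and usable(v)]
    if not train or not test:
        logger.warning("searchlight: need both train (A/B) and test (C) vectors; skipping")
        _write_manifest(cfg, "searchlight", [])
        return
    df = searchlight_recognition(train, test, montage, idx, dist=cfg.searchlight_dist, k=cfg.knn_k)
    p = Path(cfg.out_dir) / "searchlight_map.csv"
    df.to_csv(p, index=False)
    _write_manifest(cfg, "searchlight", [str(p)])


def _stage_report(cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    summary: dict = {"config_hash": cfg.config_hash, "seed": cfg.seed, "version": __version__}
    agg = out / "similarity" / "aggregates.csv"
    if agg.exists():
        df = pd.read_csv(agg)
        summary["similarity_aggregates"] = df.to_dict(orient="records")
    state = out / "classify" / "state_classification.csv"
    if state.exists():
        summary["state_classification"] = pd.read_csv(state).to_dict(orient="records")
    sid = out / "classify" / "subject_id.json"
    if sid.exists():
        summary["subject_identification"] = json.loads(sid.read_text())
    p = out / "report.json"
    p.write_text(json.dumps(summary, indent=1, default=float))
    _write_manifest(cfg, "report", [str(p)])


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "networks": _stage_networks,
    "similarity": _stage_similarity,
    "stats": _stage_stats,
    "classify": _stage_classify,
    "searchlight": _stage_searchlight,
    "report": _stage_report,
}
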