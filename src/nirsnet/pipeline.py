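"""Stage orchestration over on-disk artifacts.

Stages (simulate → preprocess → connectivity → network → stats) communicate
only through files under a run directory, each with a JSON manifest
recording the configuration hash, seed and package version, so any stage
can be rerun or audited in isolation and a rerun with the same
configuration reproduces stochastic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import pair_matrix, pairs_to_frame
from .group_stats import (
    ContrastDesign,
    build_feature_table,
    contrast_report,
    feature_row,
    roi_amplitudes,
)
from .network import aggregate, load_roi_map, to_edgelist
from .preprocess import PreprocessConfig, preprocess
from .recording import read_recording, write_recording
from .synthetic import (
    BehavioralModel,
    CohortConfig,
    CouplingSpec,
    OscillatorSpec,
    default_oscillators,
    generate_cohort,
)
from .wavelet import ANALYSIS_BAND, WaveletSpec

__all__ = ["RunConfig", "run_stage", "STAGES"]

STAGES = ("simulate", "preprocess", "connectivity", "network", "stats")


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out: Path = Path("nirsnet_run")
    seed: int = 0
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    wavelet: WaveletSpec = dataclasses.field(default_factory=WaveletSpec)
    band: tuple[float, float] = ANALYSIS_BAND
    surrogates: int = 100
    surrogate_mode: str = "both"
    aggregation: str = "zero"
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    contrasts: tuple[str, ...] = ("distance", "prior", "performance")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        cohort_raw = dict(raw.get("cohort", {}))
        if "oscillators" in cohort_raw:
            cohort_raw["oscillators"] = tuple(
                OscillatorSpec(**o) for o in cohort_raw["oscillators"]
            )
        else:
            cohort_raw["oscillators"] = default_oscillators()
        if "couplings" in cohort_raw:
            cohort_raw["couplings"] = {
                cond: tuple(
                    CouplingSpec(
                        channel_pair=tuple(c["channel_pair"]),
                        strength=c.get("strength", 0.5),
                        phase_lag=c.get("phase_lag", 0.0),
                        band=tuple(c.get("band", (0.02, 0.08))),
                    )
                    for c in specs
                )
                for cond, specs in cohort_raw["couplings"].items()
            }
        if "behavioral" in cohort_raw:
            cohort_raw["behavioral"] = BehavioralModel(**cohort_raw["behavioral"])
        if "channel_labels" in cohort_raw:
            cohort_raw["channel_labels"] = tuple(cohort_raw["channel_labels"])
        if "conditions" in cohort_raw:
            cohort_raw["conditions"] = tuple(cohort_raw["conditions"])
        if "kappa_range" in cohort_raw:
            cohort_raw["kappa_range"] = tuple(cohort_raw["kappa_range"])
        cohort_raw.setdefault("seed", raw.get("seed", 0))
        cfg = cls(
            out=Path(raw.get("out", "nirsnet_run")),
            seed=int(raw.get("seed", 0)),
            cohort=CohortConfig(**cohort_raw),
            wavelet=WaveletSpec(**raw.get("wavelet", {})),
            band=tuple(raw.get("band", ANALYSIS_BAND)),
            surrogates=int(raw.get("surrogates", 100)),
            surrogate_mode=raw.get("surrogate_mode", "both"),
            aggregation=raw.get("aggregation", "zero"),
            preprocess=PreprocessConfig(
                **{
                    k: tuple(v) if k == "order" else v
                    for k, v in raw.get("preprocess", {}).items()
                }
            ),
            contrasts=tuple(raw.get("contrasts", ("distance", "prior", "performance"))),
        )
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            return repr(o)

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _atomic_write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _write_manifest(stage_dir: Path, config: RunConfig, extra: dict | None = None) -> None:
    manifest = {
        "stage": stage_dir.name,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        **(extra or {}),
    }
    _atomic_write_text(stage_dir / "manifest.json", json.dumps(manifest, indent=1))


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path} — run the '{produced_by}' stage first"
        )
    return path


def _recording_paths(config: RunConfig, stage: str) -> list[Path]:
    root = config.out / stage
    return sorted(root.glob("*.csv"))


def _run_simulate(config: RunConfig) -> None:
    out = config.out / "recordings"
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.cohort)
    for cond, recs in cohort.recordings.items():
        for rec in recs:
            write_recording(rec, out / f"{rec.subject_id}_{cond}.csv")
    cohort.behavior.to_csv(config.out / "behavior.csv", index=False)
    cohort.kappas.to_csv(config.out / "kappa.csv", index=False)
    _write_manifest(out, config, {"n_recordings": sum(map(len, cohort.recordings.values()))})


def _run_preprocess(config: RunConfig) -> None:
    src = config.out / "recordings"
    _require(src, "simulate")
    out = config.out / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    paths = _recording_paths(config, "recordings")
    if not paths:
        raise FileNotFoundError(f"no recording CSVs under {src}")
    for p in paths:
        rec = read_recording(p)
        write_recording(preprocess(rec, config.preprocess), out / p.name)
    _write_manifest(out, config, {"n_recordings": len(paths)})


def _run_connectivity(config: RunConfig) -> None:
    src = config.out / "preprocessed"
    _require(src, "preprocess")
    out = config.out / "connectivity"
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for p in _recording_paths(config, "preprocessed"):
        rec = read_recording(p)
        pairs = pair_matrix(
            rec,
            spec=config.wavelet,
            band=config.band,
            m=config.surrogates,
            seed=config.seed,
            surrogate_mode=config.surrogate_mode,
        )
        frame = pairs_to_frame(pairs, subject=rec.subject_id, condition=rec.condition)
        frames.append(frame)
        # ROI amplitudes ride along for the stats stage.
        amps = roi_amplitudes(rec, load_roi_map(), spec=config.wavelet, band=config.band)
        _atomic_write_text(
            out / f"{rec.subject_id}_{rec.condition}_amplitude.json",
            json.dumps(amps, indent=1),
        )
    table = pd.concat(frames, ignore_index=True)
    _atomic_write_text(out / "pairs.csv", table.to_csv(index=False, float_format="%.17g"))
    _write_manifest(
        out,
        config,
        {
            "m": config.surrogates,
            "band": list(config.band),
            "surrogate_mode": config.surrogate_mode,
        },
    )


def _run_network(config: RunConfig) -> None:
    src = config.out / "connectivity" / "pairs.csv"
    _require(src, "connectivity")
    out = config.out / "network"
    out.mkdir(parents=True, exist_ok=True)
    roi_map = load_roi_map()
    table = pd.read_csv(src)
    from .connectivity import PairCoherence  # local to avoid cycle confusion

    for (subject, cond), grp in table.groupby(["subject", "condition"]):
        pairs = [
            PairCoherence(
                channels=(row.ch_i, row.ch_j),
                frequencies=np.array([]),
                wpco_spectrum=np.array([]),
                band_wpco=row.band_wpco,
                surrogate_mean=row.surrogate_mean,
                surrogate_sd=row.surrogate_sd,
                margin=row.margin,
                valid=bool(row.valid),
                n_surrogates=config.surrogates,
            )
            for row in grp.itertuples()
        ]
        net = aggregate(
            pairs,
            roi_map,
            mode=config.aggregation,
            provenance={"subject": subject, "condition": cond, "band": list(config.band)},
        )
        _atomic_write_text(
            out / f"{subject}_{cond}_adjacency.csv",
            net.to_frame().to_csv(float_format="%.17g"),
        )
        _atomic_write_text(
            out / f"{subject}_{cond}_edges.csv",
            to_edgelist(net).to_csv(index=False, float_format="%.17g"),
        )
    _write_manifest(out, config, {"aggregation": config.aggregation})


def _run_stats(config: RunConfig) -> None:
    conn = config.out / "connectivity" / "pairs.csv"
    _require(conn, "connectivity")
    net_dir = config.out / "network"
    _require(net_dir, "network")
    behavior_path = _require(config.out / "behavior.csv", "simulate")
    out = config.out / "stats"
    out.mkdir(parents=True, exist_ok=True)
    behavior = pd.read_csv(behavior_path)
    rows = []
    for adj in sorted(net_dir.glob("*_adjacency.csv")):
        subject, cond = adj.stem.rsplit("_adjacency", 1)[0].rsplit("_", 1)
        amp_path = config.out / "connectivity" / f"{subject}_{cond}_amplitude.json"
        amps = json.loads(_require(amp_path, "connectivity").read_text())
        frame = pd.read_csv(adj, index_col=0)
        from .network import RoiNetwork

        net = RoiNetwork(labels=tuple(frame.columns), matrix=frame.to_numpy())
        rows.append({"subject": subject, "condition": cond, **feature_row(amps, net)})
    features = build_feature_table(rows)
    features.to_csv(out / "features.csv", float_format="%.17g")
    for kind in config.contrasts:
        design = ContrastDesign(kind=kind)
        report = contrast_report(features, design, behavior=behavior)
        _atomic_write_text(
            out / f"contrast_{kind}.csv", report.to_csv(index=False, float_format="%.17g")
        )
    _write_manifest(out, config, {"contrasts": list(config.contrasts)})


_RUNNERS = {
    "simulate": _run_simulate,
    "preprocess": _run_preprocess,
    "connectivity": _run_connectivity,
    "network": _run_network,
    "stats": _run_stats,
}


def run_stage(stage: str, config: RunConfig) -> None:
    """Run one named stage (or ``all``) against the run directory."""
    if stage == "all":
        for s in STAGES:
            _RUNNERS[s](config)
        return
    if stage not in _RUNNERS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    _RUNNERS[stage](config)
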