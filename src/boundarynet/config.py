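"""Configuration loading and artifact persistence.

Study configurations are YAML files validated against :class:`StudyConfig`;
a ``preset`` key pulls in one of the named study presets and the remaining
keys override it.  Unknown keys are rejected.  Saved artifacts (network
weight archives, response CSVs, summary JSON) are inventoried in a run
manifest with SHA-256 checksums so identical reruns are verifiable
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import netcore
from .experiments import STUDY_PRESETS, StudyConfig, StudyResult
from .gabor import build_bank
from .netcore import (LateralFilterSpec, LayerConfig, Network, SigmoidSpec,
                      SynapticMap)

__all__ = [
    "RunManifest",
    "load_config",
    "save_config",
    "save_artifacts",
    "save_network",
    "load_network",
]

_TUPLE_FIELDS = {"grid", "orientations", "vertex_angle_sets"}


@dataclass
class RunManifest:
    config: dict
    seed: int
    files: dict[str, str]  # relative path -> sha256
    versions: dict[str, str] = field(default_factory=dict)


def _coerce(name: str, value):
    if name in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
        return tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                     for v in value)
    return value


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a study configuration, with preset inheritance."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    preset_name = raw.pop("preset", None)
    base = STUDY_PRESETS[preset_name] if preset_name else StudyConfig()
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys: {', '.join(sorted(unknown))}"
        )
    overrides = {k: _coerce(k, v) for k, v in raw.items()}
    return dataclasses.replace(base, **overrides)


def save_config(config: StudyConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_network(network: Network, path: str | Path) -> None:
    """Persist weights, afferent indices and per-layer configs (npz archive)."""
    arrays: dict[str, np.ndarray] = {}
    meta = {"n_layers": network.n_layers, "seed": network.seed,
            "retina_size": network.bank.retina_size,
            "layers": []}
    for l, (cfg, smap) in enumerate(zip(network.layer_configs, network.maps)):
        arrays[f"w{l}"] = smap.weights
        arrays[f"idx{l}"] = smap.indices
        arrays[f"off{l}"] = smap.offsets
        meta["layers"].append({
            "dims": list(cfg.dims), "n_connections": cfg.n_connections,
            "radius": cfg.radius, "pre_shape": list(smap.pre_shape),
            "lateral": dataclasses.asdict(cfg.lateral),
            "sigmoid": dataclasses.asdict(cfg.sigmoid),
        })
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_network(path: str | Path) -> Network:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]))
        bank = build_bank(meta["retina_size"])
        configs, maps = [], []
        for l, lm in enumerate(meta["layers"]):
            lateral = LateralFilterSpec(**lm["lateral"])
            cfg = LayerConfig(tuple(lm["dims"]), lm["n_connections"],
                              lm["radius"], lateral, SigmoidSpec(**lm["sigmoid"]))
            maps.append(SynapticMap(tuple(lm["pre_shape"]), data[f"idx{l}"],
                                    data[f"w{l}"], data[f"off{l}"], lm["radius"]))
            configs.append(cfg)
    return Network(bank, configs, maps, meta["seed"])


def save_artifacts(result: StudyResult, out_dir: str | Path) -> RunManifest:
    """Write weights, response tables and a summary; return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    net_path = out / "network.npz"
    save_network(result.network, net_path)
    written.append(net_path)

    for name, table in (("responses_untrained.csv", result.responses_untrained),
                        ("responses_trained.csv", result.responses_trained)):
        p = out / name
        table.to_csv(p, index=False)
        written.append(p)

    summary = {
        "study": result.config.study,
        "seed": result.config.seed,
        "provenance": result.provenance,
        "selectivity_untrained": {str(k): v for k, v in
                                  result.selectivity_untrained.items()},
        "selectivity_trained": {str(k): v for k, v in
                                result.selectivity_trained.items()},
        "n_selective_untrained": result.n_selective_untrained,
        "n_selective_trained": result.n_selective_trained,
    }
    if result.info_trained is not None:
        summary["info_trained_mean_bits"] = float(result.info_trained.max_info.mean())
        summary["info_untrained_mean_bits"] = float(result.info_untrained.max_info.mean())
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=1, sort_keys=True))
    written.append(p)

    cfg_path = out / "config.yaml"
    save_config(result.config, cfg_path)
    written.append(cfg_path)

    manifest = RunManifest(
        config=dataclasses.asdict(result.config),
        seed=result.config.seed,
        files={f.name: _sha256(f) for f in written},
    )
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=1, sort_keys=True,
                   default=str))
    return manifest
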