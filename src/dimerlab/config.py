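"""Configuration files and run manifests.

A YAML/JSON config mirrors the simulation and analysis parameters; a run
manifest records everything needed to reproduce a run set bit for bit
(config snapshot, master seed, per-run spawn keys, package version, input
checksums and output paths).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, fields
from pathlib import Path

import yaml

from . import __version__
from . import constants as C
from .mc import SimulationConfig

__all__ = ["load_config", "simulation_config_from_dict", "default_config",
           "RunManifest", "write_manifest"]

#: Analysis-side defaults, exposed alongside the simulation protocol.
ANALYSIS_DEFAULTS = {
    "contact_cutoff": C.CONTACT_CUTOFF,
    "dissociation_threshold": C.DISSOCIATION_THRESHOLD,
    "force_pn": C.PULL_FORCE_PN,
    "box_side": C.BOX_SIDE,
    "n_bootstrap": C.N_BOOTSTRAP,
    "multiple_testing": "holm",
}


def default_config() -> dict:
    cfg = {f.name: getattr(SimulationConfig(), f.name) for f in fields(SimulationConfig)}
    cfg.update(ANALYSIS_DEFAULTS)
    return cfg


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML/JSON config file over the defaults; unknown keys error."""
    cfg = default_config()
    if path is None:
        return cfg
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    unknown = sorted(set(user) - set(cfg))
    if unknown:
        raise ValueError(f"invalid config keys: {', '.join(unknown)}")
    cfg.update(user)
    return cfg


def simulation_config_from_dict(cfg: dict) -> SimulationConfig:
    names = {f.name for f in fields(SimulationConfig)}
    return SimulationConfig(**{k: v for k, v in cfg.items() if k in names})


class RunManifest(dict):
    """A JSON-serialisable record sufficient to reproduce a run."""


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int,
                   inputs: list[str | Path] = (), outputs: list[str | Path] = ()
                   ) -> RunManifest:
    manifest = RunManifest(
        version=__version__,
        seed=seed,
        run_seeds=[[seed, i] for i in range(int(config.get("n_runs", 1)))],
        config=dict(config),
        input_checksums={str(p): _checksum(Path(p)) for p in inputs},
        outputs=[str(p) for p in outputs],
    )
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
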