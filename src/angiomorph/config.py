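"""Run configuration and provenance.

A single flat :class:`RunConfig` carries every tunable parameter of the
pipeline with its default.  Configs load from JSON or TOML; unknown keys
are rejected.  Every output file gets a provenance sidecar (config hash,
catalog version, package version, seed) so a run can be reproduced from
its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    # segmentation / skeleton
    background_sigma: float = 25.0
    min_object_px: int = 50
    max_hole_px: int = 25
    min_spur_px: int = 5
    # element classification
    fusion_radius_px: float = 5.0
    min_mesh_area_px2: float = 25.0
    pixel_size: float = 1.0
    # morphometry
    tangent_window_px: int = 5
    glcm_levels: int = 64
    # screen profiling
    n_clusters: int = 7
    tsne_perplexity: float = 30.0
    tsne_seed: int = 0
    # pharmacology
    fdr_threshold: float = 0.05
    min_annotated: int = 2
    tanimoto_z_threshold: float = 2.0
    # omics
    expression_cutoff: float = 1.00
    braak_high_min: int = 5
    braak_low_max: int = 3
    patient_clusters: int = 3
    # global
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def provenance(self, catalog_version: str = "1.0") -> dict:
        return {"config_hash": self.hash(), "catalog_version": catalog_version,
                "config": asdict(self)}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a config file (JSON or TOML); unknown keys raise."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
    data.update(overrides)
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
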