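"""YAML configuration parsing for the command-line interface.

A config file may carry ``geometry``, ``artifact``, ``defect`` and
``cohort`` blocks plus an optional custom ``profile`` block; every field
has the package default, so all blocks are optional.
"""

from __future__ import annotations

import yaml

from .phantom import ArtifactSpec, AttenuationZone, CohortSpec, DefectSpec, LVGeometry
from .profiles import CameraProfile, get_profile


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return cfg


def parse_profile(cfg: dict, camera: str | None) -> CameraProfile:
    """Profile from the config's ``profile`` block or a built-in name."""
    if "profile" in cfg:
        return CameraProfile.from_dict(cfg["profile"])
    if camera is None:
        raise ValueError("no camera given and no profile block in config")
    return get_profile(camera)


def parse_geometry(cfg: dict) -> LVGeometry:
    return LVGeometry(**cfg.get("geometry", {}))


def parse_artifact(cfg: dict) -> ArtifactSpec:
    zones = tuple(
        AttenuationZone(**z) for z in cfg.get("artifact", {}).get("zones", [])
    )
    return ArtifactSpec(zones=zones)


def parse_defect(cfg: dict) -> DefectSpec | None:
    if "defect" not in cfg or cfg["defect"] is None:
        return None
    return DefectSpec(**cfg["defect"])


def parse_cohort(cfg: dict, profile: CameraProfile, seed: int) -> CohortSpec:
    block = cfg.get("cohort")
    if block is None:
        raise ValueError("config has no cohort block")
    return CohortSpec(
        n_acquisitions=int(block["n_acquisitions"]),
        extent_pct_distribution=tuple(block["extent_pct"]),
        depth_pct_distribution=tuple(block["depth_pct"]),
        center_angle_distribution=tuple(block["center_angle_deg"]),
        profile=profile,
        seed=seed,
        noise=bool(block.get("noise", True)),
        geometry=parse_geometry(cfg),
    )
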