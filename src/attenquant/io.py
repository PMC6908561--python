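"""Reading and writing study volumes, sidecars, sector tables, metrics.

Volumes travel as NIfTI (.nii.gz) with the isotropic voxel size in the
header; a JSON sidecar per study carries the camera profile, seed and —
for synthetic studies — the injected ground truth. Sector tables are
CSV, metrics are JSON; every writer is deterministic given its inputs
and embeds ``format_version`` plus package provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .profiles import CameraProfile, get_profile
from .quantify import ArtifactMetrics
from .sectorization import SectorGrid

FORMAT_VERSION = "1.0"


def _provenance(extra: dict | None = None) -> dict:
    from . import __version__

    prov = {"package": "attenquant", "version": __version__}
    if extra:
        import hashlib

        blob = json.dumps(extra, sort_keys=True, default=str).encode()
        prov["config_sha256"] = hashlib.sha256(blob).hexdigest()[:16]
    return prov


@dataclass
class StudyBundle:
    """A paired NAC/AC study ready for quantification."""

    nac_volume: np.ndarray
    ac_volume: np.ndarray
    profile: CameraProfile
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nac_volume.shape != self.ac_volume.shape:
            raise ValueError(
                f"NAC shape {self.nac_volume.shape} != AC shape {self.ac_volume.shape}"
            )


def _read_volume(path) -> tuple[np.ndarray, float]:
    """Load a NIfTI volume, returning (data, isotropic voxel size mm)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(f"{path}: non-isotropic voxels {zooms} are not supported")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return data, float(zooms[0])


def load_study(
    nac_path,
    ac_path,
    sidecar_path=None,
    profile: CameraProfile | None = None,
) -> StudyBundle:
    """Load a paired study from disk.

    The camera profile comes from the sidecar when present; without a
    sidecar the caller must supply one. Voxel sizes of the pair must
    match each other and the profile.
    """
    nac, vox_n = _read_volume(nac_path)
    ac, vox_a = _read_volume(ac_path)
    if nac.shape != ac.shape:
        raise ValueError(f"shape mismatch: NAC {nac.shape} vs AC {ac.shape}")
    if not np.isclose(vox_n, vox_a, rtol=1e-4):
        raise ValueError(f"voxel size mismatch: NAC {vox_n} mm vs AC {vox_a} mm")

    provenance: dict = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        provenance = sidecar
        prof_entry = sidecar.get("profile")
        if isinstance(prof_entry, str):
            profile = get_profile(prof_entry)
        elif isinstance(prof_entry, dict):
            profile = CameraProfile.from_dict(prof_entry)
    if profile is None:
        raise ValueError("no sidecar profile found; supply a CameraProfile")
    if not np.isclose(profile.voxel_size_mm, vox_n, rtol=1e-4):
        raise ValueError(
            f"profile voxel size {profile.voxel_size_mm} mm does not match "
            f"volume voxel size {vox_n} mm"
        )
    return StudyBundle(nac_volume=nac, ac_volume=ac, profile=profile, provenance=provenance)


def write_study(study, out_dir, stem: str = "study") -> dict:
    """Write a study's NAC/AC volumes and JSON sidecar.

    ``study`` is a :class:`~attenquant.phantom.SyntheticStudy` or a
    :class:`StudyBundle`. Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = study.profile.voxel_size_mm
    affine = np.diag([vox, vox, vox, 1.0])
    paths = {}
    for name, vol in (("nac", study.nac_volume), ("ac", study.ac_volume)):
        p = out / f"{stem}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine), str(p))
        paths[name] = p

    sidecar: dict = {
        "format_version": FORMAT_VERSION,
        "profile": study.profile.to_dict(),
    }
    for attr, key in (
        ("seed", "seed"),
        ("noise", "noise"),
    ):
        if hasattr(study, attr):
            sidecar[key] = getattr(study, attr)
    if hasattr(study, "artifact"):
        sidecar["truth_zones"] = study.artifact.to_dict()["zones"]
        sidecar["truth_factors"] = list(study.truth_factors)
        sidecar["geometry"] = study.geometry.to_dict()
        sidecar["defect"] = study.defect.to_dict() if study.defect else None
        sidecar["convention"] = study.convention.to_dict()
        if study.truth_segment_mask is not None:
            sidecar["truth_segment_mask"] = study.truth_segment_mask.astype(int).tolist()
        sidecar["truth"] = study.truth
    elif hasattr(study, "provenance"):
        sidecar["provenance"] = study.provenance
    sidecar["generator"] = _provenance(sidecar)

    p = out / f"{stem}_sidecar.json"
    with open(p, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True, default=str)
    paths["sidecar"] = p
    return paths


def write_sector_table(grid: SectorGrid, path) -> pd.DataFrame:
    """Export a sector grid as CSV: one row per (slice, sector) segment.

    Columns: ``slice_index`` (label, 1 = most basal), ``sector_index``,
    ``sector_center_deg``, ``normalized_counts``. Provenance rides in
    ``#`` comment lines (readable back with ``pd.read_csv(...,
    comment="#")``).
    """
    centers = grid.convention.sector_centers_deg
    n_slices, n_sectors = grid.values.shape
    df = pd.DataFrame(
        {
            "slice_index": np.repeat(grid.slice_labels, n_sectors),
            "sector_index": np.tile(np.arange(n_sectors), n_slices),
            "sector_center_deg": np.tile(centers, n_slices),
            "normalized_counts": grid.values.ravel(),
        }
    )
    prov = _provenance({"total_counts": grid.total_counts})
    with open(path, "w") as fh:
        fh.write(f"# format_version: {FORMAT_VERSION}\n")
        fh.write(f"# generator: {prov['package']} {prov['version']} ({prov['config_sha256']})\n")
        df.to_csv(fh, index=False)
    return df


def write_metrics(metrics: ArtifactMetrics, path, extra: dict | None = None) -> dict:
    """Write artifact metrics as JSON; returns the payload written."""
    payload = {"format_version": FORMAT_VERSION, **metrics.to_dict()}
    if extra:
        payload.update(extra)
    payload["generator"] = _provenance(payload)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload


def read_metrics(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
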