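"""Camera acquisition profiles.

A :class:`CameraProfile` bundles the per-camera constants the pipeline
needs: the isotropic reconstructed voxel size, the fixed number of
analyzed short-axis slices (counted from the base), and the NAC/AC ratio
threshold used to delineate the attenuation artifact.

Two built-in profiles are provided:

``czt``
    Dedicated cardiac camera with CZT detectors and multi-pinhole
    collimation: 4 mm isotropic voxels, 20 analyzed slices, delineation
    threshold 0.90.
``ventri``
    Conventional rotating dual-head NaI camera with parallel-hole
    collimators: 6.4 mm isotropic voxels, 12 analyzed slices, threshold
    0.85.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CameraProfile:
    """Per-camera constants of the quantification pipeline.

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"czt"``.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres. Must be positive.
    n_slices : int
        Number of analyzed short-axis slices, counted from the base.
    ratio_threshold : float
        NAC/AC ratio below which a segment is delineated as attenuation
        artifact. Strictly between 0 and 1.
    """

    name: str
    voxel_size_mm: float
    n_slices: int
    ratio_threshold: float

    def __post_init__(self) -> None:
        if not self.voxel_size_mm > 0:
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        if self.n_slices < 1:
            raise ValueError(f"n_slices must be >= 1, got {self.n_slices}")
        if not 0.0 < self.ratio_threshold < 1.0:
            raise ValueError(
                f"ratio_threshold must lie in (0, 1), got {self.ratio_threshold}"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "voxel_size_mm": self.voxel_size_mm,
            "n_slices": self.n_slices,
            "ratio_threshold": self.ratio_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraProfile":
        return cls(
            name=d["name"],
            voxel_size_mm=float(d["voxel_size_mm"]),
            n_slices=int(d["n_slices"]),
            ratio_threshold=float(d["ratio_threshold"]),
        )


CZT = CameraProfile(name="czt", voxel_size_mm=4.0, n_slices=20, ratio_threshold=0.90)
VENTRI = CameraProfile(
    name="ventri", voxel_size_mm=6.4, n_slices=12, ratio_threshold=0.85
)

BUILTIN_PROFILES: dict[str, CameraProfile] = {"czt": CZT, "ventri": VENTRI}


def get_profile(name: str) -> CameraProfile:
    """Look up a built-in camera profile by name (case-insensitive)."""
    try:
        return BUILTIN_PROFILES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown camera profile {name!r}; built-ins: {sorted(BUILTIN_PROFILES)}"
        ) from None
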