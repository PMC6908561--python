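"""Short-axis sectorization of left-ventricular count volumes.

A short-axis volume is reduced to an ``n_slices x 12`` matrix of
myocardial counts: a fixed number of analyzed slices is selected from
the base toward the apex, each slice is divided into 12 equal 30-degree
sectors about its count-weighted centre, and the per-segment count sums
are normalized to the grand total over all analyzed segments.

Axis convention: volumes are indexed ``(x, y, z)`` with ``z`` running
from apex to base, so the most basal analyzed slice has the highest
``z`` among occupied slices and carries slice label 1.

Angular convention: by default 0 degrees points at the anterior wall
(the ``+y`` in-plane direction), angles increase through the lateral
wall (90, ``+x``), the inferior wall (180) and the septum (270). Sector
``i`` covers the half-open interval ``[30*i, 30*(i+1))`` with its centre
at ``30*i + 15``. The frame can be rotated or mirrored via
:class:`AngularConvention`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import CameraProfile

#: Fraction of the maximum slice count-sum below which a slice is
#: treated as empty during basal-slice detection; robust to noise-only
#: slices while never discarding a genuine myocardial slice.
SLICE_DETECTION_FLOOR = 0.01

N_SECTORS = 12
SECTOR_SPAN_DEG = 360.0 / N_SECTORS


@dataclass(frozen=True)
class AngularConvention:
    """In-plane angular reference frame for sectorization.

    ``offset_deg`` rotates the zero direction away from anterior;
    ``sense`` flips the direction of increasing angle (+1 keeps the
    default anterior -> lateral -> inferior -> septal order).
    """

    zero_direction: str = "anterior"
    rotation_sense: str = "anterior-lateral-inferior-septal"
    offset_deg: float = 0.0
    sense: int = 1

    def __post_init__(self) -> None:
        if self.sense not in (1, -1):
            raise ValueError("sense must be +1 or -1")

    def angles_deg(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Angle of in-plane offsets ``(dx, dy)`` in [0, 360).

        ``dx``/``dy`` are offsets along the first/second volume axes
        from the slice centre. With the default frame, ``+y`` (anterior)
        maps to 0 and ``+x`` (lateral) to 90.
        """
        theta = np.degrees(np.arctan2(dx, dy))
        return (self.sense * theta - self.offset_deg) % 360.0

    def sector_of(self, angles_deg: np.ndarray) -> np.ndarray:
        """Half-open 30-degree bin index of each angle; no splitting."""
        return np.minimum(
            (np.asarray(angles_deg) // SECTOR_SPAN_DEG).astype(int), N_SECTORS - 1
        )

    @property
    def sector_centers_deg(self) -> np.ndarray:
        return np.arange(N_SECTORS) * SECTOR_SPAN_DEG + SECTOR_SPAN_DEG / 2.0

    def direction(self, angle_deg: float) -> np.ndarray:
        """Unit in-plane offset ``(dx, dy)`` pointing at ``angle_deg``.

        Inverse of :meth:`angles_deg`: ``angles_deg(*direction(a)) == a``.
        """
        phi = np.radians(self.sense * (angle_deg + self.offset_deg))
        return np.array([np.sin(phi), np.cos(phi)])

    def to_dict(self) -> dict:
        return {
            "zero_direction": self.zero_direction,
            "rotation_sense": self.rotation_sense,
            "offset_deg": self.offset_deg,
            "sense": self.sense,
        }


DEFAULT_CONVENTION = AngularConvention()


@dataclass
class SectorGrid:
    """Slice x sector matrix of myocardial counts for one volume.

    Attributes
    ----------
    values : ndarray, shape (n_slices, 12)
        Per-segment counts normalized to the grand total over all
        analyzed segments (sums to 1 when ``total_counts > 0``).
    raw_counts : ndarray, shape (n_slices, 12)
        Per-segment summed voxel counts before normalization.
    slice_indices : ndarray of int
        Volume ``z`` indices of the analyzed slices, ordered from base
        to apex; row ``k`` of the matrices corresponds to slice label
        ``k + 1``.
    centers : ndarray, shape (n_slices, 2)
        In-plane slice centres in voxel units, one per analyzed slice.
    convention : AngularConvention
    total_counts : float
        Grand total of raw counts over all analyzed segments.
    """

    values: np.ndarray
    raw_counts: np.ndarray
    slice_indices: np.ndarray
    centers: np.ndarray
    convention: AngularConvention = field(default_factory=AngularConvention)
    total_counts: float = 0.0

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def n_segments(self) -> int:
        return self.values.size

    @property
    def slice_labels(self) -> np.ndarray:
        """Slice labels 1..n, 1 = most basal analyzed slice."""
        return np.arange(1, self.n_slices + 1)


def nonempty_slices(volume: np.ndarray, floor_frac: float = SLICE_DETECTION_FLOOR) -> np.ndarray:
    """``z`` indices of slices whose count sum exceeds the detection floor."""
    sums = np.asarray(volume, dtype=float).sum(axis=(0, 1))
    if sums.max() <= 0:
        return np.array([], dtype=int)
    return np.flatnonzero(sums > floor_frac * sums.max())


def basal_slice_index(volume: np.ndarray, floor_frac: float = SLICE_DETECTION_FLOOR) -> int:
    """``z`` index of the most basal occupied slice (slice label 1)."""
    occ = nonempty_slices(volume, floor_frac)
    if occ.size == 0:
        raise ValueError("volume contains no slices above the detection floor")
    return int(occ.max())


def select_slices(volume: np.ndarray, profile: CameraProfile) -> np.ndarray:
    """Select the analyzed slices for a camera profile.

    Returns exactly ``profile.n_slices`` contiguous ``z`` indices
    ordered from base to apex, starting at the most basal slice whose
    count sum exceeds the detection floor.

    Raises
    ------
    ValueError
        If fewer than ``profile.n_slices`` slices are occupied.
    """
    occ = nonempty_slices(volume)
    if occ.size < profile.n_slices:
        raise ValueError(
            f"volume has {occ.size} occupied slices; profile "
            f"{profile.name!r} requires {profile.n_slices}"
        )
    base = occ.max()
    return np.arange(base, base - profile.n_slices, -1)


def slice_center(slice_image: np.ndarray) -> np.ndarray:
    """Count-weighted centroid of a slice, in voxel units.

    Voxel ``(i, j)`` has its centre at ``(i + 0.5, j + 0.5)``. Computed
    on the AC image of a study; the paired NAC slice reuses the same
    centre so both volumes are binned identically.
    """
    w = np.asarray(slice_image, dtype=float)
    if w.min() < 0:
        raise ValueError("slice contains negative counts")
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot locate the centre of an all-zero slice")
    ii, jj = np.meshgrid(
        np.arange(w.shape[0]) + 0.5, np.arange(w.shape[1]) + 0.5, indexing="ij"
    )
    return np.array([(ii * w).sum() / total, (jj * w).sum() / total])


def sectorize(
    volume: np.ndarray,
    slice_indices: np.ndarray,
    centers: np.ndarray,
    convention: AngularConvention = DEFAULT_CONVENTION,
    radial_band_vox: tuple[float, float] | None = None,
) -> SectorGrid:
    """Bin each analyzed slice into 12 angular sectors and normalize.

    Every voxel of each analyzed slice is assigned to exactly one sector
    by the angle of its centre relative to the slice centre (half-open
    30-degree bins); per-segment raw counts are summed and the whole
    grid is normalized by the grand total.

    Parameters
    ----------
    volume : ndarray (x, y, z)
        Non-negative count volume.
    slice_indices : sequence of int
        Analyzed ``z`` indices ordered base to apex (see
        :func:`select_slices`).
    centers : ndarray, shape (n_slices, 2)
        Per-slice in-plane centres in voxel units.
    convention : AngularConvention
    radial_band_vox : (rmin, rmax), optional
        If given, only voxels whose centre lies within this radial band
        (voxel units) around the slice centre contribute; used to
        restrict membership to the myocardium on real data. Synthetic
        phantoms have no extra-myocardial counts, so the default binning
        over the full slice is exact.

    Raises
    ------
    ValueError
        If the total count over all analyzed segments is zero.
    """
    vol = np.asarray(volume, dtype=float)
    slice_indices = np.asarray(slice_indices, dtype=int)
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (slice_indices.size, 2):
        raise ValueError("need one (x, y) centre per analyzed slice")

    nx, ny = vol.shape[0], vol.shape[1]
    ii, jj = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5, indexing="ij")

    raw = np.zeros((slice_indices.size, N_SECTORS))
    for row, (z, c) in enumerate(zip(slice_indices, centers)):
        dx, dy = ii - c[0], jj - c[1]
        sec = convention.sector_of(convention.angles_deg(dx, dy))
        w = vol[:, :, z]
        if radial_band_vox is not None:
            r = np.hypot(dx, dy)
            w = np.where((r >= radial_band_vox[0]) & (r <= radial_band_vox[1]), w, 0.0)
        raw[row] = np.bincount(sec.ravel(), weights=w.ravel(), minlength=N_SECTORS)

    total = raw.sum()
    if total <= 0:
        raise ValueError("analyzed slices contain no counts")
    return SectorGrid(
        values=raw / total,
        raw_counts=raw,
        slice_indices=slice_indices,
        centers=centers,
        convention=convention,
        total_counts=float(total),
    )


def sectorize_study(
    nac_volume: np.ndarray,
    ac_volume: np.ndarray,
    profile: CameraProfile,
    convention: AngularConvention = DEFAULT_CONVENTION,
    radial_band_vox: tuple[float, float] | None = None,
    center_mode: str = "shared",
) -> tuple[SectorGrid, SectorGrid]:
    """Sectorize a paired NAC/AC study with shared geometry.

    Slice selection and centres are computed once, on the AC volume,
    and reused for the NAC volume, so the two grids are binned
    identically (the paired-geometry contract). Returns
    ``(nac_grid, ac_grid)``.

    ``center_mode`` selects how slice centres are estimated:

    ``"shared"`` (default)
        One centre for the whole analyzed stack — the count-weighted
        centroid of the summed AC slices. Dilutes the leverage of
        focal cold defects over the centre by the slice count, keeping
        voxel-to-sector binning stable, which is what makes true
        defects invisible to the NAC/AC ratio in practice. Appropriate
        for an untilted short-axis stack.
    ``"per-slice"``
        An independent count-weighted centroid per slice; tracks a
        tilted long axis but lets a focal defect drag the centres of
        the slices it touches.
    """
    slices = select_slices(ac_volume, profile)
    if center_mode == "shared":
        c = slice_center(ac_volume[:, :, slices].sum(axis=2))
        centers = np.tile(c, (slices.size, 1))
    elif center_mode == "per-slice":
        centers = np.array([slice_center(ac_volume[:, :, z]) for z in slices])
    else:
        raise ValueError(f"unknown center_mode {center_mode!r}")
    nac_grid = sectorize(nac_volume, slices, centers, convention, radial_band_vox)
    ac_grid = sectorize(ac_volume, slices, centers, convention, radial_band_vox)
    return nac_grid, ac_grid
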