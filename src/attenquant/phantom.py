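"""Digital left-ventricular phantom with injectable attenuation artifacts.

Generates paired NAC/AC short-axis count volumes of a cylindrical
myocardial shell (optionally capped apically), modelled on commercial
cardiac SPECT phantom inserts. Attenuation artifacts are injected as
multiplicative transmission factors in angular x axial zones of the NAC
volume only; true perfusion defects scale the same voxel set in BOTH
volumes; Poisson noise is optional and applied independently to the two
volumes. All ground truth (zones, factors, masks, seeds) is recorded so
downstream quantification can be verified against it.

The default shell geometry (outer radius 32 mm, wall 10 mm) voxelizes
into exactly equal sector voxel counts at both the 4 mm and the 6.4 mm
camera grids, so every (slice, sector) segment of a noiseless phantom
carries the same expected counts and fixtures are analytically exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .profiles import CameraProfile
from .sectorization import (
    DEFAULT_CONVENTION,
    N_SECTORS,
    SECTOR_SPAN_DEG,
    AngularConvention,
    basal_slice_index,
)

#: In-plane padding (voxels per side) around the shell.
_PAD_XY = 2
#: Axial padding (empty slices) on each side of the occupied span.
_PAD_Z = 2


@dataclass(frozen=True)
class LVGeometry:
    """Geometry and activity of the myocardial shell.

    Parameters
    ----------
    outer_radius_mm, wall_thickness_mm : float
        Epicardial radius and wall thickness of the shell. The defaults
        (32 mm / 10 mm) are anatomically plausible and chosen so the
        voxelized annulus splits into 12 equal sectors at both built-in
        camera grids.
    axial_length_mm : float or None
        Axial span of the cylindrical shell; ``None`` means exactly
        ``n_slices * voxel_size_mm`` for the profile in use.
    shape : {"cylinder", "cylinder+cap"}
        Optional hemispherical apical cap; the cap lies apical to the
        analyzed span and is excluded from analysis by slice selection.
    count_density : float
        Expected counts per myocardial voxel (noiseless volumes carry
        this value exactly). The default gives segment sums of a few
        thousand counts, typical of summed clinical short-axis slices.
    """

    outer_radius_mm: float = 32.0
    wall_thickness_mm: float = 10.0
    axial_length_mm: float | None = None
    shape: str = "cylinder"
    count_density: float = 500.0

    def __post_init__(self) -> None:
        if not 0 < self.wall_thickness_mm < self.outer_radius_mm:
            raise ValueError("need 0 < wall_thickness_mm < outer_radius_mm")
        if self.count_density <= 0:
            raise ValueError("count_density must be > 0")
        if self.shape not in ("cylinder", "cylinder+cap"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def axial_length_for(self, profile: CameraProfile) -> float:
        if self.axial_length_mm is None:
            return profile.n_slices * profile.voxel_size_mm
        return self.axial_length_mm

    def to_dict(self) -> dict:
        return {
            "outer_radius_mm": self.outer_radius_mm,
            "wall_thickness_mm": self.wall_thickness_mm,
            "axial_length_mm": self.axial_length_mm,
            "shape": self.shape,
            "count_density": self.count_density,
        }


@dataclass(frozen=True)
class AttenuationZone:
    """One angular x axial zone attenuated in the NAC volume.

    ``angle_start_deg`` / ``angle_stop_deg`` bound a half-open angular
    interval in the package convention; ``stop`` may exceed 360 (or be
    smaller than ``start``) to wrap through 0. ``slice_first`` /
    ``slice_last`` are inclusive slice labels, 1 = most basal.
    ``transmission`` is the multiplicative count survival factor,
    strictly in (0, 1).
    """

    angle_start_deg: float
    angle_stop_deg: float
    slice_first: int
    slice_last: int
    transmission: float

    def __post_init__(self) -> None:
        if not 0.0 < self.transmission < 1.0:
            raise ValueError("transmission must lie strictly in (0, 1)")
        if self.slice_first < 1 or self.slice_last < self.slice_first:
            raise ValueError("need 1 <= slice_first <= slice_last")
        if not 0.0 < self.angular_width_deg <= 360.0:
            raise ValueError("angular width must lie in (0, 360]")

    @property
    def angular_width_deg(self) -> float:
        return (self.angle_stop_deg - self.angle_start_deg) % 360.0 or 360.0

    def contains_angle(self, angles_deg: np.ndarray) -> np.ndarray:
        return (np.asarray(angles_deg) - self.angle_start_deg) % 360.0 < self.angular_width_deg

    @property
    def sector_aligned(self) -> bool:
        return (
            self.angle_start_deg % SECTOR_SPAN_DEG == 0
            and self.angular_width_deg % SECTOR_SPAN_DEG == 0
        )

    def sectors(self) -> list[int]:
        """Sector indices fully covered by the zone (sector-aligned only)."""
        if not self.sector_aligned:
            raise ValueError("zone is not aligned to sector boundaries")
        first = int(self.angle_start_deg // SECTOR_SPAN_DEG)
        return [(first + k) % N_SECTORS for k in range(int(self.angular_width_deg // SECTOR_SPAN_DEG))]

    def to_dict(self) -> dict:
        return {
            "angle_start_deg": self.angle_start_deg,
            "angle_stop_deg": self.angle_stop_deg,
            "slice_first": self.slice_first,
            "slice_last": self.slice_last,
            "transmission": self.transmission,
        }


def _zones_overlap(a: AttenuationZone, b: AttenuationZone) -> bool:
    if a.slice_last < b.slice_first or b.slice_last < a.slice_first:
        return False
    da = (b.angle_start_deg - a.angle_start_deg) % 360.0
    db = (a.angle_start_deg - b.angle_start_deg) % 360.0
    return da < a.angular_width_deg or db < b.angular_width_deg


@dataclass(frozen=True)
class ArtifactSpec:
    """A set of non-overlapping attenuation zones."""

    zones: tuple[AttenuationZone, ...] = ()

    def __post_init__(self) -> None:
        zones = tuple(self.zones)
        object.__setattr__(self, "zones", zones)
        for i in range(len(zones)):
            for j in range(i + 1, len(zones)):
                if _zones_overlap(zones[i], zones[j]):
                    raise ValueError(f"zones {i} and {j} overlap")

    @property
    def sector_aligned(self) -> bool:
        return all(z.sector_aligned for z in self.zones)

    def to_dict(self) -> dict:
        return {"zones": [z.to_dict() for z in self.zones]}


@dataclass(frozen=True)
class DefectSpec:
    """A true perfusion defect: reduced uptake in both NAC and AC.

    ``center_angle_deg`` / ``axial_center_mm`` place the defect centre
    at mid-wall radius; the axial coordinate is measured from the basal
    face of the most basal occupied slice toward the apex.
    ``uptake_factor`` scales the counts of the defect voxels (0 = solid
    cold defect; 1 leaves the volumes unchanged).
    """

    center_angle_deg: float
    axial_center_mm: float
    volume_cm3: float = 2.1
    uptake_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_cm3 <= 0:
            raise ValueError("volume_cm3 must be > 0")
        if not 0.0 <= self.uptake_factor <= 1.0:
            raise ValueError("uptake_factor must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "center_angle_deg": self.center_angle_deg,
            "axial_center_mm": self.axial_center_mm,
            "volume_cm3": self.volume_cm3,
            "uptake_factor": self.uptake_factor,
        }


@dataclass
class SyntheticStudy:
    """Paired NAC/AC volumes with full ground truth.

    ``truth_segment_mask`` is the (n_slices, 12) boolean artifact mask
    implied by sector-aligned zones (``None`` when any zone is not
    sector-aligned); ``truth_voxel_mask`` marks attenuated myocardial
    voxels; ``truth_defect_mask`` marks defect voxels. ``truth`` holds
    free-form generator metadata (cohort draws, realized volumes, ...).
    """

    ac_volume: np.ndarray
    nac_volume: np.ndarray
    profile: CameraProfile
    geometry: LVGeometry
    artifact: ArtifactSpec
    defect: DefectSpec | None
    noise: bool
    seed: int | None
    truth_segment_mask: np.ndarray | None
    truth_voxel_mask: np.ndarray
    truth_factors: tuple[float, ...]
    truth_defect_mask: np.ndarray
    convention: AngularConvention = field(default_factory=AngularConvention)
    truth: dict = field(default_factory=dict)


def grid_shape(geometry: LVGeometry, profile: CameraProfile) -> tuple[int, int, int]:
    """Volume shape for a geometry/profile pair (even in-plane size)."""
    vox = profile.voxel_size_mm
    n_xy = int(np.ceil(2 * geometry.outer_radius_mm / vox)) + 2 * _PAD_XY
    n_xy += n_xy % 2  # even size centres the shell on a voxel corner
    n_shell = int(round(geometry.axial_length_for(profile) / vox))
    n_cap = int(np.ceil(geometry.outer_radius_mm / vox)) if geometry.shape == "cylinder+cap" else 0
    return n_xy, n_xy, n_shell + n_cap + 2 * _PAD_Z


def _inplane_offsets(n_xy: int, vox: float) -> tuple[np.ndarray, np.ndarray]:
    c = n_xy / 2.0
    ii, jj = np.meshgrid(np.arange(n_xy) + 0.5, np.arange(n_xy) + 0.5, indexing="ij")
    return (ii - c) * vox, (jj - c) * vox


def build_ac_volume(
    geometry: LVGeometry, profile: CameraProfile
) -> np.ndarray:
    """Noiseless AC expectation volume of the myocardial shell.

    Voxels whose centre lies inside the shell carry
    ``geometry.count_density``; all other voxels are zero. The shell is
    centred in-plane on the grid centre; the axial span runs from apex
    (low ``z``) to base (high ``z``) with the cylinder occupying the
    most basal occupied slices.

    Raises
    ------
    ValueError
        If the axial span is shorter than the profile's analyzed span.
    """
    vox = profile.voxel_size_mm
    n_shell = int(round(geometry.axial_length_for(profile) / vox))
    if n_shell < profile.n_slices:
        raise ValueError(
            f"axial span of {n_shell} slices cannot cover the "
            f"{profile.n_slices} analyzed slices of profile {profile.name!r}"
        )
    nx, ny, nz = grid_shape(geometry, profile)
    dx, dy = _inplane_offsets(nx, vox)
    r = np.hypot(dx, dy)
    inner = geometry.outer_radius_mm - geometry.wall_thickness_mm
    annulus = (r <= geometry.outer_radius_mm) & (r >= inner)

    vol = np.zeros((nx, ny, nz))
    n_cap = int(np.ceil(geometry.outer_radius_mm / vox)) if geometry.shape == "cylinder+cap" else 0
    z_apex = _PAD_Z + n_cap  # first cylinder slice
    vol[:, :, z_apex : z_apex + n_shell] = (
        annulus[:, :, None] * geometry.count_density
    )
    if n_cap:
        # hemispherical shell centred on the axis at the cylinder's apex face
        zc_mm = z_apex * vox
        for z in range(_PAD_Z, z_apex):
            dz = (z + 0.5) * vox - zc_mm
            rho = np.sqrt(r**2 + dz**2)
            cap = (rho <= geometry.outer_radius_mm) & (rho >= inner)
            vol[:, :, z] = cap * geometry.count_density
    return vol


def _zone_voxel_mask(
    volume: np.ndarray,
    zone: AttenuationZone,
    profile: CameraProfile,
    convention: AngularConvention,
    center_vox: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of the voxels a zone acts on (myocardium included or not)."""
    nx, ny, nz = volume.shape
    if center_vox is None:
        center_vox = np.array([nx / 2.0, ny / 2.0])
    ii, jj = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5, indexing="ij")
    ang = convention.angles_deg(ii - center_vox[0], jj - center_vox[1])
    in_angle = zone.contains_angle(ang)

    z_base = basal_slice_index(volume)
    mask = np.zeros(volume.shape, dtype=bool)
    for label in range(zone.slice_first, zone.slice_last + 1):
        z = z_base - (label - 1)
        if 0 <= z < nz:
            mask[:, :, z] = in_angle
    return mask


def apply_artifact(
    ac_volume: np.ndarray,
    spec: ArtifactSpec,
    profile: CameraProfile,
    convention: AngularConvention = DEFAULT_CONVENTION,
    center_vox: np.ndarray | None = None,
) -> np.ndarray:
    """Derive the NAC volume by attenuating zones of the AC volume.

    Each zone's voxels (angular interval about the in-plane shell
    centre, inclusive slice-label range counted from the base) are
    multiplied by that zone's transmission factor; everything else is
    copied unchanged. The input AC volume is not modified.
    """
    nac = np.asarray(ac_volume, dtype=float).copy()
    for zone in spec.zones:
        m = _zone_voxel_mask(ac_volume, zone, profile, convention, center_vox)
        nac[m] *= zone.transmission
    return nac


def artifact_voxel_mask(
    ac_volume: np.ndarray,
    spec: ArtifactSpec,
    profile: CameraProfile,
    convention: AngularConvention = DEFAULT_CONVENTION,
    center_vox: np.ndarray | None = None,
) -> np.ndarray:
    """Myocardial voxels (positive AC counts) attenuated by any zone."""
    mask = np.zeros(np.asarray(ac_volume).shape, dtype=bool)
    for zone in spec.zones:
        mask |= _zone_voxel_mask(ac_volume, zone, profile, convention, center_vox)
    return mask & (np.asarray(ac_volume) > 0)


def artifact_segment_mask(
    spec: ArtifactSpec, profile: CameraProfile
) -> np.ndarray | None:
    """(n_slices, 12) truth mask implied by sector-aligned zones.

    Returns ``None`` when any zone is not aligned to 30-degree sector
    boundaries (the truth is then only defined at voxel level).
    """
    if not spec.sector_aligned:
        return None
    mask = np.zeros((profile.n_slices, N_SECTORS), dtype=bool)
    for zone in spec.zones:
        rows = slice(zone.slice_first - 1, min(zone.slice_last, profile.n_slices))
        for s in zone.sectors():
            mask[rows, s] = True
    return mask


@dataclass
class DefectRealization:
    """Voxelized defect actually inserted into a volume pair."""

    voxel_mask: np.ndarray
    n_voxels: int
    realized_volume_cm3: float
    clipped: bool


def insert_defect(
    ac_volume: np.ndarray,
    nac_volume: np.ndarray,
    defect: DefectSpec,
    geometry: LVGeometry,
    profile: CameraProfile,
    convention: AngularConvention = DEFAULT_CONVENTION,
) -> tuple[np.ndarray, np.ndarray, DefectRealization]:
    """Scale the same voxel set by ``uptake_factor`` in BOTH volumes.

    The defect is voxelized by greedy nearest-voxel fill: myocardial
    voxels are taken in order of distance to the requested centre until
    the requested volume is reached (realized volume within one voxel
    volume of the request). A true defect is present regardless of
    attenuation correction, so the identical voxel set is scaled in the
    AC and NAC volumes; per-segment NAC/AC ratios are therefore
    unchanged wherever AC counts remain positive.

    Returns new arrays (inputs are not modified) and the realization.

    Raises
    ------
    ValueError
        If the requested centre does not lie within the myocardium.
    """
    ac = np.asarray(ac_volume, dtype=float)
    nac = np.asarray(nac_volume, dtype=float)
    vox = profile.voxel_size_mm
    nx, ny, _ = ac.shape

    r_mid = geometry.outer_radius_mm - geometry.wall_thickness_mm / 2.0
    d = convention.direction(defect.center_angle_deg) * (r_mid / vox)
    z_base_face = basal_slice_index(ac) + 1.0  # basal face, voxel units
    center = np.array(
        [nx / 2.0 + d[0], ny / 2.0 + d[1], z_base_face - defect.axial_center_mm / vox]
    )

    myo = np.argwhere(ac > 0)
    if myo.size == 0:
        raise ValueError("AC volume contains no myocardial voxels")
    dist = np.linalg.norm(myo + 0.5 - center, axis=1)
    if dist.min() > np.sqrt(3.0) / 2.0:
        raise ValueError("defect centre does not lie within the myocardial shell")

    n_req = max(1, int(round(defect.volume_cm3 * 1000.0 / vox**3)))
    clipped = n_req > len(myo)
    if clipped:
        warnings.warn(
            f"defect of {defect.volume_cm3} cm^3 exceeds the shell; "
            f"clipped to {len(myo)} voxels",
            stacklevel=2,
        )
        n_req = len(myo)
    order = np.argsort(dist, kind="stable")[:n_req]
    mask = np.zeros(ac.shape, dtype=bool)
    mask[tuple(myo[order].T)] = True

    ac2, nac2 = ac.copy(), nac.copy()
    ac2[mask] *= defect.uptake_factor
    nac2[mask] *= defect.uptake_factor
    return ac2, nac2, DefectRealization(
        voxel_mask=mask,
        n_voxels=n_req,
        realized_volume_cm3=n_req * vox**3 / 1000.0,
        clipped=clipped,
    )


def add_poisson_noise(
    volume: np.ndarray, seed: int | np.random.Generator | None
) -> np.ndarray:
    """Replace each voxel expectation by a Poisson draw with that mean."""
    vol = np.asarray(volume, dtype=float)
    if vol.min() < 0:
        raise ValueError("volume contains negative expectations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(vol).astype(float)


def generate_study(
    geometry: LVGeometry = LVGeometry(),
    artifact: ArtifactSpec = ArtifactSpec(),
    defect: DefectSpec | None = None,
    profile: CameraProfile | None = None,
    noise: bool = False,
    seed: int | None = None,
    convention: AngularConvention = DEFAULT_CONVENTION,
) -> SyntheticStudy:
    """Compose the full generator: shell -> defect -> artifact -> noise.

    Noise is applied independently to the NAC and AC volumes using
    streams spawned from ``seed``; regeneration from the same
    configuration and seed is bit-identical.
    """
    if profile is None:
        from .profiles import CZT

        profile = CZT
    ac = build_ac_volume(geometry, profile)

    truth: dict = {}
    defect_mask = np.zeros(ac.shape, dtype=bool)
    if defect is not None:
        ac, _, real = insert_defect(ac, ac, defect, geometry, profile, convention)
        defect_mask = real.voxel_mask
        truth["defect_realized_volume_cm3"] = real.realized_volume_cm3
        truth["defect_n_voxels"] = real.n_voxels

    voxel_mask = artifact_voxel_mask(ac, artifact, profile, convention)
    nac = apply_artifact(ac, artifact, profile, convention)

    if noise:
        ss = np.random.SeedSequence(seed)
        nac_rng, ac_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        nac = add_poisson_noise(nac, nac_rng)
        ac = add_poisson_noise(ac, ac_rng)

    return SyntheticStudy(
        ac_volume=ac,
        nac_volume=nac,
        profile=profile,
        geometry=geometry,
        artifact=artifact,
        defect=defect,
        noise=noise,
        seed=seed,
        truth_segment_mask=artifact_segment_mask(artifact, profile),
        truth_voxel_mask=voxel_mask,
        truth_factors=tuple(z.transmission for z in artifact.zones),
        truth_defect_mask=defect_mask,
        convention=convention,
        truth=truth,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for a simulated acquisition cohort.

    Per acquisition, the artifact extent (percent of segments), depth
    (percent, converted to the zone transmission factor) and centre
    angle are drawn from the stated distributions; the extent is
    realized as one contiguous sector-aligned angular block centred on
    the drawn angle, covering the most basal slices.
    """

    n_acquisitions: int
    extent_pct_distribution: tuple[float, float]
    depth_pct_distribution: tuple[float, float]
    center_angle_distribution: tuple[float, float]
    profile: CameraProfile
    seed: int
    noise: bool = True
    geometry: LVGeometry = LVGeometry()

    def __post_init__(self) -> None:
        if self.n_acquisitions < 2:
            raise ValueError("n_acquisitions must be >= 2")
        for mean, sd in (self.extent_pct_distribution, self.depth_pct_distribution):
            if not 0 < mean < 100:
                raise ValueError("extent/depth means must lie in (0, 100)")
            if sd < 0:
                raise ValueError("sds must be >= 0")
        if self.center_angle_distribution[1] < 0:
            raise ValueError("sds must be >= 0")


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """One draw from a normal truncated to (lo, hi)."""
    if sd == 0:
        return mean
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _block_for_extent(
    extent_pct: float, center_deg: float, profile: CameraProfile
) -> tuple[int, int, int]:
    """Sector-aligned contiguous block approximating a drawn extent.

    Returns ``(start_sector, n_sectors, n_slices)`` such that the block
    of ``n_sectors`` contiguous sectors over the ``n_slices`` most basal
    slices has a segment count as close as achievable to
    ``extent_pct`` of the grid, centred on ``center_deg``.
    """
    n_total = profile.n_slices * N_SECTORS
    n_target = int(round(extent_pct / 100.0 * n_total))
    if n_target < 1:
        raise ValueError("drawn extent rounds to zero segments")
    w = min(N_SECTORS, int(np.ceil(n_target / profile.n_slices)))
    s = int(np.clip(round(n_target / w), 1, profile.n_slices))
    start = int(round((center_deg - 15.0 * w) / SECTOR_SPAN_DEG)) % N_SECTORS
    return start, w, s


def generate_cohort(spec: CohortSpec, max_retries: int = 100) -> list[SyntheticStudy]:
    """Simulate a cohort of acquisitions with drawn artifact parameters.

    Each study's ``truth`` dict records the drawn extent/depth/angle and
    the achieved (sector-aligned) extent and block centre. Draws whose
    extent rounds to zero segments are redrawn (bounded retries).
    """
    rng = np.random.default_rng(spec.seed)
    ss = np.random.SeedSequence(spec.seed).spawn(spec.n_acquisitions)
    studies = []
    for i in range(spec.n_acquisitions):
        for _ in range(max_retries):
            ext = _truncnorm_draw(rng, *spec.extent_pct_distribution, 0.0, 100.0)
            try:
                dep = _truncnorm_draw(rng, *spec.depth_pct_distribution, 0.0, 100.0)
                ang = rng.normal(*spec.center_angle_distribution) % 360.0
                start, w, s = _block_for_extent(ext, ang, spec.profile)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not draw a non-empty extent")
        zone = AttenuationZone(
            angle_start_deg=(start * SECTOR_SPAN_DEG) % 360.0,
            angle_stop_deg=(start * SECTOR_SPAN_DEG + w * SECTOR_SPAN_DEG) % 360.0
            or 360.0,
            slice_first=1,
            slice_last=s,
            transmission=float(np.clip(dep / 100.0, 1e-6, 1 - 1e-6)),
        )
        study = generate_study(
            geometry=spec.geometry,
            artifact=ArtifactSpec(zones=(zone,)),
            profile=spec.profile,
            noise=spec.noise,
            seed=int(ss[i].generate_state(1)[0] % (2**31)),
        )
        n_total = spec.profile.n_slices * N_SECTORS
        study.truth.update(
            {
                "drawn_extent_pct": ext,
                "drawn_depth_pct": dep,
                "drawn_center_deg": ang,
                "achieved_extent_pct": 100.0 * w * s / n_total,
                "achieved_center_deg": (start * SECTOR_SPAN_DEG + 15.0 * w) % 360.0,
                "n_sectors": w,
                "n_slices_attenuated": s,
            }
        )
        studies.append(study)
    return studies
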