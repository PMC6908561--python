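"""NAC/AC ratio maps and attenuation-artifact metrics.

The per-segment ratio of normalized NAC to normalized AC counts is the
artifact descriptor: segments free of attenuation sit at (approximately)
1, attenuated segments fall below 1. A fixed per-camera threshold
delineates the artifact mask, from which three metrics are computed:

extent
    Fraction of analyzed segments inside the artifact.
localization
    Circular mean (mean resultant direction) of the sector-centre
    angles of the artifact segments, in [0, 360) degrees.
depth
    Mean normalized NAC counts over artifact segments divided by the
    mean over the 30% of segments with the highest counts — the
    fractional count level surviving in the attenuated area.

All three are invariant to a global rescaling of either volume, since
sector grids are normalized before the ratio is formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sectorization import (
    DEFAULT_CONVENTION,
    AngularConvention,
    SectorGrid,
    sectorize_study,
)


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves away from zero."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class RatioMap:
    """Per-segment NAC/AC normalized-count ratios.

    ``defined_mask`` marks segments whose AC raw counts are positive;
    only those entries of ``values`` are meaningful. Undefined entries
    are stored as NaN, never infinity.
    """

    values: np.ndarray
    defined_mask: np.ndarray
    convention: AngularConvention = field(default_factory=AngularConvention)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ArtifactMask:
    """Boolean delineation of the attenuation artifact."""

    mask: np.ndarray
    threshold_used: float

    @property
    def n_artifact_segments(self) -> int:
        return int(self.mask.sum())

    @property
    def n_total_segments(self) -> int:
        return int(self.mask.size)


@dataclass
class ArtifactMetrics:
    """Extent / localization / depth of one acquisition's artifact.

    ``localization_deg`` and ``depth_fraction`` are ``None`` iff the
    mask is empty (or, for localization, the resultant vector vanishes —
    flagged via ``localization_degenerate``).
    """

    extent_fraction: float
    localization_deg: float | None
    depth_fraction: float | None
    n_artifact_segments: int
    n_total_segments: int
    threshold_used: float
    localization_degenerate: bool = False

    @property
    def extent_pct(self) -> int:
        return round_half_up(100.0 * self.extent_fraction)

    @property
    def depth_pct(self) -> int | None:
        if self.depth_fraction is None:
            return None
        return round_half_up(100.0 * self.depth_fraction)

    def to_dict(self) -> dict:
        return {
            "extent_fraction": self.extent_fraction,
            "extent_pct_rounded": self.extent_pct,
            "localization_deg": self.localization_deg,
            "localization_degenerate": self.localization_degenerate,
            "depth_fraction": self.depth_fraction,
            "depth_pct_rounded": self.depth_pct,
            "n_artifact_segments": self.n_artifact_segments,
            "n_total_segments": self.n_total_segments,
            "threshold_used": self.threshold_used,
        }


def compute_ratio(nac_grid: SectorGrid, ac_grid: SectorGrid) -> RatioMap:
    """Per-segment ratio of normalized NAC to normalized AC counts.

    Segments with zero AC raw counts are marked undefined (NaN) and are
    excluded from delineation downstream.

    Raises
    ------
    ValueError
        If the grids differ in shape, analyzed slices or angular
        convention (they must come from one study).
    """
    if nac_grid.values.shape != ac_grid.values.shape:
        raise ValueError("NAC and AC grids differ in shape")
    if not np.array_equal(nac_grid.slice_indices, ac_grid.slice_indices):
        raise ValueError("NAC and AC grids were built from different slices")
    if nac_grid.convention != ac_grid.convention:
        raise ValueError("NAC and AC grids use different angular conventions")
    defined = ac_grid.raw_counts > 0
    values = np.full(ac_grid.values.shape, np.nan)
    np.divide(nac_grid.values, ac_grid.values, out=values, where=defined)
    return RatioMap(values=values, defined_mask=defined, convention=nac_grid.convention)


def _wrapped_components(mask: np.ndarray) -> np.ndarray:
    """Label 4-connected components on the slice x sector grid with
    angular wrap between the first and last sector columns."""
    from scipy import ndimage

    labels, n = ndimage.label(mask)
    if n > 1:
        # merge components touching across the angular seam
        for row in range(mask.shape[0]):
            a, b = labels[row, 0], labels[row, -1]
            if a and b and a != b:
                labels[labels == b] = a
    return labels


def delineate(
    ratio: RatioMap, threshold: float, connectivity_filter: bool = False
) -> ArtifactMask:
    """Threshold the ratio map: artifact where defined ratio < threshold.

    The comparison is strict, so a noiseless segment sitting exactly at
    the threshold is not delineated. No connectivity filtering is
    applied unless ``connectivity_filter`` is set, in which case only
    the largest wrap-aware 4-connected component is kept.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    mask = ratio.defined_mask & (ratio.values < threshold)
    if connectivity_filter and mask.any():
        labels = _wrapped_components(mask)
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        mask = labels == ids[np.argmax(counts)]
    return ArtifactMask(mask=mask, threshold_used=threshold)


def extent(mask: ArtifactMask) -> float:
    """Fraction of analyzed segments delineated as artifact.

    Undefined segments remain in the denominator (they can never be
    artifact members), so the denominator is always the full analyzed
    grid size.
    """
    return mask.n_artifact_segments / mask.n_total_segments


def localization(
    mask: ArtifactMask,
    convention: AngularConvention = DEFAULT_CONVENTION,
    ratio: RatioMap | None = None,
    weighted: bool = False,
) -> tuple[float | None, bool]:
    """Angle of the artifact centre: circular mean of sector centres.

    Each artifact segment contributes its sector-centre angle with equal
    weight; with ``weighted=True`` segments are weighted by their count
    depression ``1 - ratio`` instead (requires ``ratio``).

    Returns ``(angle_deg, degenerate)``: the angle is ``None`` for an
    empty mask, and ``None`` with ``degenerate=True`` when the resultant
    vector vanishes (perfectly antipodal mask).
    """
    m = mask.mask
    if not m.any():
        return None, False
    centers = convention.sector_centers_deg
    angles = np.broadcast_to(centers, m.shape)[m]
    if weighted:
        if ratio is None:
            raise ValueError("weighted localization requires the ratio map")
        w = np.clip(1.0 - ratio.values[m], 0.0, None)
        if w.sum() == 0:
            w = np.ones_like(w)
    else:
        w = np.ones(angles.size)
    z = np.sum(w * np.exp(1j * np.radians(angles)))
    if np.abs(z) < 1e-9 * w.sum():
        return None, True
    ang = float(np.degrees(np.angle(z)) % 360.0)
    return (0.0 if ang >= 360.0 - 1e-12 else ang), False


def depth(
    mask: ArtifactMask,
    nac_grid: SectorGrid,
    top_fraction: float = 0.30,
    ac_grid: SectorGrid | None = None,
    source: str = "nac",
) -> float | None:
    """Relative count level inside the artifact.

    Mean normalized counts over the artifact segments divided by the
    mean over the ``k = round(top_fraction * n_total)`` highest-count
    segments (ties broken by segment index, ascending). Computed on the
    NAC grid by default — the artifact is a count reduction in the
    uncorrected image — with ``source="ac"`` as a variant.

    Returns ``None`` for an empty mask.

    Raises
    ------
    ValueError
        If ``k`` rounds to zero, or ``source="ac"`` without an AC grid.
    """
    if source == "nac":
        grid = nac_grid
    elif source == "ac":
        if ac_grid is None:
            raise ValueError('source="ac" requires ac_grid')
        grid = ac_grid
    else:
        raise ValueError(f"unknown depth source {source!r}")
    if not mask.mask.any():
        return None
    flat = grid.values.ravel()
    k = round_half_up(top_fraction * flat.size)
    if k < 1:
        raise ValueError("top_fraction selects zero segments")
    top = flat[np.argsort(-flat, kind="stable")[:k]]
    return float(flat[mask.mask.ravel()].mean() / top.mean())


def quantify_grids(
    nac_grid: SectorGrid,
    ac_grid: SectorGrid,
    threshold: float,
    weighted_localization: bool = False,
    depth_source: str = "nac",
    connectivity_filter: bool = False,
    top_fraction: float = 0.30,
) -> ArtifactMetrics:
    """Ratio -> delineation -> extent/localization/depth on one study's grids."""
    ratio = compute_ratio(nac_grid, ac_grid)
    mask = delineate(ratio, threshold, connectivity_filter)
    loc, degenerate = localization(
        mask, nac_grid.convention, ratio=ratio, weighted=weighted_localization
    )
    return ArtifactMetrics(
        extent_fraction=extent(mask),
        localization_deg=loc,
        depth_fraction=depth(
            mask, nac_grid, top_fraction=top_fraction, ac_grid=ac_grid, source=depth_source
        ),
        n_artifact_segments=mask.n_artifact_segments,
        n_total_segments=mask.n_total_segments,
        threshold_used=threshold,
        localization_degenerate=degenerate,
    )


def quantify_study(
    bundle,
    threshold: float | None = None,
    convention: AngularConvention = DEFAULT_CONVENTION,
    **options,
) -> ArtifactMetrics:
    """Full pipeline on a paired study: slices -> centres -> sectorize ->
    ratio -> delineate -> metrics.

    ``bundle`` is anything carrying ``nac_volume``, ``ac_volume`` and
    ``profile`` attributes (a :class:`~attenquant.io.StudyBundle` or a
    :class:`~attenquant.phantom.SyntheticStudy`). The profile's ratio
    threshold is used unless overridden. Deterministic given inputs.
    """
    profile = bundle.profile
    nac_grid, ac_grid = sectorize_study(
        bundle.nac_volume, bundle.ac_volume, profile, convention
    )
    return quantify_grids(
        nac_grid,
        ac_grid,
        threshold if threshold is not None else profile.ratio_threshold,
        **options,
    )
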