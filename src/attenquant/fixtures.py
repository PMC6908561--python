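"""Pinned reference phantoms.

Two noiseless studies whose injected artifacts reproduce the published
phantom measurements of the two cameras, used throughout the test suite
and regenerable bit-identically from their pinned configurations:

``phantom_czt``
    CZT profile (240 segments). One artifact block over the four
    sectors centred 105/135/165/195 degrees on the 17 most basal
    slices; transmission 0.70 on the counter-clockwise pair and 0.76 on
    the clockwise pair. Ground truth: extent 68/240 (28% rounded),
    localization 150 degrees, depth (0.70 + 0.76) / 2 = 0.73.

``phantom_ventri``
    Conventional profile (144 segments). Three sectors centred
    135/165/195 degrees on the 9 most basal slices; transmissions
    0.62 / 0.66 / 0.73. Ground truth: extent 27/144 (19% rounded),
    localization 165 degrees, depth 0.67.
"""

from __future__ import annotations

from .phantom import (
    ArtifactSpec,
    AttenuationZone,
    DefectSpec,
    LVGeometry,
    SyntheticStudy,
    generate_study,
)
from .profiles import CZT, VENTRI

PHANTOM_CZT_ZONES = (
    AttenuationZone(90.0, 150.0, slice_first=1, slice_last=17, transmission=0.70),
    AttenuationZone(150.0, 210.0, slice_first=1, slice_last=17, transmission=0.76),
)

PHANTOM_VENTRI_ZONES = (
    AttenuationZone(120.0, 150.0, slice_first=1, slice_last=9, transmission=0.62),
    AttenuationZone(150.0, 180.0, slice_first=1, slice_last=9, transmission=0.66),
    AttenuationZone(180.0, 210.0, slice_first=1, slice_last=9, transmission=0.73),
)

#: Solid anterior defect matching the physical phantom experiment:
#: 2.1 cm^3, zero uptake, centred on the anterior wall mid-span.
ANTERIOR_DEFECT = DefectSpec(
    center_angle_deg=0.0, axial_center_mm=40.0, volume_cm3=2.1, uptake_factor=0.0
)

FIXTURE_SEED = 20180523


def phantom_czt(defect: bool = False, noise: bool = False) -> SyntheticStudy:
    """The pinned CZT-profile reference study (noiseless by default)."""
    return generate_study(
        geometry=LVGeometry(),
        artifact=ArtifactSpec(zones=PHANTOM_CZT_ZONES),
        defect=ANTERIOR_DEFECT if defect else None,
        profile=CZT,
        noise=noise,
        seed=FIXTURE_SEED,
    )


def phantom_ventri(defect: bool = False, noise: bool = False) -> SyntheticStudy:
    """The pinned conventional-profile reference study."""
    return generate_study(
        geometry=LVGeometry(),
        artifact=ArtifactSpec(zones=PHANTOM_VENTRI_ZONES),
        defect=ANTERIOR_DEFECT if defect else None,
        profile=VENTRI,
        noise=noise,
        seed=FIXTURE_SEED,
    )


FIXTURES = {"phantom_czt": phantom_czt, "phantom_ventri": phantom_ventri}
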