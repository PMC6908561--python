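"""Ratio maps, delineation and the extent/localization/depth metrics."""

import numpy as np
import pytest

from attenquant import (
    CZT,
    VENTRI,
    ArtifactSpec,
    compute_ratio,
    delineate,
    depth,
    extent,
    generate_study,
    localization,
    quantify_study,
)
from attenquant.fixtures import ANTERIOR_DEFECT, phantom_czt, phantom_ventri
from attenquant.quantify import ArtifactMask, RatioMap, round_half_up
from attenquant.sectorization import AngularConvention, SectorGrid, sectorize_study


def _grid_from_raw(raw):
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    return SectorGrid(
        values=raw / raw.sum(),
        raw_counts=raw,
        slice_indices=np.arange(n)[::-1],
        centers=np.tile([5.0, 5.0], (n, 1)),
        total_counts=float(raw.sum()),
    )


def _mask(bool_array, threshold=0.9):
    return ArtifactMask(mask=np.asarray(bool_array, dtype=bool), threshold_used=threshold)


class TestComputeRatio:
    def test_identical_grids_give_unit_ratios(self, rng):
        raw = rng.integers(1, 100, size=(4, 12)).astype(float)
        ratio = compute_ratio(_grid_from_raw(raw), _grid_from_raw(raw))
        assert ratio.defined_mask.all()
        np.testing.assert_allclose(ratio.values, 1.0)

    def test_renormalization_closed_form(self):
        """Scaling one segment's NAC raw counts to 0.8x AC depresses that
        segment's ratio and raises every other ratio by the same
        renormalization factor T_ac / T_nac."""
        ac_raw = np.full((3, 12), 50.0)
        nac_raw = ac_raw.copy()
        nac_raw[1, 4] *= 0.8
        ratio = compute_ratio(_grid_from_raw(nac_raw), _grid_from_raw(ac_raw))
        t_ac, t_nac = ac_raw.sum(), nac_raw.sum()
        expected = np.full((3, 12), t_ac / t_nac)
        expected[1, 4] = 0.8 * t_ac / t_nac
        np.testing.assert_allclose(ratio.values, expected, rtol=1e-12)
        assert ratio.values[1, 4] < 1.0
        others = np.ones((3, 12), dtype=bool)
        others[1, 4] = False
        assert (ratio.values[others] > 1.0).all()

    def test_zero_ac_segment_is_undefined(self):
        ac_raw = np.full((2, 12), 10.0)
        ac_raw[0, 0] = 0.0
        nac_raw = ac_raw.copy()
        ratio = compute_ratio(_grid_from_raw(nac_raw), _grid_from_raw(ac_raw))
        assert not ratio.defined_mask[0, 0]
        assert np.isnan(ratio.values[0, 0])
        mask = delineate(ratio, 0.9)
        assert not mask.mask[0, 0]

    def test_mismatched_grids_rejected(self, rng):
        a = _grid_from_raw(rng.integers(1, 9, (3, 12)))
        b = _grid_from_raw(rng.integers(1, 9, (4, 12)))
        with pytest.raises(ValueError, match="shape"):
            compute_ratio(a, b)


class TestDelineate:
    def test_threshold_is_strict(self):
        raw = np.full((1, 12), 100.0)
        ratio = RatioMap(
            values=np.array([[0.95, 0.89, 0.91] + [1.0] * 9]),
            defined_mask=np.ones((1, 12), dtype=bool),
        )
        np.testing.assert_array_equal(
            delineate(ratio, 0.90).mask[0, :3], [False, True, False]
        )
        assert not delineate(ratio, 0.85).mask.any()
        assert not delineate(
            RatioMap(values=np.ones((1, 12)), defined_mask=np.ones((1, 12), bool)), 0.9
        ).mask.any()

    def test_mask_grows_monotonically_with_threshold(self, rng):
        vals = rng.uniform(0.5, 1.2, size=(5, 12))
        ratio = RatioMap(values=vals, defined_mask=np.ones_like(vals, dtype=bool))
        prev = None
        for thr in (0.6, 0.7, 0.8, 0.9, 0.99):
            mask = delineate(ratio, thr).mask
            if prev is not None:
                assert (mask | prev == mask).all()  # superset of previous
            prev = mask

    def test_connectivity_filter_keeps_largest_component(self):
        vals = np.ones((3, 12))
        vals[0, 0] = vals[0, 11] = vals[1, 0] = 0.5   # wrap-connected blob of 3
        vals[2, 6] = 0.5                              # isolated singleton
        ratio = RatioMap(values=vals, defined_mask=np.ones_like(vals, bool))
        mask = delineate(ratio, 0.9, connectivity_filter=True)
        assert mask.n_artifact_segments == 3
        assert not mask.mask[2, 6]

    def test_out_of_range_threshold_rejected(self):
        ratio = RatioMap(values=np.ones((1, 12)), defined_mask=np.ones((1, 12), bool))
        for bad in (0.0, 1.0, -1.0, 2.0):
            with pytest.raises(ValueError):
                delineate(ratio, bad)


class TestExtent:
    @pytest.mark.parametrize(
        "n_true, shape, expected",
        [(0, (20, 12), 0.0), (36, (12, 12), 0.25), (68, (20, 12), 68 / 240)],
    )
    def test_fraction_of_segments(self, n_true, shape, expected):
        m = np.zeros(shape, dtype=bool)
        m.ravel()[:n_true] = True
        assert extent(_mask(m)) == pytest.approx(expected)

    def test_random_mask_matches_counting_oracle(self, rng):
        m = rng.random((7, 12)) < 0.3
        oracle = sum(1 for v in m.ravel() if v) / m.size
        assert extent(_mask(m)) == pytest.approx(oracle)


class TestLocalization:
    def test_symmetric_block_centers_on_150(self):
        m = np.zeros((5, 12), dtype=bool)
        m[:, 3:7] = True  # sectors centred 105, 135, 165, 195
        loc, degenerate = localization(_mask(m))
        assert loc == pytest.approx(150.0) and not degenerate

    def test_wraparound_pair_averages_to_zero(self):
        m = np.zeros((1, 12), dtype=bool)
        m[0, 11] = m[0, 0] = True  # centres 345 and 15
        loc, _ = localization(_mask(m))
        assert loc == pytest.approx(0.0, abs=1e-9)

    def test_single_segment_returns_its_center(self):
        m = np.zeros((2, 12), dtype=bool)
        m[1, 5] = True  # centre 165
        loc, _ = localization(_mask(m))
        assert loc == pytest.approx(165.0)

    def test_empty_mask_is_undefined_not_zero(self):
        loc, degenerate = localization(_mask(np.zeros((3, 12), dtype=bool)))
        assert loc is None and not degenerate

    def test_antipodal_mask_is_flagged_degenerate(self):
        m = np.zeros((1, 12), dtype=bool)
        m[0, 0] = m[0, 6] = True  # centres 15 and 195
        loc, degenerate = localization(_mask(m))
        assert loc is None and degenerate

    def test_matches_scipy_circmean_oracle(self, rng):
        from scipy.stats import circmean

        m = rng.random((6, 12)) < 0.4
        if not m.any():
            m[0, 0] = True
        loc, _ = localization(_mask(m))
        centers = AngularConvention().sector_centers_deg
        angles = np.broadcast_to(centers, m.shape)[m]
        assert loc == pytest.approx(circmean(angles, high=360.0), abs=1e-9)

    def test_depression_weighted_variant(self):
        vals = np.ones((1, 12))
        vals[0, 3], vals[0, 5] = 0.4, 0.8  # centres 105 (deep), 165 (shallow)
        ratio = RatioMap(values=vals, defined_mask=np.ones_like(vals, bool))
        m = np.zeros((1, 12), dtype=bool)
        m[0, 3] = m[0, 5] = True
        loc_u, _ = localization(_mask(m))
        loc_w, _ = localization(_mask(m), ratio=ratio, weighted=True)
        assert loc_u == pytest.approx(135.0)
        assert loc_w < loc_u  # pulled toward the deeper segment at 105


class TestDepth:
    def test_constructed_uniform_background_gives_073(self):
        raw = np.full((20, 12), 100.0)
        m = np.zeros((20, 12), dtype=bool)
        m[:17, 3:7] = True
        raw[m] *= 0.73
        val = depth(_mask(m), _grid_from_raw(raw))
        assert val == pytest.approx(0.73, rel=1e-12)

    def test_full_mask_bounded_by_one(self, rng):
        raw = rng.uniform(1.0, 10.0, size=(4, 12))
        full = _mask(np.ones((4, 12), dtype=bool))
        assert depth(full, _grid_from_raw(raw)) <= 1.0
        const = _grid_from_raw(np.full((4, 12), 5.0))
        assert depth(full, const) == pytest.approx(1.0)

    def test_matches_sort_and_average_oracle(self, rng):
        raw = rng.uniform(0.5, 20.0, size=(12, 12))
        m = rng.random((12, 12)) < 0.25
        m[0, 0] = True
        grid = _grid_from_raw(raw)
        flat = grid.values.ravel()
        k = int(np.floor(0.30 * flat.size + 0.5))
        top = sorted(flat, reverse=True)[:k]
        oracle = flat[m.ravel()].mean() / np.mean(top)
        assert depth(_mask(m), grid) == pytest.approx(oracle, rel=1e-12)

    def test_empty_mask_is_undefined(self, rng):
        grid = _grid_from_raw(rng.uniform(1, 5, (3, 12)))
        assert depth(_mask(np.zeros((3, 12), bool)), grid) is None

    def test_zero_k_is_an_error(self, rng):
        grid = _grid_from_raw(rng.uniform(1, 5, (3, 12)))
        with pytest.raises(ValueError, match="zero segments"):
            depth(_mask(np.ones((3, 12), bool)), grid, top_fraction=0.001)

    def test_ac_source_variant(self, czt_study):
        nac_grid, ac_grid = sectorize_study(
            czt_study.nac_volume, czt_study.ac_volume, CZT
        )
        ratio = compute_ratio(nac_grid, ac_grid)
        m = delineate(ratio, 0.9)
        d_nac = depth(m, nac_grid)
        d_ac = depth(m, nac_grid, ac_grid=ac_grid, source="ac")
        assert d_nac == pytest.approx(0.73, abs=1e-9)
        assert d_ac == pytest.approx(1.0, abs=1e-9)  # no depression before AC removal


class TestQuantifyStudy:
    def test_artifact_free_study_is_null(self):
        s = generate_study(artifact=ArtifactSpec(), profile=VENTRI)
        m = quantify_study(s)
        assert m.extent_fraction == 0.0
        assert m.localization_deg is None and m.depth_fraction is None

    def test_fixture_recovers_injected_truth_exactly(self, czt_study):
        m = quantify_study(czt_study)
        assert m.n_artifact_segments == 68
        assert m.extent_pct == 28
        assert m.localization_deg == pytest.approx(150.0)
        assert m.depth_pct == 73

    def test_delineation_equals_truth_mask(self, czt_study, ventri_study):
        for s in (czt_study, ventri_study):
            nac_grid, ac_grid = sectorize_study(s.nac_volume, s.ac_volume, s.profile)
            mask = delineate(
                compute_ratio(nac_grid, ac_grid), s.profile.ratio_threshold
            )
            np.testing.assert_array_equal(mask.mask, s.truth_segment_mask)

    def test_defect_only_study_has_zero_extent(self):
        s = generate_study(artifact=ArtifactSpec(), defect=ANTERIOR_DEFECT, profile=CZT)
        assert quantify_study(s).extent_fraction == 0.0

    def test_defect_changes_no_metric(self):
        """A true 2.1 cm^3 defect present in both volumes leaves extent,
        localization and depth unchanged (the polar-plot control: the
        defect appears identically in NAC and AC, the artifact does not)."""
        for fix in (phantom_czt, phantom_ventri):
            m0 = quantify_study(fix()).to_dict()
            m1 = quantify_study(fix(defect=True)).to_dict()
            for key, v0 in m0.items():
                if isinstance(v0, float):
                    assert m1[key] == pytest.approx(v0, abs=1e-12), key
                else:
                    assert m1[key] == v0, key

    def test_metrics_invariant_to_global_rescaling(self, czt_study):
        class Scaled:
            nac_volume = czt_study.nac_volume * 3.0
            ac_volume = czt_study.ac_volume * 0.25
            profile = czt_study.profile

        m0, m1 = quantify_study(czt_study), quantify_study(Scaled())
        assert m1.extent_fraction == m0.extent_fraction
        assert m1.localization_deg == pytest.approx(m0.localization_deg)
        assert m1.depth_fraction == pytest.approx(m0.depth_fraction, rel=1e-12)

    def test_extent_nondecreasing_in_threshold(self, czt_study):
        extents = [
            quantify_study(czt_study, threshold=t).extent_fraction
            for t in (0.5, 0.7, 0.8, 0.85, 0.95)
        ]
        assert extents == sorted(extents)


def test_round_half_up_breaks_ties_away_from_zero():
    assert round_half_up(18.75) == 19
    assert round_half_up(28.3333) == 28
    assert round_half_up(0.5) == 1
    assert round_half_up(-0.5) == -1
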