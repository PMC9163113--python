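import numpy as np
import pytest

from watermbf import (
    MisalignmentSpec,
    apply_bias,
    assign_territories,
    compute_atf,
    fit_image,
    misalignment_bias_field,
    regional_values,
    segment_myocardium,
)
from watermbf.kinetics import ParametricMaps
from watermbf.regions import SegmentationError, circumferential_territories


def _maps_from(mbf, ptf, v_a, v_rv):
    shape = mbf.shape
    zero = np.zeros(shape)
    mbft = np.where(v_a < 1, mbf * ptf / np.maximum(1 - v_a, 1e-12), 0.0)
    return ParametricMaps(
        mbf=mbf, ptf=ptf, v_a=v_a, v_rv=v_rv, mbft=mbft, rss=zero,
        fitted_mask=np.ones(shape, bool),
    )


@pytest.fixture(scope="module")
def fitted(noiseless_phantom):
    ph = noiseless_phantom
    mask = ph.wall_mask | ph.lv_voi | ph.rv_voi
    truths = [t.mbf for t in ph.spec.territory_truth.values()]
    grid = np.append(np.geomspace(0.2, 6.0, 100), truths)
    return fit_image(ph.image, ph.inputs, mask, mbf_grid=grid)


class TestComputeAtf:
    @pytest.mark.parametrize(
        "v_a,v_rv,expected", [(1.0, 0.0, 0.0), (0.2, 0.1, 0.7), (0.0, 0.0, 1.0)]
    )
    def test_arithmetic(self, v_a, v_rv, expected):
        shape = (2, 2, 2)
        maps = _maps_from(
            np.zeros(shape), np.zeros(shape), np.full(shape, v_a), np.full(shape, v_rv)
        )
        np.testing.assert_allclose(compute_atf(maps), expected)

    def test_cavity_near_zero_wall_near_tissue_fraction(self, noiseless_phantom, fitted):
        ph = noiseless_phantom
        atf = compute_atf(fitted)
        assert atf[ph.lv_voi].max() < 0.05
        wall_truth = 1 - ph.truth_maps["v_a"] - ph.truth_maps["v_rv"]
        np.testing.assert_allclose(
            atf[ph.wall_mask], wall_truth[ph.wall_mask], atol=1e-6
        )


class TestSegmentMyocardium:
    def test_zero_threshold_leaves_ptf_untouched(self, fitted):
        atf = compute_atf(fitted)
        _, censored = segment_myocardium(fitted.ptf, atf, atf_threshold=0.0)
        np.testing.assert_array_equal(censored, fitted.ptf)

    def test_recovers_phantom_wall(self, noiseless_phantom, fitted):
        ph = noiseless_phantom
        atf = compute_atf(fitted)
        mask, _ = segment_myocardium(fitted.ptf, atf)
        assert np.array_equal(mask, ph.wall_mask)

    def test_strong_lateral_bias_deletes_lateral_wall(self, noiseless_phantom):
        # severe attenuation error pushes lateral PTF below the floor, so
        # the delineated wall loses its lateral sector; without the ATF rule
        # the same mask question is decided by PTF alone
        ph = noiseless_phantom
        field = misalignment_bias_field(
            MisalignmentSpec(20, 0, 0, "X+20"), ph.geometry, epsilon_per_mm=0.035
        )
        biased = apply_bias(ph.image, field)
        maps = fit_image(biased, ph.inputs, ph.wall_mask)
        atf = compute_atf(maps)
        mask, _ = segment_myocardium(maps.ptf, atf)
        lateral = ph.labels == 3
        assert mask[lateral].sum() < lateral.sum()
        assert not np.array_equal(mask, ph.wall_mask)

    def test_atf_rule_off_recovers_more_wall(self, noiseless_phantom):
        # the ATF rule censors wall voxels whose fitted blood fraction is
        # inflated; switching it off can only grow the candidate set
        ph = noiseless_phantom
        maps = fit_image(ph.image, ph.inputs, ph.wall_mask)
        atf = compute_atf(maps)
        # threshold 0.8 censors the septal sectors (truth tissue fraction
        # 0.77) but not the lateral wall (0.83)
        with_rule, _ = segment_myocardium(maps.ptf, atf, atf_threshold=0.8)
        without, _ = segment_myocardium(
            maps.ptf, atf, atf_threshold=0.8, apply_atf_rule=False
        )
        assert with_rule.sum() < without.sum()
        assert np.array_equal(without, ph.wall_mask)

    def test_threshold_monotonicity(self, fitted):
        atf = compute_atf(fitted)
        sizes = []
        for thr in (0.0, 0.25, 0.5, 0.8):
            try:
                mask, _ = segment_myocardium(fitted.ptf, atf, atf_threshold=thr)
                sizes.append(mask.sum())
            except SegmentationError:
                sizes.append(0)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_empty_result_raises_segmentation_error(self):
        ptf = np.zeros((5, 5, 5))
        atf = np.ones((5, 5, 5))
        with pytest.raises(SegmentationError):
            segment_myocardium(ptf, atf)


class TestTerritories:
    def test_full_ring_gets_all_three_labels(self, noiseless_phantom):
        ph = noiseless_phantom
        labels = assign_territories(ph.wall_mask, ph.geometry)
        assert set(np.unique(labels[ph.wall_mask])) == {1, 2, 3}

    def test_patient_left_lateral_voxel_is_lcx(self):
        mask = np.zeros((11, 11, 11), bool)
        mask[9, 5, 5] = True   # +X of center: lateral wall
        mask[5, 9, 5] = True   # +Y: anterior -> LAD
        mask[5, 1, 5] = True   # -Y: inferior -> RCA
        labels = circumferential_territories(
            mask, center_mm=np.array([5.5, 5.5, 5.5]), voxel_size_mm=1.0
        )
        assert labels[9, 5, 5] == 3
        assert labels[5, 9, 5] == 1
        assert labels[5, 1, 5] == 2

    def test_labels_partition_mask(self, noiseless_phantom):
        ph = noiseless_phantom
        labels = assign_territories(ph.wall_mask, ph.geometry)
        assert np.all((labels > 0) == ph.wall_mask)

    def test_empty_mask_rejected(self, noiseless_phantom):
        with pytest.raises(ValueError):
            assign_territories(
                np.zeros(noiseless_phantom.wall_mask.shape, bool),
                noiseless_phantom.geometry,
            )


class TestRegionalValues:
    def test_uniform_maps_give_uniform_regions(self, noiseless_phantom):
        ph = noiseless_phantom
        shape = ph.wall_mask.shape
        maps = _maps_from(
            np.full(shape, 2.0), np.full(shape, 0.5), np.zeros(shape), np.zeros(shape)
        )
        df = regional_values(maps, ph.labels)
        np.testing.assert_allclose(df["mbf"], 2.0)

    def test_lv_is_count_weighted_mean_of_territories(self, noiseless_phantom, fitted):
        df = regional_values(fitted, noiseless_phantom.labels)
        terr = df.loc[["LAD", "RCA", "LCX"]]
        weighted = (terr["mbf"] * terr["n_voxels"]).sum() / terr["n_voxels"].sum()
        assert df.loc["LV", "mbf"] == pytest.approx(weighted, abs=1e-12)

    def test_noiseless_phantom_regional_means_equal_truth(
        self, noiseless_phantom, fitted
    ):
        ph = noiseless_phantom
        df = regional_values(fitted, ph.labels)
        for name in ("LAD", "RCA", "LCX"):
            truth = ph.spec.territory_truth[name]
            assert df.loc[name, "mbf"] == pytest.approx(truth.mbf, rel=1e-9)
            expected_mbft = truth.mbf * truth.ptf / (1 - truth.v_a)
            assert df.loc[name, "mbft"] == pytest.approx(expected_mbft, rel=1e-6)

    def test_empty_territory_named_in_error(self, noiseless_phantom, fitted):
        labels = noiseless_phantom.labels.copy()
        labels[labels == 2] = 1
        with pytest.raises(ValueError, match="RCA"):
            regional_values(fitted, labels)
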