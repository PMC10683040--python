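"""Unit and property tests of the Agatston scoring engine."""

import numpy as np
import pytest

from heartcac import agatston
from heartcac.io_volumes import CTVolume, RegionLabelMap

from _bruteforce import brute_force_report

SPACING = (3.0, 0.7, 0.7)


def make_ct(voxels, spacing=SPACING):
    return CTVolume(np.asarray(voxels, dtype=np.float32), spacing)


def make_labels(voxels, spacing=SPACING):
    return RegionLabelMap(np.asarray(voxels, dtype=np.int16), spacing)


def uniform_labels(shape, code, spacing=SPACING):
    return make_labels(np.full(shape, code), spacing)


class TestThreshold:
    def test_130_hu_is_inclusive_boundary(self):
        ct = make_ct(np.array([[[129.0, 130.0, 131.0]]]))
        assert agatston.threshold_calcium(ct).tolist() == [[[False, True, True]]]

    def test_air_volume_yields_empty_mask(self):
        ct = make_ct(np.full((3, 4, 4), -1000.0))
        assert not agatston.threshold_calcium(ct).any()


class TestCofactor:
    @pytest.mark.parametrize("hu,expected", [
        (130, 1), (150, 1), (199, 1), (199.9, 1),
        (200, 2), (299, 2), (300, 3), (399, 3),
        (400, 4), (1000, 4),
    ])
    def test_density_bands(self, hu, expected):
        assert agatston.cofactor(hu) == expected

    def test_below_threshold_is_an_error(self):
        with pytest.raises(ValueError):
            agatston.cofactor(129.0)


class TestAreaFilter:
    def test_component_below_one_mm2_is_dropped(self):
        # 3 pixels at 0.5 x 0.5 mm = 0.75 mm^2 < 1 mm^2
        mask = np.zeros((1, 5, 5), dtype=bool)
        mask[0, 2, 1:4] = True
        lesions = agatston.extract_lesions(mask, (3.0, 0.5, 0.5))
        assert lesions == []

    def test_component_at_or_above_one_mm2_is_kept(self):
        # 5 pixels at 0.5 x 0.5 mm = 1.25 mm^2
        mask = np.zeros((1, 5, 5), dtype=bool)
        mask[0, 2, 0:5] = True
        lesions = agatston.extract_lesions(mask, (3.0, 0.5, 0.5))
        assert len(lesions) == 1
        assert lesions[0].slice_components[0].area_mm2 == pytest.approx(1.25)

    def test_exactly_one_mm2_is_kept(self):
        mask = np.zeros((1, 4, 4), dtype=bool)
        mask[0, 1, 1:3] = True
        mask[0, 2, 1:3] = True  # 4 pixels x 0.25 = 1.0 mm^2
        lesions = agatston.extract_lesions(mask, (3.0, 0.5, 0.5))
        assert len(lesions) == 1


class TestConnectivity:
    def test_separated_clusters_are_distinct_lesions(self):
        mask = np.zeros((3, 10, 10), dtype=bool)
        mask[0, 0:2, 0:2] = True
        mask[2, 7:9, 7:9] = True
        assert len(agatston.extract_lesions(mask, (3.0, 1.0, 1.0))) == 2

    def test_diagonal_3d_contact_merges_lesions(self):
        mask = np.zeros((2, 4, 4), dtype=bool)
        mask[0, 0:2, 0:2] = True
        mask[1, 2, 2] = True  # touches (0,1,1) diagonally in 3D
        mask[1, 2:4, 2:4] = True
        assert len(agatston.extract_lesions(mask, (3.0, 1.0, 1.0))) == 1


class TestScoreLesion:
    def test_textbook_single_slice_score(self):
        mask = np.zeros((1, 5, 5), dtype=bool)
        mask[0, 2, 0:5] = True
        hu = np.where(mask, 320.0, 0.0)
        lesions = agatston.extract_lesions(mask, (3.0, 0.5, 0.5), ct_voxels=hu)
        score = agatston.score_lesion(lesions[0], (3.0, 0.5, 0.5))
        assert score == pytest.approx(1.25 * 3 * 1.0)

    def test_duplicated_slice_doubles_score(self):
        mask1 = np.zeros((2, 5, 5), dtype=bool)
        mask1[0, 1:3, 1:4] = True
        mask2 = mask1.copy()
        mask2[1] = mask2[0]
        hu1 = np.where(mask1, 250.0, 0.0)
        hu2 = np.where(mask2, 250.0, 0.0)
        s1 = agatston.score_lesion(
            agatston.extract_lesions(mask1, SPACING, ct_voxels=hu1)[0], SPACING)
        s2 = agatston.score_lesion(
            agatston.extract_lesions(mask2, SPACING, ct_voxels=hu2)[0], SPACING)
        assert s2 == pytest.approx(2 * s1)

    def test_thinner_slices_scale_score_with_warning(self):
        mask = np.zeros((1, 5, 5), dtype=bool)
        mask[0, 1:3, 1:4] = True
        hu = np.where(mask, 250.0, 0.0)
        thin = (1.5, 0.7, 0.7)
        ref = agatston.score_lesion(
            agatston.extract_lesions(mask, SPACING, ct_voxels=hu)[0], SPACING)
        with pytest.warns(UserWarning, match="thickness"):
            scaled = agatston.score_lesion(
                agatston.extract_lesions(mask, thin, ct_voxels=hu)[0], thin)
        assert scaled == pytest.approx(ref / 2)


class TestAssignVessel:
    def _lesion(self, coords):
        return agatston.CalciumLesion(lesion_id=1, voxels=np.asarray(coords))

    def test_unanimous_vote(self):
        labels = uniform_labels((3, 4, 4), 2)
        lesion = self._lesion([(1, 1, 1), (1, 1, 2)])
        assert agatston.assign_vessel(lesion, labels) == 2

    def test_other_region_lesion_is_noncoronary(self):
        labels = uniform_labels((3, 4, 4), 5)
        lesion = self._lesion([(0, 0, 0)])
        agatston.assign_vessel(lesion, labels)
        assert not lesion.is_coronary

    def test_even_split_breaks_toward_lm(self):
        arr = np.full((1, 2, 2), 1, dtype=np.int16)
        arr[0, 1, :] = 2
        labels = make_labels(arr)
        lesion = self._lesion([(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1)])
        assert agatston.assign_vessel(lesion, labels) == 1


class TestCategorize:
    @pytest.mark.parametrize("total,cat", [
        (0.0, 0), (0.99, 0), (1.0, 1), (10.0, 1), (10.5, 2),
        (100.0, 2), (100.5, 3), (400.0, 3), (400.5, 4), (401.0, 4), (5000.0, 4),
    ])
    def test_risk_bands(self, total, cat):
        assert agatston.categorize(total) == cat

    def test_negative_total_is_an_error(self):
        with pytest.raises(ValueError):
            agatston.categorize(-0.1)


def random_volume(rng, shape=(12, 20, 20)):
    """Sparse random calcium blobs over soft-tissue background."""
    hu = rng.normal(30.0, 20.0, size=shape)
    n_blobs = rng.integers(0, 5)
    for _ in range(n_blobs):
        z, y, x = (rng.integers(0, s) for s in shape)
        rz, ry, rx = rng.integers(1, 3, size=3)
        hu[max(0, z - rz):z + rz, max(0, y - ry):y + ry, max(0, x - rx):x + rx] = \
            rng.uniform(120.0, 900.0)
    labels = rng.integers(0, 6, size=shape).astype(np.int16)
    return hu.astype(np.float32), labels


class TestScoreScanOracle:
    def test_matches_brute_force_enumeration_on_random_volumes(self):
        """score_scan agrees with an independent per-voxel enumerator."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            hu, labels = random_volume(rng)
            ct = make_ct(hu)
            lab = make_labels(labels)
            rep = agatston.score_scan(ct, lab)
            ref = brute_force_report(hu, SPACING, labels)
            assert rep.total == pytest.approx(ref["total"], abs=1e-9)
            assert rep.excluded_noncoronary == pytest.approx(ref["excluded"], abs=1e-9)
            for code, name in agatston.VESSEL_NAMES.items():
                assert rep.per_vessel[name] == pytest.approx(ref["per_vessel"][code], abs=1e-9)
            assert rep.risk_category == ref["category"]

    def test_hand_computed_three_lesion_scan(self):
        """One fully hand-computed case, independent of both code paths."""
        hu = np.zeros((4, 10, 10), dtype=np.float32)
        labels = np.full((4, 10, 10), 5, dtype=np.int16)
        # lesion A: LAD, one slice, 4 pixels (1.96 mm^2), peak 350 -> cof 3
        hu[1, 2:4, 2:4] = 350.0
        labels[:, 0:5, 0:5] = 2
        # lesion B: RCA, two slices, 3 pixels each (1.47 mm^2), peak 210 -> cof 2
        hu[2, 7, 6:9] = 210.0
        hu[3, 7, 6:9] = 210.0
        labels[:, 5:, 5:] = 4
        # lesion C: aortic (other region), would score but must be excluded
        hu[0, 7, 0:3] = 600.0
        a = 4 * 0.49 * 3
        b = 2 * (3 * 0.49) * 2
        rep = agatston.score_scan(make_ct(hu), make_labels(labels))
        assert rep.per_vessel["LAD"] == pytest.approx(a, abs=1e-9)
        assert rep.per_vessel["RCA"] == pytest.approx(b, abs=1e-9)
        assert rep.total == pytest.approx(a + b, abs=1e-9)
        assert rep.excluded_noncoronary == pytest.approx(3 * 0.49 * 4 * 1, abs=1e-9)
        assert rep.risk_category == agatston.categorize(a + b)


class TestScoreProperties:
    def test_additivity_of_disjoint_lesions(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            hu1 = np.zeros((6, 12, 12), dtype=np.float32)
            hu2 = np.zeros((6, 12, 12), dtype=np.float32)
            hu1[1:3, 2:5, 2:5] = rng.uniform(150, 800)
            hu2[4:6, 8:11, 8:11] = rng.uniform(150, 800)
            labels = uniform_labels((6, 12, 12), 3)
            s1 = agatston.score_scan(make_ct(hu1), labels).total
            s2 = agatston.score_scan(make_ct(hu2), labels).total
            s12 = agatston.score_scan(make_ct(np.maximum(hu1, hu2)), labels).total
            assert s12 == pytest.approx(s1 + s2, abs=1e-9)

    def test_raising_density_never_lowers_score(self):
        labels = uniform_labels((3, 8, 8), 2)
        base = np.zeros((3, 8, 8), dtype=np.float32)
        base[1, 2:5, 2:5] = 199.0
        prev = 0.0
        for hu in (199.0, 200.0, 299.0, 300.0, 399.0, 400.0, 900.0):
            vol = base.copy()
            vol[vol > 0] = hu
            score = agatston.score_scan(make_ct(vol), labels).total
            assert score >= prev
            prev = score

    def test_slice_order_reversal_preserves_total(self, demo_scan):
        ct = demo_scan.ct
        labels = demo_scan.territories
        fwd = agatston.score_scan(ct, labels)
        rev = agatston.score_scan(
            make_ct(ct.voxels[::-1].copy(), ct.spacing),
            make_labels(labels.voxels[::-1].copy(), labels.spacing))
        assert rev.total == pytest.approx(fwd.total, abs=1e-9)
        assert rev.per_vessel == pytest.approx(fwd.per_vessel, abs=1e-9)
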