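import dataclasses

import numpy as np
import pytest

from muroct.io import AxialScale, VolumeMeta
from muroct.phantom import CorruptionSpec, corrupt, generate_phantom
from muroct.segmentation import BoundarySet, boundaries_from_classmap, oracle_classmap
from muroct.thickness import (
    BLOCK_IDS,
    QCParams,
    ThicknessMap,
    apply_qc,
    compute_thickness,
    crop_and_block,
    mirror_if_left,
    qc_ascan,
)

SCALE = AxialScale()  # 1.4 mm / 1024 samples


def _uniform_boundaries(h, w, sep, b0=100.0):
    b = b0 + sep * np.arange(9.0).reshape(9, 1, 1)
    return BoundarySet(np.tile(b, (1, h, w)), np.ones((h, w), bool))


class TestComputeThickness:
    def test_uniform_ten_sample_separation(self):
        tm = compute_thickness(_uniform_boundaries(4, 5, 10.0), SCALE)
        np.testing.assert_allclose(tm.values[:8], 13.672, atol=5e-4)

    def test_trt_from_146p36_samples(self):
        b = np.zeros((9, 1, 1))
        b[:] = np.linspace(100.0, 100.0 + 146.36, 9).reshape(9, 1, 1)
        tm = compute_thickness(BoundarySet(b, np.ones((1, 1), bool)), SCALE)
        assert tm.values[8, 0, 0] == pytest.approx(200.1, abs=0.05)

    def test_trt_equals_layer_sum(self, clean_phantom):
        vol, truth = clean_phantom
        bs = boundaries_from_classmap(oracle_classmap(truth, 256))
        tm = compute_thickness(bs, vol.scale)
        np.testing.assert_allclose(
            tm.values[:8].sum(axis=0), tm.values[8], rtol=1e-12
        )

    def test_crossing_boundaries_marked_invalid_never_negative(self):
        b = 100.0 + 10.0 * np.arange(9.0).reshape(9, 1, 1) * np.ones((9, 2, 2))
        b[3, 0, 0], b[4, 0, 0] = b[4, 0, 0], b[3, 0, 0]  # crossing
        bs = BoundarySet.__new__(BoundarySet)  # bypass validation: raw input
        bs.boundaries = b
        bs.valid = np.ones((2, 2), bool)
        tm = compute_thickness(bs, SCALE)
        assert not tm.valid[0, 0]
        assert tm.valid[1, 1]
        assert np.isnan(tm.values[:, 0, 0]).all()
        assert np.nanmin(tm.values) >= 0


class TestQC:
    def test_clean_phantom_zero_failures(self, clean_phantom):
        vol, truth = clean_phantom
        bs = boundaries_from_classmap(oracle_classmap(truth, 256))
        tm = compute_thickness(bs, vol.scale)
        rep = qc_ascan(vol, bs, tm)
        assert rep.ascan_pass.all()

    def test_corrupted_ascan_fails_contrast_for_any_positive_threshold(
        self, clean_phantom
    ):
        vol, truth = clean_phantom
        cvol, coords = corrupt(vol, CorruptionSpec(0.02, "low-contrast"), seed=5)
        bs = boundaries_from_classmap(oracle_classmap(truth, 256))
        tm = compute_thickness(bs, cvol.scale)
        rep = qc_ascan(cvol, bs, tm, QCParams(min_contrast=1e-6))
        assert not rep.contrast_pass[coords[:, 0], coords[:, 1]].any()

    def test_displaced_boundary_fails_consistency_only_there(self, clean_phantom):
        vol, truth = clean_phantom
        bs = boundaries_from_classmap(oracle_classmap(truth, 256))
        params = QCParams()
        b = bs.boundaries.copy()
        b[4, 10, 20] += params.max_jump + 1  # J+1 displacement
        b[5:, 10, 20] += params.max_jump + 1  # keep monotone
        bs2 = BoundarySet(b, bs.valid)
        tm = compute_thickness(bs2, vol.scale)
        rep = qc_ascan(vol, bs2, tm, params)
        fail = ~rep.consistency_pass
        assert fail[10, 20]
        fail[10, 20] = False
        assert not fail.any()

    def test_thickness_outlier_fails_distribution(self, clean_phantom):
        vol, truth = clean_phantom
        bs = boundaries_from_classmap(oracle_classmap(truth, 256))
        b = bs.boundaries.copy()
        b[2:, 3, 7] += 8  # inflate the IPL by 8 samples (~44 um) there
        bs2 = BoundarySet(b, bs.valid)
        tm = compute_thickness(bs2, vol.scale)
        rep = qc_ascan(vol, bs2, tm, QCParams(max_jump=100))  # isolate criterion 3
        assert not rep.distribution_pass[3, 7]
        assert rep.distribution_pass.sum() == rep.distribution_pass.size - 1

    def test_tightening_thresholds_never_retains_more(self, speckled_phantom):
        vol, truth = speckled_phantom
        bs = boundaries_from_classmap(oracle_classmap(truth, 256))
        tm = compute_thickness(bs, vol.scale)
        loose = qc_ascan(vol, bs, tm, QCParams(min_contrast=0.05))
        tight = qc_ascan(vol, bs, tm, QCParams(min_contrast=0.10))
        assert tight.ascan_pass.sum() <= loose.ascan_pass.sum()
        loose_z = qc_ascan(vol, bs, tm, QCParams(z_cap=4.0))
        tight_z = qc_ascan(vol, bs, tm, QCParams(z_cap=2.0))
        assert tight_z.ascan_pass.sum() <= loose_z.ascan_pass.sum()

    def test_invalid_everything_is_an_error(self, clean_phantom):
        vol, truth = clean_phantom
        bs = boundaries_from_classmap(oracle_classmap(truth, 256))
        tm = compute_thickness(bs, vol.scale)
        empty = ThicknessMap(tm.values, np.zeros_like(tm.valid), tm.meta)
        with pytest.raises(ValueError):
            qc_ascan(vol, bs, empty)


class TestMirror:
    def _map(self, eye, h=8, w=10):
        rng = np.random.default_rng(1)
        vals = rng.uniform(10, 30, size=(9, h, w))
        vals[8] = vals[:8].sum(axis=0)
        valid = rng.random((h, w)) > 0.1
        return ThicknessMap(vals, valid, VolumeMeta(eye=eye))

    def test_od_is_identity(self):
        tm = self._map("OD")
        out = mirror_if_left(tm)
        np.testing.assert_array_equal(out.valid, tm.valid)
        np.testing.assert_array_equal(
            np.nan_to_num(out.values), np.nan_to_num(tm.values)
        )

    def test_os_mirror_twice_is_identity(self):
        tm = self._map("OS")
        twice = mirror_if_left(mirror_if_left(tm))
        np.testing.assert_array_equal(twice.valid, tm.valid)
        np.testing.assert_array_equal(
            np.nan_to_num(twice.values), np.nan_to_num(tm.values)
        )

    def test_os_mirrors_columns(self):
        tm = self._map("OS")
        out = mirror_if_left(tm)
        np.testing.assert_array_equal(out.valid, tm.valid[:, ::-1])

    def test_mirrored_os_matches_od_of_same_geometry(self, clean_spec):
        # same animal, both eyes: after mirroring, block means must agree
        from muroct.io import VolumeMeta as VM

        _, t_od = generate_phantom(clean_spec, VM(eye="OD", age_months=1, group="WT"),
                                   1, shape=(32, 128, 256), render=False)
        _, t_os = generate_phantom(clean_spec, VM(eye="OS", age_months=1, group="WT"),
                                   1, shape=(32, 128, 256), render=False)
        valid = np.ones((32, 128), bool)
        lt_od = np.concatenate([t_od.layer_thickness_um, t_od.trt_um[None]])
        lt_os = np.concatenate([t_os.layer_thickness_um, t_os.trt_um[None]])
        m_od = ThicknessMap(lt_od, valid, VM(eye="OD"))
        m_os = mirror_if_left(ThicknessMap(lt_os, valid, VM(eye="OS")))
        b_od, _ = crop_and_block(m_od)
        b_os, _ = crop_and_block(m_os)
        for a, b in zip(b_od, b_os):
            np.testing.assert_allclose(a.mean_um, b.mean_um, rtol=1e-12)

    def test_missing_eye_metadata_is_error(self):
        tm = self._map("OD")
        tm.meta = dataclasses.replace(tm.meta)
        tm.meta.eye = "??"
        with pytest.raises(ValueError):
            mirror_if_left(tm)


class TestCropAndBlock:
    def _const_map(self, value=20.0, h=512, w=512):
        vals = np.full((9, h, w), value)
        vals[8] = 8 * value
        return ThicknessMap(vals, np.ones((h, w), bool), VolumeMeta())

    def test_constant_map_all_blocks_equal_constant(self):
        blocks, whole = crop_and_block(self._const_map(20.0, 128, 128))
        assert [b.block_id for b in blocks] == list(BLOCK_IDS)
        for b in blocks:
            assert b.retained and b.n == 42 * 42
            np.testing.assert_allclose(b.mean_um[:8], 20.0)
            np.testing.assert_allclose(b.sd_um, 0.0)
        assert whole.block_id == "whole" and whole.n == 126 * 126

    def test_block_means_match_loop_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(5, 60, size=(9, 512, 512))
        valid = rng.random((512, 512)) > 0.05
        tm = ThicknessMap(vals, valid, VolumeMeta())
        blocks, whole = crop_and_block(tm)
        # independent loop-based oracle over explicit index ranges
        for bi, b in enumerate(blocks):
            i, j = divmod(bi, 3)
            acc, cnt = np.zeros(9), 0
            for r in range(1 + 170 * i, 1 + 170 * (i + 1)):
                for c in range(1 + 170 * j, 1 + 170 * (j + 1)):
                    if valid[r, c]:
                        acc += vals[:, r, c]
                        cnt += 1
            np.testing.assert_allclose(b.mean_um, acc / cnt, rtol=1e-10)
            assert b.n == cnt

    def test_exclusion_boundary_is_strict_ten_percent(self):
        # 2890 of 28900 excluded (exactly 10.0%) -> retained; 2891 -> excluded
        for n_bad, retained in ((2890, True), (2891, False)):
            valid = np.ones((512, 512), bool)
            bad = np.zeros(170 * 170, bool)
            bad[:n_bad] = True
            valid[1:171, 1:171] = ~bad.reshape(170, 170)  # block B1
            tm = ThicknessMap(np.full((9, 512, 512), 10.0), valid, VolumeMeta())
            blocks, _ = crop_and_block(tm)
            assert blocks[0].retained is retained
            assert all(b.retained for b in blocks[1:])
            if not retained:
                assert np.isnan(blocks[0].mean_um).all() and blocks[0].n == 0

    def test_indivisible_grid_is_error(self):
        with pytest.raises(ValueError, match="3x3"):
            crop_and_block(self._const_map(10.0, 64, 128))

    def test_whole_area_uses_all_retained_ascans_even_from_dropped_blocks(self):
        valid = np.ones((128, 128), bool)
        valid[1:43, 1:43] = False  # B1 fully excluded
        vals = np.full((9, 128, 128), 7.0)
        blocks, whole = crop_and_block(ThicknessMap(vals, valid, VolumeMeta()))
        assert not blocks[0].retained
        assert whole.n == 126 * 126 - 42 * 42
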