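"""Threshold segmentation: control statistics, the two-sequence labeling
rule, the perilesional shell lattice oracle, and labelmap composition."""

import numpy as np
import pytest

from perioperf.config import Compartment
from perioperf.io import load_nifti, save_nifti
from perioperf.segmentation import (compose_labelmap, control_stats,
                                    perilesional_shell, segment_lesion)


def stats_of(mean, sd, shape=(9, 9, 9)):
    """ControlStats carrying prescribed values (mask is a corner block)."""
    from perioperf.segmentation import ControlStats
    mask = np.zeros(shape, bool)
    mask[:2, :2, :2] = True
    return ControlStats(mean=mean, sd=sd, n=int(mask.sum()), mask=mask)


class TestControlStats:
    def test_constant_volume(self):
        vol = np.full((4, 4, 4), 7.0)
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        st = control_stats(vol, mask)
        assert st.mean == 7.0 and st.sd == 0.0

    def test_two_voxel_sample_sd(self):
        vol = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        vol[0, 0, 0], vol[0, 0, 1] = 4.0, 6.0
        mask[0, 0, 0] = mask[0, 0, 1] = True
        st = control_stats(vol, mask)
        assert st.mean == 5.0
        assert st.sd == pytest.approx(np.sqrt(2.0), rel=1e-12)  # ddof=1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            control_stats(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool))

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            control_stats(np.ones((3, 3, 3)), np.zeros((4, 4, 4), bool))


class TestSegmentLesion:
    def make_volumes(self):
        t1c = np.full((9, 9, 9), 10.0)
        t2w = np.full((9, 9, 9), 100.0)
        return t1c, t2w

    def test_above_both_thresholds_is_t1c(self):
        t1c, t2w = self.make_volumes()
        t1c[4, 4, 4] = 50.0
        t2w[4, 4, 4] = 300.0
        masks = segment_lesion(t1c, t2w, stats_of(10, 1), stats_of(100, 5),
                               k=2.0, min_component_voxels=1)
        assert masks["T1C+"][4, 4, 4] and not masks["T2W+"][4, 4, 4]

    def test_above_t2w_only_is_t2w(self):
        t1c, t2w = self.make_volumes()
        t2w[4, 4, 4] = 300.0
        masks = segment_lesion(t1c, t2w, stats_of(10, 1), stats_of(100, 5),
                               k=2.0, min_component_voxels=1)
        assert masks["T2W+"][4, 4, 4] and not masks["T1C+"][4, 4, 4]

    def test_enhancing_without_edema_not_lesion(self):
        # bright on T1C alone does not qualify (rule needs T2W hyperintensity)
        t1c, t2w = self.make_volumes()
        t1c[4, 4, 4] = 50.0
        masks = segment_lesion(t1c, t2w, stats_of(10, 1), stats_of(100, 5),
                               k=2.0, min_component_voxels=1)
        assert not masks["T1C+"][4, 4, 4] and not masks["T2W+"][4, 4, 4]

    def test_monotone_in_k(self):
        rng = np.random.default_rng(0)
        t1c = rng.normal(10, 3, (9, 9, 9))
        t2w = rng.normal(100, 10, (9, 9, 9))
        sizes = []
        for k in (0.5, 1.0, 2.0, 3.0):
            m = segment_lesion(t1c, t2w, stats_of(10, 3), stats_of(100, 10),
                               k=k, min_component_voxels=1)
            sizes.append(m["T1C+"].sum() + m["T2W+"].sum())
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_negative_k_rejected(self):
        t1c, t2w = self.make_volumes()
        with pytest.raises(ValueError):
            segment_lesion(t1c, t2w, stats_of(10, 1), stats_of(100, 5), k=-1)

    def test_small_components_removed(self):
        t1c, t2w = self.make_volumes()
        t2w[4, 4, 4] = 300.0            # isolated voxel
        t2w[0:2, 0:3, 0:2] = 300.0      # 12-voxel block survives
        masks = segment_lesion(t1c, t2w, stats_of(10, 1), stats_of(100, 5),
                               k=2.0, min_component_voxels=5)
        assert not masks["T2W+"][4, 4, 4]
        assert masks["T2W+"][0, 0, 0]


class TestPerilesionalShell:
    def test_single_voxel_lattice_oracle(self):
        """One lesion voxel, 0.9-mm spacing, 2-mm radius: the shell is
        exactly the 32 lattice offsets with 0.81*(i^2+j^2+k^2) <= 4."""
        shape = (11, 11, 11)
        lesion = np.zeros(shape, bool)
        lesion[5, 5, 5] = True
        t1c = np.full(shape, 10.0)
        t2w = np.full(shape, 100.0)
        shell = perilesional_shell({"T1C+": lesion}, (0.9, 0.9, 0.9), 2.0,
                                   t1c, t2w, stats_of(10, 1, shape),
                                   stats_of(100, 5, shape), k=2.0)
        # independent lattice enumeration
        count = sum(
            1
            for i in range(-3, 4) for j in range(-3, 4) for k in range(-3, 4)
            if (i, j, k) != (0, 0, 0) and 0.81 * (i*i + j*j + k*k) <= 4.0
        )
        assert count == 32
        assert int(shell.sum()) == count
        assert not shell[5, 5, 5]

    def test_tiny_radius_empty_shell(self):
        shape = (7, 7, 7)
        lesion = np.zeros(shape, bool)
        lesion[3, 3, 3] = True
        shell = perilesional_shell({"T1C+": lesion}, (0.9, 0.9, 0.9), 0.1,
                                   np.full(shape, 10.0), np.full(shape, 100.0),
                                   stats_of(10, 1, shape),
                                   stats_of(100, 5, shape))
        assert not shell.any()

    def test_abnormal_intensity_excluded(self):
        shape = (9, 9, 9)
        lesion = np.zeros(shape, bool)
        lesion[4, 4, 4] = True
        t1c = np.full(shape, 10.0)
        t2w = np.full(shape, 100.0)
        t2w[4, 4, 5] = 300.0  # hyperintense shell candidate
        shell = perilesional_shell({"T1C+": lesion}, (0.9, 0.9, 0.9), 2.0,
                                   t1c, t2w, stats_of(10, 1, shape),
                                   stats_of(100, 5, shape))
        assert not shell[4, 4, 5]
        assert shell[4, 4, 3]

    def test_empty_lesion_gives_empty_shell(self):
        shape = (7, 7, 7)
        shell = perilesional_shell({"T1C+": np.zeros(shape, bool)},
                                   (0.9, 0.9, 0.9), 2.0,
                                   np.full(shape, 10.0), np.full(shape, 100.0),
                                   stats_of(10, 1, shape),
                                   stats_of(100, 5, shape))
        assert not shell.any()


class TestComposeLabelmap:
    def test_precedence_t1c_over_pl(self):
        shape = (5, 5, 5)
        t1c = np.zeros(shape, bool)
        t1c[2, 2, 2] = True
        pl = t1c.copy()  # candidate overlaps
        ctrl = np.zeros(shape, bool)
        ctrl[0, 0, 0] = True
        lm = compose_labelmap({"T1C+": t1c, "PL": pl}, ctrl)
        assert lm.labels[2, 2, 2] == Compartment.T1C
        assert lm.labels[0, 0, 0] == Compartment.CONTROL

    def test_control_overlap_rejected(self):
        shape = (5, 5, 5)
        t1c = np.zeros(shape, bool)
        t1c[2, 2, 2] = True
        with pytest.raises(ValueError):
            compose_labelmap({"T1C+": t1c}, t1c)

    def test_nifti_round_trip_preserves_codes(self, tmp_path):
        shape = (6, 6, 6)
        masks = {"T1C+": np.zeros(shape, bool), "T2W+": np.zeros(shape, bool)}
        masks["T1C+"][1, 1, 1] = True
        masks["T2W+"][2, 2, 2] = True
        ctrl = np.zeros(shape, bool)
        ctrl[4, 4, 4] = True
        lm = compose_labelmap(masks, ctrl)
        p = save_nifti(lm.labels, tmp_path / "labels.nii.gz", (0.9, 0.9, 0.9))
        back, spacing = load_nifti(p)
        np.testing.assert_array_equal(back, lm.labels)
        assert spacing == pytest.approx((0.9, 0.9, 0.9))


def test_noiseless_phantom_dice_one(acq, noiseless_subject):
    """On a noiseless phantom every recovered compartment equals ground
    truth exactly (Dice 1.0)."""
    design, truth, ds = noiseless_subject
    ctrl = truth.labels == Compartment.CONTROL
    st1c = control_stats(ds["t1c"], ctrl)
    st2w = control_stats(ds["t2w"], ctrl)
    lesions = segment_lesion(ds["t1c"], ds["t2w"], st1c, st2w, k=2.0)
    for name in lesions:
        lesions[name] &= ~ctrl
    pl = perilesional_shell(lesions, design.spacing, design.shell_radius_mm,
                            ds["t1c"], ds["t2w"], st1c, st2w, k=2.0)
    for mask, code in ((lesions["T1C+"], Compartment.T1C),
                       (lesions["T2W+"], Compartment.T2W),
                       (pl, Compartment.PL)):
        ref = truth.labels == code
        dice = 2 * np.sum(mask & ref) / (mask.sum() + ref.sum())
        assert dice == 1.0, f"Dice for code {code} is {dice}"
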