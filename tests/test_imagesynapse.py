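"""Segmentation-input preparation, cell typing, doublet extraction and
interface relocalization scoring."""

import numpy as np
import pytest
from scipy import ndimage

import heteroclust as hc
from heteroclust.imagesynapse import (
    builtin_segmenter,
    classify_cells_kmeans,
    contract_labels,
    extract_doublets,
    interface_relocalization,
    membrane_masks,
    prepare_inputs,
    segment_and_contract,
    variance_filter,
)
from heteroclust.synthdata import MultiChannelImage, _disk_mask


def _image_from(channels, px=0.5):
    return MultiChannelImage(channels=channels, pixel_size_um=px)


class TestPrepareInputs:
    def test_constant_brightfield_gives_zero_variance(self):
        assert variance_filter(np.full((9, 9), 7.0)).max() == 0.0

    def test_single_bright_pixel_hand_variance(self):
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        # 5x5 window at the centre: one value 10 among 25 zeros
        mean = 10.0 / 25
        expect = (24 * mean**2 + (10 - mean) ** 2) / 25
        assert variance_filter(img, radius=2)[2, 2] == pytest.approx(expect)

    def test_normalization_to_unit_interval(self, synapse_images):
        imgs, _ = synapse_images
        out = prepare_inputs(imgs[0], mode="invitro")
        assert out["nuclear"].min() == 0.0 and out["nuclear"].max() == 1.0

    def test_patient_mode_single_channel(self, synapse_images):
        imgs, _ = synapse_images
        out = prepare_inputs(imgs[0], mode="patient")
        assert set(out) == {"combined"}
        assert 0.0 <= out["combined"].min() and out["combined"].max() == 1.0

    def test_missing_channel_raises(self):
        img = _image_from({"brightfield": np.zeros((32, 32))})
        with pytest.raises(KeyError):
            prepare_inputs(img, mode="invitro")


class TestSegmentation:
    def test_single_disk_contracts_to_smaller_disk(self):
        shape = (48, 48)
        mask = _disk_mask(shape, 24, 24, 10)
        chan = np.where(mask, 1.0, 0.0)
        labels = segment_and_contract({"c": chan})
        assert labels.max() == 1
        area = (labels == 1).sum()
        assert np.pi * 7**2 < area < np.pi * 9**2  # ~radius 8 after 2-px erosion

    def test_tiny_label_vanishes_under_contraction(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[10:12, 10:12] = 1  # radius <= 2
        assert contract_labels(labels, 2).max() == 0

    def test_two_touching_disks_split(self):
        hits = 0
        imgs, _ = hc.gen_synapse_images(20, 0, 0.5, seed=21)
        for img in imgs:
            labels = segment_and_contract(prepare_inputs(img))
            hits += len(np.unique(labels)) - 1 == 2
        assert hits >= 19  # >= 95%

    def test_empty_segmentation_warns(self):
        with pytest.warns(UserWarning):
            labels = segment_and_contract({"c": np.zeros((16, 16))})
        assert labels.max() == 0


class TestCellTyping:
    MARKERS = {"T": "t_marker", "Tumour": "tumour_marker"}

    def test_planted_types_recovered(self, synapse_images):
        imgs, truth = synapse_images
        correct = total = 0
        for img, lab in zip(imgs, truth.label_masks):
            if (lab == 2).sum() == 0:
                continue
            cells = classify_cells_kmeans(lab, img, self.MARKERS, seed=0)
            for c in cells:
                want = "T" if c.label == 1 else "Tumour"
                correct += c.cell_type == want
                total += 1
        assert correct == total

    def test_k1_assigns_argmax_marker_type(self, synapse_images):
        imgs, truth = synapse_images
        lab = truth.label_masks[0]
        cells = classify_cells_kmeans(lab, imgs[0], self.MARKERS, k=1, seed=0)
        # both cells forced into one cluster; T marker dominates on average
        assert len({c.cell_type for c in cells}) == 1

    def test_fewer_cells_than_k_raises(self, synapse_images):
        imgs, truth = synapse_images
        single = (truth.label_masks[0] == 1).astype(np.int32)
        with pytest.raises(ValueError):
            classify_cells_kmeans(single, imgs[0], self.MARKERS, k=2, seed=0)


class TestDoubletExtraction:
    def _cells(self, labels, image, types):
        cells = classify_cells_kmeans(labels, image, TestCellTyping.MARKERS,
                                      k=min(2, labels.max()), seed=0)
        for c, t in zip(sorted(cells, key=lambda c: c.label), types):
            c.cell_type = t
        return cells

    def test_non_touching_pair_is_not_a_doublet(self, synapse_images):
        imgs, _ = synapse_images
        labels = np.zeros((96, 96), dtype=np.int32)
        labels[10:20, 10:20] = 1
        labels[60:70, 60:70] = 2
        cells = self._cells(labels, imgs[0], ["T", "Tumour"])
        assert extract_doublets(labels, cells) == []

    def test_triplet_chain_excluded(self, synapse_images):
        imgs, _ = synapse_images
        labels = np.zeros((96, 96), dtype=np.int32)
        labels[40:50, 10:30] = 1
        labels[40:50, 31:50] = 2
        labels[40:50, 51:70] = 3
        cells = classify_cells_kmeans(labels, imgs[0], TestCellTyping.MARKERS,
                                      k=2, seed=0)
        for c, t in zip(sorted(cells, key=lambda c: c.label), ["T", "Tumour", "T"]):
            c.cell_type = t
        assert extract_doublets(labels, cells) == []

    def test_same_type_pair_excluded(self, synapse_images):
        imgs, _ = synapse_images
        labels = np.zeros((96, 96), dtype=np.int32)
        labels[40:50, 10:30] = 1
        labels[40:50, 31:50] = 2
        cells = self._cells(labels, imgs[0], ["T", "T"])
        assert extract_doublets(labels, cells) == []

    def test_planted_pair_yields_one_doublet(self, synapse_images):
        imgs, truth = synapse_images
        lab = truth.label_masks[0]
        cells = self._cells(lab, imgs[0], ["T", "Tumour"])
        doublets = extract_doublets(lab, cells)
        assert len(doublets) == 1 and set(doublets[0].types) == {"T", "Tumour"}


class TestMembraneInvariants:
    def test_partition_of_label(self, synapse_images):
        _, truth = synapse_images
        lab = contract_labels(truth.label_masks[0], 2)
        interface, noninterface = membrane_masks(lab, 1, 2)
        mask = lab == 1
        membrane = interface | noninterface
        interior = mask & ~membrane
        assert not (interface & noninterface).any()
        assert ((membrane | interior) == mask).all()


class TestRelocalization:
    def test_uniform_marker_nonsignificant(self):
        imgs, _ = hc.gen_synapse_images(15, 0, 0.0, seed=31)
        res = hc.analyze_synapse_cohort(imgs)
        assert 0.8 < res["mean_ratio"] < 1.25

    def test_full_strength_noninterface_near_background(self):
        imgs, _ = hc.gen_synapse_images(15, 0, 1.0, seed=32)
        res = hc.analyze_synapse_cohort(imgs)
        # background level is ~2; the non-interface membrane keeps only blur spill
        assert res["mean_noninterface"] < 0.15 * res["mean_interface"]
        assert res["p"] < 0.01

    def test_additive_background_shifts_cancel_in_difference(self):
        imgs, _ = hc.gen_synapse_images(6, 0, 0.5, seed=33)
        res1 = hc.analyze_synapse_cohort(imgs)
        for img in imgs:
            img.channels["synapse_marker"] = img.channels["synapse_marker"] + 50.0
        res2 = hc.analyze_synapse_cohort(imgs)
        d1 = res1["mean_interface"] - res1["mean_noninterface"]
        d2 = res2["mean_interface"] - res2["mean_noninterface"]
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_empty_doublet_list_raises(self):
        with pytest.raises(ValueError):
            interface_relocalization([], [], [], "synapse_marker")
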