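"""Segmentation: background estimation, both detection algorithms, chaining."""

import numpy as np
import pytest

from synquant import segmentation as seg
from synquant import synthetic as syn

from conftest import match_detections


def _gaussian_blob(image, r0, c0, amp, sigma=2.0):
    h, w = image.shape
    rr, cc = np.mgrid[:h, :w]
    image += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma ** 2))
    return image


def _disk_roi(r0, c0, radius, shape):
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    px = np.argwhere((rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2)
    return seg.SynapseROI(pixels=px, centroid=(r0, c0), area=len(px),
                          roundness=1.0, equivalent_radius=radius)


class TestEstimateBackground:
    def test_constant_image(self):
        image = np.full((64, 64), 5.0)
        roi = _disk_roi(32, 32, 3, image.shape)
        bg = seg.estimate_background(image, roi)
        assert bg.mean == pytest.approx(5.0)
        assert bg.sd == pytest.approx(0.0)

    def test_annulus_overlapped_by_neighbor_errors(self):
        image = np.zeros((64, 64))
        roi = _disk_roi(32, 32, 3, image.shape)
        blocker = _disk_roi(32, 32, 15, image.shape)   # swallows the annulus
        with pytest.raises(seg.BackgroundUnavailableError):
            seg.estimate_background(image, roi, exclusion=[blocker.pixels])

    def test_flat_background_recovered_on_synthetic_fov(self):
        fov = syn.generate_fov(syn.SimParams(n_axons=3, boutons_per_axon=5),
                               (128, 128), seed=5, bg_level=10.0, noise_sd=0.0)
        rois = seg.segment_voronoi(fov.gz_image)
        assert rois
        all_px = [r.pixels for r in rois]
        for roi in rois:
            bg = seg.estimate_background(fov.gz_image, roi, exclusion=all_px)
            # annulus sits on flat background 10 plus faint PSF tails
            assert bg.mean == pytest.approx(10.0, abs=1.5)

    def test_offset_invariance(self):
        rng = np.random.default_rng(3)
        image = rng.normal(20, 2, (64, 64))
        roi = _disk_roi(30, 30, 3, image.shape)
        a = seg.estimate_background(image, roi)
        b = seg.estimate_background(image + 7.5, roi)
        assert b.mean == pytest.approx(a.mean + 7.5)
        assert b.sd == pytest.approx(a.sd)


class TestSegmentVoronoi:
    def test_blank_noise_image_empty(self):
        image = np.random.default_rng(1).normal(100, 10, (128, 128))
        assert seg.segment_voronoi(image) == []

    def test_two_separated_blobs(self):
        image = np.full((96, 96), 10.0)
        _gaussian_blob(image, 30, 30, 80)
        _gaussian_blob(image, 70, 65, 80)
        image += np.random.default_rng(2).normal(0, 1, image.shape)
        rois = seg.segment_voronoi(image)
        assert len(rois) == 2
        centers = sorted((r.centroid for r in rois))
        assert centers[0] == pytest.approx((30, 30), abs=1.0)
        assert centers[1] == pytest.approx((70, 65), abs=1.0)

    def test_merged_blobs_split_by_tessellation(self):
        # two peaks 7 px apart form one foreground component with two maxima
        image = np.full((64, 64), 10.0)
        _gaussian_blob(image, 32, 28, 80)
        _gaussian_blob(image, 32, 35, 80)
        rois = seg.segment_voronoi(image)
        assert len(rois) == 2

    def test_single_seed_reduces_to_component_labeling(self):
        # one blob: the tessellation must return exactly the thresholded
        # connected component
        image = np.full((64, 64), 10.0)
        _gaussian_blob(image, 32, 32, 80)
        rois = seg.segment_voronoi(image)
        assert len(rois) == 1
        from scipy import ndimage

        smoothed = ndimage.gaussian_filter(image, 1.0)
        bg = seg.sigma_clipped_background(smoothed)
        thr = bg.mean + max(2 * bg.sd, 0.05 * (smoothed.max() - bg.mean))
        mask = smoothed > thr
        assert rois[0].area == int(mask.sum())

    def test_rois_disjoint_and_above_threshold(self, noisy_fov):
        rois = seg.segment_voronoi(noisy_fov.gz_image)
        seen = set()
        for r in rois:
            for p in map(tuple, r.pixels):
                assert p not in seen
                seen.add(p)

    def test_recall_precision_snr5(self):
        tp = fp = n_true = 0
        for s in range(4):
            fov = syn.generate_fov(syn.SimParams(), (256, 256), seed=s,
                                   noise_sd=20.0)   # SNR 5
            rois = seg.segment_voronoi(fov.gz_image)
            det = np.array([r.centroid for r in rois]).reshape(-1, 2)
            t, f = match_detections(fov.bouton_centers, det)
            tp, fp, n_true = tp + t, fp + f, n_true + len(fov.bouton_centers)
        assert tp / n_true >= 0.9
        assert tp / (tp + fp) >= 0.9

    def test_noiseless_centroid_within_one_pixel(self, noiseless_fov):
        rois = seg.segment_voronoi(noiseless_fov.gz_image)
        det = np.array([r.centroid for r in rois])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(det).query(noiseless_fov.bouton_centers)
        assert len(det) == len(noiseless_fov.bouton_centers)
        assert d.max() <= 1.0


class TestSegmentContrast:
    def test_blank_image_empty(self):
        image = np.random.default_rng(4).normal(50, 5, (128, 128))
        assert seg.segment_contrast(image) == []

    def test_radius_filter_excludes(self):
        image = np.full((96, 96), 10.0)
        _gaussian_blob(image, 48, 48, 200, sigma=9.0)   # big blob, radius > 8
        rois = seg.segment_contrast(image, radius_range=(1.0, 8.0))
        assert rois == []

    def test_recall_on_gradient_background_snr5(self):
        tp = fp = n_true = 0
        for s in range(4):
            p = syn.SimParams(gradient_slope=0.05)
            fov = syn.generate_fov(p, (256, 256), seed=s, noise_sd=20.0,
                                   sb_bg_level=30.0)
            rois = seg.segment_contrast(fov.gz_image)
            det = np.array([r.centroid for r in rois]).reshape(-1, 2)
            t, f = match_detections(fov.bouton_centers, det)
            tp, fp, n_true = tp + t, fp + f, n_true + len(fov.bouton_centers)
        assert tp / n_true >= 0.9
        assert tp / (tp + fp) >= 0.9

    def test_invalid_radius_range(self):
        with pytest.raises(ValueError):
            seg.segment_contrast(np.zeros((64, 64)), radius_range=(5.0, 2.0))


class TestChaining:
    def _roi_at(self, r, c, i):
        px = np.array([[int(r), int(c)]])
        return seg.SynapseROI(pixels=px, centroid=(r, c), area=1,
                              roundness=1.0, equivalent_radius=0.6, roi_id=i)

    def test_collinear_boutons_form_one_chain(self):
        rois = [self._roi_at(10, 10 + 8 * i, i) for i in range(5)]
        seg.link_axonal_chains(rois, d_max=10.0, pixel_size=1.0, min_chain=3)
        ids = {r.chain_id for r in rois}
        assert len(ids) == 1 and None not in ids

    def test_isolated_bouton_excluded(self):
        rois = [self._roi_at(10, 10 + 8 * i, i) for i in range(3)]
        rois.append(self._roi_at(60, 60, 3))
        seg.link_axonal_chains(rois, d_max=10.0, pixel_size=1.0, min_chain=3)
        assert rois[3].chain_id is None
        assert all(r.chain_id is not None for r in rois[:3])

    def test_chain_assignment_matches_ground_truth_axons(self):
        from collections import Counter, defaultdict
        from scipy.spatial import cKDTree

        ok = tot = 0
        for s in range(6):
            p = syn.SimParams(n_axons=4, boutons_per_axon=8)
            fov = syn.generate_fov(p, (256, 256), seed=s, noise_sd=5.0)
            rois = seg.segment_voronoi(fov.gz_image)
            seg.link_axonal_chains(rois, d_max=1.8, pixel_size=0.1, min_chain=3)
            tree = cKDTree(fov.bouton_centers)
            chains = defaultdict(list)
            for r in rois:
                d, i = tree.query(r.centroid)
                if d < 2 and r.chain_id is not None:
                    chains[r.chain_id].append(fov.bouton_axon[i])
            for axons in chains.values():
                ok += Counter(axons).most_common(1)[0][1]
                tot += len(axons)
        assert tot > 0
        assert ok / tot >= 0.9


def test_label_image_roundtrip(noisy_fov):
    rois = seg.segment_voronoi(noisy_fov.gz_image)
    labels = seg.label_image(rois, noisy_fov.shape)
    assert labels.dtype == np.uint16
    for r in rois[:5]:
        assert np.all(labels[r.pixels[:, 0], r.pixels[:, 1]] == r.roi_id + 1)
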