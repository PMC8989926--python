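import numpy as np
import pytest

from uslesion import (PipelineConfig, initial_segmentation, propose_rois,
                      region_similarity)
from uslesion.edges import EdgeMap
from uslesion.selective_search import (build_region_map,
                                       selective_search_merge)

from oracles import rescan_merge_sequence


def edge_map_from(final: np.ndarray) -> EdgeMap:
    return EdgeMap(strong=final.copy(), weak=np.zeros_like(final), final=final)


def voronoi_labels(rng: np.random.Generator, shape=(16, 16), k=5) -> np.ndarray:
    """Random contiguous partition: nearest-seed labelling."""
    seeds_r = rng.integers(0, shape[0], size=k)
    seeds_c = rng.integers(0, shape[1], size=k)
    rows, cols = np.indices(shape)
    d = (rows[..., None] - seeds_r) ** 2 + (cols[..., None] - seeds_c) ** 2
    labels = np.argmin(d, axis=-1)
    # relabel to consecutive ids (duplicate seeds may drop a label)
    _, labels = np.unique(labels, return_inverse=True)
    return labels.reshape(shape)


class TestInitialSegmentation:
    def test_no_edges_single_region(self, rng):
        img = rng.random((12, 12))
        rm = initial_segmentation(img, edge_map_from(np.zeros((12, 12), bool)))
        assert rm.n_regions == 1
        assert np.all(rm.labels == rm.labels[0, 0])

    def test_closed_contour_splits_inside_from_outside(self):
        final = np.zeros((20, 20), dtype=bool)
        final[5, 5:15] = final[14, 5:15] = True
        final[5:15, 5] = final[5:15, 14] = True
        rm = initial_segmentation(np.zeros((20, 20)), edge_map_from(final))
        assert rm.n_regions >= 2
        assert rm.labels[10, 10] != rm.labels[0, 0]

    def test_grid_of_squares_one_region_per_cell(self):
        final = np.zeros((21, 21), dtype=bool)
        for r in (5, 10, 15):
            final[r, 3:18] = True
        for c in (3, 8, 13, 17):
            final[5:16, c] = True
        rm = initial_segmentation(np.zeros((21, 21)), edge_map_from(final))
        # 2x3 closed cells plus the surrounding background
        assert rm.n_regions == 7

    def test_every_pixel_labelled(self, rng):
        final = rng.random((15, 15)) < 0.3
        rm = initial_segmentation(rng.random((15, 15)), edge_map_from(final))
        assert rm.labels.min() >= 0
        sizes = np.bincount(rm.labels.ravel())
        assert all(rm.stats[i].size == sizes[i] for i in rm.stats)


class TestRegionSimilarity:
    def test_identical_histograms_full_gray_similarity(self):
        img = np.full((10, 10), 0.5)
        labels = np.zeros((10, 10), dtype=int)
        labels[:, 5:] = 1
        rm = build_region_map(img, labels)
        sim = region_similarity(0, 1, rm)
        assert sim.s_gray == pytest.approx(1.0)
        assert sim.s_texture == pytest.approx(1.0)

    def test_size_term_vanishes_when_regions_cover_frame(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[4:, :] = 1
        rm = build_region_map(np.linspace(0, 1, 64).reshape(8, 8), labels)
        assert region_similarity(0, 1, rm).s_size == pytest.approx(0.0)

    def test_fill_term_full_for_abutting_rectangles(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[:, 4:] = 1
        rm = build_region_map(np.zeros((8, 8)), labels)
        assert region_similarity(0, 1, rm).s_fill == pytest.approx(1.0)

    def test_components_bounded_and_total_consistent(self, rng):
        labels = voronoi_labels(rng, k=4)
        rm = build_region_map(rng.random((16, 16)), labels)
        sim = region_similarity(0, 1, rm)
        for v in (sim.s_gray, sim.s_texture, sim.s_size, sim.s_fill):
            assert 0.0 <= v <= 1.0
        assert sim.total == pytest.approx(
            sim.s_gray + sim.s_texture + sim.s_size + sim.s_fill)

    def test_unknown_or_equal_ids_rejected(self, rng):
        rm = build_region_map(rng.random((8, 8)), np.zeros((8, 8), dtype=int))
        with pytest.raises(KeyError):
            region_similarity(0, 99, rm)
        with pytest.raises(ValueError):
            region_similarity(0, 0, rm)


class TestMergeLoop:
    def test_single_region_no_merges(self, rng):
        rm = build_region_map(rng.random((8, 8)), np.zeros((8, 8), dtype=int))
        res = selective_search_merge(rm)
        assert res.merges == []
        assert len(res.proposals) == 1

    def test_three_regions_two_merges_five_records(self, rng):
        labels = np.zeros((9, 9), dtype=int)
        labels[3:6] = 1
        labels[6:] = 2
        rm = build_region_map(rng.random((9, 9)), labels)
        res = selective_search_merge(rm)
        assert len(res.merges) == 2
        assert len(res.regions) == 5

    def test_most_similar_pair_merges_first(self, rng):
        """The first merge is the brute-force argmax over all pair similarities."""
        labels = voronoi_labels(rng, k=4)
        rm = build_region_map(rng.random((16, 16)), labels)
        ids = sorted(rm.stats)
        best = max(((i, j) for i in ids for j in ids if i < j),
                   key=lambda p: region_similarity(*p, rm).total)
        res = selective_search_merge(rm)
        assert (res.merges[0].parent_a, res.merges[0].parent_b) == best

    def test_always_n_minus_one_merges(self, rng):
        for k in (2, 3, 5, 6):
            labels = voronoi_labels(rng, k=k)
            n = len(np.unique(labels))
            res = selective_search_merge(build_region_map(rng.random((16, 16)),
                                                          labels))
            assert len(res.merges) == n - 1

    def test_merge_sequence_matches_rescan_oracle(self, rng):
        """The heap-driven loop reproduces a naive oracle that recomputes all
        pairwise similarities from raw pixels every round (<=6 regions)."""
        for _ in range(10):
            img = rng.random((14, 14))
            labels = voronoi_labels(rng, shape=(14, 14), k=int(rng.integers(2, 7)))
            res = selective_search_merge(build_region_map(img, labels))
            expected = rescan_merge_sequence(img, labels)
            got = [(m.parent_a, m.parent_b, m.merged) for m in res.merges]
            assert got == expected


class TestProposeRois:
    def test_constant_image_whole_frame(self, cfg):
        rois = propose_rois(np.full((64, 64), 0.5), cfg)
        assert len(rois) == 1
        assert (rois[0].x, rois[0].y, rois[0].w, rois[0].h) == (0, 0, 64, 64)

    def test_proposals_stay_inside_frame(self, cfg, lesion_phantom):
        from uslesion import preprocess

        pre = preprocess(lesion_phantom.image, cfg)
        h, w = pre.image.shape
        rois = propose_rois(pre.image, cfg)
        assert rois
        for b in rois:
            assert 0 <= b.x and 0 <= b.y and b.x2 <= w and b.y2 <= h
            assert (b.w >= cfg.min_roi_px and b.h >= cfg.min_roi_px) or len(rois) == 1
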