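"""Detection-stage behaviour on drawn shapes and synthetic tiles."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk, line as draw_line

from gliamorph import segment
from gliamorph.errors import OrderingError
from gliamorph.segment import (
    SegmentationParams,
    assign_processes_to_cells,
    detect_cell_bodies,
    extract_process_skeleton,
    order_branches,
    segment_projection,
)

PX = 0.19


def _draw_cell(shape, center, process_angles_deg, length_um=20.0, radius_um=3.0,
               thickness_px=2, intensity=120.0, body_intensity=200.0):
    """Paint a disc body with straight processes at given angles."""
    img = np.zeros(shape, dtype=np.float32)
    r0, c0 = center
    for ang in process_angles_deg:
        a = np.deg2rad(ang)
        # length is measured from the soma contour, as the pipeline does
        r1 = int(round(r0 + np.sin(a) * (length_um + radius_um) / PX))
        c1 = int(round(c0 + np.cos(a) * (length_um + radius_um) / PX))
        rr, cc = draw_line(r0, c0, r1, c1)
        for dr in range(-thickness_px, thickness_px + 1):
            for dc in range(-thickness_px, thickness_px + 1):
                img[np.clip(rr + dr, 0, shape[0] - 1), np.clip(cc + dc, 0, shape[1] - 1)] = intensity
    rr, cc = draw_disk(center, radius_um / PX, shape=shape)
    img[rr, cc] = body_intensity
    return img


class TestBodies:
    def test_blank_image_yields_empty_detection(self):
        det = detect_cell_bodies(np.zeros((64, 64)), pixel_size_um=PX)
        assert det.n_bodies == 0

    def test_synthetic_tile_bodies_found_at_truth_centroids(self, matched_tile):
        truths = matched_tile["truths"]
        assert matched_tile["bodies"].n_bodies == len(truths)
        assert matched_tile["match_dist"].max() < 1.0

    def test_amoeboid_body_area_within_ten_percent(self):
        from gliamorph import synth

        truth, patch = synth.generate_cell("amoeboid", 8)
        det = detect_cell_bodies(patch, pixel_size_um=PX)
        assert det.n_bodies == 1
        assert det.body_areas_um2[0] == pytest.approx(truth.true_body_area_um2, rel=0.10)


class TestSkeleton:
    def test_disc_without_processes_has_no_edges(self):
        img = np.zeros((128, 128), dtype=np.float32)
        rr, cc = draw_disk((64, 64), 3.0 / PX, shape=img.shape)
        img[rr, cc] = 200.0
        det = detect_cell_bodies(img, pixel_size_um=PX)
        sg = extract_process_skeleton(img, det)
        assert sg.graph.number_of_edges() == 0

    def test_three_straight_processes_measure_twenty_um(self):
        img = _draw_cell((360, 360), (180, 180), [0, 120, 240], length_um=20.0)
        det = detect_cell_bodies(img, pixel_size_um=PX)
        sg = extract_process_skeleton(img, det)
        trees = assign_processes_to_cells(sg, det)
        (tree,) = [t for t in trees if t.owner_body is not None]
        n1, n2, n3, nseg = order_branches(tree, PX)
        assert (n1, n2, n3, nseg) == (3, 0, 0, 3)
        for s in tree.segments:
            assert s.length_um == pytest.approx(20.0, abs=1.0)

    def test_y_shaped_process_has_one_junction_three_segments(self):
        img = np.zeros((400, 400), dtype=np.float32)
        # stem from body at (200,60) to (200,200), then two arms
        rr, cc = draw_disk((200, 60), 3.0 / PX, shape=img.shape)
        for (r0, c0, r1, c1) in [(200, 60, 200, 200), (200, 200, 120, 300), (200, 200, 280, 300)]:
            lr, lc = draw_line(r0, c0, r1, c1)
            for d in (-2, -1, 0, 1, 2):
                img[np.clip(lr + d, 0, 399), lc] = 120.0
        img[rr, cc] = 200.0
        det = detect_cell_bodies(img, pixel_size_um=PX)
        sg = extract_process_skeleton(img, det)
        trees = assign_processes_to_cells(sg, det)
        (tree,) = [t for t in trees if t.owner_body is not None]
        n1, n2, n3, nseg = order_branches(tree, PX)
        assert (n1, n2, nseg) == (1, 2, 3)
        junctions = [n for n in tree.graph.nodes if tree.graph.degree(n) >= 3]
        assert len(junctions) == 1


class TestAttribution:
    def test_orphan_component_is_unattributed(self):
        img = np.zeros((300, 300), dtype=np.float32)
        rr, cc = draw_disk((80, 80), 3.0 / PX, shape=img.shape)
        img[rr, cc] = 200.0
        lr, lc = draw_line(220, 40, 220, 260)  # far from the body
        for d in (-2, -1, 0, 1, 2):
            img[lr + d, lc] = 120.0
        det = detect_cell_bodies(img, pixel_size_um=PX)
        sg = extract_process_skeleton(img, det)
        trees = assign_processes_to_cells(sg, det)
        owners = sorted((t.owner_body is not None) for t in trees)
        assert owners == [False]  # only the stray line forms a component
        with pytest.raises(OrderingError):
            order_branches(trees[0], PX)

    def test_segments_partition_between_cells_and_unattributed(self, matched_tile):
        """Every skeleton segment belongs to exactly one tree (owned or
        unattributed); only soma-boundary artefacts may be discarded."""
        sg = extract_process_skeleton(
            matched_tile["projection"], matched_tile["bodies"]
        )
        total = sg.graph.number_of_edges()
        trees = assign_processes_to_cells(sg, matched_tile["bodies"])
        seen: set[int] = set()
        by_tree = 0
        for t in trees:
            edges = (
                [id(d) for _, _, d in t.graph.edges(data=True)]
                if t.owner_body is not None
                else [id(s) for s in t.segments]
            )
            assert seen.isdisjoint(edges)  # no double attribution
            seen.update(edges)
            by_tree += len(edges)
        assert by_tree <= total
        assert by_tree >= 0.95 * total  # at most a few contact spurs dropped

    def test_two_cell_tile_counts_match_truth(self, matched_tile):
        truths = matched_tile["truths"]
        by_owner = matched_tile["by_owner"]
        labels = matched_tile["match_labels"]
        exact = 0
        for t, lbl in zip(truths, labels):
            tree = by_owner.get(lbl)
            meas = order_branches(tree, PX) if tree is not None else (0, 0, 0, 0)
            if meas == (t.true_n_primary, t.true_n_secondary, t.true_n_tertiary, t.true_n_segments):
                exact += 1
        assert exact == len(truths)


class TestInvariance:
    def test_counts_invariant_to_ninety_degree_rotation(self):
        from gliamorph import synth

        _, patch = synth.generate_cell("ramified_highCI_lowCEA", 17)

        def counts(img):
            det = detect_cell_bodies(img, pixel_size_um=PX)
            sg = extract_process_skeleton(img, det)
            trees = assign_processes_to_cells(sg, det)
            (tree,) = [t for t in trees if t.owner_body is not None]
            return order_branches(tree, PX)

        assert counts(patch) == counts(np.rot90(patch).copy())
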