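"""Outlier, edge and duplicate elimination rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gliamorph import popfilter
from gliamorph.popfilter import FilterConfig


def make_records(rows):
    base = {
        "cell_id": 0, "body_area_um2": 50.0, "roundness": 0.9,
        "centroid_x_um": 100.0, "centroid_y_um": 100.0, "subvolume_index": 0,
        "hull_min_x_um": 80.0, "hull_max_x_um": 120.0,
        "hull_min_y_um": 80.0, "hull_max_y_um": 120.0,
    }
    out = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec.update(r)
        rec["cell_id"] = i
        out.append(rec)
    return pd.DataFrame(out)


class TestOutliers:
    def test_size_and_roundness_violations_rejected_with_reason(self):
        df = make_records([
            {"body_area_um2": 9.9},
            {"body_area_um2": 600.0},
            {"body_area_um2": 100.0, "roundness": 0.65},
            {"body_area_um2": 100.0, "roundness": 0.9},
        ])
        kept, rejected = popfilter.filter_outliers(df)
        assert list(kept["cell_id"]) == [3]
        assert dict(zip(rejected["cell_id"], rejected["reject_reason"])) == {
            0: "body_too_small", 1: "body_too_large", 2: "roundness",
        }

    def test_boundary_values_are_kept(self):
        df = make_records([
            {"body_area_um2": 10.0},
            {"body_area_um2": 500.0},
            {"roundness": 0.7},
        ])
        kept, rejected = popfilter.filter_outliers(df)
        assert len(kept) == 3 and rejected.empty

    @given(areas=st.lists(st.floats(0.1, 1000, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_partition_and_idempotence(self, areas):
        df = make_records([{"body_area_um2": a} for a in areas])
        kept, rejected = popfilter.filter_outliers(df)
        assert len(kept) + len(rejected) == len(df)
        assert set(kept["cell_id"]).isdisjoint(rejected["cell_id"])
        kept2, rejected2 = popfilter.filter_outliers(kept)
        assert rejected2.empty and kept2.equals(kept)


class TestEdgeRemoval:
    BOUNDS = (0.0, 0.0, 500.0, 500.0)

    def test_interior_cell_kept_border_hull_removed(self):
        df = make_records([
            {},  # interior
            {"hull_min_x_um": -2.0},  # hull crosses the left border
            {"hull_max_y_um": 505.0},  # bottom border
        ])
        kept, removed = popfilter.remove_edge_cells(df, self.BOUNDS)
        assert list(kept["cell_id"]) == [0]
        assert set(removed["cell_id"]) == {1, 2}

    def test_exactly_the_planted_border_clipped_cells_are_removed(self):
        rng = np.random.default_rng(0)
        rows = []
        planted = set()
        for i in range(40):
            x, y = rng.uniform(60, 440, 2)
            rows.append({"centroid_x_um": x, "centroid_y_um": y,
                         "hull_min_x_um": x - 30, "hull_max_x_um": x + 30,
                         "hull_min_y_um": y - 30, "hull_max_y_um": y + 30})
        for i in range(10):  # deliberately clipped at the left border
            y = rng.uniform(60, 440)
            rows.append({"centroid_x_um": 15.0, "centroid_y_um": y,
                         "hull_min_x_um": -5.0, "hull_max_x_um": 45.0,
                         "hull_min_y_um": y - 30, "hull_max_y_um": y + 30})
            planted.add(40 + i)
        kept, removed = popfilter.remove_edge_cells(make_records(rows), self.BOUNDS)
        assert set(removed["cell_id"]) == planted


class TestDedup:
    def test_adjacent_subvolume_duplicate_merged_larger_body_kept(self):
        df = make_records([
            {"subvolume_index": 0, "body_area_um2": 40.0},
            {"subvolume_index": 1, "body_area_um2": 55.0},
        ])
        kept, dropped = popfilter.deduplicate_across_subvolumes(df)
        assert list(kept["cell_id"]) == [1]
        assert list(dropped["reject_reason"]) == ["duplicate"]

    def test_non_adjacent_and_distant_pairs_untouched(self):
        df = make_records([
            {"subvolume_index": 0},
            {"subvolume_index": 2},  # same centroid, but sub-volumes 0 and 2
            {"subvolume_index": 1, "centroid_x_um": 150.0},  # 50 um away
        ])
        kept, dropped = popfilter.deduplicate_across_subvolumes(df)
        assert len(kept) == 3 and dropped.empty

    def test_area_tie_keeps_lower_subvolume(self):
        df = make_records([
            {"subvolume_index": 1, "body_area_um2": 50.0},
            {"subvolume_index": 0, "body_area_um2": 50.0},
        ])
        kept, _ = popfilter.deduplicate_across_subvolumes(df)
        assert list(kept["subvolume_index"]) == [0]

    def test_output_has_no_matchable_pair_left(self):
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(60):
            x, y = rng.uniform(0, 300, 2)
            rows.append({"centroid_x_um": x, "centroid_y_um": y,
                         "subvolume_index": int(rng.integers(0, 3)),
                         "body_area_um2": float(rng.uniform(20, 100))})
        kept, _ = popfilter.deduplicate_across_subvolumes(make_records(rows))
        xy = kept[["centroid_x_um", "centroid_y_um"]].to_numpy()
        sv = kept["subvolume_index"].to_numpy()
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                if abs(sv[i] - sv[j]) == 1:
                    assert np.hypot(*(xy[i] - xy[j])) > 5.0


class TestPipelineFilter:
    def test_apply_all_counts_and_planted_duplicates(self):
        from gliamorph import synth

        spec = synth.TissueSpec(
            n_cells=30, width_px=2600, height_px=2600, n_planes=16,
            duplicate_fraction=0.2, seed=13,
        )
        _, truths = synth.generate_tissue(spec, render=False)
        records = synth.truths_to_records(truths)
        report = popfilter.apply_all(records)
        assert report.counts["duplicates"] == 6
        assert report.counts["kept"] + len(report.rejected) == len(records)

    def test_invalid_config_rejected(self):
        with pytest.raises(Exception):
            FilterConfig(min_body_area_um2=600, max_body_area_um2=500)
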