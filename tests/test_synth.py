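"""Generator correctness: determinism, truth self-consistency, cohorts."""

import dataclasses

import numpy as np
import pytest

from gliamorph import synth
from gliamorph.errors import ParameterError, PlacementError

from oracles import count_tree_by_traversal, hull_area_by_triangulation


class TestGenerateCell:
    def test_same_seed_is_bit_identical(self):
        t1, p1 = synth.generate_cell("ramified_highCI_highCEA", 11)
        t2, p2 = synth.generate_cell("ramified_highCI_highCEA", 11)
        assert np.array_equal(p1, p2)
        assert t1.true_CI == t2.true_CI
        assert np.array_equal(t1.true_endpoints_um, t2.true_endpoints_um)

    @pytest.mark.parametrize("seed", range(5))
    def test_amoeboid_has_ci_one_and_no_branches(self, seed):
        truth, _ = synth.generate_cell("amoeboid", seed)
        assert truth.true_CI == 1.0
        assert truth.true_n_secondary == 0
        assert truth.true_n_tertiary == 0

    def test_single_forced_bifurcation_gives_ci_three(self):
        arch = dataclasses.replace(
            synth.ARCHETYPES["ramified_lowCI_lowCEA"],
            n_primary=1,
            branch_prob_per_order=(1.0,),
            max_order=2,
        )
        truth, _ = synth.generate_cell(arch, 0)
        assert truth.true_n_segments == 3
        assert truth.true_CI == 3.0

    def test_patch_is_one_connected_component(self):
        from scipy import ndimage

        for name in synth.ARCHETYPE_ORDER:
            _, patch = synth.generate_cell(name, 2)
            _, n = ndimage.label(patch > 0, structure=np.ones((3, 3)))
            assert n == 1

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ParameterError):
            synth.generate_cell("not_a_cell", 0)

    def test_invalid_archetype_parameters_rejected(self):
        with pytest.raises(ParameterError):
            synth.CellArchetype("bad", -1.0, 4, (0.5,), 6.0, 1.0, 3, 0.7)
        with pytest.raises(ParameterError):
            synth.CellArchetype("bad", 3.0, 4, (1.5,), 6.0, 1.0, 3, 0.7)


class TestTruthSelfConsistency:
    """Stored truth must be reproducible from the stored tree by
    independent brute-force traversal / triangulation."""

    @pytest.mark.parametrize("name", synth.ARCHETYPE_ORDER)
    def test_counts_ci_and_cea_recompute_exactly(self, name):
        for seed in range(20):
            truth, _ = synth.generate_cell(name, seed)
            n1, n2, n3, nseg = count_tree_by_traversal(truth.segments)
            assert (n1, n2, n3, nseg) == (
                truth.true_n_primary,
                truth.true_n_secondary,
                truth.true_n_tertiary,
                truth.true_n_segments,
            )
            assert truth.true_CI == nseg / n1
            cea_oracle = hull_area_by_triangulation(truth.true_endpoints_um)
            assert truth.true_CEA_um2 == pytest.approx(cea_oracle, rel=1e-9, abs=1e-9)


class TestGenerateTissue:
    def test_zero_cells_gives_pure_background(self):
        spec = synth.TissueSpec(
            n_cells=0, width_px=300, height_px=300, n_planes=3,
            background_level=10.0, noise_sd=2.0, seed=0,
        )
        stack, truths = synth.generate_tissue(spec)
        assert truths == []
        assert abs(stack.planes.mean() - 10.0) < 1.0

    def test_truths_reproducible_and_counted(self):
        spec = synth.TissueSpec(
            n_cells=30, width_px=2500, height_px=2500, n_planes=3, seed=5
        )
        _, t1 = synth.generate_tissue(spec)
        _, t2 = synth.generate_tissue(spec)
        assert len(t1) == 30
        df1, df2 = synth.truths_to_dataframe(t1), synth.truths_to_dataframe(t2)
        assert df1.equals(df2)

    def test_all_amoeboid_mix_forces_ci_one(self):
        spec = synth.TissueSpec(
            n_cells=50, width_px=2500, height_px=2500, n_planes=1,
            archetype_mix=(0, 0, 0, 0, 1), seed=1,
        )
        _, truths = synth.generate_tissue(spec, render=False)
        assert all(t.true_CI == 1.0 for t in truths)

    def test_min_spacing_respected(self):
        spec = synth.TissueSpec(
            n_cells=15, width_px=3000, height_px=3000, n_planes=1,
            min_cell_spacing_um=60.0, seed=2,
        )
        _, truths = synth.generate_tissue(spec, render=False)
        pts = np.array([t.centroid_um for t in truths])
        d = np.hypot(*(pts[:, None] - pts[None]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 60.0

    def test_impossible_placement_names_achievable_count(self):
        spec = synth.TissueSpec(
            n_cells=100, width_px=600, height_px=600, n_planes=1, seed=0
        )
        with pytest.raises(PlacementError) as exc:
            synth.generate_tissue(spec)
        assert exc.value.achievable < exc.value.requested

    def test_planted_duplicates_flagged_on_adjacent_subvolume(self):
        spec = synth.TissueSpec(
            n_cells=20, width_px=2500, height_px=2500, n_planes=16,
            duplicate_fraction=0.25, seed=9,
        )
        _, truths = synth.generate_tissue(spec, render=False)
        dups = [t for t in truths if t.duplicate_of is not None]
        assert len(dups) == 5
        by_id = {t.cell_id: t for t in truths}
        for d in dups:
            src = by_id[d.duplicate_of]
            assert abs(d.subvolume_index - src.subvolume_index) == 1
            assert np.hypot(
                d.centroid_um[0] - src.centroid_um[0],
                d.centroid_um[1] - src.centroid_um[1],
            ) <= 2.0


class TestCohort:
    def test_null_effect_leaves_groups_exchangeable(self):
        cohort = synth.generate_cohort(
            5, 5, cells_per_animal=40, seed=3,
            treatment_effect={"cytoplasm_factor": 1.0},
            animal_cv=0.0, ci_animal_cv=0.0, cea_animal_cv=0.0,
        )
        ctrl = np.concatenate(
            [s.records["cytoplasm_area_um2"] for s in cohort if s.condition == "control"]
        )
        trt = np.concatenate(
            [s.records["cytoplasm_area_um2"] for s in cohort if s.condition == "treated"]
        )
        assert abs(ctrl.mean() - trt.mean()) / ctrl.mean() < 0.1

    def test_factor_two_doubles_mean_cytoplasm(self):
        cohort = synth.generate_cohort(
            7, 6, cells_per_animal=60, seed=4, animal_cv=0.0,
            treatment_effect={"cytoplasm_factor": 2.0},
        )
        ctrl = np.mean(
            [s.records["cytoplasm_area_um2"].mean() for s in cohort if s.condition == "control"]
        )
        trt = np.mean(
            [s.records["cytoplasm_area_um2"].mean() for s in cohort if s.condition == "treated"]
        )
        assert trt / ctrl == pytest.approx(2.0, rel=0.12)

    def test_cerebellum_preset_has_lower_cea_than_cortex(self):
        cohort = synth.generate_cohort(
            4, 1, regions=("frontal_cortex", "cerebellum"),
            cells_per_animal=80, seed=6,
        )
        cea = {}
        for region in ("frontal_cortex", "cerebellum"):
            cea[region] = np.concatenate(
                [s.records["CEA_um2"] for s in cohort
                 if s.region == region and s.condition == "control"]
            ).mean()
        assert cea["cerebellum"] < cea["frontal_cortex"]

    def test_unknown_region_preset_rejected(self):
        with pytest.raises(ParameterError):
            synth.generate_cohort(2, 2, regions=("atlantis",))
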