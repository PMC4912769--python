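"""Ground-truth recovery experiments.

Self-contained benchmark routines that exercise the full measurement chain
against the synthetic generator's known truth: branch-count recovery on
rendered tissue, clustering/sub-population recovery on planted mixtures,
and calibration/power of the two-group comparison on simulated cohorts.
They are used by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import stats, synth
from .imaging import split_and_project
from .segment import order_branches, segment_projection

__all__ = [
    "branch_count_recovery",
    "two_group_type1_error",
    "two_group_power",
]


def branch_count_recovery(
    n_cells: int = 200,
    seed: int = 0,
    cells_per_tile: int = 40,
    tile_px: int = 3400,
    background_level: float = 0.0,
    noise_sd: float = 0.0,
) -> dict:
    """Segment rendered tissue and compare branch counts with ground truth.

    Cells are spread over square tiles (~650 um side at the default
    calibration, about 100 cells/mm^2) and measured through the standard
    projection -> body detection -> skeleton -> attribution -> ordering
    chain.  Returns the fraction of cells whose
    (n_primary, n_secondary, n_tertiary, n_segments) match truth exactly
    and the fraction whose n_primary is within +-1.
    """
    ss = np.random.SeedSequence(seed)
    n_tiles = int(np.ceil(n_cells / cells_per_tile))
    tile_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_tiles)]
    exact = within1 = total = 0
    for t_i, t_seed in enumerate(tile_seeds):
        n_here = min(cells_per_tile, n_cells - t_i * cells_per_tile)
        spec = synth.TissueSpec(
            n_cells=n_here,
            width_px=tile_px,
            height_px=tile_px,
            n_planes=1,
            background_level=background_level,
            noise_sd=noise_sd,
            seed=t_seed,
        )
        stack, truths = synth.generate_tissue(spec)
        proj = split_and_project(stack, 1).projections[0]
        bodies, trees = segment_projection(proj, pixel_size_um=spec.pixel_size_um)
        by_owner = {t.owner_body: t for t in trees if t.owner_body is not None}
        if bodies.n_bodies:
            kd = cKDTree(bodies.centroids_um)
            _, idx = kd.query(np.array([t.centroid_um for t in truths]))
        else:
            idx = np.full(len(truths), -1)
        for truth, body_idx in zip(truths, idx):
            tree = by_owner.get(body_idx + 1) if body_idx >= 0 else None
            if tree is not None and tree.segments:
                meas = (
                    sum(1 for s in tree.segments if s.branch_order == 1),
                    sum(1 for s in tree.segments if s.branch_order == 2),
                    sum(1 for s in tree.segments if s.branch_order >= 3),
                    len(tree.segments),
                )
            elif tree is not None:
                meas = order_branches(tree, spec.pixel_size_um)
            else:
                meas = (0, 0, 0, 0)
            want = (
                truth.true_n_primary,
                truth.true_n_secondary,
                truth.true_n_tertiary,
                truth.true_n_segments,
            )
            exact += meas == want
            within1 += abs(meas[0] - want[0]) <= 1
            total += 1
    return {
        "n_cells": total,
        "exact_fraction": exact / total,
        "primary_within1_fraction": within1 / total,
    }


def _cohort_pvalue(seed: int, cytoplasm_factor: float, cells_per_animal: int) -> float:
    cohort = synth.generate_cohort(
        7,
        6,
        cells_per_animal=cells_per_animal,
        seed=seed,
        treatment_effect={"cytoplasm_factor": cytoplasm_factor},
    )
    a = [s.records["cytoplasm_area_um2"].mean() for s in cohort if s.condition == "control"]
    b = [s.records["cytoplasm_area_um2"].mean() for s in cohort if s.condition == "treated"]
    return stats.compare_two_groups(a, b).p_value


def two_group_type1_error(
    n_sims: int = 2000, seed: int = 0, cells_per_animal: int = 10, alpha: float = 0.05
) -> dict:
    """Null rejection rate of the two-group comparison (7 vs 6 animals)."""
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**30))
    p = [_cohort_pvalue(base + i, 1.0, cells_per_animal) for i in range(n_sims)]
    return {"n_sims": n_sims, "type1_error": float(np.mean(np.asarray(p) < alpha))}


def two_group_power(
    n_sims: int = 300,
    seed: int = 1,
    cells_per_animal: int = 25,
    cytoplasm_factor: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Detection rate of a planted cytoplasm-area effect (7 vs 6 animals)."""
    base = int(np.random.SeedSequence(seed ^ 0x5EED).generate_state(1)[0] % (2**30))
    p = [_cohort_pvalue(base + i, cytoplasm_factor, cells_per_animal) for i in range(n_sims)]
    return {"n_sims": n_sims, "power": float(np.mean(np.asarray(p) < alpha))}
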