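"""Shared fixtures: small synthetic tiles segmented once per session."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from gliamorph import segment, synth
from gliamorph.imaging import split_and_project


@pytest.fixture(scope="session")
def small_tile():
    """A noise-free 12-cell tile with truth, segmented once for the session."""
    spec = synth.TissueSpec(
        n_cells=12,
        width_px=2200,
        height_px=2200,
        n_planes=1,
        background_level=0.0,
        noise_sd=0.0,
        seed=42,
    )
    stack, truths = synth.generate_tissue(spec)
    proj = split_and_project(stack, 1).projections[0]
    bodies, trees = segment.segment_projection(proj, pixel_size_um=spec.pixel_size_um)
    return {
        "spec": spec,
        "stack": stack,
        "truths": truths,
        "projection": proj,
        "bodies": bodies,
        "trees": trees,
    }


def match_truth_to_bodies(truths, bodies):
    """Nearest-centroid matching truth cell -> detected body label (1-based)."""
    tc = np.array([t.centroid_um for t in truths])
    kd = cKDTree(bodies.centroids_um)
    dist, idx = kd.query(tc)
    return dist, idx + 1


@pytest.fixture(scope="session")
def matched_tile(small_tile):
    dist, labels = match_truth_to_bodies(small_tile["truths"], small_tile["bodies"])
    by_owner = {
        t.owner_body: t for t in small_tile["trees"] if t.owner_body is not None
    }
    return {**small_tile, "match_dist": dist, "match_labels": labels, "by_owner": by_owner}
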