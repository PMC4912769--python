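"""Synthetic microglia-bearing tissue with per-cell ground truth.

The generator renders GFP-like ramified and amoeboid cells on a dark, noisy
background and records, for every cell, the exact tree it drew: branch
counts by order, complexity index (CI = segments / primary ramifications),
process endpoints and their convex-hull territory (CEA), body and cytoplasm
areas.  Those records are the oracle against which the measurement pipeline
is validated.

Cells are built as rooted trees of polyline segments.  Each primary process
starts on the soma contour inside its own angular sector; on branching, a
segment spawns two children that inherit disjoint halves of the parent's
sector.  This nesting keeps sibling subtrees angularly separated, so a
rendered arbor never self-crosses and the drawn topology is unambiguous.
An amoeboid cell has at most two unbranched stubs, hence CI = 1.

Placement uses rejection sampling with a hard non-overlap constraint based
on each cell's realized arbor radius; overlapping arbors (dense networks)
can be enabled explicitly, at the price of ambiguous ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .errors import ParameterError, PlacementError
from .imaging import (
    DEFAULT_N_PLANES,
    DEFAULT_PIXEL_SIZE_UM,
    DEFAULT_Z_STEP_UM,
    ImageStack,
)

__all__ = [
    "CellArchetype",
    "GroundTruthCell",
    "TissueSpec",
    "TreeSegment",
    "ARCHETYPES",
    "ARCHETYPE_ORDER",
    "REGION_PRESETS",
    "CohortSample",
    "generate_cell",
    "generate_tissue",
    "generate_cohort",
    "truths_to_dataframe",
    "truths_to_records",
    "sample_ci_cea_mixture",
    "write_tissue",
]


# ---------------------------------------------------------------------------
# archetypes


@dataclass(frozen=True)
class CellArchetype:
    """Generative parameters of one morphological phenotype.

    ``branch_prob_per_order[o-1]`` is the probability that a segment of
    branch order ``o`` ends in a bifurcation (two children of order o+1);
    orders ``max_order`` and above never branch.  An amoeboid archetype has
    all branch probabilities zero, which forces CI = 1 (no nodes).
    """

    name: str
    body_radius_um: float
    n_primary: int
    branch_prob_per_order: tuple[float, ...]
    mean_segment_length_um: float
    segment_length_sd_um: float
    max_order: int
    process_thickness_um: float
    intensity_body: float = 200.0
    intensity_process: float = 120.0
    branch_angle_deg: float = 32.0
    turn_sd_deg: float = 6.0
    steps_per_segment: int = 6

    def __post_init__(self) -> None:
        if self.body_radius_um <= 0 or self.process_thickness_um <= 0:
            raise ParameterError(f"{self.name}: lengths must be positive")
        if self.mean_segment_length_um <= 0 or self.segment_length_sd_um < 0:
            raise ParameterError(f"{self.name}: segment lengths must be positive")
        if self.n_primary < 0 or self.max_order < 1:
            raise ParameterError(f"{self.name}: counts must be positive")
        if any(not 0.0 <= p <= 1.0 for p in self.branch_prob_per_order):
            raise ParameterError(f"{self.name}: branch probabilities must be in [0,1]")
        if self.steps_per_segment < 1:
            raise ParameterError(f"{self.name}: steps_per_segment must be >= 1")

    @property
    def is_amoeboid(self) -> bool:
        return all(p == 0.0 for p in self.branch_prob_per_order) or self.max_order == 1

    def max_reach_um(self) -> float:
        """Upper bound on the radial extent of a generated arbor."""
        cap = self.mean_segment_length_um + 2.0 * self.segment_length_sd_um
        return self.body_radius_um + self.max_order * cap

    def scaled(
        self,
        size_factor: float = 1.0,
        ci_factor: float = 1.0,
        length_factor: float = 1.0,
    ) -> "CellArchetype":
        """Return a copy with cytoplasm-size, branching and reach scaled.

        ``size_factor`` multiplies cytoplasm-area parameters (body area and
        process thickness scale linearly with it), ``ci_factor`` the branch
        probabilities (clipped to 0.97), ``length_factor`` segment lengths.
        """
        probs = tuple(min(0.97, p * ci_factor) for p in self.branch_prob_per_order)
        return dataclasses.replace(
            self,
            body_radius_um=self.body_radius_um * float(np.sqrt(size_factor)),
            process_thickness_um=self.process_thickness_um * size_factor,
            branch_prob_per_order=probs,
            mean_segment_length_um=self.mean_segment_length_um * length_factor,
            segment_length_sd_um=self.segment_length_sd_um * length_factor,
        )


#: canonical archetype order used by mixing vectors
ARCHETYPE_ORDER = (
    "ramified_lowCI_lowCEA",
    "ramified_lowCI_highCEA",
    "ramified_highCI_lowCEA",
    "ramified_highCI_highCEA",
    "amoeboid",
)

ARCHETYPES: dict[str, CellArchetype] = {
    "ramified_lowCI_lowCEA": CellArchetype(
        "ramified_lowCI_lowCEA", 3.0, 4, (0.35, 0.15), 6.5, 1.0, 3, 0.7
    ),
    "ramified_lowCI_highCEA": CellArchetype(
        "ramified_lowCI_highCEA", 3.0, 5, (0.35, 0.15), 13.0, 2.4, 3, 0.7
    ),
    "ramified_highCI_lowCEA": CellArchetype(
        "ramified_highCI_lowCEA", 3.0, 4, (0.95, 0.65), 6.0, 0.8, 3, 0.7
    ),
    "ramified_highCI_highCEA": CellArchetype(
        "ramified_highCI_highCEA", 3.2, 4, (0.95, 0.65), 11.0, 2.2, 3, 0.7
    ),
    "amoeboid": CellArchetype(
        "amoeboid", 4.0, 2, (), 3.5, 0.5, 1, 1.1, intensity_body=220.0
    ),
}


# ---------------------------------------------------------------------------
# tree sampling


@dataclass
class TreeSegment:
    """One process segment: a polyline between two nodes, with its order."""

    order: int
    polyline_um: np.ndarray  # (m, 2) absolute coordinates, cell-centred
    parent: int  # index of parent segment, -1 for primaries
    is_leaf: bool

    @property
    def length_um(self) -> float:
        d = np.diff(self.polyline_um, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class GroundTruthCell:
    """Generator-side truth for one cell; the oracle for the pipeline."""

    cell_id: int
    archetype: str
    centroid_um: tuple[float, float]
    true_body_area_um2: float
    true_cytoplasm_area_um2: float
    true_n_primary: int
    true_n_secondary: int
    true_n_tertiary: int
    true_n_segments: int
    true_CI: float
    true_CEA_um2: float
    true_endpoints_um: np.ndarray  # (n, 2) cell-centred coordinates
    subvolume_index: int = 0
    true_total_length_um: float = 0.0
    true_radius_um: float = 0.0
    duplicate_of: int | None = None
    segments: list[TreeSegment] = field(default_factory=list, repr=False)

    def endpoints_absolute_um(self) -> np.ndarray:
        if len(self.true_endpoints_um) == 0:
            return np.empty((0, 2))
        return self.true_endpoints_um + np.asarray(self.centroid_um)


def _wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _truncated_lengths(rng: np.random.Generator, mean: float, sd: float, k: int):
    # floor keeps real segments clearly longer than digitization spurs
    lo = max(2.5, mean - 2.0 * sd)
    hi = max(mean + 2.0 * sd, lo + 0.1)
    return np.clip(rng.normal(mean, sd, size=k), lo, hi)


def _sample_tree(
    archetype: CellArchetype, rng: np.random.Generator
) -> list[TreeSegment]:
    """Draw one process tree (cell-centred um coordinates).

    Vectorized over the segments of each branch order.  Headings are
    clamped into nested angular sectors so sibling subtrees never cross.
    """
    k0 = archetype.n_primary
    if k0 == 0:
        return []
    steps = archetype.steps_per_segment
    turn_sd = np.deg2rad(archetype.turn_sd_deg)
    branch_angle = np.deg2rad(archetype.branch_angle_deg)

    phase = rng.uniform(0.0, 2.0 * np.pi)
    centers = phase + 2.0 * np.pi * np.arange(k0) / k0
    half = np.full(k0, (np.pi / k0) * 0.85)
    heading = centers + rng.normal(0.0, 0.3 * half, size=k0)
    start = archetype.body_radius_um * np.column_stack(
        [np.cos(centers), np.sin(centers)]
    )

    segments: list[TreeSegment] = []
    # active cohort of one order: (start, heading, center, half, parent_idx)
    active = (start, np.asarray(heading), np.asarray(centers), half, np.full(k0, -1))
    order = 1
    while active is not None:
        pos, h, center, hw, parent = active
        k = len(h)
        lengths = _truncated_lengths(
            rng, archetype.mean_segment_length_um, archetype.segment_length_sd_um, k
        )
        step_len = lengths / steps
        pts = [pos.copy()]
        # keep headings in the central 3/4 of the sector so sibling
        # subtrees stay rasterization-distinguishable
        h_margin = np.maximum(0.04, 0.25 * hw)
        h = center + np.clip(_wrap_angle(h - center), -(hw - h_margin), hw - h_margin)
        for step_i in range(steps):
            # straight "launch": no turning until siblings have separated
            if steps > 1 and (step_i + 1) * step_len.min() > 4.0:
                h = h + rng.normal(0.0, turn_sd, size=k)
            h = center + np.clip(_wrap_angle(h - center), -(hw - h_margin), hw - h_margin)
            new = pos + step_len[:, None] * np.column_stack([np.cos(h), np.sin(h)])
            # confine positions to the sector (with a small angular margin)
            ang_rel = _wrap_angle(np.arctan2(new[:, 1], new[:, 0]) - center)
            # sector margin sized to a ~2 um arc clearance between cousins
            margin = np.minimum(
                hw * 0.45,
                np.maximum(0.04, 1.1 / np.maximum(np.hypot(new[:, 0], new[:, 1]), 4.0)),
            )
            bad = np.abs(ang_rel) > (hw - margin)
            if bad.any():
                h = np.where(bad, center - np.sign(ang_rel) * hw * 0.3, h)
                new = pos + step_len[:, None] * np.column_stack(
                    [np.cos(h), np.sin(h)]
                )
            pos = new
            pts.append(pos.copy())
        polylines = np.stack(pts, axis=1)  # (k, steps+1, 2)

        p_branch = (
            archetype.branch_prob_per_order[order - 1]
            if order < archetype.max_order
            and order <= len(archetype.branch_prob_per_order)
            else 0.0
        )
        branches = rng.random(k) < p_branch

        base = len(segments)
        for i in range(k):
            segments.append(
                TreeSegment(order, polylines[i], int(parent[i]), not branches[i])
            )

        if not branches.any():
            active = None
        else:
            idx = np.flatnonzero(branches)
            m = len(idx)
            jitter = rng.normal(0.0, 0.12 * branch_angle, size=(m, 2))
            child_start = np.repeat(pos[idx], 2, axis=0)
            end_h = h[idx]
            h_lo = end_h - branch_angle + jitter[:, 0]
            h_hi = end_h + branch_angle + jitter[:, 1]
            c_lo = center[idx] - hw[idx] / 2.0
            c_hi = center[idx] + hw[idx] / 2.0
            hw_c = hw[idx] / 2.0
            band = hw_c - np.maximum(0.04, 0.25 * hw_c)
            h_lo = c_lo + np.clip(_wrap_angle(h_lo - c_lo), -band, band)
            h_hi = c_hi + np.clip(_wrap_angle(h_hi - c_hi), -band, band)
            # guarantee sibling divergence so both raster branches resolve
            min_sep = np.minimum(0.48, c_hi + band - (c_lo - band))
            sep = _wrap_angle(h_hi - h_lo)
            short = sep < min_sep
            push = (min_sep - sep) / 2.0
            h_lo = np.where(short, np.maximum(c_lo - band, h_lo - push), h_lo)
            h_hi = np.where(short, np.minimum(c_hi + band, h_hi + push), h_hi)
            child_h = np.column_stack([h_lo, h_hi]).ravel()
            child_center = np.column_stack([c_lo, c_hi]).ravel()
            child_hw = np.repeat(hw_c, 2)
            child_parent = np.repeat(base + idx, 2)
            active = (child_start, child_h, child_center, child_hw, child_parent)
            order += 1
    return segments


def effective_process_width_um(
    archetype: CellArchetype, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> float:
    """Realized raster width of a process.

    Thickness is rendered by dilating a 1-px polyline with a disk whose
    radius is the declared thickness rounded to whole pixels, so the
    painted width is ``(2*r + 1)`` pixels; the truth cytoplasm area uses
    this realized width so it matches what the measurement stage sees.
    """
    r = max(1, int(round(archetype.process_thickness_um / 2.0 / pixel_size_um)))
    return (2 * r + 1) * pixel_size_um


def _truth_from_tree(
    archetype: CellArchetype, segments: list[TreeSegment], cell_id: int = 0
) -> GroundTruthCell:
    n_by_order = {1: 0, 2: 0, 3: 0}
    total_len = 0.0
    endpoints = []
    radius = archetype.body_radius_um
    if segments:
        pts = np.concatenate([seg.polyline_um for seg in segments])
        radius = max(radius, float(np.abs(np.hypot(pts[:, 0], pts[:, 1])).max()))
        diffs = [np.diff(seg.polyline_um, axis=0) for seg in segments]
        steps = np.concatenate(diffs)
        seg_lens = np.add.reduceat(
            np.hypot(steps[:, 0], steps[:, 1]),
            np.cumsum([0] + [len(d) for d in diffs[:-1]]),
        )
        total_len = float(seg_lens.sum())
    for seg in segments:
        o = min(seg.order, 3)
        n_by_order[o] += 1
        if seg.is_leaf:
            endpoints.append(seg.polyline_um[-1])
    endpoints_arr = np.asarray(endpoints) if endpoints else np.empty((0, 2))
    n_primary = n_by_order[1]
    n_segments = sum(n_by_order.values())
    ci = n_segments / n_primary if n_primary > 0 else 1.0
    cea = convex_hull_area(endpoints_arr)
    body_area = float(np.pi * archetype.body_radius_um**2)
    primary_len = sum(s.length_um for s in segments if s.order == 1)
    cytoplasm = body_area + primary_len * effective_process_width_um(archetype)
    return GroundTruthCell(
        cell_id=cell_id,
        archetype=archetype.name,
        centroid_um=(0.0, 0.0),
        true_body_area_um2=body_area,
        true_cytoplasm_area_um2=cytoplasm,
        true_n_primary=n_primary,
        true_n_secondary=n_by_order[2],
        true_n_tertiary=n_by_order[3],
        true_n_segments=n_segments,
        true_CI=ci,
        true_CEA_um2=cea,
        true_endpoints_um=endpoints_arr,
        true_total_length_um=total_len,
        true_radius_um=radius,
        segments=segments,
    )


def convex_hull_area(points: np.ndarray) -> float:
    """Convex-hull area of a 2D point set (0 for < 3 non-collinear points).

    Monotone-chain hull + shoelace, independent of the geometry library the
    measurement pipeline uses, so generator truth can cross-check it.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return 0.0
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]

    def half(points_list):
        chain: list[tuple[float, float]] = []
        for px, py in points_list:
            while len(chain) >= 2:
                ax, ay = chain[-2]
                bx, by = chain[-1]
                if (bx - ax) * (py - ay) - (by - ay) * (px - ax) <= 0:
                    chain.pop()
                else:
                    break
            chain.append((px, py))
        return chain

    pts_list = pts.tolist()
    lower = half(pts_list)
    upper = half(pts_list[::-1])
    hull = np.asarray(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        return 0.0
    x, y = hull[:, 0], hull[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


# ---------------------------------------------------------------------------
# rasterization


def _render_patch(
    archetype: CellArchetype,
    segments: list[TreeSegment],
    pixel_size_um: float,
) -> tuple[np.ndarray, int]:
    """Render one cell into a square float32 patch; returns (patch, centre)."""
    reach = archetype.body_radius_um
    for seg in segments:
        reach = max(reach, float(np.abs(seg.polyline_um).max()))
    extent = reach + archetype.process_thickness_um + 1.0
    c = int(np.ceil(extent / pixel_size_um))
    n = 2 * c + 1
    proc = np.zeros((n, n), dtype=bool)
    for seg in segments:
        px = np.rint(seg.polyline_um / pixel_size_um).astype(int) + c
        for (x0, y0), (x1, y1) in zip(px[:-1], px[1:]):
            rr, cc = draw_line(y0, x0, y1, x1)
            proc[rr, cc] = True
    r_dil = max(1, int(round(archetype.process_thickness_um / 2.0 / pixel_size_um)))
    if proc.any():
        proc = ndimage.binary_dilation(proc, structure=disk_footprint(r_dil))
    patch = np.zeros((n, n), dtype=np.float32)
    patch[proc] = archetype.intensity_process
    # half-pixel pull-in compensates rasterization/threshold bloom so the
    # detected body area tracks pi*r^2
    r_px = max(archetype.body_radius_um / pixel_size_um - 0.5, 1.0)
    rr, cc = draw_disk((c, c), r_px, shape=patch.shape)
    patch[rr, cc] = archetype.intensity_body
    return patch, c


def generate_cell(
    archetype: CellArchetype | str,
    seed: int,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[GroundTruthCell, np.ndarray]:
    """Generate one cell: its ground-truth record and a noise-free raster patch.

    Deterministic: the same archetype and seed always produce an identical
    truth record and identical pixels.
    """
    if isinstance(archetype, str):
        try:
            archetype = ARCHETYPES[archetype]
        except KeyError:
            raise ParameterError(f"unknown archetype {archetype!r}") from None
    rng = np.random.default_rng(seed)
    segments = _sample_tree(archetype, rng)
    truth = _truth_from_tree(archetype, segments)
    patch, _ = _render_patch(archetype, segments, pixel_size_um)
    return truth, patch


# ---------------------------------------------------------------------------
# tissue fields


@dataclass
class TissueSpec:
    """Geometry and population of one simulated tissue field."""

    width_px: int = 920
    height_px: int = 920
    n_planes: int = DEFAULT_N_PLANES
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    n_cells: int = 50
    archetype_mix: tuple[float, ...] = (0.24, 0.24, 0.24, 0.24, 0.04)
    background_level: float = 20.0
    noise_sd: float = 4.0
    min_cell_spacing_um: float = 0.0
    seed: int = 0
    allow_overlap: bool = False
    duplicate_fraction: float = 0.0
    archetypes: tuple[CellArchetype, ...] | None = None  # defaults to ARCHETYPES

    def __post_init__(self) -> None:
        mix = np.asarray(self.archetype_mix, dtype=float)
        if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
            raise ParameterError("archetype_mix must be a probability vector")
        if self.n_planes < 1 or self.min_cell_spacing_um < 0 or self.n_cells < 0:
            raise ParameterError("invalid tissue geometry")

    @property
    def n_subvolumes(self) -> int:
        return 3 if self.n_planes >= 3 else 1

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_size_um

    def archetype_list(self) -> tuple[CellArchetype, ...]:
        if self.archetypes is not None:
            return self.archetypes
        return tuple(ARCHETYPES[name] for name in ARCHETYPE_ORDER)


def _place_cells(
    rng: np.random.Generator,
    radii: np.ndarray,
    spec: TissueSpec,
    clearance_um: float = 2.0,
    max_tries: int = 4000,
) -> np.ndarray:
    """Rejection-sample centroids with non-overlap + spacing constraints.

    Cells are placed largest-first.  Raises :class:`PlacementError` naming
    the achievable count when the field is too crowded.
    """
    n = len(radii)
    w, h = spec.width_um, spec.height_um
    placed = np.empty((n, 2))
    order = np.argsort(-radii)
    pr = []  # placed radii
    for rank, i in enumerate(order):
        r = radii[i]
        margin = min(r + 1.0, min(w, h) / 2.0 - 1.0)
        ok = False
        for _ in range(max_tries):
            p = rng.uniform([margin, margin], [w - margin, h - margin])
            if rank:
                prev = placed[order[:rank]]
                d = np.hypot(*(prev - p).T)
                limit = np.maximum(
                    spec.min_cell_spacing_um,
                    0.0 if spec.allow_overlap else np.asarray(pr) + r + clearance_um,
                )
                if (d < limit).any():
                    continue
            ok = True
            break
        if not ok:
            raise PlacementError(n, rank)
        placed[i] = p
        pr.append(r)
    return placed


def generate_tissue(
    spec: TissueSpec,
    centroids_um: np.ndarray | None = None,
    render: bool = True,
) -> tuple[ImageStack | None, list[GroundTruthCell]]:
    """Generate one tissue field: an image stack plus its truth table.

    ``centroids_um`` overrides random placement (one row per cell; useful to
    plant edge-clipped cells).  With ``render=False`` only the truth list is
    produced and the stack is ``None``.
    """
    rng = np.random.default_rng(spec.seed)
    archetypes = spec.archetype_list()
    mix = np.asarray(spec.archetype_mix, dtype=float)
    if len(mix) != len(archetypes):
        raise ParameterError("archetype_mix length must match archetype list")

    choices = rng.choice(len(archetypes), size=spec.n_cells, p=mix)
    trees = [_sample_tree(archetypes[a], rng) for a in choices]
    truths = [
        _truth_from_tree(archetypes[a], t, cell_id=i)
        for i, (a, t) in enumerate(zip(choices, trees))
    ]
    radii = np.array([t.true_radius_um for t in truths]) if truths else np.empty(0)

    if spec.n_cells:
        if centroids_um is None:
            if not render and spec.min_cell_spacing_um == 0:
                # no raster -> arbors cannot collide; uniform placement
                w, h = spec.width_um, spec.height_um
                m = min(radii.max() + 1.0, min(w, h) / 4.0)
                centroids = rng.uniform([m, m], [w - m, h - m], size=(spec.n_cells, 2))
            else:
                centroids = _place_cells(rng, radii, spec)
        else:
            centroids = np.asarray(centroids_um, dtype=float)
            if centroids.shape != (spec.n_cells, 2):
                raise ParameterError("centroids_um must be (n_cells, 2)")
    else:
        centroids = np.empty((0, 2))

    n_sub = spec.n_subvolumes
    subvols = rng.integers(0, n_sub, size=spec.n_cells)
    for t, c, sv in zip(truths, centroids, subvols):
        t.centroid_um = (float(c[0]), float(c[1]))
        t.subvolume_index = int(sv)

    # planted duplicates: the same cell echoed on an adjacent sub-volume
    if spec.duplicate_fraction > 0 and n_sub > 1:
        n_dup = int(np.floor(spec.duplicate_fraction * spec.n_cells))
        dup_ids = rng.choice(spec.n_cells, size=n_dup, replace=False)
        next_id = spec.n_cells
        for i in dup_ids:
            src = truths[i]
            adj = src.subvolume_index + 1 if src.subvolume_index + 1 < n_sub else src.subvolume_index - 1
            jitter = rng.uniform(-1.0, 1.0, size=2)
            dup = dataclasses.replace(
                src,
                cell_id=next_id,
                centroid_um=(src.centroid_um[0] + jitter[0], src.centroid_um[1] + jitter[1]),
                subvolume_index=int(adj),
                duplicate_of=src.cell_id,
            )
            truths.append(dup)
            next_id += 1

    stack = None
    if render:
        from .imaging import partition_planes

        planes = np.full(
            (spec.n_planes, spec.height_px, spec.width_px),
            0.0,
            dtype=np.float32,
        )
        ranges = partition_planes(spec.n_planes, n_sub)
        for t in truths:
            arch = archetypes[choices[t.cell_id if t.duplicate_of is None else t.duplicate_of]]
            segs = truths[t.duplicate_of].segments if t.duplicate_of is not None else t.segments
            patch, c = _render_patch(arch, segs, spec.pixel_size_um)
            a, b = ranges[t.subvolume_index]
            plane = (a + b - 1) // 2
            row = int(round(t.centroid_um[1] / spec.pixel_size_um))
            col = int(round(t.centroid_um[0] / spec.pixel_size_um))
            r0, r1 = row - c, row + c + 1
            c0, c1 = col - c, col + c + 1
            pr0, pr1 = max(0, -r0), patch.shape[0] - max(0, r1 - spec.height_px)
            pc0, pc1 = max(0, -c0), patch.shape[1] - max(0, c1 - spec.width_px)
            if pr1 <= pr0 or pc1 <= pc0:
                continue
            tgt = planes[plane, max(0, r0) : max(0, r0) + pr1 - pr0,
                         max(0, c0) : max(0, c0) + pc1 - pc0]
            np.maximum(tgt, patch[pr0:pr1, pc0:pc1], out=tgt)
        planes += spec.background_level
        if spec.noise_sd > 0:
            planes += rng.normal(0.0, spec.noise_sd, size=planes.shape).astype(np.float32)
        np.clip(planes, 0.0, None, out=planes)
        stack = ImageStack(planes, spec.pixel_size_um, spec.z_step_um)
    return stack, truths


# ---------------------------------------------------------------------------
# truth tables


def truths_to_dataframe(truths: Iterable[GroundTruthCell]) -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append(
            {
                "cell_id": t.cell_id,
                "archetype": t.archetype,
                "centroid_x_um": t.centroid_um[0],
                "centroid_y_um": t.centroid_um[1],
                "subvolume_index": t.subvolume_index,
                "true_body_area_um2": t.true_body_area_um2,
                "true_cytoplasm_area_um2": t.true_cytoplasm_area_um2,
                "true_n_primary": t.true_n_primary,
                "true_n_secondary": t.true_n_secondary,
                "true_n_tertiary": t.true_n_tertiary,
                "true_n_segments": t.true_n_segments,
                "true_CI": t.true_CI,
                "true_CEA_um2": t.true_CEA_um2,
                "true_total_length_um": t.true_total_length_um,
                "true_radius_um": t.true_radius_um,
                "duplicate_of": t.duplicate_of,
            }
        )
    return pd.DataFrame(rows)


def truths_to_records(
    truths: Iterable[GroundTruthCell],
    animal_id: str = "a0",
    condition: str = "control",
    region: str = "uniform",
) -> pd.DataFrame:
    """Truth expressed in the measured-feature schema (see :mod:`morpho`).

    Used by cohort simulations that skip rendering: the generator's exact
    values stand in for measurements, so downstream filtering, clustering
    and statistics run on the same column contract.
    """
    rows = []
    for t in truths:
        pts = t.endpoints_absolute_um()
        if len(pts):
            hx0, hy0 = pts.min(axis=0)
            hx1, hy1 = pts.max(axis=0)
        else:
            hx0 = hx1 = t.centroid_um[0]
            hy0 = hy1 = t.centroid_um[1]
        r = np.sqrt(t.true_body_area_um2 / np.pi)
        rows.append(
            {
                "cell_id": t.cell_id,
                "animal_id": animal_id,
                "condition": condition,
                "region": region,
                "subvolume_index": t.subvolume_index,
                "centroid_x_um": t.centroid_um[0],
                "centroid_y_um": t.centroid_um[1],
                "body_area_um2": t.true_body_area_um2,
                "cytoplasm_area_um2": t.true_cytoplasm_area_um2,
                "roundness": 1.0,
                "mean_intensity": np.nan,
                "n_ramifications": t.true_n_segments,
                "total_ramification_length_um": t.true_total_length_um,
                "n_primary": t.true_n_primary,
                "n_secondary": t.true_n_secondary,
                "n_tertiary": t.true_n_tertiary,
                "n_segments": t.true_n_segments,
                "CI": t.true_CI,
                "CEA_um2": t.true_CEA_um2,
                "is_amoeboid": t.true_CI == 1.0,
                "hull_min_x_um": min(hx0, t.centroid_um[0] - r),
                "hull_max_x_um": max(hx1, t.centroid_um[0] + r),
                "hull_min_y_um": min(hy0, t.centroid_um[1] - r),
                "hull_max_y_um": max(hy1, t.centroid_um[1] + r),
            }
        )
    return pd.DataFrame(rows)


def write_tissue(
    out_tiff: str | Path,
    truth_csv: str | Path,
    stack: ImageStack,
    truths: list[GroundTruthCell],
    spec: TissueSpec,
) -> None:
    """Write stack (multi-page TIFF + YAML sidecar), truth CSV and spec echo."""
    from .imaging import write_stack

    write_stack(out_tiff, stack)
    truths_to_dataframe(truths).to_csv(truth_csv, index=False)
    spec_path = Path(truth_csv).with_suffix(".spec.yaml")
    payload = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(spec).items()
        if k != "archetypes"
    }
    spec_path.write_text(yaml.safe_dump(payload))


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class RegionPreset:
    archetype_mix: tuple[float, float, float, float, float]
    density_cells_per_mm2: float


#: regional mixes: cerebellum is dominated by compact low-CI/low-CEA and
#: amoeboid forms (lower mean CI and CEA, lower density than cortex)
REGION_PRESETS: dict[str, RegionPreset] = {
    "frontal_cortex": RegionPreset((0.30, 0.15, 0.15, 0.32, 0.08), 110.0),
    "hippocampus": RegionPreset((0.32, 0.12, 0.12, 0.36, 0.08), 100.0),
    "striatum": RegionPreset((0.28, 0.12, 0.25, 0.27, 0.08), 95.0),
    "cerebellum": RegionPreset((0.60, 0.05, 0.10, 0.05, 0.20), 55.0),
    "uniform": RegionPreset((0.24, 0.24, 0.24, 0.24, 0.04), 100.0),
}


@dataclass
class CohortSample:
    """One animal x region acquisition of a simulated cohort."""

    animal_id: str
    condition: str
    region: str
    stack: ImageStack | None
    truths: list[GroundTruthCell]
    records: pd.DataFrame


def generate_cohort(
    n_control: int,
    n_treated: int,
    regions: Sequence[str] = ("uniform",),
    region_presets: dict[str, RegionPreset] | None = None,
    treatment_effect: dict | None = None,
    seed: int = 0,
    cells_per_animal: int = 60,
    animal_cv: float = 0.25,
    ci_animal_cv: float = 0.08,
    cea_animal_cv: float = 0.10,
    render: bool = False,
) -> list[CohortSample]:
    """Simulate a two-condition animal cohort with regional presets.

    Treated animals have their cytoplasm-area parameters multiplied by
    ``treatment_effect['cytoplasm_factor']`` (default 2.0, emulating the
    roughly twofold cytoplasm enlargement after an inflammatory challenge).
    Animal-to-animal variability enters as lognormal random effects on size
    (``animal_cv``), branching (``ci_animal_cv``) and reach (``cea_animal_cv``).

    With ``render=False`` (the default) no raster is produced: the truth
    records, expressed in the measured-feature schema, are returned directly.
    Straight segments are used in that mode since polyline curvature only
    matters for rendering.
    """
    if n_control < 1 or n_treated < 1:
        raise ParameterError("need at least one animal per condition")
    presets = region_presets if region_presets is not None else REGION_PRESETS
    for r in regions:
        if r not in presets:
            raise ParameterError(f"unknown region preset {r!r}")
    effect = {"cytoplasm_factor": 2.0}
    if treatment_effect:
        effect.update(treatment_effect)

    ss = np.random.SeedSequence(seed)
    animal_seeds = ss.spawn(n_control + n_treated)
    base_archetypes = [ARCHETYPES[name] for name in ARCHETYPE_ORDER]
    samples: list[CohortSample] = []
    conditions = ["control"] * n_control + ["treated"] * n_treated
    for a_idx, (cond, a_ss) in enumerate(zip(conditions, animal_seeds)):
        rng = np.random.default_rng(a_ss)
        animal_id = f"{cond[:4]}{a_idx:02d}"
        size_mult = float(np.exp(rng.normal(0.0, animal_cv)))
        ci_mult = float(np.exp(rng.normal(0.0, ci_animal_cv)))
        len_mult = float(np.exp(rng.normal(0.0, cea_animal_cv)))
        if cond == "treated":
            size_mult *= effect["cytoplasm_factor"]
        archetypes = tuple(
            a.scaled(size_factor=size_mult, ci_factor=ci_mult, length_factor=len_mult)
            if not a.is_amoeboid
            else a.scaled(size_factor=size_mult)
            for a in base_archetypes
        )
        if not render:
            archetypes = tuple(
                dataclasses.replace(a, steps_per_segment=1) for a in archetypes
            )
        for region in regions:
            preset = presets[region]
            spec = TissueSpec(
                n_cells=cells_per_animal,
                archetype_mix=preset.archetype_mix,
                seed=int(rng.integers(2**31 - 1)),
                archetypes=archetypes,
                # field sized to the preset density
                width_px=int(
                    np.sqrt(cells_per_animal / preset.density_cells_per_mm2)
                    * 1000.0
                    / DEFAULT_PIXEL_SIZE_UM
                ),
                height_px=int(
                    np.sqrt(cells_per_animal / preset.density_cells_per_mm2)
                    * 1000.0
                    / DEFAULT_PIXEL_SIZE_UM
                ),
            )
            stack, truths = generate_tissue(spec, render=render)
            records = truths_to_records(truths, animal_id, cond, region)
            samples.append(CohortSample(animal_id, cond, region, stack, truths, records))
    return samples


def sample_ci_cea_mixture(
    weights: Sequence[float],
    means: Sequence[tuple[float, float]],
    sds: Sequence[tuple[float, float]],
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw (CI, CEA) from a Gaussian mixture with known component labels.

    A lightweight feature-space simulator for validating the clustering and
    sub-population stages against a planted mixture.
    """
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ParameterError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    means_a = np.asarray(means, dtype=float)
    sds_a = np.asarray(sds, dtype=float)
    vals = rng.normal(means_a[comp], sds_a[comp])
    vals = np.maximum(vals, [1.01, 1.0])
    return pd.DataFrame(
        {
            "CI": vals[:, 0],
            "CEA_um2": vals[:, 1],
            "component": comp,
            "is_amoeboid": False,
        }
    )
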