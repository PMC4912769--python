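"""End-to-end orchestration: stacks -> projections -> features -> filtered
table -> clustering / sub-populations -> statistics -> cartography.

Every stage logs its input/output counts; all randomness flows from the
seeds in the configuration; no stage mutates its input files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import carto, cluster, morpho, popfilter, stats, synth
from .errors import ConfigError, DataError
from .imaging import ImageStack, read_stack, split_and_project
from .popfilter import FilterConfig
from .segment import SegmentationParams, segment_projection, order_branches

logger = logging.getLogger("gliamorph")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "quantify_stack"]


@dataclass
class PipelineConfig:
    pixel_size_um: float = 0.19
    z_step_um: float = 2.0
    n_subvolumes: int = 3
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    filtering: FilterConfig = field(default_factory=FilterConfig)
    cluster_k: int = 4
    cluster_seed: int = 0
    cluster_n_init: int = 10
    include_amoeboid: bool = False
    out_dir: str = "gliamorph_out"
    simulate: dict | None = None  # preset/n_cells/seed/... for synthetic input

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ConfigError("calibration values must be positive")
        if self.cluster_k < 2:
            raise ConfigError("cluster_k must be >= 2")
        if not isinstance(self.segmentation, SegmentationParams):
            self.segmentation = SegmentationParams(**self.segmentation)
        if not isinstance(self.filtering, FilterConfig):
            try:
                self.filtering = FilterConfig(**self.filtering)
            except DataError as e:
                raise ConfigError(str(e)) from e

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text()) or {}
            return cls(**payload)
        except (TypeError, DataError) as e:
            raise ConfigError(f"invalid pipeline configuration: {e}") from e


@dataclass
class PipelineResult:
    records_raw: pd.DataFrame
    records: pd.DataFrame
    filter_counts: dict
    cutoffs: cluster.SubPopulationCutoffs | None
    model: cluster.ClusterModel | None
    subpopulations: pd.Series | None
    frequencies: pd.DataFrame | None
    reports: dict
    out_dir: Path | None


def quantify_stack(
    stack: ImageStack,
    config: PipelineConfig,
    animal_id: str = "a0",
    condition: str = "control",
    region: str = "na",
) -> pd.DataFrame:
    """Project a stack into sub-volumes and measure every cell."""
    n_sub = min(config.n_subvolumes, stack.n_planes)
    pset = split_and_project(stack, n_sub)
    frames = []
    offset = 0
    for sv, proj in enumerate(pset.projections):
        bodies, trees = segment_projection(proj, config.segmentation, stack.pixel_size_um)
        df = morpho.summarize_cells(
            proj,
            bodies,
            trees,
            config.segmentation,
            subvolume_index=sv,
            animal_id=animal_id,
            condition=condition,
            region=region,
            cell_id_offset=offset,
        )
        offset += bodies.n_bodies
        frames.append(df)
        logger.info(
            "projection %d/%d: %d bodies, %d trees", sv + 1, n_sub, bodies.n_bodies, len(trees)
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=morpho.FEATURE_COLUMNS)


def run_pipeline(
    config: PipelineConfig,
    stacks: list[tuple[str, ImageStack]] | None = None,
    stack_paths: list[str | Path] | None = None,
    features: pd.DataFrame | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run every stage on image stacks (or a pre-computed feature table).

    Inputs may be in-memory stacks, TIFF paths, or a feature CSV already
    produced by the quantification stage.
    """
    out_dir = Path(config.out_dir) if write_outputs else None
    log_handler = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
        log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(log_handler)
    try:
        return _run_pipeline_inner(config, stacks, stack_paths, features, out_dir)
    finally:
        if log_handler is not None:
            logger.removeHandler(log_handler)
            log_handler.close()


def _run_pipeline_inner(
    config: PipelineConfig,
    stacks,
    stack_paths,
    features,
    out_dir: Path | None,
) -> PipelineResult:

    bounds = None
    if features is None:
        collected: list[tuple[str, ImageStack]] = list(stacks or [])
        if stack_paths:
            collected += [(str(p), read_stack(p, config.pixel_size_um, config.z_step_um)) for p in stack_paths]
        if config.simulate is not None:
            sim = dict(config.simulate)
            preset_name = sim.pop("preset", "uniform")
            preset = synth.REGION_PRESETS.get(preset_name)
            if preset is None:
                raise ConfigError(f"unknown region preset {preset_name!r}")
            spec = synth.TissueSpec(
                archetype_mix=preset.archetype_mix,
                pixel_size_um=config.pixel_size_um,
                z_step_um=config.z_step_um,
                **sim,
            )
            stack, truths = synth.generate_tissue(spec)
            collected.append((f"simulated_{preset_name}", stack))
            if out_dir is not None:
                synth.truths_to_dataframe(truths).to_csv(out_dir / "truth.csv", index=False)
        if not collected:
            raise DataError("no input stacks and no feature table provided")
        frames = []
        for name, stack in collected:
            df = quantify_stack(stack, config, animal_id=name)
            frames.append(df)
            h, w = stack.shape_2d
            bounds = (0.0, 0.0, w * stack.pixel_size_um, h * stack.pixel_size_um)
        records_raw = pd.concat(frames, ignore_index=True)
    else:
        records_raw = features.copy()
    logger.info("quantified: %d cells", len(records_raw))

    report = popfilter.apply_all(records_raw, bounds, config.filtering)
    records = report.kept
    logger.info("filtering: %s", report.counts)

    cutoffs = model = labels = freqs = None
    reports: dict = {}
    control = records[records["condition"] == "control"] if "condition" in records.columns else records
    if len(control):
        try:
            cutoffs = cluster.compute_cutoffs(control, config.include_amoeboid)
        except DataError as e:
            logger.warning("cutoffs unavailable: %s", e)
    try:
        model = cluster.kmeans_ci_cea(
            records,
            k=config.cluster_k,
            seed=config.cluster_seed,
            n_init=config.cluster_n_init,
            include_amoeboid=config.include_amoeboid,
        )
    except DataError as e:
        logger.warning("clustering unavailable: %s", e)
    if cutoffs is not None:
        labels = cluster.assign_subpopulations(records, cutoffs, config.include_amoeboid)
        freqs = cluster.subpopulation_frequencies(labels, records)

    if "condition" in records.columns and records["condition"].nunique() == 2:
        summaries = stats.summarize_by_animal(records)
        conds = sorted(records["condition"].unique())
        ga = summaries[summaries["condition"] == conds[0]]
        gb = summaries[summaries["condition"] == conds[1]]
        for crit in ("body_area_um2", "cytoplasm_area_um2", "CI", "CEA_um2"):
            try:
                reports[crit] = stats.compare_two_groups(ga, gb, criterion=crit)
            except DataError:
                pass

    if out_dir is not None:
        records_raw.to_csv(out_dir / "features_raw.csv", index=False)
        records.to_csv(out_dir / "features_filtered.csv", index=False)
        report.rejected.to_csv(out_dir / "features_rejected.csv", index=False)
        if model is not None:
            model.save(out_dir / "cluster_model.json")
        if freqs is not None:
            freqs.to_csv(out_dir / "subpopulation_frequencies.csv", index=False)
        if labels is not None:
            ann = records.copy()
            ann["subpopulation"] = labels
            carto.render_cartography(
                ann,
                mode="subpopulation",
                pixel_size_um=config.pixel_size_um,
                out_png=out_dir / "cartography.png",
                out_csv=out_dir / "cartography.csv",
            )
        if reports:
            pd.DataFrame(
                [dataclasses.asdict(r) | {"criterion": k} for k, r in reports.items()]
            ).to_csv(out_dir / "group_tests.csv", index=False)
    return PipelineResult(
        records_raw=records_raw,
        records=records,
        filter_counts=report.counts,
        cutoffs=cutoffs,
        model=model,
        subpopulations=labels,
        frequencies=freqs,
        reports=reports,
        out_dir=out_dir,
    )
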