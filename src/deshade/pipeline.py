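"""End-to-end workflow: mask → classify → pretreat → indices → correlate →
select → model, from one config, with a manifest of hashed artifacts.

Outputs are a pure function of (inputs, config, seed): rerunning the same
config into a fresh directory reproduces byte-identical CSV/JSON artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    DEFAULT_STAGE1_KEEP,
    DEFAULT_STAGE2_KEEP,
    cascade_classify,
    class_pixel_stats,
    vegetation_mask,
)
from .indices import build_vi_table
from .io import SpectralCube, read_envi_cube, read_sample_table, write_envi_cube, write_sample_table
from .preprocess import PreprocessSpec
from .regression import combine_features, fit_predict
from .simulate import SceneConfig, generate_scene
from .stats import correlate_vi_lnc, select_sensitive

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Either ``cube_path`` + ``samples_path`` (ENVI header + CSV) or
    ``simulate`` (SceneConfig keyword overrides) must be given.
    """

    output_dir: str = "deshade_run"
    seed: int = 0
    cube_path: str | None = None
    samples_path: str | None = None
    simulate: dict | None = None
    pretreatments: list[dict] = field(
        default_factory=lambda: [{"method": "OS"}, {"method": "GFSG"}]
    )
    n_levels: int = 10
    level_mode: str = "equal_width"
    keep1: list[int] = field(default_factory=lambda: sorted(DEFAULT_STAGE1_KEEP))
    keep2: list[int] = field(default_factory=lambda: sorted(DEFAULT_STAGE2_KEEP))
    kmeans_k: int = 3
    roi_height: int = 30
    roi_width: int = 30
    alpha: float = 0.05
    min_abs_r: float = 0.2
    model_methods: list[str] = field(default_factory=lambda: ["MLR", "PCR", "PLSR", "SVMR"])
    test_fraction: float = 0.3
    write_cube: bool = True

    def __post_init__(self) -> None:
        if not self.pretreatments:
            raise ValueError("need at least one pretreatment")
        if not self.model_methods:
            raise ValueError("need at least one model method")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.simulate is None and (self.cube_path is None or self.samples_path is None):
            raise ValueError("config needs either simulate: or cube_path+samples_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, index=index, lineterminator="\n")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    seed = int(config.seed)

    # --- input stage ---------------------------------------------------------
    stage = "input"
    try:
        if config.simulate is not None:
            scene_kwargs = dict(config.simulate)
            scene_kwargs.setdefault("seed", seed)
            scene_cfg = SceneConfig(**scene_kwargs)
            cube, truth = generate_scene(scene_cfg)
            samples = truth.sample_points
            artifacts.append(write_sample_table(samples, outdir / "samples.csv"))
            if config.write_cube:
                hdr = write_envi_cube(cube, outdir / "cube.hdr", dtype="float32")
                artifacts += [hdr, hdr.with_suffix(".img")]
        else:
            cube = read_envi_cube(config.cube_path)
            samples = read_sample_table(config.samples_path)
    except (ValueError, OSError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- vegetation mask -----------------------------------------------------
    stage = "mask"
    try:
        mask = vegetation_mask(cube, k=config.kmeans_k, seed=seed)
        artifacts.append(_write_csv(class_pixel_stats(mask), outdir / "mask_stats.csv"))
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- two-stage classification -------------------------------------------
    stage = "classify"
    try:
        stage1, stage2 = cascade_classify(
            cube,
            mask,
            stage1_keep=config.keep1,
            n_levels=config.n_levels,
            mode=config.level_mode,
        )
        for pm, name in ((stage1, "stage1"), (stage2, "stage2")):
            label_cube = SpectralCube(
                pm.labels[:, :, None].astype(float), np.array([0.0]), origin_note=name
            )
            hdr = write_envi_cube(label_cube, outdir / f"classmap_{name}.hdr", dtype="int16", scale_factor=1)
            artifacts += [hdr, hdr.with_suffix(".img")]
            artifacts.append(
                _write_csv(class_pixel_stats(pm), outdir / f"classmap_{name}_stats.csv")
            )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- VI tables per class × pretreatment ----------------------------------
    stage = "indices"
    roi_shape = (config.roi_height, config.roi_width)
    vi_tables: dict[tuple[str, str], pd.DataFrame] = {}
    try:
        for pdict in config.pretreatments:
            pre = PreprocessSpec(**pdict)
            groups: dict[str, tuple] = {"all": (None, None), "veg": (mask, None)}
            for lv in config.keep2:
                groups[f"2-{lv}"] = (stage2, lv)
            for cls, (pixmap, lv) in groups.items():
                table = build_vi_table(
                    cube,
                    samples,
                    pixmap,
                    levels=lv,
                    pretreat=pre,
                    roi_shape=roi_shape,
                )
                if not len(table):
                    raise ValueError(f"no sample rows for class {cls} ({pre.method})")
                vi_tables[(cls, pre.method)] = table
                artifacts.append(
                    _write_csv(table, outdir / f"vi_{cls}_{pre.method}.csv", index=True)
                )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- correlation screening ------------------------------------------------
    stage = "correlate"
    try:
        report = correlate_vi_lnc(
            list(vi_tables.values()), class_names=[cls for cls, _ in vi_tables]
        )
        artifacts.append(_write_csv(report, outdir / "correlations.csv"))
        last_method = config.pretreatments[-1]["method"]
        class_report = report[
            (report["method"] == last_method)
            & (report["class"].str.startswith("2-"))
        ]
        sensitive = select_sensitive(class_report, config.alpha, config.min_abs_r)
        with open(outdir / "sensitive_indices.json", "w") as fh:
            json.dump(
                {"alpha": config.alpha, "min_abs_r": config.min_abs_r, "per_class": sensitive.per_class},
                fh,
                indent=2,
                sort_keys=True,
            )
        artifacts.append(outdir / "sensitive_indices.json")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- regression -----------------------------------------------------------
    stage = "model"
    try:
        last_method = config.pretreatments[-1]["method"]
        class_tables = {
            cls: tab
            for (cls, m), tab in vi_tables.items()
            if m == last_method and cls.startswith("2-")
        }
        features = combine_features(class_tables, sensitive)
        reports = []
        for meth in config.model_methods:
            try:
                rep = fit_predict(
                    features,
                    meth,
                    seed=seed,
                    test_fraction=config.test_fraction,
                    keep_predictions=True,
                )
            except ValueError as exc:
                logger.warning("model %s skipped: %s", meth, exc)
                continue
            reports.append(rep)
            artifacts.append(
                _write_csv(rep.predictions, outdir / f"predictions_{meth}.csv")
            )
        if not reports:
            raise ValueError("no model could be fitted")
        with open(outdir / "model_reports.json", "w") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=2, sort_keys=True)
        artifacts.append(outdir / "model_reports.json")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- manifest --------------------------------------------------------------
    stage = "manifest"
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
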