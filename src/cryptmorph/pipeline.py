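"""End-to-end pipeline: simulate/load -> segment -> features -> statistics.

``run_pipeline`` sequences the stages over either a synthetic cohort
design or a directory of grayscale TIFFs, writes all intermediate and
final tables, and records a manifest (config hash, per-stage counts,
checksums of every output file, warnings).  Given a fixed seed the run
is fully deterministic, down to the bytes of the CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortDataset, CohortDesign, CohortSpec, generate_cohort_dataset
from .images import (
    DEFAULT_PITCH_UM,
    GrayImage,
    read_gray_image,
    rescale_intensity,
    write_gray_image,
    write_label_map,
)
from .morphometry import compute_features, extract_crypts, summarize_image
from .segmentation import (
    AnnotationSet,
    ThresholdParams,
    default_grid,
    optimize_thresholds,
    segment_image,
)
from .stats import per_depth_cohort_tests, run_feature_screen

logger = logging.getLogger("cryptmorph")

HIERARCHY_COLUMNS = ["cohort", "mouse", "location", "depth_um", "image_id"]


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``design`` (synthetic generation) or ``input_dir``
    (directory of TIFFs) must be set.  With ``threshold_grid`` the
    binarization parameters are optimized against annotations
    (ground-truth centroids for synthetic runs); with ``thresholds`` a
    fixed parameter set is applied.
    """

    output_dir: Path
    design: CohortDesign | None = None
    input_dir: Path | None = None
    thresholds: ThresholdParams | None = None
    threshold_grid: list[ThresholdParams] | None = None
    pixel_pitch_um: float = DEFAULT_PITCH_UM
    seed: int = 0
    write_images: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.design is None) == (self.input_dir is None):
            raise PipelineConfigError(
                "exactly one input source (design or input_dir) must be set"
            )
        if self.thresholds is None and self.threshold_grid is None:
            self.threshold_grid = default_grid()
        self.output_dir = Path(self.output_dir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)

    def to_dict(self) -> dict:
        d: dict = dict(
            output_dir=str(self.output_dir),
            pixel_pitch_um=self.pixel_pitch_um,
            seed=self.seed,
            write_images=self.write_images,
            log_level=self.log_level,
        )
        if self.input_dir is not None:
            d["input_dir"] = str(self.input_dir)
        if self.design is not None:
            d["design"] = dict(
                seed=self.design.seed,
                scene_overrides=dict(self.design.scene_overrides),
                cohorts=[
                    dict(
                        name=c.name,
                        n_mice=c.n_mice,
                        n_stacks=c.n_stacks,
                        phenotype=c.phenotype,
                        depths_um=list(c.depths_um),
                        images_per_location=c.images_per_location,
                    )
                    for c in self.design.cohorts
                ],
            )
        if self.thresholds is not None:
            d["thresholds"] = vars(self.thresholds).copy()
        if self.threshold_grid is not None:
            d["threshold_grid"] = [vars(t).copy() for t in self.threshold_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        design = None
        if "design" in d:
            dd = d.pop("design")
            design = CohortDesign(
                cohorts=tuple(
                    CohortSpec(
                        name=c["name"],
                        n_mice=c["n_mice"],
                        n_stacks=c["n_stacks"],
                        phenotype=c.get("phenotype", "normal"),
                        depths_um=tuple(c.get("depths_um", (20, 40, 60, 80, 100))),
                        images_per_location=c.get("images_per_location", 1),
                    )
                    for c in dd["cohorts"]
                ),
                seed=dd.get("seed", 0),
                scene_overrides=dd.get("scene_overrides", {}),
            )
        thresholds = None
        if "thresholds" in d:
            thresholds = ThresholdParams(**d.pop("thresholds"))
        grid = None
        if "threshold_grid" in d:
            grid = [ThresholdParams(**g) for g in d.pop("threshold_grid")]
        return cls(design=design, thresholds=thresholds, threshold_grid=grid, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


@dataclass
class RunManifest:
    """Record of one pipeline run: what ran, what it wrote, checksums."""

    config_hash: str
    version: str
    seed: int
    stages: dict = dc_field(default_factory=dict)
    outputs: dict = dc_field(default_factory=dict)  # path -> sha256
    warnings: list = dc_field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(vars(self), fh, indent=2, sort_keys=True)
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _load_input_dir(config: PipelineConfig) -> list[GrayImage]:
    paths = sorted(config.input_dir.glob("*.tif")) + sorted(
        config.input_dir.glob("*.tiff")
    )
    if not paths:
        raise PipelineConfigError(f"no TIFF images found in {config.input_dir}")
    images = []
    for p in paths:
        img = read_gray_image(p, pitch_um=config.pixel_pitch_um)
        img.metadata.setdefault("image_id", p.stem)
        images.append(img)
    return images


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and return its manifest."""
    logging.basicConfig(level=config.log_level)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), version=__version__, seed=config.seed
    )
    config.to_yaml(out / "config.yaml")

    # --- stage 1: simulate or load -------------------------------------
    dataset: CohortDataset | None = None
    annotations: dict[str, AnnotationSet] = {}
    if config.design is not None:
        design = config.design
        if design.seed != config.seed:
            design = CohortDesign(
                cohorts=design.cohorts,
                seed=config.seed,
                scene_overrides=design.scene_overrides,
            )
        dataset = generate_cohort_dataset(design)
        images = [r.scene.image for r in dataset]
        truth_rows = []
        img_dir = out / "images"
        for r in dataset:
            pitch = r.scene.image.pixel_pitch_um
            annotations[r.image_id] = AnnotationSet(
                r.scene.truth.centroids_in_px(pitch), annotator="ground_truth"
            )
            if r.scene.shortfall:
                manifest.warnings.append(
                    f"{r.image_id}: placement shortfall of {r.scene.shortfall} crypts"
                )
            for k, g in enumerate(r.scene.truth.crypts, start=1):
                truth_rows.append(
                    dict(
                        image_id=r.image_id,
                        crypt=k,
                        x_um=g.center_um[0],
                        y_um=g.center_um[1],
                        a_um=g.a_um,
                        b_um=g.b_um,
                        orientation_rad=g.orientation_rad,
                    )
                )
            if config.write_images:
                img_dir.mkdir(exist_ok=True)
                safe = r.image_id.replace("/", "_").replace(" ", "")
                write_gray_image(img_dir / f"{safe}.tif", r.scene.image)
        pd.DataFrame(
            truth_rows,
            columns=["image_id", "crypt", "x_um", "y_um", "a_um", "b_um", "orientation_rad"],
        ).to_csv(out / "ground_truth.csv", index=False)
        manifest.stages["simulate"] = dict(
            n_images=len(images),
            n_stacks=design.total_stacks,
            n_mice=design.total_mice,
        )
    else:
        images = _load_input_dir(config)
        manifest.stages["load"] = dict(n_images=len(images))

    # --- stage 2: threshold selection ----------------------------------
    if config.thresholds is not None:
        params = config.thresholds
        manifest.stages["thresholds"] = dict(source="fixed", **vars(params))
    else:
        norm = [rescale_intensity(im) for im in images]
        ann = [
            annotations.get(im.metadata.get("image_id", ""), None) for im in images
        ]
        usable = [(n, a) for n, a in zip(norm, ann) if a is not None and len(a) > 0]
        if not usable:
            raise PipelineConfigError(
                "threshold optimization needs annotations; provide fixed "
                "thresholds for unannotated inputs"
            )
        params, best_cds = optimize_thresholds(
            [u[0] for u in usable], [u[1] for u in usable], config.threshold_grid
        )
        manifest.stages["thresholds"] = dict(
            source="grid", pooled_cds=best_cds, grid_size=len(config.threshold_grid),
            **vars(params),
        )
    logger.info("thresholds: %s", params)

    # --- stage 3: segment + features + summaries -----------------------
    feature_frames = []
    summary_rows = []
    lab_dir = out / "labels"
    for im in images:
        norm = rescale_intensity(im)
        if norm.degenerate:
            manifest.warnings.append(
                f"{im.metadata.get('image_id', '?')}: constant image, degenerate rescale"
            )
        labels = segment_image(norm, params)
        crypts = extract_crypts(labels)
        feats = compute_features(crypts, im.pixel_pitch_um)
        meta = {k: im.metadata.get(k) for k in HIERARCHY_COLUMNS}
        summary_rows.append(summarize_image(feats, meta))
        feats.insert(0, "image_id", im.metadata.get("image_id"))
        feature_frames.append(feats)
        if config.write_images:
            lab_dir.mkdir(exist_ok=True)
            safe = str(im.metadata.get("image_id", "img")).replace("/", "_").replace(" ", "")
            write_label_map(lab_dir / f"{safe}_labels.tif", labels)
    features_df = (
        pd.concat(feature_frames, ignore_index=True)
        if feature_frames
        else pd.DataFrame()
    )
    summaries = pd.DataFrame(summary_rows)
    features_df.to_csv(out / "crypt_features.csv", index=False)
    summaries.to_csv(out / "image_summaries.csv", index=False)
    manifest.stages["features"] = dict(
        n_images=len(summaries), n_crypts=int(len(features_df))
    )

    # --- stage 4: statistics -------------------------------------------
    stats_done = False
    if "cohort" in summaries.columns and summaries["cohort"].nunique() >= 2:
        try:
            anova_df, tukey_df = run_feature_screen(summaries)
            anova_df.to_csv(out / "anova_screen.csv", index=False)
            tukey_df.to_csv(out / "tukey_screen.csv", index=False)
            sig = (
                tukey_df[tukey_df["flag"] != "ns"]
                .loc[:, ["feature", "statistic", "group_i", "group_j", "p_adj", "flag"]]
                .to_dict(orient="records")
            )
            with open(out / "significant_pairs.json", "w") as fh:
                json.dump(
                    {"alpha": 0.05, "note": "p-values unadjusted across feature screens",
                     "pairs": sig},
                    fh, indent=2, sort_keys=True,
                )
            stats_done = True
            manifest.stages["stats"] = dict(
                n_screens=len(anova_df), n_significant_pairs=len(sig)
            )
            if summaries["depth_um"].nunique() > 1:
                depth_rows = []
                for col in [c for c in summaries.columns if c.endswith(("_mean", "_sd"))]:
                    try:
                        per_depth = per_depth_cohort_tests(summaries, response=col)
                    except Exception as exc:  # degenerate slices stay out of the report
                        manifest.warnings.append(f"per-depth {col}: {exc}")
                        continue
                    for depth, (res, tk) in per_depth.items():
                        t = res["cohort"]
                        depth_rows.append(
                            dict(response=col, depth_um=depth, F=t.F, p=t.p,
                                 df_num=t.df_num, df_den=t.df_den)
                        )
                pd.DataFrame(depth_rows).to_csv(out / "per_depth_anova.csv", index=False)
        except Exception as exc:
            manifest.warnings.append(f"stats stage skipped: {exc}")
    if not stats_done and "stats" not in manifest.stages:
        manifest.stages["stats"] = dict(skipped=True)

    # --- manifest -------------------------------------------------------
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.outputs[str(p.relative_to(out))] = _sha256(p)
    manifest.to_json(out / "manifest.json")
    return manifest
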