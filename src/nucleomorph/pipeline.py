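"""End-to-end orchestration: config, manifest, full runs, overlays, CSV I/O.

Outputs are deterministic byte-for-byte for a fixed input set, config and
seed: every CSV is written with a fixed 9-significant-digit float format and
carries a comment header with the tool version and the SHA-256 hash of the
effective configuration.
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
from .classifier import (
    DYSMORPHIC,
    ClassificationResult,
    FeatureLimits,
    classify,
    load_model,
)
from .contours import NucleusBoundary
from .features import DEFAULT_CURVATURE_WINDOW, ShapeFeatures, compute_features
from .image import ImageGrid, load_image
from .reporting import summarize_sample
from .segmentation import KEPT, SegmentationConfig, SnakeConfig, segment_image

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.9g"

OUTLINE_COLORS = {
    "normal": (0, 255, 0),        # green
    "dysmorphic": (255, 0, 0),    # red
    "excluded": (255, 165, 0),    # orange — red is reserved for dysmorphic
}


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys."""


@dataclass
class ClassifierBlock:
    model_path: str | None = None
    step1_mode: str = "any"
    curvature_window: int = DEFAULT_CURVATURE_WINDOW


@dataclass
class ReportingBlock:
    interval_level: float = 0.95


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classifier: ClassifierBlock = field(default_factory=ClassifierBlock)
    reporting: ReportingBlock = field(default_factory=ReportingBlock)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _build_dataclass(cls, data: dict, path: str = ""):
    """Instantiate nested config dataclasses, rejecting unknown keys."""
    field_types = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(field_types)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} under '{path or 'root'}'; "
            f"valid keys: {sorted(field_types)}"
        )
    kwargs = {}
    for name, value in data.items():
        f = field_types[name]
        if dataclasses.is_dataclass(f.type) and isinstance(value, dict):
            kwargs[name] = _build_dataclass(f.type, value, f"{path}.{name}".strip("."))
        elif isinstance(value, dict) and name in ("segmentation", "classifier", "reporting", "snake"):
            target = {
                "segmentation": SegmentationConfig,
                "classifier": ClassifierBlock,
                "reporting": ReportingBlock,
                "snake": SnakeConfig,
            }[name]
            kwargs[name] = _build_dataclass(target, value, f"{path}.{name}".strip("."))
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return _build_dataclass(PipelineConfig, data)


@dataclass
class ManifestRow:
    image_path: str
    image_id: str
    coverslip_id: str = ""
    individual_id: str = ""
    group: str = ""
    age_at_biopsy: float = float("nan")
    onset_age: float = float("nan")


def load_manifest(path: str | Path) -> list[ManifestRow]:
    df = pd.read_csv(path, comment="#")
    required = {"image_path", "image_id"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"manifest missing required columns: {sorted(missing)}")
    if df["image_id"].duplicated().any():
        dupes = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
        raise ConfigError(f"duplicate image_ids in manifest: {dupes}")
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            ManifestRow(
                image_path=str(rec["image_path"]),
                image_id=str(rec["image_id"]),
                coverslip_id=str(rec.get("coverslip_id", "") or ""),
                individual_id=str(rec.get("individual_id", "") or ""),
                group=str(rec.get("group", "") or ""),
                age_at_biopsy=float(rec.get("age_at_biopsy", float("nan"))),
                onset_age=float(rec.get("onset_age", float("nan"))),
            )
        )
    for row in rows:
        if not Path(row.image_path).exists():
            raise FileNotFoundError(f"manifest references missing file: {row.image_path}")
    return rows


def write_csv(df: pd.DataFrame, path: str | Path, config_hash: str) -> None:
    """CSV with a provenance comment header and fixed float formatting."""
    path = Path(path)
    header = f"# nucleomorph {__version__} config_hash={config_hash}\n"
    path.write_text(header + df.to_csv(index=False, float_format=FLOAT_FORMAT))


def boundaries_to_frame(boundaries: list[NucleusBoundary]) -> pd.DataFrame:
    rows = []
    for b in boundaries:
        for i, (x, y) in enumerate(b.points):
            rows.append((b.source_image_id, b.nucleus_id, i, x, y))
    return pd.DataFrame(rows, columns=["image_id", "nucleus_id", "point_index", "x", "y"])


def features_to_frame(
    entries: list[tuple[str, int, ShapeFeatures]], pixel_size_um: float
) -> pd.DataFrame:
    rows = []
    for image_id, nucleus_id, f in entries:
        rows.append(
            {
                "image_id": image_id,
                "nucleus_id": nucleus_id,
                "area_px2": f.area_a,
                "area_um2": f.area_a * pixel_size_um**2,
                "hull_area": f.hull_area_h,
                "rc": f.rc,
                "mnc": f.mnc,
                "nc_max": f.nc_max,
                "eccentricity": f.eccentricity,
                "orientation": f.orientation,
                "centroid_x": f.centroid[0],
                "centroid_y": f.centroid[1],
                "n_negative_points": f.n_negative_points,
            }
        )
    return pd.DataFrame(rows)


def write_overlay(
    image: ImageGrid,
    boundaries: list[NucleusBoundary],
    calls: dict[int, str],
    path: str | Path,
    excluded_boundaries: list[NucleusBoundary] | None = None,
) -> np.ndarray:
    """PNG overlay: normal nuclei green, dysmorphic red, excluded orange."""
    import imageio.v3 as iio

    gray = (image.pixels.astype(float) / image.saturation_level * 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)

    def draw(boundary: NucleusBoundary, color: tuple[int, int, int]) -> None:
        pts = np.rint(boundary.points).astype(int)
        cols = np.clip(pts[:, 0], 0, rgb.shape[1] - 1)
        rows = np.clip(pts[:, 1], 0, rgb.shape[0] - 1)
        rgb[rows, cols] = color

    for b in boundaries:
        label = calls.get(b.nucleus_id, "normal")
        draw(b, OUTLINE_COLORS[DYSMORPHIC if label == DYSMORPHIC else "normal"])
    for b in excluded_boundaries or []:
        draw(b, OUTLINE_COLORS["excluded"])
    iio.imwrite(Path(path), rgb)
    return rgb


@dataclass
class PipelineResult:
    out_dir: Path
    n_images: int
    n_nuclei: int
    calls: list[ClassificationResult]
    features: list[tuple[str, int, ShapeFeatures]]


def run_pipeline(
    config: PipelineConfig,
    manifest: list[ManifestRow],
    out_dir: str | Path,
    limits: FeatureLimits | None = None,
    images: dict[str, ImageGrid] | None = None,
    write_overlays: bool = True,
) -> PipelineResult:
    """Segment, featurize, classify and summarize every manifest image.

    ``images`` may pre-supply in-memory frames keyed by image_id (used by the
    synthetic path and tests); otherwise frames are loaded from image_path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    if limits is None:
        if config.classifier.model_path is None:
            raise ConfigError("no classifier limits: set classifier.model_path or pass limits")
        limits = load_model(config.classifier.model_path)

    all_boundaries: list[NucleusBoundary] = []
    feature_entries: list[tuple[str, int, ShapeFeatures]] = []
    calls: list[ClassificationResult] = []
    call_rows = []
    object_rows = []
    failed_image = None
    try:
        for row in manifest:
            if images and row.image_id in images:
                frames = [images[row.image_id]]
            else:
                frames = load_image(row.image_path)
            for frame in frames:
                frame.image_id = frame.image_id or row.image_id
                objects, boundaries = segment_image(frame, config.segmentation)
                for obj in objects:
                    minr, minc, maxr, maxc = obj.bounding_box
                    object_rows.append(
                        (frame.image_id, obj.id, obj.status, obj.area, minr, minc, maxr, maxc)
                    )
                img_calls: dict[int, str] = {}
                for b in boundaries:
                    feats = compute_features(b, window=config.classifier.curvature_window)
                    result = classify(
                        feats, limits,
                        nucleus_id=b.nucleus_id,
                        step1_mode=config.classifier.step1_mode,
                    )
                    feature_entries.append((frame.image_id, b.nucleus_id, feats))
                    calls.append(result)
                    img_calls[b.nucleus_id] = result.predicted_label
                    call_rows.append(
                        (
                            frame.image_id, b.nucleus_id, result.predicted_label,
                            result.deciding_step, *result.feature_snapshot,
                        )
                    )
                all_boundaries.extend(boundaries)
                if write_overlays:
                    overlay_dir = out_dir / "overlays"
                    overlay_dir.mkdir(exist_ok=True)
                    write_overlay(
                        frame, boundaries, img_calls,
                        overlay_dir / f"{frame.image_id}.png",
                    )
    except Exception:
        failed_image = row.image_id
        raise
    finally:
        # partial outputs are preserved on failure
        write_csv(boundaries_to_frame(all_boundaries), out_dir / "boundaries.csv", chash)
        write_csv(
            features_to_frame(feature_entries, pixel_size_um=_pixel_size(manifest, images)),
            out_dir / "features.csv", chash,
        )
        write_csv(
            pd.DataFrame(
                call_rows,
                columns=[
                    "image_id", "nucleus_id", "predicted_label", "deciding_step",
                    "rc", "mnc", "nc_max",
                ],
            ),
            out_dir / "calls.csv", chash,
        )
        write_csv(
            pd.DataFrame(
                object_rows,
                columns=[
                    "image_id", "object_id", "status", "area",
                    "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col",
                ],
            ),
            out_dir / "objects.csv", chash,
        )
        _write_summaries(manifest, call_rows, feature_entries, out_dir, chash)
        run_log = {
            "version": __version__,
            "config_hash": chash,
            "config": config.to_dict(),
            "n_images": len(manifest),
            "n_nuclei": len(calls),
            "failed_image": failed_image,
        }
        (out_dir / "run.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))

    return PipelineResult(
        out_dir=out_dir,
        n_images=len(manifest),
        n_nuclei=len(calls),
        calls=calls,
        features=feature_entries,
    )


def _pixel_size(manifest: list[ManifestRow], images: dict[str, ImageGrid] | None) -> float:
    if images:
        return next(iter(images.values())).pixel_size_um
    from .image import DEFAULT_PIXEL_SIZE_UM

    return DEFAULT_PIXEL_SIZE_UM


def _write_summaries(manifest, call_rows, feature_entries, out_dir: Path, chash: str) -> None:
    if not call_rows:
        return
    calls_df = pd.DataFrame(
        call_rows,
        columns=["image_id", "nucleus_id", "predicted_label", "deciding_step",
                 "rc", "mnc", "nc_max"],
    )
    feats_df = pd.DataFrame(
        [
            {
                "image_id": iid, "nucleus_id": nid,
                "area": f.area_a, "eccentricity": f.eccentricity, "mnc": f.mnc,
            }
            for iid, nid, f in feature_entries
        ]
    )
    meta = pd.DataFrame(
        [
            {"image_id": r.image_id, "coverslip_id": r.coverslip_id,
             "individual_id": r.individual_id, "group": r.group,
             "age_at_biopsy": r.age_at_biopsy}
            for r in manifest
        ]
    )
    merged = (
        calls_df[["image_id", "nucleus_id", "predicted_label"]]
        .merge(feats_df, on=["image_id", "nucleus_id"])
        .merge(meta, on="image_id", how="left")
    )
    for level in ("coverslip_id", "individual_id"):
        groups = []
        for key, grp in merged.groupby(level):
            if not key:
                continue
            dys = grp["predicted_label"] == DYSMORPHIC
            groups.append(
                {
                    level: key,
                    "n_nuclei": len(grp),
                    "n_dysmorphic": int(dys.sum()),
                    "percent_dysmorphic": 100.0 * dys.mean(),
                    "mean_area": grp["area"].mean(),
                    "mean_eccentricity": grp["eccentricity"].mean(),
                    "mean_mnc": grp["mnc"].mean(),
                    "age_at_biopsy": grp["age_at_biopsy"].iloc[0],
                }
            )
        if groups:
            write_csv(
                pd.DataFrame(groups), out_dir / f"summary_by_{level}.csv", chash
            )
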