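"""End-to-end orchestration: images -> filters -> masks -> metric CSVs -> report.

For every subject/visit the pipeline computes

1. large-vessel perfusion density from the superficial slab,
2. per-filter perfusion density for the superficial and deep slabs
   (the large-vessel mask is computed once per eye from the superficial
   slab and reused),
3. choriocapillaris flow-void metrics at each threshold multiplier, with
   the superficial large vessels and the optic disc excluded,

each split into the macular and peripheral regions, and then the
inter-visit repeatability report over the paired visits. Reruns with the
same configuration and seed are byte-identical. Per-image failures are
collected; a failed image excludes that subject from the paired statistics
for the affected metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as oio
from .filters import FILTER_NAMES, apply_filter
from .flowvoids import FlowVoidParams, detect_flow_voids, prepare_cc
from .regions import make_partition
from .segment import (
    BinarizeParams,
    LargeVesselParams,
    local_adaptive_binarize,
    perfusion_density,
    segment_large_vessels,
)
from .stats import build_report

log = logging.getLogger("octarep")

REFERENCE_VARIANTS = {
    "pd_percent": "none",
    "fv_area_percent": "k=1",
    "fv_count": "k=1",
    "fv_size_um2": "k=1",
}

LONG_COLUMNS = ["subject_id", "visit", "eye", "slab", "region", "variant",
                "metric", "value"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    manifest: str = ""
    out_dir: str = "results"
    filters: tuple[str, ...] = FILTER_NAMES
    window_mm: float = 1.25
    binarize_offset: float = 0.0
    macula_size_mm: float = 6.0
    k_sds: tuple[float, ...] = (1.0, 1.25)
    fv_connectivity: int = 8
    fv_min_component_px: int = 1
    lv_band_um: tuple[float, float] = (30.0, 200.0)
    lv_mean_factor: float = 2.0
    lv_min_component_px: int = 50
    icc_form: str = "ICC2"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for f in self.filters:
            if f not in FILTER_NAMES:
                raise ValueError(f"unknown filter {f!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("filters", "k_sds", "lv_band_um"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _variant_for_k(k: float) -> str:
    return f"k={k:g}"


def process_eye(
    images: dict[str, oio.EnFaceAngiogram],
    config: PipelineConfig,
    fovea_center_px=None,
    disc_mask=None,
) -> list[dict]:
    """Metric rows for one subject/visit given its per-slab images."""
    rows: list[dict] = []
    any_img = next(iter(images.values()))
    partition = make_partition(
        any_img.shape, (any_img.pitch_y_um, any_img.pitch_x_um),
        fovea_center_px, config.macula_size_mm,
    )
    region_masks = {"macula": partition.macula, "periphery": partition.periphery}
    bin_params = BinarizeParams(window_mm=config.window_mm, offset=config.binarize_offset)
    lv_params = LargeVesselParams(
        band_um=config.lv_band_um,
        mean_factor=config.lv_mean_factor,
        min_component_px=config.lv_min_component_px,
    )

    def emit(img, region, variant, metric, value):
        rows.append({
            "subject_id": img.subject_id, "visit": img.visit, "eye": img.eye,
            "slab": img.slab, "region": region, "variant": variant,
            "metric": metric, "value": value,
        })

    large_mask = None
    if "SCP" in images:
        scp = images["SCP"]
        large_mask = segment_large_vessels(scp, lv_params)
        for rname, rmask in region_masks.items():
            pd_res = perfusion_density(large_mask, rmask, region_name=rname,
                                       slab="SCP", vessel_class="large")
            emit(scp, rname, "combined", "pd_large_percent", pd_res.value_percent)

    for slab in ("SCP", "DCP"):
        if slab not in images:
            continue
        img = images[slab]
        for fname in config.filters:
            filtered = apply_filter(img, fname)
            vessels = local_adaptive_binarize(filtered, bin_params)
            for rname, rmask in region_masks.items():
                pd_res = perfusion_density(vessels, rmask, region_name=rname,
                                           slab=slab, filter=fname)
                emit(img, rname, fname, "pd_percent", pd_res.value_percent)

    if "CC" in images:
        cc = images["CC"]
        cc_img, analysable = prepare_cc(cc, large_vessels=large_mask, disc=disc_mask)
        for k in config.k_sds:
            params = FlowVoidParams(
                k_sd=k, connectivity=config.fv_connectivity,
                min_component_px=config.fv_min_component_px,
            )
            _, metrics = detect_flow_voids(cc_img, analysable, params, partition)
            for rname, m in metrics.items():
                variant = _variant_for_k(k)
                emit(cc, rname, variant, "fv_area_percent", m.area_percent)
                emit(cc, rname, variant, "fv_count", float(m.count))
                emit(cc, rname, variant, "fv_size_um2", m.mean_size_um2)
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline over a cohort manifest.

    Writes ``metrics_long.csv`` (one row per measurement) and
    ``repeatability_report.csv`` into ``config.out_dir`` and returns the
    two DataFrames plus the list of per-image failures.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    manifest = oio.read_manifest(config.manifest)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_rows: list[dict] = []
    failures: list[dict] = []
    for (sid, visit), grp in manifest.groupby(["subject_id", "visit"], sort=True):
        try:
            images = {}
            fovea = None
            disc = None
            for _, row in grp.iterrows():
                img = oio.read_image(
                    row["image_path"], row["pitch_x_um"], row["pitch_y_um"],
                    slab=row["slab"], subject_id=str(sid), visit=int(visit),
                    eye=row.get("eye"),
                )
                images[row["slab"]] = img
                if "fovea_row" in row and pd.notna(row.get("fovea_row")):
                    fovea = (float(row["fovea_row"]), float(row["fovea_col"]))
                dmp = row.get("disc_mask_path")
                if isinstance(dmp, str) and dmp:
                    disc = oio.read_mask(dmp, like=img.pixels)
            log.info("processing subject=%s visit=%s slabs=%s", sid, visit,
                     sorted(images))
            all_rows.extend(process_eye(images, config, fovea, disc))
        except Exception as exc:  # collected, subject dropped from paired stats
            log.warning("subject=%s visit=%s failed: %s", sid, visit, exc)
            failures.append({"subject_id": sid, "visit": visit, "error": str(exc)})

    metrics = pd.DataFrame(all_rows, columns=LONG_COLUMNS)
    oio.write_table(out_dir / "metrics_long.csv", metrics)
    report = build_report(metrics, REFERENCE_VARIANTS, icc_form=config.icc_form)
    oio.write_table(out_dir / "repeatability_report.csv", report)
    if failures:
        oio.write_table(out_dir / "failures.csv", pd.DataFrame(failures))
    return {"metrics": metrics, "report": report, "failures": failures}
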