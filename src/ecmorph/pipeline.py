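"""End-to-end per-ROI analysis: tissue mask → collagen segmentation →
ECM surface % → fractal dimension → degradation simulation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .degradation import ErosionTrace, simulate_degradation
from .errors import CohortEmptyError, ValidationError
from .fractal import FractalFit, estimate_fractal_dimension
from .imaging import BinaryMask, CohortManifest, RGBImage, compute_tissue_mask, iter_cohort
from .segmentation import IsletSet, ecm_surface_percent, label_islets, segment_collagen
from .stats import RoiMeasurement


@dataclass
class RoiAnalysis:
    """One ROI's full analysis: metrics plus audit objects.

    ``measurement`` is None for non-analyzable ROIs (no collagen detected —
    fractal dimension and degradation are undefined there); ``ecm_percent``
    is still reported (0.0) for such ROIs.
    """

    roi_id: str
    case_id: str
    group: str
    ecm_percent: float
    measurement: "RoiMeasurement | None"
    tissue: BinaryMask
    collagen: BinaryMask
    islets: IsletSet
    fractal_fit: "FractalFit | None"
    trace: "ErosionTrace | None"


def analyze_roi(img: RGBImage, config: "RunConfig | None" = None) -> RoiAnalysis:
    """Run the full measurement pipeline on one ROI image."""
    config = config or RunConfig()
    tissue = compute_tissue_mask(
        img,
        whiteness_threshold=config.tissue.whiteness_threshold,
        min_channel_spread=config.tissue.min_channel_spread,
        close_holes=config.tissue.close_holes,
    )
    if tissue.foreground_count() == 0:
        raise ValidationError(f"ROI {img.roi_id}: no tissue detected")
    collagen = segment_collagen(img, tissue, config.segmentation)
    islets = label_islets(
        collagen, min_islet_pixels=config.segmentation.min_islet_pixels
    )
    filtered = islets.to_mask()
    ecm = ecm_surface_percent(islets, tissue)

    fit = None
    trace = None
    measurement = None
    if not filtered.is_empty():
        fit = estimate_fractal_dimension(filtered, config.fractal)
        trace = simulate_degradation(
            filtered, tissue, se=config.erosion.element(),
            max_cycles=config.erosion.max_cycles,
        )
        measurement = RoiMeasurement(
            roi_id=img.roi_id,
            case_id=img.case_id,
            group=img.group,
            ecm_percent=ecm,
            fractal_dimension=fit.dimension_D,
            n_cycles=float(trace.n_cycles),
            velocity=trace.velocity,
        )
    return RoiAnalysis(
        roi_id=img.roi_id,
        case_id=img.case_id,
        group=img.group.value,
        ecm_percent=ecm,
        measurement=measurement,
        tissue=tissue,
        collagen=collagen,
        islets=islets,
        fractal_fit=fit,
        trace=trace,
    )


def analyses_to_frame(analyses: "list[RoiAnalysis]") -> pd.DataFrame:
    """Measurement table with one row per ROI; metrics undefined on
    collagen-free ROIs are left empty (NaN)."""
    rows = []
    for a in analyses:
        rows.append(
            {
                "roi_id": a.roi_id,
                "case_id": a.case_id,
                "group": a.group,
                "ecm_percent": a.ecm_percent,
                "fractal_dimension": a.measurement.fractal_dimension
                if a.measurement else math.nan,
                "n_cycles": a.measurement.n_cycles if a.measurement else math.nan,
                "velocity": a.measurement.velocity if a.measurement else math.nan,
            }
        )
    return pd.DataFrame(rows)


def run_analysis(
    records: "list[tuple]",
    config: "RunConfig | None" = None,
    manifest: "CohortManifest | None" = None,
) -> "list[RoiAnalysis]":
    """Analyze every loadable ROI of a cohort record list, in input order."""
    analyses = []
    for img in iter_cohort(records, manifest=manifest):
        analyses.append(analyze_roi(img, config))
    if not analyses:
        raise CohortEmptyError("no ROI could be analyzed")
    return analyses


def read_manifest_csv(path: "str | Path") -> "list[tuple]":
    """Cohort manifest CSV with columns path, roi_id, case_id, group."""
    df = pd.read_csv(path, dtype=str)
    required = {"path", "roi_id", "case_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing column(s): {sorted(missing)}")
    base = Path(path).parent
    records = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        records.append((p, row.roi_id, row.case_id, row.group))
    return records
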