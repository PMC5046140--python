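"""Objective weighting, weighted overlay, land-cover masking and the
3-class suitability regionalization with area statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Raster

__all__ = [
    "normalize_weights",
    "grouped_contribution",
    "weighted_overlay",
    "mask_landcover",
    "combine_growth_quality",
    "classify",
    "area_stats_report",
    "ClassificationResult",
    "CLASS_LABELS",
]

CLASS_LABELS = {1: "highly suitable", 2: "marginally suitable", 3: "unsuitable"}


def normalize_weights(contributions: dict[str, float]) -> dict[str, float]:
    """Turn percent contributions into weights summing to 1 (order kept)."""
    vals = np.array(list(contributions.values()), dtype=float)
    if (vals < 0).any():
        raise ValueError("contributions must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("contributions sum to zero")
    return {name: float(v / total) for name, v in zip(contributions, vals)}


def grouped_contribution(contributions: dict[str, float], names: list[str]) -> float:
    """Combined contribution of a named group of variables (same units as
    the input table, e.g. percent)."""
    missing = [n for n in names if n not in contributions]
    if missing:
        raise ValueError(f"unknown variable(s): {missing}")
    return float(sum(contributions[n] for n in names))


def _check_aligned(rasters: list[Raster]) -> None:
    for r in rasters[1:]:
        if not rasters[0].header.geometry_equal(r.header):
            raise ValueError("rasters are not on a common grid")


def weighted_overlay(suitability_rasters: dict[str, Raster], weights: dict[str, float]) -> Raster:
    """Cellwise weighted mean of per-factor suitability layers.

    Weights must sum to 1 and name exactly the given layers; nodata in any
    layer propagates.
    """
    if set(suitability_rasters) != set(weights):
        raise ValueError("weight names do not match raster names")
    w = np.array([weights[n] for n in weights], dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    layers = [suitability_rasters[n] for n in weights]
    _check_aligned(layers)
    stack = np.stack([r.values for r in layers])
    out = np.tensordot(w, stack, axes=1)
    out[~np.isfinite(stack).all(axis=0)] = np.nan
    return Raster(layers[0].header, out)


def mask_landcover(composite: Raster, landcover: Raster, allowed_classes) -> Raster:
    """Set cells whose land-cover class is not allowed to nodata."""
    if not composite.header.geometry_equal(landcover.header):
        raise ValueError("composite and land-cover rasters are not aligned")
    allowed = set(int(a) for a in allowed_classes)
    keep = np.isin(np.nan_to_num(landcover.values, nan=-1).astype(int), list(allowed))
    keep &= landcover.mask
    out = composite.values.copy()
    out[~keep] = np.nan
    return Raster(composite.header, out)


def combine_growth_quality(growth: Raster, quality: Raster, rule: str = "min") -> Raster:
    """Overlay the growth-suitability and quality-suitability maps.

    ``min`` (default): a site must satisfy both; ``product`` and ``mean``
    are softer alternatives.
    """
    if not growth.header.geometry_equal(quality.header):
        raise ValueError("growth and quality rasters are not aligned")
    g, q = growth.values, quality.values
    if rule == "min":
        out = np.fmin(g, q)
    elif rule == "product":
        out = g * q
    elif rule == "mean":
        out = 0.5 * (g + q)
    else:
        raise ValueError("rule must be 'min', 'product' or 'mean'")
    out = np.where(np.isfinite(g) & np.isfinite(q), out, np.nan)
    return Raster(growth.header, out)


@dataclass
class ClassificationResult:
    """3-class regionalization raster plus the per-class area table."""

    class_raster: Raster
    stats: pd.DataFrame  # columns: class_id, label, cell_count, area, percent


def classify(composite: Raster, t_high: float = 0.7, t_low: float = 0.4) -> ClassificationResult:
    """Cut the composite suitability into 3 classes.

    Class 1 (highly suitable): value >= t_high; class 2 (marginally
    suitable): t_low <= value < t_high; class 3 (unsuitable): value <
    t_low. Statistics cover classified (non-nodata) cells; area = count *
    cell_size^2 in the grid's own map units.
    """
    if not (0 <= t_low < t_high <= 1):
        raise ValueError("thresholds must satisfy 0 <= t_low < t_high <= 1")
    vals = composite.values
    cls = np.full(vals.shape, np.nan)
    cls[vals >= t_high] = 1
    cls[(vals >= t_low) & (vals < t_high)] = 2
    cls[vals < t_low] = 3
    counts = {cid: int((cls == cid).sum()) for cid in (1, 2, 3)}
    n_classified = sum(counts.values())
    cell_area = composite.header.cell_size**2
    rows = []
    for cid in (1, 2, 3):
        rows.append(
            {
                "class_id": cid,
                "label": CLASS_LABELS[cid],
                "cell_count": counts[cid],
                "area": counts[cid] * cell_area,
                "percent": 100.0 * counts[cid] / n_classified if n_classified else 0.0,
            }
        )
    return ClassificationResult(
        class_raster=Raster(composite.header, cls),
        stats=pd.DataFrame(rows),
    )


def area_stats_report(result) -> pd.DataFrame:
    """Per-class (label, area, percent) table plus a derived suitable-total
    row (classes 1 + 2 combined).

    Accepts a ClassificationResult or a mapping class_id -> area.
    """
    if isinstance(result, ClassificationResult):
        stats = result.stats[["class_id", "label", "area"]].copy()
    else:
        stats = pd.DataFrame(
            [
                {"class_id": int(cid), "label": CLASS_LABELS[int(cid)], "area": float(a)}
                for cid, a in result.items()
            ]
        ).sort_values("class_id", ignore_index=True)
    total = stats["area"].sum()
    if total <= 0:
        raise ValueError("total classified area is zero")
    stats["percent"] = 100.0 * stats["area"] / total
    suitable = stats[stats["class_id"].isin([1, 2])]
    extra = pd.DataFrame(
        [
            {
                "class_id": 0,
                "label": "suitable total",
                "area": suitable["area"].sum(),
                "percent": suitable["percent"].sum(),
            }
        ]
    )
    return pd.concat([stats, extra], ignore_index=True)
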