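"""RMSE accuracy testing of the suitability map against observed indicators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Raster, extract_at_points
from .samples import SamplePoint

__all__ = ["rmse", "validate_map", "ValidationReport"]


@dataclass
class ValidationReport:
    rmse: float
    n_points: int
    table: pd.DataFrame  # per-point predicted, observed, residual

    def summary(self) -> str:
        return f"RMSE = {self.rmse:.4f} over {self.n_points} points"


def rmse(predicted, observed) -> float:
    """Root mean square error: sqrt(mean((p - o)^2))."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size < 1:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def validate_map(
    suitability: Raster,
    points: list[SamplePoint],
    indicator_table: pd.DataFrame,
) -> ValidationReport:
    """RMSE between the suitability map at sample sites and the observed
    aggregative indicator.

    Points over nodata (or outside the extent) are excluded and the count
    of usable points reported.
    """
    predicted = extract_at_points(suitability, points)
    observed = np.array(
        [indicator_table["indicator"].get(p.point_id, np.nan) for p in points]
    )
    ok = np.isfinite(predicted) & np.isfinite(observed)
    if not ok.any():
        raise ValueError("no point has both a predicted and an observed value")
    table = pd.DataFrame(
        {
            "point_id": [p.point_id for p in points],
            "predicted": predicted,
            "observed": observed,
        }
    )[ok]
    table["residual"] = table["predicted"] - table["observed"]
    return ValidationReport(
        rmse=rmse(table["predicted"], table["observed"]),
        n_points=int(ok.sum()),
        table=table.reset_index(drop=True),
    )
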