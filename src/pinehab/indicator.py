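"""The aggregative quality indicator.

The four effective-compound contents (shikimic acid, procyanidins, total
flavonoids, total lignans) are treated as equally important: each is
normalized to [0, 1] across the sample set and the composite indicator is
their unweighted mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .samples import COMPOUNDS, SamplePoint, points_to_frame

__all__ = ["normalize_contents", "aggregative_indicator"]


def normalize_contents(
    points: list[SamplePoint],
    method: str = "minmax",
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Normalize per-compound contents and attach the composite indicator.

    Returns a frame indexed by ``point_id`` with one [0, 1] column per
    compound and an ``indicator`` column. ``method`` is ``minmax`` (default)
    or ``zscore`` (z-scores squashed back to [0, 1] by min-max, kept for
    sensitivity analysis). A constant compound column carries no ranking
    information and is set to 0.5 with a warning. Custom ``weights``
    (summing to 1) replace the default equal weighting.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points to normalize contents")
    if method not in ("minmax", "zscore"):
        raise ValueError("method must be 'minmax' or 'zscore'")
    frame = points_to_frame(points).set_index("point_id")
    out = pd.DataFrame(index=frame.index)
    for name in COMPOUNDS:
        col = frame[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            warnings.warn(f"compound {name!r} is constant; normalized to 0.5", stacklevel=2)
            out[name] = 0.5
            continue
        if method == "zscore":
            col = (col - col.mean()) / col.std()
        out[name] = (col - col.min()) / np.ptp(col)
    if weights is None:
        weights = {name: 0.25 for name in COMPOUNDS}
    w = np.array([weights[name] for name in COMPOUNDS])
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("compound weights must be non-negative and sum to 1")
    out["indicator"] = out[list(COMPOUNDS)].to_numpy() @ w
    return out


def aggregative_indicator(table: pd.DataFrame) -> pd.Series:
    """Composite indicator per point: the equal-weight mean of the
    normalized compound columns."""
    missing = set(COMPOUNDS) - set(table.columns)
    if missing:
        raise ValueError(f"indicator table missing compound columns: {sorted(missing)}")
    return table[list(COMPOUNDS)].mean(axis=1).rename("indicator")
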