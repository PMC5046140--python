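"""Field sample points: coordinates plus the four needle-compound contents."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

COMPOUNDS = ("shikimic", "procyanidins", "flavonoids", "lignans")

CSV_COLUMNS = ("point_id", "x", "y", "altitude") + COMPOUNDS


@dataclass
class SamplePoint:
    """One field sample: location, altitude and compound contents.

    Contents are concentrations in consistent (arbitrary) mass/mass units
    and must be non-negative.
    """

    point_id: str
    x: float
    y: float
    altitude: float = 0.0
    shikimic: float = 0.0
    procyanidins: float = 0.0
    flavonoids: float = 0.0
    lignans: float = 0.0

    def __post_init__(self) -> None:
        for name in COMPOUNDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} content must be non-negative")

    def contents(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COMPOUNDS}


def points_to_frame(points: list[SamplePoint]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in points], columns=list(CSV_COLUMNS))


def frame_to_points(frame: pd.DataFrame) -> list[SamplePoint]:
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    return [
        SamplePoint(
            point_id=str(row.point_id),
            x=float(row.x),
            y=float(row.y),
            altitude=float(row.altitude),
            shikimic=float(row.shikimic),
            procyanidins=float(row.procyanidins),
            flavonoids=float(row.flavonoids),
            lignans=float(row.lignans),
        )
        for row in frame.itertuples(index=False)
    ]


def read_points_csv(path) -> list[SamplePoint]:
    return frame_to_points(pd.read_csv(path))


def write_points_csv(points: list[SamplePoint], path) -> None:
    points_to_frame(points).to_csv(path, index=False)
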