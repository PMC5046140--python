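"""Synthetic landscapes with known ground truth.

Generates spatially autocorrelated ecological-factor rasters, a categorical
land-cover layer, presence points concentrated where suitability is high,
and per-point compound contents driven by a known composite membership —
so every downstream stage (model fit, membership recovery, overlay,
validation) can be tested against a known truth.

Default conditions mirror the study system: five factors (April and June
precipitation in mm, February and August monthly mean temperature in
degrees C, altitude in m) whose true K-t membership parameters are the
published per-factor fits, true factor weights equal to the published
normalized percent contributions, and four needle compounds (shikimic
acid, procyanidins, total flavonoids, total lignans) that share one
composite quality truth at different concentration scales.

All randomness flows from integer seeds through ``numpy.random.SeedSequence``
spawning: the landscape seed spawns one child stream per factor raster plus
one for land cover, in factor order; presence sampling and content noise
take their own seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Raster, RasterHeader, AlignmentError, extract_at_points
from .membership import MembershipParams, membership
from .samples import COMPOUNDS, SamplePoint

__all__ = [
    "FactorSpec",
    "LandcoverClass",
    "LandscapeConfig",
    "GroundTruth",
    "default_header",
    "default_config",
    "default_truth",
    "generate_factor_rasters",
    "generate_landcover",
    "simulate_true_suitability",
    "sample_presence_points",
    "simulate_contents",
]


@dataclass(frozen=True)
class FactorSpec:
    """One continuous factor layer: name, marginal moments, smoothness."""

    name: str
    mean: float
    sd: float
    corr_length: float  # Gaussian smoothing length in cells; 0 = white noise

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.corr_length < 0:
            raise ValueError("autocorrelation length must be non-negative")


@dataclass(frozen=True)
class LandcoverClass:
    class_id: int
    label: str
    proportion: float


@dataclass(frozen=True)
class LandscapeConfig:
    grid: RasterHeader
    factor_specs: tuple[FactorSpec, ...]
    landcover_classes: tuple[LandcoverClass, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(c.proportion for c in self.landcover_classes)
        if self.landcover_classes and abs(total - 1.0) > 1e-9:
            raise ValueError("land-cover proportions must sum to 1")


@dataclass(frozen=True)
class GroundTruth:
    """True per-factor memberships, factor weights and content noise."""

    memberships: dict[str, MembershipParams]
    weights: dict[str, float]
    content_scales: dict[str, float]
    content_noise_sd: dict[str, float]

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()))
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be non-negative and sum to 1")
        if any(sd < 0 for sd in self.content_noise_sd.values()):
            raise ValueError("noise sd must be non-negative")


# ---------------------------------------------------------------------------
# Default study conditions

FACTOR_NAMES = ("precip_april", "precip_june", "temp_feb", "temp_aug", "altitude")

# Published per-factor K-t fits (a, b, c, d, K)
_TRUE_KT = {
    "precip_april": (-63.9, 98.8, 113.8, 191.3, 1.62),
    "precip_june": (-63.7, 149.2, 194.2, 427.4, 2.51),
    "temp_feb": (-42.4, 5.0, 8.0, 33.6, 13.0),
    "temp_aug": (20.0, 22.0, 24.0, 36.1, 2.93),
    "altitude": (-900.0, 800.0, 1181.0, 2195.0, 2.9),
}

# Published percent contributions, normalized to weights summing to 1
_TRUE_WEIGHTS = {
    "precip_april": 0.034,
    "precip_june": 0.139,
    "temp_feb": 0.258,
    "temp_aug": 0.439,
    "altitude": 0.130,
}

# Landscape marginals: mean at the plateau center, sd = (d - a) / 6 so the
# raster spans both limbs of the true membership.
_FACTOR_MARGINALS = {
    "precip_april": (106.3, 42.5),
    "precip_june": (171.7, 81.9),
    "temp_feb": (6.5, 12.7),
    "temp_aug": (23.0, 2.7),
    "altitude": (990.0, 515.8),
}

# Compound concentration scales (arbitrary mass/mass units); noise sd is a
# fraction of scale — 0.05 by default, matching the validation scenario.
_CONTENT_SCALES = {
    "shikimic": 12.0,
    "procyanidins": 6.0,
    "flavonoids": 45.0,
    "lignans": 3.0,
}

DEFAULT_LANDCOVER = (
    LandcoverClass(1, "coniferous_forest", 0.55),
    LandcoverClass(2, "broadleaf_forest", 0.15),
    LandcoverClass(3, "farmland", 0.15),
    LandcoverClass(4, "water", 0.05),
    LandcoverClass(5, "urban", 0.10),
)


def default_header(n: int = 100, cell_size: float = 1.0) -> RasterHeader:
    return RasterHeader(n_cols=n, n_rows=n, x_origin=0.0, y_origin=0.0,
                        cell_size=cell_size)


def default_config(seed: int = 0, n: int = 100, corr_length: float = 10.0) -> LandscapeConfig:
    specs = tuple(
        FactorSpec(name, *_FACTOR_MARGINALS[name], corr_length)
        for name in FACTOR_NAMES
    )
    return LandscapeConfig(
        grid=default_header(n),
        factor_specs=specs,
        landcover_classes=DEFAULT_LANDCOVER,
        seed=seed,
    )


def default_truth(noise_fraction: float = 0.05) -> GroundTruth:
    memberships = {
        name: MembershipParams(family="kt", a=a, b=b, c=c, d=d, k=k)
        for name, (a, b, c, d, k) in _TRUE_KT.items()
    }
    return GroundTruth(
        memberships=memberships,
        weights=dict(_TRUE_WEIGHTS),
        content_scales=dict(_CONTENT_SCALES),
        content_noise_sd={
            name: noise_fraction * scale for name, scale in _CONTENT_SCALES.items()
        },
    )


# ---------------------------------------------------------------------------
# Generators

def _smooth_field(rng: np.random.Generator, shape, corr_length: float) -> np.ndarray:
    field_ = rng.standard_normal(shape)
    if corr_length > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=corr_length, mode="wrap")
    return field_


def generate_factor_rasters(config: LandscapeConfig) -> dict[str, Raster]:
    """One smoothed-Gaussian-random-field raster per factor spec.

    White noise is convolved with a Gaussian kernel of the stated
    autocorrelation length, then rescaled to the stated mean and sd.
    Deterministic given ``config.seed``.
    """
    shape = (config.grid.n_rows, config.grid.n_cols)
    children = np.random.SeedSequence(config.seed).spawn(len(config.factor_specs) + 1)
    out: dict[str, Raster] = {}
    for spec, child in zip(config.factor_specs, children):
        rng = np.random.default_rng(child)
        field_ = _smooth_field(rng, shape, spec.corr_length)
        if spec.sd == 0:
            vals = np.full(shape, spec.mean)
        else:
            std = field_.std()
            z = (field_ - field_.mean()) / (std if std > 0 else 1.0)
            vals = spec.mean + spec.sd * z
        out[spec.name] = Raster(config.grid, vals)
    return out


def generate_landcover(config: LandscapeConfig) -> Raster:
    """Categorical land-cover raster with the configured class proportions.

    A smoothed field is quantile-sliced so classes form contiguous patches
    at (approximately) the stated proportions. Uses the last spawned child
    of the landscape seed.
    """
    if not config.landcover_classes:
        raise ValueError("no land-cover classes configured")
    shape = (config.grid.n_rows, config.grid.n_cols)
    child = np.random.SeedSequence(config.seed).spawn(len(config.factor_specs) + 1)[-1]
    rng = np.random.default_rng(child)
    field_ = _smooth_field(rng, shape, corr_length=5.0)
    probs = np.cumsum([c.proportion for c in config.landcover_classes])
    edges = np.quantile(field_, probs[:-1])
    idx = np.searchsorted(edges, field_, side="right")
    ids = np.array([c.class_id for c in config.landcover_classes], dtype=float)
    return Raster(config.grid, ids[idx])


def simulate_true_suitability(factors: dict[str, Raster], truth: GroundTruth) -> Raster:
    """Cellwise weighted sum of true memberships; values in [0, 1]."""
    names = list(truth.weights)
    headers = [factors[n].header for n in names]
    for h in headers[1:]:
        if not headers[0].geometry_equal(h):
            raise AlignmentError("factor rasters are not on a common grid")
    acc = np.zeros((headers[0].n_rows, headers[0].n_cols))
    valid = np.ones_like(acc, dtype=bool)
    for name in names:
        r = factors[name]
        mu = np.full_like(acc, np.nan)
        m = r.mask
        mu[m] = membership(r.values[m], truth.memberships[name])
        acc = acc + truth.weights[name] * np.nan_to_num(mu, nan=0.0)
        valid &= m
    acc[~valid] = np.nan
    return Raster(headers[0], acc)


def sample_presence_points(
    suitability: Raster,
    n: int,
    seed: int,
    altitude: Raster | None = None,
) -> list[SamplePoint]:
    """Draw presence points with per-cell probability proportional to suitability.

    Points sit at cell centers (sampling with replacement). If an altitude
    raster is given its value is recorded on each point.
    """
    if n < 1:
        raise ValueError("need n >= 1 points")
    vals = np.nan_to_num(suitability.values, nan=0.0).ravel()
    total = vals.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample presences")
    rng = np.random.default_rng(seed)
    cells = rng.choice(vals.size, size=n, replace=True, p=vals / total)
    h = suitability.header
    points = []
    for i, cell in enumerate(cells):
        row, col = divmod(int(cell), h.n_cols)
        x, y = h.cell_center(row, col)
        alt = float(altitude.values[row, col]) if altitude is not None else 0.0
        points.append(SamplePoint(point_id=f"p{i + 1:04d}", x=x, y=y, altitude=alt))
    return points


def simulate_contents(
    points: list[SamplePoint],
    factors: dict[str, Raster],
    truth: GroundTruth,
    seed: int,
) -> list[SamplePoint]:
    """Attach compound contents: scale * composite membership + noise, >= 0.

    All four compounds share the composite quality truth, each at its own
    concentration scale, so an equal-weight aggregate of the normalized
    contents is a noisy monotone image of true suitability.
    """
    composite_map = simulate_true_suitability(factors, truth)
    composite = extract_at_points(composite_map, points)
    rng = np.random.default_rng(seed)
    out = []
    for i, p in enumerate(points):
        base = composite[i]
        contents = {}
        for name in COMPOUNDS:
            scale = truth.content_scales[name]
            sd = truth.content_noise_sd[name]
            noise = rng.normal(0.0, sd) if sd > 0 else 0.0
            contents[name] = max(0.0, scale * base + noise) if np.isfinite(base) else 0.0
        out.append(SamplePoint(point_id=p.point_id, x=p.x, y=p.y,
                               altitude=p.altitude, **contents))
    return out
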