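"""End-to-end synthetic study: landscape -> SDM -> fuzzy quality ->
overlay -> regionalization -> validation.

Chains every stage in study order on a generated landscape with known
ground truth, and reports recovery metrics (fitted membership plateaus,
weight errors, map RMSE) so the whole pipeline can be checked against the
truth that generated the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indicator as indicator_mod
from . import maxent, membership, overlay, synth, validate
from .grids import Raster, extract_at_points
from .samples import SamplePoint

__all__ = ["PipelineResult", "run_synthetic_pipeline", "recovery_metrics"]


@dataclass
class PipelineResult:
    truth: synth.GroundTruth
    factors: dict[str, Raster]
    landcover: Raster
    true_suitability: Raster
    points: list[SamplePoint]
    indicator_table: pd.DataFrame
    model: maxent.MaxentModel
    auc_train: float
    auc_test: float
    contributions: dict[str, float]
    weights: dict[str, float]
    fitted_memberships: dict[str, membership.FittedMembership]
    growth_map: Raster
    quality_map: Raster
    production_map: Raster
    classification: overlay.ClassificationResult
    area_report: pd.DataFrame
    validation: validate.ValidationReport
    presence_values: np.ndarray = field(repr=False, default=None)
    background_values: np.ndarray = field(repr=False, default=None)


def _sub_seeds(seed: int, n: int) -> list[int]:
    # deterministic integer sub-seeds below 2**31
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_synthetic_pipeline(
    seed: int = 0,
    n_points: int = 200,
    grid_n: int = 100,
    noise_fraction: float = 0.05,
    t_high: float = 0.7,
    t_low: float = 0.4,
    beta: float = 0.1,
    feature_classes: tuple[str, ...] = ("linear", "quadratic"),
    allowed_landcover: tuple[int, ...] = (1,),
    combine_rule: str = "min",
    test_fraction: float = 0.25,
    weight_source: str = "calibrated",
) -> PipelineResult:
    """Run the full pipeline on a synthetic landscape.

    Defaults are the study conditions: a 100 x 100 grid, five factors,
    200 sample points, content noise at 5% of each compound's scale, and a
    coniferous-forest land-cover mask.
    """
    s_land, s_points, s_contents, s_split, s_perm = _sub_seeds(seed, 5)
    config = synth.default_config(seed=s_land, n=grid_n)
    truth = synth.default_truth(noise_fraction=noise_fraction)

    factors = synth.generate_factor_rasters(config)
    landcover = synth.generate_landcover(config)
    true_suit = synth.simulate_true_suitability(factors, truth)
    points = synth.sample_presence_points(
        true_suit, n_points, seed=s_points, altitude=factors["altitude"]
    )
    points = synth.simulate_contents(points, factors, truth, seed=s_contents)
    indicator_table = indicator_mod.normalize_contents(points)

    names = tuple(truth.weights)
    presence = np.column_stack(
        [extract_at_points(factors[n], points) for n in names]
    )
    stack = np.stack([factors[n].values.ravel() for n in names], axis=1)
    background = stack[np.isfinite(stack).all(axis=1)]

    train, test = maxent.split_presence(presence, test_fraction=test_fraction, seed=s_split)
    model = maxent.fit_maxent(
        train, background, names=names, classes=feature_classes, beta=beta
    )
    auc_train = maxent.auc(model, train, background)
    auc_test = maxent.auc(model, test, background) if len(test) else float("nan")

    contributions = maxent.percent_contribution(model, train, background, seed=s_perm)
    maxent_weights = overlay.normalize_weights(contributions)

    ind = indicator_table["indicator"].to_numpy()
    marginal: dict[str, membership.FittedMembership] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(names):
            marginal[name] = membership.fit_membership(
                presence[:, j], ind, family="kt", n_bins=20, rescale=True
            )
    # joint calibration of memberships + weights against the indicator,
    # seeded by the marginal fits and the SDM importance weights
    joint_params, joint_weights, joint_rss = membership.fit_memberships_joint(
        presence, ind, names,
        inits={n: marginal[n].params for n in names},
        weight_inits=maxent_weights,
    )
    if weight_source == "calibrated":
        weights = joint_weights
    elif weight_source == "maxent":
        weights = maxent_weights
    else:
        raise ValueError("weight_source must be 'calibrated' or 'maxent'")
    fitted = {
        name: membership.FittedMembership(
            params=joint_params[name], goodness=joint_rss, n_points=len(points)
        )
        for name in names
    }
    quality_layers = {
        name: membership.standardize_raster(factors[name], fitted[name].params)
        for name in names
    }

    quality_map = overlay.weighted_overlay(quality_layers, weights)
    growth_map = maxent.predict(model, {n: factors[n] for n in names}, output="logistic")
    production = overlay.combine_growth_quality(growth_map, quality_map, rule=combine_rule)
    masked = overlay.mask_landcover(production, landcover, allowed_landcover)
    classification = overlay.classify(masked, t_high=t_high, t_low=t_low)
    area_report = overlay.area_stats_report(classification)
    report = validate.validate_map(quality_map, points, indicator_table)

    return PipelineResult(
        truth=truth,
        factors=factors,
        landcover=landcover,
        true_suitability=true_suit,
        points=points,
        indicator_table=indicator_table,
        model=model,
        auc_train=auc_train,
        auc_test=auc_test,
        contributions=contributions,
        weights=weights,
        fitted_memberships=fitted,
        growth_map=growth_map,
        quality_map=quality_map,
        production_map=masked,
        classification=classification,
        area_report=area_report,
        validation=report,
        presence_values=presence,
        background_values=background,
    )


def recovery_metrics(result: PipelineResult) -> pd.DataFrame:
    """Per-factor recovery of the generating truth.

    Plateau errors |b_hat - b| and |c_hat - c| are reported as fractions of
    the factor raster's value range; weight errors are absolute.
    """
    rows = []
    for name, true_w in result.truth.weights.items():
        true_p = result.truth.memberships[name]
        fit_p = result.fitted_memberships[name].params
        vals = result.factors[name].finite
        span = float(vals.max() - vals.min())
        rows.append(
            {
                "factor": name,
                "b_true": true_p.b,
                "b_fit": fit_p.b,
                "c_true": true_p.c,
                "c_fit": fit_p.c,
                "b_err_frac": abs(fit_p.b - true_p.b) / span,
                "c_err_frac": abs(fit_p.c - true_p.c) / span,
                "weight_true": true_w,
                "weight_fit": result.weights[name],
                "weight_err": abs(result.weights[name] - true_w),
            }
        )
    return pd.DataFrame(rows)
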