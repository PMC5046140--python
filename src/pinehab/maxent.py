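"""Presence-background maximum-entropy species distribution model.

Estimates the Gibbs distribution over background cells that has maximum
entropy subject to matching the presence-sample feature means — i.e. the
L1-regularized exponential model

    q_lambda(x) = exp(lambda . f(x)) / Z      over background cells,

fitted by minimizing the penalized negative log-likelihood of the presence
sample. Features are built from raw variables scaled to [0, 1] (linear and
quadratic by default, optional hinge). The L1 penalty is handled exactly by
splitting each coefficient into positive and negative parts bounded at
zero, so a smooth bound-constrained quasi-Newton solve applies.

Outputs follow the classic Maxent display conventions: the *raw* output is
the normalized density (sums to 1 over background), and the *logistic*
output is tau*r / (1 - tau + tau*r) with r the entropy-scaled raw density
and tau = 0.5, so a featureless model scores 0.5 everywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import Raster

__all__ = [
    "FeatureSet",
    "MaxentModel",
    "ResponseCurve",
    "fit_maxent",
    "predict_values",
    "predict",
    "auc_score",
    "auc",
    "percent_contribution",
    "response_curve",
    "optimal_range",
    "select_factors",
    "split_presence",
    "save_model",
    "load_model",
]

FEATURE_CLASSES = ("linear", "quadratic", "hinge")


@dataclass(frozen=True)
class FeatureSet:
    """Scaled feature expansion of a set of variables.

    Each raw variable is min-max scaled by its training range; features map
    the scaled value into [0, 1].
    """

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    classes: tuple[str, ...] = ("linear", "quadratic")
    hinge_knots: tuple[float, ...] = ()

    @classmethod
    def from_data(
        cls,
        X: np.ndarray,
        names: tuple[str, ...],
        classes: tuple[str, ...] = ("linear", "quadratic"),
        n_hinge: int = 4,
    ) -> "FeatureSet":
        X = np.asarray(X, dtype=float)
        mins = X.min(axis=0)
        maxs = X.max(axis=0)
        keep = maxs > mins
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(f"dropping constant variable(s): {dropped}", stacklevel=2)
        for c in classes:
            if c not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {c!r}")
        knots = tuple(np.linspace(0, 1, n_hinge + 1)[:-1]) if "hinge" in classes else ()
        return cls(
            names=tuple(n for n, k in zip(names, keep) if k),
            mins=mins[keep],
            maxs=maxs[keep],
            classes=tuple(classes),
            hinge_knots=knots,
        )

    @property
    def feature_labels(self) -> list[str]:
        labels = []
        for name in self.names:
            if "linear" in self.classes:
                labels.append(f"linear:{name}")
            if "quadratic" in self.classes:
                labels.append(f"quadratic:{name}")
            for t in self.hinge_knots:
                labels.append(f"hinge:{name}:{t:g}")
        return labels

    @property
    def n_features(self) -> int:
        per = ("linear" in self.classes) + ("quadratic" in self.classes) + len(self.hinge_knots)
        return per * len(self.names)

    def scale(self, X: np.ndarray) -> tuple[np.ndarray, int]:
        """Min-max scale columns by the training range, clamping to [0, 1].

        Returns the scaled matrix and the count of clamped entries.
        """
        X = np.asarray(X, dtype=float)
        z = (X - self.mins) / (self.maxs - self.mins)
        n_clamped = int(((z < 0) | (z > 1)).sum())
        return np.clip(z, 0.0, 1.0), n_clamped

    def transform(self, X: np.ndarray, warn_clamp: bool = False) -> np.ndarray:
        z, n_clamped = self.scale(X)
        if n_clamped and warn_clamp:
            warnings.warn(
                f"{n_clamped} value(s) outside the training range were clamped",
                stacklevel=2,
            )
        cols = []
        for j in range(len(self.names)):
            zj = z[:, j]
            if "linear" in self.classes:
                cols.append(zj)
            if "quadratic" in self.classes:
                cols.append(zj**2)
            for t in self.hinge_knots:
                cols.append(np.clip((zj - t) / (1.0 - t), 0.0, 1.0))
        return np.column_stack(cols) if cols else np.empty((X.shape[0], 0))


@dataclass
class MaxentModel:
    feature_set: FeatureSet
    coefficients: np.ndarray  # one per feature
    regularization: float
    log_z: float  # log partition over the training background
    entropy: float  # Shannon entropy of the background distribution
    background_means: np.ndarray  # raw-unit background means per variable
    n_background: int
    converged: bool
    objective_path: list[float] = field(default_factory=list, repr=False)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        F = self.feature_set.transform(X, warn_clamp=True)
        return F @ self.coefficients


@dataclass
class ResponseCurve:
    """Predicted logistic suitability along one variable's training range."""

    variable: str
    grid: np.ndarray
    response: np.ndarray


def _as_matrix(X, names):
    """Accept an (n, k) array or a dict of columns; return matrix + names."""
    if isinstance(X, dict):
        names = tuple(X.keys()) if names is None else tuple(names)
        return np.column_stack([np.asarray(X[n], dtype=float) for n in names]), names
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if names is None:
        names = tuple(f"var{j}" for j in range(X.shape[1]))
    return X, tuple(names)


def fit_maxent(
    presence,
    background,
    names: tuple[str, ...] | None = None,
    classes: tuple[str, ...] = ("linear", "quadratic"),
    beta: float = 0.1,
    n_hinge: int = 4,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MaxentModel:
    """Fit the L1-regularized maxent model.

    ``presence`` and ``background`` are (n, k) arrays (or dicts of columns)
    of raw variable values; ``beta`` is the L1 penalty multiplier — the
    effective per-feature penalty is beta * sd(f | background) / sqrt(n_presence),
    the usual maxent regularization scaling. The
    penalized negative log-likelihood and its gradient are exact; the
    solver is L-BFGS-B on the positive/negative coefficient split, stopping
    at projected-gradient infinity norm ``tol`` or ``max_iter`` iterations.
    """
    P, names = _as_matrix(presence, names)
    B, _ = _as_matrix(background, names)
    if P.shape[0] < 1:
        raise ValueError("need at least one presence record")
    if B.shape[0] < 10:
        raise ValueError("need at least 10 background records")
    if not (np.isfinite(P).all() and np.isfinite(B).all()):
        raise ValueError("missing values are not allowed")

    fs = FeatureSet.from_data(np.vstack([P, B]), names, classes=classes, n_hinge=n_hinge)
    kept = [names.index(n) for n in fs.names]
    Fp = fs.transform(P[:, kept])
    Fb = fs.transform(B[:, kept])
    n_feat = Fp.shape[1]
    n_bg = B.shape[0]

    # per-feature penalty scaled by background feature sd over sqrt(sample
    # size), the standard maxent regularization rule: the penalty must
    # shrink as the presence sample grows or it dominates the constraint
    # |E_pres f - E_q f| <= reg
    reg = beta * Fb.std(axis=0) / np.sqrt(Fp.shape[0]) if n_feat else np.array([])

    path: list[float] = []

    if n_feat == 0:
        lam = np.array([])
        log_z = float(np.log(n_bg))
        q = np.full(n_bg, 1.0 / n_bg)
        converged = True
    else:
        fbar = Fp.mean(axis=0)

        def objective(w):
            lam = w[:n_feat] - w[n_feat:]
            eta = Fb @ lam
            lz = logsumexp(eta)
            nll = -float(fbar @ lam) + lz
            g = -fbar + np.exp(eta - lz) @ Fb
            grad = np.concatenate([g + reg, -g + reg])
            return nll + float(reg @ np.abs(lam)), grad

        w0 = np.zeros(2 * n_feat)

        def record(wk):
            path.append(objective(wk)[0])

        res = minimize(
            objective,
            w0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * n_feat),
            callback=record,
            options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14, "maxfun": 10 * max_iter},
        )
        lam = res.x[:n_feat] - res.x[n_feat:]
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                f"maxent optimizer did not converge ({res.message}); best iterate returned",
                stacklevel=2,
            )
        eta = Fb @ lam
        log_z = float(logsumexp(eta))
        q = np.exp(eta - log_z)

    entropy = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
    return MaxentModel(
        feature_set=fs,
        coefficients=lam,
        regularization=beta,
        log_z=log_z,
        entropy=entropy,
        background_means=B[:, kept].mean(axis=0) if kept else np.array([]),
        n_background=n_bg,
        converged=converged,
        objective_path=path,
    )


def predict_values(model: MaxentModel, X, output: str = "logistic", tau: float = 0.5) -> np.ndarray:
    """Score rows of raw variable values.

    ``raw``: normalized Gibbs density relative to the training background
    (sums to 1 over the background rows). ``logistic``: tau*r/(1-tau+tau*r)
    with r = exp(entropy) * raw density; 0.5 everywhere for a featureless
    model at the default tau.
    """
    X, _ = _as_matrix(X, model.feature_set.names)
    F = model.feature_set.transform(X, warn_clamp=True)
    eta = F @ model.coefficients if model.coefficients.size else np.zeros(X.shape[0])
    raw = np.exp(eta - model.log_z)
    if output == "raw":
        return raw
    if output == "logistic":
        r = raw * np.exp(model.entropy)
        return tau * r / (1.0 - tau + tau * r)
    raise ValueError("output must be 'raw' or 'logistic'")


def predict(model: MaxentModel, factor_rasters: dict[str, Raster], output: str = "logistic") -> Raster:
    """Predict over aligned factor rasters; nodata in any layer propagates."""
    names = model.feature_set.names
    missing = [n for n in names if n not in factor_rasters]
    if missing:
        raise ValueError(f"missing factor raster(s): {missing}")
    headers = [factor_rasters[n].header for n in names]
    for h in headers[1:]:
        if not headers[0].geometry_equal(h):
            raise ValueError("factor rasters are not aligned")
    stack = np.stack([factor_rasters[n].values.ravel() for n in names], axis=1)
    valid = np.isfinite(stack).all(axis=1)
    out = np.full(stack.shape[0], np.nan)
    if valid.any():
        out[valid] = predict_values(model, stack[valid], output=output)
    h = headers[0]
    return Raster(h, out.reshape(h.n_rows, h.n_cols))


def auc_score(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(presence score > background score), ties 0.5."""
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if pos.size < 1:
        raise ValueError("need at least one presence score")
    if neg.size < 1:
        raise ValueError("background scores are empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc(model: MaxentModel, presence, background) -> float:
    """AUC of model scores for a presence set against the background."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = predict_values(model, presence, output="raw")
        bs = predict_values(model, background, output="raw")
    return auc_score(ps, bs)


def percent_contribution(
    model: MaxentModel,
    presence,
    background,
    n_permutations: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance of each variable, normalized to sum to 100.

    For each variable the values are permuted across the pooled presence +
    background rows and the drop in training AUC recorded (mean of
    ``n_permutations`` draws, negative drops floored at zero).
    """
    P, names = _as_matrix(presence, model.feature_set.names)
    B, _ = _as_matrix(background, names)
    base = auc(model, P, B)
    rng = np.random.default_rng(seed)
    n_p = P.shape[0]
    drops = np.zeros(len(names))
    for j in range(len(names)):
        pooled = np.concatenate([P[:, j], B[:, j]])
        acc = 0.0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            P2 = P.copy()
            B2 = B.copy()
            P2[:, j] = perm[:n_p]
            B2[:, j] = perm[n_p:]
            acc += base - auc(model, P2, B2)
        drops[j] = max(acc / n_permutations, 0.0)
    total = drops.sum()
    if total <= 0:
        shares = np.full(len(names), 100.0 / len(names))
    else:
        shares = 100.0 * drops / total
    return dict(zip(names, shares))


def response_curve(model: MaxentModel, variable: str, n_grid: int = 101) -> ResponseCurve:
    """Logistic response along one variable, others at the background mean."""
    names = model.feature_set.names
    if variable not in names:
        raise ValueError(f"unknown variable {variable!r}")
    j = names.index(variable)
    grid = np.linspace(model.feature_set.mins[j], model.feature_set.maxs[j], n_grid)
    X = np.tile(model.background_means, (n_grid, 1))
    X[:, j] = grid
    resp = predict_values(model, X, output="logistic")
    return ResponseCurve(variable=variable, grid=grid, response=resp)


def optimal_range(curve: ResponseCurve, fraction: float = 0.8) -> tuple[float, float]:
    """Smallest and largest grid values with response >= fraction of the peak."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    sel = curve.response >= fraction * curve.response.max()
    idx = np.flatnonzero(sel)
    if idx.size > 1 and np.any(np.diff(idx) > 1):
        warnings.warn(
            f"high-response region for {curve.variable!r} is non-contiguous",
            stacklevel=2,
        )
    return float(curve.grid[idx[0]]), float(curve.grid[idx[-1]])


def select_factors(
    contributions: dict[str, float],
    k: int | None = 5,
    min_percent: float | None = None,
) -> list[str]:
    """Top-k variables by contribution (ties broken by name), or all above
    a percent floor."""
    ordered = sorted(contributions.items(), key=lambda kv: (-kv[1], kv[0]))
    if min_percent is not None:
        return [name for name, v in ordered if v >= min_percent]
    return [name for name, _ in ordered[: min(k, len(ordered))]]


def split_presence(presence, test_fraction: float = 0.25, seed: int = 0):
    """Random train/test split of presence rows."""
    P = np.atleast_2d(np.asarray(presence, dtype=float))
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n))) if n > 1 else 0
    test_idx = order[:n_test]
    train_idx = order[n_test:]
    return P[train_idx], P[test_idx]


# ---------------------------------------------------------------------------
# Flat-text model serialization

def save_model(model: MaxentModel, path) -> None:
    payload = {
        "names": list(model.feature_set.names),
        "mins": model.feature_set.mins.tolist(),
        "maxs": model.feature_set.maxs.tolist(),
        "classes": list(model.feature_set.classes),
        "hinge_knots": list(model.feature_set.hinge_knots),
        "coefficients": model.coefficients.tolist(),
        "regularization": model.regularization,
        "log_z": model.log_z,
        "entropy": model.entropy,
        "background_means": model.background_means.tolist(),
        "n_background": model.n_background,
        "converged": model.converged,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> MaxentModel:
    with open(path, "r", encoding="utf-8") as fh:
        p = json.load(fh)
    fs = FeatureSet(
        names=tuple(p["names"]),
        mins=np.array(p["mins"]),
        maxs=np.array(p["maxs"]),
        classes=tuple(p["classes"]),
        hinge_knots=tuple(p["hinge_knots"]),
    )
    return MaxentModel(
        feature_set=fs,
        coefficients=np.array(p["coefficients"]),
        regularization=p["regularization"],
        log_z=p["log_z"],
        entropy=p["entropy"],
        background_means=np.array(p["background_means"]),
        n_background=p["n_background"],
        converged=p["converged"],
    )
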