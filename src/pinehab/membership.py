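"""Fuzzy membership standardization of ecological factors.

The primary family is the K-th-parabolic ("ridge") fuzzy distribution,
written K-t here: zero outside the support ``(a, d)``, a power-K rising
limb on ``(a, b)``, a plateau of full membership on ``[b, c]`` and a
power-K falling limb on ``(c, d)``::

    mu(x) = 0                            x <= a or x >= d
    mu(x) = ((x - a) / (b - a)) ** K     a <  x < b
    mu(x) = 1                            b <= x <= c
    mu(x) = ((d - x) / (d - c)) ** K     c <  x < d

Negative ``a`` for strictly positive quantities (precipitation, altitude)
simply means the fitted rising limb extends below the physical range.

Alternative families (trapezoidal, gaussian, sigmoid rise/fall) are
provided so the best family can be chosen by residual comparison, the way
the study's curve-fitting step selects among candidate distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .grids import Raster

__all__ = [
    "MembershipParams",
    "FittedMembership",
    "kt_membership",
    "membership",
    "fit_membership",
    "fit_best_family",
    "membership_thresholds",
    "standardize_raster",
    "read_params_csv",
    "write_params_csv",
]

FAMILIES = ("kt", "trapezoidal", "gaussian", "sigmoid-rise", "sigmoid-fall")


@dataclass(frozen=True)
class MembershipParams:
    """Parameters of one membership function.

    For the K-t and trapezoidal families ``a <= b <= c <= d`` delimit the
    support and plateau and ``k`` is the limb exponent (trapezoidal is the
    k = 1 special case with its own family tag). ``alpha``/``beta`` are the
    location/scale of the gaussian and sigmoid families.
    """

    family: str = "kt"
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    k: float = 1.0
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("kt", "trapezoidal"):
            if not (self.a <= self.b <= self.c <= self.d):
                raise ValueError("require a <= b <= c <= d")
            if self.k <= 0:
                raise ValueError("require K > 0")
        else:
            if self.beta is None or self.beta <= 0:
                raise ValueError(f"{self.family} requires beta > 0")
            if self.alpha is None:
                raise ValueError(f"{self.family} requires alpha")

    @property
    def n_free(self) -> int:
        return {"kt": 5, "trapezoidal": 4}.get(self.family, 2)


@dataclass(frozen=True)
class FittedMembership:
    params: MembershipParams
    goodness: float  # residual sum of squares
    n_points: int

    def __post_init__(self) -> None:
        if self.goodness < -1e-12:
            raise ValueError("RSS must be non-negative")


def kt_membership(x, params: MembershipParams):
    """Evaluate the K-t membership function; scalar in, scalar out."""
    if params.family not in ("kt", "trapezoidal"):
        raise ValueError("kt_membership requires a K-t or trapezoidal parameter set")
    a, b, c, d = params.a, params.b, params.c, params.d
    k = params.k if params.family == "kt" else 1.0
    if b == a or d == c:
        warnings.warn(
            "degenerate limb (b == a or d == c): membership steps 0 -> 1",
            stacklevel=2,
        )
    xa = np.asarray(x, dtype=float)
    mu = np.zeros_like(xa)
    if b > a:
        rising = (xa > a) & (xa < b)
        mu[rising] = ((xa[rising] - a) / (b - a)) ** k
    mu[(xa >= b) & (xa <= c)] = 1.0
    if d > c:
        falling = (xa > c) & (xa < d)
        mu[falling] = ((d - xa[falling]) / (d - c)) ** k
    mu[~np.isfinite(xa)] = np.nan
    return mu if np.ndim(x) else float(mu)


def membership(x, params: MembershipParams):
    """Evaluate any supported family."""
    if params.family in ("kt", "trapezoidal"):
        return kt_membership(x, params)
    xa = np.asarray(x, dtype=float)
    z = (xa - params.alpha) / params.beta
    if params.family == "gaussian":
        mu = np.exp(-0.5 * z**2)
    elif params.family == "sigmoid-rise":
        mu = 1.0 / (1.0 + np.exp(-z))
    else:  # sigmoid-fall
        mu = 1.0 / (1.0 + np.exp(z))
    return mu if np.ndim(x) else float(mu)


def membership_thresholds(params: MembershipParams, cutoff: float) -> tuple[float, float]:
    """The x-interval where membership >= cutoff, by closed-form limb inversion."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    if params.family in ("kt", "trapezoidal"):
        k = params.k if params.family == "kt" else 1.0
        root = cutoff ** (1.0 / k)
        x_low = params.a + (params.b - params.a) * root
        x_high = params.d - (params.d - params.c) * root
        return x_low, x_high
    if params.family == "gaussian":
        half = params.beta * np.sqrt(-2.0 * np.log(cutoff)) if cutoff < 1 else 0.0
        return params.alpha - half, params.alpha + half
    if cutoff == 1:
        raise ValueError("sigmoid membership never reaches 1 exactly")
    shift = params.beta * np.log(cutoff / (1 - cutoff))
    if params.family == "sigmoid-rise":
        return params.alpha + shift, np.inf
    return -np.inf, params.alpha - shift


def standardize_raster(factor: Raster, params: MembershipParams) -> Raster:
    """Cellwise membership of a factor raster; nodata propagates."""
    out = np.full_like(factor.values, np.nan)
    m = factor.mask
    out[m] = membership(factor.values[m], params)
    return Raster(factor.header, out)


# ---------------------------------------------------------------------------
# Fitting

def _bin_xy(x: np.ndarray, y: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-bin x, return per-bin means of x and y (empty bins dropped)."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        return x, y
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)
    bx, by = [], []
    for i in range(edges.size - 1):
        sel = idx == i
        if sel.any():
            bx.append(x[sel].mean())
            by.append(y[sel].mean())
    return np.array(bx), np.array(by)


def _kt_residual(theta: np.ndarray, x: np.ndarray, y: np.ndarray, fix_k: bool) -> np.ndarray:
    a, d1, d2, d3 = theta[:4]
    k = theta[4] if not fix_k else 1.0
    p = MembershipParams(
        family="kt" if not fix_k else "trapezoidal",
        a=a, b=a + d1, c=a + d1 + d2, d=a + d1 + d2 + d3,
        k=k if not fix_k else 1.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return kt_membership(x, p) - y


def _loc_scale_residual(theta, x, y, family):
    p = MembershipParams(family=family, alpha=theta[0], beta=abs(theta[1]) + 1e-12)
    return membership(x, p) - y


def _kt_inits(x: np.ndarray, y: np.ndarray, n_starts: int) -> list[np.ndarray]:
    """Multi-start initializations derived from data quantiles."""
    rng_pairs = [(0.25, 0.75), (0.1, 0.9), (0.3, 0.7), (0.4, 0.6), (0.2, 0.5),
                 (0.5, 0.8), (0.05, 0.5), (0.5, 0.95), (0.35, 0.65), (0.15, 0.85)]
    span = x.max() - x.min()
    inits = []
    # plateau seeded on the high-response region
    hi = x[y >= 0.8 * y.max()] if (y > 0).any() else x
    if hi.size >= 2:
        b0, c0 = np.quantile(hi, [0.1, 0.9])
        inits.append(np.array([b0 - 0.5 * span, max(0.5 * span, 1e-6),
                               max(c0 - b0, 1e-6), 0.5 * span, 2.0]))
    for lo, hi_q in rng_pairs:
        b0, c0 = np.quantile(x, [lo, hi_q])
        a0 = x.min() - 0.25 * span
        d0 = x.max() + 0.25 * span
        inits.append(np.array([a0, max(b0 - a0, 1e-6), max(c0 - b0, 1e-6),
                               max(d0 - c0, 1e-6), 2.0]))
        if len(inits) >= n_starts:
            break
    return inits[:n_starts]


def fit_membership(
    factor_values,
    indicator_values,
    family: str = "kt",
    n_bins: int | None = 20,
    rescale: bool = False,
    n_starts: int = 10,
) -> FittedMembership:
    """Nonlinear least-squares fit of one membership family.

    ``(factor, indicator)`` pairs are quantile-binned (bin means, ``n_bins``
    bins; pass ``None`` to fit unbinned) to stabilize the relationship, and
    optionally min-max rescaled to [0, 1] — useful when the indicator
    carries a baseline from other factors so the per-factor response does
    not span the full unit interval. Multi-start over data-quantile-derived
    initializations; the lowest-RSS solution is kept. Constraints
    ``a <= b <= c <= d`` are enforced by an increment parametrization.
    """
    x = np.asarray(factor_values, dtype=float)
    y = np.asarray(indicator_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 8:
        raise ValueError("need at least 8 points to fit a membership function")
    if np.ptp(x) == 0:
        raise ValueError("factor values are all identical; membership is unidentifiable")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")

    # degenerate: a constant indicator at full membership pins the plateau
    # to the observed factor range
    if family in ("kt", "trapezoidal") and np.ptp(y) < 1e-12 and abs(y[0] - 1.0) < 1e-12:
        pad = 0.25 * np.ptp(x)
        params = MembershipParams(
            family=family, a=x.min() - pad, b=x.min(), c=x.max(),
            d=x.max() + pad, k=1.0 if family == "trapezoidal" else 2.0,
        )
        return FittedMembership(params=params, goodness=0.0, n_points=int(x.size))

    if n_bins is not None and x.size > n_bins:
        x, y = _bin_xy(x, y, n_bins)
    if rescale:
        if np.ptp(y) == 0:
            y = np.ones_like(y)
        else:
            y = (y - y.min()) / np.ptp(y)

    span = float(x.max() - x.min())
    best: tuple[float, MembershipParams] | None = None

    if family in ("kt", "trapezoidal"):
        fix_k = family == "trapezoidal"
        # keep the support within one span of the observed data: wider
        # supports are unidentifiable and let the optimizer run away
        lower = [x.min() - span, 0.0, 0.0, 0.0, 0.05]
        upper = [x.max() + span, 2 * span, 2 * span, 2 * span, 60.0]
        for x0 in _kt_inits(x, y, n_starts):
            if fix_k:
                x0 = x0[:4]
            try:
                res = least_squares(
                    _kt_residual, x0,
                    bounds=(lower[: x0.size], upper[: x0.size]),
                    args=(x, y, fix_k), xtol=1e-12, ftol=1e-12, max_nfev=2000,
                )
            except Exception:
                continue
            a, d1, d2, d3 = res.x[:4]
            k = res.x[4] if not fix_k else 1.0
            params = MembershipParams(
                family=family, a=a, b=a + d1, c=a + d1 + d2,
                d=a + d1 + d2 + d3, k=k,
            )
            rss = float(2 * res.cost)
            if best is None or rss < best[0]:
                best = (rss, params)
    else:
        med = float(np.median(x))
        scales = [span / 6, span / 3, span]
        centers = np.quantile(x, [0.25, 0.5, 0.75])
        starts = [np.array([c, s]) for c in centers for s in scales][:n_starts]
        for x0 in starts:
            try:
                res = least_squares(
                    _loc_scale_residual, x0, args=(x, y, family),
                    xtol=1e-12, ftol=1e-12, max_nfev=2000,
                )
            except Exception:
                continue
            params = MembershipParams(
                family=family, alpha=float(res.x[0]), beta=abs(float(res.x[1])) + 1e-12
            )
            rss = float(2 * res.cost)
            if best is None or rss < best[0]:
                best = (rss, params)

    if best is None:
        raise RuntimeError(f"membership fit failed for family {family!r}")
    return FittedMembership(params=best[1], goodness=best[0], n_points=int(x.size))


def _eval_mu(X: np.ndarray, params: list[MembershipParams]) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.column_stack(
            [kt_membership(X[:, j], p) for j, p in enumerate(params)]
        )


def _amplitude_fit(mu: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Intercept (free) + non-negative amplitudes by bounded linear LS."""
    from scipy.optimize import lsq_linear

    A = np.column_stack([np.ones(len(y)), mu])
    k = mu.shape[1]
    res = lsq_linear(A, y, bounds=([-np.inf] + [0.0] * k, [np.inf] + [2.0] * k))
    return float(res.x[0]), res.x[1:]


def fit_memberships_joint(
    factor_values: np.ndarray,
    indicator_values,
    names: tuple[str, ...],
    inits: dict[str, MembershipParams] | None = None,
    weight_inits: dict[str, float] | None = None,
    n_rounds: int = 4,
) -> tuple[dict[str, MembershipParams], dict[str, float], float]:
    """Jointly calibrate all K-t memberships and factor weights.

    Fits ``indicator ~ intercept + sum_i v_i * mu_i(x_i)`` with
    ``v_i >= 0`` by backfitting: each factor's membership is refitted (with
    the multi-start marginal fitter) against its partial residual, then the
    intercept and amplitudes are re-estimated by non-negative linear least
    squares; finally all parameters are polished together by one bounded
    nonlinear least-squares solve. Returns the per-factor parameters, the
    normalized weights ``v / sum(v)`` and the residual sum of squares.

    Fitting all factors at once removes the baseline each factor's
    marginal response inherits from the others, which is what defeats
    purely marginal fitting for low-weight factors.
    """
    X = np.atleast_2d(np.asarray(factor_values, dtype=float))
    y = np.asarray(indicator_values, dtype=float)
    ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[ok], y[ok]
    k = len(names)
    if X.shape[1] != k:
        raise ValueError("factor_values columns must match names")
    if X.shape[0] < 6 * k + 2:
        raise ValueError("too few points for a joint fit")
    spans = X.max(axis=0) - X.min(axis=0)
    if (spans == 0).any():
        raise ValueError("a factor is constant; joint fit is unidentifiable")

    # --- initial state
    params: list[MembershipParams] = []
    for j, name in enumerate(names):
        if inits and name in inits and inits[name].family in ("kt", "trapezoidal"):
            params.append(inits[name])
        else:
            xj = X[:, j]
            q = np.quantile(xj, [0.3, 0.7])
            params.append(MembershipParams(
                family="kt", a=xj.min() - 0.25 * spans[j], b=q[0], c=q[1],
                d=xj.max() + 0.25 * spans[j], k=2.0))
    mu = _eval_mu(X, params)
    alpha, v = _amplitude_fit(mu, y)
    rss = float(((alpha + mu @ v - y) ** 2).sum())

    # --- backfitting rounds (dominant factors first), then a joint polish
    order = np.argsort(
        [-(weight_inits or {}).get(n, 1.0 / k) for n in names]
    )

    def unpack(theta):
        per = theta[: 5 * k].reshape(k, 5)
        out = []
        for j in range(k):
            a, d1, d2, d3, kk = per[j]
            out.append(MembershipParams(
                family="kt", a=a, b=a + d1, c=a + d1 + d2, d=a + d1 + d2 + d3, k=kk))
        return out, theta[5 * k: 6 * k], theta[-1]

    def residual(theta):
        p, vv, aa = unpack(theta)
        return aa + _eval_mu(X, p) @ vv - y

    for _outer in range(1):
        for _ in range(n_rounds):
            prev = rss
            for j in order:
                others = alpha + mu @ v - v[j] * mu[:, j]
                resid = y - others
                if v[j] > 1e-8:
                    resid = resid / v[j]
                try:
                    fit = fit_membership(X[:, j], resid, family="kt",
                                         n_bins=20, rescale=True)
                except (ValueError, RuntimeError):
                    continue
                cand = params.copy()
                cand[j] = fit.params
                mu_c = _eval_mu(X, cand)
                alpha_c, v_c = _amplitude_fit(mu_c, y)
                rss_c = float(((alpha_c + mu_c @ v_c - y) ** 2).sum())
                if rss_c < rss:
                    params, mu, alpha, v, rss = cand, mu_c, alpha_c, v_c, rss_c
            if prev - rss < 1e-8:
                break

        # joint polish from the current state
        x0 = np.zeros(6 * k + 1)
        lo = np.zeros_like(x0)
        hi = np.zeros_like(x0)
        for j in range(k):
            p = params[j]
            xj = X[:, j]
            lo[5 * j: 5 * j + 5] = [xj.min() - spans[j], 0, 0, 0, 0.05]
            hi[5 * j: 5 * j + 5] = [xj.max() + spans[j], 2 * spans[j],
                                    2 * spans[j], 2 * spans[j], 60.0]
            x0[5 * j: 5 * j + 5] = np.clip(
                [p.a, max(p.b - p.a, 1e-6), max(p.c - p.b, 0.0),
                 max(p.d - p.c, 1e-6), p.k],
                lo[5 * j: 5 * j + 5], hi[5 * j: 5 * j + 5])
            x0[5 * k + j] = v[j]
            lo[5 * k + j], hi[5 * k + j] = 0.0, 2.0
        x0[-1] = np.clip(alpha, -1, 1)
        lo[-1], hi[-1] = -1.0, 1.0
        res = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-10,
                            ftol=1e-10, max_nfev=3000)
        rss_p = float(2 * res.cost)
        if rss_p < rss:
            params, v, alpha = unpack(res.x)
            mu = _eval_mu(X, params)
            rss = rss_p

    total = v.sum()
    weights = {
        name: float(vi / total) if total > 0 else 1.0 / k
        for name, vi in zip(names, v)
    }
    return dict(zip(names, params)), weights, rss


def fit_best_family(
    factor_values,
    indicator_values,
    families: tuple[str, ...] = FAMILIES,
    **kwargs,
) -> FittedMembership:
    """Fit every candidate family and keep the lowest penalized residual.

    The penalty RSS * n / (n - p) discounts each extra free parameter so a
    simpler family wins ties.
    """
    fits = []
    for fam in families:
        try:
            fit = fit_membership(factor_values, indicator_values, family=fam, **kwargs)
        except (ValueError, RuntimeError):
            continue
        p = fit.params.n_free
        penalty = fit.n_points / max(fit.n_points - p, 1)
        fits.append((fit.goodness * penalty, fit))
    if not fits:
        raise RuntimeError("no membership family could be fitted")
    return min(fits, key=lambda t: t[0])[1]


# ---------------------------------------------------------------------------
# Parameter table I/O (factor, a, b, c, d, K, family)

def write_params_csv(params: dict[str, MembershipParams], path) -> None:
    rows = []
    for name, p in params.items():
        rows.append(
            {"factor": name, "a": p.a, "b": p.b, "c": p.c, "d": p.d,
             "K": p.k, "family": p.family, "alpha": p.alpha, "beta": p.beta}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_params_csv(path) -> dict[str, MembershipParams]:
    frame = pd.read_csv(path)
    out = {}
    for row in frame.itertuples(index=False):
        alpha = None if pd.isna(getattr(row, "alpha", np.nan)) else float(row.alpha)
        beta = None if pd.isna(getattr(row, "beta", np.nan)) else float(row.beta)
        out[str(row.factor)] = MembershipParams(
            family=str(row.family), a=float(row.a), b=float(row.b),
            c=float(row.c), d=float(row.d), k=float(row.K),
            alpha=alpha, beta=beta,
        )
    return out
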