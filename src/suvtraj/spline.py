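"""Penalized-spline regression of rate on biomarker level.

The smoother is a cubic B-spline basis with a second-order divided-difference
penalty built on the basis's Greville abscissae.  Because B-splines reproduce
linear functions through their Greville sites, the penalty's null space is
exactly the space of straight lines in the level, so the lambda -> infinity
limit of the fit is the ordinary least-squares line even with non-uniform
(quantile-placed) knots.

The smoothing parameter is chosen by restricted maximum likelihood (REML),
either with a Fellner-Schall-type fixed-point update (default) or by a
log-grid search with local refinement; the two agree at the REML optimum and
the fixed point falls back to the grid on non-convergence.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
    NumericalError,
)

logger = logging.getLogger(__name__)

DEGREE = 3  # cubic
EXTRAPOLATION_MODES = ("clamp", "linear", "error")


# ---------------------------------------------------------------------------
# basis construction


def build_knots(x: np.ndarray, n_basis: int, strategy: str = "quantile") -> np.ndarray:
    """Full (clamped) knot vector for a cubic B-spline basis over ``x``.

    ``quantile`` places interior knots at quantiles of the unique levels with
    basis dimension min(n_basis, #unique); ``unique`` places a knot at every
    unique level (fidelity mode mirroring knots-at-every-datum smoothers).
    """
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < 2:
        raise DegenerateDesignError("all levels identical; cannot build a basis")
    lo, hi = float(ux[0]), float(ux[-1])
    if strategy == "unique":
        interior = ux[1:-1]
    elif strategy == "quantile":
        p = max(DEGREE + 1, min(int(n_basis), ux.size))
        n_interior = p - (DEGREE + 1)
        if n_interior > 0:
            probs = np.arange(1, n_interior + 1) / (n_interior + 1)
            interior = np.unique(np.quantile(ux, probs))
            interior = interior[(interior > lo) & (interior < hi)]
            # thin near-coincident knots (heavily tied data can place quantile
            # knots arbitrarily close, which makes the difference penalty
            # numerically explosive); enforce half the nominal uniform gap
            min_gap = (hi - lo) / (2.0 * (n_interior + 1))
            kept = []
            last = lo
            for kn in interior:
                if kn - last >= min_gap and hi - kn >= min_gap:
                    kept.append(kn)
                    last = kn
            interior = np.array(kept)
        else:
            interior = np.array([])
    else:
        raise ValueError(f"unknown knot strategy {strategy!r}")
    return np.r_[[lo] * (DEGREE + 1), interior, [hi] * (DEGREE + 1)]


def greville_abscissae(knots: np.ndarray) -> np.ndarray:
    """Greville sites xi_i = mean of k consecutive interior knots."""
    p = len(knots) - DEGREE - 1
    return np.array([knots[i + 1 : i + DEGREE + 1].mean() for i in range(p)])


def second_difference_penalty(greville: np.ndarray) -> np.ndarray:
    """Second divided-difference matrix D (rows vanish on coefficients linear
    in the Greville sites, hence on splines that are straight lines in x)."""
    xi = np.asarray(greville, dtype=float)
    p = xi.size
    if p < 3:
        raise DegenerateDesignError("need at least 3 basis functions for a 2nd-order penalty")
    D = np.zeros((p - 2, p))
    for i in range(p - 2):
        h1 = xi[i + 1] - xi[i]
        h2 = xi[i + 2] - xi[i + 1]
        D[i, i] = 1.0 / (h1 * (h1 + h2))
        D[i, i + 1] = -1.0 / (h1 * h2)
        D[i, i + 2] = 1.0 / (h2 * (h1 + h2))
    # normalise the overall scale (mean squared row norm = 1) so smoothing
    # parameters are comparable across data sets and the normal equations
    # stay well conditioned over the whole lambda search range
    D *= math.sqrt(D.shape[0] / np.sum(D * D))
    return D


def design_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Dense B-spline design matrix at the points ``x`` (must lie in range)."""
    return BSpline.design_matrix(np.asarray(x, float), knots, DEGREE).toarray()


# ---------------------------------------------------------------------------
# REML machinery


def _solve_coef(B: np.ndarray, y: np.ndarray, D: np.ndarray, lam: float) -> np.ndarray:
    """Penalized LS coefficients via the numerically robust augmented system."""
    if lam > 0:
        aug = np.vstack([B, math.sqrt(lam) * D])
        rhs = np.r_[y, np.zeros(D.shape[0])]
    else:
        aug, rhs = B, y
    coef, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    return coef


def _reml_parts(BtB, Bty, B, y, S, lam, n, p, M):
    """Coefficients and the pieces of the restricted likelihood at ``lam``."""
    A = BtB + lam * S
    w, V = np.linalg.eigh(A)
    wmax = w[-1]
    if not np.isfinite(wmax) or wmax <= 0:
        raise NumericalError("penalized normal equations are not positive")
    winv = np.where(w > wmax * 1e-13, 1.0 / np.maximum(w, 1e-300), 0.0)
    Ainv = (V * winv) @ V.T
    coef = Ainv @ Bty
    resid = y - B @ coef
    rss = float(resid @ resid)
    pen = float(coef @ (S @ coef))
    logdetA = float(np.sum(np.log(np.maximum(w, wmax * 1e-13))))
    tr_AinvS = float(np.trace(Ainv @ S))
    return coef, rss, pen, logdetA, tr_AinvS


def reml_score(lam: float, B, y, S, M: int = 2) -> float:
    """Negative restricted log-likelihood (up to a constant) at ``lam``.

    Gaussian penalized regression with the residual variance profiled out:
    minimising this over lam is the REML smoothing selection criterion.
    """
    B = np.asarray(B, float)
    y = np.asarray(y, float)
    n, p = B.shape
    BtB = B.T @ B
    Bty = B.T @ y
    _, rss, pen, logdetA, _ = _reml_parts(BtB, Bty, B, y, S, lam, n, p, M)
    dl = max(rss + lam * pen, 1e-300)
    sig2 = dl / (n - M)
    return 0.5 * ((n - M) * (math.log(2 * math.pi * sig2) + 1.0) + logdetA - (p - M) * math.log(max(lam, 1e-300)))


def select_smoothing(
    B: np.ndarray,
    y: np.ndarray,
    D: np.ndarray,
    method: str = "efs",
    lam_bounds: tuple[float, float] = (1e-8, 1e12),
    max_iter: int = 200,
    tol: float = 1e-4,
    lam0: float = 1.0,
) -> tuple[float, dict]:
    """Choose the smoothing parameter by REML.

    ``efs`` runs the Fellner-Schall-type fixed-point update (with a log-grid
    fallback if it fails to converge); ``grid`` minimizes the REML criterion
    over a log-spaced grid with local refinement.  Returns ``(lam, info)``
    where ``info`` records convergence and the attained REML score.
    """
    B = np.asarray(B, float)
    y = np.asarray(y, float)
    n, p = B.shape
    if n <= p - 2:
        raise InsufficientDataError(
            f"smoothing selection needs more rows ({n}) than penalized dimensions ({p - 2})"
        )
    S = D.T @ D
    M = p - np.linalg.matrix_rank(D)
    BtB = B.T @ B
    Bty = B.T @ y
    lo, hi = lam_bounds

    def score(lam):
        _, rss, pen, logdetA, _ = _reml_parts(BtB, Bty, B, y, S, lam, n, p, M)
        dl = max(rss + lam * pen, 1e-300)
        sig2 = dl / (n - M)
        return 0.5 * (
            (n - M) * (math.log(2 * math.pi * sig2) + 1.0)
            + logdetA
            - (p - M) * math.log(max(lam, 1e-300))
        )

    def grid_search():
        lams = np.logspace(math.log10(lo), math.log10(hi), 81)
        scores = np.array([score(l) for l in lams])
        i = int(np.argmin(scores))
        a = lams[max(i - 1, 0)]
        b = lams[min(i + 1, len(lams) - 1)]
        res = minimize_scalar(
            lambda u: score(10.0**u),
            bounds=(math.log10(a), math.log10(b)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam = float(10.0**res.x)
        return (lam, score(lam)) if score(lam) <= scores[i] else (float(lams[i]), float(scores[i]))

    if method == "grid":
        lam, sc = grid_search()
        return lam, {"method": "grid", "converged": True, "reml": sc}
    if method != "efs":
        raise ValueError(f"unknown smoothing method {method!r}")

    lam = float(np.clip(lam0, lo, hi))
    converged = False
    for it in range(max_iter):
        _, rss, pen, _, tr_AinvS = _reml_parts(BtB, Bty, B, y, S, lam, n, p, M)
        if pen <= 1e-14 * max(rss, 1.0):
            # fit already lies in the penalty null space; push lam to the cap
            new = hi
        else:
            sig2 = (rss + lam * pen) / (n - M)
            num = max((p - M) - lam * tr_AinvS, 0.0)
            new = sig2 * num / pen
        new = float(np.clip(new, lo, hi))
        if abs(math.log(max(new, 1e-300)) - math.log(max(lam, 1e-300))) < tol:
            lam = new
            converged = True
            break
        lam = new
    info = {"method": "efs", "converged": converged, "n_iter": it + 1}
    if not converged:
        logger.warning("Fellner-Schall update did not converge; falling back to grid REML")
        glam, gsc = grid_search()
        if gsc < score(lam):
            lam = glam
        info["fallback"] = "grid"
    info["reml"] = score(lam)
    return lam, info


# ---------------------------------------------------------------------------
# estimator


class PenalizedSplineRegressor(RegressorMixin, BaseEstimator):
    """Penalized B-spline smoother of a response on a single covariate.

    Parameters
    ----------
    n_basis:
        Target basis dimension; the actual dimension is
        ``min(n_basis, #unique levels)`` (quantile strategy).
    knot_strategy:
        ``quantile`` (default) or ``unique`` (a knot at every unique level).
    lam:
        Fixed smoothing parameter; ``None`` selects it by REML.
    smoothing:
        ``efs`` (Fellner-Schall fixed point, grid fallback) or ``grid``.
    extrapolation:
        Behaviour outside the training domain: ``clamp`` (boundary value),
        ``linear`` (first-order continuation), or ``error``.

    Attributes (after fit)
    ----------------------
    knots_, coef_, lam_, edf_, sigma2_, domain_, greville_, reml_, n_iter_,
    converged_
    """

    def __init__(
        self,
        n_basis: int = 40,
        knot_strategy: str = "quantile",
        lam: float | None = None,
        smoothing: str = "efs",
        lam_bounds: tuple[float, float] = (1e-8, 1e12),
        max_iter: int = 200,
        tol: float = 1e-4,
        extrapolation: str = "clamp",
    ):
        self.n_basis = n_basis
        self.knot_strategy = knot_strategy
        self.lam = lam
        self.smoothing = smoothing
        self.lam_bounds = lam_bounds
        self.max_iter = max_iter
        self.tol = tol
        self.extrapolation = extrapolation

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y have different lengths")
        if x.size < 2:
            raise InsufficientDataError("need at least 2 observations")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in the regression data")
        if self.extrapolation not in EXTRAPOLATION_MODES:
            raise ValueError(f"extrapolation must be one of {EXTRAPOLATION_MODES}")

        knots = build_knots(x, self.n_basis, self.knot_strategy)
        B = design_matrix(x, knots)
        xi = greville_abscissae(knots)
        D = second_difference_penalty(xi)
        yw, Bw = y, B
        if sample_weight is not None:
            sw = np.sqrt(np.asarray(sample_weight, dtype=float).reshape(-1))
            Bw = B * sw[:, None]
            yw = y * sw

        if self.lam is not None:
            lam = float(self.lam)
            info = {"method": "fixed", "converged": True}
        else:
            lam, info = select_smoothing(
                Bw,
                yw,
                D,
                method=self.smoothing,
                lam_bounds=self.lam_bounds,
                max_iter=self.max_iter,
                tol=self.tol,
            )

        coef = _solve_coef(Bw, yw, D, lam)
        n, p = Bw.shape
        S = D.T @ D
        M = p - np.linalg.matrix_rank(D)
        _, rss, pen, _, tr_AinvS = _reml_parts(Bw.T @ Bw, Bw.T @ yw, Bw, yw, S, max(lam, 1e-300), n, p, M)
        resid = yw - Bw @ coef
        rss = float(resid @ resid)
        rank_B = int(np.linalg.matrix_rank(Bw.T @ Bw, hermitian=True))
        # edf lives in [null-space dimension, rank of the design]
        edf = float(np.clip(p - lam * tr_AinvS, p - np.linalg.matrix_rank(D), rank_B))

        self.knots_ = knots
        self.greville_ = xi
        self.coef_ = coef
        self.lam_ = float(lam)
        self.edf_ = edf
        self.sigma2_ = rss / max(n - edf, 1.0)
        self.domain_ = (float(np.min(x)), float(np.max(x)))
        self.reml_ = info.get("reml")
        self.n_iter_ = info.get("n_iter", 0)
        self.converged_ = bool(info.get("converged", True))
        self._spline = BSpline(knots, coef, DEGREE)
        self.n_features_in_ = 1
        return self

    def predict(self, X, extrapolation: str | None = None):
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted")
        mode = extrapolation or self.extrapolation
        x = np.asarray(X, dtype=float).reshape(-1)
        lo, hi = self.domain_
        if mode == "error" and (np.any(x < lo) or np.any(x > hi)):
            raise DomainError(f"level outside fitted domain [{lo:.4g}, {hi:.4g}]")
        xc = np.clip(x, lo, hi)
        out = self._spline(xc)
        if mode == "linear":
            deriv = self._spline.derivative()
            below = x < lo
            above = x > hi
            if below.any():
                out[below] += deriv(lo) * (x[below] - lo)
            if above.any():
                out[above] += deriv(hi) * (x[above] - hi)
        return out


# ---------------------------------------------------------------------------
# serializable fitted rate function


@dataclass
class RateFunction:
    """Fitted mapping from biomarker level to annual rate of change.

    Wraps a fitted penalized B-spline so trajectories can be integrated and
    curves re-evaluated without refitting.  Callable; outside ``domain`` the
    behaviour follows ``extrapolation`` (default: clamp to boundary value).
    """

    basis_kind: str
    knots: np.ndarray
    coefficients: np.ndarray
    lam: float
    domain: tuple[float, float]
    edf: float
    sigma2: float
    extrapolation: str = "clamp"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.domain = (float(self.domain[0]), float(self.domain[1]))
        self._spline = BSpline(self.knots, self.coefficients, DEGREE)
        self._deriv = None

    def __call__(self, level, extrapolation: str | None = None):
        mode = extrapolation or self.extrapolation
        x = np.asarray(level, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        lo, hi = self.domain
        if mode == "error" and (np.any(x < lo) or np.any(x > hi)):
            raise DomainError(f"level outside fitted domain [{lo:.4g}, {hi:.4g}]")
        out = self._spline(np.clip(x, lo, hi))
        if mode == "linear":
            if self._deriv is None:
                self._deriv = self._spline.derivative()
            below, above = x < lo, x > hi
            if below.any():
                out[below] += self._deriv(lo) * (x[below] - lo)
            if above.any():
                out[above] += self._deriv(hi) * (x[above] - hi)
        return float(out[0]) if scalar else out

    @classmethod
    def from_estimator(cls, est: PenalizedSplineRegressor, **metadata) -> "RateFunction":
        return cls(
            basis_kind="penalized_bspline",
            knots=est.knots_,
            coefficients=est.coef_,
            lam=est.lam_,
            domain=est.domain_,
            edf=est.edf_,
            sigma2=est.sigma2_,
            extrapolation=est.extrapolation,
            metadata=dict(metadata),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "basis_kind": self.basis_kind,
                "knots": self.knots.tolist(),
                "coefficients": self.coefficients.tolist(),
                "lam": self.lam,
                "domain": list(self.domain),
                "edf": self.edf,
                "sigma2": self.sigma2,
                "extrapolation": self.extrapolation,
                "metadata": self.metadata,
            },
            sort_keys=True,
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "RateFunction":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["domain"] = tuple(d["domain"])
        return cls(**d)


def fit_rate_function(
    slopes,
    n_basis: int = 40,
    knot_strategy: str = "quantile",
    lam: float | None = None,
    smoothing: str = "efs",
    weight_by_interval: bool = False,
    extrapolation: str = "clamp",
) -> RateFunction:
    """Fit the rate-vs-level penalized spline on an interval-slope set.

    ``weight_by_interval`` optionally weights each slope row by its interval
    length (off by default: rows are unweighted).
    """
    if len(slopes) < 10:
        raise InsufficientDataError(
            f"need >= 10 slope rows to fit the rate function, got {len(slopes)}"
        )
    x = np.asarray(slopes["level"], dtype=float)
    y = np.asarray(slopes["rate"], dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateDesignError("all levels identical")
    est = PenalizedSplineRegressor(
        n_basis=n_basis,
        knot_strategy=knot_strategy,
        lam=lam,
        smoothing=smoothing,
        extrapolation=extrapolation,
    )
    w = np.asarray(slopes["interval_length"], float) if weight_by_interval else None
    est.fit(x, y, sample_weight=w)
    return RateFunction.from_estimator(
        est,
        n_obs=int(len(slopes)),
        converged=est.converged_,
        reml=est.reml_,
        reference=slopes.attrs.get("reference"),
    )


def evaluate_rate(f: RateFunction, level, extrapolation: str = "clamp"):
    """Evaluate a fitted rate function (thin functional wrapper)."""
    return f(level, extrapolation=extrapolation)
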