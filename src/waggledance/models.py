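"""Distance-duration calibration models for waggle dances.

Three model families describe how a dance duration component (waggle phase
``tw``, return phase ``tr`` or circuit ``tc``, seconds) grows with feeder
distance ``d`` (km):

* **linear** — ``t = alpha + beta*d``, the straight line used by most
  short-range feeder-training studies;
* **vfk** (von Frisch-Kratky) — the saturating curve
  ``t = a + (b/c) * (1 - exp(-c*d))`` with intercept ``a``, initial slope
  ``b`` and flattening rate ``c`` (asymptote ``a + b/c``), which flattens
  continuously with distance;
* **segmented** — a continuous two-segment ("break-point") line
  ``t = beta0 + beta1*d + beta2*max(d - psi, 0)``, i.e. slope ``beta1``
  below the break-point ``psi`` and ``beta1 + beta2`` beyond it.

Each family is a scikit-learn style regressor: ``fit(X, y)`` takes distances
(1-d or a single column) and durations, fitted attributes carry a trailing
underscore, and the estimators compose with sklearn tools.  Both the vfk and
segmented fits exploit conditional linearity: for a fixed non-linear
parameter (``c`` resp. ``psi``) the model is linear in the rest, so the fit
is a deterministic 1-d profile search (dense grid, then bounded scalar
refinement) over the profiled residual sum of squares — no starting values,
no RNG.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "LinearCalibration",
    "VonFrischKratkyCalibration",
    "SegmentedCalibration",
    "fit_linear",
    "fit_vfk",
    "fit_segmented",
    "make_calibration",
    "gaussian_loglik",
    "pearson_fit_r",
    "bias_check",
    "runs_test_pvalue",
    "CalibrationError",
    "OutOfRangeError",
    "DegenerateFitError",
    "UnstableBreakError",
]


class CalibrationError(ValueError):
    """Base class for calibration model errors."""


class OutOfRangeError(CalibrationError):
    """A duration cannot be inverted under the given calibration."""


class DegenerateFitError(CalibrationError):
    """A likelihood is requested for a fit with zero residual variance."""


class UnstableBreakError(CalibrationError):
    """Too few distinct distances on one side of a fitted break-point."""


def _as_distances(X) -> np.ndarray:
    d = np.asarray(X, dtype=float)
    if d.ndim == 2 and d.shape[1] == 1:
        d = d[:, 0]
    if d.ndim > 1:
        raise ValueError("distances must be 1-d or a single column")
    return np.atleast_1d(d)


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximised Gaussian log-likelihood of a regression with given RSS.

    Profiling out the error variance (sigma^2 = rss/n) gives
    ``-(n/2) * (log(2*pi*rss/n) + 1)``, the value R's ``logLik`` reports for
    ``lm``/``nls`` fits; it is what the AICc comparison consumes.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if rss <= 0:
        raise DegenerateFitError("zero RSS: log-likelihood is unbounded")
    return -(n / 2.0) * (math.log(2.0 * math.pi * rss / n) + 1.0)


def pearson_fit_r(fitted: Sequence[float], observed: Sequence[float]) -> float:
    """Pearson correlation between model predictions and observations."""
    fitted = np.asarray(fitted, float)
    observed = np.asarray(observed, float)
    if fitted.shape != observed.shape or fitted.size < 3:
        raise ValueError("fitted and observed must be equal-length, n >= 3")
    if np.ptp(fitted) == 0 or np.ptp(observed) == 0:
        raise CalibrationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(fitted, observed).statistic)


class _Calibration(RegressorMixin, BaseEstimator):
    """Shared fit bookkeeping and the profile-OLS helper."""

    family: str = "base"
    k_: int  # parameters counted by information criteria (incl. variance)

    # subclasses implement _curve(d) -> t and _invert_scalar(t) -> d

    def _finalize(self, d: np.ndarray, y: np.ndarray, k: int) -> None:
        self.X_ = d
        self.y_ = y
        self.n_ = int(y.size)
        self.fitted_ = self._curve(d)
        self.residuals_ = y - self.fitted_
        self.rss_ = float(self.residuals_ @ self.residuals_)
        self.k_ = k
        # interpolating fits leave float-noise RSS; treat those as exact
        if self.rss_ > 1e-24 * max(1.0, float(y @ y)):
            self.loglik_ = gaussian_loglik(self.rss_, self.n_)
            self.degenerate_ = False
        else:  # interpolating fit; likelihood unbounded
            self.loglik_ = math.inf
            self.degenerate_ = True

    def predict(self, X) -> np.ndarray:
        d = _as_distances(X)
        if np.any(d < 0):
            raise ValueError("distances must be >= 0")
        return self._curve(d)

    def invert(self, t):
        """Inverse prediction: duration(s) -> distance(km).

        Raises :class:`OutOfRangeError` when ``t`` lies outside the curve's
        attainable range (below the value at d = 0, or at/above a saturating
        asymptote).
        """
        t_arr = np.asarray(t, dtype=float)
        out = np.array([self._invert_scalar(v) for v in np.atleast_1d(t_arr)])
        return float(out[0]) if t_arr.ndim == 0 else out

    def formula(self, response: str = "t") -> str:
        raise NotImplementedError

    def to_dict(self) -> dict:
        out = {"family": self.family, "params": self._params_dict()}
        for attr in ("n_", "rss_", "loglik_", "k_"):
            if hasattr(self, attr):
                out[attr.rstrip("_")] = getattr(self, attr)
        if getattr(self, "response_", None):
            out["response"] = self.response_
        if getattr(self, "boundary_warning_", False):
            out["boundary_warning"] = True
        return out


class LinearCalibration(_Calibration):
    """Straight-line calibration ``t = alpha + beta*d`` (OLS fit, k = 3)."""

    family = "linear"

    def fit(self, X, y):
        d = _as_distances(X)
        y = np.asarray(y, dtype=float)
        if d.size != y.size or d.size < 3:
            raise ValueError("need n >= 3 paired observations")
        if np.ptp(d) == 0:
            raise np.linalg.LinAlgError("distances are constant: rank-deficient")
        design = np.column_stack([np.ones_like(d), d])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.alpha_, self.beta_ = map(float, coef)
        self._finalize(d, y, k=3)
        return self

    @classmethod
    def from_params(cls, alpha: float, beta: float) -> "LinearCalibration":
        est = cls()
        est.alpha_, est.beta_ = float(alpha), float(beta)
        return est

    def _curve(self, d: np.ndarray) -> np.ndarray:
        return self.alpha_ + self.beta_ * d

    def _invert_scalar(self, t: float) -> float:
        if self.beta_ == 0:
            raise OutOfRangeError("zero slope: line is not invertible")
        d = (t - self.alpha_) / self.beta_
        if d < 0:
            raise OutOfRangeError(
                f"duration {t:.4g} s below the curve value at d=0 "
                f"({self.alpha_:.4g} s)"
            )
        return d

    def _params_dict(self) -> dict:
        return {"alpha": self.alpha_, "beta": self.beta_}

    def formula(self, response: str = "t") -> str:
        return f"{response} = {self.alpha_:.4f} + {self.beta_:.4f}*d"


class VonFrischKratkyCalibration(_Calibration):
    """Saturating calibration ``t = a + (b/c) * (1 - exp(-c*d))``.

    Fitting profiles the flattening rate ``c``: for fixed ``c`` the model is
    linear in ``(a, b)`` via the regressor ``(1 - exp(-c*d))/c``, so the
    profiled RSS is minimised over a dense log-spaced grid in ``c_bounds``
    followed by bounded scalar refinement.  If the optimum sticks to a bound
    the fit is flagged (``boundary_warning_``); at the lower bound the model
    degenerates towards the straight line ``a + b*d``.  k = 4.
    """

    family = "vfk"

    def __init__(self, c_bounds: tuple[float, float] = (1e-3, 10.0),
                 grid_size: int = 200):
        self.c_bounds = c_bounds
        self.grid_size = grid_size

    @staticmethod
    def _basis(d: np.ndarray, c: float) -> np.ndarray:
        return -np.expm1(-c * d) / c

    def _profile_rss(self, d, y, c):
        design = np.column_stack([np.ones_like(d), self._basis(d, c)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid), coef

    def fit(self, X, y):
        d = _as_distances(X)
        y = np.asarray(y, dtype=float)
        if d.size != y.size or d.size < 4:
            raise ValueError("need n >= 4 paired observations")
        lo, hi = self.c_bounds
        if not (0 < lo < hi):
            raise CalibrationError("c_bounds must be a positive interval")
        grid = np.geomspace(lo, hi, self.grid_size)
        rss = np.array([self._profile_rss(d, y, c)[0] for c in grid])
        i = int(np.argmin(rss))
        lo_i, hi_i = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
        if lo_i < hi_i:
            res = optimize.minimize_scalar(
                lambda c: self._profile_rss(d, y, c)[0],
                bounds=(lo_i, hi_i), method="bounded",
                options={"xatol": 1e-10},
            )
            c = float(res.x) if res.fun <= rss[i] else float(grid[i])
        else:
            c = float(grid[i])
        _, coef = self._profile_rss(d, y, c)
        self.a_, self.b_ = float(coef[0]), float(coef[1])
        self.c_ = c
        self.boundary_warning_ = bool(
            c <= lo * (1 + 1e-3) or c >= hi * (1 - 1e-3)
        )
        self._finalize(d, y, k=4)
        return self

    @classmethod
    def from_params(cls, a: float, b: float, c: float) -> "VonFrischKratkyCalibration":
        if c <= 0:
            raise CalibrationError("flattening rate c must be > 0")
        est = cls()
        est.a_, est.b_, est.c_ = float(a), float(b), float(c)
        return est

    @property
    def asymptote_(self) -> float:
        return self.a_ + self.b_ / self.c_

    def _curve(self, d: np.ndarray) -> np.ndarray:
        if self.c_ <= 0:
            raise CalibrationError("flattening rate c must be > 0")
        return self.a_ + self.b_ * self._basis(d, self.c_)

    def _invert_scalar(self, t: float) -> float:
        if t < self.a_:
            raise OutOfRangeError(
                f"duration {t:.4g} s below the curve value at d=0 "
                f"({self.a_:.4g} s)"
            )
        if t >= self.asymptote_:
            raise OutOfRangeError(
                f"duration {t:.4g} s at or above the saturation asymptote "
                f"a + b/c = {self.asymptote_:.4g} s; an extrapolating piece "
                "is required to decode it"
            )
        return float(-math.log1p(-self.c_ * (t - self.a_) / self.b_) / self.c_)

    def _params_dict(self) -> dict:
        return {"a": self.a_, "b": self.b_, "c": self.c_}

    def formula(self, response: str = "t") -> str:
        return (f"{response} = {self.a_:.4f} + {self.b_:.4f}/{self.c_:.4f}"
                f"*(1 - exp(-{self.c_:.4f}*d))")


class SegmentedCalibration(_Calibration):
    """Continuous two-segment ("break-point") calibration.

    ``t = beta0 + beta1*d + beta2*max(d - psi, 0)``: slope ``beta1`` up to
    the break-point ``psi`` and ``beta1 + beta2`` beyond it; the second
    segment's intercept is ``beta0 - beta2*psi``.  Fitting profiles ``psi``:
    for each candidate the design ``{1, d, (d-psi)+}`` is an OLS problem, and
    the profiled RSS is searched on a dense grid over ``psi_bounds``
    (default: 2nd-smallest to 2nd-largest distinct distance) with bounded
    scalar refinement.  Continuity at ``psi`` holds by construction.  k = 5.
    """

    family = "segmented"

    def __init__(self, psi_bounds: tuple[float, float] | None = None,
                 grid_size: int = 400):
        self.psi_bounds = psi_bounds
        self.grid_size = grid_size

    @staticmethod
    def _design(d: np.ndarray, psi: float) -> np.ndarray:
        return np.column_stack([np.ones_like(d), d, np.maximum(d - psi, 0.0)])

    def _profile_rss(self, d, y, psi):
        design = self._design(d, psi)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid), coef

    def fit(self, X, y):
        d = _as_distances(X)
        y = np.asarray(y, dtype=float)
        if d.size != y.size or d.size < 5:
            raise ValueError("need n >= 5 paired observations")
        distinct = np.unique(d)
        if distinct.size < 4:
            raise UnstableBreakError("need >= 4 distinct distances")
        bounds = self.psi_bounds or (float(distinct[1]), float(distinct[-2]))
        if not (distinct[0] <= bounds[0] < bounds[1] <= distinct[-1]):
            raise CalibrationError(
                "psi_bounds must lie strictly inside the observed distances"
            )
        grid = np.linspace(bounds[0], bounds[1], self.grid_size)
        rss = np.array([self._profile_rss(d, y, p)[0] for p in grid])
        i = int(np.argmin(rss))
        lo_i, hi_i = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
        if lo_i < hi_i:
            res = optimize.minimize_scalar(
                lambda p: self._profile_rss(d, y, p)[0],
                bounds=(lo_i, hi_i), method="bounded",
                options={"xatol": 1e-10},
            )
            psi = float(res.x) if res.fun <= rss[i] else float(grid[i])
        else:
            psi = float(grid[i])
        _, coef = self._profile_rss(d, y, psi)
        self.beta0_, self.beta1_, self.beta2_ = map(float, coef)
        self.psi_ = psi
        if (np.sum(distinct <= psi) < 2) or (np.sum(distinct >= psi) < 2):
            raise UnstableBreakError(
                f"fewer than 2 distinct distances on one side of psi={psi:.4f}"
            )
        self._finalize(d, y, k=5)
        return self

    @classmethod
    def from_params(cls, beta0: float, beta1: float, beta2: float,
                    psi: float) -> "SegmentedCalibration":
        est = cls()
        est.beta0_, est.beta1_, est.beta2_ = (
            float(beta0), float(beta1), float(beta2))
        est.psi_ = float(psi)
        return est

    @classmethod
    def from_segments(cls, intercept1: float, slope1: float, psi: float,
                      slope2: float) -> "SegmentedCalibration":
        """Build from the per-segment parametrisation printed in reports."""
        return cls.from_params(intercept1, slope1, slope2 - slope1, psi)

    @property
    def segment2_intercept_(self) -> float:
        return self.beta0_ - self.beta2_ * self.psi_

    @property
    def segment2_slope_(self) -> float:
        return self.beta1_ + self.beta2_

    def _curve(self, d: np.ndarray) -> np.ndarray:
        return (self.beta0_ + self.beta1_ * d
                + self.beta2_ * np.maximum(d - self.psi_, 0.0))

    def _invert_scalar(self, t: float) -> float:
        t_break = self.beta0_ + self.beta1_ * self.psi_
        if t <= t_break:
            if self.beta1_ <= 0:
                raise OutOfRangeError("first segment slope must be > 0")
            d = (t - self.beta0_) / self.beta1_
            if d < 0:
                raise OutOfRangeError(
                    f"duration {t:.4g} s below the curve value at d=0 "
                    f"({self.beta0_:.4g} s)"
                )
            return d
        slope2 = self.segment2_slope_
        if slope2 <= 0:
            raise OutOfRangeError(
                f"duration {t:.4g} s beyond the break-point of a "
                "non-increasing second segment"
            )
        return (t - self.segment2_intercept_) / slope2

    def _params_dict(self) -> dict:
        return {"beta0": self.beta0_, "beta1": self.beta1_,
                "beta2": self.beta2_, "psi": self.psi_}

    def formula(self, response: str = "t") -> str:
        return (f"{response} = {self.beta0_:.4f} + {self.beta1_:.4f}*d "
                f"(d <= {self.psi_:.4f}); {self.segment2_intercept_:.4f} + "
                f"{self.segment2_slope_:.4f}*d (d > {self.psi_:.4f})")


# -- thin functional wrappers ----------------------------------------------


def _wrap_fit(est: _Calibration, d, t, response: str | None):
    est.fit(np.asarray(d, float), np.asarray(t, float))
    est.response_ = response
    return est


def fit_linear(d, t, response: str | None = None) -> LinearCalibration:
    return _wrap_fit(LinearCalibration(), d, t, response)


def fit_vfk(d, t, c_bounds: tuple[float, float] = (1e-3, 10.0),
            response: str | None = None) -> VonFrischKratkyCalibration:
    return _wrap_fit(VonFrischKratkyCalibration(c_bounds=c_bounds), d, t, response)


def fit_segmented(d, t, psi_bounds: tuple[float, float] | None = None,
                  response: str | None = None) -> SegmentedCalibration:
    return _wrap_fit(SegmentedCalibration(psi_bounds=psi_bounds), d, t, response)


_FAMILIES = {
    "linear": LinearCalibration,
    "vfk": VonFrischKratkyCalibration,
    "segmented": SegmentedCalibration,
}


def make_calibration(family: str, params: Mapping[str, float]) -> _Calibration:
    """Reconstruct a parameterised calibration, e.g. from a JSON artifact."""
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise CalibrationError(f"unknown model family {family!r}") from None
    return cls.from_params(**params)


# -- bias diagnostic --------------------------------------------------------


def runs_test_pvalue(signs: Sequence[int]) -> float:
    """One-sided exact Wald-Wolfowitz runs test for too few sign runs.

    Systematic lack of fit shows up as long same-sign stretches of the
    per-distance mean residuals, i.e. fewer runs than expected under random
    arrangement.  Returns P(R <= observed runs) conditional on the numbers of
    positive and negative signs; zeros are dropped by the caller.
    """
    s = [int(np.sign(v)) for v in signs if v != 0]
    n1 = sum(1 for v in s if v > 0)
    n2 = len(s) - n1
    if n1 == 0 or n2 == 0:
        return 1.0 if len(s) < 2 else float(
            1.0 / math.comb(n1 + n2, n1))  # single possible arrangement
    r_obs = 1 + sum(1 for a, b in zip(s, s[1:]) if a != b)
    total = math.comb(n1 + n2, n1)
    p = 0.0
    for r in range(2, r_obs + 1):
        if r % 2 == 0:
            k = r // 2
            count = 2 * math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k - 1)
        else:
            k = (r - 1) // 2
            count = (math.comb(n1 - 1, k) * math.comb(n2 - 1, k - 1)
                     + math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k))
        p += count / total
    return min(p, 1.0)


def bias_check(fit: _Calibration, alpha: float = 0.05,
               extreme_ratio: float = 0.5, extreme_z: float = 2.0) -> dict:
    """Quantitative surrogate for residual-plot inspection.

    Averages residuals per distinct training distance and flags the fit as
    biased if (i) the sign sequence of these means, ordered by distance, has
    significantly too few runs (exact runs test at ``alpha``), or (ii) the
    mean residual at either extreme distance is both large — more than
    ``extreme_ratio`` times the overall residual SD — and statistically
    clear — more than ``extreme_z`` standard errors of that per-distance
    mean.  A line forced through a saturating curve fails at the extremes;
    the SE condition keeps the false-alarm rate low at the handful of
    dances recorded per feeder distance.
    """
    d = fit.X_
    resid = fit.residuals_
    distances = np.unique(d)
    means = np.array([resid[d == v].mean() for v in distances])
    sd = float(resid.std(ddof=1)) if resid.size > 1 else 0.0
    if sd <= 1e-10:  # numerically perfect fit: nothing to diagnose
        return {
            "biased": False,
            "per_distance_mean_residual": dict(zip(distances.tolist(),
                                                   means.tolist())),
            "runs_pvalue": 1.0,
            "extreme_flag": False,
        }
    p_runs = runs_test_pvalue(np.sign(means))
    counts = np.array([(d == v).sum() for v in distances])
    ses = sd / np.sqrt(counts)
    extreme = bool(sd > 0 and any(
        abs(means[i]) > extreme_ratio * sd
        and abs(means[i]) > extreme_z * ses[i]
        for i in (0, -1)))
    return {
        "biased": bool(p_runs <= alpha or extreme),
        "per_distance_mean_residual": dict(zip(distances.tolist(),
                                               means.tolist())),
        "runs_pvalue": float(p_runs),
        "extreme_flag": bool(extreme),
    }
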