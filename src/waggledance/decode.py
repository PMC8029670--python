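"""Decoding foraging distance from dance durations.

A fitted distance-duration calibration is inverted to turn a measured waggle
(or circuit) duration into a distance estimate.  Because a saturating
von Frisch-Kratky curve has a finite asymptote ``a + b/c``, it cannot decode
durations at or beyond that value: field calibrations therefore continue the
curve past the training range with a linear piece (typically the second
segment of the companion break-point model).  This module provides

* :class:`PiecewiseCalibration` — an ordered set of model pieces covering
  [0, inf), with continuity/monotonicity checks and inverse prediction;
* :func:`build_study_calibration` — saturating curve over the trained range,
  linear break-point segment beyond it;
* :func:`historical_calibrations` — published long-range calibrations for
  *Apis mellifera carnica* (a remodelled waggle-duration curve and a linear
  circuit-duration extrapolation), usable for decoding beyond 1.7 km;
* :func:`decode_distance` — point estimate with a seeded case-resampling
  bootstrap interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import DanceSummary
from .models import (
    CalibrationError,
    LinearCalibration,
    OutOfRangeError,
    SegmentedCalibration,
    VonFrischKratkyCalibration,
    _Calibration,
    fit_segmented,
    fit_vfk,
)

__all__ = [
    "Piece",
    "PiecewiseCalibration",
    "DecodedDistance",
    "build_study_calibration",
    "single_family_calibration",
    "historical_calibrations",
    "decode_distance",
]

_EPS = 1e-9


@dataclass(frozen=True)
class Piece:
    """One model piece valid on the distance interval [d_lo, d_hi)."""

    d_lo: float
    d_hi: float  # math.inf for the terminal piece
    model: _Calibration


@dataclass
class PiecewiseCalibration:
    """A continuous, strictly increasing duration curve on [0, inf)."""

    name: str
    response: str  # "tw" | "tr" | "tc"
    pieces: tuple[Piece, ...]
    provenance: str = ""
    train_d_max: float | None = None
    refit_fn: Callable[[np.ndarray, np.ndarray], "PiecewiseCalibration"] | None = (
        field(default=None, repr=False))
    continuity_tol: float = 1e-3

    def __post_init__(self) -> None:
        if not self.pieces:
            raise CalibrationError("calibration needs at least one piece")
        if self.pieces[0].d_lo != 0 or not np.isinf(self.pieces[-1].d_hi):
            raise CalibrationError("pieces must cover [0, inf)")
        for a, b in zip(self.pieces, self.pieces[1:]):
            if b.d_lo != a.d_hi:
                raise CalibrationError("pieces must be contiguous")
            jump = b.model.predict([b.d_lo])[0] - a.model.predict([a.d_hi])[0]
            if abs(jump) > self.continuity_tol:
                warnings.warn(
                    f"{self.name}: {jump:+.4g} s discontinuity at "
                    f"{b.d_lo:g} km", stacklevel=2)
        # strict monotonicity scan over a generous range
        grid = np.linspace(0.0, max(10.0, 2 * (self.train_d_max or 5.0)), 2001)
        vals = self.predict(grid)
        if np.any(np.diff(vals) <= 0):
            raise CalibrationError(
                f"{self.name}: calibration curve is not strictly increasing")

    def predict(self, d) -> np.ndarray:
        d = np.atleast_1d(np.asarray(d, dtype=float))
        out = np.empty_like(d)
        for p in self.pieces:
            mask = (d >= p.d_lo) & (d < p.d_hi)
            if mask.any():
                out[mask] = p.model.predict(d[mask])
        return out

    def invert(self, t: float) -> float:
        """Duration (s) -> distance (km) by piecewise inverse prediction."""
        t = float(t)
        first = self.pieces[0].model
        t0 = float(first.predict([0.0])[0])
        if t < t0:
            raise OutOfRangeError(
                f"duration {t:.4g} s below the curve value at d=0 ({t0:.4g} s)")
        for i, p in enumerate(self.pieces):
            t_lo = float(p.model.predict([p.d_lo])[0])
            if i > 0 and t < t_lo - _EPS:
                # duration falls in an (allowed, small) jump at the boundary
                return p.d_lo
            if np.isinf(p.d_hi):
                return float(p.model.invert(t))  # may raise OutOfRangeError
            t_hi = float(p.model.predict([p.d_hi])[0])
            if t <= t_hi + _EPS:
                d = float(p.model.invert(t))
                return float(np.clip(d, p.d_lo, p.d_hi))
        raise OutOfRangeError(f"duration {t:.4g} s not attainable")  # pragma: no cover

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "response": self.response,
            "provenance": self.provenance,
            "train_d_max": self.train_d_max,
            "pieces": [
                {"d_lo": p.d_lo,
                 "d_hi": None if np.isinf(p.d_hi) else p.d_hi,
                 "family": p.model.family,
                 "params": p.model._params_dict()}
                for p in self.pieces
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PiecewiseCalibration":
        from .models import make_calibration

        pieces = tuple(
            Piece(
                d_lo=p["d_lo"],
                d_hi=np.inf if p["d_hi"] is None else p["d_hi"],
                model=make_calibration(p["family"], p["params"]),
            )
            for p in payload["pieces"]
        )
        return cls(name=payload["name"], response=payload["response"],
                   pieces=pieces, provenance=payload.get("provenance", ""),
                   train_d_max=payload.get("train_d_max"))


@dataclass(frozen=True)
class DecodedDistance:
    """A distance estimate decoded from one dance duration."""

    duration_s: float
    point_km: float
    interval_km: tuple[float, float] | None
    extrapolated: bool
    calibration: str
    level: float | None = None

    def __post_init__(self) -> None:
        if self.point_km < 0:
            raise ValueError("decoded distance must be >= 0")
        if self.interval_km is not None:
            lo, hi = self.interval_km
            if not (lo <= self.point_km <= hi):
                raise ValueError("interval must bracket the point estimate")


def build_study_calibration(
    vfk_fit: VonFrischKratkyCalibration,
    seg_fit: SegmentedCalibration,
    switch_km: float = 1.7,
    anchor: bool = True,
    name: str = "study",
) -> PiecewiseCalibration:
    """Saturating curve up to ``switch_km``, linear segment beyond.

    The extrapolating line reuses the slope of the break-point model's second
    segment.  With ``anchor=True`` (default) its intercept is shifted so the
    curve is continuous at the switch distance; the applied offset relative
    to the segment's own intercept is recorded on the result
    (``offset_s``).  With ``anchor=False`` the printed second segment is used
    unshifted, which may leave a small jump at the switch.
    """
    resp = getattr(vfk_fit, "response_", None) or getattr(
        seg_fit, "response_", None) or "tw"
    if (getattr(seg_fit, "response_", None) or resp) != resp:
        raise CalibrationError("fits must model the same response")
    slope2 = seg_fit.segment2_slope_
    if slope2 <= 0:
        raise CalibrationError(
            "second break-point segment is non-increasing; cannot extrapolate")
    own_intercept = seg_fit.segment2_intercept_
    if anchor:
        t_switch = float(vfk_fit.predict([switch_km])[0])
        intercept = t_switch - slope2 * switch_km
    else:
        intercept = own_intercept
    line = LinearCalibration.from_params(intercept, slope2)
    train_max = switch_km
    if hasattr(vfk_fit, "X_"):
        train_max = float(np.max(vfk_fit.X_))
    cal = PiecewiseCalibration(
        name=name,
        response=resp,
        pieces=(
            Piece(0.0, switch_km, vfk_fit),
            Piece(switch_km, np.inf, line),
        ),
        provenance=("saturating fit over the trained range, break-point "
                    "second segment beyond"),
        train_d_max=train_max,
        continuity_tol=1e-6 if anchor else np.inf,
    )
    cal.offset_s = intercept - own_intercept
    cal.refit_fn = lambda d, t: build_study_calibration(
        fit_vfk(d, t, c_bounds=vfk_fit.c_bounds, response=resp),
        fit_segmented(d, t, psi_bounds=seg_fit.psi_bounds, response=resp),
        switch_km=switch_km, anchor=anchor, name=name)
    return cal


def single_family_calibration(
    fit: _Calibration, name: str | None = None
) -> PiecewiseCalibration:
    """Wrap one fitted model as a bootstrappable calibration on [0, inf).

    Used when a single family (typically the line, over short training
    ranges) serves as the whole calibration; the refit recipe refits the
    same family with the same settings, enabling bootstrap intervals.
    """
    from .models import fit_linear

    resp = getattr(fit, "response_", None) or "tw"
    fitters = {
        "linear": lambda d, t: fit_linear(d, t, response=resp),
        "vfk": lambda d, t: fit_vfk(d, t, c_bounds=getattr(
            fit, "c_bounds", (1e-3, 10.0)), response=resp),
        "segmented": lambda d, t: fit_segmented(d, t, psi_bounds=getattr(
            fit, "psi_bounds", None), response=resp),
    }
    train_max = float(np.max(fit.X_)) if hasattr(fit, "X_") else None
    cal = PiecewiseCalibration(
        name=name or f"{fit.family}_calibration",
        response=resp,
        pieces=(Piece(0.0, np.inf, fit),),
        provenance=f"single {fit.family} fit over the trained range",
        train_d_max=train_max,
    )
    fitter = fitters[fit.family]
    cal.refit_fn = lambda d, t: single_family_calibration(fitter(d, t),
                                                          name=cal.name)
    return cal


def historical_calibrations() -> list[PiecewiseCalibration]:
    """Published long-range *A. m. carnica* calibrations.

    Returns, with parameters exactly as published:

    1. ``frisch_jander_waggle`` — waggle duration, a saturating curve up to
       1.4 km (a=0.1096 s, b=1.7208 s/km, c=0.6272 1/km) continued by the
       line ``0.7198069 + 0.70947*d`` beyond (a remodelling of 1950s feeder
       trainings to 4.5 km);
    2. ``von_frisch_circuit`` — circuit duration, the linear extrapolation
       ``tc = 3.072032 + 0.8046*d`` compiled from several long-range
       trainings, applicable to far foraging distances.
    """
    fj = PiecewiseCalibration(
        name="frisch_jander_waggle",
        response="tw",
        pieces=(
            Piece(0.0, 1.4,
                  VonFrischKratkyCalibration.from_params(0.1096, 1.7208, 0.6272)),
            Piece(1.4, np.inf, LinearCalibration.from_params(0.7198069, 0.70947)),
        ),
        provenance="remodelled 1950s carnica feeder trainings (to 4.5 km)",
        train_d_max=1.4,
        continuity_tol=1e-3,
    )
    vf = PiecewiseCalibration(
        name="von_frisch_circuit",
        response="tc",
        pieces=(
            Piece(0.0, np.inf, LinearCalibration.from_params(3.072032, 0.8046)),
        ),
        provenance="linear circuit-duration extrapolation from compiled "
                   "long-range trainings",
        train_d_max=None,
    )
    return [fj, vf]


_RESPONSE_ATTR = {"tw": "tw", "tr": "tr", "tc": "tc"}


def decode_distance(
    cal: PiecewiseCalibration,
    t: float,
    dances: Sequence[DanceSummary] | None = None,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DecodedDistance:
    """Decode one duration; optionally attach a bootstrap interval.

    When the training dances are supplied, uncertainty in the calibration is
    propagated by case resampling: dances are resampled with replacement,
    the calibration's model families are refit (via its ``refit_fn``), and
    the duration is re-inverted; the interval is the expanded percentile
    interval of the resampled distances at ``level`` (percentile end-points
    taken at t-adjusted tail levels, which corrects the well-known
    undercoverage of the plain percentile interval at calibration-sized
    samples).  Replicates whose refit or inversion fails are dropped; a
    failure rate above 10% attaches a warning.  The ``extrapolated`` flag
    marks points beyond the maximum training distance.
    """
    point = cal.invert(t)
    interval = None
    if dances is not None:
        if cal.refit_fn is None:
            raise CalibrationError(
                f"calibration {cal.name!r} has no refit recipe for the bootstrap")
        attr = _RESPONSE_ATTR[cal.response]
        d_all = np.array([s.d for s in dances])
        t_all = np.array([getattr(s, attr) for s in dances])
        rng = np.random.default_rng(seed)
        n = d_all.size
        draws = []
        failures = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    boot = cal.refit_fn(d_all[idx], t_all[idx])
                draws.append(boot.invert(t))
            except (CalibrationError, np.linalg.LinAlgError, ValueError):
                failures += 1
        if failures > 0.10 * n_boot:
            warnings.warn(
                f"bootstrap refit failure rate {failures / n_boot:.1%} "
                "exceeds 10%; interval may be unreliable", stacklevel=2)
        if draws:
            # expanded percentile: tail levels widened from z to
            # sqrt(n/(n-1)) * t_{n-1} quantiles (Hesterberg's correction)
            from scipy import stats as _stats

            tail = _stats.norm.cdf(
                -np.sqrt(n / (n - 1))
                * _stats.t.ppf((1 + level) / 2, n - 1))
            lo, hi = np.quantile(draws, [tail, 1 - tail])
            interval = (float(min(lo, point)), float(max(hi, point)))
    extrapolated = (cal.train_d_max is not None
                    and point > cal.train_d_max + _EPS)
    return DecodedDistance(
        duration_s=float(t),
        point_km=point,
        interval_km=interval,
        extrapolated=bool(extrapolated),
        calibration=cal.name,
        level=level if interval is not None else None,
    )
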