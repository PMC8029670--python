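"""Synthetic feeder-training datasets.

Emulates the sampling design of a long-range feeder-training experiment with
*Apis mellifera carnica*: nine feeder distances from 0.1 to 1.7 km in 0.2 km
steps, five to eight dances per distance, each dance by a freshly marked bee,
four waggle and four return phases timed per dance from 50 Hz video.  Waggle
durations follow a chosen true distance-duration curve with Gaussian
dance-to-dance noise whose SD grows from 0.10 s at the nearest feeder to
0.19 s at the farthest; return durations follow their own (by default linear)
curve with SD 0.31 s.  Small phase-to-phase jitter within a dance and
optional 0.02 s frame quantization mimic the measurement process.

The individual-heterogeneity scenario generates colony-level curvature from
*linear* individuals: each bee dances for one distance, and bees assigned to
farther feeders get shallower personal slopes
(``slope(d) = s0 * (1 - gamma * rank(d)/(K-1))``).  Fitting colony-level
models to such data shows how between-bee heterogeneity can masquerade as a
non-linear distance code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .data import DanceObservation
from .models import make_calibration

__all__ = ["SimulationConfig", "generate_dances", "heterogeneity_scenario",
           "DEFAULT_DISTANCES_KM"]

DEFAULT_DISTANCES_KM: tuple[float, ...] = tuple(
    round(0.1 + 0.2 * i, 1) for i in range(9))

# printed colony-level fits used as default truths
_DEFAULT_WAGGLE_TRUTH = ("vfk", {"a": 0.1993, "b": 2.0018, "c": 0.6717})
_DEFAULT_RETURN_TRUTH = ("linear", {"alpha": 1.3712, "beta": 0.5238})


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic feeder-training experiment.

    ``sigma_waggle`` is either a scalar SD (s) or an ``(sd_near, sd_far)``
    pair interpolated linearly between the nearest and farthest feeder.
    ``bee_slope_sd`` adds lognormal-like multiplicative slope variation per
    bee; ``heterogeneity_gamma`` activates the rank-dependent individual
    slope scenario (requires a linear waggle truth).  ``repeat_dance_prob``
    lets a bee dance again at the next feeder distance, producing the
    multi-dance records that the one-dance-per-bee selection resolves.
    """

    waggle_truth: tuple[str, dict] = _DEFAULT_WAGGLE_TRUTH
    return_truth: tuple[str, dict] = _DEFAULT_RETURN_TRUTH
    distances_km: tuple[float, ...] = DEFAULT_DISTANCES_KM
    dances_per_distance: tuple[int, int] = (5, 8)
    sigma_waggle: float | tuple[float, float] = (0.10, 0.19)
    sigma_return: float = 0.31
    within_dance_sd: float = 0.05
    phases_per_dance: int = 4
    bee_slope_sd: float = 0.0
    heterogeneity_gamma: float = 0.0
    repeat_dance_prob: float = 0.0
    quantize_50hz: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.distances_km):
            raise ValueError("feeder distances must be positive")
        if list(self.distances_km) != sorted(self.distances_km):
            raise ValueError("feeder distances must be sorted")
        sds = (self.sigma_waggle if isinstance(self.sigma_waggle, (tuple, list))
               else (self.sigma_waggle,))
        if any(s < 0 for s in (*sds, self.sigma_return, self.within_dance_sd)):
            raise ValueError("noise SDs must be >= 0")
        lo, hi = self.dances_per_distance
        if not (1 <= lo <= hi):
            raise ValueError("dances_per_distance must be a valid range")
        if not 0 <= self.repeat_dance_prob <= 1:
            raise ValueError("repeat_dance_prob must be a probability")
        if self.heterogeneity_gamma and self.waggle_truth[0] != "linear":
            raise ValueError(
                "the heterogeneity scenario needs a linear waggle truth")

    def sigma_waggle_at(self, d: float) -> float:
        if isinstance(self.sigma_waggle, (tuple, list)):
            lo_d, hi_d = self.distances_km[0], self.distances_km[-1]
            lo_s, hi_s = self.sigma_waggle
            if hi_d == lo_d:
                return float(lo_s)
            return float(lo_s + (hi_s - lo_s) * (d - lo_d) / (hi_d - lo_d))
        return float(self.sigma_waggle)

    def replace(self, **overrides) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides)

    def to_yaml(self) -> str:
        payload = dataclasses.asdict(self)
        payload["waggle_truth"] = list(payload["waggle_truth"])
        payload["return_truth"] = list(payload["return_truth"])
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        payload = yaml.safe_load(text)
        for key in ("waggle_truth", "return_truth"):
            if key in payload:
                fam, params = payload[key]
                payload[key] = (fam, dict(params))
        for key in ("distances_km", "dances_per_distance", "sigma_waggle"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        return cls(**payload)


def heterogeneity_scenario(
    gamma: float = 0.4,
    s0: float = 1.1152,
    a0: float = 0.4475,
    **overrides,
) -> SimulationConfig:
    """Config for the individual-slope-heterogeneity confound.

    Every bee follows its own straight line through intercept ``a0``; a bee
    assigned to the ``i``-th of ``K`` distances gets slope
    ``s0 * (1 - gamma * i/(K-1))``, so close-foraging bees have steeper
    personal curves.  With ``gamma=0`` this reduces to a homogeneous linear
    truth.  Defaults for ``a0``/``s0`` are the colony-level linear waggle
    fit.
    """
    cfg = SimulationConfig(
        waggle_truth=("linear", {"alpha": a0, "beta": s0}),
        heterogeneity_gamma=gamma,
        **overrides,
    )
    k = len(cfg.distances_km)
    if k > 1 and s0 * (1 - gamma) <= 0:
        raise ValueError("gamma drives the farthest bees' slopes to <= 0")
    return cfg


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int | None = None) -> np.ndarray | float:
    """Normal draw(s) redrawn until positive (SDs are small vs means)."""
    if sd == 0:
        return mean if size is None else np.full(size, mean)
    n = size or 1
    out = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    else:
        raise ValueError(
            f"cannot draw positive durations around mean {mean:.3g}")
    return float(out[0]) if size is None else out


def generate_dances(cfg: SimulationConfig) -> list[DanceObservation]:
    """Simulate one feeder-training experiment; reproducible from the seed."""
    rng = np.random.default_rng(cfg.seed)
    waggle_curve = make_calibration(*cfg.waggle_truth)
    return_curve = make_calibration(*cfg.return_truth)
    dists = np.asarray(cfg.distances_km)
    mu_w = waggle_curve.predict(dists)
    mu_r = return_curve.predict(dists)
    if np.any(mu_w <= 0) or np.any(mu_r <= 0):
        raise ValueError("true curves give non-positive mean durations")

    k = len(dists)
    obs: list[DanceObservation] = []
    bee_counter = 0
    lo, hi = cfg.dances_per_distance

    def one_dance(bee_id: str, i: int, d: float, order: int,
                  slope_scale: float, rank_i: int | None = None) -> DanceObservation:
        if cfg.heterogeneity_gamma:
            # a bee's personal slope is set by its *assigned* (first) distance
            a0 = cfg.waggle_truth[1]["alpha"]
            s0 = cfg.waggle_truth[1]["beta"]
            rank = (rank_i if rank_i is not None else i) / (k - 1) if k > 1 else 0.0
            slope = s0 * (1 - cfg.heterogeneity_gamma * rank) * slope_scale
            if slope <= 0:
                raise ValueError("heterogeneity drives a bee slope to <= 0")
            mean_w = a0 + slope * d
        else:
            mean_w = float(mu_w[i])
            if slope_scale != 1.0:
                mean_w = (mean_w - mu_w[0]) * slope_scale + mu_w[0]
        mean_w = _truncated_normal(rng, mean_w, cfg.sigma_waggle_at(d))
        mean_r = _truncated_normal(rng, float(mu_r[i]), cfg.sigma_return)
        w = _truncated_normal(rng, mean_w, cfg.within_dance_sd,
                              cfg.phases_per_dance)
        r = _truncated_normal(rng, mean_r, cfg.within_dance_sd,
                              cfg.phases_per_dance)
        if cfg.quantize_50hz:
            w = np.maximum(np.round(np.asarray(w) / 0.02) * 0.02, 0.02)
            r = np.maximum(np.round(np.asarray(r) / 0.02) * 0.02, 0.02)
        return DanceObservation(
            bee_id=bee_id,
            feeder_distance_km=float(d),
            waggle_durations_s=tuple(np.atleast_1d(w).tolist()),
            return_durations_s=tuple(np.atleast_1d(r).tolist()),
            observed_order=order,
        )

    for i, d in enumerate(dists):
        n_d = int(rng.integers(lo, hi + 1))
        for _ in range(n_d):
            bee_counter += 1
            bee_id = f"bee{bee_counter:03d}"
            scale = (float(rng.lognormal(0.0, cfg.bee_slope_sd))
                     if cfg.bee_slope_sd > 0 else 1.0)
            obs.append(one_dance(bee_id, i, float(d), order=1,
                                 slope_scale=scale))
            if (cfg.repeat_dance_prob > 0 and i + 1 < k
                    and rng.random() < cfg.repeat_dance_prob):
                obs.append(one_dance(bee_id, i + 1, float(dists[i + 1]),
                                     order=2, slope_scale=scale, rank_i=i))
    return obs
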