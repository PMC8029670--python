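"""Reading, validating and aggregating waggle-dance timing records.

The unit of analysis is one dance: a marked forager returning from a feeder at
a known distance performs a sequence of dance circuits, and the duration of
(nominally four) consecutive waggle phases and the four subsequent return
phases is timed from 50 Hz video.  Per dance we keep the mean waggle-phase
duration ``tw``, the mean return-phase duration ``tr`` and their sum, the
circuit duration ``tc = tw + tr``.

Two CSV layouts are supported and auto-detected from the header:

* *long* — one row per dance with the individual phase timings
  (``bee_id, distance_km, waggle_1..waggle_k, return_1..return_k``);
* *summarized* — one row per dance with the per-dance means
  (``bee_id, distance_km, waggle_s, return_s, circuit_s``), the shape in
  which per-dance means are usually deposited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DanceObservation",
    "DanceSummary",
    "DanceValidationError",
    "SchemaError",
    "read_dances",
    "write_dances",
    "summarize_dance",
    "summarize_dances",
    "summaries_to_frame",
    "write_summaries",
    "select_one_dance_per_bee",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class DanceValidationError(ValueError):
    """A row violates the timing-record invariants (reports row and bee)."""


@dataclass(frozen=True)
class DanceObservation:
    """Raw timings of one recorded dance.

    Parameters
    ----------
    bee_id : str
        Opaque label of the individually marked bee.
    feeder_distance_km : float
        Distance of the feeder from the hive entrance, km (>= 0).
    waggle_durations_s, return_durations_s : tuple of float
        Ordered phase timings in seconds, nominally four of each, all > 0.
    observed_order : int, optional
        Recording order of this dance within its bee, when known.
    """

    bee_id: str
    feeder_distance_km: float
    waggle_durations_s: tuple[float, ...]
    return_durations_s: tuple[float, ...]
    observed_order: int | None = None

    def __post_init__(self) -> None:
        if self.feeder_distance_km < 0:
            raise DanceValidationError(
                f"bee {self.bee_id!r}: feeder_distance_km must be >= 0, "
                f"got {self.feeder_distance_km}"
            )
        for name, vals in (
            ("waggle", self.waggle_durations_s),
            ("return", self.return_durations_s),
        ):
            if len(vals) < 1:
                raise DanceValidationError(
                    f"bee {self.bee_id!r}: empty {name}-phase timing list"
                )
            if any(not np.isfinite(v) or v <= 0 for v in vals):
                raise DanceValidationError(
                    f"bee {self.bee_id!r}: non-positive or non-finite "
                    f"{name}-phase duration in {vals}"
                )
        if len(self.waggle_durations_s) != 4 or len(self.return_durations_s) != 4:
            warnings.warn(
                f"bee {self.bee_id!r}: expected 4 timed phases per dance, got "
                f"{len(self.waggle_durations_s)} waggle / "
                f"{len(self.return_durations_s)} return",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DanceSummary:
    """Per-dance means: the record the calibration models are fit to."""

    bee_id: str
    d: float  # feeder distance, km
    tw: float  # mean waggle-phase duration, s
    tr: float  # mean return-phase duration, s
    tc: float = field(default=float("nan"))  # circuit duration, tw + tr

    def __post_init__(self) -> None:
        if np.isnan(self.tc):
            object.__setattr__(self, "tc", self.tw + self.tr)
        if self.tw <= 0 or self.tr <= 0:
            raise DanceValidationError(
                f"bee {self.bee_id!r}: mean phase durations must be > 0"
            )
        if self.tc != self.tw + self.tr:
            raise DanceValidationError(
                f"bee {self.bee_id!r}: tc must equal tw + tr exactly"
            )


# -- ingest -----------------------------------------------------------------

_SUMMARY_COLS = ("bee_id", "distance_km", "waggle_s", "return_s")


def _phase_columns(columns: Iterable[str], prefix: str) -> list[str]:
    cols = [c for c in columns if c.startswith(f"{prefix}_") and
            c.split("_", 1)[1].isdigit()]
    return sorted(cols, key=lambda c: int(c.split("_", 1)[1]))


def read_dances(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[DanceObservation]:
    """Read dance timing records from CSV into :class:`DanceObservation`.

    The layout (long vs summarized) is detected from the header.  ``schema``
    optionally maps the canonical column names (``bee_id``, ``distance_km``,
    ...) to the names used in the file.  Rows violating the invariants raise
    :class:`DanceValidationError` naming the offending row and bee.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})

    for col in ("bee_id", "distance_km"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: required column {col!r} missing")

    wcols = _phase_columns(df.columns, "waggle")
    rcols = _phase_columns(df.columns, "return")
    summarized = not wcols
    if summarized:
        missing = [c for c in _SUMMARY_COLS if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path.name}: neither long-format phase columns "
                f"(waggle_1, ...) nor summarized columns ({', '.join(missing)} "
                "missing) found"
            )

    out: list[DanceObservation] = []
    for idx, row in df.iterrows():
        try:
            if summarized:
                waggle = (float(row["waggle_s"]),)
                ret = (float(row["return_s"]),)
            else:
                waggle = tuple(float(row[c]) for c in wcols if pd.notna(row[c]))
                ret = tuple(float(row[c]) for c in rcols if pd.notna(row[c]))
            order = (
                int(row["observed_order"])
                if "observed_order" in df.columns and pd.notna(row.get("observed_order"))
                else None
            )
            out.append(
                DanceObservation(
                    bee_id=str(row["bee_id"]),
                    feeder_distance_km=float(row["distance_km"]),
                    waggle_durations_s=waggle,
                    return_durations_s=ret,
                    observed_order=order,
                )
            )
        except DanceValidationError as err:
            raise DanceValidationError(f"row {idx}: {err}") from err
    return out


def write_dances(obs: Sequence[DanceObservation], path: str | Path) -> None:
    """Write observations as long-format CSV (inverse of :func:`read_dances`)."""
    k_w = max(len(o.waggle_durations_s) for o in obs)
    k_r = max(len(o.return_durations_s) for o in obs)
    rows = []
    for o in obs:
        row: dict[str, object] = {
            "bee_id": o.bee_id,
            "distance_km": o.feeder_distance_km,
        }
        for i in range(k_w):
            row[f"waggle_{i + 1}"] = (
                o.waggle_durations_s[i] if i < len(o.waggle_durations_s) else np.nan
            )
        for i in range(k_r):
            row[f"return_{i + 1}"] = (
                o.return_durations_s[i] if i < len(o.return_durations_s) else np.nan
            )
        if o.observed_order is not None:
            row["observed_order"] = o.observed_order
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# -- aggregation ------------------------------------------------------------


def summarize_dance(obs: DanceObservation) -> DanceSummary:
    """Average the phase timings of one dance.

    ``tw`` and ``tr`` are the arithmetic means of the waggle- and return-phase
    timings; the circuit duration is their sum, ``tc = tw + tr``, exactly.
    """
    tw = float(np.mean(obs.waggle_durations_s))
    tr = float(np.mean(obs.return_durations_s))
    return DanceSummary(bee_id=obs.bee_id, d=obs.feeder_distance_km, tw=tw, tr=tr)


def summarize_dances(obs: Iterable[DanceObservation]) -> list[DanceSummary]:
    return [summarize_dance(o) for o in obs]


def summaries_to_frame(summaries: Iterable[DanceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"bee_id": s.bee_id, "distance_km": s.d, "waggle_s": s.tw,
             "return_s": s.tr, "circuit_s": s.tc}
            for s in summaries
        ]
    )


def write_summaries(summaries: Iterable[DanceSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


# -- balanced subsampling ---------------------------------------------------


def select_one_dance_per_bee(
    obs: Sequence[DanceObservation], seed: int = 0
) -> list[DanceObservation]:
    """Keep exactly one dance per bee while balancing dances per distance.

    Individual bees differ in their distance tuning, so letting a prolific
    dancer contribute several dances would bias the colony-level calibration;
    the protocol therefore represents every bee once and equalises sample
    sizes across feeder distances.  The selection proceeds in two steps:

    1. a greedy pass assigns bees in increasing order of how many candidate
       dances they have (fewest options first), each contributing the dance
       at the currently least-represented distance among its candidates
       (remaining ties broken by a seeded RNG);
    2. a balancing pass repeatedly shifts assignments along exchange paths
       from over- to under-represented distances until no two reachable
       distances differ by more than one dance — which makes the final
       per-distance count variance minimal over all one-dance-per-bee
       subsets.

    The result is deterministic for a fixed seed and returned in input
    order.
    """
    rng = np.random.default_rng(seed)
    by_bee: dict[str, list[DanceObservation]] = {}
    for o in obs:
        by_bee.setdefault(o.bee_id, []).append(o)

    counts: dict[float, int] = {o.feeder_distance_km: 0 for o in obs}
    # fewest-options-first; RNG only breaks residual ties
    bee_order = sorted(by_bee, key=lambda b: (len(by_bee[b]), rng.random()))
    assigned: dict[str, DanceObservation] = {}
    for bee in bee_order:
        candidates = by_bee[bee]
        least = min(counts[c.feeder_distance_km] for c in candidates)
        pool = [c for c in candidates if counts[c.feeder_distance_km] == least]
        pick = pool[int(rng.integers(len(pool)))] if len(pool) > 1 else pool[0]
        counts[pick.feeder_distance_km] += 1
        assigned[bee] = pick

    def _rebalance_once() -> bool:
        # BFS in the exchange graph: distance u -> v if some bee assigned to
        # u also danced at v.  Shifting along a path from an overloaded to
        # an underloaded distance lowers the count variance by >= 2.
        for src in sorted(counts, key=lambda d: -counts[d]):
            parent: dict[float, tuple[str, DanceObservation]] = {}
            seen = {src}
            frontier = [src]
            while frontier:
                nxt = []
                for u in frontier:
                    for bee, cur in assigned.items():
                        if cur.feeder_distance_km != u:
                            continue
                        for cand in by_bee[bee]:
                            v = cand.feeder_distance_km
                            if v in seen:
                                continue
                            seen.add(v)
                            parent[v] = (bee, cand)
                            if counts[v] <= counts[src] - 2:
                                # shift assignments back along the path
                                node = v
                                while node != src:
                                    bee_, cand_ = parent[node]
                                    prev = assigned[bee_].feeder_distance_km
                                    assigned[bee_] = cand_
                                    node = prev
                                counts[v] += 1
                                counts[src] -= 1
                                return True
                            nxt.append(v)
                frontier = nxt
        return False

    while _rebalance_once():
        pass

    chosen = set(map(id, assigned.values()))
    return [o for o in obs if id(o) in chosen]
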