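"""Small-sample information-criterion comparison of calibration fits.

Competing fits of the same duration component are ranked by AICc,
``-2*loglik + 2k + 2k(k+1)/(n - k - 1)``, the Akaike criterion with the
finite-sample correction appropriate for feeder-training datasets of a few
dozen dances.  Parameter counts include the residual variance (k = 3 linear,
4 von Frisch-Kratky, 5 segmented — the break-point is counted).  Each row
also carries the fitted-vs-observed Pearson r and the bias flag from the
residual diagnostic, mirroring the three evaluation criteria of a
feeder-training model comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .models import _Calibration, bias_check, pearson_fit_r

__all__ = ["aicc", "ComparisonRow", "ComparisonTable", "compare_models"]


def aicc(loglik: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ComparisonRow:
    family: str
    biased: bool
    formula: str
    r: float
    aicc: float
    delta_aicc: float


@dataclass(frozen=True)
class ComparisonTable:
    """Ranked model comparison for one duration component."""

    response: str
    rows: tuple[ComparisonRow, ...]

    def best(self) -> ComparisonRow:
        return self.rows[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"family": r.family, "biased": r.biased, "formula": r.formula,
                 "r": r.r, "AICc": r.aicc, "dAICc": r.delta_aicc}
                for r in self.rows
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.4f")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"response": self.response,
             "rows": [r.__dict__ for r in self.rows]},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def compare_models(fits: Sequence[_Calibration],
                   response: str | None = None) -> ComparisonTable:
    """Rank fits of one response by AICc (ties: fewer parameters, then name).

    All fits must share the response label and sample size.  The returned
    rows are sorted by AICc ascending; the best row has delta_aicc = 0.
    """
    if not fits:
        raise ValueError("no fits to compare")
    responses = {getattr(f, "response_", None) for f in fits}
    if response is None:
        if len(responses) > 1:
            raise ValueError(f"fits mix responses: {responses}")
        response = responses.pop() or "t"
    elif responses - {None, response}:
        raise ValueError(f"fits mix responses: {responses}")
    ns = {f.n_ for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits differ in sample size: {ns}")

    scored = []
    for f in fits:
        scored.append(
            (
                aicc(f.loglik_, f.k_, f.n_),
                f.k_,
                f.family,
                pearson_fit_r(f.fitted_, f.y_),
                bias_check(f)["biased"],
                f,
            )
        )
    scored.sort(key=lambda s: (s[0], s[1], s[2]))
    best_aicc = scored[0][0]
    rows = tuple(
        ComparisonRow(
            family=fam,
            biased=biased,
            formula=f.formula(response),
            r=r,
            aicc=a,
            delta_aicc=a - best_aicc,
        )
        for a, _k, fam, r, biased, f in scored
    )
    return ComparisonTable(response=response, rows=rows)
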