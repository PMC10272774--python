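"""Cross-session stability and prediction-accuracy metrics.

Stability: synergy matrices extracted on different days are compared by
Pearson CC after greedy column matching on unit-normalized columns
(factorization scale and order are not identifiable), averaged over all
unordered day pairs.  Accuracy: per-day Pearson CC and MAE between the
predicted and reference angle, aggregated as mean +/- sd.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._matching import match_columns, pearson_cc  # noqa: F401 (re-export)
from .decompose import SynergyDecomposition
from .errors import ArgumentError
from .kinematics import AngleTrace, angle_error

__all__ = [
    "pearson_cc",
    "StabilityReport",
    "AccuracyReport",
    "synergy_stability",
    "accuracy_report",
]


@dataclass
class StabilityReport:
    method: str
    pair_ccs: np.ndarray      # mean matched CC per unordered session pair
    mean: float
    sd: float

    def to_dict(self):
        return {
            "method": self.method,
            "pair_ccs": np.asarray(self.pair_ccs).tolist(),
            "mean": self.mean,
            "sd": self.sd,
        }


@dataclass
class AccuracyReport:
    days: list[int]
    cc: dict[int, float] = field(default_factory=dict)
    mae: dict[int, float] = field(default_factory=dict)
    cc_mean: float = float("nan")
    cc_sd: float = float("nan")
    mae_mean: float = float("nan")
    mae_sd: float = float("nan")

    def to_dict(self):
        return {
            "days": self.days,
            "cc": {str(d): v for d, v in self.cc.items()},
            "mae": {str(d): v for d, v in self.mae.items()},
            "cc_mean": self.cc_mean,
            "cc_sd": self.cc_sd,
            "mae_mean": self.mae_mean,
            "mae_sd": self.mae_sd,
        }

    def format_table(self) -> str:
        lines = [f"{'day':>4}  {'CC':>8}  {'MAE (deg)':>10}"]
        for d in self.days:
            lines.append(f"{d:>4}  {self.cc[d]:>8.4f}  {self.mae[d]:>10.4f}")
        lines.append(
            f"mean  {self.cc_mean:>8.4f}  {self.mae_mean:>10.4f}  "
            f"(sd {self.cc_sd:.4f} / {self.mae_sd:.4f})"
        )
        return "\n".join(lines)


def synergy_stability(
    decomps: list[SynergyDecomposition],
) -> StabilityReport:
    """Mean +/- sd of matched-synergy CC over all session pairs.

    For every unordered pair of decompositions, synergy columns are
    matched greedily by CC (unit-normalized), the matched CCs averaged,
    and the pair averages aggregated.  Invariant to column permutation
    and positive column scaling of any input.
    """
    if len(decomps) < 2:
        raise ArgumentError("need at least two decompositions")
    shape = decomps[0].C.shape
    method = decomps[0].method
    for d in decomps[1:]:
        if d.C.shape != shape:
            raise ArgumentError("decompositions differ in m or r")
    pair_ccs = []
    for a, b in itertools.combinations(decomps, 2):
        _, ccs = match_columns(a.C, b.C)
        pair_ccs.append(float(np.mean(ccs)))
    pair_ccs = np.asarray(pair_ccs)
    return StabilityReport(
        method=method,
        pair_ccs=pair_ccs,
        mean=float(pair_ccs.mean()),
        sd=float(pair_ccs.std()),
    )


def accuracy_report(
    predictions: dict[int, AngleTrace],
    actuals: dict[int, AngleTrace],
) -> AccuracyReport:
    """Per-day CC / MAE between predicted and measured angle.

    ``predictions`` and ``actuals`` map day index to aligned angle
    traces; the report aggregates mean +/- sd over days.
    """
    days = sorted(predictions)
    if sorted(actuals) != days:
        raise ArgumentError("prediction and actual day sets differ")
    rep = AccuracyReport(days=days)
    for d in days:
        p, a = predictions[d], actuals[d]
        rep.cc[d] = pearson_cc(p.theta, a.theta)
        rep.mae[d] = angle_error(p, a)
    ccs = np.array([rep.cc[d] for d in days])
    maes = np.array([rep.mae[d] for d in days])
    rep.cc_mean = float(ccs.mean())
    rep.cc_sd = float(ccs.std())
    rep.mae_mean = float(maes.mean())
    rep.mae_sd = float(maes.std())
    return rep
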