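"""Engine-evaluation to win-probability mapping and the Elo score curve.

Raw engine evaluations come in two incommensurate units: centipawns (signed
hundredths of a pawn of material advantage) and signed distance-to-mate in
plies.  Both are placed on a common [0, 1] utility scale -- the active
player's time-agnostic win probability -- by fitting one logistic regression
per unit channel against game outcomes.  The two channels are fitted
independently; the discontinuity where they meet is reported as a
diagnostic rather than constrained away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .dataio import log_stage

__all__ = [
    "EngineEval",
    "UtilityMap",
    "SeparationError",
    "fit_utility_map",
    "to_win_prob",
    "elo_expected_score",
    "seam_diagnostic",
]


class SeparationError(ValueError):
    """Raised when outcomes are perfectly separated along the evaluation axis.

    Maximum-likelihood logistic coefficients diverge in this regime; refit
    with ``ridge > 0`` to obtain a penalised, finite fit.
    """


@dataclass(frozen=True, slots=True)
class EngineEval:
    """A raw engine evaluation from the active player's perspective."""

    kind: str  # "centipawn" or "mate"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("centipawn", "mate"):
            raise ValueError(f"kind must be 'centipawn' or 'mate', got {self.kind!r}")
        if self.kind == "mate" and (self.value == 0 or self.value != int(self.value)):
            raise ValueError("mate distance must be a nonzero integer")


@dataclass
class UtilityMap:
    """Fitted logistic coefficients per evaluation channel."""

    cp_intercept: float | None = None
    cp_slope: float | None = None
    mate_intercept: float | None = None
    mate_slope: float | None = None
    n_cp: int = 0
    n_mate: int = 0
    ridge: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "UtilityMap":
        return cls(**json.loads(Path(path).read_text()))


def _outcome_to_y(outcome) -> float | None:
    if outcome in (1, 0):
        return float(outcome)
    if outcome == "win":
        return 1.0
    if outcome == "loss":
        return 0.0
    return None  # draws are excluded from fitting


def _separated(x: np.ndarray, y: np.ndarray) -> bool:
    # Univariate logistic: (quasi-)separation iff the outcome classes'
    # value ranges do not overlap.
    if np.all(y == y[0]):
        return True
    x1, x0 = x[y == 1], x[y == 0]
    return bool(x1.min() >= x0.max() or x0.min() >= x1.max())


def _fit_channel(
    x: np.ndarray, y: np.ndarray, ridge: float
) -> tuple[float, float]:
    exog = sm.add_constant(x)
    if _separated(x, y):
        if ridge <= 0:
            raise SeparationError(
                "outcomes are perfectly separated along the evaluation axis; "
                "pass ridge > 0 to fit a penalised model"
            )
        model = sm.GLM(y, exog, family=sm.families.Binomial())
        res = model.fit_regularized(alpha=ridge, L1_wt=0.0)
        return float(res.params[0]), float(res.params[1])
    res = sm.Logit(y, exog).fit(disp=0)
    return float(res.params[0]), float(res.params[1])


def fit_utility_map(
    pairs: Sequence[tuple[EngineEval, object]],
    min_pairs: int = 100,
    ridge: float = 0.0,
) -> UtilityMap:
    """Fit the centipawn and mate logistic channels from (eval, outcome) pairs.

    Outcomes are coded win=1 / loss=0; draws are dropped (the calibration
    sample is restricted to decisively ended games).  A channel with fewer
    than ``min_pairs`` usable pairs is left unfitted and errors on later use.
    Perfect separation raises :class:`SeparationError` unless an L2 ``ridge``
    penalty is supplied, in which case the penalised fit is flagged on the
    returned map.
    """
    xs: dict[str, list[float]] = {"centipawn": [], "mate": []}
    ys: dict[str, list[float]] = {"centipawn": [], "mate": []}
    for ev, outcome in pairs:
        y = _outcome_to_y(outcome)
        if y is None:
            continue
        xs[ev.kind].append(float(ev.value))
        ys[ev.kind].append(y)

    out = UtilityMap(ridge=ridge)
    for kind in ("centipawn", "mate"):
        x = np.asarray(xs[kind])
        y = np.asarray(ys[kind])
        if x.size < min_pairs:
            continue
        intercept, slope = _fit_channel(x, y, ridge)
        if kind == "centipawn":
            out.cp_intercept, out.cp_slope, out.n_cp = intercept, slope, x.size
        else:
            out.mate_intercept, out.mate_slope, out.n_mate = intercept, slope, x.size
    log_stage("fit_utility_map", out.n_cp + out.n_mate)
    return out


def to_win_prob(umap: UtilityMap, ev: EngineEval) -> float:
    """Map a raw evaluation to the active player's win probability in (0, 1)."""
    if ev.kind == "centipawn":
        if umap.cp_slope is None:
            raise ValueError("centipawn channel has not been fitted")
        return float(expit(umap.cp_intercept + umap.cp_slope * ev.value))
    if umap.mate_slope is None:
        raise ValueError("mate channel has not been fitted")
    return float(expit(umap.mate_intercept + umap.mate_slope * ev.value))


def elo_expected_score(delta_elo: float) -> float:
    """Expected game score for a player rated ``delta_elo`` above the opponent.

    The standard rating curve 1 / (1 + 10^(-d/400)); at d = +100 it gives
    0.64 to two decimals.
    """
    return float(1.0 / (1.0 + 10.0 ** (-delta_elo / 400.0)))


def seam_diagnostic(
    umap: UtilityMap, cp_extreme: float = 1000.0
) -> dict[str, float]:
    """Utility gap where the centipawn and mate channels meet.

    Reports the fitted utility at +/-``cp_extreme`` centipawns against
    mate-in-+/-1; a well-ordered map has mate-in-1 above the centipawn
    extreme on each side.  The channels are fitted independently, so the
    seam is not guaranteed to be monotone -- this is the diagnostic.
    """
    out = {
        "cp_high": to_win_prob(umap, EngineEval("centipawn", cp_extreme)),
        "cp_low": to_win_prob(umap, EngineEval("centipawn", -cp_extreme)),
        "mate_plus_1": to_win_prob(umap, EngineEval("mate", 1)),
        "mate_minus_1": to_win_prob(umap, EngineEval("mate", -1)),
    }
    out["gap_high"] = out["mate_plus_1"] - out["cp_high"]
    out["gap_low"] = out["cp_low"] - out["mate_minus_1"]
    return out
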