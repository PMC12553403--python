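"""Empirical value function, time-cost curve and optimal-stopping policies.

The value function ``V_tc(T, U)`` is the raw binned probability that the
active player eventually wins, given ``T`` seconds on their clock and
pre-deliberation advantage ``U``, estimated separately per time control.
Its decrease as the clock is spent defines the empirical cost of time,

    c(dT) ~= V(T, U) - V(T - dT, U),

and the longest deliberation still worth its cost for an offered benefit
``dUC`` is

    dTmax = max { dT : V(T - dT, U + dUC) >= V(T, U) }.

Three analytic cost families provide closed-form reference policies:
linear ``c = rho*dT`` (dTmax = dUC/rho), power ``c = a*dT^b`` with b > 1
(dTmax = (dUC/a)^(1/b), concave in the benefit), and time-left-scaled power
``c = a*(dT/T)^b`` (dTmax = T*(dUC/a)^(1/b), additionally proportional to
the time remaining).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import PositionRecord, RunConfig, TimeControl, log_stage

__all__ = [
    "ValueGrid",
    "CostFamily",
    "OfferSample",
    "InestimableCellError",
    "build_value_grid",
    "time_cost",
    "delta_t_max_empirical",
    "delta_t_max_analytic",
    "implied_mean_move_times",
]


class InestimableCellError(ValueError):
    """A value-grid cell has too few observations to estimate V."""

    def __init__(self, t_index: int, u_index: int):
        self.t_index = t_index
        self.u_index = u_index
        super().__init__(
            f"value-grid cell (t_bin={t_index}, u_bin={u_index}) is below the "
            "minimum observation count"
        )


@dataclass(frozen=True, slots=True)
class CostFamily:
    """Analytic time-cost family and its parameters.

    ``rho`` is the opportunity cost per second (linear family); ``a`` and
    ``b`` the scale and exponent of the power families (b > 1 makes the
    optimal stopping time concave in the benefit).
    """

    family: str
    rho: float | None = None
    a: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.family == "linear":
            if self.rho is None or self.rho <= 0:
                raise ValueError("linear family requires rho > 0")
        elif self.family in ("power", "power_timeleft"):
            if self.a is None or self.a <= 0:
                raise ValueError(f"{self.family} family requires a > 0")
            if self.b is None or self.b <= 1:
                raise ValueError(f"{self.family} family requires b > 1")
        else:
            raise ValueError(f"unknown cost family {self.family!r}")


@dataclass(frozen=True, slots=True)
class OfferSample:
    """One computation offer: state (T, U) plus offered (dTC, dUC)."""

    T: float
    U: float
    delta_tc: float
    delta_uc: float

    def __post_init__(self) -> None:
        if min(self.T, self.U, self.delta_tc, self.delta_uc) < 0:
            raise ValueError("offer components must be nonnegative")
        if self.U > 1:
            raise ValueError("U must lie in [0, 1]")


@dataclass
class ValueGrid:
    """Binned win counts over (time left, advantage) for one time control.

    ``wins`` counts draws as half a win.  Cells with fewer than ``min_count``
    moves are flagged inestimable; lookups fall back to the nearest estimable
    cell along the time axis within the same advantage column (preserving the
    U-conditioning), unless strict mode is requested.
    """

    time_control: TimeControl
    time_edges: np.ndarray
    utility_edges: np.ndarray
    wins: np.ndarray
    totals: np.ndarray
    min_count: int = 50
    _filled: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.wins.shape != self.totals.shape:
            raise ValueError("wins and totals must have matching shapes")
        if np.any(self.wins > self.totals + 1e-9):
            raise ValueError("wins cannot exceed totals")

    # -- indexing ---------------------------------------------------------
    @property
    def time_bin(self) -> float:
        return float(self.time_edges[1] - self.time_edges[0])

    @property
    def estimable(self) -> np.ndarray:
        return self.totals >= self.min_count

    def t_index(self, T: float) -> int:
        i = int(np.searchsorted(self.time_edges, T, side="right")) - 1
        return int(np.clip(i, 0, len(self.time_edges) - 2))

    def u_index(self, U: float) -> int:
        i = int(np.searchsorted(self.utility_edges, U, side="right")) - 1
        # advantage above the top edge clamps into the top bin (saturation)
        return int(np.clip(i, 0, len(self.utility_edges) - 2))

    def raw(self) -> np.ndarray:
        """V = wins/totals with inestimable cells as NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.wins / self.totals
        v[~self.estimable] = np.nan
        return v

    def filled(self) -> np.ndarray:
        """V with inestimable cells filled from the nearest estimable cell
        along the time axis in the same advantage column (ties toward less
        time left).  Columns with no estimable cell stay NaN."""
        if self._filled is None:
            v = self.raw()
            nt = v.shape[0]
            for j in range(v.shape[1]):
                col = v[:, j]
                good = np.flatnonzero(~np.isnan(col))
                if good.size == 0 or good.size == nt:
                    continue
                idx = np.arange(nt)
                pos = np.searchsorted(good, idx)
                left = good[np.clip(pos - 1, 0, good.size - 1)]
                right = good[np.clip(pos, 0, good.size - 1)]
                nearest = np.where(idx - left <= right - idx, left, right)
                v[:, j] = col[nearest]
            self._filled = v
        return self._filled

    def value(self, T: float, U: float, mode: str = "fallback") -> float:
        """V at (T, U); ``mode='strict'`` errors on inestimable cells."""
        it, iu = self.t_index(T), self.u_index(U)
        if mode == "strict":
            if not self.estimable[it, iu]:
                raise InestimableCellError(it, iu)
            return float(self.wins[it, iu] / self.totals[it, iu])
        v = self.filled()[it, iu]
        if np.isnan(v):
            raise InestimableCellError(it, iu)
        return float(v)

    # -- construction and serialisation -----------------------------------
    @classmethod
    def from_function(
        cls,
        law,
        time_edges: np.ndarray,
        utility_edges: np.ndarray,
        time_control: TimeControl = TimeControl(300, 0),
        count: int = 50,
    ) -> "ValueGrid":
        """Grid whose cell values equal ``law(T, U)`` at bin centres.

        Used to inject a known analytic value law for exact policy checks.
        """
        tc_ = 0.5 * (np.asarray(time_edges)[:-1] + np.asarray(time_edges)[1:])
        uc_ = 0.5 * (np.asarray(utility_edges)[:-1] + np.asarray(utility_edges)[1:])
        tt, uu = np.meshgrid(tc_, uc_, indexing="ij")
        v = np.clip(law(tt, uu), 0.0, 1.0)
        totals = np.full(v.shape, count, dtype=float)
        return cls(
            time_control=time_control,
            time_edges=np.asarray(time_edges, dtype=float),
            utility_edges=np.asarray(utility_edges, dtype=float),
            wins=v * totals,
            totals=totals,
            min_count=count,
        )

    def to_frame(self) -> pd.DataFrame:
        it, iu = np.meshgrid(
            np.arange(self.wins.shape[0]), np.arange(self.wins.shape[1]), indexing="ij"
        )
        return pd.DataFrame(
            {
                "t_lo": self.time_edges[:-1][it.ravel()],
                "t_hi": self.time_edges[1:][it.ravel()],
                "u_lo": self.utility_edges[:-1][iu.ravel()],
                "u_hi": self.utility_edges[1:][iu.ravel()],
                "wins": self.wins.ravel(),
                "totals": self.totals.ravel(),
            }
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(
                f"# tc={self.time_control.label} min_count={self.min_count}\n"
            )
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ValueGrid":
        path = Path(path)
        with path.open() as fh:
            meta = fh.readline().strip().lstrip("# ").split()
            kv = dict(item.split("=") for item in meta)
            frame = pd.read_csv(fh)
        t_edges = np.unique(np.concatenate([frame["t_lo"], frame["t_hi"]]))
        u_edges = np.unique(np.concatenate([frame["u_lo"], frame["u_hi"]]))
        nt, nu = len(t_edges) - 1, len(u_edges) - 1
        wins = frame["wins"].to_numpy().reshape(nt, nu)
        totals = frame["totals"].to_numpy().reshape(nt, nu)
        return cls(
            time_control=TimeControl.from_label(kv["tc"]),
            time_edges=t_edges,
            utility_edges=u_edges,
            wins=wins,
            totals=totals,
            min_count=int(kv["min_count"]),
        )


_WIN_WEIGHT = {"win": 1.0, "draw": 0.5, "loss": 0.0}


def build_value_grid(
    records: Sequence[PositionRecord],
    time_control: TimeControl,
    config: RunConfig | None = None,
) -> ValueGrid:
    """Estimate V_tc(T, U) from move records of one time control.

    Applies the ply window and the opponent-clock floor, then bins each move
    by (clock before moving, pre-deliberation advantage) with half-open bins
    anchored at zero.  The advantage U is the shallow utility of the shallow
    argmax move -- the value of the position if the player were to move
    without deliberating.  Draws count half a win.
    """
    config = config or RunConfig()
    min_opp = config.min_opponent_clock(time_control)
    ts, us, ws = [], [], []
    for rec in records:
        if rec.time_control != time_control:
            continue
        if not (config.ply_min <= rec.ply <= config.ply_max):
            continue
        if rec.opponent_clock < min_opp:
            continue
        ts.append(rec.clock_before)
        us.append(float(rec.consideration_set.shallow.max()))
        ws.append(_WIN_WEIGHT[rec.outcome])
    if not ts:
        raise ValueError(
            "no records survive the filters (time control match, "
            f"ply in [{config.ply_min}, {config.ply_max}], "
            f"opponent clock >= {min_opp} s)"
        )
    t = np.asarray(ts)
    u = np.asarray(us)
    w = np.asarray(ws)

    dt = config.time_bin_seconds
    du = config.utility_bin_width
    n_t = int(np.floor(t.max() / dt)) + 1
    n_u = int(np.ceil((1.0 + 1e-9) / du))
    time_edges = dt * np.arange(n_t + 1)
    utility_edges = du * np.arange(n_u + 1)

    it = np.clip((t / dt).astype(int), 0, n_t - 1)
    iu = np.clip((u / du).astype(int), 0, n_u - 1)
    wins = np.zeros((n_t, n_u))
    totals = np.zeros((n_t, n_u))
    np.add.at(wins, (it, iu), w)
    np.add.at(totals, (it, iu), 1.0)
    log_stage("build_value_grid", int(totals.sum()), len(records) - int(totals.sum()))
    return ValueGrid(
        time_control=time_control,
        time_edges=time_edges,
        utility_edges=utility_edges,
        wins=wins,
        totals=totals,
        min_count=config.grid_min_count,
    )


def time_cost(
    grid: ValueGrid, T: float, U: float, delta_t: float, mode: str = "strict"
) -> float:
    """Empirical cost of spending ``delta_t`` seconds: V(T,U) - V(T-dT,U)."""
    return grid.value(T, U, mode=mode) - grid.value(T - delta_t, U, mode=mode)


def delta_t_max_empirical(
    grid: ValueGrid,
    T: float,
    U: float,
    delta_uc: float,
    contiguous: bool = False,
) -> float:
    """Longest worthwhile deliberation under the empirical value function.

    Scans dT over time-bin multiples from 0 up to T and returns the largest
    dT with ``V(T - dT, U + dUC) >= V(T, U)``; 0 when no positive dT
    qualifies.  U + dUC clamps into the top advantage bin.  With
    ``contiguous=True`` the scan stops at the first failing dT (strictly
    contiguous acceptance region), which is more conservative under
    sampling noise.
    """
    v = grid.filled()
    it0, iu0 = grid.t_index(T), grid.u_index(U)
    v0 = v[it0, iu0]
    if np.isnan(v0):
        raise InestimableCellError(it0, iu0)
    iu1 = grid.u_index(U + delta_uc)
    col = v[: it0 + 1, iu1]
    ok = col[::-1] >= v0  # ok[k] corresponds to dT = k * time_bin
    ok = np.where(np.isnan(col[::-1]), False, ok)
    if contiguous:
        bad = np.flatnonzero(~ok)
        k = (bad[0] - 1) if bad.size else (ok.size - 1)
    else:
        good = np.flatnonzero(ok)
        k = good[-1] if good.size else 0
    return float(max(k, 0) * grid.time_bin)


def delta_t_max_analytic(family: CostFamily, T: float, delta_uc: float) -> float:
    """Closed-form optimal stopping time for the analytic cost families."""
    if delta_uc < 0:
        raise ValueError("delta_uc must be nonnegative")
    if family.family == "linear":
        return delta_uc / family.rho
    if family.family == "power":
        return float((delta_uc / family.a) ** (1.0 / family.b))
    return float(T * (delta_uc / family.a) ** (1.0 / family.b))


def _policy_limit(policy, T: float, U: float, delta_uc: float) -> float:
    if isinstance(policy, CostFamily):
        return delta_t_max_analytic(policy, T, delta_uc)
    return delta_t_max_empirical(policy, T, U, delta_uc)


def implied_mean_move_times(
    policy: ValueGrid | CostFamily,
    offers: Sequence[OfferSample],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Mean move time per benefit bin under an accept/decline policy.

    Each offer is taken in full when its time price does not exceed the
    policy's dTmax at the offer's state, else declined; the time spent is
    ``motor_time + dTC`` or ``motor_time``.  Means are reported within
    benefit bins of width ``utility_bin_width``.
    """
    if not offers:
        raise ValueError("offers must be nonempty")
    config = config or RunConfig()
    du = config.utility_bin_width
    times = np.empty(len(offers))
    bins = np.empty(len(offers), dtype=int)
    for i, off in enumerate(offers):
        limit = _policy_limit(policy, off.T, off.U, off.delta_uc)
        extra = off.delta_tc if off.delta_tc <= limit else 0.0
        times[i] = config.motor_time + extra
        bins[i] = int(off.delta_uc / du)
    tc_label = (
        policy.time_control.label if isinstance(policy, ValueGrid) else "analytic"
    )
    frame = pd.DataFrame({"duc_bin_left": bins * du, "time": times})
    out = (
        frame.groupby("duc_bin_left")["time"]
        .agg(mean_time="mean", n="size")
        .reset_index()
    )
    out.insert(0, "time_control", tc_label)
    return out
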