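"""Synthetic clocked-game datasets with policy-following players.

The generator emulates the statistical structure of move-level data from
online chess without any chess semantics: positions are abstracted to an
advantage trajectory in [0, 1] evolving as a reflected random walk, and each
ply produces a consideration set whose deep utilities track the trajectory
while the shallow utilities are heteroscedastically noised copies of them.
Players follow an accept/decline deliberation policy: each ply they are
offered a computation (a time price dTC paired with the set's true benefit
dUC) and spend ``motor_time + dTC`` when the price is below the policy's
dTmax at the current state, else ``motor_time`` alone, with multiplicative
lognormal timing noise.  Clocks run down under an S+I control; a player
whose clock reaches zero loses by flagging, otherwise the outcome is decided
by the final advantage against a symmetric draw margin.

Because the generating policy and its parameters are known, every emitted
dataset carries an aligned truth table, making the simulator the ground
truth for downstream parameter-recovery checks.

Offered time prices are drawn from a bounded power-law, density
proportional to x^k on (0, cap): under such a law the mean log price among
*accepted* offers equals ``log dTmax - 1/(k+1)`` exactly, so a log-log
regression of accepted deliberation times on the benefit is a consistent
estimator of the policy's concavity exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .dataio import PositionRecord, TimeControl, log_stage
from .policy import (
    CostFamily,
    OfferSample,
    ValueGrid,
    delta_t_max_analytic,
    delta_t_max_empirical,
)
from .voc import (
    ConsiderationSet,
    MoveEval,
    benefit_of_computation,
    expected_benefit_of_computation,
)

__all__ = [
    "SimConfig",
    "DatasetTruth",
    "sample_consideration_set",
    "generate_offer",
    "generate_offers",
    "generate_dataset",
    "generate_value_records",
    "make_fixture_positions",
    "sample_engine_outcome_pairs",
    "sample_regression_dataset",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a blitz-like 300+0 population: ratings centred at 1500
    (sd 200), advantage innovations of 0.02 utility per ply, shallow
    evaluation noise of 0.08 utility (scaled per move by a heteroscedastic
    factor in [0.5, 1.5]), a 1 s motor baseline per move, 10% timing noise,
    and a concave power cost policy (a = 0.001, b = 2).  Offered time prices
    are capped at ``offer_scale_s * offer_unit_max`` seconds (40 s at the
    default 20 000 scale).
    """

    n_games: int = 200
    time_control: TimeControl = field(default_factory=lambda: TimeControl(300, 0))
    elo_mean: float = 1500.0
    elo_sd: float = 200.0
    advantage_step_sd: float = 0.02
    shallow_noise_sd: float = 0.08
    policy_family: str = "power"
    policy_params: CostFamily | ValueGrid | None = None
    consideration_size: int = 5
    motor_time: float = 1.0
    movetime_noise_cv: float = 0.1
    offer_scale_s: float = 20_000.0
    offer_unit_max: float = 2e-3
    offer_shape_k: float = 0.0
    offer_coupling: float = 0.3
    offer_duc_scale: float = 0.05
    deep_gap_scale: float = 0.08
    draw_margin: float = 0.02
    max_ply: int = 100
    seed: int = 0
    compute_expected: bool = True

    def __post_init__(self) -> None:
        if self.n_games < 1:
            raise ValueError("n_games must be >= 1")
        for name in ("advantage_step_sd", "elo_sd", "offer_unit_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("shallow_noise_sd", "motor_time", "movetime_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.consideration_size < 2:
            raise ValueError("consideration_size must be >= 2")
        if self.policy_params is None:
            if self.policy_family == "linear":
                self.policy_params = CostFamily("linear", rho=0.01)
            elif self.policy_family in ("power", "power_timeleft"):
                self.policy_params = CostFamily(
                    self.policy_family, a=0.001, b=2.0
                )
            elif self.policy_family == "empirical_grid":
                raise ValueError("empirical_grid policy requires policy_params")
            else:
                raise ValueError(f"unknown policy family {self.policy_family!r}")


@dataclass
class DatasetTruth:
    """Per-record generating truth, aligned 1:1 with the emitted records."""

    policy: CostFamily | ValueGrid
    table: pd.DataFrame


def _policy_limit(policy, T: float, U: float, duc: float) -> float:
    if isinstance(policy, CostFamily):
        return delta_t_max_analytic(policy, T, duc)
    return delta_t_max_empirical(policy, T, U, duc)


def sample_consideration_set(
    rng: np.random.Generator,
    config: SimConfig,
    anchor: float | None = None,
) -> ConsiderationSet:
    """Draw one consideration set of paired deep/shallow utilities.

    Deep utilities are the ground truth: uniform on [0, 1] when ``anchor``
    is None, otherwise the top move sits at the anchor advantage with the
    remaining moves an exponential gap below it.  Shallow utilities are the
    deep values plus clamped Normal(0, shallow_noise_sd * eps_m) noise with
    a per-move heteroscedastic factor eps_m ~ Uniform(0.5, 1.5); the
    per-move factors create variation in the expected benefit at fixed true
    benefit.  Moves are returned in descending shallow order.
    """
    k = config.consideration_size
    if anchor is None:
        deep = rng.uniform(0.0, 1.0, size=k)
    else:
        gaps = rng.exponential(config.deep_gap_scale, size=k - 1)
        deep = np.clip(np.concatenate([[anchor], anchor - gaps]), 0.0, 1.0)
    eps = rng.uniform(0.5, 1.5, size=k)
    noise = rng.standard_normal(k) * config.shallow_noise_sd * eps
    shallow = np.clip(deep + noise, 0.0, 1.0)
    order = np.argsort(-shallow, kind="stable")
    return ConsiderationSet(
        MoveEval(f"m{j}", float(shallow[j]), float(deep[j])) for j in order
    )


def _offer_arrays(
    rng: np.random.Generator, config: SimConfig, n: int
) -> tuple[np.ndarray, np.ndarray]:
    rho_s = float(np.clip(config.offer_coupling, -0.999, 0.999))
    rho_g = 2.0 * np.sin(np.pi * rho_s / 6.0)  # Gaussian-copula rank match
    z1 = rng.standard_normal(n)
    z2 = rho_g * z1 + np.sqrt(1.0 - rho_g**2) * rng.standard_normal(n)
    u1, u2 = ndtr(z1), ndtr(z2)
    x = u1 ** (1.0 / (config.offer_shape_k + 1.0))
    dtc = config.offer_scale_s * config.offer_unit_max * x
    duc = np.minimum(-config.offer_duc_scale * np.log1p(-u2), 1.0)
    return dtc, duc


def generate_offer(
    rng: np.random.Generator, config: SimConfig
) -> tuple[float, float]:
    """One computation offer (dTC seconds, dUC utility), positively coupled.

    The time price scales linearly with ``offer_scale_s``; the rank
    correlation between price and benefit is set by ``offer_coupling``
    through a Gaussian copula (0 gives independence).
    """
    dtc, duc = _offer_arrays(rng, config, 1)
    return float(dtc[0]), float(duc[0])


def generate_offers(
    rng: np.random.Generator,
    config: SimConfig,
    n: int,
    t_range: tuple[float, float] = (20.0, 280.0),
    u_range: tuple[float, float] = (0.2, 0.8),
) -> list[OfferSample]:
    """n offers with uniformly drawn starting states (T, U)."""
    dtc, duc = _offer_arrays(rng, config, n)
    ts = rng.uniform(*t_range, size=n)
    us = rng.uniform(*u_range, size=n)
    return [
        OfferSample(float(t), float(u), float(c), float(b))
        for t, u, c, b in zip(ts, us, dtc, duc)
    ]


def _reflect01(x: float) -> float:
    # reflect into [0, 1]; one bounce suffices for small innovations
    if x < 0.0:
        x = -x
    if x > 1.0:
        x = 2.0 - x
    return min(max(x, 0.0), 1.0)


def generate_dataset(
    config: SimConfig,
) -> tuple[list[PositionRecord], DatasetTruth]:
    """Simulate ``n_games`` full games; returns records and aligned truth.

    Per game, two players alternate under the configured S+I control.  Each
    ply the active player receives a consideration set anchored at their
    side of the advantage walk and a time-price offer; they accept when the
    price is within the policy's dTmax for the set's true benefit, and their
    clock updates by ``clock_after = clock_before - spent + increment``.  A
    move on which the clock would reach zero ends the game by flagging (the
    interrupted move is not emitted as a record); games surviving to
    ``max_ply`` are decided by the final advantage against the draw margin.
    """
    if config.motor_time < 0:
        raise ValueError("motor_time implies negative move times")
    policy = config.policy_params
    S = float(config.time_control.start_seconds)
    inc = float(config.time_control.increment_seconds)
    sig_log = float(np.sqrt(np.log1p(config.movetime_noise_cv**2)))

    records: list[PositionRecord] = []
    truth_rows: list[dict] = []
    for g in range(config.n_games):
        rng = np.random.default_rng([config.seed, g])
        gid = f"g{g:06d}"
        elos = config.elo_mean + config.elo_sd * rng.standard_normal(2)
        innov = config.advantage_step_sd * rng.standard_normal(config.max_ply)
        if config.movetime_noise_cv > 0:
            eta = np.exp(
                sig_log * rng.standard_normal(config.max_ply) - 0.5 * sig_log**2
            )
        else:
            eta = np.ones(config.max_ply)
        offer_dtc, _ = _offer_arrays(rng, config, config.max_ply)

        clocks = [S, S]
        adv = 0.5
        winner: int | None = None
        game_records: list[PositionRecord] = []
        game_truth: list[dict] = []
        for i in range(config.max_ply):
            ply = i + 1
            p = i % 2
            cset = sample_consideration_set(
                rng, config, anchor=adv if p == 0 else 1.0 - adv
            )
            duc = benefit_of_computation(cset)
            u_pre = float(cset.shallow.max())
            t_before = clocks[p]
            limit = _policy_limit(policy, t_before, u_pre, duc)
            accepted = offer_dtc[i] <= limit
            prescribed = config.motor_time + (offer_dtc[i] if accepted else 0.0)
            # timing noise scales the deliberation component only; the motor
            # baseline is a deterministic per-move floor
            spent = config.motor_time + (prescribed - config.motor_time) * eta[i]
            spent = float(spent)
            if spent >= t_before:
                winner = 1 - p  # flagging: the mover's clock ran out
                break
            t_after = float(t_before - spent + inc)
            clocks[p] = t_after
            game_records.append(
                PositionRecord(
                    game_id=gid,
                    ply=ply,
                    active_elo=float(elos[p]),
                    opponent_clock=clocks[1 - p],
                    clock_before=t_before,
                    clock_after=t_after,
                    time_control=config.time_control,
                    outcome="draw",  # placeholder until the game resolves
                    consideration_set=cset,
                    observed_move_id=cset.moves[0].move_id,
                )
            )
            game_truth.append(
                {
                    "game_id": gid,
                    "ply": ply,
                    "delta_uc_true": duc,
                    "e_delta_uc_true": (
                        expected_benefit_of_computation(cset)
                        if config.compute_expected
                        else np.nan
                    ),
                    "offer_dtc": float(offer_dtc[i]),
                    "policy_limit": float(limit),
                    "prescribed_time": float(prescribed),
                    "accepted": bool(accepted),
                    "spent": float(spent),
                }
            )
            adv = _reflect01(adv + innov[i])
        if winner is None:
            if adv > 0.5 + config.draw_margin:
                winner = 0
            elif adv < 0.5 - config.draw_margin:
                winner = 1
        for rec in game_records:
            p = (rec.ply - 1) % 2
            rec.outcome = (
                "draw" if winner is None else ("win" if winner == p else "loss")
            )
        records.extend(game_records)
        truth_rows.extend(game_truth)

    log_stage("generate_dataset", len(records))
    return records, DatasetTruth(policy=policy, table=pd.DataFrame(truth_rows))


def generate_value_records(
    law: Callable[[np.ndarray, np.ndarray], np.ndarray],
    n: int,
    time_control: TimeControl,
    rng: np.random.Generator,
    t_range: tuple[float, float] = (3.0, 183.0),
    u_range: tuple[float, float] = (0.2, 0.85),
    ply: int = 20,
) -> list[PositionRecord]:
    """Records whose outcomes are Bernoulli draws from a known value law.

    Each record carries a single-move consideration set pinning the
    advantage at U and an outcome sampled from ``law(T, U)``; this is the
    controlled input for validating the empirical value-grid estimator
    against a monotone ground truth.
    """
    ts = rng.uniform(*t_range, size=n)
    us = rng.uniform(*u_range, size=n)
    wins = rng.random(n) < np.clip(law(ts, us), 0.0, 1.0)
    return [
        PositionRecord(
            game_id=f"v{i:07d}",
            ply=ply,
            active_elo=1500.0,
            opponent_clock=10_000.0,
            clock_before=float(t),
            clock_after=float(t),
            time_control=time_control,
            outcome="win" if w else "loss",
            consideration_set=ConsiderationSet(
                [MoveEval("m0", float(u), float(u))]
            ),
        )
        for i, (t, u, w) in enumerate(zip(ts, us, wins))
    ]


def make_fixture_positions() -> dict[str, ConsiderationSet]:
    """Small labelled consideration sets exercising the score structure.

    ``agree``: deep and shallow argmax coincide (true benefit 0) but the
    beliefs overlap, so the expected benefit is strictly positive.
    ``disagree``: the deep argmax differs, giving a true benefit of 0.30.
    ``degenerate``: shallow equals deep everywhere; both scores are 0.
    """
    agree = ConsiderationSet(
        [
            MoveEval("a", 0.60, 0.70),
            MoveEval("b", 0.58, 0.40),
            MoveEval("c", 0.50, 0.55),
        ]
    )
    disagree = ConsiderationSet(
        [MoveEval("a", 0.60, 0.40), MoveEval("b", 0.50, 0.70)]
    )
    degenerate = ConsiderationSet(
        [MoveEval("a", 0.50, 0.50), MoveEval("b", 0.40, 0.40), MoveEval("c", 0.30, 0.30)]
    )
    return {"agree": agree, "disagree": disagree, "degenerate": degenerate}


def sample_engine_outcome_pairs(
    rng: np.random.Generator,
    n_cp: int = 50_000,
    n_mate: int = 2_000,
    cp_intercept: float = 0.0,
    cp_slope: float = 0.004,
    cp_range: float = 500.0,
    mate_intercept: float = 0.5,
    mate_slope: float = 2.0,
):
    """Synthetic (engine evaluation, outcome) pairs from known logistic laws.

    Centipawn values are uniform on +/-``cp_range`` with win probability
    ``logistic(cp_intercept + cp_slope * v)``; mate distances are drawn from
    +/-1..10 with a steep logistic in the signed distance, so a mate-in-1
    converts almost surely while the opponent's imminent mate almost never
    survives.  The generating coefficients are the recovery targets for
    utility-map fitting tests.
    """
    from scipy.special import expit

    from .utility import EngineEval

    pairs = []
    v_cp = rng.uniform(-cp_range, cp_range, size=n_cp)
    y_cp = rng.random(n_cp) < expit(cp_intercept + cp_slope * v_cp)
    pairs += [
        (EngineEval("centipawn", float(v)), "win" if y else "loss")
        for v, y in zip(v_cp, y_cp)
    ]
    d = rng.integers(1, 11, size=n_mate) * rng.choice([-1, 1], size=n_mate)
    y_m = rng.random(n_mate) < expit(mate_intercept + mate_slope * d)
    pairs += [
        (EngineEval("mate", int(v)), "win" if y else "loss")
        for v, y in zip(d, y_m)
    ]
    return pairs


def sample_regression_dataset(
    n: int,
    seed: int,
    curve: str = "sqrt",
    intercept: float = 2.0,
    benefit_slope: float = 5.0,
    elo_slope: float = 0.001,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Move-time rows from a known regression law for fit/AIC checks.

    ``curve`` selects whether the generating move time is linear in the
    benefit or in its square root.  Columns match the scored-record schema
    consumed by the regression API.
    """
    rng = np.random.default_rng(seed)
    duc = rng.uniform(0.0, 0.6, size=n)
    elo = rng.normal(1500.0, 200.0, size=n)
    bt = np.sqrt(duc) if curve == "sqrt" else duc
    mt = (
        intercept
        + benefit_slope * bt
        + elo_slope * (elo - 1500.0)
        + noise_sd * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {
            "move_time": mt,
            "delta_uc": duc,
            "elo": elo,
            "tc": "300+0",
            "tc_start": 300,
            "tc_inc": 0,
        }
    )
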