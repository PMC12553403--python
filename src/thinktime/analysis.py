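"""Move-time statistics: regressions, AIC comparison, rank-correlation summaries.

Works on the tidy scored table produced by :func:`thinktime.voc.score_records`
(one row per move with ``move_time``, ``delta_uc``/``e_delta_uc``, ``elo``,
time-control columns).  Ratings enter regressions centred at 1500 so the
benefit main effect is interpretable at the population-typical strength, and
the benefit x rating interaction carries the expertise effect.  Concavity of
the move-time/benefit relationship is tested by fitting the benefit both
untransformed and square-rooted and comparing AIC under a fixed Gaussian
convention, AIC = n*log(RSS/n) + 2k (additive constants dropped, identical
across compared models so differences are well defined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .dataio import log_stage

__all__ = [
    "RegressionResult",
    "EloBinSummary",
    "RecoveredExponent",
    "compute_move_time",
    "filter_ply_window",
    "fit_movetime_regression",
    "aic_compare",
    "spearman_by_elo",
    "binned_movetime_curve",
    "recover_cost_exponent",
]


def compute_move_time(clock_before, clock_after, increment, convention="post_increment"):
    """Seconds spent on a move, from successive clock readings.

    Under the ``post_increment`` convention the recorded clocks satisfy
    ``clock_after = clock_before - t + increment``, so
    ``t = clock_before - clock_after + increment``.  The ``literal_paper``
    convention instead subtracts the increment from the raw clock
    difference, for sources that add the increment before recording.
    Results clamp at zero (an opponent gifting clock time can otherwise
    produce negative differences).  Accepts scalars or arrays.
    """
    diff = np.asarray(clock_before, dtype=float) - np.asarray(clock_after, dtype=float)
    inc = np.asarray(increment, dtype=float)
    if convention == "post_increment":
        t = diff + inc
    elif convention == "literal_paper":
        t = diff - inc
    else:
        raise ValueError(f"unknown clock convention {convention!r}")
    t = np.maximum(t, 0.0)
    return float(t) if t.ndim == 0 else t


def filter_ply_window(records, ply_min: int = 15, ply_max: int = 75):
    """Keep moves with ply_min <= ply <= ply_max (inclusive on both ends).

    Strips opening-book plies and deep-endgame plies from the analysis.
    Accepts a record sequence or a DataFrame with a ``ply`` column.
    """
    if isinstance(records, pd.DataFrame):
        return records[(records["ply"] >= ply_min) & (records["ply"] <= ply_max)]
    return [r for r in records if ply_min <= r.ply <= ply_max]


@dataclass
class RegressionResult:
    """A fitted move-time model: terms, estimates and the fixed-AIC summary."""

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    n: int
    k: int
    rss: float
    aic: float
    resid_var: float

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params,
                "se": self.bse,
                "p": self.pvalues,
            }
        )


def _check_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.qr(exog, mode="r")
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {cols}")


def fit_movetime_regression(
    df: pd.DataFrame,
    benefit_column: str = "delta_uc",
    transform: str = "identity",
    per_time_control: bool = False,
    pooled_time_control: bool = False,
    elo_center: float = 1500.0,
) -> RegressionResult:
    """OLS of move times on the (possibly root-transformed) benefit score.

    The base design is intercept + benefit + centred Elo + their
    interaction.  With ``per_time_control`` every term is expanded into a
    separate copy per time-control setting; with ``pooled_time_control``
    the start time and increment enter directly along with their
    interactions with the benefit.  Fitting uses the QR-based least-squares
    path in statsmodels; the AIC reported follows this module's fixed
    Gaussian convention.
    """
    if transform not in ("identity", "sqrt"):
        raise ValueError("transform must be 'identity' or 'sqrt'")
    if per_time_control and pooled_time_control:
        raise ValueError("per_time_control and pooled_time_control are exclusive")
    work = pd.DataFrame(
        {
            "move_time": df["move_time"].to_numpy(dtype=float),
            "bt": (
                np.sqrt(df[benefit_column].to_numpy(dtype=float))
                if transform == "sqrt"
                else df[benefit_column].to_numpy(dtype=float)
            ),
            "elo_c": df["elo"].to_numpy(dtype=float) - elo_center,
        }
    )
    if per_time_control:
        work["tc"] = df["tc"].to_numpy()
        formula = "move_time ~ 0 + C(tc) + C(tc):bt + C(tc):elo_c + C(tc):bt:elo_c"
    elif pooled_time_control:
        work["tc_start"] = df["tc_start"].to_numpy(dtype=float)
        work["tc_inc"] = df["tc_inc"].to_numpy(dtype=float)
        formula = (
            "move_time ~ bt + elo_c + bt:elo_c + tc_start + tc_inc"
            " + bt:tc_start + bt:tc_inc"
        )
    else:
        formula = "move_time ~ bt + elo_c + bt:elo_c"

    model = smf.ols(formula, data=work)
    k = model.exog.shape[1]
    n = model.exog.shape[0]
    if n < 10 * k:
        raise ValueError(f"need at least 10 rows per term ({k} terms, {n} rows)")
    _check_rank(model.exog, model.exog_names)
    res = model.fit()
    rss = float(res.ssr)
    aic = n * float(np.log(rss / n)) + 2 * k
    log_stage("fit_movetime_regression", n)
    return RegressionResult(
        terms=list(res.params.index),
        params=res.params.to_numpy(),
        bse=res.bse.to_numpy(),
        pvalues=res.pvalues.to_numpy(),
        n=n,
        k=k,
        rss=rss,
        aic=aic,
        resid_var=rss / max(n - k, 1),
    )


def aic_compare(
    result_a: RegressionResult, result_b: RegressionResult
) -> tuple[float, str]:
    """AIC(a) - AIC(b) and which model is preferred (the lower AIC).

    Comparison is only meaningful on identical row sets; differing row
    counts are rejected.
    """
    if result_a.n != result_b.n:
        raise ValueError(
            f"models were fitted on different row sets (n={result_a.n} vs "
            f"n={result_b.n})"
        )
    delta = result_a.aic - result_b.aic
    return delta, ("a" if delta < 0 else "b")


@dataclass
class EloBinSummary:
    """Mean per-player-game Spearman rho within rating bins."""

    bin_width: float
    table: pd.DataFrame  # columns: elo_bin_left, mean_rho, n_games


def spearman_by_elo(
    df: pd.DataFrame,
    elo_bin_width: float = 100.0,
    min_games: int = 200,
    min_moves: int = 3,
    benefit_column: str = "delta_uc",
) -> EloBinSummary:
    """Per-(game, player) rank correlation of move time with benefit, by Elo.

    Each player's moves within one game give one Spearman rho (average ranks
    on ties); players contributing fewer than ``min_moves`` usable moves, or
    with a constant variable, are skipped.  Rhos are averaged within rating
    bins and bins with fewer than ``min_games`` contributions are dropped.
    """
    work = df.copy()
    if "player" not in work:
        work["player"] = (work["ply"] - 1) % 2
    rows = []
    for (_, _), grp in work.groupby(["game_id", "player"], sort=False):
        if len(grp) < min_moves:
            continue
        x = grp[benefit_column].to_numpy(dtype=float)
        y = grp["move_time"].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(x, y).statistic
        if np.isnan(rho):
            continue
        rows.append((float(grp["elo"].iloc[0]), float(rho)))
    if not rows:
        return EloBinSummary(elo_bin_width, pd.DataFrame(
            columns=["elo_bin_left", "mean_rho", "n_games"]
        ))
    frame = pd.DataFrame(rows, columns=["elo", "rho"])
    frame["elo_bin_left"] = np.floor(frame["elo"] / elo_bin_width) * elo_bin_width
    out = (
        frame.groupby("elo_bin_left")["rho"]
        .agg(mean_rho="mean", n_games="size")
        .reset_index()
    )
    out = out[out["n_games"] >= min_games].reset_index(drop=True)
    return EloBinSummary(elo_bin_width, out)


def binned_movetime_curve(
    df: pd.DataFrame,
    benefit_column: str = "delta_uc",
    bin_width: float = 0.03,
) -> pd.DataFrame:
    """Mean move time per benefit bin per time control (the headline curve)."""
    work = df.copy()
    work["benefit_bin_left"] = (
        np.floor(work[benefit_column].to_numpy(dtype=float) / bin_width) * bin_width
    )
    out = (
        work.groupby(["tc", "benefit_bin_left"])["move_time"]
        .agg(mean_move_time="mean", n="size")
        .reset_index()
        .rename(columns={"tc": "time_control"})
    )
    return out


@dataclass
class RecoveredExponent:
    """Log-log recovery of the power-cost concavity exponent."""

    slope: float
    slope_se: float
    b_hat: float
    n: int


def recover_cost_exponent(
    scored: pd.DataFrame,
    accepted: np.ndarray | pd.Series,
    motor_time: float,
) -> RecoveredExponent:
    """Estimate the power-cost exponent b from accepted deliberations.

    Under a power cost c(dT) = a*dT^b the stopping threshold scales as
    dUC^(1/b), and with a bounded power-law offer distribution the mean log
    accepted deliberation tracks the log threshold with unit slope.  OLS of
    ``log(move_time - motor_time)`` on ``log dUC`` over accepted offers
    therefore has slope 1/b; the returned ``b_hat`` is its reciprocal.
    """
    accepted = np.asarray(accepted, dtype=bool)
    extra = scored["move_time"].to_numpy(dtype=float) - motor_time
    duc = scored["delta_uc"].to_numpy(dtype=float)
    mask = accepted & (extra > 0) & (duc > 0)
    y = np.log(extra[mask])
    x = np.log(duc[mask])
    if mask.sum() < 10:
        raise ValueError("too few accepted offers for exponent recovery")
    res = stats.linregress(x, y)
    return RecoveredExponent(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        b_hat=float(1.0 / res.slope),
        n=int(mask.sum()),
    )
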