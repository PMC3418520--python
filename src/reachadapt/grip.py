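"""Trial-by-trial grip-force models for object-lifting series.

Two two-parameter models predict the grip force on trial ``n`` from a
three-trial history:

* **regression model** —
  ``GF_hat[n] = w1 * mu[n] + w2 * GF_regress[n]`` where ``mu[n]`` is
  the mean of the previous three grip forces and ``GF_regress[n]`` is
  the ordinary-least-squares line through those three forces evaluated
  one step ahead (trend extrapolation).
* **variance model** —
  ``GF_hat[n] = w1 * mu[n] + w2 * M_std[n]`` where ``M_std[n]`` is the
  standard deviation of the previous three object weights (an
  environmental-variability / safety-margin term).

Both models have exactly two adjustable parameters, so their fit
quality (variance accounted for, VAF, and Pearson correlation) can be
compared directly without complexity corrections.  ``(w1, w2)`` are
fitted by ordinary least squares of the observed grip forces on the
two regressors over all trials with a full three-trial history; there
is no intercept in the model as written (one is available behind a
flag for sensitivity analysis).

Weight units are arbitrary and absorbed into ``w2``; ``M_std`` uses
the sample (n-1) standard deviation by default, switchable via
``ddof``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GripSeries",
    "ModelFit",
    "RankDeficiencyError",
    "regression_model_predict",
    "variance_model_predict",
    "fit_model",
    "vaf",
    "generate_grip_series",
]

HISTORY = 3  # trials of history both models consume

#: Weight levels of the synthetic lifting protocol (arbitrary units).
WEIGHT_LEVELS = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

#: The embedded increasing weight series.
WEIGHT_SERIES = (1.0, 2.0, 3.0, 4.0)


class RankDeficiencyError(np.linalg.LinAlgError):
    """Raised when the two model regressors are collinear."""


@dataclass
class GripSeries:
    """Paired object-weight and grip-force sequences."""

    weights: np.ndarray  # arbitrary mass-proportional units
    gf: np.ndarray  # N

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.gf = np.asarray(self.gf, dtype=float)
        if len(self.weights) != len(self.gf):
            raise ValueError("weights and gf must share one length")
        if len(self.gf) < HISTORY + 1:
            raise ValueError(
                f"need at least {HISTORY + 1} trials (3-trial history)"
            )

    @property
    def n(self) -> int:
        return len(self.gf)

    def to_csv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("weight,grip_force\n")
            fh.write("au,N\n")  # units row
            for w, g in zip(self.weights, self.gf):
                fh.write(f"{float(w)!r},{float(g)!r}\n")

    @classmethod
    def from_csv(cls, path: str) -> "GripSeries":
        df = pd.read_csv(path, skiprows=[1])  # skip the units row
        return cls(
            weights=df["weight"].to_numpy(), gf=df["grip_force"].to_numpy()
        )


@dataclass
class ModelFit:
    """Fitted two-parameter model: weights, fit quality, residuals."""

    model: str
    w1: float
    w2: float
    vaf: float
    r: float
    predicted: np.ndarray
    residuals: np.ndarray
    intercept: Optional[float] = None


def _extrapolate_next(history: np.ndarray) -> float:
    """OLS line through (0..m-1, history), evaluated at index m."""
    m = len(history)
    x = np.arange(m, dtype=float)
    slope, intercept = np.polyfit(x, history, 1)
    return float(slope * m + intercept)


def regression_model_predict(
    gf_history: np.ndarray, w1: float, w2: float
) -> float:
    """Regression-model prediction from the previous three grip forces."""
    h = np.asarray(gf_history, dtype=float)
    if len(h) != HISTORY:
        raise ValueError(f"gf_history must have length {HISTORY}")
    return float(w1 * h.mean() + w2 * _extrapolate_next(h))


def variance_model_predict(
    gf_history: np.ndarray,
    weight_history: np.ndarray,
    w1: float,
    w2: float,
    ddof: int = 1,
) -> float:
    """Variance-model prediction from grip-force and weight histories."""
    h = np.asarray(gf_history, dtype=float)
    w = np.asarray(weight_history, dtype=float)
    if len(h) != HISTORY or len(w) != HISTORY:
        raise ValueError(f"both histories must have length {HISTORY}")
    return float(w1 * h.mean() + w2 * np.std(w, ddof=ddof))


def _design_matrix(
    series: GripSeries, model: str, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Regressors and targets over trials with a full history."""
    gf, w = series.gf, series.weights
    rows = []
    for n in range(HISTORY, series.n):
        h = gf[n - HISTORY : n]
        if model == "regression":
            rows.append((h.mean(), _extrapolate_next(h)))
        elif model == "variance":
            rows.append((h.mean(), np.std(w[n - HISTORY : n], ddof=ddof)))
        else:
            raise ValueError("model must be 'regression' or 'variance'")
    X = np.array(rows)
    y = gf[HISTORY:]
    return X, y


def fit_model(
    series: GripSeries,
    model: str = "regression",
    intercept: bool = False,
    ddof: int = 1,
) -> ModelFit:
    """Fit ``(w1, w2)`` by ordinary least squares.

    The first three trials (incomplete history) are excluded.  A
    rank-deficient design (collinear regressors, e.g. constant weights
    under the variance model) raises :class:`RankDeficiencyError`
    rather than returning an arbitrary solution.
    """
    X, y = _design_matrix(series, model, ddof=ddof)
    if intercept:
        X = np.column_stack([X, np.ones(len(X))])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            f"{model}-model regressors are collinear (rank {rank} < "
            f"{X.shape[1]}); the fit is not identifiable"
        )
    predicted = X @ coef
    residuals = y - predicted
    return ModelFit(
        model=model,
        w1=float(coef[0]),
        w2=float(coef[1]),
        vaf=vaf(y, predicted),
        r=float(stats.pearsonr(y, predicted).statistic),
        predicted=predicted,
        residuals=residuals,
        intercept=float(coef[2]) if intercept else None,
    )


def vaf(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Variance accounted for: ``1 - var(observed - predicted)/var(observed)``.

    1 for a perfect prediction, 0 for predicting a constant at the
    observed mean, negative for predictions worse than that.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(observed) != len(predicted):
        raise ValueError("series must share one length")
    denom = np.var(observed)
    if denom == 0:
        raise ValueError("VAF undefined for zero-variance observations")
    return float(1.0 - np.var(observed - predicted) / denom)


def generate_grip_series(
    generator: str = "eq3",
    w1: float = 0.7,
    w2: float = 0.3,
    weight_schedule: str = "mixed",
    noise_sd: float = 0.05,
    n: int = 200,
    seed: int = 0,
    ddof: int = 1,
) -> GripSeries:
    """Synthetic lifting session for parameter-recovery studies.

    Weight schedules: ``"random"`` draws uniformly from the weight
    levels, ``"increasing_series"`` repeats the 1-2-3-4 ramp, and
    ``"mixed"`` (default) embeds ramps into a random background,
    emulating a lifting protocol with implicit series.  Grip forces
    start at the first three weights (unit weight-to-grip mapping) and
    then follow the chosen generative law plus zero-mean Gaussian noise:
    ``"eq3"`` (regression model), ``"eq4"`` (variance model), or
    ``"averager"`` (grip force = mean of the last three weights, a
    model-free reference).  Deterministic given ``seed``.
    """
    if n < HISTORY + 1:
        raise ValueError("n too small")
    rng = np.random.default_rng(seed)
    weights = _weight_schedule(weight_schedule, n, rng)
    gf = np.empty(n)
    gf[:HISTORY] = weights[:HISTORY]
    for i in range(HISTORY, n):
        h = gf[i - HISTORY : i]
        if generator == "eq3":
            mu = regression_model_predict(h, w1, w2)
        elif generator == "eq4":
            mu = variance_model_predict(
                h, weights[i - HISTORY : i], w1, w2, ddof=ddof
            )
        elif generator == "averager":
            mu = float(np.mean(weights[i - HISTORY : i]))
        else:
            raise ValueError("generator must be 'eq3', 'eq4' or 'averager'")
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        gf[i] = mu + noise
    return GripSeries(weights=weights, gf=gf)


def _weight_schedule(
    kind: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    if kind == "increasing_series":
        reps = int(np.ceil(n / len(WEIGHT_SERIES)))
        return np.tile(WEIGHT_SERIES, reps)[:n].astype(float)
    if kind == "random":
        return rng.choice(WEIGHT_LEVELS, size=n).astype(float)
    if kind == "mixed":
        w = rng.choice(WEIGHT_LEVELS, size=n).astype(float)
        ramp = np.asarray(WEIGHT_SERIES)
        n_ramps = max(1, n // 20)
        starts = rng.choice(
            max(1, n - len(ramp)), size=min(n_ramps, n - len(ramp)),
            replace=False,
        )
        for s in sorted(starts):
            w[s : s + len(ramp)] = ramp[: len(w) - s]
        return w
    raise ValueError(
        "weight_schedule must be 'increasing_series', 'random' or 'mixed'"
    )
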