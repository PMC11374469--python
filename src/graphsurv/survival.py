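"""Discrete-time survival machinery with right censoring.

The continuous follow-up timescale is partitioned into ``n_bins`` intervals
whose interior cut points are quantiles of the *uncensored* event times in
the training split. A model emits one logit per bin; the sigmoid of logit
``d`` is the conditional hazard h_d = P(Y = d | Y >= d), and the survival
function is the running product S(d) = prod_{k<d} (1 - h_k). The training
objective is the censoring-split negative log-likelihood

    L = alpha * L_unc + beta * L_cens,   alpha + beta = 1,
    L_unc  = -log S(Y) - log h_Y        (event observed in bin Y)
    L_cens = -log S(Y + 1)              (still event-free past bin Y)

Evaluation uses the concordance index (exhaustive-pair definition) and an
IPCW time-dependent AUC (Uno-style cumulative/dynamic estimator).

Everything here is plain numpy except :func:`nll_loss`, which accepts either
an ndarray of logits or an autodiff :class:`~graphsurv.autodiff.Tensor`, so
the identical bookkeeping serves both evaluation and training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .errors import ConfigurationError, UndefinedMetricError

__all__ = [
    "SurvivalRecord", "BinEdges", "LossWeights",
    "fit_bins", "discretize", "hazards", "survival_probs", "nll_loss",
    "risk_score", "concordance_index", "time_dependent_auc",
    "read_survival_table",
]

_LOG_EPS = 1e-7  # clamp for log arguments under saturated sigmoids


@dataclass
class SurvivalRecord:
    """One subject: follow-up time (days), event indicator, optional bin."""

    sample_id: str
    time: float
    event: int
    bin: int | None = None

    def __post_init__(self):
        if self.time < 0:
            raise ConfigurationError(f"time must be >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ConfigurationError(f"event must be 0 or 1, got {self.event}")

    @property
    def censor(self) -> int:
        return 1 - self.event


@dataclass
class BinEdges:
    """Interior cut points t_1 < ... < t_{n_bins-1}; t_0 = 0, t_nbins = inf."""

    cut_points: np.ndarray

    def __post_init__(self):
        self.cut_points = np.asarray(self.cut_points, dtype=float)
        if np.any(np.diff(self.cut_points) <= 0):
            raise ConfigurationError(
                f"cut points must be strictly increasing, got {self.cut_points}")

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1

    @property
    def full_edges(self) -> np.ndarray:
        return np.concatenate([[0.0], self.cut_points, [np.inf]])


@dataclass
class LossWeights:
    alpha: float = 0.5
    beta: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0,1], got {self.alpha}")
        if self.beta is None:
            self.beta = 1.0 - self.alpha
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ConfigurationError(
                f"alpha + beta must equal 1, got {self.alpha + self.beta}")


def fit_bins(records: list[SurvivalRecord] | np.ndarray, n_bins: int = 4,
             events: np.ndarray | None = None) -> BinEdges:
    """Quantile cut points of uncensored training times.

    Accepts either a list of :class:`SurvivalRecord` or parallel
    ``times, events`` arrays. Interior edges are the k/n_bins quantiles
    (linear interpolation) of event times among uncensored subjects.
    """
    if events is None:
        times = np.array([r.time for r in records], dtype=float)
        events = np.array([r.event for r in records], dtype=int)
    else:
        times = np.asarray(records, dtype=float)
        events = np.asarray(events, dtype=int)
    uncensored = times[events == 1]
    if len(np.unique(uncensored)) < n_bins:
        raise ConfigurationError(
            f"need >= {n_bins} distinct uncensored times to fit {n_bins} bins, "
            f"got {len(np.unique(uncensored))}")
    qs = np.arange(1, n_bins) / n_bins
    cuts = np.quantile(uncensored, qs, method="linear")
    return BinEdges(cuts)


def discretize(time, edges: BinEdges):
    """Bin label(s) for time(s): half-open intervals, lower-inclusive."""
    time_arr = np.asarray(time, dtype=float)
    if np.any(time_arr < 0):
        raise ConfigurationError("negative survival time")
    bins = np.searchsorted(edges.cut_points, time_arr, side="right")
    return int(bins) if np.isscalar(time) or time_arr.ndim == 0 else bins


def hazards(logits: np.ndarray) -> np.ndarray:
    """Elementwise sigmoid: per-bin conditional hazard h_d in (0,1)."""
    logits = np.asarray(logits, dtype=float)
    return 1.0 / (1.0 + np.exp(-logits))


def survival_probs(haz: np.ndarray) -> np.ndarray:
    """S of length n_bins+1 with S[d] = prod_{k<d}(1 - h_k); S[0] = 1."""
    haz = np.asarray(haz, dtype=float)
    return np.concatenate([[1.0], np.cumprod(1.0 - haz)])


def nll_loss(logits, bin: int, censor: int, weights: LossWeights | None = None):
    """Censoring-split discrete-time NLL for one subject.

    ``logits`` may be an ndarray (returns float) or an autodiff ``Tensor``
    (returns a scalar ``Tensor`` for backprop). ``censor`` is 1 for a
    censored subject (event unobserved).
    """
    weights = weights or LossWeights()
    if censor not in (0, 1):
        raise ConfigurationError(f"censor must be 0 or 1, got {censor}")
    if isinstance(logits, Tensor):
        n_bins = logits.shape[0]
        _check_bin(bin, n_bins)
        h = logits.sigmoid()
        one_minus = (1.0 - h).clamp_min(_LOG_EPS)
        log_s_terms = one_minus.log()  # log(1 - h_k), k = 0..n_bins-1
        loss = Tensor(0.0)
        if censor == 0:
            if bin > 0:
                loss = loss + (-weights.alpha) * log_s_terms[:bin].sum()
            loss = loss + (-weights.alpha) * h[bin:bin + 1].clamp_min(_LOG_EPS).log().sum()
        else:
            loss = loss + (-weights.beta) * log_s_terms[:bin + 1].sum()
        return loss
    logits = np.asarray(logits, dtype=float)
    _check_bin(bin, logits.shape[0])
    h = hazards(logits)
    log1mh = np.log(np.maximum(1.0 - h, _LOG_EPS))
    if censor == 0:
        return float(-weights.alpha * (log1mh[:bin].sum()
                                       + np.log(max(h[bin], _LOG_EPS))))
    return float(-weights.beta * log1mh[:bin + 1].sum())


def _check_bin(bin: int, n_bins: int) -> None:
    if not 0 <= bin < n_bins:
        raise ConfigurationError(f"bin {bin} outside [0, {n_bins})")


def risk_score(logits: np.ndarray) -> float:
    """Negative expected survival mass: -sum_{d=0}^{n_bins-1} S(d).

    Monotone in every hazard; higher value means higher risk.
    """
    s = survival_probs(hazards(logits))
    n_bins = len(s) - 1
    return float(-s[:n_bins].sum())


def concordance_index(risks, times, events) -> float:
    """Exhaustive-pair concordance: P(risk_i > risk_j | T_i < T_j, i uncensored).

    Ties in risk count 0.5. Pairs are comparable when the earlier time
    belongs to an uncensored subject.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (len(risks) == len(times) == len(events)):
        raise ConfigurationError("risks, times, events must have equal length")
    # comparable[i, j]: i had the event and strictly precedes j
    comparable = (events[:, None] == 1) & (times[:, None] < times[None, :])
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise UndefinedMetricError("no comparable pairs for concordance index")
    greater = risks[:, None] > risks[None, :]
    tied = risks[:, None] == risks[None, :]
    concordant = (greater * comparable).sum() + 0.5 * (tied * comparable).sum()
    return float(concordant / n_pairs)


def time_dependent_auc(risks, times, events, eval_times,
                       train_times=None, train_events=None):
    """IPCW cumulative/dynamic AUC at each horizon plus integrated summary.

    Censoring weights come from a Kaplan-Meier estimator of the censoring
    distribution fit on the training data (defaults to the evaluation data
    when no training set is supplied). The integrated value is the
    Kaplan-Meier-weighted mean over ``eval_times``.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if eval_times.max() >= times.max():
        raise UndefinedMetricError(
            f"eval time {eval_times.max()} beyond last observed time {times.max()}")
    if train_times is None:
        train_times, train_events = times, events
    y_train = Surv.from_arrays(np.asarray(train_events, dtype=bool),
                               np.asarray(train_times, dtype=float))
    y_test = Surv.from_arrays(events, times)
    aucs, mean_auc = cumulative_dynamic_auc(y_train, y_test, risks, eval_times)
    return np.atleast_1d(aucs), float(mean_auc)


def read_survival_table(path) -> list[SurvivalRecord]:
    """Read ``survival.csv`` with columns sample_id, time_days, event."""
    df = pd.read_csv(path)
    required = {"sample_id", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"survival table missing columns: {sorted(missing)}")
    return [SurvivalRecord(str(r.sample_id), float(r.time_days), int(r.event))
            for r in df.itertuples(index=False)]
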