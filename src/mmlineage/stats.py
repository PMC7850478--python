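"""Population growth/death estimators and generation-time correlation
statistics.

Division and death dynamics are summarised exactly as mother-machine data
are usually presented: the cumulative sum of the instantaneous division
probability D(t)/N(t) per frame (a straight line under balanced growth),
and the fraction of surviving lineages over time (a straight line on a log
scale under a constant death hazard).  Correlation statistics cover pooled
mother-daughter pairs, the lag profile across generations, the one-pair-
per-lineage resampling that removes the over-representation of fast
lineages, and per-lineage (intra-lineage) correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from mmlineage.io import (
    DEATH,
    DIVISION,
    CellCycle,
    EventRecord,
    LineageSeries,
    ancestor_descendant_pairs,
    filter_lineages,
    validate_events,
)

__all__ = [
    "DivisionCurve",
    "SurvivalCurve",
    "UndefinedCorrelationError",
    "cumulative_division_probability",
    "fit_division_rate",
    "death_rate",
    "correlation",
    "one_pair_per_lineage_correlation",
    "autocorrelation",
    "intra_lineage_correlations",
    "division_count_distribution",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation coefficient is undefined (constant input)."""


@dataclass(frozen=True)
class DivisionCurve:
    """Cumulative sum of the per-frame division probability D(t)/N(t)."""

    bin_times: np.ndarray  # frame-end times, hours
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cumulative) < -1e-12):
            raise ValueError("cumulative division probability must be non-decreasing")


@dataclass(frozen=True)
class SurvivalCurve:
    """Fraction of lineages still alive at each frame, with binomial SE."""

    times: np.ndarray
    surviving_fraction: np.ndarray
    se: np.ndarray
    n0: int

    def __post_init__(self) -> None:
        f = self.surviving_fraction
        if f.size and not (f[0] <= 1.0 + 1e-12 and np.all(np.diff(f) <= 1e-12)):
            raise ValueError("surviving fraction must start <= 1 and be non-increasing")


def _death_and_end_times(events: Iterable[EventRecord]):
    """Per channel: (death time or None, last observed time)."""
    info: dict[str, tuple[float | None, float]] = {}
    for cid, recs in validate_events(events).items():
        last = recs[-1]
        death = last.time_h if last.event == DEATH else None
        info[cid] = (death, last.time_h)
    return info


def cumulative_division_probability(
    events: Iterable[EventRecord], dt_h: float = 1.0 / 6.0
) -> DivisionCurve:
    """Cumulative instantaneous division probability on the frame grid.

    For each frame (t, t + dt]: D = number of divisions among lineages alive
    at t, N = number of lineages alive at t; the curve is the running sum of
    D/N.  A lineage is alive at t until its death time; lineages ending with
    end-of-observation remain alive through their last observed time.  The
    curve is truncated with a warning at the first frame where N = 0.
    """
    if dt_h <= 0:
        raise ValueError("dt_h must be positive")
    events = list(events)
    info = _death_and_end_times(events)
    t_max = max(last for _, last in info.values())
    n_bins = int(np.ceil(t_max / dt_h - 1e-9))
    death = np.array([np.inf if d is None else d for d, _ in info.values()])
    ids = list(info)
    idx = {cid: j for j, cid in enumerate(ids)}
    div_counts = np.zeros(n_bins)
    for rec in events:
        if rec.event != DIVISION:
            continue
        b = int(np.ceil(rec.time_h / dt_h - 1e-9)) - 1  # frame (t, t+dt]
        b = max(b, 0)
        if b < n_bins and rec.time_h > death[idx[rec.channel_id]]:
            continue  # cannot happen on validated input; defensive
        if b < n_bins:
            div_counts[b] += 1
    t_starts = np.arange(n_bins) * dt_h
    alive = (death[None, :] > t_starts[:, None]).sum(axis=1)
    usable = alive > 0
    if not usable.all():
        first_zero = int(np.argmin(usable))
        warnings.warn(
            f"no lineages alive from t = {t_starts[first_zero]:.3f} h; "
            "division curve truncated there"
        )
        t_starts = t_starts[:first_zero]
        div_counts = div_counts[:first_zero]
        alive = alive[:first_zero]
    with np.errstate(invalid="ignore"):
        inst = np.where(alive > 0, div_counts / np.maximum(alive, 1), 0.0)
    return DivisionCurve(
        bin_times=t_starts + dt_h, cumulative=np.cumsum(inst)
    )


def fit_division_rate(curve: DivisionCurve) -> tuple[float, float]:
    """OLS slope (per hour) of the cumulative division probability vs time.

    Returns (slope, standard error).  Under balanced growth the slope is the
    population division rate.
    """
    t, y = curve.bin_times, curve.cumulative
    if t.size < 3:
        raise ValueError("need at least 3 points to fit a division rate")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time vector")
    res = sps.linregress(t, y)
    return float(res.slope), float(res.stderr)


def death_rate(
    events: Iterable[EventRecord], dt_h: float = 1.0 / 6.0
) -> tuple[float, float, SurvivalCurve]:
    """Constant death rate from the log-linear decay of lineage survival.

    The surviving fraction N(t)/N(0) is computed on the frame grid (lineages
    ending with end-of-observation are censored: they count as alive until
    the window end and never as deaths).  The rate is the negative OLS slope
    of log surviving fraction over the span where the fraction is positive,
    mirroring the straight-line fit on a log-scaled survival plot.

    The reported standard error is the Poisson count-based error
    rate/sqrt(number of deaths): the survival-curve points are serially
    dependent, so a naive regression error would understate the sampling
    variability.  With no deaths the rate is 0 and the error infinite.

    Returns (rate_per_h, se, SurvivalCurve).
    """
    events = list(events)
    info = _death_and_end_times(events)
    n0 = len(info)
    if n0 < 2:
        raise ValueError("need at least 2 lineages")
    t_max = max(last for _, last in info.values())
    n_bins = int(np.ceil(t_max / dt_h - 1e-9))
    times = np.arange(n_bins + 1) * dt_h
    death = np.array([np.inf if d is None else d for d, _ in info.values()])
    frac = (death[None, :] > times[:, None]).sum(axis=1) / n0
    se = np.sqrt(frac * (1 - frac) / n0)
    curve = SurvivalCurve(times=times, surviving_fraction=frac, se=se, n0=n0)
    n_deaths = int(np.isfinite(death).sum())
    if n_deaths == 0:
        warnings.warn("no deaths observed; death rate 0 with infinite relative error")
        return 0.0, float("inf"), curve
    pos = frac > 0
    if pos.sum() < 2:
        raise ValueError("survival curve has fewer than 2 positive points")
    res = sps.linregress(times[pos], np.log(frac[pos]))
    rate = -float(res.slope)
    return rate, abs(rate) / np.sqrt(n_deaths), curve


def _fisher_se(r: float, n: int) -> float:
    """Symmetric standard error of a correlation via the Fisher z scale."""
    if n <= 3:
        return float("inf")
    return float((1 - r * r) / np.sqrt(n - 3))


def correlation(
    pairs: Sequence[tuple[float, float]], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation of (ancestor, descendant) pairs.

    Returns (coefficient, standard error); the SE is Fisher-z based (applied
    at the rank scale for Spearman).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    if method == "pearson":
        r = float(sps.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(sps.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, _fisher_se(r, arr.shape[0])


def one_pair_per_lineage_correlation(
    cycles: Iterable[CellCycle],
    n_resamples: int = 1000,
    seed=None,
    method: str = "spearman",
    min_divisions: int = 4,
) -> tuple[float, float]:
    """Resampled correlation using one random mother-daughter pair per lineage.

    Fast-cycling lineages contribute many more mother-daughter pairs than
    slow ones, so the pooled coefficient over-weights them.  Drawing a
    single uniformly chosen pair per retained lineage (>= ``min_divisions``
    divisions) removes that sampling bias; the mean and standard deviation
    of the coefficient over ``n_resamples`` resamples are returned.
    """
    cycles = list(cycles)
    lineages = filter_lineages(cycles, min_divisions=min_divisions)
    per_lineage = [
        [(s.taus[k], s.taus[k + 1]) for k in range(len(s.taus) - 1)]
        for s in lineages
    ]
    per_lineage = [p for p in per_lineage if p]
    if len(per_lineage) < 3:
        raise ValueError("need at least 3 lineages with a mother-daughter pair")
    rng = np.random.default_rng(seed)
    coefs = np.empty(n_resamples)
    for i in range(n_resamples):
        chosen = [p[rng.integers(len(p))] for p in per_lineage]
        coefs[i] = correlation(chosen, method=method)[0]
    return float(coefs.mean()), float(coefs.std(ddof=0))


def autocorrelation(
    cycles: Iterable[CellCycle], max_lag: int = 10
) -> dict[int, tuple[float, float]]:
    """Generation-time correlation per ancestor-descendant lag.

    For each lag k = 1..max_lag the Pearson coefficient is computed over all
    within-channel pairs (tau_i, tau_{i+k}); lags without enough pairs are
    omitted with a warning.  Returns {lag: (coefficient, SE)}.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    cycles = list(cycles)
    out: dict[int, tuple[float, float]] = {}
    for lag in range(1, max_lag + 1):
        pairs = ancestor_descendant_pairs(cycles, lag)
        if len(pairs) < 3:
            warnings.warn(f"no usable pairs at lag {lag}; omitted")
            continue
        out[lag] = correlation(pairs, method="pearson")
    return out


def intra_lineage_correlations(
    lineages: Sequence[LineageSeries], method: str = "spearman"
) -> tuple[np.ndarray, float, float, int]:
    """Per-lineage correlation of consecutive generation times.

    Each lineage's coefficient is computed from its own (tau_k, tau_{k+1})
    pairs alone.  Lineages with fewer than three pairs or with constant
    generation times (undefined coefficient) are excluded; their count is
    reported.  Note that a lineage needs at least five division events to
    hold three complete-cycle pairs.  Pooling across
    lineages mixes between-lineage differences in mean generation time into
    the coefficient, so the per-lineage mean is systematically smaller than
    the pooled coefficient.

    Returns (per-lineage coefficients, mean, SD, n_excluded).
    """
    coefs = []
    n_excluded = 0
    for s in lineages:
        pairs = [(s.taus[k], s.taus[k + 1]) for k in range(len(s.taus) - 1)]
        if len(pairs) < 3:
            n_excluded += 1
            continue
        try:
            coefs.append(correlation(pairs, method=method)[0])
        except UndefinedCorrelationError:
            n_excluded += 1
    arr = np.asarray(coefs)
    if arr.size == 0:
        raise ValueError("no lineage yielded a defined correlation")
    return arr, float(arr.mean()), float(arr.std(ddof=0)), n_excluded


def division_count_distribution(
    events: Iterable[EventRecord],
    window_h: float,
    only_survivors: bool = False,
) -> dict[str, int]:
    """Number of division events per channel within [0, window_h].

    With ``only_survivors`` set, channels that died are excluded, matching
    the count over lineages that stayed alive for the whole observation.
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    out: dict[str, int] = {}
    for cid, recs in validate_events(events).items():
        if only_survivors and recs[-1].event == DEATH:
            continue
        out[cid] = sum(
            1 for r in recs if r.event == DIVISION and r.time_h <= window_h
        )
    return out
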