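"""Time-to-event estimation and testing.

Kaplan–Meier curves and the log-rank test are delegated to ``lifelines``; this
module exposes them in the shapes the rest of the package consumes (event-time
arrays, fixed-horizon incidences, percent reductions) and adds the
conventions used throughout: events precede censoring at tied times, time is
in days internally, and the median is the smallest time with S(t) <= 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .config import stream_rng

__all__ = [
    "KMCurve",
    "LogRankResult",
    "IncidenceEstimate",
    "km_estimate",
    "median_survival",
    "logrank",
    "incidence_at",
    "percent_reduction",
]


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) after each distinct event time."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = int(np.searchsorted(self.times, t, side="right"))
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class LogRankResult:
    chi2: float
    df: int
    pvalue: float


@dataclass
class IncidenceEstimate:
    horizon: float
    genotype: str
    incidence: float
    n: int
    method: str


def _validate_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times <= 0):
        raise ValueError("all times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function."""
    times, events = _validate_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    ev_times = ev.index.to_numpy(dtype=float)
    return KMCurve(
        times=ev_times,
        survival=surv.loc[ev.index].to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        censor_times=np.sort(times[events == 0]),
    )


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5, or None if S never reaches 0.5."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.times[below[0]])


def logrank(
    group_a: tuple,
    group_b: tuple,
    permutation: int | None = None,
    seed: int | None = None,
) -> LogRankResult:
    """Two-group log-rank test (hypergeometric variance, 1 df).

    ``group_a``/``group_b`` are ``(times, events)`` pairs.  With
    ``permutation`` set, the chi-square approximation is replaced by a label-
    permutation p-value (add-one estimator), useful for tiny cohorts.
    """
    ta, ea = _validate_times_events(*group_a)
    tb, eb = _validate_times_events(*group_b)
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1")
        return LogRankResult(chi2=0.0, df=1, pvalue=1.0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    chi2 = float(res.test_statistic)
    if permutation is None:
        return LogRankResult(chi2=chi2, df=1, pvalue=float(res.p_value))
    rng = stream_rng(0 if seed is None else seed, "logrank-perm")
    pooled_t = np.concatenate([ta, tb])
    pooled_e = np.concatenate([ea, eb])
    n_a = ta.size
    hits = 0
    for _ in range(int(permutation)):
        idx = rng.permutation(pooled_t.size)
        pa, pb = idx[:n_a], idx[n_a:]
        if pooled_e[pa].sum() + pooled_e[pb].sum() == 0:
            stat = 0.0
        else:
            stat = float(
                _ll_logrank(
                    pooled_t[pa], pooled_t[pb],
                    event_observed_A=pooled_e[pa], event_observed_B=pooled_e[pb],
                ).test_statistic
            )
        hits += stat >= chi2
    return LogRankResult(chi2=chi2, df=1, pvalue=(1 + hits) / (int(permutation) + 1))


def incidence_at(
    cohort: pd.DataFrame, genotype: str, t: float, method: str = "crude"
) -> IncidenceEstimate:
    """Lesion incidence of one genotype by day ``t``.

    ``crude`` counts lesion events by ``t`` over subjects either lesioned by
    ``t`` or still under observation at ``t`` (subjects censored lesion-free
    before ``t`` drop out of both numerator and denominator).
    ``km_complement`` is ``1 - S_KM(t)`` of the lesion-free survival curve and
    uses every subject of the genotype.
    """
    if method not in ("crude", "km_complement"):
        raise ValueError(f"unknown method {method!r}")
    sub = cohort[cohort["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"no subjects of genotype {genotype!r}")
    times = sub["lesion_time"].to_numpy(dtype=float)
    events = sub["lesion_event"].to_numpy(dtype=int)
    if method == "crude":
        lesioned = (events == 1) & (times <= t)
        eligible = lesioned | (times >= t)
        n = int(eligible.sum())
        if n == 0:
            raise ValueError(
                f"no eligible {genotype} subjects at day {t}: all censored earlier"
            )
        p = float(lesioned.sum() / n)
    else:
        curve = km_estimate(times, events)
        p = 1.0 - curve.survival_at(t)
        n = int(len(sub))
    return IncidenceEstimate(horizon=t, genotype=genotype, incidence=p, n=n, method=method)


def percent_reduction(reference_median: float, test_median: float) -> float:
    """Percent reduction of ``test`` relative to ``reference``, one decimal."""
    if reference_median <= 0:
        raise ValueError("reference median must be positive")
    return round(100.0 * (reference_median - test_median) / reference_median, 1)
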