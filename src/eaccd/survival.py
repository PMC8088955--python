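"""Censoring-aware survival primitives.

Everything downstream reduces to four estimators:

* the Kaplan-Meier product-limit curve of a cohort,
* the reverse Kaplan-Meier median follow-up (censoring as the event),
* the Mann-Whitney parameter theta = P(T_i < T_j) between two cohorts,
  estimated by plugging Kaplan-Meier curves into
  ``theta = sum_t dF_i(t) [S_j(t) + dF_j(t)/2]`` with a half-mass split of
  the probability both curves carry beyond the shorter follow-up, and
* Harrell's concordance index for a risk score against censored outcomes.

The Mann-Whitney estimate of one cohort against another, mapped through
``d = 2 |theta - 1/2|``, is the initial dissimilarity the clustering
consumes: d = 0 when survival in the two cohorts is indistinguishable and
d = 1 when one cohort stochastically dominates completely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``times`` are the distinct event times; ``survival[k]`` is the
    right-continuous value of S just after ``times[k]``.  ``last_observed``
    is the largest observed time (event or censored), beyond which the
    curve is undefined and held at its last value by convention.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int
    last_observed: float

    def surv_at(self, t: float) -> float:
        """S(t) by the right-continuous step convention; S(t)=1 before the
        first event; times beyond follow-up return the last step value."""
        if t < 0:
            raise ValueError("t must be >= 0")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def increments(self) -> np.ndarray:
        """Probability mass dF at each event time (drop of the curve)."""
        prev = np.concatenate(([1.0], self.survival[:-1]))
        return prev - self.survival

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time": self.times,
            "survival": self.survival,
            "at_risk": self.at_risk,
            "n_events": self.n_events,
        })


@dataclass(frozen=True)
class MWEstimate:
    """Symmetrized Mann-Whitney parameter estimate between two cohorts.

    ``theta`` estimates P(a survival time drawn from cohort i is shorter
    than one from cohort j); 1/2 when the distributions coincide.
    ``tau`` is the shorter of the two follow-up horizons; ``tail_mass_*``
    the Kaplan-Meier mass each cohort carries beyond it.
    """

    theta: float
    tau: float
    tail_mass_i: float
    tail_mass_j: float


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be equal-length 1-d sequences")
    if t.size == 0:
        raise ValueError("empty cohort")
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimate; ties of censorings with an event time are
    counted as still at risk at that time (events before censorings)."""
    t, e = _as_arrays(times, events)
    n = t.size
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ut, start = np.unique(t, return_index=True)
    # per distinct time: events and total leaving
    d = np.add.reduceat(e, start)
    leaving = np.add.reduceat(np.ones_like(e), start)
    at_risk = n - np.concatenate(([0], np.cumsum(leaving)[:-1]))
    mask = d > 0
    ev_t, ev_d, ev_r = ut[mask], d[mask], at_risk[mask]
    surv = np.cumprod(1.0 - ev_d / ev_r)
    return KMCurve(times=ev_t, survival=surv, at_risk=ev_r, n_events=ev_d,
                   n=n, last_observed=float(t[-1]))


def survival_rate_at(curve: KMCurve, t: float) -> float:
    """S(t) from a fitted curve (right-continuous step evaluation)."""
    return curve.surv_at(t)


def reverse_km_median_followup(times, events) -> float | None:
    """Median follow-up: Kaplan-Meier with censoring treated as the event.

    Returns the smallest time at which the reverse curve falls strictly
    below 1/2, or None when the curve never does (no censoring mass).
    """
    t, e = _as_arrays(times, events)
    rev = km_estimate(t, 1 - e)
    below = rev.survival < 0.5
    if not below.any():
        return None
    return float(rev.times[int(np.argmax(below))])


def _mw_raw(km_i: KMCurve, km_j: KMCurve) -> tuple[float, float, float, float]:
    """One-directional plug-in estimate of P(T_i < T_j), truncated at the
    shorter follow-up tau with the joint tail mass split half/half."""
    tau = min(km_i.last_observed, km_j.last_observed)
    inc_i = km_i.increments()
    use = km_i.times <= tau
    t_use = km_i.times[use]
    di = inc_i[use]
    # S_j(t) and dF_j(t) on cohort i's event grid
    dj = np.zeros_like(t_use)
    if km_j.times.size:
        idx = np.searchsorted(km_j.times, t_use, side="right") - 1
        sj = np.where(idx >= 0, km_j.survival[np.maximum(idx, 0)], 1.0)
        pos = np.searchsorted(km_j.times, t_use)
        hit = (pos < km_j.times.size) & np.isclose(
            km_j.times[np.minimum(pos, km_j.times.size - 1)], t_use)
        dj[hit] = km_j.increments()[pos[hit]]
    else:
        sj = np.ones_like(t_use)
    tail_i = km_i.surv_at(tau)
    tail_j = km_j.surv_at(tau)
    theta = float(np.sum(di * (sj + 0.5 * dj)) + 0.5 * tail_i * tail_j)
    return theta, tau, tail_i, tail_j


def mann_whitney_parameter(times_i, events_i, times_j, events_j) -> MWEstimate:
    """Estimate theta = P(T_i < T_j) from two censored cohorts.

    Kaplan-Meier plug-in with half-credit for ties, truncated at the
    shorter follow-up with a half/half split of the joint tail mass, then
    symmetrized by averaging the two directions so that
    ``theta(i,j) + theta(j,i) = 1`` holds exactly.  On fully uncensored
    data this reduces to the classical U/(nm) count with ties at 1/2.
    """
    t_i, e_i = _as_arrays(times_i, events_i)
    t_j, e_j = _as_arrays(times_j, events_j)
    if not e_i.any() or not e_j.any():
        logger.warning("Mann-Whitney estimate from a cohort with zero events; "
                       "all its mass sits in the tail beyond follow-up")
    km_i = km_estimate(t_i, e_i)
    km_j = km_estimate(t_j, e_j)
    th_ij, tau, tail_i, tail_j = _mw_raw(km_i, km_j)
    th_ji, _, _, _ = _mw_raw(km_j, km_i)
    theta = 0.5 * (th_ij + 1.0 - th_ji)
    return MWEstimate(theta=float(theta), tau=float(tau),
                      tail_mass_i=float(tail_i), tail_mass_j=float(tail_j))


def initial_dissimilarity(theta: float) -> float:
    """Map theta in [0,1] to a dissimilarity: d = 2|theta - 1/2| in [0,1]."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    return 2.0 * abs(theta - 0.5)


def harrell_c_index(risk_scores, times, events) -> float:
    """Harrell's concordance index.

    A pair is permissible when the earlier time is an observed death (or
    the times tie and exactly one is censored); it scores 1 when the
    patient with the higher risk score died earlier, 1/2 on tied scores.
    Invariant under strictly monotone transforms of the score.
    """
    s = np.asarray(risk_scores, dtype=float)
    t, e = _as_arrays(times, events)
    if s.shape != t.shape:
        raise ValueError("risk_scores must match times in length")
    conc, tied, perm = _concordance_counts(s, t, e)
    if perm == 0:
        raise ValueError("no permissible pairs")
    return (conc + 0.5 * tied) / perm


def _concordance_counts(scores: np.ndarray, t: np.ndarray, e: np.ndarray
                        ) -> tuple[float, float, float]:
    """(concordant, score-tied, permissible) pair counts.

    Counting implementation: walk distinct times in decreasing order,
    keeping a histogram of risk scores of patients with strictly later
    times; each death at time t pairs with that pool plus the patients
    censored at t itself.  Runs in O(n_times * n_distinct_scores).
    """
    codes = np.unique(scores, return_inverse=True)[1]
    n_codes = int(codes.max()) + 1
    order = np.argsort(t, kind="stable")
    t, e, codes = t[order], e[order], codes[order]
    ut, start = np.unique(t, return_index=True)
    bounds = np.append(start, t.size)
    later = np.zeros(n_codes, dtype=np.int64)
    conc = tied = perm = 0.0
    for k in range(ut.size - 1, -1, -1):
        sl = slice(bounds[k], bounds[k + 1])
        ev = e[sl] == 1
        ev_codes = codes[sl][ev]
        cens_codes = codes[sl][~ev]
        pool = later.copy()
        np.add.at(pool, cens_codes, 1)
        total = pool.sum()
        if ev_codes.size and total:
            cum = np.cumsum(pool)
            below = np.where(ev_codes > 0, cum[ev_codes - 1], 0)
            conc += float(below.sum())
            tied += float(pool[ev_codes].sum())
            perm += float(total) * ev_codes.size
        np.add.at(later, codes[sl], 1)
    return conc, tied, perm
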