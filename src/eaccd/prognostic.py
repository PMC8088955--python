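"""From a dendrogram to an ordered prognostic system.

Cutting the dendrogram at k clusters induces a k-group patient
stratification; its predictive value is the Harrell concordance of the
group number (ordered by decreasing five-year Kaplan-Meier survival) as a
risk score.  The concordance-vs-k curve rises steeply while cuts still
separate genuinely different survival and flattens once they only split
noise; the "knee" of that curve fixes the working number of groups n*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import Dendrogram
from .records import CombinationCohort, FACTORS, cases_to_frame
from .survival import KMCurve, _concordance_counts, km_estimate, survival_rate_at

logger = logging.getLogger(__name__)

FIVE_YEAR_MONTHS = 60.0


@dataclass(frozen=True)
class CIndexCurve:
    """Concordance index per candidate number of prognostic groups."""

    ks: np.ndarray
    c_values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_groups": self.ks, "c_index": self.c_values})


@dataclass
class PrognosticSystem:
    """Ordered group assignment of cohorts plus per-group survival summaries.

    Groups are numbered 1..n_groups by decreasing five-year survival, so
    risk increases with the group number.
    """

    n_groups: int
    assignment: Mapping[str, int]        # cohort label -> group number (1-based)
    group_curves: list[KMCurve]
    five_year_rates: np.ndarray
    group_sizes: np.ndarray
    c_index: float

    def to_json_dict(self) -> dict:
        return {
            "n_groups": int(self.n_groups),
            "assignment": {k: int(v) for k, v in sorted(self.assignment.items())},
            "five_year_rates": [float(x) for x in self.five_year_rates],
            "group_sizes": [int(x) for x in self.group_sizes],
            "c_index": float(self.c_index),
        }

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": np.arange(1, self.n_groups + 1),
            "n_patients": self.group_sizes,
            "five_year_rate": self.five_year_rates,
        })


def _patient_arrays(cohorts: Sequence[CombinationCohort]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenated times/events plus the cohort index of every patient."""
    times = np.concatenate([c.times for c in cohorts])
    events = np.concatenate([c.events for c in cohorts])
    idx = np.concatenate([np.full(c.size, i) for i, c in enumerate(cohorts)])
    return times, events, idx


def _ordered_groups(clusters: list[dict], cohorts: Sequence[CombinationCohort],
                    five_year_month: float) -> list[dict]:
    """Order cut clusters by decreasing five-year survival (ties: larger
    patient count first, then smallest member index); attach rates."""
    enriched = []
    for cl in clusters:
        t = np.concatenate([cohorts[i].times for i in cl["members"]])
        e = np.concatenate([cohorts[i].events for i in cl["members"]])
        curve = km_estimate(t, e)
        rate = survival_rate_at(curve, five_year_month)
        enriched.append({**cl, "curve": curve, "rate": rate, "n_patients": t.size})
    order = sorted(range(len(enriched)),
                   key=lambda i: (-enriched[i]["rate"], -enriched[i]["n_patients"],
                                  enriched[i]["members"][0]))
    ranked = [enriched[i] for i in order]
    for g, cl in enumerate(ranked, start=1):
        cl["group"] = g
    return ranked


def _system_c_index(ranked: list[dict], cohorts: Sequence[CombinationCohort]
                    ) -> float:
    times, events, coh_idx = _patient_arrays(cohorts)
    group_of_cohort = np.empty(len(cohorts), dtype=float)
    for cl in ranked:
        group_of_cohort[cl["members"]] = cl["group"]
    scores = group_of_cohort[coh_idx]
    conc, tied, perm = _concordance_counts(scores, times, events.astype(int))
    if perm == 0:
        raise ValueError("no permissible pairs")
    return (conc + 0.5 * tied) / perm


def c_index_curve(dend: Dendrogram, cohorts: Sequence[CombinationCohort],
                  k_range: Sequence[int] | None = None,
                  five_year_month: float = FIVE_YEAR_MONTHS) -> CIndexCurve:
    """Concordance of the cut-induced grouping for each candidate k."""
    n = dend.n_leaves
    if k_range is None:
        k_range = range(1, n + 1)
    ks = np.asarray(sorted(k_range), dtype=int)
    if ks[0] < 1 or ks[-1] > n:
        raise ValueError(f"k_range must lie within [1, {n}]")
    cs = np.empty(ks.size)
    for i, k in enumerate(ks):
        ranked = _ordered_groups(dend.cut(int(k)), cohorts, five_year_month)
        cs[i] = _system_c_index(ranked, cohorts)
    return CIndexCurve(ks=ks, c_values=cs)


def knee_point(curve: CIndexCurve, rel_gain: float = 0.05) -> int:
    """Smallest k beyond which every marginal concordance gain is negligible.

    A gain is negligible when it is below ``rel_gain`` times the total span
    of the curve.  A flat curve (zero span) returns the smallest k with a
    warning; a curve that keeps gaining to the end returns the largest k.
    """
    if curve.ks.size < 3:
        raise ValueError("need at least 3 curve points")
    span = float(curve.c_values.max() - curve.c_values.min())
    if span <= 0.0:
        logger.warning("flat concordance curve; knee defaults to smallest k")
        return int(curve.ks[0])
    gains = np.diff(curve.c_values)
    small = gains < rel_gain * span
    # smallest k such that all subsequent gains are below threshold
    for i in range(curve.ks.size):
        if small[i:].all():
            if i == curve.ks.size - 1:
                logger.warning("no knee found; returning largest k")
            return int(curve.ks[i])
    return int(curve.ks[-1])


def build_system(dend: Dendrogram, cohorts: Sequence[CombinationCohort],
                 n_groups: int,
                 five_year_month: float = FIVE_YEAR_MONTHS) -> PrognosticSystem:
    """Cut into ``n_groups`` risk-ordered groups with survival summaries."""
    ranked = _ordered_groups(dend.cut(n_groups), cohorts, five_year_month)
    assignment = {}
    for cl in ranked:
        for i in cl["members"]:
            assignment[cohorts[i].label] = cl["group"]
    rates = np.array([cl["rate"] for cl in ranked])
    if ranked and (np.diff(rates) > 0).any():
        logger.info("five-year rates not strictly decreasing across groups "
                    "(ties broken by size)")
    return PrognosticSystem(
        n_groups=n_groups,
        assignment=assignment,
        group_curves=[cl["curve"] for cl in ranked],
        five_year_rates=rates,
        group_sizes=np.array([cl["n_patients"] for cl in ranked]),
        c_index=_system_c_index(ranked, cohorts),
    )


def risk_category_distribution(system: PrognosticSystem, cases,
                               split: tuple[Sequence[int], Sequence[int]],
                               active_factors: Sequence[str] | None = None
                               ) -> pd.DataFrame:
    """Share of each factor level's patients in the low/high risk category.

    ``split`` partitions the group numbers 1..n_groups into a low-risk and
    a high-risk set.  Returns a frame with one row per (factor, level) and
    columns ``p_low``/``p_high`` summing to 1 within each row.
    """
    low, high = set(split[0]), set(split[1])
    if low & high or low | high != set(range(1, system.n_groups + 1)):
        raise ValueError("split must partition groups 1..n_groups")
    df = cases_to_frame(cases).copy()
    factors = list(active_factors) if active_factors is not None else [
        f for f in FACTORS if f in df.columns]
    label_cols = [f for f in FACTORS if f in df.columns]
    # recover which factor subset the system was built on by matching the
    # concatenated level labels against the assignment keys
    from .records import combination_label

    built_factors = None
    for cand in _candidate_factor_sets(label_cols):
        lab = combination_label({f: df.iloc[0][f] for f in cand}, cand)
        if lab in system.assignment:
            built_factors = cand
            break
    if built_factors is None:
        raise ValueError("cases do not match the system's combination labels")
    labels = df[built_factors].agg("".join, axis=1)
    groups = labels.map(system.assignment)
    if groups.isna().any():
        missing = sorted(labels[groups.isna()].unique())[:5]
        raise ValueError(f"cases outside the system's cohorts: {missing}")
    df["_risk_high"] = groups.isin(high)
    rows = []
    for f in factors:
        if f not in df.columns:
            continue
        for level, sub in df.groupby(f, sort=True):
            if sub.empty:
                logger.warning("factor %s level %s absent; omitted", f, level)
                continue
            p_high = float(sub["_risk_high"].mean())
            rows.append({"factor": f, "level": level,
                         "p_low": 1.0 - p_high, "p_high": p_high})
    return pd.DataFrame(rows)


def _candidate_factor_sets(available: list[str]) -> list[list[str]]:
    """Factor subsets to try when matching cases to cohort labels, largest
    first, in canonical factor order."""
    from itertools import combinations

    out = []
    for r in range(len(available), 0, -1):
        out.extend([list(c) for c in combinations(available, r)])
    return out
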