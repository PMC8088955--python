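"""Registry-like synthetic case listings with known ground truth.

The generator emulates the structure of a cancer-registry case listing:
many factor-level combinations of unequal size, cohort-structured
proportional-hazards survival, administrative right-censoring from a
uniform accrual window, and follow-up recorded in whole months.  Survival
within a combination is exponential with hazard
``lambda(c) = lambda0 * exp(eta(c))`` where ``eta(c)`` is either the sum of
per-level log-hazard effects or, when a planted-group structure is
requested, the log-hazard of the combination's group.  The exponential
family is the default because it gives closed-form oracles — e.g.
``P(T_i < T_j) = lambda_i / (lambda_i + lambda_j)`` for two cohorts —
against which the downstream estimators are tested; a Weibull shape
parameter is accepted for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import FACTOR_LEVELS, combination_label


@dataclass(frozen=True)
class PlantedGroups:
    """Known prognostic-group structure: each combination belongs to one of
    ``k_true`` groups and draws survival from its group's log hazard."""

    k_true: int
    group_log_hazards: tuple[float, ...]
    assignment: Mapping[str, int]  # combination label -> group index 0..k_true-1

    def __post_init__(self) -> None:
        if len(self.group_log_hazards) != self.k_true:
            raise ValueError("group_log_hazards must have k_true entries")
        if any(not 0 <= g < self.k_true for g in self.assignment.values()):
            raise ValueError("group indices out of range")


@dataclass
class SimulationConfig:
    """Study-condition bundle for one synthetic case listing.

    ``combination_sizes`` is either one integer (all cohorts equal) or a
    ``(lo, hi)`` range sampled per combination.  ``censoring_window_months``
    is the administrative-censoring window; the default (60, 96) reflects a
    diagnosis-window cohort with a guaranteed five-year minimum follow-up
    and up to eight years of it.  ``weibull_shape`` = 1 keeps the
    exponential default.
    """

    active_factors: tuple[str, ...] = ("T", "N", "M")
    combinations: tuple[str, ...] | None = None  # default: full level cross
    combination_sizes: int | tuple[int, int] = 200
    effects: Mapping[str, float] = field(default_factory=dict)  # level -> log-hazard
    baseline_hazard: float = 0.02  # events per month
    planted_groups: PlantedGroups | None = None
    censoring_window_months: tuple[float, float] = (60.0, 96.0)
    weibull_shape: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        lo, hi = self.censoring_window_months
        if not 0 < lo <= hi:
            raise ValueError("censoring window must satisfy 0 < lo <= hi")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")
        if isinstance(self.combination_sizes, tuple):
            lo, hi = self.combination_sizes
            if not 1 <= lo <= hi:
                raise ValueError("combination size range must satisfy 1 <= lo <= hi")
        elif self.combination_sizes < 1:
            raise ValueError("combination size must be >= 1")
        for f in self.active_factors:
            if f not in FACTOR_LEVELS:
                raise ValueError(f"unknown factor {f!r}")

    def combination_levels(self) -> list[dict[str, str]]:
        """Level mapping of every combination, in lexicographic level order."""
        factors = list(self.active_factors)
        all_levels = [
            dict(zip(factors, combo))
            for combo in product(*(FACTOR_LEVELS[f] for f in factors))
        ]
        if self.combinations is None:
            return all_levels
        by_label = {combination_label(lv, factors): lv for lv in all_levels}
        try:
            return [by_label[lab] for lab in self.combinations]
        except KeyError as exc:
            raise ValueError(f"unknown combination label {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class GroundTruth:
    """Per-combination generating hazards and (optional) planted groups."""

    hazards: Mapping[str, float]          # label -> lambda(c)
    group_of: Mapping[str, int] | None    # label -> planted group index
    config: SimulationConfig


# default filler levels for factors outside active_factors
_FILL = {"T": "T1a", "N": "N0", "M": "M0", "A": "A0", "H": "H1"}


def generate_cases(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one synthetic case listing; deterministic given ``config.seed``.

    Observed time = floor(min(survival, censoring)) months;
    event = 1 iff survival <= censoring.
    """
    rng = np.random.default_rng(config.seed)
    factors = list(config.active_factors)
    combos = config.combination_levels()
    labels = [combination_label(lv, factors) for lv in combos]
    if config.planted_groups is not None:
        missing = [lab for lab in labels if lab not in config.planted_groups.assignment]
        if missing:
            raise ValueError(
                f"planted-group assignment missing combination(s): {missing[:5]}")

    hazards: dict[str, float] = {}
    group_of: dict[str, int] | None = (
        {} if config.planted_groups is not None else None)
    rows: list[pd.DataFrame] = []
    c_lo, c_hi = config.censoring_window_months
    for lv, lab in zip(combos, labels):
        if config.planted_groups is not None:
            g = config.planted_groups.assignment[lab]
            eta = config.planted_groups.group_log_hazards[g]
            group_of[lab] = g  # type: ignore[index]
        else:
            eta = sum(config.effects.get(level, 0.0) for level in lv.values())
        lam = config.baseline_hazard * np.exp(eta)
        hazards[lab] = lam
        if isinstance(config.combination_sizes, tuple):
            size = int(rng.integers(config.combination_sizes[0],
                                    config.combination_sizes[1] + 1))
        else:
            size = int(config.combination_sizes)
        # Weibull with shape a and scale s: S(t) = exp(-(t/s)^a); a=1 -> exponential
        scale = 1.0 / lam
        surv = scale * rng.weibull(config.weibull_shape, size=size)
        cens = rng.uniform(c_lo, c_hi, size=size)
        observed = np.floor(np.minimum(surv, cens)).astype(int)
        event = (surv <= cens).astype(int)
        full = {**_FILL, **lv}
        rows.append(pd.DataFrame({
            "case_id": [f"{lab}-{i}" for i in range(size)],
            "T": full["T"], "N": full["N"], "M": full["M"],
            "A": full["A"], "H": full["H"],
            "survival_months": observed,
            "event": event,
        }))
    frame = pd.concat(rows, ignore_index=True)
    return frame, GroundTruth(hazards=hazards, group_of=group_of, config=config)


def planted_tiers_config(
    n_combinations: int = 30,
    k_true: int = 3,
    hazard_ratio: float = 3.0,
    baseline_hazard: float = 0.01,
    cohort_size: int | tuple[int, int] = 500,
    censoring_window_months: tuple[float, float] = (60.0, 96.0),
    active_factors: tuple[str, ...] = ("T", "N", "M"),
    seed: int | None = None,
) -> SimulationConfig:
    """Convenience config: ``n_combinations`` cohorts in ``k_true`` planted
    hazard tiers with a constant hazard ratio between adjacent tiers.

    Combinations are the first ``n_combinations`` of the active-factor level
    cross; tiers are contiguous blocks of roughly equal size.
    """
    base = SimulationConfig(active_factors=active_factors)
    all_labels = [combination_label(lv, list(active_factors))
                  for lv in base.combination_levels()]
    if n_combinations > len(all_labels):
        raise ValueError(
            f"at most {len(all_labels)} combinations available for {active_factors}")
    labels = tuple(all_labels[:n_combinations])
    assignment = {lab: (i * k_true) // n_combinations for i, lab in enumerate(labels)}
    log_hr = float(np.log(hazard_ratio))
    planted = PlantedGroups(
        k_true=k_true,
        group_log_hazards=tuple(g * log_hr for g in range(k_true)),
        assignment=assignment,
    )
    return SimulationConfig(
        active_factors=active_factors,
        combinations=labels,
        combination_sizes=cohort_size,
        baseline_hazard=baseline_hazard,
        planted_groups=planted,
        censoring_window_months=censoring_window_months,
        seed=seed,
    )


def truth_to_json(truth: GroundTruth) -> dict:
    """JSON-serializable ground-truth record (hazards + planted groups)."""
    return {
        "hazards": {k: float(v) for k, v in truth.hazards.items()},
        "groups": None if truth.group_of is None
        else {k: int(v) for k, v in truth.group_of.items()},
    }
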