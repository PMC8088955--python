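"""Model/Results interface wrapping the full pipeline.

``EACCDModel`` holds the case listing and the study design (active factors,
minimum cohort size); ``fit`` runs initial dissimilarities -> ensemble
learning -> minimax dendrogram -> concordance curve -> knee cut and returns
an ``EACCDResults`` carrying the fitted prognostic system, its diagnostics
and comparison/plotting helpers.

>>> from eaccd import EACCDModel
>>> from eaccd.simulate import generate_cases, planted_tiers_config
>>> cases, truth = generate_cases(planted_tiers_config(seed=7))
>>> res = EACCDModel(cases, active_factors=("T", "N", "M"), min_cases=50).fit(
...     runs=200, seed=7)
>>> res.n_groups_, round(res.c_index_, 3)  # doctest: +SKIP
(3, 0.697)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cluster, compare, prognostic, records
from .cluster import Dendrogram, DissimilarityMatrix, EnsembleConfig
from .prognostic import CIndexCurve, PrognosticSystem
from .records import CombinationCohort


class EACCDModel:
    """Consensus-clustering prognostic-group model of a censored cohort.

    Parameters
    ----------
    cases
        Case listing: DataFrame with columns case_id, T, N, M, A, H,
        survival_months, event — or a list of :class:`~eaccd.records.CaseRecord`.
    active_factors
        Ordered subset of ``("T", "N", "M", "A", "H")`` defining the
        combinations to stratify on.
    min_cases
        Minimum cohort size; smaller combinations are excluded before any
        estimation.
    five_year_month
        Horizon (months) of the survival rate used to order groups.
    """

    def __init__(self, cases, active_factors: Sequence[str] = ("T", "N", "M"),
                 min_cases: int = 50, five_year_month: float = 60.0):
        self.data = records.cases_to_frame(cases)
        self.active_factors = tuple(active_factors)
        self.min_cases = int(min_cases)
        self.five_year_month = float(five_year_month)
        all_cohorts = records.group_into_combinations(self.data, self.active_factors)
        self.cohorts: list[CombinationCohort] = records.filter_min_cases(
            all_cohorts, self.min_cases)
        self.n_excluded_cohorts = len(all_cohorts) - len(self.cohorts)
        if len(self.cohorts) < 2:
            raise ValueError(
                f"only {len(self.cohorts)} cohort(s) have >= {self.min_cases} "
                "cases; lower min_cases or supply more data")

    @classmethod
    def from_csv(cls, path, dialect: str = "recoded8", **kwargs) -> "EACCDModel":
        cases, _ = records.read_cases(path, dialect=dialect)
        return cls(cases, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "EACCDModel":
        return cls(df, **kwargs)

    def fit(self, runs: int = 1000, k_range: tuple[int, int] | None = None,
            n_groups: int | None = None, knee_rel_gain: float = 0.05,
            curve_ks: Sequence[int] | None = None,
            seed: int | None = None) -> "EACCDResults":
        """Run the pipeline and return the fitted results.

        ``n_groups`` overrides the knee rule; ``runs``/``k_range`` control
        the ensemble; ``seed`` fixes all randomness (the clustering itself
        is deterministic, the seed only drives the per-run k draws).
        """
        n = len(self.cohorts)
        initial = cluster.build_initial_matrix(self.cohorts)
        cfg = EnsembleConfig(runs=runs, k_range=k_range, seed=seed)
        learned = cluster.ensemble_learn(initial, cfg)
        dend = cluster.minimax_linkage(learned)
        if curve_ks is None:
            curve_ks = range(1, min(n, 25) + 1)
        curve = prognostic.c_index_curve(dend, self.cohorts, k_range=curve_ks,
                                         five_year_month=self.five_year_month)
        n_star = int(n_groups) if n_groups is not None else prognostic.knee_point(
            curve, rel_gain=knee_rel_gain)
        system = prognostic.build_system(dend, self.cohorts, n_star,
                                         five_year_month=self.five_year_month)
        return EACCDResults(model=self, initial_dissimilarity_=initial,
                            learned_dissimilarity_=learned, dendrogram_=dend,
                            cindex_curve_=curve, system_=system,
                            ensemble_config=cfg, seed=seed)


@dataclass
class EACCDResults:
    """Fitted prognostic system with diagnostics.

    Attributes ending in ``_`` are estimated: the initial and learned
    dissimilarity matrices, the dendrogram, the concordance curve and the
    final :class:`~eaccd.prognostic.PrognosticSystem`.
    """

    model: EACCDModel
    initial_dissimilarity_: DissimilarityMatrix
    learned_dissimilarity_: DissimilarityMatrix
    dendrogram_: Dendrogram
    cindex_curve_: CIndexCurve
    system_: PrognosticSystem
    ensemble_config: EnsembleConfig
    seed: int | None = None

    @property
    def n_groups_(self) -> int:
        return self.system_.n_groups

    @property
    def c_index_(self) -> float:
        return self.system_.c_index

    @property
    def assignment_(self) -> Mapping[str, int]:
        return self.system_.assignment

    def summary(self) -> str:
        """Plain-text fit report: design, groups, survival, concordance."""
        m = self.model
        lines = [
            "Consensus-clustering prognostic system",
            "=" * 54,
            f"Factors: {{{', '.join(m.active_factors)}}}"
            f"    cohorts: {len(m.cohorts)} (min size {m.min_cases}, "
            f"{m.n_excluded_cohorts} excluded)",
            f"Patients: {sum(c.size for c in m.cohorts)}"
            f"    ensemble runs: {self.ensemble_config.runs}"
            f"    seed: {self.seed}",
            f"Groups: {self.n_groups_}    C-index: {self.c_index_:.4f}",
            "-" * 54,
            f"{'group':>5} {'patients':>9} {'cohorts':>8} "
            f"{str(int(m.five_year_month)) + '-mo rate':>11}",
        ]
        counts = pd.Series(self.system_.assignment).value_counts()
        for g in range(1, self.n_groups_ + 1):
            lines.append(
                f"{g:>5} {int(self.system_.group_sizes[g - 1]):>9} "
                f"{int(counts.get(g, 0)):>8} "
                f"{self.system_.five_year_rates[g - 1]:>10.1%}")
        return "\n".join(lines)

    def patient_groups(self) -> pd.Series:
        """Group number of every patient, aligned with the model's cases."""
        labels = self.model.data[list(self.model.active_factors)].agg("".join, axis=1)
        return labels.map(self.system_.assignment)

    def compare_with_ajcc(self) -> dict:
        """Contrast this system with AJCC 8th-edition staging on the same
        patients: contingency table, rank correlation, paired C test."""
        df = self.model.data
        groups = self.patient_groups()
        keep = groups.notna()
        df = df[keep]
        groups = groups[keep].astype(int)
        stages = [compare.assign_ajcc8_stage(t, n, m)
                  for t, n, m in zip(df["T"], df["N"], df["M"])]
        stage_rank = pd.Series(stages).map(
            {s: i + 1 for i, s in enumerate(compare.AJCC8_STAGES)})
        table = compare.contingency(
            stages, groups,
            col_labels=sorted(groups.unique()))
        rho = compare.spearman_from_contingency(table)
        test = compare.c_index_difference_test(
            groups.to_numpy(float), stage_rank.to_numpy(float),
            df["survival_months"].to_numpy(float), df["event"].to_numpy(int))
        return {"table": table, "rho": rho, "test": test}

    def to_json(self) -> str:
        """Canonical JSON of the fitted system (deterministic given seed)."""
        payload = {
            "active_factors": list(self.model.active_factors),
            "min_cases": self.model.min_cases,
            "ensemble_runs": self.ensemble_config.runs,
            "seed": self.seed,
            "cindex_curve": {
                "ks": [int(k) for k in self.cindex_curve_.ks],
                "c": [round(float(c), 12) for c in self.cindex_curve_.c_values],
            },
            "system": self.system_.to_json_dict(),
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    # ---- plotting -------------------------------------------------------
    def plot_cindex_curve(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.plot(self.cindex_curve_.ks, self.cindex_curve_.c_values, "o-")
        ax.axvline(self.n_groups_, ls="--", c="grey")
        ax.set_xlabel("number of prognostic groups")
        ax.set_ylabel("C-index")
        return ax

    def plot_group_survival(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        for g, curve in enumerate(self.system_.group_curves, start=1):
            ax.step(np.concatenate(([0.0], curve.times)),
                    np.concatenate(([1.0], curve.survival)),
                    where="post", label=f"group {g}")
        ax.set_xlabel("months")
        ax.set_ylabel("cancer-specific survival")
        ax.legend(fontsize="small")
        return ax

    def plot_dendrogram(self, ax=None):
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

        ax = ax or plt.gca()
        Z = self.dendrogram_.to_linkage_matrix()
        # scipy requires monotone heights for plotting only; clip inversions
        Z[:, 2] = np.maximum.accumulate(Z[:, 2])
        scipy_dendrogram(Z, labels=self.dendrogram_.labels, ax=ax,
                         leaf_rotation=90)
        return ax
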