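"""Comparison of a prognostic grouping against AJCC 8th-edition staging.

Two axes of comparison:

* *stratification* — cross-tabulate patients by stage and by group and
  measure the association with Spearman's rank correlation, computed with
  midranks directly from the contingency counts (ties within a stage or a
  group share the average rank);
* *prediction* — compare the Harrell concordance of the two patient
  orderings on the same cohort with a paired test: the difference of the
  two concordance U-statistic ratios, its leave-one-subject-out jackknife
  standard error, a normal 95% CI and a two-sided p-value.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .survival import _as_arrays

AJCC8_STAGES = ("IA1", "IA2", "IA3", "IB", "IIA", "IIB", "IIIA", "IIIB", "IIIC", "IV")


@lru_cache(maxsize=1)
def _stage_lookup() -> dict[tuple[str, str], str]:
    src = importlib.resources.files("eaccd.data").joinpath("ajcc8_lung_stages.csv")
    with src.open() as fh:
        df = pd.read_csv(fh, comment="#")
    return {(r.T, r.N): r.stage for r in df.itertuples(index=False)}


def assign_ajcc8_stage(t: str, n: str, m: str) -> str:
    """Stage of an (8th-edition T, N, M) triple; any M1 is stage IV."""
    if m == "M1":
        return "IV"
    if m != "M0":
        raise ValueError(f"invalid M level {m!r}")
    try:
        return _stage_lookup()[(t, n)]
    except KeyError:
        raise ValueError(f"no stage for T={t!r}, N={n!r}") from None


@dataclass
class ContingencyTable:
    """Patient counts cross-tabulated by ordered row/column categories."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = c.astype(np.int64)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, margins: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)
        if margins:
            df["Total"] = self.row_totals
            df.loc["Total"] = np.append(self.col_totals, self.grand_total)
        return df


def contingency(stage_per_patient, group_per_patient,
                row_labels=None, col_labels=None) -> ContingencyTable:
    """Cross-tabulate two equal-length categorical patient vectors."""
    stages = pd.Series(stage_per_patient)
    groups = pd.Series(group_per_patient)
    if len(stages) != len(groups):
        raise ValueError("vectors must have equal length")
    if row_labels is None:
        row_labels = [s for s in AJCC8_STAGES if s in set(stages)] \
            if set(stages) <= set(AJCC8_STAGES) else sorted(set(stages))
    if col_labels is None:
        col_labels = sorted(set(groups))
    ri = {lab: i for i, lab in enumerate(row_labels)}
    ci = {lab: i for i, lab in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    np.add.at(counts, (stages.map(ri).to_numpy(), groups.map(ci).to_numpy()), 1)
    return ContingencyTable(row_labels=[str(r) for r in row_labels],
                            col_labels=[str(c) for c in col_labels], counts=counts)


def _midranks(totals: np.ndarray) -> np.ndarray:
    cum = np.cumsum(totals)
    return cum - totals + (totals + 1) / 2.0


def spearman_from_contingency(table: ContingencyTable) -> float:
    """Spearman's rho of the two patient-level ordinal assignments.

    Every patient in row r (column c) receives the midrank of that
    category; rho is the Pearson correlation of the midranks, computed
    from the counts without expanding to patient level.  Identical to
    ``scipy.stats.spearmanr`` on the expanded vectors.
    """
    counts = table.counts
    n = table.grand_total
    if n < 2:
        raise ValueError("need at least 2 patients")
    rt, ct = table.row_totals, table.col_totals
    if (rt > 0).sum() < 2 or (ct > 0).sum() < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    rr, cr = _midranks(rt), _midranks(ct)
    w = counts / n
    mr = float((w.sum(axis=1) * rr).sum())
    mc = float((w.sum(axis=0) * cr).sum())
    cov = float((w * np.outer(rr - mr, cr - mc)).sum())
    vr = float((w.sum(axis=1) * (rr - mr) ** 2).sum())
    vc = float((w.sum(axis=0) * (cr - mc) ** 2).sum())
    if vr == 0 or vc == 0:
        raise ValueError("degenerate table: a margin has no variation")
    return cov / np.sqrt(vr * vc)


@dataclass(frozen=True)
class CComparisonResult:
    """Paired comparison of two concordance indices on the same patients."""

    c_a: float
    c_b: float
    delta: float
    se: float
    ci95: tuple[float, float]
    p_value: float

    def __str__(self) -> str:
        return (f"C_a = {self.c_a:.4f}, C_b = {self.c_b:.4f}, "
                f"delta = {self.delta:.4f} "
                f"(95% CI {self.ci95[0]:.4f} to {self.ci95[1]:.4f}), "
                f"p = {self.p_value:.3g}")


def _pair_sums(scores: np.ndarray, t: np.ndarray, e: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject concordance sums (u_i) and permissible-pair counts (v_i).

    perm[i, j] marks i as the earlier death anchored against partner j;
    each unordered permissible pair appears exactly once.
    """
    tl = t[:, None] < t[None, :]
    te = t[:, None] == t[None, :]
    ev = e.astype(bool)
    perm = (tl & ev[:, None]) | (te & ev[:, None] & ~ev[None, :])
    s = np.where(scores[:, None] > scores[None, :], 1.0,
                 np.where(scores[:, None] == scores[None, :], 0.5, 0.0))
    sp = s * perm
    u = sp.sum(axis=1) + sp.sum(axis=0)
    v = perm.sum(axis=1) + perm.sum(axis=0)
    return u, v.astype(float)


def c_index_difference_test(scores_a, scores_b, times, events) -> CComparisonResult:
    """Test the difference of two Harrell C indices on the same patients.

    Both C statistics are ratios of pair-sums over the identical set of
    permissible pairs, so their difference is estimated subject-paired.
    The variance comes from the leave-one-subject-out jackknife of the
    difference, which is the influence-function approximation for the
    correlated U-statistic ratio pair.
    """
    t, e = _as_arrays(times, events)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != t.shape or sb.shape != t.shape:
        raise ValueError("score vectors must match times in length")
    ua, v = _pair_sums(sa, t, e)
    ub, _ = _pair_sums(sb, t, e)
    V = v.sum() / 2.0
    if V == 0:
        raise ValueError("no permissible pairs")
    Ua, Ub = ua.sum() / 2.0, ub.sum() / 2.0
    c_a, c_b = Ua / V, Ub / V
    delta = c_a - c_b
    # leave-one-out replicates of the difference
    with np.errstate(invalid="ignore", divide="ignore"):
        va = (Ua - ua) / (V - v)
        vb = (Ub - ub) / (V - v)
    d_loo = va - vb
    d_loo = np.where(np.isfinite(d_loo), d_loo, delta)  # subject in every pair
    nn = t.size
    se = float(np.sqrt((nn - 1) / nn * np.sum((d_loo - d_loo.mean()) ** 2)))
    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        from scipy.stats import norm

        p = float(2.0 * norm.sf(abs(delta) / se))
    ci = (delta - 1.96 * se, delta + 1.96 * se)
    return CComparisonResult(c_a=float(c_a), c_b=float(c_b), delta=float(delta),
                             se=se, ci95=ci, p_value=p)
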