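"""Ensemble clustering of cohorts: PAM, consensus dissimilarities, minimax linkage.

The pipeline learns a *consensus* dissimilarity from an initial one:

1. the initial dissimilarity between two cohorts is ``2 |theta - 1/2|``
   from the Mann-Whitney parameter of their survival distributions;
2. Partitioning Around Medoids (BUILD + SWAP, fully deterministic given the
   matrix) is run B times with the cluster count k drawn uniformly from a
   range, and the learned dissimilarity ``delta(i, j)`` is the fraction of
   runs separating i from j;
3. agglomerative clustering with the minimax linkage — merge the pair of
   clusters whose union has the smallest covering radius attained by one of
   its own members (the prototype) — turns delta into a dendrogram whose
   merge heights are those radii.

All tie-breaks (equal BUILD gains, equal SWAP improvements, equal nearest
medoids, equal merge radii) resolve to the smallest index, so the whole
stage is reproducible bit-for-bit from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import CombinationCohort
from .survival import initial_dissimilarity, mann_whitney_parameter

_SYM_TOL = 1e-12


@dataclass
class DissimilarityMatrix:
    """Symmetric labelled dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match labels")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be exactly zero")
        if (v < 0).any():
            raise ValueError("dissimilarities must be >= 0")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df) -> "DissimilarityMatrix":
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(dtype=float))


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble settings: B runs of PAM with k ~ Uniform{k_lo..k_hi}."""

    runs: int = 1000
    k_range: tuple[int, int] | None = None  # default (2, ceil(n/2))
    seed: int | None = None

    def resolve_k_range(self, n: int) -> tuple[int, int]:
        if self.k_range is None:
            lo, hi = 2, max(2, int(np.ceil(n / 2)))
        else:
            lo, hi = self.k_range
        if not (2 <= lo <= hi <= n - 1):
            raise ValueError(f"k_range ({lo},{hi}) must satisfy 2 <= lo <= hi <= n-1")
        return lo, hi


@dataclass(frozen=True)
class Merge:
    left: int       # node id (leaf: 0..n-1; internal: n, n+1, ...)
    right: int
    height: float   # minimax radius of the merged cluster
    size: int
    prototype: int  # leaf index of the minimax prototype


@dataclass
class Dendrogram:
    """Binary merge tree with minimax radii as heights and per-cluster prototypes."""

    labels: list[str]
    merges: list[Merge]
    _members: dict[int, list[int]] = field(default_factory=dict, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self, node: int) -> list[int]:
        """Sorted leaf indices under a node id."""
        if node < self.n_leaves:
            return [node]
        return self._members[node]

    def cut(self, n_groups: int) -> list[dict]:
        """Undo the last ``n_groups - 1`` merges.

        Returns one dict per cluster (ordered by smallest leaf index) with
        keys ``members`` (sorted leaf indices), ``labels`` and
        ``prototype`` (leaf index; the minimax prototype of the cluster's
        defining merge, or the leaf itself for singletons).
        """
        n = self.n_leaves
        if not 1 <= n_groups <= n:
            raise ValueError(f"n_groups must be in [1, {n}]")
        keep = self.merges[: n - n_groups]
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        proto = {i: i for i in range(n)}
        for i, m in enumerate(keep):
            node = n + i
            parent[find(m.left)] = node
            parent[find(m.right)] = node
            proto[node] = m.prototype
        roots: dict[int, list[int]] = {}
        for leaf in range(n):
            roots.setdefault(find(leaf), []).append(leaf)
        clusters = [
            {"members": sorted(v), "labels": [self.labels[i] for i in sorted(v)],
             "prototype": proto[k]}
            for k, v in roots.items()
        ]
        clusters.sort(key=lambda c: c["members"][0])
        return clusters

    def to_linkage_matrix(self) -> np.ndarray:
        """Scipy-style (n-1, 4) linkage matrix [left, right, height, size]."""
        return np.array([[m.left, m.right, m.height, m.size] for m in self.merges])

    def to_merge_table(self):
        import pandas as pd

        return pd.DataFrame({
            "left": [m.left for m in self.merges],
            "right": [m.right for m in self.merges],
            "height": [m.height for m in self.merges],
            "size": [m.size for m in self.merges],
            "prototype": [self.labels[m.prototype] for m in self.merges],
        })

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        text = {i: self.labels[i] for i in range(n)}
        for i, m in enumerate(self.merges):
            node = n + i
            h = m.height
            bl_l = max(h - height[m.left], 0.0)
            bl_r = max(h - height[m.right], 0.0)
            text[node] = f"({text[m.left]}:{bl_l:.6g},{text[m.right]}:{bl_r:.6g})"
            height[node] = h
        return text[2 * n - 2] + ";"


def build_initial_matrix(cohorts: Sequence[CombinationCohort]) -> DissimilarityMatrix:
    """Initial dissimilarity d(i,j) = 2 |theta_hat(i,j) - 1/2| over cohorts."""
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    n = len(cohorts)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                est = mann_whitney_parameter(
                    cohorts[i].times, cohorts[i].events,
                    cohorts[j].times, cohorts[j].events,
                )
            except ValueError as exc:
                raise ValueError(
                    f"dissimilarity failed for cohorts "
                    f"{cohorts[i].label!r} vs {cohorts[j].label!r}: {exc}"
                ) from exc
            d[i, j] = d[j, i] = initial_dissimilarity(est.theta)
    return DissimilarityMatrix(labels=[c.label for c in cohorts], values=d)


def _assign(D: np.ndarray, medoids: list[int]) -> np.ndarray:
    """Cluster id per point = position of its nearest medoid in the sorted
    medoid list (ties to the smallest medoid index)."""
    sub = D[np.array(medoids)]          # medoids sorted ascending
    return np.argmin(sub, axis=0)       # argmin -> first (smallest) medoid on ties


def pam(dissim: DissimilarityMatrix | np.ndarray, k: int, seed: int | None = None
        ) -> np.ndarray:
    """Partitioning Around Medoids, classical two-phase BUILD + SWAP.

    BUILD greedily seeds k medoids (first: the point with the smallest
    total dissimilarity; then the point with the largest decrease of the
    objective).  SWAP repeats the single best strictly-improving
    medoid/non-medoid exchange (steepest descent) until none exists.  The
    procedure is deterministic given the matrix; ``seed`` is accepted for
    interface uniformity but unused.

    Returns an integer cluster id per point, ids ordered by medoid index.
    """
    D = dissim.values if isinstance(dissim, DissimilarityMatrix) else np.asarray(dissim, float)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dnear = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        dnear = np.minimum(dnear, D[c])
    medoids = sorted(medoids)
    # SWAP (skipped for k == n: objective already 0)
    while k < n:
        med = np.array(medoids)
        sub = D[med]                              # (k, n)
        nearest = np.argmin(sub, axis=0)
        if k == 1:
            dnear, dsecond = sub[0], np.full(n, np.inf)
        else:
            part = np.partition(sub, 1, axis=0)
            dnear, dsecond = part[0], part[1]
        obj = dnear.sum()
        candidates = np.array([i for i in range(n) if i not in set(medoids)])
        best = (obj - 1e-12, None)
        for mi in range(k):                       # medoids ascending
            dwo = np.where(nearest == mi, dsecond, dnear)
            objs = np.minimum(dwo[None, :], D[candidates]).sum(axis=1)
            j = int(np.argmin(objs))              # candidates ascending: lexicographic
            if objs[j] < best[0]:
                best = (objs[j], (mi, int(candidates[j])))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = sorted(medoids)
    return _assign(D, medoids)


def ensemble_learn(dissim: DissimilarityMatrix, config: EnsembleConfig
                   ) -> DissimilarityMatrix:
    """Learned dissimilarity delta(i,j): fraction of PAM runs separating i, j.

    Each run b draws its cluster count k_b from an independent substream of
    the master seed, so the result is reproducible and order-independent.
    """
    n = dissim.n
    lo, hi = config.resolve_k_range(n)
    if config.runs < 1:
        raise ValueError("runs must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(config.runs)
    sep = np.zeros((n, n), dtype=np.int64)
    cache: dict[int, np.ndarray] = {}  # PAM is deterministic per k
    for child in children:
        k = int(np.random.default_rng(child).integers(lo, hi + 1))
        if k not in cache:
            cache[k] = pam(dissim, k)
        lab = cache[k]
        sep += lab[:, None] != lab[None, :]
    delta = sep / config.runs
    np.fill_diagonal(delta, 0.0)
    return DissimilarityMatrix(labels=list(dissim.labels), values=delta)


def _minimax_radius(D: np.ndarray, members: list[int]) -> tuple[float, int]:
    """Smallest covering radius by a member prototype; ties -> smallest index."""
    idx = np.array(members)
    ecc = D[np.ix_(idx, idx)].max(axis=1)
    best = int(np.argmin(ecc))  # members sorted ascending
    return float(ecc[best]), members[best]


def minimax_linkage(dissim: DissimilarityMatrix | np.ndarray) -> Dendrogram:
    """Agglomerative clustering with the minimax linkage.

    At each step merge the pair of clusters (G, H) minimizing
    ``r(G ∪ H) = min_{c in G ∪ H} max_{x in G ∪ H} d(c, x)``; the merge
    height is that radius and the attaining member c is recorded as the
    cluster's prototype.  Ties resolve to the pair with the smallest
    leading leaf indices.
    """
    if isinstance(dissim, DissimilarityMatrix):
        labels, D = list(dissim.labels), dissim.values
    else:
        D = np.asarray(dissim, dtype=float)
        labels = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active: list[int] = list(range(n))
    radius: dict[tuple[int, int], tuple[float, int]] = {}
    for a in range(n):
        for b in range(a + 1, n):
            radius[(a, b)] = _minimax_radius(D, sorted(members[a] + members[b]))
    merges: list[Merge] = []
    all_members = dict(members)
    for step in range(n - 1):
        # pick the minimal-radius active pair; ties -> smallest (min leaf, min leaf)
        best_key = None
        best_val = (np.inf, None)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (a, b) if a < b else (b, a)
                r, proto = radius[key]
                sort_key = (r, min(members[a][0], members[b][0]),
                            max(members[a][0], members[b][0]))
                if best_key is None or sort_key < best_sort:
                    best_key, best_val, best_sort = key, (r, proto), sort_key
        a, b = best_key
        r, proto = best_val
        node = n + step
        left, right = (a, b) if a < b else (b, a)
        new_members = sorted(members[a] + members[b])
        merges.append(Merge(left=left, right=right, height=r,
                            size=len(new_members), prototype=proto))
        active = [x for x in active if x not in (a, b)] + [node]
        members[node] = new_members
        all_members[node] = new_members
        del members[a], members[b]
        for other in active[:-1]:
            key = (other, node)
            radius[key] = _minimax_radius(D, sorted(members[other] + new_members))
    return Dendrogram(labels=labels, merges=merges,
                      _members={k: v for k, v in all_members.items() if k >= n})


def cut_dendrogram(dend: Dendrogram, n_groups: int) -> list[dict]:
    """Cut into ``n_groups`` clusters by undoing the last merges."""
    return dend.cut(n_groups)
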