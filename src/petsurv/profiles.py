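"""Unsupervised discretization of survival times into prognostic profiles.

Continuous survival times are partitioned by 1-D k-means; the quality of a
partition is summarised by the variance explained

    VE = SSB / SST,   SST = sum_i (t_i - mean)^2,
    SSB = sum_c n_c (mean_c - mean)^2,  SSW = SST - SSB,

and the number of profiles k is chosen by maximising the between/within
variance ratio (SSB/(k-1)) / (SSW/(n-k)) — the Calinski-Harabasz criterion.
Raw VE is monotone non-decreasing in k, so the penalised ratio is the
well-posed reading of "maximal between/within variance ratio"; VE itself is
reported for the chosen k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = ["SurvivalPartition", "compute_ve", "kmeans_1d", "select_k"]


@dataclass
class SurvivalPartition:
    """A k-class discretization of survival times with its variance split."""

    k: int
    labels: np.ndarray            # per-subject class ids 1..k, ordered by survival
    boundaries: np.ndarray | None  # k-1 cut points in years (None if non-contiguous)
    ve: float
    within_ss: float
    between_ss: float
    total_ss: float
    class_means: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "k": self.k,
                    "ve": self.ve,
                    "within_ss": self.within_ss,
                    "between_ss": self.between_ss,
                    "total_ss": self.total_ss,
                    "boundaries": None
                    if self.boundaries is None
                    else self.boundaries.tolist(),
                    "class_means": self.class_means.tolist(),
                    "labels": self.labels.tolist(),
                },
                indent=1,
            )
        )

    def interval_labels(self) -> list[str]:
        """Display intervals with boundaries rounded to the nearest year."""
        if self.boundaries is None:
            return []
        cuts = [0] + [int(round(b)) for b in self.boundaries]
        out = [f"({lo}-{hi}]" for lo, hi in zip(cuts[:-1], cuts[1:])]
        out.append(f"> {cuts[-1]}")
        return out


def _ordered_labels(times: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel classes 1..k by ascending class-mean survival."""
    uniq = np.unique(labels)
    means = np.array([times[labels == u].mean() for u in uniq])
    order = np.argsort(means, kind="stable")
    remap = {int(uniq[o]): rank + 1 for rank, o in enumerate(order)}
    return np.array([remap[int(l)] for l in labels]), means[order]


def _contiguous_boundaries(times: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray | None:
    """Midpoints between adjacent class extremes, or None if not 1-D contiguous."""
    cuts = []
    for c in range(1, k):
        hi = times[labels == c].max()
        lo = times[labels == c + 1].min()
        if hi > lo:
            return None
        cuts.append((hi + lo) / 2.0)
    return np.asarray(cuts)


def compute_ve(times: Iterable[float], labels: Iterable[int]) -> SurvivalPartition:
    """Variance decomposition (SST/SSB/SSW) and VE of an arbitrary labelling.

    A single-class partition has VE = 0 by definition; identical times make
    VE undefined and raise.
    """
    times = np.asarray(list(times), dtype=float)
    labels = np.asarray(list(labels))
    if times.size < 2:
        raise ValueError("need at least 2 subjects")
    if times.shape != labels.shape:
        raise ValueError("times and labels must have equal length")
    mean = times.mean()
    total_ss = float(((times - mean) ** 2).sum())
    if total_ss == 0:
        raise ValueError("all survival times identical: VE undefined (SST = 0)")
    labels, class_means = _ordered_labels(times, labels)
    k = int(labels.max())
    between_ss = 0.0
    for c in range(1, k + 1):
        sel = labels == c
        between_ss += sel.sum() * (times[sel].mean() - mean) ** 2
    between_ss = float(between_ss)
    within_ss = total_ss - between_ss
    return SurvivalPartition(
        k=k,
        labels=labels,
        boundaries=_contiguous_boundaries(times, labels, k),
        ve=between_ss / total_ss,
        within_ss=within_ss,
        between_ss=between_ss,
        total_ss=total_ss,
        class_means=class_means,
    )


def kmeans_1d(
    times: Iterable[float], k: int, restarts: int = 20, seed: int = 0
) -> SurvivalPartition:
    """Globally optimal k-means on the survival axis.

    In one dimension every k-means optimum is contiguous in the sorted order,
    so the exact solution is found by an O(k n^2) dynamic program over
    contiguous partitions (prefix-sum segment costs) rather than restarted
    Lloyd iterations, whose best-of-``restarts`` local search can miss the
    optimum.  ``restarts`` and ``seed`` are accepted for interface stability
    and unused: the exact solver is deterministic.  Classes are relabelled
    1..k by ascending survival; boundaries are midpoints between adjacent
    cluster extremes.
    """
    times = np.asarray(list(times), dtype=float)
    n = times.size
    n_distinct = np.unique(times).size
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct values ({n_distinct})")
    order = np.argsort(times, kind="stable")
    xs = times[order]
    pre = np.concatenate([[0.0], np.cumsum(xs)])
    pre2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        """Within-SS of xs[i:j] for a vector of segment starts i."""
        m = j - i
        s = pre[j] - pre[i]
        return np.maximum(pre2[j] - pre2[i] - s * s / m, 0.0)

    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            i = np.arange(kk - 1, j)
            totals = cost[kk - 1, i] + seg_cost(i, j)
            best = int(np.argmin(totals))  # first minimum: deterministic ties
            cost[kk, j] = totals[best]
            split[kk, j] = i[best]
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for kk in range(k, 0, -1):
        i = split[kk, j]
        labels_sorted[i:j] = kk
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return compute_ve(times, labels)


def select_k(
    times: Iterable[float],
    k_range: Iterable[int] = range(2, 7),
    restarts: int = 20,
    seed: int = 0,
) -> tuple[int, SurvivalPartition, dict[int, float]]:
    """Choose k by the variance-ratio criterion, at its first local maximum.

    The criterion is evaluated for each feasible k in ascending order and the
    chosen k is the first whose successor's criterion is strictly lower (the
    classical first-local-maximum reading of "the ratio was maximal": the raw
    ratio tends to keep creeping upward when dense profiles are split
    further, so the first peak marks the natural number of profiles).  If the
    criterion never falls, the largest feasible k wins; ties continue to the
    smaller k.  Returns (chosen k, its partition, {k: criterion}).  Values of
    k exceeding the number of distinct times are skipped; SSW = 0 yields an
    infinite criterion (a perfect partition).
    """
    times = np.asarray(list(times), dtype=float)
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range is empty")
    n = times.size
    n_distinct = np.unique(times).size
    parts: dict[int, SurvivalPartition] = {}
    scores: dict[int, float] = {}
    for k in k_range:
        if k > n_distinct or k >= n:
            continue
        part = kmeans_1d(times, k, restarts=restarts, seed=seed)
        if part.within_ss <= 0:
            score = np.inf
        else:
            score = (part.between_ss / (k - 1)) / (part.within_ss / (n - k)) if k > 1 else 0.0
        parts[k] = part
        scores[k] = float(score)
    if not parts:
        raise ValueError("no feasible k in k_range for these times")
    ks = sorted(parts)
    chosen = ks[-1]
    for prev, nxt in zip(ks[:-1], ks[1:]):
        if scores[prev] > scores[nxt]:
            chosen = prev
            break
    return chosen, parts[chosen], scores
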