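"""Ranking visual words by two-group Student's t-tests.

Given two user-defined groups of images, every visual word is scored by
a two-sample t-test on its frequencies; words are listed in ascending
p-value order so the most group-discriminative words come first.  The
graph can then be rebuilt on a chosen word subset to sharpen the
separation between the groups.  Per-word, per-group five-number
summaries support boxplot displays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import BoFsHistogram
from .errors import InvalidInputError, InvalidParameterError
from .simgraph import SimilarityGraph, build_knn_graph, pairwise_distances

__all__ = [
    "GroupAssignment",
    "GroupSummary",
    "FeatureRanking",
    "RankedWord",
    "ttest_words",
    "rank_words_ttest",
    "word_group_summary",
    "subset_and_rebuild",
    "save_ranking",
]


@dataclass(frozen=True)
class GroupAssignment:
    """Two disjoint image-id groups to contrast; each needs >= 2 members
    so variances are estimable."""

    group_a: frozenset
    group_b: frozenset

    def __post_init__(self) -> None:
        a, b = frozenset(self.group_a), frozenset(self.group_b)
        object.__setattr__(self, "group_a", a)
        object.__setattr__(self, "group_b", b)
        if a & b:
            raise InvalidInputError("groups must be disjoint")
        if len(a) < 2 or len(b) < 2:
            raise InvalidInputError("each group needs at least 2 images")


@dataclass(frozen=True)
class GroupSummary:
    """Boxplot statistics of one word's frequencies within one group
    (quartiles by linear interpolation)."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    mean: float
    sd: float


@dataclass(frozen=True)
class RankedWord:
    word_index: int
    t_statistic: float
    p_value: float
    q_value: float
    summary_a: GroupSummary
    summary_b: GroupSummary
    degenerate: bool = False  # zero pooled variance


@dataclass
class FeatureRanking:
    """Words ordered by ascending p (ties: |t| descending, then index).

    ``variant`` records whether the pooled-variance (classic Student)
    or Welch test produced the statistics; q-values are
    Benjamini-Hochberg adjusted p-values reported for reference only —
    the ranking itself uses raw p-values.
    """

    entries: list[RankedWord]
    variant: str = "student"
    quartile_method: str = "linear"

    def top(self, m: int) -> list[int]:
        return [e.word_index for e in self.entries[:m]]


def _summary(values: np.ndarray) -> GroupSummary:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return GroupSummary(
        minimum=float(values.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(values.max()),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
    )


def ttest_words(
    A: np.ndarray, B: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise two-sample t-tests between matrices A (n_a x w) and
    B (n_b x w).

    Returns (t, p, degenerate).  Words whose pooled variance is zero
    have no defined t statistic; they are flagged and assigned p = 1
    when the group means agree and p = 0 (with an infinite t carrying
    the sign of the difference) when they differ.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise InvalidInputError("each group needs at least 2 rows")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    var_zero = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    diff = A.mean(axis=0) - B.mean(axis=0)
    degenerate = var_zero
    deg_t = np.zeros_like(diff)
    deg_t[diff != 0] = np.sign(diff[diff != 0]) * np.inf
    t = np.where(var_zero, deg_t, t)
    p = np.where(var_zero, np.where(diff == 0, 1.0, 0.0), p)
    return t, p, degenerate


def rank_words_ttest(
    histograms: list[BoFsHistogram],
    groups: GroupAssignment,
    equal_var: bool = True,
) -> FeatureRanking:
    """Rank every visual word by a two-group Student's t-test.

    Classic pooled-variance t with n_a + n_b - 2 degrees of freedom by
    default (``equal_var=False`` switches to Welch's test).  Entries are
    sorted by ascending two-sided p-value, breaking ties by descending
    |t| then ascending word index.
    """
    by_id = {h.image_id: h for h in histograms}
    missing = (groups.group_a | groups.group_b) - set(by_id)
    if missing:
        raise InvalidInputError(f"group ids not among histograms: {sorted(missing)}")
    ids_a = sorted(groups.group_a)
    ids_b = sorted(groups.group_b)
    A = np.vstack([by_id[i].freqs for i in ids_a])
    B = np.vstack([by_id[i].freqs for i in ids_b])
    if A.shape[1] != B.shape[1]:
        raise InvalidInputError("histogram lengths differ between groups")

    t, p, degenerate = ttest_words(A, B, equal_var=equal_var)
    q = stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")

    entries = [
        RankedWord(
            word_index=w,
            t_statistic=float(t[w]),
            p_value=float(p[w]),
            q_value=float(q[w]),
            summary_a=_summary(A[:, w]),
            summary_b=_summary(B[:, w]),
            degenerate=bool(degenerate[w]),
        )
        for w in range(A.shape[1])
    ]
    # ascending p, then |t| descending, then word index ascending
    abs_t = np.nan_to_num(np.abs(t), nan=0.0, posinf=np.finfo(float).max)
    order = np.lexsort((np.arange(A.shape[1]), -abs_t, p))
    entries = [entries[i] for i in order]
    variant = "student" if equal_var else "welch"
    return FeatureRanking(entries=entries, variant=variant)


def word_group_summary(
    histograms: list[BoFsHistogram],
    groups: GroupAssignment,
    word_index: int,
) -> tuple[GroupSummary, GroupSummary]:
    """Boxplot summaries (five numbers plus mean/sd) of one word's
    frequencies in each group."""
    by_id = {h.image_id: h for h in histograms}
    missing = (groups.group_a | groups.group_b) - set(by_id)
    if missing:
        raise InvalidInputError(f"group ids not among histograms: {sorted(missing)}")
    k = histograms[0].k_words
    if not 0 <= word_index < k:
        raise InvalidParameterError(f"word_index {word_index} out of range [0, {k})")
    va = np.array([by_id[i].freqs[word_index] for i in sorted(groups.group_a)])
    vb = np.array([by_id[i].freqs[word_index] for i in sorted(groups.group_b)])
    return _summary(va), _summary(vb)


def subset_and_rebuild(
    histograms: list[BoFsHistogram],
    word_indices: list[int],
    k_nn: int = 3,
) -> SimilarityGraph:
    """Rebuild the k-NN graph using only the selected visual words.

    Histograms are restricted to the chosen coordinates without
    renormalising (renormalisation would let discarded noise words leak
    back in through the denominator), distances are recomputed and the
    graph reconstructed.  The returned graph records the subset used.
    """
    if len(word_indices) == 0:
        raise InvalidParameterError("word_indices must be non-empty")
    idx = list(word_indices)
    if len(set(idx)) != len(idx):
        raise InvalidParameterError("word_indices must be unique")
    k = histograms[0].k_words
    if any(not 0 <= w < k for w in idx):
        raise InvalidParameterError("word index out of range")

    restricted = [
        BoFsHistogram.__new__(BoFsHistogram) for _ in histograms
    ]
    for r, h in zip(restricted, histograms):
        # bypass the sums-to-1 validation: a restriction is not a histogram
        r.image_id = h.image_id
        r.freqs = h.freqs[idx]
        r.n_descriptors = h.n_descriptors
    D = pairwise_distances(restricted)
    g = build_knn_graph(D, k_nn=k_nn)
    g.word_subset = list(idx)
    return g


def save_ranking(ranking: FeatureRanking, path: str | Path) -> None:
    """Persist a ranking as CSV: one row per word with t, p, q and the
    per-group summary statistics, in ranked order."""
    rows = []
    for e in ranking.entries:
        row = {
            "word_index": e.word_index,
            "t": e.t_statistic,
            "p": e.p_value,
            "q": e.q_value,
            "degenerate": e.degenerate,
        }
        for tag, s in (("a", e.summary_a), ("b", e.summary_b)):
            row.update(
                {
                    f"mean_{tag}": s.mean,
                    f"sd_{tag}": s.sd,
                    f"min_{tag}": s.minimum,
                    f"q1_{tag}": s.q1,
                    f"median_{tag}": s.median,
                    f"q3_{tag}": s.q3,
                    f"max_{tag}": s.maximum,
                }
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["variant"] = ranking.variant
    with open(path, "w") as fh:
        fh.write(f"# test_variant={ranking.variant} quartiles={ranking.quartile_method}\n")
        df.to_csv(fh, index=False)
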