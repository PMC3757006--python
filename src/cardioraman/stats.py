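"""Nonparametric group comparison: Kruskal-Wallis omnibus with Dunn's post hoc.

The omnibus test delegates to :func:`scipy.stats.kruskal`.  Dunn's
pairwise z test on mean ranks (with tie correction) is computed here;
p-values are Bonferroni-adjusted over the number of pairs, matching the
common "Dunn's multiple comparison" reporting convention.  Summaries
are reported as mean ± SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    se: float


@dataclass(frozen=True)
class GroupComparison:
    """Result of an omnibus + post-hoc comparison across groups."""

    summaries: tuple[GroupSummary, ...]
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.summaries)

    def summary(self, label: str) -> GroupSummary:
        for s in self.summaries:
            if s.label == label:
                return s
        raise KeyError(label)


def group_compare(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Compare ≥2 labelled groups of scalars.

    Returns mean ± SE per group, the Kruskal-Wallis omnibus p-value and
    Bonferroni-adjusted Dunn pairwise p-values.  Fully tied data (every
    value identical) yields p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    labels = list(groups)
    arrays = []
    for label in labels:
        values = np.asarray(groups[label], dtype=float)
        if values.size < 1:
            raise ValidationError(f"group {label!r} is empty")
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"group {label!r} contains non-finite values")
        arrays.append(values)

    summaries = tuple(
        GroupSummary(
            label=label,
            n=int(v.size),
            mean=float(v.mean()),
            se=float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
        )
        for label, v in zip(labels, arrays)
    )

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        omnibus_p = 1.0
        pairwise = {pair: 1.0 for pair in combinations(labels, 2)}
        return GroupComparison(summaries, omnibus_p, pairwise)

    omnibus_p = float(sps.kruskal(*arrays).pvalue)
    pairwise = _dunn(labels, arrays)
    return GroupComparison(summaries, omnibus_p, pairwise)


def _dunn(labels: list[str], arrays: list[np.ndarray]) -> dict[tuple[str, str], float]:
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # mean rank per group
    mean_ranks = {}
    start = 0
    for label, values in zip(labels, arrays):
        stop = start + values.size
        mean_ranks[label] = ranks[start:stop].mean()
        start = stop
    sizes = {label: v.size for label, v in zip(labels, arrays)}
    # tie correction: sum of (t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_pairs = len(labels) * (len(labels) - 1) // 2
    pvalues: dict[tuple[str, str], float] = {}
    for a, b in combinations(labels, 2):
        sd = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if sd == 0:
            p = 1.0
        else:
            z = abs(mean_ranks[a] - mean_ranks[b]) / sd
            p = min(1.0, 2.0 * sps.norm.sf(z) * n_pairs)
        pvalues[(a, b)] = float(p)
    return pvalues
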