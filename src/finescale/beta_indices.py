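"""Pairwise similarity indices and multi-sample shared-OTU (Venn) accounting.

Qualitative indices (presence/absence): Anderberg, Jaccard, Sorensen, Ochiai.
Quantitative indices (abundance-aware): Bray-Curtis, the Chao abundance-based
Jaccard and Sorensen estimators, Smith's theta (plug-in) and the Yue-Clayton
theta (moment-debiased).  All nine live on [0, 1], are symmetric in sample
order, equal 1 on identical columns, and 0 on disjoint supports.

For a presence pair with ``a`` OTUs in both samples, ``b`` only in the first
and ``c`` only in the second:

    jaccard   = a / (a + b + c)
    sorensen  = 2a / (2a + b + c)
    ochiai    = a / sqrt((a + b)(a + c))
    anderberg = a / (a + 2(b + c))

so on any pair ``sorensen = 2J/(1+J)`` and ``anderberg = J/(2-J)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .otu_io import CountTable

__all__ = [
    "PresencePair",
    "PairwiseSimilarity",
    "VennSummary",
    "presence_pair",
    "qualitative_indices",
    "quantitative_indices",
    "all_indices",
    "pairwise_matrix",
    "venn_summary",
    "sorensen_from_jaccard",
    "anderberg_from_jaccard",
]

INDEX_NAMES = (
    "anderberg", "jaccard", "sorensen", "ochiai",
    "bray_curtis", "abund_jaccard", "abund_sorensen", "theta_smith", "theta_yc",
)


@dataclass(frozen=True)
class PresencePair:
    """Shared/unique OTU counts between two samples."""
    a: int  # present in both
    b: int  # only in first
    c: int  # only in second

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("a, b, c must be non-negative")


@dataclass(frozen=True)
class PairwiseSimilarity:
    anderberg: float
    jaccard: float
    sorensen: float
    ochiai: float
    bray_curtis: float
    abund_jaccard: float
    abund_sorensen: float
    theta_smith: float
    theta_yc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def sorensen_from_jaccard(j: float) -> float:
    """Algebraic identity S = 2J/(1+J) linking the two qualitative indices."""
    return 2.0 * j / (1.0 + j)


def anderberg_from_jaccard(j: float) -> float:
    """Algebraic identity A = J/(2-J)."""
    return j / (2.0 - j)


def presence_pair(table: CountTable, s1: str, s2: str) -> PresencePair:
    if s1 == s2:
        raise ValueError("s1 and s2 must differ")
    x = table.column(s1).to_numpy() > 0
    y = table.column(s2).to_numpy() > 0
    return PresencePair(
        a=int((x & y).sum()), b=int((x & ~y).sum()), c=int((~x & y).sum())
    )


def qualitative_indices(p: PresencePair) -> dict[str, float]:
    a, b, c = p.a, p.b, p.c
    if a + b + c == 0:
        raise ValueError("both samples are empty")
    if a + b == 0 or a + c == 0:
        raise ValueError("ochiai undefined for an empty sample")
    return {
        "anderberg": a / (a + 2 * (b + c)),
        "jaccard": a / (a + b + c),
        "sorensen": 2 * a / (2 * a + b + c),
        "ochiai": a / math.sqrt((a + b) * (a + c)),
    }


def _chao_uv(x: np.ndarray, y: np.ndarray, bias_correction: bool) -> tuple[float, float]:
    """Chao's estimated total relative abundance of shared OTUs (U for x, V for y)."""
    n, m = x.sum(), y.sum()
    shared = (x > 0) & (y > 0)
    u = x[shared].sum() / n
    v = y[shared].sum() / m
    if bias_correction:
        # f+1/f+2: shared OTUs that are singletons/doubletons in the OTHER sample
        f_plus1 = int((shared & (y == 1)).sum())
        f_plus2 = max(int((shared & (y == 2)).sum()), 1)
        u += (m - 1) / m * f_plus1 / (2 * f_plus2) * x[shared & (y == 1)].sum() / n
        g_plus1 = int((shared & (x == 1)).sum())
        g_plus2 = max(int((shared & (x == 2)).sum()), 1)
        v += (n - 1) / n * g_plus1 / (2 * g_plus2) * y[shared & (x == 1)].sum() / m
    return min(u, 1.0), min(v, 1.0)


def quantitative_indices(table: CountTable, s1: str, s2: str,
                         bias_correction: bool = True) -> dict[str, float]:
    x = table.column(s1).to_numpy().astype(np.float64)
    y = table.column(s2).to_numpy().astype(np.float64)
    n, m = x.sum(), y.sum()
    if n == 0 or m == 0:
        raise ValueError("both samples must have positive read totals")

    bray_curtis = 2.0 * np.minimum(x, y).sum() / (n + m)

    u, v = _chao_uv(x, y, bias_correction)
    if u + v == 0:
        abund_jaccard = abund_sorensen = 0.0
    else:
        abund_jaccard = min(u * v / (u + v - u * v), 1.0) if u + v - u * v > 0 else 1.0
        abund_sorensen = min(2 * u * v / (u + v), 1.0)

    p, q = x / n, y / m
    spq = float((p * q).sum())
    sp2, sq2 = float((p * p).sum()), float((q * q).sum())
    theta_smith = spq / (sp2 + sq2 - spq) if spq > 0 else 0.0

    # Yue-Clayton: unbiased moment estimators of sum(p^2), sum(q^2), sum(pq)
    sp2_hat = float((x * (x - 1)).sum()) / (n * (n - 1)) if n > 1 else sp2
    sq2_hat = float((y * (y - 1)).sum()) / (m * (m - 1)) if m > 1 else sq2
    spq_hat = float((x * y).sum()) / (n * m)
    if spq_hat <= 0:
        theta_yc = 0.0
    else:
        den = sp2_hat + sq2_hat - spq_hat
        # den <= 0 or den < num arises for sparse columns where the debiased
        # moments undershoot; the estimand is then at its ceiling
        theta_yc = 1.0 if den <= spq_hat else min(spq_hat / den, 1.0)

    return {
        "bray_curtis": float(bray_curtis),
        "abund_jaccard": float(abund_jaccard),
        "abund_sorensen": float(abund_sorensen),
        "theta_smith": float(min(theta_smith, 1.0)),
        "theta_yc": float(theta_yc),
    }


def all_indices(table: CountTable, s1: str, s2: str,
                bias_correction: bool = True) -> PairwiseSimilarity:
    vals = qualitative_indices(presence_pair(table, s1, s2))
    vals.update(quantitative_indices(table, s1, s2, bias_correction))
    return PairwiseSimilarity(**vals)


def pairwise_matrix(table: CountTable, index: str,
                    samples: Sequence[str] | None = None,
                    bias_correction: bool = True):
    """Symmetric similarity matrix plus mean +/- sd over all unordered pairs.

    Returns (matrix as pandas.DataFrame, mean, sd); sd is the sample (n-1)
    standard deviation over the C(k, 2) off-diagonal values.
    """
    import pandas as pd

    if index not in INDEX_NAMES:
        raise ValueError(f"unknown index {index!r}; choose from {INDEX_NAMES}")
    if samples is None:
        samples = table.sample_ids
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    mat = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    values = []
    for s1, s2 in itertools.combinations(samples, 2):
        sim = all_indices(table, s1, s2, bias_correction).as_dict()[index]
        mat.loc[s1, s2] = mat.loc[s2, s1] = sim
        values.append(sim)
    values = np.asarray(values)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return mat, float(values.mean()), sd


# -- Venn accounting -------------------------------------------------------

@dataclass
class VennSummary:
    """Occupancy of OTUs (or clones) across k samples.

    ``occupancy`` maps each non-empty sample subset to the number of OTUs
    present in exactly that subset (a partition of the distinct OTUs).
    ``shared_pct[x]`` holds, for every subset of x >= 2 samples, the inclusive
    percentage of OTUs present in all x of them; ``unshared_pct`` holds the
    per-sample percentage of OTUs found only in that sample.  Two denominator
    conventions are supported:

    * ``subset`` — distinct OTUs observed across the x samples of the subset
      (a single sample's own richness for the unshared class).
    * ``global`` — distinct OTUs observed across all samples considered.
    """

    sample_ids: list[str]
    weight: str
    convention: str
    occupancy: dict[frozenset, int]
    shared_pct: dict[int, list[float]] = field(default_factory=dict)
    unshared_pct: list[float] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.occupancy.values())

    def mean_sd(self, k: int) -> tuple[float, float]:
        """Mean +/- sample sd of the inclusive shared percentage over subsets of size k
        (k = 1 refers to the unshared class)."""
        vals = np.asarray(self.unshared_pct if k == 1 else self.shared_pct[k])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), sd


def venn_summary(table: CountTable, samples: Sequence[str] | None = None,
                 weight: str = "otus", convention: str = "subset") -> VennSummary:
    """Shared-OTU accounting across 2-4 (or more) samples.

    weight="otus" counts distinct OTUs; weight="clones" repeats the accounting
    over read counts (an OTU contributes its reads in the relevant samples).
    """
    if samples is None:
        samples = table.sample_ids
    samples = list(samples)
    if weight not in ("otus", "clones"):
        raise ValueError("weight must be 'otus' or 'clones'")
    if convention not in ("subset", "global"):
        raise ValueError("convention must be 'subset' or 'global'")

    sub = table.subset_samples(samples)
    counts = sub.df.to_numpy()            # OTUs x samples, empty rows dropped
    pres = counts > 0
    k = len(samples)

    occupancy: dict[frozenset, int] = {}
    patterns = {}
    for i, row in enumerate(pres):
        key = frozenset(s for s, present in zip(samples, row) if present)
        patterns.setdefault(key, []).append(i)
    for key, idx in patterns.items():
        if weight == "otus":
            occupancy[key] = len(idx)
        else:
            occupancy[key] = int(counts[idx].sum())

    def _numerator(subset_cols: list[int]) -> float:
        in_all = pres[:, subset_cols].all(axis=1)
        if weight == "otus":
            return float(in_all.sum())
        return float(counts[np.ix_(in_all.nonzero()[0], subset_cols)].sum())

    def _denominator(subset_cols: list[int]) -> float:
        if convention == "global":
            subset_cols = list(range(k))
        in_any = pres[:, subset_cols].any(axis=1)
        if weight == "otus":
            return float(in_any.sum())
        return float(counts[np.ix_(in_any.nonzero()[0], subset_cols)].sum())

    shared_pct: dict[int, list[float]] = {}
    for x in range(2, k + 1):
        vals = []
        for combo in itertools.combinations(range(k), x):
            num = _numerator(list(combo))
            den = _denominator(list(combo))
            vals.append(100.0 * num / den if den else 0.0)
        shared_pct[x] = vals

    unshared_pct = []
    for j in range(k):
        only_j = pres[:, j] & ~np.delete(pres, j, axis=1).any(axis=1)
        if weight == "otus":
            num = float(only_j.sum())
            den = float(pres.any(axis=1).sum()) if convention == "global" \
                else float(pres[:, j].sum())
        else:
            num = float(counts[only_j, j].sum())
            den = float(counts.sum()) if convention == "global" \
                else float(counts[:, j].sum())
        unshared_pct.append(100.0 * num / den if den else 0.0)

    return VennSummary(samples, weight, convention, occupancy, shared_pct, unshared_pct)
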