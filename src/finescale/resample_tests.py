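"""Resampling tests: spatial-separation subsampling, the likelihood-ratio
(G) test on phylum composition, rarefaction, and the ordination-distance
regression.

The spatial-separation design compares three subsamples drawn from one
sample (no spatial separation) against one subsample from each of three
other samples: if community differences are truly spatial, the within-sample
group shares more OTUs than the across-sample group beyond what resampling
noise alone produces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .beta_indices import venn_summary
from .otu_io import CountTable

__all__ = [
    "subsample_reads",
    "spatial_separation_test",
    "SpatialTestResult",
    "g_test",
    "GTestResult",
    "rarefaction_curve",
    "embedding_r2",
    "EmbeddingFit",
]


def subsample_reads(table: CountTable, sample: str, size: int,
                    rng: np.random.Generator | int | None = None) -> pd.Series:
    """Draw ``size`` reads without replacement from one sample's reads.

    Reads are exchangeable tokens labeled by OTU, so the draw is multivariate
    hypergeometric on the count vector.  Repeated calls with the same
    generator produce independent subsamples (overlap allowed).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    col = table.column(sample)
    total = int(col.sum())
    if size > total:
        raise ValueError(f"subsample size {size} exceeds sample total {total}")
    drawn = rng.multivariate_hypergeometric(col.to_numpy(), size)
    return pd.Series(drawn, index=col.index, name=sample)


def partition_subsamples(table: CountTable, sample: str, size: int, k: int,
                         rng: np.random.Generator | int | None = None) -> list[pd.Series]:
    """k disjoint subsamples of ``size`` reads (a joint partition draw)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    col = table.column(sample)
    remaining = col.to_numpy().copy()
    if k * size > remaining.sum():
        raise ValueError("not enough reads for a disjoint partition")
    out = []
    for i in range(k):
        drawn = rng.multivariate_hypergeometric(remaining, size)
        remaining = remaining - drawn
        out.append(pd.Series(drawn, index=col.index, name=f"{sample}_part{i + 1}"))
    return out


@dataclass
class SpatialTestResult:
    within_pct: dict[str, list[float]]   # class -> data points (within group)
    across_pct: dict[str, list[float]]
    tests: dict[str, tuple[float | None, float | None]]  # class -> (t, p)
    size: int
    seed: int | None

    def significant(self, cls: str = "unshared", alpha: float = 0.05) -> bool:
        t, p = self.tests[cls]
        return p is not None and p < alpha


def _group_percentages(columns: list[pd.Series]) -> dict[str, list[float]]:
    df = pd.concat(columns, axis=1)
    sub = CountTable(df, drop_empty=True)
    vs = venn_summary(sub, convention="global")
    return {
        "shared_by_3": vs.shared_pct[3],
        "shared_by_2": vs.shared_pct[2],
        "unshared": vs.unshared_pct,
    }


def spatial_separation_test(table: CountTable, within: str, across: list[str],
                            size: int = 28000, seed: int | None = None,
                            joint_partition: bool = True) -> SpatialTestResult:
    """Three within-sample subsamples vs one subsample from each of three
    other samples; per-class shared/unshared percentages and Student t-tests.

    Percentages use the global denominator (fraction of the group's total
    distinct OTUs).  The pairwise class contributes three data points (the
    three subsample pairs), the unshared class three (the three subsamples),
    and the all-three class a single point, which is reported without a test.

    By default the three within-sample subsamples are drawn jointly without
    replacement (disjoint reads).  Independent draws (overlap allowed,
    ``joint_partition=False``) make the within group systematically more
    self-similar than three subsamples of independent replicate samples even
    when no spatial structure exists, because the three nested subsamples
    share the one realized OTU pool of their source; the disjoint partition
    removes that bias and keeps the t-test calibrated under the
    no-structure null.
    """
    if len(across) != 3:
        raise ValueError("need exactly three across-sample ids")
    rng = np.random.default_rng(seed)
    if joint_partition:
        within_cols = partition_subsamples(table, within, size, 3, rng)
    else:
        within_cols = [subsample_reads(table, within, size, rng).rename(f"{within}_sub{i + 1}")
                       for i in range(3)]
    across_cols = [subsample_reads(table, s, size, rng).rename(f"{s}_sub") for s in across]

    within_pct = _group_percentages(within_cols)
    across_pct = _group_percentages(across_cols)

    tests: dict[str, tuple[float | None, float | None]] = {}
    for cls in ("shared_by_3", "shared_by_2", "unshared"):
        a, b = within_pct[cls], across_pct[cls]
        if len(a) < 2 or len(b) < 2:
            tests[cls] = (None, None)
            continue
        t, p = stats.ttest_ind(a, b)
        tests[cls] = (float(t), float(p))
    return SpatialTestResult(within_pct, across_pct, tests, size, seed)


# -- likelihood-ratio chi-squared (G) test -----------------------------------

@dataclass
class GTestResult:
    G: float
    df: int
    alpha: float
    critical_value: float
    p: float

    @property
    def significant(self) -> bool:
        return self.G > self.critical_value


def g_test(table: CountTable, alpha: float = 0.05) -> GTestResult:
    """Likelihood-ratio chi-squared homogeneity test, G = 2 sum O ln(O/E).

    Zero cells contribute nothing (x ln x -> 0); empty rows or columns are
    dropped with a warning before computing degrees of freedom.
    """
    obs = table.df.to_numpy().astype(np.float64)
    keep_rows = obs.sum(axis=1) > 0
    keep_cols = obs.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping empty rows/columns before the G test")
        obs = obs[keep_rows][:, keep_cols]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    mask = obs > 0
    g = 2.0 * float((obs[mask] * np.log(obs[mask] / expected[mask])).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return GTestResult(G=g, df=df, alpha=alpha,
                       critical_value=float(stats.chi2.ppf(1 - alpha, df)),
                       p=float(stats.chi2.sf(g, df)))


# -- rarefaction --------------------------------------------------------------

def rarefaction_curve(table: CountTable, sample: str,
                      depths: list[int] | None = None, reps: int = 10,
                      seed: int | None = None) -> pd.DataFrame:
    """Expected OTU count at each depth by resampling without replacement."""
    rng = np.random.default_rng(seed)
    col = table.column(sample).to_numpy()
    total = int(col.sum())
    if depths is None:
        depths = sorted({max(1, int(total * frac)) for frac in np.linspace(0.05, 1.0, 20)})
    rows = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds sample total {total}")
        if depth == total:
            richness = np.array([float((col > 0).sum())] * reps)
        else:
            richness = np.array([
                float((rng.multivariate_hypergeometric(col, depth) > 0).sum())
                for _ in range(reps)])
        rows.append((depth, richness.mean(),
                     richness.std(ddof=1) if reps > 1 else 0.0))
    return pd.DataFrame(rows, columns=["depth", "mean_otus", "sd_otus"])


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Exact hypergeometric expectation of richness at a given depth."""
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    # E[S_depth] = sum_i 1 - C(total - n_i, depth) / C(total, depth)
    log_denom = math.lgamma(total + 1) - math.lgamma(depth + 1) - math.lgamma(total - depth + 1)
    out = 0.0
    for n_i in counts:
        rem = total - int(n_i)
        if rem < depth:
            out += 1.0
            continue
        log_num = math.lgamma(rem + 1) - math.lgamma(depth + 1) - math.lgamma(rem - depth + 1)
        out += 1.0 - math.exp(log_num - log_denom)
    return out


# -- ordination-distance regression -------------------------------------------

@dataclass
class EmbeddingFit:
    distances: np.ndarray
    similarities: np.ndarray
    slope: float
    intercept: float
    r2: float


def embedding_r2(coordinates: np.ndarray, similarities) -> EmbeddingFit:
    """Regress pairwise Euclidean embedding distance on pairwise similarity.

    ``coordinates`` is a (k, 2) array of ordination positions;
    ``similarities`` a (k, k) symmetric matrix (e.g. Bray-Curtis) or a
    condensed vector in ``itertools.combinations`` order.  Returns the OLS
    fit; r^2 is the squared Pearson correlation of the pairs.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 3:
        raise ValueError("need >= 3 points with 2-D coordinates")
    k = coords.shape[0]
    sim = np.asarray(similarities, dtype=float)
    if sim.ndim == 2:
        pairs_sim = np.array([sim[i, j] for i in range(k) for j in range(i + 1, k)])
    else:
        if len(sim) != k * (k - 1) // 2:
            raise ValueError("condensed similarity length does not match point count")
        pairs_sim = sim
    dists = np.array([np.linalg.norm(coords[i] - coords[j])
                      for i in range(k) for j in range(i + 1, k)])
    if np.allclose(pairs_sim, pairs_sim[0]):
        raise ValueError("similarity vector is constant; r^2 undefined")
    res = stats.linregress(pairs_sim, dists)
    return EmbeddingFit(distances=dists, similarities=pairs_sim,
                        slope=float(res.slope), intercept=float(res.intercept),
                        r2=float(res.rvalue ** 2))
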