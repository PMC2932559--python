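import functools

import numpy as np
import pandas as pd
import pytest

from finescale.otu_io import CountTable
from finescale.rarity import (
    GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH, RarityCutoff, classify_rare,
    count_cutoff_for_proportion, filter_table, parse_cutoff, partition,
    percent_identity,
)

# ---------------------------------------------------------------------------
# cutoffs and partitioning
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("total,expected", [(77361, 3), (51836, 2), (76693, 3),
                                            (86240, 3), (10, 0)])
def test_proportion_to_count_cutoff(total, expected):
    assert count_cutoff_for_proportion(total, 0.00004) == expected


def test_cutoff_parsing():
    assert parse_cutoff("n=1") == RarityCutoff("count", 1, "rare")
    assert parse_cutoff("n<=5") == RarityCutoff("count", 5, "rare")
    assert parse_cutoff("n>10") == RarityCutoff("count", 10, "abundant")
    assert parse_cutoff("a<=0.004%") == RarityCutoff("proportion", 0.00004, "rare")
    assert parse_cutoff("a>1%") == RarityCutoff("proportion", 0.01, "abundant")
    with pytest.raises(ValueError):
        parse_cutoff("q<=5")


@pytest.fixture
def sample_table():
    df = pd.DataFrame({"s": [1, 2, 5, 11, 0], "t": [0, 0, 1, 1, 600]},
                      index=list("abcde"))
    return CountTable(df)


def test_partition_complementarity(sample_table):
    rare, abundant = partition(sample_table, "s", parse_cutoff("n<=10"))
    assert rare == {"a", "b", "c"} and abundant == {"d"}
    rare2, abundant2 = partition(sample_table, "s", parse_cutoff("n>10"))
    assert (rare2, abundant2) == (rare, abundant)
    assert rare | abundant == {"a", "b", "c", "d"}  # observed OTUs only


def test_partition_singletons_and_percent_abundance(sample_table):
    rare, _ = partition(sample_table, "s", parse_cutoff("n=1"))
    assert rare == {"a"}
    _, abundant = partition(sample_table, "t", parse_cutoff("a>1%"))
    assert abundant == {"e"}  # 600 of 602 reads; the two singletons sit at 0.17%


def test_filter_table_keeps_only_requested_side(sample_table):
    rare = filter_table(sample_table, parse_cutoff("n<=5"), "rare")
    assert rare.df.loc["d", "s"] == 0 and rare.df.loc["c", "s"] == 5
    abundant = filter_table(sample_table, parse_cutoff("n>10"), "abundant")
    assert set(abundant.otu_ids) == {"d", "e"}


# ---------------------------------------------------------------------------
# percent identity: independent memoized-recursion oracle with the same
# scoring grammar and canonical tie-break (score, matches, -columns)
# ---------------------------------------------------------------------------

NEG = (-10 ** 9, 0, 0)


def oracle_identity(a: str, b: str):
    """Gotoh local alignment by plain recursion over lexicographic tuples."""
    sub = {True: (MATCH, 1, -1), False: (MISMATCH, 0, -1)}
    open_, ext = (GAP_OPEN, 0, -1), (GAP_EXTEND, 0, -1)

    def add(u, v):
        return (u[0] + v[0], u[1] + v[1], u[2] + v[2])

    @functools.lru_cache(maxsize=None)
    def m(i, j):  # best alignment ending with column (a[i-1], b[j-1])
        if i == 0 or j == 0:
            return NEG
        prev = max(m(i - 1, j - 1), ix(i - 1, j - 1), iy(i - 1, j - 1), (0, 0, 0))
        return add(prev, sub[a[i - 1] == b[j - 1]])

    @functools.lru_cache(maxsize=None)
    def ix(i, j):  # ends with a gap consuming a[i-1]
        if i == 0:
            return NEG
        return max(add(m(i - 1, j), open_), add(ix(i - 1, j), ext))

    @functools.lru_cache(maxsize=None)
    def iy(i, j):  # ends with a gap consuming b[j-1]
        if j == 0:
            return NEG
        return max(add(m(i, j - 1), open_), add(iy(i, j - 1), ext))

    best = max(m(i, j) for i in range(len(a) + 1) for j in range(len(b) + 1))
    m.cache_clear(), ix.cache_clear(), iy.cache_clear()
    if best <= (0, 0, 0):
        return 0, 0, 0
    score, matches, neg_cols = best
    return score, matches, -neg_cols


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_identity_matches_oracle_on_short_random_pairs():
    rng = np.random.default_rng(12345)
    for _ in range(80):
        a = random_dna(rng, rng.integers(5, 31))
        b = random_dna(rng, rng.integers(5, 31))
        hit = percent_identity(a, b)
        score, matches, cols = oracle_identity(a, b)
        assert (hit.score, hit.matches, hit.alignment_length) == (score, matches, cols)


def test_identity_score_matches_biopython_aligner():
    from Bio import Align
    aligner = Align.PairwiseAligner(mode="local", match_score=MATCH,
                                    mismatch_score=MISMATCH,
                                    open_gap_score=GAP_OPEN,
                                    extend_gap_score=GAP_EXTEND)
    rng = np.random.default_rng(99)
    for _ in range(30):
        a = random_dna(rng, rng.integers(20, 120))
        b = random_dna(rng, rng.integers(20, 120))
        assert percent_identity(a, b).score == aligner.score(a, b)


def test_identity_identical_and_substituted_sequences():
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 120)
    hit = percent_identity(seq, seq)
    assert (hit.percent_identity, hit.alignment_length) == (100.0, 120)
    mutant = list(seq)
    for pos in rng.choice(120, size=12, replace=False):
        mutant[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[pos]]
    hit = percent_identity(seq, "".join(mutant))
    assert hit.percent_identity == pytest.approx(90.0, abs=2.0)
    assert hit.alignment_length >= 100


def test_unrelated_sequences_fail_the_length_gate():
    rng = np.random.default_rng(2024)
    short = 0
    for _ in range(20):
        hit = percent_identity(random_dna(rng, 120), random_dna(rng, 120))
        short += hit.alignment_length < 100
    assert short >= 18


def test_identity_rejects_empty():
    with pytest.raises(ValueError):
        percent_identity("", "ACGT")


# ---------------------------------------------------------------------------
# NUNN / UNN / UN classification
# ---------------------------------------------------------------------------

def mutated(seq, n_mut, rng):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


@pytest.fixture
def planted_sets():
    rng = np.random.default_rng(77)
    abundant = {"AB1": random_dna(rng, 200), "AB2": random_dna(rng, 200)}
    reference = {"REF1": random_dna(rng, 200)}
    rare = {
        "nunn1": mutated(abundant["AB1"], 10, rng),    # ~95% to abundant
        "nunn2": abundant["AB2"],                      # identical
        "unn1": mutated(reference["REF1"], 10, rng),   # ~95% to reference only
        "un1": random_dna(rng, 200),
    }
    return rare, abundant, reference


def test_classify_rare_recovers_planted_labels(planted_sets):
    rare, abundant, reference = planted_sets
    result = classify_rare(rare, abundant, reference_seqs=reference,
                           weights={"nunn1": 3, "nunn2": 5, "unn1": 1, "un1": 1})
    assert result.labels == {"nunn1": "NUNN", "nunn2": "NUNN",
                             "unn1": "UNN", "un1": "UN"}
    props = result.proportions(weighted=True)
    assert props["NUNN"] == pytest.approx(80.0)
    assert sum(props.values()) == pytest.approx(100.0)
    assert result.proportions(weighted=False)["NUNN"] == pytest.approx(50.0)


def test_classify_precedence_nunn_wins_over_reference(planted_sets):
    rare, abundant, _ = planted_sets
    # reference identical to the NUNN parent cannot steal the label
    result = classify_rare({"nunn2": rare["nunn2"]}, abundant,
                           reference_seqs={"R": rare["nunn2"]})
    assert result.labels["nunn2"] == "NUNN"


def test_classify_with_precomputed_reference_identity(planted_sets):
    rare, abundant, _ = planted_sets
    result = classify_rare({"un1": rare["un1"], "unn1": rare["unn1"]}, abundant,
                           reference_identity={"un1": 80.0, "unn1": 95.0})
    assert result.labels == {"un1": "UN", "unn1": "UNN"}


def test_classify_threshold_monotone(planted_sets):
    rare, abundant, reference = planted_sets
    counts = []
    for thr in (80.0, 90.0, 99.5):
        res = classify_rare(rare, abundant, reference_seqs=reference,
                            min_identity=thr)
        counts.append(sum(1 for v in res.labels.values() if v == "NUNN"))
    assert counts == sorted(counts, reverse=True)


def test_classify_rejects_overlapping_sets(planted_sets):
    rare, abundant, reference = planted_sets
    with pytest.raises(ValueError, match="overlap"):
        classify_rare({"AB1": abundant["AB1"]}, abundant, reference_seqs=reference)


def test_read_weighted_proportions_match_pooled_counts():
    # pooled read counts in the proportions follow the weights exactly
    rng = np.random.default_rng(8)
    parent = random_dna(rng, 150)
    rare = {"x": mutated(parent, 5, rng), "y": random_dna(rng, 150)}
    res = classify_rare(rare, {"A": parent}, reference_identity={},
                        weights={"x": 9, "y": 1})
    assert res.labels == {"x": "NUNN", "y": "UN"}
    assert res.proportions()["NUNN"] == pytest.approx(90.0)
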