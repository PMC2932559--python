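import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from finescale.beta_indices import (
    INDEX_NAMES, PresencePair, all_indices, anderberg_from_jaccard,
    pairwise_matrix, presence_pair, qualitative_indices, quantitative_indices,
    sorensen_from_jaccard, venn_summary,
)
from finescale.otu_io import CountTable

from conftest import random_table


def test_presence_pair_enumeration(toy_table):
    assert presence_pair(toy_table, "s1", "s2") == PresencePair(1, 1, 1)


def test_presence_pair_identical_and_disjoint():
    df = pd.DataFrame({"x": [1, 2, 0], "y": [3, 1, 0], "z": [0, 0, 5]},
                      index=["a", "b", "c"])
    t = CountTable(df)
    assert presence_pair(t, "x", "y") == PresencePair(2, 0, 0)
    assert presence_pair(t, "x", "z").a == 0


def test_qualitative_hand_values():
    vals = qualitative_indices(PresencePair(1, 1, 1))
    assert vals == pytest.approx(
        {"jaccard": 1 / 3, "sorensen": 1 / 2, "ochiai": 1 / 2, "anderberg": 1 / 5})
    full = qualitative_indices(PresencePair(9, 0, 0))
    assert all(v == 1.0 for v in full.values())


def test_qualitative_empty_sample_errors():
    with pytest.raises(ValueError, match="ochiai"):
        qualitative_indices(PresencePair(0, 5, 0))


def test_quantitative_hand_values(toy_table):
    vals = quantitative_indices(toy_table, "s1", "s2")
    assert vals["bray_curtis"] == pytest.approx(2 / 7)
    # plug-in theta on p=(2/3,1/3,0), q=(0,1/4,3/4)
    assert vals["theta_smith"] == pytest.approx((1 / 12) / (5 / 9 + 5 / 8 - 1 / 12))


def test_bray_curtis_matches_scipy(quad_table):
    from scipy.spatial.distance import braycurtis
    for s1, s2 in itertools.combinations(quad_table.sample_ids, 2):
        mine = quantitative_indices(quad_table, s1, s2)["bray_curtis"]
        ref = 1.0 - braycurtis(quad_table.column(s1), quad_table.column(s2))
        assert mine == pytest.approx(ref)


@given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
def test_qualitative_identities(a, b, c):
    if a + b == 0 or a + c == 0:
        return
    vals = qualitative_indices(PresencePair(a, b, c))
    j = vals["jaccard"]
    assert vals["sorensen"] == pytest.approx(sorensen_from_jaccard(j), abs=1e-12)
    assert vals["anderberg"] == pytest.approx(anderberg_from_jaccard(j), abs=1e-12)
    assert vals["anderberg"] <= j <= vals["sorensen"] + 1e-12
    assert j <= vals["ochiai"] + 1e-12


def test_all_indices_contracts_on_random_tables():
    rng = np.random.default_rng(11)
    for _ in range(20):
        t = random_table(rng)
        s1, s2 = t.sample_ids[:2]
        fwd = all_indices(t, s1, s2).as_dict()
        rev = all_indices(t, s2, s1).as_dict()
        for name in INDEX_NAMES:
            assert 0.0 <= fwd[name] <= 1.0
            assert fwd[name] == pytest.approx(rev[name], abs=1e-12)


def test_identical_columns_give_one_disjoint_give_zero():
    df = pd.DataFrame({"x": [4, 1, 1, 0], "same": [4, 1, 1, 0], "other": [0, 0, 0, 9]},
                      index=list("abcd"))
    t = CountTable(df)
    for name, v in all_indices(t, "x", "same").as_dict().items():
        assert v == pytest.approx(1.0), name
    for name, v in all_indices(t, "x", "other").as_dict().items():
        assert v == pytest.approx(0.0), name


def test_theta_yc_approaches_theta_smith_at_scale(toy_table):
    small = quantitative_indices(toy_table, "s1", "s2")
    big_df = toy_table.df * 100
    big = quantitative_indices(CountTable(big_df), "s1", "s2")
    # relative abundances unchanged, so the plug-in theta is scale-free
    assert big["theta_smith"] == pytest.approx(small["theta_smith"])
    assert abs(big["theta_yc"] - big["theta_smith"]) < \
        abs(small["theta_yc"] - small["theta_smith"])
    assert abs(big["theta_yc"] - big["theta_smith"]) < 0.01


def test_pairwise_matrix_six_pairs(quad_table):
    mat, mean, sd = pairwise_matrix(quad_table, "jaccard")
    off = [mat.iloc[i, j] for i in range(4) for j in range(i + 1, 4)]
    assert len(off) == 6
    assert np.allclose(np.diag(mat), 1.0)
    assert mean == pytest.approx(np.mean(off))
    assert sd == pytest.approx(np.std(off, ddof=1))
    # permuting sample order leaves the summary unchanged
    _, mean2, sd2 = pairwise_matrix(quad_table, "jaccard",
                                    samples=["q3", "q1", "q4", "q2"])
    assert (mean2, sd2) == pytest.approx((mean, sd))


def test_pairwise_matrix_identical_pair():
    t = CountTable(pd.DataFrame({"a": [2, 3], "b": [2, 3]}, index=["x", "y"]))
    _, mean, sd = pairwise_matrix(t, "theta_yc")
    assert (mean, sd) == (1.0, 0.0)


# -- Venn accounting ---------------------------------------------------------

def brute_force_occupancy(table: CountTable, weight: str = "otus"):
    occ = {}
    for otu in table.otu_ids:
        key = frozenset(s for s in table.sample_ids if table.df.loc[otu, s] > 0)
        add = 1 if weight == "otus" else int(table.df.loc[otu].sum())
        occ[key] = occ.get(key, 0) + add
    return occ


def test_venn_toy_two_samples(toy_table):
    vs = venn_summary(toy_table)
    assert vs.occupancy == {frozenset({"s1"}): 1, frozenset({"s2"}): 1,
                            frozenset({"s1", "s2"}): 1}
    assert vs.shared_pct[2] == [pytest.approx(100 / 3)]
    assert vs.unshared_pct == [pytest.approx(50.0), pytest.approx(50.0)]


def test_venn_all_shared():
    t = CountTable(pd.DataFrame(np.ones((5, 4), dtype=int),
                                index=list("abcde"), columns=list("wxyz")))
    vs = venn_summary(t)
    assert vs.shared_pct[4] == [100.0]
    assert vs.unshared_pct == [0.0] * 4


def test_venn_occupancy_partitions_random_tables():
    rng = np.random.default_rng(3)
    for _ in range(10):
        t = random_table(rng, n_otus=30, n_samples=4)
        vs = venn_summary(t)
        assert vs.occupancy == brute_force_occupancy(t)
        assert vs.total == t.shape[0]
        vsc = venn_summary(t, weight="clones")
        assert vsc.occupancy == brute_force_occupancy(t, "clones")
        assert vsc.total == int(t.df.to_numpy().sum())


def test_venn_global_vs_subset_denominators():
    # 4 OTUs: one in all three, one in s0+s1, two singles
    df = pd.DataFrame({"s0": [1, 1, 1, 0], "s1": [1, 1, 0, 0], "s2": [1, 0, 0, 1]},
                      index=list("abcd"))
    t = CountTable(df)
    subset = venn_summary(t, convention="subset")
    global_ = venn_summary(t, convention="global")
    # pair (s0, s1): 2 shared of 3 OTUs observed in the pair vs of 4 total
    assert subset.shared_pct[2][0] == pytest.approx(200 / 3)
    assert global_.shared_pct[2][0] == pytest.approx(50.0)
    assert global_.unshared_pct[2] == pytest.approx(25.0)   # d only in s2, of 4


def test_venn_unknown_sample_errors(toy_table):
    with pytest.raises(KeyError):
        venn_summary(toy_table, ["s1", "nope"])
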