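"""13-way pattern classification: decision table, symmetry, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triadexpress.classify import (CATEGORIES, CLASS_TABLE, class_recovery,
                                   class_summary, classify_gene,
                                   classify_matrix, parent_level_summary)


# --- independent oracle -----------------------------------------------------
# A second implementation of the decision rules, written as a flat
# precedence table over literal call patterns (wildcard None), kept
# deliberately different in structure from the package's rule chain.

_ORACLE_RULES = [
    # (s_mp, s_mh, s_ph) with None as wildcard -> class id
    (("M>P", "H>M", "H>P"), 1), (("ns", "H>M", "H>P"), 2),
    (("M<P", "H>M", "H>P"), 3),
    (("M>P", "H<M", "H<P"), 4), (("ns", "H<M", "H<P"), 5),
    (("M<P", "H<M", "H<P"), 6),
    (("M>P", "ns", "H>P"), 7), (("M>P", "ns", "H<P"), 7),
    (("M<P", "ns", "H>P"), 8), (("M<P", "ns", "H<P"), 8),
    (("M<P", "H>M", "ns"), 9), (("M<P", "H<M", "ns"), 9),
    (("M>P", "H>M", "ns"), 10), (("M>P", "H<M", "ns"), 10),
    (("M>P", "H<M", "H>P"), 11), (("M<P", "H>M", "H<P"), 12),
    (("ns", "ns", "ns"), 13),
]


def _oracle_classify(s_mp, s_mh, s_ph, mu_m, mu_h, mu_p):
    for (pat_mp, pat_mh, pat_ph), cid in _ORACLE_RULES:
        if ((pat_mp is None or pat_mp == s_mp)
                and (pat_mh is None or pat_mh == s_mh)
                and (pat_ph is None or pat_ph == s_ph)):
            return cid
    # distance fallback, written with argmin over an ordered candidate list
    candidates = [
        ("additive", abs(mu_h - (mu_m + mu_p) / 2)),
        ("ELD_M", abs(mu_h - mu_m)),
        ("ELD_P", abs(mu_h - mu_p)),
    ]
    winner = min(candidates, key=lambda kv: kv[1])[0]
    if winner == "additive":
        return {"M>P": 11, "M<P": 12, "ns": 13}[s_mp]
    if winner == "ELD_M":
        return 7 if mu_m > mu_p else 8
    return 9 if mu_p > mu_m else 10


ALL_COMBOS = list(itertools.product(("M>P", "M<P", "ns"),
                                    ("H>M", "H<M", "ns"),
                                    ("H>P", "H<P", "ns")))


@pytest.mark.parametrize("mu", [(10.0, 6.0, 2.0), (2.0, 9.0, 4.0),
                                (5.0, 5.0, 5.0), (1.0, 2.5, 8.0)])
def test_decision_table_matches_independent_oracle(mu):
    """All 27 signed-call combinations agree with the independently coded
    rule list, for several hybrid/parent mean layouts."""
    mu_m, mu_h, mu_p = mu
    for s_mp, s_mh, s_ph in ALL_COMBOS:
        cid, cat = classify_gene(s_mp, s_mh, s_ph, mu_m, mu_h, mu_p)
        expected = _oracle_classify(s_mp, s_mh, s_ph, mu_m, mu_h, mu_p)
        assert cid == expected, (s_mp, s_mh, s_ph, mu)
        assert cat == CLASS_TABLE[cid][1]


@pytest.mark.parametrize("calls,expected_cat", [
    (("M>P", "ns", "H>P"), "ELD_M"),          # H ≈ M > P
    (("ns", "ns", "ns"), "additive"),          # no differences anywhere
    (("ns", "H>M", "H>P"), "transgressive_up"),  # H above both parents
])
def test_classify_gene_examples(calls, expected_cat):
    _, cat = classify_gene(*calls, 10.0, 10.0, 10.0)
    assert cat == expected_cat


def test_malformed_call_symbol_rejected():
    with pytest.raises(ValueError, match="M vs P"):
        classify_gene("up", "ns", "ns", 1, 1, 1)
    with pytest.raises(ValueError, match="H vs M"):
        classify_gene("M>P", "bogus", "ns", 1, 1, 1)


def _swap_mp(s_mp, s_mh, s_ph, mu_m, mu_h, mu_p):
    """Relabel the two parents: M vs P flips sign, the H-vs-M and H-vs-P
    contrasts exchange roles."""
    flip_mp = {"M>P": "M<P", "M<P": "M>P", "ns": "ns"}
    mh_to_ph = {"H>M": "H>P", "H<M": "H<P", "ns": "ns"}
    ph_to_mh = {"H>P": "H>M", "H<P": "H<M", "ns": "ns"}
    return (flip_mp[s_mp], ph_to_mh[s_ph], mh_to_ph[s_mh], mu_p, mu_h, mu_m)


def test_parent_label_swap_symmetry_random_tables():
    """Exchanging the two parents maps ELD_M <-> ELD_P and preserves the
    additive and both transgressive categories."""
    rng = np.random.default_rng(17)
    swap_cat = {"ELD_M": "ELD_P", "ELD_P": "ELD_M"}
    for _ in range(500):
        s_mp = rng.choice(["M>P", "M<P", "ns"])
        s_mh = rng.choice(["H>M", "H<M", "ns"])
        s_ph = rng.choice(["H>P", "H<P", "ns"])
        mu = rng.uniform(0.1, 100, size=3)
        _, cat = classify_gene(s_mp, s_mh, s_ph, *mu)
        _, cat_sw = classify_gene(*_swap_mp(s_mp, s_mh, s_ph, *mu))
        assert cat_sw == swap_cat.get(cat, cat)


def test_every_combination_gets_exactly_one_class():
    for combo in ALL_COMBOS:
        cid, cat = classify_gene(*combo, 3.0, 7.0, 12.0)
        assert cid in CLASS_TABLE
        assert cat in CATEGORIES


# --- matrix-level classification -------------------------------------------

def _deg_frame(calls):
    return pd.DataFrame({"call": calls},
                        index=[f"g{i}" for i in range(len(calls))])


def _means_frame(mu_rows):
    return pd.DataFrame(mu_rows, columns=["mu_M", "mu_H", "mu_P"],
                        index=[f"g{i}" for i in range(len(mu_rows))])


def test_classify_matrix_toy_hand_derived():
    deg_mp = _deg_frame(["up", "ns", "down"])    # M>P, ns, M<P
    deg_mh = _deg_frame(["ns", "ns", "up"])      # ns, ns, H>M
    deg_ph = _deg_frame(["up", "ns", "down"])    # H>P, ns, H<P
    means = _means_frame([(8, 8, 2), (5, 5, 5), (2, 5, 8)])
    table = classify_matrix(deg_mp, deg_mh, deg_ph, means)
    assert list(table["category"]) == ["ELD_M", "additive", "additive"]
    assert list(table["class_id"]) == [7, 13, 12]


def test_classify_matrix_universe_mismatch():
    deg = _deg_frame(["ns", "ns"])
    other = _deg_frame(["ns", "ns", "ns"])
    with pytest.raises(ValueError, match="3 genes differ|1 genes differ"):
        classify_matrix(deg, other, deg, _means_frame([(1, 1, 1)] * 2))


def test_classify_matrix_order_equivariance():
    rng = np.random.default_rng(19)
    n = 30
    calls = lambda: _deg_frame(rng.choice(["up", "down", "ns"], size=n))
    mp, mh, ph = calls(), calls(), calls()
    means = _means_frame(rng.uniform(1, 50, size=(n, 3)))
    table = classify_matrix(mp, mh, ph, means)
    perm = rng.permutation(table.index)
    table_p = classify_matrix(mp.loc[perm], mh.loc[perm], ph.loc[perm],
                              means.loc[perm])
    pd.testing.assert_frame_equal(table.loc[perm], table_p)


# --- summaries --------------------------------------------------------------

def _table_from_class_counts(counts: dict[int, int]) -> pd.DataFrame:
    rows = []
    for cid, n in counts.items():
        label, cat, lvl = CLASS_TABLE[cid]
        rows += [{"class_id": cid, "class_label": label, "category": cat,
                  "parent_level": lvl}] * n
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])


def test_class_summary_partitions_and_rounds():
    table = _table_from_class_counts({13: 850, 7: 60, 9: 80, 1: 5, 4: 5})
    summ = class_summary(table)
    assert summ["per_category"]["count"].sum() == summ["total"] == 1000
    assert summ["per_category"].loc["additive", "pct"] == 85.00
    assert summ["per_class"]["count"].sum() == 1000


def test_single_gene_table_is_all_one_class():
    summ = class_summary(_table_from_class_counts({2: 1}))
    assert summ["per_category"].loc["transgressive_up", "pct"] == 100.00


def test_parent_level_mapping():
    # all-additive -> all mid-parent; ELD_M with M>P -> high parent
    table = _table_from_class_counts({13: 10, 11: 5})
    assert parent_level_summary(table) == {"high_parent": 0,
                                           "mid_parent": 15, "low_parent": 0}
    table2 = _table_from_class_counts({7: 3, 8: 2, 1: 1, 6: 4})
    counts = parent_level_summary(table2)
    # brute force: 7 (H≈M>P) and 1 (trans up) high; 8 and 6 low
    assert counts == {"high_parent": 4, "mid_parent": 0, "low_parent": 6}
    rng = np.random.default_rng(23)
    rand = _table_from_class_counts(
        {cid: int(n) for cid, n in enumerate(rng.integers(0, 20, 13), start=1)})
    expected = rand["parent_level"].value_counts().to_dict()
    got = parent_level_summary(rand)
    assert {k: v for k, v in got.items() if v} == expected


# --- recovery ---------------------------------------------------------------

def test_recovery_identity_is_perfect():
    table = _table_from_class_counts({13: 20, 7: 5, 9: 5})
    report = class_recovery(table, table)
    assert report.accuracy == 1.0
    assert np.all(np.diag(report.confusion) == report.confusion.sum(axis=1))


def test_recovery_constant_prediction_scores_truth_share():
    truth = _table_from_class_counts({13: 30, 7: 10})
    pred = truth.copy()
    pred["category"] = "additive"
    report = class_recovery(truth, pred)
    assert report.accuracy == pytest.approx(30 / 40)


def test_recovery_universe_mismatch_rejected():
    truth = _table_from_class_counts({13: 3})
    pred = _table_from_class_counts({13: 4})
    with pytest.raises(ValueError, match="differ"):
        class_recovery(truth, pred)
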