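"""FPKM, replicate averaging/correlation, expressed-gene calling, overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triadexpress.expression import (expressed_genes, fpkm, mean_replicates,
                                     overlap, overlap_to_frame, replicate_r2)

from conftest import make_matrix


def _counts(values, **kw):
    n = np.asarray(values).shape[1]
    per = n // 3
    return make_matrix(values,
                       genotypes=["M"] * per + ["H"] * per + ["P"] * per,
                       daps=[3] * n,
                       reps=list(range(1, per + 1)) * 3, **kw)


# --- FPKM -------------------------------------------------------------------

def test_fpkm_unit_definition():
    """1 fragment on a 1 kb gene in a 1M-fragment library is 1.0 FPKM."""
    em = make_matrix([[1.0], [999_999.0]], genotypes=["M"], daps=[3], reps=[1])
    out = fpkm(em, {"g0": 1000, "g1": 500})
    assert out.values.iloc[0, 0] == pytest.approx(1.0)
    assert out.unit == "fpkm"


def test_fpkm_zero_counts_stay_zero():
    em = make_matrix([[0.0], [10.0]], genotypes=["M"], daps=[3], reps=[1])
    out = fpkm(em, {"g0": 1000, "g1": 500})
    assert out.values.iloc[0, 0] == 0.0


def test_fpkm_scale_invariance():
    """Multiplying every count of one sample by a constant leaves that
    sample's FPKM column unchanged (depth cancels)."""
    rng = np.random.default_rng(0)
    vals = rng.integers(1, 500, size=(20, 3)).astype(float)
    em = _counts(vals)
    lengths = {g: int(l) for g, l in
               zip(em.gene_ids, rng.integers(200, 3000, size=20))}
    base = fpkm(em, lengths)
    for factor in (2.0, 7.5):
        scaled_vals = vals.copy()
        scaled_vals[:, 1] *= factor
        scaled = fpkm(_counts(scaled_vals), lengths)
        np.testing.assert_allclose(scaled.values.iloc[:, 1],
                                   base.values.iloc[:, 1])


def test_fpkm_missing_length_and_zero_total_errors():
    em = make_matrix([[1.0], [2.0]], genotypes=["M"], daps=[3], reps=[1])
    with pytest.raises(ValueError, match="g1"):
        fpkm(em, {"g0": 1000})
    empty = make_matrix([[0.0], [0.0]], genotypes=["M"], daps=[3], reps=[1])
    with pytest.raises(ValueError, match="zero total"):
        fpkm(empty, {"g0": 1000, "g1": 500})


# --- replicate averaging ----------------------------------------------------

def test_mean_replicates_examples_and_bruteforce():
    rng = np.random.default_rng(2)
    vals = rng.uniform(0, 50, size=(10, 9))
    em = _counts(vals)
    means = mean_replicates(em)
    assert means.values.shape == (10, 3)
    # brute-force per-cell mean
    for j, geno in enumerate(("M", "H", "P")):
        expected = vals[:, 3 * j: 3 * j + 3].mean(axis=1)
        np.testing.assert_allclose(means.values[f"{geno}_d3"], expected)
    # identical replicates -> mean equals each replicate
    const = _counts(np.tile([[1.0], [7.0]], (1, 9)))
    m2 = mean_replicates(const)
    assert (m2.values.iloc[0] == 1.0).all()
    # replicates (1, 2, 3) -> 2
    tri = _counts(np.array([[1, 2, 3, 0, 0, 0, 0, 0, 0]], dtype=float))
    assert mean_replicates(tri).values.loc["g0", "M_d3"] == 2.0


# --- replicate correlation --------------------------------------------------

def test_replicate_r2_perfect_cases():
    vals = np.array([[1, 1, 2, 4], [5, 5, 10, 20], [9, 9, 18, 36],
                     [2, 2, 4, 8]], dtype=float)
    em = make_matrix(vals, genotypes=["M", "M", "H", "H"], daps=[3] * 4,
                     reps=[1, 2, 1, 2])
    per_group, grand = replicate_r2(em, log=False)
    # duplicated replicate columns -> R^2 = 1; y = 2x -> R^2 = 1
    assert per_group[("M", 3)] == pytest.approx(1.0)
    assert per_group[("H", 3)] == pytest.approx(1.0)
    assert grand == pytest.approx(1.0)


def test_replicate_r2_matches_bruteforce_pairwise_pearson():
    rng = np.random.default_rng(3)
    vals = rng.uniform(0, 100, size=(5, 3))
    em = make_matrix(vals, genotypes=["M"] * 3, daps=[3] * 3, reps=[1, 2, 3])
    per_group, _ = replicate_r2(em)
    logv = np.log2(vals + 1)
    expected = np.mean([np.corrcoef(logv[:, i], logv[:, j])[0, 1] ** 2
                        for i, j in itertools.combinations(range(3), 2)])
    assert per_group[("M", 3)] == pytest.approx(expected)


def test_replicate_r2_invariant_under_replicate_permutation():
    rng = np.random.default_rng(4)
    vals = rng.uniform(0, 100, size=(8, 3))
    em = make_matrix(vals, genotypes=["M"] * 3, daps=[3] * 3, reps=[1, 2, 3])
    em_perm = make_matrix(vals[:, [2, 0, 1]], genotypes=["M"] * 3,
                          daps=[3] * 3, reps=[1, 2, 3])
    assert replicate_r2(em)[1] == pytest.approx(replicate_r2(em_perm)[1])


def test_replicate_r2_excludes_constant_replicate_with_warning(caplog):
    vals = np.array([[1, 5, 2], [1, 7, 4], [1, 2, 9]], dtype=float)
    em = make_matrix(vals, genotypes=["M"] * 3, daps=[3] * 3, reps=[1, 2, 3])
    with caplog.at_level("WARNING"):
        per_group, _ = replicate_r2(em)
    assert "constant replicate" in caplog.text
    # only the (rep2, rep3) pair remains
    logv = np.log2(vals + 1)
    expected = np.corrcoef(logv[:, 1], logv[:, 2])[0, 1] ** 2
    assert per_group[("M", 3)] == pytest.approx(expected)


# --- expressed genes --------------------------------------------------------

def test_expressed_genes_thresholds(triad_matrix):
    # threshold 0: every gene with nonzero mean
    assert expressed_genes(triad_matrix, "M", 3, 0) == {"g0", "g2", "g3"}
    # threshold above the max -> empty set
    assert expressed_genes(triad_matrix, "M", 3, 1e6) == set()
    # brute-force filter equivalence on the replicate means
    means = triad_matrix.group_values("H", 3).mean(axis=1)
    assert expressed_genes(triad_matrix, "H", 3, 5.0) == \
        set(means.index[means >= 5.0])


# --- overlap ----------------------------------------------------------------

def test_overlap_identical_sets_are_fully_shared():
    s = set(range(50))
    ov = overlap({"a": set(s), "b": set(s), "c": set(s)})
    assert ov.core_count == 50
    assert all(f == 100.0 for f in ov.overlap_fraction.values())


def test_overlap_core_fraction_formatting():
    """A 17,691-gene core of a 23,516-gene set is 75.23% shared."""
    core = set(range(17_691))
    full = core | {f"x{i}" for i in range(23_516 - 17_691)}
    other = core | {f"y{i}" for i in range(100)}
    ov = overlap({"g": full, "h": other})
    assert ov.overlap_fraction["g"] == 75.23


def test_overlap_regions_match_bruteforce_enumeration():
    rng = np.random.default_rng(6)
    universe = list(range(60))
    sets = {lab: {g for g in universe if rng.random() < p}
            for lab, p in (("a", 0.5), ("b", 0.4), ("c", 0.6))}
    ov = overlap(sets)
    for pattern, count in ov.region_counts.items():
        members = [g for g in set().union(*sets.values())
                   if all((g in sets[lab]) == (lab in pattern)
                          for lab in sets)]
        assert count == len(members)
    # Venn conservation: regions partition the union
    assert ov.union_size() == len(set().union(*sets.values()))
    # per-set totals recovered from regions containing the set
    for lab in sets:
        assert sum(n for pat, n in ov.region_counts.items()
                   if lab in pat) == len(sets[lab])
    frame = overlap_to_frame(ov)
    assert frame["count"].sum() == ov.union_size()


def test_overlap_requires_two_sets():
    with pytest.raises(ValueError):
        overlap({"only": {1, 2}})
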