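import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb

import coregenes as cg
from coregenes.functional_profiles import (read_matrix_tsv, write_matrix_tsv)
from conftest import gene


def _ann(mapping):
    return cg.CogAnnotation({g: cg.CogEntry(cog, cat)
                             for g, (cog, cat) in mapping.items()})


def _genome(genome_id, gene_ids):
    return cg.GenomeGeneSet(
        genome_id=genome_id,
        genes=[gene(g, genome_id, "ACGT" * 25) for g in gene_ids])


def test_build_cog_matrix_counts_copies():
    ann = _ann({
        "g1_a": ("C1", "J"), "g1_b": ("C1", "J"), "g1_c": ("C2", "K"),
        "g2_a": ("C2", "K"),
    })
    m = cg.build_cog_matrix(
        [_genome("g1", ["g1_a", "g1_b", "g1_c", "g1_d"]),
         _genome("g2", ["g2_a"]),
         _genome("g3", ["g3_a"])], ann)
    assert list(m.index) == ["g1", "g2", "g3"]
    assert list(m.columns) == ["C1", "C2"]
    assert m.loc["g1", "C1"] == 2      # paralog copies both counted
    assert m.loc["g1", "C2"] == 1
    assert m.loc["g2", "C2"] == 1
    assert m.loc["g3"].sum() == 0      # unannotated genome keeps a zero row


def test_column_filter_strict_boundary():
    # 10 genomes, fraction 0.10 -> threshold 1.0:
    # a column summing to exactly 1 is kept, 0 is removed
    data = {"kept_exact": [1] + [0] * 9,
            "kept_big": [3] * 10,
            "dropped": [0] * 10}
    m = pd.DataFrame(data, index=[f"g{i}" for i in range(10)])
    out = cg.filter_low_abundance_columns(m, 0.10)
    assert list(out.columns) == ["kept_exact", "kept_big"]
    # 20 genomes -> threshold 2.0: a single copy is now below the bar
    m20 = pd.DataFrame({"one": [1] + [0] * 19, "two": [1, 1] + [0] * 18},
                       index=[f"g{i}" for i in range(20)])
    out20 = cg.filter_low_abundance_columns(m20, 0.10)
    assert list(out20.columns) == ["two"]


def test_column_filter_idempotent_and_validated():
    m = pd.DataFrame({"a": [1, 1, 0], "b": [0, 0, 0]}, index=list("xyz"))
    once = cg.filter_low_abundance_columns(m, 0.10)
    assert cg.filter_low_abundance_columns(once, 0.10).equals(once)
    with pytest.raises(ValueError):
        cg.filter_low_abundance_columns(m, 0.0)
    with pytest.raises(ValueError):
        cg.filter_low_abundance_columns(m, 1.0)
    with pytest.raises(ValueError, match="all columns"):
        cg.filter_low_abundance_columns(
            pd.DataFrame({"b": [0, 0, 0]}, index=list("xyz")), 0.10)


def test_functional_tree_matches_scipy_cophenetic():
    """Dual route: tip-to-tip distances == scipy's cophenetic distances."""
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.integers(0, 5, size=(6, 8)),
                     index=[f"g{i}" for i in range(6)],
                     columns=[f"C{i}" for i in range(8)])
    tree = cg.functional_tree(m)
    got = cg.leaf_path_distances(tree)
    z = linkage(pdist(m.values, metric="cityblock"), method="average")
    expected = squareform(cophenet(z))
    for i in range(6):
        for j in range(6):
            assert got[f"g{i}", f"g{j}"] == pytest.approx(expected[i, j])


def test_functional_tree_row_order_invariant():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.integers(0, 4, size=(5, 6)),
                     index=[f"g{i}" for i in range(5)],
                     columns=[f"C{i}" for i in range(6)])
    t1 = cg.functional_tree(m)
    t2 = cg.functional_tree(m.iloc[::-1])
    d1, d2 = cg.leaf_path_distances(t1), cg.leaf_path_distances(t2)
    for i in m.index:
        for j in m.index:
            assert d1[i, j] == pytest.approx(d2[i, j])


def test_functional_tree_groups_similar_profiles():
    m = pd.DataFrame({"C1": [5, 5, 0, 0], "C2": [0, 0, 5, 5],
                      "C3": [1, 1, 1, 1]},
                     index=["a1", "a2", "b1", "b2"])
    d = cg.leaf_path_distances(cg.functional_tree(m))
    assert d["a1", "a2"] == 0.0
    assert d["a1", "b1"] > 0
    with pytest.raises(ValueError, match="at least 3"):
        cg.functional_tree(m.iloc[:2])


def _family(members):
    per = {}
    for m in members:
        per.setdefault(m.split("_")[0], []).append(m)
    return cg.CoreFamily("f", "c", tuple(sorted(members)),
                         {g: tuple(v) for g, v in per.items()})


def test_assign_family_category_majority():
    ann = _ann({"g1_a": ("C1", "J"), "g2_a": ("C1", "J"),
                "g3_a": ("C2", "K"), "g4_a": ("C9", "J")})
    fam = _family(["g1_a", "g2_a", "g3_a", "g4_a"])
    assert cg.assign_family_category(fam, ann) == "J"  # 3/4 >= 0.5


def test_assign_family_category_tie_and_unannotated():
    ann = _ann({"g1_a": ("C1", "J"), "g2_a": ("C2", "K")})
    fam = _family(["g1_a", "g2_a"])
    assert cg.assign_family_category(fam, ann) == cg.UNASSIGNED
    empty = _family(["g1_x", "g2_x"])
    assert cg.assign_family_category(empty, ann) == cg.UNASSIGNED
    # below-half plurality is unassigned too
    ann3 = _ann({"g1_a": ("C1", "J"), "g2_a": ("C2", "K"),
                 "g3_a": ("C3", "L")})
    assert cg.assign_family_category(
        _family(["g1_a", "g2_a", "g3_a"]), ann3) == cg.UNASSIGNED


def test_assign_family_category_multi_letter_fractional():
    # two "KT" members contribute 0.5 K + 0.5 T each: K reaches exactly
    # half together with one integral K member out of 4
    ann = _ann({"g1_a": ("C1", "KT"), "g2_a": ("C1", "KT"),
                "g3_a": ("C2", "K"), "g4_a": ("C3", "J")})
    fam = _family(["g1_a", "g2_a", "g3_a", "g4_a"])
    assert cg.assign_family_category(fam, ann) == "K"  # (0.5+0.5+1)/4 = 0.5


def _core_set(genes_by_family):
    fams = [CoreFamilyHelper(i, genes)
            for i, genes in enumerate(genes_by_family)]
    return cg.CladeCoreSet("clade", [f.fam for f in fams], 2)


class CoreFamilyHelper:
    def __init__(self, i, genes):
        self.fam = _family(genes)


def test_enrichment_exact_hypergeometric_value():
    # N=10 annotated background, K=5 in category J, n=3 core draws, k=3:
    # p = C(5,3)/C(10,3) = 10/120
    ann = {}
    for i in range(5):
        ann[f"g1_j{i}"] = ("CJ%d" % i, "J")
    for i in range(5):
        ann[f"g2_k{i}"] = ("CK%d" % i, "K")
    ann = _ann(ann)
    core = _core_set([["g1_j0"], ["g1_j1"], ["g1_j2"]])
    background = sorted(ann.entries)
    res = {r.category: r for r in
           cg.category_enrichment(core, ann, background)}
    assert res["J"].k == 3 and res["J"].n == 3
    assert res["J"].K == 5 and res["J"].N == 10
    assert res["J"].p_value == pytest.approx(10 / 120)
    assert not res["J"].enriched  # 0.0833 is not below 0.05
    assert res["J"].percent == pytest.approx(100.0)
    assert res["K"].k == 0 and res["K"].p_value == pytest.approx(1.0)
    assert not res["K"].enriched


def test_enrichment_brute_force_sum():
    """Dual route: p equals the explicit combinatorial upper-tail sum."""
    ann = {}
    for i in range(12):
        ann[f"g1_a{i}"] = (f"C{i}", "J" if i < 7 else "O")
    ann = _ann(ann)
    core = _core_set([[f"g1_a{i}"] for i in (0, 1, 2, 7, 8)])
    res = {r.category: r for r in
           cg.category_enrichment(core, ann, sorted(ann.entries))}
    N, K, n, k = 12, 7, 5, 3
    expected = sum(comb(K, x) * comb(N - K, n - x)
                   for x in range(k, min(K, n) + 1)) / comb(N, n)
    assert res["J"].p_value == pytest.approx(float(expected))


def test_enrichment_monotone_in_k():
    ann = {}
    for i in range(20):
        ann[f"g1_a{i}"] = (f"C{i}", "J" if i < 10 else "O")
    ann = _ann(ann)
    background = sorted(ann.entries)
    pvals = []
    for k in range(0, 5):
        picks = [f"g1_a{i}" for i in range(k)] + \
            [f"g1_a{10 + i}" for i in range(4 - k)]
        core = _core_set([[p] for p in picks])
        res = {r.category: r for r in
               cg.category_enrichment(core, ann, background)}
        pvals.append(res["J"].p_value)
    assert all(a > b for a, b in zip(pvals, pvals[1:]))


def test_enrichment_copies_counted_and_unannotated_excluded():
    ann = _ann({"g1_a": ("C1", "J"), "g1_b": ("C1", "J"),
                "g2_a": ("C2", "O"), "g2_b": ("C3", "O")})
    core = _core_set([["g1_a", "g1_b"]])  # paralog pair: two copies
    res = {r.category: r for r in cg.category_enrichment(
        core, ann, ["g1_a", "g1_b", "g2_a", "g2_b", "g9_unannotated"])}
    assert res["J"].n == 2 and res["J"].k == 2 and res["J"].N == 4
    empty = _core_set([["g9_unannotated"]])
    assert cg.category_enrichment(empty, ann, sorted(ann.entries)) == []


def test_enrichment_bh_correction_is_more_conservative():
    rng = np.random.default_rng(2)
    ann = {}
    cats = "JKLMO"
    for i in range(50):
        ann[f"g1_a{i}"] = (f"C{i}", cats[i % 5])
    ann = _ann(ann)
    core = _core_set([[f"g1_a{5 * i}"] for i in range(6)])  # all J
    raw = cg.category_enrichment(core, ann, sorted(ann.entries))
    bh = cg.category_enrichment(core, ann, sorted(ann.entries),
                                bh_correct=True)
    assert sum(r.enriched for r in bh) <= sum(r.enriched for r in raw)


def test_annotation_tsv_roundtrip(tmp_path):
    ann = _ann({"a": ("C1", "J"), "b": ("C2", "KT")})
    p = tmp_path / "ann.tsv"
    ann.to_tsv(p)
    back = cg.CogAnnotation.from_tsv(p)
    assert back.entries == ann.entries
    assert "a" in back and back["a"].category == "J"
    assert back.get("zz") is None and len(back) == 2


def test_matrix_tsv_roundtrip(tmp_path):
    m = pd.DataFrame({"C1": [1, 0], "C2": [2, 3]}, index=["g1", "g2"])
    m.index.name = "genome_id"
    p = tmp_path / "m.tsv"
    write_matrix_tsv(m, p)
    back = read_matrix_tsv(p)
    assert back.equals(m)
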