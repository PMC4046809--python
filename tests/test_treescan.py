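from __future__ import annotations

import numpy as np
import pytest

from _oracles import clade_oracle
from hgtscreen.synthetic_data import random_unrooted_tree, serialize_rooted_at
from hgtscreen.taxonomy import Group
from hgtscreen.treescan import (
    DONOR_GROUPS_DEFAULT,
    batch_screen,
    clade_test,
    load_manifest,
    parse_tree,
)

TAXON_OF = {
    "Q": "Monosiga", "Q2": "Monosiga", "SR": "Salpingoeca",
    "B1": "Escherichia", "B2": "Bacillus", "A1": "Ostreococcus",
    "A2": "Thalassiosira", "H1": "Homo", "H2": "Drosophila",
    "F1": "Saccharomyces", "E1": "Dictyostelium",
}


def tree_of(newick, scheme, query="Q"):
    return parse_tree(newick, scheme, query, taxon_of=TAXON_OF)


# ---------------------------------------------------------------------------
# parsing

def test_parse_round_trip_five_leaves(scheme):
    t = tree_of("((Q:1,B1:1)95:1,(H1:1,F1:1)90:1,A1:1);", scheme)
    assert sorted(t.leaves) == ["A1", "B1", "F1", "H1", "Q"]
    supports = sorted(v for v in t.splits.values() if v is not None)
    assert supports == [90.0, 95.0]
    assert t.groups["A1"] is Group.ALGA and t.groups["Q"] is Group.SELF


def test_duplicate_leaf_labels_rejected(scheme):
    with pytest.raises(ValueError, match="duplicate"):
        tree_of("((Q,B1),(B1,A1));", scheme)


def test_missing_query_rejected(scheme):
    with pytest.raises(ValueError, match="query"):
        tree_of("((B1,B2),(H1,A1));", scheme)


def test_unmappable_leaf_names_the_leaf(scheme):
    with pytest.raises(ValueError, match="XYZ"):
        parse_tree("((Q,XYZ),(H1,A1));", scheme, "Q", taxon_of=TAXON_OF)


def test_supports_absent_is_valid(scheme):
    t = tree_of("((Q,B1),(H1,F1),A1);", scheme)
    assert all(v is None for v in t.splits.values())
    assert not clade_test(t, min_support=50).passed  # fail-closed


def test_zero_threshold_accepts_unsupported_edges(scheme):
    t = tree_of("((Q,B1),(H1,F1),A1);", scheme)
    assert clade_test(t, min_support=0).passed


def test_dual_supports_use_minimum_by_default(scheme):
    t = tree_of("((Q,B1)95/62:1,(H1,F1),A1);", scheme)
    assert 62.0 in t.splits.values()
    t_first = parse_tree("((Q,B1)95/62:1,(H1,F1),A1);", scheme, "Q",
                         taxon_of=TAXON_OF, dual_support="first")
    assert 95.0 in t_first.splits.values()


def test_asterisk_support_means_unknown(scheme):
    t = tree_of("((Q,B1)*,(H1,F1),A1);", scheme)
    assert not clade_test(t, min_support=50).passed


def test_fractional_supports_rescaled(scheme):
    t = tree_of("((Q,B1)0.95,(H1,F1)0.8,A1);", scheme)
    assert clade_test(t, min_support=90).passed


def test_out_of_range_support_rejected(scheme):
    with pytest.raises(ValueError, match="support"):
        tree_of("((Q,B1)150,(H1,F1),A1);", scheme)


# ---------------------------------------------------------------------------
# clade test semantics

def test_query_with_donor_sister_passes(scheme):
    result = clade_test(tree_of("((Q,B1)95,((H1,H2),F1));", scheme), min_support=70)
    assert result.passed and result.support == 95.0
    assert result.clade_leaves == {"Q", "B1"}
    assert result.donor_composition == {Group.PROKARYOTE: 1}


def test_query_sister_to_metazoan_fails_with_reason(scheme):
    result = clade_test(tree_of("((Q,H1)99,(B1,B2));", scheme), min_support=70)
    assert not result.passed and result.violation == "kin_in_clade"


def test_weak_support_reported_as_insufficient(scheme):
    result = clade_test(tree_of("((Q,B1)60,(H1,F1),A1);", scheme), min_support=70)
    assert not result.passed and result.violation == "insufficient_support"


def test_no_donor_leaves_reported(scheme):
    result = clade_test(tree_of("((Q,E1)99,(H1,F1));", scheme), min_support=70)
    assert not result.passed and result.violation == "no_donor_leaves"


def test_smallest_passing_clade_reported(scheme):
    t = tree_of("(((Q,B1)90,B2)95,(H1,F1),A1);", scheme)
    result = clade_test(t, min_support=70)
    assert result.passed and result.clade_leaves == {"Q", "B1"}


def test_self_leaves_always_allowed_in_clade(scheme):
    t = tree_of("(((Q,SR)99,B1)95,(H1,F1),A1);", scheme)
    result = clade_test(t, min_support=70)
    assert result.passed and result.clade_leaves == {"Q", "SR", "B1"}


def test_other_euk_policy_lenient_vs_strict(scheme):
    t = tree_of("(((Q,E1)88,B1)95,(H1,F1),A1);", scheme)
    assert clade_test(t, min_support=70, allowed_other="lenient").passed
    assert not clade_test(t, min_support=70, allowed_other="strict").passed


def test_restricted_donor_group_set(scheme):
    t = tree_of("((Q,B1)95,(H1,F1),A1);", scheme)
    assert clade_test(t, donor_groups=frozenset({Group.PROKARYOTE}), min_support=70).passed
    assert not clade_test(t, donor_groups=frozenset({Group.ALGA}), min_support=70).passed


def test_mixed_donor_composition_counted(scheme):
    t = tree_of("(((Q,A1)90,B1)85,(H1,F1),A2);", scheme)
    result = clade_test(t, min_support=70)
    assert result.passed
    assert result.clade_leaves == {"Q", "A1"}
    assert result.donor_composition == {Group.ALGA: 1}


# ---------------------------------------------------------------------------
# oracle equivalence and invariances on random trees

def _random_case(rng, scheme, n_leaves):
    adj, supports, groups = random_unrooted_tree(rng, n_leaves)
    internals = [n for n in adj if str(n).startswith("I")]
    newick = serialize_rooted_at(adj, supports, internals[0])
    taxon_of = {
        leaf: {
            Group.KIN: "Homo", Group.PROKARYOTE: "Escherichia",
            Group.ALGA: "Ostreococcus", Group.OTHER_EUK: "Dictyostelium",
            Group.SELF: "Monosiga",
        }[g]
        for leaf, g in groups.items()
    }
    tree = parse_tree(newick, scheme, "Q", taxon_of=taxon_of)
    return adj, supports, groups, internals, newick, tree


def test_clade_test_matches_exhaustive_enumeration(scheme):
    rng = np.random.default_rng(2024)
    for _ in range(120):
        n_leaves = int(rng.integers(4, 13))
        min_support = float(rng.choice([0, 50, 70, 90]))
        _, _, groups, _, newick, tree = _random_case(rng, scheme, n_leaves)
        result = clade_test(tree, min_support=min_support)
        passed, smallest, passing, support_of = clade_oracle(
            newick, groups, "Q", DONOR_GROUPS_DEFAULT, min_support
        )
        assert result.passed == passed
        if passed:
            assert len(result.clade_leaves) == smallest
            assert result.clade_leaves in passing
            assert result.support == support_of[result.clade_leaves]


def test_support_threshold_monotonicity_on_random_trees(scheme):
    rng = np.random.default_rng(99)
    trees = [_random_case(rng, scheme, int(rng.integers(5, 12)))[5] for _ in range(40)]
    previous = None
    for min_support in (50, 70, 90):
        passing = {i for i, t in enumerate(trees)
                   if clade_test(t, min_support=min_support).passed}
        if previous is not None:
            assert passing <= previous
        previous = passing


def test_rerooting_and_child_permutation_invariance(scheme):
    rng = np.random.default_rng(7)
    for _ in range(25):
        adj, supports, groups, internals, newick, tree = _random_case(
            rng, scheme, int(rng.integers(5, 12))
        )
        reference = clade_test(tree, min_support=70)
        for _ in range(4):
            root = internals[int(rng.integers(len(internals)))]
            child_order = {
                node: list(rng.permutation(np.array(adj[node], dtype=object)))
                for node in internals
            }
            alt_newick = serialize_rooted_at(adj, supports, root, child_order)
            taxon_of = {
                leaf: {
                    Group.KIN: "Homo", Group.PROKARYOTE: "Escherichia",
                    Group.ALGA: "Ostreococcus", Group.OTHER_EUK: "Dictyostelium",
                    Group.SELF: "Monosiga",
                }[g]
                for leaf, g in groups.items()
            }
            alt_tree = parse_tree(alt_newick, scheme, "Q", taxon_of=taxon_of)
            alt = clade_test(alt_tree, min_support=70)
            assert alt.passed == reference.passed
            assert alt.clade_leaves == reference.clade_leaves
            assert alt.support == reference.support


# ---------------------------------------------------------------------------
# batch screening

def test_batch_screen_counts_planted_donor_clades(clean_bundle):
    verdicts = batch_screen(clean_bundle.trees, min_support=50)
    truth_hgt = set(clean_bundle.truth.loc[clean_bundle.truth["is_hgt"], "gene_id"])
    assert verdicts.predicted("treescan") == truth_hgt


def test_batch_screen_all_below_threshold_predicts_none(scheme):
    trees = {
        "q1": tree_of("((Q,B1)40,(H1,F1),A1);", scheme),
        "q2": tree_of("((Q,A1)30,(H1,F1),B1);", scheme),
    }
    verdicts = batch_screen(trees, min_support=50)
    assert verdicts.predicted("treescan") == set()


def test_manifest_loading_skips_broken_trees(tmp_path, scheme):
    good = tmp_path / "good.nwk"
    good.write_text("((Q,B1)95,(H1,F1),A1);\n")
    bad = tmp_path / "bad.nwk"
    bad.write_text("((Q,B1)95,(H1,F1);\n")  # unbalanced
    manifest = tmp_path / "manifest.tsv"
    manifest.write_text(
        "tree_path\tquery\n"
        f"good.nwk\tQ\n"
        f"bad.nwk\tQ\n"
        f"missing.nwk\tQ\n"
    )
    trees, errors = load_manifest(manifest, scheme, taxon_of=TAXON_OF)
    assert list(trees) == ["Q"]
    assert len(errors) == 2
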