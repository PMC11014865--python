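import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracle import oracle_best_edge, oracle_classify
from plastosort import fixtures as fx
from plastosort.sorter import (
    GroupBounds,
    SortCriterion,
    best_supported_edge,
    classify_origin,
    criterion_for_category,
    family_affiliation,
    summarize_calls,
    tally_internal_topology,
    OriginCall,
)
from plastosort.taxa import CategoryDef
from plastosort.treeio import parse_tree_file, reroot_at

from conftest import LEAF, expand


def tree_of(template: str):
    return parse_tree_file(expand(template))[0]


PLASTID_LATE = CategoryDef("plastid-late", "haptophytes")


class TestBestSupportedEdge:
    def test_single_qualifying_edge(self, scheme):
        tree = tree_of("((seed,(h1,h2)90)70,(d1,d2)99);")
        crit = criterion_for_category(PLASTID_LATE, scheme)
        support, side = best_supported_edge(tree, LEAF["seed"], crit, scheme)
        assert support == 70.0
        assert side == frozenset({LEAF["seed"], LEAF["h1"], LEAF["h2"]})

    def test_absent_group_yields_none(self, scheme):
        tree = tree_of("((seed,(h1,h2)90)70,(d1,d2)99);")
        crit = SortCriterion(group_bounds={"green": GroupBounds(min_count=2)})
        assert best_supported_edge(tree, LEAF["seed"], crit, scheme) is None

    def test_maximum_support_wins_among_nested_qualifiers(self, scheme):
        tree = tree_of("(((seed,h1)60,h2)85,(d1,d2)99);")
        crit = criterion_for_category(PLASTID_LATE, scheme)
        support, side = best_supported_edge(tree, LEAF["seed"], crit, scheme)
        assert support == 85.0
        assert side == frozenset({LEAF["seed"], LEAF["h1"], LEAF["h2"]})

    def test_seed_absent_raises(self, scheme):
        tree = tree_of("((h1,h2)90,(d1,d2)99);")
        crit = criterion_for_category(PLASTID_LATE, scheme)
        with pytest.raises(KeyError):
            best_supported_edge(tree, "not_there", crit, scheme)

    def test_unresolvable_leaf_raises(self, scheme):
        tree = parse_tree_file(
            expand("((seed,(h1,mystery_leaf)90)70,(d1,d2)99);")
        )[0]
        crit = criterion_for_category(PLASTID_LATE, scheme)
        with pytest.raises(ValueError, match="unresolvable"):
            best_supported_edge(tree, LEAF["seed"], crit, scheme)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5_000), n=st.integers(5, 12))
    def test_min_count_monotonicity(self, scheme, seed, n):
        """Raising a min bound can only lose qualifying edges."""
        rng = np.random.default_rng(seed)
        tree, query = fx.random_mixed_tree(n, rng)

        def result(min_count):
            crit = SortCriterion(
                group_bounds={"haptophytes": GroupBounds(min_count=min_count)},
                restrict_to="haptophytes",
            )
            return best_supported_edge(tree, query, crit, scheme)

        previous = result(1)
        for k in (2, 3, 4):
            current = result(k)
            if previous is None:
                assert current is None
            elif current is not None:
                assert current[0] <= previous[0] or current == previous
            previous = current


class TestClassifyOrigin:
    # expectations frozen from the brute-force oracle; degenerate rooted
    # quartets legitimately expose complement-side clades
    @pytest.mark.parametrize(
        "template,expected_category,expected_score",
        [
            ("((seed,(h1,h2)90)70,(d1,d2)99);", "plastid-early", 90.0),
            ("((seed,(d1,d2)88)80,(cil1,cil2)95);", "alveolate", 88.0),
            ("((seed,(h1,h2)90)70,(b1,g1)99);", "plastid-late", 70.0),
            ("((seed,(g1,g2)92)81,(b1,mz1)99);", "green-LGT", 81.0),
            ("((seed,(p1,p2)97)66,(h1,g1)99);", "prokaryote-LGT", 66.0),
        ],
    )
    def test_frozen_examples_match_oracle(
        self, scheme, categories, template, expected_category, expected_score
    ):
        tree = tree_of(template)
        call = classify_origin(tree, LEAF["seed"], categories, scheme)
        assert (call.category, call.score) == (expected_category, expected_score)
        assert oracle_classify(tree, LEAF["seed"], categories, scheme) == (
            expected_category,
            expected_score,
        )

    def test_threshold_flag(self, scheme, categories):
        tree = tree_of("((seed,(h1,h2)90)74,(b1,g1)99);")
        call = classify_origin(tree, LEAF["seed"], categories, scheme)
        assert call.score == 74.0 and not call.passed_threshold
        tree = tree_of("((seed,(h1,h2)90)75,(b1,g1)99);")
        call = classify_origin(tree, LEAF["seed"], categories, scheme)
        assert call.passed_threshold

    def test_witness_required_for_alveolate(self, scheme, categories):
        """A pure dinoflagellate clade with no ciliate must not be absorbed
        by the wider pan-alveolate category."""
        tree = tree_of("((seed,(d1,d2)88)80,(b1,(g1,g2)70)95);")
        call = classify_origin(tree, LEAF["seed"], categories, scheme)
        assert call.category == "plastid-early"
        assert call.score == 80.0

    def test_nonnested_tie_is_unresolved(self, scheme, categories):
        tree, seed = fx.planted_nonnested_tie(85.0)
        call = classify_origin(tree, seed, categories, scheme)
        assert call.category == "unresolved"
        assert call.score == 85.0

    def test_nested_tie_selects_wider_category(self, scheme, categories):
        tree, seed, narrower, wider = fx.planted_nested_tie(85.0)
        call = classify_origin(tree, seed, categories, scheme)
        assert call.category == wider
        assert call.score == 85.0

    def test_nothing_qualifies_is_unresolved_scoreless(self, scheme, categories):
        tree = tree_of("((seed,(h1,g1)90)70,(d1,b1)99);")
        call = classify_origin(tree, LEAF["seed"], categories, scheme)
        assert call.category == "unresolved"
        assert call.score is None

    def test_neutral_seed_lineage_leaves_do_not_break_purity(
        self, scheme, categories
    ):
        tree = tree_of("((seed,((h1,kar1)82,h2)90)70,(d1,d2)99);")
        call = classify_origin(tree, LEAF["seed"], categories, scheme)
        assert call.category == "plastid-early"  # complement side, support 90
        # restrict to late-vs-LGT categories: kareniacean leaf stays neutral
        late_only = [PLASTID_LATE, CategoryDef("green-LGT", "green")]
        call = classify_origin(tree, LEAF["seed"], late_only, scheme)
        assert call.category == "plastid-late"
        assert call.score == 70.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 20_000), n=st.integers(5, 12))
    def test_matches_bruteforce_oracle_on_random_trees(
        self, scheme, categories, seed, n
    ):
        rng = np.random.default_rng(seed)
        tree, query = fx.random_mixed_tree(n, rng)
        call = classify_origin(tree, query, categories, scheme)
        assert (call.category, call.score) == oracle_classify(
            tree, query, categories, scheme
        )
        for category in categories:
            mine = best_supported_edge(
                tree, query, criterion_for_category(category, scheme), scheme
            )
            assert mine == oracle_best_edge(tree, query, category, scheme)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5_000))
    def test_rooting_invariance(self, scheme, categories, seed):
        tree, truth = fx.simulate_origin_tree(
            fx.PlantedTreeSpec(
                category="plastid-late", support=88.0, clade_size=3,
                n_background_leaves=7, rng_seed=seed,
            )
        )
        reference = classify_origin(tree, truth["seed"], categories, scheme)
        for leaf in sorted(tree.leaves)[::4]:
            rerooted = reroot_at(tree, leaf)
            call = classify_origin(rerooted, truth["seed"], categories, scheme)
            assert (call.category, call.score) == (
                reference.category,
                reference.score,
            )


class TestFamilyAffiliation:
    def test_pure_family_clade(self, scheme):
        tree = tree_of("((seed,(chry1,chry2)92)85,(d1,d2)99);")
        # score is the support of the seed-containing side's own edge (85);
        # the 92 edge subtends the family clade whose seed side is impure
        assert family_affiliation(tree, LEAF["seed"], scheme) == (
            "Chrysochromulinaceae",
            85.0,
        )

    def test_mixed_family_clade_yields_none(self, scheme):
        tree = tree_of("((seed,(chry1,iso1)92)52,(d1,d2)99);")
        assert family_affiliation(tree, LEAF["seed"], scheme) == (None, None)

    def test_single_family_neighbour_yields_none(self, scheme):
        tree = tree_of("(((seed,chry1)93,d1)88,(d2,cil1)99);")
        assert family_affiliation(tree, LEAF["seed"], scheme) == (None, None)


class TestTopologyTally:
    def test_two_genus_clade_with_monophyly(self, scheme):
        tree = tree_of("(((kar1,kld1)91,tak1)88,(h1,h2)99);")
        call = tally_internal_topology(tree, scheme)
        assert call.topology == "KL|T"
        assert call.score == 91.0
        assert call.kareniaceae_monophyletic

    def test_star_tree_ambiguous(self, scheme):
        tree = tree_of("(kar1,kld1,tak1,h1);")
        call = tally_internal_topology(tree, scheme)
        assert call.topology == "ambiguous"
        assert not call.kareniaceae_monophyletic

    def test_missing_genus_ambiguous(self, scheme):
        tree = tree_of("(((kar1,kld1)91,h3)88,(h1,h2)99);")
        assert tally_internal_topology(tree, scheme).topology == "ambiguous"

    def test_impure_two_genus_side_does_not_count(self, scheme):
        tree = tree_of("((((kar1,kld1)91,h3)88,tak1)70,(h1,h2)99);")
        call = tally_internal_topology(tree, scheme)
        assert call.topology == "KL|T"  # only the pure {kar1,kld1} side
        assert call.score == 91.0
        assert not call.kareniaceae_monophyletic

    def test_alternative_topology(self, scheme):
        tree = tree_of("(((kld1,tak1)76,kar1)60,(h1,h2)99);")
        call = tally_internal_topology(tree, scheme)
        assert call.topology == "LT|K"
        assert call.score == 76.0

    def test_rooting_invariance(self, scheme):
        tree = tree_of("(((kar1,kld1)91,tak1)88,(h1,h2)99);")
        reference = tally_internal_topology(tree, scheme)
        for leaf in sorted(tree.leaves):
            call = tally_internal_topology(reroot_at(tree, leaf), scheme)
            assert (call.topology, call.score, call.kareniaceae_monophyletic) == (
                reference.topology,
                reference.score,
                reference.kareniaceae_monophyletic,
            )


class TestSummaries:
    def test_origin_proportions(self):
        calls = [
            OriginCall(seed=f"s{i}", category="plastid-late", score=90.0)
            for i in range(3)
        ] + [OriginCall(seed="s3", category="plastid-early", score=80.0)]
        table = summarize_calls(calls).set_index("category")
        assert table.loc["plastid-late", "proportion"] == pytest.approx(0.75)
        assert table.loc["plastid-early", "proportion"] == pytest.approx(0.25)
        assert abs(table["proportion"].dropna().sum() - 1.0) < 1e-9

    def test_all_unresolved_counts_without_proportions(self):
        calls = [OriginCall(seed=f"s{i}", category="unresolved") for i in range(4)]
        table = summarize_calls(calls).set_index("category")
        assert table.loc["unresolved", "count"] == 4
        assert table["proportion"].isna().all()

    def test_topology_counts_include_zero_rows(self, scheme):
        trees = [
            tree_of("(((kar1,kld1)91,tak1)88,(h1,h2)99);"),
            tree_of("(((kar1,kld1)91,tak1)88,(h1,h2)99);"),
            tree_of("(((kld1,tak1)76,kar1)60,(h1,h2)99);"),
            tree_of("(kar1,kld1,tak1,h1);"),
        ]
        calls = [tally_internal_topology(t, scheme) for t in trees]
        table = summarize_calls(calls).set_index("category")
        assert table["count"].to_dict() == {
            "KL|T": 2, "KT|L": 0, "LT|K": 1, "ambiguous": 1,
        }

    def test_empty_input(self):
        assert summarize_calls([]).empty
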