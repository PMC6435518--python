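import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trimodenet import (
    ContentProfile,
    EnrichedTerm,
    GeneSet,
    GeneSetCollection,
    TargetSet,
    ValidationError,
    enrich_terms,
    minmax_norm,
    pathway_scores,
    term_weights,
)
from _oracles import hypergeom_tail_enumeration


def term(tid, members, p, r):
    return EnrichedTerm(term_id=tid, name=tid, members=tuple(members),
                        p_value=p, ratio=r)


class TestMinmaxNorm:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3], [0, 0.5, 1]),
            ([7, 7, 7], [0, 0, 0]),
            ([5], [0]),
        ],
    )
    def test_definition_and_degenerate_cases(self, values, expected):
        assert minmax_norm(values) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            minmax_norm([1.0, float("nan")])
        with pytest.raises(ValidationError):
            minmax_norm([])

    @given(
        values=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
        scale=st.floats(0.01, 100),
        shift=st.floats(-100, 100),
    )
    def test_invariant_under_positive_affine_transform(self, values, scale, shift):
        from hypothesis import assume

        spread = max(values) - min(values)
        assume(spread == 0 or spread > 1e-3)  # keep the transform well-conditioned
        base = minmax_norm(values)
        transformed = minmax_norm([scale * v + shift for v in values])
        assert transformed == pytest.approx(base, abs=1e-7)


class TestEnrichTerms:
    def test_exact_tail_on_ten_gene_universe(self):
        universe = [f"G{i}" for i in range(10)]
        targets = TargetSet("t", "component", frozenset(universe[:3]))
        coll = GeneSetCollection((GeneSet("T1", "x", tuple(universe[:3])),))
        (out,) = enrich_terms(targets, coll, universe)
        assert out.p_value == pytest.approx(1 / 120)
        assert out.ratio == 1.0
        assert out.members == tuple(sorted(universe[:3]))

    def test_disjoint_term_omitted(self):
        universe = [f"G{i}" for i in range(8)]
        targets = TargetSet("t", "component", frozenset(universe[:2]))
        coll = GeneSetCollection((GeneSet("T1", "x", tuple(universe[4:])),))
        assert enrich_terms(targets, coll, universe) == []

    def test_saturated_targets_give_p_one(self):
        universe = [f"G{i}" for i in range(9)]
        targets = TargetSet("t", "component", frozenset(universe))
        coll = GeneSetCollection((GeneSet("T1", "x", tuple(universe[:4])),))
        (out,) = enrich_terms(targets, coll, universe)
        assert out.p_value == pytest.approx(1.0)
        assert out.ratio == pytest.approx(4 / 9)

    def test_targets_outside_universe_rejected(self):
        targets = TargetSet("t", "component", frozenset({"X"}))
        coll = GeneSetCollection((GeneSet("T1", "x", ("A",)),))
        with pytest.raises(ValidationError):
            enrich_terms(targets, coll, ["A", "B"])

    def test_matches_exhaustive_enumeration_on_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_univ = int(rng.integers(5, 13))
            universe = frozenset(f"G{i}" for i in range(n_univ))
            term_members = frozenset(
                rng.choice(sorted(universe), size=rng.integers(2, n_univ), replace=False)
            )
            targets = frozenset(
                rng.choice(sorted(universe), size=rng.integers(2, 5), replace=False)
            )
            if not term_members & targets:
                continue
            coll = GeneSetCollection((GeneSet("T1", "x", tuple(sorted(term_members))),))
            (out,) = enrich_terms(
                TargetSet("t", "component", targets), coll, universe
            )
            expected = hypergeom_tail_enumeration(universe, term_members, targets)
            assert out.p_value == pytest.approx(expected, rel=1e-9)


class TestTermWeights:
    def test_hand_arithmetic_oracle(self):
        terms = [
            term("a", ["X"], 1e-2, 0.1),
            term("b", ["X"], 1e-3, 0.2),
            term("c", ["X"], 1e-4, 0.4),
        ]
        w = term_weights("comp", terms)
        assert [w.weights[t] for t in "abc"] == pytest.approx([0, 5 / 12, 1])

    def test_single_term_gets_zero(self):
        w = term_weights("comp", [term("a", ["X"], 1e-2, 0.1)])
        assert w.weights == {"a": 0.0}

    def test_identical_terms_all_zero(self):
        terms = [term("a", ["X"], 1e-2, 0.1), term("b", ["X"], 1e-2, 0.1)]
        assert set(term_weights("comp", terms).weights.values()) == {0.0}

    def test_empty_term_list_rejected(self):
        with pytest.raises(ValidationError):
            term_weights("comp", [])

    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.01, 1.0),
                st.floats(1e-30, 1.0, allow_nan=False),
            ),
            min_size=1,
            max_size=15,
        )
    )
    def test_log_base_is_immaterial(self, data):
        terms = [
            term(f"t{i}", ["X"], p, r) for i, (r, p) in enumerate(data)
        ]
        w10 = term_weights("e", terms, log_base=10.0)
        we = term_weights("e", terms, log_base=math.e)
        for tid in w10.weights:
            assert w10.weights[tid] == pytest.approx(we.weights[tid], abs=1e-9)

    @given(
        data=st.lists(
            st.tuples(st.floats(0.01, 1.0), st.floats(1e-20, 1.0)),
            min_size=2,
            max_size=10,
        )
    )
    def test_weights_bounded_and_attain_extremes(self, data):
        terms = [term(f"t{i}", ["X"], p, r) for i, (r, p) in enumerate(data)]
        w = term_weights("e", terms)
        vals = list(w.weights.values())
        assert all(0.0 <= v <= 1.0 for v in vals)
        raws = {(round(r, 12), round(p, 18)) for r, p in data}
        if len(raws) >= 2 and max(vals) > 0:
            assert min(vals) == 0.0
            assert max(vals) == 1.0


class TestPathwayScores:
    def test_single_component_max_pathway_scores_two(self):
        terms = {
            "c": [term("P1", ["X"], 1e-4, 0.4), term("P2", ["X"], 1e-2, 0.1)]
        }
        content = ContentProfile({"c": 1.0})
        out = pathway_scores(terms, content)
        assert out[0].pathway_id == "P1"
        assert out[0].score == pytest.approx(2.0)

    def test_absent_pathway_not_reported(self):
        terms = {"c": [term("P1", ["X"], 1e-4, 0.4), term("P2", ["X"], 1e-2, 0.1)]}
        out = pathway_scores(terms, ContentProfile({"c": 1.0}))
        assert {s.pathway_id for s in out} == {"P1", "P2"}

    def test_content_weighted_sum_across_components(self):
        # in each component the pathway has max ratio, tied p: raw = 1.0
        per_comp = {
            "c1": [term("P", ["X"], 1e-2, 0.4), term("Q", ["X"], 1e-2, 0.1)],
            "c2": [term("P", ["X"], 1e-2, 0.5), term("R", ["X"], 1e-2, 0.2)],
        }
        content = ContentProfile({"c1": 1.0, "c2": 3.0})  # R = 0.25, 0.75
        out = pathway_scores(per_comp, content)
        score = {s.pathway_id: s.score for s in out}
        assert score["P"] == pytest.approx(1.0)

    def test_component_missing_from_content_rejected(self):
        terms = {"c": [term("P1", ["X"], 1e-4, 0.4)]}
        with pytest.raises(ValidationError):
            pathway_scores(terms, ContentProfile({"other": 1.0}))

    def test_linear_in_content_ratio(self):
        per_comp = {
            "c1": [term("P", ["X"], 1e-3, 0.4), term("Q", ["X"], 1e-2, 0.1)],
            "c2": [term("Q", ["X"], 1e-4, 0.5), term("R", ["X"], 1e-2, 0.2)],
        }
        base = {
            s.pathway_id: s.score
            for s in pathway_scores(per_comp, ContentProfile({"c1": 1.0, "c2": 1.0}))
        }
        skew = {
            s.pathway_id: s.score
            for s in pathway_scores(per_comp, ContentProfile({"c1": 3.0, "c2": 1.0}))
        }
        # doubling c1's share per the R_i formula: contributions scale exactly
        assert skew["P"] == pytest.approx(base["P"] * (3 / 4) / (1 / 2))
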