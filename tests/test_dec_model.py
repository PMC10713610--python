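"""DEC/DEC+J state space, rates, cladogenesis, likelihood, and marginals.

The likelihood and marginal reconstructions are pinned against a
brute-force enumeration oracle (tests/dec_oracle.py) on tiny instances.
"""

import numpy as np
import pytest

from montaves.dec_model import (
    AreaCatalog,
    DECError,
    DECParams,
    build_q_matrix,
    build_state_space,
    clado_event_table,
    fit_ml,
    log_likelihood,
    marginal_node_probs,
    read_tip_states,
)
from montaves.treekit import parse_tree

from dec_oracle import enumerate_likelihood

AB = AreaCatalog(("A", "B"))


def masks(catalog, *namegroups):
    return [catalog.mask(*g) for g in namegroups]


class TestStateSpace:
    @pytest.mark.parametrize(
        "n_areas,cap,null,expected",
        [(2, 2, True, 4), (9, 9, True, 512), (4, 2, False, 10)],
    )
    def test_sizes(self, n_areas, cap, null, expected):
        cat = AreaCatalog(tuple(f"a{i}" for i in range(n_areas)))
        space = build_state_space(cat, cap, include_null=null)
        assert space.n_states == expected

    def test_ordering_popcount_then_mask(self):
        space = build_state_space(AreaCatalog(("A", "B", "C")))
        sizes = [int(m).bit_count() for m in space.states]
        assert sizes == sorted(sizes)
        assert space.states[0] == 0  # null first
        # within a popcount class, bitmask ascending
        singles = [int(m) for m in space.states if int(m).bit_count() == 1]
        assert singles == sorted(singles)

    def test_cap_error(self):
        with pytest.raises(DECError):
            build_state_space(AB, 0)


class TestQMatrix:
    def test_two_area_rates(self):
        space = build_state_space(AB)
        q = build_q_matrix(space, DECParams(d=0.1, e=0.05)).toarray()
        i = {int(m): k for k, m in enumerate(space.states)}
        a, b, ab, null = i[1], i[2], i[3], i[0]
        assert q[a, ab] == pytest.approx(0.1)
        assert q[a, null] == pytest.approx(0.05)
        assert q[a, a] == pytest.approx(-0.15)
        # widespread range: loses either area at e, no room to gain
        assert q[ab, a] == pytest.approx(0.05)
        assert q[ab, b] == pytest.approx(0.05)
        assert q[ab, ab] == pytest.approx(-0.10)
        assert np.allclose(q[null], 0)  # null absorbing

    def test_dispersal_scales_with_source_areas(self):
        cat = AreaCatalog(("A", "B", "C"))
        space = build_state_space(cat)
        q = build_q_matrix(space, DECParams(d=0.2, e=0.0)).toarray()
        ab, abc = space.index[cat.mask("A", "B")], space.index[cat.mask("A", "B", "C")]
        assert q[ab, abc] == pytest.approx(0.4)  # two source areas

    def test_zero_params_zero_matrix(self):
        space = build_state_space(AB)
        q = build_q_matrix(space, DECParams(d=0.0, e=0.0))
        assert q.nnz == 0 or np.allclose(q.toarray(), 0)

    def test_rows_sum_to_zero_offdiag_nonneg(self):
        cat = AreaCatalog(tuple("ABCD"))
        space = build_state_space(cat)
        q = build_q_matrix(space, DECParams(d=0.13, e=0.07)).toarray()
        assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
        off = q - np.diag(np.diag(q))
        assert (off >= 0).all()


class TestCladoTable:
    def test_single_area_copy(self):
        space = build_state_space(AB)
        table = clado_event_table(space, DECParams(d=0.1, e=0.1, j=0.0))
        a = AB.mask("A")
        assert table[a] == [(a, a, 1.0)]

    def test_widespread_six_ordered_events(self):
        space = build_state_space(AB)
        table = clado_event_table(space, DECParams(d=0.1, e=0.1))
        events = table[AB.mask("A", "B")]
        assert len(events) == 6
        assert all(p == pytest.approx(1 / 6) for _, _, p in events)
        kinds = {(l, r) for l, r, _ in events}
        assert (AB.mask("A"), AB.mask("B")) in kinds  # vicariance
        assert (AB.mask("A", "B"), AB.mask("A")) in kinds  # subset sympatry

    def test_founder_weighting(self):
        space = build_state_space(AB)
        table = clado_event_table(space, DECParams(d=0.1, e=0.1, j=1.0))
        events = {(l, r): p for l, r, p in table[AB.mask("A")]}
        a, b = AB.mask("A"), AB.mask("B")
        assert events[(a, a)] == pytest.approx(2 / 4)
        assert events[(a, b)] == pytest.approx(1 / 4)
        assert events[(b, a)] == pytest.approx(1 / 4)

    def test_probabilities_sum_to_one(self):
        cat = AreaCatalog(tuple("ABCD"))
        space = build_state_space(cat)
        for j in (0.0, 0.7):
            table = clado_event_table(space, DECParams(d=0.1, e=0.1, j=j))
            for m, events in table.items():
                assert sum(p for _, _, p in events) == pytest.approx(1.0)


def _fs(catalog, mask):
    return frozenset(i for i in range(catalog.n) if mask >> i & 1)


class TestLikelihoodVsOracle:
    @pytest.mark.parametrize("j", [0.0, 0.8], ids=["DEC", "DEC+J"])
    def test_two_tip(self, j):
        tree = parse_tree("(x:1.5,y:1.5);")
        tips = {"x": AB.mask("A"), "y": AB.mask("B")}
        params = DECParams(d=0.3, e=0.1, j=j)
        ll = log_likelihood(tree, tips, params, catalog=AB)
        oracle_ll, _ = enumerate_likelihood(
            tree, {k: _fs(AB, v) for k, v in tips.items()}, 2,
            d=0.3, e=0.1, j=j,
        )
        assert ll == pytest.approx(oracle_ll, abs=1e-8)

    @pytest.mark.parametrize("j", [0.0, 0.5], ids=["DEC", "DEC+J"])
    def test_four_tip(self, j):
        tree = parse_tree("((x:1,y:1):1,(z:0.5,w:0.5):1.5);")
        tips = {
            "x": AB.mask("A"),
            "y": AB.mask("A", "B"),
            "z": AB.mask("B"),
            "w": AB.mask("B"),
        }
        params = DECParams(d=0.2, e=0.15, j=j)
        ll = log_likelihood(tree, tips, params, catalog=AB)
        oracle_ll, _ = enumerate_likelihood(
            tree, {k: _fs(AB, v) for k, v in tips.items()}, 2,
            d=0.2, e=0.15, j=j,
        )
        assert ll == pytest.approx(oracle_ll, abs=1e-8)

    def test_rotation_and_reorder_invariance(self):
        tips = {"x": AB.mask("A"), "y": AB.mask("B"), "z": AB.mask("A", "B")}
        params = DECParams(d=0.2, e=0.1)
        t1 = parse_tree("((x:1,y:1):2,z:3);")
        t2 = parse_tree("(z:3,(y:1,x:1):2);")
        assert log_likelihood(t1, tips, params, catalog=AB) == pytest.approx(
            log_likelihood(t2, tips, params, catalog=AB), abs=1e-12
        )

    def test_catalog_label_invariance(self):
        """Elevation/migration reuse the same code path: renaming areas
        cannot change the likelihood."""
        elev = AreaCatalog(("Lowland", "Montane"))
        tree = parse_tree("((x:1,y:1):2,z:3);")
        params = DECParams(d=0.2, e=0.1)
        ll_ab = log_likelihood(
            tree,
            {"x": 1, "y": 2, "z": 3},
            params,
            catalog=AB,
        )
        ll_elev = log_likelihood(
            tree,
            {"x": 1, "y": 2, "z": 3},
            params,
            catalog=elev,
        )
        assert ll_ab == pytest.approx(ll_elev, abs=1e-12)

    def test_errors(self):
        tree = parse_tree("(x:1,y:1,z:1);")
        with pytest.raises(Exception, match="bifurcating"):
            log_likelihood(
                tree, {"x": 1, "y": 1, "z": 1}, DECParams(d=0.1, e=0.1),
                catalog=AB,
            )
        tree2 = parse_tree("(x:1,y:1);")
        with pytest.raises(DECError, match="no observed state"):
            log_likelihood(tree2, {"x": 1}, DECParams(d=0.1, e=0.1), catalog=AB)


class TestMarginals:
    def test_tip_vectors_are_indicators(self):
        tree = parse_tree("(x:1,y:1);")
        tips = {"x": AB.mask("A"), "y": AB.mask("B")}
        res = marginal_node_probs(tree, tips, DECParams(d=0.2, e=0.1), catalog=AB)
        ix = tree.tip_index("x")
        v = res.node_probs[ix]
        assert v.sum() == pytest.approx(1.0)
        assert res.state_prob(ix, AB.mask("A")) == 1.0

    @pytest.mark.parametrize("j", [0.0, 0.5], ids=["DEC", "DEC+J"])
    def test_against_enumeration(self, j):
        tree = parse_tree("((x:1,y:1):1,(z:0.5,w:0.5):1.5);")
        tips = {
            "x": AB.mask("A"),
            "y": AB.mask("A", "B"),
            "z": AB.mask("B"),
            "w": AB.mask("B"),
        }
        res = marginal_node_probs(
            tree, tips, DECParams(d=0.2, e=0.15, j=j), catalog=AB
        )
        _, oracle_marg = enumerate_likelihood(
            tree, {k: _fs(AB, v) for k, v in tips.items()}, 2,
            d=0.2, e=0.15, j=j,
        )
        for node, dist in oracle_marg.items():
            for state, p in dist.items():
                mask = sum(1 << a for a in state)
                assert res.state_prob(node, mask) == pytest.approx(p, abs=1e-8)
            assert res.node_probs[node].sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_process_limit(self):
        """With d = e = 0 and both tips in A, the root must be A."""
        tree = parse_tree("(x:1,y:1);")
        tips = {"x": AB.mask("A"), "y": AB.mask("A")}
        res = marginal_node_probs(tree, tips, DECParams(d=0.0, e=0.0), catalog=AB)
        assert res.state_prob(tree.root, AB.mask("A")) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_data():
    from montaves.synthetic_data import sim_birth_death_tree, sim_dec_history

    tree = sim_birth_death_tree(12, birth=0.5, seed=7)
    tips, _ = sim_dec_history(
        tree, AB, DECParams(d=0.15, e=0.05), AB.mask("A"), seed=7
    )
    return tree, tips


class TestFit:
    def test_aic_formula_and_nesting(self, small_data):
        tree, tips = small_data
        dec = fit_ml(tree, tips, model="DEC", catalog=AB)
        decj = fit_ml(tree, tips, model="DEC+J", catalog=AB)
        assert dec.aic == pytest.approx(2 * 2 - 2 * dec.lnL)
        assert decj.aic == pytest.approx(2 * 3 - 2 * decj.lnL)
        # DEC nests inside DEC+J at j = 0
        assert decj.lnL >= dec.lnL - 1e-6

    def test_deterministic_given_seed(self, small_data):
        tree, tips = small_data
        a = fit_ml(tree, tips, model="DEC", catalog=AB, seed=3)
        b = fit_ml(tree, tips, model="DEC", catalog=AB, seed=3)
        assert (a.params.d, a.params.e, a.lnL) == (b.params.d, b.params.e, b.lnL)

    def test_probability_vectors_normalized(self, small_data):
        tree, tips = small_data
        res = fit_ml(tree, tips, model="DEC", catalog=AB)
        for v in res.node_probs.values():
            assert v.sum() == pytest.approx(1.0, abs=1e-9)


class TestTipStateIO:
    def test_read_table_with_merge_map(self, tmp_path):
        cat = AreaCatalog(
            ("Palearctic", "Wallacea", "Pacific"),
            merge_map={"Wallacea": "Islands", "Pacific": "Islands"},
        )
        p = tmp_path / "tips.tsv"
        p.write_text(
            "species\tPalearctic\tWallacea\tPacific\n"
            "sp1\t1\t0\t0\n"
            "sp2\t0\t1\t1\n"
            "sp3\t1\t1\t0\n"
        )
        states = read_tip_states(p, cat)
        merged, _ = cat.merged()
        assert merged.names == ("Palearctic", "Islands")
        assert states["sp1"] == merged.mask("Palearctic")
        assert states["sp2"] == merged.mask("Islands")
        assert states["sp3"] == merged.mask("Palearctic", "Islands")

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "tips.tsv"
        p.write_text("species\tA\nsp1\t1\n")
        with pytest.raises(DECError, match="B"):
            read_tip_states(p, AB)
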