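"""Source-node tracing and trait-ancestry rules."""

import numpy as np
import pytest

from montaves.ancestry_tracing import (
    AUSTRALO_PAPUAN,
    EURASIAN,
    AreaGroup,
    TracingError,
    area_group_probability,
    classify_species,
    classifications_to_frame,
    dedupe_source_nodes,
    migration_ancestry,
    montane_ancestry_probability,
    trace_source_node,
)
from montaves.dec_model import (
    AreaCatalog,
    DECParams,
    ELEVATION_AREAS,
    MIGRATION_AREAS,
    ReconstructionResult,
    build_state_space,
)
from montaves.treekit import parse_tree

GEO = AreaCatalog(("Palearctic", "Indomalaya", "Wallacea", "Australo-Papua"))
GEO_SPACE = build_state_space(GEO)
ELEV_SPACE = build_state_space(AreaCatalog(ELEVATION_AREAS))
MIG_SPACE = build_state_space(AreaCatalog(MIGRATION_AREAS))


def probs_from(space, assignment: dict[int, float]) -> np.ndarray:
    v = np.zeros(space.n_states)
    for mask, p in assignment.items():
        v[space.index[mask]] = p
    return v


def fake_recon(space, node_probs: dict[int, dict[int, float]]):
    return ReconstructionResult(
        space=space,
        params=DECParams(d=0.1, e=0.1),
        lnL=0.0,
        aic=0.0,
        model="DEC",
        node_probs={n: probs_from(space, d) for n, d in node_probs.items()},
    )


class TestAreaGroupProbability:
    def test_composite_split_evenly(self):
        # certain "Australo-Papua + Wallacea" counts 50% Australo-Papuan
        p = probs_from(GEO_SPACE, {GEO.mask("Australo-Papua", "Wallacea"): 1.0})
        assert area_group_probability(p, GEO_SPACE, AUSTRALO_PAPUAN) == pytest.approx(0.5)

    def test_both_members(self):
        p = probs_from(GEO_SPACE, {GEO.mask("Palearctic", "Indomalaya"): 1.0})
        assert area_group_probability(p, GEO_SPACE, EURASIAN) == pytest.approx(1.0)

    def test_mixture(self):
        p = probs_from(
            GEO_SPACE,
            {
                GEO.mask("Palearctic", "Indomalaya", "Wallacea"): 0.9,
                GEO.mask("Wallacea"): 0.1,
            },
        )
        assert area_group_probability(p, GEO_SPACE, EURASIAN) == pytest.approx(0.6)

    def test_null_mass_rejected(self):
        p = probs_from(GEO_SPACE, {0: 0.1, GEO.mask("Wallacea"): 0.9})
        with pytest.raises(TracingError, match="null"):
            area_group_probability(p, GEO_SPACE, EURASIAN)

    def test_disjoint_cover_sums_to_one(self):
        groups = [AreaGroup(n, (n,)) for n in GEO.names]
        rng = np.random.default_rng(0)
        p = np.zeros(GEO_SPACE.n_states)
        raw = rng.random(GEO_SPACE.n_states - 1)
        p[1:] = raw / raw.sum()  # leave null at 0
        total = sum(area_group_probability(p, GEO_SPACE, g) for g in groups)
        assert total == pytest.approx(1.0)


class TestTraceSourceNode:
    # tree: tips x(3), y(4); internals: parent of x,y is node 1; root 0
    tree = parse_tree("((x:1,y:1):2,z:3);")

    def nodes(self):
        t = self.tree
        inner = int(t.parent[t.tip_index("x")])
        return t, inner, t.root

    def test_parent_crosses_immediately(self):
        t, inner, root = self.nodes()
        recon = fake_recon(
            GEO_SPACE,
            {
                inner: {GEO.mask("Palearctic", "Indomalaya"): 0.9,
                        GEO.mask("Wallacea"): 0.1},
                root: {GEO.mask("Wallacea"): 1.0},
            },
        )
        cl = trace_source_node(t, recon, "x")
        assert cl.origin == "Eurasian"
        assert cl.nodes_counted == 1
        assert cl.source_node == inner
        assert cl.p_origin == pytest.approx(0.9)
        assert cl.source_node_age == pytest.approx(1.0)

    def test_walks_past_weak_node(self):
        t, inner, root = self.nodes()
        recon = fake_recon(
            GEO_SPACE,
            {
                inner: {GEO.mask("Australo-Papua"): 0.6, GEO.mask("Wallacea"): 0.4},
                root: {GEO.mask("Australo-Papua"): 0.8, GEO.mask("Wallacea"): 0.2},
            },
        )
        cl = trace_source_node(t, recon, "x")
        assert cl.origin == "Australo-Papuan"
        assert cl.nodes_counted == 2
        assert cl.source_node == root

    def test_unresolved_when_never_crossing(self):
        t, inner, root = self.nodes()
        recon = fake_recon(
            GEO_SPACE,
            {
                inner: {GEO.mask("Wallacea"): 1.0},
                root: {GEO.mask("Australo-Papua"): 0.75, GEO.mask("Wallacea"): 0.25},
            },
        )
        cl = trace_source_node(t, recon, "x")
        # exactly 0.75 does not cross the strict > 75% threshold
        assert cl.origin == "unresolved"
        assert cl.source_node is None
        assert cl.p_origin == pytest.approx(0.75)

    def test_threshold_monotonicity(self):
        """Raising the threshold never shortens the rootward walk."""
        t, inner, root = self.nodes()
        recon = fake_recon(
            GEO_SPACE,
            {
                inner: {GEO.mask("Palearctic", "Indomalaya"): 0.8,
                        GEO.mask("Wallacea"): 0.2},
                root: {GEO.mask("Palearctic", "Indomalaya"): 0.95,
                       GEO.mask("Wallacea"): 0.05},
            },
        )
        prev = 0
        for thr in (0.5, 0.75, 0.9):
            cl = trace_source_node(t, recon, "x", threshold=thr)
            assert cl.nodes_counted >= prev
            prev = cl.nodes_counted


ELEV = ELEV_SPACE.catalog
MIG = MIG_SPACE.catalog


class TestTraitAncestry:
    @pytest.mark.parametrize(
        "assignment,expected",
        [
            ({ELEV.mask("Montane"): 0.6, ELEV.mask("Lowland"): 0.1,
              ELEV.mask("Lowland", "Montane"): 0.3}, 0.75),
            ({ELEV.mask("Lowland", "Montane"): 1.0}, 0.5),
            ({ELEV.mask("Montane"): 1.0}, 1.0),
        ],
    )
    def test_montane_ancestry(self, assignment, expected):
        p = probs_from(ELEV_SPACE, assignment)
        assert montane_ancestry_probability(p, ELEV_SPACE) == pytest.approx(expected)

    def test_migration_inclusion_sums(self):
        p = probs_from(
            MIG_SPACE,
            {MIG.mask("Sedentary"): 0.3, MIG.mask("Sedentary", "Short"): 0.5,
             MIG.mask("Short"): 0.2},
        )
        out = migration_ancestry(p, MIG_SPACE)
        assert out == pytest.approx(
            {"sedentary": 0.8, "short": 0.7, "long": 0.0, "any_movement": 0.7}
        )

    def test_pure_sedentary(self):
        p = probs_from(MIG_SPACE, {MIG.mask("Sedentary"): 1.0})
        out = migration_ancestry(p, MIG_SPACE)
        assert out == pytest.approx(
            {"sedentary": 1.0, "short": 0.0, "long": 0.0, "any_movement": 0.0}
        )

    def test_uniform_over_seven_states(self):
        p = np.zeros(MIG_SPACE.n_states)
        for i, m in enumerate(MIG_SPACE.states):
            if int(m):
                p[i] = 1 / 7
        out = migration_ancestry(p, MIG_SPACE)
        assert out["sedentary"] == pytest.approx(4 / 7)

    def test_rules_are_deliberately_asymmetric(self):
        """Elevation splits composite mass 50/50; migration uses inclusion.
        Guard against 'unifying' the two rules."""
        both_elev = probs_from(ELEV_SPACE, {ELEV.mask("Lowland", "Montane"): 1.0})
        assert montane_ancestry_probability(both_elev, ELEV_SPACE) == 0.5
        both_mig = probs_from(MIG_SPACE, {MIG.mask("Sedentary", "Short"): 1.0})
        assert migration_ancestry(both_mig, MIG_SPACE)["sedentary"] == 1.0


class TestDedupe:
    tree = parse_tree("(((a:1,b:1):1,c:2):1,d:3);")

    def _recon(self):
        t = self.tree
        ab = int(t.parent[t.tip_index("a")])
        abc = int(t.parent[ab])
        eur = {GEO.mask("Palearctic", "Indomalaya"): 1.0}
        wal = {GEO.mask("Wallacea"): 1.0}
        return fake_recon(GEO_SPACE, {ab: eur, abc: wal, t.root: wal}), ab

    def test_shared_node_counted_once(self):
        recon, ab = self._recon()
        cls = classify_species(self.tree, recon, tree_id="T")
        resolved = [c for c in cls if c.origin != "unresolved"]
        assert {c.species for c in resolved} == {"a", "b"}
        unique, mean_age, mean_depth = dedupe_source_nodes(cls)
        assert unique == {("T", ab)}
        assert mean_age == pytest.approx(1.0)
        assert mean_depth == pytest.approx(1.0)

    def test_disjoint_nodes_count_equals_species(self):
        t = parse_tree("((a:1,b:1):2,(c:1,d:1):2);")
        n_ab = int(t.parent[t.tip_index("a")])
        n_cd = int(t.parent[t.tip_index("c")])
        eur = {GEO.mask("Palearctic", "Indomalaya"): 1.0}
        aus = {GEO.mask("Australo-Papua"): 1.0}
        recon = fake_recon(GEO_SPACE, {n_ab: eur, n_cd: aus, t.root: eur})
        cls = [trace_source_node(t, recon, tip, tree_id="T") for tip in "abcd"]
        unique, _, _ = dedupe_source_nodes(cls)
        assert unique == {("T", n_ab), ("T", n_cd)}

    def test_known_sharing_fixture(self):
        """Ten species in two clades with hand-countable sharing."""
        t = parse_tree(
            "(((a:1,b:1):1,(c:1.5,d:1.5):0.5):3,"
            "((e:1,f:1):2,((g:0.5,h:0.5):1,(i:1,j:1):0.5):1.5):2);"
        )
        eur = {GEO.mask("Palearctic", "Indomalaya"): 1.0}
        wal = {GEO.mask("Wallacea"): 1.0}
        n_abcd = int(t.parent[t.parent[t.tip_index("a")]])
        n_efghij = int(t.parent[t.parent[t.tip_index("e")]])
        node_probs = {
            n: wal for n in range(t.n_nodes) if not t.is_tip(n)
        }
        node_probs[n_abcd] = eur  # a,b,c,d all trace here (depth 2 each)
        node_probs[n_efghij] = eur  # e..j all trace here
        recon = fake_recon(GEO_SPACE, node_probs)
        cls = classify_species(t, recon, tree_id="T")
        unique, _, mean_depth = dedupe_source_nodes(cls)
        assert len(unique) == 2  # hand count: one shared node per clade
        # walk depths: a,b,c,d = 2; e,f = 2; g,h,i,j = 3 -> mean 2.4
        assert mean_depth == pytest.approx((2 * 6 + 3 * 4) / 10)

    def test_frame_has_one_row_per_species(self):
        recon, _ = self._recon()
        cls = classify_species(self.tree, recon, tree_id="T")
        df = classifications_to_frame(cls)
        assert len(df) == 4
        assert set(df["origin"]) == {"Eurasian", "unresolved"}
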