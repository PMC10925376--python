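"""Net graphs, cycle equivalence and generalized bibubbles."""

import random

import pytest

from genegraph.bubbles import (
    ACYCLIC_LABEL,
    NetGraph,
    canonical_bubble,
    compute_U,
    cycle_equiv_classes,
    cycle_equiv_oracle,
    find_bibubbles,
    find_bibubbles_bruteforce,
    is_bibubble,
    separates,
    to_net_graph,
)
from genegraph.core import flip, from_walks, og
from genegraph.simulate import SimConfig, simulate_pangenome


def partition(classes):
    groups = {}
    for gene, cls in classes.items():
        groups.setdefault(cls, set()).add(gene)
    return {frozenset(v) for v in groups.values()}


def bubset(bubbles):
    return {(b.entrance, b.exit, b.interior) for b in bubbles}


# -- net graph ---------------------------------------------------------------


def test_net_graph_toy1_structure(t1):
    n = to_net_graph(t1)
    # A.s | A.e,B.s,B.e,C.s | C.e: gene B is a self-loop, A and C bridges
    assert n.n_genes() == 3
    ua, va = n.edges["A"]
    ub, vb = n.edges["B"]
    uc, vc = n.edges["C"]
    assert ub == vb
    assert ua != va and uc != vc
    assert len(set(n.vertices)) == 3


def test_net_graph_parallel_structure(tpar):
    n = to_net_graph(tpar)
    assert len(n.vertices) == 4
    assert set(n.edges["B"]) == set(n.edges["D"])  # parallel middle edges
    assert n.edges["B"] != n.edges["B"][::-1] or True


def test_net_graph_skew_twins_make_one_link(t1):
    # the twin views of each edge contract the same port pair, so TOY1's
    # middle component absorbs four ports regardless of view order
    n = to_net_graph(t1)
    assert sorted(n.vertices) == [0, 1, 2]


# -- cycle equivalence -------------------------------------------------------


def triangle():
    return NetGraph(vertices=[0, 1, 2], edges={"a": (0, 1), "b": (1, 2), "c": (2, 0)})


def two_triangles():
    return NetGraph(
        vertices=[0, 1, 2, 3, 4, 5],
        edges={
            "a": (0, 1), "b": (1, 2), "c": (2, 0),
            "d": (3, 4), "e": (4, 5), "f": (5, 3),
        },
    )


def single_bridge():
    return NetGraph(vertices=[0, 1], edges={"a": (0, 1)})


@pytest.mark.parametrize("impl", [cycle_equiv_classes, cycle_equiv_oracle])
def test_triangle_is_one_class(impl):
    assert partition(impl(triangle())) == {frozenset("abc")}


@pytest.mark.parametrize("impl", [cycle_equiv_classes, cycle_equiv_oracle])
def test_two_disjoint_triangles_two_classes(impl):
    assert partition(impl(two_triangles())) == {frozenset("abc"), frozenset("def")}


@pytest.mark.parametrize("impl", [cycle_equiv_classes, cycle_equiv_oracle])
def test_single_bridge_is_acyclic_class(impl):
    classes = impl(single_bridge())
    assert classes == {"a": ACYCLIC_LABEL}


def test_toy1_classes(t1):
    classes = cycle_equiv_classes(to_net_graph(t1))
    assert classes["A"] == classes["C"] == ACYCLIC_LABEL
    assert classes["B"] != ACYCLIC_LABEL  # the self-loop is its own cycle


def test_parallel_classes(tpar):
    classes = cycle_equiv_classes(to_net_graph(tpar))
    assert classes["B"] == classes["D"] != ACYCLIC_LABEL
    assert classes["A"] == classes["C"] == ACYCLIC_LABEL


def random_net_graph(seed: int, max_genes: int = 12) -> NetGraph:
    rng = random.Random(seed)
    n_vertices = rng.randint(1, 8)
    n_edges = rng.randint(1, max_genes)
    edges = {
        f"e{i}": (rng.randrange(n_vertices), rng.randrange(n_vertices))
        for i in range(n_edges)
    }
    return NetGraph(vertices=list(range(n_vertices)), edges=edges)


@pytest.mark.parametrize("seed", range(40))
def test_cycle_classes_match_definition_oracle(seed):
    n = random_net_graph(seed)
    assert partition(cycle_equiv_classes(n)) == partition(cycle_equiv_oracle(n))


def test_oracle_size_guard():
    big = NetGraph(vertices=[0], edges={f"e{i}": (0, 0) for i in range(20)})
    with pytest.raises(ValueError):
        cycle_equiv_oracle(big)


# -- U sets and the checker --------------------------------------------------


def test_compute_U_toy1_asymmetry(t1):
    assert compute_U(t1, og(">A"), og(">C")) == {"B"}
    assert compute_U(t1, og(">A"), og("<C")) == {"B", "C"}  # passes through >C
    assert compute_U(t1, og(">C"), og("<A")) == set()


def test_compute_U_terminal_vertex(t1):
    assert compute_U(t1, og(">C"), og(">A")) == set()


@pytest.mark.parametrize("fix", ["t1", "t2", "t3"])
def test_toys_form_the_expected_bubble(request, fix):
    g = request.getfixturevalue(fix)
    assert is_bibubble(g, og(">A"), og(">C"))
    assert is_bibubble(g, og("<C"), og("<A"))  # skew twin


def test_condition_i_rejects_inverted_exit(t1):
    assert not is_bibubble(t1, og(">A"), og("<C"))


def test_degenerate_pairs_rejected(t1):
    assert not is_bibubble(t1, og(">A"), og(">A"))
    assert not is_bibubble(t1, og(">A"), og("<A"))


def test_chain_has_no_bubbles(tchain):
    assert find_bibubbles(tchain) == []
    assert find_bibubbles_bruteforce(tchain) == []


def test_edgeless_graph_has_no_bubbles():
    g = from_walks([("g1", "c1", [">A"]), ("g2", "c2", [">B"])])
    assert find_bibubbles_bruteforce(g) == []


def test_nested_fixture_matches_bruteforce():
    g = from_walks(
        [
            ("g1", "c1", [">A", ">B", ">C", ">D", ">E"]),
            ("g2", "c2", [">A", ">C", ">D", ">E"]),
            ("g3", "c3", [">A", ">B", ">C", ">E"]),
        ]
    )
    assert bubset(find_bibubbles(g)) == bubset(find_bibubbles_bruteforce(g))


def test_bruteforce_size_guard():
    g = from_walks([("g1", "c1", [f">X{i}" for i in range(61)])])
    with pytest.raises(ValueError):
        find_bibubbles_bruteforce(g)


def test_branching_entrances_subset_of_all(t1):
    all_b = bubset(find_bibubbles(t1, entrances="all"))
    br_b = bubset(find_bibubbles(t1, entrances="branching"))
    assert br_b <= all_b
    with pytest.raises(ValueError):
        find_bibubbles(t1, entrances="bogus")


# -- theorem-level properties on random graphs -------------------------------


def _random_graph(seed):
    n = random.Random(seed).randint(6, 25)
    cfg = SimConfig(
        n_genes=n, n_genomes=3, p_del=0.08, p_inv=0.06, p_dup=0.06,
        min_event_spacing=None, seed=seed,
    )
    return from_walks(simulate_pangenome(cfg).walk_specs())


@pytest.mark.parametrize("seed", range(25))
def test_reported_bubbles_satisfy_the_theorems(seed):
    g = _random_graph(seed)
    bubbles = find_bibubbles(g)
    classes = cycle_equiv_classes(to_net_graph(g))
    entrances = set()
    for bub in bubbles:
        x, y = bub.entrance, bub.exit
        # twin symmetry
        assert is_bibubble(g, x, y) and is_bibubble(g, flip(y), flip(x))
        # interior separator
        assert separates(g, bub)
        # entrance/exit cycle equivalent
        assert classes[x.gene] == classes[y.gene]
        # one bubble per entrance (both twins reserve their entrances)
        assert x not in entrances and flip(y) not in entrances
        entrances.add(x)
        entrances.add(flip(y))
    # nesting: intersecting interiors are ordered by containment
    for a in bubbles:
        for b in bubbles:
            if a is b or not (a.interior & b.interior):
                continue
            assert a.interior <= b.interior or b.interior <= a.interior


def test_canonical_bubble_twin_identity():
    a = canonical_bubble(og(">A"), og(">C"), {"B"})
    b = canonical_bubble(og("<C"), og("<A"), {"B"})
    assert a == b


def test_has_inversion_confined_to_the_bubble(t2, t3):
    from genegraph.bubbles import bubble_has_inversion

    (inv_bub,) = find_bibubbles(t2)
    assert bubble_has_inversion(t2, inv_bub)
    (dup_bub,) = find_bibubbles(t3)
    assert not bubble_has_inversion(t3, dup_bub)
    # a distant inversion on the same chromosome must not leak into an
    # unrelated duplication bubble
    g = from_walks(
        [
            ("g1", "c1", [">A", ">B", ">C", ">D", ">E", ">F"]),
            ("g2", "c2", [">A", ">B", ">B", ">C", ">D", "<E", ">F"]),
        ]
    )
    by_interior = {tuple(sorted(b.interior)): b for b in find_bibubbles(g)}
    assert not bubble_has_inversion(g, by_interior[("B",)])
    assert bubble_has_inversion(g, by_interior[("E",)])
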