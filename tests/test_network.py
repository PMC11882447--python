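import networkx as nx
import numpy as np
import pytest

from conftest import make_ser, make_water
from hydronet.hbond import find_hbonds
from hydronet.network import (
    NetworkStats,
    build_graph,
    classify_hydration,
    cluster_waters,
    compare_networks,
    count_static_switchable,
    count_water_mediated_total,
    export_graph,
    interface_breakdown,
    mediating_edges,
    model_with_consensus_waters,
    network_stats,
)
from hydronet.structure_io import Ensemble, StructureModel


# ---------------------------------------------------------------------------
# Graph helpers: build attribute-complete graphs directly
# ---------------------------------------------------------------------------

EDGE_TYPE = {
    ("residue", "residue"): "res-res",
    ("residue", "water"): "res-water",
    ("water", "water"): "water-water",
}


def make_graph(nodes, edges):
    """nodes: {name: (kind, helix, hclass)}; edges: [(a, b)]"""
    g = nx.Graph()
    for name, (kind, helix, hclass) in nodes.items():
        g.add_node(name, kind=kind, helix=helix, hclass=hclass, bw="", pos=(0, 0, 0))
    for a, b in edges:
        kinds = tuple(sorted((g.nodes[a]["kind"], g.nodes[b]["kind"])))
        g.add_edge(a, b, type=EDGE_TYPE[kinds], multiplicity=1, min_distance=2.8)
    return g


def oracle_mediating_edges(g):
    """Exhaustive path enumeration: static -> (1-2 waters) -> switchable."""
    statics = [n for n, d in g.nodes(data=True)
               if d["kind"] == "residue" and d["hclass"] == "static"]
    switch = [n for n, d in g.nodes(data=True)
              if d["kind"] == "residue" and d["hclass"] == "switchable"]
    marked = set()
    for s in statics:
        for x in switch:
            for path in nx.all_simple_paths(g, s, x, cutoff=3):
                inner = path[1:-1]
                if 1 <= len(inner) <= 2 and all(
                    g.nodes[n]["kind"] == "water" for n in inner
                ):
                    marked.update(frozenset(p) for p in zip(path, path[1:]))
    return marked


STAT = ("residue", 2, "static")
SWIT = ("residue", 6, "switchable")
WAT = ("water", None, "none")


def test_single_water_bridge_counts_two_edges():
    g = make_graph({"s": STAT, "x": SWIT, "w": WAT}, [("s", "w"), ("w", "x")])
    assert count_static_switchable(g) == 2
    assert count_water_mediated_total(g) == 2


def test_two_water_chain_counts_three_edges():
    g = make_graph({"s": STAT, "x": SWIT, "w1": WAT, "w2": WAT},
                   [("s", "w1"), ("w1", "w2"), ("w2", "x")])
    assert count_static_switchable(g) == 3


def test_waters_on_static_only_count_zero():
    g = make_graph({"s1": STAT, "s2": STAT, "w": WAT}, [("s1", "w"), ("w", "s2")])
    assert count_static_switchable(g) == 0
    assert count_water_mediated_total(g) == 2


def test_three_water_chain_does_not_mediate():
    g = make_graph(
        {"s": STAT, "x": SWIT, "w1": WAT, "w2": WAT, "w3": WAT},
        [("s", "w1"), ("w1", "w2"), ("w2", "w3"), ("w3", "x")],
    )
    assert count_static_switchable(g) == 0


def test_water_water_edge_counts_in_total():
    g = make_graph({"s": STAT, "w1": WAT, "w2": WAT}, [("s", "w1"), ("w1", "w2")])
    assert count_water_mediated_total(g) == 2
    assert count_static_switchable(g) == 0


def test_res_res_edges_not_water_mediated():
    g = make_graph({"s": STAT, "x": SWIT}, [("s", "x")])
    assert count_water_mediated_total(g) == 0
    assert count_static_switchable(g) == 0


def test_shared_edge_counted_once():
    # one static residue feeding two switchable residues through one water:
    # 3 distinct edges, each on a mediating path
    g = make_graph({"s": STAT, "x1": SWIT, "x2": SWIT, "w": WAT},
                   [("s", "w"), ("w", "x1"), ("w", "x2")])
    assert count_static_switchable(g) == 3


def test_mediating_count_bounded_by_total():
    rng = np.random.default_rng(0)
    for _ in range(50):
        g = _random_graph(rng)
        assert count_static_switchable(g) <= count_water_mediated_total(g)


def _random_graph(rng, max_nodes=12):
    n = int(rng.integers(2, max_nodes + 1))
    nodes = {}
    for i in range(n):
        kind = "water" if rng.random() < 0.45 else "residue"
        if kind == "water":
            nodes[f"n{i}"] = WAT
        else:
            nodes[f"n{i}"] = STAT if rng.random() < 0.5 else SWIT
    names = list(nodes)
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            if nodes[a][0] == nodes[b][0] == "residue":
                continue  # res-res edges never matter for mediation
            if rng.random() < 0.3:
                edges.append((a, b))
    return make_graph(nodes, edges)


def test_brute_force_oracle_agreement():
    """Counting rule matches exhaustive path enumeration on small graphs."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        g = _random_graph(rng)
        assert mediating_edges(g) == oracle_mediating_edges(g)


def test_edge_addition_monotonicity():
    rng = np.random.default_rng(7)
    for _ in range(40):
        g = _random_graph(rng)
        t0, s0 = count_water_mediated_total(g), count_static_switchable(g)
        nodes = list(g.nodes)
        candidates = [
            (a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
            if not g.has_edge(a, b)
            and not (g.nodes[a]["kind"] == g.nodes[b]["kind"] == "residue")
        ]
        if not candidates:
            continue
        a, b = candidates[int(rng.integers(len(candidates)))]
        kinds = tuple(sorted((g.nodes[a]["kind"], g.nodes[b]["kind"])))
        g.add_edge(a, b, type=EDGE_TYPE[kinds], multiplicity=1, min_distance=2.8)
        assert count_water_mediated_total(g) >= t0
        assert count_static_switchable(g) >= s0


# ---------------------------------------------------------------------------
# build_graph on real models
# ---------------------------------------------------------------------------


def test_build_graph_bridge(bridge_model):
    model, ann = bridge_model
    g = build_graph(model, find_hbonds(model), ann)
    kinds = [d["kind"] for _, d in g.nodes(data=True)]
    assert sorted(kinds) == ["residue", "residue", "water"]
    assert count_water_mediated_total(g) == 2
    assert count_static_switchable(g) == 2


def test_build_graph_empty_bonds(bridge_model):
    model, ann = bridge_model
    g = build_graph(model, [], ann)
    assert g.number_of_edges() == 0


def test_build_graph_deduplicates_to_multiplicity():
    # water equidistant from serine OG and (polar) backbone-less CB? use two
    # polar atoms of one residue: OG and O would both bond the same water
    from hydronet.structure_io import Atom, Residue

    res = Residue("A", 1, "", "SER", [
        Atom(1, "CB", "C", np.array([0.0, 0.0, -1.4])),
        Atom(2, "OG", "O", np.array([0.0, 0.0, 0.0])),
        Atom(3, "O", "O", np.array([1.0, 0.0, 0.0])),
    ])
    model = StructureModel("m", [res, make_water(2, (0.5, 2.7, 0.0))])
    bonds = find_hbonds(model)
    assert len(bonds) == 2  # two atom pairs
    g = build_graph(model, bonds, None)
    assert g.number_of_edges() == 1  # one residue-level edge
    (a, b, d), = g.edges(data=True)
    assert d["multiplicity"] == 2


def test_direct_res_res_edge():
    model = StructureModel("m", [
        make_ser(1, (0, 0, 0)),
        make_ser(2, (3.0, 0, 0), cb_offset=(0, 0, 1.4)),
    ])
    g = build_graph(model, find_hbonds(model), None)
    assert [d["type"] for _, _, d in g.edges(data=True)] == ["res-res"]


# ---------------------------------------------------------------------------
# Water clustering
# ---------------------------------------------------------------------------


def _models_with_waters(*water_sets):
    return Ensemble([
        StructureModel(f"m{i}", [make_water(j + 1, p) for j, p in enumerate(ws)])
        for i, ws in enumerate(water_sets)
    ])


def test_cluster_waters_conserved_position():
    ens = _models_with_waters([(0, 0, 0)], [(0, 0, 0)], [(0, 0, 0)])
    (cw,) = cluster_waters(ens)
    assert cw.support == pytest.approx(1.0)
    np.testing.assert_allclose(cw.position, [0, 0, 0])


def test_cluster_waters_merges_nearby():
    ens = _models_with_waters([(0, 0, 0)], [(0.3, 0, 0)])
    (cw,) = cluster_waters(ens, radius=1.0)
    np.testing.assert_allclose(cw.position, [0.15, 0, 0])


def test_cluster_waters_drops_low_support():
    ens = _models_with_waters(
        [(0, 0, 0), (10, 0, 0)], [(0.2, 0, 0)], [(0.1, 0, 0)],
    )
    out = cluster_waters(ens, radius=1.0, min_support=2)
    assert len(out) == 1  # the water at x=10 appears in only one model
    assert out[0].support == pytest.approx(1.0)


def test_cluster_waters_separated_stay_apart():
    ens = _models_with_waters([(0, 0, 0), (5, 0, 0)], [(0, 0, 0), (5, 0, 0)])
    assert len(cluster_waters(ens, radius=1.0)) == 2


def test_consensus_model_carries_cluster_centres(bridge_model):
    model, ann = bridge_model
    ens = _models_with_waters([(0, 1.96, 0)], [(0, 1.96, 0)])
    consensus = cluster_waters(ens)
    merged = model_with_consensus_waters(model, consensus)
    # original water replaced by the single consensus node
    assert len(merged.waters) == 1
    g = build_graph(merged, find_hbonds(merged), ann)
    assert count_static_switchable(g) == 2


# ---------------------------------------------------------------------------
# Interface matrix, classification, comparison, export
# ---------------------------------------------------------------------------


def test_interface_matrix_single_bridge():
    g = make_graph({"s": STAT, "x": ("residue", 7, "switchable"), "w": WAT},
                   [("s", "w"), ("w", "x")])
    mat = interface_breakdown(g)
    assert mat[1, 6] == 1 and mat[6, 1] == 1
    assert mat.sum() == 2


def test_interface_matrix_empty_graph():
    g = make_graph({}, [])
    assert interface_breakdown(g).sum() == 0


def test_interface_matrix_symmetric_random():
    rng = np.random.default_rng(3)
    for _ in range(20):
        g = _random_graph(rng)
        for n, d in g.nodes(data=True):
            if d["kind"] == "residue":
                d["helix"] = int(rng.integers(1, 8))
        mat = interface_breakdown(g)
        np.testing.assert_array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0)


@pytest.mark.parametrize("count,reference,expected", [
    (26, 20, "Hyd_high"),
    (14, 20, "Hyd_low"),
    (20, 20, "reference_like"),
])
def test_classify_hydration(count, reference, expected):
    assert classify_hydration(count, reference) == expected


def _stats(solvated):
    return NetworkStats(0, 0, np.zeros((7, 7), dtype=int), frozenset(solvated))


def test_compare_networks_fractions():
    assert compare_networks(_stats({"2.50"}), _stats({"2.50"})).fraction_shared == 1.0
    assert compare_networks(_stats({"2.50"}), _stats({"3.39"})).fraction_shared == 0.0
    cmp = compare_networks(
        _stats({"2.50", "3.39", "7.45", "7.49", "6.48"}),
        _stats({"2.50", "3.39", "1.50", "5.58", "7.53"}),
    )
    assert cmp.fraction_shared == pytest.approx(0.40)
    assert cmp.shared == {"2.50", "3.39"}


def test_compare_networks_empty_query_errors():
    with pytest.raises(ValueError):
        compare_networks(_stats(set()), _stats({"2.50"}))


def test_export_sif_and_graphml_roundtrip(tmp_path):
    g = make_graph({"s": STAT, "x": SWIT, "w": WAT}, [("s", "w"), ("w", "x")])
    sif = tmp_path / "g.sif"
    export_graph(g, sif, fmt="sif")
    assert len(sif.read_text().strip().splitlines()) == 2
    gml = tmp_path / "g.graphml"
    export_graph(g, gml, fmt="graphml")
    back = nx.read_graphml(gml)
    assert back.number_of_nodes() == 3 and back.number_of_edges() == 2
    with pytest.raises(ValueError):
        export_graph(g, tmp_path / "g.xyz", fmt="xyz")


def test_network_stats_on_fixture(network_fixture):
    model, ann, expected = network_fixture
    g = build_graph(model, find_hbonds(model), ann)
    stats = network_stats(g)
    assert stats.n_static_switchable == expected.n_static_switchable
    assert stats.n_water_mediated_total == expected.n_water_mediated_total
    assert len(stats.solvated_residues) >= 2
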