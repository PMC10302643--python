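import json

import networkx as nx
import numpy as np
import pytest

from kinetree.errors import CapacityError, StructuralError, UnsupportedElementError
from kinetree.ligand_tree import (
    ROOT,
    build_template,
    build_tree,
    canonicalize,
    encode_graph,
    load_tree_specs,
    save_tree_specs,
    tree_to_spec,
)
from conftest import make_pet3, make_pme3


def graph_key(g):
    return g.node_presence.tobytes() + g.edge_order.tobytes()


def shuffle_spec(spec, rng):
    """Relabel node ids randomly and shuffle node/edge record order."""
    ids = [n["id"] for n in spec["nodes"]]
    new = dict(zip(ids, rng.permutation(ids).tolist()))
    nodes = [{"id": new[n["id"]], "element": n["element"]} for n in spec["nodes"]]
    edges = [
        {
            "i": rec["i"] if rec["i"] == ROOT else new[rec["i"]],
            "j": new[rec["j"]],
            "order": rec["order"],
        }
        for rec in spec["edges"]
    ]
    rng.shuffle(nodes)
    rng.shuffle(edges)
    return {"name": spec["name"], "root": ROOT, "nodes": nodes, "edges": edges}


class TestBuildTree:
    def test_trimethylphosphine_is_three_layer1_nodes(self):
        t = make_pme3()
        assert len(t.nodes) == 3
        assert all(n.layer == 1 for n in t.nodes.values())
        # no carbon-carbon bonds
        assert all(u == ROOT for u, _, _ in t.edges)

    def test_tri_n_butyl_has_three_nodes_per_layer(self):
        t = build_tree(["n-butyl"] * 3, name="PnBu3")
        assert len(t.nodes) == 12
        assert t.layer_counts() == {1: 3, 2: 3, 3: 3, 4: 3}

    def test_benzyl_ring_spans_layers_2_to_5_with_aromatic_closures(self):
        t = build_tree(["adamantyl", "adamantyl", "benzyl"], name="Ad2PBn")
        aromatic = [(u, v) for u, v, o in t.edges if o == 1.5]
        assert len(aromatic) == 6
        ring_layers = {t.nodes[u].layer for u, v in aromatic} | {
            t.nodes[v].layer for u, v in aromatic
        }
        assert ring_layers == {2, 3, 4, 5}

    def test_layers_match_independent_bfs(self, phosphines):
        for t in phosphines:
            dist = nx.single_source_shortest_path_length(t.to_networkx(), ROOT)
            for n in t.nodes.values():
                assert n.layer == dist[n.id]

    def test_disconnected_spec_rejected(self):
        spec = {
            "name": "bad",
            "nodes": [{"id": 0, "element": "C"}, {"id": 1, "element": "C"}],
            "edges": [{"i": ROOT, "j": 0, "order": 1}],
        }
        with pytest.raises(StructuralError, match="disconnected"):
            build_tree(spec)

    def test_non_carbon_substituent_rejected(self):
        spec = {"name": "bad", "nodes": [{"id": 0, "element": "N"}], "edges": []}
        with pytest.raises(UnsupportedElementError):
            build_tree(spec)


class TestCanonicalize:
    def test_symmetric_ligand_invariant_under_branch_order(self, rng):
        base = tree_to_spec(build_tree(["tBu"] * 3, name="PtBu3"))
        template = build_template([canonicalize(build_tree(base))])
        ref = encode_graph(canonicalize(build_tree(base)), template)
        for _ in range(5):
            enc = encode_graph(
                canonicalize(build_tree(shuffle_spec(base, rng))), template
            )
            assert graph_key(enc) == graph_key(ref)

    def test_tert_butyl_outranks_cyclohexyl(self):
        t = canonicalize(build_tree(["cyclohexyl", "tBu", "tBu"], name="CyPtBu2"))
        # highest-priority layer-1 branch (path (0,)) must be a tert-butyl
        # carbon: three children, no ring
        first = next(n for n in t.nodes.values() if n.path == (0,))
        children = [
            n for n in t.nodes.values() if n.layer == 2 and n.path[:1] == (0,)
        ]
        assert len(children) == 3
        last = next(n for n in t.nodes.values() if n.path == (2,))
        cyclo_children = [
            n for n in t.nodes.values() if n.layer == 2 and n.path[:1] == (2,)
        ]
        assert len(cyclo_children) == 2  # the cyclohexyl branch sits last
        assert first.priority_rank == 0 and last.priority_rank == 2

    def test_ordering_decided_at_first_differing_layer(self):
        # two chains identical through layer 2; one forks at layer 3
        spec = {
            "name": "toy",
            "nodes": [{"id": i, "element": "C"} for i in range(7)],
            "edges": [
                {"i": ROOT, "j": 0, "order": 1},  # branch A: plain chain
                {"i": 0, "j": 1, "order": 1},
                {"i": 1, "j": 2, "order": 1},
                {"i": ROOT, "j": 3, "order": 1},  # branch B: forks at layer 3
                {"i": 3, "j": 4, "order": 1},
                {"i": 4, "j": 5, "order": 1},
                {"i": 4, "j": 6, "order": 1},
            ],
        }
        t = canonicalize(build_tree(spec))
        assert t.nodes[3].path == (0,)  # forked branch wins
        assert t.nodes[0].path == (1,)

    def test_permutation_invariance_of_encoding(self, phosphines, phosphine_template, rng):
        for t in phosphines:
            ref = graph_key(encode_graph(t, phosphine_template))
            spec = tree_to_spec(t)
            for _ in range(3):
                shuffled = canonicalize(build_tree(shuffle_spec(spec, rng)))
                assert graph_key(encode_graph(shuffled, phosphine_template)) == ref


class TestTemplate:
    def test_single_ligand_template_size(self):
        assert build_template([make_pme3()]).total_slots == 3

    def test_union_of_layouts(self):
        tpl = build_template([make_pme3(), make_pet3()])
        assert tpl.total_slots == 6
        assert tpl.n_layers == 2

    def test_idempotence(self, phosphines):
        tpl = build_template(phosphines)
        assert build_template(phosphines + [make_pme3()]).paths == tpl.paths

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            build_template([])


class TestEncode:
    def test_pme3_in_pet3_template(self):
        tpl = build_template([make_pme3(), make_pet3()])
        enc = encode_graph(canonicalize(make_pme3()), tpl)
        assert enc.node_presence.tolist() == [1, 1, 1, 0, 0, 0]
        root_edges = enc.edge_order[0]
        assert root_edges[1:4].tolist() == [1, 1, 1]
        assert enc.edge_order[4:].sum() == 0

    def test_capacity_error_names_layer(self, phosphine_template):
        pentyl = {
            "name": "deep",
            "nodes": [{"id": i, "element": "C"} for i in range(7)],
            "edges": [{"i": ROOT, "j": 0, "order": 1}]
            + [{"i": i, "j": i + 1, "order": 1} for i in range(6)],
        }
        tpl = build_template([make_pme3(), make_pet3()])
        with pytest.raises(CapacityError) as exc:
            encode_graph(canonicalize(build_tree(pentyl)), tpl)
        assert exc.value.layer == 3

    def test_round_trip_isomorphic(self, phosphines, phosphine_template):
        for t in phosphines:
            enc = encode_graph(t, phosphine_template)
            decoded = enc.to_networkx()
            assert nx.is_isomorphic(
                decoded,
                t.to_networkx(),
                node_match=lambda a, b: a.get("element") == b.get("element"),
                edge_match=lambda a, b: a["order"] == b["order"],
            )

    def test_vacant_slots_have_no_edges(self, small_graphs):
        for g in small_graphs:
            vacant = np.flatnonzero(g.node_presence == 0) + 1
            assert g.edge_order[vacant].sum() == 0


def test_spec_json_round_trip(tmp_path, phosphines):
    path = tmp_path / "ligands.json"
    save_tree_specs(phosphines, path)
    loaded = {t.name: t for t in load_tree_specs(path)}
    for t in phosphines:
        got = loaded[t.name]
        assert {n.id: n.layer for n in got.nodes.values()} == {
            n.id: n.layer for n in t.nodes.values()
        }
    # file is valid plain JSON
    json.loads(path.read_text())
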