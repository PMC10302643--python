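"""Tree-structured topological descriptors for phosphine ligands.

A trialkyl/arylalkyl phosphine PR3 is described by a rooted graph: the
phosphorus atom is the root and every heavy (carbon) atom of the three
substituents is a node.  Nodes are stratified into *layers* by the smallest
number of bonds separating them from phosphorus; carbons bonded directly to
P sit in layer 1, their neighbours in layer 2, and so on.  Hydrogens are
implicit and never appear.  Ring bonds that close a cycle (cyclohexyl,
adamantyl, aryl) are retained as extra edges between nodes of equal or
adjacent layers; no atom is duplicated.  Edges carry the bond order
(1 single, 1.5 aromatic, 2 double).

To make ligands of different size comparable, every tree is canonically
ordered (a CIP-inspired priority of sibling branches) and then embedded into
a fixed *template* of slots built from a reference ligand set; the result is
an :class:`AlignedGraph` — a Boolean node-presence vector plus a symmetric
bond-order matrix over slots — whose layout is identical for every ligand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import CapacityError, StructuralError, UnsupportedElementError

ROOT = "P"

_VALID_ORDERS = (1.0, 1.5, 2.0)


@dataclass(frozen=True)
class TreeNode:
    """A heavy atom of a phosphine substituent.

    ``layer`` is the bond-count distance from the phosphorus root;
    ``priority_rank`` is the position of the node within its layer after
    canonical ordering (0 = highest priority), and ``path`` is the sequence
    of sibling indices walked from the root to reach the node.  The last two
    are ``None`` until :func:`canonicalize` has run.
    """

    id: int
    layer: int
    element: str = "C"
    priority_rank: int | None = None
    path: tuple[int, ...] | None = None


@dataclass
class LigandTree:
    """P-rooted layered representation of one phosphine ligand."""

    name: str
    nodes: dict[int, TreeNode]
    edges: list[tuple[object, object, float]]  # (u, v, order); u may be ROOT

    @property
    def is_canonical(self) -> bool:
        return all(n.path is not None for n in self.nodes.values())

    @property
    def n_layers(self) -> int:
        return max((n.layer for n in self.nodes.values()), default=0)

    def layer_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for n in self.nodes.values():
            counts[n.layer] = counts.get(n.layer, 0) + 1
        return counts

    def steric_proxy(self, max_layer: int = 3) -> int:
        """Number of nodes within ``max_layer`` bonds of phosphorus.

        A crude bulk measure: counts the carbons crowding the metal-binding
        region, used by the synthetic generator as the ground-truth steric
        variable.
        """
        return sum(1 for n in self.nodes.values() if n.layer <= max_layer)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_node(ROOT, element="P")
        for n in self.nodes.values():
            g.add_node(n.id, element=n.element)
        for u, v, order in self.edges:
            g.add_edge(u, v, order=order)
        return g

    def paths(self) -> dict[int, tuple[int, ...]]:
        if not self.is_canonical:
            raise StructuralError(f"ligand {self.name!r} is not canonicalized")
        return {i: n.path for i, n in self.nodes.items()}


# ---------------------------------------------------------------------------
# construction


def build_tree(spec: Mapping | Sequence[str], name: str | None = None) -> LigandTree:
    """Build a :class:`LigandTree` from a tree-spec record or substituent list.

    ``spec`` is either a mapping ``{"name", "root", "nodes", "edges"}``
    (layers are always recomputed, never read) or a sequence of three
    substituent names from :data:`SUBSTITUENTS` (e.g. ``["tBu", "tBu",
    "benzyl"]``).
    """
    if not isinstance(spec, Mapping):
        return _tree_from_substituents(list(spec), name or "PR3")

    label = spec.get("name", name or "ligand")
    g = nx.Graph()
    g.add_node(ROOT)
    elements = {}
    for rec in spec.get("nodes", []):
        nid = int(rec["id"])
        elem = rec.get("element", "C")
        if elem != "C":
            raise UnsupportedElementError(
                f"ligand {label!r}: node {nid} has element {elem!r}; "
                "only carbon substituent atoms are supported"
            )
        elements[nid] = elem
        g.add_node(nid)
    edges = []
    for rec in spec.get("edges", []):
        u = ROOT if rec["i"] == ROOT else int(rec["i"])
        v = ROOT if rec["j"] == ROOT else int(rec["j"])
        order = float(rec.get("order", 1))
        if order not in _VALID_ORDERS:
            raise StructuralError(
                f"ligand {label!r}: bond order {order} not in {_VALID_ORDERS}"
            )
        if u == v or (u != ROOT and u not in elements) or v not in elements:
            raise StructuralError(f"ligand {label!r}: bad edge {rec}")
        g.add_edge(u, v, order=order)
        edges.append((u, v, order))
    return _finish_tree(label, g, elements, edges)


def _finish_tree(label, g, elements, edges) -> LigandTree:
    if not nx.is_connected(g):
        raise StructuralError(f"ligand {label!r}: specification is disconnected")
    layers = nx.single_source_shortest_path_length(g, ROOT)
    nodes = {
        nid: TreeNode(id=nid, layer=layers[nid], element=elements[nid])
        for nid in elements
    }
    return LigandTree(name=label, nodes=nodes, edges=edges)


# Substituent library: local graphs with atom 0 as the attachment point.
# Each entry: (edge list over local ids, bond order). Hydrogens implicit.
def _chain(n):
    return [(i, i + 1, 1.0) for i in range(n - 1)]


def _ring(n, order=1.0):
    return [(i, (i + 1) % n, order) for i in range(n)]


_ADAMANTYL_EDGES = [
    # bridgeheads 0-3, methylenes 4-9; atom 0 is the attachment bridgehead
    (0, 4, 1.0), (0, 5, 1.0), (0, 6, 1.0),
    (1, 4, 1.0), (1, 7, 1.0), (1, 8, 1.0),
    (2, 5, 1.0), (2, 7, 1.0), (2, 9, 1.0),
    (3, 6, 1.0), (3, 8, 1.0), (3, 9, 1.0),
]

SUBSTITUENTS: dict[str, tuple[int, list[tuple[int, int, float]]]] = {
    "methyl": (1, []),
    "ethyl": (2, _chain(2)),
    "n-propyl": (3, _chain(3)),
    "isopropyl": (3, [(0, 1, 1.0), (0, 2, 1.0)]),
    "n-butyl": (4, _chain(4)),
    "tBu": (4, [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]),
    "cyclopentyl": (5, _ring(5)),
    "cyclohexyl": (6, _ring(6)),
    "phenyl": (6, _ring(6, 1.5)),
    "benzyl": (7, [(0, 1, 1.0)] + [(1 + i, 1 + (i + 1) % 6, 1.5) for i in range(6)]),
    "adamantyl": (10, _ADAMANTYL_EDGES),
}


def _tree_from_substituents(subs: list[str], name: str) -> LigandTree:
    if len(subs) != 3:
        raise StructuralError(
            f"ligand {name!r}: a phosphine needs exactly 3 substituents, got {len(subs)}"
        )
    g = nx.Graph()
    g.add_node(ROOT)
    elements: dict[int, str] = {}
    edges: list[tuple[object, object, float]] = []
    offset = 0
    for sub in subs:
        try:
            n_atoms, local_edges = SUBSTITUENTS[sub]
        except KeyError:
            raise UnsupportedElementError(
                f"unknown substituent {sub!r}; known: {sorted(SUBSTITUENTS)}"
            ) from None
        ids = [offset + i for i in range(n_atoms)]
        for nid in ids:
            elements[nid] = "C"
            g.add_node(nid)
        g.add_edge(ROOT, ids[0], order=1.0)
        edges.append((ROOT, ids[0], 1.0))
        for u, v, order in local_edges:
            g.add_edge(ids[u], ids[v], order=order)
            edges.append((ids[u], ids[v], order))
        offset += n_atoms
    return _finish_tree(name, g, elements, edges)


# ---------------------------------------------------------------------------
# canonicalization


def _adjacency(tree: LigandTree) -> dict[object, list[tuple[object, float]]]:
    adj: dict[object, list[tuple[object, float]]] = {ROOT: []}
    for nid in tree.nodes:
        adj[nid] = []
    for u, v, order in tree.edges:
        adj[u].append((v, order))
        adj[v].append((u, order))
    return adj


def _branch_keys(tree: LigandTree, adj) -> dict[int, tuple]:
    """Structural priority key per node, computed over the layer DAG.

    The key emulates a hierarchical-digraph CIP comparison restricted to the
    carbon-only case: a node is characterised by (a) its total incident bond
    order (double/aromatic bonds weigh like CIP duplicate atoms), (b) the
    bond orders of its same-layer ring closures, and (c) the sorted keys of
    its next-layer children.  Children strictly increase in layer, so the
    recursion terminates even on ring systems.  Identical branches compare
    equal; their relative order is then left to the stable input order,
    which cannot change the encoding.
    """
    layers = {nid: tree.nodes[nid].layer for nid in tree.nodes}
    layers[ROOT] = 0
    memo: dict[int, tuple] = {}

    def key(nid: int) -> tuple:
        if nid in memo:
            return memo[nid]
        weight = sum(order for _, order in adj[nid])
        ring = tuple(sorted(
            (order for nb, order in adj[nid] if nb != ROOT and layers[nb] == layers[nid]),
            reverse=True,
        ))
        children = [
            (order, key(nb))
            for nb, order in adj[nid]
            if nb != ROOT and layers[nb] == layers[nid] + 1
        ]
        children.sort(reverse=True)
        k = (weight, ring, tuple(children))
        memo[nid] = k
        return k

    for nid in tree.nodes:
        key(nid)
    return memo


def canonicalize(tree: LigandTree) -> LigandTree:
    """Return a copy with canonical sibling order (`path`, `priority_rank`).

    Sibling branches under each node are sorted by descending structural
    priority; ties (identical branches) keep their input order.  Each node
    receives a root-to-node ``path`` of sibling indices, assigned the first
    time the node is reached (nodes with two shortest paths from P, e.g. the
    para carbon of a phenyl ring, are attached under their highest-priority
    parent; the second adjacency stays as a plain edge).  The result is
    independent of the input node numbering.
    """
    adj = _adjacency(tree)
    keys = _branch_keys(tree, adj)
    layers = {nid: tree.nodes[nid].layer for nid in tree.nodes}
    layers[ROOT] = 0

    paths: dict[int, tuple[int, ...]] = {}

    def assigned_neighbor_paths(nid):
        # tie-break refinement: siblings with identical structural keys can
        # still differ in which already-placed nodes their ring closures
        # reach (cage systems like adamantyl); order them by those paths
        return tuple(sorted(paths[nb] for nb, _ in adj[nid] if nb in paths))

    def assign_children(parent, parent_path):
        children = [
            (nb, order) for nb, order in adj[parent]
            if nb != ROOT and layers[nb] == layers[parent] + 1
        ]
        # primary: structural priority (descending); secondary: paths of
        # already-assigned neighbors (ascending); final ties keep adjacency
        # (input) order via sort stability — truly identical branches then
        # encode identically anyway
        children.sort(key=lambda c: assigned_neighbor_paths(c[0]))
        children.sort(key=lambda c: keys[c[0]], reverse=True)
        idx = 0
        out = []
        for nb, _ in children:
            if nb in paths:
                continue
            paths[nb] = parent_path + (idx,)
            idx += 1
            out.append(nb)
        return out

    frontier = assign_children(ROOT, ())
    while frontier:
        # process in path order so multi-parent nodes attach to the
        # highest-priority parent
        frontier.sort(key=lambda nid: paths[nid])
        nxt = []
        for nid in frontier:
            nxt.extend(assign_children(nid, paths[nid]))
        frontier = nxt

    if len(paths) != len(tree.nodes):
        raise StructuralError(
            f"ligand {tree.name!r}: {len(tree.nodes) - len(paths)} nodes unreachable "
            "through the layer hierarchy"
        )

    # rank nodes within each layer by lexicographic path
    by_layer: dict[int, list[int]] = {}
    for nid, p in paths.items():
        by_layer.setdefault(len(p), []).append(nid)
    ranks: dict[int, int] = {}
    for layer_nodes in by_layer.values():
        layer_nodes.sort(key=lambda nid: paths[nid])
        for r, nid in enumerate(layer_nodes):
            ranks[nid] = r

    new_nodes = {
        nid: replace(n, priority_rank=ranks[nid], path=paths[nid])
        for nid, n in tree.nodes.items()
    }
    return LigandTree(name=tree.name, nodes=new_nodes, edges=list(tree.edges))


# ---------------------------------------------------------------------------
# template & encoding


@dataclass(frozen=True)
class GraphTemplate:
    """Frozen slot layout shared by a ligand set.

    ``paths`` is the union of canonical branch paths over the generating
    ligands, ordered layer-major (shallow first) then lexicographically;
    ``slot_index`` maps a path to its flat position.  The template is built
    once from the training ligand set and frozen: encoding a bulkier unseen
    ligand raises :class:`CapacityError` instead of silently truncating.
    """

    paths: tuple[tuple[int, ...], ...]
    slot_index: Mapping[tuple[int, ...], int] = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "slot_index", {p: i for i, p in enumerate(self.paths)}
        )

    @property
    def total_slots(self) -> int:
        return len(self.paths)

    @property
    def n_layers(self) -> int:
        return max((len(p) for p in self.paths), default=0)


def build_template(trees: Iterable[LigandTree]) -> GraphTemplate:
    """Union-of-paths template over a collection of canonicalized trees.

    Idempotent: adding a tree whose paths already fit leaves the template
    unchanged.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("build_template requires at least one ligand tree")
    all_paths: set[tuple[int, ...]] = set()
    for t in trees:
        if not t.is_canonical:
            t = canonicalize(t)
        all_paths.update(t.paths().values())
    ordered = tuple(sorted(all_paths, key=lambda p: (len(p), p)))
    return GraphTemplate(paths=ordered)


@dataclass
class AlignedGraph:
    """Fixed-layout encoding of one ligand under a :class:`GraphTemplate`.

    ``node_presence``: float {0,1} vector of length ``template.total_slots``.
    ``edge_order``: symmetric (S+1, S+1) matrix over [root] + slots with
    entries in {0, 1, 1.5, 2}; index 0 is the phosphorus root, which is
    always present.
    """

    name: str
    node_presence: np.ndarray
    edge_order: np.ndarray
    template: GraphTemplate

    def __post_init__(self):
        s = self.template.total_slots
        assert self.node_presence.shape == (s,)
        assert self.edge_order.shape == (s + 1, s + 1)

    def to_networkx(self) -> nx.Graph:
        """Decode back to a molecular graph (root + occupied slots)."""
        g = nx.Graph()
        g.add_node(0, element="P")
        for i, present in enumerate(self.node_presence):
            if present:
                g.add_node(i + 1, element="C")
        for i, j in zip(*np.nonzero(np.triu(self.edge_order))):
            g.add_edge(int(i), int(j), order=float(self.edge_order[i, j]))
        return g


def encode_graph(tree: LigandTree, template: GraphTemplate) -> AlignedGraph:
    """Map a canonicalized tree into the template's aligned slot layout."""
    if not tree.is_canonical:
        tree = canonicalize(tree)
    s = template.total_slots
    presence = np.zeros(s)
    slot_of: dict[object, int] = {ROOT: 0}
    for nid, path in tree.paths().items():
        pos = template.slot_index.get(path)
        if pos is None:
            raise CapacityError(
                f"ligand {tree.name!r} exceeds template capacity at layer "
                f"{len(path)} (branch path {path})",
                layer=len(path),
            )
        presence[pos] = 1.0
        slot_of[nid] = pos + 1
    edge_order = np.zeros((s + 1, s + 1))
    for u, v, order in tree.edges:
        iu, iv = slot_of[u], slot_of[v]
        edge_order[iu, iv] = order
        edge_order[iv, iu] = order
    return AlignedGraph(
        name=tree.name, node_presence=presence, edge_order=edge_order,
        template=template,
    )


# ---------------------------------------------------------------------------
# serialization & bundled ligands


def tree_to_spec(tree: LigandTree) -> dict:
    return {
        "name": tree.name,
        "root": ROOT,
        "nodes": [{"id": n.id, "element": n.element} for n in tree.nodes.values()],
        "edges": [
            {"i": u if u == ROOT else int(u), "j": int(v), "order": order}
            for u, v, order in tree.edges
        ],
    }


def load_tree_specs(path: str | Path) -> list[LigandTree]:
    """Read a JSON file holding a list of tree-spec records."""
    with open(path) as fh:
        records = json.load(fh)
    if isinstance(records, Mapping):
        records = records.get("ligands", [records])
    return [build_tree(rec) for rec in records]


def save_tree_specs(trees: Iterable[LigandTree], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([tree_to_spec(t) for t in trees], fh, indent=1)


def bundled_phosphines() -> list[LigandTree]:
    """The nine reference phosphines shipped with the package.

    These are the named ligands of the Plenio Sonogashira kinetics set:
    PnBu3 (L1), PCy3 (L3), Cy2PAd (L8), Cy2PtBu (L9), iPr2PtBu (L10),
    EtPAd2 (L11), CyPtBu2 (L12), PtBu2Bn (L15) and (1-Ad)2PBn (L16).
    """
    from importlib.resources import files

    return load_tree_specs(files("kinetree.data") / "phosphines.json")


def tree_from_smiles(smiles: str, name: str | None = None) -> LigandTree:
    """Optional SMILES ingestion (requires rdkit).

    Extracts the hydrogen-suppressed heavy-atom graph of a phosphine:
    exactly one trivalent P, carbon substituents only.  Aromatic bonds map
    to order 1.5, double bonds to 2.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SMILES ingestion requires the optional rdkit extra") from exc

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructuralError(f"could not parse SMILES {smiles!r}")
    p_atoms = [a for a in mol.GetAtoms() if a.GetSymbol() == "P"]
    if len(p_atoms) != 1:
        raise StructuralError(f"expected exactly one P atom, found {len(p_atoms)}")
    p_idx = p_atoms[0].GetIdx()
    nodes = []
    id_map = {}
    for atom in mol.GetAtoms():
        if atom.GetIdx() == p_idx:
            continue
        if atom.GetSymbol() != "C":
            raise UnsupportedElementError(
                f"atom {atom.GetSymbol()!r} unsupported (carbon substituents only)"
            )
        id_map[atom.GetIdx()] = len(nodes)
        nodes.append({"id": len(nodes), "element": "C"})
    order_map = {
        Chem.BondType.SINGLE: 1.0,
        Chem.BondType.AROMATIC: 1.5,
        Chem.BondType.DOUBLE: 2.0,
    }
    edges = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = order_map.get(bond.GetBondType())
        if order is None:
            raise StructuralError(f"unsupported bond type {bond.GetBondType()}")
        ui = ROOT if u == p_idx else id_map[u]
        vi = ROOT if v == p_idx else id_map[v]
        if vi == ROOT:
            ui, vi = vi, ui
        edges.append({"i": ui, "j": vi, "order": order})
    return build_tree(
        {"name": name or smiles, "root": ROOT, "nodes": nodes, "edges": edges}
    )
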