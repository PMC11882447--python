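"""Residue/water interaction graphs and network-topology statistics.

The central objects are graphs in which every hydrogen-bonding residue and
every water is a node and every (residue-level, deduplicated) hydrogen bond
is an edge.  On top of the graph this module implements the counting rules
for water-mediated contacts: a water mediates a static-switchable interaction
when it lies on a path from a residue on a static helix through one or two
waters to a residue on a switchable helix, and every residue-water or
water-water edge on such a path counts once.

Ensemble water positions can first be condensed into consensus solvent nodes
by complete-linkage clustering of the water oxygen positions across the
lowest-energy models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .hbond import HBond
from .structure_io import Atom, BWAnnotation, Ensemble, Residue, StructureModel

N_HELICES = 7


@dataclass
class ConsensusWater:
    """A consensus solvent position shared across ensemble models."""

    position: np.ndarray
    support: float  # fraction of models contributing a member
    members: list[tuple[str, tuple[str, int, str]]]  # (model_id, residue key)


@dataclass
class NetworkStats:
    n_water_mediated_total: int
    n_static_switchable: int
    interface_matrix: np.ndarray  # 7x7 symmetric, zero diagonal
    solvated_residues: frozenset[str]  # BW codes with >= 1 water edge


@dataclass
class NetworkComparison:
    shared: frozenset[str]
    fraction_shared: float


def cluster_waters(
    ensemble: Ensemble,
    radius: float = 1.0,
    min_support: int = 2,
) -> list[ConsensusWater]:
    """Cluster water oxygen positions across models into consensus nodes.

    Complete-linkage agglomerative clustering cut at ``radius``; clusters
    supported by fewer than ``min_support`` distinct models are discarded.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    positions: list[np.ndarray] = []
    owners: list[tuple[str, tuple[str, int, str]]] = []
    for model in ensemble:
        for w in model.waters:
            ox = w.atom("O") or w.atom("OW") or (w.atoms[0] if w.atoms else None)
            if ox is None:
                continue
            positions.append(ox.position)
            owners.append((model.model_id, w.key))
    if not positions:
        return []
    pts = np.array(positions)
    if len(pts) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(pts), method="complete")
        labels = fcluster(z, t=radius, criterion="distance")
    n_models = len(ensemble)
    consensus: list[ConsensusWater] = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        member_models = {owners[i][0] for i in idx}
        if len(member_models) < min_support:
            continue
        consensus.append(
            ConsensusWater(
                position=pts[idx].mean(axis=0),
                support=len(member_models) / n_models,
                members=[owners[i] for i in idx],
            )
        )
    consensus.sort(key=lambda c: (-c.support, tuple(np.round(c.position, 3))))
    return consensus


def model_with_consensus_waters(
    model: StructureModel, consensus: list[ConsensusWater]
) -> StructureModel:
    """Replace a model's waters with consensus solvent positions.

    The result carries the polymer of ``model`` plus one HOH oxygen per
    consensus node, numbered from 9001 on chain "W".
    """
    residues = list(model.polymer_residues)
    for i, cw in enumerate(consensus):
        atom = Atom(
            serial=99000 + i,
            name="O",
            element="O",
            position=cw.position,
            record_kind="water",
        )
        residues.append(
            Residue(chain="W", seq_number=9001 + i, icode="", name="HOH", atoms=[atom])
        )
    return StructureModel(
        model_id=model.model_id + "+consensus", residues=residues, energy=model.energy
    )


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def _node_id(res: Residue) -> str:
    tag = "w" if res.is_water else "r"
    return f"{tag}:{res.chain}:{res.seq_number}{res.icode}"


def build_graph(
    model: StructureModel,
    hbonds: list[HBond],
    annotation: BWAnnotation | None = None,
) -> nx.Graph:
    """Build the residue/water interaction graph from a model's hydrogen bonds.

    One node per residue owning at least one bonded polar atom and one node
    per bonded water; multiple atom-pair bonds between the same two residues
    collapse into a single edge whose ``multiplicity`` records the bond count.
    Node attributes: ``kind`` (residue|water), ``helix`` (1-7 or None),
    ``hclass`` (static|switchable|none), ``bw`` and ``pos``.
    """
    known = set(id(r) for r in model.residues)
    g = nx.Graph()
    for bond in hbonds:
        for pa in (bond.a, bond.b):
            if id(pa.residue) not in known:
                raise ValueError(
                    f"hydrogen bond references residue {pa.residue.key} absent from model"
                )
        ra, rb = bond.a.residue, bond.b.residue
        for res in (ra, rb):
            nid = _node_id(res)
            if nid not in g:
                entry = annotation.lookup(res.chain, res.seq_number) if annotation else None
                g.add_node(
                    nid,
                    kind="water" if res.is_water else "residue",
                    helix=entry.helix_id if entry else None,
                    hclass=entry.helix_class if entry else "none",
                    bw=entry.bw_code if entry else "",
                    pos=tuple(np.round(res.atoms[0].position, 3)),
                    resname=res.name,
                )
        na, nb = _node_id(ra), _node_id(rb)
        if na == nb:
            continue
        if g.has_edge(na, nb):
            g[na][nb]["multiplicity"] += 1
            g[na][nb]["min_distance"] = min(g[na][nb]["min_distance"], bond.distance)
        else:
            kinds = sorted((g.nodes[na]["kind"], g.nodes[nb]["kind"]))
            etype = {
                ("residue", "residue"): "res-res",
                ("residue", "water"): "res-water",
                ("water", "water"): "water-water",
            }[tuple(kinds)]
            g.add_edge(na, nb, type=etype, multiplicity=1, min_distance=bond.distance)
    return g


# ---------------------------------------------------------------------------
# Counting rules
# ---------------------------------------------------------------------------


def count_water_mediated_total(graph: nx.Graph) -> int:
    """Number of edges with at least one water endpoint."""
    return sum(1 for _, _, d in graph.edges(data=True) if d["type"] != "res-res")


def _water_nodes(graph: nx.Graph) -> list[str]:
    return [n for n, d in graph.nodes(data=True) if d["kind"] == "water"]


def _residue_neighbors_of_class(graph: nx.Graph, water: str, hclass: str) -> list[str]:
    return [
        nb
        for nb in graph.neighbors(water)
        if graph.nodes[nb]["kind"] == "residue" and graph.nodes[nb]["hclass"] == hclass
    ]


def mediating_edges(graph: nx.Graph) -> set[frozenset]:
    """Edges lying on a static -> (1 or 2 waters) -> switchable path.

    Paths through more than two consecutive waters do not mediate.  Each
    qualifying residue-water or water-water edge is returned once.
    """
    marked: set[frozenset] = set()
    waters = _water_nodes(graph)
    stat = {w: _residue_neighbors_of_class(graph, w, "static") for w in waters}
    swit = {w: _residue_neighbors_of_class(graph, w, "switchable") for w in waters}
    # single-water bridges
    for w in waters:
        if stat[w] and swit[w]:
            for r in stat[w]:
                marked.add(frozenset((r, w)))
            for r in swit[w]:
                marked.add(frozenset((r, w)))
    # two-water chains
    for w1 in waters:
        for w2 in graph.neighbors(w1):
            if graph.nodes[w2]["kind"] != "water":
                continue
            if stat[w1] and swit[w2]:
                marked.add(frozenset((w1, w2)))
                for r in stat[w1]:
                    marked.add(frozenset((r, w1)))
                for r in swit[w2]:
                    marked.add(frozenset((r, w2)))
    return marked


def count_static_switchable(graph: nx.Graph) -> int:
    """Number of distinct edges on static-to-switchable water-mediated paths."""
    return len(mediating_edges(graph))


def interface_breakdown(graph: nx.Graph) -> np.ndarray:
    """7x7 matrix of interhelical polar contacts (direct + water-mediated).

    Entry (i, j), 1-based helices, counts direct residue-residue edges between
    helices i and j plus distinct residue pairs bridged through one or two
    waters.  Intra-helix contacts are excluded (zero diagonal).
    """
    mat = np.zeros((N_HELICES, N_HELICES), dtype=int)

    def helix(n: str) -> int | None:
        return graph.nodes[n]["helix"]

    for a, b, d in graph.edges(data=True):
        if d["type"] != "res-res":
            continue
        ha, hb = helix(a), helix(b)
        if ha is None or hb is None or ha == hb:
            continue
        mat[ha - 1, hb - 1] += 1
        mat[hb - 1, ha - 1] += 1

    bridged: set[tuple[str, str]] = set()
    waters = _water_nodes(graph)
    res_nb = {
        w: [n for n in graph.neighbors(w) if graph.nodes[n]["kind"] == "residue"]
        for w in waters
    }
    for w in waters:
        for i, a in enumerate(res_nb[w]):
            for b in res_nb[w][i + 1:]:
                bridged.add(tuple(sorted((a, b))))
    for w1 in waters:
        for w2 in graph.neighbors(w1):
            if graph.nodes[w2]["kind"] != "water":
                continue
            for a in res_nb[w1]:
                for b in res_nb[w2]:
                    if a != b:
                        bridged.add(tuple(sorted((a, b))))
    for a, b in bridged:
        ha, hb = helix(a), helix(b)
        if ha is None or hb is None or ha == hb:
            continue
        mat[ha - 1, hb - 1] += 1
        mat[hb - 1, ha - 1] += 1
    return mat


def solvated_residues(graph: nx.Graph) -> frozenset[str]:
    """BW codes of residues sharing at least one edge with a water node."""
    out = set()
    for a, b, d in graph.edges(data=True):
        if d["type"] != "res-water":
            continue
        for n in (a, b):
            nd = graph.nodes[n]
            if nd["kind"] == "residue" and nd["bw"]:
                out.add(nd["bw"])
    return frozenset(out)


def network_stats(graph: nx.Graph) -> NetworkStats:
    return NetworkStats(
        n_water_mediated_total=count_water_mediated_total(graph),
        n_static_switchable=count_static_switchable(graph),
        interface_matrix=interface_breakdown(graph),
        solvated_residues=solvated_residues(graph),
    )


def classify_hydration(count: int, reference: int) -> str:
    """Hyd_low / Hyd_high / reference_like versus the reference receptor count."""
    if count < 0 or reference < 0:
        raise ValueError("counts must be non-negative")
    if count > reference:
        return "Hyd_high"
    if count < reference:
        return "Hyd_low"
    return "reference_like"


def compare_networks(
    stats_query: NetworkStats,
    stats_reference: NetworkStats,
    denominator: str = "query",
) -> NetworkComparison:
    """Fraction of the query's solvated side chains shared with the reference.

    ``denominator='query'`` divides by the query's solvated set (default);
    ``'jaccard'`` divides by the union.
    """
    qset, rset = stats_query.solvated_residues, stats_reference.solvated_residues
    if not qset:
        raise ValueError("query structure has no solvated residues: fraction undefined")
    shared = qset & rset
    if denominator == "query":
        frac = len(shared) / len(qset)
    elif denominator == "jaccard":
        frac = len(shared) / len(qset | rset)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return NetworkComparison(shared=frozenset(shared), fraction_shared=round(frac, 2))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_graph(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write the graph as SIF or GraphML (Cytoscape-compatible)."""
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "sif":
        lines = [f"{a}\t{d['type']}\t{b}" for a, b, d in graph.edges(data=True)]
        for n in graph.nodes:
            if graph.degree[n] == 0:
                lines.append(n)
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = nx.Graph()
        for n, d in graph.nodes(data=True):
            g.add_node(n, **{k: ("" if v is None else v) for k, v in d.items()
                             if k != "pos"})
        for a, b, d in graph.edges(data=True):
            g.add_edge(a, b, **d)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
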