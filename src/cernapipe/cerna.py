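"""Directionality-constrained ceRNA pairing, triplet assembly and the typed
lncRNA-miRNA-mRNA network.

The sponge logic: a miRNA represses its targets, so a genuine
miRNA-transcript regulatory pair must move in opposite directions between
two stages; a lncRNA and an mRNA that both pair the same miRNA in the same
comparison compete for it and form a ceRNA triplet. The network is layered
bipartite (lncRNA-miRNA and miRNA-mRNA edges only); hubs are ranked by
degree over the union graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

NODE_KINDS = ("lncRNA", "miRNA", "mRNA")
_OPPOSITE = {"up": "down", "down": "up"}


@dataclass(frozen=True)
class DirectionalPair:
    mirna: str
    mirna_direction: str
    transcript: str
    kind: str  # lncRNA | mRNA
    transcript_direction: str
    n_sites: int
    comparison: str = ""

    def __post_init__(self) -> None:
        if self.mirna_direction not in _OPPOSITE or self.transcript_direction not in _OPPOSITE:
            raise ValueError(
                f"direction outside {{up, down}} for pair ({self.mirna}, {self.transcript})"
            )
        if self.transcript_direction != _OPPOSITE[self.mirna_direction]:
            raise ValueError(
                f"pair ({self.mirna}, {self.transcript}) is not opposite-directional"
            )
        if self.kind not in ("lncRNA", "mRNA"):
            raise ValueError(f"unknown transcript kind {self.kind!r}")
        if self.n_sites < 1:
            raise ValueError("a retained pair needs at least one predicted site")


@dataclass(frozen=True)
class CernaTriplet:
    lncrna: str
    mirna: str
    mrna: str
    lnc_sites: int
    mrna_sites: int
    mirna_direction: str
    partner_direction: str
    comparison: str = ""

    def key(self) -> tuple:
        return (self.lncrna, self.mirna, self.mrna)


def filter_directional_pairs(
    mirna_directions: dict,
    transcript_directions: dict,
    pair_table: pd.DataFrame,
    comparison: str = "",
) -> list:
    """Retain (miRNA, transcript) pairs where both partners are DE with
    strictly opposite directions and at least one predicted site exists.

    ``mirna_directions``: DE miRNA id -> up/down.
    ``transcript_directions``: DE transcript id -> (kind, up/down).
    ``pair_table``: output of :func:`cernapipe.targets.predict_targets`.
    """
    for d in mirna_directions.values():
        if d not in _OPPOSITE:
            raise ValueError(f"miRNA direction {d!r} outside {{up, down}}")
    for kind, d in transcript_directions.values():
        if d not in _OPPOSITE:
            raise ValueError(f"transcript direction {d!r} outside {{up, down}}")
    pairs = []
    for row in pair_table.itertuples(index=False):
        if row.mirna not in mirna_directions or row.transcript not in transcript_directions:
            continue
        mdir = mirna_directions[row.mirna]
        kind, tdir = transcript_directions[row.transcript]
        if tdir != _OPPOSITE[mdir] or row.n_sites < 1:
            continue
        pairs.append(
            DirectionalPair(
                mirna=row.mirna,
                mirna_direction=mdir,
                transcript=row.transcript,
                kind=kind,
                transcript_direction=tdir,
                n_sites=int(row.n_sites),
                comparison=comparison,
            )
        )
    pairs.sort(key=lambda p: (p.mirna, p.kind, p.transcript))
    return pairs


def assemble_triplets(lnc_pairs, mrna_pairs) -> list:
    """One triplet per (lncRNA, miRNA, mRNA) sharing the miRNA.

    Per miRNA the triplet count is (#lncRNA partners) x (#mRNA partners).
    """
    by_mirna: dict = {}
    mirna_dir: dict = {}
    for p in list(lnc_pairs) + list(mrna_pairs):
        if mirna_dir.setdefault(p.mirna, p.mirna_direction) != p.mirna_direction:
            raise ValueError(
                f"conflicting directions for miRNA {p.mirna} between pair lists"
            )
    for p in lnc_pairs:
        if p.kind != "lncRNA":
            raise ValueError(f"{p.transcript} is not a lncRNA pair")
        by_mirna.setdefault(p.mirna, []).append(p)
    triplets = []
    for g in sorted(mrna_pairs, key=lambda p: (p.mirna, p.transcript)):
        if g.kind != "mRNA":
            raise ValueError(f"{g.transcript} is not an mRNA pair")
        for l in sorted(by_mirna.get(g.mirna, []), key=lambda p: p.transcript):
            triplets.append(
                CernaTriplet(
                    lncrna=l.transcript,
                    mirna=g.mirna,
                    mrna=g.transcript,
                    lnc_sites=l.n_sites,
                    mrna_sites=g.n_sites,
                    mirna_direction=g.mirna_direction,
                    partner_direction=g.transcript_direction,
                    comparison=g.comparison,
                )
            )
    triplets.sort(key=lambda t: (t.mirna, t.lncrna, t.mrna))
    return triplets


@dataclass
class CernaNetwork:
    """Typed undirected graph over lncRNA, miRNA and mRNA nodes."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges:
            ku = self.graph.nodes[u]["kind"]
            kv = self.graph.nodes[v]["kind"]
            if "miRNA" not in (ku, kv) or ku == kv:
                raise ValueError(f"illegal {ku}-{kv} edge ({u}, {v})")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": n,
                "kind": self.graph.nodes[n]["kind"],
                "regulation": self.graph.nodes[n].get("regulation", "none"),
                "degree": d,
            }
            for n, d in self.graph.degree
        ]
        df = pd.DataFrame(rows, columns=["node", "kind", "regulation", "degree"])
        return df.sort_values(["degree", "node"], ascending=[False, True]).reset_index(
            drop=True
        )

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            ku = self.graph.nodes[u]["kind"]
            # orient every edge transcript -> miRNA -> transcript for output
            src, dst = (u, v) if ku != "miRNA" else (v, u) if self.graph.nodes[v]["kind"] != "miRNA" else (u, v)
            rows.append(
                {
                    "source": src,
                    "target": dst,
                    "source_kind": self.graph.nodes[src]["kind"],
                    "target_kind": self.graph.nodes[dst]["kind"],
                    "source_regulation": self.graph.nodes[src].get("regulation", "none"),
                    "target_regulation": self.graph.nodes[dst].get("regulation", "none"),
                    "comparison": data.get("comparison", ""),
                    "site_count": data.get("site_count", 0),
                }
            )
        cols = [
            "source",
            "target",
            "source_kind",
            "target_kind",
            "source_regulation",
            "target_regulation",
            "comparison",
            "site_count",
        ]
        return pd.DataFrame(rows, columns=cols).sort_values(["source", "target"]).reset_index(drop=True)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_network(triplets) -> CernaNetwork:
    """Typed network from triplet arms; shared arms become one edge.

    Node regulation attributes are carried from the DE calls embedded in the
    triplets; conflicting attributes for one node raise.
    """
    g = nx.Graph()

    def add_node(name, kind, regulation):
        if name in g.nodes:
            if g.nodes[name]["kind"] != kind:
                raise ValueError(f"node {name} appears as both {g.nodes[name]['kind']} and {kind}")
            if g.nodes[name]["regulation"] != regulation:
                raise ValueError(f"conflicting regulation attributes for node {name}")
        else:
            g.add_node(name, kind=kind, regulation=regulation)

    def add_edge(u, v, comparison, sites):
        if g.has_edge(u, v):
            comps = set(filter(None, g.edges[u, v]["comparison"].split(",")))
            if comparison:
                comps.add(comparison)
            g.edges[u, v]["comparison"] = ",".join(sorted(comps))
            g.edges[u, v]["site_count"] = max(g.edges[u, v]["site_count"], sites)
        else:
            g.add_edge(u, v, comparison=comparison, site_count=sites)

    for t in triplets:
        add_node(t.mirna, "miRNA", t.mirna_direction)
        add_node(t.lncrna, "lncRNA", t.partner_direction)
        add_node(t.mrna, "mRNA", t.partner_direction)
        add_edge(t.lncrna, t.mirna, t.comparison, t.lnc_sites)
        add_edge(t.mirna, t.mrna, t.comparison, t.mrna_sites)
    return CernaNetwork(g)


def union_networks(networks) -> CernaNetwork:
    """Union of per-comparison networks; a node regulated in conflicting
    directions across comparisons is labelled 'none' (neither up nor down)."""
    g = nx.Graph()
    for net in networks:
        for n, data in net.graph.nodes(data=True):
            if n in g.nodes:
                if g.nodes[n]["regulation"] != data["regulation"]:
                    g.nodes[n]["regulation"] = "none"
            else:
                g.add_node(n, **data)
        for u, v, data in net.graph.edges(data=True):
            if g.has_edge(u, v):
                comps = set(filter(None, g.edges[u, v]["comparison"].split(",")))
                comps |= set(filter(None, data["comparison"].split(",")))
                g.edges[u, v]["comparison"] = ",".join(sorted(comps))
                g.edges[u, v]["site_count"] = max(
                    g.edges[u, v]["site_count"], data["site_count"]
                )
            else:
                g.add_edge(u, v, **data)
    return CernaNetwork(g)


def rank_hubs(network: CernaNetwork, k: int = 25) -> list:
    """Top-k node ids by (degree desc, id asc); all nodes when k exceeds n."""
    if k < 1:
        raise ValueError("k must be >= 1")
    table = network.degree_table()
    return table["node"].head(k).tolist()


def extract_subnet(network: CernaNetwork, seeds, radius: int = 1) -> CernaNetwork:
    """Induced subgraph on all nodes within ``radius`` hops of any seed."""
    seeds = list(seeds)
    unknown = [s for s in seeds if s not in network.graph.nodes]
    if unknown:
        raise ValueError(f"unknown seed id(s): {unknown[:5]}")
    keep = set()
    for s in seeds:
        keep |= set(nx.single_source_shortest_path_length(network.graph, s, cutoff=radius))
    return CernaNetwork(network.graph.subgraph(keep).copy())
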