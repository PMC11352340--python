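"""Gene-set over-representation and candidate-gene interaction networks.

Over-representation uses the one-sided hypergeometric upper tail (Fisher
exact for a 2x2 table with fixed margins); the EASE variant conservatively
decrements the observed overlap by one before computing the tail.
Benjamini-Hochberg q-values are assigned across the tested sets.

Network analysis induces the subgraph of a user-supplied interaction edge
list on the candidate genes, reports connected components of size >= 2
labelled with the owning cases, and can expand a network with the top-k
outside interactors ranked by connectivity to the current nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "CandidateNetwork", "enrich",
           "build_candidate_network", "expand_network"]


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """Over-representation of one gene set in one query list."""

    set_name: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p_value: float
    q_value: float


def enrich(
    list_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    variant: str = "fisher",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each gene set in the list.

    Genes are matched case-insensitively; every set is first intersected
    with the universe and the query list must be a subset of the universe.
    ``variant="ease"`` computes the tail at overlap - 1 (EASE score).
    Results are sorted by ascending p-value.
    """
    if variant not in ("fisher", "ease"):
        raise ValueError(f"unknown enrichment variant {variant!r}")
    uni = {g.upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    query = {g.upper() for g in list_genes}
    if not query <= uni:
        raise ValueError(f"query genes outside universe: {sorted(query - uni)[:5]}")

    names: list[str] = []
    raw: list[tuple[int, int]] = []
    for name, members in gene_sets.items():
        members_u = {g.upper() for g in members} & uni
        overlap = len(members_u & query)
        names.append(name)
        raw.append((overlap, len(members_u)))

    n, big_n = len(query), len(uni)
    p_values: list[float] = []
    for overlap, k in raw:
        eff = overlap - 1 if variant == "ease" else overlap
        if eff <= 0:
            p_values.append(1.0)
        else:
            # P(X >= eff) for X ~ Hypergeom(N=big_n, K=k, n=n)
            p_values.append(float(hypergeom.sf(eff - 1, big_n, k, n)))

    if p_values:
        q_values = multipletests(p_values, method="fdr_bh")[1]
    else:
        q_values = []
    results = [
        EnrichmentResult(
            set_name=name,
            overlap=overlap,
            set_size=k,
            list_size=n,
            universe_size=big_n,
            p_value=p,
            q_value=float(q),
        )
        for name, (overlap, k), p, q in zip(names, raw, p_values, q_values)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.set_name))


@dataclass(slots=True)
class CandidateNetwork:
    """Interaction subgraph over candidate genes.

    nodes maps gene symbol -> set of owning case ids (empty for interactors
    added by expansion); edges carry a provenance label; components lists
    the connected components of size >= 2.
    """

    nodes: dict[str, set[str]] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    components: list[frozenset[str]] = field(default_factory=list)

    def component_cases(self) -> list[set[str]]:
        """Owning cases of each component, in component order."""
        return [
            set().union(*(self.nodes[g] for g in comp)) for comp in self.components
        ]


def _graph(edges: Iterable[tuple[str, str, str]]) -> nx.Graph:
    g = nx.Graph()
    for a, b, label in edges:
        a, b = a.upper(), b.upper()
        if a != b:
            g.add_edge(a, b, label=label)
    return g


def _finalize(net: CandidateNetwork) -> CandidateNetwork:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((a, b) for a, b, _ in net.edges)
    net.components = sorted(
        (frozenset(c) for c in nx.connected_components(g) if len(c) >= 2),
        key=lambda c: (-len(c), sorted(c)),
    )
    return net


def build_candidate_network(
    candidates_per_case: Mapping[str, Iterable[str]],
    edges: Sequence[tuple[str, str, str]],
) -> CandidateNetwork:
    """Induce the interaction subgraph on candidate genes.

    candidates_per_case maps case id -> gene symbols with prioritized
    variants in that case. Only edges whose two endpoints are both
    candidate genes are kept.
    """
    owners: dict[str, set[str]] = {}
    for case, genes in candidates_per_case.items():
        for gene in genes:
            owners.setdefault(gene.upper(), set()).add(case)
    full = _graph(edges)
    sub = full.subgraph(owners)
    net = CandidateNetwork(
        nodes=dict(owners),
        edges=sorted((a, b, d["label"]) if a < b else (b, a, d["label"])
                     for a, b, d in sub.edges(data=True)),
    )
    return _finalize(net)


def expand_network(
    net: CandidateNetwork,
    edges: Sequence[tuple[str, str, str]],
    k: int = 20,
) -> CandidateNetwork:
    """Add up to k outside interactors, best-connected first.

    Candidates are neighbours of current nodes in the full edge list that
    are not yet in the network, ranked by number of connections to current
    nodes, then total degree, then symbol. Returns a new network; the input
    is untouched.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    full = _graph(edges)
    current = set(net.nodes)
    scored: list[tuple[int, int, str]] = []
    for node in full.nodes:
        if node in current:
            continue
        links = sum(1 for nb in full.neighbors(node) if nb in current)
        if links:
            scored.append((-links, -full.degree(node), node))
    added = [name for _, _, name in sorted(scored)[:k]]

    nodes = {g: set(cases) for g, cases in net.nodes.items()}
    nodes.update({name: set() for name in added})
    sub = full.subgraph(nodes)
    expanded = CandidateNetwork(
        nodes=nodes,
        edges=sorted((a, b, d["label"]) if a < b else (b, a, d["label"])
                     for a, b, d in sub.edges(data=True)),
    )
    return _finalize(expanded)
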