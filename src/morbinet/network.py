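"""Signed weighted disease networks per stratum.

Edges are the association records whose relative risk falls in the bottom
or top vigintile of the stratum's RR distribution, carrying the signed
weight transform::

    w~ = RR       if RR > 1   (comorbid edge, positive)
    w~ = -1 / RR  if RR < 1   (exclusivity edge, negative)

so that mutual exclusivity becomes a negative interaction of comparable
magnitude.  The module also quantifies small-world-ness against a G(n, m)
random-graph ensemble and runs the clinical-chapter permutation coherence
test (are linked diseases more often from the same higher-level chapter
than a random labelling would produce?).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx
import numpy as np

from .association import AssociationRecord

__all__ = [
    "SignedNetwork",
    "SmallWorldReport",
    "signed_weight",
    "build_signed_network",
    "main_component",
    "small_worldness",
    "chapter_coherence_test",
]


def signed_weight(rr: float) -> float:
    """The signed transform w~: RR if RR > 1, -1/RR if RR < 1."""
    if rr > 1.0:
        return rr
    if 0.0 < rr < 1.0:
        return -1.0 / rr
    raise ValueError(f"no signed weight for RR = {rr}")


@dataclass
class SignedNetwork:
    """Diseases as nodes, signed transformed RRs as edge weights.

    Wraps an undirected :class:`networkx.Graph`; edge attributes ``rr``
    and ``weight`` (= w~), node attributes ``prevalence``, ``chapter`` and
    ``chronic`` where a catalog was supplied.
    """

    stratum: tuple[str, str]
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def subgraph_by_sign(self, sign: str, absolute: bool = False) -> nx.Graph:
        """Subnetwork of positive or negative edges.

        With ``absolute=True`` the negative subnetwork carries ``|w~|`` as
        ``weight`` (needed wherever weights must be nonnegative, e.g. for
        random-walk centrality).
        """
        if sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        keep = (lambda w: w > 0) if sign == "positive" else (lambda w: w < 0)
        g = nx.Graph()
        for u, v, data in self.graph.edges(data=True):
            if keep(data["weight"]):
                w = abs(data["weight"]) if absolute else data["weight"]
                g.add_edge(u, v, weight=w, rr=data["rr"])
        for node in g.nodes:
            g.nodes[node].update(self.graph.nodes[node])
        return g


@dataclass
class SmallWorldReport:
    clustering: float      # average local clustering coefficient of the network
    avg_path: float        # average shortest path length
    c_rand: float          # G(n, m) ensemble means
    l_rand: float
    s_delta: float         # (C/C_rand) / (L/L_rand)


def build_signed_network(
    records: Sequence[AssociationRecord],
    thresholds: tuple[float, float],
    catalog: Mapping[str, Mapping] | None = None,
    population: int | None = None,
) -> SignedNetwork:
    """Network of one stratum from its association records.

    Edge set: records with ``rr <= lower`` or ``rr >= upper`` threshold
    (records with ``rr == 1`` can never qualify; records with ``rr == 0``
    have no finite signed weight and are skipped with a warning).  Node
    set: diseases incident to at least one edge.
    """
    lower, upper = thresholds
    if not records:
        warnings.warn("no records supplied; empty network", stacklevel=2)
        return SignedNetwork(("", ""), nx.Graph())
    stratum = records[0].stratum
    g = nx.Graph()
    n_zero = 0
    for rec in records:
        if rec.rr == 0.0:
            n_zero += 1
            continue
        if rec.rr <= lower or rec.rr >= upper:
            if rec.rr == 1.0:
                continue
            g.add_edge(*rec.pair, weight=signed_weight(rec.rr), rr=rec.rr)
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-RR records skipped (no finite signed weight)",
            stacklevel=2,
        )
    if g.number_of_edges() == 0:
        warnings.warn(f"empty edge set for stratum {stratum}", stacklevel=2)
    if catalog is not None:
        for node in g.nodes:
            info = catalog.get(node, {})
            g.nodes[node]["chapter"] = info.get("chapter", "")
            g.nodes[node]["chronic"] = bool(info.get("chronic", False))
    return SignedNetwork(stratum, g)


def main_component(net: SignedNetwork) -> SignedNetwork:
    """Largest connected component (edges of both signs count as links).

    Ties on size are broken towards the component containing the
    lexicographically smallest disease code.
    """
    if net.graph.number_of_nodes() == 0:
        return net
    comps = sorted(
        nx.connected_components(net.graph),
        key=lambda c: (-len(c), min(c)),
    )
    return SignedNetwork(net.stratum, net.graph.subgraph(comps[0]).copy())


def _gnm_edges(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """m distinct unordered pairs sampled uniformly from C(n, 2)."""
    iu, ju = np.triu_indices(n, k=1)
    flat = rng.choice(iu.size, size=m, replace=False)
    return np.column_stack([iu[flat], ju[flat]])


def _clustering_and_path(g: ig.Graph) -> tuple[float, float]:
    c = g.transitivity_avglocal_undirected(mode="zero")
    giant = g.connected_components().giant()
    l = giant.average_path_length(directed=False)
    return float(c), float(l)


def small_worldness(
    net: SignedNetwork,
    n_random: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> SmallWorldReport:
    """Small-world-ness S = (C/C_rand)/(L/L_rand) vs a G(n, m) ensemble.

    Edge weights are ignored (all treated as 1).  The network should be
    connected (apply :func:`main_component` first); disconnected random
    samples have their path length computed on their largest component.
    S > 1 indicates the small-world regime.
    """
    g = net.graph
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n < 3 or m < 2:
        raise ValueError("network too small for a small-world estimate")
    if not nx.is_connected(g):
        warnings.warn("network not connected; consider main_component()",
                      stacklevel=2)
    idx = {node: k for k, node in enumerate(g.nodes)}
    edges = [(idx[u], idx[v]) for u, v in g.edges]
    gi = ig.Graph(n=n, edges=edges, directed=False)
    c_obs, l_obs = _clustering_and_path(gi)

    rng = np.random.default_rng(seed)
    cs = np.empty(n_random)
    ls = np.empty(n_random)
    for k in range(n_random):
        re = _gnm_edges(n, m, rng)
        gr = ig.Graph(n=n, edges=[tuple(e) for e in re], directed=False)
        cs[k], ls[k] = _clustering_and_path(gr)
    c_rand, l_rand = float(cs.mean()), float(ls.mean())
    s_delta = (c_obs / c_rand) / (l_obs / l_rand)
    return SmallWorldReport(c_obs, l_obs, c_rand, l_rand, float(s_delta))


def chapter_coherence_test(
    net: SignedNetwork,
    catalog: Mapping[str, Mapping] | Mapping[str, str],
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, np.ndarray, float]:
    """Permutation test of clinical-chapter sharing along network edges.

    ``observed`` is the fraction of edges whose endpoints share a chapter;
    the null shuffles the node -> chapter labelling while keeping the edge
    structure fixed.  Returns ``(observed, null_values, p)`` with the
    add-one empirical p-value ``(1 + #{null >= obs}) / (n_perm + 1)``.
    """
    nodes = list(net.graph.nodes)
    if not nodes:
        raise ValueError("empty network")

    def chap(code: str) -> str:
        entry = catalog[code]
        return entry["chapter"] if isinstance(entry, Mapping) else entry

    missing = [c for c in nodes if c not in catalog]
    if missing:
        raise KeyError(f"nodes with no chapter annotation: {sorted(missing)}")
    labels = np.array([chap(c) for c in nodes])
    idx = {node: k for k, node in enumerate(nodes)}
    eu = np.array([idx[u] for u, _ in net.graph.edges], dtype=np.int64)
    ev = np.array([idx[v] for _, v in net.graph.edges], dtype=np.int64)
    observed = float(np.mean(labels[eu] == labels[ev]))

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(len(nodes))
        null[k] = np.mean(labels[perm[eu]] == labels[perm[ev]])
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return observed, null, p
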