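"""PPI network construction and six-centrality key-target selection.

A protein-protein interaction network is read from a STRING-style export
(two node columns plus a combined confidence score) keeping edges whose
score is strictly above a confidence cutoff (default 0.9). Six node
centralities are computed on the resulting unweighted simple graph:

* BC — raw (unnormalized) shortest-path betweenness over unordered pairs;
* CC — closeness, ``(n_c - 1) / sum of distances`` within the node's
  connected component of size ``n_c`` (0 for isolated nodes);
* DC — degree;
* EC — eigenvector centrality: the nonnegative, Euclidean-unit-norm
  principal eigenvector of the largest connected component's adjacency
  matrix; nodes outside that component score 0;
* LAC — local average connectivity: the mean degree of a node's
  neighbors within the subgraph induced by those neighbors;
* NC — network centrality: the sum over a node's edges of the edge
  clustering coefficient ``triangles(v, w) / min(deg v - 1, deg w - 1)``
  (0 when the denominator is 0).

Key targets are the nodes at or above the per-metric median on all six
centralities simultaneously, the selection rule popularized by topology-
based plugin workflows. Medians use midpoint interpolation so the rule is
deterministic for even node counts.

Edge confidences act only as a filter, never as weights; all centralities
are computed on the unweighted graph.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

CENTRALITY_COLUMNS = ("bc", "cc", "dc", "ec", "lac", "nc")

DEFAULT_MIN_SCORE = 0.9


def load_string_edges(
    edge_table: Union[str, Path, pd.DataFrame],
    min_score: float = DEFAULT_MIN_SCORE,
    node_universe: Optional[Iterable[str]] = None,
) -> nx.Graph:
    """Build an undirected simple graph from a STRING-style edge export.

    Parameters
    ----------
    edge_table
        Path to a TSV with columns ``node1``, ``node2``, ``combined_score``
        (extra columns ignored; the first two columns and the score column
        are used), or an equivalent DataFrame.
    min_score
        Edges are kept only when their score is strictly greater than
        this cutoff, on a 0-1 scale. Scores on STRING's 0-1000 integer
        scale are auto-detected (any score > 1) and divided by 1000.
    node_universe
        Optional explicit node list; its members are added as (possibly
        isolated) nodes even when no edge survives the filter. Without
        it, only endpoint nodes of surviving edges appear.

    Duplicate rows and reversed duplicates collapse to a single
    undirected edge; self-loops are dropped.
    """
    if isinstance(edge_table, (str, Path)):
        df = pd.read_csv(edge_table, sep="\t", dtype=str)
    else:
        df = edge_table.copy()
    cols = list(df.columns)
    if "combined_score" in cols:
        score_col = "combined_score"
    elif "score" in cols:
        score_col = "score"
    else:
        score_col = cols[2]
    n1_col, n2_col = cols[0], cols[1]
    try:
        scores = df[score_col].astype(float).to_numpy()
    except ValueError as exc:
        bad = df.index[pd.to_numeric(df[score_col], errors="coerce").isna()]
        raise ValueError(
            f"malformed score on row(s) {[int(i) + 2 for i in bad[:5]]} "
            f"of the edge table"
        ) from exc
    if np.any(np.isnan(scores)):
        bad = np.flatnonzero(np.isnan(scores))
        raise ValueError(f"missing score on row(s) {[int(i) + 2 for i in bad[:5]]}")
    if scores.size and scores.max() > 1.0:  # STRING 0-1000 integer scale
        scores = scores / 1000.0

    g = nx.Graph()
    if node_universe is not None:
        g.add_nodes_from(node_universe)
    for (a, b), s in zip(df[[n1_col, n2_col]].itertuples(index=False), scores):
        if pd.isna(a) or pd.isna(b):
            raise ValueError("malformed edge row with a missing node name")
        a, b = str(a).strip(), str(b).strip()
        if a == b or s <= min_score:
            continue
        prev = g.get_edge_data(a, b, default=None)
        if prev is None or s > prev.get("score", 0.0):
            g.add_edge(a, b, score=float(s))
    return g


def _largest_component(g: nx.Graph) -> set:
    """Largest connected component; ties broken by smallest member node."""
    comps = sorted(
        nx.connected_components(g),
        key=lambda c: (-len(c), min(str(n) for n in c)),
    )
    return comps[0]


def betweenness(g: nx.Graph) -> dict:
    """Raw betweenness over unordered node pairs, by Brandes' algorithm.

    Shortest-path counts are integers and dependency accumulation is done
    in exact rational arithmetic, so results are the correctly rounded
    floats of the true rational values (on small graphs they match a
    brute-force path-enumeration oracle bit for bit).
    """
    bc = {v: Fraction(0) for v in g.nodes}
    for s in g.nodes:
        # BFS from s: path counts sigma, predecessor lists, visit order
        sigma = {s: 1}
        dist = {s: 0}
        preds: dict = {s: []}
        order = []
        q = deque([s])
        while q:
            v = q.popleft()
            order.append(v)
            for w in g[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0
                    preds[w] = []
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = {v: Fraction(0) for v in order}
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += Fraction(sigma[v], sigma[w]) * (1 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return {v: float(b / 2) for v, b in bc.items()}  # each pair counted twice


def local_average_connectivity(g: nx.Graph) -> dict:
    """LAC(v): mean within-neighborhood degree of v's neighbors."""
    lac = {}
    for v in g.nodes:
        nbrs = set(g[v])
        if not nbrs:
            lac[v] = 0.0
            continue
        # degree of each neighbor inside the induced neighborhood subgraph
        total = 0
        for w in nbrs:
            total += sum(1 for u in g[w] if u in nbrs)
        lac[v] = total / len(nbrs)
    return lac


def edge_clustering_coefficient(g: nx.Graph, v, w) -> Fraction:
    """ECC(v, w) = triangles through edge (v, w) / min(deg v - 1, deg w - 1).

    Defined as 0 when the denominator is 0 (an endpoint of degree 1).
    Returned as an exact rational.
    """
    denom = min(g.degree(v) - 1, g.degree(w) - 1)
    if denom <= 0:
        return Fraction(0)
    triangles = len(set(g[v]) & set(g[w]))
    return Fraction(triangles, denom)


def network_centrality(g: nx.Graph) -> dict:
    """NC(v): sum of edge clustering coefficients over v's edges.

    Summed in exact rational arithmetic and rounded once to float.
    """
    return {
        v: float(sum((edge_clustering_coefficient(g, v, w) for w in g[v]),
                     start=Fraction(0)))
        for v in g.nodes
    }


def _eigenvector_centrality(g: nx.Graph) -> dict:
    """Nonnegative unit-norm principal eigenvector of the largest component."""
    ec = dict.fromkeys(g.nodes, 0.0)
    comp = _largest_component(g)
    if len(comp) == 1:
        # degenerate: a single node is trivially the whole spectrum
        ec[next(iter(comp))] = 1.0
        return ec
    sub = g.subgraph(comp)
    nodes = sorted(sub.nodes, key=str)
    a = nx.to_numpy_array(sub, nodelist=nodes)
    vals, vecs = np.linalg.eigh(a)
    vec = vecs[:, -1]
    if vec.sum() < 0:
        vec = -vec
    vec = np.abs(vec)  # Perron vector is nonnegative; scrub rounding noise
    vec /= np.linalg.norm(vec)
    ec.update(zip(nodes, vec))
    return ec


def compute_centralities(g: nx.Graph) -> pd.DataFrame:
    """All six centralities for every node, as a DataFrame indexed by node.

    Columns are ``bc, cc, dc, ec, lac, nc`` (see module docstring for the
    exact definitions). Raises on an empty graph.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities of an empty graph")
    bc = betweenness(g)
    cc = nx.closeness_centrality(g, wf_improved=False)
    dc = dict(g.degree())
    ec = _eigenvector_centrality(g)
    lac = local_average_connectivity(g)
    nc = network_centrality(g)
    nodes = sorted(g.nodes, key=str)
    return pd.DataFrame(
        {
            "bc": [bc[v] for v in nodes],
            "cc": [cc[v] for v in nodes],
            "dc": [float(dc[v]) for v in nodes],
            "ec": [ec[v] for v in nodes],
            "lac": [lac[v] for v in nodes],
            "nc": [nc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def select_key_targets(table: pd.DataFrame) -> set:
    """Nodes at or above the median on all six centrality metrics.

    Medians are midpoint-interpolated (the mean of the two middle order
    statistics for even row counts), making the >=-median rule
    deterministic and row-order invariant. Values within 1e-9 relative
    (1e-12 absolute) of the median count as meeting it, so eigen-solver
    rounding cannot split exactly symmetric nodes.
    """
    if table.empty:
        raise ValueError("centrality table is empty")
    cols = list(CENTRALITY_COLUMNS)
    medians = table[cols].median(axis=0)
    at_or_above = (table[cols] >= medians) | np.isclose(
        table[cols], medians, rtol=1e-9, atol=1e-12
    )
    return set(table.index[at_or_above.all(axis=1)])
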