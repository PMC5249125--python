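"""Neighbour-joining with bootstrap, monophyly assessment, and OTU clustering.

The NJ tree is a clustering device over the p-distance matrix, not a
phylogenetic estimate; bootstrap supports are the percentage of
column-resampled replicates reproducing each internal bipartition.  OTUs
are delimited by a refined single-linkage procedure: single-linkage
connected components at a seed threshold (default 2.2%, the published BIN
seed value), with clusters of excessive diameter re-partitioned by
complete-linkage agglomeration.  The refinement stage is an explicit
approximation of the BIN system's unpublished cluster re-evaluation and is
labelled as such in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix, encode_alignment
from .io import BarcodeLibrary

DEFAULT_RSL_THRESHOLD = 0.022  # published BIN seed threshold (fraction)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeWithSupport:
    """Unrooted tree over specimen ids as a networkx graph.

    Leaf nodes are specimen-id strings; internal nodes are integers.  Edges
    carry ``length`` and, on internal edges after bootstrapping, ``support``
    in [0, 100].  NJ branch lengths may be negative; they are kept and only
    clamped for display.
    """

    graph: nx.Graph

    def leaves(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if isinstance(n, str))

    def bipartitions(self) -> list[tuple[tuple, frozenset, Optional[float]]]:
        """(edge, leaf side, support) for every edge.

        The reported side is the one not containing the lexicographically
        smallest leaf, giving a canonical form comparable across trees.
        Computed in one rooted traversal (descendant leaf sets).
        """
        leaves = self.leaves()
        ref = leaves[0]
        g = self.graph
        parent: dict = {ref: None}
        order = [ref]
        stack = [ref]
        while stack:
            node = stack.pop()
            for nb in g.neighbors(node):
                if nb not in parent:
                    parent[nb] = node
                    order.append(nb)
                    stack.append(nb)
        below: dict = {}
        for node in reversed(order):
            acc = {node} if isinstance(node, str) else set()
            for nb in g.neighbors(node):
                if nb != parent[node] and parent.get(nb) == node:
                    acc |= below[nb]
            below[node] = acc
        out = []
        for node in order[1:]:
            p = parent[node]
            data = g.edges[node, p]
            out.append(((node, p), frozenset(below[node]), data.get("support")))
        return out

    def internal_bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial splits (both sides with >= 2 leaves)."""
        n = len(self.leaves())
        return {
            side
            for _, side, _ in self.bipartitions()
            if 2 <= len(side) <= n - 2
        }

    def to_newick(self, clamp_negative: bool = True, support_labels: bool = True) -> str:
        """Newick string rooted at an arbitrary internal node."""
        g = self.graph
        internal = [n for n in g.nodes if not isinstance(n, str)]
        root = internal[0] if internal else next(iter(g.nodes))

        def fmt(node, parent) -> str:
            children = [nb for nb in g.neighbors(node) if nb != parent]
            if not children:
                ln = g.edges[node, parent]["length"]
                return f"{node}:{max(ln, 0.0) if clamp_negative else ln:.6f}"
            inner = ",".join(fmt(c, node) for c in children)
            if parent is None:
                return f"({inner});"
            ln = g.edges[node, parent]["length"]
            sup = g.edges[node, parent].get("support")
            label = f"{sup:.0f}" if (support_labels and sup is not None) else ""
            return f"({inner}){label}:{max(ln, 0.0) if clamp_negative else ln:.6f}"

        return fmt(root, None)


def _check_defined(d: np.ndarray) -> None:
    iu = np.triu_indices(d.shape[0], k=1)
    if np.isnan(d[iu]).any():
        raise ValueError("distance matrix contains undefined (NaN) pairs")


def nj_tree(m: DistanceMatrix) -> TreeWithSupport:
    """Saitou-Nei neighbour joining; deterministic for any input order.

    Q-matrix ties are broken by the lexicographically smallest pair of
    subtree representatives (each active node represented by its smallest
    leaf id), so the result does not depend on matrix row order.
    """
    n = len(m.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 specimens")
    _check_defined(m.d)
    g = nx.Graph()
    d = m.d.astype(float).copy()
    nodes: list = list(m.ids)  # active node keys, parallel to d rows
    reps = list(m.ids)  # lexicographic representative leaf of each subtree
    next_internal = 0

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        q = (k - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        ties = ties[ties[:, 0] < ties[:, 1]]
        # deterministic tie-break: smallest (rep_lo, rep_hi) pair
        rank = np.empty(k, dtype=np.int64)
        rank[np.argsort(np.array(reps))] = np.arange(k)
        ra, rb = rank[ties[:, 0]], rank[ties[:, 1]]
        key = np.minimum(ra, rb) * (k + 1) + np.maximum(ra, rb)
        i, j = sorted(ties[int(np.argmin(key))])
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        vj = d[i, j] - vi
        new = next_internal
        next_internal += 1
        g.add_edge(nodes[i], new, length=float(vi))
        g.add_edge(nodes[j], new, length=float(vj))
        du = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], du[keep]])
        d = np.hstack([d, np.append(du[keep], 0.0)[:, None]])
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[x] for x in keep] + [new]
        reps = [reps[x] for x in keep] + [new_rep]

    # closed-form three-point resolution
    (a, b, c), dm = nodes, d
    centre = next_internal
    g.add_edge(a, centre, length=float((dm[0, 1] + dm[0, 2] - dm[1, 2]) / 2))
    g.add_edge(b, centre, length=float((dm[0, 1] + dm[1, 2] - dm[0, 2]) / 2))
    g.add_edge(c, centre, length=float((dm[0, 2] + dm[1, 2] - dm[0, 1]) / 2))
    return TreeWithSupport(g)


def bootstrap_supports(
    library: BarcodeLibrary,
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeWithSupport:
    """NJ tree with bootstrap supports from alignment-column resampling.

    Replicate ``r`` draws its columns from a deterministic stream derived
    from ``(seed, r)``, so runs with the same seed are bit-identical.
    Replicates producing undefined pairwise distances are dropped (and the
    drop count recorded on the tree as ``n_dropped_replicates``).
    """
    from .distance import distance_matrix

    base_m = distance_matrix(library)
    tree = nj_tree(base_m)
    enc = encode_alignment([r.sequence for r in library])
    valid = enc >= 0
    n, L = enc.shape
    counts: dict[frozenset, int] = {}
    edges_by_split = {}
    leaves = set(tree.leaves())
    for edge, side, _ in tree.bipartitions():
        if 2 <= len(side) <= len(leaves) - 2:
            edges_by_split[side] = edge
    used = 0
    dropped = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        cols = rng.integers(0, L, size=L)
        e = enc[:, cols]
        v = valid[:, cols]
        d = np.zeros((n, n))
        ok = True
        for i in range(n):
            both = v[i] & v[i + 1 :]
            comp = both.sum(axis=1)
            if (comp == 0).any():
                ok = False
                break
            mism = ((e[i] != e[i + 1 :]) & both).sum(axis=1)
            d[i, i + 1 :] = mism / comp
            d[i + 1 :, i] = d[i, i + 1 :]
        if not ok:
            dropped += 1
            continue
        rep_tree = nj_tree(DistanceMatrix(library.ids(), d, np.ones_like(d, dtype=int)))
        used += 1
        for split in rep_tree.internal_bipartitions():
            counts[split] = counts.get(split, 0) + 1
    for split, edge in edges_by_split.items():
        sup = 100.0 * counts.get(split, 0) / used if used else float("nan")
        tree.graph.edges[edge]["support"] = sup
    tree.graph.graph["n_bootstrap_used"] = used
    tree.graph.graph["n_dropped_replicates"] = dropped
    return tree


def species_cohesion(
    tree: TreeWithSupport, labels: dict[str, str]
) -> dict[str, dict]:
    """Unrooted monophyly per species label.

    A species is cohesive iff one tree edge separates exactly its specimens
    from everything else; the bipartition's bootstrap support (if computed)
    is attached.  Singleton species are cohesive by convention with
    undefined support.
    """
    leaves = tree.leaves()
    by_species: dict[str, set] = {}
    for leaf in leaves:
        by_species.setdefault(labels[leaf], set()).add(leaf)
    all_leaves = frozenset(leaves)
    ref = leaves[0]
    splits = {}
    for _, side, sup in tree.bipartitions():
        splits[side] = sup
        splits[all_leaves - side] = sup
    out = {}
    for sp, members in sorted(by_species.items()):
        fs = frozenset(members)
        if len(members) == 1 or fs == all_leaves:
            out[sp] = {"cohesive": True, "support": None, "n": len(members)}
        elif fs in splits:
            out[sp] = {"cohesive": True, "support": splits[fs], "n": len(members)}
        else:
            out[sp] = {"cohesive": False, "support": None, "n": len(members)}
    return out


# ---------------------------------------------------------------------------
# OTU clustering


@dataclass
class OtuCluster:
    """A BIN-like operational taxonomic unit."""

    otu_id: str
    members: list[str]
    taxon_variation: dict[str, int] = field(default_factory=dict)
    status: Optional[str] = None  # concordant | discordant | singleton

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("OTU must have at least one member")


def rsl_cluster(
    m: DistanceMatrix,
    threshold: float = DEFAULT_RSL_THRESHOLD,
    refine: bool = True,
) -> list[OtuCluster]:
    """Refined single-linkage OTU delimitation.

    Stage 1: single-linkage connected components over pairs at distance
    <= threshold.  Stage 2 (refine): any cluster whose diameter exceeds
    2 x threshold is re-partitioned by complete-linkage agglomeration cut at
    the threshold.  Deterministic: members and OTUs are processed in sorted
    order regardless of input order.
    """
    n = len(m.ids)
    order = np.argsort(np.array(m.ids))
    ids = [m.ids[k] for k in order]
    d = m.d[np.ix_(order, order)]
    with np.errstate(invalid="ignore"):
        adj = csr_matrix((d <= threshold) & ~np.isnan(d))
    _, comp = connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(comp[k], []).append(k)

    clusters: list[list[int]] = []
    for members in groups.values():
        sub = d[np.ix_(members, members)]
        if refine and len(members) > 2 and np.nanmax(sub) > 2 * threshold:
            z = linkage(squareform(sub, checks=False), method="complete")
            flat = fcluster(z, t=threshold, criterion="distance")
            for c in np.unique(flat):
                clusters.append([members[k] for k in np.where(flat == c)[0]])
        else:
            clusters.append(members)

    clusters.sort(key=lambda ms: ids[ms[0]])
    return [
        OtuCluster(otu_id=f"OTU_{k + 1:04d}", members=[ids[i] for i in ms])
        for k, ms in enumerate(clusters)
    ]


def _genus(label: str) -> str:
    return label.split()[0] if label.split() else label


def discordance_report(
    otus: list[OtuCluster],
    labels: dict[str, str],
    taxonomy: Optional[dict[str, str]] = None,
) -> tuple[list[OtuCluster], pd.DataFrame]:
    """Fill each OTU's taxon-variation table and concordance status.

    ``taxonomy`` optionally maps genus -> family so conflicts spanning
    families can be ranked; without it conflicts across genera rank as
    "Genus".  Returns the updated OTUs and a report frame with taxon
    variation formatted "Taxon[n]".
    """
    rows = []
    for otu in otus:
        counts: dict[str, int] = {}
        for sid in otu.members:
            counts[labels[sid]] = counts.get(labels[sid], 0) + 1
        otu.taxon_variation = counts
        if len(otu.members) == 1:
            otu.status = "singleton"
        elif len(counts) == 1:
            otu.status = "concordant"
        else:
            otu.status = "discordant"
        genera = {_genus(sp) for sp in counts}
        if len(counts) <= 1:
            rank = ""
        elif len(genera) == 1:
            rank = "Species"
        elif taxonomy and len({taxonomy.get(g, g) for g in genera}) > 1:
            rank = "Family"
        else:
            rank = "Genus"
        variation = ", ".join(
            f"{sp}[{n}]"
            for sp, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        rows.append((otu.otu_id, len(otu.members), otu.status, rank, variation))
    frame = pd.DataFrame(
        rows, columns=["otu_id", "n_members", "status", "rank_of_conflict", "taxon_variation"]
    )
    return otus, frame
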