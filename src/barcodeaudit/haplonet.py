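"""Per-species haplotype networks from parsimony trees.

Conspecific sequences are first restricted to the columns that are
unambiguous (A/C/G/T) in every record — complete deletion, so haplotype
identity is well defined — then collapsed into haplotypes.  A maximum-
parsimony tree over the haplotypes (exact branch-and-bound up to 10
haplotypes, NNI hill climbing above) is converted into a network by
assigning Fitch states to internal nodes, merging internal nodes that
coincide with sampled haplotypes, and keeping the remainder as inferred
(frequency-0) median nodes.  Edges are weighted by the Hamming distance
between adjacent node sequences, i.e. mutational steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .io import SpecimenRecord

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_BASE_OF_BIT = {1: "A", 2: "C", 4: "G", 8: "T"}


def _lowest_base(mask: int) -> str:
    for bit in (1, 2, 4, 8):
        if mask & bit:
            return _BASE_OF_BIT[bit]
    raise ValueError("empty state set")


# ---------------------------------------------------------------------------
# haplotype collapsing


@dataclass
class HaplotypeNode:
    hap_id: str
    sequence: str  # over the retained (complete-deletion) columns
    frequency: int
    region_counts: dict[str, int] = field(default_factory=dict)
    members: list[str] = field(default_factory=list)
    defining_mutations: list[tuple[int, str, str]] = field(default_factory=list)
    is_median: bool = False

    def __post_init__(self) -> None:
        if not self.is_median and self.frequency != sum(self.region_counts.values()):
            raise ValueError("frequency must equal the sum of region counts")


@dataclass
class HaplotypeTable:
    species: str
    haplotypes: list[HaplotypeNode]
    columns: list[int]  # retained alignment columns, 1-based

    @property
    def n_specimens(self) -> int:
        return sum(h.frequency for h in self.haplotypes)


def _species_initials(species: str) -> str:
    words = species.split()
    return "".join(w[0].lower() for w in words[:2]) or "x"


def collapse_haplotypes(
    records: Sequence[SpecimenRecord], species: Optional[str] = None
) -> HaplotypeTable:
    """Collapse one species' records into haplotypes.

    Columns carrying any gap/ambiguity in any record are removed first;
    the retained 1-based column indices are recorded so mutation positions
    refer to the original alignment.  Haplotype ids are assigned by
    decreasing frequency, ties by first occurrence, and named
    "H<initials><rank>".  Defining mutations are listed relative to the
    first (most frequent) haplotype.
    """
    if not records:
        raise ValueError("collapse_haplotypes needs at least one record")
    species = species or records[0].morph_label
    L = len(records[0].sequence)
    keep = [
        c
        for c in range(L)
        if all(r.sequence[c] in "ACGT" for r in records)
    ]
    if not keep:
        raise ValueError(f"{species}: no column is unambiguous in every record")
    trimmed = ["".join(r.sequence[c] for c in keep) for r in records]

    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for k, t in enumerate(trimmed):
        if t not in groups:
            groups[t] = []
            order.append(t)
        groups[t].append(k)
    ranked = sorted(order, key=lambda t: (-len(groups[t]), order.index(t)))

    prefix = "H" + _species_initials(species)
    haps = []
    ref = ranked[0]
    for rank, t in enumerate(ranked, start=1):
        member_recs = [records[k] for k in groups[t]]
        region: dict[str, int] = {}
        for r in member_recs:
            region[r.division] = region.get(r.division, 0) + 1
        muts = [
            (keep[c] + 1, ref[c], t[c]) for c in range(len(keep)) if t[c] != ref[c]
        ]
        haps.append(
            HaplotypeNode(
                hap_id=f"{prefix}{rank}",
                sequence=t,
                frequency=len(member_recs),
                region_counts=region,
                members=[r.specimen_id for r in member_recs],
                defining_mutations=muts,
            )
        )
    return HaplotypeTable(species=species, haplotypes=haps, columns=[c + 1 for c in keep])


# ---------------------------------------------------------------------------
# parsimony trees

EXACT_LIMIT = 10  # branch-and-bound bound; NNI hill climbing above
COUNT_LIMIT = 8  # co-optimal trees are counted exhaustively up to here
MAX_NNI_SWEEPS = 50  # cap on first-improvement NNI sweeps


@dataclass
class ParsimonyTree:
    """Unrooted tree over haplotype ids with its parsimony score."""

    adjacency: dict  # node -> set of neighbours; leaves are hap_id strings
    score: int
    n_cooptimal: Optional[int] = None  # counted by the exact solver only

    def leaves(self) -> list[str]:
        return sorted(n for n in self.adjacency if isinstance(n, str))


def _leaf_masks(haps: Sequence[HaplotypeNode]) -> tuple[dict[str, np.ndarray], int]:
    """Bitmask arrays over variable columns only (constant columns score 0)."""
    seqs = {h.hap_id: h.sequence for h in haps}
    L = len(haps[0].sequence)
    variable = [c for c in range(L) if len({s[c] for s in seqs.values()}) > 1]
    masks = {
        hid: np.array([_BITS[s[c]] for c in variable], dtype=np.uint8)
        for hid, s in seqs.items()
    }
    return masks, len(variable)


def _fitch(adj: dict, masks: dict[str, np.ndarray], n_cols: int) -> int:
    """Exact Fitch parsimony score, leaf-rooted, iterative postorder."""
    leaves = [n for n in adj if isinstance(n, str)]
    if len(leaves) == 1 or n_cols == 0:
        return 0
    if len(leaves) == 2:
        a, b = leaves
        return int((masks[a] != masks[b]).sum())
    root = leaves[0]
    start = next(iter(adj[root]))
    # iterative DFS: build postorder with parents
    parent = {start: root}
    order = [start]
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb != parent[node]:
                parent[nb] = node
                order.append(nb)
                stack.append(nb)
    total = 0
    state: dict = {}
    for node in reversed(order):
        if isinstance(node, str):
            state[node] = masks[node]
            continue
        acc = None
        for nb in adj[node]:
            if nb == parent[node]:
                continue
            child = state[nb]
            if acc is None:
                acc = child
            else:
                inter = acc & child
                empty = inter == 0
                total += int(empty.sum())
                acc = np.where(empty, acc | child, inter)
        state[node] = acc
    total += int(((state[start] & masks[root]) == 0).sum())
    return total


def _edges(adj: dict) -> list[tuple]:
    seen = set()
    out = []
    for u, nbs in adj.items():
        for v in nbs:
            if (v, u) not in seen:
                seen.add((u, v))
                out.append((u, v))
    return out


def _splits(adj: dict) -> tuple:
    """Canonical, comparable representation of the unrooted topology."""
    leaves = sorted(n for n in adj if isinstance(n, str))
    ref = leaves[0]
    splits = set()
    for u, v in _edges(adj):
        comp = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for nb in adj[x]:
                if nb != v and nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        side = frozenset(n for n in comp if isinstance(n, str))
        if ref in side:
            side = frozenset(leaves) - side
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(tuple(sorted(side)))
    return tuple(sorted(splits))


def _copy_adj(adj: dict) -> dict:
    return {k: set(v) for k, v in adj.items()}


def _insert(adj: dict, leaf: str, edge: tuple, new_internal: int) -> None:
    u, v = edge
    adj[u].discard(v)
    adj[v].discard(u)
    adj[new_internal] = {u, v, leaf}
    adj[u].add(new_internal)
    adj[v].add(new_internal)
    adj[leaf] = {new_internal}


def _remove(adj: dict, leaf: str, internal: int) -> None:
    u, v = [n for n in adj[internal] if n != leaf]
    del adj[internal]
    del adj[leaf]
    adj[u].discard(internal)
    adj[v].discard(internal)
    adj[u].add(v)
    adj[v].add(u)


def _exact_search(
    hap_ids: list[str],
    masks: dict[str, np.ndarray],
    n_cols: int,
    count_cooptimal: bool = True,
) -> tuple[dict, int, Optional[int]]:
    """Branch-and-bound over unrooted topologies.

    With ``count_cooptimal`` the plateau of equally parsimonious trees is
    enumerated exhaustively and the canonically smallest one returned (with
    the count); otherwise the bound prunes ties and the first optimum found
    in the deterministic insertion order is kept.  Both modes return a tree
    of exactly minimal score.
    """
    if len(hap_ids) == 2:
        adj = {hap_ids[0]: {hap_ids[1]}, hap_ids[1]: {hap_ids[0]}}
        return adj, _fitch(adj, masks, n_cols), 1
    a, b, c = hap_ids[:3]
    adj = {-1: {a, b, c}, a: {-1}, b: {-1}, c: {-1}}
    best = {"score": None, "count": 0, "tree": None, "key": None}

    def recurse(adj: dict, idx: int, next_internal: int) -> None:
        score = _fitch(adj, masks, n_cols)
        if best["score"] is not None:
            # completions can never score below the partial tree
            if score > best["score"] or (not count_cooptimal and score >= best["score"]):
                return
        if idx == len(hap_ids):
            if best["score"] is None or score < best["score"]:
                best.update(score=score, count=1, tree=_copy_adj(adj), key=None)
                if count_cooptimal:
                    best["key"] = _splits(adj)
            elif score == best["score"] and count_cooptimal:
                best["count"] += 1
                key = _splits(adj)
                if key < best["key"]:
                    best.update(tree=_copy_adj(adj), key=key)
            return
        leaf = hap_ids[idx]
        for edge in _edges(adj):
            _insert(adj, leaf, edge, next_internal)
            recurse(adj, idx + 1, next_internal - 1)
            _remove(adj, leaf, next_internal)

    recurse(adj, 3, -2)
    count = best["count"] if count_cooptimal else None
    return best["tree"], best["score"], count


def _nni_neighbours(adj: dict) -> Iterable[dict]:
    """All one-step nearest-neighbour-interchange rearrangements."""
    for u, v in _edges(adj):
        if isinstance(u, str) or isinstance(v, str):
            continue
        u_sub = [n for n in adj[u] if n != v]
        v_sub = [n for n in adj[v] if n != u]
        for b in v_sub:
            a = u_sub[0]
            new = _copy_adj(adj)
            new[u].discard(a)
            new[a].discard(u)
            new[v].discard(b)
            new[b].discard(v)
            new[u].add(b)
            new[b].add(u)
            new[v].add(a)
            new[a].add(v)
            yield new


def _heuristic_search(
    hap_ids: list[str], masks: dict[str, np.ndarray], n_cols: int, seed: int
) -> tuple[dict, int]:
    """Greedy stepwise addition followed by NNI hill climbing."""
    rng = np.random.default_rng(seed)
    order = list(hap_ids)
    a, b, c = order[:3]
    adj = {-1: {a, b, c}, a: {-1}, b: {-1}, c: {-1}}
    next_internal = -2
    for leaf in order[3:]:
        best_edge, best_score = None, None
        for edge in _edges(adj):
            _insert(adj, leaf, edge, next_internal)
            s = _fitch(adj, masks, n_cols)
            _remove(adj, leaf, next_internal)
            if best_score is None or s < best_score:
                best_edge, best_score = edge, s
        _insert(adj, leaf, best_edge, next_internal)
        next_internal -= 1
    score = _fitch(adj, masks, n_cols)
    improved, sweeps = True, 0
    while improved and sweeps < MAX_NNI_SWEEPS:
        improved = False
        sweeps += 1
        for cand in _nni_neighbours(adj):
            s = _fitch(cand, masks, n_cols)
            if s < score:
                adj, score = cand, s
                improved = True
                break
    _ = rng  # reserved for randomised restarts
    return adj, score


def parsimony_tree(table: HaplotypeTable, seed: int = 0) -> ParsimonyTree:
    """Maximum-parsimony tree over a species' haplotypes.

    Exact branch-and-bound up to 10 haplotypes (intraspecific data are
    star-like, so the co-optimal plateau grows explosively beyond that);
    the number of co-optimal topologies is enumerated up to 8.  Larger
    sets use deterministic stepwise addition plus NNI hill climbing.
    """
    haps = table.haplotypes
    if len(haps) == 1:
        return ParsimonyTree({haps[0].hap_id: set()}, score=0, n_cooptimal=1)
    masks, n_cols = _leaf_masks(haps)
    ids = [h.hap_id for h in haps]
    if len(haps) <= EXACT_LIMIT:
        adj, score, count = _exact_search(
            ids, masks, n_cols, count_cooptimal=len(haps) <= COUNT_LIMIT
        )
        return ParsimonyTree(adj, score=score, n_cooptimal=count)
    adj, score = _heuristic_search(ids, masks, n_cols, seed)
    return ParsimonyTree(adj, score=score)


# ---------------------------------------------------------------------------
# network conversion


@dataclass
class HaplotypeNetwork:
    species: str
    graph: nx.Graph  # node attrs: frequency, region_counts, is_median, sequence
    parsimony_score: int

    def node(self, hap_id: str) -> dict:
        return self.graph.nodes[hap_id]

    def to_edge_frame(self):
        import pandas as pd

        rows = [
            (u, v, d["substitutions"]) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["hap_a", "hap_b", "substitutions"])

    def to_node_frame(self):
        import pandas as pd

        rows = []
        for n, d in self.graph.nodes(data=True):
            region = ";".join(
                f"{k}:{v}" for k, v in sorted(d["region_counts"].items())
            )
            rows.append((n, d["frequency"], region, d["is_median"]))
        return pd.DataFrame(
            rows, columns=["hap_id", "frequency", "region_counts", "is_median"]
        )


def _assign_internal_sequences(
    tree: ParsimonyTree, haps: list[HaplotypeNode]
) -> dict:
    """Full Fitch up-pass/down-pass sequence assignment for every node."""
    seqs = {h.hap_id: h.sequence for h in haps}
    L = len(haps[0].sequence)
    adj = tree.adjacency
    leaves = [n for n in adj if isinstance(n, str)]
    root = leaves[0]
    up: dict = {}

    def post(node, parent):
        if isinstance(node, str):
            up[node] = [
                _BITS[seqs[node][c]] for c in range(L)
            ]
            return up[node]
        state = None
        for nb in adj[node]:
            if nb == parent:
                continue
            child = post(nb, node)
            if state is None:
                state = list(child)
            else:
                merged = []
                for sc, cc in zip(state, child):
                    inter = sc & cc
                    merged.append(inter if inter else sc | cc)
                state = merged
        up[node] = state
        return state

    assigned: dict = {}

    def pre(node, parent):
        if parent is None:
            assigned[node] = seqs[node] if isinstance(node, str) else "".join(
                _lowest_base(m) for m in up[node]
            )
        elif isinstance(node, str):
            assigned[node] = seqs[node]
        else:
            parent_seq = assigned[parent]
            out = []
            for c, mask in enumerate(up[node]):
                pbit = _BITS[parent_seq[c]]
                out.append(parent_seq[c] if mask & pbit else _lowest_base(mask))
            assigned[node] = "".join(out)
        for nb in adj[node]:
            if nb != parent:
                pre(nb, node)

    if len(leaves) == 1:
        return {root: seqs[root]}
    post(next(iter(adj[root])), root)
    up[root] = [_BITS[b] for b in seqs[root]]
    pre(root, None)
    return assigned


def network_from_tree(tree: ParsimonyTree, table: HaplotypeTable) -> HaplotypeNetwork:
    """Convert a parsimony tree into a haplotype network.

    Internal nodes whose Fitch-assigned sequence equals a sampled haplotype
    are merged with it; remaining internal nodes become frequency-0 median
    nodes; edges are weighted by Hamming distance and zero-weight edges are
    collapsed, so every network edge carries >= 1 substitution.
    """
    haps = table.haplotypes
    assigned = _assign_internal_sequences(tree, haps)

    g = nx.Graph()
    # one network node per distinct sequence: sampled haplotypes keep their
    # ids, novel internal sequences become numbered median nodes
    rep_by_seq: dict[str, str] = {h.sequence: h.hap_id for h in haps}
    median_count = 0
    final: dict = {}
    for node, seq in assigned.items():
        if seq not in rep_by_seq:
            median_count += 1
            rep_by_seq[seq] = f"med{median_count}"
        final[node] = rep_by_seq[seq]

    for h in haps:
        g.add_node(
            h.hap_id,
            frequency=h.frequency,
            region_counts=dict(h.region_counts),
            is_median=False,
            sequence=h.sequence,
        )
    for node, seq in assigned.items():
        nid = final[node]
        if nid not in g:
            g.add_node(
                nid, frequency=0, region_counts={}, is_median=True, sequence=seq
            )
    for u in tree.adjacency:
        for v in tree.adjacency[u]:
            cu, cv = final[u], final[v]
            if cu == cv:
                continue
            w = sum(a != b for a, b in zip(assigned[u], assigned[v]))
            if g.has_edge(cu, cv):
                continue
            g.add_edge(cu, cv, substitutions=w)
    # prune median nodes of degree <= 2 that lie redundantly on a path?  No:
    # degree-2 medians are genuine intermediate states and are kept.
    return HaplotypeNetwork(species=table.species, graph=g, parsimony_score=tree.score)


def private_haplotypes(network: HaplotypeNetwork) -> dict:
    """Division-private haplotypes and fully-private divisions.

    A sampled haplotype is private to a division iff every one of its
    specimens with a known division comes from that single division.
    Specimens lacking a division are excluded from privacy claims; their
    haplotypes are listed under ``excluded_missing_division``.
    """
    private: list[tuple[str, str]] = []
    excluded: list[str] = []
    division_haps: dict[str, set] = {}
    for n, d in network.graph.nodes(data=True):
        if d["is_median"]:
            continue
        counts = {k: v for k, v in d["region_counts"].items() if k}
        if sum(d["region_counts"].values()) > sum(counts.values()):
            excluded.append(n)
        for dv in counts:
            division_haps.setdefault(dv, set()).add(n)
        if len(counts) == 1 and counts:
            private.append((n, next(iter(counts))))
    private_set = {h for h, _ in private}
    fully_private_divisions = sorted(
        dv for dv, haps in division_haps.items() if haps <= private_set
    )
    return {
        "private": sorted(private),
        "fully_private_divisions": fully_private_divisions,
        "excluded_missing_division": sorted(excluded),
        "degenerate_single_division": len(division_haps) <= 1,
    }
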