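"""Per-region phylogenies and exact rooted SPR distance.

The number of subtree-prune-and-regraft (SPR) moves needed to turn the tree
inferred from a region's homologous sequences into the species tree is a
lower bound on the number of cross-lineage transfer events affecting that
region: each discordant placement requires at least one move, and each move
can be read as one transfer.

Trees here are rooted, binary and leaf-labelled; topology is represented as
a canonical nested tuple (leaves are strings, internal nodes are 2-tuples
with children ordered by their canonical rendering), so trees hash and
compare by topology alone. Newick parsing/serialisation goes through
dendropy; multifurcations are resolved deterministically (lexicographically)
on ingest and flagged with a warning.

The SPR engine does an exact bidirectional breadth-first search over SPR
neighbourhoods with canonical-form deduplication, after collapsing maximal
pendant subtrees common to both trees. It is exact up to a configurable
leaf-count / distance cap and returns a witness move sequence whose replay
reproduces the target topology.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, Union

import dendropy
import numpy as np

Topo = Union[str, tuple]  # leaf label | (child, child)

__all__ = [
    "PhyloTree",
    "DistanceMatrix",
    "SprResult",
    "p_distance",
    "distance_matrix",
    "nj_tree",
    "spr_neighbors",
    "apply_spr",
    "random_topology",
    "random_spr",
    "spr_distance",
    "count_hgt_events",
]


# ---------------------------------------------------------------- topology --


def _canon(t: Topo) -> Topo:
    if isinstance(t, str):
        return t
    a, b = (_canon(c) for c in t)
    return (a, b) if _render(a) <= _render(b) else (b, a)


def _render(t: Topo) -> str:
    if isinstance(t, str):
        return t
    return f"({_render(t[0])},{_render(t[1])})"


def _leaves(t: Topo) -> frozenset[str]:
    if isinstance(t, str):
        return frozenset((t,))
    return _leaves(t[0]) | _leaves(t[1])


def _subtrees(t: Topo) -> Iterator[Topo]:
    """All subtrees of t, including t itself."""
    yield t
    if not isinstance(t, str):
        yield from _subtrees(t[0])
        yield from _subtrees(t[1])


@dataclass(frozen=True)
class PhyloTree:
    """A rooted binary leaf-labelled tree with optional branch lengths.

    ``lengths`` maps the leaf set of a clade to the length of the branch
    above it; it is carried for reporting only — equality, hashing and the
    SPR machinery use topology alone.
    """

    topo: Topo
    lengths: Mapping[frozenset, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "topo", _canon(self.topo))
        labels = list(self._iter_leaf_labels(self.topo))
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels")

    @staticmethod
    def _iter_leaf_labels(t: Topo) -> Iterator[str]:
        if isinstance(t, str):
            yield t
        else:
            yield from PhyloTree._iter_leaf_labels(t[0])
            yield from PhyloTree._iter_leaf_labels(t[1])

    @property
    def leaves(self) -> frozenset[str]:
        return _leaves(self.topo)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        lengths: dict[frozenset, float] = {}
        has_lengths = False

        def build(node) -> Topo:
            nonlocal has_lengths
            children = node.child_nodes()
            if not children:
                label = node.taxon.label if node.taxon else node.label
                if not label:
                    raise ValueError("unlabelled leaf in Newick input")
                topo: Topo = label.replace(" ", "_")
            else:
                subs = sorted((build(c) for c in children), key=_render)
                if len(subs) > 2:
                    warnings.warn(
                        "multifurcation resolved deterministically (lexicographic)",
                        stacklevel=2,
                    )
                topo = subs[0]
                for s in subs[1:]:
                    topo = _canon((topo, s))
            if node.edge.length is not None:
                has_lengths = True
                lengths[_leaves(topo)] = float(node.edge.length)
            return topo

        topo = build(tree.seed_node)
        if isinstance(topo, str):
            raise ValueError("tree must have at least 2 leaves")
        return cls(topo, lengths if has_lengths else None)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, include_lengths: bool = True) -> str:
        lengths = self.lengths if include_lengths else None

        def render(t: Topo) -> str:
            if isinstance(t, str):
                body = t
            else:
                body = f"({render(t[0])},{render(t[1])})"
            if lengths is not None:
                bl = lengths.get(_leaves(t))
                if bl is not None:
                    body += f":{bl:g}"
            return body

        return render(self.topo) + ";"

    # -- manipulation --------------------------------------------------------

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict to a leaf subset, suppressing degree-2 nodes."""
        keep = frozenset(keep)
        missing = keep - self.leaves
        if missing:
            raise ValueError(f"leaves not in tree: {sorted(missing)}")

        def go(t: Topo) -> Topo | None:
            if isinstance(t, str):
                return t if t in keep else None
            a, b = go(t[0]), go(t[1])
            if a is None:
                return b
            if b is None:
                return a
            return (a, b)

        topo = go(self.topo)
        if topo is None or isinstance(topo, str):
            raise ValueError("pruned tree has fewer than 2 leaves")
        return PhyloTree(topo)

    def is_isomorphic(self, other: "PhyloTree") -> bool:
        return self.topo == other.topo


# ------------------------------------------------------------- distances --


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites among columns where both rows have bases."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    a = seq_a.upper()
    b = seq_b.upper()
    comparable = 0
    diff = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            diff += 1
    if comparable == 0:
        raise ValueError("no comparable (both non-gap) columns")
    return diff / comparable


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric p-distance matrix over an ordered species list."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n), symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")


def distance_matrix(seqs: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise p-distances of an aligned multi-FASTA dict."""
    labels = tuple(sorted(seqs))
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = p_distance(seqs[labels[i]], seqs[labels[j]])
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


def nj_tree(dm: DistanceMatrix, outgroup: str) -> PhyloTree:
    """Neighbor joining (Saitou–Nei), rooted at the designated outgroup leaf.

    The Q-criterion minimum is tie-broken by the lexicographically lowest
    species pair (each cluster named by its smallest leaf), so the result is
    fully deterministic. Branch lengths are the standard NJ estimates; the
    outgroup's pendant edge keeps its full length under the root.
    """
    if outgroup not in dm.labels:
        raise ValueError(f"outgroup {outgroup!r} not among labels")
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")

    # active clusters: id -> (topology, name = smallest leaf)
    next_id = itertools.count(n)
    active: dict[int, Topo] = {i: dm.labels[i] for i in range(n)}
    names: dict[int, str] = {i: dm.labels[i] for i in range(n)}
    d: dict[frozenset, float] = {
        frozenset((i, j)): dm.values[i, j]
        for i, j in itertools.combinations(range(n), 2)
    }
    # unrooted adjacency for the final rooting pass
    adj: dict[object, list[tuple[object, float]]] = {}

    def connect(u, v, length: float) -> None:
        adj.setdefault(u, []).append((v, length))
        adj.setdefault(v, []).append((u, length))

    node_key: dict[int, object] = {i: dm.labels[i] for i in range(n)}

    while len(active) > 3:
        ids = sorted(active)
        r = len(ids)
        R = {i: sum(d[frozenset((i, j))] for j in ids if j != i) for i in ids}
        best = None
        for i, j in itertools.combinations(ids, 2):
            q = (r - 2) * d[frozenset((i, j))] - R[i] - R[j]
            key = (q, tuple(sorted((names[i], names[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = d[frozenset((i, j))]
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        lj = dij - li
        u = next(next_id)
        active[u] = (active[i], active[j])
        names[u] = min(names[i], names[j])
        uk = f"@{u}"
        node_key[u] = uk
        connect(node_key[i], uk, max(li, 0.0))
        connect(node_key[j], uk, max(lj, 0.0))
        for k in ids:
            if k in (i, j):
                continue
            d[frozenset((u, k))] = 0.5 * (
                d[frozenset((i, k))] + d[frozenset((j, k))] - dij
            )
        del active[i], active[j]

    # join the last three clusters at an unrooted center
    a, b, c = sorted(active)
    center = "@center"
    la = 0.5 * (d[frozenset((a, b))] + d[frozenset((a, c))] - d[frozenset((b, c))])
    lb = 0.5 * (d[frozenset((a, b))] + d[frozenset((b, c))] - d[frozenset((a, c))])
    lc = 0.5 * (d[frozenset((a, c))] + d[frozenset((b, c))] - d[frozenset((a, b))])
    connect(node_key[a], center, max(la, 0.0))
    connect(node_key[b], center, max(lb, 0.0))
    connect(node_key[c], center, max(lc, 0.0))

    # root on the outgroup's pendant edge
    lengths: dict[frozenset, float] = {}

    def orient(u, parent) -> Topo:
        kids = [(v, bl) for v, bl in adj[u] if v != parent]
        if not kids:  # leaf
            return u
        subs = []
        for v, bl in kids:
            sub = orient(v, u)
            lengths[_leaves(sub)] = bl
            subs.append(sub)
        topo = subs[0]
        for s in subs[1:]:
            topo = (topo, s)
        return topo

    (og_neighbor, og_len) = adj[outgroup][0]
    rest = orient(og_neighbor, outgroup)
    lengths[_leaves(rest)] = 0.0
    lengths[frozenset((outgroup,))] = og_len
    return PhyloTree((outgroup, rest), lengths)


# ------------------------------------------------------------------- SPR --


def _remove(t: Topo, target: Topo) -> Topo | None:
    """Tree with the subtree *target* pruned (parent suppressed); None if t==target."""
    if t == target:
        return None
    if isinstance(t, str):
        return t
    a = _remove(t[0], target)
    b = _remove(t[1], target)
    if a is None:
        return b
    if b is None:
        return a
    return (a, b)


def _attach(t: Topo, sub: Topo, at: Topo) -> Topo:
    """Regraft *sub* onto the edge above node *at* (``at is t`` → new root)."""
    if t == at:
        return (sub, t)
    if isinstance(t, str):
        return t
    return (_attach(t[0], sub, at), _attach(t[1], sub, at))


def spr_neighbors(t: Topo) -> dict[Topo, tuple[frozenset, frozenset]]:
    """All topologies one rooted SPR move away from *t* (canonical forms).

    Returns canonical topology -> one witness move, where a move is the pair
    (leaf set of the pruned subtree, leaf set of the node in the remaining
    tree onto whose parent edge the subtree is regrafted; regrafting above
    the root uses the remaining tree's full leaf set).
    """
    t = _canon(t)
    out: dict[Topo, tuple[frozenset, frozenset]] = {}
    for sub in _subtrees(t):
        if sub == t:
            continue
        rest = _remove(t, sub)
        for at in _subtrees(rest):
            t2 = _canon(_attach(rest, sub, at))
            if t2 == t:
                continue
            out.setdefault(t2, (_leaves(sub), _leaves(at)))
    return out


def apply_spr(tree: PhyloTree, prune: frozenset, graft: frozenset) -> PhyloTree:
    """Replay one SPR move given by (pruned-clade leaf set, regraft-node leaf set)."""
    sub = next((s for s in _subtrees(tree.topo) if _leaves(s) == prune), None)
    if sub is None or sub == tree.topo:
        raise ValueError(f"no proper subtree with leaves {sorted(prune)}")
    rest = _remove(tree.topo, sub)
    at = next((s for s in _subtrees(rest) if _leaves(s) == graft), None)
    if at is None:
        raise ValueError(f"no regraft node with leaves {sorted(graft)}")
    return PhyloTree(_attach(rest, sub, at))


def random_topology(labels: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform-ish random rooted binary topology by sequential attachment."""
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    order = list(rng.permutation(labels))
    topo: Topo = (order[0], order[1])
    for label in order[2:]:
        nodes = list(_subtrees(topo))
        at = nodes[rng.integers(len(nodes))]
        topo = _attach(topo, label, at)
    return PhyloTree(topo)


def random_spr(tree: PhyloTree, rng: np.random.Generator) -> tuple[PhyloTree, tuple]:
    """One random topology-changing SPR move applied to *tree*."""
    nbrs = spr_neighbors(tree.topo)
    keys = sorted(nbrs, key=_render)
    pick = keys[rng.integers(len(keys))]
    return PhyloTree(pick), nbrs[pick]


def _collapse_common_pendants(a: Topo, b: Topo) -> tuple[Topo, Topo, dict[str, Topo]]:
    """Replace maximal pendant subtrees common to both trees by composite leaves.

    Iteratively collapses cherries present (as identical rooted subtrees) in
    both trees; composite leaves are named by the canonical rendering of the
    collapsed subtree, so they match across the two trees. Returns the
    reduced trees and the token -> original-subtree expansion map.
    """
    tokens: dict[str, Topo] = {}
    changed = True
    while changed:
        changed = False
        subs_b = {s for s in _subtrees(b) if not isinstance(s, str)}
        for s in _subtrees(a):
            if isinstance(s, str) or s == a or s == b:
                continue
            if isinstance(s[0], str) and isinstance(s[1], str) and s in subs_b:
                token = f"<{_render(s)}>"
                tokens[token] = s
                a = _substitute(a, s, token)
                b = _substitute(b, s, token)
                changed = True
                break
    return a, b, tokens


def _substitute(t: Topo, old: Topo, new: Topo) -> Topo:
    if t == old:
        return new
    if isinstance(t, str):
        return t
    return _canon((_substitute(t[0], old, new), _substitute(t[1], old, new)))


def _expand_leafset(ls: frozenset, tokens: dict[str, Topo]) -> frozenset:
    out: set[str] = set()
    for leaf in ls:
        if leaf in tokens:
            out |= _expand_leafset(_leaves(tokens[leaf]), tokens)
        else:
            out.add(leaf)
    return frozenset(out)


@dataclass
class SprResult:
    """Outcome of an SPR-distance search.

    ``distance`` is the exact minimum number of rooted SPR moves, or None
    when the search was cut off at ``max_d`` (then ``exceeded`` is True and
    ``lower_bound`` is the best-known lower bound). ``moves`` is a witness
    sequence of (pruned-clade leaf set, regraft-node leaf set) pairs, in
    original leaf labels, whose replay on the source tree yields the target
    topology.
    """

    distance: int | None
    moves: list[tuple[frozenset, frozenset]]
    exceeded: bool = False
    lower_bound: int = 0
    stats: dict = field(default_factory=dict)


def spr_distance(
    a: PhyloTree, b: PhyloTree, max_d: int = 6, max_leaves: int = 12
) -> SprResult:
    """Exact minimum rooted-SPR distance between two trees on the same leaves.

    Bidirectional BFS over SPR neighbourhoods with canonical-form
    deduplication, after collapsing maximal common pendant subtrees. Exact up
    to ``max_d`` moves and ``max_leaves`` leaves (after collapsing); beyond
    the move cap a bounded result (``exceeded=True``) is returned rather than
    raising.
    """
    if a.leaves != b.leaves:
        raise ValueError(
            f"leaf sets differ: {sorted(a.leaves ^ b.leaves)} not shared"
        )
    ta, tb, tokens = _collapse_common_pendants(a.topo, b.topo)
    if ta == tb:
        return SprResult(0, [], stats={"expanded": 0, "collapsed_to": len(_leaves(ta))})
    n_eff = len(_leaves(ta))
    if n_eff > max_leaves:
        raise ValueError(
            f"{n_eff} leaves after common-subtree collapsing exceeds the "
            f"exact-search cap of {max_leaves}"
        )

    # parent + depth maps for each direction; meets are candidate midpoints.
    # Levels are expanded in full and the minimum total over all meets is
    # kept; the search stops only once no shorter undiscovered path can
    # exist (any such path would already have produced a meet).
    fwd_par: dict[Topo, Topo | None] = {ta: None}
    bwd_par: dict[Topo, Topo | None] = {tb: None}
    fwd_dep: dict[Topo, int] = {ta: 0}
    bwd_dep: dict[Topo, int] = {tb: 0}
    frontier_f: list[Topo] = [ta]
    frontier_b: list[Topo] = [tb]
    depth_f = depth_b = 0
    expanded = 0
    best: tuple[int, Topo] | None = None

    while True:
        if best is not None and best[0] <= depth_f + depth_b + 1:
            break
        if depth_f + depth_b >= max_d:
            if best is not None and best[0] <= max_d:
                break
            return SprResult(
                None, [], exceeded=True, lower_bound=max_d + 1,
                stats={"expanded": expanded, "collapsed_to": n_eff},
            )
        forward = len(frontier_f) <= len(frontier_b)
        frontier = frontier_f if forward else frontier_b
        par = fwd_par if forward else bwd_par
        dep = fwd_dep if forward else bwd_dep
        other_dep = bwd_dep if forward else fwd_dep
        depth = (depth_f if forward else depth_b) + 1
        nxt: list[Topo] = []
        for t in frontier:
            expanded += 1
            for t2 in spr_neighbors(t):
                if t2 in dep:
                    continue
                par[t2] = t
                dep[t2] = depth
                nxt.append(t2)
                if t2 in other_dep:
                    total = depth + other_dep[t2]
                    if best is None or total < best[0]:
                        best = (total, t2)
        if forward:
            frontier_f, depth_f = nxt, depth
        else:
            frontier_b, depth_b = nxt, depth
        if not nxt and best is None:
            raise RuntimeError("SPR search space exhausted unexpectedly")
        if not nxt:
            break

    meet = best[1]
    # reconstruct the tree path ta .. meet .. tb
    path_f: list[Topo] = []
    node: Topo | None = meet
    while node is not None:
        path_f.append(node)
        node = fwd_par[node]
    path_f.reverse()  # ta ... meet
    node = bwd_par[meet]
    while node is not None:
        path_f.append(node)
        node = bwd_par[node]
    # derive witness moves, expanding composite leaves back to original labels
    moves: list[tuple[frozenset, frozenset]] = []
    for t1, t2 in zip(path_f, path_f[1:]):
        mv = spr_neighbors(t1)[t2]
        moves.append((_expand_leafset(mv[0], tokens), _expand_leafset(mv[1], tokens)))
    dist = len(moves)
    return SprResult(
        dist, moves, lower_bound=dist,
        stats={"expanded": expanded, "collapsed_to": n_eff},
    )


def count_hgt_events(
    region_tree: PhyloTree,
    species_tree: PhyloTree,
    max_d: int = 6,
) -> tuple[int | None, frozenset[str], str | None]:
    """Lower bound on transfer events for one region.

    Prunes both trees to their common leaf set and returns
    (events lower bound, pruned leaf set, warning-or-None). Fewer than 4
    common leaves carry no rooted-topology signal: the bound is 0 with a
    warning. A capped SPR search returns (None, leaves, warning).
    """
    common = region_tree.leaves & species_tree.leaves
    if len(common) < 4:
        return 0, frozenset(common), (
            f"only {len(common)} common leaves; topology uninformative"
        )
    rt = region_tree.prune_to(common)
    st = species_tree.prune_to(common)
    res = spr_distance(rt, st, max_d=max_d)
    if res.exceeded:
        return None, frozenset(common), f"SPR distance exceeds cap {max_d}"
    return res.distance, frozenset(common), None
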