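"""Signed circular gene-order algebra.

Plastomes that have lost the canonical inverted repeat rearrange freely, and
their evolution can be modelled as a series of segment inversions acting on a
circular order of signed locally collinear blocks (LCBs).  This module
implements that algebra: canonical forms for signed circular permutations,
the exact Hannenhalli--Pevzner inversion (reversal) distance for the
unichromosomal circular model, optimal inversion scenarios, a breadth-first
search oracle used to certify the distance on small block counts, distance
matrices, and an MGR-style parsimony tree with reconstructed ancestral gene
orders.

Conventions
-----------
A permutation is stored as a tuple of signed block identifiers, one of each
of ``1..n``; the tuple is a linear reading of the circle.  Two readings are
the same genome when they differ by rotation or by whole-circle reflection
(reading the other strand), so the canonical form rotates block 1 to the
front and reflects if needed to make it positive.

An :class:`Inversion` is a pair of junction indices ``0 <= i < j <= n``;
junction ``k`` is the gap before the block at index ``k`` (junction ``n``
wraps back to junction 0).  Applying the inversion reverses the blocks in
``[i, j)`` and flips their signs.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SignedCircularPermutation",
    "Inversion",
    "InversionScenario",
    "RearrangementTree",
    "canonicalize",
    "apply_inversion",
    "reversal_distance",
    "bfs_distance_oracle",
    "sort_by_reversals",
    "distance_matrix",
    "median_permutation",
    "mgr_tree",
    "read_grimm",
    "write_grimm",
]


# ---------------------------------------------------------------------------
# permutations and inversions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignedCircularPermutation:
    """A circular order of signed block identifiers ``1..n``.

    Equality and hashing are by canonical form, so two readings of the same
    circle (any rotation, or the whole-circle reflection) compare equal.
    """

    blocks: tuple[int, ...]

    def __init__(self, blocks: Iterable[int]):
        object.__setattr__(self, "blocks", tuple(int(b) for b in blocks))
        ids = sorted(abs(b) for b in self.blocks)
        n = len(self.blocks)
        if n == 0:
            raise ValueError("empty permutation")
        if ids != list(range(1, n + 1)):
            raise ValueError(
                f"block ids must be exactly 1..{n} each once, got {ids}"
            )

    @property
    def n(self) -> int:
        return len(self.blocks)

    def canonical(self) -> "SignedCircularPermutation":
        return canonicalize(self)

    def block_set(self) -> frozenset[int]:
        return frozenset(abs(b) for b in self.blocks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedCircularPermutation):
            return NotImplemented
        return _canonical_tuple(self.blocks) == _canonical_tuple(other.blocks)

    def __hash__(self) -> int:
        return hash(_canonical_tuple(self.blocks))

    def __str__(self) -> str:
        return " ".join(f"{b:+d}" for b in self.blocks)


def _canonical_tuple(blocks: tuple[int, ...]) -> tuple[int, ...]:
    k = next(i for i, b in enumerate(blocks) if abs(b) == 1)
    rotated = blocks[k:] + blocks[:k]
    if rotated[0] < 0:
        # read the other strand: reverse order and flip every sign
        flipped = tuple(-b for b in reversed(rotated))
        k = next(i for i, b in enumerate(flipped) if abs(b) == 1)
        rotated = flipped[k:] + flipped[:k]
    return rotated


def canonicalize(p: SignedCircularPermutation) -> SignedCircularPermutation:
    """Rotation/reflection-invariant normal form (block 1 first, positive)."""
    return SignedCircularPermutation(_canonical_tuple(p.blocks))


@dataclass(frozen=True, order=True)
class Inversion:
    """Cut points ``i < j`` on the circle of junctions; inverts ``[i, j)``."""

    i: int
    j: int

    def __post_init__(self):
        if not (0 <= self.i < self.j):
            raise ValueError(f"need 0 <= i < j, got ({self.i}, {self.j})")


def apply_inversion(
    p: SignedCircularPermutation, inv: Inversion
) -> SignedCircularPermutation:
    """Reverse and sign-flip the block segment between the two cut points."""
    n = p.n
    if inv.j > n:
        raise ValueError(f"cut point {inv.j} exceeds junction count {n}")
    seg = [-b for b in reversed(p.blocks[inv.i : inv.j])]
    return SignedCircularPermutation(
        p.blocks[: inv.i] + tuple(seg) + p.blocks[inv.j :]
    )


@dataclass(frozen=True)
class InversionScenario:
    """An ordered list of inversions, applied left to right."""

    steps: tuple[Inversion, ...]

    def __len__(self) -> int:
        return len(self.steps)

    def replay(self, p: SignedCircularPermutation) -> SignedCircularPermutation:
        for inv in self.steps:
            p = apply_inversion(p, inv)
        return p


def all_inversions(n: int) -> list[Inversion]:
    """Every distinct cut-point pair; (0, n) is omitted (whole-circle flip)."""
    return [
        Inversion(i, j)
        for i in range(n)
        for j in range(i + 1, n + 1)
        if not (i == 0 and j == n)
    ]


# ---------------------------------------------------------------------------
# Hannenhalli–Pevzner distance
# ---------------------------------------------------------------------------


def _check_same_blocks(p: SignedCircularPermutation, q: SignedCircularPermutation):
    if p.block_set() != q.block_set():
        raise ValueError(
            f"mismatched block sets: {sorted(p.block_set())} vs {sorted(q.block_set())}"
        )


def _relabel(p: SignedCircularPermutation, q: SignedCircularPermutation) -> tuple[int, ...]:
    """Express ``p`` in ``q``'s frame so that ``q`` becomes the identity.

    Renaming block labels commutes with inversions (which act on positions),
    so ``d(p, q) = d(relabel(p, q), identity)``.  Both circles are read from
    their canonical rotation; the result starts with ``+1``.
    """
    qc = _canonical_tuple(q.blocks)
    rename = {}
    for idx, b in enumerate(qc, start=1):
        rename[abs(b)] = (idx, 1 if b > 0 else -1)
    out = []
    for b in _canonical_tuple(p.blocks):
        idx, sg = rename[abs(b)]
        out.append(idx * sg * (1 if b > 0 else -1))
    return tuple(out)


def _linearize(circular: tuple[int, ...]) -> tuple[int, ...]:
    """Fix block 1 forward as the frame; the rest is a linear signed permutation.

    On a circle, inverting a segment and inverting its complement give the
    same genome, so every sorting scenario can be written without ever
    cutting through the frame block; the circular distance then equals the
    linear distance of the remaining ``n - 1`` elements.
    """
    assert circular[0] == 1
    return tuple((b - 1) if b > 0 else (b + 1) for b in circular[1:])


def _breakpoint_graph(pi: Sequence[int]):
    """Cycles of the breakpoint graph of a linear signed permutation.

    Returns ``(cycles, oriented)`` where each cycle is the list of its point
    positions and ``oriented[c]`` says whether cycle ``c`` contains black
    edges traversed in both directions.
    """
    m = len(pi)
    pts = [0]
    for x in pi:
        if x > 0:
            pts.extend((2 * x - 1, 2 * x))
        else:
            pts.extend((-2 * x, -2 * x - 1))
    pts.append(2 * m + 1)
    pos = {v: i for i, v in enumerate(pts)}

    def black_partner(i: int) -> int:
        return i + 1 if i % 2 == 0 else i - 1

    def gray_partner(i: int) -> int:
        v = pts[i]
        w = v + 1 if v % 2 == 0 else v - 1
        return pos[w]

    seen = [False] * len(pts)
    cycles: list[list[int]] = []
    oriented: list[bool] = []
    for start in range(len(pts)):
        if seen[start]:
            continue
        cyc = []
        directions = set()
        i = start
        while not seen[i]:
            seen[i] = True
            cyc.append(i)
            j = black_partner(i)
            directions.add(1 if j > i else -1)
            seen[j] = True
            cyc.append(j)
            i = gray_partner(j)
        cycles.append(cyc)
        oriented.append(len(directions) > 1)
    return cycles, oriented


def _components(cycles: list[list[int]]):
    """Union cycles whose gray-edge spans interleave on the point line."""
    # gray edges of a cycle: consecutive (odd, even) traversal pairs
    spans = []
    for ci, cyc in enumerate(cycles):
        edges = []
        for k in range(1, len(cyc) + 1, 2):
            a, b = cyc[k], cyc[(k + 1) % len(cyc)]
            edges.append((min(a, b), max(a, b)))
        spans.append(edges)
    parent = list(range(len(cycles)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for c1, c2 in itertools.combinations(range(len(cycles)), 2):
        done = False
        for (i1, j1) in spans[c1]:
            for (i2, j2) in spans[c2]:
                if i1 < i2 < j1 < j2 or i2 < i1 < j2 < j1:
                    union(c1, c2)
                    done = True
                    break
            if done:
                break
    comp: dict[int, list[int]] = {}
    for ci in range(len(cycles)):
        comp.setdefault(find(ci), []).append(ci)
    return list(comp.values())


def _hurdles_and_fortress(pi: Sequence[int]) -> tuple[int, int, int]:
    """(cycles, hurdles, fortress) of the extended breakpoint graph."""
    cycles, oriented = _breakpoint_graph(pi)
    comps = _components(cycles)
    n_pts = 2 * len(pi) + 2

    # nontrivial unoriented components; an adjacency (2-point cycle) is trivial
    unoriented_comps = []
    for comp in comps:
        if all(len(cycles[c]) == 2 for c in comp):
            continue
        if any(oriented[c] for c in comp):
            continue
        pts = sorted(p for c in comp for p in cycles[c])
        unoriented_comps.append(frozenset(pts))

    if not unoriented_comps:
        return len(cycles), 0, 0

    def hurdle_set(comp_list):
        """Components whose points are circularly contiguous among the
        points of all listed components (the line is closed into a circle)."""
        marked = sorted(p for comp in comp_list for p in comp)
        label = {}
        for k, comp in enumerate(comp_list):
            for p in comp:
                label[p] = k
        seq = [label[p] for p in marked]
        hurdles = []
        for k, comp in enumerate(comp_list):
            idxs = [i for i, lab in enumerate(seq) if lab == k]
            # contiguous on the circle: gaps between consecutive occurrences
            runs = 1
            for a, b in zip(idxs, idxs[1:]):
                if b != a + 1:
                    runs += 1
            if runs > 1 and idxs[0] == 0 and idxs[-1] == len(seq) - 1:
                # wrap join
                runs -= 1
            if runs == 1:
                hurdles.append(k)
        return hurdles

    hurdle_idx = hurdle_set(unoriented_comps)
    h = len(hurdle_idx)
    f = 0
    if h % 2 == 1 and h == len([u for u in hurdle_idx]):
        # fortress iff oddly many hurdles and every one is a super hurdle:
        # deleting it would turn some protected non-hurdle into a hurdle
        all_super = True
        non_hurdles = [k for k in range(len(unoriented_comps)) if k not in hurdle_idx]
        if not non_hurdles:
            all_super = False
        else:
            for k in hurdle_idx:
                rest = [u for j, u in enumerate(unoriented_comps) if j != k]
                rest_hurdles = hurdle_set(rest)
                old = set(hurdle_idx) - {k}
                # positions shift; recompute membership by identity of sets
                new_hurdle_sets = {frozenset(rest[j]) for j in rest_hurdles}
                old_hurdle_sets = {
                    frozenset(unoriented_comps[j]) for j in old
                }
                if not (new_hurdle_sets - old_hurdle_sets):
                    all_super = False
                    break
        if all_super:
            f = 1
    return len(cycles), h, f


def hp_distance_linear(pi: Sequence[int]) -> int:
    """Exact reversal distance of a linear signed permutation (HP formula).

    ``d = (m + 1) - c + h + f`` with ``c`` breakpoint-graph cycles,
    ``h`` hurdles and ``f`` the fortress indicator.
    """
    m = len(pi)
    if m == 0:
        return 0
    c, h, f = _hurdles_and_fortress(pi)
    return (m + 1) - c + h + f


def reversal_distance(
    p: SignedCircularPermutation, q: SignedCircularPermutation
) -> int:
    """Minimal number of inversions transforming ``p`` into ``q``."""
    _check_same_blocks(p, q)
    return hp_distance_linear(_linearize(_relabel(p, q)))


# ---------------------------------------------------------------------------
# BFS oracle
# ---------------------------------------------------------------------------

_BFS_CACHE: dict[int, dict[tuple[int, ...], int]] = {}


def _bfs_map(n: int) -> dict[tuple[int, ...], int]:
    """Distance from the identity to every canonical circular state."""
    if n in _BFS_CACHE:
        return _BFS_CACHE[n]
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    frontier = [ident]
    invs = all_inversions(n)
    while frontier:
        nxt = []
        for state in frontier:
            d = dist[state]
            for inv in invs:
                seg = tuple(-b for b in reversed(state[inv.i : inv.j]))
                neigh = _canonical_tuple(state[: inv.i] + seg + state[inv.j :])
                if neigh not in dist:
                    dist[neigh] = d + 1
                    nxt.append(neigh)
        frontier = nxt
    _BFS_CACHE[n] = dist
    return dist


def bfs_distance_oracle(
    p: SignedCircularPermutation, q: SignedCircularPermutation, max_n: int = 7
) -> int:
    """Exact distance by breadth-first search over canonical circular states.

    Independent of the breakpoint-graph machinery; guarded to small ``n``
    because the state space is ``(n-1)! * 2^(n-1)``.
    """
    _check_same_blocks(p, q)
    if p.n > max_n:
        raise ValueError(f"n={p.n} exceeds the oracle guard max_n={max_n}")
    r = _canonical_tuple(_relabel(p, q))
    return _bfs_map(p.n)[r]


# ---------------------------------------------------------------------------
# scenarios and matrices
# ---------------------------------------------------------------------------


def sort_by_reversals(
    p: SignedCircularPermutation, q: SignedCircularPermutation
) -> InversionScenario:
    """A minimum-length inversion scenario from ``p`` to ``q``.

    Deterministic: at each step the distance-reducing inversion with the
    smallest left cut, then smallest right cut, is chosen.  Cut indices refer
    to the working reading of the circle at that step (starting from ``p`` as
    given), so replaying the scenario on ``p`` reproduces ``q``.
    """
    _check_same_blocks(p, q)
    steps: list[Inversion] = []
    cur = p
    d = reversal_distance(cur, q)
    while d > 0:
        for inv in all_inversions(cur.n):
            cand = apply_inversion(cur, inv)
            if reversal_distance(cand, q) == d - 1:
                steps.append(inv)
                cur = cand
                d -= 1
                break
        else:  # pragma: no cover - contradicts HP theory
            raise RuntimeError("no distance-reducing inversion found")
    return InversionScenario(tuple(steps))


def distance_matrix(perms: Sequence[SignedCircularPermutation]) -> np.ndarray:
    """Symmetric matrix of pairwise reversal distances (zero diagonal)."""
    k = len(perms)
    mat = np.zeros((k, k), dtype=int)
    for a in range(k):
        for b in range(a + 1, k):
            mat[a, b] = mat[b, a] = reversal_distance(perms[a], perms[b])
    return mat


# ---------------------------------------------------------------------------
# MGR-style parsimony tree
# ---------------------------------------------------------------------------


@dataclass
class RearrangementTree:
    """Unrooted tree over gene orders with ancestral labels and edge counts.

    ``labels`` maps every node name (leaf or ancestor) to its permutation;
    ``edges`` lists ``(node_a, node_b, inversion_count)``.
    """

    labels: dict[str, SignedCircularPermutation]
    edges: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def total_inversions(self) -> int:
        return sum(c for _, _, c in self.edges)

    def neighbors(self, name: str) -> list[str]:
        out = []
        for a, b, _ in self.edges:
            if a == name:
                out.append(b)
            elif b == name:
                out.append(a)
        return out

    def to_newick(self, root: Optional[str] = None) -> str:
        """Newick string with edge inversion counts as branch lengths."""
        if not self.edges:
            only = next(iter(self.labels))
            return f"{only};"
        if root is None:
            degree: dict[str, int] = {}
            for a, b, _ in self.edges:
                degree[a] = degree.get(a, 0) + 1
                degree[b] = degree.get(b, 0) + 1
            root = max(degree, key=lambda k: (degree[k], k))
        elen = {}
        for a, b, c in self.edges:
            elen[(a, b)] = c
            elen[(b, a)] = c

        def render(node: str, parent: Optional[str]) -> str:
            kids = [x for x in self.neighbors(node) if x != parent]
            if not kids:
                return node
            inner = ",".join(
                f"{render(k, node)}:{elen[(node, k)]}" for k in kids
            )
            return f"({inner}){node}"

        return render(root, None) + ";"


def median_permutation(
    perms: Sequence[SignedCircularPermutation], max_n: int = 6
) -> SignedCircularPermutation:
    """Exact median (minimises summed reversal distance) for small ``n``.

    Enumerates every canonical circular state via the BFS oracle tables,
    scoring each against all inputs; guarded by ``max_n``.
    """
    n = perms[0].n
    if n > max_n:
        raise ValueError(f"exhaustive median guarded to n <= {max_n}")
    for q in perms[1:]:
        _check_same_blocks(perms[0], q)
    best = None
    best_score = None
    for state in _bfs_map(n):
        cand = SignedCircularPermutation(state)
        score = sum(reversal_distance(cand, q) for q in perms)
        if best_score is None or score < best_score:
            best, best_score = cand, score
    return best


def _improve_label(
    label: SignedCircularPermutation,
    neighbors: Sequence[SignedCircularPermutation],
) -> SignedCircularPermutation:
    """Hill-climb a node label by single inversions lowering the local sum."""
    cur = label
    cur_score = sum(reversal_distance(cur, q) for q in neighbors)
    improved = True
    while improved:
        improved = False
        for inv in all_inversions(cur.n):
            cand = apply_inversion(cur, inv)
            score = sum(reversal_distance(cand, q) for q in neighbors)
            if score < cur_score:
                cur, cur_score = cand, score
                improved = True
                break
    return cur


def _label_fixed_topology(
    topology,
    leaf_perms: dict[str, SignedCircularPermutation],
    ancestor_names: Iterable[str],
) -> RearrangementTree:
    """Label a fixed unrooted topology (nested tuples of leaf names)."""
    names = iter(ancestor_names)
    edges: list[tuple[str, str]] = []
    internal: list[str] = []

    def build(node) -> str:
        if isinstance(node, str):
            return node
        me = next(names)
        internal.append(me)
        for child in node:
            edges.append((me, build(child)))
        return me

    build(topology)
    adjacency: dict[str, list[str]] = {}
    for a, b in edges:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)

    labels: dict[str, SignedCircularPermutation] = dict(leaf_perms)
    # initialise ancestors from an adjacent labelled node (leaves first)
    pending = [x for x in internal]
    while pending:
        still = []
        for node in pending:
            src = next((n for n in adjacency[node] if n in labels), None)
            if src is not None:
                labels[node] = labels[src]
            else:
                still.append(node)
        if len(still) == len(pending):  # isolated chain; seed arbitrarily
            labels[still[0]] = next(iter(leaf_perms.values()))
            still = still[1:]
        pending = still

    n = next(iter(leaf_perms.values())).n
    changed = True
    while changed:
        changed = False
        for node in internal:
            neigh = [labels[x] for x in adjacency[node]]
            if n <= 6:
                cand = median_permutation(neigh)
            else:
                cand = _improve_label(labels[node], neigh)
            old = sum(reversal_distance(labels[node], q) for q in neigh)
            new = sum(reversal_distance(cand, q) for q in neigh)
            if new < old:
                labels[node] = cand
                changed = True

    out_edges = [
        (a, b, reversal_distance(labels[a], labels[b])) for a, b in edges
    ]
    return RearrangementTree(labels=labels, edges=out_edges)


def mgr_tree(
    perms: Sequence[SignedCircularPermutation],
    names: Optional[Sequence[str]] = None,
    topology=None,
    ancestor_prefix: str = "A",
) -> RearrangementTree:
    """MGR-style most-parsimonious tree over gene orders.

    With a fixed ``topology`` (nested tuples of leaf names) only the internal
    labels are optimised.  Otherwise the greedy MGR heuristic is used:
    repeatedly apply, to some genome, the inversion that maximally decreases
    the sum of its distances to the other genomes, merging lineages into a
    named ancestor whenever two genomes coincide.  Ancestors are named
    ``A<k>`` with ``k`` counting on from the number of leaves, following the
    usual reporting convention for reconstructed plastome organisations.
    """
    if len(perms) < 3:
        raise ValueError("need at least 3 permutations")
    for q in perms[1:]:
        _check_same_blocks(perms[0], q)
    if names is None:
        names = [f"G{i+1}" for i in range(len(perms))]
    if len(names) != len(perms):
        raise ValueError("names/permutations length mismatch")

    next_anc = itertools.count(len(perms) + 1)

    def anc_name() -> str:
        return f"{ancestor_prefix}{next(anc_counter)}"

    anc_counter = next_anc

    if topology is not None:
        gen = (f"{ancestor_prefix}{k}" for k in itertools.count(len(perms) + 1))
        return _label_fixed_topology(topology, dict(zip(names, perms)), gen)

    labels: dict[str, SignedCircularPermutation] = dict(zip(names, perms))
    edges: list[tuple[str, str, int]] = []
    # lineage: [current perm, tip node name, steps applied since tip]
    lineages: list[list] = [[p, nm, 0] for p, nm in zip(perms, names)]

    def merge_equal():
        nonlocal lineages
        merged = True
        while merged and len(lineages) > 1:
            merged = False
            for a in range(len(lineages)):
                group = [a] + [
                    b
                    for b in range(len(lineages))
                    if b != a and lineages[b][0] == lineages[a][0]
                ]
                if len(group) > 1:
                    perm = canonicalize(lineages[a][0])
                    nm = anc_name()
                    labels[nm] = perm
                    for idx in group:
                        edges.append((lineages[idx][1], nm, lineages[idx][2]))
                    lineages = [
                        lin for i, lin in enumerate(lineages) if i not in group
                    ]
                    lineages.append([perm, nm, 0])
                    merged = True
                    break

    merge_equal()
    while len(lineages) > 2:
        best = None  # (delta, inversion, lineage index, new perm)
        for li, (perm, _, _) in enumerate(lineages):
            others = [l[0] for lj, l in enumerate(lineages) if lj != li]
            base = sum(reversal_distance(perm, o) for o in others)
            for inv in all_inversions(perm.n):
                cand = apply_inversion(perm, inv)
                delta = sum(reversal_distance(cand, o) for o in others) - base
                key = (delta, inv, li)
                if delta < 0 and (best is None or key < best[:3]):
                    best = (delta, inv, li, cand)
        if best is None:
            # stalled: walk the closest pair together one optimal step
            pairs = [
                (reversal_distance(lineages[a][0], lineages[b][0]), a, b)
                for a in range(len(lineages))
                for b in range(a + 1, len(lineages))
            ]
            _, a, b = min(pairs)
            scen = sort_by_reversals(lineages[a][0], lineages[b][0])
            lineages[a][0] = apply_inversion(lineages[a][0], scen.steps[0])
            lineages[a][2] += 1
        else:
            _, _, li, cand = best
            lineages[li][0] = cand
            lineages[li][2] += 1
        merge_equal()

    if len(lineages) == 2:
        (pa, na, sa), (pb, nb, sb) = lineages
        edges.append((na, nb, sa + sb + reversal_distance(pa, pb)))
    return RearrangementTree(labels=labels, edges=edges)


# ---------------------------------------------------------------------------
# GRIMM-style IO
# ---------------------------------------------------------------------------


def read_grimm(text: str) -> dict[str, SignedCircularPermutation]:
    """Parse GRIMM-style permutations: ``>name`` then signed integers.

    A trailing ``$`` (linear-genome marker) is tolerated and ignored; the
    permutations are interpreted as circular.
    """
    perms: dict[str, SignedCircularPermutation] = {}
    name = None
    buf: list[int] = []

    def flush():
        if name is not None:
            if not buf:
                raise ValueError(f"genome {name!r} has no blocks")
            perms[name] = SignedCircularPermutation(buf)

    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            buf = []
        else:
            for tok in re.split(r"\s+", line):
                if tok in ("$", "@", ""):
                    continue
                buf.append(int(tok))
    flush()
    return perms


def write_grimm(perms: dict[str, SignedCircularPermutation]) -> str:
    lines = []
    for name, p in perms.items():
        lines.append(f">{name}")
        lines.append(" ".join(f"{b:+d}" for b in p.blocks))
    return "\n".join(lines) + "\n"
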