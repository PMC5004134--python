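"""Two-round best overlap graph over cleaned compressed reads.

Round 1 removes contained reads; round 2 keeps, per read end, the single best
suffix-prefix overlap (with a 95% mutual tolerance).  The graph is then
simplified (tips, bubbles) and decomposed into maximal unbranched paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .anchor_index import CompressedRead
from .compressed_align import (
    InvertedIndex,
    OverlapAlignment,
    ScoreScheme,
    align_compressed,
    build_inverted_index,
    candidates,
    containment_score,
)


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def remove_contained(
    crs: Sequence[CompressedRead],
    index: InvertedIndex,
    scheme: ScoreScheme,
    min_shared: int = 1,
) -> tuple[list[CompressedRead], dict[str, str]]:
    """Round 1: drop reads contained in another read (either orientation).

    Mutual containments keep the lexicographically smaller read id.  Returns
    (survivors, contained_id -> container_id) so contained reads can be
    re-attached for consensus.
    """
    by_id = {cr.read_id: cr for cr in crs}
    containments: dict[str, str] = {}
    for cr in crs:
        for rid in sorted(candidates(cr, index, min_shared)):
            other = by_id.get(rid)
            if other is None:
                continue
            if containment_score(cr, other, scheme) <= 0:
                continue
            mutual = containment_score(other, cr, scheme) > 0
            if mutual and cr.read_id < rid:
                continue  # tie: the smaller id survives
            containments[cr.read_id] = rid
            break
    survivors = [cr for cr in crs if cr.read_id not in containments]
    return survivors, containments


@dataclass(frozen=True)
class Edge:
    """Dovetail overlap: read u in orientation uo followed by read v in vo."""

    u: str
    uo: str
    v: str
    vo: str
    score: float
    matched: int
    aln: OverlapAlignment | None = None

    @property
    def u_side(self) -> str:  # side of u this edge leaves from
        return "E" if self.uo == "+" else "B"

    @property
    def v_side(self) -> str:  # side of v this edge enters
        return "B" if self.vo == "+" else "E"


@dataclass
class BestOverlapGraph:
    nodes: dict[str, CompressedRead]
    adj: dict[tuple[str, str], list[Edge]] = field(default_factory=dict)

    def sides(self, rid: str) -> tuple[list[Edge], list[Edge]]:
        return self.adj.get((rid, "B"), []), self.adj.get((rid, "E"), [])

    def degree(self, rid: str, side: str) -> int:
        return len(self.adj.get((rid, side), []))

    def add_edge(self, e: Edge) -> None:
        self.adj.setdefault((e.u, e.u_side), []).append(e)
        self.adj.setdefault((e.v, e.v_side), []).append(e)

    def remove_node(self, rid: str) -> None:
        for side in ("B", "E"):
            for e in self.adj.pop((rid, side), []):
                # detach from the other endpoint
                ok, os_ = (e.v, e.v_side) if e.u == rid and e.u_side == side else (e.u, e.u_side)
                lst = self.adj.get((ok, os_))
                if lst and e in lst:
                    lst.remove(e)
        self.nodes.pop(rid, None)

    def edges(self) -> list[Edge]:
        seen: set[int] = set()
        out = []
        for lst in self.adj.values():
            for e in lst:
                if id(e) not in seen:
                    seen.add(id(e))
                    out.append(e)
        return out

    def n_edges(self) -> int:
        return len(self.edges())

    def traverse(self, rid: str, orient: str) -> list[tuple[Edge, str, str]]:
        """Edges leaving (rid, orient); yields (edge, next id, next orient)."""
        side = "E" if orient == "+" else "B"
        out = []
        for e in self.adj.get((rid, side), []):
            if e.u == rid and e.u_side == side:
                out.append((e, e.v, e.vo))
            elif e.v == rid and e.v_side == side:
                out.append((e, e.u, _flip(e.uo)))
        return out


def _edge_from_alignment(a: CompressedRead, b: CompressedRead, aln: OverlapAlignment) -> Edge | None:
    o = "+" if aln.relative_orientation == "same" else "-"
    if aln.relation == "suffix_prefix":  # a then oriented b
        return Edge(a.read_id, "+", b.read_id, o, aln.score, aln.matched_ids, aln)
    if aln.relation == "prefix_suffix":  # oriented b then a
        return Edge(b.read_id, o, a.read_id, "+", aln.score, aln.matched_ids, aln)
    return None


def best_overlaps(
    survivors: Sequence[CompressedRead],
    scheme: ScoreScheme,
    min_overlap_score: float = 150.0,
    min_shared: int = 1,
    mutual_frac: float = 0.95,
) -> BestOverlapGraph:
    """Round 2: best suffix-prefix overlap per read side.

    An edge is kept when it is the best overlap for at least one of its two
    read sides and scores >= mutual_frac of the best on the other side.
    """
    index = build_inverted_index(survivors)
    by_id = {cr.read_id: cr for cr in survivors}
    raw: list[Edge] = []
    for cr in survivors:
        for rid in sorted(candidates(cr, index, min_shared)):
            if rid <= cr.read_id:
                continue  # each unordered pair once
            aln = align_compressed(cr, by_id[rid], scheme, min_overlap_score)
            e = _edge_from_alignment(cr, by_id[rid], aln)
            if e is not None and e.score >= min_overlap_score:
                raw.append(e)

    best: dict[tuple[str, str], float] = {}
    for e in raw:
        for key in ((e.u, e.u_side), (e.v, e.v_side)):
            if e.score > best.get(key, 0.0):
                best[key] = e.score

    def rank(e: Edge):  # determinism: score, then matched, then ids
        return (-e.score, -e.matched, e.u, e.v)

    g = BestOverlapGraph(nodes=dict(sorted(by_id.items())))
    for e in sorted(raw, key=rank):
        bu = best[(e.u, e.u_side)]
        bv = best[(e.v, e.v_side)]
        if (e.score >= bu and e.score >= mutual_frac * bv) or (
            e.score >= bv and e.score >= mutual_frac * bu
        ):
            g.add_edge(e)
    return g


def _chain_from(g: BestOverlapGraph, rid: str, orient: str) -> tuple[list[str], tuple[str, str] | None, float]:
    """Walk through simple nodes from (rid, orient).

    Returns (chain node ids including start, terminal attachment (id, side)
    if the walk ended at a branching/complex node, total edge score).
    """
    chain = [rid]
    score = 0.0
    cur, co = rid, orient
    seen = {rid}
    while True:
        outs = g.traverse(cur, co)
        if len(outs) != 1:
            return chain, None, score
        e, nid, no = outs[0]
        in_side = "B" if no == "+" else "E"
        if g.degree(nid, in_side) > 1:
            return chain, (nid, in_side), score + e.score
        if nid in seen:
            return chain, None, score  # cycle
        other_side = "E" if in_side == "B" else "B"
        score += e.score
        if g.degree(nid, other_side) > 1:
            # complex node: the chain attaches to it but does not include it
            return chain, (nid, in_side), score
        chain.append(nid)
        seen.add(nid)
        cur, co = nid, no


def simplify(g: BestOverlapGraph, tip_len: int = 3, bubble_len: int = 5) -> BestOverlapGraph:
    """Remove dead-end chains of <= tip_len nodes hanging off branches and
    merge bubble paths of <= bubble_len nodes, keeping the higher-score side.
    Iterates to a fixpoint."""
    changed = True
    while changed:
        changed = False
        # tips
        for rid in sorted(g.nodes):
            degB = g.degree(rid, "B")
            degE = g.degree(rid, "E")
            if (degB == 0) == (degE == 0):
                continue  # not a dead end (or isolated)
            orient = "+" if degB == 0 else "-"  # walk away from the dead side
            chain, attach, _ = _chain_from(g, rid, orient)
            if attach is None or len(chain) > tip_len:
                continue
            if any(g.degree(n, s) > 1 for n in chain for s in "BE"):
                continue
            for n in chain:
                g.remove_node(n)
            changed = True
            break
        if changed:
            continue
        # bubbles
        for rid in sorted(g.nodes):
            for side in ("B", "E"):
                edges = g.adj.get((rid, side), [])
                if len(edges) != 2:
                    continue
                orient = "+" if side == "E" else "-"
                arms = []
                for e, nid, no in g.traverse(rid, orient):
                    in_side = "B" if no == "+" else "E"
                    if g.degree(nid, in_side) > 1:
                        arms = []
                        break  # arm is zero-length; not a simple bubble
                    chain, attach, score = _chain_from(g, nid, no)
                    arms.append((chain, attach, score + e.score))
                if len(arms) != 2:
                    continue
                (c1, a1, s1), (c2, a2, s2) = arms
                if a1 is None or a1 != a2:
                    continue
                if len(c1) > bubble_len or len(c2) > bubble_len:
                    continue
                if set(c1) & set(c2):
                    continue
                if s1 > s2 or (s1 == s2 and c1[0] <= c2[0]):
                    loser = c2
                else:
                    loser = c1
                for n in loser:
                    g.remove_node(n)
                changed = True
                break
            if changed:
                break
    return g


@dataclass(frozen=True)
class BackbonePath:
    """Maximal unbranched chain of oriented reads."""

    path_id: str
    elements: tuple[tuple[str, str], ...]
    circular: bool = False
    left_branch: bool = False  # path ends at an unresolved junction
    right_branch: bool = False


def _canonical_elements(
    elements: Sequence[tuple[str, str]],
) -> tuple[tuple[tuple[str, str], ...], bool]:
    fwd = tuple(elements)
    rev = tuple((rid, _flip(o)) for rid, o in reversed(elements))
    return (rev, True) if rev < fwd else (fwd, False)


def linear_paths(g: BestOverlapGraph) -> list[BackbonePath]:
    """Maximal unbranched paths; every node lands in exactly one path."""

    def extendable(rid: str, orient: str) -> tuple[str, str] | None:
        outs = g.traverse(rid, orient)
        if len(outs) != 1:
            return None
        _e, nid, no = outs[0]
        in_side = "B" if no == "+" else "E"
        if g.degree(nid, in_side) != 1:
            return None
        return nid, no

    visited: set[str] = set()
    paths: list[BackbonePath] = []
    counter = 0
    for start in sorted(g.nodes):
        if start in visited:
            continue
        # walk backwards to find the chain start
        rid, orient = start, "+"
        circular = False
        back = {rid}
        while True:
            prev = extendable(rid, _flip(orient))
            if prev is None:
                break
            pid, po = prev
            if pid in back:
                circular = True
                break
            rid, orient = pid, _flip(po)
            back.add(rid)
        elements = [(rid, orient)]
        visited.add(rid)
        cur, co = rid, orient
        while True:
            nxt = extendable(cur, co)
            if nxt is None:
                break
            nid, no = nxt
            if nid in visited:
                break
            elements.append((nid, no))
            visited.add(nid)
            cur, co = nid, no
        left_branch = len(g.traverse(elements[0][0], _flip(elements[0][1]))) > 0 and not circular
        right_branch = len(g.traverse(cur, co)) > 0 and not circular
        canon, flipped_path = _canonical_elements(elements)
        if flipped_path:
            left_branch, right_branch = right_branch, left_branch
        paths.append(
            BackbonePath(
                path_id=f"backbone_{counter}",
                elements=canon,
                circular=circular,
                left_branch=left_branch,
                right_branch=right_branch,
            )
        )
        counter += 1
    return paths


def write_gfa(path: str, g: BestOverlapGraph) -> None:
    """Export as GFA 1.0 (segment sequences elided, lengths tagged)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for rid in sorted(g.nodes):
            cr = g.nodes[rid]
            ln = len(cr.sequence) if cr.sequence else len(cr.anchors)
            fh.write(f"S\t{rid}\t*\tLN:i:{ln}\n")
        for e in sorted(g.edges(), key=lambda e: (e.u, e.v, e.uo, e.vo)):
            fh.write(f"L\t{e.u}\t{e.uo}\t{e.v}\t{e.vo}\t*\tSC:f:{e.score:g}\n")


def write_backbones_tsv(path: str, paths: Sequence[BackbonePath]) -> None:
    with open(path, "w") as fh:
        fh.write("path_id\tcircular\telements\n")
        for p in paths:
            els = ",".join(f"{rid}:{o}" for rid, o in p.elements)
            fh.write(f"{p.path_id}\t{int(p.circular)}\t{els}\n")
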