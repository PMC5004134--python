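"""Layout of backbone paths into draft sequences and sparse-graph consensus.

Layout uncompresses a linear path of reads back to bases, estimating each
junction from the matched anchors' positions, and patches raw-coverage gaps
with the shared contig's sequence.  Consensus threads every related read
through a sparse k-mer graph built on the draft and reads out the heaviest
source-to-sink path after coverage reweighting.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .anchor_index import Anchor, CompressedRead, ContigSet, flipped
from .basealign import BackboneIndex, ReadToBackboneAlignment, align_to_backbone
from .compressed_align import InvertedIndex, ScoreScheme, align_compressed
from .overlap_graph import BackbonePath
from .seqio import revcomp


@dataclass(frozen=True)
class Segment:
    """Provenance of one slice of a draft backbone."""

    source_id: str
    source_interval: tuple[int, int]
    backbone_interval: tuple[int, int]
    orientation: str


@dataclass(frozen=True)
class DraftBackbone:
    path_id: str
    sequence: str
    segments: tuple[Segment, ...]


def _oriented(cr: CompressedRead, orient: str) -> CompressedRead:
    return cr if orient == "+" else flipped(cr)


def _genome_frame_pos(a: Anchor, contig_len: int, k: int) -> float:
    """read_pos minus the contig-forward progress it corresponds to.

    For matched anchors on two reads the difference of these values is the
    offset between the two read starts.
    """
    adj = a.contig_off if a.orientation == "+" else contig_len - k - a.contig_off
    return a.read_pos - adj


def _junction_offset(x: CompressedRead, y: CompressedRead, scheme: ScoreScheme, contig_lengths: Mapping[str, int]) -> float | None:
    """Estimated offset of y's start relative to x's start, both oriented."""
    aln = align_compressed(x, y, scheme)
    if aln.relative_orientation != "same" or not aln.matched_pairs:
        return None
    offsets = []
    for ai, bi in aln.matched_pairs:
        a, b = x.anchors[ai], y.anchors[bi]
        clen = contig_lengths.get(a.contig_id, 0)
        offsets.append(_genome_frame_pos(a, clen, x.k) - _genome_frame_pos(b, clen, y.k))
    return statistics.median(offsets)


def _contig_filler(
    x: CompressedRead,
    y: CompressedRead,
    x_start: float,
    y_start: float,
    x_end: float,
    contigs: ContigSet,
    scheme: ScoreScheme,
) -> tuple[str, Segment] | None:
    """Bridge [x_end, y_start) with the sequence of a shared anchored contig."""
    aln = align_compressed(x, y, scheme)
    best = None
    for ai, _bi in aln.matched_pairs:
        a = x.anchors[ai]
        cseq = contigs.contigs.get(a.contig_id)
        if cseq is None:
            continue
        clen = len(cseq)
        # backbone coordinate where the contig (in read orientation) starts
        if a.orientation == "+":
            c_start = x_start + a.read_pos - a.contig_off
        else:
            c_start = x_start + a.read_pos - (clen - x.k - a.contig_off)
        c_end = c_start + clen
        cover = min(c_end, y_start) - max(c_start, x_end)
        if best is None or cover > best[0]:
            best = (cover, a, c_start)
    if best is None:
        return None
    cover, a, c_start = best
    lo = int(round(x_end - c_start))
    hi = int(round(y_start - c_start))
    clen = len(contigs.contigs[a.contig_id])
    if lo < 0 or hi > clen or hi <= lo:
        return None
    cseq = contigs.contigs[a.contig_id]
    oriented = cseq if a.orientation == "+" else revcomp(cseq)
    filler = oriented[lo:hi]
    seg = Segment(
        source_id=f"contig:{a.contig_id}",
        source_interval=(lo, hi),
        backbone_interval=(0, 0),  # fixed up by the caller
        orientation=a.orientation,
    )
    return filler, seg


def _contig_placement(a: Anchor, clen: int, k: int) -> float:
    """Backbone offset (relative to the read start) where anchor a's contig,
    taken in read orientation, begins."""
    if a.orientation == "+":
        return a.read_pos - a.contig_off
    return a.read_pos - (clen - k - a.contig_off)


def _end_extension(
    cr: CompressedRead, contigs: ContigSet, side: str
) -> tuple[str, Segment] | None:
    """Contig overhang extending past the read's start ('head') or end
    ('tail'): sequencing gaps at path ends are covered by the contigs."""
    best = None
    L = len(cr.sequence)
    for a in cr.anchors:
        cseq = contigs.contigs.get(a.contig_id)
        if cseq is None:
            continue
        clen = len(cseq)
        c_start = _contig_placement(a, clen, cr.k)
        if side == "head":
            ext = min(int(round(-c_start)), clen)
        else:
            ext = min(int(round(c_start + clen - L)), clen)
        if ext >= 1 and (best is None or ext > best[0]):
            best = (ext, a, cseq)
    if best is None:
        return None
    ext, a, cseq = best
    oriented = cseq if a.orientation == "+" else revcomp(cseq)
    if side == "head":
        piece = oriented[:ext]
        seg = Segment(f"contig:{a.contig_id}", (0, ext), (0, ext), a.orientation)
    else:
        piece = oriented[len(oriented) - ext :]
        seg = Segment(
            f"contig:{a.contig_id}", (len(oriented) - ext, len(oriented)), (0, 0), a.orientation
        )
    return piece, seg


def layout(
    path: BackbonePath,
    crs_by_id: Mapping[str, CompressedRead],
    contigs: ContigSet,
    scheme: ScoreScheme,
) -> list[DraftBackbone]:
    """Uncompress a backbone path into one or more draft sequences.

    Irreconcilable junctions (no base overlap and no bridging contig) break
    the backbone and emit separate drafts.  At the two path ends a contig
    overhanging the terminal read extends the draft.
    """
    oriented = [(_oriented(crs_by_id[rid], o), o) for rid, o in path.elements]
    drafts: list[DraftBackbone] = []
    part = 0

    def flush(seq_parts, segments):
        nonlocal part
        if not seq_parts:
            return
        pid = path.path_id if part == 0 else f"{path.path_id}.{part}"
        drafts.append(DraftBackbone(pid, "".join(seq_parts), tuple(segments)))
        part += 1

    first, forient = oriented[0]
    seq_parts = []
    segments = []
    cur_start = 0.0
    if not path.circular:
        head = _end_extension(first, contigs, "head")
        if head is not None:
            piece, seg = head
            seq_parts.append(piece)
            segments.append(seg)
            cur_start = float(len(piece))
    seq_parts.append(first.sequence)
    segments.append(
        Segment(
            first.read_id,
            (0, len(first.sequence)),
            (int(cur_start), int(cur_start) + len(first.sequence)),
            forient,
        )
    )
    cur = first
    cur_len = len(first.sequence)

    for y, yorient in oriented[1:]:
        o = _junction_offset(cur, y, scheme, contigs.lengths)
        if o is None:
            flush(seq_parts, segments)
            seq_parts = [y.sequence]
            segments = [Segment(y.read_id, (0, len(y.sequence)), (0, len(y.sequence)), yorient)]
            cur, cur_start, cur_len = y, 0.0, len(y.sequence)
            continue
        y_start = cur_start + o
        cur_end = cur_start + cur_len
        overlap = cur_end - y_start
        if overlap >= len(y.sequence):
            continue  # y adds nothing (effectively contained); keep current
        if overlap >= 0:
            cut = int(round(overlap))
            suffix = y.sequence[cut:]
            bb_at = sum(len(p) for p in seq_parts)
            seq_parts.append(suffix)
            segments.append(Segment(y.read_id, (cut, len(y.sequence)), (bb_at, bb_at + len(suffix)), yorient))
        else:
            patch = _contig_filler(cur, y, cur_start, y_start, cur_end, contigs, scheme)
            if patch is None:
                flush(seq_parts, segments)
                seq_parts = [y.sequence]
                segments = [Segment(y.read_id, (0, len(y.sequence)), (0, len(y.sequence)), yorient)]
                cur, cur_start, cur_len = y, 0.0, len(y.sequence)
                continue
            filler, seg = patch
            bb_at = sum(len(p) for p in seq_parts)
            seq_parts.append(filler)
            segments.append(
                Segment(seg.source_id, seg.source_interval, (bb_at, bb_at + len(filler)), seg.orientation)
            )
            bb_at += len(filler)
            seq_parts.append(y.sequence)
            segments.append(Segment(y.read_id, (0, len(y.sequence)), (bb_at, bb_at + len(y.sequence)), yorient))
        cur = y
        cur_start = y_start
        cur_len = len(y.sequence)

    if not path.circular:
        tail = _end_extension(cur, contigs, "tail")
        if tail is not None:
            piece, seg = tail
            bb_at = sum(len(p) for p in seq_parts)
            seq_parts.append(piece)
            segments.append(
                Segment(seg.source_id, seg.source_interval, (bb_at, bb_at + len(piece)), seg.orientation)
            )
    flush(seq_parts, segments)
    return drafts


def collect_reads(
    path: BackbonePath,
    index_all: InvertedIndex,
    containments: Mapping[str, str],
) -> list[str]:
    """Raw read ids related to a backbone: identifier sharers plus the members
    of contained reads of path nodes."""
    path_ids = {rid for rid, _ in path.elements}
    contig_ids: set[str] = set()
    for rid in path_ids:
        cr = index_all.reads.get(rid)
        if cr is not None:
            contig_ids.update(a.contig_id for a in cr.anchors)
    pool: set[str] = set()
    for cid in contig_ids:
        for rid in index_all.postings.get(cid, ()):
            cr = index_all.reads[rid]
            pool.update(cr.members)
    for contained, container in containments.items():
        if container in path_ids:
            cr = index_all.reads.get(contained)
            pool.update(cr.members if cr is not None else (contained,))
    return sorted(pool)


# ---------------------------------------------------------------------------
# Sparse k-mer graph consensus


@dataclass
class ConsensusGraph:
    """Sparse position-anchored k-mer graph over a draft backbone.

    Nodes are (sampled backbone position index, k_c-mer observed there);
    edges carry the read bases covering the g-base gap to the next sampled
    position and a weight = number of supporting sequences.  `source` and
    `sink` are virtual.
    """

    k_c: int
    g: int
    length: int
    positions: list[int]
    edges: dict[tuple, dict[tuple, float]] = field(default_factory=dict)
    cov: np.ndarray | None = None
    t: float = 0.2

    SOURCE = ("src", "")
    SINK = ("snk", "")

    def add_path(self, bstart: int, rmap: np.ndarray, seq: str, weight: float = 1.0) -> None:
        """Thread one sequence (draft or aligned read) through the graph."""
        g = self.g
        bend = bstart + len(rmap) - 1  # covered draft interval [bstart, bend)
        p = -(-bstart // g) * g  # first sampled position >= bstart
        if p > bend - 1 and not (bstart == 0 and bend >= self.length):
            return
        prev_node = None
        prev_rp = 0
        if bstart == 0:
            prev_node = self.SOURCE
            prev_rp = int(rmap[0])  # unaligned read head is not emitted
        while p <= bend - 1 or (p == self.length and bend >= self.length):
            if p >= self.length:
                break
            rp = int(rmap[p - bstart])
            node = (p // g, seq[rp : rp + self.k_c])
            if prev_node is not None:
                label = seq[prev_rp:rp]
                bucket = self.edges.setdefault(prev_node, {})
                key = (node, label)
                bucket[key] = bucket.get(key, 0.0) + weight
            prev_node, prev_rp = node, rp
            p += g
        if prev_node is not None and prev_node is not self.SOURCE and bend >= self.length:
            end_rp = int(rmap[self.length - bstart]) if self.length - bstart < len(rmap) else len(seq)
            label = seq[prev_rp:end_rp]
            bucket = self.edges.setdefault(prev_node, {})
            key = (self.SINK, label)
            bucket[key] = bucket.get(key, 0.0) + weight

    def reweight(self, w: float, pos_index: int) -> float:
        if self.cov is None:
            return w
        return w - self.t * float(self.cov[min(pos_index, len(self.cov) - 1)])


def build_consensus_graph(
    draft: str,
    alignments: Sequence[ReadToBackboneAlignment],
    k_c: int = 2,
    g: int = 2,
    t: float = 0.2,
) -> ConsensusGraph:
    L = len(draft)
    positions = list(range(0, L, g))
    cg = ConsensusGraph(k_c=k_c, g=g, length=L, positions=positions, t=t)
    # the draft itself is coverage-1 evidence (incl. any contig filler)
    cg.add_path(0, np.arange(L + 1, dtype=np.int64), draft)
    n_sampled = len(positions)
    cov = np.ones(n_sampled, dtype=np.float64)
    for aln in alignments:
        cg.add_path(aln.bstart, aln.rmap, aln.seq, weight=aln.weight)
        lo = -(-aln.bstart // g)
        hi = min(n_sampled, (aln.bend - 1) // g + 1)
        if hi > lo:
            cov[lo:hi] += aln.weight
    cg.cov = cov
    return cg


def heaviest_path(cg: ConsensusGraph) -> str:
    """Highest-total-reweighted-weight source-to-sink path, read as sequence."""
    NEG = float("-inf")
    dp: dict[tuple, float] = {cg.SOURCE: 0.0}
    back: dict[tuple, tuple] = {}
    # nodes grouped by sampled position; edges only go forward
    order: dict[int, list[tuple]] = {}
    for node in cg.edges:
        if node is cg.SOURCE:
            continue
        order.setdefault(node[0], []).append(node)

    def relax(node, pos_index):
        base = dp.get(node, NEG)
        if base == NEG:
            return
        # repr-keyed sort: virtual sink and positional nodes do not compare
        for (succ, label), w in sorted(
            cg.edges.get(node, {}).items(), key=lambda kv: (repr(kv[0][0]), kv[0][1])
        ):
            s = base + cg.reweight(w, pos_index)
            if s > dp.get(succ, NEG):
                dp[succ] = s
                back[succ] = (node, label)

    relax(cg.SOURCE, 0)
    for p in sorted(order):
        for node in sorted(order[p], key=lambda n: n[1]):
            relax(node, p)
    if cg.SINK not in back:
        return ""
    labels = []
    node = cg.SINK
    while node != cg.SOURCE:
        node, label = back[node]
        labels.append(label)
    return "".join(reversed(labels))


def sparc_consensus(
    draft: DraftBackbone,
    alignments: Sequence[ReadToBackboneAlignment],
    k_c: int = 2,
    g: int = 2,
    t: float = 0.2,
) -> str:
    """Polish a draft with the sparse-graph consensus.

    With an empty alignment pool the draft is returned unchanged.
    """
    if not alignments:
        return draft.sequence
    cg = build_consensus_graph(draft.sequence, alignments, k_c=k_c, g=g, t=t)
    out = heaviest_path(cg)
    return out if out else draft.sequence


def polish(
    draft: DraftBackbone,
    pool: Mapping[str, str],
    k_c: int = 2,
    g: int = 2,
    t: float = 0.2,
    rounds: int = 2,
    seed_k: int = 11,
    min_identity: float = 0.5,
    weights: Mapping[str, float] | None = None,
) -> tuple[str, int]:
    """Iteratively align the pool to the backbone and take consensus.

    `weights` boosts individual pool entries (accurate contig sequences get
    more than the per-read vote of 1).  Returns (polished sequence, number of
    pool sequences aligned in the last round).
    """
    seq = draft.sequence
    n_aligned = 0
    for _ in range(max(1, rounds)):
        index = BackboneIndex(seq, k=seed_k)
        alns = []
        for rid in sorted(pool):
            aln = align_to_backbone(rid, pool[rid], index, min_identity=min_identity)
            if aln is not None:
                if weights and rid in weights:
                    aln = replace(aln, weight=weights[rid])
                alns.append(aln)
        n_aligned = len(alns)
        if not alns:
            return seq, 0
        seq = sparc_consensus(DraftBackbone(draft.path_id, seq, ()), alns, k_c=k_c, g=g, t=t)
    return seq, n_aligned
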