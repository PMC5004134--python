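"""Multiple-alignment cleaning of compressed reads.

Each read is piled up against all its candidate neighbors; anchors confirmed
by too few neighbors are removed, and junctions that no neighbor alignment
crosses are called as chimera breakpoints, splitting the read.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .anchor_index import CompressedRead, canonicalize, collapse_duplicates
from .compressed_align import (
    InvertedIndex,
    OverlapAlignment,
    ScoreScheme,
    align_compressed,
    build_inverted_index,
    candidates,
)


@dataclass(frozen=True)
class Pileup:
    """All positively-scoring neighbor alignments of one target read."""

    target: CompressedRead
    supports: tuple[tuple[str, OverlapAlignment], ...]
    anchor_support: tuple[int, ...]  # per target anchor index; self excluded


@dataclass(frozen=True)
class ChimeraCall:
    read_id: str
    breakpoints: tuple[int, ...]  # anchor index starting the right fragment
    verdict: str  # clean | spurious_anchors_removed | split | discarded


def build_pileup(
    target: CompressedRead,
    index: InvertedIndex,
    scheme: ScoreScheme,
    min_shared: int = 1,
) -> Pileup:
    # collapsed twins of the target are distinct raw reads confirming every
    # anchor; only the target read itself is excluded from its own support
    supports = []
    counts = [target.multiplicity - 1] * len(target.anchors)
    for rid in sorted(candidates(target, index, min_shared)):
        neighbor = index.reads[rid]
        aln = align_compressed(target, neighbor, scheme)
        if aln.score <= 0:
            continue
        supports.append((rid, aln))
        for ai, _bi in aln.matched_pairs:
            counts[ai] += neighbor.multiplicity
    return Pileup(target=target, supports=tuple(supports), anchor_support=tuple(counts))


def remove_spurious_anchors(pileup: Pileup, min_confirm: int = 1) -> CompressedRead:
    """Drop anchors confirmed by fewer than min_confirm neighbors.

    The target's own occurrence does not count.  The surviving read is
    re-canonicalized; it may come back empty, which the caller must exclude.
    """
    if min_confirm < 1:
        raise ValueError("min_confirm must be >= 1")
    target = pileup.target
    kept = tuple(
        a for a, n in zip(target.anchors, pileup.anchor_support) if n >= min_confirm
    )
    if len(kept) == len(target.anchors):
        return target
    return canonicalize(replace(target, anchors=kept))


def detect_chimera(pileup: Pileup) -> ChimeraCall:
    """Call breakpoints at junctions no neighbor alignment crosses.

    A neighbor crosses junction j (between anchors j and j+1) when its
    alignment matches target anchors on both sides.  Reads with fewer than 2
    anchors are trivially clean.
    """
    target = pileup.target
    n = len(target.anchors)
    if n < 2:
        return ChimeraCall(target.read_id, (), "clean")
    if target.multiplicity > 1:
        # a collapsed twin is a whole-read crossing alignment everywhere
        return ChimeraCall(target.read_id, (), "clean")
    # a neighbor crosses junction j only when it matches the two flanking
    # anchors contiguously on its own side as well; a gap-jumping alignment
    # (one side of a chimera resembling a read with a missed anchor) does not
    crossed = [False] * (n - 1)
    for _rid, aln in pileup.supports:
        pairs = sorted(aln.matched_pairs)
        for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]):
            if a2 == a1 + 1 and abs(b2 - b1) == 1:
                crossed[a1] = True
    breakpoints = tuple(j + 1 for j in range(n - 1) if not crossed[j])
    if not breakpoints:
        return ChimeraCall(target.read_id, (), "clean")
    return ChimeraCall(target.read_id, breakpoints, "split")


def split_read(cr: CompressedRead, call: ChimeraCall) -> list[CompressedRead]:
    """Cut a read at its breakpoints; fragments with < 2 anchors are dropped.

    Fragment sequences are cut midway between the anchors flanking each
    breakpoint so every fragment keeps its anchors' supporting bases.
    """
    if call.verdict != "split":
        return [cr]
    bounds = [0, *call.breakpoints, len(cr.anchors)]
    frags: list[CompressedRead] = []
    for fi in range(len(bounds) - 1):
        s, e = bounds[fi], bounds[fi + 1]
        anchors = cr.anchors[s:e]
        if len(anchors) < 2:
            continue
        if cr.sequence is not None:
            left = 0 if s == 0 else int((cr.anchors[s - 1].read_pos + cr.k + cr.anchors[s].read_pos) // 2)
            right = (
                len(cr.sequence)
                if e == len(cr.anchors)
                else int((cr.anchors[e - 1].read_pos + cr.k + cr.anchors[e].read_pos) // 2)
            )
            seq = cr.sequence[left:right]
            anchors = tuple(replace(a, read_pos=a.read_pos - left) for a in anchors)
        else:
            seq = None
            anchors = tuple(anchors)
        frag_id = f"{cr.read_id}/{fi}"
        frags.append(
            canonicalize(
                CompressedRead(
                    read_id=frag_id,
                    anchors=anchors,
                    multiplicity=cr.multiplicity,
                    members=(frag_id,),
                    sequence=seq,
                    k=cr.k,
                )
            )
        )
    return frags


def auto_min_confirm(crs: Sequence[CompressedRead], index: InvertedIndex) -> int:
    """Coverage proxy: demand 2 confirmations when neighborhoods are deep."""
    if not crs:
        return 1
    depth = statistics.median(len(candidates(cr, index)) for cr in crs)
    return 2 if depth >= 12 else 1


def clean_reads(
    crs: Sequence[CompressedRead],
    scheme: ScoreScheme,
    min_confirm: int | None = None,
    remove_chimera: bool = True,
    min_shared: int = 1,
) -> tuple[list[CompressedRead], list[ChimeraCall], dict[str, str]]:
    """Full cleaning pass: spurious-anchor removal, then chimera splitting.

    Returns (cleaned collapsed reads, per-read calls, fragment->origin map).
    """
    index = build_inverted_index(crs)
    if min_confirm is None:
        min_confirm = auto_min_confirm(crs, index)

    calls: list[ChimeraCall] = []
    stage1: list[CompressedRead] = []
    for cr in crs:
        pileup = build_pileup(cr, index, scheme, min_shared)
        cleaned = remove_spurious_anchors(pileup, min_confirm)
        if cleaned.is_empty:
            calls.append(ChimeraCall(cr.read_id, (), "discarded"))
            continue
        if len(cleaned.anchors) != len(cr.anchors):
            calls.append(ChimeraCall(cr.read_id, (), "spurious_anchors_removed"))
        stage1.append(cleaned)

    if not remove_chimera:
        return collapse_duplicates(stage1), calls, {}

    index2 = build_inverted_index(stage1)
    out: list[CompressedRead] = []
    origins: dict[str, str] = {}
    for cr in stage1:
        pileup = build_pileup(cr, index2, scheme, min_shared)
        call = detect_chimera(pileup)
        if call.verdict == "clean":
            out.append(cr)
            continue
        frags = split_read(cr, call)
        if not frags:
            calls.append(ChimeraCall(cr.read_id, call.breakpoints, "discarded"))
            continue
        calls.append(call)
        for f in frags:
            origins[f.read_id] = cr.read_id
            out.append(f)
    return collapse_duplicates(out), calls, origins


def write_cleaning_report(path: str, calls: Sequence[ChimeraCall]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tverdict\tbreakpoints\n")
        for c in calls:
            bps = ",".join(map(str, c.breakpoints)) if c.breakpoints else "-"
            fh.write(f"{c.read_id}\t{c.verdict}\t{bps}\n")
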