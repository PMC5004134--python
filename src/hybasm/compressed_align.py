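"""Identifier-domain pairwise alignment of compressed reads.

Candidate overlaps come from an inverted index on contig identifiers; each
candidate pair is scored with a local Smith-Waterman over the two anchor
sequences, where a match requires equal contig id and consistent orientation.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .anchor_index import Anchor, CompressedRead, ContigSet, flipped


@dataclass(frozen=True)
class InvertedIndex:
    """contig_id -> set of compressed-read ids containing that identifier."""

    postings: Mapping[str, frozenset[str]]
    reads: Mapping[str, CompressedRead]


def build_inverted_index(crs: Iterable[CompressedRead]) -> InvertedIndex:
    postings: dict[str, set[str]] = {}
    reads: dict[str, CompressedRead] = {}
    for cr in crs:
        reads[cr.read_id] = cr
        for a in cr.anchors:
            postings.setdefault(a.contig_id, set()).add(cr.read_id)
    return InvertedIndex(
        postings={cid: frozenset(s) for cid, s in postings.items()}, reads=reads
    )


def candidates(cr: CompressedRead, index: InvertedIndex, min_shared: int = 1) -> set[str]:
    """Read ids sharing >= min_shared distinct contig identifiers with cr."""
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    counts: dict[str, int] = {}
    for cid in {a.contig_id for a in cr.anchors}:
        for rid in index.postings.get(cid, ()):
            counts[rid] = counts.get(rid, 0) + 1
    counts.pop(cr.read_id, None)
    return {rid for rid, n in counts.items() if n >= min_shared}


@dataclass(frozen=True)
class ScoreScheme:
    """Match/mismatch/gap scoring in the identifier domain.

    by_contig_length scores a match by the contig's length; by_kmer_support
    by the smaller of the two anchors' supporting k-mer counts.  Penalties
    are scaled to be commensurate with the match scores.
    """

    mode: str = "by_contig_length"
    contig_lengths: Mapping[str, int] = field(default_factory=dict)
    mismatch_penalty: float = -500.0
    gap_penalty: float = -500.0

    def __post_init__(self):
        if self.mode not in ("by_contig_length", "by_kmer_support"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")
        if self.mismatch_penalty > 0 or self.gap_penalty > 0:
            raise ValueError("penalties must be <= 0")

    @classmethod
    def from_contigs(cls, contigs: "ContigSet | Mapping[str, int]", mode: str = "by_contig_length") -> "ScoreScheme":
        lengths = contigs.lengths if isinstance(contigs, ContigSet) else dict(contigs)
        med = statistics.median(lengths.values()) if lengths else 2000
        if mode == "by_kmer_support":
            # supports are O(contig_len * hit_rate); a fixed small penalty
            return cls(mode=mode, contig_lengths=lengths, mismatch_penalty=-10.0, gap_penalty=-10.0)
        return cls(mode=mode, contig_lengths=lengths, mismatch_penalty=-med / 4, gap_penalty=-med / 4)

    def match_score(self, a: Anchor, b: Anchor) -> float:
        if self.mode == "by_kmer_support":
            return float(min(a.kmer_support, b.kmer_support))
        return float(self.contig_lengths.get(a.contig_id, 1000))


@dataclass(frozen=True)
class OverlapAlignment:
    """Best local alignment between two compressed reads.

    Spans are anchor-index intervals (0-based, half-open) in each read's
    canonical frame; matched_pairs likewise pairs canonical-frame indices.
    """

    read_a: str
    read_b: str
    relation: str  # contained_a_in_b | contained_b_in_a | suffix_prefix | prefix_suffix | none
    score: float
    matched_ids: int
    a_span: tuple[int, int]
    b_span: tuple[int, int]
    relative_orientation: str  # 'same' | 'opposite'
    matched_pairs: tuple[tuple[int, int], ...] = ()


def _sw(
    a: Sequence[Anchor], b: Sequence[Anchor], scheme: ScoreScheme
) -> tuple[float, tuple[int, int], tuple[int, int], list[tuple[int, int]]]:
    """Local DP over anchor sequences; returns score, spans, matched pairs."""
    m, n = len(a), len(b)
    gap = scheme.gap_penalty
    mis = scheme.mismatch_penalty
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, n + 1):
            bj_ = b[j - 1]
            s = scheme.match_score(ai, bj_) if ai.key == bj_.key else mis
            v = prev[j - 1] + s
            up = prev[j] + gap
            if up > v:
                v = up
            left = row[j - 1] + gap
            if left > v:
                v = left
            if v < 0:
                v = 0.0
            row[j] = v
            if v > best:
                best, bi, bj = v, i, j
    if best <= 0:
        return 0.0, (0, 0), (0, 0), []
    # traceback
    pairs: list[tuple[int, int]] = []
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        v = H[i][j]
        ai, bj_ = a[i - 1], b[j - 1]
        s = scheme.match_score(ai, bj_) if ai.key == bj_.key else mis
        if v == H[i - 1][j - 1] + s:
            if ai.key == bj_.key:
                pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif v == H[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return best, (i, bi), (j, bj), pairs


def align_compressed(
    a: CompressedRead,
    b: CompressedRead,
    scheme: ScoreScheme,
    min_overlap_score: float = 0.0,
) -> OverlapAlignment:
    """Best-of-both-orientations local alignment of two compressed reads.

    b is additionally tried in reverse-complement form; the higher-scoring
    orientation wins (ties prefer 'same').  The relation is classified from
    the optimal local alignment's spans and demoted to 'none' below
    min_overlap_score.
    """
    if a.is_empty or b.is_empty:
        return OverlapAlignment(a.read_id, b.read_id, "none", 0.0, 0, (0, 0), (0, 0), "same")

    b_rc = flipped(b)
    fw = _sw(a.anchors, b.anchors, scheme)
    rv = _sw(a.anchors, b_rc.anchors, scheme)
    if rv[0] > fw[0]:
        score, a_span, b_span_o, pairs_o = rv
        orient = "opposite"
    else:
        score, a_span, b_span_o, pairs_o = fw
        orient = "same"

    n = len(b.anchors)
    if orient == "opposite":
        b_span = (n - b_span_o[1], n - b_span_o[0])
        pairs = tuple((ai, n - 1 - bi) for ai, bi in pairs_o)
    else:
        b_span = b_span_o
        pairs = tuple(pairs_o)

    m = len(a.anchors)
    full_a = a_span == (0, m)
    # classification happens in the oriented frame
    ob = b_span_o
    full_b = ob == (0, n)
    matched = len(pairs)
    if score <= 0 or matched == 0 or score < min_overlap_score:
        relation = "none"
    elif full_b:
        relation = "contained_b_in_a"
    elif full_a:
        relation = "contained_a_in_b"
    elif a_span[1] == m and ob[0] == 0:
        relation = "suffix_prefix"  # a then (oriented) b
    elif a_span[0] == 0 and ob[1] == n:
        relation = "prefix_suffix"  # (oriented) b then a
    else:
        relation = "none"
    return OverlapAlignment(
        read_a=a.read_id,
        read_b=b.read_id,
        relation=relation,
        score=float(score),
        matched_ids=matched,
        a_span=a_span,
        b_span=b_span,
        relative_orientation=orient,
        matched_pairs=pairs,
    )


def _fitting_score(small: Sequence[Anchor], big: Sequence[Anchor], scheme: ScoreScheme) -> float:
    """Best score of an alignment matching EVERY anchor of `small`, in order,
    against `big` (local in big; interior skips of big anchors penalized).

    -inf when no such alignment exists.
    """
    m, n = len(big), len(small)
    gap = scheme.gap_penalty
    NEG = float("-inf")
    # A[j] = max over big positions i' seen so far of F[i', j] - gap * i'
    A = [0.0] + [NEG] * n  # j = 0: no small matched yet, any start is free
    best = NEG
    for i in range(1, m + 1):
        bi = big[i - 1]
        F = [NEG] * (n + 1)
        for j in range(1, n + 1):
            sj = small[j - 1]
            if bi.key != sj.key or A[j - 1] == NEG:
                continue
            prior = A[j - 1] + (gap * (i - 1) if j > 1 else 0.0)
            F[j] = scheme.match_score(bi, sj) + prior
        for j in range(1, n + 1):
            if F[j] != NEG and F[j] - gap * i > A[j]:
                A[j] = F[j] - gap * i
        if F[n] > best:
            best = F[n]
    return best


def containment_score(a: CompressedRead, b: CompressedRead, scheme: ScoreScheme) -> float:
    """Best score of an alignment matching all anchors of a inside b.

    Both orientations of a are tried.  A positive score means a is contained
    in b; a read whose identifier list is not an oriented subsequence of b's
    scores -inf.
    """
    if a.is_empty or b.is_empty:
        return float("-inf")
    return max(
        _fitting_score(a.anchors, b.anchors, scheme),
        _fitting_score(flipped(a).anchors, b.anchors, scheme),
    )


def write_alignments_tsv(path: str, alns: Iterable[OverlapAlignment]) -> None:
    with open(path, "w") as fh:
        fh.write("read_a\tread_b\trelation\tscore\tmatched_ids\ta_span\tb_span\torientation\n")
        for al in alns:
            fh.write(
                f"{al.read_a}\t{al.read_b}\t{al.relation}\t{al.score:g}\t{al.matched_ids}"
                f"\t{al.a_span[0]}-{al.a_span[1]}\t{al.b_span[0]}-{al.b_span[1]}"
                f"\t{al.relative_orientation}\n"
            )
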