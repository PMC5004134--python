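"""Unique k-mer anchoring: compress long reads into ordered contig-id lists.

Accurate pre-assembled contigs are indexed by their unique k-mers; every long
read is then reduced to the ordered, oriented list of contigs it confidently
touches.  This lossy "compressed read" is the representation every later stage
works in.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .seqio import read_fasta, revcomp

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ContigSet:
    """Accurate contigs keyed by id.

    Invariants: ids unique (enforced by the mapping), sequences over
    {A,C,G,T,N}.
    """

    contigs: Mapping[str, str]

    def __post_init__(self):
        allowed = frozenset("ACGTN")
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} is empty")
            if not set(seq) <= allowed:
                bad = sorted(set(seq) - allowed)
                raise ValueError(f"contig {cid!r} has non-ACGTN characters {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(s) for cid, s in self.contigs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "ContigSet":
        contigs: dict[str, str] = {}
        for cid, seq in read_fasta(path):
            if cid in contigs:
                raise ValueError(f"duplicate contig id {cid!r} in {path}")
            contigs[cid] = seq
        return cls(contigs)

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class KmerEntry:
    contig_id: str
    offset: int  # 0-based position of the k-mer on the contig forward strand
    strand: str  # strand of the contig on which the canonical form occurs


@dataclass(frozen=True)
class UniqueKmerIndex:
    """Canonical k-mer -> unique (contig, offset, strand) location.

    K-mers occurring in more than one contig, or more than once within a
    contig, are excluded: they cannot position a read unambiguously.
    """

    k: int
    entries: Mapping[str, KmerEntry]
    contig_lengths: Mapping[str, int]

    def __len__(self) -> int:
        return len(self.entries)


def canonical_kmer(kmer: str) -> tuple[str, str]:
    """Return (canonical form, strand of `kmer` relative to it)."""
    rc = revcomp(kmer)
    if rc < kmer:
        return rc, "-"
    return kmer, "+"


def build_unique_kmer_index(contigs: ContigSet, k: int) -> UniqueKmerIndex:
    """Index contigs by the canonical k-mers that occur exactly once overall."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not contigs.contigs:
        raise ValueError("empty contig set")
    short = [cid for cid, s in contigs.contigs.items() if len(s) < k]
    if short:
        raise ValueError(f"contigs shorter than k={k}: {short[:5]}")

    entries: dict[str, KmerEntry] = {}
    dead: set[str] = set()
    for cid, seq in contigs.contigs.items():
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if not _ACGT.issuperset(kmer):
                continue
            canon, strand = canonical_kmer(kmer)
            if canon in dead:
                continue
            if canon in entries:
                del entries[canon]
                dead.add(canon)
            else:
                entries[canon] = KmerEntry(cid, off, strand)
    return UniqueKmerIndex(k=k, entries=entries, contig_lengths=dict(contigs.lengths))


@dataclass(frozen=True)
class Anchor:
    """One contig confidently located on a read.

    read_pos is the median of the supporting k-mer start positions on the
    read (a float midpoint for even counts — the median is exactly
    mirror-symmetric under reverse complement, which strand canonicalization
    relies on).  contig_off is the median supporting offset on the contig
    forward strand; it is a placement hint for layout, not part of the
    compressed-read identity.
    """

    contig_id: str
    orientation: str  # '+'/'-' relative to the read
    read_pos: float
    kmer_support: int
    contig_off: float = 0.0

    @property
    def key(self) -> tuple[str, str]:
        return (self.contig_id, self.orientation)


def _flip_orient(o: str) -> str:
    return "-" if o == "+" else "+"


@dataclass(frozen=True)
class CompressedRead:
    """Ordered, oriented contig-identifier list standing in for a long read."""

    read_id: str
    anchors: tuple[Anchor, ...]
    multiplicity: int = 1
    members: tuple[str, ...] = ()
    sequence: str | None = None
    k: int = 1  # anchoring k-mer size; needed to mirror positions exactly

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if not self.members:
            object.__setattr__(self, "members", (self.read_id,))

    @property
    def key(self) -> tuple[tuple[str, str], ...]:
        """Identity of the compressed form: (contig_id, orientation) tuples."""
        return tuple(a.key for a in self.anchors)

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def is_empty(self) -> bool:
        return not self.anchors


def flipped(cr: CompressedRead) -> CompressedRead:
    """The reverse-complement form of a compressed read."""
    if cr.sequence is not None:
        length = len(cr.sequence)
    elif cr.anchors:
        length = max(a.read_pos for a in cr.anchors) + cr.k
    else:
        length = 0
    anchors = tuple(
        replace(a, orientation=_flip_orient(a.orientation), read_pos=length - cr.k - a.read_pos)
        for a in reversed(cr.anchors)
    )
    seq = revcomp(cr.sequence) if cr.sequence is not None else None
    return replace(cr, anchors=anchors, sequence=seq)


def canonicalize(cr: CompressedRead) -> CompressedRead:
    """Pick the lexicographically smaller of a read and its reverse complement.

    The order is on the (contig_id, orientation) key sequence; a palindromic
    key falls back to the raw sequence so ties are still broken
    deterministically.  Idempotent.
    """
    rc = flipped(cr)
    if rc.key < cr.key:
        return rc
    if rc.key == cr.key and cr.sequence is not None and rc.sequence < cr.sequence:
        return rc
    return cr


def anchor_read(
    read: str,
    index: UniqueKmerIndex,
    adaptive_frac: float = 0.008,
    min_support: int = 2,
    read_id: str = "",
) -> CompressedRead:
    """Convert a read into its compressed form.

    A contig is reported iff its count of uniquely matching k-mers reaches
    max(min_support, ceil(adaptive_frac * contig_length)).  Orientation is the
    majority strand relation of the hits; ties drop the anchor.
    """
    k = index.k
    read = read.upper()
    entries = index.entries
    # per contig: list of (read_pos, contig_off, relative orientation)
    hits: dict[str, list[tuple[int, int, str]]] = {}
    for i in range(len(read) - k + 1):
        kmer = read[i : i + k]
        canon, read_strand = canonical_kmer(kmer)
        entry = entries.get(canon)
        if entry is None:
            continue
        if k % 2 == 0 and revcomp(kmer) == kmer:
            continue  # rc-palindrome: cannot vote on orientation
        rel = "+" if read_strand == entry.strand else "-"
        hits.setdefault(entry.contig_id, []).append((i, entry.offset, rel))

    anchors: list[Anchor] = []
    for cid, hs in hits.items():
        clen = index.contig_lengths[cid]
        threshold = max(min_support, math.ceil(adaptive_frac * clen))
        if len(hs) < threshold:
            continue
        plus = [h for h in hs if h[2] == "+"]
        minus = [h for h in hs if h[2] == "-"]
        if len(plus) == len(minus):
            continue  # ambiguous orientation: drop rather than corrupt the graph
        major = plus if len(plus) > len(minus) else minus
        if len(major) < threshold:
            continue
        pos = statistics.median(h[0] for h in major)
        off = statistics.median(h[1] for h in major)
        anchors.append(
            Anchor(
                contig_id=cid,
                orientation=major[0][2],
                read_pos=float(pos),
                kmer_support=len(major),
                contig_off=float(off),
            )
        )

    anchors.sort(key=lambda a: (a.read_pos, a.contig_id))
    merged: list[Anchor] = []
    for a in anchors:
        if merged and merged[-1].key == a.key:
            prev = merged[-1]
            merged[-1] = replace(prev, kmer_support=prev.kmer_support + a.kmer_support)
        else:
            merged.append(a)
    return CompressedRead(read_id=read_id, anchors=tuple(merged), sequence=read, k=k)


def collapse_duplicates(crs: Iterable[CompressedRead]) -> list[CompressedRead]:
    """Merge reads with identical compressed forms, summing multiplicities.

    Inputs must be canonicalized.  Anchor-less reads are dropped (they carry
    no layout information and must not be merged with one another).  The
    representative is the member with the smallest read id; the full member
    list is kept for the consensus stage.
    """
    groups: dict[tuple, list[CompressedRead]] = {}
    for cr in crs:
        if cr.is_empty:
            continue
        groups.setdefault(cr.key, []).append(cr)
    out: list[CompressedRead] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda c: c.read_id)
        rep = members[0]
        out.append(
            replace(
                rep,
                multiplicity=sum(m.multiplicity for m in members),
                members=tuple(mid for m in members for mid in m.members),
            )
        )
    return out


def write_compressed_tsv(path: str, crs: Sequence[CompressedRead]) -> None:
    """Serialize compressed reads: read_id, multiplicity, anchor triples."""
    with open(path, "w") as fh:
        for cr in crs:
            triples = " ".join(
                f"{a.contig_id}:{a.orientation}:{a.read_pos:g}" for a in cr.anchors
            )
            fh.write(f"{cr.read_id}\t{cr.multiplicity}\t{triples}\n")


def read_compressed_tsv(path: str) -> list[CompressedRead]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rid, mult = parts[0], int(parts[1])
            anchors = []
            if len(parts) > 2 and parts[2]:
                for triple in parts[2].split(" "):
                    cid, orient, pos = triple.rsplit(":", 2)
                    anchors.append(Anchor(cid, orient, float(pos), 1))
            out.append(CompressedRead(rid, tuple(anchors), multiplicity=mult))
    return out
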