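"""Seed-chain-extend alignment of raw reads to a draft backbone.

Exact k-mer seeds on the dominant diagonal band are chained monotonically and
the gaps between consecutive seeds are closed with a small global DP (numba-
jitted when available).  The product is, per read, a dense map from backbone
positions to read positions — exactly what the sparse-graph consensus needs.
Coordinates for externally computed alignments can be imported from SAM
instead (see `from_sam`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import revcomp

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _dp_traceback(a: np.ndarray, b: np.ndarray) -> np.ndarray:  # pragma: no cover
    """Global alignment traceback matrix; 0=diag, 1=up (gap in b), 2=left."""
    la, lb = a.shape[0], b.shape[0]
    score = np.empty((la + 1, lb + 1), dtype=np.int32)
    tb = np.empty((la + 1, lb + 1), dtype=np.int8)
    for j in range(lb + 1):
        score[0, j] = -j
        tb[0, j] = 2
    for i in range(1, la + 1):
        score[i, 0] = -i
        tb[i, 0] = 1
        ai = a[i - 1]
        for j in range(1, lb + 1):
            s = 1 if ai == b[j - 1] else -1
            d = score[i - 1, j - 1] + s
            u = score[i - 1, j] - 1
            l = score[i, j - 1] - 1
            if d >= u and d >= l:
                score[i, j] = d
                tb[i, j] = 0
            elif u >= l:
                score[i, j] = u
                tb[i, j] = 1
            else:
                score[i, j] = l
                tb[i, j] = 2
    return tb


@njit(cache=False)
def _extend_dp(a: np.ndarray, b: np.ndarray) -> tuple:  # pragma: no cover
    """Anchored extension from (0,0); returns traceback and the best cell."""
    la, lb = a.shape[0], b.shape[0]
    score = np.empty((la + 1, lb + 1), dtype=np.int32)
    tb = np.empty((la + 1, lb + 1), dtype=np.int8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for j in range(lb + 1):
        score[0, j] = -j
        tb[0, j] = 2
    for i in range(1, la + 1):
        score[i, 0] = -i
        tb[i, 0] = 1
        ai = a[i - 1]
        for j in range(1, lb + 1):
            s = 1 if ai == b[j - 1] else -1
            d = score[i - 1, j - 1] + s
            u = score[i - 1, j] - 1
            l = score[i, j - 1] - 1
            if d >= u and d >= l:
                score[i, j] = d
                tb[i, j] = 0
            elif u >= l:
                score[i, j] = u
                tb[i, j] = 1
            else:
                score[i, j] = l
                tb[i, j] = 2
            if score[i, j] > best or (score[i, j] == best and j > bj):
                best = score[i, j]
                bi = i
                bj = j
    return tb, bi, bj


_B2C = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _B2C[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    return _B2C[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _segment_map(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    """Align read segment a to backbone segment b globally.

    Returns (m, matches): m[j] = index into a aligned at-or-after b position
    j, for j in 0..len(b) (inclusive end sentinel).
    """
    la, lb = len(a), len(b)
    m = np.empty(lb + 1, dtype=np.int64)
    if lb == 0:
        m[0] = la
        return m, 0
    if la == 0:
        m[:] = 0
        return m, 0
    tb = _dp_traceback(a, b)
    # walk back from (la, lb)
    i, j = la, lb
    m[lb] = la
    matches = 0
    while i > 0 or j > 0:
        op = tb[i, j]
        if op == 0:
            if a[i - 1] == b[j - 1]:
                matches += 1
            i -= 1
            j -= 1
            m[j] = i
        elif op == 1:
            i -= 1
        else:
            j -= 1
            m[j] = i
    return m, matches


@dataclass(frozen=True)
class ReadToBackboneAlignment:
    read_id: str
    orientation: str  # '+'/'-' of the read against the backbone
    bstart: int  # backbone interval covered, half-open
    bend: int
    seq: str  # read sequence in backbone orientation
    rmap: np.ndarray  # len bend-bstart+1; backbone pos p -> read index rmap[p-bstart]
    identity: float
    n_seeds: int
    weight: float = 1.0  # consensus vote weight (1 per read; higher for contigs)

    @property
    def read_interval(self) -> tuple[int, int]:
        return int(self.rmap[0]), int(self.rmap[-1])


class BackboneIndex:
    """Exact k-mer positions on a draft backbone (repetitive k-mers capped)."""

    def __init__(self, seq: str, k: int = 11, max_hits: int = 4):
        self.seq = seq
        self.k = k
        pos: dict[str, list[int]] = {}
        dead: set[str] = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer in dead:
                continue
            lst = pos.setdefault(kmer, [])
            lst.append(i)
            if len(lst) > max_hits:
                del pos[kmer]
                dead.add(kmer)
        self.pos = pos


def _chain(seeds: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Pick the dominant diagonal band, then a greedy monotone chain."""
    if not seeds:
        return []
    bins: dict[int, int] = {}
    for rp, bp in seeds:
        d = (bp - rp) >> 6
        bins[d] = bins.get(d, 0) + 1
    best_bin = max(sorted(bins), key=lambda d: bins.get(d - 1, 0) + bins[d] + bins.get(d + 1, 0))
    center = (best_bin << 6) + 32
    band = [s for s in seeds if abs((s[1] - s[0]) - center) <= 250]
    band.sort()
    chain: list[tuple[int, int]] = []
    for rp, bp in band:
        if not chain:
            chain.append((rp, bp))
            continue
        lr, lb = chain[-1]
        if rp <= lr or bp <= lb:
            continue
        # keep gap segments consistent: same diagonal or past the seed
        if (rp - lr == bp - lb) or (rp >= lr + k and bp >= lb + k):
            chain.append((rp, bp))
    return chain


def align_to_backbone(
    read_id: str,
    seq: str,
    index: BackboneIndex,
    min_seeds: int = 4,
    min_identity: float = 0.5,
    max_segment: int = 2500,
) -> ReadToBackboneAlignment | None:
    """Align a read to the backbone; None when no usable seed chain exists."""
    k = index.k
    best = None
    for orient, s in (("+", seq), ("-", revcomp(seq))):
        seeds = []
        for i in range(0, len(s) - k + 1):
            for bp in index.pos.get(s[i : i + k], ()):
                seeds.append((i, bp))
        chain = _chain(seeds, k)
        if best is None or len(chain) > best[2]:
            best = (orient, s, len(chain), chain)
    orient, s, n_seeds, chain = best
    if n_seeds < min_seeds:
        return None

    bstart = chain[0][1]
    bend = chain[-1][1] + k  # half-open backbone end
    rmap = np.empty(bend - bstart + 1, dtype=np.int64)
    enc = encode(s)
    benc = encode(index.seq)
    ext_cap = 2000
    matches = 0
    cols = 0
    cur_b = bstart
    prev_rp, prev_bp = None, None
    for rp, bp in chain:
        if prev_bp is not None and bp > prev_bp + k:
            # close the gap between the previous seed and this one with DP
            a_seg = enc[prev_rp + k : rp]
            b_seg = benc[prev_bp + k : bp]
            if len(a_seg) * len(b_seg) > max_segment * max_segment:
                # degenerate gap: interpolate linearly
                gm = np.linspace(0, len(a_seg), num=len(b_seg) + 1).astype(np.int64)
                gmatch = 0
            else:
                gm, gmatch = _segment_map(a_seg, b_seg)
            off = prev_bp + k - bstart
            rmap[off : off + len(b_seg) + 1] = gm + (prev_rp + k)
            matches += gmatch
            cols += max(len(a_seg), len(b_seg))
            cur_b = bp
        # seed region (may overlap the previous seed)
        for p in range(max(cur_b, bp), bp + k):
            rmap[p - bstart] = rp + (p - bp)
        added = bp + k - max(cur_b, bp)
        matches += added
        cols += added
        cur_b = bp + k
        prev_rp, prev_bp = rp, bp
    rmap[bend - bstart] = chain[-1][0] + k

    # extend past the terminal seeds toward the read ends
    left_vals: list[int] = []
    rp0, bp0 = chain[0]
    la = min(rp0, ext_cap)
    lb = min(bp0, la + 50)
    if la > 0 and lb > 0:
        tbm, bi, bj = _extend_dp(enc[rp0 - la : rp0][::-1].copy(), benc[bp0 - lb : bp0][::-1].copy())
        if bj > 0:
            ops = []
            i, j = bi, bj
            while i > 0 or j > 0:
                op = tbm[i, j]
                ops.append((op, i, j))
                if op == 0:
                    i, j = i - 1, j - 1
                elif op == 1:
                    i -= 1
                else:
                    j -= 1
            r, p = rp0 - bi, bp0 - bj
            for op, i, j in ops:  # already in ascending forward order
                if op == 0:
                    left_vals.append(r)
                    matches += enc[rp0 - la + i - 1] == benc[bp0 - lb + j - 1]
                    cols += 1
                    r += 1
                    p += 1
                elif op == 1:
                    cols += 1
                    r += 1
                else:
                    left_vals.append(r)
                    cols += 1
                    p += 1
            bstart = bp0 - bj

    right_vals: list[int] = []
    rpL, bpL = chain[-1]
    sentinel = chain[-1][0] + k
    ra = min(len(enc) - (rpL + k), ext_cap)
    rb = min(len(benc) - (bpL + k), ra + 50)
    if ra > 0 and rb > 0:
        tbm, bi, bj = _extend_dp(enc[rpL + k : rpL + k + ra], benc[bpL + k : bpL + k + rb])
        if bj > 0:
            ops = []
            i, j = bi, bj
            while i > 0 or j > 0:
                op = tbm[i, j]
                ops.append((op, i, j))
                if op == 0:
                    i, j = i - 1, j - 1
                elif op == 1:
                    i -= 1
                else:
                    j -= 1
            r, p = rpL + k, bpL + k
            for op, i, j in reversed(ops):  # ascending forward order
                if op == 0:
                    right_vals.append(r)
                    matches += enc[rpL + k + i - 1] == benc[bpL + k + j - 1]
                    cols += 1
                    r += 1
                    p += 1
                elif op == 1:
                    cols += 1
                    r += 1
                else:
                    right_vals.append(r)
                    cols += 1
                    p += 1
            bend = bpL + k + bj
            sentinel = rpL + k + bi

    if left_vals or right_vals:
        rmap = np.concatenate(
            [
                np.asarray(left_vals, dtype=np.int64),
                rmap[:-1],
                np.asarray(right_vals, dtype=np.int64),
                np.asarray([sentinel], dtype=np.int64),
            ]
        )
    identity = matches / cols if cols else 0.0
    if identity < min_identity:
        return None
    return ReadToBackboneAlignment(
        read_id=read_id,
        orientation=orient,
        bstart=bstart,
        bend=bend,
        seq=s,
        rmap=rmap,
        identity=identity,
        n_seeds=n_seeds,
    )


def from_sam(sam_path: str, backbone_names: set[str]) -> list[ReadToBackboneAlignment]:
    """Import read-to-backbone coordinates from a SAM file.

    Only cigar ops M/=/X/I/D/S/H are honored; records mapping to other
    references are skipped.
    """
    import re

    out = []
    cig_re = re.compile(r"(\d+)([MIDNSHP=X])")
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 11 or f[2] not in backbone_names:
                continue
            flag = int(f[1])
            if flag & 4:
                continue
            orient = "-" if flag & 16 else "+"
            bstart = int(f[3]) - 1
            seq = f[9].upper()
            rp, bp = 0, bstart
            pairs: list[tuple[int, int]] = []  # (backbone pos, read pos)
            for n, op in cig_re.findall(f[5]):
                n = int(n)
                if op in "SH":
                    rp += n if op == "S" else 0
                elif op in "M=X":
                    for t in range(n):
                        pairs.append((bp + t, rp + t))
                    bp += n
                    rp += n
                elif op == "I":
                    rp += n
                elif op in "DN":
                    for t in range(n):
                        pairs.append((bp + t, rp))
                    bp += n
            if not pairs:
                continue
            bend = pairs[-1][0] + 1
            rmap = np.empty(bend - bstart + 1, dtype=np.int64)
            for b, r in pairs:
                rmap[b - bstart] = r
            rmap[-1] = pairs[-1][1] + 1
            out.append(
                ReadToBackboneAlignment(
                    read_id=f[0],
                    orientation=orient,
                    bstart=bstart,
                    bend=bend,
                    seq=seq,
                    rmap=rmap,
                    identity=1.0,
                    n_seeds=0,
                )
            )
    return out
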