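"""Shared test utilities: independent identity measures and object builders.

The alignment code here is intentionally separate from the package's own
aligners so it can serve as an oracle.
"""

from __future__ import annotations

import numpy as np

from hybasm.anchor_index import Anchor, CompressedRead

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=False)
def _banded_edit(a, b, band):  # pragma: no cover - jitted
    la, lb = len(a), len(b)
    INF = 10**9
    prev = np.full(2 * band + 1, INF, dtype=np.int64)
    prev[band] = 0
    for j in range(1, band + 1):
        prev[band + j] = j
    for i in range(1, la + 1):
        cur = np.full(2 * band + 1, INF, dtype=np.int64)
        for d in range(-band, band + 1):
            j = i + d
            if j < 0 or j > lb:
                continue
            best = INF
            v = prev[d + band]
            if j > 0 and v < INF:
                v = v + (0 if a[i - 1] == b[j - 1] else 1)
                if v < best:
                    best = v
            if d + 1 <= band and prev[d + band + 1] < INF and prev[d + band + 1] + 1 < best:
                best = prev[d + band + 1] + 1
            if d - 1 >= -band and cur[d + band - 1] < INF and cur[d + band - 1] + 1 < best:
                best = cur[d + band - 1] + 1
            cur[d + band] = best
        prev = cur
    d = lb - la
    return prev[d + band] if abs(d) <= band else -1


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _enc(s: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in s], dtype=np.uint8)


def edit_distance(a: str, b: str, band: int = 200) -> int:
    """Banded Levenshtein distance; -1 if the band is exceeded."""
    return int(_banded_edit(_enc(a), _enc(b), band))


def window_identity(asm: str, genome: str, window: int = 1000) -> float:
    """Identity of an assembly against its genome, measured window-by-window.

    Each window is located in the genome by an exact 30-mer probe and scored
    with a banded edit distance; unlocatable windows are charged 15% error.
    """
    tot_err = 0
    tot_len = 0
    for w0 in range(0, len(asm) - window, window):
        aw = asm[w0 : w0 + window]
        gp = -1
        for off in range(0, window - 100, 47):
            gp = genome.find(aw[off : off + 30])
            if gp >= 0:
                gp -= off
                break
        if gp < 0:
            tot_err += int(window * 0.15)
            tot_len += window
            continue
        d = edit_distance(aw, genome[max(0, gp) : gp + window], band=150)
        tot_err += d if d >= 0 else int(window * 0.15)
        tot_len += window
    return 1 - tot_err / tot_len if tot_len else 0.0


def best_identity(asm: str, genome: str) -> float:
    from hybasm.seqio import revcomp

    return max(window_identity(asm, genome), window_identity(revcomp(asm), genome))


def mk_read(read_id: str, anchors, sequence=None, multiplicity=1, k=1) -> CompressedRead:
    """Build a CompressedRead from (contig_id, orientation[, read_pos]) specs."""
    built = []
    for i, spec in enumerate(anchors):
        if len(spec) == 2:
            cid, orient = spec
            pos = float(i * 10)
        else:
            cid, orient, pos = spec
        built.append(Anchor(str(cid), orient, float(pos), 1))
    return CompressedRead(
        read_id=read_id,
        anchors=tuple(built),
        multiplicity=multiplicity,
        sequence=sequence,
        k=k,
    )


def random_reads(rng: np.random.Generator, n: int, alphabet: int = 30, max_len: int = 15):
    """Random compressed reads over a small identifier alphabet."""
    out = []
    for i in range(n):
        length = int(rng.integers(1, max_len + 1))
        anchors = [
            (str(int(rng.integers(0, alphabet))), "+" if rng.random() < 0.5 else "-", j * 10)
            for j in range(length)
        ]
        out.append(mk_read(f"r{i:04d}", anchors))
    return out
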