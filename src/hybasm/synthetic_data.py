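"""Synthetic genomes, accurate contigs, and erroneous long reads with truth.

Every generator is reproducible per seed; a single top-level seed fans out to
independent per-stage streams so stages can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import revcomp

_BASES = np.array(list("ACGT"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class RepeatFamily:
    unit_length: int
    copies: int
    identity: float = 1.0


@dataclass(frozen=True)
class GenomeSpec:
    length: int
    repeats: tuple[RepeatFamily, ...] = ()
    seed: int = 0

    def __post_init__(self):
        need = sum(r.unit_length * r.copies for r in self.repeats)
        if need > self.length:
            raise ValueError("repeat families do not fit in the genome")


@dataclass(frozen=True)
class RepeatPlacement:
    family: int
    start: int
    end: int


def simulate_genome(spec: GenomeSpec) -> tuple[str, list[RepeatPlacement]]:
    """Uniform random genome with planted (possibly mutated) repeat copies."""
    rng = _rng(spec.seed, 0)
    seq = rng.choice(_BASES, size=spec.length)
    placements: list[RepeatPlacement] = []
    occupied: list[tuple[int, int]] = []
    for fi, fam in enumerate(spec.repeats):
        unit = rng.choice(_BASES, size=fam.unit_length)
        for _copy in range(fam.copies):
            placed = False
            for _try in range(1000):
                start = int(rng.integers(0, spec.length - fam.unit_length + 1))
                end = start + fam.unit_length
                if any(s < end and start < e for s, e in occupied):
                    continue
                copy = unit.copy()
                if fam.identity < 1.0:
                    muts = rng.random(fam.unit_length) > fam.identity
                    copy[muts] = rng.choice(_BASES, size=int(muts.sum()))
                seq[start:end] = copy
                occupied.append((start, end))
                placements.append(RepeatPlacement(fi, start, end))
                placed = True
                break
            if not placed:
                raise ValueError("could not place repeat copy (genome too crowded)")
    return "".join(seq), placements


@dataclass(frozen=True)
class ContigSimSpec:
    gap_rate: float = 1.0  # expected gaps per 10 kb
    gap_len_mean: float = 300.0
    gap_len_sigma: float = 0.25  # lognormal sigma on the gap length
    error_rate: float = 0.0  # small substitutions in contigs
    min_contig_len: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.min_contig_len < 1:
            raise ValueError("min_contig_len must be positive")


@dataclass(frozen=True)
class ContigTruth:
    contig_id: str
    start: int
    end: int


def simulate_contigs(
    genome: str, spec: ContigSimSpec
) -> tuple[dict[str, str], list[ContigTruth]]:
    """Fragment the genome at random gap positions into contig sequences."""
    rng = _rng(spec.seed, 1)
    L = len(genome)
    n_gaps = int(rng.poisson(spec.gap_rate * L / 10_000))
    starts = sorted(int(s) for s in rng.integers(0, L, size=n_gaps))
    gaps: list[tuple[int, int]] = []
    for s in starts:
        glen = max(1, int(rng.lognormal(np.log(spec.gap_len_mean), spec.gap_len_sigma)))
        e = min(L, s + glen)
        if gaps and s < gaps[-1][1]:
            continue
        gaps.append((s, e))
    contigs: dict[str, str] = {}
    truth: list[ContigTruth] = []
    prev = 0
    idx = 0
    for s, e in gaps + [(L, L)]:
        if s - prev >= spec.min_contig_len:
            cid = f"ctg{idx:04d}"
            cseq = list(genome[prev:s])
            if spec.error_rate > 0:
                errs = rng.random(len(cseq)) < spec.error_rate
                for i in np.flatnonzero(errs):
                    cseq[i] = str(rng.choice(_BASES[_BASES != cseq[i]]))
            contigs[cid] = "".join(cseq)
            truth.append(ContigTruth(cid, prev, s))
            idx += 1
        prev = e
    return contigs, truth


@dataclass(frozen=True)
class ReadSimSpec:
    coverage: float = 20.0
    length_mean: float = 8000.0  # mean of the lognormal length distribution
    length_sigma: float = 0.3
    min_length: int = 1000
    sub_rate: float = 0.05
    ins_rate: float = 0.05
    del_rate: float = 0.05
    chimera_rate: float = 0.0
    chimera_min_sep: int = 5000  # minimum genomic distance between fused loci
    seed: int = 0

    def __post_init__(self):
        total = self.sub_rate + self.ins_rate + self.del_rate
        if min(self.sub_rate, self.ins_rate, self.del_rate) < 0 or total >= 1:
            raise ValueError("error fractions must be >= 0 and sum < 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    parts: tuple[tuple[int, int, str], ...]  # (genome start, end, strand)
    chimeric: bool
    n_sub: int
    n_ins: int
    n_del: int

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]


def _mutate(template: str, spec: ReadSimSpec, rng: np.random.Generator) -> tuple[str, int, int, int]:
    n = len(template)
    u = rng.random(n)
    subs = rng.integers(1, 4, size=n)  # offset into the 3 alternative bases
    ins_bases = rng.integers(0, 4, size=n)
    out = []
    n_sub = n_ins = n_del = 0
    t_del = spec.del_rate
    t_sub = t_del + spec.sub_rate
    t_ins = t_sub + spec.ins_rate
    b2i = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, base in enumerate(template):
        ui = u[i]
        if ui < t_del:
            n_del += 1
            continue
        if ui < t_sub:
            out.append(_BASES[(b2i.get(base, 0) + subs[i]) % 4])
            n_sub += 1
            continue
        if ui < t_ins:
            out.append(_BASES[ins_bases[i]])
            n_ins += 1
        out.append(base)
    return "".join(out), n_sub, n_ins, n_del


def simulate_reads(
    genome: str, spec: ReadSimSpec
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Sample erroneous long reads; returns (records, truth).

    Chimeric reads are single-junction fusions of two independently sampled
    loci, each with its own random strand.
    """
    rng = _rng(spec.seed, 2)
    L = len(genome)
    target = spec.coverage * L
    reads: list[tuple[str, str]] = []
    truth: list[ReadTruth] = []
    total = 0
    idx = 0

    def sample_part(length: int) -> tuple[str, tuple[int, int, str]]:
        length = min(length, L)
        start = int(rng.integers(0, L - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tpl = genome[start : start + length]
        if strand == "-":
            tpl = revcomp(tpl)
        return tpl, (start, start + length, strand)

    while total < target:
        length = int(rng.lognormal(np.log(spec.length_mean) - spec.length_sigma**2 / 2, spec.length_sigma))
        length = max(spec.min_length, min(length, L))
        chimeric = rng.random() < spec.chimera_rate
        if chimeric:
            tpl1, p1 = sample_part(length // 2)
            for _try in range(100):  # fuse two distant loci
                tpl2, p2 = sample_part(length - length // 2)
                if max(p1[0], p2[0]) - min(p1[1], p2[1]) >= spec.chimera_min_sep:
                    break
            template, parts = tpl1 + tpl2, (p1, p2)
        else:
            template, part = sample_part(length)
            parts = (part,)
        seq, n_sub, n_ins, n_del = _mutate(template, spec, rng)
        rid = f"read{idx:05d}"
        reads.append((rid, seq))
        truth.append(ReadTruth(rid, parts, chimeric, n_sub, n_ins, n_del))
        total += len(seq)
        idx += 1
    return reads, truth


@dataclass(frozen=True)
class Dataset:
    genome: str
    repeats: list[RepeatPlacement]
    contigs: dict[str, str]
    contig_truth: list[ContigTruth]
    reads: list[tuple[str, str]]
    read_truth: dict[str, ReadTruth]


def standard_dataset(
    seed: int,
    genome_length: int = 100_000,
    coverage: float = 20.0,
    sub_rate: float = 0.05,
    ins_rate: float = 0.05,
    del_rate: float = 0.05,
    chimera_rate: float = 0.0,
    gap_rate: float = 1.0,
    repeats: Sequence[RepeatFamily] = (),
) -> Dataset:
    """The simulation used throughout the test-suite and acceptance checks."""
    genome, placements = simulate_genome(
        GenomeSpec(length=genome_length, repeats=tuple(repeats), seed=seed)
    )
    contigs, ctruth = simulate_contigs(genome, ContigSimSpec(gap_rate=gap_rate, seed=seed))
    reads, rtruth = simulate_reads(
        genome,
        ReadSimSpec(
            coverage=coverage,
            sub_rate=sub_rate,
            ins_rate=ins_rate,
            del_rate=del_rate,
            chimera_rate=chimera_rate,
            seed=seed,
        ),
    )
    return Dataset(
        genome=genome,
        repeats=placements,
        contigs=contigs,
        contig_truth=ctruth,
        reads=reads,
        read_truth={t.read_id: t for t in rtruth},
    )


def write_truth_tsv(path: str, truth: Sequence[ReadTruth]) -> None:
    """BED-like truth map for reads against the genome."""
    with open(path, "w") as fh:
        fh.write("read_id\tchimeric\tparts\tn_sub\tn_ins\tn_del\n")
        for t in truth:
            parts = ";".join(f"{s}-{e}:{st}" for s, e, st in t.parts)
            fh.write(f"{t.read_id}\t{int(t.chimeric)}\t{parts}\t{t.n_sub}\t{t.n_ins}\t{t.n_del}\n")


def write_contig_truth_tsv(path: str, truth: Sequence[ContigTruth]) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tstart\tend\n")
        for t in truth:
            fh.write(f"{t.contig_id}\t{t.start}\t{t.end}\n")
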