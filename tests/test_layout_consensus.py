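"""Tests for layout, backbone alignment, and the sparse-graph consensus."""

import numpy as np
import pytest

from helpers import best_identity, edit_distance
from hybasm.anchor_index import (
    ContigSet,
    anchor_read,
    build_unique_kmer_index,
    canonicalize,
    collapse_duplicates,
)
from hybasm.basealign import BackboneIndex, align_to_backbone
from hybasm.compressed_align import ScoreScheme, build_inverted_index
from hybasm.layout_consensus import (
    DraftBackbone,
    build_consensus_graph,
    collect_reads,
    heaviest_path,
    layout,
    polish,
    sparc_consensus,
)
from hybasm.overlap_graph import BackbonePath, best_overlaps, linear_paths, remove_contained
from hybasm.seqio import revcomp
from hybasm.synthetic_data import ReadSimSpec, _mutate


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _noisy(seq, seed, err=0.05):
    spec = ReadSimSpec(sub_rate=err, ins_rate=err, del_rate=err)
    out, *_ = _mutate(seq, spec, np.random.default_rng(seed))
    return out


def _compress_all(ds, k=17):
    contigs = ContigSet(ds.contigs)
    index = build_unique_kmer_index(contigs, k)
    crs = []
    for rid, seq in ds.reads:
        cr = canonicalize(anchor_read(seq, index, read_id=rid))
        if not cr.is_empty:
            crs.append(cr)
    return contigs, crs


class TestLayout:
    @pytest.fixture
    def tiny(self, rng):
        genome = _random_dna(rng, 12_000)
        contigs = ContigSet({"a": genome[:5800], "b": genome[6000:]})
        index = build_unique_kmer_index(contigs, 17)
        scheme = ScoreScheme.from_contigs(contigs)
        return genome, contigs, index, scheme

    def test_single_read_identity(self, tiny):
        genome, contigs, index, scheme = tiny
        read = genome[1000:6500]
        cr = canonicalize(anchor_read(read, index, read_id="r0"))
        path = BackbonePath("backbone_0", ((cr.read_id, "+"),))
        drafts = layout(path, {"r0": cr}, ContigSet({}), scheme)
        assert len(drafts) == 1
        assert drafts[0].sequence == cr.sequence

    def test_two_reads_exact_overlap(self, rng):
        genome = _random_dna(rng, 16_000)
        contigs = ContigSet(
            {"a": genome[:5000], "b": genome[5200:10500], "c": genome[10700:]}
        )
        index = build_unique_kmer_index(contigs, 17)
        scheme = ScoreScheme.from_contigs(contigs)
        a = genome[0:8000]
        b = genome[7900:16000]  # 100 bases raw overlap
        ca = canonicalize(anchor_read(a, index, read_id="ra"))
        cb = canonicalize(anchor_read(b, index, read_id="rb"))
        crs = {c.read_id: c for c in (ca, cb)}
        g = best_overlaps([ca, cb], scheme)
        paths = linear_paths(g)
        assert len(paths) == 1 and len(paths[0].elements) == 2
        drafts = layout(paths[0], crs, ContigSet({}), scheme)
        assert len(drafts) == 1
        # error-free reads: the junction estimate is exact
        assert len(drafts[0].sequence) == len(a) + len(b) - 100
        assert drafts[0].sequence == genome

    def test_gap_patched_by_contig(self, tiny):
        genome, contigs, index, scheme = tiny
        a = genome[0:7500]  # anchors both contigs
        b = genome[9000:12000]  # no raw overlap; the shared contig bridges
        ca = canonicalize(anchor_read(a, index, read_id="ra"))
        cb = canonicalize(anchor_read(b, index, read_id="rb"))
        path = BackbonePath("backbone_0", (("ra", "+"), ("rb", "+")))
        drafts = layout(path, {"ra": ca, "rb": cb}, contigs, scheme)
        assert len(drafts) == 1
        got = drafts[0].sequence
        assert edit_distance(got, genome, band=250) <= 200  # only the ctg gap differs
        assert any(s.source_id.startswith("contig:") for s in drafts[0].segments)

    def test_segment_map_tiles(self, tiny):
        genome, contigs, index, scheme = tiny
        a = genome[0:7000]
        b = genome[5000:12000]
        ca = canonicalize(anchor_read(a, index, read_id="ra"))
        cb = canonicalize(anchor_read(b, index, read_id="rb"))
        path = BackbonePath("backbone_0", (("ra", "+"), ("rb", "+")))
        (draft,) = layout(path, {"ra": ca, "rb": cb}, ContigSet({}), scheme)
        pos = 0
        for seg in draft.segments:
            assert seg.backbone_interval[0] == pos
            pos = seg.backbone_interval[1]
        assert pos == len(draft.sequence)


class TestCollectReads:
    def test_lonely_path(self):
        from helpers import mk_read

        cr = mk_read("r0", [("1", "+")])
        idx = build_inverted_index([cr])
        pool = collect_reads(BackbonePath("p", (("r0", "+"),)), idx, {})
        assert pool == ["r0"]

    def test_contained_rejoin(self):
        from helpers import mk_read

        a = mk_read("a", [("1", "+"), ("2", "+")])
        b = mk_read("b", [("9", "+")])
        idx = build_inverted_index([a, b])
        pool = collect_reads(BackbonePath("p", (("a", "+"),)), idx, {"b": "a"})
        assert set(pool) == {"a", "b"}

    def test_identifier_scan_oracle(self, rng):
        from helpers import random_reads

        crs = random_reads(rng, 100, alphabet=15, max_len=5)
        idx = build_inverted_index(crs)
        path = BackbonePath("p", ((crs[0].read_id, "+"), (crs[1].read_id, "+")))
        pool = set(collect_reads(path, idx, {}))
        path_ids = {a.contig_id for c in crs[:2] for a in c.anchors}
        expected = {
            c.read_id for c in crs if {a.contig_id for a in c.anchors} & path_ids
        }
        assert pool == expected


class TestBackboneAlignment:
    def test_exact_substring(self, rng):
        draft = _random_dna(rng, 5000)
        idx = BackboneIndex(draft, k=11)
        aln = align_to_backbone("r", draft[1200:2600], idx)
        assert aln is not None
        assert aln.orientation == "+"
        assert aln.bstart == 1200 and aln.bend == 2600
        assert aln.identity == 1.0

    def test_revcomp_substring(self, rng):
        draft = _random_dna(rng, 5000)
        idx = BackboneIndex(draft, k=11)
        aln = align_to_backbone("r", revcomp(draft[1200:2600]), idx)
        assert aln is not None and aln.orientation == "-"
        assert aln.bstart == 1200 and aln.bend == 2600

    def test_no_chain_returns_none(self, rng):
        draft = _random_dna(rng, 3000)
        idx = BackboneIndex(draft, k=11)
        assert align_to_backbone("r", _random_dna(rng, 800), idx) is None

    def test_simulated_positions(self, rng):
        genome = _random_dna(rng, 20_000)
        idx = BackboneIndex(genome, k=11)
        ok = 0
        n = 40
        for i in range(n):
            start = int(rng.integers(0, 15_000))
            read = _noisy(genome[start : start + 4000], 100 + i)
            aln = align_to_backbone(f"r{i}", read, idx)
            if aln is not None and abs(aln.bstart - start) <= 50:
                ok += 1
        assert ok / n >= 0.95

    def test_rmap_monotone(self, rng):
        genome = _random_dna(rng, 8000)
        idx = BackboneIndex(genome, k=11)
        read = _noisy(genome[1000:5000], 9)
        aln = align_to_backbone("r", read, idx)
        assert aln is not None
        assert np.all(np.diff(aln.rmap) >= 0)


class TestSparcConsensus:
    def test_identical_reads_identity(self, rng):
        draft = _random_dna(rng, 800)
        idx = BackboneIndex(draft, k=11)
        alns = [align_to_backbone(f"r{i}", draft, idx) for i in range(5)]
        out = sparc_consensus(DraftBackbone("p", draft, ()), alns)
        assert out == draft

    def test_empty_pool_returns_draft(self, rng):
        draft = _random_dna(rng, 500)
        assert sparc_consensus(DraftBackbone("p", draft, ()), []) == draft

    def test_substitution_corrected(self, rng):
        truth = _random_dna(rng, 600)
        draft = truth[:300] + ("A" if truth[300] != "A" else "C") + truth[301:]
        idx = BackboneIndex(draft, k=11)
        alns = []
        for i in range(10):
            a = align_to_backbone(f"r{i}", truth, idx)
            assert a is not None
            alns.append(a)
        out = sparc_consensus(DraftBackbone("p", draft, ()), alns, t=0.2)
        assert out == truth

    def test_heaviest_path_vs_enumeration(self, rng):
        # graphs with <= 12 divergence points: exhaustive path enumeration
        for trial in range(10):
            truth = _random_dna(rng, 400)
            draft = list(truth)
            for pos in rng.choice(np.arange(20, 380), size=6, replace=False):
                draft[pos] = "ACGT"[int(rng.integers(0, 4))]
            draft = "".join(draft)
            idx = BackboneIndex(draft, k=11)
            alns = []
            for i in range(6):
                # error-free reads: divergence points are exactly the planted
                # draft errors, keeping exhaustive enumeration tractable
                a = align_to_backbone(f"r{i}", truth, idx)
                if a is not None:
                    alns.append(a)
            cg = build_consensus_graph(draft, alns, k_c=3, g=2, t=0.2)
            got = heaviest_path(cg)

            # exhaustive DFS over all source->sink paths
            best = [None, float("-inf")]

            def dfs(node, seq_parts, score):
                if node == cg.SINK:
                    if score > best[1]:
                        best[0], best[1] = "".join(seq_parts), score
                    return
                for (succ, label), w in cg.edges.get(node, {}).items():
                    dfs(succ, seq_parts + [label], score + cg.reweight(w, node[0] if node != cg.SOURCE else 0))

            dfs(cg.SOURCE, [], 0.0)
            assert best[0] is not None
            assert got == best[0]

    def test_deterministic(self, rng):
        truth = _random_dna(rng, 1500)
        draft = _noisy(truth, 1, err=0.03)
        pool = {f"r{i}": _noisy(truth, 50 + i, err=0.05) for i in range(8)}
        o1, _ = polish(DraftBackbone("p", draft, ()), pool, rounds=2)
        o2, _ = polish(DraftBackbone("p", draft, ()), pool, rounds=2)
        assert o1 == o2

    def test_monotone_improvement(self, rng):
        truth = _random_dna(rng, 4000)
        draft = _noisy(truth, 2, err=0.05)
        idents = []
        for cov in (2, 5, 10, 20):
            pool = {f"r{i}": _noisy(truth, 1000 + i, err=0.05) for i in range(cov)}
            out, _ = polish(DraftBackbone("p", draft, ()), pool, rounds=1)
            d = edit_distance(out, truth, band=300)
            idents.append(1 - d / len(truth))
        # non-decreasing within sampling noise
        for lo, hi in zip(idents, idents[1:]):
            assert hi >= lo - 0.005
        assert idents[-1] > idents[0]

    def test_improvement_over_draft(self, rng):
        truth = _random_dna(rng, 3000)
        draft = _noisy(truth, 3, err=0.05)
        pool = {f"r{i}": _noisy(truth, 2000 + i, err=0.05) for i in range(20)}
        out, n = polish(DraftBackbone("p", draft, ()), pool, rounds=2)
        d_draft = edit_distance(draft, truth, band=300)
        d_out = edit_distance(out, truth, band=300)
        assert n == 20
        assert d_out < d_draft / 5
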