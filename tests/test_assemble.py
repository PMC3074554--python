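"""De Bruijn assembly: graph construction, contigs, loci, representatives."""

import numpy as np
import pytest

from ovitome.assemble import (
    AssemblyParams,
    Contig,
    assemble_transcriptome,
    build_graph,
    canonical,
    cluster_loci,
    coverage_cutoff_from_spectrum,
    extract_contigs,
    filter_min_length,
    select_representative,
)
from ovitome.preprocess import revcomp

RNG = np.random.default_rng(1234)


def random_seq(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def tiling_reads(seq, read_len=40, step=1):
    return [seq[i:i + read_len] for i in range(0, len(seq) - read_len + 1, step)]


class TestBuildGraph:
    def test_sliding_window_enumeration(self):
        # stranded mode mirrors direct enumeration
        g = build_graph(["ACGTACGT"], k=4, canonicalize=False)
        assert set(g.counts) == {"ACGT", "CGTA", "GTAC", "TACG"}
        assert g.counts["ACGT"] == 2
        assert all(g.counts[km] == 1 for km in ("CGTA", "GTAC", "TACG"))
        assert "ACGTA" in g.edges

    def test_single_kmer_sequence(self):
        g = build_graph(["ACGTACGTACGTACGTA"], k=17, canonicalize=False)
        assert g.n_kmers == 1 and len(g.edges) == 0

    def test_short_sequences_skipped(self):
        g = build_graph(["ACG"], k=15)
        assert g.n_kmers == 0

    def test_canonical_collapses_strands(self):
        seq = random_seq(100)
        g1 = build_graph([seq], k=21)
        g2 = build_graph([revcomp(seq)], k=21)
        assert g1.counts == g2.counts
        assert g1.edges == g2.edges

    def test_disjoint_sequences_share_nothing(self):
        a, b = random_seq(80), random_seq(80)
        ga = build_graph([a], k=21)
        gb = build_graph([b], k=21)
        assert not set(ga.counts) & set(gb.counts)


class TestExtractContigs:
    def test_lossless_single_transcript_reconstruction(self):
        transcript = random_seq(1000)
        params = AssemblyParams(k=21, min_kmer_coverage=1)
        graph = build_graph(tiling_reads(transcript), 21)
        contigs = extract_contigs(graph, params)
        assert len(contigs) == 1
        assert contigs[0].sequence in (transcript, revcomp(transcript))

    def test_coverage_filter_removes_singleton_error_kmer(self):
        transcript = random_seq(500)
        reads = tiling_reads(transcript) * 2  # everything at multiplicity >= 2
        # one read with a single error in the middle
        err = list(reads[100])
        err[20] = "A" if err[20] != "A" else "C"
        reads.append("".join(err))
        graph = build_graph(reads, 21)
        contigs = extract_contigs(graph, AssemblyParams(k=21, min_kmer_coverage=2))
        joined = {km for c in contigs
                  for km in (canonical(c.sequence[i:i + 21])
                             for i in range(len(c.sequence) - 20))}
        err_kmer = canonical("".join(err)[0:21])
        assert err_kmer not in joined or err_kmer in {
            canonical(transcript[i:i + 21]) for i in range(len(transcript) - 20)
        }
        # the main transcript still reconstructs
        assert any(c.sequence in (transcript, revcomp(transcript)) for c in contigs)

    def test_shared_repeat_splits_paths(self):
        # two transcripts share an exact internal repeat longer than k
        repeat = random_seq(100)
        t1 = random_seq(300) + repeat + random_seq(300)
        t2 = random_seq(300) + repeat + random_seq(300)
        params = AssemblyParams(k=21, min_kmer_coverage=1)
        graph = build_graph(tiling_reads(t1) + tiling_reads(t2), 21)
        contigs = extract_contigs(graph, params)
        assert len(contigs) >= 3  # split at the branch points
        loci = cluster_loci(contigs, graph)
        assert len(loci) == 1  # but all contigs meet at the repeat

    def test_kmer_multiplicity_conservation(self):
        reads = tiling_reads(random_seq(600)) * 3
        graph = build_graph(reads, 21)
        params = AssemblyParams(k=21, min_kmer_coverage=2)
        contigs = extract_contigs(graph, params)
        retained_total = sum(c for c in graph.counts.values() if c >= 2)
        contig_total = sum(
            graph.counts[canonical(c.sequence[i:i + 21])]
            for c in contigs
            for i in range(len(c.sequence) - 20)
        )
        assert contig_total == retained_total

    def test_raising_cutoff_never_retains_more(self):
        reads = tiling_reads(random_seq(400)) + tiling_reads(random_seq(200))
        graph = build_graph(reads, 21)

        def n_kmers_at(cov):
            contigs = extract_contigs(graph, AssemblyParams(k=21, min_kmer_coverage=cov))
            return sum(len(c.sequence) - 20 for c in contigs)

        counts = [n_kmers_at(c) for c in (1, 2, 5, 50)]
        assert counts == sorted(counts, reverse=True)

    def test_empty_graph(self):
        graph = build_graph([], 21)
        assert extract_contigs(graph, AssemblyParams(k=21, min_kmer_coverage=1)) == []


class TestCoverageCutoff:
    def test_bimodal_spectrum_valley(self):
        transcript = random_seq(800)
        reads = tiling_reads(transcript) * 10  # deep clean coverage
        noise = [random_seq(40) for _ in range(300)]  # singleton noise
        graph = build_graph(reads + noise, 21)
        cutoff = coverage_cutoff_from_spectrum(graph)
        assert 2 <= cutoff <= 10  # between noise peak (1) and signal (~200)

    def test_flat_spectrum_falls_back(self):
        graph = build_graph([random_seq(100)], 21)
        assert coverage_cutoff_from_spectrum(graph) == 2


class TestLociAndRepresentatives:
    def test_disjoint_transcripts_one_locus_each(self):
        t1, t2 = random_seq(400), random_seq(400)
        graph = build_graph(tiling_reads(t1) + tiling_reads(t2), 21)
        contigs = extract_contigs(graph, AssemblyParams(k=21, min_kmer_coverage=1))
        loci = cluster_loci(contigs, graph)
        assert len(loci) == 2
        assert all(len(l.contig_ids) == 1 for l in loci)

    def test_components_match_union_find_oracle(self):
        repeat = random_seq(60)
        t1 = random_seq(200) + repeat + random_seq(200)
        t2 = random_seq(200) + repeat + random_seq(200)
        t3 = random_seq(400)
        graph = build_graph(
            tiling_reads(t1) + tiling_reads(t2) + tiling_reads(t3), 21
        )
        contigs = extract_contigs(graph, AssemblyParams(k=21, min_kmer_coverage=1))
        loci = cluster_loci(contigs, graph)

        # independent union-find over contig adjacencies
        parent = {c.contig_id: c.contig_id for c in contigs}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        owner = {}
        for c in contigs:
            for i in range(len(c.sequence) - 20):
                owner[canonical(c.sequence[i:i + 21])] = c.contig_id
        for edge in graph.edges:
            u, v = canonical(edge[:21]), canonical(edge[1:])
            if u in owner and v in owner and owner[u] != owner[v]:
                ru, rv = find(owner[u]), find(owner[v])
                if ru != rv:
                    parent[ru] = rv
        oracle = {}
        for c in contigs:
            oracle.setdefault(find(c.contig_id), set()).add(c.contig_id)
        assert {frozenset(l.contig_ids) for l in loci} == {
            frozenset(s) for s in oracle.values()
        }

    def test_representative_maximizes_length_times_coverage(self):
        c1 = Contig("C1", "A" * 300, 4.0)
        c2 = Contig("C2", "C" * 200, 5.0)
        from ovitome.assemble import Locus

        locus = Locus("L1", {"C1", "C2"})
        select_representative(locus, [c1, c2])
        assert locus.representative == "C1"  # 1200 > 1000
        assert locus.confidence == 1200.0

    def test_single_contig_locus(self):
        from ovitome.assemble import Locus

        c = Contig("C1", "A" * 100, 2.0)
        locus = Locus("L1", {"C1"})
        select_representative(locus, [c])
        assert locus.representative == "C1"

    def test_exact_tie_broken_by_lexicographic_sequence(self):
        from ovitome.assemble import Locus

        c1 = Contig("C1", "TTTT", 2.0)
        c2 = Contig("C2", "AAAA", 2.0)
        locus = Locus("L1", {"C1", "C2"})
        select_representative(locus, [c1, c2])
        assert locus.representative == "C2"


class TestFilterMinLength:
    def test_boundary_inclusive(self):
        kept = filter_min_length(
            [Contig("a", "A" * 150, 1.0), Contig("b", "A" * 149, 1.0)], 150
        )
        assert [c.contig_id for c in kept] == ["a"]

    def test_min_len_one_is_identity(self):
        contigs = [Contig("a", "ACGT", 1.0)]
        assert filter_min_length(contigs, 1) == contigs

    def test_all_short_yields_empty(self):
        assert filter_min_length([Contig("a", "A" * 10, 1.0)], 150) == []


def test_locus_count_equals_expressed_genes_on_clean_data():
    """Error-free deep coverage: one locus per gene."""
    from ovitome import synthio

    genes = synthio.generate_transcriptome(5, (600, 800), known_fraction=0.0, seed=11)
    design = synthio.make_design(genes, n_de=0, seed=0)
    lanes = synthio.simulate_reads(
        genes, design, depth=4000, error_rate=0.0, tail_lowq_prob=0.0,
        duplicate_rate=0.0, seed=11,
    )
    seqs = {r.sequence for lane in lanes for r in lane.reads}
    contigs, loci, reps = assemble_transcriptome(
        sorted(seqs), AssemblyParams(k=21, min_kmer_coverage=2)
    )
    assert len(loci) == 5
    assert len(reps) == 5
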