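"""Desk-scale de Bruijn graph assembly, locus clustering and representative
contig selection.

The assembler counts canonical k-mers (the lexicographic minimum of a k-mer
and its reverse complement, so reads from either strand collapse; k must be
odd to rule out reverse-complement palindromes), removes k-mers below a
coverage floor, and reports contigs as maximal unbranched paths of the
remaining graph.  Contigs that were incident to a common branch point are
grouped into loci — the graph-level analogue of one gene's transcript
variants — and one representative contig per locus, the one maximizing
``length x mean k-mer coverage``, is carried forward to annotation.  A final
minimum-length filter (default 150 bp, inclusive) discards uninformative
fragments.

This is a deliberately simple single-k assembler for synthetic, desk-scale
data: no tip/bubble error correction beyond the coverage filter, no
scaffolding, and no isoform path enumeration beyond locus grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .preprocess import revcomp

logger = logging.getLogger(__name__)


@dataclass
class AssemblyParams:
    """k-mer size, coverage floor and contig length floor.

    ``min_kmer_coverage=None`` selects the coverage cutoff automatically from
    the k-mer multiplicity spectrum (see :func:`coverage_cutoff_from_spectrum`);
    an explicit integer fixes it.
    """

    k: int = 21
    min_kmer_coverage: int | None = None
    min_contig_len: int = 150

    def __post_init__(self) -> None:
        if self.k < 15 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 15")
        if self.min_contig_len < self.k:
            raise ValueError("min_contig_len must be >= k")
        if self.min_kmer_coverage is not None and self.min_kmer_coverage < 1:
            raise ValueError("min_kmer_coverage must be >= 1")


@dataclass
class Contig:
    contig_id: str
    sequence: str
    mean_coverage: float
    locus_id: str | None = None


@dataclass
class Locus:
    locus_id: str
    contig_ids: set[str]
    representative: str | None = None
    confidence: float = 0.0


@dataclass
class DeBruijnGraph:
    """k-mer multiset plus observed (k+1)-mer adjacencies, both canonical."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    edges: set[str] = field(default_factory=set)

    @property
    def n_kmers(self) -> int:
        return len(self.counts)


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_graph(sequences: Iterable[str], k: int, canonicalize: bool = True) -> DeBruijnGraph:
    """Count k-mers and record (k+1)-mer adjacencies over all input sequences.

    Sequences shorter than k are skipped with a warning.  With
    ``canonicalize`` (the default) each k-mer is stored as the lexicographic
    minimum of itself and its reverse complement; disabling it gives a plain
    stranded graph (useful for small worked examples).
    """
    graph = DeBruijnGraph(k=k)
    counts = graph.counts
    edges = graph.edges
    n_skipped = 0
    for seq in sequences:
        s = seq.upper()
        if len(s) < k:
            n_skipped += 1
            continue
        if canonicalize:
            rc = revcomp(s)
            L = len(s)
            for i in range(L - k + 1):
                fwd = s[i:i + k]
                bwd = rc[L - k - i:L - i]
                km = fwd if fwd <= bwd else bwd
                counts[km] = counts.get(km, 0) + 1
            for i in range(L - k):
                fwd = s[i:i + k + 1]
                bwd = rc[L - k - 1 - i:L - i]
                edges.add(fwd if fwd <= bwd else bwd)
        else:
            for i in range(len(s) - k + 1):
                km = s[i:i + k]
                counts[km] = counts.get(km, 0) + 1
            for i in range(len(s) - k):
                edges.add(s[i:i + k + 1])
    if n_skipped:
        logger.warning("skipped %d sequences shorter than k=%d", n_skipped, k)
    return graph


def coverage_cutoff_from_spectrum(graph: DeBruijnGraph, min_cutoff: int = 2,
                                  max_scan: int = 10_000) -> int:
    """Coverage cutoff at the valley of the k-mer multiplicity spectrum.

    Sequencing errors pile up k-mers at multiplicity 1-3 while genuine
    transcript k-mers cluster around the true coverage, so the histogram of
    multiplicities is bimodal and the valley between the two modes separates
    noise from signal.  At high coverage a fixed small cutoff fails (the same
    error is eventually observed twice), which is why the cutoff must scale
    with the data.  Falls back to ``min_cutoff`` when no valley exists
    (error-free or very shallow data).
    """
    if not graph.counts:
        return min_cutoff
    hist: dict[int, int] = {}
    for c in graph.counts.values():
        hist[c] = hist.get(c, 0) + 1
    top = min(max(hist), max_scan)
    arr = [hist.get(c, 0) for c in range(top + 2)]
    # the error peak decays from multiplicity 1; the first strict rise of the
    # histogram marks the valley before the true-coverage mode
    for c in range(min_cutoff, top):
        if arr[c + 1] > arr[c]:
            return c + 1
    return min_cutoff


def _resolve_min_coverage(graph: DeBruijnGraph, params: AssemblyParams) -> int:
    if params.min_kmer_coverage is not None:
        return params.min_kmer_coverage
    cutoff = coverage_cutoff_from_spectrum(graph)
    logger.info("auto-selected k-mer coverage cutoff: %d", cutoff)
    return cutoff


def _oriented_adjacency(
    graph: DeBruijnGraph, retained: set[str], canonicalize: bool
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Successor/predecessor sets over oriented k-mers, restricted to retained
    canonical k-mers and to adjacencies witnessed by an observed (k+1)-mer."""
    k = graph.k
    succ: dict[str, set[str]] = {}
    pred: dict[str, set[str]] = {}

    def key(km: str) -> str:
        return canonical(km) if canonicalize else km

    for edge in graph.edges:
        orientations = (edge, revcomp(edge)) if canonicalize else (edge,)
        for e in orientations:
            u, v = e[:k], e[1:]
            if key(u) in retained and key(v) in retained:
                succ.setdefault(u, set()).add(v)
                pred.setdefault(v, set()).add(u)
    return succ, pred


def extract_contigs(graph: DeBruijnGraph, params: AssemblyParams,
                    canonicalize: bool = True) -> list[Contig]:
    """Maximal unbranched paths after the coverage filter.

    Every retained k-mer lands in exactly one contig; a contig extends through
    a junction only when it is 1-in-1-out on both sides.  Contig orientation
    is normalized (lexicographic minimum of sequence and reverse complement)
    and ids are assigned in sorted-sequence order, so output is deterministic.
    """
    if params.k != graph.k:
        raise ValueError("params.k does not match graph k")
    k = graph.k
    min_cov = _resolve_min_coverage(graph, params)
    retained = {km for km, c in graph.counts.items() if c >= min_cov}
    if not retained:
        return []
    succ, pred = _oriented_adjacency(graph, retained, canonicalize)

    def key(km: str) -> str:
        return canonical(km) if canonicalize else km

    used: set[str] = set()
    raw: list[tuple[str, float]] = []

    def walk_forward(start: str, blocked: set[str]) -> list[str]:
        """Extend from oriented k-mer ``start`` through 1-in-1-out junctions."""
        path = [start]
        blocked.add(key(start))
        cur = start
        while True:
            nxts = succ.get(cur)
            if nxts is None or len(nxts) != 1:
                break
            nxt = next(iter(nxts))
            if len(pred.get(nxt, ())) != 1:
                break
            ck = key(nxt)
            if ck in blocked or ck in used:
                break
            path.append(nxt)
            blocked.add(ck)
            cur = nxt
        return path

    def walk_backward(start: str, blocked: set[str]) -> list[str]:
        """Backward extension, returned outward from ``start`` (excluded)."""
        if canonicalize:
            # predecessors of `start` are successors of its reverse complement
            return [revcomp(x) for x in walk_forward(revcomp(start), blocked)[1:]]
        path = []
        cur = start
        while True:
            prevs = pred.get(cur)
            if prevs is None or len(prevs) != 1:
                break
            prv = next(iter(prevs))
            if len(succ.get(prv, ())) != 1:
                break
            ck = key(prv)
            if ck in blocked or ck in used:
                break
            path.append(prv)
            blocked.add(ck)
            cur = prv
        return path

    for km in sorted(retained):
        if km in used:
            continue
        blocked: set[str] = set()
        fwd = walk_forward(km, blocked)
        back = walk_backward(km, blocked)
        path = back[::-1] + fwd
        used.update(key(x) for x in path)
        seq = path[0] + "".join(x[-1] for x in path[1:])
        cov = sum(graph.counts[key(x)] for x in path) / len(path)
        if canonicalize:
            rc = revcomp(seq)
            if rc < seq:
                seq = rc
        raw.append((seq, cov))

    raw.sort()
    return [
        Contig(contig_id=f"C{i:05d}", sequence=seq, mean_coverage=cov)
        for i, (seq, cov) in enumerate(raw)
    ]


def _contig_kmer_map(contigs: Sequence[Contig], k: int, canonicalize: bool = True) -> dict[str, str]:
    owner: dict[str, str] = {}
    for c in contigs:
        for i in range(len(c.sequence) - k + 1):
            km = c.sequence[i:i + k]
            owner[canonical(km) if canonicalize else km] = c.contig_id
    return owner


def cluster_loci(contigs: Sequence[Contig], graph: DeBruijnGraph,
                 canonicalize: bool = True) -> list[Locus]:
    """Group contigs into loci: connected components of the contig-adjacency
    graph, where two contigs are adjacent when an observed (k+1)-mer joins a
    k-mer of one to a k-mer of the other (i.e. they meet at a branch point).

    Sets ``locus_id`` on the contigs in place and returns the loci, labelled
    deterministically by their smallest contig id.
    """
    k = graph.k
    owner = _contig_kmer_map(contigs, k, canonicalize)
    adjacency = nx.Graph()
    adjacency.add_nodes_from(c.contig_id for c in contigs)
    for edge in graph.edges:
        u, v = edge[:k], edge[1:]
        cu = owner.get(canonical(u) if canonicalize else u)
        cv = owner.get(canonical(v) if canonicalize else v)
        if cu is not None and cv is not None and cu != cv:
            adjacency.add_edge(cu, cv)
    components = sorted(nx.connected_components(adjacency), key=min)
    by_id = {c.contig_id: c for c in contigs}
    loci = []
    for i, comp in enumerate(components):
        locus = Locus(locus_id=f"L{i:05d}", contig_ids=set(comp))
        for cid in comp:
            by_id[cid].locus_id = locus.locus_id
        loci.append(locus)
    return loci


def confidence_score(contig: Contig) -> float:
    """Representative-selection score: length x mean k-mer coverage."""
    return len(contig.sequence) * contig.mean_coverage


def select_representative(locus: Locus, contigs: Sequence[Contig]) -> Locus:
    """Pick the highest-confidence contig of a locus.

    Ties are broken by longer sequence, then lexicographically smaller
    sequence.  Sets ``representative`` and ``confidence`` in place.
    """
    if not locus.contig_ids:
        raise ValueError(f"locus {locus.locus_id} is empty")
    by_id = {c.contig_id: c for c in contigs}
    candidates = [by_id[cid] for cid in locus.contig_ids]
    best = sorted(
        candidates,
        key=lambda c: (-confidence_score(c), -len(c.sequence), c.sequence),
    )[0]
    locus.representative = best.contig_id
    locus.confidence = confidence_score(best)
    return locus


def filter_min_length(contigs: Iterable[Contig], min_len: int = 150) -> list[Contig]:
    """Keep contigs with length >= min_len (inclusive boundary)."""
    if min_len <= 0:
        raise ValueError("min_len must be > 0")
    contigs = list(contigs)
    kept = [c for c in contigs if len(c.sequence) >= min_len]
    if not kept and contigs:
        logger.info("all %d contigs shorter than %d bp", len(contigs), min_len)
    return kept


def assemble_transcriptome(
    sequences: Iterable[str], params: AssemblyParams | None = None
) -> tuple[list[Contig], list[Locus], list[Contig]]:
    """Full assembly convenience: graph -> contigs -> loci -> representatives.

    Returns (all contigs, loci with representatives chosen, representative
    contigs passing the minimum-length filter).
    """
    params = params or AssemblyParams()
    graph = build_graph(sequences, params.k)
    contigs = extract_contigs(graph, params)
    loci = cluster_loci(contigs, graph)
    by_id = {c.contig_id: c for c in contigs}
    representatives = []
    for locus in loci:
        select_representative(locus, contigs)
        representatives.append(by_id[locus.representative])
    kept = filter_min_length(representatives, params.min_contig_len)
    logger.info(
        "assembly: %d contigs, %d loci, %d representatives >= %d bp",
        len(contigs), len(loci), len(kept), params.min_contig_len,
    )
    return contigs, loci, kept
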