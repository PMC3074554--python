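"""Short-read mapping against the composite reference and per-lane counting.

Mapping mimics a seed-based ungapped aligner: an alignment is valid when the
5' seed (default 18 bp) carries at most ``max_seed_mismatches`` (default 3)
mismatches and the full read at most ``max_total_mismatches`` (default 5);
both strands are searched and the fewest-mismatch alignment wins.

Candidate positions are found by a pigeonhole word index: the read is split
into ``max_total_mismatches + 1`` disjoint pieces, so any alignment within
the total-mismatch budget leaves at least one piece exact; looking up each
piece's leading word in an exact-match index over the reference therefore
finds every valid candidate.  Verification is vectorized over candidates.

Each read is assigned to a single gene.  When several entries tie at the best
mismatch count the assignment follows a deterministic source priority —
annotated same-species mRNA > de novo contig > annotated close-relative mRNA
> unannotated entries — then lexicographic seq_id; ties across *different*
genes are counted as ambiguous so the influence of the rule is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import CompositeReference
from .preprocess import revcomp

logger = logging.getLogger(__name__)

_ENCODE = np.zeros(256, dtype=np.uint8) + 4
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

SOURCE_PRIORITY = {
    "target_annot": 0,
    "denovo": 1,
    "close_annot": 2,
    "target_unannot": 3,
    "close_unannot": 4,
}

SOURCE_CATEGORIES = tuple(SOURCE_PRIORITY)


@dataclass
class MappingParams:
    seed_length: int = 18
    max_seed_mismatches: int = 3
    max_total_mismatches: int = 5

    def __post_init__(self) -> None:
        if self.seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        if self.max_seed_mismatches < 0 or self.max_total_mismatches < 0:
            raise ValueError("mismatch bounds must be >= 0")


@dataclass(frozen=True)
class Alignment:
    seq_id: str
    offset: int                     # 0-based position on the entry
    strand: str                     # "+" or "-"
    mismatches: int
    source_category: str
    gene: str


def _source_category(source: str, symbol: str | None) -> str:
    if source == "denovo":
        return "denovo"
    base = "target" if source == "target_mrna" else "close"
    return f"{base}_annot" if symbol else f"{base}_unannot"


class ReferenceIndex:
    """Concatenated, word-indexed composite reference for pigeonhole mapping."""

    def __init__(self, reference: CompositeReference, word_size: int = 12):
        self.word_size = word_size
        self.entries = reference.entries
        self.seq_ids = [e.seq_id for e in self.entries]
        self.sources = [_source_category(e.source, e.gene_symbol) for e in self.entries]
        # gene identity: the symbol when annotated, else the entry's own id
        self.genes = [e.gene_symbol or e.seq_id for e in self.entries]
        self.lengths = np.array([len(e.sequence) for e in self.entries])
        self.starts = np.zeros(len(self.entries), dtype=np.int64)
        np.cumsum(self.lengths[:-1], out=self.starts[1:])
        self.concat = _ENCODE[
            np.frombuffer("".join(e.sequence for e in self.entries).encode(), dtype=np.uint8)
        ]
        self.ends = self.starts + self.lengths
        index: dict[bytes, list[int]] = {}
        for ei, e in enumerate(self.entries):
            s = e.sequence.encode()
            base = int(self.starts[ei])
            for pos in range(len(s) - word_size + 1):
                index.setdefault(s[pos:pos + word_size], []).append(base + pos)
        self._index = {w: np.array(p, dtype=np.int64) for w, p in index.items()}
        # priority vector for deterministic tie-breaking: (source rank, seq_id)
        order = sorted(range(len(self.entries)),
                       key=lambda i: (SOURCE_PRIORITY[self.sources[i]], self.seq_ids[i]))
        self.priority = np.empty(len(self.entries), dtype=np.int64)
        self.priority[order] = np.arange(len(order))

    def entry_of(self, concat_pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.starts, concat_pos, side="right") - 1


def _piece_offsets(read_len: int, n_pieces: int, word_size: int) -> list[int]:
    """Start offsets of disjoint pieces covering the read, each >= word_size
    when the read is long enough; otherwise as many word-length pieces as fit."""
    if read_len < word_size:
        return []
    n_pieces = min(n_pieces, read_len // word_size)
    bounds = np.linspace(0, read_len, n_pieces + 1).astype(int)
    return [int(b) for b in bounds[:-1]]


def find_alignments(
    sequence: str, index: ReferenceIndex, params: MappingParams | None = None
) -> list[Alignment]:
    """All best (fewest-total-mismatch) valid alignments of a read.

    Searches both strands; a valid alignment has at most
    ``max_seed_mismatches`` in the 5' seed and ``max_total_mismatches``
    overall.  Results are sorted by the deterministic priority order.
    """
    params = params or MappingParams()
    L = len(sequence)
    if L < params.seed_length:
        return []
    n_pieces = params.max_total_mismatches + 1
    offsets = _piece_offsets(L, n_pieces, index.word_size)
    if not offsets:
        return []
    w = index.word_size
    best_mm = params.max_total_mismatches + 1
    best: list[tuple[int, int, str, int]] = []  # (priority, offset, strand, mm)
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        cands: list[np.ndarray] = []
        for off in offsets:
            hits = index._index.get(seq[off:off + w].encode())
            if hits is not None:
                cands.append(hits - off)
        if not cands:
            continue
        starts = np.unique(np.concatenate(cands))
        starts = starts[(starts >= 0) & (starts + L <= len(index.concat))]
        if starts.size == 0:
            continue
        eidx = index.entry_of(starts)
        within = (starts + L) <= index.ends[eidx]
        starts = starts[within]
        eidx = eidx[within]
        if starts.size == 0:
            continue
        read_arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        windows = index.concat[starts[:, None] + np.arange(L)]
        neq = windows != read_arr
        total_mm = neq.sum(axis=1)
        seed_mm = neq[:, : params.seed_length].sum(axis=1)
        valid = (seed_mm <= params.max_seed_mismatches) & (
            total_mm <= params.max_total_mismatches
        )
        for s, e, mm in zip(starts[valid], eidx[valid], total_mm[valid]):
            mm = int(mm)
            if mm < best_mm:
                best_mm = mm
                best = []
            if mm == best_mm:
                best.append((int(index.priority[e]), int(s - index.starts[e]), strand, int(e)))
    if not best:
        return []
    best.sort()
    out = []
    seen = set()
    for prio, offset, strand, e in best:
        key = (e, offset, strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            Alignment(
                seq_id=index.seq_ids[e],
                offset=offset,
                strand=strand,
                mismatches=best_mm,
                source_category=index.sources[e],
                gene=index.genes[e],
            )
        )
    return out


def map_read(
    sequence: str, index: ReferenceIndex, params: MappingParams | None = None
) -> Alignment | None:
    """Best alignment of a read, or None if unmapped."""
    alignments = find_alignments(sequence, index, params)
    return alignments[0] if alignments else None


def assign_to_gene(alignments: Sequence[Alignment]) -> tuple[str | None, bool]:
    """Collapse a read's best alignments to a single gene.

    Returns (gene, ambiguous): the first alignment in priority order decides;
    the read is flagged ambiguous when equally good alignments point at
    different genes.
    """
    if not alignments:
        return None, False
    genes = {a.gene for a in alignments}
    return alignments[0].gene, len(genes) > 1


@dataclass
class CountTable:
    """Genes x lanes raw counts plus per-lane accounting."""

    counts: pd.DataFrame
    lane_totals: pd.Series
    mapped_per_lane: pd.Series
    source_breakdown: pd.DataFrame   # categories x lanes, fractions of lane reads
    ambiguous_per_lane: pd.Series


def count_reads(
    lanes: Mapping[str, Iterable[str]],
    index: ReferenceIndex,
    params: MappingParams | None = None,
) -> CountTable:
    """Map every read of every lane and build the count table.

    ``lanes`` maps lane_id -> iterable of read sequences.  Identical read
    sequences within a run are mapped once and cached.  Column sums of the
    count table equal the mapped read number of the lane.
    """
    params = params or MappingParams()
    cache: dict[str, tuple[str | None, str | None, bool]] = {}
    genes_sorted = sorted(set(index.genes))
    gene_pos = {g: i for i, g in enumerate(genes_sorted)}
    lane_ids = list(lanes)
    counts = np.zeros((len(genes_sorted), len(lane_ids)), dtype=np.int64)
    totals, mapped, ambiguous = [], [], []
    breakdown = np.zeros((len(SOURCE_CATEGORIES), len(lane_ids)), dtype=np.int64)
    cat_pos = {c: i for i, c in enumerate(SOURCE_CATEGORIES)}
    for li, lane_id in enumerate(lane_ids):
        n_total = n_mapped = n_ambig = 0
        for seq in lanes[lane_id]:
            n_total += 1
            hit = cache.get(seq)
            if hit is None:
                alns = find_alignments(seq, index, params)
                gene, ambig = assign_to_gene(alns)
                cat = alns[0].source_category if alns else None
                hit = (gene, cat, ambig)
                cache[seq] = hit
            gene, cat, ambig = hit
            if gene is None:
                continue
            n_mapped += 1
            n_ambig += ambig
            counts[gene_pos[gene], li] += 1
            breakdown[cat_pos[cat], li] += 1
        totals.append(n_total)
        mapped.append(n_mapped)
        ambiguous.append(n_ambig)
    totals = pd.Series(totals, index=lane_ids, name="lane_total")
    frac = pd.DataFrame(breakdown, index=list(SOURCE_CATEGORIES), columns=lane_ids)
    frac = frac.div(totals.replace(0, 1), axis=1)
    return CountTable(
        counts=pd.DataFrame(counts, index=genes_sorted, columns=lane_ids),
        lane_totals=totals,
        mapped_per_lane=pd.Series(mapped, index=lane_ids, name="mapped"),
        source_breakdown=frac,
        ambiguous_per_lane=pd.Series(ambiguous, index=lane_ids, name="ambiguous"),
    )


def percent_mapped(mapped: int, total: int) -> float:
    """Percent of lane reads mapped, rounded to one decimal for reporting."""
    if total <= 0:
        raise ValueError("lane total must be > 0")
    return round(100.0 * mapped / total, 1)


def summarize_mapping(table: CountTable) -> pd.DataFrame:
    """Per-lane mapping report: totals, percent mapped, source percentages."""
    if len(table.lane_totals) == 0:
        raise ValueError("count table has no lanes")
    rows = []
    for lane in table.lane_totals.index:
        row = {
            "lane": lane,
            "reads": int(table.lane_totals[lane]),
            "mapped_reads": int(table.mapped_per_lane[lane]),
            "percent_mapped": percent_mapped(
                int(table.mapped_per_lane[lane]), int(table.lane_totals[lane])
            ),
        }
        for cat in SOURCE_CATEGORIES:
            row[f"pct_{cat}"] = round(100.0 * table.source_breakdown.loc[cat, lane], 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("lane")
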