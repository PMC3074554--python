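"""Tiered cross-species homology annotation of representative contigs.

Each contig is searched against up to three donor databases — same-species
mRNAs, close-relative mRNAs, and distant-relative proteins (via six-frame
translation) — and the best hit per tier is filtered with tier-specific
identity and E-value thresholds:

    same-species nucleotide:    identity >= 90%, E <= 1e-50
    close-relative nucleotide:  identity >= 97%, E <= 1e-50
    distant-relative protein:   identity >= 80%, E <= 1e-20

The closer the species, the higher the identity demanded, because larger
reference sets (with splice variants) raise the risk of spurious cross-gene
matches.  When several tiers pass, the closest species wins
(same-species > close > distant).  Contigs with no accepted hit are marked
unannotated and excluded from the composite mapping reference.

The search itself is a seed-and-extend local aligner: exact word matches
(11 nt / 4 aa) are clustered by diagonal and extended with a banded affine-gap
Smith-Waterman; overlapping seeds on one subject merge into a single local
alignment.  E-values follow the Karlin-Altschul form E = K * m * n * e^(-lambda*S)
with configurable lambda and K, evaluated in log space so extreme scores do
not underflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .preprocess import revcomp

logger = logging.getLogger(__name__)

TIER_PRIORITY = ("target_nt", "close_nt", "distant_aa")


@dataclass(frozen=True)
class TierThresholds:
    tier: str
    min_identity: float
    max_evalue: float


DEFAULT_TIERS: dict[str, TierThresholds] = {
    "target_nt": TierThresholds("target_nt", 0.90, 1e-50),
    "close_nt": TierThresholds("close_nt", 0.97, 1e-50),
    "distant_aa": TierThresholds("distant_aa", 0.80, 1e-20),
}


@dataclass
class Scoring:
    """Alignment scoring plus Karlin-Altschul statistics for one mode."""

    mode: str                       # "nt" or "aa"
    word_size: int
    gap_open: int                   # cost of the first gapped base (positive)
    gap_extend: int                 # cost of each further gapped base
    match: int = 1
    mismatch: int = -2
    matrix: object | None = None    # substitution matrix for aa mode
    lam: float = 1.28
    k_const: float = 0.46

    def score(self, a: str, b: str) -> float:
        if self.matrix is not None:
            return float(self.matrix[a, b])
        return self.match if a == b else self.mismatch


def nt_scoring() -> Scoring:
    return Scoring(mode="nt", word_size=11, gap_open=5, gap_extend=2,
                   match=1, mismatch=-2, lam=1.28, k_const=0.46)


def aa_scoring() -> Scoring:
    return Scoring(mode="aa", word_size=4, gap_open=11, gap_extend=1,
                   matrix=substitution_matrices.load("BLOSUM62"),
                   lam=0.267, k_const=0.041)


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------

def six_frame_translate(seq: str) -> list[str]:
    """Translations of frames +1, +2, +3, -1, -2, -3; stops rendered as '*'."""
    if len(seq) < 3:
        raise ValueError("sequence must be at least 3 nt for translation")
    frames = []
    for template in (seq, revcomp(seq)):
        for offset in range(3):
            sub = template[offset:]
            usable = len(sub) - len(sub) % 3
            frames.append(str(Seq(sub[:usable]).translate()))
    return frames


# ---------------------------------------------------------------------------
# Subject databases
# ---------------------------------------------------------------------------

@dataclass
class DBRecord:
    seq_id: str
    sequence: str
    gene_symbol: str | None = None


class SubjectDB:
    """Word-indexed subject set for seeded search."""

    def __init__(self, records: Iterable[DBRecord], mode: str = "nt",
                 word_size: int | None = None):
        self.records = list(records)
        if not self.records:
            raise ValueError("subject database is empty")
        self.mode = mode
        self.word_size = word_size or (11 if mode == "nt" else 4)
        self.total_length = sum(len(r.sequence) for r in self.records)
        index: dict[str, list[tuple[int, int]]] = {}
        w = self.word_size
        for ri, rec in enumerate(self.records):
            s = rec.sequence
            for pos in range(len(s) - w + 1):
                index.setdefault(s[pos:pos + w], []).append((ri, pos))
        self._index = index

    def seeds(self, query: str) -> dict[int, list[tuple[int, int]]]:
        """Per-subject seed list: rec_idx -> [(q_pos, s_pos), ...]."""
        w = self.word_size
        out: dict[int, list[tuple[int, int]]] = {}
        for q_pos in range(len(query) - w + 1):
            for ri, s_pos in self._index.get(query[q_pos:q_pos + w], ()):
                out.setdefault(ri, []).append((q_pos, s_pos))
        return out


# ---------------------------------------------------------------------------
# Banded Smith-Waterman
# ---------------------------------------------------------------------------

@dataclass
class LocalAlignment:
    score: float
    matches: int
    aligned_pairs: int
    query_range: tuple[int, int]
    subject_range: tuple[int, int]

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_pairs if self.aligned_pairs else 0.0


_NEG = float("-inf")


def banded_smith_waterman(
    query: str, subject: str, diag_lo: int, diag_hi: int, scoring: Scoring
) -> LocalAlignment | None:
    """Local affine-gap alignment restricted to diagonals d = s_pos - q_pos in
    [diag_lo, diag_hi].  A gap of length g costs gap_open + (g-1)*gap_extend.
    Identity is counted over aligned (non-gap) columns.  Returns None if no
    positive-scoring cell exists in the band.
    """
    m, n = len(query), len(subject)
    diag_lo = max(diag_lo, 1 - m)
    diag_hi = min(diag_hi, n - 1)
    width = diag_hi - diag_lo + 1
    if width <= 0:
        return None
    go, ge = scoring.gap_open, scoring.gap_extend
    # rows i = 0..m over query; band offset b = j - i - diag_lo for subject j
    H_prev = [0.0] * (width + 2)
    E_prev = [_NEG] * (width + 2)
    F_prev = [_NEG] * (width + 2)
    ptrH = [bytearray(width + 2) for _ in range(m + 1)]
    ptrE = [bytearray(width + 2) for _ in range(m + 1)]
    ptrF = [bytearray(width + 2) for _ in range(m + 1)]
    best_score, best_i, best_b = 0.0, -1, -1
    score_fn = scoring.score
    for i in range(1, m + 1):
        qc = query[i - 1]
        H_cur = [0.0] * (width + 2)
        E_cur = [_NEG] * (width + 2)
        F_cur = [_NEG] * (width + 2)
        j_min = max(1, i + diag_lo)
        j_max = min(n, i + diag_hi)
        pH, pE, pF = ptrH[i], ptrE[i], ptrF[i]
        for j in range(j_min, j_max + 1):
            b = j - i - diag_lo + 1  # +1: sentinel column at 0
            # E: gap in query (consume subject base from the left)
            e_open = H_cur[b - 1] - go
            e_ext = E_cur[b - 1] - ge
            if e_open >= e_ext:
                E_cur[b] = e_open
                pE[b] = 0
            else:
                E_cur[b] = e_ext
                pE[b] = 1
            # F: gap in subject (consume query base from above)
            f_open = H_prev[b + 1] - go
            f_ext = F_prev[b + 1] - ge
            if f_open >= f_ext:
                F_cur[b] = f_open
                pF[b] = 0
            else:
                F_cur[b] = f_ext
                pF[b] = 1
            diag = H_prev[b] + score_fn(qc, subject[j - 1])
            h, p = 0.0, 0
            if diag > h:
                h, p = diag, 1
            if E_cur[b] > h:
                h, p = E_cur[b], 2
            if F_cur[b] > h:
                h, p = F_cur[b], 3
            H_cur[b] = h
            pH[b] = p
            if h > best_score:
                best_score, best_i, best_b = h, i, b
        H_prev, E_prev, F_prev = H_cur, E_cur, F_cur
    if best_score <= 0:
        return None
    # traceback
    i, b = best_i, best_b
    j = i + diag_lo + b - 1
    end_q, end_s = i, j
    matches = aligned = 0
    state = "H"
    while i > 0 and j > 0:
        b = j - i - diag_lo + 1
        if state == "H":
            p = ptrH[i][b]
            if p == 0:
                break
            if p == 1:
                aligned += 1
                if query[i - 1] == subject[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            opened = ptrE[i][b] == 0
            j -= 1
            if opened:
                state = "H"
        else:  # F
            opened = ptrF[i][b] == 0
            i -= 1
            if opened:
                state = "H"
    return LocalAlignment(
        score=best_score,
        matches=matches,
        aligned_pairs=aligned,
        query_range=(i, end_q),
        subject_range=(j, end_s),
    )


# ---------------------------------------------------------------------------
# Seeded search
# ---------------------------------------------------------------------------

@dataclass
class HomologyHit:
    query_id: str
    subject_id: str
    subject_gene_symbol: str | None
    percent_identity: float          # fraction over aligned columns
    score: float
    bitscore: float
    evalue: float
    log10_evalue: float
    mode: str
    strand: str = "+"


def _cluster_diagonals(seeds: list[tuple[int, int]], merge_dist: int) -> list[tuple[int, int, int]]:
    """Group seeds by diagonal proximity -> [(diag_min, diag_max, n_seeds)]."""
    diags = sorted(s - q for q, s in seeds)
    clusters = []
    start = prev = diags[0]
    count = 1
    for d in diags[1:]:
        if d - prev <= merge_dist:
            prev = d
            count += 1
        else:
            clusters.append((start, prev, count))
            start = prev = d
            count = 1
    clusters.append((start, prev, count))
    return clusters


def homology_search(
    query_id: str,
    query: str,
    db: SubjectDB,
    scoring: Scoring | None = None,
    min_seeds: int = 2,
    band_pad: int = 8,
    search_both_strands: bool = True,
) -> list[HomologyHit]:
    """Seed-and-extend search of one query against a subject database.

    Exact words shared with a subject are clustered by diagonal; each cluster
    with at least ``min_seeds`` seeds is extended by banded Smith-Waterman
    over the cluster's diagonals (padded by ``band_pad``).  One hit per
    subject is kept (the best across clusters and, for nucleotides, strands),
    sorted by E-value.  ``min_seeds=2`` is a two-hit heuristic that suppresses
    chance single-word matches; set 1 for exhaustive seeding.
    """
    scoring = scoring or (nt_scoring() if db.mode == "nt" else aa_scoring())
    if scoring.mode != db.mode:
        raise ValueError(f"scoring mode {scoring.mode} does not match db mode {db.mode}")
    strands = [(query, "+")]
    if db.mode == "nt" and search_both_strands:
        strands.append((revcomp(query), "-"))
    best: dict[int, tuple[LocalAlignment, str]] = {}
    for qseq, strand in strands:
        if len(qseq) < db.word_size:
            continue
        for ri, seeds in db.seeds(qseq).items():
            if len(seeds) < min_seeds:
                continue
            subject = db.records[ri].sequence
            for dlo, dhi, n_seeds in _cluster_diagonals(seeds, merge_dist=2 * band_pad):
                if n_seeds < min_seeds:
                    continue
                aln = banded_smith_waterman(qseq, subject, dlo - band_pad,
                                            dhi + band_pad, scoring)
                if aln is None:
                    continue
                prev = best.get(ri)
                if prev is None or aln.score > prev[0].score:
                    best[ri] = (aln, strand)
    m = len(query)
    n = db.total_length
    hits = []
    for ri, (aln, strand) in best.items():
        rec = db.records[ri]
        log10_e = (math.log10(scoring.k_const * m * n)
                   - scoring.lam * aln.score / math.log(10))
        hits.append(
            HomologyHit(
                query_id=query_id,
                subject_id=rec.seq_id,
                subject_gene_symbol=rec.gene_symbol,
                percent_identity=aln.identity,
                score=aln.score,
                bitscore=scoring.lam * aln.score / math.log(2),
                evalue=max(10.0 ** log10_e, 5e-324),
                log10_evalue=log10_e,
                mode=db.mode,
                strand=strand,
            )
        )
    hits.sort(key=lambda h: (h.log10_evalue, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# Best-hit filtering and tier precedence
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    query_id: str
    symbol: str | None = None
    tier: str | None = None
    hit: HomologyHit | None = None
    tier_conflict: bool = False      # different symbols accepted in different tiers

    @property
    def accepted(self) -> bool:
        return self.symbol is not None


def best_hit_and_filter(
    query_id: str,
    hits_per_tier: Mapping[str, Sequence[HomologyHit]],
    thresholds: Mapping[str, TierThresholds] | None = None,
) -> Annotation:
    """Apply the per-tier best-hit + threshold filter and tier precedence.

    Within each tier only the lowest-E-value hit survives; it is accepted iff
    identity >= min_identity and E <= max_evalue for that tier.  The assigned
    symbol comes from the highest-priority tier with an accepted hit.
    """
    thresholds = thresholds or DEFAULT_TIERS
    accepted: dict[str, HomologyHit] = {}
    for tier in TIER_PRIORITY:
        hits = hits_per_tier.get(tier)
        if not hits:
            continue
        top = min(hits, key=lambda h: (h.log10_evalue, h.subject_id))
        th = thresholds[tier]
        if top.percent_identity >= th.min_identity and top.evalue <= th.max_evalue:
            accepted[tier] = top
    if not accepted:
        return Annotation(query_id=query_id)
    for tier in TIER_PRIORITY:
        if tier in accepted:
            chosen = accepted[tier]
            symbols = {h.subject_gene_symbol for h in accepted.values()}
            return Annotation(
                query_id=query_id,
                symbol=chosen.subject_gene_symbol,
                tier=tier,
                hit=chosen,
                tier_conflict=len(symbols) > 1,
            )
    raise AssertionError("unreachable")


def annotate_contigs(
    queries: Iterable[tuple[str, str]],
    dbs: Mapping[str, SubjectDB],
    thresholds: Mapping[str, TierThresholds] | None = None,
    min_seeds: int = 2,
    lazy: bool = True,
) -> tuple[list[Annotation], pd.DataFrame]:
    """Annotate contigs against the available tier databases.

    ``dbs`` maps tier name ("target_nt", "close_nt", "distant_aa") to its
    database.  With ``lazy`` (default) lower-priority tiers are only searched
    when every higher tier failed, which cannot change the outcome because
    precedence would discard their hits anyway.  Returns the annotations and a
    BLAST-like tabular summary.
    """
    thresholds = thresholds or DEFAULT_TIERS
    annotations = []
    rows = []
    n_conflicts = 0
    for query_id, seq in queries:
        hits_per_tier: dict[str, list[HomologyHit]] = {}
        annotation = Annotation(query_id=query_id)
        for tier in TIER_PRIORITY:
            db = dbs.get(tier)
            if db is None:
                continue
            if tier == "distant_aa":
                hits: list[HomologyHit] = []
                if len(seq) >= 3:
                    for frame in six_frame_translate(seq):
                        if len(frame) >= db.word_size:
                            hits.extend(
                                homology_search(query_id, frame, db,
                                                min_seeds=min_seeds)
                            )
            else:
                hits = homology_search(query_id, seq, db, min_seeds=min_seeds)
            hits_per_tier[tier] = hits
            candidate = best_hit_and_filter(query_id, hits_per_tier, thresholds)
            if lazy and candidate.accepted:
                annotation = candidate
                break
            annotation = candidate
        n_conflicts += annotation.tier_conflict
        annotations.append(annotation)
        h = annotation.hit
        rows.append(
            {
                "query_id": query_id,
                "symbol": annotation.symbol,
                "tier": annotation.tier,
                "subject_id": h.subject_id if h else None,
                "identity": h.percent_identity if h else np.nan,
                "evalue": h.evalue if h else np.nan,
                "bitscore": h.bitscore if h else np.nan,
                "accepted": annotation.accepted,
            }
        )
    if n_conflicts:
        logger.info("%d contigs had conflicting symbols across tiers "
                    "(resolved by tier precedence)", n_conflicts)
    return annotations, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Composite reference
# ---------------------------------------------------------------------------

@dataclass
class CompositeEntry:
    seq_id: str
    sequence: str
    gene_symbol: str | None
    source: str                      # "denovo", "target_mrna", "close_mrna"


@dataclass
class CompositeReference:
    entries: list[CompositeEntry]

    def source_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.source] = out.get(e.source, 0) + 1
        return out


def build_composite_reference(
    annotated_contigs: Iterable[tuple[str, str, str | None]],
    target_mrnas: Iterable[tuple[str, str, str | None]],
    close_mrnas: Iterable[tuple[str, str, str | None]],
) -> CompositeReference:
    """Union of annotated de novo contigs and donor mRNAs, tagged by source.

    Donor mRNAs keep their own gene symbols; a gene present both as a contig
    and a donor mRNA yields two entries (redundancy is resolved at mapping
    time by the read-assignment priority rule).  Duplicate seq_ids raise.
    """
    entries: list[CompositeEntry] = []
    for source, items in (
        ("denovo", annotated_contigs),
        ("target_mrna", target_mrnas),
        ("close_mrna", close_mrnas),
    ):
        for seq_id, seq, symbol in items:
            entries.append(CompositeEntry(seq_id, seq.upper(), symbol, source))
    seen: set[str] = set()
    for e in entries:
        if e.seq_id in seen:
            raise ValueError(f"duplicate seq_id in composite reference: {e.seq_id}")
        seen.add(e.seq_id)
    if not any(e.source == "denovo" for e in entries):
        logger.warning("composite reference contains no de novo contigs")
    return CompositeReference(entries=entries)
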