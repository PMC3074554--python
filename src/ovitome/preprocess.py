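"""Short-read pooling, deduplication, 3' quality trimming and reference filtering.

This stage prepares the raw material for de novo assembly: lane FASTQ files are
pooled, duplicate reads are collapsed to a unique-sequence list (keeping the
best mean Phred score seen for each sequence), trailing low-quality bases are
trimmed from the 3' end, and donor reference sequences containing ambiguous
bases are removed.

The order of operations follows the assembly workflow this package implements:
reads are uniquified first and the unique list is then trimmed.  Trimming can
re-create duplicate sequences; these are tolerated downstream (the assembler
counts k-mer multiplicity, not read multiplicity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.read_id}: negative Phred score")

    @property
    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return sum(self.qualities) / len(self.qualities)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class UniqueRead:
    """One distinct read sequence with its duplicate count.

    ``best_mean_quality`` is the maximum mean Phred score over all duplicate
    records sharing the sequence; ``qualities`` are the per-base scores of the
    record that achieved it (kept so the unique list can still be 3'-trimmed).
    """

    sequence: str
    best_mean_quality: float
    multiplicity: int
    qualities: Sequence[int] = ()


def uniquify(reads: Iterable[Read]) -> list[UniqueRead]:
    """Collapse duplicate read sequences, keeping the best mean Phred score.

    Returns one :class:`UniqueRead` per distinct sequence string, sorted
    lexicographically by sequence for deterministic output.  Mean quality is
    computed on the untrimmed reads.
    """
    best: dict[str, UniqueRead] = {}
    for read in reads:
        mq = read.mean_quality
        entry = best.get(read.sequence)
        if entry is None:
            best[read.sequence] = UniqueRead(read.sequence, mq, 1, read.qualities)
        else:
            entry.multiplicity += 1
            if mq > entry.best_mean_quality:
                entry.best_mean_quality = mq
                entry.qualities = read.qualities
    return [best[s] for s in sorted(best)]


def trim_3prime(read: Read, max_phred: int = 2) -> Read:
    """Remove the maximal trailing run of bases with Phred <= ``max_phred``.

    Scanning stops at the first base (3' -> 5') above the threshold; internal
    low-quality bases are retained.  May return an empty read, which callers
    should drop before assembly.
    """
    if max_phred < 0:
        raise ValueError("max_phred must be >= 0")
    end = len(read.sequence)
    while end > 0 and read.qualities[end - 1] <= max_phred:
        end -= 1
    return Read(read.read_id, read.sequence[:end], list(read.qualities[:end]))


def filter_ambiguous(
    refs: Iterable[tuple[str, str]],
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split reference sequences into (kept, removed) by ambiguity content.

    Sequences are case-normalized to upper case; a sequence is kept iff it is
    non-empty and consists only of A/C/G/T.  Any other IUPAC code (N, R, Y, ...)
    counts as ambiguous.
    """
    kept: list[tuple[str, str]] = []
    removed: list[tuple[str, str]] = []
    for seq_id, seq in refs:
        norm = seq.upper()
        if not norm:
            logger.warning("reference %s is empty; removed", seq_id)
            removed.append((seq_id, norm))
        elif set(norm) <= {"A", "C", "G", "T"}:
            kept.append((seq_id, norm))
        else:
            removed.append((seq_id, norm))
    return kept, removed


def preprocess_reads(
    reads: Iterable[Read], max_phred: int = 2, min_len: int = 1
) -> tuple[list[UniqueRead], dict[str, int]]:
    """Uniquify pooled reads, trim 3' low-quality tails, drop short leftovers.

    ``min_len`` is typically the assembler k-mer size: reads trimmed below it
    cannot contribute a k-mer and are dropped with a logged count.  Returns the
    surviving unique reads (trimming may re-create duplicate sequences, which
    are tolerated) and a per-stage count report.
    """
    pooled = list(reads)
    unique = uniquify(pooled)
    trimmed: list[UniqueRead] = []
    n_dropped = 0
    for u in unique:
        t = trim_3prime(Read("u", u.sequence, u.qualities), max_phred)
        if len(t) >= min_len:
            trimmed.append(UniqueRead(t.sequence, u.best_mean_quality, u.multiplicity, t.qualities))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("dropped %d unique reads trimmed below %d bp", n_dropped, min_len)
    report = {
        "total_reads": len(pooled),
        "unique_reads": len(unique),
        "trimmed_kept": len(trimmed),
        "trimmed_dropped": n_dropped,
    }
    return trimmed, report


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O (thin Biopython wrappers)
# ---------------------------------------------------------------------------

def _fastq_format(phred_offset: int) -> str:
    if phred_offset == 33:
        return "fastq"
    if phred_offset == 64:
        return "fastq-illumina"
    raise ValueError(f"unsupported Phred offset {phred_offset}; use 33 or 64")


def read_fastq(path, phred_offset: int = 33) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), _fastq_format(phred_offset)):
        reads.append(Read(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]))
    return reads


def write_fastq(reads: Iterable[Read], path, phred_offset: int = 33) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), _fastq_format(phred_offset))


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in records]
    SeqIO.write(seqrecs, str(path), "fasta")
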