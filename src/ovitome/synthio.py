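"""Synthetic ground-truth data: transcriptomes, homolog pools, designs, reads.

Every downstream stage of the pipeline is exercised on data generated here,
with full knowledge of the truth: which gene each read came from, which genes
were planted as differentially expressed and at what fold change, and which
donor sequence descends from which gene.

The generator emulates the statistical structure the analysis assumes:

* a gene universe in which only a small fraction (default 11%) of genes have
  same-species mRNA sequence available ("previously known" genes);
* three donor pools for homology annotation — same-species partial mRNAs and
  error-bearing EST subfragments (known genes only), close-relative mRNAs at
  low nucleotide divergence (default 2%), and distant-relative proteins
  diverged at the amino-acid level (default 10%);
* a 2-group x 4-time-point expression design (standard vs delayed, days
  7/11/14/21, one pooled lane each) with planted fold changes on non-baseline
  lanes and strictly shared means for null genes;
* per-lane reads with Poisson-sampled per-gene counts proportional to
  abundance x length, uniform fragment starts on either strand, a constant
  high base quality with an optional geometric 3' low-quality tail, uniform
  substitution errors, and sequence duplicates.

All outputs are byte-deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .diffexpr import DAYS, GROUPS, group_comparison_name, timecourse_comparison_name
from .preprocess import Read, revcomp, write_fasta, write_fastq

logger = logging.getLogger(__name__)

_DNA = np.frombuffer(b"ACGT", dtype="S1")
_AA20 = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

SPECIES = ("target_mrna", "target_est", "close_mrna", "distant_protein")

DEFAULT_DIVERGENCE = {
    "target_mrna": 0.0,
    "target_est": 0.01,
    "close_mrna": 0.02,
    "distant_protein": 0.10,
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TrueGene:
    gene_id: str
    symbol: str
    sequence: str
    length: int
    known_in_target: bool


@dataclass
class HomologRecord:
    record_id: str
    gene_id: str
    sequence: str
    divergence: float


@dataclass
class HomologSet:
    species: str
    records: list[HomologRecord]


@dataclass(frozen=True)
class LaneSpec:
    lane_id: str
    group: str
    day: int


@dataclass
class ExpressionDesign:
    """Expected transcript abundances for the 8-lane design plus DE truth.

    ``mean_abundance`` holds relative molar abundances (genes x lanes); read
    counts are later drawn proportional to abundance x length within a lane,
    so the design is compositional like real sequencing.  ``de_truth`` lists
    (gene_id, comparison_name, designed fold change) for planted genes; all
    other genes share identical abundances across every lane.
    """

    lanes: list[LaneSpec]
    mean_abundance: pd.DataFrame
    de_truth: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.lanes) != len(GROUPS) * len(DAYS):
            raise ValueError("design must have 8 lanes (2 groups x 4 time points)")

    @property
    def lane_ids(self) -> list[str]:
        return [l.lane_id for l in self.lanes]

    @property
    def group_layout(self) -> dict[str, dict[int, str]]:
        layout: dict[str, dict[int, str]] = {g: {} for g in GROUPS}
        for lane in self.lanes:
            layout[lane.group][lane.day] = lane.lane_id
        return layout

    @property
    def planted_genes(self) -> set[str]:
        return {g for g, _, _ in self.de_truth}


@dataclass
class SimulatedLane:
    lane_id: str
    reads: list[Read]
    truth: dict[str, str]  # read_id -> source gene_id


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _DNA[rng.integers(0, 4, length)].tobytes().decode()


def generate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (600, 1500),
    known_fraction: float = 0.11,
    seed: int = 0,
) -> list[TrueGene]:
    """Random gene universe; exactly round(known_fraction * n_genes) genes are
    flagged as having same-species sequence available."""
    lo, hi = length_range
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if lo < 300 or hi < lo:
        raise ValueError("length_range must satisfy 300 <= lo <= hi")
    if not 0.0 <= known_fraction <= 1.0:
        raise ValueError("known_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, n_genes)
    n_known = round(known_fraction * n_genes)
    known = np.zeros(n_genes, dtype=bool)
    known[rng.choice(n_genes, n_known, replace=False)] = True
    genes = []
    for i in range(n_genes):
        genes.append(
            TrueGene(
                gene_id=f"G{i:04d}",
                symbol=f"SYM{i:04d}",
                sequence=_random_seq(rng, int(lengths[i])),
                length=int(lengths[i]),
                known_in_target=bool(known[i]),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Homolog derivation
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, divergence: float, alphabet: np.ndarray) -> str:
    """Substitute exactly round(divergence * len) distinct positions, always to
    a different letter, so realized divergence equals the request exactly."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_sub = round(divergence * len(seq))
    if n_sub == 0:
        return seq
    pos = rng.choice(len(seq), n_sub, replace=False)
    for p in pos:
        choices = alphabet[alphabet != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def translate_frame1(seq: str) -> str:
    """Standard-code translation of frame +1, stops rendered as '*'."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def derive_homologs(
    genes: Sequence[TrueGene],
    species_divergence: Mapping[str, float] | None = None,
    est_per_gene: int = 2,
    est_length_range: tuple[int, int] = (200, 500),
    seed: int = 0,
) -> dict[str, HomologSet]:
    """Derive the three donor pools (plus ESTs) from the true gene universe.

    Same-species mRNAs and ESTs exist only for ``known_in_target`` genes;
    close-relative mRNAs and distant-relative proteins cover every gene.
    Nucleotide pools are mutated at the nucleotide level; the distant pool is
    translated (frame +1) first and mutated at the amino-acid level.
    """
    div = dict(DEFAULT_DIVERGENCE)
    if species_divergence:
        div.update(species_divergence)
    for sp, d in div.items():
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"divergence for {sp} must lie in [0, 1], got {d}")
    if est_per_gene < 0:
        raise ValueError("est_per_gene must be >= 0")
    rng = np.random.default_rng(seed)
    known = [g for g in genes if g.known_in_target]

    target = HomologSet(
        "target_mrna",
        [
            HomologRecord(f"OAR_{g.gene_id}", g.gene_id,
                          _mutate(rng, g.sequence, div["target_mrna"], _DNA),
                          div["target_mrna"])
            for g in known
        ],
    )
    ests: list[HomologRecord] = []
    lo, hi = est_length_range
    for g in known:
        for j in range(est_per_gene):
            length = int(rng.integers(lo, min(hi, g.length) + 1))
            start = int(rng.integers(0, g.length - length + 1))
            frag = g.sequence[start:start + length]
            ests.append(
                HomologRecord(f"EST_{g.gene_id}_{j}", g.gene_id,
                              _mutate(rng, frag, div["target_est"], _DNA),
                              div["target_est"])
            )
    close = HomologSet(
        "close_mrna",
        [
            HomologRecord(f"BTA_{g.gene_id}", g.gene_id,
                          _mutate(rng, g.sequence, div["close_mrna"], _DNA),
                          div["close_mrna"])
            for g in genes
        ],
    )
    distant = HomologSet(
        "distant_protein",
        [
            HomologRecord(f"MMU_{g.gene_id}", g.gene_id,
                          _mutate(rng, translate_frame1(g.sequence),
                                  div["distant_protein"], _AA20),
                          div["distant_protein"])
            for g in genes
        ],
    )
    return {
        "target_mrna": target,
        "target_est": HomologSet("target_est", ests),
        "close_mrna": close,
        "distant_protein": distant,
    }


# ---------------------------------------------------------------------------
# Expression design
# ---------------------------------------------------------------------------

def make_design(
    genes: Sequence[TrueGene],
    n_de: int = 40,
    fold_change: float = 4.0,
    abundance_sigma: float = 1.0,
    seed: int = 0,
) -> ExpressionDesign:
    """2x4 design with log-normal baseline abundances and planted fold changes.

    Planted genes are drawn from the upper half of the abundance distribution
    (so the count test has something to see), perturbed in exactly one
    non-baseline lane, half up and half down by ``fold_change``.  Each
    perturbation makes the gene truly DE in exactly two of the ten contrasts:
    the between-group contrast at that day and the within-group contrast of
    that day vs day 7.
    """
    if fold_change < 1.0:
        raise ValueError("fold_change must be >= 1")
    n = len(genes)
    if not 0 <= n_de <= n:
        raise ValueError("n_de must lie in [0, n_genes]")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n)
    lanes = [
        LaneSpec(f"{'std' if g == 'standard' else 'del'}_d{d}", g, d)
        for g in GROUPS
        for d in DAYS
    ]
    gene_ids = [g.gene_id for g in genes]
    abundance = pd.DataFrame(
        np.tile(base[:, None], (1, len(lanes))),
        index=gene_ids,
        columns=[l.lane_id for l in lanes],
    )
    eligible = np.argsort(base)[n // 2:]
    planted_idx = rng.choice(eligible, size=n_de, replace=False)
    non_baseline = [l for l in lanes if l.day != 7]
    de_truth: list[tuple[str, str, float]] = []
    for rank, gi in enumerate(sorted(planted_idx)):
        lane = non_baseline[int(rng.integers(0, len(non_baseline)))]
        up = rank % 2 == 0
        factor = fold_change if up else 1.0 / fold_change
        gene_id = gene_ids[gi]
        abundance.loc[gene_id, lane.lane_id] *= factor
        # between-group contrast reads standard vs delayed
        group_fc = factor if lane.group == "standard" else 1.0 / factor
        de_truth.append((gene_id, group_comparison_name(lane.day), group_fc))
        de_truth.append((gene_id, timecourse_comparison_name(lane.group, lane.day), factor))
    return ExpressionDesign(lanes=lanes, mean_abundance=abundance, de_truth=de_truth)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genes: Sequence[TrueGene],
    design: ExpressionDesign,
    read_len: int = 76,
    depth: float = 20_000,
    error_rate: float = 0.005,
    tail_lowq_prob: float = 0.10,
    duplicate_rate: float = 0.05,
    depth_jitter: float = 0.10,
    base_quality: int = 37,
    tail_geom_p: float = 0.25,
    tail_error_rate: float = 0.30,
    seed: int = 0,
) -> list[SimulatedLane]:
    """Simulate the eight lanes of the design.

    Per-gene read counts are Poisson with mean ``lane_depth * abundance *
    length / sum(abundance * length)``; lane depths are drawn uniformly within
    ``depth * (1 +/- depth_jitter)``.  Reads start uniformly on either strand.
    Base quality is constant at ``base_quality``; with probability
    ``tail_lowq_prob`` a read carries a geometric-length 3' tail of quality
    <= 2 whose bases are additionally corrupted at ``tail_error_rate``.
    Uniform substitution errors are applied at ``error_rate``; each read is
    duplicated with probability ``duplicate_rate``.  Every emitted read
    (duplicates included) appears in the lane's truth table.
    """
    min_len = min(g.length for g in genes)
    if read_len > min_len:
        raise ValueError(f"read_len {read_len} exceeds shortest transcript ({min_len} bp)")
    for p, name in [(error_rate, "error_rate"), (tail_lowq_prob, "tail_lowq_prob"),
                    (duplicate_rate, "duplicate_rate")]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    gene_ids = [g.gene_id for g in genes]
    seqs = {g.gene_id: g.sequence for g in genes}
    lengths = np.array([g.length for g in genes], dtype=float)
    lane_rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(len(design.lanes))]

    lanes_out: list[SimulatedLane] = []
    for lane, rng in zip(design.lanes, lane_rngs):
        abund = design.mean_abundance[lane.lane_id].reindex(gene_ids).to_numpy()
        weights = abund * lengths
        probs = weights / weights.sum()
        lane_depth = depth * rng.uniform(1.0 - depth_jitter, 1.0 + depth_jitter)
        counts = rng.poisson(lane_depth * probs)
        reads: list[Read] = []
        truth: dict[str, str] = {}
        serial = 0
        for gid, c in zip(gene_ids, counts):
            if c == 0:
                continue
            src = seqs[gid]
            span = len(src) - read_len
            starts = rng.integers(0, span + 1, c)
            strands = rng.random(c) < 0.5
            for start, minus in zip(starts, strands):
                frag = src[start:start + read_len]
                if minus:
                    frag = revcomp(frag)
                arr = np.frombuffer(frag.encode(), dtype="S1").copy()
                qual = np.full(read_len, base_quality, dtype=int)
                if tail_lowq_prob > 0 and rng.random() < tail_lowq_prob:
                    tail = int(min(rng.geometric(tail_geom_p) + 1, read_len // 2))
                    qual[-tail:] = rng.integers(0, 3, tail)
                    tail_err = np.flatnonzero(rng.random(tail) < tail_error_rate)
                    for p in tail_err:
                        i = read_len - tail + p
                        choices = _DNA[_DNA != arr[i]]
                        arr[i] = choices[rng.integers(0, 3)]
                if error_rate > 0:
                    err = np.flatnonzero(rng.random(read_len) < error_rate)
                    for i in err:
                        choices = _DNA[_DNA != arr[i]]
                        arr[i] = choices[rng.integers(0, 3)]
                read_id = f"{lane.lane_id}:{serial:07d}"
                serial += 1
                reads.append(Read(read_id, arr.tobytes().decode(), qual.tolist()))
                truth[read_id] = gid
        if duplicate_rate > 0:
            dup_mask = rng.random(len(reads)) < duplicate_rate
            for i in np.flatnonzero(dup_mask):
                orig = reads[i]
                dup_id = f"{orig.read_id}:dup"
                reads.append(Read(dup_id, orig.sequence, list(orig.qualities)))
                truth[dup_id] = truth[orig.read_id]
        lanes_out.append(SimulatedLane(lane.lane_id, reads, truth))
    return lanes_out


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_run(
    out_dir,
    genes: Sequence[TrueGene],
    homologs: Mapping[str, HomologSet],
    design: ExpressionDesign,
    lanes: Iterable[SimulatedLane],
    phred_offset: int = 33,
) -> None:
    """Write a full simulated dataset: FASTA references, per-lane FASTQ + truth
    TSV, the design matrix, and the DE truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([(g.gene_id, g.sequence) for g in genes], out / "true_genes.fasta")
    pd.DataFrame(
        [(g.gene_id, g.symbol, g.length, g.known_in_target) for g in genes],
        columns=["gene_id", "symbol", "length", "known_in_target"],
    ).to_csv(out / "true_genes.tsv", sep="\t", index=False)
    for species, hs in homologs.items():
        write_fasta([(r.record_id, r.sequence) for r in hs.records],
                    out / f"{species}.fasta")
    design.mean_abundance.to_csv(out / "design_abundance.tsv", sep="\t")
    pd.DataFrame(design.de_truth, columns=["gene_id", "comparison", "fold_change"]).to_csv(
        out / "de_truth.tsv", sep="\t", index=False
    )
    for lane in lanes:
        write_fastq(lane.reads, out / f"{lane.lane_id}.fastq", phred_offset)
        pd.Series(lane.truth, name="gene_id").rename_axis("read_id").to_csv(
            out / f"{lane.lane_id}.truth.tsv", sep="\t"
        )
    logger.info("wrote simulated run to %s", out)
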