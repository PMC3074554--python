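"""Replicate-free differential expression: RPKM, quantile normalization,
Audic-Claverie testing, Benjamini-Hochberg correction and fold-change gating.

With a single pooled library per condition, no per-gene variance can be
estimated.  The Audic-Claverie test instead asks, for a gene with ``x`` reads
out of ``N1`` in one library and ``y`` out of ``N2`` in another, how surprising
``y`` is under the assumption that both libraries sample the same underlying
Poisson rate.  Conditioning on ``x``, the count ``Y`` follows a negative
binomial:

    P(y | x) = C(x+y, y) * q^y * (1-q)^(x+1),   q = N2 / (N1 + N2)

so the tail probabilities are regularized incomplete beta functions, which is
how this module evaluates them (numerically stable far into the tails, well
past counts of 10^7).  The two-sided p-value is the doubled smaller tail,
capped at 1.

A gene is called differentially expressed in a comparison when the
BH-adjusted p-value is below ``p_threshold`` (default 1e-15) and the fold
change of quantile-normalized RPKM values is at least ``fc_threshold``
(default 2) in either direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUPS = ("standard", "delayed")
DAYS = (7, 11, 14, 21)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def rpkm(count: float, gene_length_bp: float, lane_mapped_total: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be > 0")
    if lane_mapped_total <= 0:
        raise ValueError("lane_mapped_total must be > 0")
    return count / (gene_length_bp / 1_000.0) / (lane_mapped_total / 1_000_000.0)


def rpkm_matrix(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, int] | pd.Series,
    lane_mapped_totals: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM for a genes x lanes count table.

    ``lane_mapped_totals`` defaults to the column sums of ``counts`` (i.e. all
    counted reads in the lane are the mapped reads).
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"missing gene lengths for {missing[:5]}...")
    if lane_mapped_totals is None:
        totals = counts.sum(axis=0)
    else:
        totals = pd.Series(lane_mapped_totals).reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("lane mapped totals must be > 0")
    return counts.div(lengths / 1_000.0, axis=0).div(totals / 1_000_000.0, axis=1)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the same distribution of values.

    Each column's sorted values are replaced by the across-column mean of the
    sorted columns; ranks within a column are preserved.  Ties within a column
    receive the mean of the values they compete for (average-rank convention).
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("quantile normalization needs a rectangular matrix with >= 2 columns")
    n = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    ranks_grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, ranks_grid, mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Audic-Claverie test
# ---------------------------------------------------------------------------

def audic_claverie_logpmf(y, x, n1: float, n2: float):
    """log P(y | x) for the conditional count distribution (log-gamma space)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    q = n2 / (n1 + n2)
    return (
        special.gammaln(x + y + 1)
        - special.gammaln(x + 1)
        - special.gammaln(y + 1)
        + y * np.log(q)
        + (x + 1) * np.log1p(-q)
    )


def audic_claverie_p(x, y, n1: float, n2: float):
    """Two-sided Audic-Claverie p-value for counts ``x`` (of ``n1``) vs ``y`` (of ``n2``).

    Vectorized over ``x`` and ``y``.  Tails of the conditional negative
    binomial are evaluated with the regularized incomplete beta function:
    ``P(Y <= y | x) = I_p(x+1, y+1)`` with ``p = n1/(n1+n2)``.  The two-sided
    p is ``min(1, 2 * min(P(Y <= y), P(Y >= y)))`` and always lies in (0, 1].
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(x.dtype, np.integer) and not np.allclose(x, np.round(x)):
        raise ValueError("x must be integer counts")
    if not np.issubdtype(y.dtype, np.integer) and not np.allclose(y, np.round(y)):
        raise ValueError("y must be integer counts")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be > 0")
    xf = x.astype(float)
    yf = y.astype(float)
    p = n1 / (n1 + n2)
    lower = special.betainc(xf + 1.0, yf + 1.0, p)          # P(Y <= y)
    # P(Y >= y) = 1 - P(Y <= y-1); at y = 0 the upper tail is 1.
    upper = np.where(yf > 0, special.betainc(yf, xf + 1.0, 1.0 - p), 1.0)
    two_sided = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    # Doubled tails can underflow to 0 only for astronomically extreme counts;
    # clamp into (0, 1] to honour the p-value contract.
    two_sided = np.maximum(two_sided, np.finfo(float).tiny)
    if two_sided.ndim == 0:
        return float(two_sided)
    return two_sided


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Comparisons and DE calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Comparison:
    """A two-lane contrast; fold change and count test read lane_x vs lane_y."""

    name: str
    lane_x: str
    lane_y: str


def group_comparison_name(day: int) -> str:
    return f"standard_vs_delayed_d{day}"


def timecourse_comparison_name(group: str, day: int) -> str:
    return f"{group}_d{day}_vs_d7"


def ten_comparisons(group_layout: Mapping[str, Mapping[int, str]]) -> list[Comparison]:
    """The study design's ten contrasts.

    ``group_layout`` maps group name -> {day -> lane id} for the two healing
    groups and four time points.  Returns the four between-group contrasts at
    each day plus, within each group, day 11/14/21 vs day 7.
    """
    comps = []
    for day in DAYS:
        comps.append(
            Comparison(group_comparison_name(day), group_layout["standard"][day],
                       group_layout["delayed"][day])
        )
    for group in GROUPS:
        for day in DAYS[1:]:
            comps.append(
                Comparison(timecourse_comparison_name(group, day),
                           group_layout[group][day], group_layout[group][7])
            )
    return comps


@dataclass
class DEParams:
    """Thresholds for the two-condition DE gate."""

    p_threshold: float = 1e-15
    fc_threshold: float = 2.0
    pseudocount: float = 0.25
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class DEResult:
    """Per-comparison test table plus the across-comparison union."""

    tables: dict[str, pd.DataFrame]
    de_union: set[str] = field(default_factory=set)

    @property
    def de_counts(self) -> dict[str, int]:
        return {name: int(t["is_de"].sum()) for name, t in self.tables.items()}


def call_de(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, int] | pd.Series,
    comparisons: Iterable[Comparison],
    params: DEParams | None = None,
    lane_mapped_totals: Mapping[str, int] | pd.Series | None = None,
) -> DEResult:
    """Run the replicate-free DE gate over a set of two-lane comparisons.

    p-values come from raw counts with lane totals as ``N1``/``N2``;
    BH correction is applied within each comparison; fold changes come from
    quantile-normalized RPKM with a pseudocount on both sides.  A gene is
    called DE when the (adjusted) p is below ``p_threshold`` and
    ``|log2 FC| >= log2(fc_threshold)``.
    """
    params = params or DEParams()
    comparisons = list(comparisons)
    for comp in comparisons:
        for lane in (comp.lane_x, comp.lane_y):
            if lane not in counts.columns:
                raise ValueError(f"comparison {comp.name} references missing lane {lane}")
    if lane_mapped_totals is None:
        totals = counts.sum(axis=0)
    else:
        totals = pd.Series(lane_mapped_totals).reindex(counts.columns)
    expr = rpkm_matrix(counts, gene_lengths, totals)
    expr_qn = quantile_normalize(expr)

    tables: dict[str, pd.DataFrame] = {}
    union: set[str] = set()
    eps = params.pseudocount
    for comp in comparisons:
        x = counts[comp.lane_x].to_numpy()
        y = counts[comp.lane_y].to_numpy()
        n1 = float(totals[comp.lane_x])
        n2 = float(totals[comp.lane_y])
        p_raw = np.atleast_1d(audic_claverie_p(x, y, n1, n2))
        p_bh = bh_adjust(p_raw)
        fc = (expr_qn[comp.lane_x].to_numpy() + eps) / (expr_qn[comp.lane_y].to_numpy() + eps)
        log2_fc = np.log2(fc)
        p_used = p_bh if params.use_adjusted else p_raw
        is_de = (p_used < params.p_threshold) & (
            np.abs(log2_fc) >= np.log2(params.fc_threshold)
        )
        table = pd.DataFrame(
            {
                "gene_id": counts.index,
                "x": x,
                "y": y,
                "N1": n1,
                "N2": n2,
                "p_raw": p_raw,
                "p_bh": p_bh,
                "fold_change": fc,
                "log2_fc": log2_fc,
                "direction": np.where(log2_fc >= 0, "up", "down"),
                "is_de": is_de,
            }
        ).set_index("gene_id")
        tables[comp.name] = table
        union |= set(table.index[table["is_de"]])
    return DEResult(tables=tables, de_union=union)


# ---------------------------------------------------------------------------
# qPCR utility
# ---------------------------------------------------------------------------

def qpcr_relative(ct_target: float, ct_refs: Sequence[float]) -> float:
    """Delta-Ct relative quantification against the mean of reference genes.

    Returns ``2 ** -(ct_target - mean(ct_refs))``; triplicate averaging is
    expected to have been done upstream.
    """
    refs = np.asarray(ct_refs, dtype=float)
    if not np.isfinite(ct_target) or not np.all(np.isfinite(refs)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_target - refs.mean()))
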