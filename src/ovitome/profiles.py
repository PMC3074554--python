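"""Expression profile construction, hierarchical clustering, and Gene
Ontology analysis (hypergeometric baseline + model-based Bayesian gene-set
sampler).

Profiles: for each differentially expressed gene the four time-point values
of each healing group are standardized independently (mean 0, sd 1, sample
sd with n-1) and concatenated, standard group first, into an 8-vector, so
clustering responds to the *shape* of the time course in each group rather
than to absolute expression level.  Zero-variance blocks map to zeros and
are flagged rather than producing NaNs.

GO analysis: annotations are first closed over the ontology's is_a ancestors
(true-path rule).  The baseline is a one-sided hypergeometric over-representation
test per term with BH correction.  The model-based analysis treats each term
as a hidden on/off switch: a gene is predicted "on" iff at least one active
term annotates it, and the observed study flags arise from the prediction
through a false-positive rate ``alpha`` and a false-negative rate ``beta``.
A Metropolis sampler over term-activation states yields each term's marginal
posterior activation probability; terms are reported when that marginal
reaches 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .diffexpr import DAYS, GROUPS, bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileSet:
    """8-vector z-score profiles (genes x [4 standard, 4 delayed])."""

    values: pd.DataFrame
    degenerate_blocks: dict[str, list[str]] = field(default_factory=dict)


def build_profiles(
    rpkm_qn: pd.DataFrame,
    de_genes: Iterable[str],
    group_layout: Mapping[str, Mapping[int, str]],
) -> ProfileSet:
    """Standardize each group's 4 time points per gene and concatenate.

    ``group_layout`` maps group -> {day -> lane id}.  Each 4-block is
    standardized with the sample standard deviation (n-1); constant blocks
    become zeros and the gene is recorded under ``degenerate_blocks``.
    """
    de_genes = list(de_genes)
    columns = []
    blocks = {}
    for group in GROUPS:
        lanes = [group_layout[group][d] for d in DAYS]
        missing = [l for l in lanes if l not in rpkm_qn.columns]
        if missing:
            raise ValueError(f"missing lanes {missing} for group {group}")
        blocks[group] = rpkm_qn.loc[de_genes, lanes].to_numpy(dtype=float)
        columns.extend(f"{group}_d{d}" for d in DAYS)
    out = np.empty((len(de_genes), 8))
    degenerate: dict[str, list[str]] = {}
    for gi, gene in enumerate(de_genes):
        for bi, group in enumerate(GROUPS):
            vals = blocks[group][gi]
            sd = vals.std(ddof=1)
            if sd < 1e-12:
                z = np.zeros(4)
                degenerate.setdefault(gene, []).append(group)
            else:
                z = (vals - vals.mean()) / sd
            out[gi, 4 * bi:4 * bi + 4] = z
    if degenerate:
        logger.info("%d genes had zero-variance blocks (mapped to zeros)", len(degenerate))
    return ProfileSet(
        values=pd.DataFrame(out, index=de_genes, columns=columns),
        degenerate_blocks=degenerate,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    assignments: dict[str, int]
    k: int
    linkage: np.ndarray

    def members(self, label: int) -> list[str]:
        return [g for g, c in self.assignments.items() if c == label]


def hierarchical_cluster(
    profiles: pd.DataFrame, k: int, method: str = "average", metric: str = "euclidean"
) -> ClusterSet:
    """Agglomerative clustering of profile vectors, cut to exactly k clusters.

    Euclidean distance with average linkage by default (ward/complete are
    accepted).  The number of clusters is a free parameter: in this kind of
    time-course analysis it is typically chosen by inspecting the heat map.
    """
    n = len(profiles)
    if k < 1 or k > n:
        raise ValueError(f"k must lie in [1, {n}]")
    values = profiles.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("profiles must be finite")
    Z = hierarchy.linkage(values, method=method, metric=metric)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterSet(
        assignments=dict(zip(profiles.index, (int(l) for l in labels))),
        k=int(labels.max()),
        linkage=Z,
    )


# ---------------------------------------------------------------------------
# Ontology handling
# ---------------------------------------------------------------------------

def load_ontology(path) -> nx.DiGraph:
    """Read an OBO-subset ontology into a child -> parent (is_a) digraph."""
    import obonet

    graph = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    dag.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    return dag


def propagate_annotations(
    dag: nx.DiGraph, direct_annotations: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Close each gene's term set over is_a ancestors (true-path rule)."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("ontology graph contains a cycle")
    ancestors: dict[str, set[str]] = {}

    def anc(term: str) -> set[str]:
        cached = ancestors.get(term)
        if cached is None:
            cached = {term}
            if term in dag:
                cached |= nx.descendants(dag, term)  # edges point child -> parent
            ancestors[term] = cached
        return cached

    return {
        gene: set().union(*(anc(t) for t in terms)) if terms else set()
        for gene, terms in direct_annotations.items()
    }


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

@dataclass
class TermEnrichment:
    term_id: str
    study_count: int
    population_count: int
    p_hypergeom: float = np.nan
    p_bh: float = np.nan
    mgsa_marginal: float = np.nan


def hypergeom_enrichment(
    study_set: set[str],
    population: set[str],
    closed_annotations: Mapping[str, set[str]],
) -> list[TermEnrichment]:
    """One-sided upper-tail hypergeometric test per term, BH-corrected.

    ``study_set`` must be a subset of ``population``; terms with no annotated
    gene in the population are skipped with a warning.
    """
    if not study_set <= population:
        raise ValueError("study set must be a subset of the population")
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population:
        for term in closed_annotations.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study_set:
                term_study[term] = term_study.get(term, 0) + 1
    if not term_pop:
        logger.warning("no term annotates any population gene")
        return []
    N, n = len(population), len(study_set)
    results = []
    for term in sorted(term_pop):
        K = term_pop[term]
        k = term_study.get(term, 0)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(TermEnrichment(term, k, K, p_hypergeom=min(p, 1.0)))
    adjusted = bh_adjust([max(r.p_hypergeom, 5e-324) for r in results])
    for r, padj in zip(results, adjusted):
        r.p_bh = float(padj)
    return results


# ---------------------------------------------------------------------------
# Model-based gene set analysis
# ---------------------------------------------------------------------------

@dataclass
class MGSAParams:
    alpha: float = 0.10            # false-positive rate: P(obs on | hidden off)
    beta: float = 0.25             # false-negative rate: P(obs off | hidden on)
    prior_p: float | None = None   # term activation prior; default 1/n_terms
    iterations: int = 50_000
    burn_in_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.prior_p is not None and not 0.0 < self.prior_p < 1.0:
            raise ValueError("prior_p must lie in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _mgsa_structures(
    study_flags: Mapping[str, bool], closed_annotations: Mapping[str, set[str]]
) -> tuple[list[str], list[np.ndarray], np.ndarray]:
    genes = sorted(study_flags)
    terms = sorted({t for g in genes for t in closed_annotations.get(g, ())})
    if not terms:
        raise ValueError("no terms annotate any gene in the study universe")
    gene_pos = {g: i for i, g in enumerate(genes)}
    term_genes = []
    for t in terms:
        members = [gene_pos[g] for g in genes if t in closed_annotations.get(g, ())]
        term_genes.append(np.array(members, dtype=np.int64))
    observed = np.array([bool(study_flags[g]) for g in genes])
    return terms, term_genes, observed


def _gene_loglik_tables(observed: np.ndarray, alpha: float, beta: float):
    # log-likelihood of each gene's observation given hidden state off/on
    ll_off = np.where(observed, np.log(alpha), np.log1p(-alpha))
    ll_on = np.where(observed, np.log1p(-beta), np.log(beta))
    return ll_off, ll_on


def mgsa(
    study_flags: Mapping[str, bool],
    closed_annotations: Mapping[str, set[str]],
    params: MGSAParams | None = None,
) -> dict[str, float]:
    """Posterior marginal activation probability per term (Metropolis sampler).

    ``study_flags`` gives the observed on/off state of every gene in the
    analysis universe (e.g. "differentially expressed or not").  A gene's
    hidden state is on iff any active term annotates it; observations flow
    through the alpha/beta noise model.  Single-term toggle proposals;
    marginals are averaged over post-burn-in samples.  Reproducible given
    ``params.seed``.
    """
    params = params or MGSAParams()
    terms, term_genes, observed = _mgsa_structures(study_flags, closed_annotations)
    T = len(terms)
    prior = params.prior_p if params.prior_p is not None else 1.0 / T
    log_prior_on = np.log(prior) - np.log1p(-prior)
    ll_off, ll_on = _gene_loglik_tables(observed, params.alpha, params.beta)
    delta_gene = ll_on - ll_off   # loglik change when a gene turns on

    rng = np.random.default_rng(params.seed)
    active = np.zeros(T, dtype=bool)
    n_active_terms = np.zeros(len(observed), dtype=np.int64)  # per gene
    loglik = float(ll_off.sum())
    burn_in = int(params.iterations * params.burn_in_fraction)
    marginal_sums = np.zeros(T)
    n_samples = 0
    proposals = rng.integers(0, T, params.iterations)
    unif = rng.random(params.iterations)
    for it in range(params.iterations):
        t = int(proposals[it])
        members = term_genes[t]
        if active[t]:
            # deactivate: genes whose active count drops to zero flip off
            flips = members[n_active_terms[members] == 1]
            delta_ll = -float(delta_gene[flips].sum())
            delta_lp = -log_prior_on
        else:
            flips = members[n_active_terms[members] == 0]
            delta_ll = float(delta_gene[flips].sum())
            delta_lp = log_prior_on
        if np.log(unif[it]) < delta_ll + delta_lp:
            if active[t]:
                n_active_terms[members] -= 1
                active[t] = False
            else:
                n_active_terms[members] += 1
                active[t] = True
            loglik += delta_ll
        if it >= burn_in:
            marginal_sums += active
            n_samples += 1
    marginals = marginal_sums / max(n_samples, 1)
    return dict(zip(terms, (float(m) for m in marginals)))


def mgsa_exact(
    study_flags: Mapping[str, bool],
    closed_annotations: Mapping[str, set[str]],
    params: MGSAParams | None = None,
) -> dict[str, float]:
    """Exact posterior marginals by enumerating all 2^T activation states.

    Only feasible for small term systems (T <= ~20); serves as the reference
    for validating the sampler.
    """
    params = params or MGSAParams()
    terms, term_genes, observed = _mgsa_structures(study_flags, closed_annotations)
    T = len(terms)
    if T > 20:
        raise ValueError("exact enumeration is limited to 20 terms")
    prior = params.prior_p if params.prior_p is not None else 1.0 / T
    ll_off, ll_on = _gene_loglik_tables(observed, params.alpha, params.beta)
    log_weights = np.empty(2 ** T)
    for state in range(2 ** T):
        n_active = np.zeros(len(observed), dtype=np.int64)
        n_on = 0
        for t in range(T):
            if state >> t & 1:
                n_active[term_genes[t]] += 1
                n_on += 1
        hidden_on = n_active > 0
        ll = float(np.where(hidden_on, ll_on, ll_off).sum())
        ll += n_on * np.log(prior) + (T - n_on) * np.log1p(-prior)
        log_weights[state] = ll
    log_weights -= log_weights.max()
    weights = np.exp(log_weights)
    weights /= weights.sum()
    marginals = {}
    for t in range(T):
        mask = np.array([bool(state >> t & 1) for state in range(2 ** T)])
        marginals[terms[t]] = float(weights[mask].sum())
    return marginals


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report_clusters(
    clusters: ClusterSet,
    enrichments: Mapping[int, Sequence[TermEnrichment]],
    max_terms: int = 3,
    marginal_min: float = 0.5,
) -> dict[int, list[TermEnrichment]]:
    """Per cluster: terms with marginal >= ``marginal_min``, sorted by
    annotated-gene count descending, truncated to ``max_terms``."""
    report = {}
    for label in sorted(set(clusters.assignments.values())):
        terms = enrichments.get(label, ())
        qualifying = [t for t in terms if t.mgsa_marginal >= marginal_min]
        qualifying.sort(key=lambda t: (-t.study_count, t.term_id))
        report[label] = qualifying[:max_terms]
    return report


def term_ratio_ttest(
    rpkm_std: pd.DataFrame, rpkm_del: pd.DataFrame, genes: Iterable[str],
    pseudocount: float = 0.25,
) -> tuple[float, float]:
    """Mean log2 standard/delayed expression ratio over a gene set and the
    one-sample t-test p-value against a zero mean (thin reporting utility)."""
    genes = [g for g in genes if g in rpkm_std.index]
    if not genes:
        raise ValueError("no genes from the set are present in the matrix")
    ratios = np.log2(
        (rpkm_std.loc[genes].to_numpy() + pseudocount)
        / (rpkm_del.loc[genes].to_numpy() + pseudocount)
    ).ravel()
    t, p = stats.ttest_1samp(ratios, 0.0)
    return float(ratios.mean()), float(p)
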