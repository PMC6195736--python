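"""Pairwise gene-similarity testing and clustering under Bonferroni control.

Two genes are compared through three tests of the null hypothesis that
they share a substitution law for per-site counts:

1. Kruskal-Wallis on the two genes' per-site substitution counts.
2. A likelihood-ratio test of two separate intercept-only negative
   binomial fits against a single pooled fit (2 df: separate mean and
   dispersion vs pooled).
3. A Wald test of the gene-indicator coefficient in a pooled negative
   binomial regression.

Genes are joined only if *all three* p-values clear a Bonferroni-corrected
threshold alpha_total / C(n_genes, 2); for the 13 mtDNA protein-coding
genes this is 0.05/78.  Clusters are the connected components of the
similarity graph; components that are not cliques are reported, since the
pairwise rule does not by itself guarantee transitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .glm import PredictorSpec, fit_count_glm, glr_test, kruskal_wallis
from scipy import stats


@dataclass(frozen=True)
class PairTestResult:
    gene_a: str
    gene_b: str
    p_kw: float
    p_glr: float
    p_reg: float

    def min_p(self) -> float:
        return min(self.p_kw, self.p_glr, self.p_reg)


@dataclass
class ClusteringConfig:
    n_genes: int
    alpha_total: float = 0.05

    @property
    def n_pairs(self) -> int:
        return comb(self.n_genes, 2)

    @property
    def alpha(self) -> float:
        return self.alpha_total / self.n_pairs


def pair_tests(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    gene_a: str = "a",
    gene_b: str = "b",
) -> PairTestResult:
    """Run the three similarity tests on two genes' per-site counts."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each gene needs at least two sites")
    pooled = np.concatenate([a, b])
    if np.all(pooled == 0):
        return PairTestResult(gene_a, gene_b, 1.0, 1.0, 1.0)

    p_kw = kruskal_wallis([a, b])

    empty = PredictorSpec()
    fit_a = fit_count_glm(pd.DataFrame({"count": a}), "count", empty, family="negbin")
    fit_b = fit_count_glm(pd.DataFrame({"count": b}), "count", empty, family="negbin")
    fit_pool = fit_count_glm(
        pd.DataFrame({"count": pooled}), "count", empty, family="negbin"
    )
    if fit_a.converged and fit_b.converged and fit_pool.converged:
        # separate fits add one mean and one dispersion over the pooled fit
        stat = 2.0 * (
            fit_a.log_likelihood + fit_b.log_likelihood - fit_pool.log_likelihood
        )
        p_glr = float(stats.chi2.sf(max(stat, 0.0), 2))
    else:
        p_glr = np.nan

    df = pd.DataFrame(
        {
            "count": pooled,
            "gene": [gene_a] * len(a) + [gene_b] * len(b),
        }
    )
    fit_reg = fit_count_glm(
        df, "count", PredictorSpec(categorical=["gene"]), family="negbin"
    )
    indicator = [c for c in fit_reg.coefficients.index if c.startswith("gene[")]
    if fit_reg.converged and indicator and fit_reg.bse is not None:
        coef = float(fit_reg.coefficients[indicator[0]])
        se = float(fit_reg.bse[indicator[0]])
        z = coef / se if se > 0 else 0.0
        p_reg = float(2 * stats.norm.sf(abs(z)))
    else:
        p_reg = np.nan
    return PairTestResult(gene_a, gene_b, p_kw, p_glr, p_reg)


def all_pair_tests(
    per_gene_counts: Mapping[str, Sequence[float]]
) -> list[PairTestResult]:
    genes = sorted(per_gene_counts)
    return [
        pair_tests(per_gene_counts[a], per_gene_counts[b], a, b)
        for a, b in combinations(genes, 2)
    ]


@dataclass
class ClusterReport:
    clusters: dict[str, str]  # gene -> cluster label
    non_clique_components: list[frozenset[str]] = field(default_factory=list)
    rejected: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return sorted(set(self.clusters.values()))


def cluster_genes(
    pair_results: Sequence[PairTestResult], config: ClusteringConfig
) -> ClusterReport:
    """Cluster genes: join a pair iff every test's p-value is >= alpha.

    Clusters are connected components of the similarity graph; component
    labels join the member gene names with ``+``.  A NaN p-value (a test
    that could not be computed) is treated as a rejection, so such pairs
    are never joined silently.
    """
    genes = sorted(
        {r.gene_a for r in pair_results} | {r.gene_b for r in pair_results}
    )
    if comb(len(genes), 2) != len(pair_results):
        raise ValueError("pair_results must cover every gene pair exactly once")
    alpha = config.alpha
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    rejected: dict[tuple[str, str], list[int]] = {}
    for res in pair_results:
        ps = [res.p_kw, res.p_glr, res.p_reg]
        rej = [i + 1 for i, p in enumerate(ps) if not (p >= alpha)]
        key = tuple(sorted((res.gene_a, res.gene_b)))
        rejected[key] = rej
        if not rej:
            graph.add_edge(res.gene_a, res.gene_b)
    clusters: dict[str, str] = {}
    non_clique = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        label = "+".join(members)
        for gene in members:
            clusters[gene] = label
        k = len(members)
        if k > 1 and graph.subgraph(component).number_of_edges() < comb(k, 2):
            non_clique.append(frozenset(component))
    return ClusterReport(clusters, non_clique, rejected)


def rejection_matrix(report: ClusterReport) -> pd.DataFrame:
    """Upper-triangular matrix of rejected test indices per pair (blank = similar)."""
    genes = sorted({g for pair in report.rejected for g in pair})
    mat = pd.DataFrame("", index=genes, columns=genes)
    for (a, b), rej in report.rejected.items():
        mat.loc[a, b] = ",".join(map(str, rej))
    return mat


def write_cluster_assignment(report: ClusterReport, path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(report.clusters), "cluster": list(report.clusters.values())}
    ).sort_values("gene").to_csv(path, sep="\t", index=False)
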