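"""Collapse probe-level DNA-methylation beta values to one series per gene.

Array platforms report several CpG probes per gene, and promoter probes
(whose methylation silences the gene) behave differently from gene-body
probes.  The collapse rule implemented here:

1. keep probes whose across-sample variance exceeds 0.01 (strict),
2. cluster the surviving probes by Spearman correlation distance
   (1 - rho) with average-linkage hierarchical clustering, cut into two
   clusters by default,
3. for each cluster take the per-sample median beta and correlate it
   (Spearman) with the gene's expression; the cluster with the most
   negative correlation represents the gene's methylation.  If no cluster
   correlates negatively the gene's methylation is flagged undefined.

A binary methylated/unmethylated status follows by thresholding the
representative beta (default cutoff 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class GeneMethylation:
    """Representative methylation series for one gene."""

    gene_id: str
    representative: pd.Series | None  # per-sample median beta of the chosen cluster
    probes: list[str] = field(default_factory=list)
    rho: float = float("nan")  # Spearman vs expression for the chosen cluster
    defined: bool = False
    cluster_rhos: dict[int, float] = field(default_factory=dict)


def filter_probes(matrix: pd.DataFrame, min_variance: float = 0.01) -> pd.DataFrame:
    """Keep probes (rows) with across-sample variance strictly above ``min_variance``."""
    if matrix.shape[1] < 2:
        raise ValueError("variance filtering needs at least 2 samples")
    var = matrix.var(axis=1, ddof=1)
    return matrix.loc[var > min_variance]


def probe_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation distance (1 - rho) between probe beta vectors."""
    if matrix.shape[0] < 2:
        raise ValueError("probe distance needs at least 2 probes")
    if matrix.shape[1] < 3:
        raise ValueError("probe distance needs at least 3 samples")
    if (matrix.var(axis=1, ddof=1) == 0).any():
        raise ValueError("zero-variance probe reached probe_distance; filter probes first")
    rho = stats.spearmanr(matrix.T).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-probe case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


def cluster_probes(distance: pd.DataFrame, n_clusters: int = 2) -> pd.Series:
    """Average-linkage hierarchical clustering cut into ``n_clusters``.

    Returns integer labels (1-based) indexed by probe.  A single probe is
    its own singleton cluster.  Ties are resolved deterministically by
    scipy under a fixed input order.
    """
    probes = distance.index
    if len(probes) == 1:
        return pd.Series([1], index=probes)
    condensed = squareform(distance.to_numpy(), checks=False)
    z = linkage(condensed, method="average")
    labels = fcluster(z, t=min(n_clusters, len(probes)), criterion="maxclust")
    return pd.Series(labels, index=probes)


def select_negative_cluster(
    clusters: pd.Series,
    matrix: pd.DataFrame,
    expression: pd.Series,
    gene_id: str = "",
) -> GeneMethylation:
    """Choose the probe cluster whose median beta anticorrelates with expression.

    Samples are intersected between the beta matrix columns and the
    expression index (>= 3 required).  Per cluster the per-sample median
    beta is correlated (Spearman) with expression; the most negative rho
    wins, ties broken by larger cluster then input order.  With no
    negatively correlated cluster the result is flagged undefined.
    """
    samples = [s for s in matrix.columns if s in set(expression.index)]
    if len(samples) < 3:
        raise ValueError(f"gene {gene_id or '?'}: fewer than 3 samples shared between beta and expression")
    expr = expression.loc[samples].to_numpy(dtype=float)
    first_seen = {}
    for i, p in enumerate(clusters.index):
        first_seen.setdefault(int(clusters[p]), i)
    stats_per_cluster = []
    for label in sorted(set(int(v) for v in clusters.values)):
        probes = [p for p in clusters.index if int(clusters[p]) == label]
        med = matrix.loc[probes, samples].median(axis=0)
        rho = float(stats.spearmanr(med.to_numpy(), expr).statistic)
        stats_per_cluster.append((label, probes, med, rho))
    # most negative rho; ties -> larger cluster -> earliest input order
    best = min(stats_per_cluster, key=lambda t: (t[3], -len(t[1]), first_seen[t[0]]))
    label, probes, med, rho = best
    cluster_rhos = {lab: r for lab, _, _, r in stats_per_cluster}
    if not (rho < 0):  # NaN rho also fails
        return GeneMethylation(gene_id=gene_id, representative=None, probes=[], rho=rho,
                               defined=False, cluster_rhos=cluster_rhos)
    return GeneMethylation(gene_id=gene_id, representative=med, probes=probes, rho=rho,
                           defined=True, cluster_rhos=cluster_rhos)


def methylation_status(gene_meth: GeneMethylation | pd.Series, beta_cutoff: float = 0.3) -> pd.Series:
    """Binary methylated status: representative beta >= cutoff."""
    if isinstance(gene_meth, GeneMethylation):
        if not gene_meth.defined or gene_meth.representative is None:
            raise ValueError(f"gene {gene_meth.gene_id}: methylation undefined, no status available")
        rep = gene_meth.representative
    else:
        rep = gene_meth
    return rep >= beta_cutoff


def collapse_gene(
    gene_id: str,
    matrix: pd.DataFrame,
    expression: pd.Series,
    min_variance: float = 0.01,
    n_clusters: int = 2,
) -> GeneMethylation:
    """Variance filter + Spearman-distance clustering + negative-cluster rule for one gene."""
    kept = filter_probes(matrix, min_variance)
    if kept.empty:
        return GeneMethylation(gene_id=gene_id, representative=None, defined=False)
    if len(kept) == 1:
        clusters = pd.Series([1], index=kept.index)
    else:
        clusters = cluster_probes(probe_distance(kept), n_clusters)
    return select_negative_cluster(clusters, kept, expression, gene_id=gene_id)


def collapse_matrix(
    beta: pd.DataFrame,
    probe_map: pd.DataFrame,
    expression: pd.DataFrame,
    min_variance: float = 0.01,
    n_clusters: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse a probes x samples matrix to genes x samples.

    ``probe_map`` maps each probe to at most one gene (columns ``probe``,
    ``gene``); genes absent from the expression matrix are skipped.
    Returns the gene-level beta table and a provenance table (chosen
    probes, rho, defined flag) per gene.
    """
    reps = {}
    prov = []
    for gene, sub in probe_map.groupby("gene", sort=True):
        if gene not in expression.index:
            continue
        probes = [p for p in sub["probe"] if p in beta.index]
        if not probes:
            continue
        gm = collapse_gene(gene, beta.loc[probes], expression.loc[gene],
                           min_variance=min_variance, n_clusters=n_clusters)
        prov.append(
            {
                "gene": gene,
                "defined": gm.defined,
                "rho": gm.rho,
                "probes": ";".join(gm.probes),
            }
        )
        if gm.defined:
            reps[gene] = gm.representative
    gene_beta = pd.DataFrame(reps).T
    return gene_beta, pd.DataFrame(prov)
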