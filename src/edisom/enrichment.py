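"""Per-cluster over-representation analysis of flat gene-set terms.

For each (cluster, term) pair the overlap is scored with the upper tail of
the hypergeometric distribution — the probability of drawing at least the
observed number of term genes when sampling the cluster from the background
universe — and p-values are Benjamini–Hochberg adjusted within each
(cluster, namespace) family.  The default reporting rule flags terms with
an overlap of at least three transcripts at FDR < 0.05; all scored rows are
retained in the output so the reporting filter can be re-applied later.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterPartition
from .io import AnnotationSet

__all__ = ["hypergeom_tail", "bh_adjust", "enrich_clusters", "ENRICHMENT_COLUMNS"]

ENRICHMENT_COLUMNS = [
    "cluster",
    "namespace",
    "term_id",
    "description",
    "overlap",
    "cluster_size",
    "term_size",
    "background_size",
    "p_value",
    "q_value",
    "reported",
]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` background genes of which ``K`` carry the term; ``n`` genes are
    drawn (the cluster); ``k`` is the observed overlap.
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside 0..min(K={K}, n={n})")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    Equivalent to sorting p ascending, taking ``q_(i) = min_{j>=i} p_(j)*m/j``
    clipped at 1, and mapping back.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_clusters(
    p: ClusterPartition,
    ann: AnnotationSet,
    background: set[str],
    min_overlap: int = 3,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Score every cluster x term pair against a background universe.

    For each cluster, ``n`` is the cluster's annotated-background overlap,
    ``K`` the term's background membership, ``k`` their intersection and
    ``N`` the background size.  BH adjustment runs within each cluster
    (one namespace per call), and a row is flagged ``reported`` when
    ``k >= min_overlap`` and ``q < fdr``.  All rows are returned.
    """
    if not background:
        raise ValueError("background gene universe is empty")
    if min_overlap < 0:
        raise ValueError("min_overlap must be >= 0")
    background = set(background)
    N = len(background)

    cluster_genes: dict[int, set[str]] = {k: set() for k in range(1, p.n_clusters + 1)}
    for gene, k in p.gene_cluster.items():
        cluster_genes[k].add(gene)

    rows = []
    for cl in range(1, p.n_clusters + 1):
        genes = cluster_genes[cl] & background
        n = len(genes)
        cluster_rows = []
        for term_id, (description, members) in ann.terms.items():
            term_bg = members & background
            K = len(term_bg)
            if K == 0:
                continue
            k = len(genes & term_bg)
            cluster_rows.append(
                {
                    "cluster": cl,
                    "namespace": ann.namespace,
                    "term_id": term_id,
                    "description": description,
                    "overlap": k,
                    "cluster_size": n,
                    "term_size": K,
                    "background_size": N,
                    "p_value": hypergeom_tail(k, K, n, N),
                }
            )
        if cluster_rows:
            q = bh_adjust([r["p_value"] for r in cluster_rows])
            for r, qv in zip(cluster_rows, q):
                r["q_value"] = float(qv)
                r["reported"] = bool(r["overlap"] >= min_overlap and qv < fdr)
            rows.extend(cluster_rows)

    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
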