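"""LincRNA-mRNA co-expression network and function annotation.

Gene pairs are tested with the Pearson correlation and Fisher's asymptotic
z-test, Bonferroni-adjusted over all tested pairs; an edge is kept when the
adjusted p-value is below alpha *and* the correlation ranks in the top or
bottom 5% of all tested pairs.  LincRNAs are annotated two ways: hub-based
(a lincRNA with at least 10 mRNA partners inherits the GO enrichment of its
partner subnet) and module-based (Markov clustering of the network; a module
with at least 10 coding members and one lincRNA inherits its members'
enrichment).  GO enrichment is the hypergeometric upper tail with
Benjamini-Hochberg FDR control at 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class NetworkModule:
    module_id: str
    members: frozenset[str]


def variance_filter(matrix: pd.DataFrame, keep_fraction: float = 0.75) -> pd.DataFrame:
    """Keep genes whose expression variance ranks in the top fraction.

    The number kept is ceil(keep_fraction * n); ties are broken by gene id
    for determinism.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    n_keep = math.ceil(keep_fraction * len(matrix))
    variances = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (-variances[g], g))
    keep = sorted(order[:n_keep], key=list(matrix.index).index)
    return matrix.loc[keep]


def pcc_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with Fisher's asymptotic z-test p-value.

    z = atanh(r); p = 2 * (1 - Phi(|z| * sqrt(n - 3))).  |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    z = np.arctanh(r)
    p = 2.0 * stats.norm.sf(abs(z) * math.sqrt(n - 3))
    return r, float(p)


def build_network(
    matrix: pd.DataFrame,
    gene_types: pd.Series,
    alpha: float = 0.05,
    rank_fraction: float = 0.05,
) -> nx.Graph:
    """Co-expression network over a (variance-filtered) RPKM matrix.

    All gene pairs are tested; p_adj = min(1, m * p_raw) with m the number
    of tested pairs; an edge is retained iff p_adj < alpha and its
    correlation lies in the top or bottom ``rank_fraction`` of all tested
    correlations (exactly floor(rank_fraction * m) pairs per tail, ties
    broken by pair id).  Only nodes incident to an edge are included.
    """
    genes = list(matrix.index)
    X = matrix.to_numpy(dtype=float)
    n_tissues = X.shape[1]
    sd = X.std(axis=1)
    usable = sd > 0
    if not usable.all():
        logger.info("skipping %d zero-variance genes", int((~usable).sum()))
    idx = np.flatnonzero(usable)
    R = np.corrcoef(X[idx]) if len(idx) > 1 else np.zeros((len(idx), len(idx)))
    iu, ju = np.triu_indices(len(idx), k=1)
    r = np.clip(R[iu, ju], -1.0, 1.0)
    m = len(r)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    p_raw = 2.0 * stats.norm.sf(np.abs(z) * math.sqrt(max(n_tissues - 3, 1)))
    p_raw[np.abs(r) == 1.0] = 0.0
    p_adj = np.minimum(1.0, m * p_raw)

    pair_ids = [(genes[idx[a]], genes[idx[b]]) for a, b in zip(iu, ju)]
    k_tail = int(math.floor(rank_fraction * m))
    order = sorted(range(m), key=lambda t: (r[t], pair_ids[t]))
    bottom = set(order[:k_tail])
    top = set(order[m - k_tail :]) if k_tail else set()

    G = nx.Graph(n_tested=m, alpha=alpha, rank_fraction=rank_fraction)
    for t in range(m):
        if p_adj[t] < alpha and (t in top or t in bottom):
            a, b = pair_ids[t]
            G.add_edge(a, b, pcc=float(r[t]), p_raw=float(p_raw[t]), p_adj=float(p_adj[t]))
    for node in G.nodes:
        G.nodes[node]["gene_type"] = str(gene_types.get(node, "mRNA"))
    return G


def find_hubs(G: nx.Graph, min_partners: int = 10) -> dict[str, list[str]]:
    """Hub lincRNAs: at least ``min_partners`` distinct mRNA neighbors.

    Returns hub -> sorted mRNA partner list (lincRNA neighbors don't count).
    """
    hubs: dict[str, list[str]] = {}
    for node, data in G.nodes(data=True):
        if data.get("gene_type") != "lincRNA":
            continue
        partners = sorted(
            nb for nb in G.neighbors(node)
            if G.nodes[nb].get("gene_type") == "mRNA"
        )
        if len(partners) >= min_partners:
            hubs[node] = partners
    return hubs


def mcl_cluster(
    G: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    prune_eps: float = 1e-6,
    tol: float = 1e-8,
    min_coding: int = 10,
    min_linc: int = 1,
) -> tuple[list[NetworkModule], list[NetworkModule], bool]:
    """Markov clustering of the unweighted network with self-loops.

    Alternates expansion (matrix squaring) and inflation (entry-wise power,
    column renormalization, pruning of entries below ``prune_eps``) until
    the column-wise change drops below ``tol`` or ``max_iter`` is reached.
    Modules are the connected components of the converged matrix's support.

    Returns (all modules, reported modules, converged); a module is
    *reported* when it has at least ``min_coding`` protein-coding members
    and at least ``min_linc`` lincRNAs.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(G.nodes)
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    M = np.eye(n)
    for a, b in G.edges:
        M[index[a], index[b]] = 1.0
        M[index[b], index[a]] = 1.0
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = M @ M
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune_eps] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - M).max() < tol:
            M = inflated
            converged = True
            break
        M = inflated
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(M)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    modules: list[NetworkModule] = []
    comps = sorted(nx.connected_components(support), key=lambda c: sorted(c)[0])
    for k, comp in enumerate(comps, start=1):
        members = frozenset(nodes[i] for i in comp)
        modules.append(NetworkModule(f"module{k:03d}", members))
    reported = [
        mod
        for mod in modules
        if sum(1 for g in mod.members if G.nodes[g].get("gene_type") == "mRNA")
        >= min_coding
        and sum(1 for g in mod.members if G.nodes[g].get("gene_type") == "lincRNA")
        >= min_linc
    ]
    return modules, reported, converged


def go_enrichment(
    gene_set: set[str],
    background: set[str],
    go_annotation: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric GO-term over-representation with BH-FDR.

    For each term annotated in the set: p = P(X >= k) with X hypergeometric
    (N = background size, K = annotated in background, n = set size).
    Returns a term-per-row table with p_raw, p_fdr and a significance flag
    (p_fdr < alpha).
    """
    if not background:
        raise ValueError("empty background")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    N, n = len(background), len(gene_set)
    term_K: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for gene in background:
        for term in go_annotation.get(gene, ()):
            term_K[term] = term_K.get(term, 0) + 1
            if gene in gene_set:
                term_k[term] = term_k.get(term, 0) + 1
    terms = sorted(term_k)  # only terms observed in the set are testable
    if not terms:
        return pd.DataFrame(
            columns=["go_term", "k", "K", "n", "N", "p_raw", "p_fdr", "significant"]
        )
    rows = []
    for term in terms:
        k, K = term_k[term], term_K[term]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["go_term", "k", "K", "n", "N", "p_raw"])
    _, p_fdr, _, _ = multipletests(df["p_raw"], method="fdr_bh")
    df["p_fdr"] = p_fdr
    df["significant"] = df["p_fdr"] < alpha
    return df


def annotate_lincRNAs(
    G: nx.Graph,
    hubs: dict[str, list[str]],
    reported_modules: list[NetworkModule],
    go_annotation: dict[str, set[str]],
    background: set[str] | None = None,
    alpha: float = 0.05,
) -> tuple[dict[str, set[str]], dict]:
    """Per-lincRNA GO assignments by the hub- and module-based methods.

    A hub lincRNA inherits the significant terms of its mRNA partner
    subnet; a module lincRNA inherits the significant terms of its module's
    mRNA members.  Returns (lincRNA -> terms, summary) where the summary
    counts lincRNAs annotated per method and their overlap.
    """
    background = background or set(G.nodes)
    hub_terms: dict[str, set[str]] = {}
    for linc, partners in sorted(hubs.items()):
        enr = go_enrichment(set(partners), background, go_annotation, alpha)
        sig = set(enr.loc[enr["significant"], "go_term"])
        if sig:
            hub_terms[linc] = sig
    module_terms: dict[str, set[str]] = {}
    for mod in reported_modules:
        mrnas = {g for g in mod.members if G.nodes[g].get("gene_type") == "mRNA"}
        lincs = {g for g in mod.members if G.nodes[g].get("gene_type") == "lincRNA"}
        enr = go_enrichment(mrnas, background, go_annotation, alpha)
        sig = set(enr.loc[enr["significant"], "go_term"])
        if sig:
            for linc in lincs:
                module_terms.setdefault(linc, set()).update(sig)
    combined: dict[str, set[str]] = {}
    for d in (hub_terms, module_terms):
        for linc, terms in d.items():
            combined.setdefault(linc, set()).update(terms)
    summary = {
        "n_hub_lincRNAs": len(hubs),
        "n_module_lincRNAs": len(
            {
                g
                for mod in reported_modules
                for g in mod.members
                if G.nodes[g].get("gene_type") == "lincRNA"
            }
        ),
        "n_hub_annotated": len(hub_terms),
        "n_module_annotated": len(module_terms),
        "n_overlap_annotated": len(set(hub_terms) & set(module_terms)),
        "n_annotated": len(combined),
    }
    return combined, summary
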