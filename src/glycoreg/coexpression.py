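"""Per-tissue pairwise co-expression edges, cross-tissue aggregation, and
anti-correlated cluster detection.

Correlations are Pearson r computed across samples within each tissue, with
p-values from the t transform of r on n-2 degrees of freedom. A pair supports
an edge when |r| exceeds the threshold (0.8 by default) at p below 0.05;
aggregation counts, per pair and sign, the number of tissues supporting the
edge. Anti-correlated clusters in a single tissue are the connected
components of the positive-edge subgraph, with the reported pair of clusters
maximizing the number of negative edges between them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from glycoreg.simulate import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationEdge:
    """One gene-pair correlation within one tissue (gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    tissue: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort before gene_b")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t transform of Pearson r with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def tissue_correlations(matrix: ExpressionMatrix, genes: list[str] | None = None,
                        min_samples: int = 10,
                        log2_transform: bool = False) -> list[CorrelationEdge]:
    """All unordered gene-pair Pearson correlations, computed per tissue.

    Tissues with fewer than ``min_samples`` samples are skipped; genes with
    constant expression within a tissue are dropped from that tissue's pairs
    (warned). With ``log2_transform`` correlations are computed on
    log2(x + 1) — anti-correlated regulation is multiplicative on the
    abundance scale, so it is only linear (and detectable as negative
    Pearson r) after the log.
    """
    genes = list(genes) if genes is not None else list(matrix.values.index)
    missing = set(genes) - set(matrix.values.index)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]}")
    edges: list[CorrelationEdge] = []
    for tissue, ann in matrix.samples.groupby("tissue", sort=True):
        n = len(ann)
        if n < min_samples:
            logger.warning("tissue %s skipped: %d < %d samples", tissue, n, min_samples)
            continue
        sub = matrix.values.loc[genes, ann.index].to_numpy()
        if log2_transform:
            sub = np.log2(sub + 1.0)
        sd = sub.std(axis=1)
        keep = sd > 0
        if not keep.all():
            dropped = [g for g, k in zip(genes, keep) if not k]
            logger.warning("tissue %s: constant genes skipped: %s", tissue, dropped)
        kept_genes = [g for g, k in zip(genes, keep) if k]
        if len(kept_genes) < 2:
            continue
        R = np.corrcoef(sub[keep])
        P = _corr_pvalues(R, n)
        for i, j in itertools.combinations(range(len(kept_genes)), 2):
            a, b = sorted((kept_genes[i], kept_genes[j]))
            edges.append(CorrelationEdge(gene_a=a, gene_b=b, tissue=str(tissue),
                                         r=float(np.clip(R[i, j], -1, 1)),
                                         p=float(P[i, j]), n=n))
    return edges


def edges_to_frame(edges: list[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_a": [e.gene_a for e in edges], "gene_b": [e.gene_b for e in edges],
        "tissue": [e.tissue for e in edges], "r": [e.r for e in edges],
        "p": [e.p for e in edges], "n": [e.n for e in edges],
    })


@dataclass
class CoexpressionNetwork:
    """Aggregated cross-tissue network: one record per (pair, sign)."""

    edges: pd.DataFrame  # gene_a, gene_b, sign, tissue_count, tissues
    n_tissues: int

    @property
    def n_unique_pairs(self) -> int:
        """Distinct gene pairs supported in at least one tissue."""
        if self.edges.empty:
            return 0
        return self.edges.groupby(["gene_a", "gene_b"]).ngroups

    @property
    def n_pair_tissue_records(self) -> int:
        """Pair-tissue support records pooled over tissues (and signs)."""
        return int(self.edges["tissue_count"].sum()) if not self.edges.empty else 0


def aggregate_network(edges: list[CorrelationEdge], r_threshold: float = 0.8,
                      p_threshold: float = 0.05,
                      bh_correct: bool = False) -> CoexpressionNetwork:
    """Keep pairs with |r| > r_threshold and p < p_threshold; count tissues.

    Sign is kept per record: a pair can appear once with positive and once
    with negative support. p-values are raw by default; ``bh_correct``
    applies a Benjamini-Hochberg adjustment within each tissue first.
    """
    df = edges_to_frame(edges)
    tissues_seen = df["tissue"].nunique() if not df.empty else 0
    if df.empty:
        return CoexpressionNetwork(edges=df.assign(sign=[], tissue_count=[],
                                                   tissues=[]), n_tissues=0)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        df = df.copy()
        df["p"] = df.groupby("tissue")["p"].transform(
            lambda p: multipletests(p, method="fdr_bh")[1])
    hit = df[(df["r"].abs() > r_threshold) & (df["p"] < p_threshold)].copy()
    if hit.empty:
        empty = pd.DataFrame(columns=["gene_a", "gene_b", "sign", "tissue_count",
                                      "tissues"])
        return CoexpressionNetwork(edges=empty, n_tissues=tissues_seen)
    hit["sign"] = np.where(hit["r"] > 0, 1, -1)
    agg = (hit.groupby(["gene_a", "gene_b", "sign"])
              .agg(tissue_count=("tissue", "nunique"),
                   tissues=("tissue", lambda t: ";".join(sorted(t))))
              .reset_index())
    return CoexpressionNetwork(edges=agg, n_tissues=tissues_seen)


@dataclass
class AnticorrPartition:
    """Two opposing clusters from one tissue's signed correlation graph."""

    cluster_a: frozenset[str]
    cluster_b: frozenset[str]
    unassigned: frozenset[str]
    n_negative_between: int
    balanced: bool


def anticorrelated_clusters(edges_one_tissue: list[CorrelationEdge],
                            threshold: float = 0.8) -> AnticorrPartition:
    """Detect two opposing clusters in a single tissue's signed graph.

    Builds a graph on |r| > threshold edges; clusters are connected components
    of the positive-edge subgraph; the reported pair maximizes the number of
    negative edges between components. A negative edge inside a cluster marks
    the partition unbalanced (frustrated signs), reported best-effort.
    """
    tissues = {e.tissue for e in edges_one_tissue}
    if len(tissues) > 1:
        raise ValueError(f"edges span multiple tissues: {sorted(tissues)}")
    strong = [e for e in edges_one_tissue if abs(e.r) > threshold]
    nodes = {g for e in strong for g in (e.gene_a, e.gene_b)}
    pos = nx.Graph()
    pos.add_nodes_from(nodes)
    neg_edges = []
    for e in strong:
        if e.r > 0:
            pos.add_edge(e.gene_a, e.gene_b)
        else:
            neg_edges.append((e.gene_a, e.gene_b))
    comps = [frozenset(c) for c in nx.connected_components(pos)]
    if len(comps) < 2 or not neg_edges:
        a = comps[0] if comps else frozenset()
        rest = frozenset().union(*comps[1:]) if len(comps) > 1 else frozenset()
        return AnticorrPartition(cluster_a=a, cluster_b=frozenset(),
                                 unassigned=rest, n_negative_between=0,
                                 balanced=True)
    comp_of = {g: i for i, c in enumerate(comps) for g in c}
    between: dict[tuple[int, int], int] = {}
    intra_negative = False
    for a, b in neg_edges:
        ia, ib = comp_of[a], comp_of[b]
        if ia == ib:
            intra_negative = True
            continue
        key = (min(ia, ib), max(ia, ib))
        between[key] = between.get(key, 0) + 1
    if not between:
        logger.warning("sign-inconsistent graph: negative edges only within "
                       "positive components")
        return AnticorrPartition(cluster_a=comps[0], cluster_b=frozenset(),
                                 unassigned=frozenset().union(*comps[1:]),
                                 n_negative_between=0, balanced=False)
    (ia, ib), count = max(between.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
    chosen = comps[ia] | comps[ib]
    unassigned = frozenset(nodes - chosen)
    if intra_negative:
        logger.warning("frustrated signs: negative edge inside a positive component")
    # deterministic orientation: cluster_a holds the lexicographically first gene
    ca, cb = comps[ia], comps[ib]
    if min(cb) < min(ca):
        ca, cb = cb, ca
    return AnticorrPartition(cluster_a=ca, cluster_b=cb, unassigned=unassigned,
                             n_negative_between=count,
                             balanced=not intra_negative)
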