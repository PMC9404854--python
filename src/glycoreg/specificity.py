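"""Tissue-specificity classification and tissue-predictive benchmarking.

The five-fold rules classify each gene from its tissue-level mean expression:

* **Tissue Enriched** — at least ``fold`` (default 5) times higher expression
  in one tissue than in every other tissue.
* **Group Enriched** — at least ``fold`` times higher expression in a group of
  2-7 tissues than in all tissues outside the group.
* **Tissue Enhanced** — at least ``fold`` times higher expression in one
  tissue than the *average* of all other tissues (and not already in one of
  the previous categories).
* **Not Specific** — none of the above, or maximal expression below the
  expression floor.

Tissue-predictive ability is benchmarked by repeatedly training random-forest
classifiers on small random gene panels and scoring the pooled test-set
confusion matrix with the Gorodkin multiclass Matthews correlation
coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from glycoreg.simulate import ExpressionMatrix

logger = logging.getLogger(__name__)

CATEGORIES = ("TissueEnriched", "GroupEnriched", "TissueEnhanced", "NotSpecific")


@dataclass(frozen=True)
class SpecificityCall:
    """Per-gene specificity classification with its supporting tissues."""

    gene: str
    category: str
    tissues: tuple[str, ...]
    fold_achieved: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        n = len(self.tissues)
        ok = {"TissueEnriched": n == 1, "TissueEnhanced": n == 1,
              "GroupEnriched": 2 <= n <= 7, "NotSpecific": n == 0}
        if not ok[self.category]:
            raise ValueError(f"{self.gene}: {self.category} with {n} tissues")


@dataclass
class BenchmarkResult:
    """MCC values from repeated random-forest gene-panel models."""

    gene_class: str
    mcc_values: np.ndarray
    genes_per_model: int
    seed: int

    def summary(self) -> dict:
        vals = self.mcc_values[~np.isnan(self.mcc_values)]
        return {
            "gene_class": self.gene_class,
            "n_models": int(len(self.mcc_values)),
            "median": float(np.median(vals)),
            "iqr_low": float(np.percentile(vals, 25)),
            "iqr_high": float(np.percentile(vals, 75)),
            "genes_per_model": self.genes_per_model,
            "seed": self.seed,
        }


def mean_by_tissue(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic per-tissue mean of per-sample abundances (genes x tissues)."""
    tissue = matrix.samples["tissue"]
    counts = tissue.value_counts()
    empty = counts[counts == 0].index.tolist()
    if empty:
        logger.warning("tissues with zero samples excluded: %s", empty)
    return matrix.values.T.groupby(tissue).mean().T


def classify_one(means: np.ndarray, tissues: list[str], fold: float = 5.0,
                 expression_floor: float = 1.0, max_group: int = 7) -> tuple[str, tuple[str, ...], float]:
    """Classify one gene's tissue-mean vector; returns (category, tissues, fold_achieved).

    Group search is greedy: tissues sorted by descending mean, the candidate
    group grows from the top and is accepted at the first size in [2,
    max_group] where every member is >= fold x the maximum outside the group.
    For fold > 1 any qualifying group must consist of the top-k tissues, so
    the greedy scan is equivalent to exhaustive subset search.
    """
    means = np.asarray(means, dtype=float)
    if means.size < 2:
        raise ValueError("need >= 2 tissues")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    order = np.argsort(-means, kind="stable")
    s = means[order]

    if s[0] < expression_floor:
        return "NotSpecific", (), 0.0

    # Tissue Enriched: top tissue vs max of the rest
    max_rest = s[1]
    fa = s[0] / max_rest if max_rest > 0 else np.inf
    if s[0] >= fold * max_rest:
        return "TissueEnriched", (tissues[order[0]],), float(fa)

    # Group Enriched: grow the top group
    for k in range(2, min(max_group, means.size - 1) + 1):
        outside_max = s[k]
        if outside_max <= 0:
            ratio = np.inf
        else:
            ratio = s[k - 1] / outside_max  # weakest member vs best outsider
        if s[k - 1] >= fold * outside_max and s[k - 1] >= expression_floor:
            grp = tuple(tissues[i] for i in sorted(order[:k]))
            return "GroupEnriched", grp, float(ratio)

    # Tissue Enhanced: top tissue vs mean of the others
    mean_rest = float(np.mean(s[1:]))
    fa = s[0] / mean_rest if mean_rest > 0 else np.inf
    if s[0] >= fold * mean_rest:
        return "TissueEnhanced", (tissues[order[0]],), float(fa)

    return "NotSpecific", (), float(s[0] / max_rest if max_rest > 0 else np.inf)


def classify_specificity(tissue_means: pd.DataFrame, fold: float = 5.0,
                         expression_floor: float = 1.0,
                         max_group: int = 7) -> list[SpecificityCall]:
    """Apply the five-fold rules to every gene of a genes x tissues table.

    Precedence is Enriched > GroupEnriched > Enhanced > NotSpecific; genes
    whose expression stays below ``expression_floor`` in every tissue are
    NotSpecific.
    """
    if tissue_means.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    tissues = list(tissue_means.columns)
    calls = []
    for gene, row in zip(tissue_means.index, tissue_means.to_numpy()):
        cat, tset, fa = classify_one(row, tissues, fold, expression_floor, max_group)
        calls.append(SpecificityCall(gene=gene, category=cat, tissues=tset,
                                     fold_achieved=fa))
    return calls


def calls_to_frame(calls: list[SpecificityCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene": [c.gene for c in calls],
        "category": [c.category for c in calls],
        "tissues": [";".join(c.tissues) for c in calls],
        "fold_achieved": [c.fold_achieved for c in calls],
    })


def specificity_summary(calls: list[SpecificityCall], catalogue=None) -> pd.DataFrame:
    """Fraction of genes per specificity category, per effective gene class.

    With a catalogue the rows are effective pathway classes plus an "all"
    row; without one a single "all" row is returned. Fractions per row sum
    to 1.
    """
    by_gene = {c.gene: c.category for c in calls}
    groups: dict[str, list[str]] = {"all": list(by_gene)}
    if catalogue is not None:
        missing = [g.symbol for g in catalogue if g.symbol not in by_gene]
        if missing:
            raise ValueError(f"calls missing catalogue genes: {missing[:5]}...")
        for g in catalogue:
            groups.setdefault(g.effective_class, []).append(g.symbol)
    rows = {}
    for cls, members in groups.items():
        cats = pd.Series([by_gene[m] for m in members])
        frac = cats.value_counts(normalize=True)
        rows[cls] = {cat: float(frac.get(cat, 0.0)) for cat in CATEGORIES}
    out = pd.DataFrame(rows).T[list(CATEGORIES)]
    out["specific_fraction"] = 1.0 - out["NotSpecific"]
    out.index.name = "gene_class"
    return out


def multiclass_mcc(confusion: np.ndarray) -> float:
    """Gorodkin multiclass Matthews correlation coefficient.

    Computed from a K x K confusion matrix C (rows = true, columns =
    predicted) via the covariance form:

        MCC = (c*s - sum_k p_k t_k) /
              sqrt((s^2 - sum_k p_k^2) (s^2 - sum_k t_k^2))

    with c = trace(C), s = total, t_k = row sums, p_k = column sums. Returns
    NaN (with a warning) when a single observed or predicted class makes the
    denominator zero.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (C < 0).any():
        raise ValueError("negative counts")
    s = C.sum()
    if s == 0:
        raise ValueError("empty confusion matrix")
    c = np.trace(C)
    t = C.sum(axis=1)
    p = C.sum(axis=0)
    denom2 = (s * s - (p * p).sum()) * (s * s - (t * t).sum())
    if denom2 <= 0:
        logger.warning("degenerate confusion matrix (single class): MCC undefined")
        return float("nan")
    return float((c * s - (p * t).sum()) / np.sqrt(denom2))


def _stratified_split(tissue: np.ndarray, train_frac: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-tissue split: floor(train_frac * n) train, at least 1 test sample."""
    train_ix, test_ix = [], []
    for t in np.unique(tissue):
        ix = np.flatnonzero(tissue == t)
        if ix.size < 4:
            raise ValueError(f"tissue {t} has {ix.size} samples (<4); cannot stratify")
        rng.shuffle(ix)
        n_train = min(int(np.floor(train_frac * ix.size)), ix.size - 1)
        train_ix.append(ix[:n_train])
        test_ix.append(ix[n_train:])
    return np.concatenate(train_ix), np.concatenate(test_ix)


def predictive_benchmark(
    matrix: ExpressionMatrix,
    gene_pool: list[str],
    n_models: int = 100,
    genes_per_model: int = 30,
    train_frac: float = 0.75,
    seed: int = 0,
    n_trees: int = 500,
    gene_class: str = "pool",
) -> BenchmarkResult:
    """Tissue-prediction benchmark: repeated random-forest gene-panel models.

    Each model draws ``genes_per_model`` genes from the pool, splits samples
    75/25 stratified by tissue, fits a random forest (``n_trees`` trees,
    stock feature subsampling) on the panel's expression, and records the
    Gorodkin MCC of the pooled test confusion matrix. The seed drives both
    gene sampling and model fitting.
    """
    if len(gene_pool) < genes_per_model:
        raise ValueError("gene pool smaller than genes_per_model")
    tissue = matrix.samples["tissue"].to_numpy()
    classes = np.unique(tissue)
    if classes.size < 2:
        raise ValueError("need >= 2 tissues")
    rng = np.random.default_rng(seed)
    X_all = matrix.values.loc[gene_pool].to_numpy().T  # samples x genes
    pool_ix = np.arange(len(gene_pool))
    class_pos = {c: i for i, c in enumerate(classes)}

    mccs = np.empty(n_models)
    for m in range(n_models):
        genes_ix = rng.choice(pool_ix, size=genes_per_model, replace=False)
        train, test = _stratified_split(tissue, train_frac, rng)
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1)
        clf.fit(X_all[np.ix_(train, genes_ix)], tissue[train])
        pred = clf.predict(X_all[np.ix_(test, genes_ix)])
        K = classes.size
        conf = np.zeros((K, K), dtype=int)
        for yt, yp in zip(tissue[test], pred):
            conf[class_pos[yt], class_pos[yp]] += 1
        mccs[m] = multiclass_mcc(conf)
    return BenchmarkResult(gene_class=gene_class, mcc_values=mccs,
                           genes_per_model=genes_per_model, seed=seed)
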