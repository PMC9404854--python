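"""Immune-composition association screens.

Two complementary screens link gene expression/alteration profiles to the
cellular composition of the microenvironment:

* **correlation counting** — per cancer type, the Pearson correlation between
  each gene's expression and each immune-cell fraction; for every gene x
  cell-type pair the number of cancer types with a significant correlation
  (p < 0.05) is counted, keeping positive and negative support separately.
* **lasso screens** — an L1-regularized linear model of a response (e.g. the
  M2-macrophage fraction, or the number of tumor subclones) on gene features,
  with the penalty chosen by 10-fold cross-validation (minimum mean CV error).
  A screen is significant when the across-fold mean explained variance
  exceeds its standard deviation (mean - sd > 0); models are displayed only
  when the observed-vs-predicted Pearson r (out-of-fold) exceeds 0.3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV, Lasso
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


@dataclass
class ImmuneAssociation:
    """Cross-cancer support for one gene x cell-type association."""

    gene: str
    cell_type: str
    n_cancers_significant: int
    n_positive: int
    n_negative: int
    per_cancer: pd.DataFrame = field(repr=False)  # cancer, r, p


def immune_correlation_counts(
    expr_by_cancer: dict[str, pd.DataFrame],
    fractions_by_cancer: dict[str, pd.DataFrame],
    p_threshold: float = 0.05,
) -> list[ImmuneAssociation]:
    """Count, per gene x cell type, the cancers with significant correlation.

    ``expr_by_cancer`` maps cancer type -> genes x samples expression;
    ``fractions_by_cancer`` maps cancer type -> samples x cell-type fractions
    (sample-aligned). Cancers with < 3 aligned samples are skipped with a
    warning. Signed counts are retained.
    """
    cancers = sorted(set(expr_by_cancer) & set(fractions_by_cancer))
    if not cancers:
        raise ValueError("no shared cancer types")
    records: dict[tuple[str, str], list[dict]] = {}
    for ca in cancers:
        expr = expr_by_cancer[ca]
        frac = fractions_by_cancer[ca]
        shared = [s for s in expr.columns if s in frac.index]
        if len(shared) < 3:
            logger.warning("cancer %s skipped: %d aligned samples (< 3)",
                           ca, len(shared))
            continue
        E = expr[shared].to_numpy(dtype=float)
        F = frac.loc[shared].to_numpy(dtype=float)
        n = len(shared)
        Ez = E - E.mean(axis=1, keepdims=True)
        Fz = F - F.mean(axis=0, keepdims=True)
        Es = Ez.std(axis=1)
        Fs = Fz.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            R = (Ez @ Fz) / n / np.outer(Es, Fs)
        R = np.clip(R, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = R * np.sqrt((n - 2) / np.maximum(1.0 - R * R, 1e-300))
        P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        for i, g in enumerate(expr.index):
            for j, ct in enumerate(frac.columns):
                if not np.isfinite(R[i, j]):
                    continue
                records.setdefault((g, ct), []).append(
                    {"cancer": ca, "r": float(R[i, j]), "p": float(P[i, j]),
                     "n": n})
    out = []
    for (g, ct), recs in sorted(records.items()):
        df = pd.DataFrame(recs)
        sig = df[df["p"] < p_threshold]
        out.append(ImmuneAssociation(
            gene=g, cell_type=ct,
            n_cancers_significant=int(len(sig)),
            n_positive=int((sig["r"] > 0).sum()),
            n_negative=int((sig["r"] < 0).sum()),
            per_cancer=df))
    return out


def associations_to_frame(assocs: list[ImmuneAssociation]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene": [a.gene for a in assocs],
        "cell_type": [a.cell_type for a in assocs],
        "n_cancers_significant": [a.n_cancers_significant for a in assocs],
        "n_positive": [a.n_positive for a in assocs],
        "n_negative": [a.n_negative for a in assocs],
    })


@dataclass
class LassoScreen:
    """Cross-validated L1 screen of one response on gene features."""

    response: str
    coefficients: pd.Series          # standardized-feature scale, all features
    cv_r2_mean: float
    cv_r2_sd: float
    significant: bool
    importance_rank: pd.Series       # rank of |coef| among nonzero features
    eval_r: float
    alpha: float
    seed: int

    @property
    def displayable(self) -> bool:
        """Display rule for reporting: observed-vs-predicted r above 0.3."""
        return bool(np.isfinite(self.eval_r) and self.eval_r > 0.3)


def lasso_screen(response: pd.Series, features: pd.DataFrame,
                 folds: int = 10, seed: int = 0,
                 response_name: str | None = None) -> LassoScreen:
    """L1 screen with CV-selected penalty and the one-SD significance rule.

    Features are standardized internally. The penalty is picked by
    ``folds``-fold cross-validation (minimum mean squared error); per-fold
    explained variance is cv_r2 = 1 - MSE_fold / Var(response_fold), and the
    screen is significant when mean(cv_r2) - sd(cv_r2) > 0. Importance ranks
    order nonzero features by |standardized coefficient| (rank 1 = largest);
    eval_r is the Pearson correlation of observed vs out-of-fold
    predictions at the chosen penalty.
    """
    y = response.to_numpy(dtype=float)
    X = features.to_numpy(dtype=float)
    n = y.size
    if n < 2 * folds:
        raise ValueError(f"n = {n} < 2 x folds = {2 * folds}")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(Xs))
    model = LassoCV(cv=splits, random_state=seed, alphas=60, max_iter=50000)
    model.fit(Xs, y)
    alpha = float(model.alpha_)

    cv_r2 = []
    oof_pred = np.empty_like(y)
    for train, test in splits:
        m = Lasso(alpha=alpha, max_iter=50000)
        m.fit(Xs[train], y[train])
        pred_test = m.predict(Xs[test])
        oof_pred[test] = pred_test
        mse = float(np.mean((y[test] - pred_test) ** 2))
        var = float(np.var(y[test]))
        cv_r2.append(1.0 - mse / var if var > 0 else np.nan)
    cv_r2 = np.asarray(cv_r2, dtype=float)
    mean_r2 = float(np.nanmean(cv_r2))
    sd_r2 = float(np.nanstd(cv_r2, ddof=1))

    refit = Lasso(alpha=alpha, max_iter=50000)
    refit.fit(Xs, y)
    # observed-vs-predicted r from out-of-fold predictions: an in-sample
    # refit overstates fit quality for null responses, so the display rule
    # is applied to cross-validated predictions
    if np.ptp(oof_pred) == 0:
        eval_r = float("nan")
    else:
        eval_r = float(stats.pearsonr(y, oof_pred)[0])

    coefs = pd.Series(refit.coef_, index=features.columns, name="coef")
    nz = coefs[coefs != 0.0].abs().sort_values(ascending=False)
    rank = pd.Series(np.arange(1, len(nz) + 1), index=nz.index,
                     name="importance_rank")
    return LassoScreen(
        response=response_name or (response.name or "response"),
        coefficients=coefs, cv_r2_mean=mean_r2, cv_r2_sd=sd_r2,
        significant=bool(mean_r2 - sd_r2 > 0), importance_rank=rank,
        eval_r=eval_r, alpha=alpha, seed=seed)


def ith_screen(cohort, feature_genes: list[str] | None = None,
               folds: int = 10, seed: int = 0,
               feature_set: str = "expression") -> LassoScreen:
    """Intra-tumor-heterogeneity screen: lasso of clone count on gene features.

    ``feature_set`` picks expression (log2 tumor counts), alteration flags,
    or both. The returned screen's ``displayable`` property applies the
    eval_r > 0.3 reporting rule.
    """
    genes = feature_genes or list(cohort.snv.columns)
    feats = {}
    if feature_set in ("expression", "both"):
        tumor_cols = [f"{p}_tumor" for p in cohort.patients]
        lt = np.log2(cohort.expression.loc[genes, tumor_cols].to_numpy() + 1.0)
        for g, row in zip(genes, lt):
            feats[f"{g}_expr"] = row
    if feature_set in ("alteration", "both"):
        alt = cohort.snv[genes].to_numpy() | (cohort.cna[genes].abs().to_numpy() >= 1)
        for i, g in enumerate(genes):
            feats[f"{g}_alt"] = alt[:, i].astype(float)
    if not feats:
        raise ValueError("feature_set must be expression, alteration or both")
    features = pd.DataFrame(feats, index=cohort.patients)
    response = cohort.clone_count.astype(float)
    return lasso_screen(response, features, folds=folds, seed=seed,
                        response_name="clone_count")
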