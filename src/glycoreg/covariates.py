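"""Per-tissue, per-gene linear scan for age and sex expression effects.

For each tissue and gene, expression (normalized abundance scale, no log) is
regressed on age in decades and sex (M-F difference, coded F=0/M=1) by
ordinary least squares; coefficient p-values are two-sided t tests, adjusted
per tissue across genes by Benjamini-Hochberg. Tissues with samples of a
single sex drop the sex term. A gene is age- or sex-dependent when its
adjusted p-value falls below 0.05; the coefficient sign gives the direction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from glycoreg.simulate import ExpressionMatrix

logger = logging.getLogger(__name__)


def fit_covariate_model(y: np.ndarray, age: np.ndarray,
                        sex: np.ndarray | None = None) -> dict:
    """OLS of one gene's abundance on age (decades) and optionally sex.

    Returns coefficients and two-sided t-test p-values. A constant response
    returns zero coefficients with p = 1; a collinear design raises.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    if y.size < 10:
        raise ValueError(f"n = {y.size} < 10")
    if np.ptp(age) == 0:
        raise ValueError("age is constant")
    cols = {"age": age}
    if sex is not None:
        cols["sex"] = np.asarray(sex, dtype=float)
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    if np.ptp(y) == 0:
        out = {"age_coef": 0.0, "p_age": 1.0, "n": int(y.size)}
        if sex is not None:
            out.update(sex_coef=0.0, p_sex=1.0)
        return out
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, X).fit()
    out = {"age_coef": float(fit.params["age"]), "p_age": float(fit.pvalues["age"]),
           "n": int(y.size)}
    if sex is not None:
        out.update(sex_coef=float(fit.params["sex"]), p_sex=float(fit.pvalues["sex"]))
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def covariate_scan(matrix: ExpressionMatrix, min_samples: int = 10,
                   bh_family: str = "tissue") -> pd.DataFrame:
    """Age/sex linear scan over every gene x tissue.

    Returns one row per gene and tissue with age and sex coefficients, raw
    and BH-adjusted p-values, and the sample count. The BH family is all
    genes within one tissue (``bh_family="tissue"``, default) or all
    gene-tissue pairs (``"global"``); age and sex p-value vectors are
    adjusted separately. Single-sex tissues have missing sex columns;
    tissues under ``min_samples`` samples are skipped with a warning.
    """
    if bh_family not in ("tissue", "global"):
        raise ValueError("bh_family must be 'tissue' or 'global'")
    rows = []
    for tissue, ann in matrix.samples.groupby("tissue", sort=True):
        if len(ann) < min_samples:
            logger.warning("tissue %s skipped: %d < %d samples",
                           tissue, len(ann), min_samples)
            continue
        age = ann["age_decade"].to_numpy(dtype=float)
        sexes = ann["sex"].dropna().unique()
        use_sex = len(sexes) > 1
        sex = (ann["sex"] == "M").to_numpy(dtype=float) if use_sex else None
        sub = matrix.values.loc[:, ann.index]
        for gene, y in zip(sub.index, sub.to_numpy()):
            res = fit_covariate_model(y, age, sex)
            rows.append({"gene": gene, "tissue": str(tissue),
                         "age_coef": res["age_coef"], "p_age": res["p_age"],
                         "sex_coef": res.get("sex_coef", np.nan),
                         "p_sex": res.get("p_sex", np.nan), "n": res["n"]})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    group = out["tissue"] if bh_family == "tissue" else pd.Series("all", index=out.index)
    out["q_age"] = (out.groupby(group)["p_age"]
                       .transform(lambda p: bh_adjust(p.to_numpy())))
    out["q_sex"] = np.nan
    has_sex = out["p_sex"].notna()
    if has_sex.any():
        qs = (out.loc[has_sex].groupby(group[has_sex])["p_sex"]
                 .transform(lambda p: bh_adjust(p.to_numpy())))
        out.loc[has_sex, "q_sex"] = qs
    out["age_significant"] = out["q_age"] < 0.05
    out["sex_significant"] = out["q_sex"] < 0.05
    return out


def coefficient_matrix(scan: pd.DataFrame, which: str = "age") -> pd.DataFrame:
    """Wide gene x tissue coefficient matrix with significance stars.

    Stars follow raw p-values (* < 0.05, ** < 0.01, *** < 0.001); values are
    formatted "<coef><stars>" for heatmap-style export.
    """
    coef_col, p_col = f"{which}_coef", f"p_{which}"

    def fmt(row):
        p = row[p_col]
        stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        return f"{row[coef_col]:.3f}{stars}"

    wide = scan.assign(cell=scan.apply(fmt, axis=1)).pivot(
        index="gene", columns="tissue", values="cell")
    return wide
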