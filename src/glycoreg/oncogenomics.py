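"""Tumor alteration summaries, TMM-normalized paired differential expression,
copy-number/expression concordance, and alteration-stratified survival.

Alteration prevalence counts, per gene, the percent of patients mutated,
amplified (focal score >= +threshold), deleted (<= -threshold) and altered in
any way (each patient counted once). Count libraries are normalized by the
trimmed-mean-of-M-values (TMM) recipe; differential expression between paired
tumor/normal libraries is a per-gene paired t test on TMM-normalized log2-CPM
— a documented stand-in for moderated linear modelling, assessed on
direction/effect-size concordance and FDR control rather than numerical
identity to any specific implementation. Survival contrasts altered vs
unaltered patients with a two-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from glycoreg.covariates import bh_adjust
from glycoreg.simulate import TumorCohort

logger = logging.getLogger(__name__)


def alteration_prevalence(cohort: TumorCohort, cna_threshold: int = 1) -> pd.DataFrame:
    """Per-gene alteration percents over a cohort's patients.

    amplified <=> cna >= threshold; deleted <=> cna <= -threshold; any <=>
    mutated or amplified or deleted with each patient counted once. Returns
    a DataFrame indexed by gene with pct_mutated/pct_amplified/pct_deleted/
    pct_any in [0, 100].
    """
    if not cohort.cna.isin([-2, -1, 0, 1, 2]).all().all():
        raise ValueError("CNA scores outside {-2..2}")
    if cna_threshold not in (1, 2):
        raise ValueError("cna_threshold must be 1 or 2")
    mut = cohort.snv.to_numpy(dtype=bool)
    cna = cohort.cna.to_numpy()
    amp = cna >= cna_threshold
    dele = cna <= -cna_threshold
    anyalt = mut | amp | dele
    out = pd.DataFrame({
        "pct_mutated": 100.0 * mut.mean(axis=0),
        "pct_amplified": 100.0 * amp.mean(axis=0),
        "pct_deleted": 100.0 * dele.mean(axis=0),
        "pct_any": 100.0 * anyalt.mean(axis=0),
    }, index=pd.Index(cohort.snv.columns, name="gene"))
    out["cancer_type"] = cohort.cancer_type
    return out


def rank_oncoprint(summaries: pd.DataFrame, top_n: int = 50) -> pd.DataFrame:
    """Rank genes by pooled alteration frequency (descending; ties by symbol).

    ``summaries`` may pool several cancer types; pct_any is averaged across
    types per gene before ranking (equal cohort weights).
    """
    if summaries.empty:
        raise ValueError("no summaries to rank")
    pooled = (summaries.groupby(level=0)[
        ["pct_mutated", "pct_amplified", "pct_deleted", "pct_any"]].mean())
    pooled = (pooled.reset_index()
                    .rename(columns={pooled.index.name or "index": "gene"})
                    .sort_values(["pct_any", "gene"], ascending=[False, True])
                    .reset_index(drop=True))
    pooled.index = pd.RangeIndex(1, len(pooled) + 1, name="rank")
    return pooled.head(top_n)


# ---------------------------------------------------------------------------
# TMM normalization

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, logratio_trim: float = 0.3,
              sum_trim: float = 0.05, a_cutoff: float = -1e10) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**f)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / n_obs, ref[keep] / n_ref
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + \
        (n_ref - ref[keep]) / (n_ref * ref[keep])
    fin = np.isfinite(M) & np.isfinite(A) & (A > a_cutoff)
    M, A, w = M[fin], A[fin], w[fin]
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    rank_m = stats.rankdata(M, method="average")
    rank_a = stats.rankdata(A, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(count_matrix: pd.DataFrame, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors per library.

    The reference library is the one whose 75th-percentile scaled count is
    closest to the across-library mean of those quantiles. Doubly-trimmed
    (30% of M values, 5% of A values from each tail) precision-weighted mean
    M gives each library's factor; factors are divided by their geometric
    mean so they multiply to 1.
    """
    counts = count_matrix.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = count_matrix.columns[lib == 0].tolist()
        raise ValueError(f"all-zero libraries: {bad}")
    q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                    for j in range(counts.shape[1])])
    ref_ix = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.array([_tmm_pair(counts[:, j], counts[:, ref_ix],
                            logratio_trim, sum_trim)
                  for j in range(counts.shape[1])])
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=count_matrix.columns, name="tmm_factor")


def log2_cpm(count_matrix: pd.DataFrame, factors: pd.Series | None = None,
             prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes, prior 0.5."""
    if factors is None:
        factors = tmm_factors(count_matrix)
    eff_lib = count_matrix.sum(axis=0) * factors
    return np.log2((count_matrix + prior_count).div(eff_lib + 1.0, axis=1) * 1e6)


def paired_de(cohort: TumorCohort) -> pd.DataFrame:
    """Paired tumor-vs-normal differential expression per gene.

    TMM-normalized log2-CPM; per-gene paired t test on within-patient
    (tumor - normal) differences; BH adjustment across genes. log2_fc is the
    mean paired difference. Requires >= 3 complete pairs.
    """
    cols = list(cohort.expression.columns)
    tumor_cols = [c for c in cols if c.endswith("_tumor")]
    normal_cols = [c.replace("_tumor", "_normal") for c in tumor_cols]
    missing = [c for c in normal_cols if c not in cols]
    if missing or len(tumor_cols) != len(cols) / 2:
        raise ValueError("expression columns are not complete tumor/normal pairs")
    if len(tumor_cols) < 3:
        raise ValueError("need >= 3 tumor/normal pairs")
    lc = log2_cpm(cohort.expression)
    diff = lc[tumor_cols].to_numpy() - lc[normal_cols].to_numpy()
    lfc = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    n = diff.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(sd == 0, np.where(lfc == 0, 1.0, 0.0), p)
    out = pd.DataFrame({"log2_fc": lfc, "p": p},
                       index=pd.Index(cohort.expression.index, name="gene"))
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < 0.05
    out["cancer_type"] = cohort.cancer_type
    return out


def cna_expression_concordance(cna_prevalence: pd.Series,
                               expression_alteration: pd.Series) -> tuple[float, float]:
    """Across-gene Pearson correlation of CNA prevalence vs expression change.

    ``expression_alteration`` is |log2_fc| (or a significance rate) per gene.
    Returns (r, two-sided t-test p). Requires >= 10 shared genes.
    """
    joined = pd.concat([cna_prevalence.rename("cna"),
                        expression_alteration.rename("expr")], axis=1).dropna()
    if len(joined) < 10:
        raise ValueError(f"only {len(joined)} shared genes (< 10)")
    r, p = stats.pearsonr(joined["cna"], joined["expr"])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# survival

@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in days, event flag, alteration group."""

    patient_id: str
    time: float
    event: bool
    group: str  # "altered" | "unaltered"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: non-positive time")
        if self.group not in ("altered", "unaltered"):
            raise ValueError(f"unknown group {self.group!r}")


def survival_records(cohort: TumorCohort, gene: str,
                     cna_threshold: int = 1) -> list[SurvivalRecord]:
    """Build altered/unaltered survival records for one gene."""
    alt = (cohort.snv[gene].to_numpy()
           | (cohort.cna[gene].abs().to_numpy() >= cna_threshold))
    return [SurvivalRecord(patient_id=p, time=float(row.time),
                           event=bool(row.event),
                           group="altered" if a else "unaltered")
            for p, a, row in zip(cohort.patients, alt,
                                 cohort.survival.itertuples(index=False))]


def logrank_test(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Event times are pooled with the simultaneous-risk-set tie convention.
    Both groups must be non-empty and at least one event observed.
    """
    groups = {r.group for r in records}
    if groups != {"altered", "unaltered"}:
        raise ValueError(f"need both groups, got {sorted(groups)}")
    if not any(r.event for r in records):
        raise ValueError("no events observed")
    t_a = [r.time for r in records if r.group == "altered"]
    e_a = [r.event for r in records if r.group == "altered"]
    t_u = [r.time for r in records if r.group == "unaltered"]
    e_u = [r.event for r in records if r.group == "unaltered"]
    res = _ll_logrank(t_a, t_u, event_observed_A=e_a, event_observed_B=e_u)
    return float(res.test_statistic), float(res.p_value)


def survival_scan(cohort: TumorCohort, genes: list[str] | None = None,
                  cna_threshold: int = 1, min_group: int = 5) -> pd.DataFrame:
    """Log-rank alteration-vs-survival association for each gene.

    Genes whose altered or unaltered group falls below ``min_group`` patients
    are skipped. q is BH across tested genes.
    """
    genes = genes or list(cohort.snv.columns)
    rows = []
    for g in genes:
        recs = survival_records(cohort, g, cna_threshold)
        n_alt = sum(r.group == "altered" for r in recs)
        if n_alt < min_group or len(recs) - n_alt < min_group:
            continue
        try:
            chi2, p = logrank_test(recs)
        except ValueError:
            continue
        rows.append({"gene": g, "n_altered": n_alt,
                     "n_unaltered": len(recs) - n_alt,
                     "chi2": chi2, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
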