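"""Seeded synthetic-data generators with planted ground truth.

Every generator is a pure function of its parameters and a seed, emulating the
statistical structure of consortium expression and tumor data: log-normal
tissue expression with planted fold-enriched genes and correlated gene blocks,
linear age effects, multi-species tissue panels with conserved/divergent
profiles, and tumor cohorts with Bernoulli SNVs, categorical copy-number
scores, negative-binomial paired counts, Dirichlet immune fractions,
exponential survival and Poisson clone counts.

The planted truths ride along in a :class:`TruthSidecar` so downstream stages
can be validated against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpecDesign", "CoexprBlock", "ExpressionMatrix", "TruthSidecar", "TumorCohort",
    "simulate_tissue_expression", "simulate_age_effects", "simulate_species_panel",
    "simulate_tumor_cohort", "write_expression_bundle", "read_expression_bundle",
]


@dataclass(frozen=True)
class SpecDesign:
    """A planted tissue-specificity signal for one gene.

    category is TissueEnriched / GroupEnriched / TissueEnhanced; tissues are
    the target tissue labels (1, 2-7, or 1 respectively); fold multiplies the
    background mean in the target tissue(s).
    """

    gene: str
    category: str
    tissues: tuple[str, ...]
    fold: float

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError(f"{self.gene}: fold {self.fold} < 1")
        if self.category == "GroupEnriched" and not 2 <= len(self.tissues) <= 7:
            raise ValueError(
                f"{self.gene}: group size {len(self.tissues)} outside 2-7")
        if self.category in ("TissueEnriched", "TissueEnhanced") and len(self.tissues) != 1:
            raise ValueError(f"{self.gene}: {self.category} needs exactly one tissue")


@dataclass(frozen=True)
class CoexprBlock:
    """A co-expression block: member genes share a per-sample latent factor.

    loading is the common log2-scale loading; members with sign -1 load
    negatively (anti-correlated with the rest of the block).
    """

    block_id: int
    genes: tuple[str, ...]
    loading: float = 1.0
    signs: tuple[int, ...] | None = None


@dataclass
class ExpressionMatrix:
    """genes x samples abundance values with per-sample annotations.

    values: DataFrame indexed by gene symbol, columns = sample ids.
    samples: DataFrame indexed by sample id with columns tissue, age_decade,
    sex, species, condition, patient_id.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    dialect: str = "TPM"
    counts_flag: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample columns and annotation index differ")
        if (self.values.values < 0).any():
            raise ValueError("negative abundance values")


@dataclass
class TruthSidecar:
    """Planted per-gene attributes, recorded for downstream validation."""

    spec_design: dict[str, dict] = field(default_factory=dict)
    age_slopes: dict[str, dict[str, float]] = field(default_factory=dict)
    sex_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    coexpr_blocks: dict[str, int] = field(default_factory=dict)
    conservation: dict[str, str] = field(default_factory=dict)
    tumor_lfc: dict[str, float] = field(default_factory=dict)
    mutation_rate: dict[str, float] = field(default_factory=dict)
    cna_rate: dict[str, float] = field(default_factory=dict)
    hazard_multiplier: dict[str, float] = field(default_factory=dict)
    immune_coefs: dict[str, dict[str, float]] = field(default_factory=dict)
    clone_coefs: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSidecar":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class TumorCohort:
    """Patient-level SNV/CNA/expression/survival/immune/clone bundle.

    snv: patients x genes boolean; cna: patients x genes integers in {-2..2};
    expression: counts matrix over paired tumor/normal samples (columns
    "<patient>_tumor"/"<patient>_normal"); survival: time (days) and event per
    patient; immune_fractions: patients x cell types, rows summing to 1
    (includes an explicit Other component); clone_count: positive ints.
    """

    patients: list[str]
    snv: pd.DataFrame
    cna: pd.DataFrame
    expression: pd.DataFrame
    survival: pd.DataFrame
    immune_fractions: pd.DataFrame
    clone_count: pd.Series
    cancer_type: str = "SYN"

    def __post_init__(self) -> None:
        if not self.cna.isin([-2, -1, 0, 1, 2]).all().all():
            raise ValueError("CNA scores outside {-2..2}")
        sums = self.immune_fractions.sum(axis=1)
        if ((self.immune_fractions.values < -1e-9).any()
                or (sums > 1 + 1e-9).any()):
            raise ValueError("immune fractions out of range")
        if (self.survival["time"] <= 0).any():
            raise ValueError("non-positive survival times")


# ---------------------------------------------------------------------------
# tissue expression

def _sample_table(n_tissues: int, n_per: int, rng: np.random.Generator,
                  species: str = "human") -> pd.DataFrame:
    tissues = [f"T{i + 1:02d}" for i in range(n_tissues)]
    recs = []
    for t in tissues:
        for j in range(n_per):
            sid = f"{t}_S{j + 1:03d}"
            recs.append({
                "sample_id": sid, "tissue": t,
                "age_decade": int(rng.integers(2, 8)),  # GTEX-like 20-79
                "sex": "F" if rng.random() < 0.5 else "M",
                "species": species, "condition": "normal", "patient_id": "",
            })
    return pd.DataFrame(recs).set_index("sample_id")


def simulate_tissue_expression(
    n_tissues: int,
    n_samples_per_tissue: int,
    n_genes: int,
    spec_design: list[SpecDesign] | None = None,
    coexpr_blocks: list[CoexprBlock] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    dialect: str = "TPM",
) -> tuple[ExpressionMatrix, TruthSidecar]:
    """Log-normal tissue expression with planted specificity and blocks.

    Per-gene background means are 2**N(1, 1); a planted gene's mean in its
    target tissue(s) is fold x background; block members share a per-sample
    latent N(0,1) factor scaled by the block loading on the log2 scale;
    residual log2 noise has sd ``noise_sd``.
    """
    if min(n_tissues, n_samples_per_tissue, n_genes) < 1:
        raise ValueError("all counts must be >= 1")
    spec_design = spec_design or []
    coexpr_blocks = coexpr_blocks or []
    rng = np.random.default_rng(seed)

    samples = _sample_table(n_tissues, n_samples_per_tissue, rng)
    tissues = samples["tissue"].unique().tolist()
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    truth = TruthSidecar()

    base = 2.0 ** rng.normal(1.0, 1.0, size=n_genes)  # per-gene background mean
    log_mu = np.log2(np.tile(base[:, None], (1, len(samples))))

    tissue_of = samples["tissue"].to_numpy()
    gene_ix = {g: i for i, g in enumerate(genes)}

    for d in spec_design:
        if d.gene not in gene_ix:
            raise ValueError(f"planted gene {d.gene} not in matrix")
        for t in d.tissues:
            if t not in tissues:
                raise ValueError(f"planted tissue {t} unknown")
            log_mu[gene_ix[d.gene], tissue_of == t] += np.log2(d.fold)
        truth.spec_design[d.gene] = {
            "category": d.category, "tissues": list(d.tissues), "fold": d.fold}

    log_vals = log_mu + rng.normal(0.0, noise_sd, size=log_mu.shape)
    for b in coexpr_blocks:
        z = rng.normal(0.0, 1.0, size=len(samples))
        signs = b.signs if b.signs is not None else tuple(1 for _ in b.genes)
        if len(signs) != len(b.genes):
            raise ValueError(f"block {b.block_id}: signs/genes length mismatch")
        for g, s in zip(b.genes, signs):
            log_vals[gene_ix[g]] += s * b.loading * z
            truth.coexpr_blocks[g] = b.block_id

    values = pd.DataFrame(2.0 ** log_vals, index=pd.Index(genes, name="gene"),
                          columns=samples.index)
    return ExpressionMatrix(values=values, samples=samples, dialect=dialect), truth


def simulate_age_effects(
    matrix: ExpressionMatrix,
    genes: list[str],
    slopes_per_decade: dict[str, float] | float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, TruthSidecar]:
    """Add an additive slope x age-decade effect (abundance scale) to genes.

    slopes_per_decade may be one float for all listed genes or a per-gene dict.
    The per-gene shift is offset by a constant so it is non-negative over the
    observed age range (a constant changes the intercept, not the slope) —
    otherwise negative slopes would truncate at zero for low-expressed genes
    and flatten the planted signal. Values are clipped at zero against noise
    excursions.
    """
    if matrix.samples["age_decade"].isna().any():
        raise ValueError("age metadata missing for some samples")
    missing = set(genes) - set(matrix.values.index)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)}")
    if not isinstance(slopes_per_decade, dict):
        slopes_per_decade = {g: float(slopes_per_decade) for g in genes}
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    ages = matrix.samples["age_decade"].to_numpy(dtype=float)
    truth = TruthSidecar()
    for g in genes:
        slope = slopes_per_decade[g]
        trend = slope * ages
        shift = trend - trend.min() + rng.normal(0.0, noise_sd, size=len(ages))
        values.loc[g] = np.clip(values.loc[g].to_numpy() + shift, 0.0, None)
        truth.age_slopes[g] = {"all": slope}
    out = ExpressionMatrix(values=values, samples=matrix.samples.copy(),
                           dialect=matrix.dialect, counts_flag=matrix.counts_flag)
    return out, truth


def simulate_species_panel(
    n_species: int,
    n_tissues: int,
    conserved_genes: list[str],
    divergent_genes: list[str],
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthSidecar]:
    """Long-format species x tissue x gene panel.

    Conserved genes share one tissue profile across species up to N(0, noise_sd)
    log2 noise; divergent genes get an independently shuffled profile per
    species. Returns (long DataFrame with columns gene/species/tissue/value,
    truth sidecar with conservation labels).
    """
    if n_species < 2:
        raise ValueError("need >= 2 species")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1}" for i in range(n_species)]
    tissues = [f"T{i + 1:02d}" for i in range(n_tissues)]
    truth = TruthSidecar()
    recs = []
    for gene, level in [(g, "conserved") for g in conserved_genes] + \
                       [(g, "divergent") for g in divergent_genes]:
        profile = 2.0 ** rng.normal(1.0, 1.0, size=n_tissues)
        truth.conservation[gene] = level
        for sp in species:
            prof = profile if level == "conserved" else rng.permutation(
                2.0 ** rng.normal(1.0, 1.0, size=n_tissues))
            vals = prof * 2.0 ** rng.normal(0.0, noise_sd, size=n_tissues)
            for t, v in zip(tissues, vals):
                recs.append({"gene": gene, "species": sp, "tissue": t,
                             "value": float(v)})
    return pd.DataFrame(recs), truth


# ---------------------------------------------------------------------------
# tumor cohort

DEFAULT_CELL_TYPES = (
    "B_cells", "M1_macrophages", "M2_macrophages", "Monocytes", "Neutrophils",
    "NK_cells", "CD4_T_cells", "CD8_T_cells", "Tregs", "Dendritic_cells",
    "Other",
)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion (1/size)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_tumor_cohort(
    n_patients: int,
    genes: list[str],
    mut_rates: dict[str, float] | None = None,
    cna_rates: dict[str, float] | None = None,
    lfc_truth: dict[str, float] | None = None,
    immune_model: dict[str, dict[str, float]] | None = None,
    hazard_model: dict[str, float] | None = None,
    clone_model: dict[str, float] | None = None,
    seed: int = 0,
    amp_fraction: float = 0.5,
    base_hazard: float = 1.0 / 1000.0,
    censor_time: float = 3000.0,
    dispersion: float = 0.1,
    cancer_type: str = "SYN",
) -> tuple[TumorCohort, TruthSidecar]:
    """TCGA-like synthetic cohort with planted alteration/expression truths.

    SNVs are Bernoulli(mut_rate); CNAs are non-zero with prob cna_rate, split
    amp/del by ``amp_fraction`` (focal score magnitude 1 or 2, 70/30); paired
    tumor/normal counts are negative binomial (dispersion 0.1) with tumor mean
    scaled by 2**lfc; immune fractions are Dirichlet with per-gene expression-
    linked shifts renormalized into the Other component; survival is
    exponential with per-patient hazard multiplied for altered genes and
    administrative censoring at ``censor_time`` days; clone counts are
    1 + Poisson with rate shifted by planted drivers.
    """
    if n_patients < 10:
        raise ValueError("need >= 10 patients")
    mut_rates = mut_rates or {}
    cna_rates = cna_rates or {}
    lfc_truth = lfc_truth or {}
    immune_model = immune_model or {}
    hazard_model = hazard_model or {}
    clone_model = clone_model or {}
    for d in (mut_rates, cna_rates, lfc_truth, immune_model, hazard_model, clone_model):
        extra = set(d) - set(genes)
        if extra:
            raise ValueError(f"model genes absent from gene list: {sorted(extra)}")
    for d in (mut_rates, cna_rates):
        for g, r in d.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{g}: rate {r} outside [0,1]")

    rng = np.random.default_rng(seed)
    patients = [f"P{i + 1:04d}" for i in range(n_patients)]
    truth = TruthSidecar()
    G, P = len(genes), n_patients

    mut = np.zeros((P, G), dtype=bool)
    cna = np.zeros((P, G), dtype=int)
    for j, g in enumerate(genes):
        mr = mut_rates.get(g, 0.0)
        cr = cna_rates.get(g, 0.0)
        truth.mutation_rate[g] = mr
        truth.cna_rate[g] = cr
        mut[:, j] = rng.random(P) < mr
        hit = rng.random(P) < cr
        sign = np.where(rng.random(P) < amp_fraction, 1, -1)
        mag = np.where(rng.random(P) < 0.7, 1, 2)
        cna[:, j] = np.where(hit, sign * mag, 0)

    snv = pd.DataFrame(mut, index=patients, columns=genes)
    cna_df = pd.DataFrame(cna, index=patients, columns=genes)

    # paired tumor/normal counts
    base_mean = 2.0 ** rng.normal(6.0, 1.0, size=G)  # per-gene baseline counts
    depth = rng.uniform(0.8, 1.2, size=2 * P)        # per-library depth factor
    cols, col_mean = [], []
    for i, p in enumerate(patients):
        cols += [f"{p}_tumor", f"{p}_normal"]
    lfc = np.array([lfc_truth.get(g, 0.0) for g in genes])
    truth.tumor_lfc = {g: float(v) for g, v in zip(genes, lfc)}
    means = np.empty((G, 2 * P))
    means[:, 0::2] = (base_mean * 2.0 ** lfc)[:, None] * depth[0::2][None, :]
    means[:, 1::2] = base_mean[:, None] * depth[1::2][None, :]
    counts = _nb_counts(rng, means, dispersion)
    expression = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                              columns=cols)

    # log2 tumor expression drives immune fractions and clone counts
    tumor_log = np.log2(counts[:, 0::2] + 1.0)  # G x P
    tumor_z = (tumor_log - tumor_log.mean(axis=1, keepdims=True)) / (
        tumor_log.std(axis=1, keepdims=True) + 1e-12)

    alpha = np.array([2, 2, 2, 2, 1, 1, 2, 2, 1, 1, 12], dtype=float)
    frac = rng.dirichlet(alpha, size=P)
    for g, coefs in immune_model.items():
        truth.immune_coefs[g] = dict(coefs)
        zi = tumor_z[genes.index(g)]
        for ct, c in coefs.items():
            k = DEFAULT_CELL_TYPES.index(ct)
            frac[:, k] = np.clip(frac[:, k] + c * zi, 0.0, 0.9)
    body = frac[:, :-1]
    scale = np.minimum(1.0, 0.98 / np.maximum(body.sum(axis=1), 1e-12))
    body = body * scale[:, None]
    frac = np.column_stack([body, 1.0 - body.sum(axis=1)])
    immune = pd.DataFrame(frac, index=patients, columns=list(DEFAULT_CELL_TYPES))

    # survival: exponential with alteration-multiplied hazard
    altered_any = (snv.values | (np.abs(cna_df.values) >= 1))
    hazard = np.full(P, base_hazard)
    for g, hm in hazard_model.items():
        truth.hazard_multiplier[g] = hm
        hazard *= np.where(altered_any[:, genes.index(g)], hm, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    event = t_event <= censor_time
    time = np.minimum(t_event, censor_time)
    time = np.maximum(time, 1e-3)
    survival = pd.DataFrame({"time": time, "event": event}, index=patients)

    lam = np.full(P, 2.0)
    for g, c in clone_model.items():
        truth.clone_coefs[g] = c
        lam = lam + c * tumor_z[genes.index(g)]
    clones = pd.Series(1 + rng.poisson(np.clip(lam, 0.05, None)),
                       index=patients, name="clone_count")

    cohort = TumorCohort(patients=patients, snv=snv, cna=cna_df,
                         expression=expression, survival=survival,
                         immune_fractions=immune, clone_count=clones,
                         cancer_type=cancer_type)
    return cohort, truth


# ---------------------------------------------------------------------------
# TSV round-trips

def write_expression_bundle(matrix: ExpressionMatrix, truth: TruthSidecar | None,
                            outdir: str | Path, prefix: str = "expr") -> list[Path]:
    """Write values + annotations (+ truth sidecar) as a TSV/JSON bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    vp = outdir / f"{prefix}_values.tsv"
    matrix.values.to_csv(vp, sep="\t")
    written.append(vp)
    sp = outdir / f"{prefix}_samples.tsv"
    matrix.samples.to_csv(sp, sep="\t")
    written.append(sp)
    if truth is not None:
        tp = outdir / f"{prefix}_truth.json"
        truth.to_json(tp)
        written.append(tp)
    return written


def read_expression_bundle(outdir: str | Path, prefix: str = "expr",
                           dialect: str = "TPM") -> ExpressionMatrix:
    outdir = Path(outdir)
    values = pd.read_csv(outdir / f"{prefix}_values.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(outdir / f"{prefix}_samples.tsv", sep="\t", index_col=0,
                          keep_default_na=False,
                          dtype={"sex": str, "patient_id": str})
    samples["age_decade"] = pd.to_numeric(samples["age_decade"])
    values = values.rename_axis(index="gene", columns=samples.index.name)
    return ExpressionMatrix(values=values, samples=samples, dialect=dialect)
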