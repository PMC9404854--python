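"""Paralog-history summaries and the cross-species expression-divergence score.

Duplication-epoch compression collapses the taxon of a gene's first
duplication onto three epochs along the human lineage: *chordates* (anything
ancestral to Vertebrata), *vertebrates* (anything ancestral to Mammalia but
not to Vertebrata) and *mammals* (everything after, excluding human-terminal
duplications).

The divergence score z-scores a gene's expression across all species-tissue
observations, computes per-tissue standard deviations across species, and
reports the minimum: a gene whose profile is conserved in at least one tissue
scores low regardless of its behaviour elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: ordered human lineage, root-most first (ENSEMBL-style node names)
DEFAULT_LINEAGE = (
    "Opisthokonta", "Bilateria", "Chordata", "Vertebrata", "Euteleostomi",
    "Sarcopterygii", "Tetrapoda", "Amniota", "Mammalia", "Theria", "Eutheria",
    "Boreoeutheria", "Euarchontoglires", "Primates", "Haplorrhini",
    "Simiiformes", "Catarrhini", "Hominidae", "Homininae", "Homo sapiens",
)

EPOCHS = ("chordates", "vertebrates", "mammals")


@dataclass(frozen=True)
class ParalogRecord:
    """Paralog history of one gene: copy count, first-duplication taxon, depth."""

    gene: str
    paralog_count: int
    first_duplication_taxon: str | None = None
    ortholog_depth: str | None = None

    def __post_init__(self) -> None:
        if self.paralog_count < 0:
            raise ValueError(f"{self.gene}: negative paralog count")
        if (self.paralog_count == 0) != (self.first_duplication_taxon is None):
            raise ValueError(
                f"{self.gene}: single-copy iff no first-duplication taxon")


@dataclass(frozen=True)
class DivergenceScore:
    """Minimum across-species within-tissue SD of scaled expression."""

    gene: str
    score: float
    tissue: str

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("negative divergence score")


def compress_duplication_epoch(taxon: str,
                               taxonomy: tuple[str, ...] = DEFAULT_LINEAGE) -> str:
    """Map a first-duplication taxon onto {chordates, vertebrates, mammals}.

    Taxa ancestral to Vertebrata compress to chordates; taxa ancestral to
    Mammalia (but not to Vertebrata) to vertebrates; everything later to
    mammals. The human-terminal taxon is excluded (raises ValueError).
    """
    if taxon not in taxonomy:
        raise KeyError(f"unknown taxon {taxon!r}")
    if "Vertebrata" not in taxonomy or "Mammalia" not in taxonomy:
        raise ValueError("taxonomy must contain Vertebrata and Mammalia")
    ix = taxonomy.index(taxon)
    if ix == len(taxonomy) - 1:
        raise ValueError(f"human-terminal duplication {taxon!r} is excluded")
    if ix < taxonomy.index("Vertebrata"):
        return "chordates"
    if ix < taxonomy.index("Mammalia"):
        return "vertebrates"
    return "mammals"


def paralog_summary(records: list[ParalogRecord], catalogue,
                    taxonomy: tuple[str, ...] = DEFAULT_LINEAGE) -> pd.DataFrame:
    """Per effective-class paralog statistics.

    Returns one row per class (plus "all") with the single-copy fraction,
    mean/median paralog counts, and the fraction of duplicated genes whose
    first duplication falls in each epoch. Classes without genes are absent;
    epoch fractions are NaN when a class has no duplicated gene.
    """
    by_gene = {r.gene: r for r in records}
    missing = [g.symbol for g in catalogue if g.symbol not in by_gene]
    if missing:
        raise ValueError(f"records missing catalogue genes: {missing[:5]}...")
    groups: dict[str, list[ParalogRecord]] = {"all": [by_gene[g.symbol] for g in catalogue]}
    for g in catalogue:
        groups.setdefault(g.effective_class, []).append(by_gene[g.symbol])
    rows = {}
    for cls, recs in groups.items():
        counts = np.array([r.paralog_count for r in recs])
        dup = [r for r in recs if r.paralog_count > 0 and r.first_duplication_taxon]
        epochs = pd.Series(
            [compress_duplication_epoch(r.first_duplication_taxon, taxonomy)
             for r in dup])
        efrac = epochs.value_counts(normalize=True) if len(dup) else pd.Series(dtype=float)
        rows[cls] = {
            "n_genes": len(recs),
            "single_copy_fraction": float((counts == 0).mean()),
            "mean_paralogs": float(counts.mean()),
            "median_paralogs": float(np.median(counts)),
            **{f"epoch_{e}": float(efrac.get(e, np.nan)) if len(dup) else np.nan
               for e in EPOCHS},
        }
    out = pd.DataFrame(rows).T
    out.index.name = "gene_class"
    out["n_genes"] = out["n_genes"].astype(int)
    return out


def expression_divergence(panel: pd.DataFrame, gene: str | None = None,
                          per_species_scaling: bool = False) -> DivergenceScore:
    """Divergence score for one gene from a long species x tissue panel.

    ``panel`` columns: gene, species, tissue, value (one gene, or pass
    ``gene`` to subset). Expression is z-scored across all species-tissue
    observations (sample SD, n-1); per tissue the SD across species is taken
    and the minimum returned with its tissue. Species-tissue pairs absent
    from the panel are skipped. A panel with zero overall variance scores 0.
    """
    df = panel if gene is None else panel[panel["gene"] == gene]
    if gene is None:
        genes = df["gene"].unique()
        if len(genes) != 1:
            raise ValueError("panel holds multiple genes; pass gene=")
        gene = genes[0]
    if df["species"].nunique() < 2:
        raise ValueError("need >= 2 species")
    vals = df["value"].to_numpy(dtype=float)
    sd_all = vals.std(ddof=1)
    if sd_all == 0:
        t0 = sorted(df["tissue"].unique())[0]
        return DivergenceScore(gene=gene, score=0.0, tissue=t0)
    work = df.copy()
    if per_species_scaling:
        work["z"] = work.groupby("species")["value"].transform(
            lambda v: (v - v.mean()) / v.std(ddof=1))
    else:
        work["z"] = (vals - vals.mean()) / sd_all
    per_tissue = (work.groupby("tissue")["z"]
                      .agg(lambda z: z.std(ddof=1) if len(z) >= 2 else np.nan)
                      .dropna())
    if per_tissue.empty:
        raise ValueError("no tissue observed in >= 2 species")
    tissue = per_tissue.idxmin()
    return DivergenceScore(gene=gene, score=float(per_tissue.min()),
                           tissue=str(tissue))


def divergence_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Divergence scores for every gene in a long panel."""
    rows = []
    for g in panel["gene"].unique():
        s = expression_divergence(panel, gene=g)
        rows.append({"gene": s.gene, "score": s.score, "tissue": s.tissue})
    return pd.DataFrame(rows)
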