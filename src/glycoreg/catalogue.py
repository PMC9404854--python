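"""The curated glycosylation-factor catalogue: loading, validation, summaries.

The registry covers genes directly executing or supporting glycan assembly —
transferases, hydrolases and precursor synthesis/transport — classified into
five biosynthetic pathways (N-linked, O-linked, GPI anchoring, lipid
glycosylation, glycosaminoglycan synthesis). A gene participating in two or
more pathways has effective class ``Multiple``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

VALID_PATHWAYS = frozenset({"N_linked", "O_linked", "GPI", "Lipid", "GAG"})
VALID_FUNCTIONS = frozenset({"transferase", "hydrolase", "other"})

#: packaged fixture: synthetic reconstruction of the 242-gene registry that
#: matches the published aggregate composition (pathway and function shares)
FIXTURE_NAME = "catalogue_synthetic.tsv"


class CatalogueFormatError(ValueError):
    """Raised when a catalogue file lacks required structure."""


class CatalogueValidationError(ValueError):
    """Raised when catalogue content violates an invariant."""


@dataclass(frozen=True)
class GlycoGene:
    """One catalogue entry.

    Parameters
    ----------
    symbol : HGNC-style gene symbol, unique within a catalogue.
    pathways : non-empty subset of the five glycosylation pathways.
    function_class : transferase, hydrolase or other.
    pli : probability of loss-of-function intolerance in [0, 1], or None.
    clinvar_pathogenic : whether a pathogenic variant is reported, or None.
    """

    symbol: str
    pathways: frozenset[str]
    function_class: str
    pli: float | None = None
    clinvar_pathogenic: bool | None = None

    def __post_init__(self) -> None:
        if not self.pathways:
            raise CatalogueValidationError(f"{self.symbol}: empty pathway set")
        bad = set(self.pathways) - VALID_PATHWAYS
        if bad:
            raise CatalogueValidationError(f"{self.symbol}: unknown pathways {bad}")
        if self.function_class not in VALID_FUNCTIONS:
            raise CatalogueValidationError(
                f"{self.symbol}: unknown function class {self.function_class!r}")
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise CatalogueValidationError(f"{self.symbol}: pli {self.pli} not in [0,1]")

    @property
    def effective_class(self) -> str:
        """Single pathway, or ``Multiple`` for genes in >= 2 pathways."""
        if len(self.pathways) >= 2:
            return "Multiple"
        return next(iter(self.pathways))


@dataclass
class Catalogue:
    """Ordered, symbol-unique collection of :class:`GlycoGene`."""

    genes: list[GlycoGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise CatalogueValidationError(f"duplicate symbols: {dupes}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per gene, in catalogue order."""
        return pd.DataFrame(
            {
                "symbol": [g.symbol for g in self.genes],
                "pathways": [";".join(sorted(g.pathways)) for g in self.genes],
                "function_class": [g.function_class for g in self.genes],
                "pli": [g.pli for g in self.genes],
                "clinvar_pathogenic": [g.clinvar_pathogenic for g in self.genes],
            }
        )

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df["pli"] = df["pli"].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
        df["clinvar_pathogenic"] = df["clinvar_pathogenic"].map(
            lambda v: "" if pd.isna(v) else ("true" if v else "false"))
        df.to_csv(path, sep="\t", index=False)


def _parse_bool(value) -> bool | None:
    if pd.isna(value) or value == "":
        return None
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise CatalogueFormatError(f"unparseable boolean {value!r}")


def load_catalogue(path: str | Path) -> Catalogue:
    """Read a TSV catalogue (symbol, pathways, function_class[, pli, clinvar_pathogenic]).

    Pathways are semicolon-separated tokens. Row order is preserved. Missing
    pli / clinvar annotations are permitted and logged, not fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"symbol", "pathways", "function_class"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogueFormatError(f"{path}: missing required columns {sorted(missing)}")

    genes: list[GlycoGene] = []
    n_missing_pli = n_missing_clinvar = 0
    for row in df.itertuples(index=False):
        pathways = frozenset(t for t in str(row.pathways).split(";") if t)
        pli_raw = getattr(row, "pli", "")
        pli = None if pli_raw in ("", None) or pd.isna(pli_raw) else float(pli_raw)
        clinvar = _parse_bool(getattr(row, "clinvar_pathogenic", ""))
        if pli is None:
            n_missing_pli += 1
        if clinvar is None:
            n_missing_clinvar += 1
        genes.append(GlycoGene(symbol=str(row.symbol), pathways=pathways,
                               function_class=str(row.function_class),
                               pli=pli, clinvar_pathogenic=clinvar))
    if n_missing_pli:
        logger.info("%s: %d genes without pLI annotation", path.name, n_missing_pli)
    if n_missing_clinvar:
        logger.info("%s: %d genes without ClinVar annotation", path.name, n_missing_clinvar)
    return Catalogue(genes=genes)


def load_packaged_catalogue() -> Catalogue:
    """Load the packaged synthetic reconstruction of the 242-gene registry."""
    ref = resources.files("glycoreg.data").joinpath(FIXTURE_NAME)
    with resources.as_file(ref) as p:
        return load_catalogue(p)


def _round_half_away(x: float) -> int:
    """Round half away from zero, matching printed whole-percent figures."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def class_counts(catalogue: Catalogue, per_pathway: bool = False) -> pd.DataFrame:
    """Counts and whole-number percents per effective pathway class.

    With ``per_pathway=True`` multi-pathway genes are counted in every pathway
    they belong to (percents still use the catalogue size as denominator).
    """
    if len(catalogue) == 0:
        raise CatalogueValidationError("empty catalogue")
    counts: dict[str, int] = {}
    if per_pathway:
        for g in catalogue:
            for p in g.pathways:
                counts[p] = counts.get(p, 0) + 1
    else:
        for g in catalogue:
            c = g.effective_class
            counts[c] = counts.get(c, 0) + 1
    total = len(catalogue)
    order = ["N_linked", "O_linked", "GPI", "Lipid", "GAG", "Multiple"]
    keys = [k for k in order if k in counts] + sorted(set(counts) - set(order))
    return pd.DataFrame(
        {"count": [counts[k] for k in keys],
         "percent": [_round_half_away(100.0 * counts[k] / total) for k in keys]},
        index=pd.Index(keys, name="class"),
    )


def function_counts(catalogue: Catalogue) -> pd.DataFrame:
    """Counts and whole-number percents per function class."""
    if len(catalogue) == 0:
        raise CatalogueValidationError("empty catalogue")
    counts: dict[str, int] = {}
    for g in catalogue:
        counts[g.function_class] = counts.get(g.function_class, 0) + 1
    total = len(catalogue)
    order = ["transferase", "hydrolase", "other"]
    keys = [k for k in order if k in counts]
    return pd.DataFrame(
        {"count": [counts[k] for k in keys],
         "percent": [_round_half_away(100.0 * counts[k] / total) for k in keys]},
        index=pd.Index(keys, name="function_class"),
    )


def pathogenic_fraction(catalogue: Catalogue, by_class: bool = False):
    """Fraction of genes with a reported ClinVar-pathogenic variant.

    Missing annotations are treated as False (logged). Returns a float, or a
    Series per effective class when ``by_class`` is set.
    """
    df = catalogue.to_frame()
    n_missing = int(df["clinvar_pathogenic"].isna().sum())
    if n_missing:
        logger.info("pathogenic_fraction: %d missing ClinVar flags treated as False",
                    n_missing)
    flags = df["clinvar_pathogenic"].fillna(False).astype(bool)
    if not by_class:
        return float(flags.mean()) if len(df) else 0.0
    cls = pd.Series([g.effective_class for g in catalogue], name="class")
    return flags.groupby(cls).mean().rename("pathogenic_fraction")


def pli_category(pli: float, cutpoints: tuple[float, float] = (0.1, 0.9)) -> str:
    """Map a pLI probability onto tolerant / intermediate / intolerant.

    The conventional cutpoints 0.1 and 0.9 bound the intermediate band;
    pli < low is tolerant, pli >= high is intolerant.
    """
    low, high = cutpoints
    if not 0.0 <= pli <= 1.0:
        raise ValueError(f"pli {pli} outside [0,1]")
    if pli < low:
        return "tolerant"
    if pli >= high:
        return "intolerant"
    return "intermediate"
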