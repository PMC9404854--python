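#!/usr/bin/env python
"""Catalogue composition: pathway classes, enzyme functions, disease burden.

Loads the packaged glycosylation-factor registry and tabulates how the 242
genes distribute over the five biosynthetic pathways, the transferase /
hydrolase / other functional split, the fraction with reported pathogenic
variants, and the pLI intolerance categories.
"""

import argparse
from pathlib import Path

from glycoreg.catalogue import (
    class_counts,
    function_counts,
    load_packaged_catalogue,
    pathogenic_fraction,
    pli_category,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cat = load_packaged_catalogue()
    cc = class_counts(cat)
    fc = function_counts(cat)
    pf = pathogenic_fraction(cat, by_class=True)

    cc.to_csv(args.outdir / "catalogue_class_counts.tsv", sep="\t")
    fc.to_csv(args.outdir / "catalogue_function_counts.tsv", sep="\t")
    pf.to_csv(args.outdir / "catalogue_pathogenic_by_class.tsv", sep="\t")

    print(f"{len(cat)} glycosylation factors")
    for cls, row in cc.iterrows():
        print(f"  {cls:<9} {row['count']:>3} genes ({row['percent']}%)")
    print(f"transferases {fc.loc['transferase', 'percent']}%, "
          f"hydrolases {fc.loc['hydrolase', 'percent']}%")
    print(f"pathogenic-variant fraction overall: "
          f"{100 * pathogenic_fraction(cat):.1f}% "
          f"(GPI {100 * pf['GPI']:.0f}%, O-linked {100 * pf['O_linked']:.0f}%)")

    with_pli = [g for g in cat if g.pli is not None]
    cats = [pli_category(g.pli) for g in with_pli]
    for label in ("tolerant", "intermediate", "intolerant"):
        share = 100 * cats.count(label) / len(cats)
        print(f"  pLI {label:<12} {share:.0f}% of {len(with_pli)} annotated genes")


if __name__ == "__main__":
    main()
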