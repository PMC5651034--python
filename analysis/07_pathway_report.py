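#!/usr/bin/env python
"""Pathway-level severity report per genotype and gene-copy family.

Combines the most severe variant category per copy, its CNV status, its
cross-species status and a presence frame (found / not found / unannotated)
into the machine-readable analogue of a pathway variation figure.
"""

from pathlib import Path

import pandas as pd

from capcnv.pipeline import (
    annotate_genotype_variants,
    cnv_calls,
    cross_species_calls,
    load_dataset_view,
    pathway_report,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = load_dataset_view(ROOT / "dataset")
    anns = pd.concat(
        [annotate_genotype_variants(ds, n)[0] for n in sorted(ds.subgenome_of)],
        ignore_index=True,
    )
    report = pathway_report(ds, anns, cnv_calls(ds), cross_species_calls(ds))
    report.to_csv(ROOT / "pathway_report.tsv", sep="\t", index=False)
    interesting = report[
        (report.most_severe != "none")
        | (report.cnv != "none")
        | (report.presence != "found")
        | (report.cross_species == "exchanged")
    ]
    print(f"pathway report: {len(report)} copy x genotype entries "
          f"({report.genotype.nunique()} genotypes x "
          f"{report.family.nunique()} families)")
    print(interesting.to_string(index=False))


if __name__ == "__main__":
    main()
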