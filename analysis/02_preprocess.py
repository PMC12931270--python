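#!/usr/bin/env python
"""Apply the count-table filters and record the attrition at each step.

Singletons out first, then organelle (chloroplast/mitochondria) lineages,
then the 0.01% abundance / 5% prevalence filter that gates the network
analysis.  Writes the cleaned and network-ready tables plus an attrition
table.
"""

from pathlib import Path

import pandas as pd

from bpdnet import (abundance_prevalence_filter, read_count_table,
                    read_taxonomy, remove_organelles, remove_singletons,
                    write_count_table)

COHORT = Path("scratch/analysis/cohort")
DATA = Path("scratch/analysis")
OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = read_count_table(COHORT / "counts.tsv")
    taxonomy = read_taxonomy(COHORT / "taxonomy.tsv")
    steps = [("input", table)]
    table = remove_singletons(table)
    steps.append(("remove_singletons", table))
    table = remove_organelles(table, taxonomy)
    steps.append(("remove_organelles", table))
    write_count_table(table, DATA / "counts_clean.tsv")
    filtered = abundance_prevalence_filter(table)
    steps.append(("abundance_prevalence_filter", filtered))
    write_count_table(filtered, DATA / "counts_network_ready.tsv")

    attrition = pd.DataFrame(
        [{"step": name, "taxa": t.n_taxa, "samples": t.n_samples,
          "total_reads": int(t.counts.sum())} for name, t in steps])
    attrition.to_csv(OUT / "preprocess_attrition.tsv", sep="\t", index=False)
    print(attrition.to_string(index=False))


if __name__ == "__main__":
    main()
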