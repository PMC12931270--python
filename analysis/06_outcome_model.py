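#!/usr/bin/env python
"""Ordinal severity models: network density and keystone abundances.

Fits proportional-odds models of grade ~ predictor with forward-stepwise
clinical covariates (dropping any covariate that makes the observed
information singular).  Predictors: the per-sample leave-one-out network
density, and the log-z-scored relative abundance of each keystone ASV.
"""

from pathlib import Path

import pandas as pd

from bpdnet import read_count_table, read_metadata
from bpdnet.outcome import FitError, design_matrix, forward_stepwise, standardize
from bpdnet.pipeline import (COVARIATE_ORDER, PipelineConfig,
                             _per_sample_network_metric)

OUT = Path("results/analysis/model")
SEED = 20260930


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    filtered = read_count_table(Path("scratch/analysis/counts_network_ready.tsv"))
    metadata = read_metadata(Path("scratch/analysis/cohort/metadata.tsv"))
    meta = metadata.table.loc[filtered.sample_ids]
    y = meta["group"]
    covars = design_matrix(meta, COVARIATE_ORDER)

    config = PipelineConfig(seed=SEED)
    density = _per_sample_network_metric(config, filtered, metadata, "density")
    summaries = []

    data = covars.copy()
    data["density"] = standardize(density.loc[meta.index].to_numpy())
    fit = forward_stepwise(y, data, ["density"], list(covars.columns))
    s = fit.summary()
    s.insert(0, "model", "density")
    summaries.append(s)
    print("density model: OR = %.3f (p = %.3g), dropped: %s"
          % (s.loc["density", "OR"], s.loc["density", "p"],
             [c for c, _ in fit.dropped] or "none"))

    keystones = pd.read_csv(Path("scratch/analysis/networks/keystones.tsv"),
                            sep="\t", index_col=0)
    flagged = keystones[keystones["keystone_flag"]]
    fractions = pd.DataFrame(
        filtered.counts / filtered.depths[:, None],
        index=filtered.sample_ids, columns=filtered.taxon_ids)
    for taxon in pd.unique(flagged.index)[:4]:
        data = covars.copy()
        try:
            data[taxon] = standardize(fractions.loc[meta.index, taxon].to_numpy(),
                                      log_transform=True)
            fit = forward_stepwise(y, data, [taxon], list(covars.columns))
        except FitError as exc:
            print(f"{taxon}: model not fitted ({exc})")
            continue
        s = fit.summary()
        s.insert(0, "model", taxon)
        summaries.append(s)
        print("%s model: OR = %.3f (p = %.3g)"
              % (taxon, s.loc[taxon, "OR"], s.loc[taxon, "p"]))

    pd.concat(summaries).to_csv(OUT / "coefficients.tsv", sep="\t")


if __name__ == "__main__":
    main()
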