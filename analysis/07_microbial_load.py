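#!/usr/bin/env python
"""Does any knockout carry a higher total microbial load?

Load is the row sum of the spike-scaled table over admitted samples (the
spike calibration makes totals comparable across samples).  Log load is
compared across the design with the all-interactions
Tissue*Stage*Genotype permutational ANOVA.

Writes per amplicon: load_model.tsv and per-genotype summary.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import endostat as es
from endostat.io import read_asv_table, read_metadata

ROOT = Path(__file__).resolve().parents[1] / "results"


def run(amplicon: str) -> None:
    meta = read_metadata(ROOT / "data" / amplicon / "metadata.tsv")
    scaled = read_asv_table(ROOT / "preprocess" / amplicon / "scaled.tsv",
                            amplicon=amplicon, sample_ids=meta.sample_ids)
    load = es.microbial_load(scaled)
    plant = meta.frame[meta.frame["tissue"] != "soil"]
    load = load[[s for s in load.index if s in plant.index]]
    frame = plant.loc[load.index]
    log_load = np.log(load[load > 0])
    frame = frame.loc[log_load.index]

    model = es.ModelSpec.from_formula("tissue*stage*genotype", n_perm=199,
                                      seed=71)
    res = es.perm_anova_univariate(log_load, frame, model)
    out = ROOT / "load"
    out.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(out / f"load_model_{amplicon}.tsv", sep="\t")
    summary = (pd.DataFrame({"log_load": log_load,
                             "genotype": frame["genotype"]})
               .groupby("genotype", observed=True)["log_load"]
               .agg(["count", "mean", "std"]))
    summary.to_csv(out / f"load_by_genotype_{amplicon}.tsv", sep="\t")
    g = res.table.loc["genotype"]
    print(f"  {amplicon}: n = {len(log_load)}, genotype R2 = "
          f"{g['R2']:.4f}, p = {g['p']:.3f}")


def main() -> None:
    for amplicon in ("16S", "ITS1"):
        run(amplicon)


if __name__ == "__main__":
    main()
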