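#!/usr/bin/env python
"""Within-genotype dispersion: is any knockout's microbiome more variable?

PERMDISP2 on repeat-rarefied Bray-Curtis distances: distances to the
genotype spatial median in the PCoA embedding, tested by label permutation
with full recomputation.  Run once over all plant samples and once per
stage subset (the single-factor test cannot model interactions, so
subsetting stands in for them).

Writes per amplicon: permdisp.tsv (one row per subset).
"""

from pathlib import Path

import pandas as pd

import endostat as es
from endostat.io import read_asv_table, read_metadata

ROOT = Path(__file__).resolve().parents[1] / "results"
DEPTHS = {"16S": 1380, "ITS1": 751}


def run(amplicon: str) -> None:
    meta = read_metadata(ROOT / "data" / amplicon / "metadata.tsv")
    filtered = read_asv_table(ROOT / "preprocess" / amplicon / "filtered.tsv",
                              amplicon=amplicon, sample_ids=meta.sample_ids)
    scheme = es.RarefactionScheme(depth=DEPTHS[amplicon], iterations=25,
                                  seed=51)
    rarefied = es.repeat_rarefy_mean(filtered, scheme)
    dm = es.distance_matrix(rarefied, "bray_curtis")
    plant = meta.frame[meta.frame["tissue"] != "soil"]
    dm = dm.subset([s for s in dm.sample_ids if s in plant.index])

    rows = []
    subsets = [("all", plant.loc[dm.sample_ids])]
    for stage, sub in plant.loc[dm.sample_ids].groupby("stage",
                                                       observed=True):
        subsets.append((f"stage={stage}", sub))
    for name, sub in subsets:
        counts = sub["genotype"].value_counts()
        if (counts < 2).any() or len(counts) < 2:
            continue
        res = es.permdisp(dm.subset(sub.index), sub["genotype"],
                          n_perm=199, seed=53)
        row = res.table.iloc[0]
        rows.append({"subset": name, "n": len(sub), "F": row["F"],
                     "p": row["p"]})
        print(f"  {amplicon} {name}: n = {len(sub)}, F = {row['F']:.3f}, "
              f"p = {row['p']:.3f}")
    out = ROOT / "dispersion"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / f"permdisp_{amplicon}.tsv", sep="\t",
                              index=False)


def main() -> None:
    for amplicon in ("16S", "ITS1"):
        print(f"{amplicon}:")
        run(amplicon)


if __name__ == "__main__":
    main()
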