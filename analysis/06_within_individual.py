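#!/usr/bin/env python
"""Within-individual tissue specificity across genotypes and stages.

For each plant with a complete tissue set, the mean Bray-Curtis distance
from each tissue's community to the plant's median community measures how
homogeneous that individual's microbiome is.  Scores are compared with a
Stage*Genotype permutational ANOVA and pairwise stage post-hocs
(Benjamini-Hochberg).  Three tissue subsets: roots+rosettes (all stages),
aerial-without-siliques (flowering onwards), and all stage-present tissues.

Writes per amplicon and scheme: homogeneity_<scheme>.tsv, model and
post-hoc tables.
"""

from pathlib import Path

import endostat as es
from endostat.io import read_asv_table, read_metadata

ROOT = Path(__file__).resolve().parents[1] / "results"
SCHEMES = ("root_rosette", "aerial_no_siliques", "all_tissues")


def run(amplicon: str) -> None:
    meta = read_metadata(ROOT / "data" / amplicon / "metadata.tsv")
    table = read_asv_table(ROOT / "preprocess" / amplicon / "filtered.tsv",
                           amplicon=amplicon, sample_ids=meta.sample_ids)
    out = ROOT / "within_individual" / amplicon
    out.mkdir(parents=True, exist_ok=True)
    for scheme in SCHEMES:
        try:
            res = es.homogeneity_analysis(table, meta, scheme, n_perm=199,
                                          seed=61)
        except ValueError as exc:
            print(f"  {scheme}: skipped ({exc})")
            continue
        res.per_plant.to_csv(out / f"homogeneity_{scheme}.tsv", sep="\t")
        res.model_result.table.to_csv(out / f"model_{scheme}.tsv", sep="\t")
        res.stage_posthoc.to_csv(out / f"stage_posthoc_{scheme}.tsv",
                                 sep="\t", index=False)
        t = res.model_result.table
        msg = ", ".join(f"{term} p = {t.loc[term, 'p']:.3f}"
                        for term in t.index if ":" not in term)
        print(f"  {scheme}: {len(res.per_plant)} plants; {msg}")


def main() -> None:
    for amplicon in ("16S", "ITS1"):
        print(f"{amplicon}:")
        run(amplicon)


if __name__ == "__main__":
    main()
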