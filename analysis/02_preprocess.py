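#!/usr/bin/env python
"""Spike handling, admission, quality filtering and absolute scaling.

For each amplicon dataset: split the spike-in columns out of the table,
admit samples whose spike fraction lies in 20-80% of total reads, apply the
quality filter (>= 500 reads per sample, >= 10 reads per ASV dataset-wide),
and scale admitted samples to absolute abundance with the spike median.

Writes per amplicon: filtered.tsv (relative-scale counts), scaled.tsv
(absolute scale, admitted samples only), qc_report.tsv, load.tsv.
"""

from pathlib import Path

import pandas as pd

import endostat as es
from endostat.io import read_asv_table, read_metadata, read_spike_registry, write_asv_table
from endostat.preprocess import spike_median

ROOT = Path(__file__).resolve().parents[1] / "results"


def run(amplicon: str) -> None:
    d = ROOT / "data" / amplicon
    meta = read_metadata(d / "metadata.tsv")
    table = read_asv_table(d / "table.tsv", amplicon=amplicon,
                           sample_ids=meta.sample_ids)
    registry = read_spike_registry(d / "spikes.tsv")

    exp, spikes = es.split_spikes(table, registry)
    admitted, adm_report = es.spike_admission_filter(spikes, table.totals())
    filtered, qc = es.quality_filter(exp)
    med = spike_median(spikes, admitted)
    scale_ids = [s for s in filtered.sample_ids if s in set(admitted)]
    scaled = es.scale_by_spike(filtered.subset_samples(scale_ids), spikes, med)

    out = ROOT / "preprocess" / amplicon
    out.mkdir(parents=True, exist_ok=True)
    write_asv_table(filtered, out / "filtered.tsv")
    write_asv_table(scaled, out / "scaled.tsv")
    pd.concat([adm_report.to_frame(), qc.to_frame()]).to_csv(
        out / "qc_report.tsv", sep="\t", index=False)
    es.microbial_load(scaled).rename("load").to_csv(out / "load.tsv",
                                                    sep="\t")

    dep = filtered.totals()
    print(f"{amplicon}: {len(filtered.sample_ids)} samples pass quality "
          f"(median depth {dep.median():.0f}); "
          f"{len(scale_ids)} admitted to quantitation, spike median {med:g}; "
          f"{len(qc.dropped_samples)} samples and {len(qc.dropped_asvs)} "
          "ASVs dropped by the quality filter")


def main() -> None:
    for amplicon in ("16S", "ITS1"):
        run(amplicon)


if __name__ == "__main__":
    main()
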