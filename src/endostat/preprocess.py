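"""Spike-in handling, absolute-abundance scaling and quality filtering.

The spike-in design co-amplifies a known quantity of synthetic DNA with every
sample, so read counts can be placed on an absolute scale.  A sample is
admitted to quantitation only when its spike reads make up 20-80% of the
total (inclusive); outside that window the spike signal is too weak or too
dominant for reliable scaling.  Admitted samples are scaled by

    scaled = raw * spike_median / spike_sample

which leaves within-sample composition untouched (it is a per-sample scalar)
and makes row sums comparable across samples as microbial load.  The median
reference is computed over admitted samples by default, making the scale
factor robust to rejected outliers; the reference set is configurable.

Quality filtering drops low-depth samples first (default < 500 reads), then
rare ASVs by dataset-wide total (default < 10 reads); it operates on raw
counts, before any scaling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from endostat.io import AsvTable, SpikeRegistry


@dataclasses.dataclass
class QcReport:
    """What the preprocessing stage kept, dropped, and why.

    Each dropped sample/ASV carries exactly one primary reason.
    """

    spike_fraction: pd.Series | None = None
    admitted: pd.Index | None = None
    dropped_samples: dict[str, str] = dataclasses.field(default_factory=dict)
    dropped_asvs: dict[str, str] = dataclasses.field(default_factory=dict)
    warnings: list[str] = dataclasses.field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"item": s, "kind": "sample", "reason": r}
                for s, r in self.dropped_samples.items()]
        rows += [{"item": a, "kind": "asv", "reason": r}
                 for a, r in self.dropped_asvs.items()]
        return pd.DataFrame(rows, columns=["item", "kind", "reason"])


def split_spikes(table: AsvTable, registry: SpikeRegistry
                 ) -> tuple[AsvTable, pd.Series]:
    """Separate spike-in ASV columns from experimental ones.

    Returns the experimental table (spike columns removed) and the per-sample
    spike read count.  Per-sample totals are conserved exactly:
    experimental + spike = original.
    """
    spike_ids = [a for a in registry.ids_for(table.amplicon)
                 if a in table.counts.columns]
    spike_counts = (table.counts[spike_ids].sum(axis=1)
                    if spike_ids else
                    pd.Series(0.0, index=table.counts.index))
    exp = table.counts.drop(columns=spike_ids)
    return AsvTable(exp, table.amplicon), spike_counts


def spike_admission_filter(spike_counts: pd.Series, totals: pd.Series,
                           lo: float = 0.20, hi: float = 0.80
                           ) -> tuple[pd.Index, QcReport]:
    """Samples admitted to absolute quantitation: lo <= spike/total <= hi.

    Bounds inclusive.  ``totals`` are whole-sample totals (spike +
    experimental).  Zero-total samples are excluded with a reason rather than
    dividing by zero.
    """
    spike_counts, totals = spike_counts.align(totals, join="inner")
    report = QcReport()
    frac = pd.Series(np.nan, index=totals.index, dtype=float)
    ok = totals > 0
    frac[ok] = spike_counts[ok] / totals[ok]
    admitted = frac.index[(frac >= lo) & (frac <= hi)]
    for sid in totals.index[~ok]:
        report.dropped_samples[sid] = "zero total read count"
    for sid in frac.index[ok & ((frac < lo) | (frac > hi))]:
        report.dropped_samples[sid] = (
            f"spike fraction {frac[sid]:.3f} outside [{lo}, {hi}]"
        )
    report.spike_fraction = frac
    report.admitted = admitted
    return admitted, report


def spike_median(spike_counts: pd.Series,
                 reference: pd.Index | None = None) -> float:
    """Median spike read count over the reference set (admitted samples)."""
    s = spike_counts if reference is None else spike_counts.loc[reference]
    if len(s) == 0:
        raise ValueError("empty reference set for spike median")
    return float(s.median())


def scale_by_spike(experimental: AsvTable, spike_counts: pd.Series,
                   spike_median: float) -> AsvTable:
    """Scale each sample's counts by spike_median / spike_sample (absolute scale).

    Homogeneous of degree 1 per sample, so within-sample relative abundances
    are unchanged; row sums become comparable microbial loads.
    """
    if spike_median <= 0:
        raise ValueError(f"spike_median must be > 0, got {spike_median}")
    sc = spike_counts.reindex(experimental.counts.index)
    if sc.isna().any():
        missing = sc.index[sc.isna()].tolist()
        raise ValueError(f"no spike count for sample(s): {missing}")
    if (sc <= 0).any():
        zero = sc.index[sc <= 0].tolist()
        raise ValueError(
            f"cannot quantify sample(s) with zero spike reads: {zero}"
        )
    scaled = experimental.counts.mul(spike_median / sc, axis=0)
    return AsvTable(scaled, experimental.amplicon)


def quality_filter(table: AsvTable, min_sample_reads: float = 500,
                   min_asv_reads: float = 10) -> tuple[AsvTable, QcReport]:
    """Drop low-depth samples, then dataset-rare ASVs, in that fixed order.

    Samples with total < ``min_sample_reads`` go first; ASV totals are then
    recomputed over the surviving samples and ASVs with dataset-wide total
    < ``min_asv_reads`` are dropped.  Intended for raw (pre-scaling) counts.
    """
    report = QcReport()
    totals = table.counts.sum(axis=1)
    keep_samples = totals >= min_sample_reads
    for sid in totals.index[~keep_samples]:
        report.dropped_samples[sid] = (
            f"sample total {totals[sid]:g} < {min_sample_reads:g}"
        )
    kept = table.counts.loc[keep_samples]
    asv_totals = kept.sum(axis=0)
    keep_asvs = asv_totals >= min_asv_reads
    for aid in asv_totals.index[~keep_asvs]:
        report.dropped_asvs[aid] = (
            f"ASV total {asv_totals[aid]:g} < {min_asv_reads:g}"
        )
    kept = kept.loc[:, keep_asvs]
    if kept.empty:
        report.warnings.append("quality filter removed every sample or ASV")
    return AsvTable(kept, table.amplicon), report


def microbial_load(scaled: AsvTable) -> pd.Series:
    """Per-sample microbial load: the row sum of the spike-scaled table."""
    return scaled.counts.sum(axis=1)
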