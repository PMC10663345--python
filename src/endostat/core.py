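"""Core-microbiome membership rules.

Three definitions of the "core" taxa of a plant endosphere survey:

* **Core A** — a global core: ASVs reaching at least 0.5% relative abundance
  in four or more samples anywhere in the dataset.
* **Core B** — a tissue-and-stage-aware core: ASVs reaching at least 1%
  relative abundance in at least 20% of the samples of at least one
  tissue x stage subset (so taxa abundant only in, say, ripe-silique tissue
  still qualify).
* **Indicator Core** — ASVs statistically enriched in plant tissue relative
  to the surrounding bulk soil, by indicator-species analysis (IndVal) with a
  group-label permutation test.

All "at least" thresholds are inclusive.  Relative abundance is computed
against the per-sample total of the table handed in (normally the
quality-filtered table).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from endostat.io import AsvTable, SampleMetadata

logger = logging.getLogger(__name__)


def core_a(table: AsvTable, min_rel_abund: float = 0.005,
           min_samples: int = 4) -> list[str]:
    """ASVs at >= ``min_rel_abund`` relative abundance in >= ``min_samples``
    samples across the whole dataset."""
    rel = table.relative().to_numpy()
    hits = (rel >= min_rel_abund).sum(axis=0)
    keep = hits >= min_samples
    return [a for a, k in zip(table.asv_ids, keep) if k]


def core_b(table: AsvTable, metadata: SampleMetadata,
           min_rel_abund: float = 0.01,
           min_prevalence: float = 0.20) -> list[str]:
    """ASVs at >= ``min_rel_abund`` in >= ``min_prevalence`` of the samples of
    at least one tissue x stage subset."""
    rel = table.relative()
    meta = metadata.loc(table.sample_ids)
    keep = np.zeros(len(table.asv_ids), dtype=bool)
    for (tissue, stage), sub in meta.groupby(["tissue", "stage"],
                                             dropna=False, observed=True):
        if len(sub) == 0:
            logger.info("empty tissue=%s stage=%s subset skipped", tissue, stage)
            continue
        hits = (rel.loc[sub.index].to_numpy() >= min_rel_abund).sum(axis=0)
        keep |= hits / len(sub) >= min_prevalence
    return [a for a, k in zip(table.asv_ids, keep) if k]


@dataclasses.dataclass
class IndvalResult:
    """Per-ASV indicator statistics: best group, IndVal, permutation p."""

    frame: pd.DataFrame  # index asv_id; columns stat, best_group, p_value
    n_perm: int


def _indval_stats(mat: np.ndarray, group_masks: list[np.ndarray],
                  group_correction: bool) -> tuple[np.ndarray, np.ndarray]:
    """IndVal per ASV: max over groups of sqrt(A_g * B_g).

    A_g (specificity) = mean abundance in g over the sum of group means
    (default); B_g (fidelity) = fraction of g's samples where the ASV is
    present.  ``group_correction=True`` switches A to group totals, which
    weights specificity by group size (useful with strongly unbalanced
    groups).
    """
    means = np.stack([
        (mat[m].sum(axis=0) if group_correction else mat[m].mean(axis=0))
        for m in group_masks
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        a = means / means.sum(axis=0, keepdims=True)
    b = np.stack([(mat[m] > 0).mean(axis=0) for m in group_masks])
    iv = np.sqrt(np.where(np.isnan(a), 0.0, a) * b)
    best = iv.argmax(axis=0)
    stat = iv.max(axis=0)
    absent = mat.sum(axis=0) <= 0
    stat[absent] = np.nan
    return stat, best


def indval(table: AsvTable, groups: pd.Series, n_perm: int = 999,
           seed: int = 0, exact: bool = False,
           group_correction: bool = False) -> IndvalResult:
    """Indicator-species analysis with a permutation test on group labels.

    ``groups`` assigns each sample a group label (>= 2 non-empty groups).
    The permutation p-value uses the add-one estimator
    p = (1 + #{IndVal* >= IndVal}) / (1 + n_perm); with ``exact=True`` every
    distinct label ordering is enumerated instead (small n only) and
    p = #{IndVal* >= IndVal} / #orderings, the identity ordering included.
    """
    groups = groups.reindex(table.sample_ids)
    if groups.isna().any():
        bad = groups.index[groups.isna()].tolist()
        raise ValueError(f"samples without a group label: {bad}")
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("indval requires >= 2 groups")
    labels = groups.to_numpy()
    mat = table.matrix
    masks = [labels == lv for lv in levels]
    if any(m.sum() == 0 for m in masks):
        raise ValueError("every group must be non-empty")
    stat, best = _indval_stats(mat, masks, group_correction)

    def stats_for(perm_labels: np.ndarray) -> np.ndarray:
        pm = [perm_labels == lv for lv in levels]
        s, _ = _indval_stats(mat, pm, group_correction)
        return s

    valid = ~np.isnan(stat)
    if exact:
        orderings = set(itertools.permutations(labels))
        exceed = np.zeros(mat.shape[1])
        for perm in orderings:
            s = stats_for(np.asarray(perm, dtype=object))
            exceed += (s >= stat - 1e-12) & valid
        p = exceed / len(orderings)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(mat.shape[1])
        for _ in range(n_perm):
            s = stats_for(rng.permutation(labels))
            exceed += (s >= stat - 1e-12) & valid
        p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.where(valid, p, np.nan)
    frame = pd.DataFrame({
        "stat": stat,
        "best_group": [levels[b] if v else pd.NA for b, v in zip(best, valid)],
        "p_value": p,
    }, index=pd.Index(table.asv_ids, name="asv_id"))
    return IndvalResult(frame, n_perm if not exact else len(orderings))


def indicator_core(table: AsvTable, metadata: SampleMetadata,
                   alpha: float = 0.05, n_perm: int = 999, seed: int = 0,
                   bh_correct: bool = False) -> list[str]:
    """ASVs whose best indicator group is the plant (vs bulk soil) at
    permutation p <= alpha.

    Multiple testing across ASVs is uncorrected by default;
    ``bh_correct=True`` applies Benjamini-Hochberg across the tested ASVs.
    """
    meta = metadata.loc(table.sample_ids)
    groups = pd.Series(
        np.where(meta["tissue"] == "soil", "soil", "plant"),
        index=meta.index,
    )
    if (groups == "soil").sum() == 0:
        raise ValueError("indicator core requires soil samples")
    if (groups == "plant").sum() == 0:
        raise ValueError("indicator core requires plant samples")
    res = indval(table, groups, n_perm=n_perm, seed=seed)
    frame = res.frame.dropna(subset=["stat"])
    p = frame["p_value"].to_numpy()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    keep = (frame["best_group"] == "plant") & (p <= alpha)
    return frame.index[keep].tolist()
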