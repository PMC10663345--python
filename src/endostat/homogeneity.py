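"""Within-individual tissue homogeneity.

How alike are the microbial communities of one plant's tissues?  For each
plant with a complete set of the scheme's required tissues, Bray-Curtis
distances among its tissue samples are embedded by principal coordinates,
the plant's "median community" (spatial median in the embedding) is found,
and the mean corrected distance from each tissue to that median is the
plant's homogeneity score — small means tissues carry similar communities.
Scores are then compared across genotypes and developmental stages with a
univariate permutational ANOVA (Stage*Genotype) plus pairwise stage
post-hocs under Benjamini-Hochberg correction.

Tissue subset schemes:

* ``all_tissues`` — every tissue present at the plant's stage;
* ``root_rosette`` — root and rosette only (defined at every stage);
* ``aerial_no_siliques`` — rosette, stem, cauline leaf and flower
  (above-ground selective pressures, excluding siliques).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from endostat.io import AsvTable, DistanceMatrix, SampleMetadata, TISSUES_BY_STAGE
from endostat.diversity import distance_matrix
from endostat.permstats import (
    ModelSpec,
    PermTestResult,
    corrected_distances_to_center,
    pcoa_embed,
    perm_anova_univariate,
    permanova_pairwise,
    spatial_median,
)

SCHEMES = ("all_tissues", "root_rosette", "aerial_no_siliques")

_SCHEME_TISSUES = {
    "root_rosette": ("root", "rosette"),
    "aerial_no_siliques": ("rosette", "stem", "cauline_leaf", "flower"),
}


def required_tissues(scheme: str, stage: str) -> tuple[str, ...]:
    if scheme == "all_tissues":
        return TISSUES_BY_STAGE[stage]
    try:
        return _SCHEME_TISSUES[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def select_complete_plants(metadata: SampleMetadata, scheme: str) -> list[str]:
    """Plants having every tissue the scheme requires (for ``all_tissues``,
    every tissue present at the plant's stage)."""
    meta = metadata.frame[metadata.frame["tissue"] != "soil"]
    plants = []
    for plant_id, sub in meta.groupby("plant_id"):
        stage = sub["stage"].iloc[0]
        req = set(required_tissues(scheme, stage))
        if req <= set(sub["tissue"]):
            plants.append(str(plant_id))
    return sorted(plants)


def plant_homogeneity(dm: DistanceMatrix) -> float:
    """Mean corrected distance of one plant's tissues to the plant's median
    community (spatial median in the PCoA embedding of ``dm``)."""
    if len(dm) < 2:
        raise ValueError("plant homogeneity requires >= 2 tissue samples")
    emb = pcoa_embed(dm)
    idx = np.arange(len(dm))
    c_re = spatial_median(emb.real) if emb.real.size else np.zeros(0)
    c_im = spatial_median(emb.imaginary) if emb.imaginary.size else np.zeros(0)
    return float(corrected_distances_to_center(emb, idx, c_re, c_im).mean())


@dataclasses.dataclass
class HomogeneityAnalysis:
    """Per-plant homogeneity scores plus the Stage*Genotype test."""

    per_plant: pd.DataFrame
    model_result: PermTestResult
    stage_posthoc: pd.DataFrame


def homogeneity_table(table: AsvTable, metadata: SampleMetadata,
                      scheme: str, metric: str = "bray_curtis",
                      global_embedding: bool = False) -> pd.DataFrame:
    """Per-plant homogeneity scores for one tissue-subset scheme.

    Default geometry is per-plant: each plant's tissues are embedded from
    their own Bray-Curtis distances.  ``global_embedding=True`` instead
    embeds all selected samples at once and takes each plant's spatial
    median in that shared ordination (sensitivity variant).
    """
    plants = select_complete_plants(metadata, scheme)
    if not plants:
        raise ValueError(f"no plant has all tissues of scheme {scheme!r}")
    meta = metadata.frame
    meta = meta[meta["tissue"] != "soil"]
    rows = []
    sample_sets: dict[str, list[str]] = {}
    for plant_id in plants:
        sub = meta[meta["plant_id"] == plant_id]
        stage = sub["stage"].iloc[0]
        req = required_tissues(scheme, stage)
        sids = [sub.index[sub["tissue"] == t][0] for t in req]
        present = [s for s in sids if s in table.counts.index]
        if len(present) < len(sids):
            continue  # a required tissue was filtered out of the table
        sample_sets[plant_id] = present
        rows.append({"plant_id": plant_id,
                     "genotype": sub["genotype"].iloc[0],
                     "stage": stage, "n_tissues": len(present)})
    if not rows:
        raise ValueError(f"no plant retains all tissues of scheme {scheme!r} "
                         "in the abundance table")
    frame = pd.DataFrame(rows).set_index("plant_id")

    if global_embedding:
        all_sids = [s for sids in sample_sets.values() for s in sids]
        dm = distance_matrix(table.subset_samples(all_sids), metric)
        emb = pcoa_embed(dm)
        pos = {s: i for i, s in enumerate(dm.sample_ids)}
        scores = {}
        for plant_id, sids in sample_sets.items():
            idx = np.asarray([pos[s] for s in sids])
            c_re = (spatial_median(emb.real[idx])
                    if emb.real.size else np.zeros(0))
            c_im = (spatial_median(emb.imaginary[idx])
                    if emb.imaginary.size else np.zeros(0))
            scores[plant_id] = float(
                corrected_distances_to_center(emb, idx, c_re, c_im).mean())
    else:
        scores = {
            plant_id: plant_homogeneity(
                distance_matrix(table.subset_samples(sids), metric))
            for plant_id, sids in sample_sets.items()
        }
    frame["mean_distance_to_median"] = pd.Series(scores)
    return frame


def homogeneity_analysis(table: AsvTable, metadata: SampleMetadata,
                         scheme: str, n_perm: int = 999, seed: int = 0,
                         metric: str = "bray_curtis",
                         global_embedding: bool = False
                         ) -> HomogeneityAnalysis:
    """Within-individual homogeneity compared across stages and genotypes.

    Runs the per-plant scoring, a Stage*Genotype univariate permutational
    ANOVA on the scores, and pairwise stage post-hocs with Benjamini-Hochberg
    correction.
    """
    frame = homogeneity_table(table, metadata, scheme, metric=metric,
                              global_embedding=global_embedding)
    cells = frame.groupby(["stage", "genotype"], observed=True).size()
    if (cells < 2).any():
        bad = cells[cells < 2].index.tolist()
        raise ValueError(
            f"stage x genotype cell(s) with fewer than 2 plants: {bad}"
        )
    resp = frame["mean_distance_to_median"]
    multi_stage = frame["stage"].nunique() > 1
    formula = "stage * genotype" if multi_stage else "genotype"
    model = ModelSpec.from_formula(formula, n_perm=n_perm, seed=seed)
    result = perm_anova_univariate(resp, frame, model)

    if multi_stage:
        vals = resp.to_numpy()
        d = np.abs(vals[:, None] - vals[None, :])
        dm = DistanceMatrix(list(resp.index), d)
        posthoc = permanova_pairwise(dm, frame, "stage",
                                     n_perm=n_perm, seed=seed)
    else:
        posthoc = pd.DataFrame(columns=["level_a", "level_b", "n_a", "n_b",
                                        "SS", "R2", "F", "p", "p_adjusted"])
    return HomogeneityAnalysis(frame, result, posthoc)
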