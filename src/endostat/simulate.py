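"""Synthetic ASV datasets with the statistical structure of a field
endophyte survey.

The generator emulates a five-genotype (WT + four receptor knockouts)
Arabidopsis field experiment: plants are harvested at four developmental
stages, each plant yielding one sample per tissue present at its stage
(a Vegetative plant has only a root and a rosette; all seven tissues exist
only at the final, ripe-silique stage).  Counts are Dirichlet-multinomial
around a per-cell expected composition built additively in log space:

    log-composition = baseline + tissue + stage + genotype + plant + batch

where the genotype term is a planted log-fold change on a chosen fraction of
taxa in chosen tissue x stage cells (so a localized genotype signal, like a
single-mutant effect confined to one stage, can be planted and recovered),
the plant term is shared across all of one plant's tissues (inducing the
within-individual correlation the homogeneity analysis measures), and batch
terms follow a plate-nested-in-run structure.  Library sizes are log-normal
over roughly three orders of magnitude; synthetic spike-in reads are appended
as dedicated ASV columns to reach a per-sample spike fraction drawn from a
configured range, so spike detection and admission code paths are exercised.
Bulk-soil samples are drawn from their own community so plant-vs-soil
indicator analysis has a real contrast.

A random bifurcating tree with exponential branch lengths is produced for
16S-like tables only (tree-based metrics are not defined for ITS1 here).
All randomness flows from a single integer seed; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from endostat.io import (
    AsvTable,
    SampleMetadata,
    SpikeRegistry,
    GENOTYPES,
    STAGES,
    TISSUES_BY_STAGE,
)

#: whole plants harvested per genotype at each stage in the emulated design
DEFAULT_PLANTS_PER_STAGE: Mapping[str, int] = {
    "Vegetative": 8,
    "Flowering": 8,
    "UnripeSiliques": 18,
    "RipeSiliques": 8,
}


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic dataset generator.

    Effect scales are standard deviations of per-taxon Gaussian effects on
    the log-composition scale; ``genotype_effect`` is a deterministic
    log-fold change applied to a random ``affected_fraction`` of taxa, for
    ``target_genotype`` only, in the listed ``target_cells``
    ``(tissue, stage)`` pairs.
    """

    seed: int = 0
    amplicon: str = "16S"
    n_asvs: int = 150
    n_spike_asvs: int = 2
    n_plants_per_genotype_per_stage: int | Mapping[str, int] | None = None
    stages: Sequence[str] = STAGES
    tissues: Sequence[str] | None = None  # optional restriction within stages
    genotypes: Sequence[str] = GENOTYPES
    n_soil_samples: int = 8
    # composition model
    baseline_concentration: float = 0.3      # symmetric Dirichlet for baseline
    tissue_effect_sd: float = 1.0
    stage_effect_sd: float = 0.6
    genotype_effect: float = 0.0             # planted log-fold change
    affected_fraction: float = 0.1
    target_genotype: str = "lore"
    target_cells: Sequence[tuple[str, str]] = ()
    plant_effect_sd: float = 0.3
    run_effect_sd: float = 0.1
    plate_effect_sd: float = 0.1
    soil_effect_sd: float = 1.5
    dm_concentration: float = 30.0           # Dirichlet-multinomial overdispersion
    # depth and spike-in regime
    depth_log10_mean: float = 3.6
    depth_log10_sd: float = 0.5
    min_depth: int = 20
    spike_fraction_range: tuple[float, float] = (0.2, 0.8)
    # batch structure
    n_runs: int = 2
    n_plates_per_run: int = 2
    # tree
    branch_length_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_plants_per_genotype_per_stage is None:
            self.n_plants_per_genotype_per_stage = dict(DEFAULT_PLANTS_PER_STAGE)
        lo, hi = self.spike_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(
                f"spike_fraction_range must lie inside (0, 1); got {(lo, hi)}"
            )
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must be in [0, 1]")
        for name in ("tissue_effect_sd", "stage_effect_sd", "plant_effect_sd",
                     "run_effect_sd", "plate_effect_sd", "soil_effect_sd",
                     "dm_concentration", "baseline_concentration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if self.tissues is not None:
            known = {t for ts in TISSUES_BY_STAGE.values() for t in ts}
            bad = set(self.tissues) - known
            if bad:
                raise ValueError(f"unknown tissue(s) {sorted(bad)}")

    def n_plants(self, stage: str) -> int:
        npp = self.n_plants_per_genotype_per_stage
        return npp[stage] if isinstance(npp, Mapping) else int(npp)

    def cell_tissues(self, stage: str) -> tuple[str, ...]:
        avail = TISSUES_BY_STAGE[stage]
        if self.tissues is None:
            return avail
        return tuple(t for t in avail if t in self.tissues)


class _SimModel:
    """All dataset-level random draws, deterministic in the config seed.

    Split from the sampling loop so tests can query the exact generating
    composition of any design cell.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.n_asvs
        if np.isinf(config.baseline_concentration):
            base = np.full(k, 1.0 / k)  # flat baseline, no draw
        else:
            base = rng.dirichlet(np.full(k, config.baseline_concentration))
            base = np.clip(base, 1e-12, None)
        self.log_baseline = np.log(base / base.sum())
        all_tissues = sorted({t for ts in TISSUES_BY_STAGE.values() for t in ts})
        self.tissue_eff = {
            t: rng.normal(0.0, config.tissue_effect_sd, k) for t in all_tissues
        }
        self.stage_eff = {
            s: rng.normal(0.0, config.stage_effect_sd, k) for s in STAGES
        }
        self.soil_eff = rng.normal(0.0, config.soil_effect_sd, k)
        n_aff = int(round(config.affected_fraction * k))
        self.affected_taxa = np.sort(rng.choice(k, size=n_aff, replace=False))
        self.genotype_delta = np.zeros(k)
        self.genotype_delta[self.affected_taxa] = config.genotype_effect
        self.run_eff = {
            f"run{r + 1}": rng.normal(0.0, config.run_effect_sd, k)
            for r in range(config.n_runs)
        }
        self.plate_eff = {
            (f"run{r + 1}", f"plate{r + 1}.{p + 1}"):
                rng.normal(0.0, config.plate_effect_sd, k)
            for r in range(config.n_runs)
            for p in range(config.n_plates_per_run)
        }
        self.rng = rng  # continues into the sampling loop

    def cell_log_composition(self, genotype: str, tissue: str, stage: str
                             ) -> np.ndarray:
        eta = (self.log_baseline
               + self.tissue_eff[tissue]
               + self.stage_eff[stage])
        if (genotype == self.config.target_genotype
                and (tissue, stage) in set(map(tuple, self.config.target_cells))):
            eta = eta + self.genotype_delta
        return eta


def _softmax(eta: np.ndarray) -> np.ndarray:
    p = np.exp(eta - eta.max())
    return p / p.sum()


def expected_cell_composition(config: SimConfig, genotype: str, tissue: str,
                              stage: str) -> np.ndarray:
    """Generating composition of a design cell at zero plant/batch effects.

    Equals the softmax of the configured log-effects; with plant and batch
    scales set to zero this is exactly the mean multinomial probability of a
    sample in the cell.
    """
    if stage not in config.stages:
        raise ValueError(f"stage {stage!r} not in configured design")
    if tissue not in config.cell_tissues(stage):
        raise ValueError(
            f"tissue {tissue!r} is not harvested at stage {stage!r} in this design"
        )
    if genotype not in config.genotypes:
        raise ValueError(f"genotype {genotype!r} not in configured design")
    model = _SimModel(config)
    return _softmax(model.cell_log_composition(genotype, tissue, stage))


def _random_tree(asv_ids: Sequence[str], rng: np.random.Generator,
                 scale: float) -> TreeNode:
    """Random rooted bifurcating tree by repeated joining of random pairs,
    exponential branch lengths."""
    nodes = [TreeNode(name=a) for a in asv_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(scale))
        right.length = float(rng.exponential(scale))
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _draw_counts(eta: np.ndarray, depth: int, conc: float,
                 rng: np.random.Generator) -> np.ndarray:
    p = _softmax(eta)
    if conc > 0:
        alpha = np.clip(conc * p, 1e-12, None)
        q = rng.dirichlet(alpha)
        tot = q.sum()
        q = q / tot if tot > 0 and np.isfinite(tot) else p
    else:
        q = p
    return rng.multinomial(depth, q)


def simulate_dataset(config: SimConfig
                     ) -> tuple[AsvTable, SampleMetadata, SpikeRegistry,
                                TreeNode | None]:
    """Generate one ASV table with metadata, spike registry and (16S) tree.

    One sample per (plant, tissue); tissues follow the stage design; spike
    reads appended per sample to land its spike fraction inside the
    configured range; fully reproducible from ``config.seed``.
    """
    model = _SimModel(config)
    rng = model.rng
    cfg = config
    k = cfg.n_asvs
    asv_ids = [f"asv{i + 1:04d}" for i in range(k)]
    spike_ids = [f"spike{i + 1}" for i in range(cfg.n_spike_asvs)]

    runs = list(model.run_eff)
    plates = {r: [pl for (rr, pl) in model.plate_eff if rr == r] for r in runs}

    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    sample_ids: list[str] = []
    lo, hi = cfg.spike_fraction_range

    def _batch() -> tuple[str, str, np.ndarray]:
        r = runs[int(rng.integers(len(runs)))]
        pl = plates[r][int(rng.integers(len(plates[r])))]
        return r, pl, model.run_eff[r] + model.plate_eff[(r, pl)]

    def _emit(eta: np.ndarray, sid: str, meta: dict) -> None:
        depth = max(cfg.min_depth,
                    int(round(10 ** rng.normal(cfg.depth_log10_mean,
                                               cfg.depth_log10_sd))))
        counts = _draw_counts(eta, depth, cfg.dm_concentration, rng)
        f = rng.uniform(lo, hi)
        spike_total = int(round(depth * f / (1.0 - f)))
        if cfg.n_spike_asvs > 0:
            spikes = rng.multinomial(
                spike_total, np.full(cfg.n_spike_asvs, 1.0 / cfg.n_spike_asvs))
        else:
            spikes = np.zeros(0, dtype=int)
        rows.append(np.concatenate([counts, spikes]))
        sample_ids.append(sid)
        meta_rows.append(meta)

    for stage in cfg.stages:
        for genotype in cfg.genotypes:
            for rep in range(cfg.n_plants(stage)):
                plant_id = f"{stage}_{genotype}_p{rep + 1}"
                plant_eff = rng.normal(0.0, cfg.plant_effect_sd, k)
                for tissue in cfg.cell_tissues(stage):
                    run, plate, batch_eff = _batch()
                    eta = (model.cell_log_composition(genotype, tissue, stage)
                           + plant_eff + batch_eff)
                    sid = f"{plant_id}_{tissue}"
                    _emit(eta, sid, {
                        "sample_id": sid, "plant_id": plant_id,
                        "genotype": genotype, "tissue": tissue, "stage": stage,
                        "run": run, "plate": plate, "amplicon": cfg.amplicon,
                    })

    for i in range(cfg.n_soil_samples):
        run, plate, batch_eff = _batch()
        eta = model.log_baseline + model.soil_eff + batch_eff
        sid = f"soil_s{i + 1}"
        _emit(eta, sid, {
            "sample_id": sid, "plant_id": pd.NA, "genotype": pd.NA,
            "tissue": "soil", "stage": pd.NA,
            "run": run, "plate": plate, "amplicon": cfg.amplicon,
        })

    counts = pd.DataFrame(np.vstack(rows), index=sample_ids,
                          columns=asv_ids + spike_ids, dtype=float)
    table = AsvTable(counts, cfg.amplicon)
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    registry = SpikeRegistry({cfg.amplicon: tuple(spike_ids)})
    tree = None
    if cfg.amplicon == "16S":
        tree = _random_tree(asv_ids, rng, cfg.branch_length_scale)
    return table, metadata, registry, tree
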