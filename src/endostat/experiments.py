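"""Calibration and power experiments over the synthetic generator.

These functions express the package's standing claims about its statistics
as runnable experiments: under a null generator the permutation tests reject
at the nominal rate, and a planted, cell-confined genotype effect is
recovered by subset PERMANOVA while untouched cells stay at the nominal
rate.  They are used by the test suite and the reproduction script; the
analysis drivers tell the same story at narrative scale.
"""

from __future__ import annotations

import numpy as np

from endostat.diversity import RarefactionScheme, distance_matrix, repeat_rarefy_mean
from endostat.permstats import ModelSpec, permanova, permdisp
from endostat.preprocess import quality_filter, split_spikes
from endostat.simulate import SimConfig, simulate_dataset


def null_cell_config(seed: int) -> SimConfig:
    """One 40-sample null design cell: root tissue at the Vegetative stage,
    8 plants for each of the 5 genotypes, no genotype effect."""
    return SimConfig(seed=seed, stages=["Vegetative"], tissues=["root"],
                     n_plants_per_genotype_per_stage=8, n_soil_samples=0,
                     genotype_effect=0.0)


def effect_cell_config(seed: int, log_fold: float = np.log(4),
                       affected_fraction: float = 0.10,
                       n_per_genotype: int = 15) -> SimConfig:
    """A mature-silique / ripe-stage cell with a planted lore effect,
    emulating a single-genotype fungal signal confined to one
    tissue x stage cell (ITS1-like, no tree)."""
    return SimConfig(seed=seed, amplicon="ITS1", stages=["RipeSiliques"],
                     tissues=["mature_silique"],
                     n_plants_per_genotype_per_stage=n_per_genotype,
                     n_soil_samples=0, genotype_effect=log_fold,
                     affected_fraction=affected_fraction,
                     target_genotype="lore",
                     target_cells=[("mature_silique", "RipeSiliques")])


# permutation/rarefaction streams are decoupled from the data seed: reusing
# one seed would replay the very stream that generated the data, making the
# permutations data-dependent
_PERM_OFFSET = 1_000_003
_RAREFY_OFFSET = 2_000_003


def _genotype_p(config: SimConfig, n_perm: int, seed: int,
                rarefy_depth: int | None, rarefy_iters: int) -> float:
    table, meta, registry, _ = simulate_dataset(config)
    exp, _spikes = split_spikes(table, registry)
    if rarefy_depth is not None:
        filtered, _ = quality_filter(exp)
        data = repeat_rarefy_mean(
            filtered, RarefactionScheme(depth=rarefy_depth,
                                        iterations=rarefy_iters,
                                        seed=seed + _RAREFY_OFFSET))
    else:
        data = exp
    dm = distance_matrix(data, "bray_curtis")
    frame = meta.frame.loc[dm.sample_ids]
    res = permanova(dm, frame,
                    ModelSpec(["genotype"], n_perm=n_perm,
                              seed=seed + _PERM_OFFSET))
    return float(res.table["p"].iloc[0])


def null_rejection_rates(n_datasets: int = 500, n_perm: int = 199,
                         alpha: float = 0.05, first_seed: int = 1
                         ) -> dict[str, float]:
    """Genotype rejection rates of PERMANOVA and PERMDISP over null
    datasets (seeds first_seed .. first_seed + n_datasets - 1)."""
    rej_perm = rej_disp = 0
    for i in range(n_datasets):
        seed = first_seed + i
        table, meta, registry, _ = simulate_dataset(null_cell_config(seed))
        exp, _spikes = split_spikes(table, registry)
        dm = distance_matrix(exp, "bray_curtis")
        frame = meta.frame.loc[dm.sample_ids]
        p_perm = permanova(
            dm, frame, ModelSpec(["genotype"], n_perm=n_perm,
                                 seed=seed + _PERM_OFFSET)).table["p"].iloc[0]
        p_disp = permdisp(dm, frame["genotype"], n_perm=n_perm,
                          seed=seed + 2 * _PERM_OFFSET).table["p"].iloc[0]
        rej_perm += p_perm <= alpha
        rej_disp += p_disp <= alpha
    return {
        "permanova_rate": rej_perm / n_datasets,
        "permdisp_rate": rej_disp / n_datasets,
        "n_datasets": n_datasets,
    }


def planted_effect_power(n_simulations: int = 100, n_perm: int = 199,
                         alpha: float = 0.05, first_seed: int = 1,
                         rarefy_depth: int = 751, rarefy_iters: int = 50
                         ) -> dict[str, float]:
    """Rejection rates of the cell-subset genotype PERMANOVA with a planted
    ln(4) effect versus the matching zero-effect cell.

    The analysis pipeline is the one applied to the data proper: quality
    filter, repeat-rarefy to the ITS1 depth, Bray-Curtis, PERMANOVA.
    """
    rej_effect = rej_null = 0
    for i in range(n_simulations):
        seed = first_seed + i
        p = _genotype_p(effect_cell_config(seed), n_perm, seed,
                        rarefy_depth, rarefy_iters)
        rej_effect += p <= alpha
        null_cfg = effect_cell_config(seed + 500_000, log_fold=0.0)
        p0 = _genotype_p(null_cfg, n_perm, seed, rarefy_depth, rarefy_iters)
        rej_null += p0 <= alpha
    return {
        "power": rej_effect / n_simulations,
        "null_cell_rate": rej_null / n_simulations,
        "n_simulations": n_simulations,
    }


def effect_size_r2(seed: int = 1, n_perm: int = 199,
                   rarefy_depth: int = 751, rarefy_iters: int = 50) -> float:
    """Genotype R^2 of one planted-effect cell under the full pipeline."""
    cfg = effect_cell_config(seed)
    table, meta, registry, _ = simulate_dataset(cfg)
    exp, _spikes = split_spikes(table, registry)
    filtered, _ = quality_filter(exp)
    mean = repeat_rarefy_mean(
        filtered, RarefactionScheme(depth=rarefy_depth,
                                    iterations=rarefy_iters,
                                    seed=seed + _RAREFY_OFFSET))
    dm = distance_matrix(mean, "bray_curtis")
    res = permanova(dm, meta.frame.loc[dm.sample_ids],
                    ModelSpec(["genotype"], n_perm=n_perm,
                              seed=seed + _PERM_OFFSET))
    return float(res.table["R2"].iloc[0])
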