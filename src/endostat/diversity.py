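"""Repeated rarefaction, alpha diversity, compositional transforms and
beta-diversity metrics.

Rarefaction draws without replacement (multivariate hypergeometric) to a
fixed depth; because depth varies over orders of magnitude in amplicon
surveys, a single rarefaction discards information, so tables are rarefied
repeatedly (default 100 times) and the entrywise mean table is used
downstream.  Alpha metrics (Shannon, Pielou, Faith's PD and a
richness-corrected PD) are computed after each iteration and averaged.

Two compositional log-ratio transforms are provided: the robust CLR (centre
each sample's log abundances over its nonzero entries; zeros stay missing)
and the ALR against the spike-in reference (log count over spike reads,
which is an absolute-scale log abundance up to the spike calibration).

All logarithms are natural.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import TreeNode

from endostat.io import AsvTable, DistanceMatrix


class InsufficientDepthError(ValueError):
    """A sample's total is below the rarefaction depth; it must be excluded,
    never zero-filled."""


@dataclasses.dataclass
class RarefactionScheme:
    """Depth, iteration count and seed of a repeated-rarefaction run.

    Default depths follow the emulated survey: 1380 reads for 16S, 751 for
    ITS1 (pass ``depth=751`` for ITS1-like tables).
    """

    depth: int = 1380
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def rarefy_once(counts: np.ndarray, depth: int,
                rng: np.random.Generator) -> np.ndarray:
    """One draw without replacement to ``depth`` reads.

    Multivariate hypergeometric: the output sums exactly to ``depth`` and its
    support is contained in the input support.
    """
    c = np.asarray(counts)
    ci = np.round(c).astype(np.int64)
    if not np.allclose(c, ci):
        raise ValueError("rarefaction requires integer counts")
    total = int(ci.sum())
    if total < depth:
        raise InsufficientDepthError(
            f"sample total {total} < rarefaction depth {depth}"
        )
    return rng.multivariate_hypergeometric(ci, depth)


def _sample_rng(seed: int, iteration: int, sample_index: int
                ) -> np.random.Generator:
    # one independent stream per (iteration, sample): reproducible under
    # any execution order
    return np.random.default_rng([seed, iteration, sample_index])


def rarefiable_samples(table: AsvTable, depth: int) -> list[str]:
    tot = table.totals()
    return list(tot.index[tot >= depth])


def repeat_rarefy_mean(table: AsvTable, scheme: RarefactionScheme) -> AsvTable:
    """Entrywise mean of repeated rarefactions; every row sums to depth.

    Samples whose total is below the depth are excluded from the result (the
    caller sees the exclusion as a smaller sample set, never as zero-filled
    rows).
    """
    keep = rarefiable_samples(table, scheme.depth)
    sub = table.counts.loc[keep]
    acc = np.zeros(sub.shape, dtype=float)
    mat = sub.to_numpy()
    for it in range(scheme.iterations):
        for si in range(len(keep)):
            rng = _sample_rng(scheme.seed, it, si)
            acc[si] += rarefy_once(mat[si], scheme.depth, rng)
    acc /= scheme.iterations
    return AsvTable(pd.DataFrame(acc, index=keep, columns=sub.columns),
                    table.amplicon)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts: Iterable[float]) -> float:
    """Shannon entropy H = -sum p_i ln p_i over the positive entries."""
    c = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts,
                   dtype=float)
    c = c[c > 0]
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("shannon requires a positive total")
    p = c / c.sum()
    p = p[p > 0]  # entries can underflow to 0 under extreme magnitude ratios
    return float(-(p * np.log(p)).sum())


def pielou(counts: Iterable[float]) -> float:
    """Pielou's evenness J = H / ln(richness); undefined (NaN) at richness 1."""
    c = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts,
                   dtype=float)
    s = int((c > 0).sum())
    if s <= 1:
        return float("nan")
    return shannon(c) / np.log(s)


def _present_tips(counts: pd.Series) -> list[str]:
    return [str(a) for a, v in counts.items() if v > 0]


def faith_pd(counts: pd.Series, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    subtree spanning the present tips and the root.

    ``counts`` is indexed by ASV identifiers that must all resolve to tips.
    """
    present = set(_present_tips(counts))
    if not present:
        return 0.0
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(present - tip_names)
    if missing:
        raise KeyError(f"taxa absent from tree: {missing}")
    # postorder: an edge counts iff its subtree contains a present tip
    pd_total = 0.0
    has_present: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            hit = node.name in present
        else:
            hit = any(has_present[id(ch)] for ch in node.children)
        has_present[id(node)] = hit
        if hit and node.parent is not None and node.length:
            pd_total += node.length
    return pd_total


def richness_corrected_pd(counts: pd.Series, tree: TreeNode,
                          method: str = "per_taxon",
                          n_null: int = 100,
                          seed: int = 0) -> float:
    """Faith's PD corrected for species richness.

    ``per_taxon`` (default): PD divided by observed richness — branch length
    carried per observed taxon.  ``ses``: standardized effect size against a
    null of equally rich random tip sets, (PD - mean_null) / sd_null.
    """
    s = int((counts > 0).sum())
    if s == 0:
        return float("nan")
    obs = faith_pd(counts, tree)
    if method == "per_taxon":
        return obs / s
    if method == "ses":
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(seed)
        null = np.empty(n_null)
        for i in range(n_null):
            pick = rng.choice(len(tips), size=s, replace=False)
            null[i] = faith_pd(
                pd.Series(1.0, index=[tips[j] for j in pick]), tree)
        sd = null.std(ddof=1)
        return float((obs - null.mean()) / sd) if sd > 0 else float("nan")
    raise ValueError(f"unknown richness correction {method!r}")


def alpha_diversity_table(table: AsvTable, scheme: RarefactionScheme,
                          tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample mean alpha diversity across repeated rarefactions.

    Columns: shannon, pielou, richness, and (when a tree is given) faith_pd
    and richness_corrected_pd.  Samples below the rarefaction depth are
    excluded.
    """
    keep = rarefiable_samples(table, scheme.depth)
    sub = table.counts.loc[keep]
    mat = sub.to_numpy()
    cols = ["shannon", "pielou", "richness"]
    if tree is not None:
        cols += ["faith_pd", "richness_corrected_pd"]
    acc = np.zeros((len(keep), len(cols)))
    cnt = np.zeros((len(keep), len(cols)))  # pielou can be NaN per iteration
    for it in range(scheme.iterations):
        for si in range(len(keep)):
            rng = _sample_rng(scheme.seed, it, si)
            draw = rarefy_once(mat[si], scheme.depth, rng)
            vals = [shannon(draw), pielou(draw), float((draw > 0).sum())]
            if tree is not None:
                series = pd.Series(draw, index=sub.columns)
                fp = faith_pd(series, tree)
                vals += [fp, fp / max(1, int((draw > 0).sum()))]
            for j, v in enumerate(vals):
                if not np.isnan(v):
                    acc[si, j] += v
                    cnt[si, j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    return pd.DataFrame(mean, index=keep, columns=cols)


# ---------------------------------------------------------------------------
# beta diversity: scalar metrics
# ---------------------------------------------------------------------------

def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum |x-y| / sum (x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom <= 0:
        return float("nan")
    return float(np.abs(x - y).sum() / denom)


def jaccard_binary(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard distance on presence/absence: 1 - |A ∩ B| / |A ∪ B|."""
    a = np.asarray(x, dtype=float) > 0
    b = np.asarray(y, dtype=float) > 0
    union = (a | b).sum()
    if union == 0:
        return float("nan")
    return float(1.0 - (a & b).sum() / union)


def _edge_table(tree: TreeNode, asv_ids: list[str]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and tip-membership indicator of every non-root edge.

    Returns (lengths[e], member[e, tip]) with tips ordered as ``asv_ids``.
    """
    pos = {a: i for i, a in enumerate(asv_ids)}
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(set(asv_ids) - tip_names)
    if missing:
        raise KeyError(f"taxa absent from tree: {missing}")
    lengths: list[float] = []
    members: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        vec = np.zeros(len(asv_ids), dtype=bool)
        if node.is_tip():
            if node.name in pos:
                vec[pos[node.name]] = True
        else:
            for ch in node.children:
                vec |= below[id(ch)]
        below[id(node)] = vec
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            members.append(vec)
    return np.asarray(lengths), np.asarray(members)


def weighted_unifrac(x: pd.Series, y: pd.Series, tree: TreeNode,
                     normalized: bool = False) -> float:
    """Weighted UniFrac: sum over edges of b_e |p_e(x) - p_e(y)| where p_e is
    the fraction of a sample's reads descending from edge e.

    The raw (unnormalized) variant is the default; ``normalized=True``
    divides by sum b_e (p_e(x) + p_e(y)).
    """
    ids = list(x.index)
    if list(y.index) != ids:
        y = y.reindex(ids)
        if y.isna().any():
            raise KeyError("samples are not over the same taxa")
    xs, ys = float(x.sum()), float(y.sum())
    if xs <= 0 or ys <= 0:
        raise ValueError("weighted UniFrac requires positive totals")
    lengths, members = _edge_table(tree, [str(i) for i in ids])
    px = members @ (x.to_numpy(dtype=float) / xs)
    py = members @ (y.to_numpy(dtype=float) / ys)
    num = float((lengths * np.abs(px - py)).sum())
    if not normalized:
        return num
    den = float((lengths * (px + py)).sum())
    return num / den if den > 0 else float("nan")


# ---------------------------------------------------------------------------
# compositional transforms
# ---------------------------------------------------------------------------

def rclr_transform(table: AsvTable,
                   scale_to_median_depth: bool = True) -> pd.DataFrame:
    """Robust centred log-ratio transform; zeros become missing (NaN).

    Samples are first scaled to the dataset's median total (the robust CLR is
    scale-invariant per sample, but downstream pairwise-complete Euclidean
    distances are not, so inputs are put on a common depth first).  Each
    nonzero entry maps to ln(value) - mean(ln nonzero values of the sample).
    """
    tot = table.totals()
    if (tot <= 0).any():
        zero = tot.index[tot <= 0].tolist()
        raise ValueError(f"zero-total sample(s): {zero}")
    mat = table.counts.to_numpy(dtype=float)
    if scale_to_median_depth:
        mat = mat * (float(tot.median()) / tot.to_numpy())[:, None]
    out = np.full(mat.shape, np.nan)
    for i in range(mat.shape[0]):
        nz = mat[i] > 0
        logs = np.log(mat[i, nz])
        out[i, nz] = logs - logs.mean()
    return pd.DataFrame(out, index=table.counts.index,
                        columns=table.counts.columns)


def alr_by_spike(table: AsvTable, spike_counts: pd.Series,
                 pseudocount: float = 1.0) -> pd.DataFrame:
    """Additive log-ratio against the spike-in reference:
    ln((count) / spike_sample), with ``pseudocount`` substituted for zero
    counts only."""
    sc = spike_counts.reindex(table.counts.index)
    if sc.isna().any() or (sc <= 0).any():
        bad = sc.index[sc.isna() | (sc <= 0)].tolist()
        raise ValueError(f"zero/missing spike count for sample(s): {bad}")
    mat = table.counts.to_numpy(dtype=float)
    mat = np.where(mat > 0, mat, pseudocount)
    out = np.log(mat / sc.to_numpy()[:, None])
    return pd.DataFrame(out, index=table.counts.index,
                        columns=table.counts.columns)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

METRICS = ("bray_curtis", "jaccard", "weighted_unifrac", "euclidean")


def distance_matrix(data: AsvTable | pd.DataFrame, metric: str,
                    tree: TreeNode | None = None,
                    normalized_unifrac: bool = False) -> DistanceMatrix:
    """All-pairs sample dissimilarities.

    ``data`` is either an :class:`AsvTable` (counts; any metric) or a
    log-ratio transform DataFrame (may contain negatives and, for the robust
    CLR, NaN), for which only ``euclidean`` is meaningful.  With missing
    entries, Euclidean distances are computed over pairwise-complete
    coordinates and rescaled by sqrt(D / D_complete) to stay comparable
    across pairs.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if isinstance(data, AsvTable):
        frame = data.counts
    else:
        frame = data
        if metric != "euclidean":
            raise ValueError(
                f"metric {metric!r} is undefined on log-ratio transformed "
                "data; use 'euclidean'"
            )
    ids = [str(s) for s in frame.index]
    mat = frame.to_numpy(dtype=float)
    has_nan = np.isnan(mat).any()
    if has_nan and metric != "euclidean":
        raise ValueError("missing entries are only supported under 'euclidean'")

    if metric == "euclidean":
        if not has_nan:
            vals = squareform(pdist(mat, metric="euclidean"))
        else:
            vals = _pairwise_complete_euclidean(mat)
    elif metric == "bray_curtis":
        vals = squareform(pdist(mat, metric="braycurtis"))
    elif metric == "jaccard":
        vals = squareform(pdist(mat > 0, metric="jaccard"))
    else:  # weighted_unifrac
        if tree is None:
            raise ValueError("weighted_unifrac requires a tree")
        totals = mat.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("weighted UniFrac requires positive totals")
        lengths, members = _edge_table(tree, [str(c) for c in frame.columns])
        p = (mat / totals[:, None]) @ members.T  # samples x edges
        n = len(ids)
        vals = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(p[i] - p[i + 1:])
            d = diff @ lengths
            if normalized_unifrac:
                den = (p[i] + p[i + 1:]) @ lengths
                d = np.where(den > 0, d / den, np.nan)
            vals[i, i + 1:] = d
        vals = vals + vals.T
    if np.isnan(vals).any():
        raise ValueError("distance matrix contains undefined entries "
                         "(empty samples or no shared coordinates)")
    return DistanceMatrix(ids, vals)


def _pairwise_complete_euclidean(mat: np.ndarray) -> np.ndarray:
    n, d = mat.shape
    vals = np.zeros((n, n))
    finite = ~np.isnan(mat)
    filled = np.where(finite, mat, 0.0)
    for i in range(n):
        both = finite[i] & finite[i + 1:]
        diff = np.where(both, filled[i] - filled[i + 1:], 0.0)
        ncomp = both.sum(axis=1)
        ss = (diff ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[i, i + 1:] = np.sqrt(ss * d / ncomp)
    return vals + vals.T
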