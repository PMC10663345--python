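"""Permutational multivariate statistics on distance matrices.

PERMANOVA partitions the total sum of squared dissimilarities among the
terms of a linear design.  With G = -1/2 J D^2 J (the Gower-centred inner
product matrix, J the centring projector), the sum of squares absorbed by a
design matrix X is tr(H G) with H the orthogonal projector onto col(X);
sequential (Type-I) sums of squares are differences of these traces along a
growing design, in the order the model states.  A blocking factor (e.g.
sequencing plate nested in run) is entered first so that the fixed effects
are assessed on variation not attributable to batch.  Pseudo-F per term is
(SS_term/df_term) / (SS_res/df_res); p-values come from permuting sample
identities and recomputing every statistic, with the add-one estimator
p = (1 + #{F* >= F}) / (1 + n_perm).  For n <= 8 an exact mode enumerates
all n! relabelings.

PERMDISP2 tests homogeneity of multivariate dispersion: samples are embedded
by principal coordinates (negative eigenvalues become "imaginary" axes),
each group's centre (spatial median by default) is found, and the
group-label permutation test is run on the distances to centre, where a
squared distance is the real-block part minus the imaginary-block part,
floored at zero.  The same geometry drives the within-individual
tissue-homogeneity statistic.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orth

from endostat.io import DistanceMatrix, SampleMetadata

logger = logging.getLogger(__name__)

_F_TIE_TOL = 1e-10


def _tie_threshold(f_obs):
    """Observed-F threshold for counting permuted statistics as >=.

    Relative slack matters when the residual is numerically zero and F is
    astronomically large; ties then still count toward the numerator (the
    conservative convention).  An infinite observed F keeps an infinite
    threshold so only other infinite statistics tie with it.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    with np.errstate(invalid="ignore"):
        slack = np.maximum(_F_TIE_TOL, 1e-8 * np.abs(f_obs))
        return np.where(np.isinf(f_obs), f_obs, f_obs - slack)


@dataclasses.dataclass
class ModelSpec:
    """An ordered permutational-ANOVA model.

    ``terms`` are metadata column names or colon-joined interactions
    (``"tissue:stage"``); order matters because sums of squares are
    sequential.  ``block``, if given, must be the first term; it is fitted
    first and (optionally, ``permute_within_block=True``) restricts
    permutations to within-block exchanges.
    """

    terms: Sequence[str]
    block: str | None = None
    n_perm: int = 999
    seed: int = 0
    ss_mode: str = "sequential"
    permute_within_block: bool = False
    exact: bool = False

    def __post_init__(self) -> None:
        if self.block is not None and (not self.terms
                                       or self.terms[0] != self.block):
            raise ValueError("block term, if present, must be first")
        if self.ss_mode not in ("sequential", "marginal"):
            raise ValueError(f"unknown ss_mode {self.ss_mode!r}")
        if self.permute_within_block and self.block is None:
            raise ValueError("permute_within_block requires a block term")

    @classmethod
    def from_formula(cls, formula: str, block: str | None = None,
                     **kwargs) -> "ModelSpec":
        """Expand a formula like ``"run:plate + tissue*stage*genotype"``.

        ``A*B`` expands to main effects plus all interactions in
        lowest-order-first sequence; ``A:B`` is a single interaction term.
        """
        terms: list[str] = []
        for chunk in formula.split("+"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "*" in chunk:
                factors = [f.strip() for f in chunk.split("*")]
                for order in range(1, len(factors) + 1):
                    for combo in itertools.combinations(factors, order):
                        terms.append(":".join(combo))
            else:
                terms.append(chunk)
        return cls(terms=terms, block=block, **kwargs)


@dataclasses.dataclass
class PermTestResult:
    """Variance partition and permutation p-values of one test.

    ``table`` is indexed by term with columns SS, df, R2, F, p; in
    sequential mode term SS plus residual SS reproduce the total SS.
    """

    table: pd.DataFrame
    residual_ss: float
    total_ss: float
    n_perm: int
    extras: dict = dataclasses.field(default_factory=dict)

    def __repr__(self) -> str:  # compact, adonis-style
        lines = [self.table.to_string(float_format=lambda v: f"{v:.6g}")]
        lines.append(f"Residual SS {self.residual_ss:.6g} of total "
                     f"{self.total_ss:.6g}  ({self.n_perm} permutations)")
        return "\n".join(lines)


@dataclasses.dataclass
class OrdinationEmbedding:
    """PCoA coordinates: real axes (positive eigenvalues, scaled sqrt(l))
    and imaginary axes (negative eigenvalues, scaled sqrt(|l|)).

    Squared inter-point distances are (real-block squared differences) minus
    (imaginary-block squared differences), reproducing the input distances.
    """

    sample_ids: list[str]
    real: np.ndarray
    imaginary: np.ndarray
    eigenvalues: np.ndarray


# ---------------------------------------------------------------------------
# machinery
# ---------------------------------------------------------------------------

def gower_center(dm: DistanceMatrix) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 J D^2 J.

    tr(G) is the total sum of squares; rows and columns sum to zero.
    """
    d2 = dm.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d2 @ j


def _align_metadata(dm: DistanceMatrix,
                    metadata: SampleMetadata | pd.DataFrame) -> pd.DataFrame:
    frame = metadata.frame if isinstance(metadata, SampleMetadata) else metadata
    missing = [s for s in dm.sample_ids if s not in frame.index]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    return frame.loc[dm.sample_ids]


def _term_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    factors = [f.strip() for f in term.split(":")]
    for f in factors:
        if f not in meta.columns:
            raise KeyError(f"model term {term!r}: no metadata column {f!r}")
    combined = meta[factors[0]].astype(str)
    for f in factors[1:]:
        combined = combined + "\x1f" + meta[f].astype(str)
    return pd.get_dummies(combined).to_numpy(dtype=float)


def _sequential_projectors(meta: pd.DataFrame, terms: Sequence[str]
                           ) -> tuple[list[np.ndarray], list[int], int]:
    """Orthogonal projectors of the growing design, one per term prefix.

    Returns (projectors H_1..H_k, per-term df, residual rank deficit base).
    Raises on a term adding no rank (confounded with what precedes it).
    """
    n = len(meta)
    x = np.ones((n, 1))
    rank_prev = 1
    projectors: list[np.ndarray] = []
    dfs: list[int] = []
    for term in terms:
        x = np.hstack([x, _term_columns(meta, term)])
        basis = orth(x)
        rank = basis.shape[1]
        df = rank - rank_prev
        if df == 0:
            raise ValueError(
                f"term {term!r} is confounded with preceding terms "
                "(adds no estimable contrast)"
            )
        projectors.append(basis @ basis.T)
        dfs.append(df)
        rank_prev = rank
    return projectors, dfs, rank_prev


def _permutations(n: int, model: ModelSpec,
                  block_labels: np.ndarray | None) -> list[np.ndarray]:
    if model.exact:
        if n > 8:
            raise ValueError("exact enumeration supported for n <= 8 only")
        return [np.asarray(p) for p in itertools.permutations(range(n))]
    rng = np.random.default_rng(model.seed)
    perms = []
    for _ in range(model.n_perm):
        if model.permute_within_block and block_labels is not None:
            p = np.arange(n)
            for lv in np.unique(block_labels):
                idx = np.flatnonzero(block_labels == lv)
                p[idx] = idx[rng.permutation(len(idx))]
        else:
            p = rng.permutation(n)
        perms.append(p)
    return perms


def _partition(g: np.ndarray, projectors: list[np.ndarray],
               dfs: list[int], rank_total: int
               ) -> tuple[np.ndarray, float, np.ndarray]:
    """Sequential SS per term, residual SS and per-term pseudo-F from G."""
    n = g.shape[0]
    traces = np.array([float((h * g).sum()) for h in projectors])
    ss = np.diff(np.concatenate([[0.0], traces]))
    total = float(np.trace(g))
    ss_res = total - traces[-1]
    df_res = n - rank_total
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    # a residual that is zero up to float noise must yield a consistent
    # infinite F, or permutation tie-counting becomes erratic
    tiny = 1e-12 * max(abs(total), 1.0)
    if ss_res < tiny:
        f = np.where(ss > tiny, np.inf, np.nan)
        return ss, max(ss_res, 0.0), f
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss / np.asarray(dfs)) / (ss_res / df_res)
    return ss, ss_res, f


def permanova(dm: DistanceMatrix, metadata: SampleMetadata | pd.DataFrame,
              model: ModelSpec) -> PermTestResult:
    """PERMANOVA with sequential sums of squares in the stated term order.

    Marginal (Type-III-like) SS are available via ``model.ss_mode ==
    'marginal'``: each non-block term's SS is its trace increment when added
    last; p-values still come from the same permutation scheme.
    """
    meta = _align_metadata(dm, metadata)
    n = len(meta)
    g = gower_center(dm)
    total_ss = float(np.trace(g))
    terms = list(model.terms)
    projectors, dfs, rank_total = _sequential_projectors(meta, terms)
    df_res = n - rank_total

    block_labels = None
    if model.block is not None:
        factors = [f.strip() for f in model.block.split(":")]
        lab = meta[factors[0]].astype(str)
        for f in factors[1:]:
            lab = lab + "\x1f" + meta[f].astype(str)
        block_labels = lab.to_numpy()

    if model.ss_mode == "marginal":
        return _permanova_marginal(g, meta, model, terms, total_ss, n)

    ss, ss_res, f_obs = _partition(g, projectors, dfs, rank_total)
    perms = _permutations(n, model, block_labels)
    thresh = _tie_threshold(f_obs)
    exceed = np.zeros(len(terms))
    for p in perms:
        gp = g[np.ix_(p, p)]
        _, _, f_star = _partition(gp, projectors, dfs, rank_total)
        exceed += f_star >= thresh
    if model.exact:
        pvals = exceed / len(perms)
    else:
        pvals = (1.0 + exceed) / (1.0 + len(perms))

    table = pd.DataFrame({
        "SS": ss,
        "df": dfs,
        "R2": ss / total_ss if total_ss > 0 else np.nan,
        "F": f_obs,
        "p": pvals,
    }, index=pd.Index(terms, name="term"))
    return PermTestResult(table, ss_res, total_ss,
                          len(perms), extras={"df_res": df_res})


def _permanova_marginal(g: np.ndarray, meta: pd.DataFrame, model: ModelSpec,
                        terms: list[str], total_ss: float, n: int
                        ) -> PermTestResult:
    # full-model residual is shared; each term's SS is its unique increment
    # over the model containing every other term
    projectors_full, dfs_full, rank_full = _sequential_projectors(meta, terms)
    h_full = projectors_full[-1]
    ss_res = total_ss - float((h_full * g).sum())
    df_res = n - rank_full

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = np.empty(len(terms))
        f = np.empty(len(terms))
        for i, term in enumerate(terms):
            others = [t for j, t in enumerate(terms) if j != i]
            if others:
                proj_wo, _, rank_wo = _sequential_projectors(meta, others)
                tr_wo = float((proj_wo[-1] * gmat).sum())
            else:
                tr_wo, rank_wo = 0.0, 1
            tr_full = float((h_full * gmat).sum())
            ss[i] = tr_full - tr_wo
            df_i = rank_full - rank_wo
            res = total_ss_of(gmat) - tr_full
            f[i] = (ss[i] / max(df_i, 1)) / (res / df_res)
        return ss, f

    def total_ss_of(gmat: np.ndarray) -> float:
        return float(np.trace(gmat))

    ss_obs, f_obs = term_stats(g)
    perms = _permutations(n, model, None)
    thresh = _tie_threshold(f_obs)
    exceed = np.zeros(len(terms))
    for p in perms:
        _, f_star = term_stats(g[np.ix_(p, p)])
        exceed += f_star >= thresh
    pvals = (exceed / len(perms) if model.exact
             else (1.0 + exceed) / (1.0 + len(perms)))
    dfs = []
    for i, term in enumerate(terms):
        others = [t for j, t in enumerate(terms) if j != i]
        rank_wo = (_sequential_projectors(meta, others)[2] if others else 1)
        dfs.append(rank_full - rank_wo)
    table = pd.DataFrame({
        "SS": ss_obs, "df": dfs,
        "R2": ss_obs / total_ss if total_ss > 0 else np.nan,
        "F": f_obs, "p": pvals,
    }, index=pd.Index(terms, name="term"))
    return PermTestResult(table, ss_res, total_ss, len(perms),
                          extras={"df_res": df_res})


def perm_anova_univariate(response: pd.Series,
                          metadata: SampleMetadata | pd.DataFrame,
                          model: ModelSpec) -> PermTestResult:
    """Permutational ANOVA on a scalar response.

    Implemented as PERMANOVA on the Euclidean distance matrix of the
    response: sums of squares and F equal the classical ANOVA decomposition
    exactly; p-values come from permutation.
    """
    resp = response.dropna()
    if resp.nunique() <= 1:
        raise ValueError("response is constant: nothing to test")
    vals = resp.to_numpy(dtype=float)
    d = np.abs(vals[:, None] - vals[None, :])
    dm = DistanceMatrix(list(resp.index), d)
    return permanova(dm, metadata, model)


def permanova_pairwise(dm: DistanceMatrix,
                       metadata: SampleMetadata | pd.DataFrame,
                       factor: str,
                       levels: Sequence[str] | None = None,
                       within: Mapping[str, str] | None = None,
                       n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """All pairwise one-factor PERMANOVAs of ``factor``, Benjamini-Hochberg
    adjusted across the pair family.

    ``within`` optionally restricts to a subset first (e.g.
    ``{"stage": "RipeSiliques"}``).  Levels with fewer than two samples are
    skipped with a log entry.
    """
    from statsmodels.stats.multitest import multipletests

    meta = _align_metadata(dm, metadata)
    if within:
        mask = np.ones(len(meta), dtype=bool)
        for col, val in within.items():
            mask &= (meta[col].astype(str) == str(val)).to_numpy()
        meta = meta[mask]
    if levels is None:
        levels = sorted(meta[factor].dropna().astype(str).unique())
    rows = []
    for a, b in itertools.combinations(levels, 2):
        sub = meta[meta[factor].astype(str).isin([a, b])]
        na = int((sub[factor].astype(str) == a).sum())
        nb = int((sub[factor].astype(str) == b).sum())
        if na < 2 or nb < 2:
            logger.info("pair (%s, %s) skipped: level with < 2 samples", a, b)
            continue
        sub_dm = dm.subset(sub.index)
        res = permanova(sub_dm, sub,
                        ModelSpec(terms=[factor], n_perm=n_perm, seed=seed))
        row = res.table.iloc[0]
        rows.append({"level_a": a, "level_b": b, "n_a": na, "n_b": nb,
                     "SS": row["SS"], "R2": row["R2"], "F": row["F"],
                     "p": row["p"]})
    out = pd.DataFrame(rows, columns=["level_a", "level_b", "n_a", "n_b",
                                      "SS", "R2", "F", "p"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# ordination and dispersion
# ---------------------------------------------------------------------------

def pcoa_embed(dm: DistanceMatrix, eig_rtol: float = 1e-9
               ) -> OrdinationEmbedding:
    """Principal coordinates with explicit imaginary axes.

    Eigenvalues within ``eig_rtol`` of zero (relative to the largest
    magnitude) are dropped.  Axes are ordered by decreasing |eigenvalue|
    within each block.
    """
    g = gower_center(dm)
    evals, evecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = np.abs(evals).max() if len(evals) else 0.0
    tol = scale * eig_rtol
    pos = evals > tol
    neg = evals < -tol
    real = evecs[:, pos] * np.sqrt(evals[pos])
    neg_idx = np.flatnonzero(neg)[::-1]  # most negative first
    imaginary = evecs[:, neg_idx] * np.sqrt(-evals[neg_idx])
    return OrdinationEmbedding(list(dm.sample_ids), real, imaginary,
                               evals)


def spatial_median(points: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 1000) -> np.ndarray:
    """Geometric (spatial) median by damped Weiszfeld iteration.

    Minimises the summed Euclidean norms to the data points; when an iterate
    coincides with a data point the Vardi-Zhang damped step keeps the
    iteration well defined.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty 2-D array")
    if pts.shape[1] == 0:
        return np.zeros(0)
    m = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - m, axis=1)
        coincide = d < 1e-12
        if coincide.all():
            return m
        w = np.where(coincide, 0.0, 1.0 / np.where(coincide, 1.0, d))
        t = (pts * w[:, None]).sum(axis=0) / w.sum()
        if coincide.any():
            r_vec = ((pts - m) * w[:, None]).sum(axis=0)
            r = np.linalg.norm(r_vec)
            eta = coincide.sum()
            if r <= eta:
                return m
            gamma = eta / r
            t = (1 - gamma) * t + gamma * m
        if np.linalg.norm(t - m) <= tol * (1.0 + np.linalg.norm(m)):
            return t
        m = t
    return m


def corrected_distances_to_center(emb: OrdinationEmbedding,
                                  idx: np.ndarray,
                                  center_real: np.ndarray,
                                  center_imag: np.ndarray) -> np.ndarray:
    """Distances of the selected samples to a centre in the split embedding:
    sqrt(max(0, d_real^2 - d_imag^2))."""
    dr2 = ((emb.real[idx] - center_real) ** 2).sum(axis=1) \
        if emb.real.size else np.zeros(len(idx))
    di2 = ((emb.imaginary[idx] - center_imag) ** 2).sum(axis=1) \
        if emb.imaginary.size else np.zeros(len(idx))
    return np.sqrt(np.clip(dr2 - di2, 0.0, None))


def _batched_spatial_median(pts: np.ndarray, tol: float = 1e-8,
                            max_iter: int = 256) -> np.ndarray:
    """Weiszfeld iteration over a batch of point sets: (B, k, d) -> (B, d).

    Distances are floored at 1e-12 so an iterate landing on a data point
    keeps a finite (huge) weight and stays put; adequate for the permutation
    replicates, where exact coincidences have measure zero.
    """
    if pts.shape[2] == 0:
        return np.zeros((pts.shape[0], 0))
    m = pts.mean(axis=1)
    for _ in range(max_iter):
        diff = pts - m[:, None, :]
        dist = np.maximum(np.linalg.norm(diff, axis=2), 1e-12)
        w = 1.0 / dist
        t = (pts * w[:, :, None]).sum(axis=1) / w.sum(axis=1)[:, None]
        move = np.linalg.norm(t - m, axis=1).max()
        m = t
        if move <= tol:
            break
    return m


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    levels = np.unique(labels)
    for lv in levels:
        v = values[labels == lv]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_b = len(levels) - 1
    df_w = len(values) - len(levels)
    if df_b == 0 or df_w == 0 or ss_within == 0:
        return float("nan")
    return (ss_between / df_b) / (ss_within / df_w)


def permdisp(dm: DistanceMatrix, groups: pd.Series,
             center: str = "spatial_median", n_perm: int = 999,
             seed: int = 0) -> PermTestResult:
    """PERMDISP2: homogeneity of multivariate dispersions.

    Embeds the distance matrix by PCoA (imaginary axes kept), finds each
    group's centre (spatial median by default; ``center='centroid'`` for the
    mean), takes every sample's corrected distance to its group centre, and
    tests the one-way ANOVA F of those distances by permuting group labels
    and recomputing centres, distances and F under each permuted grouping
    (an exact Monte-Carlo test when samples are exchangeable under the
    null).

    Returns a :class:`PermTestResult` whose ``extras['distances']`` holds the
    per-sample distance to centre.  If every distance is zero the test is
    reported as a no-dispersion case (F and p are NaN).
    """
    if center not in ("spatial_median", "centroid"):
        raise ValueError(f"unknown center {center!r}")
    groups = groups.reindex(dm.sample_ids)
    if groups.isna().any():
        bad = groups.index[groups.isna()].tolist()
        raise ValueError(f"samples without group label: {bad}")
    labels = groups.astype(str).to_numpy()
    levels, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        small = levels[counts < 2].tolist()
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")

    emb = pcoa_embed(dm)

    def group_distances(lab: np.ndarray) -> np.ndarray:
        dist = np.empty(len(lab))
        for lv in levels:
            idx = np.flatnonzero(lab == lv)
            if center == "centroid":
                c_re = (emb.real[idx].mean(axis=0)
                        if emb.real.size else np.zeros(0))
                c_im = (emb.imaginary[idx].mean(axis=0)
                        if emb.imaginary.size else np.zeros(0))
            else:
                c_re = (spatial_median(emb.real[idx])
                        if emb.real.size else np.zeros(0))
                c_im = (spatial_median(emb.imaginary[idx])
                        if emb.imaginary.size else np.zeros(0))
            dist[idx] = corrected_distances_to_center(emb, idx, c_re, c_im)
        return dist

    dist = group_distances(labels)
    dseries = pd.Series(dist, index=dm.sample_ids, name="distance_to_center")
    total_ss = float(((dist - dist.mean()) ** 2).sum())
    if np.allclose(dist, 0.0):
        table = pd.DataFrame({"SS": [0.0], "df": [len(levels) - 1],
                              "R2": [np.nan], "F": [np.nan], "p": [np.nan]},
                             index=pd.Index(["groups"], name="term"))
        return PermTestResult(table, 0.0, 0.0, 0,
                              extras={"distances": dseries,
                                      "no_dispersion": True})

    f_obs = _anova_f(dist, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    coords = (np.hstack([emb.real, emb.imaginary])
              if emb.imaginary.size else emb.real)
    r = emb.real.shape[1]
    # batched recomputation: for each permutation the group centres,
    # corrected distances and F are rebuilt under the permuted labels
    perm_dist = np.empty((n_perm, n))
    for lv in levels:
        pos = perms[:, np.flatnonzero(labels == lv)]  # (B, n_lv)
        pts = coords[pos]                              # (B, n_lv, d)
        if center == "centroid":
            c = pts.mean(axis=1)
        else:
            c_re = _batched_spatial_median(pts[:, :, :r])
            c_im = _batched_spatial_median(pts[:, :, r:])
            c = np.hstack([c_re, c_im])
        diff2 = (pts - c[:, None, :]) ** 2
        d2 = diff2[:, :, :r].sum(axis=2) - diff2[:, :, r:].sum(axis=2)
        d_lv = np.sqrt(np.clip(d2, 0.0, None))
        np.put_along_axis(perm_dist, pos, d_lv, axis=1)
    # vectorised one-way F over permutations
    grand = perm_dist.mean(axis=1)
    ss_b = np.zeros(n_perm)
    ss_w = np.zeros(n_perm)
    for lv in levels:
        pos = perms[:, np.flatnonzero(labels == lv)]
        vals = np.take_along_axis(perm_dist, pos, axis=1)
        gm = vals.mean(axis=1)
        ss_b += vals.shape[1] * (gm - grand) ** 2
        ss_w += ((vals - gm[:, None]) ** 2).sum(axis=1)
    df_b = len(levels) - 1
    df_w = n - len(levels)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_star = (ss_b / df_b) / (ss_w / df_w)
    exceed = int(np.sum(~np.isnan(f_star)
                        & (f_star >= _tie_threshold(f_obs))))
    pval = (1.0 + exceed) / (1.0 + n_perm)

    grand = dist.mean()
    ss_between = sum(
        (labels == lv).sum() * (dist[labels == lv].mean() - grand) ** 2
        for lv in levels
    )
    table = pd.DataFrame({
        "SS": [ss_between],
        "df": [len(levels) - 1],
        "R2": [ss_between / total_ss if total_ss > 0 else np.nan],
        "F": [f_obs],
        "p": [pval],
    }, index=pd.Index(["groups"], name="term"))
    return PermTestResult(table, total_ss - ss_between, total_ss, n_perm,
                          extras={"distances": dseries})
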