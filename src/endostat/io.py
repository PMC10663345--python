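"""Domain types, readers/writers and validation for ASV tables, metadata,
spike registries, trees and distance matrices.

Conventions
-----------
* ASV tables are held samples x ASVs.  On disk the samples-as-rows TSV dialect
  is the default; the ASVs-as-rows dialect (common in QIIME-era exports) is
  auto-detected when known sample identifiers are supplied, and can be forced.
* All identifiers are case-sensitive opaque strings.
* Bulk-soil samples carry no plant identifier and no stage/tissue pairing
  constraint; they are flagged and excluded from plant-only analyses.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

GENOTYPES = ("WT", "efr", "fls2", "lore", "lyk4")

TISSUES = (
    "root",
    "rosette",
    "stem",
    "cauline_leaf",
    "flower",
    "immature_silique",
    "mature_silique",
    "soil",
)

STAGES = ("Vegetative", "Flowering", "UnripeSiliques", "RipeSiliques")

#: Tissues present at each developmental stage of the field design.  A
#: Vegetative plant consists only of a root and a rosette; reproductive
#: tissues accumulate through the season and ripe (mature) siliques appear
#: only at the final stage.
TISSUES_BY_STAGE: Mapping[str, tuple[str, ...]] = {
    "Vegetative": ("root", "rosette"),
    "Flowering": ("root", "rosette", "stem", "cauline_leaf", "flower"),
    "UnripeSiliques": (
        "root", "rosette", "stem", "cauline_leaf", "flower", "immature_silique",
    ),
    "RipeSiliques": (
        "root", "rosette", "stem", "cauline_leaf", "flower",
        "immature_silique", "mature_silique",
    ),
}

AMPLICONS = ("16S", "ITS1")


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifier(s): {dups}")


@dataclasses.dataclass
class AsvTable:
    """A samples x ASVs abundance matrix.

    ``counts`` is a DataFrame indexed by sample identifiers with ASV
    identifiers as columns.  Entries are non-negative reals; raw tables are
    integer-valued, while rarefaction means and spike-scaled tables are not.
    """

    counts: pd.DataFrame
    amplicon: str = "16S"

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if self.amplicon not in AMPLICONS:
            raise ValidationError(
                f"unknown amplicon {self.amplicon!r}; expected one of {AMPLICONS}"
            )
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "ASV")
        vals = self.counts.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite entry at sample {self.counts.index[bad[0]]!r}, "
                f"ASV {self.counts.columns[bad[1]]!r}"
            )
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative entry at sample {self.counts.index[bad[0]]!r}, "
                f"ASV {self.counts.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AsvTable":
        ids = [s for s in sample_ids]
        missing = set(ids) - set(self.counts.index)
        if missing:
            raise KeyError(f"samples not in table: {sorted(missing)}")
        return AsvTable(self.counts.loc[ids].copy(), self.amplicon)

    def subset_asvs(self, asv_ids: Iterable[str]) -> "AsvTable":
        ids = [a for a in asv_ids]
        missing = set(ids) - set(self.counts.columns)
        if missing:
            raise KeyError(f"ASVs not in table: {sorted(missing)}")
        return AsvTable(self.counts[ids].copy(), self.amplicon)

    def relative(self) -> pd.DataFrame:
        """Within-sample relative abundances (rows sum to 1)."""
        tot = self.totals()
        if (tot <= 0).any():
            zero = tot.index[tot <= 0].tolist()
            raise ValidationError(f"zero-total sample(s): {zero}")
        return self.counts.div(tot, axis=0)


# required metadata columns, in canonical order
METADATA_COLUMNS = (
    "sample_id", "plant_id", "genotype", "tissue", "stage",
    "run", "plate", "amplicon",
)


class SampleMetadata:
    """Per-sample design factors: plant, genotype, tissue, stage, run, plate,
    amplicon.

    Non-soil samples must carry a plant identifier, a genotype from the five
    experimental lines, and a tissue consistent with the plant's developmental
    stage (e.g. a Vegetative plant cannot yield a stem sample).  Bulk-soil
    samples (``tissue == 'soil'``) are exempt from the plant-design
    constraints and excluded by :meth:`plants`.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata missing column(s): {missing}")
        df = frame[list(METADATA_COLUMNS)].copy()
        df = df.astype({c: "string" for c in df.columns if c != "plant_id"})
        _check_unique(df["sample_id"], "sample")
        df = df.set_index("sample_id", drop=False)

        bad_t = sorted(set(df["tissue"]) - set(TISSUES))
        if bad_t:
            raise ValidationError(f"unknown tissue level(s): {bad_t}")
        bad_s = sorted(set(df["stage"].dropna()) - set(STAGES))
        if bad_s:
            raise ValidationError(f"unknown stage level(s): {bad_s}")
        bad_a = sorted(set(df["amplicon"]) - set(AMPLICONS))
        if bad_a:
            raise ValidationError(f"unknown amplicon level(s): {bad_a}")

        is_soil = df["tissue"] == "soil"
        plant = ~is_soil
        bad_g = sorted(set(df.loc[plant, "genotype"].dropna()) - set(GENOTYPES))
        if bad_g:
            raise ValidationError(f"unknown genotype level(s): {bad_g}")
        no_plant = plant & (df["plant_id"].isna() | (df["plant_id"].astype("string") == ""))
        if no_plant.any():
            raise ValidationError(
                f"non-soil sample(s) without plant_id: {df.index[no_plant].tolist()}"
            )
        for sid, row in df.loc[plant].iterrows():
            if pd.isna(row["stage"]):
                raise ValidationError(f"sample {sid!r}: non-soil sample without stage")
            allowed = TISSUES_BY_STAGE[row["stage"]]
            if row["tissue"] not in allowed:
                raise ValidationError(
                    f"sample {sid!r}: tissue {row['tissue']!r} is not harvested at "
                    f"stage {row['stage']!r} (available: {list(allowed)})"
                )
        pt = df.loc[plant, ["plant_id", "tissue"]]
        dup = pt.duplicated()
        if dup.any():
            first = pt[dup].iloc[0]
            raise ValidationError(
                f"duplicate (plant_id, tissue) pair: ({first['plant_id']!r}, "
                f"{first['tissue']!r})"
            )
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def plants(self) -> "SampleMetadata":
        """Metadata restricted to plant-derived (non-soil) samples."""
        sub = self.frame[self.frame["tissue"] != "soil"]
        return SampleMetadata(sub.reset_index(drop=True))

    def loc(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        return self.frame.loc[list(sample_ids)]

    def __len__(self) -> int:
        return len(self.frame)


@dataclasses.dataclass
class SpikeRegistry:
    """Registry of synthetic spike-in ASV identifiers, per amplicon.

    Spike reads enter the table as ordinary ASV columns; this registry is how
    they are recognised and split out.  ``spike_counts`` and ``spike_median``
    are populated by the preprocessing stage (the median is computed over the
    samples admitted to quantitation only).
    """

    spike_asv_ids: Mapping[str, tuple[str, ...]]  # amplicon -> ids
    spike_counts: pd.Series | None = None
    spike_median: float | None = None

    def ids_for(self, amplicon: str) -> tuple[str, ...]:
        return tuple(self.spike_asv_ids.get(amplicon, ()))


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise sample dissimilarities, zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} sample ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            i = int(np.argmax(np.abs(np.diag(self.values))))
            raise ValidationError(
                f"nonzero diagonal at sample {self.sample_ids[i]!r}"
            )
        if (self.values < -1e-12).any():
            raise ValidationError("negative distances present")
        # clean tiny numerical asymmetries/negatives
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Iterable[str]) -> "DistanceMatrix":
        ids = [str(s) for s in sample_ids]
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in distance matrix: {missing}")
        idx = [pos[s] for s in ids]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_asv_table(
    path: str | Path,
    format: str = "tsv",
    amplicon: str = "16S",
    orientation: str = "auto",
    sample_ids: Iterable[str] | None = None,
) -> AsvTable:
    """Read an ASV table from TSV or BIOM.

    Parameters
    ----------
    orientation : {"auto", "samples", "asvs"}
        Row meaning of a TSV table.  ``auto`` keeps samples-as-rows unless the
        supplied ``sample_ids`` overlap the columns better than the rows (the
        ASVs-as-rows dialect).  BIOM tables carry orientation internally.
    """
    path = Path(path)
    if format == "biom":
        import biom  # optional; ships with the scikit-bio stack

        bt = biom.load_table(str(path))
        df = pd.DataFrame(
            bt.matrix_data.toarray().T,
            index=[str(s) for s in bt.ids("sample")],
            columns=[str(o) for o in bt.ids("observation")],
        )
        return AsvTable(df, amplicon)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric table body in {path}: {exc}") from exc

    if orientation not in ("auto", "samples", "asvs"):
        raise ValueError(f"unknown orientation {orientation!r}")
    transpose = orientation == "asvs"
    if orientation == "auto" and sample_ids is not None:
        known = set(map(str, sample_ids))
        row_hits = len(known & set(df.index))
        col_hits = len(known & set(df.columns))
        transpose = col_hits > row_hits
    if transpose:
        df = df.T
    return AsvTable(df, amplicon)


def write_asv_table(table: AsvTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype="string")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_spike_registry(path: str | Path) -> SpikeRegistry:
    """Read a two-column TSV ``amplicon<TAB>asv_id`` of spike identifiers."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"amplicon", "asv_id"} <= set(df.columns):
        raise ValidationError("spike registry needs columns: amplicon, asv_id")
    ids = {
        amp: tuple(sub["asv_id"]) for amp, sub in df.groupby("amplicon")
    }
    return SpikeRegistry(spike_asv_ids=ids)


def write_spike_registry(reg: SpikeRegistry, path: str | Path) -> None:
    rows = [
        {"amplicon": amp, "asv_id": a}
        for amp, ids in reg.spike_asv_ids.items()
        for a in ids
    ]
    pd.DataFrame(rows, columns=["amplicon", "asv_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValidationError(
            f"distance matrix in {path} is not square-labelled "
            "(row and column identifiers differ)"
        )
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index_label="sample_id",
                         float_format="%.15g")


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree and validate tip uniqueness and branch signs."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tree tip")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValidationError(
                f"negative branch length at node {node.name!r}"
            )
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
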