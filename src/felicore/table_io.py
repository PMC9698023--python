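"""Reading, writing and QC of genus-level 16S count tables.

The tables handled here are plain TSV: taxa as rows, samples as columns,
first header cell ``taxon_id``.  Counts are integer reads.  The module also
implements the genus-collapsing rules used to reduce a feature (ASV) table
annotated with ranked lineages to a genus-keyed table: features whose genus
is unknown or is an uninformative placeholder ("uncultured", "gut
metagenome", ...) are relabelled from their family rank, keeping the
unclassified and uncultured variants distinct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "LineageMap",
    "QCThresholds",
    "RelAbundTable",
    "read_count_table",
    "write_count_table",
    "collapse_to_genus",
    "filter_low_depth",
    "to_relative_abundance",
    "read_lineage_map",
]

#: genus strings that carry no genus-level information; matching is
#: case-insensitive after stripping surrounding whitespace
UNCULTURED_TOKENS = frozenset(
    {"uncultured", "uncultured bacterium", "uncultured organism", "gut metagenome"}
)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class TableError(ValueError):
    """Raised for malformed or inconsistent tabular inputs."""


@dataclass
class QCThresholds:
    """Sample-depth and taxon-detection thresholds.

    ``min_sample_reads`` is the library-size floor below which a sample is
    dropped from all analyses; ``detection_reads`` is the minimum read count
    for a taxon to count as present in a sample.
    """

    min_sample_reads: int = 5000
    detection_reads: int = 25

    def __post_init__(self) -> None:
        if self.min_sample_reads <= 0 or self.detection_reads <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class CountTable:
    """Integer read counts, taxa x samples, wrapped around a DataFrame."""

    df: pd.DataFrame  # index: taxon ids, columns: sample ids, int values

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise TableError(f"duplicate taxon id: {dup!r}")
        if self.df.columns.has_duplicates:
            dup = self.df.columns[self.df.columns.duplicated()][0]
            raise TableError(f"duplicate sample id: {dup!r}")
        if (self.df.to_numpy() < 0).any():
            raise TableError("negative counts present")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def sample_depths(self) -> pd.Series:
        return self.df.sum(axis=0)


@dataclass
class RelAbundTable:
    """Per-sample proportions (columns sum to one), taxa x samples."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.df.sum(axis=0)
        bad = sums.index[np.abs(sums.to_numpy() - 1.0) > 1e-9]
        if len(bad):
            raise TableError(f"sample {bad[0]!r} does not sum to 1")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)


@dataclass
class LineageMap:
    """feature id -> ordered ranked lineage (domain ... genus)."""

    lineages: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def rank(self, feature_id: str, rank: str) -> str:
        lin = self.lineages[feature_id]
        return lin[RANKS.index(rank)]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineages


def _clean_rank(token: str) -> str:
    """Strip whitespace and an optional 'x__' rank prefix from a rank token."""
    token = token.strip()
    if len(token) >= 3 and token[1:3] == "__":
        token = token[3:]
    return token.strip()


def read_lineage_map(path: str | Path) -> LineageMap:
    """Read a two-column TSV (feature_id, semicolon-separated lineage)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise TableError(f"{path}: expected columns feature_id, lineage")
    lineages: dict[str, tuple[str, ...]] = {}
    for fid, lin in zip(df.iloc[:, 0], df.iloc[:, 1]):
        ranks = [_clean_rank(t) for t in str(lin).split(";")]
        ranks = (ranks + [""] * len(RANKS))[: len(RANKS)]
        if fid in lineages:
            raise TableError(f"duplicate feature id in taxonomy: {fid!r}")
        lineages[fid] = tuple(ranks)
    return LineageMap(lineages)


def read_count_table(path: str | Path) -> CountTable:
    """Read a taxa-x-samples TSV of integer counts.

    The first column holds taxon ids and the header row holds sample ids;
    duplicated ids, negative or non-integer cells are hard errors that name
    the offending row/column.
    """
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n").rstrip("\r")
    samples = header_line.split("\t")[1:]  # pandas would mangle duplicates
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise TableError(f"{path}: duplicated sample header {s!r}")
        seen.add(s)
    taxa = list(raw.iloc[:, 0])
    seen = set()
    for t in taxa:
        if t in seen:
            raise TableError(f"{path}: duplicated taxon id {t!r}")
        seen.add(t)
    mat = np.empty((len(taxa), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        col = raw.iloc[:, j + 1]
        for i, cell in enumerate(col):
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise TableError(
                    f"{path}: non-integer count at row {taxa[i]!r}, column {s!r}: {cell!r}"
                ) from None
            if v < 0:
                raise TableError(
                    f"{path}: negative count at row {taxa[i]!r}, column {s!r}: {v}"
                )
            mat[i, j] = v
    df = pd.DataFrame(mat, index=pd.Index(taxa, name="taxon_id"), columns=samples)
    return CountTable(df)


def write_count_table(t: CountTable, path: str | Path) -> None:
    """Write a count table as UTF-8 TSV with LF endings, plain integers."""
    df = t.df.copy()
    df.index.name = "taxon_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", lineterminator="\n")


def genus_label(lineage: Sequence[str]) -> str:
    """Genus-level label for one ranked lineage, with family fallback.

    The genus string is used directly unless it is empty or an uninformative
    placeholder.  An empty genus becomes ``Unclassified<Family>``; a
    placeholder genus becomes ``<Family> uncultured`` — the two remain
    distinct taxa under the same family.  If the family is empty too, the
    deepest non-empty rank is used with a rank prefix.
    """
    genus = lineage[RANKS.index("genus")].strip()
    family = lineage[RANKS.index("family")].strip()
    if genus and genus.lower() not in UNCULTURED_TOKENS:
        return genus
    if family:
        if genus:
            return f"{family} uncultured"
        return f"Unclassified{family}"
    # fall back to the deepest informative rank
    for rank in reversed(RANKS[:-2]):  # order, class, phylum, domain
        token = lineage[RANKS.index(rank)].strip()
        if token and token.lower() not in UNCULTURED_TOKENS:
            prefix = rank[0]
            warnings.warn(
                f"lineage has no genus or family; using {rank} rank: {token!r}",
                stacklevel=2,
            )
            suffix = " uncultured" if genus else ""
            return f"{prefix}__{token}{suffix}"
    raise TableError(f"lineage has no informative rank: {lineage!r}")


def collapse_to_genus(raw: CountTable, lin: LineageMap) -> CountTable:
    """Sum features sharing a genus-level label into genus-keyed taxa.

    Total reads are conserved.  Output taxa are sorted lexicographically for
    deterministic downstream files.
    """
    labels = []
    for fid in raw.taxon_ids:
        if fid not in lin:
            raise TableError(f"feature {fid!r} has no lineage")
        labels.append(genus_label(lin.lineages[fid]))
    grouped = raw.df.groupby(pd.Index(labels, name="taxon_id"), sort=True).sum()
    return CountTable(grouped)


def filter_low_depth(
    t: CountTable, q: QCThresholds | None = None
) -> tuple[CountTable, list[str]]:
    """Drop samples whose total reads fall below the library-size floor."""
    q = q or QCThresholds()
    depths = t.sample_depths()
    keep = [s for s in t.sample_ids if depths[s] >= q.min_sample_reads]
    removed = [s for s in t.sample_ids if depths[s] < q.min_sample_reads]
    if not keep:
        raise TableError(
            f"all {len(removed)} samples fall below {q.min_sample_reads} reads"
        )
    return CountTable(t.df[keep]), removed


def to_relative_abundance(t: CountTable) -> RelAbundTable:
    """Total-sum scale each sample column to proportions."""
    depths = t.sample_depths()
    zero = depths.index[depths.to_numpy() == 0]
    if len(zero):
        raise TableError(f"sample {zero[0]!r} has zero total reads")
    return RelAbundTable(t.df / depths)
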