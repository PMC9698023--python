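"""Core-microbiome extraction and percentile reference ranges.

The core taxon set is every genus detected (>= 25 reads) in at least 55% of
healthy-cohort samples.  Two per-sample summary metrics follow: the *core
microbiome sum* (summed relative abundance of all core taxa, in percent) and
*core taxa present* (percent of the core set detected).  Samples whose core
sum falls strictly below the cohort's 2.5th percentile are excluded, and
from the remainder each core taxon gets a reference range: median, SD,
prevalence and the 2.5th/10th/90th/97.5th percentiles of its relative
abundance over the samples in which it is detected.  New samples can then be
placed band-by-band against the stored ranges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .table_io import CountTable, RelAbundTable, TableError

__all__ = [
    "CoreDefinition",
    "TaxonRange",
    "CoreReference",
    "SampleAssessment",
    "taxon_prevalence",
    "extract_core",
    "core_sum",
    "core_taxa_present",
    "core_metrics",
    "exclude_low_core_samples",
    "build_reference",
    "assess_sample",
    "load_printed_reference",
    "load_printed_cohort",
]

_FIXTURES = Path(__file__).parent / "fixtures"

#: reference-band labels for one core taxon in one sample
STATUSES = ("not_detected", "below_p2_5", "low", "typical", "high", "above_p97_5")


@dataclass
class CoreDefinition:
    """Prevalence/detection thresholds that define core membership."""

    prevalence_threshold: float = 0.55
    detection_reads: int = 25
    #: compute per-taxon percentiles over detected samples only (default) or
    #: over all retained samples
    detected_only: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_threshold <= 1):
            raise ValueError("prevalence threshold must be in (0, 1]")
        if self.detection_reads <= 0:
            raise ValueError("detection_reads must be positive")


@dataclass
class TaxonRange:
    """Reference range for one taxon; abundance fields in percent units."""

    taxon: str
    median: float
    sd: float
    prevalence: float  # % of cohort samples with detection; NaN for the core total
    p2_5: float
    p10: float
    p90: float
    p97_5: float
    n_detected: int
    unstable: bool = False

    def __post_init__(self) -> None:
        qs = (self.p2_5, self.p10, self.median, self.p90, self.p97_5)
        if not all(a <= b + 1e-12 for a, b in zip(qs, qs[1:])):
            raise ValueError(f"{self.taxon}: percentiles are not monotone: {qs}")
        if not np.isnan(self.prevalence) and not (0 <= self.prevalence <= 100):
            raise ValueError(f"{self.taxon}: prevalence out of [0, 100]")


@dataclass
class CoreReference:
    """Core taxon set plus per-taxon ranges and cohort provenance."""

    definition: CoreDefinition
    core_taxa: list[str]
    ranges: dict[str, TaxonRange]
    core_total_range: TaxonRange
    excluded_samples: list[str]
    cohort_n: int

    def __post_init__(self) -> None:
        extra = set(self.ranges) - set(self.core_taxa)
        if extra:
            raise ValueError(f"ranges for non-core taxa: {sorted(extra)}")

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(self.ranges[g]) for g in self.core_taxa]
        rows.append(asdict(self.core_total_range))
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "definition": asdict(self.definition),
            "core_taxa": self.core_taxa,
            "ranges": {g: asdict(r) for g, r in self.ranges.items()},
            "core_total_range": asdict(self.core_total_range),
            "excluded_samples": self.excluded_samples,
            "cohort_n": self.cohort_n,
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CoreReference":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            definition=CoreDefinition(**payload["definition"]),
            core_taxa=payload["core_taxa"],
            ranges={g: TaxonRange(**r) for g, r in payload["ranges"].items()},
            core_total_range=TaxonRange(**payload["core_total_range"]),
            excluded_samples=payload["excluded_samples"],
            cohort_n=payload["cohort_n"],
        )


@dataclass
class SampleAssessment:
    """Band placement of one sample against a stored reference."""

    sample_id: str
    statuses: dict[str, str]  # core taxon -> status
    observed_pct: dict[str, float]
    core_sum_pct: float
    core_taxa_present_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": list(self.statuses),
                "status": list(self.statuses.values()),
                "observed_pct": [self.observed_pct[g] for g in self.statuses],
            }
        )


def taxon_prevalence(t: CountTable, d: CoreDefinition | None = None) -> pd.Series:
    """Per-taxon detection prevalence in [0, 1] (detection = >= 25 reads)."""
    d = d or CoreDefinition()
    if t.shape[1] < 1:
        raise TableError("prevalence needs at least one sample")
    return (t.df >= d.detection_reads).mean(axis=1)


def extract_core(t: CountTable, d: CoreDefinition | None = None) -> list[str]:
    """Taxa detected in at least the threshold share of samples (>= rule)."""
    d = d or CoreDefinition()
    prev = taxon_prevalence(t, d)
    core = [g for g in t.taxon_ids if prev[g] >= d.prevalence_threshold]
    if not core:
        warnings.warn("no taxa meet the core prevalence threshold", stacklevel=2)
    return core


def core_sum(rel_column: pd.Series, core: Sequence[str]) -> float:
    """Summed relative abundance of core taxa in one sample, in percent."""
    present = [g for g in core if g in rel_column.index]
    return 100.0 * float(rel_column.loc[present].sum())


def core_taxa_present(
    count_column: pd.Series, core: Sequence[str], d: CoreDefinition | None = None
) -> float:
    """Percent of the core taxon set detected (>= 25 reads) in one sample."""
    d = d or CoreDefinition()
    if not core:
        raise ValueError("core set is empty")
    detected = sum(
        1
        for g in core
        if g in count_column.index and count_column.loc[g] >= d.detection_reads
    )
    return 100.0 * detected / len(core)


def core_metrics(
    counts: CountTable,
    rel: RelAbundTable,
    core: Sequence[str],
    d: CoreDefinition | None = None,
) -> pd.DataFrame:
    """Both core metrics for every sample (vectorized convenience)."""
    d = d or CoreDefinition()
    core = [g for g in core if g in counts.df.index]
    sums = 100.0 * rel.df.loc[core].sum(axis=0)
    if core:
        present = 100.0 * (counts.df.loc[core] >= d.detection_reads).mean(axis=0)
    else:
        present = pd.Series(np.nan, index=counts.sample_ids)
    return pd.DataFrame({"core_sum_pct": sums, "core_taxa_present_pct": present})


def exclude_low_core_samples(
    rel: RelAbundTable,
    core: Sequence[str],
    q: float = 2.5,
) -> tuple[list[str], list[str], float]:
    """Drop samples whose core sum is strictly below the q-th percentile.

    The threshold is the linear-interpolation percentile of the core sums
    over all cohort samples; ties with the threshold are retained.
    """
    if rel.df.shape[1] < 2:
        raise ValueError("need at least two samples")
    core = [g for g in core if g in rel.df.index]
    sums = 100.0 * rel.df.loc[core].sum(axis=0)
    threshold = float(np.percentile(sums.to_numpy(), q))
    retained = [s for s in rel.sample_ids if sums[s] >= threshold]
    excluded = [s for s in rel.sample_ids if sums[s] < threshold]
    return retained, excluded, threshold


def _range_from_values(
    taxon: str, values: np.ndarray, prevalence: float, n_detected: int
) -> TaxonRange:
    qs = np.percentile(values, [2.5, 10, 50, 90, 97.5]) if values.size else [np.nan] * 5
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return TaxonRange(
        taxon=taxon,
        median=float(qs[2]),
        sd=sd,
        prevalence=prevalence,
        p2_5=float(qs[0]),
        p10=float(qs[1]),
        p90=float(qs[3]),
        p97_5=float(qs[4]),
        n_detected=n_detected,
        unstable=n_detected < 3,
    )


def build_reference(
    counts: CountTable,
    rel: RelAbundTable,
    core: Sequence[str],
    d: CoreDefinition | None = None,
    excluded_samples: Sequence[str] = (),
) -> CoreReference:
    """Percentile reference ranges for every core taxon.

    Expects the low-core-sum exclusion to have been applied already (pass
    the excluded ids for provenance).  Per-taxon quantiles and SD are taken
    over detected samples only by default (``d.detected_only``); prevalence
    uses the detection rule over all retained samples.  A taxon detected in
    fewer than three samples is flagged unstable.
    """
    d = d or CoreDefinition()
    ranges: dict[str, TaxonRange] = {}
    n = counts.shape[1]
    for g in core:
        det_mask = (counts.df.loc[g] >= d.detection_reads).to_numpy()
        prevalence = 100.0 * det_mask.mean()
        vals = 100.0 * rel.df.loc[g].to_numpy()
        if d.detected_only:
            vals = vals[det_mask]
        n_det = int(det_mask.sum())
        if n_det < 3:
            warnings.warn(f"core taxon {g!r} detected in only {n_det} samples", stacklevel=2)
        ranges[g] = _range_from_values(g, vals, prevalence, n_det)
    core_sums = 100.0 * rel.df.loc[[g for g in core if g in rel.df.index]].sum(axis=0)
    total = _range_from_values(
        "Core Microbiome Total", core_sums.to_numpy(), float("nan"), n
    )
    return CoreReference(
        definition=d,
        core_taxa=list(core),
        ranges=ranges,
        core_total_range=total,
        excluded_samples=list(excluded_samples),
        cohort_n=n,
    )


def _band(value: float, r: TaxonRange) -> str:
    """Band for a detected observation; boundary values go to the inner band."""
    if value < r.p2_5:
        return "below_p2_5"
    if value < r.p10:
        return "low"
    if value <= r.p90:
        return "typical"
    if value <= r.p97_5:
        return "high"
    return "above_p97_5"


def assess_sample(
    count_column: pd.Series,
    rel_column: pd.Series,
    ref: CoreReference,
    sample_id: str = "sample",
) -> SampleAssessment:
    """Place one sample's core taxa into reference bands.

    Taxa absent from the sample's index are treated as zero counts (hence
    ``not_detected``).  Taxa in the sample but not in the reference are
    ignored.
    """
    if not ref.core_taxa:
        raise ValueError("reference has no core taxa")
    d = ref.definition
    statuses: dict[str, str] = {}
    observed: dict[str, float] = {}
    for g in ref.core_taxa:
        cnt = float(count_column.loc[g]) if g in count_column.index else 0.0
        pct = 100.0 * float(rel_column.loc[g]) if g in rel_column.index else 0.0
        observed[g] = pct
        if cnt < d.detection_reads:
            statuses[g] = "not_detected"
        else:
            statuses[g] = _band(pct, ref.ranges[g])
    return SampleAssessment(
        sample_id=sample_id,
        statuses=statuses,
        observed_pct=observed,
        core_sum_pct=core_sum(rel_column, ref.core_taxa),
        core_taxa_present_pct=core_taxa_present(count_column, ref.core_taxa, d),
    )


def load_printed_reference(path: str | Path | None = None) -> pd.DataFrame:
    """Load the bundled published core-reference table (30 genera + total).

    Columns: phylum..genus taxonomy, median, sd, prevalence and the four
    percentiles, all in percent units as printed.
    """
    path = Path(path) if path else _FIXTURES / "table2_core_reference.tsv"
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for row in df.itertuples(index=False):
        prev = row.prevalence if not pd.isna(row.prevalence) else float("nan")
        TaxonRange(
            taxon=row.genus,
            median=row.median,
            sd=row.sd,
            prevalence=prev,
            p2_5=row.p2_5,
            p10=row.p10,
            p90=row.p90,
            p97_5=row.p97_5,
            n_detected=3,
        )
    return df


def load_printed_cohort(path: str | Path | None = None) -> pd.DataFrame:
    """Load the bundled published cohort characteristics table (age classes)."""
    path = Path(path) if path else _FIXTURES / "table1_cohort.tsv"
    return pd.read_csv(path, sep="\t")
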