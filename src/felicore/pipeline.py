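"""Stage orchestration: config, seed fan-out, manifests, file outputs.

Each pipeline function is a plain library call that the CLI wraps thinly.
A single run seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence`` spawning, so any stage can be re-run in
isolation and every run is bit-reproducible from (config, inputs, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_filter import (
    CatMetadata,
    HealthyCriteria,
    is_healthy_reference,
    read_metadata,
    write_metadata,
)
from .community_stats import (
    PermutationConfig,
    alpha_diversity_table,
    bray_curtis_matrix,
    dip_test,
    pairwise_permanova,
    permanova,
    permdisp,
)
from .core_reference import (
    CoreDefinition,
    CoreReference,
    assess_sample,
    build_reference,
    core_metrics,
    exclude_low_core_samples,
    extract_core,
    load_printed_cohort,
    load_printed_reference,
)
from .diff_abundance import DAConfig, da_filter, fit_da, tss_log
from .synthetic_data import (
    SimSpec,
    paperlike_spec,
    simulate_cohort,
    to_cat_metadata,
    truth_report,
)
from .table_io import (
    CountTable,
    QCThresholds,
    collapse_to_genus,
    filter_low_depth,
    read_count_table,
    read_lineage_map,
    to_relative_abundance,
    write_count_table,
)

__all__ = [
    "RunConfig",
    "stage_seeds",
    "run_build_reference",
    "run_assess",
    "run_stats",
    "run_da",
    "run_simulate",
    "fixtures_check",
]

STAGES = ("simulate", "core", "dip", "stats", "da")


@dataclass
class RunConfig:
    counts_path: Optional[str] = None
    taxonomy_path: Optional[str] = None
    metadata_path: Optional[str] = None
    outdir: str = "felicore_out"
    seed: int = 0
    qc: QCThresholds = field(default_factory=QCThresholds)
    healthy: HealthyCriteria = field(default_factory=HealthyCriteria)
    core: CoreDefinition = field(default_factory=CoreDefinition)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    da: DAConfig = field(default_factory=DAConfig)
    dip_permutations: int = 499

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        plain = {
            "counts_path", "taxonomy_path", "metadata_path", "outdir", "seed",
            "dip_permutations",
        }
        nested = {
            "qc": QCThresholds,
            "healthy": HealthyCriteria,
            "core": CoreDefinition,
            "permutation": PermutationConfig,
            "da": DAConfig,
        }
        for key, val in raw.items():
            if key in plain:
                kwargs[key] = val
            elif key in nested:
                sub = dict(val)
                for tup_key in ("bcs_range", "age_range_years"):
                    if tup_key in sub:
                        sub[tup_key] = tuple(sub[tup_key])
                if "excluded_medications" in sub:
                    sub["excluded_medications"] = frozenset(sub["excluded_medications"])
                kwargs[key] = nested[key](**sub)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)

    def content_hash(self) -> str:
        def default(o):
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan one run seed out to independent per-stage seeds (< 2^31)."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def _write_manifest(outdir: Path, config: RunConfig, counts: dict) -> None:
    manifest = {
        "felicore_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_seeds": stage_seeds(config.seed),
        "per_stage_counts": counts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _log_event(outdir: Path, event: str, **fields) -> None:
    rec = {"event": event, **fields}
    with open(outdir / "run.log", "a", encoding="utf-8", newline="\n") as fh:
        fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def _load_genus_table(config: RunConfig) -> CountTable:
    table = read_count_table(config.counts_path)
    if config.taxonomy_path:
        table = collapse_to_genus(table, read_lineage_map(config.taxonomy_path))
    return table


def run_build_reference(config: RunConfig) -> CoreReference:
    """Full reference build: cohort filter, QC, core, exclusion, ranges, dips."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    counts_log: dict[str, int] = {}

    cats = read_metadata(config.metadata_path)
    verdicts = {m.cat_id: is_healthy_reference(m, config.healthy) for m in cats}
    healthy_ids = [cid for cid, (ok, _) in verdicts.items() if ok]
    counts_log["cats_total"] = len(cats)
    counts_log["cats_healthy"] = len(healthy_ids)

    attrition: dict[str, int] = {}
    for _, (ok, reasons) in verdicts.items():
        for r in reasons:
            attrition[r] = attrition.get(r, 0) + 1
    pd.Series(attrition, name="n_failed").rename_axis("criterion").to_frame().to_csv(
        outdir / "attrition.tsv", sep="\t"
    )

    table = _load_genus_table(config)
    table, removed = filter_low_depth(table, config.qc)
    counts_log["samples_low_depth"] = len(removed)

    keep = [s for s in table.sample_ids if s in set(healthy_ids)]
    if not keep:
        raise ValueError(
            "no healthy-cohort samples survive the filters; see attrition.tsv"
        )
    table = CountTable(table.df[keep])
    counts_log["cohort_samples"] = len(keep)

    rel = to_relative_abundance(table)
    core = extract_core(table, config.core)
    counts_log["core_taxa"] = len(core)

    retained, excluded, threshold = exclude_low_core_samples(rel, core)
    counts_log["samples_excluded_low_core"] = len(excluded)
    table_kept = CountTable(table.df[retained])
    rel_kept = to_relative_abundance(table_kept)
    ref = build_reference(table_kept, rel_kept, core, config.core, excluded)
    ref.to_tsv(outdir / "core_reference.tsv")
    ref.to_json(outdir / "core_reference.json")

    # unimodality screen over detected-sample relative abundances
    dip_rows = []
    cfg = PermutationConfig(config.dip_permutations, seeds["dip"])
    for g in core:
        mask = (table_kept.df.loc[g] >= config.core.detection_reads).to_numpy()
        vals = 100.0 * rel_kept.df.loc[g].to_numpy()[mask]
        if vals.size >= 4:
            res = dip_test(vals, cfg)
            dip_rows.append(
                {"taxon": g, "dip": res.statistic, "p": res.p, "n": vals.size}
            )
    pd.DataFrame(dip_rows).to_csv(outdir / "dip_tests.tsv", sep="\t", index=False)

    _write_manifest(outdir, config, counts_log)
    _log_event(outdir, "build_reference", threshold=threshold, **counts_log)
    return ref


def run_assess(config: RunConfig, reference_path: str | Path) -> pd.DataFrame:
    """Assess every sample of the configured table against a stored reference."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = CoreReference.from_json(reference_path)
    table = _load_genus_table(config)
    shared = set(table.taxon_ids) & set(ref.core_taxa)
    if not shared:
        raise ValueError(
            "sample taxa are wholly disjoint from the reference; "
            "check that both tables are collapsed to the same genus level"
        )
    rel = to_relative_abundance(table)
    rows = []
    for s in table.sample_ids:
        a = assess_sample(table.df[s], rel.df[s], ref, sample_id=s)
        frame = a.to_frame()
        frame.insert(0, "sample_id", s)
        rows.append(frame)
        with open(outdir / f"assessment_{s}.json", "w", encoding="utf-8",
                  newline="\n") as fh:
            json.dump(
                {
                    "sample_id": s,
                    "core_sum_pct": a.core_sum_pct,
                    "core_taxa_present_pct": a.core_taxa_present_pct,
                    "statuses": a.statuses,
                    "observed_pct": a.observed_pct,
                },
                fh,
                indent=1,
            )
            fh.write("\n")
    out = pd.concat(rows, ignore_index=True)
    out.to_csv(outdir / "assessments.tsv", sep="\t", index=False)
    return out


def run_stats(config: RunConfig, group: str) -> dict[str, pd.DataFrame]:
    """Alpha diversity plus PERMANOVA/PERMDISP/pairwise for one grouping."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    table = _load_genus_table(config)
    table, _ = filter_low_depth(table, config.qc)
    meta = pd.read_csv(config.metadata_path, sep="\t", dtype=str,
                       keep_default_na=False).set_index("cat_id")
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    if group not in meta.columns:
        raise ValueError(
            f"unknown grouping column {group!r}; available: {list(meta.columns)}"
        )
    table = CountTable(table.df[list(meta.index)])
    rel = to_relative_abundance(table)
    alpha = alpha_diversity_table(table.df)
    dm = bray_curtis_matrix(rel.df)
    cfg = PermutationConfig(config.permutation.n_permutations, seeds["stats"])
    groups = meta[group]
    res = permanova(dm, groups.astype(str), cfg)[0]
    disp = permdisp(dm, groups.astype(str), cfg)
    pw = pairwise_permanova(dm, groups.astype(str), cfg)
    tests = pd.DataFrame(
        [
            {"test": r.name, "statistic": r.statistic, "R2": r.r2, "p": r.p,
             "df1": r.df[0], "df2": r.df[1], "n_permutations": r.n_permutations,
             "seed": r.seed}
            for r in (res, disp)
        ]
    )
    alpha.rename_axis("sample_id").to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    dm.to_tsv(outdir / "bray_curtis.tsv")
    tests.to_csv(outdir / "tests.tsv", sep="\t", index=False)
    pw.to_csv(outdir / "pairwise_permanova.tsv", sep="\t", index=False)
    _log_event(outdir, "stats", group=group, seed=seeds["stats"])
    return {"alpha": alpha, "tests": tests, "pairwise": pw}


def run_da(config: RunConfig, predictors: Sequence[str]) -> pd.DataFrame:
    """Differential abundance against the configured metadata predictors."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _load_genus_table(config)
    table, _ = filter_low_depth(table, config.qc)
    meta = pd.read_csv(config.metadata_path, sep="\t", keep_default_na=False,
                       na_values=[""]).set_index("cat_id")
    meta.index = meta.index.astype(str)
    keep = [s for s in table.sample_ids if s in meta.index]
    table = CountTable(table.df[keep])
    rel = to_relative_abundance(table)
    kept_taxa = da_filter(rel, config.da)
    rel_kept = type(rel)(rel.df.loc[kept_taxa] /
                         rel.df.loc[kept_taxa].sum(axis=0))
    transformed = tss_log(rel_kept, config.da)
    for p in predictors:
        if meta[p].dtype == object:
            vals = meta[p].astype(str)
            if set(vals.unique()) <= {"Y", "N"}:
                meta[p] = (vals == "Y").astype(float)
    result = fit_da(transformed, meta, predictors)
    result.to_csv(outdir / "differential_abundance.tsv", sep="\t", index=False)
    return result


def run_simulate(spec: SimSpec | str, seed: int, outdir: str | Path) -> dict:
    """Write one synthetic cohort (counts, metadata, ground truth) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(spec, str):
        if spec != "paperlike":
            raise ValueError(f"unknown canned spec {spec!r}")
        spec = paperlike_spec(seed)
    table, meta, truth = simulate_cohort(spec)
    write_count_table(table, outdir / "counts.tsv")
    write_metadata(to_cat_metadata(meta), outdir / "metadata.tsv")
    report = truth_report(truth)
    for name, df in report.items():
        df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
    summary = {
        "n_samples": table.shape[1],
        "n_taxa": table.shape[0],
        "total_reads": int(table.counts.sum()),
        "median_library": float(np.median(truth.library_sizes)),
        "n_core_truth": int(sum(t.is_core_truth for t in spec.taxa)),
    }
    with open(outdir / "simulation_summary.json", "w", encoding="utf-8",
              newline="\n") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")
    return summary


def fixtures_check() -> dict[str, float]:
    """Recompute the consistency facts of the bundled printed tables.

    Loads the published core-reference and cohort tables and recomputes the
    headline numbers: genus rows, phyla, the prevalence extremes against
    the 55% rule, the largest median, and the age-class total.
    """
    ref = load_printed_reference()
    genus_rows = ref[ref["phylum"].astype(str).str.len() > 0]
    cohort = load_printed_cohort()
    return {
        "core_genus_rows": int(len(genus_rows)),
        "core_phyla": int(genus_rows["phylum"].nunique()),
        "min_prevalence_pct": float(genus_rows["prevalence"].min()),
        "max_prevalence_pct": float(genus_rows["prevalence"].max()),
        "max_median_pct": float(genus_rows["median"].max()),
        "core_total_median_pct": float(
            ref.loc[ref["genus"] == "Core Microbiome Total", "median"].iloc[0]
        ),
        "age_class_total_n": int(cohort["n"].sum()),
        "healthy_reference_n": int(cohort["n"].sum() - cohort.loc[
            cohort["age_class"] == "senior", "n"
        ].sum()),
    }
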