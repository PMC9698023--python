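import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from felicore.core_reference import (
    CoreDefinition,
    CoreReference,
    TaxonRange,
    assess_sample,
    build_reference,
    core_sum,
    core_taxa_present,
    exclude_low_core_samples,
    extract_core,
    load_printed_cohort,
    load_printed_reference,
    taxon_prevalence,
)
from felicore.table_io import CountTable, RelAbundTable, to_relative_abundance
from felicore.synthetic_data import paperlike_spec, simulate_cohort

from conftest import manual_percentile, random_count_table


def _table(rows: dict, samples=None) -> CountTable:
    df = pd.DataFrame(rows).T
    if samples:
        df.columns = samples
    else:
        df.columns = [f"s{i}" for i in range(df.shape[1])]
    df.index.name = "taxon_id"
    return CountTable(df.astype(np.int64))


class TestPrevalence:
    def test_24_reads_is_not_detection(self):
        t = _table({"A": [24, 25, 100, 0]})
        assert taxon_prevalence(t)["A"] == pytest.approx(0.5)

    def test_six_of_ten(self):
        t = _table({"A": [30] * 6 + [0] * 4})
        assert taxon_prevalence(t)["A"] == pytest.approx(0.6)

    def test_all_zero_taxon(self):
        t = _table({"A": [0, 0, 0], "B": [99, 99, 99]})
        assert taxon_prevalence(t)["A"] == 0.0


class TestExtractCore:
    def test_55_pct_boundary_included(self):
        rows = {"edge": [25] * 11 + [0] * 9, "other": [25] * 20}
        core = extract_core(_table(rows))
        assert "edge" in core

    def test_50_pct_excluded(self):
        rows = {"half": [25] * 5 + [0] * 5, "other": [25] * 10}
        assert "half" not in extract_core(_table(rows))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        t = random_count_table(rng, n_taxa=10, n_samples=20)
        lo = set(extract_core(t, CoreDefinition(prevalence_threshold=0.3)))
        hi = set(extract_core(t, CoreDefinition(prevalence_threshold=0.7)))
        assert hi <= lo

    def test_empty_core_warns_and_returns_empty(self):
        t = _table({"A": [1, 1, 1]})
        with pytest.warns(UserWarning):
            assert extract_core(t) == []


class TestCoreMetrics:
    def test_core_sum_examples(self):
        col = pd.Series({"A": 0.30, "B": 0.25, "C": 0.45})
        assert core_sum(col, ["A", "B", "C"]) == pytest.approx(100.0)
        assert core_sum(col, []) == 0.0
        assert core_sum(col, ["A", "B"]) == pytest.approx(55.0)

    def test_core_plus_noncore_is_100(self):
        rng = np.random.default_rng(11)
        t = random_count_table(rng, n_taxa=8, n_samples=4)
        rel = to_relative_abundance(t)
        core = ["g0", "g3", "g5"]
        rest = [g for g in t.taxon_ids if g not in core]
        for s in t.sample_ids:
            total = core_sum(rel.df[s], core) + core_sum(rel.df[s], rest)
            assert total == pytest.approx(100.0)

    def test_core_taxa_present(self):
        col = pd.Series({"A": 100, "B": 24, "C": 0, "D": 25})
        assert core_taxa_present(col, ["A", "B", "C", "D"]) == pytest.approx(50.0)
        assert core_taxa_present(col, ["A", "D"]) == pytest.approx(100.0)

    def test_empty_core_is_error(self):
        with pytest.raises(ValueError):
            core_taxa_present(pd.Series({"A": 5}), [])


class TestLowCoreExclusion:
    def test_identical_sums_nothing_excluded(self):
        t = _table({"A": [50, 50, 50, 50], "B": [50, 50, 50, 50]})
        rel = to_relative_abundance(t)
        retained, excluded, thr = exclude_low_core_samples(rel, ["A"])
        assert excluded == [] and len(retained) == 4

    def test_hundred_distinct_sums_match_brute_force(self):
        rng = np.random.default_rng(42)
        n = 100
        core_frac = rng.uniform(0.3, 0.9, n)
        counts = {
            "core": (core_frac * 10000).astype(int),
            "rest": ((1 - core_frac) * 10000).astype(int),
        }
        df = pd.DataFrame(counts).T
        df.columns = [f"s{i}" for i in range(n)]
        df.index.name = "t"
        rel = to_relative_abundance(CountTable(df.astype(np.int64)))
        retained, excluded, thr = exclude_low_core_samples(rel, ["core"])
        sums = 100.0 * rel.df.loc["core"]
        expected_thr = manual_percentile(np.sort(sums.to_numpy()), 2.5)
        assert thr == pytest.approx(expected_thr, abs=1e-12)
        assert set(excluded) == set(sums.index[sums < expected_thr])
        # the lowest two always fall below; with distinct values the
        # interpolated threshold sits strictly above the 3rd smallest too
        assert len(excluded) == 3

    def test_threshold_deterministic_on_rerun(self):
        rng = np.random.default_rng(0)
        t = random_count_table(rng, n_taxa=5, n_samples=161)
        rel = to_relative_abundance(t)
        a = exclude_low_core_samples(rel, ["g0", "g1"])
        b = exclude_low_core_samples(rel, ["g0", "g1"])
        assert a == b


class TestBuildReference:
    def test_constant_taxon_all_quantiles_equal(self):
        t = _table({"A": [500] * 6, "B": [9500] * 6})
        rel = to_relative_abundance(t)
        ref = build_reference(t, rel, ["A"])
        r = ref.ranges["A"]
        assert (r.p2_5, r.p10, r.median, r.p90, r.p97_5) == (5, 5, 5, 5, 5)

    def test_detected_values_1_to_5_match_hand_percentiles(self):
        counts = {
            "A": [100, 200, 300, 400, 500, 0],
            "B": [9900, 9800, 9700, 9600, 9500, 10000],
        }
        t = _table(counts)
        rel = to_relative_abundance(t)
        ref = build_reference(t, rel, ["A"])
        r = ref.ranges["A"]
        vals = sorted([1, 2, 3, 4, 5])
        assert r.median == pytest.approx(manual_percentile(vals, 50), abs=1e-12)
        for q, field in [(2.5, "p2_5"), (10, "p10"), (90, "p90"), (97.5, "p97_5")]:
            assert getattr(r, field) == pytest.approx(
                manual_percentile(vals, q), abs=1e-12
            )
        assert r.prevalence == pytest.approx(100 * 5 / 6)

    def test_quantile_order_invariant_on_synthetic_cohort(self):
        t, _, _ = simulate_cohort(paperlike_spec(5, n_samples=60))
        rel = to_relative_abundance(t)
        core = extract_core(t)
        ref = build_reference(t, rel, core)
        for r in ref.ranges.values():
            assert r.p2_5 <= r.p10 <= r.median <= r.p90 <= r.p97_5

    def test_detected_only_switch(self):
        counts = {"A": [1000, 0, 0, 0], "B": [9000, 100, 100, 100]}
        t = _table(counts)
        rel = to_relative_abundance(t)
        with pytest.warns(UserWarning):
            det = build_reference(t, rel, ["A"], CoreDefinition(detected_only=True))
        with pytest.warns(UserWarning):
            allq = build_reference(t, rel, ["A"], CoreDefinition(detected_only=False))
        assert det.ranges["A"].median == pytest.approx(10.0)
        assert allq.ranges["A"].median == pytest.approx(0.0)
        assert det.ranges["A"].unstable  # detected in 1 < 3 samples

    def test_round_trip_json(self, tmp_path):
        t = _table({"A": [100] * 5, "B": [9900] * 5})
        rel = to_relative_abundance(t)
        ref = build_reference(t, rel, ["A", "B"])
        path = tmp_path / "ref.json"
        ref.to_json(path)
        back = CoreReference.from_json(path)
        assert back.core_taxa == ref.core_taxa
        assert back.ranges["A"] == ref.ranges["A"]


class TestAssess:
    @pytest.fixture
    def reference(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(1, 9, 50)
        return CoreReference(
            definition=CoreDefinition(),
            core_taxa=["A"],
            ranges={
                "A": TaxonRange(
                    taxon="A",
                    median=float(np.median(vals)),
                    sd=float(np.std(vals, ddof=1)),
                    prevalence=100.0,
                    p2_5=float(np.percentile(vals, 2.5)),
                    p10=float(np.percentile(vals, 10)),
                    p90=float(np.percentile(vals, 90)),
                    p97_5=float(np.percentile(vals, 97.5)),
                    n_detected=50,
                )
            },
            core_total_range=TaxonRange("Core Microbiome Total", 50, 1,
                                        float("nan"), 40, 45, 60, 65, 50),
            excluded_samples=[],
            cohort_n=50,
        )

    def _cols(self, pct):
        # counts only drive detection; proportions are set exactly
        counts = pd.Series({"A": 0 if pct == 0 else 1000, "B": 10000})
        rel = pd.Series({"A": pct / 100.0, "B": 1.0 - pct / 100.0})
        return counts, rel

    def test_at_median_is_typical(self, reference):
        med = reference.ranges["A"].median
        counts, rel = self._cols(med)
        a = assess_sample(counts, rel, reference)
        assert a.statuses["A"] == "typical"

    def test_zero_reads_not_detected(self, reference):
        counts, rel = self._cols(0.0)
        a = assess_sample(counts, rel, reference)
        assert a.statuses["A"] == "not_detected"

    def test_above_p97_5(self, reference):
        counts, rel = self._cols(reference.ranges["A"].p97_5 + 5)
        a = assess_sample(counts, rel, reference)
        assert a.statuses["A"] == "above_p97_5"

    def test_boundary_values_take_inner_band(self, reference):
        r = reference.ranges["A"]
        for pct, expect in [(r.p2_5, "low"), (r.p10, "typical"),
                            (r.p90, "typical"), (r.p97_5, "high")]:
            counts, rel = self._cols(pct)
            a = assess_sample(counts, rel, reference)
            assert a.statuses["A"] == expect, pct

    def test_missing_taxon_treated_as_zero(self, reference):
        counts = pd.Series({"B": 10000})
        rel = counts / counts.sum()
        a = assess_sample(counts, rel, reference)
        assert a.statuses["A"] == "not_detected"
        assert a.core_sum_pct == 0.0

    def test_empty_reference_is_error(self, reference):
        empty = CoreReference(
            definition=CoreDefinition(), core_taxa=[], ranges={},
            core_total_range=reference.core_total_range,
            excluded_samples=[], cohort_n=0,
        )
        counts, rel = self._cols(5)
        with pytest.raises(ValueError):
            assess_sample(counts, rel, empty)


class TestPrintedFixtures:
    def test_reference_table_shape_and_invariants(self):
        df = load_printed_reference()  # loader enforces TaxonRange invariants
        genus = df[df["phylum"].astype(str).str.len() > 0]
        assert len(genus) == 30
        assert genus["phylum"].nunique() == 5
        assert genus["prevalence"].min() >= 55.0
        assert genus["prevalence"].between(55.6, 100).all()

    def test_cohort_table_totals(self):
        cohort = load_printed_cohort()
        assert cohort["n"].sum() == 167
        assert cohort.loc[cohort["age_class"] != "senior", "n"].sum() == 161


class TestQuantileConvergence:
    def test_reference_percentiles_approach_generator_truth(self):
        """Empirical detected-abundance quantiles converge to the latent
        log-normal quantiles for a taxon that dominates nothing (so the
        compositional normalization is nearly constant)."""
        rng = np.random.default_rng(21)
        n = 2000
        # one low-abundance taxon against a fixed large background
        latent = np.exp(np.log(0.5) + 0.6 * rng.standard_normal(n))
        bg = 100.0
        rel = latent / (latent + bg)
        true_med = 0.5 / (0.5 + bg)
        assert np.median(rel) == pytest.approx(true_med, rel=0.05)
        # order-statistic CI at n=2000 for the 10th percentile
        q10 = np.percentile(rel, 10)
        true_q10 = np.exp(np.log(0.5) - 0.6 * 1.2815515655) / (
            np.exp(np.log(0.5) - 0.6 * 1.2815515655) + bg
        )
        assert q10 == pytest.approx(true_q10, rel=0.10)
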