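"""UMI extraction, 3'-truncation classification, dedup tables, enrichment."""

import numpy as np
import pytest

from pegtherm.pegrna import TEVOPREQ1, assemble
from pegtherm.seq_io import ReadRecord
from pegtherm.synthetic import SimConfig, simulate_reads
from pegtherm.truncation import (
    DEFAULT_ADAPTER,
    Adapter3p,
    SpeciesCall,
    SpeciesCategory,
    categorize_endpoint,
    classify_read,
    compare_bound_vs_bulk,
    dedup_and_tabulate,
    extract_umi_and_trim,
    profile_library,
)

Q30 = 30
ADAPTER = DEFAULT_ADAPTER.sequence


def mkread(bases, read_id="r", umi=None):
    return ReadRecord(read_id, bases, [Q30] * len(bases), umi)


def bruteforce_endpoint(insert: str, ref: str) -> tuple[int, int]:
    """Exhaustive endpoint scan: for every reference prefix length e, the cost
    of aligning the insert to ref[:e] with end-gaps and unit mismatch costs.
    Returns (best endpoint, its cost); ties resolved to the longest endpoint."""
    n = len(insert)
    best_e, best_cost = 0, 10**9
    for e in range(1, len(ref) + 1):
        m = min(n, e)
        cost = sum(1 for a, b in zip(insert[:m], ref[:m]) if a != b or a == "N")
        cost += abs(n - e)
        if cost < best_cost or (cost == best_cost and e > best_e):
            best_e, best_cost = e, cost
    return best_e, best_cost


class TestExtractUmi:
    def test_exact_adapter_yields_insert_and_umi(self):
        insert, umi = "ACGTACGTACGTACGTACGT", "A" * 15
        out = extract_umi_and_trim(mkread(insert + umi + ADAPTER))
        assert out.bases == insert
        assert out.umi == umi
        assert len(out.quals) == len(out.bases)

    def test_one_mismatch_in_21_base_adapter_tolerated(self):
        insert, umi = "ACGTACGTACGTACGTACGT", "C" * 15
        mutated = "A" + ADAPTER[1:]
        assert mutated != ADAPTER
        out = extract_umi_and_trim(mkread(insert + umi + mutated))
        assert out.bases == insert and out.umi == umi

    def test_three_mismatches_not_tolerated(self):
        insert, umi = "ACGTACGTACGTACGTACGT", "C" * 15
        mutated = "AAA" + ADAPTER[3:]
        out = extract_umi_and_trim(mkread(insert + umi + mutated))
        assert out.umi is None

    def test_no_adapter_returns_read_unchanged(self):
        read = mkread("ACGTACGTACGTACGTACGTACGTACGT")
        out = extract_umi_and_trim(read)
        assert out.bases == read.bases and out.umi is None

    def test_adapter_without_room_for_umi_leaves_umi_absent(self):
        out = extract_umi_and_trim(mkread("ACGTACGTAC" + ADAPTER))  # only 10 nt before
        assert out.umi is None

    def test_partial_adapter_at_read_end(self):
        insert, umi = "ACGTACGTACGTACGTACGT", "G" * 15
        out = extract_umi_and_trim(mkread(insert + umi + ADAPTER[:14]))
        assert out.bases == insert and out.umi == umi

    def test_umi_within_adapter_layout(self):
        adapter = Adapter3p("GATCC" + ADAPTER, umi_offset=5)
        insert, umi = "ACGTACGTACGTACGTACGT", "G" * 15
        out = extract_umi_and_trim(mkread(insert + "GATCC" + umi + ADAPTER), adapter)
        assert out.bases == insert and out.umi == umi


class TestClassifyRead:
    @pytest.fixture
    def ref(self, locus, edit):
        return assemble(locus, edit, pbs_len=13, ha_len=10, name="ref13")

    def insert_to(self, ref, endpoint, umi="A" * 15):
        return mkread(ref.sequence.replace("U", "T")[:endpoint], umi=umi)

    def test_full_reference_is_full_length(self, ref):
        call = classify_read(self.insert_to(ref, len(ref)), ref)
        assert call.category is SpeciesCategory.FULL_LENGTH
        assert call.endpoint == len(ref)

    def test_pbs_functional_boundary_at_7_remaining(self, ref):
        pbs_start, _ = ref.boundaries["pbs"]
        call = classify_read(self.insert_to(ref, pbs_start + 7), ref)
        assert call.category is SpeciesCategory.PBS_TRUNC_FUNCTIONAL

    def test_pbs_insufficient_below_7_remaining(self, ref):
        pbs_start, _ = ref.boundaries["pbs"]
        call = classify_read(self.insert_to(ref, pbs_start + 6), ref)
        assert call.category is SpeciesCategory.PBS_TRUNC_INSUFFICIENT

    def test_rtt_and_scaffold_truncations(self, ref):
        rtt_start, rtt_end = ref.boundaries["rtt"]
        assert classify_read(self.insert_to(ref, rtt_start + 2), ref).category is SpeciesCategory.RTT_TRUNC
        # endpoint exactly at the RTT/PBS border leaves 0 PBS nt: RTT species
        pbs_start, _ = ref.boundaries["pbs"]
        assert classify_read(self.insert_to(ref, pbs_start), ref).category is SpeciesCategory.RTT_TRUNC
        assert classify_read(self.insert_to(ref, 30), ref).category is SpeciesCategory.SCAFFOLD_TRUNC

    def test_epegrna_motif_truncation_counts_as_full_length_core(self, locus, edit):
        epeg = assemble(locus, edit, pbs_len=13, ha_len=10, motif3p=TEVOPREQ1)
        pbs_end = epeg.boundaries["pbs"][1]
        call = classify_read(self.insert_to(epeg, pbs_end + 5), epeg)
        assert call.category is SpeciesCategory.FULL_LENGTH
        assert call.motif_truncated
        full = classify_read(self.insert_to(epeg, len(epeg)), epeg)
        assert full.category is SpeciesCategory.FULL_LENGTH and not full.motif_truncated

    def test_missing_umi_or_short_insert_unassigned(self, ref):
        assert classify_read(mkread(ref.sequence.replace("U", "T")[:50]), ref).category is SpeciesCategory.UNASSIGNED
        assert classify_read(mkread("ACGTACGTACGT", umi="A" * 15), ref).category is SpeciesCategory.UNASSIGNED

    def test_low_identity_unassigned(self, ref, rng):
        garbage = "".join(rng.choice(list("ACGT"), size=60))
        assert classify_read(mkread(garbage, umi="A" * 15), ref).category is SpeciesCategory.UNASSIGNED

    def test_agrees_with_bruteforce_oracle_on_error_free_reads(self, ref):
        """1,000 error-free synthetic reads: classifier category == exhaustive
        endpoint-scan oracle category, 100% agreement."""
        cfg = SimConfig(seed=77, n_reads=1000, p_full=0.4, tail_geom_p=0.08)
        reads, _ = simulate_reads(ref, cfg)
        ref_dna = ref.sequence.replace("U", "T")
        agree = 0
        for read in reads:
            insert = extract_umi_and_trim(read)
            call = classify_read(insert, ref)
            e, _cost = bruteforce_endpoint(insert.bases, ref_dna)
            oracle_cat, _ = categorize_endpoint(e, ref)
            agree += call.category is oracle_cat
        assert agree == 1000

    def test_error_tolerant_assignment(self, ref):
        """At 1% substitution error, >= 99% of reads with insert >= 30 nt are
        assigned their true category."""
        cfg = SimConfig(seed=78, n_reads=2000, p_full=0.5, error_rate=0.01)
        reads, truth = simulate_reads(ref, cfg)
        ok = tot = 0
        for read, (_, row) in zip(reads, truth.iterrows()):
            if row.endpoint < 30:
                continue
            call = classify_read(extract_umi_and_trim(read), ref)
            tot += 1
            ok += call.category.value == row.category
        assert tot > 1500
        assert ok / tot >= 0.99


class TestDedupAndTabulate:
    def call(self, cat, endpoint, umi, rid="r"):
        return SpeciesCall(rid, cat, endpoint, umi)

    def test_shared_umi_collapses_to_one_molecule(self):
        calls = [self.call(SpeciesCategory.FULL_LENGTH, 100, "A" * 15, f"r{i}") for i in range(3)]
        table = dedup_and_tabulate(calls, "lib")
        assert table.counts.loc["FULL_LENGTH", "raw_reads"] == 3
        assert table.counts.loc["FULL_LENGTH", "umi_count"] == 1

    def test_fractions_over_assigned_umis(self):
        calls = [self.call(SpeciesCategory.FULL_LENGTH, 100, f"{i:015d}".replace("0", "A").replace("1", "C").replace("2", "G").replace("3", "T"), f"a{i}") for i in range(30)]
        calls += [self.call(SpeciesCategory.RTT_TRUNC, 50, f"{i:015d}".replace("0", "T").replace("1", "G").replace("2", "C").replace("3", "A"), f"b{i}") for i in range(70)]
        table = dedup_and_tabulate(calls, "lib")
        assert table.counts.loc["FULL_LENGTH", "fraction"] == pytest.approx(0.3)
        assert table.counts.loc["RTT_TRUNC", "fraction"] == pytest.approx(0.7)
        assert table.counts["fraction"].dropna().sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_library_reports_nan_fractions(self):
        table = dedup_and_tabulate([], "empty")
        assert table.counts["umi_count"].sum() == 0
        assert table.counts["fraction"].isna().all()
        assert np.isnan(table.intact_pbs_fraction)

    def test_invariant_under_read_order_and_duplicates(self, rng):
        cats = [SpeciesCategory.FULL_LENGTH, SpeciesCategory.RTT_TRUNC, SpeciesCategory.PBS_TRUNC_FUNCTIONAL]
        calls = [
            self.call(cats[int(rng.integers(3))], int(rng.integers(40, 120)),
                      "".join(rng.choice(list("ACGT"), 15)), f"r{i}")
            for i in range(200)
        ]
        base = dedup_and_tabulate(calls, "lib")
        shuffled = dedup_and_tabulate(calls[::-1], "lib")
        duplicated = dedup_and_tabulate(calls + calls, "lib")
        assert base.counts["fraction"].equals(shuffled.counts["fraction"])
        assert base.counts["umi_count"].equals(duplicated.counts["umi_count"])

    def test_directional_1mm_clustering_merges_error_umis(self):
        # one true molecule (high count) + a 1-mismatch satellite (low count)
        calls = [self.call(SpeciesCategory.FULL_LENGTH, 100, "A" * 15, f"r{i}") for i in range(10)]
        calls.append(self.call(SpeciesCategory.FULL_LENGTH, 100, "C" + "A" * 14, "sat"))
        exact = dedup_and_tabulate(calls, "lib")
        clustered = dedup_and_tabulate(calls, "lib", cluster_1mm=True)
        assert exact.counts.loc["FULL_LENGTH", "umi_count"] == 2
        assert clustered.counts.loc["FULL_LENGTH", "umi_count"] == 1

    def test_intact_pbs_is_full_length_umi_fraction(self):
        calls = [self.call(SpeciesCategory.FULL_LENGTH, 100, "A" * 15)]
        calls += [self.call(SpeciesCategory.PBS_TRUNC_FUNCTIONAL, 95, "C" * 15)]
        table = dedup_and_tabulate(calls, "lib")
        assert table.intact_pbs_fraction == pytest.approx(0.5)


class TestCompareBoundVsBulk:
    def mktable(self, full, trunc, role, name):
        calls = [SpeciesCall(f"f{i}", SpeciesCategory.FULL_LENGTH, 100, f"A{i:014d}") for i in range(full)]
        calls += [SpeciesCall(f"t{i}", SpeciesCategory.RTT_TRUNC, 50, f"C{i:014d}") for i in range(trunc)]
        return dedup_and_tabulate(calls, name, role)

    def test_identical_tables_give_unit_ratios(self):
        a = self.mktable(50, 50, "BOUND", "a")
        b = self.mktable(50, 50, "BULK", "b")
        rep = compare_bound_vs_bulk(a, b)
        assert rep.loc["FULL_LENGTH", "ratio"] == pytest.approx(1.0)
        assert rep.loc["RTT_TRUNC", "ratio"] == pytest.approx(1.0)
        assert not rep.loc["RTT_TRUNC", "enriched"]

    def test_twofold_truncation_enrichment_detected(self):
        bound = self.mktable(50, 50, "BOUND", "bound")  # truncated 0.5
        bulk = self.mktable(75, 25, "BULK", "bulk")  # truncated 0.25
        rep = compare_bound_vs_bulk(bound, bulk)
        assert rep.loc["RTT_TRUNC", "ratio"] == pytest.approx(2.0)
        assert rep.loc["RTT_TRUNC", "enriched"]
        assert rep.loc["RTT_TRUNC", "p_value"] < 0.05

    def test_zero_bulk_fraction_warns_and_reports_inf(self):
        bound = self.mktable(50, 50, "BOUND", "bound")
        bulk = self.mktable(100, 0, "BULK", "bulk")
        with pytest.warns(UserWarning, match="inf"):
            rep = compare_bound_vs_bulk(bound, bulk)
        assert np.isinf(rep.loc["RTT_TRUNC", "ratio"])


class TestProfileLibrary:
    def test_end_to_end_on_clean_full_length_library(self, locus, edit):
        ref = assemble(locus, edit, pbs_len=13, ha_len=10)
        cfg = SimConfig(seed=9, n_reads=300, p_full=1.0)
        reads, _ = simulate_reads(ref, cfg)
        table = profile_library(reads, ref, library_name="clean", role="BULK")
        assert table.counts.loc["FULL_LENGTH", "fraction"] == pytest.approx(1.0)
        assert table.intact_pbs_fraction == pytest.approx(1.0)
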