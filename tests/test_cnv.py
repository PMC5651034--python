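import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capcnv.cnv import (
    CrossSpeciesCall,
    classify_cnv_pair,
    classify_cross_species,
    reconcile_copy_sets,
    scan_large_deletions,
)
from capcnv.core import GenomicInterval, ThresholdConfig, ValidationError
from capcnv.coverage import CoverageRecord, DepthTrack
from capcnv.worked_examples import (
    ACCEPTANCE_ROWS,
    CROSS_SPECIES_EXAMPLES,
    TABLE_ROWS,
    UNRECONCILED_ROWS,
)


def rec(genotype, nc, key="gene1"):
    return CoverageRecord(
        GenomicInterval("A01", 0, 1200),
        genotype,
        "own",
        read_count=1.0 if nc > 0 else 0.0,
        nc=nc,
        gene_id=key,
    )


CALL_NAME = {
    "deletion_in_low": "Deletion",
    "duplication_in_high": "Duplication",
}


class TestClassifyPair:
    @pytest.mark.parametrize(
        "row", TABLE_ROWS, ids=[r.copy_name for r in TABLE_ROWS]
    )
    def test_published_table_rows_reproduce(self, row):
        """Printed CNV labels follow from the printed normalized coverages."""
        call = classify_cnv_pair(
            rec(row.genotype, row.nc_printed, row.copy_name),
            rec(row.other_genotype, row.nc_other, row.copy_name),
            row.pop_mean,
        )
        assert CALL_NAME[call.call] == row.printed_call
        assert call.carrier == row.printed_carrier

    @pytest.mark.parametrize(
        "row", UNRECONCILED_ROWS, ids=[r.copy_name for r in UNRECONCILED_ROWS]
    )
    def test_unreconciled_rows_land_in_duplication_branch(self, row):
        """The three known non-reproducible rows classify as duplication."""
        call = classify_cnv_pair(
            rec(row.genotype, row.nc_printed, row.copy_name),
            rec(row.other_genotype, row.nc_other, row.copy_name),
            row.pop_mean,
        )
        assert call.call == "duplication_in_high"

    def test_equal_coverage_no_call(self):
        call = classify_cnv_pair(rec("a", 100.0), rec("b", 100.0), 100.0)
        assert call.call == "none"

    def test_both_zero_flagged(self):
        call = classify_cnv_pair(rec("a", 0.0), rec("b", 0.0), 100.0)
        assert call.call == "none" and "zero" in call.evidence

    def test_population_tiebreak_unresolved_without_baseline(self):
        call = classify_cnv_pair(rec("a", 50.0), rec("b", 100.0), None)
        assert call.call == "unresolved"

    def test_symmetric_under_genotype_swap(self):
        a, b = rec("a", 40.0), rec("b", 100.0)
        c1 = classify_cnv_pair(a, b, 120.0)
        c2 = classify_cnv_pair(b, a, 120.0)
        assert (c1.call, c1.carrier) == (c2.call, c2.carrier)
        assert c1.low_genotype == c2.low_genotype == "a"

    @given(
        nc_low=st.floats(0.0, 500.0),
        nc_high=st.floats(0.1, 500.0),
        drop=st.floats(0.0, 1.0),
        pop=st.floats(10.0, 2000.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotonicity_lowering_low_never_weakens_call(
        self, nc_low, nc_high, drop, pop
    ):
        """Lowering the low genotype's coverage never turns a deletion into
        a duplication or no-call."""
        if nc_low > nc_high:
            nc_low, nc_high = nc_high, nc_low
        before = classify_cnv_pair(rec("a", nc_low), rec("b", nc_high), pop)
        after = classify_cnv_pair(
            rec("a", nc_low * drop), rec("b", nc_high), pop
        )
        if before.call == "deletion_in_low":
            assert after.call == "deletion_in_low"
        if before.call == "duplication_in_high":
            assert after.call in ("duplication_in_high", "deletion_in_low")

    def test_mismatched_regions_rejected(self):
        a = rec("a", 10.0)
        b = CoverageRecord(
            GenomicInterval("C01", 0, 1200), "b", "own", 1.0, 10.0, "gene1"
        )
        with pytest.raises(ValidationError):
            classify_cnv_pair(a, b, 100.0)


class TestCrossSpecies:
    @pytest.mark.parametrize(
        "ex",
        CROSS_SPECIES_EXAMPLES,
        ids=[e.copy_name for e in CROSS_SPECIES_EXAMPLES],
    )
    def test_published_examples(self, ex):
        call = classify_cross_species(
            ex.pcts_rapa, ex.pcts_oleracea, ex.copy_name, ex.subgenome
        )
        assert call.status == ex.expected_status
        assert call.direction == ex.expected_direction

    def test_expected_200_pct_is_present(self):
        call = classify_cross_species([200.0], [100.0], "Bna.X.A01", "A")
        assert call.status == "present"

    def test_mixed_matching_is_reduced_ambiguous(self):
        call = classify_cross_species([10.0, 80.0], [90.0], "Bna.X.A01", "A")
        assert call.status == "reduced_ambiguous"

    def test_empty_pct_list_rejected(self):
        with pytest.raises(ValidationError):
            classify_cross_species([], [100.0], "Bna.X.A01", "A")

    def test_exchange_requires_opposite_support_everywhere(self):
        call = classify_cross_species(
            [5.0, 5.0], [150.0, 90.0], "Bna.X.A01", "A"
        )
        assert call.status == "absent"  # one opposite pct below 120


class TestReconcile:
    def orth(self):
        return {
            "F1": {"tetraploid_A": "Bna.F1.A01", "tetraploid_C": "Bna.F1.C01",
                   "A": "Bra.F1.A01", "C": "Bol.F1.C01"},
            "F2": {"tetraploid_A": None, "tetraploid_C": None,
                   "A": "Bra.F2.A01", "C": None},
            "F3": {"tetraploid_A": "Bna.F3.A01", "tetraploid_C": None,
                   "A": None, "C": None},
            "F4": {"tetraploid_A": "Bna.F4.A01", "tetraploid_C": None,
                   "A": None, "C": None},
        }

    def test_labels(self):
        cross = {
            "Bna.F1.A01": CrossSpeciesCall(
                "Bna.F1.A01", "A", (5.0,), (150.0,), "exchanged", "C"
            )
        }
        covered = {
            ("F1", "A"): True, ("F1", "C"): True,
            ("F2", "A"): True,                      # lost in the tetraploid
            ("F3", "A"): False, ("F3", "C"): False,  # gained in the tetraploid
            ("F4", "A"): True,                       # covered, unannotated
        }
        out = reconcile_copy_sets(self.orth(), cross, covered)
        labels = {(r.family, r.subgenome): r.label for r in out}
        assert labels[("F1", "A")] == "exchanged"
        assert labels[("F1", "C")] == "retained"
        assert labels[("F2", "A")] == "lost_in_napus"
        assert labels[("F3", "A")] == "gained_in_napus"
        assert labels[("F4", "A")] == "covered_but_unannotated_in_diploid"

    def test_call_for_unknown_copy_rejected(self):
        cross = {
            "Bna.NOPE.A01": CrossSpeciesCall(
                "Bna.NOPE.A01", "A", (5.0,), (150.0,), "exchanged", "C"
            )
        }
        with pytest.raises(ValidationError):
            reconcile_copy_sets(self.orth(), cross, {})


def track(depth, mode="strict", genotype="g", ref="A"):
    return DepthTrack(
        reference_id=ref,
        genotype=genotype,
        mode=mode,
        depths={"A01": np.asarray(depth, dtype=np.int64)},
        total_mapped_reads=1000,
        read_length=10,
    )


class TestZeroWindowScan:
    def test_identical_genotypes_empty(self):
        d = np.full(500, 30)
        out = scan_large_deletions(
            track(d), track(d, genotype="h"), track(d, mode="gapped")
        )
        assert out == []

    def test_injected_deletion_recovered_with_conditions(self):
        own = np.full(500, 30)
        own[100:160] = 0
        other = np.full(500, 30)
        gapped = np.zeros(500)
        out = scan_large_deletions(
            track(own), track(other, genotype="h"), track(gapped, mode="gapped")
        )
        assert len(out) == 1
        c = out[0]
        assert (c.interval.start, c.interval.end) == (100, 160)
        assert c.min_other_depth == 30

    def test_short_zero_run_not_reported(self):
        own = np.full(500, 30)
        own[100:115] = 0  # 15 bases < 19 bp window
        out = scan_large_deletions(
            track(own), track(np.full(500, 30), genotype="h"),
            track(np.zeros(500), mode="gapped"),
        )
        assert out == []

    def test_weak_other_genotype_excludes_window(self):
        """Shared dropouts (reference-mapping problems) are not deletions."""
        own = np.full(500, 30)
        own[100:160] = 0
        other = np.full(500, 30)
        other[90:170] = 0
        out = scan_large_deletions(
            track(own), track(other, genotype="h"),
            track(np.zeros(500), mode="gapped"),
        )
        assert out == []

    def test_gapped_coverage_excludes_short_indel_artifacts(self):
        own = np.full(500, 30)
        own[100:160] = 0
        gapped = np.zeros(500)
        gapped[100:160] = 25  # gapped mapping spans it: not a large deletion
        out = scan_large_deletions(
            track(own), track(np.full(500, 30), genotype="h"),
            track(gapped, mode="gapped"),
        )
        assert out == []

    def test_candidates_never_overlap_covered_bases(self, default_ds):
        from capcnv.pipeline import large_deletion_calls

        calls = large_deletion_calls(default_ds)
        for name, cands in calls.items():
            sub = default_ds.subgenome_of[name]
            own = default_ds.tracks[(name, sub, "strict")]
            for c in cands:
                window = own.depths[c.interval.chrom][
                    c.interval.start : c.interval.end
                ]
                assert window.max() == 0

    def test_mismatched_references_rejected(self):
        with pytest.raises(ValidationError):
            scan_large_deletions(
                track(np.zeros(50)),
                track(np.zeros(50), genotype="h", ref="B"),
                track(np.zeros(50), mode="gapped"),
            )
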