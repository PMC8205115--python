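import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ampligeno import (
    BinCounts,
    CallThresholds,
    Genotype,
    Orientation,
    ReadCategory,
    ReadRecord,
    RunError,
    ValidationError,
    call_genotype,
    classify_read,
    compute_ratio,
    count_bins,
    match_motif,
    reverse_complement,
    run_directory,
)
from ampligeno.genotype_caller import REASON_LOW_READS, REASON_OK, REASON_RATIO_GAP

from conftest import embed


def naive_match(seq, motif, k, search_rc=True):
    """Independent oracle: all-window Hamming scan, N is always a mismatch."""

    def scan(s):
        for i in range(len(s) - len(motif) + 1):
            window = s[i:i + len(motif)]
            mm = sum(a != b or a == "N" or b == "N"
                     for a, b in zip(window, motif))
            if mm <= k:
                return True
        return False

    if scan(seq):
        return True
    return search_rc and scan(reverse_complement(seq))


class TestMatchMotif:
    def test_exact_embedded_motif_found_forward(self, assay, rng):
        seq = embed(assay.wt_motif, rng)
        assert match_motif(seq, assay.wt_motif, 0) == (True, Orientation.FWD)

    def test_reverse_complement_embed_found_on_reverse_strand(self, assay, rng):
        seq = reverse_complement(embed(assay.wt_motif, rng))
        assert match_motif(seq, assay.wt_motif, 0, search_rc=True) == (
            True, Orientation.REV)
        assert match_motif(seq, assay.wt_motif, 0, search_rc=False)[0] is False

    def test_single_substitution_needs_tolerance(self, assay, rng):
        motif = assay.wt_motif
        mutated = "T" + motif[1:] if motif[0] != "T" else "A" + motif[1:]
        seq = embed(mutated, rng)
        assert match_motif(seq, motif, 0) == (False, Orientation.NONE)
        assert match_motif(seq, motif, 1) == (True, Orientation.FWD)

    def test_n_matches_nothing_in_exact_mode(self):
        motif = "A" * 10 + "N" + "A" * 10
        assert match_motif("A" * 40, motif, 0)[0] is False
        # with tolerance 1 the N position is the single allowed mismatch
        assert match_motif("A" * 40, motif, 1)[0] is True

    def test_empty_motif_rejected(self):
        with pytest.raises(ValidationError):
            match_motif("ACGT", "", 0)

    def test_agrees_with_naive_hamming_scan_on_random_cases(self):
        """Implementation vs brute-force window scan on 1,000 random triples."""
        rng = np.random.default_rng(99)
        bases = np.array(list("ACGTN"))
        mismatches = 0
        for _ in range(1000):
            n = int(rng.integers(5, 60))
            m = int(rng.integers(1, 12))
            k = int(rng.integers(0, 3))
            seq = "".join(rng.choice(bases, size=n, p=[.24, .24, .24, .24, .04]))
            motif = "".join(rng.choice(bases, size=m, p=[.24, .24, .24, .24, .04]))
            got = match_motif(seq, motif, k)[0]
            want = naive_match(seq, motif, k)
            if got != want:
                mismatches += 1
        assert mismatches == 0


class TestClassify:
    def test_wt_only_read(self, assay, rng):
        assert classify_read(embed(assay.wt_motif, rng), assay) is ReadCategory.WT

    def test_filter_precedes_allele_motifs(self, filtered_assay, rng):
        seq = embed(filtered_assay.filter_motifs[0], rng) + filtered_assay.mut_motif
        assert classify_read(seq, filtered_assay) is ReadCategory.FILTERED

    def test_double_allele_hit_is_conflict(self, assay, rng):
        seq = embed(assay.wt_motif, rng) + assay.mut_motif
        assert classify_read(seq, assay) is ReadCategory.CONFLICT

    def test_no_hit(self, assay, rng):
        seq = embed("TTTTACGTACGTACGTACGTTTTT", rng)
        assert classify_read(seq, assay) is ReadCategory.NO_MATCH


class TestCountBins:
    def test_tallies_and_conservation(self, assay, rng):
        reads = [ReadRecord(f"w{i}", embed(assay.wt_motif, rng)) for i in range(10)]
        reads += [ReadRecord(f"m{i}", embed(assay.mut_motif, rng)) for i in range(5)]
        counts = count_bins(reads, assay)
        assert (counts.wt, counts.mut, counts.total) == (10, 5, 15)

    def test_filter_only_reads(self, filtered_assay, rng):
        fm = filtered_assay.filter_motifs[0]
        counts = count_bins(
            [ReadRecord(f"f{i}", embed(fm, rng)) for i in range(3)],
            filtered_assay)
        assert (counts.filtered, counts.total) == (3, 3)

    def test_empty_stream(self, assay):
        counts = count_bins([], assay)
        assert counts.total == 0

    def test_quality_failed_reads_not_classified(self, assay, rng):
        seq = embed(assay.wt_motif, rng)
        reads = [ReadRecord("lo", seq, qualities=[5] * len(seq)),
                 ReadRecord("hi", seq, qualities=[35] * len(seq))]
        counts = count_bins(reads, assay, min_mean_q=20.0)
        assert (counts.wt, counts.quality_failed, counts.total) == (1, 1, 2)

    def test_strand_invariance(self, assay, rng):
        reads = [ReadRecord(f"w{i}", embed(assay.wt_motif, rng)) for i in range(6)]
        reads += [ReadRecord(f"m{i}", embed(assay.mut_motif, rng)) for i in range(4)]
        flipped = [ReadRecord(r.read_id, reverse_complement(r.sequence))
                   for r in reads]
        assert vars(count_bins(reads, assay)) == vars(count_bins(flipped, assay))


class TestRatioAndCall:
    @pytest.mark.parametrize("wt,mut,expected", [
        (1000, 1000, 0.5), (0, 2000, 0.0), (3000, 1500, 2 / 3),
    ])
    def test_ratio(self, wt, mut, expected):
        assert compute_ratio(BinCounts(wt=wt, mut=mut)) == pytest.approx(
            expected, abs=1e-9)

    def test_ratio_undefined_without_allele_reads(self):
        assert compute_ratio(BinCounts(filtered=10)) is None

    @pytest.mark.parametrize("wt,mut,call,reason", [
        (400, 300, Genotype.FAIL, REASON_LOW_READS),
        (2600, 2400, Genotype.HET, REASON_OK),
        (900, 4100, Genotype.AMBIGUOUS, REASON_RATIO_GAP),
        (5000, 0, Genotype.WT, REASON_OK),
        (0, 5000, Genotype.HOM, REASON_OK),
    ])
    def test_call_windows(self, wt, mut, call, reason):
        got = call_genotype(BinCounts(wt=wt, mut=mut))
        assert (got.call, got.reason) == (call, reason)

    def test_failure_boundary_is_strict_below(self):
        t = CallThresholds()
        assert call_genotype(BinCounts(wt=t.min_reads - 1, mut=0)).call is Genotype.FAIL
        assert call_genotype(BinCounts(wt=t.min_reads, mut=0)).call is Genotype.WT

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValidationError):
            CallThresholds(hom_max=0.3, het_low=0.25)

    @given(st.integers(0, 5000), st.integers(0, 5000), st.integers(1, 50))
    def test_ratio_monotonicity(self, wt, mut, extra):
        base = compute_ratio(BinCounts(wt=wt, mut=mut))
        more_wt = compute_ratio(BinCounts(wt=wt + extra, mut=mut))
        more_mut = compute_ratio(BinCounts(wt=wt, mut=mut + extra))
        if base is not None:
            assert more_wt >= base
            assert more_mut <= base


class TestRunDirectory:
    def _write_plate(self, tmp_path, motif_db, layout, **kw):
        from ampligeno import simulate_plate

        return simulate_plate(layout, motif_db, tmp_path / "fq", seed=3, **kw)

    def test_end_to_end_recovers_truth_genotypes(self, tmp_path, assay):
        from ampligeno import LayoutEntry, load_sample_sheet, simulate_plate

        layout = [LayoutEntry(f"A{i + 1}", assay.gene, g)
                  for i, g in enumerate(["WT", "HET", "HOM", "HET"])]
        db = {assay.gene: assay}
        truth = simulate_plate(layout, db, tmp_path / "fq", seed=3, depth=2000)
        registry = load_sample_sheet(tmp_path / "fq" / "samples.tsv")
        result = run_directory(tmp_path / "fq", registry, db)
        assert len(result.calls) == 4
        by_key = {c.sample_key: c.call.value for c in result.calls}
        for row in truth.itertuples(index=False):
            assert by_key[row.sample_key] == row.genotype

    def test_unknown_gene_is_skipped_not_fatal(self, tmp_path, assay):
        from ampligeno import LayoutEntry, load_sample_sheet, simulate_plate

        layout = [LayoutEntry(f"A{i + 1}", assay.gene, "WT") for i in range(3)]
        db = {assay.gene: assay}
        simulate_plate(layout, db, tmp_path / "fq", seed=3, depth=600)
        registry = load_sample_sheet(tmp_path / "fq" / "samples.tsv")
        # drop the assay for one sample's gene by renaming it in a copy
        reg_records = list(registry)
        reg_records[0].gene = "Unknown"
        from ampligeno.sample_registry import SampleRegistry

        result = run_directory(tmp_path / "fq", SampleRegistry(reg_records),
                               db, CallThresholds(min_reads=100))
        assert len(result.calls) == 2
        assert len(result.skipped) == 1
        assert "Unknown" in result.skipped[0].reason

    def test_empty_directory_is_run_error(self, tmp_path, assay):
        from ampligeno.sample_registry import SampleRegistry

        (tmp_path / "empty").mkdir()
        with pytest.raises(RunError):
            run_directory(tmp_path / "empty", SampleRegistry([]),
                          {assay.gene: assay})
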