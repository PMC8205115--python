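import numpy as np
import pytest

from ampligeno import (
    Genotype,
    LayoutEntry,
    SimulationConfig,
    ValidationError,
    call_genotype,
    count_bins,
    simulate_plate,
    simulate_sample,
    spike_series,
    write_fastq,
)
from ampligeno.simulate import (
    PE_FORWARD_TAIL,
    PE_REVERSE_TAIL,
    build_template,
    build_templates,
    make_insert,
    parse_spike_ratio,
)


class TestTemplates:
    def test_template_structure_and_single_motif(self, assay, rng):
        insert = make_insert(assay.wt_motif, rng)
        t = build_template("t", insert, "WT", assay.wt_motif)
        assert t.sequence.startswith(PE_FORWARD_TAIL)
        assert len(t.sequence) == (len(PE_FORWARD_TAIL) + len(insert)
                                   + len(PE_REVERSE_TAIL))
        assert t.sequence.count(assay.wt_motif) == 1

    def test_insert_without_motif_rejected(self, assay):
        with pytest.raises(ValidationError, match="exactly once"):
            build_template("t", "ACGT" * 20, "WT", assay.wt_motif)

    def test_offtarget_insert_must_avoid_assay_motifs(self, assay, rng):
        bad = make_insert(assay.wt_motif, rng)
        with pytest.raises(ValidationError, match="assay motif"):
            build_templates(assay, make_insert(assay.wt_motif, rng),
                            make_insert(assay.mut_motif, rng),
                            offtarget_inserts=[("off", bad, assay.wt_motif)])


class TestSimulateSample:
    def test_hom_without_contamination_has_no_wt_reads(self, templates):
        cfg = SimulationConfig(genotype="HOM", n_reads=500, error_rate=0.0,
                               seed=1)
        _, truth = simulate_sample(cfg, templates)
        assert truth.wt_reads == 0
        assert truth.mut_reads == 500

    def test_het_fraction_within_three_binomial_sd(self, templates):
        cfg = SimulationConfig(genotype="HET", n_reads=10000, allele_bias=0.5,
                               error_rate=0.0, seed=7)
        _, truth = simulate_sample(cfg, templates)
        assert abs(truth.wt_reads / 10000 - 0.5) < 0.015

    def test_truth_recovered_exactly_without_error(self, assay, templates):
        cfg = SimulationConfig(genotype="HET", n_reads=3000, error_rate=0.0,
                               seed=3)
        records, truth = simulate_sample(cfg, templates)
        counts = count_bins(records, assay, max_mismatches=0)
        assert (counts.wt, counts.mut) == (truth.wt_reads, truth.mut_reads)
        assert counts.no_match == 0

    def test_determinism_identical_bytes(self, templates, tmp_path):
        cfg = SimulationConfig(genotype="HET", n_reads=400, seed=11)
        for name in ("a.fastq", "b.fastq"):
            records, _ = simulate_sample(cfg, templates)
            write_fastq(records, tmp_path / name)
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_het_with_contamination_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(genotype="HET", n_reads=10,
                             contamination_fraction=0.1)

    def test_empty_sample(self, templates):
        records, truth = simulate_sample(
            SimulationConfig(genotype="WT", n_reads=0), templates)
        assert records == [] and truth.n_reads == 0

    def test_offtarget_mix_counted_in_truth(self, assay, templates, rng):
        off_insert = make_insert("TTAAGGCCTTAAGGCCTTAAGGCC", rng)
        tmpl = build_templates(
            assay, make_insert(assay.wt_motif, rng),
            make_insert(assay.mut_motif, rng),
            offtarget_inserts=[("para", off_insert, "TTAAGGCCTTAAGGCCTTAAGGCC")])
        cfg = SimulationConfig(genotype="WT", n_reads=4000, error_rate=0.0,
                               offtarget_mix=[("para", tmpl["para"], 0.3)],
                               seed=5)
        records, truth = simulate_sample(cfg, tmpl)
        assert truth.offtarget_reads + truth.wt_reads == 4000
        # 3 binomial sd around the 30% mixing fraction
        sd = np.sqrt(0.3 * 0.7 / 4000)
        assert abs(truth.offtarget_reads / 4000 - 0.3) < 3 * sd


class TestSpikeSeries:
    @pytest.mark.parametrize("ratio,frac", [
        ("1:1", 0.5), ("1:500", 1 / 501), (10, 1 / 11),
    ])
    def test_ratio_convention(self, ratio, frac):
        assert parse_spike_ratio(ratio) == pytest.approx(frac)

    @pytest.mark.parametrize("bad", ["1:0", 0, "2:3", "x"])
    def test_invalid_ratio_rejected(self, bad):
        with pytest.raises((ValidationError, ValueError)):
            parse_spike_ratio(bad)

    def test_one_to_one_spike_on_hom_calls_het(self, assay, templates):
        (entry,) = spike_series("HOM", ["1:1"], templates, n_reads=5000,
                                seed=2)
        counts = count_bins(entry["records"], assay)
        assert call_genotype(counts).call is Genotype.HET

    def test_one_to_500_spike_stays_out_of_het_window(self, assay, templates):
        (entry,) = spike_series("HOM", ["1:500"], templates, n_reads=20000,
                                seed=2)
        assert entry["expected_wt_fraction"] == pytest.approx(1 / 501)
        counts = count_bins(entry["records"], assay)
        assert call_genotype(counts).call is not Genotype.HET

    def test_het_base_rejected(self, templates):
        with pytest.raises(ValidationError):
            spike_series("HET", ["1:1"], templates)


class TestSimulatePlate:
    def test_plate_files_and_truth_rows(self, tmp_path, assay):
        layout = [LayoutEntry(f"A{i + 1}", assay.gene, "HET") for i in range(8)]
        truth = simulate_plate(layout, {assay.gene: assay}, tmp_path / "p",
                               seed=1, depth=100)
        fastqs = sorted((tmp_path / "p").glob("*.fastq"))
        assert len(fastqs) == 8 and len(truth) == 8
        assert (tmp_path / "p" / "truth.tsv").exists()

    def test_same_seed_byte_identical(self, tmp_path, assay):
        layout = [LayoutEntry("A1", assay.gene, "HET"),
                  LayoutEntry("A2", assay.gene, "HOM")]
        for d in ("x", "y"):
            simulate_plate(layout, {assay.gene: assay}, tmp_path / d,
                           seed=9, depth=150)
        for f in sorted((tmp_path / "x").iterdir()):
            assert f.read_bytes() == (tmp_path / "y" / f.name).read_bytes()

    def test_duplicate_well_rejected(self, tmp_path, assay):
        layout = [LayoutEntry("A1", assay.gene, "WT"),
                  LayoutEntry("A1", assay.gene, "HOM")]
        with pytest.raises(ValidationError, match="duplicate well"):
            simulate_plate(layout, {assay.gene: assay}, tmp_path / "p", seed=1)

    def test_multi_plate_layout_row_count(self, tmp_path, assay):
        layout = [
            LayoutEntry(f"A{w + 1}", assay.gene, "WT", plate_id=f"P{p + 1}")
            for p in range(4) for w in range(6)
        ]
        truth = simulate_plate(layout, {assay.gene: assay}, tmp_path / "m",
                               seed=4, depth=20)
        assert len(truth) == 24


def test_allele_bias_sweep_spans_observed_het_range(assay, templates):
    """Mean het ratios track allele_bias across the empirical 0.39-0.729 span."""
    for bias in (0.39, 0.55, 0.729):
        cfg = SimulationConfig(genotype="HET", n_reads=4000, allele_bias=bias,
                               error_rate=0.0, seed=int(bias * 1000))
        records, _ = simulate_sample(cfg, templates)
        counts = count_bins(records, assay)
        ratio = counts.wt / (counts.wt + counts.mut)
        assert abs(ratio - bias) < 3 * np.sqrt(bias * (1 - bias) / 4000)


def test_demultiplexing_pooled_output_recovers_per_sample_counts(assay, templates):
    from ampligeno import assign_barcodes, demultiplex, generate_barcode_set
    from ampligeno.simulate import pool_with_indexes

    i5 = generate_barcode_set(1, seed=3)
    i7 = generate_barcode_set(4, seed=4)
    pairs = assign_barcodes(["P1"], i5, i7, wells=["A1", "A2", "A3", "A4"])
    per_sample, expected = {}, {}
    for i, pair in enumerate(pairs):
        key = f"s{i}"
        n = 50 + 10 * i
        cfg = SimulationConfig(genotype="WT", n_reads=n, seed=20 + i)
        per_sample[key], _ = simulate_sample(cfg, templates, sample_key=key)
        expected[(pair.plate_id, pair.well)] = n
    assignment = {f"s{i}": pair for i, pair in enumerate(pairs)}
    pooled = pool_with_indexes(per_sample, assignment)
    res = demultiplex(pooled, pairs, max_mismatch_per_index=0)
    assert {k: len(v) for k, v in res.assigned.items()} == expected
    assert not res.unassigned
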