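# Methods

## Read classification and genotype calling

Each amplicon read is compared to the gene's wild-type and mutant-specific
discriminatory motifs — ~50 bp sequences unique to one allele, placed over
the deletion breakpoint (mutant) or inside the deleted region (wild type).
Matching is windowed Hamming comparison with a configurable mismatch
budget; the default is **exact matching (0 mismatches)**, which is
appropriate because breakpoints are characterized before this stage and a
random 50-mer hit has probability 4^-50. `N` counts as a mismatch in
either sequence, so a motif containing `N` can never match in exact mode.
Both strands are searched by default (the read is also compared to the
motif's reverse complement); forward orientation is reported when both
match.

Classification precedence per read:

1. **filter motifs** — any hit removes the read (`FILTERED`). This is the
   rule that discards, e.g., the mutant-specific primer pair amplifying
   the intact wild-type allele at a different size.
2. wild-type and mutant motifs — a hit on exactly one bins the read `WT`
   or `MUT`; a hit on both is `CONFLICT` and excluded from the ratio
   (motifs should be mutually exclusive, but nothing enforces that for
   user-supplied motifs, so double hits are surfaced rather than silently
   double-counted);
3. neither — `NO_MATCH`.

Reads failing the optional mean-Phred pre-filter are counted
`quality_failed` and never classified. The six bins always sum to the
total read count; this conservation is asserted by the test suite on every
simulated run.

The genotype is called from the wild-type fraction `r = wt/(wt+mut)`,
computed over the allele bins only. Calling rules, in order:

* **FAIL** if `max(wt, mut) < min_reads` (default **500**, strict
  less-than: 499 fails, 500 does not). The maximum, not both bins, is
  compared because clean homozygotes legitimately have ~0 reads in one
  bin.
* **HOM** if `r <= 0.10`; **HET** if `0.25 <= r <= 0.80`; **WT** if
  `r >= 0.90`; anything in the gaps is **AMBIGUOUS** (reason
  `RATIO_GAP`).

The het window was chosen to contain the full range of heterozygote ratio
averages observed in production data (0.39–0.729, driven by
allele-specific amplification bias) while leaving real gaps on both sides:
off-pattern clusters (e.g. ratios of 0.15–0.23 from a bad DNA preparation)
are flagged rather than mis-called. All five thresholds are configurable
per run (`CallThresholds`, or the corresponding CLI flags). Every call
carries a reason code (`OK`, `LOW_READS`, `RATIO_GAP`) so downstream
tables never contain an unexplained class.

## Paralogue attribution

For high-homology genes the wild-type-assay reads are attributed to a
panel of labelled discriminator motifs (target locus plus candidate
paralogues) using the same matcher. Each read goes to the unique matching
label; multi-label hits are conflicts, no-hit reads are unattributed, and
the categories sum to the total. Percentages are displayed rounded
half-up to integers, with full precision kept internally. A genome
aligner would answer the same question; motif attribution was chosen
because once breakpoints are characterized the motif panel is sufficient,
needs no genome download or index, and reports exactly the quantity of
interest.

`flag_spurious_wt` annotates a genotype call when the **combined**
non-target share of attributed reads reaches `dominance_fraction`
(default 0.9). The combined share is used, not the largest single label,
because a spurious wild-type band is typically split across several
paralogues (e.g. 65% + 34%); requiring any one label to dominate would
miss exactly the cases the check exists for. The original call is always
preserved alongside the annotation.

## Multiplexing

Dual indexing uses a plate-constant i5 and well-unique i7, both 8 bp, so
capacity is `n_i5 × n_i7` (16 × 96 = 1536). The demultiplexer assigns a
read iff exactly one barcode pair lies within `max_mismatch_per_index`
Hamming distance (default 1) on *both* indexes; everything else is
unassigned, so assigned + unassigned always equals the input count. At map
load, any two pairs whose i5 *and* i7 distances are both ≤ 2×max_mismatch
are rejected as mutually reachable — the exact condition under which a
read could be ambiguous. Published index sets are licensed sequences, so
the package generates synthetic 8-mer sets with pairwise Hamming distance
≥ 3 (`generate_barcode_set`); the demultiplexer is indifferent to which
set is used. Index orientation is taken as written in the read header
comment (`...:i5+i7`); instrument-specific reverse-complement dialects are
a documented limitation.

## The simulator

Amplicon templates follow the two-round tailed-PCR structure: the
universal forward tail, a gene-specific insert embedding the allele's
motif exactly once, then the reverse complement of the universal reverse
tail. Default inserts place the 50 bp motif at template positions 43–93,
comfortably inside a 150 bp read.

Per sample, reads are drawn i.i.d. from the templates: wild types draw
only the WT-allele template, homozygotes only the mutant one, and
heterozygotes draw WT with probability `allele_bias` (default 0.5;
sweeping it over 0.39–0.729 reproduces the empirically observed het ratio
spread). A contamination fraction replaces reads with the
opposite-genotype template — a 1:k DNA spike corresponds to a read
fraction of 1/(k+1), applied at the read level (PCR competition between
the two DNAs is not modelled). Contamination is defined only for WT or HOM
base samples; "opposite genotype" has no meaning for a het. Off-target
templates (carrying a paralogue discriminator, never the assay motifs) can
be mixed in at stated fractions. After template choice, independent
per-base substitutions are applied at `error_rate` (default 0.001 —
typical for the short, high-quality reads this assay uses); indels are
deliberately not modelled, since they would conflate with the exact-match
design rather than exercise it. Reads are truncated to `read_length` from
the template 5′ end, half are emitted as reverse complements to exercise
strand handling, and qualities are constant Q37 (no quality model is
claimed). Everything derives from a single `numpy` generator, so output is
byte-identical for a given configuration and seed; the truth record stores
the exact template draws, with contaminant reads counted both in their
allele bin and in `contaminant_reads`.

What passing tests on simulated data do **not** show: robustness to
indels, adapter read-through, quality decay, chimeric amplicons, or
PCR-cycle stochasticity. The simulator validates the calling logic and its
thresholds, not the wet-lab failure modes.

## qPCR concordance and litter checks

Loss-of-allele relative quantification is `RQ = 2^-ddCt` against a
wild-type calibrator with an endogenous control; an undetermined target Ct
is RQ = 0 (no amplification, the homozygote signature) and a missing
endogenous control is an assay failure. RQ windows (HOM ≤ 0.2, HET
0.35–0.65, WT ≥ 0.8, otherwise FAIL) are centred on the one-copy
expectation of 0.5 and are configurable; the production values behind them
are not published, so these are inferred defaults. Concordance tables join
sequencing and LoA calls on sample key, drop samples without a usable
result from both methods, and stratify by the assay's high-homology flag.

The Mendelian check uses an **exact multinomial tail** (the summed
probability of all outcomes no more likely than the observed one) against
1:2:1 for het × het or 1:1 for het × WT litters — exact rather than
chi-square because litters are small. FAIL/AMBIGUOUS pups are excluded; a
genotype impossible under the cross gives an observed probability of zero
and flags immediately, and a het × het litter of ≥ 8 with neither WT nor
HOM pups is flagged regardless of p (the signature of an assay blind to
homozygotes). Default alpha 0.05. The test suite verifies the p-value
against an independent enumeration built from factorials.

## Numerical and I/O choices

* Ratio definition is the fraction `wt/(wt+mut)`, not the quotient
  `wt/mut`, so it is bounded in [0, 1] and symmetric to interpret; it is
  undefined (reported blank) only when both allele bins are empty.
* Motif length: canonical 50 bp; shorter motifs are accepted down to a
  20 bp floor with a logged warning (a 20-mer still has a ~4^-20 random
  match rate).
* Sequences and motifs are upper-cased on load; registries are UTF-8 TSV
  with headers and round-trip exactly (write → read reproduces all
  fields, with ratios serialized at full float precision).
* Default filename rule: the sample key is the text before the first
  Illumina `_S<digits>` suffix, else the basename without its sequence
  extension; a custom regex template can override it.
* Problem sizes in the routine test suite and acceptance script (plates
  of 4–96 wells, depths of 1,500–20,000 reads, 1,000-sample bias sweeps
  at depth 2,000) were chosen so every statistical assertion sits ≥ 3
  standard deviations from its boundary. At depth 2,000 with the default
  0.1% error rate, a balanced heterozygote's larger allele bin stays
  safely above the 500-read failure threshold even though ~5% of reads
  lose their motif to a substitution error.

## Known limitations

* No indel/realignment support: alleles must be characterized in advance;
  this is a genotyping tool, not an editing-outcome analyzer.
* No paired-end merging; R1 and R2 are analysed as separate runs.
* Demultiplexer assumes header-encoded index tags and one orientation
  convention.
* Concordance and Mendelian modules summarize whatever calls they are
  given; they do not model qPCR chemistry or litter structure beyond the
  stated crosses.
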