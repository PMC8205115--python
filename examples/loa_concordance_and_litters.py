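"""Compare sequencing calls with loss-of-allele qPCR and check litters.

Loss-of-allele (LoA) qPCR measures relative quantification RQ = 2^-ddCt of
the wild-type locus against a wild-type calibrator: ~1 for WT, ~0.5 for
het, ~0 for homozygotes. This example derives LoA calls from Ct values,
tabulates concordance with sequencing calls stratified by assay homology,
and runs the exact-multinomial Mendelian check on two litters.
"""

from ampligeno import (
    BinCounts,
    Genotype,
    GenotypeCall,
    LoaResult,
    concordance,
    loa_call,
    loa_relative_quantification,
    mendelian_flag,
)


def ngs(key, genotype, gene):
    return GenotypeCall(key, gene, genotype, 0.5, BinCounts(wt=1000, mut=1000), "OK")


# LoA side: Ct values -> RQ -> window call
print("LoA relative quantification:")
for key, ct_target in [("m1", 25.0), ("m2", 26.0), ("m3", None)]:
    rq = loa_relative_quantification(ct_target, 20.0, 25.0, 20.0)
    print(f"  {key}: RQ = {0.0 if rq is None else rq:.2f} -> {loa_call(rq)}")

ngs_calls = [ngs("m1", Genotype.WT, "Clic3"), ngs("m2", Genotype.HET, "Clic3"),
             ngs("m3", Genotype.HOM, "Clic3"), ngs("m4", Genotype.HET, "Psg21"),
             ngs("m5", Genotype.HOM, "Psg21")]
loa_results = [LoaResult("m1", 1.0, "WT"), LoaResult("m2", 0.5, "HET"),
               LoaResult("m3", 0.0, "HOM"), LoaResult("m4", 0.5, "HET"),
               LoaResult("m5", 0.5, "HET")]  # high-homology disagreement
tables, per_gene = concordance(ngs_calls, loa_results,
                               {"Clic3": False, "Psg21": True})
print("\nNGS vs LoA concordance by homology stratum:")
for t in tables:
    print(f"  {t.stratum}: {t.agree} agree / {t.disagree} disagree "
          f"({t.percent_agree:.0f}%)")

# Mendelian check: an all-het litter from a het x het mating is the classic
# signature of an assay that cannot see homozygotes
good = ([ngs(f"w{i}", Genotype.WT, "Clic3") for i in range(3)]
        + [ngs(f"h{i}", Genotype.HET, "Clic3") for i in range(6)]
        + [ngs(f"m{i}", Genotype.HOM, "Clic3") for i in range(3)])
bad = [ngs(f"x{i}", Genotype.HET, "Psg21") for i in range(12)]
print("\nMendelian ratio check (het x het, expected 1:2:1):")
for name, litter in (("balanced litter", good), ("all-het litter", bad)):
    flag = mendelian_flag(litter, "HET_X_HET")
    print(f"  {name}: counts={flag.counts} p={flag.p_value:.4f} "
          f"flagged={flag.flagged} {flag.note}")
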