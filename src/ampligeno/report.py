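"""Output tables, loss-of-allele qPCR comparison and litter-level checks.

The sequencing-based calls are routinely cross-checked against loss-of-allele
(LoA) qPCR: a TaqMan assay on the wild-type locus whose relative
quantification (2^-ddCt against a wild-type calibrator) sits near 1 for wild
types, 0.5 for heterozygotes and 0 for homozygotes. This module computes RQ
values and window-based LoA calls, tabulates NGS/LoA concordance stratified
by assay homology, flags litters whose genotype counts depart from Mendelian
expectation (an early warning that an assay is mis-performing), and reads
and writes the tab-delimited genotype table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .errors import RunError, ValidationError
from .genotype_caller import BinCounts, Genotype, GenotypeCall

log = logging.getLogger(__name__)


@dataclass
class LoaWindows:
    """RQ windows for LoA calls; HET is centred on the one-copy expectation
    of 0.5. Values between windows are FAIL (uninterpretable RQ)."""

    hom_max_rq: float = 0.2
    het_low_rq: float = 0.35
    het_high_rq: float = 0.65
    wt_min_rq: float = 0.8


@dataclass
class LoaResult:
    sample_key: str
    rq: Optional[float]
    loa_call: str  # WT | HET | HOM | FAIL


def loa_relative_quantification(
    ct_target_sample: Optional[float],
    ct_endo_sample: Optional[float],
    ct_target_calibrator: float,
    ct_endo_calibrator: float,
) -> Optional[float]:
    """Relative quantification by 2^-ddCt.

    An undetermined target Ct (None) means no amplification: rq = 0, the
    homozygote signature. A missing endogenous-control Ct returns None
    (assay failure).
    """
    if ct_endo_sample is None or not math.isfinite(ct_endo_sample):
        return None
    if ct_target_sample is None or not math.isfinite(ct_target_sample):
        return 0.0
    ddct = (ct_target_sample - ct_endo_sample) - (
        ct_target_calibrator - ct_endo_calibrator
    )
    return 2.0 ** (-ddct)


def loa_call(rq: Optional[float], windows: LoaWindows = LoaWindows()) -> str:
    if rq is None:
        return "FAIL"
    if rq < 0:
        raise ValidationError("RQ must be >= 0")
    if rq <= windows.hom_max_rq:
        return "HOM"
    if windows.het_low_rq <= rq <= windows.het_high_rq:
        return "HET"
    if rq >= windows.wt_min_rq:
        return "WT"
    return "FAIL"


def load_loa_table(path, windows: LoaWindows = LoaWindows()) -> List[LoaResult]:
    """Read loa.tsv: either a precomputed ``rq`` column, or the four Ct
    columns (ct_target, ct_endo, ct_target_cal, ct_endo_cal); empty cells
    mean undetermined amplification."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        if hasattr(row, "rq") and not pd.isna(row.rq):
            rq: Optional[float] = float(row.rq)
        else:
            def _ct(name):
                v = getattr(row, name, float("nan"))
                return None if pd.isna(v) else float(v)

            rq = loa_relative_quantification(
                _ct("ct_target"), _ct("ct_endo"),
                _ct("ct_target_cal") or 0.0, _ct("ct_endo_cal") or 0.0,
            )
        out.append(LoaResult(sample_key=str(row.sample_key), rq=rq,
                             loa_call=loa_call(rq, windows)))
    return out


@dataclass
class ConcordanceTable:
    stratum: str  # high_homology | no_high_homology
    agree: int
    disagree: int

    @property
    def percent_agree(self) -> Optional[float]:
        n = self.agree + self.disagree
        return 100.0 * self.agree / n if n else None


_CALLABLE = {Genotype.WT, Genotype.HET, Genotype.HOM}


def concordance(
    ngs_calls: Sequence[GenotypeCall],
    loa_results: Sequence[LoaResult],
    homology_flags: Dict[str, bool],
) -> Tuple[List[ConcordanceTable], pd.DataFrame]:
    """NGS vs LoA agreement, stratified by assay homology class.

    Samples are joined on sample_key; samples without a usable result from
    both methods (FAIL/AMBIGUOUS NGS calls, FAIL LoA calls) are excluded.
    Returns the per-stratum tables plus a per-gene breakdown; strata with no
    joined samples are omitted with a warning.
    """
    loa_by_key = {r.sample_key: r for r in loa_results}
    strata = {"high_homology": [0, 0], "no_high_homology": [0, 0]}
    gene_rows: Dict[str, List[int]] = {}
    joined = 0
    for call in ngs_calls:
        loa = loa_by_key.get(call.sample_key)
        if loa is None:
            continue
        joined += 1
        if call.call not in _CALLABLE or loa.loa_call == "FAIL":
            continue
        stratum = ("high_homology" if homology_flags.get(call.gene, False)
                   else "no_high_homology")
        agree = call.call.value == loa.loa_call
        strata[stratum][0 if agree else 1] += 1
        gene_rows.setdefault(call.gene, [0, 0])[0 if agree else 1] += 1
    if joined == 0:
        raise RunError("no samples shared between NGS calls and LoA results")
    tables = []
    for stratum, (agree, disagree) in strata.items():
        if agree + disagree == 0:
            log.warning("stratum %s has no double-called samples; omitted",
                        stratum)
            continue
        tables.append(ConcordanceTable(stratum, agree, disagree))
    per_gene = pd.DataFrame(
        [
            {"gene": g, "agree": a, "disagree": d,
             "percent_agree": 100.0 * a / (a + d)}
            for g, (a, d) in sorted(gene_rows.items())
        ],
        columns=["gene", "agree", "disagree", "percent_agree"],
    )
    return tables, per_gene


_CROSS_EXPECTATIONS = {
    "HET_X_HET": (("WT", "HET", "HOM"), (0.25, 0.5, 0.25)),
    "HET_X_WT": (("WT", "HET"), (0.5, 0.5)),
}


def _compositions(n: int, k: int):
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def exact_multinomial_p(observed: Sequence[int], probs: Sequence[float]) -> float:
    """Exact multinomial tail: total probability of outcomes no more likely
    than the observed one. Suited to litter-sized n where asymptotic
    chi-square tests misbehave."""
    n = int(sum(observed))
    dist = stats.multinomial(n, probs)
    p_obs = float(dist.pmf(observed))
    tail = 0.0
    for outcome in _compositions(n, len(probs)):
        p = float(dist.pmf(outcome))
        if p <= p_obs * (1 + 1e-9):
            tail += p
    return min(tail, 1.0)


@dataclass
class MendelianFlag:
    cross: str
    counts: Dict[str, int]
    p_value: float
    flagged: bool
    note: str = ""


def mendelian_flag(
    litter_calls: Sequence[GenotypeCall],
    cross: str,
    alpha: float = 0.05,
) -> MendelianFlag:
    """Flag a litter whose genotype counts depart from Mendelian ratios.

    Expected ratios: 1:2:1 over WT/HET/HOM for a het x het mating, 1:1 over
    WT/HET for het x WT. FAIL/AMBIGUOUS calls are excluded. A genotype
    impossible under the cross (e.g. HOM from het x WT) makes the observed
    outcome probability zero and flags immediately. A het x het litter of
    eight or more with neither WT nor HOM pups is flagged regardless of the
    p-value — the classic signature of an assay that cannot see homozygotes.
    """
    if cross not in _CROSS_EXPECTATIONS:
        raise ValidationError(f"unsupported cross {cross!r}")
    categories, probs = _CROSS_EXPECTATIONS[cross]
    counts = {c: 0 for c in categories}
    impossible = 0
    for call in litter_calls:
        if call.call not in _CALLABLE:
            continue
        if call.call.value in counts:
            counts[call.call.value] += 1
        else:
            impossible += 1
    n = sum(counts.values()) + impossible
    if n == 0:
        return MendelianFlag(cross, counts, 1.0, False, "no callable pups")
    if impossible:
        return MendelianFlag(cross, counts, 0.0, True,
                             f"{impossible} pup(s) impossible under {cross}")
    p = exact_multinomial_p([counts[c] for c in categories], probs)
    flagged = p < alpha
    note = ""
    if (cross == "HET_X_HET" and n >= 8
            and counts["WT"] == 0 and counts["HOM"] == 0):
        flagged = True
        note = "all-heterozygote het x het litter"
    return MendelianFlag(cross, counts, p, flagged, note)


GENOTYPE_TABLE_COLUMNS = [
    "sample_key", "mouse_id", "gene", "call", "ratio", "wt", "mut",
    "filtered", "no_match", "conflict", "quality_failed", "total", "reason",
]


def write_genotype_table(calls: Iterable[GenotypeCall], path) -> None:
    """Write calls as the tab-delimited genotype table, sorted by sample_key."""
    rows = []
    for c in sorted(calls, key=lambda c: c.sample_key):
        rows.append({
            "sample_key": c.sample_key, "mouse_id": c.mouse_id,
            "gene": c.gene, "call": c.call.value,
            "ratio": "" if c.ratio is None else repr(c.ratio),
            "wt": c.counts.wt, "mut": c.counts.mut,
            "filtered": c.counts.filtered, "no_match": c.counts.no_match,
            "conflict": c.counts.conflict,
            "quality_failed": c.counts.quality_failed,
            "total": c.counts.total, "reason": c.reason,
        })
    pd.DataFrame(rows, columns=GENOTYPE_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_genotype_table(path) -> List[GenotypeCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_key": str,
                                            "mouse_id": str, "gene": str,
                                            "reason": str})
    calls = []
    for row in df.itertuples(index=False):
        counts = BinCounts(
            wt=int(row.wt), mut=int(row.mut), filtered=int(row.filtered),
            no_match=int(row.no_match), conflict=int(row.conflict),
            quality_failed=int(row.quality_failed),
        )
        ratio = None if pd.isna(row.ratio) else float(row.ratio)
        calls.append(GenotypeCall(
            sample_key=str(row.sample_key),
            gene="" if pd.isna(row.gene) else str(row.gene),
            call=Genotype(row.call), ratio=ratio, counts=counts,
            reason=str(row.reason),
            mouse_id="" if pd.isna(row.mouse_id) else str(row.mouse_id),
        ))
    return calls
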