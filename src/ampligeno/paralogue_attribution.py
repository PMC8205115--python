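"""Attribution of reads to paralogue discriminator motifs.

In gene families with >90% homology over the assay region, a wild-type
assay can amplify a paralogue instead of the target locus and fake a
wild-type signal — a heterozygous-looking mouse that is really a clean
homozygote. Rather than aligning reads to the genome, this module matches
each read against a panel of labelled discriminator motifs (one per
candidate paralogue plus the target) and reports per-label counts and
percentages. A genotype call whose wild-type reads are dominated by
non-target labels is annotated SPURIOUS_WT with a putative homozygous
genotype.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .errors import ValidationError
from .genotype_caller import Genotype, GenotypeCall, match_motif
from .read_io import ReadRecord
from .sample_registry import AssayDefinition

log = logging.getLogger(__name__)

SPURIOUS_WT = "SPURIOUS_WT"


@dataclass
class MotifPanel:
    """Ordered list of (label, motif) paralogue discriminators."""

    entries: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.entries]
        if len(labels) != len(set(labels)):
            raise ValidationError("panel labels must be unique")
        self.entries = [(label, motif.upper()) for label, motif in self.entries]
        for label, motif in self.entries:
            if not motif:
                raise ValidationError(f"panel label {label!r} has empty motif")

    @property
    def labels(self) -> List[str]:
        return [label for label, _ in self.entries]


def load_panel(path) -> MotifPanel:
    """Read panel.tsv (columns: label, motif)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("label", "motif"):
        if col not in df.columns:
            raise ValidationError(f"{path}: panel is missing column {col!r}")
    return MotifPanel(entries=list(zip(df["label"], df["motif"])))


def display_percent(count: int, total: int) -> int:
    """Integer percentage, rounded half-up, as printed in reports."""
    if total == 0:
        return 0
    return int(math.floor(100.0 * count / total + 0.5))


@dataclass
class AttributionTable:
    """Per-label read counts over a motif panel.

    Percentages are of the total read count; full precision is retained in
    ``fraction_of_total`` while ``percent`` carries the rounded display
    value.
    """

    counts: Dict[str, int]
    unattributed: int
    conflict: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unattributed + self.conflict

    @property
    def attributed(self) -> int:
        return sum(self.counts.values())

    def fraction_of_total(self, label: str) -> float:
        return self.counts[label] / self.total if self.total else 0.0

    def percent(self, label: str) -> int:
        return display_percent(self.counts[label], self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": label, "count": c,
             "percent": display_percent(c, self.total)}
            for label, c in self.counts.items()
        ]
        rows.append({"label": "unattributed", "count": self.unattributed,
                     "percent": display_percent(self.unattributed, self.total)})
        rows.append({"label": "conflict", "count": self.conflict,
                     "percent": display_percent(self.conflict, self.total)})
        return pd.DataFrame(rows, columns=["label", "count", "percent"])


def attribute_reads(
    reads: Iterable[ReadRecord],
    panel: MotifPanel,
    max_mismatches: int = 0,
    search_rc: bool = True,
) -> AttributionTable:
    """Assign each read to the unique panel label whose motif it contains.

    Reads matching two or more labels are conflicts; reads matching none are
    unattributed. Categories sum to the total read count.
    """
    if not panel.entries:
        raise ValidationError("empty motif panel")
    counts = {label: 0 for label in panel.labels}
    unattributed = 0
    conflict = 0
    for read in reads:
        hits = [
            label for label, motif in panel.entries
            if match_motif(read.sequence, motif, max_mismatches, search_rc)[0]
        ]
        if len(hits) == 1:
            counts[hits[0]] += 1
        elif not hits:
            unattributed += 1
        else:
            conflict += 1
    return AttributionTable(counts=counts, unattributed=unattributed,
                            conflict=conflict)


def flag_spurious_wt(
    call: GenotypeCall,
    attribution: AttributionTable,
    target_label: str,
    dominance_fraction: float = 0.9,
) -> GenotypeCall:
    """Annotate a call whose wild-type-assay reads belong to paralogues.

    ``attribution`` must be computed on the WT-classified reads of the same
    sample, with ``target_label`` naming the intended locus in the panel.
    When non-target labels jointly capture >= dominance_fraction of the
    attributed reads, the call gains a SPURIOUS_WT annotation with putative
    genotype HOM; the original call is preserved.
    """
    if target_label not in attribution.counts:
        raise ValidationError(f"target label {target_label!r} not in panel")
    annotated = GenotypeCall(
        sample_key=call.sample_key, gene=call.gene, call=call.call,
        ratio=call.ratio, counts=call.counts, reason=call.reason,
        mouse_id=call.mouse_id, annotations=dict(call.annotations),
    )
    if attribution.attributed == 0:
        log.warning(
            "sample %s: no attributed reads, cannot assess WT specificity",
            call.sample_key,
        )
        return annotated
    non_target = attribution.attributed - attribution.counts[target_label]
    if non_target / attribution.attributed >= dominance_fraction:
        annotated.annotations["flag"] = SPURIOUS_WT
        annotated.annotations["putative_genotype"] = Genotype.HOM.value
    return annotated


def panel_from_assay(
    assay: AssayDefinition,
    paralogue_motifs: List[Tuple[str, str]],
) -> MotifPanel:
    """Panel with the assay's own WT motif as target plus paralogue motifs."""
    return MotifPanel(entries=[(assay.gene, assay.wt_motif)] + paralogue_motifs)
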