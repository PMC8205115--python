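"""Dual-index (i5/i7) multiplex bookkeeping and demultiplexing.

Samples are tagged with two 8 bp indexes: a plate-constant i5 and a
well-unique i7, so ``len(i5_set) x len(i7_set)`` samples can share one
sequencing run (16 plate indexes x a 96-well index set gives 1536). The
sequencer normally splits reads per sample itself; the demultiplexer here
makes the toolkit instrument-independent and lets the simulator's pooled
output be routed back to wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from .errors import CapacityError, ConfigurationError, ValidationError
from .read_io import DNA_ALPHABET, ReadRecord

INDEX_LENGTH = 8


@dataclass(frozen=True)
class BarcodePair:
    i5: str
    i7: str
    plate_id: str
    well: str

    def __post_init__(self) -> None:
        for name, seq in (("i5", self.i5), ("i7", self.i7)):
            if len(seq) != INDEX_LENGTH or not set(seq) <= DNA_ALPHABET:
                raise ValidationError(
                    f"{name} barcode {seq!r} is not a valid "
                    f"{INDEX_LENGTH}-mer"
                )


def multiplex_capacity(n_i5: int, n_i7: int) -> int:
    """Number of samples a dual-index layout can tag: n_i5 * n_i7."""
    if n_i5 < 1 or n_i7 < 1:
        raise ValidationError("index set sizes must be positive")
    return n_i5 * n_i7


def assign_barcodes(
    plate_ids: List[str],
    i5_set: List[str],
    i7_set: List[str],
    wells: List[str] | None = None,
) -> List[BarcodePair]:
    """Assign one plate-constant i5 and well-unique i7s to each plate.

    ``wells`` defaults to one well label per i7 barcode (W1..Wn); pass the
    A1-H12 labels for a physical 96-well plate.
    """
    if len(plate_ids) > len(i5_set):
        raise CapacityError(
            f"{len(plate_ids)} plates but only {len(i5_set)} i5 barcodes"
        )
    if wells is None:
        wells = [f"W{i + 1}" for i in range(len(i7_set))]
    if len(wells) > len(i7_set):
        raise CapacityError(
            f"{len(wells)} wells but only {len(i7_set)} i7 barcodes"
        )
    pairs = []
    for p, plate in enumerate(plate_ids):
        for w, well in enumerate(wells):
            pairs.append(BarcodePair(i5=i5_set[p], i7=i7_set[w],
                                     plate_id=plate, well=well))
    return pairs


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValidationError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def validate_barcode_map(pairs: List[BarcodePair], max_mismatch: int = 1) -> None:
    """Reject maps where a read could sit within tolerance of two pairs.

    Two pairs are mutually reachable when both their i5 and i7 distances are
    <= 2*max_mismatch; such a map could assign one read ambiguously.
    """
    seen: Dict[Tuple[str, str], BarcodePair] = {}
    for p in pairs:
        key = (p.i5, p.i7)
        if key in seen:
            raise ConfigurationError(
                f"duplicate barcode pair {key} for {p.plate_id}/{p.well} "
                f"and {seen[key].plate_id}/{seen[key].well}"
            )
        seen[key] = p
    reach = 2 * max_mismatch
    for i, a in enumerate(pairs):
        for b in pairs[i + 1:]:
            if hamming(a.i5, b.i5) <= reach and hamming(a.i7, b.i7) <= reach:
                raise ConfigurationError(
                    f"barcode pairs {a.plate_id}/{a.well} and "
                    f"{b.plate_id}/{b.well} are mutually reachable at "
                    f"max_mismatch={max_mismatch}"
                )


def parse_index_tags(description: str) -> Tuple[str, str]:
    """Extract (i5, i7) from an Illumina-style header comment.

    The comment's last colon-delimited field holds the indexes as
    ``i5+i7`` (e.g. ``1:N:0:ACGTACGT+TGCATGCA``).
    """
    if ":" not in description or "+" not in description:
        raise ValidationError(
            f"read description {description!r} carries no i5+i7 index tags"
        )
    tag = description.rsplit(":", 1)[-1]
    i5, _, i7 = tag.partition("+")
    return i5.strip(), i7.strip()


def generate_barcode_set(
    n: int,
    length: int = INDEX_LENGTH,
    min_distance: int = 3,
    seed: int = 0,
) -> List[str]:
    """Greedy synthetic barcode set with pairwise Hamming distance >= min_distance.

    Stands in for published index sets, which are licensed sequences; any
    set meeting the distance floor behaves identically in the demultiplexer.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    chosen: List[str] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 200000:
            raise CapacityError(
                f"could not find {n} barcodes of length {length} at "
                f"distance {min_distance}"
            )
        cand = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, c) >= min_distance for c in chosen):
            chosen.append(cand)
    return chosen


def load_barcode_sets(path) -> Tuple[List[str], List[str]]:
    """Read barcodes.tsv (columns: set, name, sequence) -> (i5_set, i7_set)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("set", "name", "sequence"):
        if col not in df.columns:
            raise ConfigurationError(
                f"{path}: barcode file is missing required column {col!r}"
            )
    i5 = df.loc[df["set"] == "i5", "sequence"].tolist()
    i7 = df.loc[df["set"] == "i7", "sequence"].tolist()
    return i5, i7


@dataclass
class DemuxResult:
    assigned: Dict[Tuple[str, str], List[ReadRecord]]
    unassigned: List[ReadRecord] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    @property
    def n_total(self) -> int:
        return self.n_assigned + len(self.unassigned)


def demultiplex(
    reads: Iterable[ReadRecord],
    pairs: List[BarcodePair],
    max_mismatch_per_index: int = 1,
) -> DemuxResult:
    """Route index-tagged reads to (plate, well) bins.

    A read is assigned iff exactly one pair is within
    ``max_mismatch_per_index`` Hamming distance on both indexes; all other
    reads land in the unassigned bin, so assigned + unassigned = total.
    """
    validate_barcode_map(pairs, max_mismatch_per_index)
    result = DemuxResult(assigned={(p.plate_id, p.well): [] for p in pairs})
    exact = {(p.i5, p.i7): p for p in pairs}
    for read in reads:
        i5, i7 = parse_index_tags(read.description)
        pair = exact.get((i5, i7))
        if pair is None and max_mismatch_per_index > 0:
            hits = [
                p for p in pairs
                if hamming(i5, p.i5) <= max_mismatch_per_index
                and hamming(i7, p.i7) <= max_mismatch_per_index
            ]
            pair = hits[0] if len(hits) == 1 else None
        if pair is None:
            result.unassigned.append(read)
        else:
            result.assigned[(pair.plate_id, pair.well)].append(read)
    return result
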