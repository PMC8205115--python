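"""Sample sheets, motif databases and FASTQ filename resolution.

The production pipeline this toolkit models kept mouse and assay metadata in
a relational database keyed by FASTQ filename. Here the same bookkeeping is
done with two flat TSV registries:

* ``samples.tsv`` — one row per sample: ``sample_key``, ``mouse_id``,
  ``gene`` and optional ``plate_id`` / ``well``. The mouse ID convention is
  colony_mating.litter+individual, e.g. ``Psg21_3.2a``.
* ``motifs.tsv`` — one row per gene: the wild-type and mutant discriminatory
  motifs (canonically 50 bp), optional filter motifs marking unintended
  amplicons, expected amplicon sizes and a high-homology flag.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .errors import ConfigurationError, SampleLookupError, ValidationError
from .read_io import DNA_ALPHABET

log = logging.getLogger(__name__)

CANONICAL_MOTIF_LEN = 50
MIN_MOTIF_LEN = 20

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|0[1-9]|1[0-2])$")

#: default filename rule: take the text before the first Illumina "_S<digits>"
#: suffix, else the basename without sequence extensions
_ILLUMINA_SUFFIX_RE = re.compile(r"_S\d+")
_EXTENSION_RE = re.compile(
    r"\.(fastq|fq|fasta|fa|fna)(\.gz)?$", re.IGNORECASE
)


@dataclass
class SampleRecord:
    sample_key: str
    mouse_id: str
    gene: str
    plate_id: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        if self.well and not _WELL_RE.match(self.well.upper()):
            raise ValidationError(
                f"sample {self.sample_key!r}: well {self.well!r} is not an "
                "8x12 plate coordinate (A1-H12)"
            )


@dataclass
class AssayDefinition:
    """Per-gene motif assay: a wild-type and a mutant-specific discriminatory
    motif, plus optional filter motifs that mark off-target amplicons."""

    gene: str
    wt_motif: str
    mut_motif: str
    filter_motifs: List[str] = field(default_factory=list)
    wt_amplicon_len: Optional[int] = None
    mut_amplicon_len: Optional[int] = None
    high_homology: bool = False

    def __post_init__(self) -> None:
        self.wt_motif = self.wt_motif.upper()
        self.mut_motif = self.mut_motif.upper()
        self.filter_motifs = [m.upper() for m in self.filter_motifs]
        for name, motif in self._named_motifs():
            bad = set(motif) - DNA_ALPHABET
            if bad:
                raise ValidationError(
                    f"gene {self.gene!r}: {name} contains invalid "
                    f"character(s) {sorted(bad)}"
                )
            if len(motif) < MIN_MOTIF_LEN:
                raise ValidationError(
                    f"gene {self.gene!r}: {name} is {len(motif)} bp, below "
                    f"the {MIN_MOTIF_LEN} bp floor"
                )
            if len(motif) != CANONICAL_MOTIF_LEN:
                log.warning(
                    "gene %s: %s is %d bp (canonical length is %d)",
                    self.gene, name, len(motif), CANONICAL_MOTIF_LEN,
                )
        if self.wt_motif == self.mut_motif:
            raise ValidationError(
                f"gene {self.gene!r}: wt_motif equals mut_motif"
            )
        for fm in self.filter_motifs:
            if fm in (self.wt_motif, self.mut_motif):
                raise ValidationError(
                    f"gene {self.gene!r}: filter motif duplicates an "
                    "allele motif"
                )

    def _named_motifs(self):
        yield "wt_motif", self.wt_motif
        yield "mut_motif", self.mut_motif
        for i, fm in enumerate(self.filter_motifs):
            yield f"filter_motifs[{i}]", fm


class SampleRegistry:
    """In-memory registry of SampleRecords keyed by sample_key."""

    def __init__(self, records: List[SampleRecord]):
        self._by_key: Dict[str, SampleRecord] = {}
        for rec in records:
            if rec.sample_key in self._by_key:
                raise ValidationError(
                    f"duplicate sample_key {rec.sample_key!r} in sample sheet"
                )
            self._by_key[rec.sample_key] = rec

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    def __iter__(self):
        return iter(self._by_key.values())

    def get(self, key: str) -> Optional[SampleRecord]:
        return self._by_key.get(key)

    def lookup(self, key: str) -> SampleRecord:
        rec = self._by_key.get(key)
        if rec is None:
            raise SampleLookupError(f"sample_key {key!r} not in registry")
        return rec


_SAMPLE_REQUIRED = ["sample_key", "mouse_id", "gene"]
_SAMPLE_OPTIONAL = ["plate_id", "well"]
_MOTIF_REQUIRED = ["gene", "wt_motif", "mut_motif"]


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"file not found: {path}")
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def load_sample_sheet(path) -> SampleRegistry:
    """Load a tab-delimited sample sheet into a SampleRegistry."""
    df = _read_tsv(path)
    for col in _SAMPLE_REQUIRED:
        if col not in df.columns:
            raise ConfigurationError(
                f"{path}: sample sheet is missing required column {col!r}"
            )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_key=row.sample_key,
                mouse_id=row.mouse_id,
                gene=row.gene,
                plate_id=getattr(row, "plate_id", ""),
                well=getattr(row, "well", ""),
            )
        )
    return SampleRegistry(records)


def write_sample_sheet(registry: SampleRegistry, path) -> None:
    rows = [
        {
            "sample_key": r.sample_key,
            "mouse_id": r.mouse_id,
            "gene": r.gene,
            "plate_id": r.plate_id,
            "well": r.well,
        }
        for r in registry
    ]
    cols = _SAMPLE_REQUIRED + _SAMPLE_OPTIONAL
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def load_motif_db(path) -> Dict[str, AssayDefinition]:
    """Load a tab-delimited motif database into gene -> AssayDefinition.

    ``filter_motifs`` is a semicolon-separated list; ``high_homology`` is 0/1.
    """
    df = _read_tsv(path)
    for col in _MOTIF_REQUIRED:
        if col not in df.columns:
            raise ConfigurationError(
                f"{path}: motif database is missing required column {col!r}"
            )
    db: Dict[str, AssayDefinition] = {}
    for row in df.itertuples(index=False):
        gene = row.gene
        if gene in db:
            raise ValidationError(f"duplicate gene {gene!r} in motif database")
        filters = [
            m for m in getattr(row, "filter_motifs", "").split(";") if m
        ]

        def _opt_int(name):
            val = getattr(row, name, "")
            return int(val) if val else None

        db[gene] = AssayDefinition(
            gene=gene,
            wt_motif=row.wt_motif,
            mut_motif=row.mut_motif,
            filter_motifs=filters,
            wt_amplicon_len=_opt_int("wt_amplicon_len"),
            mut_amplicon_len=_opt_int("mut_amplicon_len"),
            high_homology=str(getattr(row, "high_homology", "0")) in ("1", "True", "true"),
        )
    return db


def write_motif_db(db: Dict[str, AssayDefinition], path) -> None:
    rows = [
        {
            "gene": a.gene,
            "wt_motif": a.wt_motif,
            "mut_motif": a.mut_motif,
            "filter_motifs": ";".join(a.filter_motifs),
            "wt_amplicon_len": a.wt_amplicon_len if a.wt_amplicon_len is not None else "",
            "mut_amplicon_len": a.mut_amplicon_len if a.mut_amplicon_len is not None else "",
            "high_homology": int(a.high_homology),
        }
        for a in db.values()
    ]
    cols = _MOTIF_REQUIRED + ["filter_motifs", "wt_amplicon_len",
                              "mut_amplicon_len", "high_homology"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def parse_fastq_filename(filename: str, pattern: Optional[str] = None) -> str:
    """Resolve a sequence filename to its sample key.

    The default rule takes the text before the first Illumina ``_S<digits>``
    suffix; if no such suffix is present, the basename without its sequence
    extension is used. A custom ``pattern`` is a regex whose first capture
    group is the key.
    """
    if not filename:
        raise SampleLookupError("empty filename cannot be resolved")
    base = Path(filename).name
    if pattern is not None:
        m = re.search(pattern, base)
        if not m or not m.group(1):
            raise SampleLookupError(
                f"filename {filename!r} does not match template {pattern!r}"
            )
        return m.group(1)
    m = _ILLUMINA_SUFFIX_RE.search(base)
    if m and m.start() > 0:
        return base[: m.start()]
    key = _EXTENSION_RE.sub("", base)
    if not key:
        raise SampleLookupError(f"filename {filename!r} yields an empty key")
    return key
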