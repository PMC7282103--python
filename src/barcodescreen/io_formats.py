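"""Readers/writers for the plain-text formats the toolkit exchanges.

FASTA records, accession sample tables (TSV/CSV), BED annotations and
TSV/JSON report serialisation.  Internal coordinates are 0-based half-open
throughout the package; written reports use 1-based inclusive coordinates
(GenBank convention).

No science lives here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import ALPHABET

logger = logging.getLogger(__name__)

#: IUPAC ambiguity codes (other than N) that are collapsed to N on input.
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")


@dataclass(frozen=True)
class Annotation:
    """A named region on a sequence, 0-based half-open."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"annotation {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise ValueError(f"annotation {self.name!r}: negative start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"annotation {self.name!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PlastomeRecord:
    """One plastome (or barcode-region) sequence with optional annotations."""

    accession_id: str
    sequence: str
    species: str = ""
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.accession_id!r} has an empty sequence")
        for ann in self.annotations:
            if ann.end > len(self.sequence):
                raise ValueError(
                    f"annotation {ann.name!r} ({ann.start}:{ann.end}) extends past "
                    f"sequence of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase, map U->T, collapse non-N ambiguity codes to N.

    Raises on characters outside the A/C/G/T/N/- alphabet after mapping.
    """
    seq = raw.upper().replace("U", "T")
    present = set(seq) - ALPHABET
    if present & AMBIGUITY_CODES:
        logger.warning(
            "record %s: ambiguity codes %s mapped to N",
            record_id,
            "".join(sorted(present & AMBIGUITY_CODES)),
        )
        seq = seq.translate(str.maketrans({c: "N" for c in AMBIGUITY_CODES}))
        present = set(seq) - ALPHABET
    if present:
        raise ValueError(
            f"record {record_id!r}: unsupported characters {''.join(sorted(present))!r}"
        )
    return seq


def read_fasta(path: str | Path) -> list[PlastomeRecord]:
    """Read a (multi-)FASTA into PlastomeRecords.

    Ids are the first whitespace-delimited header token; sequences are
    normalised (uppercase, U->T, ambiguity->N).  Duplicate ids and empty
    sequences are errors.
    """
    path = Path(path)
    records: list[PlastomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(PlastomeRecord(accession_id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[PlastomeRecord], path: str | Path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


class SampleTable:
    """Accession -> species mapping (one row per accession)."""

    REQUIRED = ("accession_id", "species")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"sample table is missing required column {col!r}")
        dup = frame["accession_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate accession_id rows: {sorted(frame['accession_id'][dup])}"
            )
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SampleTable":
        return cls(pd.DataFrame(list(pairs), columns=["accession_id", "species"]))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def accessions(self) -> list[str]:
        return list(self.frame["accession_id"])

    def species_of(self, accession_id: str) -> str:
        m = dict(zip(self.frame["accession_id"], self.frame["species"]))
        try:
            return m[accession_id]
        except KeyError:
            raise KeyError(f"accession {accession_id!r} not in sample table") from None

    def species_to_accessions(self) -> dict[str, list[str]]:
        """Mapping species -> accession list, input-ordered within species."""
        out: dict[str, list[str]] = {}
        for acc, sp in zip(self.frame["accession_id"], self.frame["species"]):
            out.setdefault(sp, []).append(acc)
        return out

    def multi_accession_species(self) -> list[str]:
        """Species with >= 2 sampled accessions (the discrimination denominator)."""
        return [sp for sp, accs in self.species_to_accessions().items() if len(accs) >= 2]

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


_COLUMN_ALIASES = {
    "accession": "accession_id",
    "accession_id": "accession_id",
    "species": "species",
    "section": "section",
}


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a TSV/CSV sample table with accession and species columns.

    Column names are matched case-insensitively; 'accession' is accepted for
    'accession_id'.  Blank species cells are an error naming the row.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    frame = frame.rename(columns=_COLUMN_ALIASES)
    for col in SampleTable.REQUIRED:
        if col not in frame.columns:
            raise ValueError(f"sample table {path} is missing required column {col!r}")
    for col in frame.columns:
        frame[col] = frame[col].str.strip()
    blank = frame.index[frame["species"] == ""]
    if len(blank):
        # +2: header line plus 1-based numbering
        raise ValueError(f"sample table {path}: blank species at data row {blank[0] + 2}")
    return SampleTable(frame)


def read_bed(path: str | Path) -> list[Annotation]:
    """Read a BED (>=4 columns used: chrom, start, end, name[, score, strand])."""
    annotations = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{line_no}: expected >= 4 BED columns")
            strand = parts[5] if len(parts) >= 6 else "+"
            annotations.append(
                Annotation(name=parts[3], start=int(parts[1]), end=int(parts[2]), strand=strand)
            )
    return annotations


def write_bed(
    annotations: Iterable[Annotation], path: str | Path, chrom: str = "plastome"
) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            fh.write(f"{chrom}\t{ann.start}\t{ann.end}\t{ann.name}\t0\t{ann.strand}\n")


def _as_frame(report) -> pd.DataFrame:
    if isinstance(report, pd.DataFrame):
        return report
    if hasattr(report, "to_frame"):
        return report.to_frame()
    raise TypeError(f"cannot serialise report of type {type(report).__name__}")


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Write a report object (anything with .to_frame(), or a DataFrame).

    TSV keeps the frame's column order; JSON is a list of row objects.
    """
    frame = _as_frame(report)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'tsv' or 'json')")


def read_report(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for TSV reports written by write_report."""
    return pd.read_csv(path, sep="\t")
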