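"""Readers and writers for the formats the pipeline touches.

Three strict dialects are supported:

* protein FASTA (headers ``>id description [Organism name]``),
* 13-column tab-separated alignment hit tables in the classic extended
  BLAST tabular field order
  (``qacc sacc pident length mismatch gapopen qstart qend sstart send
  evalue bitscore stitle``), no header row, ``#`` comments skipped,
* gene-locus TSV with header
  ``genome_id gene_id start end strand label``.

Coordinates are 1-based inclusive throughout (GenBank convention).
``genome_id`` may carry a replicon suffix as ``assembly/replicon``; the part
before the first ``/`` identifies the genome assembly.

Parsers are total: every input yields either records or a located
:class:`FormatError`, never a silent partial result.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, TextIO

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid letters plus X (unknown/masked).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
#: Ambiguity/odd letters silently mapped to X (real RefSeq proteomes contain them).
_AMBIGUOUS = frozenset("BZUJO*")

HIT_COLUMNS = (
    "qacc", "sacc", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "stitle",
)

LOCI_COLUMNS = ("genome_id", "gene_id", "start", "end", "strand", "label")


class FormatError(ValueError):
    """Raised when an input stream violates one of the documented dialects."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its header metadata."""

    id: str
    description: str = ""
    organism: str = ""
    sequence: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic coordinates (1-based, inclusive)."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    label: str

    @property
    def assembly(self) -> str:
        """Genome assembly identifier (``genome_id`` up to the first ``/``)."""
        return self.genome_id.split("/", 1)[0]


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment match in the 13-field tabular dialect."""

    qacc: str
    sacc: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    stitle: str = ""

    def canonical(self) -> "AlignmentHit":
        """Round floats to the serialized precision so write∘read is identity."""
        return replace(
            self,
            pident=round(self.pident, 3),
            bitscore=round(self.bitscore, 1),
            evalue=float(f"{self.evalue:.3e}") if self.evalue else 0.0,
        )


def _coerce_stream(source: str | Path | TextIO) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def extract_organism(description: str) -> str:
    """Return the trailing bracketed scientific name of a FASTA description.

    ``"hypothetical protein [Haloferax mediterranei]"`` yields
    ``"Haloferax mediterranei"``; descriptions without a trailing bracket
    yield the empty string.
    """
    desc = description.rstrip()
    if desc.endswith("]"):
        idx = desc.rfind("[")
        if idx != -1:
            return desc[idx + 1 : -1].strip()
    return ""


def parse_fasta(source: str | Path | TextIO) -> list[ProteinRecord]:
    """Parse protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased; ambiguity letters (B, Z, U, J, O, ``*``) are
    mapped to X with a warning; any other non-amino-acid character is a
    :class:`FormatError` naming the record.
    """
    stream = _coerce_stream(source)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        parts = header.split(None, 1)
        rec_id = parts[0] if parts else ""
        if not rec_id:
            raise FormatError("FASTA header with empty id")
        if rec_id in seen:
            raise FormatError(f"duplicate FASTA id {rec_id!r}")
        seen.add(rec_id)
        seq = "".join(chunks).upper().replace(" ", "")
        if not seq:
            raise FormatError(f"record {rec_id!r} has an empty sequence")
        if any(c in _AMBIGUOUS for c in seq):
            warnings.warn(
                f"record {rec_id!r}: ambiguity letters mapped to X", stacklevel=3
            )
            seq = "".join("X" if c in _AMBIGUOUS else c for c in seq)
        bad = sorted(set(seq) - _VALID_RESIDUES)
        if bad:
            raise FormatError(
                f"record {rec_id!r} contains invalid residue(s) {''.join(bad)!r}"
            )
        description = parts[1].strip() if len(parts) > 1 else ""
        organism = extract_organism(description)
        if organism:
            # the trailing bracket moves into the organism field; write_fasta
            # re-emits it, so parse∘write is the identity
            description = description[: description.rfind("[")].rstrip()
        records.append(
            ProteinRecord(
                id=rec_id,
                description=description,
                organism=organism,
                sequence=seq,
            )
        )

    for line in stream:
        line = line.rstrip("\n")
        if line.startswith(">"):
            flush()
            header = line[1:]
            chunks = []
        elif line.strip():
            if header is None:
                raise FormatError("sequence data before first FASTA header")
            chunks.append(line.strip())
    flush()
    if not records:
        logger.warning("parse_fasta: empty input, no records parsed")
    return records


def write_fasta(records: Iterable[ProteinRecord], dest: str | Path | TextIO,
                width: int = 60) -> None:
    """Write records as wrapped FASTA; organism re-emitted as ``[...]`` suffix."""
    own = isinstance(dest, (str, Path))
    stream: TextIO = open(dest, "w", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        for rec in records:
            desc = rec.description
            if rec.organism:
                desc = f"{desc} [{rec.organism}]".strip()
            header = f">{rec.id} {desc}".rstrip()
            stream.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                stream.write(rec.sequence[i : i + width] + "\n")
    finally:
        if own:
            stream.close()


def fasta_string(records: Iterable[ProteinRecord]) -> str:
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()


# --- hit tables -------------------------------------------------------------

_INT_FIELDS = {"length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"}
_FLOAT_FIELDS = {"pident", "evalue", "bitscore"}


def read_hits(source: str | Path | TextIO) -> list[AlignmentHit]:
    """Read a 13-column hit table; rows with the wrong shape raise with line numbers."""
    stream = _coerce_stream(source)
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != 13:
            raise FormatError(
                f"line {lineno}: expected 13 tab-separated columns, got {len(cells)}"
            )
        kwargs: dict[str, object] = {}
        for name, cell in zip(HIT_COLUMNS, cells):
            if name in _INT_FIELDS:
                try:
                    kwargs[name] = int(cell)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: non-integer value {cell!r} in column {name}"
                    ) from None
            elif name in _FLOAT_FIELDS:
                try:
                    value = float(cell)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: non-numeric value {cell!r} in column {name}"
                    ) from None
                if not math.isfinite(value):
                    raise FormatError(f"line {lineno}: non-finite {name}")
                kwargs[name] = value
            else:
                kwargs[name] = cell
        hits.append(AlignmentHit(**kwargs))  # type: ignore[arg-type]
    return hits


def format_hit(hit: AlignmentHit) -> str:
    return "\t".join(
        (
            hit.qacc,
            hit.sacc,
            f"{hit.pident:.3f}",
            str(hit.length),
            str(hit.mismatch),
            str(hit.gapopen),
            str(hit.qstart),
            str(hit.qend),
            str(hit.sstart),
            str(hit.send),
            f"{hit.evalue:.3e}" if hit.evalue else "0.0",
            f"{hit.bitscore:.1f}",
            hit.stitle,
        )
    )


def write_hits(hits: Iterable[AlignmentHit], dest: str | Path | TextIO) -> None:
    own = isinstance(dest, (str, Path))
    stream: TextIO = open(dest, "w", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        for hit in hits:
            stream.write(format_hit(hit) + "\n")
    finally:
        if own:
            stream.close()


# --- gene-locus tables ------------------------------------------------------

_STRANDS = {"+", "-"}


def read_loci(source: str | Path | TextIO) -> list[GeneLocus]:
    """Read a gene-locus TSV (header required, coordinates 1-based inclusive)."""
    stream = _coerce_stream(source)
    lines = [ln.rstrip("\n") for ln in stream]
    if not lines or not lines[0].strip():
        logger.warning("read_loci: empty input")
        return []
    header = tuple(lines[0].split("\t"))
    if header != LOCI_COLUMNS:
        raise FormatError(
            f"locus table header must be {list(LOCI_COLUMNS)}, got {list(header)}"
        )
    loci: list[GeneLocus] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 6:
            raise FormatError(f"line {lineno}: expected 6 columns, got {len(cells)}")
        genome_id, gene_id, start_s, end_s, strand, label = cells
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"line {lineno}: non-integer coordinate") from None
        if start < 1:
            raise FormatError(f"line {lineno}: start must be >= 1 (1-based)")
        if start > end:
            raise FormatError(f"line {lineno}: start {start} > end {end}")
        if strand not in _STRANDS:
            raise FormatError(
                f"line {lineno}: unknown strand {strand!r}; allowed symbols: + -"
            )
        key = (genome_id, gene_id)
        if key in seen:
            raise FormatError(f"line {lineno}: duplicate locus {key}")
        seen.add(key)
        loci.append(GeneLocus(genome_id, gene_id, start, end, strand, label))
    return loci


def write_loci(loci: Iterable[GeneLocus], dest: str | Path | TextIO) -> None:
    own = isinstance(dest, (str, Path))
    stream: TextIO = open(dest, "w", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        stream.write("\t".join(LOCI_COLUMNS) + "\n")
        for locus in loci:
            stream.write(
                f"{locus.genome_id}\t{locus.gene_id}\t{locus.start}\t"
                f"{locus.end}\t{locus.strand}\t{locus.label}\n"
            )
    finally:
        if own:
            stream.close()
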