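"""Readers and writers for every external format the pipeline touches.

Two FASTA header dialects are supported besides plain ``>accession description``
headers:

* the IPI dialect, ``IPI:IPI00000001.2|SWISS-PROT:O95793-1|... Tax_Id=9606 ...``,
  whose pipe-separated tokens embed cross-references to other protein databases;
* the UniProtKB dialect, ``sp|P01111|RASN_HUMAN ...`` / ``tr|Q59F99|...``, where
  the leading ``sp``/``tr`` marks the reviewed (Swiss-Prot) or unreviewed
  (TrEMBL) section.

Evidence tables (local snapshots of PeptideAtlas, GPMDB and PRIDE) and all
reports are tab-separated text with a header row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "ProteinRecord",
    "SequenceDatabase",
    "EvidenceTable",
    "FastaDialectError",
    "FormatError",
    "parse_ipi_header",
    "parse_uniprot_header",
    "read_fasta",
    "write_fasta",
    "read_evidence_table",
    "write_tsv_report",
]

REVIEW_STATUSES = ("reviewed", "unreviewed", "not-applicable")

#: Residues accepted in sequences: the 20 standard amino acids plus the
#: ambiguity / rare codes B, J, O, U, X, Z that occur in 2011-era entries.
_SEQ_RE = re.compile(r"^[A-Z]+$")


class FastaDialectError(ValueError):
    """A FASTA header does not conform to the declared dialect."""


class FormatError(ValueError):
    """A tabular input file violates its declared format."""


@dataclass
class ProteinRecord:
    """One protein database entry.

    ``accession`` is version-stripped (``IPI00000001``, ``P01111``); the IPI
    version suffix, when present, lives in ``version``.  ``xrefs`` maps a
    database name (``SWISS-PROT``, ``TREMBL``, ``ENSEMBL``, ...) to the
    accessions cross-referenced under it, isoform suffixes preserved verbatim.
    """

    accession: str
    sequence: str
    description: str = ""
    version: int | None = None
    xrefs: dict[str, list[str]] = field(default_factory=dict)
    taxon: int | None = None
    review_status: str = "not-applicable"
    entry_name: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence or not _SEQ_RE.match(self.sequence):
            raise ValueError(
                f"record {self.accession!r}: sequence must be a non-empty "
                "uppercase A-Z string"
            )
        if self.review_status not in REVIEW_STATUSES:
            raise ValueError(f"invalid review_status {self.review_status!r}")
        for db, accs in self.xrefs.items():
            if len(accs) != len(set(accs)):
                raise ValueError(
                    f"record {self.accession!r}: duplicate xref accessions under {db!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDatabase:
    """An ordered protein database with an accession index."""

    name: str
    release: str
    records: list[ProteinRecord]
    accession_index: dict[str, ProteinRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.accession in index:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            index[rec.accession] = rec
        self.accession_index = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self.accession_index

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self.accession_index[accession]


REPOSITORIES = ("peptideatlas", "gpmdb", "pride")


@dataclass
class EvidenceTable:
    """Per-peptide evidence from one proteomics repository snapshot.

    Rows map an uppercase peptide to ``{"proteotypic": bool}`` for
    PeptideAtlas/GPMDB or ``{"experiment_count": int}`` for PRIDE.
    """

    repository: str
    rows: dict[str, dict]

    def __post_init__(self) -> None:
        if self.repository not in REPOSITORIES:
            raise ValueError(f"unknown repository {self.repository!r}")

    def proteotypic(self, peptide: str) -> bool:
        row = self.rows.get(peptide)
        return bool(row["proteotypic"]) if row else False

    def experiment_count(self, peptide: str) -> int:
        row = self.rows.get(peptide)
        return int(row["experiment_count"]) if row else 0


# ---------------------------------------------------------------------------
# Header parsing
# ---------------------------------------------------------------------------

_TAXID_RE = re.compile(r"\bTax_Id=(\d+)\s*")


def parse_ipi_header(header: str) -> tuple[str, int, dict[str, list[str]], int | None, str]:
    """Parse an IPI-dialect header (leading ``>`` already removed).

    Returns ``(accession, version, xrefs, taxon, description)``.  The
    accession is version-stripped; every ``DBNAME:acc1;acc2`` token before the
    first space becomes an xrefs entry.  Isoform suffixes on cross-referenced
    accessions (``O95793-1``) are preserved verbatim.
    """
    if not header.startswith("IPI:IPI"):
        raise FastaDialectError(f"not an IPI header: {header[:40]!r}")
    head, _, remainder = header.partition(" ")
    tokens = head.split("|")
    ipi_token = tokens[0][len("IPI:") :]
    acc, dot, version_str = ipi_token.rpartition(".")
    if not dot or not version_str.isdigit():
        raise FastaDialectError(f"IPI accession lacks integer version: {tokens[0]!r}")
    xrefs: dict[str, list[str]] = {}
    for token in tokens[1:]:
        dbname, colon, accs = token.partition(":")
        if not colon or not dbname or not accs:
            raise FastaDialectError(f"malformed cross-reference token {token!r}")
        bucket = xrefs.setdefault(dbname, [])
        for a in accs.split(";"):
            if a and a not in bucket:
                bucket.append(a)
    taxon: int | None = None
    m = _TAXID_RE.search(remainder)
    if m:
        taxon = int(m.group(1))
        remainder = remainder[: m.start()] + remainder[m.end() :]
    return acc, int(version_str), xrefs, taxon, remainder.strip()


def parse_uniprot_header(header: str) -> tuple[str, str, str, str]:
    """Parse a UniProtKB-dialect header into
    ``(accession, entry_name, review_status, description)``."""
    if not (header.startswith("sp|") or header.startswith("tr|")):
        raise FastaDialectError(f"not a UniProtKB header: {header[:40]!r}")
    parts = header.split("|", 2)
    if len(parts) < 3 or not parts[1] or not parts[2]:
        raise FastaDialectError(f"UniProtKB header needs three pipe fields: {header[:60]!r}")
    status = "reviewed" if parts[0] == "sp" else "unreviewed"
    entry_name, _, description = parts[2].partition(" ")
    return parts[1], entry_name, status, description.strip()


def _parse_plain_header(header: str) -> tuple[str, str]:
    accession, _, description = header.partition(" ")
    if not accession:
        raise FastaDialectError("empty plain header")
    return accession, description.strip()


DIALECTS = ("ipi", "uniprot", "plain")


def _record_from_header(header: str, sequence: str, dialect: str) -> ProteinRecord:
    if dialect == "ipi":
        acc, version, xrefs, taxon, desc = parse_ipi_header(header)
        return ProteinRecord(acc, sequence, desc, version=version, xrefs=xrefs, taxon=taxon)
    if dialect == "uniprot":
        acc, entry_name, status, desc = parse_uniprot_header(header)
        return ProteinRecord(acc, sequence, desc, review_status=status, entry_name=entry_name)
    acc, desc = _parse_plain_header(header)
    return ProteinRecord(acc, sequence, desc)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, dialect: str, name: str = "", release: str = "") -> SequenceDatabase:
    """Read a protein FASTA file under the given header dialect.

    Sequences are uppercased and trailing ``*`` stop characters stripped.
    Duplicate accessions, empty sequences, and headers that do not parse
    under the declared dialect are hard errors (the latter reported with the
    offending line number).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    # line numbers of '>' headers, for error reporting
    header_lines: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines.append(lineno)
    records: list[ProteinRecord] = []
    with path.open() as fh:
        for i, (title, seq) in enumerate(SimpleFastaParser(fh)):
            lineno = header_lines[i]
            seq = seq.upper().rstrip("*")
            if not seq:
                raise ValueError(f"{path}:{lineno}: empty sequence for header {title[:40]!r}")
            try:
                records.append(_record_from_header(title, seq, dialect))
            except FastaDialectError as exc:
                raise FastaDialectError(f"{path}:{lineno}: {exc}") from exc
    try:
        return SequenceDatabase(name or path.stem, release, records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _format_header(rec: ProteinRecord, dialect: str) -> str:
    if dialect == "ipi":
        version = 1 if rec.version is None else rec.version
        tokens = [f"IPI:{rec.accession}.{version}"]
        tokens += [f"{db}:{';'.join(accs)}" for db, accs in rec.xrefs.items()]
        tail = ""
        if rec.taxon is not None:
            tail += f" Tax_Id={rec.taxon}"
        if rec.description:
            tail += f" {rec.description}"
        return "|".join(tokens) + tail
    if dialect == "uniprot":
        prefix = "sp" if rec.review_status == "reviewed" else "tr"
        entry = rec.entry_name or f"{rec.accession}_SYN"
        head = f"{prefix}|{rec.accession}|{entry}"
        return f"{head} {rec.description}" if rec.description else head
    return f"{rec.accession} {rec.description}".rstrip()


def write_fasta(db: SequenceDatabase, path: str | Path, dialect: str, width: int = 60) -> None:
    """Write a database back to FASTA in the given dialect (round-trip safe)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open("w") as fh:
        for rec in db:
            fh.write(f">{_format_header(rec, dialect)}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Evidence tables and TSV reports
# ---------------------------------------------------------------------------

_EXPECTED_VALUE_COLUMN = {
    "peptideatlas": "proteotypic",
    "gpmdb": "proteotypic",
    "pride": "experiment_count",
}

_BOOL_STRINGS = {"0": False, "1": True, "true": True, "false": False}


def read_evidence_table(path: str | Path, repository: str) -> EvidenceTable:
    """Read a two-column TSV evidence snapshot for one repository.

    Expected header: ``peptide<TAB>proteotypic`` (peptideatlas/gpmdb) or
    ``peptide<TAB>experiment_count`` (pride).
    """
    if repository not in REPOSITORIES:
        raise ValueError(f"unknown repository {repository!r}")
    value_col = _EXPECTED_VALUE_COLUMN[repository]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ["peptide", value_col]:
        raise FormatError(
            f"{path}: expected columns ['peptide', {value_col!r}] for "
            f"{repository}, found {list(df.columns)}"
        )
    rows: dict[str, dict] = {}
    for peptide, raw in zip(df["peptide"], df[value_col]):
        peptide = peptide.upper()
        if peptide in rows:
            raise FormatError(f"{path}: duplicate peptide {peptide!r}")
        if value_col == "proteotypic":
            key = raw.strip().lower()
            if key not in _BOOL_STRINGS:
                raise FormatError(f"{path}: invalid boolean {raw!r} for {peptide!r}")
            rows[peptide] = {"proteotypic": _BOOL_STRINGS[key]}
        else:
            try:
                count = int(raw)
            except ValueError as exc:
                raise FormatError(f"{path}: invalid count {raw!r} for {peptide!r}") from exc
            if count < 0:
                raise FormatError(f"{path}: negative experiment_count for {peptide!r}")
            rows[peptide] = {"experiment_count": count}
    return EvidenceTable(repository, rows)


def write_evidence_table(table: EvidenceTable, path: str | Path) -> None:
    value_col = _EXPECTED_VALUE_COLUMN[table.repository]
    with Path(path).open("w") as fh:
        fh.write(f"peptide\t{value_col}\n")
        for peptide in sorted(table.rows):
            value = table.rows[peptide][value_col]
            if value_col == "proteotypic":
                value = "true" if value else "false"
            fh.write(f"{peptide}\t{value}\n")


def write_tsv_report(rows: Iterable[Mapping], path: str | Path) -> None:
    """Write an ordered sequence of same-keyed mappings as a TSV report.

    Floats are rendered with four decimal places; row order is preserved.
    For an empty row list with a known column set use
    :func:`write_tsv_report_with_columns` to still emit the header.
    """
    df = pd.DataFrame(list(rows), dtype=object)
    _to_tsv(df, path)


def write_tsv_report_with_columns(rows: Iterable[Mapping], columns: list[str], path: str | Path) -> None:
    """Like :func:`write_tsv_report` but with an explicit column set, so an
    empty row list still produces a header-only file."""
    df = pd.DataFrame(list(rows), columns=columns, dtype=object)
    _to_tsv(df, path)


def _to_tsv(df: pd.DataFrame, path: str | Path) -> None:
    # cell-wise float formatting: float_format= only covers float-dtype
    # columns, not floats inside mixed-type columns
    formatted = df.map(lambda v: f"{v:.4f}" if isinstance(v, float) else v)
    formatted.to_csv(path, sep="\t", index=False, lineterminator="\n")
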