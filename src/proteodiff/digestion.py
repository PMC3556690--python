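"""In silico tryptic digestion of sequences and whole databases.

Cleavage follows the Keil rule: trypsin cuts C-terminal of lysine (K) or
arginine (R) unless the next residue is proline (P).  Missed cleavages are
modelled by concatenating up to ``missed_cleavages + 1`` consecutive fully
cleaved fragments.  Ambiguity codes (B, J, O, U, X, Z) are ordinary residues:
they are never cleavage sites and never suppress cleavage.

All peptide coordinates are 1-based closed intervals on the parent protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import ProteinRecord, SequenceDatabase

__all__ = [
    "DigestionParams",
    "PeptideOccurrence",
    "DigestSummary",
    "cleavage_sites",
    "digest",
    "digest_database",
    "redundancy_stats",
    "filter_by_length",
]


@dataclass(frozen=True)
class DigestionParams:
    """Parameters of an in silico digest.

    ``min_length``/``max_length`` bound the retained peptide lengths in
    residues; ``None`` means unbounded.  The headline search-space comparison
    runs unfiltered; a ``min_length`` of 7 reproduces the "six or fewer
    residues removed" filter applied before evidence lookup.
    """

    enzyme: str = "trypsin"
    missed_cleavages: int = 0
    min_length: int | None = None
    max_length: int | None = None

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        for bound in (self.min_length, self.max_length):
            if bound is not None and bound < 1:
                raise ValueError("length bounds must be positive")
        if (
            self.min_length is not None
            and self.max_length is not None
            and self.min_length > self.max_length
        ):
            raise ValueError("min_length must not exceed max_length")


@dataclass(frozen=True)
class PeptideOccurrence:
    """One peptide at a definite position of its parent protein."""

    protein_accession: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    sequence: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid coordinates [{self.start}, {self.end}]")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinate span does not match peptide length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DigestSummary:
    """Digest of a whole database: totals, the distinct peptide set, and a
    per-protein occurrence index."""

    params: DigestionParams
    total_count: int
    distinct: set[str]
    occurrences: dict[str, list[PeptideOccurrence]]


def cleavage_sites(sequence: str) -> list[int]:
    """Return 1-based positions i such that trypsin cuts between residues
    i and i+1 (residue i is K/R, residue i+1 exists and is not P)."""
    if not sequence:
        raise ValueError("empty sequence")
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in "KR" and sequence[i] != "P"
    ]


def digest(record: ProteinRecord, params: DigestionParams) -> list[PeptideOccurrence]:
    """Digest one protein into peptide occurrences, ordered by (start, end).

    Fragments are the substrings between consecutive cleavage sites (plus the
    termini); each run of 1..missed_cleavages+1 consecutive fragments yields
    one peptide.  Length bounds are applied last.
    """
    seq = record.sequence
    cuts = cleavage_sites(seq)
    # fragment boundaries as 0-based half-open [b[i], b[i+1])
    bounds = [0] + cuts + [len(seq)]
    n_frag = len(bounds) - 1
    out: list[PeptideOccurrence] = []
    for i in range(n_frag):
        for j in range(i, min(i + params.missed_cleavages + 1, n_frag)):
            start0, end0 = bounds[i], bounds[j + 1]
            length = end0 - start0
            if params.min_length is not None and length < params.min_length:
                continue
            if params.max_length is not None and length > params.max_length:
                continue
            out.append(
                PeptideOccurrence(record.accession, start0 + 1, end0, seq[start0:end0])
            )
    out.sort(key=lambda occ: (occ.start, occ.end))
    return out


def digest_database(db: SequenceDatabase, params: DigestionParams) -> DigestSummary:
    """Digest every record of a database and tally total and distinct peptides."""
    if len(db) == 0:
        raise ValueError("cannot digest an empty database")
    occurrences: dict[str, list[PeptideOccurrence]] = {}
    distinct: set[str] = set()
    total = 0
    for rec in db:
        try:
            occs = digest(rec, params)
        except ValueError as exc:
            raise ValueError(f"record {rec.accession!r}: {exc}") from exc
        occurrences[rec.accession] = occs
        total += len(occs)
        distinct.update(occ.sequence for occ in occs)
    return DigestSummary(params, total, distinct, occurrences)


def redundancy_stats(summary: DigestSummary) -> float:
    """Distinct-to-total peptide ratio of a digest, in (0, 1]."""
    if summary.total_count == 0:
        raise ValueError("digest produced no peptides")
    return len(summary.distinct) / summary.total_count


def filter_by_length(peptides: Iterable[str], min_length: int) -> set[str]:
    """Keep peptides of at least ``min_length`` residues (7 removes the
    peptides of six or fewer residues that standard MS pipelines miss)."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    return {p for p in peptides if len(p) >= min_length}


def peptide_to_proteins(summary: DigestSummary) -> dict[str, set[str]]:
    """Invert a digest's occurrence index: peptide -> parent accessions."""
    parents: dict[str, set[str]] = {}
    for acc, occs in summary.occurrences.items():
        for occ in occs:
            parents.setdefault(occ.sequence, set()).add(acc)
    return parents
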