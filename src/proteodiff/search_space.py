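"""Search-space comparison and per-protein detectability.

The theoretical search space of a database is the set of distinct tryptic
peptides its digest produces.  A *lost* peptide is present in the source
digest but absent from the target digest.  For every protein carrying lost
peptides, the remaining detectable sequence is the fraction of its residues
still covered by qualifying peptides (length >= a detectability bound,
default 7) that survive in the target search space.
"""

from __future__ import annotations

from dataclasses import dataclass

from .digestion import DigestionParams, DigestSummary, PeptideOccurrence
from .io_formats import ProteinRecord, SequenceDatabase

__all__ = [
    "SearchSpaceComparison",
    "DetectabilityRecord",
    "DetectabilityReport",
    "lost_peptides",
    "compare_search_space",
    "protein_detectability",
    "detectability_report",
]


@dataclass
class SearchSpaceComparison:
    source_total: int
    source_distinct_count: int
    target_total: int
    target_distinct_count: int
    lost: set[str]
    lost_fraction: float


@dataclass(frozen=True)
class DetectabilityRecord:
    protein_accession: str
    protein_length: int
    detectable_residues: int
    fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.detectable_residues <= self.protein_length:
            raise ValueError("detectable_residues out of range")


@dataclass(frozen=True)
class DetectabilityReport:
    """Tallies over proteins affected by lost peptides: how many retain at
    most 50% / 10% / none of their detectable sequence."""

    affected_count: int
    count_le_50pct: int
    count_le_10pct: int
    count_zero: int

    def __post_init__(self) -> None:
        if not (
            self.count_zero <= self.count_le_10pct <= self.count_le_50pct <= self.affected_count
        ):
            raise ValueError("threshold counts must be nested")


def lost_peptides(source_distinct: set[str], target_distinct: set[str]) -> set[str]:
    """Distinct source peptides absent from the target search space."""
    return source_distinct - target_distinct


def compare_search_space(
    source_summary: DigestSummary, target_summary: DigestSummary
) -> SearchSpaceComparison:
    """Compare two digests produced under identical parameters."""
    if source_summary.params != target_summary.params:
        raise ValueError(
            "digestion parameter mismatch: "
            f"{source_summary.params} vs {target_summary.params}"
        )
    lost = lost_peptides(source_summary.distinct, target_summary.distinct)
    n_source = len(source_summary.distinct)
    return SearchSpaceComparison(
        source_total=source_summary.total_count,
        source_distinct_count=n_source,
        target_total=target_summary.total_count,
        target_distinct_count=len(target_summary.distinct),
        lost=lost,
        lost_fraction=len(lost) / n_source,
    )


def _qualifying(occs: list[PeptideOccurrence], detect_params: DigestionParams):
    min_len = detect_params.min_length or 1
    return (occ for occ in occs if len(occ) >= min_len)


def protein_detectability(
    record: ProteinRecord,
    occurrences: list[PeptideOccurrence],
    target_distinct: set[str],
    detect_params: DigestionParams,
) -> DetectabilityRecord:
    """Remaining detectable sequence of one protein.

    Detectable residues are the union of positions covered by qualifying
    peptides (length >= detect_params.min_length) whose sequence survives in
    the target search space; the union handles overlapping peptides when
    missed cleavages are allowed.
    """
    for occ in occurrences:
        if occ.protein_accession != record.accession:
            raise ValueError(
                f"occurrence of {occ.protein_accession!r} passed with record "
                f"{record.accession!r}"
            )
    covered: set[int] = set()
    for occ in _qualifying(occurrences, detect_params):
        if occ.sequence in target_distinct:
            covered.update(range(occ.start, occ.end + 1))
    n = len(covered)
    return DetectabilityRecord(record.accession, len(record), n, n / len(record))


def detectability_report(
    db: SequenceDatabase,
    summary: DigestSummary,
    target_distinct: set[str],
    detect_params: DigestionParams,
) -> tuple[DetectabilityReport, list[DetectabilityRecord]]:
    """Detectability tallies plus the per-protein records of affected proteins.

    A protein is *affected* when at least one of its qualifying peptides is
    absent from the target search space; it counts as not represented at all
    (``count_zero``) when its detectable fraction is exactly 0.
    """
    affected: list[DetectabilityRecord] = []
    for rec in db:
        occs = summary.occurrences.get(rec.accession, [])
        if any(occ.sequence not in target_distinct for occ in _qualifying(occs, detect_params)):
            affected.append(protein_detectability(rec, occs, target_distinct, detect_params))
    report = DetectabilityReport(
        affected_count=len(affected),
        count_le_50pct=sum(1 for r in affected if r.fraction <= 0.5),
        count_le_10pct=sum(1 for r in affected if r.fraction <= 0.1),
        count_zero=sum(1 for r in affected if r.detectable_residues == 0),
    )
    return report, affected
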