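"""Repository evidence for lost peptides and inclusion decisions.

PeptideAtlas and GPMDB report only proteotypic peptides, so presence there is
a proteotypic flag; PRIDE reports submissions as-is, so presence is having
been identified in at least one experiment.  The inclusion rule accepts a
peptide when it is proteotypic in PeptideAtlas or GPMDB, or was identified in
at least ``pride_min_experiments`` (default 5) distinct PRIDE experiments —
two deliberately different PRIDE thresholds (>=1 for presence, >=5 for
inclusion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io_formats import EvidenceTable

__all__ = [
    "VENN_REGIONS",
    "EvidenceRecord",
    "VennPartition",
    "InclusionCriteria",
    "annotate_evidence",
    "venn_partition",
    "inclusion_candidates",
]

#: The 8 disjoint regions of the three-repository Venn diagram.
VENN_REGIONS = (
    "none",
    "peptideatlas",
    "gpmdb",
    "pride",
    "peptideatlas+gpmdb",
    "peptideatlas+pride",
    "gpmdb+pride",
    "peptideatlas+gpmdb+pride",
)


@dataclass(frozen=True)
class EvidenceRecord:
    peptide: str
    proteotypic_peptideatlas: bool
    proteotypic_gpmdb: bool
    pride_experiment_count: int

    def __post_init__(self) -> None:
        if self.pride_experiment_count < 0:
            raise ValueError("pride_experiment_count must be >= 0")

    def venn_region(self) -> str:
        parts = []
        if self.proteotypic_peptideatlas:
            parts.append("peptideatlas")
        if self.proteotypic_gpmdb:
            parts.append("gpmdb")
        if self.pride_experiment_count >= 1:
            parts.append("pride")
        return "+".join(parts) if parts else "none"


@dataclass
class VennPartition:
    counts: dict[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(VENN_REGIONS)
        if unknown:
            raise ValueError(f"unknown Venn regions {sorted(unknown)}")
        self.counts = {region: self.counts.get(region, 0) for region in VENN_REGIONS}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class InclusionCriteria:
    accept_peptideatlas_proteotypic: bool = True
    accept_gpmdb_proteotypic: bool = True
    pride_min_experiments: int = 5

    def __post_init__(self) -> None:
        if self.pride_min_experiments < 1:
            raise ValueError("pride_min_experiments must be >= 1")

    def accepts(self, record: EvidenceRecord) -> bool:
        return (
            (self.accept_peptideatlas_proteotypic and record.proteotypic_peptideatlas)
            or (self.accept_gpmdb_proteotypic and record.proteotypic_gpmdb)
            or record.pride_experiment_count >= self.pride_min_experiments
        )


MIN_EVIDENCE_PEPTIDE_LENGTH = 7


def annotate_evidence(
    lost_filtered: set[str], tables: Mapping[str, EvidenceTable]
) -> list[EvidenceRecord]:
    """Annotate each length-filtered lost peptide with its repository evidence.

    Missing tables or rows mean "no evidence" (flags false, count 0), never an
    error; snapshots are inherently partial.  Output is sorted by peptide.
    """
    short = [p for p in lost_filtered if len(p) < MIN_EVIDENCE_PEPTIDE_LENGTH]
    if short:
        raise ValueError(
            f"peptides shorter than {MIN_EVIDENCE_PEPTIDE_LENGTH} residues must be "
            f"filtered before evidence lookup (e.g. {sorted(short)[0]!r})"
        )
    pa = tables.get("peptideatlas")
    gp = tables.get("gpmdb")
    pr = tables.get("pride")
    return [
        EvidenceRecord(
            peptide=p,
            proteotypic_peptideatlas=pa.proteotypic(p) if pa else False,
            proteotypic_gpmdb=gp.proteotypic(p) if gp else False,
            pride_experiment_count=pr.experiment_count(p) if pr else 0,
        )
        for p in sorted(lost_filtered)
    ]


def venn_partition(records: list[EvidenceRecord]) -> VennPartition:
    """Assign every peptide to exactly one of the 8 repository-presence regions."""
    counts = {region: 0 for region in VENN_REGIONS}
    for rec in records:
        counts[rec.venn_region()] += 1
    return VennPartition(counts)


def inclusion_candidates(
    records: list[EvidenceRecord],
    criteria: InclusionCriteria,
    peptide_to_proteins: Mapping[str, set[str]],
) -> tuple[set[str], set[str]]:
    """Peptides meeting the inclusion criteria and the proteins they affect."""
    candidates: set[str] = set()
    proteins: set[str] = set()
    for rec in records:
        if criteria.accepts(rec):
            parents = peptide_to_proteins.get(rec.peptide)
            if not parents:
                raise ValueError(
                    f"candidate peptide {rec.peptide!r} has no parent proteins"
                )
            candidates.add(rec.peptide)
            proteins.update(parents)
    return candidates, proteins
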