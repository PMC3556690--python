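"""Identifier mapping between a source and a target protein database.

Two algorithms classify every source identifier as *mapped* (exactly one
target), *multiple* (two or more), or *none*:

* **logical** — follow the cross-references embedded in the source entry.
  Only the SWISS-PROT and TREMBL namespaces can name a UniProtKB accession;
  isoform suffixes (``-N``) are stripped so several isoforms of one parent
  count as a single candidate.
* **sequence** — PICR-style mapping on 100% sequence identity: the source
  sequence must be character-identical to the full target sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import ProteinRecord, SequenceDatabase

__all__ = [
    "ALGORITHMS",
    "STATUSES",
    "MappingOutcome",
    "MappingSummary",
    "MappingConfig",
    "build_sequence_index",
    "sequence_map",
    "logical_map",
    "map_database",
    "summarize_mapping",
]

ALGORITHMS = ("logical", "sequence")
STATUSES = ("mapped", "multiple", "none")

_ISOFORM_RE = re.compile(r"-\d+$")


@dataclass(frozen=True)
class MappingOutcome:
    source_accession: str
    algorithm: str
    status: str
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        expected = "none" if not self.targets else ("mapped" if len(self.targets) == 1 else "multiple")
        if self.status != expected:
            raise ValueError(
                f"status {self.status!r} inconsistent with {len(self.targets)} targets"
            )


def _outcome(source: str, algorithm: str, targets: Iterable[str]) -> MappingOutcome:
    targets = tuple(sorted(set(targets)))
    status = "none" if not targets else ("mapped" if len(targets) == 1 else "multiple")
    return MappingOutcome(source, algorithm, status, targets)


@dataclass
class MappingSummary:
    """Per-status counts and fractions for one algorithm over one database."""

    algorithm: str
    counts: dict[str, int]
    fractions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total == 0:
            raise ValueError("empty outcome list")
        self.fractions = {s: self.counts[s] / total for s in STATUSES}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MappingConfig:
    """Which xref namespaces the logical algorithm may follow."""

    xref_namespaces: tuple[str, ...] = ("SWISS-PROT", "TREMBL")
    strip_isoform_suffix: bool = True


@dataclass
class SequenceIndex:
    """Exact-sequence index over the target database: sequence -> sorted
    accessions carrying exactly that sequence."""

    by_sequence: dict[str, list[str]]

    def lookup(self, sequence: str) -> list[str]:
        return self.by_sequence.get(sequence, [])


def build_sequence_index(target: SequenceDatabase) -> SequenceIndex:
    if len(target) == 0:
        raise ValueError("cannot index an empty database")
    by_seq: dict[str, list[str]] = {}
    for rec in target:
        by_seq.setdefault(rec.sequence, []).append(rec.accession)
    for accs in by_seq.values():
        accs.sort()
    return SequenceIndex(by_seq)


def sequence_map(record: ProteinRecord, index: SequenceIndex) -> MappingOutcome:
    """Map one source record by full-length exact sequence identity."""
    return _outcome(record.accession, "sequence", index.lookup(record.sequence))


def logical_map(
    record: ProteinRecord,
    target: SequenceDatabase,
    config: MappingConfig = MappingConfig(),
) -> MappingOutcome:
    """Map one source record via its embedded cross-references.

    Candidates are the xref accessions under the configured namespaces,
    isoform suffixes stripped and deduplicated, intersected with the target's
    accession universe.
    """
    candidates: set[str] = set()
    for namespace in config.xref_namespaces:
        for acc in record.xrefs.get(namespace, []):
            if config.strip_isoform_suffix:
                acc = _ISOFORM_RE.sub("", acc)
            candidates.add(acc)
    return _outcome(record.accession, "logical", (a for a in candidates if a in target))


def map_database(
    source: SequenceDatabase,
    target: SequenceDatabase,
    algorithm: str,
    config: MappingConfig = MappingConfig(),
) -> list[MappingOutcome]:
    """Classify every source record under one algorithm, in source order."""
    if algorithm == "sequence":
        index = build_sequence_index(target)
        return [sequence_map(rec, index) for rec in source]
    if algorithm == "logical":
        return [logical_map(rec, target, config) for rec in source]
    raise ValueError(f"unknown algorithm {algorithm!r}")


def summarize_mapping(outcomes: list[MappingOutcome]) -> MappingSummary:
    """Tally status counts and fractions for a single-algorithm outcome list."""
    if not outcomes:
        raise ValueError("empty outcome list")
    algorithms = {o.algorithm for o in outcomes}
    if len(algorithms) > 1:
        raise ValueError(f"mixed algorithms in one summary: {sorted(algorithms)}")
    counts = {s: 0 for s in STATUSES}
    for o in outcomes:
        counts[o.status] += 1
    return MappingSummary(algorithms.pop(), counts)
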