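"""End-to-end pipeline chaining all stages into one report bundle.

The bundle is a directory of deterministic TSV reports:

* ``mapping_summary.tsv`` — per-algorithm, per-status counts and fractions;
* ``search_space.tsv`` — one row per search-space metric;
* ``detectability.tsv`` — per affected protein: length, detectable residues,
  fraction;
* ``venn.tsv`` and ``candidates.tsv`` — only when evidence tables are given;
* ``summary.tsv`` — every headline statistic in one key/value table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import digestion, evidence, io_formats, mapping, search_space

logger = logging.getLogger("proteodiff")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    source_path: Path
    target_path: Path
    out_dir: Path
    source_dialect: str = "ipi"
    target_dialect: str = "uniprot"
    missed_cleavages: int = 0
    min_peptide_length: int | None = None  # headline comparison is unfiltered
    detect_min_length: int = 7
    evidence_min_length: int = 7
    mapping_config: mapping.MappingConfig = field(default_factory=mapping.MappingConfig)
    criteria: evidence.InclusionCriteria = field(default_factory=evidence.InclusionCriteria)
    evidence_paths: dict[str, Path] = field(default_factory=dict)

    def digestion_params(self) -> digestion.DigestionParams:
        return digestion.DigestionParams(
            missed_cleavages=self.missed_cleavages, min_length=self.min_peptide_length
        )


@dataclass
class PipelineResult:
    """In-memory results of one run (everything the bundle serialises)."""

    mapping_summaries: dict[str, mapping.MappingSummary]
    comparison: search_space.SearchSpaceComparison
    detect_report: search_space.DetectabilityReport
    detect_records: list[search_space.DetectabilityRecord]
    source_redundancy: float
    target_redundancy: float
    lost_filtered_count: int | None = None
    venn: evidence.VennPartition | None = None
    candidate_peptides: set[str] | None = None
    candidate_proteins: set[str] | None = None


def _write_mapping_summary(summaries: dict[str, mapping.MappingSummary], path: Path) -> None:
    rows = [
        {
            "algorithm": algo,
            "status": status,
            "count": summary.counts[status],
            "fraction": summary.fractions[status],
        }
        for algo, summary in summaries.items()
        for status in mapping.STATUSES
    ]
    io_formats.write_tsv_report(rows, path)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run mapping, search-space, detectability and (optionally) evidence
    analysis, writing the TSV bundle to ``config.out_dir``."""
    for p in (config.source_path, config.target_path, *config.evidence_paths.values()):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("reading source %s (%s dialect)", config.source_path, config.source_dialect)
    source = io_formats.read_fasta(config.source_path, config.source_dialect)
    logger.info("source: %d records", len(source))
    target = io_formats.read_fasta(config.target_path, config.target_dialect)
    logger.info("target: %d records", len(target))

    summaries: dict[str, mapping.MappingSummary] = {}
    for algo in mapping.ALGORITHMS:
        outcomes = mapping.map_database(source, target, algo, config.mapping_config)
        summaries[algo] = mapping.summarize_mapping(outcomes)
        logger.info("mapping/%s: %s", algo, summaries[algo].counts)
    _write_mapping_summary(summaries, out / "mapping_summary.tsv")

    params = config.digestion_params()
    src_digest = digestion.digest_database(source, params)
    tgt_digest = digestion.digest_database(target, params)
    logger.info(
        "digest: source %d total / %d distinct; target %d total / %d distinct",
        src_digest.total_count,
        len(src_digest.distinct),
        tgt_digest.total_count,
        len(tgt_digest.distinct),
    )
    comparison = search_space.compare_search_space(src_digest, tgt_digest)
    io_formats.write_tsv_report(
        [
            {"metric": "source_total_peptides", "value": comparison.source_total},
            {"metric": "source_distinct_peptides", "value": comparison.source_distinct_count},
            {"metric": "target_total_peptides", "value": comparison.target_total},
            {"metric": "target_distinct_peptides", "value": comparison.target_distinct_count},
            {"metric": "lost_peptides", "value": len(comparison.lost)},
            {"metric": "lost_fraction", "value": comparison.lost_fraction},
        ],
        out / "search_space.tsv",
    )

    detect_params = digestion.DigestionParams(
        missed_cleavages=config.missed_cleavages, min_length=config.detect_min_length
    )
    report, records = search_space.detectability_report(
        source, src_digest, tgt_digest.distinct, detect_params
    )
    records = sorted(records, key=lambda r: r.protein_accession)
    io_formats.write_tsv_report_with_columns(
        [
            {
                "accession": r.protein_accession,
                "length": r.protein_length,
                "detectable_residues": r.detectable_residues,
                "fraction": r.fraction,
            }
            for r in records
        ],
        ["accession", "length", "detectable_residues", "fraction"],
        out / "detectability.tsv",
    )

    result = PipelineResult(
        mapping_summaries=summaries,
        comparison=comparison,
        detect_report=report,
        detect_records=records,
        source_redundancy=digestion.redundancy_stats(src_digest),
        target_redundancy=digestion.redundancy_stats(tgt_digest),
    )

    if config.evidence_paths:
        tables = {
            repo: io_formats.read_evidence_table(path, repo)
            for repo, path in config.evidence_paths.items()
        }
        lost_filtered = digestion.filter_by_length(comparison.lost, config.evidence_min_length)
        result.lost_filtered_count = len(lost_filtered)
        logger.info(
            "evidence: %d of %d lost peptides retained after length filter",
            len(lost_filtered),
            len(comparison.lost),
        )
        ev_records = evidence.annotate_evidence(lost_filtered, tables)
        result.venn = evidence.venn_partition(ev_records)
        io_formats.write_tsv_report(
            [{"region": region, "count": result.venn.counts[region]} for region in evidence.VENN_REGIONS],
            out / "venn.tsv",
        )
        parents = digestion.peptide_to_proteins(src_digest)
        candidates, proteins = evidence.inclusion_candidates(ev_records, config.criteria, parents)
        result.candidate_peptides = candidates
        result.candidate_proteins = proteins
        by_record = {r.peptide: r for r in ev_records}
        io_formats.write_tsv_report_with_columns(
            [
                {
                    "peptide": p,
                    "reason": _reason(by_record[p], config.criteria),
                    "proteins": ";".join(sorted(parents[p])),
                }
                for p in sorted(candidates)
            ],
            ["peptide", "reason", "proteins"],
            out / "candidates.tsv",
        )

    _write_summary(result, out / "summary.tsv")
    logger.info("bundle written to %s", out)
    return result


def _reason(record: evidence.EvidenceRecord, criteria: evidence.InclusionCriteria) -> str:
    reasons = []
    if criteria.accept_peptideatlas_proteotypic and record.proteotypic_peptideatlas:
        reasons.append("peptideatlas_proteotypic")
    if criteria.accept_gpmdb_proteotypic and record.proteotypic_gpmdb:
        reasons.append("gpmdb_proteotypic")
    if record.pride_experiment_count >= criteria.pride_min_experiments:
        reasons.append(f"pride>={criteria.pride_min_experiments}")
    return ";".join(reasons)


def _write_summary(result: PipelineResult, path: Path) -> None:
    rows = []
    for algo, summary in result.mapping_summaries.items():
        for status in mapping.STATUSES:
            rows.append(
                {"statistic": f"mapping_{algo}_{status}_fraction", "value": summary.fractions[status]}
            )
    comp = result.comparison
    rows += [
        {"statistic": "source_distinct_peptides", "value": comp.source_distinct_count},
        {"statistic": "target_distinct_peptides", "value": comp.target_distinct_count},
        {"statistic": "lost_peptides", "value": len(comp.lost)},
        {"statistic": "lost_fraction", "value": comp.lost_fraction},
        {"statistic": "source_redundancy", "value": result.source_redundancy},
        {"statistic": "target_redundancy", "value": result.target_redundancy},
        {"statistic": "affected_proteins", "value": result.detect_report.affected_count},
        {"statistic": "proteins_le_50pct_detectable", "value": result.detect_report.count_le_50pct},
        {"statistic": "proteins_le_10pct_detectable", "value": result.detect_report.count_le_10pct},
        {"statistic": "proteins_not_represented", "value": result.detect_report.count_zero},
    ]
    if result.venn is not None:
        rows.append({"statistic": "lost_filtered_peptides", "value": result.lost_filtered_count})
        rows.append(
            {
                "statistic": "venn_all_three",
                "value": result.venn.counts["peptideatlas+gpmdb+pride"],
            }
        )
        rows.append({"statistic": "candidate_peptides", "value": len(result.candidate_peptides)})
        rows.append({"statistic": "candidate_proteins", "value": len(result.candidate_proteins)})
    io_formats.write_tsv_report(rows, path)
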