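"""Synthetic paired databases and evidence tables with planted ground truth.

The generator emulates a source database in IPI dialect and a target database
in UniProtKB dialect with controlled structure, so every pipeline stage can be
tested without downloading archived releases:

* *shared* proteins — identical sequence in both databases, correct
  SWISS-PROT cross-reference (every third one with an isoform suffix);
* *lost-only* proteins — present only in the source, with non-UniProtKB
  cross-references, guaranteed to carry at least one qualifying (>= 7
  residue) tryptic fragment absent from the target;
* *mutated-shared* proteins — the target carries a copy with one point
  substitution inside a single qualifying fragment, creating partial peptide
  loss with an analytically known remaining-detectable fraction;
* *multi-xref* proteins — cross-reference two valid target accessions,
  forcing a logical "multiple";
* *bad-xref* proteins — cross-reference absent accessions (sequence present
  in the target), forcing a logical "none";
* *duplicate-sequence pairs* — two target accessions share one sequence,
  forcing a sequence-identity "multiple".

Every planted expectation is recorded in a :class:`TruthManifest`.
Amino-acid composition is uniform apart from K/R at ~5% each (so tryptic
fragments average ~10 residues) and P at 3%; no other feature of real
proteomes is imitated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .digestion import cleavage_sites
from .evidence import InclusionCriteria
from .io_formats import EvidenceTable, ProteinRecord, SequenceDatabase

__all__ = [
    "SyntheticConfig",
    "TruthManifest",
    "generate_protein_sequence",
    "generate_pair",
    "generate_evidence",
    "write_manifest",
]

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# K and R at 5% each give ~10% cleavage-site frequency; P kept low so Keil
# suppression is present but rare; the remaining 17 residues share the rest.
_WEIGHTS = np.full(len(_ALPHABET), 0.87 / 17)
for _res, _w in (("K", 0.05), ("R", 0.05), ("P", 0.03)):
    _WEIGHTS[list(_ALPHABET).index(_res)] = _w

MIN_PROTEIN_LENGTH = 20
_QUALIFYING_LENGTH = 7  # detectability / evidence length bound


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic database pair.

    Defaults are proportioned like the human transition the pipeline targets:
    roughly 69% of source identifiers logically mapped, 8% multiple, 23%
    unmapped, with the sequence-identity algorithm losing slightly more than
    the logical one; evidence is sparse (a few percent of lost peptides have
    any repository record).
    """

    n_shared: int = 330
    n_lost: int = 90
    n_target_only: int = 50
    n_duplicate_sequence_pairs: int = 10
    n_multi_xref: int = 40
    n_bad_xref: int = 30
    n_mutated_shared: int = 20
    protein_length_range: tuple[int, int] = (80, 400)
    evidence_fractions: tuple[float, float] = (0.02, 0.025)  # (pa, gpmdb) proteotypic
    pride_nonzero_fraction: float = 0.05
    pride_count_range: tuple[int, int] = (1, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_shared",
            "n_lost",
            "n_target_only",
            "n_duplicate_sequence_pairs",
            "n_multi_xref",
            "n_bad_xref",
            "n_mutated_shared",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.protein_length_range
        if lo < MIN_PROTEIN_LENGTH or hi < lo:
            raise ValueError(
                f"protein_length_range must satisfy {MIN_PROTEIN_LENGTH} <= min <= max"
            )
        for f in (*self.evidence_fractions, self.pride_nonzero_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("evidence fractions must lie in [0, 1]")
        clo, chi = self.pride_count_range
        if clo < 0 or chi < clo:
            raise ValueError("pride_count_range must satisfy 0 <= min <= max")


@dataclass
class TruthManifest:
    """Planted expectations for one generated pair."""

    seed: int
    mapping_counts: dict[tuple[str, str], int]
    lost_only_accessions: list[str]
    mutated_accessions: list[str]
    mutated_fractions: dict[str, float]
    expected_lost_peptide_count: int
    expected_affected_count: int
    expected_count_le_50pct: int
    expected_count_le_10pct: int
    expected_count_zero: int
    # filled by generate_evidence
    expected_venn: dict[str, int] | None = None
    expected_candidates: set[str] | None = None


def generate_protein_sequence(rng: np.random.Generator, length: int) -> str:
    """One random protein sequence over the 20 standard residues."""
    if length < MIN_PROTEIN_LENGTH:
        raise ValueError(f"length must be >= {MIN_PROTEIN_LENGTH}, got {length}")
    return "".join(rng.choice(_ALPHABET, size=length, p=_WEIGHTS))


def _fragments(seq: str) -> list[str]:
    """Fully cleaved (mc=0) tryptic fragments of a sequence."""
    bounds = [0] + cleavage_sites(seq) + [len(seq)]
    return [seq[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]


def _draw_unique(rng: np.random.Generator, config: SyntheticConfig, used: set[str]) -> str:
    lo, hi = config.protein_length_range
    while True:
        seq = generate_protein_sequence(rng, int(rng.integers(lo, hi + 1)))
        if seq not in used:
            used.add(seq)
            return seq


def generate_pair(
    config: SyntheticConfig,
) -> tuple[SequenceDatabase, SequenceDatabase, TruthManifest]:
    """Generate a (source, target, manifest) triple with planted structure."""
    if config.n_shared < 1:
        raise ValueError("n_shared must be >= 1")
    rng = np.random.default_rng(config.seed)
    used: set[str] = set()
    source: list[ProteinRecord] = []
    target: list[ProteinRecord] = []
    n_src = 0
    n_tgt = 0

    def src_acc() -> str:
        nonlocal n_src
        n_src += 1
        return f"IPI9{n_src:07d}"

    def tgt_acc() -> str:
        nonlocal n_tgt
        n_tgt += 1
        return f"P{n_tgt:05d}"

    def src_record(seq: str, xrefs: dict[str, list[str]]) -> ProteinRecord:
        acc = src_acc()
        return ProteinRecord(
            acc, seq, "synthetic source protein", version=1, xrefs=xrefs, taxon=9606
        )

    def tgt_record(seq: str, reviewed: bool = True, acc: str | None = None) -> ProteinRecord:
        acc = acc or tgt_acc()
        return ProteinRecord(
            acc,
            seq,
            "synthetic target protein",
            review_status="reviewed" if reviewed else "unreviewed",
            entry_name=f"{acc}_SYN",
        )

    # shared: exact copies with a correct SWISS-PROT xref (every 3rd via isoform)
    for i in range(config.n_shared):
        seq = _draw_unique(rng, config, used)
        t = tgt_record(seq)
        xref = f"{t.accession}-1" if i % 3 == 0 else t.accession
        source.append(src_record(seq, {"SWISS-PROT": [xref]}))
        target.append(t)

    # multi-xref: sequence present in target once, but two valid xref targets
    for _ in range(config.n_multi_xref):
        seq = _draw_unique(rng, config, used)
        other = _draw_unique(rng, config, used)
        t_same = tgt_record(seq)
        t_other = tgt_record(other, reviewed=False)
        source.append(src_record(seq, {"SWISS-PROT": [t_same.accession, t_other.accession]}))
        target.extend([t_same, t_other])

    # bad-xref: sequence present in target, xref names an absent accession
    for i in range(config.n_bad_xref):
        seq = _draw_unique(rng, config, used)
        target.append(tgt_record(seq, reviewed=False))
        source.append(src_record(seq, {"SWISS-PROT": [f"ZZ{i:04d}"]}))

    # duplicate-sequence pairs: two target accessions share one sequence
    for _ in range(config.n_duplicate_sequence_pairs):
        seq = _draw_unique(rng, config, used)
        t1 = tgt_record(seq)
        t2 = tgt_record(seq, reviewed=False)
        target.extend([t1, t2])
        source.append(src_record(seq, {"SWISS-PROT": [t1.accession]}))

    # target-only
    for _ in range(config.n_target_only):
        target.append(tgt_record(_draw_unique(rng, config, used), reviewed=False))

    target_frag: set[str] = set()
    for rec in target:
        target_frag.update(_fragments(rec.sequence))

    # mutated-shared: one point substitution inside a single qualifying
    # fragment of the target copy; the substituted position is chosen so the
    # cleavage pattern is unchanged, making the remaining-detectable fraction
    # analytic: (qualifying residues - |lost fragment|) / protein length.
    mutated_accessions: list[str] = []
    mutated_fractions: dict[str, float] = {}
    non_krp = [r for r in _ALPHABET if r not in "KRP"]
    for _ in range(config.n_mutated_shared):
        while True:
            seq = _draw_unique(rng, config, used)
            frags = _fragments(seq)
            qualifying = [f for f in frags if len(f) >= _QUALIFYING_LENGTH]
            if len(qualifying) < 2:
                continue
            # candidate fragments: qualifying, unique within the protein,
            # absent from the target so their loss is unambiguous
            candidates = [
                k
                for k, f in enumerate(frags)
                if len(f) >= _QUALIFYING_LENGTH
                and frags.count(f) == 1
                and f not in target_frag
            ]
            if not candidates:
                continue
            k = candidates[int(rng.integers(len(candidates)))]
            frag = frags[k]
            frag_start = sum(len(f) for f in frags[:k])
            # interior, non-K/R/P position: substitution cannot create or
            # remove a cleavage site
            positions = [
                p for p in range(1, len(frag) - 1) if frag[p] not in "KRP"
            ]
            if not positions:
                continue
            p = positions[int(rng.integers(len(positions)))]
            replacement = rng.choice([r for r in non_krp if r != frag[p]])
            pos = frag_start + p
            mutated = seq[:pos] + replacement + seq[pos + 1 :]
            if mutated in used:
                continue
            used.add(mutated)
            break
        t = tgt_record(mutated)
        rec = src_record(seq, {"SWISS-PROT": [t.accession]})
        source.append(rec)
        target.append(t)
        target_frag.update(_fragments(mutated))
        mutated_accessions.append(rec.accession)
        q_residues = sum(len(f) for f in _fragments(seq) if len(f) >= _QUALIFYING_LENGTH)
        mutated_fractions[rec.accession] = (q_residues - len(frag)) / len(seq)

    # lost-only: every qualifying fragment absent from the target, so the
    # detectable fraction is exactly 0
    lost_accessions: list[str] = []
    for _ in range(config.n_lost):
        while True:
            seq = _draw_unique(rng, config, used)
            qualifying = [f for f in _fragments(seq) if len(f) >= _QUALIFYING_LENGTH]
            if qualifying and all(f not in target_frag for f in qualifying):
                break
            used.discard(seq)
        rec = src_record(seq, {"ENSEMBL": [f"ENSP{n_src:08d}"]})
        source.append(rec)
        lost_accessions.append(rec.accession)

    source_frag: set[str] = set()
    for rec in source:
        source_frag.update(_fragments(rec.sequence))
    expected_lost = len(source_frag - target_frag)

    n_mut = config.n_mutated_shared
    mapping_counts = {
        ("logical", "mapped"): config.n_shared + n_mut + config.n_duplicate_sequence_pairs,
        ("logical", "multiple"): config.n_multi_xref,
        ("logical", "none"): config.n_lost + config.n_bad_xref,
        ("sequence", "mapped"): config.n_shared + config.n_multi_xref + config.n_bad_xref,
        ("sequence", "multiple"): config.n_duplicate_sequence_pairs,
        ("sequence", "none"): config.n_lost + n_mut,
    }
    fractions = list(mutated_fractions.values())
    manifest = TruthManifest(
        seed=config.seed,
        mapping_counts=mapping_counts,
        lost_only_accessions=lost_accessions,
        mutated_accessions=mutated_accessions,
        mutated_fractions=mutated_fractions,
        expected_lost_peptide_count=expected_lost,
        expected_affected_count=config.n_lost + n_mut,
        expected_count_le_50pct=config.n_lost + sum(1 for f in fractions if f <= 0.5),
        expected_count_le_10pct=config.n_lost + sum(1 for f in fractions if f <= 0.1),
        expected_count_zero=config.n_lost,
    )
    source_db = SequenceDatabase("synthetic-source", f"seed{config.seed}", source)
    target_db = SequenceDatabase("synthetic-target", f"seed{config.seed}", target)
    return source_db, target_db, manifest


def generate_evidence(
    lost_filtered: set[str],
    config: SyntheticConfig,
    manifest: TruthManifest | None = None,
) -> dict[str, EvidenceTable]:
    """Assign repository evidence to length-filtered lost peptides.

    Proteotypic flags are Bernoulli draws at the configured fractions; a PRIDE
    experiment count is drawn uniformly from ``pride_count_range`` for the
    ``pride_nonzero_fraction`` of peptides that have any PRIDE record.  When a
    manifest is given, the expected Venn region counts and the inclusion
    candidates under the default criteria are recorded into it.
    """
    rng = np.random.default_rng(config.seed + 1)
    pa_frac, gp_frac = config.evidence_fractions
    clo, chi = config.pride_count_range
    criteria = InclusionCriteria()
    pa_rows: dict[str, dict] = {}
    gp_rows: dict[str, dict] = {}
    pr_rows: dict[str, dict] = {}
    venn = {
        "none": 0,
        "peptideatlas": 0,
        "gpmdb": 0,
        "pride": 0,
        "peptideatlas+gpmdb": 0,
        "peptideatlas+pride": 0,
        "gpmdb+pride": 0,
        "peptideatlas+gpmdb+pride": 0,
    }
    candidates: set[str] = set()
    for peptide in sorted(lost_filtered):
        pa = bool(rng.random() < pa_frac)
        gp = bool(rng.random() < gp_frac)
        count = 0
        if rng.random() < config.pride_nonzero_fraction:
            count = int(rng.integers(clo, chi + 1))
        if pa:
            pa_rows[peptide] = {"proteotypic": True}
        if gp:
            gp_rows[peptide] = {"proteotypic": True}
        if count > 0:
            pr_rows[peptide] = {"experiment_count": count}
        parts = [name for flag, name in ((pa, "peptideatlas"), (gp, "gpmdb"), (count >= 1, "pride")) if flag]
        venn["+".join(parts) if parts else "none"] += 1
        if pa or gp or count >= criteria.pride_min_experiments:
            candidates.add(peptide)
    if manifest is not None:
        manifest.expected_venn = venn
        manifest.expected_candidates = candidates
    return {
        "peptideatlas": EvidenceTable("peptideatlas", pa_rows),
        "gpmdb": EvidenceTable("gpmdb", gp_rows),
        "pride": EvidenceTable("pride", pr_rows),
    }


def write_manifest(manifest: TruthManifest, path: str | Path) -> None:
    """Write the manifest as a key/value TSV (human-readable ground truth)."""
    lines = ["key\tvalue"]
    lines.append(f"seed\t{manifest.seed}")
    for (algo, status), count in sorted(manifest.mapping_counts.items()):
        lines.append(f"mapping.{algo}.{status}\t{count}")
    lines.append(f"lost_only_accessions\t{';'.join(manifest.lost_only_accessions)}")
    lines.append(f"mutated_accessions\t{';'.join(manifest.mutated_accessions)}")
    for acc, frac in sorted(manifest.mutated_fractions.items()):
        lines.append(f"mutated_fraction.{acc}\t{frac:.4f}")
    lines.append(f"expected_lost_peptide_count\t{manifest.expected_lost_peptide_count}")
    lines.append(f"expected_affected_count\t{manifest.expected_affected_count}")
    lines.append(f"expected_count_le_50pct\t{manifest.expected_count_le_50pct}")
    lines.append(f"expected_count_le_10pct\t{manifest.expected_count_le_10pct}")
    lines.append(f"expected_count_zero\t{manifest.expected_count_zero}")
    if manifest.expected_venn is not None:
        for region, count in manifest.expected_venn.items():
            lines.append(f"venn.{region}\t{count}")
    if manifest.expected_candidates is not None:
        lines.append(f"expected_candidates\t{';'.join(sorted(manifest.expected_candidates))}")
    Path(path).write_text("\n".join(lines) + "\n")
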