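# Methods

## Problem and procedure

`proteodiff` quantifies what is lost when one protein sequence database (the
*source*, IPI-style) is replaced by another (the *target*, UniProtKB-style),
on two levels.

**Identifier level.** Every source record is classified against the target by
two algorithms. *Logical* mapping collects the cross-referenced accessions
stored on the source entry under the SWISS-PROT and TREMBL namespaces — the
only namespaces that can name a UniProtKB accession — strips isoform suffixes
(`-N`), deduplicates, and intersects with the target's accession universe.
*Sequence* mapping indexes the target by exact full-length sequence and looks
the source sequence up; it guarantees that a mapped identifier denotes the
same protein sequence. Both yield `mapped` (|targets| = 1), `multiple`
(≥ 2), or `none` (0); the three counts partition the source database.

**Peptide level.** Both databases are digested in silico and the distinct
peptide sets compared. Lost peptides are the set difference source minus
target; the lost fraction is reported relative to the distinct source set.
Per-protein detectability is the fraction of residues covered by the union of
positions of *qualifying* peptides (length ≥ the detectability bound) whose
sequence is still present in the target's distinct set; with 0 missed
cleavages peptides never overlap and the union equals the sum of retained
fragment lengths. Evidence annotation joins the length-filtered lost peptides
against three repository snapshots and applies the inclusion rule
(proteotypic in PeptideAtlas or GPMDB, or ≥ `pride_min_experiments` PRIDE
experiments).

## Digestion model and assumptions

Trypsin cleaves C-terminal of K or R unless the next residue is P (Keil
rule). This community-default rule is a deliberate choice: no exceptions
beyond proline suppression are modelled (no WKP/MRP-style refinements), no
semi-tryptic peptides, no mass or modification handling. A peptide with up to
*k* missed cleavages is a concatenation of 1..*k*+1 consecutive fully cleaved
fragments. Ambiguity codes (B, J, O, U, X, Z) are ordinary residues: never a
cleavage site, never suppressing one — only K, R and P have defined roles.
Coordinates are 1-based closed intervals; outputs are ordered by
(start, end), making every report deterministic.

Peptide identity is exact character equality throughout — no I/L folding —
because the sequence-identity mapping is defined on 100% identity and the
search-space comparison must be consistent with it.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `missed_cleavages` | 0 | fragment counting without missed-cleavage expansion; configurable for sensitivity analysis |
| `min_peptide_length` (comparison) | unbounded | the headline search-space comparison uses the raw peptide multiset |
| `detect_min_length` | 7 | a peptide of ≤ 6 residues is not reliably observable in standard MS pipelines, so only ≥ 7-residue peptides count toward detectable sequence |
| `evidence_min_length` | 7 | same bound applied before evidence lookup; the retention fraction (filtered lost / all lost) is reported |
| `pride_min_experiments` | 5 | inclusion threshold; PRIDE *presence* in the Venn partition is ≥ 1 experiment — two distinct thresholds by design |
| xref namespaces | SWISS-PROT, TREMBL | other namespaces (Ensembl, RefSeq, Vega, H-Inv) cannot name a UniProtKB entry |

The target universe for both algorithms is the supplied target FASTA, not all
of UniProtKB; supplying a larger target file changes the universe.

## Synthetic data: what it emulates and what it does not

`SyntheticConfig` defaults define the package's reference study conditions:
520 source and 530 target proteins of 80–400 residues comprising 330 shared,
90 lost-only, 20 mutated-shared, 40 multi-xref, 30 bad-xref and 10
duplicate-sequence source proteins plus 50 target-only entries. These
proportions were chosen once to resemble a realistic transition in which
roughly 69% of identifiers map logically one-to-one, ~8% multiply, ~23% not
at all, and the sequence algorithm loses slightly more than the logical one.
Evidence is sparse by default (2–2.5% proteotypic flags, 5% of peptides with
any PRIDE record, counts uniform on 1–8), mirroring the empirical situation
that the vast majority of lost peptides have no repository evidence.

Residue composition is uniform except K/R at 5% each — giving ~10% cleavage
sites and ~10-residue average tryptic fragments — and P at 3%. The generator
does **not** imitate real amino-acid composition, homology structure, isoform
sequences (only xref suffixes), or shared subsequences between unrelated
proteins. Consequently, synthetic cross-database peptide collisions occur
essentially only where planted; passing recovery tests demonstrate that the
pipeline's set arithmetic, classification and wiring are exact, not that
real-database loss percentages are reproduced. Real IPI/UniProtKB inputs are
supported through the same FASTA readers but require the archived releases.

Construction guarantees that make manifest expectations exact rather than
probabilistic: every lost-only protein is regenerated until it has at least
one qualifying (≥ 7-residue) fragment and none of its qualifying fragments
occur in the target, so its detectable fraction is exactly 0; mutated-shared
proteins receive one point substitution at an interior, non-K/R/P position of
a unique qualifying fragment (replacement also non-K/R/P), which provably
leaves the cleavage pattern unchanged and makes the expected detectable
fraction analytic: (qualifying residues − lost fragment length) / protein
length. Mapping-count expectations follow from the construction alone. The
expected lost-peptide *count* is computed at generation time from the planted
sequences' fragment sets; short (< 7 residue) fragments may legitimately
coincide across databases, and this count accounts for that.

All randomness flows from a single `numpy.random.default_rng(seed)` per
generated artifact (evidence uses `seed + 1` so tables and databases are
independent streams); identical configurations produce byte-identical files.

## Numerical and design choices

- Fractions are exact Python floats of integer ratios; reports render floats
  with 4 decimal places; TSV rows are emitted in deterministic order.
- `summarize_mapping` refuses mixed-algorithm outcome lists; fraction sums
  are exact up to float addition (tested to 1e-9).
- Degenerate inputs fail loudly: empty databases, empty sequences, duplicate
  accessions, negative experiment counts, sub-length peptides reaching the
  evidence stage, and digestion-parameter mismatches between compared digests
  are all hard errors.
- A protein counts as "not represented at all" when its detectable fraction
  is exactly 0; threshold tallies (≤ 50%, ≤ 10%, 0) are nested by
  construction.
- The detectability length bound is configurable because reasonable analyses
  may differ on it; 7 is the default for consistency with the evidence-stage
  filter.

## Problem sizes

The reference conditions (~520 proteins, ~12,000 peptides) run the full
pipeline in under a second; the acceptance script and the complete test suite
(including the 1,000-sequence digestion-oracle comparison and hypothesis
property tests) finish in a few seconds on one CPU. Digestion and set
comparison are linear in total sequence length, so full-scale databases
(~10⁵ proteins, ~4 × 10⁶ peptides) remain tractable in memory and minutes.

## Known limitations

- Only trypsin is modelled; no semi-tryptic peptides, masses, or
  modifications.
- Logical mapping uses only header-embedded cross-references; history files
  or external mapping services are out of scope.
- No fuzzy (e.g. 95%-homology) clustering: discrepancies between the two
  algorithms on real data partly reflect the source database's homology-based
  clustering, which is observed, not reimplemented.
- Repository evidence is abstracted as static TSV snapshots; reprocessing
  differences between repositories are not modelled.
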