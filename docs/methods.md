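# Methods

## Scope and data model

`gatascan` works entirely at the protein level. A dataset is a set of
protein isoform records, each carrying a unique protein id, a gene id and
a species id (FASTA `key=value` header tokens, optionally overridden by a
gene→isoform TSV), plus a species table mapping each species to one of
nine taxonomic groups (eudicots, monocots, basal angiosperm, gymnosperm,
marchantiophyta, bryophyta, lycopodiophyta, charophyta, chlorophytae), an
order (angiosperms only) and a genus. Sequences are restricted to the 20
standard residues plus X; anything else (B/Z/U/\*, lower case) is rejected
at parse time with the offending line number — loud failure over silent
remapping. All coordinates are 0-based half-open internally; 1-based
positions appear only in reports, matching the field's convention of
naming domain residues C-1 … C-26.

## Domain grammar and scanning

The class-IV zinc finger is modeled as a cysteine-spacer grammar: four
anchor cysteines with spacer1 ∈ {2, 4} residues strictly between C1–C2,
spacer2 ∈ [16, 21] between C2–C3, and exactly 2 between C3–C4. The
(spacer1, spacer2) pair maps to a type: (2,17) IVa, (2,18) IVb, (2,20)
IVc, (4,18) IV4, and (2, {16,19,21}) IVe. Two interpretation choices are
deliberate:

* **IVe** covers exactly the inner spacers in 16–21 not claimed by a named
  type. The alternative — an open-ended IVe — would shadow IVa/IVb/IVc.
* **spacer1 = 4** is legal only with spacer2 = 18, the one attested IV4
  form; (4, 20) and the like classify as nothing.

Complete candidates are enumerated over *all* cysteine quadruples
satisfying the constraints (internal cysteines inside spacers are allowed
to anchor other candidates), so the candidate set is exactly what
brute-force enumeration over C-quadruples produces; this equivalence is
asserted in tests against an independently written oracle.

**Overlap resolution** is greedy with an explicit total order: complete
before partial; then type priority IVb > IVc > IVa > IV4 > IVe > IVp
(the two dominant biological types first); then smaller start, smaller
end. A candidate is accepted iff it shares no residue with an accepted
one. This replaces the unspecified behaviour of a regex engine with a
documented, deterministic rule; the accepted set is pairwise disjoint and
byte-reproducible.

**Partial domains (IVp).** Partial motifs lack one or more anchor
cysteines, so a pure grammar match would fire on every cysteine pair.
Three truncation templates are matched, with the long spacer m restricted
to a window (default 12–21): `C X{m} C X2 C` (N-terminal pair missing),
`C X2 C X{m}` (C-terminal pair missing; the m-window must be
cysteine-free and is taken maximal), and `C X2 C X{m} C` (final cysteine
missing). A candidate must avoid the spans of retained complete hits and
must show at least 4 (configurable) of the ten IVb high-conservation
residues (T-9, P-10, W-12, R-13, G-15, P-16, G-18, L-22, N-24, A-25) at
their anchored positions; spacer-internal positions are aligned by
anchoring at the left cysteine of their spacer, positions beyond the
template's spacer length are simply unavailable, and X never counts as a
match. When two templates claim the same span the one with more
cysteines wins. The threshold and window are exposed as configuration
because partial-domain curation has no community-standard automated rule;
the default is conservative enough that featureless cysteine skeletons
are rejected while truncations of genuine IVb material pass.

## Alternative splicing

Genes are grouped by (species, gene) id; a gene with ≥ 2 isoforms is an
AS gene. Three protein-level measures are computed:

* the AS-form distribution (genes by isoform count × taxonomic group,
  with a percentage column over all AS genes);
* **UTR-only** splicing: true iff all isoform protein sequences are
  byte-identical. This is a protein-level proxy — true UTR-restricted
  splicing is a transcript-structure property, but identical encoded
  proteins are its observable footprint in protein FASTA;
* **domain-change classification** over per-isoform multisets of domain
  types: `partial_conversion` when some isoform carries a partial (IVp)
  domain while another carries a complete type and the multisets differ;
  `domain_loss` when one multiset is a strict sub-multiset of another;
  `other_change` for any other difference; `none` when all multisets are
  equal, with precedence partial_conversion > domain_loss > other_change.
  Multisets are compared without isoform-to-isoform coordinate
  projection: a faithful per-locus comparison would require genome
  alignment, which protein data cannot support.

## Frequency profiles and conservation

Domains of one fixed-length type (IVa 25, IVb 26, IVc/IV4 28 residues)
are stacked positionally — same-type domains share their exact length, so
no aligner is needed — and per-position counts over the 21-letter
alphabet are normalized by the stack depth. X occupies its own column and
counts in the denominator but is never eligible as the modal residue:
unknowns depress conservation, never inflate it. Variable-length types
(IVe, IVp) are rejected from stacking.

Profiles are stratified three ways (eudicots, monocots, non-angiosperms)
plus a merged "all". "Non-angiosperms" is the union of gymnosperm,
marchantiophyta, bryophyta, lycopodiophyta, charophyta and chlorophytae;
the single basal angiosperm belongs to no stratum and contributes only to
"all" — a deliberate resolution of an ambiguity in the three-way split,
chosen so each stratum is phylogenetically coherent. The "all" counts
equal the elementwise sum of the strata plus any basal-angiosperm
contribution.

A position is *conserved* at threshold t when its modal residue's
frequency strictly exceeds t (default 0.90, the conventional reading of
"highly conserved"); modal ties break alphabetically.

## Cohort summaries

Per-species summaries count genes, TF isoforms, AS genes and AS isoforms.
The domain-type × group table counts **every isoform's hits separately**
(isoform-level, not gene-level tallies), because census domain totals are
taken over TF isoforms; its ratio column is each type's share of the
grand total. Band statistics (gene counts per species, sequence lengths)
use closed intervals — "between 15 and 40" includes both endpoints. All
reported means and percentages are rounded half-up to 2 decimals via
exact decimal arithmetic, so ratios recomputed from a table's own cells
reproduce its ratio column digit-for-digit.

## Reference census

Three packaged TSVs transcribe a published census of GATA TFs in 165
plant species: the per-species table (gene/TF/AS counts, group, order,
genus), the 5,536-domain type × group table, and the AS-form histogram of
the 329 AS genes. The transcription was validated against every printed
marginal before freezing: per-group species counts, gene and TF sums,
and the grand totals 4,762 genes / 5,335 TFs / 329 AS genes / 902 AS
isoforms all reconcile. One published narrative figure does not follow
from the published table: the claim that 112 of 139 eudicot+monocot
species (80.58%) carry 15–40 GATA genes. The table itself yields 107
(76.98%) under the inclusive band, and no plausible re-reading of the
band or the counted quantity produces 112. The package reports the
table-derived 107/76.98; the discrepancy is asserted as-published in one
acceptance test, which therefore fails by design.

## Synthetic generator

The generator emulates a census-like cohort with fully known ground
truth. Defaults are the census conditions:

* per-group species counts 100/39/1/5/1/2/1/1/15;
* genes per species: Poisson at the census group mean, clipped to the
  census range (eudicots 2–125 mean 33.82, monocots 6–73 mean 29.28,
  small fixed counts for the minor groups);
* isoforms per gene: 1 with probability 1 − 329/4762, otherwise the
  census AS-form histogram (2 forms most common, up to 12);
* domains per TF: (0.9717, 0.0208, 0.0060, 0.0011, 0.0004) for 1–5;
* domain types: the exact census fractions (IVb 4131/5536, IVc 950/5536,
  IVp 323/5536, IVe 66/5536, IV4 40/5536, IVa 26/5536);
* protein lengths: uniform 100–400 for angiosperms (the census
  concentration band), uniform 200–850 for non-angiosperms (mean ≈ 525,
  matching the census average; about half exceed 400).

Planted domains put anchor residues (the four cysteines; for IVc also the
fully conserved P-18/G-20) in place with probability 1 and consensus
residues with probability `conservation` (default 0.95), all other
positions uniform over the 19 non-cysteine residues. Because the "else"
draw is uniform over all non-cysteine residues, the effective consensus
rate is p + (1−p)/19. Partial domains are planted only by truncating IVb
material (dropping the N-terminal cysteine pair, the C-terminal pair, or
the final cysteine): the partial-domain filter is anchored on the IVb
consensus, and an IVc-derived truncation would not — and should not —
pass it.

Two structural guarantees make recovery on cysteine-free backgrounds
exact rather than probabilistic: domains are separated by at least 22
background residues (one more than the largest legal spacer, so
cysteines of neighbouring domains can never combine into a legal
quadruple or partial template), and under the `cys_free` background
policy every cysteine in the cohort belongs to a planted domain. Under
the `natural` policy (background cysteines at ~1.4%) spurious candidates
can arise; recall of planted complete domains remains 1.0 in the tested
conditions while precision is not guaranteed.

AS scenarios rewrite the second isoform of an AS gene (further isoforms
copy the base): `utr_only` duplicates the protein exactly; `truncation_to_IVp`
truncates one complete IVb (falling back to `domain_loss` for genes
without one); `domain_loss` deletes one whole domain span; `benign`
substitutes a single background residue. Scenario frequencies default to
the census proportions of UTR-only (~32%) and domain-changing (~9%) AS
genes. When a drawn background length cannot accommodate the drawn
domain complement, the length is stretched to the feasible minimum; only
a configured *maximum* length too small for the domains is a hard error,
naming the gene.

The random stream is split hierarchically per (group, species, gene) via
seed sequences, so adding a species or changing one group's count leaves
every other species' sequences byte-identical — stable fixtures under
configuration growth.

What the generator does **not** emulate: phylogenetic covariance between
sequences, codon-level evolution, length outliers beyond the uniform
bands, partial domains that are not IVb truncations, and real
transcript-level splice structure. Passing tests on synthetic data
therefore demonstrate the correctness of the scanning/typing/accounting
machinery under known truth, not the biological completeness of the
partial-domain rule on real proteomes.

## Problem sizes and numerics

The test suite and the acceptance script use cohorts of roughly 2,000
planted domains (~2,000 proteins) for recovery and mixture checks, 1,000
random sequences (length ≤ 300, 7% cysteine) for the brute-force
equivalence check, and stacks of 300–500 planted domains for
conservation calling — sizes at which multinomial scatter is small
relative to the assertions while a full run stays in seconds. Ratio and
mean arithmetic uses exact `Decimal` computation with half-up rounding;
frequency normalization is float with an explicit 1e-9 row-sum
tolerance. Mixture recovery is checked within a 3σ multinomial envelope
per type on a no-splicing configuration (splicing scenarios would
deterministically convert a few IVb domains to IVp and bias the check).
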