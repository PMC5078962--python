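# Methods

This note records the models, parameter choices and numerical conventions
behind `pksmine`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Domain detection by exemplar alignment

Catalytic domains are located by Smith–Waterman alignment of each protein
against one packaged exemplar per domain class (BLOSUM62, gap open 10,
extend 1). Multiple occurrences of a class are found by recursive split:
the best local hit is recorded and the flanking segments are re-searched
until no alignment reaches the class threshold. Overlaps between classes
are resolved best-score-first, ties by a fixed class priority
(KS > AT > DH > ER > KR > MT > ACP > C > A > PCP > TE > tailoring).

Per-class score thresholds ship in `data/anchors.tsv`. Each was calibrated
once as `max + 3·sd` of 60 local-alignment scores of the exemplar against
shuffled-composition sequences; self-alignment scores run 5–15× above
these thresholds, so detection of planted exemplar copies has essentially
unbounded margin while shuffled sequence yields no hits.

The packaged exemplars (`data/exemplars_synthetic.fasta`) are synthetic
stand-ins: fixed-seed random amino-acid sequences with the class's anchor
residues planted at defined columns. They define a consistent coordinate
system for signature extraction and make the whole pipeline testable
offline; they are *not* profiles of real domain families, so the package
as shipped recognizes its own synthetic clusters, not arbitrary natural
proteins. Swapping in curated natural exemplars (same FASTA + anchors.tsv
format) is the intended route to real-data use — the anchor mechanism is
unchanged.

Signature residues are read by mapping the exemplar's anchor *columns*
through the pairwise alignment, not by absolute residue numbering, which
drifts between references. A query gap opposite an anchor yields `-` in
the motif; a hit that does not cover the anchored region is a partial-motif
error rather than a silent wrong call.

## Signature interpretation

* **KS**: one anchor residue; Cys → extension KS, Gln → KSQ loading
  module, anything else unknown.
* **AT** (five residues): Hamming distance to `YASHS` (methylmalonyl-CoA)
  and `HAFHS` (malonyl-CoA); distance 0 → exact call, distance 1 to
  exactly one canonical → near call, ties and gapped motifs → unknown.
  This one-mismatch rule is what maps the observed `RAFHS` variant to
  malonyl-CoA while leaving genuinely ambiguous motifs (e.g. `YAFHS`,
  distance 1 to both) uncalled.
* **KR/ER**: rule tables in `data/kr_er_rules.tsv` (regular-expression
  patterns, first match wins, rule id recorded on every call). Defaults
  follow the standard published fingerprints: an `LDD` motif marks a
  B-type KR (D-hydroxyl), a Trp at the fourth diagnostic position an
  A-type (L-hydroxyl); ER with the diagnostic Tyr → (S)-methyl, without →
  (R). The tables are editable reference data, not code.
* **A domain**: 10-residue binding-pocket code against
  `data/a_codes.tsv`, nearest code by Hamming distance with a 1-mismatch
  tolerance, ties unknown. The shipped table carries six substrates
  (glycine first); extending it is a data edit.

## Module grammar and the assembly line

Modules are parsed greedily left-to-right over domains ordered by gene
order then position, forward-strand genes only: a PKS module opens at
KS/KSQ, absorbs AT and optional DH/ER/KR/MT, closes at ACP; an NRPS
module is (C)–A–PCP; a terminal TE attaches to the last module. A module
left open at an ORF boundary is completed by the next ORF's leading
domains; spans of more than two consecutive ORFs are grammar errors, which
keeps split-module joining local and avoids spurious long-range joins.
An AT with no open module is a grammar error; ER without DH is kept but
flagged. Complementary-strand genes are excluded from the catalytic line
and inventoried as tailoring candidates (monooxygenases, P450s) without
any attempt to assign which enzyme performs which oxidation.

β-processing sets the unit's oxidation state (none → ketone, KR →
hydroxyl, DH+KR → double bond, DH+ER+KR → saturated; any other
combination → ketone with a warning). The loading module's starter is the
decarboxylated AT substrate: KSQ + malonyl-AT loads C2, KSQ +
methylmalonyl-AT loads C3.

**Precursor SMILES.** The chain is written starter-ω to carboxyl. Each
extension unit contributes an α-carbon (methyl branch iff C3) and assigns
its β-state to the carbonyl carbon inherited from the previous unit.
Double bonds are written trans (the standard DH outcome; configurable).
Stereocentres are tagged only when the module's KR type (hydroxyl) or ER
configuration (saturated C3 α-methyl) resolved; the `@`/`@@` tags follow
a fixed local atom-ordering convention and should be read as A/B-type and
S/R labels, not as independently verified CIP assignments. A terminal
NRPS glycine is appended as the C-terminal amide. Macrocyclization,
heterocycle formation and oxidative tailoring are deliberately not
modeled: the product is the linear precursor. A chain with any unknown
extender is "partial" and emits no structure.

## Cluster comparison

ORF-by-ORF comparison uses global alignment (BLOSUM62, gaps 10/1) with
free terminal gaps; identity is identical columns over aligned
(non-terminal-gap) columns, similarity additionally counts
positive-scoring BLOSUM62 pairs (the "positives" convention). Ortholog
pairs are reciprocal best hits by alignment score, ties broken to the
lower subject index and flagged. Synteny is the longest common
subsequence of subject positions in query order divided by the smaller
cluster size. Published homology tables are typically computed with local
(BLAST-style) alignments, so percentages here reproduce such tables only
approximately.

## ANIb

Fragments are consecutive non-overlapping 1,020 bp windows (terminal
fragment kept if ≥ half a window). Each fragment is placed on the subject
by exact 13-mer seeding (stride 7, diagonal voting with 20 bp binning, at
least 3 votes required — chance 13-mer matches between unrelated
sequences essentially never reach 3 votes on one diagonal) and aligned as
an infix of the candidate window with edlib (unit costs). The alignment
is scanned in 60-column chunks; chunks under 70% matches (far outside the
ANI regime, typical of rearrangement-breakpoint overhangs) count as
unalignable. Identity is matches over alignable columns; coverage is the
alignable fraction. Retention requires identity ≥ 30% and coverage ≥ 70%;
ANIb is the unweighted mean identity of retained fragments; both strands
are searched; the directionality of the measure is preserved and the CLI
reports both directions plus their mean. The species rule is
mean identity ≥ 95% (threshold inclusive, configurable within the
conventional 95–96% band).

This seeded-edit-distance engine replaces BLAST-style local alignment:
on the substitution-divergence regime the estimator targets it is exact
(identity = 1 − substitutions/columns), self-ANI is exactly 100, and
planted 1–5% divergence is recovered within ±0.1 at 500 kb. Near the top
of the regime (divergence → 25%) seeding density and the 70% chunk rule
begin to bite, so values there are approximate.

## 16S phylogeny

Pairwise 16S identity uses a glocal nucleotide alignment (match +2,
mismatch −1, gap −2, free end gaps); gap columns are excluded from the
denominator, matching the `matches/compared` reporting convention.
Tree building: complete gap deletion, then p-distance or Jukes–Cantor
(default JC, `d = −(3/4)·ln(1 − 4p/3)`, error at p ≥ 0.75), then
Saitou–Nei neighbor joining. NJ is implemented in-package to fix its
determinism contract — Q-criterion ties break to the lowest index pair,
and a negative branch length is clamped to zero with the deficit moved to
the sibling edge — and is cross-checked in tests against scikit-bio's NJ
and against exhaustive least-squares topology search (≤ 6 taxa).
Bootstrap supports come from column resampling (default 1,000
replicates, one seeded generator), re-distancing and re-joining each
replicate, and attaching bipartition frequencies to the full-data tree;
rendered newick shows supports above 50% only. The outgroup is used for
display rooting only; all computation is on the unrooted tree.

## Synthetic data: what it shows and what it does not

The generators plant every quantity the pipeline estimates: module
architectures (including mid-module ORF splits and tailoring ORFs on
either strand), signature residues, genome substitution divergence (with
optional block rearrangements, which change order but not expected ANI),
and JC evolution along a known tree (no indels — alignments are
positional). Linkers are plain random sequence; real inter-domain linkers
have composition bias and repeats that this does not emulate. Passing the
planted-truth suites therefore demonstrates the correctness of the
inference logic — grammar, signature rules, chain assembly, ANI
estimator, tree reconstruction — under the stated noise models, not the
sensitivity/specificity of domain detection on natural proteins, which
depends on the exemplar bundle used.

Problem sizes in the default suites — 500 kb genomes (10 seeds at 3%
divergence), 8-taxon 1,456-site alignments (20 seeds), 50 random clusters
end-to-end, 1,000 bootstrap replicates in the drivers and acceptance
script — were chosen to keep each study's sampling error an order of
magnitude below the effect it measures.

## Known limitations

* Exemplar bundle is synthetic (see above); natural-protein detection
  requires user-supplied exemplars.
* trans-AT PKSs, iterative modules and non-collinear assembly lines are
  out of scope for the module grammar.
* The precursor model does not perform release chemistry, cyclization or
  tailoring; stereo tags are fingerprint labels, not CIP-verified.
* ANIb values on genomes with heavy indel divergence (not just
  substitutions) will read slightly low, since indels consume alignment
  columns without matches.
* The NRPS grammar requires A and PCP (C optional); unusual NRPS domain
  orders are not parsed.
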