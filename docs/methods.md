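# Methods

## The analysis problem

In ruminants the T-cell receptor β locus ends in three tandem D-J-C
clusters rather than the usual two; in sheep the genomic order of the
clusters (1, then 3, then 2) does not follow their historical numbering.
Each cluster carries one diversity (D) gene, an ordered set of joining (J)
genes (6, 5 and 7 respectively; 17 of the 18 J genes functional) and one
constant (C) gene.  Given cDNA clones that span the 3′ end of a V gene,
the CDR3 junction, a J gene and the beginning of a C gene, the package
answers four questions per clone:

1. what are the boundaries and composition of the CDR3 junction
   (V-retained, N1, D with its trims and substitutions, N2, trimmed J);
2. which D, J and C genes were used;
3. is the D–J joining intra-cluster, inter-cluster (D strictly upstream of
   J) or a trans-rearrangement (D downstream of J, possible only through
   inversion or an inter-chromatid event);
4. is the J–C pairing canonical (own cluster), cis-spliced (C downstream of
   J on the same precursor) or trans-spliced (C upstream of J, requiring a
   second precursor RNA); and does the observed constant-region marker
   vector correspond to a germline allele, an exon swap, or a
   single-crossover recombinant.

## Junction model and decomposition

The CDR3 is delimited IMGT-style: it starts at the codon after the second
conserved V cysteine (position 104, located through an amino-acid anchor
motif, by default `YLCASS`) and ends before the phenylalanine codon of the
J-gene `FGXG` motif.  This convention yields lengths three residues larger
than Kabat numbering.  The anchor must occur exactly once across the three
forward frames; zero or multiple hits are hard errors, not guesses.

Decomposition follows maximal germline attribution, the same rule a manual
analysis applies:

* **J assignment.**  Every germline J is scanned over every 5′ trim; the
  longest exactly matching retained suffix (minimum 6 nt, two codons) wins.
  The `FGXG` position of each germline J is located once, at load time, and
  must be unique across frames.
* **D assignment.**  A junction segment belongs to a D gene when it
  contains a run of at least `min_run = 4` consecutive nucleotides of that
  gene.  The longest exact common substring with each germline D is the
  seed; the best seed wins.  Equal-length best seeds across genes are a
  genuine ambiguity: the default policy reports no call plus the candidate
  list; an optional priority policy (D1 > D3 > D2) mirrors manual curation.
  Absence of a qualifying run is a valid outcome (direct V–J joints or
  trims that erased the D).
* **Substitutions and indels inside D.**  The seed is extended outward; a
  mismatch is accepted as a recorded substitution only when the next three
  positions match on both sides, and at most one single-base insertion or
  deletion is accepted under the same look-ahead.  The look-ahead prevents
  genuinely non-templated nucleotides from being absorbed into the D
  segment; every accepted deviation is recorded, never silent.
* **V-retained prefix.**  Without the V germline sequences, V trimming and
  V-side N addition cannot be separated.  The junction prefix is attributed
  to V only against an explicitly supplied list of germline V-end suffixes
  (or the simulator's truth); otherwise the V-retained part is the anchor
  tail alone and N1 absorbs the rest.  No hidden cross-clone consensus is
  computed.

The concatenation anchor-tail + V-retained + N1 + D + N2 + J-retained must
rebuild the observed CDR3 byte-exactly; this invariant is enforced at run
time and by tests on 10,000 simulated junctions.

Maximal attribution has a known, inherent bias: a non-templated nucleotide
that happens to equal the adjacent germline base is credited to the
germline segment, so reported trims are lower bounds and N lengths
slightly underestimate the generative ones (well under one base per side
at the default parameters; measured in the test suite).

## Topology classification

With the cluster order known, classification is a total strict order
lookup.  For the sheep order 1 < 3 < 2 the full truth tables are

* trans-rearranged D–J pairs: D3–J1, D2–J3, D2–J1;
* cis-splice J–C pairs: J1–C3, J1–C2, J3–C2;
* trans-splice J–C pairs: J2–C1, J2–C3, J3–C1.

Inversion and inter-chromatid trans-rearrangement cannot be distinguished
in cDNA; a single class is emitted with a note naming both mechanisms.

The C isotype is called from the N-terminal diagnostic positions: the
third base of codon 1 separates C2 from C1/C3 (a silent difference), and
one base in each of codons 3 and 4 separates C1 from C2/C3.  The call must
be unique; ambiguous or unmatched diagnostic vectors are flagged, never
defaulted.

## Constant-region variants

Observed C portions are reduced to their bases at the marker positions (in
the packaged synthetic locus, 14 markers: 12 in exon 1, two in exon 3, six
of them non-synonymous, matching the published census; positions are
counted from the first nucleotide of the constant region in the cDNA).
Each distinct (isotype, vector) group is explained against the supplied
germline alleles (at most two per isotype per animal, as obtained by
genomic PCR) under a fixed parsimony preference:

    allele  >  exon swap  >  single-crossover recombinant  >  novel

An exon swap is an intact exon-1 block from one allele joined to the
exon-3 block of another (alternative cis/trans splicing of the third
exon).  A recombinant is explainable by one switch point between two
allele vectors; the breakpoint is reported as the maximal feasible marker
interval.  Donors may come from different isotypes — with only one C1
allele known, a C1×C3 hybrid is still explainable.  Two design choices
were genuinely open:

* **Crossover count.**  Somatic diversification is modelled with single-
  crossover parsimony; vectors needing two or more switches are `novel`.
* **Breakpoint domain.**  The observed recombinants all lie in exon 1, but
  the classifier accepts any single switch point except the exon boundary
  (which is, by definition, the exon-swap case).  This makes the class
  system closed: every single-crossover product of two alleles is
  explained as allele, exon swap or recombinant — a property the test
  suite verifies exhaustively over all donor pairs and breakpoints.

## Reporting conventions

Percentages and means are truncated — not rounded — to one decimal.  This
is the convention under which every printed figure of the source clone
table reproduces exactly (38/72 → 52.7 %, 25/60 → 41.6 %, 339/8 → 42.3 bp,
435/12 → 36.2 bp, 190/15 → 12.6 aa); ordinary half-up rounding contradicts
five of them.  Every fraction is emitted with its counts and an explicit
denominator label, because the rearrangement-class percentages reproduce
only over the 60 D-assigned clones while the splice percentages use all
72.  Three table-derived values disagree with the printed prose and are
asserted as recomputed, with the printed value documented as a known
delta: the D1-group nucleotide mean (recomputed 40.5, printed 40.3), the
D3-group mean (38.4 vs 38.5) and the no-D range maximum (45 vs 42).

## The simulator

The generator emits exactly the structure the analysis assumes, with a
per-transcript ground-truth row, so every module is testable without
external data.  Defaults are the study regime and are not tuning knobs:

| parameter | default | rationale |
| --- | --- | --- |
| rearrangement mixture (intra : inter : trans) | 25/60 : 32/60 : 3/60 | observed D-assigned class counts |
| splice mixture (canonical : cis : trans) | 49/72 : 7/72 : 16/72 | observed splice class counts |
| trims 3′V / 5′D / 3′D | truncated geometric, p = 0.5, caps 6/4/4 nt | observed trims are small; mean ≈ 1 nt per site |
| trim 5′J | truncated geometric, p = 0.35, cap 9 nt | J trimming is the deepest in the data |
| N addition per side | Poisson, mean 3 nt | puts the simulated N-D-N stretch (retained D ≈ 10 nt + N ≈ 6 nt) in the reported 13.8–16 nt band |
| substitution rate inside D | 0.01 per base | substitutions are rare, single-base events |
| exon-swap / recombinant rates | 0.05 / 0.05 | a minority of C sequences exceed the allelic forms |
| nonproductive fraction | 0 | the study pre-selected open reading frames |

Class sampling draws the rearrangement and splice classes first and then a
J cluster compatible with both, so empirical class frequencies converge to
the configured mixtures exactly; configurations that are infeasible for
the locus (e.g. any trans probability on a single-cluster locus) are
rejected up front.  Productive junctions are enforced by adjusting the N2
length to the reading frame and redrawing N nucleotides until no stop
codon remains; nonproductive ones are frameshifted.  Recombinant C
variants draw their crossover after marker 3 so the N-terminal diagnostics
still identify the generating isotype.  Ground-truth variant labels are
canonicalized to the emitted molecule: a crossover whose product equals a
pure allele vector, or leaves a donor exon-1 block intact, is labelled
allele or exon swap respectively, because no classifier could (or should)
recover the unobservable mechanism.

### The synthetic fixture locus

The packaged locus is generated deterministically from a seed: correct
sheep topology (clusters 1/3/2 with genomic ranks 1/2/3, J census 6/5/7,
TRBJ1.3 non-functional so that all 16 J genes observed in the clone table
are functional and TRBJ2.6 is the absent functional gene), D genes of 12,
15 and 18 nt with pairwise shared runs capped at 3 nt, J genes of 33 nt
with a unique `FGXG` at offset 12, and three near-identical C genes
(shared backbone; exons of 60, 18 and 30 nt) differing at the marker
positions.  Allele vectors are drawn so that every pair differs at three
or more of the nine non-diagnostic exon-1 markers and has distinct exon-1
and exon-3 blocks — the "informative markers" condition under which
variant classes are recoverable.  The nucleotide sequences are synthetic;
only the topology and censuses are real.  A user-supplied reference in the
same layout + FASTA format replaces the fixture everywhere.

## What the synthetic data do and do not show

Passing the recovery tests shows the decomposition, classifiers and
variant explanations are correct for data generated under the model's own
assumptions: exact germline segments, independent per-site trimming,
uniform N nucleotides, at most one indel inside D, biallelic C genes.
Real repertoires violate these in ways the simulator does not emulate —
sequencing error outside D, PCR chimeras and artifacts, allele-shared V
ends, D–D fusions, somatic hypermutation-like noise, non-uniform gene
usage within clusters — so the measured recovery rates (e.g. ≥ 99 % D-gene
recovery when at least `min_run + 2` D nucleotides survive trimming) are
upper bounds for real data, not estimates.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally, 1-based inclusive in
  layouts and reports.
* Longest-common-substring ties resolve to the smallest junction offset,
  then the smallest germline offset; results are deterministic and
  reproducible by brute force.
* Transcripts with zero or two anchor hits, no matching J suffix, or a J
  trim reaching past the `FGXG` phenylalanine fail with typed errors;
  pipeline runs keep such records as rows with a failure reason.
* Frameshifted or stop-containing CDR3s are annotated and flagged
  nonproductive, not discarded.
* Marker positions beyond the sequenced C portion are recorded as `N` and
  match any donor during explanation.
* All randomness flows from a single integer seed through one generator;
  identical configuration and seed reproduce output byte-for-byte.

## Problem sizes used in the checks

The property and recovery suites run at the sizes stated in their tests:
reconstruction identity on 10,000 simulated transcripts, class-fraction
recovery at n = 5,000 against binomial 95 % intervals, D-gene recovery at
n = 3,000, constant-region variant recovery at n = 2,000, and Monte-Carlo
N-length recovery at n = 400.  The whole suite completes in well under a
minute on one CPU.

## Known limitations

* No V-gene alignment or V-allele calling: transcripts begin inside V, and
  V attribution requires user-supplied V ends.
* No de-novo allele phasing from cDNA; alleles must be supplied.
* No recombination-signal (heptamer/nonamer) modelling and no statistical
  testing of usage bias; observed counts are reported as counts.
* The D-assignment rule treats "residues" as nucleotides; with `min_run`
  4 a random 4-mer match arises by chance in roughly one junction in
  three, which is why ambiguity and absence are first-class outcomes
  rather than errors.
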