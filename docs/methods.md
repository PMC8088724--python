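# Methods

## Problem setting and model

A real shotgun metagenome contains a *classified* fraction — reads a
taxonomic classifier could place — and an *unknown* fraction it could
not. `habmock` produces a benchmark that keeps the unknown fraction
verbatim and replaces the classified fraction with reads simulated from
reference genomes at the abundances the classification implies. The
benchmark therefore has (i) the original sample's depth, length and
error characteristics, (ii) the original unknown-sequence burden, and
(iii) an exact per-read ground truth for everything simulated.

The unit of processing is the *fragment*: classifiers judge a read pair
jointly and emit one record per pair, so one classification record, one
count unit and one simulated insert all correspond to one fragment.
Fragments are atomic — a pair is either kept whole or replaced whole.

## Profile construction

Let a fragment be classified to a set *T* of distinct taxa. Each taxon
in *T* receives count mass 1/|T| (proportional counting over *distinct*
taxa; multiple reference-sequence hits within one taxon collapse first).
Only taxa at species rank or below enter the profile; mass on genus or
higher ranks is itemized as dropped because it cannot be attributed to
a single genome. "Species or below" is evaluated positionally: a node
is a strain iff it lies strictly below a species node, regardless of
its literal rank string ("no rank", "subspecies", "strain"), because
rank labels below species are inconsistent in NCBI-style taxonomies.

Counts then flow through three mass-conserving transformations:

1. *Domain filter.* Counts partition by superkingdom; non-selected
   domains (default: everything but Bacteria) are set aside and their
   fragments kept as original reads. Taxa with no superkingdom ancestor
   are conservatively excluded.
2. *Orphan-strain promotion.* A strain with no assembly in the catalog
   passes its count to its species.
3. *Ratio distribution.* Each species-level count is split over the
   species' genome-bearing strains proportionally to the counts those
   strains already hold after promotion. The ratio rule is undefined
   when all strain counts are zero; the uniform split used there is the
   maximum-entropy completion. A species with no genome-bearing strain
   but an assembly at the species taxid itself keeps its count; with no
   assembly anywhere the mass is dropped and itemized (`no_reference`).

Whether distribution should use pre- or post-promotion strain counts is
ambiguous; promotion runs first here, matching the order in which the
rules are stated. All arithmetic stays fractional until the final step.

*Integerization* converts fractional per-genome counts to whole reads
by largest-remainder apportionment: floor everything, then hand the
remaining units (total rounds half up — a lone 0.5-read taxon still
yields a read) one each to the largest fractional remainders, ties
broken by larger count then accession. This conserves the total exactly
and keeps every genome within 1 read of its fractional target. Among
multiple assemblies for one taxid the choice is deterministic:
`refseq_category` "reference genome" before "representative genome"
before others, then lexicographic accession.

A fragment is **replaced** iff every taxon it was counted toward is
backed by a selected-domain reference genome (directly, via promotion,
or via distribution); otherwise it is **kept**. Replacement is
count-exact at the genome level rather than read-identity-exact: the
number of simulated fragments equals the integerized budget of the
replaced mass, so totals match even though individual simulated reads
are not paired 1:1 with removed reads.

## Read simulation

The error model is learned from the input sample: the empirical
read-length distribution and, for every position, the empirical Phred
score distribution (per mate for paired data; capped by default at the
first 100 000 reads, which stabilizes per-position frequencies while
keeping learning O(seconds)). Simulation draws a contig with
probability proportional to its length, a start uniform over valid
positions, a strand uniformly, then per-position qualities, and
substitutes each base independently with probability 10^(−Q/10),
uniformly over the three alternative bases; `N` and ambiguity codes
pass through. Scores are clamped to [0, 60].

Deliberate simplifications, and what they imply:

* **Substitutions only, no indels.** Substitutions dominate Illumina
  error; keeping reads colinear with their source makes the truth
  coordinates exact. Calibration claims are therefore against this
  model's own quality-implied rate, not against any external
  simulator's output bytes.
* **Positionwise-independent qualities.** No Markov structure along the
  read and no flowcell/tile effects.
* **Linear contigs.** Fragments never span contig ends or circular
  origins.
* **Paired-end inserts.** Insert size is unobservable from unaligned
  FASTQ, so paired simulation uses
  insert = max(len₁+len₂, 𝒩(μ, σ)) with μ = 2·(mean read length)+100 bp
  and σ = 0.1 μ by default (a conventional short-insert library), FR
  orientation; both are overridable.

Read ids encode `accession|contig|fragment_start|strand|serial`; the
truth table reports per-mate 1-based inclusive coordinates on the
forward strand. Per-genome RNG streams are seeded by a hash of
(run seed, accession), making output bytes independent of which other
genomes are in the budget — `simonly` output is byte-identical to the
simulated block of a `full` run with the same seed.

## Synthetic fixtures

The fixture generator emulates the full input surface (taxonomy dump,
genomes + assembly summary, FASTQ, classifier output) from one seed,
with truth recorded in a manifest. Defaults sketch a modest gut-like
community: 5 species × 3 strains of 20 kb uniform-random genomes,
strain abundances drawn from a flat Dirichlet, 2 000 fragments of
100 bp at Q30, 25 % of strains without a reference assembly, 30 % of
reads from a "dark" genome absent from catalog and classification
(real habitats leave anywhere from a few percent to most reads
unclassified), and 20 % of classified reads reported ambiguously under
three sibling taxa. Fixture genomes are uniform ACGT with no GC skew,
repeats, or realistic strain divergence, and fixture reads are
error-free: passing closed-loop tests demonstrates exact count/
coordinate bookkeeping, not classifier robustness or assembly realism
on real data.

## Numerical and design choices

* Mass conservation is exact in rational terms; tests allow 1e−9 of
  floating-point drift across the redistribution chain.
* Taxids present in the classification but missing from the taxonomy
  are routed to the drop report (`unresolved_taxid`) and their
  fragments kept — classifier index and taxonomy dump versions often
  disagree, and keeping is the conservative choice.
* A read whose row count disagrees with its declared `numMatches`
  triggers a warning; the observed rows win.
* Output read order is kept-block then simulated-block (grouped by
  accession) for reproducibility; `--shuffle` applies a deterministic
  seed-driven permutation for order-sensitive consumers.
* Default problem sizes in tests and the acceptance script (2 000 to
  10 000 fragments, 20–50 kb genomes, 10⁶ simulated bases for
  calibration) are chosen so each statistical check has power at 3σ
  while a full run stays in the seconds range.

## Known limitations

* Reference genomes must be local; there is no download machinery.
* Only Centrifuge-format classification input is parsed (Kraken-style
  dialects would be a natural extension); classifier hits are not
  score-thresholded before counting.
* The simulator does not model indels, PCR duplicates, optical
  artifacts or long reads.
* Abundance is measured in fragments, not bases; genomes of very
  different lengths at equal fragment counts have different coverage,
  which the genome report makes explicit.
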