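# habmock

**Habitat-specific benchmark metagenomes with a ground truth.**

Benchmarks for metagenome software (assemblers, binners, profilers) are
only as informative as the data they run on, and simulated communities
rarely resemble the habitat a study actually targets. `habmock` builds a
benchmark directly from a real shotgun sample: every read that a
taxonomic classifier placed at species or strain level — and that has a
reference genome available — is **replaced** by reads simulated from
that genome at equivalent abundance, while the unclassified fraction
(and anything else that cannot be pinned to a genome) is **kept
verbatim**. The result mirrors the original sample's composition, read
lengths, quality profile and depth, but carries an exact per-read ground
truth for the simulated fraction — including the realistic burden of
unknown sequence that purely synthetic benchmarks omit.

It is aimed at microbiome and metagenomics researchers who want to
evaluate tools and parameters *for their own habitat* (gut, urban
surface, nasal cavity, …) before committing to an analysis workflow.

## Method

Given a per-read classification (Centrifuge tab-separated output), a
taxonomy (`nodes.dmp`/`names.dmp`), and a local genome catalog
(`assembly_summary.txt` + FASTA files), the abundance profile is built
as follows:

1. **Proportional counting.** Each classified fragment distributes one
   unit of count mass equally over its distinct taxa: a read classified
   to three different taxa adds ⅓ to each. Reads classified above
   species level (genus and higher) cannot be assigned to a single
   genome and are not simulated.
2. **Domain selection.** By default only Bacteria are simulated; counts
   in other superkingdoms stay in the sample as original reads.
   Archaea, Eukaryota and Viruses can be selected too.
3. **Orphan-strain promotion.** Counts on strains with no reference
   assembly move up to their species. A "strain" is any node strictly
   below a species, whatever its rank label.
4. **Ratio distribution.** Each species-level count *c<sub>s</sub>* is
   split over that species' genome-bearing strains *i* proportionally
   to the counts *c<sub>i</sub>* they already hold:
   share<sub>i</sub> = c<sub>s</sub> · c<sub>i</sub> / Σ<sub>j</sub>c<sub>j</sub>
   (uniformly if all c<sub>j</sub> = 0).
5. **Integerization.** Fractional counts become whole reads per genome
   by largest-remainder apportionment, so totals are conserved exactly.

Read simulation learns the read-length distribution and per-position
Phred quality distributions from the input FASTQ and substitutes each
simulated base with probability 10^(−Q/10). Read ids encode genome,
contig, position and strand, and a truth table accompanies the FASTQ.

Three benchmark variants exist: `full` (kept originals + simulated
reads), `simonly` (simulated reads only), and `simscaled` (simulated
reads rescaled to a target depth via `--rn-sim N`, preserving relative
abundances).

## Worked example

The package ships a synthetic-fixture generator, so a complete run needs
no downloads:

```sh
python -c "from habmock.fixtures import FixtureSpec, generate_fixture; \
           generate_fixture(FixtureSpec(seed=11), 'demo/fx')"
habmock -i demo/fx/sample.fastq -c demo/fx/classification.tsv -o demo/out \
  --taxonomy demo/fx/taxonomy --assembly-summary demo/fx/assembly_summary.txt \
  --genomes demo/fx/genomes --seed 11
```

prints

```
INFO input fragments: 2000 (1400 classified, 600 unclassified)
INFO mode full: kept 600 fragment(s), simulated 1400 fragment(s) from 11 genome(s)
INFO outputs in demo/out (0.2 s)
```

The fixture's 2000-read sample had 30 % unclassifiable ("dark") reads;
those 600 are copied into the benchmark unchanged, and the 1400
classified reads are replaced by 1400 simulated reads drawn from the 11
reference genomes at the classified abundances — output depth equals
input depth. `demo/out/` then contains the benchmark FASTQ, its per-read
`truth.tsv`, and the reports:

```
taxid  name                    rank       fractional_count  reads_allocated  accession
3000   Species sp0 strain st0  strain     412.250000        412              GCF_000000000.1
3002   Species sp0 strain st2  subspecies 72.750000         73               GCF_000000002.1
...
accession        taxid  reads_allocated  fold_coverage
GCF_000000000.1  3000   412              2.0600
```

The fractional counts reflect proportional counting plus promotion and
ratio distribution; `reads_allocated` is their largest-remainder
integerization; `fold_coverage` is reads × mean read length / genome
length. `drop_report.tsv` itemizes any count mass that could not be
simulated (above-species, no reference, unresolved taxid) and
`manifest.json` records every run parameter for reproducibility.

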