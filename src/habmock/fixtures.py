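"""Self-consistent synthetic input bundles with known ground truth.

A fixture bundle emulates everything the pipeline consumes from the real
world: an NCBI-style taxonomy dump, reference genomes with an assembly
summary, a sample FASTQ and a classifier output — all generated from one
seed so every downstream quantity (abundances, multi-mapped read counts,
the unclassified fraction) is known exactly and recorded in a manifest.

The "dark" genome emulates a sample's unknown sequence fraction: its
reads come from a genome that is deliberately absent from both the
catalog and the taxonomy-backed classification, so they exercise the
kept-fraction path. Real metagenomes routinely leave large fractions of
reads unclassified, so the generator defaults to a substantial dark
fraction. Genomes are uniform-random nucleotide strings: adequate for
count/coordinate bookkeeping, unrealistic for GC structure or
phylogenetic divergence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from habmock.classification import ClassificationSet, ReadAssignment
from habmock.errors import ConfigurationError

BACTERIA_TAXID = 2
ARCHAEA_TAXID = 2157

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureSpec:
    """Knobs of the synthetic community and its sequencing run.

    Defaults describe a modest gut-like community: a handful of species
    with strain structure, a quarter of strains lacking a reference
    assembly, roughly a third of reads unclassifiable, and a fifth of
    classified reads ambiguous between sibling strains.
    """

    n_species: int = 5
    strains_per_species: int = 3
    genome_length: int = 20_000
    missing_genome_fraction: float = 0.25
    n_fragments: int = 2_000
    unclassified_fraction: float = 0.30
    multimap_fraction: float = 0.20
    read_length: int = 100
    quality_mean: int = 30
    seed: int = 42
    paired: bool = False
    n_archaea_species: int = 0

    def validate(self) -> None:
        for name in ("missing_genome_fraction", "unclassified_fraction", "multimap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        for name in ("n_species", "strains_per_species", "genome_length",
                     "n_fragments", "read_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.quality_mean <= 60:
            raise ConfigurationError("quality_mean must be a Phred score in [0,60]")
        n_classified = self.n_fragments - round(self.unclassified_fraction * self.n_fragments)
        if n_classified > 0 and self.missing_genome_fraction >= 1.0:
            raise ConfigurationError(
                "classified reads requested but every genome is missing"
            )


@dataclass
class StrainTruth:
    taxid: int
    species_taxid: int
    accession: str | None  # None: no reference assembly (orphan strain)
    abundance: float
    true_count: int = 0


@dataclass
class FixtureBundle:
    out_dir: Path
    nodes_path: Path
    names_path: Path
    assembly_summary_path: Path
    genomes_dir: Path
    fastq_paths: list[Path]
    classification_path: Path
    manifest_path: Path
    manifest: dict = field(default_factory=dict)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _write_fasta(path: Path, contig: str, seq: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureBundle:
    """Write a complete input bundle under ``out_dir`` and return it.

    Emits nodes.dmp/names.dmp (root -> superkingdom -> genus -> species ->
    strain lineages), FASTA genomes for the non-missing strains, an
    assembly summary over them, the sample FASTQ(s), a classifier output
    assigning true taxids (with a fraction of reads listed under three
    sibling taxa and dark reads marked unclassified), and a JSON manifest
    recording every truth value.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    tax_dir = out_dir / "taxonomy"
    genomes_dir = out_dir / "genomes"
    tax_dir.mkdir(parents=True, exist_ok=True)
    genomes_dir.mkdir(parents=True, exist_ok=True)

    # ---- taxonomy -------------------------------------------------------
    # taxid layout: genus 1000+d; species 2000+i; strain 3000+100*i+k
    nodes: list[tuple[int, int, str]] = [
        (1, 1, "no rank"),
        (BACTERIA_TAXID, 1, "superkingdom"),
        (ARCHAEA_TAXID, 1, "superkingdom"),
        (1000, BACTERIA_TAXID, "genus"),
        (1001, ARCHAEA_TAXID, "genus"),
    ]
    names = {
        1: "root",
        BACTERIA_TAXID: "Bacteria",
        ARCHAEA_TAXID: "Archaea",
        1000: "Bacterigenus",
        1001: "Archaeigenus",
    }
    strains: list[StrainTruth] = []
    total_species = spec.n_species + spec.n_archaea_species
    for i in range(total_species):
        species_taxid = 2000 + i
        genus = 1001 if i >= spec.n_species else 1000
        nodes.append((species_taxid, genus, "species"))
        names[species_taxid] = f"Species sp{i}"
        for k in range(spec.strains_per_species):
            strain_taxid = 3000 + 100 * i + k
            # exercise the positional strain rule: label ranks inconsistently
            rank = ("strain", "no rank", "subspecies")[k % 3]
            nodes.append((strain_taxid, species_taxid, rank))
            names[strain_taxid] = f"Species sp{i} strain st{k}"
            strains.append(StrainTruth(strain_taxid, species_taxid, None, 0.0))

    nodes_path = tax_dir / "nodes.dmp"
    names_path = tax_dir / "names.dmp"
    with open(nodes_path, "w") as fh:
        for taxid, parent, rank in nodes:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w") as fh:
        for taxid, _parent, _rank in nodes:
            fh.write(f"{taxid}\t|\t{names[taxid]}\t|\t\t|\tscientific name\t|\n")

    # ---- genomes & assembly summary -------------------------------------
    n_missing = round(spec.missing_genome_fraction * len(strains))
    missing_idx = set(rng.choice(len(strains), size=n_missing, replace=False).tolist())
    sequences: dict[int, str] = {}  # strain taxid -> genome sequence
    summary_rows: list[str] = []
    for idx, strain in enumerate(strains):
        seq = _random_sequence(rng, spec.genome_length)
        sequences[strain.taxid] = seq
        if idx in missing_idx:
            continue
        accession = f"GCF_{idx:09d}.1"
        strain.accession = accession
        _write_fasta(genomes_dir / f"{accession}.fna", f"{accession}_c1", seq)
        summary_rows.append(
            "\t".join(
                [accession, "-", "-", "-", "na", str(strain.taxid),
                 str(strain.species_taxid), names[strain.taxid], "-"]
            )
        )
    summary_path = out_dir / "assembly_summary.txt"
    with open(summary_path, "w") as fh:
        fh.write("# Synthetic assembly summary\n")
        fh.write(
            "# assembly_accession\tbioproject\tbiosample\twgs_master\t"
            "refseq_category\ttaxid\tspecies_taxid\torganism_name\tftp_path\n"
        )
        fh.write("".join(r + "\n" for r in summary_rows))

    dark_seq = _random_sequence(rng, spec.genome_length)

    # ---- reads -----------------------------------------------------------
    n_dark = round(spec.unclassified_fraction * spec.n_fragments)
    n_classified = spec.n_fragments - n_dark
    abundances = rng.dirichlet(np.ones(len(strains)))
    for strain, p in zip(strains, abundances):
        strain.abundance = float(p)
    strain_choice = rng.choice(len(strains), size=n_classified, p=abundances)
    for idx in strain_choice:
        strains[idx].true_count += 1
    multimap_mask = rng.random(n_classified) < spec.multimap_fraction

    mates = 2 if spec.paired else 1
    if spec.paired:
        fastq_paths = [out_dir / "sample_R1.fastq", out_dir / "sample_R2.fastq"]
    else:
        fastq_paths = [out_dir / "sample.fastq"]
    qual_str = chr(33 + spec.quality_mean) * spec.read_length
    insert = int(2.5 * spec.read_length)

    read_truth: dict[str, dict] = {}
    cls_rows: list[str] = []
    fhs = [open(p, "w") for p in fastq_paths]
    try:
        def emit_fragment(read_id: str, seq: str) -> None:
            span = insert if spec.paired else spec.read_length
            start = int(rng.integers(0, len(seq) - span + 1))
            if spec.paired:
                r1 = seq[start : start + spec.read_length]
                frag_end = start + insert
                r2 = _revcomp(seq[frag_end - spec.read_length : frag_end])
                fhs[0].write(f"@{read_id}/1\n{r1}\n+\n{qual_str}\n")
                fhs[1].write(f"@{read_id}/2\n{r2}\n+\n{qual_str}\n")
            else:
                r = seq[start : start + spec.read_length]
                fhs[0].write(f"@{read_id}\n{r}\n+\n{qual_str}\n")

        serial = 0
        for j, idx in enumerate(strain_choice):
            strain = strains[int(idx)]
            read_id = f"fx{serial:07d}"
            serial += 1
            emit_fragment(read_id, sequences[strain.taxid])
            if multimap_mask[j]:
                taxa = _sibling_taxa(strains, int(idx))
                for t in taxa:
                    seq_id = _accession_of(strains, t) or f"ref|{t}"
                    cls_rows.append(
                        f"{read_id}\t{seq_id}\t{t}\t100\t0\t{spec.read_length}\t"
                        f"{spec.read_length}\t{len(taxa)}"
                    )
                read_truth[read_id] = {"taxid": strain.taxid, "taxa": sorted(taxa)}
            else:
                seq_id = strain.accession or f"ref|{strain.taxid}"
                cls_rows.append(
                    f"{read_id}\t{seq_id}\t{strain.taxid}\t100\t0\t"
                    f"{spec.read_length}\t{spec.read_length}\t1"
                )
                read_truth[read_id] = {"taxid": strain.taxid, "taxa": [strain.taxid]}
        for _ in range(n_dark):
            read_id = f"fx{serial:07d}"
            serial += 1
            emit_fragment(read_id, dark_seq)
            cls_rows.append(f"{read_id}\tunclassified\t0\t0\t0\t0\t{spec.read_length}\t1")
            read_truth[read_id] = {"taxid": 0, "taxa": []}
    finally:
        for fh in fhs:
            fh.close()

    classification_path = out_dir / "classification.tsv"
    with open(classification_path, "w") as fh:
        fh.write(
            "readID\tseqID\ttaxID\tscore\t2ndBestScore\thitLength\t"
            "queryLength\tnumMatches\n"
        )
        fh.write("".join(r + "\n" for r in cls_rows))

    manifest = {
        "spec": asdict(spec),
        "n_classified": int(n_classified),
        "n_unclassified": int(n_dark),
        "n_multimapped": int(multimap_mask.sum()),
        "mates": mates,
        "strains": {
            str(s.taxid): {
                "species_taxid": s.species_taxid,
                "accession": s.accession,
                "abundance": s.abundance,
                "true_count": s.true_count,
            }
            for s in strains
        },
        "reads": read_truth,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return FixtureBundle(
        out_dir=out_dir,
        nodes_path=nodes_path,
        names_path=names_path,
        assembly_summary_path=summary_path,
        genomes_dir=genomes_dir,
        fastq_paths=fastq_paths,
        classification_path=classification_path,
        manifest_path=manifest_path,
        manifest=manifest,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _accession_of(strains: list[StrainTruth], taxid: int) -> str | None:
    for s in strains:
        if s.taxid == taxid:
            return s.accession
    return None


def _sibling_taxa(strains: list[StrainTruth], idx: int) -> list[int]:
    """The true strain plus two siblings (same species where possible)."""
    me = strains[idx]
    same_species = [s.taxid for s in strains
                    if s.species_taxid == me.species_taxid and s.taxid != me.taxid]
    others = [s.taxid for s in strains
              if s.species_taxid != me.species_taxid]
    pool = same_species + others
    return [me.taxid] + pool[:2]


def oracle_classify(
    fastq_ids: list[str], bundle: FixtureBundle
) -> ClassificationSet:
    """Perfect classifier for closed-loop tests.

    Fixture reads are looked up in the manifest; simulated benchmark
    reads (ids encoding ``accession|contig|...``) are resolved through
    the bundle's strain table. Foreign ids raise ``KeyError``.
    """
    acc_to_taxid = {
        info["accession"]: int(taxid)
        for taxid, info in bundle.manifest["strains"].items()
        if info["accession"]
    }
    assigned: list[ReadAssignment] = []
    unclassified: set[str] = set()
    for read_id in fastq_ids:
        truth = bundle.manifest["reads"].get(read_id)
        if truth is not None:
            if truth["taxid"] == 0:
                unclassified.add(read_id)
            else:
                assigned.append(ReadAssignment(read_id, frozenset(truth["taxa"])))
            continue
        if "|" in read_id:
            accession = read_id.split("|")[0]
            if accession in acc_to_taxid:
                assigned.append(
                    ReadAssignment(read_id, frozenset({acc_to_taxid[accession]}))
                )
                continue
        raise KeyError(f"read id {read_id!r} unknown to this fixture bundle")
    return ClassificationSet(assigned=assigned, unclassified_ids=unclassified)
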