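"""Pipeline orchestration: partition, simulate, merge, report.

``create_benchmark`` wires the stages together: parse the taxonomy,
classification and genome catalog, build the per-genome read budget,
decide which original fragments are replaced and which are kept, learn
the error profile from the input FASTQ, simulate the replacement reads
and merge everything into the final benchmark sample with its ground
truth and reports.

Three output modes exist:

* ``full`` — kept original reads plus simulated reads (the benchmark
  mirrors the original sample, unknown fraction included);
* ``simonly`` — only the simulated replacement reads;
* ``simscaled`` — only simulated reads, with the classified profile
  rescaled to a target read depth while preserving relative abundances.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from habmock._version import __version__ as _version
from habmock.catalog import (
    GenomeCatalog,
    load_sequences,
    measure_genome,
    parse_assembly_summary,
)
from habmock.classification import ClassificationSet, parse_centrifuge, split_by_read_ids
from habmock.errors import ConfigurationError, SimulationError
from habmock.profile import (
    CountTable,
    GenomeBudget,
    count_assignments,
    distribute_species_counts,
    filter_domains,
    integerize,
    promote_orphan_strains,
    scale_counts,
)
from habmock.simulate import ErrorProfile, coverage_of, learn_profile, simulate_genome_reads
from habmock.taxonomy import TaxonomyTree, load_taxonomy

MODES = ("full", "simonly", "simscaled")


@dataclass
class BenchmarkPlan:
    mode: str
    domains: frozenset[str]
    budget: GenomeBudget
    kept_ids: set[str]
    replaced_ids: set[str]
    seed: int
    target_total: int | None = None
    final_counts: CountTable | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; valid: {MODES}")
        if self.mode == "simscaled" and self.target_total is None:
            raise ConfigurationError("simscaled mode requires target_total")
        overlap = self.kept_ids & self.replaced_ids
        if overlap:
            raise ValueError(f"{len(overlap)} fragment(s) both kept and replaced")


def normalize_fragment_id(title: str) -> str:
    """FASTQ title -> fragment id: first token, mate suffix stripped."""
    token = title.split()[0]
    if token.endswith("/1") or token.endswith("/2"):
        token = token[:-2]
    return token


def read_fastq_fragment_ids(path: str | Path) -> list[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [normalize_fragment_id(t) for t, _s, _q in FastqGeneralIterator(fh)]


def partition_reads(
    classification: ClassificationSet,
    budget: GenomeBudget,
    excluded: CountTable,
    tree: TaxonomyTree,
    catalog: GenomeCatalog,
) -> tuple[set[str], set[str]]:
    """Split fragments into (replaced_ids, kept_ids).

    A fragment is replaced iff *every* taxon it was counted toward ends
    up backed by a reference genome in a selected domain — directly, via
    orphan-strain promotion, or via species-level distribution.
    Unclassified, above-species, unresolved, excluded-domain and
    no-reference fragments are kept.
    """
    fate_cache: dict[int, bool] = {}

    def simulated(taxid: int) -> bool:
        if taxid in fate_cache:
            return fate_cache[taxid]
        ok = False
        if taxid in tree and tree.at_or_below_species(taxid) and taxid not in excluded.counts:
            if catalog.by_taxid.get(taxid):
                ok = True
            else:
                species = tree.species_ancestor(taxid)
                ok = bool(catalog.by_species.get(species))
        fate_cache[taxid] = ok
        return ok

    replaced: set[str] = set()
    kept: set[str] = set(classification.unclassified_ids)
    for assignment in classification.assigned:
        if all(simulated(t) for t in assignment.taxa):
            replaced.add(assignment.read_id)
        else:
            kept.add(assignment.read_id)
    return replaced, kept


@dataclass
class OutputBundle:
    out_dir: Path
    fastq_paths: list[Path]
    truth_path: Path
    abundance_report: Path
    genome_report: Path
    drop_report: Path
    manifest_path: Path
    n_kept: int = 0
    n_simulated_fragments: int = 0

    @property
    def n_output_fragments(self) -> int:
        return self.n_kept + self.n_simulated_fragments


def _accession_seed(seed: int, accession: str) -> int:
    digest = hashlib.sha256(f"{seed}|{accession}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class _FastqWriter:
    def __init__(self, path: Path):
        self.path = path
        self._fh = gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")

    def write(self, title: str, seq: str, qual: str) -> None:
        self._fh.write(f"@{title}\n{seq}\n+\n{qual}\n")

    def close(self) -> None:
        self._fh.close()


def assemble_benchmark(
    original_fastq: list[str | Path],
    plan: BenchmarkPlan,
    catalog: GenomeCatalog,
    profile: ErrorProfile,
    out_dir: str | Path,
    tree: TaxonomyTree | None = None,
    shuffle: bool = False,
    gzip_output: bool = False,
) -> OutputBundle:
    """Produce the benchmark FASTQ(s), truth table and reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paired = profile.paired
    ext = ".fastq.gz" if gzip_output else ".fastq"
    if paired:
        fastq_paths = [out_dir / f"benchmark_R1{ext}", out_dir / f"benchmark_R2{ext}"]
    else:
        fastq_paths = [out_dir / f"benchmark{ext}"]

    records: list[tuple[tuple[str, str, str], ...]] = []  # per fragment, per mate

    n_kept = 0
    if plan.mode == "full":
        openers = [
            gzip.open(p, "rt") if str(p).endswith(".gz") else open(p)
            for p in original_fastq
        ]
        iters = [FastqGeneralIterator(fh) for fh in openers]
        try:
            for entries in zip(*iters):
                frag_id = normalize_fragment_id(entries[0][0])
                if frag_id in plan.kept_ids:
                    records.append(tuple(entries))
                    n_kept += 1
        finally:
            for fh in openers:
                fh.close()

    truth_path = out_dir / "truth.tsv"
    truth_rows: list[str] = []
    by_accession = {r.accession: r for r in catalog.records()}
    n_sim = 0
    for accession in sorted(plan.budget.allocations):
        n_frags = plan.budget.allocations[accession]
        if n_frags <= 0:
            continue
        record = by_accession.get(accession)
        if record is None:
            raise SimulationError(f"budget names unknown accession {accession}")
        if not record.measured:
            record = measure_genome(record)
        sequences = load_sequences(record)
        taxid = plan.budget.source_taxid.get(accession, record.taxid)
        acc_seed = _accession_seed(plan.seed, accession)
        pending: list[tuple[str, str, str]] = []
        for read in simulate_genome_reads(
            record, n_frags, profile, acc_seed, sequences=sequences
        ):
            suffix = f"/{read.mate}" if read.mate else ""
            pending.append((f"{read.read_id}{suffix}", read.sequence, read.qualities))
            truth_rows.append(
                "\t".join(
                    str(v)
                    for v in (
                        read.read_id,
                        accession,
                        taxid,
                        read.contig,
                        read.start + 1,
                        read.start + len(read.sequence),
                        read.strand,
                        read.mate if read.mate else "none",
                    )
                )
            )
            if not paired or read.mate == 2:
                records.append(tuple(pending))
                pending = []
                n_sim += 1

    if shuffle:
        order = np.random.default_rng(plan.seed).permutation(len(records))
        records = [records[i] for i in order]

    writers = [_FastqWriter(p) for p in fastq_paths]
    try:
        for fragment in records:
            for writer, (title, seq, qual) in zip(writers, fragment):
                writer.write(title, seq, qual)
    finally:
        for w in writers:
            w.close()

    with open(truth_path, "w") as fh:
        fh.write(
            "# coordinates are 1-based inclusive on the forward strand\n"
            "read_id\taccession\ttaxid\tcontig\tstart_1based\tend_1based\tstrand\tmate\n"
        )
        fh.write("".join(row + "\n" for row in truth_rows))

    bundle = OutputBundle(
        out_dir=out_dir,
        fastq_paths=fastq_paths,
        truth_path=truth_path,
        abundance_report=out_dir / "abundance_report.tsv",
        genome_report=out_dir / "genome_report.tsv",
        drop_report=out_dir / "drop_report.tsv",
        manifest_path=out_dir / "manifest.json",
        n_kept=n_kept,
        n_simulated_fragments=n_sim,
    )
    write_reports(plan, catalog, profile, bundle, tree=tree)
    return bundle


def write_reports(
    plan: BenchmarkPlan,
    catalog: GenomeCatalog,
    profile: ErrorProfile,
    bundle: OutputBundle,
    tree: TaxonomyTree | None = None,
) -> None:
    """Write the abundance, genome-selection and drop reports plus the
    run manifest. Byte-deterministic for a given plan."""

    def tax_name(taxid: int) -> str:
        return tree.name_of(taxid) if tree is not None and taxid in tree else str(taxid)

    def tax_rank(taxid: int) -> str:
        return tree.rank_of(taxid) if tree is not None and taxid in tree else "unknown"

    counts = plan.final_counts.counts if plan.final_counts is not None else {}
    acc_of_taxid = {t: a for a, t in plan.budget.source_taxid.items()}
    with open(bundle.abundance_report, "w") as fh:
        fh.write("taxid\tname\trank\tfractional_count\treads_allocated\taccession\n")
        for taxid in sorted(set(counts) | set(acc_of_taxid)):
            acc = acc_of_taxid.get(taxid, "")
            allocated = plan.budget.allocations.get(acc, 0) if acc else 0
            fh.write(
                f"{taxid}\t{tax_name(taxid)}\t{tax_rank(taxid)}\t"
                f"{counts.get(taxid, 0.0):.6f}\t{allocated}\t{acc}\n"
            )

    by_accession = {r.accession: r for r in catalog.records()}
    with open(bundle.genome_report, "w") as fh:
        fh.write("accession\ttaxid\treads_allocated\tfold_coverage\n")
        for accession in sorted(plan.budget.allocations):
            n = plan.budget.allocations[accession]
            record = by_accession[accession]
            if not record.measured:
                record = measure_genome(record)
            cov = coverage_of(n, profile, record)
            taxid = plan.budget.source_taxid.get(accession, record.taxid)
            fh.write(f"{accession}\t{taxid}\t{n}\t{cov:.4f}\n")

    with open(bundle.drop_report, "w") as fh:
        fh.write("taxid\tname\tcount\treason\n")
        for drop in sorted(plan.budget.drop_report, key=lambda d: (d.reason, d.taxid)):
            fh.write(f"{drop.taxid}\t{tax_name(drop.taxid)}\t{drop.count:.6f}\t{drop.reason}\n")

    manifest = {
        "tool": "habmock",
        "version": _version,
        "mode": plan.mode,
        "domains": sorted(plan.domains),
        "seed": plan.seed,
        "target_total": plan.target_total,
        "paired": profile.paired,
        "n_kept_fragments": bundle.n_kept,
        "n_simulated_fragments": bundle.n_simulated_fragments,
        "n_replaced_fragments": len(plan.replaced_ids),
        "budget_total": plan.budget.total(),
        "outputs": {
            "fastq": [p.name for p in bundle.fastq_paths],
            "truth": bundle.truth_path.name,
        },
    }
    with open(bundle.manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class RunResult:
    plan: BenchmarkPlan
    bundle: OutputBundle
    profile: ErrorProfile
    n_input_fragments: int
    n_classified: int
    n_unclassified: int
    dropped_orphan_classifications: int
    elapsed_s: float = 0.0


def create_benchmark(
    fastq_paths: list[str | Path],
    classification_path: str | Path,
    nodes_path: str | Path,
    names_path: str | Path,
    assembly_summary_path: str | Path,
    genomes_dir: str | Path,
    out_dir: str | Path,
    domains: set[str] = frozenset({"Bacteria"}),
    mode: str = "full",
    target_total: int | None = None,
    seed: int = 42,
    learn_cap: int = 100_000,
    shuffle: bool = False,
    gzip_output: bool = False,
    mean_insert: float | None = None,
    sd_insert: float | None = None,
) -> RunResult:
    """Run the full pipeline and return the plan, outputs and profile."""
    t0 = time.monotonic()
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; valid: {MODES}")
    if mode == "simscaled" and target_total is None:
        raise ConfigurationError("simscaled mode requires target_total (rn-sim)")

    tree = load_taxonomy(nodes_path, names_path)
    catalog = parse_assembly_summary(assembly_summary_path, genomes_dir, tree)
    classification = parse_centrifuge(classification_path)

    fragment_ids = read_fastq_fragment_ids(fastq_paths[0])
    classification, n_dropped = split_by_read_ids(classification, set(fragment_ids))

    table = count_assignments(classification, tree)
    selected, excluded = filter_domains(table, tree, set(domains))
    selected = promote_orphan_strains(selected, catalog, tree)
    selected = distribute_species_counts(selected, catalog, tree)
    if mode == "simscaled":
        selected = scale_counts(selected, target_total)
    budget = integerize(selected, catalog, tree)

    replaced, kept = partition_reads(classification, budget, excluded, tree, catalog)
    plan = BenchmarkPlan(
        mode=mode,
        domains=frozenset(domains),
        budget=budget,
        kept_ids=kept if mode == "full" else set(),
        replaced_ids=replaced,
        seed=seed,
        target_total=target_total,
        final_counts=selected,
    )

    profile = learn_profile(
        list(fastq_paths), max_reads=learn_cap,
        mean_insert=mean_insert, sd_insert=sd_insert,
    )
    bundle = assemble_benchmark(
        list(fastq_paths), plan, catalog, profile, out_dir,
        tree=tree, shuffle=shuffle, gzip_output=gzip_output,
    )
    return RunResult(
        plan=plan,
        bundle=bundle,
        profile=profile,
        n_input_fragments=len(fragment_ids),
        n_classified=len(classification.assigned),
        n_unclassified=len(classification.unclassified_ids),
        dropped_orphan_classifications=n_dropped,
        elapsed_s=time.monotonic() - t0,
    )
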