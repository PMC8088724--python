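"""From weighted read assignments to an integer per-genome read budget.

The abundance profile evolves through a fixed sequence of mass-conserving
transformations:

1. ``count_assignments`` — each classified fragment distributes one unit
   of count mass equally over its distinct taxa; only taxa at species
   rank or below are retained (genus-and-higher mass is itemized as
   dropped, since such reads cannot be pinned to a single genome).
2. ``filter_domains`` — partition by superkingdom; by default only
   Bacteria are simulated and other domains' reads are kept verbatim.
3. ``promote_orphan_strains`` — strains with no reference assembly hand
   their counts to their species.
4. ``distribute_species_counts`` — species-level counts are split over
   that species' genome-bearing strains in the ratio of the counts those
   strains already hold (uniformly if all are zero).
5. optional ``scale_counts`` — rescale the profile to a target depth
   while preserving relative abundances.
6. ``integerize`` — largest-remainder apportionment to whole reads per
   genome.

All arithmetic is fractional until the final step; every unit of mass is
either allocated to a genome or itemized in a drop report, so totals are
conserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from habmock.catalog import GenomeCatalog, GenomeRecord, genomes_for
from habmock.classification import ClassificationSet
from habmock.errors import ConfigurationError
from habmock.taxonomy import TaxonomyTree

VALID_DOMAINS = frozenset({"Bacteria", "Archaea", "Eukaryota", "Viruses"})

#: drop reasons
ABOVE_SPECIES = "above_species"
UNRESOLVED = "unresolved_taxid"
NO_REFERENCE = "no_reference"


@dataclass(frozen=True)
class DropRecord:
    taxid: int
    count: float
    reason: str


@dataclass
class CountTable:
    """taxid -> fractional read count, with provenance and itemized drops."""

    counts: dict[int, float] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)
    drop_report: list[DropRecord] = field(default_factory=list)

    def total(self) -> float:
        return sum(self.counts.values())

    def dropped_total(self) -> float:
        return sum(d.count for d in self.drop_report)

    def copy(self) -> "CountTable":
        return CountTable(dict(self.counts), dict(self.provenance), list(self.drop_report))


@dataclass
class GenomeBudget:
    """Integer read allocation per assembly accession."""

    allocations: dict[str, int] = field(default_factory=dict)
    source_taxid: dict[str, int] = field(default_factory=dict)
    drop_report: list[DropRecord] = field(default_factory=list)

    def total(self) -> int:
        return sum(self.allocations.values())


def count_assignments(
    classification: ClassificationSet, tree: TaxonomyTree
) -> CountTable:
    """Proportional counting of classified fragments over their taxa.

    Each fragment contributes total mass exactly 1, split equally among
    its distinct taxa (one third each for a fragment classified to three
    different taxa). Mass landing on a taxon above species rank, or on a
    taxid absent from the taxonomy, goes to the drop report.
    """
    table = CountTable()
    dropped: dict[str, dict[int, float]] = {}
    for assignment in classification.assigned:
        w = assignment.weight_per_taxon
        for taxid in assignment.taxa:
            if taxid not in tree:
                dropped.setdefault(UNRESOLVED, {}).setdefault(taxid, 0.0)
                dropped[UNRESOLVED][taxid] += w
            elif tree.at_or_below_species(taxid):
                table.counts[taxid] = table.counts.get(taxid, 0.0) + w
                table.provenance[taxid] = "direct"
            else:
                dropped.setdefault(ABOVE_SPECIES, {}).setdefault(taxid, 0.0)
                dropped[ABOVE_SPECIES][taxid] += w
    for reason, by_taxid in dropped.items():
        for taxid, count in sorted(by_taxid.items()):
            table.drop_report.append(DropRecord(taxid, count, reason))
    return table


def filter_domains(
    table: CountTable, tree: TaxonomyTree, domains: set[str]
) -> tuple[CountTable, CountTable]:
    """Partition counts by superkingdom into (selected, excluded).

    Excluded mass is *kept* downstream as original reads, never dropped.
    Taxa with no superkingdom on their root path are conservatively
    excluded.
    """
    if not domains:
        raise ConfigurationError("at least one domain must be selected")
    unknown = set(domains) - VALID_DOMAINS
    if unknown:
        raise ConfigurationError(
            f"unknown domain(s) {sorted(unknown)}; valid: {sorted(VALID_DOMAINS)}"
        )
    selected = CountTable(drop_report=list(table.drop_report))
    excluded = CountTable()
    for taxid, count in table.counts.items():
        kingdom = tree.superkingdom_of(taxid)
        target = selected if kingdom in domains else excluded
        target.counts[taxid] = count
        target.provenance[taxid] = table.provenance.get(taxid, "direct")
    return selected, excluded


def promote_orphan_strains(
    table: CountTable, catalog: GenomeCatalog, tree: TaxonomyTree
) -> CountTable:
    """Move counts of strains lacking a reference assembly to their species.

    A "strain" is any node strictly below a species node. Mass is
    conserved exactly: promoted counts are added to the species taxid
    (creating it in the table if needed).
    """
    out = table.copy()
    for taxid in sorted(table.counts):
        if not tree.is_strain(taxid):
            continue
        if genomes_for(catalog, taxid, tree):
            continue
        species = tree.species_ancestor(taxid)
        assert species is not None  # guaranteed by at_or_below_species filter
        moved = out.counts.pop(taxid)
        out.provenance.pop(taxid, None)
        out.counts[species] = out.counts.get(species, 0.0) + moved
        if out.provenance.get(species) != "direct":
            out.provenance[species] = "promoted"
    return out


def distribute_species_counts(
    table: CountTable, catalog: GenomeCatalog, tree: TaxonomyTree
) -> CountTable:
    """Split species-level counts over genome-bearing strains by ratio.

    Each species count is distributed across that species' strain taxids
    that have assemblies, proportionally to the counts those strains
    already carry; uniformly when all carry zero. If the species has no
    genome-bearing strain but owns an assembly at the species taxid
    itself, the count stays put. With no assembly anywhere the mass is
    dropped with reason ``no_reference``.
    """
    out = table.copy()
    species_taxids = [
        t for t in sorted(table.counts) if tree.species_ancestor(t) == t
    ]
    for species in species_taxids:
        strain_taxids = sorted(
            {r.taxid for r in catalog.strain_records_of(species)}
        )
        if not strain_taxids:
            if catalog.by_taxid.get(species):
                continue  # species' own assembly is the only candidate
            dropped = out.counts.pop(species)
            out.provenance.pop(species, None)
            out.drop_report.append(DropRecord(species, dropped, NO_REFERENCE))
            continue
        mass = out.counts.pop(species)
        out.provenance.pop(species, None)
        existing = [out.counts.get(t, 0.0) for t in strain_taxids]
        denom = sum(existing)
        for taxid, have in zip(strain_taxids, existing):
            share = mass * (have / denom) if denom > 0 else mass / len(strain_taxids)
            if share > 0 or taxid in out.counts:
                out.counts[taxid] = out.counts.get(taxid, 0.0) + share
                if out.provenance.get(taxid) != "direct":
                    out.provenance[taxid] = "distributed"
    return out


def scale_counts(table: CountTable, target_total: int) -> CountTable:
    """Rescale all counts so they sum to ``target_total``.

    Relative abundances are preserved exactly in fractional space; the
    drop report is carried through unscaled.
    """
    current = table.total()
    if current <= 0:
        raise ConfigurationError("cannot scale an empty count table")
    if target_total <= 0:
        raise ConfigurationError("target_total must be positive")
    factor = target_total / current
    out = table.copy()
    out.counts = {t: c * factor for t, c in table.counts.items()}
    return out


def _resolve_genome(
    taxid: int, catalog: GenomeCatalog, tree: TaxonomyTree | None
) -> GenomeRecord:
    candidates = genomes_for(catalog, taxid, tree)
    if not candidates:
        raise ValueError(f"no genome resolvable for taxid {taxid}")
    return min(candidates, key=GenomeRecord.sort_key)


def integerize(
    table: CountTable,
    catalog: GenomeCatalog,
    tree: TaxonomyTree | None = None,
) -> GenomeBudget:
    """Largest-remainder apportionment of fractional counts to whole reads.

    Every remaining taxid must resolve to at least one assembly (the
    catalog's deterministic preference picks among several). All counts
    are floored, then the remaining ``round(total) - sum(floors)`` units
    go one each to the largest fractional remainders, ties broken by
    larger count then accession. The allocation totals ``round(total)``
    and each genome's allocation differs from its fractional count by
    less than 1.
    """
    per_accession: dict[str, float] = {}
    source_taxid: dict[str, int] = {}
    for taxid in sorted(table.counts):
        record = _resolve_genome(taxid, catalog, tree)
        per_accession[record.accession] = (
            per_accession.get(record.accession, 0.0) + table.counts[taxid]
        )
        source_taxid.setdefault(record.accession, taxid)

    # half units round up: a lone 0.5-read taxon still gets its read
    total = math.floor(sum(per_accession.values()) + 0.5)
    allocations = {acc: math.floor(c) for acc, c in per_accession.items()}
    remaining = total - sum(allocations.values())
    remainders = sorted(
        per_accession.items(),
        key=lambda kv: (-(kv[1] - math.floor(kv[1])), -kv[1], kv[0]),
    )
    for acc, _count in remainders[:remaining]:
        allocations[acc] += 1

    return GenomeBudget(
        allocations=allocations,
        source_taxid=source_taxid,
        drop_report=list(table.drop_report),
    )
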