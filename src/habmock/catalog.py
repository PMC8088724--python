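"""Local reference-genome catalog keyed by taxid via an assembly summary.

The catalog is built from an ``assembly_summary.txt``-dialect table (the
NCBI RefSeq catalog format) plus a directory of FASTA files named by
assembly accession (``<accession>*.fna`` or ``.fna.gz``). Rows whose FASTA
is absent are reported as unavailable rather than failing, so a partial
local mirror still works. No network access happens anywhere in this
module.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

from habmock.errors import DataError, ParseError
from habmock.taxonomy import TaxonomyTree

# deterministic preference among multiple assemblies of one taxid
_CATEGORY_ORDER = {"reference genome": 0, "representative genome": 1}

_IUPAC_DNA = set("ACGTURYSWKMBDHVN")


@dataclass
class GenomeRecord:
    """One reference assembly and, once measured, its contig lengths."""

    accession: str
    taxid: int
    species_taxid: int
    fasta_path: Path
    total_length: int = 0
    refseq_category: str = "na"
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def measured(self) -> bool:
        return bool(self.contig_lengths)

    def sort_key(self) -> tuple[int, str]:
        return (_CATEGORY_ORDER.get(self.refseq_category, 2), self.accession)


@dataclass
class GenomeCatalog:
    by_taxid: dict[int, list[GenomeRecord]] = field(default_factory=dict)
    by_species: dict[int, list[GenomeRecord]] = field(default_factory=dict)
    unavailable: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len({r.accession for recs in self.by_taxid.values() for r in recs})

    def records(self) -> list[GenomeRecord]:
        seen: dict[str, GenomeRecord] = {}
        for recs in self.by_taxid.values():
            for r in recs:
                seen[r.accession] = r
        return sorted(seen.values(), key=GenomeRecord.sort_key)

    def add(self, record: GenomeRecord) -> None:
        self.by_taxid.setdefault(record.taxid, []).append(record)
        self.by_species.setdefault(record.species_taxid, []).append(record)
        self.by_taxid[record.taxid].sort(key=GenomeRecord.sort_key)
        self.by_species[record.species_taxid].sort(key=GenomeRecord.sort_key)

    def strain_records_of(self, species_taxid: int) -> list[GenomeRecord]:
        """Assemblies of the species that sit below the species taxid itself."""
        return [
            r
            for r in self.by_species.get(species_taxid, [])
            if r.taxid != species_taxid
        ]


def _find_fasta(genomes_dir: Path, accession: str) -> Path | None:
    for pattern in (f"{accession}*.fna", f"{accession}*.fna.gz",
                    f"{accession}*.fa", f"{accession}*.fasta"):
        hits = sorted(genomes_dir.glob(pattern))
        if hits:
            return hits[0]
    return None


def parse_assembly_summary(
    path: str | Path,
    genomes_dir: str | Path,
    tree: TaxonomyTree | None = None,
) -> GenomeCatalog:
    """Build a :class:`GenomeCatalog` from an assembly-summary table.

    Comment lines start with ``#``; the header is the comment line carrying
    the column names. One record is created per row whose FASTA exists
    under ``genomes_dir``; the rest are listed in ``catalog.unavailable``.
    An empty ``species_taxid`` column is recomputed from the taxonomy when
    a tree is supplied.
    """
    path = Path(path)
    genomes_dir = Path(genomes_dir)
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("# ").rstrip()
                if "assembly_accession" in stripped:
                    header = stripped.split("\t")
                continue
            if header is None:
                raise ParseError(f"{path}: data row before header line")
            values = line.split("\t")
            rows.append(dict(zip(header, values)))

    if header is None:
        raise ParseError(f"{path}: no header line with 'assembly_accession'")
    for col in ("assembly_accession", "taxid"):
        if col not in header:
            raise ParseError(f"{path}: missing required column {col!r}")

    catalog = GenomeCatalog()
    seen_accessions: set[str] = set()
    for row in rows:
        accession = row["assembly_accession"]
        if accession in seen_accessions:
            raise ParseError(f"{path}: duplicate accession {accession}")
        seen_accessions.add(accession)
        taxid = int(row["taxid"])
        species_raw = row.get("species_taxid", "").strip()
        if species_raw:
            species_taxid = int(species_raw)
        elif tree is not None and taxid in tree:
            species_taxid = tree.species_ancestor(taxid) or taxid
        else:
            species_taxid = taxid
        fasta = _find_fasta(genomes_dir, accession)
        if fasta is None:
            catalog.unavailable.append(accession)
            continue
        catalog.add(
            GenomeRecord(
                accession=accession,
                taxid=taxid,
                species_taxid=species_taxid,
                fasta_path=fasta,
                refseq_category=row.get("refseq_category", "na") or "na",
            )
        )
    return catalog


def genomes_for(
    catalog: GenomeCatalog, taxid: int, tree: TaxonomyTree | None = None
) -> list[GenomeRecord]:
    """Assemblies usable for ``taxid``: exact matches, else — when the
    taxid is a species — all assemblies filed under that species."""
    exact = catalog.by_taxid.get(taxid, [])
    if exact:
        return list(exact)
    if tree is not None and taxid in tree and tree.rank_of(taxid) == "species":
        return list(catalog.by_species.get(taxid, []))
    return []


def open_fasta(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def measure_genome(record: GenomeRecord) -> GenomeRecord:
    """Return a copy of ``record`` with per-contig and total lengths set.

    Lengths are case-insensitive (soft-masked lowercase counts normally);
    characters outside the IUPAC nucleotide alphabet raise
    :class:`DataError`, as does an empty FASTA.
    """
    contig_lengths: dict[str, int] = {}
    with open_fasta(record.fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - _IUPAC_DNA
            if bad:
                raise DataError(
                    f"{record.fasta_path}: contig {rec.id} has non-nucleotide "
                    f"characters {sorted(bad)}"
                )
            contig_lengths[rec.id] = len(seq)
    if not contig_lengths:
        raise DataError(f"{record.fasta_path}: no sequences")
    return replace(
        record,
        contig_lengths=contig_lengths,
        total_length=sum(contig_lengths.values()),
    )


def load_sequences(record: GenomeRecord) -> dict[str, str]:
    """Contig id -> upper-case sequence, for position-addressed extraction."""
    with open_fasta(record.fasta_path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
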