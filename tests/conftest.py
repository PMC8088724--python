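import pytest

from habmock.catalog import GenomeCatalog, GenomeRecord
from habmock.fixtures import FixtureSpec, generate_fixture
from habmock.taxonomy import TaxNode, TaxonomyTree


SUPERKINGDOM_NAMES = {2: "Bacteria", 2157: "Archaea", 2759: "Eukaryota", 10239: "Viruses"}


def make_tree(spec: dict[int, tuple[int, str]], names: dict[int, str] | None = None) -> TaxonomyTree:
    """Build a TaxonomyTree from {taxid: (parent, rank)}.

    Superkingdom nodes at the canonical NCBI taxids get their canonical
    names automatically; everything else is named by its taxid.
    """
    names = {**SUPERKINGDOM_NAMES, **(names or {})}
    nodes = {t: TaxNode(p, r, names.get(t, str(t))) for t, (p, r) in spec.items()}
    if 1 not in nodes:
        nodes[1] = TaxNode(1, "no rank", "root")
    return TaxonomyTree(nodes=nodes)


def make_catalog(entries, tmp_path=None) -> GenomeCatalog:
    """Build a GenomeCatalog from (accession, taxid, species_taxid) tuples.

    fasta_path points nowhere unless tmp_path is given; fine for tests
    that never read sequence.
    """
    catalog = GenomeCatalog()
    for accession, taxid, species_taxid in entries:
        path = (tmp_path / f"{accession}.fna") if tmp_path else f"{accession}.fna"
        catalog.add(GenomeRecord(accession, taxid, species_taxid, path))
    return catalog


@pytest.fixture(scope="session")
def basic_tree() -> TaxonomyTree:
    """root -> Bacteria(2)/Archaea(2157)/Eukaryota(2759) with one genus,
    two species, strains below; plus a human-like eukaryote strainless
    species and a rankless limb for edge cases."""
    return make_tree(
        {
            1: (1, "no rank"),
            2: (1, "superkingdom"),
            2157: (1, "superkingdom"),
            2759: (1, "superkingdom"),
            1000: (2, "genus"),
            2001: (1000, "species"),
            2002: (1000, "species"),
            3001: (2001, "strain"),
            3002: (2001, "no rank"),
            3003: (2002, "subspecies"),
            4001: (2157, "genus"),
            4002: (4001, "species"),
            4003: (4002, "no rank"),
            9606: (2759, "species"),
            5000: (1, "no rank"),  # no superkingdom on path
        }
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default-parameter fixture bundle shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_fixture(FixtureSpec(seed=11), out)


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """Closed-loop bundle: full references, no dark matter, no multimap."""
    out = tmp_path_factory.mktemp("clean_bundle")
    spec = FixtureSpec(
        missing_genome_fraction=0.0,
        unclassified_fraction=0.0,
        multimap_fraction=0.0,
        n_fragments=1500,
        seed=5,
    )
    return generate_fixture(spec, out)
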