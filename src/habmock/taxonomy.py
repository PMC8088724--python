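"""NCBI-format taxonomy: parsing and the rank/lineage queries profiling needs.

The taxonomy is consumed from ``nodes.dmp``/``names.dmp`` dump files
(fields separated by ``\\t|\\t``, lines terminated ``\\t|``). Queries are
positional rather than label-based where it matters: any node strictly
below a species node is treated as a strain, regardless of whether NCBI
labels it "strain", "subspecies" or "no rank".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from habmock.errors import ParseError, StructuralError

ROOT_TAXID = 1


@dataclass(frozen=True)
class TaxNode:
    parent: int
    rank: str
    name: str


@dataclass
class TaxonomyTree:
    """Node table (taxid -> parent, rank, name) with lineage queries.

    Invariants: every non-root parent exists; following parents from any
    node reaches the root in finitely many steps (checked at load time).
    """

    nodes: dict[int, TaxNode]
    root: int = ROOT_TAXID
    # caches for repeated queries on large trees
    _species_cache: dict[int, int | None] = field(default_factory=dict, repr=False)
    _kingdom_cache: dict[int, str | None] = field(default_factory=dict, repr=False)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def _node(self, taxid: int) -> TaxNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise KeyError(f"taxid {taxid} not in taxonomy") from None

    def name_of(self, taxid: int) -> str:
        return self._node(taxid).name

    def rank_of(self, taxid: int) -> str:
        return self._node(taxid).rank

    def lineage(self, taxid: int) -> list[int]:
        """Path from ``taxid`` up to and including the root."""
        self._node(taxid)
        path = [taxid]
        while taxid != self.root:
            taxid = self.nodes[taxid].parent
            path.append(taxid)
        return path

    def species_ancestor(self, taxid: int) -> int | None:
        """Nearest ancestor-or-self of rank "species"; None if absent."""
        if taxid in self._species_cache:
            return self._species_cache[taxid]
        result = None
        for t in self.lineage(taxid):
            if self.nodes[t].rank == "species":
                result = t
                break
        self._species_cache[taxid] = result
        return result

    def at_or_below_species(self, taxid: int) -> bool:
        """True iff the node sits at species rank or anywhere below it."""
        return self.species_ancestor(taxid) is not None

    def is_strain(self, taxid: int) -> bool:
        """True iff the node sits strictly below a species node."""
        sp = self.species_ancestor(taxid)
        return sp is not None and sp != taxid

    def superkingdom_of(self, taxid: int) -> str | None:
        """Name of the nearest ancestor-or-self of rank "superkingdom"."""
        if taxid in self._kingdom_cache:
            return self._kingdom_cache[taxid]
        result = None
        for t in self.lineage(taxid):
            if self.nodes[t].rank == "superkingdom":
                result = self.nodes[t].name
                break
        self._kingdom_cache[taxid] = result
        return result


# module-level functional aliases mirroring the method API
def species_ancestor(tree: TaxonomyTree, taxid: int) -> int | None:
    return tree.species_ancestor(taxid)


def at_or_below_species(tree: TaxonomyTree, taxid: int) -> bool:
    return tree.at_or_below_species(taxid)


def superkingdom_of(tree: TaxonomyTree, taxid: int) -> str | None:
    return tree.superkingdom_of(taxid)


def _split_dmp_line(line: str, path: Path, lineno: int) -> list[str]:
    line = line.rstrip()
    if line.endswith("|"):
        line = line[:-1].rstrip("\t")
    fields = [f.strip() for f in line.split("\t|\t")]
    # tolerate plain pipe-delimited variants some tools emit
    if len(fields) == 1 and "|" in line:
        fields = [f.strip() for f in line.split("|")]
    if not fields or fields == [""]:
        raise ParseError(f"{path}:{lineno}: empty record")
    return fields


def load_taxonomy(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Parse ``nodes.dmp`` and ``names.dmp`` into a :class:`TaxonomyTree`.

    Every taxid in the nodes file appears in the result; scientific names
    are attached where present, otherwise the name falls back to the taxid
    rendered as text. Raises :class:`ParseError` on malformed lines and
    :class:`StructuralError` on a missing root, missing parents or cycles.
    """
    nodes_path = Path(nodes_path)
    names_path = Path(names_path)

    parents: dict[int, int] = {}
    ranks: dict[int, str] = {}
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp_line(line, nodes_path, lineno)
            if len(fields) < 3:
                raise ParseError(
                    f"{nodes_path}:{lineno}: expected >=3 fields "
                    f"(taxid, parent, rank), got {len(fields)}"
                )
            try:
                taxid = int(fields[0])
                parent = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{nodes_path}:{lineno}: non-integer taxid or parent"
                ) from None
            parents[taxid] = parent
            ranks[taxid] = fields[2]

    if ROOT_TAXID not in parents:
        raise StructuralError(f"{nodes_path}: missing root taxid {ROOT_TAXID}")

    names: dict[int, str] = {}
    with open(names_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp_line(line, names_path, lineno)
            if len(fields) < 2:
                raise ParseError(f"{names_path}:{lineno}: expected >=2 fields")
            name_class = fields[3] if len(fields) >= 4 else "scientific name"
            if name_class == "scientific name":
                try:
                    names[int(fields[0])] = fields[1]
                except ValueError:
                    raise ParseError(
                        f"{names_path}:{lineno}: non-integer taxid"
                    ) from None

    nodes: dict[int, TaxNode] = {}
    for taxid, parent in parents.items():
        if taxid == ROOT_TAXID:
            parent = ROOT_TAXID  # NCBI convention: root is its own parent
        elif parent not in parents:
            raise StructuralError(
                f"{nodes_path}: node {taxid} has unknown parent {parent}"
            )
        nodes[taxid] = TaxNode(parent, ranks[taxid], names.get(taxid, str(taxid)))

    _check_acyclic(nodes)
    return TaxonomyTree(nodes=nodes, root=ROOT_TAXID)


def _check_acyclic(nodes: dict[int, TaxNode]) -> None:
    """Walk each node to the root once, with a visited set; cycles raise."""
    reaches_root: set[int] = {ROOT_TAXID}
    for start in nodes:
        path = []
        t = start
        seen_on_path: set[int] = set()
        while t not in reaches_root:
            if t in seen_on_path:
                raise StructuralError(f"taxonomy cycle involving taxid {t}")
            seen_on_path.add(t)
            path.append(t)
            t = nodes[t].parent
        reaches_root.update(path)
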