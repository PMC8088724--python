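"""Per-read classification input in Centrifuge's tab-separated dialect.

A classifier reports one row per (read, reference hit); a read matched
against k references occupies k consecutive rows sharing a readID. A read
hitting several references of the *same* taxon still represents a single
taxonomic assignment, so rows are collapsed to the distinct taxIDs of the
read and the read's unit of count mass is split equally among them:
a read classified to three different taxa contributes one third to each.

For paired-end data the classifier judges the fragment (both mates)
jointly and emits a single readID per pair, so one ReadAssignment stands
for one fragment throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from habmock.errors import ParseError

REQUIRED_COLUMNS = ("readID", "seqID", "taxID")


@dataclass(frozen=True)
class ReadAssignment:
    """One classified fragment: its distinct taxa and per-taxon weight."""

    read_id: str
    taxa: frozenset[int]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if not self.taxa:
            raise ValueError("taxa must be non-empty")

    @property
    def weight_per_taxon(self) -> float:
        return 1.0 / len(self.taxa)


@dataclass
class ClassificationSet:
    """All fragments of a sample, split into assigned and unclassified."""

    assigned: list[ReadAssignment] = field(default_factory=list)
    unclassified_ids: set[str] = field(default_factory=set)

    @property
    def assigned_ids(self) -> set[str]:
        return {a.read_id for a in self.assigned}

    def total_fragments(self) -> int:
        return len(self.assigned) + len(self.unclassified_ids)


def parse_centrifuge(path: str | Path) -> ClassificationSet:
    """Parse a Centrifuge-format classification table.

    Rows with ``taxID`` 0 or ``seqID`` "unclassified" populate the
    unclassified set; all other rows of a read are grouped into one
    :class:`ReadAssignment` over that read's distinct taxIDs. A read whose
    row count disagrees with its reported ``numMatches`` triggers a
    warning; the row count wins.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"readID": str, "seqID": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty classification file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    df["taxID"] = pd.to_numeric(df["taxID"], errors="raise").astype(int)

    unclassified_mask = (df["taxID"] == 0) | (df["seqID"] == "unclassified")
    unclassified_ids = set(df.loc[unclassified_mask, "readID"])

    hits = df.loc[~unclassified_mask]
    assigned: list[ReadAssignment] = []
    if len(hits):
        grouped = hits.groupby("readID", sort=False)
        if "numMatches" in hits.columns:
            sizes = grouped.size()
            declared = grouped["numMatches"].first()
            bad = sizes.index[(sizes != declared).to_numpy()]
            if len(bad):
                warnings.warn(
                    f"{path}: {len(bad)} read(s) whose row count disagrees with "
                    f"numMatches (e.g. {bad[0]!r}); using row counts",
                    stacklevel=2,
                )
        for read_id, taxids in grouped["taxID"].unique().items():
            assigned.append(ReadAssignment(str(read_id), frozenset(int(t) for t in taxids)))

    # a read with both hit and unclassified rows counts as assigned
    unclassified_ids -= {a.read_id for a in assigned}
    return ClassificationSet(assigned=assigned, unclassified_ids=unclassified_ids)


def split_by_read_ids(
    classification: ClassificationSet, fastq_ids: set[str]
) -> tuple[ClassificationSet, int]:
    """Drop assignments whose read id is absent from the FASTQ.

    Returns the filtered set and the number of dropped records (orphan
    assignments plus orphan unclassified ids).
    """
    kept_assigned = [a for a in classification.assigned if a.read_id in fastq_ids]
    kept_uncls = classification.unclassified_ids & fastq_ids
    dropped = (len(classification.assigned) - len(kept_assigned)) + (
        len(classification.unclassified_ids) - len(kept_uncls)
    )
    return ClassificationSet(assigned=kept_assigned, unclassified_ids=kept_uncls), dropped
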