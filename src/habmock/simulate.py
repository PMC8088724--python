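"""Empirical Illumina-style read simulation from reference genomes.

The simulator learns read lengths and positionwise Phred quality
distributions directly from the input sample, then draws fragments
uniformly from reference contigs (probability proportional to contig
length) and introduces substitution errors at the rate each sampled
quality score implies (``p = 10^(-Q/10)``). Substitutions are uniform
over the three alternative bases; ``N`` and other ambiguity codes pass
through untouched. Indels are not modelled: substitutions dominate
Illumina error and keeping reads colinear with their source makes the
per-read truth coordinates exact.

Read ids encode the source for ground truth:
``<accession>|<contig>|<fragment_start_0based>|<strand>|<serial>``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from habmock.catalog import GenomeRecord, load_sequences, open_fasta
from habmock.errors import DataError, SimulationError

MAX_PHRED = 60
_PLACEMENT_TRIES = 100

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVNacgturyswkmbdhvn",
                            "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class _Categorical:
    """Vectorized sampler over a finite value -> probability mapping."""

    def __init__(self, dist: dict[int, float]):
        items = sorted(dist.items())
        self.values = np.array([v for v, _ in items])
        probs = np.array([p for _, p in items], dtype=float)
        self.cdf = np.cumsum(probs / probs.sum())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.values[np.searchsorted(self.cdf, rng.random(n), side="right")]

    def sample_one(self, rng: np.random.Generator) -> int:
        return int(self.sample(rng, 1)[0])


@dataclass
class ErrorProfile:
    """Read-length and per-position quality distributions of a sample.

    ``length_dist`` maps read length to probability; ``qual_dist`` holds
    one Phred-score distribution per read position. Paired profiles carry
    a second set for mate 2 plus insert-size parameters. Insert size is
    not observable from unaligned FASTQ, so ``mean_insert`` defaults to a
    conventional short-insert library (see ``learn_profile``).
    """

    length_dist: dict[int, float]
    qual_dist: list[dict[int, float]]
    paired: bool = False
    length_dist2: dict[int, float] | None = None
    qual_dist2: list[dict[int, float]] | None = None
    mean_insert: float = 0.0
    sd_insert: float = 0.0

    def __post_init__(self) -> None:
        self._len1 = _Categorical(self.length_dist)
        self._qmat1 = _pack_positional(self.qual_dist)
        self._len2 = _Categorical(self.length_dist2) if self.length_dist2 else None
        self._qmat2 = _pack_positional(self.qual_dist2) if self.qual_dist2 else None

    @property
    def mean_read_length(self) -> float:
        m1 = sum(length * p for length, p in self.length_dist.items())
        if not self.paired:
            return m1
        m2 = sum(length * p for length, p in (self.length_dist2 or self.length_dist).items())
        return (m1 + m2) / 2.0

    def expected_error_rate(self, mate: int = 1) -> float:
        """Mean substitution probability implied by the quality profile,
        averaged over positions weighted by how often each is covered."""
        quals = self.qual_dist if mate == 1 or not self.qual_dist2 else self.qual_dist2
        lengths = self.length_dist if mate == 1 or not self.length_dist2 else self.length_dist2
        # P(position p is covered) = P(length > p)
        weights = []
        for p in range(len(quals)):
            weights.append(sum(prob for length, prob in lengths.items() if length > p))
        total_w = sum(weights)
        rate = 0.0
        for p, dist in enumerate(quals):
            pos_rate = sum(prob * 10 ** (-q / 10) for q, prob in dist.items())
            rate += weights[p] * pos_rate
        return rate / total_w

    def _sample_length(self, rng: np.random.Generator, mate: int) -> int:
        sampler = self._len2 if (mate == 2 and self._len2) else self._len1
        return sampler.sample_one(rng)

    def _sample_qualities(self, rng: np.random.Generator, length: int, mate: int) -> np.ndarray:
        values, cdfs = self._qmat2 if (mate == 2 and self._qmat2) else self._qmat1
        pos = np.minimum(np.arange(length), len(values) - 1)
        u = rng.random(length)
        idx = (cdfs[pos] < u[:, None]).sum(axis=1)
        return values[pos, np.minimum(idx, values.shape[1] - 1)]


def _pack_positional(dists: list[dict[int, float]]) -> tuple[np.ndarray, np.ndarray]:
    """Pad per-position categorical distributions into (values, cdf)
    matrices so one read's qualities can be drawn in a single shot."""
    width = max(len(d) for d in dists)
    values = np.zeros((len(dists), width), dtype=np.int64)
    cdfs = np.ones((len(dists), width), dtype=float)
    for p, dist in enumerate(dists):
        items = sorted(dist.items())
        vals = np.array([v for v, _ in items])
        probs = np.array([pr for _, pr in items], dtype=float)
        cdf = np.cumsum(probs / probs.sum())
        values[p, : len(vals)] = vals
        values[p, len(vals) :] = vals[-1]
        cdfs[p, : len(vals)] = cdf
    return values, cdfs


def _scan_fastq(path: str | Path, max_reads: int):
    lengths: dict[int, int] = {}
    qual_counts: list[dict[int, int]] = []
    n = 0
    with open_fasta(Path(path)) as fh:
        for _title, seq, qual in FastqGeneralIterator(fh):
            if n >= max_reads:
                break
            n += 1
            lengths[len(seq)] = lengths.get(len(seq), 0) + 1
            if len(qual) > len(qual_counts):
                qual_counts.extend({} for _ in range(len(qual) - len(qual_counts)))
            for p, ch in enumerate(qual):
                q = ord(ch) - 33
                if q < 0:
                    raise DataError(f"{path}: invalid quality character {ch!r}")
                q = min(q, MAX_PHRED)
                qual_counts[p][q] = qual_counts[p].get(q, 0) + 1
    if n == 0:
        raise DataError(f"{path}: no reads")
    length_dist = {length: c / n for length, c in sorted(lengths.items())}
    qual_dist = [
        {q: c / sum(counts.values()) for q, c in sorted(counts.items())}
        for counts in qual_counts
    ]
    return length_dist, qual_dist, n


def learn_profile(
    fastq_paths: list[str | Path],
    max_reads: int = 100_000,
    mean_insert: float | None = None,
    sd_insert: float | None = None,
) -> ErrorProfile:
    """Learn an :class:`ErrorProfile` from one (single-end) or two
    (paired-end) FASTQ files, capped at ``max_reads`` reads per file.

    Distributions are plain empirical frequencies. For paired data the
    two mates get independent length and quality profiles and must agree
    in read count over the sampled window. Insert size cannot be learned
    from unaligned reads, so unless overridden it defaults to
    ``2 x mean read length + 100`` bp (sd 10% of the mean), a typical
    short-insert Illumina library.
    """
    if not fastq_paths:
        raise DataError("at least one FASTQ path required")
    if max_reads <= 0:
        raise DataError("max_reads must be positive")
    if len(fastq_paths) == 1:
        length_dist, qual_dist, _ = _scan_fastq(fastq_paths[0], max_reads)
        return ErrorProfile(length_dist=length_dist, qual_dist=qual_dist, paired=False)
    if len(fastq_paths) != 2:
        raise DataError(f"expected 1 or 2 FASTQ paths, got {len(fastq_paths)}")

    l1, q1, n1 = _scan_fastq(fastq_paths[0], max_reads)
    l2, q2, n2 = _scan_fastq(fastq_paths[1], max_reads)
    if n1 != n2:
        raise DataError(
            f"mate files disagree in read count over the learning window "
            f"({n1} vs {n2})"
        )
    mean_len = (sum(k * v for k, v in l1.items()) + sum(k * v for k, v in l2.items())) / 2
    mi = mean_insert if mean_insert is not None else 2 * mean_len + 100
    si = sd_insert if sd_insert is not None else 0.1 * mi
    return ErrorProfile(
        length_dist=l1,
        qual_dist=q1,
        paired=True,
        length_dist2=l2,
        qual_dist2=q2,
        mean_insert=mi,
        sd_insert=si,
    )


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    qualities: str
    source_accession: str
    contig: str
    start: int  # 0-based, on the forward reference strand
    strand: str  # orientation of this read: '+' or '-'
    mate: int  # 1, 2, or 0 for single-end


@dataclass(frozen=True)
class Fragment:
    """A placed fragment: where it sits and the read length(s) drawn."""

    contig: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    lengths: tuple[int, ...]  # (len,) single-end, (len1, len2) paired
    span: int  # fragment extent on the reference (= insert size if paired)


def sample_fragment(
    genome: GenomeRecord, profile: ErrorProfile, rng: np.random.Generator
) -> Fragment:
    """Draw a fragment placement from a measured genome.

    The contig is chosen with probability proportional to its length and
    the start uniformly among valid positions. Draws that do not fit are
    resampled up to a bounded number of tries; a genome shorter than
    every sampled length raises :class:`SimulationError`.
    """
    if not genome.measured:
        raise SimulationError(f"{genome.accession}: genome not measured")
    contigs = sorted(genome.contig_lengths)
    clens = np.array([genome.contig_lengths[c] for c in contigs], dtype=float)
    cprobs = clens / clens.sum()
    for _ in range(_PLACEMENT_TRIES):
        idx = rng.choice(len(contigs), p=cprobs)
        clen = int(clens[idx])
        len1 = profile._sample_length(rng, 1)
        if profile.paired:
            len2 = profile._sample_length(rng, 2)
            insert = max(
                len1 + len2, int(round(rng.normal(profile.mean_insert, profile.sd_insert)))
            )
            span, lengths = insert, (len1, len2)
        else:
            span, lengths = len1, (len1,)
        if span > clen:
            continue
        start = int(rng.integers(0, clen - span + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        return Fragment(contigs[idx], start, strand, lengths, span)
    raise SimulationError(
        f"{genome.accession}: no contig can host a sampled fragment after "
        f"{_PLACEMENT_TRIES} tries (genome too short for the read length profile)"
    )


_ALT_BASES = {
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
}


def apply_errors(template: str, qualities: str, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``10^(-Q/10)``.

    Substitutions are uniform over the three other canonical bases;
    non-ACGT characters (``N`` and IUPAC ambiguity codes) pass through.
    """
    if len(template) != len(qualities):
        raise DataError("template and qualities differ in length")
    q = np.frombuffer(qualities.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
    if (q < 0).any():
        raise DataError("invalid quality character below '!'")
    return _apply_errors_array(template, q, rng)


def _apply_errors_array(template: str, q: np.ndarray, rng: np.random.Generator) -> str:
    p = 10.0 ** (-q / 10.0)
    hits = np.nonzero(rng.random(len(template)) < p)[0]
    if len(hits) == 0:
        return template
    picks = rng.integers(0, 3, size=len(hits))
    chars = list(template)
    for i, pick in zip(hits, picks):
        alts = _ALT_BASES.get(chars[i])
        if alts is not None:
            chars[i] = alts[pick]
    return "".join(chars)


def _phred_string(q: np.ndarray) -> str:
    return (q + 33).astype(np.uint8).tobytes().decode("ascii")


def simulate_genome_reads(
    genome: GenomeRecord,
    n_fragments: int,
    profile: ErrorProfile,
    seed: int,
    sequences: dict[str, str] | None = None,
    start_serial: int = 0,
) -> Iterator[SimulatedRead]:
    """Simulate ``n_fragments`` fragments from one genome.

    Yields one read per fragment (single-end) or two (paired-end, FR
    orientation). Deterministic for a given seed: identical seeds give
    byte-identical reads.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")
    if n_fragments == 0:
        return
    rng = np.random.default_rng(seed)
    if sequences is None:
        sequences = load_sequences(genome)

    for serial in range(start_serial, start_serial + n_fragments):
        frag = sample_fragment(genome, profile, rng)
        seq = sequences[frag.contig]
        stem = f"{genome.accession}|{frag.contig}|{frag.start}|{frag.strand}|{serial}"
        if not profile.paired:
            (len1,) = frag.lengths
            template = seq[frag.start : frag.start + len1]
            if frag.strand == "-":
                template = reverse_complement(template)
            q = profile._sample_qualities(rng, len1, 1)
            yield SimulatedRead(
                read_id=stem,
                sequence=_apply_errors_array(template, q, rng),
                qualities=_phred_string(q),
                source_accession=genome.accession,
                contig=frag.contig,
                start=frag.start,
                strand=frag.strand,
                mate=0,
            )
            continue

        # paired-end, FR orientation: mate 1 reads inward from the
        # fragment's 5' end on the fragment strand, mate 2 from the other
        len1, len2 = frag.lengths
        fend = frag.start + frag.span
        if frag.strand == "+":
            placements = [
                (1, len1, frag.start, "+"),
                (2, len2, fend - len2, "-"),
            ]
        else:
            placements = [
                (1, len1, fend - len1, "-"),
                (2, len2, frag.start, "+"),
            ]
        for mate, rlen, rstart, rstrand in placements:
            template = seq[rstart : rstart + rlen]
            if rstrand == "-":
                template = reverse_complement(template)
            q = profile._sample_qualities(rng, rlen, mate)
            yield SimulatedRead(
                read_id=stem,
                sequence=_apply_errors_array(template, q, rng),
                qualities=_phred_string(q),
                source_accession=genome.accession,
                contig=frag.contig,
                start=rstart,
                strand=rstrand,
                mate=mate,
            )


def coverage_of(n_fragments: int, profile: ErrorProfile, genome: GenomeRecord) -> float:
    """Fold-coverage of ``genome`` by ``n_fragments`` simulated fragments:
    fragments x mean read length x reads-per-fragment / assembly length."""
    if not genome.measured or genome.total_length <= 0:
        raise SimulationError(f"{genome.accession}: genome not measured")
    reads_per_fragment = 2 if profile.paired else 1
    return n_fragments * profile.mean_read_length * reads_per_fragment / genome.total_length
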