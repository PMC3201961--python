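"""Marker lists, seg files, count files, FASTQ demultiplexing and marker validation.

A *seg file* is the tab-delimited four-spore segregation profile consumed by
the crossover engine: one line per marker giving chromosome, position, a
placeholder column, and the genotype code of each of the four spores
(0 = first-named parent, 1 = second parent).  Two dialects circulate: the
GenotypeCaller dialect (``spaceholder`` third column, LF line ends) and the
Allelescan dialect (empty third column, CRLF line ends).  Both are accepted
on read; writing always emits the GenotypeCaller dialect.

A *count file* tabulates, per marker and per reference-genome pool, the
read observations at that marker: how many reads matched each parental
allele and the summed base qualities of those reads.  Aggregate lines are
sufficient for every scoring formula downstream; an optional verbose mode
records one line per read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "MarkerClass",
    "MarkerRecord",
    "SegRecord",
    "PileupObservation",
    "PoolCounts",
    "GenomeAnnotation",
    "Tetrad",
    "SegParseError",
    "read_seg",
    "write_seg",
    "read_marker_list",
    "write_marker_list",
    "read_counts",
    "write_counts",
    "aggregate_observations",
    "read_annotation",
    "write_annotation",
    "demultiplex_fastq",
    "validate_markers",
    "normalize_chromosome",
]

# Genome pools: reads are split by which parental reference they aligned to.
POOL_A = "A"
POOL_B = "B"
POOLS = (POOL_A, POOL_B)

# Base classes at a marker position.
MATCHES_A = "matches_A"
MATCHES_B = "matches_B"
OTHER = "other"
BASE_CLASSES = (MATCHES_A, MATCHES_B, OTHER)


class MarkerClass:
    SNP = "SNP"
    INSERTION = "insertion"
    DELETION = "deletion"
    TELOMERIC_SNP = "telomeric_SNP"

    ALL = (SNP, INSERTION, DELETION, TELOMERIC_SNP)


_ROMAN = {
    "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6, "VII": 7,
    "VIII": 8, "IX": 9, "X": 10, "XI": 11, "XII": 12, "XIII": 13,
    "XIV": 14, "XV": 15, "XVI": 16,
}


def normalize_chromosome(token: str | int) -> int:
    """Map a chromosome identifier (``5``, ``"5"``, ``"V"``, ``"chrV"``) to an int."""
    if isinstance(token, (int, np.integer)):
        return int(token)
    tok = token.strip()
    if tok.lower().startswith("chr"):
        tok = tok[3:]
    if tok.isdigit():
        return int(tok)
    roman = tok.upper()
    if roman in _ROMAN:
        return _ROMAN[roman]
    raise ValueError(f"unrecognized chromosome identifier: {token!r}")


@dataclass(frozen=True)
class MarkerRecord:
    """One expected polymorphism between the two parental genomes."""

    marker_id: str
    chromosome: int
    pos_A: int
    marker_class: str
    allele_A: str
    allele_B: str
    pos_B: int | None = None
    indel_length: int = 0

    def __post_init__(self) -> None:
        if self.pos_A < 1:
            raise ValueError(f"{self.marker_id}: pos_A must be >= 1")
        if self.allele_A == self.allele_B:
            raise ValueError(f"{self.marker_id}: parental alleles are identical")
        if self.marker_class not in MarkerClass.ALL:
            raise ValueError(f"{self.marker_id}: unknown marker class {self.marker_class!r}")
        if self.marker_class == MarkerClass.TELOMERIC_SNP and self.pos_B is not None:
            raise ValueError(f"{self.marker_id}: telomeric SNPs have no parent-B position")
        if self.marker_class in (MarkerClass.INSERTION, MarkerClass.DELETION):
            if self.indel_length < 1:
                raise ValueError(f"{self.marker_id}: indel_length must be >= 1")
        elif self.indel_length != 0:
            raise ValueError(f"{self.marker_id}: indel_length must be 0 for SNPs")


@dataclass(frozen=True)
class SegRecord:
    """One seg-file line: a marker and the four spores' genotype codes."""

    chromosome: int
    position: int
    genotypes: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.genotypes) != 4:
            raise ValueError("a seg record carries exactly four genotype codes")
        if any(g not in (0, 1) for g in self.genotypes):
            raise ValueError(f"genotype codes must be 0 or 1, got {self.genotypes}")


@dataclass(frozen=True)
class PileupObservation:
    """One read's evidence at one marker in one genome pool.

    ``quality`` is the per-read score contribution: the base quality at a SNP
    position, the quality at the reference base of an insertion, or (for
    deletion-supporting reads) it may be left None with the two border-base
    qualities carried in ``border_qualities``.
    """

    marker_id: str
    genome_pool: str
    base_class: str
    quality: float | None = None
    border_qualities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.genome_pool not in POOLS:
            raise ValueError(f"unknown genome pool {self.genome_pool!r}")
        if self.base_class not in BASE_CLASSES:
            raise ValueError(f"unknown base class {self.base_class!r}")
        if self.quality is not None and self.quality < 0:
            raise ValueError("quality must be non-negative")


@dataclass
class PoolCounts:
    """Aggregated pileup at one marker in one genome pool."""

    marker_id: str
    genome_pool: str
    count: dict = field(default_factory=lambda: {c: 0 for c in BASE_CLASSES})
    qsum: dict = field(default_factory=lambda: {c: 0.0 for c in BASE_CLASSES})

    def add(self, base_class: str, quality: float) -> None:
        self.count[base_class] += 1
        self.qsum[base_class] += quality

    @property
    def depth(self) -> int:
        return sum(self.count.values())


@dataclass(frozen=True)
class GenomeAnnotation:
    """Chromosome lengths and centromere positions (bp, 1-based midpoints)."""

    lengths: Mapping[int, int]
    centromeres: Mapping[int, int]

    def __post_init__(self) -> None:
        for chrom, cen in self.centromeres.items():
            length = self.lengths.get(chrom)
            if length is None:
                raise ValueError(f"centromere given for unknown chromosome {chrom}")
            if not 0 < cen < length:
                raise ValueError(
                    f"chromosome {chrom}: centromere {cen} outside (0, {length})"
                )

    def chromosomes(self) -> list[int]:
        return sorted(self.lengths)


class Tetrad:
    """Ordered per-chromosome segregation profile of one four-spore tetrad.

    Stores, per chromosome, a strictly increasing position vector and an
    ``(n, 4)`` genotype matrix with codes 0/1.
    """

    def __init__(self, data: Mapping[int, tuple[np.ndarray, np.ndarray]] | None = None):
        self._data: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (pos, geno) in sorted(data.items()):
                self.set_chromosome(chrom, pos, geno)

    def set_chromosome(self, chrom: int, positions, genotypes) -> None:
        pos = np.asarray(positions, dtype=np.int64)
        geno = np.asarray(genotypes, dtype=np.int8)
        if geno.ndim != 2 or geno.shape[1] != 4:
            raise ValueError("genotypes must be an (n, 4) array")
        if pos.shape[0] != geno.shape[0]:
            raise ValueError("positions and genotypes disagree in length")
        if pos.size and np.any(np.diff(pos) <= 0):
            bad = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            raise ValueError(
                f"chromosome {chrom}: positions not strictly increasing near index {bad}"
            )
        if geno.size and not np.isin(geno, (0, 1)).all():
            raise ValueError(f"chromosome {chrom}: genotype codes must be 0 or 1")
        self._data[chrom] = (pos, geno)

    @classmethod
    def from_records(cls, records: Iterable[SegRecord]) -> "Tetrad":
        by_chrom: dict[int, list[SegRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chromosome, []).append(rec)
        tetrad = cls()
        for chrom, recs in sorted(by_chrom.items()):
            recs.sort(key=lambda r: r.position)
            pos = np.array([r.position for r in recs], dtype=np.int64)
            if pos.size and np.any(np.diff(pos) == 0):
                dup = int(pos[np.flatnonzero(np.diff(pos) == 0)[0]])
                raise ValueError(f"duplicate position {dup} on chromosome {chrom}")
            geno = np.array([r.genotypes for r in recs], dtype=np.int8)
            tetrad.set_chromosome(chrom, pos, geno)
        return tetrad

    def chromosomes(self) -> list[int]:
        return sorted(self._data)

    def chromosome(self, chrom: int) -> tuple[np.ndarray, np.ndarray]:
        return self._data[chrom]

    def records(self) -> Iterator[SegRecord]:
        for chrom in self.chromosomes():
            pos, geno = self._data[chrom]
            for p, g in zip(pos.tolist(), geno.tolist()):
                yield SegRecord(chrom, p, tuple(int(x) for x in g))

    @property
    def n_markers(self) -> int:
        return sum(pos.size for pos, _ in self._data.values())

    def permute_spores(self, order: Sequence[int]) -> "Tetrad":
        """Return a tetrad with spore columns reordered (0-based permutation)."""
        if sorted(order) != [0, 1, 2, 3]:
            raise ValueError("order must be a permutation of 0..3")
        out = Tetrad()
        for chrom, (pos, geno) in self._data.items():
            out.set_chromosome(chrom, pos.copy(), geno[:, list(order)].copy())
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tetrad):
            return NotImplemented
        if self.chromosomes() != other.chromosomes():
            return False
        for chrom in self.chromosomes():
            p1, g1 = self._data[chrom]
            p2, g2 = other._data[chrom]
            if not (np.array_equal(p1, p2) and np.array_equal(g1, g2)):
                return False
        return True


class SegParseError(ValueError):
    """Raised when a seg file line cannot be parsed; names the line number."""


def read_seg(path) -> Tetrad:
    """Read a seg file (either dialect) into a :class:`Tetrad`.

    Records are sorted by (chromosome, position); duplicated positions within
    a chromosome are rejected.
    """
    records: list[SegRecord] = []
    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise SegParseError(
                    f"{path}: line {lineno}: expected >= 7 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom = normalize_chromosome(fields[0])
                position = int(fields[1])
            except ValueError as exc:
                raise SegParseError(f"{path}: line {lineno}: {exc}") from exc
            genos = []
            for tok in fields[3:7]:
                if tok not in ("0", "1"):
                    raise SegParseError(
                        f"{path}: line {lineno}: genotype code {tok!r} not in {{0,1}}"
                    )
                genos.append(int(tok))
            records.append(SegRecord(chrom, position, tuple(genos)))
    return Tetrad.from_records(records)


def write_seg(tetrad: Tetrad, path) -> None:
    """Write a tetrad in the GenotypeCaller dialect (LF, ``spaceholder`` column)."""
    with open(path, "w", newline="") as fh:
        for rec in tetrad.records():
            g = "\t".join(str(x) for x in rec.genotypes)
            fh.write(f"{rec.chromosome}\t{rec.position}\tspaceholder\t{g}\n")


# ---------------------------------------------------------------------------
# Marker lists
# ---------------------------------------------------------------------------

_MARKER_HEADER = "#marker_id\tchromosome\tpos_A\tpos_B\tmarker_class\tallele_A\tallele_B\tindel_length"


def write_marker_list(markers: Iterable[MarkerRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(_MARKER_HEADER + "\n")
        for m in markers:
            pos_b = "" if m.pos_B is None else str(m.pos_B)
            fh.write(
                f"{m.marker_id}\t{m.chromosome}\t{m.pos_A}\t{pos_b}\t"
                f"{m.marker_class}\t{m.allele_A}\t{m.allele_B}\t{m.indel_length}\n"
            )


def read_marker_list(path) -> list[MarkerRecord]:
    markers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 8:
                raise ValueError(f"{path}: line {lineno}: expected 8 fields, got {len(f)}")
            markers.append(
                MarkerRecord(
                    marker_id=f[0],
                    chromosome=normalize_chromosome(f[1]),
                    pos_A=int(f[2]),
                    pos_B=int(f[3]) if f[3] else None,
                    marker_class=f[4],
                    allele_A=f[5],
                    allele_B=f[6],
                    indel_length=int(f[7]),
                )
            )
    return markers


# ---------------------------------------------------------------------------
# Count files
# ---------------------------------------------------------------------------

_COUNT_HEADER = "#marker_id\tpool\tbase_class\tcount\tquality_sum"


def aggregate_observations(
    observations: Iterable[PileupObservation],
) -> dict[tuple[str, str], PoolCounts]:
    """Collapse per-read observations into per-(marker, pool) aggregates.

    Deletion-supporting reads carrying border qualities contribute the mean of
    the two border-base qualities; reads with a single border base are dropped
    with a warning.
    """
    out: dict[tuple[str, str], PoolCounts] = {}
    for obs in observations:
        q = obs.quality
        if q is None:
            if obs.border_qualities is None or len(obs.border_qualities) < 2:
                warnings.warn(
                    f"{obs.marker_id}: deletion observation with a single border "
                    "base dropped",
                    stacklevel=2,
                )
                continue
            q = float(np.mean(obs.border_qualities[:2]))
        key = (obs.marker_id, obs.genome_pool)
        if key not in out:
            out[key] = PoolCounts(obs.marker_id, obs.genome_pool)
        out[key].add(obs.base_class, q)
    return out


def write_counts(
    counts: Mapping[tuple[str, str], PoolCounts] | Iterable[PoolCounts], path
) -> None:
    if isinstance(counts, Mapping):
        items = [counts[k] for k in sorted(counts)]
    else:
        items = sorted(counts, key=lambda c: (c.marker_id, c.genome_pool))
    with open(path, "w") as fh:
        fh.write(_COUNT_HEADER + "\n")
        for pc in items:
            for base_class in BASE_CLASSES:
                n = pc.count[base_class]
                if n == 0 and pc.qsum[base_class] == 0:
                    continue
                fh.write(
                    f"{pc.marker_id}\t{pc.genome_pool}\t{base_class}\t{n}\t"
                    f"{pc.qsum[base_class]:g}\n"
                )


def read_counts(path, known_markers: set[str] | None = None) -> dict[tuple[str, str], PoolCounts]:
    """Read a count file into per-(marker, pool) aggregates.

    If ``known_markers`` is given, an observation referencing an unlisted
    marker is an error.
    """
    out: dict[tuple[str, str], PoolCounts] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 fields, got {len(f)}")
            marker_id, pool, base_class, n, qsum = f
            if known_markers is not None and marker_id not in known_markers:
                raise ValueError(f"{path}: line {lineno}: unknown marker {marker_id!r}")
            if pool not in POOLS:
                raise ValueError(f"{path}: line {lineno}: unknown pool {pool!r}")
            if base_class not in BASE_CLASSES:
                raise ValueError(f"{path}: line {lineno}: unknown base class {base_class!r}")
            key = (marker_id, pool)
            if key not in out:
                out[key] = PoolCounts(marker_id, pool)
            out[key].count[base_class] += int(n)
            out[key].qsum[base_class] += float(qsum)
    return out


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


def read_annotation(path) -> GenomeAnnotation:
    lengths: dict[int, int] = {}
    centromeres: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom_tok, length, cen = line.split("\t")
            chrom = normalize_chromosome(chrom_tok)
            lengths[chrom] = int(length)
            centromeres[chrom] = int(cen)
    return GenomeAnnotation(lengths, centromeres)


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chromosome\tlength\tcentromere_position\n")
        for chrom in annotation.chromosomes():
            fh.write(
                f"{chrom}\t{annotation.lengths[chrom]}\t{annotation.centromeres[chrom]}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ demultiplexing
# ---------------------------------------------------------------------------


def demultiplex_fastq(
    reads,
    barcode_set: Sequence[str],
    barcode_length: int = 3,
    quality_encoding: str = "sanger",
) -> dict[str, list]:
    """Split FASTQ reads by an inline barcode at the start of each read.

    ``reads`` may be a path to a FASTQ file or an iterable of Biopython
    ``SeqRecord`` objects.  A read whose first ``barcode_length`` bases
    exactly match one of the barcodes is assigned to that pool, with the
    barcode bases and their qualities trimmed off; all other reads go to the
    ``"discard"`` pool untrimmed.  ``quality_encoding`` selects the FASTQ
    quality convention when reading from a path: ``"sanger"`` (phred+33) or
    ``"illumina"`` (the legacy phred+64 encoding).
    """
    from Bio import SeqIO

    barcodes = [b.upper() for b in barcode_set]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcode in barcode set")
    if any(len(b) != barcode_length for b in barcodes):
        raise ValueError(f"all barcodes must have length {barcode_length}")

    if isinstance(reads, (str, Path)):
        fmt = {"sanger": "fastq", "illumina": "fastq-illumina"}.get(quality_encoding)
        if fmt is None:
            raise ValueError("quality_encoding must be 'sanger' or 'illumina'")
        records = SeqIO.parse(str(reads), fmt)
    else:
        records = reads

    pools: dict[str, list] = {b: [] for b in barcodes}
    pools["discard"] = []
    for rec in records:
        prefix = str(rec.seq[:barcode_length]).upper()
        if prefix in pools:
            pools[prefix].append(rec[barcode_length:])
        else:
            pools["discard"].append(rec)
    return pools


# ---------------------------------------------------------------------------
# Marker validation against parental sequencing
# ---------------------------------------------------------------------------

REMOVED_UNRELIABLE = "wrong_parent_score"
REMOVED_UNRESOLVABLE = "no_correct_parent_reads"


@dataclass(frozen=True)
class MarkerValidationReport:
    retained: list
    removed: list  # (MarkerRecord, reason, details) tuples


def validate_markers(
    parentA_counts: Mapping[tuple[str, str], PoolCounts],
    parentB_counts: Mapping[tuple[str, str], PoolCounts],
    marker_list: Sequence[MarkerRecord],
) -> MarkerValidationReport:
    """Filter markers that parental resequencing cannot genotype reliably.

    Each haploid parent is sequenced separately and its reads piled up on
    the marker list.  For every marker, in every genome pool of every
    parental dataset, the cumulative quality score of reads showing the
    *wrong* parent's allele is compared with the score for the correct
    allele: if wrong >= correct / 2 the marker is unreliable and removed.
    A marker with zero correct-parent reads in both pools of both datasets
    is removed as unresolvable, with a distinct reason code.

    Idempotent: running the retained list through again removes nothing.
    """
    retained: list[MarkerRecord] = []
    removed: list[tuple[MarkerRecord, str, dict]] = []
    datasets = ((MATCHES_A, MATCHES_B, parentA_counts), (MATCHES_B, MATCHES_A, parentB_counts))
    for marker in marker_list:
        unreliable = None
        correct_seen = 0
        for correct_class, wrong_class, counts in datasets:
            for pool in POOLS:
                pc = counts.get((marker.marker_id, pool))
                if pc is None or pc.depth == 0:
                    continue
                correct = pc.qsum[correct_class]
                wrong = pc.qsum[wrong_class]
                correct_seen += pc.count[correct_class]
                if wrong >= 0.5 * correct:
                    unreliable = {
                        "pool": pool,
                        "correct_score": correct,
                        "wrong_score": wrong,
                    }
        if correct_seen == 0:
            removed.append((marker, REMOVED_UNRESOLVABLE, {}))
        elif unreliable is not None:
            removed.append((marker, REMOVED_UNRELIABLE, unreliable))
        else:
            retained.append(marker)
    return MarkerValidationReport(retained=retained, removed=removed)
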