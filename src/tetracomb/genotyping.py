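"""Quality-score genotyping of markers in hybrid-cross spores.

Each spore's reads are aligned against both parental reference genomes and
split into two pools by the genome they aligned to.  Within a pool, the
evidence at a marker is summarized by a *cumulative quality score* per
candidate genotype: the sum of base qualities of reads showing that allele
minus the sum of base qualities of all other reads at the position.  A
genotype is provisionally called in a pool when its score strictly exceeds
a user-chosen threshold; the two pools' provisional calls are then
reconciled into a final call.  Markers genotyped in all four spores form
the seg file consumed by the crossover engine.

Indels are scored with two modifications: an insertion-supporting read
contributes the quality of the insertion's reference base (the center base
of an odd-length insertion, or the right-most of the two center bases of an
even-length one), while a deletion-supporting read contributes the mean of
the two base qualities bordering the deleted region.  Because alignment
tolerates mismatches near read ends, reads whose marker-overlapping bases
fall within a few bases of either read end are excluded from indel scoring
upstream.  A final indel call additionally requires the winning pool's
score to be at least twice the same indel's score in the other pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .markers_io import (
    BASE_CLASSES,
    MATCHES_A,
    MATCHES_B,
    POOL_A,
    POOL_B,
    POOLS,
    MarkerClass,
    MarkerRecord,
    PileupObservation,
    PoolCounts,
    Tetrad,
    aggregate_observations,
)

__all__ = [
    "GenotypingConfig",
    "ProvisionalCall",
    "FinalCall",
    "cumulative_scores",
    "provisional_call_snp",
    "provisional_call_from_counts",
    "indel_reference_offset",
    "provisional_call_indel",
    "reconcile",
    "genotype_spore_counts",
    "build_seg",
    "select_threshold",
    "CALL_A",
    "CALL_B",
    "CALL_NEITHER",
    "CALL_NONE",
]

CALL_A = "A"
CALL_B = "B"
CALL_NEITHER = "neither"  # provisional: no genotype passed the threshold
CALL_NONE = "none"        # final: marker not genotyped

# Cumulative-quality-score thresholds for which master files are emitted.
DEFAULT_THRESHOLD_LADDER = (20, 50, 80, 100, 120, 150, 200, 250, 300, 400, 500)


@dataclass(frozen=True)
class GenotypingConfig:
    threshold: float = 150.0
    threshold_ladder: tuple = DEFAULT_THRESHOLD_LADDER
    indel_dominance_factor: float = 2.0
    edge_exclusion: int = 3

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.indel_dominance_factor <= 1:
            raise ValueError("indel_dominance_factor must exceed 1")
        if self.edge_exclusion < 0:
            raise ValueError("edge_exclusion must be >= 0")


@dataclass(frozen=True)
class ProvisionalCall:
    marker_id: str
    genome_pool: str
    call: str  # CALL_A | CALL_B | CALL_NEITHER
    score_A: float
    score_B: float


@dataclass(frozen=True)
class FinalCall:
    marker_id: str
    call: str  # CALL_A | CALL_B | CALL_NONE
    provenance: tuple  # pools whose provisional calls contributed


def cumulative_scores(counts: PoolCounts) -> dict[str, float]:
    """Per-genotype cumulative quality scores for one marker in one pool.

    score(g) = sum of qualities of reads in class g minus the sum of
    qualities of all other reads at the marker.  The ``other`` class drags
    both parental scores down but is never itself a callable genotype.
    """
    total = sum(counts.qsum[c] for c in BASE_CLASSES)
    return {
        CALL_A: counts.qsum[MATCHES_A] - (total - counts.qsum[MATCHES_A]),
        CALL_B: counts.qsum[MATCHES_B] - (total - counts.qsum[MATCHES_B]),
    }


def provisional_call_snp(
    scores: Mapping[str, float], config: GenotypingConfig, *, marker_id: str = "",
    genome_pool: str = POOL_A,
) -> ProvisionalCall:
    """Call the highest-scoring parental genotype iff its score strictly
    exceeds the threshold; ties above threshold yield ``neither``."""
    sa, sb = scores[CALL_A], scores[CALL_B]
    passing = [g for g, s in ((CALL_A, sa), (CALL_B, sb)) if s > config.threshold]
    if len(passing) == 1:
        call = passing[0]
    else:
        call = CALL_NEITHER
    return ProvisionalCall(marker_id, genome_pool, call, sa, sb)


def provisional_call_from_counts(
    counts: PoolCounts, config: GenotypingConfig
) -> ProvisionalCall:
    return provisional_call_snp(
        cumulative_scores(counts), config,
        marker_id=counts.marker_id, genome_pool=counts.genome_pool,
    )


def indel_reference_offset(indel: MarkerRecord) -> int:
    """1-based offset of the scoring base within an inserted sequence.

    Center base for odd lengths; the right-most of the two center bases for
    even lengths.
    """
    if indel.marker_class != MarkerClass.INSERTION:
        raise ValueError("reference offsets are defined for insertions only")
    length = indel.indel_length
    if length < 1:
        raise ValueError("insertion length must be >= 1")
    if length % 2:
        return (length + 1) // 2
    return length // 2 + 1


def provisional_call_indel(
    observations: Iterable[PileupObservation],
    marker: MarkerRecord,
    config: GenotypingConfig,
    genome_pool: str | None = None,
) -> ProvisionalCall:
    """Provisional indel call from per-read observations in one pool.

    Each read contributes a single effective quality (already the reference
    base quality for insertion-supporting reads, or derived from the two
    border-base qualities for deletion-supporting reads); cumulative scoring
    and thresholding then follow the SNP procedure.
    """
    obs = list(observations)
    if genome_pool is None:
        pools = {o.genome_pool for o in obs}
        if len(pools) > 1:
            raise ValueError("observations span multiple pools; pass genome_pool")
        genome_pool = pools.pop() if pools else POOL_A
    aggregated = aggregate_observations(obs)
    counts = aggregated.get(
        (marker.marker_id, genome_pool), PoolCounts(marker.marker_id, genome_pool)
    )
    return provisional_call_from_counts(counts, config)


def reconcile(
    call_A_pool: ProvisionalCall | None,
    call_B_pool: ProvisionalCall | None,
    marker_class: str,
    config: GenotypingConfig,
) -> FinalCall:
    """Reconcile the two pools' provisional calls into a final genotype.

    SNPs: agreeing calls win; conflicting calls are discarded; a single-pool
    call is accepted only when the called genotype matches the parent whose
    reference genome produced it (reads carrying a parent-A allele align
    preferentially to the parent-A genome, and vice versa).

    Indels additionally require the winning pool's cumulative score for the
    called genotype to be at least ``indel_dominance_factor`` times the score
    for the same genotype in the other pool.

    Telomeric SNPs have a known position only in the parent-A reference, so
    they are decided from the A pool alone.
    """
    marker_id = (call_A_pool or call_B_pool).marker_id

    if marker_class == MarkerClass.TELOMERIC_SNP:
        if call_A_pool is None or call_A_pool.call == CALL_NEITHER:
            return FinalCall(marker_id, CALL_NONE, ())
        return FinalCall(marker_id, call_A_pool.call, (POOL_A,))

    a = call_A_pool.call if call_A_pool is not None else CALL_NEITHER
    b = call_B_pool.call if call_B_pool is not None else CALL_NEITHER

    if a == b:
        if a == CALL_NEITHER:
            return FinalCall(marker_id, CALL_NONE, ())
        call, provenance = a, (POOL_A, POOL_B)
    elif CALL_NEITHER in (a, b):
        # One pool abstained: accept only the pool whose own parent was called.
        if a != CALL_NEITHER:
            call, provenance = (a, (POOL_A,)) if a == CALL_A else (CALL_NONE, ())
        else:
            call, provenance = (b, (POOL_B,)) if b == CALL_B else (CALL_NONE, ())
    else:
        # Conflicting non-neither calls.
        return FinalCall(marker_id, CALL_NONE, ())

    if call == CALL_NONE:
        return FinalCall(marker_id, CALL_NONE, ())

    if marker_class in (MarkerClass.INSERTION, MarkerClass.DELETION):
        # An absent pool is an empty pileup: all cumulative scores are zero.
        def _score(pc: ProvisionalCall | None) -> float:
            if pc is None:
                return 0.0
            return pc.score_A if call == CALL_A else pc.score_B

        score_a = _score(call_A_pool)
        score_b = _score(call_B_pool)
        win, other = max(score_a, score_b), min(score_a, score_b)
        if win < config.indel_dominance_factor * other:
            return FinalCall(marker_id, CALL_NONE, ())

    return FinalCall(marker_id, call, provenance)


def genotype_spore_counts(
    counts: Mapping[tuple[str, str], PoolCounts],
    markers: Sequence[MarkerRecord],
    config: GenotypingConfig,
) -> dict[str, FinalCall]:
    """Final genotype calls for one spore from its count-file aggregates."""
    out: dict[str, FinalCall] = {}
    for marker in markers:
        provisional = {}
        for pool in POOLS:
            pc = counts.get((marker.marker_id, pool))
            if pc is None:
                pc = PoolCounts(marker.marker_id, pool)
            provisional[pool] = provisional_call_snp(
                cumulative_scores(pc), config,
                marker_id=marker.marker_id, genome_pool=pool,
            )
        out[marker.marker_id] = reconcile(
            provisional[POOL_A], provisional[POOL_B], marker.marker_class, config
        )
    return out


@dataclass
class SegBuildReport:
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_discarded: int = 0
    missing_per_spore: list = field(default_factory=lambda: [0, 0, 0, 0])


def build_seg(
    spore_calls: Sequence[Mapping[str, FinalCall]],
    markers: Sequence[MarkerRecord],
) -> tuple[Tetrad, SegBuildReport]:
    """Assemble a seg profile from four spores' final calls.

    Only markers genotyped (call != none) in all four spores are kept;
    a gene conversion cannot be scored unambiguously at a marker where any
    spore is missing.  Genotype code 0 = parent A, 1 = parent B, spores in
    the given order.
    """
    if len(spore_calls) != 4:
        raise ValueError("exactly four spore call sets are required")
    keysets = [set(c) for c in spore_calls]
    if any(ks != keysets[0] for ks in keysets[1:]):
        raise ValueError("spore call sets cover different marker lists")

    report = SegBuildReport(n_markers_in=len(markers))
    by_chrom: dict[int, list[tuple[int, tuple[int, int, int, int]]]] = {}
    for marker in markers:
        calls = [calls_map.get(marker.marker_id) for calls_map in spore_calls]
        genos = []
        missing = False
        for spore_idx, call in enumerate(calls):
            if call is None or call.call == CALL_NONE:
                report.missing_per_spore[spore_idx] += 1
                missing = True
            elif not missing:
                genos.append(0 if call.call == CALL_A else 1)
        if missing:
            report.n_discarded += 1
            continue
        by_chrom.setdefault(marker.chromosome, []).append((marker.pos_A, tuple(genos)))

    tetrad = Tetrad()
    for chrom, rows in sorted(by_chrom.items()):
        rows.sort()
        pos = np.array([p for p, _ in rows], dtype=np.int64)
        geno = np.array([g for _, g in rows], dtype=np.int8)
        tetrad.set_chromosome(chrom, pos, geno)
    report.n_markers_out = tetrad.n_markers
    return tetrad, report


def select_threshold(
    accuracy_table: Iterable[tuple[float, float, float]],
    *,
    max_mean_incorrect: float = 3.0,
    excluded_thresholds: tuple = (20, 50),
) -> float:
    """Pick the quality-score threshold from a simulation accuracy table.

    ``accuracy_table`` rows are (threshold, mean fraction of markers
    genotyped correctly, mean count of markers genotyped incorrectly).
    Returns the threshold maximizing the correct fraction subject to the
    mean incorrect count being at most ``max_mean_incorrect``; the lowest
    two ladder rungs are excluded because one or two reads suffice to reach
    them.  Ties go to the smaller threshold (more markers callable).
    """
    candidates = [
        (correct, -float(threshold))
        for threshold, correct, incorrect in accuracy_table
        if threshold not in excluded_thresholds and incorrect <= max_mean_incorrect
    ]
    if not candidates:
        raise ValueError(
            "no threshold meets the accuracy constraint; deeper sequencing "
            "coverage is needed"
        )
    best = max(candidates)
    return -best[1]
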