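"""Detection and fine-grained classification of meiotic recombination events.

Input is a four-spore segregation profile (a :class:`~tetracomb.markers_io.Tetrad`).
Markers segregating 2:2 define the phase of the four chromatids; a crossover
(CO) appears as a reciprocal genotype switch between adjacent 2:2 markers,
involving either two chromatids (a single CO) or all four (a double CO).
Markers with non-2:2 segregation (3:1, 1:3, 4:0, 0:4) mark gene-conversion
(GC) tracts, which may be directly connected to a CO (lying between the
markers that flank the genotype switch), detached but nearby, or independent
non-crossovers (NCOs).

CO categories
    0  CO without detectable GC tract
    1  CO with connected GC on a crossing chromatid
    2  CO with connected GC on a non-crossing chromatid only
    3  CO whose connected GC involves both kinds of chromatid, or a 4:0 tract
    4  CO with a discontinuous or otherwise complex connected GC
    5  double CO (four chromatids switch in one marker interval), plain
    6  double CO with internal GC
    7  double CO, complex
    8  two closely spaced COs sharing one chromatid, reinterpreted as a
       single CO with a GC on a non-crossing chromatid

GC categories (a tract may carry several labels)
    0  independent NCO (3:1 or 1:3, away from any CO)
    1  tract connected to a CO
    2  independent 4:0 / 0:4 tract
    3  tract containing the first genotyped marker of a chromosome
    4  tract containing the last genotyped marker of a chromosome
    5  two closely spaced COs on the same two chromatids, reinterpreted as a
       double NCO
    6  tract near a CO on a chromatid not involved in that CO
    7  tract near a CO on a chromatid involved in that CO
    8  Type 1 tract whose CO also has a Type 6 partner
    9  Type 1 tract whose CO also has a Type 7 partner
    10 Type 1 tract with no Type 8/9 partner

Event positions use marker midpoints and keep half-integer precision; all
distances are in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .markers_io import Tetrad

__all__ = [
    "CrossOverConfig",
    "CrossoverEvent",
    "ConversionTract",
    "EventReport",
    "find_crossovers",
    "attach_connected_gc",
    "merge_close_cos",
    "group_gc_tracts",
    "associate_gc_with_co",
    "event_position_and_length",
    "pair_double_co_chromatids",
    "classify_tetrad",
]

DOUBLE_CO_TYPES = (5, 6, 7)


@dataclass(frozen=True)
class CrossOverConfig:
    """Tunable ranges for event classification.

    ``merge_range``: two single COs closer than this are reinterpreted as one
    recombination event (0 disables merging entirely).  ``gc_assoc_range``:
    a detached GC tract closer than this to a CO is considered part of that
    CO's event.  Both default to 5 kb, the gap separating the cluster of
    single-initiation products from genuinely independent events in
    wild-type data.  ``rng_seed`` controls the random pairing of chromatids
    in double COs.
    """

    merge_range: float = 5000.0
    gc_assoc_range: float = 5000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.merge_range < 0 or self.gc_assoc_range < 0:
            raise ValueError("ranges must be >= 0")


@dataclass
class CrossoverEvent:
    chromosome: int
    position: float
    co_type: int | None
    chromatids: tuple[int, ...]  # spore indices, 1-based
    flank_left: float
    flank_right: float
    chromatid_pairs: tuple[tuple[int, int], ...] = ()
    linked_gc_ids: tuple[int, ...] = ()
    # full-array marker indices of the bounding 2:2 markers (internal)
    _left_idx: int = field(default=-1, repr=False, compare=False)
    _right_idx: int = field(default=-1, repr=False, compare=False)
    _left_genotypes: tuple[int, ...] = field(default=(), repr=False, compare=False)

    @property
    def is_double(self) -> bool:
        return len(self.chromatids) == 4

    @property
    def n_crossovers(self) -> int:
        """Number of exchanges the event represents (a double CO is two)."""
        return 2 if self.is_double else 1


@dataclass
class ConversionTract:
    tract_id: int
    chromosome: int
    gc_types: set[int]
    segregation_class: str  # "3:1", "1:3", "4:0", "0:4" or "2:2" for merged-CO tracts
    chromatids: tuple[int, ...]  # spore indices, 1-based
    est_start: float
    est_end: float
    length_est: float
    length_min: float
    length_max: float
    marker_count: int
    first_marker_pos: float
    last_marker_pos: float
    n_B_alleles_at_first_marker: int
    connected_co: int | None = None  # index of the CO the tract is attached to
    nearby_co: int | None = None     # CO it was associated with (types 6/7)
    open_start: bool = False
    open_end: bool = False

    @property
    def position(self) -> float:
        return 0.5 * (self.est_start + self.est_end)

    @property
    def is_nco(self) -> bool:
        """Counted as a non-crossover in summaries (GC Types 0, 5 and 6)."""
        return bool(self.gc_types & {0, 5, 6})


@dataclass
class EventReport:
    tetrad_id: str = ""
    crossovers: list = field(default_factory=list)
    tracts: list = field(default_factory=list)
    flags: list = field(default_factory=list)
    chromosomes: list = field(default_factory=list)

    @property
    def co_count(self) -> int:
        return sum(e.n_crossovers for e in self.crossovers)

    @property
    def nco_count(self) -> int:
        return sum(1 for t in self.tracts if t.is_nco)

    def per_chromosome_co_counts(self) -> dict[int, int]:
        counts = {c: 0 for c in self.chromosomes}
        for e in self.crossovers:
            counts[e.chromosome] = counts.get(e.chromosome, 0) + e.n_crossovers
        return counts

    @property
    def e0_chromosomes(self) -> list[int]:
        counts = self.per_chromosome_co_counts()
        return [c for c in self.chromosomes if counts.get(c, 0) == 0]


# ---------------------------------------------------------------------------
# Position / length arithmetic
# ---------------------------------------------------------------------------


def event_position_and_length(
    flank_left: float | None,
    flank_right: float | None,
    converted_positions: Sequence[float] | None = None,
) -> dict:
    """Midpoint-based position and tract-length estimates.

    With no converted markers this is a simple CO: position is the midpoint
    of the two flanking markers.  With converted markers it is a GC tract
    bounded by ``flank_left``/``flank_right`` (the nearest unconverted
    markers; ``None`` for a chromosome end): the estimated boundaries are the
    midpoints between the last converted and first unconverted marker on each
    side, the minimum length uses the innermost (converted) markers, the
    maximum the outermost (flanking) markers.  Open ends fall back to the
    terminal converted marker.
    """
    if not converted_positions:
        if flank_left is None or flank_right is None:
            raise ValueError("a crossover needs both flanking markers")
        mid = 0.5 * (flank_left + flank_right)
        return {
            "position": mid,
            "est_start": mid,
            "est_end": mid,
            "length_est": 0.0,
            "length_min": 0.0,
            "length_max": float(flank_right - flank_left),
            "open_start": False,
            "open_end": False,
        }

    first = float(min(converted_positions))
    last = float(max(converted_positions))
    open_start = flank_left is None
    open_end = flank_right is None
    est_start = first if open_start else 0.5 * (flank_left + first)
    est_end = last if open_end else 0.5 * (last + flank_right)
    outer_left = first if open_start else float(flank_left)
    outer_right = last if open_end else float(flank_right)
    return {
        "position": 0.5 * (est_start + est_end),
        "est_start": est_start,
        "est_end": est_end,
        "length_est": est_end - est_start,
        "length_min": last - first,
        "length_max": outer_right - outer_left,
        "open_start": open_start,
        "open_end": open_end,
    }


def pair_double_co_chromatids(
    left_genotypes: Sequence[int], rng: np.random.Generator
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Randomly pair the four chromatids of a double CO.

    Each exchange joins one chromatid of each parental genotype (taken on the
    proximal side of the event), so exactly two reciprocal pairings are
    consistent with the segregation data; one is chosen uniformly.  Returned
    pairs use 1-based spore indices.
    """
    genos = list(left_genotypes)
    zeros = [i for i, g in enumerate(genos) if g == 0]
    ones = [i for i, g in enumerate(genos) if g == 1]
    if len(zeros) != 2 or len(ones) != 2:
        raise ValueError("a double CO requires two chromatids of each genotype")
    if rng.random() < 0.5:
        pairs = ((zeros[0], ones[0]), (zeros[1], ones[1]))
    else:
        pairs = ((zeros[0], ones[1]), (zeros[1], ones[0]))
    return tuple(tuple(sorted(i + 1 for i in pair)) for pair in pairs)


# ---------------------------------------------------------------------------
# Stage 1: raw CO detection
# ---------------------------------------------------------------------------


def find_crossovers(tetrad: Tetrad) -> list[CrossoverEvent]:
    """Locate reciprocal genotype switches between adjacent 2:2 markers.

    Returns untyped events (``co_type`` is ``None``): single COs with the two
    switching chromatids, and double-CO candidates where all four chromatids
    switch in the same interval.  Because 2:2 holds on both flanks, the
    number of switching chromatids is always 0, 2 or 4.
    """
    events: list[CrossoverEvent] = []
    for chrom in tetrad.chromosomes():
        pos, geno = tetrad.chromosome(chrom)
        if pos.size < 2:
            continue
        sums = geno.sum(axis=1)
        idx22 = np.flatnonzero(sums == 2)
        if idx22.size < 2:
            continue
        g22 = geno[idx22]
        changed = g22[1:] != g22[:-1]
        n_changed = changed.sum(axis=1)
        if np.any(n_changed % 2):
            raise AssertionError(
                f"chromosome {chrom}: non-reciprocal change between 2:2 markers"
            )
        for k in np.flatnonzero(n_changed > 0):
            chromatids0 = np.flatnonzero(changed[k])
            left_idx = int(idx22[k])
            right_idx = int(idx22[k + 1])
            left_pos = float(pos[left_idx])
            right_pos = float(pos[right_idx])
            events.append(
                CrossoverEvent(
                    chromosome=chrom,
                    position=0.5 * (left_pos + right_pos),
                    co_type=None,
                    chromatids=tuple(int(i) + 1 for i in chromatids0),
                    flank_left=left_pos,
                    flank_right=right_pos,
                    _left_idx=left_idx,
                    _right_idx=right_idx,
                    _left_genotypes=tuple(int(g) for g in geno[left_idx]),
                )
            )
    return events


# ---------------------------------------------------------------------------
# Stage 2: typing COs from their connected tracts
# ---------------------------------------------------------------------------


def _switch_info(seq: np.ndarray) -> tuple[bool, int]:
    """For a chromatid's genotype sequence across a CO interval (ends differ),
    return (is_monotone_single_switch, index of the last pre-switch marker)."""
    switched = seq != seq[0]
    monotone = bool(np.all(np.diff(switched.astype(np.int8)) >= 0))
    j1 = int(np.flatnonzero(~switched)[-1])
    return monotone, j1


def _make_tract(
    tract_id: int,
    chrom: int,
    pos: np.ndarray,
    geno: np.ndarray,
    run: list[int],
    gc_types: set[int],
    chromatids0: Iterable[int],
    connected_co: int | None,
) -> ConversionTract:
    """Build a tract from a run of converted full-array marker indices."""
    first_i, last_i = run[0], run[-1]
    flank_left = float(pos[first_i - 1]) if first_i > 0 else None
    flank_right = float(pos[last_i + 1]) if last_i + 1 < pos.size else None
    metrics = event_position_and_length(
        flank_left, flank_right, [float(pos[i]) for i in (first_i, last_i)]
    )
    n_b = int(geno[first_i].sum())
    seg_class = {0: "4:0", 1: "3:1", 2: "2:2", 3: "1:3", 4: "0:4"}[n_b]
    if first_i == 0:
        gc_types = gc_types | {3}
    if last_i + 1 == pos.size:
        gc_types = gc_types | {4}
    return ConversionTract(
        tract_id=tract_id,
        chromosome=chrom,
        gc_types=set(gc_types),
        segregation_class=seg_class,
        chromatids=tuple(sorted(int(i) + 1 for i in chromatids0)),
        est_start=metrics["est_start"],
        est_end=metrics["est_end"],
        length_est=metrics["length_est"],
        length_min=metrics["length_min"],
        length_max=metrics["length_max"],
        marker_count=last_i - first_i + 1,
        first_marker_pos=float(pos[first_i]),
        last_marker_pos=float(pos[last_i]),
        n_B_alleles_at_first_marker=n_b,
        connected_co=connected_co,
        open_start=metrics["open_start"],
        open_end=metrics["open_end"],
    )


def attach_connected_gc(
    tetrad: Tetrad,
    raw_cos: list[CrossoverEvent],
    rng: np.random.Generator | None = None,
) -> tuple[list[CrossoverEvent], list[ConversionTract]]:
    """Type each CO from the non-2:2 markers between its flanking markers.

    Single COs become Types 0-4, doubles Types 5-7.  Connected tracts are
    built here: runs of interior markers sharing a deviation signature, with
    GC Type 1 on chromatids involved in the CO and GC Type 6 otherwise.
    CO positions are refined to the mean of the per-chromatid switch
    midpoints, which reduces to the flank midpoint when there is no tract.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    cos: list[CrossoverEvent] = []
    tracts: list[ConversionTract] = []

    for event in raw_cos:
        pos, geno = tetrad.chromosome(event.chromosome)
        li, ri = event._left_idx, event._right_idx
        left = geno[li]
        right = geno[ri]
        cross0 = [c - 1 for c in event.chromatids]
        cross_set = set(cross0)
        interior = list(range(li + 1, ri))

        # Per crossing chromatid: monotone? and switch midpoint.
        midpoints = []
        complex_cross = False
        for x in cross0:
            seq = geno[li : ri + 1, x]
            monotone, j1 = _switch_info(seq)
            complex_cross |= not monotone
            midpoints.append(0.5 * (float(pos[li + j1]) + float(pos[li + j1 + 1])))

        # Deviation signature of each interior marker.
        sigs: list[frozenset[int]] = []
        has_cross = has_noncross = has40 = False
        for j in interior:
            dev: set[int] = set()
            for i in range(4):
                if i in cross_set:
                    continue
                if geno[j, i] != left[i]:
                    dev.add(i)
            cross_state = tuple(int(geno[j, x]) for x in cross0)
            if cross_state not in (
                tuple(int(left[x]) for x in cross0),
                tuple(int(right[x]) for x in cross0),
            ):
                dev |= cross_set
                has_cross = True
            if dev - cross_set:
                has_noncross = True
            if int(geno[j].sum()) in (0, 4):
                has40 = True
            sigs.append(frozenset(dev))

        if event.is_double:
            if not interior:
                co_type = 5
            elif not complex_cross:
                co_type = 6
            else:
                co_type = 7
            pairs = pair_double_co_chromatids(event._left_genotypes, rng)
        else:
            pairs = ()
            if not interior:
                co_type = 0
            elif has40 or (has_cross and has_noncross):
                co_type = 3
            elif complex_cross:
                co_type = 4
            elif has_cross:
                co_type = 1
            else:
                # deviations only on non-crossing chromatids
                runs_dev = {s for s in sigs if s}
                contiguous = all(
                    s1 == s2 for s1, s2 in zip(sigs, sigs[1:])
                )
                co_type = 2 if len(runs_dev) == 1 and contiguous else 4

        position = float(np.mean(midpoints))

        linked: list[int] = []
        # Group interior markers into tracts by (signature, segregation sum).
        run: list[int] = []
        run_key: tuple | None = None

        def flush() -> None:
            nonlocal run, run_key
            if run and run_key is not None and run_key[0]:
                dev_set = set(run_key[0])
                gc = {1} if dev_set & cross_set else {6}
                tract = _make_tract(
                    len(tracts), event.chromosome, pos, geno, run, gc,
                    dev_set, len(cos),
                )
                linked.append(tract.tract_id)
                tracts.append(tract)
            run, run_key = [], None

        for j, sig in zip(interior, sigs):
            key = (sig, int(geno[j].sum()))
            if run and (key != run_key or j != run[-1] + 1):
                flush()
            run.append(j)
            run_key = key
        flush()

        cos.append(
            CrossoverEvent(
                chromosome=event.chromosome,
                position=position,
                co_type=co_type,
                chromatids=event.chromatids,
                flank_left=event.flank_left,
                flank_right=event.flank_right,
                chromatid_pairs=pairs,
                linked_gc_ids=tuple(linked),
                _left_idx=li,
                _right_idx=ri,
                _left_genotypes=event._left_genotypes,
            )
        )
    return cos, tracts


# ---------------------------------------------------------------------------
# Stage 3: merging closely spaced single COs
# ---------------------------------------------------------------------------


def merge_close_cos(
    tetrad: Tetrad,
    cos: list[CrossoverEvent],
    tracts: list[ConversionTract],
    merge_range: float,
) -> tuple[list[CrossoverEvent], list[ConversionTract], list[str]]:
    """Reinterpret pairs of closely spaced single COs as single events.

    Adjacent single COs whose positions are strictly within ``merge_range``
    of each other are chained into clusters.  A cluster of two sharing both
    chromatids becomes one GC Type 5 tract (a double NCO); sharing exactly
    one chromatid it becomes one CO Type 8 with a GC on the chromatid common
    to both COs; with four distinct chromatids the pair is kept and flagged.
    Clusters of three or more COs are never merged automatically: a manual
    inspection flag is raised.  Double COs do not participate.

    With ``merge_range`` 0 nothing is merged and every reciprocal switch
    remains an independent CO.
    """
    flags: list[str] = []
    if merge_range <= 0 or not cos:
        return list(cos), list(tracts), flags

    keep: list[CrossoverEvent] = [e for e in cos if e.is_double]
    new_tracts = list(tracts)

    for chrom in tetrad.chromosomes():
        singles = sorted(
            (e for e in cos if e.chromosome == chrom and not e.is_double),
            key=lambda e: e.position,
        )
        if not singles:
            continue
        # chain-cluster by inter-CO (position) distance < merge_range
        clusters: list[list[CrossoverEvent]] = [[singles[0]]]
        for e in singles[1:]:
            if e.position - clusters[-1][-1].position < merge_range:
                clusters[-1].append(e)
            else:
                clusters.append([e])
        pos, geno = tetrad.chromosome(chrom)
        for cluster in clusters:
            if len(cluster) == 1:
                keep.append(cluster[0])
                continue
            if len(cluster) > 2:
                flags.append(
                    f"chromosome {chrom}: {len(cluster)} COs within "
                    f"{merge_range:g} bp near position {cluster[0].position:.0f}; "
                    "inspect manually"
                )
                keep.extend(cluster)
                continue
            co1, co2 = cluster
            union = set(co1.chromatids) | set(co2.chromatids)
            span_first = int(np.searchsorted(pos, co1.flank_right))
            span_last = int(np.searchsorted(pos, co2.flank_left, side="right")) - 1
            if len(union) == 2:
                # same two chromatids: a double NCO (GC Type 5)
                chromatids = tuple(sorted(union))
                tract = ConversionTract(
                    tract_id=len(new_tracts),
                    chromosome=chrom,
                    gc_types={5},
                    segregation_class="2:2",
                    chromatids=chromatids,
                    est_start=co1.position,
                    est_end=co2.position,
                    length_est=co2.position - co1.position,
                    length_min=max(0.0, co2.flank_left - co1.flank_right),
                    length_max=co2.flank_right - co1.flank_left,
                    marker_count=max(0, span_last - span_first + 1),
                    first_marker_pos=float(co1.flank_right),
                    last_marker_pos=float(co2.flank_left),
                    n_B_alleles_at_first_marker=int(geno[span_first].sum())
                    if span_first < pos.size
                    else 0,
                )
                new_tracts.append(tract)
            elif len(union) == 3:
                shared = set(co1.chromatids) & set(co2.chromatids)
                crossing = tuple(sorted(union - shared))
                merged = CrossoverEvent(
                    chromosome=chrom,
                    position=0.5 * (co1.position + co2.position),
                    co_type=8,
                    chromatids=crossing,
                    flank_left=co1.flank_left,
                    flank_right=co2.flank_right,
                    _left_idx=co1._left_idx,
                    _right_idx=co2._right_idx,
                    _left_genotypes=co1._left_genotypes,
                )
                tract = ConversionTract(
                    tract_id=len(new_tracts),
                    chromosome=chrom,
                    gc_types={6},
                    segregation_class="2:2",
                    chromatids=tuple(shared),
                    est_start=co1.position,
                    est_end=co2.position,
                    length_est=co2.position - co1.position,
                    length_min=max(0.0, co2.flank_left - co1.flank_right),
                    length_max=co2.flank_right - co1.flank_left,
                    marker_count=max(0, span_last - span_first + 1),
                    first_marker_pos=float(co1.flank_right),
                    last_marker_pos=float(co2.flank_left),
                    n_B_alleles_at_first_marker=int(geno[span_first].sum())
                    if span_first < pos.size
                    else 0,
                )
                new_tracts.append(tract)
                # inherited Type 1 tracts of the pair partner the new GC 6
                for old in (co1, co2):
                    for tid in old.linked_gc_ids:
                        if 1 in new_tracts[tid].gc_types:
                            new_tracts[tid].gc_types.add(8)
                merged.linked_gc_ids = tuple(
                    tid for old in (co1, co2) for tid in old.linked_gc_ids
                ) + (tract.tract_id,)
                keep.append(merged)
            else:
                flags.append(
                    f"chromosome {chrom}: close CO pair on four distinct "
                    f"chromatids near position {co1.position:.0f}; kept as two COs"
                )
                keep.extend(cluster)

    keep.sort(key=lambda e: (e.chromosome, e.position))
    return keep, new_tracts, flags


# ---------------------------------------------------------------------------
# Stage 4: detached tract grouping
# ---------------------------------------------------------------------------


def group_gc_tracts(
    tetrad: Tetrad,
    co_intervals: dict[int, list[tuple[int, int]]] | None = None,
) -> list[ConversionTract]:
    """Group detached non-2:2 markers into conversion tracts.

    Markers interior to a CO interval (``co_intervals``, full-array index
    pairs per chromosome) are excluded — they were attached to their CO.
    Remaining non-2:2 markers are grouped into maximal runs of adjacent
    markers sharing a segregation class and deviant chromatid set; a lone
    marker is a tract of its own.  Deviant chromatids are read against the
    nearest flanking 2:2 marker.  Provisional labels are GC Type 0 for
    3:1/1:3 tracts and Type 2 for 4:0/0:4 tracts; tracts touching the first
    or last genotyped marker of a chromosome additionally get Type 3 or 4.
    """
    co_intervals = co_intervals or {}
    tracts: list[ConversionTract] = []
    for chrom in tetrad.chromosomes():
        pos, geno = tetrad.chromosome(chrom)
        sums = geno.sum(axis=1)
        non22 = sums != 2
        excluded = np.zeros(pos.size, dtype=bool)
        for li, ri in co_intervals.get(chrom, []):
            if ri > li + 1:
                excluded[li + 1 : ri] = True
        idx22 = np.flatnonzero(~non22)
        candidates = np.flatnonzero(non22 & ~excluded)

        run: list[int] = []
        run_key: tuple | None = None

        def background(j: int) -> np.ndarray:
            k = int(np.searchsorted(idx22, j))
            if k > 0:
                return geno[idx22[k - 1]]
            if k < idx22.size:
                return geno[idx22[k]]
            raise ValueError(
                f"chromosome {chrom}: no 2:2 marker to phase conversions against"
            )

        def flush() -> None:
            nonlocal run, run_key
            if run:
                dev_set, s = run_key
                gc = {0} if s in (1, 3) else {2}
                tracts.append(
                    _make_tract(
                        len(tracts), chrom, pos, geno, run, gc, dev_set, None
                    )
                )
            run, run_key = [], None

        for j in candidates.tolist():
            bg = background(j)
            dev = frozenset(int(i) for i in np.flatnonzero(geno[j] != bg))
            key = (dev, int(sums[j]))
            if run and (key != run_key or j != run[-1] + 1):
                flush()
            run.append(j)
            run_key = key
        flush()
    return tracts


# ---------------------------------------------------------------------------
# Stage 5: associating detached tracts with COs
# ---------------------------------------------------------------------------


def associate_gc_with_co(
    tracts: list[ConversionTract],
    cos: list[CrossoverEvent],
    gc_assoc_range: float,
) -> list[ConversionTract]:
    """Finalize GC type labels by proximity to the finalized CO list.

    A detached tract strictly within ``gc_assoc_range`` of its nearest CO
    (ties broken to the leftmost CO) becomes Type 7 if it lies on a chromatid
    involved in that CO, Type 6 otherwise; the CO's directly connected
    Type 1 tract, if any, is additionally labeled Type 8 (Type 6 partner) or
    Type 9 (Type 7 partner).  Type 1 tracts with no such partner get
    Type 10.  Remaining detached 3:1 tracts stay Type 0 (NCOs) and 4:0
    tracts stay Type 2.
    """
    by_chrom: dict[int, list[tuple[float, int]]] = {}
    for ci, co in enumerate(cos):
        by_chrom.setdefault(co.chromosome, []).append((co.position, ci))
    for lst in by_chrom.values():
        lst.sort()

    for tract in tracts:
        if not (tract.gc_types & {0, 2}):
            continue
        candidates = by_chrom.get(tract.chromosome, [])
        best: tuple[float, float, int] | None = None  # (distance, co_pos, idx)
        for co_pos, ci in candidates:
            dist = min(abs(co_pos - tract.est_start), abs(co_pos - tract.est_end))
            cand = (dist, co_pos, ci)
            if best is None or cand < best:
                best = cand
        if best is None or best[0] >= gc_assoc_range:
            continue
        _, _, ci = best
        co = cos[ci]
        provisional = tract.gc_types & {0, 2}
        tract.gc_types -= provisional
        involved = bool(set(tract.chromatids) & set(co.chromatids))
        new_type = 7 if involved else 6
        tract.gc_types.add(new_type)
        tract.nearby_co = ci
        for tid in co.linked_gc_ids:
            partner = tracts[tid] if tid < len(tracts) else None
            if partner is not None and 1 in partner.gc_types:
                partner.gc_types.add(8 if new_type == 6 else 9)

    for tract in tracts:
        if 1 in tract.gc_types and not (tract.gc_types & {8, 9}):
            tract.gc_types.add(10)
    return tracts


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def classify_tetrad(
    tetrad: Tetrad,
    config: CrossOverConfig | None = None,
    tetrad_id: str = "",
) -> EventReport:
    """Run the full event-detection pipeline on one tetrad.

    Stages, in order: raw CO detection; typing of COs from connected
    tracts; merging of closely spaced single COs; grouping of detached
    non-2:2 markers into tracts; association of detached tracts with COs
    and final GC labels.
    """
    config = config or CrossOverConfig()
    rng = np.random.default_rng(config.rng_seed)

    raw = find_crossovers(tetrad)
    co_intervals: dict[int, list[tuple[int, int]]] = {}
    for e in raw:
        co_intervals.setdefault(e.chromosome, []).append((e._left_idx, e._right_idx))

    cos, connected = attach_connected_gc(tetrad, raw, rng)
    cos, tracts, flags = merge_close_cos(tetrad, cos, connected, config.merge_range)
    detached = group_gc_tracts(tetrad, co_intervals)

    # Renumber: connected/merged tracts first, then detached.
    offset = len(tracts)
    for t in detached:
        t.tract_id += offset
    all_tracts = tracts + detached

    # linked ids survive renumbering (connected tracts kept their ids);
    # rebuild connected_co indices against the final CO list, clearing links
    # to COs that were merged away
    for t in all_tracts:
        t.connected_co = None
    for i, co in enumerate(cos):
        for tid in co.linked_gc_ids:
            all_tracts[tid].connected_co = i

    associate_gc_with_co(all_tracts, cos, config.gc_assoc_range)

    return EventReport(
        tetrad_id=tetrad_id,
        crossovers=cos,
        tracts=all_tracts,
        flags=flags,
        chromosomes=tetrad.chromosomes(),
    )
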