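"""Ground-truth simulators: tetrads, read pileups, and genotyping accuracy.

``simulate_tetrad`` draws crossovers from a stationary gamma renewal process
along each chromosome (shape gamma controls interference), picks the two
chromatids of each CO independently among the currently opposite-genotype
strands (giving the no-chromatid-interference 1:2:1 ratio for adjacent
pairs), attaches a conversion tract across a configurable fraction of CO
breakpoints, scatters independent NCO and 4:0 conversion tracts, and reads
the resulting four-chromatid haplotypes off a realistic marker grid.  The
returned :class:`SimTruth` records every event with enough annotation to
verify recovery by the crossover engine.

``simulate_pileups`` turns true spore genotypes into per-marker read
observations with Poisson depth, a positional (per-cycle) substitution
error profile, a matching per-cycle quality model, and imperfect splitting
of reads between the two reference-genome pools.

``simulate_genotyping_experiment`` reproduces the threshold-selection
procedure: a ~700 kb chimeric chromosome with a crossover every 140 kb is
genotyped at several coverage levels and quality-score thresholds, several
times each, yielding the accuracy table that threshold selection consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotyping import (
    CALL_A,
    CALL_B,
    GenotypingConfig,
    cumulative_scores,
    provisional_call_snp,
    reconcile,
)
from .markers_io import (
    MATCHES_A,
    MATCHES_B,
    OTHER,
    POOL_A,
    POOL_B,
    GenomeAnnotation,
    MarkerClass,
    PileupObservation,
    PoolCounts,
    Tetrad,
)

__all__ = [
    "YEAST_GENOME",
    "SimTetradConfig",
    "SimEvent",
    "SimTruth",
    "ReadSimConfig",
    "make_marker_map",
    "simulate_tetrad",
    "simulate_tetrad_batch",
    "RecoveryResult",
    "verify_recovery",
    "simulate_pileups",
    "simulate_pileup_observations",
    "genotype_from_pileups",
    "simulate_genotyping_experiment",
    "accuracy_table",
]

# S. cerevisiae reference chromosome lengths and centromere midpoints (bp),
# rounded from the standard assembly; used as the default simulated genome.
YEAST_GENOME = GenomeAnnotation(
    lengths={
        1: 230_218, 2: 813_184, 3: 316_620, 4: 1_531_933,
        5: 576_874, 6: 270_161, 7: 1_090_940, 8: 562_643,
        9: 439_888, 10: 745_751, 11: 666_816, 12: 1_078_177,
        13: 924_431, 14: 784_333, 15: 1_091_291, 16: 948_066,
    },
    centromeres={
        1: 151_465, 2: 238_207, 3: 114_385, 4: 449_711,
        5: 151_987, 6: 148_510, 7: 497_038, 8: 105_703,
        9: 355_629, 10: 436_307, 11: 440_129, 12: 150_828,
        13: 268_031, 14: 628_758, 15: 326_584, 16: 555_957,
    },
)

# Chromatids (spores) 1,2 start as parent A (code 0); 3,4 as parent B.
_INITIAL_GENOTYPES = (0, 0, 1, 1)


@dataclass(frozen=True)
class SimTetradConfig:
    """Study conditions for the tetrad simulator.

    Marker spacing is lognormal with median 56 bp and a log-sd chosen so
    the mean spacing is ~178 bp, matching a ~67,000-marker map over the
    12 Mb genome.  CO placement uses a gamma renewal process with the
    wild-type interference parameters (shape 1.96, scale 61.7 kb), giving
    ~100 COs per tetrad.  65% of COs carry a connected conversion tract;
    tract lengths are lognormal with mean 2.3 kb and sd 1.5 kb.  Detached
    NCO tracts arrive at ~46 per tetrad and independent 4:0 tracts at ~1.
    """

    annotation: GenomeAnnotation = YEAST_GENOME
    marker_spacing_median_bp: float = 56.0
    marker_spacing_log_sd: float = 1.521
    gamma_shape: float = 1.96
    gamma_scale_kb: float = 61.7
    expected_nco_per_tetrad: float = 46.0
    expected_gc40_per_tetrad: float = 1.0
    tract_mean_bp: float = 2300.0
    tract_sd_bp: float = 1500.0
    co_tract_fraction: float = 0.65
    min_event_separation_bp: float | None = None

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale_kb <= 0:
            raise ValueError("gamma parameters must be positive")
        if self.tract_mean_bp <= 0 or self.marker_spacing_median_bp <= 0:
            raise ValueError("means must be positive")
        if not 0 <= self.co_tract_fraction <= 1:
            raise ValueError("co_tract_fraction must be in [0, 1]")


@dataclass
class SimEvent:
    kind: str                      # "co" | "nco" | "gc40"
    chromosome: int
    position: float                # CO breakpoint / tract center
    chromatids: tuple[int, ...]    # 1-based spore indices
    tract_start: float | None = None
    tract_end: float | None = None
    detectable: bool = True
    expected_co_type: int | None = None
    expected_gc_types: frozenset[int] = frozenset()
    n_tract_markers: int = 0
    first_marker_pos: int | None = None
    last_marker_pos: int | None = None


@dataclass
class SimTruth:
    events: list = field(default_factory=list)
    marker_map: dict = field(default_factory=dict)  # chrom -> int positions

    def detectable_events(self) -> list:
        return [e for e in self.events if e.detectable]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def make_marker_map(
    config: SimTetradConfig, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Draw a marker grid per chromosome from the lognormal spacing model.

    The marker map is a property of the cross (the fixed set of
    polymorphisms), so batches of tetrads should share one map.
    """
    mu = np.log(config.marker_spacing_median_bp)
    sigma = config.marker_spacing_log_sd
    mean_gap = float(np.exp(mu + sigma**2 / 2.0))
    out: dict[int, np.ndarray] = {}
    for chrom in config.annotation.chromosomes():
        length = config.annotation.lengths[chrom]
        n_draw = int(length / mean_gap * 1.4) + 50
        gaps = rng.lognormal(mu, sigma, size=n_draw)
        pos = np.cumsum(gaps)
        while pos.size and pos[-1] < length:
            extra = rng.lognormal(mu, sigma, size=n_draw // 2 + 10)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        pos = pos[pos < length - 1]
        pos = np.unique(np.maximum(1, np.round(pos).astype(np.int64)))
        out[chrom] = pos
    return out


def _interval_clear(
    kept: list[tuple[float, float]], start: float, end: float, sep: float
) -> bool:
    return all(end + sep <= s or e + sep <= start for s, e in kept)


def simulate_tetrad(
    config: SimTetradConfig | None = None,
    seed: int | np.random.Generator = 0,
    marker_map: Mapping[int, np.ndarray] | None = None,
) -> tuple[Tetrad, SimTruth]:
    """Simulate one tetrad's segregation profile with full ground truth.

    CO breakpoints come from a gamma renewal process started in equilibrium
    (a long burn-in upstream of the chromosome) so pooled inter-CO distances
    follow the target gamma distribution.  With ``min_event_separation_bp``
    set, events that would come closer than that (interval to interval) are
    thinned/rejected, and the truth contains only the placed events.
    """
    config = config or SimTetradConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if marker_map is None:
        marker_map = make_marker_map(config, rng)

    shape = config.gamma_shape
    scale_bp = config.gamma_scale_kb * 1000.0
    mean_gap = shape * scale_bp
    sep = config.min_event_separation_bp
    t_mu, t_sigma = _lognormal_params(config.tract_mean_bp, config.tract_sd_bp)
    genome_size = sum(config.annotation.lengths.values())

    truth = SimTruth(marker_map={c: np.asarray(p) for c, p in marker_map.items()})
    tetrad = Tetrad()

    for chrom in config.annotation.chromosomes():
        length = config.annotation.lengths[chrom]
        markers = np.asarray(marker_map[chrom])
        # --- CO breakpoints: stationary renewal via upstream burn-in
        burn = 10.0 * mean_gap
        x = -burn
        breakpoints: list[float] = []
        while True:
            x += float(rng.gamma(shape, scale_bp))
            if x >= length:
                break
            if x > 0:
                breakpoints.append(x)

        # --- chromatid state walk + switch placement
        state = list(_INITIAL_GENOTYPES)
        toggles: list[list[float]] = [[], [], [], []]
        kept_intervals: list[tuple[float, float]] = []
        co_events: list[SimEvent] = []
        for p in breakpoints:
            has_tract = rng.random() < config.co_tract_fraction
            t = float(rng.lognormal(t_mu, t_sigma)) if has_tract else 0.0
            a, b = p - t / 2.0, p + t / 2.0
            if sep is not None and not _interval_clear(kept_intervals, a, b, sep):
                continue
            zeros = [i for i, g in enumerate(state) if g == 0]
            ones = [i for i, g in enumerate(state) if g == 1]
            i = zeros[rng.integers(len(zeros))]
            j = ones[rng.integers(len(ones))]
            # one crossing chromatid switches at each tract boundary
            first, second = (i, j) if rng.random() < 0.5 else (j, i)
            toggles[first].append(a)
            toggles[second].append(b)
            state[i], state[j] = 1, 0
            kept_intervals.append((a, b))

            inside = markers[(markers > a) & (markers < b)]
            left_ok = bool(np.any(markers <= a))
            right_ok = bool(np.any(markers >= b))
            detectable = left_ok and right_ok
            if has_tract and inside.size:
                co_type, gc = 1, frozenset({1})
            else:
                co_type, gc = 0, frozenset()
            co_events.append(
                SimEvent(
                    kind="co",
                    chromosome=chrom,
                    position=p,
                    chromatids=(i + 1, j + 1),
                    tract_start=a if has_tract else None,
                    tract_end=b if has_tract else None,
                    detectable=detectable,
                    expected_co_type=co_type,
                    expected_gc_types=gc,
                    n_tract_markers=int(inside.size),
                    first_marker_pos=int(inside[0]) if inside.size else None,
                    last_marker_pos=int(inside[-1]) if inside.size else None,
                )
            )

        # --- detached conversion tracts (NCOs and 4:0s)
        frac = length / genome_size
        nco_specs = [
            ("nco", rng.poisson(config.expected_nco_per_tetrad * frac)),
            ("gc40", rng.poisson(config.expected_gc40_per_tetrad * frac)),
        ]
        tract_events: list[SimEvent] = []
        for kind, count in nco_specs:
            for _ in range(int(count)):
                placed = False
                for _attempt in range(200):
                    c = float(rng.uniform(0, length))
                    t = float(rng.lognormal(t_mu, t_sigma))
                    s, e = c - t / 2.0, c + t / 2.0
                    if sep is not None and not _interval_clear(kept_intervals, s, e, sep):
                        continue
                    placed = True
                    break
                if not placed:
                    continue
                kept_intervals.append((s, e))
                inside = markers[(markers > s) & (markers < e)]
                if kind == "nco":
                    k = int(rng.integers(4))
                    targets = [k]
                else:
                    # convert both chromatids carrying one parental allele
                    allele = int(rng.integers(2))
                    targets = [
                        i
                        for i in range(4)
                        if _chromatid_genotype_at(toggles[i], _INITIAL_GENOTYPES[i], c)
                        == allele
                    ]
                for i in targets:
                    toggles[i].extend([s, e])
                gc = frozenset({0}) if kind == "nco" else frozenset({2})
                extra: set[int] = set()
                if inside.size:
                    if int(inside[0]) == int(markers[0]):
                        extra.add(3)
                    if int(inside[-1]) == int(markers[-1]):
                        extra.add(4)
                tract_events.append(
                    SimEvent(
                        kind=kind,
                        chromosome=chrom,
                        position=c,
                        chromatids=tuple(sorted(i + 1 for i in targets)),
                        tract_start=s,
                        tract_end=e,
                        detectable=bool(inside.size),
                        expected_co_type=None,
                        expected_gc_types=gc | frozenset(extra),
                        n_tract_markers=int(inside.size),
                        first_marker_pos=int(inside[0]) if inside.size else None,
                        last_marker_pos=int(inside[-1]) if inside.size else None,
                    )
                )

        # --- read genotypes off the marker grid
        geno = np.empty((markers.size, 4), dtype=np.int8)
        for i in range(4):
            tog = np.sort(np.asarray(toggles[i], dtype=float))
            flips = np.searchsorted(tog, markers.astype(float), side="right")
            geno[:, i] = _INITIAL_GENOTYPES[i] ^ (flips & 1)
        tetrad.set_chromosome(chrom, markers, geno)
        events = co_events + tract_events
        if sep is not None:
            _annotate_grid_detectability(events, markers, sep)
        truth.events.extend(events)

    truth.events.sort(key=lambda e: (e.chromosome, e.position))
    return tetrad, truth


def _chromatid_genotype_at(toggles: list[float], init: int, pos: float) -> int:
    return init ^ (int(np.searchsorted(np.sort(np.asarray(toggles)), pos)) & 1)


def _annotate_grid_detectability(
    events: list[SimEvent], markers: np.ndarray, sep: float
) -> None:
    """Demote events the marker grid cannot resolve as clean, separate events.

    Events were placed with true intervals at least ``sep`` apart, but the
    classifier works in marker space: estimated boundaries are midpoints with
    flanking markers, so a long marker gap can pull an estimated boundary far
    beyond the true one, and a gap with no marker between two events fuses
    them into a single interval.  An event keeps ``detectable`` only if (a)
    at least one marker separates its interval from each neighbor's, and (b)
    its midpoint-estimated span stays at least ``sep`` away from every
    neighbor's estimated position.
    """

    def interval(ev: SimEvent) -> tuple[float, float]:
        if ev.tract_start is not None:
            return ev.tract_start, ev.tract_end
        return ev.position, ev.position

    def est_span(ev: SimEvent) -> tuple[float, float]:
        s, e = interval(ev)
        lo = int(np.searchsorted(markers, s))
        hi = int(np.searchsorted(markers, e, side="right"))
        first = float(markers[lo]) if lo < markers.size else e
        last = float(markers[hi - 1]) if hi > 0 and hi - 1 >= lo else s
        left = float(markers[lo - 1]) if lo > 0 else first
        right = float(markers[hi]) if hi < markers.size else last
        if hi <= lo:  # no marker inside the interval
            mid = 0.5 * (left + right)
            return mid, mid
        return 0.5 * (left + first), 0.5 * (last + right)

    ordered = sorted(events, key=lambda ev: interval(ev)[0])
    for ev1, ev2 in zip(ordered, ordered[1:]):
        _, e1 = interval(ev1)
        s2, _ = interval(ev2)
        n_between = int(
            np.searchsorted(markers, s2) - np.searchsorted(markers, e1, side="right")
        )
        if n_between < 1:
            ev1.detectable = False
            ev2.detectable = False
            continue
        a1, b1 = est_span(ev1)
        a2, b2 = est_span(ev2)
        gap = min(abs(a2 - b1), abs(a2 - 0.5 * (a1 + b1)), abs(0.5 * (a2 + b2) - b1))
        if gap < sep:
            if ev1.kind != "co" or ev2.kind != "co":
                # a tract this close to a CO is legitimately relabeled 6/7
                if ev1.kind != "co":
                    ev1.detectable = False
                if ev2.kind != "co":
                    ev2.detectable = False
            else:
                ev1.detectable = False
                ev2.detectable = False


def simulate_tetrad_batch(
    n_tetrads: int,
    config: SimTetradConfig | None = None,
    seed: int = 0,
) -> tuple[list[Tetrad], list[SimTruth]]:
    """Simulate a batch of tetrads sharing one marker map."""
    config = config or SimTetradConfig()
    rng = np.random.default_rng(seed)
    marker_map = make_marker_map(config, rng)
    tetrads, truths = [], []
    for _ in range(n_tetrads):
        tet, tru = simulate_tetrad(config, rng, marker_map)
        tetrads.append(tet)
        truths.append(tru)
    return tetrads, truths


@dataclass(frozen=True)
class RecoveryResult:
    n_detectable: int
    n_recovered: int
    mismatches: tuple

    @property
    def fraction_recovered(self) -> float:
        if self.n_detectable == 0:
            return 1.0
        return self.n_recovered / self.n_detectable


def verify_recovery(truth: SimTruth, report) -> RecoveryResult:
    """Check that every detectable simulated event was classified correctly.

    Intended for simulations run with ``min_event_separation_bp`` above the
    classifier's merge/association ranges, where each event must map onto
    exactly one recovered CO or tract of the expected type.  A truth CO
    matches a recovered CO with the same chromatids whose flanking markers
    bracket the true breakpoint and whose type agrees; its connected tract
    (if detectable) must cover exactly the true tract markers and carry GC
    Type 1.  A truth NCO/4:0 tract matches a recovered tract with the same
    marker span whose labels include the expected ones.
    """
    cos = list(report.crossovers)
    tracts = list(report.tracts)
    mismatches: list[tuple] = []
    detectable = truth.detectable_events()
    for ev in detectable:
        if ev.kind == "co":
            cands = [
                c
                for c in cos
                if c.chromosome == ev.chromosome
                and set(c.chromatids) == set(ev.chromatids)
                and c.flank_left <= ev.position <= c.flank_right
            ]
            if len(cands) != 1 or cands[0].co_type != ev.expected_co_type:
                mismatches.append(("co", ev))
                continue
            if ev.expected_co_type == 1:
                linked = cands[0].linked_gc_ids
                ok = (
                    len(linked) == 1
                    and 1 in tracts[linked[0]].gc_types
                    and tracts[linked[0]].first_marker_pos == ev.first_marker_pos
                    and tracts[linked[0]].last_marker_pos == ev.last_marker_pos
                )
                if not ok:
                    mismatches.append(("co_tract", ev))
        else:
            cands = [
                t
                for t in tracts
                if t.chromosome == ev.chromosome
                and t.marker_count == ev.n_tract_markers
                and t.first_marker_pos == ev.first_marker_pos
            ]
            if len(cands) != 1 or not (ev.expected_gc_types <= cands[0].gc_types):
                mismatches.append((ev.kind, ev))
            elif ev.kind == "nco" and set(cands[0].chromatids) != set(ev.chromatids):
                mismatches.append(("nco_chromatid", ev))
    return RecoveryResult(
        n_detectable=len(detectable),
        n_recovered=len(detectable) - len(mismatches),
        mismatches=tuple(mismatches),
    )


# ---------------------------------------------------------------------------
# Read / pileup simulation
# ---------------------------------------------------------------------------


def _default_error_profile(read_length: int) -> np.ndarray:
    """Per-cycle substitution probability: low early, growing late in the read."""
    cycles = np.arange(read_length)
    return 0.002 + 0.018 * (cycles / max(1, read_length - 1)) ** 2


def _default_quality_profile(read_length: int) -> np.ndarray:
    """Per-cycle base quality: declines from ~38 toward ~18 at the last cycle."""
    cycles = np.arange(read_length)
    return np.round(38.0 - 20.0 * (cycles / max(1, read_length - 1)) ** 1.5)


@dataclass(frozen=True)
class ReadSimConfig:
    coverage: float = 25.0
    read_length: int = 36
    error_by_cycle: tuple[float, ...] | None = None
    quality_by_cycle: tuple[float, ...] | None = None
    mispool_rate: float = 0.1  # fraction of reads assigned to the wrong genome pool
    edge_exclusion: int = 3

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.error_by_cycle is not None and any(
            not 0 <= p <= 1 for p in self.error_by_cycle
        ):
            raise ValueError("error probabilities must lie in [0, 1]")

    def error_profile(self) -> np.ndarray:
        if self.error_by_cycle is not None:
            return np.asarray(self.error_by_cycle, dtype=float)
        return _default_error_profile(self.read_length)

    def quality_profile(self) -> np.ndarray:
        if self.quality_by_cycle is not None:
            return np.asarray(self.quality_by_cycle, dtype=float)
        return _default_quality_profile(self.read_length)


def simulate_pileups(
    true_genotypes: Sequence[int],
    config: ReadSimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized SNP pileup simulation for one spore.

    Returns ``(counts, qsums)`` arrays of shape (n_markers, 2 pools,
    3 base classes), class order (matches_A, matches_B, other).  Depth per
    marker is Poisson(coverage); each read observes the marker at a uniform
    random cycle, flips to a wrong base with the cycle's error probability
    (one third of errors hit the other parent's allele, two thirds an
    unexpected base), carries the cycle's quality, and lands in its true
    parent's genome pool except for a ``mispool_rate`` fraction.
    """
    truth = np.asarray(true_genotypes, dtype=np.int8)
    n_markers = truth.size
    err = config.error_profile()
    qual = config.quality_profile()

    depth = rng.poisson(config.coverage, size=n_markers)
    total = int(depth.sum())
    marker_of_read = np.repeat(np.arange(n_markers), depth)
    cycle = rng.integers(0, config.read_length, size=total)
    has_err = rng.random(total) < err[cycle]
    to_wrong_parent = has_err & (rng.random(total) < 1.0 / 3.0)
    to_other = has_err & ~to_wrong_parent

    true_class = truth[marker_of_read].astype(np.int64)  # 0 = matches_A, 1 = matches_B
    base_class = true_class.copy()
    base_class[to_wrong_parent] = 1 - true_class[to_wrong_parent]
    base_class[to_other] = 2

    pool = true_class.copy()
    mispooled = rng.random(total) < config.mispool_rate
    pool[mispooled] = 1 - pool[mispooled]

    q = qual[cycle]
    flat = (marker_of_read * 6 + pool * 3 + base_class).astype(np.int64)
    counts = np.bincount(flat, minlength=n_markers * 6).reshape(n_markers, 2, 3)
    qsums = np.bincount(flat, weights=q, minlength=n_markers * 6).reshape(
        n_markers, 2, 3
    )
    return counts, qsums


def simulate_pileup_observations(
    marker_ids: Sequence[str],
    true_genotypes: Sequence[int],
    config: ReadSimConfig,
    rng: np.random.Generator,
    marker_classes: Sequence[str] | None = None,
    border_offset: int = 1,
) -> list[PileupObservation]:
    """Per-read observation stream (slow path, for round-trip tests and I/O).

    For deletion markers each supporting read carries the two border-base
    qualities instead of a single quality; reads whose marker-overlapping
    bases fall within ``config.edge_exclusion`` bases of either read end are
    excluded, thinning indel depth accordingly.
    """
    truth = np.asarray(true_genotypes, dtype=np.int8)
    err = config.error_profile()
    qual = config.quality_profile()
    pools = (POOL_A, POOL_B)
    classes = (MATCHES_A, MATCHES_B, OTHER)
    out: list[PileupObservation] = []
    for m, marker_id in enumerate(marker_ids):
        mclass = marker_classes[m] if marker_classes is not None else MarkerClass.SNP
        is_indel = mclass in (MarkerClass.INSERTION, MarkerClass.DELETION)
        for _ in range(int(rng.poisson(config.coverage))):
            cycle = int(rng.integers(0, config.read_length))
            if is_indel and (
                cycle < config.edge_exclusion
                or cycle >= config.read_length - config.edge_exclusion
            ):
                continue
            true_class = int(truth[m])
            if rng.random() < err[cycle]:
                base_class = 1 - true_class if rng.random() < 1.0 / 3.0 else 2
            else:
                base_class = true_class
            pool = true_class
            if rng.random() < config.mispool_rate:
                pool = 1 - pool
            if mclass == MarkerClass.DELETION and base_class == true_class:
                q2 = qual[min(cycle + border_offset, config.read_length - 1)]
                out.append(
                    PileupObservation(
                        marker_id=marker_id,
                        genome_pool=pools[pool],
                        base_class=classes[base_class],
                        quality=None,
                        border_qualities=(float(qual[cycle]), float(q2)),
                    )
                )
            else:
                out.append(
                    PileupObservation(
                        marker_id=marker_id,
                        genome_pool=pools[pool],
                        base_class=classes[base_class],
                        quality=float(qual[cycle]),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Threshold-selection experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChimeraConfig:
    """A chimeric single chromosome alternating parental blocks.

    Defaults follow the genotyping accuracy simulation: ~700 kb with a
    crossover every 140 kb (five COs), markers from the standard spacing
    model.
    """

    length: int = 700_000
    co_spacing: int = 140_000
    marker_spacing_median_bp: float = 56.0
    marker_spacing_log_sd: float = 1.521

    def true_genotypes(self, positions: np.ndarray) -> np.ndarray:
        return ((positions // self.co_spacing) % 2).astype(np.int8)


def genotype_from_pileups(
    counts: np.ndarray,
    qsums: np.ndarray,
    threshold: float,
    config: GenotypingConfig | None = None,
) -> np.ndarray:
    """Final SNP genotype calls from pileup aggregate arrays.

    Applies per-pool cumulative scoring and thresholding, then the two-pool
    reconciliation rules, marker by marker via the genotyping module.
    Returns an int array with 0 (parent A), 1 (parent B), -1 (not called).
    """
    base_cfg = config or GenotypingConfig(threshold=threshold)
    if base_cfg.threshold != threshold:
        base_cfg = GenotypingConfig(
            threshold=threshold,
            threshold_ladder=base_cfg.threshold_ladder,
            indel_dominance_factor=base_cfg.indel_dominance_factor,
            edge_exclusion=base_cfg.edge_exclusion,
        )
    n = counts.shape[0]
    out = np.full(n, -1, dtype=np.int8)
    for m in range(n):
        provisional = []
        for pool_idx, pool in enumerate((POOL_A, POOL_B)):
            pc = PoolCounts(marker_id=str(m), genome_pool=pool)
            for c_idx, c in enumerate((MATCHES_A, MATCHES_B, OTHER)):
                pc.count[c] = int(counts[m, pool_idx, c_idx])
                pc.qsum[c] = float(qsums[m, pool_idx, c_idx])
            provisional.append(
                provisional_call_snp(
                    cumulative_scores(pc), base_cfg, marker_id=str(m), genome_pool=pool
                )
            )
        final = reconcile(provisional[0], provisional[1], MarkerClass.SNP, base_cfg)
        if final.call == CALL_A:
            out[m] = 0
        elif final.call == CALL_B:
            out[m] = 1
    return out


def simulate_genotyping_experiment(
    chimera: ChimeraConfig | None = None,
    coverage_levels: Sequence[float] = (25.0,),
    threshold_ladder: Sequence[float] = (20, 50, 80, 100, 120, 150, 200, 250, 300, 400, 500),
    n_reps: int = 6,
    read_config: ReadSimConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[dict]:
    """Genotyping accuracy on the chimeric chromosome.

    For each (coverage, rep) a fresh pileup is simulated and genotyped at
    every threshold in the ladder.  Returns one row per (coverage,
    threshold, rep) with keys ``coverage, threshold, rep, n_markers,
    frac_correct, n_incorrect, n_uncalled``.  This mimics genotyping of a
    single spore, not a whole tetrad.
    """
    chimera = chimera or ChimeraConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mu = np.log(chimera.marker_spacing_median_bp)
    sigma = chimera.marker_spacing_log_sd
    mean_gap = float(np.exp(mu + sigma**2 / 2.0))
    n_draw = int(chimera.length / mean_gap * 1.4) + 50
    gaps = rng.lognormal(mu, sigma, size=n_draw)
    pos = np.cumsum(gaps)
    pos = np.unique(np.maximum(1, np.round(pos[pos < chimera.length]).astype(np.int64)))
    truth = chimera.true_genotypes(pos)

    rows: list[dict] = []
    for coverage in coverage_levels:
        for rep in range(n_reps):
            cfg = read_config or ReadSimConfig()
            cfg = ReadSimConfig(
                coverage=float(coverage),
                read_length=cfg.read_length,
                error_by_cycle=cfg.error_by_cycle,
                quality_by_cycle=cfg.quality_by_cycle,
                mispool_rate=cfg.mispool_rate,
                edge_exclusion=cfg.edge_exclusion,
            )
            counts, qsums = simulate_pileups(truth, cfg, rng)
            for threshold in threshold_ladder:
                calls = genotype_from_pileups(counts, qsums, float(threshold))
                called = calls >= 0
                n_correct = int(np.sum(called & (calls == truth)))
                n_incorrect = int(np.sum(called & (calls != truth)))
                rows.append(
                    {
                        "coverage": float(coverage),
                        "threshold": float(threshold),
                        "rep": rep,
                        "n_markers": int(truth.size),
                        "frac_correct": n_correct / truth.size,
                        "n_incorrect": n_incorrect,
                        "n_uncalled": int(np.sum(~called)),
                    }
                )
    return rows


def accuracy_table(
    rows: Iterable[dict], coverage: float
) -> list[tuple[float, float, float]]:
    """Collapse experiment rows at one coverage into the threshold table
    consumed by threshold selection: (threshold, mean correct fraction,
    mean incorrect count)."""
    acc: dict[float, list[tuple[float, float]]] = {}
    for row in rows:
        if row["coverage"] == coverage:
            acc.setdefault(row["threshold"], []).append(
                (row["frac_correct"], row["n_incorrect"])
            )
    return [
        (
            threshold,
            float(np.mean([a for a, _ in vals])),
            float(np.mean([b for _, b in vals])),
        )
        for threshold, vals in sorted(acc.items())
    ]
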