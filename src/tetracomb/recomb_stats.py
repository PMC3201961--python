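"""Genome-wide recombination-regulation statistics over classified tetrads.

Covers the standard read-outs of crossover control in budding yeast:

* **CO interference** — inter-CO distances are fitted to a gamma
  distribution; the shape parameter gamma measures interference strength
  (gamma = 1 is a memoryless Poisson process, i.e. no interference).
* **Chromatid interference** — adjacent CO pairs involve 2, 3 or 4 distinct
  chromatids in a 1:2:1 ratio when chromatids are chosen independently;
  deviation is tested with a Pearson chi-square (df 2).
* **CO homeostasis** — the Pearson correlation between per-tetrad CO and
  NCO totals.
* **Regional suppression** — distances from each CO to the centromere and to
  the nearest telomere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .crossover_engine import EventReport
from .markers_io import GenomeAnnotation

__all__ = [
    "GammaFitResult",
    "ChromatidInterferenceResult",
    "SummaryStats",
    "inter_event_distances",
    "fit_gamma",
    "chromatid_interference",
    "chromatid_interference_from_counts",
    "adjacent_co_pair_chromatid_counts",
    "centromere_telomere_distances",
    "homeostasis",
    "summarize",
]

GAMMA_SHAPE_CAP = 1e6


@dataclass(frozen=True)
class GammaFitResult:
    shape: float          # gamma (dimensionless)
    scale: float          # beta, same units as the input distances (kb)
    n_distances: int
    log_likelihood: float


@dataclass(frozen=True)
class ChromatidInterferenceResult:
    n2: int
    n3: int
    n4: int
    chi_square: float
    p_value: float

    @property
    def n_pairs(self) -> int:
        return self.n2 + self.n3 + self.n4

    @property
    def ratio(self) -> tuple[float, float, float]:
        """Counts normalized to the 2-chromatid class, as conventionally printed."""
        if self.n2 == 0:
            return (float("nan"),) * 3
        return (1.0, self.n3 / self.n2, self.n4 / self.n2)


def _co_positions(report: EventReport) -> dict[int, list[float]]:
    out: dict[int, list[float]] = {}
    for co in report.crossovers:
        out.setdefault(co.chromosome, []).append(co.position)
    for lst in out.values():
        lst.sort()
    return out


def _nco_positions(report: EventReport) -> dict[int, list[float]]:
    out: dict[int, list[float]] = {}
    for t in report.tracts:
        if t.is_nco:
            out.setdefault(t.chromosome, []).append(t.position)
    for lst in out.values():
        lst.sort()
    return out


def inter_event_distances(reports: Iterable[EventReport]) -> dict[str, list[float]]:
    """Pooled within-chromosome inter-event distances (bp).

    Returns lists under the keys ``co_co`` (adjacent CO pairs), ``nco_nco``
    (adjacent NCO pairs) and ``co_gc`` (distance from each CO to the nearest
    GC tract on each side, per side).
    """
    co_co: list[float] = []
    nco_nco: list[float] = []
    co_gc: list[float] = []
    for report in reports:
        cos = _co_positions(report)
        for positions in cos.values():
            co_co.extend(float(b - a) for a, b in zip(positions, positions[1:]))
        for positions in _nco_positions(report).values():
            nco_nco.extend(float(b - a) for a, b in zip(positions, positions[1:]))
        gc_by_chrom: dict[int, np.ndarray] = {}
        for t in report.tracts:
            gc_by_chrom.setdefault(t.chromosome, [])
        for t in report.tracts:
            gc_by_chrom[t.chromosome].append(t.position)
        for chrom, positions in cos.items():
            gcs = np.sort(np.asarray(gc_by_chrom.get(chrom, []), dtype=float))
            if gcs.size == 0:
                continue
            for p in positions:
                k = int(np.searchsorted(gcs, p))
                left = gcs[:k]
                right = gcs[k:]
                if left.size:
                    co_gc.append(float(p - left[-1]))
                if right.size:
                    co_gc.append(float(right[0] - p))
    return {"co_co": co_co, "nco_nco": nco_nco, "co_gc": co_gc}


def fit_gamma(distances_kb: Sequence[float]) -> GammaFitResult:
    """Maximum-likelihood gamma fit to inter-CO distances (in kb).

    The shape is solved from the digamma equation
    ``log(k) - psi(k) = log(mean) - mean(log)`` and the scale is
    ``mean / shape``.  Exponential data recover shape ~ 1.  Degenerate
    (zero-variance) input caps the shape at 1e6 with a warning.
    """
    x = np.asarray(distances_kb, dtype=float)
    if x.size == 0:
        raise ValueError("no distances to fit")
    if np.any(x <= 0):
        raise ValueError("all distances must be positive")
    if x.size < 30:
        warnings.warn(
            f"gamma fit on only {x.size} distances; estimates will be noisy "
            "(a few hundred inter-CO distances are typically needed)",
            stacklevel=2,
        )
    mean = float(np.mean(x))
    s = float(np.log(mean) - np.mean(np.log(x)))
    if s <= 1e-12:  # zero-variance (constant) input, up to rounding
        warnings.warn("degenerate (constant) distances; shape capped", stacklevel=2)
        shape = GAMMA_SHAPE_CAP
    else:
        # Minka-style initialization, then solve log(k) - psi(k) = s.
        shape0 = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
        try:
            shape = float(
                optimize.brentq(
                    lambda k: np.log(k) - special.digamma(k) - s,
                    shape0 / 100.0,
                    shape0 * 100.0,
                    xtol=1e-12,
                )
            )
        except ValueError:
            shape = min(shape0, GAMMA_SHAPE_CAP)
    shape = min(shape, GAMMA_SHAPE_CAP)
    scale = mean / shape
    loglik = float(np.sum(stats.gamma.logpdf(x, a=shape, loc=0.0, scale=scale)))
    return GammaFitResult(shape=shape, scale=scale, n_distances=int(x.size),
                          log_likelihood=loglik)


def chi_square_1_2_1(n2: int, n3: int, n4: int) -> tuple[float, float]:
    """Pearson chi-square of (n2, n3, n4) against expected 1:2:1, df 2.

    The df-2 survival function has the closed form exp(-x/2).
    """
    observed = np.array([n2, n3, n4], dtype=float)
    total = observed.sum()
    if total == 0:
        raise ValueError("no CO pairs to test")
    expected = total * np.array([0.25, 0.5, 0.25])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(np.exp(-chi2 / 2.0))


def chromatid_interference_from_counts(
    n2: int, n3: int, n4: int
) -> ChromatidInterferenceResult:
    chi2, p = chi_square_1_2_1(n2, n3, n4)
    return ChromatidInterferenceResult(n2=n2, n3=n3, n4=n4, chi_square=chi2, p_value=p)


def adjacent_co_pair_chromatid_counts(
    reports: Iterable[EventReport],
    distance_range: tuple[float | None, float | None] = (None, None),
) -> tuple[int, int, int]:
    """Count adjacent same-chromosome CO pairs by chromatids involved (2/3/4).

    ``distance_range = (lo, hi)`` restricts to pairs with lo <= distance < hi
    (either bound may be None).  Double COs contribute the union of their two
    randomly assigned chromatid pairs.
    """
    lo, hi = distance_range
    counts = [0, 0, 0]
    for report in reports:
        by_chrom: dict[int, list[tuple[float, frozenset]]] = {}
        for co in report.crossovers:
            by_chrom.setdefault(co.chromosome, []).append(
                (co.position, frozenset(co.chromatids))
            )
        for lst in by_chrom.values():
            lst.sort(key=lambda t: t[0])
            for (p1, c1), (p2, c2) in zip(lst, lst[1:]):
                d = p2 - p1
                if lo is not None and d < lo:
                    continue
                if hi is not None and d >= hi:
                    continue
                n = len(c1 | c2)
                if n < 2 or n > 4:
                    raise AssertionError(f"impossible chromatid union size {n}")
                counts[n - 2] += 1
    return tuple(counts)


def chromatid_interference(
    reports: Iterable[EventReport],
    distance_range: tuple[float | None, float | None] = (None, None),
) -> ChromatidInterferenceResult:
    """Test chromatid interference on adjacent CO pairs pooled over tetrads."""
    n2, n3, n4 = adjacent_co_pair_chromatid_counts(list(reports), distance_range)
    return chromatid_interference_from_counts(n2, n3, n4)


def centromere_telomere_distances(
    reports: Iterable[EventReport],
    annotation: GenomeAnnotation,
    include_ncos: bool = False,
) -> dict[str, list[float]]:
    """Distances (bp) from each event to the centromere and nearest telomere."""
    out: dict[str, list[float]] = {"co_centromere": [], "co_telomere": []}
    if include_ncos:
        out["nco_centromere"] = []
        out["nco_telomere"] = []
    for report in reports:
        sources = [("co", _co_positions(report))]
        if include_ncos:
            sources.append(("nco", _nco_positions(report)))
        for prefix, by_chrom in sources:
            for chrom, positions in by_chrom.items():
                if chrom not in annotation.lengths:
                    raise ValueError(f"chromosome {chrom} missing from annotation")
                length = annotation.lengths[chrom]
                cen = annotation.centromeres[chrom]
                for p in positions:
                    out[f"{prefix}_centromere"].append(abs(p - cen))
                    out[f"{prefix}_telomere"].append(min(p, length - p))
    return out


def homeostasis(per_tetrad_counts: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation between per-tetrad CO and NCO totals.

    A negative correlation — NCOs dropping while COs hold steady — is the
    signature of crossover homeostasis.
    """
    if len(per_tetrad_counts) < 3:
        raise ValueError("homeostasis needs at least 3 tetrads")
    cos = np.array([c for c, _ in per_tetrad_counts], dtype=float)
    ncos = np.array([n for _, n in per_tetrad_counts], dtype=float)
    if np.std(cos) == 0 or np.std(ncos) == 0:
        warnings.warn("zero variance in per-tetrad counts; correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(cos, ncos)[0])


@dataclass
class SummaryStats:
    n_tetrads: int
    co_total: int
    nco_total: int
    per_tetrad_co: list[int]
    per_tetrad_nco: list[int]
    per_chromosome_co: dict[int, int]
    e0_total: int
    per_tetrad_e0: list[int]
    gc_type_counts: dict[int, int]
    gc_type_length_stats: dict[int, dict[str, float]]  # mean/median/sd of length_est
    co_type_counts: dict[int, int]
    homeostasis_r: float | None = None


def summarize(reports: Sequence[EventReport]) -> SummaryStats:
    """Pooled and per-tetrad event statistics for a batch of tetrads."""
    if not reports:
        raise ValueError("no reports to summarize")
    per_co = [r.co_count for r in reports]
    per_nco = [r.nco_count for r in reports]
    per_e0 = [len(r.e0_chromosomes) for r in reports]
    per_chrom: dict[int, int] = {}
    co_type_counts: dict[int, int] = {}
    gc_counts: dict[int, int] = {}
    gc_lengths: dict[int, list[float]] = {}
    for r in reports:
        for chrom, n in r.per_chromosome_co_counts().items():
            per_chrom[chrom] = per_chrom.get(chrom, 0) + n
        for co in r.crossovers:
            co_type_counts[co.co_type] = co_type_counts.get(co.co_type, 0) + 1
        for t in r.tracts:
            for gt in sorted(t.gc_types):
                gc_counts[gt] = gc_counts.get(gt, 0) + 1
                gc_lengths.setdefault(gt, []).append(t.length_est)
    length_stats = {
        gt: {
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        }
        for gt, v in gc_lengths.items()
    }
    r_homeo: float | None = None
    if len(reports) >= 3:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r_homeo = homeostasis(list(zip(per_co, per_nco)))
        except ValueError:
            r_homeo = None
    return SummaryStats(
        n_tetrads=len(reports),
        co_total=int(sum(per_co)),
        nco_total=int(sum(per_nco)),
        per_tetrad_co=per_co,
        per_tetrad_nco=per_nco,
        per_chromosome_co=per_chrom,
        e0_total=int(sum(per_e0)),
        per_tetrad_e0=per_e0,
        gc_type_counts=gc_counts,
        gc_type_length_stats=length_stats,
        co_type_counts=co_type_counts,
        homeostasis_r=r_homeo,
    )
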