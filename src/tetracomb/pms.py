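"""Post-meiotic segregation (PMS) detection from mother/daughter tetrad pairs.

Unrepaired heteroduplex DNA in a spore segregates its two mismatched strands
at the first mitotic division: the mother cell and its daughter then differ
in genotype at the affected markers.  Genotyping the four mothers and four
daughters as two separate tetrads and comparing them position by position
reveals these events.  Spore pairing is positional: spore *i* of the mother
tetrad is compared with spore *i* of the daughter tetrad.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers_io import Tetrad

__all__ = ["PMSEvent", "PMSResult", "find_pms", "group_pms_runs"]


@dataclass(frozen=True)
class PMSEvent:
    chromosome: int
    position: int
    spore_index: int  # 1-based
    mother_genotype: int
    daughter_genotype: int

    def __post_init__(self) -> None:
        if self.mother_genotype == self.daughter_genotype:
            raise ValueError("a PMS event requires differing genotypes")


@dataclass(frozen=True)
class PMSResult:
    events: tuple[PMSEvent, ...]
    n_shared_markers: int
    n_skipped_markers: int  # markers absent from one of the two segs


def find_pms(mother: Tetrad, daughter: Tetrad) -> PMSResult:
    """Compare mother and daughter segs; one event per differing (marker, spore).

    Markers present in only one seg are skipped and counted.  Swapping the
    inputs yields the same events with genotypes exchanged.
    """
    events: list[PMSEvent] = []
    shared = 0
    skipped = 0
    chroms = sorted(set(mother.chromosomes()) | set(daughter.chromosomes()))
    for chrom in chroms:
        has_m = chrom in mother.chromosomes()
        has_d = chrom in daughter.chromosomes()
        if not (has_m and has_d):
            only = mother if has_m else daughter
            skipped += only.chromosome(chrom)[0].size
            continue
        pos_m, geno_m = mother.chromosome(chrom)
        pos_d, geno_d = daughter.chromosome(chrom)
        common, idx_m, idx_d = np.intersect1d(pos_m, pos_d, return_indices=True)
        shared += common.size
        skipped += (pos_m.size - common.size) + (pos_d.size - common.size)
        gm = geno_m[idx_m]
        gd = geno_d[idx_d]
        diff_rows, diff_cols = np.nonzero(gm != gd)
        for r, c in zip(diff_rows.tolist(), diff_cols.tolist()):
            events.append(
                PMSEvent(
                    chromosome=chrom,
                    position=int(common[r]),
                    spore_index=c + 1,
                    mother_genotype=int(gm[r, c]),
                    daughter_genotype=int(gd[r, c]),
                )
            )
    events.sort(key=lambda e: (e.chromosome, e.position, e.spore_index))
    return PMSResult(events=tuple(events), n_shared_markers=shared,
                     n_skipped_markers=skipped)


def group_pms_runs(result: PMSResult, mother: Tetrad) -> list[list[PMSEvent]]:
    """Group PMS events into runs of adjacent markers on the same spore.

    Adjacency is with respect to the mother seg's marker order (no
    intervening genotyped marker without a PMS event on that spore).  A
    convenience for manual curation of heteroduplex tracts.
    """
    runs: list[list[PMSEvent]] = []
    by_key: dict[tuple[int, int], list[PMSEvent]] = {}
    for ev in result.events:
        by_key.setdefault((ev.chromosome, ev.spore_index), []).append(ev)
    for (chrom, _spore), evs in sorted(by_key.items()):
        pos, _ = mother.chromosome(chrom)
        index_of = {int(p): i for i, p in enumerate(pos.tolist())}
        current: list[PMSEvent] = []
        prev_idx: int | None = None
        for ev in evs:
            i = index_of.get(ev.position)
            if current and (i is None or prev_idx is None or i != prev_idx + 1):
                runs.append(current)
                current = []
            current.append(ev)
            prev_idx = i
        if current:
            runs.append(current)
    return runs
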