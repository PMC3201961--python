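"""Experimental-design arithmetic for sequencing-based tetrad genotyping."""

from __future__ import annotations

__all__ = ["expected_coverage", "projected_wrong_calls", "YEAST_GENOME_SIZE"]

YEAST_GENOME_SIZE = 12_000_000  # bp


def expected_coverage(
    reads_per_lane: float,
    read_length_bp: float,
    usable_fraction: float = 0.85,
    genome_size_bp: float = YEAST_GENOME_SIZE,
) -> float:
    """Expected fold coverage per lane.

    reads x read length x fraction of reads that align, divided by the
    genome size.  With 10 million 50-base reads and 85% usable this yields
    ~35-fold over the 12 Mb yeast genome.
    """
    if min(reads_per_lane, read_length_bp, usable_fraction, genome_size_bp) <= 0:
        raise ValueError("all inputs must be positive")
    return reads_per_lane * read_length_bp * usable_fraction / genome_size_bp


def projected_wrong_calls(
    miscall_fraction: float, n_markers: int, n_spores: int = 4
) -> float:
    """Expected wrong genotype calls per tetrad before four-spore filtering.

    The per-spore miscall fraction (e.g. 0.0003 for 0.03%) times the marker
    count times the number of spores.
    """
    if not 0 <= miscall_fraction <= 1:
        raise ValueError("miscall_fraction must be in [0, 1]")
    return miscall_fraction * n_markers * n_spores
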