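"""Normalized coverage records and covered-region discovery.

Normalized coverage (NC) is the per-base read density of a region scaled by
total sequencing effort and reference size::

    nc = (read_count / region_length) * (genome_size / total_mapped_reads)

which equals 1 for a region covered at the genome-wide average density and is
invariant under joint rescaling of read_count and total_mapped_reads. On
capture data NC is therefore the effective enrichment of the region, and is
comparable across genotypes and references sequenced to different depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    GeneModel,
    GenomicInterval,
    ThresholdConfig,
    ValidationError,
)


@dataclass
class DepthTrack:
    """Per-base read depth for one genotype on one reference and mode.

    ``mode`` distinguishes strict placement (no alignment gaps; long
    deletions leave zero-coverage windows) from gapped placement (reads
    span InDels up to the mapper's gap limit). ``read_starts`` holds sorted
    mapped read start positions when placements are available in memory or
    from a BED sidecar; depth-only tracks loaded from BedGraph estimate
    region read counts from depth mass instead.

    ``indel_observations`` are per-read gap records ``(kind, chrom,
    ref_start, length)`` with kind ``del``/``ins``, produced by gapped
    placement; they feed the short-InDel evidence aggregator.
    """

    reference_id: str
    genotype: str
    mode: str
    depths: dict[str, np.ndarray]
    total_mapped_reads: int
    read_length: int
    read_starts: dict[str, np.ndarray] | None = None
    indel_observations: list[tuple[str, str, int, int]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "gapped"):
            raise ValidationError(f"unknown mapping mode {self.mode!r}")
        for chrom, d in self.depths.items():
            if np.any(d < 0):
                raise ValidationError(f"negative depth on {chrom}")

    @property
    def genome_size(self) -> int:
        return sum(len(d) for d in self.depths.values())

    def depth_mass(self) -> int:
        return int(sum(int(d.sum()) for d in self.depths.values()))


@dataclass(frozen=True)
class CoverageRecord:
    """Read count and normalized coverage of one region for one genotype."""

    region: GenomicInterval
    genotype: str
    reference_id: str
    read_count: float
    nc: float
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.nc < 0 or self.read_count < 0:
            raise ValidationError("negative coverage")
        if (self.nc == 0) != (self.read_count == 0):
            raise ValidationError("nc must be zero exactly when read_count is")


@dataclass
class PopulationReference:
    """Per-copy mean normalized coverage over a simulated population."""

    mean_nc: dict[str, float]
    n_genotypes: int

    def __post_init__(self) -> None:
        if self.n_genotypes < 1:
            raise ValidationError("population needs at least one genotype")
        if any(v < 0 for v in self.mean_nc.values()):
            raise ValidationError("negative population mean")


def normalize_coverage(
    read_count: float,
    region_length: int,
    total_mapped_reads: int,
    genome_size: int,
) -> float:
    """Region read count normalized to length, read number and genome size."""
    if region_length <= 0 or total_mapped_reads <= 0 or genome_size <= 0:
        raise ValidationError(
            "region_length, total_mapped_reads and genome_size must be > 0"
        )
    if read_count < 0:
        raise ValidationError("read_count must be >= 0")
    return (read_count / region_length) * (genome_size / total_mapped_reads)


def region_read_count(track: DepthTrack, region: GenomicInterval) -> float:
    """Reads overlapping the region by at least one base.

    Counts placements when available (a read spanning two regions counts in
    each); otherwise estimates count as depth mass / read length.
    """
    if region.chrom not in track.depths:
        raise ValidationError(
            f"chrom {region.chrom} missing from track "
            f"{track.genotype}/{track.reference_id}"
        )
    if track.read_starts is not None and region.chrom in track.read_starts:
        starts = track.read_starts[region.chrom]
        lo = np.searchsorted(starts, region.start - track.read_length + 1)
        hi = np.searchsorted(starts, region.end)
        return float(hi - lo)
    mass = float(track.depths[region.chrom][region.start : region.end].sum())
    return mass / track.read_length


def region_coverage(
    track: DepthTrack,
    region: GenomicInterval,
    gene_id: str | None = None,
) -> CoverageRecord:
    count = region_read_count(track, region)
    nc = (
        0.0
        if count == 0
        else normalize_coverage(
            count, len(region), track.total_mapped_reads, track.genome_size
        )
    )
    return CoverageRecord(
        region=region,
        genotype=track.genotype,
        reference_id=track.reference_id,
        read_count=count,
        nc=nc,
        gene_id=gene_id,
    )


def gene_coverage(track: DepthTrack, gene: GeneModel) -> CoverageRecord:
    """Coverage over the annotated gene span (the preferred region proxy)."""
    return region_coverage(track, gene.span, gene_id=gene.gene_id)


def discover_covered_regions(
    track: DepthTrack, thresholds: ThresholdConfig | None = None
) -> list[GenomicInterval]:
    """Maximal regions covered by overlapping reads, filtered by NC.

    A region is a maximal run of bases with depth >= min_overlap_reads; runs
    whose normalized coverage falls below min_region_nc are dropped. Output
    is sorted and disjoint.
    """
    thr = thresholds or ThresholdConfig()
    out: list[GenomicInterval] = []
    for chrom in sorted(track.depths):
        d = track.depths[chrom]
        mask = d >= thr.min_overlap_reads
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        changes = np.flatnonzero(np.diff(padded.astype(np.int8)))
        run_starts, run_ends = changes[::2], changes[1::2]
        for s, e in zip(run_starts, run_ends):
            iv = GenomicInterval(chrom, int(s), int(e))
            rec = region_coverage(track, iv)
            if rec.nc >= thr.min_region_nc:
                out.append(iv)
    return out


__all__ = [
    "DepthTrack",
    "CoverageRecord",
    "PopulationReference",
    "normalize_coverage",
    "region_read_count",
    "region_coverage",
    "gene_coverage",
    "discover_covered_regions",
]
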