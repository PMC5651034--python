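"""Shared coordinate conventions, interval algebra and gene models.

All in-memory coordinates are 0-based half-open on the forward strand of a
named sequence. 1-based inclusive coordinates appear only at the GFF3/VCF
boundaries (see :mod:`capcnv.io`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

VALID_ALPHABET = frozenset("ACGTN")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length in bases between two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_overlapping_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Minimal sorted disjoint list covering the same bases.

    Abutting intervals ([0,5) and [5,9)) are merged. Strand is dropped.
    """
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


@dataclass(frozen=True)
class GeneModel:
    """A gene copy with exon/CDS structure.

    ``copy_name`` follows the dotted Genus.GENE.Chrom convention used for
    Brassica gene copies (e.g. ``Bna.ZTL.A02``); lettered suffixes for
    duplicated copies on one chromosome (``Bol.FLC.C09a``) are accepted.
    """

    gene_id: str
    copy_name: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        exs = sorted(self.exons, key=lambda e: e.start)
        for prev, cur in zip(exs, exs[1:]):
            if cur.start < prev.end:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(exs))
        object.__setattr__(
            self, "cds", tuple(sorted(self.cds, key=lambda c: c.start))
        )
        for c in self.cds:
            if not any(
                e.start <= c.start and c.end <= e.end for e in self.exons
            ):
                raise ValidationError(
                    f"{self.gene_id}: CDS {c} not inside any exon"
                )

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def in_frame(self) -> bool:
        """Whether total CDS length is a codon multiple (pseudogenes fail)."""
        return self.cds_length > 0 and self.cds_length % 3 == 0

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.span.chrom, a.end, b.start))
        return out

    @classmethod
    def parse_copy_name(cls, copy_name: str) -> tuple[str, str, str]:
        """Split ``Genus.GENE.Chrom[suffix]`` into its three fields."""
        parts = copy_name.split(".")
        if len(parts) < 3:
            raise ValidationError(f"copy name {copy_name!r} not Genus.GENE.Chrom")
        return parts[0], ".".join(parts[1:-1]), parts[-1]


@dataclass
class ReferenceSet:
    """Named nucleotide sequences used as a mapping target."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq.upper()) - VALID_ALPHABET
            if bad:
                raise ValidationError(
                    f"{name}: invalid characters {sorted(bad)}"
                )

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def interval_seq(self, iv: GenomicInterval) -> str:
        seq = self.sequences[iv.chrom]
        if iv.end > len(seq):
            raise ValidationError(
                f"{iv} outside {iv.chrom} (length {len(seq)})"
            )
        return seq[iv.start : iv.end]


@dataclass(frozen=True)
class ThresholdConfig:
    """Every numeric decision threshold of the analysis, in one place.

    Defaults follow the study conventions: regions need a normalized mean
    coverage of at least 10 and two overlapping reads; the two-genotype
    unbalance test fires at a 1.5-fold ratio; coverage below 30% of the other
    genotype (or of the population mean) is read as a deletion; SNPs are kept
    at MQ>=50, DP>=10 and InDels at MQ>=30, DP>=10; large deletions are
    scanned as 19 bp zero-coverage windows; gapped mapping of 100 bp reads
    resolves InDels only up to 18 bp; diploid reads on the tetraploid are
    expected near 200% of the tetraploid population mean.
    """

    min_region_nc: float = 10.0
    min_overlap_reads: int = 2
    unbalance_factor: float = 1.5
    deletion_ratio: float = 0.3
    pop_deletion_ratio: float = 0.3
    snp_min_mq: float = 50.0
    snp_min_dp: int = 10
    indel_min_mq: float = 30.0
    indel_min_dp: int = 10
    zero_window: int = 19
    max_short_indel: int = 18
    diploid_expected_pct: float = 200.0
    absent_pct: float = 30.0
    present_pct: float = 60.0
    exchange_pct: float = 120.0
    bootstrap_reps: int = 100
    strong_cov_min: float = 10.0
    low_cov_max: float = 2.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if not getattr(self, name) > 0:
                raise ValidationError(f"threshold {name} must be positive")
        if not self.deletion_ratio < 1.0 / self.unbalance_factor:
            raise ValidationError(
                "deletion_ratio must be below 1/unbalance_factor"
            )


@dataclass(frozen=True)
class RegionAssignment:
    region: GenomicInterval
    region_id: str
    gene_id: str | None
    target_gene: str | None

    @property
    def excluded(self) -> bool:
        """Non-genic regions (no gene overlap, no target hit) are excluded."""
        return self.gene_id is None and self.target_gene is None


def assign_regions_to_genes(
    regions: Mapping[str, GenomicInterval],
    genes: Sequence[GeneModel],
    target_map: Mapping[str, str] | None = None,
) -> list[RegionAssignment]:
    """Associate covered regions with annotated genes and/or target hits.

    A region is analyzable if it overlaps an annotated gene or has an entry
    in ``target_map`` (a region_id -> target-gene table standing in for a
    sequence-similarity search against the tetraploid target genes); regions
    with neither are flagged excluded. Multi-gene overlaps resolve to the
    maximum overlap, ties to the lexicographically smallest gene_id.
    """
    ids = list(regions)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate region identifiers")
    target_map = target_map or {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    out = []
    for rid in sorted(ids):
        region = regions[rid]
        best: tuple[int, str] | None = None
        for g in by_chrom.get(region.chrom, []):
            ov = interval_overlap(region, g.span)
            if ov > 0:
                key = (-ov, g.gene_id)
                if best is None or key < best:
                    best = key
        gene_id = best[1] if best else None
        out.append(
            RegionAssignment(region, rid, gene_id, target_map.get(rid))
        )
    return out


@dataclass
class LiftTable:
    """Piecewise-constant old->new coordinate map emitted by patching.

    ``breaks``/``offsets`` give, per chromosome, sorted old positions at which
    the offset changes and the offset valid from each break; positions inside
    removed spans lift to ``None``.
    """

    breaks: dict[str, list[int]] = field(default_factory=dict)
    offsets: dict[str, list[int | None]] = field(default_factory=dict)

    def lift(self, chrom: str, pos: int) -> int | None:
        if chrom not in self.breaks:
            return pos
        i = bisect.bisect_right(self.breaks[chrom], pos) - 1
        off = self.offsets[chrom][i]
        return None if off is None else pos + off


def patch_reference(
    ref: ReferenceSet,
    excise: Sequence[GenomicInterval] = (),
    replace_map: Mapping[GenomicInterval, str] | None = None,
) -> tuple[ReferenceSet, LiftTable]:
    """Cut spans out of a reference, optionally substituting new sequence.

    Mirrors the reference-surgery step of capture pipelines where a
    misassembled gene copy is excised or replaced by an externally sequenced
    allele before mapping. Returns the patched reference and a lift table
    mapping retained old coordinates to new ones (bases inside an excised or
    replaced span lift to ``None``). The operation is reversible given the
    lift table and the removed sequences.
    """
    replace_map = dict(replace_map or {})
    edits: list[tuple[GenomicInterval, str]] = [
        (iv, "") for iv in excise
    ] + list(replace_map.items())
    for iv, repl in edits:
        if iv.chrom not in ref.sequences:
            raise ValidationError(f"{iv.chrom} not in reference")
        if iv.end > len(ref.sequences[iv.chrom]):
            raise ValidationError(f"{iv} outside reference")
        if set(repl.upper()) - VALID_ALPHABET:
            raise ValidationError("replacement sequence has invalid alphabet")
    per_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for iv, repl in edits:
        per_chrom.setdefault(iv.chrom, []).append((iv, repl))
    for chrom, chrom_edits in per_chrom.items():
        chrom_edits.sort(key=lambda e: e[0].start)
        for (a, _), (b, _) in zip(chrom_edits, chrom_edits[1:]):
            if b.start < a.end:
                raise ValidationError(f"overlapping edits on {chrom}")

    new_seqs: dict[str, str] = {}
    lift = LiftTable()
    for chrom, seq in ref.sequences.items():
        chrom_edits = per_chrom.get(chrom)
        if not chrom_edits:
            new_seqs[chrom] = seq
            continue
        pieces: list[str] = []
        breaks: list[int] = [0]
        offsets: list[int | None] = [0]
        cursor = 0
        delta = 0
        for iv, repl in chrom_edits:
            pieces.append(seq[cursor : iv.start])
            pieces.append(repl)
            breaks.append(iv.start)
            offsets.append(None)
            delta += len(repl) - len(iv)
            breaks.append(iv.end)
            offsets.append(delta)
            cursor = iv.end
        pieces.append(seq[cursor:])
        new_seqs[chrom] = "".join(pieces)
        lift.breaks[chrom] = breaks
        lift.offsets[chrom] = offsets
    return ReferenceSet(new_seqs), lift


__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ReferenceSet",
    "ThresholdConfig",
    "RegionAssignment",
    "LiftTable",
    "ValidationError",
    "interval_overlap",
    "merge_overlapping_intervals",
    "assign_regions_to_genes",
    "patch_reference",
]
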