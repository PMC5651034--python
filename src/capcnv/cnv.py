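"""CNV decision procedures on normalized coverage.

Two-genotype classification proceeds in three steps: (1) an unbalance test —
the higher coverage must be at least unbalance_factor (1.5x, i.e. "at least
50% higher") times the lower, otherwise no call; (2) a hard deletion test —
the low genotype below deletion_ratio (30%) of the high one is a deletion;
(3) a population tiebreak — the low genotype is compared to the mean
normalized coverage of the orthologous region in a tetraploid population:
below pop_deletion_ratio (30%) it is a deletion in the low genotype,
otherwise a duplication in the high genotype.

Cross-species status of a tetraploid gene copy is read from diploid
normalized coverages expressed as percent of the tetraploid population mean
(a diploid carrying the copy is expected near 200%, since its sequenced gene
space is about half that of the allotetraploid at comparable read numbers):
the progenitor matching the copy's subgenome below absent_pct everywhere is
absent, above present_pct everywhere present, otherwise reduced/ambiguous;
an absent/reduced matching progenitor combined with the other progenitor
everywhere above exchange_pct indicates a homoeologous exchange supplied by
the other subgenome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import GeneModel, GenomicInterval, ThresholdConfig, ValidationError
from .coverage import CoverageRecord, DepthTrack


@dataclass(frozen=True)
class CNVCall:
    key: str  # gene_id or region id
    low_genotype: str
    high_genotype: str
    nc_low: float
    nc_high: float
    ratio_low_high: float
    pop_ratio: float | None
    call: str  # none | deletion_in_low | duplication_in_high | unresolved
    evidence: str

    @property
    def carrier(self) -> str | None:
        """Genotype carrying the event (deletion: low; duplication: high)."""
        if self.call == "deletion_in_low":
            return self.low_genotype
        if self.call == "duplication_in_high":
            return self.high_genotype
        return None


@dataclass(frozen=True)
class CrossSpeciesCall:
    copy_name: str
    subgenome: str  # A | C
    pct_matching: tuple[float, ...]
    pct_other: tuple[float, ...]
    status: str  # present | absent | reduced_ambiguous | exchanged
    direction: str | None = None  # subgenome that supplied the copy


@dataclass(frozen=True)
class LargeDeletionCandidate:
    genotype: str
    interval: GenomicInterval
    min_other_depth: float
    mean_other_depth: float
    max_own_gapped_depth: float
    overlaps_gene: bool = False

    def __post_init__(self) -> None:
        if len(self.interval) < 1:
            raise ValidationError("empty candidate interval")


def classify_cnv_pair(
    rec_g1: CoverageRecord,
    rec_g2: CoverageRecord,
    pop_mean: float | None,
    thresholds: ThresholdConfig | None = None,
) -> CNVCall:
    """Classify one region between two genotypes of the same species."""
    thr = thresholds or ThresholdConfig()
    if rec_g1.region != rec_g2.region or rec_g1.reference_id != rec_g2.reference_id:
        raise ValidationError("records must describe the same region")
    if pop_mean is not None and pop_mean <= 0:
        raise ValidationError("pop_mean must be positive when given")
    key = rec_g1.gene_id or (
        f"{rec_g1.region.chrom}:{rec_g1.region.start}-{rec_g1.region.end}"
    )
    # deterministic low/high assignment; ties broken by genotype name
    a, b = sorted((rec_g1, rec_g2), key=lambda r: (r.nc, r.genotype))
    low, high = a, b
    if high.nc == 0:
        return CNVCall(
            key, low.genotype, high.genotype, 0.0, 0.0, 0.0, None,
            "none", "zero_coverage_both",
        )
    ratio = low.nc / high.nc
    pop_ratio = None if pop_mean is None else low.nc / pop_mean
    common = dict(
        key=key,
        low_genotype=low.genotype,
        high_genotype=high.genotype,
        nc_low=low.nc,
        nc_high=high.nc,
        ratio_low_high=ratio,
        pop_ratio=pop_ratio,
    )
    if high.nc < thr.unbalance_factor * low.nc:
        return CNVCall(call="none", evidence="balanced", **common)
    if ratio < thr.deletion_ratio:
        return CNVCall(
            call="deletion_in_low",
            evidence=f"low/high={ratio:.3f}<{thr.deletion_ratio}",
            **common,
        )
    if pop_mean is None:
        return CNVCall(
            call="unresolved", evidence="no population reference", **common
        )
    if pop_ratio < thr.pop_deletion_ratio:
        return CNVCall(
            call="deletion_in_low",
            evidence=f"low/pop={pop_ratio:.3f}<{thr.pop_deletion_ratio}",
            **common,
        )
    return CNVCall(
        call="duplication_in_high",
        evidence=f"low/pop={pop_ratio:.3f}>={thr.pop_deletion_ratio}",
        **common,
    )


def classify_cross_species(
    pcts_progenitor_a: Sequence[float],
    pcts_progenitor_c: Sequence[float],
    copy_name: str,
    copy_subgenome: str,
    thresholds: ThresholdConfig | None = None,
) -> CrossSpeciesCall:
    """Copy status from diploid coverages in percent of the population mean."""
    thr = thresholds or ThresholdConfig()
    if copy_subgenome not in ("A", "C"):
        raise ValidationError(f"bad subgenome {copy_subgenome!r}")
    if not pcts_progenitor_a or not pcts_progenitor_c:
        raise ValidationError("need at least one percentage per progenitor")
    by_sub = {"A": tuple(pcts_progenitor_a), "C": tuple(pcts_progenitor_c)}
    matching = by_sub[copy_subgenome]
    other_sub = "C" if copy_subgenome == "A" else "A"
    other = by_sub[other_sub]
    if all(p < thr.absent_pct for p in matching):
        status = "absent"
    elif all(p >= thr.present_pct for p in matching):
        status = "present"
    else:
        status = "reduced_ambiguous"
    direction = None
    if status in ("absent", "reduced_ambiguous") and all(
        p >= thr.exchange_pct for p in other
    ):
        status, direction = "exchanged", other_sub
    return CrossSpeciesCall(
        copy_name=copy_name,
        subgenome=copy_subgenome,
        pct_matching=matching,
        pct_other=other,
        status=status,
        direction=direction,
    )


@dataclass(frozen=True)
class CopyReconciliation:
    family: str
    subgenome: str
    napus_copy: str | None
    diploid_copy: str | None
    label: str  # retained | lost_in_napus | gained_in_napus | exchanged |
    #            covered_but_unannotated_in_diploid | absent


def reconcile_copy_sets(
    ortholog_map: Mapping[str, Mapping[str, str | None]],
    cross_calls: Mapping[str, CrossSpeciesCall],
    diploid_covered: Mapping[tuple[str, str], bool],
) -> list[CopyReconciliation]:
    """Per-copy gain/loss/exchange labels across tetraploid and progenitors.

    ``ortholog_map[family]`` maps 'tetraploid_A'/'tetraploid_C'/'A'/'C' to a
    copy name or None (annotation present or not); ``diploid_covered`` flags
    capture coverage of the family locus in each progenitor subgenome.
    """
    known_napus = {
        m.get(f"tetraploid_{sub}")
        for m in ortholog_map.values()
        for sub in ("A", "C")
    }
    for copy_name in cross_calls:
        if copy_name not in known_napus:
            raise ValidationError(
                f"cross-species call for {copy_name} missing from ortholog map"
            )
    out = []
    for family in sorted(ortholog_map):
        m = ortholog_map[family]
        for sub in ("A", "C"):
            napus_copy = m.get(f"tetraploid_{sub}")
            diploid_copy = m.get(sub)
            covered_here = diploid_covered.get((family, sub), False)
            covered_any = covered_here or diploid_covered.get(
                (family, "C" if sub == "A" else "A"), False
            )
            if napus_copy is None:
                if diploid_copy is None:
                    continue
                label = "lost_in_napus" if covered_here else "absent"
            else:
                call = cross_calls.get(napus_copy)
                if call is not None and call.status == "exchanged":
                    label = "exchanged"
                elif not covered_any:
                    label = "gained_in_napus"
                elif diploid_copy is None:
                    label = "covered_but_unannotated_in_diploid"
                else:
                    label = "retained"
            out.append(
                CopyReconciliation(family, sub, napus_copy, diploid_copy, label)
            )
    return out


def scan_large_deletions(
    strict_own: DepthTrack,
    strict_other: DepthTrack,
    gapped_own: DepthTrack,
    thresholds: ThresholdConfig | None = None,
    genes: Sequence[GeneModel] = (),
) -> list[LargeDeletionCandidate]:
    """Zero-coverage window scan for deletions beyond the short-InDel limit.

    Reports maximal runs of >= zero_window bases with zero strict-mode depth
    in the carrier that are strongly covered in the other genotype (mean
    strict depth >= strong_cov_min) and lowly covered in the carrier's gapped
    placement (mean depth <= low_cov_max). The other-genotype condition
    separates genotype-specific deletions from shared reference-mapping
    dropouts.
    """
    thr = thresholds or ThresholdConfig()
    if not (
        strict_own.reference_id
        == strict_other.reference_id
        == gapped_own.reference_id
    ):
        raise ValidationError("tracks must share a reference")
    out: list[LargeDeletionCandidate] = []
    for chrom in sorted(strict_own.depths):
        if chrom not in strict_other.depths or chrom not in gapped_own.depths:
            raise ValidationError(f"chrom {chrom} missing from a track")
        own = strict_own.depths[chrom]
        other = strict_other.depths[chrom]
        gapped = gapped_own.depths[chrom]
        mask = own == 0
        padded = np.concatenate(([False], mask, [False]))
        changes = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(changes[::2], changes[1::2]):
            s, e = int(s), int(e)
            if e - s < thr.zero_window:
                continue
            mean_other = float(other[s:e].mean())
            mean_gapped = float(gapped[s:e].mean())
            if mean_other < thr.strong_cov_min or mean_gapped > thr.low_cov_max:
                continue
            iv = GenomicInterval(chrom, s, e)
            overlaps = any(
                g.span.chrom == chrom and g.span.start < e and s < g.span.end
                for g in genes
            )
            out.append(
                LargeDeletionCandidate(
                    genotype=strict_own.genotype,
                    interval=iv,
                    min_other_depth=float(other[s:e].min()),
                    mean_other_depth=mean_other,
                    max_own_gapped_depth=float(gapped[s:e].max()),
                    overlaps_gene=overlaps,
                )
            )
    return out


__all__ = [
    "CNVCall",
    "CrossSpeciesCall",
    "LargeDeletionCandidate",
    "CopyReconciliation",
    "classify_cnv_pair",
    "classify_cross_species",
    "reconcile_copy_sets",
    "scan_large_deletions",
]
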