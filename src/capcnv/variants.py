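"""SNP/InDel filtering, zygosity accounting and consequence annotation.

Substitution severity uses the Grantham (1974) physico-chemical distance
between amino acids (composition, polarity, molecular volume), binned into
the classical classes: <=50 conservative, 51-100 moderately conservative,
101-150 moderately radical, >150 radical. Annotation distinguishes silent
(non-coding within the analyzed region), synonymous and nonsynonymous CDS
substitutions, stop gain/loss, canonical splice-site (first/last two intron
bases) hits, and in-frame vs frameshift InDels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .core import GeneModel, GenomicInterval, ReferenceSet, ThresholdConfig, ValidationError
from .coverage import DepthTrack

SNP = "snp"
INDEL = "indel"

#: Grantham (1974) amino-acid distance matrix, upper triangle.
_GRANTHAM_ORDER = "SRLPTAVGIFYCHQNKDEMW"
_GRANTHAM_UPPER = [
    # S    R    L    P    T    A    V    G    I    F    Y    C    H    Q    N    K    D    E    M    W
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],  # S
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],  # R
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],  # L
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],  # P
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],  # T
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],  # A
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],  # V
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],  # G
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],  # I
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],  # F
    [194, 83, 99, 143, 85, 160, 122, 36, 37],  # Y
    [174, 154, 139, 202, 154, 170, 196, 215],  # C
    [24, 68, 32, 81, 40, 87, 115],  # H
    [46, 53, 61, 29, 101, 130],  # Q
    [94, 23, 42, 142, 174],  # N
    [101, 56, 95, 110],  # K
    [45, 160, 181],  # D
    [126, 152],  # E
    [67],  # M
]

GRANTHAM: dict[tuple[str, str], int] = {}
for _i, _row in enumerate(_GRANTHAM_UPPER):
    for _k, _d in enumerate(_row):
        _a, _b = _GRANTHAM_ORDER[_i], _GRANTHAM_ORDER[_i + 1 + _k]
        GRANTHAM[(_a, _b)] = _d
        GRANTHAM[(_b, _a)] = _d
for _a in _GRANTHAM_ORDER:
    GRANTHAM[(_a, _a)] = 0

RADICALITY_BINS = (
    (50, "conservative"),
    (100, "moderately_conservative"),
    (150, "moderately_radical"),
)

CATEGORIES = (
    "silent",
    "synonymous",
    "nonsynonymous",
    "inframe_indel",
    "frameshift_indel",
    "splice_donor",
    "splice_acceptor",
    "stop_gain",
    "stop_loss",
)

#: Severity order for per-copy reporting; nonsynonymous sub-ranked by
#: radicality so a radical change outranks a conservative one.
_SEVERITY = {
    "frameshift_indel": 90,
    "stop_gain": 80,
    "stop_loss": 80,
    "splice_donor": 70,
    "splice_acceptor": 70,
    ("nonsynonymous", "radical"): 64,
    ("nonsynonymous", "moderately_radical"): 63,
    ("nonsynonymous", "moderately_conservative"): 62,
    ("nonsynonymous", "conservative"): 61,
    "inframe_indel": 50,
    "synonymous": 40,
    "silent": 30,
}


@dataclass(frozen=True)
class VariantRecord:
    """A filtered-callset row: one biallelic variant for one genotype."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    vtype: str  # snp | indel
    mq: float
    dp: int
    zygosity: str  # hom | het
    genotype: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError("ref and alt alleles must differ")
        if self.vtype == SNP and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValidationError("snp must have single-base alleles")
        if self.vtype not in (SNP, INDEL):
            raise ValidationError(f"bad variant type {self.vtype!r}")
        if self.dp < 0 or self.pos < 1:
            raise ValidationError("dp must be >= 0 and pos >= 1")
        if self.zygosity not in ("hom", "het"):
            raise ValidationError(f"bad zygosity {self.zygosity!r}")

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


@dataclass(frozen=True)
class ConsequenceAnnotation:
    category: str
    protein_change: str | None = None
    grantham_distance: int | None = None
    radicality: str = "none"
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"bad category {self.category!r}")
        if (self.radicality != "none") != (self.category == "nonsynonymous"):
            raise ValidationError(
                "radicality is set exactly for nonsynonymous substitutions"
            )


def filter_variants(
    records: Iterable[VariantRecord], thresholds: ThresholdConfig | None = None
) -> list[VariantRecord]:
    """Keep SNPs at MQ>=50 & DP>=10 and InDels at MQ>=30 & DP>=10."""
    thr = thresholds or ThresholdConfig()
    out = []
    for r in records:
        if r.vtype == SNP:
            keep = r.mq >= thr.snp_min_mq and r.dp >= thr.snp_min_dp
        else:
            keep = r.mq >= thr.indel_min_mq and r.dp >= thr.indel_min_dp
        if keep:
            out.append(r)
    return out


@dataclass(frozen=True)
class HetStats:
    n_snp: int
    n_indel: int
    het_snp_pct: float | None
    het_indel_pct: float | None
    het_combined_pct: float | None


def heterozygosity_stats(
    records: Sequence[VariantRecord],
) -> tuple[HetStats, list[VariantRecord]]:
    """Heterozygous fractions plus the homozygous-only subset.

    Only homozygous variants are treated as true variants downstream; the
    heterozygous fraction itself is a reported statistic.
    """

    def pct(subset: list[VariantRecord]) -> float | None:
        if not subset:
            return None
        het = sum(1 for r in subset if r.zygosity == "het")
        return 100.0 * het / len(subset)

    snps = [r for r in records if r.vtype == SNP]
    indels = [r for r in records if r.vtype == INDEL]
    stats = HetStats(
        n_snp=len(snps),
        n_indel=len(indels),
        het_snp_pct=pct(snps),
        het_indel_pct=pct(indels),
        het_combined_pct=pct(list(records)),
    )
    hom = [r for r in records if r.zygosity == "hom"]
    return stats, hom


def grantham_distance(aa_ref: str, aa_alt: str) -> int:
    key = (aa_ref.upper(), aa_alt.upper())
    if key not in GRANTHAM:
        raise ValidationError(f"non-standard residue in {key}")
    return GRANTHAM[key]


def grantham_class(aa_ref: str, aa_alt: str) -> tuple[int, str]:
    """Grantham distance and its conservative-to-radical class."""
    d = grantham_distance(aa_ref, aa_alt)
    for upper, label in RADICALITY_BINS:
        if d <= upper:
            return d, label
    return d, "radical"


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of CDS bases in transcription order."""
    pos = [p for c in gene.cds for p in range(c.start, c.end)]
    if gene.strand == "-":
        pos.reverse()
    return pos


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _read_base(ref: ReferenceSet, chrom: str, pos: int, strand: str) -> str:
    b = ref.sequences[chrom][pos].upper()
    return b.translate(_COMPLEMENT) if strand == "-" else b


def _splice_sites(gene: GeneModel) -> dict[int, str]:
    """Map genomic position -> splice category for 2-base canonical sites."""
    sites: dict[int, str] = {}
    for intron in gene.introns():
        if len(intron) < 4:
            continue
        if gene.strand == "+":
            donor = (intron.start, intron.start + 1)
            acceptor = (intron.end - 2, intron.end - 1)
        else:
            donor = (intron.end - 1, intron.end - 2)
            acceptor = (intron.start + 1, intron.start)
        for p in donor:
            sites[p] = "splice_donor"
        for p in acceptor:
            sites[p] = "splice_acceptor"
    return sites


def annotate_variant(
    record: VariantRecord,
    gene: GeneModel,
    ref: ReferenceSet,
    flank: int = 1000,
) -> ConsequenceAnnotation:
    """Functional consequence of one variant against one gene copy.

    Variants are annotated against each overlapping copy independently.
    Genes whose CDS length is not a codon multiple are treated as putative
    pseudogenes: translation-dependent categories are skipped and CDS
    substitutions fall back to silent with the pseudogene flag set.
    """
    pos0 = record.pos - 1
    span = gene.span
    if record.chrom != span.chrom or not (
        span.start - flank <= pos0 < span.end + flank
    ):
        raise ValidationError(
            f"variant {record.chrom}:{record.pos} outside neighborhood of "
            f"{gene.copy_name}"
        )

    if record.vtype == INDEL:
        # affected reference span past the anchor base (insertion: the
        # insertion point between anchor and next base)
        if len(record.ref) > len(record.alt):
            affected = GenomicInterval(
                record.chrom, pos0 + 1, pos0 + len(record.ref)
            )
            in_cds = any(
                affected.start < c.end and c.start < affected.end
                for c in gene.cds
            )
        else:
            point = pos0 + 1
            in_cds = any(c.start <= point < c.end for c in gene.cds)
        if in_cds:
            if not gene.in_frame:
                return ConsequenceAnnotation("silent", pseudogene=True)
            if record.indel_length % 3 == 0:
                return ConsequenceAnnotation("inframe_indel")
            return ConsequenceAnnotation("frameshift_indel")
        return ConsequenceAnnotation("silent")

    # substitutions
    splice = _splice_sites(gene)
    if pos0 in splice:
        return ConsequenceAnnotation(splice[pos0])
    cds_pos = _cds_positions(gene)
    try:
        idx = cds_pos.index(pos0)
    except ValueError:
        return ConsequenceAnnotation("silent")
    if not gene.in_frame:
        return ConsequenceAnnotation("silent", pseudogene=True)
    codon_i = idx // 3
    codon_genomic = cds_pos[3 * codon_i : 3 * codon_i + 3]
    ref_codon = "".join(
        _read_base(ref, record.chrom, p, gene.strand) for p in codon_genomic
    )
    alt_base = (
        record.alt.upper().translate(_COMPLEMENT)
        if gene.strand == "-"
        else record.alt.upper()
    )
    within = idx % 3
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    n_codons = len(cds_pos) // 3
    is_terminal = codon_i == n_codons - 1
    change = f"{aa_ref}{codon_i + 1}{aa_alt}"
    if aa_ref == aa_alt:
        return ConsequenceAnnotation("synonymous", protein_change=change)
    if aa_alt == "*" and not is_terminal:
        return ConsequenceAnnotation("stop_gain", protein_change=change)
    if aa_ref == "*" and is_terminal:
        return ConsequenceAnnotation("stop_loss", protein_change=change)
    if aa_ref == "*" or aa_alt == "*":
        # premature reference stop or terminal stop gained again: treat the
        # remaining stop-involving cases as stop category by direction
        cat = "stop_gain" if aa_alt == "*" else "stop_loss"
        return ConsequenceAnnotation(cat, protein_change=change)
    d, radicality = grantham_class(aa_ref, aa_alt)
    return ConsequenceAnnotation(
        "nonsynonymous",
        protein_change=change,
        grantham_distance=d,
        radicality=radicality,
    )


def severity_key(ann: ConsequenceAnnotation) -> int:
    if ann.category == "nonsynonymous":
        return _SEVERITY[("nonsynonymous", ann.radicality)]
    return _SEVERITY[ann.category]


def severity_rank(
    annotations: Sequence[ConsequenceAnnotation],
) -> tuple[ConsequenceAnnotation | None, list[ConsequenceAnnotation]]:
    """Most severe annotation and the full list ordered most-severe-first.

    The hierarchy mirrors per-copy pathway displays where only the most
    severe variant class of a copy is shown.
    """
    if not annotations:
        return None, []
    ordered = sorted(annotations, key=severity_key, reverse=True)
    return ordered[0], ordered


def call_short_indels(
    track: DepthTrack,
    thresholds: ThresholdConfig | None = None,
    min_support: int = 2,
    genotype: str | None = None,
) -> list[VariantRecord]:
    """Aggregate gapped-placement gap observations into InDel calls.

    With 100 bp single reads a gapped mapper only places reads across
    InDels up to max_short_indel bases, so this pathway cannot emit calls
    for longer events; those are left to the zero-coverage window scan.
    Support (reads sharing the identical gap) becomes DP.
    """
    thr = thresholds or ThresholdConfig()
    if track.mode != "gapped":
        raise ValidationError("short-InDel calling requires a gapped track")
    counts: dict[tuple[str, str, int, int], int] = {}
    for kind, chrom, start, length in track.indel_observations:
        counts[(kind, chrom, start, length)] = (
            counts.get((kind, chrom, start, length), 0) + 1
        )
    out = []
    for (kind, chrom, start, length), n in sorted(counts.items()):
        if n < min_support or length > thr.max_short_indel:
            continue
        if kind == "del":
            ref_a, alt_a = "N" * (length + 1), "N"
        else:
            ref_a, alt_a = "N", "N" * (length + 1)
        out.append(
            VariantRecord(
                chrom=chrom,
                pos=start,  # anchor base before the gap, 1-based
                ref=ref_a,
                alt=alt_a,
                vtype=INDEL,
                mq=60.0,
                dp=n,
                zygosity="hom",
                genotype=genotype or track.genotype,
            )
        )
    return out


__all__ = [
    "VariantRecord",
    "ConsequenceAnnotation",
    "HetStats",
    "GRANTHAM",
    "CATEGORIES",
    "filter_variants",
    "heterozygosity_stats",
    "grantham_distance",
    "grantham_class",
    "annotate_variant",
    "severity_rank",
    "severity_key",
    "call_short_indels",
]
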