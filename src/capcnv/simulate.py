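"""Synthetic allotetraploid capture dataset generator.

The generator emulates the study design the pipeline is built for: a
tetraploid reference made of two diverged but collinear subgenomes (A and
C), two diploid progenitor-like references (one subgenome each), diploid
genotypes carrying injected variation (SNPs, short InDels, large deletions,
duplications, whole-copy losses, and reciprocal homoeologous exchanges fixed
in the tetraploid), and capture-style depth tracks.

Reads are abstracted as placed 100 bp intervals without base-call errors:
the downstream analysis consumes depth and called variants only. Placement
follows a best-homologous-match rule — a read is compared against the
homologous position on its own chromosome and on the partner subgenome
chromosome and is placed at the candidate with fewer mismatches when that
count is within the strict mapper's tolerance. Strict placement rejects any
read crossing an InDel junction; gapped placement additionally places reads
across a single gap of at most max_short_indel bases (the 18 bp limit of
gapped mapping with 100 bp single reads), recording the gap observation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    GeneModel,
    GenomicInterval,
    ReferenceSet,
    ValidationError,
)
from .coverage import DepthTrack

MAX_SHORT_INDEL = 18

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

EVENT_KINDS = (
    "snp",
    "small_insertion",
    "small_deletion",
    "large_deletion",
    "duplication",
    "gene_loss",
    "homoeologous_exchange",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs of the generator.

    Defaults emulate the sequencing design: 100 bp single-end reads,
    1e5 reads per genotype, ~5% subgenome divergence (enough that strict
    placement keeps cross-subgenome reads mostly apart), 100:1 on-target
    capture enrichment, and 20 target genes per subgenome.
    """

    n_genes_per_subgenome: int = 20
    gene_length: int = 1200
    intergenic_length: int = 20000
    intron_length: int = 150
    subgenome_divergence: float = 0.05
    read_length: int = 100
    n_reads: int = 100_000
    on_target_enrichment: float = 100.0
    max_mismatches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.subgenome_divergence < 0.5):
            raise ValidationError("divergence must be in [0, 0.5)")
        if self.read_length < 1 or self.n_reads < 0:
            raise ValidationError("read_length >= 1 and n_reads >= 0 required")
        if self.n_genes_per_subgenome < 1:
            raise ValidationError("need at least one gene per subgenome")
        cds_total = self.gene_length - 2 * self.intron_length
        if cds_total < 9 or cds_total % 3:
            raise ValidationError(
                "gene_length minus two introns must be a positive codon multiple"
            )


@dataclass(frozen=True)
class VariantSpec:
    """A requested event; coordinates are realized by the generator."""

    kind: str
    gene_id: str | None = None
    interval: tuple[str, int, int] | None = None
    size: int = 1
    zygosity: str = "hom"
    placement: str = "cds"
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.zygosity not in ("hom", "het"):
            raise ValidationError(f"bad zygosity {self.zygosity!r}")
        if self.kind in ("small_insertion", "small_deletion"):
            if not 1 <= self.size <= MAX_SHORT_INDEL:
                raise ValidationError(
                    f"short InDel size must be in [1, {MAX_SHORT_INDEL}]"
                )
        if self.kind == "large_deletion" and self.size <= MAX_SHORT_INDEL:
            raise ValidationError(
                f"large deletion must exceed {MAX_SHORT_INDEL} bp"
            )


@dataclass(frozen=True)
class InjectedEvent:
    """A realized event: replace reference ``[start, end)`` by ``alt``."""

    event_id: str
    kind: str
    chrom: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    zygosity: str
    gene_id: str | None = None
    consequence: str | None = None
    source_start: int | None = None  # duplication template span
    source_end: int | None = None

    @property
    def size(self) -> int:
        return abs((self.end - self.start) - len(self.alt_allele))

    @property
    def footprint(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, max(self.end, self.start + 1)
        )


@dataclass
class TruthSet:
    """Machine-readable ledger of injected events for recovery testing."""

    genotype: str
    reference_id: str
    events: tuple[InjectedEvent, ...]

    def __post_init__(self) -> None:
        ids = [e.event_id for e in self.events]
        if len(set(ids)) != len(ids):
            raise ValidationError("event ids must be unique")

    def of_kind(self, *kinds: str) -> list[InjectedEvent]:
        return [e for e in self.events if e.kind in kinds]

    def to_json(self) -> str:
        payload = {
            "genotype": self.genotype,
            "reference_id": self.reference_id,
            "events": [vars(e) for e in self.events],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        payload = json.loads(text)
        events = tuple(InjectedEvent(**e) for e in payload["events"])
        return cls(payload["genotype"], payload["reference_id"], events)


@dataclass
class Haplotype:
    sequences: dict[str, str]
    events: tuple[InjectedEvent, ...]


@dataclass
class Genotype:
    """A sequenced individual: two haplotypes over a source reference."""

    name: str
    source_ref_id: str
    haplotypes: tuple[Haplotype, Haplotype]

    @property
    def events(self) -> tuple[InjectedEvent, ...]:
        return self.haplotypes[0].events


@dataclass
class SimulatedReferences:
    tetraploid: ReferenceSet
    diploids: dict[str, ReferenceSet]  # subgenome -> reference
    genes: dict[str, list[GeneModel]]  # 'tetraploid' | 'A' | 'C'
    targets: dict[str, list[GenomicInterval]]
    families: dict[str, str]  # copy_name -> family id


def partner_chrom(chrom: str) -> str | None:
    if chrom.startswith("A"):
        return "C" + chrom[1:]
    if chrom.startswith("C"):
        return "A" + chrom[1:]
    return None


def _gene_structure(cfg: SimulationConfig) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Relative exon and intron offsets within a gene span.

    Three exons, two introns; the first exon length is deliberately not a
    codon multiple so codons straddle exon junctions.
    """
    cds_total = cfg.gene_length - 2 * cfg.intron_length
    e1 = cds_total // 3 + 1
    e2 = cds_total // 3
    e3 = cds_total - e1 - e2
    i = cfg.intron_length
    exons = [
        (0, e1),
        (e1 + i, e1 + i + e2),
        (e1 + i + e2 + i, cfg.gene_length),
    ]
    introns = [(e1, e1 + i), (e1 + i + e2, e1 + i + e2 + i)]
    return exons, introns


def _random_gene(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    exons, introns = _gene_structure(cfg)
    n_codons = sum(e - s for s, e in exons) // 3
    codons = ["ATG"]
    codons += [
        _NON_STOP_CODONS[k]
        for k in rng.integers(0, len(_NON_STOP_CODONS), n_codons - 2)
    ]
    codons.append("TAA")
    cds = "".join(codons)
    parts = []
    cursor = 0
    for k, (s, e) in enumerate(exons):
        parts.append(cds[cursor : cursor + (e - s)])
        cursor += e - s
        if k < len(introns):
            ilen = introns[k][1] - introns[k][0]
            interior = "".join(
                _BASES[b] for b in rng.integers(0, 4, ilen - 4)
            )
            parts.append("GT" + interior + "AG")
    return "".join(parts)


def _repair_gene(seq: bytearray, offset: int, cfg: SimulationConfig) -> None:
    """Restore start/stop codons, remove internal stops, fix splice sites."""
    exons, introns = _gene_structure(cfg)
    cds_pos = [
        offset + p for s, e in exons for p in range(s, e)
    ]
    seq[cds_pos[0] : cds_pos[0] + 1] = b"A"
    seq[cds_pos[1] : cds_pos[1] + 1] = b"T"
    seq[cds_pos[2] : cds_pos[2] + 1] = b"G"
    # internal codons: recode stops via third base
    n_codons = len(cds_pos) // 3
    for k in range(1, n_codons - 1):
        p0, p1, p2 = cds_pos[3 * k : 3 * k + 3]
        codon = bytes([seq[p0], seq[p1], seq[p2]]).decode()
        if codon in _STOPS:
            seq[p2] = ord("T")
    p0, p1, p2 = cds_pos[-3:]
    seq[p0], seq[p1], seq[p2] = ord("T"), ord("A"), ord("A")
    for s, e in introns:
        seq[offset + s] = ord("G")
        seq[offset + s + 1] = ord("T")
        seq[offset + e - 2] = ord("A")
        seq[offset + e - 1] = ord("G")


def _build_gene_models(
    chrom: str, prefix: str, cfg: SimulationConfig, n: int | None = None
) -> list[GeneModel]:
    exons_rel, _ = _gene_structure(cfg)
    unit = cfg.gene_length + cfg.intergenic_length
    off0 = cfg.intergenic_length // 2
    out = []
    for i in range(n or cfg.n_genes_per_subgenome):
        start = off0 + i * unit
        family = f"G{i + 1:02d}"
        span = GenomicInterval(chrom, start, start + cfg.gene_length, "+")
        exons = tuple(
            GenomicInterval(chrom, start + s, start + e, "+")
            for s, e in exons_rel
        )
        out.append(
            GeneModel(
                gene_id=f"{prefix}{chrom}g{(i + 1) * 10:04d}",
                copy_name=f"{prefix}.{family}.{chrom}",
                span=span,
                exons=exons,
                cds=exons,
                strand="+",
            )
        )
    return out


def _gene_offsets(cfg: SimulationConfig, n: int) -> list[int]:
    unit = cfg.gene_length + cfg.intergenic_length
    return [cfg.intergenic_length // 2 + i * unit for i in range(n)]


def simulate_reference_pair(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedReferences:
    """A collinear A/C subgenome pair plus the tetraploid concatenation.

    The C subgenome is derived from the A subgenome by per-base substitution
    at the configured divergence, followed by gene-structure repair (start
    and stop codons, internal-stop removal, canonical splice dinucleotides),
    so the two subgenomes stay alignable position-by-position. The diploid
    references equal the corresponding subgenome before any genotype-specific
    variation; every gene has three exons with an in-frame CDS and terminal
    stop codon.
    """
    cfg = config
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_genes_per_subgenome
    unit = cfg.gene_length + cfg.intergenic_length
    chrom_len = n * unit
    base = rng.integers(0, 4, chrom_len)
    seq_a = bytearray("".join(_BASES[b] for b in base), "ascii")
    offsets = _gene_offsets(cfg, n)
    for off in offsets:
        gene = _random_gene(rng, cfg)
        seq_a[off : off + cfg.gene_length] = gene.encode()

    seq_c = bytearray(seq_a)
    if cfg.subgenome_divergence > 0:
        arr = np.frombuffer(bytes(seq_c), dtype=np.uint8).copy()
        hit = rng.random(chrom_len) < cfg.subgenome_divergence
        shift = rng.integers(1, 4, chrom_len)
        lut = {ord(b): i for i, b in enumerate(_BASES)}
        idx = np.array([lut.get(x, 0) for x in arr[hit]])
        new_idx = (idx + shift[hit]) % 4
        arr[hit] = np.frombuffer(_BASES.encode(), dtype=np.uint8)[new_idx]
        seq_c = bytearray(arr.tobytes())
    for off in offsets:
        _repair_gene(seq_c, off, cfg)

    a_str, c_str = seq_a.decode(), seq_c.decode()
    tetra = ReferenceSet({"A01": a_str, "C01": c_str})
    dip_a = ReferenceSet({"A01": a_str})
    dip_c = ReferenceSet({"C01": c_str})
    genes_a = _build_gene_models("A01", "Bra", cfg)
    genes_c = _build_gene_models("C01", "Bol", cfg)
    genes_t = _build_gene_models("A01", "Bna", cfg) + _build_gene_models(
        "C01", "Bna", cfg
    )
    families = {
        g.copy_name: GeneModel.parse_copy_name(g.copy_name)[1]
        for g in genes_a + genes_c + genes_t
    }
    def bait(g: GeneModel) -> GenomicInterval:
        return GenomicInterval(g.span.chrom, g.span.start, g.span.end)

    targets = {
        "tetraploid": [bait(g) for g in genes_t],
        "A": [bait(g) for g in genes_a],
        "C": [bait(g) for g in genes_c],
    }
    return SimulatedReferences(
        tetraploid=tetra,
        diploids={"A": dip_a, "C": dip_c},
        genes={"tetraploid": genes_t, "A": genes_a, "C": genes_c},
        targets=targets,
        families=families,
    )


# ---------------------------------------------------------------------------
# event realization


def _codon_positions(gene: GeneModel) -> list[int]:
    return [p for c in gene.cds for p in range(c.start, c.end)]


def _realize_snp(
    spec: VariantSpec,
    gene: GeneModel,
    ref: ReferenceSet,
    rng: np.random.Generator,
) -> tuple[int, str, str]:
    """Choose a position and alleles honoring the intended consequence."""
    from Bio.Seq import Seq

    seq = ref.sequences[gene.span.chrom]
    cds_pos = _codon_positions(gene)
    n_codons = len(cds_pos) // 3

    def codon_at(k: int) -> str:
        return "".join(seq[cds_pos[3 * k + j]] for j in range(3))

    intent = spec.consequence or "nonsynonymous"
    order = list(rng.permutation(np.arange(1, n_codons - 1)))
    if intent == "synonymous":
        for k in order:
            codon = codon_at(k)
            for b in _BASES:
                if b != codon[2] and str(
                    Seq(codon[:2] + b).translate()
                ) == str(Seq(codon).translate()):
                    return cds_pos[3 * k + 2], codon[2], b
    elif intent == "nonsynonymous":
        for k in order:
            codon = codon_at(k)
            for b in _BASES:
                alt = codon[0] + b + codon[2]
                if (
                    b != codon[1]
                    and alt not in _STOPS
                    and str(Seq(alt).translate())
                    != str(Seq(codon).translate())
                ):
                    return cds_pos[3 * k + 1], codon[1], b
    elif intent == "stop_gain":
        for k in order:
            codon = codon_at(k)
            for stop in _STOPS:
                diff = [j for j in range(3) if codon[j] != stop[j]]
                if len(diff) == 1:
                    j = diff[0]
                    return cds_pos[3 * k + j], codon[j], stop[j]
    elif intent == "stop_loss":
        k = n_codons - 1
        codon = codon_at(k)  # TAA by construction
        return cds_pos[3 * k], codon[0], "C"  # TAA -> CAA (Gln)
    elif intent in ("splice_donor", "splice_acceptor"):
        introns = gene.introns()
        intron = introns[int(rng.integers(0, len(introns)))]
        pos = intron.start if intent == "splice_donor" else intron.end - 1
        old = seq[pos]
        return pos, old, "A" if old != "A" else "C"
    elif intent == "silent":
        introns = gene.introns()
        intron = introns[int(rng.integers(0, len(introns)))]
        pos = int(rng.integers(intron.start + 2, intron.end - 2))
        old = seq[pos]
        return pos, old, "A" if old != "A" else "C"
    raise ValidationError(
        f"could not realize snp intent {intent!r} in {gene.copy_name}"
    )


def realize_specs(
    specs: Sequence[VariantSpec],
    ref: ReferenceSet,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
    id_prefix: str = "e",
) -> list[InjectedEvent]:
    by_id = {g.gene_id: g for g in genes}
    by_copy = {g.copy_name: g for g in genes}
    events: list[InjectedEvent] = []
    occupied: dict[str, list[GenomicInterval]] = {}

    def collides(iv: GenomicInterval) -> bool:
        return any(
            iv.start < o.end and o.start < iv.end
            for o in occupied.get(iv.chrom, [])
        )

    for i, spec in enumerate(specs):
        gene = None
        if spec.gene_id is not None:
            gene = by_id.get(spec.gene_id) or by_copy.get(spec.gene_id)
            if gene is None:
                raise ValidationError(f"unknown gene {spec.gene_id!r}")
        chrom = gene.span.chrom if gene else (spec.interval or ("?",))[0]

        if spec.kind == "snp":
            for _attempt in range(20):
                pos, ref_b, alt_b = _realize_snp(spec, gene, ref, rng)
                iv = GenomicInterval(chrom, pos, pos + 1)
                if not collides(iv):
                    break
            else:
                raise ValidationError("could not place snp without overlap")
            ev = InjectedEvent(
                f"{id_prefix}{i:03d}", "snp", chrom, pos, pos + 1,
                ref_b, alt_b, spec.zygosity, gene.gene_id, spec.consequence,
            )
        elif spec.kind in ("small_deletion", "large_deletion"):
            retriable = False
            if spec.interval is not None:
                chrom, s, e = spec.interval
                if e - s != spec.size:
                    raise ValidationError("interval size mismatch")
            else:
                exons, introns = gene.exons, gene.introns()
                if spec.placement == "exon_intron_boundary":
                    intron = introns[-1]
                    s = intron.end - (spec.size - spec.size // 3)
                elif spec.placement == "intron":
                    intron = introns[0]
                    s = intron.start + 4
                else:  # cds interior, position drawn at random
                    retriable = True
                    exon = exons[1]
                    lo = exon.start + 3
                    hi = exon.end - 3 - spec.size
                    s = int(rng.integers(lo, hi))
                e = s + spec.size
            if retriable:
                for _attempt in range(20):
                    if not collides(GenomicInterval(chrom, s, e)):
                        break
                    s = int(rng.integers(lo, hi))
                    e = s + spec.size
                else:
                    raise ValidationError("could not place deletion")
            ev = InjectedEvent(
                f"{id_prefix}{i:03d}", spec.kind, chrom, s, e,
                ref.sequences[chrom][s:e], "", spec.zygosity,
                gene.gene_id if gene else None, spec.consequence,
            )
        elif spec.kind == "small_insertion":
            exon = gene.exons[1]
            p = int(rng.integers(exon.start + 3, exon.end - 3))
            ins = "".join(_BASES[b] for b in rng.integers(0, 4, spec.size))
            ev = InjectedEvent(
                f"{id_prefix}{i:03d}", "small_insertion", chrom, p, p,
                "", ins, spec.zygosity, gene.gene_id, spec.consequence,
            )
        elif spec.kind == "duplication":
            span = gene.span
            ev = InjectedEvent(
                f"{id_prefix}{i:03d}", "duplication", chrom,
                span.end, span.end, "",
                ref.sequences[chrom][span.start : span.end],
                spec.zygosity, gene.gene_id, spec.consequence,
                source_start=span.start, source_end=span.end,
            )
        elif spec.kind == "gene_loss":
            span = gene.span
            ev = InjectedEvent(
                f"{id_prefix}{i:03d}", "gene_loss", chrom,
                span.start, span.end,
                ref.sequences[chrom][span.start : span.end], "",
                spec.zygosity, gene.gene_id, spec.consequence,
            )
        elif spec.kind == "homoeologous_exchange":
            span = gene.span
            part = partner_chrom(chrom)
            if part is None or part not in ref.sequences:
                raise ValidationError(
                    "exchange requires both subgenomes in the reference"
                )
            ev = InjectedEvent(
                f"{id_prefix}{i:03d}", "homoeologous_exchange", chrom,
                span.start, span.end,
                ref.sequences[chrom][span.start : span.end],
                ref.sequences[part][span.start : span.end],
                spec.zygosity, gene.gene_id, spec.consequence,
            )
        else:  # pragma: no cover - guarded by VariantSpec
            raise ValidationError(spec.kind)

        if collides(ev.footprint):
            raise ValidationError(
                f"event {ev.event_id} overlaps a previous event"
            )
        occupied.setdefault(ev.chrom, []).append(ev.footprint)
        events.append(ev)
    return events


def apply_events(
    sequences: Mapping[str, str], events: Iterable[InjectedEvent]
) -> dict[str, str]:
    out = {c: s for c, s in sequences.items()}
    per_chrom: dict[str, list[InjectedEvent]] = {}
    for ev in events:
        per_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in per_chrom.items():
        seq = out[chrom]
        for ev in sorted(evs, key=lambda e: e.start, reverse=True):
            if seq[ev.start : ev.end] != ev.ref_allele:
                raise ValidationError(
                    f"{ev.event_id}: reference allele mismatch at "
                    f"{chrom}:{ev.start}"
                )
            seq = seq[: ev.start] + ev.alt_allele + seq[ev.end :]
        out[chrom] = seq
    return out


def inject_variants(
    ref: ReferenceSet,
    genes: Sequence[GeneModel],
    specs: Sequence[VariantSpec],
    rng: np.random.Generator | int,
    name: str = "genotype",
    source_ref_id: str = "ref",
) -> tuple[Genotype, TruthSet]:
    """Realize specs on a reference and build a two-haplotype genotype.

    Homozygous events go to both haplotypes, heterozygous events to the
    first only, so heterozygous depth effects are halved and GT fields can
    be derived. The truth ledger records realized coordinates on the source
    reference; because the subgenomes are collinear by construction, those
    coordinates are simultaneously valid on the tetraploid reference (until
    a chromosome-end extension differs between references).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    events = realize_specs(specs, ref, genes, rng, id_prefix=f"{name}.e")
    hap0 = apply_events(ref.sequences, events)
    hom = tuple(e for e in events if e.zygosity == "hom")
    hap1 = apply_events(ref.sequences, hom)
    genotype = Genotype(
        name=name,
        source_ref_id=source_ref_id,
        haplotypes=(
            Haplotype(hap0, tuple(events)),
            Haplotype(hap1, hom),
        ),
    )
    return genotype, TruthSet(name, source_ref_id, tuple(events))


# ---------------------------------------------------------------------------
# read placement and depth


_STRUCTURAL = {
    "small_deletion",
    "large_deletion",
    "gene_loss",
    "small_insertion",
    "duplication",
}


def _haplotype_map(
    genotype_len: int, events: Sequence[InjectedEvent]
) -> np.ndarray:
    """Per-base homologous reference position of a haplotype chromosome.

    Novel inserted bases map to -1; duplicated-copy bases map back to the
    template span (capture baits and homologous placement both treat the
    copy as its template).
    """
    structural = [e for e in events if e.kind in _STRUCTURAL]
    ref_len = genotype_len + sum(
        (e.end - e.start) - len(e.alt_allele) for e in structural
    )
    parts = []
    cursor = 0
    for ev in sorted(structural, key=lambda e: e.start):
        parts.append(np.arange(cursor, ev.start, dtype=np.int64))
        if ev.kind == "duplication":
            parts.append(
                np.arange(ev.source_start, ev.source_end, dtype=np.int64)
            )
        elif ev.kind == "small_insertion":
            parts.append(np.full(len(ev.alt_allele), -1, dtype=np.int64))
        cursor = ev.end
    parts.append(np.arange(cursor, ref_len, dtype=np.int64))
    return np.concatenate(parts) if len(parts) > 1 else parts[0]


def _seq_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _sliding_count(mask: np.ndarray, width: int) -> np.ndarray:
    cs = np.concatenate(([0], np.cumsum(mask.astype(np.int64))))
    return cs[width:] - cs[:-width]


def simulate_depth(
    genotype: Genotype,
    mapping_ref: ReferenceSet,
    reference_id: str,
    mode: str,
    config: SimulationConfig,
    rng: np.random.Generator | int,
    targets: Sequence[GenomicInterval],
) -> DepthTrack:
    """Place capture-enriched reads from a genotype onto a reference.

    Read start positions on the genotype are sampled with
    ``on_target_enrichment``-fold weight when the read overlaps a capture
    target. Placement on the mapping reference follows the homologous
    coordinates (own chromosome, partner subgenome chromosome as the
    alternative candidate), with strict/gapped junction handling as
    described in the module docstring.
    """
    if mode not in ("strict", "gapped"):
        raise ValidationError(f"unknown mapping mode {mode!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    cfg = config
    rl = cfg.read_length

    ref_bytes = {c: _seq_bytes(s) for c, s in mapping_ref.sequences.items()}
    diff = {c: np.zeros(len(b) + 1, dtype=np.int64) for c, b in ref_bytes.items()}
    read_starts: dict[str, list[np.ndarray]] = {c: [] for c in ref_bytes}
    indel_obs: list[tuple[str, str, int, int]] = []
    mapped = 0

    for h_i, hap in enumerate(genotype.haplotypes):
        n_hap = cfg.n_reads // 2 + (cfg.n_reads % 2 if h_i == 0 else 0)
        if n_hap == 0:
            continue
        chroms = sorted(hap.sequences)
        per_chrom = []
        for chrom in chroms:
            seq = hap.sequences[chrom]
            if len(seq) < rl:
                per_chrom.append(None)
                continue
            g = _seq_bytes(seq)
            m = _haplotype_map(len(seq), [e for e in hap.events if e.chrom == chrom])
            assert len(m) == len(seq)
            # capture-target mask lifted into genotype coordinates
            tmask_len = max(
                (iv.end for iv in targets if iv.chrom == chrom), default=0
            )
            t_ref = np.zeros(max(tmask_len, 1), dtype=bool)
            for iv in targets:
                if iv.chrom == chrom:
                    t_ref[iv.start : iv.end] = True
            valid = m >= 0
            t_g = np.zeros(len(m), dtype=bool)
            inside = valid & (m < len(t_ref))
            t_g[inside] = t_ref[m[inside]]
            on_target_start = _sliding_count(t_g, rl) > 0
            w = np.where(on_target_start, cfg.on_target_enrichment, 1.0)
            # clean windows: no junction breaks, no novel bases
            brk = np.empty(len(m), dtype=bool)
            brk[:-1] = m[1:] != m[:-1] + 1
            brk[-1] = True
            clean = (m[: len(m) - rl + 1] >= 0) & (
                _sliding_count(brk[:-1], rl - 1)[: len(m) - rl + 1] == 0
                if rl > 1
                else True
            )
            per_chrom.append((g, m, w, clean))
        weights = np.concatenate(
            [
                (pc[2] if pc is not None else np.zeros(0))
                for pc in per_chrom
            ]
        )
        if weights.sum() == 0:
            continue
        starts_global = rng.choice(
            len(weights), size=n_hap, p=weights / weights.sum()
        )
        offset = 0
        for chrom, pc in zip(chroms, per_chrom):
            if pc is None:
                continue
            g, m, w, clean = pc
            n_pos = len(w)
            sel = starts_global[(starts_global >= offset) & (starts_global < offset + n_pos)] - offset
            offset += n_pos
            if len(sel) == 0:
                continue
            is_clean = clean[sel]
            s_clean = sel[is_clean]
            s_dirty = sel[~is_clean]

            if len(s_clean):
                r = m[s_clean]
                reads = g[s_clean[:, None] + np.arange(rl)]
                best_mm = np.full(len(s_clean), rl + 1, dtype=np.int64)
                best_chrom = np.full(len(s_clean), -1, dtype=np.int64)
                cand_names = [chrom]
                part = partner_chrom(chrom)
                if part is not None and part in ref_bytes:
                    cand_names.append(part)
                for ci, cname in enumerate(cand_names):
                    refb = ref_bytes[cname]
                    ok = r + rl <= len(refb)
                    if not ok.any():
                        continue
                    mm = np.full(len(s_clean), rl + 1, dtype=np.int64)
                    rows = np.flatnonzero(ok)
                    cand = refb[r[rows][:, None] + np.arange(rl)]
                    mm[rows] = (reads[rows] != cand).sum(axis=1)
                    better = mm < best_mm
                    best_mm[better] = mm[better]
                    best_chrom[better] = ci
                placed = best_mm <= cfg.max_mismatches
                for ci, cname in enumerate(cand_names):
                    hit = placed & (best_chrom == ci)
                    if not hit.any():
                        continue
                    rr = r[hit]
                    np.add.at(diff[cname], rr, 1)
                    np.add.at(diff[cname], rr + rl, -1)
                    read_starts[cname].append(rr)
                    mapped += int(hit.sum())

            if mode == "gapped":
                for s in s_dirty:
                    res = _place_gapped(
                        int(s), g, m, ref_bytes, chrom, cfg
                    )
                    if res is None:
                        continue
                    cname, segments, gap = res
                    for r0, length in segments:
                        diff[cname][r0] += 1
                        diff[cname][r0 + length] -= 1
                    read_starts[cname].append(
                        np.array([segments[0][0]], dtype=np.int64)
                    )
                    if gap is not None:
                        indel_obs.append((gap[0], cname, gap[2], gap[3]))
                    mapped += 1

    depths = {
        c: np.cumsum(d[:-1]).astype(np.int64) for c, d in diff.items()
    }
    starts_sorted = {
        c: np.sort(np.concatenate(v)) if v else np.zeros(0, dtype=np.int64)
        for c, v in read_starts.items()
    }
    return DepthTrack(
        reference_id=reference_id,
        genotype=genotype.name,
        mode=mode,
        depths=depths,
        total_mapped_reads=mapped,
        read_length=rl,
        read_starts=starts_sorted,
        indel_observations=indel_obs,
    )


def _place_gapped(
    s: int,
    g: np.ndarray,
    m: np.ndarray,
    ref_bytes: Mapping[str, np.ndarray],
    chrom: str,
    cfg: SimulationConfig,
) -> tuple[str, list[tuple[int, int]], tuple[str, int, int] | None] | None:
    """Try to place a junction-crossing read with a single small gap."""
    rl = cfg.read_length
    window = m[s : s + rl]
    # decompose into runs of contiguous reference positions / novel bases
    runs: list[tuple[int, int, int]] = []  # (offset_in_read, length, ref_start)
    i = 0
    while i < rl:
        if window[i] < 0:
            j = i
            while j < rl and window[j] < 0:
                j += 1
            runs.append((i, j - i, -1))
            i = j
        else:
            j = i
            while j + 1 < rl and window[j + 1] == window[j] + 1:
                j += 1
            runs.append((i, j - i + 1, int(window[i])))
            i = j + 1
    if chrom not in ref_bytes:
        return None
    refb = ref_bytes[chrom]

    def mm_of(off: int, length: int, r0: int) -> int:
        if r0 + length > len(refb) or r0 < 0:
            return rl + 1
        return int((g[s + off : s + off + length] != refb[r0 : r0 + length]).sum())

    mapped_runs = [r for r in runs if r[2] >= 0]
    novel_runs = [r for r in runs if r[2] < 0]
    if len(mapped_runs) == 2 and not novel_runs:
        (o1, l1, r1), (o2, l2, r2) = mapped_runs
        gap = r2 - (r1 + l1)
        if 1 <= gap <= MAX_SHORT_INDEL and l1 >= 1 and l2 >= 1:
            if mm_of(o1, l1, r1) + mm_of(o2, l2, r2) <= cfg.max_mismatches:
                return (
                    chrom,
                    [(r1, l1), (r2, l2)],
                    ("del", chrom, r1 + l1, gap),
                )
        return None
    if len(mapped_runs) == 2 and len(novel_runs) == 1:
        (o1, l1, r1), (o2, l2, r2) = mapped_runs
        ins_len = novel_runs[0][1]
        if (
            r2 == r1 + l1
            and ins_len <= MAX_SHORT_INDEL
            and l1 >= 1
            and l2 >= 1
            and mm_of(o1, l1, r1) + mm_of(o2, l2, r2) <= cfg.max_mismatches
        ):
            return (
                chrom,
                [(r1, l1), (r2, l2)],
                ("ins", chrom, r1 + l1, ins_len),
            )
        return None
    return None


def simulate_population_reference(
    config: SimulationConfig,
    n_genotypes: int,
    ref: ReferenceSet,
    reference_id: str,
    genes: Sequence[GeneModel],
    targets: Sequence[GenomicInterval],
    rng: np.random.Generator | int,
):
    """Per-copy mean normalized coverage over CNV-free tetraploid genotypes.

    Stands in for the large resequenced population used as the coverage
    baseline; each simulated genotype is the reference itself, so only
    sampling noise differentiates them.
    """
    from .coverage import PopulationReference, gene_coverage

    if n_genotypes < 1:
        raise ValidationError("n_genotypes must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sums: dict[str, float] = {g.copy_name: 0.0 for g in genes}
    plain = Genotype(
        name="pop",
        source_ref_id=reference_id,
        haplotypes=(
            Haplotype(dict(ref.sequences), ()),
            Haplotype(dict(ref.sequences), ()),
        ),
    )
    for _ in range(n_genotypes):
        track = simulate_depth(
            plain, ref, reference_id, "strict", config, rng, targets
        )
        for g in genes:
            sums[g.copy_name] += gene_coverage(track, g).nc
    return PopulationReference(
        mean_nc={k: v / n_genotypes for k, v in sums.items()},
        n_genotypes=n_genotypes,
    )


__all__ = [
    "SimulationConfig",
    "VariantSpec",
    "InjectedEvent",
    "TruthSet",
    "Haplotype",
    "Genotype",
    "SimulatedReferences",
    "MAX_SHORT_INDEL",
    "partner_chrom",
    "simulate_reference_pair",
    "realize_specs",
    "apply_events",
    "inject_variants",
    "simulate_depth",
    "simulate_population_reference",
]
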