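"""Default synthetic study dataset and its on-disk representation.

The default dataset mirrors the study design end to end: an allotetraploid
reference with A and C subgenomes, two diploid genotypes per progenitor
species (L1/L2 on A, K1/K2 on C), homozygous duplications and whole-copy
losses spread over the target genes, a homozygous 57 bp deletion spanning an
exon/intron boundary (the classic *FLC*-type event), SNPs of every
consequence class in both zygosities, short InDels on both sides of the
18 bp gapped-mapping limit, a reciprocal homoeologous exchange fixed in the
tetraploid reference, and three reconciliation scenarios: a tetraploid-only
copy (gained), a diploid-only copy (lost from the tetraploid), and a copy
covered but unannotated in the diploid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomicInterval,
    ReferenceSet,
    ThresholdConfig,
    ValidationError,
)
from .coverage import DepthTrack, PopulationReference
from .phylo import Alignment
from .simulate import (
    Genotype,
    InjectedEvent,
    SimulationConfig,
    SimulatedReferences,
    TruthSet,
    VariantSpec,
    _gene_structure,
    _random_gene,
    apply_events,
    inject_variants,
    realize_specs,
    simulate_depth,
    simulate_population_reference,
    simulate_reference_pair,
)
from .variants import VariantRecord
from . import io as cio

EXCHANGE_FAMILY = "G05"
UNANNOTATED_FAMILY = "G06"
GAINED_FAMILY = "G98"
LOST_FAMILY = "G99"
LARGE_DEL_FAMILY = "G03"
LARGE_DEL_SIZE = 57


@dataclass
class Dataset:
    config: SimulationConfig
    thresholds: ThresholdConfig
    refs: dict[str, ReferenceSet]
    genes: dict[str, list[GeneModel]]
    targets: dict[str, list[GenomicInterval]]
    families: dict[str, str]
    ortholog_map: dict[str, dict[str, str | None]]
    genotypes: dict[str, Genotype]
    truths: dict[str, TruthSet]
    reference_truth: TruthSet | None
    tracks: dict[tuple[str, str, str], DepthTrack]
    population: PopulationReference | None
    vcf_records: dict[str, list[VariantRecord]]
    seed: int = 0

    #: genotype name -> progenitor subgenome
    subgenome_of: dict[str, str] = field(default_factory=dict)

    def pair(self, subgenome: str) -> tuple[str, str]:
        names = sorted(
            g for g, s in self.subgenome_of.items() if s == subgenome
        )
        if len(names) != 2:
            raise ValidationError(f"expected 2 genotypes on {subgenome}")
        return names[0], names[1]

    def gene_by_copy(self, copy_name: str) -> GeneModel:
        for genes in self.genes.values():
            for g in genes:
                if g.copy_name == copy_name:
                    return g
        raise KeyError(copy_name)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _gene_model_at(
    chrom: str, start: int, cfg: SimulationConfig, gene_id: str, copy_name: str
) -> GeneModel:
    exons_rel, _ = _gene_structure(cfg)
    exons = tuple(
        GenomicInterval(chrom, start + s, start + e, "+") for s, e in exons_rel
    )
    return GeneModel(
        gene_id=gene_id,
        copy_name=copy_name,
        span=GenomicInterval(chrom, start, start + cfg.gene_length, "+"),
        exons=exons,
        cds=exons,
        strand="+",
    )


def _append_gene(
    ref: ReferenceSet,
    chrom: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    lead: int,
) -> tuple[ReferenceSet, int]:
    """Append ``lead`` random bases plus one gene (plus a trailing pad)."""
    pad = cfg.intergenic_length // 2
    lead_seq = "".join("ACGT"[b] for b in rng.integers(0, 4, lead))
    gene_seq = _random_gene(rng, cfg)
    tail = "".join("ACGT"[b] for b in rng.integers(0, 4, pad))
    seqs = dict(ref.sequences)
    start = len(seqs[chrom]) + lead
    seqs[chrom] = seqs[chrom] + lead_seq + gene_seq + tail
    return ReferenceSet(seqs), start


def default_variant_specs(genes_by_copy: Mapping[str, GeneModel]) -> dict[str, list[VariantSpec]]:
    """The injected-event plan of the default dataset, per genotype."""

    def gid(copy: str) -> str:
        return genes_by_copy[copy].gene_id

    def a(fam: str) -> str:
        return gid(f"Bra.{fam}.A01")

    def c(fam: str) -> str:
        return gid(f"Bol.{fam}.C01")

    v = VariantSpec
    return {
        "L1": [
            v("duplication", a("G04")),
            v("duplication", a("G07")),
            v("duplication", a("G10")),
            v("gene_loss", a("G08")),
            v("gene_loss", a("G12")),
            v("snp", a("G01"), consequence="nonsynonymous"),
            v("snp", a("G02"), consequence="synonymous"),
            v("snp", a("G09"), consequence="stop_gain"),
            v("snp", a("G11"), consequence="silent"),
            v("snp", a("G13"), consequence="splice_donor"),
            v("snp", a("G14"), consequence="nonsynonymous", zygosity="het"),
            v("snp", a("G15"), consequence="synonymous", zygosity="het"),
            v("small_deletion", a("G16"), size=2, consequence="frameshift_indel"),
            v("small_deletion", a("G17"), size=6, consequence="inframe_indel"),
            v("small_insertion", a("G18"), size=4, consequence="frameshift_indel"),
            v("small_insertion", a("G19"), size=3, zygosity="het",
              consequence="inframe_indel"),
        ],
        "L2": [
            v("large_deletion", a(LARGE_DEL_FAMILY), size=LARGE_DEL_SIZE,
              placement="exon_intron_boundary"),
            v("duplication", a("G11")),
            v("duplication", a("G14")),
            v("gene_loss", a("G13")),
            v("gene_loss", a("G02")),
            v("snp", a("G01"), consequence="nonsynonymous"),
            v("snp", a("G04"), consequence="stop_loss"),
            v("snp", a("G07"), consequence="splice_acceptor"),
            v("snp", a("G16"), consequence="synonymous"),
            v("snp", a("G20"), consequence="nonsynonymous", zygosity="het"),
            v("small_deletion", a("G18"), size=1, consequence="frameshift_indel"),
            v("small_insertion", a("G19"), size=6, consequence="inframe_indel"),
        ],
        "K1": [
            v("duplication", c("G04")),
            v("duplication", c("G10")),
            v("gene_loss", c("G07")),
            v("gene_loss", c("G15")),
            v("snp", c("G01"), consequence="nonsynonymous"),
            v("snp", c("G02"), consequence="nonsynonymous"),
            v("snp", c("G08"), consequence="synonymous"),
            v("snp", c("G09"), consequence="silent"),
            v("snp", c("G12"), consequence="nonsynonymous", zygosity="het"),
            v("small_insertion", c("G13"), size=5, consequence="frameshift_indel"),
            v("small_deletion", c("G14"), size=4, zygosity="het",
              consequence="frameshift_indel"),
        ],
        "K2": [
            v("duplication", c("G09")),
            v("duplication", c("G13")),
            v("duplication", c("G16")),
            v("gene_loss", c("G01")),
            v("gene_loss", c("G11")),
            v("snp", c("G02"), consequence="nonsynonymous"),
            v("snp", c("G04"), consequence="splice_donor"),
            v("snp", c("G08"), consequence="stop_gain", zygosity="het"),
            v("snp", c("G10"), consequence="synonymous"),
            v("snp", c("G12"), consequence="silent"),
            v("small_deletion", c("G17"), size=9, consequence="inframe_indel"),
            v("small_insertion", c("G18"), size=1, consequence="frameshift_indel"),
        ],
    }


def vcf_from_truth(
    truth: TruthSet,
    ref: ReferenceSet,
    rng: np.random.Generator,
    snp_mq: tuple[float, float] = (55.0, 6.0),
    indel_mq: tuple[float, float] = (40.0, 8.0),
    mean_dp: float = 30.0,
) -> list[VariantRecord]:
    """VCF-style records of injected small variants with noisy MQ/DP.

    MQ and DP are drawn as configured constants plus noise so the filter
    stage has realistic records to reject; zygosity carries through to GT.
    """
    out = []
    for ev in truth.of_kind("snp", "small_insertion", "small_deletion"):
        seq = ref.sequences[ev.chrom]
        if ev.kind == "snp":
            pos, ref_a, alt_a = ev.start + 1, ev.ref_allele, ev.alt_allele
            mq = float(np.clip(rng.normal(*snp_mq), 0, 60))
            vtype = "snp"
        elif ev.kind == "small_deletion":
            anchor = seq[ev.start - 1]
            pos = ev.start  # 1-based position of the anchor base
            ref_a, alt_a = anchor + ev.ref_allele, anchor
            mq = float(np.clip(rng.normal(*indel_mq), 0, 60))
            vtype = "indel"
        else:
            anchor = seq[ev.start - 1]
            pos = ev.start
            ref_a, alt_a = anchor, anchor + ev.alt_allele
            mq = float(np.clip(rng.normal(*indel_mq), 0, 60))
            vtype = "indel"
        out.append(
            VariantRecord(
                chrom=ev.chrom,
                pos=pos,
                ref=ref_a,
                alt=alt_a,
                vtype=vtype,
                mq=round(mq, 1),
                dp=int(rng.poisson(mean_dp)),
                zygosity=ev.zygosity,
                genotype=truth.genotype,
            )
        )
    return out


def build_default_dataset(
    seed: int = 0,
    config: SimulationConfig | None = None,
    thresholds: ThresholdConfig | None = None,
    n_population: int = 20,
    with_tracks: bool = True,
    scenarios: bool = True,
) -> Dataset:
    """Assemble the default synthetic study dataset under one seed."""
    cfg = replace(config or SimulationConfig(), seed=seed)
    if cfg.n_genes_per_subgenome < 20:
        raise ValidationError("default dataset expects >= 20 genes/subgenome")
    thr = thresholds or ThresholdConfig()
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(seed).spawn(40)
    ]
    rng_ref, rng_scen, rng_vcf = streams[0], streams[1], streams[2]

    sim = simulate_reference_pair(cfg, rng_ref)
    genes = {k: list(v) for k, v in sim.genes.items()}
    targets = {k: list(v) for k, v in sim.targets.items()}
    families = dict(sim.families)

    # reciprocal homoeologous exchange fixed in the tetraploid reference
    ex_specs = [
        VariantSpec("homoeologous_exchange", f"Bna.{EXCHANGE_FAMILY}.A01"),
        VariantSpec("homoeologous_exchange", f"Bna.{EXCHANGE_FAMILY}.C01"),
    ]
    ex_events = realize_specs(
        ex_specs, sim.tetraploid, genes["tetraploid"], rng_ref, id_prefix="ref.e"
    )
    napus_ref = ReferenceSet(
        apply_events(sim.tetraploid.sequences, ex_events)
    )
    reference_truth = TruthSet("reference", "tetraploid", tuple(ex_events))

    refs = {
        "tetraploid": napus_ref,
        "A": sim.diploids["A"],
        "C": sim.diploids["C"],
    }

    ortholog_map: dict[str, dict[str, str | None]] = {}
    for i in range(cfg.n_genes_per_subgenome):
        fam = f"G{i + 1:02d}"
        ortholog_map[fam] = {
            "tetraploid_A": f"Bna.{fam}.A01",
            "tetraploid_C": f"Bna.{fam}.C01",
            "A": f"Bra.{fam}.A01",
            "C": f"Bol.{fam}.C01",
        }

    if scenarios:
        # gained in the tetraploid: a copy with no diploid counterpart
        refs["tetraploid"], g_start = _append_gene(
            refs["tetraploid"], "A01", cfg, rng_scen, cfg.intergenic_length // 2
        )
        gained = _gene_model_at(
            "A01", g_start, cfg, "BnaA01g9800", f"Bna.{GAINED_FAMILY}.A01"
        )
        genes["tetraploid"].append(gained)
        targets["tetraploid"].append(
            GenomicInterval(gained.span.chrom, gained.span.start, gained.span.end)
        )
        families[gained.copy_name] = GAINED_FAMILY
        ortholog_map[GAINED_FAMILY] = {
            "tetraploid_A": gained.copy_name,
            "tetraploid_C": None, "A": None, "C": None,
        }
        # lost from the tetraploid: a diploid-only copy, staggered past the
        # tetraploid extension so homologous coordinates never collide
        lead = cfg.intergenic_length + cfg.gene_length
        refs["A"], l_start = _append_gene(refs["A"], "A01", cfg, rng_scen, lead)
        lost = _gene_model_at(
            "A01", l_start, cfg, "BraA01g9900", f"Bra.{LOST_FAMILY}.A01"
        )
        genes["A"].append(lost)
        targets["A"].append(
            GenomicInterval(lost.span.chrom, lost.span.start, lost.span.end)
        )
        families[lost.copy_name] = LOST_FAMILY
        ortholog_map[LOST_FAMILY] = {
            "tetraploid_A": None, "tetraploid_C": None,
            "A": lost.copy_name, "C": None,
        }
        # covered but unannotated in the diploid: drop the annotation,
        # keep the bait target
        genes["A"] = [
            g
            for g in genes["A"]
            if families.get(g.copy_name) != UNANNOTATED_FAMILY
        ]
        ortholog_map[UNANNOTATED_FAMILY]["A"] = None

    genes_by_copy = {
        g.copy_name: g for gl in genes.values() for g in gl
    }
    spec_plan = default_variant_specs(genes_by_copy)
    # L-genotype specs reference the unannotated family's gene model; keep a
    # lookup that still contains it for placement purposes
    placement_genes = {
        "A": genes["A"]
        + (
            [sim.genes["A"][int(UNANNOTATED_FAMILY[1:]) - 1]]
            if scenarios
            else []
        ),
        "C": genes["C"],
    }

    genotypes: dict[str, Genotype] = {}
    truths: dict[str, TruthSet] = {}
    vcf_records: dict[str, list[VariantRecord]] = {}
    subgenome_of = {"L1": "A", "L2": "A", "K1": "C", "K2": "C"}
    for k, name in enumerate(sorted(spec_plan)):
        sub = subgenome_of[name]
        gt, truth = inject_variants(
            refs[sub],
            placement_genes[sub],
            spec_plan[name],
            streams[3 + k],
            name=name,
            source_ref_id=sub,
        )
        genotypes[name] = gt
        truths[name] = truth
        vcf_records[name] = vcf_from_truth(truth, refs[sub], rng_vcf)

    tracks: dict[tuple[str, str, str], DepthTrack] = {}
    population = None
    if with_tracks:
        t_i = 8
        for name in sorted(genotypes):
            sub = subgenome_of[name]
            for ref_id, mode in (
                (sub, "strict"),
                (sub, "gapped"),
                ("tetraploid", "strict"),
            ):
                tracks[(name, ref_id, mode)] = simulate_depth(
                    genotypes[name],
                    refs[ref_id],
                    ref_id,
                    mode,
                    cfg,
                    streams[t_i],
                    targets[sub],
                )
                t_i += 1
        population = simulate_population_reference(
            cfg,
            n_population,
            refs["tetraploid"],
            "tetraploid",
            genes["tetraploid"],
            targets["tetraploid"],
            streams[t_i],
        )

    return Dataset(
        config=cfg,
        thresholds=thr,
        refs=refs,
        genes=genes,
        targets=targets,
        families=families,
        ortholog_map=ortholog_map,
        genotypes=genotypes,
        truths=truths,
        reference_truth=reference_truth,
        tracks=tracks,
        population=population,
        vcf_records=vcf_records,
        seed=seed,
        subgenome_of=subgenome_of,
    )


def family_alignment(
    ds: Dataset,
    family: str,
    outgroup_divergence: float = 0.15,
    rng: np.random.Generator | int | None = None,
) -> Alignment:
    """Positional alignment of a family's copies plus a synthetic outgroup.

    The subgenomes are collinear by construction, so the copies align
    position-by-position without an alignment step. The outgroup is the
    ancestral (A) copy mutated at ``outgroup_divergence``.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    m = ds.ortholog_map[family]
    names, seqs = [], []
    pairs = [
        (m.get("tetraploid_A"), "tetraploid"),
        (m.get("tetraploid_C"), "tetraploid"),
        (m.get("A"), "A"),
        (m.get("C"), "C"),
    ]
    by_copy = {g.copy_name: g for gl in ds.genes.values() for g in gl}
    for copy_name, ref_id in pairs:
        if copy_name is None:
            continue
        gene = by_copy[copy_name]
        names.append(copy_name)
        seqs.append(ds.refs[ref_id].interval_seq(gene.span))
    if len(names) < 3:
        raise ValidationError(f"family {family} has fewer than 3 copies")
    names.append("outgroup")
    seqs.append(_mutate(seqs[0], outgroup_divergence, rng))
    return Alignment(tuple(names), tuple(seqs))


def deletion_scan_experiment(
    seed: int = 0,
    size: int = LARGE_DEL_SIZE,
    config: SimulationConfig | None = None,
    n_reads: int = 8400,
):
    """Two-genotype deletion experiment for the zero-coverage window scan.

    Injects one homozygous deletion of ``size`` bases spanning an
    exon/intron boundary into the first of two otherwise identical diploid
    genotypes, simulates strict-mode depth for both plus gapped-mode depth
    for the carrier (defaults give ~30x on-target), and runs the scan.
    Returns ``(candidates, truth_event)``.
    """
    from .cnv import scan_large_deletions

    cfg = replace(config or SimulationConfig(), seed=seed, n_reads=n_reads)
    s_ref, s1, s2, s3, s4 = np.random.SeedSequence(seed).spawn(5)
    sim = simulate_reference_pair(cfg, np.random.default_rng(s_ref))
    genes = sim.genes["A"]
    kind = "large_deletion" if size > 18 else "small_deletion"
    carrier, truth = inject_variants(
        sim.diploids["A"],
        genes,
        [
            VariantSpec(
                kind,
                genes[2].gene_id,
                size=size,
                placement="exon_intron_boundary",
            )
        ],
        np.random.default_rng(s1),
        name="carrier",
        source_ref_id="A",
    )
    other, _ = inject_variants(
        sim.diploids["A"], genes, [], np.random.default_rng(s2),
        name="other", source_ref_id="A",
    )
    args = (sim.diploids["A"], "A", cfg)
    strict_own = simulate_depth(
        carrier, *args[:2], "strict", cfg, np.random.default_rng(s3),
        sim.targets["A"],
    )
    gapped_own = simulate_depth(
        carrier, *args[:2], "gapped", cfg, np.random.default_rng(s3),
        sim.targets["A"],
    )
    strict_other = simulate_depth(
        other, *args[:2], "strict", cfg, np.random.default_rng(s4),
        sim.targets["A"],
    )
    candidates = scan_large_deletions(
        strict_own, strict_other, gapped_own, ThresholdConfig(), genes=genes
    )
    return candidates, truth.events[0]


def indel_boundary_experiment(
    seed: int = 0,
    lengths: Sequence[int] = tuple(range(1, 31)),
    config: SimulationConfig | None = None,
    n_reads: int = 12600,
    min_support: int = 2,
) -> dict[int, bool]:
    """Which single-deletion lengths the gapped short-InDel pathway recovers.

    One homozygous deletion per length, each in the coding interior of a
    different gene, simulated at ~30x gapped 100 bp placement. Returns
    length -> recovered. Gapped placement only spans gaps up to 18 bp, so
    longer deletions cannot be called by this pathway.
    """
    from .variants import call_short_indels

    base = config or SimulationConfig()
    n_genes = max(base.n_genes_per_subgenome, len(lengths))
    cfg = replace(
        base, seed=seed, n_reads=n_reads, n_genes_per_subgenome=n_genes
    )
    s_ref, s1, s2 = np.random.SeedSequence(seed).spawn(3)
    sim = simulate_reference_pair(cfg, np.random.default_rng(s_ref))
    genes = sim.genes["A"]
    specs = [
        VariantSpec(
            "large_deletion" if ln > 18 else "small_deletion",
            genes[i].gene_id,
            size=ln,
        )
        for i, ln in enumerate(lengths)
    ]
    carrier, truth = inject_variants(
        sim.diploids["A"], genes, specs, np.random.default_rng(s1),
        name="carrier", source_ref_id="A",
    )
    gapped = simulate_depth(
        carrier, sim.diploids["A"], "A", "gapped", cfg,
        np.random.default_rng(s2), sim.targets["A"],
    )
    calls = call_short_indels(gapped, ThresholdConfig(), min_support=min_support)
    call_keys = {
        (c.chrom, c.pos, c.indel_length)
        for c in calls
        if len(c.ref) > len(c.alt)
    }
    recovered = {}
    for ev in truth.events:
        recovered[ev.size] = (ev.chrom, ev.start, ev.size) in call_keys
    return recovered


def diploid_expectation_pct(
    config: SimulationConfig | None = None,
    seed: int = 0,
    subgenome: str = "A",
) -> float:
    """Mean on-target NC of a diploid vs a tetraploid control, in percent.

    Simulates a CNV-free diploid genotype (one subgenome) and a tetraploid
    control with equal read numbers, places both on the tetraploid
    reference, and returns the diploid's mean normalized coverage over its
    subgenome's target genes as a percentage of the control's. Because the
    diploid's sequenced gene space is about half the tetraploid's at equal
    read number, the expectation is around 200%.
    """
    from .coverage import gene_coverage

    cfg = replace(config or SimulationConfig(intergenic_length=8800), seed=seed)
    s_ref, s_dip, s_tet = np.random.SeedSequence(seed).spawn(3)
    sim = simulate_reference_pair(cfg, np.random.default_rng(s_ref))
    tetra = sim.tetraploid

    def plain(ref: ReferenceSet, name: str, ref_id: str) -> Genotype:
        from .simulate import Haplotype

        return Genotype(
            name=name,
            source_ref_id=ref_id,
            haplotypes=(
                Haplotype(dict(ref.sequences), ()),
                Haplotype(dict(ref.sequences), ()),
            ),
        )

    dip = plain(sim.diploids[subgenome], "diploid", subgenome)
    control = plain(tetra, "control", "tetraploid")
    track_dip = simulate_depth(
        dip, tetra, "tetraploid", "strict", cfg,
        np.random.default_rng(s_dip), sim.targets[subgenome],
    )
    track_ctl = simulate_depth(
        control, tetra, "tetraploid", "strict", cfg,
        np.random.default_rng(s_tet), sim.targets["tetraploid"],
    )
    sub_genes = [
        g
        for g in sim.genes["tetraploid"]
        if g.span.chrom.startswith(subgenome)
    ]
    mean_dip = float(
        np.mean([gene_coverage(track_dip, g).nc for g in sub_genes])
    )
    mean_ctl = float(
        np.mean([gene_coverage(track_ctl, g).nc for g in sub_genes])
    )
    return 100.0 * mean_dip / mean_ctl


# -- persistence ------------------------------------------------------------

def write_dataset(ds: Dataset, directory: str | Path) -> None:
    """Write the dataset as plain-text files (FASTA/GFF3/BED/BedGraph/VCF/
    TSV/JSON); everything written round-trips through the module readers."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover
        raise ValidationError(f"cannot create {d}: {exc}") from exc
    for ref_id, ref in ds.refs.items():
        cio.write_fasta(ref, d / f"ref_{ref_id}.fasta")
        cio.write_gff3(ds.genes[ref_id], d / f"genes_{ref_id}.gff3")
        cio.write_bed(
            {
                f"{ref_id}_t{i:03d}": iv
                for i, iv in enumerate(ds.targets[ref_id])
            },
            d / f"targets_{ref_id}.bed",
        )
    manifest = []
    for (name, ref_id, mode), track in sorted(ds.tracks.items()):
        fname = f"depth_{name}_{ref_id}_{mode}.bedgraph"
        cio.write_bedgraph(track, d / fname)
        manifest.append(
            {
                "genotype": name,
                "reference": ref_id,
                "mode": mode,
                "total_mapped_reads": track.total_mapped_reads,
                "read_length": track.read_length,
                "path": fname,
            }
        )
    pd.DataFrame(manifest).to_csv(d / "tracks.tsv", sep="\t", index=False)
    for name, records in sorted(ds.vcf_records.items()):
        cio.write_vcf(records, d / f"variants_{name}.vcf", sample=name)
    for name, truth in sorted(ds.truths.items()):
        (d / f"truth_{name}.json").write_text(truth.to_json() + "\n")
    if ds.reference_truth is not None:
        (d / "truth_reference.json").write_text(
            ds.reference_truth.to_json() + "\n"
        )
    if ds.population is not None:
        cio.write_population_tsv(ds.population, d / "population_tetraploid.tsv")
    fam_df = pd.DataFrame(
        sorted(ds.families.items()), columns=["copy_name", "family"]
    )
    fam_df.to_csv(d / "families.tsv", sep="\t", index=False)
    orth_rows = [
        {"family": fam, **m} for fam, m in sorted(ds.ortholog_map.items())
    ]
    pd.DataFrame(orth_rows).to_csv(
        d / "orthologs.tsv", sep="\t", index=False
    )
    meta = {
        "config": asdict(ds.config),
        "thresholds": asdict(ds.thresholds),
        "seed": ds.seed,
        "subgenome_of": ds.subgenome_of,
    }
    cio.write_json(meta, d / "dataset.json")


@dataclass
class LoadedDataset:
    """The file-backed view of a written dataset (no haplotype sequences)."""

    config: SimulationConfig
    thresholds: ThresholdConfig
    refs: dict[str, ReferenceSet]
    genes: dict[str, list[GeneModel]]
    targets: dict[str, dict[str, GenomicInterval]]
    families: dict[str, str]
    ortholog_map: dict[str, dict[str, str | None]]
    truths: dict[str, TruthSet]
    reference_truth: TruthSet | None
    tracks: dict[tuple[str, str, str], DepthTrack]
    population: PopulationReference | None
    vcf_records: dict[str, list[VariantRecord]]
    subgenome_of: dict[str, str]
    seed: int


def read_dataset(directory: str | Path) -> LoadedDataset:
    d = Path(directory)
    meta = cio.read_json(d / "dataset.json")
    cfg = SimulationConfig(**meta["config"])
    thr = ThresholdConfig(**meta["thresholds"])
    refs, genes, targets = {}, {}, {}
    for fa in sorted(d.glob("ref_*.fasta")):
        ref_id = fa.stem[len("ref_") :]
        refs[ref_id] = cio.read_fasta(fa)
        genes[ref_id] = cio.read_gff3(d / f"genes_{ref_id}.gff3")
        targets[ref_id] = cio.read_bed(d / f"targets_{ref_id}.bed")
    tracks = {}
    if (d / "tracks.tsv").exists():
        man = pd.read_csv(d / "tracks.tsv", sep="\t")
        for row in man.itertuples():
            ref = refs[row.reference]
            lengths = {c: len(s) for c, s in ref.sequences.items()}
            tracks[(row.genotype, row.reference, row.mode)] = cio.read_bedgraph(
                d / row.path,
                lengths,
                row.reference,
                row.genotype,
                row.mode,
                int(row.total_mapped_reads),
                int(row.read_length),
            )
    truths = {}
    for tf in sorted(d.glob("truth_*.json")):
        t = TruthSet.from_json(tf.read_text())
        truths[t.genotype] = t
    reference_truth = truths.pop("reference", None)
    vcf_records = {}
    for vf in sorted(d.glob("variants_*.vcf")):
        name = vf.stem[len("variants_") :]
        vcf_records[name] = cio.read_vcf(vf, genotype=name)
    pop = None
    if (d / "population_tetraploid.tsv").exists():
        pop = cio.read_population_tsv(d / "population_tetraploid.tsv")
    fam_df = pd.read_csv(d / "families.tsv", sep="\t")
    families = dict(zip(fam_df["copy_name"], fam_df["family"]))
    orth_df = pd.read_csv(d / "orthologs.tsv", sep="\t")
    ortholog_map = {}
    for row in orth_df.to_dict("records"):
        fam = row.pop("family")
        ortholog_map[fam] = {
            k: (None if pd.isna(v) else v) for k, v in row.items()
        }
    return LoadedDataset(
        config=cfg,
        thresholds=thr,
        refs=refs,
        genes=genes,
        targets=targets,
        families=families,
        ortholog_map=ortholog_map,
        truths=truths,
        reference_truth=reference_truth,
        tracks=tracks,
        population=pop,
        vcf_records=vcf_records,
        subgenome_of=meta["subgenome_of"],
        seed=meta["seed"],
    )


__all__ = [
    "Dataset",
    "LoadedDataset",
    "build_default_dataset",
    "diploid_expectation_pct",
    "default_variant_specs",
    "vcf_from_truth",
    "family_alignment",
    "write_dataset",
    "read_dataset",
    "EXCHANGE_FAMILY",
    "UNANNOTATED_FAMILY",
    "GAINED_FAMILY",
    "LOST_FAMILY",
    "LARGE_DEL_FAMILY",
    "LARGE_DEL_SIZE",
]
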