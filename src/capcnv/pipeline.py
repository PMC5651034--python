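"""End-to-end orchestration and summary reports.

The stage functions operate on a dataset object (in-memory or loaded from a
written dataset directory) and return plain pandas DataFrames plus the
domain objects; ``run_pipeline`` chains them file-to-file and writes a
deterministic report bundle with a manifest of every threshold used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .cnv import (
    CNVCall,
    CrossSpeciesCall,
    LargeDeletionCandidate,
    classify_cnv_pair,
    classify_cross_species,
    reconcile_copy_sets,
    scan_large_deletions,
)
from .core import GeneModel, ThresholdConfig, ValidationError
from .coverage import gene_coverage
from .dataset import EXCHANGE_FAMILY, family_alignment, read_dataset
from .io import write_json, write_vcf
from .phylo import bootstrap_support, write_newick
from .variants import (
    ConsequenceAnnotation,
    VariantRecord,
    annotate_variant,
    filter_variants,
    heterozygosity_stats,
    severity_key,
    severity_rank,
)

log = logging.getLogger("capcnv")


def _copy_subgenome(copy_name: str) -> str:
    chrom = GeneModel.parse_copy_name(copy_name)[2]
    return chrom[0]


def coverage_table(ds) -> pd.DataFrame:
    """Per-copy normalized coverage for every genotype and reference."""
    rows = []
    for (name, ref_id, mode), track in sorted(ds.tracks.items()):
        if mode != "strict":
            continue
        for gene in ds.genes[ref_id]:
            rec = gene_coverage(track, gene)
            rows.append(
                {
                    "genotype": name,
                    "reference": ref_id,
                    "mode": mode,
                    "chrom": gene.span.chrom,
                    "start": gene.span.start,
                    "end": gene.span.end,
                    "gene_id": gene.gene_id,
                    "copy_name": gene.copy_name,
                    "family": ds.families.get(gene.copy_name),
                    "read_count": rec.read_count,
                    "nc": rec.nc,
                }
            )
    return pd.DataFrame(rows)


def cnv_calls(ds, coverage: pd.DataFrame | None = None) -> list[CNVCall]:
    """Two-genotype CNV classification per species pair on own references."""
    thr = ds.thresholds
    cov = coverage if coverage is not None else coverage_table(ds)
    calls = []
    for sub in ("A", "C"):
        g1, g2 = ds.pair(sub) if hasattr(ds, "pair") else tuple(
            sorted(n for n, s in ds.subgenome_of.items() if s == sub)
        )
        own = cov[(cov.reference == sub)]
        for gene in ds.genes[sub]:
            fam = ds.families.get(gene.copy_name)
            napus_copy = (
                ds.ortholog_map.get(fam, {}).get(f"tetraploid_{sub}")
                if fam
                else None
            )
            pop_mean = None
            if (
                ds.population is not None
                and napus_copy in ds.population.mean_nc
            ):
                pop_mean = ds.population.mean_nc[napus_copy]
            track1 = ds.tracks[(g1, sub, "strict")]
            track2 = ds.tracks[(g2, sub, "strict")]
            calls.append(
                classify_cnv_pair(
                    gene_coverage(track1, gene),
                    gene_coverage(track2, gene),
                    pop_mean,
                    thr,
                )
            )
    return calls


def cnv_table(calls: Sequence[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in calls])


def cross_species_calls(ds) -> dict[str, CrossSpeciesCall]:
    """Status of every tetraploid copy from diploid-on-tetraploid coverage."""
    thr = ds.thresholds
    if ds.population is None:
        raise ValidationError("population baseline required")
    by_sub: dict[str, list[str]] = {"A": [], "C": []}
    for name, sub in sorted(ds.subgenome_of.items()):
        by_sub[sub].append(name)
    out: dict[str, CrossSpeciesCall] = {}
    for gene in ds.genes["tetraploid"]:
        copy = gene.copy_name
        pop_mean = ds.population.mean_nc.get(copy)
        if not pop_mean:
            continue
        pcts: dict[str, list[float]] = {}
        for sub, names in by_sub.items():
            pcts[sub] = [
                100.0
                * gene_coverage(
                    ds.tracks[(n, "tetraploid", "strict")], gene
                ).nc
                / pop_mean
                for n in names
            ]
        out[copy] = classify_cross_species(
            pcts["A"], pcts["C"], copy, _copy_subgenome(copy), thr
        )
    return out


def cross_species_table(calls: Mapping[str, CrossSpeciesCall]) -> pd.DataFrame:
    rows = []
    for copy, c in sorted(calls.items()):
        rows.append(
            {
                "copy_name": copy,
                "subgenome": c.subgenome,
                "pct_matching": ";".join(f"{p:.1f}" for p in c.pct_matching),
                "pct_other": ";".join(f"{p:.1f}" for p in c.pct_other),
                "status": c.status,
                "direction": c.direction,
            }
        )
    return pd.DataFrame(rows)


def diploid_coverage_flags(ds) -> dict[tuple[str, str], bool]:
    """Whether each family locus is capture-covered in each progenitor."""
    thr = ds.thresholds
    by_copy = {g.copy_name: g for gl in ds.genes.values() for g in gl}
    flags: dict[tuple[str, str], bool] = {}
    for fam, m in ds.ortholog_map.items():
        for sub in ("A", "C"):
            copy = m.get(sub)
            span = None
            if copy is not None and copy in by_copy:
                span = by_copy[copy].span
            else:
                tcopy = m.get(f"tetraploid_{sub}")
                if tcopy is not None and tcopy in by_copy:
                    cand = by_copy[tcopy].span
                    chrom_seq = ds.refs[sub].sequences.get(cand.chrom)
                    if chrom_seq is not None and cand.end <= len(chrom_seq):
                        span = cand
            if span is None:
                flags[(fam, sub)] = False
                continue
            covered = False
            for name, s in ds.subgenome_of.items():
                if s != sub:
                    continue
                track = ds.tracks.get((name, sub, "strict"))
                if track is None:
                    continue
                from .coverage import region_coverage

                if region_coverage(track, span).nc >= thr.min_region_nc:
                    covered = True
            flags[(fam, sub)] = covered
    return flags


def reconciliation(ds, cross: Mapping[str, CrossSpeciesCall] | None = None):
    cross = cross if cross is not None else cross_species_calls(ds)
    return reconcile_copy_sets(
        ds.ortholog_map, cross, diploid_coverage_flags(ds)
    )


def large_deletion_calls(ds) -> dict[str, list[LargeDeletionCandidate]]:
    """Zero-coverage window scan per genotype against its pair partner."""
    out: dict[str, list[LargeDeletionCandidate]] = {}
    for sub in ("A", "C"):
        names = sorted(n for n, s in ds.subgenome_of.items() if s == sub)
        for own in names:
            other = [n for n in names if n != own][0]
            out[own] = scan_large_deletions(
                ds.tracks[(own, sub, "strict")],
                ds.tracks[(other, sub, "strict")],
                ds.tracks[(own, sub, "gapped")],
                ds.thresholds,
                genes=ds.genes[sub],
            )
    return out


# -- variant stage ----------------------------------------------------------

def _gene_for_variant(
    rec: VariantRecord, genes: Sequence[GeneModel]
) -> GeneModel | None:
    pos0 = rec.pos - 1
    for g in genes:
        if g.span.chrom == rec.chrom and g.span.start <= pos0 < g.span.end:
            return g
    return None


def annotate_genotype_variants(
    ds, genotype: str
) -> tuple[pd.DataFrame, list[VariantRecord]]:
    """Filter, keep homozygous records as true variants, and annotate.

    Returns the annotation table and the heterozygous sidecar records.
    """
    thr = ds.thresholds
    sub = ds.subgenome_of[genotype]
    records = ds.vcf_records[genotype]
    kept = filter_variants(records, thr)
    stats, hom = heterozygosity_stats(kept)
    het = [r for r in kept if r.zygosity == "het"]
    rows = []
    for rec in kept:
        gene = _gene_for_variant(rec, ds.genes[sub])
        if gene is None:
            ann = ConsequenceAnnotation("silent")
            copy_name = None
        else:
            ann = annotate_variant(rec, gene, ds.refs[sub])
            copy_name = gene.copy_name
        rows.append(
            {
                "genotype": genotype,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "vtype": rec.vtype,
                "zygosity": rec.zygosity,
                "copy_name": copy_name,
                "family": ds.families.get(copy_name) if copy_name else None,
                "category": ann.category,
                "protein_change": ann.protein_change,
                "grantham": ann.grantham_distance,
                "radicality": ann.radicality,
                "pseudogene": ann.pseudogene,
            }
        )
    return pd.DataFrame(rows), het


def variant_class_summary(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype counts by variant class (the bar-plot numbers).

    SNP subclasses (silent, synonymous, nonsynonymous, splice, stop) and
    InDel subclasses (silent, inframe, frameshift, splice) each sum to their
    type totals, and hom + het = total.
    """
    rows = []
    for (genotype, vtype), grp in annotations.groupby(
        ["genotype", "vtype"], sort=True
    ):
        cats = grp.category
        row = {
            "genotype": genotype,
            "vtype": vtype,
            "total": len(grp),
            "hom": int((grp.zygosity == "hom").sum()),
            "het": int((grp.zygosity == "het").sum()),
            "silent": int((cats == "silent").sum()),
            "splice": int(cats.isin(["splice_donor", "splice_acceptor"]).sum()),
        }
        if vtype == "snp":
            row["synonymous"] = int((cats == "synonymous").sum())
            row["nonsynonymous"] = int((cats == "nonsynonymous").sum())
            row["stop"] = int(cats.isin(["stop_gain", "stop_loss"]).sum())
        else:
            row["inframe"] = int((cats == "inframe_indel").sum())
            row["frameshift"] = int((cats == "frameshift_indel").sum())
        rows.append(row)
    return pd.DataFrame(rows)


def pathway_report(
    ds,
    annotations: pd.DataFrame,
    cnv: Sequence[CNVCall],
    cross: Mapping[str, CrossSpeciesCall],
) -> pd.DataFrame:
    """Per-genotype, per-copy pathway summary (the pathway-figure table).

    Each analyzed copy appears exactly once per genotype with its most
    severe variant category, its CNV status, and a presence frame: found,
    not_found (known tetraploid copy without diploid counterpart) or
    unannotated (covered but not an annotated gene in the diploid).
    """
    cnv_by_key = {}
    for c in cnv:
        cnv_by_key[c.key] = c
    by_copy = {g.copy_name: g for gl in ds.genes.values() for g in gl}
    rows = []
    for genotype in sorted(ds.subgenome_of):
        sub = ds.subgenome_of[genotype]
        gsub = annotations[annotations.genotype == genotype]
        for fam in sorted(ds.ortholog_map):
            m = ds.ortholog_map[fam]
            napus_copy = m.get(f"tetraploid_{sub}")
            diploid_copy = m.get(sub)
            if diploid_copy is None and napus_copy is None:
                continue
            if diploid_copy is not None:
                presence = "found"
                copy = diploid_copy
            else:
                call = cross.get(napus_copy)
                covered = diploid_coverage_flags(ds).get((fam, sub), False)
                presence = "unannotated" if covered else "not_found"
                copy = napus_copy
            if copy in cnv_by_key or (
                diploid_copy and by_copy[diploid_copy].gene_id in cnv_by_key
            ):
                c = cnv_by_key.get(copy) or cnv_by_key[
                    by_copy[diploid_copy].gene_id
                ]
                cnv_status = (
                    "duplication"
                    if c.call == "duplication_in_high"
                    and c.carrier == genotype
                    else "deletion"
                    if c.call == "deletion_in_low" and c.carrier == genotype
                    else "none"
                )
            else:
                cnv_status = "none"
            fam_ann = gsub[gsub.family == fam]
            if len(fam_ann):
                anns = [
                    ConsequenceAnnotation(
                        category=r.category,
                        protein_change=r.protein_change
                        if isinstance(r.protein_change, str)
                        else None,
                        grantham_distance=int(r.grantham)
                        if pd.notna(r.grantham)
                        else None,
                        radicality=r.radicality,
                    )
                    for r in fam_ann.itertuples()
                ]
                top, _ = severity_rank(anns)
                severe = top.category
                if top.category == "nonsynonymous":
                    severe = f"nonsynonymous_{top.radicality}"
            else:
                severe = "none"
            rows.append(
                {
                    "genotype": genotype,
                    "family": fam,
                    "copy_name": copy,
                    "presence": presence,
                    "cnv": cnv_status,
                    "most_severe": severe,
                    "cross_species": (
                        cross.get(napus_copy).status
                        if napus_copy in cross
                        else None
                    ),
                }
            )
    return pd.DataFrame(rows)


# -- end-to-end -------------------------------------------------------------

@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0
    bootstrap_reps: int | None = None  # default: thresholds.bootstrap_reps
    phylo_families: tuple[str, ...] = ("G01", EXCHANGE_FAMILY)


class _DatasetView:
    """LoadedDataset + helpers expected by the stage functions."""

    def __init__(self, loaded, thresholds):
        self._loaded = loaded
        self.thresholds = thresholds
        for name in (
            "refs", "genes", "targets", "families", "ortholog_map",
            "truths", "tracks", "population", "vcf_records", "subgenome_of",
            "seed",
        ):
            setattr(self, name, getattr(loaded, name))

    def pair(self, sub):
        names = sorted(
            n for n, s in self.subgenome_of.items() if s == sub
        )
        return names[0], names[1]


def load_dataset_view(
    input_dir: str, thresholds: ThresholdConfig | None = None
):
    """Load a written dataset directory for use with the stage functions."""
    loaded = read_dataset(input_dir)
    return _DatasetView(loaded, thresholds or loaded.thresholds)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on a written dataset directory.

    Stages communicate only through declared files; the bundle contains the
    coverage table, CNV and cross-species calls, reconciliation labels,
    large-deletion candidates, filtered+annotated variants with the
    homozygous-only callset and heterozygous sidecar, class summaries, the
    pathway report, NJ trees with bootstrap support, recovery metrics
    against the truth ledger, and a manifest of thresholds and versions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    reps = config.bootstrap_reps or thr.bootstrap_reps
    try:
        loaded = read_dataset(config.input_dir)
    except Exception as exc:
        raise ValidationError(f"[load] {exc}") from exc
    ds = _DatasetView(loaded, thr)
    log.info("thresholds: %s", asdict(thr))

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise ValidationError(f"[{name}] {exc}") from exc

    cov = stage("coverage", lambda: coverage_table(ds))
    cov.to_csv(out / "coverage.tsv", sep="\t", index=False, float_format="%.6g")

    calls = stage("cnv", lambda: cnv_calls(ds, cov))
    cnv_table(calls).to_csv(
        out / "cnv_calls.tsv", sep="\t", index=False, float_format="%.6g"
    )

    cross = stage("crossmap", lambda: cross_species_calls(ds))
    cross_species_table(cross).to_csv(
        out / "cross_species.tsv", sep="\t", index=False
    )
    recon = stage("reconcile", lambda: reconciliation(ds, cross))
    pd.DataFrame([asdict(r) for r in recon]).to_csv(
        out / "copy_reconciliation.tsv", sep="\t", index=False
    )

    bigdel = stage("bigdel", lambda: large_deletion_calls(ds))
    rows = []
    for name, cands in sorted(bigdel.items()):
        for c in cands:
            rows.append(
                {
                    "genotype": name,
                    "chrom": c.interval.chrom,
                    "start": c.interval.start,
                    "end": c.interval.end,
                    "mean_other_depth": c.mean_other_depth,
                    "max_own_gapped_depth": c.max_own_gapped_depth,
                    "overlaps_gene": c.overlaps_gene,
                }
            )
    pd.DataFrame(rows).to_csv(
        out / "large_deletions.tsv", sep="\t", index=False, float_format="%.6g"
    )

    ann_frames, het_all = [], []
    for name in sorted(ds.subgenome_of):
        ann, het = stage(
            "variants", lambda n=name: annotate_genotype_variants(ds, n)
        )
        ann_frames.append(ann)
        het_all.extend(het)
        hom_records = [
            r
            for r in filter_variants(ds.vcf_records[name], thr)
            if r.zygosity == "hom"
        ]
        write_vcf(
            hom_records, out / f"true_variants_{name}.vcf", sample=name
        )
    annotations = pd.concat(ann_frames, ignore_index=True)
    annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    write_vcf(het_all, out / "heterozygous_sidecar.vcf", sample="combined")

    summary = stage("report", lambda: variant_class_summary(annotations))
    summary.to_csv(out / "variant_class_summary.tsv", sep="\t", index=False)
    pathway = stage(
        "report", lambda: pathway_report(ds, annotations, calls, cross)
    )
    pathway.to_csv(out / "pathway_report.tsv", sep="\t", index=False)

    for i, fam in enumerate(config.phylo_families):
        aln = stage("phylo", lambda f=fam: family_alignment(ds, f, rng=config.seed))
        tree = stage(
            "phylo",
            lambda a=aln: bootstrap_support(
                a, reps=reps, seed=config.seed, outgroup="outgroup"
            ),
        )
        write_newick(tree, out / f"tree_{fam}.nwk")

    recovery = stage("recovery", lambda: cnv_recovery_metrics(ds, calls))
    write_json(recovery, out / "cnv_recovery.json")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "bootstrap_reps": reps,
        "thresholds": asdict(thr),
        "input_dir": str(config.input_dir),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    write_json(manifest, out / "manifest.json")
    return manifest


def cnv_recovery_metrics(ds, calls: Sequence[CNVCall]) -> dict:
    """Precision/recall of homozygous CNV events against the truth ledger."""
    truth_events = {}
    gene_ids = {g.gene_id for gl in ds.genes.values() for g in gl}
    for name, truth in ds.truths.items():
        for ev in truth.of_kind("duplication", "gene_loss"):
            if ev.zygosity != "hom" or ev.gene_id not in gene_ids:
                continue
            kind = (
                "duplication" if ev.kind == "duplication" else "deletion"
            )
            truth_events[(ev.gene_id, name)] = kind
    called = {}
    for c in calls:
        if c.call == "deletion_in_low":
            called[(c.key, c.carrier)] = "deletion"
        elif c.call == "duplication_in_high":
            called[(c.key, c.carrier)] = "duplication"
    tp = sum(
        1
        for k, v in called.items()
        if truth_events.get(k) == v
    )
    fp = len(called) - tp
    fn = len(truth_events) - tp
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    return {
        "n_truth": len(truth_events),
        "n_called": len(called),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
    }


__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "load_dataset_view",
    "coverage_table",
    "cnv_calls",
    "cnv_table",
    "cross_species_calls",
    "cross_species_table",
    "diploid_coverage_flags",
    "reconciliation",
    "large_deletion_calls",
    "annotate_genotype_variants",
    "variant_class_summary",
    "pathway_report",
    "cnv_recovery_metrics",
]
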