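"""Readers and writers for the standard text formats of the pipeline.

Conventions: BED and BedGraph are 0-based half-open; GFF3 and VCF are
1-based inclusive. All writers emit deterministic, sorted output so a rerun
of the pipeline produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel, GenomicInterval, ReferenceSet, ValidationError
from .coverage import DepthTrack, PopulationReference
from .variants import VariantRecord


# -- FASTA ------------------------------------------------------------------

def write_fasta(ref: ReferenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(ref.sequences[name]), id=name, description="")
        for name in sorted(ref.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> ReferenceSet:
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }
    return ReferenceSet(seqs)


def read_alignment_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Aligned FASTA -> (names, equal-length gapped sequences)."""
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if len({len(s) for s in seqs}) > 1:
        raise ValidationError("alignment sequences differ in length")
    return names, seqs


# -- GFF3 -------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.span.chrom, g.span.start)):
        attrs = f"ID={g.gene_id};Name={g.copy_name}"
        lines.append(
            "\t".join(
                [
                    g.span.chrom, "capcnv", "gene",
                    str(g.span.start + 1), str(g.span.end), ".",
                    g.strand, ".", attrs,
                ]
            )
        )
        for i, e in enumerate(g.exons, 1):
            lines.append(
                "\t".join(
                    [
                        e.chrom, "capcnv", "exon",
                        str(e.start + 1), str(e.end), ".",
                        g.strand, ".",
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
                    ]
                )
            )
        for i, c in enumerate(g.cds, 1):
            lines.append(
                "\t".join(
                    [
                        c.chrom, "capcnv", "CDS",
                        str(c.start + 1), str(c.end), ".",
                        g.strand, ".",
                        f"ID={g.gene_id}.cds{i};Parent={g.gene_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, _score, strand, _frame, attrs = (
            line.split("\t")
        )
        a = _gff_attrs(attrs)
        iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
        if ftype == "gene":
            gid = a["ID"]
            genes[gid] = {
                "copy_name": a.get("Name", gid),
                "span": iv,
                "strand": strand,
                "exons": [],
                "cds": [],
            }
            order.append(gid)
        elif ftype in ("exon", "CDS"):
            parent = a["Parent"]
            genes[parent]["exons" if ftype == "exon" else "cds"].append(iv)
    return [
        GeneModel(
            gene_id=gid,
            copy_name=g["copy_name"],
            span=g["span"],
            exons=tuple(g["exons"]),
            cds=tuple(g["cds"]),
            strand=g["strand"],
        )
        for gid, g in ((gid, genes[gid]) for gid in order)
    ]


# -- BED --------------------------------------------------------------------

def write_bed(
    intervals: Mapping[str, GenomicInterval] | Sequence[GenomicInterval],
    path: str | Path,
) -> None:
    if isinstance(intervals, Mapping):
        items = list(intervals.items())
    else:
        items = [(f"iv{i}", iv) for i, iv in enumerate(intervals)]
    items.sort(key=lambda kv: (kv[1].chrom, kv[1].start, kv[0]))
    lines = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}" for name, iv in items
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path) -> dict[str, GenomicInterval]:
    out: dict[str, GenomicInterval] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        name = parts[3] if len(parts) > 3 else f"iv{i}"
        out[name] = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
    return out


# -- BedGraph ---------------------------------------------------------------

def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    """Run-length encoded per-base depth; zero runs are omitted."""
    lines = []
    for chrom in sorted(track.depths):
        d = track.depths[chrom]
        if len(d) == 0:
            continue
        change = np.flatnonzero(np.diff(d)) + 1
        bounds = np.concatenate(([0], change, [len(d)]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            v = int(d[s])
            if v != 0:
                lines.append(f"{chrom}\t{s}\t{e}\t{v}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bedgraph(
    path: str | Path,
    chrom_lengths: Mapping[str, int],
    reference_id: str,
    genotype: str,
    mode: str,
    total_mapped_reads: int,
    read_length: int,
) -> DepthTrack:
    depths = {
        c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()
    }
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        chrom, s, e, v = line.split("\t")
        depths[chrom][int(s) : int(e)] = int(v)
    return DepthTrack(
        reference_id=reference_id,
        genotype=genotype,
        mode=mode,
        depths=depths,
        total_mapped_reads=total_mapped_reads,
        read_length=read_length,
    )


# -- VCF --------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##INFO=<ID=TYPE,Number=1,Type=String,Description="snp or indel">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(
    records: Sequence[VariantRecord], path: str | Path, sample: str
) -> None:
    lines = [_VCF_HEADER.rstrip("\n")]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        gt = "1/1" if r.zygosity == "hom" else "0/1"
        lines.append(
            "\t".join(
                [
                    r.chrom, str(r.pos), ".", r.ref, r.alt, ".", "PASS",
                    f"MQ={r.mq:g};TYPE={r.vtype}", "GT:DP", f"{gt}:{r.dp}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, genotype: str | None = None) -> list[VariantRecord]:
    out = []
    sample_name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line:
            continue
        if line.startswith("#CHROM"):
            cols = line.split("\t")
            sample_name = cols[9] if len(cols) > 9 else None
            continue
        chrom, pos, _id, ref, alt, _q, _f, info, fmt, sample = line.split("\t")
        info_d = dict(
            kv.split("=", 1) for kv in info.split(";") if "=" in kv
        )
        fmt_d = dict(zip(fmt.split(":"), sample.split(":")))
        vtype = info_d.get(
            "TYPE", "snp" if len(ref) == 1 and len(alt) == 1 else "indel"
        )
        zyg = "het" if fmt_d.get("GT") in ("0/1", "0|1", "1|0") else "hom"
        out.append(
            VariantRecord(
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                vtype=vtype,
                mq=float(info_d.get("MQ", 0)),
                dp=int(fmt_d.get("DP", 0)),
                zygosity=zyg,
                genotype=genotype or sample_name or "sample",
            )
        )
    return out


# -- tables -----------------------------------------------------------------

def write_population_tsv(pop: PopulationReference, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(pop.mean_nc.items()), columns=["copy_name", "mean_nc"]
    )
    df["n_genotypes"] = pop.n_genotypes
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_population_tsv(path: str | Path) -> PopulationReference:
    df = pd.read_csv(path, sep="\t")
    return PopulationReference(
        mean_nc=dict(zip(df["copy_name"], df["mean_nc"].astype(float))),
        n_genotypes=int(df["n_genotypes"].iloc[0]),
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


__all__ = [
    "write_fasta", "read_fasta", "read_alignment_fasta",
    "write_gff3", "read_gff3",
    "write_bed", "read_bed",
    "write_bedgraph", "read_bedgraph",
    "write_vcf", "read_vcf",
    "write_population_tsv", "read_population_tsv",
    "write_json", "read_json",
]
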