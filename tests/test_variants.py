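import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capcnv.core import (
    GeneModel,
    GenomicInterval,
    ReferenceSet,
    ThresholdConfig,
    ValidationError,
)
from capcnv.variants import (
    ConsequenceAnnotation,
    VariantRecord,
    annotate_variant,
    call_short_indels,
    filter_variants,
    grantham_class,
    grantham_distance,
    heterozygosity_stats,
    severity_rank,
)


def rec(vtype="snp", mq=60.0, dp=30, zygosity="hom", pos=5, ref="A", alt="C"):
    if vtype == "indel" and len(ref) == len(alt):
        ref, alt = "AT", "A"
    return VariantRecord("A01", pos, ref, alt, vtype, mq, dp, zygosity, "g")


class TestFilter:
    @pytest.mark.parametrize(
        "vtype,mq,dp,kept",
        [
            ("snp", 49.9, 50, False),  # MQ boundary
            ("snp", 50.0, 10, True),
            ("snp", 60.0, 9, False),  # DP boundary
            ("indel", 30.0, 10, True),
            ("indel", 29.9, 100, False),
        ],
    )
    def test_boundaries(self, vtype, mq, dp, kept):
        out = filter_variants([rec(vtype, mq, dp)])
        assert (len(out) == 1) is kept

    def test_random_records_match_bruteforce_predicate(self, rng):
        records = [
            rec(
                vtype=("snp", "indel")[int(rng.integers(0, 2))],
                mq=float(rng.uniform(0, 60)),
                dp=int(rng.integers(0, 40)),
            )
            for _ in range(1000)
        ]
        kept = filter_variants(records)
        expected = [
            r
            for r in records
            if (r.vtype == "snp" and r.mq >= 50 and r.dp >= 10)
            or (r.vtype == "indel" and r.mq >= 30 and r.dp >= 10)
        ]
        assert kept == expected


class TestHetStats:
    def test_all_homozygous(self):
        stats, hom = heterozygosity_stats([rec() for _ in range(5)])
        assert stats.het_snp_pct == 0.0 and len(hom) == 5

    def test_two_of_twenty(self):
        records = [rec() for _ in range(18)] + [
            rec(zygosity="het") for _ in range(2)
        ]
        stats, hom = heterozygosity_stats(records)
        assert stats.het_combined_pct == pytest.approx(10.0)
        assert len(hom) == 18

    def test_empty_input_reports_none(self):
        stats, hom = heterozygosity_stats([])
        assert stats.het_snp_pct is None and hom == []

    def test_random_matches_counting_oracle(self, rng):
        records = [
            rec(
                vtype=("snp", "indel")[int(rng.integers(0, 2))],
                zygosity=("hom", "het")[int(rng.integers(0, 2))],
            )
            for _ in range(200)
        ]
        stats, hom = heterozygosity_stats(records)
        snps = [r for r in records if r.vtype == "snp"]
        n_het = sum(r.zygosity == "het" for r in snps)
        assert stats.het_snp_pct == pytest.approx(100 * n_het / len(snps))
        assert all(r.zygosity == "hom" for r in hom)
        assert len(hom) + sum(r.zygosity == "het" for r in records) == 200


class TestGrantham:
    @pytest.mark.parametrize(
        "a,b,dist,label",
        [
            ("W", "C", 215, "radical"),
            ("L", "I", 5, "conservative"),
            ("R", "P", 103, "moderately_radical"),
            ("F", "S", 155, "radical"),
            ("H", "Y", 83, "moderately_conservative"),
            ("T", "N", 65, "moderately_conservative"),
        ],
    )
    def test_known_pairs(self, a, b, dist, label):
        assert grantham_class(a, b) == (dist, label)

    def test_symmetry_and_zero_diagonal(self):
        for a, b in [("A", "W"), ("D", "K"), ("C", "G")]:
            assert grantham_distance(a, b) == grantham_distance(b, a)
        assert grantham_distance("Q", "Q") == 0

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValidationError):
            grantham_class("B", "A")


# -- annotation on a hand-built gene ---------------------------------------

def _codon_seq(codons, exon_split):
    """Build a forward-strand gene: exons from codons, GT..AG introns."""
    cds = "".join(codons)
    intron = "GT" + "T" * 26 + "AG"
    parts, cursor = [], 0
    for length in exon_split:
        parts.append(cds[cursor : cursor + length])
        cursor += length
    return (intron).join(parts), len(intron)


@pytest.fixture()
def toy_gene():
    # 6 codons: M K W T S * split 7|11 across two exons (codon straddles)
    codons = ["ATG", "AAA", "TGG", "ACT", "TCA", "TAA"]
    gene_seq, ilen = _codon_seq(codons, (7, 11))
    seq = "CCCCC" + gene_seq + "CCCCC"
    start = 5
    e1 = GenomicInterval("A01", start, start + 7)
    e2 = GenomicInterval("A01", start + 7 + ilen, start + 18 + ilen)
    gene = GeneModel(
        "toy",
        "Bra.TOY.A01",
        GenomicInterval("A01", start, start + 18 + ilen),
        (e1, e2),
        (e1, e2),
        "+",
    )
    return gene, ReferenceSet({"A01": seq})


class TestAnnotate:
    def test_nonsynonymous_tryptophan_to_cysteine_is_radical(self, toy_gene):
        gene, ref = toy_gene
        # codon 3 = TGG (W); third base G->C makes TGC (C): W->C, radical
        pos0 = gene.cds[0].start + 8 + 30  # offset of that base in genome
        # locate TGG third base: cds index 8 -> genomic position
        genomic = [p for c in gene.cds for p in range(c.start, c.end)][8]
        v = rec(pos=genomic + 1, ref="G", alt="C")
        ann = annotate_variant(v, gene, ref)
        assert ann.category == "nonsynonymous"
        assert ann.protein_change == "W3C"
        assert ann.grantham_distance == 215 and ann.radicality == "radical"

    def test_synonymous_third_position(self, toy_gene):
        gene, ref = toy_gene
        genomic = [p for c in gene.cds for p in range(c.start, c.end)][5]
        v = rec(pos=genomic + 1, ref="A", alt="G")  # AAA -> AAG, both K
        ann = annotate_variant(v, gene, ref)
        assert ann.category == "synonymous"
        assert ann.radicality == "none"

    def test_stop_gain_before_natural_end(self, toy_gene):
        gene, ref = toy_gene
        # codon 5 TCA -> TGA by C->G at second position
        genomic = [p for c in gene.cds for p in range(c.start, c.end)][13]
        ann = annotate_variant(rec(pos=genomic + 1, ref="C", alt="G"), gene, ref)
        assert ann.category == "stop_gain"

    def test_stop_loss_extends_peptide(self, toy_gene):
        gene, ref = toy_gene
        # natural stop TAA -> CAA (Gln)
        genomic = [p for c in gene.cds for p in range(c.start, c.end)][15]
        ann = annotate_variant(rec(pos=genomic + 1, ref="T", alt="C"), gene, ref)
        assert ann.category == "stop_loss"

    def test_splice_donor_and_acceptor(self, toy_gene):
        gene, ref = toy_gene
        intron = gene.introns()[0]
        don = annotate_variant(
            rec(pos=intron.start + 1, ref="G", alt="A"), gene, ref
        )
        acc = annotate_variant(
            rec(pos=intron.end, ref="G", alt="C"), gene, ref
        )
        assert don.category == "splice_donor"
        assert acc.category == "splice_acceptor"

    def test_intron_interior_is_silent(self, toy_gene):
        gene, ref = toy_gene
        intron = gene.introns()[0]
        ann = annotate_variant(
            rec(pos=intron.start + 10, ref="T", alt="G"), gene, ref
        )
        assert ann.category == "silent"

    def test_frameshift_vs_inframe_indel(self, toy_gene):
        gene, ref = toy_gene
        p = gene.cds[0].start + 3  # inside CDS
        anchor = ref.sequences["A01"][p]
        fs = rec(
            vtype="indel", pos=p + 1,
            ref=anchor + ref.sequences["A01"][p + 1], alt=anchor,
        )
        assert annotate_variant(fs, gene, ref).category == "frameshift_indel"
        inf = rec(
            vtype="indel", pos=p + 1,
            ref=anchor + ref.sequences["A01"][p + 1 : p + 4], alt=anchor,
        )
        assert annotate_variant(inf, gene, ref).category == "inframe_indel"

    def test_reverse_strand_equals_revcomp_forward(self, toy_gene):
        """Annotating on '-' equals annotating the revcomp construct on '+'."""
        from Bio.Seq import Seq

        gene, ref = toy_gene
        seq = ref.sequences["A01"]
        L = len(seq)
        rc = str(Seq(seq).reverse_complement())

        def flip(ivl):
            return GenomicInterval(ivl.chrom, L - ivl.end, L - ivl.start)

        gene_minus = GeneModel(
            "toy-", "Bra.TOY.C01",
            flip(gene.span),
            tuple(flip(e) for e in gene.exons),
            tuple(flip(c) for c in gene.cds),
            "-",
        )
        ref_minus = ReferenceSet({"A01": rc})
        # every CDS substitution: forward annotation on rc == minus-strand
        cds_fwd = [p for c in gene.cds for p in range(c.start, c.end)]
        for p in cds_fwd:
            base = seq[p]
            alt = "A" if base != "A" else "G"
            fwd = annotate_variant(rec(pos=p + 1, ref=base, alt=alt), gene, ref)
            comp = str(Seq(base).complement())
            alt_c = str(Seq(alt).complement())
            minus_pos = L - p  # 1-based on the flipped axis
            # the minus-strand gene sits on the ORIGINAL sequence; its codons
            # read off the reverse complement
            minus = annotate_variant(
                rec(pos=minus_pos, ref=comp, alt=alt_c), gene_minus, ref_minus
            )
            assert (fwd.category, fwd.protein_change) == (
                minus.category,
                minus.protein_change,
            )

    def test_outside_neighborhood_rejected(self, toy_gene):
        gene, ref = toy_gene
        big_ref = ReferenceSet({"A01": ref.sequences["A01"] + "A" * 3000})
        with pytest.raises(ValidationError):
            annotate_variant(rec(pos=3000, ref="A", alt="C"), gene, big_ref)

    def test_pseudogene_cds_flagged_not_translated(self):
        # CDS of 7 bases: not a codon multiple
        span = GenomicInterval("A01", 0, 7)
        gene = GeneModel("ps", "Bra.PS.A01", span, (span,), (span,), "+")
        ref = ReferenceSet({"A01": "ATGAAATTTTTTT"})
        ann = annotate_variant(rec(pos=2, ref="T", alt="C"), gene, ref)
        assert ann.pseudogene and ann.category == "silent"

    def test_cds_snp_categories_partition(self, toy_gene):
        """Each CDS substitution receives exactly one category."""
        gene, ref = toy_gene
        seq = ref.sequences["A01"]
        cats = {"synonymous", "nonsynonymous", "stop_gain", "stop_loss"}
        for p in [q for c in gene.cds for q in range(c.start, c.end)]:
            base = seq[p]
            for alt in "ACGT":
                if alt == base:
                    continue
                ann = annotate_variant(rec(pos=p + 1, ref=base, alt=alt), gene, ref)
                assert ann.category in cats


class TestSeverity:
    def test_nonsynonymous_outranks_synonymous(self):
        anns = [
            ConsequenceAnnotation("synonymous"),
            ConsequenceAnnotation(
                "nonsynonymous", grantham_distance=5, radicality="conservative"
            ),
        ]
        top, ordered = severity_rank(anns)
        assert top.category == "nonsynonymous"
        assert ordered[-1].category == "synonymous"

    def test_single_silent(self):
        top, _ = severity_rank([ConsequenceAnnotation("silent")])
        assert top.category == "silent"

    def test_empty(self):
        assert severity_rank([]) == (None, [])

    @given(st.permutations(range(5)))
    @settings(max_examples=20, deadline=None)
    def test_order_invariance(self, perm):
        base = [
            ConsequenceAnnotation("frameshift_indel"),
            ConsequenceAnnotation("stop_gain"),
            ConsequenceAnnotation(
                "nonsynonymous", grantham_distance=200, radicality="radical"
            ),
            ConsequenceAnnotation("synonymous"),
            ConsequenceAnnotation("silent"),
        ]
        shuffled = [base[i] for i in perm]
        top, _ = severity_rank(shuffled)
        assert top.category == "frameshift_indel"


class TestShortIndelCalls:
    def test_requires_gapped_track(self):
        from capcnv.coverage import DepthTrack

        track = DepthTrack(
            "ref", "g", "strict", {"A01": np.zeros(10, dtype=int)}, 0, 100
        )
        with pytest.raises(ValidationError):
            call_short_indels(track)

    def test_support_threshold_and_length_cap(self):
        from capcnv.coverage import DepthTrack

        obs = [("del", "A01", 100, 5)] * 3 + [("del", "A01", 200, 7)] + [
            ("del", "A01", 300, 25)
        ] * 9
        track = DepthTrack(
            "ref", "g", "gapped", {"A01": np.zeros(400, dtype=int)}, 0, 100,
            indel_observations=obs,
        )
        calls = call_short_indels(track, ThresholdConfig(), min_support=2)
        assert [(c.pos, c.dp) for c in calls] == [(100, 3)]
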