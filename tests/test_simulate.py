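import numpy as np
import pytest

from capcnv.core import ValidationError
from capcnv.coverage import gene_coverage, region_coverage
from capcnv.simulate import (
    MAX_SHORT_INDEL,
    SimulationConfig,
    VariantSpec,
    apply_events,
    inject_variants,
    simulate_depth,
    simulate_population_reference,
    simulate_reference_pair,
)

SMALL = SimulationConfig(
    n_genes_per_subgenome=5, intergenic_length=3000, seed=11
)


class TestReferencePair:
    def test_zero_divergence_identical_subgenomes(self):
        cfg = SimulationConfig(
            n_genes_per_subgenome=3,
            intergenic_length=2000,
            subgenome_divergence=0.0,
            seed=3,
        )
        sim = simulate_reference_pair(cfg)
        assert (
            sim.tetraploid.sequences["A01"] == sim.tetraploid.sequences["C01"]
        )

    def test_divergence_within_three_sigma_of_binomial(self):
        cfg = SimulationConfig(
            n_genes_per_subgenome=10,
            intergenic_length=5000,
            subgenome_divergence=0.03,
            seed=5,
        )
        sim = simulate_reference_pair(cfg)
        a = np.frombuffer(sim.tetraploid.sequences["A01"].encode(), np.uint8)
        c = np.frombuffer(sim.tetraploid.sequences["C01"].encode(), np.uint8)
        n = len(a)
        observed = int((a != c).sum())
        expected = 0.03 * n
        sigma = np.sqrt(n * 0.03 * 0.97)
        # gene repair reverts a handful of sites, so stay within 3 sigma
        assert abs(observed - expected) < 3 * sigma

    def test_same_seed_byte_identical(self):
        s1 = simulate_reference_pair(SMALL)
        s2 = simulate_reference_pair(SMALL)
        assert s1.tetraploid.sequences == s2.tetraploid.sequences
        assert s1.genes["A"] == s2.genes["A"]

    def test_diploids_equal_subgenomes(self):
        sim = simulate_reference_pair(SMALL)
        assert (
            sim.diploids["A"].sequences["A01"]
            == sim.tetraploid.sequences["A01"]
        )

    def test_gene_models_well_formed(self):
        from Bio.Seq import Seq

        sim = simulate_reference_pair(SMALL)
        for ref_key, ref in (("A", sim.diploids["A"]), ("C", sim.diploids["C"])):
            for g in sim.genes[ref_key]:
                assert len(g.exons) >= 2
                assert g.in_frame
                cds = "".join(ref.interval_seq(c) for c in g.cds)
                prot = str(Seq(cds).translate())
                assert prot.startswith("M") and prot.endswith("*")
                assert "*" not in prot[:-1]
                for intron in g.introns():
                    iseq = ref.interval_seq(intron)
                    assert iseq[:2] == "GT" and iseq[-2:] == "AG"

    def test_zero_genes_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_genes_per_subgenome=0)


class TestInjectVariants:
    def test_empty_specs_identity(self):
        sim = simulate_reference_pair(SMALL)
        gt, truth = inject_variants(
            sim.diploids["A"], sim.genes["A"], [], 1, name="g"
        )
        assert gt.haplotypes[0].sequences == sim.diploids["A"].sequences
        assert truth.events == ()

    def test_57bp_boundary_deletion(self):
        sim = simulate_reference_pair(SMALL)
        genes = sim.genes["A"]
        gt, truth = inject_variants(
            sim.diploids["A"],
            genes,
            [
                VariantSpec(
                    "large_deletion",
                    genes[1].gene_id,
                    size=57,
                    placement="exon_intron_boundary",
                )
            ],
            2,
        )
        ev = truth.events[0]
        assert ev.size == 57
        old = len(sim.diploids["A"].sequences["A01"])
        assert len(gt.haplotypes[0].sequences["A01"]) == old - 57
        # spans the last intron/exon boundary
        intron = genes[1].introns()[-1]
        assert ev.start < intron.end <= ev.end

    def test_duplication_adds_gene_length(self):
        sim = simulate_reference_pair(SMALL)
        genes = sim.genes["A"]
        gt, truth = inject_variants(
            sim.diploids["A"], genes,
            [VariantSpec("duplication", genes[0].gene_id)], 3,
        )
        old = len(sim.diploids["A"].sequences["A01"])
        assert len(gt.haplotypes[0].sequences["A01"]) == old + len(
            genes[0].span
        )

    def test_heterozygous_event_on_first_haplotype_only(self):
        sim = simulate_reference_pair(SMALL)
        genes = sim.genes["A"]
        gt, truth = inject_variants(
            sim.diploids["A"], genes,
            [VariantSpec("snp", genes[0].gene_id, zygosity="het",
                         consequence="nonsynonymous")], 4,
        )
        ref_seq = sim.diploids["A"].sequences["A01"]
        assert gt.haplotypes[0].sequences["A01"] != ref_seq
        assert gt.haplotypes[1].sequences["A01"] == ref_seq

    def test_homoeologous_exchange_swaps_in_partner_sequence(self):
        sim = simulate_reference_pair(SMALL)
        genes = sim.genes["tetraploid"]
        a_copy = next(g for g in genes if g.span.chrom == "A01")
        gt, truth = inject_variants(
            sim.tetraploid, genes,
            [VariantSpec("homoeologous_exchange", a_copy.gene_id)], 5,
        )
        span = a_copy.span
        new_a = gt.haplotypes[0].sequences["A01"][span.start : span.end]
        assert new_a == sim.tetraploid.sequences["C01"][span.start : span.end]

    def test_overlapping_specs_rejected(self):
        sim = simulate_reference_pair(SMALL)
        genes = sim.genes["A"]
        with pytest.raises(ValidationError):
            inject_variants(
                sim.diploids["A"], genes,
                [
                    VariantSpec("gene_loss", genes[0].gene_id),
                    VariantSpec(
                        "large_deletion",
                        genes[0].gene_id,
                        size=57,
                        placement="exon_intron_boundary",
                    ),
                ],
                6,
            )

    def test_wrong_reference_allele_rejected(self):
        from capcnv.simulate import InjectedEvent

        sim = simulate_reference_pair(SMALL)
        ev = InjectedEvent("x", "snp", "A01", 10, 11, "Z", "A", "hom")
        with pytest.raises(ValidationError):
            apply_events(sim.diploids["A"].sequences, [ev])

    def test_spec_size_classes_enforced(self):
        with pytest.raises(ValidationError):
            VariantSpec("small_deletion", "g", size=MAX_SHORT_INDEL + 1)
        with pytest.raises(ValidationError):
            VariantSpec("large_deletion", "g", size=MAX_SHORT_INDEL)


class TestDepthSimulation:
    def _plain(self, sim, sub="A"):
        from capcnv.simulate import Genotype, Haplotype

        seqs = dict(sim.diploids[sub].sequences)
        return Genotype(
            "plain", sub, (Haplotype(dict(seqs), ()), Haplotype(dict(seqs), ()))
        )

    def test_zero_reads_zero_track(self):
        cfg = SimulationConfig(
            n_genes_per_subgenome=3, intergenic_length=2000, n_reads=0, seed=1
        )
        sim = simulate_reference_pair(cfg)
        track = simulate_depth(
            self._plain(sim), sim.diploids["A"], "A", "strict", cfg, 1,
            sim.targets["A"],
        )
        assert track.depth_mass() == 0 and track.total_mapped_reads == 0

    def test_unknown_mode_rejected(self):
        sim = simulate_reference_pair(SMALL)
        with pytest.raises(ValidationError):
            simulate_depth(
                self._plain(sim), sim.diploids["A"], "A", "soft", SMALL, 1,
                sim.targets["A"],
            )

    def test_strict_conservation_mass_equals_reads_times_length(self):
        sim = simulate_reference_pair(SMALL)
        track = simulate_depth(
            self._plain(sim), sim.diploids["A"], "A", "strict", SMALL, 2,
            sim.targets["A"],
        )
        assert track.depth_mass() == (
            track.total_mapped_reads * SMALL.read_length
        )

    def test_hom_deletion_zero_window_with_covered_flanks(self):
        sim = simulate_reference_pair(SMALL)
        genes = sim.genes["A"]
        gt, truth = inject_variants(
            sim.diploids["A"], genes,
            [VariantSpec("large_deletion", genes[2].gene_id, size=57,
                         placement="exon_intron_boundary")], 7,
        )
        track = simulate_depth(
            gt, sim.diploids["A"], "A", "strict", SMALL, 8, sim.targets["A"]
        )
        ev = truth.events[0]
        d = track.depths["A01"]
        assert d[ev.start : ev.end].max() == 0
        assert ev.end - ev.start >= 19
        # flanks one read-length away are at normal depth
        assert d[ev.start - SMALL.read_length - 10] >= 20
        assert d[ev.end + SMALL.read_length + 10] >= 20

    def test_hom_duplication_doubles_depth(self):
        sim = simulate_reference_pair(SMALL)
        genes = sim.genes["A"]
        gt, _ = inject_variants(
            sim.diploids["A"], genes,
            [VariantSpec("duplication", genes[1].gene_id)], 9,
        )
        track = simulate_depth(
            gt, sim.diploids["A"], "A", "strict", SMALL, 10, sim.targets["A"]
        )
        dup = gene_coverage(track, genes[1]).nc
        flank = np.mean(
            [gene_coverage(track, genes[i]).nc for i in (0, 2, 3, 4)]
        )
        ratio = dup / flank
        # Poisson counting noise: ~4000 reads per gene -> sigma ~ 2%
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_same_seed_identical_tracks(self):
        sim = simulate_reference_pair(SMALL)
        t1 = simulate_depth(
            self._plain(sim), sim.diploids["A"], "A", "strict", SMALL, 42,
            sim.targets["A"],
        )
        t2 = simulate_depth(
            self._plain(sim), sim.diploids["A"], "A", "strict", SMALL, 42,
            sim.targets["A"],
        )
        assert np.array_equal(t1.depths["A01"], t2.depths["A01"])
        assert t1.total_mapped_reads == t2.total_mapped_reads


class TestPopulationReference:
    def test_single_genotype_table_positive_and_keyed_by_copy(self):
        sim = simulate_reference_pair(SMALL)
        pop = simulate_population_reference(
            SMALL, 1, sim.tetraploid, "tetraploid", sim.genes["tetraploid"],
            sim.targets["tetraploid"], 1,
        )
        assert set(pop.mean_nc) == {
            g.copy_name for g in sim.genes["tetraploid"]
        }
        assert all(v > 0 for v in pop.mean_nc.values())

    def test_population_cv_small_at_deep_coverage(self):
        sim = simulate_reference_pair(SMALL)
        ncs = {g.copy_name: [] for g in sim.genes["tetraploid"]}
        rng = np.random.default_rng(5)
        for _ in range(8):
            pop = simulate_population_reference(
                SMALL, 1, sim.tetraploid, "tetraploid",
                sim.genes["tetraploid"], sim.targets["tetraploid"], rng,
            )
            for k, v in pop.mean_nc.items():
                ncs[k].append(v)
        for k, vals in ncs.items():
            vals = np.array(vals)
            assert vals.std() / vals.mean() < 0.2

    def test_gene_absent_from_targets_absent_from_table(self):
        sim = simulate_reference_pair(SMALL)
        subset = sim.genes["tetraploid"][:3]
        pop = simulate_population_reference(
            SMALL, 1, sim.tetraploid, "tetraploid", subset,
            sim.targets["tetraploid"], 2,
        )
        assert set(pop.mean_nc) == {g.copy_name for g in subset}

    def test_zero_genotypes_rejected(self):
        sim = simulate_reference_pair(SMALL)
        with pytest.raises(ValidationError):
            simulate_population_reference(
                SMALL, 0, sim.tetraploid, "tetraploid",
                sim.genes["tetraploid"], sim.targets["tetraploid"], 1,
            )
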