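import math

import numpy as np
import pytest

from exonskip.simulate import (
    IndelAllele,
    IndelSpectrum,
    InsufficientFlankError,
    IsoformMixture,
    ReadTooLongError,
    SimConfig,
    apply_deletion,
    expected_junction_counts,
    isoform_weights_for_psi,
    random_genome,
    simulate_amplicon_reads,
    simulate_gene_counts,
    simulate_junction_reads,
)

from conftest import brute_force_expected_junctions


def _mix(gene, weight_inclusion):
    inc = gene.labels
    exc = tuple(l for l in inc if l != inc[1])
    return IsoformMixture(
        gene=gene,
        isoforms=((inc, weight_inclusion), (exc, 1.0 - weight_inclusion)),
    )


class TestJunctionReads:
    def test_pure_inclusion_has_no_exclusion_truth(self, kras, tmp_path):
        gene, _, _ = kras
        mix = IsoformMixture(gene=gene, isoforms=(((1, 2, 3), 1.0),))
        cfg = SimConfig(seed=1, depth=1000)
        truth = simulate_junction_reads(mix, cfg, tmp_path / "a.sam")
        assert truth.expected.get((1, 3), 0.0) == 0.0
        assert (1, 3) not in truth.realized

    def test_exclusion_fraction_matches_binomial_oracle(self, kras, tmp_path):
        gene, _, _ = kras
        mix = _mix(gene, 0.5)
        cfg = SimConfig(seed=7, depth=10000)
        truth = simulate_junction_reads(mix, cfg, tmp_path / "a.sam")
        oracle = brute_force_expected_junctions(mix, cfg, truth.min_overhang)
        total = sum(oracle.values())
        p = oracle[(1, 3)] / total
        observed = truth.realized[(1, 3)]
        n = sum(truth.realized.values())
        sd = math.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) <= 3 * sd

    def test_expected_counts_equal_brute_force_enumeration(self, ctnnb1):
        gene, _, _ = ctnnb1
        mix = IsoformMixture(
            gene=gene,
            isoforms=(
                ((2, 3, 4, 5, 6, 7), 0.55),
                ((2, 4, 5, 6, 7), 0.20),
                ((2, 5, 6, 7), 0.15),
                ((2, 7), 0.10),
            ),
        )
        cfg = SimConfig(seed=1, depth=5000, read_length=60)
        expected = expected_junction_counts(mix, cfg, min_overhang=6)
        oracle = brute_force_expected_junctions(mix, cfg, 6)
        assert set(expected) == set(oracle)
        for junc in oracle:
            assert expected[junc] == pytest.approx(oracle[junc], rel=1e-9)

    def test_equal_seeds_give_byte_identical_sam(self, kras, tmp_path):
        gene, _, _ = kras
        mix = _mix(gene, 0.6)
        for name in ("a", "b"):
            cfg = SimConfig(seed=42, depth=500)
            simulate_junction_reads(mix, cfg, tmp_path / f"{name}.sam")
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()

    def test_read_longer_than_mrna_rejected(self, kras, tmp_path):
        gene, _, _ = kras
        mix = _mix(gene, 0.5)
        cfg = SimConfig(seed=1, depth=10, read_length=650)  # exclusion mRNA is 600
        with pytest.raises(ReadTooLongError, match="read too long"):
            simulate_junction_reads(mix, cfg, tmp_path / "a.sam")

    def test_mixture_validation(self, kras):
        gene, _, _ = kras
        with pytest.raises(ValueError, match="sum to 1"):
            IsoformMixture(gene=gene, isoforms=(((1, 2, 3), 0.7), ((1, 3), 0.7)))
        with pytest.raises(ValueError, match="strictly increasing"):
            IsoformMixture(gene=gene, isoforms=(((2, 1, 3), 1.0),))

    def test_weights_for_target_psi_invert_the_junction_formula(self, kras):
        gene, _, _ = kras
        cfg = SimConfig(seed=1, depth=1000)
        for psi in (0.15, 0.64, 0.85, 1.0):
            mix = isoform_weights_for_psi(gene, (1, 2, 3), psi, cfg)
            e = expected_junction_counts(mix, cfg)
            inc = e.get((1, 2), 0.0) + e.get((2, 3), 0.0)
            exc = e.get((1, 3), 0.0)
            got = inc / (inc + exc)
            assert got == pytest.approx(psi, abs=1e-9)


class TestAmpliconReads:
    def setup_method(self):
        self.ref = random_genome(240, seed=99)

    def test_ref_only_spectrum_has_no_indels(self):
        spec = IndelSpectrum(target=("amp", 120),
                             alleles=(IndelAllele("ref", None, 1.0),))
        cfg = SimConfig(seed=1, depth=200, error_rate=0.0)
        reads, truth = simulate_amplicon_reads(spec, self.ref, cfg)
        assert all(r == self.ref for r in reads)
        assert truth.loc[truth.kind == "ref", "count"].iloc[0] == 200

    def test_insertion_fraction_within_binomial_tolerance(self):
        spec = IndelSpectrum(
            target=("amp", 120),
            alleles=(IndelAllele("ins", "T", 0.65), IndelAllele("ref", None, 0.35)),
        )
        cfg = SimConfig(seed=5, depth=5000)
        _, truth = simulate_amplicon_reads(spec, self.ref, cfg)
        n_ins = truth.loc[truth.kind == "ins", "count"].iloc[0]
        sd = math.sqrt(5000 * 0.65 * 0.35)
        assert abs(n_ins - 0.65 * 5000) <= 3 * sd

    def test_deterministic_deletion_allele_matches_reference(self):
        cut = 120
        deleted_seq = self.ref[cut - 2 : cut]
        spec = IndelSpectrum(
            target=("amp", cut),
            alleles=(IndelAllele("del", deleted_seq, 0.999),
                     IndelAllele("ref", None, 0.001)),
        )
        cfg = SimConfig(seed=3, depth=50, error_rate=0.0)
        reads, truth = simulate_amplicon_reads(spec, self.ref, cfg)
        expected = self.ref[: cut - 2] + self.ref[cut:]
        n_del = truth.loc[truth.kind == "del", "count"].iloc[0]
        assert sum(r == expected for r in reads) == n_del

    def test_cut_too_close_to_end(self):
        spec = IndelSpectrum(target=("amp", 5),
                             alleles=(IndelAllele("ref", None, 1.0),))
        with pytest.raises(InsufficientFlankError, match="insufficient flank"):
            simulate_amplicon_reads(spec, self.ref, SimConfig(seed=1, depth=10))

    def test_spectrum_validation(self):
        with pytest.raises(ValueError, match="ref allele"):
            IndelSpectrum(target=("amp", 120),
                          alleles=(IndelAllele("ins", "T", 1.0),))
        with pytest.raises(ValueError, match="sum to 1"):
            IndelSpectrum(
                target=("amp", 120),
                alleles=(IndelAllele("ins", "T", 0.5),
                         IndelAllele("ref", None, 0.4)),
            )


class TestApplyDeletion:
    def test_single_base_deletion(self, p65):
        gene, _, _ = p65
        genome = random_genome(gene.end + 200, seed=1)
        mutated, truth = apply_deletion(gene, genome, (400, 400))
        assert len(genome) - len(mutated) == 1
        assert truth.length == 1

    def test_p65_allele_removes_exons_5_to_7(self, p65):
        gene, _, _ = p65
        genome = random_genome(gene.end + 200, seed=1)
        mutated, truth = apply_deletion(gene, genome, (400, 2667))
        assert truth.length == 2268
        assert truth.removed_exons == (5, 6, 7)
        assert len(genome) - len(mutated) == 2268

    def test_ctnnb1_allele_starts_in_intron_2_ends_in_exon_4(self, ctnnb1):
        gene, _, _ = ctnnb1
        genome = random_genome(gene.end + 200, seed=1)
        _, truth = apply_deletion(gene, genome, (160, 991))
        assert truth.length == 832
        assert truth.context5 == "intronic"
        assert truth.context3 == "exonic"

    def test_out_of_range(self, p65):
        gene, _, _ = p65
        genome = random_genome(100, seed=1)
        with pytest.raises(ValueError, match="out of range"):
            apply_deletion(gene, genome, (50, 200))


class TestGeneCounts:
    def test_zero_reduction_groups_indistinguishable(self):
        df, _ = simulate_gene_counts(5000, 0.0, 50, seed=2)
        clone = df[df.group == "clone"]["count"].to_numpy(float)
        parent = df[df.group == "parent"]["count"].to_numpy(float)
        # same generating mean: difference within 3 s.e. of zero
        se = math.sqrt(clone.var(ddof=1) / 50 + parent.var(ddof=1) / 50)
        assert abs(clone.mean() - parent.mean()) <= 3 * se

    def test_determinism_and_truth(self):
        df1, truth = simulate_gene_counts(1000, 0.47, 3, seed=9)
        df2, _ = simulate_gene_counts(1000, 0.47, 3, seed=9)
        assert df1.equals(df2)
        assert truth["reduction"] == 0.47

    def test_invalid_reduction(self):
        with pytest.raises(ValueError):
            simulate_gene_counts(1000, 1.0, 3, seed=1)


def test_random_genome_planting():
    g = random_genome(50, seed=4, plant={10: "ATG"})
    assert g[9:12] == "ATG"
    assert len(g) == 50
    assert random_genome(50, seed=4) != random_genome(50, seed=5)
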