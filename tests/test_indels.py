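import math

import pysam
import pytest
from hypothesis import given, settings, strategies as st

from exonskip.indels import (
    InsufficientDataError,
    align_reads,
    call_indels,
    classify_sgrna,
    correlate_editing_skipping,
    left_align_deletion,
    left_align_insertion,
)
from exonskip.simulate import (
    IndelAllele,
    IndelSpectrum,
    SimConfig,
    random_genome,
    simulate_amplicon_reads,
)


def amp_header(ref):
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "amplicon", "LN": len(ref)}]}
    )


def amp_read(header, name, start1, cigartuples, seq):
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = 0
    rec.reference_id = 0
    rec.reference_start = start1 - 1
    rec.mapping_quality = 60
    rec.cigartuples = cigartuples
    rec.query_sequence = seq
    return rec


class TestCallIndels:
    def test_all_reference_reads_unedited(self):
        ref = random_genome(100, seed=1)
        header = amp_header(ref)
        reads = [amp_read(header, f"r{i}", 1, [(0, 100)], ref) for i in range(5)]
        table = call_indels(reads, ref)
        assert table.edited_fraction == 0.0
        assert table.rows.empty

    def test_substitutions_never_create_indel_rows(self):
        ref = random_genome(100, seed=1)
        header = amp_header(ref)
        mutated = "G" if ref[49] != "G" else "C"
        seq = ref[:49] + mutated + ref[50:]
        table = call_indels([amp_read(header, "r", 1, [(0, 100)], seq)], ref)
        assert table.rows.empty
        assert table.edited_fraction == 0.0

    def test_homopolymer_deletion_aggregates_after_left_alignment(self):
        # the same 1-nt deletion in AAAA represented at two alignment
        # positions must collapse into a single row
        ref = "CCGT" + "AAAA" + "GTCC"  # homopolymer at positions 5-8
        header = amp_header(ref)
        seq = "CCGT" + "AAA" + "GTCC"
        r1 = amp_read(header, "r1", 1, [(0, 4), (2, 1), (0, 7)], seq)
        r2 = amp_read(header, "r2", 1, [(0, 7), (2, 1), (0, 4)], seq)
        table = call_indels([r1, r2], ref, min_frequency=0.0)
        assert len(table.rows) == 1
        row = table.rows.iloc[0]
        assert (row["position"], row["type"], row["allele"], row["count"]) == \
            (5, "del", "A", 2)

    def test_insertion_anchored_and_left_aligned(self):
        ref = "CCGA" + "TTT" + "GACC"
        header = amp_header(ref)
        # insert an extra T after the TTT run: shifts to anchor 4
        seq = "CCGA" + "TTTT" + "GACC"
        rec = amp_read(header, "r", 1, [(0, 7), (1, 1), (0, 4)], seq)
        table = call_indels([rec], ref, min_frequency=0.0)
        row = table.rows.iloc[0]
        assert (row["position"], row["type"], row["allele"]) == (4, "ins", "T")

    def test_min_frequency_filters_rows_not_edited_fraction(self):
        ref = random_genome(100, seed=2)
        header = amp_header(ref)
        reads = [amp_read(header, f"r{i}", 1, [(0, 100)], ref) for i in range(99)]
        seq = ref[:50] + ref[51:]
        reads.append(amp_read(header, "rx", 1, [(0, 50), (2, 1), (0, 49)], seq))
        table = call_indels(reads, ref, min_frequency=0.05)
        assert table.rows.empty  # 1% allele filtered from the table
        assert table.edited_fraction == pytest.approx(0.01)

    def test_frequencies_plus_reference_fraction_sum_to_one(self):
        ref = random_genome(240, seed=7)
        spec = IndelSpectrum(
            target=("amp", 120),
            alleles=(
                IndelAllele("ins", "T", 0.4),
                IndelAllele("del", 3, 0.25),
                IndelAllele("ref", None, 0.35),
            ),
        )
        cfg = SimConfig(seed=3, depth=2000, error_rate=0.0)
        _, _ = spec, cfg
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            sam = os.path.join(d, "a.sam")
            simulate_amplicon_reads(spec, ref, cfg, out_sam=sam)
            table = call_indels(sam, ref, min_frequency=0.0)
        total = table.rows.frequency.sum() + (1 - table.edited_fraction)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_spectrum_recovery_within_binomial_tolerance(self):
        ref = random_genome(240, seed=9)
        spec = IndelSpectrum(
            target=("amp", 120),
            alleles=(IndelAllele("ins", "T", 0.65),
                     IndelAllele("ref", None, 0.35)),
        )
        cfg = SimConfig(seed=17, depth=5000)
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            sam = os.path.join(d, "a.sam")
            simulate_amplicon_reads(spec, ref, cfg, out_sam=sam)
            table = call_indels(sam, ref, window=(100, 140))
        freq = table.rows[table.rows.type == "ins"].frequency.sum()
        sd = math.sqrt(0.65 * 0.35 / 5000)
        assert abs(freq - 0.65) <= 3 * sd

    def test_empty_input_flagged(self):
        table = call_indels([], "ACGT" * 10)
        assert table.n_reads == 0
        assert math.isnan(table.edited_fraction)


class TestLeftAlignment:
    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_idempotent(self, data):
        ref = data.draw(
            st.text(alphabet="ACGT", min_size=20, max_size=40), label="ref"
        )
        pos = data.draw(st.integers(2, len(ref) - 5), label="pos")
        d = data.draw(st.integers(1, 3), label="len")
        seq = ref[pos - 1 : pos - 1 + d]
        p1, s1 = left_align_deletion(pos, seq, ref)
        assert (p1, s1) == left_align_deletion(p1, s1, ref)
        ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
        a1, i1 = left_align_insertion(pos, ins, ref)
        assert (a1, i1) == left_align_insertion(a1, i1, ref)

    def test_deletion_shift_preserves_haplotype(self):
        ref = "GGCACACAT"
        # deleting CA at 5-6 shifts through the CA repeat to position 3
        pos, seq = left_align_deletion(5, "CA", ref)
        assert (pos, seq) == (3, "CA")
        assert ref[: pos - 1] + ref[pos + 1 :] == ref[:4] + ref[6:]


class TestClassify:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.65, "strong"), (0.20, "weak"), (0.05, "weak"), (0.201, "strong")],
    )
    def test_threshold_is_strict(self, fraction, expected):
        assert classify_sgrna(fraction) == expected

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            classify_sgrna(1.5)


class TestCorrelation:
    def test_monotone_pairs(self):
        pairs = [(0.1, 0.05), (0.3, 0.12), (0.5, 0.2), (0.9, 0.4)]
        rho, n = correlate_editing_skipping(pairs)
        assert rho == pytest.approx(1.0)
        assert n == 4

    def test_anti_monotone_pairs(self):
        pairs = [(0.1, 0.4), (0.5, 0.2), (0.9, 0.05)]
        rho, _ = correlate_editing_skipping(pairs)
        assert rho == pytest.approx(-1.0)

    def test_missing_pairs_dropped(self):
        pairs = [(0.1, 0.05), (0.3, None), (None, 0.2),
                 (0.5, 0.2), (0.9, 0.4)]
        rho, n = correlate_editing_skipping(pairs)
        assert n == 3
        assert rho == pytest.approx(1.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError, match="insufficient data"):
            correlate_editing_skipping([(0.1, 0.2), (0.2, 0.3)])

    def test_noisy_guide_panel(self):
        # 11 guides, skip fraction = 0.3 * edited + noise (sd 0.03)
        import numpy as np

        rng = np.random.default_rng(12)
        edited = np.linspace(0.05, 0.9, 11)
        skip = 0.3 * edited + rng.normal(0, 0.03, size=11)
        rho, n = correlate_editing_skipping(list(zip(edited, skip)))
        assert n == 11
        assert rho > 0.7


class TestNaiveAligner:
    def test_recovers_planted_indels_from_raw_reads(self):
        ref = random_genome(200, seed=5)
        cut = 100
        reads = [
            ref,  # reference read
            ref[:cut] + "T" + ref[cut:],  # +T at the cut
            ref[: cut - 2] + ref[cut:],  # -2 deletion
        ]
        records = align_reads(reads, ref)
        table = call_indels(records, ref, min_frequency=0.0)
        kinds = sorted(zip(table.rows["type"], table.rows["count"]))
        assert kinds == [("del", 1), ("ins", 1)]
        assert table.edited_fraction == pytest.approx(2 / 3)
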