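"""Read simulator: presets, coverage arithmetic, error process, codec."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from Bio import SeqIO
from hypothesis import given, settings
from hypothesis import strategies as st

from retrobench import read_sim as rs
from retrobench.family_synth import ParameterError
from retrobench.read_sim import (
    ErrorProfile,
    ReadTruth,
    encode_read_id,
    fragment_id,
    get_profile,
    parse_read_id,
    preset_profiles,
    reads_per_locus,
    simulate_reads,
    write_fastq,
    write_fastq_pair,
)


class TestPresets:
    def test_six_presets_with_expected_geometry(self):
        presets = {p.name: p for p in preset_profiles()}
        assert set(presets) == {
            "illumina76se", "illumina76pe", "illumina150se",
            "illumina150pe", "pacbio_standard", "pacbio_hifi",
        }
        assert {p.read_length for p in presets.values()} == {76, 150, 750}
        assert presets["illumina76pe"].layout == "paired_end"
        assert presets["pacbio_standard"].layout == "single_end"

    def test_hifi_total_error_is_0002(self):
        hifi = get_profile("pacbio_hifi")
        assert hifi.total_error == pytest.approx(0.002)

    def test_illumina_presets_substitution_only(self):
        for name in ("illumina76se", "illumina76pe", "illumina150se", "illumina150pe"):
            p = get_profile(name)
            assert p.ins_rate == 0.0 and p.del_rate == 0.0

    def test_profile_invariants_enforced(self):
        with pytest.raises(ParameterError):
            ErrorProfile("bad", 100, "paired_end", 0.01,
                         mean_fragment=150.0, sd_fragment=10.0)
        with pytest.raises(ParameterError):
            ErrorProfile("bad", 100, "single_end", 0.6, ins_rate=0.3, del_rate=0.2)


class TestReadsPerLocus:
    @pytest.mark.parametrize(
        "cov,cls,rl,layout,expected",
        [
            (10, "solo_ltr", 76, "single_end", 131),
            (10, "provirus", 750, "single_end", 133),
            (10, "solo_ltr", 150, "paired_end", 66),
            (10, "provirus", 76, "single_end", 1315),
        ],
    )
    def test_equalized_coverage_arithmetic(self, cov, cls, rl, layout, expected):
        assert reads_per_locus(cov, cls, rl, layout) == expected

    def test_profile_independent_for_equal_geometry(self):
        # same read length and layout -> same count, regardless of error model
        assert reads_per_locus(10, "provirus", 750, "single_end") == reads_per_locus(
            10, "provirus", 750, "single_end"
        )

    def test_coverage_equalization_across_layouts(self):
        """Total simulated bases differ only by floor-rounding remainders."""
        for cls, L in (("solo_ltr", 1000), ("provirus", 10_000)):
            for rl in (76, 150):
                se = reads_per_locus(10, cls, rl, "single_end") * rl
                pe = reads_per_locus(10, cls, rl, "paired_end") * rl
                assert abs(se - pe) < 2 * rl
                assert abs(se - 10 * L) < rl

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            reads_per_locus(0, "solo_ltr", 76, "single_end")
        with pytest.raises(ParameterError):
            reads_per_locus(10, "ltr5", 76, "single_end")


class TestTruthCodec:
    def test_round_trip_examples(self):
        truth = ReadTruth("y03", 417, "-", 2, 1009)
        assert parse_read_id(encode_read_id(truth)) == truth
        assert fragment_id(encode_read_id(truth)) == "y03|417|-|1009"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        start=st.integers(min_value=0, max_value=10**6),
        strand=st.sampled_from(["+", "-"]),
        mate=st.integers(min_value=0, max_value=2),
        serial=st.integers(min_value=0, max_value=10**6),
    )
    def test_round_trip_property(self, start, strand, mate, serial):
        truth = ReadTruth("o10", start, strand, mate, serial)
        assert parse_read_id(encode_read_id(truth)) == truth


class TestSimulateReads:
    def test_zero_error_reads_are_exact_substrings(self, toy_family):
        locus = toy_family.simulated_loci[0]
        profile = ErrorProfile("clean", 76, "single_end", 0.0)
        recs = simulate_reads(toy_family, locus, 50, profile, seed=3)
        seq = toy_family.locus_sequence(locus)
        from retrobench.family_synth import seq_to_codes, codes_to_seq

        rc = codes_to_seq((3 - seq_to_codes(seq))[::-1])
        for rec in recs:
            assert rec.sequence in seq or rec.sequence in rc
            truth = parse_read_id(rec.read_id)
            expected = seq[truth.start : truth.start + 76]
            if truth.strand == "-":
                expected = codes_to_seq((3 - seq_to_codes(expected))[::-1])
            assert rec.sequence == expected

    def test_count_and_length_contract(self, toy_family):
        locus = next(
            l for l in toy_family.simulated_loci if l.element_class == "solo_ltr"
        )
        profile = get_profile("illumina76se")
        recs = simulate_reads(toy_family, locus, 131, profile, seed=5)
        assert len(recs) == 131
        assert all(len(r.sequence) == 76 == len(r.qualities) for r in recs)

    def test_error_rate_recovery_binomial_oracle(self, toy_family):
        """Observed error events per template base match the profile's model.

        Per template base the process applies independent deletion,
        substitution (if not deleted) and insertion draws, so the event
        probability is del + ins + (1-del)*subst with variance
        p_x(1-p_x) + ins(1-ins), p_x = del + (1-del)*subst.
        """
        locus = next(
            l for l in toy_family.simulated_loci if l.element_class == "provirus"
        )
        profile = get_profile("pacbio_standard")
        recs = simulate_reads(toy_family, locus, 140, profile, seed=9)
        events = sum(r.n_errors for r in recs)
        bases = sum(r.n_template for r in recs)
        assert bases > 100_000
        d, s, i = profile.del_rate, profile.subst_rate, profile.ins_rate
        p_event = d + i + (1 - d) * s
        px = d + (1 - d) * s
        var = px * (1 - px) + i * (1 - i)
        se = np.sqrt(var / bases)
        assert abs(events / bases - p_event) < 3 * se

    def test_edit_distance_consistent_with_event_count(self, toy_family):
        """Alignment distance to the template tracks applied error events."""
        import edlib

        locus = next(
            l for l in toy_family.simulated_loci if l.element_class == "provirus"
        )
        seq = toy_family.locus_sequence(locus)
        profile = get_profile("pacbio_hifi")
        profile = replace(profile, read_length=600)
        recs = simulate_reads(toy_family, locus, 60, profile, seed=2)
        from retrobench.family_synth import codes_to_seq, seq_to_codes

        for rec in recs:
            truth = parse_read_id(rec.read_id)
            tpl = seq[truth.start : truth.start + 650]
            if truth.strand == "-":
                # minus-strand reads run leftwards from start + read_length
                window = seq[max(0, truth.start - 50) : truth.start + 600]
                tpl = codes_to_seq((3 - seq_to_codes(window))[::-1])
            d = edlib.align(rec.sequence, tpl, mode="HW")["editDistance"]
            assert d <= rec.n_errors

    def test_byte_identical_fastq_under_seed(self, toy_family, tmp_path):
        locus = toy_family.simulated_loci[1]
        profile = get_profile("illumina150se")
        for run in ("a", "b"):
            recs = simulate_reads(toy_family, locus, 40, profile, seed=21)
            write_fastq(recs, tmp_path / f"{run}.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_fastq_is_parseable_with_biopython(self, toy_family, tmp_path):
        locus = toy_family.simulated_loci[0]
        recs = simulate_reads(toy_family, locus, 10, get_profile("illumina76se"), 1)
        write_fastq(recs, tmp_path / "r.fastq")
        parsed = list(SeqIO.parse(str(tmp_path / "r.fastq"), "fastq"))
        assert len(parsed) == 10
        assert str(parsed[0].seq) == recs[0].sequence

    def test_paired_end_layout(self, toy_family, tmp_path):
        locus = next(
            l
            for l in toy_family.simulated_loci
            if l.element_class == "provirus" and l.length >= 400
        )
        profile = ErrorProfile(
            "pe", 76, "paired_end", 0.002, mean_fragment=300.0, sd_fragment=30.0
        )
        recs = simulate_reads(toy_family, locus, 60, profile, seed=4)
        assert len(recs) == 60
        mates = {parse_read_id(r.read_id).mate for r in recs}
        assert mates == {1, 2}
        frags = {fragment_id(r.read_id) for r in recs}
        assert len(frags) == 30
        write_fastq_pair(recs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        n1 = sum(1 for _ in SeqIO.parse(str(tmp_path / "r1.fq"), "fastq"))
        n2 = sum(1 for _ in SeqIO.parse(str(tmp_path / "r2.fq"), "fastq"))
        assert n1 == n2 == 30

    def test_infeasible_locus_and_preconditions(self, toy_family):
        solo = next(
            l for l in toy_family.simulated_loci if l.element_class == "solo_ltr"
        )
        with pytest.raises(rs.InfeasibleLocusError):
            simulate_reads(toy_family, solo, 5, get_profile("pacbio_hifi"), 1)
        with pytest.raises(ParameterError):
            simulate_reads(toy_family, solo, -1, get_profile("illumina76se"), 1)
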