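import numpy as np
import pytest

from ampliskip.classify import ReadCall, classify_reads
from ampliskip.phasing import (
    PhasedCounts,
    allele_balance,
    allele_skip_direct,
    allele_skip_indirect,
    genotype_calls,
    genotype_read,
    mask_structural_phase,
    overall_fractions,
    quantify,
)
from ampliskip.synthetic_data import AlleleSpec, ErrorModel, SequencedRead, simulate_sample
from ampliskip.pipeline import format_pct

from conftest import patient1_alleles


def pct(x: float) -> float:
    return round(100 * x, 1)


# --- contingency tables transcribed from the published per-patient counts ---

PATIENT1 = PhasedCounts(
    {
        "splice_allele": {"skip56": 128, "full": 22},
        "trans_allele": {"full": 262},
    }
)
PATIENT3 = PhasedCounts(
    {
        "unphased": {"skip56": 938, "skip6": 52},
        "splice_allele": {"full": 132},
        "trans_allele": {"full": 1273},
    }
)
PATIENT2 = PhasedCounts({"unphased": {"skip56": 692, "skip6": 90, "full": 519}})
PATIENT4 = PhasedCounts({"unphased": {"skip56": 6511, "full": 854}})
PATIENT7 = PhasedCounts({"unphased": {"skip56": 286, "full": 233}})


class TestQuantify:
    def test_patient2_overall_fractions(self):
        counts, fracs = quantify(PATIENT2)
        assert counts.n_total == 1301
        assert pct(fracs["fraction_skip56"]) == 53.2
        assert pct(fracs["fraction_skip6"]) == 6.9

    def test_patient4_homozygote_fraction(self):
        _, fracs = quantify(PATIENT4)
        assert pct(fracs["fraction_skip56"]) == 88.4

    def test_patient3_both_skip_fractions(self):
        _, fracs = quantify(PATIENT3)
        assert pct(fracs["fraction_skip56"]) == 39.2
        assert pct(fracs["fraction_skip6"]) == 2.2

    def test_only_full_reads_gives_zero_fractions(self):
        _, fracs = quantify(PhasedCounts({"unphased": {"full": 10}}))
        assert fracs["fraction_skip56"] == 0 and fracs["fraction_skip6"] == 0

    def test_known_denominator_excludes_other(self):
        counts = PhasedCounts({"unphased": {"skip56": 30, "full": 50, "other": 20}})
        assert overall_fractions(counts, "all")["fraction_skip56"] == 0.30
        assert overall_fractions(counts, "known")["fraction_skip56"] == pytest.approx(0.375)

    def test_conservation_of_calls(self):
        calls = [
            ReadCall(f"r{i}", iso, {}, 1, allele)
            for i, (iso, allele) in enumerate(
                [("full", "splice_allele"), ("skip56", "unphased"), ("other", "unphased")] * 7
            )
        ]
        counts = PhasedCounts.from_calls(calls)
        assert counts.n_total == len(calls)


class TestDirectEstimate:
    def test_patient1_splice_allele(self):
        est = allele_skip_direct(PATIENT1, "splice_allele")
        assert est.method == "direct"
        assert est.n_support == 150
        assert pct(est.fraction_skip56) == 85.3

    def test_patient1_trans_allele_shows_no_skipping(self):
        est = allele_skip_direct(PATIENT1, "trans_allele")
        assert est.fraction_skip56 == 0 and est.fraction_skip6 == 0

    def test_empty_row_flagged_undefined(self):
        est = allele_skip_direct(PhasedCounts({}), "splice_allele")
        assert not est.defined
        assert est.fraction_skip56 is None and est.warnings


class TestIndirectEstimate:
    def test_patient3_worked_example(self):
        # S = 938 + 52 skipped reads, I = 132 phased splice-allele inclusions
        est = allele_skip_indirect(PATIENT3)
        assert est.method == "indirect"
        assert est.n_support == 938 + 52 + 132
        assert est.fraction_skipped == pytest.approx(990 / 1122)
        assert pct(est.fraction_skipped) == 88.2
        assert est.assumptions  # attribution assumption is surfaced

    def test_no_skipped_reads_gives_zero(self):
        est = allele_skip_indirect(PhasedCounts({"splice_allele": {"full": 40}}))
        assert est.fraction_skipped == 0

    def test_no_inclusion_reads_gives_one_with_warning(self):
        est = allele_skip_indirect(PhasedCounts({"unphased": {"skip56": 40}}))
        assert est.fraction_skipped == 1.0
        assert est.warnings

    def test_empty_table_flagged_undefined(self):
        est = allele_skip_indirect(PhasedCounts({}))
        assert not est.defined


class TestAlleleBalance:
    def test_patient1_balance(self):
        balance = allele_balance(PATIENT1)
        assert pct(balance["trans_allele"]) == 63.6
        assert pct(balance["splice_allele"]) == 36.4

    def test_patient3_inclusion_read_share(self):
        # 132 of 1405 phased (inclusion) reads arise from the splice allele
        balance = allele_balance(PATIENT3)
        assert pct(balance["splice_allele"]) == 9.4

    def test_single_allele_only(self):
        balance = allele_balance(PhasedCounts({"trans_allele": {"full": 7}}))
        assert balance["trans_allele"] == 1.0

    def test_no_phased_reads_is_an_error(self):
        with pytest.raises(ValueError):
            allele_balance(PhasedCounts({"unphased": {"skip56": 5}}))


class TestGenotypeRead:
    def test_error_free_reads_phase_to_planted_base(self, model, isoforms, snv823):
        em = ErrorModel(sub_rate=0, ins_rate=0, del_rate=0)
        reads, truth = simulate_sample(
            model, isoforms, patient1_alleles(), 300, em, snvs=[snv823], seed=5
        )
        calls = classify_reads(reads, isoforms)
        calls = genotype_calls(reads, calls, snv823, isoforms, model)
        for call, true_allele in zip(calls, truth.true_allele):
            assert call.allele == true_allele
            assert call.phase_reason == "direct"

    def test_snv_inside_skipped_exon_is_structurally_unphasable(
        self, model, isoforms, snv467
    ):
        skip56 = isoforms[1]
        read = SequencedRead("r", skip56.sequence, (14,) * len(skip56.sequence))
        call = classify_reads([read], isoforms)[0]
        out = genotype_read(read, call, snv467, isoforms, model)
        assert out.allele == "unphased" and out.phase_reason == "structural"

    def test_deletion_spanning_snv_site_is_unphased(self, model, isoforms, snv823):
        full = isoforms[0]
        off = snv823.amplicon_offset
        # drop a 7 nt window centred on the site so the gap must span it
        seq = full.sequence[: off - 3] + full.sequence[off + 4:]
        read = SequencedRead("r", seq, (14,) * len(seq))
        call = classify_reads([read], isoforms)[0]
        out = genotype_read(read, call, snv823, isoforms, model)
        assert out.allele == "unphased"

    def test_third_base_is_unphased(self, model, isoforms, snv823):
        full = isoforms[0]
        off = snv823.amplicon_offset
        third = next(b for b in "ACGT" if b not in (snv823.ref_base, snv823.alt_base))
        seq = full.sequence[:off] + third + full.sequence[off + 1:]
        read = SequencedRead("r", seq, (14,) * len(seq))
        call = classify_reads([read], isoforms)[0]
        out = genotype_read(read, call, snv823, isoforms, model)
        assert out.allele == "unphased" and out.phase_reason == "third_base"

    def test_low_quality_base_at_site_is_gated(self, model, isoforms, snv823):
        full = isoforms[0]
        off = snv823.amplicon_offset
        seq = full.sequence[:off] + snv823.splice_allele_base + full.sequence[off + 1:]
        quals = [14] * len(seq)
        quals[off] = 3
        read = SequencedRead("r", seq, tuple(quals))
        call = classify_reads([read], isoforms)[0]
        gated = genotype_read(read, call, snv823, isoforms, model)
        assert gated.phase_reason == "low_quality"
        ungated = genotype_read(
            read, call, snv823, isoforms, model, min_base_quality=0
        )
        assert ungated.allele == "splice_allele"

    def test_other_reads_are_not_genotyped(self, model, isoforms, snv823):
        call = ReadCall("r", "other", {}, 0)
        read = SequencedRead("r", "ACGT", (14,) * 4)
        out = genotype_read(read, call, snv823, isoforms, model)
        assert out.allele == "unphased" and out.phase_reason == "no_call"


class TestEstimatorConsistency:
    def test_parameter_recovery_within_three_binomial_sd(self, patient1_phased_20k):
        _, calls, _ = patient1_phased_20k
        counts = PhasedCounts.from_calls(calls)
        est = allele_skip_direct(counts, "splice_allele")
        p = 0.853
        sd = np.sqrt(p * (1 - p) / est.n_support)
        assert abs(est.fraction_skip56 - p) <= 3 * sd

    def test_indirect_matches_direct_after_masking(self, patient1_phased_20k):
        # masking phased skipped reads emulates an SNV inside the skipped exons
        _, calls, _ = patient1_phased_20k
        counts = PhasedCounts.from_calls(calls)
        direct = allele_skip_direct(counts, "splice_allele")
        masked = mask_structural_phase(counts)
        indirect = allele_skip_indirect(masked)
        assert abs(indirect.fraction_skipped - direct.fraction_skipped) <= 0.02


class TestFormatting:
    @pytest.mark.parametrize(
        "fraction, rendered",
        [(0.8843, "88.4%"), (0.364, "36.4%"), (0.8525, "85.3%"), (0.0, "0.0%")],
    )
    def test_percentages_render_half_up_one_decimal(self, fraction, rendered):
        assert format_pct(fraction) == rendered


class TestVcfExport:
    def test_vcf_stub_parses_with_cyvcf2(self, model, snv823, tmp_path):
        from cyvcf2 import VCF

        from ampliskip.phasing import write_snv_vcf

        path = tmp_path / "snv.vcf"
        write_snv_vcf(snv823, model, path)
        records = list(VCF(str(path)))
        assert len(records) == 1
        rec = records[0]
        assert rec.CHROM == model.name
        assert rec.POS == snv823.amplicon_offset + 1
        assert rec.REF == "C" and rec.ALT == ["T"]
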