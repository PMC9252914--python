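import dataclasses

import pytest
from hypothesis import given, strategies as st

from clonevo.errors import ConfigurationError, FormatError, ValidationError
from clonevo.variant_io import (
    Effect,
    PatientCase,
    Timepoint,
    VariantRecord,
    correct_af_for_purity,
    match_variants,
    normalize_variant,
    partition_somatic_constitutional,
    read_cna_bed,
    read_variant_table,
    write_cna_bed,
    write_variant_table,
)


def make_record(**kw):
    base = dict(
        chrom="chr1", pos=100, ref="A", alt="T", alt_count=45, depth=100,
        effect=Effect.missense, gene="JAK2", coding=True, timepoint=Timepoint.INI,
    )
    base.update(kw)
    return VariantRecord(**base)


class TestVariantRecord:
    def test_af_from_counts(self):
        assert make_record(alt_count=45, depth=100).af == pytest.approx(0.45)

    def test_zero_depth_af(self):
        assert make_record(alt_count=0, depth=0).af == 0.0

    @pytest.mark.parametrize(
        "kw",
        [
            dict(pos=0),
            dict(alt_count=101),
            dict(alt_count=-1),
            dict(ref="T", alt="T"),
            dict(ref="a"),
            dict(alt="N"),
        ],
    )
    def test_invariant_violations(self, kw):
        with pytest.raises(ValidationError):
            make_record(**kw)


class TestTsvRoundTrip:
    def test_example_row(self, tmp_path):
        path = tmp_path / "v.tsv"
        write_variant_table([make_record()], path, patient_id="P1")
        (rec,) = read_variant_table(path, dialect="tsv")
        assert rec.af == pytest.approx(0.45)
        assert rec.gene == "JAK2"
        assert rec.timepoint is Timepoint.INI

    def test_round_trip_identity(self, tmp_path, small_sim):
        # identity oracle: writer -> reader reproduces all fields exactly
        _, sim = small_sim
        records = [
            r for tp in Timepoint for r in sim["cases"][0].timepoint(tp)
        ][:50]
        path = tmp_path / "rt.tsv"
        write_variant_table(records, path, patient_id="P01")
        back = read_variant_table(path, dialect="tsv")
        assert back == records

    def test_double_round_trip_bit_identical(self, tmp_path, small_sim):
        _, sim = small_sim
        records = sim["cases"][1].timepoint(Timepoint.INI)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_variant_table(records, p1, patient_id="X")
        write_variant_table(read_variant_table(p1), p2, patient_id="X")
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\n1\t2\n")
        with pytest.raises(FormatError):
            read_variant_table(path)

    def test_zero_depth_nonzero_alt_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        header = "chrom\tpos\tref\talt\talt_count\tdepth\teffect\tgene\tcoding\ttimepoint\tpatient_id"
        path.write_text(header + "\nchr1\t5\tA\tT\t3\t0\tother\t\t1\tINI\tP1\n")
        with pytest.raises(ValidationError):
            read_variant_table(path)

    def test_missing_file_is_configuration_error(self, tmp_path):
        with pytest.raises(ConfigurationError):
            read_variant_table(tmp_path / "nope.tsv")


class TestVcf:
    def test_ad_parsing_and_multiallelic_split(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=EFFECT,Number=1,Type=String,Description="effect">\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            '##INFO=<ID=TIMEPOINT,Number=1,Type=String,Description="tp">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="depths">\n'
            "##contig=<ID=chr9>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr9\t5073770\trs1\tG\tT\t.\t.\tEFFECT=missense;GENE=JAK2;TIMEPOINT=INI\tAD\t60,40\n"
            "chr9\t600\t.\tA\tC,G\t.\t.\tEFFECT=other;TIMEPOINT=REL\tAD\t50,30,20\n"
        )
        records = read_variant_table(vcf, dialect="vcf")
        assert len(records) == 3
        assert records[0].af == pytest.approx(0.40)
        assert records[0].gene == "JAK2"
        multi = [r for r in records if r.pos == 600]
        assert {r.alt for r in multi} == {"C", "G"}
        assert all(r.depth == 100 for r in multi)
        assert sorted(r.af for r in multi) == pytest.approx([0.2, 0.3])

    def test_missing_ad_is_format_error(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t10\t.\tA\tT\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(FormatError):
            read_variant_table(vcf, dialect="vcf")


class TestPartitionSomaticConstitutional:
    def _case(self, ini, rem):
        return PatientCase(
            patient_id="P",
            variants={Timepoint.INI: ini, Timepoint.REM: rem, Timepoint.REL: []},
        )

    def test_high_rem_af_is_constitutional(self):
        v = make_record()
        rem = make_record(alt_count=48, depth=100, timepoint=Timepoint.REM)
        out = partition_somatic_constitutional(self._case([v], [rem]))
        assert out["constitutional"] == [v]
        assert not out["somatic_INI"]

    def test_absent_in_remission_is_somatic(self):
        v = make_record()
        rem = make_record(alt_count=0, depth=80, timepoint=Timepoint.REM)
        out = partition_somatic_constitutional(self._case([v], [rem]))
        assert out["somatic_INI"] == [v]

    def test_shallow_remission_is_unevaluable(self):
        v = make_record()
        rem = make_record(alt_count=0, depth=5, timepoint=Timepoint.REM)
        out = partition_somatic_constitutional(self._case([v], [rem]))
        assert out["unevaluable"] == [v]

    def test_missing_rem_timepoint_is_configuration_error(self):
        case = PatientCase(patient_id="P", variants={Timepoint.INI: [make_record()]})
        with pytest.raises(ConfigurationError):
            partition_somatic_constitutional(case)

    def test_partition_exhaustive_on_simulated_cases(self, small_sim):
        _, sim = small_sim
        for case in sim["cases"]:
            out = partition_somatic_constitutional(case)
            n_in = sum(
                1
                for tp in (Timepoint.INI, Timepoint.REL)
                for v in case.timepoint(tp)
                if v.alt_count > 0
            )
            n_out = sum(len(bucket) for bucket in out.values())
            assert n_out == n_in

    def test_simulated_labels_recovered(self, small_sim):
        # simulator ground truth: germline vs somatic recovered at depth 100
        _, sim = small_sim
        for case, truth in zip(sim["cases"], sim["truths"]):
            out = partition_somatic_constitutional(case)
            detected = {
                v.key
                for tp in (Timepoint.INI, Timepoint.REL)
                for v in case.timepoint(tp)
                if v.alt_count > 0
            }
            const_keys = {v.key for v in out["constitutional"]}
            somatic_keys = {v.key for v in out["somatic_INI"] + out["somatic_REL"]}
            assert const_keys == detected & truth.germline_keys
            assert somatic_keys == detected - truth.germline_keys


class TestPurityCorrection:
    def test_triggered(self):
        v = correct_af_for_purity(make_record(alt_count=15, depth=100), 0.30)
        assert v.af_adjusted == pytest.approx(0.50)
        assert v.corrected

    def test_not_triggered_above_threshold(self):
        v = make_record(alt_count=45, depth=100)
        assert correct_af_for_purity(v, 0.95) is v

    def test_capped_at_one(self):
        v = correct_af_for_purity(make_record(alt_count=90, depth=100), 0.50)
        assert v.af_adjusted == 1.0

    def test_invalid_blast_fraction(self):
        with pytest.raises(ValidationError):
            correct_af_for_purity(make_record(), 0.0)

    @given(
        alt=st.integers(0, 100),
        blast=st.floats(0.05, 0.79),
    )
    def test_idempotent(self, alt, blast):
        v = make_record(alt_count=alt, depth=100)
        once = correct_af_for_purity(v, blast)
        twice = correct_af_for_purity(once, blast)
        assert once == twice

    def test_preserves_other_fields(self):
        v = make_record(alt_count=10, depth=100)
        c = correct_af_for_purity(v, 0.4)
        assert dataclasses.replace(c, af_adjusted=None, corrected=False) == v


class TestMatchVariants:
    def test_identical_lists_all_shared(self):
        a = [make_record(pos=p) for p in (1, 2, 3)]
        out = match_variants(a, list(a))
        assert len(out["shared"]) == 3
        assert not out["only_a"] and not out["only_b"]

    def test_disjoint_lists(self):
        a = [make_record(pos=1)]
        b = [make_record(pos=2)]
        out = match_variants(a, b)
        assert not out["shared"]
        assert len(out["only_a"]) == len(out["only_b"]) == 1

    def test_duplicate_key_names_offender(self):
        a = [make_record(pos=7), make_record(pos=7)]
        with pytest.raises(ValidationError, match="7"):
            match_variants(a, [])

    def test_simulated_overlap_bucket_sizes(self, rng):
        # simulator ground truth: 500 variants, planted 30% overlap
        shared_n, a_only_n, b_only_n = 150, 175, 175
        positions = rng.choice(100_000, size=shared_n + a_only_n + b_only_n, replace=False) + 1
        recs = [make_record(pos=int(p)) for p in positions]
        a = recs[: shared_n + a_only_n]
        b = recs[:shared_n] + recs[shared_n + a_only_n :]
        out = match_variants(a, b)
        assert len(out["shared"]) == shared_n
        assert len(out["only_a"]) == a_only_n
        assert len(out["only_b"]) == b_only_n

    def test_every_variant_in_exactly_one_bucket(self, small_sim):
        _, sim = small_sim
        case = sim["cases"][0]
        a = case.timepoint(Timepoint.INI)
        b = case.timepoint(Timepoint.REL)
        out = match_variants(a, b)
        keys = (
            set(out["shared"]) | set(out["only_a"]) | set(out["only_b"])
        )
        assert keys == {v.key for v in a} | {v.key for v in b}
        assert len(out["shared"]) + len(out["only_a"]) == len(a)
        assert len(out["shared"]) + len(out["only_b"]) == len(b)


class TestNormalizeVariant:
    def test_snv_unchanged(self):
        v = make_record()
        assert normalize_variant(v) is v

    def test_suffix_trim(self):
        v = make_record(ref="AT", alt="CT")
        n = normalize_variant(v)
        assert (n.ref, n.alt, n.pos) == ("A", "C", v.pos)

    def test_prefix_trim_advances_pos(self):
        v = make_record(ref="AC", alt="AG", pos=10)
        n = normalize_variant(v)
        assert (n.ref, n.alt, n.pos) == ("C", "G", 11)

    def test_left_align_with_genome(self):
        #        123456789
        genome = {"chr1": "GGGCACACT"}
        # deletion of "AC" reported at pos 5 (ref ACA alt A after trim is ambiguous)
        v = make_record(chrom="chr1", pos=5, ref="ACA", alt="A")
        n = normalize_variant(v, genome)
        assert len(n.ref) - len(n.alt) == 2
        # left-aligned representation starts at the first C of the CACAC tract
        assert n.pos <= v.pos


class TestCnaBed:
    def test_round_trip(self, tmp_path, small_sim):
        _, sim = small_sim
        segs = sim["cases"][0].cna_profiles[Timepoint.INI]
        path = tmp_path / "cna.bed"
        write_cna_bed(segs, path)
        assert read_cna_bed(path) == segs

    def test_bad_state_rejected(self, tmp_path):
        path = tmp_path / "cna.bed"
        path.write_text("chr1\t0\t100\tamplification\n")
        with pytest.raises(ValidationError):
            read_cna_bed(path)
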