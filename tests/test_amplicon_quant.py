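import math

import pytest
from hypothesis import given, settings, strategies as st

from crispredit.amplicon_quant import (
    MergedAmplicon,
    OutcomeClass,
    UniqueAmplicon,
    approx_find,
    classify_amplicon,
    deduplicate,
    detection_limit,
    extract_umi,
    match_and_trim_flanks,
    merge_pair,
    quality_filter,
    run_pipeline,
    summarize,
    umi_capacity,
)
from crispredit.repair_design import PTS_SEQUENCE
from crispredit.seqio import QualifiedRead, reverse_complement
from crispredit.simdata import simulate_locus


def q(seq, score=35):
    return QualifiedRead("r", seq, (score,) * len(seq))


@pytest.fixture(scope="module")
def amplicon300():
    return simulate_locus(300, seed=9, ensure_guide=False).locus.seq


def edit_distance_oracle(a, b):
    """Plain Wagner-Fischer, for cross-checking approx_find."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestMergePair:
    def test_exact_overlap_reconstruction(self, amplicon300):
        r1 = q(amplicon300[:180])
        r2 = q(reverse_complement(amplicon300[-180:]))
        merged = merge_pair(r1, r2)
        assert merged is not None
        assert merged.seq == amplicon300

    def test_disagreement_resolves_to_higher_quality(self, amplicon300):
        r1_seq = amplicon300[:180]
        mism_pos = 150  # inside the overlap [120, 180)
        altered = r1_seq[:mism_pos] + ("A" if r1_seq[mism_pos] != "A" else "C") \
            + r1_seq[mism_pos + 1:]
        r1 = QualifiedRead("r", altered, (35,) * len(altered))
        r2 = q(reverse_complement(amplicon300[-180:]), score=20)
        merged = merge_pair(r1, r2)
        assert merged is not None
        assert merged.seq[mism_pos] == altered[mism_pos]  # r1 base, Q35 > Q20
        assert merged.quals[mism_pos] == 35  # max of the two

    def test_no_overlap_rejected(self):
        r1 = q("A" * 50)
        r2 = q("C" * 50)
        assert merge_pair(r1, r2) is None

    def test_min_overlap_enforced(self, amplicon300):
        r1 = q(amplicon300[:150])
        r2 = q(reverse_complement(amplicon300[140:290]))  # only 10 nt shared
        assert merge_pair(r1, r2, min_overlap=20) is None

    def test_mismatch_fraction_limit(self, amplicon300):
        r1 = q(amplicon300[:180])
        tail = amplicon300[-180:]
        # corrupt a third of the 60-nt overlap region
        region = list(tail[:60])
        for i in range(0, 60, 3):
            region[i] = "A" if region[i] != "A" else "C"
        corrupted = "".join(region) + tail[60:]
        r2 = q(reverse_complement(corrupted))
        assert merge_pair(r1, r2, max_mismatch_frac=0.1) is None

    def test_seed_error_falls_back_to_scan(self, amplicon300):
        # error in the first 16 bases of rc(r2) defeats the seed index
        r1 = q(amplicon300[:180])
        tail = amplicon300[-180:]
        corrupted = ("A" if tail[2] != "A" else "C") .join([tail[:2], tail[3:]])
        r2 = q(reverse_complement(corrupted))
        merged = merge_pair(r1, r2)
        assert merged is not None
        assert len(merged.seq) == 300


class TestQualityFilter:
    def test_all_q30_passes(self):
        assert quality_filter(MergedAmplicon("ACGT", (30, 30, 30, 30)))

    def test_one_base_q29_fails(self):
        quals = (35,) * 448 + (29,)
        assert not quality_filter(MergedAmplicon("A" * 449, quals))

    def test_fractional_threshold(self):
        quals = (2,) * 5 + (35,) * 95
        amp = MergedAmplicon("A" * 100, quals)
        assert quality_filter(amp, min_q=30, min_fraction=0.9)
        assert not quality_filter(amp, min_q=30, min_fraction=1.0)


class TestExtractUmi:
    def test_basic(self):
        amp = MergedAmplicon("ACGTACTTTT", (30,) * 10)
        out = extract_umi(amp, k=6)
        assert out.umi == "ACGTAC"
        assert out.seq == "TTTT"
        assert len(out.quals) == 4

    def test_too_short_rejected(self):
        assert extract_umi(MergedAmplicon("ACGTA", (30,) * 5), k=6) is None

    def test_umi_space(self):
        assert umi_capacity(6) == 4096

    def test_offset(self):
        amp = MergedAmplicon("TTACGTACGG", (30,) * 10)
        out = extract_umi(amp, k=6, offset=2)
        assert out.umi == "ACGTAC"
        assert out.seq == "TTGG"


class TestApproxFind:
    def test_exact_substring(self):
        dist, start, end = approx_find("CASA"[:3], "ABCASA"[:5])
        assert dist == 0

    def test_matches_edit_distance_oracle(self):
        pattern = "ACGTACGTAC"
        text = "TTTTACGTTCGTACTTTT"
        dist, start, end = approx_find(pattern, text)
        best = min(
            edit_distance_oracle(pattern, text[i:j])
            for i in range(len(text)) for j in range(i, len(text) + 1)
        )
        assert dist == best
        assert edit_distance_oracle(pattern, text[start:end]) == dist

    @given(st.text(alphabet="ACGT", min_size=4, max_size=10),
           st.text(alphabet="ACGT", min_size=1, max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_infix_distance_property(self, pattern, text):
        dist, start, end = approx_find(pattern, text)
        best = min(
            edit_distance_oracle(pattern, text[i:j])
            for i in range(len(text) + 1) for j in range(i, len(text) + 1)
        )
        assert dist == best
        assert edit_distance_oracle(pattern, text[start:end]) == dist


@pytest.fixture(scope="module")
def parts(amplicon300):
    return amplicon300[:50], amplicon300[50:250], amplicon300[250:]


class TestMatchAndTrimFlanks:

    def test_exact_flanks_accepted(self, parts):
        flank5, insert, flank3 = parts
        trimmed = match_and_trim_flanks(flank5 + insert + flank3, flank5, flank3)
        assert trimmed == flank5 + insert + flank3

    def test_extra_primer_tails_trimmed(self, parts):
        flank5, insert, flank3 = parts
        read = "GGGGGG" + flank5 + insert + flank3 + "AAAAAA"
        trimmed = match_and_trim_flanks(read, flank5, flank3)
        assert trimmed == flank5 + insert + flank3

    @pytest.mark.parametrize("n_subs,accepted", [(5, True), (6, False)])
    def test_error_rate_boundary(self, parts, n_subs, accepted):
        flank5, insert, flank3 = parts
        mutated = list(flank5)
        for i in range(0, n_subs * 8, 8):
            mutated[i] = "A" if mutated[i] != "A" else "C"
        read = "".join(mutated) + insert + flank3
        result = match_and_trim_flanks(read, flank5, flank3,
                                       max_error_rate=0.1)
        assert (result is not None) is accepted

    def test_missing_flank3_rejected(self, parts):
        flank5, insert, _ = parts
        read = flank5 + insert + "G" * 50
        assert match_and_trim_flanks(read, flank5, "C" * 50) is None

    def test_interior_indel_kept(self, parts):
        flank5, insert, flank3 = parts
        read = flank5 + insert[:90] + insert[95:] + flank3
        trimmed = match_and_trim_flanks(read, flank5, flank3)
        assert trimmed == read


class TestDeduplicate:
    def test_spec_example(self):
        records = [("U1", "S1")] * 3 + [("U2", "S1")] + [("U1", "S2")]
        bins = deduplicate(records)
        assert sorted(b.duplicate_count for b in bins) == [1, 1, 3]
        assert len(bins) == 3

    def test_all_distinct_identity(self):
        records = [(f"U{i}", "S") for i in range(10)]
        assert all(b.duplicate_count == 1 for b in deduplicate(records))

    @given(st.lists(st.tuples(st.text(alphabet="ACGT", min_size=2, max_size=2),
                              st.text(alphabet="ACGT", min_size=1, max_size=4)),
                    min_size=1, max_size=50))
    def test_pigeonhole_and_conservation(self, records):
        bins = deduplicate(records)
        assert len(bins) <= len(records)
        assert sum(b.duplicate_count for b in bins) == len(records)

    def test_requires_umi(self):
        with pytest.raises(ValueError):
            deduplicate([MergedAmplicon("ACGT", (30,) * 4)])


@pytest.fixture(scope="module")
def ref(amplicon300):
    return amplicon300


class TestClassifyAmplicon:

    def test_exact(self, ref):
        assert classify_amplicon(ref, ref) is OutcomeClass.EXACT_REF

    def test_templated_insertion(self, ref):
        edited = ref[:150] + PTS_SEQUENCE + ref[150:]
        assert classify_amplicon(edited, ref) is OutcomeClass.TEMPLATED_PTS

    def test_templated_with_mutations_still_templated(self, ref):
        damaged_pts = "TTTATTTAATTAAATATA"  # 1 edit from the cassette
        edited = ref[:150] + damaged_pts + ref[150:]
        assert classify_amplicon(edited, ref) is OutcomeClass.TEMPLATED_PTS
        assert classify_amplicon(edited, ref, pts_max_mismatch=0) \
            is OutcomeClass.INDEL

    def test_deletion_is_indel(self, ref):
        assert classify_amplicon(ref[:150] + ref[154:], ref) is OutcomeClass.INDEL

    def test_substitution_is_snp(self, ref):
        snp = ref[:77] + ("A" if ref[77] != "A" else "C") + ref[78:]
        assert classify_amplicon(snp, ref) is OutcomeClass.SNP

    def test_one_bp_insertion_ambiguous(self, ref):
        assert classify_amplicon(ref[:150] + "A" + ref[150:], ref) \
            is OutcomeClass.AMBIGUOUS_1BP

    def test_strict_mode_equals_substring_search(self, ref):
        for seq in (ref, ref[:150] + PTS_SEQUENCE + ref[150:],
                    ref[:150] + PTS_SEQUENCE[:-1] + "G" + ref[150:]):
            strict = classify_amplicon(seq, ref, pts_max_mismatch=0)
            assert (strict is OutcomeClass.TEMPLATED_PTS) == (PTS_SEQUENCE in seq)


class TestSummarize:
    @staticmethod
    def _bins(counts):
        out = []
        i = 0
        for cls, n in counts.items():
            for _ in range(n):
                out.append((UniqueAmplicon(f"U{i}", f"S{i}", 1), cls))
                i += 1
        return out

    def test_spec_arithmetic(self):
        bins = self._bins({OutcomeClass.TEMPLATED_PTS: 15, OutcomeClass.INDEL: 1,
                           OutcomeClass.SNP: 4, OutcomeClass.EXACT_REF: 980})
        summary = summarize(bins)
        assert summary.templated_pct == pytest.approx(1.5)
        assert summary.indel_pct == pytest.approx(0.1)
        assert summary.total == 1000

    def test_counts_sum_to_total(self):
        bins = self._bins({OutcomeClass.TEMPLATED_PTS: 3, OutcomeClass.SNP: 2,
                           OutcomeClass.EXACT_REF: 5})
        summary = summarize(bins)
        assert sum(summary.counts.values()) == summary.total == 10

    def test_single_exact_read(self):
        summary = summarize(self._bins({OutcomeClass.EXACT_REF: 1}))
        assert summary.templated_pct == summary.indel_pct == summary.snp_pct == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_lod_value(self):
        assert summarize(self._bins({OutcomeClass.EXACT_REF: 1}),
                         umi_len=6).limit_of_detection_pct \
            == pytest.approx(0.0244140625)


class TestDetectionLimit:
    def test_six(self):
        assert detection_limit(6) == pytest.approx(100 / 4 ** 6)
        assert round(detection_limit(6), 2) == 0.02

    def test_one(self):
        assert detection_limit(1) == 25.0

    def test_monotone_decreasing(self):
        values = [detection_limit(k) for k in range(1, 10)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid(self):
        with pytest.raises(ValueError):
            detection_limit(0)


class TestPipelineConservation:
    def test_every_pair_accounted(self, sim_reference):
        from crispredit.simdata import AmpliconSimSpec, simulate_amplicon_run

        spec = AmpliconSimSpec(reference=sim_reference, templated_frac=0.1,
                               indel_frac=0.05, n_molecules=300,
                               dup_mean=2.0, seed=21)
        run = simulate_amplicon_run(spec)
        result = run_pipeline(list(zip(run.r1, run.r2)), sim_reference)
        assert result.conservation_holds()
        assert sum(result.summary.counts.values()) == result.summary.total
        pct_sum = sum(100.0 * v / result.summary.total
                      for v in result.summary.counts.values())
        assert pct_sum == pytest.approx(100.0)
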