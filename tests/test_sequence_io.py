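"""Trimming, collapsing, RPM normalization and the contaminant screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dorna import sequence_io as sio
from dorna.references import DEFAULT_ADAPTER3, contaminant_records

INSERT = "GACTCTTAGCGG"


def make_read(insert, adapter=DEFAULT_ADAPTER3, rid="r1"):
    return sio.Read(rid, insert + adapter)


class TestTrimAdapter:
    def test_full_adapter_recovers_insert(self):
        res = sio.trim_adapter(make_read(INSERT))
        assert res.accepted and res.insert.sequence == INSERT

    def test_partial_adapter_at_read_end(self):
        # only 10 adapter bases sequenced: seed (8 nt) still present
        read = sio.Read("r", INSERT + DEFAULT_ADAPTER3[:10])
        res = sio.trim_adapter(read)
        assert res.accepted and res.insert.sequence == INSERT

    def test_adapter_only_read_rejected_as_out_of_window(self):
        res = sio.trim_adapter(sio.Read("r", DEFAULT_ADAPTER3))
        assert not res.accepted and res.reason == "length_out_of_window"

    def test_31nt_insert_rejected(self):
        res = sio.trim_adapter(make_read("A" * 31))
        assert res.reason == "length_out_of_window"

    def test_no_adapter_rejected(self):
        res = sio.trim_adapter(sio.Read("r", "ACGT" * 7))
        assert res.reason == "no_adapter"

    def test_single_n_kept_two_rejected(self):
        assert sio.trim_adapter(make_read("GACTCTTAGCNG")).accepted
        assert sio.trim_adapter(make_read("GACTCTTAGNNG")).reason == "too_many_N"

    def test_mismatch_in_adapter_tail_tolerated(self):
        adapter = DEFAULT_ADAPTER3[:12] + "A" + DEFAULT_ADAPTER3[13:]  # 1/21 < 0.1
        res = sio.trim_adapter(sio.Read("r", INSERT + adapter))
        assert res.accepted and res.insert.sequence == INSERT

    def test_leftmost_seed_wins(self):
        seq = "AAGGTTCCAAGG" + DEFAULT_ADAPTER3 + "CCC" + DEFAULT_ADAPTER3
        res = sio.trim_adapter(sio.Read("r", seq))
        assert res.insert.sequence == "AAGGTTCCAAGG"

    def test_quality_sliced_with_insert(self):
        read = sio.Read("r", INSERT + DEFAULT_ADAPTER3, "I" * 12 + "#" * len(DEFAULT_ADAPTER3))
        res = sio.trim_adapter(read)
        assert res.insert.quality == "I" * 12

    def test_trimming_never_lengthens(self):
        # already-trimmed insert with no adapter: rejected, never shortened
        res = sio.trim_adapter(sio.Read("r", INSERT))
        assert not res.accepted and res.reason == "no_adapter"

    def test_empty_read_is_input_error(self):
        with pytest.raises(sio.InputError):
            sio.Read("r", "")

    def test_adapter_shorter_than_overlap_is_config_error(self):
        with pytest.raises(sio.ConfigurationError):
            sio.TrimConfig(adapter3="ACGTA", min_overlap=8)

    def test_oracle_equivalence_on_random_reads(self, rng):
        """Adapter localization agrees with a naive substring scan."""
        cfg = sio.TrimConfig()
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        seed = cfg.adapter3[: cfg.min_overlap]
        for _ in range(1000):
            n = int(rng.integers(8, 31))
            insert = rng.choice(bases, size=n).tobytes().decode()
            seq = insert + cfg.adapter3
            expected_cut = seq.find(seed)
            res = sio.trim_adapter(sio.Read("r", seq), cfg)
            if res.accepted:
                assert len(res.insert.sequence) == expected_cut
            else:  # seed landed early inside the insert -> short insert
                assert expected_cut < cfg.min_insert or res.reason is not None


class TestCollapse:
    def test_hand_countable(self):
        uniques = sio.collapse_reads(["AAAGGGTT", "AAAGGGTT", "CCCGGGTT"])
        assert [(u.sequence, u.count) for u in uniques] == [("AAAGGGTT", 2), ("CCCGGGTT", 1)]

    def test_empty_stream(self):
        assert sio.collapse_reads([]) == []

    def test_u_and_t_collapse_together(self):
        uniques = sio.collapse_reads(["ACGUACGU", "ACGTACGT"])
        assert len(uniques) == 1 and uniques[0].count == 2

    def test_tie_breaks_lexicographic(self):
        uniques = sio.collapse_reads(["TTTTTTTT", "AAAAAAAA"])
        assert [u.sequence for u in uniques] == ["AAAAAAAA", "TTTTTTTT"]

    @given(st.lists(st.text(alphabet="ACGT", min_size=8, max_size=30), max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_count_conservation(self, seqs):
        uniques = sio.collapse_reads(seqs)
        assert sum(u.count for u in uniques) == len(seqs)
        assert len({u.sequence for u in uniques}) == len(uniques)


class TestRpmNormalize:
    def test_basic_scaling(self):
        out = sio.rpm_normalize([sio.UniqueRead("A" * 12, 5)], total=1_000_000)
        assert out[0].rpm == pytest.approx(5.0)

    def test_count_equals_total(self):
        out = sio.rpm_normalize([sio.UniqueRead("A" * 12, 7)], total=7)
        assert out[0].rpm == pytest.approx(1e6)

    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=100))
    @settings(max_examples=50, deadline=None)
    def test_rpm_sums_to_one_million(self, counts):
        uniques = [sio.UniqueRead("ACGTACGTACGT", c) for c in counts]
        out = sio.rpm_normalize(uniques)
        assert sum(u.rpm for u in out) == pytest.approx(1e6, rel=1e-6)

    def test_zero_total_error(self):
        with pytest.raises(sio.InputError):
            sio.rpm_normalize([], total=0)

    def test_total_smaller_than_counts_error(self):
        with pytest.raises(sio.InputError):
            sio.rpm_normalize([sio.UniqueRead("A" * 12, 5)], total=4)


class TestContaminantScreen:
    def test_dorna_core_is_clean(self):
        assert sio.screen_contaminants("GACTCTTAGCGG", contaminant_records()) == []
        assert sio.screen_contaminants("CGACTCTTAGCGG", contaminant_records()) == []

    def test_prefix_of_contaminant_hits_offset_zero(self):
        name, seq = contaminant_records()[0]
        hits = sio.screen_contaminants(seq[:12], contaminant_records())
        assert any(h.name == name and h.offset == 0 and h.strand == "+" for h in hits)

    def test_planted_query_found_at_planted_offset(self, rng):
        name, seq = "TruSeq_universal_adapter", dict(contaminant_records())["TruSeq_universal_adapter"]
        offset = int(rng.integers(0, len(seq) - 12))
        hits = sio.screen_contaminants(seq[offset : offset + 12], contaminant_records())
        assert (name, offset, "+") in [(h.name, h.offset, h.strand) for h in hits]

    def test_short_query_refused(self):
        with pytest.raises(sio.InputError):
            sio.screen_contaminants("ACGTACG", contaminant_records())


class TestRoundTrip:
    def test_fastq_roundtrip(self, tmp_path):
        reads = [sio.Read("a", "ACGTACGTACGT", "IIIIIIIIIIII"), sio.Read("b", "GGGGCCCCAAAA")]
        path = tmp_path / "x.fastq"
        sio.write_fastq(reads, path)
        back = list(sio.read_fastq(path))
        assert [r.sequence for r in back] == [r.sequence for r in reads]

    def test_collapsed_tsv_roundtrip(self, tmp_path):
        uniques = sio.rpm_normalize([sio.UniqueRead("ACGTACGTACGT", 3), sio.UniqueRead("GGGGCCCCAAAA", 1)])
        path = tmp_path / "c.tsv"
        sio.write_collapsed_tsv(uniques, path, metadata={"rpm_denominator": 4})
        back = sio.read_collapsed_tsv(path)
        assert back == uniques

    def test_collapsed_fasta_headers(self, tmp_path):
        path = tmp_path / "c.fa"
        sio.write_collapsed_fasta([sio.UniqueRead("ACGTACGTACGT", 9)], path)
        assert path.read_text().startswith(">seq1_x9\n")

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "x.fastq.gz"
        sio.write_fastq([sio.Read("a", "ACGTACGTACGT")], path)
        assert [r.id for r in sio.read_fastq(path)] == ["a"]
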