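"""Anchor derivation, ladder classification and the ratio statistic."""

import numpy as np
import pytest

from dorna import classify, simulate
from dorna import sequence_io as sio
from dorna.classify import AnchorError, classify_read, derive_anchor
from dorna.mapper import Feature, ReferenceFeatureSet
from dorna.references import synthetic_precursor


def make_refs(prefix14="CGACTCTTAGCGGT", upstream="AACCGGTTAACCGGTTAACC"):
    """Minimal 5.8S-bearing record: ITS1 + 5.8S."""
    s58 = prefix14 + "ACCGGTTACGGATTACCGGATTACCG"
    seq = upstream + s58
    n = len(upstream)
    return ReferenceFeatureSet(
        records={"T": seq},
        features=[Feature("T", "ITS1", 0, n), Feature("T", "5.8S", n, len(seq))])


class TestDeriveAnchor:
    def test_human_anchor_sequences(self, human_refs, human_anchor):
        assert human_anchor.core_sequence == "GACTCTTAGCGG"
        assert human_anchor.c_variant_sequence == "CGACTCTTAGCGG"
        assert human_anchor.c_variant_sequence[0] == "C"
        # 3' coordinate points at the invariant G13
        acc = human_anchor.accession
        assert human_refs.records[acc][human_anchor.three_prime_ref_pos] == "G"

    def test_fly_anchor_plus1_base_and_2nt_divergence(self, fly_refs, human_anchor):
        anchor = derive_anchor(fly_refs, next(iter(fly_refs.records)))
        assert anchor.c_variant_sequence[0] == "A"
        diff = sum(a != b for a, b in zip(anchor.core_sequence, human_anchor.core_sequence))
        assert diff == 2

    def test_position13_not_g_fails_validation(self):
        refs = make_refs(prefix14="CGACTCTTAGCGAT")
        with pytest.raises(AnchorError) as err:
            derive_anchor(refs, "T")
        assert err.value.code == "anchor_validation"

    def test_position14_not_u_fails_validation(self):
        refs = make_refs(prefix14="CGACTCTTAGCGGA")
        with pytest.raises(AnchorError) as err:
            derive_anchor(refs, "T")
        assert err.value.code == "anchor_validation"

    def test_missing_58s_feature(self):
        refs = ReferenceFeatureSet(records={"T": "ACGT" * 30})
        with pytest.raises(AnchorError) as err:
            derive_anchor(refs, "T")
        assert err.value.code == "missing_58S_feature"

    def test_insufficient_upstream(self):
        refs = make_refs(upstream="ACG")
        with pytest.raises(AnchorError) as err:
            derive_anchor(refs, "T")
        assert err.value.code == "insufficient_upstream"


class TestClassifyRead:
    def test_core_is_dorna(self, human_anchor):
        call = classify_read(human_anchor.core_sequence, human_anchor)
        assert call.category == "doRNA" and call.five_prime_offset == 0

    def test_c_variant(self, human_anchor):
        call = classify_read(human_anchor.c_variant_sequence, human_anchor)
        assert call.category == "C-doRNA" and call.five_prime_offset == -1
        assert call.five_prime_base == "C"

    def test_3prime_extension_is_non_dorna(self, human_anchor):
        extended = human_anchor.core_sequence + "T"
        assert classify_read(extended, human_anchor).category == "non_doRNA"

    def test_18mer_extends_into_its1(self, human_anchor):
        seq = human_anchor.expected_sequence(18)
        call = classify_read(seq, human_anchor)
        assert call.category == "extended_variant" and call.five_prime_offset == -6

    def test_19mer_beyond_max_length_is_non_dorna(self, human_refs, human_anchor):
        feat = human_refs.feature(human_anchor.accession, "5.8S")
        seq = human_refs.records[human_anchor.accession]
        window19 = seq[feat.start - 6 : feat.start + 13]
        assert classify_read(window19, human_anchor).category == "non_doRNA"

    def test_fly_13mer_named_plus1_variant(self, fly_refs):
        anchor = derive_anchor(fly_refs, next(iter(fly_refs.records)))
        call = classify_read(anchor.c_variant_sequence, anchor)
        assert call.category == "plus1_variant" and call.five_prime_base == "A"

    def test_internal_mismatch_tolerated_when_allowed(self, human_anchor):
        core = human_anchor.core_sequence
        variant = core[:5] + ("A" if core[5] != "A" else "C") + core[6:]
        assert classify_read(variant, human_anchor).category == "non_doRNA"
        call = classify_read(variant, human_anchor, allow_mismatches=1)
        assert call.category == "doRNA" and call.mismatches == 1

    def test_3prime_g_substitution_never_tolerated(self, human_anchor):
        variant = human_anchor.core_sequence[:-1] + "A"
        assert classify_read(variant, human_anchor, allow_mismatches=1).category == "non_doRNA"

    def test_length_bounds(self, human_anchor):
        with pytest.raises(sio.InputError):
            classify_read("ACGTACG", human_anchor)

    def test_mismatch_toggle_monotone(self, human_anchor, rng):
        """allow_mismatches=1 never removes family members."""
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for _ in range(300):
            L = int(rng.integers(8, 31))
            seq = rng.choice(bases, size=L).tobytes().decode()
            strict = classify_read(seq, human_anchor, 0)
            loose = classify_read(seq, human_anchor, 1)
            if strict.category != "non_doRNA":
                assert loose.category != "non_doRNA"

    def test_exclusive_single_category(self, human_anchor):
        """Every family window sequence gets exactly one ladder offset."""
        seen = set()
        for length in range(12, human_anchor.max_total_length + 1):
            call = classify_read(human_anchor.expected_sequence(length), human_anchor)
            assert call.category != "non_doRNA"
            assert call.five_prime_offset not in seen
            seen.add(call.five_prime_offset)


class TestLadder:
    def test_planted_ladder_recovered_exactly(self, human_anchor):
        planted = {0: 100, -1: 500, -2: 20}
        uniques = [sio.UniqueRead(human_anchor.expected_sequence(12 - off), n)
                   for off, n in planted.items()]
        uniques.append(sio.UniqueRead("ACGTACGTACGTACGTACGT", 7))
        ladder = classify.tabulate_ladder(uniques, human_anchor)
        for off, n in planted.items():
            assert int(ladder.loc[ladder["offset"] == off, "count"].iloc[0]) == n
        non = ladder.loc[ladder["category"] == "non_doRNA", "count"].iloc[0]
        assert int(non) == 7

    def test_empty_library_all_zero(self, human_anchor):
        ladder = classify.tabulate_ladder([], human_anchor)
        assert int(ladder["count"].sum()) == 0

    def test_total_conservation(self, human_anchor, rng):
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        uniques = sio.collapse_reads(
            [rng.choice(bases, size=int(rng.integers(8, 31))).tobytes().decode()
             for _ in range(500)])
        ladder = classify.tabulate_ladder(uniques, human_anchor)
        assert int(ladder["count"].sum()) == sum(u.count for u in uniques)

    def test_family_rows_end_at_position13(self, human_refs, human_anchor):
        """3'-invariance: every ladder row sequence ends on the anchored G."""
        seq = human_refs.records[human_anchor.accession]
        end = human_anchor.three_prime_ref_pos + 1
        ladder = classify.tabulate_ladder([], human_anchor)
        family = ladder[ladder["category"] != "non_doRNA"]
        for row in family.itertuples(index=False):
            assert seq[end - row.length : end] == row.sequence
            assert row.sequence[-1] == "G"


class TestRatio:
    def test_point_estimate(self):
        est = classify.estimate_ratio(500, 100, seed=0)
        assert est.ratio == pytest.approx(5.0)

    def test_equal_counts_ci_contains_one(self):
        est = classify.estimate_ratio(10_000, 10_000, seed=0)
        assert est.ratio == 1.0 and est.ci_low <= 1.0 <= est.ci_high

    def test_seed_reproducibility(self):
        a = classify.estimate_ratio(500, 100, seed=42)
        b = classify.estimate_ratio(500, 100, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_zero_denominator_error(self):
        with pytest.raises(ZeroDivisionError):
            classify.estimate_ratio(5, 0)

    def test_negative_counts_error(self):
        with pytest.raises(sio.InputError):
            classify.estimate_ratio(-1, 5)

    def test_identical_samples_not_significant(self):
        est = classify.estimate_ratio(5000, 1000, seed=0)
        cmp_ = classify.compare_ratios(est, est, seed=1)
        assert cmp_.p_value > 0.5 and abs(cmp_.log_ratio_diff) < 1e-12

    def test_planted_5_vs_1_significant(self):
        """Ratios 5 vs 1 at 1e4 family reads: detected in >= 95% of seeds."""
        detected = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.multinomial(10_000, [5 / 6, 1 / 6])
            y = rng.multinomial(10_000, [0.5, 0.5])
            ea = classify.estimate_ratio(int(x[0]), int(x[1]), n_bootstrap=1000, seed=seed)
            eb = classify.estimate_ratio(int(y[0]), int(y[1]), n_bootstrap=1000, seed=seed + 1)
            detected += classify.compare_ratios(ea, eb, n_bootstrap=1000, seed=seed + 2).p_value < 0.01
        assert detected >= 29

    def test_ttest_plumbing(self):
        stat, p = classify.ratio_ttest([5.0, 5.1, 4.9], [1.0, 1.1, 0.9])
        assert p < 0.001


def test_ratio_recovery_all_presets():
    """|estimated - true|/true < 0.05 at 1e5 family reads, count level."""
    for preset, true_ratio in simulate.PRESET_RATIOS.items():
        cfg = simulate.LibrarySimConfig(species_preset=preset)
        rng = np.random.default_rng(5)
        counts = simulate.simulate_family_counts(cfg, 100_000, rng)
        est = classify.estimate_ratio(counts[-1], counts[0], seed=5)
        assert abs(est.ratio - true_ratio) / true_ratio < 0.05
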