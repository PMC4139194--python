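"""Read-to-mature assignment, RPM normalization and arm classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpress.quant import (
    MatureReference,
    classify_arms,
    match_read,
    normalize_rpm,
    quantify,
)

REF = MatureReference("ref", "hp", "5p", "UGAGGUAGUAGGUUGUAUAGUU")  # 22 nt


def mutate(seq: str, positions: list[int]) -> str:
    """Flip the base at each 1-based position to a different nucleotide."""
    order = "ACGU"
    out = list(seq)
    for p in positions:
        out[p - 1] = order[(order.index(out[p - 1]) + 1) % 4]
    return "".join(out)


def brute_force_accept(read: str, ref_seq: str) -> bool:
    """Independent position-by-position re-statement of the mapping policy."""
    read = read.upper().replace("T", "U")
    if len(read) < 17:
        return False
    if len(read) - len(ref_seq) > 4:
        return False
    mm = 0
    for i in range(min(17, len(read), len(ref_seq))):
        if read[i] != ref_seq[i] or read[i] == "N":
            mm += 1
    return mm <= 2


class TestMatchRead:
    def test_identical_read_accepts_with_zero_mismatches(self):
        res = match_read(REF.sequence, REF)
        assert res.accepted and res.mismatches == ()

    @pytest.mark.parametrize(
        "positions,accepted",
        [
            ([5, 12], True),  # two core mismatches tolerated
            ([3, 9, 15], False),  # three core mismatches reject
            ([19, 21, 22], True),  # tail mismatches unconstrained
            ([1, 17], True),  # boundary: position 17 is still core
            ([1, 17, 16], False),
            ([2, 11, 18, 20], True),  # only two of four fall in the core
            ([2, 11, 16, 20], False),  # third core mismatch dominates
        ],
    )
    def test_mismatch_policy(self, positions, accepted):
        assert match_read(mutate(REF.sequence, positions), REF).accepted is accepted

    def test_dna_read_matches_rna_reference(self):
        assert match_read(REF.sequence.replace("U", "T"), REF).accepted

    def test_three_prime_overhang(self):
        assert match_read(REF.sequence + "AAAA", REF).accepted
        assert not match_read(REF.sequence + "AAAAA", REF).accepted

    def test_short_read_rejected_and_bad_input_raises(self):
        assert not match_read(REF.sequence[:16], REF).accepted
        with pytest.raises(ValueError):
            match_read("", REF)
        with pytest.raises(ValueError):
            match_read("UGAGGUAGUAGGUUGUXUAGUU", REF)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_comparator(self, data):
        rng_seq = st.text(alphabet="ACGUTN", min_size=17, max_size=26)
        ref_seq = data.draw(st.text(alphabet="ACGU", min_size=17, max_size=26))
        ref = MatureReference("r", "h", "5p", ref_seq)
        # mix free reads with near-copies of the reference
        if data.draw(st.booleans()):
            read = data.draw(rng_seq)
        else:
            k = data.draw(st.integers(0, 5))
            pos = data.draw(
                st.lists(st.integers(1, len(ref_seq)), min_size=k, max_size=k, unique=True)
            )
            read = mutate(ref_seq, pos)
        assert match_read(read, ref).accepted == brute_force_accept(read, ref_seq)


class TestQuantify:
    def test_exact_copies_counted(self, three_refs):
        counts = quantify([three_refs[0].sequence] * 10, three_refs)
        assert counts.loc["mirA", "rep1"] == 10
        assert counts.loc["mirB", "rep1"] == 0

    def test_multimapper_split_fractionally(self):
        a = MatureReference("a", "h1", "5p", "UGAGGUAGUAGGUUGUAUAGUU")
        # differs only at position 20: any read matching a also matches b
        b = MatureReference("b", "h2", "5p", mutate(a.sequence, [20]))
        counts = quantify([a.sequence] * 4, [a, b])
        assert counts.loc["a", "rep1"] == counts.loc["b", "rep1"] == 2.0
        counts_all = quantify([a.sequence] * 4, [a, b], policy="all")
        assert counts_all.loc["a", "rep1"] == counts_all.loc["b", "rep1"] == 4.0

    def test_blacklisted_reads_excluded(self, three_refs):
        decoy = "A" * 30
        reads = [three_refs[0].sequence] * 3 + [decoy[2:26]]
        counts = quantify(reads, three_refs, blacklist=[decoy])
        assert counts["rep1"].sum() == 3

    def test_order_independence(self, three_refs):
        reads = [three_refs[i % 3].sequence for i in range(30)]
        c1 = quantify(reads, three_refs)
        c2 = quantify(reads[::-1], three_refs)
        pd.testing.assert_frame_equal(c1, c2)

    def test_collapsed_mapping_equivalent_to_read_list(self, three_refs):
        reads = {three_refs[0].sequence: 7, three_refs[2].sequence: 2}
        c1 = quantify(reads, three_refs)
        c2 = quantify(
            [three_refs[0].sequence] * 7 + [three_refs[2].sequence] * 2, three_refs
        )
        pd.testing.assert_frame_equal(c1, c2)

    def test_generator_ledger_is_recovered_exactly(self, small_panel):
        from mirpress.synthetic import gen_reads

        reads, ledger = gen_reads(small_panel, 2000, seed=5)
        counts = quantify(reads, small_panel.mirnas)
        assert {n: counts.loc[n, "rep1"] for n in counts.index} == ledger

    def test_empty_refs_rejected(self):
        with pytest.raises(ValueError):
            quantify(["ACGU" * 6], [])


class TestNormalizeRpm:
    def test_forced_arithmetic(self):
        counts = pd.DataFrame({"rep1": [2.0, 8.0]}, index=["a", "b"])
        prof = normalize_rpm(counts)
        assert list(prof.rpm["rep1"]) == [200000.0, 800000.0]

    def test_replicate_sum_is_one_million(self, small_panel):
        from mirpress.synthetic import gen_reads

        reads = {}
        for rep in ("rep1", "rep2"):
            reads[rep], _ = gen_reads(small_panel, 1500, seed=hash(rep) % 1000)
        prof = normalize_rpm(quantify(reads, small_panel.mirnas))
        assert np.allclose(prof.rpm.sum(axis=0), 1e6)

    def test_identical_replicates_have_zero_sd(self):
        counts = pd.DataFrame({"r1": [5.0, 5.0], "r2": [5.0, 5.0]}, index=["a", "b"])
        assert (normalize_rpm(counts).sd_rpm == 0).all()

    def test_genome_mode_rescales_by_total_ratio(self):
        counts = pd.DataFrame({"r1": [2.0, 3.0, 5.0]}, index=["a", "b", "c"])
        mirna = normalize_rpm(counts)
        genome = normalize_rpm(counts, "genome_mapped", {"r1": 100.0})
        # denominator 10 vs 100: every RPM shrinks tenfold
        assert np.allclose(genome.rpm, mirna.rpm * (10.0 / 100.0))

    def test_zero_denominator_raises(self):
        counts = pd.DataFrame({"r1": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            normalize_rpm(counts)
        with pytest.raises(ValueError):
            normalize_rpm(counts + 1, "genome_mapped", {"r1": 0})


class TestClassifyArms:
    PAIRING = [("hp", "m-5p", "m-3p")]

    def call(self, rpm5, rpm3, threshold=4.0):
        s = pd.Series({"m-5p": rpm5, "m-3p": rpm3})
        return classify_arms(s, self.PAIRING, threshold)[0]

    def test_ratio_above_threshold_calls_star(self):
        c = self.call(100, 20)
        assert c.star_arm == "m-3p" and c.dominant_arm == "m-5p" and c.ratio == 5

    def test_ratio_exactly_threshold_is_not_star(self):
        assert self.call(100, 25).star_arm is None

    def test_both_arms_high_but_50fold_apart(self):
        c = self.call(20000, 1_000_000)
        assert c.star_arm == "m-5p" and c.ratio == 50

    def test_missing_arm_counts_as_zero(self):
        s = pd.Series({"m-5p": 10.0})
        c = classify_arms(s, self.PAIRING)[0]
        assert c.star_arm == "m-3p" and math.isinf(c.ratio)
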