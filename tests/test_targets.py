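"""Seed motifs, UTR scanning, target-site abundance and junction screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirpress as mp
from mirpress.targets import FLANK_LEN, junction_scan, scan_sequence, seed_motif


def brute_scan(seq: str, motif: str) -> list[int]:
    seq = seq.upper().replace("T", "U")
    return [
        i
        for i in range(len(seq) - len(motif) + 1)
        if all(seq[i + j] == motif[j] and seq[i + j] != "N" for j in range(len(motif)))
    ]


class TestSeedMotif:
    def test_let7_motif(self):
        m = seed_motif("UGAGGUAGUAGGUUGUAUAGUU", "let-7-5p")
        assert m.motif == "CUACCUC" and m.motif_dna == "CTACCTC"

    def test_poly_a_gives_poly_u(self):
        assert seed_motif("A" * 22).motif == "U" * 7

    def test_same_seed_same_motif(self):
        a = seed_motif("UGAGGUAGUAGGUUGUAUAGUU")
        b = seed_motif("GGAGGUAGCCCCCCCCCCCCCC")  # identical positions 2-8
        assert a.motif == b.motif

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            seed_motif("UGAGGUA")


class TestScanSequence:
    def test_motif_itself(self):
        m = seed_motif("UGAGGUAGUAGGUUGUAUAGUU")
        assert scan_sequence(m.motif, m) == [0]

    def test_tandem_repeat(self):
        m = seed_motif("UGAGGUAGUAGGUUGUAUAGUU")
        assert scan_sequence(m.motif * 2, m) == [0, 7]

    def test_overlapping_matches_found(self):
        assert scan_sequence("A" * 9, "A" * 7) == [0, 1, 2]

    def test_dna_sequence_and_n_handling(self):
        m = seed_motif("UGAGGUAGUAGGUUGUAUAGUU")
        assert scan_sequence("GG" + m.motif_dna + "TT", m) == [2]
        broken = "GG" + m.motif_dna[:3] + "N" + m.motif_dna[4:] + "TT"
        assert scan_sequence(broken, m) == []

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGTUN", min_size=0, max_size=60),
        motif_seed=st.text(alphabet="ACGU", min_size=7, max_size=7),
    )
    def test_matches_sliding_window_oracle(self, seq, motif_seed):
        assert scan_sequence(seq, motif_seed) == brute_scan(seq, motif_seed)


class TestGeneSiteCounts:
    def test_max_over_isoforms(self):
        m = seed_motif("UGAGGUAGUAGGUUGUAUAGUU", "let-7-5p")
        pad = "ACACACACAC"
        utrs = [
            ("g1", "g1|u1", pad + m.motif + pad),
            ("g1", "g1|u2", pad + (m.motif + pad) * 3),
            ("g2", "g2|u1", pad * 3),
        ]
        counts = mp.gene_site_counts(utrs, [m])
        assert counts.loc["g1", "let-7-5p"] == 3
        assert counts.loc["g2", "let-7-5p"] == 0

    def test_duplicate_utr_id_raises(self):
        m = seed_motif("UGAGGUAGUAGGUUGUAUAGUU", "x")
        with pytest.raises(ValueError, match="duplicate"):
            mp.gene_site_counts([("g", "u", "ACGU" * 5), ("g", "u", "ACGU" * 5)], [m])

    def test_planted_fixture_matches_ledger(self, small_panel):
        for seed in range(6):
            utr_set = mp.gen_utr_set(small_panel, n_genes=5, site_rate=0.5,
                                     seed=seed, isoforms=2)
            motifs = [seed_motif(m.sequence, m.name) for m in small_panel.mirnas]
            counts = mp.gene_site_counts(utr_set.utrs, motifs)
            expected = utr_set.ledger_max_counts().reindex(
                index=counts.index, columns=counts.columns, fill_value=0
            )
            pd.testing.assert_frame_equal(counts, expected.astype(int))


class TestTargetSiteAbundance:
    def test_forced_arithmetic(self):
        counts = pd.DataFrame({"m": [2, 1]}, index=["A", "B"])
        tsa = mp.target_site_abundance(counts, {"A": 10.0, "B": 5.0})
        assert tsa["m"] == 25.0

    def test_no_targets_gives_zero(self):
        counts = pd.DataFrame({"m": [0, 0]}, index=["A", "B"])
        assert mp.target_site_abundance(counts, {"A": 1.0, "B": 1.0})["m"] == 0.0

    def test_linear_in_expression(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 4, (6, 3)), index=list("ABCDEF"), columns=list("xyz")
        )
        expr = pd.Series(rng.random(6) * 10, index=list("ABCDEF"))
        t1 = mp.target_site_abundance(counts, expr)
        t2 = mp.target_site_abundance(counts, expr * 2)
        assert np.allclose(t2, t1 * 2)

    def test_monotone_in_site_counts(self):
        counts = pd.DataFrame({"m": [1, 1]}, index=["A", "B"])
        expr = {"A": 3.0, "B": 4.0}
        bumped = counts.copy()
        bumped.loc["A", "m"] += 1
        assert (
            mp.target_site_abundance(bumped, expr)["m"]
            >= mp.target_site_abundance(counts, expr)["m"]
        )

    def test_negative_expression_raises_and_missing_warns(self):
        counts = pd.DataFrame({"m": [1]}, index=["A"])
        with pytest.raises(ValueError):
            mp.target_site_abundance(counts, {"A": -1.0})
        with pytest.warns(UserWarning):
            tsa = mp.target_site_abundance(counts, {"B": 1.0})
        assert tsa["m"] == 0.0


class TestJunctionScan:
    MATURE = "UGAGGUAGUAGGUUGUAUAGUU"

    def perfect_insert(self):
        from Bio.Seq import Seq

        return str(Seq(self.MATURE).reverse_complement_rna())

    def test_perfect_insert_contains_designed_motif(self):
        m = seed_motif(self.MATURE, "let-7-5p")
        assert scan_sequence(self.perfect_insert(), m)

    def test_only_designed_matches_with_inert_flanks(self):
        m = seed_motif(self.MATURE, "let-7-5p")
        rep = junction_scan(
            self.perfect_insert(), "CCCCCC", "CCCCCC", [m],
            mean_rpm={"let-7-5p": 120.0}, designed="let-7-5p",
        )
        assert rep.matching_mirnas == ["let-7-5p"]
        assert rep.additive_expression == 120.0

    def test_adventitious_site_across_junction_adds_expression(self):
        m_designed = seed_motif(self.MATURE, "let-7-5p")
        # mature whose target motif is CAGCUAA, spelled across the 3' junction
        other = seed_motif("AUUAGCUGCCCCCCCCCCCCCC", "other")
        assert other.motif == "CAGCUAA"
        insert = self.perfect_insert() + "CAGC"
        rep = junction_scan(
            insert, "CCCCCC", "UAAAAA", [m_designed, other],
            mean_rpm={"let-7-5p": 100.0, "other": 40.0}, designed="let-7-5p",
        )
        assert "other" in rep.matching_mirnas
        assert rep.additive_expression == 140.0
        # each miRNA counted once however many sites it matches
        assert rep.additive_expression == sum(
            {"let-7-5p": 100.0, "other": 40.0}[n] for n in rep.matching_mirnas
        )

    def test_exclude_designed_option(self):
        m = seed_motif(self.MATURE, "let-7-5p")
        rep = junction_scan(
            self.perfect_insert(), "CCCCCC", "CCCCCC", [m],
            mean_rpm={"let-7-5p": 120.0}, designed="let-7-5p",
            include_designed=False,
        )
        assert rep.additive_expression == 0.0

    def test_wrong_flank_length_raises(self):
        m = seed_motif(self.MATURE, "let-7-5p")
        with pytest.raises(ValueError):
            junction_scan(self.perfect_insert(), "CCC", "CCCCCC", [m], {}, "x")
        rep = junction_scan(
            self.perfect_insert(), "CCC", "CCCCCC", [m], {"let-7-5p": 1.0},
            designed="let-7-5p", allow_flank_length_mismatch=True,
        )
        assert rep.matching_mirnas == ["let-7-5p"]
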