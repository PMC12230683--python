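from __future__ import annotations

import numpy as np
import pytest

from diffdigest.digestion import (
    CutSiteList,
    SequenceRecord,
    Topology,
    digest,
    find_cut_sites,
    fragments_from_cuts,
)
from diffdigest.enzyme_db import EnzymeRecord, reverse_complement
from conftest import random_seq
from oracle_helpers import naive_cut_sites


def lin(seq, id="s"):
    return SequenceRecord.from_raw(id, seq, Topology.LINEAR)


def circ(seq, id="s"):
    return SequenceRecord.from_raw(id, seq, Topology.CIRCULAR)


class TestFindCutSites:
    def test_xhoi_site_in_forward_cloning_primer(self, enzymes):
        rec = lin("gtacctcgagCCTACTTGTACAGCTCGTCCATGCC")
        assert find_cut_sites(rec, enzymes["XhoI"]).positions == (5,)

    def test_xbai_site_in_reverse_cloning_primer(self, enzymes):
        rec = lin("cgtatctagaATTCGCCACCATGGTGAGCAAGG")
        assert find_cut_sites(rec, enzymes["XbaI"]).positions == (5,)

    def test_site_spanning_circular_origin(self, enzymes):
        # sequence ends ...G and begins AATTC: the EcoRI window exists
        # only across the origin
        rec = circ("AATTC" + "G" * 20)
        assert find_cut_sites(rec, enzymes["EcoRI"]).positions == (0,)
        assert find_cut_sites(lin(rec.seq), enzymes["EcoRI"]).positions == ()

    def test_no_site_no_cuts(self, enzymes):
        assert find_cut_sites(lin("GGGG"), enzymes["EcoRI"]).positions == ()

    def test_minus_strand_site_found(self, enzymes):
        # GAGACC is the reverse complement of the BsaI site GGTCTC;
        # minus-strand cut = w + L - cut_bottom = 2 + 6 - 11 = -3 -> off
        # the linear end, but with enough 5' context the cut lands inside
        rec = lin("A" * 10 + "GAGACC" + "A" * 10)
        # window at w=10; cut = 10 + 6 - 11 = 5
        assert find_cut_sites(rec, enzymes["BsaI"]).positions == (5,)

    def test_outside_cut_off_linear_end_dropped(self, enzymes):
        # BsaI cuts 1 nt past its site: window at 4, cut at 11 > len-1
        rec = lin("AAAA" + "GGTCTC")
        assert find_cut_sites(rec, enzymes["BsaI"]).positions == ()
        # on a circular molecule the same cut wraps around
        assert find_cut_sites(circ(rec.seq), enzymes["BsaI"]).positions == (1,)

    def test_overlapping_palindromic_sites_all_found(self):
        enz = EnzymeRecord("TestI", "ATAT", 2, 2)
        rec = lin("GATATATG")
        assert find_cut_sites(rec, enz).positions == (3, 5)

    def test_agrees_with_naive_windowed_scan(self, rng, enzymes):
        """Oracle equivalence on random sequences and enzymes, both
        topologies, with planted overlapping palindromic sites."""
        pool = list(enzymes.values()) + [EnzymeRecord("OvlI", "ATAT", 2, 2)]
        for i in range(200):
            n = int(rng.integers(30, 300))
            seq = random_seq(rng, n, "ACGTN" if i % 5 == 0 else "ACGT")
            if i % 3 == 0:  # plant overlapping palindrome run
                k = min(n, 9)
                seq = seq[: n - k] + "ATATATATA"[:k]
            enz = pool[int(rng.integers(len(pool)))]
            topo = Topology.CIRCULAR if i % 2 else Topology.LINEAR
            rec = SequenceRecord("r", seq, topo)
            got = find_cut_sites(rec, enz).positions
            want = naive_cut_sites(
                seq, enz.site, enz.cut_top, enz.cut_bottom,
                topo is Topology.CIRCULAR,
            )
            assert list(got) == want, (seq, enz.name, topo)


class TestFragmentsFromCuts:
    @pytest.mark.parametrize(
        "cuts, length, topo, expected",
        [
            ((100, 400), 1000, Topology.CIRCULAR, {300, 700}),
            ((), 1000, Topology.LINEAR, {1000}),
            ((0,), 1000, Topology.CIRCULAR, {1000}),
            ((10, 20, 995), 1000, Topology.LINEAR, {10, 975, 5}),
        ],
    )
    def test_examples(self, cuts, length, topo, expected):
        frags = fragments_from_cuts(CutSiteList(cuts), length, topo)
        assert set(frags) == expected
        assert sum(frags) == length

    def test_linear_multiset_keeps_duplicates(self):
        frags = fragments_from_cuts(
            CutSiteList((10, 20, 995)), 1000, Topology.LINEAR
        )
        assert sorted(frags) == [5, 10, 10, 975]

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            fragments_from_cuts(CutSiteList((1000,)), 1000, Topology.LINEAR)


class TestDigest:
    def test_uncut_molecule_gives_single_full_length_band(self, enzymes):
        pat = digest(circ("ACGT" * 100), enzymes["NotI"])
        assert pat.lengths == (400,) and pat.uncut

    def test_fragments_sorted_descending(self, enzymes):
        rec = circ("GAATTC" + "A" * 100 + "GAATTC" + "C" * 300)
        pat = digest(rec, enzymes["EcoRI"])
        assert pat.lengths == tuple(sorted(pat.lengths, reverse=True))
        assert sum(pat.lengths) == len(rec.seq)

    def test_conservation_over_random_digests(self, rng, enzymes):
        """Fragment lengths always sum to the molecule length."""
        pool = list(enzymes.values())
        for i in range(300):
            n = int(rng.integers(20, 500))
            topo = Topology.CIRCULAR if i % 2 else Topology.LINEAR
            rec = SequenceRecord("r", random_seq(rng, n), topo)
            enz = pool[int(rng.integers(len(pool)))]
            assert sum(digest(rec, enz).lengths) == n

    def test_rotation_invariance_of_circular_digests(self, rng, enzymes):
        """A circular digest is a property of the molecule, not of where
        the sequence string happens to start."""
        pool = [enzymes[n] for n in ("EcoRI", "AvaI", "BsaI", "XmnI")]
        for _ in range(10):
            n = int(rng.integers(60, 200))
            seq = random_seq(rng, n)
            enz = pool[int(rng.integers(len(pool)))]
            ref = sorted(digest(SequenceRecord("r", seq, Topology.CIRCULAR), enz).lengths)
            for r in range(1, n, max(1, n // 17)):
                rot = seq[r:] + seq[:r]
                got = sorted(
                    digest(SequenceRecord("r", rot, Topology.CIRCULAR), enz).lengths
                )
                assert got == ref, (seq, enz.name, r)

    def test_strand_invariance_of_circular_digests(self, rng, enzymes):
        """On a circular molecule, digesting the reverse complement gives
        the same bands for every enzyme: reflection of the cut set plus
        the uniform overhang shift leaves circular gaps unchanged."""
        pool = list(enzymes.values())
        for _ in range(50):
            n = int(rng.integers(40, 400))
            seq = random_seq(rng, n)
            enz = pool[int(rng.integers(len(pool)))]
            fwd = sorted(digest(circ(seq), enz).lengths)
            rev = sorted(digest(circ(reverse_complement(seq)), enz).lengths)
            assert fwd == rev, (seq, enz.name)

    def test_strand_invariance_of_linear_digests_blunt_cutters(
        self, rng, enzymes
    ):
        """For blunt cutters (cut_top == cut_bottom) even the terminal
        fragments of a linear digest are strand-invariant."""
        pool = [e for e in enzymes.values() if e.cut_top == e.cut_bottom]
        assert len(pool) >= 5
        for _ in range(50):
            n = int(rng.integers(40, 400))
            seq = random_seq(rng, n)
            enz = pool[int(rng.integers(len(pool)))]
            fwd = sorted(digest(lin(seq), enz).lengths)
            rev = sorted(digest(lin(reverse_complement(seq)), enz).lengths)
            assert fwd == rev, (seq, enz.name)

    def test_linear_terminal_fragments_shift_by_overhang(self, enzymes):
        """A staggered cutter's linear digest is strand-invariant only up
        to its overhang: the reverse complement shifts the first and last
        fragments by exactly delta = cut_bottom - cut_top (4 nt for
        EcoRI); interior fragments are unchanged."""
        ecori = enzymes["EcoRI"]
        delta = ecori.cut_bottom - ecori.cut_top
        seq = "C" * 30 + "GAATTC" + "A" * 50 + "GAATTC" + "T" * 20
        fwd = fragments_from_cuts(
            find_cut_sites(lin(seq), ecori), len(seq), Topology.LINEAR
        )
        rev = fragments_from_cuts(
            find_cut_sites(lin(reverse_complement(seq)), ecori),
            len(seq),
            Topology.LINEAR,
        )
        assert fwd[1:-1] == list(reversed(rev[1:-1]))
        assert rev[-1] == fwd[0] + delta
        assert rev[0] == fwd[-1] - delta


class TestSequenceRecord:
    def test_normalization_strips_whitespace_and_digits(self):
        rec = SequenceRecord.from_raw("p", "acg t\n1 acgt")
        assert rec.seq == "ACGTACGT"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord.from_raw("p", "ACGU")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord.from_raw("p", "  12  ")
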