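"""Restriction/ligation engine: site finding, digestion, sticky-end rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barkit.seq import (
    BUILTIN_ENZYMES,
    Fragment,
    InvalidEnzymeError,
    IUPAC_SETS,
    LigationError,
    NucSequence,
    OverhangKind,
    RestrictionEnzyme,
    StickyEnd,
    Topology,
    circularize,
    digest,
    ends_compatible,
    find_sites,
    join,
    revcomp,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=400)


def brute_force_sites(bases: str, pattern: str) -> set[int]:
    """Position-by-position IUPAC comparison on both strands."""
    from barkit.seq import iupac_revcomp

    out = set()
    for pat in {pattern, iupac_revcomp(pattern)}:
        for s in range(len(bases) - len(pat) + 1):
            if all(bases[s + j] in IUPAC_SETS[c] for j, c in enumerate(pat)):
                out.add(s)
    return out


class TestFindSites:
    def test_absent_motif_gives_empty_list(self):
        seq = NucSequence("x", "AAAA" * 20)
        assert find_sites(seq, BUILTIN_ENZYMES["EcoRV"]) == []

    @pytest.mark.parametrize("enzyme", ["SfiI", "EcoRV", "BlpI", "SpeI"])
    def test_agrees_with_bruteforce_on_random_sequences(self, enzyme, rng):
        enz = BUILTIN_ENZYMES[enzyme]
        from tests.conftest import random_bases

        for _ in range(200):
            bases = random_bases(rng, 200)
            got = {c.start for c in find_sites(NucSequence("r", bases), enz)}
            assert got == brute_force_sites(bases, enz.recognition)

    def test_agrees_with_biopython_restriction(self, rng):
        from Bio.Restriction import EcoRV, SfiI
        from Bio.Seq import Seq
        from tests.conftest import random_bases

        for _ in range(50):
            bases = random_bases(rng, 3000)
            seq = NucSequence("r", bases)
            # Biopython reports 1-based cut positions; ours are site starts
            ours_ecorv = sorted(c.cut_top for c in find_sites(seq, BUILTIN_ENZYMES["EcoRV"]))
            theirs = sorted(p - 1 for p in EcoRV.search(Seq(bases)))
            assert ours_ecorv == theirs
            ours_sfi = sorted(c.cut_top for c in find_sites(seq, BUILTIN_ENZYMES["SfiI"]))
            theirs = sorted(p - 1 for p in SfiI.search(Seq(bases)))
            assert ours_sfi == theirs

    def test_n_in_sequence_never_matches_concrete_pattern_position(self):
        seq = NucSequence("x", "GATNTC")
        assert find_sites(seq, BUILTIN_ENZYMES["EcoRV"]) == []

    def test_circular_site_across_origin(self):
        # EcoRV site split by the origin of a circular sequence
        bases = "ATC" + "T" * 50 + "GAT"
        seq = NucSequence("c", bases, Topology.circular)
        sites = find_sites(seq, BUILTIN_ENZYMES["EcoRV"])
        assert len(sites) == 1

    def test_invalid_pattern_rejected(self):
        with pytest.raises(InvalidEnzymeError):
            RestrictionEnzyme("bad", "GAXATC", 3, 3)


class TestDigest:
    def test_zero_sites_returns_input_unchanged(self):
        seq = NucSequence("x", "ACGT" * 10)
        frags = digest(seq, BUILTIN_ENZYMES["EcoRV"])
        assert len(frags) == 1 and frags[0].seq.bases == seq.bases

    def test_circular_single_site_linearizes_blunt(self):
        seq = NucSequence("c", "GATATC" + "A" * 94, Topology.circular)
        frags = digest(seq, BUILTIN_ENZYMES["EcoRV"])
        assert len(frags) == 1
        assert len(frags[0]) == 100
        assert frags[0].left_end.kind == OverhangKind.blunt
        assert frags[0].right_end.kind == OverhangKind.blunt

    def test_linear_k_sites_give_k_plus_1_fragments(self, rng):
        bases = "TTT".join(["GATATC"] * 4)
        frags = digest(NucSequence("x", bases), BUILTIN_ENZYMES["EcoRV"])
        assert len(frags) == 5
        assert sum(len(f) for f in frags) == len(bases)

    @settings(max_examples=150, derandomize=True)
    @given(dna)
    def test_rejoining_adjacent_fragments_reproduces_input(self, bases):
        for enzyme in ("EcoRV", "SfiI", "SpeI"):
            seq = NucSequence("x", bases) if bases else None
            if seq is None:
                continue
            frags = digest(seq, BUILTIN_ENZYMES[enzyme])
            whole = frags[0]
            for f in frags[1:]:
                whole = join(whole, f)
            assert whole.seq.bases == bases

    def test_join_then_digest_recovers_fragments_with_original_ends(self, cassette):
        mono = cassette.excise_monomer()
        dimer = join(mono, mono)
        frags = digest(Fragment(dimer.seq, dimer.left_end, dimer.right_end), BUILTIN_ENZYMES["SfiI"])
        assert len(frags) == 2
        for f in frags:
            assert f.left_end == mono.left_end
            assert f.right_end == mono.right_end
            assert f.seq.bases == mono.seq.bases


class TestStickyEnds:
    def test_blunt_ends_compatible(self):
        assert ends_compatible(StickyEnd(OverhangKind.blunt), StickyEnd(OverhangKind.blunt))

    def test_identical_odd_protrusions_incompatible(self):
        a = StickyEnd(OverhangKind.three_prime, "ACC")
        assert not ends_compatible(a, a)

    def test_reverse_complement_protrusions_compatible(self):
        a = StickyEnd(OverhangKind.three_prime, "ACC")
        b = StickyEnd(OverhangKind.three_prime, "GGT")
        # explicit antiparallel base-pairing: ACC (5'->3') pairs with GGT (5'->3')
        assert revcomp("ACC") == "GGT"
        assert ends_compatible(a, b) and ends_compatible(b, a)

    def test_kind_mismatch_incompatible(self):
        a = StickyEnd(OverhangKind.three_prime, "ACC")
        b = StickyEnd(OverhangKind.five_prime, "GGT")
        assert not ends_compatible(a, b)

    @pytest.mark.parametrize("k", range(64))
    def test_no_3nt_overhang_is_self_compatible(self, k):
        # head-to-head ligation of any same-enzyme monomer is impossible:
        # no odd-length protrusion equals its own reverse complement
        over = "".join("ACGT"[(k >> (2 * i)) & 3] for i in range(3))
        end = StickyEnd(OverhangKind.three_prime, over)
        assert not ends_compatible(end, end)

    def test_incompatible_join_raises_naming_protrusions(self):
        a = Fragment(NucSequence("a", "AAAA"), right_end=StickyEnd(OverhangKind.three_prime, "ACC"))
        b = Fragment(NucSequence("b", "TTTT"), left_end=StickyEnd(OverhangKind.three_prime, "ACC"))
        with pytest.raises(LigationError, match="ACC"):
            join(a, b)

    def test_blunt_join_concatenates(self):
        a = Fragment(NucSequence("a", "AAAA"))
        b = Fragment(NucSequence("b", "TTTT"))
        assert join(a, b).seq.bases == "AAAATTTT"

    def test_circularize_requires_compatible_ends(self, cassette):
        mono = cassette.excise_monomer()
        circ = circularize(mono)
        assert circ.is_circular and len(circ) == len(mono)
        bad = Fragment(NucSequence("x", "AAAA"), right_end=StickyEnd(OverhangKind.three_prime, "ACC"))
        with pytest.raises(LigationError):
            circularize(bad)


class TestNucSequence:
    def test_alphabet_enforced(self):
        with pytest.raises(ValueError):
            NucSequence("x", "ACGU")

    @settings(max_examples=100, derandomize=True)
    @given(dna.filter(bool))
    def test_reverse_complement_is_involution(self, bases):
        seq = NucSequence("x", bases)
        assert seq.reverse_complement().reverse_complement().bases == bases
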