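"""Insertion alleles and the four mapping-strategy predictors."""

import numpy as np
import pytest

from barkit.cassette import LOX_SEQUENCES, LoxVariant
from barkit.mapping import (
    Cointegrant,
    CopySpec,
    InsertionStructure,
    InvalidStructureError,
    InvalidSubstrateError,
    Lox66Plasmid,
    MappingParams,
    NonClonableError,
    Orientation,
    Outcome,
    Resolution,
    apply_insertion,
    clone_flank,
    cre_lox_integrate,
    make_lox66_plasmid,
    map_junction_read,
    predict_inverse_splinkerette,
    predict_splinkerette,
    predict_tail_pcr,
)
from barkit.seq import NucSequence, Topology, revcomp
from barkit.simulate import StructureMix, make_library

F, R = Orientation.forward, Orientation.reverse


def single_copy(left=20, right=30, deletion=2):
    return InsertionStructure((CopySpec(F, left, right),), None, deletion)


class TestApplyInsertion:
    def test_length_bookkeeping_single_copy(self, toy_genome, cassette):
        st = InsertionStructure((CopySpec(F, 0, 0),), None, 0)
        m = apply_insertion(toy_genome.contigs, "chr1", 50_000, st, cassette)
        assert len(m.mutated) == len(toy_genome.contigs["chr1"]) + len(cassette.seq)

    def test_length_bookkeeping_randomized(self, toy_genome, cassette, rng):
        for _ in range(30):
            k = int(rng.integers(1, 4))
            copies = tuple(
                CopySpec(
                    F if rng.random() < 0.5 else R,
                    int(rng.integers(0, 800)),
                    int(rng.integers(0, 800)),
                )
                for _ in range(k)
            )
            deletion = int(rng.integers(0, 6))
            co = (
                Cointegrant("mito", 100, 100 + int(rng.integers(500, 2000)))
                if rng.random() < 0.3
                else None
            )
            st = InsertionStructure(copies, co, deletion)
            m = apply_insertion(toy_genome.contigs, "chr2", 40_000, st, cassette)
            expect = (
                len(toy_genome.contigs["chr2"])
                - deletion
                + sum(len(cassette.seq) - c.left_trim - c.right_trim for c in copies)
                + (co.end - co.start if co else 0)
            )
            assert len(m.mutated) == expect
            # provenance partitions the chromosome
            assert m.provenance[0].start == 0
            assert m.provenance[-1].end == len(m.mutated)
            for a, b in zip(m.provenance, m.provenance[1:]):
                assert a.end == b.start

    def test_head_to_head_junction_sequence(self, toy_genome, cassette):
        st = InsertionStructure((CopySpec(R, 0, 0), CopySpec(F, 0, 0)), None, 0)
        m = apply_insertion(toy_genome.contigs, "chr1", 50_000, st, cassette)
        cas = cassette.seq.bases
        junction = m.mutated.bases[50_000 + len(cas) - 30 : 50_000 + len(cas) + 30]
        assert junction == revcomp(cas[:30]) + cas[:30]

    def test_reextracting_block_reproduces_insert(self, toy_genome, cassette, rng):
        for _ in range(20):
            st = InsertionStructure(
                (
                    CopySpec(F, int(rng.integers(0, 100)), int(rng.integers(0, 100))),
                    CopySpec(R, int(rng.integers(0, 100)), int(rng.integers(0, 100))),
                ),
                None,
                int(rng.integers(0, 6)),
            )
            m = apply_insertion(toy_genome.contigs, "chr3", 60_000, st, cassette)
            cas = cassette.seq.bases
            want = (
                cas[st.copies[0].left_trim : len(cas) - st.copies[0].right_trim]
                + revcomp(cas[st.copies[1].left_trim : len(cas) - st.copies[1].right_trim])
            )
            block = m.mutated.bases[60_000 : 60_000 + len(want)]
            assert block == want

    def test_excessive_trim_rejected(self, toy_genome, cassette):
        st = InsertionStructure((CopySpec(F, 1500, 1500),), None, 0)
        with pytest.raises(InvalidStructureError):
            apply_insertion(toy_genome.contigs, "chr1", 1000, st, cassette)


@pytest.fixture(scope="module")
def single_mutant(toy_genome, cassette):
    return apply_insertion(
        toy_genome.contigs, "chr2", 40_000, single_copy(), cassette, mutant_id="single"
    )


class TestTailPcr:
    def test_single_copy_reaches_genomic_junction(self, single_mutant, toy_genome):
        products, res = predict_tail_pcr(single_mutant, annotations=toy_genome.features)
        assert res.outcome == Outcome.genomic_junction
        assert res.interval[0] <= single_mutant.position <= res.interval[1]
        assert res.feature_class is not None
        # the product physically contains genomic sequence
        flank = toy_genome.contigs["chr2"].bases[39_950:40_000]
        assert flank in products[0].bases

    def test_head_to_head_amplifies_vector_only(self, toy_genome, cassette):
        st = InsertionStructure((CopySpec(R, 20, 20), CopySpec(F, 20, 20)), None, 0)
        m = apply_insertion(toy_genome.contigs, "chr1", 50_000, st, cassette)
        _, res = predict_tail_pcr(m)
        assert res.outcome == Outcome.vector_only

    def test_mito_cointegrant_detected(self, toy_genome, cassette):
        st = InsertionStructure(
            (CopySpec(F, 20, 20),), Cointegrant("mito", 2_000, 4_000), 0
        )
        m = apply_insertion(toy_genome.contigs, "chr1", 50_000, st, cassette)
        _, res = predict_tail_pcr(m)
        assert res.outcome == Outcome.mito_cointegrant

    def test_empty_primer_set_rejected(self, single_mutant):
        with pytest.raises(ValueError):
            predict_tail_pcr(single_mutant, ad_primers=[])
        with pytest.raises(ValueError):
            predict_tail_pcr(single_mutant, nested_windows=[(400, 420)])


class TestSplinkerette:
    def test_single_copy_junction(self, single_mutant):
        products, res = predict_splinkerette(single_mutant)
        assert res.outcome == Outcome.genomic_junction
        assert res.resolution == Resolution.bounded_by_site
        assert res.interval[0] <= single_mutant.position <= res.interval[1]

    def test_incompatible_adaptor_rejected(self, single_mutant):
        with pytest.raises(InvalidSubstrateError):
            predict_splinkerette(single_mutant, adaptor_overhang="GATC")

    def test_buffer_resected_away_gives_no_product(self, toy_genome, cassette):
        # left trim beyond the promoter removes every vector primer site
        st = InsertionStructure((CopySpec(F, 500, 20),), None, 0)
        m = apply_insertion(toy_genome.contigs, "chr1", 50_000, st, cassette)
        _, res = predict_splinkerette(m)
        assert res.outcome == Outcome.no_product


class TestInverseSplinkerette:
    def test_product_length_tracks_site_distance(self, toy_genome, cassette):
        from barkit.seq import BUILTIN_ENZYMES, find_sites

        st = single_copy(left=10, right=10, deletion=0)
        m = apply_insertion(toy_genome.contigs, "chr2", 40_000, st, cassette, mutant_id="x")
        product, res = predict_inverse_splinkerette(m)
        assert res.outcome == Outcome.genomic_junction
        # nearest upstream genomic EcoRV cut in the original chromosome
        cuts = [
            c.cut_top
            for c in find_sites(toy_genome.contigs["chr2"], BUILTIN_ENZYMES["EcoRV"])
            if c.cut_top <= 40_000
        ]
        d = 40_000 - cuts[-1]
        params = MappingParams()
        spec = cassette.spec
        ec = cassette.elements["ura4_marker"][0] + spec.ura4_ecorv_offset
        w_in_start = ec - 83
        constant = (ec + 3 - w_in_start) + (cassette.sfi_cut_left - st.copies[0].left_trim)
        assert len(product) == d + constant
        assert res.interval[0] <= m.position <= res.interval[1]

    def test_site_adjacent_to_junction_is_exact(self, cassette, toy_genome):
        # build a chromosome with an EcoRV site 3 bp from the insertion point
        rng = np.random.default_rng(0)
        from barkit.cassette import constrained_filler

        left = constrained_filler(rng, 3000, ("GATATC", "GGCCNNNNNGGCC"))
        right = constrained_filler(rng, 3000, ("GATATC", "GGCCNNNNNGGCC"))
        chrom = left[:-9] + "GATATC" + left[-3:] + right
        genome = {"c": NucSequence("c", chrom), "mito": toy_genome.contigs["mito"]}
        pos = len(left)
        m = apply_insertion(genome, "c", pos, single_copy(deletion=0), cassette)
        _, res = predict_inverse_splinkerette(m, params=MappingParams(exact_threshold=30))
        assert res.outcome == Outcome.genomic_junction
        assert res.resolution == Resolution.exact_junction

    def test_no_ecorv_anywhere_gives_no_product(self, cassette, toy_genome):
        rng = np.random.default_rng(1)
        from barkit.cassette import constrained_filler

        bare = constrained_filler(rng, 6000, ("GATATC", "GGCCNNNNNGGCC"))
        genome = {"c": NucSequence("c", bare), "mito": toy_genome.contigs["mito"]}
        m = apply_insertion(genome, "c", 3000, single_copy(), cassette)
        # the cassette's own EcoRV is present, but no genomic site exists
        # within the circularization cap on the buffer side
        _, res = predict_inverse_splinkerette(m, params=MappingParams(circularization_cap_bp=2500))
        assert res.outcome == Outcome.no_product


class TestMapJunctionRead:
    def test_recovery_over_simulated_mutants(self, toy_genome):
        lib = make_library(
            toy_genome, 30, rng_seed=50, structure_mix=StructureMix(1.0, 0, 0, 0, 0)
        )
        mapped = 0
        for m in lib:
            products, res = predict_tail_pcr(m)
            if res.outcome != Outcome.genomic_junction:
                continue
            hit = map_junction_read(products[0], toy_genome.contigs, toy_genome.features, m.cassette)
            assert hit.outcome == Outcome.genomic_junction
            assert hit.chromosome == m.chromosome
            assert hit.interval[0] <= m.position <= hit.interval[1]
            mapped += 1
        assert mapped >= 20

    def test_wholly_vector_read_unmappable(self, single_mutant, toy_genome):
        read = NucSequence("v", single_mutant.cassette.seq.bases[100:500])
        res = map_junction_read(read, toy_genome.contigs, cassette=single_mutant.cassette)
        assert res.outcome == Outcome.no_product

    def test_duplicated_locus_is_ambiguous(self, toy_genome):
        repeat = toy_genome.contigs["chr1"].bases[10_000:10_060]
        fake = {
            "chr1": toy_genome.contigs["chr1"],
            "chr2": NucSequence("chr2", toy_genome.contigs["chr2"].bases + repeat),
        }
        res = map_junction_read(NucSequence("r", repeat), fake)
        assert res.ambiguous


@pytest.fixture(scope="module")
def plasmid():
    return make_lox66_plasmid(11)


class TestCreLox:
    def test_integration_makes_one_loxp_and_one_hybrid(self, single_mutant, plasmid):
        integ = cre_lox_integrate(single_mutant, plasmid, cre_present=True)
        b = integ.mutated.bases
        loxp, hybrid = LOX_SEQUENCES[LoxVariant.loxP], LOX_SEQUENCES[LoxVariant.hybrid_66_71]
        lox71, lox66 = LOX_SEQUENCES[LoxVariant.lox71], LOX_SEQUENCES[LoxVariant.lox66]
        assert b.count(loxp) + b.count(revcomp(loxp)) == 1
        assert b.count(hybrid) + b.count(revcomp(hybrid)) == 1
        assert b.count(lox71) + b.count(revcomp(lox71)) == 0
        assert b.count(lox66) + b.count(revcomp(lox66)) == 0
        assert len(integ.mutated) == len(single_mutant.mutated) + len(plasmid.seq)

    def test_without_cre_nothing_happens(self, single_mutant, plasmid):
        out = cre_lox_integrate(single_mutant, plasmid, cre_present=False)
        assert out.mutated.bases == single_mutant.mutated.bases
        assert any("Cre absent" in e for e in out.event_log)

    def test_integration_is_one_way(self, single_mutant, plasmid):
        integ = cre_lox_integrate(single_mutant, plasmid, cre_present=True)
        again = cre_lox_integrate(integ, plasmid, cre_present=True)
        assert again.mutated.bases == integ.mutated.bases
        assert any("one-way" in e for e in again.event_log)

    def test_multiple_lox71_rejected(self, toy_genome, cassette, plasmid):
        st = InsertionStructure((CopySpec(F, 20, 20), CopySpec(F, 20, 20)), None, 0)
        m = apply_insertion(toy_genome.contigs, "chr1", 50_000, st, cassette)
        with pytest.raises(InvalidSubstrateError):
            cre_lox_integrate(m, plasmid, cre_present=True)


class TestCloneFlank:
    def test_recovered_plasmid_carries_true_flank(self, single_mutant, plasmid, toy_genome):
        integ = cre_lox_integrate(single_mutant, plasmid, cre_present=True)
        circle, res = clone_flank(integ, plasmid)
        assert circle.topology == Topology.circular
        assert res.outcome == Outcome.genomic_junction
        assert res.interval[0] <= single_mutant.position <= res.interval[1]
        # the cloned genomic segment maps back to the true locus
        a, b = res.interval
        flank = toy_genome.contigs["chr2"].bases[a + 10 : a + 110]
        assert flank in circle.bases

    def test_cut_inside_origin_is_non_clonable(self, single_mutant):
        bad = make_lox66_plasmid(3)
        # corrupt: plant a SpeI site inside the origin element
        s, e = bad.elements["puc_origin"]
        seq = bad.seq.bases
        seq = seq[: s + 50] + "ACTAGT" + seq[s + 56 :]
        bad = Lox66Plasmid(NucSequence("pBad", seq, Topology.circular), bad.elements)
        integ = cre_lox_integrate(single_mutant, bad, cre_present=True)
        with pytest.raises(NonClonableError):
            clone_flank(integ, bad)


class TestMethodComplementarity:
    def test_union_of_methods_beats_each_single_method(self, toy_genome):
        # mixed structure panel: single copies, head-to-head tandems,
        # mitochondrial co-integrants
        mix = StructureMix(0.4, 0.0, 0.3, 0.0, 0.3)
        lib = make_library(toy_genome, 40, rng_seed=31, structure_mix=mix)
        resolved: dict[str, set[str]] = {"tail": set(), "spl": set(), "isp": set()}
        for m in lib:
            for name, fn in (
                ("tail", predict_tail_pcr),
                ("spl", predict_splinkerette),
                ("isp", predict_inverse_splinkerette),
            ):
                _, res = fn(m)
                if res.outcome == Outcome.genomic_junction:
                    assert res.interval[0] <= m.position <= res.interval[1]
                    resolved[name].add(m.mutant_id)
        union = set().union(*resolved.values())
        for name, got in resolved.items():
            assert len(union) > len(got), f"{name} alone resolves everything"
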