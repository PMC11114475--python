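import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from symbiopsi.io_formats import GeneModel, Interval, SequenceRecord
from symbiopsi.pseudogene_caller import (
    CallerConfig,
    PseudogeneFragment,
    call_pseudogenes,
    chain_fragments,
    find_fragments,
    mask_genes,
)
from symbiopsi.synthetic_data import back_translate, random_protein, reverse_complement

from oracles import translated_hits

CFG = CallerConfig()


def make_gene(scaffold, start, end, gene_id="g1", taxon="T"):
    exons = [Interval(scaffold, start, end, "+")]
    return GeneModel(gene_id, taxon, scaffold, "+", exons, list(exons))


def rand_nt(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def frag(scaffold, strand, start, end, score=100.0, query="p", frame=0, identity=0.9):
    return PseudogeneFragment(
        query_protein=query,
        location=Interval(scaffold, start, end, strand),
        frame=frame,
        identity=identity,
        score=score,
        query_span=(0, (end - start) // 3),
    )


class TestMasking:
    def test_gene_span_masked_rest_untouched(self):
        genome = [SequenceRecord("s", "A" * 100)]
        masked = mask_genes(genome, [make_gene("s", 10, 20)])
        seq = masked[0].seq
        assert seq[10:20] == "N" * 10
        assert seq[:10] == "A" * 10 and seq[20:] == "A" * 80

    def test_no_genes_unchanged(self):
        genome = [SequenceRecord("s", "ACGT" * 10)]
        assert mask_genes(genome, [])[0].seq == genome[0].seq

    def test_overlapping_genes_mask_union(self):
        genome = [SequenceRecord("s", "A" * 60)]
        models = [make_gene("s", 10, 30, "g1"), make_gene("s", 20, 40, "g2")]
        seq = mask_genes(genome, models)[0].seq
        assert seq == "A" * 10 + "N" * 30 + "A" * 20


class TestFindFragments:
    def test_exact_planted_copy_identity_one(self):
        rng = np.random.default_rng(0)
        prot = random_protein(rng, 100)
        cds = back_translate(prot, 0.5, rng)
        genome = [SequenceRecord("s", rand_nt(rng, 500) + cds + rand_nt(rng, 500))]
        frags = find_fragments(SequenceRecord("p", prot, "aa"), genome, CFG)
        assert len(frags) == 1
        f = frags[0]
        assert f.identity == 1.0
        assert f.location == Interval("s", 500, 500 + len(cds), "+")
        assert f.frame == (500 % 3)
        assert f.query_span == (0, 100)

    def test_reverse_complement_copy_on_minus_strand(self):
        rng = np.random.default_rng(1)
        prot = random_protein(rng, 80)
        cds = back_translate(prot, 0.5, rng)
        insert = reverse_complement(cds)
        genome = [SequenceRecord("s", rand_nt(rng, 300) + insert + rand_nt(rng, 300))]
        frags = find_fragments(SequenceRecord("p", prot, "aa"), genome, CFG)
        assert len(frags) == 1
        assert frags[0].location.strand == "-"
        assert frags[0].identity == 1.0
        assert frags[0].location.start == 300
        assert frags[0].location.end == 300 + len(cds)

    def test_heavily_substituted_copy_rejected(self):
        """A copy with ~30% amino-acid substitutions falls below the 75%
        identity rule; verified against the brute-force oracle."""
        rng = np.random.default_rng(2)
        prot = random_protein(rng, 100)
        aas = sorted(set(prot))
        mutated = list(prot)
        for pos in rng.choice(len(prot), size=30, replace=False):
            alts = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != mutated[pos]]
            mutated[pos] = alts[rng.integers(len(alts))]
        cds = back_translate("".join(mutated), 0.5, rng)
        genome = [SequenceRecord("s", rand_nt(rng, 200) + cds + rand_nt(rng, 200))]
        frags = find_fragments(SequenceRecord("p", prot, "aa"), genome, CFG)
        oracle = translated_hits(prot, [("s", genome[0].seq)])
        assert frags == [] and oracle == []

    def test_empty_for_unrelated_sequence(self):
        rng = np.random.default_rng(3)
        prot = random_protein(rng, 60)
        genome = [SequenceRecord("s", rand_nt(rng, 2000))]
        assert find_fragments(SequenceRecord("p", prot, "aa"), genome, CFG) == []


class TestChaining:
    def test_gap_800_merges(self):
        frags = [frag("s", "+", 0, 300), frag("s", "+", 1100, 1400)]
        assert len(chain_fragments(frags, CFG)) == 1

    def test_gap_1000_splits(self):
        """The chaining rule is strictly < 1 kb."""
        frags = [frag("s", "+", 0, 300), frag("s", "+", 1300, 1600)]
        calls = chain_fragments(frags, CFG)
        assert len(calls) == 2

    def test_gap_999_merges(self):
        frags = [frag("s", "+", 0, 300), frag("s", "+", 1299, 1600)]
        assert len(chain_fragments(frags, CFG)) == 1

    def test_opposite_strands_never_chain(self):
        frags = [frag("s", "+", 0, 300), frag("s", "-", 400, 700)]
        calls = chain_fragments(frags, CFG)
        assert len(calls) == 2
        assert {c.strand for c in calls} == {"+", "-"}

    def test_representative_is_highest_scoring(self):
        frags = [
            frag("s", "+", 0, 300, score=50.0, query="low"),
            frag("s", "+", 400, 700, score=90.0, query="high"),
        ]
        calls = chain_fragments(frags, CFG)
        assert len(calls) == 1
        assert calls[0].representative_query == "high"
        assert calls[0].location == Interval("s", 0, 700, "+")

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["s1", "s2"]),
                st.sampled_from(["+", "-"]),
                st.integers(0, 5000),
                st.integers(1, 600),
            ),
            min_size=0,
            max_size=25,
        )
    )
    def test_calls_partition_fragments(self, raw):
        """Every fragment lands in exactly one call; spans cover members."""
        frags = [frag(s, t, a, a + w) for s, t, a, w in raw]
        calls = chain_fragments(frags, CFG)
        members = [f for c in calls for f in c.fragments]
        assert len(members) == len(frags)
        assert {id(f) for f in members} == {id(f) for f in frags}
        for c in calls:
            assert all(
                f.location.scaffold == c.location.scaffold
                and f.location.strand == c.strand
                for f in c.fragments
            )
            assert c.location.start == min(f.location.start for f in c.fragments)
            assert c.location.end == max(f.location.end for f in c.fragments)


class TestCallPseudogenes:
    def test_empty_proteome_zero_calls(self):
        genome = [SequenceRecord("s", "ACGT" * 100)]
        assert call_pseudogenes([], genome, [], CFG) == []

    def test_fragmented_copy_chains_into_one_call(self):
        """Two pieces of one decayed copy 500 bp apart become one call
        with two fragments."""
        rng = np.random.default_rng(4)
        prot = random_protein(rng, 120)
        cds = back_translate(prot, 0.5, rng)
        half = (len(cds) // 6) * 3
        genome_seq = (
            rand_nt(rng, 400) + cds[:half] + rand_nt(rng, 500) + cds[half:]
            + rand_nt(rng, 400)
        )
        genome = [SequenceRecord("s", genome_seq)]
        calls = call_pseudogenes(
            [SequenceRecord("p", prot, "aa")], genome, [], CFG
        )
        assert len(calls) == 1
        assert len(calls[0].fragments) == 2

    def test_no_call_overlaps_any_gene_span(self, default_cohort, default_calls):
        """Masking correctness on the full synthetic cohort."""
        for taxon, calls in default_calls.items():
            spans = [m.span for m in default_cohort.annotations[taxon]]
            for c in calls:
                assert not any(c.location.overlaps(sp) for sp in spans)

    def test_calls_sorted_and_deterministic(self, default_cohort):
        taxon = "S2_1"
        args = (
            default_cohort.proteomes[taxon],
            default_cohort.genomes[taxon],
            default_cohort.annotations[taxon],
        )
        a = call_pseudogenes(*args, CFG, taxon=taxon)
        b = call_pseudogenes(*args, CFG, taxon=taxon)
        assert [(c.call_id, c.location) for c in a] == [
            (c.call_id, c.location) for c in b
        ]
        keys = [(c.location.scaffold, c.location.start) for c in a]
        assert keys == sorted(keys)
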