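import numpy as np
import pytest

from symbiopsi.io_formats import SequenceRecord
from symbiopsi.synthetic_data import (
    CohortConfig,
    DecayParams,
    decay_sequence,
    simulate_cohort,
    translate_cds,
    write_cohort,
)

from conftest import make_config


class TestDecay:
    def make_cds(self, rng, n_codons=100):
        from symbiopsi.synthetic_data import back_translate, random_protein

        return SequenceRecord("src", back_translate(random_protein(rng, n_codons), 0.5, rng))

    def test_zero_decay_is_identity(self):
        rng = np.random.default_rng(0)
        cds = self.make_cds(rng)
        out = decay_sequence(cds, DecayParams(0, 0, 0, 0), rng)
        assert out.seq == cds.seq
        assert "identity=1.0000" in out.description

    def test_full_truncation_shortens(self):
        rng = np.random.default_rng(1)
        cds = self.make_cds(rng)
        out = decay_sequence(
            cds, DecayParams(0, 0, truncation_fraction=1.0, premature_stop_rate=0), rng
        )
        assert len(out.seq) < len(cds.seq)

    def test_substitution_rate_matches_bernoulli_expectation(self):
        """Realized nt identity over many replicates tracks the per-site
        substitution probability (0.10 -> identity ~ 0.90)."""
        rng = np.random.default_rng(2)
        cds = self.make_cds(rng)  # 300 nt
        params = DecayParams(0.10, 0, 0, 0)
        n_reps = 1000
        mismatches = 0
        for _ in range(n_reps):
            out = decay_sequence(cds, params, rng)
            mismatches += sum(a != b for a, b in zip(out.seq, cds.seq))
        rate = mismatches / (n_reps * len(cds.seq))
        # binomial SE over 300k sites ~ 0.00055; allow 5 sigma
        assert abs(rate - 0.10) < 5 * np.sqrt(0.1 * 0.9 / (n_reps * len(cds.seq)))

    def test_length_not_divisible_by_three_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            decay_sequence(SequenceRecord("x", "ACGTA"), DecayParams(), rng)


class TestSimulateCohort:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = make_config(seed=5)
        for d in ("a", "b"):
            write_cohort(simulate_cohort(cfg), tmp_path / d)
        for fa in sorted((tmp_path / "a").iterdir()):
            fb = tmp_path / "b" / fa.name
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_zero_rate_groups_have_no_planted_loci(self):
        cfg = make_config(
            pseudogene_rate={"Ev": 0.0, "S1": 0.5, "S2": 0.5, "Po": 0.0}
        )
        cohort = simulate_cohort(cfg)
        taxa_with = {p.taxon for p in cohort.truth.planted_pseudogenes}
        assert not any(t.startswith(("Ev", "Po")) for t in taxa_with)
        assert any(t.startswith("S1") for t in taxa_with)

    def test_simulated_cds_translate_without_internal_stops(self, small_cohort):
        for taxon, models in small_cohort.annotations.items():
            seqs = {r.id: r.seq for r in small_cohort.genomes[taxon]}
            for m in models:
                prot = translate_cds(m.spliced_cds(seqs[m.scaffold]))
                assert "*" not in prot, m.gene_id

    def test_proteome_matches_cds_translation(self, small_cohort):
        for taxon, models in small_cohort.annotations.items():
            seqs = {r.id: r.seq for r in small_cohort.genomes[taxon]}
            prots = {r.id: r.seq for r in small_cohort.proteomes[taxon]}
            for m in models:
                assert translate_cds(m.spliced_cds(seqs[m.scaffold])) == prots[m.gene_id]

    def test_planted_loci_outside_gene_models(self, small_cohort):
        for p in small_cohort.truth.planted_pseudogenes:
            for m in small_cohort.annotations[p.taxon]:
                assert not p.location.overlaps(m.span)

    def test_planted_counts_poisson_calibrated(self):
        """Per-group planted totals track Poisson(rate x genes) within 3
        sigma of the mean over replicate seeds."""
        n_seeds = 8
        cfg0 = make_config()
        rate = cfg0.pseudogene_rate
        genes = cfg0.n_families * cfg0.genes_per_family_per_taxon
        totals = {g: [] for g in cfg0.taxa_per_group}
        for seed in range(n_seeds):
            cohort = simulate_cohort(make_config(seed=100 + seed))
            for g in totals:
                totals[g].append(
                    sum(
                        1
                        for p in cohort.truth.planted_pseudogenes
                        if cohort.config.group_of(p.taxon) == g
                    )
                )
        for g, counts in totals.items():
            lam = rate[g] * genes * cfg0.taxa_per_group[g]
            mean = np.mean(counts)
            se = np.sqrt(lam / n_seeds)
            assert abs(mean - lam) < 3 * se + 1e-9, (g, mean, lam)

    def test_shared_repeat_kmers_in_every_taxon(self, small_cohort):
        """Planted repeat k-mers are core by construction."""
        k = small_cohort.config.k_shared_repeat
        from oracles import naive_kmer_set

        rep_kmers = None
        for taxon, genome in small_cohort.genomes.items():
            seqs = {r.id: r.seq for r in genome}
            rep_seqs = [
                seqs[iv.scaffold][iv.start : iv.end]
                for iv in small_cohort.truth.repeat_intervals[taxon]
            ]
            kmers = naive_kmer_set(rep_seqs, k)
            rep_kmers = kmers if rep_kmers is None else rep_kmers & kmers
            genome_kmers = naive_kmer_set([r.seq for r in genome], k)
            assert kmers <= genome_kmers
        assert rep_kmers  # the shared library is non-empty in every taxon

    def test_infeasible_packing_reports_sizes(self):
        cfg = make_config(genome_length=5_000)
        with pytest.raises(ValueError, match="pack"):
            simulate_cohort(cfg)

    def test_group_parameter_maps_validated(self):
        with pytest.raises(ValueError, match="labels"):
            CohortConfig(gc_target={"Ev": 0.5})
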